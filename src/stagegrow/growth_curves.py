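"""von Bertalanffy growth curves for a biphasic (larval/adult) life history.

All functions are pure and vectorised: scalar or array inputs are accepted,
lengths are in mm, times in years, rates per year.  Curves return the analytic
value unclamped — a larval length for ``t < t0`` is negative by construction;
clamping (if any) belongs to the observation layer, not here.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "larval_length",
    "length_at_metamorphosis",
    "adult_length",
    "adult_length_at_recapture",
    "age_at_length_larval",
    "WEEKS_PER_YEAR",
]

#: Reporting conversion only; the model works in years throughout.
WEEKS_PER_YEAR = 52.18


def _check_finite(**kwargs) -> None:
    for name, value in kwargs.items():
        if not np.all(np.isfinite(value)):
            raise ValueError(f"non-finite value for {name!r}")


def larval_length(t, L_inf, k_L, t0):
    """Length at known age ``t`` for an aquatic larva.

    L(t) = L_inf * (1 - exp(-k_L * (t - t0)))

    Parameters
    ----------
    t : age in years (age 0 = pond filling / hatch).
    L_inf : asymptotic length, mm; must be positive.
    k_L : larval Brody growth coefficient, per year; must be positive.
    t0 : theoretical age at length zero, years.
    """
    _check_finite(t=t, L_inf=L_inf, k_L=k_L, t0=t0)
    if np.any(np.asarray(L_inf) <= 0) or np.any(np.asarray(k_L) <= 0):
        raise ValueError("L_inf and k_L must be positive")
    t = np.asarray(t, dtype=float)
    out = L_inf * -np.expm1(-k_L * (t - t0))
    return out if out.ndim else float(out)


def length_at_metamorphosis(t_m, L_inf, k_L, t0):
    """Length at metamorphosis: the larval curve evaluated at age ``t_m``."""
    return larval_length(t_m, L_inf, k_L, t0)


def adult_length(t, t_m, L_tm, L_inf, k_A, t0):
    """Length at age ``t`` for a terrestrial adult.

    L(t) = L_inf - (L_inf - L_tm) * exp(-k_A * (t - (t_m + t0)))

    The curve starts at the length at metamorphosis ``L_tm`` (reached at age
    ``t_m + t0`` on the shifted clock) and relaxes toward ``L_inf`` at rate
    ``k_A``.
    """
    _check_finite(t=t, t_m=t_m, L_tm=L_tm, L_inf=L_inf, k_A=k_A, t0=t0)
    if np.any(np.asarray(k_A) <= 0):
        raise ValueError("k_A must be positive")
    if np.any(np.asarray(L_inf) < np.asarray(L_tm)):
        raise ValueError("L_inf must be >= L_tm")
    t = np.asarray(t, dtype=float)
    out = L_inf - (L_inf - L_tm) * np.exp(-k_A * (t - (t_m + t0)))
    return out if out.ndim else float(out)


def adult_length_at_recapture(t, dt, t_m, L_tm, L_inf, k_A, t0):
    """Adult length at a recapture ``dt`` years after first capture at age ``t``."""
    if np.any(np.asarray(dt) < 0):
        raise ValueError("dt must be non-negative")
    return adult_length(np.asarray(t, dtype=float) + dt, t_m, L_tm, L_inf, k_A, t0)


def age_at_length_larval(L, L_inf, k_L, t0):
    """Analytic inverse of :func:`larval_length`.

    t(L) = t0 - ln(1 - L / L_inf) / k_L

    Raises for ``L >= L_inf`` (no finite age reaches the asymptote).
    """
    _check_finite(L=L, L_inf=L_inf, k_L=k_L, t0=t0)
    if np.any(np.asarray(L) >= np.asarray(L_inf)):
        raise ValueError("L must be strictly below L_inf")
    L = np.asarray(L, dtype=float)
    out = t0 - np.log1p(-L / L_inf) / k_L
    return out if out.ndim else float(out)
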