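"""Derived ecological quantities computed from posterior draws.

These are the headline outputs of the fitted growth model: the larval time
to the size threshold for metamorphosis, first-year adult growth, the
predicted adult age distribution (hence a longevity proxy), and the
population growth curve with credible and posterior-predictive bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .growth_curves import (
    WEEKS_PER_YEAR,
    adult_length,
    age_at_length_larval,
    larval_length,
    length_at_metamorphosis,
)
from .mcmc import PosteriorSamples
from .model_spec import latent_age_log_density

__all__ = ["ReportBundle", "compute_derived"]

#: population-mean age at metamorphosis used for the display curve
_TM_MID = 0.45
#: adult age distribution support (years): youngest possible adult to t_max
_AGE_SUPPORT = (0.2, 20.0)


@dataclass
class ReportBundle:
    """Derived quantities with equal-tailed 95% credible intervals."""

    time_to_threshold_weeks: dict
    first_year_adult_growth_mm: dict
    n_draws_excluded: int
    age_grid: np.ndarray
    age_density: np.ndarray
    age_quantiles: dict
    curve_ages: np.ndarray
    curve_mean: np.ndarray
    curve_band_mean: np.ndarray
    curve_band_predictive: np.ndarray
    threshold_mm: float = 35.0
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "threshold_mm": self.threshold_mm,
            "time_to_threshold_weeks": self.time_to_threshold_weeks,
            "first_year_adult_growth_mm": self.first_year_adult_growth_mm,
            "n_draws_excluded": self.n_draws_excluded,
            "age_distribution": {
                "grid_years": self.age_grid.tolist(),
                "density": self.age_density.tolist(),
                "quantiles": self.age_quantiles,
            },
            "growth_curve": {
                "age_years": self.curve_ages.tolist(),
                "mean": self.curve_mean.tolist(),
                "band_mean_95": self.curve_band_mean.tolist(),
                "band_predictive_95": self.curve_band_predictive.tolist(),
            },
            **self.extras,
        }


def _mean_cri(x: np.ndarray) -> dict:
    lo, hi = np.percentile(x, [2.5, 97.5])
    return {"mean": float(np.mean(x)), "lo95": float(lo), "hi95": float(hi)}


def _mean_ltm_over_prior(mu, kl, t0, lo=0.2, hi=0.7):
    """Population-mean length at metamorphosis, tm averaged over U(lo, hi).

    Closed form: Linf * (1 - exp(kl*t0) * (exp(-kl*lo) - exp(-kl*hi)) / (kl*(hi-lo))).
    """
    return mu * (
        1.0 - np.exp(kl * t0) * (np.exp(-kl * lo) - np.exp(-kl * hi)) / (kl * (hi - lo))
    )


def _population_curve(ages, mu, kl, ka, t0):
    """Biphasic display curve: larval to tm = 0.45 yr, adult beyond."""
    ltm = length_at_metamorphosis(_TM_MID, mu, kl, t0)
    larval = larval_length(ages, mu, kl, t0)
    adult = adult_length(ages, _TM_MID, ltm, mu, ka, t0)
    return np.where(ages <= _TM_MID + t0, larval, adult)


def compute_derived(
    samples: PosteriorSamples,
    threshold_mm: float = 35.0,
    rng: np.random.Generator | None = None,
    n_age_grid: int = 801,
    curve_max_age: float = 13.0,
) -> ReportBundle:
    """Compute all derived quantities, one value per retained draw.

    Draws with an asymptote at or below ``threshold_mm`` never reach the
    threshold; they are excluded from the time-to-threshold summary and
    counted in ``n_draws_excluded``.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    mu = samples.pooled("mu_Linf")
    kl = samples.pooled("k_larval")
    ka = samples.pooled("k_adult")
    t0 = samples.pooled("t0")
    alpha = samples.pooled("alpha")
    s2t = samples.pooled("sigma2_t")
    s2l = samples.pooled("sigma2_L")

    ok = mu > threshold_mm
    n_excluded = int(np.sum(~ok))
    if not np.any(ok):
        raise ValueError("no draw has an asymptote above the threshold")
    t_thresh = (
        age_at_length_larval(threshold_mm, mu[ok], kl[ok], t0[ok]) * WEEKS_PER_YEAR
    )
    t_thresh = np.atleast_1d(t_thresh)

    ltm_bar = _mean_ltm_over_prior(mu, kl, t0)
    first_year = (mu - ltm_bar) * -np.expm1(-ka)

    # predicted adult age distribution: truncated lognormal per draw, averaged
    lo, hi = _AGE_SUPPORT
    grid = np.linspace(lo, hi, n_age_grid)
    dens = np.zeros_like(grid)
    for d in range(mu.size):
        dens += np.exp(
            latent_age_log_density(grid, alpha[d], s2t[d], lo, hi)
        )
    dens /= mu.size
    dens /= np.trapezoid(dens, grid)
    cdf = np.concatenate([[0.0], np.cumsum((dens[1:] + dens[:-1]) / 2 * np.diff(grid))])
    cdf /= cdf[-1]
    q = {
        "q2.5": float(np.interp(0.025, cdf, grid)),
        "q50": float(np.interp(0.5, cdf, grid)),
        "mean": float(np.trapezoid(grid * dens, grid)),
        "q97.5": float(np.interp(0.975, cdf, grid)),
    }

    ages = np.linspace(0.0, curve_max_age, 261)
    curves = np.stack(
        [_population_curve(ages, mu[d], kl[d], ka[d], t0[d]) for d in range(mu.size)]
    )
    noise = np.sqrt(s2l)[:, None] * rng.standard_normal(curves.shape)
    band_mean = np.percentile(curves, [2.5, 97.5], axis=0)
    band_pred = np.percentile(curves + noise, [2.5, 97.5], axis=0)

    return ReportBundle(
        time_to_threshold_weeks=_mean_cri(t_thresh),
        first_year_adult_growth_mm=_mean_cri(first_year),
        n_draws_excluded=n_excluded,
        age_grid=grid,
        age_density=dens,
        age_quantiles=q,
        curve_ages=ages,
        curve_mean=curves.mean(axis=0),
        curve_band_mean=band_mean,
        curve_band_predictive=band_pred,
        threshold_mm=threshold_mm,
    )
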