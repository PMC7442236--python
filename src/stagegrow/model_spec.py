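"""Joint probability model: priors, latent distributions, likelihoods, posterior.

The model ties three observation streams to one biphasic von Bertalanffy
curve.  Eight population-level parameters are estimated:

====================  =====================================================
``mu_Linf``           population mean asymptotic length (mm)
``sigma2_Linf``       between-individual variance of the asymptote (mm^2)
``k_larval``          larval growth rate (per year)
``k_adult``           adult growth rate (per year)
``t0``                theoretical age at length zero (years)
``alpha``             median adult age at first capture (years)
``sigma2_t``          variance of log age at first capture
``sigma2_L``          observation variance (mm^2), shared across stages
====================  =====================================================

Latent variables: an age at metamorphosis ``tm ~ U(0.2, 0.7)`` for every
metamorph and every adult, an age at first capture per adult from a lognormal
with median ``alpha`` truncated to ``(tm_i, t_max)``, and a per-adult
asymptote ``Linf_i ~ N(mu_Linf, sigma2_Linf)`` truncated below at that
individual's length at metamorphosis.  Larvae and metamorphs use the
population-mean asymptote directly: without repeated larval measures,
individual heterogeneity is identifiable only in the adult stage.

Gamma priors use the shape-rate convention.  Latent-variable densities are
booked in :func:`log_prior` (hierarchical prior), not in the likelihoods.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING

import numpy as np
from scipy.special import gammaln, log_ndtr

from .growth_curves import larval_length, length_at_metamorphosis

if TYPE_CHECKING:  # pragma: no cover
    from .data_model import AdultCaptureHistory, Dataset, LarvalRecord, MetamorphRecord

__all__ = [
    "PopulationParameters",
    "LatentState",
    "PriorSpec",
    "ModelState",
    "default_priors",
    "latent_age_log_density",
    "log_prior",
    "log_lik_larvae",
    "log_lik_metamorphs",
    "log_lik_adults",
    "log_posterior",
]

_LOG_2PI = float(np.log(2.0 * np.pi))

POPULATION_PARAM_NAMES = (
    "mu_Linf",
    "sigma2_Linf",
    "k_larval",
    "k_adult",
    "t0",
    "alpha",
    "sigma2_t",
    "sigma2_L",
)


@dataclass(frozen=True)
class PopulationParameters:
    mu_Linf: float
    sigma2_Linf: float
    k_larval: float
    k_adult: float
    t0: float
    alpha: float
    sigma2_t: float
    sigma2_L: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in POPULATION_PARAM_NAMES])

    @classmethod
    def from_array(cls, arr) -> "PopulationParameters":
        return cls(**dict(zip(POPULATION_PARAM_NAMES, map(float, arr))))


@dataclass
class LatentState:
    """Per-individual latent quantities (empty arrays when a stream is empty)."""

    tm_metamorph: np.ndarray = field(default_factory=lambda: np.empty(0))
    tm_adult: np.ndarray = field(default_factory=lambda: np.empty(0))
    age_first_capture: np.ndarray = field(default_factory=lambda: np.empty(0))
    Linf_individual: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self):
        self.tm_metamorph = np.asarray(self.tm_metamorph, dtype=float)
        self.tm_adult = np.asarray(self.tm_adult, dtype=float)
        self.age_first_capture = np.asarray(self.age_first_capture, dtype=float)
        self.Linf_individual = np.asarray(self.Linf_individual, dtype=float)
        n = len(self.tm_adult)
        if len(self.age_first_capture) != n or len(self.Linf_individual) != n:
            raise ValueError("adult latent vectors must share one length")

    def copy(self) -> "LatentState":
        return LatentState(
            self.tm_metamorph.copy(),
            self.tm_adult.copy(),
            self.age_first_capture.copy(),
            self.Linf_individual.copy(),
        )


@dataclass
class ModelState:
    params: PopulationParameters
    latents: LatentState

    def copy(self) -> "ModelState":
        return ModelState(self.params, self.latents.copy())


@dataclass(frozen=True)
class PriorSpec:
    """Hyperparameters of every prior; defaults reproduce the fitted model.

    Uniform priors are (lower, upper) pairs; gamma priors are (shape, rate).
    """

    mu_Linf: tuple[float, float] = (30.0, 100.0)
    t0: tuple[float, float] = (-2.0, 2.0)
    alpha: tuple[float, float] = (0.5, 20.0)
    k_larval: tuple[float, float] = (0.1, 0.1)
    k_adult: tuple[float, float] = (0.1, 0.1)
    sigma2_t: tuple[float, float] = (0.1, 0.1)
    sigma2_L: tuple[float, float] = (0.1, 0.1)
    sigma2_Linf: tuple[float, float] = (0.1, 0.1)
    tm_bounds: tuple[float, float] = (0.2, 0.7)
    t_max: float = 20.0

    UNIFORM_PARAMS = ("mu_Linf", "t0", "alpha")
    GAMMA_PARAMS = ("k_larval", "k_adult", "sigma2_t", "sigma2_L", "sigma2_Linf")

    def to_dict(self) -> dict:
        return {
            **{n: list(getattr(self, n)) for n in self.UNIFORM_PARAMS},
            **{n: list(getattr(self, n)) for n in self.GAMMA_PARAMS},
            "tm_bounds": list(self.tm_bounds),
            "t_max": self.t_max,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PriorSpec":
        kwargs = {}
        for key, value in d.items():
            kwargs[key] = tuple(value) if isinstance(value, (list, tuple)) else value
        return cls(**kwargs)


def default_priors() -> PriorSpec:
    """The vague priors under which the model was originally fitted."""
    return PriorSpec()


# ---------------------------------------------------------------------------
# density helpers (vectorised, return -inf outside support)
# ---------------------------------------------------------------------------


def _uniform_logpdf(x, lo: float, hi: float):
    x = np.asarray(x, dtype=float)
    out = np.where((x >= lo) & (x <= hi), -np.log(hi - lo), -np.inf)
    return out if out.ndim else float(out)


def _gamma_logpdf(x, shape: float, rate: float):
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(
            x > 0,
            shape * np.log(rate) - gammaln(shape) + (shape - 1) * np.log(x) - rate * x,
            -np.inf,
        )
    return out if out.ndim else float(out)


def _normal_logpdf(x, mean, var):
    return -0.5 * (_LOG_2PI + np.log(var) + (np.asarray(x, dtype=float) - mean) ** 2 / var)


def _log_ndtr_diff(a, b):
    """log(Phi(b) - Phi(a)) for a < b, stable in both tails."""
    la, lb = log_ndtr(a), log_ndtr(b)
    with np.errstate(divide="ignore"):
        return lb + np.log1p(-np.exp(la - lb))


def latent_age_log_density(t, alpha, sigma2_t, lower, upper):
    """Log-density of a lognormal age with median ``alpha``, truncated.

    The untruncated distribution is ``log t ~ N(log(alpha), sigma2_t)``;
    mass is renormalised to ``[lower, upper]`` and the density is ``-inf``
    outside.  All arguments broadcast.
    """
    alpha = np.asarray(alpha, dtype=float)
    sigma2_t = np.asarray(sigma2_t, dtype=float)
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    if np.any(alpha <= 0) or np.any(sigma2_t <= 0):
        raise ValueError("alpha and sigma2_t must be positive")
    if np.any(lower <= 0) or np.any(lower >= upper):
        raise ValueError("require 0 < lower < upper")
    t = np.asarray(t, dtype=float)
    sd = np.sqrt(sigma2_t)
    mu = np.log(alpha)
    with np.errstate(divide="ignore", invalid="ignore"):
        logpdf = np.where(
            t > 0,
            -np.log(np.where(t > 0, t, 1.0))
            - 0.5 * (_LOG_2PI + np.log(sigma2_t))
            - (np.log(np.where(t > 0, t, 1.0)) - mu) ** 2 / (2 * sigma2_t),
            -np.inf,
        )
    log_mass = _log_ndtr_diff((np.log(lower) - mu) / sd, (np.log(upper) - mu) / sd)
    out = np.where((t >= lower) & (t <= upper), logpdf - log_mass, -np.inf)
    return out if out.ndim else float(out)


def _truncnorm_lower_logpdf(x, mean, var, lower):
    """Normal(mean, var) truncated below at ``lower``; -inf at or below it."""
    sd = np.sqrt(var)
    log_mass = log_ndtr((mean - lower) / sd)  # log P(X > lower)
    out = np.where(
        np.asarray(x, dtype=float) > lower,
        _normal_logpdf(x, mean, var) - log_mass,
        -np.inf,
    )
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# prior / likelihood / posterior
# ---------------------------------------------------------------------------


def _population_log_prior(p: PopulationParameters, priors: PriorSpec) -> float:
    total = 0.0
    for name in PriorSpec.UNIFORM_PARAMS:
        lo, hi = getattr(priors, name)
        total += _uniform_logpdf(getattr(p, name), lo, hi)
    for name in PriorSpec.GAMMA_PARAMS:
        shape, rate = getattr(priors, name)
        total += _gamma_logpdf(getattr(p, name), shape, rate)
    return float(total)


def log_prior(state: ModelState, priors: PriorSpec) -> float:
    """Sum of population-parameter and latent-variable log prior densities."""
    p, lat = state.params, state.latents
    total = _population_log_prior(p, priors)
    if not np.isfinite(total):
        return -np.inf
    lo, hi = priors.tm_bounds
    for tm in (lat.tm_metamorph, lat.tm_adult):
        if tm.size:
            total += float(np.sum(_uniform_logpdf(tm, lo, hi)))
    if lat.tm_adult.size:
        if not np.isfinite(total):
            return -np.inf
        # age at first capture: lognormal truncated to (tm_i, t_max)
        if np.any(lat.tm_adult >= priors.t_max):
            return -np.inf
        total += float(
            np.sum(
                latent_age_log_density(
                    lat.age_first_capture, p.alpha, p.sigma2_t,
                    lat.tm_adult, priors.t_max,
                )
            )
        )
        # individual asymptote, truncated below at length at metamorphosis
        ltm = length_at_metamorphosis(lat.tm_adult, p.mu_Linf, p.k_larval, p.t0)
        total += float(
            np.sum(
                _truncnorm_lower_logpdf(
                    lat.Linf_individual, p.mu_Linf, p.sigma2_Linf, ltm
                )
            )
        )
    return float(total) if np.isfinite(total) else -np.inf


def _loglik_larvae_arrays(ages, svl, mu_Linf, k_larval, t0, sigma2_L):
    mean = larval_length(ages, mu_Linf, k_larval, t0)
    return _normal_logpdf(svl, mean, sigma2_L)


def log_lik_larvae(larvae: "list[LarvalRecord]", state: ModelState) -> float:
    """Gaussian length likelihood of known-age larvae on the larval curve."""
    if not larvae:
        return 0.0
    p = state.params
    ages = np.array([r.age_years for r in larvae])
    svl = np.array([r.svl_mm for r in larvae])
    return float(
        np.sum(_loglik_larvae_arrays(ages, svl, p.mu_Linf, p.k_larval, p.t0, p.sigma2_L))
    )


def _loglik_metamorphs_arrays(tm, svl, mu_Linf, k_larval, t0, sigma2_L):
    mean = length_at_metamorphosis(tm, mu_Linf, k_larval, t0)
    return _normal_logpdf(svl, mean, sigma2_L)


def log_lik_metamorphs(metamorphs: "list[MetamorphRecord]", state: ModelState) -> float:
    """Metamorph sizes on the larval curve evaluated at each latent ``tm``."""
    if len(metamorphs) != state.latents.tm_metamorph.size:
        raise ValueError(
            f"{len(metamorphs)} metamorph records but "
            f"{state.latents.tm_metamorph.size} tm latents"
        )
    if not metamorphs:
        return 0.0
    p = state.params
    svl = np.array([r.svl_mm for r in metamorphs])
    return float(
        np.sum(
            _loglik_metamorphs_arrays(
                state.latents.tm_metamorph, svl, p.mu_Linf, p.k_larval, p.t0, p.sigma2_L
            )
        )
    )


def _adult_occasion_means(
    occ_age, occ_idx, tm_adult, age_first, linf_ind, mu_Linf, k_larval, k_adult, t0
):
    """Predicted SVL for flattened occasions; ``occ_age = age_first[i] + dt``."""
    ltm = length_at_metamorphosis(tm_adult, mu_Linf, k_larval, t0)
    linf = linf_ind[occ_idx]
    return linf - (linf - ltm[occ_idx]) * np.exp(
        -k_adult * (occ_age - (tm_adult[occ_idx] + t0))
    )


def log_lik_adults(adults: "list[AdultCaptureHistory]", state: ModelState) -> float:
    """Adult capture-history likelihood on the individual's adult curve.

    Each occasion of individual ``i`` is Gaussian around the adult curve at
    age ``age_first_capture[i] + dt``, with the individual's asymptote and
    the population curve's length at that individual's metamorphosis.
    """
    lat = state.latents
    if len(adults) != lat.tm_adult.size:
        raise ValueError(
            f"{len(adults)} adult histories but {lat.tm_adult.size} latent triples"
        )
    if not adults:
        return 0.0
    p = state.params
    occ_idx = np.concatenate(
        [np.full(h.n_occasions, i) for i, h in enumerate(adults)]
    )
    occ_dt = np.concatenate(
        [[o.time_offset_years for o in h.occasions] for h in adults]
    )
    occ_svl = np.concatenate([[o.svl_mm for o in h.occasions] for h in adults])
    occ_age = lat.age_first_capture[occ_idx] + occ_dt
    mean = _adult_occasion_means(
        occ_age, occ_idx, lat.tm_adult, lat.age_first_capture, lat.Linf_individual,
        p.mu_Linf, p.k_larval, p.k_adult, p.t0,
    )
    return float(np.sum(_normal_logpdf(occ_svl, mean, p.sigma2_L)))


def log_posterior(state: ModelState, ds: "Dataset", priors: PriorSpec) -> float:
    """Unnormalised log posterior; ``-inf`` whenever any support is violated."""
    lp = log_prior(state, priors)
    if not np.isfinite(lp):
        return -np.inf
    lp += log_lik_larvae(ds.larvae, state)
    lp += log_lik_metamorphs(ds.metamorphs, state)
    lp += log_lik_adults(ds.adults, state)
    return float(lp) if np.isfinite(lp) else -np.inf
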