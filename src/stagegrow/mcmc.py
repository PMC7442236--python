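"""Adaptive componentwise Metropolis-within-Gibbs sampler.

Every scalar component — each of the eight population parameters and every
latent variable — gets its own random-walk Metropolis update on a transformed
scale (log for positive parameters, logit between prior bounds, shifted-log
above a moving lower bound) with the appropriate Jacobian correction, so
proposals always respect supports.  Proposal scales adapt toward a 0.44
acceptance rate during burn-in only (Robbins-Monro on the log scale) and are
frozen afterwards, preserving ergodicity of the post-burn-in kernel.

Latent vectors are updated element-wise but evaluated vectorised: latents of
different individuals are conditionally independent given the population
parameters, so a whole vector of proposals can be accepted or rejected
per element using only that element's likelihood and prior terms.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.special import expit, log_ndtr
from scipy.stats import truncnorm

from .data_model import Dataset
from .model_spec import (
    POPULATION_PARAM_NAMES,
    LatentState,
    ModelState,
    PopulationParameters,
    PriorSpec,
    _gamma_logpdf,
    _normal_logpdf,
    latent_age_log_density,
)
from .growth_curves import length_at_metamorphosis

__all__ = [
    "FitConfig",
    "PosteriorSamples",
    "InitializationError",
    "initialize_state",
    "mh_step",
    "run_mcmc",
    "ComponentwiseMetropolis",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


class InitializationError(RuntimeError):
    """No finite-posterior starting state found within the retry budget."""


@dataclass
class FitConfig:
    """MCMC protocol; the defaults are the full three-chain protocol."""

    n_chains: int = 3
    n_iter: int = 500_000
    n_burnin: int = 100_000
    thin: int = 100
    seed: int = 0
    adapt: bool = True
    target_accept: float = 0.44
    proposal_scale: float = 0.3
    store_latents: bool = True
    init_retries: int = 100

    def __post_init__(self):
        if not self.n_burnin < self.n_iter:
            raise ValueError("n_burnin must be < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_chains < 2:
            raise ValueError("n_chains must be >= 2 for convergence diagnostics")

    @property
    def n_retained(self) -> int:
        span = self.n_iter - self.n_burnin
        return -(-span // self.thin)  # ceil


@dataclass
class PosteriorSamples:
    """Thinned post-burn-in draws: shape (n_chains, n_retained, n_params)."""

    names: list[str]
    draws: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.draws = np.asarray(self.draws, dtype=float)
        if self.draws.ndim != 3 or self.draws.shape[2] != len(self.names):
            raise ValueError("draws must have shape (n_chains, n_retained, n_params)")
        self._index = {n: i for i, n in enumerate(self.names)}

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_retained(self) -> int:
        return self.draws.shape[1]

    def get(self, name: str) -> np.ndarray:
        """Per-chain draws of one parameter, shape (n_chains, n_retained)."""
        return self.draws[:, :, self._index[name]]

    def pooled(self, name: str) -> np.ndarray:
        return self.get(name).reshape(-1)

    def population_names(self) -> list[str]:
        return [n for n in self.names if n in POPULATION_PARAM_NAMES]

    def to_dataframe(self) -> pd.DataFrame:
        frames = []
        for c in range(self.n_chains):
            df = pd.DataFrame(self.draws[c], columns=self.names)
            df.insert(0, "iter", np.arange(self.n_retained))
            df.insert(0, "chain", c)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def save(self, draws_csv, provenance_json=None) -> None:
        self.to_dataframe().to_csv(draws_csv, index=False)
        if provenance_json is not None:
            with open(provenance_json, "w") as fh:
                json.dump(self.provenance, fh, indent=2)

    @classmethod
    def load(cls, draws_csv, provenance_json=None) -> "PosteriorSamples":
        df = pd.read_csv(draws_csv)
        names = [c for c in df.columns if c not in ("chain", "iter")]
        chains = sorted(df["chain"].unique())
        draws = np.stack(
            [df.loc[df["chain"] == c, names].to_numpy() for c in chains]
        )
        provenance = {}
        if provenance_json is not None:
            with open(provenance_json) as fh:
                provenance = json.load(fh)
        return cls(names=names, draws=draws, provenance=provenance)


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------


def _to_logit(x, lo, hi):
    u = (x - lo) / (hi - lo)
    return np.log(u) - np.log1p(-u)


def _from_logit(z, lo, hi):
    return lo + (hi - lo) * expit(z)


def _logit_logjac(x, lo, hi):
    return np.log(x - lo) + np.log(hi - x) - np.log(hi - lo)


# transform kind and affected cache components per population parameter
_POP_TRANSFORM = {
    "mu_Linf": "logit",
    "t0": "logit",
    "alpha": "logit",
    "sigma2_Linf": "log",
    "k_larval": "log",
    "k_adult": "log",
    "sigma2_t": "log",
    "sigma2_L": "log",
}
_POP_AFFECTS = {
    "mu_Linf": ("larv", "meta", "adult", "linf"),
    "k_larval": ("larv", "meta", "adult", "linf"),
    "t0": ("larv", "meta", "adult", "linf"),
    "k_adult": ("adult",),
    "sigma2_L": ("larv", "meta", "adult"),
    "alpha": ("age",),
    "sigma2_t": ("age",),
    "sigma2_Linf": ("linf",),
}


class _GrowthSampler:
    """One chain's state, caches, and update sweeps over the growth model."""

    def __init__(
        self,
        ds: Dataset,
        priors: PriorSpec,
        state: ModelState,
        rng: np.random.Generator,
        proposal_scale: float = 0.3,
        target_accept: float = 0.44,
    ):
        self.priors = priors
        self.rng = rng
        self.target = target_accept

        self.larv_age = np.array([r.age_years for r in ds.larvae])
        self.larv_svl = np.array([r.svl_mm for r in ds.larvae])
        self.meta_svl = np.array([r.svl_mm for r in ds.metamorphs])
        self.n_meta = len(ds.metamorphs)
        self.n_adult = len(ds.adults)
        if ds.adults:
            self.occ_idx = np.concatenate(
                [np.full(h.n_occasions, i) for i, h in enumerate(ds.adults)]
            )
            self.occ_dt = np.concatenate(
                [[o.time_offset_years for o in h.occasions] for h in ds.adults]
            )
            self.occ_svl = np.concatenate(
                [[o.svl_mm for o in h.occasions] for h in ds.adults]
            )
        else:
            self.occ_idx = np.empty(0, dtype=int)
            self.occ_dt = np.empty(0)
            self.occ_svl = np.empty(0)

        self.pop = {n: getattr(state.params, n) for n in POPULATION_PARAM_NAMES}
        lat = state.latents
        self.tm_m = lat.tm_metamorph.astype(float).copy()
        self.tm_a = lat.tm_adult.astype(float).copy()
        self.age = lat.age_first_capture.astype(float).copy()
        self.linf = lat.Linf_individual.astype(float).copy()

        # per-component proposal scales on the transformed scale
        ls = _safe_log(float(proposal_scale))
        self.log_scale_pop = {n: ls for n in POPULATION_PARAM_NAMES}
        self.log_scale_tm_m = np.full(self.n_meta, ls)
        self.log_scale_tm_a = np.full(self.n_adult, ls)
        self.log_scale_age = np.full(self.n_adult, ls)
        self.log_scale_linf = np.full(self.n_adult, ls)
        self.log_scale_joint = min(ls, np.log(0.1))  # ridge move starts small

        lo, hi = priors.tm_bounds
        self._lp_tm_const = -(self.n_meta + self.n_adult) * np.log(hi - lo)
        self._recompute_all()
        if not np.isfinite(self.log_post):
            raise ValueError("sampler requires a finite log posterior at the start")

    # -- cached component evaluation ------------------------------------

    def _comp_larv(self, pop) -> float:
        if self.larv_age.size == 0:
            return 0.0
        mean = pop["mu_Linf"] * -np.expm1(
            -pop["k_larval"] * (self.larv_age - pop["t0"])
        )
        return float(np.sum(_normal_logpdf(self.larv_svl, mean, pop["sigma2_L"])))

    def _comp_meta(self, pop, tm_m) -> np.ndarray:
        if self.n_meta == 0:
            return np.empty(0)
        mean = pop["mu_Linf"] * -np.expm1(-pop["k_larval"] * (tm_m - pop["t0"]))
        return _normal_logpdf(self.meta_svl, mean, pop["sigma2_L"])

    def _ltm(self, pop, tm_a) -> np.ndarray:
        return pop["mu_Linf"] * -np.expm1(-pop["k_larval"] * (tm_a - pop["t0"]))

    def _comp_adult(self, pop, tm_a, age, linf) -> np.ndarray:
        if self.n_adult == 0:
            return np.empty(0)
        ltm = self._ltm(pop, tm_a)
        occ_age = age[self.occ_idx] + self.occ_dt
        li = linf[self.occ_idx]
        mean = li - (li - ltm[self.occ_idx]) * np.exp(
            -pop["k_adult"] * (occ_age - (tm_a[self.occ_idx] + pop["t0"]))
        )
        lp = _normal_logpdf(self.occ_svl, mean, pop["sigma2_L"])
        return np.bincount(self.occ_idx, weights=lp, minlength=self.n_adult)

    def _comp_age(self, pop, tm_a, age) -> np.ndarray:
        if self.n_adult == 0:
            return np.empty(0)
        return latent_age_log_density(
            age, pop["alpha"], pop["sigma2_t"], tm_a, self.priors.t_max
        )

    def _comp_linf(self, pop, tm_a, linf) -> np.ndarray:
        if self.n_adult == 0:
            return np.empty(0)
        ltm = self._ltm(pop, tm_a)
        sd = np.sqrt(pop["sigma2_Linf"])
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(
                linf > ltm,
                _normal_logpdf(linf, pop["mu_Linf"], pop["sigma2_Linf"])
                - log_ndtr((pop["mu_Linf"] - ltm) / sd),
                -np.inf,
            )
        return out

    def _pop_prior_term(self, name: str, value: float) -> float:
        if name in PriorSpec.UNIFORM_PARAMS:
            lo, hi = getattr(self.priors, name)
            return -np.log(hi - lo) if lo <= value <= hi else -np.inf
        shape, rate = getattr(self.priors, name)
        return float(_gamma_logpdf(value, shape, rate))

    def _recompute_all(self) -> None:
        self.c_larv = self._comp_larv(self.pop)
        self.c_meta = self._comp_meta(self.pop, self.tm_m)
        self.c_adult = self._comp_adult(self.pop, self.tm_a, self.age, self.linf)
        self.c_age = self._comp_age(self.pop, self.tm_a, self.age)
        self.c_linf = self._comp_linf(self.pop, self.tm_a, self.linf)
        self.c_pop_prior = sum(
            self._pop_prior_term(n, self.pop[n]) for n in POPULATION_PARAM_NAMES
        )

    @property
    def log_post(self) -> float:
        return float(
            self.c_larv
            + self.c_meta.sum()
            + self.c_adult.sum()
            + self.c_age.sum()
            + self.c_linf.sum()
            + self.c_pop_prior
            + self._lp_tm_const
        )

    # -- updates ---------------------------------------------------------

    def _update_pop(self, name: str) -> bool:
        pop = self.pop
        x = pop[name]
        scale = np.exp(self.log_scale_pop[name])
        kind = _POP_TRANSFORM[name]
        eps = scale * self.rng.standard_normal()
        if eps == 0.0:  # zero-scale proposal: exact identity
            x_new, d_jac = x, 0.0
        elif kind == "log":
            x_new = x * np.exp(eps)
            d_jac = np.log(x_new) - np.log(x)
        else:
            lo, hi = getattr(self.priors, name)
            z = _to_logit(x, lo, hi) + eps
            x_new = _from_logit(z, lo, hi)
            d_jac = _logit_logjac(x_new, lo, hi) - _logit_logjac(x, lo, hi)

        new_pop = dict(pop)
        new_pop[name] = x_new
        delta = self._pop_prior_term(name, x_new) - self._pop_prior_term(name, x)
        affected = _POP_AFFECTS[name]
        cand: dict[str, object] = {}
        if np.isfinite(delta):
            if "larv" in affected:
                cand["larv"] = self._comp_larv(new_pop)
                delta += cand["larv"] - self.c_larv
            if "meta" in affected:
                cand["meta"] = self._comp_meta(new_pop, self.tm_m)
                delta += cand["meta"].sum() - self.c_meta.sum()
            if "adult" in affected:
                cand["adult"] = self._comp_adult(new_pop, self.tm_a, self.age, self.linf)
                delta += cand["adult"].sum() - self.c_adult.sum()
            if "age" in affected:
                cand["age"] = self._comp_age(new_pop, self.tm_a, self.age)
                delta += cand["age"].sum() - self.c_age.sum()
            if "linf" in affected:
                cand["linf"] = self._comp_linf(new_pop, self.tm_a, self.linf)
                delta += cand["linf"].sum() - self.c_linf.sum()
            delta += d_jac

        accept = np.log(self.rng.random()) < delta
        if accept:
            self.pop = new_pop
            self.c_pop_prior += self._pop_prior_term(name, x_new) - self._pop_prior_term(
                name, x
            )
            for key, value in cand.items():
                setattr(self, f"c_{key}", value)
        self._last_delta = delta
        return bool(accept)

    def _update_tm_m(self) -> np.ndarray:
        if self.n_meta == 0:
            return np.empty(0, dtype=bool)
        lo, hi = self.priors.tm_bounds
        z = _to_logit(self.tm_m, lo, hi)
        eps = np.exp(self.log_scale_tm_m) * self.rng.standard_normal(self.n_meta)
        tm_new = np.where(eps == 0.0, self.tm_m, _from_logit(z + eps, lo, hi))
        cand = self._comp_meta(self.pop, tm_new)
        delta = (
            cand
            - self.c_meta
            + _logit_logjac(tm_new, lo, hi)
            - _logit_logjac(self.tm_m, lo, hi)
        )
        accept = np.log(self.rng.random(self.n_meta)) < delta
        self.tm_m[accept] = tm_new[accept]
        self.c_meta[accept] = cand[accept]
        self._last_delta_vec = delta
        return accept

    def _update_tm_a(self) -> np.ndarray:
        if self.n_adult == 0:
            return np.empty(0, dtype=bool)
        lo, hi = self.priors.tm_bounds
        z = _to_logit(self.tm_a, lo, hi)
        eps = np.exp(self.log_scale_tm_a) * self.rng.standard_normal(self.n_adult)
        tm_new = np.where(eps == 0.0, self.tm_a, _from_logit(z + eps, lo, hi))
        cand_adult = self._comp_adult(self.pop, tm_new, self.age, self.linf)
        cand_age = self._comp_age(self.pop, tm_new, self.age)
        cand_linf = self._comp_linf(self.pop, tm_new, self.linf)
        with np.errstate(invalid="ignore"):
            delta = (
                (cand_adult - self.c_adult)
                + (cand_age - self.c_age)
                + (cand_linf - self.c_linf)
                + _logit_logjac(tm_new, lo, hi)
                - _logit_logjac(self.tm_a, lo, hi)
            )
        delta = np.where(np.isnan(delta), -np.inf, delta)
        accept = np.log(self.rng.random(self.n_adult)) < delta
        self.tm_a[accept] = tm_new[accept]
        self.c_adult[accept] = cand_adult[accept]
        self.c_age[accept] = cand_age[accept]
        self.c_linf[accept] = cand_linf[accept]
        return accept

    def _update_age(self) -> np.ndarray:
        if self.n_adult == 0:
            return np.empty(0, dtype=bool)
        lo = self.tm_a
        hi = self.priors.t_max
        z = _to_logit(self.age, lo, hi)
        eps = np.exp(self.log_scale_age) * self.rng.standard_normal(self.n_adult)
        age_new = np.where(eps == 0.0, self.age, _from_logit(z + eps, lo, hi))
        cand_adult = self._comp_adult(self.pop, self.tm_a, age_new, self.linf)
        cand_age = self._comp_age(self.pop, self.tm_a, age_new)
        delta = (
            (cand_adult - self.c_adult)
            + (cand_age - self.c_age)
            + _logit_logjac(age_new, lo, hi)
            - _logit_logjac(self.age, lo, hi)
        )
        accept = np.log(self.rng.random(self.n_adult)) < delta
        self.age[accept] = age_new[accept]
        self.c_adult[accept] = cand_adult[accept]
        self.c_age[accept] = cand_age[accept]
        return accept

    def _update_linf(self) -> np.ndarray:
        if self.n_adult == 0:
            return np.empty(0, dtype=bool)
        bound = self._ltm(self.pop, self.tm_a)
        z = np.log(self.linf - bound)
        eps = np.exp(self.log_scale_linf) * self.rng.standard_normal(self.n_adult)
        z_new = z + eps
        linf_new = np.where(eps == 0.0, self.linf, bound + np.exp(z_new))
        cand_adult = self._comp_adult(self.pop, self.tm_a, self.age, linf_new)
        cand_linf = self._comp_linf(self.pop, self.tm_a, linf_new)
        delta = (
            (cand_adult - self.c_adult)
            + (cand_linf - self.c_linf)
            + np.where(eps == 0.0, 0.0, z_new - z)  # shifted-log Jacobian
        )
        accept = np.log(self.rng.random(self.n_adult)) < delta
        self.linf[accept] = linf_new[accept]
        self.c_adult[accept] = cand_adult[accept]
        self.c_linf[accept] = cand_linf[accept]
        return accept

    def _update_joint_ka_age(self) -> bool:
        """Joint scaling move along the k_adult / latent-age ridge.

        First-capture sizes pin down ``exp(-k_A (age_i - tm_i))`` per
        individual, so single-site updates cannot move ``k_A`` and the age
        vector together.  This move proposes ``k_A' = k_A e^eps`` while
        rescaling every age so that product is preserved
        (``age_i' = tm_i + e^{-eps} (age_i - tm_i)``), leaving all
        first-capture means invariant; only recapture terms and the age
        prior change.  Deterministic-map MH: |det J| = e^{(1-n) eps}.
        """
        if self.n_adult == 0:
            return False
        eps = np.exp(self.log_scale_joint) * self.rng.standard_normal()
        if eps == 0.0:
            return True
        ka_new = self.pop["k_adult"] * np.exp(eps)
        age_new = self.tm_a + np.exp(-eps) * (self.age - self.tm_a)
        new_pop = dict(self.pop)
        new_pop["k_adult"] = ka_new
        cand_adult = self._comp_adult(new_pop, self.tm_a, age_new, self.linf)
        cand_age = self._comp_age(new_pop, self.tm_a, age_new)
        d_prior = self._pop_prior_term("k_adult", ka_new) - self._pop_prior_term(
            "k_adult", self.pop["k_adult"]
        )
        delta = (
            cand_adult.sum()
            - self.c_adult.sum()
            + cand_age.sum()
            - self.c_age.sum()
            + d_prior
            + (1 - self.n_adult) * eps
        )
        accept = np.log(self.rng.random()) < delta
        if accept:
            self.pop = new_pop
            self.age = age_new
            self.c_adult = cand_adult
            self.c_age = cand_age
            self.c_pop_prior += d_prior
        return bool(accept)

    def sweep(self, adapt: bool = False, step: int = 1) -> dict:
        """One full sweep over all components; optionally adapt scales."""
        gamma = (step + 10.0) ** -0.6 if adapt else 0.0
        flags: dict[str, object] = {}
        for name in POPULATION_PARAM_NAMES:
            acc = self._update_pop(name)
            flags[name] = acc
            if adapt:
                self.log_scale_pop[name] = float(
                    np.clip(
                        self.log_scale_pop[name] + gamma * (float(acc) - self.target),
                        -8.0,
                        4.0,
                    )
                )
        for key, update, scales in (
            ("tm_metamorph", self._update_tm_m, "log_scale_tm_m"),
            ("tm_adult", self._update_tm_a, "log_scale_tm_a"),
            ("age_first_capture", self._update_age, "log_scale_age"),
            ("Linf_individual", self._update_linf, "log_scale_linf"),
        ):
            acc = update()
            flags[key] = acc
            if adapt and acc.size:
                updated = getattr(self, scales) + gamma * (
                    acc.astype(float) - self.target
                )
                setattr(self, scales, np.clip(updated, -8.0, 4.0))
        acc = self._update_joint_ka_age()
        flags["joint_k_adult_age"] = acc
        if adapt and self.n_adult:
            self.log_scale_joint = float(
                np.clip(
                    self.log_scale_joint + gamma * (float(acc) - self.target),
                    -8.0,
                    4.0,
                )
            )
        return flags

    def state(self) -> ModelState:
        return ModelState(
            params=PopulationParameters(**self.pop),
            latents=LatentState(
                tm_metamorph=self.tm_m.copy(),
                tm_adult=self.tm_a.copy(),
                age_first_capture=self.age.copy(),
                Linf_individual=self.linf.copy(),
            ),
        )

    def draw_vector(self, store_latents: bool) -> np.ndarray:
        parts = [np.array([self.pop[n] for n in POPULATION_PARAM_NAMES])]
        if store_latents:
            parts += [self.tm_m, self.tm_a, self.age, self.linf]
        return np.concatenate(parts)


def parameter_names(ds: Dataset, store_latents: bool = True) -> list[str]:
    names = list(POPULATION_PARAM_NAMES)
    if store_latents:
        names += [f"tm_metamorph[{j}]" for j in range(len(ds.metamorphs))]
        names += [f"tm_adult[{i}]" for i in range(len(ds.adults))]
        names += [f"age_first_capture[{i}]" for i in range(len(ds.adults))]
        names += [f"Linf_individual[{i}]" for i in range(len(ds.adults))]
    return names


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def initialize_state(
    priors: PriorSpec, ds: Dataset, rng: np.random.Generator, retries: int = 100
) -> ModelState:
    """Draw an overdispersed starting state with a finite log posterior.

    Population parameters are drawn uniformly over ranges much wider than any
    plausible posterior (but narrower than the vaguest prior supports, so
    short burn-ins remain practical); latent ages come from the lognormal
    clipped into its truncation interval.
    """
    from .model_spec import log_posterior  # local to avoid cycle at import

    n_meta, n_adult = len(ds.metamorphs), len(ds.adults)
    lo_tm, hi_tm = priors.tm_bounds
    for _ in range(retries):
        params = PopulationParameters(
            mu_Linf=rng.uniform(40.0, 80.0),
            sigma2_Linf=rng.uniform(0.5, 8.0),
            k_larval=rng.uniform(0.3, 3.0),
            k_adult=rng.uniform(0.3, 3.0),
            t0=rng.uniform(-0.5, 0.5),
            alpha=rng.uniform(2.0, 8.0),
            sigma2_t=rng.uniform(0.1, 1.0),
            sigma2_L=rng.uniform(0.5, 8.0),
        )
        tm_m = rng.uniform(lo_tm, hi_tm, n_meta)
        tm_a = rng.uniform(lo_tm, hi_tm, n_adult)
        raw_age = np.exp(
            np.log(params.alpha) + np.sqrt(params.sigma2_t) * rng.standard_normal(n_adult)
        )
        age = np.clip(raw_age, tm_a + 0.05, priors.t_max - 0.05)
        ltm = length_at_metamorphosis(tm_a, params.mu_Linf, params.k_larval, params.t0)
        sd = np.sqrt(params.sigma2_Linf)
        a_std = (ltm - params.mu_Linf) / sd
        linf = truncnorm.rvs(
            a_std, np.inf, loc=params.mu_Linf, scale=sd, size=n_adult, random_state=rng
        )
        state = ModelState(
            params=params,
            latents=LatentState(
                tm_metamorph=tm_m,
                tm_adult=tm_a,
                age_first_capture=age,
                Linf_individual=linf,
            ),
        )
        if np.isfinite(log_posterior(state, ds, priors)):
            return state
    raise InitializationError(
        f"no finite-posterior starting state after {retries} attempts"
    )


def mh_step(
    state: ModelState,
    ds: Dataset,
    priors: PriorSpec,
    scales: float | dict,
    rng: np.random.Generator,
) -> tuple[ModelState, dict]:
    """One non-adaptive Metropolis-within-Gibbs sweep from ``state``.

    ``scales`` is either a single proposal scale applied to every component
    or a dict with keys among the population parameter names plus
    ``tm_metamorph``, ``tm_adult``, ``age_first_capture``, ``Linf_individual``.
    Returns the new state and per-component acceptance flags (booleans for
    population parameters, boolean arrays for latent vectors).
    """
    base = scales if np.isscalar(scales) else 0.3
    sampler = _GrowthSampler(ds, priors, state, rng, proposal_scale=float(base))
    if isinstance(scales, dict):
        for name, value in scales.items():
            if name in sampler.log_scale_pop:
                sampler.log_scale_pop[name] = _safe_log(value)
            elif name == "tm_metamorph":
                sampler.log_scale_tm_m[:] = _safe_log(value)
            elif name == "tm_adult":
                sampler.log_scale_tm_a[:] = _safe_log(value)
            elif name == "age_first_capture":
                sampler.log_scale_age[:] = _safe_log(value)
            elif name == "Linf_individual":
                sampler.log_scale_linf[:] = _safe_log(value)
            else:
                raise KeyError(f"unknown proposal-scale component {name!r}")
    elif np.isscalar(scales):
        value = _safe_log(scales)
        for name in sampler.log_scale_pop:
            sampler.log_scale_pop[name] = value
        sampler.log_scale_tm_m[:] = value
        sampler.log_scale_tm_a[:] = value
        sampler.log_scale_age[:] = value
        sampler.log_scale_linf[:] = value
    flags = sampler.sweep(adapt=False)
    return sampler.state(), flags


def _safe_log(value) -> float:
    return float(np.log(value)) if value > 0 else -np.inf  # exp(-inf) == 0.0


def _data_fingerprint(ds: Dataset) -> str:
    h = hashlib.sha256()
    h.update(
        json.dumps(
            {
                "n_larvae": len(ds.larvae),
                "n_metamorphs": len(ds.metamorphs),
                "n_adults": len(ds.adults),
                "svl_sum": float(
                    sum(r.svl_mm for r in ds.larvae)
                    + sum(r.svl_mm for r in ds.metamorphs)
                    + sum(o.svl_mm for hh in ds.adults for o in hh.occasions)
                ),
            },
            sort_keys=True,
        ).encode()
    )
    return h.hexdigest()[:16]


def run_mcmc(
    ds: Dataset,
    priors: PriorSpec,
    config: FitConfig,
    progress: Callable[[str], None] | None = None,
) -> PosteriorSamples:
    """Run ``config.n_chains`` independent adaptive chains and pool the draws.

    Proposal scales adapt during burn-in only and are frozen afterwards; the
    chains use per-chain substreams of one master seed, so results are fully
    reproducible.
    """
    names = parameter_names(ds, config.store_latents)
    children = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    all_draws = np.empty((config.n_chains, config.n_retained, len(names)))
    report_every = max(1, config.n_iter // 20)
    for c, child in enumerate(children):
        rng = np.random.default_rng(child)
        state = initialize_state(priors, ds, rng, retries=config.init_retries)
        sampler = _GrowthSampler(
            ds,
            priors,
            state,
            rng,
            proposal_scale=config.proposal_scale,
            target_accept=config.target_accept,
        )
        kept = 0
        for it in range(config.n_iter):
            adapting = config.adapt and it < config.n_burnin
            sampler.sweep(adapt=adapting, step=it + 1)
            if it >= config.n_burnin and (it - config.n_burnin) % config.thin == 0:
                all_draws[c, kept] = sampler.draw_vector(config.store_latents)
                kept += 1
            if progress is not None and (it + 1) % report_every == 0:
                progress(
                    f"chain {c}: iteration {it + 1}/{config.n_iter} "
                    f"(log posterior {sampler.log_post:.1f})"
                )
        assert kept == config.n_retained
    provenance = {
        "config": asdict(config),
        "seed": config.seed,
        "data_fingerprint": _data_fingerprint(ds),
        "store_latents": config.store_latents,
    }
    return PosteriorSamples(names=names, draws=all_draws, provenance=provenance)


# ---------------------------------------------------------------------------
# generic kernel (used for known-target checks and prior-only stubs)
# ---------------------------------------------------------------------------


class ComponentwiseMetropolis:
    """Adaptive componentwise random-walk Metropolis on an unconstrained vector.

    A minimal generic kernel targeting an arbitrary ``logpdf``; used to verify
    the sampling machinery against analytically known targets.
    """

    def __init__(
        self,
        logpdf: Callable[[np.ndarray], float],
        x0,
        scale: float = 0.5,
        target_accept: float = 0.44,
        rng: np.random.Generator | None = None,
    ):
        self.logpdf = logpdf
        self.x = np.asarray(x0, dtype=float).copy()
        self.d = self.x.size
        self.log_scale = np.full(self.d, np.log(scale))
        self.target = target_accept
        self.rng = rng if rng is not None else np.random.default_rng()
        self.lp = float(logpdf(self.x))
        if not np.isfinite(self.lp):
            raise ValueError("logpdf must be finite at x0")

    def run(
        self, n_iter: int, n_burnin: int = 0, thin: int = 1, adapt: bool = True
    ) -> np.ndarray:
        kept = []
        for it in range(n_iter):
            adapting = adapt and it < n_burnin
            gamma = (it + 11.0) ** -0.6 if adapting else 0.0
            for j in range(self.d):
                prop = self.x.copy()
                prop[j] += np.exp(self.log_scale[j]) * self.rng.standard_normal()
                lp_new = float(self.logpdf(prop))
                acc = np.log(self.rng.random()) < lp_new - self.lp
                if acc:
                    self.x = prop
                    self.lp = lp_new
                if adapting:
                    self.log_scale[j] = np.clip(
                        self.log_scale[j] + gamma * (float(acc) - self.target),
                        -8.0,
                        4.0,
                    )
            if it >= n_burnin and (it - n_burnin) % thin == 0:
                kept.append(self.x.copy())
        return np.asarray(kept)
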