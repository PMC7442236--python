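"""Convergence diagnostics, posterior summaries, posterior-predictive checks.

PSRF is the classic (non-split) Gelman-Rubin statistic to match the
WinBUGS-era convention; a split-chain variant is available behind a flag.
The multivariate PSRF follows Brooks & Gelman.  Effective sample size uses
Geyer's initial-positive-sequence truncation of the autocorrelation function,
summed across chains.  Bayesian p-values compare a chi-square-type
discrepancy (sum of squared Pearson residuals) between observed and
posterior-replicated data, separately for larval sizes and adult
between-occasion growth increments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import eigh

from .data_model import Dataset
from .growth_curves import larval_length, length_at_metamorphosis
from .mcmc import PosteriorSamples

__all__ = [
    "psrf",
    "multivariate_psrf",
    "effective_sample_size",
    "bayesian_pvalue",
    "summarize",
    "diagnostics_report",
    "DegenerateChainError",
]


class DegenerateChainError(ValueError):
    """Chains with zero within-chain variance admit no convergence statistic."""


def _as_chain_matrix(chains) -> np.ndarray:
    arr = np.asarray(chains, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected shape (n_chains, n_draws)")
    m, n = arr.shape
    if m < 2:
        raise ValueError("need at least 2 chains")
    if n < 2:
        raise ValueError("need at least 2 draws per chain")
    return arr


def _split(arr: np.ndarray) -> np.ndarray:
    n = arr.shape[1] // 2
    return np.concatenate([arr[:, :n], arr[:, n : 2 * n]], axis=0)


def psrf(chains, split: bool = False) -> float:
    """Gelman-Rubin potential scale reduction factor for one parameter.

    R-hat = sqrt(((n-1)/n * W + B/n) / W) with W the mean within-chain
    variance and B the between-chain variance of means (times n).
    """
    arr = _as_chain_matrix(chains)
    if split:
        arr = _split(arr)
    m, n = arr.shape
    within = arr.var(axis=1, ddof=1)
    w = within.mean()
    if w == 0:
        raise DegenerateChainError("zero within-chain variance")
    b = n * arr.mean(axis=1).var(ddof=1)
    return float(np.sqrt(((n - 1) / n * w + b / n) / w))


def multivariate_psrf(chains) -> float:
    """Brooks-Gelman multivariate PSRF over a matrix of parameters.

    ``chains`` has shape (n_chains, n_draws, n_params).  MPSRF =
    sqrt((n-1)/n + (m+1)/m * lambda1) with lambda1 the largest eigenvalue
    of W^-1 B / n.
    """
    arr = np.asarray(chains, dtype=float)
    if arr.ndim != 3:
        raise ValueError("expected shape (n_chains, n_draws, n_params)")
    m, n, p = arr.shape
    if m < 2:
        raise ValueError("need at least 2 chains")
    if p >= n:
        raise ValueError("parameter count must be below draws per chain")
    w = np.zeros((p, p))
    for c in range(m):
        w += np.cov(arr[c].T, ddof=1).reshape(p, p)
    w /= m
    means = arr.mean(axis=1)
    b_over_n = np.cov(means.T, ddof=1).reshape(p, p)
    try:
        lam = eigh(b_over_n, w, eigvals_only=True)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular within-chain covariance; select a parameter subset"
        ) from exc
    lam1 = float(lam[-1])
    return float(np.sqrt((n - 1) / n + (m + 1) / m * lam1))


def _ess_one_chain(x: np.ndarray) -> float:
    n = x.size
    x = x - x.mean()
    # autocovariance via FFT
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n].real / n
    if acov[0] <= 0:
        raise DegenerateChainError("constant chain")
    rho = acov / acov[0]
    # Geyer initial positive sequence: Gamma_k = rho_{2k} + rho_{2k+1},
    # tau = -1 + 2 * sum of leading positive Gamma_k
    total = 0.0
    k = 0
    while 2 * k + 1 < n:
        g = rho[2 * k] + rho[2 * k + 1]
        if g <= 0:
            break
        total += g
        k += 1
    tau = max(-1.0 + 2.0 * total, 1.0 / n)
    return n / tau


def effective_sample_size(chains) -> float:
    """ESS via initial-positive-sequence truncation, summed across chains."""
    arr = _as_chain_matrix(chains)
    return float(sum(_ess_one_chain(row) for row in arr))


# ---------------------------------------------------------------------------
# posterior predictive checks
# ---------------------------------------------------------------------------


def _adult_increment_arrays(ds: Dataset):
    """Flattened successive-occasion pairs: (individual, dt_a, dt_b, svl_a, svl_b)."""
    idx, dt_a, dt_b, svl_a, svl_b = [], [], [], [], []
    for i, h in enumerate(ds.adults):
        for a, b in zip(h.occasions, h.occasions[1:]):
            idx.append(i)
            dt_a.append(a.time_offset_years)
            dt_b.append(b.time_offset_years)
            svl_a.append(a.svl_mm)
            svl_b.append(b.svl_mm)
    return (
        np.asarray(idx, dtype=int),
        np.asarray(dt_a),
        np.asarray(dt_b),
        np.asarray(svl_a),
        np.asarray(svl_b),
    )


def bayesian_pvalue(
    samples: PosteriorSamples,
    ds: Dataset,
    stage: str,
    rng: np.random.Generator,
) -> float:
    """Posterior predictive p-value for one stage's goodness of fit.

    For each retained draw the discrepancy ``D = sum(((obs - mean)/sigma_L)^2)``
    is computed for the observed data and for a replicate simulated from that
    draw; the p-value is the fraction of draws with ``D_rep > D_obs`` (ties
    count one half).  Values near 0.5 indicate an adequate observation model.

    ``stage`` is ``"larval"`` (lengths of known-age larvae) or
    ``"adult_increments"`` (successive-occasion growth increments, which
    sidestep the unknown age at first capture entering both occasions).
    """
    if samples.n_retained == 0:
        raise ValueError("empty posterior samples")
    mu = samples.pooled("mu_Linf")
    kl = samples.pooled("k_larval")
    t0 = samples.pooled("t0")
    s2l = samples.pooled("sigma2_L")
    n_draws = mu.size

    if stage == "larval":
        if not ds.larvae:
            raise ValueError("no larval data")
        ages = np.array([r.age_years for r in ds.larvae])
        svl = np.array([r.svl_mm for r in ds.larvae])
        d_obs = np.empty(n_draws)
        d_rep = np.empty(n_draws)
        for d in range(n_draws):
            mean = larval_length(ages, mu[d], kl[d], t0[d])
            sd = np.sqrt(s2l[d])
            d_obs[d] = np.sum(((svl - mean) / sd) ** 2)
            rep = mean + sd * rng.standard_normal(mean.size)
            d_rep[d] = np.sum(((rep - mean) / sd) ** 2)
    elif stage == "adult_increments":
        idx, dt_a, dt_b, svl_a, svl_b = _adult_increment_arrays(ds)
        if idx.size == 0:
            raise ValueError("no adult recapture increments")
        needed = [f"tm_adult[{idx[0]}]"]
        if needed[0] not in samples.names:
            raise ValueError(
                "adult-increment p-value needs latent draws (store_latents=True)"
            )
        n_adult = sum(1 for n in samples.names if n.startswith("tm_adult["))
        tm = np.stack(
            [samples.pooled(f"tm_adult[{i}]") for i in range(n_adult)], axis=1
        )
        age = np.stack(
            [samples.pooled(f"age_first_capture[{i}]") for i in range(n_adult)], axis=1
        )
        linf = np.stack(
            [samples.pooled(f"Linf_individual[{i}]") for i in range(n_adult)], axis=1
        )
        ka = samples.pooled("k_adult")
        obs_inc = svl_b - svl_a
        d_obs = np.empty(n_draws)
        d_rep = np.empty(n_draws)
        for d in range(n_draws):
            ltm = length_at_metamorphosis(tm[d], mu[d], kl[d], t0[d])
            li = linf[d][idx]
            base = age[d][idx] - (tm[d][idx] + t0[d])
            mean_a = li - (li - ltm[idx]) * np.exp(-ka[d] * (base + dt_a))
            mean_b = li - (li - ltm[idx]) * np.exp(-ka[d] * (base + dt_b))
            mean_inc = mean_b - mean_a
            sd = np.sqrt(s2l[d])
            d_obs[d] = np.sum(((obs_inc - mean_inc) / sd) ** 2)
            rep_a = mean_a + sd * rng.standard_normal(mean_a.size)
            rep_b = mean_b + sd * rng.standard_normal(mean_b.size)
            d_rep[d] = np.sum((((rep_b - rep_a) - mean_inc) / sd) ** 2)
    else:
        raise ValueError(f"unknown stage {stage!r}")

    return float(np.mean(d_rep > d_obs) + 0.5 * np.mean(d_rep == d_obs))


# ---------------------------------------------------------------------------
# summaries and report
# ---------------------------------------------------------------------------


def summarize(samples: PosteriorSamples, parameters: list[str] | None = None) -> pd.DataFrame:
    """Posterior mean and equal-tailed 95% credible interval, pooled chains."""
    if samples.n_retained == 0:
        raise ValueError("empty posterior samples")
    names = parameters if parameters is not None else samples.names
    rows = []
    for name in names:
        x = samples.pooled(name)
        lo, hi = np.percentile(x, [2.5, 97.5])
        rows.append(
            {"parameter": name, "mean": float(x.mean()), "lo95": float(lo), "hi95": float(hi)}
        )
    return pd.DataFrame(rows).set_index("parameter")


@dataclass
class DiagnosticsReport:
    psrf: dict
    multivariate_psrf: float
    ess: dict
    bayes_p_larval: float | None
    bayes_p_adult_increments: float | None

    def to_dict(self) -> dict:
        return {
            "psrf": self.psrf,
            "multivariate_psrf": self.multivariate_psrf,
            "ess": self.ess,
            "bayes_p_larval": self.bayes_p_larval,
            "bayes_p_adult_increments": self.bayes_p_adult_increments,
        }


def diagnostics_report(
    samples: PosteriorSamples,
    ds: Dataset | None = None,
    rng: np.random.Generator | None = None,
    parameters: list[str] | None = None,
) -> DiagnosticsReport:
    """PSRF/ESS for the population parameters plus goodness-of-fit p-values.

    The multivariate PSRF is computed over the population parameters only
    (latent blocks would make W singular at realistic draw counts).  P-values
    require the dataset; they are ``None`` when it is not supplied.
    """
    names = parameters if parameters is not None else samples.population_names()
    r = {n: psrf(samples.get(n)) for n in names}
    ess = {n: effective_sample_size(samples.get(n)) for n in names}
    mats = np.stack(
        [np.stack([samples.get(n)[c] for n in names], axis=1) for c in range(samples.n_chains)]
    )
    mpsrf = multivariate_psrf(mats)
    p_larv = p_adult = None
    if ds is not None:
        rng = rng if rng is not None else np.random.default_rng(0)
        if ds.larvae:
            p_larv = bayesian_pvalue(samples, ds, "larval", rng)
        has_incr = any(h.n_occasions >= 2 for h in ds.adults)
        latents_stored = any(n.startswith("tm_adult[") for n in samples.names)
        if has_incr and latents_stored:
            p_adult = bayesian_pvalue(samples, ds, "adult_increments", rng)
    return DiagnosticsReport(
        psrf=r,
        multivariate_psrf=mpsrf,
        ess=ess,
        bayes_p_larval=p_larv,
        bayes_p_adult_increments=p_adult,
    )
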