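"""PSRF/MPSRF/ESS against brute-force oracles; p-values; posterior summaries."""

import numpy as np
import pytest

import stagegrow as sg
from stagegrow.diagnostics import DegenerateChainError


def _brute_psrf(arr):
    # independent textbook evaluation of the Gelman-Rubin formula
    m, n = arr.shape
    chain_means = arr.mean(axis=1)
    w = np.mean([np.var(arr[c], ddof=1) for c in range(m)])
    b = n * np.var(chain_means, ddof=1)
    return np.sqrt(((n - 1) / n * w + b / n) / w)


def test_psrf_identical_chains():
    chain = np.random.default_rng(0).normal(size=500)
    arr = np.stack([chain, chain])
    n = 500
    assert sg.psrf(arr) == pytest.approx(np.sqrt((n - 1) / n), abs=1e-12)


def test_psrf_separated_chains():
    rng = np.random.default_rng(1)
    arr = np.stack([rng.normal(0, 1, 500), rng.normal(10, 1, 500)])
    assert sg.psrf(arr) > 3


def test_psrf_iid_chains_near_one():
    rng = np.random.default_rng(2)
    arr = rng.normal(size=(3, 5000))
    assert sg.psrf(arr) < 1.05


def test_psrf_matches_brute_force_oracle():
    rng = np.random.default_rng(3)
    arr = rng.normal(0, 1, size=(4, 300)) + rng.normal(0, 0.3, size=(4, 1))
    assert sg.psrf(arr) == pytest.approx(_brute_psrf(arr), rel=1e-12)


def test_psrf_degenerate():
    arr = np.ones((2, 100))
    with pytest.raises(DegenerateChainError):
        sg.psrf(arr)


def test_mpsrf_identical_chains():
    rng = np.random.default_rng(4)
    chain = rng.normal(size=(400, 3))
    arr = np.stack([chain, chain, chain])
    n = 400
    assert sg.multivariate_psrf(arr) == pytest.approx(np.sqrt((n - 1) / n), abs=1e-9)


def test_mpsrf_reduces_to_psrf_up_to_chain_factor():
    # with one parameter, MPSRF^2 - (n-1)/n = (m+1)/m * (PSRF^2 - (n-1)/n)
    rng = np.random.default_rng(5)
    arr = rng.normal(size=(3, 800)) + rng.normal(0, 0.2, size=(3, 1))
    m, n = arr.shape
    mp = sg.multivariate_psrf(arr[:, :, None])
    r = sg.psrf(arr)
    lhs = mp**2 - (n - 1) / n
    rhs = (m + 1) / m * (r**2 - (n - 1) / n)
    assert lhs == pytest.approx(rhs, abs=1e-9)


def test_mpsrf_matches_eigen_oracle():
    rng = np.random.default_rng(6)
    m, n, p = 3, 500, 2
    arr = rng.normal(size=(m, n, p)) @ np.array([[1.0, 0.4], [0.0, 0.8]])
    arr += rng.normal(0, 0.15, size=(m, 1, p))
    w = sum(np.cov(arr[c].T, ddof=1) for c in range(m)) / m
    b_over_n = np.cov(arr.mean(axis=1).T, ddof=1)
    lam = np.max(np.linalg.eigvals(np.linalg.inv(w) @ b_over_n).real)
    expected = np.sqrt((n - 1) / n + (m + 1) / m * lam)
    assert sg.multivariate_psrf(arr) == pytest.approx(expected, rel=1e-9)


def test_ess_iid():
    rng = np.random.default_rng(7)
    arr = rng.normal(size=(3, 4000))
    ess = sg.effective_sample_size(arr)
    assert 0.8 * 12_000 <= ess <= 1.2 * 12_000


def test_ess_ar1():
    # AR(1) with phi = 0.9 has asymptotic ESS = n (1-phi)/(1+phi)
    rng = np.random.default_rng(8)
    phi, n = 0.9, 20_000
    chains = []
    for _ in range(2):
        x = np.empty(n)
        x[0] = rng.normal()
        eps = rng.normal(size=n) * np.sqrt(1 - phi**2)
        for i in range(1, n):
            x[i] = phi * x[i - 1] + eps[i]
        chains.append(x)
    ess = sg.effective_sample_size(np.stack(chains))
    expected = 2 * n * (1 - phi) / (1 + phi)
    assert expected / 1.5 <= ess <= expected * 1.5


def test_ess_constant_chain():
    with pytest.raises(DegenerateChainError):
        sg.effective_sample_size(np.ones((2, 100)))


# --------------------------------------------------------------- p-values


def _larval_samples(sigma2_L, n_draws=50):
    names = ["mu_Linf", "k_larval", "k_adult", "t0", "alpha",
             "sigma2_t", "sigma2_L", "sigma2_Linf"]
    vals = dict(mu_Linf=59.0, k_larval=1.77, k_adult=0.91, t0=0.0,
                alpha=4.5, sigma2_t=0.25, sigma2_L=sigma2_L, sigma2_Linf=5.0)
    draws = np.tile([vals[n] for n in names], (2, n_draws, 1))
    return sg.PosteriorSamples(names=names, draws=draws)


class _EchoRng:
    """Fake generator whose 'noise' reproduces the observed residuals."""

    def __init__(self, z):
        self._z = z

    def standard_normal(self, size):
        return self._z[:size]


def test_pvalue_ties_count_half(small_dataset):
    ds, truth = small_dataset
    samples = _larval_samples(truth["params"]["sigma2_L"])
    ages = np.array([r.age_years for r in ds.larvae])
    svl = np.array([r.svl_mm for r in ds.larvae])
    mean = sg.larval_length(ages, 59.0, 1.77, 0.0)
    z = (svl - mean) / np.sqrt(truth["params"]["sigma2_L"])
    p = sg.bayesian_pvalue(samples, ds, "larval", _EchoRng(z))
    assert p == 0.5


def test_pvalue_inflated_replicate_variance(small_dataset):
    ds, _ = small_dataset
    # draws claim an observation variance 100x the truth: replicates are much
    # more dispersed than the data, so D_rep dominates D_obs
    samples = _larval_samples(sigma2_L=400.0)
    p = sg.bayesian_pvalue(samples, ds, "larval", np.random.default_rng(0))
    assert p > 0.95


def test_pvalue_order_invariance(small_dataset):
    ds, truth = small_dataset
    samples = _larval_samples(truth["params"]["sigma2_L"])
    p1 = sg.bayesian_pvalue(samples, ds, "larval", np.random.default_rng(3))
    shuffled = sg.Dataset(
        larvae=list(np.random.default_rng(0).permutation(np.array(ds.larvae, dtype=object))),
        metamorphs=ds.metamorphs,
        adults=ds.adults,
    )
    p2 = sg.bayesian_pvalue(samples, shuffled, "larval", np.random.default_rng(3))
    assert p1 == p2


def test_pvalue_requires_data():
    samples = _larval_samples(4.0)
    with pytest.raises(ValueError):
        sg.bayesian_pvalue(samples, sg.Dataset(), "larval", np.random.default_rng(0))
    with pytest.raises(ValueError):
        sg.bayesian_pvalue(samples, sg.Dataset(), "bogus", np.random.default_rng(0))


# --------------------------------------------------------------- summaries


def test_summarize_constant_draws():
    names = ["a"]
    draws = np.full((2, 50, 1), 3.25)
    s = sg.summarize(sg.PosteriorSamples(names=names, draws=draws))
    assert s.loc["a", "mean"] == 3.25
    assert s.loc["a", "lo95"] == s.loc["a", "hi95"] == 3.25


def test_summarize_arithmetic_and_shift():
    draws = np.arange(1.0, 101.0).reshape(2, 50, 1)
    ps = sg.PosteriorSamples(names=["a"], draws=draws)
    s = sg.summarize(ps)
    assert s.loc["a", "mean"] == pytest.approx(50.5)
    shifted = sg.summarize(sg.PosteriorSamples(names=["a"], draws=draws + 7.0))
    assert shifted.loc["a", "mean"] == pytest.approx(57.5)


def test_summarize_percentile_oracle():
    rng = np.random.default_rng(9)
    draws = rng.normal(size=(3, 400, 1))
    s = sg.summarize(sg.PosteriorSamples(names=["a"], draws=draws))
    lo, hi = np.percentile(draws.reshape(-1), [2.5, 97.5])
    assert s.loc["a", "lo95"] == pytest.approx(lo)
    assert s.loc["a", "hi95"] == pytest.approx(hi)
    assert s.loc["a", "lo95"] <= s.loc["a", "hi95"]
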