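"""Priors, latent densities, stage likelihoods and the joint posterior."""

import numpy as np
import pytest
from scipy import integrate, stats

import stagegrow as sg
from stagegrow.model_spec import _population_log_prior

LOG_2PI = np.log(2 * np.pi)


def _flat_state(params, **latents):
    return sg.ModelState(params=params, latents=sg.LatentState(**latents))


@pytest.fixture()
def params():
    return sg.PopulationParameters(
        mu_Linf=59.0, sigma2_Linf=5.0, k_larval=1.77, k_adult=0.91,
        t0=0.0, alpha=4.5, sigma2_t=0.25, sigma2_L=4.0,
    )


# ----------------------------------------------------------------- priors


def test_default_priors_are_the_published_ones():
    pr = sg.default_priors()
    assert pr.mu_Linf == (30.0, 100.0)
    assert pr.t0 == (-2.0, 2.0)
    assert pr.alpha == (0.5, 20.0)
    for name in ("k_larval", "k_adult", "sigma2_t", "sigma2_L", "sigma2_Linf"):
        assert getattr(pr, name) == (0.1, 0.1)
    assert pr.tm_bounds == (0.2, 0.7)
    # shape-rate convention: Gamma(0.1, 0.1) has mean 1
    shape, rate = pr.k_larval
    assert shape / rate == 1.0


def test_prior_support(params):
    pr = sg.default_priors()
    state = _flat_state(params)
    base = sg.log_prior(state, pr)
    assert np.isfinite(base)
    # uniform density inside the bounds
    assert _population_log_prior(params, pr) == pytest.approx(
        np.log(1 / 70)
        + np.log(1 / 4)
        + np.log(1 / 19.5)
        + sum(
            stats.gamma.logpdf(getattr(params, n), 0.1, scale=10.0)
            for n in ("k_larval", "k_adult", "sigma2_t", "sigma2_L", "sigma2_Linf")
        ),
        abs=1e-10,
    )
    # t0 outside U(-2, 2)
    bad = sg.PopulationParameters(**{**params.__dict__, "t0": 2.5})
    assert sg.log_prior(_flat_state(bad), pr) == -np.inf
    bad = sg.PopulationParameters(**{**params.__dict__, "k_adult": -0.1})
    assert sg.log_prior(_flat_state(bad), pr) == -np.inf


# ------------------------------------------------------- latent age density


def test_latent_age_outside_support():
    assert sg.latent_age_log_density(20.1, 4.0, 0.25, 0.5, 20.0) == -np.inf
    assert sg.latent_age_log_density(0.4, 4.0, 0.25, 0.5, 20.0) == -np.inf


def test_latent_age_normalises_to_one():
    val, _ = integrate.quad(
        lambda t: np.exp(sg.latent_age_log_density(t, 4.0, 0.25, 0.5, 20.0)),
        0.5, 20.0, limit=200,
    )
    assert val == pytest.approx(1.0, abs=1e-6)


def test_latent_age_matches_quadrature_oracle():
    # independent oracle: scipy lognorm density renormalised by quadrature
    alpha, s2, lo, hi = 4.0, 0.25, 0.5, 20.0
    sd = np.sqrt(s2)
    dens = lambda t: stats.lognorm.pdf(t, sd, scale=alpha)
    mass, _ = integrate.quad(dens, lo, hi, limit=200)
    for t in (1.0, 4.0, 9.5):
        expected = np.log(dens(t) / mass)
        assert sg.latent_age_log_density(t, alpha, s2, lo, hi) == pytest.approx(
            expected, abs=1e-9
        )


def test_latent_age_bad_bounds():
    with pytest.raises(ValueError):
        sg.latent_age_log_density(1.0, 4.0, 0.25, 5.0, 2.0)


# ------------------------------------------------------------- likelihoods


def test_larvae_at_predicted_mean(params):
    rec = sg.LarvalRecord(
        wetland_id="W1",
        capture_date=__import__("datetime").date(2011, 1, 15),
        pond_fill_date=__import__("datetime").date(2010, 11, 1),
        svl_mm=sg.larval_length(75 / 365.25, 59.0, 1.77, 0.0),
    )
    state = _flat_state(params)
    expected = -0.5 * np.log(2 * np.pi * params.sigma2_L)
    assert sg.log_lik_larvae([rec], state) == pytest.approx(expected, abs=1e-10)
    # duplicating a record doubles the contribution
    assert sg.log_lik_larvae([rec, rec], state) == pytest.approx(2 * expected)


def test_larvae_per_record_oracle(params, small_dataset):
    ds, _ = small_dataset
    state = _flat_state(params)
    expected = sum(
        stats.norm.logpdf(
            r.svl_mm,
            sg.larval_length(r.age_years, params.mu_Linf, params.k_larval, params.t0),
            np.sqrt(params.sigma2_L),
        )
        for r in ds.larvae
    )
    assert sg.log_lik_larvae(ds.larvae, state) == pytest.approx(expected, rel=1e-12)


def test_metamorphs_empty_and_mismatch(params):
    assert sg.log_lik_metamorphs([], _flat_state(params)) == 0.0
    recs = [sg.MetamorphRecord("W1", 2011, 39.3)]
    with pytest.raises(ValueError):
        sg.log_lik_metamorphs(recs, _flat_state(params))  # no tm latent


def test_metamorphs_oracle(params):
    recs = [sg.MetamorphRecord("W1", 2011, 30.0), sg.MetamorphRecord("W1", 2011, 40.0)]
    tm = np.array([0.3, 0.6])
    state = _flat_state(params, tm_metamorph=tm)
    expected = sum(
        stats.norm.logpdf(
            r.svl_mm,
            sg.length_at_metamorphosis(t, params.mu_Linf, params.k_larval, params.t0),
            np.sqrt(params.sigma2_L),
        )
        for r, t in zip(recs, tm)
    )
    assert sg.log_lik_metamorphs(recs, state) == pytest.approx(expected, rel=1e-12)


def test_adults_occasion_oracle(params, small_dataset, true_state):
    ds, truth = small_dataset
    lat = truth["latents"]
    expected = 0.0
    for i, h in enumerate(ds.adults):
        ltm = sg.length_at_metamorphosis(
            lat["tm_adult"][i], params.mu_Linf, params.k_larval, params.t0
        )
        for occ in h.occasions:
            mean = sg.adult_length_at_recapture(
                lat["age_first_capture"][i], occ.time_offset_years,
                lat["tm_adult"][i], ltm, lat["Linf_individual"][i],
                params.k_adult, params.t0,
            )
            expected += stats.norm.logpdf(occ.svl_mm, mean, np.sqrt(params.sigma2_L))
    assert sg.log_lik_adults(ds.adults, true_state) == pytest.approx(expected, rel=1e-10)


def test_adults_additivity(params):
    from datetime import date

    h2 = sg.AdultCaptureHistory(
        "A1", date(2011, 11, 1),
        (sg.CaptureOccasion(0.0, 50.0), sg.CaptureOccasion(1.0, 53.0)),
    )
    lat = dict(
        tm_adult=[0.45], age_first_capture=[4.0], Linf_individual=[60.0]
    )
    state = _flat_state(params, **lat)
    h_first = sg.AdultCaptureHistory("A1", date(2011, 11, 1), (h2.occasions[0],))
    ll_first = sg.log_lik_adults([h_first], state)
    ll_both = sg.log_lik_adults([h2], state)
    # the second occasion adds its own Gaussian term
    ltm = sg.length_at_metamorphosis(0.45, params.mu_Linf, params.k_larval, params.t0)
    mean2 = sg.adult_length_at_recapture(4.0, 1.0, 0.45, ltm, 60.0, params.k_adult, params.t0)
    assert ll_both - ll_first == pytest.approx(
        stats.norm.logpdf(53.0, mean2, np.sqrt(params.sigma2_L)), rel=1e-10
    )


def test_adult_single_occasion_at_mean(params):
    from datetime import date

    ltm = sg.length_at_metamorphosis(0.45, params.mu_Linf, params.k_larval, params.t0)
    mean = sg.adult_length(4.0, 0.45, ltm, 60.0, params.k_adult, params.t0)
    h = sg.AdultCaptureHistory(
        "A1", date(2011, 11, 1), (sg.CaptureOccasion(0.0, mean),)
    )
    state = _flat_state(
        params, tm_adult=[0.45], age_first_capture=[4.0], Linf_individual=[60.0]
    )
    assert sg.log_lik_adults([h], state) == pytest.approx(
        -0.5 * np.log(2 * np.pi * params.sigma2_L), abs=1e-10
    )


# --------------------------------------------------------------- posterior


def test_log_prior_term_by_term(params):
    pr = sg.default_priors()
    state = _flat_state(
        params,
        tm_metamorph=[0.3, 0.5],
        tm_adult=[0.45],
        age_first_capture=[4.0],
        Linf_individual=[60.0],
    )
    ltm = sg.length_at_metamorphosis(0.45, params.mu_Linf, params.k_larval, params.t0)
    sd = np.sqrt(params.sigma2_Linf)
    expected = (
        _population_log_prior(params, pr)
        + 3 * np.log(1 / 0.5)  # three uniform tm latents
        + sg.latent_age_log_density(4.0, params.alpha, params.sigma2_t, 0.45, 20.0)
        + stats.truncnorm.logpdf(
            60.0, (ltm - params.mu_Linf) / sd, np.inf,
            loc=params.mu_Linf, scale=sd,
        )
    )
    assert sg.log_prior(state, pr) == pytest.approx(expected, rel=1e-10)


def test_log_prior_latent_support(params):
    pr = sg.default_priors()
    # an adult younger than its age at metamorphosis is impossible
    state = _flat_state(
        params, tm_adult=[0.6], age_first_capture=[0.4], Linf_individual=[60.0]
    )
    assert sg.log_prior(state, pr) == -np.inf
    # individual asymptote below the length at metamorphosis is impossible
    state = _flat_state(
        params, tm_adult=[0.6], age_first_capture=[4.0], Linf_individual=[20.0]
    )
    assert sg.log_prior(state, pr) == -np.inf


def test_log_posterior_decomposes(params, small_dataset, true_state):
    ds, _ = small_dataset
    pr = sg.default_priors()
    total = sg.log_posterior(true_state, ds, pr)
    assert np.isfinite(total)
    assert total == pytest.approx(
        sg.log_prior(true_state, pr)
        + sg.log_lik_larvae(ds.larvae, true_state)
        + sg.log_lik_metamorphs(ds.metamorphs, true_state)
        + sg.log_lik_adults(ds.adults, true_state),
        rel=1e-12,
    )


def test_log_posterior_empty_dataset_is_prior(params):
    pr = sg.default_priors()
    state = _flat_state(params)
    assert sg.log_posterior(state, sg.Dataset(), pr) == pytest.approx(
        sg.log_prior(state, pr)
    )


def test_log_posterior_out_of_support(params, small_dataset):
    ds, _ = small_dataset
    pr = sg.default_priors()
    bad = sg.PopulationParameters(**{**params.__dict__, "sigma2_L": -1.0})
    n_m, n_a = len(ds.metamorphs), len(ds.adults)
    state = _flat_state(
        bad,
        tm_metamorph=np.full(n_m, 0.45),
        tm_adult=np.full(n_a, 0.45),
        age_first_capture=np.full(n_a, 4.0),
        Linf_individual=np.full(n_a, 60.0),
    )
    assert sg.log_posterior(state, ds, pr) == -np.inf


def test_likelihood_order_invariance(params, small_dataset, true_state):
    ds, _ = small_dataset
    shuffled = list(ds.larvae)
    np.random.default_rng(0).shuffle(shuffled)
    assert sg.log_lik_larvae(shuffled, true_state) == pytest.approx(
        sg.log_lik_larvae(ds.larvae, true_state), rel=1e-12
    )
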