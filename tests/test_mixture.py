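import math

import numpy as np
import pytest
from scipy import stats

import mitofibre as mf
from mitofibre.mixture import (McmcConfig, ModelParams, fit_model,
                               log_unnormalized_posterior,
                               membership_probability)


def _tiny_instance(seed=1):
    truth = mf.sample_ground_truth(seed=seed, k=3, pi=0.3)
    data, _ = mf.generate_dataset(truth, n_per_subject=[3, 3, 3], seed=seed + 1)
    prior = mf.PriorSpec(am=1.0, ac=0.0, g=2.0, h=0.1)
    params = ModelParams(m=np.array([1.0, 0.9, 0.8]),
                         c=np.array([0.1, -0.1, 0.0]),
                         tau=20.0, mu_m=1.0, mu_c=0.0,
                         tau_m=40.0, tau_c=60.0, pi=0.2)
    return data, prior, params


def _exhaustive_oracle(params, data, prior):
    """Independent evaluation via scipy densities, summing over both Z
    assignments per patient fibre explicitly."""
    p = params
    tot = 0.0
    for i, s in enumerate(data.controls):
        tot += stats.norm.logpdf(s.y, p.m[i] * s.x + p.c[i],
                                 1 / math.sqrt(p.tau)).sum()
    pat = data.patient
    for xj, yj in zip(pat.x, pat.y):
        mu = p.m[-1] * xj + p.c[-1]
        lik = ((1 - p.pi) * stats.norm.pdf(yj, mu, 1 / math.sqrt(p.tau))
               + p.pi * stats.norm.pdf(yj, mu,
                                       1 / math.sqrt(prior.gamma_fixed)))
        tot += math.log(lik)
    a = prior.slope_lower
    for mi in p.m:
        tot += stats.truncnorm.logpdf(
            mi, (a - p.mu_m) * math.sqrt(p.tau_m), np.inf,
            loc=p.mu_m, scale=1 / math.sqrt(p.tau_m))
    tot += stats.norm.logpdf(p.c, p.mu_c, 1 / math.sqrt(p.tau_c)).sum()
    tot += stats.norm.logpdf(p.mu_m, prior.am, math.sqrt(prior.bm))
    tot += stats.norm.logpdf(p.mu_c, prior.ac, math.sqrt(prior.bc))
    tot += stats.gamma.logpdf(p.tau, prior.g, scale=1 / prior.h)
    tot += stats.gamma.logpdf(p.tau_m, prior.gm, scale=1 / prior.hm)
    tot += stats.gamma.logpdf(p.tau_c, prior.gc, scale=1 / prior.hc)
    tot += stats.uniform.logpdf(p.pi, prior.pi_lower,
                                prior.pi_upper - prior.pi_lower)
    return tot


def test_marginal_likelihood_matches_exhaustive_z_sum():
    data, prior, params = _tiny_instance()
    val = log_unnormalized_posterior(params, data, prior)
    assert val == pytest.approx(_exhaustive_oracle(params, data, prior),
                                abs=1e-10)


def test_log_posterior_fibre_order_invariance_and_support():
    data, prior, params = _tiny_instance()
    val = log_unnormalized_posterior(params, data, prior)
    rng = np.random.default_rng(0)
    shuffled = []
    for s in data.subjects:
        idx = rng.permutation(s.n)
        shuffled.append(mf.SubjectBlock(s.subject_id, s.subject_type,
                                        s.fibre_ids[idx], s.x[idx], s.y[idx]))
    data2 = mf.MitoDataset(data.mass_channel, data.oxphos_channel, shuffled,
                           logged=True)
    assert log_unnormalized_posterior(params, data2, prior) == pytest.approx(
        val, abs=1e-12)
    # off-support states return -inf
    import dataclasses

    bad = dataclasses.replace(params, pi=0.7)
    assert log_unnormalized_posterior(bad, data, prior) == -np.inf
    bad = dataclasses.replace(params, m=np.array([1.0, 0.9, 0.05]))
    assert log_unnormalized_posterior(bad, data, prior) == -np.inf


def test_identical_components_make_pi_irrelevant():
    data, prior, params = _tiny_instance()
    import dataclasses

    prior_eq = dataclasses.replace(prior, gamma_fixed=params.tau)
    vals = [log_unnormalized_posterior(dataclasses.replace(params, pi=p),
                                       data, prior_eq)
            for p in (0.05, 0.2, 0.45)]
    assert vals[0] == pytest.approx(vals[1], abs=1e-10)
    assert vals[1] == pytest.approx(vals[2], abs=1e-10)


def test_membership_probability_degenerate_and_oracle():
    # identical components -> returns pi exactly
    assert membership_probability(1.3, 0.7, 1.0, 0.0, 25.0, 25.0, 0.37) \
        == pytest.approx(0.37, abs=1e-14)
    assert membership_probability(5.0, 1.0, 1.0, 0.0, 25.0, 1e-4, 0.0) == 0.0
    assert membership_probability(5.0, 1.0, 1.0, 0.0, 25.0, 1e-4, 1.0) == 1.0
    # direct high-precision density-ratio evaluation
    tau, gamma, pi = 25.0, 1e-4, 0.2
    m_k, c_k, x = 1.1, -0.3, 2.0
    y = m_k * x + c_k + 20 / math.sqrt(tau)
    f1 = stats.norm.pdf(y, m_k * x + c_k, 1 / math.sqrt(gamma))
    f0 = stats.norm.pdf(y, m_k * x + c_k, 1 / math.sqrt(tau))
    expected = pi * f1 / ((1 - pi) * f0 + pi * f1)
    assert membership_probability(y, x, m_k, c_k, tau, gamma, pi) \
        == pytest.approx(expected, abs=1e-12)


def test_membership_monotone_in_residual_magnitude():
    resid = np.linspace(0, 3, 50)
    p = membership_probability(resid, np.zeros_like(resid), 0.0, 0.0,
                               25.0, 1e-4, 0.2)
    assert (np.diff(p) >= 0).all()
    assert ((p >= 0) & (p <= 1)).all()


def test_draw_support_constraints(fitted):
    post = fitted.posterior
    prior = fitted.draws.prior
    assert ((post["pi"] >= prior.pi_lower) & (post["pi"] <= prior.pi_upper)).all()
    assert (post["m"] >= prior.slope_lower).all()
    assert (post["tau"] > 0).all()
    # membership probabilities only exist for patient fibres
    assert fitted.membership.shape[1] == fitted.model.dataset.patient.n
    assert ((fitted.membership >= 0) & (fitted.membership <= 1)).all()


def test_parameter_recovery_on_synthetic_data(fitted, small_truth, small_dataset):
    _, labels = small_dataset
    post = fitted.posterior
    lo, hi = mf.hdi(post["pi"], 0.95, support=(0, 0.5))
    assert lo <= small_truth.pi <= hi
    for i in range(small_truth.k):
        mean = post["m"][:, i].mean()
        sd = post["m"][:, i].std(ddof=1)
        assert abs(mean - small_truth.m[i]) < 3 * sd
    # classifications recover the true labels almost everywhere
    cls = fitted.classification()
    cm = mf.confusion_matrix(cls.label, labels)
    assert mf.misclassification_rate(cm) < 5.0


def test_summary_table_shape_and_content(fitted):
    table = fitted.summary()
    k = fitted.model.dataset.k
    assert len(table) == 6 + 2 * k
    assert {"mean", "sd", "hdi_2.5%", "hdi_97.5%", "ess", "r_hat"} <= set(
        table.columns)
    assert (table.loc["pi", "hdi_2.5%"] <= table.loc["pi", "mean"]
            <= table.loc["pi", "hdi_97.5%"])
    assert (table["ess"] > 0).all()


def test_zero_deficient_patient_yields_small_pi(healthy_patient_fit):
    _, _, res = healthy_patient_fit
    assert float(np.median(res.posterior["pi"])) < 0.05


def test_patient_with_few_fibres_warns():
    truth = mf.sample_ground_truth(seed=21, k=3, pi=0.0)
    data, _ = mf.generate_dataset(truth, n_per_subject=[30, 30, 4], seed=22)
    prior = mf.HierarchicalMixtureModel(data).prior
    with pytest.warns(UserWarning):
        fit_model(data, prior, McmcConfig(chains=1, iterations=200,
                                          burn_in=100, seed=1))


def test_mcmc_config_validation():
    with pytest.raises(ValueError):
        McmcConfig(chains=0)
    with pytest.raises(ValueError):
        McmcConfig(iterations=100, burn_in=100)


def test_draws_reproducible_and_serialisable(small_dataset):
    data, _ = small_dataset
    prior = mf.HierarchicalMixtureModel(data).prior
    cfg = McmcConfig(chains=1, iterations=300, burn_in=200, seed=77)
    a = fit_model(data, prior, cfg)
    b = fit_model(data, prior, cfg)
    np.testing.assert_array_equal(a.chains[0].params["pi"],
                                  b.chains[0].params["pi"])
    frame = a.to_frame()
    assert set(frame.columns) == {"chain", "draw", "parameter", "value"}
    assert frame["parameter"].nunique() == 6 + 2 * data.k
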