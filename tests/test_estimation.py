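"""Two-level ML deviance, fitting, robust scaling, and difference tests."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from nlmsem import estimation as est
from nlmsem._linalg import vech
from nlmsem.aggregation import AugmentedDataset, sufficient_stats
from nlmsem.model_core import (
    BETWEEN_IN_GROUP,
    SATURATED,
    AnalysisSpec,
    PopulationConfig,
    group_sigma,
    population_moments,
    population_theta,
)


def _random_aug(rng, n_groups=4, group_size=3):
    wv = rng.standard_normal((n_groups * group_size, 12))
    pb = rng.standard_normal((n_groups, 3))
    gm = wv.reshape(n_groups, group_size, 12).mean(axis=1)
    return AugmentedDataset(
        within_vars=wv,
        between_vars=np.hstack([gm, pb]),
        group_id=np.repeat(np.arange(n_groups), group_size),
        group_size=group_size,
        n_groups=n_groups,
    )


def _random_pd(rng, p, dof=18):
    a = rng.standard_normal((p, dof))
    return a @ a.T / dof


def test_deviance_matches_raw_data_gaussian_oracle(rng):
    """The sufficient-statistic deviance equals the per-group multivariate
    normal log-density of the raw data (profiled means), constants included."""
    n_groups, group_size = 4, 3
    aug = _random_aug(rng, n_groups, group_size)
    stats = sufficient_stats(aug)
    sw, sb = _random_pd(rng, 12), _random_pd(rng, 12)
    theta = np.concatenate([vech(sw), vech(sb)])
    f = est.neg2loglik(theta, stats, SATURATED)

    p, q = 12, 3
    emb = np.zeros((15, 15))
    emb[np.ix_(BETWEEN_IN_GROUP, BETWEEN_IN_GROUP)] = sb
    cov = np.zeros((group_size * p + q, group_size * p + q))
    for i in range(group_size):
        for k in range(group_size):
            cov[i * p : (i + 1) * p, k * p : (k + 1) * p] = emb[:12, :12] + (sw if i == k else 0.0)
        cov[i * p : (i + 1) * p, group_size * p :] = emb[:12, 12:]
        cov[group_size * p :, i * p : (i + 1) * p] = emb[:12, 12:].T
    cov[group_size * p :, group_size * p :] = emb[12:, 12:]
    mu_g = aug.between_vars.mean(axis=0)
    mean = np.concatenate([np.tile(mu_g[:12], group_size), mu_g[12:]])
    x = np.hstack([aug.within_vars.reshape(n_groups, group_size * p), aug.between_vars[:, 12:]])
    oracle = -2.0 * multivariate_normal(mean=mean, cov=cov).logpdf(x).sum()
    assert f == pytest.approx(oracle, abs=1e-8 * abs(oracle))


def test_deviance_dimension_mismatch_raises(stats_wibi):
    with pytest.raises(ValueError, match="shape"):
        est.neg2loglik(np.zeros(10), stats_wibi, AnalysisSpec.from_name("WIBI"))


def test_gradient_matches_finite_differences(stats_wibi, rng):
    spec = AnalysisSpec.from_name("WIBI")
    theta = est.start_values(stats_wibi, spec)
    x = theta.values
    f0, g = est._eval_deviance(x, spec, stats_wibi, want_grad=True)
    eps = 1e-6
    for k in rng.choice(len(x), size=10, replace=False):
        xp, xm = x.copy(), x.copy()
        xp[k] += eps
        xm[k] -= eps
        fp, _ = est._eval_deviance(xp, spec, stats_wibi, False)
        fm, _ = est._eval_deviance(xm, spec, stats_wibi, False)
        assert g[k] == pytest.approx((fp - fm) / (2 * eps), rel=5e-4, abs=5e-4)


def _population_stats(cfg, n_groups=None, group_size=None):
    """SufficientStats holding exact population moments (no sampling).

    The deviance's between term weights ln|Sigma_g| by J but the trace by
    J-1 (exact profiled-mean ML), so its minimizer is (J-1)/J * s_b; the
    injected s_b compensates by J/(J-1) to make the population values the
    exact optimum."""
    ng = n_groups or cfg.n_groups
    ns = group_size or cfg.group_size
    pop = population_moments(cfg)
    sg = group_sigma(pop.sigma_w, pop.sigma_b, ns) * ng / (ng - 1)
    from nlmsem.aggregation import SufficientStats

    return SufficientStats(s_pw=pop.sigma_w, s_b=sg, n_groups=ng, group_size=ns, group_moments=None)


def test_fit_recovers_population_parameters_from_exact_moments():
    cfg = PopulationConfig(n_groups=500, group_size=30, phi21=0.3,
                           gamma3_within=0.2, gamma3_between=0.2)
    stats = _population_stats(cfg)
    spec = AnalysisSpec.from_name("WIBI")
    theta_pop = population_theta(cfg, spec)
    f0, g0 = est._eval_deviance(theta_pop.values, spec, stats, want_grad=True)
    assert np.max(np.abs(g0)) < 1e-6 * max(1.0, abs(f0))
    res = est.fit(stats, spec)
    assert res.converged and res.admissible
    assert res.theta["w.gamma3"] == pytest.approx(0.20, abs=1e-3)
    assert res.theta["b.gamma3"] == pytest.approx(0.20, abs=1e-3)
    assert res.theta["w.psi"] == pytest.approx(cfg.residual_variance("within"), abs=1e-3)


def test_saturated_fit_attains_zero_statistic(stats_wibi):
    fs = est.fit(stats_wibi, SATURATED)
    assert fs.converged
    test = est.overall_test(fs, fs)
    assert test.t_ml == 0.0 and test.p_ml == 1.0


def test_structured_deviance_dominates_saturated(stats_wibi):
    fs = est.fit(stats_wibi, SATURATED)
    ft = est.fit(stats_wibi, AnalysisSpec.from_name("WIBI"))
    assert ft.minus2ll >= fs.minus2ll - 1e-6
    test = est.overall_test(ft, fs)
    assert test.t_ml >= 0 and test.df == 100 and 0 <= test.p_ml <= 1


def test_overall_test_requires_saturated_baseline(stats_wibi):
    ft = est.fit(stats_wibi, AnalysisSpec.from_name("WIBI"))
    with pytest.raises(ValueError, match="saturated"):
        est.overall_test(ft, ft)


def test_group_scores_sum_to_zero_at_optimum(stats_wibi):
    ft = est.fit(stats_wibi, AnalysisSpec.from_name("WIBI"))
    scores = est.group_scores(ft, stats_wibi)
    assert scores.shape == (stats_wibi.n_groups, 56)
    total = np.abs(scores.sum(axis=0))
    assert np.max(total) < 0.05  # deviance-scale gradient at the solution


def test_mlr_scaling_near_one_for_exactly_normal_data(rng):
    """With jointly normal two-level data (no product kurtosis) the
    sandwich correction converges to 1; both formulas agree."""
    cfg = PopulationConfig(n_groups=1500, group_size=5, phi21=0.3,
                           gamma3_within=0.2, gamma3_between=0.2)
    pop = population_moments(cfg)
    cw = np.linalg.cholesky(pop.sigma_w)
    cb = np.linalg.cholesky(pop.sigma_b)
    j, c = cfg.n_groups, cfg.group_size
    b = rng.standard_normal((j, 12)) @ cb.T
    w = rng.standard_normal((j * c, 12)) @ cw.T
    z = w.copy()
    z[:, :9] += np.repeat(b[:, :9], c, axis=0)
    gm = z.reshape(j, c, 12).mean(axis=1)
    aug = AugmentedDataset(
        within_vars=z,
        between_vars=np.hstack([gm, b[:, 9:12]]),
        group_id=np.repeat(np.arange(j), c),
        group_size=c,
        n_groups=j,
    )
    stats = sufficient_stats(aug)
    fs = est.fit(stats, SATURATED)
    ft = est.fit(stats, AnalysisSpec.from_name("WIBI"))
    t = est.overall_test(ft, fs)
    c_score = est.mlr_scale(ft, fs, stats, t, method="score").scaling_c
    c_moment = est.mlr_scale(ft, fs, stats, t, method="moment").scaling_c
    assert abs(c_score - 1.0) < 0.1
    assert abs(c_moment - 1.0) < 0.1
    assert c_score == pytest.approx(c_moment, abs=0.1)


def test_mlr_scaling_on_product_data(stats_wibi):
    fs = est.fit(stats_wibi, SATURATED)
    ft = est.fit(stats_wibi, AnalysisSpec.from_name("WIBI"))
    t2 = est.mlr_scale(ft, fs, stats_wibi)
    assert t2.scaling_c > 1.0  # product indicators are leptokurtic
    assert t2.t_mlr == pytest.approx(t2.t_ml / t2.scaling_c)
    assert 0 <= t2.p_mlr <= 1


def test_partial_tests_have_level_specific_df(stats_wibi):
    fs = est.fit(stats_wibi, SATURATED)
    tw = est.partial_test(stats_wibi, "within", "free", fit_saturated=fs, robust=False)
    tb = est.partial_test(stats_wibi, "between", "free", fit_saturated=fs, robust=False)
    assert tw.df == 50 and tb.df == 50
    assert tw.test_type == "within_partial" and tb.test_type == "between_partial"
    t0 = est.partial_test(stats_wibi, "within", "fixed_zero", fit_saturated=fs, robust=False)
    assert t0.df == 51


def test_chisq_diff_rejects_non_nested_pairs(stats_wibi):
    f1 = est.fit(stats_wibi, AnalysisSpec.from_name("WIB0"))
    f2 = est.fit(stats_wibi, AnalysisSpec.from_name("W0BI"))
    with pytest.raises(ValueError, match="not nested"):
        est.chisq_diff(f1, f2)
    with pytest.raises(ValueError, match="no free-parameter difference"):
        est.chisq_diff(f1, f1)


def test_difference_test_non_negative_and_detects_interaction(stats_wibi):
    """Delta chi2 >= 0, and the within interaction present in the data is
    picked up with an overwhelming statistic."""
    t, fr, ff = est.diff_test(
        stats_wibi, AnalysisSpec.from_name("W0B0"), AnalysisSpec.from_name("WIB0"), robust=False
    )
    assert t.df == 1
    assert t.t_ml >= 0.0
    assert t.p_ml < 1e-6


def test_robust_difference_uses_full_model_scaling(stats_wibi):
    t, _, _ = est.diff_test(
        stats_wibi, AnalysisSpec.from_name("W0B0"), AnalysisSpec.from_name("WIBI"), robust=True
    )
    assert t.df == 2
    assert t.t_mlr == pytest.approx(t.t_ml / t.scaling_c)


def test_project_theta_maps_shared_parameters(stats_wibi):
    full = est.fit(stats_wibi, AnalysisSpec.from_name("WIBI"))
    proj = est.project_theta(full.theta, AnalysisSpec.from_name("W0B0"))
    assert len(proj.values) == 54
    assert proj["w.gamma1"] == full.theta["w.gamma1"]
    assert "w.gamma3" not in proj.index
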