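"""Model definition: parameter counts, implied moments, population values."""

import numpy as np
import pytest

from nlmsem import model_core as mc
from nlmsem._linalg import is_pd, vech
from nlmsem.model_core import (
    AnalysisSpec,
    ParameterVector,
    PopulationConfig,
    count_free_params,
    degrees_of_freedom,
    group_sigma,
    implied_moments,
    moment_jacobian,
    population_moments,
    population_theta,
)

ALL_POP_CONFIGS = [
    PopulationConfig(
        n_groups=10, group_size=30, phi21=phi,
        gamma3_within=g3w, gamma3_between=g3b,
    )
    for phi in (0.0, 0.30)
    for g3w, g3b in ((0.0, 0.0), (0.2, 0.0), (0.0, 0.2), (0.2, 0.2))
]


@pytest.mark.parametrize(
    "name, params, df",
    [
        ("WIBI", (28, 28, 56), 100),
        ("WIB0", (28, 27, 55), 101),
        ("W0BI", (27, 28, 55), 101),
        ("W0B0", (27, 27, 54), 102),
        ("PS_WIB_s", (28, 78, 106), 50),
        ("PS_W0B_s", (27, 78, 105), 51),
        ("PS_W_s_BI", (78, 28, 106), 50),
        ("PS_W_s_B0", (78, 27, 105), 51),
        ("SAT", (78, 78, 156), 0),
    ],
)
def test_free_params_and_df(name, params, df):
    spec = AnalysisSpec.from_name(name)
    assert count_free_params(spec) == params
    assert degrees_of_freedom(spec)[2] == df
    assert spec.name == name or name == "SAT"


def test_df_is_saturated_minus_target_per_level():
    spec = AnalysisSpec.from_name("PS_WIB_s")
    dfw, dfb, dft = degrees_of_freedom(spec)
    assert (dfw, dfb) == (50, 0)
    assert dft == dfw + dfb


def test_spec_name_round_trip_and_serialization():
    for name in ("W0B0", "WIB0", "W0BI", "WIBI", "PS_W0B_s", "PS_WIB_s", "PS_W_s_B0", "PS_W_s_BI"):
        spec = AnalysisSpec.from_name(name)
        assert spec.name == name
        assert AnalysisSpec.from_dict(spec.to_dict()) == spec


def test_unknown_spec_name_raises():
    with pytest.raises(ValueError, match="unknown analysis model"):
        AnalysisSpec.from_name("WIBIX")


def test_parameter_vector_name_index_round_trip():
    spec = AnalysisSpec.from_name("WIBI")
    theta = population_theta(ALL_POP_CONFIGS[-1], spec)
    assert len(theta.names) == 56
    for i, name in enumerate(theta.names):
        assert theta.index[name] == i
        assert theta[name] == theta.values[i]
    assert theta.names[0] == "w.lam_y2"
    assert "w.gamma3" in theta.index and "b.gamma3" in theta.index


def test_parameter_vector_dimension_mismatch_raises():
    spec = AnalysisSpec.from_name("WIBI")
    with pytest.raises(ValueError, match="needs"):
        ParameterVector(spec, np.zeros(55))


def test_implied_variance_decomposition_unit_eta():
    """With population values, Var(y1) = Var(eta) + error = 1.25 and the
    structural R^2 pieces add to one: 0.09+0.09+0.04+0.78."""
    cfg = PopulationConfig(n_groups=10, group_size=30, phi21=0.0, gamma3_within=0.2, gamma3_between=0.2)
    mom = population_moments(cfg)
    assert mom.sigma_w[0, 0] == pytest.approx(1.25, abs=1e-12)
    assert cfg.residual_variance("within") == pytest.approx(0.78, abs=1e-12)


def test_product_y_covariance_is_structural_zero_without_interaction():
    cfg = PopulationConfig(n_groups=10, group_size=30, phi21=0.30)
    spec = AnalysisSpec.from_name("W0B0")
    mom = implied_moments(population_theta(cfg, spec), spec)
    for sigma in (mom.sigma_w, mom.sigma_b):
        assert np.allclose(sigma[9:12, 0:3], 0.0, atol=1e-14)


def test_product_indicator_variance_composition():
    """Anchor product indicator: variance = loading^2 * Var(xi1xi2) + resid."""
    spec = AnalysisSpec.from_name("WIBI")
    cfg = PopulationConfig(n_groups=10, group_size=30, gamma3_within=0.2, gamma3_between=0.2)
    theta = population_theta(cfg, spec)
    vals = theta.values.copy()
    vals[theta.index["w.phi33"]] = 1.5
    vals[theta.index["w.th_p1"]] = 0.5
    mom = implied_moments(ParameterVector(spec, vals), spec)
    assert mom.sigma_w[9, 9] == pytest.approx(1.5 + 0.5, abs=1e-12)


@pytest.mark.parametrize("cfg", ALL_POP_CONFIGS)
def test_population_moments_symmetric_pd(cfg):
    mom = population_moments(cfg)
    for sigma in (mom.sigma_w, mom.sigma_b):
        assert np.allclose(sigma, sigma.T, atol=1e-10)
        assert is_pd(sigma)
    assert is_pd(group_sigma(mom.sigma_w, mom.sigma_b, cfg.group_size))


def test_implied_moments_match_brute_force_component_oracle(rng):
    """Monte Carlo oracle: simulate one level's latent system directly and
    compare empirical augmented moments with the implied matrix."""
    phi21, g3 = 0.30, 0.20
    n = 400_000
    lam = np.array([1.0, np.sqrt(0.8), np.sqrt(0.8)])
    ev = np.sqrt([0.25, 0.2, 0.2])
    chol = np.linalg.cholesky([[1.0, phi21], [phi21, 1.0]])
    xi = rng.standard_normal((n, 2)) @ chol.T
    zeta_var = 1 - (0.09 + 0.09 + 2 * 0.09 * phi21 + g3**2 * (1 + phi21**2))
    eta = 0.3 * xi[:, 0] + 0.3 * xi[:, 1] + g3 * (xi[:, 0] * xi[:, 1] - phi21) + rng.normal(0, np.sqrt(zeta_var), n)
    y = eta[:, None] * lam + rng.standard_normal((n, 3)) * ev
    x1 = xi[:, [0]] * lam + rng.standard_normal((n, 3)) * ev
    x2 = xi[:, [1]] * lam + rng.standard_normal((n, 3)) * ev
    pw = x1 * x2  # matched pairs share the triplet position
    data = np.hstack([y, x1, x2, pw])
    emp = np.cov(data, rowvar=False)
    cfg = PopulationConfig(n_groups=10, group_size=30, phi21=phi21, gamma3_within=g3, gamma3_between=g3)
    sigma = population_moments(cfg).sigma_w
    # entrywise within ~5 MC standard errors (normal-theory SE approximation)
    se = np.sqrt((np.outer(np.diag(sigma), np.diag(sigma)) + sigma**2) / n)
    # product-moment entries are kurtotic; allow a generous multiple
    assert np.all(np.abs(emp - sigma) < 12 * se)


@pytest.mark.parametrize("name", ["WIBI", "W0BI", "PS_WIB_s"])
def test_moment_jacobian_matches_finite_differences(name, rng):
    cfg = PopulationConfig(n_groups=10, group_size=7, phi21=0.3, gamma3_within=0.2, gamma3_between=0.2)
    spec = AnalysisSpec.from_name(name)
    theta = population_theta(cfg, spec)
    vals = theta.values + 0.01 * rng.standard_normal(theta.values.shape)
    theta = ParameterVector(spec, vals)
    jac = moment_jacobian(theta, cfg.group_size)
    eps = 1e-6
    for k in rng.choice(len(vals), size=12, replace=False):
        vp, vm = vals.copy(), vals.copy()
        vp[k] += eps
        vm[k] -= eps
        mp, mm = implied_moments(ParameterVector(spec, vp), spec), implied_moments(ParameterVector(spec, vm), spec)
        fd_w = (vech(mp.sigma_w) - vech(mm.sigma_w)) / (2 * eps)
        gp = vech(group_sigma(mp.sigma_w, mp.sigma_b, cfg.group_size))
        gm = vech(group_sigma(mm.sigma_w, mm.sigma_b, cfg.group_size))
        fd_g = (gp - gm) / (2 * eps)
        assert np.allclose(jac[k, : mc.N_LEVEL_MOMENTS], fd_w, atol=1e-6)
        assert np.allclose(jac[k, mc.N_LEVEL_MOMENTS :], fd_g, atol=1e-6)


try:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        phi=st.floats(-0.8, 0.8),
        g3w=st.floats(0.0, 0.35),
        g3b=st.floats(0.0, 0.35),
    )
    def test_population_construction_keeps_unit_eta_variance(phi, g3w, g3b):
        """Whatever the admissible design, the residual-variance rule keeps
        Var(eta)=1, so Var(y1) at each level is exactly 1.25 and the implied
        matrices stay symmetric positive definite."""
        cfg = PopulationConfig(
            n_groups=10, group_size=30, phi21=phi,
            gamma3_within=g3w, gamma3_between=g3b,
        )
        mom = population_moments(cfg)
        assert mom.sigma_w[0, 0] == pytest.approx(1.25, abs=1e-10)
        assert mom.sigma_b[0, 0] == pytest.approx(1.25, abs=1e-10)
        assert is_pd(mom.sigma_w) and is_pd(mom.sigma_b)

except ImportError:  # hypothesis is an optional test dependency
    pass


def test_reliability_exact_for_both_indicator_types():
    cfg = PopulationConfig(n_groups=10, group_size=30)
    assert cfg.reliability(cfg.loading_scale, cfg.err_var_scale) == pytest.approx(0.80, abs=1e-12)
    assert cfg.reliability(cfg.loading_other, cfg.err_var_other) == pytest.approx(0.80, abs=1e-12)


def test_inadmissible_population_config_raises():
    with pytest.raises(ValueError):
        PopulationConfig(n_groups=0, group_size=30)
    with pytest.raises(ValueError):
        PopulationConfig(n_groups=10, group_size=30, phi21=1.5)
    with pytest.raises(ValueError, match="residual variance"):
        PopulationConfig(n_groups=10, group_size=30, gamma1=0.8, gamma2=0.8)
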