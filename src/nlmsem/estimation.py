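"""Normal-theory ML fitting and likelihood-ratio tests on sufficient statistics.

The balanced two-level Gaussian deviance used throughout is

    -2lnL = (N-J)[ln|Sigma_W| + tr(S_PW Sigma_W^-1)]
            + J ln|Sigma_g| + (J-1) tr(S_B Sigma_g^-1) + const,

where Sigma_g is the 15x15 implied covariance of the group-level vector
(group means of the 12 within-varying variables plus the three
between-only products) and the constant makes the value equal to the exact
profiled-mean Gaussian log-density of the raw data.  Mean structure is
saturated, so all tests are driven by covariance restrictions.

The robust (rescaled) statistic divides T_ML by a sandwich scaling factor
computed from the empirical covariance of per-group moment contributions,
with groups as the i.i.d. sampling units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats as spstats
from scipy.linalg import cho_factor, cho_solve

from ._linalg import duplication_matrix, nearest_psd, vech
from .aggregation import SufficientStats
from .model_core import (
    BETWEEN_IN_GROUP,
    N_GROUP_VARS,
    N_LEVEL_MOMENTS,
    N_LEVEL_VARS,
    SATURATED,
    AnalysisSpec,
    ParameterVector,
    check_admissible,
    count_free_params,
    degrees_of_freedom,
    group_sigma,
    implied_moments,
    is_nested,
    level_sigma,
    moment_jacobian,
)

__all__ = [
    "FitResult",
    "TestResult",
    "neg2loglik",
    "fit",
    "overall_test",
    "mlr_scale",
    "partial_test",
    "chisq_diff",
    "diff_test",
]


@dataclass
class FitResult:
    theta: ParameterVector
    minus2ll: float
    spec: AnalysisSpec
    converged: bool
    n_iterations: int
    admissible: bool
    gradient_norm: float
    n_groups: int
    group_size: int

    def to_dict(self) -> dict:
        return {
            "model": self.spec.name,
            "minus2ll": self.minus2ll,
            "converged": self.converged,
            "admissible": self.admissible,
            "n_iterations": self.n_iterations,
            "gradient_norm": self.gradient_norm,
            "estimates": self.theta.to_dict(),
        }


@dataclass
class TestResult:
    t_ml: float
    df: int
    p_ml: float
    test_type: str = "overall"
    t_mlr: float | None = None
    scaling_c: float | None = None
    p_mlr: float | None = None
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "test_type": self.test_type,
            "t_ml": self.t_ml,
            "df": self.df,
            "p_ml": self.p_ml,
            "t_mlr": self.t_mlr,
            "scaling_c": self.scaling_c,
            "p_mlr": self.p_mlr,
        }


# ---------------------------------------------------------------------------
# Deviance and gradient
# ---------------------------------------------------------------------------


def _deviance_constant(stats: SufficientStats) -> float:
    n, j, c = stats.n_total, stats.n_groups, stats.group_size
    q = N_GROUP_VARS - N_LEVEL_VARS
    return (n * N_LEVEL_VARS + j * q) * math.log(2.0 * math.pi) + j * N_LEVEL_VARS * math.log(c)


def _eval_deviance(
    values: np.ndarray,
    spec: AnalysisSpec,
    stats: SufficientStats,
    want_grad: bool,
) -> tuple[float, np.ndarray | None]:
    nw = count_free_params(spec)[0]
    vw, vb = values[:nw], values[nw:]
    if not np.all(np.isfinite(values)):
        return np.inf, (np.zeros_like(values) if want_grad else None)
    sw, jw = level_sigma(vw, spec.within_mode, spec.within_interaction, want_jac=want_grad)
    sb, jb = level_sigma(vb, spec.between_mode, spec.between_interaction, want_jac=want_grad)
    j, c = stats.n_groups, stats.group_size
    n_within = stats.n_total - j
    sg = group_sigma(sw, sb, c)
    try:
        cw = cho_factor(sw, lower=True, check_finite=False)
        cg = cho_factor(sg, lower=True, check_finite=False)
    except np.linalg.LinAlgError:
        return np.inf, (np.zeros_like(values) if want_grad else None)
    logdet_w = 2.0 * float(np.log(np.diag(cw[0])).sum())
    logdet_g = 2.0 * float(np.log(np.diag(cg[0])).sum())
    if not (np.isfinite(logdet_w) and np.isfinite(logdet_g)):
        return np.inf, (np.zeros_like(values) if want_grad else None)
    inv_w_s = cho_solve(cw, stats.s_pw, check_finite=False)  # Sigma_W^-1 S_PW
    inv_g_s = cho_solve(cg, stats.s_b, check_finite=False)
    f = (
        n_within * (logdet_w + float(np.trace(inv_w_s)))
        + j * logdet_g
        + (j - 1) * float(np.trace(inv_g_s))
        + _deviance_constant(stats)
    )
    if not want_grad:
        return f, None
    eye_w = np.eye(N_LEVEL_VARS)
    eye_g = np.eye(N_GROUP_VARS)
    inv_w = cho_solve(cw, eye_w, check_finite=False)
    inv_g = cho_solve(cg, eye_g, check_finite=False)
    # dF/dSigma_W and dF/dSigma_B as full symmetric matrices
    a_w = n_within * (inv_w - inv_w @ stats.s_pw @ inv_w)
    g_g = j * inv_g - (j - 1) * inv_g @ stats.s_b @ inv_g
    d_sw = a_w + g_g[:N_LEVEL_VARS, :N_LEVEL_VARS] / c
    d_sb = g_g[np.ix_(BETWEEN_IN_GROUP, BETWEEN_IN_GROUP)]
    grad = np.empty_like(values)
    grad[:nw] = np.einsum("kij,ij->k", jw, d_sw)
    grad[nw:] = np.einsum("kij,ij->k", jb, d_sb)
    return f, grad


def neg2loglik(
    theta: ParameterVector | np.ndarray, stats: SufficientStats, spec: AnalysisSpec | None = None
) -> float:
    """Exact balanced two-level Gaussian deviance (profiled saturated means)."""
    if isinstance(theta, ParameterVector):
        spec = theta.spec
        values = theta.values
    else:
        if spec is None:
            raise ValueError("spec required when theta is a bare array")
        values = np.asarray(theta, dtype=float)
    expected = count_free_params(spec)[2]
    if values.shape != (expected,):
        raise ValueError(f"theta has shape {values.shape}, spec {spec.name} needs ({expected},)")
    f, _ = _eval_deviance(values, spec, stats, want_grad=False)
    return f


# ---------------------------------------------------------------------------
# Starting values
# ---------------------------------------------------------------------------


def _between_target(stats: SufficientStats) -> np.ndarray:
    """Moment estimator of Sigma_B: group-level covariance minus the
    within contamination S_PW/NS on the common block."""
    sb12 = stats.s_b[np.ix_(BETWEEN_IN_GROUP, BETWEEN_IN_GROUP)].copy()
    sb12[:9, :9] -= stats.s_pw[:9, :9] / stats.group_size
    return sb12


def _structured_start(s: np.ndarray, interaction: str) -> np.ndarray:
    """Heuristic starts for one structured level from its target matrix."""
    s = np.asarray(s)
    diag = np.clip(np.diag(s), 0.05, None)
    lam = np.ones(8)
    theta = 0.5 * diag
    phi11 = max(abs(s[3, 4]), 0.05)
    phi22 = max(abs(s[6, 7]), 0.05)
    phi33 = max(abs(s[9, 10]), 0.05)
    phi21 = float(np.clip(s[3, 6], -0.9 * math.sqrt(phi11 * phi22), 0.9 * math.sqrt(phi11 * phi22)))
    # factor-score proxies: block averages of the target matrix
    p = np.zeros((12, 4))
    p[0:3, 0] = p[3:6, 1] = p[6:9, 2] = p[9:12, 3] = 1.0 / 3.0
    cavg = p.T @ s @ p  # (eta*, xi1*, xi2*, xi3*) proxy covariance
    k = 3 if interaction == "free" else 2
    cxx = cavg[1 : 1 + k, 1 : 1 + k] + 1e-3 * np.eye(k)
    gammas = np.linalg.solve(cxx, cavg[1 : 1 + k, 0])
    gam = np.zeros(3)
    gam[:k] = np.clip(gammas, -2.0, 2.0)
    psi = max(0.5 * cavg[0, 0], 0.05)
    vals = np.concatenate(
        [
            lam,
            theta,
            [phi11, phi21, phi22, phi33],
            [gam[0], gam[1]],
            [gam[2]] if interaction == "free" else [],
            [psi],
        ]
    )
    return vals


def start_values(stats: SufficientStats, spec: AnalysisSpec) -> ParameterVector:
    parts = []
    targets = {"within": stats.s_pw, "between": _between_target(stats)}
    for level in ("within", "between"):
        target = targets[level]
        if spec.mode(level) == "saturated":
            parts.append(vech(nearest_psd(target, floor=1e-4)))
        else:
            parts.append(_structured_start(nearest_psd(target, floor=1e-4), spec.interaction(level)))
    return ParameterVector(spec, np.concatenate(parts))


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def fit(
    stats: SufficientStats,
    spec: AnalysisSpec,
    starts: ParameterVector | np.ndarray | None = None,
    max_iterations: int = 500,
    gradient_tol: float = 1e-3,
) -> FitResult:
    """Quasi-Newton minimization of the deviance with analytic gradients.

    One automatic restart from perturbed starting values is attempted when
    the first pass fails to reach the gradient tolerance.
    """
    if starts is None:
        x0 = start_values(stats, spec).values
    elif isinstance(starts, ParameterVector):
        x0 = starts.values.copy()
    else:
        x0 = np.asarray(starts, dtype=float).copy()

    def objective(x: np.ndarray) -> tuple[float, np.ndarray]:
        f, g = _eval_deviance(x, spec, stats, want_grad=True)
        if not np.isfinite(f):
            return 1e12, np.zeros_like(x)
        return f, g

    def tol_for(f: float) -> float:
        # gradient tolerance scaled to the deviance magnitude: near the
        # optimum the deviance error is O(|g|^2 / curvature) with curvature
        # of order N, so |g| ~ 5e-7*|f| leaves the fit value accurate to
        # far below the 0.01 resolution that matters for the statistics
        return max(gradient_tol, 5e-7 * abs(f))

    best = None
    n_iter_total = 0
    for attempt in range(3):
        res = optimize.minimize(
            objective,
            x0,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": max_iterations, "ftol": 1e-13, "gtol": 1e-6, "maxcor": 25},
        )
        n_iter_total += res.nit
        gnorm = float(np.max(np.abs(res.jac)))
        if best is None or res.fun < best[0].fun:
            best = (res, gnorm)
        if gnorm <= tol_for(res.fun):
            break
        if attempt == 0:
            # restarting L-BFGS at the same point with fresh curvature
            # memory typically finishes the job in a couple of iterations
            x0 = res.x
        else:
            # deterministic perturbed restart as a last resort
            rng = np.random.default_rng(12345 + attempt)
            x0 = res.x * (1.0 + 0.02 * rng.standard_normal(res.x.shape))
    res, gnorm = best
    theta = ParameterVector(spec, res.x)
    converged = bool(np.isfinite(res.fun)) and gnorm <= tol_for(res.fun)
    try:
        admissible = check_admissible(theta)
    except ValueError:
        admissible = False
    return FitResult(
        theta=theta,
        minus2ll=float(res.fun),
        spec=spec,
        converged=converged,
        n_iterations=n_iter_total,
        admissible=admissible,
        gradient_norm=gnorm,
        n_groups=stats.n_groups,
        group_size=stats.group_size,
    )


def project_theta(theta: ParameterVector, spec: AnalysisSpec) -> ParameterVector:
    """Map a fitted parameter vector onto a nested spec's layout by name;
    parameters absent from the nested spec are dropped, new ones start at
    benign defaults (only arises for saturated levels, which share names)."""
    from .model_core import parameter_names

    src = theta.to_dict()
    names = parameter_names(spec)
    vals = np.array([src.get(n, 0.0) for n in names])
    return ParameterVector(spec, vals)


# ---------------------------------------------------------------------------
# Tests
# ---------------------------------------------------------------------------


def overall_test(fit_target: FitResult, fit_saturated: FitResult) -> TestResult:
    """Likelihood-ratio statistic of the target model against the fully
    saturated baseline; df = saturated minus target free parameters."""
    if fit_saturated.spec != SATURATED:
        raise ValueError("baseline fit must be the fully saturated model")
    t = fit_target.minus2ll - fit_saturated.minus2ll
    if t < -1e-4:
        raise RuntimeError(f"negative likelihood-ratio statistic {t}: optimization failure")
    t = max(t, 0.0)
    df = degrees_of_freedom(fit_target.spec)[2]
    test_type = "overall"
    if fit_target.spec.between_mode == "saturated" and fit_target.spec.within_mode == "structured":
        test_type = "within_partial"
    elif fit_target.spec.within_mode == "saturated" and fit_target.spec.between_mode == "structured":
        test_type = "between_partial"
    p = float(spstats.chi2.sf(t, df)) if df > 0 else 1.0
    return TestResult(t_ml=t, df=df, p_ml=p, test_type=test_type)


def _normal_theory_weight(sigma: np.ndarray) -> np.ndarray:
    """V = 0.5 D' (Sigma^-1 kron Sigma^-1) D in vech coordinates."""
    p = sigma.shape[0]
    inv = np.linalg.inv(sigma)
    d = duplication_matrix(p)
    return 0.5 * d.T @ np.kron(inv, inv) @ d


def _residual_weight(v_big: np.ndarray, delta: np.ndarray) -> np.ndarray:
    """U = V - V D (D'VD)^-1 D'V for one model's moment Jacobian D."""
    vd = v_big @ delta
    h = delta.T @ vd
    try:
        sol = np.linalg.solve(h, vd.T)
    except np.linalg.LinAlgError as exc:
        w, vecs = np.linalg.eigh(0.5 * (h + h.T))
        bad = np.where(w < 1e-10 * w.max())[0]
        raise ValueError(
            f"moment Jacobian rank-deficient (null directions: {bad.tolist()}); "
            "model not identified"
        ) from exc
    return v_big - vd @ sol


def group_scores(fitres: FitResult, stats: SufficientStats) -> np.ndarray:
    """Per-group score vectors of the deviance at the fitted parameters.

    The deviance is a sum of per-group terms that are linear in each
    group's moment contributions (vech W_j, vech B_j), so the J x p score
    matrix is a single linear map of ``stats.group_moments``.  At the
    optimum the scores sum to (numerical) zero.
    """
    if stats.group_moments is None:
        raise ValueError("stats were computed without per-group moment contributions")
    spec, theta = fitres.spec, fitres.theta
    j, c = stats.n_groups, stats.group_size
    kappa = (j - 1) / j
    mom = implied_moments(theta, spec)
    sigma_w = mom.sigma_w
    sigma_g = group_sigma(sigma_w, mom.sigma_b, c)
    inv_w = np.linalg.inv(sigma_w)
    inv_g = np.linalg.inv(sigma_g)
    jac = moment_jacobian(theta, c)
    d12 = duplication_matrix(N_LEVEL_VARS)
    d15 = duplication_matrix(N_GROUP_VARS)
    jac_w, jac_g = jac[:, :N_LEVEL_MOMENTS], jac[:, N_LEVEL_MOMENTS:]
    const = (c - 1) * (jac_w @ (d12.T @ inv_w.reshape(-1))) + jac_g @ (d15.T @ inv_g.reshape(-1))
    lin_w = (c - 1) * (jac_w @ (d12.T @ np.kron(inv_w, inv_w) @ d12))
    lin_g = kappa * (jac_g @ (d15.T @ np.kron(inv_g, inv_g) @ d15))
    return (
        const[None, :]
        - stats.group_moments[:, :N_LEVEL_MOMENTS] @ lin_w.T
        - stats.group_moments[:, N_LEVEL_MOMENTS:] @ lin_g.T
    )


def observed_information(fitres: FitResult, stats: SufficientStats, eps: float = 1e-5) -> np.ndarray:
    """Observed information (half the deviance Hessian) at the solution,
    by central differences of the analytic gradient."""
    x = fitres.theta.values
    spec = fitres.spec
    n = len(x)
    h = np.empty((n, n))
    for k in range(n):
        step = eps * max(1.0, abs(x[k]))
        xp = x.copy(); xp[k] += step
        xm = x.copy(); xm[k] -= step
        _, gp = _eval_deviance(xp, spec, stats, want_grad=True)
        _, gm = _eval_deviance(xm, spec, stats, want_grad=True)
        h[k] = (gp - gm) / (2.0 * step)
    return 0.25 * (h + h.T)  # information of the log-likelihood = Hessian(deviance)/2


def _sandwich_trace(fitres: FitResult, stats: SufficientStats) -> float:
    """tr(A^-1 B) with A the observed information and B the empirical
    covariance of per-group log-likelihood scores."""
    scores = 0.5 * group_scores(fitres, stats)  # deviance scores -> loglik scale
    b = scores.T @ scores
    a = observed_information(fitres, stats)
    try:
        return float(np.trace(np.linalg.solve(a, b)))
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            f"observed information singular for model {fitres.spec.name}; "
            "model not identified at the solution"
        ) from exc


def mlr_scale(
    fit_target: FitResult,
    fit_baseline: FitResult,
    stats: SufficientStats,
    test: TestResult | None = None,
    method: str = "score",
) -> TestResult:
    """Rescaled (robust) statistic T_MLR = T_ML / c.

    ``method="score"`` (default) uses the classical sandwich-trace form
    c = [tr(A1^-1 B1) - tr(A0^-1 B0)] / df with A the observed information
    and B the cluster-score covariance of each model (groups as i.i.d.
    units).  ``method="moment"`` uses the asymptotically equivalent
    moment-space form c = tr((U_target - U_baseline) Gamma_hat) / df with
    U the residual normal-theory weight and Gamma_hat the empirical
    covariance of per-group moment contributions.  The baseline term is
    kept in both because even the saturated two-level model restricts the
    group-level moments (the within-product block of Sigma_g is tied to
    Sigma_W/NS).
    """
    if stats.group_moments is None:
        raise ValueError("stats were computed without per-group moment contributions")
    if test is None:
        test = overall_test(fit_target, fit_baseline)
    if method == "score":
        c_scale = (_sandwich_trace(fit_baseline, stats) - _sandwich_trace(fit_target, stats)) / test.df
    elif method == "moment":
        j, c_size = stats.n_groups, stats.group_size
        mom = implied_moments(fit_target.theta, fit_target.spec)
        sigma_g = group_sigma(mom.sigma_w, mom.sigma_b, c_size)
        v_w = (c_size - 1) * _normal_theory_weight(mom.sigma_w)
        v_b = ((j - 1) / j) * _normal_theory_weight(sigma_g)
        n_mom = v_w.shape[0] + v_b.shape[0]
        v_big = np.zeros((n_mom, n_mom))
        v_big[: v_w.shape[0], : v_w.shape[0]] = v_w
        v_big[v_w.shape[0] :, v_w.shape[0] :] = v_b
        delta_t = moment_jacobian(fit_target.theta, c_size).T
        delta_s = moment_jacobian(fit_baseline.theta, c_size).T
        u_diff = _residual_weight(v_big, delta_t) - _residual_weight(v_big, delta_s)
        gamma = np.cov(stats.group_moments, rowvar=False, ddof=1)
        c_scale = float(np.sum(u_diff * gamma)) / test.df
    else:
        raise ValueError(f"unknown scaling method {method!r}")
    if c_scale <= 0:
        raise RuntimeError(f"non-positive scaling factor {c_scale}")
    t_mlr = test.t_ml / c_scale
    return TestResult(
        t_ml=test.t_ml,
        df=test.df,
        p_ml=test.p_ml,
        test_type=test.test_type,
        t_mlr=t_mlr,
        scaling_c=c_scale,
        p_mlr=float(spstats.chi2.sf(t_mlr, test.df)),
    )


def partial_test(
    stats: SufficientStats,
    level: str,
    interaction: str = "free",
    fit_saturated: FitResult | None = None,
    robust: bool = True,
) -> TestResult:
    """Level-specific fit test: the named level structured, the other
    saturated, compared against the fully saturated model."""
    if level == "within":
        spec = AnalysisSpec("structured", "saturated", interaction, "fixed_zero")
    elif level == "between":
        spec = AnalysisSpec("saturated", "structured", "fixed_zero", interaction)
    else:
        raise ValueError(f"level must be 'within' or 'between', got {level!r}")
    if fit_saturated is None:
        fit_saturated = fit(stats, SATURATED)
    fit_ps = fit(stats, spec)
    test = overall_test(fit_ps, fit_saturated)
    if robust:
        test = mlr_scale(fit_ps, fit_saturated, stats, test)
    return test


def chisq_diff(fit_restricted: FitResult, fit_full: FitResult) -> TestResult:
    """Unscaled chi-square difference test for nested models."""
    if not is_nested(fit_restricted.spec, fit_full.spec):
        raise ValueError(
            f"{fit_restricted.spec.name} is not nested in {fit_full.spec.name}"
        )
    ddf = count_free_params(fit_full.spec)[2] - count_free_params(fit_restricted.spec)[2]
    if ddf <= 0:
        raise ValueError("nested pair has no free-parameter difference")
    t = fit_restricted.minus2ll - fit_full.minus2ll
    if t < -1e-4:
        raise RuntimeError(f"negative chi-square difference {t}: optimization failure")
    t = max(t, 0.0)
    return TestResult(
        t_ml=t, df=ddf, p_ml=float(spstats.chi2.sf(t, ddf)), test_type="difference"
    )


def diff_test(
    stats: SufficientStats,
    spec_restricted: AnalysisSpec,
    spec_full: AnalysisSpec,
    fits: dict[str, FitResult] | None = None,
    robust: bool = True,
) -> tuple[TestResult, FitResult, FitResult]:
    """Fit a nested pair and form the chi-square difference test.

    With ``robust=True`` the raw -2lnL difference is rescaled by the full
    model's sandwich scaling factor, Delta = (T_ML,r - T_ML,f) / c_full,
    and referred to a central chi-square with the free-parameter
    difference as df; no Satorra-Bentler difference correction is
    applied.  Using one common scaling avoids the extra noise that
    differencing two independently rescaled statistics of size ~T would
    add (T * delta(1/c)), and the full model's c is used because the full
    model remains correctly specified under both hypotheses.  With
    ``robust=False`` the raw -2lnL difference is used.

    When the difference comes out negative (optimizer noise), the
    restricted model is refit starting from the full model's solution
    projected onto the restricted layout.
    """
    fits = fits if fits is not None else {}
    fr = fits.get(spec_restricted.name) or fit(stats, spec_restricted)
    ff = fits.get(spec_full.name) or fit(stats, spec_full)
    if fr.minus2ll - ff.minus2ll < 0.0:
        retry = fit(stats, spec_restricted, starts=project_theta(ff.theta, spec_restricted))
        if retry.minus2ll < fr.minus2ll:
            fr = retry
    fits[spec_restricted.name] = fr
    fits[spec_full.name] = ff
    raw = chisq_diff(fr, ff)
    if not robust:
        return raw, fr, ff
    fs = fits.get(SATURATED.name) or fit(stats, SATURATED)
    fits[SATURATED.name] = fs
    tf = mlr_scale(ff, fs, stats)
    t = raw.t_ml / tf.scaling_c
    result = TestResult(
        t_ml=raw.t_ml,
        df=raw.df,
        p_ml=raw.p_ml,
        test_type="difference",
        t_mlr=t,
        scaling_c=tf.scaling_c,
        p_mlr=float(spstats.chi2.sf(t, raw.df)),
        extra={"t_mlr_full": tf.t_mlr},
    )
    return result, fr, ff
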