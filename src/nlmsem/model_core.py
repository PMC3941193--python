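"""Model definition for the nonlinear two-level SEM with latent interactions.

The model family is fixed: at each level (within groups, between groups)
there are two exogenous latent predictors measured by three indicators each
(x1..x3 for xi1, x4..x6 for xi2), one endogenous latent eta measured by
y1..y3, and one latent product term xi1*xi2 measured by three matched-pair
product indicators (x1*x4, x2*x5, x3*x6).  The structural equation at each
level is

    eta = gamma1*xi1 + gamma2*xi2 + gamma3*(xi1*xi2) + zeta

with the interaction effect gamma3 either freely estimated or fixed to
zero.  A level can instead be "saturated": all 78 covariance elements of
its 12 observed variables are free.  Mean structure is always saturated, so
degrees of freedom arise from covariance restrictions only.

Identification follows the unconstrained product-indicator approach: the
first loading of every latent variable (including the product term) is
fixed to 1, latent variances are free, and the covariances of the product
term with xi1 and xi2 are fixed to 0 (they vanish for jointly normal,
zero-mean predictors).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Literal

import numpy as np

from ._linalg import is_pd, vech

Level = Literal["within", "between"]

# Observed-variable layouts (fixed across the package).
WITHIN_VARS: tuple[str, ...] = (
    "y1", "y2", "y3", "x1", "x2", "x3", "x4", "x5", "x6", "pw1", "pw2", "pw3"
)
BETWEEN_VARS: tuple[str, ...] = (
    "y1", "y2", "y3", "x1", "x2", "x3", "x4", "x5", "x6", "pb1", "pb2", "pb3"
)
#: Group-level observed vector: means of the 12 within-varying columns
#: followed by the three between-only product indicators.
GROUP_VARS: tuple[str, ...] = WITHIN_VARS + ("pb1", "pb2", "pb3")

N_LEVEL_VARS = 12
N_GROUP_VARS = 15
N_LEVEL_MOMENTS = N_LEVEL_VARS * (N_LEVEL_VARS + 1) // 2  # 78
N_GROUP_MOMENTS = N_GROUP_VARS * (N_GROUP_VARS + 1) // 2  # 120

#: Coordinates of the 12 between-model variables inside the 15-dim group vector.
BETWEEN_IN_GROUP = np.array([0, 1, 2, 3, 4, 5, 6, 7, 8, 12, 13, 14])
#: Coordinates of the 12 within-model variables inside the group vector.
WITHIN_IN_GROUP = np.arange(12)

#: Default non-anchor loading: gives indicator reliability exactly 0.80
#: with error variance 0.20 (the conventional rounded value is 0.894).
LOADING_OTHER = math.sqrt(0.8)

MODEL_NAMES = ("M_W0B0", "M_WIB0", "M_W0BI", "M_WIBI")


@dataclass(frozen=True)
class PopulationConfig:
    """All data-generating constants for one Monte Carlo design cell."""

    n_groups: int
    group_size: int = 30
    phi21: float = 0.0
    gamma1: float = 0.30
    gamma2: float = 0.30
    gamma3_within: float = 0.0
    gamma3_between: float = 0.0
    loading_scale: float = 1.0
    loading_other: float = LOADING_OTHER
    err_var_scale: float = 0.25
    err_var_other: float = 0.20
    eta_var: float = 1.0
    n_y: int = 3
    n_x_per_factor: int = 3
    icc_target: float = 0.50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_groups < 1 or self.group_size < 1:
            raise ValueError("n_groups and group_size must be positive")
        if not -1.0 <= self.phi21 <= 1.0:
            raise ValueError("phi21 must lie in [-1, 1]")
        for g3 in (self.gamma3_within, self.gamma3_between):
            v = self.residual_variance_for(g3)
            if v <= 0.0:
                raise ValueError(f"implied residual variance {v} <= 0")

    @property
    def n_total(self) -> int:
        return self.n_groups * self.group_size

    def reliability(self, loading: float, err_var: float) -> float:
        return loading**2 * self.eta_var / (loading**2 * self.eta_var + err_var)

    def gamma3(self, level: Level) -> float:
        return self.gamma3_within if level == "within" else self.gamma3_between

    def residual_variance_for(self, gamma3: float) -> float:
        """zeta variance forcing Var(eta)=eta_var given the structural effects."""
        explained = (
            self.gamma1**2
            + self.gamma2**2
            + 2.0 * self.gamma1 * self.gamma2 * self.phi21
            + gamma3**2 * (1.0 + self.phi21**2)
        )
        return self.eta_var - explained

    def residual_variance(self, level: Level) -> float:
        return self.residual_variance_for(self.gamma3(level))

    @property
    def intercept_between(self) -> float:
        """alpha making E[eta_B]=0: cancels gamma3B * E[xi1B*xi2B]."""
        return -self.gamma3_between * self.phi21

    @property
    def model_name(self) -> str:
        w = "I" if self.gamma3_within else "0"
        b = "I" if self.gamma3_between else "0"
        return f"M_W{w}B{b}"

    @classmethod
    def from_model_name(
        cls,
        name: str,
        n_groups: int,
        group_size: int = 30,
        phi21: float = 0.0,
        seed: int = 0,
        interaction_effect: float = 0.20,
        **kwargs,
    ) -> "PopulationConfig":
        key = name.upper().removeprefix("M_")
        if key not in ("W0B0", "WIB0", "W0BI", "WIBI"):
            raise ValueError(f"unknown population model {name!r}")
        return cls(
            n_groups=n_groups,
            group_size=group_size,
            phi21=phi21,
            gamma3_within=interaction_effect if "WI" in key else 0.0,
            gamma3_between=interaction_effect if "BI" in key else 0.0,
            seed=seed,
            **kwargs,
        )

    def with_seed(self, seed: int) -> "PopulationConfig":
        return replace(self, seed=seed)


# ---------------------------------------------------------------------------
# Analysis specifications
# ---------------------------------------------------------------------------

Mode = Literal["structured", "saturated"]
Interaction = Literal["free", "fixed_zero"]

_SPEC_NAMES = {
    "W0B0": ("structured", "structured", "fixed_zero", "fixed_zero"),
    "WIB0": ("structured", "structured", "free", "fixed_zero"),
    "W0BI": ("structured", "structured", "fixed_zero", "free"),
    "WIBI": ("structured", "structured", "free", "free"),
    "PS_W0B_S": ("structured", "saturated", "fixed_zero", "fixed_zero"),
    "PS_WIB_S": ("structured", "saturated", "free", "fixed_zero"),
    "PS_W_S_B0": ("saturated", "structured", "fixed_zero", "fixed_zero"),
    "PS_W_S_BI": ("saturated", "structured", "fixed_zero", "free"),
    "SAT": ("saturated", "saturated", "fixed_zero", "fixed_zero"),
}


@dataclass(frozen=True)
class AnalysisSpec:
    """Which analysis model to fit: per level, saturated vs structured,
    interaction effect free vs fixed to zero."""

    within_mode: Mode = "structured"
    between_mode: Mode = "structured"
    within_interaction: Interaction = "free"
    between_interaction: Interaction = "free"

    within_layout: tuple[str, ...] = field(default=WITHIN_VARS)
    between_layout: tuple[str, ...] = field(default=BETWEEN_VARS)

    def interaction(self, level: Level) -> Interaction:
        return self.within_interaction if level == "within" else self.between_interaction

    def mode(self, level: Level) -> Mode:
        return self.within_mode if level == "within" else self.between_mode

    @classmethod
    def from_name(cls, name: str) -> "AnalysisSpec":
        key = name.strip().upper().replace("SATURATED", "SAT")
        if key not in _SPEC_NAMES:
            raise ValueError(f"unknown analysis model {name!r}; known: {sorted(_SPEC_NAMES)}")
        wm, bm, wi, bi = _SPEC_NAMES[key]
        return cls(wm, bm, wi, bi)

    @property
    def name(self) -> str:
        if self.within_mode == "saturated" and self.between_mode == "saturated":
            return "SAT"
        if self.between_mode == "saturated":
            return "PS_W%sB_s" % ("I" if self.within_interaction == "free" else "0")
        if self.within_mode == "saturated":
            return "PS_W_s_B%s" % ("I" if self.between_interaction == "free" else "0")
        return "W%sB%s" % (
            "I" if self.within_interaction == "free" else "0",
            "I" if self.between_interaction == "free" else "0",
        )

    def to_dict(self) -> dict:
        return {
            "within_mode": self.within_mode,
            "between_mode": self.between_mode,
            "within_interaction": self.within_interaction,
            "between_interaction": self.between_interaction,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisSpec":
        return cls(
            d.get("within_mode", "structured"),
            d.get("between_mode", "structured"),
            d.get("within_interaction", "free"),
            d.get("between_interaction", "free"),
        )


SATURATED = AnalysisSpec.from_name("SAT")


def is_nested(restricted: AnalysisSpec, full: AnalysisSpec) -> bool:
    """True if `restricted` is nested in `full` within this model family."""
    for level in ("within", "between"):
        mr, mf = restricted.mode(level), full.mode(level)
        if mr == "saturated" and mf != "saturated":
            return False
        if mr == "structured" and mf == "structured":
            if restricted.interaction(level) == "free" and full.interaction(level) != "free":
                return False
    return True


# ---------------------------------------------------------------------------
# Parameter layout
# ---------------------------------------------------------------------------

_STRUCT_NAMES_BASE = (
    ["lam_y2", "lam_y3", "lam_x2", "lam_x3", "lam_x5", "lam_x6", "lam_p2", "lam_p3"]
    + [f"th_{v}" for v in ("y1", "y2", "y3", "x1", "x2", "x3", "x4", "x5", "x6", "p1", "p2", "p3")]
    + ["phi11", "phi21", "phi22", "phi33", "gamma1", "gamma2"]
)


def level_param_names(mode: Mode, interaction: Interaction) -> list[str]:
    if mode == "saturated":
        iu = np.triu_indices(N_LEVEL_VARS)
        return [f"s_{i + 1}_{j + 1}" for i, j in zip(iu[0], iu[1])]
    names = list(_STRUCT_NAMES_BASE)
    if interaction == "free":
        names.append("gamma3")
    names.append("psi")
    return names


def count_free_params(spec: AnalysisSpec) -> tuple[int, int, int]:
    """Free parameters (within, between, total); a saturated level has 78,
    a structured level 28 (interaction free) or 27 (fixed to zero)."""
    counts = []
    for level in ("within", "between"):
        if spec.mode(level) == "saturated":
            counts.append(N_LEVEL_MOMENTS)
        else:
            counts.append(27 + (spec.interaction(level) == "free"))
    return counts[0], counts[1], counts[0] + counts[1]


def degrees_of_freedom(spec: AnalysisSpec) -> tuple[int, int, int]:
    """(df_within, df_between, df_total); each level contributes 78 minus its
    free parameter count, so a saturated level contributes 0."""
    w, b, _ = count_free_params(spec)
    return N_LEVEL_MOMENTS - w, N_LEVEL_MOMENTS - b, 2 * N_LEVEL_MOMENTS - w - b


@dataclass
class ParameterVector:
    """Ordered free parameters with a name -> index map.

    Names are prefixed "w." / "b." by level.  Variances are stored
    unconstrained; admissibility is checked after fitting, not enforced.
    """

    spec: AnalysisSpec
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = count_free_params(self.spec)[2]
        if self.values.shape != (expected,):
            raise ValueError(
                f"parameter vector has shape {self.values.shape}, "
                f"spec {self.spec.name} needs ({expected},)"
            )
        self.names: list[str] = parameter_names(self.spec)
        self.index: dict[str, int] = {n: i for i, n in enumerate(self.names)}

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.index[name]])

    def split(self) -> tuple[np.ndarray, np.ndarray]:
        nw = count_free_params(self.spec)[0]
        return self.values[:nw], self.values[nw:]

    def to_dict(self) -> dict[str, float]:
        return dict(zip(self.names, map(float, self.values)))


def parameter_names(spec: AnalysisSpec) -> list[str]:
    return [
        f"w.{n}" for n in level_param_names(spec.within_mode, spec.within_interaction)
    ] + [
        f"b.{n}" for n in level_param_names(spec.between_mode, spec.between_interaction)
    ]


# ---------------------------------------------------------------------------
# Implied moments
# ---------------------------------------------------------------------------


@dataclass
class ImpliedMoments:
    sigma_w: np.ndarray  # 12x12
    sigma_b: np.ndarray  # 12x12

    def sigma_group(self, group_size: int) -> np.ndarray:
        return group_sigma(self.sigma_w, self.sigma_b, group_size)


def group_sigma(sigma_w: np.ndarray, sigma_b: np.ndarray, group_size: int) -> np.ndarray:
    """Implied covariance of the 15-dim group-level vector: the common block
    gets Sigma_B + Sigma_W/NS, between-only products load only on Sigma_B,
    within-only products only on Sigma_W/NS."""
    g = np.zeros((N_GROUP_VARS, N_GROUP_VARS))
    g[:N_LEVEL_VARS, :N_LEVEL_VARS] += sigma_w / group_size
    g[np.ix_(BETWEEN_IN_GROUP, BETWEEN_IN_GROUP)] += sigma_b
    return g


def _structured_sigma(
    vals: np.ndarray, interaction: Interaction, want_jac: bool
) -> tuple[np.ndarray, np.ndarray | None]:
    """Sigma = Lambda Psi Lambda' + diag(theta) for one structured level.

    Latent order (xi1, xi2, xi1*xi2, eta).  Optionally returns the stack of
    d(Sigma)/d(param), shape (n_par, 12, 12).
    """
    free_g3 = interaction == "free"
    n_par = 28 if free_g3 else 27
    if vals.shape != (n_par,):
        raise ValueError(f"expected {n_par} level parameters, got {vals.shape}")
    lam = vals[:8]
    theta = vals[8:20]
    phi11, phi21, phi22, phi33 = vals[20:24]
    gamma1, gamma2 = vals[24:26]
    gamma3 = vals[26] if free_g3 else 0.0
    psi = vals[-1]

    L = np.zeros((N_LEVEL_VARS, 4))
    L[0:3, 3] = (1.0, lam[0], lam[1])
    L[3:6, 0] = (1.0, lam[2], lam[3])
    L[6:9, 1] = (1.0, lam[4], lam[5])
    L[9:12, 2] = (1.0, lam[6], lam[7])

    # Psi = B V B' with B = [[I3, 0], [gamma', 1]], V = blockdiag(Phi_xi, psi)
    gamma = np.array([gamma1, gamma2, gamma3])
    phi = np.array([[phi11, phi21, 0.0], [phi21, phi22, 0.0], [0.0, 0.0, phi33]])
    psi_mat = np.zeros((4, 4))
    psi_mat[:3, :3] = phi
    psi_mat[:3, 3] = psi_mat[3, :3] = phi @ gamma
    psi_mat[3, 3] = gamma @ phi @ gamma + psi

    M = L @ psi_mat  # 12x4, reused for loading derivatives
    sigma = M @ L.T
    sigma[np.diag_indices(N_LEVEL_VARS)] += theta

    if not want_jac:
        return sigma, None

    jac = np.zeros((n_par, N_LEVEL_VARS, N_LEVEL_VARS))
    # loadings: dSigma = e_r (L Psi)_{.,k}' + (L Psi)_{.,k} e_r'
    load_pos = [(1, 3), (2, 3), (4, 0), (5, 0), (7, 1), (8, 1), (10, 2), (11, 2)]
    for p, (row, k) in enumerate(load_pos):
        col = M[:, k]
        jac[p, row, :] += col
        jac[p, :, row] += col
    # residual variances
    for p in range(12):
        jac[8 + p, p, p] = 1.0
    # latent covariance parameters via dPsi = B dV B' (B = [[I,0],[gamma',1]])
    def _psi_jac_from_dv(dv: np.ndarray) -> np.ndarray:
        dpsi = np.zeros((4, 4))
        dphi = dv[:3, :3]
        dpsi[:3, :3] = dphi
        dpsi[:3, 3] = dpsi[3, :3] = dphi @ gamma
        dpsi[3, 3] = gamma @ dphi @ gamma + dv[3, 3]
        return dpsi

    dv_list = []
    for (i, j) in ((0, 0), (0, 1), (1, 1), (2, 2)):  # phi11, phi21, phi22, phi33
        dv = np.zeros((4, 4))
        dv[i, j] = dv[j, i] = 1.0
        dv_list.append(dv)
    for p, dv in enumerate(dv_list):
        dpsi = _psi_jac_from_dv(dv)
        jac[20 + p] = L @ dpsi @ L.T
    # gamma derivatives: dB = E_{3,r}; dPsi = dB V B' + B V dB'
    v_mat = np.zeros((4, 4))
    v_mat[:3, :3] = phi
    v_mat[3, 3] = psi
    b_mat = np.eye(4)
    b_mat[3, :3] = gamma
    vb = v_mat @ b_mat.T
    gamma_idx = [24, 25] + ([26] if free_g3 else [])
    for p, r in zip(gamma_idx, range(3) if free_g3 else range(2)):
        db = np.zeros((4, 4))
        db[3, r] = 1.0
        dpsi = db @ vb
        dpsi = dpsi + dpsi.T
        jac[p] = L @ dpsi @ L.T
    # psi (zeta variance): dV = E_{3,3}
    dv = np.zeros((4, 4))
    dv[3, 3] = 1.0
    dpsi = _psi_jac_from_dv(dv)
    jac[n_par - 1] = L @ dpsi @ L.T
    return sigma, jac


@lru_cache(maxsize=2)
def _saturated_basis(p: int = N_LEVEL_VARS) -> np.ndarray:
    """Constant Jacobian of a saturated level: symmetric basis matrices."""
    iu = np.triu_indices(p)
    n = len(iu[0])
    jac = np.zeros((n, p, p))
    for k, (i, j) in enumerate(zip(iu[0], iu[1])):
        jac[k, i, j] = jac[k, j, i] = 1.0
    return jac


def _saturated_sigma(vals: np.ndarray, want_jac: bool) -> tuple[np.ndarray, np.ndarray | None]:
    from ._linalg import unvech

    sigma = unvech(vals, N_LEVEL_VARS)
    return sigma, (_saturated_basis() if want_jac else None)


def level_sigma(
    vals: np.ndarray, mode: Mode, interaction: Interaction, want_jac: bool = False
) -> tuple[np.ndarray, np.ndarray | None]:
    if mode == "saturated":
        return _saturated_sigma(vals, want_jac)
    return _structured_sigma(vals, interaction, want_jac)


def implied_moments(theta: ParameterVector | np.ndarray, spec: AnalysisSpec) -> ImpliedMoments:
    """Level-specific model-implied augmented covariance matrices."""
    if not isinstance(theta, ParameterVector):
        theta = ParameterVector(spec, theta)
    vw, vb = theta.split()
    if not (np.all(np.isfinite(vw)) and np.all(np.isfinite(vb))):
        raise ValueError("non-finite parameter values")
    sw, _ = level_sigma(vw, spec.within_mode, spec.within_interaction)
    sb, _ = level_sigma(vb, spec.between_mode, spec.between_interaction)
    return ImpliedMoments(sigma_w=sw, sigma_b=sb)


def moment_jacobian(theta: ParameterVector, group_size: int) -> np.ndarray:
    """Jacobian of (vech Sigma_W, vech Sigma_group) w.r.t. the free parameters.

    Shape (n_par, 78 + 120).  Used by the robust (sandwich) scaling factor.
    """
    spec = theta.spec
    vw, vb = theta.split()
    _, jw = level_sigma(vw, spec.within_mode, spec.within_interaction, want_jac=True)
    _, jb = level_sigma(vb, spec.between_mode, spec.between_interaction, want_jac=True)
    n_par = len(theta.values)
    out = np.zeros((n_par, N_LEVEL_MOMENTS + N_GROUP_MOMENTS))
    nw = jw.shape[0]
    # within parameters: affect Sigma_W directly and Sigma_group via /NS
    gW = np.zeros((nw, N_GROUP_VARS, N_GROUP_VARS))
    gW[:, :N_LEVEL_VARS, :N_LEVEL_VARS] = jw / group_size
    out[:nw, :N_LEVEL_MOMENTS] = vech(jw)
    out[:nw, N_LEVEL_MOMENTS:] = vech(gW)
    # between parameters: affect Sigma_group only
    gB = np.zeros((jb.shape[0], N_GROUP_VARS, N_GROUP_VARS))
    gB[:, BETWEEN_IN_GROUP[:, None], BETWEEN_IN_GROUP[None, :]] = jb
    out[nw:, N_LEVEL_MOMENTS:] = vech(gB)
    return out


# ---------------------------------------------------------------------------
# Population parameter values
# ---------------------------------------------------------------------------


def population_level_values(
    config: PopulationConfig, level: Level, interaction: Interaction
) -> np.ndarray:
    """Population values of one structured level's parameter subvector.

    The product-indicator measurement parameters follow from normal-theory
    moment algebra: matched pair (k, l) has loading lam_k*lam_l on the
    product factor and residual variance Var(x_k)Var(x_l) - (lam_k*lam_l)^2
    (the Cov(x_k, x_l)^2 term cancels against the phi21^2 part of
    Var(xi1*xi2) = 1 + phi21^2).
    """
    s, o = config.loading_scale, config.loading_other
    ths, tho = config.err_var_scale, config.err_var_other
    phi = config.phi21
    g3 = config.gamma3(level)
    lam = [o, o, o, o, o, o]  # y2, y3, x2, x3, x5, x6
    phi33 = 1.0 + phi**2
    pair_lams = [s * s, o * o, o * o]
    lam_p = [pair_lams[1] / pair_lams[0], pair_lams[2] / pair_lams[0]]
    var_x = [s * s + ths, o * o + tho, o * o + tho]
    th_p = [
        var_x[0] * var_x[0] + (s * s * phi) ** 2 - pair_lams[0] ** 2 * phi33,
        var_x[1] * var_x[1] + (o * o * phi) ** 2 - pair_lams[1] ** 2 * phi33,
        var_x[2] * var_x[2] + (o * o * phi) ** 2 - pair_lams[2] ** 2 * phi33,
    ]
    vals = (
        lam[:2]
        + lam[2:6]
        + lam_p
        + [ths, tho, tho, ths, tho, tho, ths, tho, tho]
        + th_p
        + [1.0, phi, 1.0, phi33 * pair_lams[0] ** 2]
        + [config.gamma1, config.gamma2]
    )
    # gamma3 on the product factor as scaled by its anchor: anchor loading is
    # lam1*lam4 = 1 for the default scale loadings, so gamma3 is unchanged.
    if interaction == "free":
        vals.append(g3 / pair_lams[0])
    vals.append(config.residual_variance(level))
    return np.asarray(vals, dtype=float)


def population_theta(config: PopulationConfig, spec: AnalysisSpec) -> ParameterVector:
    """Population parameter vector for `spec`; saturated levels get the
    population implied covariance elements."""
    parts = []
    for level in ("within", "between"):
        if spec.mode(level) == "saturated":
            vals = population_level_values(
                config, level, "free" if config.gamma3(level) else "fixed_zero"
            )
            sig, _ = _structured_sigma(
                vals, "free" if config.gamma3(level) else "fixed_zero", False
            )
            parts.append(vech(sig))
        else:
            parts.append(
                population_level_values(config, level, spec.interaction(level))
            )
    return ParameterVector(spec, np.concatenate(parts))


def population_moments(config: PopulationConfig) -> ImpliedMoments:
    """Population augmented covariance matrices Sigma*_W and Sigma*_B."""
    sw, _ = _structured_sigma(
        population_level_values(config, "within", "free"), "free", False
    )
    sb, _ = _structured_sigma(
        population_level_values(config, "between", "free"), "free", False
    )
    return ImpliedMoments(sigma_w=sw, sigma_b=sb)


def check_admissible(theta: ParameterVector) -> bool:
    """All variances non-negative and implied level matrices positive definite."""
    for name, value in zip(theta.names, theta.values):
        base = name.split(".", 1)[1]
        if base.startswith(("th_", "psi", "phi11", "phi22", "phi33")) and value < 0:
            return False
        if base.startswith("s_"):
            i, j = base.split("_")[1:]
            if i == j and value < 0:
                return False
    mom = implied_moments(theta, theta.spec)
    return is_pd(mom.sigma_w) and is_pd(mom.sigma_b)
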