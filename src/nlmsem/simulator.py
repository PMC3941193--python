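"""Generate balanced two-level datasets from the four population models.

Each observed indicator is the sum of an independent between-group and a
within-group component (random-intercept decomposition).  Both components
follow the same nonlinear factor model: two correlated exogenous latents,
their product, and an endogenous latent measured by three indicators each,
with loadings (1, .894, .894), error variances (.25, .20, .20) and latent
variances 1 at each level, so every indicator has reliability 0.80 and an
intraclass correlation of 0.50.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .model_core import Level, PopulationConfig

INDICATOR_COLS = ("y1", "y2", "y3", "x1", "x2", "x3", "x4", "x5", "x6")


@dataclass
class TwoLevelDataset:
    """Balanced subject-by-indicator table with group ids.

    ``latent`` (the truth channel) optionally retains the generated latent
    scores for parameter-recovery and oracle tests; it is never used by the
    analysis pipeline.
    """

    group_id: np.ndarray  # (N,)
    indicators: np.ndarray  # (N, 9) columns INDICATOR_COLS
    config: PopulationConfig
    latent: dict[str, np.ndarray] | None = None

    @property
    def n_groups(self) -> int:
        return self.config.n_groups

    @property
    def group_size(self) -> int:
        return self.config.group_size

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.indicators, columns=list(INDICATOR_COLS))
        df.insert(0, "group_id", self.group_id)
        return df

    def write_csv(self, path: str | Path) -> None:
        """One row per subject; the generating config goes in a JSON sidecar."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        cfg = {
            k: getattr(self.config, k)
            for k in (
                "n_groups", "group_size", "phi21", "gamma1", "gamma2",
                "gamma3_within", "gamma3_between", "loading_scale",
                "loading_other", "err_var_scale", "err_var_other", "seed",
            )
        }
        path.with_suffix(".config.json").write_text(json.dumps(cfg, indent=1))

    @classmethod
    def read_csv(cls, path: str | Path, config: PopulationConfig | None = None) -> "TwoLevelDataset":
        path = Path(path)
        df = pd.read_csv(path)
        if config is None:
            sidecar = path.with_suffix(".config.json")
            cfg = json.loads(sidecar.read_text())
            config = PopulationConfig(**cfg)
        return cls(
            group_id=df["group_id"].to_numpy(),
            indicators=df[list(INDICATOR_COLS)].to_numpy(dtype=float),
            config=config,
        )


def population_residual_variance(config: PopulationConfig, level: Level) -> float:
    """zeta variance giving Var(eta)=1:  1 - [g1^2 + g2^2 + 2 g1 g2 phi21
    + g3^2 (1 + phi21^2)]."""
    v = config.residual_variance(level)
    if v <= 0:
        raise ValueError(f"residual variance {v} <= 0 for level {level}")
    return v


def population_intercept(config: PopulationConfig) -> float:
    """alpha = -gamma3B * phi21, cancelling E[xi1B * xi2B]."""
    return config.intercept_between


def _component(
    config: PopulationConfig, level: Level, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Draw n i.i.d. rows of one level's latent system and its 9 indicators."""
    phi = np.array([[1.0, config.phi21], [config.phi21, 1.0]])
    try:
        chol = np.linalg.cholesky(phi)
    except np.linalg.LinAlgError as exc:
        raise ValueError("predictor covariance matrix not positive definite") from exc
    xi = rng.standard_normal((n, 2)) @ chol.T
    g3 = config.gamma3(level)
    zeta = rng.normal(0.0, np.sqrt(config.residual_variance(level)), size=n)
    # the product term is centered (equivalently alpha = -g3*phi21) so that
    # the component, and hence every indicator, has mean zero
    eta = (
        config.gamma1 * xi[:, 0]
        + config.gamma2 * xi[:, 1]
        + g3 * (xi[:, 0] * xi[:, 1] - config.phi21)
        + zeta
    )
    lam = np.array([config.loading_scale, config.loading_other, config.loading_other])
    evar = np.array([config.err_var_scale, config.err_var_other, config.err_var_other])
    out = np.empty((n, 9))
    out[:, 0:3] = eta[:, None] * lam + rng.normal(0.0, np.sqrt(evar), size=(n, 3))
    out[:, 3:6] = xi[:, [0]] * lam + rng.normal(0.0, np.sqrt(evar), size=(n, 3))
    out[:, 6:9] = xi[:, [1]] * lam + rng.normal(0.0, np.sqrt(evar), size=(n, 3))
    return out, {"xi1": xi[:, 0], "xi2": xi[:, 1], "eta": eta}


def simulate_dataset(
    config: PopulationConfig,
    rng: np.random.Generator | None = None,
    keep_latent: bool = False,
) -> TwoLevelDataset:
    """Simulate one balanced two-level dataset (observed = between + within)."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    ng, ns = config.n_groups, config.group_size
    between, lat_b = _component(config, "between", ng, rng)
    within, lat_w = _component(config, "within", ng * ns, rng)
    group_id = np.repeat(np.arange(ng), ns)
    indicators = between[group_id] + within
    latent = None
    if keep_latent:
        latent = {f"{k}_b": v for k, v in lat_b.items()}
        latent.update({f"{k}_w": v for k, v in lat_w.items()})
        latent["between"] = between
        latent["within"] = within
    return TwoLevelDataset(group_id=group_id, indicators=indicators, config=config, latent=latent)


def icc_anova(dataset: TwoLevelDataset) -> np.ndarray:
    """Per-indicator intraclass correlation from the one-way random-effects
    ANOVA estimator (between variance over total variance)."""
    ng, ns = dataset.n_groups, dataset.group_size
    x = dataset.indicators.reshape(ng, ns, -1)
    gmeans = x.mean(axis=1)
    grand = gmeans.mean(axis=0)
    msa = ns * ((gmeans - grand) ** 2).sum(axis=0) / (ng - 1)
    msw = ((x - gmeans[:, None, :]) ** 2).sum(axis=(0, 1)) / (ng * (ns - 1))
    tau2 = np.clip((msa - msw) / ns, 0.0, None)
    return tau2 / (tau2 + msw)
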