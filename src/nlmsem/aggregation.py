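"""Latent aggregation and sufficient statistics for balanced two-level ML.

Observed indicators are decomposed into estimated between-group and
within-group components.  The between component of each indicator is the
empirical-Bayes prediction from a one-way random-intercept model (the
shrunken group mean); the within component is the observed value minus the
between estimate, so the decomposition reconstructs the data exactly.
Matched-pair product indicators are then built at each level —
(x1,x4), (x2,x5), (x3,x6) — pairing indicators of equal reliability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._linalg import vech
from .model_core import N_GROUP_MOMENTS, N_LEVEL_MOMENTS, WITHIN_VARS
from .simulator import INDICATOR_COLS, TwoLevelDataset

logger = logging.getLogger(__name__)

#: matched pairs as column indices into the 9 indicator columns (x1..x6 are 3..8)
PRODUCT_PAIRS = ((3, 6), (4, 7), (5, 8))


@dataclass
class RandomInterceptFit:
    """Per-indicator balanced one-way random-intercept ML solution."""

    mu: float
    tau2: float  # between-group variance
    sigma2: float  # within-group variance
    shrinkage: float  # w = tau2 / (tau2 + sigma2/NS)


@dataclass
class Decomposition:
    between: np.ndarray  # (NG, 9) EB between-component estimates
    within: np.ndarray  # (N, 9)  observed minus between estimate
    group_id: np.ndarray
    fits: list[RandomInterceptFit]
    group_size: int
    n_groups: int


@dataclass
class AugmentedDataset:
    """Per-level variable sets after decomposition and product construction."""

    within_vars: np.ndarray  # (N, 12): y1..y3, x1..x6 within comps, pw1..pw3
    between_vars: np.ndarray  # (NG, 15): group means of the 12, plus pb1..pb3
    group_id: np.ndarray
    group_size: int
    n_groups: int

    def within_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.within_vars, columns=list(WITHIN_VARS))
        df.insert(0, "group_id", self.group_id)
        return df

    def between_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.between_vars, columns=[f"m_{v}" for v in WITHIN_VARS] + ["pb1", "pb2", "pb3"])
        df.insert(0, "group_id", np.arange(self.n_groups))
        return df


@dataclass
class SufficientStats:
    """Balanced two-level moment summaries plus per-group contributions.

    ``s_pw`` is the pooled within-group covariance (divisor N-J) of the 12
    within-varying variables; ``s_b`` the covariance of the 15 group-level
    variables around the grand mean (divisor J-1).  ``group_moments`` holds
    each group's contribution to (vech s_pw, vech s_b), the i.i.d. units
    that drive the robust scaling factor.
    """

    s_pw: np.ndarray  # (12, 12)
    s_b: np.ndarray  # (15, 15)
    n_groups: int
    group_size: int
    group_moments: np.ndarray | None = None  # (J, 78 + 120)

    @property
    def n_total(self) -> int:
        return self.n_groups * self.group_size


def fit_random_intercept(values: np.ndarray, n_groups: int, group_size: int) -> RandomInterceptFit:
    """Closed-form ML for the balanced one-way random-intercept model.

    With a profiled grand mean, sigma2_hat = SSW/(N-J) and the ML between
    variance is tau2_hat = max(0, c*sum((xbar_j - xbar)^2)/J - sigma2_hat)/c.
    """
    x = values.reshape(n_groups, group_size)
    gmeans = x.mean(axis=1)
    mu = float(gmeans.mean())
    ssw = float(((x - gmeans[:, None]) ** 2).sum())
    sigma2 = ssw / (n_groups * (group_size - 1))
    m = group_size * float(((gmeans - mu) ** 2).mean())
    tau2 = max(0.0, (m - sigma2) / group_size)
    if tau2 == 0.0:
        logger.warning("between-group variance estimated at boundary 0; using grand mean")
        w = 0.0
    else:
        w = tau2 / (tau2 + sigma2 / group_size)
    return RandomInterceptFit(mu=mu, tau2=tau2, sigma2=sigma2, shrinkage=w)


def estimate_between_components(
    dataset: TwoLevelDataset, method: str = "eb"
) -> tuple[np.ndarray, list[RandomInterceptFit]]:
    """Per-group between-component estimates for each of the 9 indicators.

    ``method="eb"`` gives empirical-Bayes predictions mu + w*(xbar_j - mu);
    ``method="group_mean"`` returns the raw group means (w = 1), provided as
    a sensitivity switch.
    """
    ng, ns = dataset.n_groups, dataset.group_size
    x = dataset.indicators.reshape(ng, ns, -1)
    gmeans = x.mean(axis=1)
    fits = [
        fit_random_intercept(dataset.indicators[:, k], ng, ns)
        for k in range(len(INDICATOR_COLS))
    ]
    if method == "group_mean":
        return gmeans, fits
    if method != "eb":
        raise ValueError(f"unknown aggregation method {method!r}")
    mu = np.array([f.mu for f in fits])
    w = np.array([f.shrinkage for f in fits])
    return mu + w * (gmeans - mu), fits


def decompose(dataset: TwoLevelDataset, method: str = "eb") -> Decomposition:
    """Split every indicator into between estimate plus within remainder;
    the two add back to the observed value exactly."""
    between, fits = estimate_between_components(dataset, method=method)
    within = dataset.indicators - between[dataset.group_id]
    return Decomposition(
        between=between,
        within=within,
        group_id=dataset.group_id,
        fits=fits,
        group_size=dataset.group_size,
        n_groups=dataset.n_groups,
    )


def build_products(decomp: Decomposition) -> AugmentedDataset:
    """Append matched-pair product indicators at each level.

    Between components are centered at their grand mean before
    multiplication; within components are already centered by construction.
    """
    ng, ns = decomp.n_groups, decomp.group_size
    pw = np.column_stack(
        [decomp.within[:, k] * decomp.within[:, l] for k, l in PRODUCT_PAIRS]
    )
    bc = decomp.between - decomp.between.mean(axis=0)
    pb = np.column_stack([bc[:, k] * bc[:, l] for k, l in PRODUCT_PAIRS])
    within_vars = np.hstack([decomp.within, pw])
    # group-level observed vector: group means of the reconstructed observed
    # indicators (between estimate + within component), group means of the
    # within products, then the between-only products
    observed = decomp.within + decomp.between[decomp.group_id]
    obs_means = observed.reshape(ng, ns, -1).mean(axis=1)
    pw_means = pw.reshape(ng, ns, -1).mean(axis=1)
    between_vars = np.hstack([obs_means, pw_means, pb])
    return AugmentedDataset(
        within_vars=within_vars,
        between_vars=between_vars,
        group_id=decomp.group_id,
        group_size=ns,
        n_groups=ng,
    )


def aggregate(dataset: TwoLevelDataset, method: str = "eb") -> AugmentedDataset:
    """Decompose and build products in one step."""
    return build_products(decompose(dataset, method=method))


def sufficient_stats(aug: AugmentedDataset, keep_group_moments: bool = True) -> SufficientStats:
    """Pooled within and between covariance matrices of the augmented data."""
    ng, ns = aug.n_groups, aug.group_size
    if ng < 2:
        raise ValueError("at least two groups are required")
    wv = aug.within_vars.reshape(ng, ns, -1)
    gmeans = wv.mean(axis=1)
    dev = wv - gmeans[:, None, :]
    # per-group pooled-within contributions W_j with divisor NS-1 so that
    # s_pw (divisor N-J) is their unweighted mean over groups
    if ns < 2:
        raise ValueError("group size must be at least 2 for a pooled within matrix")
    w_j = np.einsum("jip,jiq->jpq", dev, dev) / (ns - 1)
    s_pw = w_j.mean(axis=0)
    gv = aug.between_vars
    gd = gv - gv.mean(axis=0)
    s_b = gd.T @ gd / (ng - 1)
    group_moments = None
    if keep_group_moments:
        b_j = np.einsum("jp,jq->jpq", gd, gd) * (ng / (ng - 1))
        group_moments = np.concatenate([vech(w_j), vech(b_j)], axis=1)
        assert group_moments.shape == (ng, N_LEVEL_MOMENTS + N_GROUP_MOMENTS)
    return SufficientStats(
        s_pw=s_pw,
        s_b=s_b,
        n_groups=ng,
        group_size=ns,
        group_moments=group_moments,
    )


def stats_from_dataset(dataset: TwoLevelDataset, method: str = "eb", keep_group_moments: bool = True) -> SufficientStats:
    return sufficient_stats(aggregate(dataset, method=method), keep_group_moments=keep_group_moments)
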