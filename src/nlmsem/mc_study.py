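"""Monte Carlo engine: rejection rates and mean statistics over design cells.

The experimental design crosses four population models (interaction effects
at neither, one, or both levels), three numbers of groups (200, 500, 1000),
and two predictor correlations (0, 0.30) — 24 cells.  For each cell a
battery of analysis models is fitted to every replication and the
chi-square / robust chi-square overall tests, level-specific partially
saturated tests, and chi-square difference tests are tallied at a nominal
alpha of 0.05 (rejection when p < alpha, strictly).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .aggregation import stats_from_dataset
from .estimation import FitResult, diff_test, fit, mlr_scale, overall_test
from .model_core import SATURATED, AnalysisSpec, PopulationConfig, degrees_of_freedom
from .simulator import simulate_dataset

logger = logging.getLogger(__name__)

NG_LEVELS = (200, 500, 1000)
PHI_LEVELS = (0.0, 0.30)
POPULATION_MODELS = ("M_W0B0", "M_WIB0", "M_W0BI", "M_WIBI")

#: analysis battery per population model (overall/partial chi-square tests
#: and nested difference-test pairs)
DEFAULT_PLAN: dict[str, dict] = {
    "M_WIBI": {
        "chi_tests": ["WIBI", "PS_WIB_s", "PS_W_s_BI", "W0BI", "WIB0", "PS_W0B_s", "PS_W_s_B0"],
        "diff_tests": [],
    },
    "M_W0B0": {
        "chi_tests": [],
        "diff_tests": [("W0B0", "WIBI"), ("PS_W0B_s", "PS_WIB_s"), ("PS_W_s_B0", "PS_W_s_BI")],
    },
    "M_WIB0": {
        "chi_tests": [],
        "diff_tests": [("W0B0", "WIB0"), ("PS_W0B_s", "PS_WIB_s")],
    },
    "M_W0BI": {
        "chi_tests": [],
        "diff_tests": [("W0B0", "W0BI"), ("PS_W_s_B0", "PS_W_s_BI")],
    },
}


@dataclass
class StudyConfig:
    """Configuration for one Monte Carlo study run."""

    population_models: tuple[str, ...] = POPULATION_MODELS
    ng_levels: tuple[int, ...] = NG_LEVELS
    phi_levels: tuple[float, ...] = PHI_LEVELS
    group_size: int = 30
    replications: int = 200
    master_seed: int = 20140304
    alpha: float = 0.05
    plan: dict = field(default_factory=lambda: DEFAULT_PLAN)

    def __post_init__(self) -> None:
        if self.replications < 1:
            raise ValueError("replications must be >= 1")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        kwargs = {k: d[k] for k in (
            "population_models", "ng_levels", "phi_levels", "group_size",
            "replications", "master_seed", "alpha", "plan",
        ) if k in d}
        for key in ("population_models", "ng_levels", "phi_levels"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


def replication_rng(master_seed: int, cell: tuple, rep: int) -> np.random.Generator:
    """Deterministic per-replication generator: any single replication is
    reproducible in isolation from (master seed, cell identifier, index)."""
    model, ng, phi = cell
    entropy = [int(master_seed), POPULATION_MODELS.index(model), int(ng), int(round(phi * 100)), int(rep)]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def run_replication(
    config: PopulationConfig,
    rng: np.random.Generator,
    chi_tests: list[str],
    diff_tests: list[tuple[str, str]],
    estimators: tuple[str, ...] = ("ML", "MLR"),
) -> list[dict]:
    """Simulate one dataset and evaluate the full analysis battery on it."""
    dataset = simulate_dataset(config, rng=rng)
    stats = stats_from_dataset(dataset)
    fits: dict[str, FitResult] = {}
    records: list[dict] = []
    robust = "MLR" in estimators
    need_sat = bool(chi_tests) or (robust and bool(diff_tests))
    if need_sat:
        fits[SATURATED.name] = fit(stats, SATURATED)
    for name in chi_tests:
        spec = AnalysisSpec.from_name(name)
        f = fits.get(name) or fit(stats, spec)
        fits[name] = f
        test = overall_test(f, fits[SATURATED.name])
        if robust:
            test = mlr_scale(f, fits[SATURATED.name], stats, test)
        records.append(
            {
                "analysis": name,
                "kind": "chi2",
                "df": test.df,
                "t_ml": test.t_ml,
                "p_ml": test.p_ml,
                "t_mlr": test.t_mlr,
                "p_mlr": test.p_mlr,
                "scaling_c": test.scaling_c,
                "converged": f.converged and fits[SATURATED.name].converged,
                "admissible": f.admissible,
            }
        )
    for rname, fname in diff_tests:
        sr, sf = AnalysisSpec.from_name(rname), AnalysisSpec.from_name(fname)
        test, fr, ff = diff_test(stats, sr, sf, fits=fits, robust=robust)
        records.append(
            {
                "analysis": f"{rname} vs {fname}",
                "kind": "diff",
                "df": test.df,
                "t_ml": test.t_ml,
                "p_ml": test.p_ml,
                "t_mlr": test.t_mlr,
                "p_mlr": test.p_mlr,
                "scaling_c": test.scaling_c,
                "converged": fr.converged and ff.converged,
                "admissible": fr.admissible and ff.admissible,
            }
        )
    return records


def run_cell(
    pop_config: PopulationConfig,
    replications: int,
    master_seed: int,
    chi_tests: list[str] | None = None,
    diff_tests: list[tuple[str, str]] | None = None,
    alpha: float = 0.05,
    estimators: tuple[str, ...] = ("ML", "MLR"),
) -> pd.DataFrame:
    """All replications of one design cell; returns per-replication records."""
    model = pop_config.model_name
    cell = (model, pop_config.n_groups, pop_config.phi21)
    plan = DEFAULT_PLAN.get(model, {"chi_tests": [], "diff_tests": []})
    chi_tests = plan["chi_tests"] if chi_tests is None else chi_tests
    diff_tests = plan["diff_tests"] if diff_tests is None else diff_tests
    rows = []
    for rep in range(replications):
        rng = replication_rng(master_seed, cell, rep)
        try:
            records = run_replication(pop_config, rng, chi_tests, diff_tests, estimators)
        except Exception:  # noqa: BLE001 - a failed replication is data, not fatal
            logger.exception("replication %d of cell %s failed", rep, cell)
            records = [{"analysis": "<failed>", "kind": "error", "converged": False, "admissible": False}]
        for rec in records:
            rec.update(
                {
                    "population": model,
                    "ng": pop_config.n_groups,
                    "ns": pop_config.group_size,
                    "phi21": pop_config.phi21,
                    "replication": rep,
                }
            )
            logger.info(
                "cell=%s rep=%d analysis=%s converged=%s admissible=%s t_ml=%s t_mlr=%s",
                cell, rep, rec.get("analysis"), rec.get("converged"),
                rec.get("admissible"), rec.get("t_ml"), rec.get("t_mlr"),
            )
        rows.extend(records)
    if not rows:
        raise RuntimeError(f"cell {cell}: no analyses produced any records")
    df = pd.DataFrame(rows)
    if not df["converged"].any():
        raise RuntimeError(f"cell {cell}: all replications failed")
    return df


def tally(records: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Aggregate per-replication records into mean statistics and rejection
    percentages over converged, admissible replications, with binomial
    Monte Carlo standard errors."""
    records = records[records["kind"] != "error"]
    out = []
    keys = ["population", "ng", "phi21", "analysis", "kind"]
    for key, grp in records.groupby(keys, sort=False):
        used = grp[grp["converged"] & grp["admissible"]]
        n_used = len(used)
        row = dict(zip(keys, key))
        row.update(
            {
                "df": int(used["df"].iloc[0]) if n_used else None,
                "n_used": n_used,
                "n_nonconverged": int((~grp["converged"]).sum()),
                "n_inadmissible": int((grp["converged"] & ~grp["admissible"]).sum()),
            }
        )
        for est, tcol, pcol in (("ml", "t_ml", "p_ml"), ("mlr", "t_mlr", "p_mlr")):
            if n_used and used[tcol].notna().all():
                rate = float((used[pcol] < alpha).mean() * 100.0)
                row[f"mean_chi2_{est}"] = float(used[tcol].mean())
                row[f"reject_{est}_pct"] = rate
                p = rate / 100.0
                row[f"reject_{est}_se_pct"] = float(np.sqrt(p * (1 - p) / n_used) * 100.0)
            else:
                row[f"mean_chi2_{est}"] = row[f"reject_{est}_pct"] = row[f"reject_{est}_se_pct"] = np.nan
        out.append(row)
    return pd.DataFrame(out)


def run_study(config: StudyConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All requested cells; returns (per-replication records, tallied table)."""
    all_records = []
    for model in config.population_models:
        plan = config.plan.get(model, {"chi_tests": [], "diff_tests": []})
        if not plan["chi_tests"] and not plan["diff_tests"]:
            continue
        for ng in config.ng_levels:
            for phi in config.phi_levels:
                pop = PopulationConfig.from_model_name(
                    model, n_groups=ng, group_size=config.group_size, phi21=phi
                )
                logger.info("running cell %s NG=%d phi21=%.2f", model, ng, phi)
                rec = run_cell(
                    pop,
                    replications=config.replications,
                    master_seed=config.master_seed,
                    chi_tests=plan["chi_tests"],
                    diff_tests=plan["diff_tests"],
                    alpha=config.alpha,
                )
                all_records.append(rec)
    records = pd.concat(all_records, ignore_index=True)
    return records, tally(records, alpha=config.alpha)


# ---------------------------------------------------------------------------
# Publication-style table layouts
# ---------------------------------------------------------------------------

_TABLE_LAYOUT = {
    2: ("M_WIBI", "chi2", ["WIBI", "PS_WIB_s", "PS_W_s_BI"], (0.0,)),
    3: ("M_WIBI", "chi2", ["W0BI", "PS_W0B_s", "WIB0", "PS_W_s_B0"], (0.0, 0.30)),
    4: ("M_W0B0", "diff", ["W0B0 vs WIBI", "PS_W0B_s vs PS_WIB_s", "PS_W_s_B0 vs PS_W_s_BI"], (0.0, 0.30)),
    5: ("M_WIB0", "diff", ["W0B0 vs WIB0", "PS_W0B_s vs PS_WIB_s"], (0.0, 0.30)),
    6: ("M_W0BI", "diff", ["W0B0 vs W0BI", "PS_W_s_B0 vs PS_W_s_BI"], (0.0, 0.30)),
}


def summarize(tallied: pd.DataFrame, table: int) -> pd.DataFrame:
    """Reshape a tallied study into the layout of one results table
    (2: Type-I of correct models, ML vs MLR; 3: power of misspecified
    models; 4-6: difference tests), NG rows by analysis columns."""
    if table not in _TABLE_LAYOUT:
        raise ValueError(f"table must be one of {sorted(_TABLE_LAYOUT)}")
    model, kind, analyses, phis = _TABLE_LAYOUT[table]
    if tallied.empty or "population" not in tallied.columns:
        logger.warning("table %d: no tallied results", table)
        return pd.DataFrame()
    sub = tallied[(tallied["population"] == model) & (tallied["kind"] == kind)]
    rows = []
    estimators = ("ml", "mlr") if table == 2 else ("mlr",)
    for phi in phis:
        for est in estimators:
            for ng in sorted(sub["ng"].unique()):
                row = {"phi21": phi, "estimator": est.upper(), "ng": ng}
                for a in analyses:
                    cell = sub[(sub["ng"] == ng) & (sub["phi21"] == phi) & (sub["analysis"] == a)]
                    if cell.empty:
                        logger.warning("table %d: missing cell %s ng=%s phi=%s", table, a, ng, phi)
                        continue
                    cell = cell.iloc[0]
                    row[f"{a}:chi2"] = round(cell[f"mean_chi2_{est}"], 2)
                    row[f"{a}:df"] = cell["df"]
                    row[f"{a}:reject_pct"] = round(cell[f"reject_{est}_pct"], 1)
                rows.append(row)
    return pd.DataFrame(rows)
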