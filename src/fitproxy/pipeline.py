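"""End-to-end analysis: ingest or simulate a population, gene-drop the
pedigree, compute the short-term fitness proxies for the founder cohort, and
compare them against pedigree-derived reproductive values and lineage
survival.

Outputs mirror the shapes of the study's tables and figures: a per-founder
fitness table joined with reproductive values, a proxy-by-stage correlation
table, an age-class correlation table for annual de-lifed fitness, a
logistic-regression table for lineage survival, and the reproductive-value
stabilisation curve.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .genedrop import (
    GeneDropResult,
    lineage_longevity,
    lineage_survives,
    run_gene_drop,
    stabilisation_curve,
)
from .metrics import (
    OFFSPRING_STAGES,
    annual_delifed_by_age,
    build_transition_matrix,
    delifed_lifetime,
    igr,
    lrs,
)
from .pedigree import (
    BreedingTable,
    CensusSeries,
    FounderRoster,
    Pedigree,
    identify_founders,
    read_breeding,
    read_census,
    read_pedigree,
)
from .simulate import SimConfig, SimOutput, simulate_population
from .stats import (
    fisher_exact_2x2,
    logistic_fit,
    pearson_ci,
    rank_sum,
    zscore,
)

LRS_STAGES = ("eggs", "hatchlings", "fledglings", "recruits", "broods")


@dataclass
class AnalysisConfig:
    """Configuration for one full analysis run.

    Either ``sim`` (a synthetic population is generated) or the three input
    paths must be provided.  Analysis conventions (de-lifing offspring weight,
    survival definition) surface here and are echoed into run metadata.
    """

    sim: Optional[SimConfig] = None
    pedigree_path: Optional[str] = None
    breeding_path: Optional[str] = None
    census_path: Optional[str] = None
    cohort_window: Optional[tuple[int, int]] = None
    n_reps: int = 10_000
    seed: int = 1
    delifing_weight: float = 1.0
    survival_definition: str = "genealogical"  # or "allele"
    final_year: Optional[int] = None

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items()}
        if self.sim is not None:
            d["sim"] = self.sim.__dict__
        return d


@dataclass
class AnalysisReport:
    founders: pd.DataFrame
    correlations: pd.DataFrame
    age_class_correlations: pd.DataFrame
    regressions: pd.DataFrame
    stabilisation: pd.DataFrame
    summary: pd.DataFrame
    origin_tests: dict
    meta: dict
    gene_drop: GeneDropResult = field(repr=False, default=None)
    truth: Optional[dict] = None


def _config_hash(cfg: AnalysisConfig) -> str:
    text = json.dumps(cfg.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def build_fitness_table(
    ped: Pedigree,
    breeding: BreedingTable,
    census: CensusSeries,
    roster: FounderRoster,
    gd: GeneDropResult,
    final_year: int,
    delifing_weight: float = 1.0,
    survival_definition: str = "genealogical",
) -> pd.DataFrame:
    """One row per cohort root: proxies, reproductive value and outcomes.

    Roots without a computable breeding lifespan (died as juveniles) are
    flagged incomplete and excluded from downstream correlations and
    regressions, mirroring the removal of founders with incomplete
    life-history data.
    """
    rows = []
    for entry in roster.entries:
        ind = ped[entry.id]
        complete = ind.death_year - ind.birth_year >= 1
        row: dict = {
            "id": entry.id,
            "origin": entry.origin,
            "status": entry.status,
            "sex": ind.sex,
            "birth_year": ind.birth_year,
            "death_year": ind.death_year,
            "complete_life_history": complete,
        }
        for stage in LRS_STAGES:
            row[f"lrs_{stage}"] = lrs(breeding, entry.id, stage)
        if complete:
            for stage in OFFSPRING_STAGES:
                row[f"igr_{stage}"] = igr(
                    build_transition_matrix(breeding, ped, entry.id, stage)
                )
            row["delifed_lifetime"] = delifed_lifetime(
                breeding, census, ped, entry.id, delifing_weight
            )
            by_age = annual_delifed_by_age(
                breeding, census, ped, entry.id, delifing_weight
            )
            for age, p in by_age.items():
                row[f"delifed_age{age}"] = p
        row["rv_final"] = gd.reproductive_value(entry.id, final_year)
        row["allele_survival_prob"] = gd.allele_survival_probability(entry.id)
        row["lineage_longevity"] = lineage_longevity(ped, entry.id, final_year)
        if survival_definition == "genealogical":
            row["survived"] = int(lineage_survives(ped, entry.id, final_year))
        else:
            row["survived"] = int(row["allele_survival_prob"] > 0)
        rows.append(row)
    df = pd.DataFrame(rows)
    # stable column order: delifed_age columns sorted by age
    age_cols = sorted(
        (c for c in df.columns if c.startswith("delifed_age")),
        key=lambda c: int(c.removeprefix("delifed_age")),
    )
    fixed = [c for c in df.columns if not c.startswith("delifed_age")]
    return df[fixed + age_cols]


def _safe_pearson(x, y) -> dict:
    try:
        est = pearson_ci(np.asarray(x, float), np.asarray(y, float))
        return {"r": est.r, "n": est.n, "ci_low": est.ci_low,
                "ci_high": est.ci_high, "p": est.p,
                "significant": not (est.ci_low <= 0 <= est.ci_high)}
    except ValueError:
        return {"r": np.nan, "n": len(x), "ci_low": np.nan, "ci_high": np.nan,
                "p": np.nan, "significant": False}


def proxy_metrics(df: pd.DataFrame) -> list[tuple[str, str, str]]:
    """(column, metric, stage) triples for the proxies under comparison."""
    out = [(f"lrs_{s}", "lrs", s) for s in LRS_STAGES]
    out += [(f"igr_{s}", "igr", s) for s in OFFSPRING_STAGES]
    out.append(("delifed_lifetime", "delifed", "recruits"))
    return [t for t in out if t[0] in df.columns]


def correlation_table(ft: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of each proxy with final-year reproductive value,
    among surviving lineages with complete data."""
    sub = ft[(ft["survived"] == 1) & ft["complete_life_history"]]
    rows = []
    for col, metric, stage in proxy_metrics(ft):
        rec = _safe_pearson(sub[col], sub["rv_final"])
        rows.append({"metric": metric, "stage": stage, **rec})
    return pd.DataFrame(rows)


def age_class_correlation_table(ft: pd.DataFrame) -> pd.DataFrame:
    sub = ft[(ft["survived"] == 1) & ft["complete_life_history"]]
    rows = []
    for col in (c for c in ft.columns if c.startswith("delifed_age")):
        age = int(col.removeprefix("delifed_age"))
        have = sub[sub[col].notna()]
        rec = _safe_pearson(have[col], have["rv_final"])
        rows.append({"age": age, **rec})
    return pd.DataFrame(rows).sort_values("age").reset_index(drop=True)


def regression_table(ft: pd.DataFrame) -> pd.DataFrame:
    """Logistic regression of lineage survival on each z-scored proxy."""
    sub = ft[ft["complete_life_history"]]
    rows = []
    for col, metric, stage in proxy_metrics(ft):
        x = sub[col].to_numpy(float)
        y = sub["survived"].to_numpy(float)
        try:
            fit = logistic_fit(y, zscore(x))
            rows.append({
                "variable": col, "metric": metric, "stage": stage,
                "slope": fit.slope, "ci_low": fit.ci_low,
                "ci_high": fit.ci_high, "p": fit.p,
                "separation": fit.separation,
            })
        except ValueError:
            rows.append({"variable": col, "metric": metric, "stage": stage,
                         "slope": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                         "p": np.nan, "separation": False})
    return pd.DataFrame(rows)


def summarize_metrics(ft: pd.DataFrame) -> pd.DataFrame:
    """Mean and sample SD per proxy column (Table-1 shape)."""
    if ft.empty:
        raise ValueError("empty fitness table")
    sub = ft[ft["complete_life_history"]]
    cols = [c for c, _, _ in proxy_metrics(ft)]
    cols += [c for c in ft.columns if c.startswith("delifed_age")]
    rows = []
    for col in cols:
        vals = sub[col].dropna()
        rows.append({
            "variable": col,
            "mean": float(vals.mean()) if len(vals) else np.nan,
            "sd": float(vals.std(ddof=1)) if len(vals) > 1 else np.nan,
            "n": int(len(vals)),
        })
    return pd.DataFrame(rows)


def origin_comparison(ft: pd.DataFrame) -> dict:
    """Origin x lineage-survival Fisher test and rank-sum of reproductive
    values between origins (introduced vs native)."""
    out: dict = {}
    groups = ft.groupby("origin")
    if set(groups.groups) >= {"introduced", "native"}:
        intro = ft[ft["origin"] == "introduced"]
        native = ft[ft["origin"] == "native"]
        table = [
            [int(intro["survived"].sum()), int((1 - intro["survived"]).sum())],
            [int(native["survived"].sum()), int((1 - native["survived"]).sum())],
        ]
        try:
            out["fisher_origin_survival_p"] = fisher_exact_2x2(table)
        except ValueError:
            out["fisher_origin_survival_p"] = float("nan")
        out["origin_survival_table"] = table
        try:
            w, p = rank_sum(intro["rv_final"], native["rv_final"])
            out["ranksum_rv_W"] = w
            out["ranksum_rv_p"] = p
        except ValueError:
            pass
        out["mean_rv_introduced"] = float(intro["rv_final"].mean())
        out["mean_rv_native"] = float(native["rv_final"].mean())
    return out


def run_full_analysis(cfg: AnalysisConfig) -> AnalysisReport:
    """Execute simulate/ingest -> gene drop -> proxies -> comparisons."""
    truth = None
    if cfg.sim is not None:
        sim_out: SimOutput = simulate_population(cfg.sim)
        ped, breeding, census = sim_out.pedigree, sim_out.breeding, sim_out.census
        truth = sim_out.truth
        cohort_window = cfg.cohort_window or cfg.sim.cohort_window
    else:
        if not (cfg.pedigree_path and cfg.breeding_path and cfg.census_path):
            raise ValueError("provide either a sim config or all three input paths")
        census = read_census(cfg.census_path)
        ped = read_pedigree(cfg.pedigree_path, last_census_year=census.final_year)
        breeding = read_breeding(cfg.breeding_path)
        if cfg.cohort_window is None:
            raise ValueError("cohort_window required for file inputs")
        cohort_window = cfg.cohort_window

    final_year = cfg.final_year or census.final_year
    roster = identify_founders(ped, cohort_window)
    gd = run_gene_drop(ped, roster, n_reps=cfg.n_reps, seed=cfg.seed,
                       final_year=final_year)
    ft = build_fitness_table(ped, breeding, census, roster, gd, final_year,
                             cfg.delifing_weight, cfg.survival_definition)
    n_excluded = int((~ft["complete_life_history"]).sum())
    report = AnalysisReport(
        founders=ft,
        correlations=correlation_table(ft),
        age_class_correlations=age_class_correlation_table(ft),
        regressions=regression_table(ft),
        stabilisation=stabilisation_curve(gd, final_year),
        summary=summarize_metrics(ft),
        origin_tests=origin_comparison(ft),
        meta={
            "seed": cfg.seed,
            "n_reps": cfg.n_reps,
            "final_year": int(final_year),
            "cohort_window": list(cohort_window),
            "n_roots": len(roster),
            "n_excluded_incomplete": n_excluded,
            "delifing_weight": cfg.delifing_weight,
            "survival_definition": cfg.survival_definition,
            "logistic_model": "ML logistic regression with Wald 95% CIs",
            "config_hash": _config_hash(cfg),
            "version": __version__,
        },
        gene_drop=gd,
        truth=truth,
    )
    return report


def write_report(report: AnalysisReport, directory: str | Path) -> dict[str, Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    tables = {
        "founders.csv": report.founders,
        "correlations.csv": report.correlations,
        "age_class_correlations.csv": report.age_class_correlations,
        "regressions.csv": report.regressions,
        "stabilisation.csv": report.stabilisation,
        "summary.csv": report.summary,
    }
    for name, df in tables.items():
        path = directory / name
        df.to_csv(path, index=False, float_format="%.10g")
        paths[name] = path
    meta = dict(report.meta)
    meta["origin_tests"] = report.origin_tests
    (directory / "run_meta.json").write_text(json.dumps(meta, indent=2))
    paths["run_meta.json"] = directory / "run_meta.json"
    if report.truth is not None:
        (directory / "truth.json").write_text(json.dumps(report.truth, indent=2))
        paths["truth.json"] = directory / "truth.json"
    return paths
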