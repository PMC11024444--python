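"""End-to-end orchestration: simulate/load -> censor -> metrics -> stats ->
clustering -> summaries, under one YAML-or-dict configuration.

Every stage writes plain CSV/JSON so any stage can be re-run standalone;
numeric outputs are formatted deterministically, so a repeated run with the
same configuration and seed is byte-identical.  Plots are regenerable
artifacts (never inputs) and are only produced when requested.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from .clustering import ClusterResult, KSelection, PurityTable, kmeans_profiles, \
    purity_table, select_k
from .cohort import CohortDataset
from .errors import ConfigurationError, DomainError
from .grid import PHENOTYPES, POST_BASELINE_ACUTE, TEMP_GRID, TIMEPOINTS
from .metrics import METRIC_NAMES
from .stats import delta_metrics, kruskal_wallis_panel, mean_difference_profile, \
    profile_band, results_to_frame
from .synthetic import NoiseModel, default_group_sizes, simulate_cohort

__all__ = ["CensoringRule", "apply_censoring", "summarize_cohort",
           "run_pipeline", "PipelineResult", "FLOAT_FORMAT"]

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.10g"


# ---------------------------------------------------------------------------
# Censoring

@dataclass(frozen=True)
class CensoringRule:
    """Exclude post-baseline acute samples of flagged patients.

    Emulates the per-protocol rule that censors a cCAD patient's T2–T48
    samples after a procedure-related troponin rise above the upper reference
    limit; baseline and follow-up samples are always retained.
    """

    column: str = "troponin_above_url"
    phenotype: str = "cCAD"
    timepoints: tuple[str, ...] = POST_BASELINE_ACUTE


def apply_censoring(dataset: CohortDataset, rule: CensoringRule | None = None,
                    ) -> CohortDataset:
    """Mark samples excluded by the censoring rule; log each exclusion."""
    rule = rule or CensoringRule()
    m = dataset.manifest
    if rule.column not in m.columns:
        raise ConfigurationError(
            f"censoring rule reads manifest column {rule.column!r}, which does not exist"
        )
    hit = (m[rule.column].astype(bool)
           & (m["phenotype"] == rule.phenotype)
           & m["timepoint"].isin(rule.timepoints))
    for sid in m.loc[hit, "sample_id"]:
        logger.info("censoring sample %s (%s flagged)", sid, rule.column)
    manifest = m.assign(censored=m["censored"] | hit)
    return CohortDataset(manifest=manifest, thermograms=dataset.thermograms,
                         panels=dataset.panels)


# ---------------------------------------------------------------------------
# Cohort summaries

def _pct(count: float, denom: float) -> float:
    return float(np.floor(count / denom * 1000.0 + 0.5) / 10.0)


def summarize_categorical(manifest: pd.DataFrame, column: str,
                          by: str = "phenotype") -> pd.DataFrame:
    """Frequency and within-group percentage of each level of a categorical.

    Percentages use non-missing group counts as denominators; missing values
    are counted in a separate ``missing`` row.  Cells carry count, percentage
    and a ``"n (pct)"`` formatted string under a two-level column index.
    """
    if column not in manifest.columns:
        raise ConfigurationError(f"unknown manifest column {column!r}")
    groups = [g for g in PHENOTYPES if g in set(manifest[by])] \
        + sorted(set(manifest[by]) - set(PHENOTYPES))
    levels = sorted(manifest[column].dropna().unique(), key=str)
    out: dict[tuple[str, str], list] = {}
    for g in groups:
        sub = manifest.loc[manifest[by] == g, column]
        denom = int(sub.notna().sum())
        counts, pcts, fmts = [], [], []
        for lev in levels:
            n = int((sub == lev).sum())
            if denom == 0:
                pct, fmt = float("nan"), f"{n} (--)"
            else:
                pct = _pct(n, denom)
                fmt = f"{n} ({pct:.1f})"
            counts.append(n)
            pcts.append(pct)
            fmts.append(fmt)
        n_missing = int(sub.isna().sum())
        out[(g, "count")] = counts + [n_missing]
        out[(g, "pct")] = pcts + [float("nan")]
        out[(g, "formatted")] = fmts + [str(n_missing)]
    idx = pd.Index([str(l) for l in levels] + ["missing"], name=column)
    return pd.DataFrame(out, index=idx)


def summarize_continuous(manifest: pd.DataFrame, column: str,
                         by: str = "phenotype", skewed: bool = False) -> pd.DataFrame:
    """Mean +- SD per group, or median (Q1, Q3) when ``skewed`` is set."""
    if column not in manifest.columns:
        raise ConfigurationError(f"unknown manifest column {column!r}")
    rows = {}
    for g, sub in manifest.groupby(by, sort=False):
        v = sub[column].dropna()
        if skewed:
            rows[g] = {"median": v.median(), "q1": v.quantile(0.25),
                       "q3": v.quantile(0.75), "n": len(v),
                       "formatted": f"{v.median():.2f} ({v.quantile(0.25):.2f}, "
                                    f"{v.quantile(0.75):.2f})"}
        else:
            rows[g] = {"mean": v.mean(), "sd": v.std(ddof=1), "n": len(v),
                       "formatted": f"{v.mean():.2f} ± {v.std(ddof=1):.2f}"}
    return pd.DataFrame(rows).T


def summarize_cohort(manifest: pd.DataFrame,
                     categorical: Sequence[str] = (),
                     continuous: Sequence[str] = (),
                     skewed: Sequence[str] = (),
                     by: str = "phenotype") -> dict[str, pd.DataFrame]:
    """Per-phenotype cohort summary tables plus group-size counts.

    Returns a dict with one table per requested variable and a ``"groups"``
    table of patient counts per phenotype (with the cohort total).
    """
    patients = manifest.drop_duplicates("patient_id") if "patient_id" in manifest \
        else manifest
    sizes = patients[by].value_counts()
    order = [g for g in PHENOTYPES if g in sizes.index] \
        + [g for g in sizes.index if g not in PHENOTYPES]
    groups = sizes.loc[order].to_frame("n")
    groups.loc["total"] = int(sizes.sum())
    out: dict[str, pd.DataFrame] = {"groups": groups}
    for col in categorical:
        out[col] = summarize_categorical(manifest, col, by=by)
    for col in continuous:
        out[col] = summarize_continuous(manifest, col, by=by, skewed=col in skewed)
    return out


# ---------------------------------------------------------------------------
# Full pipeline

@dataclass
class PipelineResult:
    """In-memory artifacts of one pipeline run plus where they were written."""

    dataset: CohortDataset
    stats_tables: dict[str, pd.DataFrame]
    cluster_result: ClusterResult
    purity: PurityTable
    k_selection: KSelection | None
    summaries: dict[str, pd.DataFrame]
    output_dir: Path | None


def default_config() -> dict[str, Any]:
    return {
        "mode": "simulate",
        "seed": 0,
        "output_dir": None,
        "simulate": {
            "n_per_group": default_group_sizes(),
            "timepoints": list(TIMEPOINTS),
            "frac_tmi_80c": 7.0 / 60.0,
            "n_ccad_type4mi": 1,
            "noise": {},
        },
        "censoring": {"column": "troponin_above_url"},
        "stats": {"adjust": "holm", "families": ["T0", "Tfu", "delta"]},
        "clustering": {"k": 3, "restarts": 50, "timepoint": "T0", "k_scan": None},
        "plots": False,
    }


def _merge(base: dict, override: Mapping) -> dict:
    out = dict(base)
    for key, val in override.items():
        if isinstance(val, Mapping) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = val
    return out


def _write_csv(frame: pd.DataFrame, path: Path, index: bool = True) -> None:
    frame.to_csv(path, float_format=FLOAT_FORMAT, index=index, lineterminator="\n")


def _config_hash(config: dict) -> str:
    # output_dir is run bookkeeping, not an analysis parameter
    payload = {k: v for k, v in config.items() if k != "output_dir"}
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_pipeline(config: Mapping[str, Any] | str | Path | None = None,
                 dataset: CohortDataset | None = None) -> PipelineResult:
    """Execute the whole analysis under one configuration.

    ``config`` may be a dict, a YAML file path, or None for the defaults.  In
    ``simulate`` mode the synthetic cohort is generated under the configured
    seed; alternatively pass an already-built ``dataset``.  Writes all stage
    outputs (manifest, panels, three stats families, clustering, summaries,
    run log) under ``output_dir`` when configured.
    """
    if isinstance(config, (str, Path)):
        config = yaml.safe_load(Path(config).read_text())
    config = _merge(default_config(), config or {})
    seed = config["seed"]

    if dataset is None:
        if config["mode"] != "simulate":
            raise ConfigurationError(
                f"mode {config['mode']!r} requires an explicit dataset"
            )
        sim = config["simulate"]
        dataset = simulate_cohort(
            n_per_group=sim["n_per_group"],
            timepoints=tuple(sim["timepoints"]),
            noise=NoiseModel(**sim.get("noise", {})),
            seed=seed,
            frac_tmi_80c=sim["frac_tmi_80c"],
            n_ccad_type4mi=sim.get("n_ccad_type4mi", 1),
        )
        logger.info("simulated cohort: %d samples", len(dataset))

    cens = config.get("censoring")
    if cens and cens.get("column") in dataset.manifest.columns:
        dataset = apply_censoring(dataset, CensoringRule(column=cens["column"]))

    dataset.compute_panels()
    active = dataset.active_manifest()
    panels = dataset.panels

    # Statistics families: group comparisons at T0 and Tfu, and the
    # within-patient follow-up-minus-baseline change.
    adjust = config["stats"]["adjust"]
    stats_tables: dict[str, pd.DataFrame] = {}
    fam_present = set(active["timepoint"])
    for family in config["stats"]["families"]:
        if family == "delta":
            if not {"T0", "Tfu"} <= fam_present:
                continue
            t0 = active.loc[active["timepoint"] == "T0"]
            tfu = active.loc[active["timepoint"] == "Tfu"]
            delta = delta_metrics(panels.loc[t0["sample_id"]],
                                  panels.loc[tfu["sample_id"]],
                                  t0["patient_id"], tfu["patient_id"])
            pheno = t0.set_index("patient_id")["phenotype"].loc[delta.index]
            res = kruskal_wallis_panel(delta, pheno, adjust=adjust)
        else:
            if family not in fam_present:
                continue
            fam = active.loc[active["timepoint"] == family]
            res = kruskal_wallis_panel(panels.loc[fam["sample_id"]],
                                       fam["phenotype"], adjust=adjust)
        stats_tables[family] = results_to_frame(res)

    # Clustering at the configured timepoint (baseline by default).
    clu = config["clustering"]
    ctp = clu.get("timepoint", "T0")
    cm = active.loc[active["timepoint"] == ctp]
    curves = dataset.curves(cm["sample_id"])
    result = kmeans_profiles(curves, clu["k"], seed=seed,
                             restarts=clu["restarts"],
                             sample_ids=list(cm["sample_id"]))
    purity = purity_table(result, dict(zip(cm["sample_id"], cm["phenotype"])))
    ksel = None
    if clu.get("k_scan"):
        lo, hi = clu["k_scan"]
        ksel = select_k(curves, range(lo, hi + 1), seed=seed,
                        restarts=min(clu["restarts"], 10),
                        sample_ids=list(cm["sample_id"]))

    summaries = summarize_cohort(dataset.manifest,
                                 categorical=config.get("summaries", {})
                                 .get("categorical", []),
                                 continuous=config.get("summaries", {})
                                 .get("continuous", []))

    outdir = config.get("output_dir")
    output_dir = None
    if outdir:
        output_dir = Path(outdir)
        _write_outputs(output_dir, config, dataset, stats_tables, result,
                       purity, ksel, summaries)
    return PipelineResult(dataset=dataset, stats_tables=stats_tables,
                          cluster_result=result, purity=purity,
                          k_selection=ksel, summaries=summaries,
                          output_dir=output_dir)


def _write_outputs(outdir: Path, config: dict, dataset: CohortDataset,
                   stats_tables: dict[str, pd.DataFrame], result: ClusterResult,
                   purity: PurityTable, ksel: KSelection | None,
                   summaries: dict[str, pd.DataFrame]) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    _write_csv(dataset.manifest, outdir / "manifest.csv", index=False)
    _write_csv(dataset.panels, outdir / "panels.csv")

    for family, table in stats_tables.items():
        _write_csv(table, outdir / f"stats_{family.lower()}.csv")

    cdir = outdir / "clusters"
    cdir.mkdir(exist_ok=True)
    _write_csv(result.assignments_frame(), cdir / "assignments.csv", index=False)
    centers = pd.DataFrame(result.centers.T,
                           columns=[f"cluster{i}" for i in range(1, result.k + 1)],
                           index=pd.Index(TEMP_GRID, name="temperature"))
    _write_csv(centers, cdir / "centers.csv")
    _write_csv(purity.counts, cdir / "purity_counts.csv")
    _write_csv(purity.percentages, cdir / "purity_percentages.csv")
    if ksel is not None:
        _write_csv(ksel.table, cdir / "k_selection.csv", index=False)

    sdir = outdir / "summary_tables"
    sdir.mkdir(exist_ok=True)
    for name, table in summaries.items():
        _write_csv(table, sdir / f"{name}.csv")

    # Profile bands per phenotype x timepoint (long format) and the
    # follow-up-minus-baseline mean difference profiles.
    active = dataset.active_manifest()
    band_rows = []
    for (ph, tp), grp in active.groupby(["phenotype", "timepoint"], sort=True):
        band = profile_band(dataset.curves(grp["sample_id"]))
        band_rows.append(band.to_frame().assign(phenotype=ph, timepoint=tp))
    _write_csv(pd.concat(band_rows, ignore_index=True),
               outdir / "profile_bands.csv", index=False)
    if {"T0", "Tfu"} <= set(active["timepoint"]):
        _write_csv(mean_difference_profile(dataset),
                   outdir / "difference_profiles.csv")

    log = {
        "tlbkit_version": _version,
        "seed": config["seed"],
        "config_hash": _config_hash(config),
        "n_samples": int(len(dataset.manifest)),
        "n_censored": int(dataset.manifest["censored"].sum()),
        "stats_families": {k: int(len(v)) for k, v in stats_tables.items()},
        "cluster_k": result.k,
    }
    (outdir / "run_log.json").write_text(json.dumps(log, indent=1, sort_keys=True) + "\n")

    if config.get("plots"):
        _write_plots(outdir, dataset, result)


def _write_plots(outdir: Path, dataset: CohortDataset, result: ClusterResult) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fdir = outdir / "figures"
    fdir.mkdir(exist_ok=True)
    active = dataset.active_manifest()
    tps = [t for t in TIMEPOINTS if t in set(active["timepoint"])]
    phenos = [p for p in PHENOTYPES if p in set(active["phenotype"])]

    fig, axes = plt.subplots(len(phenos), len(tps),
                             figsize=(2.4 * len(tps), 2.2 * len(phenos)),
                             sharex=True, sharey=True, squeeze=False)
    for i, ph in enumerate(phenos):
        for j, tp in enumerate(tps):
            grp = active.loc[(active["phenotype"] == ph) & (active["timepoint"] == tp)]
            ax = axes[i][j]
            if len(grp):
                band = profile_band(dataset.curves(grp["sample_id"]))
                ax.fill_between(TEMP_GRID, band.lower_curve, band.upper_curve,
                                color="goldenrod", alpha=0.4)
                ax.plot(TEMP_GRID, band.center_curve, color="black", lw=1)
            if i == 0:
                ax.set_title(tp, fontsize=9)
            if j == 0:
                ax.set_ylabel(ph, fontsize=9)
    fig.supxlabel("temperature (degC)")
    fig.supylabel("Cp_ex (cal/(degC.g))")
    fig.tight_layout()
    fig.savefig(fdir / "median_bands.png", dpi=120)
    plt.close(fig)

    fig, axes = plt.subplots(1, result.k, figsize=(3.0 * result.k, 2.6),
                             sharey=True, squeeze=False)
    for c in range(1, result.k + 1):
        ax = axes[0][c - 1]
        for sid, lab in zip(result.sample_ids, result.assignments):
            if lab == c:
                ax.plot(TEMP_GRID, dataset.thermograms[sid].cp_excess,
                        lw=0.4, alpha=0.5)
        ax.plot(TEMP_GRID, result.centers[c - 1], color="black", lw=1.5)
        ax.set_title(f"cluster {c}", fontsize=9)
    fig.tight_layout()
    fig.savefig(fdir / "cluster_facets.png", dpi=120)
    plt.close(fig)
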