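"""Non-parametric group statistics and profile-level summaries.

Per-metric comparisons across the phenotype groups use the Kruskal–Wallis
rank test (chi-square reference, tie-corrected) with a family-wise adjustment
across the 19 metrics — Holm step-down by default, Bonferroni and
Benjamini–Hochberg selectable.  Pairwise two-group comparisons use the
Wilcoxon rank-sum (Mann–Whitney) test for independent groups, exact when
sample sizes permit and there are no ties, or the signed-rank test for
within-patient pairs.  Longitudinal change is summarized per patient as the
follow-up-minus-baseline difference of every metric, and whole-profile
variation as pointwise median / 95% quantile-interval bands and per-phenotype
mean difference curves.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .cohort import CohortDataset
from .errors import DomainError, PairingError
from .grid import TEMP_GRID
from .io import Thermogram
from .metrics import METRIC_NAMES

__all__ = [
    "MetricTestResult",
    "ProfileSummary",
    "kruskal_wallis_panel",
    "results_to_frame",
    "pairwise_wilcoxon",
    "delta_metrics",
    "profile_band",
    "mean_difference_profile",
]

logger = logging.getLogger(__name__)

_ADJUST_METHODS = {"holm": "holm", "bonferroni": "bonferroni", "bh": "fdr_bh",
                   "fdr_bh": "fdr_bh"}


@dataclass(frozen=True)
class MetricTestResult:
    """Kruskal–Wallis outcome for one metric within one contrast family."""

    metric_name: str
    statistic: float
    p_unadjusted: float
    p_adjusted: float
    group_summaries: pd.DataFrame  # index group, columns median/q1/q3/n


@dataclass(frozen=True)
class ProfileSummary:
    """Pointwise center curve and 95% quantile-interval band."""

    center_curve: np.ndarray
    lower_curve: np.ndarray
    upper_curve: np.ndarray
    n: int

    @property
    def temperature(self) -> np.ndarray:
        return TEMP_GRID

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "temperature": TEMP_GRID, "center": self.center_curve,
            "lower": self.lower_curve, "upper": self.upper_curve,
        })


def _group_summaries(values: pd.Series, groups: pd.Series) -> pd.DataFrame:
    rows = {}
    for g, v in values.groupby(groups, sort=False):
        rows[g] = {"median": v.median(), "q1": v.quantile(0.25),
                   "q3": v.quantile(0.75), "n": len(v)}
    return pd.DataFrame(rows).T


def kruskal_wallis_panel(panels: pd.DataFrame, groups: Sequence[str],
                         adjust: str = "holm") -> list[MetricTestResult]:
    """One Kruskal–Wallis test per metric, family-adjusted across the panel.

    Parameters
    ----------
    panels
        Samples x 19 metric table (canonical column order).
    groups
        Group label per sample, aligned with ``panels`` rows.
    adjust
        ``"holm"`` (default), ``"bonferroni"`` or ``"bh"``.

    A metric that is constant across all samples gets p = 1 with a warning.
    Metric values that are NaN for a sample are dropped from that metric's
    test.  Every group must contribute at least two samples.
    """
    if adjust not in _ADJUST_METHODS:
        raise DomainError(f"unknown adjustment {adjust!r}; use one of {sorted(_ADJUST_METHODS)}")
    groups = pd.Series(np.asarray(groups), index=panels.index, name="group")
    counts = groups.value_counts()
    if len(counts) < 2:
        raise DomainError("need at least two groups")
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise DomainError(f"groups with fewer than 2 samples: {small}")

    stats_, pvals, summaries = [], [], []
    for metric in panels.columns:
        col = panels[metric]
        ok = col.notna()
        samples = [col[ok & (groups == g)].to_numpy() for g in counts.index]
        if np.ptp(col[ok].to_numpy()) == 0:
            warnings.warn(f"metric {metric} constant across all samples; p set to 1",
                          stacklevel=2)
            h, p = 0.0, 1.0
        else:
            h, p = sps.kruskal(*samples)
        stats_.append(float(h))
        pvals.append(float(p))
        summaries.append(_group_summaries(col[ok], groups[ok]))
    adjusted = multipletests(pvals, method=_ADJUST_METHODS[adjust])[1]
    return [MetricTestResult(m, h, p, float(pa), s)
            for m, h, p, pa, s in zip(panels.columns, stats_, pvals, adjusted, summaries)]


def results_to_frame(results: Iterable[MetricTestResult]) -> pd.DataFrame:
    """Tabulate test results: one row per metric, unadjusted/adjusted p columns."""
    frame = pd.DataFrame(
        [(r.metric_name, r.statistic, r.p_unadjusted, r.p_adjusted) for r in results],
        columns=["metric", "statistic", "p_unadjusted", "p_adjusted"],
    ).set_index("metric")
    return frame


def _rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p: exact for n <= 25 without ties,
    otherwise normal approximation with tie and continuity correction."""
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    if max(len(x), len(y)) <= 25 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.pvalue)


def _signed_rank_p(x: np.ndarray, y: np.ndarray) -> float:
    d = x - y
    if np.all(d == 0):
        warnings.warn("all paired differences are zero; p set to 1", stacklevel=3)
        return 1.0
    nz = d[d != 0]
    method = "exact" if (len(nz) <= 25 and len(np.unique(np.abs(nz))) == len(nz)) \
        else "approx"
    res = sps.wilcoxon(x, y, zero_method="wilcox", correction=True, method=method)
    return float(res.pvalue)


def pairwise_wilcoxon(panels: pd.DataFrame, groups: Sequence[str],
                      metric_name: str, paired: bool = False,
                      patient_ids: Sequence[str] | None = None,
                      ) -> dict[tuple[str, str], float]:
    """Two-sided pairwise Wilcoxon p-values for one metric, all group pairs.

    Independent groups use the rank-sum form; with ``paired=True`` samples are
    matched by ``patient_ids`` and compared with the signed-rank form (every
    patient must appear in both groups of a pair).
    """
    if metric_name not in panels.columns:
        raise DomainError(f"unknown metric {metric_name!r}")
    groups = pd.Series(np.asarray(groups), index=panels.index)
    if paired and patient_ids is None:
        raise PairingError("paired comparison requires patient_ids")
    col = panels[metric_name]
    labels = list(dict.fromkeys(groups))
    out: dict[tuple[str, str], float] = {}
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            xa, xb = col[groups == a], col[groups == b]
            if paired:
                pa = pd.Series(np.asarray(patient_ids), index=panels.index)
                xa = xa.set_axis(pa[groups == a])
                xb = xb.set_axis(pa[groups == b])
                if set(xa.index) != set(xb.index) or xa.index.duplicated().any():
                    raise PairingError(
                        f"groups {a!r} and {b!r} are not matched one-to-one by patient id"
                    )
                xb = xb.loc[xa.index]
                out[(a, b)] = _signed_rank_p(xa.to_numpy(), xb.to_numpy())
            else:
                out[(a, b)] = _rank_sum_p(xa.to_numpy(), xb.to_numpy())
    return out


def delta_metrics(panels_t0: pd.DataFrame, panels_tfu: pd.DataFrame,
                  patient_ids_t0: Sequence[str] | None = None,
                  patient_ids_tfu: Sequence[str] | None = None) -> pd.DataFrame:
    """Within-patient metric change, follow-up minus baseline.

    Inputs are metric tables for the two timepoints; if ``patient_ids_*`` are
    given the tables are re-indexed by patient, otherwise their indexes are
    assumed to already be patient ids.  Patients present at only one timepoint
    are dropped (logged).  Returns a patients x 19 table of differences.
    """
    t0 = panels_t0 if patient_ids_t0 is None else panels_t0.set_axis(list(patient_ids_t0))
    tfu = panels_tfu if patient_ids_tfu is None else panels_tfu.set_axis(list(patient_ids_tfu))
    common = t0.index.intersection(tfu.index)
    if len(common) == 0:
        raise DomainError("no patients present at both timepoints")
    dropped = sorted(set(t0.index).symmetric_difference(tfu.index))
    if dropped:
        logger.info("delta_metrics: dropping %d unpaired patients: %s",
                    len(dropped), dropped[:10])
    delta = tfu.loc[common] - t0.loc[common]
    delta.index.name = "patient_id"
    return delta


def profile_band(thermograms: Sequence[Thermogram] | np.ndarray,
                 center: str = "median") -> ProfileSummary:
    """Pointwise median (or mean) curve with the 2.5%/97.5% quantile band."""
    if isinstance(thermograms, np.ndarray):
        mat = np.atleast_2d(thermograms)
    else:
        thermograms = list(thermograms)
        if not thermograms:
            raise DomainError("profile_band needs at least one thermogram")
        mat = np.stack([t.cp_excess for t in thermograms])
    if mat.size == 0:
        raise DomainError("profile_band needs at least one thermogram")
    if center == "median":
        c = np.median(mat, axis=0)
    elif center == "mean":
        c = mat.mean(axis=0)
    else:
        raise DomainError(f"unknown center {center!r}")
    lower = np.quantile(mat, 0.025, axis=0)
    upper = np.quantile(mat, 0.975, axis=0)
    return ProfileSummary(c, lower, upper, mat.shape[0])


def mean_difference_profile(dataset: CohortDataset, t_from: str = "T0",
                            t_to: str = "Tfu") -> pd.DataFrame:
    """Per-phenotype pointwise mean of the (t_to - t_from) difference curves.

    Only patients with an uncensored sample at both timepoints contribute; a
    phenotype with no such pairs is omitted with a warning.  Returns a
    451 x phenotypes DataFrame indexed by temperature.
    """
    m = dataset.active_manifest()
    cols: dict[str, np.ndarray] = {}
    for phenotype, grp in m.groupby("phenotype", sort=False):
        a = grp.loc[grp["timepoint"] == t_from].set_index("patient_id")["sample_id"]
        b = grp.loc[grp["timepoint"] == t_to].set_index("patient_id")["sample_id"]
        patients = a.index.intersection(b.index)
        if len(patients) == 0:
            warnings.warn(f"no {t_from}/{t_to} pairs for phenotype {phenotype}; omitted",
                          stacklevel=2)
            continue
        diffs = (dataset.curves(b.loc[patients]) - dataset.curves(a.loc[patients]))
        cols[phenotype] = diffs.mean(axis=0)
    out = pd.DataFrame(cols, index=pd.Index(TEMP_GRID, name="temperature"))
    return out
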