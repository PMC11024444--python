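"""Unsupervised k-means clustering of whole TLB profiles.

Baseline profiles are clustered as raw 451-dimensional curve vectors with
Euclidean distance and no per-feature standardization: the grid points share
one physical unit, and standardizing would distort peak-amplitude
information.  Cluster count is assessed by within-cluster sum of squares
(elbow) and mean silhouette; purity is reported as a phenotype x cluster
contingency table with column percentages, clusters relabeled in decreasing
size order for stable reporting.

Lloyd's algorithm with k-means++ initialization and best-of-restarts is
provided by scikit-learn (which also relocates any cluster that empties
during iteration).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .errors import DomainError
from .grid import PHENOTYPES
from .io import Thermogram

__all__ = ["ClusterResult", "PurityTable", "KSelection",
           "kmeans_profiles", "select_k", "purity_table"]

DEFAULT_RESTARTS = 50


@dataclass(frozen=True)
class ClusterResult:
    """k-means output on curve vectors; labels are 1..k, 1 the largest cluster."""

    k: int
    sample_ids: tuple[str, ...]
    assignments: np.ndarray          # int labels in 1..k
    centers: np.ndarray              # (k, 451) curves, row i is cluster i+1
    wss: float                       # total within-cluster sum of squares
    silhouette_mean: float
    seed: int
    restarts: int

    def assignments_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sample_id": self.sample_ids,
                             "cluster": self.assignments})


@dataclass(frozen=True)
class KSelection:
    """WSS and silhouette per candidate k, plus the silhouette-maximizing k."""

    table: pd.DataFrame              # columns k, wss, silhouette
    best_k: int


@dataclass(frozen=True)
class PurityTable:
    """Phenotype x cluster contingency: counts, column percentages, totals."""

    counts: pd.DataFrame             # rows phenotype, columns cluster label
    percentages: pd.DataFrame        # 100 * count / cluster total, 1 decimal
    totals: pd.Series                # samples per cluster

    def formatted(self) -> pd.DataFrame:
        """Cells as ``"n (pct%)"``, mirroring the published table layout."""
        return pd.DataFrame(
            {c: [f"{int(self.counts.loc[r, c])} ({self.percentages.loc[r, c]:.1f}%)"
                 for r in self.counts.index] for c in self.counts.columns},
            index=self.counts.index,
        )


def _as_matrix(thermograms: Sequence[Thermogram] | np.ndarray,
               sample_ids: Sequence[str] | None) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(thermograms, np.ndarray):
        mat = np.atleast_2d(np.asarray(thermograms, dtype=float))
        ids = tuple(sample_ids) if sample_ids is not None \
            else tuple(f"S{i}" for i in range(mat.shape[0]))
    else:
        thermograms = list(thermograms)
        mat = np.stack([t.cp_excess for t in thermograms])
        ids = tuple(t.sample_id for t in thermograms)
    if len(ids) != mat.shape[0]:
        raise DomainError("sample_ids length does not match curve count")
    return mat, ids


def kmeans_profiles(thermograms: Sequence[Thermogram] | np.ndarray, k: int,
                    seed: int = 0, restarts: int = DEFAULT_RESTARTS,
                    sample_ids: Sequence[str] | None = None) -> ClusterResult:
    """Cluster profiles with k-means (k-means++ init, best of ``restarts``).

    Deterministic given ``seed``.  Output labels are renumbered so cluster 1
    is the largest (ties broken by the fitted label index).
    """
    mat, ids = _as_matrix(thermograms, sample_ids)
    n = mat.shape[0]
    if k < 2 or k > n:
        raise DomainError(f"need 2 <= k <= n (got k={k}, n={n})")
    km = KMeans(n_clusters=k, init="k-means++", n_init=restarts,
                random_state=seed, algorithm="lloyd").fit(mat)
    sizes = np.bincount(km.labels_, minlength=k)
    order = np.argsort(-sizes, kind="stable")        # old label -> rank
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(1, k + 1)
    assignments = relabel[km.labels_]
    centers = km.cluster_centers_[order]
    if 2 <= k < n:
        sil = float(silhouette_score(mat, km.labels_, metric="euclidean"))
    else:
        sil = float("nan")
    return ClusterResult(k=k, sample_ids=ids, assignments=assignments,
                         centers=centers, wss=float(km.inertia_),
                         silhouette_mean=sil, seed=seed, restarts=restarts)


def select_k(thermograms: Sequence[Thermogram] | np.ndarray,
             k_range: Sequence[int] = range(2, 9), seed: int = 0,
             restarts: int = DEFAULT_RESTARTS,
             sample_ids: Sequence[str] | None = None) -> KSelection:
    """Run k-means over ``k_range`` and report WSS and silhouette per k.

    ``best_k`` maximizes the mean silhouette; the full table supports elbow
    inspection of the WSS curve.
    """
    mat, ids = _as_matrix(thermograms, sample_ids)
    n = mat.shape[0]
    if n < 3:
        raise DomainError("need at least 3 samples to assess cluster count")
    ks = [k for k in k_range if 2 <= k <= n - 1]
    if not ks:
        raise DomainError(f"k_range {list(k_range)} has no usable values for n={n}")
    rows = []
    for k in ks:
        res = kmeans_profiles(mat, k, seed=seed, restarts=restarts, sample_ids=ids)
        rows.append({"k": k, "wss": res.wss, "silhouette": res.silhouette_mean})
    table = pd.DataFrame(rows)
    best_k = int(table.loc[table["silhouette"].idxmax(), "k"])
    return KSelection(table=table, best_k=best_k)


def _round_half_up(x: np.ndarray, decimals: int = 1) -> np.ndarray:
    factor = 10.0 ** decimals
    return np.floor(np.abs(x) * factor + 0.5) / factor * np.sign(x)


def purity_table(result: ClusterResult,
                 phenotypes: Mapping[str, str] | Sequence[str]) -> PurityTable:
    """Cross-tabulate cluster assignments against phenotype labels.

    ``phenotypes`` is either a sample_id -> phenotype mapping or a sequence
    aligned with the clustered samples.  Percentages are column-wise shares of
    each cluster, rounded half-away-from-zero to one decimal.
    """
    if isinstance(phenotypes, Mapping):
        try:
            labels = [phenotypes[s] for s in result.sample_ids]
        except KeyError as e:
            raise DomainError(f"missing phenotype label for sample {e.args[0]!r}") from None
    else:
        labels = list(phenotypes)
        if len(labels) != len(result.sample_ids):
            raise DomainError("phenotype labels do not match clustered samples")
    if any(pd.isna(l) for l in labels):
        raise DomainError("missing phenotype label")
    frame = pd.DataFrame({"phenotype": labels, "cluster": result.assignments})
    counts = pd.crosstab(frame["phenotype"], frame["cluster"])
    row_order = [p for p in PHENOTYPES if p in counts.index] \
        + [p for p in counts.index if p not in PHENOTYPES]
    counts = counts.loc[row_order, sorted(counts.columns)]
    totals = counts.sum(axis=0)
    pct = counts.div(totals, axis=1) * 100.0
    pct = pd.DataFrame(_round_half_up(pct.to_numpy()),
                       index=pct.index, columns=pct.columns)
    return PurityTable(counts=counts, percentages=pct, totals=totals)
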