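"""The longitudinal analysis container: thermograms + metadata + metric panels."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError
from .grid import PHENOTYPES, TIMEPOINTS
from .io import Thermogram
from .metrics import compute_panel, panels_to_frame

__all__ = ["CohortDataset"]

_MANIFEST_REQUIRED = ("sample_id", "patient_id", "phenotype", "timepoint")


@dataclass
class CohortDataset:
    """Thermograms indexed by (patient, phenotype, timepoint).

    ``manifest`` is one row per sample with at least sample_id, patient_id,
    phenotype and timepoint (plus a boolean ``censored`` column, clinical
    flags, and — for synthetic cohorts — the true subtype label).
    ``thermograms`` maps sample_id to its profile; ``panels`` caches the
    samples x 19 metric table.
    """

    manifest: pd.DataFrame
    thermograms: dict[str, Thermogram]
    panels: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        m = self.manifest
        missing = [c for c in _MANIFEST_REQUIRED if c not in m.columns]
        if missing:
            raise ValidationError(f"manifest lacks required columns {missing}")
        if m["sample_id"].duplicated().any():
            dupes = m.loc[m["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValidationError(f"duplicate sample ids in manifest: {dupes[:5]}")
        bad_ph = set(m["phenotype"]) - set(PHENOTYPES)
        if bad_ph:
            raise ValidationError(f"unknown phenotypes in manifest: {sorted(bad_ph)}")
        bad_tp = set(m["timepoint"]) - set(TIMEPOINTS)
        if bad_tp:
            raise ValidationError(f"unknown timepoints in manifest: {sorted(bad_tp)}")
        unmatched = set(m["sample_id"]) - set(self.thermograms)
        if unmatched:
            raise ValidationError(
                f"manifest rows without thermograms: {sorted(unmatched)[:5]}"
            )
        if "censored" not in m.columns:
            self.manifest = m.assign(censored=False)

    def __len__(self) -> int:
        return len(self.manifest)

    # -- selection ---------------------------------------------------------

    def active_manifest(self) -> pd.DataFrame:
        """Manifest rows not excluded by censoring."""
        return self.manifest.loc[~self.manifest["censored"]]

    def subset(self, timepoint: str | None = None,
               phenotype: str | None = None,
               include_censored: bool = False) -> pd.DataFrame:
        m = self.manifest if include_censored else self.active_manifest()
        if timepoint is not None:
            m = m.loc[m["timepoint"] == timepoint]
        if phenotype is not None:
            m = m.loc[m["phenotype"] == phenotype]
        return m

    def curves(self, sample_ids: Iterable[str]) -> np.ndarray:
        """Stack profiles into an (n_samples, 451) matrix, row order preserved."""
        return np.stack([self.thermograms[s].cp_excess for s in sample_ids])

    # -- metrics -----------------------------------------------------------

    def compute_panels(self, windows: Mapping[str, tuple[float, float]] | None = None,
                       force: bool = False) -> pd.DataFrame:
        """Compute (and cache) the 19-metric panel for every sample."""
        if self.panels is None or force:
            panels = [compute_panel(self.thermograms[s], windows)
                      for s in self.manifest["sample_id"]]
            self.panels = panels_to_frame(panels)
        return self.panels

    def panels_for(self, sample_ids: Iterable[str]) -> pd.DataFrame:
        return self.compute_panels().loc[list(sample_ids)]
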