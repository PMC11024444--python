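"""Extraction of the 19-metric panel that summarizes a TLB profile.

Plasma thermograms are characterized by three canonical transitions: a major
peak at 60–66 degC (Peak 1, dominated by albumin), a smaller peak at
67–73 degC (Peak 2, globulins) and a shoulder at 73–81 degC (Peak 3).  The
panel captures:

* the three peak amplitudes and their temperatures,
* the three pairwise amplitude ratios,
* the valley V1.2 between Peak 1 and Peak 2 (amplitude, temperature, and its
  ratio to each peak),
* four whole-profile summaries: the global maximum and its temperature, the
  first-moment temperature T_FM (amplitude-weighted mean temperature, a
  single-number thermal-stability shift), the width at half height, and the
  integrated area.

Peak windows are half-open [low, high) so the shared 73 degC edge belongs to
exactly one window; extrema ties are broken toward the lowest temperature so
the panel is deterministic on plateaus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd

from .errors import DomainError
from .grid import DEFAULT_PEAK_WINDOWS, TEMP_GRID
from .io import Thermogram

__all__ = [
    "METRIC_NAMES",
    "MetricPanel",
    "find_peak",
    "find_valley",
    "global_metrics",
    "compute_panel",
    "panels_to_frame",
]

#: Canonical metric order, used for every tabular output.
METRIC_NAMES: tuple[str, ...] = (
    "Peak1", "Peak2", "Peak3",
    "TPeak1", "TPeak2", "TPeak3",
    "P1.P2", "P1.P3", "P2.P3",
    "V12", "TV12",
    "V12.P1", "V12.P2", "V12.P3",
    "Max", "TMax", "TFM", "Width", "Area",
)


@dataclass(frozen=True)
class MetricPanel:
    """The 19 TLB metrics of one thermogram.

    Amplitudes in cal/(degC.g), temperatures in degC, ratios dimensionless,
    area in cal/g.  Ratios with a zero denominator are NaN.
    """

    sample_id: str
    peak1: float
    peak2: float
    peak3: float
    t_peak1: float
    t_peak2: float
    t_peak3: float
    r_p1p2: float
    r_p1p3: float
    r_p2p3: float
    v12: float
    t_v12: float
    r_v12p1: float
    r_v12p2: float
    r_v12p3: float
    max_amp: float
    t_max: float
    t_fm: float
    width: float
    area: float

    def to_dict(self) -> dict[str, float]:
        """Metrics keyed by their canonical labels, in canonical order."""
        vals = (self.peak1, self.peak2, self.peak3,
                self.t_peak1, self.t_peak2, self.t_peak3,
                self.r_p1p2, self.r_p1p3, self.r_p2p3,
                self.v12, self.t_v12,
                self.r_v12p1, self.r_v12p2, self.r_v12p3,
                self.max_amp, self.t_max, self.t_fm, self.width, self.area)
        return dict(zip(METRIC_NAMES, vals))

    def to_series(self) -> pd.Series:
        return pd.Series(self.to_dict(), name=self.sample_id)


class GlobalMetrics(NamedTuple):
    max_amp: float
    t_max: float
    t_fm: float
    width: float
    area: float


def find_peak(tg: Thermogram, window: tuple[float, float]) -> tuple[float, float]:
    """Maximum amplitude and its temperature within a half-open window.

    Returns the largest ``cp_excess`` over grid points with
    ``window[0] <= T < window[1]`` and the temperature at which it occurs;
    ties go to the lowest temperature.
    """
    lo, hi = window
    mask = (TEMP_GRID >= lo) & (TEMP_GRID < hi)
    if not mask.any():
        raise DomainError(f"peak window [{lo}, {hi}) contains no grid points")
    cp = tg.cp_excess[mask]
    i = int(np.argmax(cp))
    return float(cp[i]), float(TEMP_GRID[mask][i])


def find_valley(tg: Thermogram, t_left: float, t_right: float) -> tuple[float, float]:
    """Minimum amplitude and its temperature strictly between two temperatures.

    Intended for V1.2: ``t_left`` / ``t_right`` are the detected Peak 1 and
    Peak 2 temperatures.  Ties go to the lowest temperature.
    """
    if t_left >= t_right:
        raise DomainError(f"need t_left < t_right (got {t_left}, {t_right})")
    mask = (TEMP_GRID > t_left) & (TEMP_GRID < t_right)
    if not mask.any():
        raise DomainError(
            f"no grid points strictly between {t_left} and {t_right} degC"
        )
    cp = tg.cp_excess[mask]
    i = int(np.argmin(cp))
    return float(cp[i]), float(TEMP_GRID[mask][i])


def _half_height_width(cp: np.ndarray, imax: int, half: float) -> float:
    """Width between the outermost half-maximum crossings around the global max.

    The left edge is the first upward crossing of ``half`` before the maximum,
    the right edge the last downward crossing after it, each located by linear
    interpolation between the bracketing grid points.  If the profile never
    drops below half height on one side, that edge is truncated at the grid
    boundary (with a warning).
    """
    above = cp >= half
    if not above[imax]:
        # only possible for a non-positive maximum (half > max); width has no
        # meaningful definition there
        warnings.warn("profile maximum is non-positive; width undefined",
                      stacklevel=3)
        return float("nan")
    i0 = int(np.flatnonzero(above)[0])
    if i0 == 0:
        t_lo = TEMP_GRID[0]
        warnings.warn("half-height width truncated at 45 degC", stacklevel=3)
    else:
        f = (half - cp[i0 - 1]) / (cp[i0] - cp[i0 - 1])
        t_lo = TEMP_GRID[i0 - 1] + f * (TEMP_GRID[i0] - TEMP_GRID[i0 - 1])
    j0 = int(np.flatnonzero(above)[-1])
    if j0 == cp.size - 1:
        t_hi = TEMP_GRID[-1]
        warnings.warn("half-height width truncated at 90 degC", stacklevel=3)
    else:
        f = (cp[j0] - half) / (cp[j0] - cp[j0 + 1])
        t_hi = TEMP_GRID[j0] + f * (TEMP_GRID[j0 + 1] - TEMP_GRID[j0])
    return float(t_hi - t_lo)


def global_metrics(tg: Thermogram) -> GlobalMetrics:
    """Whole-profile summaries: Max, T_Max, T_FM, Width, Area.

    * ``max_amp``/``t_max``: global maximum over the full grid, ties to the
      lowest temperature.
    * ``t_fm``: first-moment temperature, sum(T_i cp_i) / sum(cp_i); NaN (with
      a warning) if the total signal is non-positive.
    * ``width``: full span above half the global maximum (outermost crossings).
    * ``area``: trapezoidal integral of cp_excess over 45–90 degC.
    """
    cp = tg.cp_excess
    imax = int(np.argmax(cp))
    max_amp = float(cp[imax])
    t_max = float(TEMP_GRID[imax])
    total = float(cp.sum())
    if total <= 0:
        warnings.warn(
            f"{tg.sample_id}: total signal <= 0; first-moment temperature undefined",
            stacklevel=2,
        )
        t_fm = float("nan")
    else:
        t_fm = float((TEMP_GRID * cp).sum() / total)
    area = float(np.trapezoid(cp, TEMP_GRID))
    width = _half_height_width(cp, imax, max_amp / 2.0)
    return GlobalMetrics(max_amp, t_max, t_fm, width, area)


def _ratio(num: float, den: float, label: str, sample_id: str) -> float:
    if den == 0.0:
        warnings.warn(f"{sample_id}: ratio {label} undefined (zero denominator)",
                      stacklevel=3)
        return float("nan")
    return num / den


def compute_panel(tg: Thermogram,
                  windows: Mapping[str, tuple[float, float]] | None = None,
                  ) -> MetricPanel:
    """Assemble the full 19-metric panel for one thermogram.

    ``windows`` may override the three peak search ranges (defaults: 60–66,
    67–73, 73–81 degC, half-open).  The valley is searched strictly between
    the detected Peak 1 and Peak 2 temperatures.
    """
    w = dict(DEFAULT_PEAK_WINDOWS)
    if windows:
        w.update(windows)
    peak1, t_peak1 = find_peak(tg, w["Peak1"])
    peak2, t_peak2 = find_peak(tg, w["Peak2"])
    peak3, t_peak3 = find_peak(tg, w["Peak3"])
    v12, t_v12 = find_valley(tg, t_peak1, t_peak2)
    g = global_metrics(tg)
    sid = tg.sample_id
    return MetricPanel(
        sample_id=sid,
        peak1=peak1, peak2=peak2, peak3=peak3,
        t_peak1=t_peak1, t_peak2=t_peak2, t_peak3=t_peak3,
        r_p1p2=_ratio(peak1, peak2, "Peak1/Peak2", sid),
        r_p1p3=_ratio(peak1, peak3, "Peak1/Peak3", sid),
        r_p2p3=_ratio(peak2, peak3, "Peak2/Peak3", sid),
        v12=v12, t_v12=t_v12,
        r_v12p1=_ratio(v12, peak1, "V1.2/Peak1", sid),
        r_v12p2=_ratio(v12, peak2, "V1.2/Peak2", sid),
        r_v12p3=_ratio(v12, peak3, "V1.2/Peak3", sid),
        max_amp=g.max_amp, t_max=g.t_max, t_fm=g.t_fm,
        width=g.width, area=g.area,
    )


def panels_to_frame(panels: list[MetricPanel] | Mapping[str, MetricPanel]) -> pd.DataFrame:
    """Stack metric panels into a samples x 19 DataFrame (canonical column order)."""
    if isinstance(panels, Mapping):
        panels = list(panels.values())
    frame = pd.DataFrame([p.to_dict() for p in panels],
                         index=[p.sample_id for p in panels])
    frame.index.name = "sample_id"
    return frame[list(METRIC_NAMES)]
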