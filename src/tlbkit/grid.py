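"""Shared constants for the standard TLB analysis frame.

All finalized thermograms live on a uniform temperature grid from 45.0 to
90.0 degC in 0.1 degC steps (451 points); the three canonical plasma
transition windows and the study's phenotype/timepoint vocabularies are
defined here so every module agrees on them.
"""

from __future__ import annotations

import numpy as np

GRID_START: float = 45.0
GRID_STOP: float = 90.0
GRID_STEP: float = 0.1
N_GRID: int = 451

#: The standard 451-point analysis grid, rounded to one decimal so that grid
#: values compare exactly against window edges expressed as 0.1-multiples.
TEMP_GRID: np.ndarray = np.round(np.linspace(GRID_START, GRID_STOP, N_GRID), 1)
TEMP_GRID.setflags(write=False)

PHENOTYPES: tuple[str, ...] = ("cCAD", "TMI", "nTMi")
TIMEPOINTS: tuple[str, ...] = ("T0", "T2", "T4", "T24", "T48", "Tfu")
#: Acute-course timepoints after baseline; these are the ones a censoring rule
#: may exclude (baseline and follow-up are always retained).
POST_BASELINE_ACUTE: tuple[str, ...] = ("T2", "T4", "T24", "T48")

# Peak windows, degC.  Half-open [low, high) so that the shared 73 degC edge
# between the Peak 2 and Peak 3 ranges belongs to exactly one window.
PEAK1_WINDOW: tuple[float, float] = (60.0, 66.0)
PEAK2_WINDOW: tuple[float, float] = (67.0, 73.0)
PEAK3_WINDOW: tuple[float, float] = (73.0, 81.0)
DEFAULT_PEAK_WINDOWS: dict[str, tuple[float, float]] = {
    "Peak1": PEAK1_WINDOW,
    "Peak2": PEAK2_WINDOW,
    "Peak3": PEAK3_WINDOW,
}
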