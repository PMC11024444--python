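"""Raw DSC scan handling and the preprocessing chain that finalizes a TLB profile.

A raw differential scanning calorimetry (DSC) scan is a two-column curve of
measured heat signal against temperature.  Turning it into a thermal liquid
biopsy (TLB) profile — excess specific heat capacity Cp^ex in cal/(degC.g) on
the standard 45–90 degC / 0.1 degC grid — takes four corrections, applied in
this order:

1. instrument-baseline correction by subtraction of a buffer reference scan,
2. normalization by sample protein concentration (and cell volume / scan rate)
   to convert the power-like signal into heat capacity per gram,
3. removal of any residual linear sample baseline anchored on the flat flanks
   of the scan,
4. linear interpolation onto the uniform analysis grid.

Duplicate scans of the same sample are averaged pointwise, with the observed
replicate spread recorded in the profile's provenance.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import CoverageError, DomainError, ScanParseError, ValidationError
from .grid import GRID_START, GRID_STOP, N_GRID, TEMP_GRID

__all__ = [
    "RawScan",
    "Thermogram",
    "read_scan",
    "subtract_buffer",
    "normalize_concentration",
    "linear_baseline_correct",
    "regrid",
    "average_replicates",
    "write_thermogram",
    "read_thermogram",
    "DEFAULT_CELL_VOLUME_ML",
]

#: Volume of the calorimeter's thermal sensing area, ml.
DEFAULT_CELL_VOLUME_ML: float = 0.3

_DELIMS = re.compile(r"[,\t;]|\s+")


@dataclass(frozen=True)
class RawScan:
    """An instrument-level DSC curve.

    Parameters
    ----------
    sample_id
        Identifier of the scanned sample (or buffer batch).
    temperature
        Strictly increasing temperatures, degC.
    signal
        Heat signal per temperature point, one value per temperature.
    scan_rate
        Heating rate in degC/min (1.0 for the standard protocol).
    role
        Either ``"sample"`` or ``"buffer"``.
    """

    sample_id: str
    temperature: np.ndarray
    signal: np.ndarray
    scan_rate: float = 1.0
    role: str = "sample"

    def __post_init__(self) -> None:
        t = np.asarray(self.temperature, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        if t.ndim != 1 or s.ndim != 1 or t.size != s.size:
            raise ValidationError(
                f"{self.sample_id}: temperature and signal must be 1-D and of "
                f"equal length (got {t.size} and {s.size})"
            )
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            bad = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 1
            raise ValidationError(
                f"{self.sample_id}: temperature must be strictly increasing "
                f"(violation at point {bad + 1})"
            )
        if self.role not in ("sample", "buffer"):
            raise ValidationError(f"unknown scan role {self.role!r}")
        object.__setattr__(self, "temperature", t)
        object.__setattr__(self, "signal", s)

    def __len__(self) -> int:
        return self.temperature.size

    def replace_signal(self, signal: np.ndarray) -> "RawScan":
        return RawScan(self.sample_id, self.temperature, signal,
                       self.scan_rate, self.role)

    def covers(self, low: float = GRID_START, high: float = GRID_STOP) -> bool:
        return bool(self.temperature[0] <= low and self.temperature[-1] >= high)


@dataclass(frozen=True)
class Thermogram:
    """A finalized TLB profile on the standard 451-point grid.

    ``cp_excess`` holds excess specific heat capacity in cal/(degC.g);
    ``provenance`` records the corrections that produced the profile
    (buffer id, protein concentration, baseline anchors, replicate count...).
    """

    sample_id: str
    cp_excess: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        cp = np.asarray(self.cp_excess, dtype=float)
        if cp.shape != (N_GRID,):
            raise ValidationError(
                f"{self.sample_id}: cp_excess must have {N_GRID} points on the "
                f"standard grid (got shape {cp.shape})"
            )
        if not np.all(np.isfinite(cp)):
            raise ValidationError(f"{self.sample_id}: cp_excess contains non-finite values")
        object.__setattr__(self, "cp_excess", cp)

    @property
    def grid(self) -> np.ndarray:
        """The shared 45.0–90.0 degC grid (0.1 degC step)."""
        return TEMP_GRID


def read_scan(path: str | Path, role: str = "sample",
              sample_id: str | None = None, scan_rate: float = 1.0) -> RawScan:
    """Read a raw scan from a delimited text file.

    The file must contain at least two numeric columns (temperature, signal);
    comma, semicolon, tab or whitespace delimiters are auto-detected and an
    optional single header line is skipped.
    """
    path = Path(path)
    temps: list[float] = []
    sigs: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = [f for f in _DELIMS.split(line) if f]
            if len(fields) < 2:
                raise ScanParseError(f"{path}: line {lineno}: expected >= 2 columns")
            try:
                t, s = float(fields[0]), float(fields[1])
            except ValueError:
                if lineno == 1 and not temps:
                    continue  # header line
                raise ScanParseError(
                    f"{path}: line {lineno}: non-numeric value in {fields[:2]!r}"
                ) from None
            temps.append(t)
            sigs.append(s)
    if not temps:
        raise ScanParseError(f"{path}: no data rows")
    return RawScan(sample_id or path.stem, np.array(temps), np.array(sigs),
                   scan_rate=scan_rate, role=role)


def subtract_buffer(sample: RawScan, buffer: RawScan) -> RawScan:
    """Subtract a buffer reference scan from a sample scan (instrument baseline).

    The buffer is linearly interpolated onto the sample's temperatures; the
    returned scan is restricted to the temperatures the buffer covers, and the
    buffer must cover the sample's portion of the 45–90 degC analysis range.
    """
    blo, bhi = buffer.temperature[0], buffer.temperature[-1]
    need_lo = max(GRID_START, sample.temperature[0])
    need_hi = min(GRID_STOP, sample.temperature[-1])
    if blo > need_lo or bhi < need_hi:
        raise CoverageError(
            f"buffer {buffer.sample_id} spans [{blo}, {bhi}] degC and does not "
            f"cover the sample's analysis range [{need_lo}, {need_hi}]"
        )
    mask = (sample.temperature >= blo) & (sample.temperature <= bhi)
    t = sample.temperature[mask]
    corrected = sample.signal[mask] - np.interp(t, buffer.temperature, buffer.signal)
    return RawScan(sample.sample_id, t, corrected, sample.scan_rate, sample.role)


def normalize_concentration(scan: RawScan, protein_conc: float,
                            cell_volume: float = DEFAULT_CELL_VOLUME_ML,
                            scan_rate: float | None = None) -> RawScan:
    """Convert the heat signal to heat capacity per gram of protein.

    Divides the signal by ``scan_rate x protein_conc x cell_volume`` — i.e. by
    the heating rate and the protein mass in the sensing volume.  With the
    signal in mcal/min, concentration in mg/ml and volume in ml, the result is
    in cal/(degC.g).

    Parameters
    ----------
    protein_conc
        Sample protein concentration, mg/ml (assay-measured, ~2 mg/ml).
    cell_volume
        Sensing-cell volume, ml (0.3 ml for the standard instrument).
    scan_rate
        Heating rate, degC/min; defaults to the scan's own rate.
    """
    rate = scan.scan_rate if scan_rate is None else scan_rate
    if protein_conc <= 0 or cell_volume <= 0 or rate <= 0:
        raise DomainError(
            "protein_conc, cell_volume and scan_rate must all be positive "
            f"(got {protein_conc}, {cell_volume}, {rate})"
        )
    return scan.replace_signal(scan.signal / (rate * protein_conc * cell_volume))


def linear_baseline_correct(scan: RawScan,
                            low_window: tuple[float, float] = (45.0, 50.0),
                            high_window: tuple[float, float] = (85.0, 90.0),
                            ) -> RawScan:
    """Remove a residual linear sample baseline.

    A straight line through the (mean temperature, mean signal) points of two
    flat anchor windows — by default the 45–50 and 85–90 degC flanks, outside
    the three transition windows — is subtracted from the signal.  After
    correction the mean signal within each anchor window is zero.
    """
    anchors = []
    for lo, hi in (low_window, high_window):
        m = (scan.temperature >= lo) & (scan.temperature <= hi)
        if m.sum() < 3:
            raise DomainError(
                f"anchor window [{lo}, {hi}] degC contains only {int(m.sum())} "
                "points; need at least 3"
            )
        anchors.append((scan.temperature[m].mean(), scan.signal[m].mean()))
    (x0, y0), (x1, y1) = anchors
    slope = (y1 - y0) / (x1 - x0)
    baseline = y0 + slope * (scan.temperature - x0)
    return scan.replace_signal(scan.signal - baseline)


def regrid(scan: RawScan, provenance: dict | None = None) -> Thermogram:
    """Interpolate a corrected scan onto the standard 451-point grid.

    Linear interpolation; input points that coincide with grid points are
    preserved exactly.  The scan must cover [45, 90] degC.
    """
    if not scan.covers():
        raise CoverageError(
            f"{scan.sample_id}: scan spans [{scan.temperature[0]}, "
            f"{scan.temperature[-1]}] degC; the analysis grid needs [45, 90]"
        )
    cp = np.interp(TEMP_GRID, scan.temperature, scan.signal)
    return Thermogram(scan.sample_id, cp, dict(provenance or {}))


def average_replicates(reps: Sequence[Thermogram]) -> Thermogram:
    """Pointwise mean of duplicate profiles of one sample.

    The provenance of the result records the replicate count and the maximum
    pointwise absolute spread between replicates (reported, not thresholded).
    """
    reps = list(reps)
    if not reps:
        raise DomainError("average_replicates needs at least one replicate")
    stack = np.stack([r.cp_excess for r in reps])
    spread = float(np.max(stack.max(axis=0) - stack.min(axis=0))) if len(reps) > 1 else 0.0
    prov = dict(reps[0].provenance)
    prov.update(replicates=len(reps), max_replicate_spread=spread)
    return Thermogram(reps[0].sample_id, stack.mean(axis=0), prov)


def preprocess_scan(sample: RawScan, buffer: RawScan, protein_conc: float,
                    cell_volume: float = DEFAULT_CELL_VOLUME_ML,
                    low_anchor: tuple[float, float] = (45.0, 50.0),
                    high_anchor: tuple[float, float] = (85.0, 90.0),
                    ) -> Thermogram:
    """Full correction chain: buffer subtraction -> concentration normalization
    -> linear baseline removal -> regridding."""
    s = subtract_buffer(sample, buffer)
    s = normalize_concentration(s, protein_conc, cell_volume)
    s = linear_baseline_correct(s, low_anchor, high_anchor)
    return regrid(s, provenance={
        "buffer_id": buffer.sample_id,
        "protein_conc_mg_ml": protein_conc,
        "cell_volume_ml": cell_volume,
        "baseline_anchors": [list(low_anchor), list(high_anchor)],
    })


# ---------------------------------------------------------------------------
# Finalized-profile persistence: CSV curve + JSON metadata sidecar.

def write_thermogram(tg: Thermogram, path: str | Path,
                     metadata: dict | None = None) -> Path:
    """Write a profile as ``temperature,cp_excess`` CSV (451 rows) plus a JSON
    sidecar carrying sample id, provenance and any extra metadata.

    Values are written with full float precision so that a write/read
    round-trip reproduces the profile exactly.
    """
    path = Path(path)
    with open(path, "w", newline="\n") as fh:
        fh.write("temperature,cp_excess\n")
        for t, c in zip(TEMP_GRID, tg.cp_excess):
            fh.write(f"{t:.1f},{float(c)!r}\n")
    sidecar = {"sample_id": tg.sample_id, "provenance": tg.provenance}
    sidecar.update(metadata or {})
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1) + "\n")
    return path


def read_thermogram(path: str | Path) -> Thermogram:
    """Read a finalized profile written by :func:`write_thermogram`."""
    path = Path(path)
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    if data.shape != (N_GRID, 2):
        raise ValidationError(f"{path}: expected {N_GRID} rows of temperature,cp_excess")
    if not np.allclose(data[:, 0], TEMP_GRID, atol=1e-9):
        raise ValidationError(f"{path}: temperature column is not the standard grid")
    sample_id, prov = path.stem, {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        sample_id = meta.get("sample_id", sample_id)
        prov = meta.get("provenance", {})
    return Thermogram(sample_id, data[:, 1], prov)
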