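"""Synthetic thermogram cohorts with myocardial-injury phenotype structure.

The study's patient data are not publicly available, so every downstream
stage is exercised on simulated cohorts that reproduce the qualitative
signatures reported for the three phenotypes:

* **cCAD** (chronic coronary atherosclerotic disease, the diseased control):
  a quiescent-like profile at every timepoint — dominant Peak 1 near 63 degC,
  smaller Peak 2 near 70 degC, small Peak 3 shoulder near 77 degC — with only
  a mild Peak 1 depression at baseline.
* **TMI** (acute thrombotic MI): strongly diminished Peak 1 and an elevated
  Peak 3 at baseline.  A minority subtype (``TMI_80C``) instead shows small
  Peak 1/Peak 2 amplitudes with a dominant, clearly defined 80 degC peak.
* **nTMi** (acute non-thrombotic myocardial injury): diminished Peak 1 and an
  elevated 68–75 degC region at baseline.

Each phenotype recovers toward the shared quiescent signature along the acute
time course T0 -> T2 -> T4 -> T24 -> T48 -> Tfu via a monotone recovery
fraction lambda (0 at baseline, 1 at follow-up), with nTMi recovering faster
than TMI.  Curves are sums of Gaussian components — chosen over two-state
denaturation transitions because the analysis consumes only curve shape and
Gaussians give closed-form oracles for every metric.  The component constants
are implementation defaults tuned for qualitative fidelity and testability,
not values estimated from patient data.

Noise model: one multiplicative amplitude factor and one temperature jitter
per patient (shared across that patient's timepoints — patients serve as
their own controls), plus i.i.d. pointwise Gaussian noise per scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort import CohortDataset
from .errors import DomainError, ValidationError
from .grid import TEMP_GRID, TIMEPOINTS
from .io import Thermogram

__all__ = [
    "GaussianComponent",
    "PhenotypeTemplate",
    "NoiseModel",
    "default_templates",
    "default_group_sizes",
    "simulate_thermogram",
    "simulate_cohort",
    "DEFAULT_FRAC_TMI_80C",
]

#: Fraction of TMI patients carrying the 80 degC-peak subtype (7 of 60).
DEFAULT_FRAC_TMI_80C: float = 7.0 / 60.0


@dataclass(frozen=True)
class GaussianComponent:
    """One thermal transition: amplitude * exp(-(T - center)^2 / (2 sigma^2))."""

    center: float   # degC
    sigma: float    # degC
    amplitude: float  # cal/(degC.g)

    def __call__(self, temps: np.ndarray) -> np.ndarray:
        return self.amplitude * np.exp(-((temps - self.center) ** 2)
                                       / (2.0 * self.sigma ** 2))


#: The shared stable-state signature every phenotype recovers to.
QUIESCENT_COMPONENTS: tuple[GaussianComponent, ...] = (
    GaussianComponent(63.0, 1.8, 0.150),
    GaussianComponent(70.0, 2.0, 0.095),
    GaussianComponent(77.0, 2.2, 0.040),
)


@dataclass(frozen=True)
class PhenotypeTemplate:
    """Acute and quiescent mixtures plus a recovery schedule for one phenotype.

    ``timepoint_weights`` maps each timepoint to the recovery fraction
    lambda in [0, 1]; the mean curve at a timepoint is
    ``(1 - lambda) * acute + lambda * quiescent``.  lambda(T0) = 0 (fully
    acute at baseline) and lambda(Tfu) = 1 (fully quiescent at follow-up).
    """

    phenotype: str
    acute: tuple[GaussianComponent, ...]
    timepoint_weights: dict[str, float]
    quiescent: tuple[GaussianComponent, ...] = QUIESCENT_COMPONENTS

    def __post_init__(self) -> None:
        for comp in (*self.acute, *self.quiescent):
            if comp.sigma <= 0 or comp.amplitude < 0 or not 50.0 <= comp.center <= 85.0:
                raise ValidationError(f"invalid template component {comp}")
        lam = self.timepoint_weights
        if any(not 0.0 <= v <= 1.0 for v in lam.values()):
            raise ValidationError("recovery fractions must lie in [0, 1]")
        if lam.get("T0", 0.0) != 0.0 or lam.get("Tfu", 1.0) != 1.0:
            raise ValidationError("need lambda(T0) = 0 and lambda(Tfu) = 1")

    def mixture(self, components: tuple[GaussianComponent, ...],
                temps: np.ndarray, shift: float = 0.0) -> np.ndarray:
        return sum((c(temps - shift) for c in components),
                   start=np.zeros_like(temps, dtype=float))

    def mean_curve(self, timepoint: str, temps: np.ndarray | None = None,
                   shift: float = 0.0) -> np.ndarray:
        """Noise-free expected curve at a timepoint (optionally jittered by
        ``shift`` degC toward higher temperatures)."""
        if timepoint not in self.timepoint_weights:
            raise DomainError(
                f"{self.phenotype}: unknown timepoint {timepoint!r}; have "
                f"{sorted(self.timepoint_weights)}"
            )
        temps = TEMP_GRID if temps is None else np.asarray(temps, dtype=float)
        lam = self.timepoint_weights[timepoint]
        return ((1.0 - lam) * self.mixture(self.acute, temps, shift)
                + lam * self.mixture(self.quiescent, temps, shift))


@dataclass(frozen=True)
class NoiseModel:
    """Per-scan and per-patient variability.

    ``pointwise_sd``: additive Gaussian noise per grid point, cal/(degC.g) —
    instrument noise.  ``amplitude_cv``: log-scale SD of the multiplicative
    per-sample scale — residual concentration/composition variability.
    ``shift_sd``: SD of the per-sample temperature jitter, degC.
    """

    pointwise_sd: float = 0.0030
    amplitude_cv: float = 0.08
    shift_sd: float = 0.25

    def __post_init__(self) -> None:
        if min(self.pointwise_sd, self.amplitude_cv, self.shift_sd) < 0:
            raise ValidationError("noise parameters must be non-negative")

    @classmethod
    def silent(cls) -> "NoiseModel":
        return cls(0.0, 0.0, 0.0)


def default_templates() -> dict[str, PhenotypeTemplate]:
    """Templates for the three phenotypes plus the TMI 80 degC-peak subtype.

    Baseline orderings mirror the reported signatures: cCAD keeps the dominant
    Peak 1; TMI and nTMi have diminished Peak 1; TMI has the highest Peak 3;
    nTMi elevates the 68–75 degC region; TMI_80C has a dominant 80 degC peak.
    Recovery is monotone, with nTMi faster than TMI and cCAD nearly stable.
    """
    return {
        "cCAD": PhenotypeTemplate(
            "cCAD",
            acute=(GaussianComponent(63.0, 1.8, 0.135),
                   GaussianComponent(70.0, 2.0, 0.097),
                   GaussianComponent(77.0, 2.2, 0.042)),
            timepoint_weights={"T0": 0.0, "T2": 0.40, "T4": 0.55,
                               "T24": 0.75, "T48": 0.85, "Tfu": 1.0},
        ),
        "TMI": PhenotypeTemplate(
            "TMI",
            acute=(GaussianComponent(63.0, 1.8, 0.085),
                   GaussianComponent(70.0, 2.0, 0.090),
                   GaussianComponent(77.0, 2.2, 0.075)),
            timepoint_weights={"T0": 0.0, "T2": 0.05, "T4": 0.12,
                               "T24": 0.35, "T48": 0.55, "Tfu": 1.0},
        ),
        "nTMi": PhenotypeTemplate(
            "nTMi",
            acute=(GaussianComponent(63.0, 1.8, 0.095),
                   GaussianComponent(70.5, 2.0, 0.105),
                   GaussianComponent(76.0, 1.1, 0.055)),
            timepoint_weights={"T0": 0.0, "T2": 0.10, "T4": 0.22,
                               "T24": 0.50, "T48": 0.70, "Tfu": 1.0},
        ),
        "TMI_80C": PhenotypeTemplate(
            "TMI_80C",
            acute=(GaussianComponent(63.0, 1.8, 0.045),
                   GaussianComponent(70.0, 2.0, 0.040),
                   GaussianComponent(80.0, 1.4, 0.165)),
            timepoint_weights={"T0": 0.0, "T2": 0.05, "T4": 0.12,
                               "T24": 0.35, "T48": 0.55, "Tfu": 1.0},
        ),
    }


def default_group_sizes() -> dict[str, int]:
    """The study's group sizes: 35 cCAD, 60 TMI, 20 nTMi (115 patients)."""
    return {"cCAD": 35, "TMI": 60, "nTMi": 20}


def _render(template: PhenotypeTemplate, timepoint: str, scale: float,
            shift: float, eps: np.ndarray) -> np.ndarray:
    return template.mean_curve(timepoint, shift=shift) * scale + eps


def simulate_thermogram(template: PhenotypeTemplate, timepoint: str,
                        noise: NoiseModel | None = None,
                        seed: int | np.random.Generator | None = None,
                        sample_id: str = "synthetic") -> Thermogram:
    """Draw one noisy thermogram from a phenotype template.

    With an all-zero noise model the output is exactly the template's mean
    curve at the timepoint; the same seed always yields the same profile.
    """
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    shift = rng.normal(0.0, noise.shift_sd)
    scale = float(np.exp(rng.normal(0.0, noise.amplitude_cv)))
    eps = rng.normal(0.0, noise.pointwise_sd, TEMP_GRID.size)
    cp = _render(template, timepoint, scale, shift, eps)
    return Thermogram(sample_id, cp, {
        "synthetic": True, "phenotype": template.phenotype,
        "timepoint": timepoint,
    })


def simulate_cohort(n_per_group: dict[str, int] | None = None,
                    timepoints: tuple[str, ...] = TIMEPOINTS,
                    templates: dict[str, PhenotypeTemplate] | None = None,
                    noise: NoiseModel | None = None,
                    seed: int | None = None,
                    frac_tmi_80c: float = DEFAULT_FRAC_TMI_80C,
                    n_ccad_type4mi: int = 1) -> CohortDataset:
    """Simulate a longitudinal cohort with per-patient random effects.

    Each patient gets one multiplicative amplitude factor and one temperature
    jitter, shared across all of that patient's timepoints; pointwise noise is
    drawn per scan.  TMI patients carry the 80 degC subtype with probability
    ``frac_tmi_80c`` (default 7/60).  ``n_ccad_type4mi`` cCAD patients are
    flagged ``troponin_above_url`` in the manifest, emulating the per-protocol
    post-procedure troponin rise that censors their post-baseline acute
    samples (one patient in the study).  Metadata keeps the true phenotype and
    subtype labels so recovery of structure can be tested.
    """
    if n_per_group is None:
        n_per_group = default_group_sizes()
    if not timepoints:
        raise DomainError("need at least one timepoint")
    if any(n <= 0 for n in n_per_group.values()):
        raise DomainError("group sizes must be positive")
    if not 0.0 <= frac_tmi_80c <= 1.0:
        raise DomainError("frac_tmi_80c must lie in [0, 1]")
    templates = templates or default_templates()
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed)

    rows: list[dict] = []
    thermograms: dict[str, Thermogram] = {}
    for phenotype, n in n_per_group.items():
        for p in range(1, n + 1):
            patient_id = f"{phenotype}-{p:03d}"
            subtype = phenotype
            if phenotype == "TMI" and rng.random() < frac_tmi_80c:
                subtype = "TMI_80C"
            scale_p = float(np.exp(rng.normal(0.0, noise.amplitude_cv)))
            shift_p = float(rng.normal(0.0, noise.shift_sd))
            flagged = phenotype == "cCAD" and p <= n_ccad_type4mi
            template = templates[subtype]
            for tp in timepoints:
                sample_id = f"{patient_id}_{tp}"
                eps = rng.normal(0.0, noise.pointwise_sd, TEMP_GRID.size)
                cp = _render(template, tp, scale_p, shift_p, eps)
                thermograms[sample_id] = Thermogram(sample_id, cp, {
                    "synthetic": True, "phenotype": phenotype,
                    "subtype": subtype, "timepoint": tp,
                })
                rows.append({
                    "sample_id": sample_id, "patient_id": patient_id,
                    "phenotype": phenotype, "subtype": subtype,
                    "timepoint": tp, "censored": False,
                    "troponin_above_url": bool(flagged),
                })
    manifest = pd.DataFrame(rows)
    return CohortDataset(manifest=manifest, thermograms=thermograms)
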