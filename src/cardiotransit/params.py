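"""Domain parameter types and calibrated population presets.

The imaging presets encode the group means reported for paced hiPSC-derived
cardiomyocytes loaded with Rhod-2 (wild type, CRISPLD1 knock-out, and each
line treated with 5 uM helothermine).  Amplitude is the peak F/F0 ratio;
rise time is the interval from the 15%-height onset to the peak; decay-50 is
the interval from the peak to 50% loss of transient height.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

__all__ = [
    "TransientParams",
    "AcquisitionParams",
    "PopulationPreset",
    "CountSimParams",
    "ConcordancePreset",
    "IMAGING_PRESETS",
    "CONCORDANCE_PRESETS",
    "METRIC_NAMES",
]

#: per-cell metrics carried through the hierarchical population model
METRIC_NAMES = ("amplitude_peak", "rise_time_ms", "decay50_ms")


@dataclass(frozen=True)
class TransientParams:
    """Ground-truth shape of one paced calcium transient.

    amplitude_peak
        Peak F/F0 ratio (dimensionless, >= 1; 1 means no transient).
    rise_time_ms
        Time from the 15%-height onset crossing to the peak, ms.
    decay50_ms
        Time from the peak to 50% loss of transient height, ms.
    baseline_f0
        Resting fluorescence in expected photons per pixel per line.
    pacing_hz
        Field-stimulation frequency, Hz (0.25 Hz in the study protocol).
    """

    amplitude_peak: float
    rise_time_ms: float
    decay50_ms: float
    baseline_f0: float = 80.0
    pacing_hz: float = 0.25

    def __post_init__(self) -> None:
        if self.amplitude_peak < 1.0:
            raise ValueError("amplitude_peak must be >= 1 (F/F0 ratio)")
        if self.rise_time_ms <= 0 or self.decay50_ms <= 0:
            raise ValueError("rise_time_ms and decay50_ms must be positive")
        if self.baseline_f0 <= 0:
            raise ValueError("baseline_f0 must be positive")
        if self.pacing_hz <= 0:
            raise ValueError("pacing_hz must be positive")
        epoch_ms = 1000.0 / self.pacing_hz
        if self.rise_time_ms + 2.0 * self.decay50_ms >= epoch_ms:
            raise ValueError(
                "transient does not fit one pacing epoch: "
                f"rise_time_ms + 2*decay50_ms = "
                f"{self.rise_time_ms + 2 * self.decay50_ms:.1f} ms "
                f">= {epoch_ms:.1f} ms"
            )

    @property
    def epoch_s(self) -> float:
        return 1.0 / self.pacing_hz


@dataclass(frozen=True)
class AcquisitionParams:
    """Confocal line-scan acquisition settings (512 px, 45 um, 1057.7 Hz,
    20,000 lines by default, matching the study's scanner configuration)."""

    n_pixels: int = 512
    scan_width_um: float = 45.0
    line_rate_hz: float = 1057.7
    n_lines: int = 20000
    photon_gain: float = 1.0
    bleach_rate: float = 0.0  # monoexponential photobleaching constant, 1/s

    def __post_init__(self) -> None:
        if self.n_pixels < 8:
            raise ValueError("n_pixels must be >= 8")
        if self.line_rate_hz <= 0:
            raise ValueError("line_rate_hz must be positive")
        if self.n_lines < 1:
            raise ValueError("n_lines must be >= 1")
        if self.photon_gain <= 0:
            raise ValueError("photon_gain must be positive")

    @property
    def dt(self) -> float:
        return 1.0 / self.line_rate_hz

    @property
    def duration_s(self) -> float:
        return self.n_lines / self.line_rate_hz

    @property
    def pixel_size_um(self) -> float:
        return self.scan_width_um / self.n_pixels


def _as_metric_map(value: float | Mapping[str, float]) -> dict[str, float]:
    if isinstance(value, Mapping):
        missing = set(METRIC_NAMES) - set(value)
        if missing:
            raise ValueError(f"missing metrics in mapping: {sorted(missing)}")
        return {m: float(value[m]) for m in METRIC_NAMES}
    return {m: float(value) for m in METRIC_NAMES}


@dataclass(frozen=True)
class PopulationPreset:
    """Generative parameters of one cell group.

    ``cv_between_cell`` is the coefficient of variation of each metric across
    cells; ``sd_between_diff`` is the between-differentiation-batch SD in the
    units of each metric.  Either may be a scalar (applied to every metric)
    or a per-metric mapping.
    """

    group_label: str
    mean_params: TransientParams
    cv_between_cell: float | Mapping[str, float] = 0.2
    sd_between_diff: float | Mapping[str, float] = 0.0
    n_diff: int = 3
    helothermine_conc_uM: float = 0.0

    def __post_init__(self) -> None:
        cv = _as_metric_map(self.cv_between_cell)
        sd = _as_metric_map(self.sd_between_diff)
        if any(v < 0 for v in cv.values()):
            raise ValueError("cv_between_cell must be >= 0")
        if any(v < 0 for v in sd.values()):
            raise ValueError("sd_between_diff must be >= 0")
        if self.n_diff < 1:
            raise ValueError("n_diff must be >= 1")
        object.__setattr__(self, "cv_between_cell", cv)
        object.__setattr__(self, "sd_between_diff", sd)

    def metric_mean(self, metric: str) -> float:
        return float(getattr(self.mean_params, metric))


def _imaging_preset(
    label: str,
    amplitude: float,
    rise_ms: float,
    decay50_ms: float,
    helothermine_uM: float,
    cv: float = 0.2,
    sd_frac: float = 0.05,
) -> PopulationPreset:
    mean = TransientParams(amplitude, rise_ms, decay50_ms)
    sd = {
        "amplitude_peak": sd_frac * amplitude,
        "rise_time_ms": sd_frac * rise_ms,
        "decay50_ms": sd_frac * decay50_ms,
    }
    return PopulationPreset(
        group_label=label,
        mean_params=mean,
        cv_between_cell=cv,
        sd_between_diff=sd,
        n_diff=3,
        helothermine_conc_uM=helothermine_uM,
    )


#: group means calibrated to the reported confocal imaging results
IMAGING_PRESETS: dict[str, PopulationPreset] = {
    "WT": _imaging_preset("WT", 2.8, 169.5, 603.5, 0.0),
    "KO": _imaging_preset("KO", 3.5, 199.0, 460.8, 0.0),
    "WT_HELHO": _imaging_preset("WT_HELHO", 2.5, 207.1, 731.9, 5.0),
    "KO_HELHO": _imaging_preset("KO_HELHO", 2.8, 170.0, 650.2, 5.0),
}

#: cells measured per group in the study (treated-group counts unreported;
#: defaulted to 180)
GROUP_N_CELLS: dict[str, int] = {
    "WT": 181,
    "KO": 183,
    "WT_HELHO": 180,
    "KO_HELHO": 180,
}


@dataclass(frozen=True)
class CountSimParams:
    """Negative-binomial count simulation for one species.

    ``design`` maps sample id -> stage label; ``stages`` orders the stages
    control-first.  ``planted_effects`` maps gene index -> {stage: log2FC}.
    Var(count) = mu + dispersion * mu^2.
    """

    n_genes: int
    design: Mapping[str, str]
    stages: tuple[str, ...]
    dispersion: float = 0.05
    size_factor_range: tuple[float, float] = (0.7, 1.4)
    planted_effects: Mapping[int, Mapping[str, float]] = field(default_factory=dict)
    base_mean: float | None = None  # None -> lognormal draw per gene
    base_mean_log_sigma: float = 1.0
    base_mean_median: float = 150.0
    base_mean_overrides: Mapping[int, float] = field(default_factory=dict)
    gene_prefix: str = "G"

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not self.design:
            raise ValueError("design is empty")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        lo, hi = self.size_factor_range
        if lo <= 0 or hi < lo:
            raise ValueError("size factors must be positive")
        unknown = set(self.design.values()) - set(self.stages)
        if unknown:
            raise ValueError(f"design stages not in stage order: {sorted(unknown)}")
        for g in self.planted_effects:
            if not (0 <= g < self.n_genes):
                raise ValueError(f"planted gene index out of range: {g}")


@dataclass(frozen=True)
class ConcordancePreset:
    """Paired human/mouse simulation with planted concordant progressive genes.

    Gene 0 emulates the CRISPLD1 profile (human log2FC 1.6 at the compensated
    stage and 2.6 at moderate failure; mouse 1.5 and 2.3).  The remaining
    planted genes are progressive in either direction with early-stage
    |log2FC| >= 1.8 on a 20,000-gene null background.
    """

    n_genes: int = 20000
    n_planted: int = 25
    dispersion: float = 0.05
    size_factor_range: tuple[float, float] = (0.7, 1.4)
    human_n: tuple[int, int, int] = (4, 5, 5)  # NF, CH, mHF
    mouse_n: tuple[int, int, int] = (4, 4, 5)  # sham, 1wTAC, 8wTAC
    crispld1_human: tuple[float, float] = (1.6, 2.6)
    crispld1_mouse: tuple[float, float] = (1.5, 2.3)
    planted_early_lfc: tuple[float, float] = (1.8, 2.4)
    planted_step_lfc: tuple[float, float] = (0.5, 1.0)
    planted_base_mean: tuple[float, float] = (200.0, 800.0)

    def __post_init__(self) -> None:
        if self.n_planted > self.n_genes:
            raise ValueError("n_planted must be <= n_genes")
        if self.n_planted < 0:
            raise ValueError("n_planted must be >= 0")


CONCORDANCE_PRESETS: dict[str, ConcordancePreset] = {
    "default": ConcordancePreset(),
    "null": ConcordancePreset(n_planted=0),
}

HUMAN_STAGES = ("NF", "CH", "mHF")
MOUSE_STAGES = ("sham", "1wTAC", "8wTAC")


def preset_without_noise(preset: PopulationPreset) -> PopulationPreset:
    """Degenerate copy of a preset with all between-cell/batch variance removed."""
    return replace(preset, cv_between_cell=0.0, sd_between_diff=0.0)
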