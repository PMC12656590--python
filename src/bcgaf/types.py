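"""Core domain types for the multi-site BCG atrial-fibrillation pipeline.

The vocabulary follows bed-sensor ballistocardiography practice: a
*recording* is one participant's simultaneous multi-sensor session, a
*block* is one 32.768 s analysis window of one sensor channel, and the
participant-level rhythm label (AF vs. non-AF) is inherited by every block
of that participant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from types import MappingProxyType
from typing import Mapping, Optional

import numpy as np

#: Full-scale range of the 16-bit sensor ADC, in anonymous counts.
ADC_MIN = 0
ADC_MAX = 65535

#: Analysis window and hop, chosen as powers of two at fs = 500 Hz
#: (32.768 s -> 16,384 samples; 4.096 s -> 2,048 samples).
BLOCK_SECONDS = 32.768
STRIDE_SECONDS = 4.096

#: Raw-amplitude motion-artifact threshold, in counts.
RAW_NOISE_THRESHOLD = 34000.0


class RhythmLabel(str, Enum):
    """Participant-level cardiac rhythm class."""

    AF = "AF"
    NON_AF = "NON_AF"


class SensorPlacement(str, Enum):
    """Sensor position on the bed, named by distance from the head.

    The four sheet sensors lie under the mattress with their upper edges
    0, 25, 45 and 65 cm from the base of the head; BCG2 sits at chest
    (heart) level and carries the strongest cardiac content, while BCG3/4
    sit near the diaphragm and pick up relatively more respiration.
    """

    BCG1 = "BCG1"
    BCG2 = "BCG2"
    BCG3 = "BCG3"
    BCG4 = "BCG4"

    @property
    def offset_cm(self) -> int:
        return {"BCG1": 0, "BCG2": 25, "BCG3": 45, "BCG4": 65}[self.value]


_DEFAULT_CARDIAC_GAIN = MappingProxyType(
    {
        SensorPlacement.BCG1: 700.0,
        SensorPlacement.BCG2: 900.0,
        SensorPlacement.BCG3: 400.0,
        SensorPlacement.BCG4: 200.0,
    }
)
_DEFAULT_RESP_GAIN = MappingProxyType(
    {
        SensorPlacement.BCG1: 100.0,
        SensorPlacement.BCG2: 80.0,
        SensorPlacement.BCG3: 300.0,
        SensorPlacement.BCG4: 350.0,
    }
)


@dataclass(frozen=True)
class SynthParams:
    """Parameters of the synthetic BCG generator.

    Amplitudes are in raw ADC counts. The defaults emulate supine rest
    recordings: a DC offset near 32,800 counts, heartbeat-driven damped
    oscillations whose gain peaks at the chest-level sensor, a ~0.25 Hz
    respiratory component strongest at the lumbar sensors, white sensor
    noise, and sporadic motion bursts that push the raw amplitude past
    the 34,000-count artifact threshold.
    """

    duration_s: float = 300.0
    fs: float = 500.0
    mean_hr_bpm: float = 66.0
    hr_jitter_bpm: float = 8.0
    rr_cv_sinus: float = 0.03
    rr_cv_af: float = 0.24
    kernel_freq_hz: float = 5.0
    kernel_decay_s: float = 0.15
    resp_freq_hz: float = 0.25
    dc_offset: float = 32800.0
    cardiac_gain_by_placement: Mapping[SensorPlacement, float] = field(
        default_factory=lambda: _DEFAULT_CARDIAC_GAIN
    )
    resp_gain_by_placement: Mapping[SensorPlacement, float] = field(
        default_factory=lambda: _DEFAULT_RESP_GAIN
    )
    noise_sd: float = 25.0
    artifact_rate_per_min: float = 0.4
    artifact_amplitude: float = 2000.0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.duration_s < 0:
            raise ValueError(f"duration_s must be non-negative, got {self.duration_s}")
        if self.mean_hr_bpm <= 0:
            raise ValueError(f"mean_hr_bpm must be positive, got {self.mean_hr_bpm}")
        if self.rr_cv_af <= self.rr_cv_sinus:
            raise ValueError("rr_cv_af must exceed rr_cv_sinus")
        if self.kernel_decay_s <= 0:
            raise ValueError("kernel_decay_s must be positive")
        if self.noise_sd < 0 or self.artifact_rate_per_min < 0:
            raise ValueError("noise_sd and artifact_rate_per_min must be >= 0")
        for gains in (self.cardiac_gain_by_placement, self.resp_gain_by_placement):
            if any(g < 0 for g in gains.values()):
                raise ValueError("channel gains must be non-negative")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))

    @property
    def mean_rr_s(self) -> float:
        return 60.0 / self.mean_hr_bpm


@dataclass
class Recording:
    """One participant's simultaneous multi-sensor raw BCG session."""

    participant_id: str
    label: RhythmLabel
    channels: Mapping[SensorPlacement, np.ndarray]
    fs: float
    mean_hr_bpm: Optional[float] = None

    def __post_init__(self) -> None:
        lengths = {len(sig) for sig in self.channels.values()}
        if len(lengths) > 1:
            raise ValueError("all channels of a recording must have equal length")
        for placement, sig in self.channels.items():
            if sig.min() < ADC_MIN or sig.max() > ADC_MAX:
                raise ValueError(f"{placement.value}: samples outside [0, 65535]")
        if self.channels and self.n_samples < int(round(BLOCK_SECONDS * self.fs)):
            raise ValueError(
                f"recording shorter than one {BLOCK_SECONDS} s analysis block"
            )

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class Block:
    """One sliding analysis window of one channel, with identity."""

    participant_id: str
    placement: Optional[SensorPlacement]
    start_sample: int
    raw: np.ndarray
    label: Optional[RhythmLabel]
    fs: float


class DegenerateBlockError(ValueError):
    """Raised when a zero-variance block cannot be standardized."""


class NoiseRule(str, Enum):
    RAW_THRESHOLD = "RAW_THRESHOLD"
    STD_THRESHOLD = "STD_THRESHOLD"


@dataclass(frozen=True)
class NoiseDecision:
    """Outcome of a per-block motion-artifact screen."""

    included: bool
    rule: NoiseRule
    statistic: float
    threshold: float


@dataclass(frozen=True, order=True)
class SpectrumSetting:
    """Featurization setting: crop the spectrum to [lowcut, highcut] Hz
    and aggregate into ``nbins`` equal-width power bins."""

    lowcut_hz: float
    highcut_hz: float
    nbins: int

    def __post_init__(self) -> None:
        if not self.lowcut_hz < self.highcut_hz:
            raise ValueError("lowcut_hz must be below highcut_hz")
        if self.nbins < 1:
            raise ValueError("nbins must be >= 1")

    def __str__(self) -> str:
        return f"{self.lowcut_hz:g}-{self.highcut_hz:g}Hz_{self.nbins}bins"


@dataclass
class SpectralFeatures:
    """Binned one-sided power spectrum of one standardized block."""

    participant_id: str
    placement: Optional[SensorPlacement]
    start_sample: int
    label: Optional[RhythmLabel]
    setting: SpectrumSetting
    values: np.ndarray

    def __post_init__(self) -> None:
        if len(self.values) != self.setting.nbins:
            raise ValueError("feature length must equal nbins")
        if np.any(self.values < 0):
            raise ValueError("binned power must be non-negative")


class Family(str, Enum):
    """Classifier family."""

    DT = "DT"
    RF = "RF"
    LR = "LR"
    ADA = "ADA"


_REQUIRED_KEYS = {
    Family.DT: {"max_depth"},
    Family.RF: {"max_depth"},
    Family.LR: {"C"},
    Family.ADA: {"max_depth", "learning_rate"},
}


@dataclass(frozen=True)
class ClassifierConfig:
    """One grid point: classifier family + hyperparameters + featurization."""

    family: Family
    hyperparameters: tuple  # sorted tuple of (name, value) pairs
    setting: SpectrumSetting

    def __post_init__(self) -> None:
        hp = dict(self.hyperparameters)
        required = _REQUIRED_KEYS[self.family]
        if set(hp) != required:
            raise ValueError(
                f"{self.family.value} requires hyperparameters {sorted(required)}, "
                f"got {sorted(hp)}"
            )
        for name, value in hp.items():
            if not isinstance(value, (int, float)) or value <= 0:
                raise ValueError(f"hyperparameter {name} must be a positive number")
        object.__setattr__(
            self, "hyperparameters", tuple(sorted(self.hyperparameters))
        )

    @staticmethod
    def make(family: Family, setting: SpectrumSetting, **hyperparameters) -> "ClassifierConfig":
        return ClassifierConfig(
            family=family,
            hyperparameters=tuple(sorted(hyperparameters.items())),
            setting=setting,
        )

    @property
    def params(self) -> dict:
        return dict(self.hyperparameters)


@dataclass
class CVResult:
    """Cross-validated accuracy of one configuration."""

    config: ClassifierConfig
    fold_accuracies: np.ndarray
    mean_accuracy: float
    sd_accuracy: float

    @staticmethod
    def from_folds(config: ClassifierConfig, fold_accuracies) -> "CVResult":
        accs = np.asarray(fold_accuracies, dtype=float)
        return CVResult(
            config=config,
            fold_accuracies=accs,
            mean_accuracy=float(accs.mean()),
            sd_accuracy=float(accs.std(ddof=0)),
        )


@dataclass
class BlockPrediction:
    """Per-block classifier output; higher score means more AF-like."""

    participant_id: str
    placement: Optional[SensorPlacement]
    start_sample: int
    predicted: RhythmLabel
    score: Optional[float] = None


@dataclass
class EvalReport:
    """Confusion-matrix metrics of a block-level evaluation.

    AF is the positive class. Undefined metrics (e.g. recall with no
    positive blocks, AUC with a single class) are reported as None.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: Optional[float]
    recall: Optional[float]
    specificity: Optional[float]
    precision: Optional[float]
    f1: Optional[float]
    auc: Optional[float]

    @staticmethod
    def from_counts(tp: int, fp: int, tn: int, fn: int,
                    auc: Optional[float] = None) -> "EvalReport":
        total = tp + fp + tn + fn
        accuracy = (tp + tn) / total if total else None
        recall = tp / (tp + fn) if (tp + fn) else None
        specificity = tn / (tn + fp) if (tn + fp) else None
        precision = tp / (tp + fp) if (tp + fp) else None
        if recall is None or precision is None or (recall + precision) == 0:
            f1 = None
            if recall is None:
                warnings.warn("recall undefined: no positive-class blocks", stacklevel=2)
        else:
            f1 = 2 * recall * precision / (recall + precision)
        return EvalReport(tp, fp, tn, fn, accuracy, recall,
                          specificity, precision, f1, auc)

    def rounded(self, ndigits: int = 2) -> dict:
        """Metrics rounded half-away-from-zero, for table-style reporting."""
        from .metrics import round_half_away

        out = {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn}
        for name in ("accuracy", "recall", "specificity", "precision", "f1", "auc"):
            value = getattr(self, name)
            out[name] = None if value is None else round_half_away(value, ndigits)
        return out


@dataclass
class FusedPrediction:
    """OR-rule fusion of time-aligned per-sensor block predictions."""

    participant_id: str
    start_sample: int
    sensors_used: frozenset
    available: frozenset
    predicted: RhythmLabel

    def __post_init__(self) -> None:
        if not self.available:
            raise ValueError("a fused prediction requires at least one available sensor")
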