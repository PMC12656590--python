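"""Block segmentation, standardization, noise rejection and spectral
featurization of raw BCG channels.

The processing chain per channel is: slide a 32.768 s window every
4.096 s; screen each block for motion artifacts (raw amplitude above
34,000 counts, or alternatively a calibrated threshold on the
standardized amplitude); standardize the surviving blocks to zero mean
and unit variance; apply a Hanning-windowed FFT; and aggregate the
one-sided power spectrum into equal-width frequency bins over a chosen
[lowcut, highcut] Hz range. At 500 Hz one block is 16,384 samples and
its one-sided spectrum has 8,193 points spanning 0–250 Hz.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .types import (
    BLOCK_SECONDS,
    RAW_NOISE_THRESHOLD,
    STRIDE_SECONDS,
    Block,
    DegenerateBlockError,
    NoiseDecision,
    NoiseRule,
    Recording,
    RhythmLabel,
    SensorPlacement,
    SpectralFeatures,
    SpectrumSetting,
)


def n_blocks(n_samples: int, block_len: int, stride: int) -> int:
    """Number of full sliding windows: floor((N - L) / S) + 1, or 0 if N < L."""
    if n_samples < block_len:
        return 0
    return (n_samples - block_len) // stride + 1


def segment_blocks(
    signal: np.ndarray,
    fs: float,
    block_s: float = BLOCK_SECONDS,
    stride_s: float = STRIDE_SECONDS,
    *,
    participant_id: str = "",
    placement: Optional[SensorPlacement] = None,
    label: Optional[RhythmLabel] = None,
) -> List[Block]:
    """Cut a channel into sliding blocks; the trailing partial window is
    dropped. A signal shorter than one block is an error."""
    signal = np.asarray(signal)
    block_len = int(round(block_s * fs))
    stride = int(round(stride_s * fs))
    if len(signal) < block_len:
        raise ValueError(
            f"signal of {len(signal)} samples is shorter than one "
            f"{block_len}-sample block"
        )
    count = n_blocks(len(signal), block_len, stride)
    return [
        Block(
            participant_id=participant_id,
            placement=placement,
            start_sample=i * stride,
            raw=signal[i * stride : i * stride + block_len],
            label=label,
            fs=fs,
        )
        for i in range(count)
    ]


def standardize(raw: np.ndarray) -> np.ndarray:
    """Subtract the mean and divide by the population SD (divisor N).

    Raises :class:`DegenerateBlockError` on a zero-variance block; the
    caller is expected to exclude such blocks.
    """
    x = np.asarray(raw, dtype=float)
    sd = x.std(ddof=0)
    if sd == 0:
        raise DegenerateBlockError("zero-variance block cannot be standardized")
    return (x - x.mean()) / sd


def reject_noisy_raw(block: Block, threshold: float = RAW_NOISE_THRESHOLD) -> NoiseDecision:
    """Raw-amplitude screen: exclude when max(raw) exceeds the threshold."""
    statistic = float(np.max(block.raw))
    return NoiseDecision(
        included=statistic <= threshold,
        rule=NoiseRule.RAW_THRESHOLD,
        statistic=statistic,
        threshold=float(threshold),
    )


def max_standardized(block: Block) -> float:
    """Per-block maximum of the standardized amplitude (the screening
    statistic of the standardized-threshold rule)."""
    return float(np.max(standardize(block.raw)))


def reject_noisy_standardized(block: Block, threshold: float) -> NoiseDecision:
    """Standardized-amplitude screen; a degenerate (constant) block is
    excluded with an infinite statistic."""
    try:
        statistic = max_standardized(block)
    except DegenerateBlockError:
        statistic = math.inf
    return NoiseDecision(
        included=statistic <= threshold,
        rule=NoiseRule.STD_THRESHOLD,
        statistic=statistic,
        threshold=float(threshold),
    )


def calibrate_standardized_threshold(
    blocks: Sequence[Block], target_excluded_fraction: float
) -> float:
    """Threshold on the standardized amplitude that excludes the same
    portion of blocks as a given raw-amplitude screen would.

    Returns the smallest per-block max-standardized-amplitude quantile
    such that ``floor(fraction * n)`` blocks are excluded; with tied
    statistics fewer blocks may be excluded (ties break toward
    inclusion). Degenerate blocks are skipped.
    """
    if not 0 <= target_excluded_fraction < 1:
        raise ValueError("target_excluded_fraction must be in [0, 1)")
    stats = []
    for block in blocks:
        try:
            stats.append(max_standardized(block))
        except DegenerateBlockError:
            continue
    if not stats:
        raise ValueError("no standardizable blocks to calibrate on")
    stats = np.sort(np.asarray(stats))
    n = stats.size
    m = int(math.floor(target_excluded_fraction * n))
    # Threshold = largest statistic kept; exactly the m larger ones exceed it.
    return float(stats[n - 1 - m])


def power_spectrum(standardized: np.ndarray, fs: float) -> Tuple[np.ndarray, np.ndarray]:
    """One-sided Hanning-windowed power spectrum, |FFT|^2 / N.

    Frequencies are k*fs/N for k = 0..N/2; a 16,384-sample block at
    500 Hz yields 8,193 points spanning [0, 250] Hz. No window-gain
    compensation is applied — downstream classifiers only require a
    consistent scaling.
    """
    x = np.asarray(standardized, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("power_spectrum expects a one-dimensional block")
    n = x.size
    windowed = x * np.hanning(n)
    spectrum = np.fft.rfft(windowed)
    power = (spectrum.real**2 + spectrum.imag**2) / n
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    return freqs, power


def crop_and_bin(
    freqs: np.ndarray, power: np.ndarray, setting: SpectrumSetting
) -> np.ndarray:
    """Crop the spectrum to [lowcut, highcut] (both ends closed) and sum
    the power within ``nbins`` equal-width contiguous intervals.

    The last interval is closed so the point at ``highcut`` is kept;
    empty intervals contribute 0. Summation (rather than averaging)
    conserves total cropped power across binnings.
    """
    freqs = np.asarray(freqs)
    power = np.asarray(power)
    mask = (freqs >= setting.lowcut_hz) & (freqs <= setting.highcut_hz)
    if not mask.any():
        raise ValueError(
            f"no spectrum points survive cropping to "
            f"[{setting.lowcut_hz}, {setting.highcut_hz}] Hz"
        )
    f = freqs[mask]
    p = power[mask]
    width = (setting.highcut_hz - setting.lowcut_hz) / setting.nbins
    idx = np.floor((f - setting.lowcut_hz) / width).astype(int)
    idx = np.clip(idx, 0, setting.nbins - 1)  # closes the last interval
    return np.bincount(idx, weights=p, minlength=setting.nbins)


def spectral_features(block: Block, setting: SpectrumSetting) -> SpectralFeatures:
    """Standardize one block and compute its binned power features."""
    freqs, power = power_spectrum(standardize(block.raw), block.fs)
    return SpectralFeatures(
        participant_id=block.participant_id,
        placement=block.placement,
        start_sample=block.start_sample,
        label=block.label,
        setting=setting,
        values=crop_and_bin(freqs, power, setting),
    )


def band_power(
    freqs: np.ndarray,
    power: np.ndarray,
    centers: Iterable[float],
    halfwidth_hz: float,
) -> float:
    """Total power within ±halfwidth bands around the given frequencies
    (used to quantify the heart-rate harmonic comb)."""
    freqs = np.asarray(freqs)
    power = np.asarray(power)
    total = 0.0
    for c in centers:
        total += float(power[(freqs >= c - halfwidth_hz) & (freqs <= c + halfwidth_hz)].sum())
    return total


@dataclass
class FeatureDataset:
    """Featurized, noise-screened blocks of one placement (or a pool).

    ``meta`` has one row per *included* block (participant_id, placement,
    start_sample, label); ``features[setting]`` is the row-aligned binned
    power matrix for each requested setting. ``n_total_blocks`` counts
    blocks before noise rejection.
    """

    meta: pd.DataFrame
    features: Dict[SpectrumSetting, np.ndarray]
    n_total_blocks: int

    @property
    def n_included(self) -> int:
        return len(self.meta)

    @property
    def n_excluded(self) -> int:
        return self.n_total_blocks - self.n_included

    @property
    def settings(self) -> List[SpectrumSetting]:
        return list(self.features)

    def labels_by_participant(self) -> Dict[str, RhythmLabel]:
        return {
            pid: RhythmLabel(lbl)
            for pid, lbl in self.meta.groupby("participant_id")["label"].first().items()
        }


def featurize_recordings(
    recordings: Iterable[Recording],
    placements: Optional[Sequence[SensorPlacement]] = None,
    settings: Sequence[SpectrumSetting] = (),
    noise_rule: NoiseRule = NoiseRule.RAW_THRESHOLD,
    threshold: float = RAW_NOISE_THRESHOLD,
    block_s: float = BLOCK_SECONDS,
    stride_s: float = STRIDE_SECONDS,
) -> FeatureDataset:
    """Segment, screen and featurize every requested channel of a cohort.

    Blocks failing the noise screen (or degenerate blocks) are dropped;
    surviving blocks are featurized under every setting at once so a
    grid search never recomputes spectra.
    """
    settings = list(settings)
    rows = []
    columns: Dict[SpectrumSetting, list] = {s: [] for s in settings}
    total = 0
    for rec in recordings:
        for placement, signal in rec.channels.items():
            if placements is not None and placement not in placements:
                continue
            blocks = segment_blocks(
                signal,
                rec.fs,
                block_s,
                stride_s,
                participant_id=rec.participant_id,
                placement=placement,
                label=rec.label,
            )
            total += len(blocks)
            for block in blocks:
                if noise_rule is NoiseRule.RAW_THRESHOLD:
                    decision = reject_noisy_raw(block, threshold)
                else:
                    decision = reject_noisy_standardized(block, threshold)
                if not decision.included:
                    continue
                try:
                    std = standardize(block.raw)
                except DegenerateBlockError:
                    continue
                freqs, power = power_spectrum(std, block.fs)
                rows.append(
                    {
                        "participant_id": block.participant_id,
                        "placement": placement.value,
                        "start_sample": block.start_sample,
                        "label": block.label.value,
                    }
                )
                for setting in settings:
                    columns[setting].append(crop_and_bin(freqs, power, setting))
    meta = pd.DataFrame(
        rows, columns=["participant_id", "placement", "start_sample", "label"]
    )
    features = {
        s: (np.vstack(vals) if vals else np.empty((0, s.nbins)))
        for s, vals in columns.items()
    }
    return FeatureDataset(meta=meta, features=features, n_total_blocks=total)
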