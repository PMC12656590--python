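"""Seeded synthetic multi-sensor BCG cohort generator.

The generator emulates the signal structure a piezoelectric sheet sensor
records from a supine participant:

* a near-periodic train of heartbeat-induced vibrations — an impulse
  train at the beat times convolved with a damped-oscillation kernel —
  whose regularity in sinus rhythm produces a comb of spectral peaks at
  integer multiples of the heart rate below ~10 Hz, and whose
  irregularity in atrial fibrillation (high RR-interval variability)
  destroys that comb;
* a low-frequency respiratory oscillation, relatively strongest at the
  lumbar-level sensors;
* a large DC offset near 32,800 counts from the 16-bit unsigned ADC;
* white sensor noise; and
* sporadic motion-artifact bursts whose raw amplitude exceeds the
  34,000-count rejection threshold.

All randomness flows through one explicit integer seed; per-participant
and per-channel sub-streams are derived deterministically with
``numpy.random.SeedSequence``, so identical seeds give bit-identical
cohorts.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .types import (
    ADC_MAX,
    ADC_MIN,
    Recording,
    RhythmLabel,
    SensorPlacement,
    SynthParams,
)

#: Minimum physiologically plausible RR interval (truncation point of the
#: sinus-rhythm RR distribution), seconds.
MIN_RR_S = 0.2

#: Carrier frequency of motion-artifact bursts, Hz.
_ARTIFACT_CARRIER_HZ = 8.0


def generate_rr_series(
    label: RhythmLabel,
    duration_s: float,
    params: SynthParams,
    seed: int,
) -> np.ndarray:
    """Generate strictly increasing beat times in ``[0, duration_s)``.

    Sinus rhythm draws successive RR intervals from a normal distribution
    (mean ``60/mean_hr_bpm``, coefficient of variation ``rr_cv_sinus``)
    truncated below at 0.2 s. AF draws independent log-normal intervals
    with the same mean and coefficient of variation ``rr_cv_af``, which
    is high enough to destroy the spectral harmonic comb.
    """
    if params.mean_hr_bpm <= 0:
        raise ValueError(f"mean_hr_bpm must be positive, got {params.mean_hr_bpm}")
    if duration_s < 0:
        raise ValueError(f"duration_s must be non-negative, got {duration_s}")
    if duration_s == 0:
        return np.empty(0)

    rng = np.random.default_rng(seed)
    mean_rr = 60.0 / params.mean_hr_bpm

    def draw(size: int) -> np.ndarray:
        if label is RhythmLabel.NON_AF:
            sd = params.rr_cv_sinus * mean_rr
            a = (MIN_RR_S - mean_rr) / sd
            return stats.truncnorm.rvs(
                a, np.inf, loc=mean_rr, scale=sd, size=size, random_state=rng
            )
        sigma2 = np.log1p(params.rr_cv_af**2)
        mu = np.log(mean_rr) - sigma2 / 2.0
        return rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=size)

    phase = rng.uniform(0.0, mean_rr)
    batch = int(np.ceil(duration_s / mean_rr * 1.5)) + 20
    intervals = draw(batch)
    while phase + intervals.sum() < duration_s:  # pragma: no cover - ample margin
        intervals = np.concatenate([intervals, draw(batch)])
    beats = phase + np.concatenate(([0.0], np.cumsum(intervals)))
    return beats[beats < duration_s]


def _beat_kernel(params: SynthParams) -> np.ndarray:
    """Damped-oscillation response of the sensor to one heartbeat."""
    t = np.arange(0.0, 6.0 * params.kernel_decay_s, 1.0 / params.fs)
    return np.exp(-t / params.kernel_decay_s) * np.sin(
        2.0 * np.pi * params.kernel_freq_hz * t
    )


def synthesize_channel(
    beat_times: np.ndarray,
    placement: SensorPlacement,
    params: SynthParams,
    seed: int,
) -> np.ndarray:
    """Render one clean (artifact-free) channel as 16-bit unsigned counts.

    signal = dc_offset
             + cardiac_gain * (impulse train at beat_times  *  kernel)
             + resp_gain * sin(2*pi*resp_freq*t + phase)
             + white noise,
    rounded and clipped to [0, 65535]. The convolution kernel is
    ``exp(-t/kernel_decay_s) * sin(2*pi*kernel_freq_hz*t)``.
    """
    if params.kernel_decay_s <= 0:
        raise ValueError("kernel_decay_s must be positive")
    n = params.n_samples
    beat_times = np.asarray(beat_times, dtype=float)
    if beat_times.size and (beat_times.min() < 0 or beat_times.max() >= params.duration_s):
        raise ValueError("beat_times must lie within [0, duration_s)")

    rng = np.random.default_rng(seed)
    impulses = np.zeros(n)
    if beat_times.size:
        idx = np.floor(beat_times * params.fs).astype(int)
        np.add.at(impulses, idx, 1.0)
    cardiac = np.convolve(impulses, _beat_kernel(params))[:n]

    t = np.arange(n) / params.fs
    resp_phase = rng.uniform(0.0, 2.0 * np.pi)
    resp = np.sin(2.0 * np.pi * params.resp_freq_hz * t + resp_phase)

    x = (
        params.dc_offset
        + params.cardiac_gain_by_placement[placement] * cardiac
        + params.resp_gain_by_placement[placement] * resp
    )
    if params.noise_sd > 0:
        x = x + rng.normal(0.0, params.noise_sd, size=n)
    return np.clip(np.rint(x), ADC_MIN, ADC_MAX).astype(np.uint16)


def inject_motion_artifacts(
    signal: np.ndarray,
    params: SynthParams,
    seed: int,
    return_events: bool = False,
):
    """Overwrite Poisson-distributed burst windows with high-amplitude
    transients; samples outside bursts are unchanged.

    Burst count is Poisson with rate ``artifact_rate_per_min``; each
    burst lasts 0.5–2 s and is a Hann-enveloped oscillation whose peak
    raw amplitude equals ``dc_offset + artifact_amplitude``, so with the
    required ``artifact_amplitude + dc_offset > 34,000`` every burst
    fails the raw-amplitude noise screen.
    """
    if params.artifact_rate_per_min < 0:
        raise ValueError("artifact_rate_per_min must be >= 0")
    if params.artifact_amplitude + params.dc_offset <= 34000:
        raise ValueError("artifact_amplitude + dc_offset must exceed 34,000")

    out = np.asarray(signal).copy()
    n = out.size
    rng = np.random.default_rng(seed)
    n_events = rng.poisson(params.artifact_rate_per_min * n / params.fs / 60.0)
    events = []
    for _ in range(n_events):
        dur = rng.uniform(0.5, 2.0)
        length = min(int(round(dur * params.fs)), n)
        start = int(rng.integers(0, n - length + 1))
        env = np.hanning(length)
        env = env / env.max()
        peak = int(np.argmax(env))
        tt = (np.arange(length) - peak) / params.fs
        burst = params.dc_offset + params.artifact_amplitude * env * np.cos(
            2.0 * np.pi * _ARTIFACT_CARRIER_HZ * tt
        )
        out[start : start + length] = np.clip(
            np.rint(burst), ADC_MIN, ADC_MAX
        ).astype(out.dtype)
        events.append((start, start + length))
    return (out, events) if return_events else out


def generate_recording(
    participant_id: str,
    label: RhythmLabel,
    params: SynthParams,
    seed,
    placements: Optional[Sequence[SensorPlacement]] = None,
    with_artifacts: bool = True,
) -> Recording:
    """Generate one participant: a shared beat train rendered through each
    requested sensor placement (channels are simultaneous by construction)."""
    placements = list(placements) if placements is not None else list(SensorPlacement)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    sub = [int(s) for s in (ss.generate_state(2 + 2 * len(placements)) & 0x7FFFFFFF)]

    hr_rng = np.random.default_rng(sub[0])
    hr = float(np.clip(hr_rng.normal(params.mean_hr_bpm, params.hr_jitter_bpm), 40.0, 140.0))
    p = replace(params, mean_hr_bpm=hr)

    beats = generate_rr_series(label, p.duration_s, p, sub[1])
    channels = {}
    for j, placement in enumerate(placements):
        sig = synthesize_channel(beats, placement, p, sub[2 + 2 * j])
        if with_artifacts and p.artifact_rate_per_min > 0:
            sig = inject_motion_artifacts(sig, p, sub[3 + 2 * j])
        channels[placement] = sig
    return Recording(
        participant_id=participant_id,
        label=label,
        channels=channels,
        fs=p.fs,
        mean_hr_bpm=hr,
    )


def generate_cohort(
    n_af: int,
    n_non_af: int,
    params: SynthParams,
    seed: int,
    placements: Optional[Sequence[SensorPlacement]] = None,
    with_artifacts: bool = True,
) -> list:
    """Generate ``n_af + n_non_af`` labelled recordings with distinct
    participant ids and per-participant jittered heart rates.

    Deterministic given ``seed``: participant sub-streams are spawned
    from one :class:`numpy.random.SeedSequence`.
    """
    if n_af < 0 or n_non_af < 0:
        raise ValueError("cohort sizes must be non-negative")
    labels = [RhythmLabel.AF] * n_af + [RhythmLabel.NON_AF] * n_non_af
    children = np.random.SeedSequence(seed).spawn(len(labels))
    cohort = []
    for i, (label, child) in enumerate(zip(labels, children)):
        cohort.append(
            generate_recording(
                participant_id=f"P{i + 1:03d}",
                label=label,
                params=params,
                seed=child,
                placements=placements,
                with_artifacts=with_artifacts,
            )
        )
    return cohort
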