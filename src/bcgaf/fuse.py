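"""Decision-level fusion of per-sensor block predictions.

Channels are recorded simultaneously, so blocks from different sensors
align exactly by (participant_id, start_sample). The OR rule labels a
time-aligned block AF when *any* available sensor's classifier labels it
AF; a block is excluded only when every sensor in the chosen subset
failed noise rejection. Fusing therefore never decreases the number of
included blocks, never decreases recall, and never increases
specificity on the blocks every component sensor saw.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple  # noqa: F401

import pandas as pd

from .classify import evaluate
from .types import (
    BlockPrediction,
    EvalReport,
    FusedPrediction,
    RhythmLabel,
    SensorPlacement,
)


def combine_or(
    predictions_by_sensor: Mapping[SensorPlacement, Sequence[BlockPrediction]],
    subset: Iterable[SensorPlacement],
) -> List[FusedPrediction]:
    """Fuse time-aligned predictions from the sensors in ``subset``.

    Only sensors whose block passed noise rejection contribute (i.e.
    have a prediction); a block appears in the output whenever at least
    one subset sensor has a prediction for it.
    """
    subset = frozenset(SensorPlacement(p) for p in subset)
    if not subset:
        raise ValueError("the sensor subset must be non-empty")
    by_key: Dict[Tuple[str, int], Dict[SensorPlacement, BlockPrediction]] = {}
    for placement in subset:
        for pred in predictions_by_sensor.get(placement, ()):
            by_key.setdefault((pred.participant_id, pred.start_sample), {})[
                placement
            ] = pred
    fused = []
    for (pid, start), avail in sorted(by_key.items()):
        any_af = any(p.predicted is RhythmLabel.AF for p in avail.values())
        fused.append(
            FusedPrediction(
                participant_id=pid,
                start_sample=start,
                sensors_used=subset,
                available=frozenset(avail),
                predicted=RhythmLabel.AF if any_af else RhythmLabel.NON_AF,
            )
        )
    return fused


@dataclass
class FusionReport:
    """Evaluation of one sensor subset plus its block-retention count."""

    subset: frozenset
    report: EvalReport
    included_blocks: int
    included_fraction: Optional[float]


def fusion_report(
    fused: Sequence[FusedPrediction],
    labels: Mapping[str, RhythmLabel],
    total_blocks: Optional[int] = None,
) -> FusionReport:
    """Evaluate fused predictions and count the blocks retained; the
    retention fraction uses ``total_blocks`` (e.g. all time-aligned test
    blocks) as the denominator when given."""
    fused = list(fused)
    if not fused:
        raise ValueError("cannot report on an empty fusion result")
    report = evaluate(fused, labels)
    included = len(fused)
    fraction = included / total_blocks if total_blocks else None
    return FusionReport(
        subset=fused[0].sensors_used,
        report=report,
        included_blocks=included,
        included_fraction=fraction,
    )


def all_subsets(
    placements: Sequence[SensorPlacement] = tuple(SensorPlacement),
) -> List[frozenset]:
    """All non-empty sensor subsets (15 for four sensors), smallest first."""
    subsets = []
    for r in range(1, len(placements) + 1):
        for combo in itertools.combinations(placements, r):
            subsets.append(frozenset(combo))
    return subsets


def participant_accuracy(
    predictions: Sequence, labels: Mapping[str, RhythmLabel]
) -> pd.DataFrame:
    """Per-participant fraction of included blocks whose prediction
    matches the participant's rhythm label.

    For an AF participant this is the fraction of blocks predicted AF;
    for a non-AF participant, the fraction predicted non-AF. A labelled
    participant with zero included blocks is reported with a missing
    accuracy (and a warning).
    """
    counts: Dict[str, List[int]] = {}
    for p in predictions:
        truth = RhythmLabel(labels[p.participant_id])
        correct = RhythmLabel(p.predicted) is truth
        n_ok, n_all = counts.get(p.participant_id, (0, 0))
        counts[p.participant_id] = [n_ok + correct, n_all + 1]
    rows = []
    for pid in sorted(labels):
        n_ok, n_all = counts.get(pid, (0, 0))
        if n_all == 0:
            warnings.warn(f"participant {pid} has no included blocks", stacklevel=2)
        rows.append(
            {
                "participant_id": pid,
                "label": RhythmLabel(labels[pid]).value,
                "n_blocks": n_all,
                "accuracy": n_ok / n_all if n_all else None,
            }
        )
    return pd.DataFrame(rows, columns=["participant_id", "label", "n_blocks", "accuracy"])
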