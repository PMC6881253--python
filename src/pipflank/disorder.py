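"""Consensus calls over externally produced per-residue disorder scores.

Disorder predictors are never executed here; their per-residue score tracks
(one value in [0, 1] per residue per predictor) arrive as files or arrays.
The consensus convention: a residue (or a motif window) is disordered when
the mean score across predictors is >= 0.5, threshold inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .errors import TrackAlignmentError

DISORDER_THRESHOLD = 0.5


@dataclass
class DisorderTrack:
    """Per-predictor per-residue scores for one protein."""

    protein_id: str
    scores: Mapping[str, np.ndarray]  # predictor -> scores in [0, 1]

    def __post_init__(self) -> None:
        if not self.scores:
            raise ValueError("at least one predictor track required")
        arrays = {k: np.asarray(v, dtype=float) for k, v in self.scores.items()}
        lengths = {len(v) for v in arrays.values()}
        if len(lengths) != 1:
            raise TrackAlignmentError(
                f"{self.protein_id}: predictor tracks differ in length {lengths}"
            )
        for name, arr in arrays.items():
            if not np.isfinite(arr).all():
                raise TrackAlignmentError(f"{self.protein_id}/{name}: missing scores")
            if ((arr < 0) | (arr > 1)).any():
                raise ValueError(f"{self.protein_id}/{name}: scores outside [0, 1]")
        self.scores = arrays

    def __len__(self) -> int:
        return len(next(iter(self.scores.values())))


def consensus_disorder(track: DisorderTrack) -> tuple[np.ndarray, np.ndarray]:
    """(mean score per residue, boolean disordered call per residue)."""
    stacked = np.vstack(list(track.scores.values()))
    mean = stacked.mean(axis=0)
    return mean, mean >= DISORDER_THRESHOLD


@dataclass(frozen=True)
class MotifDisorderAnnotation:
    call: str                 # 'D' or 'F'
    avg_propensity: float
    per_predictor_means: dict[str, float]
    consistent: bool


def annotate_motif_disorder(
    track: DisorderTrack, motif_span: tuple[int, int]
) -> MotifDisorderAnnotation:
    """Disorder annotation for a motif window (1-based, inclusive).

    ``consistent`` is True when every predictor's own motif-average falls on
    the same side of the 0.5 threshold as the consensus call.
    """
    start, end = motif_span
    if not (1 <= start <= end <= len(track)):
        raise ValueError("motif span outside track")
    sl = slice(start - 1, end)
    per_pred = {k: float(v[sl].mean()) for k, v in track.scores.items()}
    avg = float(np.mean(list(per_pred.values())))
    call = "D" if avg >= DISORDER_THRESHOLD else "F"
    sides = {m >= DISORDER_THRESHOLD for m in per_pred.values()}
    return MotifDisorderAnnotation(
        call=call,
        avg_propensity=avg,
        per_predictor_means=per_pred,
        consistent=len(sides) == 1,
    )
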