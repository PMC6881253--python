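"""Secondary chemical shifts and Cα-based helicity estimation.

A residue's secondary chemical shift (SCS) is its observed shift minus a
random-coil reference for the same residue type in the same sequence
context.  Positive Cα SCS reports helical backbone sampling; the fractional
helicity of a peptide window is estimated from the mean Cα SCS on a linear
scale where 3.2 ppm corresponds to 100% helix.  Negative means clamp to 0%.

The shipped reference is a compact Cα coil library distilled for disordered
peptides near 25 °C / pH 6.3: a per-residue baseline plus a small
nearest-neighbour correction table (the dominant term being the well-known
upfield shift of a residue preceding proline).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ShiftConsistencyError, UnsupportedNucleusError
from .motifs import AMINO_ACIDS, round_half_up

#: ppm of mean Cα SCS corresponding to 100% helix
FULL_HELIX_CA_PPM = 3.2

#: Cα random-coil baselines (ppm), disordered-peptide conditions
RANDOM_COIL_CA: dict[str, float] = {
    "A": 52.8, "C": 58.3, "D": 54.5, "E": 56.9, "F": 58.1,
    "G": 45.4, "H": 55.8, "I": 61.6, "K": 56.7, "L": 55.5,
    "M": 55.8, "N": 53.3, "P": 63.5, "Q": 56.2, "R": 56.5,
    "S": 58.7, "T": 62.0, "V": 62.6, "W": 57.6, "Y": 58.2,
}

#: correction to residue i's Cα from the identity of residue i+1
NEIGHBOR_NEXT_CA: dict[str, float] = {
    "P": -1.90, "G": -0.10, "V": -0.10, "I": -0.10, "T": -0.08,
}
#: correction to residue i's Cα from the identity of residue i-1
NEIGHBOR_PREV_CA: dict[str, float] = {
    "P": -0.25, "G": 0.10, "A": 0.05, "V": -0.05, "W": -0.10, "Y": -0.08,
}


@dataclass(frozen=True)
class RandomCoilReference:
    """Baselines plus nearest-neighbour corrections per nucleus (Cα shipped)."""

    baselines: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {"CA": RANDOM_COIL_CA}
    )
    next_corr: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {"CA": NEIGHBOR_NEXT_CA}
    )
    prev_corr: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {"CA": NEIGHBOR_PREV_CA}
    )

    def nuclei(self) -> tuple[str, ...]:
        return tuple(self.baselines)


DEFAULT_REFERENCE = RandomCoilReference()


@dataclass
class ShiftTable:
    """Observed shifts: one row per (residue index, nucleus).

    ``data`` columns: index (1-based), aa, nucleus, ppm, assigned (bool).
    """

    data: pd.DataFrame

    REQUIRED = ("index", "aa", "nucleus", "ppm", "assigned")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.data.columns)
        if missing:
            raise ValueError(f"shift table missing columns {sorted(missing)}")
        dup = self.data.duplicated(subset=["index", "nucleus"])
        if dup.any():
            raise ValueError("duplicate (index, nucleus) rows")
        assigned = self.data[self.data["assigned"]]
        if not np.isfinite(assigned["ppm"].to_numpy(float)).all():
            raise ValueError("assigned shifts must be finite")

    def nucleus(self, nucleus: str) -> pd.DataFrame:
        return self.data[self.data["nucleus"] == nucleus]


@dataclass(frozen=True)
class SCSProfile:
    """Per-residue Δδ, window mean, and the helicity it implies."""

    indices: np.ndarray        # 1-based residue indices with assigned Δδ
    delta: np.ndarray          # Δδ (ppm), same order as indices
    mean_scs: float            # ppm over the requested window
    helicity: float            # percent, clamped to [0, 100]
    nucleus: str = "CA"


def random_coil_shift(
    seq: str,
    i: int,
    nucleus: str = "CA",
    ref: RandomCoilReference = DEFAULT_REFERENCE,
) -> float:
    """Coil reference shift for residue ``i`` (1-based) of ``seq``.

    Baseline for the residue type plus neighbour corrections from i±1 when
    those neighbours exist and the table carries a term for them.
    """
    if nucleus not in ref.baselines:
        raise UnsupportedNucleusError(
            f"reference covers {ref.nuclei()}, not {nucleus!r}"
        )
    seq = seq.upper()
    if not (1 <= i <= len(seq)):
        raise ValueError("index outside sequence")
    aa = seq[i - 1]
    if aa not in AMINO_ACIDS:
        raise ValueError(f"non-canonical residue {aa!r}")
    shift = ref.baselines[nucleus][aa]
    if i > 1:
        shift += ref.prev_corr[nucleus].get(seq[i - 2], 0.0)
    if i < len(seq):
        shift += ref.next_corr[nucleus].get(seq[i], 0.0)
    return shift


def secondary_shifts(
    obs: ShiftTable,
    seq: str,
    ref: RandomCoilReference = DEFAULT_REFERENCE,
    nucleus: str = "CA",
    window: tuple[int, int] | None = None,
) -> SCSProfile:
    """Δδ = δ_obs − δ_coil for assigned residues; mean over ``window``.

    Unassigned residues carry no Δδ and are excluded from the mean.
    ``window`` is a 1-based inclusive residue-index range (default: all
    assigned residues of the requested nucleus).
    """
    seq = seq.upper()
    rows = obs.nucleus(nucleus)
    indices, deltas = [], []
    for _, row in rows.iterrows():
        i = int(row["index"])
        if not (1 <= i <= len(seq)):
            raise ShiftConsistencyError(f"index {i} outside sequence")
        if str(row["aa"]).upper() != seq[i - 1]:
            raise ShiftConsistencyError(
                f"residue mismatch at {i}: table {row['aa']!r} vs seq {seq[i-1]!r}"
            )
        if not row["assigned"]:
            continue
        indices.append(i)
        deltas.append(float(row["ppm"]) - random_coil_shift(seq, i, nucleus, ref))
    indices = np.asarray(indices, dtype=int)
    deltas = np.asarray(deltas, dtype=float)
    if window is not None:
        lo, hi = window
        sel = (indices >= lo) & (indices <= hi)
    else:
        sel = np.ones(len(indices), dtype=bool)
    mean = float(deltas[sel].mean()) if sel.any() else float("nan")
    return SCSProfile(
        indices=indices,
        delta=deltas,
        mean_scs=mean,
        helicity=helicity_percent(mean) if np.isfinite(mean) else float("nan"),
        nucleus=nucleus,
    )


def helicity_percent(mean_scs: float) -> float:
    """Percent helicity from a mean Cα SCS on the 3.2-ppm-per-100% scale.

    Non-positive means clamp to 0; the scale is capped at 100.
    """
    return min(100.0, max(0.0, mean_scs / FULL_HELIX_CA_PPM) * 100.0)


def helicity_percent_rounded(mean_scs: float, decimals: int = 1) -> float:
    """Helicity rounded half-up for comparison with printed tables."""
    return round_half_up(helicity_percent(mean_scs), decimals)
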