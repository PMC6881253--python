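"""Motif data model, coordinate assignment, classification, and logos.

PCNA-interacting short linear motifs (PIP-box, PIP-degron, APIM) are compared
on a shared coordinate ladder: the PIP-box glutamine is coordinate 1 and the
two aromatic anchors are coordinates 7 and 8.  Residues N-terminal of the
glutamine carry negative coordinates (there is no coordinate 0) and residues
C-terminal of coordinate 8 are labelled +1, +2, ...  The five-residue APIM
core [K/R]-[F/Y/W]-[L/I/V/A]-[L/I/V/A]-[K/R] occupies coordinates 6..+2,
reflecting how the two motif families overlay in crystal structures of their
PCNA complexes.

Internally coordinates are plain integers: ...,-2,-1,1..8,9,10,... where 9
renders as "+1".  :func:`coord_label` converts to the display form.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import (
    EmptyInputError,
    IncompleteMapError,
    InvalidSpanError,
    UndefinedColumnError,
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"

#: aliphatic hydrophobics accepted at coordinate 4 of a PIP motif
HYDROPHOBIC_4 = frozenset("LMIV")
#: aromatics accepted at coordinates 7/8; W included so APIM-aligned entries
#: are not misclassified (the consensus allows W at coordinate 7)
AROMATIC_78 = frozenset("YFW")
BASIC = frozenset("KR")
APIM_CORE_SETS = (
    frozenset("KR"),
    frozenset("FYW"),
    frozenset("LIVA"),
    frozenset("LIVA"),
    frozenset("KR"),
)

MOTIF_CLASSES = ("pip_box", "pip_degron", "apim", "unknown")
EVIDENCE_CODES = ("B", "B*", "C", "CY")

PIP_SPAN_LEN = 8
APIM_CORE_LEN = 5
APIM_CORE_START_COORD = 6  # core K/R aligns with PIP coordinate 6


def coord_label(coord: int) -> str:
    """Render an internal integer coordinate in the field's notation.

    >>> [coord_label(c) for c in (-1, 1, 8, 9, 10)]
    ['-1', '1', '8', '+1', '+2']
    """
    if coord == 0:
        raise ValueError("coordinate 0 does not exist")
    if coord > PIP_SPAN_LEN:
        return f"+{coord - PIP_SPAN_LEN}"
    return str(coord)


def _shift(coord: int, delta: int) -> int:
    """Move along the coordinate ladder skipping 0."""
    out = coord + delta
    if coord > 0 and out <= 0:
        out -= 1
    elif coord < 0 and out >= 0:
        out += 1
    return out


@dataclass(frozen=True)
class MotifEntry:
    """One curated motif: context sequence, span, class and annotations.

    ``motif_start``/``motif_end`` are 1-based inclusive indices into
    ``context_seq`` covering coordinates 1..8 (PIP classes) or the 5-residue
    APIM core.  ``context_seq`` may contain alignment gaps ``-``.
    """

    protein_id: str
    species: str
    context_seq: str
    motif_start: int
    motif_end: int
    declared_class: str = "unknown"
    evidence_code: str = "B"
    kd_molar: float | None = None
    measure_ph: float | None = None
    measure_temp_K: float | None = None
    disorder_call: str | None = None
    disorder_avg: float | None = None

    def __post_init__(self) -> None:
        seq = self.context_seq.upper()
        object.__setattr__(self, "context_seq", seq)
        if not seq or len(seq) > 50:
            raise ValueError(
                f"{self.protein_id}: context must be 1-50 residues (curation rule)"
            )
        bad = set(seq) - set(AMINO_ACIDS) - {GAP}
        if bad:
            raise ValueError(f"{self.protein_id}: non-canonical letters {sorted(bad)}")
        if not (1 <= self.motif_start <= self.motif_end <= len(seq)):
            raise ValueError(f"{self.protein_id}: motif span outside context")
        if self.declared_class not in MOTIF_CLASSES:
            raise ValueError(f"{self.protein_id}: unknown class {self.declared_class}")
        if self.evidence_code not in EVIDENCE_CODES:
            raise ValueError(f"{self.protein_id}: unknown evidence {self.evidence_code}")
        if self.kd_molar is not None and not self.kd_molar > 0:
            raise ValueError(f"{self.protein_id}: kd_molar must be positive")
        if self.disorder_call is not None and self.disorder_call not in ("D", "F"):
            raise ValueError(f"{self.protein_id}: disorder_call must be D or F")

    @property
    def motif_seq(self) -> str:
        return self.context_seq[self.motif_start - 1 : self.motif_end]


@dataclass(frozen=True)
class PositionMap:
    """Bijection between covered 1-based context indices and motif coordinates."""

    index_to_coord: Mapping[int, int]
    context_seq: str

    def __post_init__(self) -> None:
        coords = list(self.index_to_coord.values())
        if 0 in coords:
            raise ValueError("coordinate 0 is forbidden")
        idx = sorted(self.index_to_coord)
        ordered = [self.index_to_coord[i] for i in idx]
        if ordered != sorted(ordered):
            raise ValueError("coordinates must increase along the sequence")

    @property
    def coord_to_index(self) -> dict[int, int]:
        return {c: i for i, c in self.index_to_coord.items()}

    def residue_at(self, coord: int) -> str | None:
        """Residue letter at a motif coordinate, or None if uncovered."""
        i = self.coord_to_index.get(coord)
        return None if i is None else self.context_seq[i - 1]

    def coords(self) -> list[int]:
        return sorted(self.index_to_coord.values())


def assign_positions(entry: MotifEntry) -> PositionMap:
    """Map every context index of ``entry`` onto the motif coordinate ladder.

    PIP classes anchor span start at coordinate 1 and span end at 8 (the span
    must be 8 columns, gaps included); APIM anchors its 5-residue core at
    coordinates 6..+2.  Remaining context residues are extended contiguously
    in both directions, skipping coordinate 0.
    """
    span_len = entry.motif_end - entry.motif_start + 1
    if entry.declared_class == "apim":
        if span_len != APIM_CORE_LEN:
            raise InvalidSpanError(
                f"{entry.protein_id}: APIM core must span {APIM_CORE_LEN} residues, "
                f"got {span_len}"
            )
        start_coord = APIM_CORE_START_COORD
    else:
        if span_len != PIP_SPAN_LEN:
            raise InvalidSpanError(
                f"{entry.protein_id}: PIP motif must span {PIP_SPAN_LEN} columns, "
                f"got {span_len}"
            )
        start_coord = 1

    mapping: dict[int, int] = {}
    coord = start_coord
    for i in range(entry.motif_start, entry.motif_end + 1):
        mapping[i] = coord
        coord = _shift(coord, 1)
    coord = start_coord
    for i in range(entry.motif_start - 1, 0, -1):
        coord = _shift(coord, -1)
        mapping[i] = coord
    coord = mapping[entry.motif_end]
    for i in range(entry.motif_end + 1, len(entry.context_seq) + 1):
        coord = _shift(coord, 1)
        mapping[i] = coord
    return PositionMap(index_to_coord=mapping, context_seq=entry.context_seq)


@dataclass(frozen=True)
class MotifClassification:
    """Feature flags and the class they imply."""

    motif_class: str
    has_Q1: bool
    has_hydrophobic4: bool
    has_aromatic7: bool
    has_aromatic8: bool
    degron_basic_plus4: bool
    degron_TD56: bool
    apim_consensus: bool

    @property
    def n_aromatics_missing(self) -> int:
        return (not self.has_aromatic7) + (not self.has_aromatic8)


def classify_motif(
    entry: MotifEntry, pmap: PositionMap | None = None, *, strict: bool = False
) -> MotifClassification:
    """Derive feature flags from a position map and infer the motif class.

    With ``strict=True`` an entry whose map does not cover all of coordinates
    1..8 raises :class:`IncompleteMapError`; by default an uncovered
    coordinate simply fails the corresponding feature test, which is what the
    set-level census needs (an APIM at a chain start has no coordinate 1).
    """
    if pmap is None:
        pmap = assign_positions(entry)
    if strict:
        missing = [c for c in range(1, 9) if pmap.residue_at(c) is None]
        if missing:
            raise IncompleteMapError(
                f"{entry.protein_id}: coordinates {missing} absent from map"
            )

    res = pmap.residue_at
    has_Q1 = res(1) == "Q"
    has_h4 = res(4) in HYDROPHOBIC_4
    has_a7 = res(7) in AROMATIC_78
    has_a8 = res(8) in AROMATIC_78
    basic_p4 = res(12) in BASIC  # +4
    td56 = res(5) == "T" and res(6) == "D"
    apim = all(
        res(c) in allowed
        for c, allowed in zip(range(6, 11), APIM_CORE_SETS)
    )

    if apim and entry.declared_class == "apim":
        cls = "apim"
    elif has_Q1 and has_h4 and has_a7 and has_a8:
        cls = "pip_degron" if basic_p4 else "pip_box"
    elif apim:
        cls = "apim"
    else:
        cls = "unknown"
    return MotifClassification(
        motif_class=cls,
        has_Q1=has_Q1,
        has_hydrophobic4=has_h4,
        has_aromatic7=has_a7,
        has_aromatic8=has_a8,
        degron_basic_plus4=basic_p4,
        degron_TD56=td56,
        apim_consensus=apim,
    )


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round with ties away from zero, matching printed-table conventions."""
    factor = 10.0 ** decimals
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class MotifSetStatistics:
    """Degeneracy census over a motif set."""

    total: int
    counts: dict[str, int]
    fractions: dict[str, float]
    percents: dict[str, int] = field(default_factory=dict)


def motif_set_statistics(entries: Sequence[MotifEntry]) -> MotifSetStatistics:
    """Census of anchor-residue degeneracy across a motif set.

    Reports, over all entries, the fraction lacking Q at coordinate 1, lacking
    an aliphatic hydrophobic at 4, and lacking exactly one or both of the
    aromatics at 7/8.  Percentages are rounded half-up to integers for
    comparison with printed values.
    """
    if not entries:
        raise EmptyInputError("motif census requires at least one entry")
    counts = {"no_Q1": 0, "no_hydrophobic4": 0,
              "missing_one_aromatic": 0, "missing_both_aromatics": 0}
    for entry in entries:
        flags = classify_motif(entry)
        counts["no_Q1"] += not flags.has_Q1
        counts["no_hydrophobic4"] += not flags.has_hydrophobic4
        counts["missing_one_aromatic"] += flags.n_aromatics_missing == 1
        counts["missing_both_aromatics"] += flags.n_aromatics_missing == 2
    total = len(entries)
    fractions = {k: v / total for k, v in counts.items()}
    percents = {k: int(round_half_up(100.0 * f)) for k, f in fractions.items()}
    return MotifSetStatistics(total=total, counts=counts,
                              fractions=fractions, percents=percents)


@dataclass(frozen=True)
class LogoMatrix:
    """Per-coordinate amino-acid frequencies and information content (bits)."""

    coords: tuple[int, ...]
    frequencies: np.ndarray  # shape (n_coords, 20), rows sum to 1
    information: np.ndarray  # bits, in [0, log2(20)]
    counts: np.ndarray  # observations per coordinate

    def freq(self, coord: int, aa: str) -> float:
        return float(self.frequencies[self.coords.index(coord),
                                      AMINO_ACIDS.index(aa)])


def build_logo(entries: Sequence[MotifEntry],
               coords: Iterable[int]) -> LogoMatrix:
    """Amino-acid frequency/information matrix over motif coordinates.

    Gap characters are excluded from the counts.  Information content is
    ``log2(20) - H`` with H the Shannon entropy of the observed frequencies;
    no small-sample correction is applied (the set-level logo is descriptive).
    """
    coords = tuple(coords)
    if not entries:
        raise EmptyInputError("logo requires at least one entry")
    freq = np.zeros((len(coords), len(AMINO_ACIDS)))
    nobs = np.zeros(len(coords), dtype=int)
    for entry in entries:
        pmap = assign_positions(entry)
        for j, c in enumerate(coords):
            aa = pmap.residue_at(c)
            if aa is None or aa == GAP:
                continue
            freq[j, AMINO_ACIDS.index(aa)] += 1
            nobs[j] += 1
    if (nobs == 0).any():
        empty = [coord_label(coords[j]) for j in np.flatnonzero(nobs == 0)]
        raise UndefinedColumnError(f"no observations at coordinates {empty}")
    freq /= nobs[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freq > 0, freq * np.log2(freq), 0.0)
    info = np.log2(len(AMINO_ACIDS)) + plogp.sum(axis=1)
    info = np.clip(info, 0.0, np.log2(len(AMINO_ACIDS)))
    return LogoMatrix(coords=coords, frequencies=freq,
                      information=info, counts=nobs)
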