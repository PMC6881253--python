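"""pH-dependent peptide charges and net charge per residue (NCPR).

Net charge per residue over the motif plus a fixed-length flanking window is
the sequence feature that tracks PCNA binding affinity across ligands sharing
the same core motif: the clamp surface around the binding pocket is strongly
negative, so basic flanks pay off.  Two charge conventions are exposed:

``integer``
    K/R = +1, D/E = -1, His neutral, everything else 0 (the convention of
    the common NCPR tools; default, and the one used for figure parity).
``fractional``
    Henderson-Hasselbalch fractional charges at the stated pH,
    acids  -1 / (1 + 10**(pKa - pH)),  bases  +1 / (1 + 10**(pH - pKa)).

Free termini contribute an extra basic (N) / acidic (C) group unless the
peptide is capped (acetylated / amidated, as the synthesised peptides were).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import InvalidResidueError
from .motifs import AMINO_ACIDS

#: standard-biochemistry side-chain and terminal pKa values
DEFAULT_PKA: dict[str, float] = {
    "D": 3.65, "E": 4.25, "C": 8.3, "Y": 10.1,
    "H": 6.0, "K": 10.5, "R": 12.5,
    "n_term": 8.0, "c_term": 3.55,
}
ACIDIC = frozenset("DECY")
BASIC = frozenset("HKR")

#: printed p21-derived peptide set (all N-acetylated / C-amidated), with the
#: PIP motif QTSMTDFY span (1-based, inclusive) in each construct
P21_VARIANTS: dict[str, tuple[str, tuple[int, int]]] = {
    "p21_140_164": ("RKRRQTSMTDFYHSKRRLIFSKRKP", (5, 12)),
    "p21_140_157": ("RKRRQTSMTDFYHSKRRL", (5, 12)),
    "p21_143_157": ("RQTSMTDFYHSKRRL", (2, 9)),
    "S2": ("RKRRQTSMTDFYHSESSL", (5, 12)),
    "S1": ("SESSQTSMTDFYHSKRRL", (5, 12)),
    "D1.2": ("SESSQTSMTDFYHSESSL", (5, 12)),
}


@dataclass(frozen=True)
class PeptideConstruct:
    """A peptide at a stated pH with terminal-cap flags."""

    sequence: str
    ph: float
    n_cap: bool = True
    c_cap: bool = True

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise ValueError("sequence must be non-empty")
        bad = set(seq) - set(AMINO_ACIDS)
        if bad:
            raise InvalidResidueError(f"non-canonical letters {sorted(bad)}")
        if not 0 < self.ph < 14:
            raise ValueError("ph must lie in (0, 14)")


@dataclass(frozen=True)
class ChargeProfile:
    """Per-residue charges and NCPR over a window."""

    per_residue: np.ndarray
    net: float
    ncpr: float
    window_start: int  # 1-based, inclusive
    window_end: int
    flank_len: int
    left_truncated: bool
    right_truncated: bool


def residue_charge(
    aa: str,
    ph: float,
    pka_set: Mapping[str, float] | None = None,
    mode: str = "fractional",
) -> float:
    """Charge of a single residue side chain at ``ph``."""
    aa = aa.upper()
    if aa not in AMINO_ACIDS:
        raise InvalidResidueError(f"unknown residue {aa!r}")
    if mode == "integer":
        if aa in "KR":
            return 1.0
        if aa in "DE":
            return -1.0
        return 0.0
    if mode != "fractional":
        raise ValueError(f"unknown charge mode {mode!r}")
    pka = dict(DEFAULT_PKA if pka_set is None else pka_set)
    if aa in ACIDIC:
        return -1.0 / (1.0 + 10.0 ** (pka[aa] - ph))
    if aa in BASIC:
        return 1.0 / (1.0 + 10.0 ** (ph - pka[aa]))
    return 0.0


def _terminal_charges(
    ph: float, n_free: bool, c_free: bool,
    pka: Mapping[str, float], mode: str,
) -> float:
    q = 0.0
    if n_free:
        q += 1.0 if mode == "integer" else 1.0 / (1.0 + 10.0 ** (ph - pka["n_term"]))
    if c_free:
        q += -1.0 if mode == "integer" else -1.0 / (1.0 + 10.0 ** (pka["c_term"] - ph))
    return q


def net_charge(
    p: PeptideConstruct,
    mode: str = "integer",
    pka_set: Mapping[str, float] | None = None,
) -> float:
    """Net charge of the whole construct, terminal groups included when free."""
    pka = dict(DEFAULT_PKA if pka_set is None else pka_set)
    q = sum(residue_charge(a, p.ph, pka, mode) for a in p.sequence)
    return q + _terminal_charges(p.ph, not p.n_cap, not p.c_cap, pka, mode)


def ncpr_window(
    full_seq: str,
    motif_span: tuple[int, int],
    flank_len: int,
    ph: float,
    n_cap: bool = True,
    c_cap: bool = True,
    mode: str = "integer",
    pka_set: Mapping[str, float] | None = None,
) -> ChargeProfile:
    """NCPR over the motif plus up to ``flank_len`` residues on each side.

    The window is truncated at the chain termini (flags record which side);
    NCPR is normalised by the effective window length.  Terminal-group
    charges enter only when the window reaches an uncapped chain end.
    """
    start, end = motif_span
    seq = full_seq.upper()
    if not (1 <= start <= end <= len(seq)):
        raise ValueError("motif span outside sequence")
    if flank_len < 0:
        raise ValueError("flank_len must be >= 0")
    lo = max(1, start - flank_len)
    hi = min(len(seq), end + flank_len)
    pka = dict(DEFAULT_PKA if pka_set is None else pka_set)
    window = seq[lo - 1 : hi]
    charges = np.array([residue_charge(a, ph, pka, mode) for a in window])
    net = float(charges.sum())
    net += _terminal_charges(
        ph, n_free=(lo == 1 and not n_cap), c_free=(hi == len(seq) and not c_cap),
        pka=pka, mode=mode,
    )
    return ChargeProfile(
        per_residue=charges,
        net=net,
        ncpr=net / len(window),
        window_start=lo,
        window_end=hi,
        flank_len=flank_len,
        left_truncated=(start - flank_len) < 1,
        right_truncated=(end + flank_len) > len(seq),
    )


def ncpr_flank_profile(
    entries: Sequence[tuple[str, tuple[int, int], float]],
    flank_lens: Iterable[int] = range(1, 10),
    mode: str = "integer",
    pka_set: Mapping[str, float] | None = None,
) -> dict[int, float]:
    """Mean NCPR per flank length over entries with complete windows.

    For each flank length, entries whose chain is too short for the full
    window on either side are excluded from the average (they would dilute
    the per-length comparison with shorter effective windows).  A length with
    no complete entry maps to NaN rather than zero.
    """
    if not entries:
        raise ValueError("profile requires at least one entry")
    out: dict[int, float] = {}
    for fl in flank_lens:
        vals = []
        for seq, span, ph in entries:
            prof = ncpr_window(seq, span, fl, ph, mode=mode, pka_set=pka_set)
            if not (prof.left_truncated or prof.right_truncated):
                vals.append(prof.ncpr)
        out[fl] = float(np.mean(vals)) if vals else float("nan")
    return out
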