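"""Seeded generators for every input the pipeline consumes.

Each generator emulates one instrument or curation product with known ground
truth, so every fitting and regression stage has a recovery oracle:

* :func:`gen_sensorgram` / :func:`gen_steady_state` — single-cycle SPR time
  courses (five sequential two-fold injections, 90 s contact / 225 s
  dissociation) and equilibrium (c, Rss) series.
* :func:`gen_itc` — reverse-titration isotherms at the p21 design point
  (10 uM peptide in the cell, 40 uM trimer in the syringe, 19 x 2 uL).
* :func:`gen_shift_profile` — Cα shift tables for a peptide with a chosen
  fractional helicity over a chosen span (inverts the 3.2-ppm scale).
* :func:`gen_motif_set` — motif tables with a fixed p21-like core, flanks
  built to hit prescribed net charges exactly, and affinities drawn from
  ln KD = a + b * NCPR + Gaussian noise.

All noise is Gaussian; identical arguments and seed give bit-identical
output (``numpy.random.default_rng``).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .binding import (
    Injection,
    ITCExperiment,
    SPRSeries,
    itc_one_site_model,
    spr_kinetic_model,
    spr_steady_state_model,
)
from .charge import ncpr_window
from .nmr import ShiftTable, random_coil_shift, FULL_HELIX_CA_PPM

#: p21-like PIP motif used as the fixed core of generated motif sets
CORE_MOTIF = "QTSMTDFY"


def gen_sensorgram(
    kon: float = 1.7e6,
    koff: float = 0.14,
    rmax: float = 100.0,
    top_conc: float = 200e-9,
    n_injections: int = 5,
    contact_s: float = 90.0,
    dissoc_s: float = 225.0,
    tail_s: float = 300.0,
    dt: float = 1.0,
    noise_sigma: float = 0.0,
    seed: int | None = None,
) -> SPRSeries:
    """Noisy single-cycle 1:1 sensorgram with a two-fold dilution ladder.

    Injections run lowest concentration first, ``noise_sigma`` is absolute
    (RU).  Defaults are the p21-like design: kon 1.7e6 /(M s), koff 0.14 /s,
    top concentration 200 nM.
    """
    concs = top_conc / 2.0 ** np.arange(n_injections - 1, -1, -1)
    schedule = []
    t0 = 0.0
    for c in concs:
        schedule.append(Injection(t0, t0 + contact_s, float(c)))
        t0 += contact_s + dissoc_s
    t_end = schedule[-1].t_end + tail_s
    t = np.arange(0.0, t_end, dt)
    r = spr_kinetic_model(t, tuple(schedule), kon, koff, rmax)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        r = r + rng.normal(0.0, noise_sigma, size=r.shape)
    return SPRSeries(time=t, response=r, schedule=tuple(schedule), rmax0=rmax)


def gen_steady_state(
    kd: float = 3.0e-6,
    rmax: float = 100.0,
    n: float = 1.0,
    concs: np.ndarray | None = None,
    rel_noise: float = 0.0,
    seed: int | None = None,
) -> SPRSeries:
    """Equilibrium (c, Rss) series from the steady-state model.

    Default concentration ladder: eight two-fold steps spanning KD/8..16*KD.
    ``rel_noise`` scales Gaussian noise by the plateau response Rmax/n.
    """
    if concs is None:
        concs = kd * 2.0 ** np.arange(-3.0, 5.0)
    concs = np.asarray(concs, dtype=float)
    r = spr_steady_state_model(concs, 1.0 / kd, rmax, n)
    if rel_noise > 0:
        rng = np.random.default_rng(seed)
        r = r + rng.normal(0.0, rel_noise * rmax / n, size=r.shape)
    return SPRSeries(conc=concs, response=np.asarray(r), rmax0=rmax)


def gen_itc(
    n: float = 3.0,
    kd: float = 67e-9,
    dh: float = -230e3,
    cell_conc: float = 10e-6,
    syringe_conc: float = 40e-6,
    v0: float = 200e-6,
    n_injections: int = 19,
    inj_vol: float = 2e-6,
    q_dil: float = 0.0,
    rel_noise: float = 0.0,
    seed: int | None = None,
    temp_K: float = 298.15,
) -> ITCExperiment:
    """Reverse-titration isotherm at the p21 design point.

    Defaults follow the measured system: n = 3 peptides per trimer,
    KD = 67 nM, dH = -230 kJ/mol (per mole of bound peptide), 10 uM peptide
    in a 200 uL cell titrated with 40 uM trimer in 19 x 2 uL injections at
    25 C.  ``rel_noise`` scales Gaussian noise by the largest |heat|.
    """
    volumes = np.full(n_injections, inj_vol)
    exp = ITCExperiment(
        v0=v0, cell_conc=cell_conc, syringe_conc=syringe_conc,
        inj_volumes=volumes, heats=np.zeros(n_injections), temp_K=temp_K,
    )
    heats = itc_one_site_model(exp, n, 1.0 / kd, dh, q_dil)
    if rel_noise > 0:
        rng = np.random.default_rng(seed)
        heats = heats + rng.normal(
            0.0, rel_noise * np.abs(heats).max(), size=heats.shape
        )
    exp.heats = heats
    return exp


def gen_shift_profile(
    seq: str,
    helicity_fraction: float,
    span: tuple[int, int] | None = None,
    noise_sigma: float = 0.0,
    seed: int | None = None,
) -> ShiftTable:
    """Cα shift table for ``seq`` with helical sampling over ``span``.

    Residues inside ``span`` (1-based inclusive; default whole sequence) get
    delta_obs = delta_coil + 3.2 * helicity_fraction (+ noise); residues
    outside stay at coil.
    """
    if not 0.0 <= helicity_fraction <= 1.0:
        raise ValueError("helicity_fraction must lie in [0, 1]")
    seq = seq.upper()
    lo, hi = span if span is not None else (1, len(seq))
    rng = np.random.default_rng(seed)
    rows = []
    for i, aa in enumerate(seq, start=1):
        ppm = random_coil_shift(seq, i, "CA")
        if lo <= i <= hi:
            ppm += FULL_HELIX_CA_PPM * helicity_fraction
        if noise_sigma > 0:
            ppm += rng.normal(0.0, noise_sigma)
        rows.append({"index": i, "aa": aa, "nucleus": "CA",
                     "ppm": ppm, "assigned": True})
    return ShiftTable(pd.DataFrame(rows))


def _flank_with_charge(rng: np.random.Generator, length: int, charge: int) -> str:
    """Random S/G flank carrying exactly ``charge`` (integer convention)."""
    if abs(charge) > length:
        raise ValueError("flank too short for requested charge")
    flank = list(rng.choice(list("SG"), size=length))
    pos = rng.choice(length, size=abs(charge), replace=False)
    letters = "KR" if charge > 0 else "ED"
    for p in pos:
        flank[p] = str(rng.choice(list(letters)))
    return "".join(flank)


def gen_motif_set(
    n_entries: int = 50,
    a: float = -12.0,
    b: float = -20.0,
    sigma: float = 0.0,
    charge_range: tuple[int, int] = (-6, 6),
    flank_len: int = 7,
    ph: float = 7.4,
    seed: int | None = None,
) -> pd.DataFrame:
    """Motif table with a fixed core and a prescribed charge-affinity law.

    Every entry carries the p21-like core QTSMTDFY with random flanks of
    ``flank_len`` residues on each side whose integer net charge is drawn
    uniformly from ``charge_range`` (hit exactly by construction).  Then
    ln KD = a + b * NCPR + N(0, sigma), NCPR in integer mode over the
    motif +/- flank window.  Columns: protein_id, context_seq, motif_start,
    motif_end, ncpr, kd_molar, ln_kd.
    """
    if n_entries < 3:
        raise ValueError("need >= 3 entries")
    rng = np.random.default_rng(seed)
    lo, hi = charge_range
    rows = []
    for k in range(n_entries):
        left = _flank_with_charge(rng, flank_len, int(rng.integers(lo, hi + 1)))
        right = _flank_with_charge(rng, flank_len, int(rng.integers(lo, hi + 1)))
        seq = left + CORE_MOTIF + right
        span = (flank_len + 1, flank_len + len(CORE_MOTIF))
        ncpr = ncpr_window(seq, span, flank_len, ph, mode="integer").ncpr
        ln_kd = a + b * ncpr + (rng.normal(0.0, sigma) if sigma > 0 else 0.0)
        rows.append({
            "protein_id": f"synthetic_{k:03d}",
            "species": "synthetic",
            "context_seq": seq,
            "motif_start": span[0],
            "motif_end": span[1],
            "ncpr": ncpr,
            "kd_molar": float(np.exp(ln_kd)),
            "ln_kd": float(ln_kd),
        })
    return pd.DataFrame(rows)
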