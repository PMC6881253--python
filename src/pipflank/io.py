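"""Readers and writers for the pipeline's tab-separated text formats.

All tables are plain tab-separated text with a header row; empty cells mean
"absent", never zero.  Sequences travel as FASTA (via Biopython) or inline
table fields.  Reports are deterministic: stable row ordering and fixed
float formatting.
"""

from __future__ import annotations

import logging
import warnings
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .binding import AffinityRecord, ITCExperiment, SPRSeries, Injection
from .disorder import DisorderTrack
from .errors import TableFormatError
from .motifs import AMINO_ACIDS, MotifEntry
from .nmr import ShiftTable

log = logging.getLogger("pipflank")

MOTIF_COLUMNS = (
    "protein_id", "species", "context_seq", "motif_start", "motif_end",
    "declared_class", "evidence_code", "kd_molar", "measure_ph",
    "measure_temp_K", "disorder_call", "disorder_avg",
)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Named amino-acid sequences from a FASTA file, order preserved.

    Lowercase letters are uppercased with a warning; non-amino-acid
    alphabets are rejected.
    """
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if seq != seq.upper():
            warnings.warn(f"{rec.id}: lowercase letters uppercased")
            seq = seq.upper()
        bad = set(seq) - set(AMINO_ACIDS) - {"-"}
        if bad:
            raise TableFormatError(
                f"{rec.id}: non-amino-acid letters {sorted(bad)}"
            )
        out[rec.id] = seq
    if not out:
        raise TableFormatError(f"{path}: no FASTA records found")
    return out


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and np.isnan(value)) \
            or value == "":
        return None
    return float(value)


def read_motif_table(path: str | Path) -> list[MotifEntry]:
    """Typed motif entries from the tab-separated motif-table contract."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(MOTIF_COLUMNS) - set(df.columns)
    if missing:
        raise TableFormatError(f"{path}: missing columns {sorted(missing)}")
    entries = []
    for pos, row in enumerate(df.itertuples(index=False), start=2):
        try:
            entries.append(MotifEntry(
                protein_id=row.protein_id,
                species=row.species,
                context_seq=row.context_seq,
                motif_start=int(row.motif_start),
                motif_end=int(row.motif_end),
                declared_class=row.declared_class or "unknown",
                evidence_code=row.evidence_code or "B",
                kd_molar=_opt_float(row.kd_molar),
                measure_ph=_opt_float(row.measure_ph),
                measure_temp_K=_opt_float(row.measure_temp_K),
                disorder_call=row.disorder_call or None,
                disorder_avg=_opt_float(row.disorder_avg),
            ))
        except (ValueError, TypeError) as exc:
            raise TableFormatError(f"{path} line {pos}: {exc}") from exc
    return entries


def write_motif_table(entries: Sequence[MotifEntry], path: str | Path) -> None:
    rows = []
    for e in entries:
        rows.append({
            "protein_id": e.protein_id, "species": e.species,
            "context_seq": e.context_seq, "motif_start": e.motif_start,
            "motif_end": e.motif_end, "declared_class": e.declared_class,
            "evidence_code": e.evidence_code,
            "kd_molar": "" if e.kd_molar is None else repr(e.kd_molar),
            "measure_ph": "" if e.measure_ph is None else repr(e.measure_ph),
            "measure_temp_K": "" if e.measure_temp_K is None
            else repr(e.measure_temp_K),
            "disorder_call": e.disorder_call or "",
            "disorder_avg": "" if e.disorder_avg is None
            else repr(e.disorder_avg),
        })
    pd.DataFrame(rows, columns=MOTIF_COLUMNS).to_csv(path, sep="\t", index=False)


def load_reference_motif_table() -> list[MotifEntry]:
    """The packaged synthetic stand-in for the curated 83-motif table.

    The originally curated table is not available in machine-readable form;
    this synthetic reconstruction contains the motifs whose sequences are
    public plus filler rows chosen so the set reproduces the published
    aggregate degeneracy statistics.
    """
    ref = resources.files("pipflank.data") / "table2_synthetic.tsv"
    with resources.as_file(ref) as path:
        return read_motif_table(path)


def read_shift_table(path: str | Path) -> ShiftTable:
    """Observed-shift table: index, aa, nucleus, ppm, assigned."""
    df = pd.read_csv(path, sep="\t")
    missing = set(ShiftTable.REQUIRED) - set(df.columns)
    if missing:
        raise TableFormatError(f"{path}: missing columns {sorted(missing)}")
    df["assigned"] = df["assigned"].astype(bool)
    return ShiftTable(df)


def write_shift_table(table: ShiftTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index=False)


def read_spr_steady(path: str | Path) -> SPRSeries:
    """Two-column steady-state series: conc_M, Rss_RU."""
    df = pd.read_csv(path, sep="\t")
    if not {"conc_M", "Rss_RU"} <= set(df.columns):
        raise TableFormatError(f"{path}: need columns conc_M, Rss_RU")
    return SPRSeries(conc=df["conc_M"].to_numpy(),
                     response=df["Rss_RU"].to_numpy())


def read_spr_kinetic(path: str | Path, schedule_path: str | Path) -> SPRSeries:
    """Time course (t_s, R_RU) plus a sidecar schedule (t_start, t_end, conc_M)."""
    df = pd.read_csv(path, sep="\t")
    if not {"t_s", "R_RU"} <= set(df.columns):
        raise TableFormatError(f"{path}: need columns t_s, R_RU")
    sched = pd.read_csv(schedule_path, sep="\t")
    if not {"t_start", "t_end", "conc_M"} <= set(sched.columns):
        raise TableFormatError(
            f"{schedule_path}: need columns t_start, t_end, conc_M")
    injections = tuple(
        Injection(float(r.t_start), float(r.t_end), float(r.conc_M))
        for r in sched.itertuples(index=False)
    )
    return SPRSeries(time=df["t_s"].to_numpy(),
                     response=df["R_RU"].to_numpy(), schedule=injections)


def write_spr_series(series: SPRSeries, path: str | Path,
                     schedule_path: str | Path | None = None) -> None:
    if series.is_kinetic:
        pd.DataFrame({"t_s": series.time, "R_RU": series.response}).to_csv(
            path, sep="\t", index=False)
        if schedule_path is not None:
            pd.DataFrame(
                [{"t_start": i.t_start, "t_end": i.t_end, "conc_M": i.conc}
                 for i in series.schedule]
            ).to_csv(schedule_path, sep="\t", index=False)
    else:
        pd.DataFrame({"conc_M": series.conc,
                      "Rss_RU": series.response}).to_csv(
            path, sep="\t", index=False)


def read_itc(path: str | Path) -> ITCExperiment:
    """Per-injection ITC table with '# key value' header lines.

    Header keys: v0_L, cell_M, syringe_M, T_K; columns: volume_L, heat_J.
    """
    header: dict[str, float] = {}
    body: list[str] = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            key, value = line[1:].split(None, 1)
            header[key] = float(value)
        elif line.strip():
            body.append(line)
    for key in ("v0_L", "cell_M", "syringe_M", "T_K"):
        if key not in header:
            raise TableFormatError(f"{path}: missing header field {key}")
    df = pd.read_csv(pd.io.common.StringIO("\n".join(body)), sep="\t",
                     float_precision="round_trip")
    if not {"volume_L", "heat_J"} <= set(df.columns):
        raise TableFormatError(f"{path}: need columns volume_L, heat_J")
    return ITCExperiment(
        v0=header["v0_L"], cell_conc=header["cell_M"],
        syringe_conc=header["syringe_M"],
        inj_volumes=df["volume_L"].to_numpy(),
        heats=df["heat_J"].to_numpy(), temp_K=header["T_K"],
    )


def write_itc(exp: ITCExperiment, path: str | Path) -> None:
    lines = [
        f"# v0_L {exp.v0!r}", f"# cell_M {exp.cell_conc!r}",
        f"# syringe_M {exp.syringe_conc!r}", f"# T_K {exp.temp_K!r}",
        "volume_L\theat_J",
    ]
    for v, h in zip(exp.inj_volumes, exp.heats):
        lines.append(f"{float(v)!r}\t{float(h)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_disorder_tracks(path: str | Path) -> dict[str, DisorderTrack]:
    """Long-format tracks: protein_id, residue_index, predictor, score."""
    df = pd.read_csv(path, sep="\t")
    need = {"protein_id", "residue_index", "predictor", "score"}
    if not need <= set(df.columns):
        raise TableFormatError(f"{path}: need columns {sorted(need)}")
    out: dict[str, DisorderTrack] = {}
    for pid, grp in df.groupby("protein_id", sort=True):
        scores = {}
        for pred, sub in grp.groupby("predictor", sort=True):
            sub = sub.sort_values("residue_index")
            idx = sub["residue_index"].to_numpy(int)
            if not np.array_equal(idx, np.arange(1, len(idx) + 1)):
                raise TableFormatError(
                    f"{pid}/{pred}: residue indices must run 1..N with no gaps")
            scores[pred] = sub["score"].to_numpy(float)
        out[str(pid)] = DisorderTrack(protein_id=str(pid), scores=scores)
    return out


def write_affinity_report(records: Iterable[AffinityRecord],
                          path: str | Path) -> None:
    """Deterministic tab-separated affinity report (sorted by ligand, method)."""
    rows = []
    for r in sorted(records, key=lambda r: (r.ligand_id, r.method)):
        rows.append({
            "ligand_id": r.ligand_id, "method": r.method,
            "kd_M": f"{r.kd:.6e}",
            "kd_err_M": "" if r.kd_err is None else f"{r.kd_err:.6e}",
            "ka_per_M": f"{r.ka:.6e}",
            "kon_per_M_s": "" if r.kon is None else f"{r.kon:.6e}",
            "koff_per_s": "" if r.koff is None else f"{r.koff:.6e}",
            "dH_J_mol": "" if r.dH is None else f"{r.dH:.6e}",
            "dG_J_mol": "" if r.dG is None else f"{r.dG:.6e}",
            "minus_TdS_J_mol": "" if r.minus_TdS is None
            else f"{r.minus_TdS:.6e}",
            "n": "" if r.n is None else f"{r.n:.4f}",
            "T_K": f"{r.temp_K:.2f}",
            "ph": "" if r.ph is None else f"{r.ph:.2f}",
            "warnings": ";".join(r.warnings),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
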