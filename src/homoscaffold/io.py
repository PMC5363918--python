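"""Readers and writers: FASTA, BLAST tabular (outfmt 6), pipeline TSV reports."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .model import HSP, SequenceRecord

__all__ = [
    "AlignmentTable",
    "read_fasta",
    "write_fasta",
    "parse_blast_tab",
    "write_report",
    "REPORT_COLUMNS",
    "STATUSES",
]

#: standard 12-column BLAST tabular layout (``-outfmt 6``)
BLAST_STD_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()

STATUSES = ("unaligned", "filtered_out", "chimeric", "redundant", "component", "singleton_pp")

REPORT_COLUMNS = (
    "polypeptide_id",
    "status",
    "best_hit_id",
    "pp_id",
    "q_interval",
    "s_interval",
    "chimera_flag",
)


@dataclass
class AlignmentTable:
    """Parsed BLAST tabular file: HSP rows plus optional qlen/slen columns."""

    rows: list[HSP]
    has_lengths: bool = False
    has_btop: bool = False
    query_lengths: dict[str, int] = field(default_factory=dict)
    subject_lengths: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.rows)

    def attach_lengths(
        self,
        queries: Sequence[SequenceRecord] | None = None,
        subjects: Sequence[SequenceRecord] | None = None,
    ) -> None:
        """Supply sequence lengths from FASTA records.

        Lengths already present (extended BLAST columns) must agree with the
        FASTA; a conflict is an error rather than a silent preference.
        """
        for recs, table in ((queries, self.query_lengths), (subjects, self.subject_lengths)):
            if recs is None:
                continue
            for r in recs:
                if r.id in table and table[r.id] != r.length:
                    raise ValueError(
                        f"length conflict for {r.id}: alignment table says "
                        f"{table[r.id]}, FASTA says {r.length}"
                    )
                table[r.id] = r.length


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read protein FASTA; joins wrapped lines, strips ``*`` stops with a warning."""
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    stripped = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if "*" in seq:
            stripped += 1
            seq = seq.replace("*", "")
        records.append(SequenceRecord(id=rec.id, sequence=seq))
    if stripped:
        warnings.warn(f"stripped '*' stop symbols from {stripped} sequence(s) in {path}")
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    """Write FASTA wrapped at ``width`` columns; X is a legal residue."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def parse_blast_tab(path: str | Path, column_spec: str = "auto") -> AlignmentTable:
    """Parse BLAST tabular output (``-outfmt 6`` dialects).

    ``column_spec`` is one of:

    - ``"std"`` — the default 12 columns;
    - ``"std qlen slen"`` — plus query/subject full lengths;
    - ``"std qlen slen btop"`` — plus the btop traceback string;
    - ``"auto"`` — infer from the field count (12, 14 or 15).

    Comment lines starting with ``#`` are skipped.
    """
    expected = {"std": 12, "std qlen slen": 14, "std qlen slen btop": 15}
    if column_spec not in expected and column_spec != "auto":
        raise ValueError(f"unknown column_spec {column_spec!r}")
    rows: list[HSP] = []
    qlens: dict[str, int] = {}
    slens: dict[str, int] = {}
    ncols: int | None = expected.get(column_spec)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if ncols is None:
                if len(fields) not in (12, 14, 15):
                    raise ValueError(
                        f"expected 12, 14 or 15 columns at line {lineno}, got {len(fields)}"
                    )
                ncols = len(fields)
            if len(fields) != ncols:
                raise ValueError(f"expected {ncols} columns at line {lineno}, got {len(fields)}")
            try:
                hsp = HSP(
                    query_id=fields[0],
                    subject_id=fields[1],
                    identity_pct=float(fields[2]),
                    align_len=int(fields[3]),
                    mismatch=int(fields[4]),
                    gapopen=int(fields[5]),
                    qstart=int(fields[6]),
                    qend=int(fields[7]),
                    sstart=int(fields[8]),
                    send=int(fields[9]),
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                    btop=fields[14] if ncols == 15 else None,
                )
            except ValueError as exc:
                raise ValueError(f"bad alignment row at line {lineno} of {path}: {exc}") from exc
            if ncols >= 14:
                for d, key, val in ((qlens, fields[0], fields[12]), (slens, fields[1], fields[13])):
                    try:
                        length = int(val)
                    except ValueError as exc:
                        raise ValueError(f"non-numeric length at line {lineno}: {val!r}") from exc
                    if d.get(key, length) != length:
                        raise ValueError(f"inconsistent length for {key} at line {lineno}")
                    d[key] = length
            rows.append(hsp)
    return AlignmentTable(
        rows=rows,
        has_lengths=(ncols or 12) >= 14,
        has_btop=(ncols or 12) == 15,
        query_lengths=qlens,
        subject_lengths=slens,
    )


def write_blast_tab(rows: Iterable[HSP], path: str | Path,
                    query_lengths: dict[str, int] | None = None,
                    subject_lengths: dict[str, int] | None = None) -> None:
    """Write HSPs in BLAST tabular form (extended with qlen/slen when given)."""
    extended = query_lengths is not None and subject_lengths is not None
    with open(path, "w") as fh:
        for h in rows:
            fields = [
                h.query_id, h.subject_id, f"{h.identity_pct:.3f}", str(h.align_len),
                str(h.mismatch), str(h.gapopen), str(h.qstart), str(h.qend),
                str(h.sstart), str(h.send), f"{h.evalue:.2g}", f"{h.bitscore:.1f}",
            ]
            if extended:
                fields += [str(query_lengths[h.query_id]), str(subject_lengths[h.subject_id])]
            fh.write("\t".join(fields) + "\n")


def _fmt_interval(iv: tuple[int, int] | None) -> str:
    return f"{iv[0]}-{iv[1]}" if iv else "."


def write_report(assignments: pd.DataFrame | list[dict], path: str | Path) -> pd.DataFrame:
    """Write the per-polypeptide status report as TSV.

    One row per input polypeptide with columns ``polypeptide_id, status,
    best_hit_id, pp_id, q_interval, s_interval, chimera_flag``.  Statuses
    partition the polypeptides; component rows of one protein product are
    ordered by the start of their reference interval.
    """
    df = pd.DataFrame(assignments, columns=list(REPORT_COLUMNS))
    if df["polypeptide_id"].duplicated().any():
        dup = df.loc[df["polypeptide_id"].duplicated(), "polypeptide_id"].iloc[0]
        raise ValueError(f"internal consistency error: {dup!r} assigned more than one status")
    bad = set(df["status"]) - set(STATUSES)
    if bad:
        raise ValueError(f"unknown status values: {sorted(bad)}")
    def sort_start(iv: str) -> int:
        return int(iv.split("-")[0]) if iv not in (".", "", None) else -1
    df = df.assign(_s=df["s_interval"].map(sort_start)).sort_values(
        ["pp_id", "_s", "polypeptide_id"], kind="stable"
    ).drop(columns="_s")
    df.to_csv(path, sep="\t", index=False)
    return df
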