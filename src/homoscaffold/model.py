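"""Core alignment model: HSPs, colinear chaining, coverage, coordinate maps.

Protein-vs-protein local alignments arrive as high-scoring segment pairs
(HSPs).  A single query/subject pair may be split over several HSPs; the
pipeline treats the pair as one *chained alignment*: the colinear subset of
HSPs (consistent left-to-right order on both sequences, pairwise overlap of
at most one residue on either axis) that maximises the number of aligned
query residues.

All coordinates are 1-based and inclusive, matching BLAST tabular output.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "SequenceRecord",
    "HSP",
    "ChainedAlignment",
    "FilterParams",
    "chain_hsps",
    "coverage",
    "map_ref_to_query",
    "nearest_mappable_left",
    "build_chains",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SequenceRecord:
    """One protein sequence (20-letter alphabet plus X for scaffold gaps)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class HSP:
    """One high-scoring segment pair between a query and a subject protein."""

    query_id: str
    subject_id: str
    identity_pct: float
    align_len: int
    mismatch: int = 0
    gapopen: int = 0
    qstart: int = 0
    qend: int = 0
    sstart: int = 0
    send: int = 0
    evalue: float = 0.0
    bitscore: float = 0.0
    btop: str | None = None

    def __post_init__(self) -> None:
        if self.qstart > self.qend:
            raise ValueError(
                f"HSP {self.query_id}/{self.subject_id}: qstart {self.qstart} > qend {self.qend}"
            )
        if self.sstart > self.send:
            raise ValueError(
                f"HSP {self.query_id}/{self.subject_id}: sstart {self.sstart} > send {self.send}"
            )
        if self.qstart < 1 or self.sstart < 1:
            raise ValueError("coordinates are 1-based; must be >= 1")
        if self.align_len < 1:
            raise ValueError("align_len must be >= 1")
        if not 0.0 <= self.identity_pct <= 100.0:
            raise ValueError(f"identity_pct {self.identity_pct} outside [0, 100]")

    @property
    def query_span(self) -> int:
        return self.qend - self.qstart + 1

    @property
    def subject_span(self) -> int:
        return self.send - self.sstart + 1


@dataclass
class ChainedAlignment:
    """Colinear set of HSPs for one (query, subject) pair.

    ``query_length``/``subject_length`` may be attached after construction
    (e.g. from FASTA); coverage properties require them.
    """

    query_id: str
    subject_id: str
    hsps: list[HSP]
    query_length: int | None = None
    subject_length: int | None = None

    def __post_init__(self) -> None:
        self.hsps = sorted(self.hsps, key=lambda h: (h.qstart, h.qend))
        for h in self.hsps:
            if h.query_id != self.query_id or h.subject_id != self.subject_id:
                raise ValueError("all HSPs of a chain must share query and subject ids")

    @property
    def q_interval(self) -> tuple[int, int]:
        return (min(h.qstart for h in self.hsps), max(h.qend for h in self.hsps))

    @property
    def s_interval(self) -> tuple[int, int]:
        return (min(h.sstart for h in self.hsps), max(h.send for h in self.hsps))

    @property
    def identity_pct(self) -> float:
        """Alignment-length weighted mean identity over member HSPs."""
        total = sum(h.align_len for h in self.hsps)
        return sum(h.identity_pct * h.align_len for h in self.hsps) / total

    @property
    def bitscore(self) -> float:
        return sum(h.bitscore for h in self.hsps)

    def query_positions(self) -> set[int]:
        pos: set[int] = set()
        for h in self.hsps:
            pos.update(range(h.qstart, h.qend + 1))
        return pos

    def subject_positions(self) -> set[int]:
        pos: set[int] = set()
        for h in self.hsps:
            pos.update(range(h.sstart, h.send + 1))
        return pos

    @property
    def query_coverage(self) -> float:
        if self.query_length is None:
            raise ValueError(f"query length unknown for {self.query_id}")
        return coverage(self, self.query_length, self.subject_length or max(self.s_interval))[0]

    @property
    def subject_coverage(self) -> float:
        if self.subject_length is None:
            raise ValueError(f"subject length unknown for {self.subject_id}")
        return coverage(self, self.query_length or max(self.q_interval), self.subject_length)[1]


@dataclass(frozen=True)
class FilterParams:
    """Identity/coverage threshold triple for best-hit retention.

    An alignment is retained when its identity is at least ``min_identity``
    and the query (polypeptide) coverage clears a branch-dependent bound: at
    least ``min_qcov_high_ref`` when the reference protein is covered at or
    above ``ref_cov_boundary``, otherwise at least ``min_qcov_low_ref``.
    The conventional notation 80/60/70 encodes
    identity / qcov-at-high-ref-cov / qcov-at-low-ref-cov (the latter two in
    percent).
    """

    min_identity: float = 80.0
    min_qcov_high_ref: float = 0.60
    min_qcov_low_ref: float = 0.70
    ref_cov_boundary: float = 0.40

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_identity <= 100.0:
            raise ValueError("min_identity outside [0, 100]")
        for name in ("min_qcov_high_ref", "min_qcov_low_ref", "ref_cov_boundary"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} outside [0, 1]")

    @classmethod
    def from_triple(cls, triple: str) -> "FilterParams":
        """Parse the ``identity/cov_high/cov_low`` percent notation, e.g. ``80/60/70``."""
        parts = triple.strip().split("/")
        if len(parts) != 3:
            raise ValueError(f"expected identity/cov_high/cov_low, got {triple!r}")
        ident, high, low = (float(p) for p in parts)
        return cls(min_identity=ident, min_qcov_high_ref=high / 100.0, min_qcov_low_ref=low / 100.0)

    @property
    def triple(self) -> str:
        return (
            f"{self.min_identity:g}/{self.min_qcov_high_ref * 100:g}/"
            f"{self.min_qcov_low_ref * 100:g}"
        )


def _compatible(a: HSP, b: HSP) -> bool:
    # a may precede b in a chain: b starts at/after a's end on both axes,
    # sharing at most one residue per axis.
    return a.qend <= b.qstart and a.send <= b.sstart


def chain_hsps(hsps: Sequence[HSP]) -> ChainedAlignment:
    """Select the colinear HSP subset maximising aligned query residues.

    Colinear means a consistent ordering on query and subject with at most a
    one-residue overlap between members on either axis.  Ties are broken by
    higher total bitscore, then by fewer HSPs.  Dynamic program over HSPs
    sorted by query start; overlap with the immediate predecessor (at most
    one residue) is discounted from the covered-residue total.
    """
    if not hsps:
        raise ValueError("no HSPs")
    first = hsps[0]
    for h in hsps:
        if h.query_id != first.query_id or h.subject_id != first.subject_id:
            raise ValueError("chain_hsps requires a single query/subject pair")

    order = sorted(range(len(hsps)), key=lambda i: (hsps[i].qstart, hsps[i].qend, hsps[i].sstart, hsps[i].send, i))
    items = [hsps[i] for i in order]
    n = len(items)
    # dp[i]: best (covered, bitscore, -count) for a chain ending in items[i]
    dp: list[tuple[int, float, int]] = [(h.query_span, h.bitscore, -1) for h in items]
    parent = [-1] * n
    for j in range(n):
        hj = items[j]
        for i in range(j):
            hi = items[i]
            if not _compatible(hi, hj):
                continue
            gain = hj.qend - max(hi.qend, hj.qstart - 1)
            cand = (dp[i][0] + gain, dp[i][1] + hj.bitscore, dp[i][2] - 1)
            if cand > dp[j]:
                dp[j] = cand
                parent[j] = i
    best = max(range(n), key=lambda j: dp[j])
    chain: list[HSP] = []
    j = best
    while j != -1:
        chain.append(items[j])
        j = parent[j]
    chain.reverse()
    return ChainedAlignment(first.query_id, first.subject_id, chain)


def coverage(chain: ChainedAlignment, query_len: int, subject_len: int) -> tuple[float, float]:
    """Query and subject coverage as |union of aligned positions| / length."""
    if query_len <= 0 or subject_len <= 0:
        raise ValueError("sequence lengths must be positive")
    qpos = chain.query_positions()
    spos = chain.subject_positions()
    if max(qpos) > query_len:
        raise ValueError(
            f"coordinate exceeds length: query {chain.query_id} position {max(qpos)} > {query_len}"
        )
    if max(spos) > subject_len:
        raise ValueError(
            f"coordinate exceeds length: subject {chain.subject_id} position {max(spos)} > {subject_len}"
        )
    return len(qpos) / query_len, len(spos) / subject_len


_BTOP_TOKEN = re.compile(r"(\d+)|([A-Z*-][A-Z*-])")


def _walk_btop(hsp: HSP, ref_pos: int) -> int | None:
    """Exact query position aligned to ``ref_pos`` from the btop traceback.

    Returns the query position of the last query residue consumed at or
    before the column aligned to ``ref_pos`` (so a subject residue sitting in
    a query-gap column maps to the nearest query residue on its left).
    """
    qpos = hsp.qstart - 1  # last consumed query position
    spos = hsp.sstart - 1
    for m in _BTOP_TOKEN.finditer(hsp.btop or ""):
        if m.group(1):
            k = int(m.group(1))
            if spos + k >= ref_pos:
                return qpos + (ref_pos - spos)
            qpos += k
            spos += k
        else:
            qc, sc = m.group(2)
            if qc != "-":
                qpos += 1
            if sc != "-":
                spos += 1
            if spos >= ref_pos:
                return qpos if qpos >= hsp.qstart else None
    raise ValueError(f"btop string of {hsp.query_id}/{hsp.subject_id} ends before subject {ref_pos}")


def map_ref_to_query(chain: ChainedAlignment, ref_pos: int) -> int | None:
    """Map a reference (subject) position to the aligned query position.

    Uses the btop traceback when present, otherwise linear interpolation
    within the covering HSP.  Returns ``None`` when ``ref_pos`` falls in the
    gap between two HSPs of the chain.
    """
    lo, hi = chain.s_interval
    if not lo <= ref_pos <= hi:
        raise ValueError(f"ref position {ref_pos} outside subject interval [{lo}, {hi}]")
    for h in sorted(chain.hsps, key=lambda h: h.sstart):
        if h.sstart <= ref_pos <= h.send:
            if h.btop:
                return _walk_btop(h, ref_pos)
            if h.send == h.sstart:
                return h.qstart
            frac = (ref_pos - h.sstart) * (h.qend - h.qstart) / (h.send - h.sstart)
            return h.qstart + int(frac + 0.5)
    return None


def nearest_mappable_left(chain: ChainedAlignment, ref_pos: int) -> tuple[int, int]:
    """Closest mappable reference position at or left of ``ref_pos``.

    Returns ``(ref_pos', query_pos)``.  Used by the scaffolder when a cut
    position lands between HSPs.
    """
    lo, _ = chain.s_interval
    for pos in range(ref_pos, lo - 1, -1):
        q = map_ref_to_query(chain, pos)
        if q is not None:
            return pos, q
    raise ValueError(f"no mappable position at or left of {ref_pos} in chain {chain.query_id}/{chain.subject_id}")


def build_chains(
    hsps: Iterable[HSP],
    query_lengths: dict[str, int] | None = None,
    subject_lengths: dict[str, int] | None = None,
) -> dict[str, list[ChainedAlignment]]:
    """Group HSPs by (query, subject), chain each pair, index chains by query.

    Lengths, when given, are attached so coverage properties work downstream.
    """
    by_pair: dict[tuple[str, str], list[HSP]] = {}
    for h in hsps:
        by_pair.setdefault((h.query_id, h.subject_id), []).append(h)
    out: dict[str, list[ChainedAlignment]] = {}
    for (qid, sid) in sorted(by_pair):
        chain = chain_hsps(by_pair[(qid, sid)])
        if query_lengths is not None:
            if qid not in query_lengths:
                raise KeyError(f"query {qid} absent from supplied lengths")
            chain.query_length = query_lengths[qid]
        if subject_lengths is not None:
            if sid not in subject_lengths:
                raise KeyError(f"subject {sid} absent from supplied lengths")
            chain.subject_length = subject_lengths[sid]
        out.setdefault(qid, []).append(chain)
    return out
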