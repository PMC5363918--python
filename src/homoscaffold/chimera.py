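"""Chimeric polypeptide detection from chained alignments.

A chimera is a polypeptide whose disjoint regions derive from two different
genes (a type II clustering error).  The screen: among a query's chained
alignments with at least ``min_identity`` percent identity, the query is
tagged chimeric when two of them hit *different* reference proteins over
*disjoint* query regions and no retained alignment covers more than
``max_region_cov`` of the query — a single dominant alignment is taken as
evidence that the polypeptide is one gene with secondary similarity, not a
fusion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

from .model import ChainedAlignment, chain_hsps

__all__ = ["ChimeraCall", "ChimeraEvidence", "detect_chimera", "apply_chimera_policy"]


@dataclass(frozen=True)
class ChimeraEvidence:
    subject_id: str
    q_interval: tuple[int, int]
    identity_pct: float
    query_coverage: float


@dataclass
class ChimeraCall:
    query_id: str
    is_chimeric: bool
    evidence: list[ChimeraEvidence]


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)


def detect_chimera(
    chains: Sequence[ChainedAlignment],
    min_identity: float = 50.0,
    max_region_cov: float = 0.70,
    max_region_overlap: int = 0,
    identity_mode: Literal["chain", "hsp"] = "chain",
) -> ChimeraCall:
    """Classify one query's alignments as chimeric or not.

    ``identity_mode`` controls where the identity screen applies: ``"chain"``
    (default) keeps whole chained alignments whose length-weighted identity
    clears ``min_identity``; ``"hsp"`` screens individual HSPs first and
    re-chains the survivors.  ``max_region_overlap`` relaxes the disjointness
    requirement to that many shared query residues (default strict 0).
    """
    if not chains:
        raise ValueError("no chains for chimera detection")
    qid = chains[0].query_id
    if any(c.query_id != qid for c in chains):
        raise ValueError("detect_chimera expects chains of a single query")
    if any(c.query_length is None for c in chains):
        raise ValueError(f"unknown query length for {qid}")

    if identity_mode == "chain":
        retained = [c for c in chains if c.identity_pct >= min_identity]
    elif identity_mode == "hsp":
        retained = []
        for c in chains:
            keep = [h for h in c.hsps if h.identity_pct >= min_identity]
            if keep:
                sub = chain_hsps(keep)
                sub.query_length = c.query_length
                sub.subject_length = c.subject_length
                retained.append(sub)
    else:
        raise ValueError(f"unknown identity_mode {identity_mode!r}")

    call = ChimeraCall(query_id=qid, is_chimeric=False, evidence=[])
    if len(retained) < 2:
        return call
    if any(c.query_coverage > max_region_cov for c in retained):
        return call

    best_pair: tuple[float, ChainedAlignment, ChainedAlignment] | None = None
    for i, a in enumerate(retained):
        for b in retained[i + 1 :]:
            if a.subject_id == b.subject_id:
                continue
            if _overlap(a.q_interval, b.q_interval) > max_region_overlap:
                continue
            score = a.query_coverage + b.query_coverage
            if best_pair is None or score > best_pair[0]:
                best_pair = (score, a, b)
    if best_pair is not None:
        _, a, b = best_pair
        pair = sorted((a, b), key=lambda c: c.q_interval)
        call.is_chimeric = True
        call.evidence = [
            ChimeraEvidence(c.subject_id, c.q_interval, c.identity_pct, c.query_coverage)
            for c in pair
        ]
    return call


def apply_chimera_policy(
    calls: Iterable[ChimeraCall], policy: Literal["tag", "drop"] = "tag"
) -> tuple[set[str], set[str]]:
    """Resolve chimera calls into (queries proceeding to filtering, flagged queries).

    ``tag`` (default) keeps chimeric sequences in the pipeline but records the
    flag; ``drop`` removes them before best-hit selection.
    """
    if policy not in ("tag", "drop"):
        raise ValueError(f"unknown chimera policy {policy!r}")
    flagged = {c.query_id for c in calls if c.is_chimeric}
    all_ids = {c.query_id for c in calls} | flagged
    proceeding = all_ids - flagged if policy == "drop" else all_ids
    return proceeding, flagged
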