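"""Redundancy reduction and scaffolding of polypeptides into protein products.

Polypeptides sharing a best-hit reference protein form a group.  Within a
group, a greedy positional cover keeps the members that together cover the
reference: repeatedly pick the member adding the most reference positions
not yet covered; members that add nothing are redundant.  Retained members,
sorted by their first aligned reference position, are then cut-and-joined:
overlapping neighbours are cut at the rightmost reference residue their
alignments share (the left member supplies residues up to the cut, the right
member after it); a gap of ``n`` uncovered reference residues between
neighbours is bridged by ``n`` X residues.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .besthit import BestHit
from .model import SequenceRecord, map_ref_to_query, nearest_mappable_left

__all__ = [
    "ReferenceGroup",
    "ProteinProduct",
    "select_nonredundant",
    "scaffold_group",
    "run_step5",
]


@dataclass
class ReferenceGroup:
    """All best hits pointing at one reference protein."""

    subject_id: str
    members: list[BestHit]
    subject_length: int

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("empty reference group")
        if any(m.subject_id != self.subject_id for m in self.members):
            raise ValueError("group members must share the reference protein")


@dataclass
class Segment:
    query_id: str
    query_slice: tuple[int, int]  # 1-based inclusive positions of the polypeptide
    ref_interval: tuple[int, int]
    # polypeptide positions actually mapped to ref_interval (query_slice may
    # additionally carry unaligned termini at the product's outer ends)
    q_aligned: tuple[int, int] | None = None

    @property
    def length(self) -> int:
        return self.query_slice[1] - self.query_slice[0] + 1


@dataclass
class ProteinProduct:
    """Scaffolded output sequence for one reference protein."""

    pp_id: str
    subject_id: str
    sequence: str
    segments: list[Segment]
    gaps: list[tuple[tuple[int, int], int]] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return len(self.segments)

    @property
    def n_gap_residues(self) -> int:
        return sum(n for _, n in self.gaps)


def _preference(m: BestHit) -> tuple[float, int, str]:
    # higher identity, then longer query, then smaller query id
    return (-m.chain.identity_pct, -(m.chain.query_length or 0), m.query_id)


def _greedy_cover(
    candidates: list[BestHit], footprints: dict[str, frozenset[int]], target: frozenset[int]
) -> list[BestHit]:
    """Max-new-positions greedy, then prune picks made fully redundant later."""
    covered: set[int] = set()
    picks: list[BestHit] = []
    remaining = list(candidates)
    while covered != target and remaining:
        remaining.sort(
            key=lambda m: (-len(footprints[m.query_id] - covered),) + _preference(m)
        )
        pick = remaining.pop(0)
        if not footprints[pick.query_id] - covered:
            break
        picks.append(pick)
        covered |= footprints[pick.query_id]
    for m in sorted(picks, key=lambda m: len(footprints[m.query_id])):
        others = set().union(
            *(footprints[o.query_id] for o in picks if o is not m), frozenset()
        )
        if footprints[m.query_id] <= others:
            picks.remove(m)
    return picks


def select_nonredundant(
    group: ReferenceGroup, max_exact: int = 40
) -> tuple[list[BestHit], list[str]]:
    """Minimum-cardinality positional cover of the reference protein.

    Retains the smallest set of members whose aligned reference positions
    reproduce the whole group's position union — the members with the best
    coverage of their region of the reference; everything else is redundant.
    Duplicate and nested footprints are discarded up front (keeping the
    higher-identity, then longer, then lexicographically first member), a
    greedy cover seeds an upper bound, and a branch-and-bound search
    certifies minimality.  Groups with more than ``max_exact`` distinct
    maximal footprints (far beyond realistic redundancy) fall back to the
    pruned greedy cover.
    """
    footprints = {m.query_id: frozenset(m.chain.subject_positions()) for m in group.members}
    target = frozenset(set().union(*footprints.values()))

    # domination filter: a member whose footprint is contained in a preferred
    # member's footprint can always be replaced by that member in a cover
    ordered = sorted(group.members, key=lambda m: (-len(footprints[m.query_id]),) + _preference(m))
    candidates: list[BestHit] = []
    for m in ordered:
        if not any(footprints[m.query_id] <= footprints[c.query_id] for c in candidates):
            candidates.append(m)

    best = _greedy_cover(candidates, footprints, target)
    if 1 < len(candidates) <= max_exact and len(best) > 1:
        by_position: dict[int, list[int]] = {}
        for idx, c in enumerate(candidates):
            for p in footprints[c.query_id]:
                by_position.setdefault(p, []).append(idx)
        best_k = len(best)
        best_sel: list[int] | None = None
        budget = [200_000]

        def search(chosen: list[int], covered: frozenset[int]) -> None:
            nonlocal best_k, best_sel
            if budget[0] <= 0:
                return
            budget[0] -= 1
            if covered == target:
                if len(chosen) < best_k:
                    best_k, best_sel = len(chosen), list(chosen)
                return
            if len(chosen) + 1 >= best_k:
                return
            # branch on the uncovered position with the fewest coverers
            uncovered = target - covered
            pivot = min(uncovered, key=lambda p: (len(by_position[p]), p))
            for idx in by_position[pivot]:
                if idx in chosen:
                    continue
                search(chosen + [idx], covered | footprints[candidates[idx].query_id])

        search([], frozenset())
        if best_sel is not None:
            best = [candidates[i] for i in sorted(best_sel)]

    retained_ids = {m.query_id for m in best}
    retained = [m for m in group.members if m.query_id in retained_ids]
    redundant = [m.query_id for m in group.members if m.query_id not in retained_ids]
    return retained, redundant


def _shared_rightmost(prev: BestHit, nxt: BestHit) -> int:
    """Rightmost reference residue covered by both members' alignments."""
    shared = prev.chain.subject_positions() & nxt.chain.subject_positions()
    if shared:
        return max(shared)
    # outer intervals overlap but footprints miss each other (inter-HSP
    # holes); cut at the smaller alignment end
    return min(prev.chain.s_interval[1], nxt.chain.s_interval[1])


def _map_left(member: BestHit, ref_pos: int) -> int:
    """Query position for ``ref_pos``, falling back leftward across HSP gaps."""
    q = map_ref_to_query(member.chain, ref_pos)
    if q is None:
        pos, q = nearest_mappable_left(member.chain, ref_pos)
        warnings.warn(
            f"cut position {ref_pos} unmappable in {member.query_id}; "
            f"using nearest mappable position {pos}"
        )
    return q


def scaffold_group(
    retained: Sequence[BestHit],
    sequences: Mapping[str, SequenceRecord],
    pp_id: str | None = None,
) -> ProteinProduct:
    """Join the non-redundant members of one group into a protein product.

    A single member becomes the product verbatim.  Otherwise members are
    sorted by first aligned reference position and joined pairwise: a cut at
    the rightmost shared reference residue for overlapping neighbours, or
    ``n`` X residues for neighbours ``n`` uncovered reference positions
    apart.  Unaligned query termini survive only at the outer ends of the
    product (junctions are trimmed to the aligned regions).
    """
    if not retained:
        raise ValueError("cannot scaffold an empty member list")
    subject_id = retained[0].subject_id
    pp_id = pp_id or f"PP_{subject_id}"

    if len(retained) == 1:
        m = retained[0]
        seq = sequences[m.query_id].sequence
        return ProteinProduct(
            pp_id=pp_id,
            subject_id=subject_id,
            sequence=seq,
            segments=[
                Segment(m.query_id, (1, len(seq)), m.chain.s_interval, m.chain.q_interval)
            ],
        )

    members = sorted(retained, key=lambda m: (m.chain.s_interval, m.query_id))
    # reference-coordinate cut between each consecutive pair; None marks a gap
    cuts: list[int | None] = []
    for prev, nxt in zip(members, members[1:]):
        if nxt.chain.s_interval[0] <= prev.chain.s_interval[1]:
            cuts.append(_shared_rightmost(prev, nxt))
        else:
            cuts.append(None)

    pieces: list[str] = []
    segments: list[Segment] = []
    gaps: list[tuple[tuple[int, int], int]] = []
    for i, m in enumerate(members):
        seq = sequences[m.query_id].sequence
        s_lo, s_hi = m.chain.s_interval
        # left bound of this member's contribution
        if i == 0:
            q_from, ref_from = 1, s_lo
            qa_from = map_ref_to_query(m.chain, s_lo)
        else:
            cut = cuts[i - 1]
            if cut is None:
                q_from = map_ref_to_query(m.chain, s_lo)
                ref_from = s_lo
                prev_hi = members[i - 1].chain.s_interval[1]
                n_x = s_lo - prev_hi - 1
                if n_x > 0:
                    gaps.append(((prev_hi + 1, s_lo - 1), n_x))
                    pieces.append("X" * n_x)
            else:
                q_from = _map_left(m, cut) + 1
                ref_from = cut + 1
            qa_from = q_from
        # right bound
        if i == len(members) - 1:
            q_to, ref_to = len(seq), s_hi
            qa_to = map_ref_to_query(m.chain, s_hi)
        else:
            cut = cuts[i]
            if cut is None:
                q_to = map_ref_to_query(m.chain, s_hi)
                ref_to = s_hi
            else:
                q_to = _map_left(m, min(cut, s_hi))
                ref_to = min(cut, s_hi)
            qa_to = q_to
        if q_from is None or q_to is None or q_from > q_to:
            warnings.warn(f"member {m.query_id} contributes no residues after cutting; skipped")
            continue
        pieces.append(seq[q_from - 1 : q_to])
        segments.append(
            Segment(m.query_id, (q_from, q_to), (ref_from, ref_to), (qa_from, qa_to))
        )

    sequence = "".join(pieces).strip("X")
    return ProteinProduct(pp_id=pp_id, subject_id=subject_id, sequence=sequence,
                          segments=segments, gaps=gaps)


def run_step5(
    best_hits: Mapping[str, BestHit],
    sequences: Mapping[str, SequenceRecord],
    subject_lengths: Mapping[str, int],
) -> tuple[list[ProteinProduct], dict[str, str], float]:
    """Group best hits by reference, reduce redundancy, scaffold every group.

    Returns the protein products, a status per best-hit query (``redundant``,
    ``component`` or ``singleton_pp``), and the redundancy factor
    (best-hit queries per protein product).
    """
    groups: dict[str, list[BestHit]] = {}
    for qid in sorted(best_hits):
        hit = best_hits[qid]
        groups.setdefault(hit.subject_id, []).append(hit)

    products: list[ProteinProduct] = []
    statuses: dict[str, str] = {}
    for sid in sorted(groups):
        group = ReferenceGroup(subject_id=sid, members=groups[sid],
                               subject_length=subject_lengths[sid])
        retained, redundant = select_nonredundant(group)
        pp = scaffold_group(retained, sequences)
        products.append(pp)
        for qid in redundant:
            statuses[qid] = "redundant"
        label = "singleton_pp" if len(retained) == 1 else "component"
        for m in retained:
            statuses[m.query_id] = label
    factor = len(best_hits) / len(products) if products else float("nan")
    return products, statuses, factor
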