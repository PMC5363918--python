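"""Shared fixtures and small builders for the test suite."""

from __future__ import annotations

import itertools

import pytest

from homoscaffold.besthit import BestHit
from homoscaffold.model import HSP, ChainedAlignment


def make_hsp(
    qs: int, qe: int, ss: int, se: int,
    query_id: str = "q", subject_id: str = "s",
    identity: float = 90.0, bitscore: float = 50.0, btop: str | None = None,
) -> HSP:
    return HSP(
        query_id=query_id, subject_id=subject_id, identity_pct=identity,
        align_len=max(qe - qs + 1, se - ss + 1),
        qstart=qs, qend=qe, sstart=ss, send=se, bitscore=bitscore, btop=btop,
    )


def make_chain(
    *hsps: HSP, query_length: int | None = None, subject_length: int | None = None
) -> ChainedAlignment:
    return ChainedAlignment(
        hsps[0].query_id, hsps[0].subject_id, list(hsps),
        query_length=query_length, subject_length=subject_length,
    )


def make_member(
    query_id: str, ss: int, se: int, subject_id: str = "ref",
    identity: float = 90.0, query_length: int | None = None, subject_length: int = 1000,
) -> BestHit:
    qlen = query_length or (se - ss + 1)
    h = make_hsp(1, se - ss + 1, ss, se, query_id=query_id, subject_id=subject_id,
                 identity=identity)
    chain = make_chain(h, query_length=qlen, subject_length=subject_length)
    return BestHit(query_id=query_id, subject_id=subject_id, chain=chain)


def brute_force_chain_objective(hsps) -> tuple[int, float, int]:
    """Exhaustive optimum of (covered query residues, bitscore, -n) over colinear subsets."""

    def valid(subset) -> bool:
        s = sorted(subset, key=lambda h: (h.qstart, h.sstart))
        return all(
            s[i].qend <= s[j].qstart and s[i].send <= s[j].sstart
            for i in range(len(s)) for j in range(i + 1, len(s))
        )

    best: tuple[int, float, int] | None = None
    for k in range(1, len(hsps) + 1):
        for combo in itertools.combinations(hsps, k):
            if not valid(combo):
                continue
            pos: set[int] = set()
            for h in combo:
                pos.update(range(h.qstart, h.qend + 1))
            t = (len(pos), round(sum(h.bitscore for h in combo), 9), -k)
            if best is None or t > best:
                best = t
    assert best is not None
    return best


def brute_force_min_cover(members) -> int:
    """Smallest number of members whose footprint union equals the group union."""
    union = set().union(*(m.chain.subject_positions() for m in members))
    for k in range(1, len(members) + 1):
        for combo in itertools.combinations(members, k):
            if set().union(*(m.chain.subject_positions() for m in combo)) == union:
                return k
    raise AssertionError("unreachable")


@pytest.fixture
def small_sim_plan():
    from homoscaffold.simulate import SimulationPlan

    return SimulationPlan(n_proteins=30, seed=11)
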