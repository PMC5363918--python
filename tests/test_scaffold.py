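"""Redundancy reduction and cut-and-join scaffolding."""

import random

import numpy as np
import pytest

from homoscaffold.besthit import BestHit
from homoscaffold.model import SequenceRecord
from homoscaffold.scaffold import (
    ReferenceGroup,
    run_step5,
    scaffold_group,
    select_nonredundant,
)

from .conftest import brute_force_min_cover, make_chain, make_hsp, make_member


class TestSelectNonredundant:
    def test_identical_intervals_keep_higher_identity(self):
        a = make_member("qa", 1, 100, identity=90.0)
        b = make_member("qb", 1, 100, identity=85.0)
        retained, redundant = select_nonredundant(ReferenceGroup("ref", [a, b], 1000))
        assert [m.query_id for m in retained] == ["qa"]
        assert redundant == ["qb"]

    def test_nested_member_is_redundant(self):
        outer = make_member("qo", 1, 100)
        inner = make_member("qi", 20, 60)
        retained, redundant = select_nonredundant(ReferenceGroup("ref", [outer, inner], 1000))
        assert [m.query_id for m in retained] == ["qo"]
        assert redundant == ["qi"]

    def test_disjoint_members_both_retained(self):
        a = make_member("qa", 1, 100)
        b = make_member("qb", 150, 200)
        retained, redundant = select_nonredundant(ReferenceGroup("ref", [a, b], 1000))
        assert {m.query_id for m in retained} == {"qa", "qb"} and not redundant

    def test_bridge_interval_not_overcounted(self):
        # a middle interval that max-gain greedy would pick first, although
        # the flanking pair already covers everything it covers
        picks = [
            make_member("mid", 8, 23),
            make_member("left", 1, 15),
            make_member("right", 16, 30),
            make_member("lo", 1, 9),
            make_member("hi", 22, 30),
        ]
        retained, _ = select_nonredundant(ReferenceGroup("ref", picks, 1000))
        assert len(retained) == 2

    def test_matches_brute_force_minimum_on_random_groups(self):
        rng = np.random.default_rng(99)
        for _ in range(300):
            slen = int(rng.integers(50, 200))
            n = int(rng.integers(1, 11))
            members = [
                make_member(f"q{i:02d}", a := int(rng.integers(1, slen)),
                            int(rng.integers(a, min(slen, a + 120))),
                            identity=float(rng.integers(50, 101)), subject_length=slen)
                for i in range(n)
            ]
            group = ReferenceGroup("ref", members, slen)
            retained, redundant = select_nonredundant(group)
            union = set().union(*(m.chain.subject_positions() for m in members))
            got = set().union(*(m.chain.subject_positions() for m in retained))
            assert got == union  # cover preserved
            assert len(retained) == brute_force_min_cover(members)
            assert {m.query_id for m in retained} | set(redundant) == {
                m.query_id for m in members
            }


def exact_fragments(protein: str, intervals, subject_id="ref"):
    """Members that are exact substrings of ``protein`` over given ref intervals."""
    members, seqs = [], {}
    for i, (a, b) in enumerate(intervals):
        qid = f"f{i}"
        frag = protein[a - 1 : b]
        seqs[qid] = SequenceRecord(qid, frag)
        h = make_hsp(1, b - a + 1, a, b, query_id=qid, subject_id=subject_id, identity=100.0)
        chain = make_chain(h, query_length=len(frag), subject_length=len(protein))
        members.append(BestHit(qid, subject_id, chain))
    return members, seqs


@pytest.fixture
def protein():
    rng = random.Random(17)
    return "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(200))


class TestScaffoldGroup:
    def test_single_member_verbatim(self, protein):
        members, seqs = exact_fragments(protein, [(1, 150)])
        pp = scaffold_group(members, seqs)
        assert pp.sequence == protein[:150]
        assert pp.n_components == 1 and not pp.gaps

    def test_gap_bridged_with_x_run(self, protein):
        # ref 1-100 and 120-200: 19 uncovered interior residues
        members, seqs = exact_fragments(protein, [(1, 100), (120, 200)])
        pp = scaffold_group(members, seqs)
        assert pp.sequence == protein[:100] + "X" * 19 + protein[119:200]
        assert pp.gaps == [((101, 119), 19)]

    def test_abutting_intervals_join_directly(self, protein):
        members, seqs = exact_fragments(protein, [(1, 100), (101, 200)])
        pp = scaffold_group(members, seqs)
        assert pp.sequence == protein
        assert not pp.gaps

    def test_overlap_cut_reconstructs_protein(self, protein):
        # fragments 1-100 and 80-180 of a 180-residue protein: cut at the
        # rightmost shared residue (100); product equals the protein
        members, seqs = exact_fragments(protein[:180], [(1, 100), (80, 180)])
        pp = scaffold_group(members, seqs)
        assert pp.sequence == protein[:180]
        assert [s.ref_interval for s in pp.segments] == [(1, 100), (101, 180)]

    def test_unaligned_termini_trimmed_at_junctions_only(self, protein):
        members, seqs = exact_fragments(protein, [(1, 100), (80, 200)])
        # give both members unalignable tails
        seqs["f0"] = SequenceRecord("f0", seqs["f0"].sequence + "WWWW")
        seqs["f1"] = SequenceRecord("f1", "VVVV" + seqs["f1"].sequence)
        for m in members:
            m.chain.query_length = seqs[m.query_id].length
        members[1].chain.hsps[0] = make_hsp(5, 125, 80, 200, query_id="f1",
                                            subject_id="ref", identity=100.0)
        pp = scaffold_group(members, seqs)
        # junction tails vanish; the product is the clean protein sequence
        assert pp.sequence == protein

    def test_segments_sorted_and_lengths_reconcile(self, protein):
        members, seqs = exact_fragments(protein, [(1, 80), (70, 140), (160, 200)])
        pp = scaffold_group(members, seqs)
        starts = [s.ref_interval[0] for s in pp.segments]
        assert starts == sorted(starts)
        assert len(pp.sequence) == sum(s.length for s in pp.segments) + pp.n_gap_residues
        assert not pp.sequence.startswith("X") and not pp.sequence.endswith("X")


class TestRunStep5:
    def test_identical_copies_collapse_to_one_product(self, protein):
        members, seqs = exact_fragments(protein, [(1, 200)] * 10)
        hits = {m.query_id: m for m in members}
        products, statuses, factor = run_step5(hits, seqs, {"ref": 200})
        assert len(products) == 1
        assert factor == 10.0
        assert sum(1 for s in statuses.values() if s == "redundant") == 9
        assert list(statuses.values()).count("singleton_pp") == 1

    def test_three_references_three_products(self, protein):
        hits = {}
        seqs = {}
        for i, ref in enumerate(["r1", "r2", "r3"]):
            members, s = exact_fragments(protein, [(1, 150)], subject_id=ref)
            m = members[0]
            qid = f"{ref}_frag"
            m = BestHit(qid, ref, m.chain)
            m.chain.query_id = qid  # rename for uniqueness
            for h in m.chain.hsps:
                object.__setattr__(h, "query_id", qid)
            hits[qid] = m
            seqs[qid] = SequenceRecord(qid, s["f0"].sequence)
        products, statuses, factor = run_step5(hits, seqs, {"r1": 200, "r2": 200, "r3": 200})
        assert len(products) == 3 and factor == 1.0
        assert set(statuses.values()) == {"singleton_pp"}
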