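"""HSP chaining, coverage arithmetic and coordinate mapping."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from homoscaffold.model import (
    HSP,
    FilterParams,
    chain_hsps,
    coverage,
    map_ref_to_query,
    nearest_mappable_left,
)

from .conftest import brute_force_chain_objective, make_chain, make_hsp


class TestChainHsps:
    def test_single_hsp_is_its_own_chain(self):
        chain = chain_hsps([make_hsp(1, 50, 101, 150)])
        assert len(chain.hsps) == 1
        assert len(chain.query_positions()) == 50

    def test_six_residue_overlap_forces_a_choice(self):
        # A q1-50 (bitscore 80) vs B q45-100 (bitscore 90) overlap by 6 aa:
        # not chainable together, and B alone covers 56 > 50 residues
        a = make_hsp(1, 50, 1, 50, bitscore=80.0)
        b = make_hsp(45, 100, 60, 115, bitscore=90.0)
        chain = chain_hsps([a, b])
        assert [h.qstart for h in chain.hsps] == [45]
        assert len(chain.query_positions()) == 56

    def test_one_residue_overlap_is_allowed(self):
        a = make_hsp(1, 50, 1, 50)
        b = make_hsp(50, 100, 50, 100)
        chain = chain_hsps([a, b])
        assert len(chain.hsps) == 2
        assert len(chain.query_positions()) == 100

    def test_overlap_rule_applies_to_subject_axis_too(self):
        # disjoint on the query but 10-residue overlap on the subject
        a = make_hsp(1, 50, 1, 50)
        b = make_hsp(60, 100, 41, 81)
        assert len(chain_hsps([a, b]).hsps) == 1

    def test_empty_input_errors(self):
        with pytest.raises(ValueError, match="no HSPs"):
            chain_hsps([])

    def test_mixed_pairs_rejected(self):
        a = make_hsp(1, 10, 1, 10)
        b = make_hsp(20, 30, 20, 30, subject_id="other")
        with pytest.raises(ValueError, match="single query/subject"):
            chain_hsps([a, b])

    def test_matches_exhaustive_search_on_random_instances(self):
        rng = np.random.default_rng(421)
        for _ in range(300):
            n = int(rng.integers(1, 9))
            hsps = []
            for _ in range(n):
                qs = int(rng.integers(1, 120)); qe = qs + int(rng.integers(0, 60))
                ss = int(rng.integers(1, 120)); se = ss + int(rng.integers(0, 60))
                hsps.append(make_hsp(qs, qe, ss, se, bitscore=float(rng.integers(10, 100))))
            chain = chain_hsps(hsps)
            got = (len(chain.query_positions()), round(chain.bitscore, 9), -len(chain.hsps))
            assert got == brute_force_chain_objective(hsps)


class TestCoverage:
    def test_single_hsp_half_coverage(self):
        chain = make_chain(make_hsp(10, 59, 101, 150))
        qc, _ = coverage(chain, 100, 200)
        assert qc == pytest.approx(0.50)

    def test_union_not_sum(self):
        chain = make_chain(make_hsp(1, 50, 1, 50), make_hsp(50, 100, 50, 100))
        qc, _ = coverage(chain, 100, 100)
        assert qc == pytest.approx(1.0)

    def test_disjoint_hsps_add_up(self):
        chain = make_chain(make_hsp(1, 40, 1, 40), make_hsp(61, 100, 61, 100))
        qc, _ = coverage(chain, 100, 100)
        assert qc == pytest.approx(0.80)

    def test_position_beyond_length_errors(self):
        chain = make_chain(make_hsp(10, 59, 101, 150))
        with pytest.raises(ValueError, match="coordinate exceeds length"):
            coverage(chain, 50, 200)

    def test_adding_disjoint_hsp_never_decreases_coverage(self):
        base = make_chain(make_hsp(10, 40, 10, 40))
        grown = make_chain(make_hsp(10, 40, 10, 40), make_hsp(50, 70, 50, 70))
        assert coverage(grown, 100, 100)[0] >= coverage(base, 100, 100)[0]
        assert coverage(grown, 100, 100)[1] >= coverage(base, 100, 100)[1]


class TestMapRefToQuery:
    def test_ungapped_linear_offset(self):
        chain = make_chain(make_hsp(10, 59, 101, 150))
        assert map_ref_to_query(chain, 120) == 29

    def test_between_hsps_returns_none(self):
        chain = make_chain(make_hsp(1, 20, 1, 20), make_hsp(40, 60, 41, 61))
        assert map_ref_to_query(chain, 30) is None

    def test_outside_interval_errors(self):
        chain = make_chain(make_hsp(10, 59, 101, 150))
        with pytest.raises(ValueError, match="outside subject interval"):
            map_ref_to_query(chain, 50)

    def test_btop_mismatch_walk(self):
        # 10 matches, one A/G mismatch, 39 matches: same geometry as ungapped
        chain = make_chain(make_hsp(10, 59, 101, 150, btop="10AG39"))
        assert map_ref_to_query(chain, 120) == 29
        assert map_ref_to_query(chain, 101) == 10
        assert map_ref_to_query(chain, 150) == 59

    def test_btop_query_gap_walk(self):
        # hand-expanded columns: 10 matches (q10-19/s101-110), query gap
        # consuming s111, 5 matches (q20-24/s112-116), A/C mismatch
        # (q25/s117), 20 matches (q26-45/s118-137)
        chain = make_chain(make_hsp(10, 45, 101, 137, btop="10-G5AC20"))
        assert map_ref_to_query(chain, 105) == 14
        assert map_ref_to_query(chain, 111) == 19  # gap column -> nearest left residue
        assert map_ref_to_query(chain, 112) == 20
        assert map_ref_to_query(chain, 117) == 25
        assert map_ref_to_query(chain, 137) == 45

    def test_btop_subject_gap_walk(self):
        # 5 matches (q1-5/s1-5), subject gap consuming q6, 10 matches (q7-16/s6-15)
        chain = make_chain(make_hsp(1, 16, 1, 15, btop="5C-10"))
        assert map_ref_to_query(chain, 5) == 5
        assert map_ref_to_query(chain, 6) == 7
        assert map_ref_to_query(chain, 15) == 16

    def test_monotone_within_chain(self):
        chain = make_chain(
            make_hsp(5, 30, 11, 36), make_hsp(40, 80, 50, 90, btop="20AC20")
        )
        lo, hi = chain.s_interval
        mapped = [map_ref_to_query(chain, p) for p in range(lo, hi + 1)]
        present = [m for m in mapped if m is not None]
        assert present == sorted(present)

    def test_nearest_mappable_left_falls_back(self):
        chain = make_chain(make_hsp(1, 20, 1, 20), make_hsp(40, 60, 41, 61))
        pos, q = nearest_mappable_left(chain, 30)
        assert (pos, q) == (20, 20)


class TestFilterParams:
    def test_triple_round_trip(self):
        p = FilterParams.from_triple("80/60/70")
        assert (p.min_identity, p.min_qcov_high_ref, p.min_qcov_low_ref) == (80.0, 0.60, 0.70)
        assert p.triple == "80/60/70"

    @given(st.floats(min_value=-50, max_value=200))
    @settings(max_examples=30, derandomize=True)
    def test_identity_bounds_enforced(self, ident):
        if 0 <= ident <= 100:
            assert FilterParams(min_identity=ident).min_identity == ident
        else:
            with pytest.raises(ValueError):
                FilterParams(min_identity=ident)
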