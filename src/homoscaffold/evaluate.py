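"""Precision assessment: expected group, TP/FP/FN, Sn/Sp, shift reports.

The gold standard ("expected group") is the set of proteins in a trusted
proteome of the target species that (i) some polypeptide aligns to well and
(ii) some protein of the reference species also aligns to well — proteins
the data could realistically evidence.  Scaffolded products are then aligned
back to this proteome: a product with a significant hit to an expected
protein is a true positive, one without is a false positive, and an
expected protein never hit significantly is a false negative.  Sensitivity
Sn = TP/(TP+FN); specificity Sp = TP/(TP+FP).

Expected-group construction uses strict inequalities (identity > 60,
coverage > 0.70) while product classification uses non-strict ones
(identity >= 60, expected-protein coverage >= 0.70); both follow the
protocol's wording and are deliberately not harmonised.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .besthit import best_hits_per_query
from .io import AlignmentTable
from .model import FilterParams, HSP, SequenceRecord, build_chains
from .scaffold import ProteinProduct, run_step5

__all__ = [
    "EvaluationCounts",
    "ExpectedGroup",
    "build_expected_group",
    "classify",
    "coverage_shift_report",
    "length_distribution",
    "products_vs_truth",
    "sweep_evaluation",
]


@dataclass
class EvaluationCounts:
    TP: int
    FP: int
    FN: int

    @property
    def Sn(self) -> float:
        return self.TP / (self.TP + self.FN) if self.TP + self.FN > 0 else 0.0

    @property
    def Sp(self) -> float:
        if self.TP + self.FP == 0:
            warnings.warn("no protein products; specificity undefined")
            return math.nan
        return self.TP / (self.TP + self.FP)


@dataclass
class ExpectedGroup:
    protein_ids: set[str]
    provenance: dict[str, dict[str, str]] = field(default_factory=dict)

    def __contains__(self, pid: str) -> bool:
        return pid in self.protein_ids

    def __len__(self) -> int:
        return len(self.protein_ids)


def _chain_table(table: AlignmentTable):
    return build_chains(
        table.rows,
        query_lengths=table.query_lengths or None,
        subject_lengths=table.subject_lengths or None,
    )


def _significant_subjects(
    table: AlignmentTable,
    min_id: float,
    min_cov: float,
    coverage_side: Literal["query", "subject"],
    strict: bool,
) -> dict[str, str]:
    """Map of subject id -> one query evidencing it under the thresholds."""
    hit: dict[str, str] = {}
    for qid, chains in _chain_table(table).items():
        for c in chains:
            cov = c.query_coverage if coverage_side == "query" else c.subject_coverage
            ok = (
                (c.identity_pct > min_id and cov > min_cov)
                if strict
                else (c.identity_pct >= min_id and cov >= min_cov)
            )
            if ok:
                hit.setdefault(c.subject_id, qid)
    return hit


def build_expected_group(
    poly_vs_truth: AlignmentTable,
    refspecies_vs_truth: AlignmentTable,
    min_id: float = 60.0,
    min_cov: float = 0.70,
    coverage_side: Literal["query", "subject"] = "query",
) -> ExpectedGroup:
    """Proteins of the trusted proteome evidenced by both alignment tables.

    A protein joins the group when some polypeptide and some
    reference-species protein each align to it with identity strictly above
    ``min_id`` and coverage strictly above ``min_cov``.  ``coverage_side``
    selects which sequence the coverage condition is measured on (the query,
    i.e. the aligned polypeptide / reference protein, by default).
    """
    if not poly_vs_truth.rows or not refspecies_vs_truth.rows:
        warnings.warn("empty alignment table; expected group is empty")
        return ExpectedGroup(protein_ids=set())
    by_poly = _significant_subjects(poly_vs_truth, min_id, min_cov, coverage_side, strict=True)
    by_ref = _significant_subjects(refspecies_vs_truth, min_id, min_cov, coverage_side, strict=True)
    ids = set(by_poly) & set(by_ref)
    provenance = {
        pid: {"polypeptide": by_poly[pid], "reference_species": by_ref[pid]} for pid in ids
    }
    return ExpectedGroup(protein_ids=ids, provenance=provenance)


def classify(
    pp_vs_expected: AlignmentTable,
    expected: ExpectedGroup,
    pp_ids: Sequence[str],
    min_id: float = 60.0,
    min_cov: float = 0.70,
) -> EvaluationCounts:
    """Count TP/FP products and FN expected proteins.

    An alignment is significant when identity >= ``min_id`` and the expected
    protein's coverage >= ``min_cov``.  A product matching several expected
    proteins counts once as TP (all matched proteins are covered); TP + FP
    equals the number of products.
    """
    tp_products: set[str] = set()
    covered_expected: set[str] = set()
    for qid, chains in _chain_table(pp_vs_expected).items():
        for c in chains:
            if c.subject_id not in expected:
                continue
            if c.identity_pct >= min_id and c.subject_coverage >= min_cov:
                tp_products.add(qid)
                covered_expected.add(c.subject_id)
    pp_set = set(pp_ids)
    stray = tp_products - pp_set
    if stray:
        raise ValueError(f"alignment queries not in the product list: {sorted(stray)[:3]}")
    tp = len(tp_products)
    fp = len(pp_set) - tp
    fn = len(expected.protein_ids - covered_expected)
    return EvaluationCounts(TP=tp, FP=fp, FN=fn)


def _best_subject_coverage(table: AlignmentTable) -> dict[str, float]:
    out: dict[str, float] = {}
    for qid, chains in _chain_table(table).items():
        out[qid] = max(c.subject_coverage for c in chains)
    return out


def coverage_shift_report(
    before: AlignmentTable | Mapping[str, float],
    after: AlignmentTable | Mapping[str, float],
    bins: Sequence[float] = (0.0, 0.25, 0.50, 0.75, 0.9999, 1.0001),
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Transition matrix of per-sequence coverage bins before vs after scaffolding.

    ``before``/``after`` are either alignment tables (each sequence scored by
    its best subject coverage) or precomputed ``id -> coverage`` mappings
    (e.g. polypeptides keyed to the product that absorbed them).  Returns the
    (before-bin x after-bin) count matrix and marginals: fraction moved up,
    moved down, and at full coverage afterwards.
    """
    cov_b = _best_subject_coverage(before) if isinstance(before, AlignmentTable) else dict(before)
    cov_a = _best_subject_coverage(after) if isinstance(after, AlignmentTable) else dict(after)
    common = sorted(set(cov_b) & set(cov_a))
    if len(common) < len(cov_b) or len(common) < len(cov_a):
        warnings.warn("query universes differ; restricting to their intersection")
    edges = np.asarray(bins, dtype=float)
    labels = [f"[{lo:.2f},{hi:.2f})" for lo, hi in zip(edges[:-1], edges[1:])]
    b_idx = np.clip(np.searchsorted(edges, [cov_b[q] for q in common], side="right") - 1, 0, len(labels) - 1)
    a_idx = np.clip(np.searchsorted(edges, [cov_a[q] for q in common], side="right") - 1, 0, len(labels) - 1)
    matrix = pd.DataFrame(0, index=labels, columns=labels)
    for bi, ai in zip(b_idx, a_idx):
        matrix.iat[bi, ai] += 1
    n = max(len(common), 1)
    marginals = {
        "moved_up": float(np.sum(a_idx > b_idx)) / n,
        "moved_down": float(np.sum(a_idx < b_idx)) / n,
        "at_full_coverage": float(np.mean([cov_a[q] >= 1.0 for q in common])) if common else 0.0,
    }
    return matrix, marginals


def products_vs_truth(
    products: Sequence[ProteinProduct],
    truth_seqs: Mapping[str, SequenceRecord],
    source_of_segment: Mapping[str, str] | None = None,
) -> AlignmentTable:
    """Analytic product-vs-trusted-proteome alignment from segment provenance.

    For indel-free synthetic data each product segment corresponds to an
    exactly positioned window of the protein its polypeptide came from, so
    the alignment table can be written down instead of running an aligner:
    one HSP per segment, with the identity recomputed from the actual
    residues (a mis-scaffolded segment therefore scores honestly low).
    ``source_of_segment`` maps a polypeptide id to its true source protein;
    by default the product's best-hit subject id is used (valid when the
    reference and trusted proteomes share ids).
    """
    rows: list[HSP] = []
    qlens: dict[str, int] = {}
    slens: dict[str, int] = {s.id: s.length for s in truth_seqs.values()}
    for pp in products:
        qlens[pp.pp_id] = len(pp.sequence)
        gaps_after = {g_lo - 1: n for (g_lo, _), n in pp.gaps}  # keyed by preceding ref end
        pp_pos = 1  # position of the current segment's slice start within the product
        for seg in pp.segments:
            if seg.q_aligned is None:
                pp_pos += seg.length + gaps_after.get(seg.ref_interval[1], 0)
                continue
            sid = (
                source_of_segment.get(seg.query_id, pp.subject_id)
                if source_of_segment
                else pp.subject_id
            )
            truth = truth_seqs.get(sid)
            if truth is None:
                pp_pos += seg.length + gaps_after.get(seg.ref_interval[1], 0)
                continue
            lo, hi = seg.ref_interval
            q_off = seg.q_aligned[0] - seg.query_slice[0]
            pp_start = pp_pos + q_off
            alen = min(hi - lo + 1, seg.q_aligned[1] - seg.q_aligned[0] + 1)
            q_part = pp.sequence[pp_start - 1 : pp_start - 1 + alen]
            s_part = truth.sequence[lo - 1 : lo - 1 + alen]
            alen = min(len(q_part), len(s_part))
            if alen >= 1:
                mm = sum(a != b for a, b in zip(q_part[:alen], s_part[:alen]))
                rows.append(HSP(
                    query_id=pp.pp_id, subject_id=sid,
                    identity_pct=100.0 * (alen - mm) / alen,
                    align_len=alen, mismatch=mm,
                    qstart=pp_start, qend=pp_start + alen - 1,
                    sstart=lo, send=lo + alen - 1,
                    bitscore=2.0 * (alen - mm),
                ))
            pp_pos += seg.length + gaps_after.get(seg.ref_interval[1], 0)
    return AlignmentTable(rows, has_lengths=True, query_lengths=qlens, subject_lengths=slens)


def sweep_evaluation(
    chains_by_query,
    sequences: Mapping[str, SequenceRecord],
    ref_lengths: Mapping[str, int],
    truth_seqs: Mapping[str, SequenceRecord],
    expected: ExpectedGroup,
    triples: Sequence[FilterParams],
    source_of_query: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Run best-hit selection + scaffolding per filter triple and score each.

    Returns a table with columns ``triple, n_retained, n_products, TP, FP,
    FN, Sn, Sp`` — the sensitivity/specificity trade-off across filtering
    stringencies.
    """
    records = []
    for params in triples:
        hits = best_hits_per_query(chains_by_query, params)
        products, _, _ = run_step5(hits, sequences, ref_lengths)
        table = products_vs_truth(products, truth_seqs, source_of_query)
        counts = classify(table, expected, [p.pp_id for p in products])
        records.append({
            "triple": params.triple,
            "n_retained": len(hits),
            "n_products": len(products),
            "TP": counts.TP, "FP": counts.FP, "FN": counts.FN,
            "Sn": counts.Sn, "Sp": counts.Sp,
        })
    return pd.DataFrame.from_records(records)


def length_distribution(
    lengths: Sequence[int], bin_edges: Sequence[float]
) -> tuple[np.ndarray, np.ndarray, float]:
    """Histogram of sequence lengths: (counts, fractions, mean length)."""
    edges = np.asarray(bin_edges, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly ascending")
    arr = np.asarray(lengths, dtype=float)
    if arr.size == 0:
        counts = np.zeros(len(edges) - 1, dtype=int)
        return counts, counts.astype(float), math.nan
    counts, _ = np.histogram(arr, bins=edges)
    return counts, counts / arr.size, float(arr.mean())
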