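"""Best-hit selection: filter chained alignments, rank, pick one hit per query.

Filtering uses the identity/coverage triple with a reference-coverage branch
point: short alignments relative to the reference (subject coverage below
the boundary, default 40%) must cover more of the query, making the filter
more stringent for small fragments.  Retained alignments of a query are
ordered by query coverage, then identity, then subject coverage; the top of
the list is the best hit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .model import ChainedAlignment, FilterParams

__all__ = ["BestHit", "passes_filter", "filter_alignments", "select_best_hit", "sweep_params"]


@dataclass
class BestHit:
    query_id: str
    subject_id: str
    chain: ChainedAlignment

    @property
    def rank_key(self) -> tuple[float, float, float]:
        c = self.chain
        return (c.query_coverage, c.identity_pct, c.subject_coverage)


def passes_filter(chain: ChainedAlignment, params: FilterParams) -> bool:
    if chain.identity_pct < params.min_identity:
        return False
    # boundary: subject coverage exactly at the branch point takes the
    # high-reference-coverage branch ("equal or above")
    if chain.subject_coverage >= params.ref_cov_boundary:
        return chain.query_coverage >= params.min_qcov_high_ref
    return chain.query_coverage >= params.min_qcov_low_ref


def filter_alignments(
    chains: Sequence[ChainedAlignment], params: FilterParams
) -> list[ChainedAlignment]:
    """Retain chains passing the identity and branch-dependent coverage gates."""
    return [c for c in chains if passes_filter(c, params)]


def select_best_hit(retained: Sequence[ChainedAlignment]) -> BestHit | None:
    """Top of the (query coverage, identity, subject coverage) ordering.

    Returns ``None`` on an empty input (the query is filtered out).  A full
    three-key tie is broken by the lexicographically smallest subject id so
    outputs are reproducible regardless of input order.
    """
    if not retained:
        return None
    qid = retained[0].query_id
    if any(c.query_id != qid for c in retained):
        raise ValueError("select_best_hit expects chains of a single query")
    best = min(
        retained,
        key=lambda c: (-c.query_coverage, -c.identity_pct, -c.subject_coverage, c.subject_id),
    )
    return BestHit(query_id=qid, subject_id=best.subject_id, chain=best)


def best_hits_per_query(
    chains_by_query: Mapping[str, Sequence[ChainedAlignment]], params: FilterParams
) -> dict[str, BestHit]:
    """Filter and select the best hit for every query; dropped queries omitted."""
    out: dict[str, BestHit] = {}
    for qid in sorted(chains_by_query):
        hit = select_best_hit(filter_alignments(chains_by_query[qid], params))
        if hit is not None:
            out[qid] = hit
    return out


def sweep_params(
    chains_by_query: Mapping[str, Sequence[ChainedAlignment]],
    triples: Iterable[FilterParams],
) -> pd.DataFrame:
    """Retained-query counts for each filter triple.

    Returns a DataFrame with columns ``triple, n_retained`` (queries with at
    least one chain passing the triple).  With the vacuous triple 0/0/0 every
    aligned query is retained.
    """
    triples = list(triples)
    if not triples:
        raise ValueError("no filter triples supplied")
    records = []
    for params in triples:
        n = sum(
            1 for qid in chains_by_query if filter_alignments(chains_by_query[qid], params)
        )
        records.append({"triple": params.triple, "n_retained": n})
    return pd.DataFrame.from_records(records)
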