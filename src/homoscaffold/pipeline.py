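"""One-command orchestration: chimera screen -> best hit -> scaffolding.

Runs the in-memory pipeline on FASTA + BLAST-tabular inputs, writes the
product FASTA, the per-polypeptide status report and a run manifest, and
returns a summary of counts.  Outputs are a pure function of (inputs,
config); two runs with the same config are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal

import yaml

from . import __version__
from .besthit import best_hits_per_query
from .chimera import apply_chimera_policy, detect_chimera
from .io import parse_blast_tab, read_fasta, write_report
from .model import FilterParams, build_chains
from .scaffold import ProteinProduct, run_step5

__all__ = ["RunConfig", "run_workflow"]


@dataclass
class RunConfig:
    polypeptides: str
    reference: str
    alignments: str
    out_dir: str = "homoscaffold_out"
    filter_triple: str = "80/60/70"
    ref_cov_boundary: float = 0.40
    chimera_min_identity: float = 50.0
    chimera_max_region_cov: float = 0.70
    chimera_policy: Literal["tag", "drop"] = "tag"
    chimera_identity_mode: Literal["chain", "hsp"] = "chain"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    @property
    def filter_params(self) -> FilterParams:
        base = FilterParams.from_triple(self.filter_triple)
        return FilterParams(
            min_identity=base.min_identity,
            min_qcov_high_ref=base.min_qcov_high_ref,
            min_qcov_low_ref=base.min_qcov_low_ref,
            ref_cov_boundary=self.ref_cov_boundary,
        )


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(65536), b""):
            h.update(block)
    return h.hexdigest()


def _write_products(products: list[ProteinProduct], path: Path) -> None:
    with open(path, "w") as fh:
        for pp in sorted(products, key=lambda p: p.pp_id):
            fh.write(f">{pp.pp_id} subject={pp.subject_id} components={pp.n_components}\n")
            for i in range(0, len(pp.sequence), 60):
                fh.write(pp.sequence[i : i + 60] + "\n")


def run_workflow(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the summary dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    polys = read_fasta(config.polypeptides)
    refs = read_fasta(config.reference)
    table = parse_blast_tab(config.alignments)
    table.attach_lengths(queries=polys, subjects=refs)

    chains_by_query = build_chains(
        table.rows, query_lengths=table.query_lengths, subject_lengths=table.subject_lengths
    )

    calls = [
        detect_chimera(
            chains_by_query[qid],
            min_identity=config.chimera_min_identity,
            max_region_cov=config.chimera_max_region_cov,
            identity_mode=config.chimera_identity_mode,
        )
        for qid in sorted(chains_by_query)
    ]
    proceeding, flagged = apply_chimera_policy(calls, policy=config.chimera_policy)

    params = config.filter_params
    best_hits = best_hits_per_query(
        {q: chains_by_query[q] for q in sorted(proceeding)}, params
    )

    seq_by_id = {r.id: r for r in polys}
    ref_lengths = {r.id: r.length for r in refs}
    products, step5_status, redundancy_factor = run_step5(best_hits, seq_by_id, ref_lengths)

    pp_of_query = {
        seg.query_id: pp.pp_id for pp in products for seg in pp.segments
    }
    for qid, hit in best_hits.items():
        if step5_status.get(qid) == "redundant":
            pp_of_query.setdefault(qid, ".")

    rows = []
    for rec in polys:
        qid = rec.id
        if qid in step5_status:
            status = step5_status[qid]
        elif qid in flagged and config.chimera_policy == "drop":
            status = "chimeric"
        elif qid in chains_by_query:
            status = "filtered_out"
        else:
            status = "unaligned"
        hit = best_hits.get(qid)
        rows.append({
            "polypeptide_id": qid,
            "status": status,
            "best_hit_id": hit.subject_id if hit else ".",
            "pp_id": pp_of_query.get(qid, "."),
            "q_interval": f"{hit.chain.q_interval[0]}-{hit.chain.q_interval[1]}" if hit else ".",
            "s_interval": f"{hit.chain.s_interval[0]}-{hit.chain.s_interval[1]}" if hit else ".",
            "chimera_flag": 1 if qid in flagged else 0,
        })

    pp_path = out / "pp.fasta"
    report_path = out / "report.tsv"
    _write_products(products, pp_path)
    report = write_report(rows, report_path)

    counts = report["status"].value_counts().to_dict()
    summary = {
        "n_polypeptides": len(polys),
        "status_counts": {s: int(counts.get(s, 0)) for s in sorted(counts)},
        "n_chimeric_flagged": len(flagged),
        "n_best_hit_queries": len(best_hits),
        "n_products": len(products),
        "redundancy_factor": redundancy_factor,
        "mean_product_length": (
            sum(len(p.sequence) for p in products) / len(products) if products else None
        ),
        "filter_triple": params.triple,
    }
    manifest = {
        "tool": "homoscaffold",
        "version": __version__,
        "config": asdict(config),
        "inputs": {
            name: _sha256(getattr(config, name))
            for name in ("polypeptides", "reference", "alignments")
        },
        "summary": summary,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
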