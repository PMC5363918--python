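"""Seeded synthetic benchmark: proteomes, fragments, redundancy, chimeras.

The generator emulates the error structure of a de novo transcriptome
translated to polypeptides:

- a *trusted proteome* of the target species (random proteins, acting as
  the gold standard the evaluation aligns back to);
- a *reference proteome* of a related species — each target protein with a
  fixed per-residue substitution divergence (no indels, so ground-truth
  coordinates stay exact);
- *polypeptides*: overlapping fragments tiling each target protein, with
  random unalignable terminal extensions (mimicking mistranslated UTR),
  duplicated ``copies`` times (redundancy), plus *chimeras* fusing fragments
  of two different proteins;
- the exact fragment-to-reference alignment table with analytically
  computed identities and coordinates — no aligner is invoked.

Reference and trusted-proteome entries share ids (orthologs are 1:1 by
construction), which keeps ground-truth bookkeeping trivial.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .io import AlignmentTable, write_blast_tab, write_fasta
from .model import AMINO_ACIDS, HSP, SequenceRecord

__all__ = ["SimulationPlan", "SimulationData", "simulate", "score_against_truth"]

TRUTH_COLUMNS = (
    "polypeptide_id source_protein ref_start ref_end n_substitutions is_chimera chimera_parts"
).split()


@dataclass(frozen=True)
class SimulationPlan:
    """Study conditions for one synthetic benchmark run.

    Defaults model a moderately diverged reference species (5% amino-acid
    substitutions), light fragmentation (1–3 overlapping fragments per
    protein), four-fold redundancy, about 1% chimerism, and unalignable
    terminal extensions of up to 30% of a fragment's length.
    """

    n_proteins: int = 500
    length_dist: tuple[float, float] = (400.0, 150.0)  # mean, sd in residues
    min_protein_len: int = 80
    divergence: float = 0.05
    fragments_per_protein: tuple[int, int] = (1, 3)
    overlap_run: tuple[int, int] = (5, 30)
    copies: int = 4
    chimera_rate: float = 0.01
    chimera_part_max_frac: float = 0.65
    terminal_extension: tuple[float, float] = (0.0, 0.30)
    fragment_dropout: float = 0.0
    min_fragment_len: int = 30
    seed: int = 42

    def __post_init__(self) -> None:
        for name in ("divergence", "chimera_rate", "fragment_dropout"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.5 <= self.chimera_part_max_frac <= 1.0:
            raise ValueError("chimera_part_max_frac must be in [0.5, 1]")
        if self.copies < 1 or self.n_proteins < 1:
            raise ValueError("copies and n_proteins must be >= 1")


@dataclass
class SimulationData:
    plan: SimulationPlan
    reference: list[SequenceRecord]
    targets: list[SequenceRecord]
    polypeptides: list[SequenceRecord]
    alignments: AlignmentTable          # polypeptides vs reference proteome
    poly_vs_truth: AlignmentTable       # polypeptides vs trusted proteome
    ref_vs_truth: AlignmentTable        # reference proteome vs trusted proteome
    truth: pd.DataFrame

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "ref": out / "ref.fasta",
            "targets": out / "targets.fasta",
            "polypeptides": out / "polypeptides.fasta",
            "alignments": out / "alignments.tsv",
            "poly_vs_truth": out / "poly_vs_truth.tsv",
            "ref_vs_truth": out / "ref_vs_truth.tsv",
            "truth": out / "truth.tsv",
        }
        write_fasta(self.reference, paths["ref"])
        write_fasta(self.targets, paths["targets"])
        write_fasta(self.polypeptides, paths["polypeptides"])
        for key, table in (
            ("alignments", self.alignments),
            ("poly_vs_truth", self.poly_vs_truth),
            ("ref_vs_truth", self.ref_vs_truth),
        ):
            write_blast_tab(table.rows, paths[key], table.query_lengths, table.subject_lengths)
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def _mutate(rng: np.random.Generator, seq: str, divergence: float) -> tuple[str, int]:
    """Substitute a Binomial(L, divergence) number of residues; no indels."""
    n_sub = rng.binomial(len(seq), divergence)
    if n_sub == 0:
        return seq, 0
    positions = rng.choice(len(seq), size=n_sub, replace=False)
    out = list(seq)
    for p in positions:
        choices = [a for a in AMINO_ACIDS if a != out[p]]
        out[p] = choices[rng.integers(len(choices))]
    return "".join(out), n_sub


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _tile(rng: np.random.Generator, length: int, plan: SimulationPlan) -> list[tuple[int, int]]:
    """Overlapping fragment intervals (1-based inclusive) tiling [1, length]."""
    fmin, fmax = plan.fragments_per_protein
    n_frag = int(rng.integers(fmin, fmax + 1))
    min_block = plan.min_fragment_len
    n_frag = max(1, min(n_frag, length // min_block))
    if n_frag == 1:
        return [(1, length)]
    spare = length - n_frag * min_block
    cuts = np.sort(rng.integers(0, spare + 1, size=n_frag - 1))
    sizes = min_block + np.diff(np.concatenate(([0], cuts, [spare])))
    bounds = np.concatenate(([0], np.cumsum(sizes)))
    intervals = []
    for i in range(n_frag):
        start, end = int(bounds[i]) + 1, int(bounds[i + 1])
        if i < n_frag - 1:
            end = min(end + int(rng.integers(plan.overlap_run[0], plan.overlap_run[1] + 1)), length)
        intervals.append((start, end))
    return intervals


def _hsp_row(qid: str, sid: str, qseq_part: str, sseq_part: str,
             qstart: int, sstart: int) -> HSP:
    mm = _hamming(qseq_part, sseq_part)
    alen = len(qseq_part)
    return HSP(
        query_id=qid, subject_id=sid,
        identity_pct=round(100.0 * (alen - mm) / alen, 3),
        align_len=alen, mismatch=mm, gapopen=0,
        qstart=qstart, qend=qstart + alen - 1,
        sstart=sstart, send=sstart + alen - 1,
        evalue=1e-60, bitscore=round(2.0 * (alen - mm), 1),
    )


def simulate(plan: SimulationPlan) -> SimulationData:
    """Generate the full synthetic benchmark for one plan (deterministic in seed)."""
    rng = np.random.default_rng(plan.seed)
    mean, sd = plan.length_dist

    targets: list[SequenceRecord] = []
    reference: list[SequenceRecord] = []
    n_subs: dict[str, int] = {}
    for i in range(plan.n_proteins):
        pid = f"PROT{i:05d}"
        length = max(plan.min_protein_len, int(round(rng.normal(mean, sd))))
        tseq = _random_protein(rng, length)
        rseq, ns = _mutate(rng, tseq, plan.divergence)
        targets.append(SequenceRecord(pid, tseq))
        reference.append(SequenceRecord(pid, rseq))
        n_subs[pid] = ns

    tgt_by_id = {r.id: r.sequence for r in targets}
    ref_by_id = {r.id: r.sequence for r in reference}

    polys: list[SequenceRecord] = []
    aln_rows: list[HSP] = []
    truth_rows: list[dict] = []
    vs_truth_rows: list[HSP] = []

    emin, emax = plan.terminal_extension
    for rec in targets:
        intervals = _tile(rng, len(rec.sequence), plan)
        keep = [rng.random() >= plan.fragment_dropout for _ in intervals]
        if not any(keep):
            keep[0] = True
        for f, ((a, b), kept) in enumerate(zip(intervals, keep)):
            # extensions drawn for every tiled fragment so the residue
            # stream (and thus downstream fragments) is dropout-independent
            frag = rec.sequence[a - 1 : b]
            total_frac = rng.uniform(emin, emax)
            left_share = rng.uniform(0.0, 1.0)
            ext_n = _random_protein(rng, int(round(total_frac * left_share * len(frag))))
            ext_c = _random_protein(rng, int(round(total_frac * (1 - left_share) * len(frag))))
            if not kept:
                continue
            seq = ext_n + frag + ext_c
            for c in range(plan.copies):
                qid = f"{rec.id}.F{f}.C{c}"
                polys.append(SequenceRecord(qid, seq))
                aln_rows.append(
                    _hsp_row(qid, rec.id, frag, ref_by_id[rec.id][a - 1 : b], len(ext_n) + 1, a)
                )
                vs_truth_rows.append(_hsp_row(qid, rec.id, frag, frag, len(ext_n) + 1, a))
                truth_rows.append({
                    "polypeptide_id": qid, "source_protein": rec.id,
                    "ref_start": a, "ref_end": b,
                    "n_substitutions": _hamming(frag, ref_by_id[rec.id][a - 1 : b]),
                    "is_chimera": 0, "chimera_parts": ".",
                })

    # chimera_rate is the chimeric fraction of the emitted polypeptide set:
    # n_chim / (n_base + n_chim) == rate; at rate 1 only chimeras are emitted
    if plan.chimera_rate >= 1.0:
        n_chim = len(polys)
        polys, aln_rows, truth_rows, vs_truth_rows = [], [], [], []
    else:
        rate = plan.chimera_rate
        n_chim = int(round(rate / (1.0 - rate) * len(polys)))
    mf = plan.chimera_part_max_frac
    for j in range(n_chim):
        for _ in range(100):
            ia, ib = rng.choice(plan.n_proteins, size=2, replace=False)
            ta, tb = targets[int(ia)], targets[int(ib)]
            len1 = int(rng.integers(plan.min_fragment_len + 20,
                                    min(150, len(ta.sequence)) + 1))
            lo = int(np.ceil(len1 * (1 - mf) / mf))
            hi = int(np.floor(len1 * mf / (1 - mf)))
            lo = max(lo, plan.min_fragment_len)
            hi = min(hi, len(tb.sequence))
            if lo > hi:
                continue
            len2 = int(rng.integers(lo, hi + 1))
            total = len1 + len2
            if max(len1, len2) / total > mf:
                continue
            s1 = int(rng.integers(1, len(ta.sequence) - len1 + 2))
            s2 = int(rng.integers(1, len(tb.sequence) - len2 + 2))
            break
        else:
            raise RuntimeError("could not place chimera parts under the plan's constraints")
        part1 = ta.sequence[s1 - 1 : s1 - 1 + len1]
        part2 = tb.sequence[s2 - 1 : s2 - 1 + len2]
        qid = f"CHIM{j:05d}"
        polys.append(SequenceRecord(qid, part1 + part2))
        for (pid, part, s, qstart) in ((ta.id, part1, s1, 1), (tb.id, part2, s2, len1 + 1)):
            aln_rows.append(
                _hsp_row(qid, pid, part, ref_by_id[pid][s - 1 : s - 1 + len(part)], qstart, s)
            )
            vs_truth_rows.append(_hsp_row(qid, pid, part, part, qstart, s))
        truth_rows.append({
            "polypeptide_id": qid, "source_protein": ta.id,
            "ref_start": s1, "ref_end": s1 + len1 - 1,
            "n_substitutions": _hamming(part1, ref_by_id[ta.id][s1 - 1 : s1 - 1 + len1]),
            "is_chimera": 1,
            "chimera_parts": f"{ta.id}:{s1}-{s1 + len1 - 1};{tb.id}:{s2}-{s2 + len2 - 1}",
        })

    qlens = {r.id: r.length for r in polys}
    tlens = {r.id: r.length for r in targets}
    rlens = {r.id: r.length for r in reference}
    alignments = AlignmentTable(aln_rows, has_lengths=True,
                                query_lengths=dict(qlens), subject_lengths=dict(rlens))
    poly_vs_truth = AlignmentTable(vs_truth_rows, has_lengths=True,
                                   query_lengths=dict(qlens), subject_lengths=dict(tlens))
    rvt_rows = [
        _hsp_row(r.id, r.id, r.sequence, tgt_by_id[r.id], 1, 1) for r in reference
    ]
    ref_vs_truth = AlignmentTable(rvt_rows, has_lengths=True,
                                  query_lengths=dict(rlens), subject_lengths=dict(tlens))
    truth = pd.DataFrame(truth_rows, columns=list(TRUTH_COLUMNS))
    return SimulationData(
        plan=plan, reference=reference, targets=targets, polypeptides=polys,
        alignments=alignments, poly_vs_truth=poly_vs_truth,
        ref_vs_truth=ref_vs_truth, truth=truth,
    )


def score_against_truth(
    report: pd.DataFrame | str | Path,
    truth: pd.DataFrame | str | Path,
    ref_lengths: Mapping[str, int] | None = None,
) -> dict[str, float]:
    """Recovery metrics of a pipeline run against the generator's ground truth.

    Reports the fraction of fragmented source proteins reconstructed as a
    product, chimera recall/precision and the false-flag rate on clean
    polypeptides, the observed redundancy factor, and (when reference
    lengths are supplied) the mean product coverage of its source protein.
    """
    if not isinstance(report, pd.DataFrame):
        report = pd.read_csv(report, sep="\t", dtype={"q_interval": str, "s_interval": str})
    if not isinstance(truth, pd.DataFrame):
        truth = pd.read_csv(truth, sep="\t")
    missing = set(truth["polypeptide_id"]) - set(report["polypeptide_id"])
    if missing:
        raise ValueError(f"polypeptides missing from report: {sorted(missing)[:3]}")

    merged = report.merge(truth, on="polypeptide_id", how="left")
    clean = merged[merged["is_chimera"] == 0]
    sources = set(clean["source_protein"])
    in_pp = clean["status"].isin(["component", "singleton_pp"])
    recovered = set(clean.loc[in_pp, "best_hit_id"])
    flagged = merged["chimera_flag"].astype(int) == 1
    is_chim = merged["is_chimera"].fillna(0).astype(int) == 1
    n_chim = int(is_chim.sum())
    n_flag = int(flagged.sum())
    metrics = {
        "protein_recovery": len(recovered & sources) / len(sources) if sources else float("nan"),
        "chimera_recall": float((flagged & is_chim).sum()) / n_chim if n_chim else float("nan"),
        "chimera_precision": float((flagged & is_chim).sum()) / n_flag if n_flag else float("nan"),
        "false_flag_rate": float((flagged & ~is_chim).sum()) / int((~is_chim).sum())
        if int((~is_chim).sum()) else float("nan"),
        "n_products": float(report.loc[report["pp_id"] != ".", "pp_id"].nunique()),
    }
    best_hit_rows = merged["status"].isin(["component", "singleton_pp", "redundant"])
    n_pp = metrics["n_products"]
    metrics["redundancy_factor"] = float(best_hit_rows.sum()) / n_pp if n_pp else float("nan")
    if ref_lengths is not None:
        covs = []
        comp = merged[merged["status"].isin(["component", "singleton_pp"])]
        for (pp_id, sid), rows in comp.groupby(["pp_id", "best_hit_id"]):
            positions: set[int] = set()
            for iv in rows["s_interval"]:
                lo, hi = (int(x) for x in str(iv).split("-"))
                positions.update(range(lo, hi + 1))
            covs.append(len(positions) / ref_lengths[sid])
        metrics["mean_pp_ref_coverage"] = float(np.mean(covs)) if covs else float("nan")
    return metrics
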