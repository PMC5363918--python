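# Methods

## Problem and model

De novo transcriptome assemblies of species without a reference genome
yield polypeptide sets with three systematic defects: *fragmentation* (one
gene's product split over several contigs), *redundancy* (alternative
transcripts, alleles and near-identical copies), and *chimerism* (one
contig fusing parts of two genes).  When a related, well-annotated species
is available, its proteome can arbitrate all three: fragments of one
protein share a best hit, redundant copies cover the same reference
region, and chimeras align disjoint regions to different references.

The pipeline consumes protein-vs-protein local alignments (BLAST tabular)
of the polypeptides against the reference proteome and proceeds in three
stages.

**Chaining.** All HSPs of one (polypeptide, reference) pair are reduced to
a single chained alignment: the colinear subset — consistent ordering on
both sequences, at most one shared residue between members on either axis —
that maximises the number of aligned query residues, with ties broken by
total bitscore, then by fewer HSPs.  The overlap rule is applied on the
query *and* subject axes; a subject-only reading would allow the same
reference region to be counted twice.  A chain's identity is the
alignment-length-weighted mean of its members' identities, and coverage is
always a union of positions divided by sequence length, so it cannot
exceed 1.  Chaining is solved exactly by dynamic programming over HSPs
sorted by query start; transitivity of the pairwise compatibility relation
makes consecutive-pair checks sufficient.

**Chimera screen.** Among a query's chains with identity ≥ 50%, the query
is tagged chimeric when two chains hit different references over disjoint
query regions and no chain covers more than 70% of the query.  Disjoint
means zero shared residues by default (`max_region_overlap` relaxes this).
The identity screen is applied at chain level by default, which keeps it
consistent with the coverage logic downstream; a per-HSP mode
(`identity_mode="hsp"`) screens individual HSPs and re-chains the
survivors.  Tagged sequences stay in the pipeline (`tag` policy, the
default) because downstream filtering and redundancy reduction remove most
of them anyway; `drop` removes them before best-hit selection.

**Best hit.** A chain is retained when identity ≥ 80% and query coverage
clears a branch-dependent bound: ≥ 60% when the chain covers at least 40%
of the reference, ≥ 70% otherwise — stricter for short fragments, whose
assignment is intrinsically less certain.  Subject coverage exactly at the
40% boundary takes the high-coverage branch.  Retained chains are ordered
by (query coverage, identity, subject coverage) descending; the top is the
best hit, with a full tie broken by the smallest subject id so outputs are
order-independent.

**Redundancy and scaffolding.** Polypeptides sharing a best-hit reference
form a group.  The non-redundant members are the smallest subset whose
aligned reference positions reproduce the whole group's position union —
each retained member is the best cover of its region of the reference.
This minimum positional cover is computed exactly: duplicate and nested
footprints are discarded first (keeping the higher-identity, then longer,
then lexicographically first member), a pruned greedy cover seeds an upper
bound, and a branch-and-bound search over the remaining candidates
certifies minimality.  A plain max-gain greedy is *not* minimum-cardinality
on "bridge" configurations (a middle fragment picked first although the
flanking pair covers everything), which is why the exact search exists;
groups with more than 40 distinct maximal footprints — far beyond
realistic redundancy levels — fall back to the pruned greedy.

Retained members sorted by first aligned reference position are joined
pairwise.  Overlapping neighbours are cut at the rightmost reference
residue both alignments cover: the left member contributes residues
mapping to the reference at or before the cut, the right member after it
(keeping the longer prefix intact).  Reference-to-query mapping uses the
btop traceback when present and linear interpolation within the covering
HSP otherwise; a cut landing between two HSPs falls back to the nearest
mappable position leftward with a warning.  Neighbours `n ≥ 1` uncovered
reference residues apart are joined with `n` X residues
(`n = next_start − prev_end − 1`, so abutting intervals join directly).
Unaligned query termini are kept at the outer ends of a product (and a
single-member product is its polypeptide verbatim) but trimmed at
junctions, preventing duplicated overlap sequence.  Three-way overlaps are
handled pairwise-consecutively.

## Evaluation protocol

The gold standard ("expected group") is the subset of a trusted proteome
of the target species evidenced twice over: some polypeptide aligns to the
protein with identity > 60 and coverage > 0.70, and some reference-species
protein does too.  The coverage condition is measured on the query side
(the aligned polypeptide / reference protein) by default — the condition
asks whether the aligned sequence is substantially explained by the truth
protein; a `coverage_side="subject"` option measures it on the truth
protein instead.  Products are then aligned back to the trusted proteome:
TP = products with a significant hit (identity ≥ 60, expected-protein
coverage ≥ 0.70) to an expected protein, FP = products with none, FN =
expected proteins never hit.  Construction uses strict inequalities and
classification non-strict ones; both follow the protocol as stated and are
deliberately not harmonised.  A product matching several expected proteins
counts once as TP while covering all matched proteins.  Sn = TP/(TP+FN),
Sp = TP/(TP+FP); Sp is NaN (with a warning) when there are no products.

For synthetic data the product-vs-truth table is built analytically from
segment provenance rather than by running an aligner: each product segment
maps to an exactly known window of its source protein (the generator plants
no indels), and identities are recomputed from the actual residues, so a
mis-scaffolded segment scores honestly low.

## Synthetic benchmark

The generator emulates the study conditions end to end with substitutions
only — no indels — so ground-truth coordinates stay exact (indel modes are
a non-goal).  Defaults, chosen once as realistic for a plant-proteome
setting:

| parameter | default | rationale |
|---|---|---|
| `n_proteins` | 500 | large enough for stable rates, seconds to run |
| `length_dist` | (400, 150) aa | typical plant protein length scale |
| `divergence` | 0.05 | congeneric reference species (≈95% identity) |
| `fragments_per_protein` | (1, 3) | most transcripts near full length, a minority fragmented |
| `overlap_run` | (5, 30) aa | assembler fragments overlap by short runs |
| `copies` | 4 | observed redundancy factors cluster near four |
| `chimera_rate` | 0.01 | ≈1% chimerism, the level seen in real assemblies |
| `chimera_part_max_frac` | 0.65 | parts stay under the 70% dominant-alignment veto |
| `terminal_extension` | (0.0, 0.30) | unalignable termini from mistranslated UTR |
| `fragment_dropout` | 0.0 | optional stress knob producing interior X gaps |

`chimera_rate` is the chimeric fraction of the emitted polypeptide set
(rate 1 emits only chimeras).  Copies are identical duplicates, so a
planted copy number is recovered exactly as the redundancy factor when
each protein yields one fragment.  Reference and trusted-proteome entries
share ids (orthologs are 1:1 by construction).  The alignment tables are
written analytically in the extended BLAST tabular dialect (qlen/slen), so
the parsers and the full pipeline are exercised without an aligner.

What the generator does **not** emulate: indels and frameshifts, paralog
families and cross-homology between reference proteins (so spurious
secondary hits never occur), expression-dependent fragment abundance, and
sequencing error.  Passing tests therefore demonstrate the correctness of
the combinatorial and bookkeeping machinery under the stated error
structure, not robustness to alignment noise between distant homologs.

## Numerical and design choices

- Coordinates are 1-based inclusive throughout, as in BLAST tabular.
- Interpolated coordinate mapping rounds half up (`floor(x+0.5)`), avoiding
  Python's banker's rounding for reproducibility.
- A reference position aligned to a query-gap btop column maps to the
  nearest query residue on its left.
- Sequence lengths may come from extended BLAST columns or FASTA; a
  conflict between the two is an error, never a silent preference.
- The run manifest records the tool version, the echoed config and SHA-256
  checksums of all inputs; statuses (`unaligned`, `filtered_out`,
  `chimeric`, `redundant`, `component`, `singleton_pp`) partition the
  input, with chimera tags carried in a separate report column under the
  default `tag` policy.
- Test and benchmark problem sizes (tens to hundreds of proteins, ~4,000
  polypeptides) keep the whole suite in seconds while leaving every rate
  estimated from hundreds of events.

## Known limitations

- Products never merge across reference proteins, so a gene absent from
  the reference proteome cannot be reconstructed (orphan genes stay
  unaligned), and paralog fusion is out of scope.
- The minimum-cover tie among equal-cardinality solutions is resolved by
  search order (deterministic, but not guaranteed to maximise summed
  identity over the retained set).
- Chimera breakpoints are not resolved into two repaired sequences; the
  screen only tags, and scaffolding may incidentally cut a chimera at a
  junction.
- The evaluation's Sn mixes product counts (TP) with protein counts (FN),
  as the protocol defines; with heavy many-to-one matching the two scales
  can diverge.
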