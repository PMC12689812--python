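# Methods

## The detection model

A somatic variant creates a tumour-exclusive SpCas9 site when it completes
an NGG PAM absent from the reference. Because the N of NGG matches any
base, only the GG dinucleotide matters: the operational rule for SNVs is
*adjacency* — an alt G with a reference G at the 5′ or 3′ neighbour creates
a plus-strand GG; an alt C with a neighbouring reference C creates a CC,
which is a GG read on the minus strand. Each qualifying dinucleotide is one
candidate, because each defines a distinct Cas9 docking position: a GAG→GGG
change therefore emits two candidates, one per new dinucleotide. Novelty
holds by construction (ref ≠ alt) and is still re-verified against the
reference dinucleotide, so no emitted candidate can be non-novel.

The 20-nt protospacer is read 5′ of the PAM on the PAM strand. For
SNV-created sites the edited base sits inside the PAM, never inside the
protospacer, so the protospacer is identical between the reference and the
tumour haplotype — a property the tests assert (the guide sequence occurs
verbatim in the reference; exclusivity comes from the PAM). Candidates
within 20 bp of a contig end are dropped and counted: a guide needs its full
spacer.

Variants are evaluated independently against the reference; phasing of
nearby somatic variants is ignored. Each sample's candidates are
deduplicated on (contig, dinucleotide start, strand) with all creating
variants kept in the provenance.

### Indels

Insertions and deletions with a length change below 300 bp are accepted.
The detection rule rescans the alternate haplotype over ±25 bp around the
edit (`window_halfwidth`, configurable) and emits one candidate per GG/CC
dinucleotide that is not already present at its reference-aligned position:
bases left of the edit map unchanged, bases right of it shift by the length
difference, inserted bases have no reference position (left-normalised
indels are assumed, sharing their anchor base with the reference). Because
dinucleotides far from the edit map exactly and match the reference, the
mapping rule alone confines candidates to the edited neighbourhood. These
candidates are flagged `indel_derived` so downstream users can filter them;
the SNV adjacency rule is the better-characterised pathway and the indel
rescan is this package's own operationalisation of indel support.

## Guide scores

Specificity aggregates per-off-target similarities `s ∈ [0, 1]` as
`100 / (1 + Σ s)` over all hits except the intended site: 100 means no
predicted off-target burden, and the score strictly decreases with every
added hit. Two per-hit models are provided:

* **CFD-style**: `s = Π penalty(position, guide base, off-target base) ×
  PAM-class penalty`. Position/identity-dependent penalties load from a TSV
  (`PenaltyModel.from_tsv`; columns position/ref_base/obs_base/penalty with
  `PAM` rows for PAM-class penalties). The in-repo default is the uniform
  model — every mismatch 0.5, non-NGG PAM 0.5 — which preserves all the
  structural properties (empty product = 1, monotone aggregation) without
  shipping a penalty table; for publication-grade numbers either supply the
  published table or import precomputed scores.
* **MIT-style**: `s = Π (1 − W[pos]) × 1/(((19 − d̄)/19)·4 + 1) × 1/m²` with
  the classic 20-position weight vector (PAM-distal position 1), `d̄` the
  mean distance between neighbouring mismatch positions and `m` the
  mismatch count; a lone mismatch uses only its position weight.

Off-target enumeration is a brute-force scan of both strands for NGG and
NAG PAMs with up to 4 mismatches and no bulges (CRISPOR-family defaults),
vectorised with numpy sliding windows; it is intended for desk-scale
genomes (the tests cross-check it against a naive Hamming oracle up to
200 kb). On-target flagging uses a supplied locus when known, otherwise the
first perfect hit in position order.

Efficiency scores (Doench- and Moreno-style, 0–100) are imported from a
precomputed per-guide table — the fidelity path, since these regressions are
external models — with missing guides feeding the ranking's missing-value
rule. A deterministic built-in surrogate (smooth GC-optimum term plus small
position heuristics) exists only so synthetic fixtures run end to end; it is
documented as non-publication-grade and never stands in for a trained
model.

## Annotation

Gene assignment uses the gene span, not exons: intronic sites still carry
gene-level expression, copy number and dependency. When spans overlap, the
most highly expressed gene wins (missing expression sorts last, remaining
ties break lexicographically) and alternates are recorded. Copy number is
taken per gene. Dependency follows the DepMap convention — ≤ −0.5 depleting,
≤ −1 strongly lethal, 0 non-essential — exposed as a qualitative label on
the record. Annotation never alters discovery fields and preserves the
candidate count; a candidate without a gene has all gene-keyed features
missing.

## Ranking

Each of the seven features is ranked within the sample from 1 (worst) to
*n* (best). Higher values are better for all seven — for dependency a higher
(less negative) score means a less essential gene and hence a safer edit.
Tie handling is the average-rank convention: it preserves rank-sum totals,
keeping composites comparable across tie patterns. Missing values all
receive rank 1 and share it; the non-missing entries occupy the ranks above
the missing block (so `[missing, 10, 20] → [1, 2, 3]`).

The composite is the weighted rank sum
`2·CFD + MIT + 0.5·(Doench + Moreno) + dependency + expression + copy
number` (weights configurable). The doubled CFD weight prioritises
specificity, i.e. safety; the two efficiency ranks are folded into a single
half-weighted term because sequence-based efficiency predictors are the
least reliable features. Scores are min–max normalised to 0–100 within the
sample; a lone candidate or an all-tied dataset is defined as 100 (a lone
candidate is trivially the sample's most promising site). Final ranks run
from 1 (best) downward with shared ties (competition ranking).

The sample report applies two default thresholds: at least 86 novel PAM
sites per sample (feasibility — samples below this rarely offer top
candidates with high specificity) and, for the top-3 candidates, CFD > 90
and MIT > 80 (safety). A missing specificity score fails its cut.

## Breakpoint junctions

Junction windows are 60-mers: 30 retained nucleotides per side,
reverse-complemented where the reported orientation requires it, so the
joined sequence reads 5′→3′ across the junction as on the derivative
chromosome. Positions are numbered −30…−1 and +1…+30 with no position 0;
the index↔position mapping is bijective and tested as such. Flanks within
30 bp of a contig end are N-padded with a warning, and candidates whose
guide would include an N are dropped.

Junction-created PAMs are restricted to the (−1, +1) dinucleotide exactly:
GG gives an NGG candidate with guide −22…−3 (N at −2), CC gives a CCN
candidate with guide = reverse complement of +3…+22. Novelty requires that
*neither* wild-type context already supplies the partner base at the same
offset — the base natively following the left flank and the base natively
preceding the right flank are both checked against G (or C).

Spanning guides come from NGG motifs whose N sits at +6…+16 and CCN motifs
whose first C sits at −18…−8; these readings (N-based and first-C-based)
are the ones that make the two ranges strand-symmetric and keep both
junction overlaps within 5–15 nt. Guides must read at least 4 nt from each
side of the junction, which is the operational tumour-specificity criterion
for this class: no genome-wide uniqueness search is required (an off-target
check through the scoring module can be layered on). Junctions are modelled
as clean joins; microhomology and non-templated insertions at real
junctions are a known limitation. Per breakpoint, spanning guides are
deduplicated against junction-created PAMs on (motif, guide).

Breakpoint input positions are 1-based and name the junction-adjacent
retained base per side (see README for the strand semantics); the BEDPE
resemblance is in the column layout, not the 0-based BED convention.

## Cohort statistics

Variant-derived sites are keyed (contig, GG start, strand); junction
candidates are keyed (motif, guide sequence) because junction coordinates
differ between patients for the same biological target. The recurrence rate
is the fraction of site-occurrences belonging to sites observed in at least
two patients: from a multiplicity histogram `{m: sites}` over `T` total
occurrences, `rate = Σ_{m≥2} m·sites / T`. This occurrence-weighted
definition is adopted because it is the unique simple definition consistent
with both published cohort rates (120/8750 ≈ 1.4% for SNV-derived sites;
102/1818 ≈ 5.6% for SV/ecDNA-derived sites); site-weighted alternatives
(56/8750, 51/1818) reproduce neither.

## Synthetic data

The generator emulates the pipeline's inputs with guaranteed-detectable
planted events: every plant writes its required context into the genome
(e.g. a plus-strand PAM SNV forces a reference G at the 3′ neighbour and
non-G at the site and 5′ neighbour, so the alt G creates exactly one novel
GG) and every neutral event is rejection-sampled against the detection
scanners rather than assumed neutral, guaranteeing a clean false-positive
surface. Planted events occupy positions at least 60 bp apart so their
3-bp edits never interact. Defaults describe one 100-kb contig at 41% GC
with 10 planted PAM SNVs (5 per strand class) among 90 neutral SNVs — a
per-sample scale chosen so the whole suite runs in seconds while matching
the order of magnitude of exonic variant counts in a low-burden paediatric
tumour. Feature values are drawn independently per gene (TPM log-normal
with log-mean 1.5 and log-sd 1.2, copy number uniform on 0…8, dependency
uniform on [−2, 0.5]); no correlation structure, mutational signatures,
chromosome-level clustering or real base composition are modelled. Passing
the planted-recovery tests therefore demonstrates correctness of the
detection logic under the stated rules, not performance on real tumour
sequencing data, where variant-calling noise, germline contamination and
soft-masked or repetitive context dominate.

All randomness flows from a single integer seed (numpy `default_rng`); the
same spec yields byte-identical files.

## Numerical choices and degenerate inputs

* One internal coordinate convention (0-based half-open) with conversion at
  the parsers, preventing off-by-one drift; VCF/GTF are 1-based on disk.
* Soft-masked (lowercase) reference sequence is treated as normal sequence;
  characters outside ACGTN map to N, and N never matches a PAM base or a
  guide base.
* Variants whose ref allele mismatches the genome are skipped with a
  warning and counted, not fatal — this catches genome-build errors while
  letting toy genomes through.
* Empty candidate sets: ranking raises (`no candidates`), discovery and the
  junction analysis return empty results with zeroed counters.
* Score sums in the specificity aggregation validate `s ∈ [0, 1]` and the
  aggregation is exactly 100 for an empty hit list.
* Verification sizes: oracle equivalence runs 20 seeds × 1,000 SNVs on
  100-kb genomes, ranking equivalence 100 random 50-candidate tables, and
  off-target enumeration is cross-checked on genomes up to 200 kb — sizes
  at which the brute-force oracles are exact and fast.

## Known limitations

* NGG PAMs only (SpCas9); other Cas variants' PAMs are out of scope.
* No germline-variant awareness: novelty is relative to the reference, so a
  patient's private germline variant could in principle pre-create a "novel"
  dinucleotide. Tumour/normal-aware calling upstream mitigates this.
* No bulge-tolerant off-target alignment and no genome-scale FM-index
  search; the enumerator is exact but brute-force.
* Indel-created PAM detection is this package's operationalisation (flagged
  in output); junction analysis assumes clean joins.
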