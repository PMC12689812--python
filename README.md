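# neopam

Tumour genomes carry somatic events their matched normal tissue lacks. When a
somatic variant creates a new `GG` dinucleotide (or a `CC`, read as `GG` on
the minus strand), it completes a 5′-NGG-3′ protospacer adjacent motif (PAM)
that SpCas9 requires for cleavage — and that exists *only* in the tumour.
Such **novel PAM sites** are tumour-exclusive CRISPR-Cas9 docking sites: a
guide RNA targeting the adjacent 20-nt protospacer cuts tumour DNA but not
the patient's germline, which makes them attractive integration sites for
therapeutic transgene knock-in (for example, immune-stimulating cytokines in
immune-excluded solid tumours). `neopam` is a library plus a thin CLI for
discovering, annotating, ranking and cross-patient bookkeeping of these
sites, written for computational biologists building personalised
gene-editing workflows.

## What it computes

**Discovery.** For each somatic SNV the scanner applies the adjacency rule —
a new G next to an existing reference G, or a new C next to an existing C —
on both strands; each novel dinucleotide is one candidate (so `GAG→GGG`
yields two). The created base always lies inside the PAM, never inside the
protospacer, so the guide sequence is pure reference: tumour exclusivity is
carried by the PAM alone. Small indels (<300 bp) are handled by rescanning
the alternate haplotype with reference-aligned position mapping; such
candidates are flagged `indel_derived`.

**Annotation.** Each candidate gets its containing gene (span-based), and
per-gene expression (TPM), copy number and DepMap-style gene dependency,
plus four guide scores: CFD- and MIT-style specificity (0–100, aggregated as
`100 / (1 + Σ s)` over per-off-target similarities) and Doench-/
Moreno-style cutting efficiency (imported from a precomputed score table, or
a labelled built-in surrogate).

**Ranking.** Within one sample, candidates are ranked per feature from 1
(worst) to *n* (best), ties sharing the average rank and missing values all
receiving rank 1. The composite score is

```
2·rank(CFD) + rank(MIT) + 0.5·(rank(Doench) + rank(Moreno))
  + rank(dependency) + rank(expression) + rank(copy number)
```

min–max normalised to 0–100 (100 = most promising). A sample report flags
feasibility (≥ 86 novel PAM sites) and safety (top-3 candidates with
CFD > 90 and MIT > 80).

**Breakpoint junctions.** Structural-variant and ecDNA junctions juxtapose
sequences absent from the reference. From a BEDPE-like breakpoint table,
`neopam` builds strand-corrected 60-nt junction windows (positions −30…−1
and +1…+30), detects junction-created PAMs (`GG`/`CC` exactly at (−1, +1),
novel only if neither wild-type context already supplies the partner base)
and junction-spanning guides (NGG with N at +6…+16, CCN with first C at
−18…−8, at least 4 nt of the guide on each side of the junction).

**Cohort recurrence.** Sites are keyed genomically (variant-derived) or by
(motif, guide sequence) (junction-derived); the recurrence rate is the
fraction of site-occurrences belonging to sites seen in ≥ 2 patients.

## Worked example

`examples/01_discover_and_rank.py` simulates a tumour sample (100-kb genome,
10 planted PAM-creating SNVs among 90 neutral ones), runs discovery,
annotation and ranking, and prints:

```
100 somatic variants scanned; 10 created at least one novel PAM; 10 candidate sites after deduplication

rank  site                 gene       CFD    MIT   score
   1  chr1:28980 +        GENE0005    98.7   86.8   100.0
   2  chr1:93959 -        GENE0018    96.8   61.8    75.0
   3  chr1:59400 +        GENE0011    90.2   40.9    71.9
   4  chr1:57959 -        GENE0011    61.1   90.2    62.5
   5  chr1:74460 +        GENE0014    68.9   48.1    51.6

sample report: 10 PAM sites (feasibility minimum 86: not met); top-3 CFD>90 checks [True, True, True]
```

Exactly the 10 planted sites are recovered (none of the 90 neutral SNVs
produces a false call); the normalized score orders them within the sample,
and the report warns that a 10-site sample is below the feasibility
threshold. `examples/02_breakpoint_junctions.py` and
`examples/03_cohort_recurrence.py` walk through the junction and cohort
analyses the same way.

The same pipeline is available from the shell:

```bash
neopam simulate --seed 7 --output-dir fix
neopam run-all --genome fix/genome.fa --vcf fix/variants.vcf \
    --gtf fix/genes.gtf --sample S1 --scores fix/guide_scores.tsv \
    --output-dir out
```

## Input formats

- reference genome: FASTA (a `.fai` index is built if absent);
- somatic variants: VCF 4.x (PASS records; multi-allelic records split;
  indels with ≥300 bp length change dropped), or a minimal 5-column TSV
  (`contig pos ref alt sample`);
- gene models: GTF/GFF3;
- feature tables: TSV with `gene_id` and `value` columns (optional
  per-sample columns);
- guide scores: TSV with `protospacer, cfd_spec, mit_spec, doench, moreno`;
- breakpoints: TSV with `chrom1 pos1 strand1 chrom2 pos2 strand2 class
  sample`. Positions are 1-based and name the junction-adjacent retained
  base; strand `+` keeps the reference-plus flank on that side (side 1:
  upstream of and including `pos1`; side 2: downstream of and including
  `pos2`), strand `-` keeps the reverse complement of the opposite side.

All internal coordinates are 0-based half-open; exported tables say which
convention each column uses.

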