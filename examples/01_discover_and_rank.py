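"""Discover tumour-exclusive PAM sites in a synthetic sample and rank them.

Builds a seeded synthetic tumour (100-kb genome, 10 planted PAM-creating
SNVs among 90 neutral ones, gene models and feature tables), scans the
variants for novel NGG PAMs, annotates and ranks the candidates, and prints
the top of the ranked table.
"""

from neopam import (
    FixtureSpec,
    ScoreSet,
    annotate_sample,
    discover_sample,
    flag_sample,
    generate,
    rank_candidates,
)
from neopam.genome_io import FeatureTable
import pandas as pd

bundle = generate(FixtureSpec(seed=11, n_pam_snvs_plus=5, n_pam_snvs_minus=5,
                              n_neutral_snvs=90))

result = discover_sample(bundle.variants, bundle.genome, bundle.genes)
print(f"{result.n_variants} somatic variants scanned; "
      f"{result.n_variants_with_pam} created at least one novel PAM; "
      f"{len(result)} candidate sites after deduplication")

tables = {
    kind: FeatureTable(kind, pd.DataFrame(
        {"value": [v for v in vals.values()]}, index=list(vals.keys())))
    for kind, vals in bundle.features.items()
}
scores = {row["protospacer"]: ScoreSet(row["cfd_spec"], row["mit_spec"],
                                       row["doench"], row["moreno"])
          for row in bundle.score_rows}
annotated = annotate_sample(result.candidates, bundle.genes, tables,
                            lambda proto: scores.get(proto, ScoreSet()))

ranked = rank_candidates(annotated)
print("\nrank  site                 gene       CFD    MIT   score")
for r in ranked[:5]:
    c = r.annotated.candidate
    print(f"{r.final_rank:>4}  {c.contig}:{c.gg_start}{c.strand:>2}        "
          f"{r.annotated.gene_id or '-':<10} "
          f"{r.annotated.scores.cfd_spec or float('nan'):>5.1f} "
          f"{r.annotated.scores.mit_spec or float('nan'):>6.1f} "
          f"{r.normalized_score:>7.1f}")

report = flag_sample(ranked)
print(f"\nsample report: {report.n_candidates} PAM sites "
      f"(feasibility minimum {report.min_pam_count}: "
      f"{'met' if report.meets_min_pam_count else 'not met'}); "
      f"top-3 CFD>90 checks {report.top3_cfd_pass}")
# The normalized score runs 0-100 within this sample (100 = most promising);
# the feasibility minimum reflects that samples with few PAM sites rarely
# offer top candidates with high specificity.
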