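"""Find CRISPR target sites created by SV/ecDNA breakpoint junctions.

Generates a synthetic genome with three planted junction-GG breakpoints and
three neutral ones, extracts the strand-corrected 60-nt junction windows,
and reports junction-created PAMs and junction-spanning guides.
"""

from neopam import FixtureSpec, analyze_cohort_breakpoints, generate

bundle = generate(FixtureSpec(seed=23, n_pam_snvs_plus=0, n_pam_snvs_minus=0,
                              n_neutral_snvs=0, n_junction_breakpoints=3,
                              n_neutral_breakpoints=3))

result = analyze_cohort_breakpoints(bundle.breakpoints, bundle.genome)
print(f"{len(bundle.breakpoints)} breakpoints analysed; "
      f"{len(result.candidates)} junction candidates\n")
for c in result.candidates:
    b = c.breakpoint
    print(f"{b.svclass:<14} {b.contig1}:{b.pos1}|{b.contig2}:{b.pos2}  "
          f"{c.kind:<15} {c.motif}  guide={c.grna}  "
          f"overlap {c.left_overlap}+{c.right_overlap} nt")

print("\nper-sample summary:")
print(result.per_sample.to_string(index=False))
# 'junction_pam' sites have the GG (or CC) formed exactly across the join;
# 'spanning_guide' sites read at least 4 nt from each side of the junction,
# which is what makes them tumour-exclusive despite a reference-like PAM.
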