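"""How often does the same tumour-exclusive site recur across patients?

Simulates a small cohort of independent tumours, pools their discovered PAM
sites by genomic identity and computes the recurrence rate: the fraction of
site-occurrences belonging to sites seen in at least two patients.
"""

from neopam import FixtureSpec, discover_sample, generate, recurrence, site_key

cohort: dict[str, set] = {}
for i in range(6):
    bundle = generate(FixtureSpec(seed=100 + i, sample_id=f"P{i + 1}",
                                  n_pam_snvs_plus=5, n_pam_snvs_minus=5,
                                  n_neutral_snvs=50))
    sites = {site_key(c)
             for c in discover_sample(bundle.variants, bundle.genome)}
    cohort[f"P{i + 1}"] = sites
    print(f"P{i + 1}: {len(sites)} tumour-exclusive PAM sites")

summary = recurrence(cohort)
print(f"\n{summary.total_occurrences} site-occurrences across "
      f"{len(cohort)} patients")
print(f"multiplicity histogram: {dict(sorted(summary.histogram.items()))}")
print(f"recurrence rate: {summary.recurrence_rate_pct:.1f}%")
# Independent genomes share no sites, so the rate is 0%: each patient's
# tumour genomes demand individually selected target sites.
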