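"""Cross-sample bookkeeping: per-sample PAM yields and cohort recurrence.

Because tumour-exclusive target sites are created by private somatic events,
the interesting cohort question is how often the *same* site recurs across
patients.  Sites are keyed genomically for variant-derived PAMs
(contig, GG start, strand) and by (motif, guide sequence) for
breakpoint-derived candidates — junction coordinates differ between patients
for the same biological target, the guide sequence does not.

The recurrence rate is the fraction of site-occurrences that belong to sites
seen in at least two patients: with a multiplicity histogram
``{patients-per-site: site count}``, ``rate = Σ_{m≥2} m·count_m / total
occurrences``.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .breakpoint_pam import BreakpointPamCandidate
from .pam_discovery import PamCandidate

__all__ = [
    "site_key",
    "SampleYield",
    "sample_yield",
    "cohort_yield_summary",
    "RecurrenceSummary",
    "recurrence",
    "recurrence_from_histogram",
]

SiteKey = tuple


def site_key(candidate: PamCandidate | BreakpointPamCandidate) -> SiteKey:
    """Canonical cross-sample identity of a candidate."""
    if isinstance(candidate, PamCandidate):
        return (candidate.contig, candidate.gg_start, candidate.strand)
    return candidate.site_key


@dataclass(frozen=True)
class SampleYield:
    """Per-sample discovery yield."""

    sample_id: str
    n_variants: int
    n_candidates: int
    n_variants_with_candidate: int

    @property
    def fraction_yielding(self) -> float | None:
        """Fraction of variants creating ≥1 candidate (None for 0 variants)."""
        if self.n_variants == 0:
            return None
        return self.n_variants_with_candidate / self.n_variants


def sample_yield(
    sample_id: str,
    variants: Iterable,
    candidates: Iterable[PamCandidate],
) -> SampleYield:
    """Yield counts for one sample's completed discovery."""
    variants = list(variants)
    candidates = list(candidates)
    yielding = {
        (v.contig, v.pos, v.ref_allele, v.alt_allele)
        for c in candidates
        for v in (c.provenance or (c.variant,))
    }
    return SampleYield(
        sample_id=sample_id,
        n_variants=len(variants),
        n_candidates=len(candidates),
        n_variants_with_candidate=len(yielding),
    )


def cohort_yield_summary(yields: Iterable[SampleYield]) -> dict:
    """Cohort medians of variant counts, candidate counts and fractions."""
    yields = list(yields)
    fracs = [y.fraction_yielding for y in yields if y.fraction_yielding is not None]
    return {
        "n_samples": len(yields),
        "median_variants": statistics.median(y.n_variants for y in yields)
        if yields else None,
        "median_candidates": statistics.median(y.n_candidates for y in yields)
        if yields else None,
        "median_fraction_yielding": statistics.median(fracs) if fracs else None,
    }


@dataclass
class RecurrenceSummary:
    """Cohort recurrence: multiplicity histogram and occurrence-based rate."""

    total_occurrences: int
    histogram: dict[int, int] = field(default_factory=dict)  # multiplicity → sites

    @property
    def recurrent_occurrences(self) -> int:
        return sum(m * n for m, n in self.histogram.items() if m >= 2)

    @property
    def recurrence_rate(self) -> float:
        if self.total_occurrences == 0:
            return 0.0
        return self.recurrent_occurrences / self.total_occurrences

    @property
    def recurrence_rate_pct(self) -> float:
        return 100.0 * self.recurrence_rate


def recurrence(per_sample_site_sets: Mapping[str, Iterable[SiteKey]]) -> RecurrenceSummary:
    """Recurrence over per-sample site sets.

    Multiplicity of a site = number of distinct samples containing its key;
    the rate is the fraction of occurrences belonging to sites with
    multiplicity ≥ 2.
    """
    if len(per_sample_site_sets) < 2:
        raise ValueError("recurrence requires at least two samples")
    multiplicity: dict[SiteKey, int] = {}
    total = 0
    for _, sites in per_sample_site_sets.items():
        sites = set(sites)
        total += len(sites)
        for key in sites:
            multiplicity[key] = multiplicity.get(key, 0) + 1
    histogram: dict[int, int] = {}
    for m in multiplicity.values():
        histogram[m] = histogram.get(m, 0) + 1
    return RecurrenceSummary(total_occurrences=total, histogram=histogram)


def recurrence_from_histogram(
    histogram: Mapping[int, int], total_occurrences: int
) -> RecurrenceSummary:
    """Recurrence from a pre-tabulated multiplicity histogram.

    ``histogram`` may list only multiplicities ≥ 2; singleton sites are
    inferred from the occurrence total.
    """
    hist = {int(m): int(n) for m, n in histogram.items() if m >= 2}
    accounted = sum(m * n for m, n in hist.items())
    if accounted > total_occurrences:
        raise ValueError("histogram exceeds the stated occurrence total")
    hist[1] = hist.get(1, 0) + (total_occurrences - accounted)
    return RecurrenceSummary(total_occurrences=total_occurrences, histogram=hist)
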