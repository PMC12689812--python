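"""Detection of somatic-variant-created novel NGG PAM sites.

A tumour-exclusive Cas9 docking site arises when a somatic variant creates a
GG dinucleotide (plus strand) or a CC dinucleotide (read as GG on the minus
strand) that is absent from the reference genome.  For SNVs the rule is
adjacency: a new G next to an existing G, or a new C next to an existing C.
The N of the NGG motif matches any base, so variants that only change an N
never create a site.  Each novel dinucleotide defines one distinct candidate,
so a GAG→GGG change emits two.

For SNV-created candidates the created base always sits inside the PAM, never
inside the 20-nt protospacer, so the protospacer is pure reference sequence:
tumour specificity is carried by the PAM alone.

Small indels (<300 bp length change) are handled by rescanning the alternate
haplotype around the edit and keeping dinucleotides whose reference-aligned
position does not already carry the same dinucleotide; such candidates are
flagged ``indel_derived``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .genome_io import (
    GenomicInterval,
    ReferenceGenome,
    SomaticVariant,
    reverse_complement,
)

__all__ = [
    "PamCandidate",
    "DiscoveryResult",
    "scan_snv_for_novel_pams",
    "scan_indel_for_novel_pams",
    "is_novel_pam",
    "discover_sample",
]

PROTOSPACER_LENGTH = 20
DEFAULT_INDEL_WINDOW = 25


@dataclass(frozen=True)
class PamCandidate:
    """A novel PAM site and its guide.

    ``gg_start`` is the plus-strand 0-based coordinate of the left base of
    the PAM's GG dinucleotide (the CC dinucleotide for minus-strand
    candidates).  ``pam_3mer`` and ``protospacer`` are read 5'→3' on the PAM
    strand from the tumour (alt) haplotype.
    """

    sample_id: str
    variant: SomaticVariant
    strand: str
    contig: str
    gg_start: int
    n_position: int
    pam_3mer: str
    protospacer: str
    is_novel: bool = True
    indel_derived: bool = False
    gene_id: str | None = None
    provenance: tuple[SomaticVariant, ...] = ()

    def __post_init__(self) -> None:
        if len(self.pam_3mer) != 3 or self.pam_3mer[1:] != "GG":
            raise ValueError(f"PAM {self.pam_3mer!r} does not match NGG")
        if len(self.protospacer) != PROTOSPACER_LENGTH:
            raise ValueError("protospacer must be 20 nt")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def gg_interval(self) -> GenomicInterval:
        return GenomicInterval(self.contig, self.gg_start, self.gg_start + 2)

    @property
    def dedup_key(self) -> tuple:
        key = (self.contig, self.gg_start, self.strand)
        # indel-derived sites at the same anchor can differ in sequence
        return key + ((self.protospacer,) if self.indel_derived else ())


def is_novel_pam(
    genome: ReferenceGenome, contig: str, gg_start: int, strand: str
) -> bool:
    """True iff the reference lacks GG (+) / CC (−) at the dinucleotide."""
    dinuc = genome.fetch(contig, gg_start, gg_start + 2)
    return dinuc != ("GG" if strand == "+" else "CC")


def _plus_candidate(
    variant: SomaticVariant, genome: ReferenceGenome, gg_start: int
) -> PamCandidate | None:
    """Build a + strand candidate for a GG at [gg_start, gg_start+2)."""
    contig = variant.contig
    n_pos = gg_start - 1
    if n_pos - PROTOSPACER_LENGTH < 0 or gg_start + 2 > genome.length(contig):
        return None
    p = variant.pos0
    pam = list(genome.fetch(contig, n_pos, n_pos + 3))
    if n_pos <= p < n_pos + 3:
        pam[p - n_pos] = variant.alt_allele
    protospacer = genome.fetch(contig, n_pos - PROTOSPACER_LENGTH, n_pos)
    if "N" in protospacer:
        return None
    return PamCandidate(
        sample_id=variant.sample_id,
        variant=variant,
        strand="+",
        contig=contig,
        gg_start=gg_start,
        n_position=n_pos,
        pam_3mer="".join(pam),
        protospacer=protospacer,
        provenance=(variant,),
    )


def _minus_candidate(
    variant: SomaticVariant, genome: ReferenceGenome, cc_start: int
) -> PamCandidate | None:
    """Build a − strand candidate for a CC at [cc_start, cc_start+2)."""
    contig = variant.contig
    n_pos = cc_start + 2  # plus-strand coordinate of the PAM's N base
    if cc_start < 0 or n_pos + 1 + PROTOSPACER_LENGTH > genome.length(contig):
        return None
    p = variant.pos0
    pam_plus = list(genome.fetch(contig, cc_start, cc_start + 3))
    if cc_start <= p < cc_start + 3:
        pam_plus[p - cc_start] = variant.alt_allele
    protospacer = reverse_complement(
        genome.fetch(contig, cc_start + 3, cc_start + 3 + PROTOSPACER_LENGTH)
    )
    if "N" in protospacer:
        return None
    return PamCandidate(
        sample_id=variant.sample_id,
        variant=variant,
        strand="-",
        contig=contig,
        gg_start=cc_start,
        n_position=n_pos,
        pam_3mer=reverse_complement("".join(pam_plus)),
        protospacer=protospacer,
        provenance=(variant,),
    )


def scan_snv_for_novel_pams(
    variant: SomaticVariant, genome: ReferenceGenome
) -> list[PamCandidate]:
    """Candidates created by one SNV (up to two per strand class).

    A new G adjacent to an existing reference G creates a plus-strand GG; a
    new C adjacent to an existing reference C creates a CC read as GG on the
    minus strand.  Novelty holds by construction (ref ≠ alt) and is
    re-verified against the reference.
    """
    if variant.vtype != "SNV":
        raise ValueError("scan_snv_for_novel_pams requires an SNV")
    contig, p, alt = variant.contig, variant.pos0, variant.alt_allele
    length = genome.length(contig)
    out: list[PamCandidate] = []
    if alt == "G":
        if p - 1 >= 0 and genome.fetch(contig, p - 1, p) == "G":
            cand = _plus_candidate(variant, genome, p - 1)
            if cand is not None:
                out.append(cand)
        if p + 1 < length and genome.fetch(contig, p + 1, p + 2) == "G":
            cand = _plus_candidate(variant, genome, p)
            if cand is not None:
                out.append(cand)
    elif alt == "C":
        if p - 1 >= 0 and genome.fetch(contig, p - 1, p) == "C":
            cand = _minus_candidate(variant, genome, p - 1)
            if cand is not None:
                out.append(cand)
        if p + 1 < length and genome.fetch(contig, p + 1, p + 2) == "C":
            cand = _minus_candidate(variant, genome, p)
            if cand is not None:
                out.append(cand)
    return [c for c in out if is_novel_pam(genome, c.contig, c.gg_start, c.strand)]


def _alt_window(
    variant: SomaticVariant, genome: ReferenceGenome, halfwidth: int
) -> tuple[str, int, list[int | None]]:
    """Alternate haplotype around an indel plus the per-base mapping to
    reference coordinates (None for inserted bases)."""
    contig, p0 = variant.contig, variant.pos0
    ref_len = len(variant.ref_allele)
    left_start = max(0, p0 - halfwidth)
    right_end = min(genome.length(contig), p0 + ref_len + halfwidth)
    left = genome.fetch(contig, left_start, p0)
    right = genome.fetch(contig, p0 + ref_len, right_end)
    window = left + variant.alt_allele + right
    coords: list[int | None] = [left_start + i for i in range(len(left))]
    # left-normalised indels share their first (anchor) base with the reference
    coords.append(p0)
    coords.extend([None] * (len(variant.alt_allele) - 1))
    coords.extend(p0 + ref_len + i for i in range(len(right)))
    return window, left_start, coords


def scan_indel_for_novel_pams(
    variant: SomaticVariant,
    genome: ReferenceGenome,
    window_halfwidth: int = DEFAULT_INDEL_WINDOW,
) -> list[PamCandidate]:
    """Candidates created by a small insertion or deletion.

    The alternate haplotype over ±``window_halfwidth`` around the edit is
    rescanned for GG/CC dinucleotides; one candidate is emitted for each
    dinucleotide that is not already present at its reference-aligned
    position (bases left of the edit map unchanged, bases right of it are
    shifted by the length difference, inserted bases have no reference
    position).  Protospacers are read from the alternate haplotype.
    """
    if variant.vtype not in ("INS", "DEL"):
        raise ValueError("scan_indel_for_novel_pams requires an INS or DEL")
    window, _, coords = _alt_window(variant, genome, window_halfwidth)
    out: list[PamCandidate] = []
    for i in range(len(window) - 1):
        pair = window[i : i + 2]
        if pair not in ("GG", "CC"):
            continue
        r1, r2 = coords[i], coords[i + 1]
        preexisting = (
            r1 is not None
            and r2 == r1 + 1
            and genome.fetch(variant.contig, r1, r1 + 2) == pair
        )
        if preexisting:
            continue
        gg_start = r1 if r1 is not None else (r2 - 1 if r2 is not None else variant.pos0)
        if pair == "GG":
            if i - 1 - PROTOSPACER_LENGTH < 0:
                continue
            protospacer = window[i - 1 - PROTOSPACER_LENGTH : i - 1]
            pam = window[i - 1 : i + 2]
            n_pos = coords[i - 1] if coords[i - 1] is not None else gg_start - 1
            strand = "+"
        else:
            if i + 3 + PROTOSPACER_LENGTH > len(window):
                continue
            protospacer = reverse_complement(window[i + 3 : i + 3 + PROTOSPACER_LENGTH])
            pam = reverse_complement(window[i : i + 3])
            n_pos = coords[i + 2] if coords[i + 2] is not None else gg_start + 2
            strand = "-"
        if "N" in protospacer or "N" in pam:
            continue
        out.append(
            PamCandidate(
                sample_id=variant.sample_id,
                variant=variant,
                strand=strand,
                contig=variant.contig,
                gg_start=gg_start,
                n_position=n_pos,
                pam_3mer=pam,
                protospacer=protospacer,
                indel_derived=True,
                provenance=(variant,),
            )
        )
    return out


def derive_protospacer(
    genome: ReferenceGenome, contig: str, n_position: int, strand: str
) -> str:
    """The 20 nt immediately 5' of the NGG on the PAM strand (reference
    haplotype; for SNV candidates the alt base lies inside the PAM, so the
    reference read equals the tumour read)."""
    if strand == "+":
        if n_position - PROTOSPACER_LENGTH < 0:
            raise ValueError("insufficient 5' flank for a full protospacer")
        return genome.fetch(contig, n_position - PROTOSPACER_LENGTH, n_position)
    if n_position + 1 + PROTOSPACER_LENGTH > genome.length(contig):
        raise ValueError("insufficient 5' flank for a full protospacer")
    return reverse_complement(
        genome.fetch(contig, n_position + 1, n_position + 1 + PROTOSPACER_LENGTH)
    )


@dataclass
class DiscoveryResult:
    """Deduplicated candidates plus per-sample summary counters."""

    candidates: list[PamCandidate] = field(default_factory=list)
    n_variants: int = 0
    n_variants_with_pam: int = 0
    n_candidates_raw: int = 0

    def __iter__(self):
        return iter(self.candidates)

    def __len__(self) -> int:
        return len(self.candidates)


def discover_sample(
    variants: list[SomaticVariant],
    genome: ReferenceGenome,
    genes: list | None = None,
    window_halfwidth: int = DEFAULT_INDEL_WINDOW,
    include_indels: bool = True,
) -> DiscoveryResult:
    """Scan every variant of one sample and deduplicate the candidates.

    Candidates sharing (contig, dinucleotide start, strand) are merged; all
    creating variants are kept in ``provenance``.  Per-variant failures
    (insufficient flank, N in the window) drop the affected candidate only.
    """
    result = DiscoveryResult()
    by_key: dict[tuple, PamCandidate] = {}
    for var in variants:
        result.n_variants += 1
        if var.vtype == "SNV":
            cands = scan_snv_for_novel_pams(var, genome)
        elif include_indels:
            cands = scan_indel_for_novel_pams(var, genome, window_halfwidth)
        else:
            cands = []
        if cands:
            result.n_variants_with_pam += 1
        for cand in cands:
            result.n_candidates_raw += 1
            key = cand.dedup_key
            if key in by_key:
                prev = by_key[key]
                by_key[key] = replace(
                    prev, provenance=prev.provenance + (var,)
                )
            else:
                by_key[key] = cand
    candidates = sorted(
        by_key.values(), key=lambda c: (c.contig, c.gg_start, c.strand)
    )
    if genes:
        tagged = []
        for cand in candidates:
            containing = sorted(
                (g.gene_id for g in genes if g.contains(cand.contig, cand.gg_start)),
            )
            tagged.append(
                replace(cand, gene_id=containing[0]) if containing else cand
            )
        candidates = tagged
    result.candidates = candidates
    return result
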