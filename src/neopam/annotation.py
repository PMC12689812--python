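"""Gene context and multi-omics feature annotation of PAM candidates.

Each candidate is assigned the gene whose span contains its GG dinucleotide
(gene span, not exon-only: intronic sites still carry gene-level features).
When several genes overlap the site, the most highly expressed one wins
(ties broken by lexicographic gene id) and the alternates are recorded.
Expression (TPM), copy number and gene dependency are then copied from the
feature tables by gene id, and the four guide scores attached.  Every
feature may individually be missing; a candidate without a gene has all
gene-keyed features missing.

Dependency semantics follow the DepMap convention: values at or below −0.5
indicate depletion in most cell lines, at or below −1 strong lethality, and
0 a non-essential gene.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .genome_io import FeatureTable, GeneModel
from .guide_scoring import ScoreSet
from .pam_discovery import PamCandidate

__all__ = [
    "AnnotatedCandidate",
    "annotate_gene",
    "annotate_features",
    "annotate_sample",
    "dependency_class",
]

DEPENDENCY_DEPLETION = -0.5
DEPENDENCY_STRONG_LETHALITY = -1.0


def dependency_class(dependency: float | None) -> str | None:
    """Qualitative essentiality label for a dependency score."""
    if dependency is None:
        return None
    if dependency <= DEPENDENCY_STRONG_LETHALITY:
        return "strong_lethality"
    if dependency <= DEPENDENCY_DEPLETION:
        return "depletion"
    return "non_essential"


@dataclass(frozen=True)
class AnnotatedCandidate:
    """A PAM candidate with gene context, feature values and guide scores."""

    candidate: PamCandidate
    gene_id: str | None = None
    symbol: str | None = None
    alternate_genes: tuple[str, ...] = ()
    expression_tpm: float | None = None
    copy_number: float | None = None
    dependency: float | None = None
    scores: ScoreSet = ScoreSet()

    def __post_init__(self) -> None:
        if self.gene_id is None and any(
            v is not None
            for v in (self.expression_tpm, self.copy_number, self.dependency)
        ):
            raise ValueError("gene-keyed features require a gene assignment")
        if self.expression_tpm is not None and self.expression_tpm < 0:
            raise ValueError("TPM must be non-negative")
        if self.copy_number is not None and self.copy_number < 0:
            raise ValueError("copy number must be non-negative")

    @property
    def dependency_class(self) -> str | None:
        return dependency_class(self.dependency)


def annotate_gene(
    candidate: PamCandidate,
    genes: Sequence[GeneModel],
    expression: FeatureTable | None = None,
    sample_id: str | None = None,
) -> tuple[GeneModel | None, tuple[str, ...]]:
    """Gene whose span contains the GG dinucleotide, plus alternates.

    With several overlapping genes the one with the highest expression is
    chosen (missing expression sorts last; remaining ties break by
    lexicographic gene id).
    """
    containing = [g for g in genes if g.contains(candidate.contig, candidate.gg_start)]
    if not containing:
        return None, ()

    def sort_key(g: GeneModel):
        tpm = expression.get(g.gene_id, sample_id) if expression is not None else None
        return (-(tpm if tpm is not None else float("-inf")), g.gene_id)

    containing.sort(key=sort_key)
    best = containing[0]
    return best, tuple(g.gene_id for g in containing[1:])


def annotate_features(
    candidate: PamCandidate,
    gene: GeneModel | None,
    alternates: tuple[str, ...],
    tables: Mapping[str, FeatureTable],
    scores: ScoreSet,
    sample_id: str | None = None,
) -> AnnotatedCandidate:
    """Copy feature values from the tables by gene id (absent keys stay
    missing) and attach guide scores.  Discovery fields are never altered."""
    if gene is None:
        return AnnotatedCandidate(candidate=candidate, scores=scores)
    get = lambda kind: (
        tables[kind].get(gene.gene_id, sample_id) if kind in tables else None
    )
    return AnnotatedCandidate(
        candidate=candidate,
        gene_id=gene.gene_id,
        symbol=gene.symbol,
        alternate_genes=alternates,
        expression_tpm=get("expression"),
        copy_number=get("copy_number"),
        dependency=get("dependency"),
        scores=scores,
    )


def annotate_sample(
    candidates: Sequence[PamCandidate],
    genes: Sequence[GeneModel],
    tables: Mapping[str, FeatureTable],
    score_lookup,
    sample_id: str | None = None,
) -> list[AnnotatedCandidate]:
    """Annotate every candidate of one sample.

    ``score_lookup`` maps a protospacer to a :class:`ScoreSet` (e.g. a
    score-table ``dict.get`` with a default, or a closure running the
    built-in scorers).  Candidate count and order are preserved.
    """
    expression = tables.get("expression")
    out: list[AnnotatedCandidate] = []
    for cand in candidates:
        gene, alternates = annotate_gene(cand, genes, expression, sample_id)
        scores = score_lookup(cand.protospacer) or ScoreSet()
        out.append(
            annotate_features(cand, gene, alternates, tables, scores, sample_id)
        )
    return out
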