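"""Reading and validation of the external inputs.

All downstream modules operate on the in-memory records defined here:

* :class:`ReferenceGenome` -- upper-cased, N-normalised contig sequences with
  strand-aware ``fetch``.
* :class:`SomaticVariant` -- one tumour-specific SNV or small indel in VCF
  convention (1-based position of the first reference base).
* :class:`GeneModel` -- gene span plus exon intervals, 0-based half-open.
* :class:`FeatureTable` -- one per-gene feature (expression in TPM, copy
  number, or DepMap-style gene dependency), possibly with per-sample columns.

Internal coordinates are 0-based half-open throughout; VCF and GTF positions
are converted on load.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import pandas as pd

__all__ = [
    "reverse_complement",
    "GenomicInterval",
    "SomaticVariant",
    "ReferenceGenome",
    "GeneModel",
    "FeatureTable",
    "VariantLoadResult",
    "load_reference",
    "load_somatic_variants",
    "load_somatic_variants_tsv",
    "load_gene_models",
    "load_feature_table",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID = set("ACGTN")

MAX_INDEL_LENGTH = 300  # |len(ref) - len(alt)| must be strictly below this


def reverse_complement(seq: str) -> str:
    """Reverse complement of an upper-case A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on a named contig."""

    contig: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < self.start:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class SomaticVariant:
    """A tumour-specific variant in VCF convention.

    ``pos`` is the 1-based position of the first reference base; use
    :attr:`pos0` for the internal 0-based coordinate.
    """

    contig: str
    pos: int
    ref_allele: str
    alt_allele: str
    vtype: str
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles are identical")
        if self.vtype not in ("SNV", "INS", "DEL"):
            raise ValueError(f"unknown variant type {self.vtype!r}")
        is_snv = len(self.ref_allele) == 1 and len(self.alt_allele) == 1
        if is_snv != (self.vtype == "SNV"):
            raise ValueError("SNV type requires both alleles of length 1")
        if abs(len(self.ref_allele) - len(self.alt_allele)) >= MAX_INDEL_LENGTH:
            raise ValueError(f"indel length change must be < {MAX_INDEL_LENGTH} bp")

    @property
    def pos0(self) -> int:
        return self.pos - 1

    @property
    def ref_end0(self) -> int:
        """0-based end (exclusive) of the reference allele."""
        return self.pos0 + len(self.ref_allele)

    @classmethod
    def from_alleles(
        cls, contig: str, pos: int, ref: str, alt: str, sample_id: str = ""
    ) -> "SomaticVariant":
        """Build a variant, inferring the type from allele lengths."""
        ref, alt = ref.upper(), alt.upper()
        if len(ref) == 1 and len(alt) == 1:
            vtype = "SNV"
        elif len(alt) > len(ref):
            vtype = "INS"
        elif len(ref) > len(alt):
            vtype = "DEL"
        else:
            raise ValueError(
                f"equal-length multi-nucleotide substitution {ref}>{alt} not supported"
            )
        return cls(contig, pos, ref, alt, vtype, sample_id)


class ReferenceGenome:
    """In-memory reference genome over the alphabet {A, C, G, T, N}.

    Sequences are case-normalised to upper on construction (soft-masked
    lowercase is treated as normal sequence) and characters outside ACGTN are
    mapped to N.
    """

    def __init__(self, contigs: Mapping[str, str]):
        if not contigs:
            raise ValueError("empty genome")
        self._seqs: dict[str, str] = {}
        for name, seq in contigs.items():
            seq = seq.upper()
            if not set(seq) <= _VALID:
                seq = "".join(c if c in _VALID else "N" for c in seq)
            self._seqs[name] = seq

    @property
    def contigs(self) -> tuple[str, ...]:
        return tuple(self._seqs)

    def __contains__(self, contig: str) -> bool:
        return contig in self._seqs

    def length(self, contig: str) -> int:
        return len(self._seqs[contig])

    def sequence(self, contig: str) -> str:
        """Full plus-strand sequence of a contig."""
        return self._seqs[contig]

    def fetch(self, contig: str, start: int, end: int, strand: str = "+") -> str:
        """Sequence of ``[start, end)``; minus strand returns the reverse
        complement of the plus-strand fetch."""
        if contig not in self._seqs:
            raise KeyError(f"unknown contig {contig!r}")
        if start < 0 or end > len(self._seqs[contig]) or start > end:
            raise IndexError(
                f"interval [{start}, {end}) out of bounds for contig "
                f"{contig} (length {len(self._seqs[contig])})"
            )
        seq = self._seqs[contig][start:end]
        return seq if strand == "+" else reverse_complement(seq)

    def fetch_interval(self, iv: GenomicInterval) -> str:
        return self.fetch(iv.contig, iv.start, iv.end, iv.strand)


def load_reference(path: str | Path) -> ReferenceGenome:
    """Load a FASTA file (building the .fai index if needed)."""
    from pyfaidx import Fasta

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fasta = Fasta(str(path), as_raw=True, sequence_always_upper=True)
    contigs = {name: str(fasta[name][:]) for name in fasta.keys()}
    fasta.close()
    return ReferenceGenome(contigs)


@dataclass
class VariantLoadResult:
    """Variants plus bookkeeping counters from a load."""

    variants: list[SomaticVariant] = field(default_factory=list)
    n_records: int = 0
    dropped_filtered: int = 0
    dropped_long_indel: int = 0
    dropped_other: int = 0
    ref_mismatches: int = 0

    def __iter__(self) -> Iterator[SomaticVariant]:
        return iter(self.variants)

    def __len__(self) -> int:
        return len(self.variants)


def _classify_and_append(
    result: VariantLoadResult,
    contig: str,
    pos: int,
    ref: str,
    alt: str,
    sample_id: str,
    genome: ReferenceGenome | None,
) -> None:
    if abs(len(ref) - len(alt)) >= MAX_INDEL_LENGTH:
        result.dropped_long_indel += 1
        return
    try:
        var = SomaticVariant.from_alleles(contig, pos, ref, alt, sample_id)
    except ValueError:
        result.dropped_other += 1
        return
    if genome is not None:
        if contig not in genome:
            warnings.warn(f"contig {contig!r} absent from reference; variant skipped")
            result.ref_mismatches += 1
            return
        end = var.pos0 + len(ref)
        if end > genome.length(contig) or genome.fetch(contig, var.pos0, end) != ref:
            warnings.warn(
                f"ref allele mismatch at {contig}:{pos} ({ref}); variant skipped"
            )
            result.ref_mismatches += 1
            return
    result.variants.append(var)


def load_somatic_variants(
    path: str | Path,
    sample_id: str = "",
    genome: ReferenceGenome | None = None,
) -> VariantLoadResult:
    """Load somatic variants from a VCF.

    Only PASS (or unfiltered) records are kept; multi-allelic records are
    split into one variant per alt allele; indels with a length change of
    300 bp or more are dropped and counted.  When ``genome`` is given,
    records whose ref allele disagrees with the loaded reference are skipped
    with a warning (counted), not fatal.
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    result = VariantLoadResult()
    vcf = VCF(str(path))
    for rec in vcf:
        result.n_records += 1
        if rec.FILTER is not None:  # cyvcf2: None means PASS or '.'
            result.dropped_filtered += 1
            continue
        for alt in rec.ALT:
            _classify_and_append(
                result, rec.CHROM, rec.POS, rec.REF.upper(), alt.upper(),
                sample_id, genome,
            )
    vcf.close()
    return result


def load_somatic_variants_tsv(
    path: str | Path,
    genome: ReferenceGenome | None = None,
) -> VariantLoadResult:
    """Load variants from the minimal 5-column TSV fallback:
    contig, pos (1-based), ref, alt, sample."""
    path = Path(path)
    result = VariantLoadResult()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "contig":  # optional header
                continue
            if len(fields) < 5:
                raise ValueError(f"expected 5 columns, got {len(fields)}: {line!r}")
            contig, pos, ref, alt, sample = fields[:5]
            result.n_records += 1
            _classify_and_append(
                result, contig, int(pos), ref.upper(), alt.upper(), sample, genome
            )
    return result


@dataclass
class GeneModel:
    """A gene: span, exons and strand, in internal 0-based coordinates."""

    gene_id: str
    symbol: str
    contig: str
    start: int
    end: int
    strand: str
    exons: tuple[GenomicInterval, ...] = ()

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.contig, self.start, self.end, self.strand)

    def contains(self, contig: str, pos: int) -> bool:
        return contig == self.contig and self.start <= pos < self.end


def load_gene_models(
    path: str | Path, genome: ReferenceGenome | None = None
) -> list[GeneModel]:
    """Load gene models from GTF/GFF3 (1-based inclusive coordinates are
    converted to 0-based half-open)."""
    import gffutils

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    exons_by_gene: dict[str, list[GenomicInterval]] = {}
    for ex in db.features_of_type("exon"):
        gid = ex.attributes.get("gene_id", [None])[0]
        if gid is None:
            continue
        exons_by_gene.setdefault(gid, []).append(
            GenomicInterval(ex.seqid, ex.start - 1, ex.end, ex.strand or "+")
        )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        gid = g.attributes.get("gene_id", [g.id])[0]
        symbol = g.attributes.get("gene_name", [gid])[0]
        if genome is not None and g.seqid not in genome:
            warnings.warn(f"gene {gid} on contig {g.seqid!r} absent from reference")
        exons = tuple(
            sorted(exons_by_gene.get(gid, []), key=lambda iv: (iv.start, iv.end))
        )
        genes.append(
            GeneModel(gid, symbol, g.seqid, g.start - 1, g.end, g.strand or "+", exons)
        )
    if not genes:
        warnings.warn(f"no gene features found in {path}")
    return genes


FEATURE_KINDS = ("expression", "copy_number", "dependency")


@dataclass
class FeatureTable:
    """Per-gene values for one feature, with optional per-sample columns.

    Expression (TPM) and copy number must be non-negative; dependency is
    unbounded (typically at or below 0 for essential genes).
    """

    kind: str
    frame: pd.DataFrame  # indexed by gene_id; columns: value[, <sample>...]

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.kind in ("expression", "copy_number"):
            if (self.frame.to_numpy() < 0).any():
                raise ValueError(f"{self.kind} values must be non-negative")

    def get(self, gene_id: str, sample: str | None = None) -> float | None:
        """Value for a gene (sample-matched column when available), or None."""
        if gene_id not in self.frame.index:
            return None
        row = self.frame.loc[gene_id]
        col = sample if sample is not None and sample in self.frame.columns else "value"
        val = row[col]
        return None if pd.isna(val) else float(val)

    @property
    def genes(self) -> Sequence[str]:
        return list(self.frame.index)


def load_feature_table(path: str | Path, feature_kind: str) -> FeatureTable:
    """Load a TSV with a ``gene_id`` column and numeric value column(s).

    Non-numeric entries become missing; duplicate gene ids are an error.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if "gene_id" not in df.columns:
        raise ValueError(f"missing 'gene_id' column in {path}")
    if df["gene_id"].duplicated().any():
        dupes = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValueError(f"duplicate gene_id entries: {dupes}")
    df = df.set_index("gene_id")
    for col in df.columns:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    return FeatureTable(feature_kind, df)
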