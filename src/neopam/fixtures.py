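"""Deterministic synthetic data with known ground truth.

The generator emulates the inputs of the discovery pipeline — a reference
genome, tumour variant calls, gene models, per-gene feature tables, a guide
score table and a breakpoint list — with planted events whose detectability
is guaranteed at plant time:

* a planted plus-strand PAM SNV writes a reference G 3' of the site, makes
  the site base non-G and the 5' neighbour non-G, so the alt G creates
  exactly one novel GG;
* the minus-strand (CC) and insertion-created cases are planted with the
  mirrored guards;
* planted junction breakpoints write a G as the last retained base of the
  left flank and the first retained base of the right flank, with non-G
  wild-type continuation bases, so the join creates exactly one novel
  junction NGG;
* neutral SNVs and neutral breakpoints are rejection-sampled against the
  discovery scanners, guaranteeing a clean false-positive test surface.

Everything is driven by one integer seed; the same spec produces
byte-identical files.  Feature values are drawn independently per gene
(TPM log-normal, copy number uniform on 0..8, dependency uniform on
[−2, 0.5]); no mutational-signature or chromosome-clustering realism is
attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .breakpoint_pam import Breakpoint, build_junction_window, detect_junction_pam
from .genome_io import GeneModel, GenomicInterval, ReferenceGenome, SomaticVariant
from .pam_discovery import PamCandidate, scan_snv_for_novel_pams

__all__ = ["FixtureSpec", "PlantedSite", "FixtureBundle", "generate"]

_BASES = np.array(list("ACGT"))
_EDIT_SLOT_SPACING = 60  # planted events never share a ±30 bp neighbourhood


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions of one synthetic dataset."""

    seed: int = 0
    contig_lengths: tuple[int, ...] = (100_000,)
    gc_fraction: float = 0.41
    n_pam_snvs_plus: int = 5
    n_pam_snvs_minus: int = 5
    n_neutral_snvs: int = 90
    n_indel_pams: int = 0
    n_junction_breakpoints: int = 0
    n_neutral_breakpoints: int = 0
    n_genes: int = 20
    sample_id: str = "S1"
    tpm_log_mean: float = 1.5
    tpm_log_sigma: float = 1.2
    copy_number_max: int = 8
    dependency_range: tuple[float, float] = (-2.0, 0.5)
    missing_feature_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.gc_fraction <= 0.0 or self.gc_fraction >= 1.0:
            raise ValueError("GC fraction must lie strictly inside (0, 1)")
        if min(self.contig_lengths, default=0) < 400:
            raise ValueError("contigs must be at least 400 bp for planting")


@dataclass(frozen=True)
class PlantedSite:
    """Ground truth for one planted event."""

    kind: str  # 'snv_pam' | 'indel_pam' | 'junction_pam'
    contig: str
    gg_start: int  # plus-strand coordinate; junction: left-anchor base
    strand: str
    protospacer: str
    variant: SomaticVariant | None = None
    breakpoint: Breakpoint | None = None


@dataclass
class FixtureBundle:
    """All generated inputs plus their ground truth (and file paths when
    written to disk)."""

    spec: FixtureSpec
    genome: ReferenceGenome
    variants: list[SomaticVariant]
    ground_truth: list[PlantedSite]
    genes: list[GeneModel]
    features: dict[str, dict[str, float | None]]
    score_rows: list[dict]
    breakpoints: list[Breakpoint]
    paths: dict[str, Path] = field(default_factory=dict)


def _random_contig(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.arange(4), size=length, p=p)


def _slots(rng: np.random.Generator, contig_lengths, n_needed: int):
    """Well-separated editable positions as (contig index, position)."""
    slots = [
        (ci, pos)
        for ci, length in enumerate(contig_lengths)
        for pos in range(_EDIT_SLOT_SPACING, length - _EDIT_SLOT_SPACING,
                         _EDIT_SLOT_SPACING)
    ]
    if len(slots) < n_needed:
        raise ValueError("contigs too short for the requested number of events")
    order = rng.permutation(len(slots))
    return [slots[i] for i in order]


def _set(seq: np.ndarray, pos: int, base: str) -> None:
    seq[pos] = "ACGT".index(base)


def _get(seq: np.ndarray, pos: int) -> str:
    return "ACGT"[seq[pos]]


def _pick_base(rng: np.random.Generator, exclude: str) -> str:
    choices = [b for b in "ACGT" if b not in exclude]
    return choices[rng.integers(len(choices))]


def generate(spec: FixtureSpec, output_dir: str | Path | None = None) -> FixtureBundle:
    """Generate one fixture bundle (optionally writing all files)."""
    rng = np.random.default_rng(spec.seed)
    contig_names = [f"chr{i + 1}" for i in range(len(spec.contig_lengths))]
    seqs = [
        _random_contig(rng, length, spec.gc_fraction)
        for length in spec.contig_lengths
    ]

    n_events = (
        spec.n_pam_snvs_plus + spec.n_pam_snvs_minus + spec.n_indel_pams
        + 2 * spec.n_junction_breakpoints + spec.n_neutral_snvs
    )
    slots = _slots(rng, spec.contig_lengths, n_events)
    slot_iter = iter(slots)

    # --- phase 1: edit the genome for the planted events -------------------
    planted_plus, planted_minus, planted_indel = [], [], []
    for _ in range(spec.n_pam_snvs_plus):
        ci, p = next(slot_iter)
        seq = seqs[ci]
        _set(seq, p + 1, "G")
        if _get(seq, p) == "G":
            _set(seq, p, _pick_base(rng, "G"))
        if _get(seq, p - 1) == "G":
            _set(seq, p - 1, _pick_base(rng, "G"))
        planted_plus.append((ci, p))
    for _ in range(spec.n_pam_snvs_minus):
        ci, p = next(slot_iter)
        seq = seqs[ci]
        _set(seq, p - 1, "C")
        if _get(seq, p) == "C":
            _set(seq, p, _pick_base(rng, "C"))
        if _get(seq, p + 1) == "C":
            _set(seq, p + 1, _pick_base(rng, "C"))
        planted_minus.append((ci, p))
    for _ in range(spec.n_indel_pams):
        ci, p = next(slot_iter)
        seq = seqs[ci]
        _set(seq, p, "G")
        if _get(seq, p + 1) == "G":
            _set(seq, p + 1, _pick_base(rng, "G"))
        if _get(seq, p - 1) == "G":
            _set(seq, p - 1, _pick_base(rng, "G"))
        planted_indel.append((ci, p))
    planted_junctions = []
    for k in range(spec.n_junction_breakpoints):
        ci, a = next(slot_iter)
        cj, b = next(slot_iter)
        _set(seqs[ci], a, "G")
        if _get(seqs[ci], a + 1) == "G":
            _set(seqs[ci], a + 1, _pick_base(rng, "G"))
        _set(seqs[cj], b, "G")
        if _get(seqs[cj], b - 1) == "G":
            _set(seqs[cj], b - 1, _pick_base(rng, "G"))
        planted_junctions.append((ci, a, cj, b))

    genome = ReferenceGenome(
        {
            name: "".join(_BASES[seq])
            for name, seq in zip(contig_names, seqs)
        }
    )

    # --- phase 2: variant records and ground truth -------------------------
    variants: list[SomaticVariant] = []
    truth: list[PlantedSite] = []
    for ci, p in planted_plus:
        contig = contig_names[ci]
        var = SomaticVariant.from_alleles(
            contig, p + 1, genome.fetch(contig, p, p + 1), "G", spec.sample_id
        )
        variants.append(var)
        truth.append(
            PlantedSite("snv_pam", contig, p, "+",
                        genome.fetch(contig, p - 21, p - 1), var)
        )
    for ci, p in planted_minus:
        contig = contig_names[ci]
        var = SomaticVariant.from_alleles(
            contig, p + 1, genome.fetch(contig, p, p + 1), "C", spec.sample_id
        )
        variants.append(var)
        truth.append(
            PlantedSite("snv_pam", contig, p - 1, "-",
                        genome.fetch(contig, p + 2, p + 22, "-"), var)
        )
    for ci, p in planted_indel:
        contig = contig_names[ci]
        var = SomaticVariant(contig, p + 1, "G", "GG", "INS", spec.sample_id)
        variants.append(var)
        truth.append(
            PlantedSite("indel_pam", contig, p, "+",
                        genome.fetch(contig, p - 21, p - 1), var)
        )

    # neutral SNVs: rejection-sampled so they create no PAM
    for _ in range(spec.n_neutral_snvs):
        ci, p = next(slot_iter)
        contig = contig_names[ci]
        ref = genome.fetch(contig, p, p + 1)
        alts = [b for b in "ACGT" if b != ref]
        order = rng.permutation(len(alts))
        for idx in order:
            var = SomaticVariant.from_alleles(contig, p + 1, ref, alts[idx],
                                              spec.sample_id)
            if not scan_snv_for_novel_pams(var, genome):
                variants.append(var)
                break
        else:  # pragma: no cover - every ref base admits a neutral alt
            raise RuntimeError("could not sample a neutral SNV")

    # --- phase 3: breakpoints ----------------------------------------------
    breakpoints: list[Breakpoint] = []
    classes = ("ecDNA", "deletion", "inversion", "translocation")
    for k, (ci, a, cj, b) in enumerate(planted_junctions):
        bkp = Breakpoint(
            spec.sample_id, contig_names[ci], a + 1, "+",
            contig_names[cj], b + 1, "+", classes[k % len(classes)],
        )
        breakpoints.append(bkp)
        window = build_junction_window(bkp, genome)
        cands = detect_junction_pam(window)
        assert len(cands) == 1, "planting guarantee violated"
        truth.append(
            PlantedSite("junction_pam", contig_names[ci], a, "+",
                        cands[0].grna, breakpoint=bkp)
        )
    # neutral breakpoints edit nothing, so anchors are free random draws
    n_neutral_bkp = 0
    while n_neutral_bkp < spec.n_neutral_breakpoints:
        ci = int(rng.integers(len(contig_names)))
        cj = int(rng.integers(len(contig_names)))
        a = int(rng.integers(60, spec.contig_lengths[ci] - 60))
        b = int(rng.integers(60, spec.contig_lengths[cj] - 60))
        bkp = Breakpoint(
            spec.sample_id, contig_names[ci], a + 1, "+",
            contig_names[cj], b + 1, "+",
            classes[(len(breakpoints)) % len(classes)],
        )
        if detect_junction_pam(build_junction_window(bkp, genome)):
            continue  # junction happened to create a PAM; resample
        breakpoints.append(bkp)
        n_neutral_bkp += 1

    # --- phase 4: genes and feature tables ---------------------------------
    genes: list[GeneModel] = []
    per_contig = max(1, spec.n_genes // max(1, len(contig_names)))
    gi = 0
    for name, length in zip(contig_names, spec.contig_lengths):
        width = length // per_contig
        for j in range(per_contig):
            if gi >= spec.n_genes:
                break
            start = j * width + width // 10
            end = (j + 1) * width - width // 10
            strand = "+" if gi % 2 == 0 else "-"
            n_exons = int(rng.integers(1, 4))
            bounds = np.sort(rng.integers(start, end, size=2 * n_exons))
            exons = tuple(
                GenomicInterval(name, int(bounds[2 * e]), int(bounds[2 * e + 1]) + 1,
                                strand)
                for e in range(n_exons)
            )
            genes.append(
                GeneModel(f"GENE{gi:04d}", f"SYM{gi}", name, start, end,
                          strand, exons)
            )
            gi += 1

    features: dict[str, dict[str, float | None]] = {
        "expression": {}, "copy_number": {}, "dependency": {},
    }
    for g in genes:
        tpm = float(rng.lognormal(spec.tpm_log_mean, spec.tpm_log_sigma))
        cn = float(rng.integers(0, spec.copy_number_max + 1))
        dep = float(rng.uniform(*spec.dependency_range))
        for kind, val in (("expression", round(tpm, 3)),
                          ("copy_number", cn), ("dependency", round(dep, 4))):
            miss = rng.random() < spec.missing_feature_fraction
            features[kind][g.gene_id] = None if miss else val

    score_rows = [
        {
            "protospacer": site.protospacer,
            "cfd_spec": round(float(rng.uniform(50, 100)), 2),
            "mit_spec": round(float(rng.uniform(40, 100)), 2),
            "doench": round(float(rng.uniform(30, 80)), 2),
            "moreno": round(float(rng.uniform(30, 80)), 2),
        }
        for site in truth
    ]

    bundle = FixtureBundle(
        spec=spec, genome=genome, variants=variants, ground_truth=truth,
        genes=genes, features=features, score_rows=score_rows,
        breakpoints=breakpoints,
    )
    if output_dir is not None:
        _write_bundle(bundle, Path(output_dir))
    return bundle


# --- file writers -----------------------------------------------------------


def _write_fasta(genome: ReferenceGenome, path: Path) -> None:
    with open(path, "w") as fh:
        for contig in genome.contigs:
            fh.write(f">{contig}\n")
            seq = genome.sequence(contig)
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def _write_vcf(bundle: FixtureBundle, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FILTER=<ID=PASS,Description="All filters passed">\n')
        for contig in bundle.genome.contigs:
            fh.write(
                f"##contig=<ID={contig},length={bundle.genome.length(contig)}>\n"
            )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        ordered = sorted(bundle.variants, key=lambda v: (v.contig, v.pos))
        for v in ordered:
            fh.write(
                f"{v.contig}\t{v.pos}\t.\t{v.ref_allele}\t{v.alt_allele}"
                f"\t.\tPASS\t.\n"
            )


def _write_gtf(bundle: FixtureBundle, path: Path) -> None:
    with open(path, "w") as fh:
        for g in bundle.genes:
            attrs = f'gene_id "{g.gene_id}"; gene_name "{g.symbol}";'
            fh.write(
                f"{g.contig}\tsynthetic\tgene\t{g.start + 1}\t{g.end}\t."
                f"\t{g.strand}\t.\t{attrs}\n"
            )
            for k, ex in enumerate(g.exons):
                ex_attrs = attrs + f' transcript_id "{g.gene_id}.t1";'
                fh.write(
                    f"{g.contig}\tsynthetic\texon\t{ex.start + 1}\t{ex.end}\t."
                    f"\t{g.strand}\t.\t{ex_attrs}\n"
                )


def _write_feature_tsv(values: dict[str, float | None], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tvalue\n")
        for gene_id, val in values.items():
            fh.write(f"{gene_id}\t{'NA' if val is None else val}\n")


def _write_scores_tsv(rows: list[dict], path: Path) -> None:
    cols = ["protospacer", "cfd_spec", "mit_spec", "doench", "moreno"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[c]) for c in cols) + "\n")


def _write_breakpoints_tsv(bkps: list[Breakpoint], path: Path) -> None:
    cols = ["chrom1", "pos1", "strand1", "chrom2", "pos2", "strand2",
            "class", "sample"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for b in bkps:
            fh.write(
                f"{b.contig1}\t{b.pos1}\t{b.strand1}\t{b.contig2}\t{b.pos2}"
                f"\t{b.strand2}\t{b.svclass}\t{b.sample_id}\n"
            )


def _write_ground_truth_tsv(truth: list[PlantedSite], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("kind\tcontig\tgg_start_0based\tstrand\tprotospacer\n")
        for site in truth:
            fh.write(
                f"{site.kind}\t{site.contig}\t{site.gg_start}\t{site.strand}"
                f"\t{site.protospacer}\n"
            )


def _write_bundle(bundle: FixtureBundle, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "genome.fa",
        "vcf": outdir / "variants.vcf",
        "gtf": outdir / "genes.gtf",
        "expression": outdir / "expression.tsv",
        "copy_number": outdir / "copy_number.tsv",
        "dependency": outdir / "dependency.tsv",
        "scores": outdir / "guide_scores.tsv",
        "breakpoints": outdir / "breakpoints.tsv",
        "ground_truth": outdir / "ground_truth.tsv",
    }
    _write_fasta(bundle.genome, paths["fasta"])
    _write_vcf(bundle, paths["vcf"])
    _write_gtf(bundle, paths["gtf"])
    for kind in ("expression", "copy_number", "dependency"):
        _write_feature_tsv(bundle.features[kind], paths[kind])
    _write_scores_tsv(bundle.score_rows, paths["scores"])
    _write_breakpoints_tsv(bundle.breakpoints, paths["breakpoints"])
    _write_ground_truth_tsv(bundle.ground_truth, paths["ground_truth"])
    bundle.paths = paths
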