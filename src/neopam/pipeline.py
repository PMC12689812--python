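"""Stage orchestration over the library modules.

Stages communicate through headered TSV files carrying a schema comment
line, so every intermediate is inspectable and diff-able:

    discover   genome + VCF            → candidate TSV
    annotate   candidates + GTF/tables → annotated TSV
    rank       annotated               → ranked TSV + sample report (JSON)
    breakpoints genome + breakpoint TSV → junction candidate TSV
    recur      candidate TSVs          → cohort recurrence summary

The click command line in :mod:`neopam.cli` is a thin wrapper over these
functions; they are equally usable from Python.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from . import annotation, breakpoint_pam, cohort_stats, guide_scoring
from .genome_io import (
    ReferenceGenome,
    SomaticVariant,
    load_feature_table,
    load_gene_models,
    load_reference,
    load_somatic_variants,
)
from .pam_discovery import PamCandidate, discover_sample
from .ranking import RankingWeights, ReportThresholds, flag_sample, rank_candidates

SCHEMA_PREFIX = "# neopam schema v1"

CANDIDATE_COLUMNS = [
    "sample_id", "contig", "variant_pos_1based", "ref", "alt", "strand",
    "gg_start_0based", "n_pos_0based", "pam_3mer", "protospacer", "gene_id",
    "indel_derived",
]
ANNOTATION_COLUMNS = [
    "symbol", "tpm", "copy_number", "dependency",
    "cfd_spec", "mit_spec", "doench", "moreno",
]


def _write_tsv(df: pd.DataFrame, path: Path, stage: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"{SCHEMA_PREFIX} {stage}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_stage_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def candidates_to_frame(candidates: list[PamCandidate]) -> pd.DataFrame:
    rows = [
        {
            "sample_id": c.sample_id,
            "contig": c.contig,
            "variant_pos_1based": c.variant.pos,
            "ref": c.variant.ref_allele,
            "alt": c.variant.alt_allele,
            "strand": c.strand,
            "gg_start_0based": c.gg_start,
            "n_pos_0based": c.n_position,
            "pam_3mer": c.pam_3mer,
            "protospacer": c.protospacer,
            "gene_id": c.gene_id or "",
            "indel_derived": c.indel_derived,
        }
        for c in candidates
    ]
    return pd.DataFrame(rows, columns=CANDIDATE_COLUMNS)


def frame_to_candidates(df: pd.DataFrame) -> list[PamCandidate]:
    missing = [c for c in CANDIDATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"candidate table missing columns: {missing}")
    out = []
    for r in df.itertuples(index=False):
        var = SomaticVariant.from_alleles(
            r.contig, int(r.variant_pos_1based), r.ref, r.alt, str(r.sample_id)
        )
        gene = None if pd.isna(r.gene_id) or r.gene_id == "" else str(r.gene_id)
        out.append(
            PamCandidate(
                sample_id=str(r.sample_id), variant=var, strand=r.strand,
                contig=r.contig, gg_start=int(r.gg_start_0based),
                n_position=int(r.n_pos_0based), pam_3mer=r.pam_3mer,
                protospacer=r.protospacer, indel_derived=bool(r.indel_derived),
                gene_id=gene, provenance=(var,),
            )
        )
    return out


def run_discover(
    genome: ReferenceGenome | str | Path,
    vcf_path: str | Path,
    sample_id: str,
    out_tsv: str | Path | None = None,
    gtf_path: str | Path | None = None,
) -> pd.DataFrame:
    if not isinstance(genome, ReferenceGenome):
        genome = load_reference(genome)
    loaded = load_somatic_variants(vcf_path, sample_id, genome)
    variants = [
        v if v.sample_id == sample_id
        else SomaticVariant(v.contig, v.pos, v.ref_allele, v.alt_allele,
                            v.vtype, sample_id)
        for v in loaded.variants
    ]
    genes = load_gene_models(gtf_path, genome) if gtf_path else None
    result = discover_sample(variants, genome, genes)
    df = candidates_to_frame(result.candidates)
    if out_tsv is not None:
        _write_tsv(df, Path(out_tsv), "discover")
    return df


def run_annotate(
    genome: ReferenceGenome | str | Path,
    candidates_tsv: str | Path,
    gtf_path: str | Path,
    out_tsv: str | Path | None = None,
    expression_tsv: str | Path | None = None,
    copy_number_tsv: str | Path | None = None,
    dependency_tsv: str | Path | None = None,
    scores_tsv: str | Path | None = None,
    scoring_mode: str = "table_import",
    sample_id: str | None = None,
) -> pd.DataFrame:
    if not isinstance(genome, ReferenceGenome):
        genome = load_reference(genome)
    candidates = frame_to_candidates(read_stage_tsv(candidates_tsv))
    genes = load_gene_models(gtf_path, genome)
    tables = {}
    for kind, path in (("expression", expression_tsv),
                       ("copy_number", copy_number_tsv),
                       ("dependency", dependency_tsv)):
        if path is not None:
            tables[kind] = load_feature_table(path, kind)
    score_table = (
        guide_scoring.load_score_table(scores_tsv) if scores_tsv else {}
    )

    def score_lookup(protospacer: str) -> guide_scoring.ScoreSet:
        entry = score_table.get(protospacer.upper())
        if entry is not None:
            return entry
        if scoring_mode == "builtin":
            cfd, mit = guide_scoring.specificity_scores(protospacer, genome)
            doench, moreno = guide_scoring.efficiency_surrogate(protospacer)
            return guide_scoring.ScoreSet(cfd, mit, doench, moreno)
        return guide_scoring.ScoreSet()

    annotated = annotation.annotate_sample(
        candidates, genes, tables, score_lookup, sample_id
    )
    base = candidates_to_frame(candidates)
    extra = pd.DataFrame(
        [
            {
                "symbol": a.symbol or "",
                "tpm": a.expression_tpm,
                "copy_number": a.copy_number,
                "dependency": a.dependency,
                "cfd_spec": a.scores.cfd_spec,
                "mit_spec": a.scores.mit_spec,
                "doench": a.scores.doench,
                "moreno": a.scores.moreno,
            }
            for a in annotated
        ],
        columns=ANNOTATION_COLUMNS,
    )
    base["gene_id"] = [a.gene_id or "" for a in annotated]
    df = pd.concat([base, extra], axis=1)
    if out_tsv is not None:
        _write_tsv(df, Path(out_tsv), "annotate")
    return df


def _frame_to_annotated(df: pd.DataFrame) -> list[annotation.AnnotatedCandidate]:
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotated table missing columns: {missing}")
    candidates = frame_to_candidates(df)
    out = []

    def val(x):
        return None if pd.isna(x) else float(x)

    for cand, r in zip(candidates, df.itertuples(index=False)):
        gene = cand.gene_id
        symbol = None
        if gene is not None:
            symbol = gene if pd.isna(r.symbol) or r.symbol == "" else str(r.symbol)
        out.append(
            annotation.AnnotatedCandidate(
                candidate=cand,
                gene_id=gene,
                symbol=symbol,
                expression_tpm=val(r.tpm) if gene else None,
                copy_number=val(r.copy_number) if gene else None,
                dependency=val(r.dependency) if gene else None,
                scores=guide_scoring.ScoreSet(
                    val(r.cfd_spec), val(r.mit_spec), val(r.doench), val(r.moreno)
                ),
            )
        )
    return out


def run_rank(
    annotated_tsv: str | Path,
    out_tsv: str | Path | None = None,
    report_json: str | Path | None = None,
    weights: RankingWeights = RankingWeights(),
    thresholds: ReportThresholds = ReportThresholds(),
) -> pd.DataFrame:
    df = read_stage_tsv(annotated_tsv)
    if df.empty:
        raise ValueError("no candidates")
    annotated = _frame_to_annotated(df)
    ranked = rank_candidates(annotated, weights)
    rows = []
    for r in ranked:
        row = {
            "sample_id": r.annotated.candidate.sample_id,
            "contig": r.annotated.candidate.contig,
            "gg_start_0based": r.annotated.candidate.gg_start,
            "strand": r.annotated.candidate.strand,
            "protospacer": r.annotated.candidate.protospacer,
            "gene_id": r.annotated.gene_id or "",
        }
        row.update({f"rank_{f}": r.feature_ranks[f] for f in r.feature_ranks})
        row.update(
            raw_score=r.raw_score,
            normalized_score=round(r.normalized_score, 4),
            final_rank=r.final_rank,
        )
        rows.append(row)
    out = pd.DataFrame(rows)
    if out_tsv is not None:
        _write_tsv(out, Path(out_tsv), "rank")
    if report_json is not None:
        report = flag_sample(ranked, thresholds)
        payload = {
            "n_candidates": report.n_candidates,
            "min_pam_count": report.min_pam_count,
            "meets_min_pam_count": report.meets_min_pam_count,
            "top3_cfd_pass": report.top3_cfd_pass,
            "top3_mit_pass": report.top3_mit_pass,
            "all_top3_pass": report.all_top3_pass,
        }
        Path(report_json).write_text(json.dumps(payload, indent=2) + "\n")
    return out


def run_breakpoints(
    genome: ReferenceGenome | str | Path,
    breakpoints_tsv: str | Path,
    out_tsv: str | Path | None = None,
    summary_tsv: str | Path | None = None,
) -> pd.DataFrame:
    if not isinstance(genome, ReferenceGenome):
        genome = load_reference(genome)
    bkps = breakpoint_pam.load_breakpoints(breakpoints_tsv)
    result = breakpoint_pam.analyze_cohort_breakpoints(bkps, genome)
    if out_tsv is not None:
        _write_tsv(result.table, Path(out_tsv), "breakpoints")
    if summary_tsv is not None:
        _write_tsv(result.per_sample, Path(summary_tsv), "breakpoints-summary")
    return result.table


def run_recur(
    candidate_tsvs: list[str | Path],
    out_json: str | Path | None = None,
) -> cohort_stats.RecurrenceSummary:
    per_sample: dict[str, set] = {}
    for path in candidate_tsvs:
        df = read_stage_tsv(path)
        for r in df.itertuples(index=False):
            per_sample.setdefault(str(r.sample_id), set()).add(
                (r.contig, int(r.gg_start_0based), r.strand)
            )
    summary = cohort_stats.recurrence(per_sample)
    if out_json is not None:
        payload = {
            "total_occurrences": summary.total_occurrences,
            "histogram": {str(k): v for k, v in sorted(summary.histogram.items())},
            "recurrent_occurrences": summary.recurrent_occurrences,
            "recurrence_rate_pct": round(summary.recurrence_rate_pct, 2),
        }
        Path(out_json).write_text(json.dumps(payload, indent=2) + "\n")
    return summary


def run_all(
    genome_path: str | Path,
    vcf_path: str | Path,
    gtf_path: str | Path,
    sample_id: str,
    output_dir: str | Path,
    expression_tsv: str | Path | None = None,
    copy_number_tsv: str | Path | None = None,
    dependency_tsv: str | Path | None = None,
    scores_tsv: str | Path | None = None,
    breakpoints_tsv: str | Path | None = None,
    scoring_mode: str = "table_import",
    weights: RankingWeights = RankingWeights(),
    thresholds: ReportThresholds = ReportThresholds(),
) -> dict[str, Path]:
    """Discover → annotate → rank (→ breakpoints) over one sample."""
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = load_reference(genome_path)
    paths = {
        "candidates": outdir / "candidates.tsv",
        "annotated": outdir / "annotated.tsv",
        "ranked": outdir / "ranked.tsv",
        "report": outdir / "sample_report.json",
    }
    run_discover(genome, vcf_path, sample_id, paths["candidates"], gtf_path)
    run_annotate(
        genome, paths["candidates"], gtf_path, paths["annotated"],
        expression_tsv, copy_number_tsv, dependency_tsv, scores_tsv,
        scoring_mode, sample_id,
    )
    run_rank(paths["annotated"], paths["ranked"], paths["report"],
             weights, thresholds)
    if breakpoints_tsv is not None:
        paths["breakpoint_candidates"] = outdir / "breakpoint_candidates.tsv"
        paths["breakpoint_summary"] = outdir / "breakpoint_summary.tsv"
        run_breakpoints(genome, breakpoints_tsv,
                        paths["breakpoint_candidates"],
                        paths["breakpoint_summary"])
    return paths
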