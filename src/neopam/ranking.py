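"""Weighted rank-sum prioritisation of annotated PAM candidates.

Within one dataset (one sample's candidate set) every candidate is ranked
per feature from 1 (worst) to n (best); higher values are better for all
seven features — for gene dependency a higher (less negative) score means a
less essential gene and hence a safer target.  Ties share the average of the
spanned ranks; candidates missing a feature all receive rank 1 for it.  The
composite raw score is

    2·rank(CFD) + rank(MIT) + 0.5·(rank(Doench) + rank(Moreno))
    + rank(dependency) + rank(expression) + rank(copy number)

which is min–max normalised to 0–100 within the dataset (100 = most
promising; a lone candidate or an all-tied dataset scores 100), and final
ranks are assigned from highest to lowest normalised score with shared ties.

A sample-level report flags feasibility/safety: samples need a minimum
number of novel PAM sites (default 86) and the top-3 candidates are checked
against CFD > 90 and MIT > 80 specificity cuts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

from .annotation import AnnotatedCandidate

__all__ = [
    "RankingWeights",
    "RankedCandidate",
    "ReportThresholds",
    "SampleReport",
    "rank_feature",
    "composite_score",
    "rank_candidates",
    "flag_sample",
]

FEATURES = ("cfd_spec", "mit_spec", "doench", "moreno",
            "dependency", "expression", "copy_number")


@dataclass(frozen=True)
class RankingWeights:
    """Feature weights of the composite score (all must be ≥ 0)."""

    w_cfd: float = 2.0
    w_mit: float = 1.0
    w_eff: float = 0.5  # applied to rank(Doench) + rank(Moreno)
    w_dependency: float = 1.0
    w_expression: float = 1.0
    w_copy_number: float = 1.0

    def __post_init__(self) -> None:
        if any(
            w < 0
            for w in (self.w_cfd, self.w_mit, self.w_eff,
                      self.w_dependency, self.w_expression, self.w_copy_number)
        ):
            raise ValueError("weights must be non-negative")


@dataclass(frozen=True)
class ReportThresholds:
    """Feasibility/safety thresholds for the sample report."""

    min_pam_count: int = 86
    cfd_cut: float = 90.0
    mit_cut: float = 80.0

    def __post_init__(self) -> None:
        if self.min_pam_count < 0 or self.cfd_cut < 0 or self.mit_cut < 0:
            raise ValueError("thresholds must be non-negative")


@dataclass(frozen=True)
class RankedCandidate:
    """An annotated candidate with its ranks and final placement."""

    annotated: AnnotatedCandidate
    feature_ranks: Mapping[str, float]
    raw_score: float
    normalized_score: float
    final_rank: int


def rank_feature(
    values: Sequence[float | None], direction: str = "higher"
) -> np.ndarray:
    """Ranks 1 (worst) to n (best), average ranks for ties.

    Missing values (None) all receive — and share — rank 1; the remaining
    entries occupy the ranks above the missing block.
    """
    if len(values) == 0:
        raise ValueError("cannot rank an empty feature vector")
    if direction not in ("higher", "lower"):
        raise ValueError("direction must be 'higher' or 'lower'")
    n = len(values)
    ranks = np.ones(n, dtype=float)
    present = np.array([v is not None for v in values])
    if present.any():
        vals = np.array([v for v in values if v is not None], dtype=float)
        if direction == "lower":
            vals = -vals
        n_missing = n - int(present.sum())
        ranks[present] = rankdata(vals, method="average") + n_missing
    return ranks


def composite_score(
    ranks: Mapping[str, float], weights: RankingWeights = RankingWeights()
) -> float:
    """Weighted rank sum over the seven features."""
    return (
        weights.w_cfd * ranks["cfd_spec"]
        + weights.w_mit * ranks["mit_spec"]
        + weights.w_eff * (ranks["doench"] + ranks["moreno"])
        + weights.w_dependency * ranks["dependency"]
        + weights.w_expression * ranks["expression"]
        + weights.w_copy_number * ranks["copy_number"]
    )


def _feature_value(cand: AnnotatedCandidate, feature: str) -> float | None:
    if feature == "expression":
        return cand.expression_tpm
    if feature in ("copy_number", "dependency"):
        return getattr(cand, feature)
    return getattr(cand.scores, feature)


def rank_candidates(
    candidates: Sequence[AnnotatedCandidate],
    weights: RankingWeights = RankingWeights(),
) -> list[RankedCandidate]:
    """Rank one dataset of annotated candidates.

    Per-feature ranks → weighted composite → min–max normalisation to
    0–100 → final ranks (1 = best, shared on ties).  Input order never
    influences any rank or score; the returned list is sorted by final rank
    with coordinate tie-breaking for a stable layout only.
    """
    if not candidates:
        raise ValueError("empty dataset: no candidates to rank")
    feature_ranks = {
        f: rank_feature([_feature_value(c, f) for c in candidates])
        for f in FEATURES
    }
    raw = np.array(
        [
            composite_score({f: feature_ranks[f][i] for f in FEATURES}, weights)
            for i in range(len(candidates))
        ]
    )
    lo, hi = raw.min(), raw.max()
    if hi > lo:
        norm = (raw - lo) / (hi - lo) * 100.0
    else:
        norm = np.full_like(raw, 100.0)  # lone or all-tied dataset
    final = rankdata(-norm, method="min").astype(int)
    ranked = [
        RankedCandidate(
            annotated=c,
            feature_ranks={f: float(feature_ranks[f][i]) for f in FEATURES},
            raw_score=float(raw[i]),
            normalized_score=float(norm[i]),
            final_rank=int(final[i]),
        )
        for i, c in enumerate(candidates)
    ]
    ranked.sort(
        key=lambda r: (
            r.final_rank,
            r.annotated.candidate.contig,
            r.annotated.candidate.gg_start,
            r.annotated.candidate.strand,
        )
    )
    return ranked


@dataclass
class SampleReport:
    """Feasibility/safety summary for one sample's ranked candidates."""

    n_candidates: int
    min_pam_count: int
    meets_min_pam_count: bool
    top3: list[RankedCandidate] = field(default_factory=list)
    top3_cfd_pass: list[bool] = field(default_factory=list)
    top3_mit_pass: list[bool] = field(default_factory=list)

    @property
    def all_top3_pass(self) -> bool:
        return (
            self.meets_min_pam_count
            and all(self.top3_cfd_pass)
            and all(self.top3_mit_pass)
        )


def flag_sample(
    ranked: Sequence[RankedCandidate],
    thresholds: ReportThresholds = ReportThresholds(),
) -> SampleReport:
    """Per-sample report: total PAM count against the feasibility minimum,
    and top-3 specificity against the CFD/MIT safety cuts (a missing score
    fails its cut)."""
    top3 = list(ranked[:3])
    cfd_pass = [
        (r.annotated.scores.cfd_spec is not None
         and r.annotated.scores.cfd_spec > thresholds.cfd_cut)
        for r in top3
    ]
    mit_pass = [
        (r.annotated.scores.mit_spec is not None
         and r.annotated.scores.mit_spec > thresholds.mit_cut)
        for r in top3
    ]
    return SampleReport(
        n_candidates=len(ranked),
        min_pam_count=thresholds.min_pam_count,
        meets_min_pam_count=len(ranked) >= thresholds.min_pam_count,
        top3=top3,
        top3_cfd_pass=cfd_pass,
        top3_mit_pass=mit_pass,
    )
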