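"""Guide specificity and efficiency scoring.

Two specificity scores are provided, both on a 0–100 scale where 100 means no
predicted off-target burden:

* a CFD-style score: each off-target hit contributes a similarity
  ``s = Π penalty(position, guide base, off-target base) × PAM-class
  penalty``, and the per-guide score is ``100 / (1 + Σ s)`` over all hits
  excluding the intended site;
* an MIT-style score: per-hit similarity uses the classic position-weight
  vector together with a mean-pairwise-distance term and a
  mismatch-count term, aggregated the same way.

Position/identity-dependent CFD penalties are supplied via
:meth:`PenaltyModel.from_tsv` (a published mismatch-penalty table); a
uniform-penalty model (every mismatch 0.5) is the in-repo default so the
package runs with no external data.  The shipped MIT position weights are the
standard published vector (position 1 = PAM-distal, position 20 =
PAM-proximal).

Efficiency scores (Doench and Moreno-Mateos style, 0–100) are imported from a
precomputed guide-score table; a deterministic built-in surrogate based on GC
content and simple position heuristics exists so synthetic fixtures run end
to end.  The surrogate is NOT a publication-grade efficiency model.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_io import GenomicInterval, ReferenceGenome, reverse_complement

__all__ = [
    "MIT_POSITION_WEIGHTS",
    "PenaltyModel",
    "OffTargetHit",
    "ScoreSet",
    "enumerate_offtargets",
    "cfd_hit_score",
    "mit_hit_score",
    "aggregate_specificity",
    "specificity_scores",
    "efficiency_scores",
    "load_score_table",
]

# Classic per-position mismatch weights (position 1 = PAM-distal).
MIT_POSITION_WEIGHTS: tuple[float, ...] = (
    0.0, 0.0, 0.014, 0.0, 0.0, 0.395, 0.317, 0.0, 0.389, 0.079,
    0.445, 0.508, 0.613, 0.851, 0.732, 0.828, 0.615, 0.804, 0.685, 0.583,
)

GUIDE_LENGTH = 20


@dataclass(frozen=True)
class PenaltyModel:
    """Mismatch penalties for CFD-style scoring plus MIT position weights.

    ``mismatch_penalties`` maps ``(position, guide_base, offtarget_base)`` to
    a penalty in [0, 1]; positions run 1..20 with 20 PAM-proximal.  When the
    mapping is None every mismatch costs ``uniform_penalty``.  Non-canonical
    PAMs (anything but NGG) cost ``pam_penalties`` keyed by the PAM's last
    two bases, defaulting to ``uniform_penalty``.
    """

    mismatch_penalties: Mapping[tuple[int, str, str], float] | None = None
    uniform_penalty: float = 0.5
    pam_penalties: Mapping[str, float] | None = None
    position_weights: tuple[float, ...] = MIT_POSITION_WEIGHTS

    def __post_init__(self) -> None:
        vals = list((self.mismatch_penalties or {}).values())
        vals += list((self.pam_penalties or {}).values())
        vals.append(self.uniform_penalty)
        if any(not 0.0 <= v <= 1.0 for v in vals):
            raise ValueError("all penalties must lie in [0, 1]")

    @classmethod
    def uniform(cls, penalty: float = 0.5) -> "PenaltyModel":
        return cls(uniform_penalty=penalty)

    @classmethod
    def from_tsv(cls, path: str | Path, uniform_penalty: float = 0.5) -> "PenaltyModel":
        """Load a penalty table (columns: position, ref_base, obs_base,
        penalty); rows with position 'PAM' define PAM-class penalties keyed
        by ref_base (the PAM's last two bases)."""
        df = pd.read_csv(path, sep="\t", dtype={"position": str})
        mm: dict[tuple[int, str, str], float] = {}
        pam: dict[str, float] = {}
        for row in df.itertuples(index=False):
            if str(row.position).upper() == "PAM":
                pam[row.ref_base.upper()] = float(row.penalty)
            else:
                mm[(int(row.position), row.ref_base.upper(), row.obs_base.upper())] = (
                    float(row.penalty)
                )
        return cls(mismatch_penalties=mm, uniform_penalty=uniform_penalty,
                   pam_penalties=pam)

    def mismatch_penalty(self, position: int, guide_base: str, ot_base: str) -> float:
        if self.mismatch_penalties is None:
            return self.uniform_penalty
        key = (position, guide_base, ot_base)
        if key not in self.mismatch_penalties:
            raise KeyError(f"no penalty for mismatch {key}")
        return self.mismatch_penalties[key]

    def pam_penalty(self, pam: str) -> float:
        if pam[1:] == "GG":
            return 1.0
        if self.pam_penalties is not None and pam[1:] in self.pam_penalties:
            return self.pam_penalties[pam[1:]]
        return self.uniform_penalty


@dataclass(frozen=True)
class OffTargetHit:
    """One genomic site similar to a guide.

    ``mismatches`` lists (position 1..20 with 20 PAM-proximal, guide base,
    off-target base).
    """

    interval: GenomicInterval  # the 20-nt site, plus-strand coordinates
    site_seq: str  # 20 nt + 3 nt PAM, read 5'→3' on the hit strand
    pam: str
    mismatches: tuple[tuple[int, str, str], ...]
    is_on_target: bool = False

    @property
    def n_mismatches(self) -> int:
        return len(self.mismatches)


def _pam_mask(arr: np.ndarray, patterns: Iterable[str]) -> np.ndarray:
    """Boolean mask over window starts whose PAM (at offset GUIDE_LENGTH)
    matches any pattern; ``arr`` is the uint8-encoded sequence."""
    n = len(arr) - GUIDE_LENGTH - 3 + 1
    mask = np.zeros(n, dtype=bool)
    for pat in patterns:
        m = np.ones(n, dtype=bool)
        for off, ch in enumerate(pat):
            if ch == "N":
                continue
            m &= arr[GUIDE_LENGTH + off : GUIDE_LENGTH + off + n] == ord(ch)
        mask |= m
    return mask


def enumerate_offtargets(
    protospacer: str,
    genome: ReferenceGenome,
    max_mismatches: int = 4,
    pam_patterns: Sequence[str] = ("NGG", "NAG"),
    on_target: GenomicInterval | None = None,
) -> list[OffTargetHit]:
    """Brute-force search of both strands for sites within
    ``max_mismatches`` of the protospacer and followed by an allowed PAM.

    The on-target site is included and flagged: the hit matching
    ``on_target`` when given, otherwise the first zero-mismatch hit in
    position order.
    """
    if len(protospacer) != GUIDE_LENGTH:
        raise ValueError("protospacer must be 20 nt")
    guide = np.frombuffer(protospacer.encode(), dtype=np.uint8)
    hits: list[OffTargetHit] = []
    for contig in genome.contigs:
        plus = genome.sequence(contig)
        length = len(plus)
        for strand, seq in (("+", plus), ("-", reverse_complement(plus))):
            arr = np.frombuffer(seq.encode(), dtype=np.uint8)
            n = length - GUIDE_LENGTH - 3 + 1
            if n <= 0:
                continue
            pam_ok = _pam_mask(arr, pam_patterns)
            windows = np.lib.stride_tricks.sliding_window_view(arr, GUIDE_LENGTH)[:n]
            mm_counts = (windows != guide).sum(axis=1)
            starts = np.nonzero(pam_ok & (mm_counts <= max_mismatches))[0]
            for j in map(int, starts):
                site = seq[j : j + GUIDE_LENGTH + 3]
                mismatches = tuple(
                    (k + 1, protospacer[k], site[k])
                    for k in range(GUIDE_LENGTH)
                    if site[k] != protospacer[k]
                )
                if strand == "+":
                    iv = GenomicInterval(contig, j, j + GUIDE_LENGTH, "+")
                else:
                    start_plus = length - (j + GUIDE_LENGTH)
                    iv = GenomicInterval(contig, start_plus, start_plus + GUIDE_LENGTH, "-")
                hits.append(
                    OffTargetHit(iv, site, site[GUIDE_LENGTH:], mismatches)
                )
    hits.sort(key=lambda h: (h.interval.contig, h.interval.start, h.interval.strand))
    flagged: list[OffTargetHit] = []
    found_on_target = False
    for h in hits:
        is_ot = False
        if on_target is not None:
            is_ot = (
                h.interval.contig == on_target.contig
                and h.interval.start == on_target.start
                and h.interval.strand == on_target.strand
            )
        elif not found_on_target and h.n_mismatches == 0:
            is_ot = True
        if is_ot:
            found_on_target = True
            h = OffTargetHit(h.interval, h.site_seq, h.pam, h.mismatches, True)
        flagged.append(h)
    return flagged


def cfd_hit_score(
    protospacer: str, hit: OffTargetHit, penalties: PenaltyModel
) -> float:
    """Product of per-mismatch penalties times the PAM-class penalty; 1.0
    for a perfect match with canonical NGG."""
    s = penalties.pam_penalty(hit.pam)
    for pos, gbase, obase in hit.mismatches:
        s *= penalties.mismatch_penalty(pos, gbase, obase)
    return s


def mit_hit_score(
    protospacer: str, hit: OffTargetHit, weights: PenaltyModel | None = None
) -> float:
    """Per-hit similarity from position weights, mismatch spacing and count.

    ``Π (1 − W[pos]) × 1 / (((19 − d̄)/19)·4 + 1) × 1/m²`` where ``d̄`` is the
    mean distance between neighbouring mismatch positions; a perfect match
    scores 1.0 and a single mismatch uses only its position weight.
    """
    w = (weights or PenaltyModel()).position_weights
    m = hit.n_mismatches
    if m == 0:
        return 1.0
    score = 1.0
    positions = sorted(pos for pos, _, _ in hit.mismatches)
    for pos in positions:
        score *= 1.0 - w[pos - 1]
    if m > 1:
        d_mean = (positions[-1] - positions[0]) / (m - 1)
        score *= 1.0 / (((19.0 - d_mean) / 19.0) * 4.0 + 1.0)
        score *= 1.0 / (m * m)
    return score


def aggregate_specificity(off_target_scores: Iterable[float]) -> float:
    """``100 / (1 + Σ s)`` over per-hit similarities (on-target excluded);
    100 when there are no off-targets, strictly decreasing per added hit."""
    total = 0.0
    for s in off_target_scores:
        if not 0.0 <= s <= 1.0:
            raise ValueError(f"per-hit similarity {s} outside [0, 1]")
        total += s
    return 100.0 / (1.0 + total)


def specificity_scores(
    protospacer: str,
    genome: ReferenceGenome,
    penalties: PenaltyModel | None = None,
    max_mismatches: int = 4,
    pam_patterns: Sequence[str] = ("NGG", "NAG"),
    on_target: GenomicInterval | None = None,
) -> tuple[float, float]:
    """(CFD-style, MIT-style) specificity for a guide against a genome."""
    penalties = penalties or PenaltyModel()
    hits = enumerate_offtargets(
        protospacer, genome, max_mismatches, pam_patterns, on_target
    )
    off = [h for h in hits if not h.is_on_target]
    cfd = aggregate_specificity(cfd_hit_score(protospacer, h, penalties) for h in off)
    mit = aggregate_specificity(mit_hit_score(protospacer, h, penalties) for h in off)
    return cfd, mit


@dataclass(frozen=True)
class ScoreSet:
    """The four per-guide scores, each in [0, 100] or missing (None)."""

    cfd_spec: float | None = None
    mit_spec: float | None = None
    doench: float | None = None
    moreno: float | None = None

    def __post_init__(self) -> None:
        for name in ("cfd_spec", "mit_spec", "doench", "moreno"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 100.0:
                raise ValueError(f"{name}={v} outside [0, 100]")


def _gc_fraction(seq: str) -> float:
    return sum(c in "GC" for c in seq) / len(seq)


def efficiency_surrogate(protospacer: str) -> tuple[float, float]:
    """Deterministic stand-in efficiency scores (0–100).

    A smooth GC-optimum term plus small position heuristics (G at the
    PAM-proximal end favoured, leading T disfavoured).  Not a trained
    efficiency model; provided only so synthetic fixtures run end to end.
    """
    gc = _gc_fraction(protospacer)
    base = 100.0 * max(0.0, 1.0 - abs(gc - 0.55) / 0.55)
    doench = base
    if protospacer[-1] == "G":
        doench = min(100.0, doench + 10.0)
    if protospacer[0] == "T":
        doench = max(0.0, doench - 10.0)
    moreno = 100.0 * max(0.0, 1.0 - abs(gc - 0.60) / 0.60)
    if protospacer.count("A") > GUIDE_LENGTH // 2:
        moreno = max(0.0, moreno - 15.0)
    return round(doench, 2), round(moreno, 2)


def load_score_table(path: str | Path) -> dict[str, ScoreSet]:
    """Load a guide-score TSV keyed by protospacer (columns: protospacer,
    cfd_spec, mit_spec, doench, moreno; missing cells allowed)."""
    df = pd.read_csv(path, sep="\t")
    if "protospacer" not in df.columns:
        raise ValueError(f"missing 'protospacer' column in {path}")
    table: dict[str, ScoreSet] = {}
    for row in df.itertuples(index=False):
        vals = {}
        for name in ("cfd_spec", "mit_spec", "doench", "moreno"):
            v = getattr(row, name, None)
            vals[name] = None if v is None or pd.isna(v) else float(v)
        table[row.protospacer.upper()] = ScoreSet(**vals)
    return table


def efficiency_scores(
    protospacer: str,
    mode: str = "table_import",
    table: Mapping[str, ScoreSet] | None = None,
) -> tuple[float | None, float | None]:
    """(Doench-style, Moreno-style) efficiency for a guide.

    ``table_import`` looks the guide up in a precomputed score table and
    returns (None, None) when absent (feeding the ranking's missing-value
    rule); ``builtin_surrogate`` computes the deterministic stand-in.
    """
    if mode == "table_import":
        if table is None:
            raise ValueError("table_import mode requires a score table")
        entry = table.get(protospacer.upper())
        if entry is None:
            return None, None
        return entry.doench, entry.moreno
    if mode == "builtin_surrogate":
        return efficiency_surrogate(protospacer)
    raise ValueError(f"unknown efficiency mode {mode!r}")
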