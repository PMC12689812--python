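"""Novel PAMs and guides at structural-variant / ecDNA breakpoint junctions.

Rearrangement junctions (from deletions, insertions, inversions, tandem
duplications, translocations, or ecDNA circularisation) juxtapose two
genomic segments and can create CRISPR target sites absent from the
reference genome.  For every breakpoint a 60-nt junction window is built
from the 30 retained nucleotides on each side, strand-corrected so the
joined sequence reads 5'→3' across the junction as on the derivative
chromosome.  Window positions are numbered −30…−1 (left flank) and +1…+30
(right flank); there is no position 0.

Two candidate classes are detected:

* **junction-created PAM** — the (−1, +1) dinucleotide is GG (NGG motif,
  guide = positions −22…−3) or CC (CCN motif, guide = reverse complement of
  +3…+22).  The site is novel only if neither wild-type context already
  supplies the partner base at the same offset (the base natively following
  the left flank, and the base natively preceding the right flank, are both
  checked).
* **junction-spanning guide** — an NGG whose N lies at +6…+16, or a CCN
  whose first C lies at −18…−8, yields a 20-nt guide crossing the junction;
  guides need at least 4 nt on each side of the junction, which is the
  operational tumour-specificity requirement for this class.

Breakpoint input is a BEDPE-like TSV (chrom1, pos1, strand1, chrom2, pos2,
strand2, class, sample).  Positions are 1-based and name the
junction-adjacent retained base on each side; strand '+' means the retained
flank lies on the reference plus strand (side 1: upstream of and including
pos1; side 2: downstream of and including pos2), strand '−' means the
retained flank is the reverse complement of the opposite reference side.
Junctions are modelled as clean joins (no microhomology or non-templated
insertions).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .genome_io import ReferenceGenome, reverse_complement

__all__ = [
    "FLANK",
    "Breakpoint",
    "JunctionWindow",
    "BreakpointPamCandidate",
    "load_breakpoints",
    "junction_pos_to_index",
    "index_to_junction_pos",
    "build_junction_window",
    "detect_junction_pam",
    "is_junction_pam_novel",
    "detect_spanning_guides",
    "analyze_cohort_breakpoints",
]

FLANK = 30
GUIDE_LENGTH = 20
MIN_SIDE_OVERLAP = 4
SV_CLASSES = (
    "ecDNA", "deletion", "insertion", "inversion",
    "tandem_duplication", "translocation",
)


@dataclass(frozen=True)
class Breakpoint:
    """One junction: per-side contig, 1-based junction-adjacent position,
    and orientation of the retained flank."""

    sample_id: str
    contig1: str
    pos1: int
    strand1: str
    contig2: str
    pos2: int
    strand2: str
    svclass: str = "deletion"

    def __post_init__(self) -> None:
        if self.strand1 not in "+-" or self.strand2 not in "+-":
            raise ValueError("strands must be '+' or '-'")
        if self.pos1 < 1 or self.pos2 < 1:
            raise ValueError("positions are 1-based and must be >= 1")


def load_breakpoints(path: str | Path) -> list[Breakpoint]:
    """Read the BEDPE-like breakpoint TSV (see module docstring)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = ["chrom1", "pos1", "strand1", "chrom2", "pos2", "strand2",
                "class", "sample"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"breakpoint table missing columns: {missing}")
    return [
        Breakpoint(
            sample_id=str(r.sample),
            contig1=str(r.chrom1), pos1=int(r.pos1), strand1=str(r.strand1),
            contig2=str(r.chrom2), pos2=int(r.pos2), strand2=str(r.strand2),
            svclass=str(r.svclass),
        )
        for r in df.rename(columns={"class": "svclass"}).itertuples(index=False)
    ]


@dataclass(frozen=True)
class JunctionWindow:
    """The joined 60-mer around a junction plus the wild-type continuation
    bases used for the novelty check."""

    breakpoint: Breakpoint
    left: str  # positions −30…−1, 5'→3' on the derivative
    right: str  # positions +1…+30
    native_after_left: str  # base natively following the left flank
    native_before_right: str  # base natively preceding the right flank

    def __post_init__(self) -> None:
        if len(self.left) != FLANK or len(self.right) != FLANK:
            raise ValueError("flanks must be exactly 30 nt (N-padded if short)")

    @property
    def joined(self) -> str:
        return self.left + self.right

    def base(self, pos: int) -> str:
        return self.joined[junction_pos_to_index(pos)]


def junction_pos_to_index(pos: int) -> int:
    """Map junction position (−30…−1, +1…+30; no 0) to 0…59."""
    if pos == 0 or not -FLANK <= pos <= FLANK:
        raise ValueError(f"junction position {pos} out of range")
    return pos + FLANK if pos < 0 else pos + FLANK - 1


def index_to_junction_pos(idx: int) -> int:
    """Inverse of :func:`junction_pos_to_index`."""
    if not 0 <= idx < 2 * FLANK:
        raise ValueError(f"index {idx} out of range")
    return idx - FLANK if idx < FLANK else idx - FLANK + 1


def _padded_fetch(genome: ReferenceGenome, contig: str, start: int, end: int) -> str:
    """Plus-strand fetch with N padding outside the contig bounds."""
    length = genome.length(contig)
    left_pad = max(0, -start)
    right_pad = max(0, end - length)
    if left_pad or right_pad:
        warnings.warn(
            f"junction flank at {contig}:[{start},{end}) crosses the contig "
            "end; padding with N"
        )
    core = genome.fetch(contig, max(0, start), min(length, end))
    return "N" * left_pad + core + "N" * right_pad


def build_junction_window(bkp: Breakpoint, genome: ReferenceGenome) -> JunctionWindow:
    """Extract and strand-correct the two 30-nt flanks of a junction.

    Each flank is the retained sequence adjacent to the junction,
    reverse-complemented when the retained side's orientation requires it,
    so the joined 60-mer reads 5'→3' across the junction as on the
    derivative chromosome.  The wild-type continuation bases are recorded
    from the unrearranged reference.
    """
    c1, p1 = bkp.contig1, bkp.pos1 - 1  # 0-based junction-adjacent base
    c2, p2 = bkp.contig2, bkp.pos2 - 1
    if bkp.strand1 == "+":
        left = _padded_fetch(genome, c1, p1 - FLANK + 1, p1 + 1)
        native_after_left = _padded_fetch(genome, c1, p1 + 1, p1 + 2)
    else:
        left = reverse_complement(_padded_fetch(genome, c1, p1, p1 + FLANK))
        native_after_left = reverse_complement(_padded_fetch(genome, c1, p1 - 1, p1))
    if bkp.strand2 == "+":
        right = _padded_fetch(genome, c2, p2, p2 + FLANK)
        native_before_right = _padded_fetch(genome, c2, p2 - 1, p2)
    else:
        right = reverse_complement(_padded_fetch(genome, c2, p2 - FLANK + 1, p2 + 1))
        native_before_right = reverse_complement(
            _padded_fetch(genome, c2, p2 + 1, p2 + 2)
        )
    return JunctionWindow(bkp, left, right, native_after_left, native_before_right)


@dataclass(frozen=True)
class BreakpointPamCandidate:
    """A junction-created PAM or junction-spanning guide."""

    breakpoint: Breakpoint
    kind: str  # 'junction_pam' | 'spanning_guide'
    motif: str  # 'NGG' | 'CCN'
    grna: str
    left_overlap: int  # protospacer nt 5' of the junction (positions < 0)
    right_overlap: int
    pam_position: int  # junction position of the N (NGG) / first C (CCN)
    is_novel: bool = True

    def __post_init__(self) -> None:
        if len(self.grna) != GUIDE_LENGTH:
            raise ValueError("gRNA must be 20 nt")
        if self.kind == "spanning_guide" and (
            self.left_overlap < MIN_SIDE_OVERLAP
            or self.right_overlap < MIN_SIDE_OVERLAP
        ):
            raise ValueError("spanning guides need >= 4 nt on each side")
        if self.left_overlap + self.right_overlap != GUIDE_LENGTH:
            raise ValueError("side overlaps must sum to the guide length")

    @property
    def site_key(self) -> tuple[str, str]:
        """Cross-sample identity: junction coordinates differ between
        patients for the same biological target, so key by sequence."""
        return (self.motif, self.grna)


def is_junction_pam_novel(window: JunctionWindow, motif: str) -> bool:
    """Novelty of a (−1, +1) junction dinucleotide.

    For GG: novel iff neither the base natively following the left flank nor
    the base natively preceding the right flank is G (otherwise the same
    dinucleotide already exists in one wild-type context).  Symmetric with C
    for CC.
    """
    partner = {"NGG": "G", "CCN": "C"}[motif]
    return (
        window.native_after_left != partner
        and window.native_before_right != partner
    )


def _overlaps(start_idx: int) -> tuple[int, int]:
    """(left, right) junction overlap of a 20-mer starting at joined index
    ``start_idx`` (junction between indices 29 and 30)."""
    left = max(0, min(GUIDE_LENGTH, FLANK - start_idx))
    return left, GUIDE_LENGTH - left


def detect_junction_pam(window: JunctionWindow) -> list[BreakpointPamCandidate]:
    """Junction-created PAMs: GG or CC exactly at the (−1, +1) dinucleotide.

    Only novel candidates are emitted; windows with N at −1/+1 or in the
    guide yield no call.
    """
    b_minus1, b_plus1 = window.base(-1), window.base(1)
    joined = window.joined
    out: list[BreakpointPamCandidate] = []
    if b_minus1 == "G" and b_plus1 == "G":
        # N of the PAM at −2; guide entirely in the left flank (−22…−3)
        grna = joined[junction_pos_to_index(-22) : junction_pos_to_index(-3) + 1]
        if "N" not in grna and is_junction_pam_novel(window, "NGG"):
            out.append(
                BreakpointPamCandidate(
                    window.breakpoint, "junction_pam", "NGG", grna,
                    left_overlap=GUIDE_LENGTH, right_overlap=0, pam_position=-2,
                )
            )
    if b_minus1 == "C" and b_plus1 == "C":
        grna = reverse_complement(
            joined[junction_pos_to_index(3) : junction_pos_to_index(22) + 1]
        )
        if "N" not in grna and is_junction_pam_novel(window, "CCN"):
            out.append(
                BreakpointPamCandidate(
                    window.breakpoint, "junction_pam", "CCN", grna,
                    left_overlap=0, right_overlap=GUIDE_LENGTH, pam_position=2,
                )
            )
    return out


def detect_spanning_guides(
    window: JunctionWindow,
    n_pos_range: tuple[int, int] = (6, 16),
    c_pos_range: tuple[int, int] = (-18, -8),
    min_overlap: int = MIN_SIDE_OVERLAP,
) -> list[BreakpointPamCandidate]:
    """Guides spanning the junction.

    NGG motifs with the N at junction positions +6…+16 give a guide in the
    20 nt 5' of the N; CCN motifs with the first C at −18…−8 give the
    reverse complement of the 20 nt beginning 3 positions after that C.
    Only guides with at least ``min_overlap`` nt on both sides of the
    junction (and no N) are kept.
    """
    joined = window.joined
    out: list[BreakpointPamCandidate] = []
    for pos in range(n_pos_range[0], n_pos_range[1] + 1):
        i = junction_pos_to_index(pos)
        if i + 2 >= len(joined) or not (joined[i + 1] == "G" and joined[i + 2] == "G"):
            continue
        if i - GUIDE_LENGTH < 0:
            continue
        grna = joined[i - GUIDE_LENGTH : i]
        left, right = _overlaps(i - GUIDE_LENGTH)
        if "N" in grna or left < min_overlap or right < min_overlap:
            continue
        out.append(
            BreakpointPamCandidate(
                window.breakpoint, "spanning_guide", "NGG", grna,
                left_overlap=left, right_overlap=right, pam_position=pos,
            )
        )
    for pos in range(c_pos_range[0], c_pos_range[1] + 1):
        i = junction_pos_to_index(pos)
        if i + 1 >= len(joined) or not (joined[i] == "C" and joined[i + 1] == "C"):
            continue
        if i + 3 + GUIDE_LENGTH > len(joined):
            continue
        grna = reverse_complement(joined[i + 3 : i + 3 + GUIDE_LENGTH])
        left, right = _overlaps(i + 3)
        if "N" in grna or left < min_overlap or right < min_overlap:
            continue
        out.append(
            BreakpointPamCandidate(
                window.breakpoint, "spanning_guide", "CCN", grna,
                left_overlap=left, right_overlap=right, pam_position=pos,
            )
        )
    return out


@dataclass
class BreakpointCohortResult:
    """All junction candidates plus per-sample / per-class summaries."""

    candidates: list[BreakpointPamCandidate] = field(default_factory=list)
    table: pd.DataFrame | None = None
    per_sample: pd.DataFrame | None = None


def analyze_cohort_breakpoints(
    breakpoints: Iterable[Breakpoint],
    genome: ReferenceGenome,
) -> BreakpointCohortResult:
    """Run junction-PAM and spanning-guide detection over a breakpoint list.

    Candidates are deduplicated per breakpoint on (kind, motif, guide);
    counts are summarised per sample and per source class, with cohort
    medians available from the per-sample table.
    """
    all_cands: list[BreakpointPamCandidate] = []
    for bkp in breakpoints:
        window = build_junction_window(bkp, genome)
        # junction-created PAMs first so spanning guides dedup against them
        seen: set[tuple] = set()
        for cand in detect_junction_pam(window) + detect_spanning_guides(window):
            key = (cand.motif, cand.grna)
            if key not in seen:
                seen.add(key)
                all_cands.append(cand)
    rows = [
        {
            "sample": c.breakpoint.sample_id,
            "svclass": c.breakpoint.svclass,
            "kind": c.kind,
            "motif": c.motif,
            "contig1": c.breakpoint.contig1,
            "pos1": c.breakpoint.pos1,
            "contig2": c.breakpoint.contig2,
            "pos2": c.breakpoint.pos2,
            "pam_position": c.pam_position,
            "grna": c.grna,
            "left_overlap": c.left_overlap,
            "right_overlap": c.right_overlap,
            "is_novel": c.is_novel,
        }
        for c in all_cands
    ]
    table = pd.DataFrame(
        rows,
        columns=["sample", "svclass", "kind", "motif", "contig1", "pos1",
                 "contig2", "pos2", "pam_position", "grna", "left_overlap",
                 "right_overlap", "is_novel"],
    )
    if len(table):
        per_sample = (
            table.groupby(["sample", "svclass", "kind"])
            .size()
            .rename("n_candidates")
            .reset_index()
        )
    else:
        per_sample = pd.DataFrame(
            columns=["sample", "svclass", "kind", "n_candidates"]
        )
    return BreakpointCohortResult(all_cands, table, per_sample)
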