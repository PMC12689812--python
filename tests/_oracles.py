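"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the package's scanning/ranking code paths: the PAM
oracle diffs dinucleotide occurrences between the reference and mutated
windows with plain string scans, the off-target oracle is a position-by-
position loop, the ranking oracle recomputes average ranks by counting, and
the junction oracle rescans the joined 60-mer with explicit positional
filters.
"""

from __future__ import annotations

COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(COMP)[::-1]


def snv_pam_oracle(genome, variant, flank: int = 25) -> set[tuple[int, str]]:
    """Novel GG/CC dinucleotide positions created by an SNV.

    Scans the ±flank window of the reference and of the mutated haplotype
    and returns {(plus-strand dinucleotide start, strand)} for dinucleotides
    present in the mutated window but absent at the same position in the
    reference.
    """
    contig, p = variant.contig, variant.pos - 1
    length = genome.length(contig)
    lo, hi = max(0, p - flank), min(length, p + flank + 1)
    ref = genome.fetch(contig, lo, hi)
    alt = ref[: p - lo] + variant.alt_allele + ref[p - lo + 1 :]
    out: set[tuple[int, str]] = set()
    for i in range(len(alt) - 1):
        if alt[i : i + 2] == "GG" and ref[i : i + 2] != "GG":
            out.add((lo + i, "+"))
        if alt[i : i + 2] == "CC" and ref[i : i + 2] != "CC":
            out.add((lo + i, "-"))
    return out


def offtarget_oracle(
    protospacer: str,
    genome,
    max_mismatches: int = 4,
    pam_patterns: tuple[str, ...] = ("NGG", "NAG"),
) -> set[tuple[str, int, str, int]]:
    """All {(contig, plus-strand spacer start, strand, mismatches)} sites.

    Naive per-position loop over both strands with explicit PAM pattern
    matching and Hamming counting.
    """

    def pam_ok(pam: str) -> bool:
        return any(
            all(pc == "N" or pc == sc for pc, sc in zip(pat, pam))
            for pat in pam_patterns
        )

    k = len(protospacer)
    hits: set[tuple[str, int, str, int]] = set()
    for contig in genome.contigs:
        plus = genome.sequence(contig)
        minus = revcomp(plus)
        n = len(plus)
        for strand, seq in (("+", plus), ("-", minus)):
            for j in range(n - k - 3 + 1):
                if not pam_ok(seq[j + k : j + k + 3]):
                    continue
                mm = sum(a != b for a, b in zip(seq[j : j + k], protospacer))
                if mm <= max_mismatches:
                    start = j if strand == "+" else n - (j + k)
                    hits.add((contig, start, strand, mm))
    return hits


def rank_oracle(values: list[float | None]) -> list[float]:
    """Average ranks, 1 = worst, missing values all share rank 1."""
    n_missing = sum(v is None for v in values)
    ranks = []
    for v in values:
        if v is None:
            ranks.append(1.0)
            continue
        present = [w for w in values if w is not None]
        less = sum(w < v for w in present)
        eq = sum(w == v for w in present)
        ranks.append(n_missing + less + (eq + 1) / 2.0)
    return ranks


def composite_oracle(features: dict[str, list[float | None]],
                     weights=None) -> list[float]:
    """Weighted rank-sum per candidate from per-feature value lists."""
    w = weights or {"cfd_spec": 2.0, "mit_spec": 1.0, "doench": 0.5,
                    "moreno": 0.5, "dependency": 1.0, "expression": 1.0,
                    "copy_number": 1.0}
    n = len(next(iter(features.values())))
    ranks = {f: rank_oracle(vals) for f, vals in features.items()}
    return [
        sum(w[f] * ranks[f][i] for f in features) for i in range(n)
    ]


def normalize_oracle(raw: list[float]) -> list[float]:
    lo, hi = min(raw), max(raw)
    if hi == lo:
        return [100.0] * len(raw)
    return [(r - lo) / (hi - lo) * 100.0 for r in raw]


def final_rank_oracle(norm: list[float]) -> list[int]:
    return [1 + sum(other > s for other in norm) for s in norm]


def junction_oracle(joined: str) -> dict[str, list]:
    """Junction-created and spanning motifs in a 60-mer (junction between
    string indices 29 and 30), with independently computed overlaps."""

    def pos_of(idx: int) -> int:
        return idx - 30 if idx < 30 else idx - 29

    created = []
    if joined[29] == "G" and joined[30] == "G":
        created.append(("NGG", joined[8:28]))
    if joined[29] == "C" and joined[30] == "C":
        created.append(("CCN", revcomp(joined[32:52])))
    spanning = []
    for i in range(len(joined) - 2):
        if joined[i + 1 : i + 3] == "GG" and 6 <= pos_of(i) <= 16:
            if i - 20 < 0:
                continue
            grna = joined[i - 20 : i]
            left = sum(1 for k in range(i - 20, i) if k < 30)
            if left >= 4 and 20 - left >= 4 and "N" not in grna:
                spanning.append(("NGG", grna, left, 20 - left, pos_of(i)))
        if joined[i : i + 2] == "CC" and -18 <= pos_of(i) <= -8:
            if i + 23 > len(joined):
                continue
            grna = revcomp(joined[i + 3 : i + 23])
            left = sum(1 for k in range(i + 3, i + 23) if k < 30)
            if left >= 4 and 20 - left >= 4 and "N" not in grna:
                spanning.append(("CCN", grna, left, 20 - left, pos_of(i)))
    return {"created": created, "spanning": spanning}
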