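"""Microsatellite/homopolymer catalog and triplet sequence-complexity stats.

Repeat criteria follow the IMEX-style thresholds used throughout the
pipeline: homopolymeric runs of >=6 bp, di-/tri-nucleotide motifs with >=4
whole repetitions, and tetra- through hexa-nucleotide motifs with >=3 whole
repetitions. Only perfect runs qualify; an interruption splits a candidate
region into sub-runs that are evaluated independently. A motif must be
aperiodic (minimal period equal to its length) so that poly-A is catalogued
as a homopolymer rather than as (AA)n.

Sequence complexity of a window of length n with overlapping-triplet counts
c_t (l = n - 2 triplets in total) is

    S = sum_t c_t (c_t - 1) / (2 (l - 1))

so S = 0 exactly when all triplets are distinct and S is maximal for
homopolymers. Because larger S means *more* repetitive sequence, reports
also expose the normalized complement 1 - sum c_t(c_t-1) / (l(l-1)), which
is high for complex sequence and low for repeats; the raw S is always kept.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

#: minimum whole-unit copy numbers per motif length
MIN_COPIES = {1: 6, 2: 4, 3: 4, 4: 3, 5: 3, 6: 3}

_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def minimal_period(motif: str) -> int:
    for p in range(1, len(motif)):
        if len(motif) % p == 0 and motif == motif[:p] * (len(motif) // p):
            return p
    return len(motif)


def canonical_motif(motif: str) -> str:
    """Lexicographically smallest rotation (strand is not collapsed)."""
    return min(motif[i:] + motif[:i] for i in range(len(motif)))


def base_class(motif: str) -> str:
    bases = set(motif)
    if bases <= {"A", "T"}:
        return "AT"
    if bases <= {"G", "C"}:
        return "GC"
    return "mixed"


#: reported jointly with their reverse-complement family, e.g. AG and CT runs
DINUC_FAMILIES = {
    "AT": "AT/TA", "TA": "AT/TA",
    "AC": "AC/GT", "CA": "AC/GT", "GT": "AC/GT", "TG": "AC/GT",
    "AG": "AG/CT", "GA": "AG/CT", "CT": "AG/CT", "TC": "AG/CT",
    "CG": "CG/GC", "GC": "CG/GC",
}


@dataclass(frozen=True)
class RepeatInterval:
    """A perfect tandem repeat run (0-based half-open, whole units only)."""

    chrom: str
    start: int
    end: int
    motif: str
    unit_length: int
    copy_number: int

    def __post_init__(self):
        if self.end - self.start != self.unit_length * self.copy_number:
            raise ValueError("run length must equal unit_length * copy_number")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def base_class(self) -> str:
        return base_class(self.motif)

    @property
    def is_homopolymer(self) -> bool:
        return self.unit_length == 1

    @property
    def family(self) -> str | None:
        if self.unit_length == 2:
            return DINUC_FAMILIES[self.motif]
        return None


def detect_repeats(sequence: str, chrom: str = "") -> list[RepeatInterval]:
    """Catalog all maximal qualifying perfect repeat runs in ``sequence``.

    For each period p the maximal per-character-periodic regions are found,
    truncated to whole units from the left; runs whose motif is itself
    periodic with a smaller period are left to that smaller period. N (or
    any non-ACGT letter) interrupts a run.
    """
    seq = sequence.upper()
    n = len(seq)
    arr = np.frombuffer(seq.encode("ascii"), dtype="S1")
    valid = (arr == b"A") | (arr == b"C") | (arr == b"G") | (arr == b"T")
    out: list[RepeatInterval] = []
    for p, min_cp in MIN_COPIES.items():
        if n < p * min_cp:
            continue
        eq = (arr[p:] == arr[:-p]) & valid[p:] & valid[:-p]
        if not eq.any():
            continue
        # maximal runs of True in eq: eq[i] means seq[i] == seq[i+p]
        padded = np.concatenate(([False], eq, [False]))
        d = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(d == 1)
        ends = np.flatnonzero(d == -1)  # exclusive in eq-index space
        for a, b in zip(starts, ends):
            region_len = (b - a) + p  # seq[a : b + p] is p-periodic
            copies = region_len // p
            if copies < min_cp:
                continue
            motif = seq[a : a + p]
            if minimal_period(motif) != p:
                continue
            out.append(
                RepeatInterval(chrom, int(a), int(a) + p * copies, motif, p, copies)
            )
    out.sort(key=lambda r: (r.start, r.unit_length))
    return out


def split_imperfect(region: str, chrom: str = "", offset: int = 0) -> list[RepeatInterval]:
    """Evaluate an interrupted candidate region: each maximal perfect sub-run
    is tested independently against the copy-number thresholds."""
    runs = detect_repeats(region, chrom)
    if offset:
        runs = [
            RepeatInterval(r.chrom, r.start + offset, r.end + offset, r.motif,
                           r.unit_length, r.copy_number)
            for r in runs
        ]
    return runs


@dataclass(frozen=True)
class RepeatHit:
    status: str  # "in_repeat" or "adjacent"
    run: RepeatInterval


class RepeatCatalog:
    """Indexed genome-wide repeat catalog supporting variant association."""

    def __init__(self, runs: list[RepeatInterval]):
        from intervaltree import IntervalTree

        self.runs = list(runs)
        self._trees: dict[str, IntervalTree] = {}
        for r in self.runs:
            self._trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end, r)

    @classmethod
    def from_genome(cls, genome) -> "RepeatCatalog":
        runs: list[RepeatInterval] = []
        for name in genome.names:
            runs.extend(detect_repeats(genome.seqs[name], name))
        return cls(runs)

    def __len__(self) -> int:
        return len(self.runs)

    def query(self, chrom: str, pos: int, flank: int = 1) -> RepeatHit | None:
        """Associate a (0-based) site with the catalog.

        ``in_repeat`` if the site lies inside a run; ``adjacent`` if within
        ``flank`` bp of a run boundary; longest overlapping run wins ties.
        """
        tree = self._trees.get(chrom)
        if tree is None:
            return None
        inside = tree[pos]
        if inside:
            run = max(inside, key=lambda iv: iv.end - iv.begin).data
            return RepeatHit("in_repeat", run)
        near = tree[max(0, pos - flank) : pos + flank + 1]
        if near:
            run = max(near, key=lambda iv: iv.end - iv.begin).data
            return RepeatHit("adjacent", run)
        return None

    def homopolymer_census(self) -> dict[tuple[str, int], int]:
        """Run counts keyed by (base class A/T|G/C, run length in bp)."""
        census: dict[tuple[str, int], int] = {}
        for r in self.runs:
            if r.is_homopolymer:
                key = (r.base_class, r.length)
                census[key] = census.get(key, 0) + 1
        return census

    def dinucleotide_census(self) -> dict[str, int]:
        census: dict[str, int] = {}
        for r in self.runs:
            if r.unit_length == 2:
                census[r.family] = census.get(r.family, 0) + 1
        return census


@dataclass(frozen=True)
class ComplexityResult:
    S: float
    triplet_counts: dict
    l: int
    n: int
    flagged: bool = False
    truncated: bool = False

    @property
    def complement(self) -> float:
        """1 - sum c(c-1)/(l(l-1)): ~1 for complex sequence, ~0 for repeats."""
        if self.l < 2:
            return float("nan")
        ssum = sum(c * (c - 1) for c in self.triplet_counts.values())
        return 1.0 - ssum / (self.l * (self.l - 1))


def sequence_complexity(window: str) -> ComplexityResult:
    """Triplet repetitiveness statistic S of a window (see module docstring)."""
    window = window.upper()
    n = len(window)
    if n < 3:
        raise ValueError("window must be at least 3 bp")
    l = n - 2
    if any(b not in "ACGT" for b in window):
        return ComplexityResult(float("nan"), {}, l, n, flagged=True)
    counts = Counter(window[i : i + 3] for i in range(l))
    if l == 1:
        s = 0.0
    else:
        s = sum(c * (c - 1) for c in counts.values()) / (2 * (l - 1))
    return ComplexityResult(s, dict(counts), l, n)


def gc_fraction(window: str) -> float:
    window = window.upper()
    acgt = sum(window.count(b) for b in "ACGT")
    if acgt == 0:
        return float("nan")
    return (window.count("G") + window.count("C")) / acgt


def window_stats(genome, chrom: str, pos: int, width: int = 41):
    """(S, GC) of the ``width`` bp window centered on a callable site.

    Windows are truncated at contig edges; below 21 bp the result is
    flagged unavailable. Windows containing N are flagged for S.
    """
    half = width // 2
    seq = genome.seqs[chrom]
    lo, hi = max(0, pos - half), min(len(seq), pos + half + 1)
    window = seq[lo:hi]
    truncated = len(window) < width
    if len(window) < 21:
        res = ComplexityResult(float("nan"), {}, max(len(window) - 2, 0),
                               len(window), flagged=True, truncated=True)
        return res, float("nan")
    res = sequence_complexity(window)
    if truncated:
        res = ComplexityResult(res.S, res.triplet_counts, res.l, res.n,
                               res.flagged, True)
    return res, gc_fraction(window)


_BASE_CODE = np.full(128, -1, dtype=np.int16)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i


def window_stats_batch(genome, chrom: str, positions: np.ndarray, width: int = 41):
    """Vectorized (S, GC) for many same-chromosome sites (interior sites only
    get exact full windows; edge windows are truncated like window_stats)."""
    seq = genome.seqs[chrom]
    codes = _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    n = len(seq)
    half = width // 2
    valid = codes >= 0
    gc_cum = np.concatenate(([0], np.cumsum((codes == 1) | (codes == 2))))
    acgt_cum = np.concatenate(([0], np.cumsum(valid)))
    # triplet codes at each start position
    trip = codes[:-2] * 16 + codes[1:-1] * 4 + codes[2:]
    trip_ok = valid[:-2] & valid[1:-1] & valid[2:]

    S = np.empty(len(positions))
    gc = np.empty(len(positions))
    for i, pos in enumerate(positions):
        lo, hi = max(0, int(pos) - half), min(n, int(pos) + half + 1)
        denom = acgt_cum[hi] - acgt_cum[lo]
        gc[i] = (gc_cum[hi] - gc_cum[lo]) / denom if denom else np.nan
        l = hi - lo - 2
        if hi - lo < 21 or not trip_ok[lo : lo + l].all():
            S[i] = np.nan
            continue
        counts = np.bincount(trip[lo : lo + l])
        S[i] = (counts * (counts - 1)).sum() / (2 * (l - 1)) if l > 1 else 0.0
    return S, gc
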