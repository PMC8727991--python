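"""Synthetic MA experiments with known ground truth.

The generator emulates the design of a mutation-accumulation experiment in
an obligately outcrossing, mismatch-repair-impaired C. elegans background:
a multi-chromosome nuclear genome (autosomes plus X) with arm/core/tip
recombination domains, planted homopolymers and microsatellites on an
AT-rich background, gene models with exons and introns, per-generation
mutation sampling from class-specific rates, indel hotspots whose
per-run rate depends on homopolymer length (peaking at 11 bp for A/T runs
and 8 bp for G/C runs), a deletion bias, A/T->T/A transversions
concentrated at homopolymer boundaries, read-support counts from a
Poisson-depth / per-read-error sequencing model, and an unmutated
ancestral control.

Mutations are planted as fixed (homozygous) per line, matching the
post-MA inbreeding step of the emulated design; at most one hit per site
per line is assumed, which is accurate at realistic rates. A single global
seed drives hierarchical per-line and per-stage streams, so any subset of
the simulation is reproducible on its own.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .formats import CALL_COLUMNS
from .genome import (
    GenomicInterval,
    GeneModel,
    ReferenceGenome,
    AnnotationLayers,
    layers_from_components,
    mask_from_sequence,
)
from .repeats import RepeatCatalog
from .study_tables import SUBSTITUTION_CLASSES, TRANSITION_CLASSES, StudyTables

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

def _default_at_runs():
    # planted A/T homopolymer runs per Mb by length (AT-rich genome)
    return {6: 350, 7: 260, 8: 190, 9: 140, 10: 100, 11: 75, 12: 55,
            13: 40, 14: 28, 15: 20, 16: 14}


def _default_gc_runs():
    return {6: 100, 7: 70, 8: 50, 9: 34, 10: 22, 11: 14, 12: 9,
            13: 6, 14: 4, 15: 3, 16: 2}


def _default_dinuc_runs():
    # runs per Mb per motif family, 4-8 whole units each
    return {"AT/TA": 120, "AC/GT": 100, "AG/CT": 100, "CG/GC": 30}


@dataclass(frozen=True)
class GenomeSpec:
    """Layout of a synthetic nuclear genome (lengths in bp)."""

    chromosomes: tuple = (("I", 400_000), ("II", 350_000), ("X", 250_000))
    gc: float = 0.36
    x_names: tuple = ("X",)
    mito_length: int = 0  # >0 adds an MtDNA chromosome
    place_genes: bool = True
    germline_fraction: float = 0.5
    at_runs_per_mb: dict = field(default_factory=_default_at_runs)
    gc_runs_per_mb: dict = field(default_factory=_default_gc_runs)
    dinuc_runs_per_mb: dict = field(default_factory=_default_dinuc_runs)
    tri_runs_per_mb: int = 30
    tetra_runs_per_mb: int = 10
    #: explicit (chrom, start, motif, copies) plantings
    explicit_repeats: tuple = ()
    tip_fraction: float = 0.0875   # total share in the two chromosome tips
    arm_fraction: float = 0.325    # total share in the two arms
    chromatin_states: int = 5
    chromatin_block: int = 10_000
    at_cluster_per_mb: int = 25
    at_cluster_length: int = 200

    def __post_init__(self):
        if not self.chromosomes:
            raise ValueError("need at least one chromosome")
        if not (0 < self.gc < 1):
            raise ValueError("gc must be in (0, 1)")


@dataclass(frozen=True)
class SpectrumConfig:
    """Class-specific mutation rates and indel dynamics.

    Substitution rates are per callable nuclear site per generation on the
    whole-genome denominator: the expected count of class c in a line is
    rate_c * G * B_total, with sites drawn among bases able to produce the
    class. Indels are drawn at the total ``indel_rate`` and allocated to
    homopolymer runs (weighted by the length-multiplier tables),
    dinucleotide runs, and background sites.
    """

    substitution_rates: dict  # class -> per-site per-generation rate
    indel_rate: float = 2.23e-7
    deletion_bias: float = 1.94  # deletion : insertion odds
    indel_size_probs: tuple = ()  # P(size = 1..100); default built below
    at_multipliers: dict = field(default_factory=lambda: {
        6: 1.0, 7: 2.0, 8: 4.5, 9: 9.0, 10: 15.0, 11: 20.0, 12: 15.0,
        13: 9.0, 14: 5.0, 15: 2.5, 16: 1.5})
    gc_multipliers: dict = field(default_factory=lambda: {
        6: 2.0, 7: 6.0, 8: 10.0, 9: 7.0, 10: 4.0, 11: 2.5, 12: 1.5,
        13: 1.0, 14: 0.8, 15: 0.6, 16: 0.5})
    homopolymer_fraction: float = 0.80
    dinucleotide_fraction: float = 0.04
    #: probability that a dinucleotide-run event is a deletion, per family
    dinuc_deletion_fraction: dict = field(default_factory=lambda: {
        "AT/TA": 1 / 3, "AC/GT": 0.55, "AG/CT": 0.55, "CG/GC": 1.0})
    #: share of A/T->T/A substitutions planted at A/T homopolymer boundaries
    at_ta_boundary_fraction: float = 0.8
    #: X-chromosome rate factors (substitutions lower, indels higher)
    x_substitution_factor: float = 0.86
    x_indel_factor: float = 1.15

    def __post_init__(self):
        if any(r < 0 for r in self.substitution_rates.values()) or self.indel_rate < 0:
            raise ValueError("rates must be non-negative")
        if not self.indel_size_probs:
            p = np.zeros(100)
            p[0] = 0.96
            tail = 0.55 ** np.arange(99)
            p[1:] = 0.04 * tail / tail.sum()
            object.__setattr__(self, "indel_size_probs", tuple(p))
        probs = np.asarray(self.indel_size_probs)
        if abs(probs.sum() - 1) > 1e-9 or (probs < 0).any():
            raise ValueError("indel size distribution must sum to 1")

    @property
    def snp_rate(self) -> float:
        return float(sum(self.substitution_rates.values()))

    @property
    def deletion_fraction(self) -> float:
        return self.deletion_bias / (1 + self.deletion_bias)

    def expected_deletion_fraction(self, dinuc_family_weights=None) -> float:
        """Expected overall deletion share given the event allocation."""
        base = (1 - self.dinucleotide_fraction) * self.deletion_fraction
        if self.dinucleotide_fraction == 0:
            return base
        if dinuc_family_weights is None:
            fam = float(np.mean(list(self.dinuc_deletion_fraction.values())))
        else:
            w = pd.Series(dinuc_family_weights, dtype=float)
            w = w / w.sum()
            fam = float(sum(w.get(k, 0) * v
                            for k, v in self.dinuc_deletion_fraction.items()))
        return base + self.dinucleotide_fraction * fam

    def scaled(self, factor: float) -> "SpectrumConfig":
        """All rates multiplied by ``factor`` (for scaled-up simulations)."""
        return replace(
            self,
            substitution_rates={k: v * factor
                                for k, v in self.substitution_rates.items()},
            indel_rate=self.indel_rate * factor,
        )


def default_spectrum(
    snp_rate: float = 0.42e-7,
    tstv: float = 1.15,
    indel_rate: float = 2.23e-7,
    deletion_bias: float = 1.94,
) -> SpectrumConfig:
    """Study-condition spectrum: class shares follow the observed knockdown
    spectrum, rescaled so the planted Ts/Tv matches the per-line mean."""
    counts = StudyTables().table2["total"]
    shares = counts / counts.sum()
    ts_share = sum(shares[c] for c in TRANSITION_CLASSES)
    target_ts = tstv / (1 + tstv)
    adj = {}
    for cls in SUBSTITUTION_CLASSES:
        f = target_ts / ts_share if cls in TRANSITION_CLASSES else \
            (1 - target_ts) / (1 - ts_share)
        adj[cls] = snp_rate * shares[cls] * f
    return SpectrumConfig(substitution_rates=adj, indel_rate=indel_rate,
                          deletion_bias=deletion_bias)


@dataclass(frozen=True)
class ExperimentConfig:
    """MA design: lines, generations per line, and the coverage model."""

    n_lines: int = 20
    generations: int | tuple = 40  # scalar, or one value per line
    depth: float = 30.0
    ancestor_depth: float = 30.0
    error_rate: float = 0.01
    n_noise_sites: int = 10_000
    seed: int = 0

    def __post_init__(self):
        gens = (self.generations,) if np.isscalar(self.generations) \
            else tuple(self.generations)
        if not np.isscalar(self.generations) and len(gens) != self.n_lines:
            raise ValueError("need one generation count per line")
        if self.n_lines < 1 or min(gens) < 1:
            raise ValueError("need n_lines >= 1 and generations >= 1")
        if not (0 <= self.error_rate < 0.5):
            raise ValueError("error rate must lie in [0, 0.5)")

    @property
    def line_ids(self) -> list[str]:
        return [f"L{i:02d}" for i in range(1, self.n_lines + 1)]

    @property
    def line_generations(self) -> dict[str, float]:
        if np.isscalar(self.generations):
            return {lid: float(self.generations) for lid in self.line_ids}
        return {lid: float(g) for lid, g in zip(self.line_ids, self.generations)}


# ---------------------------------------------------------------------------
# Genome construction
# ---------------------------------------------------------------------------

def _random_sequence(rng, length: int, gc: float) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=length, p=probs)


def _make_genes(rng, chrom: str, length: int, germline_fraction: float,
                counter: list) -> list[GeneModel]:
    genes = []
    pos = int(rng.integers(200, 1500))
    while True:
        n_exons = int(rng.integers(3, 6))
        exon_lens = 3 * rng.integers(40, 90, size=n_exons)
        intron_lens = rng.integers(120, 400, size=n_exons - 1)
        span = int(exon_lens.sum() + intron_lens.sum())
        if pos + span + 200 >= length:
            break
        exons = []
        cur = pos
        for i in range(n_exons):
            exons.append((cur, cur + int(exon_lens[i])))
            cur += int(exon_lens[i])
            if i < n_exons - 1:
                cur += int(intron_lens[i])
        counter[0] += 1
        genes.append(GeneModel(
            gene_id=f"gene{counter[0]:05d}", chrom=chrom,
            strand="+" if rng.random() < 0.5 else "-", exons=tuple(exons),
            germline_expressed=bool(rng.random() < germline_fraction),
        ))
        pos = cur + int(rng.integers(400, 2700))
    return genes


def _plant_run(seq: np.ndarray, occupied: np.ndarray, start: int,
               motif: str, copies: int) -> None:
    """Write a perfect run and break periodic extension at both flanks."""
    p = len(motif)
    unit = np.frombuffer(motif.encode(), dtype="S1")
    end = start + p * copies
    seq[start:end] = np.tile(unit, copies)
    # flanks must differ from the base one period inward
    for flank, inner in ((start - 1, start - 1 + p), (end, end - p)):
        if 0 <= flank < len(seq):
            bad = seq[inner]
            choices = [b for b in b"ACGT" if bytes([b]) != bad]
            seq[flank] = bytes([choices[flank % 3]])
    occupied[max(0, start - 2): min(len(seq), end + 2)] = True


def _sample_plant_site(rng, free: np.ndarray, span: int, tries: int = 200):
    n = len(free)
    for _ in range(tries):
        start = int(rng.integers(2, n - span - 2))
        if free[start - 2 : start + span + 2].all():
            return start
    return None


@dataclass
class SyntheticReference:
    genome: ReferenceGenome
    layers: AnnotationLayers
    catalog: RepeatCatalog
    planted: list
    domain_intervals: list
    chromatin_intervals: list
    at_cluster_intervals: list

    def write(self, out_dir) -> dict:
        """Emit FASTA / GFF3 / BED / expression-TSV files for round-trips."""
        from pathlib import Path

        from . import formats

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": out / "genome.fa",
            "gff": out / "genes.gff3",
            "domains": out / "domains.bed",
            "chromatin": out / "chromatin.bed",
            "at_clusters": out / "at_clusters.bed",
            "expression": out / "expression.tsv",
            "repeats": out / "repeats.bed",
        }
        formats.write_fasta(self.genome.seqs, paths["fasta"])
        formats.write_gff3(self.layers.genes, paths["gff"])
        formats.write_bed(self.domain_intervals, paths["domains"])
        formats.write_bed(self.chromatin_intervals, paths["chromatin"])
        formats.write_bed(self.at_cluster_intervals, paths["at_clusters"])
        formats.write_expression_table(self.layers.genes, paths["expression"])
        formats.write_bed(
            [GenomicInterval(r.chrom, r.start, r.end, f"{r.motif}x{r.copy_number}")
             for r in self.catalog.runs],
            paths["repeats"],
        )
        return paths


def build_reference(spec: GenomeSpec = GenomeSpec(), seed: int = 0,
                    out_dir=None) -> SyntheticReference:
    """Deterministically build a genome + annotation layers from a spec."""
    rng = np.random.default_rng([seed, 101])
    seqs: dict[str, str] = {}
    names: list[str] = []
    genes: list[GeneModel] = []
    planted = []
    domain_ivs: list[GenomicInterval] = []
    chromatin_ivs: list[GenomicInterval] = []
    cluster_ivs: list[GenomicInterval] = []
    counter = [0]
    states = [f"state{i}" for i in range(1, spec.chromatin_states + 1)]

    explicit = {}
    for chrom, start, motif, copies in spec.explicit_repeats:
        explicit.setdefault(chrom, []).append((start, motif, copies))

    for chrom, length in spec.chromosomes:
        names.append(chrom)
        seq = _random_sequence(rng, length, spec.gc)
        occupied = np.zeros(length, dtype=bool)

        chrom_genes = (
            _make_genes(rng, chrom, length, spec.germline_fraction, counter)
            if spec.place_genes else []
        )
        for g in chrom_genes:
            for s, e in g.exons:
                occupied[s:e] = True
        genes.extend(chrom_genes)

        # explicit plantings first (validated against gene frames)
        for start, motif, copies in explicit.get(chrom, []):
            span = len(motif) * copies
            for g in chrom_genes:
                for s, e in g.exons:
                    if start < e and start + span > s and span % 3 != 0:
                        raise ValueError(
                            f"explicit repeat at {chrom}:{start} breaks the "
                            f"reading frame of {g.gene_id}"
                        )
            _plant_run(seq, occupied, start, motif, copies)
            planted.append((chrom, start, motif, copies))

        mb = length / 1e6
        jobs = []
        for base, table in (("A", spec.at_runs_per_mb), ("G", spec.gc_runs_per_mb)):
            for run_len, per_mb in table.items():
                for _ in range(int(round(per_mb * mb))):
                    motif = base if rng.random() < 0.5 else {"A": "T", "G": "C"}[base]
                    jobs.append((motif, run_len))
        for family, per_mb in spec.dinuc_runs_per_mb.items():
            motifs = family.split("/")
            for _ in range(int(round(per_mb * mb))):
                motif = motifs[int(rng.integers(len(motifs)))]
                jobs.append((motif, int(rng.integers(4, 9))))
        for per_mb, unit_len, min_cp, max_cp in (
            (spec.tri_runs_per_mb, 3, 4, 7), (spec.tetra_runs_per_mb, 4, 3, 5),
        ):
            for _ in range(int(round(per_mb * mb))):
                while True:
                    motif = "".join(rng.choice(list("ACGT"), size=unit_len))
                    from .repeats import minimal_period
                    if minimal_period(motif) == unit_len:
                        break
                jobs.append((motif, int(rng.integers(min_cp, max_cp + 1))))
        rng.shuffle(jobs)
        for motif, copies in jobs:
            span = len(motif) * copies
            start = _sample_plant_site(rng, ~occupied, span)
            if start is None:
                continue
            _plant_run(seq, occupied, start, motif, copies)
            planted.append((chrom, start, motif, copies))

        seqs[chrom] = seq.tobytes().decode("ascii")

        # recombination domains: tip / arm / core / arm / tip
        t = int(length * spec.tip_fraction / 2)
        a = int(length * spec.arm_fraction / 2)
        bounds = [0, t, t + a, length - t - a, length - t, length]
        labels = ["tip", "arm", "core", "arm", "tip"]
        for (s, e), lab in zip(zip(bounds[:-1], bounds[1:]), labels):
            if e > s:
                domain_ivs.append(GenomicInterval(chrom, s, e, lab))
        for s in range(0, length, spec.chromatin_block):
            chromatin_ivs.append(GenomicInterval(
                chrom, s, min(length, s + spec.chromatin_block),
                states[int(rng.integers(len(states)))]))
        for _ in range(int(round(spec.at_cluster_per_mb * mb))):
            s = int(rng.integers(0, max(1, length - spec.at_cluster_length)))
            cluster_ivs.append(GenomicInterval(
                chrom, s, s + spec.at_cluster_length, "at_cluster"))

    mito_names = ()
    if spec.mito_length > 0:
        names.append("MtDNA")
        seqs["MtDNA"] = _random_sequence(
            rng, spec.mito_length, 0.24).tobytes().decode("ascii")
        mito_names = ("MtDNA",)

    genome = ReferenceGenome(
        names=names, seqs=seqs,
        callable_mask={n: mask_from_sequence(s) for n, s in seqs.items()},
        x_names=frozenset(spec.x_names), mito_names=frozenset(mito_names),
    )
    layers = layers_from_components(genome, genes, domain_ivs, chromatin_ivs,
                                    cluster_ivs)
    catalog = RepeatCatalog.from_genome(genome)
    ref = SyntheticReference(genome, layers, catalog, planted, domain_ivs,
                             chromatin_ivs, cluster_ivs)
    if out_dir is not None:
        ref.write(out_dir)
    return ref


# ---------------------------------------------------------------------------
# Mutation sampling
# ---------------------------------------------------------------------------

def _site_pools(genome: ReferenceGenome, spectrum: SpectrumConfig):
    """Callable A/T and G/C site pools per nuclear chromosome, with
    chromosome sampling weights incorporating the X factors."""
    pools = {"AT": {}, "GC": {}}
    for chrom in genome.nuclear_names:
        arr = np.frombuffer(genome.seqs[chrom].encode(), dtype="S1")
        m = genome.callable_mask[chrom]
        pools["AT"][chrom] = np.flatnonzero(m & ((arr == b"A") | (arr == b"T")))
        pools["GC"][chrom] = np.flatnonzero(m & ((arr == b"G") | (arr == b"C")))
    return pools


def _chrom_weights(genome, pools, base_class, factor_x):
    chroms = genome.nuclear_names
    w = np.array([
        len(pools[base_class][c]) * (factor_x if not genome.is_autosome(c) else 1.0)
        for c in chroms], dtype=float)
    return chroms, w / w.sum()


_ALT_OF = {
    "A/T->G/C": {"A": "G", "T": "C"},
    "A/T->T/A": {"A": "T", "T": "A"},
    "A/T->C/G": {"A": "C", "T": "G"},
    "G/C->A/T": {"G": "A", "C": "T"},
    "G/C->T/A": {"G": "T", "C": "A"},
    "G/C->C/G": {"G": "C", "C": "G"},
}


def _clamped_multiplier(table: dict, length: int) -> float:
    lo, hi = min(table), max(table)
    return float(table[min(max(length, lo), hi)])


def _run_event(rng, genome, run, used, is_del: bool):
    """Build one +/-1-unit indel record inside a run.

    The anchor slides to the next free unit-aligned slot so several events
    can hit the same hot run in one line without colliding; returns None
    only when the run is saturated.
    """
    p = run.unit_length
    offsets = rng.permutation(run.copy_number)
    for o in offsets:
        pos0 = run.start - 1 + p * int(o)
        if (run.chrom, pos0) in used:
            continue
        used.add((run.chrom, pos0))
        seq = genome.seqs[run.chrom]
        anchor = seq[pos0]
        unit = seq[pos0 + 1 : pos0 + 1 + p]
        if is_del:
            return pos0 + 1, anchor + unit, anchor
        return pos0 + 1, anchor, anchor + unit
    return None


def simulate_ma_lines(
    reference: SyntheticReference,
    spectrum: SpectrumConfig,
    experiment: ExperimentConfig,
) -> pd.DataFrame:
    """Plant fixed mutations per line; returns the truth set (1-based pos)."""
    genome = reference.genome
    catalog = reference.catalog
    B = genome.callable_bases()
    pools = _site_pools(genome, spectrum)

    total_rate = spectrum.snp_rate + spectrum.indel_rate
    if total_rate * max(experiment.line_generations.values()) > 0.10:
        warnings.warn("per-site hit probability exceeds 10%; the one-hit-per-"
                      "site approximation is no longer accurate")

    hp_runs = [r for r in catalog.runs if r.is_homopolymer
               and not genome.is_mito(r.chrom) and r.start >= 1]
    hp_w = np.array([
        _clamped_multiplier(
            spectrum.at_multipliers if r.base_class == "AT"
            else spectrum.gc_multipliers, r.length)
        * (spectrum.x_indel_factor if not genome.is_autosome(r.chrom) else 1.0)
        for r in hp_runs], dtype=float)
    if hp_w.size:
        hp_w = hp_w / hp_w.sum()
    dn_runs = [r for r in catalog.runs if r.unit_length == 2
               and not genome.is_mito(r.chrom) and r.start >= 1]
    dn_w = np.array([
        spectrum.x_indel_factor if not genome.is_autosome(r.chrom) else 1.0
        for r in dn_runs], dtype=float)
    if dn_w.size:
        dn_w = dn_w / dn_w.sum()
    at_runs = [r for r in hp_runs if r.base_class == "AT"]
    at_run_w = np.array([r.length for r in at_runs], dtype=float)
    if at_run_w.size:
        at_run_w = at_run_w / at_run_w.sum()

    sub_chrom_w = {bc: _chrom_weights(genome, pools, bc,
                                      spectrum.x_substitution_factor)
                   for bc in ("AT", "GC")}
    ind_chrom_w = {bc: _chrom_weights(genome, pools, bc,
                                      spectrum.x_indel_factor)
                   for bc in ("AT", "GC")}

    size_probs = np.asarray(spectrum.indel_size_probs)
    rows = []
    for li, line in enumerate(experiment.line_ids):
        rng = np.random.default_rng([experiment.seed, 1, li])
        G = experiment.line_generations[line]
        used: set[tuple[str, int]] = set()

        def _claim(chrom, pos0):
            if (chrom, pos0) in used:
                return False
            used.add((chrom, pos0))
            return True

        def _random_site(base_class, weights):
            chroms, w = weights[base_class]
            for _ in range(50):
                chrom = chroms[int(rng.choice(len(chroms), p=w))]
                pos0 = int(rng.choice(pools[base_class][chrom]))
                if _claim(chrom, pos0):
                    return chrom, pos0
            raise RuntimeError("site pool exhausted")

        # --- substitutions ---
        for cls in SUBSTITUTION_CLASSES:
            rate = spectrum.substitution_rates.get(cls, 0.0)
            n = rng.poisson(rate * G * B)
            base_class = "AT" if cls.startswith("A/T") else "GC"
            n_boundary = 0
            if cls == "A/T->T/A" and at_runs:
                n_boundary = int(rng.binomial(n, spectrum.at_ta_boundary_fraction))
            for i in range(n):
                chrom = pos0 = None
                if i < n_boundary:
                    for _ in range(6):  # boundary base must itself be A/T
                        r = at_runs[int(rng.choice(len(at_runs), p=at_run_w))]
                        cand = r.start - 1 if rng.random() < 0.5 else r.end
                        if (0 <= cand < genome.length(r.chrom)
                                and genome.callable_mask[r.chrom][cand]
                                and genome.base(r.chrom, cand) in "AT"
                                and _claim(r.chrom, cand)):
                            chrom, pos0 = r.chrom, cand
                            break
                if chrom is None:
                    chrom, pos0 = _random_site(base_class, sub_chrom_w)
                ref = genome.base(chrom, pos0)
                rows.append((line, chrom, pos0 + 1, ref, _ALT_OF[cls][ref],
                             "snp", int(rng.integers(1, G + 1))))

        # --- indels ---
        n_indels = rng.poisson(spectrum.indel_rate * G * B)
        kinds = rng.choice(
            3, size=n_indels,
            p=[spectrum.homopolymer_fraction, spectrum.dinucleotide_fraction,
               1 - spectrum.homopolymer_fraction - spectrum.dinucleotide_fraction],
        )
        for kind in kinds:
            if kind == 0 and hp_runs:
                r = hp_runs[int(rng.choice(len(hp_runs), p=hp_w))]
                is_del = bool(rng.random() < spectrum.deletion_fraction)
                ev = _run_event(rng, genome, r, used, is_del)
                if ev is None:
                    continue
                pos, ref, alt = ev
            elif kind == 1 and dn_runs:
                r = dn_runs[int(rng.choice(len(dn_runs), p=dn_w))]
                is_del = bool(rng.random() < spectrum.dinuc_deletion_fraction.get(
                    r.family, 0.5))
                ev = _run_event(rng, genome, r, used, is_del)
                if ev is None:
                    continue
                pos, ref, alt = ev
            else:
                is_del = bool(rng.random() < spectrum.deletion_fraction)
                size = int(rng.choice(100, p=size_probs)) + 1
                ok = False
                for _ in range(50):
                    chrom, pos0 = _random_site(
                        "AT" if rng.random() < 0.64 else "GC", ind_chrom_w)
                    if (pos0 + size + 1 < genome.length(chrom)
                            and genome.callable_mask[chrom][pos0:pos0 + size + 1].all()):
                        ok = True
                        break
                    used.discard((chrom, pos0))
                if not ok:
                    continue
                seq = genome.seqs[chrom]
                if is_del:
                    ref, alt = seq[pos0 : pos0 + size + 1], seq[pos0]
                else:
                    ref = seq[pos0]
                    alt = ref + "".join(rng.choice(list("ACGT"), size=size))
                pos = pos0 + 1
            rows.append((line, r.chrom if kind in (0, 1) else chrom, pos, ref,
                         alt, "deletion" if is_del else "insertion",
                         int(rng.integers(1, G + 1))))

    truth = pd.DataFrame(
        rows, columns=["line", "chrom", "pos", "ref", "alt", "vtype", "generation"]
    )
    return truth.sort_values(["line", "chrom", "pos"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Read evidence
# ---------------------------------------------------------------------------

@dataclass
class SimulatedEvidence:
    calls: pd.DataFrame          # candidate per-line calls (true + noise)
    pileup: pd.DataFrame         # per candidate position x line: K, N
    ancestor_calls: pd.DataFrame
    truth_keys: pd.DataFrame     # (line, chrom, pos, alt) of planted variants
    noise_keys: pd.DataFrame     # (chrom, pos, alt) of error-only sites


def simulate_read_evidence(
    truth: pd.DataFrame,
    reference: SyntheticReference,
    experiment: ExperimentConfig,
) -> SimulatedEvidence:
    """Read support for every candidate site in every line.

    True variants are fixed in their carrier line, so supporting reads are
    K ~ Binomial(N, 1-e) of N ~ Poisson(depth); non-carrier lines see only
    scattered errors toward that allele (rate e/3 per read). Error-only
    noise sites put K ~ Binomial(N, e) in every line, emulating systematic
    sequencing/alignment noise shared across the experiment — exactly what
    the cross-line binomial verification is built to remove. The ancestral
    control is an extra library with no planted variants; it reports a
    putative call where its own support would trigger a lenient caller
    (K >= 2 and K/N >= 0.2).
    """
    genome = reference.genome
    rng = np.random.default_rng([experiment.seed, 2])
    e = experiment.error_rate
    lines = experiment.line_ids
    n_lines = len(lines)

    cand = truth[["chrom", "pos", "ref", "alt", "vtype"]].drop_duplicates(
        ["chrom", "pos", "alt"]).reset_index(drop=True)
    truth_positions = set(zip(truth["chrom"], truth["pos"]))

    noise_rows = []
    nuclear = genome.nuclear_names
    lens = np.array([genome.length(c) for c in nuclear], dtype=float)
    while len(noise_rows) < experiment.n_noise_sites:
        chrom = nuclear[int(rng.choice(len(nuclear), p=lens / lens.sum()))]
        pos0 = int(rng.integers(1, genome.length(chrom) - 1))
        if not genome.callable_mask[chrom][pos0]:
            continue
        if (chrom, pos0 + 1) in truth_positions:
            continue
        ref = genome.base(chrom, pos0)
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        noise_rows.append((chrom, pos0 + 1, ref, alt, "snp"))
        truth_positions.add((chrom, pos0 + 1))
    noise = pd.DataFrame(noise_rows, columns=["chrom", "pos", "ref", "alt", "vtype"])

    allc = pd.concat([cand.assign(is_noise=False), noise.assign(is_noise=True)],
                     ignore_index=True)
    P = len(allc)
    key_index = {k: i for i, k in
                 enumerate(zip(allc["chrom"], allc["pos"], allc["alt"]))}
    line_index = {lid: j for j, lid in enumerate(lines)}

    N = rng.poisson(experiment.depth, size=(P, n_lines))
    p_support = np.full((P, n_lines), e / 3)
    p_support[allc["is_noise"].to_numpy(), :] = e
    carrier = np.zeros((P, n_lines), dtype=bool)
    ti = np.array([key_index[(c, p, a)] for c, p, a in
                   zip(truth["chrom"], truth["pos"], truth["alt"])])
    tj = np.array([line_index[l] for l in truth["line"]])
    if len(ti):
        carrier[ti, tj] = True
        p_support[ti, tj] = 1 - e
    K = rng.binomial(N, p_support)

    pileup = pd.DataFrame({
        "chrom": np.repeat(allc["chrom"].to_numpy(), n_lines),
        "pos": np.repeat(allc["pos"].to_numpy(), n_lines),
        "alt": np.repeat(allc["alt"].to_numpy(), n_lines),
        "line": np.tile(np.array(lines, dtype=object), P),
        "K": K.ravel(),
        "N": N.ravel(),
    })

    # carrier calls
    cK, cN = K[ti, tj], N[ti, tj]
    good = (cN >= 1) & (cK >= 1)
    true_calls = pd.DataFrame({
        "line": truth["line"].to_numpy()[good],
        "chrom": truth["chrom"].to_numpy()[good],
        "pos": truth["pos"].to_numpy()[good],
        "ref": truth["ref"].to_numpy()[good],
        "alt": truth["alt"].to_numpy()[good],
        "vtype": truth["vtype"].to_numpy()[good],
        "K": cK[good],
        "N": cN[good],
        "mq": rng.normal(55, 3, size=int(good.sum())),
        "n_callers": 2 + (rng.random(int(good.sum())) < 0.9).astype(int),
    })

    # error-only calls wherever a stray read supports a noise allele
    noise_mask = allc["is_noise"].to_numpy()
    ni, nj = np.nonzero((K >= 1) & noise_mask[:, None])
    noise_calls = pd.DataFrame({
        "line": np.array(lines, dtype=object)[nj],
        "chrom": allc["chrom"].to_numpy()[ni],
        "pos": allc["pos"].to_numpy()[ni],
        "ref": allc["ref"].to_numpy()[ni],
        "alt": allc["alt"].to_numpy()[ni],
        "vtype": allc["vtype"].to_numpy()[ni],
        "K": K[ni, nj],
        "N": N[ni, nj],
        "mq": np.clip(rng.normal(45, 8, size=len(ni)), 10, 70),
        "n_callers": 1 + (rng.random(len(ni)) < 0.3).astype(int),
    })
    calls = pd.concat([true_calls, noise_calls], ignore_index=True)[CALL_COLUMNS]

    aN = rng.poisson(experiment.ancestor_depth, size=P)
    aK = rng.binomial(aN, np.where(noise_mask, e, e / 3))
    with np.errstate(invalid="ignore", divide="ignore"):
        anc_called = (aK >= 2) & (aK / np.maximum(aN, 1) >= 0.2)
    ancestor_calls = pd.DataFrame({
        "line": "ancestor",
        "chrom": allc["chrom"].to_numpy()[anc_called],
        "pos": allc["pos"].to_numpy()[anc_called],
        "ref": allc["ref"].to_numpy()[anc_called],
        "alt": allc["alt"].to_numpy()[anc_called],
        "vtype": allc["vtype"].to_numpy()[anc_called],
        "K": aK[anc_called],
        "N": aN[anc_called],
        "mq": 50.0,
        "n_callers": 2,
    })[CALL_COLUMNS]

    return SimulatedEvidence(
        calls=calls,
        pileup=pileup,
        ancestor_calls=ancestor_calls,
        truth_keys=truth[["line", "chrom", "pos", "alt"]].copy(),
        noise_keys=noise[["chrom", "pos", "alt"]].copy(),
    )
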