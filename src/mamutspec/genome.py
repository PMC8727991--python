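"""Reference genome container and layered site annotations.

The genome model holds chromosome sequences, a callable-site mask (the
denominator of all per-base mutation rates), and the annotation layers that
every downstream stage queries: functional class (exon/intron/intergenic),
recombination domain (arm/core/tip), germline expression, recombination
rate, chromatin state and periodic A/T-cluster membership.

Coordinates are 0-based half-open internally; VCF I/O converts to and from
1-based positions at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ACGT = frozenset("ACGT")

FUNC_INTERGENIC, FUNC_INTRON, FUNC_EXON = 0, 1, 2
FUNCTIONAL_NAMES = ("intergenic", "intron", "exon")

DOM_CORE, DOM_ARM, DOM_TIP = 0, 1, 2
DOMAIN_NAMES = ("core", "arm", "tip")

#: cM/Mb assigned per recombination domain when no explicit track is given.
#: Arms recombine at high rates, cores at low rates and tips barely at all.
DEFAULT_RECOMB_BY_DOMAIN = {"arm": 6.0, "core": 1.5, "tip": 0.1}


class MaskedSiteError(ValueError):
    """Raised when a site-level query hits an uncallable (masked) position."""


class AnnotationGapError(ValueError):
    """Raised when the domain intervals leave part of a chromosome uncovered."""


@dataclass(frozen=True)
class GenomicInterval:
    """A labelled 0-based half-open interval on a chromosome."""

    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")


@dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene: CDS exons in genomic order plus expression flag."""

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    germline_expressed: bool = False

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        prev_end = -1
        for s, e in self.exons:
            if s < 0 or e <= s:
                raise ValueError(f"bad exon ({s}, {e}) in {self.gene_id}")
            if s < prev_end:
                raise ValueError(f"overlapping exons in {self.gene_id}")
            prev_end = e

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass(frozen=True)
class SiteAnnotation:
    """Everything the pipeline knows about one callable site."""

    chromosome: str
    functional_class: str
    domain: str
    germline_expressed: bool
    recombination_rate: float
    chromatin_state: str
    at_cluster: bool


@dataclass
class ReferenceGenome:
    """Chromosome sequences plus the callable mask.

    ``callable_mask`` is True exactly where the base is one of A/C/G/T and
    the site meets the coverage/quality criteria used for rate denominators
    (for a freshly loaded FASTA that is simply "not N").
    """

    names: list[str]
    seqs: dict[str, str]
    callable_mask: dict[str, np.ndarray]
    x_names: frozenset[str] = frozenset({"X"})
    mito_names: frozenset[str] = frozenset({"MtDNA"})

    def __post_init__(self):
        if len(self.names) != len(set(self.names)):
            raise ValueError("duplicate chromosome names")
        for name in self.names:
            if len(self.seqs[name]) != len(self.callable_mask[name]):
                raise ValueError(f"mask/sequence length mismatch on {name}")

    def is_mito(self, name: str) -> bool:
        return name in self.mito_names

    def is_autosome(self, name: str) -> bool:
        return name not in self.x_names and name not in self.mito_names

    @property
    def nuclear_names(self) -> list[str]:
        return [n for n in self.names if not self.is_mito(n)]

    def length(self, name: str) -> int:
        return len(self.seqs[name])

    def callable_bases(self, names=None) -> int:
        names = self.nuclear_names if names is None else names
        return int(sum(self.callable_mask[n].sum() for n in names))

    def base(self, chrom: str, pos: int) -> str:
        return self.seqs[chrom][pos]

    def gc_fraction(self, names=None) -> float:
        names = self.nuclear_names if names is None else names
        gc = total = 0
        for n in names:
            s = self.seqs[n]
            gc += s.count("G") + s.count("C")
            total += s.count("A") + s.count("T") + s.count("G") + s.count("C")
        return gc / total


def mask_from_sequence(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype="S1")
    return (arr == b"A") | (arr == b"C") | (arr == b"G") | (arr == b"T")


def load_reference(fasta_path, x_names=("X",), mito_names=("MtDNA",)) -> ReferenceGenome:
    """Load a FASTA into a :class:`ReferenceGenome`.

    The callable mask starts out True at A/C/G/T and False elsewhere (N and
    ambiguity codes). Gzipped input is accepted.
    """
    from .formats import read_fasta

    records = read_fasta(fasta_path)
    if not records:
        raise ValueError(f"no sequences in {fasta_path}")
    names = [name for name, _ in records]
    if len(names) != len(set(names)):
        raise ValueError(f"duplicate sequence names in {fasta_path}")
    seqs = {name: seq.upper() for name, seq in records}
    mask = {name: mask_from_sequence(seq) for name, seq in seqs.items()}
    return ReferenceGenome(
        names=names,
        seqs=seqs,
        callable_mask=mask,
        x_names=frozenset(x_names),
        mito_names=frozenset(mito_names),
    )


@dataclass
class AnnotationLayers:
    """Per-chromosome annotation tracks, index-aligned with the sequences."""

    functional: dict[str, np.ndarray]  # uint8, FUNC_* codes
    domain: dict[str, np.ndarray]  # uint8, DOM_* codes
    germline: dict[str, np.ndarray]  # bool
    recomb: dict[str, np.ndarray]  # float32, cM/Mb
    chromatin: dict[str, np.ndarray]  # uint8 index into chromatin_states
    chromatin_states: list[str]
    at_cluster: dict[str, np.ndarray]  # bool
    genes: list[GeneModel] = field(default_factory=list)

    def genes_on(self, chrom: str) -> list[GeneModel]:
        return [g for g in self.genes if g.chrom == chrom]


def _empty_layers(genome: ReferenceGenome) -> AnnotationLayers:
    lens = {n: genome.length(n) for n in genome.names}
    return AnnotationLayers(
        functional={n: np.zeros(L, dtype=np.uint8) for n, L in lens.items()},
        domain={n: np.zeros(L, dtype=np.uint8) for n, L in lens.items()},
        germline={n: np.zeros(L, dtype=bool) for n, L in lens.items()},
        recomb={n: np.zeros(L, dtype=np.float32) for n, L in lens.items()},
        chromatin={n: np.zeros(L, dtype=np.uint8) for n, L in lens.items()},
        chromatin_states=["none"],
        at_cluster={n: np.zeros(L, dtype=bool) for n, L in lens.items()},
    )


def layers_from_components(
    genome: ReferenceGenome,
    genes: list[GeneModel],
    domain_intervals: list[GenomicInterval],
    chromatin_intervals: list[GenomicInterval] | None = None,
    at_cluster_intervals: list[GenomicInterval] | None = None,
    recomb_by_domain: dict[str, float] | None = None,
) -> AnnotationLayers:
    """Rasterize interval-level annotations into per-site tracks.

    Domain intervals must tile each nuclear chromosome completely; gaps are
    an error because every callable site needs exactly one domain label.
    Gene spans set intron, exons override to exon (exon > intron precedence
    for overlapping gene models); everything else stays intergenic.
    """
    layers = _empty_layers(genome)
    recomb_map = dict(DEFAULT_RECOMB_BY_DOMAIN)
    if recomb_by_domain:
        recomb_map.update(recomb_by_domain)

    dom_code = {name: code for code, name in enumerate(DOMAIN_NAMES)}
    covered = {n: np.zeros(genome.length(n), dtype=bool) for n in genome.names}
    for iv in domain_intervals:
        if iv.label not in dom_code:
            raise ValueError(f"unknown domain label {iv.label!r}")
        layers.domain[iv.chrom][iv.start : iv.end] = dom_code[iv.label]
        layers.recomb[iv.chrom][iv.start : iv.end] = recomb_map[iv.label]
        covered[iv.chrom][iv.start : iv.end] = True
    gaps = []
    for n in genome.nuclear_names:
        missing = np.flatnonzero(~covered[n])
        if missing.size:
            # report the first uncovered run per chromosome
            breaks = np.flatnonzero(np.diff(missing) > 1)
            first_end = int(missing[breaks[0]] if breaks.size else missing[-1]) + 1
            gaps.append(f"{n}:{int(missing[0])}-{first_end} ({missing.size} sites total)")
    if gaps:
        raise AnnotationGapError("domain intervals leave gaps: " + ", ".join(gaps))

    for gene in genes:
        s, e = gene.span
        func = layers.functional[gene.chrom]
        func[s:e] = np.maximum(func[s:e], FUNC_INTRON)
        if gene.germline_expressed:
            layers.germline[gene.chrom][s:e] = True
    for gene in genes:
        for s, e in gene.exons:
            layers.functional[gene.chrom][s:e] = FUNC_EXON
    layers.genes = list(genes)

    if chromatin_intervals:
        states = sorted({iv.label for iv in chromatin_intervals})
        layers.chromatin_states = states
        code = {s: i for i, s in enumerate(states)}
        for iv in chromatin_intervals:
            layers.chromatin[iv.chrom][iv.start : iv.end] = code[iv.label]
    if at_cluster_intervals:
        for iv in at_cluster_intervals:
            layers.at_cluster[iv.chrom][iv.start : iv.end] = True
    return layers


def load_annotations(
    genome: ReferenceGenome,
    gff_path,
    domains_bed,
    expression_table,
    chromatin_bed=None,
    at_cluster_bed=None,
    recomb_by_domain: dict[str, float] | None = None,
) -> AnnotationLayers:
    """Load GFF3 genes/exons, domain BED and a gene-expression TSV into tracks."""
    from .formats import read_bed_intervals, read_expression_table, read_gff3_genes

    expressed = read_expression_table(expression_table)
    genes = read_gff3_genes(gff_path, germline_ids=expressed)
    domains = read_bed_intervals(domains_bed)
    chromatin = read_bed_intervals(chromatin_bed) if chromatin_bed else None
    at_clusters = read_bed_intervals(at_cluster_bed) if at_cluster_bed else None
    return layers_from_components(
        genome, genes, domains, chromatin, at_clusters, recomb_by_domain
    )


def annotate_site(
    genome: ReferenceGenome, layers: AnnotationLayers, chrom: str, pos: int
) -> SiteAnnotation:
    """Resolve one callable site to its full annotation (total, deterministic)."""
    if not (0 <= pos < genome.length(chrom)):
        raise IndexError(f"{chrom}:{pos} outside chromosome")
    if not genome.callable_mask[chrom][pos]:
        raise MaskedSiteError(f"{chrom}:{pos} is masked")
    return SiteAnnotation(
        chromosome=chrom,
        functional_class=FUNCTIONAL_NAMES[layers.functional[chrom][pos]],
        domain=DOMAIN_NAMES[layers.domain[chrom][pos]],
        germline_expressed=bool(layers.germline[chrom][pos]),
        recombination_rate=float(layers.recomb[chrom][pos]),
        chromatin_state=layers.chromatin_states[layers.chromatin[chrom][pos]],
        at_cluster=bool(layers.at_cluster[chrom][pos]),
    )
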