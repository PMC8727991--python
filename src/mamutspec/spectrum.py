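"""Mutation classification and every rate, ratio and bias statistic.

Rates follow the MA-line estimator: for line i with F accepted mutations,
G generations and B callable bases in the queried partition,

    mu_i = F_i / (G_i * B),

and the experiment-wide rate is the arithmetic mean of the line-specific
rates, with a 95% CI of t_{0.975, n-1} * SEM over lines. Substitutions are
strand-collapsed into six classes (transitions are A/T->G/C and G/C->A/T);
trinucleotide contexts are collapsed with their reverse complements into 32
keys. Mitochondrial rates weight each heteroplasmic variant by its read
frequency, so a variant at 5% heteroplasmy contributes 0.05 events.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats

from .genome import DOMAIN_NAMES, FUNCTIONAL_NAMES, AnnotationLayers, ReferenceGenome
from .repeats import RepeatCatalog, revcomp
from .study_tables import SUBSTITUTION_CLASSES, TRANSITION_CLASSES

_CLASS_OF = {
    ("A", "G"): "A/T->G/C", ("T", "C"): "A/T->G/C",
    ("A", "T"): "A/T->T/A", ("T", "A"): "A/T->T/A",
    ("A", "C"): "A/T->C/G", ("T", "G"): "A/T->C/G",
    ("G", "A"): "G/C->A/T", ("C", "T"): "G/C->A/T",
    ("G", "T"): "G/C->T/A", ("C", "A"): "G/C->T/A",
    ("G", "C"): "G/C->C/G", ("C", "G"): "G/C->C/G",
}


def classify_substitution(ref: str, alt: str) -> tuple[str, bool]:
    """Strand-collapsed substitution class and transition flag."""
    key = (ref.upper(), alt.upper())
    if key[0] == key[1] or key not in _CLASS_OF:
        raise ValueError(f"not a substitution: {ref}>{alt}")
    cls = _CLASS_OF[key]
    return cls, cls in TRANSITION_CLASSES


def collapse_triplet(triplet: str) -> str:
    """Canonical key shared by a triplet and its reverse complement."""
    triplet = triplet.upper()
    if len(triplet) != 3 or any(b not in "ACGT" for b in triplet):
        return "NA"
    return min(triplet, revcomp(triplet))


def collapse_context(genome: ReferenceGenome, chrom: str, pos0: int) -> str:
    """Collapsed 5'-x[focal]y-3' key for a 0-based site ("NA" at edges/N)."""
    seq = genome.seqs[chrom]
    if pos0 < 1 or pos0 + 2 > len(seq):
        return "NA"
    return collapse_triplet(seq[pos0 - 1 : pos0 + 2])


def all_collapsed_triplets() -> list[str]:
    return sorted({collapse_triplet("".join(t)) for t in product("ACGT", repeat=3)})


# ---------------------------------------------------------------------------
# Coding effect
# ---------------------------------------------------------------------------

def _translate(codon: str) -> str:
    from Bio.Seq import Seq

    return str(Seq(codon).translate())


def _cds_sequence(gene, genome: ReferenceGenome) -> str:
    seq = "".join(genome.seqs[gene.chrom][s:e] for s, e in gene.exons)
    return revcomp(seq) if gene.strand == "-" else seq


def _cds_index(gene, pos0: int) -> int | None:
    """CDS coordinate of a genomic site, or None if not exonic."""
    offset = 0
    for s, e in gene.exons:
        if s <= pos0 < e:
            idx = offset + (pos0 - s)
            return gene.cds_length - 1 - idx if gene.strand == "-" else idx
        offset += e - s
    return None


def classify_coding_effect(
    genome: ReferenceGenome, layers: AnnotationLayers,
    chrom: str, pos0: int, ref: str, alt: str, vtype: str,
) -> str:
    """synonymous / nonsynonymous / frameshift / in-frame-indel / noncoding."""
    gene = next(
        (g for g in layers.genes_on(chrom) if g.span[0] <= pos0 < g.span[1]), None
    )
    if gene is None:
        return "noncoding"
    if vtype != "snp":
        # indel anchored in/into the CDS: the first changed base is pos0 + 1
        if _cds_index(gene, pos0 + 1) is None and _cds_index(gene, pos0) is None:
            return "noncoding"
        size = len(alt) - len(ref)
        return "frameshift" if size % 3 != 0 else "in-frame-indel"
    idx = _cds_index(gene, pos0)
    if idx is None:
        return "noncoding"
    if gene.cds_length % 3 != 0:
        raise ValueError(f"broken reading frame in {gene.gene_id}")
    cds = _cds_sequence(gene, genome)
    base = alt if gene.strand == "+" else revcomp(alt)
    ci, off = divmod(idx, 3)
    codon = cds[3 * ci : 3 * ci + 3]
    mutated = codon[:off] + base + codon[off + 1 :]
    return "synonymous" if _translate(codon) == _translate(mutated) else "nonsynonymous"


def synonymous_site_counts(genes, genome: ReferenceGenome) -> tuple[float, float]:
    """Fractional (nonsynonymous, synonymous) site counts over gene models.

    Nei-Gojobori style: each codon position contributes the fraction of its
    three possible changes that are synonymous. Total sites per gene equal
    the CDS length.
    """
    nonsyn = syn = 0.0
    for gene in genes:
        cds = _cds_sequence(gene, genome)
        if len(cds) % 3 != 0:
            raise ValueError(f"broken reading frame in {gene.gene_id}")
        for ci in range(len(cds) // 3):
            codon = cds[3 * ci : 3 * ci + 3]
            aa = _translate(codon)
            for off in range(3):
                s = 0
                for b in "ACGT":
                    if b == codon[off]:
                        continue
                    mutated = codon[:off] + b + codon[off + 1 :]
                    if _translate(mutated) == aa:
                        s += 1
                syn += s / 3
                nonsyn += 1 - s / 3
    return nonsyn, syn


# ---------------------------------------------------------------------------
# Record annotation
# ---------------------------------------------------------------------------

def annotate_records(
    calls: pd.DataFrame,
    genome: ReferenceGenome,
    layers: AnnotationLayers,
    catalog: RepeatCatalog,
    flank: int = 1,
    coding_effects: bool = True,
) -> pd.DataFrame:
    """Turn accepted calls (1-based pos) into fully classified mutation
    records: class, context, repeat status, partition labels, indel size."""
    records = []
    for r in calls.itertuples():
        pos0 = int(r.pos) - 1
        rec = dict(
            line=r.line, chrom=r.chrom, pos=int(r.pos), ref=r.ref, alt=r.alt,
            vtype=r.vtype, is_autosome=genome.is_autosome(r.chrom),
        )
        if r.vtype == "snp":
            cls, is_ts = classify_substitution(r.ref, r.alt)
            rec.update(
                subst_class=cls, is_transition=is_ts,
                context=collapse_context(genome, r.chrom, pos0), indel_size=0,
            )
            query_pos = pos0
        else:
            rec.update(
                subst_class=None, is_transition=False, context="NA",
                indel_size=len(r.alt) - len(r.ref),
            )
            query_pos = pos0 + 1  # first base after the anchor
        hit = catalog.query(r.chrom, query_pos, flank=flank)
        if hit is None:
            rec.update(repeat_status="complex", run_length=0, run_class=None,
                       run_unit=0, run_family=None)
        else:
            rec.update(
                repeat_status=hit.status, run_length=hit.run.length,
                run_class=hit.run.base_class, run_unit=hit.run.unit_length,
                run_family=hit.run.family,
            )
        rec.update(
            functional=FUNCTIONAL_NAMES[layers.functional[r.chrom][pos0]],
            domain=DOMAIN_NAMES[layers.domain[r.chrom][pos0]],
            germline=bool(layers.germline[r.chrom][pos0]),
        )
        if coding_effects and rec["functional"] == "exon":
            rec["coding_effect"] = classify_coding_effect(
                genome, layers, r.chrom, pos0, r.ref, r.alt, r.vtype
            )
        else:
            rec["coding_effect"] = "noncoding"
        records.append(rec)
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# Rates
# ---------------------------------------------------------------------------

@dataclass
class RateTable:
    """Per-line rates for one partition plus their mean and 95% CI."""

    label: str
    per_line: pd.Series  # index: line id, values: mu_i
    B: int

    @property
    def n(self) -> int:
        return len(self.per_line)

    @property
    def mean(self) -> float:
        return float(self.per_line.mean())

    @property
    def ci95(self) -> float:
        if self.n < 2:
            return float("nan")
        sem = self.per_line.std(ddof=1) / np.sqrt(self.n)
        return float(stats.t.ppf(0.975, self.n - 1) * sem)


def mutation_rate(F: float, G: float, B: float) -> float:
    """mu = F / (G * B), variants per base per generation."""
    if B <= 0:
        raise ValueError("B must be positive")
    if G < 1:
        raise ValueError("G must be >= 1")
    return F / (G * B)


def line_mean_rate(
    records: pd.DataFrame,
    line_generations: dict[str, float],
    B: int,
    label: str = "all",
    mask: pd.Series | None = None,
) -> RateTable:
    """Per-line and averaged rate for the records selected by ``mask``.

    Every sequenced line contributes, including lines with zero mutations
    in the partition.
    """
    if B <= 0:
        raise ValueError(f"partition {label!r} has no callable bases")
    sub = records if mask is None else records[mask]
    counts = sub.groupby("line").size() if len(sub) else pd.Series(dtype=float)
    lines = pd.Index(line_generations.keys(), name="line")
    counts = counts.reindex(lines, fill_value=0).astype(float)
    gens = pd.Series(line_generations)
    return RateTable(label=label, per_line=counts / (gens * B), B=B)


def fold_change(
    table: RateTable,
    reference_mean: float,
    reference_per_line: pd.Series | None = None,
):
    """Rate fold change vs a reference spectrum, with a Welch t-test on
    per-line rates when reference per-line rates are available."""
    if reference_mean == 0:
        return {"fold": float("nan"), "defined": False}
    out = {"fold": table.mean / reference_mean, "defined": True}
    if reference_per_line is not None and table.n >= 2 and len(reference_per_line) >= 2:
        t, p = stats.ttest_ind(table.per_line, reference_per_line, equal_var=False)
        out.update(t=float(t), p=float(p))
    return out


def tstv_ratio(records: pd.DataFrame, per_line: bool = False) -> float:
    """Transition/transversion ratio, pooled or as the mean of line ratios."""
    snps = records[records["vtype"] == "snp"]
    if per_line:
        def _ratio(g):
            tv = (~g["is_transition"]).sum()
            return np.nan if tv == 0 else g["is_transition"].sum() / tv
        vals = snps.groupby("line").apply(_ratio, include_groups=False).dropna()
        return float(vals.mean())
    ts = int(snps["is_transition"].sum())
    tv = len(snps) - ts
    if tv == 0:
        raise ZeroDivisionError("no transversions in pooled records")
    return ts / tv


def tstv_from_class_counts(counts: pd.Series) -> float:
    ts = sum(counts.get(c, 0) for c in TRANSITION_CLASSES)
    tv = sum(counts.get(c, 0) for c in SUBSTITUTION_CLASSES) - ts
    return ts / tv


def at_bias(class_counts: pd.Series, gc_fraction: float) -> dict:
    """Fraction of GC-changing substitutions that move toward A+T.

    The normalized version divides each direction's count by the fraction
    of genomic sites able to produce it (G/C sites for AT-ward changes,
    A/T sites for GC-ward changes); with uniform composition it reduces
    exactly to the raw count fraction.
    """
    if not (0 < gc_fraction < 1):
        raise ValueError("gc_fraction must be in (0, 1)")
    to_at = class_counts.get("G/C->A/T", 0) + class_counts.get("G/C->T/A", 0)
    to_gc = class_counts.get("A/T->G/C", 0) + class_counts.get("A/T->C/G", 0)
    raw = to_at / (to_at + to_gc)
    wa = to_at / gc_fraction
    wg = to_gc / (1 - gc_fraction)
    return {"normalized": wa / (wa + wg), "raw": raw}


def indel_summary(records: pd.DataFrame) -> dict:
    """Size histograms, 1-bp fractions, deletion:insertion ratio and the
    summed signed length change (net bp gained/lost)."""
    ind = records[records["vtype"].isin(["insertion", "deletion"])]
    sizes = ind["indel_size"].astype(int)
    dels = sizes[sizes < 0]
    ins = sizes[sizes > 0]
    return {
        "n_deletions": int(len(dels)),
        "n_insertions": int(len(ins)),
        "deletion_1bp_fraction": float((dels == -1).mean()) if len(dels) else 0.0,
        "insertion_1bp_fraction": float((ins == 1).mean()) if len(ins) else 0.0,
        "deletion_insertion_ratio": (len(dels) / len(ins)) if len(ins) else np.nan,
        "net_bp_change": int(sizes.sum()),
        "size_histogram_del": (-dels).value_counts().sort_index().to_dict(),
        "size_histogram_ins": ins.value_counts().sort_index().to_dict(),
        "per_line_counts": ind.groupby(["line", "vtype"]).size().to_dict(),
    }


def homopolymer_indel_rates(
    records: pd.DataFrame,
    catalog: RepeatCatalog,
    line_generations: dict[str, float],
) -> pd.DataFrame:
    """Per-run indel rates by homopolymer base class, run length and
    direction: events / (runs of that length * total line-generations)."""
    census = catalog.homopolymer_census()
    total_gens = float(sum(line_generations.values()))
    ind = records[
        records["vtype"].isin(["insertion", "deletion"])
        & (records["repeat_status"] == "in_repeat")
        & (records["run_unit"] == 1)
    ]
    counts = ind.groupby(["run_class", "run_length", "vtype"]).size()
    rows = []
    for (bc, length), n_runs in sorted(census.items()):
        for direction in ("deletion", "insertion"):
            n_events = int(counts.get((bc, length, direction), 0))
            rows.append(
                dict(base_class=bc, run_length=length, direction=direction,
                     n_events=n_events, n_runs=n_runs,
                     rate_per_run=n_events / (n_runs * total_gens))
            )
    return pd.DataFrame(rows)


def homopolymer_rate_peak(rate_table: pd.DataFrame, base_class: str = "AT") -> int:
    """Run length with the highest combined per-run indel rate."""
    sub = rate_table[rate_table["base_class"] == base_class]
    total = sub.groupby("run_length")["rate_per_run"].sum()
    return int(total.idxmax())


def snp_adjacency_by_run_length(
    records: pd.DataFrame, catalog: RepeatCatalog, base_class: str = "AT"
) -> pd.DataFrame:
    """SNPs adjacent to homopolymer runs, normalized per run of each length."""
    census = catalog.homopolymer_census()
    snps = records[
        (records["vtype"] == "snp")
        & records["repeat_status"].isin(["adjacent", "in_repeat"])
        & (records["run_unit"] == 1)
        & (records["run_class"] == base_class)
    ]
    counts = snps.groupby("run_length").size()
    rows = [
        dict(run_length=length, n_snps=int(counts.get(length, 0)), n_runs=n,
             snps_per_run=counts.get(length, 0) / n)
        for (bc, length), n in sorted(census.items())
        if bc == base_class
    ]
    return pd.DataFrame(rows)


def dinucleotide_indel_dynamics(
    records: pd.DataFrame,
    catalog: RepeatCatalog,
    line_generations: dict[str, float],
) -> pd.DataFrame:
    """Insertion/deletion rates per dinucleotide motif family, normalized
    per run and per total line-generations."""
    census = catalog.dinucleotide_census()
    total_gens = float(sum(line_generations.values()))
    ind = records[
        records["vtype"].isin(["insertion", "deletion"])
        & (records["repeat_status"] == "in_repeat")
        & (records["run_unit"] == 2)
    ]
    rows = []
    for family, n_runs in sorted(census.items()):
        sub = ind[ind["run_family"] == family]
        for direction in ("deletion", "insertion"):
            n_events = int((sub["vtype"] == direction).sum())
            rows.append(
                dict(family=family, direction=direction, n_events=n_events,
                     n_runs=n_runs,
                     rate_per_run=n_events / (n_runs * total_gens))
            )
    return pd.DataFrame(rows)


def mito_rate(
    heteroplasmies: pd.DataFrame,
    line_generations: dict[str, float],
    L_mt: int = 13794,
) -> RateTable:
    """Heteroplasmy-weighted mitochondrial mutation rate.

    Per line: (sum of variant read frequencies) / (L_mt * G); a multi-bp
    deletion counts once at its frequency. The overall rate averages over
    *all* sequenced lines, including those with no mitochondrial variant.
    """
    if L_mt <= 0:
        raise ValueError("L_mt must be positive")
    if len(heteroplasmies):
        f = heteroplasmies["frequency"]
        if ((f <= 0) | (f > 1)).any():
            raise ValueError("heteroplasmy frequencies must lie in (0, 1]")
        sums = heteroplasmies.groupby("line")["frequency"].sum()
    else:
        sums = pd.Series(dtype=float)
    lines = pd.Index(line_generations.keys(), name="line")
    sums = sums.reindex(lines, fill_value=0.0)
    gens = pd.Series(line_generations)
    return RateTable(label="mito", per_line=sums / (L_mt * gens), B=L_mt)


# ---------------------------------------------------------------------------
# Partition comparisons
# ---------------------------------------------------------------------------

def callable_by_functional(genome: ReferenceGenome, layers: AnnotationLayers) -> dict:
    out = {}
    for i, name in enumerate(FUNCTIONAL_NAMES):
        out[name] = int(
            sum((genome.callable_mask[c] & (layers.functional[c] == i)).sum()
                for c in genome.nuclear_names)
        )
    return out


def callable_by_domain(genome: ReferenceGenome, layers: AnnotationLayers) -> dict:
    out = {}
    for i, name in enumerate(DOMAIN_NAMES):
        out[name] = int(
            sum((genome.callable_mask[c] & (layers.domain[c] == i)).sum()
                for c in genome.nuclear_names)
        )
    return out


def partition_compare(
    records: pd.DataFrame,
    line_generations: dict[str, float],
    partition_column: str,
    B_by_label: dict[str, int],
    mask: pd.Series | None = None,
) -> dict:
    """Per-partition rate tables plus ANOVA / Welch tests on per-line rates.

    With fewer than two lines only the descriptive rate tables are
    returned (tests skipped).
    """
    sub = records if mask is None else records[mask]
    tables = {}
    for label, B in B_by_label.items():
        if B <= 0:
            continue
        tables[label] = line_mean_rate(
            sub, line_generations, B, label=label,
            mask=sub[partition_column] == label,
        )
    out = {"tables": tables}
    if len(line_generations) >= 2 and len(tables) >= 2:
        groups = [t.per_line.to_numpy() for t in tables.values()]
        f, p = stats.f_oneway(*groups)
        out["anova"] = {"F": float(f), "p": float(p)}
        labels = list(tables)
        welch = {}
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                t, p = stats.ttest_ind(
                    tables[labels[i]].per_line, tables[labels[j]].per_line,
                    equal_var=False,
                )
                welch[(labels[i], labels[j])] = {"t": float(t), "p": float(p)}
        out["welch"] = welch
    return out


def compare_x_autosomes(
    records: pd.DataFrame,
    line_generations: dict[str, float],
    B_x: int,
    B_autosomes: int,
    vtype: str = "snp",
) -> dict:
    """Paired (within-line) t-test of X vs autosomal per-line rates."""
    sub = records[records["vtype"] == vtype] if vtype else records
    tab_x = line_mean_rate(sub, line_generations, B_x, "X",
                           mask=~sub["is_autosome"])
    tab_a = line_mean_rate(sub, line_generations, B_autosomes, "autosomes",
                           mask=sub["is_autosome"])
    out = {"X": tab_x, "autosomes": tab_a,
           "mean_difference": tab_x.mean - tab_a.mean}
    if tab_x.n >= 2:
        t, p = stats.ttest_rel(tab_x.per_line, tab_a.per_line)
        out["paired_t"] = {"t": float(t), "p": float(p)}
    return out
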