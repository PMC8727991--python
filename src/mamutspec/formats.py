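"""Standard-format I/O: FASTA, GFF3, BED, expression TSV, and call VCFs.

All readers accept plain or gzipped text. Variant calls travel as pandas
DataFrames inside the pipeline; the VCF writer/reader here converts between
that table and one VCF per line (with K/N/MQ in INFO) plus a sidecar TSV
carrying the caller concordance sets.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .genome import GeneModel, GenomicInterval

#: columns of the in-memory variant-call table
CALL_COLUMNS = [
    "line", "chrom", "pos", "ref", "alt", "vtype", "K", "N", "mq", "n_callers",
]


def _open_text(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path) -> list[tuple[str, str]]:
    with _open_text(path) as fh:
        return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(fh, "fasta")]


def write_fasta(records: dict[str, str], path, width: int = 70) -> None:
    with _open_text(path, "wt") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_bed_intervals(path) -> list[GenomicInterval]:
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name"], usecols=range(4),
    )
    return [
        GenomicInterval(r.chrom, int(r.start), int(r.end), str(r.name))
        for r in df.itertuples()
    ]


def write_bed(intervals, path) -> None:
    with _open_text(path, "wt") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label}\n")


def read_expression_table(path) -> set[str]:
    """Two-column TSV gene_id -> 0/1 germline-expressed flag."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "expressed"])
    return set(df.loc[df.expressed.astype(int) == 1, "gene_id"].astype(str))


def write_expression_table(genes: list[GeneModel], path) -> None:
    with _open_text(path, "wt") as fh:
        for g in genes:
            fh.write(f"{g.gene_id}\t{int(g.germline_expressed)}\n")


def write_gff3(genes: list[GeneModel], path) -> None:
    with _open_text(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            s, e = g.span
            fh.write(
                f"{g.chrom}\tmamutspec\tgene\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            for i, (xs, xe) in enumerate(g.exons):
                fh.write(
                    f"{g.chrom}\tmamutspec\texon\t{xs + 1}\t{xe}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.e{i};Parent={g.gene_id}\n"
                )


def read_gff3_genes(path, germline_ids: set[str] | None = None) -> list[GeneModel]:
    import gffutils

    germline_ids = germline_ids or set()
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for g in db.features_of_type("gene"):
        exons = sorted(
            (e.start - 1, e.end) for e in db.children(g, featuretype="exon")
        )
        if not exons:
            exons = [(g.start - 1, g.end)]
        genes.append(
            GeneModel(
                gene_id=g.id,
                chrom=g.seqid,
                strand=g.strand,
                exons=tuple(exons),
                germline_expressed=g.id in germline_ids,
            )
        )
    return genes


# ---------------------------------------------------------------------------
# VCF call tables
# ---------------------------------------------------------------------------

def _vcf_header(genome):
    import pysam

    header = pysam.VariantHeader()
    for name in genome.names:
        header.contigs.add(name, length=genome.length(name))
    header.info.add("K", 1, "Integer", "Reads supporting the variant")
    header.info.add("NT", 1, "Integer", "Total high-quality reads at site")
    header.info.add("MQRMS", 1, "Float", "Root-mean-square mapping quality")
    header.info.add("VT", 1, "String", "Variant type (snp/insertion/deletion)")
    return header


def write_calls_vcf(calls: pd.DataFrame, genome, vcf_path, callers_tsv=None) -> None:
    """Write one line's calls as VCF (1-based) plus a caller-set sidecar TSV."""
    import pysam

    header = _vcf_header(genome)
    with pysam.VariantFile(str(vcf_path), "w", header=header) as out:
        for r in calls.sort_values(["chrom", "pos"]).itertuples():
            rec = out.new_record(
                contig=r.chrom, start=int(r.pos) - 1, alleles=(r.ref, r.alt)
            )
            rec.info["K"] = int(r.K)
            rec.info["NT"] = int(r.N)
            rec.info["MQRMS"] = float(r.mq)
            rec.info["VT"] = r.vtype
            out.write(rec)
    if callers_tsv is not None:
        calls[["chrom", "pos", "alt", "n_callers"]].to_csv(
            callers_tsv, sep="\t", index=False
        )


def read_calls_vcf(vcf_path, line_id, callers_tsv=None) -> pd.DataFrame:
    import pysam

    rows = []
    with pysam.VariantFile(str(vcf_path)) as vf:
        for rec in vf:
            ref, alt = rec.ref, rec.alts[0]
            rows.append(
                dict(
                    line=line_id, chrom=rec.contig, pos=rec.pos, ref=ref, alt=alt,
                    vtype=rec.info["VT"], K=int(rec.info["K"]),
                    N=int(rec.info["NT"]), mq=float(rec.info["MQRMS"]),
                    n_callers=np.nan,
                )
            )
    calls = pd.DataFrame(rows, columns=CALL_COLUMNS)
    if callers_tsv is not None:
        sidecar = pd.read_csv(callers_tsv, sep="\t")
        calls = calls.drop(columns="n_callers").merge(
            sidecar, on=["chrom", "pos", "alt"], how="left"
        )
    return calls
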