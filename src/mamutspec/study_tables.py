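"""Published summary tables of the msh-2(RNAi) knockdown MA experiment.

These fixtures transcribe, once, the reference dataset this package's
defaults emulate: 19 obligately outcrossing C. elegans MA lines propagated
for a mean of 40.3 generations under RNAi knockdown of the mismatch-repair
gene msh-2, compared against wildtype (selfing, repair-proficient) MA
lines. They are the inputs to :mod:`mamutspec.reporting`, which recomputes
every derived statistic from them through the spectrum operations; no
derived value is stored here.

``validate_tables`` asserts the internal consistency of the transcription
(row/column sums, fold-change arithmetic) so silent drift is impossible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

SUBSTITUTION_CLASSES = (
    "A/T->G/C",
    "A/T->T/A",
    "A/T->C/G",
    "G/C->A/T",
    "G/C->T/A",
    "G/C->C/G",
)

#: strand-collapsed transitions
TRANSITION_CLASSES = ("A/T->G/C", "G/C->A/T")


def _table1() -> pd.DataFrame:
    # per-class mutation rates in units of 1e-7 per site per generation
    # (CNV rows are per protein-coding gene per generation)
    rows = [
        ("snp", 0.0184, 0.42),
        ("indel", 0.0068, 2.23),
        ("deletion", 0.0051, 1.47),
        ("insertion", 0.0018, 0.76),
        ("mito", 1.05, 2.18),
        ("cnv_gain", 26.40, 10.70),
        ("cnv_loss", 11.90, 3.95),
    ]
    return pd.DataFrame(rows, columns=["class", "wildtype", "knockdown"]).set_index(
        "class"
    )


def _table2() -> pd.DataFrame:
    # substitution counts partitioned into complex vs repeat sequence
    rows = [
        ("A/T->G/C", 886, 832, 54),
        ("A/T->T/A", 545, 98, 447),
        ("A/T->C/G", 403, 367, 36),
        ("G/C->A/T", 768, 708, 60),
        ("G/C->T/A", 494, 472, 22),
        ("G/C->C/G", 29, 27, 2),
    ]
    return pd.DataFrame(
        rows, columns=["class", "total", "complex", "repeat"]
    ).set_index("class")


def _table3() -> pd.DataFrame:
    # heteroplasmic mtDNA variants: line, generations, frequency of reads
    rows = [
        ("16", 33, 721, "T->C", 0.937),
        ("16", 33, 6361, "1034bp_del", 0.817),
        ("38", 43, 8872, "C->T", 0.034),
        ("34", 43, 11722, "T8->T9", 0.040),
        ("4", 44, 11722, "T8->T9", 0.049),
    ]
    return pd.DataFrame(
        rows, columns=["line", "generations", "position", "mutation", "frequency"]
    )


@dataclass(frozen=True)
class StudyTables:
    """Printed per-class rates, spectrum partition and mtDNA variant tables."""

    table1: pd.DataFrame = field(default_factory=_table1)
    table2: pd.DataFrame = field(default_factory=_table2)
    table3: pd.DataFrame = field(default_factory=_table3)

    # scalar constants of the experiment
    n_lines: int = 19
    mean_generations: float = 40.3
    n_snps: int = 3125
    n_deletions: int = 7180
    n_insertions: int = 3681
    n_deletions_1bp: int = 6960
    n_insertions_1bp: int = 3513
    #: printed summed signed length change of indels longer than 1 bp
    net_loss_gt1bp: int = 381
    #: genomic G+C fraction of C. elegans
    genome_gc: float = 0.36
    #: mtDNA length (bp), the default heteroplasmy-rate denominator
    mito_length: int = 13794


def validate_tables(tables: StudyTables | None = None) -> StudyTables:
    """Checksum the fixture transcription against its own invariants."""
    t = tables or StudyTables()
    t2 = t.table2
    assert list(t2.index) == list(SUBSTITUTION_CLASSES)
    assert int(t2["total"].sum()) == t.n_snps == 3125
    assert int(t2["complex"].sum()) == 2504
    assert int(t2["repeat"].sum()) == 621
    assert ((t2["complex"] + t2["repeat"]) == t2["total"]).all()
    # fold changes implied by table 1 rates must match within rounding
    t1 = t.table1
    for cls, printed in [("indel", 327.94), ("deletion", 288.24), ("insertion", 422.22)]:
        fold = t1.loc[cls, "knockdown"] / t1.loc[cls, "wildtype"]
        assert abs(fold - printed) < 0.5, (cls, fold)
    assert t.n_deletions_1bp <= t.n_deletions
    assert t.n_insertions_1bp <= t.n_insertions
    assert ((t.table3["frequency"] > 0) & (t.table3["frequency"] <= 1)).all()
    return t
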