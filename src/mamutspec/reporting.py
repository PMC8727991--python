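"""Recompute every derived Results statistic and render machine reports.

``recompute_results`` takes only the transcribed summary tables of the
reference experiment (:mod:`mamutspec.study_tables`) and pushes them
through the spectrum operations — pooled Ts/Tv, repeat-partition shares,
composition-normalized AT bias, indel net-loss accounting, combined and
fold-change rates, and the heteroplasmy-weighted mtDNA rate. Nothing here
is hand-entered: every number is derived at call time.

``analysis_bundle`` produces the matching report for a pipeline run on
actual (or simulated) mutation records.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from . import spectrum as sp
from .study_tables import StudyTables, validate_tables


def recompute_results(tables: StudyTables | None = None) -> dict:
    t = validate_tables(tables)
    t1, t2, t3 = t.table1, t.table2, t.table3
    class_counts = t2["total"]

    bias = sp.at_bias(class_counts, t.genome_gc)

    # indel length accounting from the printed counts
    net_1bp = t.n_insertions_1bp - t.n_deletions_1bp
    net_total = net_1bp - t.net_loss_gt1bp
    per_genome = abs(net_total) / t.n_lines
    per_genome_per_gen = per_genome / t.mean_generations

    # heteroplasmy-weighted mitochondrial rate; lines without a variant
    # contribute zero regardless of their generation number
    gens = {str(r.line): float(r.generations) for r in t3.itertuples()}
    for i in range(t.n_lines - len(gens)):
        gens[f"zero{i:02d}"] = t.mean_generations
    mito = sp.mito_rate(t3.rename(columns={"line": "line"}), gens, t.mito_length)

    scale = 1e-7  # table 1 rates are printed in units of 1e-7
    return {
        "tstv_pooled": sp.tstv_from_class_counts(class_counts),
        "substitutions_in_complex_fraction": t2["complex"].sum() / class_counts.sum(),
        "repeat_substitutions_at_ta_share": t2.loc["A/T->T/A", "repeat"]
        / t2["repeat"].sum(),
        "at_ta_repeat_associated_fraction": t2.loc["A/T->T/A", "repeat"]
        / t2.loc["A/T->T/A", "total"],
        "at_bias_normalized": bias["normalized"],
        "at_bias_raw": bias["raw"],
        "net_loss_1bp": -net_1bp,
        "net_loss_total_bp": -net_total,
        "net_loss_per_genome_bp": per_genome,
        "net_loss_per_genome_per_generation_bp": per_genome_per_gen,
        "deletion_1bp_fraction": t.n_deletions_1bp / t.n_deletions,
        "insertion_1bp_fraction": t.n_insertions_1bp / t.n_insertions,
        "deletion_insertion_ratio": t.n_deletions / t.n_insertions,
        "combined_nuclear_rate": (t1.loc["snp", "knockdown"]
                                  + t1.loc["indel", "knockdown"]) * scale,
        "snp_fold_change": t1.loc["snp", "knockdown"] / t1.loc["snp", "wildtype"],
        "indel_fold_change": t1.loc["indel", "knockdown"]
        / t1.loc["indel", "wildtype"],
        "deletion_fold_change": t1.loc["deletion", "knockdown"]
        / t1.loc["deletion", "wildtype"],
        "insertion_fold_change": t1.loc["insertion", "knockdown"]
        / t1.loc["insertion", "wildtype"],
        "mito_rate": mito.mean,
        "mito_rate_ci95": mito.ci95,
    }


def analysis_bundle(records: pd.DataFrame, reference, line_generations: dict,
                    genome_gc: float | None = None) -> dict:
    """Rates/spectrum report for a set of accepted mutation records."""
    genome = reference.genome
    B = genome.callable_bases()
    if genome_gc is None:
        genome_gc = genome.gc_fraction()
    snps = records["vtype"] == "snp"
    out: dict = {"n_records": int(len(records)), "B_callable": int(B)}
    if records.empty:
        out["note"] = "no mutations"
        return out

    def _table(mask, label):
        t = sp.line_mean_rate(records, line_generations, B, label, mask=mask)
        return {"mean": t.mean, "ci95": t.ci95, "n_lines": t.n}

    out["rates"] = {
        "snp": _table(snps, "snp"),
        "insertion": _table(records["vtype"] == "insertion", "insertion"),
        "deletion": _table(records["vtype"] == "deletion", "deletion"),
        "indel": _table(records["vtype"] != "snp", "indel"),
    }
    out["rates_by_class"] = {
        cls: _table(records["subst_class"] == cls, cls)
        for cls in records.loc[snps, "subst_class"].dropna().unique()
    }
    n_ts = int(records.loc[snps, "is_transition"].sum())
    n_tv = int(snps.sum()) - n_ts
    out["tstv_pooled"] = (n_ts / n_tv) if n_tv else None
    counts = records.loc[snps, "subst_class"].value_counts()
    if counts.sum() and 0 < genome_gc < 1:
        out["at_bias"] = sp.at_bias(counts, genome_gc)
    out["indels"] = {
        k: v for k, v in sp.indel_summary(records).items()
        if k not in ("size_histogram_del", "size_histogram_ins",
                     "per_line_counts")
    }
    hp = sp.homopolymer_indel_rates(records, reference.catalog, line_generations)
    if len(hp) and hp["n_events"].sum():
        out["homopolymer_peak_at"] = sp.homopolymer_rate_peak(hp, "AT")
    out["repeat_status_counts"] = (
        records.loc[snps, "repeat_status"].value_counts().to_dict()
    )
    return out


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj


def render_report(results: dict) -> str:
    """Deterministic machine-readable JSON for any results bundle."""
    return json.dumps(_jsonable(results), indent=1, sort_keys=True)
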