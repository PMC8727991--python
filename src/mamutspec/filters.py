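"""Candidate-call acceptance pipeline for MA lines.

Two stages mirror the study design:

1. Hard thresholds per call — minimum RMS mapping quality (30 for SNPs,
   40 for indels), minimum supporting reads (3 / 5), at least 80% of
   high-quality reads supporting the variant, concordance of at least two
   independent callers, and absence of the variant from the ancestral
   control (any ancestral support removes the call).

2. Cross-line binomial verification — at each candidate position the
   pooled supporting-read fraction across all sequenced lines,
   P = sum(K) / sum(N), estimates the probability that any single read
   calls the variant by chance. Each carrier line's evidence is scored by
   the binomial point mass C(N,K) P^K (1-P)^(N-K); a Holm-Bonferroni
   step-down over all candidate p-values then decides which variants show
   evidence inconsistent with shared noise. *Significant after correction
   means the variant is retained*: its read support cannot be explained by
   the cross-line error rate. The point mass is the statistic as the
   pipeline defines it; an upper-tail mode P(X >= K) is available and is
   flagged in outputs when used, since the point mass is not a
   conventional p-value.

Real MA data has fixed (homozygous) mutations private to one line, so a
true variant has K ~ N in its carrier and near-zero support elsewhere,
driving the point mass far below any Holm threshold, while a systematic
artifact shared across lines yields a large P and unremarkable per-line
evidence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

VARIANT_POSITION_KEY = ["chrom", "pos", "alt"]


@dataclass(frozen=True)
class FilterConfig:
    min_rms_mq_snp: float = 30.0
    min_rms_mq_indel: float = 40.0
    min_reads_snp: int = 3
    min_reads_indel: int = 5
    min_support_fraction: float = 0.80
    min_callers: int = 2
    alpha: float = 0.05
    #: use the upper-tail probability P(X >= K) instead of the point mass
    tail: bool = False

    def __post_init__(self):
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        for v in (self.min_rms_mq_snp, self.min_rms_mq_indel, self.min_reads_snp,
                  self.min_reads_indel, self.min_support_fraction, self.min_callers):
            if v < 0:
                raise ValueError("thresholds must be non-negative")


@dataclass(frozen=True)
class ErrorRateEstimate:
    """Pooled chance-call probability at one position: P = sum K / sum N."""

    P: float
    total_K: int
    total_N: int


def apply_hard_filters(
    calls: pd.DataFrame,
    ancestor_calls: pd.DataFrame | None,
    config: FilterConfig = FilterConfig(),
) -> tuple[pd.DataFrame, pd.Series]:
    """Apply the per-call threshold filters.

    Returns the surviving calls and a per-rule rejection log (counts). A
    call is rejected by the *first* failing rule in a fixed order so the
    log partitions the rejected set.
    """
    if calls.empty:
        return calls.copy(), pd.Series(dtype=int)
    c = calls.copy()
    is_indel = c["vtype"].isin(["insertion", "deletion"])
    reason = pd.Series("", index=c.index, dtype=object)

    no_cov = c["N"] <= 0
    reason[no_cov & (reason == "")] = "no coverage"

    mq_min = np.where(is_indel, config.min_rms_mq_indel, config.min_rms_mq_snp)
    reason[(c["mq"] < mq_min) & (reason == "")] = "min_rms_mq"

    k_min = np.where(is_indel, config.min_reads_indel, config.min_reads_snp)
    fail_reads = c["K"] < k_min
    reason[fail_reads & ~is_indel & (reason == "")] = "min_reads_snp"
    reason[fail_reads & is_indel & (reason == "")] = "min_reads_indel"

    with np.errstate(invalid="ignore", divide="ignore"):
        frac = c["K"] / c["N"]
    reason[(frac < config.min_support_fraction) & (reason == "")] = "support fraction"

    reason[(c["n_callers"] < config.min_callers) & (reason == "")] = "min_callers"

    if ancestor_calls is not None and not ancestor_calls.empty:
        anc = ancestor_calls.loc[
            ancestor_calls["K"] >= 1, VARIANT_POSITION_KEY
        ].drop_duplicates()
        in_anc = c.merge(anc, on=VARIANT_POSITION_KEY, how="left", indicator=True)
        flagged = (in_anc["_merge"] == "both").to_numpy()
        reason[flagged & (reason == "").to_numpy()] = "in ancestor"

    survivors = c[reason == ""]
    log = reason[reason != ""].value_counts()
    return survivors, log


def cross_line_error_rate(position_calls: pd.DataFrame) -> ErrorRateEstimate:
    """Pooled P at one position across *all* sequenced lines, carriers and
    non-carriers alike. Raises if no line has coverage."""
    total_K = int(position_calls["K"].sum())
    total_N = int(position_calls["N"].sum())
    if total_N == 0:
        raise ZeroDivisionError("no coverage at position across any line")
    return ErrorRateEstimate(total_K / total_N, total_K, total_N)


def binomial_point_probability(K, N, P, tail: bool = False):
    """Binomial mass C(N,K) P^K (1-P)^(N-K), computed in log space.

    With ``tail=True`` returns the upper tail P(X >= K) instead. Vectorized
    over K, N; stable for N up to at least 1e5.
    """
    K = np.asarray(K)
    N = np.asarray(N)
    P = np.asarray(P, dtype=float)
    if np.any((P < 0) | (P > 1)):
        raise ValueError("P must lie in [0, 1]")
    if np.any((K < 0) | (K > N)):
        raise ValueError("require 0 <= K <= N")
    if tail:
        out = stats.binom.sf(K - 1, N, P)
    else:
        out = np.exp(stats.binom.logpmf(K, N, P))
    return out if out.ndim else float(out)


def holm_bonferroni(pvalues, alpha: float = 0.05) -> np.ndarray:
    """Step-down Holm-Bonferroni retention vector (True = significant).

    Sorts ascending and compares p_(i) against alpha / (m - i + 1); ties
    keep their stable original order. Empty input gives an empty vector.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any(~np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be finite and in [0, 1]")
    reject, *_ = multipletests(p, alpha=alpha, method="holm")
    return reject


def consensus_filter(
    calls: pd.DataFrame,
    pileup: pd.DataFrame,
    config: FilterConfig = FilterConfig(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-line binomial verification of hard-filtered candidate calls.

    ``pileup`` holds per-line (K, N) read support at every candidate
    position, including non-carrier lines. Returns (accepted calls,
    quarantine) where quarantine collects candidates whose pooled error
    rate was undefined (no coverage anywhere) rather than silently
    dropping them. Accepted calls gain columns ``P``, ``p_value`` and
    ``p_value_is_tail``.
    """
    if calls.empty:
        empty = calls.copy()
        return empty, empty.copy()

    pooled = (
        pileup.groupby(VARIANT_POSITION_KEY, sort=False)[["K", "N"]]
        .sum()
        .reset_index()
        .rename(columns={"K": "sum_K", "N": "sum_N"})
    )
    merged = calls.merge(pooled, on=VARIANT_POSITION_KEY, how="left", validate="m:1")
    missing = merged["sum_N"].isna() | (merged["sum_N"] == 0)
    quarantine = calls[missing.to_numpy()].copy()
    ok = merged[~missing.to_numpy()].copy()
    if ok.empty:
        return ok, quarantine
    ok["P"] = ok["sum_K"] / ok["sum_N"]
    ok["p_value"] = binomial_point_probability(
        ok["K"].to_numpy(), ok["N"].to_numpy(), ok["P"].to_numpy(), tail=config.tail
    )
    ok["p_value_is_tail"] = config.tail
    keep = holm_bonferroni(ok["p_value"].to_numpy(), alpha=config.alpha)
    accepted = ok[keep].drop(columns=["sum_K", "sum_N"]).reset_index(drop=True)
    return accepted, quarantine


def filter_pipeline(
    calls: pd.DataFrame,
    pileup: pd.DataFrame,
    ancestor_calls: pd.DataFrame | None = None,
    config: FilterConfig = FilterConfig(),
):
    """Hard thresholds then cross-line consensus; returns
    (accepted, rejection_log, quarantine)."""
    survivors, log = apply_hard_filters(calls, ancestor_calls, config)
    accepted, quarantine = consensus_filter(survivors, pileup, config)
    if not quarantine.empty:
        log = log.add(pd.Series({"quarantined (undefined P)": len(quarantine)}),
                      fill_value=0).astype(int)
    return accepted, log, quarantine
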