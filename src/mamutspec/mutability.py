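"""Penalized logistic regression of site mutability on genomic features.

Mutated sites plus a large uniform sample of non-mutated callable sites
form the training set (class imbalance is deliberately preserved: the
fitted probabilities are meaningful in *relative* terms only). Predictors
are chromosome, functional class and collapsed trinucleotide context as
indicator blocks, numeric recombination rate, 41-bp G+C content and 41-bp
triplet complexity S, and binary germline-expression, repeat, chromatin
state and A/T-cluster features.

The fit is an elastic-net-penalized logistic regression with the glmnet
parameterization: per-observation mean log-loss plus
lambda * [(1-alpha)/2 ||c||^2 + alpha ||c||_1], with features standardized
internally and coefficients reported on the original scale. Odds ratios
are OR = e^c per predictor. Defaults lambda = 6.83e-5 and alpha = 0.01 are
configurable; lambda can be re-selected by k-fold cross-validated deviance.

Predicted mutabilities are binned (default width 0.015 over [0, 0.12],
eight bins) and a per-bin mutation rate SNP_b / (B_b * G) is regressed on
the bin midpoint to check that predicted mutability tracks realized rates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats
from sklearn.linear_model import LogisticRegression

from .repeats import window_stats_batch
from .spectrum import collapse_triplet


# ---------------------------------------------------------------------------
# Feature construction
# ---------------------------------------------------------------------------

def repeat_track(reference) -> dict[str, np.ndarray]:
    """Per-chromosome boolean track: site lies inside a cataloged repeat."""
    track = {n: np.zeros(reference.genome.length(n), dtype=bool)
             for n in reference.genome.names}
    for r in reference.catalog.runs:
        track[r.chrom][r.start : r.end] = True
    return track


def site_features(reference, chrom: str, positions: np.ndarray,
                  _track=None) -> pd.DataFrame:
    """Raw (unexpanded) predictor values for 0-based sites on one chromosome."""
    genome, layers = reference.genome, reference.layers
    positions = np.asarray(positions, dtype=int)
    track = _track if _track is not None else repeat_track(reference)
    S, gc = window_stats_batch(genome, chrom, positions)
    seq = genome.seqs[chrom]
    context = [
        collapse_triplet(seq[p - 1 : p + 2]) if 1 <= p <= len(seq) - 2 else "NA"
        for p in positions
    ]
    from .genome import DOMAIN_NAMES, FUNCTIONAL_NAMES

    return pd.DataFrame({
        "chromosome": chrom,
        "functional": np.array(FUNCTIONAL_NAMES)[layers.functional[chrom][positions]],
        "context": context,
        "recombination": layers.recomb[chrom][positions].astype(float),
        "gc41": gc,
        "complexity41": S,
        "germline": layers.germline[chrom][positions].astype(float),
        "repeat": track[chrom][positions].astype(float),
        "chromatin": np.array(layers.chromatin_states)[layers.chromatin[chrom][positions]],
        "at_cluster": layers.at_cluster[chrom][positions].astype(float),
        "domain": np.array(DOMAIN_NAMES)[layers.domain[chrom][positions]],
    })


_CATEGORICAL = ("chromosome", "functional", "context", "chromatin")
_NUMERIC = ("recombination", "gc41", "complexity41", "germline", "repeat",
            "at_cluster")


def expand_features(raw: pd.DataFrame) -> pd.DataFrame:
    """Indicator-expand categoricals; drop constant columns and rows with
    unavailable numerics."""
    x = pd.get_dummies(
        raw[list(_CATEGORICAL)], columns=list(_CATEGORICAL), dtype=float
    )
    x = pd.concat([x, raw[list(_NUMERIC)].astype(float)], axis=1)
    keep = [c for c in x.columns if x[c].nunique() > 1]
    return x[keep]


def build_training_set(
    reference,
    mutations: pd.DataFrame,
    n_random: int = 100_000,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Mutated sites (response 1) plus uniform random non-mutated callable
    sites (response 0), with features computed identically for both strata.
    Rows whose 41-bp window statistics are unavailable are dropped."""
    genome = reference.genome
    rng = np.random.default_rng([seed, 7])
    track = repeat_track(reference)
    mut_keys = set(zip(mutations["chrom"], mutations["pos"] - 1))

    nuclear = genome.nuclear_names
    lens = np.array([genome.length(c) for c in nuclear], dtype=float)
    per_chrom_mut = {
        c: np.array(sorted({p for ch, p in mut_keys if ch == c}), dtype=int)
        for c in nuclear
    }
    per_chrom_rand: dict[str, list[int]] = {c: [] for c in nuclear}
    n_drawn = 0
    while n_drawn < n_random:
        k = n_random - n_drawn
        ci = rng.choice(len(nuclear), size=k, p=lens / lens.sum())
        for i, c in enumerate(nuclear):
            pos = rng.integers(0, int(lens[i]), size=int((ci == i).sum()))
            pos = pos[genome.callable_mask[c][pos]]
            pos = [int(p) for p in pos if (c, p) not in mut_keys]
            per_chrom_rand[c].extend(pos)
            n_drawn += len(pos)
    frames, ys = [], []
    for c in nuclear:
        for positions, label in ((per_chrom_mut[c], 1),
                                 (np.array(per_chrom_rand[c], dtype=int), 0)):
            if len(positions) == 0:
                continue
            frames.append(site_features(reference, c, positions, _track=track))
            ys.append(np.full(len(positions), label))
    raw = pd.concat(frames, ignore_index=True)
    y = np.concatenate(ys)
    ok = raw[["gc41", "complexity41"]].notna().all(axis=1).to_numpy()
    return expand_features(raw[ok].reset_index(drop=True)), y[ok]


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

@dataclass
class MutabilityModel:
    feature_names: list[str]
    coef: pd.Series          # original-scale coefficients
    intercept: float
    lam: float
    alpha: float
    n_mutated: int
    n_random: int

    def odds_ratios(self) -> pd.DataFrame:
        """OR = e^c per predictor, sorted by |log OR| (strongest first)."""
        df = pd.DataFrame({"coef": self.coef, "OR": np.exp(self.coef)})
        return df.reindex(df["coef"].abs().sort_values(ascending=False).index)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Per-site mutation probability (relative mutability)."""
        x = X.reindex(columns=self.feature_names, fill_value=0.0).to_numpy(float)
        z = x @ self.coef.to_numpy() + self.intercept
        return 1.0 / (1.0 + np.exp(-z))

    def to_json(self, path) -> None:
        payload = {
            "feature_names": self.feature_names,
            "coef": self.coef.to_dict(),
            "intercept": self.intercept,
            "lambda": self.lam,
            "alpha": self.alpha,
            "n_mutated": self.n_mutated,
            "n_random": self.n_random,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "MutabilityModel":
        with open(path) as fh:
            d = json.load(fh)
        coef = pd.Series(d["coef"]).reindex(d["feature_names"])
        return cls(d["feature_names"], coef, d["intercept"], d["lambda"],
                   d["alpha"], d["n_mutated"], d["n_random"])


def fit_penalized_logistic(
    X: pd.DataFrame,
    y: np.ndarray,
    lam: float = 6.83e-5,
    alpha: float = 0.01,
    seed: int = 0,
    max_iter: int = 500,
) -> MutabilityModel:
    """Elastic-net logistic fit (glmnet parameterization, see module doc).

    ``lam = 0`` removes the penalty entirely. Separation cannot blow up
    coefficients as long as lam > 0 (the penalty keeps them finite).
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training set needs both classes")
    x = X.to_numpy(dtype=float)
    mean = x.mean(axis=0)
    std = x.std(axis=0)
    std[std == 0] = 1.0
    xs = (x - mean) / std
    n = len(y)
    if lam > 0:
        clf = LogisticRegression(
            solver="saga", l1_ratio=alpha, C=1.0 / (lam * n),
            max_iter=max_iter, tol=1e-4, random_state=seed,
        )
    else:
        clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=max_iter,
                                 tol=1e-8)
    clf.fit(xs, y)
    c_std = clf.coef_[0]
    coef = pd.Series(c_std / std, index=list(X.columns))
    intercept = float(clf.intercept_[0] - np.sum(c_std * mean / std))
    return MutabilityModel(
        feature_names=list(X.columns), coef=coef, intercept=intercept,
        lam=lam, alpha=alpha, n_mutated=int(y.sum()), n_random=int((y == 0).sum()),
    )


def select_lambda_cv(
    X: pd.DataFrame,
    y: np.ndarray,
    lambdas=None,
    alpha: float = 0.01,
    k: int = 10,
    seed: int = 0,
) -> tuple[float, pd.DataFrame]:
    """lambda.min: the grid value minimizing k-fold cross-validated deviance."""
    from sklearn.metrics import log_loss
    from sklearn.model_selection import StratifiedKFold

    if lambdas is None:
        lambdas = np.logspace(-6, -1, 8)
    folds = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    records = []
    for lam in lambdas:
        losses = []
        for tr, te in folds.split(X, y):
            model = fit_penalized_logistic(X.iloc[tr], y[tr], lam=lam,
                                           alpha=alpha, seed=seed)
            losses.append(log_loss(y[te], model.predict(X.iloc[te]), labels=[0, 1]))
        records.append({"lambda": float(lam), "cv_deviance": 2 * float(np.mean(losses))})
    table = pd.DataFrame(records)
    return float(table.loc[table["cv_deviance"].idxmin(), "lambda"]), table


def null_deviance(y: np.ndarray) -> float:
    p = y.mean()
    return float(-2 * np.sum(y * np.log(p) + (1 - y) * np.log1p(-p)))


def model_deviance(model: MutabilityModel, X: pd.DataFrame, y: np.ndarray) -> float:
    p = np.clip(model.predict(X), 1e-12, 1 - 1e-12)
    return float(-2 * np.sum(y * np.log(p) + (1 - y) * np.log1p(-p)))


def variance_explained(model: MutabilityModel, X: pd.DataFrame,
                       y: np.ndarray) -> float:
    """Deviance-based pseudo-R^2: 1 - D_model / D_null."""
    return 1.0 - model_deviance(model, X, y) / null_deviance(y)


# ---------------------------------------------------------------------------
# Mutability binning
# ---------------------------------------------------------------------------

@dataclass
class BinRateResult:
    table: pd.DataFrame
    slope: float
    intercept: float
    r: float
    r_squared: float
    p: float


def bin_rates(
    site_probs: np.ndarray,
    mutation_probs: np.ndarray,
    bin_width: float = 0.015,
    prob_range: tuple[float, float] = (0.0, 0.12),
    G: float = 40.3,
    weight_by_sites: bool = True,
) -> BinRateResult:
    """Bin genome-site predictions, count mutations per bin, and regress
    the per-bin rate SNP_b / (B_b * G) on the bin midpoint.

    Sites and mutations predicted above the range are excluded (the range
    is chosen to cover essentially all of both); empty bins are excluded
    from the regression. By default each bin is weighted by its site count
    B_b: bin occupancies span orders of magnitude, and under Poisson
    mutation counts the variance of a bin's rate estimate scales as 1/B_b,
    so on small (simulated) genomes an unweighted fit would be dominated
    by the noisiest, near-empty bins. Set ``weight_by_sites=False`` for
    the plain unweighted regression; at genome scale, where every bin
    holds a large number of sites, the two agree.
    """
    lo, hi = prob_range
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    site_probs = np.asarray(site_probs)
    mutation_probs = np.asarray(mutation_probs)
    B, _ = np.histogram(site_probs, bins=edges)
    SNP, _ = np.histogram(mutation_probs, bins=edges)
    mid = (edges[:-1] + edges[1:]) / 2
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = SNP / (B * G)
    table = pd.DataFrame({
        "bin_low": edges[:-1], "bin_high": edges[1:], "midpoint": mid,
        "SNP_b": SNP, "B": B, "rate": rate,
    })
    ok = B > 0
    if ok.sum() < 2:
        nan = float("nan")
        return BinRateResult(table, nan, nan, nan, nan, nan)
    x, y_, w = mid[ok], rate[ok], B[ok].astype(float)
    if not weight_by_sites:
        w = np.ones_like(w)
    wsum = w.sum()
    mx, my = np.average(x, weights=w), np.average(y_, weights=w)
    cov = np.average((x - mx) * (y_ - my), weights=w)
    vx = np.average((x - mx) ** 2, weights=w)
    vy = np.average((y_ - my) ** 2, weights=w)
    slope = cov / vx
    r = cov / np.sqrt(vx * vy) if vx > 0 and vy > 0 else float("nan")
    # two-sided t-test on the weighted correlation, df = n_bins - 2
    df = int(ok.sum()) - 2
    if df > 0 and abs(r) < 1:
        t = r * np.sqrt(df / (1 - r**2))
        p = float(2 * sstats.t.sf(abs(t), df))
    else:
        p = float("nan")
    return BinRateResult(table, float(slope), float(my - slope * mx),
                         float(r), float(r**2), p)
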