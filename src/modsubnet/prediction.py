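"""Age prediction from subnetwork or gene features with support vector regression.

Features are per-sample activities: the mean normalized expression of a
subnetwork's member genes, or a single gene's expression row. An
epsilon-insensitive SVR with a linear kernel and conventional defaults
(C = 1, epsilon = 0.1) maps feature activities to chronological age.

Performance is reported as mean squared error (MSE, age^2 units) and the
squared Pearson correlation between true and predicted ages (SCC). SCC is
offset-invariant, which matters when training and test cohorts have different
lifespans; MSE is not, which is why both are reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.feature_selection import f_classif
from sklearn.svm import SVR
from statsmodels.stats.multitest import multipletests

from .io import ExpressionDataset
from .scoring import Subnetwork, weight_network
from .search import GrowthEngine, remove_redundant
from .significance import select_significant, significance_table

__all__ = [
    "FeatureMatrix",
    "RegressionEval",
    "build_features",
    "fit_predict_svr",
    "evaluate",
    "sampling_experiment",
    "stratified_folds",
    "cv_discover_and_predict",
    "select_top_genes_ftest",
    "compare_medians",
]

SVR_C = 1.0
SVR_EPSILON = 0.1


@dataclass
class FeatureMatrix:
    """Sample x feature activity matrix with per-sample ages."""

    values: pd.DataFrame  # samples x features
    ages: pd.Series

    def __post_init__(self) -> None:
        if self.values.shape[1] < 1:
            raise ValueError("at least one feature is required")
        if self.values.isna().to_numpy().any():
            raise ValueError("feature matrix contains missing values")
        if len(self.ages) != self.values.shape[0]:
            raise ValueError("ages length must match sample count")

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class RegressionEval:
    """MSE and squared correlation coefficient of an age-prediction run."""

    mse: float
    scc: float

    def __post_init__(self) -> None:
        if self.mse < 0 or not (0.0 <= self.scc <= 1.0 + 1e-12):
            raise ValueError("invalid evaluation metrics")


def _feature_column(feat, d: ExpressionDataset) -> tuple[str, np.ndarray]:
    if isinstance(feat, Subnetwork):
        members = list(feat.members)
        name = feat.seed
    elif isinstance(feat, str):
        members, name = [feat], feat
    else:  # explicit member collection
        members = sorted(feat)
        name = "+".join(members)
    unknown = [m for m in members if m not in d.values.index]
    if unknown:
        raise ValueError(f"feature genes absent from dataset: {unknown[:5]}")
    return name, d.values.loc[members].to_numpy(dtype=float).mean(axis=0)


def build_features(subs_or_genes, d: ExpressionDataset) -> FeatureMatrix:
    """One column per subnetwork (mean member expression) or per gene id."""
    feats = list(subs_or_genes)
    if not feats:
        raise ValueError("empty feature list")
    cols, names = [], []
    for i, feat in enumerate(feats):
        name, col = _feature_column(feat, d)
        names.append(f"{name}#{i}" if name in names else name)
        cols.append(col)
    values = pd.DataFrame(np.column_stack(cols), index=d.samples, columns=names)
    return FeatureMatrix(values, d.ages.copy())


def fit_predict_svr(train: FeatureMatrix, test: FeatureMatrix) -> np.ndarray:
    """Train a linear-kernel epsilon-SVR on *train* and predict ages for *test*."""
    if train.feature_names != test.feature_names:
        raise ValueError("train and test feature names/order must match")
    if train.values.shape[0] < 2:
        raise ValueError("need at least 2 training samples")
    X = train.values.to_numpy(dtype=float)
    y = train.ages.to_numpy(dtype=float)
    Xt = test.values.to_numpy(dtype=float)
    if not (np.isfinite(X).all() and np.isfinite(y).all() and np.isfinite(Xt).all()):
        raise ValueError("non-finite values in features or ages")
    model = SVR(kernel="linear", C=SVR_C, epsilon=SVR_EPSILON)
    model.fit(X, y)
    return model.predict(Xt)


def evaluate(true_ages, predicted_ages) -> RegressionEval:
    """MSE and squared Pearson correlation between true and predicted ages."""
    t = np.asarray(true_ages, dtype=float)
    p = np.asarray(predicted_ages, dtype=float)
    if t.shape != p.shape or t.ndim != 1 or t.size < 3:
        raise ValueError("need equal-length 1-D vectors with >= 3 entries")
    if np.ptp(t) == 0:
        raise ValueError("true ages are constant")
    mse = float(np.mean((t - p) ** 2))
    if np.ptp(p) == 0:
        warnings.warn("constant predictions; SCC set to 0")
        return RegressionEval(mse=mse, scc=0.0)
    r = np.corrcoef(t, p)[0, 1]
    return RegressionEval(mse=mse, scc=float(min(r * r, 1.0)))


def _bootstrap_ci_median(
    x: np.ndarray, rng: np.random.Generator, n_boot: int = 2000, level: float = 0.95
) -> tuple[float, float]:
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    meds = np.median(x[idx], axis=1)
    lo, hi = np.quantile(meds, [(1 - level) / 2, 1 - (1 - level) / 2])
    return float(lo), float(hi)


def sampling_experiment(
    features,
    d_train: ExpressionDataset,
    d_test: ExpressionDataset,
    k: int,
    n_draws: int = 1000,
    rng_seed: int = 0,
    n_boot: int = 2000,
) -> dict:
    """Repeatedly draw k features, train on one study, test on the other.

    Returns per-draw MSE/SCC arrays plus a summary with the median of each
    metric and its percentile-bootstrap 95% confidence interval.
    """
    features = list(features)
    if k > len(features):
        raise ValueError(f"k={k} exceeds feature pool of {len(features)}")
    rng = np.random.default_rng(rng_seed)
    mses = np.empty(n_draws)
    sccs = np.empty(n_draws)
    for i in range(n_draws):
        # canonical (sorted) subset order: the same subset always yields the
        # same feature matrix regardless of draw order
        chosen = [features[j] for j in sorted(rng.choice(len(features), size=k, replace=False))]
        tr = build_features(chosen, d_train)
        te = build_features(chosen, d_test)
        ev = evaluate(te.ages.to_numpy(), fit_predict_svr(tr, te))
        mses[i], sccs[i] = ev.mse, ev.scc
    summary = {}
    for name, arr in (("mse", mses), ("scc", sccs)):
        lo, hi = _bootstrap_ci_median(arr, rng, n_boot=n_boot)
        summary[name] = {"median": float(np.median(arr)), "ci_low": lo, "ci_high": hi}
    return {"k": k, "n_draws": n_draws, "mse": mses, "scc": sccs, "summary": summary}


def stratified_folds(
    d: ExpressionDataset, n_folds: int = 5, rng_seed: int = 0
) -> np.ndarray:
    """Age-stratified fold assignment (one integer in [0, n_folds) per sample).

    Each age group is shuffled and dealt round-robin, starting from a rotating
    fold, so per-fold counts within every age group differ by at most one.
    """
    ages = d.ages.to_numpy()
    rng = np.random.default_rng(rng_seed)
    folds = np.full(d.n_samples, -1, dtype=int)
    offset = 0
    for age in np.unique(ages):
        idx = np.flatnonzero(ages == age)
        if idx.size < n_folds:
            warnings.warn(
                f"age group {age} has {idx.size} samples < {n_folds} folds; "
                "folds will be only near-balanced"
            )
        idx = rng.permutation(idx)
        folds[idx] = (np.arange(idx.size) + offset) % n_folds
        offset += idx.size
    return folds


def select_top_genes_ftest(d_train: ExpressionDataset, n_top: int = 100) -> list[str]:
    """Top differentially expressed genes by one-way F-test across age groups.

    Genes are ranked by Benjamini-Hochberg adjusted p, then raw p, then gene
    id; constant genes (undefined F) rank last.
    """
    ages = d_train.ages.to_numpy()
    if np.unique(ages).size < 2:
        raise ValueError("need at least 2 age groups")
    X = d_train.values.to_numpy(dtype=float).T  # samples x genes
    with np.errstate(divide="ignore", invalid="ignore"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, pvals = f_classif(X, ages)
    pvals = np.where(np.isfinite(pvals), pvals, 1.0)
    qvals = multipletests(pvals, method="fdr_bh")[1]
    order = sorted(
        range(d_train.n_genes), key=lambda i: (qvals[i], pvals[i], d_train.genes[i])
    )
    if n_top > d_train.n_genes:
        warnings.warn(f"n_top={n_top} exceeds gene count; returning all genes")
        n_top = d_train.n_genes
    return [d_train.genes[i] for i in order[:n_top]]


def compare_medians(runs_a, runs_b) -> float:
    """Two-sided Wilcoxon rank-sum p-value comparing two metric samples.

    Exact null distribution for small untied samples (both sizes <= 20);
    normal approximation with tie correction otherwise.
    """
    a = np.asarray(runs_a, dtype=float)
    b = np.asarray(runs_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need >= 2 values")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (no_ties and max(a.size, b.size) <= 20) else "asymptotic"
    return float(
        stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
    )


def cv_discover_and_predict(
    g,
    d: ExpressionDataset,
    mode: str = "modular",
    beta: float = 250.0,
    r_threshold: float = 0.05,
    k: int = 25,
    n_folds: int = 5,
    rng_seed: int = 0,
    n_perm: int = 0,
    n_interactomes: int = 0,
    self_alpha: float = 0.001,
    comp_alpha: float = 0.05,
    max_overlap: float = 0.25,
    discover_on: str = "train",
) -> list[dict]:
    """Cross-validated age prediction with per-fold feature discovery.

    For each fold the network is re-weighted, subnetworks grown, optionally
    filtered by the two significance tests (``n_perm``/``n_interactomes`` > 0),
    reduced to a non-redundant set, and the top-``k`` by score (minimum size 2)
    used as SVR features; everything is computed on training samples only and
    evaluated on the held-out fold.

    ``discover_on="all"`` deliberately discovers features on the full dataset
    (including test samples) — a leakage probe whose optimistic results
    demonstrate why per-fold discovery is required.
    """
    if discover_on not in ("train", "all"):
        raise ValueError("discover_on must be 'train' or 'all'")
    folds = stratified_folds(d, n_folds=n_folds, rng_seed=rng_seed)
    samples = np.asarray(d.samples)

    def discover(d_fit):
        gw = weight_network(g, d_fit)
        if n_perm > 0 and n_interactomes > 0:
            table, subs = significance_table(
                gw,
                d_fit,
                mode=mode,
                beta=beta,
                r_threshold=r_threshold,
                n_perm=n_perm,
                n_interactomes=n_interactomes,
                rng_seed=rng_seed,
                self_alpha=self_alpha,
                comp_alpha=comp_alpha,
            )
            return select_significant(
                table, subs, self_alpha, comp_alpha, max_overlap
            )
        subs = GrowthEngine(gw, d_fit).grow_all(
            mode=mode, beta=beta, r_threshold=r_threshold
        )
        return remove_redundant(
            [s for s in subs if s.size >= 2], max_overlap=max_overlap
        )

    shared = discover(d) if discover_on == "all" else None
    results = []
    for fold in range(n_folds):
        test_mask = folds == fold
        d_tr = d.subset_samples(samples[~test_mask])
        feats = shared if shared is not None else discover(d_tr)
        feats = feats[:k]
        if not feats:
            warnings.warn(f"fold {fold}: no candidate subnetworks; skipped")
            continue
        # activity is a per-sample quantity, so slicing the full feature matrix
        # by fold introduces no cross-sample leakage
        full = build_features(feats, d)
        tr = FeatureMatrix(full.values.loc[~test_mask], full.ages.loc[~test_mask])
        te = FeatureMatrix(full.values.loc[test_mask], full.ages.loc[test_mask])
        pred = fit_predict_svr(tr, te)
        truth = te.ages.to_numpy()
        if truth.size >= 3 and np.ptp(truth) > 0:
            ev = evaluate(truth, pred)
        else:  # degenerate fold (e.g. leave-one-out): keep predictions only
            ev = None
        results.append(
            {
                "fold": fold,
                "n_features": len(feats),
                "feature_seeds": tuple(f.seed for f in feats),
                "predicted": pred,
                "true_ages": truth,
                "eval": ev,
            }
        )
    return results
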