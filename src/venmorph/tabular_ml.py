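"""Consensus variable importance, misclassification census and group stats.

Two resampling procedures form the core of the tabular analysis:

**Bootstrap consensus importance** — classifiers in this domain handle only
a limited number of predictors at once, so importance is assessed on random
feature subsets: each repetition draws ``subset_size`` features uniformly
without replacement, fits every classifier adapter, and ranks the subset by
permutation importance measured on held-out rows.  Aggregation reports, per
feature, how often it took first place among runs that included it, its
median rank and rank variance — overall and per adapter.

**Balanced subsample census** — with 706 pyramidal cells to 55 VENs the
classes are heavily imbalanced, so classifiers are repeatedly retrained on
balanced draws of ``n_per_class`` cells per class and evaluated on every
cell left out of that draw.  The census accumulates, per cell and adapter,
the fraction of evaluations that misclassified it; a cell counts as
misclassified by an adapter when that fraction exceeds 0.5, and the number
of adapters misclassifying each cell identifies the consistently
problematic reconstructions.

Group comparison uses Mann–Whitney U (smaller-U convention) with Bonferroni
correction and Cohen's d; classification metrics (accuracy, precision,
recall, F1, ROC-AUC with VEN as the positive class) are shared with the CNN
stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .morphometry import LABEL_COLUMN

__all__ = [
    "ClassifierAdapter",
    "default_adapters",
    "ImportanceRanking",
    "bootstrap_importance",
    "rank_correlation_between_adapters",
    "subsample_census",
    "misclassified_by_at_least",
    "compare_groups",
    "classification_metrics",
    "POSITIVE_LABEL",
]

POSITIVE_LABEL = "VEN"


@dataclass
class ClassifierAdapter:
    """Uniform fit/predict/score wrapper around an estimator factory.

    ``factory(seed)`` must return an unfitted scikit-learn-compatible
    estimator; adapters are deterministic under a provided seed.
    """

    name: str
    factory: object  # callable(seed) -> estimator
    _model: object = field(default=None, repr=False)

    def fit(self, X: np.ndarray, y: np.ndarray, seed: int = 0):
        self._model = self.factory(seed)
        self._model.fit(X, y)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self._model.predict(X)

    def predict_score(self, X: np.ndarray) -> np.ndarray:
        """Continuous score for the positive class (for ROC curves)."""
        m = self._model
        if hasattr(m, "predict_proba"):
            proba = m.predict_proba(X)
            return proba[:, list(m.classes_).index(1)]
        return m.decision_function(X)

    def permutation_importance(
        self, X: np.ndarray, y: np.ndarray, rng: np.random.Generator
    ) -> np.ndarray:
        """Accuracy drop when each feature column is shuffled (one pass)."""
        base = float(np.mean(self.predict(X) == y))
        scores = np.empty(X.shape[1])
        for j in range(X.shape[1]):
            Xp = X.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            scores[j] = base - float(np.mean(self.predict(Xp) == y))
        return scores


def default_adapters(fast: bool = False) -> list[ClassifierAdapter]:
    """The stock adapter set: random forest, gradient boosting, XGBoost,
    SVM and a CART-style decision tree (C5.0 stand-in).

    ``fast=True`` shrinks the ensembles for resampling-heavy procedures.
    """
    n_trees = 30 if fast else 100

    def rf(seed):
        return RandomForestClassifier(n_estimators=n_trees, random_state=seed)

    def gb(seed):
        return GradientBoostingClassifier(
            n_estimators=n_trees, random_state=seed
        )

    def xgb(seed):
        from xgboost import XGBClassifier

        return XGBClassifier(
            n_estimators=n_trees,
            random_state=seed,
            verbosity=0,
            eval_metric="logloss",
            n_jobs=1,
        )

    def svm(seed):
        # scores come from decision_function; no probability calibration
        return SVC(kernel="rbf", random_state=seed)

    def tree(seed):
        return DecisionTreeClassifier(random_state=seed)

    return [
        ClassifierAdapter("random_forest", rf),
        ClassifierAdapter("gradient_boosting", gb),
        ClassifierAdapter("xgboost", xgb),
        ClassifierAdapter("svm", svm),
        ClassifierAdapter("decision_tree", tree),
    ]


def _split_table(table: pd.DataFrame):
    feats = [c for c in table.columns if c != LABEL_COLUMN]
    X = table[feats].to_numpy(dtype=float)
    # undefined metrics (flagged as NaN upstream) are median-imputed so that
    # every adapter — including SVM — accepts the matrix
    if np.isnan(X).any():
        med = np.nanmedian(X, axis=0)
        rows, cols = np.nonzero(np.isnan(X))
        X[rows, cols] = med[cols]
    y = (table[LABEL_COLUMN] == POSITIVE_LABEL).to_numpy(dtype=int)
    return feats, X, y


def _ranks_desc(scores: np.ndarray) -> np.ndarray:
    """Rank 1 = highest score; ties get the average rank."""
    return stats.rankdata(-scores, method="average")


# ---------------------------------------------------------------------------
# bootstrap consensus importance


@dataclass
class ImportanceRanking:
    """Aggregated output of the bootstrap importance procedure.

    ``summary`` has one row per feature: inclusion count, first-position
    frequency (ties share 1/t each), median rank and rank variance,
    aggregated over all adapters.  ``per_adapter`` holds the same summary
    computed separately for each adapter.
    """

    summary: pd.DataFrame
    per_adapter: dict[str, pd.DataFrame]
    n_reps: int
    subset_size: int

    def consensus_order(self, by: str = "first_position_frequency") -> list[str]:
        asc = by in ("median_rank",)
        return list(self.summary.sort_values(by, ascending=asc).index)


def bootstrap_importance(
    table: pd.DataFrame,
    adapters: list[ClassifierAdapter],
    subset_size: int = 10,
    n_reps: int = 5000,
    seed: int = 0,
    holdout_fraction: float = 0.3,
) -> ImportanceRanking:
    """Consensus variable importance over random feature subsets.

    Per repetition: draw ``subset_size`` features without replacement, split
    rows into fit/holdout, fit each adapter and rank the subset by
    permutation importance on the holdout rows (rank 1 = most important,
    ties share first place as 1/t).
    """
    feats, X, y = _split_table(table)
    m = len(feats)
    if subset_size > m:
        raise ValueError(f"subset_size {subset_size} exceeds feature count {m}")
    if len(np.unique(y)) < 2:
        raise ValueError("both class labels required")

    rng = np.random.default_rng(seed)
    stats_all = {
        f: {"included": 0, "first": 0.0, "ranks": []} for f in feats
    }
    stats_ad = {
        a.name: {f: {"included": 0, "first": 0.0, "ranks": []} for f in feats}
        for a in adapters
    }

    n = len(y)
    n_hold = max(2, int(round(holdout_fraction * n)))
    for rep in range(n_reps):
        subset = rng.choice(m, size=subset_size, replace=False)
        sub_feats = [feats[j] for j in subset]
        # stratified-ish split: reshuffle until the fit rows hold both labels
        order = rng.permutation(n)
        hold, fit = order[:n_hold], order[n_hold:]
        if len(np.unique(y[fit])) < 2 or len(np.unique(y[hold])) < 2:
            continue
        Xs = X[:, subset]
        rep_seed = int(rng.integers(2**31))
        for adapter in adapters:
            adapter.fit(Xs[fit], y[fit], seed=rep_seed)
            imp = adapter.permutation_importance(Xs[hold], y[hold], rng)
            ranks = _ranks_desc(imp)
            top = ranks.min()
            n_top = int(np.sum(ranks == top))
            for f, r in zip(sub_feats, ranks):
                for bucket in (stats_all[f], stats_ad[adapter.name][f]):
                    bucket["included"] += 1
                    bucket["ranks"].append(r)
                    if r == top:
                        bucket["first"] += 1.0 / n_top

    def summarize(buckets) -> pd.DataFrame:
        rows = {}
        for f, b in buckets.items():
            ranks = np.array(b["ranks"], dtype=float)
            rows[f] = {
                "n_included": b["included"],
                "first_position_frequency": (
                    b["first"] / b["included"] if b["included"] else np.nan
                ),
                "median_rank": float(np.median(ranks)) if len(ranks) else np.nan,
                "rank_variance": (
                    float(np.var(ranks, ddof=1)) if len(ranks) > 1 else np.nan
                ),
            }
        df = pd.DataFrame.from_dict(rows, orient="index")
        df.index.name = "feature"
        return df.loc[[f for f in feats]]

    return ImportanceRanking(
        summary=summarize(stats_all),
        per_adapter={name: summarize(b) for name, b in stats_ad.items()},
        n_reps=n_reps,
        subset_size=subset_size,
    )


def rank_correlation_between_adapters(
    per_adapter: dict[str, pd.DataFrame],
) -> tuple[pd.DataFrame, float, float]:
    """Pairwise Spearman correlation of per-adapter median-rank vectors.

    Returns (correlation matrix, mean, SD) over adapter pairs — the
    inter-algorithm consistency summary.
    """
    names = list(per_adapter)
    if len(names) < 2:
        raise ValueError("need at least 2 adapters")
    vectors = {n: per_adapter[n]["median_rank"].to_numpy() for n in names}
    mat = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    offdiag = []
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            b = names[j]
            rho = stats.spearmanr(vectors[a], vectors[b]).statistic
            mat.loc[a, b] = mat.loc[b, a] = rho
            offdiag.append(rho)
    offdiag = np.array(offdiag)
    return mat, float(offdiag.mean()), float(offdiag.std(ddof=1) if len(offdiag) > 1 else 0.0)


# ---------------------------------------------------------------------------
# balanced subsample census


def subsample_census(
    table: pd.DataFrame,
    adapters: list[ClassifierAdapter],
    n_per_class: int = 50,
    n_reps: int = 5000,
    seed: int = 0,
    misclassification_threshold: float = 0.5,
) -> pd.DataFrame:
    """Repeated balanced-subsample misclassification census.

    Per repetition, ``n_per_class`` cells per class train every adapter;
    each adapter then predicts every cell *outside* that training draw.
    The returned frame has one row per cell: per-adapter evaluation count
    and misclassification fraction, plus ``n_classifiers_misclassifying``
    (adapters whose fraction exceeds the threshold).
    """
    if len(adapters) < 2:
        raise ValueError("census requires at least 2 adapters")
    feats, X, y = _split_table(table)
    cells = np.array(table.index)
    idx_pos = np.flatnonzero(y == 1)
    idx_neg = np.flatnonzero(y == 0)
    for name, idx in (("positive", idx_pos), ("negative", idx_neg)):
        if len(idx) < n_per_class:
            raise ValueError(
                f"{name} class has {len(idx)} cells < n_per_class={n_per_class}"
            )

    rng = np.random.default_rng(seed)
    n = len(y)
    n_eval = {a.name: np.zeros(n, dtype=int) for a in adapters}
    n_mis = {a.name: np.zeros(n, dtype=int) for a in adapters}

    for rep in range(n_reps):
        train = np.concatenate([
            rng.choice(idx_pos, size=n_per_class, replace=False),
            rng.choice(idx_neg, size=n_per_class, replace=False),
        ])
        mask = np.ones(n, dtype=bool)
        mask[train] = False
        if not mask.any():
            continue
        rep_seed = int(rng.integers(2**31))
        for adapter in adapters:
            adapter.fit(X[train], y[train], seed=rep_seed)
            pred = adapter.predict(X[mask])
            n_eval[adapter.name][mask] += 1
            wrong = pred != y[mask]
            n_mis[adapter.name][np.flatnonzero(mask)[wrong]] += 1

    data = {}
    for a in adapters:
        with np.errstate(invalid="ignore"):
            frac = np.where(
                n_eval[a.name] > 0, n_mis[a.name] / np.maximum(n_eval[a.name], 1),
                np.nan,
            )
        data[f"{a.name}__n_evaluations"] = n_eval[a.name]
        data[f"{a.name}__n_misclassified"] = n_mis[a.name]
        data[f"{a.name}__fraction"] = frac
    df = pd.DataFrame(data, index=pd.Index(cells, name="cell_id"))
    frac_cols = [f"{a.name}__fraction" for a in adapters]
    df["n_classifiers_misclassifying"] = (
        (df[frac_cols] > misclassification_threshold).sum(axis=1).astype(int)
    )
    df[LABEL_COLUMN] = table[LABEL_COLUMN].to_numpy()
    return df


def misclassified_by_at_least(census: pd.DataFrame, k: int) -> list[str]:
    """Cells misclassified by at least ``k`` adapters (the census lists)."""
    sel = census[census["n_classifiers_misclassifying"] >= k]
    return list(
        sel.sort_values("n_classifiers_misclassifying", ascending=False).index
    )


# ---------------------------------------------------------------------------
# group comparison and metrics


def compare_groups(
    table: pd.DataFrame,
    group_mask,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-feature Mann–Whitney U with Bonferroni correction and Cohen's d.

    ``group_mask`` is a boolean vector selecting group 1; U is reported in
    the smaller-U convention (min(U1, U2)); p_adj = min(1, m·p) with m the
    number of features tested; d = (mean1 − mean2) / pooled SD.
    """
    group_mask = np.asarray(group_mask, dtype=bool)
    if group_mask.all() or not group_mask.any():
        raise ValueError("both groups must be non-empty")
    feats = [c for c in table.columns if c != LABEL_COLUMN]
    m = len(feats)
    rows = {}
    for f in feats:
        vals = table[f].to_numpy(dtype=float)
        a, b = vals[group_mask], vals[~group_mask]
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        u = float(min(res.statistic, len(a) * len(b) - res.statistic))
        sd_pool = np.sqrt(
            (
                (len(a) - 1) * np.var(a, ddof=1) + (len(b) - 1) * np.var(b, ddof=1)
            )
            / (len(a) + len(b) - 2)
        ) if len(a) > 1 and len(b) > 1 else np.nan
        d = (a.mean() - b.mean()) / sd_pool if sd_pool and sd_pool > 0 else np.nan
        rows[f] = {
            "U": u,
            "p": float(res.pvalue),
            "p_adj": float(min(1.0, m * res.pvalue)),
            "cohens_d": float(d) if d == d else np.nan,
            "significant": bool(min(1.0, m * res.pvalue) < alpha),
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "feature"
    return df


def classification_metrics(
    y_true, y_pred, scores=None
) -> dict:
    """Accuracy, precision, recall, F1 and ROC-AUC (positive class = 1/VEN).

    With single-class truth the AUC is undefined: returned as None with
    ``auc_defined`` False.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must have equal length")
    tp = int(np.sum((y_pred == 1) & (y_true == 1)))
    fp = int(np.sum((y_pred == 1) & (y_true == 0)))
    fn = int(np.sum((y_pred == 0) & (y_true == 1)))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    out = {
        "accuracy": float(np.mean(y_true == y_pred)),
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "roc_auc": None,
        "auc_defined": False,
    }
    if scores is not None and len(np.unique(y_true)) == 2:
        out["roc_auc"] = float(roc_auc_score(y_true, np.asarray(scores, float)))
        out["auc_defined"] = True
    return out
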