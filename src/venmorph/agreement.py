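"""Expert-vs-machine agreement statistics on variable-importance rankings.

Human experts and classification algorithms both produce rankings of the
morphometric variables (rank 1 = most important).  Three statistics
quantify how well they agree:

- **Fleiss' kappa** across raters, treating the variables as items and the
  assigned rank values as categories — chance-corrected agreement for
  m raters, with the large-sample z statistic and two-sided p value;
- **Spearman's rho** between two consensus rankings (e.g. the human-driven
  and the information-driven consensus);
- **Rank-position variance** per rater group: how variable each group's
  rank assignments are per variable, summarized as group mean ± SD of
  variances and the expert/algorithm ratio (a ratio of 14 means the
  algorithms are 14× more consistent than the experts).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats import inter_rater

__all__ = [
    "RankingMatrix",
    "fleiss_kappa",
    "spearman_between",
    "variance_consistency",
]

EXPERT = "expert"
ALGORITHM = "algorithm"


@dataclass
class RankingMatrix:
    """Raters × variables matrix of ranks with a rater-kind annotation.

    ``ranks`` rows are raters, columns variables; each row should be a
    permutation of 1..n_variables (average-rank ties allowed).  ``kinds``
    maps rater id → "expert" | "algorithm".
    """

    ranks: pd.DataFrame
    kinds: dict[str, str]

    def __post_init__(self) -> None:
        unknown = set(self.kinds.values()) - {EXPERT, ALGORITHM}
        if unknown:
            raise ValueError(f"unknown rater kinds: {unknown}")
        missing = set(self.ranks.index) - set(self.kinds)
        if missing:
            raise ValueError(f"raters without a kind: {sorted(missing)}")

    def subset(self, kind: str) -> pd.DataFrame:
        keep = [r for r in self.ranks.index if self.kinds[r] == kind]
        return self.ranks.loc[keep]

    @classmethod
    def from_csv(cls, path, kind: str = EXPERT) -> "RankingMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(ranks=df, kinds={r: kind for r in df.index})

    def merged_with(self, other: "RankingMatrix") -> "RankingMatrix":
        ranks = pd.concat([self.ranks, other.ranks])
        return RankingMatrix(ranks=ranks, kinds={**self.kinds, **other.kinds})


def _category_table(ranks: pd.DataFrame) -> np.ndarray:
    """Items × categories count table: items = variables, categories = the
    distinct rank values assigned across all raters."""
    values = np.unique(ranks.to_numpy())
    table = np.zeros((ranks.shape[1], len(values)), dtype=int)
    for j, var in enumerate(ranks.columns):
        col = ranks[var].to_numpy()
        for k, v in enumerate(values):
            table[j, k] = int(np.sum(col == v))
    return table


def fleiss_kappa(matrix: RankingMatrix | pd.DataFrame) -> dict:
    """Fleiss' kappa for m raters over the ranking matrix.

    Returns ``{"kappa", "z", "p", "n_items", "n_raters"}``.  z and p follow
    the classical large-sample variance of kappa under the null of chance
    agreement.  Degenerate single-category data leave kappa undefined
    (NaN, flagged via ``defined``).
    """
    ranks = matrix.ranks if isinstance(matrix, RankingMatrix) else matrix
    if ranks.shape[0] < 2 or ranks.shape[1] < 2:
        raise ValueError("need at least 2 raters and 2 items")
    table = _category_table(ranks)
    n_raters = int(table.sum(axis=1)[0])
    N = table.shape[0]

    p_j = table.sum(axis=0) / (N * n_raters)
    if np.max(p_j) == 1.0:
        return {
            "kappa": math.nan, "z": math.nan, "p": math.nan,
            "n_items": N, "n_raters": n_raters, "defined": False,
        }
    kappa = float(inter_rater.fleiss_kappa(table, method="fleiss"))

    # large-sample variance (Fleiss 1971)
    q_j = 1.0 - p_j
    s = float(np.sum(p_j * q_j))
    var = (2.0 / (N * n_raters * (n_raters - 1))) * (
        s**2 - float(np.sum(p_j * q_j * (q_j - p_j)))
    ) / s**2
    z = kappa / math.sqrt(var) if var > 0 else math.nan
    p = 2.0 * (1.0 - stats.norm.cdf(abs(z))) if z == z else math.nan
    return {
        "kappa": kappa, "z": float(z), "p": float(p),
        "n_items": N, "n_raters": n_raters, "defined": True,
    }


def spearman_between(consensus_a, consensus_b) -> dict:
    """Spearman rank correlation between two consensus rankings.

    Accepts aligned rank vectors (or Series sharing an index).  Average-rank
    ties are handled by scipy; p is the t-approximation.
    """
    a = pd.Series(consensus_a)
    b = pd.Series(consensus_b)
    if isinstance(consensus_a, pd.Series) and isinstance(consensus_b, pd.Series):
        common = a.index.intersection(b.index)
        if len(common) != len(a) or len(common) != len(b):
            raise ValueError("consensus rankings must cover the same variables")
        a, b = a.loc[common], b.loc[common]
    if len(a) != len(b):
        raise ValueError("rankings must have equal length")
    if len(a) < 3:
        raise ValueError("need at least 3 variables")
    res = stats.spearmanr(a.to_numpy(float), b.to_numpy(float))
    return {"rho": float(res.statistic), "p": float(res.pvalue), "n": len(a)}


def variance_consistency(matrix: RankingMatrix) -> dict:
    """Per-group rank-position variance and the expert/algorithm ratio.

    For every variable the sample variance of the ranks assigned within
    each rater group is computed; each group is summarized as mean ± SD of
    those variances.  The ratio (expert mean / algorithm mean) expresses
    how many times more consistent the algorithms are.  A group with a
    single rater has undefined variance (flagged, NaN).
    """
    out: dict = {}
    for kind in (EXPERT, ALGORITHM):
        sub = matrix.subset(kind)
        if sub.empty:
            raise ValueError(f"no raters of kind {kind!r}")
        if sub.shape[0] < 2:
            out[kind] = {"mean": math.nan, "sd": math.nan, "defined": False}
            continue
        variances = sub.var(axis=0, ddof=1).to_numpy(float)
        out[kind] = {
            "mean": float(np.mean(variances)),
            "sd": float(np.std(variances, ddof=1)),
            "defined": True,
            "per_variable": dict(zip(sub.columns, variances)),
        }
    e, a = out[EXPERT], out[ALGORITHM]
    if e.get("defined") and a.get("defined") and a["mean"] > 0:
        out["expert_to_algorithm_ratio"] = e["mean"] / a["mean"]
    else:
        out["expert_to_algorithm_ratio"] = math.nan
    return out
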