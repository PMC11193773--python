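"""Shadow-feature ranking and the heuristic top-N feature-subset search.

Ranking: each iteration appends a permuted ("shadow") copy of every feature,
fits a random forest on the augmented matrix, and scores a real feature a
"hit" when its impurity importance exceeds the maximum shadow importance.
After ``n_iter`` iterations a two-sided binomial test at level ``alpha``
classifies features as confirmed (more hits than chance), rejected (fewer),
or tentative.  The final list covers *all* features, ordered confirmed →
tentative → rejected and, within a class, by mean importance (ties broken by
name), so prefixes of any length are well defined.

Subset search: for each candidate size N on the grid, the top-N prefix FS_N
is evaluated by (repeated) stratified 5-fold CV with the six default model
families; MCC_N^i is recorded per family, Best_MCC_N = max_i MCC_N^i, and the
best feature subset is the prefix whose Best_MCC is maximal (smallest N on
ties).  Using all six untuned families keeps the chosen subset from being
biased toward one model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import binomtest
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import matthews_corrcoef
from sklearn.model_selection import StratifiedKFold

from .modeling import FAMILIES, build_estimator, make_default_model
from .preprocess import fit_quartile_scaler

__all__ = ["RankedFeatureList", "SubsetSearchResult",
           "shadow_feature_ranking", "heuristic_subset_search",
           "DEFAULT_GRID"]

DEFAULT_GRID = tuple(range(50, 201, 10))
_STATUS_ORDER = {"confirmed": 0, "tentative": 1, "rejected": 2}


@dataclass
class RankedFeatureList:
    """All features in descending importance order, with per-feature mean
    importance and confirmation status."""

    names: tuple[str, ...]
    importance: dict[str, float]
    status: dict[str, str]

    def __post_init__(self):
        if len(set(self.names)) != len(self.names):
            raise ValueError("ranking contains duplicate feature names")

    def prefix(self, n: int) -> list[str]:
        if n > len(self.names):
            raise ValueError(f"prefix {n} exceeds {len(self.names)} ranked features")
        return list(self.names[:n])

    def n_confirmed(self) -> int:
        return sum(1 for s in self.status.values() if s == "confirmed")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "feature": self.names,
            "importance": [self.importance[n] for n in self.names],
            "status": [self.status[n] for n in self.names],
        })


def shadow_feature_ranking(m: pd.DataFrame, labels, n_iter: int = 30,
                           alpha: float = 0.05, seed: int = 0,
                           n_estimators: int = 300,
                           max_depth: int | None = 7) -> RankedFeatureList:
    """Rank features against permuted shadow copies with a random forest."""
    y = np.asarray(labels, int)
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class")
    if n_iter < 10:
        raise ValueError("n_iter must be >= 10 for the binomial test")
    rng = np.random.default_rng(seed)
    X = m.to_numpy(float)
    n, p = X.shape
    hits = np.zeros(p, int)
    imp_sum = np.zeros(p)
    for it in range(n_iter):
        shadow = X.copy()
        for j in range(p):
            rng.shuffle(shadow[:, j])
        aug = np.hstack([X, shadow])
        forest = RandomForestClassifier(
            n_estimators=n_estimators, max_depth=max_depth, n_jobs=1,
            random_state=int(rng.integers(2**31 - 1)))
        forest.fit(aug, y)
        imp = forest.feature_importances_
        real, sh = imp[:p], imp[p:]
        hits += real > sh.max()
        imp_sum += real
    mean_imp = imp_sum / n_iter
    status = {}
    for j, name in enumerate(m.columns):
        pval = binomtest(int(hits[j]), n_iter, 0.5, alternative="two-sided").pvalue
        if pval < alpha and hits[j] > n_iter / 2:
            status[name] = "confirmed"
        elif pval < alpha and hits[j] < n_iter / 2:
            status[name] = "rejected"
        else:
            status[name] = "tentative"
    importance = {name: float(mean_imp[j]) for j, name in enumerate(m.columns)}
    order = sorted(m.columns,
                   key=lambda nm: (_STATUS_ORDER[status[nm]], -importance[nm], nm))
    return RankedFeatureList(tuple(order), importance, status)


@dataclass
class SubsetSearchResult:
    """The per-(N, family) MCC grid and the subset it selects."""

    grid: tuple[int, ...]
    mcc: pd.DataFrame            # index N, columns model families
    best_mcc: pd.Series          # per-N max over families
    best_n: int
    best_family: str             # family achieving the max at best_n
    best_features: list[str]     # BFS: the ranked prefix of length best_n

    def recompute_from_grid(self) -> tuple[pd.Series, int]:
        """Independent re-derivation of Best_MCC and the chosen N from the
        stored grid (max over families per N; argmax over N, smallest on ties)."""
        best = self.mcc.max(axis=1)
        chosen = int(best.index[np.flatnonzero(best.values == best.values.max())[0]])
        return best, chosen


def heuristic_subset_search(m: pd.DataFrame, labels, ranking: RankedFeatureList,
                            grid: Sequence[int] = DEFAULT_GRID,
                            cv_folds: int = 5, repeats: int = 3,
                            seed: int = 0,
                            families: Sequence[str] = FAMILIES,
                            ) -> SubsetSearchResult:
    """Evaluate ranked prefixes FS_N over the grid and pick the best subset.

    Per repeat, MCC is computed from the confusion counts pooled over the
    stratified folds (scaler re-fit per training fold); MCC_N^family is the
    mean over repeats.  Ties across families at the per-N max are reported
    using the fixed precedence order of ``families``.
    """
    y = np.asarray(labels, int)
    grid = tuple(int(n) for n in grid)
    if max(grid) > len(ranking.names):
        raise ValueError("grid exceeds the number of ranked features")
    mcc = pd.DataFrame(index=pd.Index(grid, name="N"),
                       columns=list(families), dtype=float)
    for N in grid:
        Xn = m[ranking.prefix(N)]
        for fam in families:
            per_repeat = []
            for r in range(repeats):
                skf = StratifiedKFold(n_splits=cv_folds, shuffle=True,
                                      random_state=seed + 1000 * r)
                truth, preds = [], []
                for tr, te in skf.split(Xn, y):
                    if len(np.unique(y[tr])) < 2:
                        raise ValueError("degenerate fold: single class")
                    scaler = fit_quartile_scaler(Xn.iloc[tr])
                    est = build_estimator(make_default_model(fam, seed))
                    est.fit(scaler.transform(Xn.iloc[tr]).to_numpy(), y[tr])
                    preds.append(est.predict(scaler.transform(Xn.iloc[te]).to_numpy()))
                    truth.append(y[te])
                per_repeat.append(matthews_corrcoef(
                    np.concatenate(truth), np.concatenate(preds)))
            mcc.loc[N, fam] = float(np.mean(per_repeat))
    best_mcc = mcc.max(axis=1)
    best_n = int(best_mcc.index[np.flatnonzero(
        best_mcc.values == best_mcc.values.max())[0]])
    row = mcc.loc[best_n]
    best_family = next(f for f in families if row[f] == row.max())
    return SubsetSearchResult(grid, mcc, best_mcc, best_n, best_family,
                              ranking.prefix(best_n))


def dump_search_result(result: SubsetSearchResult, csv_path: str | Path,
                       json_path: str | Path) -> None:
    """Persist the MCC grid as CSV and the chosen subset as JSON."""
    result.mcc.to_csv(csv_path)
    Path(json_path).write_text(json.dumps({
        "best_n": result.best_n,
        "best_family": result.best_family,
        "best_mcc": float(result.best_mcc.loc[result.best_n]),
        "best_features": result.best_features,
    }, indent=2))
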