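"""Random-forest attribution of keystone abundance to soil covariates.

A regression forest of fully grown trees is bagged explicitly (bootstrap
indices drawn per tree) so that out-of-bag permutation importance — the
percent increase in OOB mean squared error when a predictor is shuffled —
can be computed exactly, tree by tree, in the manner of the classic
randomForest %IncMSE. Impurity importance (increase in node purity) comes
from the trees' variance-reduction totals. Significance is assessed by
refitting the forest on response-permuted data and comparing observed
importances with the refit null distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeRegressor

__all__ = [
    "RfDriverReport",
    "keystone_abundance_response",
    "rf_importance",
    "rf_permutation_significance",
]


@dataclass
class RfDriverReport:
    importance: pd.DataFrame  # per predictor: pct_inc_mse, inc_node_purity [, p_*]
    n_trees: int
    oob_r_squared: float
    selected: list[str] = field(default_factory=list)
    alpha: float | None = None


def keystone_abundance_response(table: pd.DataFrame, keystones) -> pd.Series:
    """Summed relative abundance of the keystone OTUs in each sample.

    A presence-count response (number of keystone OTUs observed per sample)
    is available via :func:`keystone_presence_response`.
    """
    keystones = [k for k in keystones]
    if not keystones:
        raise ValueError("empty keystone set")
    missing = [k for k in keystones if k not in table.columns]
    if missing:
        raise ValueError(f"keystones absent from table: {missing}")
    X = table.to_numpy(dtype=float)
    totals = X.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("zero-sum sample(s)")
    sub = table[keystones].to_numpy(dtype=float)
    return pd.Series(sub.sum(axis=1) / totals, index=table.index, name="keystone_abundance")


def keystone_presence_response(table: pd.DataFrame, keystones) -> pd.Series:
    keystones = [k for k in keystones]
    if not keystones:
        raise ValueError("empty keystone set")
    sub = (table[keystones].to_numpy(dtype=float) > 0).sum(axis=1)
    return pd.Series(sub, index=table.index, name="keystone_presence")


class _BaggedForest:
    """Regression bagging with per-tree OOB bookkeeping."""

    def __init__(self, n_trees: int, mtry: int, rng: np.random.Generator):
        self.n_trees = n_trees
        self.mtry = mtry
        self.rng = rng
        self.trees: list[DecisionTreeRegressor] = []
        self.oob_idx: list[np.ndarray] = []

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_BaggedForest":
        n = X.shape[0]
        for _ in range(self.n_trees):
            boot = self.rng.integers(0, n, size=n)
            oob = np.setdiff1d(np.arange(n), boot)
            tree = DecisionTreeRegressor(
                max_features=self.mtry,
                random_state=int(self.rng.integers(2**31)),
            )
            tree.fit(X[boot], y[boot])
            self.trees.append(tree)
            self.oob_idx.append(oob)
        return self

    def oob_predictions(self, X: np.ndarray) -> np.ndarray:
        n = X.shape[0]
        pred_sum = np.zeros(n)
        pred_cnt = np.zeros(n)
        for tree, oob in zip(self.trees, self.oob_idx):
            if oob.size == 0:
                continue
            pred_sum[oob] += tree.predict(X[oob])
            pred_cnt[oob] += 1
        with np.errstate(invalid="ignore"):
            return np.where(pred_cnt > 0, pred_sum / np.maximum(pred_cnt, 1), np.nan)

    def permutation_importance(self, X: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Mean per-tree increase in OOB MSE when each predictor is shuffled,
        as a percentage of the baseline OOB MSE."""
        p = X.shape[1]
        inc = np.zeros(p)
        base_total = 0.0
        n_used = 0
        for tree, oob in zip(self.trees, self.oob_idx):
            if oob.size < 2:
                continue
            Xo = X[oob]
            yo = y[oob]
            base = np.mean((tree.predict(Xo) - yo) ** 2)
            base_total += base
            n_used += 1
            perm = self.rng.permutation(oob.size)
            for j in range(p):
                Xp = Xo.copy()
                Xp[:, j] = Xo[perm, j]
                inc[j] += np.mean((tree.predict(Xp) - yo) ** 2) - base
        if n_used == 0:
            raise ValueError("no usable out-of-bag data")
        base_mean = base_total / n_used
        return 100.0 * (inc / n_used) / max(base_mean, 1e-12)

    def impurity_importance(self) -> np.ndarray:
        return np.mean([t.feature_importances_ for t in self.trees], axis=0)


def _fit_report(
    X: np.ndarray, y: np.ndarray, names: list[str], n_trees: int, rng: np.random.Generator
) -> tuple[pd.DataFrame, float, _BaggedForest]:
    mtry = max(1, int(np.ceil(X.shape[1] / 3)))  # regression-forest default
    forest = _BaggedForest(n_trees, mtry, rng).fit(X, y)
    pct = forest.permutation_importance(X, y)
    purity = forest.impurity_importance()
    oob_pred = forest.oob_predictions(X)
    ok = ~np.isnan(oob_pred)
    ss_res = np.sum((y[ok] - oob_pred[ok]) ** 2)
    ss_tot = np.sum((y[ok] - y[ok].mean()) ** 2)
    oob_r2 = float(1.0 - ss_res / ss_tot) if ss_tot > 0 else np.nan
    imp = pd.DataFrame(
        {"pct_inc_mse": pct, "inc_node_purity": purity}, index=names
    )
    return imp, oob_r2, forest


def _prepare(X, y):
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xv = X.to_numpy(dtype=float)
    else:
        Xv = np.asarray(X, dtype=float)
        names = [f"x{j}" for j in range(Xv.shape[1])]
    yv = np.asarray(y, dtype=float)
    if Xv.shape[1] < 2:
        raise ValueError("need at least 2 predictors")
    if Xv.shape[0] < 10:
        raise ValueError("need at least 10 observations")
    if np.ptp(yv) == 0:
        raise ValueError("constant response")
    return Xv, yv, names


def rf_importance(X, y, n_trees: int = 999, seed: int | None = None) -> RfDriverReport:
    """Fit the forest and report both importance measures (no p-values)."""
    Xv, yv, names = _prepare(X, y)
    rng = np.random.default_rng(seed)
    imp, oob_r2, _ = _fit_report(Xv, yv, names, n_trees, rng)
    return RfDriverReport(importance=imp, n_trees=n_trees, oob_r_squared=oob_r2)


def rf_permutation_significance(
    X,
    y,
    n_perm: int = 999,
    n_trees: int = 300,
    alpha: float = 0.01,
    seed: int | None = None,
) -> RfDriverReport:
    """Permutation significance of forest importances (rfPermute-style).

    The null importance distribution of each predictor comes from refitting
    the forest on ``n_perm`` response-permuted datasets;
    p = (1 + #{null >= observed}) / (1 + n_perm). Selected drivers are the
    predictors with p <= alpha on the %IncMSE measure.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    Xv, yv, names = _prepare(X, y)
    rng = np.random.default_rng(seed)
    imp, oob_r2, _ = _fit_report(Xv, yv, names, n_trees, rng)
    obs_pct = imp["pct_inc_mse"].to_numpy()
    obs_pur = imp["inc_node_purity"].to_numpy()
    ge_pct = np.zeros(len(names))
    ge_pur = np.zeros(len(names))
    for _ in range(n_perm):
        y_perm = rng.permutation(yv)
        imp_null, _, _ = _fit_report(Xv, y_perm, names, n_trees, rng)
        ge_pct += imp_null["pct_inc_mse"].to_numpy() >= obs_pct
        ge_pur += imp_null["inc_node_purity"].to_numpy() >= obs_pur
    imp = imp.copy()
    imp["p_value"] = (1.0 + ge_pct) / (1.0 + n_perm)
    imp["p_value_purity"] = (1.0 + ge_pur) / (1.0 + n_perm)
    selected = [n for n, p in zip(names, imp["p_value"]) if p <= alpha]
    return RfDriverReport(
        importance=imp,
        n_trees=n_trees,
        oob_r_squared=oob_r2,
        selected=selected,
        alpha=alpha,
    )
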