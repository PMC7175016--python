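"""Random-forest decoding of value-driven choice outcomes from ROI betas.

Transfer-phase single-trial betas from all subjects are pooled into one
fixed-effects matrix (rows shuffled so subjects and trials intermix),
split 2/3-1/3 into training and validation sets, and decoded with an
ensemble of decision trees. Each tree is grown on a class-balanced
bootstrap of the training rows (equal numbers of optimal and suboptimal
choices, so the forest cannot learn the base rate) with a random
mtry-subset of features considered at every split. Out-of-bag (OOB)
votes - trees whose bootstrap excluded a row - give a training-set error
estimate; feature relevance is measured by permutation importance on the
OOB predictions; per-trial vote shares quantify prediction uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.metrics import roc_auc_score
from sklearn.tree import DecisionTreeClassifier

from .signals import ROI_GROUPS

LABEL_POSITIVE = "optimal"
META_COLS = ("label", "dvalue")


@dataclass
class TrialBetaMatrix:
    """Pooled, shuffled decoding matrix.

    ``data`` holds numeric feature columns (ROI betas plus integer-coded
    subject_id and trial_sign), a ``label`` column in {optimal,
    suboptimal} and, when available, a ``dvalue`` column. ``codes`` maps
    the categorical feature names to their code -> level tables.
    """

    data: pd.DataFrame
    feature_cols: list
    codes: dict = field(default_factory=dict)
    shuffle_seed: int = None

    @property
    def X(self) -> np.ndarray:
        return self.data[self.feature_cols].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return (self.data["label"] == LABEL_POSITIVE).to_numpy(dtype=int)

    @property
    def dvalues(self) -> np.ndarray:
        return self.data["dvalue"].to_numpy(dtype=float)

    def subset_rows(self, mask) -> "TrialBetaMatrix":
        return TrialBetaMatrix(self.data[mask].reset_index(drop=True),
                               list(self.feature_cols), dict(self.codes),
                               self.shuffle_seed)

    def subset_features(self, keep) -> "TrialBetaMatrix":
        keep = list(keep)
        missing = set(keep) - set(self.feature_cols)
        if missing:
            raise KeyError(f"unknown features: {sorted(missing)}")
        cols = keep + [c for c in META_COLS if c in self.data.columns]
        return TrialBetaMatrix(self.data[cols].copy(), keep, dict(self.codes),
                               self.shuffle_seed)


def assemble_matrix(tables, seed: int) -> TrialBetaMatrix:
    """Concatenate per-subject beta tables, drop misses, shuffle rows.

    All tables must share the same columns. ``subject_id`` and
    ``trial_sign`` are integer-coded so they can enter the trees as
    features (splits on integer codes approximate categorical splits).
    """
    tables = list(tables)
    cols = list(tables[0].columns)
    for t in tables[1:]:
        if list(t.columns) != cols:
            raise ValueError("feature columns differ across subject tables")
    df = pd.concat(tables, ignore_index=True)
    df = df[df["label"].notna()].reset_index(drop=True)
    rng = np.random.default_rng(seed)
    df = df.iloc[rng.permutation(len(df))].reset_index(drop=True)

    codes = {}
    for cat in ("subject_id", "trial_sign"):
        levels = sorted(df[cat].unique())
        codes[cat] = {lvl: i for i, lvl in enumerate(levels)}
        df[cat] = df[cat].map(codes[cat]).astype(int)
    feature_cols = [c for c in df.columns if c not in META_COLS]
    return TrialBetaMatrix(df, feature_cols, codes, shuffle_seed=seed)


def split_train_validation(matrix: TrialBetaMatrix, train_fraction: float = 2 / 3,
                           seed: int = 0):
    """Disjoint row partition into training and validation sets."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    n = len(matrix.data)
    n_train = int(round(n * train_fraction))
    perm = np.random.default_rng(seed).permutation(n)
    train_mask = np.zeros(n, dtype=bool)
    train_mask[perm[:n_train]] = True
    return matrix.subset_rows(train_mask), matrix.subset_rows(~train_mask)


class BalancedRandomForest:
    """Ensemble of trees on class-balanced bootstraps with OOB bookkeeping."""

    def __init__(self, n_trees: int = 2000, mtry: int = None, seed: int = 0,
                 min_samples_leaf: int = 1):
        self.n_trees = n_trees
        self.mtry = mtry
        self.seed = seed
        self.min_samples_leaf = min_samples_leaf
        self.trees_ = None

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("training set contains a single class")
        p = X.shape[1]
        mtry = self.mtry or max(1, int(np.sqrt(p)))
        if not 1 <= mtry <= p:
            raise ValueError(f"mtry must lie in [1, {p}]")
        self.mtry_ = mtry
        idx_by_class = [np.flatnonzero(y == c) for c in classes]
        n_each = min(len(ix) for ix in idx_by_class)

        rng = np.random.default_rng(self.seed)
        self.trees_ = []
        self.oob_masks_ = []
        self.bootstrap_counts_ = []
        for _ in range(self.n_trees):
            boot = np.concatenate([
                rng.choice(ix, size=n_each, replace=True) for ix in idx_by_class])
            oob = np.ones(len(y), dtype=bool)
            oob[boot] = False
            tree = DecisionTreeClassifier(
                max_features=mtry, min_samples_leaf=self.min_samples_leaf,
                random_state=int(rng.integers(0, 2**31 - 1)))
            tree.fit(X[boot], y[boot])
            self.trees_.append(tree)
            self.oob_masks_.append(oob)
            self.bootstrap_counts_.append(
                {int(c): int(np.sum(y[boot] == c)) for c in classes})
        self._X_train, self._y_train = X, y
        return self

    def votes(self, X) -> np.ndarray:
        """Per-row proportion of trees voting for the positive (optimal) class."""
        X = np.asarray(X, dtype=float)
        total = np.zeros(X.shape[0])
        for tree in self.trees_:
            total += tree.predict(X)
        return total / len(self.trees_)

    def predict(self, X) -> np.ndarray:
        """Majority vote; an exact tie (vote = 0.5) resolves to suboptimal."""
        return (self.votes(X) > 0.5).astype(int)

    def oob_votes(self, X=None) -> np.ndarray:
        """OOB vote share per training row (NaN where no tree left it out).

        ``X`` may override the training matrix (e.g. a column-permuted
        copy) while keeping the per-tree OOB row assignment.
        """
        X = self._X_train if X is None else np.asarray(X, dtype=float)
        total = np.zeros(X.shape[0])
        count = np.zeros(X.shape[0])
        for tree, oob in zip(self.trees_, self.oob_masks_):
            if oob.any():
                total[oob] += tree.predict(X[oob])
                count[oob] += 1
        with np.errstate(invalid="ignore"):
            return np.where(count > 0, total / np.maximum(count, 1), np.nan)

    @property
    def oob_error_(self) -> float:
        """Proportion of training rows whose aggregated OOB vote is wrong."""
        v = self.oob_votes()
        ok = np.isfinite(v)
        pred = (v[ok] > 0.5).astype(int)
        return float(np.mean(pred != self._y_train[ok]))


def train_forest(train: TrialBetaMatrix, n_trees: int = 2000, mtry: int = None,
                 seed: int = 0) -> BalancedRandomForest:
    return BalancedRandomForest(n_trees=n_trees, mtry=mtry, seed=seed).fit(
        train.X, train.y)


def tune_mtry(train: TrialBetaMatrix, n_trees: int = 500, start: int = None,
              step_factor: float = 1.5, improve: float = 0.05,
              seed: int = 0) -> int:
    """Stepwise OOB-error search for mtry, starting at floor(sqrt(p)).

    From the starting value the search walks left (divide by
    ``step_factor``) and right (multiply) while each step improves the
    OOB error by more than ``improve`` relative to the current best.
    """
    p = len(train.feature_cols)
    if p < 2:
        raise ValueError("need at least 2 features to tune mtry")
    start = start or max(1, int(np.sqrt(p)))

    def oob(m):
        return BalancedRandomForest(n_trees=n_trees, mtry=m, seed=seed).fit(
            train.X, train.y).oob_error_

    best_m, best_e = start, oob(start)
    for direction in (-1, 1):
        m, e = best_m, best_e
        while True:
            nxt = (max(1, int(np.floor(m / step_factor))) if direction < 0
                   else min(p, int(np.ceil(m * step_factor))))
            if nxt == m:
                break
            e_nxt = oob(nxt)
            if e_nxt < e - improve * max(e, 1e-12):
                m, e = nxt, e_nxt
                if e < best_e:
                    best_m, best_e = m, e
            else:
                break
    return best_m


def permutation_importance(model: BalancedRandomForest, feature_names,
                           n_repeats: int = 10, seed: int = 0) -> pd.DataFrame:
    """OOB permutation importance: baseline accuracy minus permuted accuracy.

    Each repeat shuffles one feature column over the training rows and
    re-aggregates the OOB votes; the mean accuracy drop over repeats is
    that feature's importance (negative values are meaningful: permuting
    the feature *helped*). Returns a table sorted by descending
    importance with a 1-based ``rank`` column.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    X, y = model._X_train, model._y_train
    base_votes = model.oob_votes()
    ok = np.isfinite(base_votes)
    baseline = float(np.mean((base_votes[ok] > 0.5).astype(int) == y[ok]))

    rng = np.random.default_rng(seed)
    rows = []
    for j, name in enumerate(feature_names):
        drops = []
        for _ in range(n_repeats):
            Xp = X.copy()
            Xp[:, j] = Xp[rng.permutation(X.shape[0]), j]
            v = model.oob_votes(Xp)
            acc = float(np.mean((v[ok] > 0.5).astype(int) == y[ok]))
            drops.append(baseline - acc)
        rows.append({"feature": name, "importance": float(np.mean(drops)),
                     "sd": float(np.std(drops))})
    table = pd.DataFrame(rows).sort_values(
        "importance", ascending=False, kind="stable").reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table


def evaluate(model: BalancedRandomForest, validation: TrialBetaMatrix) -> dict:
    """Held-out accuracy, ROC AUC from vote shares, and per-trial votes."""
    votes = model.votes(validation.X)
    pred = (votes > 0.5).astype(int)
    y = validation.y
    acc = float(np.mean(pred == y))
    if np.unique(y).size < 2:
        auc = float("nan")
    else:
        auc = float(roc_auc_score(y, votes))
    return {"accuracy": acc, "auc": auc, "votes": votes, "predicted": pred}


def uncertainty_dvalue_regression(votes, dvalues):
    """OLS of the trial's value difference on forest vote uncertainty.

    Uncertainty is the disagreement share 1 - max(vote, 1 - vote), in
    [0, 0.5]. Returns slope, intercept, adjusted R-squared and the fitted
    results object; zero variance in uncertainty is flagged with NaNs.
    """
    votes = np.asarray(votes, dtype=float)
    dvalues = np.asarray(dvalues, dtype=float)
    unc = 1.0 - np.maximum(votes, 1.0 - votes)
    if np.ptp(unc) == 0:
        return {"slope": float("nan"), "intercept": float("nan"),
                "adj_r2": float("nan"), "uncertainty": unc, "fit": None}
    fit = sm.OLS(dvalues, sm.add_constant(unc)).fit()
    with np.errstate(divide="ignore", invalid="ignore"):
        adj_r2 = float(fit.rsquared_adj)  # -inf when dvalues are constant
    return {"slope": float(fit.params[1]), "intercept": float(fit.params[0]),
            "adj_r2": adj_r2, "uncertainty": unc, "fit": fit}


def ablation_suite(train: TrialBetaMatrix, validation: TrialBetaMatrix,
                   groups: dict = None, n_trees: int = 500, seed: int = 0,
                   extra_features=("subject_id", "trial_sign")) -> pd.DataFrame:
    """Decoding accuracy with each region group removed and in isolation.

    ``groups`` defaults to the striatal / frontal / perceptual split.
    Isolated configurations keep the categorical covariates listed in
    ``extra_features``.
    """
    groups = groups or {k: list(v) for k, v in ROI_GROUPS.items()}
    for name, members in groups.items():
        unknown = set(members) - set(train.feature_cols)
        if unknown:
            raise KeyError(f"group {name!r} names unknown features: {sorted(unknown)}")

    def run(features, config):
        tr = train.subset_features(features)
        va = validation.subset_features(features)
        model = train_forest(tr, n_trees=n_trees, seed=seed)
        ev = evaluate(model, va)
        return {"configuration": config, "n_features": len(features),
                "oob_error": model.oob_error_, "accuracy": ev["accuracy"],
                "auc": ev["auc"]}

    rows = [run(list(train.feature_cols), "full")]
    for name, members in groups.items():
        without = [c for c in train.feature_cols if c not in members]
        rows.append(run(without, f"without_{name}"))
        isolated = list(members) + [c for c in extra_features
                                    if c in train.feature_cols]
        rows.append(run(isolated, f"only_{name}"))
    return pd.DataFrame(rows)


def difficulty_split(matrix: TrialBetaMatrix, quantile: float = 1 / 3):
    """Partition trials into easiest and hardest by |dValue|.

    The easy subset is the top ``quantile`` fraction of absolute value
    differences, the hard subset the bottom fraction (default: terciles).
    """
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must lie strictly inside (0, 1)")
    adv = np.abs(matrix.dvalues)
    lo = np.quantile(adv, quantile)
    hi = np.quantile(adv, 1.0 - quantile)
    return matrix.subset_rows(adv >= hi), matrix.subset_rows(adv <= lo)


@dataclass
class RFReport:
    """Summary of one decoding run."""

    oob_error: float
    validation_accuracy: float
    auc: float
    importance: pd.DataFrame
    votes: np.ndarray
    n_trees: int
    mtry: int
    n_train: int
    n_validation: int

    def to_dict(self) -> dict:
        return {
            "oob_error": self.oob_error,
            "validation_accuracy": self.validation_accuracy,
            "auc": self.auc,
            "n_trees": self.n_trees,
            "mtry": self.mtry,
            "n_train": self.n_train,
            "n_validation": self.n_validation,
            "importance": self.importance.to_dict(orient="records"),
        }


def decode(matrix: TrialBetaMatrix, n_trees: int = 2000, mtry: int = None,
           train_fraction: float = 2 / 3, seed: int = 0,
           tune: bool = False, n_importance_repeats: int = 10,
           shuffle_labels: bool = False, add_random_control: bool = False):
    """End-to-end decoding run; returns (RFReport, extras).

    ``shuffle_labels`` permutes the labels (chance-level control);
    ``add_random_control`` appends a standard-normal noise feature that
    should rank last with non-positive importance. ``extras`` carries the
    trained model, splits, and the uncertainty regression when dvalues
    are present.
    """
    rng = np.random.default_rng(seed)
    work = matrix
    if add_random_control:
        data = work.data.copy()
        data["random_control"] = rng.standard_normal(len(data))
        work = TrialBetaMatrix(data, work.feature_cols + ["random_control"],
                               dict(work.codes), work.shuffle_seed)
    if shuffle_labels:
        data = work.data.copy()
        data["label"] = data["label"].to_numpy()[rng.permutation(len(data))]
        work = TrialBetaMatrix(data, list(work.feature_cols),
                               dict(work.codes), work.shuffle_seed)

    train, validation = split_train_validation(
        work, train_fraction, seed=int(rng.integers(0, 2**31 - 1)))
    if tune and mtry is None:
        mtry = tune_mtry(train, n_trees=min(n_trees, 500),
                         seed=int(rng.integers(0, 2**31 - 1)))
    model = train_forest(train, n_trees=n_trees, mtry=mtry,
                         seed=int(rng.integers(0, 2**31 - 1)))
    importance = permutation_importance(
        model, train.feature_cols, n_repeats=n_importance_repeats,
        seed=int(rng.integers(0, 2**31 - 1)))
    ev = evaluate(model, validation)
    report = RFReport(
        oob_error=model.oob_error_, validation_accuracy=ev["accuracy"],
        auc=ev["auc"], importance=importance, votes=ev["votes"],
        n_trees=model.n_trees, mtry=model.mtry_,
        n_train=len(train.data), n_validation=len(validation.data))
    extras = {"model": model, "train": train, "validation": validation}
    if "dvalue" in validation.data.columns and validation.data["dvalue"].notna().all():
        extras["uncertainty_regression"] = uncertainty_dvalue_regression(
            ev["votes"], validation.dvalues)
    return report, extras
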