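"""Splitting, mRMR feature ranking, CV feature-count selection, and the
class-weighted L2 logistic model.

The classifier predicts whether a region is cribriform Gleason-4
(GP4Crib+, target 1) versus GP3 / non-cribriform GP4 (target 0) with

    P = 1 / (1 + exp(-(w0 + w1*X1 + ... + wn*Xn)))

and a 0.5 probability threshold.  Features enter in their carried units
(ADC features in 1e-3 mm^2/s), so a single-ADC-feature model's decision
boundary -w0/w1 is directly a printable ADC cutoff.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import balanced_accuracy_score, mutual_info_score
from sklearn.model_selection import StratifiedKFold

POSITIVE_LABEL = "GP4Crib+"
SPLITS = ("train", "validation", "test")
DEFAULT_FRACTIONS = (0.6, 0.2, 0.2)
MAX_FEATURES = 20


class StratificationError(ValueError):
    pass


def target_from_label(labels) -> np.ndarray:
    return (np.asarray(labels) == POSITIVE_LABEL).astype(int)


# ------------------------------------------------------------------ split

def _largest_remainder(total: int, fractions) -> np.ndarray:
    """Integer apportionment of ``total`` by the largest-remainder method."""
    exact = np.asarray(fractions, dtype=float) * total
    base = np.floor(exact).astype(int)
    rem = exact - base
    order = np.argsort(-rem, kind="stable")  # ties: earlier split first
    for idx in order[: total - base.sum()]:
        base[idx] += 1
    return base


def split_dataset(
    table: pd.DataFrame,
    fractions=DEFAULT_FRACTIONS,
    seed: int = 0,
    label_col: str = "label",
    volume_col: str = "volume_cc",
) -> pd.DataFrame:
    """Assign class- and volume-balanced train/validation/test splits.

    Overall split sizes follow the largest-remainder apportionment of the
    fractions; per-class counts are apportioned the same way, reconciled
    against the overall sizes.  Within a class, rows are ordered by volume
    (descending) and dealt to the split with the lowest fill fraction, so
    the volume distribution is balanced across splits.  Returns a copy of
    the table with a ``split`` column.
    """
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    n = len(table)
    totals = _largest_remainder(n, fractions)

    class_sizes = table[label_col].value_counts()
    for lab, size in class_sizes.items():
        if size < len(SPLITS):
            warnings.warn(
                f"class {lab!r} has only {size} rows for {len(SPLITS)} splits; "
                "best-effort allocation",
                stacklevel=2,
            )

    # Per-class quotas: floors first, then the leftover seats go to the
    # split with the largest per-class remainder that still has capacity.
    labs = sorted(class_sizes.index, key=lambda l: (-class_sizes[l], str(l)))
    quotas = {}
    capacity = totals.astype(int).copy()
    for lab in labs:
        base = np.floor(np.asarray(fractions) * class_sizes[lab]).astype(int)
        quotas[lab] = base
        capacity -= base
    for lab in labs:
        exact = np.asarray(fractions) * class_sizes[lab]
        rem = exact - np.floor(exact)
        seats = int(class_sizes[lab] - quotas[lab].sum())
        order = np.argsort(-rem, kind="stable")
        for _ in range(seats):
            for idx in order:
                if capacity[idx] > 0:
                    quotas[lab][idx] += 1
                    capacity[idx] -= 1
                    break

    split_col = pd.Series(index=table.index, dtype=object)
    for lab in labs:
        rows = table.index[table[label_col] == lab].to_numpy()
        rows = rng.permutation(rows)
        vols = table.loc[rows, volume_col].to_numpy()
        rows = rows[np.argsort(-vols, kind="stable")]
        q = quotas[lab].astype(float)
        filled = np.zeros(len(SPLITS))
        for r in rows:
            frac = np.where(q > 0, filled / np.maximum(q, 1e-12), np.inf)
            best = np.flatnonzero(frac == frac.min())
            s = int(best[0]) if len(best) == 1 else int(rng.choice(best))
            split_col[r] = SPLITS[s]
            filled[s] += 1
    out = table.copy()
    out["split"] = split_col
    return out


# ------------------------------------------------------------------ mRMR

def _equal_frequency_bins(x: np.ndarray, n_bins: int = 10) -> np.ndarray:
    edges = np.unique(np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1]))
    return np.searchsorted(edges, x, side="right")


@dataclass
class MrmrRanking:
    features: list[str]
    scores: list[float]  # relevance - redundancy at each selection step

    def top(self, k: int) -> list[str]:
        return self.features[:k]


def mrmr_rank(
    X: pd.DataFrame, y: np.ndarray, max_features: int = MAX_FEATURES, n_bins: int = 10
) -> MrmrRanking:
    """Greedy minimum-redundancy-maximum-relevance ranking (MID scheme).

    The first feature maximizes I(feature; target); step k maximizes
    I(f; target) - mean_{s in selected} I(f; s).  Mutual information is
    estimated on 10 equal-frequency bins.  Ties break toward the
    lexicographically smaller feature name.
    """
    if X.shape[1] < 1:
        raise ValueError("need at least one candidate feature")
    y = np.asarray(y)
    cols = sorted(X.columns)
    binned = {c: _equal_frequency_bins(X[c].to_numpy().astype(float), n_bins) for c in cols}
    relevance = {c: mutual_info_score(binned[c], y) for c in cols}

    selected: list[str] = []
    scores: list[float] = []
    redundancy_sum = {c: 0.0 for c in cols}
    remaining = set(cols)
    while remaining and len(selected) < max_features:
        best_name, best_score = None, -np.inf
        for c in sorted(remaining):
            red = redundancy_sum[c] / len(selected) if selected else 0.0
            sc = relevance[c] - red
            if sc > best_score + 1e-12:
                best_name, best_score = c, sc
        selected.append(best_name)
        scores.append(best_score)
        remaining.discard(best_name)
        for c in remaining:
            redundancy_sum[c] += mutual_info_score(binned[c], binned[best_name])
    return MrmrRanking(features=selected, scores=scores)


# ------------------------------------------------------------------ model

@dataclass(frozen=True)
class Hyperparams:
    C: float = 1.0
    penalty: str = "l2"
    max_iter: int = 10
    class_weight: object = "balanced"
    fit_intercept: bool = True

    def to_jsonable(self) -> dict:
        cw = self.class_weight
        if isinstance(cw, dict):
            cw = {str(k): v for k, v in cw.items()}
        return {"C": self.C, "penalty": self.penalty, "max_iter": self.max_iter,
                "class_weight": cw, "fit_intercept": self.fit_intercept}


# Candidate grid used for hyperparameter optimization; the first entry of
# each list is the configuration the default pipeline uses.
HYPERPARAM_GRID = {
    "C": [0.001, 0.01, 0.1, 1, 2, 10],
    "penalty": ["l1", "l2", "elasticnet"],
    "max_iter": [10, 50, 100, 500],
    "class_weight": ["balanced", {0: 0.2, 1: 0.8}, {0: 1, 1: 10}],
    "fit_intercept": [True, False],
}


@dataclass
class LogisticModel:
    intercept: float
    coefficients: dict[str, float]
    hyperparams: Hyperparams = field(default_factory=Hyperparams)
    threshold: float = 0.5
    converged: bool = True

    @property
    def feature_names(self) -> list[str]:
        return list(self.coefficients)

    def to_json(self) -> str:
        return json.dumps(
            {
                "intercept": self.intercept,
                "coefficients": self.coefficients,
                "hyperparams": self.hyperparams.to_jsonable(),
                "threshold": self.threshold,
                "converged": self.converged,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "LogisticModel":
        d = json.loads(text)
        hp = d.get("hyperparams", {})
        cw = hp.get("class_weight", "balanced")
        if isinstance(cw, dict):
            cw = {int(k): v for k, v in cw.items()}
        return cls(
            intercept=d["intercept"],
            coefficients=d["coefficients"],
            hyperparams=Hyperparams(
                C=hp.get("C", 1.0), penalty=hp.get("penalty", "l2"),
                max_iter=hp.get("max_iter", 10), class_weight=cw,
                fit_intercept=hp.get("fit_intercept", True),
            ),
            threshold=d.get("threshold", 0.5),
            converged=d.get("converged", True),
        )


def fit_logistic(
    X: pd.DataFrame, y: np.ndarray, hyperparams: Hyperparams | None = None
) -> LogisticModel:
    """Fit the weighted, L2-penalized logistic regression (intercept unpenalized)."""
    hp = hyperparams or Hyperparams()
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to fit the model")
    solver = "lbfgs" if hp.penalty == "l2" else "saga"
    kwargs = {}
    if hp.penalty == "elasticnet":
        kwargs["l1_ratio"] = 0.5
    clf = LogisticRegression(
        C=hp.C, penalty=hp.penalty, max_iter=hp.max_iter,
        class_weight=hp.class_weight, fit_intercept=hp.fit_intercept,
        solver=solver, tol=1e-4, **kwargs,
    )
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        clf.fit(X.to_numpy().astype(float), y)
        converged = not any(issubclass(w.category, ConvergenceWarning) for w in caught)
    coeffs = dict(zip(X.columns, clf.coef_[0].tolist()))
    intercept = float(clf.intercept_[0]) if hp.fit_intercept else 0.0
    return LogisticModel(intercept=intercept, coefficients=coeffs,
                         hyperparams=hp, converged=converged)


def predict_probability(model: LogisticModel, X) -> np.ndarray:
    """P(GP4Crib+) for rows of ``X`` (DataFrame or mapping of feature -> value)."""
    if isinstance(X, dict):
        X = pd.DataFrame({k: [v] for k, v in X.items()})
    missing = [f for f in model.feature_names if f not in X.columns]
    if missing:
        raise KeyError(f"missing model features: {missing}")
    z = model.intercept + sum(
        w * X[f].to_numpy().astype(float) for f, w in model.coefficients.items()
    )
    return 1.0 / (1.0 + np.exp(-z))


def predict_label(model: LogisticModel, X) -> np.ndarray:
    return (predict_probability(model, X) >= model.threshold).astype(int)


def decision_boundary_1d(model: LogisticModel) -> float:
    """Feature value where P = 0.5 for a single-feature model: -w0/w1."""
    if len(model.coefficients) != 1:
        raise ValueError("decision boundary is defined for single-feature models only")
    (w1,) = model.coefficients.values()
    if w1 == 0:
        raise ValueError("zero coefficient: no decision boundary")
    return -model.intercept / w1


# ------------------------------------------------- feature count selection

def _cv_balanced_accuracy(
    X: pd.DataFrame, y: np.ndarray, hp: Hyperparams, n_folds: int, seed: int
) -> float:
    if y.sum() < n_folds or (1 - y).sum() < n_folds:
        raise StratificationError(
            f"need >= {n_folds} rows of each class for {n_folds}-fold stratified CV"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    accs = []
    for tr, te in skf.split(X, y):
        m = fit_logistic(X.iloc[tr], y[tr], hp)
        accs.append(balanced_accuracy_score(y[te], predict_label(m, X.iloc[te])))
    return float(np.mean(accs))


def select_feature_count_cv(
    X: pd.DataFrame,
    y: np.ndarray,
    ranking: MrmrRanking,
    k_max: int = MAX_FEATURES,
    hyperparams: Hyperparams | None = None,
    n_folds: int = 3,
    seed: int = 0,
) -> tuple[int, list[float]]:
    """Choose the feature count maximizing stratified CV balanced accuracy.

    Ties break toward the smaller k.  Returns (k, CV trace over k=1..k_max).
    """
    if not ranking.features:
        raise ValueError("empty ranking")
    hp = hyperparams or Hyperparams()
    k_max = min(k_max, len(ranking.features))
    trace = []
    for k in range(1, k_max + 1):
        trace.append(_cv_balanced_accuracy(X[ranking.top(k)], y, hp, n_folds, seed))
    best_k = int(np.argmax(trace)) + 1  # argmax returns the first maximum
    return best_k, trace


def tune_hyperparameters(
    X: pd.DataFrame,
    y: np.ndarray,
    grid: dict | None = None,
    n_folds: int = 3,
    seed: int = 0,
) -> Hyperparams:
    """Exhaustive grid search scored by stratified CV balanced accuracy.

    The grid is iterated with the default configuration first, and a
    candidate must strictly beat the incumbent, so ties resolve toward the
    default (the configuration the study design prefers).
    """
    import itertools

    grid = grid or HYPERPARAM_GRID
    best_hp = Hyperparams()
    best_score = _cv_balanced_accuracy(X, y, best_hp, n_folds, seed)
    for C, pen, mi, cw, fi in itertools.product(
        grid["C"], grid["penalty"], grid["max_iter"], grid["class_weight"],
        grid["fit_intercept"],
    ):
        hp = Hyperparams(C=C, penalty=pen, max_iter=mi, class_weight=cw, fit_intercept=fi)
        if hp == best_hp:
            continue
        score = _cv_balanced_accuracy(X, y, hp, n_folds, seed)
        if score > best_score + 1e-12:
            best_hp, best_score = hp, score
    return best_hp
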