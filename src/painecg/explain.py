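"""Explainability suite for the pain cascade.

Six complementary views of a fitted model:

1. Shapley values - the game-theoretic attribution
   ``phi_i = sum_{S subset N\\i} |S|!(|N|-|S|-1)!/|N|! [f(S u i) - f(S)]``
   where ``f(S)`` evaluates the model on the explained row with features
   outside ``S`` replaced by background values. :func:`exact_shapley`
   enumerates every subset (the oracle, feasible to ~12 features);
   :func:`tree_shapley` computes the identical interventional quantity for
   tree ensembles in closed form per leaf, by tracking on which features
   the explained row and a background row take different branches.
2. Gini importance - mean decrease in impurity across the ensemble.
3. Pearson feature correlations.
4. Partial dependence (PD) and individual conditional expectation (ICE):
   ``PD(x_s) = E_{x_c}[f(x_s, x_c)]`` marginalized empirically, with PD the
   exact columnwise mean of the ICE curves.
5. Permutation importance - drop in accuracy (classifier) or R^2
   (regressor) when one feature is shuffled, repeated with different seeds.
6. Global surrogate - a shallow decision tree distilled from the model's
   predictions, with IF/AND/THEN rule export and a fidelity score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import factorial
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import is_classifier
from sklearn.cluster import KMeans
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.metrics import accuracy_score, r2_score
from sklearn.model_selection import train_test_split
from sklearn.tree import BaseDecisionTree, DecisionTreeClassifier, DecisionTreeRegressor

from ._rng import child_seed, rng_for
from .errors import ValidationError

__all__ = [
    "ShapleyExplanation",
    "PDPResult",
    "ImportanceReport",
    "SurrogateResult",
    "exact_shapley",
    "tree_shapley",
    "shapley_interaction",
    "gini_importance",
    "permutation_importance",
    "partial_dependence_ice",
    "ice_phenotypes",
    "feature_correlations",
    "global_surrogate",
]

logger = logging.getLogger(__name__)

EXACT_SUBSET_LIMIT = 12


@dataclass
class ShapleyExplanation:
    """Per-feature contributions for one row; base + sum(phi) = model output."""

    base_value: float
    phi: np.ndarray
    model_output: float
    feature_names: list[str] | None = None

    @property
    def efficiency_gap(self) -> float:
        return float(abs(self.base_value + self.phi.sum() - self.model_output))


@dataclass
class PDPResult:
    feature: str
    grid: np.ndarray
    pd_values: np.ndarray  # mean over instances at each grid point
    ice: np.ndarray  # (n_instances, n_grid)


@dataclass
class ImportanceReport:
    method: str  # "gini" | "permutation"
    features: list[str]
    mean: np.ndarray
    sd: np.ndarray | None
    n_repeats: int
    metric_name: str

    def ranking(self) -> list[str]:
        order = np.argsort(-self.mean)
        return [self.features[i] for i in order]

    def as_frame(self) -> pd.DataFrame:
        data = {"feature": self.features, "importance_mean": self.mean}
        if self.sd is not None:
            data["importance_sd"] = self.sd
        return pd.DataFrame(data).sort_values("importance_mean", ascending=False)


@dataclass
class SurrogateResult:
    tree: BaseDecisionTree
    fidelity: float
    rules: list[str]


# ---------------------------------------------------------------------------
# model adapters


def _as_output_fn(model) -> Callable[[np.ndarray], np.ndarray]:
    """Scalar output convention: P(pain) for classifiers, prediction for regressors."""
    if callable(model) and not hasattr(model, "predict"):
        return model
    if is_classifier(model):
        def fn(X: np.ndarray) -> np.ndarray:
            proba = model.predict_proba(np.asarray(X))
            return proba[:, -1]
        return fn
    return lambda X: np.asarray(model.predict(np.asarray(X)), dtype=float)


def _component_trees(model) -> tuple[list, bool]:
    """The individual fitted trees of an ensemble (or [model] for a single tree)."""
    if isinstance(model, (RandomForestClassifier, RandomForestRegressor)):
        return list(model.estimators_), is_classifier(model)
    if isinstance(model, BaseDecisionTree):
        return [model], is_classifier(model)
    raise ValidationError(
        f"unsupported model type {type(model).__name__}: tree_shapley needs a "
        "decision tree or random forest"
    )


def _leaf_paths(tree, classifier: bool) -> list[tuple[float, dict[int, list[tuple[float, bool]]]]]:
    """Per leaf: (leaf value, {feature: [(threshold, is_left_branch), ...]})."""
    t = tree.tree_
    leaves: list[tuple[float, dict[int, list[tuple[float, bool]]]]] = []

    def walk(node: int, conds: dict[int, list[tuple[float, bool]]]) -> None:
        if t.children_left[node] == -1:
            val = t.value[node].ravel()
            if classifier:
                total = val.sum()
                value = float(val[-1] / total) if total > 0 else 0.0
            else:
                value = float(val[0])
            leaves.append((value, {f: list(c) for f, c in conds.items()}))
            return
        f, thr = int(t.feature[node]), float(t.threshold[node])
        conds.setdefault(f, []).append((thr, True))
        walk(int(t.children_left[node]), conds)
        conds[f][-1] = (thr, False)
        walk(int(t.children_right[node]), conds)
        conds[f].pop()
        if not conds[f]:
            del conds[f]

    walk(0, {})
    return leaves


def _satisfies(values: np.ndarray, conds: list[tuple[float, bool]]) -> np.ndarray:
    """Whether each value passes every split condition on one feature."""
    ok = np.ones(values.shape[0], dtype=bool)
    for thr, is_left in conds:
        ok &= (values <= thr) if is_left else (values > thr)
    return ok


def _weight_tables(n_max: int) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form Shapley weights for the leaf game [U in S, V disjoint S].

    wp[u, v] = (u-1)! v! / (u+v)!  (contribution of each present-side feature)
    wm[u, v] = u! (v-1)! / (u+v)!  (magnitude for each absent-side feature)
    """
    fact = np.array([factorial(i) for i in range(2 * n_max + 1)], dtype=float)
    wp = np.zeros((n_max + 1, n_max + 1))
    wm = np.zeros((n_max + 1, n_max + 1))
    for u in range(n_max + 1):
        for v in range(n_max + 1):
            if u >= 1:
                wp[u, v] = fact[u - 1] * fact[v] / fact[u + v]
            if v >= 1:
                wm[u, v] = fact[u] * fact[v - 1] / fact[u + v]
    return wp, wm


# ---------------------------------------------------------------------------
# Shapley values


def exact_shapley(
    model_fn,
    row: np.ndarray,
    background: np.ndarray,
    feature_subset_size_limit: int = EXACT_SUBSET_LIMIT,
    feature_names: Sequence[str] | None = None,
) -> ShapleyExplanation:
    """Shapley values by full subset enumeration (the independent oracle).

    ``f(S)`` is the model on ``row`` with features outside ``S`` replaced by
    background values, averaged over the background set. Exact but
    exponential in the number of features; refuses more than
    ``feature_subset_size_limit`` and points the caller at the tree
    estimator instead.
    """
    fn = _as_output_fn(model_fn)
    row = np.asarray(row, dtype=float).ravel()
    background = np.atleast_2d(np.asarray(background, dtype=float))
    n = row.size
    if n > feature_subset_size_limit:
        raise ValidationError(
            f"{n} features exceeds the exact-enumeration limit "
            f"({feature_subset_size_limit}); use tree_shapley or a sampled estimator"
        )
    m = background.shape[0]
    # f(S) for every subset bitmask
    f_of = np.empty(1 << n)
    for mask in range(1 << n):
        comp = background.copy()
        for i in range(n):
            if mask >> i & 1:
                comp[:, i] = row[i]
        f_of[mask] = float(np.mean(fn(comp)))
    fact = [factorial(i) for i in range(n + 1)]
    phi = np.zeros(n)
    for i in range(n):
        bit = 1 << i
        for mask in range(1 << n):
            if mask & bit:
                continue
            s = bin(mask).count("1")
            w = fact[s] * fact[n - s - 1] / fact[n]
            phi[i] += w * (f_of[mask | bit] - f_of[mask])
    full = (1 << n) - 1
    return ShapleyExplanation(
        base_value=float(f_of[0]),
        phi=phi,
        model_output=float(f_of[full]),
        feature_names=list(feature_names) if feature_names is not None else None,
    )


def tree_shapley(
    model,
    rows: np.ndarray,
    background: np.ndarray,
    feature_names: Sequence[str] | None = None,
) -> list[ShapleyExplanation]:
    """Interventional Shapley values for tree ensembles, exact per background row.

    For each (tree, background row z) the model restricted to the hybrid
    inputs is a sum over leaves of AND-games: a leaf is reached iff every
    path feature where the explained row x and z diverge takes x's branch
    (set U) or z's branch (set V) as subset membership dictates. The Shapley
    value of such a game has the closed form (|U|-1)! |V|! / (|U|+|V|)! per
    U-feature (negated analogue for V), so exact attributions cost one pass
    over the leaves - no subset enumeration. Averaging over trees and
    background rows yields values identical to :func:`exact_shapley`.
    """
    trees, classifier = _component_trees(model)
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    Z = np.atleast_2d(np.asarray(background, dtype=float))
    m = Z.shape[0]
    n_feat = rows.shape[1]
    wp, wm = _weight_tables(64)
    fn = _as_output_fn(model)
    base = float(np.mean(fn(Z)))
    outputs = fn(rows)

    # background split satisfaction per leaf does not depend on the explained
    # row; evaluate it once
    prepared = []
    for t in trees:
        for value, conds in _leaf_paths(t, classifier):
            feats = list(conds.keys())
            if not feats:
                continue  # constant tree: contributes to base only
            B = np.column_stack([_satisfies(Z[:, f], conds[f]) for f in feats])
            prepared.append((value, feats, conds, B))

    explanations = []
    for r_idx in range(rows.shape[0]):
        x = rows[r_idx]
        phi = np.zeros(n_feat)
        for value, feats, conds, B in prepared:
            a = np.array([_satisfies(x[f][None], conds[f])[0] for f in feats])
            dead = np.any(~a[None, :] & ~B, axis=1)
            if dead.all():
                continue
            U = a[None, :] & ~B  # (m, k) x-side divergences
            V = ~a[None, :] & B  # z-side divergences
            u = U.sum(axis=1)
            v = V.sum(axis=1)
            alive = ~dead
            wpu = np.where(alive, wp[u, v], 0.0)
            wmu = np.where(alive, wm[u, v], 0.0)
            contrib = value * (U * wpu[:, None] - V * wmu[:, None]).sum(axis=0)
            for j, f in enumerate(feats):
                phi[f] += contrib[j]
        phi /= len(trees) * m
        explanations.append(
            ShapleyExplanation(
                base_value=base,
                phi=phi,
                model_output=float(outputs[r_idx]),
                feature_names=list(feature_names) if feature_names is not None else None,
            )
        )
    return explanations


def shapley_interaction(
    model,
    rows: np.ndarray,
    background: np.ndarray,
    pair: tuple[int, int] | None = None,
) -> np.ndarray:
    """Shapley interaction values for a tree ensemble.

    ``Phi[i, j]`` (i != j) is half the change in feature i's Shapley value
    when j is forced present versus forced absent - zero for additive
    models. The diagonal holds each feature's main effect, defined so every
    row sums to that feature's Shapley value. Returns an array of shape
    (n_rows, n_features, n_features), or (n_rows,) values for one ``pair``.
    """
    trees, classifier = _component_trees(model)
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    Z = np.atleast_2d(np.asarray(background, dtype=float))
    m = Z.shape[0]
    n_feat = rows.shape[1]
    wp, wm = _weight_tables(64)
    all_leaves = [_leaf_paths(t, classifier) for t in trees]

    phis = tree_shapley(model, rows, Z)
    out = np.zeros((rows.shape[0], n_feat, n_feat))
    for r_idx in range(rows.shape[0]):
        x = rows[r_idx]
        inter = np.zeros((n_feat, n_feat))
        for leaves in all_leaves:
            for value, conds in leaves:
                feats = list(conds.keys())
                if len(feats) < 2:
                    continue
                a = np.array([_satisfies(x[f][None], conds[f])[0] for f in feats])
                B = np.column_stack([_satisfies(Z[:, f], conds[f]) for f in feats])
                dead = np.any(~a[None, :] & ~B, axis=1)
                U = a[None, :] & ~B
                V = ~a[None, :] & B
                u = U.sum(axis=1)
                v = V.sum(axis=1)
                for z_idx in range(m):
                    if dead[z_idx]:
                        continue
                    uu, vv = int(u[z_idx]), int(v[z_idx])
                    if uu + vv < 2:
                        continue
                    u_feats = [feats[k] for k in range(len(feats)) if U[z_idx, k]]
                    v_feats = [feats[k] for k in range(len(feats)) if V[z_idx, k]]
                    # phi_i with j forced present minus j forced absent, halved
                    for i_f in u_feats:
                        for j_f in u_feats:
                            if i_f == j_f:
                                continue
                            inter[i_f, j_f] += 0.5 * value * wp[uu - 1, vv]
                        for j_f in v_feats:
                            inter[i_f, j_f] -= 0.5 * value * wp[uu, vv - 1]
                    for i_f in v_feats:
                        for j_f in u_feats:
                            inter[i_f, j_f] -= 0.5 * value * wm[uu - 1, vv]
                        for j_f in v_feats:
                            if i_f == j_f:
                                continue
                            inter[i_f, j_f] += 0.5 * value * wm[uu, vv - 1]
        inter /= len(trees) * m
        np.fill_diagonal(inter, 0.0)
        inter = 0.5 * (inter + inter.T)  # enforce symmetry against float drift
        main = phis[r_idx].phi - inter.sum(axis=1)
        inter[np.diag_indices(n_feat)] = main
        out[r_idx] = inter
    if pair is not None:
        i, j = pair
        return out[:, i, j]
    return out


# ---------------------------------------------------------------------------
# importances


def gini_importance(ensemble, feature_names: Sequence[str] | None = None) -> ImportanceReport:
    """Mean decrease in impurity, normalized to sum to 1."""
    imp = np.asarray(ensemble.feature_importances_, dtype=float)
    total = imp.sum()
    imp = imp / total if total > 0 else np.full_like(imp, 1.0 / len(imp))
    names = list(feature_names) if feature_names is not None else [
        f"f{i}" for i in range(len(imp))
    ]
    return ImportanceReport(
        method="gini", features=names, mean=imp, sd=None, n_repeats=1,
        metric_name="impurity_decrease",
    )


def permutation_importance(
    model,
    X: np.ndarray | pd.DataFrame,
    y: np.ndarray,
    metric: str = "accuracy",
    n_repeats: int = 100,
    seed: int = 0,
    feature_names: Sequence[str] | None = None,
) -> ImportanceReport:
    """Performance drop when each feature is shuffled, repeated ``n_repeats`` times.

    importance = baseline metric - mean permuted metric, with the SD over
    repeats quantifying shuffle noise. Accuracy is only valid for
    classifiers and R^2 only for regressors.
    """
    if isinstance(X, pd.DataFrame):
        feature_names = feature_names or list(X.columns)
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if metric == "accuracy":
        if not (is_classifier(model) or hasattr(model, "predict_proba")):
            raise ValidationError("accuracy metric requires a classifier")
        score = lambda Xe: accuracy_score(y, model.predict(Xe))
    elif metric == "r2":
        if is_classifier(model):
            raise ValidationError("r2 metric requires a regressor")
        score = lambda Xe: r2_score(y, model.predict(Xe))
    else:
        raise ValidationError(f"metric must be 'accuracy' or 'r2', got {metric!r}")

    baseline = score(X)
    n_feat = X.shape[1]
    drops = np.empty((n_feat, n_repeats))
    for j in range(n_feat):
        for r in range(n_repeats):
            rng = rng_for(child_seed(seed, f"perm-{j}"), f"rep-{r}")
            Xp = X.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            drops[j, r] = baseline - score(Xp)
    names = list(feature_names) if feature_names is not None else [
        f"f{i}" for i in range(n_feat)
    ]
    return ImportanceReport(
        method="permutation",
        features=names,
        mean=drops.mean(axis=1),
        sd=drops.std(axis=1, ddof=1) if n_repeats > 1 else None,
        n_repeats=n_repeats,
        metric_name=metric,
    )


# ---------------------------------------------------------------------------
# PDP / ICE


def partial_dependence_ice(
    model,
    X: pd.DataFrame | np.ndarray,
    feature: str | int,
    grid: np.ndarray | None = None,
    n_grid: int = 50,
    percentile_range: tuple[float, float] = (1.0, 99.0),
) -> PDPResult:
    """ICE curves (one per instance) and their exact mean, the partial dependence.

    ``ice[i, j]`` is the model output on row i with the target feature set
    to ``grid[j]``; the grid spans the 1st-99th percentile of the observed
    values by default.
    """
    if isinstance(X, pd.DataFrame):
        if isinstance(feature, str):
            col_idx = X.columns.get_loc(feature)
            feat_name = feature
        else:
            col_idx, feat_name = int(feature), str(X.columns[feature])
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.asarray(X, dtype=float)
        col_idx = int(feature)
        feat_name = f"f{col_idx}"
    if not np.issubdtype(Xa[:, col_idx].dtype, np.number):
        raise ValidationError(f"feature {feat_name} is not numeric")
    fn = _as_output_fn(model)
    if grid is None:
        lo, hi = np.percentile(Xa[:, col_idx], percentile_range)
        if lo == hi:
            grid = np.array([lo])
        else:
            grid = np.linspace(lo, hi, n_grid)
    grid = np.asarray(grid, dtype=float)
    ice = np.empty((Xa.shape[0], grid.size))
    for j, value in enumerate(grid):
        Xg = Xa.copy()
        Xg[:, col_idx] = value
        ice[:, j] = fn(Xg)
    return PDPResult(feature=feat_name, grid=grid, pd_values=ice.mean(axis=0), ice=ice)


def ice_phenotypes(
    pdp_result: PDPResult, k: int = 3, seed: int = 0
) -> tuple[np.ndarray, float]:
    """Cluster ICE curve *shapes* into response phenotypes.

    Curves are centered at their leftmost grid value (so clusters reflect
    shape, not offset) and grouped by seeded k-means. Returns (cluster
    assignment per instance, mean within-cluster dispersion).
    """
    curves = pdp_result.ice - pdp_result.ice[:, [0]]
    if k > curves.shape[0]:
        raise ValidationError(f"k={k} exceeds {curves.shape[0]} instances")
    km = KMeans(n_clusters=k, n_init=10, random_state=child_seed(seed, "ice-kmeans"))
    labels = km.fit_predict(curves)
    dispersion = float(km.inertia_ / curves.shape[0])
    return labels, dispersion


# ---------------------------------------------------------------------------
# correlations and surrogate


def feature_correlations(feature_table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise-complete Pearson correlation matrix of the numeric feature columns.

    Zero-variance columns come out as NaN rows/columns (undefined), matching
    the convention that a correlation with a constant has no value.
    """
    numeric = feature_table.select_dtypes(include=[np.number])
    if len(numeric) < 3:
        raise ValidationError("need at least 3 rows for a correlation matrix")
    return numeric.corr(method="pearson")


def _tree_rules(
    tree: BaseDecisionTree, feature_names: Sequence[str], classifier: bool
) -> list[str]:
    t = tree.tree_
    rules: list[str] = []

    def walk(node: int, conds: list[str]) -> None:
        if t.children_left[node] == -1:
            val = t.value[node].ravel()
            if classifier:
                total = val.sum()
                outcome = f"pain_probability = {val[-1] / total:.3f}" if total else "pain_probability = 0"
            else:
                outcome = f"predicted_intensity = {val[0]:.1f}"
            cond_str = " AND ".join(conds) if conds else "TRUE"
            rules.append(f"IF {cond_str} THEN {outcome}")
            return
        name = feature_names[int(t.feature[node])]
        thr = float(t.threshold[node])
        walk(int(t.children_left[node]), conds + [f"{name} <= {thr:.4g}"])
        walk(int(t.children_right[node]), conds + [f"{name} > {thr:.4g}"])

    walk(0, [])
    return rules


def global_surrogate(
    model,
    X: pd.DataFrame | np.ndarray,
    max_depth: int = 5,
    seed: int = 0,
    test_fraction: float = 0.25,
) -> SurrogateResult:
    """Distill the model into a depth-limited decision tree with IF/AND/THEN rules.

    The surrogate is fit to the model's own predictions; fidelity is the
    agreement with those predictions on a held-out subset (accuracy for
    classifiers, R^2 for regressors).
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.asarray(X, dtype=float)
        names = [f"f{i}" for i in range(Xa.shape[1])]
    clf = is_classifier(model)
    y_model = model.predict(Xa)
    rs = child_seed(seed, "surrogate")
    stratify = y_model if clf and len(np.unique(y_model)) > 1 else None
    X_tr, X_te, y_tr, y_te = train_test_split(
        Xa, y_model, test_size=test_fraction, random_state=rs, stratify=stratify
    )
    if clf:
        surrogate = DecisionTreeClassifier(max_depth=max_depth, random_state=rs)
    else:
        surrogate = DecisionTreeRegressor(max_depth=max_depth, random_state=rs)
    surrogate.fit(X_tr, y_tr)
    pred = surrogate.predict(X_te)
    fidelity = float(accuracy_score(y_te, pred)) if clf else float(r2_score(y_te, pred))
    return SurrogateResult(
        tree=surrogate, fidelity=fidelity, rules=_tree_rules(surrogate, names, clf)
    )
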