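"""Two-group stepwise discriminant function analysis (DFA).

Feature selection is driven by Wilks' lambda, ``det(W)/det(T)`` with W the
pooled within-group scatter and T the total scatter on the current feature
subset: small lambda means strong group separation.  At each step the
candidate whose entry most reduces lambda is tested with the partial-F
statistic

    F = (n - g - q) * (lambda_small / lambda_large - 1) / (g - 1)

(g = 2 groups, q = number of features already entered) against entry /
removal probability thresholds (defaults 0.05 / 0.10).  After selection,
Fisher's linear classification functions built from the pooled
within-group covariance assign cases to groups, and the reciprocal
biological-replicate split (train on replicate 1, test on replicate 2 and
vice versa, technical replicates as cases) estimates classification
accuracy.

For a single feature the entry F equals the squared pooled two-sample t,
which ties this module's selection criterion to the univariate statistics
module exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateDataError, InsufficientDataError
from .io import FeatureSignalMatrix

_TINY = 1e-300


@dataclass
class DFAConfig:
    """Stepwise selection and validation settings.

    ``tolerance`` is the minimum fraction of a candidate's within-group
    variance left unexplained by the already-entered features; exact
    duplicates of entered features are excluded by it.  ``max_steps``
    defaults to twice the candidate count (set at fit time when None),
    the conventional stepping bound.
    """

    p_enter: float = 0.05
    p_remove: float = 0.10
    tolerance: float = 1e-8
    max_steps: int | None = None
    priors: Literal["equal", "proportional"] = "equal"
    select_on: Literal["all", "training"] = "all"

    def __post_init__(self) -> None:
        if not self.p_enter < self.p_remove:
            raise ValueError("p_enter must be < p_remove")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")


@dataclass
class StepRecord:
    step: int
    action: str  # "enter" | "remove"
    feature: str
    wilks_lambda: float
    F: float
    p: float


@dataclass
class DFAResult:
    """Outcome of one two-group discriminant analysis."""

    comparison_id: str
    selected: list[str]
    trace: list[StepRecord] = field(default_factory=list)
    coefficients: dict | None = None
    training_accuracy_percent: float | None = None
    test_accuracy_percent: float | None = None
    directions: dict = field(default_factory=dict)

    @property
    def lambda_trace(self) -> list[float]:
        return [r.wilks_lambda for r in self.trace if r.action == "enter"]


# ---------------------------------------------------------------------------
# scatter matrices and Wilks' lambda
# ---------------------------------------------------------------------------

def _check_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, list]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be cases x features with one label per case")
    groups = sorted(pd.unique(y).tolist())
    if len(groups) != 2:
        raise ValueError(f"exactly two groups required, got {groups}")
    for gr in groups:
        if (y == gr).sum() < 2:
            raise InsufficientDataError(f"group {gr!r} has fewer than 2 cases")
    return X, y, groups


def scatter_matrices(
    X: np.ndarray, y: np.ndarray, subset: Sequence[int]
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled within-group scatter W and total scatter T on a subset."""
    X, y, groups = _check_xy(X, y)
    sub = list(subset)
    Xs = X[:, sub]
    grand = Xs.mean(axis=0)
    Xc = Xs - grand
    T = Xc.T @ Xc
    W = np.zeros_like(T)
    for gr in groups:
        Xg = Xs[y == gr]
        Gc = Xg - Xg.mean(axis=0)
        W += Gc.T @ Gc
    return W, T


def wilks_lambda(X: np.ndarray, y: np.ndarray, subset: Sequence[int]) -> float:
    """det(W)/det(T) on the given feature subset; 1.0 for the empty set."""
    if len(subset) == 0:
        return 1.0
    W, T = scatter_matrices(X, y, subset)
    det_t = float(np.linalg.det(T))
    if det_t <= 0:
        raise DegenerateDataError(
            "total scatter is singular on the requested subset"
        )
    det_w = float(np.linalg.det(W))
    lam = det_w / det_t
    return min(max(lam, 0.0), 1.0)


def partial_f(
    X: np.ndarray,
    y: np.ndarray,
    current_subset: Sequence[int],
    candidate: int,
    mode: Literal["enter", "remove"] = "enter",
) -> tuple[float, float]:
    """Partial-F statistic and p-value for entering/removing a feature.

    Both modes compare the same nested pair of subsets; removal of the
    most recently entered feature reproduces its entry test exactly.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    g = 2
    current = list(current_subset)
    if mode == "enter":
        if candidate in current:
            raise ValueError("candidate already entered")
        small, large = current, current + [candidate]
        q = len(current)
    elif mode == "remove":
        if candidate not in current:
            raise ValueError("candidate not in subset")
        large = current
        small = [j for j in current if j != candidate]
        q = len(current) - 1
    else:
        raise ValueError(f"unknown mode {mode!r}")
    df2 = n - g - q
    if df2 <= 0:
        raise InsufficientDataError(
            f"no residual degrees of freedom (n={n}, entered={q})"
        )
    lam_small = wilks_lambda(X, y, small)
    lam_large = wilks_lambda(X, y, large)
    if lam_large <= _TINY:
        return math.inf, 0.0
    F = df2 * (lam_small / lam_large - 1.0) / (g - 1)
    F = max(F, 0.0)
    p = float(sps.f.sf(F, g - 1, df2))
    return F, p


def within_group_tolerance(
    X: np.ndarray, y: np.ndarray, subset: Sequence[int], candidate: int
) -> float:
    """1 - R^2 of the candidate on the entered subset, within groups."""
    sub = list(subset)
    W, _ = scatter_matrices(X, y, sub + [candidate])
    w_cc = W[-1, -1]
    if w_cc <= 0:
        # candidate constant within groups: either informative
        # (between-group variance remains) or globally constant
        _, T = scatter_matrices(X, y, [candidate])
        return 1.0 if T[0, 0] > 0 else 0.0
    if not sub:
        return 1.0
    W_ss = W[:-1, :-1]
    w_cs = W[:-1, -1]
    try:
        r2 = float(w_cs @ np.linalg.solve(W_ss, w_cs)) / w_cc
    except np.linalg.LinAlgError:
        return 0.0
    return max(0.0, 1.0 - r2)


# ---------------------------------------------------------------------------
# stepwise selection
# ---------------------------------------------------------------------------

def stepwise_select(
    X: np.ndarray,
    y: np.ndarray,
    config: DFAConfig | None = None,
    feature_names: Sequence[str] | None = None,
) -> tuple[list[str], list[StepRecord]]:
    """Wilks'-lambda stepwise feature selection for two groups.

    Enter the candidate with the smallest entry p-value while it is below
    ``p_enter``; after each entry remove entered features whose removal
    p-value exceeds ``p_remove``.  Ties break by smaller p, then
    lexicographic feature name.  Stops when no candidate qualifies, when a
    subset state repeats (cycle guard) or at ``max_steps``.
    """
    config = config or DFAConfig()
    X, y, _ = _check_xy(X, y)
    p_feat = X.shape[1]
    names = list(feature_names) if feature_names is not None else [
        f"f{j}" for j in range(p_feat)
    ]
    if len(names) != p_feat:
        raise ValueError("feature_names length mismatch")
    max_steps = config.max_steps if config.max_steps is not None else 2 * p_feat
    entered: list[int] = []
    trace: list[StepRecord] = []
    seen_states: set[frozenset] = set()
    step = 0
    while step < max_steps:
        step += 1
        n = X.shape[0]
        if n - 2 - len(entered) <= 0:
            break
        best: tuple[float, str, int, float] | None = None  # (p, name, idx, F)
        for j in range(p_feat):
            if j in entered:
                continue
            if within_group_tolerance(X, y, entered, j) < config.tolerance:
                continue
            try:
                F, p = partial_f(X, y, entered, j, mode="enter")
            except (DegenerateDataError, InsufficientDataError):
                continue
            key = (p, names[j])
            if best is None or key < (best[0], best[1]):
                best = (p, names[j], j, F)
        if best is None or best[0] >= config.p_enter:
            break
        p_best, name_best, j_best, f_best = best
        entered.append(j_best)
        trace.append(
            StepRecord(
                step=step,
                action="enter",
                feature=name_best,
                wilks_lambda=wilks_lambda(X, y, entered),
                F=f_best,
                p=p_best,
            )
        )
        # removal phase: peel off entered features that lost significance
        while len(entered) > 1:
            worst: tuple[float, str, int, float] | None = None
            for j in entered:
                try:
                    F, p = partial_f(X, y, entered, j, mode="remove")
                except (DegenerateDataError, InsufficientDataError):
                    continue
                key = (-p, names[j])
                if worst is None or key < (-worst[0], worst[1]):
                    worst = (p, names[j], j, F)
            if worst is None or worst[0] <= config.p_remove:
                break
            p_w, name_w, j_w, f_w = worst
            entered.remove(j_w)
            trace.append(
                StepRecord(
                    step=step,
                    action="remove",
                    feature=name_w,
                    wilks_lambda=wilks_lambda(X, y, entered),
                    F=f_w,
                    p=p_w,
                )
            )
        state = frozenset(entered)
        if state in seen_states:
            break
        seen_states.add(state)
    return [names[j] for j in entered], trace


# ---------------------------------------------------------------------------
# classification functions
# ---------------------------------------------------------------------------

def fit_classification_functions(
    X: np.ndarray,
    y: np.ndarray,
    selected: Sequence[int] | None = None,
    priors: Literal["equal", "proportional"] = "equal",
) -> dict:
    """Fisher's linear classification functions for two groups.

    For group k: score_k(x) = mu_k' S^-1 x - 0.5 mu_k' S^-1 mu_k +
    ln(prior_k), with S the pooled within-group covariance on the selected
    features.  Returns ``{label: {"coef": array, "const": float}}``.
    """
    X, y, groups = _check_xy(X, y)
    sel = list(selected) if selected is not None else list(range(X.shape[1]))
    if not sel:
        raise InsufficientDataError("no features selected")
    Xs = X[:, sel]
    n = Xs.shape[0]
    W, _ = scatter_matrices(X, y, sel)
    S = W / (n - len(groups))
    try:
        S_inv = np.linalg.inv(S)
    except np.linalg.LinAlgError as exc:
        raise DegenerateDataError(
            "pooled within-group covariance is singular"
        ) from exc
    if not np.all(np.isfinite(S_inv)):
        raise DegenerateDataError("pooled within-group covariance is singular")
    functions = {}
    for gr in groups:
        mu = Xs[y == gr].mean(axis=0)
        prior = 0.5 if priors == "equal" else float((y == gr).mean())
        coef = S_inv @ mu
        const = -0.5 * float(mu @ coef) + math.log(prior)
        functions[gr] = {"coef": coef, "const": const, "indices": sel}
    return functions


def classify(functions: dict, X: np.ndarray) -> np.ndarray:
    """Assign each case to the group with the highest classification score.

    Exact ties go to the lexicographically first group label.
    """
    X = np.asarray(X, dtype=float)
    labels = sorted(functions)
    sel = functions[labels[0]]["indices"]
    Xs = X[:, sel]
    scores = np.column_stack(
        [Xs @ functions[gr]["coef"] + functions[gr]["const"] for gr in labels]
    )
    return np.asarray(labels, dtype=object)[np.argmax(scores, axis=1)]


def _accuracy_percent(predicted: np.ndarray, truth: np.ndarray) -> float:
    return 100.0 * float(np.mean(predicted == truth))


# ---------------------------------------------------------------------------
# reciprocal biological-replicate validation
# ---------------------------------------------------------------------------

def case_matrix(
    matrix: FeatureSignalMatrix,
    bulks: Sequence[str],
    features: Sequence[str],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Technical replicates of the given bulks as DFA cases.

    Returns (X cases x features, labels, biological replicate per case,
    kept feature names).  Features with any masked or missing value among
    these cases are dropped.
    """
    cols: list[str] = []
    labels: list[str] = []
    bio: list[int] = []
    for b in bulks:
        d = matrix.design[matrix.design["target"] == b]
        d = d.sort_values(["biological_replicate", "technical_replicate"])
        cols.extend(d.index)
        labels.extend([b] * len(d))
        bio.extend(d["biological_replicate"].tolist())
    if not cols:
        raise InsufficientDataError(f"no hybridizations for bulks {bulks}")
    vals = matrix.values.loc[list(features), cols]
    ok = ~matrix.mask.loc[list(features), cols]
    usable = ok.all(axis=1) & vals.notna().all(axis=1)
    kept = [f for f in features if usable[f]]
    X = vals.loc[kept].T.to_numpy(dtype=float)
    return X, np.asarray(labels, dtype=object), np.asarray(bio), kept


def _direction_eval(
    X: np.ndarray,
    y: np.ndarray,
    bio: np.ndarray,
    train_rep: int,
    test_rep: int,
    config: DFAConfig,
    names: list[str],
    global_selection: list[str] | None,
) -> dict:
    train = bio == train_rep
    test = bio == test_rep
    for gr in np.unique(y):
        if (y[train] == gr).sum() < 2:
            raise InsufficientDataError(
                f"fewer than 2 training cases for group {gr!r}"
            )
    if global_selection is None:
        sel_names, trace = stepwise_select(
            X[train], y[train], config, feature_names=names
        )
    else:
        sel_names, trace = global_selection, []
    idx = [names.index(s) for s in sel_names]
    labels = sorted(np.unique(y).tolist())
    note = ""
    if idx:
        try:
            functions = fit_classification_functions(
                X[train], y[train], idx, priors=config.priors
            )
        except DegenerateDataError:
            # more selected features than the training split can support
            return {
                "selected": sel_names,
                "trace": trace,
                "functions": None,
                "training_accuracy_percent": math.nan,
                "test_accuracy_percent": math.nan,
                "note": "singular pooled covariance on the training split",
            }
        if len(idx) > train.sum() - len(labels):
            note = "selection exceeds training degrees of freedom"
        pred_train = classify(functions, X[train])
        pred_test = classify(functions, X[test])
    else:
        # empty selection: equal priors give a tie, resolved to the
        # lexicographically first label
        functions = None
        pred_train = np.full(train.sum(), labels[0], dtype=object)
        pred_test = np.full(test.sum(), labels[0], dtype=object)
    return {
        "selected": sel_names,
        "trace": trace,
        "functions": functions,
        "training_accuracy_percent": _accuracy_percent(pred_train, y[train]),
        "test_accuracy_percent": _accuracy_percent(pred_test, y[test]),
        "note": note,
    }


def reciprocal_cross_validate(
    matrix: FeatureSignalMatrix,
    comparison: Sequence[str],
    config: DFAConfig | None = None,
    features: Sequence[str] | None = None,
) -> DFAResult:
    """Train on one biological replicate, test on the other, both ways.

    Cases are technical replicates (6 per group per direction in the
    reference design).  With ``select_on="all"`` (default) the stepwise
    selection runs once on all cases and Table-style per-direction
    accuracies are computed for that single feature set; with
    ``select_on="training"`` selection is repeated on each direction's
    training cases.
    """
    config = config or DFAConfig()
    if features is None:
        features = matrix.features_of_category("subtracted")
    X, y, bio, names = case_matrix(matrix, comparison, features)
    reps = sorted(np.unique(bio).tolist())
    if len(reps) < 2:
        raise InsufficientDataError(
            "reciprocal validation needs >=2 biological replicates"
        )
    r1, r2 = reps[0], reps[1]
    comparison_id = "-".join(comparison)
    if config.select_on == "all":
        selected, trace = stepwise_select(X, y, config, feature_names=names)
        global_sel: list[str] | None = selected
    else:
        global_sel, trace = None, []
    d_forward = _direction_eval(X, y, bio, r1, r2, config, names, global_sel)
    d_reciprocal = _direction_eval(X, y, bio, r2, r1, config, names, global_sel)
    if config.select_on == "training":
        selected = d_forward["selected"]
        trace = d_forward["trace"]
    train_acc = np.mean(
        [d_forward["training_accuracy_percent"], d_reciprocal["training_accuracy_percent"]]
    )
    test_acc = np.mean(
        [d_forward["test_accuracy_percent"], d_reciprocal["test_accuracy_percent"]]
    )
    coeffs = d_forward["functions"]
    if coeffs is not None:
        coeffs = {
            gr: {"coef": f["coef"].tolist(), "const": f["const"]}
            for gr, f in coeffs.items()
        }
    return DFAResult(
        comparison_id=comparison_id,
        selected=list(selected),
        trace=trace,
        coefficients=coeffs,
        training_accuracy_percent=float(train_acc),
        test_accuracy_percent=float(test_acc),
        directions={
            "forward": {
                k: v for k, v in d_forward.items() if k not in ("functions", "trace")
            },
            "reciprocal": {
                k: v for k, v in d_reciprocal.items() if k not in ("functions", "trace")
            },
        },
    )
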