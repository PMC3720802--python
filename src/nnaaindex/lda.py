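"""Stepwise linear discriminant analysis for two-class peptide data.

Variables enter and leave the discriminant function by the partial-F
statistic derived from Wilks' lambda (default thresholds: enter when
F > 3.84, remove when F < 2.71, the conventional 5% / 10% nominal levels).
The fitted classifier is the two-class Fisher discriminant
Y = a0 + a1 X1 + ... + an Xn with a pooled within-class covariance; LOO
classification metrics (accuracy, sensitivity, specificity, MCC) treat the
biologically active class as positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LDAModel",
    "ConfusionStats",
    "stepwise_select",
    "fit_lda",
    "loo_classify",
]

_EPS = 1e-12


@dataclass
class ConfusionStats:
    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n

    @property
    def sensitivity(self) -> float:
        pos = self.tp + self.fn
        return self.tp / pos if pos else 0.0

    @property
    def specificity(self) -> float:
        neg = self.tn + self.fp
        return self.tn / neg if neg else 0.0

    @property
    def mcc(self) -> float:
        """Matthews correlation coefficient; 0 when a marginal is empty."""
        tp, fn, tn, fp = self.tp, self.fn, self.tn, self.fp
        denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        if denom == 0:
            return 0.0
        return (tp * tn - fp * fn) / np.sqrt(denom)

    @classmethod
    def from_predictions(cls, y_true, y_pred, positive) -> "ConfusionStats":
        yt = np.asarray(y_true)
        yp = np.asarray(y_pred)
        t = yt == positive
        p = yp == positive
        return cls(
            tp=int((t & p).sum()),
            fn=int((t & ~p).sum()),
            tn=int((~t & ~p).sum()),
            fp=int((~t & p).sum()),
        )


@dataclass
class LDAModel:
    selected_variables: list[int]
    variable_names: list[str]
    classes: tuple          # (negative, positive)
    priors: np.ndarray      # aligned with classes
    intercept: float        # a0
    coefficients: np.ndarray            # a1..an on selected variables
    standardized_coefficients: np.ndarray
    group_means: np.ndarray             # 2 x n_selected
    pooled_covariance: np.ndarray

    def decision_scores(self, X) -> np.ndarray:
        """a0 + a.x on the selected variables; > 0 means the positive class."""
        X = np.atleast_2d(np.asarray(X, float))
        if X.shape[1] == len(self.variable_names):
            X = X[:, self.selected_variables]
        elif X.shape[1] != len(self.selected_variables):
            raise ValueError(
                f"expected {len(self.variable_names)} (full) or "
                f"{len(self.selected_variables)} (selected) columns, "
                f"got {X.shape[1]}"
            )
        return self.intercept + X @ self.coefficients

    def predict(self, X) -> np.ndarray:
        s = self.decision_scores(X)
        return np.where(s > 0, self.classes[1], self.classes[0])

    def posterior_positive(self, X) -> np.ndarray:
        """Posterior probability of the positive class (equal-covariance
        Gaussian model => logistic of the decision score)."""
        return 1.0 / (1.0 + np.exp(-self.decision_scores(X)))

    def to_dict(self) -> dict:
        return {
            "kind": "lda",
            "selected_variables": list(map(int, self.selected_variables)),
            "variable_names": list(self.variable_names),
            "classes": list(self.classes),
            "priors": self.priors.tolist(),
            "intercept": float(self.intercept),
            "coefficients": self.coefficients.tolist(),
            "standardized_coefficients": self.standardized_coefficients.tolist(),
            "group_means": self.group_means.tolist(),
            "pooled_covariance": self.pooled_covariance.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LDAModel":
        return cls(
            selected_variables=list(map(int, d["selected_variables"])),
            variable_names=list(d["variable_names"]),
            classes=tuple(d["classes"]),
            priors=np.asarray(d["priors"], float),
            intercept=float(d["intercept"]),
            coefficients=np.asarray(d["coefficients"], float),
            standardized_coefficients=np.asarray(
                d["standardized_coefficients"], float
            ),
            group_means=np.asarray(d["group_means"], float),
            pooled_covariance=np.asarray(d["pooled_covariance"], float),
        )


def _check_two_classes(labels: np.ndarray):
    classes = sorted(pd.unique(labels).tolist())
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {classes}")
    counts = [(labels == c).sum() for c in classes]
    if min(counts) < 2:
        raise ValueError("each class needs at least 2 samples")
    return classes


def _wilks_lambda(X: np.ndarray, groups: np.ndarray, cols) -> float:
    """Wilks' lambda det(W)/det(T) on the given columns."""
    cols = list(cols)
    if not cols:
        return 1.0
    Xs = X[:, cols]
    grand = Xs.mean(axis=0)
    T = (Xs - grand).T @ (Xs - grand)
    W = np.zeros_like(T)
    for g in np.unique(groups):
        Xg = Xs[groups == g]
        cg = Xg.mean(axis=0)
        W += (Xg - cg).T @ (Xg - cg)
    sT, ldT = np.linalg.slogdet(T)
    sW, ldW = np.linalg.slogdet(W)
    if sT <= 0:
        return 1.0  # degenerate total scatter: no discrimination possible
    if sW <= 0:
        return 0.0  # perfect separation / singular within-scatter
    return float(np.exp(ldW - ldT))


def _partial_f(lam_without: float, lam_with: float, n: int, g: int,
               p_in: int) -> float:
    """Partial F for adding one variable to p_in already-included ones."""
    df2 = n - g - p_in
    if df2 <= 0:
        return 0.0
    if lam_with <= _EPS:
        return np.inf
    return (df2 / (g - 1)) * (lam_without / lam_with - 1.0)


def stepwise_select(X, labels, f_enter: float = 3.84,
                    f_remove: float = 2.71) -> list[int]:
    """Forward stepwise selection with backward elimination on partial F.

    A variable enters when its partial F (from the Wilks' lambda change)
    exceeds ``f_enter`` and is removed when it drops below ``f_remove``.
    Ties resolve to the lower column index; the procedure is deterministic.
    """
    X = np.asarray(X, float)
    labels = np.asarray(labels)
    n, p = X.shape
    _check_two_classes(labels)
    g = 2
    selected: list[int] = []
    # feasibility cap: more variables than this would leave the pooled
    # within-class covariance rank-deficient in a leave-one-out refit
    max_in = max(n - g - 2, 1)
    max_steps = 4 * p + 4
    for _ in range(max_steps):
        changed = False
        lam_cur = _wilks_lambda(X, labels, selected)
        # entry (skip once separation is already perfect: no candidate can
        # reduce Wilks' lambda further)
        best_j, best_f = -1, -np.inf
        if (lam_cur > _EPS and len(selected) < max_in
                and n - g - len(selected) >= 1):
            for j in range(p):
                if j in selected:
                    continue
                lam_j = _wilks_lambda(X, labels, selected + [j])
                f = _partial_f(lam_cur, lam_j, n, g, len(selected))
                if f > best_f:
                    best_j, best_f = j, f
        entered = -1
        if best_j >= 0 and best_f > f_enter:
            selected.append(best_j)
            entered = best_j
            changed = True
        # removal
        while len(selected) > 1:
            lam_full = _wilks_lambda(X, labels, selected)
            worst_j, worst_f = -1, np.inf
            for j in sorted(selected):
                rest = [k for k in selected if k != j]
                lam_rest = _wilks_lambda(X, labels, rest)
                f = _partial_f(lam_rest, lam_full, n, g, len(rest))
                if f < worst_f:
                    worst_j, worst_f = j, f
            if worst_f < f_remove and worst_j != entered:
                selected.remove(worst_j)
                changed = True
            else:
                break
        if not changed:
            break
    if not selected:
        raise ValueError(
            f"no variable reached the entry threshold F>{f_enter}; "
            "review the thresholds or the descriptor set"
        )
    return selected


def fit_lda(X, labels, priors=None, selected: list[int] | None = None,
            variable_names: list[str] | None = None,
            positive=None) -> LDAModel:
    """Two-class Fisher discriminant on the selected variables.

    ``priors`` default to equal; pass "proportional" for empirical class
    frequencies.  The positive class defaults to the lexicographically larger
    label (e.g. "strong" over "moderate").
    """
    X = np.asarray(X, float)
    labels = np.asarray(labels)
    n, p_all = X.shape
    classes = _check_two_classes(labels)
    if positive is None:
        positive = classes[1]
    if positive not in classes:
        raise ValueError(f"positive class {positive!r} not among {classes}")
    negative = classes[0] if positive == classes[1] else classes[1]

    if selected is None:
        selected = list(range(p_all))
    if len(set(selected)) != len(selected) or not selected:
        raise ValueError("selected variables must be non-empty and unique")
    if variable_names is None:
        variable_names = [f"x{j + 1}" for j in range(p_all)]

    Xs = X[:, selected]
    p = Xs.shape[1]
    mask_pos = labels == positive
    mu_pos = Xs[mask_pos].mean(axis=0)
    mu_neg = Xs[~mask_pos].mean(axis=0)
    Sw = ((Xs[mask_pos] - mu_pos).T @ (Xs[mask_pos] - mu_pos)
          + (Xs[~mask_pos] - mu_neg).T @ (Xs[~mask_pos] - mu_neg))
    pooled = Sw / (n - 2)
    if np.linalg.matrix_rank(pooled) < p:
        raise ValueError(
            "pooled within-class covariance is singular; select fewer variables"
        )
    if priors is None:
        pri = np.array([0.5, 0.5])
    elif isinstance(priors, str) and priors == "proportional":
        pri = np.array([(~mask_pos).mean(), mask_pos.mean()])
    else:
        pri = np.asarray(priors, float)
        pri = pri / pri.sum()

    coef = np.linalg.solve(pooled, mu_pos - mu_neg)
    intercept = float(-coef @ (mu_pos + mu_neg) / 2.0 + np.log(pri[1] / pri[0]))
    std_coef = coef * np.sqrt(np.diag(pooled))
    return LDAModel(
        selected_variables=list(selected),
        variable_names=list(variable_names),
        classes=(negative, positive),
        priors=pri,
        intercept=intercept,
        coefficients=coef,
        standardized_coefficients=std_coef,
        group_means=np.vstack([mu_neg, mu_pos]),
        pooled_covariance=pooled,
    )


def loo_classify(X, labels, f_enter: float = 3.84, f_remove: float = 2.71,
                 priors=None, positive=None,
                 mode: str = "paper") -> ConfusionStats:
    """LOO classification metrics for the stepwise LDA model.

    ``mode="paper"`` (default) performs stepwise selection once on the full
    data and cross-validates only the discriminant fit, which matches the
    conventional reporting for small datasets; ``mode="strict"`` repeats the
    selection inside every fold.
    """
    X = np.asarray(X, float)
    labels = np.asarray(labels)
    n = X.shape[0]
    classes = _check_two_classes(labels)
    if positive is None:
        positive = classes[1]
    if mode not in ("paper", "strict"):
        raise ValueError(f"unknown LOO mode {mode!r}")

    selected_full = stepwise_select(X, labels, f_enter, f_remove)
    preds = []
    for i in range(n):
        keep = np.arange(n) != i
        lab_tr = labels[keep]
        if len(np.unique(lab_tr)) < 2:
            raise ValueError(f"fold {i} leaves a single-class training set")
        if mode == "strict":
            sel = stepwise_select(X[keep], lab_tr, f_enter, f_remove)
        else:
            sel = selected_full
        model = fit_lda(X[keep], lab_tr, priors=priors, selected=sel,
                        positive=positive)
        preds.append(model.predict(X[i:i + 1, :])[0])
    return ConfusionStats.from_predictions(labels, np.asarray(preds), positive)
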