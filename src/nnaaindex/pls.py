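"""NIPALS partial least squares with leave-one-out cross-validation.

Univariate-response PLS fitted by the classic NIPALS outer/inner-relation
scheme: per component a weight vector w maximizes covariance between the X
block and the response, the X score t = Xw and response score u are linked by
the inner relation u ~ b t, and both blocks are deflated before the next
component is extracted.  Model quality is reported as calibration R² and
leave-one-out Q² = 1 - PRESS / total sum of squares, with autoscaling
recomputed inside every fold so no information leaks from the held-out sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PLSModel",
    "FitStats",
    "fit_pls",
    "predict",
    "loo_q2",
    "select_components",
    "loo_press_profile",
    "q2_score",
]

_EPS = 1e-12


@dataclass
class FitStats:
    """Fit statistics: calibration R², LOO Q², RMS error, PRESS, sample count."""

    r2: float
    q2: float | None
    rms: float
    press: float | None
    n: int


@dataclass
class PLSModel:
    n_components: int
    variable_names: list[str]
    x_means: np.ndarray
    x_sds: np.ndarray
    y_mean: float
    y_sd: float
    x_weights: np.ndarray       # p x A (W)
    x_loadings: np.ndarray      # p x A (P)
    x_scores: np.ndarray        # n x A (T)
    y_scores: np.ndarray        # n x A (U)
    inner_coefficients: np.ndarray  # length A (b per component)
    y_loadings: np.ndarray      # length A (q)
    coefficients: np.ndarray    # regression vector on original scale
    intercept: float
    fit_stats: FitStats

    def predict(self, X_new) -> np.ndarray:
        return predict(self, X_new)

    def to_dict(self) -> dict:
        return {
            "kind": "pls",
            "n_components": int(self.n_components),
            "variable_names": list(self.variable_names),
            "x_means": self.x_means.tolist(),
            "x_sds": self.x_sds.tolist(),
            "y_mean": float(self.y_mean),
            "y_sd": float(self.y_sd),
            "x_weights": self.x_weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "x_scores": self.x_scores.tolist(),
            "y_scores": self.y_scores.tolist(),
            "inner_coefficients": self.inner_coefficients.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "coefficients": self.coefficients.tolist(),
            "intercept": float(self.intercept),
            "fit_stats": {
                "r2": self.fit_stats.r2,
                "q2": self.fit_stats.q2,
                "rms": self.fit_stats.rms,
                "press": self.fit_stats.press,
                "n": self.fit_stats.n,
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PLSModel":
        fs = d["fit_stats"]
        return cls(
            n_components=int(d["n_components"]),
            variable_names=list(d["variable_names"]),
            x_means=np.asarray(d["x_means"], float),
            x_sds=np.asarray(d["x_sds"], float),
            y_mean=float(d["y_mean"]),
            y_sd=float(d["y_sd"]),
            x_weights=np.asarray(d["x_weights"], float),
            x_loadings=np.asarray(d["x_loadings"], float),
            x_scores=np.asarray(d["x_scores"], float),
            y_scores=np.asarray(d["y_scores"], float),
            inner_coefficients=np.asarray(d["inner_coefficients"], float),
            y_loadings=np.asarray(d["y_loadings"], float),
            coefficients=np.asarray(d["coefficients"], float),
            intercept=float(d["intercept"]),
            fit_stats=FitStats(
                r2=fs["r2"], q2=fs["q2"], rms=fs["rms"],
                press=fs["press"], n=int(fs["n"]),
            ),
        )


def q2_score(y_true, y_pred, y_mean: float | None = None) -> float:
    """1 - sum((y - yhat)^2) / sum((y - ybar)^2).

    ``y_mean`` defaults to the mean of ``y_true``; pass the training mean for
    external-set validation.
    """
    y = np.asarray(y_true, float)
    yhat = np.asarray(y_pred, float)
    ybar = y.mean() if y_mean is None else float(y_mean)
    ss_tot = ((y - ybar) ** 2).sum()
    if ss_tot == 0:
        raise ValueError("response has zero variance about the reference mean")
    return float(1.0 - ((y - yhat) ** 2).sum() / ss_tot)


def _coerce_X(X):
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(c) for c in X.columns]
    if hasattr(X, "values") and hasattr(X, "variable_names"):  # DescriptorMatrix
        return np.asarray(X.values, float), list(X.variable_names)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return X, [f"x{j + 1}" for j in range(X.shape[1])]


def _autoscale_train(X: np.ndarray, warn: bool = True):
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    dead = sds <= _EPS
    if dead.any() and warn:
        warnings.warn(
            f"{int(dead.sum())} zero-variance column(s) dropped from PLS fit",
            stacklevel=3,
        )
    safe = np.where(dead, 1.0, sds)
    Xs = (X - means) / safe
    Xs[:, dead] = 0.0
    return Xs, means, np.where(dead, np.inf, sds)


def _nipals(E: np.ndarray, f: np.ndarray, A: int,
            tol: float = 1e-12, max_iter: int = 500):
    """NIPALS extraction of A components from autoscaled blocks.

    Returns (W, P, T, U, b, q).  For a univariate response the inner loop
    converges in a single pass; the iteration is kept for generality.
    """
    n, p = E.shape
    W = np.zeros((p, A))
    P = np.zeros((p, A))
    T = np.zeros((n, A))
    U = np.zeros((n, A))
    b = np.zeros(A)
    q = np.zeros(A)
    E = E.copy()
    f = f.copy()
    for a in range(A):
        u = f.copy()
        if np.linalg.norm(u) <= _EPS:
            raise np.linalg.LinAlgError(
                f"response fully deflated before component {a + 1}"
            )
        w = np.zeros(p)
        for _ in range(max_iter):
            w_new = E.T @ u
            nw = np.linalg.norm(w_new)
            if nw <= _EPS:
                raise np.linalg.LinAlgError(
                    f"X block fully deflated before component {a + 1}; "
                    "reduce the number of components"
                )
            w_new /= nw
            if np.linalg.norm(w_new - w) <= tol:
                w = w_new
                break
            w = w_new
            t = E @ w
            qa = float(f @ t / (t @ t))
            u = f / qa if abs(qa) > _EPS else f.copy()
        t = E @ w
        tt = float(t @ t)
        ba = float(u @ t / tt)
        qa = float(f @ t / tt)
        pa = E.T @ t / tt
        E -= np.outer(t, pa)
        f = f - qa * t
        W[:, a] = w
        P[:, a] = pa
        T[:, a] = t
        U[:, a] = u
        b[a] = ba
        q[a] = qa
    return W, P, T, U, b, q


def fit_pls(X, y, A: int, variable_names: list[str] | None = None) -> PLSModel:
    """Fit a NIPALS PLS model with ``A`` components.

    X columns and y are autoscaled (centered, unit variance) before
    extraction; the returned regression vector and intercept are on the
    original scale.
    """
    Xa, names = _coerce_X(X)
    if variable_names is not None:
        names = list(variable_names)
    y = np.asarray(y, float).ravel()
    n, p = Xa.shape
    if y.shape[0] != n:
        raise ValueError(f"X has {n} rows but y has {y.shape[0]} values")
    if n < 3:
        raise ValueError("need at least 3 samples")
    if A < 1:
        raise ValueError("number of components must be >= 1")
    if y.std(ddof=1) <= _EPS:
        raise ValueError("constant response; nothing to model")
    Xc = Xa - Xa.mean(axis=0)
    rank = np.linalg.matrix_rank(Xc)
    if A > rank:
        raise ValueError(f"A={A} exceeds rank of centered X ({rank})")

    Xs, xm, xsd = _autoscale_train(Xa)
    ym = float(y.mean())
    ysd = float(y.std(ddof=1))
    f = (y - ym) / ysd

    W, P, T, U, b, q = _nipals(Xs, f, A)
    # beta on the autoscaled space: W (P'W)^-1 q
    beta_s = W @ np.linalg.solve(P.T @ W, q)
    finite = np.isfinite(xsd)
    coef = np.where(finite, ysd * beta_s / np.where(finite, xsd, 1.0), 0.0)
    intercept = ym - float(coef @ xm)

    fitted = Xa @ coef + intercept
    ss_res = float(((y - fitted) ** 2).sum())
    ss_tot = float(((y - ym) ** 2).sum())
    stats = FitStats(
        r2=1.0 - ss_res / ss_tot,
        q2=None,
        rms=float(np.sqrt(ss_res / n)),
        press=None,
        n=n,
    )
    return PLSModel(
        n_components=A, variable_names=names,
        x_means=xm, x_sds=xsd, y_mean=ym, y_sd=ysd,
        x_weights=W, x_loadings=P, x_scores=T, y_scores=U,
        inner_coefficients=b, y_loadings=q,
        coefficients=coef, intercept=intercept, fit_stats=stats,
    )


def predict(model: PLSModel, X_new) -> np.ndarray:
    Xa, _ = _coerce_X(X_new)
    p = len(model.variable_names)
    if Xa.shape[1] != p:
        raise ValueError(
            f"X has {Xa.shape[1]} columns, model was trained on {p}"
        )
    return Xa @ model.coefficients + model.intercept


def loo_press_profile(X, y, A_max: int, warn: bool = True):
    """LOO predictions and PRESS for every component count 1..A_max.

    All folds are processed simultaneously (3-D batched NIPALS, exact per-fold
    re-autoscaling and refit).  Returns (press vector of length A_eff,
    prediction matrix n x A_eff); A_eff may be below ``A_max`` when the rank
    of the fold design matrices is exhausted.
    """
    Xa, _ = _coerce_X(X)
    y = np.asarray(y, float).ravel()
    n, p = Xa.shape
    if n < 3:
        raise ValueError("need at least 3 samples for LOO")
    if y.std(ddof=1) <= _EPS:
        raise ValueError("constant response; nothing to model")
    A_max = int(min(A_max, p, n - 2))
    if A_max < 1:
        raise ValueError("no components can be extracted")

    idx = np.arange(n)
    train_idx = np.stack([np.delete(idx, i) for i in range(n)])  # n x (n-1)
    Xt = Xa[train_idx]              # n x (n-1) x p
    yt = y[train_idx]               # n x (n-1)

    xm = Xt.mean(axis=1)            # n x p
    xsd = Xt.std(axis=1, ddof=1)
    dead = xsd <= _EPS
    if dead.any() and warn:
        warnings.warn(
            "zero-variance column(s) inside LOO fold(s) dropped for those folds",
            stacklevel=3,
        )
    xsd_safe = np.where(dead, 1.0, xsd)
    E = (Xt - xm[:, None, :]) / xsd_safe[:, None, :]
    E[dead[:, None, :].repeat(n - 1, axis=1)] = 0.0
    ym = yt.mean(axis=1)
    ysd = yt.std(axis=1, ddof=1)
    ysd_safe = np.where(ysd <= _EPS, 1.0, ysd)
    f = (yt - ym[:, None]) / ysd_safe[:, None]
    f[ysd <= _EPS] = 0.0

    xh = (Xa - xm) / xsd_safe       # held-out rows, fold-scaled
    xh[dead] = 0.0

    preds = np.empty((n, A_max))
    acc = np.zeros(n)
    for a in range(A_max):
        w = np.einsum("fij,fi->fj", E, f)
        nw = np.linalg.norm(w, axis=1)
        alive = nw > _EPS
        nw_safe = np.where(alive, nw, 1.0)
        w = w / nw_safe[:, None]
        w[~alive] = 0.0
        t = np.einsum("fij,fj->fi", E, w)
        tt = (t * t).sum(axis=1)
        tt_safe = np.where(tt > _EPS, tt, 1.0)
        qa = (f * t).sum(axis=1) / tt_safe
        pa = np.einsum("fij,fi->fj", E, t) / tt_safe[:, None]
        E -= t[:, :, None] * pa[:, None, :]
        f -= qa[:, None] * t
        th = (xh * w).sum(axis=1)
        xh = xh - th[:, None] * pa
        acc = acc + qa * th
        preds[:, a] = ym + np.where(ysd <= _EPS, 0.0, ysd) * acc
    press = ((y[:, None] - preds) ** 2).sum(axis=0)
    return press, preds


def loo_q2(X, y, A: int) -> FitStats:
    """Leave-one-out statistics at ``A`` components.

    Autoscaling and the PLS fit are recomputed on every n-1 subset; Q² uses
    the full-sample response mean in the denominator; RMS is the CV RMS,
    sqrt(PRESS / n).
    """
    y = np.asarray(y, float).ravel()
    press, preds = loo_press_profile(X, y, A)
    a = min(A, press.shape[0]) - 1
    q2 = q2_score(y, preds[:, a])
    model = fit_pls(X, y, min(A, press.shape[0]))
    n = y.shape[0]
    return FitStats(
        r2=model.fit_stats.r2,
        q2=q2,
        rms=float(np.sqrt(press[a] / n)),
        press=float(press[a]),
        n=n,
    )


def select_components(X, y, A_max: int) -> int:
    """Component count minimizing LOO PRESS over 1..A_max (ties -> smaller A)."""
    if A_max < 1:
        raise ValueError("A_max must be >= 1")
    press, _ = loo_press_profile(X, y, A_max)
    return int(np.argmin(press)) + 1
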