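"""Model validation: Y-randomization, rational train/test splitting, and
external-set statistics.

Y-randomization refits the model on permuted responses and regresses the
resulting R² and Q² against |r(y_perm, y)|; intercepts of those lines below
0.300 (R²) and 0.050 (Q²) are the conventional evidence that the real model
is not a chance correlation.  The rational split clusters samples by k-means
(k=2) on autoscaled descriptors, sorts each cluster by activity and
alternates members into training (odd ranks) and test (even ranks) sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .pls import FitStats, PLSModel, fit_pls, loo_q2, predict, q2_score

__all__ = [
    "PermutationReport",
    "SplitAssignment",
    "y_randomization",
    "pls_modeler",
    "kmeans_odd_even_split",
    "external_validate",
    "R2_INTERCEPT_LIMIT",
    "Q2_INTERCEPT_LIMIT",
]

R2_INTERCEPT_LIMIT = 0.300
Q2_INTERCEPT_LIMIT = 0.050


@dataclass
class PermutationReport:
    records: pd.DataFrame        # columns r, r2, q2 (last row = unpermuted)
    r2_intercept: float
    q2_intercept: float
    r2_slope: float
    q2_slope: float
    n_permutations: int
    seed: int
    r2_limit: float = R2_INTERCEPT_LIMIT
    q2_limit: float = Q2_INTERCEPT_LIMIT

    @property
    def passes(self) -> bool:
        """Intercept flags against the printed limits (0.300 / 0.050)."""
        return (self.r2_intercept < self.r2_limit
                and self.q2_intercept < self.q2_limit)

    @property
    def validates_model(self) -> bool:
        """Full validation verdict: intercepts below the limits AND the
        unpermuted model both clears the Q² limit itself and outperforms
        every permuted refit.  The intercept criteria alone cannot reject a
        model that was never internally predictive to begin with (an
        underfit chance model has a low-lying cloud and low intercepts), so
        the real model must also dominate its own permutation null.
        """
        if not self.passes:
            return False
        rec = self.records.dropna()
        real = rec[rec["r"] == 1.0]
        if real.empty:
            return False
        q2_real = float(real["q2"].iloc[-1])
        q2_perm = rec[rec["r"] < 1.0]["q2"]
        return q2_real > self.q2_limit and bool((q2_real > q2_perm).all())


@dataclass
class SplitAssignment:
    train_ids: list
    test_ids: list
    cluster_labels: pd.Series    # indexed by sample id
    ranks: pd.Series             # within-cluster activity rank (1-based)

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test sets overlap")


def pls_modeler(mask=None, n_components: int = 1):
    """Modeler callable for :func:`y_randomization`: PLS with a fixed variable
    subset and component count, returning (R², Q²)."""

    def _fit(X, y):
        Xa = np.asarray(X, float)
        if mask is not None:
            Xa = Xa[:, np.asarray(mask, bool)]
        r2 = fit_pls(Xa, y, n_components).fit_stats.r2
        q2 = loo_q2(Xa, y, n_components).q2
        return r2, q2

    return _fit


def _line(x: np.ndarray, y: np.ndarray):
    slope, intercept = np.polyfit(x, y, 1)
    return float(intercept), float(slope)


def y_randomization(X, y, modeler, n_perm: int = 50, seed: int | None = None,
                    include_unpermuted: bool = True) -> PermutationReport:
    """Response-permutation test.

    ``modeler`` is a callable (X, y) -> (R², Q²); it is refit on each of
    ``n_perm`` shuffled responses.  The report records each permutation's
    |Pearson r| to the original response and fits ordinary least-squares
    lines R² ~ r and Q² ~ r, including the unpermuted model at r = 1 by
    default.
    """
    if n_perm < 10:
        raise ValueError("n_perm must be >= 10 for a meaningful test")
    if seed is None:
        raise ValueError("y_randomization requires an explicit seed")
    y = np.asarray(y, float).ravel()
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_perm):
        yp = rng.permutation(y)
        r = abs(float(np.corrcoef(yp, y)[0, 1]))
        try:
            r2, q2 = modeler(X, yp)
        except Exception as exc:  # noqa: BLE001 - recorded and excluded
            warnings.warn(f"modeler failed on a permutation: {exc}")
            r2, q2 = np.nan, np.nan
        rows.append({"r": r, "r2": r2, "q2": q2})
    if include_unpermuted:
        r2, q2 = modeler(X, y)
        rows.append({"r": 1.0, "r2": r2, "q2": q2})
    rec = pd.DataFrame(rows)
    ok = rec.dropna()
    r2_b, r2_m = _line(ok["r"].to_numpy(), ok["r2"].to_numpy())
    q2_b, q2_m = _line(ok["r"].to_numpy(), ok["q2"].to_numpy())
    return PermutationReport(
        records=rec,
        r2_intercept=r2_b, q2_intercept=q2_b,
        r2_slope=r2_m, q2_slope=q2_m,
        n_permutations=n_perm, seed=seed,
    )


def kmeans_odd_even_split(X, y, seed: int, sample_ids=None) -> SplitAssignment:
    """k=2 k-means on autoscaled descriptors, then an odd/even activity split.

    Within each cluster, samples are sorted by ascending activity (ties by
    sample id); odd ranks (1st, 3rd, ...) go to training, even ranks to test.
    """
    Xa = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    n = Xa.shape[0]
    if n < 4:
        raise ValueError("need at least 4 samples to split")
    if sample_ids is None:
        sample_ids = [str(i) for i in range(n)]
    sample_ids = list(map(str, sample_ids))

    sds = Xa.std(axis=0, ddof=1)
    sds = np.where(sds == 0, 1.0, sds)
    Z = (Xa - Xa.mean(axis=0)) / sds
    km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(Z)
    labels = km.labels_
    if len(np.unique(labels)) < 2:
        raise ValueError("k-means produced an empty cluster")

    train, test = [], []
    ranks = {}
    for c in np.unique(labels):
        members = [i for i in range(n) if labels[i] == c]
        members.sort(key=lambda i: (y[i], sample_ids[i]))
        for rank, i in enumerate(members, start=1):
            ranks[sample_ids[i]] = rank
            (train if rank % 2 == 1 else test).append(sample_ids[i])
    return SplitAssignment(
        train_ids=train,
        test_ids=test,
        cluster_labels=pd.Series(labels, index=sample_ids),
        ranks=pd.Series(ranks),
    )


def external_validate(model: PLSModel, X_test, y_test) -> FitStats:
    """External-set statistics: Q²ext against the training-set mean, and RMS.

    Q²ext = 1 - sum((y - yhat)²) / sum((y - ybar_train)²) with ybar_train
    taken from the fitted model's stored centering parameter.
    """
    y = np.asarray(y_test, float).ravel()
    yhat = predict(model, X_test)
    q2e = q2_score(y, yhat, y_mean=model.y_mean)
    ss = float(((y - yhat) ** 2).sum())
    return FitStats(
        r2=q2e, q2=q2e,
        rms=float(np.sqrt(ss / y.shape[0])),
        press=ss, n=y.shape[0],
    )
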