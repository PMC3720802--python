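"""Derivation of low-dimensional amino-acid property scales by factor analysis.

A residue-by-property matrix (hundreds of physicochemical descriptors for
natural and non-natural amino acids) is compressed into a small number of
interpretable factors: principal-component extraction from the property
correlation matrix, Kaiser-normalized varimax rotation, and an oblique promax
step that allows the factors to correlate.  Per-residue factor scores computed
from the rotated solution form the scale table used to encode peptides.

The six default factor names follow the conventional property patterns for
amino-acid scales of this kind: geometric characteristics, hydrogen bonding,
connectivity, accessible surface area, integy moments and volume/shape.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_FACTOR_NAMES = (
    "geometric",
    "h_bond",
    "connectivity",
    "asa",
    "integy_moment",
    "volume_shape",
)

__all__ = [
    "PropertyTable",
    "FactorModel",
    "ScaleTable",
    "standardize",
    "fit_factor_model",
    "compute_scores",
    "factor_correlations",
    "eigenvalue_profile",
    "tucker_congruence",
    "match_factors",
    "DEFAULT_FACTOR_NAMES",
]


@dataclass
class PropertyTable:
    """Residue-by-property numeric matrix.

    Rows are residue identifiers (one-letter codes or opaque numeric IDs for
    non-natural residues), columns are named physicochemical properties.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.shape[0] < 2 or df.shape[1] < 2:
            raise ValueError(
                f"property table needs at least 2 rows and 2 columns, got {df.shape}"
            )
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate residue ids: {dups}")
        if df.columns.duplicated().any():
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate property names: {dups}")
        if df.isna().any().any():
            bad = df.columns[df.isna().any()].tolist()
            raise ValueError(f"missing cells in properties: {bad}")
        self.data = df.astype(float)

    @property
    def row_ids(self) -> list[str]:
        return [str(i) for i in self.data.index]

    @property
    def col_names(self) -> list[str]:
        return [str(c) for c in self.data.columns]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @classmethod
    def from_arrays(cls, row_ids, col_names, values) -> "PropertyTable":
        return cls(pd.DataFrame(np.asarray(values, dtype=float),
                                index=list(row_ids), columns=list(col_names)))


@dataclass
class ScaleTable:
    """Residue id -> vector of factor scores (the derived amino-acid scale)."""

    data: pd.DataFrame  # index residue id, columns factor names

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate residue ids in scale table: {dups}")
        self.data = self.data.astype(float)
        self.data.index = self.data.index.map(str)

    @property
    def factor_names(self) -> list[str]:
        return [str(c) for c in self.data.columns]

    @property
    def n_factors(self) -> int:
        return self.data.shape[1]

    @property
    def residue_ids(self) -> list[str]:
        return list(self.data.index)

    def scores(self, residue_id: str) -> np.ndarray:
        try:
            return self.data.loc[str(residue_id)].to_numpy()
        except KeyError:
            raise KeyError(f"unknown residue id {residue_id!r}") from None

    def __contains__(self, residue_id: str) -> bool:
        return str(residue_id) in self.data.index


@dataclass
class FactorModel:
    """Fitted factor-analysis model of a property table.

    ``pattern_loadings`` are the oblique regression coefficients of properties
    on factors (values may exceed 1); ``structure_loadings`` are the
    property-factor correlations (pattern x phi); ``phi`` is the inter-factor
    correlation matrix.  ``communalities`` are rotation-invariant row sums of
    squared unrotated loadings.
    """

    n_factors: int
    property_names: list[str]
    factor_names: list[str]
    col_means: np.ndarray
    col_sds: np.ndarray
    eigenvalues: np.ndarray          # full spectrum, descending
    unrotated_loadings: np.ndarray   # p x m
    pattern_loadings: np.ndarray     # p x m
    structure_loadings: np.ndarray   # p x m
    phi: np.ndarray                  # m x m
    communalities: np.ndarray        # length p
    score_coefficients: np.ndarray   # p x m
    explained_variance_fraction: float
    rotation: str = "promax"
    promax_power: int = 4
    score_method: str = "regression"

    def to_dict(self) -> dict:
        return {
            "n_factors": int(self.n_factors),
            "property_names": list(self.property_names),
            "factor_names": list(self.factor_names),
            "col_means": self.col_means.tolist(),
            "col_sds": self.col_sds.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "unrotated_loadings": self.unrotated_loadings.tolist(),
            "pattern_loadings": self.pattern_loadings.tolist(),
            "structure_loadings": self.structure_loadings.tolist(),
            "phi": self.phi.tolist(),
            "communalities": self.communalities.tolist(),
            "score_coefficients": self.score_coefficients.tolist(),
            "explained_variance_fraction": float(self.explained_variance_fraction),
            "rotation": self.rotation,
            "promax_power": int(self.promax_power),
            "score_method": self.score_method,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FactorModel":
        arrays = {
            k: np.asarray(d[k], dtype=float)
            for k in (
                "col_means", "col_sds", "eigenvalues", "unrotated_loadings",
                "pattern_loadings", "structure_loadings", "phi",
                "communalities", "score_coefficients",
            )
        }
        return cls(
            n_factors=int(d["n_factors"]),
            property_names=list(d["property_names"]),
            factor_names=list(d["factor_names"]),
            explained_variance_fraction=float(d["explained_variance_fraction"]),
            rotation=d.get("rotation", "promax"),
            promax_power=int(d.get("promax_power", 4)),
            score_method=d.get("score_method", "regression"),
            **arrays,
        )


def standardize(table: PropertyTable):
    """Column-standardize a property table (mean 0, sd 1, n-1 denominator).

    Returns the standardized table together with the per-column means and
    standard deviations so later score computation can reuse them.
    """
    X = table.values
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    zero = np.flatnonzero(sds == 0)
    if zero.size:
        names = [table.col_names[i] for i in zero]
        raise ValueError(f"zero-variance property columns: {names}")
    Z = (X - means) / sds
    out = PropertyTable.from_arrays(table.row_ids, table.col_names, Z)
    return out, means, sds


def _varimax(loadings: np.ndarray, normalize: bool = True,
             tol: float = 1e-8, max_iter: int = 1000):
    """Varimax rotation (SVD-based pairwise-free algorithm, as in base R).

    Returns (rotated loadings, rotation matrix).  With ``normalize`` the rows
    are Kaiser-normalized by their communality before rotation.
    """
    A = np.asarray(loadings, dtype=float).copy()
    p, m = A.shape
    if m == 1:
        return A, np.eye(1)
    h = None
    if normalize:
        h = np.sqrt((A ** 2).sum(axis=1))
        h = np.where(h == 0, 1.0, h)
        A = A / h[:, None]
    T = np.eye(m)
    d_old = 0.0
    for _ in range(max_iter):
        Z = A @ T
        B = A.T @ (Z ** 3 - Z @ np.diag((Z ** 2).sum(axis=0)) / p)
        u, s, vt = np.linalg.svd(B)
        T = u @ vt
        d = s.sum()
        if d < d_old * (1 + tol):
            break
        d_old = d
    else:
        # plateau criterion can keep creeping on near-flat landscapes
        # (e.g. two tight row clusters); the solution after max_iter is
        # still usable, so return it as base R's varimax does
        warnings.warn("varimax criterion still increasing after "
                      f"{max_iter} sweeps; returning current rotation")
    Z = A @ T
    if normalize:
        Z = Z * h[:, None]
    return Z, T


def _promax(unrotated: np.ndarray, power: int = 4, normalize: bool = True):
    """Promax oblique rotation of a loading matrix.

    The varimax solution is raised elementwise to ``power`` (keeping signs) to
    form a simple-structure target, and the least-squares oblique transform to
    that target is applied.  Power 1 leaves the varimax solution unchanged.

    Returns (pattern, total rotation matrix U with pattern = unrotated @ U,
    phi).
    """
    V, T = _varimax(unrotated, normalize=normalize)
    m = V.shape[1]
    if m == 1:
        sign = 1.0
        return V.copy(), np.eye(1), np.eye(1)
    target = V * np.abs(V) ** (power - 1)
    U, *_ = np.linalg.lstsq(V, target, rcond=None)
    d = np.diag(np.linalg.inv(U.T @ U))
    U = U @ np.diag(np.sqrt(d))
    pattern = V @ U
    U_total = T @ U
    phi = np.linalg.inv(U_total.T @ U_total)
    return pattern, U_total, phi


def fit_factor_model(
    table: PropertyTable,
    n_factors: int,
    promax_power: int = 4,
    rotation: str = "promax",
    score_method: str = "regression",
) -> FactorModel:
    """Fit the factor model: PCA extraction + Kaiser-normalized promax rotation.

    Extraction is the eigendecomposition of the property correlation matrix;
    the ``n_factors`` leading components, scaled by the square roots of their
    eigenvalues, form the unrotated loadings.  ``rotation`` is ``"promax"``
    (oblique, default) or ``"varimax"`` (orthogonal, phi = identity).

    Factor order follows descending eigenvalues and each rotated factor is
    flipped so that its maximum-|loading| entry is positive, which makes runs
    reproducible despite the sign/rotation indeterminacy of factor analysis.
    """
    n, p = table.values.shape
    if n_factors < 1:
        raise ValueError("n_factors must be >= 1")
    if n_factors > min(p, n - 1):
        raise ValueError(
            f"n_factors={n_factors} exceeds min(n_properties, n_rows-1)="
            f"{min(p, n - 1)}"
        )
    if rotation not in ("promax", "varimax"):
        raise ValueError(f"unknown rotation {rotation!r}")
    if score_method not in ("regression", "bartlett"):
        raise ValueError(f"unknown score_method {score_method!r}")

    ztable, means, sds = standardize(table)
    Z = ztable.values
    R = (Z.T @ Z) / (n - 1)
    eigval, eigvec = np.linalg.eigh(R)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    lam = eigval[:n_factors]
    if np.any(lam <= 0):
        raise ValueError("retained eigenvalues must be positive; reduce n_factors")
    A = eigvec[:, :n_factors] * np.sqrt(lam)
    # deterministic sign for the unrotated solution too
    for j in range(n_factors):
        i = int(np.argmax(np.abs(A[:, j])))
        if A[i, j] < 0:
            A[:, j] = -A[:, j]

    communalities = (A ** 2).sum(axis=1)

    if rotation == "varimax":
        pattern, U = _varimax(A, normalize=True)
        phi = np.eye(n_factors)
    else:
        pattern, U, phi = _promax(A, power=promax_power, normalize=True)

    # sign convention: max-|loading| entry of each rotated factor positive
    s = np.ones(n_factors)
    for j in range(n_factors):
        i = int(np.argmax(np.abs(pattern[:, j])))
        if pattern[i, j] < 0:
            s[j] = -1.0
    S = np.diag(s)
    pattern = pattern @ S
    U = U @ S
    phi = S @ phi @ S

    structure = pattern @ phi

    if score_method == "regression":
        # Thurstone regression weights: B = R^{-1} x structure
        coef = np.linalg.lstsq(R, structure, rcond=None)[0]
    else:
        # Bartlett weighted least squares with uniquenesses from the
        # retained-factor communalities (clipped away from zero)
        psi = np.clip(1.0 - communalities, 1e-6, None)
        Pw = pattern / psi[:, None]
        coef = Pw @ np.linalg.inv(pattern.T @ Pw)

    factor_names = [
        DEFAULT_FACTOR_NAMES[j] if j < len(DEFAULT_FACTOR_NAMES) else f"factor{j + 1}"
        for j in range(n_factors)
    ]
    return FactorModel(
        n_factors=n_factors,
        property_names=table.col_names,
        factor_names=factor_names,
        col_means=means,
        col_sds=sds,
        eigenvalues=eigval,
        unrotated_loadings=A,
        pattern_loadings=pattern,
        structure_loadings=structure,
        phi=phi,
        communalities=communalities,
        score_coefficients=coef,
        explained_variance_fraction=float(lam.sum() / p),
        rotation=rotation,
        promax_power=promax_power,
        score_method=score_method,
    )


def compute_scores(model: FactorModel, table: PropertyTable,
                   factor_names: list[str] | None = None) -> ScaleTable:
    """Per-residue factor scores: standardized properties x score coefficients.

    Table columns are matched to the model's property names by name
    (order-insensitive); a mismatch in either direction is an error.
    """
    have = set(table.col_names)
    want = set(model.property_names)
    missing = sorted(want - have)
    extra = sorted(have - want)
    if missing or extra:
        raise ValueError(
            f"property columns do not match model: missing={missing}, extra={extra}"
        )
    df = table.data[model.property_names]
    Z = (df.to_numpy() - model.col_means) / model.col_sds
    scores = Z @ model.score_coefficients
    names = list(factor_names) if factor_names is not None else model.factor_names
    if len(names) != model.n_factors:
        raise ValueError("factor_names length must equal n_factors")
    return ScaleTable(pd.DataFrame(scores, index=table.row_ids, columns=names))


def factor_correlations(model: FactorModel) -> np.ndarray:
    """Inter-factor correlation matrix phi (identity for orthogonal rotation)."""
    return model.phi.copy()


def eigenvalue_profile(table: PropertyTable) -> pd.Series:
    """Eigenvalues of the property correlation matrix, descending.

    Helper for choosing the number of factors by scree/eigenvalue inspection;
    no automatic selection is performed.
    """
    ztable, _, _ = standardize(table)
    Z = ztable.values
    n = Z.shape[0]
    eigval = np.linalg.eigvalsh((Z.T @ Z) / (n - 1))[::-1]
    return pd.Series(eigval, index=[f"component{j + 1}" for j in range(len(eigval))])


def tucker_congruence(a: np.ndarray, b: np.ndarray) -> float:
    """Tucker congruence coefficient between two loading vectors."""
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    denom = np.sqrt((a ** 2).sum() * (b ** 2).sum())
    if denom == 0:
        return 0.0
    return float(np.abs(a @ b) / denom)


def match_factors(estimated: np.ndarray, truth: np.ndarray):
    """Match estimated factors to true ones by maximal Tucker congruence.

    Returns (column permutation applied to ``estimated``, per-factor
    congruence after matching).  Used for parameter-recovery checks where the
    factor order and sign are arbitrary.
    """
    from scipy.optimize import linear_sum_assignment

    est = np.asarray(estimated, float)
    tru = np.asarray(truth, float)
    m = tru.shape[1]
    C = np.zeros((est.shape[1], m))
    for i in range(est.shape[1]):
        for j in range(m):
            C[i, j] = tucker_congruence(est[:, i], tru[:, j])
    rows, cols = linear_sum_assignment(-C)
    perm = np.empty(m, dtype=int)
    cong = np.empty(m)
    for r, c in zip(rows, cols):
        perm[c] = r
        cong[c] = C[r, c]
    return perm, cong
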