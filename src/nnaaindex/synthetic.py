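"""Synthetic fixtures with known ground truth.

Two generators make every stage of the toolkit testable without external
data: a residue-by-property matrix with a planted low-rank factor structure
(scores x sparse loadings + Gaussian noise), and peptide QSAR datasets whose
activity is an exact linear function of the encoded descriptors plus noise.
Both are pure functions of their spec and seed, and both return the ground
truth (loadings/scores, regression coefficients) for recovery checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .encoding import Peptide, encode_dataset
from .scales import DEFAULT_FACTOR_NAMES, PropertyTable, ScaleTable

__all__ = [
    "FactorFixtureSpec",
    "QSARFixtureSpec",
    "make_property_table",
    "synthetic_scale_table",
    "make_qsar_dataset",
    "make_classification_dataset",
]

_NATURAL = list("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class FactorFixtureSpec:
    """Planted-factor property matrix.

    Each property loads ``loading_value`` on exactly one factor (properties
    are spread evenly over factors); ``loading_sparsity`` is the fraction of
    properties that load on no factor at all (pure noise columns).
    ``factor_correlation`` is planted uniformly between all factor pairs via
    a Cholesky transform of the target correlation matrix.
    """

    n_entities: int = 300
    n_properties: int = 40
    n_factors: int = 4
    loading_value: float = 0.9
    loading_sparsity: float = 0.0
    factor_correlation: float = 0.0
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_entities <= self.n_factors:
            raise ValueError("n_entities must exceed n_factors")
        if self.n_properties < self.n_factors:
            raise ValueError("n_properties must be >= n_factors")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.loading_sparsity < 1.0:
            raise ValueError("loading_sparsity must be in [0, 1)")
        if not -1.0 / max(self.n_factors - 1, 1) < self.factor_correlation < 1.0:
            raise ValueError("factor_correlation leaves the PSD range")


@dataclass
class QSARFixtureSpec:
    """Peptide dataset with a known linear structure-activity relationship.

    If ``true_coefficients`` is None, ``n_informative`` descriptor positions
    get nonzero coefficients (magnitude in [0.5, 1.5], random sign).
    """

    n_peptides: int = 48
    length: int = 2
    true_coefficients: np.ndarray | None = None
    n_informative: int = 3
    activity_noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_peptides < 3:
            raise ValueError("n_peptides must be >= 3")
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if self.activity_noise_sd < 0:
            raise ValueError("activity_noise_sd must be >= 0")


def make_property_table(spec: FactorFixtureSpec):
    """Generate (PropertyTable, true_loadings, true_scores).

    X = scores @ loadings.T + noise, with correlated factor scores when
    requested.  Reproducible from the seed.
    """
    rng = np.random.default_rng(spec.seed)
    m, p, n = spec.n_factors, spec.n_properties, spec.n_entities

    loadings = np.zeros((p, m))
    primary = np.arange(p) % m
    silent = rng.random(p) < spec.loading_sparsity
    for j in range(p):
        if not silent[j]:
            loadings[j, primary[j]] = spec.loading_value

    phi = np.full((m, m), spec.factor_correlation)
    np.fill_diagonal(phi, 1.0)
    chol = np.linalg.cholesky(phi)
    scores = rng.standard_normal((n, m)) @ chol.T

    X = scores @ loadings.T + spec.noise_sd * rng.standard_normal((n, p))
    table = PropertyTable.from_arrays(
        [f"e{i + 1:04d}" for i in range(n)],
        [f"prop{j + 1:03d}" for j in range(p)],
        X,
    )
    return table, loadings, scores


def synthetic_scale_table(n_residues: int = 615, n_factors: int = 6,
                          seed: int = 0) -> ScaleTable:
    """Standalone synthetic scale table for encoding/design tests.

    The first 20 ids are the canonical one-letter codes; the remainder are
    numeric ids emulating a non-natural residue catalog.  Scores are
    independent standard normals.
    """
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    rng = np.random.default_rng(seed)
    ids = _NATURAL[:min(20, n_residues)]
    ids += [str(k + 1) for k in range(n_residues - len(ids))]
    names = [
        DEFAULT_FACTOR_NAMES[j] if j < len(DEFAULT_FACTOR_NAMES)
        else f"factor{j + 1}"
        for j in range(n_factors)
    ]
    scores = rng.standard_normal((n_residues, n_factors))
    return ScaleTable(pd.DataFrame(scores, index=ids, columns=names))


def make_qsar_dataset(scales: ScaleTable, spec: QSARFixtureSpec):
    """Generate (peptides with activities, true_coefficients).

    Sequences are uniform random draws from the scale table's residues;
    activity = encoded descriptors . true_coefficients + Gaussian noise.
    """
    if not scales.residue_ids:
        raise ValueError("empty scale table")
    rng = np.random.default_rng(spec.seed)
    n_desc = scales.n_factors * spec.length
    coef = spec.true_coefficients
    if coef is None:
        coef = np.zeros(n_desc)
        pos = rng.choice(n_desc, size=min(spec.n_informative, n_desc),
                         replace=False)
        coef[pos] = ((0.5 + rng.random(pos.shape[0]))
                     * rng.choice([-1.0, 1.0], pos.shape[0]))
    else:
        coef = np.asarray(coef, float)
        if coef.shape[0] != n_desc:
            raise ValueError(
                f"true_coefficients has length {coef.shape[0]}, "
                f"expected {n_desc}"
            )

    ids = np.asarray(scales.residue_ids)
    peptides = [
        Peptide(tokens=list(rng.choice(ids, size=spec.length)),
                sample_id=f"s{i + 1:03d}")
        for i in range(spec.n_peptides)
    ]
    X = encode_dataset(peptides, scales).values
    y = X @ coef + spec.activity_noise_sd * rng.standard_normal(spec.n_peptides)
    for p, yi in zip(peptides, y):
        p.activity = float(yi)
    return peptides, coef


def make_classification_dataset(scales: ScaleTable, spec: QSARFixtureSpec,
                                labels: tuple[str, str] = ("moderate", "strong")):
    """Two-class dataset: latent linear activity thresholded at its median.

    Returns (peptides with class labels, true_coefficients, informative
    descriptor indices).  Peptides above the median latent activity get
    ``labels[1]`` (the active class).
    """
    peptides, coef = make_qsar_dataset(scales, spec)
    y = np.array([p.activity for p in peptides])
    cut = float(np.median(y))
    for p in peptides:
        p.activity = labels[1] if p.activity > cut else labels[0]
    return peptides, coef, [int(i) for i in np.flatnonzero(coef)]
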