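import numpy as np
import pandas as pd
import pytest

import nnaaindex as nx


@pytest.fixture(scope="session")
def factor_fixture():
    """Default planted-factor property table (300 x 40, 4 factors)."""
    spec = nx.FactorFixtureSpec(seed=1)
    table, loadings, scores = nx.make_property_table(spec)
    return spec, table, loadings, scores


@pytest.fixture(scope="session")
def small_scales():
    """30-residue, 6-factor synthetic scale table (letters + numeric ids)."""
    return nx.synthetic_scale_table(n_residues=30, n_factors=6, seed=0)


@pytest.fixture(scope="session")
def dipeptide_dataset(small_scales):
    """48 random dipeptides with activity linear in 5 descriptors + noise."""
    spec = nx.QSARFixtureSpec(n_peptides=48, length=2, n_informative=5,
                              activity_noise_sd=0.2, seed=11)
    peptides, coef = nx.make_qsar_dataset(small_scales, spec)
    X = nx.encode_dataset(peptides, small_scales).values
    y = np.array([p.activity for p in peptides], dtype=float)
    return peptides, X, y, coef


@pytest.fixture(scope="session")
def planted_gapls_problem(small_scales):
    """50 dipeptides, activity from 3 of the 12 descriptors (noise sd 0.1)."""
    spec = nx.QSARFixtureSpec(n_peptides=50, length=2, n_informative=3,
                              activity_noise_sd=0.1, seed=7)
    peptides, coef = nx.make_qsar_dataset(small_scales, spec)
    X = nx.encode_dataset(peptides, small_scales).values
    y = np.array([p.activity for p in peptides], dtype=float)
    return X, y, set(int(i) for i in np.flatnonzero(coef))


@pytest.fixture(scope="session")
def heptapeptide_classes(small_scales):
    """20 heptapeptides in two classes from a thresholded latent activity."""
    spec = nx.QSARFixtureSpec(n_peptides=20, length=7, n_informative=2,
                              activity_noise_sd=0.5, seed=3)
    peptides, coef, informative = nx.make_classification_dataset(
        small_scales, spec)
    X = nx.encode_dataset(peptides, small_scales).values
    labels = np.array([p.activity for p in peptides])
    return X, labels, informative


@pytest.fixture()
def toy_property_table():
    rng = np.random.default_rng(5)
    X = rng.standard_normal((12, 5))
    return nx.PropertyTable(pd.DataFrame(
        X, index=[f"r{i}" for i in range(12)],
        columns=[f"p{j}" for j in range(5)]))
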