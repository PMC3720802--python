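"""Factor-analysis scale derivation: standardization, extraction, rotation,
scoring, and parameter recovery on fixtures with known structure."""

import subprocess

import numpy as np
import pandas as pd
import pytest

import nnaaindex as nx
from nnaaindex.scales import _promax, _varimax, match_factors


class TestStandardize:
    def test_symmetric_column(self):
        t = nx.PropertyTable(pd.DataFrame(
            {"a": [1.0, 2.0, 3.0], "b": [5.0, 1.0, 0.0]},
            index=["x", "y", "z"]))
        out, means, sds = nx.standardize(t)
        np.testing.assert_allclose(out.data["a"], [-1, 0, 1], atol=1e-12)
        assert means[0] == pytest.approx(2.0)

    def test_hand_computed_zscores(self):
        col = np.array([2.0, 4.0, 6.0, 8.0])
        t = nx.PropertyTable(pd.DataFrame(
            {"a": col, "b": [1.0, 0.0, 1.0, 2.0]}))
        out, means, sds = nx.standardize(t)
        sd = np.sqrt(20.0 / 3.0)
        np.testing.assert_allclose(out.data["a"], (col - 5.0) / sd,
                                   atol=1e-12)
        assert sds[0] == pytest.approx(sd)

    def test_idempotent(self, toy_property_table):
        once, _, _ = nx.standardize(toy_property_table)
        twice, _, _ = nx.standardize(once)
        np.testing.assert_allclose(once.values, twice.values, atol=1e-12)

    def test_zero_variance_column_named(self):
        t = nx.PropertyTable(pd.DataFrame(
            {"flat": [1.0, 1.0, 1.0], "ok": [0.0, 1.0, 2.0]}))
        with pytest.raises(ValueError, match="flat"):
            nx.standardize(t)


class TestPropertyTableInvariants:
    def test_rejects_duplicates_and_missing(self):
        with pytest.raises(ValueError, match="duplicate residue"):
            nx.PropertyTable(pd.DataFrame(
                np.ones((3, 2)), index=["a", "a", "b"], columns=["p", "q"]))
        with pytest.raises(ValueError, match="missing"):
            nx.PropertyTable(pd.DataFrame(
                {"p": [1.0, np.nan], "q": [0.0, 1.0]}))

    def test_rejects_tiny(self):
        with pytest.raises(ValueError, match="at least 2"):
            nx.PropertyTable(pd.DataFrame({"p": [1.0, 2.0]}))


class TestFactorModel:
    def test_loading_recovery_on_planted_structure(self, factor_fixture):
        """Planted 4-factor structure is recovered with Tucker congruence
        > 0.95 per factor (up to permutation/sign)."""
        _, table, true_loadings, _ = factor_fixture
        model = nx.fit_factor_model(table, 4)
        _, cong = match_factors(model.pattern_loadings, true_loadings)
        assert (cong > 0.95).all()

    def test_score_recovery_on_planted_structure(self, factor_fixture):
        _, table, true_loadings, true_scores = factor_fixture
        model = nx.fit_factor_model(table, 4)
        scales = nx.compute_scores(model, table)
        perm, _ = match_factors(model.pattern_loadings, true_loadings)
        est = scales.data.to_numpy()[:, perm]
        for j in range(4):
            r = abs(np.corrcoef(est[:, j], true_scores[:, j])[0, 1])
            assert r > 0.9

    def test_communalities_rotation_invariant(self, factor_fixture):
        _, table, _, _ = factor_fixture
        model = nx.fit_factor_model(table, 4)
        rowsums = (model.unrotated_loadings ** 2).sum(axis=1)
        np.testing.assert_allclose(model.communalities, rowsums, atol=1e-10)

    def test_full_decomposition_communalities_one(self, toy_property_table):
        p = toy_property_table.values.shape[1]
        model = nx.fit_factor_model(toy_property_table, p)
        np.testing.assert_allclose(model.communalities, 1.0, atol=1e-8)
        assert model.explained_variance_fraction == pytest.approx(1.0)

    def test_promax_power_one_is_varimax(self, factor_fixture):
        _, table, _, _ = factor_fixture
        mv = nx.fit_factor_model(table, 4, rotation="varimax")
        mp = nx.fit_factor_model(table, 4, promax_power=1)
        np.testing.assert_allclose(mp.phi, np.eye(4), atol=1e-8)
        np.testing.assert_allclose(mp.pattern_loadings, mv.pattern_loadings,
                                   atol=1e-8)

    def test_reconstruction_error_decreases_with_factors(self, factor_fixture):
        """L L' approximates the correlation matrix increasingly well."""
        _, table, _, _ = factor_fixture
        zt, _, _ = nx.standardize(table)
        Z = zt.values
        R = Z.T @ Z / (Z.shape[0] - 1)
        errors = []
        for m in (1, 2, 3, 4):
            L = nx.fit_factor_model(table, m).unrotated_loadings
            errors.append(np.max(np.abs(L @ L.T - R)))
        assert all(a >= b - 1e-12 for a, b in zip(errors, errors[1:]))

    def test_phi_symmetric_unit_diagonal(self, factor_fixture):
        _, table, _, _ = factor_fixture
        model = nx.fit_factor_model(table, 4)
        phi = nx.factor_correlations(model)
        np.testing.assert_allclose(phi, phi.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(phi), 1.0, atol=1e-10)

    def test_planted_factor_correlation_recovered(self):
        spec = nx.FactorFixtureSpec(n_entities=800, n_properties=20,
                                    n_factors=2, factor_correlation=0.4,
                                    noise_sd=0.3, seed=9)
        table, _, _ = nx.make_property_table(spec)
        model = nx.fit_factor_model(table, 2)
        assert abs(abs(model.phi[0, 1]) - 0.4) < 0.1

    def test_orthogonal_rotation_phi_identity(self, factor_fixture):
        _, table, _, _ = factor_fixture
        model = nx.fit_factor_model(table, 4, rotation="varimax")
        np.testing.assert_allclose(nx.factor_correlations(model),
                                   np.eye(4), atol=1e-12)

    def test_n_factors_too_large_errors(self, toy_property_table):
        with pytest.raises(ValueError, match="exceeds"):
            nx.fit_factor_model(toy_property_table, 6)

    def test_deterministic_repeat(self, factor_fixture):
        _, table, _, _ = factor_fixture
        m1 = nx.fit_factor_model(table, 3)
        m2 = nx.fit_factor_model(table, 3)
        np.testing.assert_array_equal(m1.pattern_loadings,
                                      m2.pattern_loadings)


class TestScores:
    def test_training_scores_centered(self, factor_fixture):
        _, table, _, _ = factor_fixture
        model = nx.fit_factor_model(table, 4)
        scales = nx.compute_scores(model, table)
        np.testing.assert_allclose(scales.data.mean(axis=0), 0.0, atol=1e-8)

    def test_mean_profile_scores_zero(self, factor_fixture):
        _, table, _, _ = factor_fixture
        model = nx.fit_factor_model(table, 4)
        mean_row = pd.DataFrame([model.col_means], index=["avg"],
                                columns=model.property_names)
        probe = nx.PropertyTable(pd.concat(
            [mean_row, mean_row.rename(index={"avg": "avg2"}) + 1.0]))
        scales = nx.compute_scores(model, probe)
        np.testing.assert_allclose(scales.scores("avg"), 0.0, atol=1e-10)

    def test_column_order_insensitive(self, factor_fixture):
        _, table, _, _ = factor_fixture
        model = nx.fit_factor_model(table, 3)
        shuffled = nx.PropertyTable(table.data[table.data.columns[::-1]])
        a = nx.compute_scores(model, table).data
        b = nx.compute_scores(model, shuffled).data
        pd.testing.assert_frame_equal(a, b)

    def test_column_mismatch_lists_names(self, factor_fixture):
        _, table, _, _ = factor_fixture
        model = nx.fit_factor_model(table, 3)
        bad = nx.PropertyTable(table.data.rename(
            columns={"prop001": "renamed"}))
        with pytest.raises(ValueError, match="prop001"):
            nx.compute_scores(model, bad)


class TestRotationAgainstR:
    def test_varimax_and_promax_match_base_r(self, factor_fixture):
        """Kaiser-normalized varimax and promax agree with R stats::varimax /
        stats::promax on the same unrotated loadings."""
        _, table, _, _ = factor_fixture
        A = nx.fit_factor_model(table, 3).unrotated_loadings
        np.savetxt("/tmp/nnaa_A.csv", A, delimiter=",")
        rcode = (
            'A <- as.matrix(read.csv("/tmp/nnaa_A.csv", header=FALSE));'
            'v <- varimax(A, normalize=TRUE);'
            'p <- promax(A, m=4);'
            'write.table(unclass(v$loadings), "/tmp/nnaa_v.csv", sep=",",'
            ' row.names=FALSE, col.names=FALSE);'
            'write.table(unclass(p$loadings), "/tmp/nnaa_p.csv", sep=",",'
            ' row.names=FALSE, col.names=FALSE)'
        )
        subprocess.run(["Rscript", "-e", rcode], check=True,
                       capture_output=True)
        v_r = np.loadtxt("/tmp/nnaa_v.csv", delimiter=",")
        p_r = np.loadtxt("/tmp/nnaa_p.csv", delimiter=",")
        v_py, _ = _varimax(A)
        p_py, _, _ = _promax(A)

        def aligned(est, ref):
            perm, _ = match_factors(est, ref)
            out = est[:, perm]
            for j in range(out.shape[1]):
                if out[:, j] @ ref[:, j] < 0:
                    out[:, j] = -out[:, j]
            return out

        assert np.max(np.abs(aligned(v_py, v_r) - v_r)) < 1e-3
        assert np.max(np.abs(aligned(p_py, p_r) - p_r)) < 1e-4


def test_eigenvalue_profile_sums_to_p(toy_property_table):
    prof = nx.eigenvalue_profile(toy_property_table)
    assert prof.sum() == pytest.approx(toy_property_table.values.shape[1])
    assert (np.diff(prof.to_numpy()) <= 1e-12).all()
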