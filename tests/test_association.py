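"""Refit t-statistics, matrix assembly/filtering, and clustering."""

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.cluster.hierarchy import fcluster
from scipy.spatial.distance import pdist
from scipy.special import expit

from faidr.association import (
    assemble_matrix,
    filter_features,
    hierarchical_cluster,
    refit_tstats,
    uncentered_correlation_distance,
    write_cdt,
)
from faidr.io import FaidrFit
from tests.conftest import make_table


def unit_fit(table, coefficients):
    return FaidrFit(
        function_name="f",
        feature_names=table.feature_names,
        coefficients=np.asarray(coefficients, float),
        intercept=0.0,
        idr_ids=table.idr_ids,
        responsibilities=np.ones(table.n_idrs),
        lambda_=0.2,
        alpha=0.99,
        n_em_iterations=1,
    )


class TestRefitTstats:
    def _simulate(self, effect, seed, n=1000):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((n, 2))
        y = (rng.random(n) < expit(effect * X[:, 0])).astype(float)
        return make_table(X, [1] * n), y

    def test_no_selection_gives_zeros(self):
        table, y = self._simulate(0.0, 0)
        t, capped = refit_tstats(table, y, unit_fit(table, [0.0, 0.0]))
        assert np.all(t == 0.0) and not capped

    def test_null_feature_small_t(self):
        table, y = self._simulate(0.0, 1)
        t, _ = refit_tstats(table, y, unit_fit(table, [0.1, 0.0]))
        assert abs(t[0]) < 3.0
        assert t[1] == 0.0  # unselected stays exactly zero

    def test_informative_feature_large_t(self):
        table, y = self._simulate(2.0, 2)
        t, _ = refit_tstats(table, y, unit_fit(table, [0.5, 0.0]))
        assert t[0] > 3.0

    def test_single_idr_matches_plain_logistic(self):
        """With one IDR per protein and unit responsibilities, the t-statistics
        equal those of an ordinary unweighted logistic regression."""
        table, y = self._simulate(1.0, 3, n=400)
        t, _ = refit_tstats(table, y, unit_fit(table, [0.5, -0.2]))
        ref = sm.Logit(y, sm.add_constant(table.X)).fit(disp=0)
        expected = np.asarray(ref.params[1:]) / np.asarray(ref.bse[1:])
        assert np.abs(t - expected).max() < 1e-6

    def test_separation_capped(self):
        # perfectly separable labels -> capped |t| = 50 with the warning flag
        X = np.r_[np.full((20, 1), -2.0), np.full((20, 1), 2.0)]
        X = X + np.linspace(0, 0.1, 40)[:, None]
        table = make_table(X, [1] * 40)
        y = np.r_[np.zeros(20), np.ones(20)]
        t, capped = refit_tstats(table, y, unit_fit(table, [1.0]))
        assert capped and abs(t[0]) == 50.0 and t[0] > 0


class TestAssembleFilter:
    def make(self):
        return assemble_matrix(
            [("fa", np.array([3.0, 0.0, -5.0])), ("fb", np.array([1.0, 0.0, 2.0]))],
            ["x", "y", "z"],
        )

    def test_assembly_and_zero_fill(self):
        m = self.make()
        assert m.values.shape == (2, 3)
        assert m.values.loc["fa", "z"] == -5.0
        assert not m.selected.loc["fa", "y"]

    def test_duplicate_functions_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            assemble_matrix([("fa", np.zeros(2)), ("fa", np.zeros(2))], ["x", "y"])

    def test_function_order_permutation_invariant_columns(self):
        m1 = self.make()
        m2 = assemble_matrix(
            [("fb", np.array([1.0, 0.0, 2.0])), ("fa", np.array([3.0, 0.0, -5.0]))],
            ["x", "y", "z"],
        )
        assert m1.feature_names == m2.feature_names
        assert m1.values.loc["fa"].equals(m2.values.loc["fa"])

    def test_threshold_inclusive_and_modes(self):
        m = self.make()
        signed = filter_features(m, 3.0, "signed")
        assert signed.feature_names == ["x"]  # t=3.0 kept (inclusive); z max is 2
        absolute = filter_features(m, 3.0, "absolute")
        assert absolute.feature_names == ["x", "z"]  # |-5| kept in absolute mode

    def test_all_zero_column_dropped(self):
        assert "y" not in filter_features(self.make(), 0.5).feature_names

    @pytest.mark.parametrize("mode", ["signed", "absolute"])
    def test_filter_monotone_in_threshold(self, mode):
        m = self.make()
        loose = set(filter_features(m, 1.0, mode).feature_names)
        tight = set(filter_features(m, 4.0, mode).feature_names)
        assert tight <= loose


class TestDistance:
    def test_closed_forms(self):
        x = np.array([1.0, 2.0, 3.0])
        assert uncentered_correlation_distance(x, x) == pytest.approx(0.0, abs=1e-12)
        assert uncentered_correlation_distance(x, -x) == pytest.approx(2.0, abs=1e-12)
        assert uncentered_correlation_distance(
            np.array([1.0, 0.0]), np.array([0.0, 1.0])
        ) == pytest.approx(1.0, abs=1e-12)

    def test_zero_norm_rejected(self):
        with pytest.raises(ValueError, match="zero-norm"):
            uncentered_correlation_distance(np.zeros(3), np.ones(3))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_properties_and_scipy_agreement(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.standard_normal((2, 5))
        d = uncentered_correlation_distance(x, y)
        assert 0.0 - 1e-12 <= d <= 2.0 + 1e-12
        assert d == pytest.approx(uncentered_correlation_distance(y, x), abs=1e-12)
        assert d == pytest.approx(float(pdist([x, y], "cosine")[0]), abs=1e-10)


class TestClustering:
    def planted(self):
        rng = np.random.default_rng(0)
        a = np.array([3.0, 3.0, 0.1, 0.1])
        b = np.array([0.1, 0.1, 3.0, 3.0])
        rows = [(f"fa{i}", a + 0.05 * rng.standard_normal(4)) for i in range(4)]
        rows += [(f"fb{i}", b + 0.05 * rng.standard_normal(4)) for i in range(4)]
        return assemble_matrix(rows, ["w", "x", "y", "z"])

    def test_identical_rows_merge_at_zero(self):
        m = assemble_matrix(
            [(f, np.array([1.0, 2.0])) for f in "abc"], ["x", "y"]
        )
        res = hierarchical_cluster(m, axis="rows")
        assert np.allclose(res.linkage[:, 2], 0.0, atol=1e-12)

    def test_planted_partition_recovered(self):
        res = hierarchical_cluster(self.planted(), axis="rows")
        groups = fcluster(res.linkage, 2, criterion="maxclust")
        assert len(set(groups[:4])) == 1 and len(set(groups[4:])) == 1
        assert groups[0] != groups[4]

    def test_leaf_order_deterministic(self):
        m = self.planted()
        r1 = hierarchical_cluster(m, axis="columns")
        r2 = hierarchical_cluster(m, axis="columns")
        assert r1.ordered_names == r2.ordered_names

    def test_too_few_items(self):
        m = assemble_matrix([("fa", np.array([1.0, 2.0]))], ["x", "y"])
        with pytest.raises(ValueError, match="at least 2"):
            hierarchical_cluster(m, axis="rows")

    def test_cdt_output_readable(self, tmp_path):
        import pandas as pd

        m = self.planted()
        path = str(tmp_path / "out.cdt")
        write_cdt(m, path, hierarchical_cluster(m, "rows"), hierarchical_cluster(m, "columns"))
        df = pd.read_csv(path, sep="\t", skiprows=[1])
        assert df.shape[0] == 8 and set(["w", "x", "y", "z"]) <= set(df.columns)
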