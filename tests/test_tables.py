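import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from biodivmap.tables import (
    CovariateTable,
    IncidenceMatrix,
    call_presences,
    compute_vifs,
    filter_by_incidence,
    reduce_covariates_vif,
    split_train_test,
    train_size,
)


def make_incidence(values, point_ids=None):
    values = np.asarray(values)
    n, s = values.shape
    return IncidenceMatrix(
        values=values,
        sample_ids=[f"s{i}" for i in range(n)],
        point_ids=point_ids or [f"p{i}" for i in range(n)],
        species_ids=[f"sp{j}" for j in range(s)],
        x=np.arange(n, dtype=float),
        y=np.arange(n, dtype=float) ** 2,
    )


def make_covariates(values):
    values = np.asarray(values, dtype=float)
    return CovariateTable(
        values=values,
        covariate_names=[f"c{j}" for j in range(values.shape[1])],
        sample_ids=[f"s{i}" for i in range(values.shape[0])],
    )


class TestCallPresences:
    def coverage(self, rows):
        return pd.DataFrame(rows, columns=["sample_id", "species_id", "covered_fraction"])

    def test_strictly_above_half_is_presence(self):
        Y = call_presences(self.coverage([("a", "x", 0.51)]))
        assert Y.values[0, 0] == 1

    def test_exactly_half_is_absence(self):
        Y = call_presences(self.coverage([("a", "x", 0.50)]))
        assert Y.values[0, 0] == 0

    def test_zero_coverage_is_absence(self):
        Y = call_presences(self.coverage([("a", "x", 0.0)]))
        assert Y.values[0, 0] == 0

    def test_missing_pairs_are_absences(self):
        Y = call_presences(
            self.coverage([("a", "x", 0.9), ("b", "y", 0.8)]),
        )
        assert Y.values.sum() == 2
        assert Y.values[Y.sample_ids.index("a"), Y.species_ids.index("y")] == 0

    def test_fraction_out_of_range_raises(self):
        with pytest.raises(ValueError):
            call_presences(self.coverage([("a", "x", 1.2)]))

    def test_duplicate_pairs_raise(self):
        with pytest.raises(ValueError):
            call_presences(self.coverage([("a", "x", 0.6), ("a", "x", 0.7)]))

    def test_roundtrip_identity_on_binary_fractions(self):
        # encoding an incidence matrix as 0/1 coverage fractions and
        # re-calling presences is the identity
        Y = make_incidence([[1, 0], [0, 1], [1, 1]])
        rows = [
            (s, sp, float(Y.values[i, j]))
            for i, s in enumerate(Y.sample_ids)
            for j, sp in enumerate(Y.species_ids)
        ]
        df = pd.DataFrame(rows, columns=["sample_id", "species_id", "covered_fraction"])
        back = call_presences(df, sample_ids=Y.sample_ids, species_ids=Y.species_ids)
        np.testing.assert_array_equal(back.values, Y.values)


class TestFilterByIncidence:
    def test_below_threshold_dropped(self):
        values = np.zeros((10, 2), dtype=int)
        values[:5, 0] = 1  # incidence 5: dropped at min_sites=6
        values[:6, 1] = 1  # incidence 6: kept
        kept = filter_by_incidence(make_incidence(values), min_sites=6)
        assert kept.species_ids == ["sp1"]

    def test_min_one_keeps_any_presence(self):
        values = np.zeros((4, 3), dtype=int)
        values[0, 0] = 1
        values[1, 2] = 1
        kept = filter_by_incidence(make_incidence(values), min_sites=1)
        assert kept.species_ids == ["sp0", "sp2"]

    def test_all_below_gives_empty_with_warning(self, caplog):
        values = np.zeros((4, 2), dtype=int)
        with caplog.at_level("WARNING"):
            kept = filter_by_incidence(make_incidence(values), min_sites=1)
        assert kept.n_species == 0
        assert any("removed every species" in r.message for r in caplog.records)

    def test_idempotent(self):
        values = (np.arange(40).reshape(8, 5) % 3 == 0).astype(int)
        once = filter_by_incidence(make_incidence(values), min_sites=2)
        twice = filter_by_incidence(once, min_sites=2)
        np.testing.assert_array_equal(once.values, twice.values)
        assert once.species_ids == twice.species_ids

    def test_order_preserved(self):
        values = np.ones((6, 4), dtype=int)
        kept = filter_by_incidence(make_incidence(values), min_sites=2)
        assert kept.species_ids == ["sp0", "sp1", "sp2", "sp3"]

    def test_empty_matrix_raises(self):
        Y = make_incidence(np.ones((3, 2), dtype=int))
        Y.values = np.empty((0, 0), dtype=np.int8)
        Y.sample_ids, Y.point_ids, Y.species_ids = [], [], []
        with pytest.raises(ValueError):
            filter_by_incidence(Y)


class TestVIF:
    def test_duplicate_column_removed_exactly_once(self, rng):
        base = rng.normal(size=(40, 1))
        values = np.column_stack([base, base, rng.normal(size=(40, 2))])
        reduced, log = reduce_covariates_vif(make_covariates(values), vif_threshold=10)
        assert reduced.n_covariates == 3
        assert len(log) == 1
        assert log["covariate"].iloc[0] == "c0"  # tie broken by column order

    def test_orthogonal_columns_untouched(self):
        n = 8
        q, _ = np.linalg.qr(np.random.default_rng(1).normal(size=(n, 4)))
        reduced, log = reduce_covariates_vif(make_covariates(q), vif_threshold=1.5)
        assert reduced.n_covariates == 4
        assert len(log) == 0

    def test_vif_matches_statsmodels_oracle(self, rng):
        from statsmodels.stats.outliers_influence import variance_inflation_factor
        import statsmodels.api as sm

        X = rng.normal(size=(50, 5))
        X[:, 0] += 0.8 * X[:, 1]  # induce collinearity
        ours = compute_vifs(X)
        design = sm.add_constant(X)
        theirs = [variance_inflation_factor(design, k + 1) for k in range(5)]
        np.testing.assert_allclose(ours, theirs, rtol=1e-8)

    def test_final_vifs_below_threshold(self, rng):
        X = rng.normal(size=(60, 6))
        X[:, 0] = X[:, 1] + 0.05 * rng.normal(size=60)
        X[:, 2] = X[:, 3] - X[:, 4] + 0.05 * rng.normal(size=60)
        reduced, _ = reduce_covariates_vif(make_covariates(X), vif_threshold=5)
        assert np.all(compute_vifs(reduced.values) <= 5)

    def test_more_covariates_than_rows_raises(self, rng):
        with pytest.raises(ValueError):
            reduce_covariates_vif(make_covariates(rng.normal(size=(3, 5))))

    def test_single_covariate_raises(self, rng):
        with pytest.raises(ValueError):
            reduce_covariates_vif(make_covariates(rng.normal(size=(10, 1))))


class TestSplit:
    def test_reference_split_sizes_121(self):
        assert train_size(121, 0.75) == 91
        Y = make_incidence(np.ones((121, 2), dtype=int))
        X = make_covariates(np.random.default_rng(0).normal(size=(121, 3)))
        split = split_train_test(Y, X, 0.75, seed=0)
        assert split.Y_train.n_samples == 91
        assert split.Y_test.n_samples == 30

    def test_rounding_ties_up(self):
        assert train_size(4, 0.75) == 3  # 3.0 exact
        assert train_size(2, 0.75) == 2  # 1.5 -> 2 (ties up)
        Y = make_incidence(np.ones((4, 2), dtype=int))
        X = make_covariates(np.zeros((4, 2)))
        split = split_train_test(Y, X, 0.75, seed=1)
        assert (split.Y_train.n_samples, split.Y_test.n_samples) == (3, 1)

    def test_empty_partition_raises(self):
        Y = make_incidence(np.ones((10, 2), dtype=int))
        X = make_covariates(np.zeros((10, 2)))
        with pytest.raises(ValueError):
            split_train_test(Y, X, 0.999, seed=0)

    def test_invalid_fraction_raises(self):
        Y = make_incidence(np.ones((10, 2), dtype=int))
        X = make_covariates(np.zeros((10, 2)))
        for frac in (0.0, 1.0, -0.5):
            with pytest.raises(ValueError):
                split_train_test(Y, X, frac, seed=0)

    @given(n=st.integers(5, 200), seed=st.integers(0, 100))
    @settings(max_examples=25, deadline=None)
    def test_partitions_disjoint_and_exhaustive(self, n, seed):
        Y = make_incidence(np.ones((n, 2), dtype=int))
        X = make_covariates(np.zeros((n, 2)))
        split = split_train_test(Y, X, 0.75, seed=seed)
        merged = np.sort(np.concatenate([split.train_idx, split.test_idx]))
        np.testing.assert_array_equal(merged, np.arange(n))

    def test_group_by_point_keeps_pairs_together(self):
        point_ids = [f"p{i // 2}" for i in range(40)]  # 20 points, all paired
        Y = make_incidence(np.ones((40, 2), dtype=int), point_ids=point_ids)
        X = make_covariates(np.zeros((40, 2)))
        split = split_train_test(Y, X, 0.75, seed=3, group_by_point=True)
        train_points = set(split.Y_train.point_ids)
        assert train_points.isdisjoint(set(split.Y_test.point_ids))

    def test_seeded_reproducibility(self):
        Y = make_incidence(np.ones((30, 2), dtype=int))
        X = make_covariates(np.zeros((30, 2)))
        a = split_train_test(Y, X, 0.75, seed=5)
        b = split_train_test(Y, X, 0.75, seed=5)
        np.testing.assert_array_equal(a.train_idx, b.train_idx)
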