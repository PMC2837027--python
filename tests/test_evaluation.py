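"""Accuracy measures and the repeated random-split evaluation protocol."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from duplexnn import (
    GeneratorConfig,
    SplitSpec,
    export_correlation_table,
    generate_dataset,
    mfe_ad,
    pearson,
    random_split,
    repeated_evaluation,
    rmse,
    summarize,
)


class TestPointMeasures:
    @pytest.mark.parametrize("a,b,expected", [(-5.0, -5.0, 0.0), (-5.0, -7.5, 2.5)])
    def test_mfe_ad(self, a, b, expected):
        assert mfe_ad(a, b) == expected
        assert mfe_ad(b, a) == expected

    def test_pearson_extremes(self):
        assert pearson([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)
        assert pearson([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_pearson_zero_variance_warns_nan(self):
        with pytest.warns(UserWarning, match="variance"):
            assert np.isnan(pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))

    def test_pearson_matches_covariance_oracle(self, rng):
        x, y = rng.normal(size=10), rng.normal(size=10)
        # direct textbook formula
        expected = float(
            np.sum((x - x.mean()) * (y - y.mean()))
            / np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        )
        assert pearson(x, y) == pytest.approx(expected, abs=1e-12)

    def test_rmse_examples(self):
        assert rmse([1.0, 2.0], [1.0, 2.0]) == 0.0
        assert rmse([0.0, 0.0], [3.0, 4.0]) == pytest.approx(np.sqrt(12.5))

    def test_rmse_pair_order_invariance(self, rng):
        x, y = rng.normal(size=8), rng.normal(size=8)
        perm = rng.permutation(8)
        assert rmse(x, y) == pytest.approx(rmse(x[perm], y[perm]))


class TestRandomSplit:
    @pytest.mark.parametrize("n,train,test", [(340, 228, 112), (197, 132, 65)])
    def test_published_design_sizes(self, n, train, test):
        assert SplitSpec(0.67, 1, 0).train_size(n) == train
        assert n - SplitSpec(0.67, 1, 0).train_size(n) == test

    def test_partition(self, synth_noise_free):
        tr, te = random_split(synth_noise_free, SplitSpec(0.67, 1, 7), 0)
        ids = sorted(r.duplex_id for r in tr) + sorted(r.duplex_id for r in te)
        assert sorted(ids) == sorted(r.duplex_id for r in synth_noise_free)
        assert not set(r.duplex_id for r in tr) & set(r.duplex_id for r in te)

    def test_reproducible_per_iteration(self, synth_noise_free):
        spec = SplitSpec(0.67, 5, 11)
        a = random_split(synth_noise_free, spec, 3)
        b = random_split(synth_noise_free, spec, 3)
        assert [r.duplex_id for r in a[0]] == [r.duplex_id for r in b[0]]
        c = random_split(synth_noise_free, spec, 4)
        assert [r.duplex_id for r in a[0]] != [r.duplex_id for r in c[0]]


class TestRepeatedEvaluation:
    def test_noise_free_is_exact(self, synth_noise_free):
        res = repeated_evaluation(synth_noise_free, 3, SplitSpec(0.67, 50, 2))
        assert np.all(res.rmse_values <= 1e-9)
        finite = res.r_values[np.isfinite(res.r_values)]
        np.testing.assert_allclose(finite, 1.0, atol=1e-9)

    def test_deterministic_under_seed(self, synth_noise_free):
        a = repeated_evaluation(synth_noise_free, 3, SplitSpec(0.67, 10, 9))
        b = repeated_evaluation(synth_noise_free, 3, SplitSpec(0.67, 10, 9))
        np.testing.assert_array_equal(a.rmse_values, b.rmse_values)
        np.testing.assert_array_equal(a.r_values, b.r_values)
        assert a.best_iteration == b.best_iteration
        assert dict(a.best_params.values) == dict(b.best_params.values)

    def test_rmse_monotone_in_noise(self):
        means = []
        for sd in (0.0, 0.5, 2.0):
            ds = generate_dataset(GeneratorConfig(n_duplexes=150, noise_sd=sd, seed=31))
            res = repeated_evaluation(ds, 3, SplitSpec(0.67, 30, 5))
            means.append(res.rmse_values.mean())
        assert means[0] <= means[1] <= means[2]

    def test_seed_families_statistically_indistinguishable(self):
        # different master seeds change the splits but not the RMSE distribution
        from scipy import stats

        ds = generate_dataset(GeneratorConfig(n_duplexes=150, noise_sd=0.5, seed=8))
        a = repeated_evaluation(ds, 3, SplitSpec(0.67, 100, 1))
        b = repeated_evaluation(ds, 3, SplitSpec(0.67, 100, 2))
        assert not np.array_equal(a.rmse_values, b.rmse_values)
        assert stats.ks_2samp(a.rmse_values, b.rmse_values).pvalue > 0.01

    def test_best_selection_criterion(self):
        ds = generate_dataset(GeneratorConfig(n_duplexes=150, noise_sd=0.5, seed=17))
        res = repeated_evaluation(ds, 3, SplitSpec(0.67, 20, 4))
        r = np.where(np.isfinite(res.r_values), res.r_values, -np.inf)
        best = res.best_iteration
        assert r[best] == r.max()
        # among max-r iterations: lowest RMSE, then lowest index
        ties = np.flatnonzero(r == r.max())
        winners = ties[res.rmse_values[ties] == res.rmse_values[ties].min()]
        assert best == winners.min()


class TestSummarize:
    def test_examples(self):
        s = summarize([1, 2, 3, 4, 5])
        assert (s.min, s.median, s.max, s.mean) == (1, 3, 5, 3)

    def test_constant_vector(self):
        s = summarize([2.0, 2.0, 2.0])
        assert s.stddev == 0 and s.q1 == s.q3 == 2.0

    @given(st.lists(st.floats(-100, 100), min_size=1, max_size=50))
    def test_matches_order_statistics_oracle(self, values):
        s = summarize(values)
        v = np.sort(np.asarray(values, dtype=float))
        assert s.min == v[0] and s.max == v[-1]
        assert s.min <= s.q1 <= s.median <= s.q3 <= s.max
        # type-7 quantile: linear interpolation at h = (n-1)p
        for q, p in ((s.q1, 0.25), (s.median, 0.5), (s.q3, 0.75)):
            h = (len(v) - 1) * p
            lo, hi = int(np.floor(h)), int(np.ceil(h))
            assert q == pytest.approx(v[lo] + (h - lo) * (v[hi] - v[lo]), abs=1e-9)

    def test_mfe_ad_summary_nonnegative(self, rng):
        diffs = [mfe_ad(a, b) for a, b in rng.normal(size=(30, 2))]
        s = summarize(diffs)
        assert s.min >= 0 and s.mean >= 0


class TestExportCorrelationTable:
    def test_row_per_duplex(self, synth_noise_free):
        from duplexnn import load_reference_parameters, estimate_free_energy

        params = load_reference_parameters(3)
        table = export_correlation_table(synth_noise_free, params)
        assert len(table) == len(synth_noise_free)
        r0 = synth_noise_free[0]
        assert table.loc[0, "dg_est"] == pytest.approx(
            estimate_free_energy(r0.seq1, params)
        )

    def test_empty(self):
        from duplexnn import DuplexDataset, load_reference_parameters

        table = export_correlation_table(DuplexDataset([], "x"), load_reference_parameters(3))
        assert len(table) == 0
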