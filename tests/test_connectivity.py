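"""Correlation, FDR-thresholding and window arithmetic tests.

The BH-FDR brute-force oracle tests every candidate threshold i*q/m over
the sorted p-values; the Pearson p-value oracle integrates the Student-t
density numerically.  Both stay independent of the implementation paths
they check.
"""

import numpy as np
import pytest
import scipy.integrate
import scipy.special
from hypothesis import given, strategies as st

import dynfc as d
from dynfc.io_formats import ValidationError


def bh_oracle(p, q):
    """Brute-force Benjamini-Hochberg: largest p_(i) <= i*q/m is the cut."""
    p = np.asarray(p)
    m = p.size
    order = np.sort(p)
    cut = 0.0
    for i, pv in enumerate(order, start=1):
        if pv <= i * q / m:
            cut = pv
    return p <= cut if cut > 0 else np.zeros(m, bool)


def t_sf_oracle(tval, df):
    """Two-sided p by numerical integration of the t density."""
    c = scipy.special.gamma((df + 1) / 2) / (
        np.sqrt(df * np.pi) * scipy.special.gamma(df / 2)
    )
    dens = lambda x: c * (1 + x**2 / df) ** (-(df + 1) / 2)
    tail, _ = scipy.integrate.quad(dens, abs(tval), np.inf)
    return 2 * tail


def _ts(data, tr=2.0):
    return d.RoiTimeSeries(np.asarray(data, float), tr_s=tr,
                           roi_labels=[f"r{i}" for i in range(np.asarray(data).shape[1])])


class TestZscore:
    def test_mean_zero_sd_one(self, rng):
        ts = _ts(rng.standard_normal((50, 4)) * 3 + 5)
        z = d.zscore(ts)
        assert np.allclose(z.data.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(z.data.std(axis=0, ddof=1), 1, atol=1e-12)

    def test_idempotent(self, rng):
        ts = _ts(rng.standard_normal((30, 3)))
        once = d.zscore(ts)
        twice = d.zscore(once)
        assert np.allclose(once.data, twice.data, atol=1e-12)

    def test_constant_column_names_roi(self):
        data = np.column_stack([np.arange(10.0), np.full(10, 2.0)])
        with pytest.raises(ValidationError, match="r1"):
            d.zscore(_ts(data))

    def test_pearson_invariant_to_zscoring(self, rng):
        ts = _ts(rng.standard_normal((40, 6)) * 7 + 2)
        r_raw = d.pearson_with_pvalues(ts).r
        r_z = d.pearson_with_pvalues(d.zscore(ts)).r
        assert np.allclose(r_raw, r_z, atol=1e-12)


class TestSplitConcat:
    def test_task_run_halves(self):
        ts = _ts(np.random.default_rng(0).standard_normal((252, 4)))
        a, b = d.split_halves(ts)
        assert a.n_vols == b.n_vols == 126
        assert a.duration_s == b.duration_s == 252.0
        assert np.array_equal(np.vstack([a.data, b.data]), ts.data)
        assert (a.session_id, b.session_id) == ("task1", "task2")

    def test_odd_volume_count_rejected(self):
        with pytest.raises(ValidationError):
            d.split_halves(_ts(np.zeros((5, 2)) + np.arange(5)[:, None]))

    def test_group_concatenation_of_19_subjects(self, rng):
        subs = [_ts(rng.standard_normal((126, 3))) for _ in range(19)]
        group = d.concat_subjects(subs)
        assert group.n_vols == 19 * 126 == 2394

    def test_single_subject_identity(self, rng):
        ts = _ts(rng.standard_normal((10, 3)))
        assert np.array_equal(d.concat_subjects([ts]).data, ts.data)

    def test_label_mismatch_rejected(self, rng):
        a = _ts(rng.standard_normal((10, 2)))
        b = d.RoiTimeSeries(rng.standard_normal((10, 2)), tr_s=2.0,
                            roi_labels=["x", "y"])
        with pytest.raises(ValidationError):
            d.concat_subjects([a, b])


class TestPearson:
    def test_perfect_linear_dependence(self):
        x = np.arange(10.0)
        res = d.pearson_with_pvalues(_ts(np.column_stack([x, 2 * x])))
        assert res.r[0, 1] == pytest.approx(1.0, abs=1e-12)
        assert res.p[0, 1] == 0.0

    def test_independent_columns_near_zero(self, rng):
        x = rng.standard_normal(1000)
        y = rng.permutation(x)
        res = d.pearson_with_pvalues(_ts(np.column_stack([x, y])))
        assert abs(res.r[0, 1]) < 0.1
        assert res.p[0, 1] > 0.001

    def test_p_matches_t_density_integration(self, rng):
        n = 22
        data = rng.standard_normal((n, 2))
        data[:, 1] += 0.5 * data[:, 0]
        res = d.pearson_with_pvalues(_ts(data))
        r = res.r[0, 1]
        t = r * np.sqrt((n - 2) / (1 - r**2))
        assert res.p[0, 1] == pytest.approx(t_sf_oracle(t, n - 2), abs=1e-12)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValidationError):
            d.pearson_with_pvalues(_ts(np.array([[0.0, 1.0], [1.0, 0.0]])))


class TestFdrThreshold:
    def _result(self, p_upper, r_value=0.5):
        # Build a CorrelationResult with prescribed upper-triangle p-values.
        k = p_upper.shape[0]
        r = np.full((k, k), r_value)
        np.fill_diagonal(r, 1.0)
        p = np.zeros((k, k))
        iu = np.triu_indices(k, 1)
        p[iu] = p_upper[iu]
        p = p + p.T
        return d.CorrelationResult(r=r, p=p, n_samples=100,
                                   labels=[f"r{i}" for i in range(k)])

    def test_all_tiny_p_survive(self):
        res = d.fdr_threshold(self._result(np.full((5, 5), 1e-6)), q=0.05)
        iu = np.triu_indices(5, 1)
        assert np.all(res.thresholded[iu] == 0.5)

    def test_all_half_p_all_zeroed(self):
        res = d.fdr_threshold(self._result(np.full((5, 5), 0.5)), q=0.05)
        assert np.all(res.thresholded == 0)

    def test_stepup_vector_example(self):
        # p = {0.01, 0.02, 0.03, 0.04}, m = 4, q = 0.05: the largest p equals
        # 4 * 0.05 / 4, so every hypothesis is rejected by the step-up rule.
        survivors = bh_oracle(np.array([0.01, 0.02, 0.03, 0.04]), q=0.05)
        assert survivors.all()

    def test_matches_brute_force_oracle(self, rng):
        iu = np.triu_indices(8, 1)
        for _ in range(200):
            pu = np.zeros((8, 8))
            pu[iu] = rng.uniform(0, 0.2, iu[0].size)
            res = d.fdr_threshold(self._result(pu), q=0.05)
            expect = bh_oracle(pu[iu], 0.05)
            assert np.array_equal(res.thresholded[iu] != 0, expect)

    def test_symmetric_zero_diagonal(self, rng):
        pu = np.zeros((6, 6))
        iu = np.triu_indices(6, 1)
        pu[iu] = rng.uniform(0, 1, iu[0].size)
        res = d.fdr_threshold(self._result(pu), q=0.5)
        assert np.array_equal(res.thresholded, res.thresholded.T)
        assert np.all(np.diag(res.thresholded) == 0)

    def test_negative_correlations_survive(self, rng):
        res = self._result(np.full((4, 4), 1e-8), r_value=-0.7)
        thr = d.fdr_threshold(res, q=0.05).thresholded
        iu = np.triu_indices(4, 1)
        assert np.all(thr[iu] == -0.7)

    def test_bad_q_rejected(self):
        with pytest.raises(ValueError):
            d.fdr_threshold(self._result(np.full((4, 4), 0.5)), q=1.5)


class TestMakeWindows:
    @pytest.mark.parametrize(
        "n_vols,window_s,expected",
        [(126, 44, 105), (90, 44, 69), (126, 66, 94), (90, 66, 58)],
    )
    def test_printed_window_counts(self, n_vols, window_s, expected):
        assert d.make_windows(n_vols, window_s, 2.0).n_windows == expected

    def test_single_window_when_window_fills_series(self):
        spec = d.make_windows(22, 44, 2.0)
        assert spec.n_windows == 1
        assert list(spec.starts) == [0]

    def test_window_longer_than_series_rejected(self):
        with pytest.raises(ValidationError):
            d.make_windows(20, 44, 2.0)

    @given(
        n_vols=st.integers(2, 200),
        window_vols=st.integers(2, 200),
        step=st.integers(1, 10),
    )
    def test_count_matches_enumeration(self, n_vols, window_vols, step):
        # Oracle: count the valid 0-based start indices one by one.
        valid = [s for s in range(n_vols) if s % step == 0
                 and s + window_vols <= n_vols]
        if window_vols > n_vols:
            with pytest.raises(ValidationError):
                d.make_windows(n_vols, window_vols * 2.0, 2.0, step)
        else:
            spec = d.make_windows(n_vols, window_vols * 2.0, 2.0, step)
            assert spec.n_windows == len(valid)
            assert list(spec.starts) == valid


class TestWindowedConnectivity:
    def test_window_count_and_block_dominance(self, planted_two_block):
        ts, part = planted_two_block
        spec = d.make_windows(ts.n_vols, 44, 2.0)
        wc = d.windowed_connectivity(ts, spec, q=0.05)
        assert len(wc.results) == spec.n_windows == 105
        same = np.equal.outer([part[i] for i in range(32)],
                              [part[i] for i in range(32)])
        np.fill_diagonal(same, False)
        for res in wc.results:
            thr = np.abs(res.thresholded)
            assert thr[same].mean() > thr[~same].mean()

    def test_constant_partition_windows_similar(self, planted_two_block):
        ts, _ = planted_two_block
        spec = d.make_windows(ts.n_vols, 44, 2.0)
        wc = d.windowed_connectivity(ts, spec, q=0.05)
        rs = np.stack([res.r for res in wc.results])
        diffs = [np.abs(rs[i] - rs[j]).mean()
                 for i in range(0, 105, 20) for j in range(0, 105, 20)]
        assert np.mean(diffs) < 0.2

    def test_group_mode_sample_size(self, rng):
        subs = [_ts(rng.standard_normal((30, 4))) for _ in range(3)]
        spec = d.make_windows(30, 20, 2.0)
        wc = d.windowed_connectivity(subs, spec, q=0.05)
        assert all(res.n_samples == 30 for res in wc.results)


class TestQuarterAverage:
    @pytest.mark.parametrize(
        "n,expected",
        [(105, (26, 26, 26, 27)), (69, (17, 17, 17, 18)),
         (94, (24, 24, 24, 22)), (58, (15, 15, 15, 13))],
    )
    def test_group_sizes(self, n, expected):
        assert d.quarter_group_sizes(n) == expected

    def _uniform_wc(self, n_windows, rng):
        spec = d.make_windows(n_windows + 21, 44, 2.0)
        assert spec.n_windows == n_windows
        m = rng.standard_normal((6, 6))
        r = np.corrcoef(m @ m.T)
        p = np.full_like(r, 1e-4)
        np.fill_diagonal(p, 0.0)
        res = d.CorrelationResult(r=r, p=p, n_samples=22,
                                  labels=[f"r{i}" for i in range(6)])
        return d.WindowedConnectivity(
            spec=spec, results=[res] * n_windows, tr_s=2.0
        )

    def test_identical_windows_average_to_common_matrix(self, rng):
        wc = self._uniform_wc(8, rng)
        quarters = d.quarter_average(wc)
        assert len(quarters) == 4
        for qa in quarters:
            assert np.allclose(qa.result.r, wc.results[0].r, atol=1e-12)

    def test_time_labels(self, rng):
        wc = self._uniform_wc(105, rng)
        labels = [qa.label for qa in d.quarter_average(wc)]
        assert labels == ["1-51", "53-103", "105-155", "157-209"]

    def test_too_few_windows_rejected(self, rng):
        wc = self._uniform_wc(8, rng)
        wc3 = d.WindowedConnectivity(
            spec=d.make_windows(24, 44, 2.0), results=wc.results[:3], tr_s=2.0
        )
        with pytest.raises(ValidationError):
            d.quarter_average(wc3)


class TestNetworkAverage:
    def test_fixture_table_reduces_32_to_8(self, roi_table, rng):
        ts = d.RoiTimeSeries(rng.standard_normal((20, 32)), tr_s=2.0,
                             roi_labels=list(roi_table["label"]))
        nets = d.network_average(ts, roi_table)
        assert nets.n_rois == 8
        assert nets.roi_labels == list(d.io_formats.NETWORK_NAMES)
        dmn = roi_table[roi_table["network"] == "DMN"]["label"]
        idx = [ts.roi_labels.index(lab) for lab in dmn]
        assert np.allclose(nets.data[:, 0], ts.data[:, idx].mean(axis=1))

    def test_identical_rois_give_identical_networks(self, roi_table):
        sig = np.sin(np.arange(20.0))[:, None]
        ts = d.RoiTimeSeries(np.repeat(sig, 32, axis=1), tr_s=2.0,
                             roi_labels=list(roi_table["label"]))
        nets = d.network_average(ts, roi_table)
        assert np.allclose(nets.data, sig, atol=1e-12)

    def test_unknown_label_rejected(self, roi_table, rng):
        ts = _ts(rng.standard_normal((10, 2)))
        with pytest.raises(ValidationError):
            d.network_average(ts, roi_table)
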