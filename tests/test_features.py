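"""Epoch segmentation, the six features against brute-force oracles, scaling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nirscombo.features import (
    FEATURE_NAMES,
    DegenerateEpochError,
    Epoch,
    MinMaxScaling,
    compute_features,
    epochize,
    feat_kurtosis,
    feat_mean,
    feat_peak,
    feat_skewness,
    feat_slope,
    feat_variance,
    feature_table,
    rescale_minmax,
)
from nirscombo.mbll import HemoSeries
from nirscombo.synthetic import ParadigmSpec, build_block_labels


def make_epoch(data, fs=1.81, label="task"):
    data = np.asarray(data, dtype=float)
    return Epoch(subject_id=0, channel_index=0, label=label, start=0,
                 end=data.size, chromophore="HbO", data=data,
                 t=np.arange(data.size) / fs)


class TestEpochize:
    def test_default_paradigm_epoch_counts(self):
        p = ParadigmSpec()
        labels = build_block_labels(p)
        rng = np.random.default_rng(0)
        x = HemoSeries(hbo=rng.normal(size=(labels.size, 16)),
                       hbr=rng.normal(size=(labels.size, 16)), fs=p.fs_out)
        epochs = epochize(x, labels)
        task = [e for e in epochs if e.label == "task"]
        assert len(task) == 5 * 16 * 2  # 160 task epochs per subject
        assert len(epochs) == 11 * 16 * 2  # 5 task + 6 rest blocks

    def test_single_channel_single_trial(self):
        labels = np.array([0, 0, 1, 1, 0, 0])
        x = HemoSeries(hbo=np.arange(6.0).reshape(-1, 1),
                       hbr=np.zeros((6, 1)), fs=1.0)
        epochs = epochize(x, labels, chromophores=("HbO",))
        assert [e.label for e in epochs] == ["rest", "task", "rest"]
        np.testing.assert_array_equal(epochs[1].data, [2.0, 3.0])
        # half-open ranges tile the series without overlap
        assert [(e.start, e.end) for e in epochs] == [(0, 2), (2, 4), (4, 6)]

    def test_drop_initial_rest_balances_classes(self):
        labels = np.array([0, 0, 1, 1, 0, 0])
        x = HemoSeries(hbo=np.zeros((6, 1)), hbr=np.zeros((6, 1)), fs=1.0)
        epochs = epochize(x, labels, chromophores=("HbO",), drop_initial_rest=True)
        assert [e.label for e in epochs] == ["task", "rest"]

    def test_misaligned_and_empty_labels_rejected(self):
        x = HemoSeries(hbo=np.zeros((6, 1)), hbr=np.zeros((6, 1)), fs=1.0)
        with pytest.raises(ValueError):
            epochize(x, np.array([0, 1]))
        with pytest.raises(ValueError):
            epochize(x, np.array([]))


class TestFeatureValues:
    @pytest.mark.parametrize("func,data,expected", [
        (feat_mean, [1, 2, 3], 2.0),
        (feat_mean, [7, 7, 7], 7.0),
        (feat_variance, [1, 2, 3], 2.0 / 3.0),  # population variance, divide by N
        (feat_variance, [5, 5], 0.0),
        (feat_skewness, [-1, 0, 1], 0.0),
        (feat_kurtosis, [-1, 1, -1, 1], 1.0),  # two-point distribution
        (feat_peak, [0.1, 0.5, 0.3], 0.5),
        (feat_peak, [-3, -1, -2], -1.0),  # signed maximum, not absolute
    ])
    def test_hand_computed_examples(self, func, data, expected):
        assert func(make_epoch(data)) == pytest.approx(expected, abs=1e-12)

    def test_absolute_peak_option(self):
        e = make_epoch([-3.0, -1.0, -2.0])
        assert feat_peak(e) == -1.0
        assert feat_peak(e, absolute=True) == 3.0

    def test_slope_of_exact_line_and_constant(self):
        e = Epoch(subject_id=0, channel_index=0, label="task", start=0, end=3,
                  chromophore="HbO", data=np.array([0.0, 1.0, 2.0]),
                  t=np.array([0.0, 1.0, 2.0]))
        assert feat_slope(e) == pytest.approx(1.0, abs=1e-12)
        assert feat_slope(make_epoch([4.0, 4.0, 4.0])) == pytest.approx(0.0, abs=1e-12)

    def test_brute_force_oracles_on_random_epochs(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            data = rng.normal(0, rng.uniform(0.5, 3), size=rng.integers(5, 120))
            e = make_epoch(data)
            n = data.size
            mu = sum(data) / n
            var = sum((v - mu) ** 2 for v in data) / n
            sd = var ** 0.5
            skew = sum(((v - mu) / sd) ** 3 for v in data) / n
            kurt = sum(((v - mu) / sd) ** 4 for v in data) / n
            # closed-form least-squares slope via normal equations
            t = e.t
            slope = (n * (t * data).sum() - t.sum() * data.sum()) / (
                n * (t * t).sum() - t.sum() ** 2)
            got = compute_features(e)
            assert got["mean"] == pytest.approx(mu, rel=1e-12, abs=1e-12)
            assert got["variance"] == pytest.approx(var, rel=1e-12)
            assert got["skewness"] == pytest.approx(skew, rel=1e-10, abs=1e-10)
            assert got["kurtosis"] == pytest.approx(kurt, rel=1e-10)
            assert got["peak"] == max(data)
            assert got["slope"] == pytest.approx(slope, rel=1e-9)

    def test_degenerate_epoch_raises_then_drops_in_batch_mode(self, caplog):
        const = make_epoch([2.0, 2.0, 2.0])
        with pytest.raises(DegenerateEpochError):
            feat_skewness(const)
        with pytest.raises(DegenerateEpochError):
            feat_kurtosis(const)
        ok = make_epoch([1.0, 2.0, 3.0])
        df = feature_table([const, ok], on_degenerate="drop")
        assert len(df) == 1
        with pytest.raises(DegenerateEpochError):
            feature_table([const, ok], on_degenerate="error")

    def test_empty_epoch_rejected(self):
        with pytest.raises(ValueError):
            feat_mean(np.array([]))


class TestFeatureProperties:
    @given(st.lists(st.floats(-1e3, 1e3), min_size=4, max_size=80))
    @settings(max_examples=200, deadline=None)
    def test_pearson_inequality(self, values):
        data = np.asarray(values)
        if data.std() < 1e-6:
            return
        e = make_epoch(data)
        assert feat_kurtosis(e) >= feat_skewness(e) ** 2 + 1 - 1e-7

    def test_only_slope_depends_on_sample_order(self):
        rng = np.random.default_rng(1)
        data = rng.normal(size=60)
        shuffled = rng.permutation(data)
        a = compute_features(make_epoch(data))
        b = compute_features(make_epoch(shuffled))
        for name in FEATURE_NAMES:
            if name == "slope":
                continue
            assert a[name] == pytest.approx(b[name], rel=1e-12)
        assert a["slope"] != pytest.approx(b["slope"], rel=1e-3)

    def test_affine_response(self):
        rng = np.random.default_rng(2)
        data = rng.normal(size=50)
        a, b = 2.5, -1.3
        f0 = compute_features(make_epoch(data))
        f1 = compute_features(make_epoch(a * data + b))
        assert f1["mean"] == pytest.approx(a * f0["mean"] + b, rel=1e-10)
        assert f1["peak"] == pytest.approx(a * f0["peak"] + b, rel=1e-10)
        assert f1["variance"] == pytest.approx(a**2 * f0["variance"], rel=1e-10)
        assert f1["skewness"] == pytest.approx(f0["skewness"], rel=1e-9)
        assert f1["kurtosis"] == pytest.approx(f0["kurtosis"], rel=1e-9)


class TestRescaling:
    def feature_frame(self, col):
        df = pd.DataFrame({name: col if name == "mean" else np.linspace(0, 1, len(col))
                           for name in FEATURE_NAMES})
        return df

    def test_hand_example(self):
        df = self.feature_frame([2.0, 4.0, 6.0])
        out, _ = rescale_minmax(df, by=None)
        np.testing.assert_allclose(out["mean"], [0, 0.5, 1.0])

    def test_already_unit_interval_unchanged(self):
        df = self.feature_frame([0.0, 0.25, 1.0])
        out, _ = rescale_minmax(df, by=None)
        np.testing.assert_allclose(out["mean"], [0.0, 0.25, 1.0])

    def test_order_preserved_and_bounded(self):
        rng = np.random.default_rng(3)
        col = rng.normal(size=40)
        out, _ = rescale_minmax(self.feature_frame(col), by=None)
        assert out["mean"].min() == 0 and out["mean"].max() == 1
        assert np.array_equal(np.argsort(out["mean"]), np.argsort(col))

    def test_constant_column_error_names_column(self):
        df = self.feature_frame([3.0, 3.0, 3.0])
        with pytest.raises(ValueError, match="mean"):
            rescale_minmax(df, by=None)

    def test_train_fold_scaling_applies_to_test_fold(self):
        train = self.feature_frame([0.0, 10.0, 5.0])
        test = self.feature_frame([2.5, 7.5, 12.0])
        scaling = MinMaxScaling.fit(train)
        out = scaling.transform(test)
        np.testing.assert_allclose(out["mean"], [0.25, 0.75, 1.2])  # may exceed [0,1]
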