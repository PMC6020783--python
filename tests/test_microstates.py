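import numpy as np
import pytest

import erptopo as et
from erptopo.core import average_reference
from erptopo.microstates import (MicrostateAAHC, MicrostateKMeans, assign,
                                 cell_grand_means, cross_validate_k,
                                 explained_variance, microstate_quantifiers,
                                 microstate_test, smooth_labels,
                                 spatial_correlation)
from erptopo.synthetic import make_templates


def _two_template_series(n=40, c=10, seed=0):
    tpl = make_templates(2, c, seed)
    maps = np.empty((n, c))
    maps[0::2] = tpl[0]
    maps[1::2] = tpl[1]
    return maps, tpl


def _recovery(model, truth):
    return np.abs(spatial_correlation(model.templates_, truth)).max(axis=0)


class TestKMeans:
    def test_exact_recovery_on_noise_free_data(self):
        maps, tpl = _two_template_series()
        model = MicrostateKMeans(n_states=2, n_init=5,
                                 random_state=0).fit(maps)
        assert np.all(_recovery(model, tpl) > 1 - 1e-10)
        assert model.explained_variance_ == pytest.approx(1.0, abs=1e-10)

    def test_k_one_rejected(self):
        maps, _ = _two_template_series()
        with pytest.raises(ValueError):
            MicrostateKMeans(n_states=1).fit(maps)

    def test_k_exceeding_distinct_maps_rejected(self):
        maps = np.tile([[1.0, -1.0, 0.0]], (8, 1))
        with pytest.raises(ValueError, match="distinct"):
            MicrostateKMeans(n_states=2).fit(maps)

    def test_explained_variance_nests_in_k(self, rng):
        maps = average_reference(rng.standard_normal((60, 12)))
        ev = [MicrostateKMeans(n_states=k, n_init=10, random_state=1)
              .fit(maps).explained_variance_ for k in (2, 3)]
        assert ev[1] >= ev[0] - 1e-9

    def test_templates_have_unit_gfp(self, rng):
        maps = average_reference(rng.standard_normal((40, 8)))
        model = MicrostateKMeans(n_states=3, random_state=2).fit(maps)
        np.testing.assert_allclose(model.templates_.std(axis=1), 1.0,
                                   atol=1e-10)

    def test_sklearn_param_interface(self):
        model = MicrostateKMeans(n_states=5)
        assert model.get_params()["n_states"] == 5
        model.set_params(polarity="ignore")
        assert model.polarity == "ignore"


class TestAAHC:
    def test_exact_recovery_on_noise_free_data(self):
        maps, tpl = _two_template_series()
        model = MicrostateAAHC(n_states=2).fit(maps)
        assert np.all(_recovery(model, tpl) > 1 - 1e-10)

    def test_deterministic(self, rng):
        maps = average_reference(rng.standard_normal((50, 10)))
        a = MicrostateAAHC(n_states=3).fit(maps)
        b = MicrostateAAHC(n_states=3).fit(maps)
        np.testing.assert_array_equal(a.templates_, b.templates_)
        np.testing.assert_array_equal(a.labels_, b.labels_)

    def test_close_to_kmeans_on_four_template_data(self):
        tpl = make_templates(4, 16, 3)
        reps = np.repeat(tpl, 15, axis=0)
        rng = np.random.default_rng(4)
        maps = 10 * reps + 1.0 * rng.standard_normal(reps.shape)
        km = MicrostateKMeans(n_states=4, n_init=20, random_state=5) \
            .fit(maps)
        ah = MicrostateAAHC(n_states=4).fit(maps)
        assert ah.explained_variance_ > 0.95 * km.explained_variance_


class TestAssign:
    def test_template_maps_get_their_own_label(self):
        maps, tpl = _two_template_series()
        model = MicrostateKMeans(n_states=2, random_state=0).fit(maps)
        labels = assign(tpl, model)
        assert labels[0] != labels[1]
        corr = spatial_correlation(tpl, model.templates_)
        assert corr[0, labels[0]] == pytest.approx(1.0, abs=1e-10)

    def test_polarity_modes_on_negated_template(self):
        maps, tpl = _two_template_series()
        sens = MicrostateKMeans(n_states=2, random_state=0,
                                polarity="sensitive").fit(maps)
        ign = MicrostateKMeans(n_states=2, random_state=0,
                               polarity="ignore").fit(maps)
        lab = assign(tpl[1][None], ign)[0]
        assert assign(-tpl[1][None], ign)[0] == lab
        # polarity-sensitive: the negated map anti-correlates with its own
        # template, so it lands wherever the signed correlation is best
        neg = assign(-tpl[1][None], sens)[0]
        corr = spatial_correlation(-tpl[1][None], sens.templates_)[0]
        assert neg == np.argmax(corr)

    def test_zero_map_label_zero_with_warning(self):
        maps, _ = _two_template_series()
        model = MicrostateKMeans(n_states=2, random_state=0).fit(maps)
        with pytest.warns(RuntimeWarning, match="zero map"):
            assert assign(np.zeros((1, 10)), model)[0] == 0


class TestSmoothLabels:
    def _model(self):
        maps, tpl = _two_template_series()
        return MicrostateKMeans(n_states=2, random_state=0).fit(maps), tpl

    def test_short_segment_dissolved(self):
        model, tpl = self._model()
        maps = np.vstack([tpl[0]] * 2 + [tpl[1]] + [tpl[0]] * 2)
        labels = model.predict(maps)
        out = smooth_labels(labels, maps, model, min_duration_ms=8.0,
                            dt=4.0)
        assert len(set(out)) == 1

    def test_long_segments_untouched(self):
        model, tpl = self._model()
        maps = np.vstack([tpl[0]] * 5 + [tpl[1]] * 5)
        labels = model.predict(maps)
        out = smooth_labels(labels, maps, model, min_duration_ms=12.0,
                            dt=4.0)
        np.testing.assert_array_equal(out, labels)

    def test_alternating_singletons_collapse_to_one_class(self):
        model, tpl = self._model()
        maps = np.vstack([tpl[i % 2] for i in range(10)])
        labels = model.predict(maps)
        out = smooth_labels(labels, maps, model, min_duration_ms=8.0,
                            dt=4.0)
        assert len(set(out)) == 1


class TestExplainedVariance:
    def test_perfect_model_explains_everything(self):
        maps, _ = _two_template_series()
        model = MicrostateKMeans(n_states=2, random_state=0).fit(maps)
        assert explained_variance(maps, model, model.predict(maps)) == \
            pytest.approx(1.0, abs=1e-10)

    def test_orthogonal_labels_explain_nothing(self):
        maps, tpl = _two_template_series()
        model = MicrostateKMeans(n_states=2, random_state=0).fit(maps)
        own = model.predict(maps)
        wrong = 1 - own  # orthogonal template for every map
        assert explained_variance(maps, model, wrong) == \
            pytest.approx(0.0, abs=1e-10)

    def test_matches_direct_formula(self, rng):
        maps = average_reference(rng.standard_normal((30, 8)))
        model = MicrostateKMeans(n_states=3, random_state=1).fit(maps)
        labels = model.predict(maps)
        g = maps.std(axis=1)
        corr = spatial_correlation(maps, model.templates_)
        picked = corr[np.arange(30), labels]
        manual = ((g * picked) ** 2).sum() / (g ** 2).sum()
        assert explained_variance(maps, model, labels) == \
            pytest.approx(manual, abs=1e-10)

    def test_all_zero_data_rejected(self):
        maps, _ = _two_template_series()
        model = MicrostateKMeans(n_states=2, random_state=0).fit(maps)
        with pytest.raises(ValueError, match="all-zero"):
            explained_variance(np.zeros((5, 10)), model, np.zeros(5, int))


class TestQuantifiers:
    def test_closed_form_conventions(self):
        labels = np.zeros(30, dtype=int)
        labels[10:20] = 1
        gfp = np.ones(30)
        times = 4.0 * np.arange(30)
        q = microstate_quantifiers(labels, gfp, times, 2).loc[1]
        assert q["onset"] == 40.0
        assert q["offset"] == 76.0
        assert q["duration"] == 40.0
        assert q["auc"] == 40.0
        assert q["cog"] == 58.0
        assert q["mean_gfp"] == 1.0

    def test_absent_class_flagged(self):
        q = microstate_quantifiers(np.zeros(5, int), np.ones(5),
                                   4.0 * np.arange(5), 2)
        assert not q.loc[1, "present"]
        assert q.loc[1, "duration"] == 0.0

    def test_disjoint_segments_pool(self):
        labels = np.array([0, 1, 0, 0, 1, 0])
        q = microstate_quantifiers(labels, np.ones(6), 4.0 * np.arange(6),
                                   2).loc[1]
        assert q["onset"] == 4.0 and q["offset"] == 16.0
        assert q["duration"] == 8.0


class TestCrossValidation:
    def test_plateau_at_true_class_count(self):
        # near-noise-free: exactly zero noise would leave only 3 distinct
        # normalized maps, making k > 3 undefined by the fit contract
        ds, _ = et.generate_dataset(et.SyntheticSpec(
            n_subjects=8, n_channels=16, n_timepoints=90, n_templates=3,
            noise_sd=0.05, subject_amp_sd=0.0, seed=6))
        curve = cross_validate_k(ds, None, range(2, 6), n_splits=3,
                                 rng=0, n_init=5)
        i3 = curve.k_values.index(3)
        assert curve.test_ev[i3] - curve.test_ev[i3 - 1] > 0.05
        assert curve.test_ev[i3 + 1] - curve.test_ev[i3] < 0.01

    def test_learning_curve_non_decreasing_per_split(self):
        ds, _ = et.generate_dataset(et.SyntheticSpec(
            n_subjects=8, n_channels=12, n_timepoints=40, n_templates=3,
            noise_sd=2.0, seed=7))
        curve = cross_validate_k(ds, None, range(2, 6), n_splits=3,
                                 rng=1, n_init=5)
        assert np.all(np.diff(curve.per_split_learning, axis=1) > -1e-9)

    def test_seed_reproducibility(self):
        ds, _ = et.generate_dataset(et.SyntheticSpec(
            n_subjects=6, n_channels=10, n_timepoints=30, n_templates=2,
            noise_sd=1.0, seed=8))
        a = cross_validate_k(ds, None, (2, 3), n_splits=2, rng=9, n_init=3)
        b = cross_validate_k(ds, None, (2, 3), n_splits=2, rng=9, n_init=3)
        np.testing.assert_array_equal(a.test_ev, b.test_ev)

    def test_too_small_split_rejected(self):
        ds, _ = et.generate_dataset(et.SyntheticSpec(
            n_subjects=4, n_channels=8, n_timepoints=20, n_templates=2,
            seed=0))
        with pytest.raises(ValueError, match="fewer than 2"):
            cross_validate_k(ds, None, (2,), split_fraction=0.25,
                             n_splits=1)


class TestMicrostateTest:
    def test_identical_conditions_p_one(self, rng):
        one = average_reference(rng.standard_normal((4, 1, 20, 8)))
        data = np.repeat(one, 2, axis=1)
        ds = et.ErpDataset(data, tuple("abcd"), ("X", "Y"),
                           is_average_referenced=True)
        d = et.define_design({"f": {"X": 1, "Y": 2}}, ("X", "Y"))
        maps = cell_grand_means(ds).reshape(-1, 8)
        model = MicrostateKMeans(n_states=2, random_state=0).fit(maps)
        res = microstate_test(ds, d, model,
                              cfg=et.RandConfig(n_runs=19, seed=0))
        np.testing.assert_allclose(res["observed_variance"], 0, atol=1e-10)
        np.testing.assert_allclose(res["p"], 1.0)

    def test_window_restricts_analysis(self):
        ds, _ = et.generate_dataset(et.SyntheticSpec(
            n_subjects=6, n_channels=10, n_timepoints=40, n_templates=2,
            noise_sd=1.0, seed=10))
        d = et.define_design({"cond": {"A": 1, "B": 2}},
                             ds.condition_tags)
        maps = cell_grand_means(ds).reshape(-1, 10)
        model = MicrostateKMeans(n_states=2, random_state=0).fit(maps)
        res = microstate_test(ds, d, model, window=(0, 76),
                              cfg=et.RandConfig(n_runs=9, seed=1))
        offsets = res[(res.quantifier == "offset")]
        assert np.all(res["p"] > 0)
        assert set(res["effect"]) == {"cond"}
        assert len(offsets) == 2
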