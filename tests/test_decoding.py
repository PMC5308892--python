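"""SVM decoding pipeline: separability, chance calibration, determinism."""

import numpy as np
import pytest

from ensemblecode import decoding
from ensemblecode.errors import ConfigurationError, InsufficientTrialsError

FOUR = ["ACS_ALONE", "ACS_US", "VCS_ALONE", "VCS_US"]


def four_way_labels(n_per=20):
    return np.repeat(FOUR, n_per)


def separable_features(rng, n_per=20, n_units=40, noise=0.01):
    mus = np.zeros((4, n_units))
    block = n_units // 4
    for i in range(4):
        mus[i, i * block:(i + 1) * block] = 5.0
    labels = four_way_labels(n_per)
    idx = np.repeat(np.arange(4), n_per)
    return mus[idx] + rng.normal(0, noise, (4 * n_per, n_units)), labels


class TestCollapseLabels:
    def test_relational_and_physical_axes(self):
        labels = np.array(FOUR)
        rel = decoding.collapse_labels(labels, "RELATIONAL_BINARY")
        assert list(rel) == ["ALONE", "PAIRED", "ALONE", "PAIRED"]
        phy = decoding.collapse_labels(labels, "PHYSICAL_BINARY")
        assert list(phy) == ["ACS", "ACS", "VCS", "VCS"]

    def test_box_labels(self):
        labels = np.array(["ACS_US_B1", "ACS_US_B2"])
        assert list(decoding.collapse_labels(labels, "BOX_BINARY")) == ["B1", "B2"]
        with pytest.raises(ConfigurationError):
            decoding.collapse_labels(np.array(["ACS_US"]), "BOX_BINARY")


class TestDecodeOnce:
    def test_separable_features_decode_perfectly(self, rng):
        feats, labels = separable_features(rng)
        run = decoding.decode_once(feats, labels, rng,
                                   grid=decoding.REDUCED_GRID)
        assert run.accuracy == 1.0
        assert run.confusion.to_numpy().trace() == 40

    def test_constant_features_fall_to_chance(self, rng):
        feats = np.ones((80, 30))
        run = decoding.decode_once(feats, four_way_labels(), rng,
                                   grid=decoding.REDUCED_GRID)
        assert run.accuracy == pytest.approx(0.25)

    def test_null_accuracy_centred_on_chance(self):
        rng = np.random.default_rng(5)
        accs = []
        for _ in range(30):
            feats = rng.normal(5, 1, (80, 30))
            run = decoding.decode_once(feats, four_way_labels(), rng,
                                       grid=decoding.REDUCED_GRID)
            accs.append(run.accuracy)
        accs = np.array(accs)
        se = accs.std(ddof=1) / np.sqrt(len(accs))
        assert abs(accs.mean() - 0.25) < 3 * max(se, 0.01)

    def test_confusion_rows_sum_to_test_counts(self, rng):
        feats = rng.normal(0, 1, (80, 20))
        run = decoding.decode_once(feats, four_way_labels(), rng,
                                   grid=decoding.REDUCED_GRID)
        assert (run.confusion.sum(axis=1) == 10).all()
        assert len(run.readout_correct) == 40

    def test_insufficient_trials_names_condition(self, rng):
        feats = rng.normal(0, 1, (70, 10))
        labels = np.repeat(FOUR, [20, 20, 20, 10])
        with pytest.raises(InsufficientTrialsError) as exc:
            decoding.decode_once(feats, labels, rng)
        assert "VCS_US" in str(exc.value)

    def test_determinism_under_same_rng_state(self):
        feats, labels = separable_features(np.random.default_rng(0), noise=1.0)
        r1 = decoding.decode_once(feats, labels, np.random.default_rng(9),
                                  grid=decoding.REDUCED_GRID)
        r2 = decoding.decode_once(feats, labels, np.random.default_rng(9),
                                  grid=decoding.REDUCED_GRID)
        assert r1.accuracy == r2.accuracy
        assert r1.cost == r2.cost and r1.gamma == r2.gamma
        assert np.array_equal(r1.trial_ids, r2.trial_ids)

    def test_collapsed_confusion_never_below_mapped_fourway(self, rng):
        # folding a 4-way confusion along either axis can only merge
        # within-group confusions into correct classifications
        feats, labels = separable_features(rng, noise=3.0)
        run = decoding.decode_once(feats, labels, rng,
                                   grid=decoding.REDUCED_GRID)
        conf = run.confusion
        raw_acc = conf.to_numpy().trace() / conf.to_numpy().sum()
        for labeling in ("RELATIONAL_BINARY", "PHYSICAL_BINARY"):
            groups = decoding.collapse_labels(np.array(conf.index), labeling)
            collapsed = conf.groupby(groups).sum().T.groupby(groups).sum().T
            coll_acc = (collapsed.to_numpy().trace()
                        / collapsed.to_numpy().sum())
            assert coll_acc >= raw_acc - 1e-12


class TestChanceCalibration:
    def test_chance_mean_near_one_over_k(self):
        rng = np.random.default_rng(2)
        feats = rng.normal(5, 1, (80, 25))
        ch4 = decoding.chance_calibration(feats, four_way_labels(), rng,
                                          n_shuffles=25,
                                          grid=decoding.REDUCED_GRID)
        assert abs(ch4.accuracies.mean() - 0.25) < 0.06
        labels2 = decoding.collapse_labels(four_way_labels(),
                                           "RELATIONAL_BINARY")
        ch2 = decoding.chance_calibration(
            feats, labels2, rng, n_shuffles=25, grid=decoding.REDUCED_GRID,
            sample_labels=four_way_labels())
        assert abs(ch2.accuracies.mean() - 0.5) < 0.08

    def test_cutoff_insensitive_to_informative_features(self):
        # labels are shuffled, so signal in the features must not move the
        # chance distribution beyond sampling error
        rng = np.random.default_rng(3)
        null_feats = rng.normal(5, 1, (80, 30))
        info_feats, labels = separable_features(rng, noise=0.5, n_units=30)
        ch_null = decoding.chance_calibration(null_feats, labels, rng,
                                              n_shuffles=30,
                                              grid=decoding.REDUCED_GRID)
        ch_info = decoding.chance_calibration(info_feats, labels, rng,
                                              n_shuffles=30,
                                              grid=decoding.REDUCED_GRID)
        assert abs(ch_null.accuracies.mean() - ch_info.accuracies.mean()) < 0.08

    def test_pooled_cutoff_available(self, rng):
        feats = rng.normal(5, 1, (80, 10))
        ch = decoding.chance_calibration(feats, four_way_labels(), rng,
                                         n_shuffles=10,
                                         grid=decoding.REDUCED_GRID)
        assert 0.0 <= ch.cutoff("pooled") <= 1.0
        assert ch.n_readouts_per_rep == 40
        with pytest.raises(ConfigurationError):
            ch.cutoff("bogus")


class TestDecodeStage:
    def test_informative_pool_beats_chance(self):
        rng = np.random.default_rng(4)
        n_units, n_trials = 30, 80
        labels = four_way_labels()
        unit_rates = np.empty((n_units, n_trials))
        for u in range(n_units):
            gain = rng.lognormal(0.8, 0.3, 4)[
                np.repeat(np.arange(4), 20)]
            unit_rates[u] = rng.poisson(5.0 * gain) + 0.0
        res = decoding.decode_stage(unit_rates, labels, stage="TEST",
                                    n_sets=2, n_neurons=20, n_repeats=3,
                                    n_chance_shuffles=15, rng=rng,
                                    grid=decoding.REDUCED_GRID)
        assert res.mean_relative > 0
        assert (res.relative_accuracy <= res.raw_accuracy).all()

    def test_small_pool_degrades_with_note(self, rng):
        unit_rates = rng.normal(5, 1, (8, 80))
        res = decoding.decode_stage(unit_rates, four_way_labels(),
                                    stage="TEST", n_sets=1, n_neurons=150,
                                    n_repeats=2, n_chance_shuffles=10,
                                    rng=rng, grid=decoding.REDUCED_GRID)
        assert res.n_neurons == 8
        assert res.notes

    def test_unknown_labeling_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            decoding.decode_stage(rng.normal(size=(5, 80)), four_way_labels(),
                                  stage="S", labeling="SIXWAY")

    def test_stage_determinism(self):
        unit_rates = np.random.default_rng(0).normal(5, 1, (12, 80))
        kw = dict(stage="S", n_sets=1, n_neurons=10, n_repeats=2,
                  n_chance_shuffles=10, grid=decoding.REDUCED_GRID)
        a = decoding.decode_stage(unit_rates, four_way_labels(),
                                  rng=np.random.default_rng(21), **kw)
        b = decoding.decode_stage(unit_rates, four_way_labels(),
                                  rng=np.random.default_rng(21), **kw)
        assert np.array_equal(a.raw_accuracy, b.raw_accuracy)
        assert np.array_equal(a.chance_cutoff, b.chance_cutoff)


class TestSweeps:
    def test_ensemble_size_improves_informative_decoding(self):
        from conftest import heterogeneous_ensemble, small_config
        from ensemblecode import synthetic
        rng = np.random.default_rng(6)
        ens = heterogeneous_ensemble(25, rng,
                                     classes=("RELATIONAL", "PHYSICAL"))
        config = small_config(n_cs_alone=20, n_paired=20, seed=6)
        rng_ds = np.random.default_rng(6)
        table = synthetic.make_trial_table(config, rng_ds)
        ss = synthetic.simulate_spike_trains(table, ens, rng_ds)
        out = decoding.sweep_parameters(
            ss, table, rng, bin_sizes_ms=(200.0,), window_starts_ms=(100.0,),
            ensemble_sizes=(5, 40), n_repeats=4, n_chance_shuffles=10,
            grid=decoding.REDUCED_GRID, n_per_condition=10,
            n_train_per_condition=5)
        small = out[out["n_neurons"] == 5]["raw_mean"].item()
        large = out[out["n_neurons"] == 40]["raw_mean"].item()
        assert large >= small

    def test_pre_cs_window_is_uninformative(self):
        from conftest import heterogeneous_ensemble, small_config
        from ensemblecode import synthetic
        rng = np.random.default_rng(8)
        ens = heterogeneous_ensemble(20, rng, classes=("RELATIONAL",))
        config = small_config(n_cs_alone=20, n_paired=20, seed=8)
        rng_ds = np.random.default_rng(8)
        table = synthetic.make_trial_table(config, rng_ds)
        ss = synthetic.simulate_spike_trains(table, ens, rng_ds)
        out = decoding.sweep_parameters(
            ss, table, rng, bin_sizes_ms=(200.0,),
            window_starts_ms=(-300.0, 100.0), n_repeats=4,
            n_chance_shuffles=12, grid=decoding.REDUCED_GRID,
            n_per_condition=10, n_train_per_condition=5)
        pre = out[out["window_start_ms"] == -300.0].iloc[0]
        post = out[out["window_start_ms"] == 100.0].iloc[0]
        assert pre["raw_mean"] <= pre["chance_cutoff"] + 0.05
        assert post["raw_mean"] > pre["raw_mean"]
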