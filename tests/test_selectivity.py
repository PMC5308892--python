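"""Differentiation index, mutual information (with brute-force oracle),
permutation conventions, and neuron categorization."""

import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ensemblecode import selectivity, synthetic
from ensemblecode.errors import (ConfigurationError, IncompleteProfileError,
                                 UndefinedValueError)

from conftest import small_config


class TestDifferentiationIndex:
    @pytest.mark.parametrize("fr1,fr2,expected", [
        (5.0, 5.0, 0.0), (3.0, 1.0, 0.5), (4.0, 0.0, 1.0), (0.0, 4.0, -1.0),
    ])
    def test_printed_formula(self, fr1, fr2, expected):
        assert selectivity.differentiation_index(fr1, fr2) == pytest.approx(expected)

    def test_both_zero_undefined(self):
        with pytest.raises(UndefinedValueError):
            selectivity.differentiation_index(0.0, 0.0)

    def test_negative_rate_rejected(self):
        with pytest.raises(ConfigurationError):
            selectivity.differentiation_index(-1.0, 2.0)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.floats(min_value=0.01, max_value=100),
           st.floats(min_value=0.01, max_value=100),
           st.floats(min_value=0.01, max_value=1000))
    def test_scale_invariance(self, fr1, fr2, scale):
        a = selectivity.differentiation_index(fr1, fr2)
        b = selectivity.differentiation_index(scale * fr1, scale * fr2)
        assert a == pytest.approx(b, rel=1e-9)
        assert -1.0 <= a <= 1.0


def brute_force_mi(rates, labels, n_bins):
    """Independent oracle: explicit contingency-table summation in bits."""
    rates = np.asarray(rates, dtype=float)
    lo, hi = rates.min(), rates.max()
    if hi == lo:
        bins = [0] * len(rates)
    else:
        bins = [min(int((r - lo) / (hi - lo) * n_bins), n_bins - 1)
                for r in rates]
    joint = Counter(zip(labels, bins))
    n = len(rates)
    pi = Counter(labels)
    pj = Counter(bins)
    mi = 0.0
    for (c, b), k in joint.items():
        p = k / n
        mi += p * math.log2(p / ((pi[c] / n) * (pj[b] / n)))
    return mi


class TestMutualInformation:
    def test_two_conditions_disjoint_bins_one_bit(self):
        rates = np.array([1.0] * 10 + [9.0] * 10)
        labels = np.array(["A"] * 10 + ["B"] * 10)
        assert selectivity.mutual_information(rates, labels) == pytest.approx(1.0)

    def test_four_conditions_disjoint_bins_two_bits(self):
        rates = np.repeat([1.0, 4.0, 7.0, 10.0], 5)
        labels = np.repeat(list("ABCD"), 5)
        assert selectivity.mutual_information(rates, labels) == pytest.approx(2.0)

    def test_constant_rate_zero_information(self):
        rates = np.full(20, 3.0)
        labels = np.repeat(["A", "B"], 10)
        assert selectivity.mutual_information(rates, labels) == 0.0

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1),
           st.integers(min_value=2, max_value=4),
           st.integers(min_value=2, max_value=4))
    def test_matches_brute_force_oracle(self, seed, n_bins, n_conds):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3 * n_conds, 40))
        labels = np.array([f"c{i % n_conds}" for i in range(n)])
        rates = rng.poisson(4.0, n).astype(float)
        got = selectivity.mutual_information(rates, labels, n_bins=n_bins)
        want = brute_force_mi(rates, labels, n_bins)
        assert got == pytest.approx(want, abs=1e-12)
        assert got >= -1e-12

    def test_independence_limit(self):
        rng = np.random.default_rng(0)
        mis = []
        for n in (40, 4000):
            rates = rng.poisson(5.0, n).astype(float)
            labels = np.array(["A", "B"] * (n // 2))
            mis.append(selectivity.mutual_information(rates, labels))
        assert mis[1] < mis[0]        # plug-in bias shrinks with n
        assert mis[1] < 0.02

    def test_histogram_normalization(self):
        rng = np.random.default_rng(1)
        rates = rng.poisson(3.0, 30).astype(float)
        labels = np.repeat(["A", "B", "C"], 10)
        hist = selectivity.rate_condition_histogram(rates, labels)
        assert hist.to_numpy().sum() == pytest.approx(1.0, abs=1e-12)
        assert (hist.sum(axis=1) > 0).all()


class TestPermutationConventions:
    def test_extreme_effect_floors_at_one_over_nplus1(self, rng):
        rates = np.array([1.0] * 20 + [50.0] * 20)
        labels = np.repeat(["A", "B"], 20)
        res = selectivity.mi_permutation_test(rates, labels, n_perm=500,
                                              rng=rng)
        assert res.p == pytest.approx(1 / 501)
        assert res.normalized > 3

    def test_degenerate_null_keeps_valid_p(self, rng):
        rates = np.full(20, 2.0)
        labels = np.repeat(["A", "B"], 10)
        res = selectivity.permutation_selectivity_test(
            selectivity.mutual_information, rates, labels, n_perm=100,
            rng=rng)
        assert res.p == pytest.approx(1.0)
        assert math.isnan(res.normalized)

    def test_generic_and_fast_paths_agree(self, rng):
        rates = np.concatenate([rng.poisson(3.0, 20), rng.poisson(8.0, 20)]) * 1.0
        labels = np.repeat(["A", "B"], 20)
        slow = selectivity.permutation_selectivity_test(
            selectivity.mutual_information, rates, labels, n_perm=800,
            rng=np.random.default_rng(0))
        fast = selectivity.mi_permutation_test(rates, labels, n_perm=800,
                                               rng=np.random.default_rng(1))
        assert slow.observed == pytest.approx(fast.observed, abs=1e-12)
        assert slow.p == pytest.approx(fast.p, abs=0.05)
        assert slow.normalized == pytest.approx(fast.normalized, rel=0.3)

    def test_null_p_values_super_uniform(self):
        # under label-independence P(p <= a) <= a for every a
        rng = np.random.default_rng(3)
        labels = np.repeat(["A", "B"], 20)
        ps = []
        for _ in range(300):
            rates = rng.poisson(2.5, 40).astype(float)
            ps.append(selectivity.mi_permutation_test(
                rates, labels, n_perm=300, rng=rng).p)
        ps = np.array(ps)
        for a in (0.05, 0.10, 0.25):
            se = math.sqrt(a * (1 - a) / len(ps))
            assert ps.mean() > 0.3
            assert (ps <= a).mean() <= a + 3 * se


class TestResponsivenessAndCategory:
    def test_classification_rules(self):
        assert selectivity.classify_neuron(0.01, 0.50, True) == "RELATIONAL"
        assert selectivity.classify_neuron(0.50, 0.01, True) == "PHYSICAL"
        assert selectivity.classify_neuron(0.01, 0.01, True) == "CONJUNCTIVE"
        assert selectivity.classify_neuron(0.50, 0.50, True) == "NONSELECTIVE"
        assert selectivity.classify_neuron(0.01, 0.50, False) is None
        assert selectivity.classify_neuron(
            0.50, 0.50, True, conjunctive_one_vs_rest_p=0.01) == "CONJUNCTIVE"
        with pytest.raises(IncompleteProfileError):
            selectivity.classify_neuron(float("nan"), 0.5, True)

    def test_responsiveness_detects_rate_change(self, rng):
        stim = rng.poisson(12.0, 40).astype(float)
        iti = rng.poisson(5.0, 40).astype(float)
        res = selectivity.responsiveness_test(stim, iti, n_perm=300, rng=rng)
        assert res.p < 0.05

    def test_responsiveness_null_calibrated(self):
        rng = np.random.default_rng(4)
        hits = 0
        n = 200
        for _ in range(n):
            stim = rng.poisson(5.0, 30).astype(float)
            iti = rng.poisson(5.0, 30).astype(float)
            if selectivity.responsiveness_test(stim, iti, n_perm=200,
                                               rng=rng).p <= 0.05:
                hits += 1
        assert hits <= 20    # binomial 99.9% upper bound at p=0.05

    def test_profile_recovers_generator_classes(self):
        config = small_config(n_cs_alone=10, n_paired=30,
                              iti_range_ms=(22000.0, 24000.0), seed=3)
        specs = tuple(
            [synthetic.relational_spec(f"r{i}", baseline_rate=6.0,
                                       paired_gain=3.0) for i in range(5)]
            + [synthetic.physical_spec(f"p{i}", baseline_rate=6.0,
                                       preferred_gain=3.0) for i in range(5)]
            + [synthetic.unresponsive_spec(f"u{i}", baseline_rate=6.0)
               for i in range(5)])
        ens = synthetic.EnsembleSpec(
            specs, {"RELATIONAL": 1 / 3, "PHYSICAL": 1 / 3,
                    "UNRESPONSIVE": 1 / 3})
        rng_ds = np.random.default_rng(3)
        table = synthetic.make_trial_table(config, rng_ds)
        ss = synthetic.simulate_spike_trains(table, ens, rng_ds)
        prof = selectivity.profile_units(ss, table, np.random.default_rng(5),
                                         n_perm=500)
        # single-unit categories carry the contrasts' alpha-level error, so
        # assert a clear majority per generator class
        for klass in ("RELATIONAL", "PHYSICAL"):
            sub = prof[prof["neuron_class"] == klass]
            assert (sub["category"] == klass).sum() >= 3
        unresp = prof[prof["neuron_class"] == "UNRESPONSIVE"]
        assert (~unresp["responsive"]).sum() >= 3
        # convention: Fr1 = alone-group rate for the relational contrast, so
        # paired-enhanced units carry a negative signed index
        rel = prof[prof["neuron_class"] == "RELATIONAL"]
        assert rel["idx_rel"].mean() < -0.2
        phys = prof[prof["neuron_class"] == "PHYSICAL"]
        assert abs(phys["idx_rel"].mean()) < 0.15
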