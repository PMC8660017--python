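"""omega-squared PEV, permutation significance, favorite-location
selection, and neuron classification."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wmcap.information import (
    GROUP_TABLE,
    NeuronClassification,
    PevTimecourse,
    analysis_bin_edges,
    bin_spikes,
    binomial_proportion_test,
    classify_significance,
    favorite_location,
    n_sample_bins,
    omega_squared,
    permutation_pev_test,
    pev_timecourse,
    phase_flags,
)
from wmcap.task import DomainError, SpikeTable, SpikeTrain, TrialRecord


def brute_force_omega(values, groups):
    """Independent oracle: direct group/grand means and sums of squares."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = sorted(set(groups.tolist()))
    grand = sum(values) / len(values)
    ss_effect = 0.0
    ss_within = 0.0
    for lab in labels:
        sub = [v for v, g in zip(values, groups) if g == lab]
        m = sum(sub) / len(sub)
        ss_effect += len(sub) * (m - grand) ** 2
        ss_within += sum((v - m) ** 2 for v in sub)
    ss_total = ss_effect + ss_within
    df = len(labels) - 1
    ms_error = ss_within / (len(values) - len(labels))
    return (ss_effect - df * ms_error) / (ss_total + ms_error)


class TestOmegaSquared:
    def test_worked_example(self):
        d = omega_squared([2, 4, 8, 10], ["A", "A", "B", "B"])
        assert d.ss_effect == pytest.approx(36.0)
        assert d.ss_total == pytest.approx(40.0)
        assert d.ms_error == pytest.approx(2.0)
        assert d.df_effect == 1
        assert d.omega_squared == pytest.approx(34 / 42)

    def test_no_effect_goes_negative(self):
        d = omega_squared([1, 2, 3, 1, 2, 3], ["A"] * 3 + ["B"] * 3)
        assert d.omega_squared == pytest.approx(-0.2)

    def test_constant_data_flagged_undefined(self):
        d = omega_squared([5, 5, 5, 5], ["A", "A", "B", "B"])
        assert d.undefined

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            omega_squared([1, 2, 3], ["A", "A", "A"])
        with pytest.raises(DomainError):
            omega_squared([1, 2, 3], ["A", "A", "B"])  # singleton group

    def test_matches_brute_force_oracle_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            k = rng.integers(2, 4)
            sizes = rng.integers(2, 8, size=k)
            values = rng.poisson(6, size=sizes.sum()).astype(float)
            groups = np.repeat(np.arange(k), sizes)
            got = omega_squared(values, groups).omega_squared
            want = brute_force_omega(values, groups)
            if np.isnan(want) or np.isnan(got):
                assert np.isnan(want) and np.isnan(got)
            else:
                assert got == pytest.approx(want, abs=1e-10)

    @given(st.lists(st.integers(0, 20), min_size=4, max_size=40))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_label_symmetry(self, counts):
        """Identical data order yields identical omega^2; swapping group
        labels leaves the decomposition unchanged."""
        n = len(counts) // 2 * 2
        vals = np.array(counts[:n], dtype=float)
        g1 = np.array(["A", "B"] * (n // 2))
        g2 = np.array(["B", "A"] * (n // 2))
        d1 = omega_squared(vals, g1)
        d2 = omega_squared(vals, g2)
        if not (d1.undefined or d2.undefined):
            assert d1.omega_squared == pytest.approx(d2.omega_squared)
            assert d1.ss_effect == pytest.approx(d2.ss_effect)


class TestBinning:
    def test_sample_phase_has_four_bins(self):
        assert n_sample_bins() == 4
        edges = analysis_bin_edges()
        assert len(edges) - 1 == 9  # 4 sample + 5 delay bins
        np.testing.assert_allclose(edges[:5], [0.0, 0.2, 0.4, 0.6, 0.8])

    def test_bad_bin_width_raises(self):
        with pytest.raises(DomainError, match="partial bins"):
            analysis_bin_edges(bin_width=0.3)

    def test_empty_and_single_spike(self):
        trials = [TrialRecord(0, 0, {4: "A", 1: "B"}, 4, 4, "correct")]
        empty = SpikeTable([SpikeTrain(0, 0, [])])
        bc = bin_spikes(empty, trials)
        assert bc.counts.sum() == 0
        one = SpikeTable([SpikeTrain(0, 0, [0.35])])
        bc = bin_spikes(one, trials)
        assert bc.counts[0, 0].tolist() == [0, 1, 0, 0, 0, 0, 0, 0, 0]

    def test_half_open_bin_convention(self):
        trials = [TrialRecord(0, 0, {4: "A", 1: "B"}, 4, 4, "correct")]
        spikes = SpikeTable([SpikeTrain(0, 0, [0.2])])  # exactly on an edge
        bc = bin_spikes(spikes, trials)
        assert bc.counts[0, 0, 1] == 1 and bc.counts[0, 0, 0] == 0

    def test_poisson_mean_count(self):
        rng = np.random.default_rng(1)
        trials = [TrialRecord(i, 0, {4: "A", 1: "B"}, 4, 4, "correct")
                  for i in range(10_000)]
        trains = [SpikeTrain(0, i, np.sort(rng.uniform(0, 1.8,
                                                       rng.poisson(18))))
                  for i in range(10_000)]
        bc = bin_spikes(SpikeTable(trains), trials)
        assert bc.counts.mean() == pytest.approx(2.0, rel=0.03)


class TestPermutationTest:
    def test_observed_above_all_gives_add_one_floor(self):
        vals = np.array([0, 0, 0, 0, 30, 30, 30, 30], dtype=float)
        g = np.array(["A"] * 4 + ["B"] * 4)
        p = permutation_pev_test(vals, g, n_perm=1000, seed=0)
        # only relabelings reproducing the perfect split tie the observed;
        # the add-one estimator keeps p at least 1/1001
        assert p >= 1 / 1001
        assert p < 0.05

    def test_constant_data_gives_p_one(self):
        vals = np.full(12, 3.0)
        g = np.array(["A", "B"] * 6)
        assert permutation_pev_test(vals, g, n_perm=500, seed=0) == 1.0

    def test_seed_determinism(self):
        rng = np.random.default_rng(2)
        vals = rng.poisson(5, 40).astype(float)
        g = np.array(["A", "B"] * 20)
        p1 = permutation_pev_test(vals, g, n_perm=300, seed=7)
        p2 = permutation_pev_test(vals, g, n_perm=300, seed=7)
        assert p1 == p2

    def test_n_perm_domain(self):
        with pytest.raises(DomainError):
            permutation_pev_test([1.0, 2, 3, 4], ["A", "A", "B", "B"],
                                 n_perm=0)

    def test_null_rejection_rate_near_alpha(self):
        """Color-independent Poisson counts are declared significant at
        about the 5% criterion (Monte Carlo check at 500 neuron-bins)."""
        rng = np.random.default_rng(3)
        rejections = 0
        n_bins = 500
        g = np.array(["A"] * 30 + ["B"] * 30)
        for i in range(n_bins):
            vals = rng.poisson(3.0, 60).astype(float)
            p = permutation_pev_test(vals, g, n_perm=200, seed=1000 + i)
            rejections += p < 0.05
        assert 0.03 <= rejections / n_bins <= 0.07


class TestFavoriteLocation:
    def test_recovers_tuned_location(self, carrying_experiment, fav_map):
        trials, spikes, neurons = carrying_experiment
        hits = 0
        for n in neurons:
            got = favorite_location(spikes, trials, n.neuron_id)
            hits += got == n.favorite_location
        assert hits >= round(0.95 * len(neurons))

    def test_argmax_and_tie_break(self):
        """Deterministic counts make location 5 win; exact ties break to
        the lowest index."""
        trials = []
        trains = []
        tid = 0
        for loc in (4, 5, 6):
            for color, rate in (("A", 4), ("B", 16)):
                for _ in range(6):
                    trials.append(TrialRecord(tid, 0, {loc: color, 1: "A"},
                                              loc, loc, "correct"))
                    gain = rate if loc == 5 else 4  # only loc 5 informative
                    ts = np.linspace(0.01, 0.79, gain)
                    trains.append(SpikeTrain(0, tid, ts))
                    tid += 1
        spikes = SpikeTable(trains)
        assert favorite_location(spikes, trials, 0) == 5

        # all candidates identical -> tie -> lowest location index (4)
        trains_tie = [SpikeTrain(1, t.trial_id,
                                 np.linspace(0.01, 0.79,
                                             8 if t.colors_shown[t.target_location] == "A" else 3))
                      for t in trials]
        spikes_tie = SpikeTable(trains_tie)
        assert favorite_location(spikes_tie, trials, 1) == 4

    def test_no_usable_trials_raises(self):
        trials = [TrialRecord(0, 0, {1: "A", 2: "B"}, 1, 1, "correct")]
        spikes = SpikeTable([SpikeTrain(0, 0, [0.1])])
        with pytest.raises(DomainError):
            favorite_location(spikes, trials, 0)


class TestClassification:
    def test_truth_table_is_bijection(self):
        triples = [t for t in itertools.product([True, False], repeat=3)
                   if any(t)]
        assert sorted(GROUP_TABLE) == sorted(triples)
        assert len(set(GROUP_TABLE.values())) == 7
        assert GROUP_TABLE[(True, False, False)] == "I"
        assert GROUP_TABLE[(True, True, True)] == "VII"

    def _classification(self, sample, delay):
        return NeuronClassification(
            0, 4,
            dict(zip((1, 2, 3), sample)),
            dict(zip((1, 2, 3), delay)),
        )

    def test_group_and_pooled_membership(self):
        c = self._classification((True, False, False), (False, False, False))
        assert c.group("sample") == "I"
        assert c.pooled_groups("sample") == {1}
        assert c.group("delay") is None
        assert not c.in_delay_population

        c = self._classification((True, True, True), (False, True, True))
        assert c.group("sample") == "VII"
        assert c.pooled_groups("sample") == {1, 2, 3}
        assert c.group("delay") == "VI"

    def test_unavailable_load_excluded_from_pooled_groups(self):
        c = self._classification((True, None, False), (None, None, None))
        assert c.pooled_groups("sample") == {1}
        assert c.group("sample") == "I"  # missing load counts as not significant

    def test_phase_flags_default_vs_strict(self):
        edges = analysis_bin_edges()
        p = np.ones(9)
        p[[0, 2]] = 0.01  # two significant sample bins, not consecutive
        tc = PevTimecourse(0, 1, "ipsi", edges, np.zeros(9), p, 40)
        assert phase_flags(tc) == (True, False)
        assert phase_flags(tc, strict=True) == (False, False)
        p[[5, 6]] = 0.01  # consecutive delay bins
        assert phase_flags(tc, strict=True) == (False, True)

    def test_classify_from_generator(self, carrying_experiment, fav_map):
        """Color-selective load-1 neurons land in pooled group 1 during
        the sample phase."""
        trials, spikes, neurons = carrying_experiment
        n = neurons[0]
        tcs = {
            load: pev_timecourse(spikes, trials, n.neuron_id,
                                 n.favorite_location, load,
                                 n_perm=300, seed=5)
            for load in (1, 2, 3)
        }
        c = classify_significance(n.neuron_id, n.favorite_location, tcs)
        assert 1 in c.pooled_groups("sample")

    def test_contralateral_load_leaves_information_unchanged(
            self, carrying_experiment):
        """Hemifield independence: adding contralateral items (ipsi load
        fixed at 1) does not reduce sample-phase information."""
        trials, spikes, neurons = carrying_experiment
        per_load = {load: [] for load in (1, 2, 3)}
        for n in neurons:
            for load in (1, 2, 3):
                tc = pev_timecourse(spikes, trials, n.neuron_id,
                                    n.favorite_location, load,
                                    axis="contra", n_perm=1, seed=0)
                assert tc.n_trials > 0
                per_load[load].append(np.nanmean(tc.omega2[:4]))
        m1, m2, m3 = (np.mean(per_load[l]) for l in (1, 2, 3))
        assert abs(m1 - m2) < 0.08
        assert abs(m1 - m3) < 0.08

    def test_load_ordering_of_information(self, carrying_experiment):
        """Equal-weight normalization attenuates sample-phase information
        as ipsilateral load grows."""
        trials, spikes, neurons = carrying_experiment
        means = {load: [] for load in (1, 2, 3)}
        for n in neurons:
            for load in (1, 2, 3):
                tc = pev_timecourse(spikes, trials, n.neuron_id,
                                    n.favorite_location, load,
                                    n_perm=1, seed=0)
                means[load].append(np.nanmean(tc.omega2[:4]))
        m1, m2, m3 = (np.mean(means[l]) for l in (1, 2, 3))
        assert m1 > m2 >= m3 - 0.02


class TestBinomialTest:
    def test_worked_examples(self):
        assert binomial_proportion_test(0, 10) == pytest.approx(1.0)
        assert binomial_proportion_test(1, 1) == pytest.approx(0.05)

    def test_large_count_tail(self):
        """34 significant of 362 at p0=0.05 is far beyond chance; the exact
        tail sum oracle agrees."""
        from math import comb

        k, n, p0 = 34, 362, 0.05
        oracle = sum(
            comb(n, i) * p0 ** i * (1 - p0) ** (n - i) for i in range(k, n + 1)
        )
        got = binomial_proportion_test(k, n, p0)
        assert got == pytest.approx(oracle, rel=1e-9)
        assert got < 0.001

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            binomial_proportion_test(5, 3)
        with pytest.raises(DomainError):
            binomial_proportion_test(1, 3, p0=0.0)
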