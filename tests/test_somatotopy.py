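import numpy as np
import pandas as pd
import pytest

from corticolink import modulation as mod
from corticolink import somatotopy as st
from corticolink import synthetic_cortex as sc
from corticolink.core_model import SpikeTable


def regular_spikes(rate, a, b, channel=0):
    """Deterministic spike train at an exact rate on [a, b)."""
    if rate <= 0:
        return np.empty(0)
    return np.arange(a, b - 1e-12, 1.0 / rate)


def flexion_trials(n_per_digit=10, trial_len=4.0):
    rows, t = [], 1.0
    for rep in range(n_per_digit):
        for d in range(1, 6):
            rows.append(dict(trial_id=len(rows), condition="digit_flexion",
                             phase="flexion", phase_start_s=t, phase_end_s=t + 1.0,
                             amplitude_level_uA=np.nan, cued_digit=d, target_id=np.nan))
            t += trial_len
    return pd.DataFrame(rows)


class TestMotorMap:
    def _spikes_for_rates(self, trials, rates_by_digit, base=10.0):
        times = []
        prev_end = 0.0
        for r in trials.itertuples():
            times.append(regular_spikes(base, prev_end, r.phase_start_s))
            times.append(regular_spikes(rates_by_digit[int(r.cued_digit)],
                                        r.phase_start_s, r.phase_end_s))
            prev_end = r.phase_end_s
        t = np.concatenate(times)
        return SpikeTable(np.zeros(len(t), int), np.zeros(len(t), int), np.sort(t))

    def test_equal_rates_zero_modulation(self):
        trials = flexion_trials()
        spikes = self._spikes_for_rates(trials, {d: 20.0 for d in range(1, 6)})
        m = st.motor_map(spikes, trials, channel_ids=[0])
        assert np.allclose(m.values.loc[0].to_numpy(), 0.0, atol=0.1)

    def test_modulation_arithmetic(self):
        # rates (10,10,10,10,60) -> modulations (-0.5,-0.5,-0.5,-0.5,+2.0)
        trials = flexion_trials()
        spikes = self._spikes_for_rates(trials, {1: 10, 2: 10, 3: 10, 4: 10, 5: 60})
        m = st.motor_map(spikes, trials, channel_ids=[0])
        # the max-spread response-window selection biases the top digit's
        # window rate slightly upward, hence the tolerance
        assert np.allclose(m.values.loc[0].to_numpy(),
                           [-0.5, -0.5, -0.5, -0.5, 2.0], atol=0.15)

    def test_silent_channel_masked(self):
        trials = flexion_trials()
        spikes = SpikeTable(np.array([0]), np.array([0]), np.array([trials["phase_end_s"].max() + 5]))
        m = st.motor_map(spikes, trials, channel_ids=[0])
        assert m.values.loc[0].isna().all()

    def test_generator_profile_recovered(self):
        truth = sc.make_ground_truth(n_m1=24, n_s1=4, seed=0, digit_pref_strength=1.5)
        ses = sc.simulate_behavior_session(truth, "digit_flexion", n_trials=125, seed=1)
        m = st.motor_map(ses.spikes, ses.trials)
        pref_est = m.values.idxmax(axis=1).to_numpy()
        assert np.mean(pref_est == truth.m1_preferred_digit) >= 0.8


class TestProjectionMap:
    def _results(self, z_by_stim, n_m1=4):
        rows = []
        for stim, zvec in z_by_stim.items():
            for m in range(n_m1):
                rows.append(dict(motor_channel=m, stim_channel=stim, delta_rate_hz=0.0,
                                 z=zvec[m], p=0.5, sign="none", usable=True))
        return pd.DataFrame(rows)

    def test_uniform_coupling_normalizes_to_one(self):
        am = sc._make_arraymap(4, 2, np.array([1, 2]))
        res = self._results({1000: np.full(4, 3.0), 1001: np.full(4, 7.0)})
        p = st.projection_map(res, am)
        assert np.allclose(p.values.to_numpy(), 1.0)

    def test_digit_rescale_invariance(self):
        # multiplying all couplings of one digit by a constant leaves the
        # within-digit-normalized map unchanged
        am = sc._make_arraymap(4, 2, np.array([1, 2]))
        rng = np.random.default_rng(2)
        z1, z2 = rng.random(4) + 1, rng.random(4) + 1
        p_a = st.projection_map(self._results({1000: z1, 1001: z2}), am)
        p_b = st.projection_map(self._results({1000: z1 * 7.3, 1001: z2}), am)
        assert np.allclose(p_a.values.to_numpy(), p_b.values.to_numpy())

    def test_no_pf_labels_rejected(self):
        am = sc._make_arraymap(4, 2, np.array([1, 2]))
        am.loc[am["region"] == "S1", "pf_dominant"] = 0
        with pytest.raises(ValueError, match="PF"):
            st.projection_map(self._results({1000: np.ones(4)}), am)

    def test_unlabeled_digit_excluded_with_warning(self):
        am = sc._make_arraymap(4, 2, np.array([1, 1]))  # no digit-2 stim channel
        res = self._results({1000: np.ones(4), 1001: np.ones(4)})
        p = st.projection_map(res, am, digits_included=[1, 2])
        assert list(p.values.columns) == [1]


class TestSmoothing:
    def test_constant_map_unchanged(self):
        am = sc._make_arraymap(16, 2, np.array([1, 2]))
        dm = st.DigitMap(pd.DataFrame({1: np.full(16, 2.5)}, index=range(16)), "motor")
        sm = st.smooth_map(dm, am)
        assert np.allclose(sm.values[1].to_numpy(), 2.5)

    def test_delta_symmetric_neighbors(self):
        am = sc._make_arraymap(100, 2, np.array([1, 2]))  # 10x10 grid
        v = np.zeros(100)
        v[55] = 1.0  # interior electrode (row 5, col 5)
        dm = st.DigitMap(pd.DataFrame({1: v}, index=range(100)), "motor")
        sm = st.smooth_map(dm, am).values[1]
        # mask renormalization near edges breaks exact symmetry; relative
        # agreement at 1e-3 reflects the kernel itself being symmetric
        assert sm.loc[45] == pytest.approx(sm.loc[65], rel=1e-3)
        assert sm.loc[54] == pytest.approx(sm.loc[56], rel=1e-3)
        assert sm.loc[55] == sm.max()


class TestGradientMap:
    def test_monotone_profiles(self):
        vals = pd.DataFrame(
            {1: [1.0, 5.0], 2: [2.0, 4.0], 3: [3.0, 3.0], 4: [4.0, 2.0], 5: [5.0, 1.0]},
            index=[0, 1],
        )
        rho = st.gradient_map(st.DigitMap(vals, "motor"))
        assert rho.loc[0] == pytest.approx(1.0)
        assert rho.loc[1] == pytest.approx(-1.0)

    def test_constant_profile_masked(self):
        vals = pd.DataFrame({d: [1.0] for d in range(1, 6)}, index=[0])
        rho = st.gradient_map(st.DigitMap(vals, "motor"))
        assert np.isnan(rho.loc[0])


@pytest.fixture(scope="module")
def biased_maps():
    """Moderate-scale somatotopically biased cortex with recovered maps."""
    truth = sc.make_ground_truth(n_m1=48, n_s1=32, seed=5, somato_beta=2.0)
    passive = sc.simulate_passive_session(truth, seed=6)
    flexion = sc.simulate_behavior_session(truth, "digit_flexion", seed=7)
    res = mod.modulation_table(passive.spikes, passive.trains, passive.duration_s, seed=8)
    motor = st.motor_map(flexion.spikes, flexion.trials)
    proj = st.projection_map(res, truth.arraymap)
    return truth, res, motor, proj


class TestSomatotopicLinkage:
    def test_beta_two_matched_greater(self, biased_maps):
        truth, _, motor, proj = biased_maps
        ms = st.smooth_map(motor, truth.arraymap)
        ps = st.smooth_map(proj, truth.arraymap)
        t = st.matched_vs_unmatched(ms, ps)
        assert t.p < 0.001 and t.matched_greater

    def test_unsmoothed_conclusion_unchanged(self, biased_maps):
        truth, _, motor, proj = biased_maps
        t = st.matched_vs_unmatched(motor, proj)
        assert t.p < 0.01 and t.matched_greater

    def test_shuffled_motor_map_destroys_effect(self, biased_maps):
        truth, _, motor, proj = biased_maps
        rng = np.random.default_rng(9)
        shuf = st.DigitMap(
            pd.DataFrame(motor.values.to_numpy()[rng.permutation(len(motor.values))],
                         index=motor.values.index, columns=motor.values.columns),
            "motor",
        )
        t = st.matched_vs_unmatched(st.smooth_map(shuf, truth.arraymap),
                                    st.smooth_map(proj, truth.arraymap))
        assert t.p > 0.001

    def test_preference_profile_rank_order(self, biased_maps):
        truth, _, motor, proj = biased_maps
        r = st.preference_profile_analysis(motor, proj, truth.arraymap,
                                           n_shuffles=500, seed=10)
        assert r.rank_means[0] > r.rank_means[1] > r.rank_means[-1]
        assert r.kruskal_p < 0.001
        assert r.shuffle_p < 0.05

    def test_identical_profiles_r_one(self):
        am = sc._make_arraymap(16, 2, np.array([1, 2]))
        rng = np.random.default_rng(11)
        vals = pd.DataFrame(rng.random((16, 5)), index=range(16), columns=range(1, 6))
        r = st.preference_profile_analysis(
            st.DigitMap(vals, "motor"), st.DigitMap(vals.copy(), "projection"),
            am, n_shuffles=50, seed=12, smooth=False,
        )
        assert np.allclose(r.per_channel_r.to_numpy(), 1.0)


class TestPatternCorrelation:
    def test_identical_vectors_correlation_one(self):
        am = sc._make_arraymap(4, 4, np.array([1, 2, 1, 2]))
        rng = np.random.default_rng(13)
        v = rng.random(4)
        rows = [dict(motor_channel=m, stim_channel=1000 + s, delta_rate_hz=0.0,
                     z=v[m] + 0.01 * s, p=0.5, sign="none", usable=True)
                for s in range(4) for m in range(4)]
        pc = st.pattern_correlation(pd.DataFrame(rows), am)
        assert np.all(pc.within_array > 0.99)

    def test_smooth_coupling_field_negative_distance_slope(self):
        truth = sc.make_ground_truth(n_m1=32, n_s1=32, seed=14,
                                     coupling_smoothness=1.5)
        ses = sc.simulate_passive_session(truth, seed=15)
        res = mod.modulation_table(ses.spikes, ses.trains, ses.duration_s, seed=16)
        pc = st.pattern_correlation(res, truth.arraymap)
        assert pc.within_array.mean() > pc.between_array.mean()
        assert pc.distance_slope < 0 and pc.distance_slope_p < 0.01
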