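import numpy as np
import pandas as pd
import pytest

from corticolink import synthetic_cortex as sc
from corticolink import task_dependence as td
from corticolink.core_model import SpikeTable


def regular_table(rate, T, channel=0):
    t = np.arange(0.0005, T, 1.0 / rate)
    return SpikeTable(np.full(len(t), channel), np.zeros(len(t), int), t)


def squeeze_trials(n=16, amps=(20.0, 32.0, 44.0, 56.0)):
    rows, t = [], 2.0
    for k in range(n):
        rows.append(dict(trial_id=k, condition="squeeze", phase="squeeze",
                         phase_start_s=t, phase_end_s=t + 1.0,
                         amplitude_level_uA=amps[k % len(amps)],
                         cued_digit=np.nan, target_id=np.nan))
        t += 3.0
    return pd.DataFrame(rows)


class TestPhaseRates:
    def test_constant_channel_constant_rates(self):
        trials = squeeze_trials()
        spikes = regular_table(10.0, trials["phase_end_s"].max() + 2)
        tab = td.phase_rates(spikes, trials)
        assert np.allclose(tab["rate_hz"], 10.0, atol=0.01)
        assert np.allclose(tab["baseline_hz"], 10.0, atol=2.0)

    def test_short_phase_dropped_with_warning(self):
        trials = squeeze_trials(4)
        trials.loc[0, "phase_end_s"] = trials.loc[0, "phase_start_s"] + 0.3
        spikes = regular_table(10.0, trials["phase_end_s"].max() + 2)
        with pytest.warns(UserWarning, match="dropped"):
            tab = td.phase_rates(spikes, trials)
        assert tab["trial_id"].nunique() == 3

    def test_generator_phase_gains_recovered(self):
        truth = sc.make_ground_truth(n_m1=8, n_s1=8, seed=0, task_gain_sd=0.5,
                                     excitatory_fraction=1.0)
        ses = sc.simulate_behavior_session(truth, "squeeze", n_trials=80, seed=1)
        tab = td.phase_rates(ses.spikes, ses.trials)
        pair = sc._pick_stim_pair(truth)
        hi = tab[tab["amplitude_uA"] == 56.0].groupby("channel")["rate_hz"].mean()
        expect = truth.baseline_hz + np.mean(
            [truth.indirect_shift_hz(int(i), 56.0, "squeeze") for i in pair], axis=0
        )
        direct = 100.0 * np.sum(
            [truth.direct_probability(int(i), 56.0) for i in pair], axis=0
        )
        # background and indirect spikes lose the 1.6-ms hardware blank
        # (16% duty at 100 Hz); evoked spikes land outside the blank
        resid = hi.to_numpy() - (0.84 * expect + direct)
        assert np.abs(resid).max() < 4.0


class TestAnova:
    def _rate_table(self, truth, seed, n_trials=96):
        sq = sc.simulate_behavior_session(truth, "squeeze", n_trials=n_trials, seed=seed)
        gt = sc.simulate_behavior_session(truth, "grasp_transport", n_trials=n_trials, seed=seed + 1)
        return pd.concat(
            [td.phase_rates(sq.spikes, sq.trials), td.phase_rates(gt.spikes, gt.trials)],
            ignore_index=True,
        )

    def test_null_interaction_rate_nominal(self):
        # task-invariant gains: amplitude effect present, no interaction
        truth = sc.make_ground_truth(n_m1=48, n_s1=8, seed=2, task_gain_sd=0.0,
                                     excitatory_fraction=1.0)
        res = td.anova_task_amp(self._rate_table(truth, 3))
        frac = (res["p_interaction"] < 0.05).mean()
        assert frac <= 0.15  # ~binomial(48, 0.05) upper band

    def test_task_gated_interaction_detected(self):
        truth = sc.make_ground_truth(n_m1=24, n_s1=8, seed=4, task_gain_sd=1.0,
                                     excitatory_fraction=1.0,
                                     indirect_gain_mean_hz=12.0)
        res = td.anova_task_amp(self._rate_table(truth, 5))
        sig = res.dropna(subset=["td_index"])
        assert (res["p_interaction"] < 0.05).mean() > 0.3
        assert len(sig) and sig["td_index"].median() > 0.03

    def test_zero_variance_channel_masked(self):
        tab = pd.DataFrame(
            dict(channel=0, trial_id=range(24), phase=["squeeze", "grasp", "transport"] * 8,
                 amplitude_uA=[20.0, 32.0, 44.0, 56.0] * 6, rate_hz=5.0, baseline_hz=5.0)
        )
        res = td.anova_task_amp(tab)
        assert np.isnan(res["F_amp"].iloc[0])


class TestModulationVsBaseline:
    def test_identical_baselines_normalize_to_one(self):
        rng = np.random.default_rng(6)
        rows = []
        for ch in range(6):
            for ph in td.PHASES:
                for k, a in enumerate([20.0, 32.0, 44.0, 56.0] * 3):
                    rows.append(dict(channel=ch, trial_id=k, phase=ph, amplitude_uA=a,
                                     rate_hz=10 + rng.random(), baseline_hz=8.0))
        r = td.modulation_vs_baseline(pd.DataFrame(rows))
        assert np.allclose(r.table["norm_baseline"], 1.0)

    def test_saturation_produces_negative_relationship(self):
        # constructed positive control: modulation proportional to 1/baseline
        rows = []
        rng = np.random.default_rng(7)
        for ch in range(20):
            bases = 5 + 10 * rng.random(3)
            for ph, b in zip(td.PHASES, bases):
                for k, a in enumerate([20.0, 56.0] * 6):
                    rate = b + (40.0 / b if a == 56.0 else 0.0)
                    rows.append(dict(channel=ch, trial_id=k, phase=ph,
                                     amplitude_uA=a, rate_hz=rate, baseline_hz=b))
        r = td.modulation_vs_baseline(pd.DataFrame(rows))
        assert r.spearman_rho < -0.5 and r.spearman_p < 0.001

    def test_baseline_independent_gains_friedman_null(self):
        truth = sc.make_ground_truth(n_m1=24, n_s1=8, seed=8, task_gain_sd=0.0,
                                     excitatory_fraction=1.0)
        sq = sc.simulate_behavior_session(truth, "squeeze", n_trials=64, seed=9)
        gt = sc.simulate_behavior_session(truth, "grasp_transport", n_trials=64, seed=10)
        tab = pd.concat(
            [td.phase_rates(sq.spikes, sq.trials), td.phase_rates(gt.spikes, gt.trials)],
            ignore_index=True,
        )
        r = td.modulation_vs_baseline(tab)
        assert r.friedman_p > 0.01


class TestAmplitudeClassifier:
    def _table(self, sep, seed, n_trials=48):
        """Rate table with amplitude-coded mean rates, separation ``sep``."""
        rng = np.random.default_rng(seed)
        amps = [20.0, 32.0, 44.0, 56.0]
        rows = []
        for ph in td.PHASES:
            for k in range(n_trials):
                a = amps[k % 4]
                for ch in range(12):
                    mu = 10 + sep * amps.index(a) * (1 + 0.2 * ch)
                    rows.append(dict(channel=ch, trial_id=k, phase=ph, amplitude_uA=a,
                                     rate_hz=mu + rng.normal(0, 0.5), baseline_hz=10.0))
        return pd.DataFrame(rows)

    def test_separable_amplitudes_perfect_within(self):
        acc = td.amplitude_classifier(self._table(5.0, 11))
        assert np.all(np.diag(acc.to_numpy(float)) == 1.0)

    def test_shuffled_labels_near_chance(self):
        tab = self._table(5.0, 12)
        rng = np.random.default_rng(13)
        amps = [20.0, 32.0, 44.0, 56.0]
        for ph in td.PHASES:
            m = tab["phase"] == ph
            trials = tab.loc[m, "trial_id"].unique()
            remap = dict(zip(trials, rng.choice(amps, size=len(trials))))
            tab.loc[m, "amplitude_uA"] = tab.loc[m, "trial_id"].map(remap)
        acc = td.amplitude_classifier(tab)
        within = np.diag(acc.to_numpy(float))
        # binomial band around chance = 1/4 at 48 trials
        assert np.all(np.abs(within - 0.25) < 0.25)

    def test_divergent_transport_gain_drops_cross_accuracy(self):
        truth = sc.make_ground_truth(n_m1=48, n_s1=8, seed=14, task_gain_sd=0.0,
                                     excitatory_fraction=1.0,
                                     indirect_gain_mean_hz=12.0)
        rng = np.random.default_rng(15)
        # transport susceptibility decorrelated from squeeze/grasp, with
        # sign flips (responses can invert across tasks)
        truth.task_gain["transport"] = rng.normal(0.0, 1.0, truth.n_m1)
        sq = sc.simulate_behavior_session(truth, "squeeze", n_trials=96, seed=16)
        gt = sc.simulate_behavior_session(truth, "grasp_transport", n_trials=96, seed=17)
        tab = pd.concat(
            [td.phase_rates(sq.spikes, sq.trials, window_s=0.5),
             td.phase_rates(gt.spikes, gt.trials, window_s=0.5)],
            ignore_index=True,
        )
        acc = td.amplitude_classifier(tab)
        within = np.diag(acc.to_numpy(float)).mean()
        cross_tr = float(np.mean([
            acc.loc["transport", "squeeze"], acc.loc["transport", "grasp"],
            acc.loc["squeeze", "transport"], acc.loc["grasp", "transport"],
        ]))
        assert cross_tr < within - 0.1


class TestTargetClassifiers:
    def test_single_perfect_channel_full_accuracy(self):
        rows, times, t = [], [], 2.0
        rng = np.random.default_rng(18)
        for k in range(64):
            tgt = k % 8
            rows.append(dict(trial_id=k, condition="grasp_transport", phase="reach",
                             phase_start_s=t, phase_end_s=t + 1.5,
                             amplitude_level_uA=np.nan, cued_digit=np.nan, target_id=tgt))
            rate = 10 + 12 * tgt  # rate codes the target exactly
            times.append(np.arange(t - 0.4, t + 0.6, 1.0 / rate))
            t += 3.0
        tt = np.sort(np.concatenate(times))
        spikes = SpikeTable(np.zeros(len(tt), int), np.zeros(len(tt), int), tt)
        acc = td.target_classifier(spikes, pd.DataFrame(rows))
        assert acc == 1.0

    def test_tuned_population_high_accuracy(self):
        truth = sc.make_ground_truth(n_m1=32, n_s1=4, seed=19, tuning_gain_hz=18.0,
                                     baseline_hz=12.0)
        ses = sc.simulate_behavior_session(truth, "grasp_transport", n_trials=96, seed=20)
        acc = td.target_classifier(ses.spikes, ses.trials)
        assert acc > 0.8

    def test_rate_filter_rejects_silent_population(self):
        rows = [dict(trial_id=0, condition="grasp_transport", phase="reach",
                     phase_start_s=2.0, phase_end_s=3.5, amplitude_level_uA=np.nan,
                     cued_digit=np.nan, target_id=0)]
        spikes = SpikeTable(np.zeros(3, int), np.zeros(3, int), np.array([0.5, 2.0, 3.0]))
        with pytest.raises(ValueError, match="activity filter"):
            td.target_classifier(spikes, pd.DataFrame(rows))

    def test_center_out_variant_beats_chance(self):
        truth = sc.make_ground_truth(n_m1=24, n_s1=4, seed=21, tuning_gain_hz=12.0)
        ses = sc.simulate_behavior_session(truth, "center_out", seed=22)
        acc = td.center_out_classifier(ses.spikes, ses.trials)
        assert acc > 0.5  # chance 0.125
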