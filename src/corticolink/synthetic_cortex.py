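"""Synthetic cortical sessions with known S1->M1 coupling ground truth.

The generator emulates the recording/stimulation setup the analyses were
designed for: ~96-channel M1 grids of Poisson threshold-crossing channels,
two 32-channel stimulable S1 arrays with projected-field (PF) digit labels,
1-s 100-Hz ICMS trains, and 1.6-ms post-pulse hardware blanking.  Two kinds
of coupling are injected per (S1, M1) pair:

* **direct** — per-pulse Bernoulli(p_direct) evoked spikes at latency
  Normal(mu_lat, sigma_lat) ms, truncated below the 2-ms analysis blank.
  The per-pulse probability scales linearly with pulse amplitude (reference
  60 uA) but is task-invariant by construction.
* **indirect** — an additive firing-rate shift (Hz, signed, rectified at
  0 Hz) during the train, scaled linearly by amplitude and multiplied by a
  per-channel, per-task gain, which is what makes indirect effects task
  dependent.

Somatotopy enters as a bias factor beta >= 1 multiplying both p_direct and
|indirect gain| when the S1 channel's dominant PF digit equals the M1
channel's preferred movement digit; preferred digits follow a lateral-to-
medial gradient across both grids so that map analyses see realistic
spatial structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_model import (
    ANALYSIS_BLANK_MS,
    AMPLITUDE_LEVELS_UA,
    HARDWARE_BLANK_MS,
    BlankSchedule,
    SpikeTable,
    StimTrain,
    quantize_time,
)

N_DIGITS = 5
REFERENCE_AMPLITUDE_UA = 60.0
RECRUITMENT_THRESHOLD_UA = 20.0
REACTION_LAG_S = 0.2


def indirect_recruitment(amplitude_uA):
    """Normalized recruitment of trans-synaptic (indirect) effects vs pulse
    amplitude: zero at/below the ~20-uA perceptual/recruitment threshold,
    rising supralinearly (quadratically, the lower limb of a sigmoid
    recruitment curve) to 1 at the 60-uA passive reference."""
    a = np.maximum(0.0, np.asarray(amplitude_uA, dtype=float) - RECRUITMENT_THRESHOLD_UA)
    return (a / (REFERENCE_AMPLITUDE_UA - RECRUITMENT_THRESHOLD_UA)) ** 2

_CUBE_CORNERS = np.array(
    [[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)], dtype=float
) / np.sqrt(3.0)


@dataclass
class GroundTruth:
    """Generative parameters for one synthetic cortex."""

    baseline_hz: np.ndarray            # (n_m1,)
    digit_pref: np.ndarray             # (n_m1, 5), rows sum to 0 (modulation units)
    vel_tuning: np.ndarray             # (n_m1, 3), Hz per unit velocity
    p_direct: np.ndarray               # (n_s1, n_m1), per-pulse probability at 60 uA
    mu_lat_ms: np.ndarray              # (n_s1, n_m1)
    sigma_lat_ms: np.ndarray           # (n_s1, n_m1)
    indirect_gain_hz: np.ndarray       # (n_s1, n_m1), signed additive shift at 60 uA
    task_gain: dict                    # task -> (n_m1,) multiplier on indirect gain
    s1_pf_digit: np.ndarray            # (n_s1,), dominant PF digit 1..5
    somato_beta: float
    m1_channel_ids: np.ndarray
    s1_channel_ids: np.ndarray
    arraymap: pd.DataFrame

    def __post_init__(self) -> None:
        if np.any((self.p_direct < 0) | (self.p_direct > 1)):
            raise ValueError("p_direct must lie in [0, 1]")
        active = self.p_direct > 0
        if np.any((self.mu_lat_ms[active] < 2.0) | (self.mu_lat_ms[active] > 6.0)):
            raise ValueError("direct latencies must lie in [2, 6] ms")
        if np.any(
            (self.sigma_lat_ms[active] < 0.0) | (self.sigma_lat_ms[active] > 1.0)
        ):
            raise ValueError("latency jitter must lie in [0, 1] ms")

    @property
    def n_m1(self) -> int:
        return len(self.baseline_hz)

    @property
    def n_s1(self) -> int:
        return len(self.s1_pf_digit)

    @property
    def m1_preferred_digit(self) -> np.ndarray:
        """Preferred movement digit per M1 channel (1..5)."""
        return np.argmax(self.digit_pref, axis=1) + 1

    def indirect_shift_hz(self, s1_index: int, amplitude_uA: float, task: str) -> np.ndarray:
        """Additive rate shift on every M1 channel for one stim channel,
        scaled by the amplitude recruitment curve and the task gain."""
        gain = self.task_gain.get(task, np.ones(self.n_m1))
        return self.indirect_gain_hz[s1_index] * float(indirect_recruitment(amplitude_uA)) * gain

    def direct_probability(self, s1_index: int, amplitude_uA: float) -> np.ndarray:
        """Per-pulse evoked-spike probability; amplitude-scaled, task-invariant."""
        return np.clip(self.p_direct[s1_index] * amplitude_uA / REFERENCE_AMPLITUDE_UA, 0.0, 1.0)


@dataclass
class Session:
    """One simulated recording session plus its generating truth."""

    spikes: SpikeTable
    trains: list
    trials: pd.DataFrame
    arraymap: pd.DataFrame
    truth: GroundTruth
    duration_s: float
    metadata: dict = field(default_factory=dict)


def _make_arraymap(n_m1: int, n_s1: int, pf_digit: np.ndarray, pitch_um: float = 400.0) -> pd.DataFrame:
    """M1 grid (10 columns) plus two S1 arrays, checkerboard-style wiring ignored."""
    rows = []
    m1_cols = 10
    for i in range(n_m1):
        rows.append(
            dict(
                electrode_id=i,
                grid_row=i // m1_cols,
                grid_col=i % m1_cols,
                wired=True,
                region="M1",
                array_id="M1-lateral",
                pf_dominant=0,
                pf_digits="",
                pitch_um=pitch_um,
            )
        )
    s1_cols = 8
    half = max(n_s1 // 2, 1)
    for j in range(n_s1):
        arr = "S1-medial" if j >= half else "S1-lateral"
        local = j - half if j >= half else j
        rows.append(
            dict(
                electrode_id=1000 + j,
                grid_row=local // s1_cols,
                grid_col=local % s1_cols,
                wired=True,
                region="S1",
                array_id=arr,
                pf_dominant=int(pf_digit[j]),
                pf_digits=str(int(pf_digit[j])),
                pitch_um=pitch_um,
            )
        )
    return pd.DataFrame(rows)


def make_ground_truth(
    n_m1: int = 96,
    n_s1: int = 64,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    baseline_hz: float = 10.0,
    coupled_fraction: float = 0.5,
    direct_fraction: float = 0.3,
    p_direct_range: tuple = (0.1, 0.5),
    latency_range_ms: tuple = (2.5, 5.5),
    jitter_range_ms: tuple = (0.1, 0.8),
    indirect_gain_mean_hz: float = 8.0,
    excitatory_fraction: float = 0.8,
    tuning_gain_hz: float = 8.0,
    digit_pref_strength: float = 1.0,
    somato_beta: float = 1.0,
    task_gain_sd: float = 0.0,
    coupling_smoothness: float = 0.0,
) -> GroundTruth:
    """Draw one synthetic cortex.

    Defaults mirror the study conditions: ~10 Hz baselines, about half the
    (S1, M1) pairs coupled with mostly excitatory indirect shifts, ~30% of
    coupled pairs also carrying a direct (pulse-locked) input at 2.5-5.5 ms
    latency with sub-millisecond jitter.  ``somato_beta`` > 1 introduces the
    somatotopic link; ``task_gain_sd`` > 0 makes indirect gains task
    dependent (log-normal per-channel, per-task multipliers).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    lam0 = rng.lognormal(mean=np.log(baseline_hz), sigma=0.3, size=n_m1)

    # Preferred digits follow a spatial gradient across the 10-column M1 grid.
    m1_cols = np.arange(n_m1) % 10
    pref_digit = np.clip((m1_cols / 10 * N_DIGITS).astype(int) + 1, 1, N_DIGITS)
    digits = np.arange(1, N_DIGITS + 1)
    width = 1.0
    profile = np.exp(-0.5 * ((digits[None, :] - pref_digit[:, None]) / width) ** 2)
    profile *= digit_pref_strength * (1.0 + 0.3 * rng.standard_normal((n_m1, 1)))
    digit_pref = profile - profile.mean(axis=1, keepdims=True)

    vel_tuning = rng.standard_normal((n_m1, 3))
    vel_tuning *= tuning_gain_hz / np.maximum(
        np.linalg.norm(vel_tuning, axis=1, keepdims=True), 1e-12
    )

    # S1 PF digits: gradient along each array, matching the M1 convention.
    s1_half = max(n_s1 // 2, 1)
    s1_pf = np.clip(
        ((np.arange(n_s1) % s1_half) / s1_half * N_DIGITS).astype(int) + 1, 1, N_DIGITS
    )

    coupled = rng.random((n_s1, n_m1)) < coupled_fraction
    direct = coupled & (rng.random((n_s1, n_m1)) < direct_fraction)

    p_direct = np.zeros((n_s1, n_m1))
    p_direct[direct] = rng.uniform(*p_direct_range, size=int(direct.sum()))
    mu = np.full((n_s1, n_m1), 4.0)
    mu[direct] = rng.uniform(*latency_range_ms, size=int(direct.sum()))
    sig = np.full((n_s1, n_m1), 0.3)
    sig[direct] = rng.uniform(*jitter_range_ms, size=int(direct.sum()))

    sign = np.where(rng.random((n_s1, n_m1)) < excitatory_fraction, 1.0, -1.0)
    gain = np.zeros((n_s1, n_m1))
    gain[coupled] = sign[coupled] * rng.exponential(indirect_gain_mean_hz, size=int(coupled.sum()))

    if coupling_smoothness > 0:
        # spatially smooth coupling field: neighboring S1 electrodes (within
        # an array) evoke similar M1 activation patterns, for both the
        # indirect gains and the direct per-pulse probabilities
        from scipy import ndimage

        half, s1_cols = n_s1 // 2, 8
        for field_ in (gain, p_direct):
            for lo in (0, half):
                block = field_[lo: lo + half].reshape(-1, s1_cols, n_m1)
                field_[lo: lo + half] = ndimage.gaussian_filter(
                    block, (coupling_smoothness, coupling_smoothness, 0), mode="nearest"
                ).reshape(half, n_m1)
        np.clip(p_direct, 0.0, 1.0, out=p_direct)

    matched = s1_pf[:, None] == (np.argmax(digit_pref, axis=1) + 1)[None, :]
    if somato_beta != 1.0:
        p_direct = np.clip(np.where(matched, p_direct * somato_beta, p_direct), 0, 1)
        gain = np.where(matched, gain * somato_beta, gain)

    task_gain = {}
    for task in ("squeeze", "grasp", "transport"):
        if task_gain_sd > 0:
            task_gain[task] = rng.lognormal(mean=0.0, sigma=task_gain_sd, size=n_m1)
        else:
            task_gain[task] = np.ones(n_m1)

    return GroundTruth(
        baseline_hz=lam0,
        digit_pref=digit_pref,
        vel_tuning=vel_tuning,
        p_direct=p_direct,
        mu_lat_ms=mu,
        sigma_lat_ms=sig,
        indirect_gain_hz=gain,
        task_gain=task_gain,
        s1_pf_digit=s1_pf,
        somato_beta=somato_beta,
        m1_channel_ids=np.arange(n_m1),
        s1_channel_ids=1000 + np.arange(n_s1),
        arraymap=_make_arraymap(n_m1, n_s1, s1_pf),
    )


# ---------------------------------------------------------------------------
# Point-process machinery
# ---------------------------------------------------------------------------

def _segment_deltas(windows: list) -> list:
    """Resolve possibly-overlapping (start, end, delta) windows into disjoint
    segments carrying the summed delta, so composition stays additive."""
    if not windows:
        return []
    w = np.asarray(windows, dtype=float)
    edges = np.unique(np.concatenate([w[:, 0], w[:, 1]]))
    accum = np.zeros(len(edges))
    np.add.at(accum, np.searchsorted(edges, w[:, 0]), w[:, 2])
    np.add.at(accum, np.searchsorted(edges, w[:, 1]), -w[:, 2])
    level = np.cumsum(accum)[:-1]  # net delta on [edges[i], edges[i+1])
    keep = level != 0.0
    return list(zip(edges[:-1][keep], edges[1:][keep], level[keep]))


def _channel_spike_times(
    rng: np.random.Generator, lam0: float, duration_s: float, windows: list
) -> np.ndarray:
    """Homogeneous Poisson background plus additive piecewise-constant rate
    shifts, rectified at 0 Hz (negative shifts thin the background)."""
    n = rng.poisson(lam0 * duration_s)
    times = rng.random(n) * duration_s
    times.sort()
    keep = np.ones(n, dtype=bool)
    extra = []
    for a, b, d in _segment_deltas(windows):
        if d < 0:
            lo, hi = np.searchsorted(times, [a, b])
            p_keep = max(lam0 + d, 0.0) / lam0 if lam0 > 0 else 0.0
            keep[lo:hi] &= rng.random(hi - lo) < p_keep
        elif d > 0:
            m = rng.poisson(d * (b - a))
            extra.append(a + rng.random(m) * (b - a))
    times = times[keep]
    if extra:
        times = np.concatenate([times] + extra)
        times.sort()
    return times


def _truncated_latencies_s(
    rng: np.random.Generator,
    mu_ms: np.ndarray,
    sigma_ms: np.ndarray,
    lo_ms: float,
    hi_ms: float,
) -> np.ndarray:
    """Normal latencies truncated to [lo, hi) ms, sigma = 0 degenerating to mu."""
    out = np.empty(len(mu_ms))
    degen = sigma_ms <= 0
    out[degen] = np.clip(mu_ms[degen], lo_ms, hi_ms - 1e-6)
    if np.any(~degen):
        m, s = mu_ms[~degen], sigma_ms[~degen]
        a, b = (lo_ms - m) / s, (hi_ms - m) / s
        out[~degen] = stats.truncnorm.rvs(a, b, loc=m, scale=s, random_state=rng)
    return out * 1e-3


def _direct_events(
    rng: np.random.Generator,
    truth: GroundTruth,
    train: StimTrain,
    s1_index: int,
    amplitude_uA: float,
) -> tuple:
    """Evoked (channel, time) pairs for one train: per-pulse Bernoulli hits
    with truncated-normal latencies."""
    p = truth.direct_probability(s1_index, amplitude_uA)
    active = np.flatnonzero(p > 0)
    if len(active) == 0:
        return np.empty(0, int), np.empty(0, float)
    hits = rng.random((train.n_pulses, len(active))) < p[active]
    pulse_idx, ch_idx = np.nonzero(hits)
    if len(pulse_idx) == 0:
        return np.empty(0, int), np.empty(0, float)
    chans = active[ch_idx]
    lat = _truncated_latencies_s(
        rng,
        truth.mu_lat_ms[s1_index, chans],
        truth.sigma_lat_ms[s1_index, chans],
        ANALYSIS_BLANK_MS,
        train.inter_pulse_interval_s * 1e3,
    )
    return chans, train.pulse_times_s[pulse_idx] + lat


def _assemble_spikes(
    rng: np.random.Generator,
    truth: GroundTruth,
    duration_s: float,
    windows_per_channel: list,
    direct_chunks: list,
    trains: list,
) -> SpikeTable:
    chans, times = [], []
    for m, lam0 in enumerate(truth.baseline_hz):
        t = _channel_spike_times(rng, lam0, duration_s, windows_per_channel[m])
        chans.append(np.full(len(t), truth.m1_channel_ids[m]))
        times.append(t)
    for ch_idx, t in direct_chunks:
        chans.append(truth.m1_channel_ids[ch_idx])
        times.append(t)
    spikes = SpikeTable(
        np.concatenate(chans), np.zeros(sum(map(len, chans)), int), quantize_time(np.concatenate(times))
    )
    if trains:
        hw = BlankSchedule.from_pulses(
            np.concatenate([tr.pulse_times_s for tr in trains]), HARDWARE_BLANK_MS
        )
        spikes = spikes.select(~hw.contains(spikes.time_s))
    return spikes


# ---------------------------------------------------------------------------
# Protocols
# ---------------------------------------------------------------------------

def simulate_passive_session(
    truth: GroundTruth,
    n_trains_per_channel: int = 15,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    frequency_hz: float = 100.0,
    amplitude_uA: float = 60.0,
    train_duration_s: float = 1.0,
    stim_channels: np.ndarray | None = None,
    intertrain_gap_s: tuple = (3.0, 4.0),
) -> Session:
    """Passive stimulation protocol: each S1 channel stimulated
    ``n_trains_per_channel`` times (minimum 15) in 1-s trains, shuffled
    order, with inter-train gaps drawn uniformly from [3, 4] s."""
    if n_trains_per_channel < 1:
        raise ValueError("need at least one train per channel")
    if rng is None:
        rng = np.random.default_rng(seed)
    if stim_channels is None:
        stim_channels = truth.s1_channel_ids
    stim_channels = np.asarray(stim_channels)
    s1_lookup = {int(c): i for i, c in enumerate(truth.s1_channel_ids)}

    order = np.repeat(stim_channels, n_trains_per_channel)
    rng.shuffle(order)

    trains, windows = [], [[] for _ in range(truth.n_m1)]
    direct_chunks, trial_rows = [], []
    t = float(rng.uniform(*intertrain_gap_s))
    for k, ch in enumerate(order):
        s = s1_lookup[int(ch)]
        tr = StimTrain.regular([int(ch)], t, train_duration_s, frequency_hz, amplitude_uA)
        trains.append(tr)
        shift = truth.indirect_shift_hz(s, amplitude_uA, "passive")
        for m in np.flatnonzero(shift != 0):
            windows[m].append((t, t + train_duration_s, shift[m]))
        direct_chunks.append(_direct_events(rng, truth, tr, s, amplitude_uA))
        trial_rows.append(
            dict(
                trial_id=k,
                condition="passive",
                phase="train",
                phase_start_s=t,
                phase_end_s=t + train_duration_s,
                amplitude_level_uA=amplitude_uA,
                cued_digit=np.nan,
                target_id=np.nan,
            )
        )
        t += train_duration_s + float(rng.uniform(*intertrain_gap_s))
    duration = t

    spikes = _assemble_spikes(rng, truth, duration, windows, direct_chunks, trains)
    return Session(
        spikes=spikes,
        trains=trains,
        trials=pd.DataFrame(trial_rows),
        arraymap=truth.arraymap,
        truth=truth,
        duration_s=duration,
        metadata={"protocol": "passive", "seed": seed, "frequency_hz": frequency_hz,
                  "amplitude_uA": amplitude_uA, "n_trains_per_channel": n_trains_per_channel},
    )


DEFAULT_TRIALS = {"digit_flexion": 125, "squeeze": 208, "grasp_transport": 208, "center_out": 80}


def _pick_stim_pair(truth: GroundTruth) -> np.ndarray:
    """Two feedback electrodes, PFs on thumb and index when available,
    choosing within digit the electrode with the strongest aggregate M1
    effect (feedback electrodes are picked to evoke robust sensations)."""
    strength = np.abs(truth.indirect_gain_hz).sum(axis=1)

    def best(digit, fallback):
        idx = np.flatnonzero(truth.s1_pf_digit == digit)
        return idx[np.argmax(strength[idx])] if len(idx) else fallback

    a = best(1, 0)
    b = best(2, min(1, truth.n_s1 - 1))
    return np.array([a, b])


def simulate_behavior_session(
    truth: GroundTruth,
    protocol: str,
    n_trials: int | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    frequency_hz: float = 100.0,
    stim_pair: np.ndarray | None = None,
    reach_speed: float = 0.5,
    transport_duration_s: float = 1.5,
) -> Session:
    """Behavioral protocols with ICMS delivered through a two-electrode pair.

    * ``digit_flexion``: cued single-digit flexions, rate scaled by the
      channel's digit-preference profile during the flexion epoch.
    * ``squeeze``: 1-s object contact triggers a 1-s train at one of the four
      amplitudes {20, 32, 44, 56} uA, randomized and balanced.
    * ``grasp_transport``: reach (velocity-tuned) -> grasp with ICMS ->
      transport with ICMS continuing; 8 cube-corner targets.
    * ``center_out``: planar 8-target reaches, cosine-tuned, 10 reps/target.
    """
    if protocol not in DEFAULT_TRIALS:
        raise ValueError(f"unknown protocol {protocol!r}")
    if rng is None:
        rng = np.random.default_rng(seed)
    if n_trials is None:
        n_trials = DEFAULT_TRIALS[protocol]
    if stim_pair is None:
        stim_pair = _pick_stim_pair(truth)

    trains, windows = [], [[] for _ in range(truth.n_m1)]
    direct_chunks, trial_rows = [], []
    t = 1.0

    def add_shift(a, b, delta):
        for m in np.flatnonzero(delta != 0):
            windows[m].append((a, b, delta[m]))

    def stim_bout(a, b, amp, task):
        tr = StimTrain.regular(
            [int(truth.s1_channel_ids[i]) for i in stim_pair], a, b - a, frequency_hz, amp
        )
        trains.append(tr)
        shift = np.mean(
            [truth.indirect_shift_hz(int(i), amp, task) for i in stim_pair], axis=0
        )
        add_shift(a, b, shift)
        for i in stim_pair:
            direct_chunks.append(_direct_events(rng, truth, tr, int(i), amp))

    if protocol == "digit_flexion":
        cued = rng.permutation(np.tile(np.arange(1, 6), int(np.ceil(n_trials / 5)))[:n_trials])
        for k in range(n_trials):
            onset = t + 1.0 + REACTION_LAG_S
            delta = truth.baseline_hz * truth.digit_pref[:, cued[k] - 1]
            add_shift(onset, onset + 1.0, delta)
            trial_rows.append(
                dict(trial_id=k, condition="digit_flexion", phase="flexion",
                     phase_start_s=onset, phase_end_s=onset + 1.0,
                     amplitude_level_uA=np.nan, cued_digit=int(cued[k]), target_id=np.nan)
            )
            t = onset + 1.5
    elif protocol == "squeeze":
        amps = rng.permutation(
            np.tile(AMPLITUDE_LEVELS_UA, int(np.ceil(n_trials / 4)))[:n_trials]
        )
        for k in range(n_trials):
            contact = t + 1.0
            stim_bout(contact, contact + 1.0, amps[k], "squeeze")
            trial_rows.append(
                dict(trial_id=k, condition="squeeze", phase="squeeze",
                     phase_start_s=contact, phase_end_s=contact + 1.0,
                     amplitude_level_uA=amps[k], cued_digit=np.nan, target_id=np.nan)
            )
            t = contact + 2.0
    elif protocol == "grasp_transport":
        amps = rng.permutation(
            np.tile(AMPLITUDE_LEVELS_UA, int(np.ceil(n_trials / 4)))[:n_trials]
        )
        targets = rng.permutation(np.tile(np.arange(8), int(np.ceil(n_trials / 8)))[:n_trials])
        for k in range(n_trials):
            reach0, grasp0 = t, t + 1.5
            trans0 = grasp0 + 1.0
            trans1 = trans0 + transport_duration_s
            v_out = _CUBE_CORNERS[targets[k]] * reach_speed
            add_shift(reach0, grasp0, truth.vel_tuning @ v_out)
            add_shift(trans0, trans1, truth.vel_tuning @ (-v_out))
            # one continuous train over grasp+transport; indirect gain switches
            # with the behavioral phase (grasp vs transport task gain)
            tr = StimTrain.regular(
                [int(truth.s1_channel_ids[i]) for i in stim_pair],
                grasp0, trans1 - grasp0, frequency_hz, amps[k],
            )
            trains.append(tr)
            for phase, a, b in (("grasp", grasp0, trans0), ("transport", trans0, trans1)):
                shift = np.mean(
                    [truth.indirect_shift_hz(int(i), amps[k], phase) for i in stim_pair], axis=0
                )
                add_shift(a, b, shift)
            for i in stim_pair:
                direct_chunks.append(_direct_events(rng, truth, tr, int(i), amps[k]))
            for phase, a, b in (
                ("reach", reach0, grasp0),
                ("grasp", grasp0, trans0),
                ("transport", trans0, trans1),
            ):
                trial_rows.append(
                    dict(trial_id=k, condition="grasp_transport", phase=phase,
                         phase_start_s=a, phase_end_s=b,
                         amplitude_level_uA=amps[k], cued_digit=np.nan,
                         target_id=int(targets[k]))
                )
            t = trans1 + 1.0
    elif protocol == "center_out":
        n_targets = 8
        targets = rng.permutation(np.tile(np.arange(n_targets), int(np.ceil(n_trials / n_targets)))[:n_trials])
        for k in range(n_trials):
            onset = t + 0.5
            theta = 2 * np.pi * targets[k] / n_targets
            v = np.array([np.cos(theta), np.sin(theta), 0.0]) * reach_speed
            add_shift(onset, onset + 1.5, truth.vel_tuning @ v)
            trial_rows.append(
                dict(trial_id=k, condition="center_out", phase="reach",
                     phase_start_s=onset, phase_end_s=onset + 1.5,
                     amplitude_level_uA=np.nan, cued_digit=np.nan, target_id=int(targets[k]))
            )
            t = onset + 2.0

    duration = t + 1.0
    spikes = _assemble_spikes(rng, truth, duration, windows, direct_chunks, trains)
    return Session(
        spikes=spikes,
        trains=trains,
        trials=pd.DataFrame(trial_rows),
        arraymap=truth.arraymap,
        truth=truth,
        duration_s=duration,
        metadata={"protocol": protocol, "seed": seed, "n_trials": n_trials},
    )
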