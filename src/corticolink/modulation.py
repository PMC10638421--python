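"""Detection of ICMS-evoked firing-rate modulation against bootstrap nulls.

For each motor channel a null distribution of baseline fluctuations is built
by repeatedly sampling pairs of consecutive 1-s intervals from the intertrial
periods and averaging their rate differences.  Post-pulse blanking (the
first ``analysis_blank_ms`` after each would-be pulse) is *simulated in the
baseline* so that null and stimulation statistics see the same duty cycle.
A (motor, stim) pair's modulation is the mean train-vs-pre-train rate
change; it is expressed as a z-score against the channel's null and called
significant when it falls beyond every null draw (empirical p < 1/(n+1),
i.e. p < 0.001 at the default 1000 resamples).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_model import ANALYSIS_BLANK_MS, SpikeTable, StimTrain

SIGN_EXCITATORY = "excitatory"
SIGN_INHIBITORY = "inhibitory"
SIGN_NONE = "none"


@dataclass
class NullDistribution:
    """Empirical null of mean baseline rate differences for one channel."""

    channel: int
    draws: np.ndarray
    n_pairs_per_draw: int
    degenerate: bool = False

    @property
    def mean(self) -> float:
        return float(np.mean(self.draws))

    @property
    def sd(self) -> float:
        return float(np.std(self.draws))


@dataclass
class ModulationResult:
    motor_channel: int
    stim_channel: int
    delta_rate_hz: float
    z: float
    p: float
    sign: str
    usable: bool = True


def intertrial_intervals(
    trains: list, session_duration_s: float, min_length_s: float = 2.0
) -> np.ndarray:
    """Gaps between stimulation bouts (and the leading/trailing stretches),
    keeping only those long enough to hold two consecutive 1-s intervals."""
    spans = sorted((tr.start_s, tr.end_s) for tr in trains)
    gaps, cursor = [], 0.0
    for a, b in spans:
        if a - cursor >= min_length_s:
            gaps.append((cursor, a))
        cursor = max(cursor, b)
    if session_duration_s - cursor >= min_length_s:
        gaps.append((cursor, session_duration_s))
    return np.array(gaps).reshape(-1, 2)


def _lattice_starts(intervals: np.ndarray, pair_span_s: float, step_s: float) -> np.ndarray:
    """Candidate pair start times on a fixed lattice inside the intertrial
    intervals.  The lattice (one blanking period) lets baseline blanking be
    pre-applied to the spike train once instead of per sample."""
    starts = []
    for a, b in intervals:
        t0 = np.ceil(a / step_s) * step_s
        n = int(np.floor((b - pair_span_s - t0) / step_s)) + 1
        if n > 0:
            starts.append(t0 + np.arange(n) * step_s)
    if not starts:
        return np.empty(0)
    return np.concatenate(starts)


def _blank_filtered_times(times: np.ndarray, blank_at_hz: float, blank_ms: float) -> np.ndarray:
    """Drop spikes that would fall in a simulated blank window, for blank
    windows phase-locked to the absolute lattice of period 1/blank_at_hz."""
    period = 1.0 / blank_at_hz
    return times[np.mod(times, period) >= blank_ms * 1e-3]


def baseline_null(
    spikes: SpikeTable,
    intertrial: np.ndarray,
    n_resamples: int = 1000,
    n_pairs_per_draw: int = 15,
    blank_at_hz: float | None = 100.0,
    analysis_blank_ms: float = ANALYSIS_BLANK_MS,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    channel_ids: np.ndarray | None = None,
    interval_s: float = 1.0,
) -> dict:
    """Bootstrap null of baseline fluctuations, one per motor channel.

    Each of ``n_resamples`` draws samples ``n_pairs_per_draw`` consecutive
    1-s interval pairs (with replacement) from the intertrial periods and
    records the mean rate difference.  Returns ``{channel:
    NullDistribution}``.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    intertrial = np.asarray(intertrial, dtype=float).reshape(-1, 2)
    step = 1.0 / blank_at_hz if blank_at_hz else interval_s
    candidates = _lattice_starts(intertrial, 2 * interval_s, step)
    if len(candidates) == 0:
        raise ValueError("no intertrial interval can hold a consecutive 1-s pair")
    if len(candidates) < n_pairs_per_draw:
        warnings.warn(
            f"only {len(candidates)} candidate interval pairs for "
            f"{n_pairs_per_draw} per draw; sampling with replacement"
        )
    if channel_ids is None:
        channel_ids = spikes.channels
    picks = candidates[rng.integers(0, len(candidates), size=(n_resamples, n_pairs_per_draw))]

    nulls = {}
    for ch in np.asarray(channel_ids, dtype=int):
        t = spikes.times_for(int(ch))
        if blank_at_hz:
            t = _blank_filtered_times(t, blank_at_hz, analysis_blank_ms)
        c0 = np.searchsorted(t, picks)
        c1 = np.searchsorted(t, picks + interval_s)
        c2 = np.searchsorted(t, picks + 2 * interval_s)
        diffs = ((c2 - c1) - (c1 - c0)) / interval_s
        draws = diffs.mean(axis=1)
        degenerate = bool(np.std(draws) == 0)
        if degenerate:
            warnings.warn(f"degenerate null (SD = 0) for channel {ch}")
        nulls[int(ch)] = NullDistribution(int(ch), draws, n_pairs_per_draw, degenerate)
    return nulls


def _blanked_count(times: np.ndarray, start: float, end: float,
                   blank_starts: np.ndarray, blank_s: float) -> int:
    """Events in [start, end) excluding the per-pulse blank windows."""
    lo, hi = np.searchsorted(times, [start, end])
    n = hi - lo
    if len(blank_starts):
        b0 = np.searchsorted(times, blank_starts)
        b1 = np.searchsorted(times, np.minimum(blank_starts + blank_s, end))
        n -= int(np.sum(b1 - b0))
    return int(n)


def stim_modulation(
    spikes: SpikeTable,
    trains: list,
    null: NullDistribution,
    analysis_blank_ms: float = ANALYSIS_BLANK_MS,
    baseline_s: float = 1.0,
    min_trains: int = 15,
) -> ModulationResult:
    """Modulation of one motor channel by one stim channel's trains.

    Per train: rate during the train minus rate in the 1-s interval that
    precedes it, both with the first ``analysis_blank_ms`` after each
    (actual or simulated) pulse discarded; the per-train differences are
    averaged and z-scored against the channel's null.
    """
    if len(trains) < min_trains:
        warnings.warn(
            f"{len(trains)} trains < protocol minimum {min_trains}; proceeding"
        )
    times = spikes.times_for(null.channel)
    blank_s = analysis_blank_ms * 1e-3
    diffs = []
    for tr in trains:
        dur = tr.end_s - tr.start_s
        stim_n = _blanked_count(times, tr.start_s, tr.end_s, tr.pulse_times_s, blank_s)
        # simulated pulse lattice in the pre-train baseline
        b0 = tr.start_s - baseline_s
        sim = b0 + np.arange(int(round(baseline_s * tr.frequency_hz))) / tr.frequency_hz
        base_n = _blanked_count(times, b0, tr.start_s, sim, blank_s)
        diffs.append(stim_n / dur - base_n / baseline_s)
    delta = float(np.mean(diffs))

    stim_channel = trains[0].stim_channel_ids[0] if trains else -1
    if null.degenerate:
        return ModulationResult(null.channel, stim_channel, delta, np.nan, np.nan,
                                SIGN_NONE, usable=False)
    z = (delta - null.mean) / null.sd
    n_extreme = int(np.sum(np.abs(null.draws - null.mean) >= abs(delta - null.mean)))
    p = (1 + n_extreme) / (len(null.draws) + 1)
    significant = n_extreme == 0
    sign = (SIGN_EXCITATORY if z > 0 else SIGN_INHIBITORY) if significant else SIGN_NONE
    return ModulationResult(null.channel, int(stim_channel), delta, float(z), float(p), sign)


def modulation_table(
    spikes: SpikeTable,
    trains: list,
    session_duration_s: float,
    n_resamples: int = 1000,
    n_pairs_per_draw: int | None = None,
    blank_at_hz: float | None = 100.0,
    analysis_blank_ms: float = ANALYSIS_BLANK_MS,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    channel_ids: np.ndarray | None = None,
) -> pd.DataFrame:
    """All-pairs modulation results: one shared null per motor channel,
    trains grouped by stimulating channel.

    ``n_pairs_per_draw`` defaults to the per-stim-channel train count so the
    null's variance matches the statistic's sampling variance.
    """
    by_stim: dict[int, list] = {}
    for tr in trains:
        by_stim.setdefault(int(tr.stim_channel_ids[0]), []).append(tr)
    counts = [len(v) for v in by_stim.values()]
    if n_pairs_per_draw is None:
        n_pairs_per_draw = int(np.median(counts)) if counts else 15
    intertrial = intertrial_intervals(trains, session_duration_s)
    nulls = baseline_null(
        spikes, intertrial, n_resamples, n_pairs_per_draw, blank_at_hz,
        analysis_blank_ms, seed=seed, rng=rng, channel_ids=channel_ids,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rows = [
            stim_modulation(spikes, tr_list, null, analysis_blank_ms)
            for s, tr_list in sorted(by_stim.items())
            for null in nulls.values()
        ]
    return pd.DataFrame([vars(r) for r in rows])


@dataclass
class PrevalenceSummary:
    per_channel: pd.DataFrame      # proportion, mean_z, mixed_sign per motor channel
    proportion_grid: np.ndarray    # grid-shaped, NaN where unwired/absent
    mean_z_grid: np.ndarray


def summarize_prevalence(results: pd.DataFrame, arraymap: pd.DataFrame) -> PrevalenceSummary:
    """Per-motor-channel prevalence of significant modulation across stim
    channels, the mean z map, and a mixed-sign flag (channel shows both
    significant increases and decreases)."""
    usable = results[results["usable"]]
    grp = usable.groupby("motor_channel")
    per_channel = pd.DataFrame(
        {
            "proportion": grp.apply(
                lambda g: float(np.mean(g["sign"] != SIGN_NONE)), include_groups=False
            ),
            "mean_z": grp["z"].mean(),
            "mixed_sign": grp.apply(
                lambda g: bool(
                    (g["sign"] == SIGN_EXCITATORY).any() and (g["sign"] == SIGN_INHIBITORY).any()
                ),
                include_groups=False,
            ),
        }
    ).reset_index()

    m1 = arraymap[arraymap["region"] == "M1"]
    n_rows = int(m1["grid_row"].max()) + 1
    n_cols = int(m1["grid_col"].max()) + 1
    prop = np.full((n_rows, n_cols), np.nan)
    meanz = np.full((n_rows, n_cols), np.nan)
    lookup = per_channel.set_index("motor_channel")
    for _, row in m1.iterrows():
        if not row["wired"] or row["electrode_id"] not in lookup.index:
            continue
        r, c = int(row["grid_row"]), int(row["grid_col"])
        prop[r, c] = lookup.loc[row["electrode_id"], "proportion"]
        meanz[r, c] = lookup.loc[row["electrode_id"], "mean_z"]
    return PrevalenceSummary(per_channel, prop, meanz)
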