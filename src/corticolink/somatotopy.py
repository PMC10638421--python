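"""Somatotopic mapping: motor maps, sensory projection maps, and their linkage.

A *motor map* gives, per M1 channel and digit, the baseline-normalized
modulation of firing during attempted flexion of that digit.  A *sensory
projection map* gives, per M1 channel and digit, the ICMS-evoked modulation
when stimulating through S1 channels whose projected field (PF) lies on that
digit, normalized within digit by the mean across M1 channels (so that
digit-wide differences in stimulation efficacy cancel).  Somatotopic linkage
is tested by comparing, across channels, the projection-map activation for
each channel's preferred movement digit against all other digits
(Wilcoxon rank-sum), and by a digit-preference-rank analysis with a
shuffle-then-smooth null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .core_model import DEFAULT_BIN_MS, SpikeTable


@dataclass
class DigitMap:
    """Per-channel x per-digit modulation values (motor or projection)."""

    values: pd.DataFrame               # index = channel id, columns = digit (int)
    source: str                        # 'motor' | 'projection'
    smoothed: bool = False

    @property
    def digits(self) -> np.ndarray:
        return np.asarray(self.values.columns, dtype=int)

    def preferred_digit(self) -> pd.Series:
        return self.values.idxmax(axis=1)


def motor_map(
    spikes: SpikeTable,
    trials: pd.DataFrame,
    channel_ids: np.ndarray | None = None,
    window_s: float = 2.0,
    bin_ms: float = DEFAULT_BIN_MS,
    response_window_bins: int = 10,
    min_trials_per_digit: int = 10,
) -> DigitMap:
    """Digit-selectivity map from attempted single-digit flexions.

    Per channel, peri-movement histograms (20-ms bins over ``window_s``
    centered on movement start) are averaged per digit; the contiguous
    ``response_window_bins``-bin window maximizing the spread between the
    most- and least-responsive digit is selected, and modulation is
    ``(rate_d - mean over digits) / mean over digits``.  Channels with zero
    mean rate in the selected window are masked (NaN row).
    """
    flex = trials[trials["phase"] == "flexion"]
    digits = np.sort(flex["cued_digit"].dropna().unique().astype(int))
    counts = flex.groupby("cued_digit").size()
    low = counts[counts < min_trials_per_digit]
    if len(low):
        warnings.warn(f"fewer than {min_trials_per_digit} flexions for digits {low.index.tolist()}")
    if channel_ids is None:
        channel_ids = spikes.channels
    w_s = bin_ms * 1e-3
    n_bins = int(round(window_s / w_s))
    half = window_s / 2

    rows = {}
    for ch in np.asarray(channel_ids, dtype=int):
        t = spikes.times_for(int(ch))
        peth = np.zeros((len(digits), n_bins))
        for di, d in enumerate(digits):
            onsets = flex.loc[flex["cued_digit"] == d, "phase_start_s"].to_numpy()
            for t0 in onsets:
                edges = t0 - half + np.arange(n_bins + 1) * w_s
                peth[di] += np.histogram(t, bins=edges)[0]
            peth[di] /= max(len(onsets), 1) * w_s
        # sliding response window maximizing max-min spread across digits
        kernel = np.ones(response_window_bins) / response_window_bins
        win_means = np.apply_along_axis(
            lambda x: np.convolve(x, kernel, mode="valid"), 1, peth
        )
        spread = win_means.max(axis=0) - win_means.min(axis=0)
        j = int(np.argmax(spread))
        rates = win_means[:, j]
        mean_rate = rates.mean()
        rows[int(ch)] = (
            (rates - mean_rate) / mean_rate if mean_rate > 0 else np.full(len(digits), np.nan)
        )
    values = pd.DataFrame.from_dict(rows, orient="index", columns=digits)
    return DigitMap(values.sort_index(), source="motor")


def projection_map(
    results: pd.DataFrame,
    arraymap: pd.DataFrame,
    digits_included: np.ndarray | None = None,
    normalize: bool = True,
) -> DigitMap:
    """ICMS-evoked activation per M1 channel, grouped by the PF digit of the
    stimulating channels and normalized within digit by the mean across M1
    channels.  Digits with no labeled stim channel are excluded (warning);
    no labels at all is an error.
    """
    s1 = arraymap[(arraymap["region"] == "S1") & (arraymap["pf_dominant"] > 0)]
    if len(s1) == 0:
        raise ValueError("no S1 channels carry PF digit labels")
    if digits_included is None:
        digits_included = np.sort(s1["pf_dominant"].unique().astype(int))
    pf_of = s1.set_index("electrode_id")["pf_dominant"].astype(int)

    cols = {}
    for d in np.asarray(digits_included, dtype=int):
        stim_ids = pf_of.index[pf_of == d]
        sub = results[results["stim_channel"].isin(stim_ids)]
        if len(sub) == 0:
            warnings.warn(f"digit {d}: no stim channels with that PF; excluded")
            continue
        per_channel = sub.groupby("motor_channel")["z"].mean()
        if normalize:
            grand = per_channel.mean()
            per_channel = per_channel / grand if grand != 0 else per_channel * np.nan
        cols[d] = per_channel
    values = pd.DataFrame(cols)
    return DigitMap(values.sort_index(), source="projection")


def _m1_grid(arraymap: pd.DataFrame) -> pd.DataFrame:
    m1 = arraymap[arraymap["region"] == "M1"]
    return m1.set_index("electrode_id")[["grid_row", "grid_col", "wired"]]


def smooth_map(dmap: DigitMap, arraymap: pd.DataFrame, sigma_pitch: float = 1.0) -> DigitMap:
    """2D Gaussian smoothing on the electrode grid (sigma = one electrode
    pitch by default), with the kernel renormalized over wired, unmasked
    electrodes so edges and unwired cells neither leak nor dilute."""
    grid = _m1_grid(arraymap)
    n_rows = int(grid["grid_row"].max()) + 1
    n_cols = int(grid["grid_col"].max()) + 1
    out = {}
    for d in dmap.values.columns:
        val = np.zeros((n_rows, n_cols))
        mask = np.zeros((n_rows, n_cols))
        for ch, v in dmap.values[d].items():
            if ch not in grid.index or not grid.loc[ch, "wired"] or not np.isfinite(v):
                continue
            r, c = int(grid.loc[ch, "grid_row"]), int(grid.loc[ch, "grid_col"])
            val[r, c], mask[r, c] = v, 1.0
        num = ndimage.gaussian_filter(val * mask, sigma_pitch, mode="constant")
        den = ndimage.gaussian_filter(mask, sigma_pitch, mode="constant")
        sm = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
        col = {}
        for ch in dmap.values.index:
            if ch in grid.index:
                r, c = int(grid.loc[ch, "grid_row"]), int(grid.loc[ch, "grid_col"])
                col[ch] = sm[r, c] if mask[r, c] else np.nan
            else:
                col[ch] = np.nan
        out[d] = col
    values = pd.DataFrame(out).loc[dmap.values.index]
    return DigitMap(values, source=dmap.source, smoothed=True)


@dataclass
class MatchedTest:
    statistic: float
    p: float
    median_matched: float
    median_unmatched: float

    @property
    def matched_greater(self) -> bool:
        return self.median_matched > self.median_unmatched


def matched_vs_unmatched(motor: DigitMap, projection: DigitMap) -> MatchedTest:
    """Rank-sum test of projection-map activation for somatotopically matched
    (PF digit == preferred movement digit) vs unmatched pairs, pooled over
    M1 channels."""
    digits = [d for d in projection.values.columns if d in set(motor.values.columns)]
    if len(digits) < 2:
        raise ValueError("need at least two shared digits")
    matched, unmatched = [], []
    for ch in projection.values.index:
        if ch not in motor.values.index:
            continue
        prof = motor.values.loc[ch, digits]
        if prof.isna().any():
            continue
        pref = prof.idxmax()
        for d in digits:
            v = projection.values.loc[ch, d]
            if not np.isfinite(v):
                continue
            (matched if d == pref else unmatched).append(v)
    if min(len(matched), len(unmatched)) < 5:
        warnings.warn("fewer than 5 values in a group; low power")
    stat, p = stats.ranksums(matched, unmatched)
    return MatchedTest(float(stat), float(p), float(np.median(matched)), float(np.median(unmatched)))


@dataclass
class PreferenceProfileResult:
    rank_means: np.ndarray             # mean activation by motor-preference rank
    kruskal_p: float
    per_channel_r: pd.Series
    mean_r: float
    shuffle_p: float


def preference_profile_analysis(
    motor_raw: DigitMap,
    projection_raw: DigitMap,
    arraymap: pd.DataFrame,
    n_shuffles: int = 10000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    smooth: bool = True,
    sigma_pitch: float = 1.0,
) -> PreferenceProfileResult:
    """Does a channel's movement digit-preference profile predict which PF
    digits most effectively drive it?

    Activations are grouped by motor-preference rank (rank 1 = most
    preferred digit) and compared with Kruskal-Wallis; per-channel Pearson r
    between the motor and projection profiles is tested against a null in
    which electrode and digit assignments are shuffled and the maps are then
    re-smoothed ("shuffle then smooth"), so smoothing artifacts cannot
    masquerade as structure.  Pass the *unsmoothed* maps.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    digits = [d for d in projection_raw.values.columns if d in set(motor_raw.values.columns)]
    if len(digits) < 3:
        raise ValueError("need at least 3 shared digits")


    motor_sm = smooth_map(motor_raw, arraymap, sigma_pitch) if smooth else motor_raw

    def _prep_proj(p_raw):
        p = smooth_map(p_raw, arraymap, sigma_pitch) if smooth else p_raw
        chans = [
            ch
            for ch in p.values.index
            if ch in motor_sm.values.index
            and np.isfinite(motor_sm.values.loc[ch, digits]).all()
            and np.isfinite(p.values.loc[ch, digits]).all()
        ]
        M = motor_sm.values.loc[chans, digits].to_numpy(float)
        P = p.values.loc[chans, digits].to_numpy(float)
        return chans, M, P

    chans, M, P = _prep_proj(projection_raw)

    # activation by motor-preference rank
    order = np.argsort(-M, axis=1)
    by_rank = np.take_along_axis(P, order, axis=1)
    rank_means = by_rank.mean(axis=0)
    groups = [by_rank[:, k] for k in range(by_rank.shape[1])]
    kw_p = float(stats.kruskal(*groups).pvalue)

    def _mean_r(Mv, Pv):
        Mc = Mv - Mv.mean(axis=1, keepdims=True)
        Pc = Pv - Pv.mean(axis=1, keepdims=True)
        denom = np.linalg.norm(Mc, axis=1) * np.linalg.norm(Pc, axis=1)
        ok = denom > 0
        r = np.full(len(Mv), np.nan)
        r[ok] = np.sum(Mc * Pc, axis=1)[ok] / denom[ok]
        return r

    r_obs = _mean_r(M, P)
    per_channel_r = pd.Series(r_obs, index=chans)
    mean_r = float(np.nanmean(r_obs))

    # shuffle-then-smooth null on the raw projection values, computed on the
    # grid directly (much cheaper than rebuilding DigitMaps per shuffle)
    grid = _m1_grid(arraymap)
    raw_P = projection_raw.values.loc[:, digits]
    p_chans = [ch for ch in raw_P.index if ch in grid.index and grid.loc[ch, "wired"]]
    rr = grid.loc[p_chans, "grid_row"].to_numpy(int)
    cc = grid.loc[p_chans, "grid_col"].to_numpy(int)
    n_rows, n_cols = int(grid["grid_row"].max()) + 1, int(grid["grid_col"].max()) + 1
    Rv = raw_P.loc[p_chans].to_numpy(float)
    finite = np.isfinite(Rv).all(axis=1)
    keep_idx = [i for i, ch in enumerate(p_chans) if ch in chans]
    mgrid = np.zeros((n_rows, n_cols))
    mgrid[rr[finite], cc[finite]] = 1.0
    den = ndimage.gaussian_filter(mgrid, sigma_pitch, mode="constant") if smooth else None

    null = np.empty(n_shuffles)
    for b in range(n_shuffles):
        perm_rows = rng.permutation(len(Rv))
        perm_cols = rng.permutation(len(digits))
        Rs = Rv[perm_rows][:, perm_cols]
        if smooth:
            Ps = np.empty_like(Rs)
            for d in range(len(digits)):
                vg = np.zeros((n_rows, n_cols))
                vg[rr[finite], cc[finite]] = np.where(finite, Rs[:, d], 0.0)[finite]
                num = ndimage.gaussian_filter(vg, sigma_pitch, mode="constant")
                sm = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
                Ps[:, d] = sm[rr, cc]
        else:
            Ps = Rs
        null[b] = np.nanmean(_mean_r(M, Ps[keep_idx]))
    shuffle_p = float((1 + np.sum(null >= mean_r)) / (n_shuffles + 1))

    return PreferenceProfileResult(rank_means, kw_p, per_channel_r, mean_r, shuffle_p)


def gradient_map(dmap: DigitMap) -> pd.Series:
    """Per-channel Spearman correlation between the digit profile and digit
    index (thumb = 1 ... pinky = 5); constant profiles are masked."""
    digits = dmap.digits.astype(float)
    if len(digits) < 3:
        raise ValueError("need at least 3 digits")
    out = {}
    for ch, row in dmap.values.iterrows():
        v = row.to_numpy(float)
        if not np.isfinite(v).all() or np.ptp(v) == 0:
            out[ch] = np.nan
        else:
            out[ch] = float(stats.spearmanr(v, digits).statistic)
    return pd.Series(out)


@dataclass
class PatternCorrelation:
    within_array: np.ndarray
    between_array: np.ndarray
    ranksum_p: float
    distance_slope: float
    distance_slope_p: float


def pattern_correlation(results: pd.DataFrame, arraymap: pd.DataFrame) -> PatternCorrelation:
    """Similarity of the M1 activation patterns evoked by different S1
    channels: within- vs between-array pairwise Pearson correlations
    (rank-sum test) and, within array, correlation regressed on the grid
    distance between the two stim electrodes."""
    pivot = results.pivot_table(index="motor_channel", columns="stim_channel", values="z")
    stim_ids = pivot.columns.to_numpy()
    vec = pivot.to_numpy(float)
    s1 = arraymap[arraymap["region"] == "S1"].set_index("electrode_id")
    corr = np.corrcoef(vec.T)

    within, between, dists, wcorr = [], [], [], []
    for i in range(len(stim_ids)):
        for j in range(i + 1, len(stim_ids)):
            a, b = stim_ids[i], stim_ids[j]
            if a not in s1.index or b not in s1.index:
                continue
            c = corr[i, j]
            if not np.isfinite(c):
                continue
            if s1.loc[a, "array_id"] == s1.loc[b, "array_id"]:
                within.append(c)
                d = np.hypot(
                    s1.loc[a, "grid_row"] - s1.loc[b, "grid_row"],
                    s1.loc[a, "grid_col"] - s1.loc[b, "grid_col"],
                )
                dists.append(d)
                wcorr.append(c)
            else:
                between.append(c)
    _, p = stats.ranksums(within, between)
    if len(dists) >= 3 and np.ptp(dists) > 0:
        fit = stats.linregress(dists, wcorr)
        slope, slope_p = float(fit.slope), float(fit.pvalue)
    else:
        slope, slope_p = np.nan, np.nan
    return PatternCorrelation(
        np.asarray(within), np.asarray(between), float(p), slope, slope_p
    )
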