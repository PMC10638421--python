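"""Task dependence of ICMS-evoked motor-cortex activity.

Firing rates are extracted in three behavioral analysis windows that share
identical ICMS but differ in movement context: the 1-s post-contact window
of the squeeze task, the 1-s post-contact (grasp) window of the
grasp-and-transport task, and the first second of the transport phase.
Each channel gets a two-factor (phase x amplitude) fixed-effects ANOVA with
interaction; the task-dependence index is the interaction F divided by the
amplitude main-effect F, computed only for amplitude-significant channels.
Direct (pulse-locked) inputs are task-invariant by construction upstream, so
their td-index sits near zero while task-gated indirect effects spread wide.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.naive_bayes import GaussianNB

from .core_model import SpikeTable

PHASES = ("squeeze", "grasp", "transport")
BASELINE_S = 0.5


def _rate(times: np.ndarray, a: float, b: float) -> float:
    lo, hi = np.searchsorted(times, [a, b])
    return (hi - lo) / (b - a)


def phase_rates(
    spikes: SpikeTable,
    trials: pd.DataFrame,
    channel_ids: np.ndarray | None = None,
    window_s: float = 1.0,
) -> pd.DataFrame:
    """Per-(channel, trial, phase) firing rates plus phase-specific baselines.

    Stimulation windows are the first ``window_s`` of the squeeze, grasp and
    transport phases.  Baselines: the half second preceding object contact
    (squeeze, grasp) and the first half second of the reach (transport).
    Trials whose phase is shorter than the window are dropped with a warning.
    """
    if channel_ids is None:
        channel_ids = spikes.channels
    times = {int(c): spikes.times_for(int(c)) for c in channel_ids}

    rows = []
    dropped = 0
    reach_start = (
        trials[trials["phase"] == "reach"].set_index("trial_id")["phase_start_s"]
        if (trials["phase"] == "reach").any()
        else pd.Series(dtype=float)
    )
    for _, tr in trials.iterrows():
        phase = tr["phase"]
        if phase not in PHASES:
            continue
        a = float(tr["phase_start_s"])
        if float(tr["phase_end_s"]) - a < window_s - 1e-9:
            dropped += 1
            continue
        if phase == "transport":
            if tr["trial_id"] not in reach_start.index:
                dropped += 1
                continue
            b0 = float(reach_start.loc[tr["trial_id"]])
            base_win = (b0, b0 + BASELINE_S)
        else:
            base_win = (a - BASELINE_S, a)
        for ch in times:
            rows.append(
                dict(
                    channel=ch,
                    trial_id=int(tr["trial_id"]),
                    phase=phase,
                    amplitude_uA=float(tr["amplitude_level_uA"]),
                    rate_hz=_rate(times[ch], a, a + window_s),
                    baseline_hz=_rate(times[ch], *base_win),
                )
            )
    if dropped:
        warnings.warn(f"dropped {dropped} trial-phases shorter than the analysis window")
    return pd.DataFrame(rows)


@dataclass
class TaskDependenceResult:
    channel: int
    F_task: float
    F_amp: float
    F_interaction: float
    p_task: float
    p_amp: float
    p_interaction: float
    td_index: float          # NaN unless amplitude main effect significant
    amp_mod_index: float


def _twoway_anova(y: np.ndarray, phase: np.ndarray, amp: np.ndarray):
    """Balanced-ish two-factor fixed-effects ANOVA with interaction,
    type-II sums of squares via nested OLS fits."""
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    df = pd.DataFrame({"y": y, "phase": phase, "amp": amp.astype(str)})
    model = ols("y ~ C(phase) * C(amp)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    f = table["F"]
    p = table["PR(>F)"]
    return (
        float(f["C(phase)"]), float(f["C(amp)"]), float(f["C(phase):C(amp)"]),
        float(p["C(phase)"]), float(p["C(amp)"]), float(p["C(phase):C(amp)"]),
    )


def anova_task_amp(rate_table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-channel phase x amplitude ANOVA and the task-dependence index
    td = F_interaction / F_amplitude (amplitude-significant channels only)."""
    out = []
    for ch, g in rate_table.groupby("channel"):
        y = g["rate_hz"].to_numpy(float)
        if np.var(y) == 0:
            out.append(TaskDependenceResult(int(ch), *([np.nan] * 8)))
            continue
        ft, fa, fi, pt, pa, pi = _twoway_anova(
            y, g["phase"].to_numpy(), g["amplitude_uA"].to_numpy()
        )
        td = fi / fa if (pa < alpha and fa > 0) else np.nan
        amps = g.groupby("amplitude_uA")["rate_hz"].mean()
        base = g["baseline_hz"].mean()
        amp_mod = (amps.loc[amps.index.max()] - amps.loc[amps.index.min()]) / base if base > 0 else np.nan
        out.append(TaskDependenceResult(int(ch), ft, fa, fi, pt, pa, pi, td, amp_mod))
    return pd.DataFrame([vars(r) for r in out])


@dataclass
class BaselineModulationResult:
    table: pd.DataFrame            # channel, phase, norm_baseline, amp_mod_index
    friedman_stat: float
    friedman_p: float
    spearman_rho: float
    spearman_p: float


def modulation_vs_baseline(rate_table: pd.DataFrame) -> BaselineModulationResult:
    """Relationship between ICMS modulation depth and (task-dependent)
    baseline rate.  A saturation account predicts a negative correlation;
    Friedman's test asks whether modulation differs systematically across
    phases (channels as blocks)."""
    rows = []
    for (ch, phase), g in rate_table.groupby(["channel", "phase"]):
        amps = g.groupby("amplitude_uA")["rate_hz"].mean()
        rows.append(
            dict(channel=ch, phase=phase, baseline_hz=g["baseline_hz"].mean(),
                 amp_span_hz=amps.loc[amps.index.max()] - amps.loc[amps.index.min()])
        )
    tab = pd.DataFrame(rows)
    mean_base = tab.groupby("channel")["baseline_hz"].transform("mean")
    tab["norm_baseline"] = np.where(mean_base > 0, tab["baseline_hz"] / mean_base, np.nan)
    tab["amp_mod_index"] = np.where(mean_base > 0, tab["amp_span_hz"] / mean_base, np.nan)

    wide = tab.pivot(index="channel", columns="phase", values="amp_mod_index").dropna()
    if wide.shape[1] >= 3 and len(wide) >= 3:
        fr = stats.friedmanchisquare(*[wide[c] for c in wide.columns])
        f_stat, f_p = float(fr.statistic), float(fr.pvalue)
    else:
        f_stat, f_p = np.nan, np.nan
    ok = tab[["norm_baseline", "amp_mod_index"]].dropna()
    rho = stats.spearmanr(ok["norm_baseline"], ok["amp_mod_index"])
    return BaselineModulationResult(tab, f_stat, f_p, float(rho.statistic), float(rho.pvalue))


def _design_matrices(rate_table: pd.DataFrame, phase: str):
    g = rate_table[rate_table["phase"] == phase]
    X = g.pivot(index="trial_id", columns="channel", values="rate_hz")
    B = g.pivot(index="trial_id", columns="channel", values="baseline_hz")
    y = g.groupby("trial_id")["amplitude_uA"].first().loc[X.index]
    return (X - B).to_numpy(float), y.to_numpy(float)


def amplitude_classifier(
    rate_table: pd.DataFrame, conditions: tuple = PHASES, shrinkage: str | float = "auto"
) -> pd.DataFrame:
    """LDA decoding of ICMS amplitude from baseline-subtracted rates.

    Within-condition accuracy by leave-one-out cross-validation; cross-
    condition by training on all trials of one phase and testing on all of
    another.  Chance is 1/(number of amplitude levels).  Shrinkage-
    regularized LDA guards against singular within-class covariance.
    """
    data = {c: _design_matrices(rate_table, c) for c in conditions}
    acc = pd.DataFrame(index=conditions, columns=conditions, dtype=float)
    for train_c in conditions:
        Xtr, ytr = data[train_c]
        for test_c in conditions:
            if test_c == train_c:
                correct = 0
                for i in range(len(ytr)):
                    mask = np.arange(len(ytr)) != i
                    clf = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=shrinkage)
                    clf.fit(Xtr[mask], ytr[mask])
                    correct += int(clf.predict(Xtr[i: i + 1])[0] == ytr[i])
                acc.loc[train_c, test_c] = correct / len(ytr)
            else:
                Xte, yte = data[test_c]
                clf = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=shrinkage)
                clf.fit(Xtr, ytr)
                acc.loc[train_c, test_c] = float(np.mean(clf.predict(Xte) == yte))
    return acc


def target_classifier(
    spikes: SpikeTable,
    trials: pd.DataFrame,
    min_rate_hz: float = 5.0,
    window_s: float = 1.0,
    pre_onset_s: float = 0.4,
) -> float:
    """Naive-Bayes decoding of the reach target from 1 s of population
    activity starting 400 ms before movement onset, leave-one-out CV.
    Channels must be active (session mean rate above ``min_rate_hz``)."""
    reach = trials[(trials["phase"] == "reach") & trials["target_id"].notna()]
    span = spikes.time_s.max() - spikes.time_s.min() if len(spikes) else 0.0
    active = [
        int(c) for c in spikes.channels if len(spikes.times_for(int(c))) / max(span, 1e-9) > min_rate_hz
    ]
    if not active:
        raise ValueError(f"no channel exceeds the {min_rate_hz}-Hz activity filter")
    times = {c: spikes.times_for(c) for c in active}
    X = np.array(
        [
            [_rate(times[c], t0 - pre_onset_s, t0 - pre_onset_s + window_s) for c in active]
            for t0 in reach["phase_start_s"].to_numpy(float)
        ]
    )
    y = reach["target_id"].to_numpy(int)
    correct = 0
    for i in range(len(y)):
        mask = np.arange(len(y)) != i
        clf = GaussianNB()
        clf.fit(X[mask], y[mask])
        correct += int(clf.predict(X[i: i + 1])[0] == y[i])
    return correct / len(y)


def center_out_classifier(
    spikes: SpikeTable,
    trials: pd.DataFrame,
    bin_ms: float = 20.0,
    smooth_std_ms: float = 100.0,
    n_components: int = 10,
) -> float:
    """Center-out variant: Gaussian-smoothed (std 100 ms) binned rates
    averaged over the reach, top principal components, LDA, leave-one-out."""
    reach = trials[(trials["phase"] == "reach") & trials["target_id"].notna()]
    chans = spikes.channels
    w = bin_ms * 1e-3
    feats = []
    for _, tr in reach.iterrows():
        a, b = float(tr["phase_start_s"]), float(tr["phase_end_s"])
        n_bins = int(np.floor((b - a) / w))
        edges = a + np.arange(n_bins + 1) * w
        row = []
        for c in chans:
            counts = np.histogram(spikes.times_for(int(c)), bins=edges)[0] / w
            row.append(ndimage.gaussian_filter1d(counts.astype(float), smooth_std_ms / bin_ms).mean())
        feats.append(row)
    X = np.asarray(feats)
    y = reach["target_id"].to_numpy(int)
    n_components = min(n_components, X.shape[1], len(y) - 2)
    correct = 0
    for i in range(len(y)):
        mask = np.arange(len(y)) != i
        pca = PCA(n_components=n_components)
        Ztr = pca.fit_transform(X[mask])
        clf = LinearDiscriminantAnalysis()
        clf.fit(Ztr, y[mask])
        correct += int(clf.predict(pca.transform(X[i: i + 1]))[0] == y[i])
    return correct / len(y)
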