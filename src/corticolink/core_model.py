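"""Shared data types and time/bin conventions for ICMS cortico-cortical analyses.

All times are continuous seconds on a 30-kHz clock (resolution 1/30000 s);
every interval in the package is half-open ``[start, end)``.  Spikes are
threshold-crossing events (``unit_id`` 0 means unsorted); stimulation pulses
are charge-balanced asymmetric biphasic pulses (200-us cathodal phase at the
nominal amplitude, 100-us interphase gap, 400-us anodal phase at half
amplitude, so net charge is exactly zero).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

CLOCK_HZ = 30_000
HARDWARE_BLANK_MS = 1.6
ANALYSIS_BLANK_MS = 2.0
DEFAULT_BIN_MS = 20.0
AMPLITUDE_LEVELS_UA = (20.0, 32.0, 44.0, 56.0)

SCHEMA_VERSION = "1.0"

TRIAL_COLUMNS = [
    "trial_id",
    "condition",
    "phase",
    "phase_start_s",
    "phase_end_s",
    "amplitude_level_uA",
    "cued_digit",
    "target_id",
]

ARRAYMAP_COLUMNS = [
    "electrode_id",
    "grid_row",
    "grid_col",
    "wired",
    "region",
    "array_id",
    "pf_dominant",
    "pf_digits",
    "pitch_um",
]


def quantize_time(t: np.ndarray | float) -> np.ndarray | float:
    """Snap times to the 30-kHz acquisition clock."""
    return np.round(np.asarray(t, dtype=float) * CLOCK_HZ) / CLOCK_HZ


@dataclass
class SpikeTable:
    """Timestamped threshold-crossing events, sorted by (channel, time)."""

    channel_id: np.ndarray
    unit_id: np.ndarray
    time_s: np.ndarray

    def __post_init__(self) -> None:
        self.channel_id = np.asarray(self.channel_id, dtype=np.int64)
        self.unit_id = np.asarray(self.unit_id, dtype=np.int64)
        self.time_s = np.asarray(self.time_s, dtype=float)
        if not (len(self.channel_id) == len(self.unit_id) == len(self.time_s)):
            raise ValueError("SpikeTable columns must have equal length")
        if np.any(self.time_s < 0):
            raise ValueError("spike times must be non-negative")
        order = np.lexsort((self.time_s, self.channel_id))
        if not np.array_equal(order, np.arange(len(order))):
            self.channel_id = self.channel_id[order]
            self.unit_id = self.unit_id[order]
            self.time_s = self.time_s[order]

    def __len__(self) -> int:
        return len(self.time_s)

    @property
    def channels(self) -> np.ndarray:
        return np.unique(self.channel_id)

    def times_for(self, channel: int, unit: int | None = None) -> np.ndarray:
        mask = self.channel_id == channel
        if unit is not None:
            mask &= self.unit_id == unit
        return self.time_s[mask]

    def select(self, mask: np.ndarray) -> "SpikeTable":
        return SpikeTable(self.channel_id[mask], self.unit_id[mask], self.time_s[mask])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"channel_id": self.channel_id, "unit_id": self.unit_id, "time_s": self.time_s}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SpikeTable":
        for col in ("channel_id", "unit_id", "time_s"):
            if col not in df.columns:
                raise SchemaError(f"spike table missing required column '{col}'")
        return cls(
            df["channel_id"].to_numpy(),
            df["unit_id"].to_numpy(),
            df["time_s"].to_numpy(),
        )

    @classmethod
    def empty(cls) -> "SpikeTable":
        return cls(np.empty(0, int), np.empty(0, int), np.empty(0, float))

    @classmethod
    def concatenate(cls, tables: list["SpikeTable"]) -> "SpikeTable":
        if not tables:
            return cls.empty()
        return cls(
            np.concatenate([t.channel_id for t in tables]),
            np.concatenate([t.unit_id for t in tables]),
            np.concatenate([t.time_s for t in tables]),
        )


@dataclass
class StimTrain:
    """One stimulation bout: pulse times, per-pulse amplitude, pulse shape."""

    stim_channel_ids: tuple
    pulse_times_s: np.ndarray
    pulse_amplitude_uA: np.ndarray
    frequency_hz: float
    cathodal_us: float = 200.0
    interphase_us: float = 100.0
    anodal_us: float = 400.0
    anodal_fraction: float = 0.5

    def __post_init__(self) -> None:
        self.stim_channel_ids = tuple(int(c) for c in np.atleast_1d(self.stim_channel_ids))
        self.pulse_times_s = np.asarray(self.pulse_times_s, dtype=float)
        amp = np.asarray(self.pulse_amplitude_uA, dtype=float)
        if amp.ndim == 0:
            amp = np.full(len(self.pulse_times_s), float(amp))
        self.pulse_amplitude_uA = amp
        if len(self.pulse_amplitude_uA) != len(self.pulse_times_s):
            raise ValueError("one amplitude per pulse required")
        if np.any(np.diff(self.pulse_times_s) <= 0):
            raise ValueError("pulse times must be strictly increasing")
        if np.any(self.pulse_amplitude_uA <= 0):
            raise ValueError("pulse amplitudes must be positive")
        if self.frequency_hz <= 0 or self.frequency_hz > 300:
            raise ValueError("pulse frequency must be in (0, 300] Hz")

    @property
    def n_pulses(self) -> int:
        return len(self.pulse_times_s)

    @property
    def inter_pulse_interval_s(self) -> float:
        return 1.0 / self.frequency_hz

    @property
    def start_s(self) -> float:
        return float(self.pulse_times_s[0])

    @property
    def end_s(self) -> float:
        """End of the bout: last pulse plus one inter-pulse interval."""
        return float(self.pulse_times_s[-1]) + self.inter_pulse_interval_s

    def net_charge_nC(self) -> np.ndarray:
        """Per-pulse net charge; exactly zero for the balanced asymmetric shape."""
        cath = self.cathodal_us * self.pulse_amplitude_uA
        anod = self.anodal_us * (self.anodal_fraction * self.pulse_amplitude_uA)
        return (anod - cath) * 1e-3  # uA*us -> nC

    def cathodal_charge_nC(self) -> float:
        """Total cathodal-phase charge delivered over the bout."""
        return float(np.sum(self.cathodal_us * self.pulse_amplitude_uA) * 1e-3)

    @classmethod
    def regular(
        cls,
        stim_channel_ids,
        start_s: float,
        duration_s: float,
        frequency_hz: float,
        amplitude_uA: float,
    ) -> "StimTrain":
        n = int(round(duration_s * frequency_hz))
        times = quantize_time(start_s + np.arange(n) / frequency_hz)
        return cls(stim_channel_ids, times, np.full(n, float(amplitude_uA)), frequency_hz)


def merge_windows(windows: np.ndarray) -> np.ndarray:
    """Merge overlapping/adjacent half-open intervals into a disjoint sorted set."""
    windows = np.asarray(windows, dtype=float).reshape(-1, 2)
    if len(windows) == 0:
        return windows
    order = np.argsort(windows[:, 0])
    windows = windows[order]
    merged = [windows[0].copy()]
    for start, end in windows[1:]:
        if start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append(np.array([start, end]))
    return np.array(merged)


@dataclass
class BlankSchedule:
    """Post-pulse recording-suppression windows.

    Hardware blanking is the 1.6-ms sample-and-hold after every pulse; the
    analysis additionally discards the first 2 ms after each pulse to avoid
    residual artifact.  Windows are half-open and stored merged.
    """

    windows: np.ndarray
    hardware_blank_ms: float = HARDWARE_BLANK_MS
    analysis_blank_ms: float = ANALYSIS_BLANK_MS

    def __post_init__(self) -> None:
        self.windows = merge_windows(self.windows)

    @classmethod
    def from_pulses(cls, pulse_times_s: np.ndarray, blank_ms: float) -> "BlankSchedule":
        t = np.asarray(pulse_times_s, dtype=float)
        return cls(np.column_stack([t, t + blank_ms * 1e-3]))

    def contains(self, times: np.ndarray) -> np.ndarray:
        """Boolean mask: which times fall inside a blank window."""
        times = np.asarray(times, dtype=float)
        if len(self.windows) == 0:
            return np.zeros(times.shape, dtype=bool)
        idx = np.searchsorted(self.windows[:, 0], times, side="right") - 1
        inside = idx >= 0
        inside[inside] = times[inside] < self.windows[idx[inside], 1]
        return inside

    def total_blanked_s(self, span: tuple[float, float] | None = None) -> float:
        w = self.windows
        if span is not None:
            w = np.clip(w, span[0], span[1])
        if len(w) == 0:
            return 0.0
        return float(np.sum(np.maximum(w[:, 1] - w[:, 0], 0.0)))


@dataclass
class BinnedRates:
    """Firing-rate matrix, channels x bins, in Hz; bins are half-open."""

    rates_hz: np.ndarray
    channel_ids: np.ndarray
    bin_width_ms: float
    start_s: float

    @property
    def n_bins(self) -> int:
        return self.rates_hz.shape[1]

    @property
    def bin_edges_s(self) -> np.ndarray:
        w = self.bin_width_ms * 1e-3
        return self.start_s + np.arange(self.n_bins + 1) * w

    @property
    def bin_centers_s(self) -> np.ndarray:
        e = self.bin_edges_s
        return 0.5 * (e[:-1] + e[1:])


class SchemaError(ValueError):
    """A required column or header field is missing or malformed."""


def bin_spikes(
    spikes: SpikeTable,
    span: tuple[float, float],
    bin_width_ms: float = DEFAULT_BIN_MS,
    channel_ids: np.ndarray | None = None,
) -> BinnedRates:
    """Bin spikes into fixed-width bins and convert counts to Hz.

    The last partial bin is dropped.  A spike exactly on a bin edge belongs
    to the later bin.  Channels requested but absent from ``spikes`` yield a
    zero row with a warning.
    """
    start, end = float(span[0]), float(span[1])
    if end <= start:
        raise ValueError("empty span")
    if bin_width_ms <= 0:
        raise ValueError("bin width must be positive")
    width = bin_width_ms * 1e-3
    n_bins = int(np.floor((end - start) / width + 1e-9))
    if n_bins == 0:
        raise ValueError("span shorter than one bin")
    if channel_ids is None:
        channel_ids = spikes.channels
    channel_ids = np.asarray(channel_ids, dtype=np.int64)
    present = set(spikes.channels.tolist())
    missing = [c for c in channel_ids.tolist() if c not in present]
    if missing:
        warnings.warn(f"channels absent from spike table, zero rows emitted: {missing}")
    counts = np.zeros((len(channel_ids), n_bins), dtype=float)
    edges = start + np.arange(n_bins + 1) * width
    for i, ch in enumerate(channel_ids):
        t = spikes.times_for(int(ch))
        t = t[(t >= start) & (t < edges[-1])]
        if len(t):
            counts[i] = np.histogram(t, bins=edges)[0]
    return BinnedRates(counts / width, channel_ids, bin_width_ms, start)


def apply_blanking(spikes: SpikeTable, schedule: BlankSchedule) -> SpikeTable:
    """Drop every event that falls inside a scheduled blank window (idempotent)."""
    inside = schedule.contains(spikes.time_s)
    n_removed = int(inside.sum())
    if n_removed:
        warnings.warn(f"blanking removed {n_removed} events", stacklevel=2)
    return spikes.select(~inside)


# ---------------------------------------------------------------------------
# Event-table I/O: delimited text with a JSON sidecar header.
# ---------------------------------------------------------------------------

def _canonical_trials(trials: pd.DataFrame) -> pd.DataFrame:
    df = trials.copy()
    for col in TRIAL_COLUMNS:
        if col not in df.columns:
            if col in ("trial_id", "condition", "phase", "phase_start_s", "phase_end_s"):
                raise SchemaError(f"trial table missing required column '{col}'")
            df[col] = np.nan
    df = df[TRIAL_COLUMNS]
    return df.sort_values(["trial_id", "phase_start_s"], kind="stable").reset_index(drop=True)


def write_event_tables(
    out_dir: str | Path,
    spikes: SpikeTable,
    trains: list[StimTrain],
    trials: pd.DataFrame,
    arraymap: pd.DataFrame,
    metadata: dict | None = None,
) -> Path:
    """Write a session as TSV tables plus a JSON sidecar header.

    Layout: ``spikes.tsv``, ``pulses.tsv`` (one row per pulse, train-indexed),
    ``trials.tsv``, ``arraymap.tsv``, ``header.json``.  The canonical form is
    sorted and fixed-precision, so write-then-read round-trips losslessly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    spikes.to_frame().to_csv(out_dir / "spikes.tsv", sep="\t", index=False, float_format="%.9f")

    pulse_rows = []
    for k, tr in enumerate(trains):
        pulse_rows.append(
            pd.DataFrame(
                {
                    "train_id": k,
                    "stim_channel_ids": ",".join(str(c) for c in tr.stim_channel_ids),
                    "pulse_time_s": tr.pulse_times_s,
                    "pulse_amplitude_uA": tr.pulse_amplitude_uA,
                    "frequency_hz": tr.frequency_hz,
                }
            )
        )
    pulses = (
        pd.concat(pulse_rows, ignore_index=True)
        if pulse_rows
        else pd.DataFrame(
            columns=["train_id", "stim_channel_ids", "pulse_time_s", "pulse_amplitude_uA", "frequency_hz"]
        )
    )
    pulses.to_csv(out_dir / "pulses.tsv", sep="\t", index=False, float_format="%.9f")

    _canonical_trials(trials).to_csv(out_dir / "trials.tsv", sep="\t", index=False, float_format="%.9f")

    am = arraymap.copy()
    for col in ARRAYMAP_COLUMNS:
        if col not in am.columns:
            raise SchemaError(f"array map missing required column '{col}'")
    am[ARRAYMAP_COLUMNS].to_csv(out_dir / "arraymap.tsv", sep="\t", index=False)

    header = {
        "schema_version": SCHEMA_VERSION,
        "units": {"time": "s", "amplitude": "uA", "rate": "Hz"},
        "clock_hz": CLOCK_HZ,
        "n_spikes": int(len(spikes)),
        "n_trains": len(trains),
    }
    if metadata:
        header["metadata"] = metadata
    (out_dir / "header.json").write_text(json.dumps(header, indent=2, sort_keys=True))
    return out_dir


def read_event_tables(in_dir: str | Path):
    """Read a session written by :func:`write_event_tables`.

    Returns ``(spikes, trains, trials, arraymap, header)``.  Unsorted spike
    times are auto-sorted with a warning; a missing required column raises
    :class:`SchemaError` naming the column.
    """
    in_dir = Path(in_dir)
    header = json.loads((in_dir / "header.json").read_text())
    if header.get("schema_version") != SCHEMA_VERSION:
        raise SchemaError(
            f"schema version mismatch: {header.get('schema_version')!r} != {SCHEMA_VERSION!r}"
        )

    sdf = pd.read_csv(in_dir / "spikes.tsv", sep="\t")
    for col in ("channel_id", "unit_id", "time_s"):
        if col not in sdf.columns:
            raise SchemaError(f"spike table missing required column '{col}'")
    if len(sdf) and not sdf.groupby("channel_id")["time_s"].apply(
        lambda s: bool(np.all(np.diff(s.to_numpy()) >= 0))
    ).all():
        warnings.warn("spike times unsorted within channel; auto-sorting")
    spikes = SpikeTable.from_frame(sdf)

    pdf = pd.read_csv(
        in_dir / "pulses.tsv", sep="\t", dtype={"stim_channel_ids": str}
    )
    trains = []
    if len(pdf):
        for _, grp in pdf.groupby("train_id", sort=True):
            chans = tuple(int(c) for c in str(grp["stim_channel_ids"].iloc[0]).split(","))
            trains.append(
                StimTrain(
                    chans,
                    grp["pulse_time_s"].to_numpy(),
                    grp["pulse_amplitude_uA"].to_numpy(),
                    float(grp["frequency_hz"].iloc[0]),
                )
            )

    trials = pd.read_csv(in_dir / "trials.tsv", sep="\t")
    trials = _canonical_trials(trials)
    arraymap = pd.read_csv(in_dir / "arraymap.tsv", sep="\t")
    for col in ARRAYMAP_COLUMNS:
        if col not in arraymap.columns:
            raise SchemaError(f"array map missing required column '{col}'")
    return spikes, trains, trials, arraymap, header
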