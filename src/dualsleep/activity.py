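"""The neural-activity statistic: z-score, binarize, rolling-sum call, events, overlap.

A neuron's raw trace is z-scored against its whole-experiment mean and SD,
binarized at >3 SD, and called *active* when any window of 10 consecutive
frames contains at least 7 supra-threshold frames. Firing events are
counted as strict local maxima of the z-scored trace above 3 SD with a
minimum separation of 30 frames (tallest-peak-wins suppression). Active
sets from different epochs are compared as percentage overlaps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from dualsleep.containers import TraceMatrix

THRESHOLD_SD = 3.0
WINDOW = 10
MIN_COUNT = 7
MIN_PEAK_HEIGHT = 3.0
MIN_PEAK_DISTANCE = 30


@dataclass
class ZScoreMatrix:
    """n x t matrix of traces in units of SD about each neuron's mean."""

    values: np.ndarray
    degenerate: np.ndarray  # rows with zero variance (set to all-zero)
    neuron_ids: np.ndarray = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.degenerate = np.asarray(self.degenerate, dtype=bool)
        if self.neuron_ids is None:
            self.neuron_ids = np.arange(self.values.shape[0])


@dataclass
class BinaryActivityMatrix:
    """n x t matrix in {0, 1}: 1 marks frames above the z threshold."""

    values: np.ndarray
    threshold_sd: float = THRESHOLD_SD
    neuron_ids: np.ndarray = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.uint8)
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("binary matrix must contain only 0/1")
        if self.neuron_ids is None:
            self.neuron_ids = np.arange(self.values.shape[0])


@dataclass
class ActivityCall:
    neuron_id: int
    is_active: bool
    window: int = WINDOW
    min_count: int = MIN_COUNT

    def __post_init__(self):
        if self.min_count > self.window:
            raise ValueError("min_count must be <= window")


@dataclass
class EpochDefinition:
    """A half-open frame interval [start_frame, end_frame) with a name."""

    name: str
    start_frame: int
    end_frame: int

    def __post_init__(self):
        if self.end_frame <= self.start_frame:
            raise ValueError("epoch must have positive length")

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame


def zscore(traces: TraceMatrix | np.ndarray) -> ZScoreMatrix:
    """Z-score each neuron's trace against its whole-experiment mean and SD.

    Rows with zero variance cannot be scaled; they are set to all-zero and
    flagged degenerate rather than raising.
    """
    if isinstance(traces, TraceMatrix):
        values, ids = traces.values, traces.neuron_ids
    else:
        values, ids = np.asarray(traces, dtype=float), None
    if values.ndim != 2 or values.shape[1] < 2:
        raise ValueError("need an (n, t) matrix with t >= 2")
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=0, keepdims=True)
    degenerate = sd[:, 0] == 0
    sd[degenerate] = 1.0
    z = (values - mean) / sd
    z[degenerate] = 0.0
    return ZScoreMatrix(values=z, degenerate=degenerate, neuron_ids=ids)


def binarize(z: ZScoreMatrix | np.ndarray, threshold_sd: float = THRESHOLD_SD) -> BinaryActivityMatrix:
    """1 where z strictly exceeds ``threshold_sd``, else 0.

    A value exactly at the threshold maps to 0 (the supra-threshold rule is
    strict; see the boundary unit tests).
    """
    values = z.values if isinstance(z, ZScoreMatrix) else np.asarray(z, dtype=float)
    ids = z.neuron_ids if isinstance(z, ZScoreMatrix) else None
    return BinaryActivityMatrix(
        values=(values > threshold_sd).astype(np.uint8),
        threshold_sd=threshold_sd,
        neuron_ids=ids,
    )


def rolling_window_sums(row: np.ndarray, window: int) -> np.ndarray:
    """Sums of every length-``window`` run of consecutive frames (stride 1)."""
    c = np.concatenate([[0], np.cumsum(row)])
    return c[window:] - c[:-window]


def classify_active(
    b: BinaryActivityMatrix | np.ndarray,
    window: int = WINDOW,
    min_count: int = MIN_COUNT,
) -> list[ActivityCall]:
    """Call each neuron active iff some ``window``-frame run holds >= ``min_count`` ones.

    The window slides by one frame. With the defaults (10, 7) a neuron is
    active when its z-trace exceeds threshold in at least 7 of 10
    consecutive frames somewhere in the recording.
    """
    if isinstance(b, BinaryActivityMatrix):
        values, ids = b.values, b.neuron_ids
    else:
        values = np.asarray(b)
        ids = np.arange(values.shape[0])
    if min_count > window:
        raise ValueError("min_count must be <= window")
    if values.shape[1] < window:
        raise ValueError(f"need at least {window} frames")
    calls = []
    for i in range(values.shape[0]):
        active = bool(rolling_window_sums(values[i], window).max() >= min_count)
        calls.append(ActivityCall(int(ids[i]), active, window, min_count))
    return calls


def percent_active(calls: list[ActivityCall] | np.ndarray, groups: np.ndarray | None = None):
    """Percentage of neurons called active: 100 * active / total.

    With ``groups`` (e.g. the slice index per neuron) a dict of group →
    percentage is returned, matching the per-slice convention; otherwise a
    single pooled percentage.
    """
    if isinstance(calls, list) and calls and isinstance(calls[0], ActivityCall):
        flags = np.array([c.is_active for c in calls], dtype=bool)
    else:
        flags = np.asarray(calls, dtype=bool)
    if flags.size == 0:
        raise ValueError("percent_active requires at least one neuron")
    if groups is None:
        return 100.0 * flags.mean()
    groups = np.asarray(groups)
    return {g: 100.0 * flags[groups == g].mean() for g in np.unique(groups)}


def _find_peaks_row(row: np.ndarray, min_height: float, min_separation: int) -> np.ndarray:
    """Strict local maxima above min_height, tallest-first suppression.

    Peaks strictly closer than ``min_separation`` frames to an already-kept
    (taller, or equally tall but earlier) peak are dropped — the semantics
    of MATLAB ``findpeaks`` with 'minpeakheight'/'minpeakdistance'.
    """
    interior = np.arange(1, len(row) - 1)
    is_peak = (row[1:-1] > row[:-2]) & (row[1:-1] > row[2:]) & (row[1:-1] > min_height)
    idx = interior[is_peak]
    if idx.size == 0:
        return idx
    order = idx[np.lexsort((idx, -row[idx]))]
    kept: list[int] = []
    for i in order:
        if all(abs(i - j) >= min_separation for j in kept):
            kept.append(int(i))
    return np.array(sorted(kept), dtype=int)


def count_events(
    z: ZScoreMatrix | np.ndarray,
    min_height: float = MIN_PEAK_HEIGHT,
    min_separation: int = MIN_PEAK_DISTANCE,
) -> np.ndarray:
    """Number of firing events per neuron from the z-scored traces."""
    values = z.values if isinstance(z, ZScoreMatrix) else np.asarray(z, dtype=float)
    return np.array([len(_find_peaks_row(r, min_height, min_separation)) for r in values])


def epoch_overlap(
    active_a: set,
    active_b: set,
    denominator: str = "a",
) -> tuple[float, set]:
    """Percentage overlap of two active-neuron id sets.

    ``100 * |a ∩ b| / |denominator set|`` where the denominator is set
    ``a`` (default), ``b`` or their union. Following the convention used to
    ask what fraction of sleep-active neurons were also wake-active, pass
    the sleep-epoch set as ``active_a``. An empty denominator yields NaN.
    """
    a, b = set(active_a), set(active_b)
    inter = a & b
    denom = {"a": a, "b": b, "union": a | b}.get(denominator)
    if denom is None:
        raise ValueError("denominator must be 'a', 'b' or 'union'")
    if not denom:
        return float("nan"), inter
    return 100.0 * len(inter) / len(denom), inter


def define_epochs(
    movement: np.ndarray,
    fs: float,
    onset_quiescence_s: float = 30.0,
    epoch_min: float = 5.0,
    baseline_end_frame: int | None = None,
) -> list[EpochDefinition]:
    """Epoch a recording around sleep onset from a per-frame movement trace.

    Sleep onset is the start of the first run of behavioral inactivity
    (movement == 0) lasting at least ``onset_quiescence_s`` seconds. The
    ``epoch_min``-minute window following that initial quiescence is the
    'early' sleep epoch; the next ``epoch_min`` minutes are 'mid' sleep.
    If ``baseline_end_frame`` is given, [0, baseline_end_frame) is emitted
    as the 'wake' baseline epoch. Epochs are clipped to the trace; if no
    qualifying quiescence run exists, no sleep epochs are returned.
    """
    movement = np.asarray(movement)
    T = len(movement)
    epochs: list[EpochDefinition] = []
    if baseline_end_frame is not None and baseline_end_frame > 0:
        epochs.append(EpochDefinition("wake", 0, min(int(baseline_end_frame), T)))

    need = int(round(onset_quiescence_s * fs))
    inactive = movement == 0
    onset = None
    run = 0
    for t in range(T):
        run = run + 1 if inactive[t] else 0
        if run >= need:
            onset = t - need + 1
            break
    if onset is None:
        return epochs

    ep_frames = int(round(epoch_min * 60 * fs))
    start = onset + need
    for name in ("early", "mid"):
        end = min(start + ep_frames, T)
        if end > start:
            epochs.append(EpochDefinition(name, start, end))
        start = end
    return epochs
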