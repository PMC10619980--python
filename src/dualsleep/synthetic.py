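"""Synthetic-data generators with known ground truth.

Every input the pipeline consumes can be generated here: GCaMP-like ROI
traces (sparse transients convolved with an exponential decay kernel plus
Gaussian noise), small single-slice movies with Gaussian-blob ROIs and
planted rigid sub-pixel shifts, two-state (wake/sleep) semi-Markov
per-minute behavior logs under a 12:12 light schedule, Bernoulli air-puff
response tables, and differential-expression tables with a planted set of
true positives.

All generators are driven by one integer seed through a hierarchical
``numpy.random.SeedSequence``: each simulated object (neuron, fly, gene
block) gets its own child stream, so enlarging a simulation does not perturb
the objects already drawn.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from dualsleep.containers import MovieStack, ROILabels, TraceMatrix

MINUTES_PER_DAY = 1440
DAY_MINUTES = 720  # lights on 08:00-20:00; logs start at lights-on


@dataclass
class SimConfig:
    """Parameters of the synthetic recordings.

    Defaults describe a plausible two-photon soma recording with a slow
    nuclear-localized indicator: ~11.6 min at 4.3 volumes/s, sparse
    transients (0.5 events/min) with a 2.5 s decay constant, peak amplitude
    8 noise-SD units over unit Gaussian noise — slow enough that a real
    transient spans several volumes, as nuclear GCaMP transients do.
    Behavioral defaults give flies that sleep more at night (mean night
    sleep bout 25 min vs 12 min by day) and are active 2.69 counts per
    waking minute.
    """

    seed: int = 0
    T: int = 3000                  # frames per trace
    fs: float = 4.3                # frames (volumes) per second, per slice
    n_active: int = 20
    n_silent: int = 20
    event_rate: float = 0.5        # transients per minute, active neurons
    kernel_tau: float = 2.5        # s, exponential decay constant (slow nuclear indicator)
    amplitude: float = 8.0         # a.u., transient peak height
    noise_sd: float = 1.0          # a.u., i.i.d. Gaussian noise
    # mean (sleep_bout_min, wake_bout_min) per phase
    day_bout_params: tuple[float, float] = (12.0, 24.0)
    night_bout_params: tuple[float, float] = (25.0, 10.0)
    wake_activity_mean: float = 2.69  # counts per waking minute

    def __post_init__(self):
        if self.T <= 0 or self.fs <= 0:
            raise ValueError("T and fs must be positive")
        if self.n_active < 0 or self.n_silent < 0:
            raise ValueError("neuron counts must be non-negative")
        if self.event_rate <= 0 or self.kernel_tau <= 0 or self.amplitude <= 0:
            raise ValueError("event_rate, kernel_tau and amplitude must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for pair in (self.day_bout_params, self.night_bout_params):
            if min(pair) <= 0:
                raise ValueError("bout duration means must be positive")
        if self.wake_activity_mean < 1:
            raise ValueError("wake_activity_mean must be >= 1 (wake minutes have counts >= 1)")


@dataclass
class TraceTruth:
    """Ground truth for one simulated neuron."""

    neuron_id: int
    is_active: bool
    event_times: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self):
        self.event_times = np.asarray(self.event_times, dtype=int)
        if not self.is_active and self.event_times.size:
            raise ValueError("silent neurons must have no events")
        if self.event_times.size and np.any(np.diff(self.event_times) <= 0):
            raise ValueError("event_times must be strictly increasing")


@dataclass
class BehaviorTruth:
    """Ground truth for one simulated fly's sleep/wake sequence.

    ``true_bouts`` are maximal same-state runs split at light transitions,
    so they tile the minute sequence exactly and match what run-length bout
    detection should recover.
    """

    state_sequence: np.ndarray          # per-minute 'wake'/'sleep'
    true_bouts: list[tuple[int, int, str]]  # (start_min, duration_min, state)

    def __post_init__(self):
        total = sum(d for _, d, _ in self.true_bouts)
        if total != len(self.state_sequence):
            raise ValueError("bouts must tile the state sequence")
        if any(d < 1 for _, d, _ in self.true_bouts):
            raise ValueError("bout durations must be >= 1 min")


def exponential_kernel(tau_s: float, fs: float, cutoff: float = 1e-4) -> np.ndarray:
    """Instantaneous-rise, exponential-decay calcium kernel, peak = 1.

    Truncated where the decay falls below ``cutoff`` of the peak.
    """
    n = max(2, int(np.ceil(-np.log(cutoff) * tau_s * fs)))
    return np.exp(-np.arange(n) / (tau_s * fs))


def _events_to_trace(T: int, events: np.ndarray, kernel: np.ndarray, amplitude: float) -> np.ndarray:
    delta = np.zeros(T)
    delta[events] = amplitude
    return np.convolve(delta, kernel)[:T]


def make_traces(cfg: SimConfig) -> tuple[TraceMatrix, list[TraceTruth]]:
    """Simulate GCaMP-like fluorescence traces with planted transients.

    Active neurons carry a Poisson number of transients (rate
    ``cfg.event_rate`` per minute) at uniformly drawn frames, convolved with
    an exponential kernel of decay constant ``cfg.kernel_tau`` seconds and
    scaled to peak ``cfg.amplitude``; i.i.d. Gaussian noise of SD
    ``cfg.noise_sd`` is added. Silent neurons are noise only.

    Returns the trace matrix (active rows first) and per-neuron truth.
    """
    kernel = exponential_kernel(cfg.kernel_tau, cfg.fs)
    n_total = cfg.n_active + cfg.n_silent
    streams = np.random.SeedSequence(cfg.seed).spawn(n_total)
    duration_min = cfg.T / cfg.fs / 60.0

    values = np.empty((n_total, cfg.T))
    truths: list[TraceTruth] = []
    for i in range(n_total):
        rng = np.random.default_rng(streams[i])
        active = i < cfg.n_active
        if active:
            n_events = rng.poisson(cfg.event_rate * duration_min)
            n_events = min(n_events, cfg.T)
            events = np.sort(rng.choice(cfg.T, size=n_events, replace=False))
            trace = _events_to_trace(cfg.T, events, kernel, cfg.amplitude)
        else:
            events = np.array([], dtype=int)
            trace = np.zeros(cfg.T)
        if cfg.noise_sd > 0:
            trace = trace + rng.normal(0.0, cfg.noise_sd, cfg.T)
        values[i] = trace
        truths.append(TraceTruth(neuron_id=i, is_active=active, event_times=events))

    return TraceMatrix(values=values, fs=cfg.fs), truths


def _blob(shape: tuple[int, int], center: tuple[float, float], sigma: float) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return np.exp(-(((yy - center[0]) ** 2) + (xx - center[1]) ** 2) / (2 * sigma**2))


def default_roi_centers(frame_shape: tuple[int, int], n_rois: int, blob_sigma: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Place ROI centers on a jittered grid with >= 4*sigma spacing."""
    spacing = 4.0 * blob_sigma
    margin = 3.0 * blob_sigma
    ys = np.arange(margin, frame_shape[0] - margin, spacing)
    xs = np.arange(margin, frame_shape[1] - margin, spacing)
    grid = np.array([(y, x) for y in ys for x in xs])
    if len(grid) < n_rois:
        raise ValueError(f"frame too small for {n_rois} ROIs at sigma={blob_sigma}")
    chosen = grid[rng.choice(len(grid), size=n_rois, replace=False)]
    jitter = rng.uniform(-0.5, 0.5, size=chosen.shape)
    return chosen + jitter


def make_movie(
    cfg: SimConfig,
    frame_shape: tuple[int, int] = (96, 96),
    n_rois: int = 8,
    shifts: np.ndarray | None = None,
    blob_sigma: float = 2.5,
    baseline: float = 1.0,
) -> tuple[np.ndarray, ROILabels, np.ndarray, list[TraceTruth]]:
    """Simulate a single-slice movie of Gaussian-blob ROIs with rigid shifts.

    Each ROI is a Gaussian blob whose brightness follows its simulated trace
    on top of a constant baseline; every frame is then rigidly translated by
    its (dy, dx) shift, applied in the Fourier domain so sub-pixel truths
    are exact.

    Parameters
    ----------
    shifts : ndarray, shape (T, 2), optional
        Planted per-frame (dy, dx) shifts; zeros if omitted. Shifts larger
        than a quarter of the frame are refused (registration could not be
        expected to recover them).

    Returns
    -------
    movie : ndarray (t, y, x)
    labels : ROILabels — planted ROI footprints (blob above 10% of peak)
    shifts : ndarray (t, 2) — the planted shifts, verbatim
    truths : list of TraceTruth
    """
    if shifts is None:
        shifts = np.zeros((cfg.T, 2))
    shifts = np.asarray(shifts, dtype=float)
    if shifts.shape != (cfg.T, 2):
        raise ValueError(f"shifts must have shape ({cfg.T}, 2)")
    lim = min(frame_shape) / 4.0
    if np.any(np.abs(shifts) > lim):
        raise ValueError(f"shifts exceeding frame_shape/4 ({lim:g} px) are not supported")

    trace_cfg = SimConfig(**{**cfg.__dict__, "n_active": n_rois, "n_silent": 0})
    traces, truths = make_traces(trace_cfg)

    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 0xC0FFEE)))
    centers = default_roi_centers(frame_shape, n_rois, blob_sigma, rng)

    blobs = np.stack([_blob(frame_shape, tuple(c), blob_sigma) for c in centers])
    labels = np.zeros(frame_shape, dtype=np.int32)
    # later ROIs do not overwrite earlier ones (centers are well separated)
    for r in range(n_rois):
        mask = (blobs[r] > 0.1) & (labels == 0)
        labels[mask] = r + 1

    # brightness = baseline + trace (shifted up so blobs are never negative)
    offset = max(0.0, -traces.values.min())
    movie = baseline + np.einsum("rt,ryx->tyx", traces.values + offset, blobs)

    for t in range(cfg.T):
        if np.any(shifts[t]):
            movie[t] = np.real(np.fft.ifft2(ndimage.fourier_shift(np.fft.fft2(movie[t]), shifts[t])))

    return movie, ROILabels(labels=labels), shifts, truths


def _draw_bout(rng: np.random.Generator, mean_min: float) -> int:
    """Integer bout duration >= 1 min, geometric with the given mean."""
    p = 1.0 / max(mean_min, 1.0)
    return int(rng.geometric(p))


def make_behavior_log(
    cfg: SimConfig,
    n_days: int = 3,
    fly_id: int = 0,
    sleep_probability: float | None = None,
) -> tuple[pd.DataFrame, BehaviorTruth]:
    """Simulate a per-minute activity log for one fly under a 12:12 schedule.

    Minute 0 is lights-on (08:00). The fly alternates wake and sleep bouts
    whose integer durations are geometric with phase-specific means
    (``cfg.day_bout_params`` / ``cfg.night_bout_params`` = (mean sleep,
    mean wake) in minutes). Wake minutes get activity counts
    ``1 + Poisson(wake_activity_mean - 1)``; sleep minutes get 0.

    ``sleep_probability=0`` forces a fully awake fly (one wake bout per
    phase in the truth).

    Returns
    -------
    log : DataFrame with columns fly_id, minute_index, activity, phase
    truth : BehaviorTruth
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, fly_id, 0xBEE)))
    n_min = n_days * MINUTES_PER_DAY

    states = np.empty(n_min, dtype=object)
    if sleep_probability == 0:
        states[:] = "wake"
    else:
        t = 0
        state = "wake"
        while t < n_min:
            day = (t % MINUTES_PER_DAY) < DAY_MINUTES
            mean_sleep, mean_wake = cfg.day_bout_params if day else cfg.night_bout_params
            dur = _draw_bout(rng, mean_sleep if state == "sleep" else mean_wake)
            states[t : t + dur] = state
            t += dur
            state = "sleep" if state == "wake" else "wake"

    phase = np.where((np.arange(n_min) % MINUTES_PER_DAY) < DAY_MINUTES, "day", "night")
    activity = np.zeros(n_min, dtype=int)
    wake_mask = states == "wake"
    activity[wake_mask] = 1 + rng.poisson(cfg.wake_activity_mean - 1.0, int(wake_mask.sum()))

    # truth bouts: maximal same-state runs, split at light transitions
    bouts: list[tuple[int, int, str]] = []
    start = 0
    for m in range(1, n_min + 1):
        boundary = m == n_min or states[m] != states[m - 1] or phase[m] != phase[m - 1]
        if boundary:
            bouts.append((start, m - start, str(states[start])))
            start = m
    truth = BehaviorTruth(state_sequence=states, true_bouts=bouts)

    log = pd.DataFrame(
        {
            "fly_id": fly_id,
            "minute_index": np.arange(n_min),
            "activity": activity,
            "phase": phase,
        }
    )
    return log, truth


def make_responses(
    p_wake: float,
    p_sleep: float,
    schedule: np.ndarray,
    state_sequence: np.ndarray,
    seed: int = 0,
    fly_id: int = 0,
) -> pd.DataFrame:
    """Simulate binary air-puff responses with state-dependent probability.

    ``schedule`` holds stimulus times as minute indices into
    ``state_sequence``; at each stimulus the fly responds (1) with
    probability ``p_wake`` if awake and ``p_sleep`` if asleep.
    """
    for p in (p_wake, p_sleep):
        if not 0.0 <= p <= 1.0:
            raise ValueError("probabilities must be in [0, 1]")
    schedule = np.asarray(schedule, dtype=int)
    state_sequence = np.asarray(state_sequence)
    if schedule.size and (schedule.min() < 0 or schedule.max() >= len(state_sequence)):
        raise ValueError("stimulus times outside the state sequence")

    rng = np.random.default_rng(np.random.SeedSequence((seed, fly_id, 0xA1B)))
    states = state_sequence[schedule]
    p = np.where(states == "wake", p_wake, p_sleep)
    responses = (rng.random(len(schedule)) < p).astype(int)
    return pd.DataFrame(
        {
            "fly_id": fly_id,
            "stimulus_index": np.arange(len(schedule)),
            "time_min": schedule,
            "state": states,
            "response": responses,
        }
    )


def make_de_table(
    n_genes: int = 1000,
    n_true: int = 50,
    logfc_effect_sd: float = 0.5,
    seed: int = 0,
    base_effect: float = 1.0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Simulate a differential-expression result table with planted positives.

    True DE genes get ``|log2fc| = base_effect + |N(0, logfc_effect_sd)|``
    (random sign) and FDR ~ U(0, 0.01); null genes get log2fc ~ N(0, 0.1)
    and FDR ~ U(0, 1). True genes are well expressed in both groups; a
    fraction of nulls is lowly expressed so the CPM filter has work to do.

    Returns the table (gene_id, log2fc, fdr, mean_cpm_group1,
    mean_cpm_group2) and a boolean truth flag per gene.
    """
    if n_true > n_genes:
        raise ValueError("n_true must be <= n_genes")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xDE)))
    is_true = np.zeros(n_genes, dtype=bool)
    is_true[rng.choice(n_genes, size=n_true, replace=False)] = True

    log2fc = rng.normal(0.0, 0.1, n_genes)
    sign = rng.choice([-1.0, 1.0], n_genes)
    effect = base_effect + np.abs(rng.normal(0.0, logfc_effect_sd, n_genes))
    log2fc[is_true] = (sign * effect)[is_true]

    fdr = rng.uniform(0.0, 1.0, n_genes)
    fdr[is_true] = rng.uniform(0.0, 0.01, int(is_true.sum()))

    cpm1 = rng.lognormal(np.log(20.0), 1.0, n_genes)
    cpm2 = cpm1 * rng.lognormal(0.0, 0.2, n_genes)
    well_expressed = 10.0 + rng.lognormal(np.log(40.0), 0.5, (int(is_true.sum()), 2))
    cpm1[is_true], cpm2[is_true] = well_expressed[:, 0], well_expressed[:, 1]

    table = pd.DataFrame(
        {
            "gene_id": [f"gene{i:05d}" for i in range(n_genes)],
            "log2fc": log2fc,
            "fdr": fdr,
            "mean_cpm_group1": cpm1,
            "mean_cpm_group2": cpm2,
        }
    )
    return table, is_true
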