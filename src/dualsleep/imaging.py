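"""Volumetric movie preprocessing: registration, slice timing, segmentation, traces.

The preprocessing chain mirrors standard two-photon soma imaging practice:
rigid sub-pixel registration by upsampled cross-correlation, per-slice
acquisition-timing correction by band-limited (sinc) temporal interpolation
against a reference z-slice, a temporal standard-deviation projection to
localize active somata, marker-based watershed segmentation of that
projection, and per-ROI mean-fluorescence trace extraction.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage
from skimage.filters import gaussian, threshold_otsu
from skimage.feature import peak_local_max
from skimage.registration import phase_cross_correlation
from skimage.segmentation import watershed

from dualsleep.containers import MovieStack, ROILabels, TraceMatrix

DEFAULT_REFERENCE_SLICE = 8  # 0-based: the ninth z-slice


def translate(image: np.ndarray, shift: tuple[float, float]) -> np.ndarray:
    """Rigidly translate a 2-D image by (dy, dx) in the Fourier domain."""
    return np.real(np.fft.ifft2(ndimage.fourier_shift(np.fft.fft2(image), shift)))


def register_frames(
    frames: np.ndarray,
    upsample: int = 10,
    reference: str = "first",
) -> tuple[np.ndarray, np.ndarray]:
    """Rigid sub-pixel registration of a 2-D time series by cross-correlation.

    Each frame's displacement relative to the reference image is estimated
    by upsampled cross-correlation to 1/``upsample`` pixel precision and
    undone by Fourier translation.

    Parameters
    ----------
    frames : ndarray (t, y, x)
    upsample : int >= 1
        Sub-pixel precision factor.
    reference : {'first', 'mean'}
        Reference image: the first frame (default) or the temporal mean.

    Returns
    -------
    registered : ndarray (t, y, x)
    shifts : ndarray (t, 2)
        Estimated (dy, dx) displacement of each input frame relative to the
        reference; translating registered frame t by ``shifts[t]``
        reproduces the input frame (up to interpolation error).
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise ValueError("need a (t, y, x) stack with at least 2 frames")
    if upsample < 1:
        raise ValueError("upsample must be >= 1")
    if reference == "first":
        ref = frames[0]
    elif reference == "mean":
        ref = frames.mean(axis=0)
    else:
        raise ValueError("reference must be 'first' or 'mean'")

    registered = np.empty_like(frames)
    shifts = np.zeros((frames.shape[0], 2))
    for t in range(frames.shape[0]):
        frame = frames[t]
        if np.ptp(frame) == 0:
            warnings.warn(f"frame {t} has zero variance; assuming zero shift")
            registered[t] = frame
            continue
        # phase_cross_correlation returns the shift that registers the
        # moving frame onto the reference, i.e. minus its displacement
        reg_shift, _, _ = phase_cross_correlation(
            ref, frame, upsample_factor=upsample, normalization=None
        )
        shifts[t] = -reg_shift
        registered[t] = translate(frame, reg_shift)
    return registered, shifts


def _sinc_shift(x: np.ndarray, delay: float, pad: int) -> np.ndarray:
    """Evaluate band-limited series x at sample coordinates k + delay.

    Truncated-sinc interpolation on a reflection-padded copy to suppress
    edge ringing. x has time on axis 0.
    """
    T = x.shape[0]
    pad = min(pad, T - 1)
    # interpolate the fluctuation about the temporal mean: the DC component
    # passes through exactly despite kernel truncation
    mu = x.mean(axis=0, keepdims=True)
    centered = x - mu
    padded = np.concatenate([centered[pad:0:-1], centered, centered[-2 : -2 - pad : -1]], axis=0)
    # padded index of original sample k is k + pad
    k = np.arange(T)[:, None]
    m = np.arange(T + 2 * pad)[None, :]
    S = np.sinc(k + pad + delay - m)
    flat = padded.reshape(padded.shape[0], -1)
    return (S @ flat).reshape(x.shape) + mu


def correct_slice_timing(
    stack: MovieStack,
    reference_slice: int = DEFAULT_REFERENCE_SLICE,
    pad: int = 64,
) -> MovieStack:
    """Align every z-slice's time series to the reference slice's time grid.

    Slices of a volume are acquired sequentially (slice 0 first, flyback
    frames at the end of the volume), so slice ``j`` lags the reference by
    ``(j - reference_slice) / (n_slices + n_flyback)`` volume periods. Each
    voxel's time series is resampled onto the reference grid by band-limited
    sinc interpolation; the reference slice is returned bit-unchanged.
    """
    if not 0 <= reference_slice < stack.n_slices:
        raise ValueError("reference_slice out of range")
    if stack.n_frames < 8:
        raise ValueError("need at least 8 time points for sinc interpolation")

    n_positions = stack.n_slices + stack.n_flyback
    out = np.empty_like(stack.data)
    for j in range(stack.n_slices):
        delay = (reference_slice - j) / n_positions
        if j == reference_slice:
            out[:, j] = stack.data[:, j]
        else:
            out[:, j] = _sinc_shift(stack.data[:, j], delay, pad)
    return MovieStack(
        data=out,
        fs_volume=stack.fs_volume,
        n_flyback=stack.n_flyback,
        z_step_um=stack.z_step_um,
        px_um=stack.px_um,
    )


def sd_projection(stack_slice: np.ndarray) -> np.ndarray:
    """Per-pixel temporal standard deviation (sample SD, divisor t-1)."""
    stack_slice = np.asarray(stack_slice, dtype=float)
    if stack_slice.ndim != 3 or stack_slice.shape[0] < 2:
        raise ValueError("need a (t, y, x) stack with at least 2 frames")
    return stack_slice.std(axis=0, ddof=1)


def segment_rois(
    sd_image: np.ndarray,
    smoothing_sigma: float = 1.0,
    min_area: int = 4,
    max_area: int = 10_000,
    min_peak_distance: int = 3,
) -> ROILabels:
    """Marker-based watershed segmentation of an SD projection.

    The image is Gaussian-smoothed, thresholded (Otsu), and local maxima of
    the smoothed image above the threshold seed a watershed on the inverted
    intensity. Regions outside ``[min_area, max_area]`` pixels are
    discarded and labels renumbered consecutively. A blank image yields
    zero ROIs.
    """
    sd_image = np.asarray(sd_image, dtype=float)
    if sd_image.ndim != 2:
        raise ValueError("sd_image must be 2-D")
    if np.any(sd_image < 0):
        raise ValueError("sd_image must be non-negative")

    empty = ROILabels(labels=np.zeros(sd_image.shape, dtype=np.int32))
    if np.ptp(sd_image) == 0:
        return empty
    smoothed = gaussian(sd_image, sigma=smoothing_sigma, preserve_range=True)
    if np.ptp(smoothed) == 0:
        return empty
    thresh = threshold_otsu(smoothed)
    mask = smoothed > thresh
    if not mask.any():
        return empty

    peaks = peak_local_max(smoothed, min_distance=min_peak_distance, labels=mask)
    if len(peaks) == 0:
        return empty
    markers = np.zeros(sd_image.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = watershed(-smoothed, markers=markers, mask=mask)

    out = np.zeros_like(labels)
    next_id = 1
    for rid in np.unique(labels):
        if rid == 0:
            continue
        area = int((labels == rid).sum())
        if min_area <= area <= max_area:
            out[labels == rid] = next_id
            next_id += 1
    return ROILabels(labels=out)


def extract_traces(stack_slice: np.ndarray, labels: ROILabels, fs: float = 1.0) -> TraceMatrix:
    """Mean fluorescence of every ROI's pixels per frame: an n x t array."""
    stack_slice = np.asarray(stack_slice, dtype=float)
    if stack_slice.ndim != 3:
        raise ValueError("stack_slice must be (t, y, x)")
    if stack_slice.shape[1:] != labels.labels.shape:
        raise ValueError("labels and frames must share spatial shape")

    rows, ids = [], []
    for rid in labels.roi_ids:
        mask = labels.labels == rid
        if not mask.any():
            warnings.warn(f"ROI {rid} has zero pixels; excluded")
            continue
        rows.append(stack_slice[:, mask].mean(axis=1))
        ids.append(int(rid))
    values = np.array(rows) if rows else np.empty((0, stack_slice.shape[0]))
    return TraceMatrix(
        values=values,
        fs=fs,
        neuron_ids=np.array(ids, dtype=int),
        slice_index=np.full(len(ids), labels.slice_index, dtype=int),
    )
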