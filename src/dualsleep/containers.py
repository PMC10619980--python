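"""Shared data containers for the imaging/activity pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class TraceMatrix:
    """Per-ROI fluorescence over time: an ``n_neurons x t`` array.

    Parameters
    ----------
    values : ndarray, shape (n_neurons, t)
        Raw fluorescence (a.u.), one row per neuron.
    fs : float
        Sampling rate of each row in frames per second (the per-slice
        volume rate for two-photon data).
    neuron_ids : ndarray of int
        Stable identifiers, one per row.
    slice_index : ndarray of int
        The z-slice each neuron was segmented on.
    """

    values: np.ndarray
    fs: float
    neuron_ids: np.ndarray = None
    slice_index: np.ndarray = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (n_neurons x t)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace values must be finite")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        n = self.values.shape[0]
        if self.neuron_ids is None:
            self.neuron_ids = np.arange(n)
        else:
            self.neuron_ids = np.asarray(self.neuron_ids)
        if self.slice_index is None:
            self.slice_index = np.zeros(n, dtype=int)
        else:
            self.slice_index = np.asarray(self.slice_index, dtype=int)
        if len(self.neuron_ids) != n or len(self.slice_index) != n:
            raise ValueError("neuron_ids / slice_index length mismatch")

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


@dataclass
class MovieStack:
    """A volumetric movie: ``t x z x y x x`` intensities plus acquisition geometry.

    ``n_flyback`` counts the placeholder frames acquired while the scanner
    returns to the top of the volume; they are not part of ``data`` but they
    do occupy acquisition time, so they enter the per-slice timing offsets.
    """

    data: np.ndarray
    fs_volume: float
    n_flyback: int = 2
    z_step_um: float = 6.0
    px_um: float = 667.0 / 256.0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("data must be 4-D (t, z, y, x)")
        if self.fs_volume <= 0:
            raise ValueError("fs_volume must be positive")
        if self.n_flyback < 0:
            raise ValueError("n_flyback must be >= 0")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_slices(self) -> int:
        return self.data.shape[1]

    @property
    def fs_slice(self) -> float:
        """Sampling rate of a single slice's time series (== volume rate)."""
        return self.fs_volume


@dataclass
class ROILabels:
    """Per-slice integer label image; 0 is background, ROIs are 1..n."""

    labels: np.ndarray
    slice_index: int = 0

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2-D image")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")

    @property
    def roi_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    @property
    def n_rois(self) -> int:
        return len(self.roi_ids)

    def centroids(self) -> dict[int, tuple[float, float]]:
        """(row, col) centroid of each ROI."""
        out = {}
        for rid in self.roi_ids:
            ys, xs = np.nonzero(self.labels == rid)
            out[int(rid)] = (float(ys.mean()), float(xs.mean()))
        return out
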