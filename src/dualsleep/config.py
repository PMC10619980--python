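"""Run configuration: every pipeline parameter with its default, YAML-loadable.

Defaults are the printed analysis parameters: z threshold 3 SD, rolling
window 10 frames with >= 7 required, peak height 3 / separation 30 frames,
sleep >= 5 min, CPM 5, FDR 0.05, |log2FC| 0.58, reference z-slice 9 (index
8). Unknown keys are rejected on load; every run should write its resolved
config next to its outputs.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class SimulateConfig(_Strict):
    T: int = Field(3000, gt=0)
    fs: float = Field(4.3, gt=0)
    n_active: int = Field(20, ge=0)
    n_silent: int = Field(20, ge=0)
    event_rate: float = Field(0.5, gt=0)
    kernel_tau: float = Field(2.5, gt=0)
    amplitude: float = Field(8.0, gt=0)
    noise_sd: float = Field(1.0, ge=0)
    day_bout_params: tuple[float, float] = (12.0, 24.0)
    night_bout_params: tuple[float, float] = (25.0, 10.0)
    wake_activity_mean: float = Field(2.69, ge=1)
    n_days: int = Field(3, ge=1)
    n_flies: int = Field(6, ge=1)
    movie_frames: int = Field(120, gt=0)
    frame_shape: tuple[int, int] = (96, 96)
    n_rois: int = Field(8, ge=1)
    max_shift_px: float = Field(2.0, ge=0)
    n_genes: int = Field(1000, ge=1)
    n_true_genes: int = Field(50, ge=0)


class ImagingConfig(_Strict):
    upsample: int = Field(10, ge=1)
    reference_frame: str = "first"
    reference_slice: int = Field(8, ge=0)
    smoothing_sigma: float = Field(1.0, ge=0)
    min_area: int = Field(4, ge=1)
    max_area: int = Field(10_000, ge=1)
    min_peak_distance: int = Field(3, ge=1)


class ActivityConfig(_Strict):
    threshold_sd: float = 3.0
    window: int = Field(10, ge=1)
    min_count: int = Field(7, ge=1)
    min_peak_height: float = 3.0
    min_peak_distance: int = Field(30, ge=1)
    onset_quiescence_s: float = Field(30.0, gt=0)
    epoch_min: float = Field(5.0, gt=0)


class ConnectivityConfig(_Strict):
    r_threshold: float = Field(0.5, gt=0, lt=1)


class BehaviorConfig(_Strict):
    min_sleep: int = Field(5, ge=1)
    short_min: int = Field(1, ge=1)
    n_pre_stimuli: int = Field(10, ge=1)


class GenefilterConfig(_Strict):
    min_mean_cpm: float = 5.0
    max_fdr: float = 0.05
    min_abs_log2fc: float = 0.58


class RunConfig(_Strict):
    seed: int = 0
    simulate: SimulateConfig = SimulateConfig()
    imaging: ImagingConfig = ImagingConfig()
    activity: ActivityConfig = ActivityConfig()
    connectivity: ConnectivityConfig = ConnectivityConfig()
    behavior: BehaviorConfig = BehaviorConfig()
    genefilter: GenefilterConfig = GenefilterConfig()


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a YAML config, merging overrides onto defaults.

    An empty (or absent) file yields all defaults; unknown keys raise a
    validation error naming the offending key.
    """
    if path is None:
        return RunConfig()
    raw = Path(path).read_text()
    data = yaml.safe_load(raw) or {}
    if not isinstance(data, dict):
        raise ValueError("config file must contain a YAML mapping")
    return RunConfig.model_validate(data)


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    """Write the fully resolved configuration as YAML."""
    Path(path).write_text(yaml.safe_dump(cfg.model_dump(mode="json"), sort_keys=False))
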