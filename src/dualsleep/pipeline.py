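"""Stage orchestration: simulate → imaging → activity → connectivity, plus
behavior and DE filtering, each reading its inputs from and writing its
outputs to a run directory, with a machine-readable RunReport.
"""

from __future__ import annotations

import graphlib
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from dualsleep import activity as act
from dualsleep import behavior as beh
from dualsleep import connectivity as conn
from dualsleep import genefilter as gf
from dualsleep import imaging as img
from dualsleep import io
from dualsleep import synthetic as syn
from dualsleep.config import RunConfig, dump_config

STAGE_DEPENDENCIES: dict[str, list[str]] = {
    "simulate": [],
    "imaging": ["simulate"],
    "activity": ["imaging"],
    "connectivity": ["activity"],
    "behavior": ["simulate"],
    "de-filter": ["simulate"],
}


@dataclass
class RunReport:
    """What a run did: per-stage parameters, outputs and warnings."""

    out_dir: str
    seed: int
    version: str
    stages: list[dict] = field(default_factory=list)

    def add_stage(self, name: str, params: dict, inputs: list[str], outputs: list[str],
                  stage_warnings: list[str]) -> None:
        self.stages.append(
            {
                "stage": name,
                "parameters": params,
                "inputs": inputs,
                "outputs": outputs,
                "warnings": stage_warnings,
            }
        )

    @property
    def output_files(self) -> list[str]:
        return [p for s in self.stages for p in s["outputs"]]


def order_stages(stages: list[str]) -> list[str]:
    """Resolve a stage list into dependency order; unknown names or cycles raise."""
    unknown = set(stages) - set(STAGE_DEPENDENCIES)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    wanted = set(stages)
    # pull in missing prerequisites
    changed = True
    while changed:
        changed = False
        for s in list(wanted):
            for dep in STAGE_DEPENDENCIES[s]:
                if dep not in wanted:
                    wanted.add(dep)
                    changed = True
    ts = graphlib.TopologicalSorter({s: STAGE_DEPENDENCIES[s] for s in wanted})
    return [s for s in ts.static_order() if s in wanted]


def _sim_config(cfg: RunConfig) -> syn.SimConfig:
    s = cfg.simulate
    return syn.SimConfig(
        seed=cfg.seed,
        T=s.T,
        fs=s.fs,
        n_active=s.n_active,
        n_silent=s.n_silent,
        event_rate=s.event_rate,
        kernel_tau=s.kernel_tau,
        amplitude=s.amplitude,
        noise_sd=s.noise_sd,
        day_bout_params=s.day_bout_params,
        night_bout_params=s.night_bout_params,
        wake_activity_mean=s.wake_activity_mean,
    )


def run_pipeline(cfg: RunConfig, stages: list[str], out_dir: str | Path) -> RunReport:
    """Execute the requested stages in dependency order under ``out_dir``.

    Every stage records its parameters, inputs, outputs and warnings in the
    returned RunReport, which is also written to ``report.json``; the
    resolved configuration is written to ``config_resolved.yaml``. A stage
    whose upstream outputs are missing raises, naming the missing stage.
    """
    from dualsleep import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(out_dir=str(out), seed=cfg.seed, version=__version__)
    dump_config(cfg, out / "config_resolved.yaml")

    for stage in order_stages(stages):
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            runner = _STAGE_RUNNERS[stage]
            params, inputs, outputs = runner(cfg, out)
        report.add_stage(stage, params, inputs, outputs, [str(w.message) for w in caught])

    io.write_json(out / "report.json", report.__dict__)
    return report


def _require(out: Path, name: str, stage: str) -> Path:
    p = out / name
    if not p.exists():
        raise FileNotFoundError(
            f"stage '{stage}' needs {name}; run its upstream stage first"
        )
    return p


def _run_simulate(cfg: RunConfig, out: Path):
    s = cfg.simulate
    sim = _sim_config(cfg)

    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 0x5F1)))
    movie_cfg = syn.SimConfig(**{**sim.__dict__, "T": s.movie_frames})
    shifts = rng.uniform(-s.max_shift_px, s.max_shift_px, (s.movie_frames, 2))
    shifts[0] = 0.0
    movie, labels, shifts, movie_truth = syn.make_movie(
        movie_cfg, frame_shape=tuple(s.frame_shape), n_rois=s.n_rois, shifts=shifts
    )
    io.write_movie(out / "movie.tif", movie, {"fs": s.fs, "frame_shape": list(s.frame_shape)})
    io.write_labels(out / "movie_labels_truth.tif", labels)
    io.write_json(out / "movie_truth.json", {
        "shifts": shifts,
        "events": {str(t.neuron_id): t.event_times for t in movie_truth},
    })

    traces, truths = syn.make_traces(sim)
    io.write_traces(out / "traces.csv", traces)
    io.write_json(out / "traces_truth.json", {
        str(t.neuron_id): {"is_active": bool(t.is_active), "event_times": t.event_times}
        for t in truths
    })

    logs, truth_bouts = [], {}
    for fly in range(s.n_flies):
        log, truth = syn.make_behavior_log(sim, n_days=s.n_days, fly_id=fly)
        logs.append(log)
        truth_bouts[str(fly)] = truth.true_bouts
    io.write_table(out / "behavior_log.csv", pd.concat(logs, ignore_index=True))
    io.write_json(out / "behavior_truth.json", truth_bouts)

    de, de_truth = syn.make_de_table(n_genes=s.n_genes, n_true=s.n_true_genes, seed=cfg.seed)
    io.write_table(out / "de_table.tsv", de)
    io.write_json(out / "de_truth.json", {"true_genes": de.loc[de_truth, "gene_id"].tolist()})

    outputs = [
        "movie.tif", "movie_truth.json", "movie_labels_truth.tif",
        "traces.csv", "traces_truth.json",
        "behavior_log.csv", "behavior_truth.json",
        "de_table.tsv", "de_truth.json",
    ]
    return s.model_dump(mode="json"), [], [str(out / o) for o in outputs]


def _run_imaging(cfg: RunConfig, out: Path):
    p = cfg.imaging
    movie_path = _require(out, "movie.tif", "imaging")
    movie, meta = io.read_movie(movie_path)
    registered, shifts = img.register_frames(movie, upsample=p.upsample, reference=p.reference_frame)
    sd = img.sd_projection(registered)
    labels = img.segment_rois(
        sd,
        smoothing_sigma=p.smoothing_sigma,
        min_area=p.min_area,
        max_area=p.max_area,
        min_peak_distance=p.min_peak_distance,
    )
    traces = img.extract_traces(registered, labels, fs=meta.get("fs", 1.0))
    io.write_json(out / "registration_shifts.json", {"shifts": shifts})
    io.write_labels(out / "roi_labels.tif", labels)
    io.write_traces(out / "movie_traces.csv", traces)
    outputs = ["registration_shifts.json", "roi_labels.tif", "movie_traces.csv"]
    return p.model_dump(), [str(movie_path)], [str(out / o) for o in outputs]


def _run_activity(cfg: RunConfig, out: Path):
    p = cfg.activity
    traces_path = _require(out, "traces.csv", "activity")
    traces = io.read_traces(traces_path)
    z = act.zscore(traces)
    b = act.binarize(z, threshold_sd=p.threshold_sd)
    calls = act.classify_active(b, window=p.window, min_count=p.min_count)
    events = act.count_events(z, min_height=p.min_peak_height, min_separation=p.min_peak_distance)
    table = pd.DataFrame(
        {
            "neuron_id": [c.neuron_id for c in calls],
            "is_active": [c.is_active for c in calls],
            "n_events": events,
            "degenerate": z.degenerate,
        }
    )
    io.write_table(out / "activity_calls.csv", table)
    io.write_json(out / "activity_summary.json", {
        "percent_active": act.percent_active(calls),
        "n_neurons": len(calls),
        "parameters": p.model_dump(),
    })
    outputs = ["activity_calls.csv", "activity_summary.json"]
    return p.model_dump(), [str(traces_path)], [str(out / o) for o in outputs]


def _run_connectivity(cfg: RunConfig, out: Path):
    p = cfg.connectivity
    traces_path = _require(out, "traces.csv", "connectivity")
    calls_path = _require(out, "activity_calls.csv", "connectivity")
    traces = io.read_traces(traces_path)
    calls = io.read_table(calls_path)
    active_ids = calls.loc[calls["is_active"], "neuron_id"].to_numpy()
    mask = np.isin(traces.neuron_ids, active_ids)
    if mask.sum() < 2:
        warnings.warn("fewer than 2 active neurons; connectivity skipped")
        io.write_json(out / "connectivity.json", {"mean_degree": None})
        return p.model_dump(), [str(traces_path), str(calls_path)], [str(out / "connectivity.json")]
    corr = conn.correlation_matrix(traces.values[mask], neuron_ids=traces.neuron_ids[mask])
    graph = conn.build_graph(corr, r_threshold=p.r_threshold)
    md = conn.mean_degree(graph)
    pd.DataFrame(corr.values, index=corr.neuron_ids, columns=corr.neuron_ids).to_csv(
        out / "correlation_matrix.csv"
    )
    io.write_json(out / "connectivity.json", {
        "mean_degree": md,
        "r_threshold": p.r_threshold,
        "n_active": int(mask.sum()),
    })
    outputs = ["correlation_matrix.csv", "connectivity.json"]
    return p.model_dump(), [str(traces_path), str(calls_path)], [str(out / o) for o in outputs]


def _run_behavior(cfg: RunConfig, out: Path):
    p = cfg.behavior
    log_path = _require(out, "behavior_log.csv", "behavior")
    log = io.read_table(log_path)
    bouts = beh.classify_bouts(beh.detect_bouts(log), min_sleep=p.min_sleep, short_min=p.short_min)
    summary = beh.architecture_summary(bouts, log)
    io.write_table(out / "bouts.csv", bouts)
    io.write_table(out / "architecture_summary.csv", summary)
    outputs = ["bouts.csv", "architecture_summary.csv"]
    return p.model_dump(), [str(log_path)], [str(out / o) for o in outputs]


def _run_defilter(cfg: RunConfig, out: Path):
    p = cfg.genefilter
    de_path = _require(out, "de_table.tsv", "de-filter")
    table = io.read_table(de_path)
    kept = gf.cpm_filter(table, min_mean_cpm=p.min_mean_cpm)
    up, down = gf.significance_filter(kept, max_fdr=p.max_fdr, min_abs_log2fc=p.min_abs_log2fc)
    comparison = gf.set_overlap({"up": up, "down": down}) if up or down else None
    io.write_json(out / "de_genes.json", {
        "n_input": len(table),
        "n_after_cpm_filter": len(kept),
        "up": up,
        "down": down,
        "counts": comparison.counts if comparison else {},
    })
    return p.model_dump(), [str(de_path)], [str(out / "de_genes.json")]


_STAGE_RUNNERS = {
    "simulate": _run_simulate,
    "imaging": _run_imaging,
    "activity": _run_activity,
    "connectivity": _run_connectivity,
    "behavior": _run_behavior,
    "de-filter": _run_defilter,
}
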