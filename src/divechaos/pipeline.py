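"""End-to-end orchestration: load/simulate -> select -> embed -> features
-> cluster -> summarize, with a JSON run manifest.

Every number that influences an output is echoed into ``manifest.json`` in
the output directory; a rerun with the identical resolved configuration
reuses persisted stage outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .clustering import assign, model_scan, semantic_labels, serialize_fit
from .embedding import (EmbeddingParams, false_nearest_fraction,
                        segment_median_curve, select_delay, select_dimension)
from .errors import ConfigError, DataError
from .invariants import sliding_features
from .io_depth import read_depth_record, regularize, write_depth_record
from .summaries import daypart_partition, diurnal_percentiles, time_budget
from .synthetic import SimConfig, simulate_dive_record

log = logging.getLogger("divechaos")


@dataclass
class RunConfig:
    """Resolved pipeline configuration; fully serializable."""

    input_csv: str | None = None
    simulate: bool = False
    sim_duration_days: float = 2.0
    sim_seed: int = 0
    sim_overrides: dict = field(default_factory=dict)
    gap_policy: str = "linear"
    max_gap_s: float = 600.0
    tau_s: float | str = "auto"          # seconds or "auto"
    m: int | str = 3                     # dimension or "auto"
    fnn_r_t: float = 3.0
    fnn_threshold: float = 0.01
    fnn_max_m: int = 5
    window_s: float = 1800.0
    step_s: float = 600.0
    period_range: tuple = (60.0, 3600.0)
    k_min: int = 1
    k_max: int = 6
    n_init: int = 20
    cluster_seed: int = 0
    bin_h: int = 3
    utc_offset_h: float = 0.0
    min_confidence: float = 0.9

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["period_range"] = list(self.period_range)
        return d


def load_config(path) -> RunConfig:
    """Read a flat key-value (YAML) config file into a RunConfig."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    bad = set(raw) - known
    if bad:
        raise ConfigError(f"unknown config keys: {sorted(bad)}")
    if "period_range" in raw:
        raw["period_range"] = tuple(raw["period_range"])
    return RunConfig(**raw)


def _load_record(config: RunConfig):
    if config.simulate:
        sim = SimConfig(**config.sim_overrides)
        record, trace = simulate_dive_record(
            sim, config.sim_duration_days * 86400.0, config.sim_seed)
        return record, trace
    if not config.input_csv:
        raise ConfigError("either input_csv or simulate must be given")
    p = Path(config.input_csv)
    if not p.exists():
        raise ConfigError(f"input path does not exist: {p}")
    rec = read_depth_record(p, strict=False)
    return regularize(rec, gap_policy=config.gap_policy,
                      max_gap_s=config.max_gap_s), None


def _select_params(record, config: RunConfig, manifest: dict) -> EmbeddingParams:
    if config.tau_s == "auto":
        try:
            ami = segment_median_curve(record, "ami")
            acf = segment_median_curve(record, "acf")
            ami.acf = acf.acf
            sel = select_delay(ami)
        except DataError:
            # record shorter than two 6-h segments: use global curves
            from .embedding import (DelaySelection, auto_mutual_information,
                                    autocorrelation)
            max_lag = min(1800.0, record.duration_s / 4)
            lags, I = auto_mutual_information(record.depth, max_lag, dt=record.dt)
            _, R = autocorrelation(record.depth, max_lag, dt=record.dt)
            from .embedding import lag_grid
            sel = select_delay(DelaySelection(
                lags_s=lags, ami=I,
                acf=R[lag_grid(max_lag, record.dt)]))
            manifest["tau_selection_segments"] = "global (record < 12 h)"
        tau_s = sel.tau_s
        manifest["tau_method"] = sel.method
        manifest["acf_zero_s"] = sel.acf_zero_s
    else:
        tau_s = float(config.tau_s)
        manifest["tau_method"] = "fixed"
    if config.m == "auto":
        tau = int(round(tau_s / record.dt))
        prof = false_nearest_fraction(record.depth, tau,
                                      range(1, config.fnn_max_m + 1),
                                      r_t=config.fnn_r_t,
                                      theiler=int(1020 / record.dt))
        m = select_dimension(prof, config.fnn_threshold)
        manifest["fnn_profile"] = dict(zip(prof.m_values.tolist(),
                                           prof.fnn_fraction.tolist()))
    else:
        m = int(config.m)
    manifest["tau_s"] = tau_s
    manifest["m"] = m
    return EmbeddingParams(tau_s=tau_s, m=m, dt=record.dt)


def run(config: RunConfig, outdir) -> dict:
    """Execute the pipeline; returns a dict of output paths.

    Idempotent for an identical resolved config: stages whose outputs
    already exist under a matching manifest are reused.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    cfg = config.to_dict()
    if manifest_path.exists():
        old = json.loads(manifest_path.read_text())
        if old.get("config") == cfg and (out / "labels.csv").exists():
            log.info("outputs up to date; reusing %s", out)
            return {k: str(out / v) for k, v in old["outputs"].items()}

    manifest: dict = {"config": cfg, "timings_s": {}, "outputs": {}}
    t0 = time.time()
    record, trace = _load_record(config)
    manifest["n_samples"] = record.n
    manifest["timings_s"]["load"] = round(time.time() - t0, 2)

    t0 = time.time()
    params = _select_params(record, config, manifest)
    manifest["timings_s"]["select_params"] = round(time.time() - t0, 2)

    t0 = time.time()
    feats = sliding_features(record, params, window_s=config.window_s,
                             step_s=config.step_s,
                             period_range=config.period_range)
    feats.to_csv(out / "features.csv", index=False)
    manifest["outputs"]["features"] = "features.csv"
    manifest["n_windows"] = len(feats)
    manifest["timings_s"]["features"] = round(time.time() - t0, 2)

    t0 = time.time()
    scan = model_scan(feats, k_range=range(config.k_min, config.k_max + 1),
                      n_init=config.n_init, seed=config.cluster_seed)
    scan.table.to_csv(out / "model_scan.csv", index=False)
    (out / "mixture.json").write_text(json.dumps(serialize_fit(scan.fit), indent=1))
    members = assign(scan.fit, feats)
    labels, info = semantic_labels(scan.fit, feats, members)
    labels.to_csv(out / "labels.csv", index=False)
    manifest["selected_k"] = scan.k
    manifest["structure"] = scan.structure
    manifest["tag_of_component"] = {str(k): v for k, v in
                                    info["tag_of_component"].items()}
    manifest["outputs"].update(model_scan="model_scan.csv",
                               mixture="mixture.json", labels="labels.csv")
    manifest["timings_s"]["cluster"] = round(time.time() - t0, 2)

    t0 = time.time()
    budget = time_budget(labels)
    budget_hi = time_budget(labels, min_confidence=config.min_confidence)
    budget.to_csv(out / "budget.csv", index=False)
    budget_hi.to_csv(out / "budget_confident.csv", index=False)
    part = daypart_partition(labels, bin_h=config.bin_h,
                             utc_offset_h=config.utc_offset_h)
    part.to_csv(out / "daypart_partition.csv", index=False)
    diurnal = {}
    for featname in ("Ek_med", "L_med", "lyap", "period_s"):
        tab = diurnal_percentiles(feats["window_mid"], feats[featname],
                                  bin_h=config.bin_h,
                                  utc_offset_h=config.utc_offset_h)
        tab.insert(0, "feature", featname)
        diurnal[featname] = tab
    pd.concat(diurnal.values()).to_csv(out / "diurnal.csv", index=False)
    manifest["outputs"].update(budget="budget.csv",
                               budget_confident="budget_confident.csv",
                               daypart="daypart_partition.csv",
                               diurnal="diurnal.csv")
    manifest["timings_s"]["summaries"] = round(time.time() - t0, 2)

    if trace is not None and record.n <= 400_000:
        write_depth_record(record, out / "record.csv", state=trace.states)
        manifest["outputs"]["record"] = "record.csv"

    manifest_path.write_text(json.dumps(_jsonable(manifest), indent=1))
    manifest["outputs"]["manifest"] = "manifest.json"
    return {k: str(out / v) for k, v in manifest["outputs"].items()}


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
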