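"""End-to-end orchestration: simulate -> decode -> ersp -> stats -> report.

A run is fully determined by its :class:`RunConfig` (two top-level seeds:
one for data generation, one for fold/permutation draws).  Every artifact
embeds the config hash so artifacts from different configurations cannot be
mixed silently.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import cluster as cluster_mod
from . import decoding, ersp, simulate
from .csp import CSP
from .decoding import make_grid
from .epochs import EpochSet, crop_time, load_epochs, save_epochs

log = logging.getLogger("covertbci")

__all__ = ["RunConfig", "run_pipeline", "config_hash", "load_config"]

_REQUIRED_KEYS = ("simulation", "decoding", "ersp", "stats")


@dataclass
class RunConfig:
    """Declarative description of a full pipeline run."""

    simulation: simulate.SimulationConfig = field(
        default_factory=simulate.SimulationConfig)
    # decoding
    grid_t_range_ms: tuple[float, float] = (0.0, 1200.0)
    grid_f_range_hz: tuple[float, float] = (4.0, 50.0)
    grid_dt_ms: float = 200.0
    grid_df_hz: float = 2.0
    m: int = 2
    n_folds: int = 10
    fir_order: int = 512
    svm_penalty: float = 1.0
    selection_n_sd: float = 2.0
    selection_floor_alpha: float | None = None
    analysis_seed: int = 0
    # ersp
    ersp_f_range_hz: tuple[float, float] = (5.0, 30.0)
    ersp_df_hz: float = 1.0
    ersp_decim_ms: float = 5.0
    ersp_t_range_ms: tuple[float, float] = (-300.0, 1200.0)
    ersp_report_t_range_ms: tuple[float, float] = (0.0, 1200.0)
    # stats
    bands: dict = field(default_factory=lambda: {
        "theta": (4.0, 8.0), "alpha": (8.0, 13.0)})
    n_perm: int = 5000
    stats_alpha: float = 0.05
    min_run: int = 3

    def ersp_freqs(self) -> np.ndarray:
        f0, f1 = self.ersp_f_range_hz
        return np.arange(f0, f1 + self.ersp_df_hz / 2, self.ersp_df_hz)


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj


def config_hash(config: RunConfig) -> str:
    cfg = dataclasses.asdict(config)
    cfg["simulation"].pop("montage", None)
    payload = json.dumps(_to_jsonable(cfg), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path) -> RunConfig:
    """Build a RunConfig from a YAML mapping, validating keys up front."""
    import yaml

    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    for key in _REQUIRED_KEYS:
        if key not in raw:
            raise KeyError(f"config missing required section {key!r}")
    sim_raw = dict(raw["simulation"])
    effects = sim_raw.pop("effects", None)
    if effects is not None:
        sim_raw["effects"] = tuple(
            simulate.EffectSpec(
                band_hz=tuple(e["band_hz"]), window_ms=tuple(e["window_ms"]),
                channels=e["channels"] if isinstance(e["channels"], str)
                else tuple(e["channels"]),
                amplitude_no=e["amplitude_no"], amplitude_yes=e["amplitude_yes"],
                spatial_decay=e.get("spatial_decay", 0.35),
            ) for e in effects)
    if "epoch_ms" in sim_raw:
        sim_raw["epoch_ms"] = tuple(sim_raw["epoch_ms"])
    sim = simulate.SimulationConfig(**sim_raw)
    kwargs: dict = {"simulation": sim}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    for section in ("decoding", "ersp", "stats"):
        for k, v in (raw.get(section) or {}).items():
            if k not in known:
                raise KeyError(f"unknown config key {k!r} in section {section!r}")
            if isinstance(v, list):
                v = tuple(v)
            if k == "bands":
                v = {name: tuple(b) for name, b in v.items()}
            kwargs[k] = v
    return RunConfig(**kwargs)


def _round6(x):
    if isinstance(x, float):
        return float(f"{x:.6g}")
    if isinstance(x, dict):
        return {k: _round6(v) for k, v in x.items()}
    if isinstance(x, list):
        return [_round6(v) for v in x]
    return x


def _write_json(path: Path, payload: dict, cfg_hash: str) -> None:
    payload = dict(payload)
    payload["config_hash"] = cfg_hash
    path.write_text(json.dumps(_round6(_to_jsonable(payload)), indent=1,
                               sort_keys=True))


def check_hash(path: Path, cfg_hash: str) -> dict:
    payload = json.loads(Path(path).read_text())
    if payload.get("config_hash") != cfg_hash:
        raise ValueError(
            f"artifact {path} was produced under a different configuration "
            f"({payload.get('config_hash')} != {cfg_hash})"
        )
    return payload


def simulate_stage(config: RunConfig, out_dir: Path) -> list[Path]:
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort = simulate.generate_cohort(config.simulation)
    paths = []
    for i, epochs in enumerate(cohort):
        p = out_dir / f"subject_{i:02d}.npz"
        save_epochs(epochs, p)
        paths.append(p)
    _write_json(out_dir / "manifest.json",
                {"n_subjects": len(paths), "files": [p.name for p in paths]},
                config_hash(config))
    return paths


def _load_cohort(data_dir: Path, config: RunConfig) -> list[EpochSet]:
    manifest = check_hash(data_dir / "manifest.json", config_hash(config))
    return [load_epochs(data_dir / name) for name in manifest["files"]]


def decode_stage(config: RunConfig, cohort: list[EpochSet], out_dir: Path) -> dict:
    out_dir.mkdir(parents=True, exist_ok=True)
    grid = make_grid(config.grid_t_range_ms, config.grid_f_range_hz,
                     config.grid_dt_ms, config.grid_df_hz)
    amap = decoding.accuracy_map(
        cohort, grid, m=config.m, n_folds=config.n_folds,
        seed=config.analysis_seed, penalty=config.svm_penalty,
        fir_order=config.fir_order)
    floor = None
    if config.selection_floor_alpha is not None:
        n_test = cohort[0].n_trials // (2 * config.n_folds)
        floor = decoding.chance_threshold(max(n_test, 1),
                                          config.selection_floor_alpha)
    selected = decoding.select_subwindows(amap, n_sd=config.selection_n_sd,
                                          floor=floor)
    combined = [
        decoding.decode_combined(
            ep, selected, m=config.m, n_folds=config.n_folds,
            seed=np.random.SeedSequence([config.analysis_seed, i]),
            penalty=config.svm_penalty, fir_order=config.fir_order)
        for i, ep in enumerate(cohort)
    ] if selected else []
    n_test = cohort[0].n_trials // (2 * config.n_folds)
    means = amap.mean
    summary = {
        "selected_windows": [list(w) for w in selected],
        "selection_threshold": float(means.mean() + config.selection_n_sd
                                     * means.std(ddof=0)),
        "chance_threshold": decoding.chance_threshold(max(n_test, 1), 0.05),
        "best_window": list(amap.best_window()),
        "best_window_accuracy": float(means.max()),
        "combined_accuracy_mean": (float(np.mean([r.mean_accuracy
                                                  for r in combined]))
                                   if combined else None),
        "combined_accuracy_sd": (float(np.std([r.mean_accuracy
                                               for r in combined], ddof=1))
                                 if len(combined) > 1 else None),
        "combined_per_subject": [r.as_dict() for r in combined],
        "n_features_combined": 2 * config.m * len(selected),
    }
    amap.to_frame().to_csv(out_dir / "accuracy_map.csv", index=False)
    _write_json(out_dir / "decoding_summary.json", summary, config_hash(config))
    np.save(out_dir / "per_subject_accuracy.npy", amap.per_subject)
    return {"summary": summary, "accuracy_map": amap, "combined": combined}


def pattern_stage(config: RunConfig, cohort: list[EpochSet],
                  selected: list, out_dir: Path) -> dict:
    """Group-mean last-minus-first spatial-pattern difference per selected
    subwindow (the discriminative scalp topography)."""
    out_dir.mkdir(parents=True, exist_ok=True)
    out = {}
    for w in selected:
        diffs = []
        for ep in cohort:
            filtered = decoding.bandpass_fir(ep, w[2], w[3],
                                             order=config.fir_order)
            block = crop_time(filtered, w[0], w[1])
            csp = CSP(m=config.m, class_order=decoding.CLASS_ORDER)
            csp.fit(block.data, block.labels)
            diffs.append(csp.pattern_difference())
        out[decoding._window_tag(tuple(w))] = {
            "channels": list(cohort[0].montage.names),
            "mean_difference": np.mean(diffs, axis=0),
        }
    _write_json(out_dir / "pattern_differences.json", out, config_hash(config))
    return out


def ersp_stage(config: RunConfig, cohort: list[EpochSet], out_dir: Path
               ) -> dict[str, list]:
    out_dir.mkdir(parents=True, exist_ok=True)
    freqs = config.ersp_freqs()
    maps: dict[str, list] = {"yes": [], "no": []}
    for i, ep in enumerate(cohort):
        per_class = ersp.induced_power(ep, freqs, config.ersp_decim_ms,
                                       config.ersp_t_range_ms)
        for label, tfmap in per_class.items():
            norm = ersp.baseline_normalize(tfmap)
            maps[label].append(norm.crop_times(*config.ersp_report_t_range_ms))
    np.savez(
        out_dir / "ersp_maps.npz",
        yes=np.stack([m.values for m in maps["yes"]]),
        no=np.stack([m.values for m in maps["no"]]),
        freqs_hz=freqs,
        times_ms=maps["yes"][0].times_ms,
        channels=np.array(maps["yes"][0].channels),
        config_hash=np.array(config_hash(config)),
    )
    return maps


def stats_stage(config: RunConfig, maps: dict[str, list], out_dir: Path) -> dict:
    out_dir.mkdir(parents=True, exist_ok=True)
    results = {}
    for name, band in config.bands.items():
        res = cluster_mod.permutation_null(
            maps["no"], maps["yes"], band_hz=band, band_name=name,
            n_perm=config.n_perm, alpha=config.stats_alpha,
            seed=np.random.SeedSequence(
                [config.analysis_seed, zlib.crc32(name.encode()) % (2**31)]),
            min_run=config.min_run)
        results[name] = {
            "band_hz": list(band),
            "selected_electrodes": list(res.selected_electrodes),
            "t_threshold": res.t_threshold,
            "n_clusters": len(res.clusters),
            "clusters": [
                {"t_mass": c.t_mass, "p_value": c.p_value,
                 "significant": bool(c.significant),
                 "n_bins": int(c.bins.shape[0]),
                 "freq_range_hz": [float(res.freqs_hz[c.bins[:, 0].min()]),
                                   float(res.freqs_hz[c.bins[:, 0].max()])],
                 "time_range_ms": [float(res.times_ms[c.bins[:, 1].min()]),
                                   float(res.times_ms[c.bins[:, 1].max()])]}
                for c in res.clusters
            ],
            "null_95_quantile": res.null_quantile,
        }
    _write_json(out_dir / "cluster_results.json", results, config_hash(config))
    return results


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute every stage and write a consolidated summary report."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stages: dict = {}
    t_all = time.time()

    def timed(name, fn, *args):
        t0 = time.time()
        log.info("stage %s starting", name)
        try:
            result = fn(*args)
        except Exception:
            log.error("stage %s failed; config hash %s", name,
                      config_hash(config))
            raise
        log.info("stage %s done in %.1f s", name, time.time() - t0)
        return result

    cohort = timed("simulate", lambda: simulate.generate_cohort(config.simulation))
    simulate_stage(config, out_dir / "data")
    dec = timed("decode", decode_stage, config, cohort, out_dir / "decode")
    patterns = timed(
        "patterns", pattern_stage, config, cohort,
        dec["summary"]["selected_windows"] or [list(dec["summary"]["best_window"])],
        out_dir / "decode")
    maps = timed("ersp", ersp_stage, config, cohort, out_dir / "ersp")
    stats_res = timed("stats", stats_stage, config, maps, out_dir / "stats")

    stages["decoding"] = dec["summary"]
    stages["cluster_stats"] = stats_res
    stages["pattern_windows"] = sorted(patterns.keys())
    log.info("pipeline finished in %.1f s", time.time() - t_all)
    _write_json(out_dir / "summary.json", stages, config_hash(config))
    return stages
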