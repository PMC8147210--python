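"""End-to-end experiment orchestration.

One config drives the whole chain: emulate the drying/rewetting design,
render a raw scene per sample, calibrate against white/dark references, mask
the background, extract per-sample mean spectra, restrict to the low-noise
band window, fit one PLS model per preprocessing method on a shared
calibration/validation split, and produce moisture maps for a subset of
samples with the best model.  A manifest records the config and seed so a
rerun reproduces the run exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .calibration import MaskParams, apply_mask, build_mask, calibrate, mean_spectrum
from .design import DesignConfig, emulate_design, records_to_frame
from .errors import FeedcubeError
from .hypercube_io import Hypercube, ReferencePanel, subrange_indices, write_envi
from .mapping import median_filter_3x3, predict_map, render_map
from .pls import PreprocessMethod, format_report, model_to_json, run_table1
from .preprocessing import SpectraTable
from .scene import SceneConfig, synth_scene

__all__ = ["RunConfig", "run_all", "load_config", "config_to_dict", "config_from_dict"]

log = logging.getLogger("feedcube")

DEFAULT_METHODS = ("raw", "mean", "max", "range", "msc", "snv", "sg1", "sg2")


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one experiment run."""

    design: DesignConfig = field(default_factory=DesignConfig)
    scene: SceneConfig = field(default_factory=SceneConfig)
    methods: tuple[str, ...] = DEFAULT_METHODS
    band_range: tuple[float, float] = (894.0, 1917.0)
    mask_params: MaskParams = field(default_factory=MaskParams)
    split_frac: float = 0.7
    max_lv: int = 10
    seed: int = 0
    outdir: str = "feedcube_run"
    n_map_samples: int = 5  # maps + exported ENVI scenes for the first record of this many groups

    def __post_init__(self) -> None:
        if not self.methods:
            raise FeedcubeError("methods must be non-empty")
        lo, hi = self.band_range
        wl = self.scene.grid.band_centers
        if lo < wl[0] - 1e-9 or hi > wl[-1] + 1e-9:
            raise FeedcubeError("band_range must lie within the scene grid")


def _sample_seeds(seed: int, n: int) -> list[int]:
    # stable per-record scene seeds derived from the run seed
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n)]


def _extract_spectrum(record, scene_cfg: SceneConfig, mask_params: MaskParams):
    cube, white, dark, truth, true_mask = synth_scene(record, scene_cfg)
    refl = calibrate(cube, ReferencePanel(white, dark))
    mask = build_mask(refl, mask_params)
    masked = apply_mask(refl, mask)
    return mean_spectrum(masked), (cube, white, dark, truth, true_mask, masked)


def run_all(config: RunConfig) -> Path:
    """Execute the full experiment; returns the run directory.

    Outputs: ``reference.csv`` (sample bookkeeping), ``report.csv`` /
    ``report.txt`` (one row per preprocessing method), ``model_<kind>.json``,
    ``betas.csv`` (regression coefficients over wavelength), per-sample maps
    (PNG + CSV) and ENVI scenes for the export subset, and
    ``manifest.json``.  Any stage failure is re-raised naming the stage and
    sample.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()

    records = emulate_design(config.design)
    ref = records_to_frame(records)
    ref.to_csv(out / "reference.csv", index=False)
    log.info("design: %d records emitted in %.2fs", len(records), time.perf_counter() - t0)

    seeds = _sample_seeds(config.seed, len(records))
    spectra = []
    for i, record in enumerate(records):
        try:
            scene_cfg = replace(config.scene, seed=seeds[i])
            spectrum, _ = _extract_spectrum(record, scene_cfg, config.mask_params)
            spectra.append(spectrum)
        except FeedcubeError as exc:
            raise FeedcubeError(
                f"stage=extract sample={record.group_id}/{record.treatment}/{record.step_index}: {exc}"
            ) from exc
    X = np.vstack(spectra)
    ids = [f"{r.group_id}|{r.treatment}|{r.step_index}" for r in records]
    y = np.array([100.0 * r.M_wb for r in records])
    table = SpectraTable(X, config.scene.grid, y, ids)
    log.info("extract: %d mean spectra in %.2fs", table.n, time.perf_counter() - t0)

    sub_idx = subrange_indices(config.scene.grid, *config.band_range)
    sub = table.subset_bands(sub_idx)
    methods = [PreprocessMethod(kind=k) for k in config.methods]
    report, models = run_table1(sub, methods, seed=config.seed,
                                frac=config.split_frac, max_lv=config.max_lv)
    for kind, model in models.items():
        model.band_indices = sub_idx
        model_to_json(model, out / f"model_{kind}.json")
    report.to_csv(out / "report.csv", index=False)
    (out / "report.txt").write_text(format_report(report) + "\n")
    log.info("models: %d methods fitted in %.2fs", len(models), time.perf_counter() - t0)

    # beta-coefficient curves over wavelength (one column per method)
    betas = {"wavelength_nm": sub.grid.band_centers}
    for kind, model in models.items():
        betas[kind] = model.beta
    import pandas as pd

    pd.DataFrame(betas).to_csv(out / "betas.csv", index=False)

    best_kind = report.loc[report["r2_pred"].idxmax(), "method"]
    best = models[best_kind]

    # maps + exported scenes for the first record of each exported group
    group_first = {}
    for i, r in enumerate(records):
        group_first.setdefault(r.group_id, i)
    export = list(group_first.values())[: config.n_map_samples]
    for i in export:
        record = records[i]
        scene_cfg = replace(config.scene, seed=seeds[i])
        _, (cube, white, dark, truth, true_mask, masked) = _extract_spectrum(
            record, scene_cfg, config.mask_params
        )
        tag = f"{record.group_id.split()[0]}_{record.treatment}_{record.step_index}"
        write_envi(cube, out / f"scene_{tag}.hdr")
        write_envi(Hypercube(white, config.scene.grid), out / f"white_{tag}.hdr")
        write_envi(Hypercube(dark, config.scene.grid), out / f"dark_{tag}.hdr")
        mmap = median_filter_3x3(predict_map(masked, best))
        mmap.provenance = f"model={best_kind} sample={tag}"
        render_map(mmap, out / f"map_{tag}.png")
        np.savetxt(out / f"map_{tag}.csv", mmap.values, delimiter=",", fmt="%.4f")
    log.info("maps: %d samples mapped with '%s' in %.2fs",
             len(export), best_kind, time.perf_counter() - t0)

    manifest = {
        "config": config_to_dict(config),
        "best_method": str(best_kind),
        "n_records": len(records),
        "outputs": sorted(p.name for p in out.iterdir()),
        "created": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


# ---------------------------------------------------------------------------
# config (de)serialisation
# ---------------------------------------------------------------------------

def config_to_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d["scene"]["grid"] = {
        "start": float(config.scene.grid.band_centers[0]),
        "stop": float(config.scene.grid.band_centers[-1]),
        "n_bands": config.scene.grid.count,
    }
    return d


def config_from_dict(d: dict) -> RunConfig:
    from .hypercube_io import make_grid

    d = dict(d)
    design = DesignConfig(**{**d.get("design", {}),
                             **{k: tuple(v) for k, v in d.get("design", {}).items()
                                if k in ("initial_moisture", "initial_mass")}})
    scene_d = dict(d.get("scene", {}))
    grid_d = scene_d.pop("grid", None)
    if grid_d is not None:
        scene_d["grid"] = make_grid(grid_d["start"], grid_d["stop"], grid_d["n_bands"])
    for k in ("scatter_offset_range", "scatter_slope_range"):
        if k in scene_d:
            scene_d[k] = tuple(scene_d[k])
    scene = SceneConfig(**scene_d)
    mask_d = d.get("mask_params", {})
    return RunConfig(
        design=design,
        scene=scene,
        methods=tuple(d.get("methods", DEFAULT_METHODS)),
        band_range=tuple(d.get("band_range", (894.0, 1917.0))),
        mask_params=MaskParams(**mask_d),
        split_frac=d.get("split_frac", 0.7),
        max_lv=d.get("max_lv", 10),
        seed=d.get("seed", 0),
        outdir=d.get("outdir", "feedcube_run"),
        n_map_samples=d.get("n_map_samples", 5),
    )


def load_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from YAML (or a manifest's ``config`` block)."""
    doc = yaml.safe_load(Path(path).read_text())
    if "config" in doc and isinstance(doc["config"], dict):
        doc = doc["config"]
    return config_from_dict(doc)
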