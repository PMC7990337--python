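"""End-to-end pipeline: seed -> bootstrap -> refine (half-sets) -> clean ->
average -> FSC -> classify -> lattice statistics, driven by one YAML config.

Every stage logs its parameters and particle counts as JSON lines; all
randomness flows from the config seed, so reruns with an identical config are
reproducible.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_formats
from .align_average import (
    AngularGrid,
    IterationSpec,
    RefinementSchedule,
    TomogramSource,
    average_particles,
    bootstrap_reference,
    recenter_reference,
    run_refinement,
    soft_sphere_mask,
)
from .classification import build_wmd_stack, pca_classify
from .cleanup import apply_cc_cutoff, exclude_edge_particles
from .errors import ConfigError, PipelineError
from .geometry import seed_tube_surface
from .io_formats import DensityVolume
from .lattice import arch_tilt_stats, neighbor_stats
from .resolution import fsc, resolution_at, write_fsc_curve
from .simulator import load_fixture, make_fixture

logger = logging.getLogger(__name__)


DEFAULT_SCHEDULE = [
    # capture: lock every seed onto its own coat unit (protein-only mask
    # following the reference's apex, wide shift radius covering half a
    # lattice cell)
    {"cone_half": 10.0, "cone_step": 5.0, "inplane_range": 5.0, "inplane_step": 5.0,
     "max_shift_vox": 10.0, "lowpass_A": 40.0, "cc_mask": "protein",
     "local_refine_rounds": 2},
    # refine: narrow search against the sharpened average
    {"cone_half": 8.0, "cone_step": 4.0, "inplane_range": 4.0, "inplane_step": 4.0,
     "max_shift_vox": 4.0, "lowpass_A": 28.0, "cc_mask": "protein",
     "local_refine_rounds": 2},
]


def default_config(fixture_dir: str, output_dir: str, seed: int = 1,
                   halfsets: bool = False) -> dict:
    return {
        "seed": int(seed),
        "fixture_dir": str(fixture_dir),
        "output_dir": str(output_dir),
        "spacing_A": 44.0,
        "halfsets": bool(halfsets),
        "bootstrap": {
            "subset_fraction": 0.5,
            "angular_steps": [8.0, 7.0, 6.0, 5.0, 4.0],
            "lowpass_A": 40.0,
            "max_shift_vox": 7.0,
        },
        "schedule": [dict(s) for s in DEFAULT_SCHEDULE],
        "dedup_A": 55.0,
        "cc_cutoff": None,
        "edge_exclude": True,
        "fsc_threshold": 0.143,
        "classify": None,
        "neighbor_radius_A": 120.0,
    }


def parse_schedule(entries) -> RefinementSchedule:
    its = []
    for s in entries:
        its.append(IterationSpec(
            grid=AngularGrid(s["cone_half"], s["cone_step"],
                             s["inplane_range"], s["inplane_step"]),
            max_shift_vox=float(s["max_shift_vox"]),
            lowpass_A=s.get("lowpass_A"),
            cc_mask=s.get("cc_mask", "sphere"),
            local_refine_rounds=int(s.get("local_refine_rounds", 2)),
        ))
    return RefinementSchedule(its)


def validate_config(cfg: dict) -> None:
    if "schedule" not in cfg or not cfg["schedule"]:
        raise ConfigError("config is missing the refinement schedule")
    if "output_dir" not in cfg:
        raise ConfigError("config is missing output_dir")
    if "fixture_dir" not in cfg and "fixture" not in cfg:
        raise ConfigError("config must name a fixture_dir or a fixture preset")
    parse_schedule(cfg["schedule"])  # raises on malformed entries


class _JsonlLog:
    def __init__(self, path: Path):
        self.path = path
        self.records: list = []

    def log(self, stage: str, **payload) -> None:
        rec = {"stage": stage, **payload}
        self.records.append(rec)
        with open(self.path, "a") as fh:
            fh.write(json.dumps(rec, sort_keys=True, default=_jsonable) + "\n")


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serializable: {type(o)}")


def seed_fixture(bundle, spacing_A: float) -> pd.DataFrame:
    """Seed every tube of a fixture; particle ids unique across tubes."""
    tables = []
    next_pid = 0
    for tube in bundle.tubes:
        t = seed_tube_surface(tube, spacing_A, bundle.manifest["voxel_size_A"])
        t["particle_id"] = np.arange(next_pid, next_pid + len(t))
        next_pid += len(t)
        tables.append(t)
    return pd.concat(tables, ignore_index=True)


def run_pipeline(config, seed: int | None = None, output_dir: str | None = None) -> dict:
    """Execute the full workflow described by ``config`` (path or dict).

    Returns a results dict; artifacts (tables, maps, FSC curves, metrics log)
    are written under the configured output directory.
    """
    cfg = io_formats.load_config(config) if not isinstance(config, dict) else dict(config)
    if seed is not None:
        cfg["seed"] = int(seed)
    if output_dir is not None:
        cfg["output_dir"] = str(output_dir)
    validate_config(cfg)
    out = Path(cfg["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "metrics.jsonl"
    log_path.unlink(missing_ok=True)
    log = _JsonlLog(log_path)
    rng_seed = int(cfg.get("seed", 1))

    # --- fixture ---------------------------------------------------------
    if "fixture_dir" in cfg and cfg["fixture_dir"]:
        fixture_dir = Path(cfg["fixture_dir"])
        if not (fixture_dir / "manifest.yaml").exists():
            fx = dict(cfg.get("fixture") or {})
            preset = fx.pop("preset", "small")
            make_fixture(preset, rng_seed, fixture_dir, overwrite=True, **fx)
    else:
        fixture_dir = out / "fixture"
        fx = dict(cfg.get("fixture") or {})
        preset = fx.pop("preset", "small")
        make_fixture(preset, rng_seed, fixture_dir, overwrite=True, **fx)
    bundle = load_fixture(fixture_dir)
    vx = bundle.manifest["voxel_size_A"]
    box = int(cfg.get("boxsize", bundle.manifest["boxsize"]))
    log.log("fixture", dir=str(fixture_dir), preset=bundle.manifest["preset"],
            voxel_size_A=vx, boxsize=box, n_tubes=len(bundle.tubes))

    # --- seeding ---------------------------------------------------------
    spacing = float(cfg.get("spacing_A", 44.0))
    seeds = seed_fixture(bundle, spacing)
    io_formats.write_particle_table(seeds, out / "seeds.tsv")
    log.log("seed", spacing_A=spacing, n_seeds=len(seeds))

    # --- subtomogram source with the composite Fourier mask ---------------
    mask = bundle.particle_mask(box)
    source = TomogramSource(bundle.tomograms, box, mask)

    # --- ab initio bootstrap ----------------------------------------------
    bcfg = cfg.get("bootstrap", {})
    ref, table, binfo = bootstrap_reference(
        seeds, source, vx, box,
        subset_fraction=float(bcfg.get("subset_fraction", 0.5)),
        angular_steps=tuple(bcfg.get("angular_steps", (8, 7, 6, 5, 4))),
        lowpass_A=bcfg.get("lowpass_A", 40.0),
        max_shift_vox=float(bcfg.get("max_shift_vox", 7.0)),
        seed=rng_seed,
    )
    log.log("bootstrap", **binfo)
    io_formats.write_volume(ref, out / "reference_bootstrap.mrc")
    io_formats.write_particle_table(table, out / "particles_bootstrap.tsv")

    # --- refinement (optionally independent half-sets) --------------------
    # The whole refinement runs in the seeding gauge (membrane mid-plane
    # through the box center); the arch-axis gauge is fixed afterwards, on the
    # sharp final averages.
    schedule = parse_schedule(cfg["schedule"])
    halfsets = bool(cfg.get("halfsets", False))
    real_mask = soft_sphere_mask(box)
    groups, averages, metrics, audit = run_refinement(
        table, source, ref, schedule, vx,
        halfsets=halfsets,
        dedup_distance_A=float(cfg.get("dedup_A", 55.0)),
        real_mask=real_mask,
    )
    for m in metrics:
        log.log("refine", **m)
    with open(out / "audit.jsonl", "w") as fh:
        for rec in audit:
            fh.write(json.dumps(rec, sort_keys=True) + "\n")

    # --- gauge: rotate/shift so the arch axis is +z and the arch centroid
    # the box center, per group, estimated on the final refined averages
    for g in list(groups):
        _ref2, t2, (r_g, s_g) = recenter_reference(averages[g].mean_map, groups[g])
        groups[g] = t2
        log.log("recenter", group=g, gauge_shift_vox=list(map(float, s_g)),
                gauge_angle_deg=float(np.rad2deg(np.arccos(
                    np.clip((np.trace(r_g) - 1) / 2, -1, 1)))))

    # --- cleaning ---------------------------------------------------------
    tomo_dims = {
        t["tomo_id"]: list(reversed(t["shape_zyx"]))  # (nx, ny, nz)
        for t in bundle.manifest["tomograms"]
    }
    cleaned = {}
    for g, t in groups.items():
        if cfg.get("cc_cutoff") is not None:
            t, rep = apply_cc_cutoff(t, cfg["cc_cutoff"])
            log.log("cc_cutoff", group=g, cutoff=rep.cc_cutoff_used,
                    n_in=rep.n_input, n_out=rep.n_after_cc_cut)
        if cfg.get("edge_exclude", True):
            t, rep = exclude_edge_particles(t, tomo_dims, box)
            log.log("edge_exclude", group=g, n_in=rep.n_input, n_out=rep.n_after_edge)
        if len(t) == 0:
            raise PipelineError(f"cleaning removed every particle in group {g!r}")
        cleaned[g] = t

    # --- final averages ----------------------------------------------------
    final_avg = {}
    for g, t in cleaned.items():
        avg = average_particles(t, source, real_mask=real_mask)
        final_avg[g] = avg
        io_formats.write_volume(avg.mean_map, out / f"average_{g}.mrc")
        io_formats.write_particle_table(t, out / f"particles_{g}.tsv")
    results: dict = {
        "n_seeds": int(len(seeds)),
        "n_final": {g: int(len(t)) for g, t in cleaned.items()},
        "mean_cc": {g: float(np.nanmean(t["cc_score"])) for g, t in cleaned.items()},
    }
    if halfsets and {"odd", "even"} <= set(final_avg):
        curve = fsc(final_avg["odd"].mean_map, final_avg["even"].mean_map,
                    real_mask=real_mask)
        est = resolution_at(curve, float(cfg.get("fsc_threshold", 0.143)))
        write_fsc_curve(curve, out / "fsc.tsv")
        results["fsc_resolution_A"] = est.resolution_A
        results["fsc_crossed"] = est.crossed
        log.log("fsc", resolution_A=est.resolution_A, crossed=est.crossed,
                threshold=est.threshold)

    combined = pd.concat(list(cleaned.values()), ignore_index=True)

    # --- classification (optional) ----------------------------------------
    ccfg = cfg.get("classify")
    if ccfg:
        g0 = next(iter(final_avg))
        stack = build_wmd_stack(combined, source, final_avg[g0].mean_map, real_mask)
        cls = pca_classify(stack, int(ccfg.get("n_components", 5)),
                           int(ccfg.get("k", 2)), seed=rng_seed)
        combined = combined.set_index("particle_id")
        combined.loc[cls.labels.index, "class_id"] = cls.labels.astype("Int64")
        combined = combined.reset_index()
        log.log("classify", k=int(ccfg.get("k", 2)),
                explained_variance=list(map(float, cls.explained_variance)))
        results["class_counts"] = {
            int(k): int(v) for k, v in cls.labels.value_counts().items()
        }

    # --- lattice statistics ------------------------------------------------
    tilt = arch_tilt_stats(combined, bundle.tubes, vx)
    neigh = neighbor_stats(combined, float(cfg.get("neighbor_radius_A", 120.0)),
                           vx, tubes=bundle.tubes)
    results["tilt_mean_deg"] = tilt.tilt_mean_deg
    results["tilt_sd_deg"] = tilt.tilt_sd_deg
    results["tilt_n"] = int(len(tilt.per_particle))
    results["modal_spacing_A"] = neigh.modal_spacing_A
    results["regularity_index"] = neigh.regularity_index
    log.log("lattice", tilt_mean_deg=tilt.tilt_mean_deg, tilt_sd_deg=tilt.tilt_sd_deg,
            n_excluded=tilt.n_excluded, modal_spacing_A=neigh.modal_spacing_A,
            regularity_index=neigh.regularity_index)
    io_formats.write_particle_table(combined, out / "particles_final.tsv")
    with open(out / "results.json", "w") as fh:
        json.dump(results, fh, indent=2, sort_keys=True, default=_jsonable)
    return results
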