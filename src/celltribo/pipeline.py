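"""End-to-end orchestration: simulate (optional) -> friction -> damage -> contact.

A run is described by a YAML configuration (see :func:`run_pipeline`); the
result is a :class:`ReportBundle` of tidy tables plus a provenance block
(config hash, seed, package version) sufficient for an exact rerun.  Stage
failures are collected into a manifest and reported, never silently
dropped.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import __version__
from .contact import MATERIALS, SphereProbe, pressure_sweep
from .damage import DetectionParams, RegionLayout, batch_damage
from .friction import batch_friction, summarize_by_condition
from .io import IOError_, read_image_pair, read_trace, write_image_pair, write_trace
from .synthetic import ImageScenario, TraceScenario, generate_experiment_set

log = logging.getLogger(__name__)

__all__ = ["ReportBundle", "run_pipeline"]


@dataclass
class ReportBundle:
    """Aggregated results of one pipeline run."""

    friction_table: pd.DataFrame
    friction_summary: pd.DataFrame
    amonton: dict[str, float]
    damage_table: pd.DataFrame
    damage_summary: pd.DataFrame
    contact_table: pd.DataFrame
    failures: list[tuple[str, str]]
    provenance: dict

    @property
    def results_hash(self) -> str:
        """Hash over the result tables only (provenance timestamps excluded)."""
        h = hashlib.sha256()
        for frame in (self.friction_table, self.friction_summary,
                      self.damage_table, self.damage_summary, self.contact_table):
            h.update(frame.round(12).to_csv(index=False).encode())
        h.update(json.dumps(self.amonton, sort_keys=True).encode())
        return h.hexdigest()

    def write(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.friction_table.to_csv(out / "friction_per_slide.csv", index=False)
        self.friction_summary.to_csv(out / "friction_summary.csv", index=False)
        self.damage_table.to_csv(out / "damage_per_slide.csv", index=False)
        self.damage_summary.to_csv(out / "damage_summary.csv", index=False)
        self.contact_table.to_csv(out / "contact_pressures.csv", index=False)
        report = {
            "amonton_fits": self.amonton,
            "failures": [list(f) for f in self.failures],
            "results_hash": self.results_hash,
            "provenance": self.provenance,
        }
        (out / "report.yaml").write_text(yaml.safe_dump(report, sort_keys=False))
        return out


def _config_hash(config: Mapping) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()


def _scenario_from(cls, overrides: Mapping | None):
    overrides = dict(overrides or {})
    if "image_size" in overrides:
        overrides["image_size"] = tuple(overrides["image_size"])
    return cls(**overrides)


def run_pipeline(config: Mapping, out_dir: str | Path | None = None) -> ReportBundle:
    """Run the configured stages and return a :class:`ReportBundle`.

    Configuration keys (all optional unless noted):

    - ``seed``: base seed for any simulation (default 0).
    - ``simulate``: ``{forces, repeats, trace: {...}, image: {...},
      damage_by_force: {F: [p_remove, p_dead]}, include_images}`` —
      generates the inputs in memory (and writes them under
      ``out_dir/simulated`` when an output directory is given).
    - ``traces``: ``{path, glob}`` — read trace CSVs instead of simulating.
    - ``images``: ``{path, glob}`` — read ``*_blue.tif`` pairs.
    - ``layout``: ``{track_width, track_center_y, ref_offset_factor}``
      for the damage regions (sidecar hints fill missing values).
    - ``detection``: :class:`DetectionParams` overrides.
    - ``contact``: ``{forces, pairings: [[label, R_mm, probe, substrate]]}``
      with material names from the built-in table.
    """
    config = dict(config)
    seed = int(config.get("seed", 0))
    failures: list[tuple[str, str]] = []

    traces: list[tuple[str, object]] = []
    image_jobs: list[tuple[str, object, object, float, RegionLayout, float]] = []
    det = DetectionParams(**config.get("detection", {}))
    layout_cfg = dict(config.get("layout", {}))

    sim_cfg = config.get("simulate")
    if sim_cfg:
        trace_scn = _scenario_from(TraceScenario, sim_cfg.get("trace"))
        image_scn = _scenario_from(ImageScenario, sim_cfg.get("image"))
        damage_map = sim_cfg.get("damage_by_force")
        if damage_map is not None:
            damage_map = {float(k): tuple(v) for k, v in damage_map.items()}
        records = generate_experiment_set(
            forces=sim_cfg["forces"],
            repeats=int(sim_cfg.get("repeats", 1)),
            trace_template=trace_scn,
            image_template=image_scn,
            damage_by_force=damage_map,
            seed=seed,
            include_images=bool(sim_cfg.get("include_images", True)),
        )
        sim_dir = Path(out_dir) / "simulated" if out_dir else None
        for rec in records:
            label = f"F{rec.f_n:g}_r{rec.repeat}"
            traces.append((label, rec.trace))
            if sim_dir is not None:
                write_trace(sim_dir / f"{label}.csv", rec.trace,
                            dataclasses.asdict(rec.trace_truth))
            if rec.blue is not None:
                scn = rec.image_scenario
                layout = RegionLayout.default(
                    scn.image_size, scn.pixel_size,
                    layout_cfg.get("track_center_y", scn.center_y),
                    layout_cfg.get("track_width", scn.track_width),
                    ref_offset_factor=layout_cfg.get("ref_offset_factor", 3.0),
                )
                image_jobs.append(
                    (label, rec.blue, rec.red, scn.pixel_size, layout, rec.f_n)
                )
                if sim_dir is not None:
                    write_image_pair(
                        sim_dir / label, rec.blue, rec.red, scn.pixel_size,
                        meta={"f_n_mN": rec.f_n,
                              "track_width_um": scn.track_width,
                              "track_center_y_um": scn.center_y},
                    )

    trace_cfg = config.get("traces")
    if trace_cfg:
        base = Path(trace_cfg["path"])
        for p in sorted(base.glob(trace_cfg.get("glob", "*.csv"))):
            try:
                traces.append((p.stem, read_trace(
                    p,
                    column_map=trace_cfg.get("column_map"),
                    unit_scale=trace_cfg.get("unit_scale"),
                )))
            except IOError_ as exc:
                failures.append((p.name, str(exc)))

    image_cfg = config.get("images")
    if image_cfg:
        base = Path(image_cfg["path"])
        for blue_path in sorted(base.glob(image_cfg.get("glob", "*_blue.tif"))):
            stem = blue_path.name[: -len("_blue.tif")]
            red_path = blue_path.parent / f"{stem}_red.tif"
            try:
                blue, red, meta = read_image_pair(blue_path, red_path)
                px = float(meta["pixel_size_um"])
                width = layout_cfg.get("track_width", meta.get("track_width_um"))
                center = layout_cfg.get("track_center_y",
                                        meta.get("track_center_y_um"))
                if width is None or center is None:
                    raise IOError_("track geometry missing (config or sidecar)")
                layout = RegionLayout.default(
                    blue.shape, px, float(center), float(width),
                    ref_offset_factor=layout_cfg.get("ref_offset_factor", 3.0),
                )
                image_jobs.append(
                    (stem, blue, red, px, layout, float(meta.get("f_n_mN", 0)))
                )
            except (IOError_, KeyError, ValueError) as exc:
                failures.append((blue_path.name, str(exc)))

    # ---- friction stage
    friction_table, fits, friction_failures = batch_friction(traces)
    failures.extend(friction_failures)
    friction_summary = summarize_by_condition(friction_table)
    amonton = {name: fit.mu for name, fit in fits.items()}

    # ---- damage stage
    if image_jobs:
        damage_table, damage_summary, damage_failures = batch_damage(
            image_jobs, params=det
        )
        failures.extend(damage_failures)
    else:
        damage_table, damage_summary = pd.DataFrame(), pd.DataFrame()
        if config.get("images"):
            failures.append(("damage", "no image pairs available"))
        else:
            log.info("no images configured; damage stage skipped")

    # ---- contact stage
    contact_cfg = config.get("contact")
    if contact_cfg:
        pairings = []
        for label, r_mm, probe_mat, substrate in contact_cfg["pairings"]:
            pairings.append(
                (label, SphereProbe(R=float(r_mm)),
                 MATERIALS[probe_mat], MATERIALS[substrate])
            )
        contact_table = pressure_sweep(contact_cfg["forces"], pairings)
    else:
        contact_table = pd.DataFrame()

    provenance = {
        "config_hash": _config_hash(config),
        "seed": seed,
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    bundle = ReportBundle(
        friction_table=friction_table,
        friction_summary=friction_summary,
        amonton=amonton,
        damage_table=damage_table,
        damage_summary=damage_summary,
        contact_table=contact_table,
        failures=failures,
        provenance=provenance,
    )
    if out_dir is not None:
        bundle.write(out_dir)
    return bundle
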