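"""Readers and writers for traces, image pairs and run configuration.

Traces travel as plain CSV with the header ``time_s,x_mm,h_mm,fx_mN,fz_mN``
plus an optional YAML sidecar for metadata/ground truth; images as
single-channel 16-bit grayscale TIFFs with ``_blue.tif`` / ``_red.tif``
suffixes and a YAML sidecar recording the pixel size, track-geometry hint
and normal-force label.  Readers validate rather than coerce: missing
columns, non-monotone time, NaN runs and unit ambiguity are explicit
errors, never silent guesses.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile
import yaml

from .friction import TraceError, TribometerTrace

log = logging.getLogger(__name__)

__all__ = [
    "TRACE_COLUMNS",
    "IOError_",
    "read_trace",
    "write_trace",
    "read_image_pair",
    "write_image_pair",
    "load_config",
]

#: Canonical trace CSV columns (field -> column name).
TRACE_COLUMNS: dict[str, str] = {
    "t": "time_s",
    "x": "x_mm",
    "h_m": "h_mm",
    "fx": "fx_mN",
    "fz": "fz_mN",
}


class IOError_(ValueError):
    """Raised for malformed input files."""


def read_trace(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    unit_scale: Mapping[str, float] | None = None,
    meta: Mapping | None = None,
    max_nan_run: int = 0,
) -> TribometerTrace:
    """Read one trace CSV, optionally remapping another export dialect.

    Parameters
    ----------
    column_map : field -> column name, for tribometers whose export headers
        differ from the canonical contract (fields: t, x, h_m, fx, fz).
    unit_scale : field -> multiplicative factor into the canonical units
        (s, mm, mN); e.g. ``{"fx": 1e-3}`` for a column recorded in uN.
    max_nan_run : longest tolerated run of missing samples per column
        (interpolated); anything longer is an error naming the column.
    """
    path = Path(path)
    if not path.exists():
        raise IOError_(f"trace file not found: {path}")
    frame = pd.read_csv(path, float_precision="round_trip")
    cmap = dict(TRACE_COLUMNS)
    cmap.update(column_map or {})
    missing = [col for col in cmap.values() if col not in frame.columns]
    if missing:
        raise IOError_(f"{path.name}: missing column(s) {missing}")

    scale = {k: 1.0 for k in cmap}
    scale.update(unit_scale or {})
    data = {}
    for fld, col in cmap.items():
        series = pd.to_numeric(frame[col], errors="coerce") * scale[fld]
        if series.isna().any():
            runs = series.isna().astype(int).groupby(series.notna().cumsum()).sum()
            longest = int(runs.max())
            if longest > max_nan_run:
                raise IOError_(
                    f"{path.name}: column '{col}' has a NaN run of {longest} "
                    f"samples (tolerance {max_nan_run})"
                )
            series = series.interpolate(limit_direction="both")
        data[fld] = series.to_numpy(dtype=float)
    if not np.all(np.diff(data["t"]) > 0):
        raise IOError_(f"{path.name}: time column is not strictly increasing")

    sidecar = path.with_suffix(".yaml")
    file_meta: dict = {}
    if sidecar.exists():
        file_meta = yaml.safe_load(sidecar.read_text()) or {}
    if meta:
        file_meta.update(meta)
    try:
        return TribometerTrace(meta=file_meta, **data)
    except TraceError as exc:
        raise IOError_(f"{path.name}: {exc}") from exc


def write_trace(
    path: str | Path, trace: TribometerTrace, ground_truth: Mapping | None = None
) -> Path:
    """Write a trace as canonical CSV (+ YAML sidecar for meta/ground truth)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    # %.17g guarantees bit-exact float round-trips through text
    trace.to_frame().to_csv(path, index=False, float_format="%.17g")
    sidecar_data = {k: v for k, v in trace.meta.items()}
    if ground_truth is not None:
        sidecar_data["ground_truth"] = dict(ground_truth)
    if sidecar_data:
        path.with_suffix(".yaml").write_text(
            yaml.safe_dump(_yaml_ready(sidecar_data), sort_keys=False)
        )
    return path


def _yaml_ready(obj):
    """Convert numpy scalars/arrays so YAML stays plain."""
    if isinstance(obj, dict):
        return {k: _yaml_ready(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_yaml_ready(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_image_pair(
    stem: str | Path,
    blue: np.ndarray,
    red: np.ndarray,
    pixel_size_um: float,
    meta: Mapping | None = None,
) -> tuple[Path, Path]:
    """Write ``<stem>_blue.tif`` / ``<stem>_red.tif`` plus a YAML sidecar."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    blue_path = stem.parent / f"{stem.name}_blue.tif"
    red_path = stem.parent / f"{stem.name}_red.tif"
    tifffile.imwrite(blue_path, np.asarray(blue, dtype=np.uint16))
    tifffile.imwrite(red_path, np.asarray(red, dtype=np.uint16))
    sidecar = {"pixel_size_um": float(pixel_size_um)}
    sidecar.update(_yaml_ready(dict(meta or {})))
    (stem.parent / f"{stem.name}.yaml").write_text(
        yaml.safe_dump(sidecar, sort_keys=False)
    )
    return blue_path, red_path


def read_image_pair(
    blue_path: str | Path,
    red_path: str | Path,
    sidecar: str | Path | Mapping | None = None,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Load a blue/red TIFF pair and its metadata.

    The sidecar (path to YAML, or an already-loaded mapping) must provide
    ``pixel_size_um``; mismatched image dimensions are an error.
    """
    blue_path, red_path = Path(blue_path), Path(red_path)
    for p in (blue_path, red_path):
        if not p.exists():
            raise IOError_(f"image not found: {p}")
    blue = tifffile.imread(blue_path)
    red = tifffile.imread(red_path)
    if blue.shape != red.shape:
        raise IOError_(
            f"channel dimension mismatch: {blue.shape} vs {red.shape}"
        )
    if isinstance(sidecar, (str, Path)):
        meta = yaml.safe_load(Path(sidecar).read_text()) or {}
    elif sidecar is None:
        guess = blue_path.parent / (blue_path.name.replace("_blue.tif", "") + ".yaml")
        meta = yaml.safe_load(guess.read_text()) if guess.exists() else {}
    else:
        meta = dict(sidecar)
    if "pixel_size_um" not in meta:
        raise IOError_("pixel size missing from image metadata")
    if float(np.ptp(blue)) == 0 and float(np.ptp(red)) == 0:
        log.warning("both channels are blank: %s", blue_path.name)
    return blue, red, meta


def load_config(path: str | Path) -> dict:
    """Load a YAML run configuration; referenced paths must exist."""
    path = Path(path)
    if not path.exists():
        raise IOError_(f"config not found: {path}")
    cfg = yaml.safe_load(path.read_text()) or {}
    for key in ("traces", "images"):
        base = cfg.get(key, {}).get("path")
        if base is not None and not Path(base).exists():
            raise IOError_(f"configured {key} path does not exist: {base}")
    return cfg
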