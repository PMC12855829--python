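"""Readers and writers for the pipeline's on-disk artifacts.

All tabular artifacts are CSV (small at desk scale, auditable, diffable);
frames are 8-bit grayscale PNG named ``{profile_id}_{frame_index:05d}.png``
with a per-profile sidecar CSV keeping the depth/time metadata in sync.
Floats round-trip through 12 significant digits.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .imaging import DETECTION_COLUMNS, Frame

__all__ = [
    "SchemaError",
    "write_table",
    "read_table",
    "write_frames",
    "read_frames",
    "write_light_profile",
    "write_manifest",
    "read_manifest",
    "DETECTION_SCHEMA",
    "BIN_SCHEMA",
    "TRUTH_SCHEMA",
    "LIGHT_SCHEMA",
]

_FLOAT_FORMAT = "%.12g"

DETECTION_SCHEMA = tuple(DETECTION_COLUMNS)
BIN_SCHEMA = (
    "profile_id", "time", "taxon", "size_class", "bin_index", "bin_mid_depth",
    "density", "sampled_volume_L", "illuminance_lx", "temperature_C", "chl_a_ugL",
)
TRUTH_SCHEMA = (
    "profile_id", "taxon", "depth_m", "esd_true_mm", "lateral_mm",
    "axis_ratio", "antenna", "size_class",
)
LIGHT_SCHEMA = (
    "profile_id", "bin_index", "bin_mid_depth_m", "illuminance_lx",
    "irradiance_w_m2", "photon_flux_umol",
)
FRAME_SIDECAR_SCHEMA = ("frame_index", "top_depth_m", "time_utc", "pixel_pitch_mm")


class SchemaError(ValueError):
    """A table's header does not match its documented schema."""


def _check_schema(df: pd.DataFrame, schema: tuple[str, ...], name: str) -> None:
    missing = [c for c in schema if c not in df.columns]
    unexpected = [c for c in df.columns if c not in schema]
    if missing or unexpected:
        raise SchemaError(
            f"{name}: missing columns {missing or 'none'}, unexpected columns {unexpected or 'none'}"
        )


def write_table(df: pd.DataFrame, path: str | Path, schema: tuple[str, ...] | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = df
    if schema is not None:
        _check_schema(df, schema, path.name)
        out = df[list(schema)]
    out.to_csv(path, index=False, float_format=_FLOAT_FORMAT)
    return path


def read_table(path: str | Path, schema: tuple[str, ...] | None = None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"missing expected table {path}")
    df = pd.read_csv(path)
    if schema is not None:
        _check_schema(df, schema, path.name)
    return df


# ---------------------------------------------------------------------------
# Frames
# ---------------------------------------------------------------------------

def write_frames(frames: list[Frame], outdir: str | Path) -> Path:
    """PNG per frame plus one sidecar CSV per profile; returns the sidecar path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not frames:
        raise ValueError("no frames to write")
    profile_id = frames[0].profile_id
    records = []
    for f in frames:
        if f.profile_id != profile_id:
            raise ValueError("write_frames expects frames from a single profile")
        name = f"{f.profile_id}_{f.frame_index:05d}.png"
        iio.imwrite(outdir / name, f.pixels.astype(np.uint8))
        records.append(
            {
                "frame_index": f.frame_index,
                "top_depth_m": f.top_depth_m,
                "time_utc": f.time.isoformat() if f.time is not None else "",
                "pixel_pitch_mm": f.pixel_pitch_mm,
            }
        )
    sidecar = outdir / f"{profile_id}_frames.csv"
    pd.DataFrame(records).to_csv(sidecar, index=False, float_format=_FLOAT_FORMAT)
    return sidecar


def read_frames(outdir: str | Path, profile_id: str) -> list[Frame]:
    """Rebuild a profile's Frame list from PNGs and their sidecar."""
    outdir = Path(outdir)
    sidecar = outdir / f"{profile_id}_frames.csv"
    if not sidecar.exists():
        raise FileNotFoundError(f"missing expected frame sidecar {sidecar}")
    meta = pd.read_csv(sidecar)
    _check_schema(meta, FRAME_SIDECAR_SCHEMA, sidecar.name)
    frames = []
    for rec in meta.itertuples(index=False):
        png = outdir / f"{profile_id}_{int(rec.frame_index):05d}.png"
        if not png.exists():
            raise FileNotFoundError(f"sidecar lists frame {rec.frame_index} but {png} is missing")
        frames.append(
            Frame(
                pixels=iio.imread(png),
                pixel_pitch_mm=float(rec.pixel_pitch_mm),
                top_depth_m=float(rec.top_depth_m),
                profile_id=profile_id,
                frame_index=int(rec.frame_index),
            )
        )
    return frames


# ---------------------------------------------------------------------------
# Light profiles and manifests
# ---------------------------------------------------------------------------

def write_light_profile(light, profile_id: str, path: str | Path, append: bool = False) -> Path:
    """Light-profile CSV with photometric and radiometric columns."""
    from .lightfield import irradiance_to_photon_flux, lux_to_irradiance

    lx = np.asarray(light.illuminance_lx, float)
    w = lux_to_irradiance(lx, light.wavelength_nm)
    flux = irradiance_to_photon_flux(w, light.wavelength_nm)
    df = pd.DataFrame(
        {
            "profile_id": profile_id,
            "bin_index": np.arange(light.n_bins),
            "bin_mid_depth_m": light.bin_mid_depth,
            "illuminance_lx": lx,
            "irradiance_w_m2": w,
            "photon_flux_umol": flux,
        }
    )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if append and path.exists():
        df.to_csv(path, mode="a", header=False, index=False, float_format=_FLOAT_FORMAT)
    else:
        df.to_csv(path, index=False, float_format=_FLOAT_FORMAT)
    return path


def write_manifest(config_dict: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(_jsonable(config_dict), fh, sort_keys=True)
    return path


def read_manifest(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _jsonable(obj):
    try:
        json.dumps(obj)
        return obj
    except TypeError:
        pass
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)
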