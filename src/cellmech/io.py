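"""Readers and writers for the package's plain-text/TIFF formats.

Force-volume container: ``header.json`` (probe parameters, grid shape,
pixel size, units) plus ``curves.csv`` in long format with columns
pixel_row, pixel_col, z_nm, force_pN.  Images and masks are multi-page
TIFF with a JSON sidecar carrying channel names and pixel size.  Traction
fields and tracks are tidy CSVs.  All JSON is written with sorted keys and
CSVs with a fixed dialect (UTF-8, comma, '.' decimal) so that identical
inputs produce byte-identical files.

Pixel coordinates are 0-based (row, col) with the origin at the top left;
physical coordinates are in um.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .coloc import ImageStack
from .forcevolume import ForceCurve, ForceVolumeMap, ProbeParams
from .quantify import TractionField, Track

__all__ = [
    "FormatError",
    "write_force_volume",
    "read_force_volume",
    "write_image_stack",
    "read_image_stack",
    "write_mask",
    "read_mask",
    "write_traction_field",
    "read_traction_field",
    "write_tracks",
    "read_tracks",
    "write_manifest",
]

FORCE_VOLUME_UNITS = {"z": "nm", "force": "pN", "pixel_size": "um"}


class FormatError(ValueError):
    """A file does not conform to the package's container formats."""


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def write_force_volume(fv: ForceVolumeMap, out_dir: str | Path) -> Path:
    """Write header.json + curves.csv; returns the directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows, cols = fv.shape
    probe = fv.curve(0, 0).probe
    header = {
        "format": "cellmech-force-volume-v1",
        "grid_shape": [rows, cols],
        "pixel_size_um": fv.pixel_size_um,
        "probe": dataclasses.asdict(probe),
        "units": FORCE_VOLUME_UNITS,
    }
    _dump_json(header, out_dir / "header.json")
    frames = []
    for r in range(rows):
        for c in range(cols):
            curve = fv.curve(r, c)
            frames.append(
                pd.DataFrame(
                    {
                        "pixel_row": r,
                        "pixel_col": c,
                        "z_nm": curve.z_nm,
                        "force_pN": curve.force_pn,
                    }
                )
            )
    pd.concat(frames, ignore_index=True).to_csv(
        out_dir / "curves.csv", index=False, float_format="%.17g"
    )
    return out_dir


def read_force_volume(path: str | Path) -> ForceVolumeMap:
    """Read the header.json + curves.csv container back into a map."""
    path = Path(path)
    header_path = path / "header.json"
    curves_path = path / "curves.csv"
    if not header_path.exists() or not curves_path.exists():
        raise FormatError(f"{path} is not a force-volume container")
    header = json.loads(header_path.read_text(encoding="utf-8"))
    units = header.get("units", {})
    if units != FORCE_VOLUME_UNITS:
        raise FormatError(f"unit mismatch: expected {FORCE_VOLUME_UNITS}, got {units}")
    rows, cols = header["grid_shape"]
    probe = ProbeParams(**header["probe"])
    table = pd.read_csv(curves_path, float_precision="round_trip")
    expected_cols = {"pixel_row", "pixel_col", "z_nm", "force_pN"}
    if set(table.columns) != expected_cols:
        raise FormatError(f"curves.csv columns {sorted(table.columns)} != {sorted(expected_cols)}")
    grouped = dict(tuple(table.groupby(["pixel_row", "pixel_col"], sort=True)))
    missing = [
        (r, c) for r in range(rows) for c in range(cols) if (r, c) not in grouped
    ]
    if missing:
        raise FormatError(f"missing pixels in curves.csv: {missing[:10]}")
    curves = []
    for r in range(rows):
        row_curves = []
        for c in range(cols):
            g = grouped[(r, c)]
            try:
                curve = ForceCurve(
                    g["z_nm"].to_numpy(), g["force_pN"].to_numpy(), probe, pixel=(r, c)
                )
            except ValueError as exc:
                raise FormatError(f"bad curve at pixel ({r}, {c}): {exc}") from exc
            row_curves.append(curve)
        curves.append(row_curves)
    return ForceVolumeMap(curves=curves, pixel_size_um=header["pixel_size_um"])


def write_image_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a multi-page TIFF plus a JSON sidecar with channel names."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    names = list(stack.channels)
    data = np.stack([stack.channels[n] for n in names]).astype(np.float32)
    axes = "CYX" if data.ndim == 3 else "CZYX"
    tifffile.imwrite(path, data, photometric="minisblack")
    sidecar = {
        "channels": names,
        "pixel_size_um": stack.pixel_size_um,
        "axes": axes,
        "bit_depth": stack.bit_depth,
    }
    _dump_json(sidecar, path.with_suffix(".json"))
    return path


def read_image_stack(path: str | Path) -> ImageStack:
    """Read a multi-page TIFF; channel names from the sidecar if present."""
    path = Path(path)
    data = np.asarray(tifffile.imread(path))
    sidecar_path = path.with_suffix(".json")
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text(encoding="utf-8"))
        names = sidecar["channels"]
        pixel_size = sidecar.get("pixel_size_um", 1.0)
        bit_depth = sidecar.get("bit_depth")
        if data.ndim == 2:
            data = data[None]
        if len(names) != data.shape[0]:
            raise FormatError(
                f"sidecar lists {len(names)} channels but TIFF has {data.shape[0]} pages"
            )
    else:
        import warnings

        if data.ndim == 2:
            data = data[None]
        names = [f"ch{i}" for i in range(data.shape[0])]
        pixel_size, bit_depth = 1.0, None
        warnings.warn(f"no sidecar for {path}; channels auto-named {names}")
    channels = {name: data[i].astype(float) for i, name in enumerate(names)}
    return ImageStack(channels=channels, pixel_size_um=pixel_size, bit_depth=bit_depth)


def write_mask(mask: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(mask, dtype=np.uint8))
    return path


def read_mask(path: str | Path) -> np.ndarray:
    return np.asarray(tifffile.imread(path)) > 0


def write_traction_field(fieldobj: TractionField, out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows, cols = fieldobj.tx_pa.shape
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    pd.DataFrame(
        {
            "row": rr.ravel(),
            "col": cc.ravel(),
            "tx_pa": fieldobj.tx_pa.ravel(),
            "ty_pa": fieldobj.ty_pa.ravel(),
            "in_mask": fieldobj.cell_mask.ravel().astype(int),
        }
    ).to_csv(out_dir / "traction.csv", index=False, float_format="%.17g")
    _dump_json(
        {
            "format": "cellmech-traction-v1",
            "grid_shape": [rows, cols],
            "grid_spacing_um": fieldobj.grid_spacing_um,
        },
        out_dir / "traction.json",
    )
    return out_dir


def read_traction_field(path: str | Path) -> TractionField:
    path = Path(path)
    meta = json.loads((path / "traction.json").read_text(encoding="utf-8"))
    table = pd.read_csv(path / "traction.csv", float_precision="round_trip")
    rows, cols = meta["grid_shape"]
    if len(table) != rows * cols:
        raise FormatError(f"traction.csv has {len(table)} rows, expected {rows * cols}")
    tx = np.zeros((rows, cols))
    ty = np.zeros((rows, cols))
    mask = np.zeros((rows, cols), dtype=bool)
    r = table["row"].to_numpy()
    c = table["col"].to_numpy()
    tx[r, c] = table["tx_pa"].to_numpy()
    ty[r, c] = table["ty_pa"].to_numpy()
    mask[r, c] = table["in_mask"].to_numpy() > 0
    return TractionField(tx, ty, meta["grid_spacing_um"], mask)


def write_tracks(tracks: list[Track], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frames = [
        pd.DataFrame(
            {"label": t.label, "t_s": t.t_s, "x_um": t.x_um, "y_um": t.y_um}
        )
        for t in tracks
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.17g")
    return path


def read_tracks(path: str | Path) -> list[Track]:
    table = pd.read_csv(path, float_precision="round_trip")
    tracks = []
    for label, g in table.groupby("label", sort=True):
        g = g.sort_values("t_s")
        tracks.append(
            Track(
                t_s=g["t_s"].to_numpy(),
                x_um=g["x_um"].to_numpy(),
                y_um=g["y_um"].to_numpy(),
                label=label,
            )
        )
    return tracks


def write_manifest(path: str | Path, stage: str, params: dict, seed: int | None) -> Path:
    """Machine-readable run manifest: stage, parameters and seed.

    Deliberately excludes timestamps so reruns are byte-identical.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    _dump_json({"stage": stage, "seed": seed, "params": params}, path)
    return path
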