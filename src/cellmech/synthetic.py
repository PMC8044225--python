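"""Synthetic ground-truth generators for every pipeline input.

Each generator returns its dataset together with a :class:`SyntheticTruth`
record holding the exact quantities the analysis is supposed to recover
(true modulus/height maps, true overlap fractions, true total force, true
contact durations).  All generators are bit-reproducible for a fixed seed
and parameter set.

The defaults mirror the acquisition conditions of the study this package
quantifies: a 35 nm paraboloidal tip on a 0.068 N/m cantilever with a
400 pN trigger for force-volume scans, ~kPa-soft dome-shaped cells on a
rigid (MPa) plastic dish, diffraction-blurred vesicle puncta, traction
fields localized under a cell mask, and 1-s-interval vesicle movies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .contact import contact_force, indentation_at_force, solve_indentation
from .coloc import ImageStack
from .forcevolume import ForceCurve, ForceVolumeMap, ProbeParams
from .quantify import TractionField

__all__ = [
    "ProbeParams",
    "VirtualCell",
    "SyntheticTruth",
    "PlacementError",
    "make_virtual_cell",
    "simulate_force_curve",
    "simulate_force_volume",
    "simulate_coloc_stack",
    "simulate_traction_field",
    "simulate_vesicle_movie",
]


@dataclass
class VirtualCell:
    """Ground-truth dome-shaped cell on a rigid substrate.

    height_map_um is the local sample thickness h (0 exactly on substrate
    pixels); modulus_map_pa the true apparent modulus per pixel.
    """

    height_map_um: np.ndarray
    modulus_map_pa: np.ndarray
    substrate_modulus_pa: float
    pixel_size_um: float

    def __post_init__(self):
        if self.height_map_um.shape != self.modulus_map_pa.shape:
            raise ValueError("height and modulus maps must share shape")
        if np.any(self.height_map_um < 0):
            raise ValueError("heights must be >= 0")

    @property
    def substrate_mask(self) -> np.ndarray:
        return self.height_map_um == 0


@dataclass
class SyntheticTruth:
    """Ground truth paired with a generated dataset."""

    kind: str  # force_volume | coloc_stack | traction | vesicle_movie
    payload: dict[str, Any]
    seed: int


class PlacementError(RuntimeError):
    """Vesicles could not be placed without violating separation rules."""


def make_virtual_cell(
    shape: tuple[int, int] = (32, 32),
    cell_radius_um: float = 25.0,
    max_height_um: float = 5.0,
    e_cell_pa: float = 10e3,
    e_periphery_factor: float = 1.6,
    pixel_size_um: float = 1.875,
    seed: int = 0,
    periphery_height_um: float = 2.0,
    substrate_modulus_pa: float = 1e6,
) -> VirtualCell:
    """Spherical-cap cell: height profile of a cap of base radius
    ``cell_radius_um`` and apex ``max_height_um`` centered in the grid,
    zero outside.  The modulus is ``e_cell_pa`` in the tall region and
    ``e_cell_pa * e_periphery_factor`` in the thin periphery (height below
    ``periphery_height_um``); substrate pixels get ``substrate_modulus_pa``.
    Fully deterministic; the seed is only recorded alongside.
    """
    if max_height_um <= 0 or cell_radius_um <= 0 or pixel_size_um <= 0:
        raise ValueError("dimensions must be positive")
    rows, cols = shape
    half_extent = (min(rows, cols) / 2.0) * pixel_size_um
    if cell_radius_um > half_extent:
        raise ValueError("cell does not fit in the grid")
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    cy, cx = (rows - 1) / 2.0, (cols - 1) / 2.0
    r_um = np.hypot(rr - cy, cc - cx) * pixel_size_um
    # sphere radius for a cap of base radius a and apex height hmax
    a, hmax = cell_radius_um, max_height_um
    r_sphere = (a**2 + hmax**2) / (2.0 * hmax)
    inside = r_um < a
    height = np.zeros(shape, dtype=float)
    height[inside] = np.sqrt(np.maximum(r_sphere**2 - r_um[inside] ** 2, 0.0)) - (r_sphere - hmax)
    height = np.maximum(height, 0.0)

    modulus = np.full(shape, substrate_modulus_pa, dtype=float)
    cell = height > 0
    modulus[cell] = e_cell_pa
    modulus[cell & (height < periphery_height_um)] = e_cell_pa * e_periphery_factor
    return VirtualCell(height, modulus, substrate_modulus_pa, pixel_size_um)


def simulate_force_curve(
    e_true_pa: float,
    h_um: float,
    probe: ProbeParams | None = None,
    baseline_slope_pn_per_nm: float = 0.0,
    noise_sd_pn: float = 10.0,
    n_points: int = 512,
    seed: int = 0,
    z0_nm: float = 0.0,
    rng: np.random.Generator | None = None,
    pixel: tuple[int, int] | None = None,
) -> ForceCurve:
    """Simulate one approach force-distance curve.

    The contact branch obeys the bottom-effect-corrected Hertz law with the
    cantilever-deflection coupling delta = (z - z0) - F/k solved implicitly
    per sample; a linear virtual-deflection baseline (slope in pN/nm of z)
    and additive Gaussian force noise are superimposed, and the sweep is
    sized so the contact force reaches the probe's trigger force at the last
    sample.  Half of the samples lie before contact.

    ``h_um`` is the local sample thickness; ``np.inf`` means a thick/rigid
    location with no bottom effect (use the substrate modulus there).
    """
    if noise_sd_pn < 0:
        raise ValueError("noise_sd_pn must be >= 0")
    if n_points < 16:
        raise ValueError("n_points must be >= 16")
    if not (h_um > 0):  # also rejects NaN
        raise ValueError("h_um must be > 0 (np.inf for substrate)")
    probe = probe or ProbeParams()
    rng = rng if rng is not None else np.random.default_rng(seed)

    r_m = probe.tip_radius_nm * 1e-9
    nu = probe.poisson_ratio
    k_si = probe.spring_constant_n_per_m
    h_m = np.inf if np.isinf(h_um) else h_um * 1e-6
    f_trig_n = probe.trigger_force_pn * 1e-12

    delta_trig_m = indentation_at_force(f_trig_n, e_true_pa, nu, r_m, h_m)
    # z travel past contact includes the cantilever deflection at trigger
    span_nm = delta_trig_m * 1e9 + probe.trigger_force_pn / probe.spring_constant_pn_per_nm
    z = np.linspace(z0_nm - span_nm, z0_nm + span_nm, n_points)

    z_rel_m = np.maximum(z - z0_nm, 0.0) * 1e-9
    delta_m = solve_indentation(z_rel_m, e_true_pa, nu, r_m, k_si, h_m)
    force_pn = contact_force(delta_m, e_true_pa, nu, r_m, h_m) * 1e12
    force_pn = force_pn + baseline_slope_pn_per_nm * (z - z[0])
    if noise_sd_pn > 0:
        force_pn = force_pn + rng.normal(0.0, noise_sd_pn, size=n_points)
    return ForceCurve(z_nm=z, force_pn=force_pn, probe=probe, pixel=pixel)


def simulate_force_volume(
    cell: VirtualCell,
    probe: ProbeParams | None = None,
    noise_sd_pn: float = 10.0,
    seed: int = 0,
    n_points: int = 512,
    baseline_slope_pn_per_nm: float = 0.0,
    tilt_nm_per_px: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> tuple[ForceVolumeMap, SyntheticTruth]:
    """One simulated approach curve per pixel of a virtual cell.

    Substrate pixels (height 0) are simulated with the substrate modulus and
    no bottom effect; cell pixels with their true modulus and thickness.
    The contact point encodes topography plus an optional stage-tilt plane:
    z0 = a*row + b*col + c - height, i.e. the tip meets taller sample
    earlier.  Truth carries the exact modulus, height and z0 maps.
    """
    probe = probe or ProbeParams()
    rng = np.random.default_rng(seed)
    rows, cols = cell.height_map_um.shape
    a_t, b_t, c_t = tilt_nm_per_px
    curves: list[list[ForceCurve]] = []
    z0_map = np.zeros((rows, cols))
    for r in range(rows):
        row_curves = []
        for c in range(cols):
            h = cell.height_map_um[r, c]
            z0 = a_t * r + b_t * c + c_t - h * 1000.0
            z0_map[r, c] = z0
            if h == 0:
                e, h_sim = cell.substrate_modulus_pa, np.inf
            else:
                e, h_sim = cell.modulus_map_pa[r, c], h
            row_curves.append(
                simulate_force_curve(
                    e, h_sim, probe,
                    baseline_slope_pn_per_nm=baseline_slope_pn_per_nm,
                    noise_sd_pn=noise_sd_pn, n_points=n_points,
                    z0_nm=z0, rng=rng, pixel=(r, c),
                )
            )
        curves.append(row_curves)
    fv = ForceVolumeMap(curves=curves, pixel_size_um=cell.pixel_size_um)
    truth = SyntheticTruth(
        kind="force_volume",
        payload={
            "height_map_um": cell.height_map_um.copy(),
            "modulus_map_pa": cell.modulus_map_pa.copy(),
            "z0_map_nm": z0_map,
            "substrate_mask": cell.substrate_mask,
            "tilt_nm_per_px": tuple(tilt_nm_per_px),
        },
        seed=seed,
    )
    return fv, truth


def _place_centers(
    rng: np.random.Generator,
    shape: tuple[int, int],
    n: int,
    margin: float,
    min_sep: float,
    forbidden: Sequence[tuple[float, float]] = (),
    forbidden_sep: float = 0.0,
    max_tries: int = 20000,
) -> list[tuple[float, float]]:
    centers: list[tuple[float, float]] = []
    tries = 0
    while len(centers) < n:
        if tries >= max_tries:
            raise PlacementError(
                f"could not place {n} vesicles after {max_tries} tries "
                "(image too crowded for the separation rules)"
            )
        tries += 1
        y = rng.uniform(margin, shape[0] - 1 - margin)
        x = rng.uniform(margin, shape[1] - 1 - margin)
        if any(np.hypot(y - cy, x - cx) < min_sep for cy, cx in centers):
            continue
        if any(np.hypot(y - cy, x - cx) < forbidden_sep for cy, cx in forbidden):
            continue
        centers.append((y, x))
    return centers


def _paint_disks(shape, centers, radius, intensity) -> np.ndarray:
    img = np.zeros(shape, dtype=float)
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    for cy, cx in centers:
        img[np.hypot(rr - cy, cc - cx) <= radius] += intensity
    return img


def simulate_coloc_stack(
    shape: tuple[int, int] = (192, 192),
    n_vesicles_per_channel: int = 30,
    overlap_fraction: float = 0.5,
    vesicle_radius_px: float = 4.0,
    psf_sigma_px: float = 1.5,
    intensity: float = 200.0,
    noise_sd: float = 0.0,
    n_channels: int = 2,
    seed: int = 0,
) -> tuple[ImageStack, SyntheticTruth]:
    """Two- or three-channel vesicle image with a controlled true overlap.

    A rounded fraction of channel-2 (and channel-3) vesicles share centers
    with channel-1 vesicles; the remainder are placed at least
    4 * vesicle_radius away from every channel-1 vesicle.  Disks are blurred
    with a Gaussian PSF, then Gaussian noise is added (clipped at 0).
    Truth records the realized per-pair overlap fraction and all centers.
    """
    if not 0 <= overlap_fraction <= 1:
        raise ValueError("overlap_fraction must be in [0, 1]")
    if n_channels not in (2, 3):
        raise ValueError("n_channels must be 2 or 3")
    rng = np.random.default_rng(seed)
    n = n_vesicles_per_channel
    n_shared = int(round(overlap_fraction * n))
    # non-shared vesicles must stay segmentably disjoint from channel-1
    # objects: at least 4 radii apart and beyond the mutual PSF support
    # (blur truncated at 3 sigma past the disk edge)
    clear_sep = max(
        4.0 * vesicle_radius_px, 2.0 * (vesicle_radius_px + 3.0 * psf_sigma_px) + 1.0
    )
    margin = 4.0 * vesicle_radius_px
    min_sep = 4.0 * vesicle_radius_px

    ch1 = _place_centers(rng, shape, n, margin, min_sep)
    channels = {"ch1": ch1}
    for name in ["ch2", "ch3"][: n_channels - 1]:
        shared = ch1[:n_shared]
        extra = _place_centers(
            rng, shape, n - n_shared, margin, min_sep,
            forbidden=ch1, forbidden_sep=clear_sep,
        )
        channels[name] = shared + extra

    images = {}
    for name, centers in channels.items():
        img = _paint_disks(shape, centers, vesicle_radius_px, intensity)
        img = ndimage.gaussian_filter(img, psf_sigma_px, truncate=3.0)
        if noise_sd > 0:
            img = img + rng.normal(0.0, noise_sd, size=shape)
        images[name] = np.clip(img, 0.0, None)

    pairs = {}
    for name in list(channels)[1:]:
        pairs[f"ch1_{name}"] = n_shared / n if n else 0.0
    truth = SyntheticTruth(
        kind="coloc_stack",
        payload={
            "overlap_fraction": dict(pairs),
            "n_shared": n_shared,
            "centers": {k: list(v) for k, v in channels.items()},
        },
        seed=seed,
    )
    return ImageStack(channels=images, pixel_size_um=0.1), truth


def simulate_traction_field(
    cell_mask: np.ndarray,
    peak_stress_pa: float = 100.0,
    pattern: str = "uniform",
    grid_spacing_um: float = 1.0,
    noise_sd_pa: float = 0.0,
    seed: int = 0,
    decay_um: float = 2.0,
) -> tuple[TractionField, SyntheticTruth]:
    """Traction vector field localized under a cell mask.

    ``uniform``: magnitude = peak everywhere under the mask;
    ``edge_concentrated``: peak at the mask boundary decaying inward with
    length scale ``decay_um``.  Vectors point inward (contractile).  Truth
    stores the exact (noiseless) mean stress, total force and area.
    """
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if not np.any(cell_mask):
        raise ValueError("cell mask is empty")
    if pattern not in ("uniform", "edge_concentrated"):
        raise ValueError(f"unknown pattern {pattern!r}")
    rng = np.random.default_rng(seed)
    rows, cols = cell_mask.shape
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    com = ndimage.center_of_mass(cell_mask)
    dy, dx = com[0] - rr, com[1] - cc
    norm = np.hypot(dy, dx)
    degenerate = norm == 0  # pixel exactly at the centroid: direction arbitrary
    norm[degenerate] = 1.0
    uy, ux = dy / norm, dx / norm
    uy[degenerate], ux[degenerate] = 1.0, 0.0

    if pattern == "uniform":
        mag = np.where(cell_mask, peak_stress_pa, 0.0)
    else:
        depth_px = ndimage.distance_transform_edt(cell_mask)
        mag = np.where(
            cell_mask,
            peak_stress_pa * np.exp(-np.maximum(depth_px - 1, 0) * grid_spacing_um / decay_um),
            0.0,
        )
    ty, tx = mag * uy, mag * ux
    area_um2 = float(cell_mask.sum()) * grid_spacing_um**2
    true_mean = float(np.mean(mag[cell_mask]))
    true_total_n = float(np.sum(mag[cell_mask])) * grid_spacing_um**2 * 1e-12
    if noise_sd_pa > 0:
        ty = ty + rng.normal(0.0, noise_sd_pa, size=cell_mask.shape)
        tx = tx + rng.normal(0.0, noise_sd_pa, size=cell_mask.shape)
    fieldobj = TractionField(tx_pa=tx, ty_pa=ty, grid_spacing_um=grid_spacing_um,
                            cell_mask=cell_mask)
    truth = SyntheticTruth(
        kind="traction",
        payload={"mean_stress_pa": true_mean, "total_force_n": true_total_n,
                 "area_um2": area_um2},
        seed=seed,
    )
    return fieldobj, truth


def _spread_anchors(region: np.ndarray, n: int, min_sep_px: float) -> list[tuple[int, int]]:
    """Pick n well-separated pixels of a region, deepest-first."""
    dt = ndimage.distance_transform_edt(region)
    order = np.argsort(dt, axis=None)[::-1]
    coords = np.column_stack(np.unravel_index(order, region.shape))
    anchors: list[tuple[int, int]] = []
    for y, x in coords:
        if dt[y, x] <= 1:
            break
        if all(np.hypot(y - ay, x - ax) >= min_sep_px for ay, ax in anchors):
            anchors.append((int(y), int(x)))
            if len(anchors) == n:
                return anchors
    raise PlacementError(f"cannot place {n} separated anchors in region")


def simulate_vesicle_movie(
    n_frames: int,
    frame_interval_s: float,
    compartment_mask: np.ndarray,
    contact_intervals: Sequence[Sequence[tuple[int, int]]] | Sequence[tuple[int, int]],
    step_sd_px: float = 0.5,
    seed: int = 0,
    spot_sigma_px: float = 1.5,
    spot_intensity: float = 200.0,
) -> tuple[ImageStack, pd.DataFrame, SyntheticTruth]:
    """Vesicle movie with prescribed compartment-contact intervals.

    ``contact_intervals`` is a list per vesicle of inclusive frame intervals
    (enter, exit); a flat list of tuples means a single vesicle.  During an
    interval the vesicle centroid (rounded to the nearest pixel) lies inside
    the compartment mask, outside it otherwise; positions jitter with SD
    ``step_sd_px`` around well-separated anchors so contacts are unambiguous.
    True durations are (exit - enter + 1) * frame_interval (inclusive-frame
    counting).  Returns (rendered movie, detection table with columns
    frame, label, y_px, x_px, and truth).
    """
    compartment_mask = np.asarray(compartment_mask, dtype=bool)
    if contact_intervals and isinstance(contact_intervals[0], tuple):
        contact_intervals = [list(contact_intervals)]  # type: ignore[list-item]
    per_vesicle: list[list[tuple[int, int]]] = [list(iv) for iv in contact_intervals]
    for ivs in per_vesicle:
        last_exit = -1
        for enter, exit_ in ivs:
            if not (0 <= enter <= exit_ < n_frames):
                raise ValueError(f"interval {(enter, exit_)} out of range [0, {n_frames})")
            if enter <= last_exit:
                raise ValueError("intervals overlap or are unordered")
            last_exit = exit_

    rng = np.random.default_rng(seed)
    n_ves = len(per_vesicle)
    inside_anchors = _spread_anchors(compartment_mask, n_ves, min_sep_px=6.0)
    outside_anchors = _spread_anchors(~compartment_mask, n_ves, min_sep_px=6.0)

    def jitter(anchor, want_inside):
        ay, ax = anchor
        for _ in range(100):
            y = ay + rng.normal(0, step_sd_px)
            x = ax + rng.normal(0, step_sd_px)
            iy, ix = int(round(y)), int(round(x))
            if 0 <= iy < compartment_mask.shape[0] and 0 <= ix < compartment_mask.shape[1]:
                if compartment_mask[iy, ix] == want_inside:
                    return y, x
        return float(ay), float(ax)

    rows = []
    positions = np.zeros((n_ves, n_frames, 2))
    for v, ivs in enumerate(per_vesicle):
        inside_frames = np.zeros(n_frames, dtype=bool)
        for enter, exit_ in ivs:
            inside_frames[enter:exit_ + 1] = True
        for t in range(n_frames):
            anchor = inside_anchors[v] if inside_frames[t] else outside_anchors[v]
            y, x = jitter(anchor, bool(inside_frames[t]))
            positions[v, t] = (y, x)
            rows.append({"frame": t, "label": v, "y_px": y, "x_px": x})
    detections = pd.DataFrame(rows)

    frames = np.zeros((n_frames,) + compartment_mask.shape)
    yy, xx = np.meshgrid(
        np.arange(compartment_mask.shape[0]), np.arange(compartment_mask.shape[1]),
        indexing="ij",
    )
    for t in range(n_frames):
        for v in range(n_ves):
            y, x = positions[v, t]
            frames[t] += spot_intensity * np.exp(
                -((yy - y) ** 2 + (xx - x) ** 2) / (2 * spot_sigma_px**2)
            )
    movie = ImageStack(channels={"vesicles": frames}, pixel_size_um=0.1)

    durations = [
        [(exit_ - enter + 1) * frame_interval_s for enter, exit_ in ivs]
        for ivs in per_vesicle
    ]
    truth = SyntheticTruth(
        kind="vesicle_movie",
        payload={
            "contact_intervals": [list(map(tuple, ivs)) for ivs in per_vesicle],
            "durations_s": durations,
            "frame_interval_s": frame_interval_s,
            "positions": positions,
        },
        seed=seed,
    )
    return movie, detections, truth
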