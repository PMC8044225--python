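"""Mechano-morphometric summaries: traction-field statistics, FRET ratio,
corrected total cell fluorescence, cell-shape metrics, track metrics,
nearest-neighbor detection linking and vesicle-compartment residence times.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage import measure

__all__ = [
    "TractionField",
    "TractionSummary",
    "Track",
    "ShapeMetrics",
    "ResidenceRecord",
    "traction_summary",
    "fret_ratio",
    "corrected_total_fluorescence",
    "shape_metrics",
    "track_metrics",
    "link_detections",
    "residence_times",
]


@dataclass
class TractionField:
    """Grid of 2-D traction vectors (Pa) with a cell mask."""

    tx_pa: np.ndarray
    ty_pa: np.ndarray
    grid_spacing_um: float
    cell_mask: np.ndarray

    def __post_init__(self):
        self.tx_pa = np.asarray(self.tx_pa, dtype=float)
        self.ty_pa = np.asarray(self.ty_pa, dtype=float)
        self.cell_mask = np.asarray(self.cell_mask, dtype=bool)
        if not (self.tx_pa.shape == self.ty_pa.shape == self.cell_mask.shape):
            raise ValueError("traction components and mask must share shape")
        if self.grid_spacing_um <= 0:
            raise ValueError("grid_spacing_um must be > 0")
        if not np.all(np.isfinite(self.tx_pa)) or not np.all(np.isfinite(self.ty_pa)):
            raise ValueError("traction magnitudes must be finite")

    @property
    def magnitude_pa(self) -> np.ndarray:
        return np.hypot(self.tx_pa, self.ty_pa)


@dataclass
class TractionSummary:
    mean_stress_pa: float
    total_force_n: float
    area_um2: float
    n_vectors: int


def traction_summary(fieldobj: TractionField, margin_um: float = 2.0) -> TractionSummary:
    """Total traction force and mean stress under (and near) the cell.

    The summary region is the cell mask dilated by ``margin_um`` (vectors
    within that distance of the cell count as "near").  The total force is
    the sum of traction magnitudes times the area per vector
    (grid_spacing^2); the mean stress is the mean magnitude over the region,
    so total_force = mean_stress * area holds exactly for any field.
    """
    mask = fieldobj.cell_mask
    if not np.any(mask):
        raise ValueError("cell mask is empty")
    if margin_um > 0:
        dist_um = ndimage.distance_transform_edt(~mask) * fieldobj.grid_spacing_um
        region = dist_um <= margin_um
    else:
        region = mask
    mag = fieldobj.magnitude_pa[region]
    a_um2 = fieldobj.grid_spacing_um**2
    total_n = float(mag.sum()) * a_um2 * 1e-12  # Pa * um^2 = 1e-12 N
    return TractionSummary(
        mean_stress_pa=float(mag.mean()),
        total_force_n=total_n,
        area_um2=float(region.sum()) * a_um2,
        n_vectors=int(region.sum()),
    )


def fret_ratio(
    yfp: np.ndarray, cfp: np.ndarray, mask: np.ndarray
) -> tuple[float, np.ndarray]:
    """FRET ratio = (sum of YFP) / (sum of CFP) over the mask.

    Also returns the per-pixel ratio image (NaN where CFP is zero).
    """
    yfp, cfp = np.asarray(yfp, float), np.asarray(cfp, float)
    mask = np.asarray(mask, bool)
    if not (yfp.shape == cfp.shape == mask.shape):
        raise ValueError("images and mask must share shape")
    if not np.any(mask):
        raise ValueError("mask is empty")
    den = float(cfp[mask].sum())
    if den <= 0:
        raise ValueError("CFP sum over mask is zero; ratio undefined")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio_img = np.where(cfp > 0, yfp / np.where(cfp > 0, cfp, 1.0), np.nan)
    return float(yfp[mask].sum()) / den, ratio_img


def corrected_total_fluorescence(
    image: np.ndarray, cell_mask: np.ndarray, background_mask: np.ndarray
) -> float:
    """Corrected total cell fluorescence (CTCF).

    CTCF = integrated intensity over the cell mask minus (cell area in
    pixels) x (mean background intensity) - the standard background-
    subtracted integrated density.
    """
    image = np.asarray(image, float)
    cell_mask = np.asarray(cell_mask, bool)
    background_mask = np.asarray(background_mask, bool)
    if not np.any(cell_mask) or not np.any(background_mask):
        raise ValueError("cell and background masks must be non-empty")
    if np.any(cell_mask & background_mask):
        raise ValueError("cell and background masks must be disjoint")
    integrated = float(image[cell_mask].sum())
    return integrated - float(cell_mask.sum()) * float(image[background_mask].mean())


@dataclass
class ShapeMetrics:
    aspect_ratio: float
    cell_centroid_um: tuple[float, float]
    nucleus_centroid_um: tuple[float, float]
    nucleus_centroid_distance_um: float


def _feret_ratio(mask: np.ndarray) -> float:
    ys, xs = np.nonzero(mask)
    pts = np.column_stack([ys, xs]).astype(float)
    extents = []
    for theta in np.deg2rad(np.arange(0, 180, 1.0)):
        proj = pts @ np.array([np.cos(theta), np.sin(theta)])
        extents.append(proj.max() - proj.min() + 1.0)
    extents = np.asarray(extents)
    return float(extents.max() / extents.min())


def shape_metrics(
    cell_mask: np.ndarray,
    nucleus_mask: np.ndarray,
    pixel_size_um: float = 1.0,
    method: str = "ellipse",
) -> ShapeMetrics:
    """Aspect ratio and nucleus-to-centroid distance of a cell mask.

    ``method="ellipse"`` (default): ratio of major to minor axis of the
    best-fit ellipse from the mask's second moments.  ``method="feret"``:
    ratio of maximal to minimal Feret (caliper) diameter.  The distance is
    the Euclidean distance between the cell-mask and nucleus-mask centroids
    in um; a polarized cell has an off-center nucleus.
    """
    cell_mask = np.asarray(cell_mask, bool)
    nucleus_mask = np.asarray(nucleus_mask, bool)
    if cell_mask.sum() < 2 or nucleus_mask.sum() < 1:
        raise ValueError("degenerate mask")
    if method == "ellipse":
        props = measure.regionprops(cell_mask.astype(np.uint8))[0]
        if props.axis_minor_length == 0:
            raise ValueError("degenerate (collinear) mask")
        aspect = props.axis_major_length / props.axis_minor_length
    elif method == "feret":
        aspect = _feret_ratio(cell_mask)
    else:
        raise ValueError("method must be 'ellipse' or 'feret'")
    cell_c = ndimage.center_of_mass(cell_mask)
    nuc_c = ndimage.center_of_mass(nucleus_mask)
    dist = float(np.hypot(cell_c[0] - nuc_c[0], cell_c[1] - nuc_c[1])) * pixel_size_um
    return ShapeMetrics(
        aspect_ratio=float(aspect),
        cell_centroid_um=(cell_c[0] * pixel_size_um, cell_c[1] * pixel_size_um),
        nucleus_centroid_um=(nuc_c[0] * pixel_size_um, nuc_c[1] * pixel_size_um),
        nucleus_centroid_distance_um=dist,
    )


@dataclass
class Track:
    """Time-ordered positions of one tracked object (t in s, x/y in um)."""

    t_s: np.ndarray
    x_um: np.ndarray
    y_um: np.ndarray
    label: int | str = 0

    def __post_init__(self):
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.x_um = np.asarray(self.x_um, dtype=float)
        self.y_um = np.asarray(self.y_um, dtype=float)
        if not (self.t_s.shape == self.x_um.shape == self.y_um.shape):
            raise ValueError("t, x, y must have equal length")
        if np.any(np.diff(self.t_s) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return self.t_s.size


def track_metrics(track: Track) -> tuple[float, float, float]:
    """(path_length_um, net_displacement_um, mean_speed_um_per_min).

    Path length is the summed step norms; net displacement the straight-
    line start-to-end distance (the two bracket any sensible notion of
    "distance traveled"); mean speed is path length over elapsed time.
    """
    if len(track) < 2:
        raise ValueError("track needs >= 2 samples")
    dx, dy = np.diff(track.x_um), np.diff(track.y_um)
    path = float(np.sum(np.hypot(dx, dy)))
    net = float(np.hypot(track.x_um[-1] - track.x_um[0], track.y_um[-1] - track.y_um[0]))
    elapsed_min = (track.t_s[-1] - track.t_s[0]) / 60.0
    return path, net, path / elapsed_min


def link_detections(
    detections: Sequence[Sequence[tuple[float, float]]],
    max_step_px: float,
    frame_interval_s: float = 1.0,
    pixel_size_um: float = 1.0,
) -> list[Track]:
    """Greedy mutual-nearest-neighbor frame-to-frame linking.

    ``detections[f]`` is the list of (y, x) centroids in frame f.  A
    detection links to one in the next frame iff each is the other's
    nearest neighbor and their distance is <= ``max_step_px``; ties break
    deterministically on the lowest index.  Unmatched detections start new
    tracks.
    """
    n_frames = len(detections)
    tracks_pts: list[list[tuple[int, float, float]]] = []
    active: dict[int, int] = {}  # detection index in current frame -> track id

    for f in range(n_frames):
        pts = [(float(y), float(x)) for y, x in detections[f]]
        new_active: dict[int, int] = {}
        if f == 0 or not active:
            matches = {}
        else:
            prev_pts = [(float(y), float(x)) for y, x in detections[f - 1]]
            matches = _mutual_nn(prev_pts, pts, max_step_px)
        for j, (y, x) in enumerate(pts):
            src = None
            for i, jj in matches.items():
                if jj == j and i in active:
                    src = i
                    break
            if src is not None:
                tid = active[src]
            else:
                tid = len(tracks_pts)
                tracks_pts.append([])
            tracks_pts[tid].append((f, y, x))
            new_active[j] = tid
        active = new_active

    out = []
    for tid, pts in enumerate(tracks_pts):
        frames = np.array([p[0] for p in pts], dtype=float)
        ys = np.array([p[1] for p in pts])
        xs = np.array([p[2] for p in pts])
        out.append(
            Track(
                t_s=frames * frame_interval_s,
                x_um=xs * pixel_size_um,
                y_um=ys * pixel_size_um,
                label=tid,
            )
        )
    return out


def _mutual_nn(a, b, max_step):
    """Mutual nearest neighbors between point lists a and b within max_step."""
    if not a or not b:
        return {}
    pa = np.asarray(a, float)
    pb = np.asarray(b, float)
    d = np.hypot(pa[:, None, 0] - pb[None, :, 0], pa[:, None, 1] - pb[None, :, 1])
    nn_ab = np.argmin(d, axis=1)  # argmin takes the lowest index on ties
    nn_ba = np.argmin(d, axis=0)
    matches = {}
    for i, j in enumerate(nn_ab):
        if nn_ba[j] == i and d[i, j] <= max_step:
            matches[i] = int(j)
    return matches


@dataclass
class ResidenceRecord:
    """One contact run of a tracked vesicle with a compartment."""

    label: int | str
    enter_s: float
    exit_s: float
    duration_s: float
    n_frames: int


def residence_times(
    tracks: Sequence[Track],
    compartment_masks: np.ndarray,
    frame_interval_s: float = 1.0,
    pixel_size_um: float = 1.0,
) -> list[ResidenceRecord]:
    """Durations of each maximal run a track spends inside a compartment.

    ``compartment_masks`` is one 2-D mask used for every frame, or a 3-D
    (frame, y, x) stack.  A track sample is "inside" when its position,
    rounded to the nearest pixel, falls on compartment foreground.  Each
    maximal run of consecutive inside samples yields one record with
    duration = run length x frame_interval (inclusive-frame counting: a
    single-frame touch counts one interval).
    """
    masks = np.asarray(compartment_masks, dtype=bool)
    per_frame = masks.ndim == 3
    records: list[ResidenceRecord] = []
    for track in tracks:
        frames = np.rint(track.t_s / frame_interval_s).astype(int)
        rows = np.rint(track.y_um / pixel_size_um).astype(int)
        cols = np.rint(track.x_um / pixel_size_um).astype(int)
        shape = masks.shape[-2:]
        if np.any((rows < 0) | (rows >= shape[0]) | (cols < 0) | (cols >= shape[1])):
            raise ValueError(f"track {track.label!r} leaves the mask raster")
        if per_frame and np.any(frames >= masks.shape[0]):
            raise ValueError(f"track {track.label!r} touches frames without a mask")
        inside = np.empty(len(track), dtype=bool)
        for i, (fr, r, c) in enumerate(zip(frames, rows, cols)):
            m = masks[fr] if per_frame else masks
            inside[i] = m[r, c]
        # maximal runs of consecutive inside samples
        i = 0
        while i < len(inside):
            if inside[i]:
                j = i
                while j + 1 < len(inside) and inside[j + 1]:
                    j += 1
                records.append(
                    ResidenceRecord(
                        label=track.label,
                        enter_s=float(track.t_s[i]),
                        exit_s=float(track.t_s[j]),
                        duration_s=(j - i + 1) * frame_interval_s,
                        n_frames=j - i + 1,
                    )
                )
                i = j + 1
            else:
                i += 1
    return records
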