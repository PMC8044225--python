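"""Force-volume AFM analysis: baseline (virtual deflection) correction,
two-pass Hertz fitting with the bottom-effect thin-sample correction,
substrate identification, plane flattening, cell masking and height-band
modulus statistics.

Pipeline (``process_force_volume``):

1. per curve: remove the linear virtual-deflection baseline;
2. pass 1: linearized Hertz fit (power-law inversion, F^(2/3) vs. tip-sample
   separation) for contact point z0 and an uncorrected apparent modulus;
3. pixels with pass-1 modulus above a stiffness threshold are the plastic
   substrate; a plane fitted to their contact points converts each pixel's
   z0 into a sample height;
4. pass 2: nonlinear refit of the force-indentation curve with the
   bottom-effect factor at the now-known height, giving the substrate-
   corrected apparent modulus;
5. mask: keep pixels that are tall enough, soft enough and had a clean
   baseline; report mean modulus in height bands.

Units follow the AFM convention: z in nm, force in pN, heights in um,
moduli in Pa.  The fitted stiffness is an *apparent* elastic modulus
(finite indentation rate; viscoelasticity is not modeled).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .contact import bottom_effect_factor, contact_force

__all__ = [
    "ProbeParams",
    "ForceCurve",
    "FitResult",
    "BaselineInfo",
    "ForceVolumeMap",
    "BandStats",
    "ProcessConfig",
    "correct_virtual_deflection",
    "fit_hertz_linearized",
    "bottom_effect_factor",
    "identify_substrate",
    "flatten_heights",
    "fit_bottom_effect",
    "build_cell_mask",
    "band_statistics",
    "process_force_volume",
]

logger = logging.getLogger(__name__)

STATUS_OK = "ok"
STATUS_NO_BASELINE = "no_baseline"
STATUS_NO_CONTACT = "no_contact"
STATUS_EXCLUDED = "excluded"


@dataclass(frozen=True)
class ProbeParams:
    """AFM probe and acquisition parameters.

    tip_radius_nm : paraboloidal tip apex radius R.
    spring_constant_n_per_m : cantilever spring constant k (1 N/m = 1000 pN/nm).
    poisson_ratio : sample Poisson ratio nu (0.5 = incompressible).
    trigger_force_pn : force setpoint terminating each approach curve.
    velocity_um_per_s : probe approach speed (metadata only).
    """

    tip_radius_nm: float = 35.0
    spring_constant_n_per_m: float = 0.068
    poisson_ratio: float = 0.5
    trigger_force_pn: float = 400.0
    velocity_um_per_s: float = 100.0

    def __post_init__(self):
        if self.tip_radius_nm <= 0:
            raise ValueError("tip_radius_nm must be > 0")
        if self.spring_constant_n_per_m <= 0:
            raise ValueError("spring_constant_n_per_m must be > 0")
        if not (0.0 <= self.poisson_ratio <= 0.5 + 1e-12):
            raise ValueError("poisson_ratio must be in [0, 0.5]")
        if self.trigger_force_pn <= 0:
            raise ValueError("trigger_force_pn must be > 0")

    @property
    def spring_constant_pn_per_nm(self) -> float:
        return self.spring_constant_n_per_m * 1000.0


@dataclass
class ForceCurve:
    """One approach force-distance record.

    z_nm increases toward the sample (strictly monotone); force_pn is the
    cantilever force at each piezo position.
    """

    z_nm: np.ndarray
    force_pn: np.ndarray
    probe: ProbeParams
    pixel: tuple[int, int] | None = None

    def __post_init__(self):
        self.z_nm = np.asarray(self.z_nm, dtype=float)
        self.force_pn = np.asarray(self.force_pn, dtype=float)
        if self.z_nm.shape != self.force_pn.shape:
            raise ValueError("z and force must have the same length")
        if self.z_nm.size < 16:
            raise ValueError("a force curve needs at least 16 samples")
        dz = np.diff(self.z_nm)
        if not (np.all(dz > 0) or np.all(dz < 0)):
            raise ValueError("z must be strictly monotone")
        if np.all(dz < 0):  # store in approach order
            self.z_nm = self.z_nm[::-1].copy()
            self.force_pn = self.force_pn[::-1].copy()

    def __len__(self) -> int:
        return self.z_nm.size


@dataclass
class BaselineInfo:
    slope_pn_per_nm: float
    intercept_pn: float
    residual_sd_pn: float
    status: str
    n_window: int


@dataclass
class FitResult:
    contact_point_z0_nm: float = np.nan
    apparent_modulus_pa: float = np.nan
    baseline_slope_pn_per_nm: float = np.nan
    fit_rmse_pn: float = np.nan
    n_fit_points: int = 0
    status: str = STATUS_EXCLUDED


def correct_virtual_deflection(
    curve: ForceCurve,
    baseline_fraction: float = 0.3,
    max_baseline_sd_pn: float = 25.0,
) -> tuple[ForceCurve, BaselineInfo]:
    """Remove the linear virtual-deflection baseline from a force curve.

    A line is least-squares fitted to the first ``baseline_fraction`` of the
    samples (the pre-contact region) and subtracted from the whole trace.
    The baseline is flagged unidentifiable (``no_baseline``) when its
    residual SD exceeds ``max_baseline_sd_pn`` or when contact intrudes into
    the window (the corrected force at the window's end rises clearly above
    the residual noise).
    """
    if not 0 < baseline_fraction <= 1:
        raise ValueError("baseline_fraction must be in (0, 1]")
    z, f = curve.z_nm, curve.force_pn
    if np.ptp(z) == 0:
        raise ValueError("degenerate curve: zero variance in z")
    n_win = max(int(round(baseline_fraction * len(z))), 4)
    coeffs = np.polyfit(z[:n_win], f[:n_win], 1)
    line = np.polyval(coeffs, z)
    corrected = f - line
    sd = float(np.std(corrected[:n_win]))

    status = STATUS_OK
    if sd > max_baseline_sd_pn:
        status = STATUS_NO_BASELINE
    else:
        # contact intruding into the window: tail of the window sits well
        # above the residual noise after correction
        n_tail = max(n_win // 10, 2)
        tail_mean = float(np.mean(corrected[n_win - n_tail:n_win]))
        if tail_mean > max(3.0 * sd, 1.0):
            status = STATUS_NO_BASELINE

    out = replace(curve, z_nm=z.copy(), force_pn=corrected)
    info = BaselineInfo(
        slope_pn_per_nm=float(coeffs[0]),
        intercept_pn=float(coeffs[1]),
        residual_sd_pn=sd,
        status=status,
        n_window=n_win,
    )
    return out, info


def _contact_threshold(force_pn: np.ndarray, baseline_sd_pn: float) -> float:
    # 3x the baseline noise, with a small floor for noiseless data
    return max(3.0 * baseline_sd_pn, 1e-9 * max(float(np.max(force_pn)), 1.0), 1e-3)


def _first_sustained_crossing(force_pn: np.ndarray, threshold: float, run: int = 4) -> int | None:
    above = force_pn > threshold
    if above.size < run:
        return None
    window = np.ones(run, dtype=int)
    sustained = np.convolve(above.astype(int), window, mode="valid") == run
    idx = np.flatnonzero(sustained)
    return int(idx[0]) if idx.size else None


def fit_hertz_linearized(
    curve: ForceCurve,
    max_indentation_nm: float = 800.0,
    baseline_sd_pn: float = 0.0,
    n_irls: int = 3,
) -> FitResult:
    """Pass-1 Hertz fit by power-law inversion.

    On the contact branch the half-space Hertz law gives F^(2/3) linear in
    the tip-sample separation s = z - F/k, so the modulus and contact point
    come from a line fit: y = a*(s - s0) with

        E = (3/4) * (1 - nu^2) * a^(3/2) / sqrt(R),   z0 = s0.

    The contact branch is the first sustained (4-sample) crossing of a force
    threshold (3x baseline noise SD); the fit is restricted to indentations
    <= ``max_indentation_nm`` and refined once with the fitted intercept.
    Iteratively reweighted least squares (weights ~ F^(2/3)) counteracts the
    noise amplification of the 2/3-power transform at low force.
    """
    probe = curve.probe
    z, f = curve.z_nm, curve.force_pn
    threshold = _contact_threshold(f, baseline_sd_pn)
    start = _first_sustained_crossing(f, threshold)
    if start is None:
        return FitResult(status=STATUS_NO_CONTACT)

    k = probe.spring_constant_pn_per_nm
    s = z - f / k  # tip-sample separation, nm

    sel = np.zeros(len(z), dtype=bool)
    sel[start:] = f[start:] > threshold
    a_fit = b_fit = np.nan
    for _ in range(max(n_irls, 1)):
        if sel.sum() < 8:
            return FitResult(status=STATUS_NO_CONTACT)
        y = f[sel] ** (2.0 / 3.0)
        w = f[sel] ** (2.0 / 3.0)
        a_fit, b_fit = np.polyfit(s[sel], y, 1, w=np.sqrt(w))
        if a_fit <= 0:
            return FitResult(status=STATUS_NO_CONTACT)
        s0 = -b_fit / a_fit
        indent = s - s0
        sel = (f > threshold) & (indent > 0) & (indent <= max_indentation_nm)
        sel[:start] = False

    if sel.sum() < 8 or a_fit <= 0:
        return FitResult(status=STATUS_NO_CONTACT)
    s0 = -b_fit / a_fit

    # slope a is in pN^(2/3)/nm; convert to SI for the modulus
    a_si = a_fit * (1e-12) ** (2.0 / 3.0) / 1e-9
    e_pa = 0.75 * (1.0 - probe.poisson_ratio**2) * a_si**1.5 / np.sqrt(probe.tip_radius_nm * 1e-9)
    model = (np.maximum(a_fit * (s[sel] - s0), 0.0)) ** 1.5
    rmse = float(np.sqrt(np.mean((f[sel] - model) ** 2)))
    return FitResult(
        contact_point_z0_nm=float(s0),
        apparent_modulus_pa=float(e_pa),
        fit_rmse_pn=rmse,
        n_fit_points=int(sel.sum()),
        status=STATUS_OK,
    )


def fit_bottom_effect(
    curve: ForceCurve,
    height_um: float,
    z0_init_nm: float,
    e_init_pa: float,
    max_indentation_nm: float = 800.0,
    baseline_sd_pn: float = 0.0,
    z0_window_nm: float = 20.0,
    refit_z0: bool = True,
) -> FitResult:
    """Pass-2 fit: bottom-effect-corrected Hertz model at known sample height.

    Nonlinear least squares of F = (4/3) E/(1-nu^2) sqrt(R) d^(3/2) f(chi)
    with chi = sqrt(R*d)/h and the measured indentation d = (z - z0) - F/k,
    over indentations <= ``max_indentation_nm``.  Free parameters are the
    modulus E and (optionally) the contact point, constrained within
    +/- ``z0_window_nm`` of the pass-1 value to avoid the degenerate E-z0
    trade-off.  On failure the pass-1 result is kept and flagged.
    """
    probe = curve.probe
    if not np.isfinite(e_init_pa) or e_init_pa <= 0 or not np.isfinite(z0_init_nm):
        return FitResult(status=STATUS_EXCLUDED)
    h_m = np.inf if not np.isfinite(height_um) else height_um * 1e-6
    if np.isfinite(h_m) and h_m <= 0:
        return FitResult(status=STATUS_EXCLUDED)

    k = probe.spring_constant_pn_per_nm
    z, f = curve.z_nm, curve.force_pn
    threshold = _contact_threshold(f, baseline_sd_pn)

    indent0 = (z - z0_init_nm) - f / k
    sel = (f > threshold) & (indent0 > 0) & (indent0 <= max_indentation_nm + z0_window_nm)
    if sel.sum() < 8:
        return FitResult(status=STATUS_NO_CONTACT)
    z_s, f_s = z[sel], f[sel]
    r_m = probe.tip_radius_nm * 1e-9
    nu = probe.poisson_ratio

    def residuals(p):
        e_pa, z0 = p
        d_m = np.maximum((z_s - z0) - f_s / k, 0.0) * 1e-9
        model_pn = contact_force(d_m, e_pa, nu, r_m, h_m) * 1e12
        return model_pn - f_s

    lo_z0 = z0_init_nm - z0_window_nm
    hi_z0 = z0_init_nm + z0_window_nm
    if not refit_z0:
        lo_z0, hi_z0 = z0_init_nm - 1e-9, z0_init_nm + 1e-9
    try:
        sol = least_squares(
            residuals,
            x0=[e_init_pa, z0_init_nm],
            bounds=([1e-3, lo_z0], [1e9, hi_z0]),
            x_scale=[max(e_init_pa, 1.0), max(z0_window_nm, 1.0)],
            max_nfev=200,
        )
    except Exception:  # pragma: no cover - scipy failure path
        sol = None
    if sol is None or not sol.success or sol.x[0] <= 0:
        return FitResult(
            contact_point_z0_nm=z0_init_nm,
            apparent_modulus_pa=e_init_pa,
            n_fit_points=int(sel.sum()),
            status=STATUS_EXCLUDED,
        )
    e_fit, z0_fit = sol.x
    rmse = float(np.sqrt(np.mean(sol.fun**2)))
    return FitResult(
        contact_point_z0_nm=float(z0_fit),
        apparent_modulus_pa=float(e_fit),
        fit_rmse_pn=rmse,
        n_fit_points=int(sel.sum()),
        status=STATUS_OK,
    )


@dataclass
class ForceVolumeMap:
    """2-D grid of force curves plus rasters derived during processing."""

    curves: list[list[ForceCurve]]
    pixel_size_um: float
    height_um: np.ndarray | None = None
    modulus_pa_pass1: np.ndarray | None = None
    modulus_pa_pass2: np.ndarray | None = None
    z0_nm: np.ndarray | None = None
    mask: np.ndarray | None = None
    status: np.ndarray | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.curves), len(self.curves[0])

    def curve(self, row: int, col: int) -> ForceCurve:
        return self.curves[row][col]


@dataclass
class BandStats:
    """Mean apparent modulus per height band (bands in um, [lo, hi))."""

    bands_um: tuple[tuple[float, float], ...]
    mean_modulus_pa: tuple[float, ...]
    counts: tuple[int, ...]


@dataclass
class ProcessConfig:
    stiff_threshold_pa: float = 65e3
    min_height_nm: float = 100.0
    max_indentation_nm: float = 800.0
    baseline_fraction: float = 0.3
    max_baseline_sd_pn: float = 25.0
    bands_um: tuple[tuple[float, float], ...] = ((2.0, 5.0), (0.0, 2.0))
    refit_z0: bool = True
    # below this estimated height pass 2 is skipped (pixel is masked out anyway)
    min_refit_height_nm: float = 50.0


def identify_substrate(
    first_pass: Sequence[Sequence[FitResult]],
    stiff_threshold_pa: float = 65e3,
) -> np.ndarray:
    """Binary raster of substrate pixels: fit ok and modulus above threshold.

    Very stiff regions are taken to be the bare plastic dish.
    """
    rows = len(first_pass)
    cols = len(first_pass[0])
    out = np.zeros((rows, cols), dtype=bool)
    for r in range(rows):
        for c in range(cols):
            fit = first_pass[r][c]
            out[r, c] = fit.status == STATUS_OK and fit.apparent_modulus_pa > stiff_threshold_pa
    return out


class FlatteningError(RuntimeError):
    """Raised when no usable substrate plane can be fitted."""


def flatten_heights(
    z0_nm: np.ndarray,
    substrate: np.ndarray,
    pixel_size_um: float | None = None,
) -> tuple[np.ndarray, tuple[float, float, float], int]:
    """Convert contact points to sample heights by planar substrate flattening.

    A plane z0 = alpha*row + beta*col + gamma is least-squares fitted to the
    contact points of substrate pixels; the height of every pixel is the
    plane minus its own contact point (the tip meets a taller sample
    earlier, i.e. at smaller z).  Returns (heights in um, plane
    coefficients, count of small negative heights clamped to 0).
    """
    z0_nm = np.asarray(z0_nm, dtype=float)
    substrate = np.asarray(substrate, dtype=bool)
    ok = substrate & np.isfinite(z0_nm)
    if ok.sum() < 3:
        raise FlatteningError("need >= 3 substrate pixels with contact points")
    rr, cc = np.nonzero(ok)
    design = np.column_stack([rr, cc, np.ones(rr.size)])
    if np.linalg.matrix_rank(design) < 3:
        raise FlatteningError("substrate pixels are collinear; cannot fit plane")
    coeffs, *_ = np.linalg.lstsq(design, z0_nm[ok], rcond=None)
    rows, cols = z0_nm.shape
    rgrid, cgrid = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    plane = coeffs[0] * rgrid + coeffs[1] * cgrid + coeffs[2]
    heights_um = (plane - z0_nm) / 1000.0
    clamped = int(np.sum(heights_um < 0))
    if clamped:
        logger.info("flatten_heights: clamped %d negative heights to 0", clamped)
    heights_um = np.maximum(heights_um, 0.0)
    return heights_um, (float(coeffs[0]), float(coeffs[1]), float(coeffs[2])), clamped


def build_cell_mask(
    heights_um: np.ndarray,
    moduli_pa: np.ndarray,
    statuses: np.ndarray,
    min_height_nm: float = 100.0,
    stiff_threshold_pa: float = 65e3,
) -> np.ndarray:
    """Cell mask: tall enough, soft enough, and a clean fit.

    A pixel is kept iff height >= ``min_height_nm``, modulus <=
    ``stiff_threshold_pa`` and its per-curve status is ok (curves without an
    identifiable baseline or contact are excluded).
    """
    heights_um = np.asarray(heights_um, dtype=float)
    moduli_pa = np.asarray(moduli_pa, dtype=float)
    statuses = np.asarray(statuses)
    if not heights_um.shape == moduli_pa.shape == statuses.shape:
        raise ValueError("rasters must share shape")
    return (
        (heights_um * 1000.0 >= min_height_nm)
        & (moduli_pa <= stiff_threshold_pa)
        & (statuses == STATUS_OK)
    )


def band_statistics(
    heights_um: np.ndarray,
    moduli_pa: np.ndarray,
    mask: np.ndarray,
    bands_um: Sequence[tuple[float, float]] = ((2.0, 5.0), (0.0, 2.0)),
) -> BandStats:
    """Mean apparent modulus over masked pixels per height band [lo, hi)."""
    if not np.any(mask):
        raise ValueError("mask is empty")
    means, counts = [], []
    for lo, hi in bands_um:
        sel = mask & (heights_um >= lo) & (heights_um < hi)
        n = int(sel.sum())
        means.append(float(np.mean(moduli_pa[sel])) if n else float("nan"))
        counts.append(n)
    return BandStats(tuple((float(lo), float(hi)) for lo, hi in bands_um),
                     tuple(means), tuple(counts))


@dataclass
class ProcessResult:
    fv: ForceVolumeMap
    band_stats: BandStats | None
    substrate: np.ndarray
    plane_nm: tuple[float, float, float]
    exclusions: dict[str, int] = field(default_factory=dict)
    pass1: list[list[FitResult]] | None = None
    pass2: list[list[FitResult]] | None = None
    baselines: list[list[BaselineInfo]] | None = None


def process_force_volume(fv: ForceVolumeMap, config: ProcessConfig | None = None) -> ProcessResult:
    """Run the full two-pass force-volume pipeline on a map.

    Executes baseline correction, pass-1 linearized Hertz fits, substrate
    identification (> stiffness threshold), plane flattening to heights,
    pass-2 bottom-effect refits at the flattened heights, cell masking and
    height-band statistics.  Deterministic for fixed input.
    """
    cfg = config or ProcessConfig()
    rows, cols = fv.shape
    pass1: list[list[FitResult]] = [[FitResult() for _ in range(cols)] for _ in range(rows)]
    pass2: list[list[FitResult]] = [[FitResult() for _ in range(cols)] for _ in range(rows)]
    baselines: list[list[BaselineInfo]] = [[None] * cols for _ in range(rows)]  # type: ignore
    corrected: list[list[ForceCurve]] = [[None] * cols for _ in range(rows)]  # type: ignore

    for r in range(rows):
        for c in range(cols):
            curve = fv.curve(r, c)
            cur, info = correct_virtual_deflection(
                curve, cfg.baseline_fraction, cfg.max_baseline_sd_pn
            )
            baselines[r][c] = info
            corrected[r][c] = cur
            if info.status != STATUS_OK:
                pass1[r][c] = FitResult(status=STATUS_NO_BASELINE)
                continue
            fit = fit_hertz_linearized(
                cur, cfg.max_indentation_nm, baseline_sd_pn=info.residual_sd_pn
            )
            fit.baseline_slope_pn_per_nm = info.slope_pn_per_nm
            pass1[r][c] = fit

    substrate = identify_substrate(pass1, cfg.stiff_threshold_pa)
    z0_grid = np.array(
        [[pass1[r][c].contact_point_z0_nm for c in range(cols)] for r in range(rows)]
    )
    heights_um, plane, n_clamped = flatten_heights(z0_grid, substrate, fv.pixel_size_um)

    for r in range(rows):
        for c in range(cols):
            p1 = pass1[r][c]
            if p1.status != STATUS_OK:
                pass2[r][c] = FitResult(status=p1.status)
                continue
            h_um = np.inf if substrate[r, c] else heights_um[r, c]
            if np.isfinite(h_um) and h_um * 1000.0 < cfg.min_refit_height_nm:
                # too thin to refit reliably; masked out downstream
                pass2[r][c] = replace(p1, status=STATUS_EXCLUDED)
                continue
            info = baselines[r][c]
            fit = fit_bottom_effect(
                corrected[r][c],
                h_um,
                p1.contact_point_z0_nm,
                p1.apparent_modulus_pa,
                cfg.max_indentation_nm,
                baseline_sd_pn=info.residual_sd_pn,
                refit_z0=cfg.refit_z0,
            )
            pass2[r][c] = fit

    mod1 = np.array([[pass1[r][c].apparent_modulus_pa for c in range(cols)] for r in range(rows)])
    mod2 = np.array([[pass2[r][c].apparent_modulus_pa for c in range(cols)] for r in range(rows)])
    status = np.array(
        [[pass2[r][c].status for c in range(cols)] for r in range(rows)], dtype=object
    )
    mask = build_cell_mask(heights_um, mod2, status, cfg.min_height_nm, cfg.stiff_threshold_pa)

    band_stats = None
    if np.any(mask):
        band_stats = band_statistics(heights_um, mod2, mask, cfg.bands_um)

    statuses_flat = [pass2[r][c].status for r in range(rows) for c in range(cols)]
    exclusions = {
        "no_baseline": statuses_flat.count(STATUS_NO_BASELINE),
        "no_contact": statuses_flat.count(STATUS_NO_CONTACT),
        "excluded": statuses_flat.count(STATUS_EXCLUDED),
        "negative_heights_clamped": n_clamped,
    }
    logger.info("process_force_volume exclusions: %s", exclusions)

    fv_out = ForceVolumeMap(
        curves=fv.curves,
        pixel_size_um=fv.pixel_size_um,
        height_um=heights_um,
        modulus_pa_pass1=mod1,
        modulus_pa_pass2=mod2,
        z0_nm=z0_grid,
        mask=mask,
        status=status,
    )
    return ProcessResult(
        fv=fv_out,
        band_stats=band_stats,
        substrate=substrate,
        plane_nm=plane,
        exclusions=exclusions,
        pass1=pass1,
        pass2=pass2,
        baselines=baselines,
    )
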