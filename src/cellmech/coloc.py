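"""Object-based colocalization: Phansalkar local thresholding, binary
median denoising, Manders split coefficients and conjunction (triple)
colocalization.

The Manders split coefficients for two channels S1, S2 are

    M1 = sum_i S1_i,coloc / sum_i S1_i
    M2 = sum_j S2_j,coloc / sum_j S2_j

where S1_i,coloc = S1_i if both channels are present at pixel i.  Presence
is decided by segmentation (raw confocal intensities are never exactly
zero): each channel is normalized, locally thresholded with the Phansalkar
method, and the binary mask denoised with a 2-D median filter.  M1 answers
"what fraction of channel-1 signal sits where channel 2 is also present";
the pair is deliberately asymmetric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "ImageStack",
    "ThresholdParams",
    "ColocResult",
    "normalize_channel",
    "phansalkar_threshold",
    "median_filter_mask",
    "manders_split",
    "conjunction_mask",
    "coloc_pipeline",
]


@dataclass
class ImageStack:
    """Named multi-channel intensity raster (2-D, or 3-D as (z, y, x))."""

    channels: dict[str, np.ndarray]
    pixel_size_um: float = 1.0
    bit_depth: int | None = None

    def __post_init__(self):
        shapes = {np.asarray(v).shape for v in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError("channels must share shape")
        for name, img in self.channels.items():
            img = np.asarray(img, dtype=float)
            if np.any(img < 0):
                raise ValueError(f"channel {name!r} has negative intensities")
            self.channels[name] = img

    @property
    def shape(self):
        return next(iter(self.channels.values())).shape


@dataclass(frozen=True)
class ThresholdParams:
    """Phansalkar local-threshold parameters (for intensities in [0, 1]).

    t = m * (1 + p * exp(-q * m) + k * ((s / r) - 1))

    with m, s the local mean and SD in a square window.  Defaults are the
    method's published values (k=0.25, r=0.5, p=2, q=10) with a 15 px
    window, as shipped by the common auto-local-threshold tools.
    """

    window: int = 15
    k_p: float = 0.25
    r_p: float = 0.5
    p_p: float = 2.0
    q_p: float = 10.0

    def __post_init__(self):
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 3")
        if self.r_p <= 0:
            raise ValueError("r_p must be > 0")


@dataclass
class ColocResult:
    m1: float
    m2: float
    pair: tuple[str, str]
    n_total: int
    n_mask1: int
    n_mask2: int
    n_coloc: int
    undefined: bool = False  # a denominator was zero


def normalize_channel(image: np.ndarray) -> np.ndarray:
    """Min-max normalize to [0, 1]; a constant image maps to all zeros."""
    image = np.asarray(image, dtype=float)
    lo, hi = float(np.min(image)), float(np.max(image))
    if hi == lo:
        return np.zeros_like(image)
    return (image - lo) / (hi - lo)


def phansalkar_threshold(image: np.ndarray, params: ThresholdParams | None = None) -> np.ndarray:
    """Binary foreground mask from the Phansalkar local threshold.

    Local mean and SD are computed over a square window with edge
    replication; a pixel is foreground iff its intensity strictly exceeds
    t = m * (1 + p*exp(-q*m) + k*((s/r) - 1)).  Designed for low-contrast
    normalized images.
    """
    params = params or ThresholdParams()
    image = np.asarray(image, dtype=float)
    w = params.window
    # clamp at 0: the running-sum filter can leave tiny negative means in
    # all-zero regions, which would flip the sign of the threshold
    mean = np.maximum(ndimage.uniform_filter(image, size=w, mode="nearest"), 0.0)
    mean_sq = ndimage.uniform_filter(image * image, size=w, mode="nearest")
    sd = np.sqrt(np.maximum(mean_sq - mean * mean, 0.0))
    t = mean * (
        1.0
        + params.p_p * np.exp(-params.q_p * mean)
        + params.k_p * ((sd / params.r_p) - 1.0)
    )
    return image > t


def median_filter_mask(mask: np.ndarray, neighborhood: int = 16,
                       interpret: str = "side") -> np.ndarray:
    """2-D median (majority-vote) filter of a binary mask.

    ``neighborhood`` sets the square window: with ``interpret="side"`` it is
    the window side, rounded up to the next odd value for a well-defined
    center (16 -> 17); with ``interpret="radius"`` the side is
    2*neighborhood + 1.  Edges are handled by replication.
    """
    if neighborhood < 1:
        raise ValueError("neighborhood must be >= 1")
    if interpret == "side":
        size = neighborhood if neighborhood % 2 == 1 else neighborhood + 1
    elif interpret == "radius":
        size = 2 * neighborhood + 1
    else:
        raise ValueError("interpret must be 'side' or 'radius'")
    mask = np.asarray(mask).astype(bool)
    out = ndimage.median_filter(mask.astype(np.uint8), size=size, mode="nearest")
    return out.astype(bool)


def manders_split(
    s1: np.ndarray,
    mask1: np.ndarray,
    s2: np.ndarray,
    mask2: np.ndarray,
    pair: tuple[str, str] = ("ch1", "ch2"),
) -> ColocResult:
    """Manders split coefficients over segmentation masks.

    M1 = (sum of S1 where both masks are set) / (sum of S1 where mask1 is
    set); M2 symmetrically.  A zero denominator yields NaN with the
    ``undefined`` flag set.
    """
    s1, s2 = np.asarray(s1, float), np.asarray(s2, float)
    mask1, mask2 = np.asarray(mask1, bool), np.asarray(mask2, bool)
    if not (s1.shape == s2.shape == mask1.shape == mask2.shape):
        raise ValueError("images and masks must share shape")
    coloc = mask1 & mask2
    den1, den2 = float(s1[mask1].sum()), float(s2[mask2].sum())
    num1, num2 = float(s1[coloc].sum()), float(s2[coloc].sum())
    undefined = den1 == 0 or den2 == 0
    m1 = num1 / den1 if den1 > 0 else float("nan")
    m2 = num2 / den2 if den2 > 0 else float("nan")
    return ColocResult(
        m1=m1, m2=m2, pair=pair, n_total=int(s1.size),
        n_mask1=int(mask1.sum()), n_mask2=int(mask2.sum()),
        n_coloc=int(coloc.sum()), undefined=undefined,
    )


def conjunction_mask(mask_a: np.ndarray, mask_b: np.ndarray) -> np.ndarray:
    """Conjunction ("A+B") mask: logical AND of two segmentation masks."""
    mask_a, mask_b = np.asarray(mask_a, bool), np.asarray(mask_b, bool)
    if mask_a.shape != mask_b.shape:
        raise ValueError("masks must share shape")
    return mask_a & mask_b


def _segment_channel(
    image: np.ndarray,
    params: ThresholdParams,
    median_neighborhood: int,
    median_interpret: str,
) -> np.ndarray:
    """normalize -> Phansalkar per 2-D slice -> median filter per slice."""
    norm = normalize_channel(image)
    if norm.ndim == 2:
        slices = [norm]
    else:
        slices = [norm[z] for z in range(norm.shape[0])]
    masks = []
    for sl in slices:
        m = phansalkar_threshold(sl, params)
        if median_neighborhood:
            m = median_filter_mask(m, median_neighborhood, median_interpret)
        masks.append(m)
    return masks[0] if norm.ndim == 2 else np.stack(masks)


def coloc_pipeline(
    stack: ImageStack,
    pair: tuple[str, str] | None = None,
    conjunction: tuple[tuple[str, str], str] | None = None,
    params: ThresholdParams | None = None,
    median_neighborhood: int = 16,
    median_interpret: str = "side",
    conjunction_intensity: str = "first",
    per_slice: bool = False,
) -> ColocResult:
    """Full colocalization program for a channel pair or a conjunction.

    Each involved channel is normalized, Phansalkar-thresholded and
    median-denoised (2-D, per z-slice for stacks).  For
    ``conjunction=((a, b), c)`` the first operand is the AND of the a and b
    masks, with intensity taken from channel a (``conjunction_intensity=
    "first"``) or the pixel-wise minimum of a and b (``"min"``).  Z-stacks
    are pooled: one pair of coefficients from sums over all slices
    (``per_slice=True`` instead averages per-slice coefficients).
    """
    if (pair is None) == (conjunction is None):
        raise ValueError("provide exactly one of pair= or conjunction=")
    params = params or ThresholdParams()

    def get(name):
        if name not in stack.channels:
            raise KeyError(f"channel {name!r} not in stack {sorted(stack.channels)}")
        return stack.channels[name]

    if pair is not None:
        name1, name2 = pair
        s1, s2 = get(name1), get(name2)
        mask1 = _segment_channel(s1, params, median_neighborhood, median_interpret)
        mask2 = _segment_channel(s2, params, median_neighborhood, median_interpret)
        label = (name1, name2)
    else:
        (name_a, name_b), name_c = conjunction
        sa, sb, sc = get(name_a), get(name_b), get(name_c)
        mask_a = _segment_channel(sa, params, median_neighborhood, median_interpret)
        mask_b = _segment_channel(sb, params, median_neighborhood, median_interpret)
        mask1 = conjunction_mask(mask_a, mask_b)
        s1 = sa if conjunction_intensity == "first" else np.minimum(sa, sb)
        s2 = sc
        mask2 = _segment_channel(sc, params, median_neighborhood, median_interpret)
        label = (f"{name_a}+{name_b}", name_c)

    if per_slice and np.ndim(s1) == 3:
        results = [
            manders_split(s1[z], mask1[z], s2[z], mask2[z], label)
            for z in range(s1.shape[0])
        ]
        m1 = float(np.nanmean([r.m1 for r in results]))
        m2 = float(np.nanmean([r.m2 for r in results]))
        return ColocResult(
            m1=m1, m2=m2, pair=label, n_total=int(np.size(s1)),
            n_mask1=sum(r.n_mask1 for r in results),
            n_mask2=sum(r.n_mask2 for r in results),
            n_coloc=sum(r.n_coloc for r in results),
            undefined=any(r.undefined for r in results),
        )
    return manders_split(s1, mask1, s2, mask2, label)
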