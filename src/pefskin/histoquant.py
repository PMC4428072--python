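"""Quantification of collagen in stained skin sections.

Masson's Trichrome renders collagen blue: pixels whose blue/red
intensity ratio exceeds a threshold (default 2) form the collagen mask.
From the mask and the image texture the module derives local fiber
density (mask fraction within a 50 px disc), pixel-wise axial fiber
orientation (structure tensor), and local directional variance
(1 minus the mean resultant length of doubled angles within the disc;
0 = perfectly aligned, 1 = isotropic - elevated alignment is a scar
signature).  Herovici stains young, uncrosslinked collagen III blue and
mature crosslinked collagen I red, so the mean blue/red ratio within
the (registered) collagen mask indexes fiber age.  Adjacent sections
are registered by Fourier phase correlation.

All angle conventions are image coordinates: angles in [0, pi),
measured from the +x (column) axis toward +y (rows).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve
from skimage.feature import structure_tensor
from skimage.registration import phase_cross_correlation

__all__ = [
    "SectionImage",
    "FiberMaps",
    "SubregionStats",
    "collagen_mask",
    "local_density",
    "orientation_map",
    "directional_variance",
    "register_sections",
    "herovici_ratio",
    "blue_red_ratio_map",
    "subregion_stats",
    "analyze_trichrome",
]

#: guard against zero red on the 8-bit scale; does not alter the >2
#: decision for ordinary pixels
EPS_RED = 1.0


@dataclass
class SectionImage:
    """RGB section raster with pixel size in micrometres."""

    rgb: np.ndarray  # (H, W, 3)
    px_size_um: float
    stain: str = "trichrome"

    def __post_init__(self) -> None:
        self.rgb = np.asarray(self.rgb)
        if self.rgb.ndim != 3 or self.rgb.shape[2] != 3:
            raise ValueError("expected an H x W x 3 raster")
        if not self.px_size_um > 0:
            raise ValueError("px_size_um must be positive")

    @property
    def gray(self) -> np.ndarray:
        return self.rgb.astype(float).mean(axis=2)


@dataclass
class FiberMaps:
    """Collagen mask plus density/orientation/variance rasters."""

    mask: np.ndarray
    density: np.ndarray
    orientation: np.ndarray  # axial angle in [0, pi); NaN where undefined
    dir_variance: np.ndarray  # in [0, 1]; NaN where undefined
    px_size_um: float


@dataclass
class SubregionStats:
    region_um: tuple  # (x0, y0, width, height)
    mean_density: float
    mean_dir_variance: float
    mean_blue_red_ratio: float | None = None


def collagen_mask(
    img: SectionImage, ratio_threshold: float = 2.0, eps: float = EPS_RED
) -> np.ndarray:
    """Binary collagen raster: blue/(red + eps) > ratio_threshold."""
    rgb = img.rgb.astype(float)
    return rgb[..., 2] / (rgb[..., 0] + eps) > ratio_threshold


def blue_red_ratio_map(img: SectionImage, eps: float = EPS_RED) -> np.ndarray:
    """Per-pixel blue/(red + eps) intensity ratio."""
    rgb = img.rgb.astype(float)
    return rgb[..., 2] / (rgb[..., 0] + eps)


def _disc_kernel(radius_px: int) -> np.ndarray:
    r = int(radius_px)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (yy**2 + xx**2 <= r**2).astype(float)


def _disc_mean(values: np.ndarray, weights: np.ndarray, radius_px: int):
    """Disc-weighted sums of ``values`` and ``weights`` (partial discs at
    borders: the disc is intersected with the image, no padding bias)."""
    disc = _disc_kernel(radius_px)
    s = fftconvolve(values * weights, disc, mode="same")
    n = fftconvolve(weights.astype(float), disc, mode="same")
    return s, n


def local_density(mask: np.ndarray, radius_px: int = 50) -> np.ndarray:
    """Fraction of collagen-positive pixels within a Euclidean disc."""
    mask = np.asarray(mask)
    if radius_px < 1:
        raise ValueError("radius must be >= 1")
    if 2 * radius_px + 1 > max(mask.shape):
        raise ValueError("disc larger than image")
    ones = np.ones_like(mask, dtype=float)
    s, n = _disc_mean(mask.astype(float), ones, radius_px)
    return np.clip(s / n, 0.0, 1.0)


def orientation_map(
    img: SectionImage,
    mask: np.ndarray,
    tensor_sigma: float = 2.0,
    min_coherence: float = 1e-2,
) -> np.ndarray:
    """Pixel-wise axial fiber orientation from the local structure tensor.

    The fiber direction is the minor eigenvector of the Gaussian-
    weighted structure tensor (gradients are strongest across a fiber).
    Angles lie in [0, pi).  Pixels with an isotropic or featureless
    neighbourhood (coherence below ``min_coherence``) are undefined
    (NaN) and excluded from downstream variance statistics, as are
    pixels outside the mask.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty collagen mask")
    arr, arc, acc = structure_tensor(
        img.gray, sigma=tensor_sigma, order="rc", mode="mirror"
    )
    # rows are y, cols are x: Sxx = Acc, Syy = Arr, Sxy = Arc
    trace = arr + acc
    lam_diff = np.sqrt((acc - arr) ** 2 + 4 * arc**2)  # lambda1 - lambda2
    with np.errstate(invalid="ignore", divide="ignore"):
        coherence = np.where(trace > 0, lam_diff / trace, 0.0)
    phi_major = 0.5 * np.arctan2(2 * arc, acc - arr)  # dominant gradient dir
    theta = np.mod(phi_major + np.pi / 2, np.pi)  # fiber = perpendicular
    theta[~mask] = np.nan
    theta[coherence < min_coherence] = np.nan
    theta[trace <= 1e-12 * max(trace.max(), 1e-300)] = np.nan
    return theta


def directional_variance(
    orientation: np.ndarray, mask: np.ndarray, radius_px: int = 50
) -> np.ndarray:
    """Local directional variance of axial angles within a disc.

    1 - R where R is the mean resultant length of unit vectors at the
    doubled angles 2*theta over defined mask pixels in the disc.  0 for
    perfect alignment; 1 when the doubled angles cancel (e.g. two equal
    orthogonal families, or isotropic orientations).  NaN where the
    disc contains no defined orientation.
    """
    orientation = np.asarray(orientation, dtype=float)
    valid = np.asarray(mask, dtype=bool) & np.isfinite(orientation)
    ang = np.where(valid, orientation, 0.0)
    c, n = _disc_mean(np.cos(2 * ang), valid, radius_px)
    s, _ = _disc_mean(np.sin(2 * ang), valid, radius_px)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.hypot(c, s) / n
    out = 1.0 - np.clip(r, 0.0, 1.0)
    out[n < 0.5] = np.nan
    return out


def register_sections(img_a: SectionImage, img_b: SectionImage):
    """Translation (dx, dy) in px aligning ``img_b`` onto ``img_a``.

    Integer-shift Fourier phase correlation; invariant to global
    intensity scaling.  Raises on flat (zero-variance) input.
    """
    if abs(img_a.px_size_um - img_b.px_size_um) > 1e-9:
        raise ValueError("sections must share a pixel size")
    a, b = img_a.gray, img_b.gray
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("flat image cannot be registered")
    shift, _, _ = phase_cross_correlation(a, b, normalization="phase")
    dy, dx = shift
    return float(dx), float(dy)


def herovici_ratio(
    img: SectionImage, mask: np.ndarray, eps: float = EPS_RED
) -> float:
    """Mean blue/(red + eps) over the collagen mask of a Herovici section."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty collagen mask")
    return float(blue_red_ratio_map(img, eps=eps)[mask].mean())


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def subregion_stats(
    maps: FiberMaps,
    herovici: np.ndarray | None = None,
    region_um: tuple | None = None,
) -> SubregionStats:
    """Plain means of density, directional variance and blue/red ratio
    over a rectangular subregion.

    ``region_um`` is (x0, y0, width, height) in micrometres; by default
    a 300 x 700 um window centred in the image.  The rectangle converts
    to pixels by rounding half up and must lie inside the image.
    """
    h, w = maps.density.shape
    px = maps.px_size_um
    if region_um is None:
        # centred 300 x 700 um window, clipped to the image if smaller
        rw, rh = min(300.0, w * px), min(700.0, h * px)
        x0 = (w * px - rw) / 2
        y0 = (h * px - rh) / 2
        region_um = (x0, y0, rw, rh)
    x0, y0, rw, rh = region_um
    c0, r0 = _round_half_up(x0 / px), _round_half_up(y0 / px)
    c1, r1 = _round_half_up((x0 + rw) / px), _round_half_up((y0 + rh) / px)
    if r0 < 0 or c0 < 0 or r1 > h or c1 > w or r1 <= r0 or c1 <= c0:
        raise ValueError("subregion outside image")
    sl = np.s_[r0:r1, c0:c1]
    dv = maps.dir_variance[sl]
    ratio = None
    if herovici is not None:
        in_mask = maps.mask[sl]
        ratio = float(herovici[sl][in_mask].mean()) if in_mask.any() else np.nan
    return SubregionStats(
        region_um=tuple(region_um),
        mean_density=float(np.mean(maps.density[sl])),
        mean_dir_variance=float(np.nanmean(dv)) if np.isfinite(dv).any() else np.nan,
        mean_blue_red_ratio=ratio,
    )


def analyze_trichrome(
    img: SectionImage,
    ratio_threshold: float = 2.0,
    radius_px: int = 50,
    tensor_sigma: float = 2.0,
) -> FiberMaps:
    """Mask, density, orientation and directional variance in one pass."""
    mask = collagen_mask(img, ratio_threshold=ratio_threshold)
    density = local_density(mask, radius_px=radius_px)
    orient = orientation_map(img, mask, tensor_sigma=tensor_sigma)
    dvar = directional_variance(orient, mask, radius_px=radius_px)
    return FiberMaps(
        mask=mask,
        density=density,
        orientation=orient,
        dir_variance=dvar,
        px_size_um=img.px_size_um,
    )
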