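"""Synthetic inputs with the statistical structure the analysis assumes.

Three generators, all pure functions of (parameters, seed):

* fiber-texture section images (Trichrome- or Herovici-like colouring)
  with known fill fraction, mean axial orientation and von Mises axial
  concentration, plus per-pixel ground-truth mask and angle maps;
* L25 response tables with additive per-factor level effects and
  multiplicative log-normal noise (positivity is required by the
  larger-is-better S/N statistic);
* tensile stress-strain records with a configurable nonlinear toe
  region followed by an exactly linear segment of known modulus.

Axial angles are drawn by the standard axial-data construction: the
doubled angle 2*theta follows a von Mises law with concentration kappa,
so the directional-variance statistic (defined on doubled angles) sees
exactly the intended concentration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.draw import polygon

from .histoquant import SectionImage
from .mechanics import StressStrainRecord
from .taguchi import TaguchiDesign

__all__ = [
    "FiberImageTruth",
    "TaguchiTruth",
    "generate_fiber_image",
    "generate_taguchi_responses",
    "generate_stress_strain",
]

# stain colour models (R, G, B): fiber blue/red ratio must clear the
# mask threshold of 2, background must fail it
_TRICHROME_FIBER = (60, 60, 200)
_TRICHROME_BG = (200, 160, 170)
_HEROVICI_NEW = (60, 60, 200)  # young, uncrosslinked collagen III
_HEROVICI_MATURE = (200, 60, 60)  # mature, crosslinked collagen I
_HEROVICI_BG = (230, 220, 210)


@dataclass(frozen=True)
class FiberImageTruth:
    """Ground-truth parameters of a synthetic fiber texture."""

    fill_fraction: float = 0.3
    mean_angle_rad: float = 0.0
    kappa: float = 4.0  # von Mises concentration on doubled angles
    fiber_width_px: float = 3.0
    fiber_length_px: float = 120.0
    stain: str = "trichrome"
    new_fraction: float = 0.5  # herovici only: fraction of "young" fibers
    noise_sd: float = 2.0
    px_size_um: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.fill_fraction < 1:
            raise ValueError("fill_fraction must be in [0, 1)")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if self.stain not in ("trichrome", "herovici"):
            raise ValueError("stain must be 'trichrome' or 'herovici'")


def _draw_segment(mask, angles, ages, center, theta, length, width, age, rng):
    h, w = mask.shape
    r0, c0 = center
    dr, dc = np.sin(theta), np.cos(theta)
    nr, nc = -dc, dr  # unit normal
    hl, hw = length / 2.0, width / 2.0
    rr = [r0 - dr * hl - nr * hw, r0 - dr * hl + nr * hw,
          r0 + dr * hl + nr * hw, r0 + dr * hl - nr * hw]
    cc = [c0 - dc * hl - nc * hw, c0 - dc * hl + nc * hw,
          c0 + dc * hl + nc * hw, c0 + dc * hl - nc * hw]
    pr, pc = polygon(rr, cc, shape=mask.shape)
    mask[pr, pc] = True
    angles[pr, pc] = theta
    ages[pr, pc] = age


def generate_fiber_image(
    truth: FiberImageTruth, size: tuple[int, int] = (256, 256)
) -> tuple[SectionImage, np.ndarray, np.ndarray]:
    """Render a fiber texture; returns (image, mask, angle_map).

    Straight fibers of the given width are stamped at angles drawn from
    the axial von Mises law until the target fill fraction is reached.
    The angle map holds the axial angle in [0, pi) of the most recently
    drawn fiber per pixel, NaN off the mask.  Same seed, same output.
    """
    h, w = size
    rng = np.random.default_rng(truth.seed)
    mask = np.zeros((h, w), dtype=bool)
    angles = np.full((h, w), np.nan)
    ages = np.zeros((h, w), dtype=np.uint8)  # herovici: 1 new, 2 mature
    target = truth.fill_fraction * h * w
    max_segments = 50000
    n_seg = 0
    while mask.sum() < target:
        if n_seg >= max_segments:
            raise RuntimeError("target fill fraction unreachable")
        if truth.kappa > 0:
            delta = rng.vonmises(0.0, truth.kappa)
        else:
            delta = rng.uniform(-np.pi, np.pi)
        theta = np.mod(truth.mean_angle_rad + delta / 2.0, np.pi)
        # centres drawn on an extended canvas so fiber coverage is
        # stationary across the image (no border depletion)
        pad = truth.fiber_length_px / 2.0 + truth.fiber_width_px
        center = (rng.uniform(-pad, h + pad), rng.uniform(-pad, w + pad))
        age = 1 if rng.uniform() < truth.new_fraction else 2
        _draw_segment(
            mask, angles, ages, center, theta,
            truth.fiber_length_px, truth.fiber_width_px, age, rng,
        )
        n_seg += 1

    rgb = np.empty((h, w, 3), dtype=float)
    if truth.stain == "trichrome":
        rgb[:] = _TRICHROME_BG
        rgb[mask] = _TRICHROME_FIBER
    else:
        rgb[:] = _HEROVICI_BG
        rgb[ages == 1] = _HEROVICI_NEW
        rgb[ages == 2] = _HEROVICI_MATURE
    if truth.noise_sd > 0:
        rgb += rng.normal(0.0, truth.noise_sd, rgb.shape)
    rgb = np.clip(np.round(rgb), 0, 255).astype(np.uint8)
    img = SectionImage(rgb=rgb, px_size_um=truth.px_size_um, stain=truth.stain)
    return img, mask, angles


@dataclass(frozen=True)
class TaguchiTruth:
    """Additive-effects model for synthetic L25 collagen responses.

    Per-run replicate responses are
    ``y = (baseline + sum_f effects[f][level]) * exp(N(0, noise_sd))``.
    """

    effects: tuple  # (n_factors, 5) additive level effects
    baseline: float = 1.0
    noise_sd: float = 0.1  # SD of the log-normal multiplicative noise
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")


def generate_taguchi_responses(
    design: TaguchiDesign, truth: TaguchiTruth
) -> pd.DataFrame:
    """Synthetic replicate responses for every design run.

    Returns a tidy table with columns ``run``, ``rep``, ``y``; strictly
    positive by construction.  Raises if the additive means are not all
    positive.
    """
    eff = np.asarray(truth.effects, dtype=float)
    if eff.shape != (len(design.factors), 5):
        raise ValueError("effects must be (n_factors, 5)")
    rng = np.random.default_rng(truth.seed)
    means = truth.baseline + np.sum(
        eff[np.arange(eff.shape[0])[None, :], design.runs], axis=1
    )
    if np.any(means <= 0):
        raise ValueError("baseline + effects must stay positive")
    rows = []
    for run, mu in enumerate(means):
        noise = np.exp(rng.normal(0.0, truth.noise_sd, truth.replicates))
        for rep, y in enumerate(mu * noise):
            rows.append((run, rep, float(y)))
    return pd.DataFrame(rows, columns=["run", "rep", "y"])


def generate_stress_strain(
    y_true: float,
    noise_sd: float = 0.0,
    n_points: int = 200,
    seed: int = 0,
    toe_strain: float = 0.0,
    max_strain: float = 0.15,
    a0_mm2: float = 5.0,
    l0_mm: float = 10.0,
) -> StressStrainRecord:
    """Synthetic tensile record with modulus ``y_true`` (N/mm^2).

    The toe region (strain below ``toe_strain``) is quadratic and joins
    the linear branch C1-continuously: beyond the toe the stress is
    exactly ``y_true * (strain - toe_strain/2)``, so a fit windowed past
    the toe recovers the modulus exactly at zero noise.  Noise is
    multiplicative Gaussian on stress.
    """
    if y_true <= 0:
        raise ValueError("y_true must be positive")
    rng = np.random.default_rng(seed)
    strain = np.linspace(0.0, max_strain, n_points)
    if toe_strain > 0:
        stress = np.where(
            strain <= toe_strain,
            y_true * strain**2 / (2 * toe_strain),
            y_true * (strain - toe_strain / 2),
        )
    else:
        stress = y_true * strain
    if noise_sd > 0:
        stress = stress * (1.0 + rng.normal(0.0, noise_sd, stress.shape))
    return StressStrainRecord(
        force_N=stress * a0_mm2,
        elongation_mm=strain * l0_mm,
        A0_mm2=a0_mm2,
        L0_mm=l0_mm,
    )
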