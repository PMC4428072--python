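"""Young's modulus from tensile force-elongation records.

Stress is F/A0, strain is dL/L0; the modulus is the least-squares slope
of stress against strain restricted to the linear part of the curve.
The linear part is operationalized as a configurable strain window
(default 0.02-0.10), with an optional automatic pick that maximizes R^2
over sliding windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["StressStrainRecord", "youngs_modulus", "record_from_csv"]


@dataclass
class StressStrainRecord:
    """Force (N) and elongation (mm) series with sample geometry.

    A0 is the sample cross-section (mm^2), L0 the gauge length (mm), so
    stress = F/A0 is in N/mm^2 and strain = dL/L0 dimensionless.
    """

    force_N: np.ndarray
    elongation_mm: np.ndarray
    A0_mm2: float
    L0_mm: float

    def __post_init__(self) -> None:
        self.force_N = np.asarray(self.force_N, dtype=float)
        self.elongation_mm = np.asarray(self.elongation_mm, dtype=float)
        if self.A0_mm2 <= 0 or self.L0_mm <= 0:
            raise ValueError("A0 and L0 must be positive")
        if self.force_N.shape != self.elongation_mm.shape:
            raise ValueError("force and elongation series differ in length")
        if np.any(np.diff(self.elongation_mm) < 0):
            raise ValueError("elongation must be non-decreasing")

    @property
    def strain(self) -> np.ndarray:
        return self.elongation_mm / self.L0_mm

    @property
    def stress(self) -> np.ndarray:
        return self.force_N / self.A0_mm2


def youngs_modulus(
    rec: StressStrainRecord,
    linear_window: tuple[float, float] = (0.02, 0.10),
    auto_window: bool = False,
    min_points: int = 5,
) -> float:
    """Slope (N/mm^2) of stress vs strain inside the linear window.

    With ``auto_window`` the window is chosen as the sliding strain
    interval of the given width maximizing the R^2 of the linear fit.
    Raises if fewer than ``min_points`` samples fall in the window or
    the windowed strain range is zero.
    """
    strain, stress = rec.strain, rec.stress
    if auto_window:
        linear_window = _best_window(
            strain, stress, width=linear_window[1] - linear_window[0]
        )
    lo, hi = linear_window
    sel = (strain >= lo) & (strain <= hi)
    if sel.sum() < max(2, min_points):
        raise ValueError(
            f"only {int(sel.sum())} points in strain window [{lo}, {hi}]"
        )
    s = strain[sel]
    if np.ptp(s) == 0:
        raise ValueError("zero strain range inside window")
    slope, _ = np.polyfit(s, stress[sel], 1)
    return float(slope)


def _best_window(strain, stress, width: float, n_starts: int = 50):
    starts = np.linspace(strain.min(), max(strain.max() - width, strain.min()),
                         n_starts)
    best, best_r2 = (strain.min(), strain.min() + width), -np.inf
    for s0 in starts:
        sel = (strain >= s0) & (strain <= s0 + width)
        if sel.sum() < 5 or np.ptp(strain[sel]) == 0:
            continue
        r = np.corrcoef(strain[sel], stress[sel])[0, 1]
        if np.isfinite(r) and r**2 > best_r2:
            best_r2, best = r**2, (s0, s0 + width)
    return best


def record_from_csv(path, a0_mm2: float, l0_mm: float) -> StressStrainRecord:
    """Load a (force_N, elongation_mm) CSV into a record."""
    df = pd.read_csv(path)
    if not {"force_N", "elongation_mm"} <= set(df.columns):
        raise ValueError("CSV needs columns force_N, elongation_mm")
    return StressStrainRecord(
        df["force_N"].to_numpy(), df["elongation_mm"].to_numpy(), a0_mm2, l0_mm
    )
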