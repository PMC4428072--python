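"""DC conduction in the layered skin fold: nabla.(sigma nabla U) = 0.

Skin behaves resistively for pulses much longer than the membrane
charging time, so a direct-current conductance model suffices: the
potential solves the heterogeneous Laplace equation with the applied
voltage on the cathode contact, ground on the anode contact, and zero
normal current elsewhere.  A closed-form series-layer solution (the
layers act as resistors in series within the treated column) serves as
an independent 1D oracle for the 2D solver.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._fv import RectFV
from .core import ElectrodeSpec, SimulationDomain, SkinStack

__all__ = [
    "PotentialField",
    "EFieldMap",
    "analytic_series_field",
    "solve_potential_2d",
    "efield_from_potential",
    "per_layer_field",
    "total_current",
]


@dataclass
class PotentialField:
    """Cell-centred electric potential (V) and the assembled system."""

    values: np.ndarray  # (nx, ny), V
    voltage: float
    domain: SimulationDomain
    _fv: RectFV


@dataclass
class EFieldMap:
    """Per-cell field components and magnitude (V/mm)."""

    ex: np.ndarray
    ey: np.ndarray
    magnitude: np.ndarray
    domain: SimulationDomain


def analytic_series_field(
    stack: SkinStack, voltage: float, folded: bool = True
) -> dict[str, float]:
    """Per-layer |E| (V/mm) of a laterally uniform stack, in closed form.

    With a uniform current density J through the (optionally mirrored)
    stack, J = V / sum_i(t_i / sigma_i) and E_i = J / sigma_i.
    """
    layers = list(stack.layers)
    if folded:
        layers = layers + list(reversed(layers))
    if any(l.sigma <= 0 for l in layers):
        raise ValueError("all conductivities must be positive")
    r_area = sum(l.thickness_um * 1e-6 / l.sigma for l in layers)  # ohm m^2
    j = voltage / r_area  # A/m^2
    return {l.name: j / l.sigma / 1e3 for l in stack.layers}  # V/mm


def solve_potential_2d(domain: SimulationDomain, voltage: float) -> PotentialField:
    """Solve the DC conduction problem on the fold domain.

    Dirichlet U = ``voltage`` on the cathode contact (x = 0, treated
    columns), U = 0 on the anode contact; zero normal current on all
    other boundaries.  Sparse direct solve.
    """
    fv = RectFV(
        domain.x_edges_um * 1e-6,
        domain.y_edges_um * 1e-6,
        domain.out_of_plane_um * 1e-6,
        domain.sigma,
    )
    jt = np.flatnonzero(domain.treated)
    fv.add_dirichlet(np.zeros_like(jt), jt, "x-", voltage)
    fv.add_dirichlet(np.full_like(jt, domain.nx - 1), jt, "x+", 0.0)
    u = fv.solve_steady()
    return PotentialField(values=u, voltage=voltage, domain=domain, _fv=fv)


def _face_flux_x(domain: SimulationDomain, u: np.ndarray, voltage: float):
    """Current density (A/m^2) through x-faces, harmonic-mean form.

    Returns (nx+1, ny); boundary faces use the Dirichlet contact values
    on treated columns and zero current elsewhere.
    """
    dx = np.diff(domain.x_edges_um) * 1e-6
    sig = domain.sigma
    jx = np.zeros((domain.nx + 1, domain.ny))
    res = dx[:-1, None] / (2 * sig[:-1, :]) + dx[1:, None] / (2 * sig[1:, :])
    jx[1:-1, :] = (u[:-1, :] - u[1:, :]) / res
    t = domain.treated
    jx[0, t] = (voltage - u[0, t]) / (dx[0] / (2 * sig[0, t]))
    jx[-1, t] = (u[-1, t] - 0.0) / (dx[-1] / (2 * sig[-1, t]))
    return jx


def efield_from_potential(potential: PotentialField) -> EFieldMap:
    """Per-cell field (V/mm) from the solved potential.

    Within each cell the field is the face current density divided by
    the cell conductivity (E = J/sigma), averaged over the two opposing
    faces; this reproduces the series solution exactly on laterally
    uniform stacks.
    """
    domain = potential.domain
    u = potential.values
    jx = _face_flux_x(domain, u, potential.voltage)
    ex = 0.5 * (jx[:-1, :] + jx[1:, :]) / domain.sigma

    dy = np.diff(domain.y_edges_um) * 1e-6
    jy = np.zeros((domain.nx, domain.ny + 1))
    res = dy[None, :-1] / (2 * domain.sigma[:, :-1]) + dy[None, 1:] / (
        2 * domain.sigma[:, 1:]
    )
    jy[:, 1:-1] = (u[:, :-1] - u[:, 1:]) / res
    ey = 0.5 * (jy[:, :-1] + jy[:, 1:]) / domain.sigma

    ex /= 1e3  # V/m -> V/mm
    ey /= 1e3
    return EFieldMap(
        ex=ex, ey=ey, magnitude=np.hypot(ex, ey), domain=domain
    )


def per_layer_field(efield: EFieldMap, domain: SimulationDomain) -> pd.Series:
    """|E| (V/mm) per named layer at the treated-column layer midpoint.

    Sampled at the lateral centre of the treated region, at the midpoint
    depth of each layer's outer slab (the mirrored slab is symmetric).
    """
    jc = domain.center_column
    xc = 0.5 * (domain.x_edges_um[:-1] + domain.x_edges_um[1:])
    out = {}
    for name, i0, i1 in domain.slabs:
        if name in out:
            continue
        mid = 0.5 * (domain.x_edges_um[i0] + domain.x_edges_um[i1])
        i = i0 + int(np.argmin(np.abs(xc[i0:i1] - mid)))
        out[name] = float(efield.magnitude[i, jc])
    return pd.Series(out, name="E_V_per_mm")


def total_current(
    potential: PotentialField,
    domain: SimulationDomain,
    electrode: ElectrodeSpec | None = None,
) -> float:
    """Current (A) through the cathode contact.

    Integral of sigma dU/dn over the contact, times the out-of-plane
    depth implied by the electrode contact area.
    """
    jx = _face_flux_x(domain, potential.values, potential.voltage)
    dy = np.diff(domain.y_edges_um) * 1e-6
    w = domain.out_of_plane_um * 1e-6
    t = domain.treated
    return float(np.sum(jx[0, t] * dy[t]) * w)


def anode_current(potential: PotentialField, domain: SimulationDomain) -> float:
    """Current (A) through the anode contact (conservation check)."""
    jx = _face_flux_x(potential.domain, potential.values, potential.voltage)
    dy = np.diff(domain.y_edges_um) * 1e-6
    w = domain.out_of_plane_um * 1e-6
    t = domain.treated
    return float(np.sum(jx[-1, t] * dy[t]) * w)
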