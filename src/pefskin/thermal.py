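"""Transient heat conduction with duty-cycle-averaged Joule sources.

Solves rho*cp dT/dt = div(lambda grad T) + q on the skin-fold domain,
where q = sigma |E|^2 * duty is the pulse-train-averaged volumetric
heating from the DC field solution.  The electrode plates are included
as conducting solids.  Boundary conditions: the far lateral (body)
boundary is held at T_in; exposed skin and electrode side faces
exchange heat with air by convection (coefficient h); the outer
electrode faces are either clamped at T_in (default, modelling the
electrode assembly as a heat sink in thermal contact with the body -
the only configuration under which the system reaches a steady state
within the treatment time) or convective.

Time integration is backward Euler: the grid resolves 5-um strata, so
an explicit scheme would be prohibitively stiff at dt ~ 0.05 s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from ._fv import RectFV
from .core import ElectrodeSpec, SimulationDomain, PulseProtocol, ThermalBoundary
from .efield import EFieldMap

__all__ = [
    "JouleSourceMap",
    "TemperatureSeries",
    "joule_source_map",
    "solve_transient",
    "steady_state_temperatures",
    "time_to_steady",
]


@dataclass
class JouleSourceMap:
    """Per-cell volumetric heating q (W/m^3) on the skin grid."""

    q: np.ndarray  # (nx, ny)
    domain: SimulationDomain

    @property
    def total_power(self) -> float:
        """Domain-integrated power (W)."""
        dx = np.diff(self.domain.x_edges_um) * 1e-6
        dy = np.diff(self.domain.y_edges_um) * 1e-6
        w = self.domain.out_of_plane_um * 1e-6
        return float(np.sum(self.q * dx[:, None] * dy[None, :] * w))


def joule_source_map(
    efield: EFieldMap, domain: SimulationDomain, protocol: PulseProtocol
) -> JouleSourceMap:
    """Average Joule heating q = sigma |E|^2 * (t_p * f) per cell."""
    if efield.magnitude.shape != domain.sigma.shape:
        raise ValueError("field and domain grids do not match")
    e_si = efield.magnitude * 1e3  # V/mm -> V/m
    q = domain.sigma * e_si**2 * protocol.duty
    return JouleSourceMap(q=q, domain=domain)


@dataclass
class TemperatureSeries:
    """Result of a transient thermal run.

    ``layer_traces`` holds the temperature (deg C) at each layer's
    treated-centre midpoint versus ``times``; ``snapshots`` holds full
    fields (NaN on inactive cells) at coarser intervals.  ``power_in``
    and ``power_out_final`` support steady-state energy audits.
    """

    times: np.ndarray
    layer_traces: dict
    snapshot_times: np.ndarray
    snapshots: list
    final_field: np.ndarray
    T_in: float
    domain: SimulationDomain
    skin_row_offset: int
    power_in: float
    power_out_final: float
    layer_cells: dict = field(default_factory=dict)

    def drift(self) -> float:
        """Largest trace variation (deg C) over the final 10% of the run."""
        i0 = int(0.9 * (len(self.times) - 1))
        return max(
            float(np.ptp(tr[i0:])) for tr in self.layer_traces.values()
        )


def _thermal_grid(domain: SimulationDomain, electrode: ElectrodeSpec):
    """Extend the skin grid with electrode plates over the treated columns."""
    n_e = max(2, int(round(electrode.thickness_um / 250.0)))
    te = electrode.thickness_um
    x_skin = domain.x_edges_um
    x_top = np.linspace(-te, 0.0, n_e + 1)
    x_bot = np.linspace(x_skin[-1], x_skin[-1] + te, n_e + 1)
    x_all = np.concatenate([x_top[:-1], x_skin, x_bot[1:]])
    nx = len(x_all) - 1
    ny = domain.ny

    lam = np.empty((nx, ny))
    rho_cp = np.empty((nx, ny))
    active = np.zeros((nx, ny), dtype=bool)

    sl_top = slice(0, n_e)
    sl_skin = slice(n_e, n_e + domain.nx)
    sl_bot = slice(n_e + domain.nx, nx)

    lam[sl_skin] = domain.lam
    rho_cp[sl_skin] = domain.rho * domain.cp
    active[sl_skin] = True

    for sl in (sl_top, sl_bot):
        lam[sl] = electrode.lam
        rho_cp[sl] = electrode.rho * electrode.cp
        active[sl, domain.treated] = True

    return x_all, lam, rho_cp, active, n_e


def solve_transient(
    domain: SimulationDomain,
    q: JouleSourceMap,
    bc: ThermalBoundary,
    dt: float = 0.05,
    t_end: float = 70.0,
    snapshot_every: float = 5.0,
) -> TemperatureSeries:
    """Integrate the bioheat equation from T = T_in with backward Euler."""
    if dt <= 0 or t_end <= 0:
        raise ValueError("dt and t_end must be positive")
    if bc.T_air > bc.T_in + 100 or bc.h < 0:
        raise ValueError("non-physical boundary condition")
    electrode = domain.electrode
    x_all, lam, rho_cp, active, n_e = _thermal_grid(domain, electrode)
    ny = domain.ny
    nx = lam.shape[0]
    w = domain.out_of_plane_um * 1e-6

    fv = RectFV(x_all * 1e-6, domain.y_edges_um * 1e-6, w, lam, active=active)

    jt = np.flatnonzero(domain.treated)
    ju = np.flatnonzero(~domain.treated)
    i_skin0, i_skin1 = n_e, n_e + domain.nx - 1

    # outer electrode faces
    if bc.electrode_outer == "fixed":
        fv.add_dirichlet(np.zeros_like(jt), jt, "x-", bc.clamp_temp)
        fv.add_dirichlet(np.full_like(jt, nx - 1), jt, "x+", bc.clamp_temp)
    else:
        fv.add_robin(np.zeros_like(jt), jt, "x-", bc.h, bc.T_air)
        fv.add_robin(np.full_like(jt, nx - 1), jt, "x+", bc.h, bc.T_air)

    # exposed skin surface over the untreated margin
    if ju.size:
        fv.add_robin(np.full_like(ju, i_skin0), ju, "x-", bc.h, bc.T_air)
        fv.add_robin(np.full_like(ju, i_skin1), ju, "x+", bc.h, bc.T_air)

    # electrode side faces to air
    e_rows = np.concatenate([np.arange(n_e), np.arange(i_skin1 + 1, nx)])
    if jt.size and jt[0] > 0:
        fv.add_robin(e_rows, np.full_like(e_rows, jt[0]), "y-", bc.h, bc.T_air)
    if jt.size and jt[-1] < ny - 1:
        fv.add_robin(e_rows, np.full_like(e_rows, jt[-1]), "y+", bc.h, bc.T_air)

    # far lateral boundary: body at T_in
    skin_rows = np.arange(i_skin0, i_skin1 + 1)
    if not domain.treated[0]:
        fv.add_dirichlet(skin_rows, np.zeros_like(skin_rows), "y-", bc.T_in)
        fv.add_dirichlet(skin_rows, np.full_like(skin_rows, ny - 1), "y+", bc.T_in)

    a_mat, b_vec = fv.operator()
    mass = fv.flatten(rho_cp) * fv.flatten(fv.vol) / dt

    source_full = np.zeros((nx, ny))
    source_full[i_skin0 : i_skin1 + 1, :] = q.q * (
        np.diff(domain.x_edges_um)[:, None] * 1e-6
    ) * (np.diff(domain.y_edges_um)[None, :] * 1e-6) * w
    s_vec = fv.flatten(source_full)

    lhs = (sp.diags(mass) + a_mat).tocsc()
    lu = splu(lhs)

    # trace cells: layer midpoints on the treated centre column
    jc = domain.center_column
    xc_skin = 0.5 * (domain.x_edges_um[:-1] + domain.x_edges_um[1:])
    trace_idx: dict[str, list[int]] = {}
    layer_cells: dict[str, np.ndarray] = {}
    for name, i0, i1 in domain.slabs:
        mid = 0.5 * (domain.x_edges_um[i0] + domain.x_edges_um[i1])
        i = i0 + int(np.argmin(np.abs(xc_skin[i0:i1] - mid)))
        trace_idx.setdefault(name, []).append(int(fv.index[n_e + i, jc]))
    for name in trace_idx:
        rows = domain.layer_rows(name) + n_e
        cells = fv.index[np.ix_(rows, jt)]
        layer_cells[name] = cells[cells >= 0]

    n_steps = int(round(t_end / dt))
    times = np.arange(n_steps + 1) * dt
    t_vec = np.full(fv.n, bc.T_in)
    traces = {name: np.empty(n_steps + 1) for name in trace_idx}
    for name, idx in trace_idx.items():
        traces[name][0] = t_vec[idx].max()

    snap_stride = max(1, int(round(snapshot_every / dt)))
    snapshot_times = [0.0]
    snapshots = [fv.embed(t_vec)]

    for step in range(1, n_steps + 1):
        t_vec = lu.solve(mass * t_vec + b_vec + s_vec)
        if not np.all(np.isfinite(t_vec)):
            raise RuntimeError(f"thermal solve diverged at step {step}")
        for name, idx in trace_idx.items():
            traces[name][step] = t_vec[idx].max()
        if step % snap_stride == 0 or step == n_steps:
            snapshot_times.append(step * dt)
            snapshots.append(fv.embed(t_vec))

    power_out = fv.boundary_outflow(t_vec)
    return TemperatureSeries(
        times=times,
        layer_traces=traces,
        snapshot_times=np.asarray(snapshot_times),
        snapshots=snapshots,
        final_field=snapshots[-1],
        T_in=bc.T_in,
        domain=domain,
        skin_row_offset=n_e,
        power_in=q.total_power,
        power_out_final=power_out,
        layer_cells=layer_cells,
    )


class NotSteadyError(RuntimeError):
    pass


def steady_state_temperatures(
    series: TemperatureSeries, tol: float = 0.05, strict: bool = False
) -> dict[str, float]:
    """Per-layer maximum temperature over the treated column at the final time.

    With ``strict`` the final 10% of every trace must vary by less than
    ``tol`` deg C, otherwise :class:`NotSteadyError` reports the
    achieved drift.
    """
    drift = series.drift()
    if strict and drift > tol:
        raise NotSteadyError(
            f"traces still drift by {drift:.3f} degC over the final 10%"
        )
    flat = series.final_field[np.isfinite(series.final_field)]
    out = {}
    for name, cells in series.layer_cells.items():
        out[name] = float(flat[cells].max())
    return out


def time_to_steady(series: TemperatureSeries, frac: float = 0.05) -> float:
    """Earliest time from which every layer midpoint trace stays within
    ``frac`` of its final temperature rise above T_in.

    Returns 0 for an unheated run (zero final rise everywhere).
    """
    t_settle = 0.0
    for trace in series.layer_traces.values():
        rise = trace[-1] - series.T_in
        if abs(rise) < 1e-9:  # unheated trace: settled from the start
            continue
        ok = np.abs(trace - trace[-1]) <= frac * abs(rise)
        # last index before which the criterion is violated
        bad = np.flatnonzero(~ok)
        t_layer = 0.0 if bad.size == 0 else series.times[min(bad[-1] + 1, len(trace) - 1)]
        t_settle = max(t_settle, float(t_layer))
    if t_settle >= series.times[-1]:
        raise NotSteadyError("traces do not settle within the simulated horizon")
    return t_settle
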