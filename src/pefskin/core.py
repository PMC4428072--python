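"""Domain types for layered-skin electro-thermal simulation.

The model system is a dorsal skin fold pinched between two plate
electrodes: the five-layer stack (stratum corneum, epidermis, dermis,
panniculus carnosus, subcutaneous tissue) appears twice, mirrored about
the fold midplane, so the subcutaneous layers of the two skin halves
touch at the centre.  Material properties are tabulated per layer for
two membrane states, ``normal`` (intact) and ``electroporated``
(end-of-treatment conductivities).

Lengths are stored in micrometres and converted to SI internally;
temperatures are degrees Celsius at the interface.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "MaterialLayer",
    "SkinStack",
    "ElectrodeSpec",
    "PulseProtocol",
    "ThermalBoundary",
    "SimulationDomain",
    "default_stack",
    "default_electrode",
    "duty_and_vrms",
    "build_fold_domain",
    "stack_to_csv",
    "stack_from_csv",
    "save_config",
    "load_config",
]


@dataclass(frozen=True)
class MaterialLayer:
    """One skin stratum with its electrical and thermal properties.

    Parameters
    ----------
    name : str
        Layer label (e.g. ``"dermis"``).
    thickness_um : float
        Layer thickness in micrometres.
    sigma : float
        Electrical conductivity, S/m.
    lam : float
        Thermal conductivity, W/(K·m).
    cp : float
        Specific heat capacity, J/(kg·K).
    rho : float
        Mass density, kg/m^3.
    """

    name: str
    thickness_um: float
    sigma: float
    lam: float
    cp: float
    rho: float

    def __post_init__(self) -> None:
        for attr in ("thickness_um", "sigma", "lam", "cp", "rho"):
            if not getattr(self, attr) > 0:
                raise ValueError(f"{self.name}: {attr} must be > 0")


# Material registry: per-layer properties of rat skin used by the
# conduction and bioheat models.  Thickness (um), sigma (S/m),
# lambda (W/K/m), cp (J/kg/K), rho (kg/m^3).
_LAYER_TABLE = {
    "normal": [
        ("stratum corneum", 5.0, 0.0000125, 0.23, 3300.0, 1100.0),
        ("epidermis", 5.0, 0.2, 0.23, 3300.0, 1100.0),
        ("dermis", 400.0, 0.2, 0.45, 3300.0, 1100.0),
        ("panniculus carnosus", 300.0, 0.4, 0.5, 3300.0, 1100.0),
        ("subcutaneous", 300.0, 0.02, 0.19, 3300.0, 1100.0),
    ],
    "electroporated": [
        ("stratum corneum", 5.0, 1.0, 0.23, 3300.0, 1100.0),
        ("epidermis", 5.0, 0.8, 0.23, 3300.0, 1100.0),
        ("dermis", 400.0, 0.8, 0.45, 3300.0, 1100.0),
        ("panniculus carnosus", 300.0, 1.0, 0.5, 3300.0, 1100.0),
        ("subcutaneous", 300.0, 0.2, 0.19, 3300.0, 1100.0),
    ],
}

_ELECTRODE_ROW = dict(sigma=1.45e6, lam=16.0, cp=466.0, rho=8000.0)


@dataclass(frozen=True)
class SkinStack:
    """Ordered list of layers from the outer surface inward."""

    layers: tuple[MaterialLayer, ...]
    state: str = "custom"

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("stack needs at least one layer")

    @property
    def thickness_um(self) -> float:
        return float(sum(l.thickness_um for l in self.layers))

    def layer(self, name: str) -> MaterialLayer:
        for l in self.layers:
            if l.name == name:
                return l
        raise KeyError(name)


def default_stack(state: str) -> SkinStack:
    """Return the tabulated five-layer rat-skin stack for a membrane state.

    ``state`` is ``"normal"`` or ``"electroporated"``.
    """
    try:
        rows = _LAYER_TABLE[state]
    except KeyError:
        raise ValueError(
            f"unknown state {state!r}; expected 'normal' or 'electroporated'"
        ) from None
    return SkinStack(tuple(MaterialLayer(*row) for row in rows), state=state)


@dataclass(frozen=True)
class ElectrodeSpec:
    """Plate electrode pair: contact area, gap, and plate material.

    ``thickness_um`` is the plate thickness used when the electrodes are
    included as conducting solids in the thermal model.
    """

    contact_area_cm2: float = 1.0
    separation_mm: float = 2.0
    thickness_um: float = 1000.0
    sigma: float = _ELECTRODE_ROW["sigma"]
    lam: float = _ELECTRODE_ROW["lam"]
    cp: float = _ELECTRODE_ROW["cp"]
    rho: float = _ELECTRODE_ROW["rho"]

    def __post_init__(self) -> None:
        if self.contact_area_cm2 <= 0 or self.separation_mm <= 0:
            raise ValueError("electrode geometry must be positive")

    @property
    def contact_width_um(self) -> float:
        """Width of the contact in the 2D cross-section (square contact)."""
        return math.sqrt(self.contact_area_cm2) * 1e4

    @property
    def separation_um(self) -> float:
        return self.separation_mm * 1e3


def default_electrode() -> ElectrodeSpec:
    return ElectrodeSpec()


@dataclass(frozen=True)
class PulseProtocol:
    """Square-pulse train: voltage (V), pulse length t_p (s), count, frequency (Hz)."""

    voltage: float
    t_p: float
    n_pulses: int
    freq: float

    def __post_init__(self) -> None:
        if self.voltage < 0 or self.t_p < 0 or self.n_pulses <= 0 or self.freq <= 0:
            raise ValueError("protocol parameters out of range")
        if self.t_p * self.freq >= 1:
            raise ValueError("duty cycle t_p*freq must be < 1")

    @property
    def duty(self) -> float:
        """Fraction of time the pulse is on."""
        return self.t_p * self.freq

    @property
    def v_rms(self) -> float:
        """RMS voltage of the square pulse train, V*sqrt(t_p*f)."""
        return self.voltage * math.sqrt(self.duty)

    @property
    def total_time_s(self) -> float:
        return self.n_pulses / self.freq


def duty_and_vrms(protocol: PulseProtocol) -> tuple[float, float]:
    """Duty cycle and RMS voltage of a pulse train."""
    return protocol.duty, protocol.v_rms


@dataclass(frozen=True)
class ThermalBoundary:
    """Thermal boundary data.

    T_in is the initial/body temperature (deg C), imposed on the far
    lateral (body) boundary; T_air the ambient air temperature; h the
    convection coefficient (W/K/m^2) between exposed surfaces and air.
    ``electrode_outer`` selects the condition on the outer electrode
    faces: ``"fixed"`` clamps them at ``electrode_temp`` (defaults to
    T_in), modelling the electrode assembly as a heat sink in thermal
    contact with the body; ``"convective"`` applies h to T_air instead.
    """

    T_in: float = 37.0
    T_air: float = 25.0
    h: float = 5.0
    electrode_outer: str = "fixed"
    electrode_temp: float | None = None

    def __post_init__(self) -> None:
        if self.h < 0:
            raise ValueError("h must be >= 0")
        if self.electrode_outer not in ("fixed", "convective"):
            raise ValueError("electrode_outer must be 'fixed' or 'convective'")

    @property
    def clamp_temp(self) -> float:
        return self.T_in if self.electrode_temp is None else self.electrode_temp


@dataclass
class SimulationDomain:
    """2D rectilinear skin-fold cross-section.

    Axes: depth ``x`` from cathode (x=0) to anode, lateral ``y`` centred
    on the treated region.  The grid is layer-conforming along depth:
    cell boundaries coincide with layer interfaces, so 5 um strata are
    resolved without a uniform fine mesh.

    Attributes
    ----------
    x_edges_um, y_edges_um : ndarray
        Cell edge coordinates (depth: nx+1, lateral: ny+1).
    treated : ndarray of bool, shape (ny,)
        Columns under the electrode contact.
    slabs : list of (name, i0, i1)
        Depth row ranges of the mirrored layer slabs (10 entries for the
        default five-layer stack).
    sigma, lam, cp, rho : ndarray, shape (nx, ny)
        Per-cell material properties (SI units).
    layer_of_row : list of str, length nx
        Layer name of each depth row.
    """

    x_edges_um: np.ndarray
    y_edges_um: np.ndarray
    treated: np.ndarray
    slabs: list
    sigma: np.ndarray
    lam: np.ndarray
    cp: np.ndarray
    rho: np.ndarray
    layer_of_row: list
    electrode: ElectrodeSpec
    treated_stack: SkinStack
    untreated_stack: SkinStack

    @property
    def nx(self) -> int:
        return len(self.x_edges_um) - 1

    @property
    def ny(self) -> int:
        return len(self.y_edges_um) - 1

    @property
    def depth_um(self) -> float:
        return float(self.x_edges_um[-1] - self.x_edges_um[0])

    @property
    def width_um(self) -> float:
        return float(self.y_edges_um[-1] - self.y_edges_um[0])

    @property
    def out_of_plane_um(self) -> float:
        """Out-of-plane depth implied by the electrode contact area."""
        treated_width = self.y_edges_um[np.flatnonzero(self.treated)[-1] + 1] - \
            self.y_edges_um[np.flatnonzero(self.treated)[0]]
        return self.electrode.contact_area_cm2 * 1e8 / treated_width

    @property
    def center_column(self) -> int:
        jt = np.flatnonzero(self.treated)
        return int(jt[len(jt) // 2])

    def layer_rows(self, name: str) -> np.ndarray:
        """All depth-row indices belonging to a named layer (both mirrored slabs)."""
        rows = [i for i, n in enumerate(self.layer_of_row) if n == name]
        if not rows:
            raise KeyError(name)
        return np.asarray(rows)

    def layer_names(self) -> list[str]:
        seen: list[str] = []
        for name, _, _ in self.slabs:
            if name not in seen:
                seen.append(name)
        return seen


def _subdivide(t0: float, t1: float, target: float) -> np.ndarray:
    n = max(1, int(round((t1 - t0) / target)))
    return np.linspace(t0, t1, n + 1)


def build_fold_domain(
    stack: SkinStack,
    electrode: ElectrodeSpec | None = None,
    lateral_treated_um: float | None = None,
    lateral_margin_um: float = 5000.0,
    cell_size_um: float = 10.0,
    lateral_cell_um: float = 250.0,
    untreated_stack: SkinStack | None = None,
    mismatch_tol: float = 0.05,
) -> SimulationDomain:
    """Construct the mirrored skin-fold domain between the electrode plates.

    The stack is mirrored about the fold midplane (the innermost layers
    of the two skin halves are adjacent at the midline); the outer
    surfaces touch the electrodes.  Columns under the electrode contact
    use ``stack`` (normally the electroporated properties); the lateral
    margin uses ``untreated_stack`` (default: the normal-skin stack with
    matching layer thicknesses).

    Raises ``ValueError`` if twice the stack thickness differs from the
    electrode separation by more than ``mismatch_tol`` (the fold must
    fill the gap).
    """
    electrode = electrode or default_electrode()
    if lateral_treated_um is None:
        lateral_treated_um = electrode.contact_width_um
    depth = 2 * stack.thickness_um
    mismatch = abs(depth - electrode.separation_um) / electrode.separation_um
    if mismatch > mismatch_tol:
        raise ValueError(
            f"folded stack depth {depth:.0f} um differs from electrode "
            f"separation {electrode.separation_um:.0f} um by {100 * mismatch:.1f}%"
        )
    if untreated_stack is None:
        if len(stack.layers) == 5:
            untreated_stack = default_stack("normal")
        else:
            untreated_stack = stack
    if len(untreated_stack.layers) != len(stack.layers):
        raise ValueError("treated and untreated stacks must have matching layers")

    mirrored = list(stack.layers) + list(reversed(stack.layers))
    mirrored_un = list(untreated_stack.layers) + list(reversed(untreated_stack.layers))

    # depth grid, conforming to layer interfaces
    x_edges = [0.0]
    slabs = []
    layer_of_row: list[str] = []
    for lay in mirrored:
        seg = _subdivide(x_edges[-1], x_edges[-1] + lay.thickness_um, cell_size_um)
        i0 = len(x_edges) - 1
        x_edges.extend(seg[1:].tolist())
        i1 = len(x_edges) - 1
        slabs.append((lay.name, i0, i1))
        layer_of_row.extend([lay.name] * (i1 - i0))
    x_edges = np.asarray(x_edges)

    # lateral grid: margin | treated | margin, conforming at region edges
    y_parts = []
    if lateral_margin_um > 0:
        y_parts.append(_subdivide(0.0, lateral_margin_um, lateral_cell_um))
    t0 = lateral_margin_um
    seg = _subdivide(t0, t0 + lateral_treated_um, lateral_cell_um)
    y_parts.append(seg if not y_parts else seg[1:])
    if lateral_margin_um > 0:
        t1 = t0 + lateral_treated_um
        y_parts.append(_subdivide(t1, t1 + lateral_margin_um, lateral_cell_um)[1:])
    y_edges = np.concatenate(y_parts)
    y_centers = 0.5 * (y_edges[:-1] + y_edges[1:])
    treated = (y_centers > lateral_margin_um) & (
        y_centers < lateral_margin_um + lateral_treated_um
    )
    if lateral_margin_um == 0:
        treated[:] = True

    nx, ny = len(x_edges) - 1, len(y_edges) - 1
    sigma = np.empty((nx, ny))
    lam = np.empty((nx, ny))
    cp = np.empty((nx, ny))
    rho = np.empty((nx, ny))
    for (name, i0, i1), lay_t, lay_u in zip(slabs, mirrored, mirrored_un):
        for arr, attr in ((sigma, "sigma"), (lam, "lam"), (cp, "cp"), (rho, "rho")):
            arr[i0:i1, treated] = getattr(lay_t, attr)
            arr[i0:i1, ~treated] = getattr(lay_u, attr)

    return SimulationDomain(
        x_edges_um=x_edges,
        y_edges_um=y_edges,
        treated=treated,
        slabs=slabs,
        sigma=sigma,
        lam=lam,
        cp=cp,
        rho=rho,
        layer_of_row=layer_of_row,
        electrode=electrode,
        treated_stack=stack,
        untreated_stack=untreated_stack,
    )


# ---------------------------------------------------------------------------
# configuration I/O

_CSV_COLUMNS = [
    "name",
    "thickness_um",
    "sigma_S_per_m",
    "lambda_W_per_mK",
    "cp_J_per_kgK",
    "rho_kg_per_m3",
]


def stack_to_csv(stack: SkinStack, path_or_buf=None):
    """Write a stack as a material table CSV (outer surface first)."""
    df = pd.DataFrame(
        [
            [l.name, l.thickness_um, l.sigma, l.lam, l.cp, l.rho]
            for l in stack.layers
        ],
        columns=_CSV_COLUMNS,
    )
    return df.to_csv(path_or_buf, index=False)


def stack_from_csv(path_or_buf, state: str = "custom") -> SkinStack:
    """Read a material table CSV back into a :class:`SkinStack`."""
    if isinstance(path_or_buf, str) and "\n" in path_or_buf:
        path_or_buf = io.StringIO(path_or_buf)
    df = pd.read_csv(path_or_buf)
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"material table missing columns: {sorted(missing)}")
    layers = tuple(
        MaterialLayer(
            str(r["name"]),
            float(r["thickness_um"]),
            float(r["sigma_S_per_m"]),
            float(r["lambda_W_per_mK"]),
            float(r["cp_J_per_kgK"]),
            float(r["rho_kg_per_m3"]),
        )
        for _, r in df.iterrows()
    )
    return SkinStack(layers, state=state)


def save_config(
    path,
    protocol: PulseProtocol,
    electrode: ElectrodeSpec | None = None,
    boundary: ThermalBoundary | None = None,
    geometry: dict | None = None,
) -> None:
    """Write protocol/electrode/boundary settings to a YAML file."""
    cfg = {"protocol": asdict(protocol)}
    if electrode is not None:
        cfg["electrode"] = asdict(electrode)
    if boundary is not None:
        cfg["boundary"] = asdict(boundary)
    if geometry:
        cfg["geometry"] = dict(geometry)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def load_config(path) -> dict:
    """Read a YAML config; returns dict with typed objects where present."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    out: dict = {}
    if "protocol" in cfg:
        out["protocol"] = PulseProtocol(**cfg["protocol"])
    if "electrode" in cfg:
        out["electrode"] = ElectrodeSpec(**cfg["electrode"])
    if "boundary" in cfg:
        out["boundary"] = ThermalBoundary(**cfg["boundary"])
    out["geometry"] = cfg.get("geometry", {})
    return out
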