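"""Finite-volume assembly of 2D diffusion operators on rectilinear grids.

Shared by the DC conduction solver (k = electrical conductivity) and the
transient bioheat solver (k = thermal conductivity).  Cells may be
deactivated (e.g. air above the lateral skin margin in the thermal
grid); faces between an active and an inactive cell default to zero
flux, with Dirichlet/Robin conditions added explicitly per face.

Sign convention: the assembled operator ``A`` satisfies ``A u = b + s``
for steady diffusion with sources ``s >= 0`` (W per cell), i.e. ``A``
collects conductances on the diagonal and negative couplings off it
(an M-matrix, so the discrete maximum principle holds).
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

_SIDES = ("x-", "x+", "y-", "y+")


class RectFV:
    """Assembler for a 5-point diffusion stencil with harmonic-mean faces.

    Parameters
    ----------
    x_edges_m, y_edges_m : array
        Cell edges in metres (depth, lateral).
    w_m : float
        Out-of-plane depth in metres.
    k : ndarray (nx, ny)
        Cell conductivity (S/m or W/K/m).
    active : ndarray of bool, optional
        Active-cell mask.
    """

    def __init__(self, x_edges_m, y_edges_m, w_m, k, active=None):
        self.x_edges = np.asarray(x_edges_m, dtype=float)
        self.y_edges = np.asarray(y_edges_m, dtype=float)
        self.w = float(w_m)
        self.k = np.asarray(k, dtype=float)
        self.nx = len(self.x_edges) - 1
        self.ny = len(self.y_edges) - 1
        if self.k.shape != (self.nx, self.ny):
            raise ValueError("k shape mismatch")
        self.dx = np.diff(self.x_edges)
        self.dy = np.diff(self.y_edges)
        self.vol = self.dx[:, None] * self.dy[None, :] * self.w
        if active is None:
            active = np.ones((self.nx, self.ny), dtype=bool)
        self.active = np.asarray(active, dtype=bool)
        self.n = int(self.active.sum())
        self.index = -np.ones((self.nx, self.ny), dtype=np.int64)
        self.index[self.active] = np.arange(self.n)

        rows, cols, vals = [], [], []
        diag = np.zeros(self.n)

        # x-direction interior faces
        both = self.active[:-1, :] & self.active[1:, :]
        i, j = np.nonzero(both)
        if i.size:
            ka, kb = self.k[i, j], self.k[i + 1, j]
            area = self.dy[j] * self.w
            with np.errstate(divide="ignore"):
                t = area / (self.dx[i] / (2 * ka) + self.dx[i + 1] / (2 * kb))
            a, b = self.index[i, j], self.index[i + 1, j]
            rows += [a, b]
            cols += [b, a]
            vals += [-t, -t]
            np.add.at(diag, a, t)
            np.add.at(diag, b, t)

        # y-direction interior faces
        both = self.active[:, :-1] & self.active[:, 1:]
        i, j = np.nonzero(both)
        if i.size:
            ka, kb = self.k[i, j], self.k[i, j + 1]
            area = self.dx[i] * self.w
            with np.errstate(divide="ignore"):
                t = area / (self.dy[j] / (2 * ka) + self.dy[j + 1] / (2 * kb))
            a, b = self.index[i, j], self.index[i, j + 1]
            rows += [a, b]
            cols += [b, a]
            vals += [-t, -t]
            np.add.at(diag, a, t)
            np.add.at(diag, b, t)

        self._rows = list(np.concatenate(rows)) if rows else []
        self._cols = list(np.concatenate(cols)) if cols else []
        self._vals = list(np.concatenate(vals)) if vals else []
        self._diag = diag
        self._b = np.zeros(self.n)
        # (cell index, conductance, external value) per boundary face,
        # kept for post-hoc boundary-flux audits
        self._bc: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []

    # -- geometry helpers ---------------------------------------------------
    def _face_geom(self, i, j, side):
        i = np.atleast_1d(np.asarray(i, dtype=int))
        j = np.atleast_1d(np.asarray(j, dtype=int))
        if side in ("x-", "x+"):
            area = self.dy[j] * self.w
            half = self.dx[i] / 2.0
        else:
            area = self.dx[i] * self.w
            half = self.dy[j] / 2.0
        return i, j, area, half

    def add_dirichlet(self, i, j, side, value) -> None:
        """Fix the face value on the given side of cells (i, j)."""
        i, j, area, half = self._face_geom(i, j, side)
        t = area / (half / self.k[i, j])
        idx = self.index[i, j]
        if np.any(idx < 0):
            raise ValueError("Dirichlet face on inactive cell")
        value = np.broadcast_to(np.asarray(value, dtype=float), idx.shape).copy()
        np.add.at(self._diag, idx, t)
        np.add.at(self._b, idx, t * value)
        self._bc.append((idx, t, value))

    def add_robin(self, i, j, side, h, t_inf) -> None:
        """Convective exchange h*(u - t_inf) on the given faces."""
        if h == 0:
            return
        i, j, area, half = self._face_geom(i, j, side)
        u = area / (half / self.k[i, j] + 1.0 / h)
        idx = self.index[i, j]
        if np.any(idx < 0):
            raise ValueError("Robin face on inactive cell")
        value = np.broadcast_to(np.asarray(t_inf, dtype=float), idx.shape).copy()
        np.add.at(self._diag, idx, u)
        np.add.at(self._b, idx, u * value)
        self._bc.append((idx, u, value))

    # -- assembly / solution -------------------------------------------------
    def operator(self) -> tuple[sp.csr_matrix, np.ndarray]:
        a = sp.coo_matrix(
            (
                np.concatenate([self._vals, self._diag]) if self._vals else self._diag,
                (
                    np.concatenate([self._rows, np.arange(self.n)])
                    if self._rows
                    else np.arange(self.n),
                    np.concatenate([self._cols, np.arange(self.n)])
                    if self._cols
                    else np.arange(self.n),
                ),
            ),
            shape=(self.n, self.n),
        ).tocsr()
        return a, self._b.copy()

    def solve_steady(self, source=None) -> np.ndarray:
        """Solve A u = b + source; returns the full (nx, ny) field (NaN inactive)."""
        a, b = self.operator()
        if source is not None:
            b = b + np.asarray(source, dtype=float)
        lu = splu(a.tocsc())
        u = lu.solve(b)
        if not np.all(np.isfinite(u)):
            raise RuntimeError("singular or disconnected diffusion system")
        return self.embed(u)

    def embed(self, u: np.ndarray) -> np.ndarray:
        full = np.full((self.nx, self.ny), np.nan)
        full[self.active] = u
        return full

    def flatten(self, field: np.ndarray) -> np.ndarray:
        return np.asarray(field)[self.active]

    def boundary_outflow(self, u_flat: np.ndarray) -> float:
        """Total flux leaving through Dirichlet/Robin faces (W or A)."""
        total = 0.0
        for idx, coef, value in self._bc:
            total += float(np.sum(coef * (u_flat[idx] - value)))
        return total
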