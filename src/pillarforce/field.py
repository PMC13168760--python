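"""Stimulation-chamber electric field: analytic estimate and 2-D solver.

Field stimulation applies a potential difference between two parallel
electrodes across the culture well.  The zeroth-order design number is the
parallel-plate estimate ``E = V / d`` (40 V across 22 mm gives about
1.82 V/mm).  Insulating structures in the chamber (e.g. polymer-coated
micropillars) perturb the field locally; a 2-D finite-difference Laplace
solver quantifies that perturbation: Dirichlet potentials on the electrode
boundaries, zero normal flux on the remaining walls and on insulator
surfaces (perfect insulator), 5-point stencil, solved directly as a sparse
linear system with a residual check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import lil_matrix
from scipy.sparse.linalg import spsolve

__all__ = [
    "ChamberSpec",
    "FieldMap",
    "uniform_field_estimate",
    "solve_field_fd",
]


def uniform_field_estimate(voltage_v: float, gap_mm: float) -> float:
    """Parallel-plate field strength ``E = V / d`` in V/mm."""
    if gap_mm <= 0:
        raise ValueError(f"electrode gap must be positive, got {gap_mm}")
    if voltage_v < 0:
        raise ValueError("voltage must be nonnegative")
    return voltage_v / gap_mm


@dataclass(frozen=True)
class ChamberSpec:
    """2-D chamber cross-section between two plate electrodes.

    The domain is ``electrode_gap_mm`` wide (x, electrode to electrode) and
    ``height_mm`` tall (y).  The left electrode is at ``voltage_v``, the
    right at 0; top and bottom walls are insulating.  ``insulators`` is a
    list of circular inclusions ``(cx_mm, cy_mm, radius_mm)`` treated as
    perfect insulators (zero normal flux on their boundary).
    """

    voltage_v: float = 40.0
    electrode_gap_mm: float = 22.0
    height_mm: float = 11.0
    spacing_mm: float = 0.2
    insulators: tuple = ()

    def __post_init__(self) -> None:
        if self.voltage_v < 0:
            raise ValueError("voltage must be nonnegative")
        if self.electrode_gap_mm <= 0 or self.height_mm <= 0:
            raise ValueError("chamber dimensions must be positive")
        if not 0 < self.spacing_mm < self.electrode_gap_mm / 10.0:
            raise ValueError(
                "grid spacing must be positive and below one tenth of the gap"
            )
        object.__setattr__(self, "insulators", tuple(tuple(c) for c in self.insulators))


@dataclass(frozen=True)
class FieldMap:
    """Solved potential (V) and field magnitude (V/mm) on the grid.

    Grid cells inside insulators hold NaN.  ``x_mm`` / ``y_mm`` are the
    cell-center coordinates; ``residual`` is the max absolute discrete
    Laplacian over interior conducting cells.
    """

    potential_v: np.ndarray
    e_magnitude_v_per_mm: np.ndarray
    x_mm: np.ndarray
    y_mm: np.ndarray
    spacing_mm: float
    residual: float


def _insulator_mask(spec: ChamberSpec, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    X, Y = np.meshgrid(x, y)
    mask = np.zeros(X.shape, dtype=bool)
    for cx, cy, r in spec.insulators:
        mask |= (X - cx) ** 2 + (Y - cy) ** 2 <= r**2
    return mask


def _masked_gradient(phi: np.ndarray, active: np.ndarray, axis: int, h: float) -> np.ndarray:
    """Derivative along ``axis`` using central differences where both
    neighbors are conducting, one-sided at insulator or wall boundaries."""
    fwd = np.roll(phi, -1, axis=axis)
    bwd = np.roll(phi, 1, axis=axis)
    ok_f = np.roll(active, -1, axis=axis) & active
    ok_b = np.roll(active, 1, axis=axis) & active
    # roll wraps around; edge rows/cols must not use the wrapped neighbor
    edge_f = np.zeros_like(active)
    edge_b = np.zeros_like(active)
    sl_f = [slice(None)] * phi.ndim
    sl_f[axis] = -1
    sl_b = [slice(None)] * phi.ndim
    sl_b[axis] = 0
    edge_f[tuple(sl_f)] = True
    edge_b[tuple(sl_b)] = True
    ok_f &= ~edge_f
    ok_b &= ~edge_b

    grad = np.full(phi.shape, np.nan)
    central = ok_f & ok_b
    grad[central] = (fwd[central] - bwd[central]) / (2.0 * h)
    fwd_only = ok_f & ~ok_b
    grad[fwd_only] = (fwd[fwd_only] - phi[fwd_only]) / h
    bwd_only = ok_b & ~ok_f
    grad[bwd_only] = (phi[bwd_only] - bwd[bwd_only]) / h
    isolated = active & ~ok_f & ~ok_b
    grad[isolated] = 0.0
    return grad


def solve_field_fd(spec: ChamberSpec, max_residual: float = 1e-6) -> FieldMap:
    """Solve Laplace's equation on the chamber and return the field map.

    5-point finite-difference stencil on a uniform grid; Dirichlet columns
    at the two electrodes, homogeneous Neumann (mirror) on the top/bottom
    walls and on insulator interfaces.  The sparse system is solved
    directly; the discrete residual must fall below ``max_residual`` times
    the applied potential or an error is raised.
    """
    h = spec.spacing_mm
    nx = int(round(spec.electrode_gap_mm / h)) + 1
    ny = int(round(spec.height_mm / h)) + 1
    x = np.linspace(0.0, spec.electrode_gap_mm, nx)
    y = np.linspace(0.0, spec.height_mm, ny)
    ins = _insulator_mask(spec, x, y)
    if ins[:, 0].any() or ins[:, -1].any():
        raise ValueError("insulator inclusions must not touch the electrodes")

    idx = -np.ones((ny, nx), dtype=int)
    active = ~ins
    idx[active] = np.arange(int(active.sum()))
    n = int(active.sum())

    A = lil_matrix((n, n))
    rhs = np.zeros(n)
    for j in range(ny):
        for i in range(nx):
            if not active[j, i]:
                continue
            row = idx[j, i]
            if i == 0:
                A[row, row] = 1.0
                rhs[row] = spec.voltage_v
                continue
            if i == nx - 1:
                A[row, row] = 1.0
                rhs[row] = 0.0
                continue
            # interior: sum of fluxes to active neighbors; inactive or
            # out-of-domain neighbors are mirrored (zero normal flux)
            diag = 0.0
            for dj, di in ((0, 1), (0, -1), (1, 0), (-1, 0)):
                jj, ii = j + dj, i + di
                if 0 <= jj < ny and 0 <= ii < nx and active[jj, ii]:
                    A[row, idx[jj, ii]] = 1.0
                    diag -= 1.0
            A[row, row] = diag
    phi_flat = spsolve(A.tocsr(), rhs)

    phi = np.full((ny, nx), np.nan)
    phi[active] = phi_flat

    # residual: discrete Laplacian with mirror at inactive neighbors
    residual = 0.0
    for j in range(1, ny - 1):
        for i in range(1, nx - 1):
            if not active[j, i]:
                continue
            acc, cnt = 0.0, 0
            for dj, di in ((0, 1), (0, -1), (1, 0), (-1, 0)):
                jj, ii = j + dj, i + di
                if 0 <= jj < ny and 0 <= ii < nx and active[jj, ii]:
                    acc += phi[jj, ii] - phi[j, i]
                    cnt += 1
            if cnt:
                residual = max(residual, abs(acc))
    if spec.voltage_v > 0 and residual > max_residual * spec.voltage_v:
        raise RuntimeError(
            f"finite-difference solution did not satisfy the residual bound: "
            f"{residual:.3e} > {max_residual:.1e} * {spec.voltage_v}"
        )

    gx = _masked_gradient(phi, active, axis=1, h=h)
    gy = _masked_gradient(phi, active, axis=0, h=h)
    emag = np.hypot(gx, gy)
    return FieldMap(
        potential_v=phi,
        e_magnitude_v_per_mm=emag,
        x_mm=x,
        y_mm=y,
        spacing_mm=h,
        residual=residual,
    )
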