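"""Diffusion-approximation light transport on a 2D voxel grid, the
photoacoustic forward model, the least-squares data error and its adjoint
gradient with respect to chromophore concentrations.

The fluence Phi at each optical wavelength solves the diffusion equation

    -div(D grad Phi) + mu_a Phi = 0,     D = 1 / (3 (mu_a + mu_s')),

discretized with a 5-point finite-volume scheme (harmonic averaging of D at
voxel interfaces) and Robin boundary conditions Phi + 2 A D dPhi/dn = s on
every edge with A = 1 (matched refractive index).  The excitation beam
enters as the boundary source s: a Gaussian lateral profile on the
illuminated edge, zero elsewhere.  The modelled initial pressure is

    p = S * Gamma * Phi * mu_a      (voxelwise, per wavelength),

with S the system calibration factor and Gamma the Grueneisen parameter.

The gradient of the data error is the discrete adjoint of the assembled
linear system (discretize-then-differentiate), so it matches finite
differences of the implemented forward chain to machine-level tolerance:
one forward and one adjoint solve per wavelength, reusing the same sparse
factorization (the system matrix is symmetric).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping

import numpy as np
from scipy.linalg import cho_solve_banded, cholesky_banded
from scipy.sparse import csc_matrix

from .exceptions import (
    AlignmentError,
    DiffusionValidityError,
    ShapeError,
    SolverFailureError,
)

__all__ = [
    "DomainGrid",
    "OpticalMaps",
    "SourceModel",
    "FluenceStack",
    "PressureStack",
    "assemble_absorption",
    "solve_fluence",
    "forward_pressure",
    "predict_pressure",
    "data_error",
    "data_error_gradient",
    "data_error_and_gradient",
]

# Robin boundary coefficient alpha = 1 / (2 A) with A = 1.
_ROBIN_ALPHA = 0.5
# Floor on the total attenuation mu_a + mu_s' entering the diffusion
# coefficient (1/mm).  Physical inputs never reach it; it keeps the forward
# model defined when the unconstrained inversion probes extreme iterates
# (the gradient is consistently zero where the clamp is active).
_ATTENUATION_FLOOR = 1e-3


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DomainGrid:
    """Rectangular voxel grid: ``nx`` columns, ``ny`` rows, spacing in mm.

    Row index 0 is the illuminated (top) edge; the row index increases with
    depth.  Voxel centres sit at (j + 1/2) * spacing laterally and
    (i + 1/2) * spacing in depth.
    """

    nx: int
    ny: int
    spacing: float

    def __post_init__(self):
        if self.nx < 2 or self.ny < 2 or self.spacing <= 0:
            raise ShapeError("DomainGrid needs nx, ny >= 2 and spacing > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.ny, self.nx)

    @property
    def n_voxels(self) -> int:
        return self.nx * self.ny

    @property
    def extent_mm(self) -> tuple[float, float]:
        return (self.nx * self.spacing, self.ny * self.spacing)

    def x_centres(self) -> np.ndarray:
        return (np.arange(self.nx) + 0.5) * self.spacing

    def y_centres(self) -> np.ndarray:
        return (np.arange(self.ny) + 0.5) * self.spacing


@dataclass(frozen=True)
class OpticalMaps:
    """Absorption and reduced scattering (1/mm) maps at one wavelength.

    Physical maps have mu_a >= 0.  The unconstrained inversion can probe
    slightly negative absorption during line searches; those internal
    evaluations set ``allow_negative_absorption`` and only require the
    diffusion coefficient to remain positive (mu_a + mu_s' > 0).
    """

    mu_a: np.ndarray
    mus_prime: np.ndarray
    allow_negative_absorption: bool = False

    def __post_init__(self):
        mu_a = np.asarray(self.mu_a, dtype=float)
        mus = np.asarray(self.mus_prime, dtype=float)
        if mu_a.shape != mus.shape or mu_a.ndim != 2:
            raise ShapeError("OpticalMaps need matching 2-D mu_a and mus_prime")
        if not self.allow_negative_absorption and np.any(mu_a < 0):
            raise DiffusionValidityError("mu_a must be nonnegative")
        if np.any(mus <= 0):
            raise DiffusionValidityError(
                "mus_prime must be strictly positive (diffusion validity)")
        if not self.allow_negative_absorption and np.any(mu_a + mus <= 0):
            raise DiffusionValidityError("mu_a + mus_prime must stay positive")
        object.__setattr__(self, "mu_a", mu_a)
        object.__setattr__(self, "mus_prime", mus)


@dataclass(frozen=True)
class SourceModel:
    """Gaussian excitation beam entering through one boundary edge.

    ``diameter_1e_mm`` is the 1/e *intensity* diameter: the boundary source
    falls to 1/e of its peak at a lateral offset of one radius.  ``power``
    is the integrated (line) power of the beam, arbitrary units: the profile
    is normalized so its lateral integral equals ``power``.  A beam-diameter
    error in an inversion model therefore redistributes the same pulse
    energy rather than changing it — pulse energy is measured and
    normalized out in practice, so it is not part of the mismatch.
    """

    centre_mm: float = 2.5
    diameter_1e_mm: float = 3.0
    power: float = 1.0
    edge: str = "top"

    def __post_init__(self):
        if self.diameter_1e_mm <= 0:
            raise ShapeError("beam diameter must be positive")
        if self.edge != "top":
            raise ShapeError("only top-edge illumination is supported")

    def profile(self, x_mm: np.ndarray, power: float | None = None) -> np.ndarray:
        """Boundary source values at lateral positions ``x_mm`` (per mm)."""
        p = self.power if power is None else power
        radius = 0.5 * self.diameter_1e_mm
        norm = radius * math.sqrt(math.pi)
        x = np.asarray(x_mm, dtype=float)
        return (p / norm) * np.exp(-((x - self.centre_mm) / radius) ** 2)

    def scaled(self, diameter_factor: float) -> "SourceModel":
        """Copy with the 1/e diameter multiplied by ``diameter_factor``."""
        return SourceModel(self.centre_mm, self.diameter_1e_mm * diameter_factor,
                           self.power, self.edge)


def _check_wavelengths(wavelengths: np.ndarray) -> np.ndarray:
    wl = np.asarray(wavelengths, dtype=float)
    if wl.ndim != 1 or np.any(np.diff(wl) <= 0):
        raise ShapeError("wavelengths must be 1-D and strictly increasing")
    return wl


@dataclass(frozen=True)
class FluenceStack:
    """Fluence per voxel per wavelength, shape (N, ny, nx), arbitrary units."""

    values: np.ndarray
    wavelengths: np.ndarray
    grid: DomainGrid

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        wl = _check_wavelengths(self.wavelengths)
        if values.shape != (wl.size, self.grid.ny, self.grid.nx):
            raise ShapeError("FluenceStack values must have shape (N, ny, nx)")
        if np.any(values < 0):
            raise ShapeError("fluence must be nonnegative")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "wavelengths", wl)


@dataclass(frozen=True)
class PressureStack:
    """Multiwavelength initial-pressure images, shape (N, ny, nx).

    ``role`` is "model" for forward-model output and "measured" for
    (simulated or acquired) data.
    """

    values: np.ndarray
    wavelengths: np.ndarray
    grid: DomainGrid
    role: str = "model"

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        wl = _check_wavelengths(self.wavelengths)
        if values.shape != (wl.size, self.grid.ny, self.grid.nx):
            raise ShapeError("PressureStack values must have shape (N, ny, nx)")
        if self.role not in ("model", "measured"):
            raise ShapeError("PressureStack role must be 'model' or 'measured'")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "wavelengths", wl)

    # -- serialization ------------------------------------------------------

    def to_hdf5(self, group) -> None:
        """Write datasets values[ny, nx, N], wavelengths[N], spacing, role."""
        group.create_dataset("values", data=np.moveaxis(self.values, 0, -1))
        group.create_dataset("wavelengths", data=self.wavelengths)
        group.attrs["spacing"] = self.grid.spacing
        group.attrs["role"] = self.role

    @classmethod
    def from_hdf5(cls, group) -> "PressureStack":
        values = np.moveaxis(np.asarray(group["values"]), -1, 0)
        wl = np.asarray(group["wavelengths"])
        ny, nx = values.shape[1:]
        grid = DomainGrid(nx=nx, ny=ny, spacing=float(group.attrs["spacing"]))
        return cls(values, wl, grid, role=str(group.attrs["role"]))

    def to_npz(self, path) -> None:
        np.savez(path, values=self.values, wavelengths=self.wavelengths,
                 spacing=self.grid.spacing, role=self.role)

    @classmethod
    def from_npz(cls, path) -> "PressureStack":
        with np.load(path, allow_pickle=False) as f:
            values = f["values"]
            wl = f["wavelengths"]
            ny, nx = values.shape[1:]
            grid = DomainGrid(nx=nx, ny=ny, spacing=float(f["spacing"]))
            return cls(values, wl, grid, role=str(f["role"]))


# ---------------------------------------------------------------------------
# Forward model
# ---------------------------------------------------------------------------


def assemble_absorption(concentrations: Mapping[str, np.ndarray], spectra,
                        wavelength: float) -> np.ndarray:
    """Absorption map mu_a = sum_k alpha_k(lambda) * c_k (1/mm).

    ``spectra`` is any object with an ``alpha(name, wavelength)`` method
    (specific absorption per unit concentration), e.g.
    :class:`qpatmi.spectral_phantom.SpectralLibrary`.
    """
    mu_a = None
    for name, c in concentrations.items():
        c = np.asarray(c, dtype=float)
        term = float(spectra.alpha(name, wavelength)) * c
        mu_a = term if mu_a is None else mu_a + term
    if mu_a is None:
        raise ShapeError("at least one chromophore required")
    return mu_a


@lru_cache(maxsize=8)
def _coo_pattern(ny: int, nx: int):
    """COO (rows, cols) for diagonal + x-face + y-face entries, cached."""
    idx = np.arange(ny * nx).reshape(ny, nx)
    px = idx[:, :-1].ravel()
    qx = idx[:, 1:].ravel()
    py = idx[:-1, :].ravel()
    qy = idx[1:, :].ravel()
    diag = idx.ravel()
    rows = np.concatenate([diag, px, qx, py, qy])
    cols = np.concatenate([diag, qx, px, qy, py])
    return rows, cols


def _harmonic(dp: np.ndarray, dq: np.ndarray) -> np.ndarray:
    return 2.0 * dp * dq / (dp + dq)


def _boundary_conductance(d_edge: np.ndarray, spacing: float) -> np.ndarray:
    """Face conductance of the Robin boundary: harmonic of alpha and 2D/dx."""
    beta = 2.0 * d_edge / spacing
    return _ROBIN_ALPHA * beta / (_ROBIN_ALPHA + beta)


def _system_parts(optics: OpticalMaps, source: SourceModel, grid: DomainGrid,
                  power: float | None = None):
    """Face conductances, diagonal and right-hand side of the discrete system."""
    ny, nx = grid.shape
    if optics.mu_a.shape != (ny, nx):
        raise ShapeError("optical maps do not match the domain grid")
    dx = grid.spacing
    mu_t = np.maximum(optics.mu_a + optics.mus_prime, _ATTENUATION_FLOOR)
    d = 1.0 / (3.0 * mu_t)

    dh_x = _harmonic(d[:, :-1], d[:, 1:])          # (ny, nx-1)
    dh_y = _harmonic(d[:-1, :], d[1:, :])          # (ny-1, nx)

    gb = {"top": _boundary_conductance(d[0, :], dx),
          "bottom": _boundary_conductance(d[-1, :], dx),
          "left": _boundary_conductance(d[:, 0], dx),
          "right": _boundary_conductance(d[:, -1], dx)}

    diag = optics.mu_a * dx * dx
    diag[:, :-1] += dh_x
    diag[:, 1:] += dh_x
    diag[:-1, :] += dh_y
    diag[1:, :] += dh_y
    diag[0, :] += gb["top"] * dx
    diag[-1, :] += gb["bottom"] * dx
    diag[:, 0] += gb["left"] * dx
    diag[:, -1] += gb["right"] * dx

    s_top = source.profile(grid.x_centres(), power=power)
    b = np.zeros((ny, nx))
    b[0, :] = gb["top"] * dx * s_top
    aux = {"d": d, "gb": gb, "s_top": s_top, "dx": dx,
           "unclamped": optics.mu_a + optics.mus_prime > _ATTENUATION_FLOOR}
    return diag, dh_x, dh_y, b.ravel(), aux


def _assemble_system(optics: OpticalMaps, source: SourceModel, grid: DomainGrid,
                     power: float | None = None):
    """Sparse (CSC) system A Phi = b; reference path used by the tests."""
    ny, nx = grid.shape
    diag, dh_x, dh_y, b, aux = _system_parts(optics, source, grid, power)
    data = np.concatenate([diag.ravel(), -dh_x.ravel(), -dh_x.ravel(),
                           -dh_y.ravel(), -dh_y.ravel()])
    rows, cols = _coo_pattern(ny, nx)
    a = csc_matrix((data, (rows, cols)), shape=(grid.n_voxels, grid.n_voxels))
    return a, b, aux


class _BandedFactor:
    """Cholesky factorization of the SPD diffusion matrix in banded storage.

    The 5-point stencil on an (ny, nx) grid has bandwidth nx, so banded
    Cholesky (LAPACK pbtrf) is much faster than general sparse LU at the
    grid sizes used here.
    """

    def __init__(self, diag, dh_x, dh_y, shape):
        ny, nx = shape
        ab = np.zeros((nx + 1, ny * nx))
        ab[-1] = diag.ravel()
        sup = np.zeros((ny, nx))
        sup[:, 1:] = -dh_x
        ab[-2] = sup.ravel()
        supn = np.zeros((ny, nx))
        supn[1:, :] = -dh_y
        ab[0] = supn.ravel()
        try:
            self._cb = cholesky_banded(ab, lower=False, check_finite=False)
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            raise SolverFailureError(
                f"diffusion system factorization failed: {exc}") from exc

    def solve(self, rhs: np.ndarray) -> np.ndarray:
        return cho_solve_banded((self._cb, False), rhs, check_finite=False)


def solve_fluence(optics: OpticalMaps, source: SourceModel, grid: DomainGrid,
                  power: float | None = None) -> np.ndarray:
    """Solve the diffusion system at one wavelength; returns Phi, (ny, nx)."""
    diag, dh_x, dh_y, b, _ = _system_parts(optics, source, grid, power)
    phi = _BandedFactor(diag, dh_x, dh_y, grid.shape).solve(b)
    if not np.all(np.isfinite(phi)):
        raise SolverFailureError("diffusion solve produced non-finite fluence")
    return phi.reshape(grid.shape)


def forward_pressure(fluence: FluenceStack, mu_a: np.ndarray,
                     grueneisen: np.ndarray | float = 1.0,
                     calibration: float = 1.0) -> PressureStack:
    """Initial pressure p = S * Gamma * Phi * mu_a, per voxel per wavelength.

    ``mu_a`` has shape (N, ny, nx) (one absorption map per wavelength).
    """
    mu_a = np.asarray(mu_a, dtype=float)
    if mu_a.shape != fluence.values.shape:
        raise ShapeError("mu_a stack must match the fluence stack shape")
    gamma = np.asarray(grueneisen, dtype=float)
    values = calibration * gamma * fluence.values * mu_a
    return PressureStack(values, fluence.wavelengths, fluence.grid, role="model")


def predict_pressure(concentrations: Mapping[str, np.ndarray], spectra,
                     source: SourceModel, mus_prime: np.ndarray,
                     wavelengths: np.ndarray, grid: DomainGrid,
                     grueneisen: np.ndarray | float = 1.0,
                     calibration: float = 1.0,
                     powers: np.ndarray | None = None) -> PressureStack:
    """Full forward chain: concentrations -> mu_a -> fluence -> pressure stack.

    ``mus_prime`` is a (ny, nx) map used at all wavelengths or an
    (N, ny, nx) stack.
    """
    wl = _check_wavelengths(wavelengths)
    mus_prime = np.asarray(mus_prime, dtype=float)
    if mus_prime.ndim == 2:
        mus_prime = np.broadcast_to(mus_prime, (wl.size,) + grid.shape)
    gamma = np.asarray(grueneisen, dtype=float)
    values = np.empty((wl.size,) + grid.shape)
    for n, lam in enumerate(wl):
        mu_a = assemble_absorption(concentrations, spectra, lam)
        power = None if powers is None else float(powers[n])
        optics = OpticalMaps(mu_a, mus_prime[n], allow_negative_absorption=True)
        phi = solve_fluence(optics, source, grid, power)
        values[n] = calibration * gamma * phi * mu_a
    return PressureStack(values, wl, grid, role="model")


def data_error(model: PressureStack, measured: PressureStack) -> float:
    """Least-squares data error: sum of squared voxel-wavelength differences."""
    if model.grid != measured.grid or not np.array_equal(model.wavelengths,
                                                         measured.wavelengths):
        raise AlignmentError("pressure stacks must share grid and wavelengths")
    diff = model.values - measured.values
    return float(np.dot(diff.ravel(), diff.ravel()))


# ---------------------------------------------------------------------------
# Adjoint gradient of the data error
# ---------------------------------------------------------------------------


def _adjoint_mu_a_gradient(phi: np.ndarray, w: np.ndarray, aux: dict,
                           df_dmu_direct: np.ndarray) -> np.ndarray:
    """d(data error)/d(mu_a) for one wavelength via the discrete adjoint.

    ``phi`` is the fluence, ``w`` the adjoint solution (same shape), and
    ``df_dmu_direct`` the explicit mu_a-dependence of the residual term.
    """
    d = aux["d"]
    dx = aux["dx"]

    # Interior faces: w^T (dA/dDh) phi = (w_p - w_q)(phi_p - phi_q).
    df_dd = np.zeros_like(d)
    cx = (w[:, :-1] - w[:, 1:]) * (phi[:, :-1] - phi[:, 1:])
    denom = (d[:, :-1] + d[:, 1:]) ** 2
    df_dd[:, :-1] += -cx * 2.0 * d[:, 1:] ** 2 / denom
    df_dd[:, 1:] += -cx * 2.0 * d[:, :-1] ** 2 / denom

    cy = (w[:-1, :] - w[1:, :]) * (phi[:-1, :] - phi[1:, :])
    denom = (d[:-1, :] + d[1:, :]) ** 2
    df_dd[:-1, :] += -cy * 2.0 * d[1:, :] ** 2 / denom
    df_dd[1:, :] += -cy * 2.0 * d[:-1, :] ** 2 / denom

    # Boundary faces: contribution w_p * dx * (s - phi_p) per unit d(gb),
    # with d(gb)/dD = (alpha / (alpha + beta))^2 * 2 / dx,  beta = 2 D / dx.
    def gb_sensitivity(d_edge):
        beta = 2.0 * d_edge / dx
        return (_ROBIN_ALPHA / (_ROBIN_ALPHA + beta)) ** 2 * 2.0 / dx

    df_dd[0, :] += w[0, :] * dx * (aux["s_top"] - phi[0, :]) * gb_sensitivity(d[0, :])
    df_dd[-1, :] += w[-1, :] * dx * (0.0 - phi[-1, :]) * gb_sensitivity(d[-1, :])
    df_dd[:, 0] += w[:, 0] * dx * (0.0 - phi[:, 0]) * gb_sensitivity(d[:, 0])
    df_dd[:, -1] += w[:, -1] * dx * (0.0 - phi[:, -1]) * gb_sensitivity(d[:, -1])

    # Absorption diagonal: -w_p * phi_p * dx^2; chain dD/dmu_a = -3 D^2
    # (zero where the attenuation floor is active).
    dd_dmu = np.where(aux["unclamped"], -3.0 * d * d, 0.0)
    return df_dmu_direct - w * phi * dx * dx + df_dd * dd_dmu


def data_error_and_gradient(concentrations: Mapping[str, np.ndarray], spectra,
                            source: SourceModel, measured: PressureStack,
                            mus_prime: np.ndarray,
                            grueneisen: np.ndarray | float = 1.0,
                            calibration: float = 1.0,
                            powers: np.ndarray | None = None,
                            ) -> tuple[float, dict[str, np.ndarray]]:
    """Data error and its gradient w.r.t. every chromophore concentration.

    One forward and one adjoint solve per wavelength, sharing the LU
    factorization (the diffusion matrix is symmetric).  The gradient
    includes both the direct mu_a-dependence of p = S Gamma Phi mu_a and
    the implicit dependence of Phi on mu_a through the diffusion operator
    and its Robin boundary terms.

    ``mus_prime`` is (N, ny, nx) or a single (ny, nx) map used at all
    wavelengths; ``powers`` optionally overrides the source power per
    wavelength.  Returns ``(error, {name: (ny, nx) gradient})``.
    """
    grid = measured.grid
    wl = measured.wavelengths
    mus_prime = np.asarray(mus_prime, dtype=float)
    if mus_prime.ndim == 2:
        mus_prime = np.broadcast_to(mus_prime, (wl.size,) + grid.shape)
    if mus_prime.shape != (wl.size,) + grid.shape:
        raise ShapeError("mus_prime must be (ny, nx) or (N, ny, nx)")
    gamma = np.broadcast_to(np.asarray(grueneisen, dtype=float), grid.shape)

    names = list(concentrations.keys())
    for name in names:
        if np.asarray(concentrations[name]).shape != grid.shape:
            raise ShapeError(f"concentration map {name!r} does not match the grid")

    f = 0.0
    grad = {name: np.zeros(grid.shape) for name in names}
    for n, lam in enumerate(wl):
        mu_a = assemble_absorption(concentrations, spectra, lam)
        optics = OpticalMaps(mu_a, mus_prime[n], allow_negative_absorption=True)
        power = None if powers is None else float(powers[n])
        diag, dh_x, dh_y, b, aux = _system_parts(optics, source, grid, power)
        lu = _BandedFactor(diag, dh_x, dh_y, grid.shape)
        phi = lu.solve(b).reshape(grid.shape)
        p = calibration * gamma * phi * mu_a
        r = p - measured.values[n]
        f += float(np.dot(r.ravel(), r.ravel()))

        g_phi = 2.0 * calibration * gamma * mu_a * r
        w = lu.solve(g_phi.ravel()).reshape(grid.shape)
        df_dmu_direct = 2.0 * calibration * gamma * phi * r
        df_dmu = _adjoint_mu_a_gradient(phi, w, aux, df_dmu_direct)
        for name in names:
            grad[name] += float(spectra.alpha(name, lam)) * df_dmu
    return f, grad


def data_error_gradient(concentrations: Mapping[str, np.ndarray], spectra,
                        source: SourceModel, measured: PressureStack,
                        mus_prime: np.ndarray,
                        grueneisen: np.ndarray | float = 1.0,
                        calibration: float = 1.0,
                        powers: np.ndarray | None = None) -> dict[str, np.ndarray]:
    """Gradient of :func:`data_error` w.r.t. each concentration map."""
    _, grad = data_error_and_gradient(concentrations, spectra, source, measured,
                                      mus_prime, grueneisen, calibration, powers)
    return grad
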