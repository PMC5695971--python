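"""Quasi-Newton minimization of the data error and the data + MI error.

The unknowns are the per-voxel concentrations of all chromophores (CuCl2,
NiCl2, India ink and water by default).  Two error functionals are
supported:

    eps_d      = sum_{n,m} [p_model - p_meas]^2                (data error)
    eps_d+MI   = eps_d + gamma * I(c_CuCl2, c_NiCl2)           (with MI)

where I is the KDE mutual-information estimate over the designated
independent-chromophore pair.  Minimization uses limited-memory BFGS with a
two-phase schedule: the MI weight gamma is zero for the first
``mi_activation`` iterations (so the optimizer is not trapped in local
minima of the MI term while the concentration maps are still near their
homogeneous initialization), then switches to its configured value; the
quasi-Newton memory is cleared at the switch because the objective changes
discontinuously.

gamma is never prescribed by theory; by default it is auto-scaled once at
activation so the MI term is 10% of the current data error, then frozen.

Concentrations are initialized spatially homogeneous at the true background
values and are unconstrained by default (bounds can be configured).
Internally each chromophore is scaled by a typical magnitude so the
optimizer sees comparably conditioned variables; results are reported in
physical units (g/L).

Grueneisen/calibration preprocessing for measured data (divide the images
by S and by the concentration-dependent Grueneisen map) is provided by
:func:`grueneisen_map`, :func:`estimate_calibration` and
:func:`precorrect_images`; simulation-native data (S = Gamma = 1) needs no
correction.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize

from . import mi_core
from .exceptions import (
    CalibrationError,
    ConfigError,
    CorrectionError,
    ShapeError,
)
from .fluence_forward import (
    DomainGrid,
    PressureStack,
    SourceModel,
    data_error_and_gradient,
    predict_pressure,
)

__all__ = [
    "InversionConfig",
    "GrueneisenModel",
    "InversionResult",
    "total_error",
    "total_gradient",
    "gamma_schedule",
    "invert",
    "grueneisen_map",
    "precorrect_images",
    "estimate_calibration",
]

#: Expected concentration magnitudes of the study's chromophores (g/L for the
#: salts; the ink unit and the water fraction are O(1) by construction).
#: Used to scale the optimizer variables; override via InversionConfig.scales.
TYPICAL_SCALES = {"CuCl2": 36.0, "NiCl2": 399.0, "ink": 1.0, "water": 1.0}


def spectral_preconditioner(spectra, wavelengths: np.ndarray,
                            names: Sequence[str],
                            scales: Mapping[str, float],
                            condition_cap: float | None) -> np.ndarray:
    """Chromophore-space preconditioner T (c_voxel = T y_voxel).

    Starting from the diagonal magnitude scaling, the K x K map additionally
    whitens the scaled spectral matrix A = [alpha_k(lambda_n) s_k] up to a
    condition cap: singular directions below sigma_max / cap keep their
    (damped) sensitivity instead of being amplified.  The cap limits how
    strongly weakly-determined spectral combinations (e.g. ink vs water) are
    accelerated, because fully whitening them would amplify data noise into
    the concentration maps.  ``condition_cap=None`` returns the purely
    diagonal scaling.
    """
    s = np.array([float(scales[name]) for name in names])
    if condition_cap is None:
        return np.diag(s)
    if condition_cap < 1:
        raise ConfigError("condition_cap must be >= 1")
    a = np.column_stack([
        [float(spectra.alpha(name, w)) for w in wavelengths] for name in names])
    a = a * s
    _, sig, vt = np.linalg.svd(a, full_matrices=False)
    if sig[0] <= 0:
        raise ConfigError("spectral matrix has no sensitivity at these wavelengths")
    damped = np.maximum(sig, sig[0] / condition_cap)
    p = (vt.T * (1.0 / damped)) @ vt
    return s[:, None] * p


_AUTO_GAMMA_FRACTION = 0.1
_AUTO_GAMMA_MI_FLOOR = 1e-3   # nats; guards the auto scale against MI ~ 0


def _default_init() -> dict[str, float]:
    # Homogeneous start at the true background composition.
    return {"CuCl2": 0.0, "NiCl2": 0.0, "ink": 1.0, "water": 1.0}


@dataclass(frozen=True)
class InversionConfig:
    """Settings of the two-phase L-BFGS inversion.

    total_iterations : quasi-Newton iteration budget (default 300)
    mi_activation    : iteration at which the MI term switches on (default
                       200); with gamma = 0 or activation == total the run
                       is a pure data-error inversion
    gamma            : MI weight; "auto" scales the MI term to 10% of the
                       data error at activation (then frozen)
    mi_pair          : the independent-chromophore subset entering the MI
    memory           : L-BFGS history length
    gradient_tolerance : projected-gradient stop tolerance; 0 disables it
                       (fixed iteration budget, mirroring the protocol)
    init             : per-chromophore homogeneous initialization values;
                       its keys define the unknown set
    bounds           : optional per-chromophore (lo, hi) bounds, physical
                       units; default unbounded (requires condition_cap=None)
    scales           : optional per-chromophore variable scaling override
    condition_cap    : optional condition cap of the chromophore-space
                       spectral preconditioner (see
                       :func:`spectral_preconditioner`); the default None
                       uses plain magnitude scaling, which leaves weakly
                       determined spectral combinations essentially frozen
                       at their initialization — an implicit regularization
                       that keeps the unmixing stable under model mismatch
    kde              : KDE settings for the MI term
    """

    total_iterations: int = 300
    mi_activation: int = 200
    gamma: float | str = "auto"
    mi_pair: tuple[str, str] = ("CuCl2", "NiCl2")
    memory: int = 10
    gradient_tolerance: float = 0.0
    init: Mapping[str, float] = field(default_factory=_default_init)
    bounds: Mapping[str, tuple[float | None, float | None]] | None = None
    scales: Mapping[str, float] | None = None
    condition_cap: float | None = None
    kde: mi_core.KDESettings = field(default_factory=mi_core.KDESettings)

    def __post_init__(self):
        if not (0 <= self.mi_activation <= self.total_iterations):
            raise ConfigError("need 0 <= mi_activation <= total_iterations")
        if not isinstance(self.gamma, str) and self.gamma < 0:
            raise ConfigError("gamma must be >= 0")
        if isinstance(self.gamma, str) and self.gamma != "auto":
            raise ConfigError("gamma must be a number or 'auto'")
        for name in self.mi_pair:
            if name not in self.init:
                raise ConfigError(f"MI chromophore {name!r} not among unknowns")

    def resolve_transform(self, spectra, wavelengths: np.ndarray) -> np.ndarray:
        """Chromophore-space variable transform for the optimizer."""
        names = list(self.init.keys())
        scales = {name: TYPICAL_SCALES.get(name, 1.0) for name in names}
        if self.scales:
            scales.update({k: float(v) for k, v in self.scales.items() if k in scales})
        if self.bounds and self.condition_cap is not None:
            raise ConfigError("bounds require condition_cap=None (diagonal scaling)")
        return spectral_preconditioner(spectra, wavelengths, names, scales,
                                       self.condition_cap)


@dataclass(frozen=True)
class GrueneisenModel:
    """Concentration dependence of the Grueneisen parameter.

    Gamma = Gamma_H2O * (1 + sum_i beta_i c_i) with the published slopes
    beta = 5.80e-3 L/g for CuCl2 and 2.25e-3 L/g for NiCl2.
    """

    gamma_water: float = 1.0
    beta: Mapping[str, float] = field(
        default_factory=lambda: {"CuCl2": 5.80e-3, "NiCl2": 2.25e-3})

    def __post_init__(self):
        if self.gamma_water <= 0:
            raise ConfigError("Gamma_H2O must be positive")


@dataclass(frozen=True)
class InversionResult:
    """Estimated concentration maps plus per-iteration traces.

    ``traces`` maps "eps_d", "mi", "gamma" and "total" to arrays with one
    entry per accepted quasi-Newton step (the initial point included); the
    "total" trace of each phase is non-increasing.
    """

    estimates: Mapping[str, np.ndarray]
    traces: Mapping[str, np.ndarray]
    iterations: int
    gamma_value: float
    converged: bool
    config: InversionConfig

    def to_hdf5(self, group) -> None:
        est = group.create_group("estimates")
        for name, arr in self.estimates.items():
            est.create_dataset(name, data=arr)
        tr = group.create_group("traces")
        for name, arr in self.traces.items():
            tr.create_dataset(name, data=np.asarray(arr))
        cfg = group.create_group("config")
        cfg.attrs["total_iterations"] = self.config.total_iterations
        cfg.attrs["mi_activation"] = self.config.mi_activation
        cfg.attrs["gamma"] = str(self.config.gamma)
        cfg.attrs["mi_pair"] = ",".join(self.config.mi_pair)
        group.attrs["iterations"] = self.iterations
        group.attrs["gamma_value"] = self.gamma_value
        group.attrs["converged"] = self.converged


# ---------------------------------------------------------------------------
# Error functionals
# ---------------------------------------------------------------------------


def _mi_of_pair(concentrations: Mapping[str, np.ndarray],
                pair: Sequence[str], settings: mi_core.KDESettings,
                grids=None, bandwidths=None) -> mi_core.MIResult:
    samples = np.vstack([np.asarray(concentrations[name], dtype=float).ravel()
                         for name in pair])
    return mi_core.mutual_information(samples, settings, grids=grids,
                                      bandwidths=bandwidths)


def total_error(concentrations: Mapping[str, np.ndarray],
                measured: PressureStack, spectra, source: SourceModel,
                mus_prime: np.ndarray, gamma: float,
                mi_settings: mi_core.KDESettings = mi_core.KDESettings(),
                mi_pair: Sequence[str] = ("CuCl2", "NiCl2"),
                mi_grids=None, mi_bandwidths=None,
                grueneisen: np.ndarray | float = 1.0,
                calibration: float = 1.0) -> float:
    """eps_d + gamma * MI over the designated independent pair."""
    if gamma < 0:
        raise ConfigError("gamma must be >= 0")
    model = predict_pressure(concentrations, spectra, source, mus_prime,
                             measured.wavelengths, measured.grid,
                             grueneisen, calibration)
    diff = model.values - measured.values
    f = float(np.dot(diff.ravel(), diff.ravel()))
    if gamma > 0:
        f += gamma * _mi_of_pair(concentrations, mi_pair, mi_settings,
                                 mi_grids, mi_bandwidths).mi
    return f


def total_gradient(concentrations: Mapping[str, np.ndarray],
                   measured: PressureStack, spectra, source: SourceModel,
                   mus_prime: np.ndarray, gamma: float,
                   mi_settings: mi_core.KDESettings = mi_core.KDESettings(),
                   mi_pair: Sequence[str] = ("CuCl2", "NiCl2"),
                   mi_grids=None, mi_bandwidths=None,
                   grueneisen: np.ndarray | float = 1.0,
                   calibration: float = 1.0) -> dict[str, np.ndarray]:
    """Gradient of :func:`total_error`; MI rows only for the independent pair."""
    _, grad = data_error_and_gradient(concentrations, spectra, source, measured,
                                      mus_prime, grueneisen, calibration)
    if gamma > 0:
        samples = np.vstack([np.asarray(concentrations[name], dtype=float).ravel()
                             for name in mi_pair])
        gmi = mi_core.mi_gradient(samples, mi_settings, grids=mi_grids,
                                  bandwidths=mi_bandwidths)
        shape = measured.grid.shape
        for row, name in enumerate(mi_pair):
            grad[name] = grad[name] + gamma * gmi[row].reshape(shape)
    return grad


def gamma_schedule(iteration: int, config: InversionConfig,
                   gamma_value: float | None = None) -> float:
    """Effective MI weight at ``iteration``: 0 before activation."""
    if not (0 <= iteration < config.total_iterations or
            config.total_iterations == 0):
        raise ConfigError("iteration outside the configured budget")
    if iteration < config.mi_activation:
        return 0.0
    if gamma_value is not None:
        return float(gamma_value)
    if isinstance(config.gamma, str):
        raise ConfigError("gamma='auto' must be resolved before scheduling")
    return float(config.gamma)


# ---------------------------------------------------------------------------
# Grueneisen / calibration preprocessing
# ---------------------------------------------------------------------------


def grueneisen_map(concentrations: Mapping[str, np.ndarray],
                   model: GrueneisenModel) -> np.ndarray:
    """Voxelwise Gamma = Gamma_H2O * (1 + sum_i beta_i c_i)."""
    total = None
    for name, beta in model.beta.items():
        if name in concentrations:
            term = beta * np.asarray(concentrations[name], dtype=float)
            total = term if total is None else total + term
    if total is None:
        total = 0.0
    return model.gamma_water * (1.0 + total)


def precorrect_images(measured: PressureStack, calibration: float,
                      grueneisen: np.ndarray | float) -> PressureStack:
    """Divide measured images by S * Gamma (inverse of the forward factors)."""
    gamma = np.asarray(grueneisen, dtype=float)
    if calibration <= 0 or np.any(gamma <= 0):
        raise CorrectionError("calibration and Grueneisen factors must be positive")
    return PressureStack(measured.values / (calibration * gamma),
                         measured.wavelengths, measured.grid, role=measured.role)


def estimate_calibration(measured: PressureStack,
                         model_at_truth: PressureStack) -> float:
    """Least-squares scalar S: <p_model, p_meas> / <p_model, p_model>."""
    if model_at_truth.grid != measured.grid or not np.array_equal(
            model_at_truth.wavelengths, measured.wavelengths):
        raise ShapeError("stacks must share grid and wavelengths")
    pm = model_at_truth.values.ravel()
    denom = float(np.dot(pm, pm))
    if denom == 0.0:
        raise CalibrationError("zero model stack: calibration undefined")
    return float(np.dot(pm, measured.values.ravel()) / denom)


# ---------------------------------------------------------------------------
# The minimization driver
# ---------------------------------------------------------------------------


class _Objective:
    """Transformed objective/gradient closure with a small trace cache.

    The optimizer variable y relates to the physical concentrations through
    the chromophore-space map T: c_voxel = T y_voxel (see
    :func:`spectral_preconditioner`); gradients map back through T^T.
    """

    def __init__(self, names, transform, grid: DomainGrid, measured, spectra,
                 source, mus_prime, grueneisen, calibration, mi_pair, kde):
        self.names = names
        self.transform = np.asarray(transform, dtype=float)
        self.transform_inv = np.linalg.inv(self.transform)
        self.grid = grid
        self.measured = measured
        self.spectra = spectra
        self.source = source
        self.mus_prime = mus_prime
        self.grueneisen = grueneisen
        self.calibration = calibration
        self.mi_pair = mi_pair
        self.kde = kde
        self.gamma = 0.0
        self._cache: OrderedDict[bytes, tuple[float, float, float]] = OrderedDict()

    def unpack(self, x: np.ndarray) -> dict[str, np.ndarray]:
        y = x.reshape(len(self.names), self.grid.n_voxels)
        c = self.transform @ y
        return {name: c[i].reshape(self.grid.shape)
                for i, name in enumerate(self.names)}

    def pack(self, concentrations: Mapping[str, np.ndarray]) -> np.ndarray:
        c = np.vstack([np.asarray(concentrations[name], dtype=float).ravel()
                       for name in self.names])
        return (self.transform_inv @ c).ravel()

    def components(self, x: np.ndarray) -> tuple[float, float]:
        """(eps_d, MI) at x, bypassing the gradient machinery."""
        c = self.unpack(x)
        model = predict_pressure(c, self.spectra, self.source, self.mus_prime,
                                 self.measured.wavelengths, self.grid,
                                 self.grueneisen, self.calibration)
        diff = model.values - self.measured.values
        f_d = float(np.dot(diff.ravel(), diff.ravel()))
        mi = _mi_of_pair(c, self.mi_pair, self.kde).mi if self.gamma > 0 else 0.0
        return f_d, mi

    def __call__(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        c = self.unpack(x)
        f_d, grad = data_error_and_gradient(
            c, self.spectra, self.source, self.measured, self.mus_prime,
            self.grueneisen, self.calibration)
        mi = 0.0
        if self.gamma > 0:
            samples = np.vstack([c[name].ravel() for name in self.mi_pair])
            mi = mi_core.mutual_information(samples, self.kde).mi
            gmi = mi_core.mi_gradient(samples, self.kde)
            for row, name in enumerate(self.mi_pair):
                grad[name] = grad[name] + self.gamma * gmi[row].reshape(self.grid.shape)
        f = f_d + self.gamma * mi
        g_c = np.vstack([grad[name].ravel() for name in self.names])
        g = (self.transform.T @ g_c).ravel()
        self._cache[x.tobytes()] = (f_d, mi, f)
        while len(self._cache) > 8:
            self._cache.popitem(last=False)
        return f, g

    def trace_entry(self, x: np.ndarray) -> tuple[float, float, float]:
        key = x.tobytes()
        if key in self._cache:
            return self._cache[key]
        f_d, mi = self.components(x)
        return f_d, mi, f_d + self.gamma * mi


def invert(measured: PressureStack, spectra, source: SourceModel,
           config: InversionConfig, mus_prime: np.ndarray,
           grueneisen: np.ndarray | float = 1.0,
           calibration: float = 1.0) -> InversionResult:
    """Run the two-phase quasi-Newton inversion.

    ``measured`` must be pre-corrected for S and Gamma (see
    :func:`precorrect_images`) or simulation-native (S = Gamma = 1); the
    inversion itself then uses S = Gamma = 1 in its forward model.
    ``mus_prime`` is the (assumed known) reduced-scattering map, (ny, nx)
    used at all wavelengths or (N, ny, nx).
    """
    if measured.wavelengths.size < 2:
        raise ShapeError("inversion needs at least 2 wavelengths")
    grid = measured.grid
    names = list(config.init.keys())
    transform = config.resolve_transform(spectra, measured.wavelengths)
    obj = _Objective(names, transform, grid, measured, spectra, source, mus_prime,
                     grueneisen, calibration, config.mi_pair, config.kde)

    x0 = obj.pack({name: np.full(grid.shape, float(config.init[name]))
                   for name in names})

    bounds = None
    if config.bounds:
        # Only reachable with a diagonal transform (checked in the config).
        scale_diag = np.diag(transform)
        bounds = []
        for name, s in zip(names, scale_diag):
            lo, hi = config.bounds.get(name, (None, None))
            lo = None if lo is None else lo / s
            hi = None if hi is None else hi / s
            bounds.extend([(lo, hi)] * grid.n_voxels)

    gtol = config.gradient_tolerance if config.gradient_tolerance > 0 else 1e-32
    options = dict(maxcor=config.memory, ftol=1e-32, gtol=gtol,
                   maxfun=10 ** 7, maxls=60)

    traces = {"eps_d": [], "mi": [], "gamma": [], "total": []}

    def record(x):
        f_d, mi, f = obj.trace_entry(x)
        traces["eps_d"].append(f_d)
        traces["mi"].append(mi)
        traces["gamma"].append(obj.gamma)
        traces["total"].append(f)

    iterations = 0
    converged = True
    x = x0

    def run_phase(x, n_iter):
        nonlocal iterations, converged
        if n_iter <= 0:
            return x
        res = minimize(obj, x, jac=True, method="L-BFGS-B", bounds=bounds,
                       options={**options, "maxiter": n_iter},
                       callback=record)
        iterations += res.nit
        if res.status == 2:  # line-search/rounding failure: partial result
            converged = False
        return res.x

    # A numeric gamma of 0 is a pure data-error inversion: single phase.
    pure_data = not isinstance(config.gamma, str) and config.gamma == 0
    phase1 = config.total_iterations if pure_data else config.mi_activation

    # Phase 1: data error only.
    obj.gamma = 0.0
    record(x)
    x = run_phase(x, phase1)

    # Resolve the MI weight, then phase 2 with a fresh quasi-Newton memory.
    remaining = 0 if pure_data else config.total_iterations - config.mi_activation
    gamma_value = 0.0 if isinstance(config.gamma, str) else float(config.gamma)
    if remaining > 0:
        if config.gamma == "auto":
            f_d, _ = obj.components(x)
            obj.gamma = 1.0  # force MI evaluation in components()
            _, mi_now = obj.components(x)
            gamma_value = _AUTO_GAMMA_FRACTION * f_d / max(mi_now,
                                                           _AUTO_GAMMA_MI_FLOOR)
        obj.gamma = gamma_value
        x = run_phase(x, remaining)

    estimates = obj.unpack(x)
    return InversionResult(
        estimates=estimates,
        traces={k: np.asarray(v) for k, v in traces.items()},
        iterations=iterations,
        gamma_value=float(gamma_value),
        converged=converged,
        config=config,
    )
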