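"""Surrogate spectral library and the numerical tissue-mimicking phantom.

The phantom is a 5 x 5 mm^2 domain at 100 um voxel spacing (50 x 50 voxels)
containing six disc insertions in two columns: CuCl2 solutions at 12, 24 and
36 g/L on the left and NiCl2 at 133, 266 and 399 g/L on the right, with
concentration increasing with depth so the deeper insertions keep a usable
signal-to-noise ratio despite the fluence decay.  The background is a
water + India-ink solution; 1% Intralipid provides the scattering
(mu_s' ~ 1 /mm at 800 nm with a power-law wavelength dependence).

The true CuCl2/NiCl2 absorption spectra are only available as measured
curves, so this module ships a smooth surrogate library with the same
qualitative behaviour over 750-890 nm — CuCl2 rising with wavelength, NiCl2
falling, ink weak and nearly flat, water from published pure-water values —
rescaled so the wavelength-averaged absorption of the 36 g/L CuCl2 and the
399 g/L NiCl2 solutions both equal 0.52 /mm over the eight imaging bands
(comparable to blood in this window).

Simulated multiwavelength images are the product of the diffusion-model
fluence and the absorption map (calibration and Grueneisen factors equal to
one), plus additive Gaussian noise with standard deviation equal to a fixed
fraction (default 10%) of the mean of the data.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import GeometryError, ShapeError, WavelengthRangeError
from .fluence_forward import (
    DomainGrid,
    OpticalMaps,
    PressureStack,
    SourceModel,
    assemble_absorption,
    solve_fluence,
)

__all__ = [
    "WAVELENGTHS_NM",
    "ChromophoreSpectrum",
    "SpectralLibrary",
    "Insertion",
    "Background",
    "PhantomSpec",
    "Phantom",
    "NoiseModel",
    "surrogate_spectra",
    "load_packaged_spectra",
    "build_numerical_phantom",
    "simulate_images",
    "add_noise",
]

#: The eight imaging wavelengths: equally spaced over 750-890 nm.
WAVELENGTHS_NM = np.linspace(750.0, 890.0, 8)

_BAND = (750.0, 890.0)

# Pure-water absorption (1/mm) at the imaging bands, from published
# spectrophotometric values (Hale & Querry / Kou et al.); interpolated
# linearly in between.
_WATER_TABLE_NM = np.array([750.0, 770.0, 790.0, 810.0, 830.0, 850.0, 870.0, 890.0])
_WATER_TABLE_MUA = np.array([0.0026, 0.0025, 0.0024, 0.0029, 0.0034,
                             0.0043, 0.0055, 0.0065])

# Average absorption of both insertion columns over the imaging bands (1/mm).
_COLUMN_MEAN_MUA = 0.52
_CU_REF_CONC = 36.0    # g/L
_NI_REF_CONC = 399.0   # g/L

# Scattering power-law exponent of Intralipid and its reference wavelength.
_MIE_EXPONENT = 2.4
_MIE_REF_NM = 800.0


def _unit_shapes(wavelengths: np.ndarray) -> dict[str, np.ndarray]:
    """Unscaled spectral shapes of the surrogate library."""
    u = (wavelengths - 750.0) / 140.0
    return {
        "CuCl2": 0.35 + 0.65 * u ** 1.3,          # rising over the band
        "NiCl2": 1.0 - 0.55 * u ** 0.9,           # falling over the band
        "ink": 0.006 * (800.0 / wavelengths),     # weak, nearly flat
        "water": np.interp(wavelengths, _WATER_TABLE_NM, _WATER_TABLE_MUA),
    }


def _salt_scales() -> dict[str, float]:
    """Scale factors anchoring the mean column absorption at the 8 bands."""
    shapes = _unit_shapes(WAVELENGTHS_NM)
    return {
        "CuCl2": _COLUMN_MEAN_MUA / (_CU_REF_CONC * float(shapes["CuCl2"].mean())),
        "NiCl2": _COLUMN_MEAN_MUA / (_NI_REF_CONC * float(shapes["NiCl2"].mean())),
    }


@dataclass(frozen=True)
class ChromophoreSpectrum:
    """Specific absorption alpha(lambda) of one chromophore.

    Units are 1/mm per g/L for the salts and the ink-equivalent unit; for
    water, 1/mm at unit (dimensionless) water fraction.
    """

    name: str
    wavelengths_nm: np.ndarray
    alpha: np.ndarray

    def __post_init__(self):
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        al = np.asarray(self.alpha, dtype=float)
        if wl.shape != al.shape or wl.ndim != 1:
            raise ShapeError("spectrum needs matching 1-D wavelength/alpha arrays")
        if np.any(np.diff(wl) <= 0):
            raise ShapeError("spectrum wavelengths must be strictly increasing")
        if np.any(al < 0):
            raise ShapeError("specific absorption must be nonnegative")
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "alpha", al)


@dataclass(frozen=True)
class SpectralLibrary:
    """Specific absorption spectra plus the unit scattering spectrum.

    ``mus_prime_unit`` is the reduced scattering of 1% Intralipid at unit
    amplitude: (lambda / 800 nm)^(-2.4), i.e. ~1 /mm at 800 nm.
    """

    wavelengths_nm: np.ndarray
    spectra: Mapping[str, ChromophoreSpectrum]
    mus_prime_unit: np.ndarray

    def __post_init__(self):
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "mus_prime_unit",
                           np.asarray(self.mus_prime_unit, dtype=float))

    @property
    def chromophores(self) -> tuple[str, ...]:
        return tuple(self.spectra.keys())

    def _interp(self, table: np.ndarray, wavelength) -> float | np.ndarray:
        wl = np.asarray(wavelength, dtype=float)
        lo, hi = self.wavelengths_nm[0], self.wavelengths_nm[-1]
        if np.any(wl < lo) or np.any(wl > hi):
            raise WavelengthRangeError(
                f"wavelength {wavelength} nm outside the library band [{lo}, {hi}]")
        out = np.interp(wl, self.wavelengths_nm, table)
        return out if out.ndim else float(out)

    def alpha(self, name: str, wavelength) -> float | np.ndarray:
        """Specific absorption of ``name`` at ``wavelength`` (nm)."""
        if name not in self.spectra:
            raise ShapeError(f"unknown chromophore {name!r}")
        return self._interp(self.spectra[name].alpha, wavelength)

    def mus_prime(self, wavelength, amplitude: float = 1.0) -> float | np.ndarray:
        """Reduced scattering at ``wavelength`` for the given amplitude."""
        return amplitude * self._interp(self.mus_prime_unit, wavelength)

    # -- serialization ------------------------------------------------------

    def to_csv(self, path) -> None:
        df = pd.DataFrame({"wavelength_nm": self.wavelengths_nm})
        for name in self.chromophores:
            df[f"alpha_{name}"] = self.spectra[name].alpha
        df["mus_prime"] = self.mus_prime_unit
        df.to_csv(path, index=False, float_format="%.12g")

    @classmethod
    def from_csv(cls, path) -> "SpectralLibrary":
        df = pd.read_csv(path)
        wl = df["wavelength_nm"].to_numpy(dtype=float)
        spectra = {}
        for col in df.columns:
            if col.startswith("alpha_"):
                name = col[len("alpha_"):]
                spectra[name] = ChromophoreSpectrum(name, wl, df[col].to_numpy(dtype=float))
        return cls(wl, spectra, df["mus_prime"].to_numpy(dtype=float))


def surrogate_spectra(wavelengths: Sequence[float] | None = None) -> SpectralLibrary:
    """Build the surrogate spectral library at the given wavelengths.

    The salt spectra are rescaled (once, at the eight default bands) so the
    wavelength-averaged absorption of the 36 g/L CuCl2 and 399 g/L NiCl2
    solutions both equal 0.52 /mm; the rescaling is independent of the
    wavelengths requested here, so alpha remains a fixed function of
    wavelength.  Requests outside 750-890 nm raise
    :class:`WavelengthRangeError`.
    """
    wl = WAVELENGTHS_NM.copy() if wavelengths is None else np.asarray(wavelengths, dtype=float)
    if np.any(wl < _BAND[0]) or np.any(wl > _BAND[1]):
        raise WavelengthRangeError(f"wavelengths must lie within {_BAND} nm")
    if np.any(np.diff(wl) <= 0):
        raise ShapeError("wavelengths must be strictly increasing")
    shapes = _unit_shapes(wl)
    scales = _salt_scales()
    spectra = {
        "CuCl2": ChromophoreSpectrum("CuCl2", wl, scales["CuCl2"] * shapes["CuCl2"]),
        "NiCl2": ChromophoreSpectrum("NiCl2", wl, scales["NiCl2"] * shapes["NiCl2"]),
        "ink": ChromophoreSpectrum("ink", wl, shapes["ink"]),
        "water": ChromophoreSpectrum("water", wl, shapes["water"]),
    }
    mus_unit = (wl / _MIE_REF_NM) ** (-_MIE_EXPONENT)
    return SpectralLibrary(wl, spectra, mus_unit)


def load_packaged_spectra() -> SpectralLibrary:
    """Load the versioned CSV spectral library shipped with the package."""
    text = resources.files(__package__).joinpath("data/spectra.csv").read_text()
    return SpectralLibrary.from_csv(io.StringIO(text))


# ---------------------------------------------------------------------------
# Phantom geometry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Insertion:
    """A disc insertion: centre (x, depth) in mm, radius in mm, one salt."""

    centre_mm: tuple[float, float]
    radius_mm: float
    chromophore: str
    concentration: float

    def __post_init__(self):
        if self.radius_mm <= 0:
            raise GeometryError("insertion radius must be positive")


@dataclass(frozen=True)
class Background:
    """Background composition and scattering of the phantom."""

    ink_concentration: float = 1.0
    water_fraction: float = 1.0
    scattering_amplitude: float = 1.0   # mu_s' at 800 nm, 1/mm (1% Intralipid)
    scattering_exponent: float = _MIE_EXPONENT


def _default_insertions() -> tuple[Insertion, ...]:
    cu_x, ni_x = 1.7, 3.3
    depths = (1.25, 2.5, 3.75)
    cu = [Insertion((cu_x, d), 0.4, "CuCl2", c)
          for d, c in zip(depths, (12.0, 24.0, 36.0))]
    ni = [Insertion((ni_x, d), 0.4, "NiCl2", c)
          for d, c in zip(depths, (133.0, 266.0, 399.0))]
    return tuple(cu + ni)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and composition of the numerical phantom."""

    grid: DomainGrid = field(default_factory=lambda: DomainGrid(50, 50, 0.1))
    background: Background = field(default_factory=Background)
    insertions: tuple[Insertion, ...] = field(default_factory=_default_insertions)

    def __post_init__(self):
        ex, ey = self.grid.extent_mm
        for ins in self.insertions:
            x, y = ins.centre_mm
            r = ins.radius_mm
            if not (r <= x <= ex - r and r <= y <= ey - r):
                raise GeometryError(f"insertion at {ins.centre_mm} leaves the domain")
        for i, a in enumerate(self.insertions):
            for b in self.insertions[i + 1:]:
                dist = np.hypot(a.centre_mm[0] - b.centre_mm[0],
                                a.centre_mm[1] - b.centre_mm[1])
                if dist < a.radius_mm + b.radius_mm:
                    raise GeometryError("insertions overlap")

    # -- serialization ------------------------------------------------------

    def to_yaml(self, path) -> None:
        doc = {
            "grid": {"nx": self.grid.nx, "ny": self.grid.ny,
                     "spacing_mm": self.grid.spacing},
            "background": {
                "ink_concentration": self.background.ink_concentration,
                "water_fraction": self.background.water_fraction,
                "scattering_amplitude": self.background.scattering_amplitude,
                "scattering_exponent": self.background.scattering_exponent,
            },
            "insertions": [
                {"centre_mm": list(ins.centre_mm), "radius_mm": ins.radius_mm,
                 "chromophore": ins.chromophore,
                 "concentration": ins.concentration}
                for ins in self.insertions
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PhantomSpec":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        grid = DomainGrid(nx=int(doc["grid"]["nx"]), ny=int(doc["grid"]["ny"]),
                          spacing=float(doc["grid"]["spacing_mm"]))
        bg = Background(**doc.get("background", {}))
        insertions = tuple(
            Insertion(tuple(d["centre_mm"]), d["radius_mm"], d["chromophore"],
                      d["concentration"])
            for d in doc.get("insertions", []))
        return cls(grid, bg, insertions)


@dataclass(frozen=True)
class Phantom:
    """Built phantom: concentration fields plus the scattering amplitude map."""

    spec: PhantomSpec
    concentrations: Mapping[str, np.ndarray]
    scattering_amplitude: np.ndarray

    @property
    def grid(self) -> DomainGrid:
        return self.spec.grid

    def insertion_mask(self, chromophore: str | None = None) -> np.ndarray:
        """Boolean mask of insertion voxels (optionally one salt only)."""
        grid = self.grid
        xx, yy = np.meshgrid(grid.x_centres(), grid.y_centres())
        mask = np.zeros(grid.shape, dtype=bool)
        for ins in self.spec.insertions:
            if chromophore is not None and ins.chromophore != chromophore:
                continue
            mask |= (xx - ins.centre_mm[0]) ** 2 + (yy - ins.centre_mm[1]) ** 2 \
                <= ins.radius_mm ** 2
        return mask

    def mus_prime(self, spectra: SpectralLibrary, wavelength: float) -> np.ndarray:
        return self.scattering_amplitude * float(
            spectra._interp(spectra.mus_prime_unit, wavelength))


def build_numerical_phantom(spec: PhantomSpec | None = None) -> Phantom:
    """Rasterize the phantom onto its voxel grid.

    A voxel belongs to an insertion when its centre lies inside the disc.
    The background carries ink and water; water is present everywhere
    (the insertions are aqueous solutions), ink only outside the insertions.
    """
    spec = spec or PhantomSpec()
    grid = spec.grid
    xx, yy = np.meshgrid(grid.x_centres(), grid.y_centres())
    fields = {name: np.zeros(grid.shape) for name in ("CuCl2", "NiCl2", "ink", "water")}
    any_mask = np.zeros(grid.shape, dtype=bool)
    for ins in spec.insertions:
        mask = (xx - ins.centre_mm[0]) ** 2 + (yy - ins.centre_mm[1]) ** 2 \
            <= ins.radius_mm ** 2
        fields[ins.chromophore][mask] = ins.concentration
        any_mask |= mask
    fields["ink"][~any_mask] = spec.background.ink_concentration
    fields["water"][:] = spec.background.water_fraction
    scattering = np.full(grid.shape, spec.background.scattering_amplitude)
    return Phantom(spec, fields, scattering)


# ---------------------------------------------------------------------------
# Image simulation and noise
# ---------------------------------------------------------------------------


def save_phantom_images(path, phantom: Phantom, stack: PressureStack) -> None:
    """Write truth concentrations, optics and images to one HDF5 container."""
    import h5py

    with h5py.File(path, "w") as fh:
        truth = fh.create_group("truth")
        for name, arr in phantom.concentrations.items():
            truth.create_dataset(name, data=arr)
        optics = fh.create_group("optics")
        optics.create_dataset("scattering_amplitude", data=phantom.scattering_amplitude)
        stack.to_hdf5(fh.create_group("images"))


def load_images(path) -> PressureStack:
    """Read the measured image stack back from an HDF5 container."""
    import h5py

    with h5py.File(path, "r") as fh:
        return PressureStack.from_hdf5(fh["images"])


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian noise; 'amplitude' is the standard deviation,
    expressed as a fraction of the mean of the data."""

    fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.fraction < 0:
            raise ShapeError("noise fraction must be >= 0")


def add_noise(stack: PressureStack, fraction: float, seed: int) -> PressureStack:
    """Add zero-mean Gaussian noise with sigma = fraction * mean(stack)."""
    if fraction < 0:
        raise ShapeError("noise fraction must be >= 0")
    if fraction == 0:
        return stack
    sigma = fraction * float(stack.values.mean())
    rng = np.random.default_rng(seed)
    noisy = stack.values + rng.normal(0.0, sigma, size=stack.values.shape)
    return PressureStack(noisy, stack.wavelengths, stack.grid, role=stack.role)


def simulate_images(phantom: Phantom, spectra: SpectralLibrary,
                    source: SourceModel | None = None,
                    wavelengths: Sequence[float] | None = None,
                    noise: NoiseModel | None = None) -> PressureStack:
    """Simulate the measured multiwavelength photoacoustic image stack.

    Per wavelength the fluence is solved with the phantom's true optics and
    the image is Phi * mu_a (calibration factor and Grueneisen parameter
    equal to one); Gaussian noise is then added per :class:`NoiseModel`.
    Fully reproducible given the noise seed.
    """
    source = source or SourceModel()
    wl = WAVELENGTHS_NM.copy() if wavelengths is None else np.asarray(wavelengths, dtype=float)
    noise = noise or NoiseModel()
    grid = phantom.grid
    values = np.empty((wl.size,) + grid.shape)
    for n, lam in enumerate(wl):
        mu_a = assemble_absorption(phantom.concentrations, spectra, lam)
        mus = phantom.mus_prime(spectra, lam)
        phi = solve_fluence(OpticalMaps(mu_a, mus), source, grid)
        values[n] = phi * mu_a
    stack = PressureStack(values, wl, grid, role="measured")
    return add_noise(stack, noise.fraction, noise.seed)
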