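"""Model-mismatch case studies, ROI error metrics and result tables.

The two case studies probe how sensitive the inversion is to errors in
"known" model parameters.  Images are always simulated with the true
phantom optics; the inversion model is then handed a perturbed parameter —
the excitation-beam 1/e diameter or the scattering amplitude, scaled by
(1 + level) for a grid of relative errors up to +/-75% — and run once with
the plain data-error functional and once with the data + MI functional.
Quantification accuracy is summarized by ROI error metrics:

* inside an insertion: mean over its voxels of |c_est - c_true| / c_true,
  in percent, averaged over the two salts for the headline number;
* outside the insertions: mean |c_est - c_true| normalized by the salt's
  maximum true concentration, in percent (the background truth is zero, so
  per-voxel normalization is undefined there).

Each (case, level, functional, seed) combination contributes one table row;
tables round-trip losslessly through CSV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import MetricError, ShapeError
from .fluence_forward import SourceModel
from .inversion import InversionConfig, InversionResult, invert
from .spectral_phantom import (
    WAVELENGTHS_NM,
    NoiseModel,
    Phantom,
    PhantomSpec,
    SpectralLibrary,
    build_numerical_phantom,
    simulate_images,
    surrogate_spectra,
)

__all__ = [
    "ErrorMetricSpec",
    "MismatchTable",
    "StudySettings",
    "roi_error",
    "insertion_errors",
    "run_beam_mismatch_study",
    "run_scattering_mismatch_study",
    "run_case_studies",
    "relative_improvement",
]

logger = logging.getLogger("qpatmi")

#: Default relative-error grid of the full-scale studies.
DEFAULT_LEVELS = (-0.75, -0.5, -0.25, 0.0, 0.25, 0.5, 0.75)
#: Coarser grid used for scaled-down (desk-scale) runs.
SCALED_LEVELS = (-0.75, -0.375, 0.0, 0.375, 0.75)

_FUNCTIONALS = ("eps_d", "eps_d_mi")


@dataclass(frozen=True)
class ErrorMetricSpec:
    """Conventions of the ROI error metric.

    ``inside_normalization`` divides each voxel error by the local true
    concentration; ``outside_normalization`` divides by the chromophore's
    maximum true concentration.  The insertion mask of each salt and its
    complement partition the grid.
    """

    inside_normalization: str = "per_voxel_truth"
    outside_normalization: str = "max_truth"
    salts: tuple[str, str] = ("CuCl2", "NiCl2")


def roi_error(estimate: np.ndarray, truth: np.ndarray, mask: np.ndarray,
              normalization: str = "per_voxel_truth") -> float:
    """Mean concentration error over ``mask``, in percent.

    ``per_voxel_truth`` normalizes each voxel by its true value (insertion
    convention; requires truth > 0 on the mask).  ``max_truth`` normalizes
    by the maximum of the full truth map (background convention).
    """
    estimate = np.asarray(estimate, dtype=float)
    truth = np.asarray(truth, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if estimate.shape != truth.shape or mask.shape != truth.shape:
        raise ShapeError("estimate, truth and mask must share one shape")
    if not mask.any():
        raise MetricError("empty ROI mask")
    err = np.abs(estimate[mask] - truth[mask])
    if normalization == "per_voxel_truth":
        t = truth[mask]
        if np.any(t <= 0):
            raise MetricError("per-voxel normalization needs positive truth in ROI")
        return float(np.mean(err / t) * 100.0)
    if normalization == "max_truth":
        cmax = float(truth.max())
        if cmax <= 0:
            raise MetricError("max-truth normalization needs a positive truth map")
        return float(np.mean(err) / cmax * 100.0)
    raise MetricError(f"unknown normalization {normalization!r}")


def insertion_errors(result: InversionResult, phantom: Phantom,
                     spec: ErrorMetricSpec = ErrorMetricSpec()) -> dict[str, float]:
    """Inside/outside ROI errors of both salts plus the headline average."""
    out: dict[str, float] = {}
    for name in spec.salts:
        mask = phantom.insertion_mask(name)
        truth = phantom.concentrations[name]
        est = result.estimates[name]
        out[f"roi_{name}_pct"] = roi_error(est, truth, mask, "per_voxel_truth")
        out[f"outside_{name}_pct"] = roi_error(est, truth, ~mask, "max_truth")
    out["roi_error_pct"] = float(np.mean([out[f"roi_{n}_pct"] for n in spec.salts]))
    out["outside_error_pct"] = float(max(out[f"outside_{n}_pct"] for n in spec.salts))
    return out


# ---------------------------------------------------------------------------
# Study configuration and result table
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StudySettings:
    """Everything a mismatch study needs besides the level grid and seeds."""

    phantom_spec: PhantomSpec = field(default_factory=PhantomSpec)
    wavelengths: tuple[float, ...] = tuple(WAVELENGTHS_NM)
    source: SourceModel = field(default_factory=SourceModel)
    noise_fraction: float = 0.1
    inversion: InversionConfig = field(default_factory=InversionConfig)
    spectra: SpectralLibrary | None = None   # default: packaged surrogate
    metric: ErrorMetricSpec = field(default_factory=ErrorMetricSpec)

    def resolve_spectra(self) -> SpectralLibrary:
        return self.spectra if self.spectra is not None else surrogate_spectra()


@dataclass(frozen=True)
class MismatchTable:
    """Per-(level, functional, seed) ROI errors of one mismatch case."""

    parameter: str
    frame: pd.DataFrame
    seeds: tuple[int, ...]

    def __post_init__(self):
        required = {"level", "functional", "seed", "roi_error_pct"}
        if not required.issubset(self.frame.columns):
            raise ShapeError(f"MismatchTable frame needs columns {sorted(required)}")
        if (self.frame["roi_error_pct"] < 0).any():
            raise ShapeError("ROI errors must be nonnegative")

    @property
    def levels(self) -> np.ndarray:
        return np.sort(self.frame["level"].unique())

    def median_roi(self, functional: str) -> pd.Series:
        """Median-over-seeds headline ROI error per level for one functional."""
        sub = self.frame[self.frame["functional"] == functional]
        return sub.groupby("level")["roi_error_pct"].median()

    def median_outside(self, functional: str) -> pd.Series:
        sub = self.frame[self.frame["functional"] == functional]
        return sub.groupby("level")["outside_error_pct"].median()

    # -- serialization (bit-exact round trip) -------------------------------

    def to_csv(self, path) -> None:
        df = self.frame.copy()
        df.insert(0, "parameter", self.parameter)
        df.to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "MismatchTable":
        df = pd.read_csv(path, float_precision="round_trip")
        parameter = str(df["parameter"].iloc[0])
        seeds = tuple(int(s) for s in sorted(df["seed"].unique()))
        return cls(parameter, df.drop(columns=["parameter"]), seeds)


# ---------------------------------------------------------------------------
# Study runners
# ---------------------------------------------------------------------------


def _study_config(settings: StudySettings, functional: str) -> InversionConfig:
    if functional == "eps_d":
        return replace(settings.inversion, gamma=0.0)
    if functional == "eps_d_mi":
        return settings.inversion
    raise ShapeError(f"unknown functional {functional!r}")


def _run_one(phantom: Phantom, spectra: SpectralLibrary, measured,
             inv_source: SourceModel, inv_mus: np.ndarray,
             settings: StudySettings, functional: str) -> tuple[dict, InversionResult]:
    config = _study_config(settings, functional)
    result = invert(measured, spectra, inv_source, config, inv_mus)
    row = insertion_errors(result, phantom, settings.metric)
    row["gamma_value"] = result.gamma_value
    row["converged"] = bool(result.converged)
    return row, result


def _run_study(parameter: str, levels: Sequence[float], settings: StudySettings,
               seeds: Sequence[int],
               shared_level0: dict | None = None) -> MismatchTable:
    if any(lev <= -1.0 for lev in levels):
        raise ShapeError("mismatch levels must be > -1 (parameter stays positive)")
    phantom = build_numerical_phantom(settings.phantom_spec)
    spectra = settings.resolve_spectra()
    wl = np.asarray(settings.wavelengths, dtype=float)
    mus_true = np.stack([phantom.mus_prime(spectra, lam) for lam in wl])

    rows = []
    for seed in seeds:
        measured = simulate_images(
            phantom, spectra, settings.source, wl,
            NoiseModel(settings.noise_fraction, int(seed)))
        for level in levels:
            if parameter == "beam_diameter":
                inv_source = settings.source.scaled(1.0 + level)
                inv_mus = mus_true
            elif parameter == "scattering_amplitude":
                inv_source = settings.source
                inv_mus = mus_true * (1.0 + level)
            else:
                raise ShapeError(f"unknown mismatch parameter {parameter!r}")
            for functional in _FUNCTIONALS:
                key = (int(seed), functional)
                if level == 0.0 and shared_level0 is not None and key in shared_level0:
                    row = dict(shared_level0[key])
                else:
                    logger.info("mismatch %s level %+.3f seed %d functional %s",
                                parameter, level, seed, functional)
                    row, _ = _run_one(phantom, spectra, measured, inv_source,
                                      inv_mus, settings, functional)
                    if level == 0.0 and shared_level0 is not None:
                        shared_level0[key] = dict(row)
                rows.append({"level": float(level), "functional": functional,
                             "seed": int(seed), **row})
    frame = pd.DataFrame(rows)
    return MismatchTable(parameter, frame, tuple(int(s) for s in seeds))


def run_beam_mismatch_study(levels: Sequence[float] = DEFAULT_LEVELS,
                            settings: StudySettings = StudySettings(),
                            seeds: Sequence[int] = (0,)) -> MismatchTable:
    """Beam-diameter mismatch: simulate with the true beam, invert with the
    1/e diameter scaled by (1 + level)."""
    return _run_study("beam_diameter", levels, settings, seeds)


def run_scattering_mismatch_study(levels: Sequence[float] = DEFAULT_LEVELS,
                                  settings: StudySettings = StudySettings(),
                                  seeds: Sequence[int] = (0,)) -> MismatchTable:
    """Scattering-amplitude mismatch: invert with mu_s' scaled by (1 + level)."""
    return _run_study("scattering_amplitude", levels, settings, seeds)


def run_case_studies(levels: Sequence[float] = DEFAULT_LEVELS,
                     settings: StudySettings = StudySettings(),
                     seeds: Sequence[int] = (0,)) -> tuple[MismatchTable, MismatchTable]:
    """Run both case studies, sharing the (identical) level-0 inversions."""
    shared: dict = {}
    beam = _run_study("beam_diameter", levels, settings, seeds, shared)
    scat = _run_study("scattering_amplitude", levels, settings, seeds, shared)
    return beam, scat


def relative_improvement(tables: MismatchTable | Sequence[MismatchTable]) -> dict:
    """Relative accuracy improvement of eps_d+MI over eps_d, in percent.

    Per level (median over seeds): (err_d - err_dMI) / err_d * 100; the
    summary aggregates all nonzero levels of the given tables.  Levels with
    err_d = 0 are excluded and flagged.
    """
    if isinstance(tables, MismatchTable):
        tables = [tables]
    per_level = []
    excluded = []
    for table in tables:
        med_d = table.median_roi("eps_d")
        med_mi = table.median_roi("eps_d_mi")
        for level in table.levels:
            if level == 0.0:
                continue
            d = float(med_d.loc[level])
            m = float(med_mi.loc[level])
            if d == 0.0:
                excluded.append((table.parameter, float(level)))
                continue
            per_level.append({"parameter": table.parameter, "level": float(level),
                              "improvement_pct": (d - m) / d * 100.0})
    if not per_level:
        raise MetricError("no usable mismatch levels for the improvement summary")
    vals = np.array([p["improvement_pct"] for p in per_level])
    return {
        "mean_pct": float(vals.mean()),
        "min_pct": float(vals.min()),
        "max_pct": float(vals.max()),
        "per_level": per_level,
        "excluded_levels": excluded,
        "note": "mean over all nonzero (case, level) pairs; level 0 excluded",
    }
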