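"""Verification of camera NDVI against spectrometer NDVI.

The wavelength sweep asks: which spectrometer band combination produces
NDVI values closest to what the camera actually reports?  If the
calibration is faithful, the sweep minimum should land on the band
centres the camera was calibrated to.  Agreement with a reference
instrument is summarized by ordinary least squares plus the standard
deviation of the paired differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateSignalError, InvalidInputError
from .radiometry import ndvi_value
from .spectral import SpectralCurve


@dataclass
class SweepResult:
    """Outcome of a wavelength sweep."""

    swept_band: str  # "red" | "nir"
    wavelengths: np.ndarray  # nm, strictly increasing
    mean_abs_pct_diff: np.ndarray  # percent, per wavelength
    best_wavelength: float  # nm, argmin (ties -> lowest wavelength)

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.mean_abs_pct_diff = np.asarray(self.mean_abs_pct_diff, dtype=float)
        if np.any(np.diff(self.wavelengths) <= 0):
            raise InvalidInputError("sweep wavelengths must be strictly increasing")


def _spectral_ndvi(curve: SpectralCurve, red_nm: float, nir_nm: float) -> float:
    return ndvi_value(float(curve.at(nir_nm)), float(curve.at(red_nm)))


def wavelength_sweep(
    camera_ndvi,
    spectra: list[SpectralCurve],
    fixed: tuple[str, float],
    sweep: tuple[str, tuple[float, float], float],
) -> SweepResult:
    """Sweep one band of the spectrometer NDVI against camera NDVI.

    ``fixed`` is ("nir", 750.0)-style; ``sweep`` is
    ("red", (600.0, 700.0), 10.0): band role, inclusive range, step.
    For each candidate wavelength the spectrometer NDVI is computed per
    sample and compared to the camera value as a mean absolute relative
    difference in percent (denominator: the spectrometer value).
    Samples where the spectrometer NDVI is exactly zero are excluded at
    that wavelength with a warning; the best wavelength is the argmin,
    ties broken toward the shorter wavelength.
    """
    camera_ndvi = np.asarray(camera_ndvi, dtype=float)
    if camera_ndvi.size < 1:
        raise InvalidInputError("need at least one sample")
    if camera_ndvi.size != len(spectra):
        raise InvalidInputError("camera values and spectra must be sample-aligned")
    fixed_role, fixed_nm = fixed
    sweep_role, (lo, hi), step = sweep
    if {fixed_role, sweep_role} != {"red", "nir"}:
        raise InvalidInputError("one band must be 'red' and the other 'nir'")
    n_steps = int(round((hi - lo) / step))
    wavelengths = lo + step * np.arange(n_steps + 1)

    mean_diffs = np.empty(wavelengths.size)
    for k, lam in enumerate(wavelengths):
        red_nm, nir_nm = (lam, fixed_nm) if sweep_role == "red" else (fixed_nm, lam)
        diffs = []
        for cam, curve in zip(camera_ndvi, spectra):
            spec_ndvi = _spectral_ndvi(curve, red_nm, nir_nm)
            if spec_ndvi == 0.0:
                warnings.warn(
                    f"sample {curve.name!r} excluded at {lam:g} nm: spectrometer NDVI is 0",
                    stacklevel=2,
                )
                continue
            diffs.append(100.0 * abs(cam - spec_ndvi) / abs(spec_ndvi))
        if not diffs:
            raise DegenerateSignalError(f"all samples excluded at {lam:g} nm")
        mean_diffs[k] = float(np.mean(diffs))

    best = float(wavelengths[int(np.argmin(mean_diffs))])  # argmin takes first on ties
    return SweepResult(
        swept_band=sweep_role,
        wavelengths=wavelengths,
        mean_abs_pct_diff=mean_diffs,
        best_wavelength=best,
    )


def compare_to_reference(camera_vals, reference_vals) -> dict:
    """OLS agreement of camera NDVI with a reference instrument.

    Returns ``{"r2", "slope", "intercept", "sd_diff"}`` where the line
    is camera = slope·reference + intercept, ``r2`` is the squared
    Pearson correlation and ``sd_diff`` is the population standard
    deviation of (camera − reference).
    """
    cam = np.asarray(camera_vals, dtype=float)
    ref = np.asarray(reference_vals, dtype=float)
    if cam.shape != ref.shape or cam.size < 3:
        raise InvalidInputError("need equal-length inputs with at least 3 samples")
    if np.ptp(ref) == 0:
        raise DegenerateSignalError("reference values have zero variance")
    res = stats.linregress(ref, cam)
    diff = cam - ref
    return {
        "r2": float(res.rvalue**2),
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "sd_diff": float(diff.std(ddof=0)),
    }
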