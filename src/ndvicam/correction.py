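"""Red-leak removal and dual-camera registration.

The NIR camera sits behind a colour lighting filter that passes NIR
freely but also transmits 5–15 % of red light, so the measured NIR
reflectance is contaminated additively by a fraction of the red-band
signal.  The leak fraction is predicted from the filter transmission
curve and removed per pixel after calibration (working in reflectance
space keeps the correction independent of camera gamma).

The two cameras sit side by side on a rigid mount, so registration is
modelled as a pure translation: normalized cross-correlation over
integer shifts inside a search radius, refined to sub-pixel accuracy by
parabolic interpolation of the correlation peak along each axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import (
    DegenerateSignalError,
    DimensionError,
    InvalidInputError,
    NoFeaturesError,
)
from .radiometry import BandDefinition, ReflectanceImage
from .spectral import STANDARD_GRID, SpectralCurve


@dataclass(frozen=True)
class LeakModel:
    """Fraction of red-band signal additively contaminating measured NIR."""

    fraction: float

    def __post_init__(self):
        if not 0.0 <= self.fraction < 1.0:
            raise InvalidInputError("leak fraction must lie in [0, 1)")


@dataclass(frozen=True)
class RigidShift:
    """Translation of the NIR frame relative to the red frame, in pixels.

    ``dx`` is columns, ``dy`` rows; both may be fractional.  ``score``
    is the peak normalized cross-correlation in [0, 1].
    """

    dx: float
    dy: float
    score: float = 1.0

    def negated(self) -> "RigidShift":
        return RigidShift(-self.dx, -self.dy, self.score)


def _band_signal(
    band: BandDefinition,
    grid: np.ndarray,
    illumination: np.ndarray,
    reflectance: np.ndarray,
    transmission: np.ndarray,
) -> float:
    sel = (grid >= band.lo) & (grid <= band.hi)
    return float(np.sum(illumination[sel] * reflectance[sel] * transmission[sel]))


def estimate_leak_fraction(
    filter_transmission: SpectralCurve,
    red_band: BandDefinition,
    nir_band: BandDefinition,
    illumination: SpectralCurve | None = None,
    typical_reflectance: SpectralCurve | None = None,
) -> LeakModel:
    """Predict the red-leak fraction from the filter transmission curve.

    The in-band signal for each band is the sum over a common 1 nm grid
    of illumination x reflectance x filter transmission, and the leak
    fraction is S_red / (S_red + S_nir).  Omitted illumination or
    reflectance curves default to flat (spectrally neutral) curves.
    """
    grid = STANDARD_GRID
    if illumination is None:
        illumination = SpectralCurve.flat(1.0, grid)
    if typical_reflectance is None:
        typical_reflectance = SpectralCurve.flat(1.0, grid)
    t = filter_transmission.at(grid)
    i = illumination.at(grid)
    r = typical_reflectance.at(grid)
    s_red = _band_signal(red_band, grid, i, r, t)
    s_nir = _band_signal(nir_band, grid, i, r, t)
    total = s_red + s_nir
    if total <= 0:
        raise DegenerateSignalError("zero total in-band signal")
    return LeakModel(fraction=s_red / total)


def contaminated_nir_targets(panel, leak: LeakModel) -> np.ndarray:
    """Panel reflectances as the leak-affected NIR camera actually sees them.

    The NIR camera images every panel patch through the leaky filter, so
    the signal it records for a patch is R_nir + f·R_red.  Fitting the
    NIR calibration against these adjusted targets makes the calibrated
    image an estimate of the *measured* (contaminated) reflectance, which
    the per-pixel subtraction in :func:`correct_nir_leak` then converts
    to true NIR reflectance — without the subtraction being applied
    twice (once implicitly by the fit, once explicitly).
    """
    return panel.reflectances("nir") + leak.fraction * panel.reflectances("red")


def correct_nir_leak(
    nir_meas: ReflectanceImage, red: ReflectanceImage, leak: LeakModel
) -> ReflectanceImage:
    """Subtract the leaked red fraction from measured NIR reflectance.

    nir_corr = nir_meas − f·red, clamped at 0 with clamped pixels
    flagged.  With f = 0 the output equals the input exactly.
    """
    if nir_meas.shape != red.shape:
        raise DimensionError("nir and red images have different shapes")
    if leak.fraction == 0.0:
        return ReflectanceImage(nir_meas.values.copy(), nir_meas.band, nir_meas.mask.copy())
    corrected = nir_meas.values - leak.fraction * red.values
    clamped = corrected < 0.0
    corrected = np.clip(corrected, 0.0, None)
    mask = nir_meas.mask & red.mask & ~clamped
    return ReflectanceImage(values=corrected, band=nir_meas.band, mask=mask)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return 0.0
    return float((a * b).sum() / denom)


def _parabolic_offset(cm: float, c0: float, cp: float) -> float:
    """Sub-pixel offset of a parabola through three equally spaced points."""
    denom = cm - 2.0 * c0 + cp
    if denom >= 0:  # not a proper maximum; keep the integer peak
        return 0.0
    off = 0.5 * (cm - cp) / denom
    return float(np.clip(off, -0.5, 0.5))


def estimate_shift(
    red: ReflectanceImage, nir: ReflectanceImage, search_radius: int = 10
) -> RigidShift:
    """Estimate the translation of ``nir`` relative to ``red``.

    Exhaustive normalized cross-correlation over integer shifts within
    ``search_radius``, evaluated on the overlapping region only, then
    refined to sub-pixel by 1-D parabolic fits along each axis of the
    correlation surface.  If the NIR content sits at (+dx, +dy) relative
    to the red content, the returned shift is (dx, dy); apply its
    negation to the NIR image to align it.
    """
    if red.shape != nir.shape:
        raise DimensionError("images must share a shape")
    h, w = red.shape
    if search_radius > min(h, w) // 4:
        raise InvalidInputError("search_radius must be <= min(dim)/4")
    a = np.where(red.mask, red.values, np.nan)
    b = np.where(nir.mask, nir.values, np.nan)
    if np.nanstd(a) == 0 or np.nanstd(b) == 0:
        raise NoFeaturesError("zero-variance image; cannot register")

    r = search_radius
    size = 2 * r + 1
    corr = np.full((size, size), -np.inf)
    for i, dy in enumerate(range(-r, r + 1)):
        for j, dx in enumerate(range(-r, r + 1)):
            # nir(y, x) ~ red(y - dy, x - dx): compare shifted overlaps.
            ra = a[max(0, -dy) : h - max(0, dy), max(0, -dx) : w - max(0, dx)]
            rb = b[max(0, dy) : h - max(0, -dy), max(0, dx) : w - max(0, -dx)]
            valid = np.isfinite(ra) & np.isfinite(rb)
            if valid.sum() < 16:
                continue
            corr[i, j] = _pearson(ra[valid], rb[valid])

    i0, j0 = np.unravel_index(np.argmax(corr), corr.shape)
    peak = corr[i0, j0]
    if not np.isfinite(peak):
        raise NoFeaturesError("no valid overlap inside the search radius")

    dy = float(i0 - r)
    dx = float(j0 - r)
    if 0 < i0 < size - 1 and np.isfinite(corr[i0 - 1, j0]) and np.isfinite(corr[i0 + 1, j0]):
        dy += _parabolic_offset(corr[i0 - 1, j0], peak, corr[i0 + 1, j0])
    if 0 < j0 < size - 1 and np.isfinite(corr[i0, j0 - 1]) and np.isfinite(corr[i0, j0 + 1]):
        dx += _parabolic_offset(corr[i0, j0 - 1], peak, corr[i0, j0 + 1])
    return RigidShift(dx=dx, dy=dy, score=float(np.clip(peak, 0.0, 1.0)))


def apply_shift(img: ReflectanceImage, shift: RigidShift) -> ReflectanceImage:
    """Translate an image by (dx, dy) with bilinear resampling.

    Output pixel (y, x) samples the source at (y − dy, x − dx); samples
    falling outside the source frame are masked.
    """
    if not (np.isfinite(shift.dx) and np.isfinite(shift.dy)):
        raise InvalidInputError("shift must be finite")
    if shift.dx == 0.0 and shift.dy == 0.0:
        return ReflectanceImage(img.values.copy(), img.band, img.mask.copy())
    h, w = img.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    src_y = yy - shift.dy
    src_x = xx - shift.dx
    coords = np.stack([src_y, src_x])
    values = ndimage.map_coordinates(img.values, coords, order=1, mode="constant", cval=0.0)
    inside = (src_y >= 0) & (src_y <= h - 1) & (src_x >= 0) & (src_x <= w - 1)
    # a resampled pixel is valid only if all contributing source pixels were
    src_valid = ndimage.map_coordinates(
        img.mask.astype(float), coords, order=1, mode="constant", cval=0.0
    )
    mask = inside & (src_valid >= 1.0 - 1e-9)
    return ReflectanceImage(values=values, band=img.band, mask=mask)
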