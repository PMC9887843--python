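"""NDVI image construction, region statistics and display colouring."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib import colormaps

from .errors import ConfigError, DimensionError, EmptyRegionError, InvalidInputError
from .radiometry import (
    DEFAULT_ENCODING,
    EncodedImage,
    EncodingSpec,
    ReflectanceImage,
    encode_ndvi,
    ndvi_array,
)

#: |mean| below this is treated as zero when forming the coefficient of variation.
_COV_MEAN_EPS = 1e-12


@dataclass(frozen=True)
class RegionStats:
    """Descriptive statistics of NDVI over a region of interest.

    ``sd`` is the population standard deviation, ``cov = sd/mean`` (NaN
    when the mean is numerically zero) and ``skewness`` is the
    Fisher–Pearson coefficient g1 = m3 / m2^(3/2) (0 for constant
    regions).
    """

    mean: float
    sd: float
    cov: float
    skewness: float
    n: int


def build_ndvi_image(
    red: ReflectanceImage,
    nir: ReflectanceImage,
    spec: EncodingSpec = DEFAULT_ENCODING,
) -> EncodedImage:
    """Per-pixel NDVI from co-registered reflectance bands, 16-bit encoded.

    The output mask is the union of the input masks with pixels where
    nir + red is numerically zero additionally masked.
    """
    if red.shape != nir.shape:
        raise DimensionError("red and nir images have different shapes")
    values, defined = ndvi_array(nir.values, red.values)
    mask = red.mask & nir.mask & defined
    return encode_ndvi(values, mask=mask, spec=spec)


def region_stats(ndvi: np.ndarray, roi=None) -> RegionStats:
    """Statistics of decoded NDVI values inside a rectangle or boolean mask.

    ``roi`` may be a :class:`~ndvicam.calibration.Rect`, a boolean mask of
    the same shape, or None for the whole grid.
    """
    ndvi = np.asarray(ndvi, dtype=float)
    if roi is None:
        vals = ndvi.ravel()
    elif hasattr(roi, "slices"):
        vals = ndvi[roi.slices()].ravel()
    else:
        roi = np.asarray(roi, dtype=bool)
        if roi.shape != ndvi.shape:
            raise DimensionError("roi mask shape does not match grid")
        vals = ndvi[roi]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise EmptyRegionError("region contains no valid pixels")
    mean = float(vals.mean())
    m2 = float(((vals - mean) ** 2).mean())
    m3 = float(((vals - mean) ** 3).mean())
    sd = float(np.sqrt(m2))
    # constant regions accumulate ~1e-16 rounding residue; snap to zero
    scale = max(abs(mean), float(np.max(np.abs(vals))), 1e-300)
    if sd <= 1e-12 * scale:
        sd, m2 = 0.0, 0.0
    cov = (sd / mean if abs(mean) >= _COV_MEAN_EPS else float("nan")) if sd > 0 else 0.0
    skew = m3 / m2 ** 1.5 if m2 > 0 else 0.0
    return RegionStats(mean=mean, sd=sd, cov=cov, skewness=skew, n=int(vals.size))


def _build_lut(cmap_name: str) -> np.ndarray:
    cmap = colormaps[cmap_name]
    return (cmap(np.linspace(0.0, 1.0, 256))[:, :3] * 255).astype(np.uint8)


# Named 256-entry look-up tables. The default renders low NDVI red and
# high NDVI green, a common display convention for vegetation indices.
_LUTS = {
    "green_red": lambda: _build_lut("RdYlGn"),
    "gray": lambda: np.repeat(np.arange(256, dtype=np.uint8)[:, None], 3, axis=1),
    "viridis": lambda: _build_lut("viridis"),
}

DEFAULT_LUT = "green_red"


def available_luts() -> tuple[str, ...]:
    return tuple(sorted(_LUTS))


def colorize(enc: EncodedImage, lut_name: str = DEFAULT_LUT) -> np.ndarray:
    """Render an encoded NDVI image through a 256-entry LUT.

    Codes index the LUT by their top byte (code // 256); masked pixels
    render black.  The mapping is deterministic: the same input and LUT
    produce byte-identical output.
    """
    if enc.payload != "ndvi":
        raise InvalidInputError("colorize expects an NDVI payload")
    try:
        lut = _LUTS[lut_name]()
    except KeyError:
        raise ConfigError(
            f"unknown LUT {lut_name!r}; available: {available_luts()}"
        ) from None
    idx = (enc.codes // 256).astype(np.intp)
    rgb = lut[idx]
    rgb[~enc.mask] = 0
    return rgb
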