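"""Core radiometric types and integer encodings.

A camera frame carries 8-bit digital numbers (DN).  Calibrated products
are stored as relative reflectance in percent, or as NDVI, both scaled
into unsigned 16-bit integer codes for compact lossless storage:

* reflectance 0–100 %  ->  codes 0–65 536 (linear),
* NDVI −1…+1           ->  codes 0–65 536 (linear),

with out-of-range values saturating at the ends of the scale.  The
nominal top of the scale (65 536) does not fit in 16 bits, so stored
codes clamp at 65 535 while the pure decode formula keeps the exact
denominator of 65 536; the worst-case round-trip error is one code.
Rounding is half-away-from-zero so results are platform independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DimensionError, InvalidInputError, UndefinedPixelError

#: Relative tolerance (in percent reflectance) below which nir + red is
#: treated as zero signal and NDVI is undefined.
NDVI_EPSILON = 1e-6


@dataclass(frozen=True)
class BandDefinition:
    """A spectral band: centre wavelength and full width at half maximum.

    ``fwhm = 0`` is allowed and denotes an idealized (delta-like)
    spectrometer band.
    """

    name: str
    center_wavelength: float  # nm
    fwhm: float = 0.0  # nm

    def __post_init__(self):
        if not 400.0 <= self.center_wavelength <= 1000.0:
            raise InvalidInputError(
                f"band centre {self.center_wavelength} nm outside [400, 1000]"
            )
        if self.fwhm < 0:
            raise InvalidInputError("fwhm must be >= 0")

    @property
    def lo(self) -> float:
        """Lower band edge (centre − fwhm/2)."""
        return self.center_wavelength - self.fwhm / 2.0

    @property
    def hi(self) -> float:
        """Upper band edge (centre + fwhm/2)."""
        return self.center_wavelength + self.fwhm / 2.0


# Band centres used by the dual Raspberry Pi camera rig: the visible red
# channel is taken as 620 nm and the NIR channel as 750 nm (broadband
# Bayer channels; the fwhm values are nominal channel widths).
RED_620 = BandDefinition("red620", 620.0, 60.0)
NIR_750 = BandDefinition("nir750", 750.0, 100.0)

# Micasense RedEdge narrowband alternatives (red / red-edge / NIR).
RED_668 = BandDefinition("red668", 668.0, 10.0)
REDEDGE_717 = BandDefinition("rededge717", 717.0, 10.0)
NIR_840 = BandDefinition("nir840", 840.0, 40.0)


@dataclass(frozen=True)
class CameraConfig:
    """Exposure settings of one camera."""

    iso: float = 400.0
    shutter_speed: float = 400.0  # microseconds

    def __post_init__(self):
        if self.shutter_speed <= 0:
            raise InvalidInputError("shutter_speed must be > 0")
        if self.iso <= 0:
            raise InvalidInputError("iso must be > 0")


# Factory-default settings for the two cameras (visible-red camera uses a
# much shorter shutter because it is prone to saturation).
RED_CAMERA = CameraConfig(iso=400, shutter_speed=400)
NIR_CAMERA = CameraConfig(iso=400, shutter_speed=2500)


@dataclass
class DigitalImage:
    """An 8-bit multi-channel camera frame.

    ``pixels`` has shape (rows, cols) for a single channel or
    (rows, cols, n_channels); ``channels`` labels the last axis.
    """

    pixels: np.ndarray
    channels: tuple[str, ...] = ("red",)
    camera_role: str = "red-cam"  # "red-cam" | "nir-cam"
    settings: CameraConfig = field(default_factory=CameraConfig)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim == 2:
            self.pixels = self.pixels[:, :, None]
        if self.pixels.ndim != 3:
            raise InvalidInputError("pixels must be 2-D or 3-D")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise InvalidInputError("image must be at least 1x1")
        if self.pixels.shape[2] != len(self.channels):
            raise InvalidInputError("channel labels do not match pixel planes")
        if self.pixels.min() < 0 or self.pixels.max() > 255:
            raise InvalidInputError("digital numbers must lie in [0, 255]")
        if self.camera_role not in ("red-cam", "nir-cam"):
            raise InvalidInputError(f"unknown camera role {self.camera_role!r}")
        self.pixels = self.pixels.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    def channel(self, label: str) -> np.ndarray:
        """Return one channel plane as a 2-D uint8 array."""
        try:
            idx = self.channels.index(label)
        except ValueError:
            raise InvalidInputError(
                f"channel {label!r} not in {self.channels}"
            ) from None
        return self.pixels[:, :, idx]


@dataclass
class ReflectanceImage:
    """Single-band relative reflectance in percent, with a validity mask.

    ``mask`` is True where the pixel is valid; clamped or undefined
    pixels are flagged False but keep their clamped value.
    """

    values: np.ndarray
    band: BandDefinition
    mask: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InvalidInputError("reflectance values must be 2-D")
        if self.mask is None:
            self.mask = np.ones(self.values.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise DimensionError("mask shape does not match values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class EncodingSpec:
    """Linear 16-bit integer scaling of reflectance or NDVI."""

    scale_denominator: int = 65536
    max_code: int = 65535
    rounding: str = "half-away-from-zero"

    def __post_init__(self):
        if not (0 < self.max_code < self.scale_denominator <= 65536):
            raise InvalidInputError(
                "require 0 < max_code < scale_denominator <= 65536"
            )


DEFAULT_ENCODING = EncodingSpec()


@dataclass
class EncodedImage:
    """16-bit integer codes plus the spec that produced them."""

    codes: np.ndarray
    payload: str  # "reflectance" | "ndvi"
    spec: EncodingSpec = DEFAULT_ENCODING
    mask: np.ndarray | None = None
    band: BandDefinition | None = None

    def __post_init__(self):
        self.codes = np.asarray(self.codes)
        if self.payload not in ("reflectance", "ndvi"):
            raise InvalidInputError(f"unknown payload {self.payload!r}")
        if self.codes.min(initial=0) < 0 or self.codes.max(initial=0) > self.spec.max_code:
            raise InvalidInputError("codes out of [0, max_code]")
        self.codes = self.codes.astype(np.uint16)
        if self.mask is None:
            self.mask = np.ones(self.codes.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer, ties away from zero (not banker's)."""
    return np.copysign(np.floor(np.abs(x) + 0.5), x)


def encode_reflectance(
    img: ReflectanceImage, spec: EncodingSpec = DEFAULT_ENCODING
) -> EncodedImage:
    """Scale percent reflectance linearly into 16-bit codes.

    0 % maps to code 0 and 100 % to the (nominal) top of scale; values
    outside [0, 100] saturate.  Masked pixels encode 0 and stay flagged
    in the output mask.  A non-finite *unmasked* value is an error.
    """
    v = img.values
    bad = ~np.isfinite(v) & img.mask
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise InvalidInputError(f"non-finite unmasked reflectance at pixel ({r}, {c})")
    safe = np.where(img.mask, v, 0.0)
    codes = _round_half_away(safe / 100.0 * spec.scale_denominator)
    codes = np.clip(codes, 0, spec.max_code)
    codes = np.where(img.mask, codes, 0)
    return EncodedImage(
        codes=codes, payload="reflectance", spec=spec, mask=img.mask.copy(), band=img.band
    )


def decode_reflectance(enc: EncodedImage) -> ReflectanceImage:
    """Invert :func:`encode_reflectance` (error at most one code step)."""
    if enc.payload != "reflectance":
        raise TypeError(f"expected reflectance payload, got {enc.payload!r}")
    v = enc.codes.astype(float) * (100.0 / enc.spec.scale_denominator)
    band = enc.band if enc.band is not None else BandDefinition("unknown", 620.0)
    return ReflectanceImage(values=v, band=band, mask=enc.mask.copy())


def ndvi_value(nir: float, red: float, eps: float = NDVI_EPSILON) -> float:
    """NDVI = (NIR − RED) / (NIR + RED) on percent reflectances.

    Raises :class:`UndefinedPixelError` when the total signal is at or
    below ``eps`` — callers working on images mask such pixels instead.
    """
    if nir < 0 or red < 0:
        raise InvalidInputError("reflectances must be non-negative")
    total = nir + red
    if total <= eps:
        raise UndefinedPixelError(f"nir + red = {total} <= {eps}")
    return (nir - red) / total


def ndvi_array(
    nir: np.ndarray, red: np.ndarray, eps: float = NDVI_EPSILON
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized NDVI; returns (values, defined_mask).

    Undefined pixels (nir + red <= eps) get value 0 and mask False.
    """
    nir = np.asarray(nir, dtype=float)
    red = np.asarray(red, dtype=float)
    if nir.shape != red.shape:
        raise DimensionError("nir and red shapes differ")
    total = nir + red
    defined = total > eps
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(defined, (nir - red) / np.where(defined, total, 1.0), 0.0)
    return out, defined


def encode_ndvi(
    values: np.ndarray,
    mask: np.ndarray | None = None,
    spec: EncodingSpec = DEFAULT_ENCODING,
) -> EncodedImage:
    """Scale NDVI in [−1, 1] linearly into 16-bit codes (−1 -> 0)."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if mask is None:
        mask = np.ones(values.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    bad = ~np.isfinite(values) & mask
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise InvalidInputError(f"non-finite unmasked NDVI at pixel ({r}, {c})")
    safe = np.where(mask, values, -1.0)
    codes = _round_half_away((safe + 1.0) / 2.0 * spec.scale_denominator)
    codes = np.clip(codes, 0, spec.max_code)
    codes = np.where(mask, codes, 0)
    return EncodedImage(codes=codes, payload="ndvi", spec=spec, mask=mask.copy())


def decode_ndvi(code, spec: EncodingSpec = DEFAULT_ENCODING):
    """Map a 16-bit code (or array) back to NDVI: code·(2/65536) − 1.

    Accepts the nominal endpoint 65 536 even though stored codes cap at
    65 535, so the decode of the nominal top of scale is exactly +1.
    """
    arr = np.asarray(code, dtype=float)
    if arr.min() < 0 or arr.max() > spec.scale_denominator:
        raise InvalidInputError(
            f"code out of [0, {spec.scale_denominator}]"
        )
    out = arr * (2.0 / spec.scale_denominator) - 1.0
    return float(out) if np.isscalar(code) or arr.ndim == 0 else out
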