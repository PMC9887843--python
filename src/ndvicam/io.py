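"""Reading and writing image artifacts.

Camera frames travel as 8-bit PNG.  Calibrated products (reflectance or
NDVI) travel as 16-bit grayscale PNG, always accompanied by a JSON
sidecar (``<image>.json``) recording the payload kind, the encoding
scale and the band; without the sidecar a 16-bit image is ambiguous and
is refused.  Validity masks are stored as 8-bit PNGs
(``<image>.mask.png``, 255 = valid) next to the image when any pixel is
masked.  Lossy formats are rejected.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .errors import FormatError, MetadataError
from .radiometry import (
    BandDefinition,
    CameraConfig,
    DigitalImage,
    EncodedImage,
    EncodingSpec,
)

_LOSSY_SUFFIXES = {".jpg", ".jpeg", ".webp"}


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _mask_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".mask.png")


def write_image(img, path) -> Path:
    """Write a :class:`DigitalImage` (8-bit) or :class:`EncodedImage`
    (16-bit grayscale) as PNG with its JSON sidecar."""
    path = Path(path)
    if isinstance(img, DigitalImage):
        pixels = img.pixels[:, :, 0] if img.pixels.shape[2] == 1 else img.pixels
        iio.imwrite(path, pixels, extension=".png")
        sidecar = {
            "depth": 8,
            "channels": list(img.channels),
            "camera_role": img.camera_role,
            "settings": {"iso": img.settings.iso, "shutter_speed": img.settings.shutter_speed},
        }
    elif isinstance(img, EncodedImage):
        iio.imwrite(path, img.codes.astype(np.uint16), extension=".png")
        sidecar = {
            "depth": 16,
            "payload": img.payload,
            "scale_denominator": img.spec.scale_denominator,
            "max_code": img.spec.max_code,
            "band": None
            if img.band is None
            else {
                "name": img.band.name,
                "center_wavelength": img.band.center_wavelength,
                "fwhm": img.band.fwhm,
            },
        }
        if not img.mask.all():
            iio.imwrite(_mask_path(path), (img.mask * np.uint8(255)), extension=".png")
            sidecar["mask"] = _mask_path(path).name
    else:
        raise TypeError(f"cannot write {type(img).__name__}")
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))
    return path


def read_image(path, camera_role: str | None = None):
    """Load an image written by :func:`write_image` (or any clean PNG).

    8-bit, 1–3 channel PNGs load as :class:`DigitalImage`; 16-bit
    grayscale PNGs load as :class:`EncodedImage` and require the JSON
    sidecar.  Lossy formats raise :class:`FormatError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in _LOSSY_SUFFIXES:
        raise FormatError(f"lossy format {path.suffix!r} rejected; use PNG")
    arr = iio.imread(path)
    sidecar = None
    sc_path = _sidecar_path(path)
    if sc_path.exists():
        sidecar = json.loads(sc_path.read_text())

    if arr.dtype == np.uint8:
        if arr.ndim == 2:
            arr = arr[:, :, None]
        if arr.ndim != 3 or arr.shape[2] > 4:
            raise FormatError(f"unsupported 8-bit layout {arr.shape}")
        if arr.shape[2] == 4:  # drop alpha
            arr = arr[:, :, :3]
        if sidecar is not None and sidecar.get("depth") == 8:
            channels = tuple(sidecar["channels"])
            role = sidecar["camera_role"]
            settings = CameraConfig(**sidecar["settings"])
        else:
            channels = ("red",) if arr.shape[2] == 1 else ("red", "green", "blue")
            role = camera_role or "red-cam"
            settings = CameraConfig()
        if camera_role is not None:
            role = camera_role
        return DigitalImage(arr, channels, role, settings)

    if arr.dtype == np.uint16:
        if arr.ndim != 2:
            raise FormatError("16-bit images must be single-band grayscale")
        if sidecar is None or sidecar.get("depth") != 16:
            raise MetadataError(f"16-bit image {path.name} is missing its JSON sidecar")
        spec = EncodingSpec(
            scale_denominator=int(sidecar["scale_denominator"]),
            max_code=int(sidecar["max_code"]),
        )
        band = None
        if sidecar.get("band"):
            b = sidecar["band"]
            band = BandDefinition(b["name"], b["center_wavelength"], b["fwhm"])
        mask = None
        if sidecar.get("mask"):
            mask = iio.imread(path.parent / sidecar["mask"]) > 0
        return EncodedImage(arr, payload=sidecar["payload"], spec=spec, mask=mask, band=band)

    raise FormatError(f"unsupported bit depth {arr.dtype}")
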