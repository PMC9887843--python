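"""Empirical-line reflectance calibration from a six-material panel.

Consumer cameras apply a gamma correction in hardware, so digital number
is a power law, not a line, in scene reflectance.  The calibration model
used here is

    R/100 = a * (DN/255)**gamma + b

fitted by least squares to the mean DN of each reference patch against
its known band reflectance.  With six references gamma is a free
parameter (bounded to [1, 4], started at 2.2); with only two references
(brightest + darkest material) the system is exactly determined once
gamma is fixed, and the default fixed de-gamma exponent is 2.12766, an
empirically determined value for this camera family.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import (
    AllSaturatedError,
    BoundsError,
    ConvergenceError,
    InvalidInputError,
    SaturatedPatchError,
    SingularFitError,
)
from .radiometry import BandDefinition, DigitalImage, ReflectanceImage

# Patch-statistics choices: a 10% margin is eroded from every ROI edge so
# placement does not need to be pixel perfect, pixels at DN >= 250 are
# dropped as saturated, and a patch mean >= 240 triggers a warning since
# calibration cannot be trusted near the top of the sensor range.
ROI_MARGIN_FRACTION = 0.10
SATURATION_EXCLUDE_DN = 250
SATURATION_WARN_DN = 240

#: Fixed de-gamma exponent used in two-reference mode.
DEFAULT_FIXED_GAMMA = 2.12766

GAMMA_BOUNDS = (1.0, 4.0)
GAMMA_INIT = 2.2


@dataclass(frozen=True)
class Rect:
    """0-based half-open rectangle: rows [row0, row0+height), cols alike."""

    row0: int
    col0: int
    height: int
    width: int

    def __post_init__(self):
        if self.height < 1 or self.width < 1:
            raise InvalidInputError("ROI must be at least 1x1")

    def slices(self) -> tuple[slice, slice]:
        return (
            slice(self.row0, self.row0 + self.height),
            slice(self.col0, self.col0 + self.width),
        )

    def eroded(self, fraction: float = ROI_MARGIN_FRACTION) -> "Rect":
        """Shrink by ``fraction`` of each dimension on every side."""
        dr = int(self.height * fraction)
        dc = int(self.width * fraction)
        return Rect(self.row0 + dr, self.col0 + dc, self.height - 2 * dr, self.width - 2 * dc)

    def shifted(self, drow: int, dcol: int) -> "Rect":
        return Rect(self.row0 + drow, self.col0 + dcol, self.height, self.width)


@dataclass(frozen=True)
class PanelMaterial:
    name: str
    red_reflectance: float  # percent
    nir_reflectance: float  # percent

    def __post_init__(self):
        for v in (self.red_reflectance, self.nir_reflectance):
            if not 0.0 <= v <= 100.0:
                raise InvalidInputError("panel reflectance must lie in [0, 100]")


# Measured relative reflectances of the six Kayospruce Odyssey reference
# materials on the calibration board (red band / NIR band, percent).
DEFAULT_PANEL_MATERIALS = (
    PanelMaterial("White", 92.69, 87.62),
    PanelMaterial("Sand", 63.59, 60.85),
    PanelMaterial("Brown", 16.29, 16.13),
    PanelMaterial("Indian Burch", 66.72, 62.69),
    PanelMaterial("Forest Green", 4.90, 5.88),
    PanelMaterial("Burgundy", 25.53, 39.40),
)


@dataclass
class ReferencePanel:
    """The calibration board: six known materials plus their patch ROIs."""

    materials: tuple[PanelMaterial, ...] = DEFAULT_PANEL_MATERIALS
    rois: tuple[Rect, ...] | None = None

    def __post_init__(self):
        self.materials = tuple(self.materials)
        if self.rois is not None:
            self.rois = tuple(self.rois)
            if len(self.rois) != len(self.materials):
                raise InvalidInputError("one ROI per material required")

    def reflectances(self, channel: str) -> np.ndarray:
        """Known reflectances (%) for ``channel`` in panel order."""
        if channel == "red":
            return np.array([m.red_reflectance for m in self.materials])
        if channel == "nir":
            return np.array([m.nir_reflectance for m in self.materials])
        raise InvalidInputError(f"unknown panel channel {channel!r}")

    def with_rois(self, rois) -> "ReferencePanel":
        return ReferencePanel(self.materials, tuple(rois))

    @classmethod
    def from_csv(cls, path) -> "ReferencePanel":
        """Load materials from a CSV with columns name, red_reflectance, nir_reflectance."""
        df = pd.read_csv(path)
        mats = tuple(
            PanelMaterial(str(r["name"]), float(r["red_reflectance"]), float(r["nir_reflectance"]))
            for _, r in df.iterrows()
        )
        return cls(materials=mats)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "name": [m.name for m in self.materials],
                "red_reflectance": [m.red_reflectance for m in self.materials],
                "nir_reflectance": [m.nir_reflectance for m in self.materials],
            }
        ).to_csv(path, index=False)


def default_panel(rois=None) -> ReferencePanel:
    """The packaged six-material reference panel."""
    return ReferencePanel(DEFAULT_PANEL_MATERIALS, tuple(rois) if rois else None)


@dataclass
class CalibrationModel:
    """Fitted DN -> reflectance mapping R/100 = a·(DN/255)^gamma + b."""

    a: float
    b: float
    gamma: float
    mode: str  # "six-reference" | "two-reference"
    rmse: float  # percent reflectance, over the fitted points
    n_refs: int

    def __post_init__(self):
        if not GAMMA_BOUNDS[0] <= self.gamma <= GAMMA_BOUNDS[1]:
            raise InvalidInputError(f"gamma {self.gamma} outside {GAMMA_BOUNDS}")
        if self.rmse < 0:
            raise InvalidInputError("rmse must be >= 0")

    def predict(self, dn) -> np.ndarray:
        """Reflectance (%) predicted for digital numbers, unclamped."""
        x = np.asarray(dn, dtype=float) / 255.0
        return 100.0 * (self.a * np.power(x, self.gamma) + self.b)

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "a": self.a,
                    "b": self.b,
                    "gamma": self.gamma,
                    "mode": self.mode,
                    "rmse": self.rmse,
                    "n_refs": self.n_refs,
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path) -> "CalibrationModel":
        d = json.loads(Path(path).read_text())
        return cls(**d)


def extract_panel_means(
    img: DigitalImage, panel: ReferencePanel, channel: str = "red"
) -> np.ndarray:
    """Mean DN of each reference patch, in panel order.

    Each ROI is eroded by a 10% margin on every side and pixels at
    DN >= 250 are excluded as saturated.  A patch whose mean is >= 240
    triggers a saturation warning; a patch with more than half of its
    pixels excluded raises :class:`SaturatedPatchError`.
    """
    if panel.rois is None:
        raise InvalidInputError("panel has no ROIs")
    plane = img.channel(channel).astype(float)
    h, w = plane.shape
    means = []
    for mat, roi in zip(panel.materials, panel.rois):
        if (
            roi.row0 < 0
            or roi.col0 < 0
            or roi.row0 + roi.height > h
            or roi.col0 + roi.width > w
        ):
            raise BoundsError(f"ROI for {mat.name!r} outside image {h}x{w}")
        patch = plane[roi.eroded().slices()]
        ok = patch < SATURATION_EXCLUDE_DN
        if ok.sum() <= 0.5 * patch.size:
            raise SaturatedPatchError(
                f"patch {mat.name!r}: >50% of pixels saturated (DN >= {SATURATION_EXCLUDE_DN})"
            )
        mean = float(patch[ok].mean())
        if mean >= SATURATION_WARN_DN:
            warnings.warn(
                f"patch {mat.name!r} mean DN {mean:.1f} >= {SATURATION_WARN_DN}; "
                "calibration may be unreliable near saturation",
                stacklevel=2,
            )
        means.append(mean)
    return np.array(means)


def _model(x, a, b, gamma):
    return a * np.power(x, gamma) + b


def fit_calibration(
    dn_means,
    known_reflectances,
    mode: str = "six-reference",
    fixed_gamma: float | None = None,
) -> CalibrationModel:
    """Fit the empirical-line model to reference patches.

    In six-reference mode ``a``, ``b`` and ``gamma`` are all fitted by
    nonlinear least squares; in two-reference mode the caller passes the
    brightest and darkest references only, gamma is held fixed (default
    2.12766) and ``a``, ``b`` solve the 2x2 system exactly.
    """
    dn = np.asarray(dn_means, dtype=float)
    refl = np.asarray(known_reflectances, dtype=float)
    if dn.shape != refl.shape:
        raise InvalidInputError("dn_means and known_reflectances lengths differ")
    x = dn / 255.0
    y = refl / 100.0

    if np.ptp(dn) == 0:
        raise SingularFitError("all reference digital numbers are equal")

    if mode == "two-reference":
        if dn.size != 2:
            raise InvalidInputError("two-reference mode takes exactly 2 references")
        gamma = DEFAULT_FIXED_GAMMA if fixed_gamma is None else float(fixed_gamma)
        xg = np.power(x, gamma)
        a = (y[0] - y[1]) / (xg[0] - xg[1])
        b = y[0] - a * xg[0]
        return CalibrationModel(a=float(a), b=float(b), gamma=gamma,
                                mode=mode, rmse=0.0, n_refs=2)

    if mode != "six-reference":
        raise InvalidInputError(f"unknown calibration mode {mode!r}")
    if np.unique(dn).size < 4:
        raise InvalidInputError("six-reference mode needs >= 4 distinct DN values")

    if fixed_gamma is not None:
        # Fixed-gamma least squares reduces to a linear solve in (a, b).
        gamma = float(fixed_gamma)
        A = np.column_stack([np.power(x, gamma), np.ones_like(x)])
        (a, b), *_ = np.linalg.lstsq(A, y, rcond=None)
        pred = _model(x, a, b, gamma)
        rmse = float(np.sqrt(np.mean((pred - y) ** 2))) * 100.0
        return CalibrationModel(a=float(a), b=float(b), gamma=gamma,
                                mode=mode, rmse=rmse, n_refs=dn.size)

    try:
        popt, _ = curve_fit(
            _model,
            x,
            y,
            p0=[1.0, 0.0, GAMMA_INIT],
            bounds=([-np.inf, -np.inf, GAMMA_BOUNDS[0]], [np.inf, np.inf, GAMMA_BOUNDS[1]]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        resid = None
        raise ConvergenceError(f"calibration fit did not converge: {exc}", resid) from exc
    a, b, gamma = (float(p) for p in popt)
    pred = _model(x, a, b, gamma)
    rmse = float(np.sqrt(np.mean((pred - y) ** 2))) * 100.0
    return CalibrationModel(a=a, b=b, gamma=gamma, mode=mode, rmse=rmse, n_refs=dn.size)


def apply_calibration(
    img: DigitalImage,
    model: CalibrationModel,
    channel: str = "red",
    band: BandDefinition | None = None,
) -> ReflectanceImage:
    """Convert every pixel of one channel to reflectance (%).

    Values outside [0, 100] are clamped and the clamped pixels flagged
    False in the output mask.  The mapping is monotone in DN whenever
    the fitted gain is positive.
    """
    dn = img.channel(channel)
    r = model.predict(dn)
    in_bounds = (r >= 0.0) & (r <= 100.0)
    r = np.clip(r, 0.0, 100.0)
    if band is None:
        band = BandDefinition(channel, 620.0 if img.camera_role == "red-cam" else 750.0)
    return ReflectanceImage(values=r, band=band, mask=in_bounds)


def select_shutter_speed(exposure_series, panel: ReferencePanel, channel: str = "red") -> float:
    """Pick the longest shutter whose brightest patch mean DN stays < 240.

    ``exposure_series`` is a list of (shutter_us, DigitalImage) with
    strictly increasing shutter speeds.  Exposures whose panel extraction
    fails outright from saturation are treated as disqualified.
    """
    if len(exposure_series) < 2:
        raise InvalidInputError("need at least 2 exposures")
    shutters = [s for s, _ in exposure_series]
    if any(b <= a for a, b in zip(shutters, shutters[1:])):
        raise InvalidInputError("shutter speeds must be strictly increasing")
    best = None
    for shutter, img in exposure_series:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                brightest = float(extract_panel_means(img, panel, channel).max())
        except SaturatedPatchError:
            continue
        if brightest < SATURATION_WARN_DN and (best is None or shutter > best):
            best = shutter
    if best is None:
        raise AllSaturatedError("every exposure saturates the brightest reference")
    return best
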