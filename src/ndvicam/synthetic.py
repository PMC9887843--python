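"""Ground-truthed synthetic scenes, cameras and spectrometer.

The simulator provides everything the pipeline needs without hardware:

* a simplified chlorophyll-dependent leaf reflectance model — red-band
  reflectance decays exponentially with chlorophyll content, with an
  absorption kernel peaking at 680 nm, while the NIR plateau is
  pigment-independent;
* the six-material calibration board with its known reflectances;
* a two-camera imaging model with gamma encoding, shutter-proportional
  gain, additive DN noise, sensor saturation, red-light leak onto the
  NIR channel and a rigid inter-camera misalignment;
* an idealized spectrometer referenced to a 99 % diffuse standard.

The leaf model is a deliberately small stand-in for a full radiative
transfer model: it reproduces only the properties the pipeline relies
on (red sensitivity to chlorophyll that peaks near the 680 nm absorption
maximum, an insensitive NIR plateau, smooth monotone curves).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .calibration import DEFAULT_FIXED_GAMMA, Rect, ReferencePanel, default_panel
from .errors import InvalidInputError, SceneSpecError
from .radiometry import (
    NIR_CAMERA,
    RED_CAMERA,
    CameraConfig,
    DigitalImage,
)
from .spectral import STANDARD_GRID, SpectralCurve

# Leaf model constants (percent reflectance): baseline + amplitude for
# the visible red region, NIR plateau level, absorption kernel strength
# and spectral width around the 680 nm chlorophyll absorption peak.
LEAF_BASELINE = 2.0
LEAF_AMPLITUDE = 48.0
NIR_PLATEAU = 47.0
ABSORB_K0 = 0.08  # cm^2 / µg, at the 680 nm peak
ABSORB_PEAK_NM = 680.0
ABSORB_WIDTH_NM = 45.0
BLEND_LO, BLEND_HI = 700.0, 720.0

#: Reference illumination (µmol m^-2 s^-1) at which camera gain is 1.
REFERENCE_IRRADIANCE = 800.0

#: Shutter speeds (µs) at which each camera's linear gain is 1.  The
#: factory settings (400 µs red, 2500 µs NIR) therefore run at gain 0.8,
#: which keeps the brightest reference below the DN 240 exposure cap —
#: exactly the headroom the exposure-selection rule enforces in the field.
NOMINAL_SHUTTER = {"red-cam": 500.0, "nir-cam": 3125.0}

SPECTRALON_REFLECTANCE = 99.0  # percent, flat 400–1500 nm


@dataclass(frozen=True)
class LeafModelParams:
    """Biophysical inputs of the leaf model.

    Only chlorophyll content (``cab``) drives the simplified model; the
    remaining traits are carried for provenance and a realistic record
    of what a full radiative-transfer run would consume.
    """

    cab: float = 30.0  # chlorophyll a+b, µg cm^-2
    structure_n: float = 1.2
    carotenoid: float = 10.0  # µg cm^-2
    brown: float = 1.0
    ewt: float = 0.015  # equivalent water thickness, cm
    lma: float = 0.009  # leaf mass per area, g cm^-2

    def __post_init__(self):
        if self.cab < 0 or any(
            v < 0 for v in (self.structure_n, self.carotenoid, self.brown, self.ewt, self.lma)
        ):
            raise InvalidInputError("leaf model parameters must be >= 0")


def absorption_coefficient(wavelength) -> np.ndarray:
    """Chlorophyll absorption kernel k(λ), Gaussian around 680 nm."""
    lam = np.asarray(wavelength, dtype=float)
    return ABSORB_K0 * np.exp(-(((lam - ABSORB_PEAK_NM) / ABSORB_WIDTH_NM) ** 2))


def leaf_reflectance(cab: float, wavelength) -> np.ndarray | float:
    """Leaf reflectance (%) at ``wavelength`` nm for chlorophyll ``cab``.

    Visible region (λ <= 700): R = 2 + 48·exp(−k(λ)·cab), strictly
    decreasing in cab wherever k > 0.  NIR region (λ >= 720): constant
    47 % plateau.  The two regimes are blended linearly on (700, 720).
    """
    if cab < 0:
        raise InvalidInputError("cab must be >= 0")
    lam = np.asarray(wavelength, dtype=float)
    if lam.min() < 400.0 or lam.max() > 900.0:
        raise InvalidInputError("wavelength outside the model domain [400, 900] nm")
    red_part = LEAF_BASELINE + LEAF_AMPLITUDE * np.exp(-absorption_coefficient(lam) * cab)
    red_at_700 = LEAF_BASELINE + LEAF_AMPLITUDE * np.exp(
        -absorption_coefficient(BLEND_LO) * cab
    )
    w = np.clip((lam - BLEND_LO) / (BLEND_HI - BLEND_LO), 0.0, 1.0)
    out = np.where(lam <= BLEND_LO, red_part, (1.0 - w) * red_at_700 + w * NIR_PLATEAU)
    return float(out) if np.isscalar(wavelength) else out


def leaf_spectrum(cab: float, grid=STANDARD_GRID, name: str | None = None) -> SpectralCurve:
    """Full leaf reflectance curve on a wavelength grid."""
    grid = np.asarray(grid, dtype=float)
    return SpectralCurve(grid, leaf_reflectance(cab, grid), name or f"leaf_cab{cab:g}")


@dataclass(frozen=True)
class Region:
    """One rectangular scene region: a panel patch or a leaf."""

    rect: Rect
    kind: str  # "panel" | "leaf"
    value: float  # panel material index, or chlorophyll content

    def __post_init__(self):
        if self.kind not in ("panel", "leaf"):
            raise InvalidInputError(f"unknown region kind {self.kind!r}")


@dataclass
class SceneSpec:
    """Declarative description of a synthetic scene."""

    size: tuple[int, int]  # (rows, cols)
    regions: list[Region] = field(default_factory=list)
    illumination: float = REFERENCE_IRRADIANCE  # µmol m^-2 s^-1
    shift: tuple[float, float] = (0.0, 0.0)  # (dx cols, dy rows) of the NIR frame
    leak_fraction: float = 0.10
    gamma: float = DEFAULT_FIXED_GAMMA
    noise_sd: float = 1.5  # DN
    seed: int = 0
    background: tuple[float, float] = (18.0, 18.0)  # red %, nir %

    def __post_init__(self):
        h, w = self.size
        if not 0.0 <= self.leak_fraction <= 0.2:
            raise SceneSpecError("leak fraction must lie in [0, 0.2]")
        if not 1.0 <= self.gamma <= 4.0:
            raise SceneSpecError("gamma must lie in [1, 4]")
        occupancy = np.zeros((h, w), dtype=bool)
        for reg in self.regions:
            r = reg.rect
            if r.row0 < 0 or r.col0 < 0 or r.row0 + r.height > h or r.col0 + r.width > w:
                raise SceneSpecError(f"region {reg} outside the {h}x{w} scene")
            sl = r.slices()
            if occupancy[sl].any():
                raise SceneSpecError(f"region {reg} overlaps a previous region")
            occupancy[sl] = True


@dataclass
class SceneTruth:
    """Ground truth of a rendered scene (pre-leak reflectance maps)."""

    red_reflectance: np.ndarray  # percent
    nir_reflectance: np.ndarray  # percent
    cab_map: np.ndarray  # µg cm^-2, NaN outside leaves
    shift: tuple[float, float]
    leak_fraction: float
    seed: int

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "red_reflectance": self.red_reflectance.tolist(),
                    "nir_reflectance": self.nir_reflectance.tolist(),
                    "cab_map": np.where(np.isnan(self.cab_map), None, self.cab_map).tolist(),
                    "shift": list(self.shift),
                    "leak_fraction": self.leak_fraction,
                    "seed": self.seed,
                }
            )
        )

    @classmethod
    def from_json(cls, path) -> "SceneTruth":
        d = json.loads(Path(path).read_text())
        cab = np.array(
            [[np.nan if v is None else v for v in row] for row in d["cab_map"]], dtype=float
        )
        return cls(
            red_reflectance=np.asarray(d["red_reflectance"], dtype=float),
            nir_reflectance=np.asarray(d["nir_reflectance"], dtype=float),
            cab_map=cab,
            shift=tuple(d["shift"]),
            leak_fraction=float(d["leak_fraction"]),
            seed=int(d["seed"]),
        )


def _truth_maps(spec: SceneSpec, panel: ReferencePanel):
    h, w = spec.size
    red = np.full((h, w), spec.background[0], dtype=float)
    nir = np.full((h, w), spec.background[1], dtype=float)
    cab = np.full((h, w), np.nan)
    red_known = panel.reflectances("red")
    nir_known = panel.reflectances("nir")
    for reg in spec.regions:
        sl = reg.rect.slices()
        if reg.kind == "panel":
            idx = int(reg.value)
            red[sl] = red_known[idx]
            nir[sl] = nir_known[idx]
        else:
            red[sl] = leaf_reflectance(reg.value, 620.0)
            nir[sl] = leaf_reflectance(reg.value, 750.0)
            cab[sl] = reg.value
    return red, nir, cab


def _camera_dn(
    reflectance_pct: np.ndarray,
    gain: float,
    gamma: float,
    noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    signal = np.clip(gain * reflectance_pct / 100.0, 0.0, None)
    dn = 255.0 * np.power(signal, 1.0 / gamma)
    if noise_sd > 0:
        dn = dn + rng.normal(0.0, noise_sd, size=dn.shape)
    return np.clip(np.floor(dn + 0.5), 0, 255).astype(np.uint8)


def _warp(field_map: np.ndarray, dx: float, dy: float) -> np.ndarray:
    """Translate content by (+dx, +dy) with bilinear sampling, edge padded."""
    if dx == 0.0 and dy == 0.0:
        return field_map.copy()
    h, w = field_map.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    return ndimage.map_coordinates(
        field_map, np.stack([yy - dy, xx - dx]), order=1, mode="nearest"
    )


def camera_gain(camera: CameraConfig, role: str, illumination: float) -> float:
    """Shutter- and illumination-proportional linear gain (1 at nominal)."""
    return (camera.shutter_speed / NOMINAL_SHUTTER[role]) * (
        illumination / REFERENCE_IRRADIANCE
    )


def render_scene(
    spec: SceneSpec,
    cameras: tuple[CameraConfig, CameraConfig] = (RED_CAMERA, NIR_CAMERA),
    panel: ReferencePanel | None = None,
) -> tuple[DigitalImage, DigitalImage, SceneTruth]:
    """Render the red-camera and NIR-camera frames of a scene.

    The red camera images the red-band reflectance directly.  The NIR
    camera sees the NIR reflectance contaminated by ``leak_fraction`` of
    the red signal, and its whole frame is translated by the
    inter-camera shift before gamma encoding.  Rendering is fully
    deterministic given ``spec.seed``.
    """
    if panel is None:
        panel = default_panel()
    red_cam, nir_cam = cameras
    rng = np.random.default_rng(spec.seed)
    red_map, nir_map, cab_map = _truth_maps(spec, panel)

    g_red = camera_gain(red_cam, "red-cam", spec.illumination)
    g_nir = camera_gain(nir_cam, "nir-cam", spec.illumination)

    red_dn = _camera_dn(red_map, g_red, spec.gamma, spec.noise_sd, rng)

    contaminated = nir_map + spec.leak_fraction * red_map
    dx, dy = spec.shift
    nir_seen = _warp(contaminated, dx, dy)
    nir_dn = _camera_dn(nir_seen, g_nir, spec.gamma, spec.noise_sd, rng)

    red_img = DigitalImage(red_dn, ("red",), "red-cam", red_cam)
    nir_img = DigitalImage(nir_dn, ("red",), "nir-cam", nir_cam)
    truth = SceneTruth(
        red_reflectance=red_map,
        nir_reflectance=nir_map,
        cab_map=cab_map,
        shift=spec.shift,
        leak_fraction=spec.leak_fraction,
        seed=spec.seed,
    )
    return red_img, nir_img, truth


def simulate_spectrometer(targets, grid=STANDARD_GRID) -> list[SpectralCurve]:
    """Idealized spectrometer: reflectance curves for a list of targets.

    Each target is ``("leaf", cab)`` or ``("spectralon", None)``.  The
    instrument references every measurement to a 99 % diffuse standard,
    so the standard itself reads 99 % at every wavelength and leaf
    curves are returned on an absolute percent-reflectance scale.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.min() < 400.0 or grid.max() > 900.0:
        raise InvalidInputError("grid outside the leaf model domain [400, 900] nm")
    curves = []
    for kind, value in targets:
        if kind == "spectralon":
            curves.append(SpectralCurve.flat(SPECTRALON_REFLECTANCE, grid, "spectralon"))
        elif kind == "leaf":
            curves.append(leaf_spectrum(float(value), grid))
        else:
            raise InvalidInputError(f"unknown spectrometer target {kind!r}")
    return curves


def panel_layout(
    patch: int = 24, margin: int = 4, origin: tuple[int, int] = (4, 4)
) -> list[Rect]:
    """Six panel-patch ROIs laid out in a 2x3 grid."""
    r0, c0 = origin
    rois = []
    for i in range(6):
        row = r0 + (i // 3) * (patch + margin)
        col = c0 + (i % 3) * (patch + margin)
        rois.append(Rect(row, col, patch, patch))
    return rois


def standard_scene(
    leaf_cabs=(),
    patch: int = 24,
    margin: int = 4,
    seed: int = 0,
    **spec_kwargs,
) -> tuple[SceneSpec, ReferencePanel, list[Rect]]:
    """A board-plus-leaves scene: the six panel patches in two rows, then
    leaf patches tiled below, sized to fit.

    Returns the scene spec, the default panel with its in-scene ROIs and
    the leaf ROIs (in rendering order of ``leaf_cabs``).
    """
    rois = panel_layout(patch, margin)
    regions = [Region(roi, "panel", i) for i, roi in enumerate(rois)]
    leaf_rois: list[Rect] = []
    per_row = 3
    base_row = rois[-1].row0 + patch + 2 * margin
    for j, cab in enumerate(leaf_cabs):
        row = base_row + (j // per_row) * (patch + margin)
        col = 4 + (j % per_row) * (patch + margin)
        rect = Rect(row, col, patch, patch)
        leaf_rois.append(rect)
        regions.append(Region(rect, "leaf", float(cab)))
    n_leaf_rows = -(-len(leaf_rois) // per_row) if leaf_rois else 0
    height = base_row + n_leaf_rows * (patch + margin) + margin
    width = 4 + 3 * (patch + margin) + margin
    spec = SceneSpec(size=(height, width), regions=regions, seed=seed, **spec_kwargs)
    return spec, default_panel(rois), leaf_rois
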