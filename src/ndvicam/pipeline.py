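"""Top-level pipeline: captured frames in, NDVI image and statistics out.

Stage order mirrors the capture workflow: extract panel means on both
frames, fit one calibration per camera, convert both frames to
reflectance, remove the red leak from the NIR band, register the NIR
image onto the red image, compute NDVI, encode and save, then summarize
the requested regions.  Any stage failure aborts the run with an error
naming the stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as ndvio
from .calibration import (
    CalibrationModel,
    Rect,
    ReferencePanel,
    apply_calibration,
    default_panel,
    extract_panel_means,
    fit_calibration,
)
from .correction import (
    LeakModel,
    apply_shift,
    contaminated_nir_targets,
    correct_nir_leak,
    estimate_leak_fraction,
    estimate_shift,
)
from .errors import ConfigError, PipelineStageError
from .ndvi import build_ndvi_image, region_stats
from .radiometry import DEFAULT_ENCODING, NIR_750, RED_620, decode_ndvi
from .spectral import SpectralCurve

log = logging.getLogger("ndvicam")


def _rect(seq) -> Rect:
    return Rect(*(int(v) for v in seq))


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    red_image: Path
    nir_image: Path
    output_dir: Path
    panel_rois: list[Rect]
    nir_panel_rois: list[Rect] | None = None
    panel_csv: Path | None = None
    analysis_rois: dict[str, Rect] = field(default_factory=dict)
    calibration_mode: str = "six-reference"
    fixed_gamma: float | None = None
    leak_fraction: float | None = None
    filter_transmission_csv: Path | None = None
    search_radius: int = 10
    red_model_json: Path | None = None
    nir_model_json: Path | None = None
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, d: dict, base: Path | None = None) -> "RunConfig":
        base = Path(base) if base else Path(".")

        def p(key, required=False):
            v = d.get(key)
            if v is None:
                if required:
                    raise ConfigError(f"config missing required path {key!r}")
                return None
            return base / v

        if "panel_rois" not in d or not d["panel_rois"]:
            raise ConfigError("config missing panel ROIs")
        return cls(
            red_image=p("red_image", required=True),
            nir_image=p("nir_image", required=True),
            output_dir=p("output_dir", required=True),
            panel_rois=[_rect(r) for r in d["panel_rois"]],
            nir_panel_rois=[_rect(r) for r in d["nir_panel_rois"]]
            if d.get("nir_panel_rois")
            else None,
            panel_csv=p("panel_csv"),
            analysis_rois={k: _rect(v) for k, v in d.get("analysis_rois", {}).items()},
            calibration_mode=d.get("calibration_mode", "six-reference"),
            fixed_gamma=d.get("fixed_gamma"),
            leak_fraction=d.get("leak_fraction"),
            filter_transmission_csv=p("filter_transmission_csv"),
            search_radius=int(d.get("search_radius", 10)),
            red_model_json=p("red_model_json"),
            nir_model_json=p("nir_model_json"),
            seed=int(d.get("seed", 0)),
            log_level=d.get("log_level", "INFO"),
        )

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        d = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
        return cls.from_dict(d, base=path.parent)

    def validate(self) -> None:
        for pth in (self.red_image, self.nir_image):
            if not Path(pth).exists():
                raise ConfigError(f"input image {pth} does not exist")
        if self.leak_fraction is None and self.filter_transmission_csv is None:
            raise ConfigError("provide leak_fraction or filter_transmission_csv")
        if self.leak_fraction is not None and not 0.0 <= self.leak_fraction < 1.0:
            raise ConfigError("leak_fraction must lie in [0, 1)")


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as exc:
                raise PipelineStageError(name, exc) from exc

        return wrapper

    return deco


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; returns a machine-readable summary.

    Outputs written to ``config.output_dir``: ``ndvi.png`` (+ sidecar,
    + mask), per-camera calibration model JSON, ``stats.csv`` and
    ``summary.json``.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    @_stage("load-images")
    def load():
        red = ndvio.read_image(config.red_image, camera_role="red-cam")
        nir = ndvio.read_image(config.nir_image, camera_role="nir-cam")
        if red.camera_role != "red-cam" or nir.camera_role != "nir-cam":
            raise ConfigError("camera roles are swapped or missing")
        return red, nir

    red_img, nir_img = load()
    log.info("loaded %s %s and %s %s", config.red_image, red_img.shape,
             config.nir_image, nir_img.shape)

    panel = (
        ReferencePanel.from_csv(config.panel_csv) if config.panel_csv else default_panel()
    )
    red_panel = panel.with_rois(config.panel_rois)
    nir_panel = panel.with_rois(config.nir_panel_rois or config.panel_rois)

    @_stage("extract-panel-means")
    def panel_means():
        m_red = extract_panel_means(red_img, red_panel, "red")
        m_nir = extract_panel_means(nir_img, nir_panel, "red")
        return m_red, m_nir

    means_red, means_nir = panel_means()
    log.info("panel means red=%s nir=%s", means_red.round(1), means_nir.round(1))

    @_stage("leak-model")
    def leak_model_stage():
        if config.leak_fraction is not None:
            return LeakModel(config.leak_fraction)
        curve = SpectralCurve.from_csv(config.filter_transmission_csv)
        return estimate_leak_fraction(curve, RED_620, NIR_750)

    leak_model = leak_model_stage()
    log.info("leak fraction f=%.4f", leak_model.fraction)

    @_stage("fit-calibration")
    def fit():
        if config.red_model_json and config.nir_model_json:
            return (
                CalibrationModel.from_json(config.red_model_json),
                CalibrationModel.from_json(config.nir_model_json),
            )
        kw = dict(mode=config.calibration_mode, fixed_gamma=config.fixed_gamma)
        # The NIR camera sees the panel through the leaky filter, so its
        # calibration targets are the leak-adjusted panel reflectances.
        nir_targets = contaminated_nir_targets(nir_panel, leak_model)
        return (
            fit_calibration(means_red, red_panel.reflectances("red"), **kw),
            fit_calibration(means_nir, nir_targets, **kw),
        )

    model_red, model_nir = fit()
    model_red.to_json(out / "model_red.json")
    model_nir.to_json(out / "model_nir.json")
    log.info("calibration red: gamma=%.4f rmse=%.3f%%; nir: gamma=%.4f rmse=%.3f%%",
             model_red.gamma, model_red.rmse, model_nir.gamma, model_nir.rmse)

    @_stage("apply-calibration")
    def calibrate():
        r = apply_calibration(red_img, model_red, "red", RED_620)
        n = apply_calibration(nir_img, model_nir, "red", NIR_750)
        return r, n

    red_refl, nir_refl = calibrate()

    @_stage("leak-correction")
    def leak():
        return correct_nir_leak(nir_refl, red_refl, leak_model)

    nir_corr = leak()

    @_stage("align")
    def align():
        shift = estimate_shift(red_refl, nir_corr, config.search_radius)
        return shift, apply_shift(nir_corr, shift.negated())

    shift, nir_aligned = align()
    log.info("estimated shift dx=%.2f dy=%.2f score=%.3f", shift.dx, shift.dy, shift.score)

    @_stage("ndvi")
    def ndvi():
        enc = build_ndvi_image(red_refl, nir_aligned, DEFAULT_ENCODING)
        ndvio.write_image(enc, out / "ndvi.png")
        return enc

    enc = ndvi()

    @_stage("region-stats")
    def stats():
        decoded = decode_ndvi(enc.codes.astype(float))
        rows = []
        for name, roi in config.analysis_rois.items():
            grid = decoded.copy()
            grid[~enc.mask] = float("nan")
            s = region_stats(grid, roi)
            rows.append(
                {"image": "ndvi.png", "roi": name, "n": s.n, "mean": s.mean,
                 "sd": s.sd, "cov": s.cov, "skewness": s.skewness}
            )
        df = pd.DataFrame(rows)
        df.to_csv(out / "stats.csv", index=False)
        return rows

    stat_rows = stats()

    summary = {
        "red_image": str(config.red_image),
        "nir_image": str(config.nir_image),
        "panel_means_red": means_red.tolist(),
        "panel_means_nir": means_nir.tolist(),
        "model_red": {"a": model_red.a, "b": model_red.b, "gamma": model_red.gamma,
                      "rmse": model_red.rmse},
        "model_nir": {"a": model_nir.a, "b": model_nir.b, "gamma": model_nir.gamma,
                      "rmse": model_nir.rmse},
        "leak_fraction": leak_model.fraction,
        "shift": {"dx": shift.dx, "dy": shift.dy, "score": shift.score},
        "regions": stat_rows,
        "seed": config.seed,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary
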