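import numpy as np
import pytest

import ndvicam as nc
from ndvicam.correction import contaminated_nir_targets

#: Shutter speeds at which the simulated cameras run at unit gain.
UNIT_GAIN_RED = nc.CameraConfig(iso=400, shutter_speed=500)
UNIT_GAIN_NIR = nc.CameraConfig(iso=400, shutter_speed=3125)

TRUE_LEAK = 0.10
TRUE_SHIFT = (2.0, -1.5)
LEAF_CABS = (5.0, 15.0, 25.0, 35.0, 45.0, 60.0)


@pytest.fixture(scope="session")
def panel():
    return nc.default_panel()


@pytest.fixture(scope="session")
def noiseless_scene():
    """A rendered noiseless board-plus-leaves scene with known truth."""
    spec, panel, leaf_rois = nc.standard_scene(
        LEAF_CABS, noise_sd=0.0, leak_fraction=TRUE_LEAK, shift=TRUE_SHIFT, seed=3
    )
    red, nir, truth = nc.render_scene(spec, panel=panel)
    return {
        "spec": spec,
        "panel": panel,
        "leaf_rois": leaf_rois,
        "red": red,
        "nir": nir,
        "truth": truth,
    }


def run_reflectance_pipeline(red, nir, panel, leak_fraction, search_radius=8):
    """Calibrate, leak-correct and align a rendered scene in memory.

    Returns (red_reflectance, aligned_nir_reflectance, shift).
    """
    import warnings

    leak = nc.LeakModel(leak_fraction)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        m_red = nc.extract_panel_means(red, panel, "red")
        m_nir = nc.extract_panel_means(nir, panel, "red")
    model_red = nc.fit_calibration(m_red, panel.reflectances("red"))
    model_nir = nc.fit_calibration(m_nir, contaminated_nir_targets(panel, leak))
    red_refl = nc.apply_calibration(red, model_red, "red", nc.RED_620)
    nir_refl = nc.apply_calibration(nir, model_nir, "red", nc.NIR_750)
    nir_corr = nc.correct_nir_leak(nir_refl, red_refl, leak)
    shift = nc.estimate_shift(red_refl, nir_corr, search_radius)
    nir_aligned = nc.apply_shift(nir_corr, shift.negated())
    return red_refl, nir_aligned, shift


def leaf_camera_ndvi(red_refl, nir_aligned, leaf_rois):
    """Per-leaf mean camera NDVI from calibrated, aligned reflectance."""
    enc = nc.build_ndvi_image(red_refl, nir_aligned)
    decoded = nc.decode_ndvi(enc.codes.astype(float))
    decoded[~enc.mask] = np.nan
    return [nc.region_stats(decoded, roi.eroded(0.2)).mean for roi in leaf_rois]


def true_leaf_ndvi(cab):
    return nc.ndvi_value(nc.leaf_reflectance(cab, 750.0), nc.leaf_reflectance(cab, 620.0))
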