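"""Shared fixtures: one rendered ground-truth scene and its pipeline products."""

import warnings

import numpy as np
import pytest

import echoprey as ep


@pytest.fixture(scope="session")
def gt_scene():
    """Ground-truth scene: three planted schools over a 25 m seabed."""
    return ep.SyntheticScene(
        schools=[
            ep.TrueSchool(center_ping=100, center_depth_m=8.0,
                          length_m=20.0, thickness_m=3.0),
            ep.TrueSchool(center_ping=300, center_depth_m=12.0,
                          length_m=10.0, thickness_m=4.0,
                          core_intensity_db=-18.0),
            ep.TrueSchool(center_ping=480, center_depth_m=6.0,
                          length_m=8.0, thickness_m=2.0,
                          core_intensity_db=-26.0),
        ],
        n_pings=600,
        seabed_depth_m=25.0,
        rng_seed=42,
    )


@pytest.fixture(scope="session")
def gt_pipeline(gt_scene):
    """Scene rendered and run through calibration and preprocessing."""
    records, truth = ep.render_echogram(gt_scene)
    echo = ep.pings_to_echogram(records)
    fit = ep.TVGFit(gt_scene.tvg_exponent_true,
                    gt_scene.absorption_true_db_per_m)
    corrected = ep.apply_tvg(echo, fit)
    bottom = ep.detect_bottom(corrected)
    domain = ep.build_analysis_domain(corrected, bottom)
    cleaned = ep.remove_background_noise(corrected, fit)
    return {
        "scene": gt_scene, "records": records, "truth": truth,
        "echogram": echo, "fit": fit, "corrected": corrected,
        "bottom": bottom, "domain": domain, "cleaned": cleaned,
    }


@pytest.fixture(scope="session")
def gt_schools(gt_pipeline):
    schools, n_discarded = ep.detect_schools(
        gt_pipeline["cleaned"], gt_pipeline["domain"],
        ep.SHAPES_PRESETS["ground_truth"])
    return schools, n_discarded


@pytest.fixture(scope="session")
def sphere_drop():
    """A noiseless 300-region sphere drop with the study's 10log truth."""
    depths = np.linspace(3.5, 34.5, 300)
    records, annotations = ep.make_sphere_drop(
        depths, tvg_exponent_true=10.0, absorption_true_db_per_m=0.05,
        noise_sd_db=0.0, seed=11)
    echo = ep.pings_to_echogram(records)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        regions = ep.extract_sphere_regions(echo, annotations)
    return {"depths": depths, "records": records,
            "annotations": annotations, "echogram": echo,
            "regions": regions}
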