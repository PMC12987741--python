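"""Shared fixtures: simulated subjects reused across test modules."""

import numpy as np
import pytest
from hypothesis import settings

import fpetconn as fp
from fpetconn.simulate import random_loading

settings.register_profile("ci", derandomize=True, max_examples=30, deadline=None)
settings.load_profile("ci")

MID_BAND = fp.FrequencyBand(0.01, 0.1)
EXCLUDE_S = 600.0


@pytest.fixture(scope="session")
def default_subject():
    """Default high-sensitivity subject: 24x24x16 grid, 1500 frames of 1 s."""
    return fp.simulate_subject(fp.SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def dual_band_subject():
    """Two networks at 0.005 Hz and 0.05 Hz with independent loadings."""
    rng = np.random.default_rng(7)
    l_slow = random_loading(20, 3, rng)
    l_mid = random_loading(20, 3, rng)
    nets = [
        fp.NetworkSpec(fp.FrequencyBand(0.001, 0.01), l_slow, 1.0),
        fp.NetworkSpec(fp.FrequencyBand(0.04, 0.06), l_mid, 1.0),
    ]
    return fp.simulate_subject(fp.SimulationConfig(seed=3, networks=nets))


def run_compcor_pipeline(subject, band=MID_BAND, t_min=EXCLUDE_S):
    """Window exclusion -> unified design -> voxelwise regression -> regions."""
    keep = subject.series.frame_onsets >= t_min
    series = fp.exclude_uptake_window(subject.series, t_min)
    motion = fp.MotionTrace(subject.motion.params[keep],
                            subject.series.frame_duration)
    design = fp.build_compcor_design(
        series, subject.tissue_maps["WM"], subject.tissue_maps["CSF"],
        motion, band)
    gm_mask = subject.tissue_maps["GM"].prob >= 0.5
    cleaned = fp.compcor_residualize(series, design, mask=gm_mask)
    regions = fp.extract_regional_timeseries(cleaned, subject.parcels)
    return {
        "series": series,
        "motion": motion,
        "design": design,
        "gm_mask": gm_mask,
        "cleaned": cleaned,
        "regions": regions,
        "matrix": fp.pearson_connectivity(regions, band=band),
        "uptake": subject.truth.uptake[keep],
    }


@pytest.fixture(scope="session")
def default_pipeline(default_subject):
    return run_compcor_pipeline(default_subject)


@pytest.fixture(scope="session")
def dual_band_pipeline(dual_band_subject):
    return run_compcor_pipeline(dual_band_subject)
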