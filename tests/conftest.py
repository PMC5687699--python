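"""Shared fixtures: synthetic pipelines reused across test modules."""

import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

import pulsewave as pw
from pulsewave.bandmap import band_roi_mask


def run_band_pipeline(seed=0, gradient=0.0, f_hint=None, **cine_kwargs):
    """Full cine -> tracking -> angiography -> band series pipeline."""
    cine, truth = pw.generate_cine(ventral_dorsal_gradient=gradient, seed=seed,
                                   **cine_kwargs)
    pm = pw.project_principal(pw.track_region(cine, truth.motion_roi))
    contour = pw.segment_contour(truth.contour)
    band = pw.build_band(contour, float(np.mean(contour.segment_lengths)))
    roi = band_roi_mask(band, cine.shape[:2])
    field = pw.cf_angiogram(cine, motion=pm, roi_mask=roi, f_hint=f_hint)
    series = pw.band_signal(field, band)
    return {"cine": cine, "truth": truth, "band": band, "field": field,
            "series": series, "motion": pm}


@pytest.fixture(scope="session")
def pipeline_factory():
    return run_band_pipeline


@pytest.fixture(scope="session")
def gradient_run():
    """Pipeline on a cine with an injected ventral-dorsal gradient of 0.7 rad."""
    return run_band_pipeline(seed=1, gradient=0.7)


@pytest.fixture(scope="session")
def av_run():
    """Pipeline on a default cine (arterial +0.5 / venous -0.5, no gradient)."""
    return run_band_pipeline(seed=2)


@pytest.fixture(scope="session")
def quiet_run():
    """Noise-free pipeline for exactness checks."""
    return run_band_pipeline(seed=3, gradient=0.7, noise_sd=0.0)
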