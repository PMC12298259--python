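import numpy as np
import pytest

from qams import (
    DilutionDesign,
    default_detector_models,
    fit_linear,
    fit_loglog,
    make_dilution_series,
    simulate_calibration,
)
from qams.calibration import CalibrationPoint
from qams.reference import C1_MG_PER_ML


@pytest.fixture(scope="session")
def dilution_design():
    return DilutionDesign(c1_by_compound=dict(C1_MG_PER_ML))


@pytest.fixture(scope="session")
def noise_free_models():
    return default_detector_models(rel_noise=0.0)


@pytest.fixture(scope="session")
def noise_free_series(dilution_design, noise_free_models):
    """Noise-free calibration series per (detector, compound), built from the
    published regression parameters at the six-level dilution design."""
    out = {}
    for detector, models in noise_free_models.items():
        for compound, model in models.items():
            conc = make_dilution_series(dilution_design, compound)
            out[(detector, compound)] = simulate_calibration(
                conc, model, seed=0, compound=compound
            )
    return out


@pytest.fixture(scope="session")
def noise_free_fits(noise_free_series):
    """Calibration fits on the noise-free series; these recover the published
    slopes/intercepts exactly."""
    fits = {}
    for (detector, compound), series in noise_free_series.items():
        points = [
            CalibrationPoint(concentration=c, peak_area=a)
            for c, a in zip(series.conc_mg_per_ml, series.peak_area)
        ]
        fitter = fit_linear if detector == "PDA" else fit_loglog
        fits[(detector, compound)] = fitter(points, compound=compound, detector=detector)
    return fits
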