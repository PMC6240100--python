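import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from phospholfq.design import StudyDesign, TruthParams
from phospholfq.simulate import generate_study

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_study():
    """Desk-scale study: 2 genotypes x 1 treatment x 2 bio x 2 tech, 30 peptides."""
    design = StudyDesign(
        treatments=("vehicle_24h",),
        n_biological=2,
        gradient_minutes=5.0,
    )
    truth = TruthParams(n_peptides=30, frac_regulated=0.2)
    runs, ids, gt = generate_study(design, truth, seed=42)
    return design, truth, runs, ids, gt


@pytest.fixture(scope="session")
def noiseless_study():
    """No dropout, no background, no technical noise: truth exactly visible."""
    design = StudyDesign(
        treatments=("vehicle_24h",),
        n_biological=2,
        gradient_minutes=5.0,
    )
    truth = TruthParams(
        n_peptides=20,
        frac_regulated=0.0,
        biological_cv=0.0,
        technical_cv=0.0,
        dropout_prob=0.0,
        mz_error_ppm_sd=0.0,
        rt_jitter_min_sd=0.0,
        background_peaks_per_scan=0.0,
    )
    runs, ids, gt = generate_study(design, truth, seed=7)
    return design, truth, runs, ids, gt
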