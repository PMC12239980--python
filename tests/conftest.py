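import numpy as np
import pytest

from correaevo.simulate import SimConfig, simulate_cohort
from correaevo.variant_model import apply_filter_cascade, LesionSample, Patient


@pytest.fixture(scope="session")
def small_cohort():
    """A 6-patient mixed-trajectory cohort with truth, filtered calls."""
    cfg = SimConfig(n_patients=6, trajectory_mix=(3, 2, 1),
                    n_variants_mean=120.0, seed=42)
    cohort, truth = simulate_cohort(cfg)
    filtered = []
    for patient in cohort:
        samples = {}
        for stage, sample in patient.samples.items():
            kept, _ = apply_filter_cascade(sample.variants)
            samples[stage] = LesionSample(
                patient_id=patient.patient_id, stage=stage, variants=kept,
                cnv_events=sample.cnv_events,
                depth_pre_dedup=sample.depth_pre_dedup,
                depth_post_dedup=sample.depth_post_dedup,
                oscore=sample.oscore)
        filtered.append(Patient(patient_id=patient.patient_id,
                                samples=samples))
    return filtered, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
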