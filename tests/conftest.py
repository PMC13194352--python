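import numpy as np
import pytest

from asdscreen import preprocess as pp
from asdscreen import synth


@pytest.fixture(scope="session")
def clean_beats():
    """30 artifact-free beats at 86 bpm with known fiducials (no jitter)."""
    ecg, gt = synth.generate_ecg(86, 30, 0.0, seed=1)
    pcg, gt = synth.generate_pcg(
        gt, 39.65, 96.2, 238.5, noise_snr_db=30.0, seed=2
    )
    return ecg, pcg, gt


@pytest.fixture(scope="session")
def clean_filtered(clean_beats):
    ecg, pcg, gt = clean_beats
    return pp.bandpass_ecg(ecg), pp.bandpass_pcg(pcg), gt


@pytest.fixture(scope="session")
def asd_subject():
    """Full composed subject (ASD: fixed splitting) with ground truth."""
    rec, gt = synth.generate_subject(
        "ASD",
        {"s2_split_ms": 39.65, "emat_ms": 96.2, "s1s2_ms": 238.5},
        seed=3,
    )
    return rec, gt


@pytest.fixture(scope="session")
def control_subject():
    """Control subject: respiration-modulated splitting."""
    rec, gt = synth.generate_subject(
        "control",
        {"s2_split_ms": 28.20, "emat_ms": 96.2, "s1s2_ms": 243.5},
        seed=4,
    )
    return rec, gt


@pytest.fixture(scope="session")
def reference_cohort():
    """Index-level 50/50 cohort drawn from the reference marginals."""
    spec = synth.default_cohort_spec(n_per_group=50)
    return synth.generate_cohort_indices(spec, seed=7)
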