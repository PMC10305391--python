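import numpy as np
import pytest

from ppgstress import (
    DEFAULT_STATES,
    PhysioState,
    SynthConfig,
    generate_cohort,
    generate_nni_series,
    preprocess,
    render_ppg,
)

FS = 255.0


@pytest.fixture(scope="session")
def clean_state() -> PhysioState:
    """Deterministic-modulation-only state: bounded interval distribution,
    so the z-score outlier pass flags nothing and recovery is exact."""
    return PhysioState(
        name="rest", mean_rr=850.0, rr_jitter_sd=0.0,
        resp_mod_amp=40.0, resp_mod_freq=0.25, lf_mod_amp=10.0, lf_mod_freq=0.1,
    )


@pytest.fixture(scope="session")
def clean_recording(clean_state):
    """A clean 360 s rendering with its ground truth."""
    truth = generate_nni_series(clean_state, 360.0, seed=101)
    rec = render_ppg(truth, fs=FS, duration_s=360.0)
    return rec, truth


@pytest.fixture(scope="session")
def small_cohort_nnis():
    """Preprocessed NNI series of a reduced cohort (4 subjects x 3 states,
    240 s recordings) shared by the dataset/modelling tests."""
    cfg = SynthConfig(n_subjects=4, duration_s=240.0, seed=5)
    cohort = generate_cohort(cfg)
    return {f"{rec.subject_id}_{rec.state}": preprocess(rec) for rec, _ in cohort}


def random_nni_batches(n_series: int, seed: int, min_len: int = 4, max_len: int = 120):
    """Random NNI arrays (ms) for oracle-equivalence sweeps."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_series):
        n = int(rng.integers(min_len, max_len))
        out.append(rng.uniform(300.0, 1300.0, size=n))
    return out
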