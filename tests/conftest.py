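import numpy as np
import pytest

from habitat_tex import pipeline, synth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_cohort():
    """A small default-scenario cohort shared across tests (read-only)."""
    studies, truth = synth.generate_cohort(6, 6, "default", seed=99)
    return studies, truth


@pytest.fixture(scope="session")
def small_feature_table(small_cohort):
    studies, truth = small_cohort
    cfg = pipeline.PipelineConfig()
    table, excluded = pipeline.build_feature_table(studies, truth, cfg)
    return table, excluded


@pytest.fixture(scope="session")
def noiseless_study():
    """One lesion with noise-free kinetics and known per-pixel TTP."""
    r = np.random.default_rng(7)
    kin = synth.KineticParams(
        ttp_mixture=(0.15, 0.15, 0.1, 0.1, 0.15, 0.15, 0.1, 0.1),
        peak_enhancement_range=(1.0, 1.5),
        washout_rate=0.2,
        noise_sd=0.0,
    )
    mask = synth.generate_lesion(r, (64, 64))
    ttp = synth.assign_ttp(mask, kin.ttp_mixture, r)
    study = synth.generate_study(mask, ttp, kin, seed=r)
    return study, mask, ttp
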