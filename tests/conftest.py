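import numpy as np
import pandas as pd
import pytest

import valnorm as vn


@pytest.fixture(scope="session")
def study1_session():
    return vn.generate_session(1, "dual", seed=11)


@pytest.fixture(scope="session")
def clean_truth():
    """Noise-free ground truth with on-grid HRF peak: the exact-recovery regime."""
    return vn.default_ground_truth(
        "full",
        seed=5,
        noise_sd=0.0,
        beta_noise_sd=0.0,
        drift_amplitude=0.0,
        param_cv=0.0,
        miss_prob=0.0,
        hrf_peak_range_s=(5.5, 5.5),
    )


@pytest.fixture(scope="session")
def default_truth():
    return vn.default_ground_truth("full", seed=5)


@pytest.fixture(scope="session")
def clean_recording(study1_session, clean_truth):
    beh = vn.simulate_behavior(study1_session, clean_truth)
    rec = vn.simulate_recording(study1_session, beh, clean_truth, n_channels=2)
    return rec


@pytest.fixture(scope="session")
def two_group_amplitudes(default_truth):
    """Beta-stage mechanism cohort: 20 dual + 20 single participants,
    21 safe levels per context, beta differing between experiments only."""
    rng = np.random.default_rng(77)
    dual = vn.simulate_cohort_amplitudes(
        20, default_truth, "dual", "none", n_levels=21, seed=rng
    )
    single = vn.simulate_cohort_amplitudes(
        20, default_truth, "single", "none", n_levels=21, seed=rng
    )
    single["participant"] += 100
    dual["participant"] = "d" + dual["participant"].astype(str)
    single["participant"] = "s" + single["participant"].astype(str)
    return pd.concat([dual, single], ignore_index=True)


@pytest.fixture(scope="session")
def two_group_params(two_group_amplitudes):
    """Per participant x context full-model fits on the mechanism cohort."""
    from valnorm.group_stats import fit_participant_params

    return fit_participant_params(
        two_group_amplitudes, by=("participant", "context")
    )
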