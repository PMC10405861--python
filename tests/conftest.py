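import numpy as np
import pandas as pd
import pytest

from serialdep import (
    estimate_bias,
    model_free_bias,
    sample_phenotype,
    simulate_cohort,
)
from serialdep.pipeline import preprocess_tables

RECOVERY_SEED = 123
RECOVERY_N_SUBJECTS = 40


@pytest.fixture(scope="session")
def recovery_cohort():
    """40 simulated observers on the predictable-task design, analysed with
    the subject-level pipeline: generative truth vs fitted amplitudes.

    The recovery experiment isolates estimator error: no lapses and no
    between-session drift, response noise at the realistic 11-degree level,
    amplitudes uniform over the observed single-subject range.
    """
    def sampler(rng):
        return sample_phenotype(rng, lapse_rate=0.0, session_jitter_sd=0.0)

    tables, truth = simulate_cohort(
        RECOVERY_N_SUBJECTS, sampler, seed=RECOVERY_SEED, study=1
    )
    errors, _ = preprocess_tables(tables)
    rows = []
    for subject, grp in errors.groupby("subject"):
        d = grp["prev_dist_deg"].to_numpy()
        e = grp["error_deg"].to_numpy()
        rows.append(
            {
                "subject": subject,
                "fitted_amp": estimate_bias(d, e, "subject").amplitude_deg,
                "model_free": model_free_bias(d, e, 54.0).bias_deg,
                "n_trials": len(grp),
            }
        )
    fitted = pd.DataFrame(rows).merge(truth, on="subject")
    assert len(fitted) == RECOVERY_N_SUBJECTS
    return fitted


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
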