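"""Synthetic observers: phenotype inversion and response generation."""

import numpy as np
import pandas as pd
import pytest

from serialdep.circular import circ_sd, signed_diff
from serialdep.design import generate_study1_design
from serialdep.dvm import curve_amplitude, curve_fwhm, dvm_value
from serialdep.observer import (
    ObserverPhenotype,
    phenotype_to_params,
    sample_phenotype,
    simulate_cohort,
    simulate_responses,
)


def random_walk_design(n, seed, subject="w01"):
    """Minimal single-block design: a free orientation random walk."""
    rng = np.random.default_rng(seed)
    stim = rng.uniform(0.0, 180.0, n)
    return pd.DataFrame(
        {
            "study": 1,
            "subject": subject,
            "session": 1,
            "block": 0,
            "trial": np.arange(n),
            "task": "no_rotation",
            "response_mode": "adjust",
            "bin": 0,
            "stimulus_deg": stim,
        }
    )


class TestPhenotypeInversion:
    def test_round_trip_amplitude_and_width(self):
        p = phenotype_to_params(ObserverPhenotype(amp_true=3.0, fwhm_true=35.0))
        assert curve_amplitude(p) == pytest.approx(3.0, abs=0.05)
        assert curve_fwhm(p) == pytest.approx(35.0, abs=0.05)

    def test_repulsive_round_trip(self):
        p = phenotype_to_params(ObserverPhenotype(amp_true=-2.0, fwhm_true=30.0))
        assert curve_amplitude(p) == pytest.approx(-2.0, abs=0.05)

    def test_zero_amplitude_convention(self):
        p = phenotype_to_params(ObserverPhenotype(amp_true=0.0, fwhm_true=35.0))
        assert p.a == 0.0 and p.kappa == 1.0

    def test_unattainable_width_signalled(self):
        with pytest.raises(ValueError):
            phenotype_to_params(ObserverPhenotype(amp_true=9.0, fwhm_true=70.0))

    def test_phenotype_validation(self):
        with pytest.raises(ValueError):
            ObserverPhenotype(amp_true=0.0, fwhm_true=95.0)
        with pytest.raises(ValueError):
            ObserverPhenotype(amp_true=0.0, noise_sd=-1.0)
        with pytest.raises(ValueError):
            ObserverPhenotype(amp_true=0.0, lapse_rate=1.0)


class TestSimulateResponses:
    def test_noiseless_null_observer_reproduces_stimulus(self):
        design = generate_study1_design("s", seed=1)
        phen = ObserverPhenotype(amp_true=0.0, noise_sd=0.0)
        out = simulate_responses(design, phen, seed=2)
        adj = out[out["response_mode"] == "adjust"]
        no_rot = adj[adj["task"] == "no_rotation"]
        np.testing.assert_allclose(no_rot["response_deg"], no_rot["stimulus_deg"])
        # rotation trials adjust toward the rotated target
        cw = adj[adj["task"] == "rotate_cw"]
        np.testing.assert_allclose(
            cw["response_deg"], (cw["stimulus_deg"] + 60.0) % 180.0
        )
        assert out[out["response_mode"] == "none"]["response_deg"].isna().all()

    def test_noiseless_error_equals_bias_curve(self):
        design = random_walk_design(500, seed=3)
        phen = ObserverPhenotype(amp_true=3.0, fwhm_true=35.0, noise_sd=0.0)
        out = simulate_responses(design, phen, seed=4)
        params = phenotype_to_params(phen)
        prev = out["stimulus_deg"].shift(1)
        err = signed_diff(
            out["response_deg"].to_numpy()[1:], out["stimulus_deg"].to_numpy()[1:]
        )
        dist = signed_diff(prev.to_numpy()[1:], out["stimulus_deg"].to_numpy()[1:])
        np.testing.assert_allclose(err, dvm_value(dist, params), atol=1e-9)
        # the first trial of a block carries no history bias
        assert out["response_deg"].iloc[0] == pytest.approx(
            out["stimulus_deg"].iloc[0]
        )

    def test_same_seed_identical_tables(self):
        design = generate_study1_design("s", seed=1)
        phen = ObserverPhenotype(amp_true=2.0, noise_sd=11.0, lapse_rate=0.05)
        a = simulate_responses(design, phen, seed=9)
        b = simulate_responses(design, phen, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_missing_columns_signalled(self):
        with pytest.raises(ValueError, match="missing columns"):
            simulate_responses(
                pd.DataFrame({"stimulus_deg": [1.0]}),
                ObserverPhenotype(amp_true=0.0),
                seed=1,
            )

    def test_residual_noise_sd_converges_to_generative_value(self):
        """Circular SD of simulated errors approaches noise_sd at large n."""
        design = random_walk_design(10_000, seed=5)
        phen = ObserverPhenotype(amp_true=0.0, noise_sd=11.0, lapse_rate=0.0)
        out = simulate_responses(design, phen, seed=6)
        err = signed_diff(
            out["response_deg"].to_numpy(), out["stimulus_deg"].to_numpy()
        )
        assert circ_sd(err) == pytest.approx(11.0, abs=0.5)

    def test_conditional_mean_error_converges_to_bias_curve(self):
        """Binned mean error tracks the generative curve pointwise."""
        n = 200_000
        design = random_walk_design(n, seed=7)
        phen = ObserverPhenotype(
            amp_true=4.0, fwhm_true=35.0, noise_sd=11.0, lapse_rate=0.0
        )
        out = simulate_responses(design, phen, seed=8)
        params = phenotype_to_params(phen)
        stim = out["stimulus_deg"].to_numpy()
        err = signed_diff(out["response_deg"].to_numpy()[1:], stim[1:])
        dist = signed_diff(stim[:-1], stim[1:])
        bins = np.arange(-90.0, 91.0, 10.0)
        idx = np.digitize(dist, bins[1:-1])
        for b in range(18):
            sel = idx == b
            center = bins[b] + 5.0
            assert np.mean(err[sel]) == pytest.approx(
                float(dvm_value(center, params)), abs=0.3
            ), f"bin centred at {center}"


class TestSimulateCohort:
    def test_degenerate_single_subject_matches_simulate_responses(self):
        phen = ObserverPhenotype(amp_true=2.0, fwhm_true=30.0, noise_sd=5.0)
        tables, truth = simulate_cohort(1, lambda rng: phen, seed=11, study=1)
        assert len(tables) == 1 and len(truth) == 1
        assert truth.loc[0, "amp_true"] == 2.0
        assert set(tables[0]["session"]) == {1, 2}
        assert "response_deg" in tables[0].columns

    def test_zero_jitter_shares_generative_amplitude(self):
        phen = ObserverPhenotype(
            amp_true=3.0, fwhm_true=30.0, noise_sd=5.0, session_jitter_sd=0.0
        )
        _, truth = simulate_cohort(3, lambda rng: phen, seed=12, study=1)
        assert (truth["amp_s1"] == truth["amp_s2"]).all()

    def test_jitter_perturbs_second_session_only(self):
        phen = ObserverPhenotype(
            amp_true=3.0, fwhm_true=30.0, noise_sd=5.0, session_jitter_sd=2.0
        )
        _, truth = simulate_cohort(5, lambda rng: phen, seed=13, study=1)
        assert (truth["amp_s1"] == 3.0).all()
        assert (truth["amp_s2"] != truth["amp_s1"]).all()

    def test_sampled_phenotypes_always_feasible(self, rng):
        for _ in range(50):
            phen = sample_phenotype(rng)
            phenotype_to_params(phen)  # must not raise

    def test_invalid_arguments_signalled(self):
        with pytest.raises(ValueError):
            simulate_cohort(0, lambda rng: None, seed=1)
        with pytest.raises(ValueError):
            simulate_cohort(1, lambda rng: None, seed=1, study=3)
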