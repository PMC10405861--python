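"""Simulated observers with known history-bias phenotypes.

The generative model of a response on an adjustment trial is

    response = wrap(stimulus + global_bias + dvm(prev_stim - stim) + noise)

with wrapped-normal motor/sensory noise on the doubled orientation circle
and, with probability ``lapse_rate``, a uniform-random orientation instead
(an attentional lapse).  The history bias depends only on the immediately
preceding trial's stimulus (lag 1) and is applied after every trial type;
the first trial of a block has no preceding stimulus and carries no bias.
On rotation trials the adjustment target is the stimulus rotated by +/-60
degrees; 2AFC and no-response trials receive no adjustment response.

Defaults are calibrated to the statistical structure of real adjustment
data: response-error circular SD of about 11 degrees, single-subject bias
amplitudes spanning roughly -3 to +9 degrees, and tuning widths of about
12 to 71 degrees (centred near 38), subject to the joint feasibility of
amplitude and width under the bias-curve parameter bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import design as dsg
from .circular import wrap_orientation
from .dvm import (
    DvMParams,
    dvm_value,
    max_amplitude_for_fwhm,
    max_fwhm_for_amplitude,
    params_from_amplitude_fwhm,
)

ROTATION_MAGNITUDE_DEG = 60.0

__all__ = [
    "ObserverPhenotype",
    "phenotype_to_params",
    "simulate_responses",
    "simulate_cohort",
    "sample_phenotype",
]


@dataclass(frozen=True)
class ObserverPhenotype:
    """Generative parameters of one simulated observer.

    amp_true
        Signed serial-bias amplitude in degrees (positive = attractive).
    fwhm_true
        Tuning width of the bias curve in degrees, in (0, 90).
    global_bias
        Constant directional response bias in degrees.
    noise_sd
        Circular SD of the motor/sensory response noise, degrees.
    lapse_rate
        Probability of a uniform-random lapse response, in [0, 1).
    session_jitter_sd
        SD of the normal perturbation applied to ``amp_true`` for the
        second session of a two-session simulation, degrees.
    """

    amp_true: float
    fwhm_true: float = 35.0
    global_bias: float = 0.0
    noise_sd: float = 11.0
    lapse_rate: float = 0.0
    session_jitter_sd: float = 0.0

    def __post_init__(self):
        if abs(self.amp_true) > 15.0:
            raise ValueError("|amp_true| must be <= 15 degrees")
        if not 0.0 < self.fwhm_true < 90.0:
            raise ValueError("fwhm_true must lie in (0, 90) degrees")
        if self.noise_sd < 0.0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.lapse_rate < 1.0:
            raise ValueError("lapse_rate must lie in [0, 1)")
        if self.session_jitter_sd < 0.0:
            raise ValueError("session_jitter_sd must be >= 0")


def phenotype_to_params(phenotype: ObserverPhenotype) -> DvMParams:
    """DvM parameters reproducing the phenotype's amplitude and width.

    Numerical inversion of the curve readouts; raises ``ValueError`` when
    the requested width is unattainable within kappa in [0, 200].
    """
    return params_from_amplitude_fwhm(phenotype.amp_true, phenotype.fwhm_true)


def _adjust_target(task: np.ndarray, stimulus: np.ndarray) -> np.ndarray:
    """Orientation the observer tries to reproduce on each trial."""
    target = stimulus.copy()
    target[task == dsg.TASK_ROTATE_CW] += ROTATION_MAGNITUDE_DEG
    target[task == dsg.TASK_ROTATE_CCW] -= ROTATION_MAGNITUDE_DEG
    return wrap_orientation(target)


def simulate_responses(
    design: pd.DataFrame,
    phenotype: ObserverPhenotype,
    seed: int,
    params: DvMParams | None = None,
) -> pd.DataFrame:
    """Fill a trial table with simulated adjustment responses.

    Returns a copy of ``design`` with a ``response_deg`` column (NaN for
    no-response and 2AFC trials).  Deterministic for a given seed.
    """
    required = {"session", "block", "trial", "task", "response_mode", "stimulus_deg"}
    missing = required - set(design.columns)
    if missing:
        raise ValueError(f"design table missing columns: {sorted(missing)}")
    if params is None:
        params = phenotype_to_params(phenotype)
    rng = np.random.default_rng(seed)

    table = design.sort_values(["session", "block", "trial"]).reset_index(drop=True)
    stim = table["stimulus_deg"].to_numpy(dtype=float)
    task = table["task"].to_numpy()

    prev_stim = (
        table.groupby(["session", "block"], sort=False)["stimulus_deg"]
        .shift(1)
        .to_numpy(dtype=float)
    )
    has_prev = ~np.isnan(prev_stim)
    bias = np.zeros(len(table))
    if phenotype.amp_true != 0.0:
        dist = np.zeros(len(table))
        dist[has_prev] = (
            np.mod(prev_stim[has_prev] - stim[has_prev] + 90.0, 180.0) - 90.0
        )
        dist[has_prev] = np.where(dist[has_prev] == -90.0, 90.0, dist[has_prev])
        bias[has_prev] = dvm_value(dist[has_prev], params)

    noise = rng.normal(0.0, phenotype.noise_sd, size=len(table))
    lapses = rng.random(len(table)) < phenotype.lapse_rate
    lapse_resp = rng.uniform(0.0, 180.0, size=len(table))

    target = _adjust_target(task, stim)
    response = wrap_orientation(target + phenotype.global_bias + bias + noise)
    response = np.where(lapses, lapse_resp, response)
    response = np.where(
        table["response_mode"].to_numpy() == dsg.MODE_ADJUST, response, np.nan
    )
    table["response_deg"] = response
    return table


def sample_phenotype(
    rng: np.random.Generator,
    amp_range: tuple[float, float] = (-3.0, 9.0),
    fwhm_range: tuple[float, float] = (12.0, 71.0),
    fwhm_mean: float = 37.6,
    fwhm_sd: float = 14.7,
    noise_sd: float = 11.0,
    global_bias_sd: float = 1.0,
    lapse_rate: float = 0.01,
    session_jitter_sd: float = 1.0,
) -> ObserverPhenotype:
    """Draw a phenotype from the cohort distribution the package emulates.

    Amplitudes are uniform over the observed single-subject range (about
    -3 to +9 degrees); tuning widths follow a normal distribution matching
    the observed cohort (mean ~37.6, SD ~14.7 degrees) truncated to
    ``fwhm_range``; response noise matches the ~11-degree circular SD of
    real adjustment errors.  The width draw is additionally truncated to
    what the amplitude permits: under the |a| <= 15 bound, large
    amplitudes are only representable with narrower tunings (a 5% safety
    margin keeps the implied |a| clear of its bound).
    """
    amp = float(rng.uniform(*amp_range))
    lo, hi = fwhm_range
    if amp != 0.0:
        hi = min(hi, 0.95 * max_fwhm_for_amplitude(amp))
    lo = min(lo, hi)
    if hi > lo:
        while True:  # rejection sampling of the truncated normal
            fwhm = float(rng.normal(fwhm_mean, fwhm_sd))
            if lo <= fwhm <= hi:
                break
    else:
        fwhm = lo
    return ObserverPhenotype(
        amp_true=amp,
        fwhm_true=fwhm,
        global_bias=float(rng.normal(0.0, global_bias_sd)),
        noise_sd=noise_sd,
        lapse_rate=lapse_rate,
        session_jitter_sd=session_jitter_sd,
    )


def simulate_cohort(
    n_subjects: int,
    phenotype_sampler,
    seed: int,
    study: int = 1,
):
    """Simulate a two-session cohort with per-subject phenotypes.

    ``phenotype_sampler(rng)`` must return an :class:`ObserverPhenotype`.
    Session 1 uses ``amp_true``; session 2 uses ``amp_true`` perturbed by a
    normal draw with SD ``session_jitter_sd`` (the within-observer
    instability of the bias).  Returns ``(tables, truth)``: one trial table
    per subject (both sessions, responses filled) and a truth table of the
    generative values.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if study not in (1, 2):
        raise ValueError("study must be 1 or 2")
    rng = np.random.default_rng(seed)
    generator = (
        dsg.generate_study1_design if study == 1 else dsg.generate_study2_design
    )
    tables, truth_rows = [], []
    for i in range(n_subjects):
        subject = f"sim{i:03d}"
        phen = phenotype_sampler(rng)
        amp_cap = max_amplitude_for_fwhm(phen.fwhm_true) * 0.999
        amp_s2 = float(
            np.clip(
                phen.amp_true + rng.normal(0.0, phen.session_jitter_sd),
                -amp_cap,
                amp_cap,
            )
        )
        design = generator(subject, int(rng.integers(2**31)))
        sessions = []
        for session, amp in ((1, phen.amp_true), (2, amp_s2)):
            part = design[design["session"] == session]
            phen_s = replace(phen, amp_true=amp)
            sessions.append(
                simulate_responses(part, phen_s, seed=int(rng.integers(2**31)))
            )
        tables.append(pd.concat(sessions, ignore_index=True))
        truth_rows.append(
            {
                "subject": subject,
                "amp_true": phen.amp_true,
                "amp_s1": phen.amp_true,
                "amp_s2": amp_s2,
                "fwhm_true": phen.fwhm_true,
                "global_bias": phen.global_bias,
                "noise_sd": phen.noise_sd,
                "lapse_rate": phen.lapse_rate,
                "session_jitter_sd": phen.session_jitter_sd,
            }
        )
    return tables, pd.DataFrame(truth_rows)
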