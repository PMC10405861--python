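# Methods

This note documents the models, estimators, and numerical choices behind
`serialdep`, the assumptions they rest on, and what the synthetic-data
experiments do and do not establish.

## Orientation space and circular statistics

Stimulus orientations live on a half-circle: θ and θ+180° are the same
grating. All angle arithmetic therefore wraps orientations to [0°, 180°)
and signed differences to (−90°, +90°], with positive values denoting a
clockwise displacement and the boundary tie resolved to +90° by
convention (the bias curve is essentially zero there either way).
Circular means and SDs use the standard axial treatment: angles are
doubled, the mean-resultant direction and length R are computed on the
full circle, the SD is √(−2 ln R), and both are halved back to
orientation units. `scipy.stats.circmean/circstd` on doubled angles
serve as an independent oracle in the test suite; the implementation is
a direct transcription of the resultant-vector definitions.

## The bias curve

The derivative-of-von-Mises (DvM) curve models the mean response error as
a function of the signed previous-minus-current distance x:

y(x) = −a κ sin(x) e^{κ cos(x)} / (2π I₀(κ)),  x in degrees → radians
via π/180.

Parameters: a ∈ [−15, 15] (signed; note the leading minus sign, so
attractive curves carry a < 0), κ ∈ [0, 200], symmetry axis µ fixed at 0.
Degrees of distance map one-to-one onto degrees of phase (π/180). Under
this convention shallow curves (small κ) peak close to ±90° and do not
return to zero within the measured range; this is exactly the regime in
which the FWHM is reported as *undefined* (a half-maximum crossing would
fall outside (0°, 90°)), and it is what bounds the attainable widths to
roughly 6.5°–76°. The evaluation is numerically stable across the whole
κ range by writing e^{κ cos x}/I₀(κ) = e^{κ(cos x − 1)}/i0e(κ).

Readouts are closed-form: the positive-lobe extremum solves
cos x = (−1 + √(1+4κ²))/(2κ), the signed amplitude (attraction positive)
is the curve value there, and the FWHM comes from bisection on the two
half-maximum crossings (well below 0.1° accuracy). The amplitude bound
|a| ≤ 15 couples amplitude and width: wide curves have small per-unit-a
peaks, so e.g. a 9° amplitude is only representable at widths below
~56°. `max_fwhm_for_amplitude` / `max_amplitude_for_fwhm` expose this
feasibility frontier, and the phenotype sampler respects it.

## Designs

Study 1 (predictable): 2 sessions × 8 blocks × 144 trials. Tasks
alternate in miniblocks of four (reproduce ×4, rotate ×4, …); the
rotation direction is constant within a session, flips between sessions,
and its session-1 value is a stable hash of the subject label so a
cohort is counterbalanced. The 18 ten-degree distance bins covering
[−90°, 90°) are balanced exactly against the four serial positions
*within each session* (16 each, 32 over the experiment), so each session
is analysable alone. 20% of trials withhold the response
(230 = round(0.2·1152) per session — an exact 20% of 1152 is not an
integer; the session's first trial always requires a response).

Study 2 (unpredictable): 5 blocks × 396 trials (2 blocks in session 1, 3
in session 2), task order fully random. 540 trials (27.27%) replace the
adjustment with a 2AFC probe, twice as often on rotation as on
no-rotation trials (360/180). Among the 1440 non-2AFC trials every bin
occurs 40× per task, rotation split equally over the two directions;
2AFC trials draw their bins uniformly and sit outside the
counterbalance. The 2/3 block split across sessions precludes exact
per-session balance, so study-2 balance is enforced over the experiment.

Orientations are realized by drawing the actual distance uniformly
within the assigned bin and chaining current = wrap(previous − d) within
a block; the first trial of each block restarts the chain at a fresh
uniform orientation, so its assigned bin (kept for the count matrices)
has no realized counterpart and never enters the analysis.

## Synthetic observers

A phenotype is (amplitude, FWHM, global bias, noise SD, lapse rate,
between-session jitter). Responses on adjustment trials are

response = wrap(target + global_bias + DvM(prev_stim − stim) + ε),

where target is the stimulus (no-rotation) or the stimulus ±60°
(rotation trials; the simulator does not model rotation errors), ε is
wrapped-normal with the phenotype's SD, and with probability
`lapse_rate` the response is replaced by a uniform orientation — the
attentional failures the 3-SD filter is designed to catch. The history
bias uses only the immediately preceding trial's stimulus (lag 1, the
only lag analysed) and applies after every trial type; block-first
trials carry no bias. Session 2 perturbs the amplitude by
N(0, jitter_sd), clipped to the feasible range for the subject's width.

Cohort defaults emulate real adjustment data: noise_sd = 11° (observed
dispersion ≈ 11.1 ± 0.5°), amplitudes uniform on [−3°, +9°] (observed
single-subject range ≈ −2.8° to +8.8°), widths normal with mean 37.6°
and SD 14.7° truncated to [12°, 71°] (the observed width distribution)
and to the amplitude-feasibility frontier, lapse rate 1%,
session jitter 1°. What the generator does *not* emulate: multi-lag
history kernels, feedback-driven learning, rotation-trial response
strategies, reaction times, and any dependence of noise on the task
context. Passing tests therefore demonstrate correctness of the
estimators under a lag-1 DvM world with stationary wrapped-normal noise,
not that real observers satisfy those assumptions.

## Preprocessing

The analysis set is the *no-switch, no-rotation* trials: adjustment-mode
no-rotation trials with a response whose immediately preceding trial (in
presentation order, same block — breaks interrupt the trial stream) was
also a responded adjustment no-rotation trial. Each kept trial records
the signed error (response − stimulus), the distance to the previous
stimulus, and the distance to the upcoming stimulus (for the
temporal-control analysis). Lapses are removed in a single, non-iterated
pass: a trial is dropped when its error deviates from the
subject-session circular mean by more than 3 circular SDs (doubled-angle
metric throughout). Afterwards the subject-session circular mean error
(the global bias, e.g. a constant clockwise tilt of responses) is
subtracted; only this residual error enters the estimators.

## Estimators

**Group level.** The DvM is fit by least squares to pooled raw
(distance, error) trials.

**Subject level.** Trials are first reduced to a moving-average curve:
at each integer distance −90…90, the circular mean of errors whose
distance lies within ±10° (the distance axis wraps with period 180°).
The DvM is then fit to the defined curve points — but the model
prediction is passed through the *identical* smoothing operator (the
same trial-membership matrix, row-normalised) before comparison, and
points are weighted by their window counts (a mean of n trials has
variance σ²/n). Rationale: a direct fit to smoothed points inherits the
window's attenuation — up to ~40% amplitude underestimation for narrow
tunings — whereas the smoothing-aware fit recovers noiseless generating
parameters to ~10⁻⁴ and is unbiased under noise. Reported amplitude and
FWHM always describe the underlying, unsmoothed curve.

**Optimisation.** The DvM is linear in a, so a is profiled out in closed
form (clipped to its bounds) and the search is one-dimensional in κ: a
dense log-spaced grid (121 points over [0, 200]) followed by bounded
scalar refinement between the best grid point's neighbours. This finds
the global constrained minimum up to grid granularity, is ~100× faster
than generic 2-D multi-start least squares (which the permutation and
type-I-error machinery needs), and ties resolve to the lowest SSE, then
the smallest κ. R² is computed on the points (and weights) used in the
fit; a constant-y input returns the degenerate flat fit (a = 0, R²
undefined).

**Inference.** Permutation tests shuffle the pairing of each observer's
distances and errors and re-run the full pipeline (re-smoothing
included) per permutation; p is the plain proportion of permutations
with amplitude ≥ observed (one-sided, group level, where attraction is
expected) or |amplitude| ≥ |observed| (two-sided, subject level), ties
counting as extreme and no +1 correction. Bootstrap SDs resample trials
with replacement through the same pipeline. One caveat documented by
the test suite: the permutation null of the DvM amplitude is
heavy-tailed, because the globally optimal fit to pure noise often runs
to shallow boundary solutions (κ → 0, |a| → 15) that turn a broad noise
undulation into a sizeable "amplitude" — the spurious-fit regime known
for this model family. Type-I error is nevertheless exactly calibrated
(the null and the observed statistic share the pathology); the cost is
single-subject power, which is one reason the model-free measure exists.

**Model-free estimator.** bias = circ_mean(errors | 0 < d ≤ L) −
circ_mean(errors | −L ≤ d < 0); positive = attraction; d = 0 joins
neither bin; default L = 54°. `range_covering_area` computes the L
covering a given fraction of the fitted lobe's area, mirroring how such
bounds are chosen from group data. Its permutation test shuffles the
CW/CCW bin labels (two-sided).

## Stability analysis

Each subject × session cell gets the subject-level pipeline (two-sided
permutation p) plus the model-free bias; cells with fewer than 10 usable
trials are flagged and excluded. Between-session Pearson and Spearman
correlations are computed for the model-based amplitudes on the subset
significant in both sessions (FWHM correlations additionally require a
defined width in both), and for the model-free measure on all subjects.
The polar angle arctan(amp₂/amp₁) (45° = perfect test–retest equality)
feeds a median split on mean absolute amplitude — ties at the median go
to the bottom half — compared with a pooled-variance two-sample t-test
(df = n₁+n₂−2) and Cohen's d. At realistic amplitude spreads and
per-session trial counts the both-significant subset can be small (the
heavy-tailed null limits per-session power), so the all-subject
model-free correlation is the more robust stability readout on
synthetic cohorts.

## Problem sizes and seeds

The validation experiments run at the sizes a desk check needs: 40
observers for parameter recovery and estimator agreement (full study-1
designs, ~550 analysable trials each), 500 replicates × 200 permutations
for the type-I rate, and two 100-observer cohorts (amplitude spread
SD 2.5° + jitter 1° vs jitter-only) for the stability contrast — large
enough that a true between-session correlation of zero is confidently
distinguished from 0.5. Every stochastic stage takes an explicit seed;
the pipeline runner records all derived seeds in its provenance log, and
identical configurations reproduce identical numbers.

## Known limitations

* Parameter recovery accuracy is noise-limited: with 11° response noise
  and ~550 trials per observer, even an oracle that knows each subject's
  true κ and fits only the amplitude has a cohort MAE of ~0.75°; the
  free-κ estimator sits ~20% above that floor. Recovering amplitudes
  much more precisely requires more trials, not a better optimiser.
* The FWHM of shallow curves is undefined by construction; width
  statistics on cohorts are therefore conditional on definedness.
* The generator's lag-1 assumption means multi-lag analyses of simulated
  data will correctly find nothing beyond lag 1.
* The 20°-window, 1°-step moving average and the 18-bin design
  granularity are fixed conventions of the analysed paradigm, exposed as
  parameters but not systematically explored here.
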