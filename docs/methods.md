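# Methods

This note records the models, numerical choices and design decisions
behind `rtvalid`, and what the synthetic cohort does and does not show.

## Diffusion model

The decision process is a Wiener process with drift, diffusion
coefficient *s*, absorbing boundaries at 0 and *a*, start point
*z = z_r·a*. Everything is stimulus-coded: the upper boundary is the "R"
response and the drift is +*v* for rightward and −*v* for leftward
stimuli, so *z_r* > 0.5 expresses a stimulus-independent preference for
"R". Observed RT is the first-passage time plus the non-decision time
*t_er*. The full model adds trial-to-trial variability: drift
N(*v*, *sv*), start U(*z_r* ± *szr*/2), non-decision
U(*t_er* ± *st*/2); setting all three spreads to zero recovers the
simple model exactly, which is the default everywhere.

**Scale convention.** *s* = 1 throughout. The *s* = 0.1 convention found
in parts of the literature is an exact reparameterization (divide *v*,
*a*, *sv* by 10); `rescale_diffusion` converts, and a test asserts the
densities are invariant under conversion.

**Density numerics.** The defective first-passage density uses the
classic pair of series (small-time and large-time), choosing per time
point whichever needs fewer terms for a truncation error of the
normalised density below 1e−12; after the exponential prefactor the
absolute error stays well below the 1e−7 target over the parameter
ranges used here (drift ≤ ~5, boundary ≤ ~3). Total probability,
boundary-hit probabilities, and the closed-form mean/variance of the
first-passage time agree with adaptive quadrature of the density to
1e−6 or better in the tests.

**First-passage moments.** EZ and EZ2 need the forward map from
parameters to observable moments. The unconditional mean and variance of
the first-passage time for arbitrary start point were derived by solving
the backward ODEs for E[T] and E[T²] (the variance expression is the
long exponential formula in `fpt_variance`); negative drift is handled
by mirror symmetry and drifts with *2va/s² <* 0.02 switch to the
driftless limit, where the exact expression loses precision to
cancellation. The classic EZ closed-form inversion is algebraically
exact against this forward map — the round-trip test demands 1e−8 over a
grid of 100+ parameter sets and observes ~1e−13.

**Simulation.** Two routes exist, deliberately kept distinct:

- `simulate_diffusion` integrates the SDE by Euler–Maruyama with
  dt = 1e−4 s (configurable), augmented with a per-step Brownian-bridge
  crossing test near either boundary. Plain Euler overestimates
  first-passage times by O(√dt) because it misses within-step crossings;
  the bridge test removes that leading bias, and the simulated RT
  distributions match the analytic densities with KS distance ≲ 0.006 at
  10⁵ trials. This route is the independent oracle for the density code.
- `sample_fpt_inverse_cdf` draws the boundary from its closed-form
  probability and the decision time by inverting the tabulated
  conditional CDF of the series density (4000-point grid; interpolation
  error orders of magnitude below sampling noise). It is statistically
  equivalent (checked by two-sample KS against the Euler route) and
  ~50× faster, so the *session generator* uses it whenever participants
  follow the simple model. `sampler="euler"` forces the SDE route.

Censoring: trials that would finish after the 3 s deadline are recorded
with `rt = 3.0` and `timed_out = True`; every estimator excludes them.

## LBA

Each response side has an accumulator with threshold *b*, start drawn
U(0, *A*), and a ballistic slope drawn N(·, *sdrift*); the stimulus-matching
accumulator has mean slope *v_c*, the other *v_e*. `start_bias` lowers
the "R" threshold and raises the "L" one symmetrically, so positive
values favour "R"; with it at zero the two sides are exchangeable
(asserted analytically). Trials where both sampled slopes are ≤ 0 never
finish; the defective densities therefore integrate to
1 − Φ(−v_c/s)Φ(−v_e/s), and the simulator either redraws such trials
(default, the count is reported) or censors them at the deadline.
`sdrift` is fixed at 1 during fitting — the standard scaling constraint.

## Synthetic cohort (what the generator emulates)

The generator reproduces the structure of a two-hour factorial session:
20 participants, 18 main blocks of 156 trials in the fixed emphasis/bias
schedule (each emphasis × biased-status cell four times in blocks 2–17;
two extra speed/no-bias blocks at positions 1 and 18, needed so the
null data set can be built from disjoint halves of one cell), 50/50
easy/hard randomly intermixed within block, stimulus base rate 2/3
toward the favoured side in biased blocks, 3 s response deadline.
Practice blocks are not simulated; they never enter any analysis.

Manipulations map to parameters by construction (selective influence is
*exactly true* in the generator): easy doubles the drift, accuracy
emphasis doubles the boundary, a bias shifts *z_r* by 0.05 toward the
favoured side, with base parameters v = 1, a = 1, z_r = 0.5,
t_er = 0.3 s. These defaults put block accuracy at ~0.73–0.98 and median
RTs at ~0.45–0.76 s — speed blocks fast and error-prone, accuracy blocks
slow and accurate, the qualitative ordering of the behavioural
manipulation checks the design is anchored to. Participant heterogeneity
is mean-preserving log-normal on (v, a, t_er) with CV 0.10 and
logit-normal on z_r with SD 0.10 — a typical between-subject spread for
this class of task; all of it is configurable.

What the generator does **not** emulate: practice/fatigue drift across
blocks, sequential dependencies, contaminant responses, lapses, or
trial-to-trial variability (unless switched on). Passing the recovery
suites therefore shows the *procedures* behave correctly under the
model's own assumptions plus censoring — not that real data are this
clean.

**Relabeling.** Before construction, biased blocks are recoded so the
favoured option reads "R" (left-biased blocks swap both stimulus and
response labels); in no-bias blocks both labels are flipped for the
even-indexed half of trials to average out any side preference.
Accuracy, RTs and the truth pattern are invariant; the recode is an
involution on the flipped half.

**Pseudo-experiments.** The 14 canonical direction patterns are the
swap-equivalence classes of {A, 0, B}³; the class list and its data-set
order are fixed study design, and `enumerate_patterns` asserts the
hardcoded canonical labelings cover exactly the brute-force classes.
Source cells follow the fixed provenance table (no-bias cells preferred,
then the error-richest cell: hard over easy, speed over accuracy). Each
condition samples 312 trials per participant without replacement from
its cell's blocks (4 × 78 same-difficulty trials; the speed/no-bias cell
has 6 blocks, and the null data set instead splits that 468-trial pool
into disjoint halves of 234). Participant ids are shuffled per data set
and A/B order is flipped for the even-numbered half; the stored truth is
swapped along with the flip so it always describes the delivered data.

## Estimation

One outlier rule everywhere, applied before anything else: drop trials
with rt < 0.18 s and censored trials. Proportions at 0, ½ or 1 are
edge-corrected by 1/(2n) (the ½ case is nudged toward the sign implied
by correct responses being faster or slower than errors).

- **EZ**: closed-form inversion of (Pc, mean and variance of
  correct-response RTs); assumes an unbiased start.
- **EZ2**: Levenberg–Marquardt least squares on the six per-stimulus-side
  moment residuals (logit response proportion, RT mean, RT standard
  deviation for each side) over (v, log a, logit z_r, t_er), started
  from the EZ solution plus two jittered restarts. Exact forward moments
  round-trip to ~1e−16 cost; side-symmetric input returns z_r = 0.5.
- **ML diffusion**: Nelder–Mead on (v, log a, logit z_r, bounded t_er)
  with five jittered starts from the EZ2 initial value, maximising the
  summed log defective density. t_er is kept below the fastest retained
  RT by a logistic transform.
- **ML LBA**: same scheme over (log b, logit A/b, v_c, v_e, bounded t0),
  sdrift fixed at 1, side-specific threshold offset optionally freed.
  Recovery of the start range A requires a regime where it carries mass
  (A/b large); the recovery test uses b = 1, A = 0.8 and documents this.

Full-diffusion maximum likelihood (three variability dimensions) is
deliberately not provided; variability parameters can be frozen at zero,
which reproduces the common practice of fitting the simple model.

## Inference

- **Estimate-based** (the modal practice): per component, a two-sided
  paired t-test across participants on the mapped parameter (v→ease,
  a→caution, z_r→bias-R, t_er→ndt; an LBA map is provided), α = 0.05,
  no multiple-testing correction; the significant condition with the
  higher mean gets the label.
- **Heuristic**: ease by the classic 5 % accuracy rule; caution when the
  slower condition (0.9 RT quantile, cutoff 50 ms) is also the more
  accurate; bias by an SDT criterion difference beyond 0.1 (criterion
  C = ½[z(H)+z(FA)] with H, FA the 'L'-response rates to left/right
  stimuli; positive C = leftward bias — the probit convention the
  printed criterion values require); ndt by a common ≥ 50 ms shift of
  the 0.1 RT quantile in both response classes. The 5 % rule is the only
  cutoff taken from practice verbatim; the RT and criterion cutoffs are
  package defaults, clearly labelled and configurable.

Both procedures are antisymmetric under condition swap (tested).

## Scoring

Slots are data set × component. Classification: equal → correct;
manipulated but called null → miss; null but called → false alarm;
opposite directions → flip (the 3×3 label table partitions into
3/2/2/2). Keys: *planned* (truth as constructed), *alt 1* (ease truth
copied from caution wherever caution ≠ 0; data sets whose ease and
caution truths oppose cannot be rescored and are dropped — ids 8, 11, 12
for the canonical patterns, detected generically for user-supplied
ones), *alt 2* (same coupling into ndt), *no-ndt* (ndt column dropped,
42 slots). Proportions are stored at full precision and rounded
half-up to two decimals only for display. Method agreement is the
proportion of identical {A, 0, B} entries over shared slots.

## Replication sizes and observed behaviour

The end-to-end recovery study runs 50 replicate blinded studies on data
sets 1–4 (the null and the three single-component manipulations) with
EZ2 fits and paired t-tests: each manipulated component is detected in
100 % of replicates and the null data set's false-alarm rate (0.065 over
200 component slots at seed 1) sits inside the binomial 95 % band around
α = 0.05. ML consistency is checked across n ∈ {250, 1000, 4000} with
16 replicates per size (median combined relative error decreases
monotonically); EZ, being closed-form, is checked at 100 replicates.
These sizes are the package's chosen trade-off between statistical
resolution and suite runtime.

A finding worth flagging: although the generator enforces exact
selective influence, the estimate-based pipeline still produces ease and
non-decision-time false alarms in caution-manipulated data sets. The
mechanism is censoring: accuracy-emphasis conditions lose their slowest
trials to the 3 s deadline, which biases RT moments and hence the
drift/t_er estimates by a small, consistent amount that 20 paired
participants can detect. Scoring the same tables under the no-ndt or
coupled keys raises accuracy substantially (0.80 → 0.95 planned → no-ndt
at seed 1), echoing the pattern such validation studies report on real
data — a reminder that statistically significant parameter differences
need not reflect manipulated constructs.

## Known limitations

- The series density is tuned for the moderate parameter ranges of this
  task class; extreme drifts (va/s² ≫ 40) would overflow the variance
  closed form before the density fails.
- EZ2's least squares can in principle sit in a local minimum for
  pathological moment sets; the converged flag and residual cost are
  reported.
- The heuristic's RT/criterion cutoffs are conventions, not estimates;
  its performance depends on them.
- Agreement and scoring assume every method answers every slot; partial
  submissions are not modelled.
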