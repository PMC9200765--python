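# Methods

`crabloom` analyses escape decisions of crabs confronted with one or two
simultaneously approaching looming stimuli, together with the responses
of their looming-sensitive lobula giant neurons (MLG1/MLG2-like cells).
The package contains the full chain: stimulus kinematics, a synthetic
generator for behavioural trials and spike trains, circular statistics
for escape directions, spike-train response quantification, and the
decision procedures that discriminate *selective* from *divided*
attention behaviourally and *select-stronger* (max) from *sum* / *average*
integration neurally.

## Stimulus model

A looming stimulus simulates an object of diameter D approaching at
constant speed v from starting distance d0 on a direct collision course.
Its full angular subtense at time-to-collision tau is

    theta(tau) = 2 * arctan( (D/2) / (v * tau) ),

capped at 180 deg once the remaining distance falls below one object
radius (on screen, the disk has filled the monitor and stops changing).
The expansion rate is the analytic derivative,

    dtheta/dt = 2 R v / (d^2 + R^2)   [rad/s],  R = D/2,  d = v * tau.

Defaults reproduce the two experimental setups: behaviour (30 mm, 200
mm/s, 5000 mm; initial subtense 0.34 deg, collision after 25 s) and
electrophysiology (30 mm, 90 mm/s, 1000 mm; initial subtense 1.7 deg,
collision after 11.1 s).  Stimulus photometry is summarized by Weber
contrast (L_stim - L_bg)/L_bg, negative for dark stimuli; a display
linearization LUT is computed by numerically inverting a measured
radiance curve.  The exact-arctan form is used rather than the
small-angle approximation; at these geometries both round to the same
printed subtenses.

## Synthetic behaviour

Each crab completes Latin-square-ordered blocks of treatments (Single,
Paired 90, Paired 180, and contrast variants).  Per trial:

- body orientation: the azimuth of the crab's lateral (long) body axis
  in the stimulus frame, uniform on [0, 360);
- response: Bernoulli with probability 0.754 per trial (the average
  response probability of the tethered preparation; configurable per
  treatment);
- escape direction: von Mises with concentration kappa = 8 (a realistic
  directional scatter of ~20 deg SD) around a mode set by the simulated
  mechanism.  Under *selective* attention one stimulus is chosen with
  log-weights `lateral_bias * cos(2 * (azimuth - body_axis)) +
  contrast_bias * |contrast|` and the crab runs directly away from it;
  the cos(2.) term is the axial alignment of the stimulus with the
  lateral body axis, where crab visual acuity peaks.  Under *divided*
  attention the crab runs at the circular mean of the away-directions
  (for opposed stimuli, one of the two orthogonal directions at random).
- timing: Gaussian on the sqrt(time-to-collision) scale (mean 1.6
  sqrt-s ~ 2.6 s before collision, SD 0.25, between-crab SD 0.15),
  squared back; escape timing is analysed on that square-root scale.

The generator reproduces the *structure* the analysis assumes — mixture
modes, axial symmetry for opposed stimuli, orientation- and
contrast-dependent choice, repeated measures per crab.  It does not
emulate habituation/sensitization across presentations, claw
lateralization, or any coupling between timing and direction, so passing
tests validate the statistical machinery, not those aspects of real
behaviour.

## Synthetic spike trains

Spike trains are inhomogeneous Poisson processes (Lewis thinning) with

    lambda(t) = r0 + g * c_scale * rule({ w_i |c_i| dtheta_i/dt }),

driven by the angular expansion rate of each stimulus; `rule` is max,
sum, or average.  Defaults: spontaneous rate r0 = 2 Hz (lobula giants
fire sparsely at rest), gain g = 0.9 Hz/(deg/s) (peak responses of a
few hundred Hz near collision), receptive weights 1.0 (primary
location) and 0.5 (secondary) emulating MLG1 receptive-field
inhomogeneity (equal weights emulate the more uniform MLG2), a 30-s
spontaneous segment before stimulation, three trials per treatment per
neuron, and 10% lognormal jitter of weights and 20% of gain across
neurons.  Expansion-rate drive (rather than angular size) makes the
rate peak near the predicted collision and lets lower contrast shift
threshold crossings later — the qualitative signatures of the recorded
cells.  The functional form is a generator choice, not a biophysical
claim; there is no adaptation, bursting, or conduction delay.

## Circular statistics

All implemented from the standard formulas (angles in degrees, [0, 360);
axial data doubled mod 360 and the mean halved back):

- vector summaries (mean direction, mean resultant length rho); means
  with rho < 1e-12 are flagged undefined rather than reported;
- multimodal transform: angles x4 (90-deg separation) or x2 (180-deg /
  axial) mod 360.  In the canonical frame (one stimulus approaching
  from 0 deg; the other from 270 or 180) this maps both selective
  escape modes onto 0 deg and the divided mode onto 180 deg, so one
  post-transform mean direction separates the hypotheses;
- Rayleigh test with the classical series p-value approximation
  (validated: type-I error 0.047 at alpha = 0.05, n = 30; p-values
  uniform under the null);
- Rao homogeneity test, dispersion component: weighted-heterogeneity
  chi-square of per-group resultant lengths with delta-method
  variances, k - 1 df (validated: type-I error 0.053 at n = 50);
- percentile bootstrap confidence arcs for the circular mean,
  re-centred through the shortest arc (coverage 0.92-0.98 at kappa = 8,
  n = 40);
- the green/white/red sector protocol for 90-deg pairs: with stimuli at
  0/270 deg, the central 45 deg around each selective mode (90, 180) is
  white and excluded; the inner flank [112.5, 157.5) centred on the
  divided mode (135) is green; the outer flanks are red.  Selective
  behaviour puts ~50% of green+red escapes in green; a divided
  contribution inflates it.  Green proportions are compared by
  permutation (exhaustive enumeration when feasible);
- orientation bins: four half-open 90-deg bins centred on 0/90/180/270,
  so bins centred 0/180 collect trials with the reference stimulus on
  the lateral axis and 90/270 on the anterior-posterior axis.

## Spike-train quantification

Rates are estimated by summing Gaussian kernels (FWHM 200 ms, sigma ~
84.9 ms) at each spike time on a uniform grid (default dt = 1 ms;
population runs use 5 ms, still 40x finer than the kernel), truncating
at the recording edges, then rescaling globally so the trapezoidal
integral over the whole recording equals the spike count — conservation
is exact by construction and asserted everywhere.  Spontaneous mean and
SD are measured on the smoothed rate over the unstimulated segment
(edges trimmed by 3 sigma).  Response onset is the earliest time the
rate exceeds mean + 2 SD and stays above for a minimum duration;
`detect_onset` defaults to one kernel FWHM (0.2 s), but the pipeline
default is 0.4 s because one-FWHM excursions of a smoothed 2-5 Hz
baseline above the 2-SD threshold are common over an 11-s trial and
produce spurious early onsets.  Peak and average rate are measured from
onset to the end of stimulation (the predicted collision); onset is
reported as time-to-collision (positive before collision).

## Decision procedures

**Behavioural verdict.**  Directions are rotated into the canonical
stimulus frame (mirrored if the second stimulus sits at +90 deg).  Per
paired treatment: transform (x4 or x2), Rayleigh-test the transformed
paired and single samples, bootstrap the transformed means, Rao-test
the dispersions, and (90-deg pairs) run the sector permutation test
against the single-treatment distribution combined with a copy rotated
by -90 deg.  A treatment is classified *selective* if its transformed
distribution is significantly directional with mean within 90 deg of
the selective pole (0 deg), *divided* if nearer the divided pole
(180 deg), else inconclusive; the dataset verdict is the consensus of
informative treatments, inconclusive on disagreement or when fewer than
10 trials respond per group.  Paired-180 escape directions are treated
as axial throughout.  At the study scale (kappa = 8, 40 trials per
treatment) the generating mechanism is recovered in ~100% of seeds, and
as kappa -> 0 the verdict degrades to inconclusive rather than to the
wrong mechanism.

**Neural verdict.**  Per neuron with complete Primary / Secondary /
Paired metrics (trial-averaged), the observed paired peak rate is
compared with the max, sum, and mean of the single-stimulus peaks.  The
verdict is the rule with the smallest median relative error across
neurons, declared only if the paired-bootstrap 95% CI of the
median-error difference to the runner-up excludes zero.  The peak rate
drives the verdict because it is measured identically in every
treatment; the average rate during response is windowed by each
treatment's own onset, so blends of single-stimulus averages are not
predictions of the paired average — its errors are reported as
supporting statistics only.  With equal receptive weights the max and
average predictions coincide and the procedure correctly returns
inconclusive.

**Timing contrasts.**  Pairwise group differences in sqrt-transformed
escape timing (or onset time-to-collision) are tested by permuting
treatment labels within subject, preserving the repeated-measures
dependence; the permutation distribution is enumerated exactly when the
number of within-subject arrangements is small.  P-values are
Holm-adjusted across contrasts; contrasts with fewer than 3 subjects
per group are skipped.

## Numerical choices and edge cases

- Angles: half-open interval convention [lo, hi) everywhere; angles
  normalized to [0, 360); degrees in interfaces, radians internally.
- Kernel support truncated at +-6 sigma (relative mass error < 1e-9)
  before the exact global renormalization.
- Permutation p-values use the add-one estimator (1 + #extreme)/(1 + B)
  for sampled permutations and the exact count for enumerations.
- Degenerate inputs: empty spike trains give zero-rate profiles;
  perfectly concentrated escape samples make the sector test
  uninformative (p = 1 recorded with a note); balanced angular samples
  have undefined means and produce full-circle bootstrap arcs with a
  warning.
- All randomness flows through `numpy.random.default_rng` seeds carried
  in the parameter objects; identical config + seed yields
  byte-identical reports (JSON with sorted keys, no timestamps).

## Validation scales and limitations

The acceptance checks run at the study's scale: 40 trials/treatment and
100 seeds for behavioural recovery; 20 neurons, 3 trials/treatment and
100 seeds for rule recovery; 500 trials for onset localization (5 -> 40
Hz step, 60-s baseline); 50 trains per contrast level for the HC/LC
onset direction; 20 000 / 10 000 replicates for the Rayleigh / Rao
type-I calibration.  With the 200-ms kernel and 2-SD criterion, steps
whose response sits less than ~2 baseline SDs above threshold (e.g.
5 -> 30 Hz) localize within one FWHM in only ~90% of trials — an
intrinsic limit of the threshold method at that signal-to-noise ratio,
not an implementation artifact.  All recovery percentages describe the
synthetic generator's conditions; real recordings with drifting
baselines or adaptation would lower them.
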