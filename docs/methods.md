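# Methods

This note documents the models implemented in `patchforage`, their
assumptions, the defaults and why, and what the synthetic-data generators
do and do not emulate.

## The economic model

At an indifference point two options are, by definition, of equal perceived
value: `V(E) = d(E)·V₀`, where `V₀` is the value of the effortful option,
`V(E)` the value of the easy option at indifference, and `d(E) ∈ [0, 1]` the
discount factor at effort level `E`. Two assumptions make the model
operational:

1. **Value is linear in bacterial optical density (OD) with zero
   intercept.** The value slope then cancels from every ratio, so ODs can be
   used directly in place of values (`value_slope` is kept explicit in
   `EffortDiscountModel` but never matters to a prediction).
2. **`d(E)` is independent of `V₀`** (the basic discounting assumption).
   One measured indifference pair then predicts all others: every OD pair in
   the ratio `d : 1` is an indifference point.

Effort `E` itself is never quantified by the assay — it is fixed by the
bacterial-elongation protocol — so `d` is estimated *at* that effort level
rather than fitted as a function of effort. A small catalog of conventional
forms (linear, hyperbolic, exponential in `E`) is provided for completeness
(`DISCOUNT_FORMS`) but deliberately left unfitted; its parameterisations are
the conventional ones, not estimates.

**Choice link.** The assay only constrains the sign/zero structure of
preference (positive when the normal option's discounted value is larger,
zero at equality). To connect values to the magnitude of the preference
index `I`, the model offers two links: Herrnstein matching
(`P(normal) = v_N/(v_N + v_E′)`, the default, the simplest link reproducing
the observed sign pattern) and a logistic in the value difference with
sensitivity `β`. Observed magnitudes calibrate `β`; they are not predictions
of the discounting model itself.

**Indifference-OD estimation.** `estimate_indifference_od` reports two
readings of a measured preference curve: (a) the experimental rule — the
condition whose 95% CI contains zero (nearest-zero mean wins if several
qualify), and (b) the zero crossing of the piecewise-linear interpolation of
mean `I` against OD. Both are returned; when every mean has the same sign
the result is flagged as having no indifference point in range.

## Three-state patch-leaving kinetics

States are defined purely by zone occupancy of the two tracked body points:
F (head and tail both in contact with the patch), B (exactly one), O
(neither). "Contact" means within `δ` mm of the patch (inside or on the
boundary); `δ` defaults to 0 because the patch margin is traced manually
around the visible food and contact is taken literally.

The chain is linear (F ↔ B ↔ O): a worm cannot cross from fully-on to
fully-off food without its two ends disagreeing in between. Estimators:

* `P_X = T_X / ΣT` — fraction of total observation time in each state.
* `k_XY = N_XY / T_X` — transitions out of X into Y over total time in X,
  reported per minute. This is the maximum-likelihood estimator for a
  continuous-time Markov chain with exponential dwell times.

**Segmentation details** (all configurable):

* Interval boundaries fall at the midpoint between the two frames flanking
  a label change.
* Debounce default is 1 frame (off): no smoothing is applied unless asked
  for, since the classification rule itself is noise-free on clean
  coordinates. Blips shorter than the debounce are merged only when both
  neighbours agree.
* A direct F↔O adjacency in the frame labels (a border crossing faster than
  one frame) is repaired by inserting a B interval one inter-frame period
  long, centred on the boundary: the border zone must be physically crossed
  and the model admits only the four transitions F→B, B→O, O→B, B→F. The
  repair restores the two transitions that actually occurred.
* The first and last intervals are censored at the recording edges: they
  contribute occupancy time but the truncated edge contributes no
  transition (standard censored-likelihood treatment; unbiased at the
  cohort level, confirmed by the recovery tests).
* Tracking dropouts up to 2 s are linearly interpolated; longer gaps split
  the recording into independent segments. The threshold is a package
  choice — short dropouts are tracker blinks, multi-second ones usually mean
  the worm left the field or the tracker lost identity.

**Speeds.** Frame-to-frame centroid displacement over the frame interval. A
step counts toward a state's mean only when both flanking frames carry that
label, so state-change frames contaminate neither mean; B frames are
excluded because "on food / off food" is a binary contrast and the border is
neither. Per-worm `k` values are reported for worm-level statistics; pooled
`ΣN/ΣT` is used for parameter recovery, where it is the cohort MLE.

**Reporting.** `PatchKineticsResults.per_worm` is the worm-level table
(state probabilities, rates, speeds); `.pooled` the cohort MLE; `.ilr()`
the compositional coordinates of the per-worm state probabilities.

## Compositional statistics

State probabilities sum to 1, so they are compositional and are analysed
after an isometric log-ratio transform with the partition {F} | {B, O}
followed by {B} | {O}:

    z₁ = √(2/3) · ln(P_F / √(P_B·P_O)),   z₂ = √(1/2) · ln(P_B / P_O)

The first balance is the scientifically interesting contrast (time on food
against everything else); the second separates border from off-food time.
The transform is an isometry of the simplex and exactly invertible
(`ilr_inverse`). Zero components (a worm that never visited a state) are
replaced multiplicatively with ε = half the smallest observable nonzero
fraction — half of one frame over the worm's frame count — and the
composition renormalised before transforming.

## Preference statistics

The preference index `I = (n_N − n_L)/(n_N + n_L)` is computed per plate;
plates with zero countable worms are excluded and logged. Cohort summaries
use the one-sample *t* test against zero with 95% CIs from the *t*
quantile. One-way ANOVA reports `η² = SS_between/SS_total` from an explicit
sum-of-squares decomposition (the effect size is defined on it); partial
`η² = SS_effect/(SS_effect + SS_error)` is provided for multifactor
designs. Welch's correction (fractional Welch–Satterthwaite df) is used for
two-sample comparisons with unequal variances. Rank-biserial correlation is
`r = 2U/(n₁n₂) − 1`. Tukey and Dunnett post-hoc families wrap scipy with
computed, not tabulated, critical values.

**Outlier rule.** Extreme outliers are values below `Q1 − 3·IQR` or above
`Q3 + 3·IQR`. The upper bound is deliberately written with `Q3`: stating it
from `Q1` would make the band asymmetric in a way that cannot be intended,
since it would flag values inside the box whenever the IQR is large.

## EPG pump detection

Each pharyngeal pump produces a stereotyped biphasic voltage transient.
Detection: second-order Butterworth band-pass (1–100 Hz by default,
zero-phase, with even-reflection padding — odd-reflection padding creates
high-pass edge transients that masquerade as events), rectification,
thresholding at `c = 5` times the robust noise sigma (1.4826·MAD of the
filtered trace, insensitive to sparse spikes), and peak picking with a
100 ms refractory period (the physiological bound on the pump rhythm,
~5–6 Hz maximum). The threshold never drops below 30% of the largest
rectified excursion so that noise-free traces do not trigger on filter
ripple; both threshold terms scale linearly with the trace, making the
detected count invariant to amplitude scaling. The detector's contract is
precision/recall ≥ 0.95 at SNR ≥ 5 on synthetic ground truth, not
bit-compatibility with any particular acquisition software. Per-worm
frequency is event count over recording duration; the cohort mean is
unweighted over worms.

## Synthetic-data generators

The generators define the study conditions the tests run under:

* **Tracks.** A Gillespie simulation of the F–B–O chain (exponential dwell
  times — exactly the model under which `N/T` is the MLE) is rendered into
  head/tail coordinates inside a 10 mm well with a centred circular patch of
  diameter 3.5 mm. Recordings default to 15 min at 2 frames/s. Within F and
  O the body midpoint performs a persistent random walk at the state's mean
  speed (defaults 0.05 mm/s on food, 0.15 mm/s off food — slow dwelling on
  food versus brisk roaming off it) inside the admissible region; in B the
  contact point slides along the patch boundary with the straddling end
  alternating between visits (the state is defined by one-point contact
  only, so the geometry is free). Default rate constants are
  k_FB = 0.2, k_BO = 0.5, k_OB = 1.5, k_BF = 2.0 per min: the assay reports
  rate constants only graphically, so the defaults are illustrative values
  chosen once to satisfy the observed qualitative orderings
  (k_BF > k_FB, k_OB > k_BO) and to give a realistic on-food-dominated
  occupancy (stationary P ≈ 0.88/0.09/0.03).
* **T-maze plates.** `n_normal ~ Binomial(n_worms, p_normal)` per plate,
  with `E[I] = 2p − 1`. Defaults: 30 countable worms per plate.
* **EPG.** Jittered-regular (not Poisson) pump trains — pumping is
  rhythmic — at 4 Hz for 5 min, sampled at 1 kHz, with a
  Gaussian-derivative biphasic template (20 ms width) in Gaussian noise;
  amplitude 1 and noise SD 0.2 give SNR 5.

What the generators do **not** emulate, and hence what passing tests do not
show about real data: worm body kinematics (undulation, reversals, omega
turns), area-restricted search, chemotaxis gradients, patch depletion,
tracker head/tail swaps, non-exponential dwell-time distributions,
plate-to-plate overdispersion in T-maze counts (real plates share
environmental effects the binomial model ignores), and real EPG waveform
variability (E/R sub-spikes, baseline drift, movement artefacts).

## Problem sizes and numerical choices

The statistical self-checks use 100 chains × 100 min for stationary
occupancy (initial states drawn from the stationary law, so occupancy is
unbiased at finite horizon), 60 worms × 15 min for pooled rate recovery
(within 10% of truth for the balanced rate set used there; rarely visited
states at the skewed default rates carry larger Monte-Carlo error than that
at this cohort size), 2000 replicates for type-I-error calibration, and
fixed seeds throughout (every generator takes an explicit seed, default 0).
Tolerances: simplex sums are checked to 1e-6 before the ILR; compositional
round trips hold to 1e-10; estimator identities (F = t², scipy
cross-checks) to relative 1e-9. Degenerate inputs fail loudly rather than
silently: empty plates are excluded and logged, unvisited states yield NaN
rates (not zero), degenerate polygons, non-monotonic timestamps and
overlapping spike templates are rejected.

## Known limitations

* The discounting model is evaluated at a single effort level; fitting
  `d(E)` against graded effort requires data the assay does not produce.
* The B-state rendering is schematic (boundary straddling), adequate for
  classification round trips but not for posture-level analyses.
* Frame-resolution segmentation cannot see dwells much shorter than one
  frame period; the F↔O repair recovers the transition count but assigns
  the bridging B dwell a nominal one-frame duration.
* The pump detector assumes a roughly stationary noise floor over the
  recording; slow drifts larger than the pass band's low edge are removed,
  faster ones are not.
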