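# Methods

## Problem and model

`motormap` simulates and analyses automatic motor mapping by epidural
cortical surface stimulation. A 32-channel surface array (8×4 electrodes,
700-μm pitch, ≈5.0×2.2 mm² footprint) stimulates the motor cortex one
electrode at a time; the motor threshold (MT) of each electrode — the
stimulus intensity that evokes a motor evoked potential (MEP) above a
predetermined amplitude criterion — is estimated from the stream of
evoked/not-evoked outcomes, and the per-electrode MT landscape is the motor
map. Intensities live on a discrete grid, 20–100% of maximum stimulator
output (MSO) in 5% steps, with 100% MSO = 1.0 mA. An electrode with no
significant MEP at 100% MSO is nonresponsive.

Two relative-frequency MT criteria are implemented:

* **Tracking (novel) criterion.** A ±1-step staircase: step down after a
  significant MEP, up after a nonsignificant one. The staircase stops once
  the last five delivered intensities span at most one step (i.e. are
  confined to two adjacent levels); MT = mean of the last two intensities,
  so tracking MTs live on a 2.5%-MSO half-step lattice. The literal phrase
  "intensity changes within ±5%" is vacuous for a ±5% staircase, so the
  two-adjacent-levels reading is used; a wider three-level reading is
  conceivable but does not reproduce the characteristic two-level
  oscillation before stopping. If a step above 100% MSO is demanded the
  electrode is declared nonresponsive (`nonresponsive_repeats` can require
  k consecutive failures at the ceiling). When the stop rule and the
  ceiling rule fire on the same stimulus — possible only for thresholds
  within half a step of the ceiling — the stop rule wins, since no further
  intensity is actually demanded.

* **Conventional criterion.** MT is the lowest intensity evoking
  significant MEPs in at least 5 of 10 consecutive trials. Each level is
  classified with early stopping (positive at the 5th significant MEP;
  negative at the 6th nonsignificant, when 5-of-10 has become impossible by
  pigeonhole); the walk moves down after a positive level and up after a
  negative one, each level classified at most once, and terminates at the
  first adjacent positive/negative pair (MT = the positive member), at a
  positive grid floor (MT = 20%), or at a negative ceiling (nonresponsive).
  The 5-significant / 6-nonsignificant pair is the only early-stopping rule
  consistent with the 5-of-10 definition.

For a deterministic responder with threshold θ, the conventional MT is the
lowest grid level ≥ θ and the tracking MT is that level minus 2.5% MSO;
both criteria therefore rank electrodes identically on noise-free data,
and recover θ within one step (conventional) or half a step plus
quantization (tracking).

## Scheduler

Mapping runs on a fixed slot clock (4 Hz for the tracking protocol, 1 Hz
for the conventional one). At each slot one electrode is drawn uniformly at
random among the unresolved electrodes outside their refractory window and
receives the intensity its estimator demands; empty eligibility sets emit
pause slots. The tracking protocol forbids re-stimulating an electrode
within 2 s (8 slots at 4 Hz); the conventional protocol applies no
refractory beyond its 1-s slot spacing, since the 2-s rule exists to
protect against >1-Hz same-site stimulation effects. Every electrode
starts at 50% MSO. Elapsed mapping time is the closed span of occupied
slots plus one slot width; interior pause slots count, trailing ones
cannot occur (the run ends on the resolving stimulus). The 10-pulse,
500-μs, 1-kHz biphasic train is carried as metadata only; within-train
dynamics are not modelled.

Because electrode state machines do not interact, the resulting map is
independent of scheduler interleaving for deterministic responders; this
is asserted by comparing runs under different scheduler seeds.

## Virtual subjects

Each simulated subject draws per-electrode true thresholds from
θ(x,y) = θ_hot + g·‖(x,y) − hotspot‖ + jitter: a low-threshold hotspot
placed uniformly within the central half of the array, a radial gradient
g, and i.i.d. Gaussian jitter. Responses follow a cumulative-Gaussian
recruitment curve, P(significant | I) = Φ((I − θ)/s); s = 0 gives a
deterministic step responder. MEP amplitudes are drawn above the
significance criterion on significant trials and below it otherwise; they
are cosmetic (the estimators consume the boolean). Defaults: θ_hot ~
U(30, 45)% MSO, g = 14 %/mm, jitter sd 3% MSO, s = 2.5% MSO, significance
amplitude 50 μV (wrist-extensor preset; 25–40 μV presets suit a soleus
map). The gradient default is set so that thresholds can exceed the
resolvable range (> 97.5% MSO) at array margins for off-centre hotspots —
the smallest round value with that property given the array geometry —
which yields a small, variable population of nonresponsive electrodes, as
in real maps. All constants are invented, config-exposed values, not
measurements.

ICMS-style reference maps are fabricated by sampling the same smooth
(jitter-free) threshold field on a 0.5-mm lattice, rescaling monotonically
to μA (100% MSO ↦ 60 μA by default) with additive Gaussian noise, marking
sites above 60 μA nonresponsive, and growing the lattice outward until the
responsive region is surrounded by a nonresponsive ring.

What the generator does **not** emulate: anesthesia-depth drift and halted
mapping periods, spatial interactions between nearby stimulation sites,
EMG noise structure, session-to-session electrode impedance changes, and
the wider between-animal spread of excitability seen in vivo. Passing
tests therefore demonstrate the correctness and efficiency of the
algorithms under a clean, stationary recruitment model — not performance
on real animals. In particular, simulated conventional sessions are
cheaper than real ones (~900 vs ~1500 stimuli), so the novel/conventional
stimulus-count ratio simulates near 0.36 rather than the ~0.25 observed in
vivo, and the narrow simulated between-subject spread depresses
cross-method ICCs (see below).

## Statistics

* **Map comparison.** Tied-rank Spearman: average ranks with ties,
  nonresponsive electrodes entering at the tied worst rank (option to
  exclude them instead); rho is the Pearson correlation of the rank
  vectors. Significance: permute one rank vector 2,000 times; the observed
  rho is significant if it exceeds the 99th percentile of the null
  (one-sided). The p-value uses the +1 convention, bounded below by
  1/(n_perm+1). The type-I error of the criterion is ≈1%, verified by
  simulation.
* **Map parameters.** Minimum MT (mA, over responsive electrodes) indexes
  excitability; map area is the count of electrodes with MT ≤ 0.95 mA.
* **ICC.** Two-way, absolute-agreement, single-measure (McGraw–Wong A,1),
  computed from the ANOVA mean squares in-package (the pingouin reference
  implementation rejects designs smaller than 5 observations; it is used
  as an oracle in the tests). A constant session matrix leaves the
  coefficient (a variance ratio) undefined and is reported as NaN even
  though agreement is exact. A,1 was chosen over the consistency variant
  because test–retest agreement of the *same* measurement is the question;
  note this penalises the built-in half-step offset between the two MT
  criteria when they are compared to each other.
* **Interpolation / cross-modality.** Motor maps are linearly interpolated
  over the Delaunay triangulation of the responsive electrode positions;
  queries outside the convex hull are refused (NaN) rather than
  extrapolated. The surface-vs-ICMS correlation ranks the ICMS MTs of the
  responsive ICMS sites against the interpolated surface MT evaluated at
  those coordinates, with the same permutation rule; out-of-hull sites are
  excluded and counted. On coincident sites this reduces exactly to the
  generic tied-rank Spearman test (asserted).
* **Session tests.** Tie-corrected Friedman across sessions (in-package:
  the scipy implementation rejects k=2 and fully tied designs, both needed
  as degenerate cases; scipy is the oracle at k≥3), with pairwise Wilcoxon
  signed-rank post hoc at Bonferroni-corrected α = 0.01. Fully tied data
  yield χ² = 0, p = 1; all-zero difference vectors yield p = 1.

## Protocol and problem sizes

`run_protocol` maps each subject four times in fixed order — pre1, pre2
(conventional, 1 Hz), novel (4 Hz), post (conventional) — on the same
threshold landscape with independent per-session response noise, then
computes the per-subject pairwise correlations, cohort ICC tables, and
Friedman/Wilcoxon tests on durations and correlations. All randomness
(landscape, scheduling, responses, permutations) derives from the
per-subject seed, so results are bit-reproducible.

The default validation cohort is 12 subjects (the study's sample size),
which runs in a couple of seconds; property sweeps use an 800-point
brute-force θ grid and 1,000-replicate permutation-calibration runs. On
the default cohort the novel mapping takes a median ≈1.5 min and ≈315
stimuli (printed range 229–409), with a time ratio to conventional
mapping of ≈1/10.

## Known limitations

* The cohort-level ICC between the conventional and tracking sessions
  simulates at ≈0.73–0.78 (population value), below the ≥0.8 reported in
  vivo: the generator's narrow between-subject spread (θ_hot over a 15%
  MSO range against a 5% grid; map areas confined to 29–32 electrodes)
  leaves little true variance for the agreement ratio, and the half-step
  offset between criteria does the rest. At n = 12 the map-area ICC can be
  undefined outright (all areas identical).
* The conventional criterion's caching (each level classified once) means
  a single misclassified level near threshold shifts the MT by one step;
  the real procedure's behaviour on re-visits is not documented and is not
  modelled.
* The stop rule's alternative three-level reading, and electrode-order
  policies other than uniform random, are not implemented.
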