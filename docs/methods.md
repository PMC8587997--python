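# Methods

`gaitprint` implements a complete pipeline for gait-based person
identification and its explanation: a synthetic running-kinematics
generator, gait-event detection and step-cycle extraction, outlier
screening and scaling, a shallow identification network, layer-wise
relevance propagation (LRP), and a principal-subspace overlap statistic
that separates *unique* from *generic* movement characteristics. This note
records the models, the defaults and why they were chosen, the numerical
conventions, and what the synthetic experiments can and cannot show.

## Data representation

The unit of analysis is the **step cycle**: the period between two
consecutive touch-downs of opposite feet, time-normalized to a fixed grid
of `T` points (the canonical convention is `T = 100`). Each cycle carries
18 joint locations — the six spine joints L5S1, L4L3, L1T12, T9T8, T1C7
and C1Head, plus shoulder, elbow, wrist, hip, knee and ankle each in a
standing-side and a swinging-side role — with three movement planes per
joint, ordered abduction (frontal), rotation (transverse), flexion
(sagittal). Flattened joint-major with the timepoint running fastest, a
canonical cycle is a vector of `18 x 3 x T` variables: 5400 at `T = 100`.
All modules share this layout (`gaitprint.layout.VariableLayout`).

Because the 5400-input network (10800 hidden nodes, ~78M weights) is far
too large to train repeatedly in routine testing, the layout is parametric
in `T`. The *reduced* scale used by the test-suite and the acceptance
script sets `T = 30` (1620 variables, 3240 hidden nodes); full scale
remains the documented default for real recordings. Reducing `T`
subsamples the phase grid only — the joint roster, planes and every
processing rule are identical at both scales.

## Synthetic cohort generator

The generator emulates a cohort of trained runners recorded at 240 Hz over
three trials per participant (two training runs "CR"/"WR" and a held-out
run "TR"), with known ground truth for everything downstream:

* **Generic waveform.** Every joint/plane trajectory is a truncated
  Fourier series (4 harmonics) in step phase, shared by the whole cohort,
  with physiologic amplitude scales (sagittal ranges largest: knee ~55
  deg, hip ~35 deg; frontal/transverse ~3-8 deg). Spine
  frontal/transverse series use a sine-only basis so they vanish at
  touch-down and alternate sign between left- and right-standing steps —
  exactly the asymmetry that trunk mirroring later removes. Each extremity
  is one stride-periodic series whose two halves become the standing- and
  swinging-role trajectories, keeping each physical leg's channel
  continuous as roles alternate.
* **Planted individuality.** Participants differ through signature bumps:
  Gaussian deviations in phase (sigma 20-35% of the window width),
  multiplied by a flat-top (Tukey, 25% edge taper) window so the deviation
  is identically zero outside its phase window. Defaults plant bumps in
  the windows 25-35% and 70-80% of the step cycle, in all three planes of
  ten joints (four spine joints and the six lower-extremity roles),
  with per-participant random centre, width, sign and amplitude
  (`signature_amplitude`, default 10 deg, jittered 0.8-1.2x). The bump
  geometry mirrors where real runners are reported to be most
  distinguishable (mid-stance and mid-swing; spine and lower
  extremities); the amplitude is at the upper end of reported
  inter-individual differences in running kinematics so that the planted
  construct is unambiguous: it is the ground truth that relevance
  rankings are validated against, and an oracle whose signal drowned in
  shared variance could not validate anything.
* **Noise model.** White measurement noise per sample (default sd 1.5
  deg), per-step scaling of bump amplitudes (sd 10%), per-step duration
  jitter (sd 3% of the 0.35 s mean step), and a per-participant cadence
  offset (sd 2%). A `coefficient_jitter` knob can perturb the shared
  Fourier coefficients per participant; it defaults to 0 so that planted
  bumps are the *only* deterministic individuality and the signature mask
  is a complete oracle.
* **Foot/toe heights.** Each marker follows a low stance plateau (1 cm)
  plus a `sqrt(sin)` swing arc (foot peak 15 cm, toe 10 cm), with the
  standing leg in contact for 60% of its step cycle. The arc's steep
  approach near ground contact makes threshold crossing sharp, which is
  what keeps threshold-based event detection accurate; a configurable
  `strike_offset_s` shifts toe contact relative to foot contact to emulate
  rear- vs forefoot strikes. Heights carry 2 mm of sensor noise and are
  clipped at zero.

Everything is seeded through `numpy` `SeedSequence` streams: identical
configurations reproduce trials bit for bit, and each (participant, trial)
pair draws from an independent stream.

What the generator does **not** emulate: soft-tissue artifact, sensor
drift, asymmetric pathology, speed changes within a trial, or broad-band
individual differences beyond the planted windows (unless
`coefficient_jitter` is enabled). Passing the synthetic acceptance suite
therefore demonstrates that the pipeline recovers *planted, localized*
individuality under realistic noise — not that real runners are
identifiable; that claim belongs to studies on real recordings.

## Event detection and cycle extraction

Per side, swing maxima of the mean foot/toe height (peaks at least 0.2 s
apart, prominence 25% of the channel range) delimit search windows.
Within each window, touch-down is the first sample at which either the
foot or the toe height drops below that channel's window-local minimum
plus 2 cm; take-off is the last such sample. Window-local minima make the
rule drift-tolerant; using both markers makes it strike-pattern-invariant.
On synthetic ground truth the mean absolute touchdown error is ~2 ms at
240 Hz (the detector fires at the threshold crossing just before contact),
comfortably below the ~10 ms accuracy reported for such threshold rules
against instrumented treadmills.

Cycles span consecutive touchdowns of opposite feet (same-side pairs —
a missed event — are skipped with a warning; the trailing partial segment
is dropped). Each cycle is linearly resampled to `T` points including both
endpoints, chosen over spline interpolation for monotonicity and absence
of ringing. For left-standing cycles, spine frontal- and transverse-plane
angles are sign-flipped; extremity channels are relabeled left/right to
standing/swinging. The operation is an involution, which the tests
exploit.

## Outlier screening and scaling

Per participant, flattened cycles are reduced to loadings on their first
three principal axes (mean-centred PCA, no variance scaling) and screened
with **local outlier probabilities** (LoOP): the probabilistic set
distance of a point is `lambda` times the quadratic mean of its
k-nearest-neighbour distances; its PLOF compares that with the expectation
over the neighbours; PLOF values are normalized by their quadratic mean
and mapped through the Gaussian error function. Parameters are the
standard defaults (`k = 20`, `lambda = 3`, cutoff 0.5). Note that LoOP at
cutoff 0.5 flags ~6% even of a perfect Gaussian cloud — edge points
genuinely sit in lower local density — so a few percent of removals on
clean data is expected behaviour, not a defect. Participants with too few
cycles for the neighbourhood are kept unscreened, with a warning.

Surviving cycles are scaled individually: z-scored over the cycle's own
variables, then divided by the maximum absolute z so the extreme value
sits exactly at -1 or +1. The statistics are per *cycle*, not per
variable; the alternative reading (per-variable across cycles) would
destroy the within-cycle amplitude relations that the network and LRP
operate on. Scaled cycles are stacked row-wise into one data matrix with
a deterministic (participant, trial, onset) row order.

## Identification network

A three-layer fully connected network: `n` inputs (one per variable),
`2n` tanh hidden nodes, one linear output per participant, read out
through a softmax. Training: softmax cross-entropy, plain mini-batch
gradient descent, batch size 25, epoch cap 1000, on a seeded draw of
cycles per participant from the pooled CR/WR data; evaluation classifies
every TR cycle, and accuracy per participant is
`n_correct / n_total * 100` with the overall ratio cycle-weighted.

Choices the architecture leaves open, and how they were fixed:

* **Loss/optimizer**: softmax cross-entropy with plain gradient descent is
  the simplest fully reproducible scheme for a ~200-sample separable
  problem. Learning rate 0.05: at 0.01 the loss is still ~1.6 when
  training accuracy first reaches 100%, and a barely converged network
  produces diffuse, initialization-dominated relevance (see below).
* **Initialization**: uniform on the Glorot scale shrunk by
  `init_scale = 0.2`, seeded. Shrinking matters for attribution, not for
  accuracy: epsilon-LRP credits input variables through *whatever*
  weights exist, and at Glorot scale the never-updated random weights of
  uninformative inputs retain enough magnitude to soak up relevance.
* **Early stopping**: training stops once training accuracy is 100% *and*
  the loss is at or below 0.05 for 10 consecutive epochs, under the
  1000-epoch cap. Stopping on accuracy alone halts far from the loss
  minimum; driving the fit toward the max-margin solution grows the
  discriminative weight structure relative to the bias-like structure and
  markedly sharpens the relevance ranking.

On the default synthetic cohort, five training cycles per participant
yield >99% held-out accuracy and ten cycles yield 100%.

## Layer-wise relevance propagation

The pre-softmax score of the correct output node is redistributed with the
epsilon rule, `R_j = sum_k z_jk / (z_k + eps * sign(z_k)) * R_k` with
`z_jk = a_j * w_jk` and `z_k = sum_j z_jk`; biases are excluded from the
denominators so total relevance is conserved up to epsilon-driven error at
every layer (the test suite asserts conservation per layer against a
loop-based oracle). The tanh nonlinearity is treated as transparent — the
standard treatment for element-wise activations. Only correctly classified
held-out cycles are explained; passing a misclassified cycle is a contract
violation.

Raw patterns are smoothed along each `T`-point trajectory with the kernel
(0.25, 0.50, 0.25), applied twice (a knob allows more passes); smoothing
never crosses trajectory boundaries, since adjacent flat indices of
different joints are not temporal neighbours. Edge samples use the
truncated kernel renormalized to sum to one (2/3, 1/3), preserving the
pattern's total mass without inventing data. Patterns are then averaged
per participant, rectified, normalized to their maximum (values in [0, 1],
maximum exactly 1), averaged across participants, normalized again, and
sorted in descending order; ties break by ascending flat index so the
ranking is reproducible.

On the default cohort the top 10% of this ranking falls predominantly
inside the generator's planted-signature mask. Two effects keep recovery
below 100% and are worth understanding before interpreting real-data
rankings: (1) smoothing spreads relevance one or two grid cells past
window edges; (2) variables with large shared baselines acquire small
bias-like weights during training (a constant input component is
indistinguishable from a bias term for gradient descent), and epsilon-LRP
faithfully credits that pathway even though it carries no discriminative
information. Both are properties of the method, not bugs; the acceptance
bound (>= 80% of the top 10% inside the mask) was met under the default
conditions with these effects present.

## Subspace overlap

For a subset size `k` from the schedule 10, 15, 20, ... (step five, up to
all variables; a coarser schedule is configurable), the held-out cycles
restricted to the `k` most (least) relevant variables are freshly
projected onto their first three principal axes. Each participant's
projected cycles form a 3-D point cloud bounded by an **alpha shape**: the
Delaunay tetrahedra admitted in order of increasing circumradius until the
complex is a single connected region whose vertices cover every point —
the smallest such alpha, matching the MATLAB `alphaShape` default
criterion. Degenerate (coplanar) clouds fall back to the convex hull of
minutely jittered points, with a warning.

Overlap of participant a with participant b is estimated by seeded
Monte-Carlo membership sampling: points uniform in a's bounding box,
accepted if inside a's shape (membership via `Delaunay.find_simplex`
against the kept-tetrahedron set), and the fraction also inside b's shape,
expressed as a percentage of a's volume. The quantity is deliberately
asymmetric (a percentage *of a's volume*); the curve averages all ordered
pairs and reports mean +/- SEM per size. One sample set per reference
participant is reused against all partners, which leaves the estimate
unchanged and cuts the cost twenty-fold. A stage failure at one size
(e.g. a rank-deficient subset) records that size as missing and continues.

On the default synthetic cohort the most-relevant curve lies strictly
below the least-relevant curve at every tested size, and both decline as
the subspace grows — the unique/generic signature. Note the alpha-shape
caveat: at the critical alpha, the bounding volume of a *random* cloud is
concave and underestimates the occupied region (a uniform unit-cube sample
of 1000 random points yields ~0.83); the overlap statistic is therefore
comparative, not an absolute volume fraction. The analytic oracle tests
use uniform grids, for which the alpha shape is exact.

The extreme 10% of ranked variables (540 at full scale) are profiled by
movement plane (flexion/extension, ab-/adduction, int/ext rotation), by
cycle timepoint (raw counts and a 5-point moving average), and by joint
group (spine, upper, lower extremities).

## Pipeline, determinism, artifacts

`run_pipeline` sequences simulate, segment, preprocess, train, relevance,
overlap and profile; per-stage seeds derive deterministically from one
global seed, every artifact is persisted (arrays as `.npz`, tables as CSV,
logs as JSON) with a SHA-256 checksum in the run manifest, and a rerun
under the same configuration reproduces every numeric output bit for bit
(timings and timestamps aside). `validate_io_roundtrip` re-hashes and
re-parses every artifact. The `gaitprint` CLI exposes each stage as a
subcommand over the persisted intermediates, plus `all`.

## Problem sizes used in tests and the acceptance script

The suite and the acceptance script use the default 20-participant cohort
with 30 s trials at the reduced `T = 30` grid (1620 variables), which
keeps a full identification experiment to a few minutes on one CPU while
preserving every convention of the full-scale layout. Overlap curves in
the tests use a coarsened size schedule and 10^4-2x10^4 Monte-Carlo
samples per reference volume; the defaults (step 5, 10^5 samples) remain
available for full-scale runs.

## Known limitations

* The alpha-shape volume of sparse or elongated clouds is sensitive to the
  critical-alpha rule; overlap percentages should be compared within a
  run, not across datasets.
* LRP relevance depends on the trained network; different seeds reorder
  individual variables (the aggregate spatial pattern is stable, and the
  acceptance checks hold across the tested seeds).
* The generator's planted-signature oracle is only complete when
  `coefficient_jitter = 0`; with broad-band individuality enabled, mask
  recovery is no longer a meaningful target.
* Real recordings (e.g. exported motion-capture joint angles) can be fed
  in through the long-format CSV reader, but no vendor formats are parsed.
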