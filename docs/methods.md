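# Methods

This note documents the models, conventions and numerical choices behind
`manimouse`, in the order the pipeline applies them.

## Scope and data model

The package post-processes two synchronized data streams from an open-field
session of a mouse in a circular arena: (i) behavior video derivatives —
per-frame key-point coordinates (7 body points including both ears),
per-frame behavior class labels or probabilities over {running, sitting,
grooming}, and the arena image; and (ii) a miniscope calcium-imaging matrix
(neurons × frames, 15 Hz, GCaMP6f-type indicator). It does **not** perform
pose estimation, behavior classification, or calcium source extraction —
those belong to upstream networks and extraction pipelines; this package
consumes their outputs (or synthetic stand-ins) and carries them through to
group-level statistics.

## Synthetic data generator

No public dataset accompanies this analysis style, so the generator is a
first-class module and every downstream stage is exercised on its output.

**Calcium model.** Each neuron emits a Bernoulli event train (probability
`event_rate / fps` per frame — a discretized Poisson process) convolved with
a peak-normalized difference-of-exponentials kernel, `exp(-t/τ_d) −
exp(-t/τ_r)`, plus i.i.d. Gaussian noise. Defaults: rise `τ_r` = 0.07 s and
decay `τ_d` = 0.6 s (fast-indicator-like asymmetry), `event_rate` = 0.4
events/s, `noise_sd` = 0.05 (≈5% of the unit transient peak). Population
coordination is planted by a *shared* event train: independently per neuron
and frame slot, with probability `shared_factor` the slot is read from the
shared train instead of the neuron's own. This preserves each neuron's
marginal rate exactly while raising pairwise correlation monotonically in
`shared_factor`.

**What the group effect is, and why.** The two default cohort groups differ
*only* in coordination: the baseline group has `shared_factor` 0.5
(structured, coordinated ensembles) and the "compact" group 0.1
(decoordinated, homogeneous activity), both at 0.4 events/s. The design
question was which generator regime actually produces a *compact* manifold
(low intracluster distance) under the embedding used downstream. Measured
over a wide grid of (event rate × shared factor), t-SNE embedded spread
**increases** monotonically with both parameters: the perplexity-adaptive
bandwidths of t-SNE discard global scale, so any planted synchrony adds
similarity *structure*, which the embedding spreads out, whereas a
homogeneous cloud of many independent sources embeds as the tightest
possible blob. (The same monotonicity holds for joint multi-session
embeddings and, via total variance, for PCA/MDS.) A compact manifold —
"most points close together, low variability of overall circuit activity" —
therefore corresponds in this model family to *loss of coordinated ensemble
structure*, not to extra synchronous events. Planting the effect purely in
`shared_factor` at equal rates has a second virtue: frame-permutation
surrogates of the two groups are *statistically identical*, so the shuffle
control removes exactly (and only) the feature that separates the groups,
which is the logic the control exists to certify.

**Behavior model.** A three-state semi-Markov chain with geometric
(memoryless) dwell times; per-frame leave probability `1/(dwell·fps)`, exit
uniformly to the other two states. Default mean dwells: running 2 s,
sitting 4 s, grooming 3 s — dwell times of a few seconds are what the
2-s analysis windows are designed around.

**Key points.** A rigid 7-point body frame (nose, ears, neck, body center,
tail base, tail tip) rides on a Gaussian-smoothed random-walk position and
heading, radially clipped inside the arena. Ears sit symmetrically so the
inter-ear distance is exact by construction — this is the reference scale
for PCK.

**Not modeled:** biophysical indicator dynamics and saturation, spatial
footprints, motion artifacts, photobleaching, place-field structure, or any
behavior–neural coupling. Passing tests therefore certify the *analysis
chain*, not fidelity to any particular biological dataset.

## Composite frames

Behavior is temporal, so single frames under-determine it. A composite frame
encodes a 21-frame window into one RGB image: G = mean of the 10 preceding
frames' green channels, R = the scored (center) frame's red channel, B =
mean of the 10 following frames' blue channels. Means are computed in
floating point and rounded half-up to 8-bit. Streams skip the first and
last 10 frames of a video (windows are never padded) and the skip count is
logged. Centers step by a configurable stride because training pipelines
differ in how densely they sample.

## Arena segmentation and zones

The arena is a disc split into a central zone (bounded by a painted marker
circle) plus three annuli of equal width out to the wall. From an overhead
image, the wall is found by a circular Hough transform on a Canny edge map
(σ = 2) and refined by an algebraic (Kåsa) least-squares circle fit over
edge pixels within 6 px of the coarse circle — the refinement centers the
estimate between the two edge responses of a finite-width boundary ring,
removing the ±2 px one-sided bias of the discrete Hough radius. The central
marker is the connected edge component nearest the center within a quarter-
size region of interest; its radius is the midpoint of the 10th and 90th
percentiles of its band's radial distances (robust to the pixel-count
imbalance between the ring's two edge responses). A Hough accumulator below
0.3 (normalized) is reported as a detection failure rather than a guess.

Zone membership uses half-open radial bins `[0, r_c) [r_c, r_i) [r_i, r_m)
[r_m, r_o]` — outer edge inclusive, everything beyond labeled `outside` —
so every point gets exactly one label.

## Key-point evaluation (PCK)

A predicted point is correct when its Euclidean error is at most
`d_factor × D`, with `d_factor` = 0.25 and `D` the *per-frame* ground-truth
inter-ear distance. Per-frame D (rather than a session mean) makes the
criterion stricter exactly when the animal is close to the camera and
degrades gracefully with perspective; the boundary is inclusive ("within a
circle" read as a closed disc). Percentages are per key point over frames,
then averaged over key points.

## Behavior-label denoising

Stage 1 is a discrete-state forward Bayes filter — the categorical analogue
of a Kalman predict/update cycle: predict `p′ = Tᵀp` with a row-stochastic
behavior transition matrix `T`, update `p″ ∝ p′ ⊙ obs`, renormalize. The
default `T` has 0.9 self-transition with the remainder split evenly (a mild
persistence prior; upstream classifiers rarely publish their matrix, so it
is a config knob). The filter initializes from the first observation. If a
prediction and observation have disjoint support the filter resets to the
observation — the only consistent continuation for hard one-hot streams
under near-deterministic dynamics. Stage 2 replaces each *non-overlapping*
25-frame block by its modal label (a trailing short block uses its own
mode); ties break to the label of the block's central frame. Mode smoothing
on disjoint blocks is idempotent, which a sliding-window version is not.

## Kinematics

Speed is `‖Δposition‖ × fps` of a reference point (default: ear midpoint —
always present and robust to limb jitter), with the first frame copying the
second. The smoothed trace is a Savitzky–Golay filter, window 15 frames
(1 s at 15 Hz), order 3, clipped at zero. Zone occupancy classifies the
reference point per frame; occupancy seconds sum to session duration by
construction.

## Manifold construction

Sessions are segmented into non-overlapping 30-frame windows (2 s at
15 Hz), starting at frame 0, trailing remainder dropped and logged. Each
window is flattened frame-major: `x[i·N + j] = f_{t+i}[j]`, giving one
point in `R^{30N}` per window — 150 points for a 5-min session. Traces are
not z-scored by default (a `standardize` flag exists).

Embeddings delegate to established implementations: scikit-learn t-SNE
(Barnes–Hut, Euclidean metric, PCA initialization, perplexity 30 clamped to
`(n−1)/3` with a logged warning), PCA, FastICA, SMACOF MDS, and umap-learn.
The default is 2-D t-SNE: descriptors (intracluster distance, ellipses) are
defined on the 2-D projection, and 2-D is also the stable choice at
per-session point counts. All randomness is seeded; the embedding seed is a
pipeline parameter.

**Numerical stability floor.** t-SNE embeddings of very small sessions
(≲60 windows, i.e. under ~2 min of recording) can blow up — isolated
points are ejected far from the cloud, inflating session descriptors by
orders of magnitude. All default analyses therefore run at ≥90 windows per
session; the synthetic study uses 150 (the 5-min session length).

**Intracluster distance.** For a session's embedded points,
`ICD = 1/(n(n−1)) Σ_i Σ_{j≠i} ‖x_i − x_j‖₂` — the mean over ordered pairs,
equal to the mean over unordered pairs, computed from the condensed
distance vector. Lower values mean a more compact (more stereotyped)
population trajectory. Sessions are embedded independently (per-session
embedding), keeping sessions exchangeable units for classification.

## Behavior epochs and ellipse descriptors

Each 2-s window inherits the behavior label that wins the frame count among
its 30 frames (tie → central frame's label). Per behavior with ≥3 windows,
the 2-D sub-cloud is summarized by its sample covariance (n−1 denominator)
eigenvalues λ1 ≥ λ2 and the descriptors

    area          S = π · λ1 · λ2
    eccentricity  c = √(1 − λ2²/λ1²)

This eigenvalue-product form (`convention="eigenvalue"`) is the default:
the descriptors enter only *relative* group comparisons, and any fixed
monotone reparameterization preserves directions and classifications. The
conventional 95% confidence ellipse — semi-axes `√(χ²₂,₀.₉₅ λ)`, area
`π χ² √(λ1 λ2)`, eccentricity `√(1 − λ2/λ1)` — is available as
`convention="standard"`. Note the eigenvalue-product convention makes area
scale as the *fourth* power of isotropic point-cloud scale (each eigenvalue
scales quadratically); eccentricity is scale- and rotation-invariant in
both conventions. Zero leading variance is a degenerate-geometry error,
never a silent zero.

## Group classification and shuffle control

Sessions are the classification unit (a `mouse` split unit can be selected;
session-level splitting matches how per-session descriptors enter group
statistics). "10 independent repeats" is implemented as 10 independent
stratified train/test resplits (test fraction 0.3); splits are drawn per
group in label-sorted order so the report is invariant to which group is
named first.

With a single feature the encoder is a decision threshold: candidate cuts
are midpoints between consecutive sorted training values (plus open ends),
both directions tried, training accuracy decides, first-best wins (fully
deterministic, no test peeking). With two or more features a Fisher linear
discriminant is fit on the training split. Metrics (accuracy, precision,
recall, F1; positive class = first-named group) are computed on the test
split only and aggregated as mean ± SEM (`sd/√n_repeats`).

The negative control regenerates every descriptor from temporally shuffled
recordings — default `permute_frames`, an independent random permutation of
the time axis per neuron, which preserves each neuron's value multiset
exactly while destroying all cross-neuron coordination;
`phase_randomize` (amplitude-preserving Fourier-phase surrogates, conjugate
symmetry maintained, DC fixed, Nyquist sign-randomized for even lengths) is
available for spectrum-preserving nulls. Original and shuffled reports are
compared per metric with two-sided Student's t or Mann–Whitney tests;
identical metric vectors return p = 1 by convention. Because the repeats
are resplits of one cohort they are not independent samples, so these
p-values calibrate adequately only when session descriptors are in the
stable embedding regime (see the stability floor above) — the null
calibration test checks precisely this.

## Problem sizes used in the validation suite

The synthetic study mirrors a realistic recording design: 2 groups × 12
sessions, 80 neurons, 4500 frames (5 min at 15 Hz), t-SNE seed fixed,
window 30 — and evaluates direction consistency over 10 cohort seeds. The
null-calibration study uses 10 sessions/group at 40 neurons × 2700 frames
(3 min; 90 windows, the stability floor) over 10 cohort seeds. These sizes
are the package's validation design; nothing in the implementation depends
on them.

## Known limitations

- The generator's planted effect is a coordination difference; it does not
  emulate disease physiology (amplitude changes, rate drifts, cell loss).
  Conclusions transfer to real data only insofar as group differences
  express themselves as manifold compactness differences.
- t-SNE intracluster distances are not comparable across sessions with very
  different window counts, and absolute values depend on embedding
  hyperparameters; only within-design comparisons are meaningful.
- The label filter assumes per-frame class probabilities; upstream
  networks emitting uncalibrated scores should be normalized first.
- Single-animal tracking only; the arena detector assumes one dominant
  circular boundary with an interior marker.
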