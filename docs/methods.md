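# Methods

This note records the models, numerical choices, and design decisions
behind `leapkit`, and what the synthetic benchmarks do and do not
demonstrate about real data.

## Trajectory model and neighbor lists

A trajectory is a dense array of positions for `n_units` tracked units over
`n_frames` frames, with persistent integer identities, an optional
orthorhombic per-frame box, per-axis periodicity flags, and a sampling
interval `dt` (frame times are `frame_index * dt`, 0-based). Triclinic
cells are rejected explicitly; units of length are carried opaquely
(Å, pixels, μm), so only ratios such as `rcut`/spacing matter.

Neighbor lists are built per frame with a kd-tree (`scipy.spatial.cKDTree`)
over the candidate units. Periodic axes are handled by wrapping coordinates
into the box and using the tree's toroidal topology; free axes are given an
artificial period larger than the data extent plus `2·rcut`, which makes
the torus metric coincide with the Euclidean one. This gives a single code
path, near-linear scaling, and exact minimum-image distances; equality with
an O(N²) brute-force oracle is asserted in the tests. `rcut` must be below
half the smallest periodic box edge. Descriptor centers and neighbor
candidates are independently configurable (e.g. descriptors on a surface
layer with the full system as neighbor pool — the default pool is all
units, since restricting the pool changes the physics being measured and
should be a deliberate choice).

## LENS

LENS compares the neighbor-identity sets of consecutive frames:
δ = #(union − intersection) / #(concatenation). Edge conventions: two empty
lists give δ = 0 (no environment, no change); a one-sided empty list
follows the formula and gives 1. The raw series has one value per
transition; the value at step *s* describes the change arriving at frame
*s* + 1 (`t0_frame = 1`).

## SOAP and τSOAP

The SOAP power spectrum is computed in-package. The neighbor density is a
sum of Gaussians of width σ at the neighbor positions relative to the
center (the center itself contributes no density, so an empty environment
is an exactly zero, flagged vector). The density is expanded in

- a radial basis φ_α(r) = (rcut − r)^(α+2), α = 1..n_max, orthonormalized
  with the analytic overlap matrix via S^{−1/2};
- complex spherical harmonics up to l_max,

and contracted over the magnetic index into p(n, n′, l), n ≤ n′. The
angular part of each Gaussian is the exact closed form involving the
modified spherical Bessel function i_l; it is evaluated through the
exponentially scaled Bessel function `scipy.special.ive`, so the
computation cannot overflow even for σ ≪ rcut. The radial integral uses
96-node Gauss–Legendre quadrature. Rotational invariance of the result is
exact by construction (verified to 1e−8 against randomly rotated frames,
the residual coming from the neighbor search, not the expansion).

Each neighbor's density is weighted by a smooth cosine cutoff function
decaying to zero over the outer `cutoff_width` (default rcut/4) of the
sphere. Without it, a neighbor vibrating across the cutoff radius enters
and leaves the density discontinuously, and these boundary flickers — not
genuine geometry changes — dominate the τSOAP noise floor on a thermally
vibrating lattice.

τSOAP is the Euclidean distance between consecutive L2-normalized SOAP
vectors, λ = √(2 − 2 p̂_t·p̂_{t+Δt}); inner products are clamped to [−1, 1]
before the square root so rounding cannot produce NaN, making √2 the exact
upper bound. The proportionality constant is fixed to 1: the later min-max
normalization makes any constant irrelevant. Steps touching a flagged empty
environment are missing (NaN) and propagate through smoothing, pairing, and
classification.

Defaults: n_max = 8, l_max = 8, σ = rcut/8 for the calculator itself;
the one-call pipeline uses n_max = 6, l_max = 4, which resolve
lattice-scale rearrangements at a fraction of the cost. All are
configurable. 2D trajectories are embedded at z = 0.

## Smoothing and normalization

Both raw series are smoothed by a centered moving average with truncated
edge windows (no phase lag; width 1 is the identity; missing values are
excluded from each window). Normalization is min-max to [0, 1] over the
*whole dataset* — all centers jointly, per descriptor — preserving
cross-unit intensity comparisons; the recorded (min, max) bounds permit
inversion. A constant series normalizes to zeros with a warning. Note the
corollary: on an event-free system the normalized τSOAP is amplified
numerical noise, so quantitative contracts (e.g. "τSOAP = 0 after a pure
swap") are asserted on raw values.

## The LEAP plane, χ, and magnitude

The two normalized series are paired per (center, step); a step missing in
either component is missing in the pair. χ = (δ − λ)/(δ + λ) with
χ(0, 0) := 0 — a quiescent unit is "neutral", not diffusive or structural.
χ is computed on normalized components, so its sign structure inherits the
dataset-level scaling. The magnitude is the Euclidean norm of the pair.

## Classification

Two complementary modes:

- **State models.** A Gaussian KDE (Scott's-rule bandwidth) summarizes the
  value distribution; extrema are located with a prominence filter (1% of
  the peak height) that suppresses the KDE's numerical micro-wiggles. A
  Gaussian mixture with one component per KDE peak (means initialized at
  the peaks, refined by EM via scikit-learn) yields states sorted by mean;
  values outside the central 95% interval (|x − μ| > 1.96σ) of *every*
  state are outliers — the rare, relevant fluctuations. This is a
  deliberately simple univariate state finder; time-resolution-optimizing
  cluster analysis is out of scope.

- **Threshold quadrants.** Explicit (or KDE-tail-derived) thresholds on the
  two components split the LEAP plane into quiescent / LENS-dominated /
  τSOAP-dominated / mixed. Boundaries are inclusive on the quiescent side.
  `tail_threshold` places the threshold where the KDE-smoothed distribution
  holds a given tail mass (default 2%) beyond the dominant peak; it errors
  when two dominant peaks of equal height make "the" tail ambiguous.

Maximal runs of a label become events with start/end frames and times.

## Correlation statistics

- Inter-event intervals are measured between successive event *start*
  times. The headline construction is two-stage, one mean interval per
  center with ≥ 2 events, then statistics across centers; a pooled-interval
  mode is also provided (and is the right input for least-squares CDF
  fitting, since per-center means of many intervals concentrate and are no
  longer exponential). An optional restriction keeps only events before the
  center's first event of another type (structural activity *preceding* a
  diffusive event).
- The exponential model P_{n≥1} = 1 − e^{−τ/τ*} is fitted by MLE
  (τ* = sample mean, exactly) and by least squares against the empirical
  CDF at plotting positions k/(n+1); both are reported, MLE is the
  default headline.
- Counts of type-a events preceding each type-b event are windowed by
  default (since the previous b-event); an unwindowed mode exists. The
  positive counts are fitted with the same exponential form to give a
  characteristic count n*.
- Cross-class distance densities pool all minimum-image a–b distances over
  frames, histogrammed to unit area (Freedman–Diaconis bin count by
  default), optionally rescaled by a first-neighbor distance.
- g(r) uses kd-tree pair enumeration and ideal-gas shell normalization at
  the subset's density (2D areas or 3D volumes); per-bin standard errors
  follow Poisson counting.
- Spike coincidence reports the histogram of pairwise |Δstart| across
  centers and the fraction within a window.
- Event-aligned χ traces re-index each center's χ series to its first
  event start (offset 0 = the event step) and average across centers,
  with NaN padding outside the series.

## The synthetic generators

The generators are first-class, tested code; they define the study
conditions under which the package's claims are verified.

- **Vibrating lattice**: simple-cubic (or square) sites plus i.i.d.
  Gaussian jitter per frame, amplitude 0.05·spacing by default (must stay
  below 0.3·spacing). I.i.d. jitter rather than integrated dynamics is a
  deliberate choice: it gives analytic control over event purity. Its cost
  is that the per-step noise displacement is √2·amplitude — *larger*
  relative to single-frame amplitude than physical, temporally correlated
  vibration would give, which makes the noise floor conservative.
- **Swap**: two units farther apart than 2·rcut exchange positions from the
  event frame on. On a frozen lattice this gives exactly (LENS, τSOAP) =
  (1, 0) at the event step; the 2·rcut precondition is enforced.
- **Rearrangement**: every neighbor in the center's *persistent* shell
  (inside rcut on both sides of the transition) moves by the displacement
  scale along a random direction with a guaranteed inward radial component
  (≥ 40% of the displacement) — a compression-type collapse. Inward motion
  cannot eject a neighbor, random per-neighbor directions break rigidity
  (a rigid rotation of the shell would be exactly SOAP-invariant), and the
  radial component is what the descriptor resolves best. A post-hoc check
  verifies the center's list is unchanged across the event transition;
  fresh directions are drawn on violation, the scale halved only as a last
  resort. An optional `revert_after` relaxes the shell back — a transient
  rattling event — which the mixed benchmark uses so that persistent
  distortion cannot give later swap events genuine mixed character.
- **Slider**: one unit translated one site per step; its neighbor
  identities turn over every step (sustained high LENS, χ > 0 plateau).
- **Slip plane**: all units on one side of a plane rigidly shifted by one
  lattice vector; every interface-adjacent atom replaces one of its six
  first-shell neighbors at the same step (LENS = 2/12 each,
  simultaneous by construction).
- **Wave field**: a 2D jittering lattice crossed left-to-right by an
  activity band. At band entry, entering particles in the same front
  column exchange sites with partners far away in y (identity turnover —
  LENS spike, χ > 0); while inside the band they ride a moving sinusoidal
  compression (geometry change with mostly preserved identities — τSOAP
  activity, χ < 0). Ground truth records each particle's entry frame,
  which increases linearly with its x position.
- **Poisson event series**: per-center exponential interarrival times,
  vectorized, for τ* parameter-recovery checks.

Every injected event is mirrored in a tidy ground-truth table
(event_type, frame, id); all generators are deterministic given their seed.

What passing these benchmarks shows: the formulas, conventions, and
pipeline plumbing behave exactly as specified on systems where ground truth
is knowable. What they do not show: performance on real MD noise (
temporally correlated, anharmonic, with genuine mixed events), real
tracking artifacts (broken tracks, localization error), or the
heavy-tailed descriptor distributions of systems near criticality.

## Benchmark problem sizes

The shipped benchmarks run on desk-scale systems chosen to keep the full
suite fast while leaving comfortable statistical margins: 6×6×3 frozen
lattices for the exact contracts; 1,000 random periodic points for the
neighbor oracle and 10,000 random list pairs for the LENS oracle; 500
centers × horizon 10,000 at rate 1/2 (≈2.5 M intervals) for τ* recovery;
a 7×7×4 lattice × 60 frames with 10 swaps + 10 rearrangements for
classification recall; 5,000-particle ideal gases for the spatial nulls;
and a 400-particle, 30-frame wave field for the χ sign pattern.

## Known limitations

- Orthorhombic boxes only; no trajectory alignment or drift unwrapping.
- Single-species SOAP by default (a species label is carried but
  per-species channels are not expanded).
- The univariate state finder assumes roughly Gaussian peaks; strongly
  skewed state distributions will mislocate the 95% interval.
- Dataset-level min-max normalization couples thresholds across the whole
  dataset: adding data rescales both components (χ is invariant under
  joint rescaling, thresholds are not).
- `tail_threshold` on a distribution whose tail mass exceeds the requested
  fraction (very frequent events) returns a threshold inside the event
  population rather than between noise and events.
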