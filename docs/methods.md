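# Methods

This note records the model choices, parameter conventions, and numerical
decisions behind `cootseg`, and what the synthetic evaluation does and does
not establish.

## Geodesic transform and cue maps

The discrete geodesic distance uses a **pure intensity cost**: each step
between adjacent pixels costs |I(a) − I(b)| (the Euclidean norm of the
channel difference for vector-valued images), with no spatial length term.
Consequences worth knowing:

- Flat regions cost nothing to traverse, so a click "floods" its whole
  iso-intensity basin with cue value 1. This is what makes the encoding
  contrast-aware and parameter-free; it also means a cue map on a noiseless
  constant image is 1 everywhere.
- The transform is *scale-sensitive*: multiplying intensities by k
  multiplies distances by k, and the cue exp(−D) has a useful dynamic range
  only when typical accumulated costs are of order 1–10. This drives the
  pipeline's two scale conventions (below).
- Distances come from Dijkstra's algorithm on the explicit 4/8- (2D) or
  6/26-connected (3D) pixel graph — exact, not a raster-sweep
  approximation, which is what permits bit-exact oracle tests. Default
  connectivity is 8 (2D) / 26 (3D). Voxel spacing is recorded on images but
  deliberately not folded into the cost (that would reintroduce a
  parameter).

## Scale conventions in the pipeline

Two stages consume geodesic distances with *different* needs:

- The **initial-phase cue map** should describe the whole crop, so the crop
  is min-max normalized to [0, 1] first (the normalization module's default
  target interval). Crossing the tumour boundary then costs a fraction of
  1, and exp(−D) grades smoothly from the clicks across the object.
- The **refinement maps** need α = exp(−min(Df, Db)) to be a *local* bump
  around each corrective click — the fusion should leave P untouched away
  from clicks. They are therefore computed on the crop's native intensity
  units, where even the noise floor (σ ≈ 5 intensity units per step) makes
  α negligible a few pixels from a click. Computing them on the normalized
  crop instead makes α ≈ 0.5 crop-wide and lets a single background click
  erase the segmentation — measured, not hypothetical.

## Baseline segmenter

The initial segmenter is a deliberately simple, deterministic stand-in for
a learned model, preserving the (image, cue) → (Pf, Pb) dataflow so any
trained predictor can be registered in its place:

    Pf = clip(w · cue + (1 − w) · similarity, 0, 1),  Pb = 1 − Pf,

with similarity = exp(−(I − μ)² / 2s²), μ and s the mean/std of intensities
where cue ≥ 0.99 (the clicked basin), Gaussian-smoothed with σ = 2 px;
w = 0.5. With no cue ≥ 0.99 pixel it degrades to Pf = cue. It has no
hidden randomness; identical inputs give identical outputs.

## Fusion and CRF refinement

Fusion is the convex combination R = (1 − α) P + α E; because Ef + Eb = 1
(they are a two-way softmax of −Df, −Db) the pair R stays normalized. An
empty click side is assigned the fixed distance 10¹⁰, which drives its
exponential to exactly 0 in floating point; with no clicks at all the maps
are neutral (E = 0.5, α ≈ 0) and flagged.

The CRF couples the negative-log unaries of R (probabilities clamped to
[ε, 1−ε], ε = 10⁻⁶) with a contrast-sensitive Potts term over the 8/26
neighborhood, weighted by λ = 5 and divided by the Euclidean inter-pixel
distance (1, √2, √3). The contrast scale σ defaults to a **robust noise
estimate**, 1.4826 × median |ΔI| over neighbor pairs in the crop. The more
obvious choice — the std of crop intensities — absorbs the very
object/background contrast the term should preserve (crops are bimodal),
turning the Potts term into uniform shrinkage that can delete the object;
the median of neighbor differences sees essentially only noise.

The energy is submodular, so the global minimum subject to the click
constraints is found by one max-flow/min-cut. Numerics: capacities are
fixed-point integers (scale 2²⁰ per unit energy), because the solver
accumulates in 32-bit integers the scale is automatically lowered so that
an upper bound on the min cut (the energy of the click-consistent
threshold labeling) stays below 2³⁰; clicked pixels get terminal capacity
2³¹ − 1, unreachable by any finite cut. Label recovery walks the residual
graph from the source. On small grids the cut's energy matches exhaustive
enumeration to 10⁻⁹.

Each refinement round recomputes Ef, Eb, α from the cumulative corrective
click set, fuses against the *original* initial probabilities (rounds do
not compound), and re-cuts with all corrective clicks as hard constraints.
Rounds with no new clicks therefore reproduce the previous round's mask
exactly.

## HOG features

Gradients are forward differences with the last row/column replicated
(border gradient 0); orientations are unsigned, θ ∈ [0°, 180°), with
θ = 0 where both differences vanish. The 64-wide × 128-high window tiles
into 8×8 cells; 16×16 blocks slide at stride 8 → 105 blocks. Votes are
per-pixel and unweighted by default (a magnitude-weighted mode exists
behind a flag); each block histogram sums to exactly 256. The selective-bin
plan (9 bins for flagged blocks, 4 elsewhere) is supplied as an external
block mask — the package does not recompute the mask from a training
corpus — and defaults to all-high.

For classifier input, descriptors are rescaled to per-block vote
*fractions* (counts / 256): bounded [0, 1] inputs keep the ELM's sigmoid
hidden layer out of saturation, which is worth ~0.3 accuracy on the
phantom task.

## ELM and COA

The ELM draws W, b ~ U[−1, 1] and solves β in closed form: the exact
Moore–Penrose pseudoinverse when ridge = 0 (used by the interpolation
tests), else the Tikhonov-stabilized normal equations. Module defaults are
L = 100 hidden units, sigmoid activation, ridge = 10⁻⁸; binary problems
use a single output column thresholded at 0.5 (ties → 1), multiclass uses
one-hot targets and argmax.

The COA minimizes a black-box fitness over a box. Per iteration, with
amplitudes A = 1 − t/T and B = 2 − t/T: every follower, with probability
0.5, moves about its leader (index 1 + (i mod NL)) by
leader + 2·R1·cos(2πR)·(leader − pos); otherwise it chain-averages with
its predecessor or wanders towards a uniform random point of the box.
Followers swap roles with their leader on improvement; leaders orbit the
global best with the B amplitude, drawing per-dimension random vectors
with probability P = 0.5 and shared scalars otherwise. gBest is elitist and
every position is clamped to the box after each move. One seeded generator
with a fixed draw order makes runs bit-reproducible. On the 5-D sphere
(box [−10, 10], N = 30, 200 iterations) the median best over 10 seeds is
~10⁻⁷, versus ~7 for an equal-evaluation random search.

COA-ELM searches the flattened (W, b) in [−1, 1]^{L(n+1)}; candidate
fitness is misclassification on a stratified held-out fraction (default
20%) with β refit in closed form per candidate, and the returned model
refits β on all data. The with/without-COA comparison
(`elm.compare_coa_vs_plain`) is paired on a single stratified validation
split — selection and comparison use the same split, both arms fit β on
the training fraction only — which isolates exactly what the optimizer
contributes.

## Synthetic phantoms: what they emulate, and limits

The generator reproduces the structural difficulty of the target regime —
small lesions whose mean intensity sits only `contrast` units under the
surrounding tissue, inside a large organ blob, under a smooth bias field
and additive noise. Benchmark conditions, fixed once: 256×256 frame, one
tumour of radius 5–12 px for the segmentation suites, contrast 20, noise
σ 5, bias amplitude 0.05; the classifier calibration uses the easier
contrast 40 / σ 2 regime with 60 + 60 samples, L = 200 and ridge 1.0
(the 945-dimensional descriptors need more capacity and shrinkage than the
module defaults aimed at small feature spaces).

What the phantoms do **not** model: real CT texture and organ context,
partial-volume boundaries, Hounsfield calibration, slice anisotropy, and
inter-patient variability. Passing the seeded suites shows the pipeline's
machinery is correct and well-conditioned in a controlled low-contrast
regime; it is not evidence of clinical-grade accuracy.

Measured suite behavior (2-D, one CPU): initial-phase mean Dice ≈ 0.97
over 20 phantoms; three oracle-click refinement rounds end at mean Dice
≈ 0.999, with per-round Dice non-decreasing in ≥ 90% of cases at the
pinned suite seed (0.70–0.95 across other seeds — an early round
occasionally over-trims before later clicks correct it; the hard
constraints make recovery monotone thereafter). Mean initial Dice rises monotonically with
tumour contrast (≈ 0.74 / 0.97 / 1.00 at contrast 10 / 20 / 40).

## Degenerate inputs and conventions

- Constant image under min-max normalization → all-ef1 (no division by 0).
- Empty-vs-empty masks: Dice 1.0, flagged; zero-denominator metrics take
  their trivially-ideal value (or 0 for error rates), flagged; MCC is 0
  when a marginal vanishes.
- A mask thinner than the inward shift leaves clicks on the boundary
  pixels themselves; a single-pixel mask yields that pixel.
- Contradictory clicks (same pixel both labels) are rejected before the
  cut; labelings violating clicked pixels are rejected by the energy
  evaluator.
- Non-finite fitness values in the COA are treated as +∞.

## Known limitations

- The initial segmenter is a non-learned baseline; its accuracy ceiling on
  real data would be far below a trained model's, and the pipeline's
  quality numbers above are phantom-specific.
- The refinement's locality depends on the native intensity scale; images
  pre-normalized to tiny ranges would need an explicit σ/scale choice.
- 3-D works throughout but is tested at reduced sizes; the graph cut on
  full 512³ volumes would need a blockwise or banded solver.
- The selective-bin block mask is an input, not learned from data.
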