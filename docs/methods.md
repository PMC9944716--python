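# Methods

`nmgreg` registers a 3D volume (the *floating* image, e.g. a preoperative
CT angiogram) to a single 2D projection image (the *fixed* image, e.g. an
intraoperative angiogram) by optimizing the six parameters of a rigid
pose.  Every candidate pose is evaluated by rendering a digitally
reconstructed radiograph (DRR) of the posed volume and scoring its
similarity to the fixed image; the similarity is maximized coarse-to-fine
over a Gaussian image pyramid with a regular-step gradient descent.

## Rigid pose model

A pose is `(rx, ry, rz, tx, ty, tz)`: intrinsic Z–Y–X Euler rotations in
degrees about the volume's physical center, followed by a translation in
mm, `p' = R (p − c) + c + t`.  Rotating about the volume center keeps the
translation parameters small and interpretable.  Euler decomposition is
supported away from gimbal lock (`|ry| → 90°` raises an error rather than
resolving the ambiguity silently).

## DRR rendering

Each detector pixel is the line integral of volume intensity along its
ray, computed by fixed-step ray marching (step `ray_step`, default half
the smallest voxel spacing) with trilinear interpolation.  The volume is
treated as a trilinear field that decays linearly to zero over one voxel
beyond the boundary voxel centers, so the field's integral equals
`sum(voxels) × voxel volume` exactly and parallel projections conserve
mass — the property the analytic projector tests rely on.  Intensity is
integrated directly (no Beer–Lambert exponentiation): the similarity
metrics used downstream are insensitive to monotone intensity maps, and
the linear model admits exact closed-form oracles (homogeneous cube,
linearity, mass conservation).

Geometry: the detector normal is world +Y before posing; columns run
along +X, rows along +Z.  Parallel and perspective (point-source) modes
are provided.  Perspective is the benchmark default (source-to-isocenter
1000 mm, isocenter-to-detector 200 mm) because translation along the ray
axis is invisible to a parallel beam; under perspective it is observable
through magnification, albeit ~40× more weakly than in-plane motion —
which shapes several optimizer choices below.

## Similarity: weighted NMI + gradient difference (NMG)

Two complementary terms are combined:

* **NMI** `= 1 + MI(A,B)/H(A,B) = (H(A)+H(B))/H(A,B)` ∈ [1, 2], from a
  joint histogram (64 bins, per-image linear min–max binning, nearest-bin
  assignment, every pixel counted — fully deterministic).  Entropies are
  in bits.  Degenerate case: both images constant gives NMI 2 if the
  constants share a bin, else 1.
* **GD** `= Σ σ_v/(σ_v + I_dV²) + Σ σ_h/(σ_h + I_dH²)` with
  `I_dV = ∂A/∂m − s·∂B/∂m`, `I_dH = ∂A/∂n − s·∂B/∂n` (central
  differences, one-sided at borders).  The scale factor `s` is fit by
  least squares per evaluation (`s = ⟨g_a, g_b⟩/⟨g_b, g_b⟩`, 1 if B has
  no gradient); σ defaults to the variance of A's corresponding gradient
  component (floor 1e−8), which makes GD invariant to the reference
  image's intensity scale.

Raw NMI spans [1, 2] while raw GD scales with pixel count, so equal
weights on the raw values would be dominated by GD.  By default both are
rescaled to [0, 1] — `I_NMI = NMI − 1`, `I_GD = GD/(2N)` — and combined
as `NMG = α₁ I_NMI + α₂ I_GD` with `α₁ = α₂ = 0.5`; the optimizer
minimizes `cost = 1 − NMG`.  A raw (unnormalized) mode is retained.
NMG is deliberately not symmetric in its arguments: `s` and the auto
sigmas are referenced to the fixed image.

## Multiresolution pyramid

Levels are built by the classic REDUCE step with the 5×5 separable
binomial window (1,4,6,4,1)/16 (normalized, symmetric), border
replication, output size `ceil(n/2)`, spacing doubled.  One same-window
smoothing pass additionally precedes each reduce and is applied once at
the finest level.  Registration runs coarsest level first; each level's
optimum seeds the next.  At every level the candidate DRR is rendered on
a detector downsampled by the level's factor and then passed through the
same smoothing as the fixed level image, so at the finest level a fixed
image that is itself a DRR of the volume gives a cost of exactly zero at
the true pose — the pipeline's self-consistency anchor.  Only the 2D
comparison is downsampled; the 3D volume is projected at reduced detector
resolution instead of being resampled, which is cheaper and has the same
effect on the cost surface.

## Optimization

**Regular-step gradient descent (RSGD).**  The cost gradient is estimated
by central finite differences and each parameter moves a fixed step along
its own descent direction, `θᵢ ← θᵢ − αᵢ·sign(gᵢ)`, halving its step
(`relax = 0.5`) whenever its gradient direction reverses — in one
dimension this is exactly the textbook rule (fixed step along the
gradient, step reduced on direction change).  The step length is kept
*per parameter* because the 6-DOF cost is severely anisotropic: in-plane
translation decorrelates thin-vessel images within ~0.5 mm, while
translation along the ray only changes magnification by ~0.1 % per mm.  A
single shared step length is ground down by the strong axes' oscillation
near their optima long before the weak axis has travelled anywhere (we
measured exactly this failure: the shared step collapsed below its floor
within ~30 iterations while the out-of-plane translation still had >90 %
of its initial offset left).

Three further choices address the weak-axis endgame, all deterministic:

* **Step regrowth** (`grow = 1.2`, the customary resilient-propagation
  factor): a parameter's step grows mildly while its gradient direction
  stays consistent, capped at `step0`.  This rescues an axis whose step
  collapsed early from coupling bias — the apparent optimum of one
  parameter shifts while others are still far from theirs.  Relaxation
  (0.5) outpaces regrowth (1.2) near an optimum, so convergence is
  preserved.  Off by default in the optimizer; enabled by the
  registration driver.
* **Step-tied probes**: the finite-difference offset per axis is
  `clip(αᵢ, step_min, 0.5)` — the slope is measured over the distance
  about to be travelled.  Fixed 0.5-unit probes cannot see structure
  finer than 0.5, which leaves the search blocked at
  coordinate-stationary points ~0.3 mm from the true optimum.
* **Step-budget restarts** (`restarts = 2` in the driver): when every
  step has fallen below `step_min` with iteration budget remaining and
  the best cost still improving, the step lengths are reset to `step0`
  from the best point.  Each re-convergence tightens the strong axes'
  residuals, which in turn un-biases the weak axis (its conditional
  optimum is offset by roughly ten times the other axes' residuals).

Stopping: all steps below `step_min` (0.01), vanishing gradient, cost
plateau (`|Δcost| < 1e−6` for 5 consecutive iterations), or `max_iter`
(200 per level).  The returned optimum is the best point visited, not the
last iterate.  Per-level initial steps: 4.0 at the coarsest level, 1.0 at
the finest (halved per intermediate level).

**Parameter scales.**  Degrees and millimetres are treated as equivalent
units by default.  For the finer pyramid levels the driver additionally
balances per-parameter *image-motion* sensitivity: it measures the RMS
change of the DRR per unit change of each parameter at the initial pose
(valid anywhere, unlike cost curvature) and gives parameters that move
the image more than the median parameter a proportionally finer step,
clipped to [0.25, 1] so no axis's resolution is degraded.  The coarsest
level always runs at natural units — long uniform steps are what give it
its capture range (scales below 1 there measurably destroy capture).

**Baselines.**  Plain gradient descent (fixed step, no relaxation) and
Powell's direction-set method (scipy implementation, Brent line
minimization) are provided behind the same interface for comparison runs.

## Synthetic vessel phantoms and the benchmark

No paired volume/projection data ships with the package, so every stage
is validated on synthetic phantoms that reproduce what the metric
actually responds to: sparse, bright, curvilinear structure on a dark
background.  A phantom is `n_branches` (default 4) smooth random-walk
tubes with smoothly varying radius (1.5–3 mm) and antialiased
partial-volume rasterization in a 64³ grid at 1 mm spacing, plus optional
additive Gaussian noise (default off — the benchmark isolates geometric
convergence).  Randomness comes from numpy's seeded PCG64 generator, so
volumes are bit-reproducible across platforms.

A benchmark case fixes the ground-truth pose at zero, renders the
reference DRR with the perspective geometry above (128×128 detector,
pitch chosen so the magnified volume fits with ~40 % margin), and starts
from the canonical offset `(0, 0, 0, 10, −50, −70)` (deg, mm) scaled by
`extent/256` — 64 mm phantoms start at `(2.5, −12.5, −17.5)` mm, about a
third of the volume extent; successive trials add 20·extent/256 to each
translation.  Because the fixed image is the phantom's own DRR, recovered
pose error is measured exactly, with zero model mismatch; what passing
does **not** show is robustness to the background clutter, contrast
dynamics, soft-tissue occlusion, and projection-model mismatch of real
angiograms — the generator makes no attempt to emulate those.

Typical behaviour at these conditions (one CPU): ~30–40 s per
registration, 130–180 iterations across both levels, all six parameters
recovered to well within 0.05°/0.05 mm in most seeds.  The weakly
observed out-of-plane translation is the accuracy bottleneck; its
residual is set by the coupling floor (≈10× the other axes' residuals)
and occasionally lands near 0.05 mm.

## Numerical choices and degenerate inputs

* Histograms: constant images map all pixels to bin 0; probabilities are
  exact ratios of integer counts.
* `0·log 0 := 0`; MI is clipped at 0 against roundoff; NMI's degenerate
  joint-entropy case is defined explicitly (above).
* Rays that miss the volume's bounding box contribute exactly 0; the
  ray–box intersection pads the box by one voxel so boundary
  interpolation is not truncated.
* Constant images are written to rasters as all zeros (their min–max
  range is empty); intensity normalization of a constant image returns
  all zeros.
* All optimizers are deterministic; identical inputs give bit-identical
  traces.  Registration results are reproducible run to run except for
  wall-clock fields.

## Known limitations

* Single-view registration: depth accuracy is fundamentally limited by
  perspective sensitivity; a parallel-beam setup cannot recover depth at
  all.  Biplane registration is out of scope.
* Rigid poses only; no deformation model.
* The Euler parameterization is undefined at `|ry| = 90°`.
* The phantom benchmark's accuracy statements transfer to real
  angiograms only qualitatively (see above).
* Throughput is single-image; there is no batch pipeline.
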