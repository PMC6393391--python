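# Methods

## Coordinate conventions

All skeleton mathematics is carried out in physical micrometres. A point
maps to the voxel `floor(coord / voxel_size)` (0-based, per axis), and a
voxel index maps back to the physical coordinate of its centre,
`(index + 0.5) * voxel_size`. Distances inside the intensity score are
measured in *voxel* units (displacement divided per-axis by the voxel size)
so that the Gaussian width σ keeps its meaning on anisotropic grids, and the
"three voxel sizes" margins of the branch frame use the *largest* per-axis
voxel size, the conservative choice. Skeleton points that fall outside the
volume contribute a zero score and zero gradient rather than raising: a
perturbed skeleton near a stack border must not abort the solver.

## The sparse-curvature segment optimizer

The optimized interior points of a segment minimize the sum of an intensity
term and an L1 penalty on second differences (a discrete curvature). The
model's premise is that tortuosity is *sparse*: few points of a real
neurite carry large curvature, so the L1 penalty (whose proximal map is the
soft threshold) zeroes most second differences while allowing isolated large
ones — corners survive, noise wiggle does not. The constrained reformulation
introduces split variables `d_i = 2p_i − p_{i−1} − p_{i+1}` and multipliers
`r_i`, and each split-Bregman sweep performs:

1. **Position update.** Joint gradient descent over all interior points on
   the augmented Lagrangian, endpoints frozen; 20 fixed-size steps. The
   gradient aggregates the analytic intensity gradient, the adjoint of the
   second-difference operator applied to `r`, and (by default) the
   `(1/μ) Dᵀ(Dp − d)` term of the quadratic coupling. The coupling term is
   part of the Lagrangian being minimized, so it is included; a config
   switch (`p_update_includes_quadratic=False`) exposes the variant without
   it for comparison.
2. **Shrinkage update.** `d_i ← shrink(Dp_i + μ r_i, λμ)` — the closed-form
   minimizer of the d-subproblem. The L2 comparator replaces this single
   line with the ridge shrink `v / (1 + 2λμ)`; everything else is shared, so
   the two pipelines isolate the penalty as the only difference.
3. **Multiplier update.** `r_i ← r_i + Dp_i − d_i` (additive form).

Five sweeps are the operating point; more do not measurably improve the
result. `d` starts at the second differences of the input and `r` at zero.
Gradient descent with a fixed step was chosen for the nonconvex, coupled
position subproblem because it is self-contained and exactly deterministic;
no line search means no data-dependent branching.

### Parameter defaults

| parameter | default | meaning |
|---|---|---|
| σ | 1.73 voxels | Gaussian width of the intensity score; matches the PSF-scale blur of a sub-2.5-µm neurite |
| halfwidth | 6 voxels | neighborhood half-extent, ⌈3σ⌉ — covers >99% of the Gaussian mass |
| λ | 1000 | curvature sparsity weight |
| μ | 0.001 | penalty scale; shrink threshold λμ = 1 µm, coupling weight 1/2μ = 500 |
| step size | 5·10⁻⁵ | fixed gradient step |
| inner steps | 20 | position-update steps per sweep |
| outer sweeps | 5 | split-Bregman iterations |

σ and the iteration counts are the published operating point of the method.
λ, μ and the gradient schedule have no published values; they were fixed
once on the synthetic fold-line phantoms (30°/SD 50 and 90°/SD 100) so that
the optimizer halves the distance to the true centerline while keeping a
corner-scale second difference, and then frozen. The balance to understand:
with 8-bit-scale intensities the magnitude of the intensity gradient is of
order 10³ per µm, so λ and 1/μ must sit at a comparable scale for the
curvature terms to matter at all; the shrink threshold λμ ≈ 1 µm separates
corner-scale second differences (≈ 2·spacing·cos(angle/2)) from
noise-scale ones. All values are config-overridable.

## The branch-point optimizer

Each bifurcation is treated as three segments meeting at a point. For one
pairing (through-path S1, side arm S2):

1. S1 is optimized on the real image and resampled so consecutive *chord*
   distances equal 1 µm (sphere-marching, exact across corners).
2. A *skeleton template* is synthesized: the resampled S1 rasterized,
   blurred with a σ = 1.73-voxel Gaussian and normalized to max 255. On this
   volume every S1 point is near-equally bright and brighter than any
   off-path point, so the intensity term confines the branch point to the
   skeleton without biasing it along the skeleton — which matters because in
   real images branch points are often *dimmer* than their surroundings.
3. The branch point is the discrete argmin over S1's resampled points of
   the template score plus `branch_lam` times the squared perpendicular
   distance from the line carried by the side arm's direction frame
   (reference point `p_fx` and unit vector `dv₁`, both required to clear
   three voxel sizes of margin). The projector `I − dv₁dv₁ᵀ` equals
   `dv₂dv₂ᵀ + dv₃dv₃ᵀ` for any orthonormal completion, so the objective
   never depends on a choice of `dv₂, dv₃`.
4. The side arm is re-anchored at the new branch point and re-optimized on
   the real image; steps 3–4 repeat until the branch point moves less than
   0.1 µm or 10 iterations elapse.

The template intensity term and the quadratic term live on different scales
(255-normalized intensities vs µm²), so the template score is divided by its
own maximum magnitude over the candidate set before the weighted sum;
`branch_lam` defaults to 1. Step 4 runs on the real image (the template
encodes only S1 and carries no information about the side arm).

The procedure runs three times — once per way of pairing the three segments
— and each pass *re-extracts* its local structure from the untruncated arm
walks with the standard budgets (through-path ≤ 16 traced points centred on
the branch point, side arm ≤ 21), mirroring the original extraction. The
three converged points are averaged. Passes whose side arm is too short to
carry a frame are dropped from the average; if all three drop, the input
branch point is returned with a warning.

## Whole-tree workflow

Branch nodes (≥ 2 children) are processed in increasing node-id order;
multifurcations are decomposed into successive bifurcations — (child 1,
child 2), then (child 1, child k) for each further child — with the results
averaged and the node flagged in the report, since accuracy is expected to
degrade there. After all branch points have moved, every maximal segment
between branch/terminal nodes is re-optimized with its (possibly moved)
endpoints fixed. Topology — ids, parent links, type codes — is never
modified, terminal points never move, and the whole pass is deterministic:
identical inputs produce bitwise-identical SWC output. A reconstruction
whose nodes lie more than 10 µm outside the volume is rejected before any
mutation (frame mismatch).

## Morphometry

Total length is the sum of parent–child edge lengths. The local branch
angle walks 10 µm of arc along each child arm (linear interpolation within
edges) and measures the angle between the two chords from the branch point.
The consistency metric x-resamples both skeletons (51 points at 1-µm
x-steps), forms consecutive-point segments, and pairs each segment of one
skeleton with the segment of the other minimizing the segment-to-segment
distance — computed exactly: the squared distance is a convex quadratic
over the (s, t) parameter box, so the minimum is the interior stationary
point or lies on one of the four edges, all of which are enumerated. The
metric requires x-monotone paths and raises otherwise; this is a documented
limitation of the protocol, not of the skeletons.

## Synthetic phantoms

The generator emulates how a thin fluorescent neurite appears in a
light-microscopy stack: a one-voxel-wide binary centerline (a voxel is set
iff its centre lies within half a voxel diagonal of the polyline — the
tolerance that guarantees 26-connectivity without thickening axis-aligned
runs), convolved with a σ = 1.73-voxel Gaussian standing in for the PSF,
rescaled to max 255, plus i.i.d. Gaussian noise clipped below at zero
(intensities must stay non-negative; no upper clip or re-quantization is
applied). The fold-line phantom places the corner at the top middle of a
156×156×57 stack with both 60-µm legs descending symmetrically, which makes
the ground truth x-monotone and hence usable with the x-resampling
consistency metric; corner angles of 30° (sharp) and 90° (mild) and noise
SDs of 50 and 100 are the standard conditions. Ground truth is sampled at
0.5 µm — finer than the 1-µm resample spacing, so distance-to-truth metrics
are not resolution-limited. Initial "traced" skeletons are the ground truth
resampled at 1 µm plus i.i.d. uniform ±2 µm per-axis perturbation with
fixed endpoints. The Y phantom rasterizes three straight arms from a
junction, each blurred with its own kernel width and scaled to its own peak
before summation — the per-arm radius/intensity variation that makes real
branch points hard.

What the phantoms do **not** model: realistic PSFs (Airy, Gibson–Lanni),
Poisson/shot noise, varying radius along a single neurite, crossing or
densely packed neurites, and multi-neuron scenes. Passing the phantom suite
therefore establishes the solvers' correctness and their behavior under
heavy additive noise and sharp tortuosity, not performance on crowded
tissue.

## Numerical choices and degenerate inputs

- Argmin ties in the branch objective go to the smaller index; branch
  candidates are the discrete 1-µm resampled points (no continuous
  refinement), bounding quantization error by half the spacing.
- Consecutive skeleton points closer than 10⁻⁶ µm are merged before
  optimization (tracer stutter).
- Segments with fewer than 3 points, and side arms too short for a frame,
  are returned unchanged with a warning rather than raising.
- A non-finite objective (runaway step size) raises a divergence error
  naming λ, μ and the step size.
- The split-Bregman objective is not guaranteed monotone on the nonconvex
  intensity term; monotone decrease is asserted only on the fixed phantom
  fixtures where it is observed.

## Problem sizes

The test suite and the acceptance script run the full study design at its
native sizes: 156×156×57 fold-line stacks with ~120-point segments, a
64×64×32 Y phantom with a 15-case displacement grid, and three-trace
consistency runs — a few minutes end to end on one CPU.
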