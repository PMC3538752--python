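# Methods

This note documents the models, numerical choices and limitations behind
`gstract`, in the order data flows through the package.

## Tensor model and fit

The diffusion signal follows the mono-exponential single-tensor model
`S_k = S0 · exp(−b_k g_kᵀ D g_k)` with a symmetric 3×3 tensor **D** stored
as six unique components `(dxx, dyy, dzz, dxy, dxz, dyz)`. The fit is
log-linear least squares over `(ln S0, D)` — closed-form, deterministic,
and exact for the emulated clinical protocol (one b=0 image plus six
diffusion directions: seven equations, seven unknowns). Weighted or
nonlinear fitting would change little at these direction counts and would
cost determinism. Voxels with any non-positive signal cannot be
log-transformed; they receive the zero tensor and a flag.

Eigenvalues are returned in non-increasing order. Fractional anisotropy is
the standard normalized eigenvalue-dispersion measure, computed on
eigenvalues clamped at zero and clipped to [0, 1]; Westin shape fractions
are `cl = (λ₁−λ₂)/λ₁`, `cp = (λ₂−λ₃)/λ₁`, `cs = λ₃/λ₁`, with ties in the
class assignment broken linear > planar > spherical. Tensors are sampled
at arbitrary positions by component-wise trilinear interpolation (voxel
centers sit at integer indices under the affine); eigen-analysis always
happens after interpolation, never before.

## Software phantoms

The generator produces tube-shaped bundles with known centerlines:

| parameter | default | rationale |
|---|---|---|
| voxel size | 2 mm isotropic | clinical DTI scale |
| volume | 64³ (spiral: 48×48×16) | bundle plus ample background |
| tube radius | 4 mm | two-voxel cross-section, white-matter-like |
| in-tube eigenvalues | (1.7, 0.3, 0.3)·10⁻³ mm²/s | prolate, FA = 0.799 |
| background diffusivity | 0.7·10⁻³ mm²/s | isotropic, FA = 0 |
| b-value / gradients | 1000 s/mm², 6 oblique double gradients | emulated protocol |
| S0 | 1000 a.u. | arbitrary units |
| branching | 30 mm trunk, 30 mm arms at ±40°, 10 mm fillet | smooth Y |
| kissing | two 30 mm-radius arcs tangent at the center, ±60° | tangential contact |
| spiral | Archimedean, r 41→6 mm over 3.5 turns | see below |

Centerlines are arc-length sampled at voxel/4 = 0.5 mm. A voxel belongs to
the tube when its center lies within the tube radius of a centerline;
in-tube voxels receive a prolate tensor aligned with the local tangent,
and voxels claimed by several curves (the branch junction, the kissing
region) receive the component-wise mean of the contributing tensors —
the partial-volume mixture that defeats single-tensor trackers at
crossings. The spiral's radial pitch (10 mm/turn) deliberately exceeds the
8 mm tube diameter: consecutive whorls must be separated by background, or
the swept tube degenerates into a solid disc in which a "spiral" is no
longer defined and radial shortcuts become legitimate paths. A validity
check rejects specs that violate this.

Noise is Rician — `v → √((v+n₁)² + n₂²)` with `n₁, n₂ ~ N(0, σ²)` and
`σ = S0/SNR` defined on the b=0 image, matching MR magnitude statistics.
The unit-variance draws depend only on the seed, so realizations at SNR 15
and 30 with the same seed differ only by the σ scaling.

End ROIs are one-voxel-thick axis-aligned slabs through the curve
endpoints, extending one tube radius plus one voxel laterally (they cover
the full tube diameter); for the branching phantom the far ROI covers both
leaf endpoints.

## Deterministic trackers

SP integrates the sign-coherent major-eigenvector field with classical
RK4 at a fixed 0.5 mm step, bidirectionally from every seed (+e₁ forward,
−e₁ backward; at every evaluation, including all four RK4 stages, the
eigenvector sign is flipped to keep a non-negative dot product with the
incoming direction). TD propagates `v_out = normalize((D/λ₁)·v_in)`.
Seeds are placed at every voxel center whose FA clears the threshold
(density configurable). Fibers terminate when the interpolated FA drops
below the threshold, on leaving the volume, or at 2000 steps; no
angle-based stop is applied. A fiber belongs to the ROI-to-ROI tract when
any sample point falls in each mask voxel-wise; fibers are not clipped to
the ROIs. Both propagation loops are vectorized over all active seeds; a
single-seed call is the batch of one.

The adaptive clinical protocol tries the FA threshold 0.25 and, on
failure, 0.2; at each threshold the ROIs are dilated by 0, 1, … 4 voxels
(box structuring element) until a connection appears. The
stricter-threshold tract is selected iff it required at most two more
paddings than the relaxed one. Tracking is threshold-dependent but
ROI-independent, so the implementation tracks once per threshold and
re-filters per padding.

## Global search

The lattice spacing is `average_step / mean(‖offsets‖)` so the mean
neighbor step is exactly the configured 2 mm (per-step lengths then range
0.99–2.43 mm). The 74-direction set is the unique natural lattice
construction reaching 74: all primitive integer offsets in {−2..2}³ minus
the (2,2,1) permutation class; adding that class gives the 98-direction
refinement used in the angular-resolution experiment.

Edge costs (see README for the formula) are evaluated once, vectorized,
for every (node, offset) pair: nodes are lattice points inside the search
box whose interpolated FA clears the threshold; an edge additionally
requires its midpoint FA to clear it. Costs are even in the direction
(both p̂ and d are), so each edge is computed once and mirrored. The
multiplicative combination with a floor ε = 10⁻³ keeps every edge cost in
[ε·ℓ, ℓ]; `h(n) = ε · dist(n, nearest goal)` is therefore admissible and
consistent and A* is exact. Priority ties break by insertion order (FIFO)
for fully deterministic runs. The search kernel is numba-compiled.

`reconstruct_pathway` emits one minimum-cost path per qualifying start
node in the seed ROI, deduplicated. Rather than one A* per start node, it
runs a single multi-source Dijkstra from the goal ROI over the reversed
(node, arrival-offset) graph and reads each start node's optimal path off
the resulting shortest-path tree; cost symmetry and the symmetric bending
constraint make this exactly equivalent (the equivalence is asserted
against per-start A* in the tests). On failure the FA threshold falls back
from 0.3 to 0.15; ROI padding is never applied to GS. For phantoms, all
methods instead use one phantom-specific threshold: the mean FA in the
pathway core (inner half-radius of the tube, computed from the fitted
field) minus 0.1 — the offset stands in for a value that could not be
recovered from the source material.

## Similarity framework

Fibers that are not uniformly sampled (GS paths are grid-bound) are
resampled to the trackers' 0.5 mm step by arc-length interpolation —
points stay on the original polyline, no smoothing. For each fiber pair,
end correspondence uses the orientation of the second fiber minimizing
summed endpoint distances; at each end, the closest point on the other
fiber to each endpoint is found (exact index test for "endpoint", ties to
the lower index), and if exactly one of the two closest points is
interior, the protruding segment beyond it is removed on that fiber. Both
interior (diverging ends) or both endpoints: no trim. A trim that would
leave fewer than two points is refused and recorded.

The per-pair distance is the mean of Euclidean distances over the
deduplicated bidirectional closest-point relation; the tract-level
relation pairs every fiber with its closest counterpart in the other
tract (both directions, duplicates excluded — deduplication emphasizes
outliers rather than washing them out). S_avg and S_min are the mean and
minimum over that relation; FA similarity averages trilinearly
interpolated FA over every point of every trimmed fiber participating in
the relation, per tract, excluding and counting out-of-field points.

## Statistics

Group comparisons use the Mann-Whitney U test: exact two-sided p by
enumeration over all C(n₁+n₂, n₁) group assignments (midranks handle
ties) for combined n ≤ 12, and the tie-corrected normal approximation
otherwise; significance at α = 0.05 by default. All-tied samples return
p = 1 with a flag.

## Benchmark suite and problem sizes

`run_phantom_suite` builds each configured phantom at each SNR from a
single master seed, fits tensors from the noisy DWI, derives the phantom
threshold, runs each method (SP/TD with the padding escalation, GS
without), and records connection status, padding used, pairwise
similarities for connected method pairs, spiral first-cycle coverage (the
arc-length fraction of the ground-truth first 360° of centerline lying
within one tube radius of the longest fiber reaching the outer ROI), and
runtimes. Reports serialize to JSON/CSV; without the wall-clock fields
the JSON is byte-identical across runs of the same seed.

The acceptance script runs the full default suite (branching, kissing,
spiral × SNR 15, 30 × SP, TD, GS), five-seed spiral coverage at SNR 15,
and the five-seed 74-vs-98-offset comparison on the branching phantom —
sizes chosen so the whole study completes in well under half an hour on a
single CPU while every quantity is still estimated from multiple noise
realizations where it is stochastic.

## What the phantoms do and do not show

The phantoms share the limitations of any flat-profile tube model: FA is
exactly constant inside the tube (the only FA structure is the
partial-volume boundary), tensors are noiseless before DWI simulation,
and there is no eddy-current, motion, ghosting or susceptibility
artifact. Consequently local-tracker termination inside the tube is
driven purely by image noise, and its strength is a steep function of
SNR. Under these conditions the qualitative method ranking reproduces at
SNR 15 — SP/TD fail the spiral, terminating at the pathway border with
roughly two-thirds of the first cycle covered, while GS traverses all
3.5 turns — but at SNR 30 the 2σ margin between the FA threshold and the
in-tube FA distribution lets a fraction of SP/TD fibers survive the full
~518 mm spiral, so the local trackers also connect there. Real phantom
databases (and tissue) carry structural FA texture that terminates
trackers at lower noise; passing tests on these phantoms therefore
demonstrates the algorithms' contracts and their relative behavior, not
absolute clinical failure rates. The clinical protocol itself
(fMRI-derived ROIs, patient anatomy, expert validation) is out of scope.

Other known limitations: single-tensor model only (no HARDI/ODF terms in
the cost); the GS grid is axis-aligned in world space; the branching
phantom's combined leaf ROI can draw all minimum-cost paths to whichever
leaf noise makes marginally cheaper — focusing the goal ROI per leaf (or
a bounding box) recovers both branches, mirroring how anatomical
knowledge steers the search clinically.
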