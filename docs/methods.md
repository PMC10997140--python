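# Methods

This note documents the models, conventions and numerical choices behind
`csvtract`, and what the synthetic test bed does and does not establish about
real data.

## Coordinate and data conventions

All internal computation happens in world coordinates: RAS millimetres with
x > 0 on the right, so "left hemisphere" is testable as negative world x.
Voxel indices are 0-based and a voxel's centre sits at `affine @ (i, j, k, 1)`;
`world_to_voxel` rounds to the nearest lattice point. TCK/TRK voxel and
corner-offset conventions are resolved only at the I/O boundary (via
nibabel's streamline readers); weights, labels and provenance travel in a
plain-text TSV sidecar keyed by streamline index so both dialects carry the
same metadata and files stay diffable. NIfTI stores the affine in
single precision, so affine round-trips are bit-exact for the
float32-representable lattices used here (2-mm isotropic grids).

## The synthetic phantom

The phantom stands in for per-subject anatomy that cannot be shipped. Its
default scene emulates the study conditions: a 56³ grid of 2-mm isotropic
voxels; a 3×3×3-voxel CSv-like blob per hemisphere; seven tubular bundles
(SLF I/II/III, cingulum, callosal fibres, arcuate fasciculus, corticospinal
tract) of 30 streamlines each, radius 2 mm, laid out as straight spokes
radiating from a hub beside the *right* CSv blob; the left hemisphere is
deliberately empty so contralateral selections act as a negative control.
The callosal spoke crosses the mid-sagittal plane (tilted slightly off −x so
its far endpoint stays clear of the contralateral CSv blob); the CST spoke
carries two waypoint ROIs, every other bundle exactly one, encoding the
two-ROI AND topology of the corticospinal rule.

Waypoint ROIs are 4-mm half-extent boxes centred on each spoke. Their
pairwise separation is *verified at generation time* (minimum
centre-to-centre gap > 2 voxel widths, checked on the realised masks), and
every generated streamline is checked to cross all of its own bundle's ROIs
and none of any other bundle's; violations raise instead of silently
producing an ambiguous phantom. A configurable fraction (default 0.3) of
each bundle's streamlines is rerouted to terminate inside the CSv selection
distance; the rest start 7 mm out, beyond it. This makes the selection stage's
ground truth exact by construction.

Diffusion signal follows a multi-stick forward model per voxel,

S(g, b) = S0 · [ Σₖ fₖ · exp(−b·d_ax·(g·tₖ)²) + f_iso · exp(−b·d_iso) ],

with stick orientations tₖ taken from the mean local tangents of the truth
streamlines traversing the voxel, equal stick fractions, d_ax = 1.0×10⁻³
mm²/s, free water d_iso = 3.0×10⁻³ mm²/s, S0 = 100, and a 64-direction
b = 1000 s/mm² scheme with six b = 0 volumes (directions from a deterministic
spherical spiral). Noise is Rician — |S + N(0, σ) + i·N(0, σ)| with
σ = S0/SNR — reflecting magnitude MR images; a Gaussian option exists for
analytic tests, and the signal is exactly the closed form when SNR is
infinite. Voxels without bundle content are pure free water.

What the phantom does *not* emulate: cortical folding, fibre fanning,
curvature-dependent tracking failures, partial-volume mixtures beyond
per-voxel multi-stick, registration error, or physiological noise. Passing
tests therefore demonstrate that the *selection, classification, filtering
and statistics logic* is correct on unambiguous geometry — not that the
end-to-end analysis is robust to the anatomical ambiguity of real brains.

Candidate sets mix jittered copies of truth streamlines (σ = 0.2 mm,
subsampled without replacement when possible) with persistent random walks
through the bundle region whose orientations are decorrelated from the stick
field; all candidates respect the [4, 250] mm length bounds and carry one of
four provenance tags emulating pooling over four curvature settings
(5.7°, 11.5°, 23.1°, 47.2°). Distractor endpoints are rejected within 7 mm of
a CSv centre so that endpoint-selection ground truth stays unambiguous.

## Tensor fitting

Ordinary (unweighted) log-linear least squares of
ln S = ln S0 − b·gᵀDg, with ln S0 fitted jointly so b = 0 volumes enter the
same design; one pseudo-inverse serves all voxels. Non-positive signals are
clamped to 10⁻⁶·S0 (per voxel, configurable) before the log. OLS was chosen
over iterated WLS or robust variants because it is deterministic, exact on
noiseless single-tensor signal (property-tested over random SPD tensors),
and sufficient for the map's descriptive role. Eigenvalues are sorted
descending; the principal direction's sign is fixed (first non-negligible
component positive) for determinism, and the colour map uses absolute
components so the encoding is antipodally symmetric.

## LiFE filtering

The design matrix follows the linear fascicle evaluation structure: rows are
(voxel, diffusion direction) pairs over the white-matter mask, columns are
candidates. Each streamline is resampled at half the voxel size — a step
that cannot skip an axis-aligned voxel on the lattice — and each node
deposits, in its voxel's rows, the stick attenuation profile for its local
tangent, demeaned across directions; node contributions within a voxel sum.
The target is the measured diffusion-weighted signal demeaned per voxel.
The forward model inside the filter (single stick, fixed d_ax, demeaned) is
pinned here explicitly for reproducibility.

Weights solve min_w ½||y − Mw||² s.t. w ≥ 0 by cyclic coordinate descent
with exact projected 1-D minimisers, so the objective is non-increasing
(asserted in tests). Convergence is declared when the scaled KKT residual —
|∇ⱼ| on active coordinates, max(0, −∇ⱼ) on zero coordinates, relative to
‖Mᵀy‖_∞ — falls below `tol` (default 10⁻⁸); non-convergence returns the best
iterate with a warning. The solver contract is KKT-satisfaction, not a named
algorithm; tests cross-check it against `scipy.optimize.nnls` and against an
exhaustive active-set enumeration on small problems. A streamline is culled
when its weight falls below ε = 10⁻⁸ of the maximum weight ("did not
contribute" read as numerically zero). Note that NNLS drops *redundant*
streamlines as well as inconsistent ones: two near-collinear true candidates
may share, or concentrate, their weight, so the true-keep rate on dense
bundles sits slightly below 1 by design.

## CSv selection

"Within 3 mm of CSv voxels" is read as an inclusive (≤) Euclidean distance
from a streamline *endpoint* (either end; interior points never qualify) to
the nearest true-voxel *centre*. Centre distance is the simplest verifiable
rule; at 2-mm voxels the centre-versus-boundary difference is up to half a
voxel diagonal, and the `distance_target` field exists so a boundary rule
could be added without API change. A streamline qualifying at both CSv masks
is assigned to the hemisphere with the smaller distance; exact ties go to the
left — the convention is arbitrary but deterministic and documented.

## Classification

A tract claims a streamline when the streamline crosses ALL of its waypoint
ROIs (CST: two, others: one). Pass-through is decided by half-voxel-step
resampling with nearest-voxel lookup, and a negative verdict is confirmed by
an exact segment/voxel-box slab test, so the result equals exact geometric
intersection even when a segment grazes a voxel corner between samples.
Assignment is exclusive with precedence CST > AF > callosal > cingulum >
SLF I > SLF II > SLF III (most specific rule first); all multi-rule matches
are logged before resolution, and a non-exclusive mode counts every match,
so no ambiguity is hidden. The anatomical drawing rules for the ROIs
(sulcal landmarks on the AC coronal slice, the mid-sagittal callosal plane,
the cerebral peduncle) are treated as mask-authoring guidance: masks are
inputs, and the implementable content is the Boolean logic on them.

## Statistics

Proportions are tract count over total CSv streamline count per
subject-hemisphere (summing to 1 in exclusive mode; zero-streamline
hemispheres are flagged degenerate, not dropped). The one-sample t-test is
two-sided with a matching two-sided 95% CI — reconstructing published t
values from published CIs confirms a two-sided construction is consistent
with them — and SEM uses the n−1 standard deviation. Samples with *exactly*
identical values (including all-zero tracts) are reported as "test not
performed" rather than producing a meaningless statistic; the identity check
is exact rather than a variance threshold because twelve copies of the same
float can yield a rounding-level nonzero variance. Bonferroni correction
divides the family alpha by the number of tracts (0.05/7, conventionally
reported as 0.007). Presence is reported as k of n subject-hemispheres
containing at least one streamline of the tract.

## Pipeline and problem sizes

The `run-all` pipeline generates one phantom per subject (seeds
`seed + subject`), with 12 subjects by default to match the study cohort;
tests and the demo config use 2–4 subjects and smaller candidate sets, which
exercise identical code paths at a size chosen for fast iteration.
Determinism is end-to-end: a config hash and seed stamp every artifact, and
reruns with identical configs are byte-identical. Statistics on the phantom
cohort measure sampling variability of candidate generation only — per-subject
anatomy does not vary — so their role is to verify the inference machinery,
not to model between-subject anatomical variance.

## Known limitations

- Straight-spoke bundle geometry cannot probe curvature-induced
  classification errors or genuinely crossing waypoint ROIs.
- The LiFE forward model matches the phantom's generative stick model; on
  real data model mismatch would lower the separation between true and
  spurious streamlines.
- The exact slab fallback in `passes_roi` assumes axis-aligned (no
  shear/rotation) voxel grids, which covers all grids this package builds;
  oblique acquisitions would fall back to sampling-only verdicts.
- No multiple-comparison procedures beyond Bonferroni, and no mixed-effects
  modelling of the cohort.
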