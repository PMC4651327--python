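# Methods

## The counting model and its assumptions

The pipeline assumes the regime that holds for microglia in the retinal
plexiform layers: bright, branched cells on a dark background, arranged
in a mosaic in which neighboring territories do not overlap, imaged as a
short Z-stack (optical sections every 2 µm, typically 5–9 slices per
field at 1380×1040 px). Under those assumptions a cell is a connected
patch of above-threshold signal whose extent exceeds one 50 px grid
tile, and two detections closer than the minimum distance must come from
the same cell. The algorithm has no shape model beyond this — it is not
a general blob detector, and it will overcount if distinct cells
approach closer than `min_distance` or undercount if one cell's
footprint fragments into pieces farther apart than `min_distance`.
Where the mosaic assumption fails (the NFL-GCL), only the labeled-area
fraction is meaningful and the package measures that instead.

## Parameters

| name | default | units | meaning |
|---|---|---|---|
| `umbral` | 0.2 | fraction of image max | pixels strictly below it are zeroed after normalization |
| `min_distance` | 50 | px | detections closer than this merge into one cell |
| `box_size` | 50 | px | side of the grid tiles; small enough that every cell spans ≥ 4 tiles |
| `z_step_um` | 2 | µm | slice spacing of the acquisition, carried as metadata |

The threshold comparison is strict (`< umbral` → 0; values equal to the
umbral survive). The merge relation is also strict (`< min_distance`
links; a pair at exactly the minimum distance stays two cells), chains
transitively through connected components, and picks the largest-mass
member as the representative, with ties broken by raster order of the
tile index so reported positions are reproducible. `min_distance`
defaults to one tile (50 px); the interactive tool this design follows
exposes the distance as a user parameter without a canonical value, so
it is overridable everywhere and recorded in all outputs.

Numerical conventions: coordinates are 0-based `(row, col) = (y, x)`
with pixel centers at integers; distances are Euclidean in pixel units
(µm conversion is deliberately outside the core); 8-/16-bit unsigned
input is converted to floating point before any arithmetic; a blank
field normalizes to a blank field (count 0, area 0%) rather than raising
a division error, because blank fields occur in batch scans. The grid is
anchored at pixel (0, 0); since 1380 and 1040 are not multiples of 50,
the right/bottom tiles are partial and are processed identically — every
pixel belongs to exactly one tile and the tile masses sum to the
thresholded image total. The center of mass is computed on thresholded
(not binarized, not raw) intensities: thresholding precedes segmentation
in the pipeline order, and "center of mass" implies mass weighting.

## Synthetic ground truth

The generator emulates the two labeling regimes.

**Mosaic scenes** (`sample_mosaic` + `render_stack`): cell centers are
placed by dart throwing until all pairwise distances exceed
`min_separation` (default 125 px, i.e. beyond `min_distance` plus the
largest cell footprint diameter, ≈ 72 px, so distinct cells can never
merge), with an attempt cap that reports the achieved count on failure.
Each cell is a Gaussian soma (σ 5–7 px, amplitude 200) with 6–9 radial
branches (length 31–35 px, amplitude 140, 3 px wide, terminal bouton),
blurred by a σ = 1 px Gaussian point-spread, spread across slices by a
triangular depth profile centered on a per-cell focal slice, over a
faint background (level 2) with additive Gaussian noise (σ 2, clipped at
zero). The geometry guarantees the property the grid step relies on:
every cell's above-threshold footprint spans at least 4 tiles. Because
straight radial branches at an unlucky rotation can miss the diagonal
neighbor of a mid-tile cell, the renderer re-rolls a deficient cell's
branch orientation from that cell's own deterministic child RNG until
the property holds, then asserts it. All randomness flows from the scene
seed; identical parameters reproduce stacks bit for bit.

**Confluent scenes** (`render_confluent`): a band-passed noise field
stands in for the tangle of overlapping processes; its intensity mapping
is calibrated by bisection until the area fraction measured by the
actual pipeline on the final noisy stack is within 2 points of the
target. The realized above-threshold mask is stored as ground truth, so
area-fraction tests compare against an exactly known quantity.

What the generator does **not** emulate: real microglial morphology
(process tortuosity, activation states), staining variability between
animals, uneven illumination, vignetting, or out-of-focus haze from
adjacent layers. Passing tests therefore demonstrate the correctness of
the algorithmic pipeline under its stated assumptions, not detection
performance on real tissue; intensity statistics of the synthetic images
are conventions, not calibrated values.

## Validation statistics

The manual-vs-automatic harness regresses the automatic count on the
manual count (that orientation matches how such validations are plotted:
automatic as a function of manual) with a free intercept, reports the
OLS slope/intercept and Pearson r overall and per group × layer
subgroup, and tests for a systematic difference with a two-sided
Wilcoxon signed-rank on the paired differences. Conventions: zero
differences are dropped (standard signed-rank practice); midranks under
ties. Up to 150 nonzero pairs the exact null distribution of the rank
sum is computed by a generating-function convolution over doubled
midranks — exact under ties, where enumeration-based exact routines in
common reference implementations fall back to approximation — at cost
O(n·S), microseconds at these sizes; beyond 150 a normal approximation
with tie correction and continuity correction is used. The exact
two-sided p is the symmetric tail mass P(|W⁺ − S/2| ≥ |w⁺ − S/2|),
which coincides with twice the smaller tail because the null
distribution is symmetric. With fewer than about 10 nonzero pairs the
exact distribution is too coarse for p < 0.05 two-sided, which is a
property of the test, not of the implementation.

The simulated manual observer equals the algorithm's count plus
symmetric miscount noise: −1, 0, +1 with equal probability per field,
floored at zero — an attentive observer who occasionally misses or
double-counts one soma, with no systematic bias. One replicate
experiment pairs 120 automatic field counts with one observer draw and
computes the full summary. Because the paired differences depend only on
the noise, the Wilcoxon outcome of a replicate is driven entirely by the
observer draw; the per-replicate probability of a (type-I) significant
result under this null is ≈ 3.8% with the exact path, so a batch of 100
replicates typically contains 2–6 significant ones — an irreducible
statistical fluctuation, not a pipeline failure.

Group summaries discard the k largest and k smallest values (default
k = 10, so a 141-value subgroup retains 121) and report n, mean, SD
(ddof = 1), median and quartiles of the remainder; trimming is by sorted
order and hence permutation-invariant.

Density maps place per-field counts at the field centers along the two
sampled meridians and interpolate piecewise-linearly on a Delaunay
triangulation — chosen because it passes exactly through the data and
never exceeds the input range — onto a configurable regular grid, with
no extrapolation beyond the convex hull of the sampled positions.
Collinear layouts (a single meridian) fall back to 1D interpolation
along the principal axis with a warning. Group averages are taken per
grid cell over the retinas that cover it.

## Problem sizes used by the test and acceptance runs

Unit tests run on reduced frames (≈ 400×520 px) to stay fast; the
acceptance checks use the full 1040×1380 frame: 120 rendered mosaic
scenes of 5–40 cells (serving both the exact-recovery check and the
observer experiment), 1,000 random point sets of up to 200 points for
the merge oracle, and 100 observer replicates of 120 fields. One
full-frame field counts in well under a second on a single CPU.

## Known limitations

- The synthetic appearance model is an engineering stand-in; recovery
  results bound algorithmic, not biological, error.
- The 4-tile footprint guarantee is enforced for the default 50 px box;
  rendering scenes for very different box sizes would need re-derived
  geometry.
- The merge step treats chains of detections as one cell; a row of
  genuinely distinct cells each within `min_distance` of the next would
  collapse — excluded by the mosaic separation assumption, not by the
  algorithm.
- The replicate-experiment criterion for the observer harness is itself
  a Monte Carlo estimate: with 100 replicates and a true
  non-significance rate of ~96%, the observed count fluctuates with
  standard deviation ≈ 1.9 around 96.
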