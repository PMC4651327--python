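"""Synthetic fluorescence Z-stacks with known ground truth.

Two labeling regimes are emulated so every stage of the counting pipeline
can be tested without real retinas:

* **Mosaic** (plexiform layers): branched bright cells on a dark
  background, arranged with a minimum pairwise separation so each cell is
  individually identifiable — the regime in which per-cell counting is
  valid.
* **Confluent** (nerve fiber / ganglion cell layer): overlapping
  filamentous labeling where individual cells cannot be told apart and
  only the labeled-area fraction is meaningful.

The cell appearance model is deliberately simple — a Gaussian soma plus
radiating branch segments, spread across slices by a triangular depth
profile and blurred by a Gaussian point-spread — and is an engineering
stand-in, not a calibrated microglia morphology model.  Its geometry is
sized so that with the default pipeline parameters (umbral 0.2, 50 px
boxes) every rendered cell's above-threshold footprint spans at least 4
grid tiles, which is the property the grid segmentation relies on.

All randomness flows from a single integer seed; identical parameters and
seed reproduce stacks bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import disk as draw_disk, line as draw_line

from .core import (
    ImageStack,
    Projection,
    apply_threshold,
    normalize,
    z_project,
)

__all__ = [
    "CellSpec",
    "GroundTruthScene",
    "RenderedDataset",
    "MosaicInfeasibleError",
    "sample_mosaic",
    "render_stack",
    "render_confluent",
]

# Default frame mirrors the acquisition geometry: 1380x1040 px fields,
# optical sections every 2 um, ~5-9 slices per stack depending on layer.
DEFAULT_SIZE = (1040, 1380)
DEFAULT_N_SLICES = 7
DEFAULT_Z_STEP_UM = 2.0

# Intensity model (8-bit-like scale).  The background is faint and the
# soma bright so that thresholding at 0.2 of the image maximum removes
# background in expectation while keeping branches.
SOMA_AMPLITUDE = 200.0
BRANCH_AMPLITUDE = 140.0
DEFAULT_BACKGROUND = 2.0
DEFAULT_NOISE_SD = 2.0
PSF_SIGMA = 1.0


class MosaicInfeasibleError(RuntimeError):
    """Raised when the requested cell count cannot be placed at the
    requested separation; carries the number of cells achieved."""

    def __init__(self, requested: int, achieved: int, min_separation: float):
        self.requested = requested
        self.achieved = achieved
        super().__init__(
            f"placed only {achieved}/{requested} cells at separation "
            f">= {min_separation} px before hitting the attempt cap"
        )


@dataclass(frozen=True)
class CellSpec:
    """Geometry of one synthetic cell."""

    center: tuple[float, float]  # (y, x) px
    soma_radius: float  # px (Gaussian sigma of the soma blob)
    n_branches: int
    branch_length: float  # px
    brightness: float = 1.0  # per-cell intensity jitter factor


@dataclass
class GroundTruthScene:
    """Planted cells and imaging parameters for one synthetic field."""

    image_size: tuple[int, int] = DEFAULT_SIZE
    cells: list[CellSpec] = field(default_factory=list)
    n_slices: int = DEFAULT_N_SLICES
    background_level: float = DEFAULT_BACKGROUND
    noise_sd: float = DEFAULT_NOISE_SD
    seed: int = 0
    min_separation: float | None = None

    def __post_init__(self) -> None:
        h, w = self.image_size
        for c in self.cells:
            y, x = c.center
            if not (0 <= y < h and 0 <= x < w):
                raise ValueError(f"cell center {c.center} outside {self.image_size}")
        if self.min_separation is not None and len(self.cells) > 1:
            pts = np.array([c.center for c in self.cells])
            d2 = np.sum((pts[:, None] - pts[None, :]) ** 2, axis=-1)
            np.fill_diagonal(d2, np.inf)
            if math.sqrt(d2.min()) < self.min_separation:
                raise ValueError("mosaic scene violates its separation constraint")

    @property
    def n_cells(self) -> int:
        return len(self.cells)


@dataclass
class RenderedDataset:
    """A rendered stack together with the scene that produced it.

    For confluent renders ``mask`` records the realized binary label mask
    (the pixels above threshold after the core pipeline), which is the
    ground truth for the area-fraction measure.
    """

    stack: ImageStack
    truth: GroundTruthScene
    mask: np.ndarray | None = None


def _sample_morphology(rng: np.random.Generator) -> dict:
    # Branch reach must exceed ~30 px so even a cell centered mid-tile
    # can reach a fourth grid tile (worst case needs ~29.3 px), while the
    # whole footprint stays narrow enough (diameter ~72 px) that mosaic
    # separations beyond min_distance + diameter remain attainable.
    return {
        "soma_radius": float(rng.uniform(5.0, 7.0)),
        "n_branches": int(rng.integers(6, 10)),
        "branch_length": float(rng.uniform(31.0, 35.0)),
        "brightness": float(rng.uniform(0.8, 1.0)),
    }


def sample_mosaic(
    n_cells: int,
    min_separation: float = 125.0,
    size: tuple[int, int] = DEFAULT_SIZE,
    seed: int = 0,
    n_slices: int = DEFAULT_N_SLICES,
    margin: float = 40.0,
    max_attempts: int = 50000,
    background_level: float = DEFAULT_BACKGROUND,
    noise_sd: float = DEFAULT_NOISE_SD,
) -> GroundTruthScene:
    """Place ``n_cells`` centers with pairwise distance >= ``min_separation``.

    Dart-throwing (rejection sampling) keeps the arrangement irregular,
    like a biological mosaic; ``margin`` keeps whole footprints inside the
    frame.  If the separation is infeasible within ``max_attempts`` the
    error reports how many cells were achieved.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    h, w = size
    if margin * 2 >= min(h, w):
        raise ValueError("margin leaves no room for cell centers")
    rng = np.random.default_rng(seed)
    centers = np.empty((0, 2))
    attempts = 0
    sep2 = min_separation**2
    while len(centers) < n_cells:
        if attempts >= max_attempts:
            raise MosaicInfeasibleError(n_cells, len(centers), min_separation)
        attempts += 1
        pt = rng.uniform((margin, margin), (h - margin, w - margin))
        if not len(centers) or (((centers - pt) ** 2).sum(axis=1) >= sep2).all():
            centers = np.vstack([centers, pt])
    cells = [
        CellSpec(center=(float(y), float(x)), **_sample_morphology(rng))
        for y, x in centers
    ]
    return GroundTruthScene(
        image_size=size,
        cells=cells,
        n_slices=n_slices,
        background_level=background_level,
        noise_sd=noise_sd,
        seed=seed,
        min_separation=min_separation if n_cells > 1 else None,
    )


def _render_cell_patch(cell: CellSpec, rng: np.random.Generator) -> tuple[np.ndarray, int, int]:
    """Render one cell onto a local patch.

    Returns ``(patch, y0, x0)`` where (y0, x0) is the patch origin in the
    global frame (may be negative near edges; the caller clips).
    """
    reach = int(math.ceil(cell.branch_length + 3 * cell.soma_radius + 4 * PSF_SIGMA))
    side = 2 * reach + 1
    patch = np.zeros((side, side), dtype=np.float64)
    cy = cx = reach  # cell center at the patch center

    # Soma: Gaussian blob.
    yy, xx = np.mgrid[0:side, 0:side]
    r2 = (yy - cy) ** 2 + (xx - cx) ** 2
    patch += SOMA_AMPLITUDE * np.exp(-r2 / (2.0 * cell.soma_radius**2))

    # Branches: straight 3-px-wide segments at jittered regular angles.
    base = rng.uniform(0, 2 * math.pi)
    for k in range(cell.n_branches):
        ang = base + 2 * math.pi * k / cell.n_branches + rng.normal(0, 0.15)
        length = cell.branch_length * rng.uniform(0.95, 1.0)
        ty = int(round(cy + length * math.sin(ang)))
        tx = int(round(cx + length * math.cos(ang)))
        rr, cc = draw_line(cy, cx, ty, tx)
        for dy, dx in ((0, 0), (1, 0), (0, 1)):
            r, c = rr + dy, cc + dx
            ok = (r >= 0) & (r < side) & (c >= 0) & (c < side)
            patch[r[ok], c[ok]] = np.maximum(patch[r[ok], c[ok]], BRANCH_AMPLITUDE)
        # Terminal bouton: a small full-amplitude disk keeps the branch
        # tip above threshold after the point-spread blur, so the
        # above-threshold reach equals the drawn branch length.
        rr, cc = draw_disk((ty, tx), 2.0, shape=patch.shape)
        patch[rr, cc] = np.maximum(patch[rr, cc], BRANCH_AMPLITUDE)

    patch = gaussian_filter(patch, PSF_SIGMA) * cell.brightness
    y0 = int(round(cell.center[0])) - reach
    x0 = int(round(cell.center[1])) - reach
    return patch, y0, x0


def _depth_weights(n_slices: int, focal: float, half_width: float) -> np.ndarray:
    """Triangular depth profile, peak 1 at the focal slice."""
    k = np.arange(n_slices, dtype=np.float64)
    return np.clip(1.0 - np.abs(k - focal) / half_width, 0.0, 1.0)


def _add_patch(canvas: np.ndarray, patch: np.ndarray, y0: int, x0: int) -> None:
    h, w = canvas.shape
    ph, pw = patch.shape
    ys, xs = max(y0, 0), max(x0, 0)
    ye, xe = min(y0 + ph, h), min(x0 + pw, w)
    if ys >= ye or xs >= xe:
        return
    canvas[ys:ye, xs:xe] += patch[ys - y0 : ye - y0, xs - x0 : xe - x0]


def _footprint_tiles(
    patch: np.ndarray,
    level: float,
    y0: int = 0,
    x0: int = 0,
    shape: tuple[int, int] | None = None,
    box: int = 50,
) -> int:
    """Number of grid tiles touched by pixels of ``patch`` >= ``level``.

    ``(y0, x0)`` is the patch origin in the global frame; pixels falling
    outside ``shape`` (the image bounds) do not count.
    """
    ys, xs = np.nonzero(patch >= level)
    ys, xs = ys + y0, xs + x0
    if shape is not None:
        keep = (ys >= 0) & (ys < shape[0]) & (xs >= 0) & (xs < shape[1])
        ys, xs = ys[keep], xs[keep]
    if len(ys) == 0:
        return 0
    return len(set(zip(ys // box, xs // box)))


def render_stack(scene: GroundTruthScene, check_footprint: bool = True) -> RenderedDataset:
    """Render a mosaic scene into a noisy Z-stack.

    Each cell is drawn as a bright soma plus radiating branches, blurred
    by the point-spread, distributed over slices with a triangular depth
    profile centered on a per-cell focal slice, and superposed on a faint
    background with additive Gaussian noise (clipped at zero).

    Every cell's above-threshold footprint is guaranteed to span >= 4
    grid tiles at the default 50 px box size — the geometric premise of
    grid-based counting.  Straight radial branches at a random rotation
    can miss the diagonal neighbor of a mid-tile cell, so a cell whose
    first draw falls short re-rolls its branch orientation (from its own
    deterministic child RNG) until the footprint property holds; the
    result is asserted when ``check_footprint`` is set.
    """
    rng = np.random.default_rng(scene.seed)
    h, w = scene.image_size
    n = scene.n_slices

    # First pass: per-cell patches and depth profiles.  Each cell draws
    # from its own child RNG so re-rolling one cell's branches cannot
    # perturb any other cell.
    cell_rngs = [np.random.default_rng([scene.seed, i]) for i in range(len(scene.cells))]
    patches = []
    for cell, crng in zip(scene.cells, cell_rngs):
        patch, y0, x0 = _render_cell_patch(cell, crng)
        focal = float(rng.uniform(0.25, 0.75) * (n - 1)) if n > 1 else 0.0
        weights = _depth_weights(n, focal, half_width=max(n / 2.0, 1.0))
        patches.append([patch, y0, x0, weights])

    # The pipeline thresholds at umbral x the projection maximum; the
    # maximum comes from the brightest soma, which branch re-rolls do not
    # change, so the level can be fixed before the second pass.  A 10%
    # margin keeps the property robust to the slight level shift that
    # background and noise introduce in the final image.
    if scene.cells:
        level = 0.2 * max(p[0].max() * p[3].mean() for p in patches)
        for i, (cell, crng) in enumerate(zip(scene.cells, cell_rngs)):
            patch, y0, x0, weights = patches[i]
            w_mean = weights.mean()
            tries = 0
            while (
                _footprint_tiles(patch * w_mean, 1.1 * level, y0, x0, (h, w)) < 4
                and tries < 100
            ):
                patch, y0, x0 = _render_cell_patch(cell, crng)
                tries += 1
            patches[i][:3] = [patch, y0, x0]
            if check_footprint:
                tiles = _footprint_tiles(patch * w_mean, level, y0, x0, (h, w))
                assert tiles >= 4, (
                    f"cell footprint spans only {tiles} grid tiles; "
                    "cells must span >= 4 tiles for grid counting"
                )

    stack = np.zeros((n, h, w), dtype=np.float32)
    for patch, y0, x0, weights in patches:
        for k in range(n):
            if weights[k] > 0:
                _add_patch(stack[k], (patch * weights[k]).astype(np.float32), y0, x0)

    stack += np.float32(scene.background_level)
    if scene.noise_sd > 0:
        stack += scene.noise_sd * rng.standard_normal(stack.shape, dtype=np.float32)
    np.clip(stack, 0.0, None, out=stack)
    img = ImageStack(
        stack,
        z_step_um=DEFAULT_Z_STEP_UM,
        field_id=f"synthetic_seed{scene.seed}",
        layer="IPL",
    )
    return RenderedDataset(img, scene)


def render_confluent(
    target_fraction: float,
    size: tuple[int, int] = DEFAULT_SIZE,
    seed: int = 0,
    n_slices: int = 5,
    umbral: float = 0.2,
    tol: float = 0.02,
    max_iter: int = 40,
) -> RenderedDataset:
    """Render overlapping, confluent labeling hitting a target area fraction.

    A smooth random field stands in for the tangle of overlapping
    processes.  The field's intensity mapping is calibrated iteratively
    (bisection on the cut level) until the area fraction measured by the
    core pipeline on the final noisy stack falls within ``tol`` of
    ``target_fraction``.  The realized above-threshold mask is recorded as
    ground truth.
    """
    if not 0.0 <= target_fraction <= 1.0:
        raise ValueError("target_fraction must lie in [0, 1]")
    h, w = size
    rng = np.random.default_rng(seed)
    scene = GroundTruthScene(
        image_size=size, cells=[], n_slices=n_slices,
        background_level=0.0, noise_sd=1.0, seed=seed,
    )

    if target_fraction == 0.0:
        stack = ImageStack(
            np.zeros((n_slices, h, w), dtype=np.float32),
            z_step_um=DEFAULT_Z_STEP_UM, field_id=f"confluent_seed{seed}",
            layer="NFL_GCL",
        )
        return RenderedDataset(stack, scene, mask=np.zeros((h, w), dtype=bool))

    # Filamentous-looking base texture: band-passed white noise.
    base = gaussian_filter(rng.standard_normal((h, w)), 3.0)
    base -= gaussian_filter(base, 12.0)
    base -= base.min()
    noise = scene.noise_sd * rng.standard_normal((n_slices, h, w), dtype=np.float32)

    def realize(cut: float) -> tuple[ImageStack, float, np.ndarray]:
        # Map the texture so pixels with base >= cut land above the
        # pipeline threshold once the image is normalized to its max.
        fmax = base.max()
        offset = (umbral * fmax - cut) / (1.0 - umbral)
        img = np.clip(base + offset, 0.0, None)
        img *= 200.0 / img.max()
        arr = (img[np.newaxis] + noise).clip(0.0).astype(np.float32)
        stk = ImageStack(
            arr, z_step_um=DEFAULT_Z_STEP_UM,
            field_id=f"confluent_seed{seed}", layer="NFL_GCL",
        )
        proj = apply_threshold(normalize(z_project(stk)), umbral)
        mask = proj.pixels > 0
        return stk, mask.mean(), mask

    lo, hi = float(base.min()), float(base.max())
    if target_fraction == 1.0:
        stk, frac, mask = realize(lo)
    else:
        cut = float(np.quantile(base, 1.0 - target_fraction))
        stk, frac, mask = realize(cut)
        it = 0
        while abs(frac - target_fraction) > tol and it < max_iter:
            if frac > target_fraction:
                lo = cut
            else:
                hi = cut
            cut = 0.5 * (lo + hi)
            stk, frac, mask = realize(cut)
            it += 1
    if abs(frac - target_fraction) > tol:
        raise RuntimeError(
            f"could not reach area fraction {target_fraction:.3f} "
            f"(achieved {frac:.3f} after {max_iter} iterations)"
        )
    return RenderedDataset(stk, scene, mask=mask)
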