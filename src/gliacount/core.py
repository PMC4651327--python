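"""Core counting pipeline for Iba-1+ microglia in retinal whole mounts.

The counting algorithm operates on a per-field Z-stack of single-channel
fluorescence images and proceeds in five steps:

1. **Z projection** — per-pixel arithmetic mean of the slices.
2. **Normalization** — divide by the image maximum, mapping intensities
   to [0, 1].
3. **Thresholding** — zero every pixel strictly below the *umbral*
   (threshold fraction, default 0.2); pixels at or above it keep their
   value (the image is not binarized at this stage).
4. **Grid segmentation** — partition the image into ``box_size`` ×
   ``box_size`` tiles (default 50 px; partial tiles at the right/bottom
   edges are processed like any other) and compute the intensity-weighted
   center of mass of every tile with nonzero signal.  Because even the
   smallest microglial cell spans several tiles, a single cell typically
   yields multiple nearby centroids.
5. **Minimum-distance merging** — centroids closer than ``min_distance``
   are considered to belong to the same cell; connected groups collapse to
   one representative detection each.

Counting this way works in the plexiform layers (IPL/OPL), where microglia
tile the retina as a non-overlapping mosaic.  In the NFL-GCL, where labeled
cells overlap, :func:`area_fraction` quantifies the percentage of pixels
above threshold instead.

All coordinates are 0-based ``(row, col) = (y, x)`` with pixel centers at
integer positions.  Distances are Euclidean, in pixel units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

__all__ = [
    "ImageStack",
    "Projection",
    "DetectionParams",
    "BoxDetection",
    "CellDetections",
    "AreaFractionResult",
    "z_project",
    "normalize",
    "apply_threshold",
    "segment_grid",
    "merge_detections",
    "count_cells",
    "area_fraction",
]

LAYERS = ("IPL", "OPL", "NFL_GCL")


@dataclass
class ImageStack:
    """Ordered Z-slices of one field/layer, single channel.

    Parameters
    ----------
    slices : ndarray, shape (n_slices, H, W)
        Non-negative intensities.  8-/16-bit unsigned input is converted
        to floating point; arithmetic never happens on integer dtypes.
    z_step_um : float
        Physical slice spacing in micrometres (acquisition default 2 µm).
    field_id : str
        Opaque label for the imaged field.
    layer : str or None
        One of ``IPL``, ``OPL``, ``NFL_GCL`` when known.
    """

    slices: np.ndarray
    z_step_um: float = 2.0
    field_id: str = ""
    layer: str | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.slices)
        if arr.ndim == 2:
            arr = arr[np.newaxis]
        if arr.ndim != 3 or arr.shape[0] < 1:
            raise ValueError(
                "stack must contain >=1 slice of identical 2D dimensions"
            )
        if arr.shape[1] < 1 or arr.shape[2] < 1:
            raise ValueError("slices must be non-empty 2D images")
        if not np.issubdtype(arr.dtype, np.floating):
            arr = arr.astype(np.float32)
        if np.min(arr) < 0:
            raise ValueError("intensities must be non-negative")
        if self.layer is not None and self.layer not in LAYERS:
            raise ValueError(f"layer must be one of {LAYERS}, got {self.layer!r}")
        self.slices = arr

    @property
    def n_slices(self) -> int:
        return self.slices.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width) of each slice in pixels."""
        return self.slices.shape[1:]

    @classmethod
    def from_slices(
        cls,
        slices: Sequence[np.ndarray],
        z_step_um: float = 2.0,
        field_id: str = "",
        layer: str | None = None,
    ) -> "ImageStack":
        """Build a stack from a sequence of equally sized 2D arrays."""
        slices = list(slices)
        if not slices:
            raise ValueError("stack must contain >=1 slice")
        shapes = {np.asarray(s).shape for s in slices}
        if len(shapes) != 1:
            raise ValueError(f"slice dimensions differ: {sorted(shapes)}")
        return cls(np.stack([np.asarray(s) for s in slices]), z_step_um, field_id, layer)


@dataclass
class Projection:
    """2D projection image (non-negative intensities)."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels, dtype=np.float64)
        if arr.ndim != 2:
            raise ValueError("projection must be a 2D image")
        self.pixels = arr

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class DetectionParams:
    """Tunable parameters of the counting pipeline.

    umbral : normalized-intensity cutoff in [0, 1]; pixels strictly below
        it are zeroed (default 0.2).
    min_distance : minimum Euclidean distance in px between two distinct
        cells; nearer centroids merge (default 50).
    box_size : side of the square grid tiles in px (default 50, chosen so
        the smallest cells still span at least 4 tiles).
    """

    umbral: float = 0.2
    min_distance: float = 50.0
    box_size: int = 50

    def __post_init__(self) -> None:
        if not 0.0 <= self.umbral <= 1.0:
            raise ValueError(f"umbral must lie in [0, 1], got {self.umbral}")
        if self.min_distance <= 0:
            raise ValueError("min_distance must be positive")
        if int(self.box_size) != self.box_size or self.box_size < 2:
            raise ValueError("box_size must be an integer >= 2")


@dataclass(frozen=True)
class BoxDetection:
    """Center of mass of one grid tile with nonzero signal.

    ``centroid`` is (y, x) in the global image frame; ``mass`` is the sum
    of thresholded intensities inside the tile.
    """

    box_index: tuple[int, int]
    centroid: tuple[float, float]
    mass: float


@dataclass
class CellDetections:
    """Final cell positions for one field after duplicate suppression."""

    positions: list[tuple[float, float]]
    params: DetectionParams = field(default_factory=DetectionParams)

    @property
    def count(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class AreaFractionResult:
    """Percentage of pixels labeled above threshold in one field."""

    labeled_pixels: int
    total_pixels: int

    @property
    def percent_labeled(self) -> float:
        return 100.0 * self.labeled_pixels / self.total_pixels


def z_project(stack: ImageStack) -> Projection:
    """Average the stack along Z, per pixel.

    The result (the *Z projection*) has the same dimensions as the slices
    and collapses the optical sections taken every ``z_step_um`` into a
    single intensity image.
    """
    return Projection(stack.slices.mean(axis=0, dtype=np.float64))


def normalize(image: Projection) -> Projection:
    """Scale the image so its maximum pixel equals 1.

    A blank (all-zero) image is returned unchanged rather than raising a
    division error: blank fields do occur in batch scans of whole mounts.
    """
    px = image.pixels
    peak = px.max(initial=0.0)
    if peak <= 0:
        return Projection(np.zeros_like(px))
    return Projection(px / peak)


def apply_threshold(image: Projection, umbral: float) -> Projection:
    """Zero every pixel strictly below ``umbral``; keep the rest as-is.

    The input is expected on the normalized [0, 1] scale.  Pixels exactly
    equal to the umbral are preserved.  The output is *not* binarized.
    """
    if not 0.0 <= umbral <= 1.0:
        raise ValueError(f"umbral must lie in [0, 1], got {umbral}")
    px = image.pixels
    return Projection(np.where(px < umbral, 0.0, px))


def segment_grid(image: Projection, box_size: int) -> list[BoxDetection]:
    """Partition the image into square tiles and locate per-tile signal.

    The grid is anchored at pixel (0, 0); when the image dimensions are
    not multiples of ``box_size`` (the acquisition frame 1380×1040 is not
    a multiple of 50) the right/bottom edge tiles are partial and are
    processed identically, so every pixel belongs to exactly one tile.
    Tiles whose total intensity is zero yield no detection.

    Returns detections in raster order of the tile grid.
    """
    if int(box_size) != box_size or box_size < 2:
        raise ValueError("box_size must be an integer >= 2")
    box_size = int(box_size)
    px = image.pixels
    h, w = px.shape
    detections: list[BoxDetection] = []
    for bi, r0 in enumerate(range(0, h, box_size)):
        r1 = min(r0 + box_size, h)
        for bj, c0 in enumerate(range(0, w, box_size)):
            c1 = min(c0 + box_size, w)
            tile = px[r0:r1, c0:c1]
            mass = float(tile.sum())
            if mass <= 0:
                continue
            rows = tile.sum(axis=1)
            cols = tile.sum(axis=0)
            cy = float(rows @ np.arange(r0, r1)) / mass
            cx = float(cols @ np.arange(c0, c1)) / mass
            detections.append(BoxDetection((bi, bj), (cy, cx), mass))
    return detections


def merge_detections(
    points: Sequence[BoxDetection],
    min_distance: float,
    params: DetectionParams | None = None,
) -> CellDetections:
    """Collapse centroids closer than ``min_distance`` into single cells.

    Pairs of points at Euclidean distance strictly below ``min_distance``
    are considered to belong to the same cell; the relation chains
    transitively (connected components), so an elongated cell whose tile
    centroids form a chain still counts once.  Each component is
    represented by its largest-mass member, ties broken by raster order of
    the tile index, which makes reported positions deterministic.
    """
    if min_distance <= 0:
        raise ValueError("min_distance must be positive")
    if params is None:
        params = DetectionParams(min_distance=float(min_distance))
    if not points:
        return CellDetections([], params)
    coords = np.array([p.centroid for p in points], dtype=np.float64)
    tree = cKDTree(coords)
    pairs = tree.query_pairs(min_distance, output_type="ndarray")
    if len(pairs):
        # query_pairs returns d <= r; the merge relation is strict (<),
        # so a pair at exactly min_distance stays two cells.
        d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
        pairs = pairs[d < min_distance]
    n = len(points)
    adj = sparse.coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    n_comp, labels = connected_components(adj, directed=False)
    positions: list[tuple[float, float]] = []
    order = sorted(
        range(n),
        key=lambda i: (-points[i].mass, points[i].box_index[0], points[i].box_index[1], i),
    )
    seen: set[int] = set()
    for i in order:
        if labels[i] not in seen:
            seen.add(labels[i])
            positions.append(points[i].centroid)
    assert len(positions) == n_comp
    return CellDetections(positions, params)


def count_cells(stack: ImageStack, params: DetectionParams | None = None) -> CellDetections:
    """Run the full counting pipeline on one IPL/OPL field.

    Composition of :func:`z_project`, :func:`normalize`,
    :func:`apply_threshold`, :func:`segment_grid` and
    :func:`merge_detections`.  The pre-merge number of signal tiles is an
    upper bound on the returned count.  Because of the normalization step
    the result is invariant under multiplying every slice by a positive
    constant.
    """
    if params is None:
        params = DetectionParams()
    proj = apply_threshold(normalize(z_project(stack)), params.umbral)
    boxes = segment_grid(proj, params.box_size)
    return merge_detections(boxes, params.min_distance, params)


def area_fraction(stack: ImageStack, umbral: float = 0.2) -> AreaFractionResult:
    """Percentage of the field labeled above threshold (NFL-GCL measure).

    Projects, normalizes and thresholds like the counting pipeline, then
    binarizes (every nonzero pixel becomes 1) and reports
    ``100 * labeled_pixels / total_pixels``.
    """
    proj = apply_threshold(normalize(z_project(stack)), umbral)
    labeled = int(np.count_nonzero(proj.pixels))
    return AreaFractionResult(labeled, int(proj.pixels.size))
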