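"""Reading and writing stacks, detections and result tables.

A field's Z-stack is stored either as one multi-page grayscale TIFF or as
a folder of single-page TIFFs whose filename sort order is the Z order.
Results are written as delimited text (CSV); position tables state the
coordinate convention in a header comment.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .core import AreaFractionResult, CellDetections, ImageStack
from .synth import GroundTruthScene, RenderedDataset

__all__ = [
    "read_stack",
    "write_stack",
    "write_positions_csv",
    "write_ground_truth_csv",
    "write_results_csv",
]

POSITION_HEADER = (
    "# positions are 0-based (y, x) pixel coordinates, pixel centers at integers"
)


def read_stack(
    path: str | Path,
    z_step_um: float = 2.0,
    layer: str | None = None,
) -> ImageStack:
    """Load a Z-stack from a multi-page TIFF or a folder of TIFFs.

    Folder slices are sorted by filename.  8-/16-bit unsigned data is
    converted to floating point.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such stack: {path}")
    if path.is_dir():
        pages = sorted(
            p for p in path.iterdir() if p.suffix.lower() in {".tif", ".tiff"}
        )
        if not pages:
            raise FileNotFoundError(f"no TIFF slices found in folder {path}")
        slices = [tifffile.imread(p) for p in pages]
        shapes = {s.shape for s in slices}
        if len(shapes) != 1:
            raise ValueError(f"slice dimensions differ in {path}: {sorted(shapes)}")
        arr = np.stack(slices)
    else:
        try:
            arr = tifffile.imread(path)
        except Exception as exc:  # noqa: BLE001 - surface the file name
            raise OSError(f"cannot read TIFF stack {path}: {exc}") from exc
        if arr.ndim == 2:
            arr = arr[np.newaxis]
    if arr.ndim != 3:
        raise ValueError(
            f"{path}: expected single-channel 2D slices, got array shape {arr.shape}"
        )
    return ImageStack(arr, z_step_um=z_step_um, field_id=path.stem, layer=layer)


def write_stack(path: str | Path, stack: ImageStack | RenderedDataset) -> Path:
    """Write a stack as a multi-page 16-bit grayscale TIFF."""
    if isinstance(stack, RenderedDataset):
        stack = stack.stack
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.clip(np.rint(stack.slices), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(path, data, photometric="minisblack")
    return path


def write_positions_csv(path: str | Path, detections: CellDetections, field_id: str = "") -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        fh.write(POSITION_HEADER + "\n")
        writer = csv.writer(fh)
        writer.writerow(["field_id", "cell_id", "y_px", "x_px"])
        for i, (y, x) in enumerate(detections.positions):
            writer.writerow([field_id, i, f"{y:.3f}", f"{x:.3f}"])
    return path


def write_ground_truth_csv(path: str | Path, scene: GroundTruthScene) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "cell_id": i,
            "y_px": c.center[0],
            "x_px": c.center[1],
            "soma_radius_px": c.soma_radius,
            "n_branches": c.n_branches,
            "branch_length_px": c.branch_length,
        }
        for i, c in enumerate(scene.cells)
    ]
    pd.DataFrame(rows, columns=[
        "cell_id", "y_px", "x_px", "soma_radius_px", "n_branches", "branch_length_px",
    ]).to_csv(path, index=False)
    return path


def write_results_csv(path: str | Path, table: pd.DataFrame, excel: bool = False) -> Path:
    """Write the batch results table as CSV (optionally also .xlsx)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
    if excel:
        table.to_excel(path.with_suffix(".xlsx"), index=False)
    return path
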