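"""Batch processing over folders of fields ("autocount").

Mirrors the interactive workflow of the original tool: count cells in one
IPL/OPL image, measure the labeled-area percentage in one NFL-GCL image,
or sweep a folder and route every stack to the appropriate measure,
logging each image name as it is processed and exporting a results table.

Layer routing is by filename pattern: batch runs need explicit rules, so
the default routes files containing ``IPL`` or ``OPL`` to cell counting
and files containing ``NFL`` to area fraction.  Per-file failures are
collected and reported, not fatal.
"""

from __future__ import annotations

import fnmatch
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .core import AreaFractionResult, CellDetections, DetectionParams, area_fraction, count_cells
from .io import read_stack, write_positions_csv, write_results_csv

__all__ = [
    "BatchConfig",
    "BatchResult",
    "count_single",
    "area_single",
    "autocount",
]

logger = logging.getLogger("gliacount")

RESULT_COLUMNS = [
    "image_name",
    "layer",
    "count",
    "percent_labeled",
    "umbral",
    "min_distance",
    "box_size",
    "n_slices",
]

DEFAULT_ROUTING = {"*IPL*": "IPL", "*OPL*": "OPL", "*NFL*": "NFL_GCL"}


@dataclass
class BatchConfig:
    """Configuration of one autocount run.

    ``layer_routing`` maps glob-style filename patterns to layers; the
    first matching pattern (in insertion order) wins.  IPL/OPL fields are
    counted with ``params_ipl_opl``; NFL-GCL fields are measured with
    ``umbral_nfl``.
    """

    images_root: Path
    results_dir: Path
    params_ipl_opl: DetectionParams = field(default_factory=DetectionParams)
    umbral_nfl: float = 0.2
    layer_routing: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_ROUTING))
    position_export: bool = False
    excel_export: bool = False
    z_step_um: float = 2.0

    def __post_init__(self) -> None:
        self.images_root = Path(self.images_root)
        self.results_dir = Path(self.results_dir)
        if not 0.0 <= self.umbral_nfl <= 1.0:
            raise ValueError(f"umbral_nfl must lie in [0, 1], got {self.umbral_nfl}")
        bad = set(self.layer_routing.values()) - {"IPL", "OPL", "NFL_GCL"}
        if bad:
            raise ValueError(f"unknown layers in routing: {sorted(bad)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "BatchConfig":
        """Load a config from a YAML key-value file."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        params = DetectionParams(**raw.pop("params_ipl_opl", {}))
        return cls(
            images_root=Path(raw.pop("images_root")),
            results_dir=Path(raw.pop("results_dir")),
            params_ipl_opl=params,
            **raw,
        )

    def route(self, name: str) -> str | None:
        for pattern, layer in self.layer_routing.items():
            if fnmatch.fnmatch(name, pattern):
                return layer
        return None


@dataclass
class BatchResult:
    """Outcome of an autocount run: the results table plus any failures."""

    table: pd.DataFrame
    failures: dict[str, str] = field(default_factory=dict)
    results_path: Path | None = None

    @property
    def ok(self) -> bool:
        return not self.failures


def count_single(stack_path: str | Path, params: DetectionParams | None = None,
                 z_step_um: float = 2.0) -> CellDetections:
    """Count cells in one IPL/OPL stack (file or folder of slices)."""
    params = params or DetectionParams()
    t0 = time.perf_counter()
    stack = read_stack(stack_path, z_step_um=z_step_um)
    det = count_cells(stack, params)
    logger.info(
        "counted %s: %d cells (umbral=%g, distance=%g) in %.2f s",
        Path(stack_path).name, det.count, params.umbral, params.min_distance,
        time.perf_counter() - t0,
    )
    return det


def area_single(stack_path: str | Path, umbral: float = 0.2,
                z_step_um: float = 2.0) -> AreaFractionResult:
    """Measure the labeled-area percentage in one NFL-GCL stack."""
    t0 = time.perf_counter()
    stack = read_stack(stack_path, z_step_um=z_step_um)
    res = area_fraction(stack, umbral)
    logger.info(
        "measured %s: %.2f%% labeled (umbral=%g) in %.2f s",
        Path(stack_path).name, res.percent_labeled, umbral,
        time.perf_counter() - t0,
    )
    return res


def _discover(root: Path) -> list[Path]:
    """Stacks under root: multi-page TIFFs plus folders of TIFF slices."""
    entries: list[Path] = []
    for p in sorted(root.iterdir()):
        if p.is_file() and p.suffix.lower() in {".tif", ".tiff"}:
            entries.append(p)
        elif p.is_dir() and any(
            q.suffix.lower() in {".tif", ".tiff"} for q in p.iterdir()
        ):
            entries.append(p)
    return entries


def autocount(config: BatchConfig) -> BatchResult:
    """Process every routed stack under ``images_root``.

    IPL/OPL fields are counted, NFL-GCL fields measured by area fraction.
    Writes ``results.csv`` (one row per field, lexicographic by image
    name) to ``results_dir``; optionally per-cell position files and a
    spreadsheet copy.  Individual file failures are logged and collected.
    """
    root = config.images_root
    if not root.is_dir():
        raise FileNotFoundError(f"images folder does not exist: {root}")
    stacks = [p for p in _discover(root) if config.route(p.name)]
    if not stacks:
        raise FileNotFoundError(f"no images found under {root}")

    rows: list[dict] = []
    failures: dict[str, str] = {}
    for path in stacks:  # _discover sorts, so row order is deterministic
        layer = config.route(path.name)
        logger.info("autocount: measuring %s (%s)", path.name, layer)
        try:
            stack = read_stack(path, z_step_um=config.z_step_um, layer=layer)
            row = {
                "image_name": path.name,
                "layer": layer,
                "count": pd.NA,
                "percent_labeled": pd.NA,
                "umbral": config.umbral_nfl,
                "min_distance": pd.NA,
                "box_size": pd.NA,
                "n_slices": stack.n_slices,
            }
            if layer in ("IPL", "OPL"):
                p = config.params_ipl_opl
                det = count_cells(stack, p)
                row.update(count=det.count, umbral=p.umbral,
                           min_distance=p.min_distance, box_size=p.box_size)
                if config.position_export:
                    write_positions_csv(
                        config.results_dir / f"{path.stem}_positions.csv",
                        det, field_id=path.stem,
                    )
            else:
                res = area_fraction(stack, config.umbral_nfl)
                row.update(percent_labeled=round(res.percent_labeled, 4))
            rows.append(row)
        except Exception as exc:  # noqa: BLE001 - per-file failure policy
            logger.error("autocount: %s failed: %s", path.name, exc)
            failures[path.name] = str(exc)

    table = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    out = write_results_csv(config.results_dir / "results.csv", table,
                            excel=config.excel_export)
    return BatchResult(table=table, failures=failures, results_path=out)
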