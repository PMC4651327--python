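"""Batch-process a folder of fields, routing each stack by layer.

Writes six synthetic TIFF stacks (four mosaics named *_IPL/*_OPL, two
confluent fields named *_NFL) into a temporary folder, then runs
autocount: IPL/OPL fields are counted, NFL fields measured by area
fraction, and a results table is exported as CSV.
"""

import tempfile
from pathlib import Path

from gliacount import (
    BatchConfig,
    autocount,
    render_confluent,
    render_stack,
    sample_mosaic,
    write_stack,
)

root = Path(tempfile.mkdtemp(prefix="gliacount_"))
images, results = root / "images", root / "results"

SIZE = (400, 520)  # reduced frame keeps the example quick
for i, (n, layer) in enumerate([(5, "IPL"), (7, "IPL"), (6, "OPL"), (8, "OPL")]):
    ds = render_stack(sample_mosaic(n, seed=50 + i, size=SIZE, n_slices=4))
    write_stack(images / f"field{i}_{layer}.tif", ds)
for i, frac in enumerate([0.3, 0.5]):
    write_stack(images / f"field{i}_NFL.tif", render_confluent(frac, size=SIZE, seed=60 + i))

outcome = autocount(BatchConfig(images_root=images, results_dir=results))
print(outcome.table.to_string(index=False))
print(f"\nresults written to {outcome.results_path}")
# Each row is one field: a cell count for IPL/OPL stacks, a labeled-area
# percentage for NFL stacks, with the parameters used alongside.
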