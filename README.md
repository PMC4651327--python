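# gliacount

Automatic counting of Iba-1+ microglial cells in whole-mount retina
fluorescence Z-stacks, with an immunolabeled area-fraction measure for
layers where individual cells cannot be separated.

Microglia proliferate and change morphology when the retina is injured
(glaucoma models, ocular hypertension, other insults), so counting them
is a routine readout in retinal neurobiology — and is usually done by
hand, field by field, which is slow and observer-dependent. In the inner
and outer plexiform layers (IPL/OPL) microglia tile the retina as a
non-overlapping mosaic, which makes automatic per-cell counting
possible. In the nerve fiber/ganglion cell layer (NFL-GCL) labeled cells
overlap, so the fraction of labeled area is quantified instead.

`gliacount` is a Python library with a thin command-line interface. It
ships a synthetic ground-truth image generator that emulates both
labeling regimes, so the whole pipeline is testable without real
retinas, and a validation harness reproducing the manual-vs-automatic
comparison statistics.

## The algorithm

For a per-field Z-stack `I_1 … I_n` (single channel, slices every 2 µm):

1. **Z projection** — per-pixel mean: `P = (1/n) Σ_k I_k`.
2. **Normalization** — `P ← P / max(P)`, so intensities lie in [0, 1].
3. **Threshold** — pixels strictly below the *umbral* `u` (default 0.2)
   are zeroed; the rest keep their value.
4. **Grid segmentation** — the image is partitioned into `b × b` tiles
   (default 50 px, anchored at the origin; partial edge tiles are
   processed like any other). For every tile with nonzero signal the
   intensity-weighted center of mass is computed in global coordinates.
   The tile size is chosen so that even the smallest cell spans at least
   4 tiles, so one cell typically produces several nearby centroids.
5. **Minimum-distance merge** — centroids closer than `d_min` (default
   50 px) are considered the same cell: connected components of the
   `< d_min` graph each collapse to their largest-mass member. The count
   is the number of components.

The area-fraction measure shares steps 1–3, then binarizes (nonzero → 1)
and reports `100 · labeled / total` percent.

## Worked example

```python
from gliacount import count_cells, render_stack, sample_mosaic

scene = sample_mosaic(n_cells=12, seed=42, n_slices=5)   # ground truth
dataset = render_stack(scene)                            # noisy Z-stack
detections = count_cells(dataset.stack)                  # the pipeline
print(detections.count)
```

Running `python examples/count_mosaic_field.py` prints:

```
planted cells : 12
counted cells : 12
params        : umbral=0.2, min_distance=50.0 px, box_size=50 px
detection-to-soma distance (px): median 5.2, max 8.4
```

Twelve cells were planted with known centers, twelve were counted, and
every reported position lies within a few pixels of a planted soma — no
cell was missed, split into two detections, or merged with a neighbor.

The other examples cover the remaining capabilities: labeled-area
fraction of a confluent field (`labeled_area_fraction.py`), folder
batch processing with CSV export (`batch_autocount_folder.py`), the
manual-vs-automatic validation statistics
(`validate_against_observer.py`), and interpolated retinal density maps
(`retina_density_map.py`).

## Command line

```sh
gliacount count field_07_IPL.tif --umbral 0.2 --distance 50
gliacount area field_03_NFL.tif --umbral-nfl 0.2
gliacount autocount --images-root images/ --results-dir results/
gliacount simulate --out-dir fixtures/ --n-mosaic 4 --n-confluent 2
gliacount validate paired_counts.csv
```

`autocount` routes every stack in a folder by filename pattern (IPL/OPL
→ cell counting, NFL → area fraction), logs each image as it is
processed, and writes one results row per field.

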