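"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by the most literal route possible
(explicit loops, exhaustive enumeration, closed-form textbook formulas)
and never shares code with the implementation it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def mean_projection_loop(slices: np.ndarray) -> np.ndarray:
    """Per-pixel arithmetic mean via an explicit triple loop."""
    n, h, w = slices.shape
    out = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            s = 0.0
            for k in range(n):
                s += float(slices[k, i, j])
            out[i, j] = s / n
    return out


def tile_centroids_loop(image: np.ndarray, box: int) -> dict:
    """Mass-weighted tile centroids via an explicit double loop.

    Returns {(tile_row, tile_col): (cy, cx, mass)} for nonzero tiles.
    """
    h, w = image.shape
    out = {}
    for bi in range(math.ceil(h / box)):
        for bj in range(math.ceil(w / box)):
            mass = sy = sx = 0.0
            for i in range(bi * box, min((bi + 1) * box, h)):
                for j in range(bj * box, min((bj + 1) * box, w)):
                    v = float(image[i, j])
                    mass += v
                    sy += v * i
                    sx += v * j
            if mass > 0:
                out[(bi, bj)] = (sy / mass, sx / mass, mass)
    return out


def merge_count_union_find(coords: np.ndarray, min_distance: float) -> int:
    """Connected components of the '< min_distance' graph via union-find."""
    n = len(coords)
    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(n):
        for j in range(i + 1, n):
            d = math.dist(coords[i], coords[j])
            if d < min_distance:
                parent[find(i)] = find(j)
    return len({find(i) for i in range(n)})


def area_percent_loop(image: np.ndarray, umbral: float) -> float:
    """Percent of normalized pixels >= umbral, counted pixel by pixel."""
    peak = 0.0
    for row in image:
        for v in row:
            peak = max(peak, float(v))
    labeled = 0
    total = 0
    for row in image:
        for v in row:
            total += 1
            if peak > 0 and float(v) / peak >= umbral:
                labeled += 1
    return 100.0 * labeled / total


def pearson_and_slope_closed_form(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Textbook Pearson r and OLS slope/intercept of y on x."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n = x.size
    sx, sy = x.sum(), y.sum()
    sxx, syy, sxy = (x * x).sum(), (y * y).sum(), (x * y).sum()
    cov = sxy - sx * sy / n
    varx = sxx - sx * sx / n
    vary = syy - sy * sy / n
    r = cov / math.sqrt(varx * vary)
    slope = cov / varx
    intercept = (sy - slope * sx) / n
    return r, slope, intercept


def wilcoxon_exhaustive(diffs: np.ndarray) -> tuple[float, float]:
    """Signed-rank statistic and two-sided p by enumerating all 2^n signs.

    Drops zero differences and uses midranks for ties.  The two-sided p
    is the symmetric tail mass P(|W+ - S/2| >= |w+ - S/2|) under the
    uniform sign-flip null.
    """
    d = np.asarray(diffs, dtype=np.float64)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 0.0, 1.0
    absd = np.abs(d)
    order = np.argsort(absd, kind="stable")
    ranks = np.empty(n)
    i = 0
    sorted_abs = absd[order]
    while i < n:
        j = i
        while j < n and sorted_abs[j] == sorted_abs[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0  # midrank of positions i..j-1 (1-based)
        i = j
    w_plus = ranks[d > 0].sum()
    total = ranks.sum()
    observed_dev = abs(w_plus - total / 2.0)
    hits = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if abs(w - total / 2.0) >= observed_dev - 1e-9:
            hits += 1
    return min(w_plus, total - w_plus), hits / 2.0**n


def trimmed_sort_and_slice(values, k: int) -> dict:
    """Trim-k summary via Python sort and slice."""
    v = sorted(float(x) for x in values)
    kept = v[k: len(v) - k] if k else v
    arr = np.array(kept)
    return {
        "n": len(kept),
        "mean": arr.mean(),
        "sd": arr.std(ddof=1) if len(kept) > 1 else 0.0,
        "median": float(np.median(arr)),
        "q25": float(np.percentile(arr, 25)),
        "q75": float(np.percentile(arr, 75)),
    }
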