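"""Tests for the manual-vs-automatic validation statistics and maps."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from gliacount import (
    build_density_map,
    average_density_maps,
    linear_fit_and_r,
    load_paired_counts,
    observer_experiment,
    simulate_manual_observer,
    trimmed_group_summary,
    wilcoxon_signed_rank,
)

from oracles import (
    pearson_and_slope_closed_form,
    trimmed_sort_and_slice,
    wilcoxon_exhaustive,
)


def make_pairs(manual, auto, group="naive", layer="IPL"):
    n = len(manual)
    return pd.DataFrame({
        "field_id": [f"f{i}" for i in range(n)],
        "group": [group] * n,
        "layer": [layer] * n,
        "manual_count": manual,
        "auto_count": auto,
    })


class TestLinearFit:
    def test_identity_counts_give_unit_slope_and_r(self):
        m = np.array([10, 14, 20, 26, 31])
        s = linear_fit_and_r(make_pairs(m, m))
        assert s.slope == pytest.approx(1.0)
        assert s.intercept == pytest.approx(0.0)
        assert s.pearson_r == pytest.approx(1.0)

    def test_doubled_counts_give_slope_two(self):
        m = np.array([5, 9, 12, 20])
        s = linear_fit_and_r(make_pairs(m, 2 * m))
        assert s.slope == pytest.approx(2.0)
        assert s.pearson_r == pytest.approx(1.0)

    def test_matches_closed_form_oracle(self, rng):
        manual = rng.integers(5, 40, size=60)
        auto = rng.poisson(manual)  # observer noise
        s = linear_fit_and_r(make_pairs(manual, auto))
        r, slope, intercept = pearson_and_slope_closed_form(manual, auto)
        assert s.pearson_r == pytest.approx(r, abs=1e-12)
        assert s.slope == pytest.approx(slope, abs=1e-12)
        assert s.intercept == pytest.approx(intercept, abs=1e-12)

    def test_subgroup_fits_reported_per_group_and_layer(self, rng):
        frames = []
        for g in ("naive", "contralateral", "OHT"):
            for l in ("IPL", "OPL"):
                m = rng.integers(5, 40, size=20)
                frames.append(make_pairs(m, m + rng.integers(-1, 2, size=20), g, l))
        s = linear_fit_and_r(pd.concat(frames, ignore_index=True))
        assert set(s.subgroups) == {(g, l) for g in ("OHT", "contralateral", "naive")
                                    for l in ("IPL", "OPL")}
        for fit in s.subgroups.values():
            assert fit.n == 20
            assert fit.pearson_r > 0.9

    def test_zero_variance_manual_reported_as_undefined(self):
        s = linear_fit_and_r(make_pairs([7, 7, 7, 7], [6, 7, 8, 7]))
        assert np.isnan(s.slope) and np.isnan(s.pearson_r)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            linear_fit_and_r(make_pairs([1, 2], [1, 2]))


class TestWilcoxon:
    def test_small_fixture_matches_exhaustive_enumeration(self):
        diffs = np.array([1.0, -1.0, 2.0, -2.0])
        stat, p = wilcoxon_signed_rank(diffs)
        stat_o, p_o = wilcoxon_exhaustive(diffs)
        assert stat == pytest.approx(stat_o)
        assert p == pytest.approx(p_o)

    def test_n6_fixture_exact_p_matches_enumeration(self):
        diffs = np.array([3.0, -1.0, 4.0, 2.0, -5.0, 6.0])
        stat, p = wilcoxon_signed_rank(diffs)
        stat_o, p_o = wilcoxon_exhaustive(diffs)
        assert (stat, p) == (pytest.approx(stat_o), pytest.approx(p_o))

    def test_random_fixtures_up_to_n12_match_enumeration(self, rng):
        for n in range(2, 13):
            for _ in range(3):
                diffs = rng.integers(-6, 7, size=n).astype(float)
                if not np.any(diffs):
                    diffs[0] = 1.0
                stat, p = wilcoxon_signed_rank(diffs)
                stat_o, p_o = wilcoxon_exhaustive(diffs)
                assert stat == pytest.approx(stat_o), diffs
                assert p == pytest.approx(p_o), diffs

    def test_agrees_with_reference_implementation_without_ties(self):
        diffs = np.array([1.3, -2.7, 3.1, -4.9, 5.2, 6.8, -7.4, 8.9])
        stat, p = wilcoxon_signed_rank(diffs)
        ref = sps.wilcoxon(diffs, method="exact")
        assert stat == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_identical_columns_degenerate(self):
        pairs = make_pairs([4, 6, 9], [4, 6, 9])
        with pytest.warns(UserWarning, match="degenerate"):
            stat, p = wilcoxon_signed_rank(pairs)
        assert (stat, p) == (0.0, 1.0)

    def test_large_sample_uses_normal_approximation(self, rng):
        diffs = rng.integers(-5, 6, size=200).astype(float)
        diffs[diffs == 0] = 1.0
        stat, p = wilcoxon_signed_rank(diffs)
        assert 0.0 <= p <= 1.0
        ref = sps.wilcoxon(diffs, method="approx", correction=True)
        assert p == pytest.approx(ref.pvalue, abs=0.02)


class TestTrimming:
    def test_141_values_retain_121(self, rng):
        values = rng.normal(20, 5, size=141)
        assert trimmed_group_summary(values, k=10).n == 121

    def test_constant_list(self):
        s = trimmed_group_summary([5.0] * 30, k=10)
        assert s.median == 5.0 and s.mean == 5.0 and s.sd == 0.0

    def test_matches_sort_and_slice_oracle(self, rng):
        values = rng.uniform(0, 100, size=57)
        s = trimmed_group_summary(values, k=10)
        o = trimmed_sort_and_slice(values, 10)
        for name in ("n", "mean", "sd", "median", "q25", "q75"):
            assert getattr(s, name) == pytest.approx(o[name]), name

    def test_permutation_invariant(self, rng):
        values = rng.uniform(0, 100, size=45)
        shuffled = rng.permutation(values)
        assert trimmed_group_summary(values, 10) == trimmed_group_summary(shuffled, 10)

    def test_too_short_list_rejected(self):
        with pytest.raises(ValueError, match="more than 20"):
            trimmed_group_summary([1.0] * 20, k=10)


def two_meridian_layout(n_per_arm=5, extent=4.0):
    """Field centers along a horizontal and a vertical meridian crossing
    at the optic nerve (origin), like the sampling scheme of a whole
    mount."""
    layout = {}
    ts = np.linspace(-extent, extent, n_per_arm)
    for i, t in enumerate(ts):
        layout[f"h{i}"] = (t, 0.12 * (-1) ** i)  # slight jitter off-axis
        layout[f"v{i}"] = (0.12 * (-1) ** (i + 1), t)
    return layout


class TestDensityMap:
    def test_uniform_counts_give_constant_map(self):
        layout = two_meridian_layout()
        counts = {f: 7 for f in layout}
        dm = build_density_map(counts, layout, resolution=40)
        inside = dm.grid[~np.isnan(dm.grid)]
        np.testing.assert_allclose(inside, 7.0, atol=1e-9)

    def test_hotspot_field_is_the_map_maximum(self):
        layout = two_meridian_layout()
        counts = {f: 5 for f in layout}
        counts["h0"] = 30  # inferior-retina hotspot
        dm = build_density_map(counts, layout, resolution=80)
        iy, ix = np.unravel_index(np.nanargmax(dm.grid), dm.grid.shape)
        hx, hy = layout["h0"]
        assert abs(dm.x_coords[ix] - hx) < 0.3
        assert abs(dm.y_coords[iy] - hy) < 0.3

    def test_interpolant_passes_through_field_counts(self, rng):
        layout = two_meridian_layout()
        counts = {f: int(c) for f, c in zip(layout, rng.integers(3, 30, len(layout)))}
        dm = build_density_map(counts, layout, resolution=60)
        from scipy.interpolate import LinearNDInterpolator

        pts = np.array([layout[f] for f in counts])
        interp = LinearNDInterpolator(pts, np.array(list(counts.values()), float))
        for f, c in counts.items():
            assert interp(*layout[f]) == pytest.approx(c)

    def test_map_bounded_by_input_counts(self, rng):
        layout = two_meridian_layout()
        counts = {f: int(c) for f, c in zip(layout, rng.integers(3, 30, len(layout)))}
        dm = build_density_map(counts, layout, resolution=50)
        inside = dm.grid[~np.isnan(dm.grid)]
        assert inside.min() >= min(counts.values()) - 1e-9
        assert inside.max() <= max(counts.values()) + 1e-9

    def test_collinear_layout_falls_back_to_1d_with_warning(self):
        layout = {f"f{i}": (float(i), 0.0) for i in range(5)}
        counts = {f: i + 1 for i, f in enumerate(layout)}
        with pytest.warns(UserWarning, match="collinear"):
            dm = build_density_map(counts, layout, resolution=30)
        assert dm.grid.shape[0] == 1
        assert dm.grid.min() >= 1 and dm.grid.max() <= 5

    def test_export_writes_text_matrix_and_image(self, tmp_path, rng):
        layout = two_meridian_layout()
        counts = {f: int(c) for f, c in zip(layout, rng.integers(3, 30, len(layout)))}
        dm = build_density_map(counts, layout, resolution=30, group="naive", layer="IPL")
        from gliacount import save_density_map

        txt, png = tmp_path / "map.txt", tmp_path / "map.png"
        save_density_map(dm, txt_path=txt, png_path=png)
        grid = np.loadtxt(txt)
        np.testing.assert_allclose(grid, dm.grid, atol=1e-4, equal_nan=True)
        assert png.stat().st_size > 0

    def test_group_average_of_identical_maps_is_identity(self, rng):
        layout = two_meridian_layout()
        counts = {f: int(c) for f, c in zip(layout, rng.integers(3, 30, len(layout)))}
        dm = build_density_map(counts, layout, resolution=40)
        avg = average_density_maps([dm, dm, dm])
        np.testing.assert_allclose(avg.grid, dm.grid, equal_nan=True)


class TestObserverExperiment:
    def test_positions_loadable_and_observer_structure(self, rng):
        auto = rng.integers(5, 41, size=120)
        manual = simulate_manual_observer(auto, np.random.default_rng(1))
        assert np.all(np.abs(manual - auto) <= 1)
        assert np.all(manual >= 0)

    def test_single_replicate_reproduces_agreement_structure(self, rng):
        auto = np.resize(np.arange(5, 41), 120)
        s = observer_experiment(auto, np.random.default_rng(3))
        assert 0.9 <= s.slope <= 1.1
        assert s.pearson_r > 0.9
        assert s.wilcoxon_p > 0.05


class TestPairedCountsIO:
    def test_roundtrip_csv(self, tmp_path, rng):
        m = rng.integers(5, 40, size=12)
        pairs = make_pairs(m, m + rng.integers(-1, 2, size=12))
        path = tmp_path / "pairs.csv"
        pairs.to_csv(path, index=False)
        loaded = load_paired_counts(path)
        pd.testing.assert_frame_equal(loaded, pairs)

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("a,b\n1,2\n")
        with pytest.raises(ValueError, match="missing columns"):
            load_paired_counts(path)
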