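import numpy as np
import pytest

from aevindex.grid import Grid, ParameterError, RegionSet, make_grid
from aevindex.index import (
    BIN_LABELS,
    bin_percentiles,
    layer_contributions,
    mpa_overlap,
    percent_difference,
    polynya_region_stats,
    regional_index,
    scale_and_sum,
)
from aevindex.layers import LayerStack


def toy_grid(nlat=6, nlon=6):
    g = make_grid((-78, -66), lon_step=360 / nlon, lat_step=12 / nlat)
    g.cell_area[:] = 1.0  # unit areas make hand arithmetic easy
    return g


def toy_regions(grid, split=None):
    if split is None:
        masks = {"R1": grid.ocean_mask.copy()}
    else:
        left = grid.lon2d() < split
        masks = {"R1": grid.ocean_mask & left, "R2": grid.ocean_mask & ~left}
    return RegionSet(grid, masks)


def stack_from(grid, **kw):
    layers = {k: np.full(grid.shape, np.nan) for k in ("npp", "kgp", "dfp", "epp", "app")}
    layers.update({k: np.asarray(v, dtype=float) for k, v in kw.items()})
    return LayerStack(grid, **layers)


class TestScaleAndSum:
    def test_constant_layers_sum_to_five(self):
        g = toy_grid()
        zone = g.ocean_mask
        st = stack_from(g, **{k: np.full(g.shape, c) for k, c in
                              zip(("npp", "kgp", "dfp", "epp", "app"), (1, 2, 3, 4, 5))})
        total, scaled = scale_and_sum(st, zone)
        assert np.allclose(total[zone], 5.0)
        for s in scaled.values():
            assert np.allclose(s[zone], 1.0)

    def test_zero_layer_contributes_nothing(self):
        g = toy_grid()
        zone = g.ocean_mask
        base = {k: np.ones(g.shape) for k in ("npp", "kgp", "dfp", "epp")}
        with pytest.warns(UserWarning):
            total, _ = scale_and_sum(stack_from(g, app=np.zeros(g.shape), **base), zone)
        assert np.allclose(total[zone], 4.0)

    def test_three_cell_hand_computed(self):
        g = toy_grid(1, 3)
        zone = g.ocean_mask
        npp = np.array([[2.0, 1.0, 0.0]])
        kgp = np.array([[0.0, 3.0, 6.0]])
        st = stack_from(g, npp=npp, kgp=kgp,
                        dfp=np.zeros((1, 3)), epp=np.zeros((1, 3)), app=np.zeros((1, 3)))
        with pytest.warns(UserWarning):
            total, _ = scale_and_sum(st, zone)
        # npp/2 + kgp/6 per cell
        assert np.allclose(total, [[1.0, 1.0, 1.0]])

    def test_missing_inside_zone_counts_as_zero(self):
        g = toy_grid(1, 3)
        zone = g.ocean_mask
        npp = np.array([[2.0, np.nan, 1.0]])
        ones = np.ones((1, 3))
        st = stack_from(g, npp=npp, kgp=ones, dfp=ones, epp=ones, app=ones)
        total, _ = scale_and_sum(st, zone)
        assert total[0, 1] == pytest.approx(4.0)  # four live layers only


class TestRegionalIndex:
    def test_max_cell_is_one(self):
        g = toy_grid()
        rs = toy_regions(g, split=180)
        aevsum = np.abs(np.sin(np.arange(36).reshape(6, 6) / 3.0)) + 0.1
        res = regional_index(aevsum, rs)
        for m in rs.masks.values():
            assert np.nanmax(res.aev[m]) == pytest.approx(1.0)

    def test_half_of_regional_max(self):
        g = toy_grid(1, 4)
        rs = toy_regions(g)
        res = regional_index(np.array([[2.5, 1.25, 0.5, 0.0]]), rs)
        assert res.aev[0, 0] == pytest.approx(1.0)
        assert res.aev[0, 1] == pytest.approx(0.5)

    def test_regional_geq_hemispheric(self):
        g = toy_grid()
        rs = toy_regions(g, split=180)
        rng = np.random.default_rng(3)
        aevsum = rng.uniform(0.1, 4.0, g.shape)
        reg = regional_index(aevsum, rs, "regional")
        hemi = regional_index(aevsum, rs, "hemispheric")
        sel = np.isfinite(reg.aev) & np.isfinite(hemi.aev)
        assert np.all(reg.aev[sel] >= hemi.aev[sel] - 1e-12)

    def test_idempotent(self):
        g = toy_grid()
        rs = toy_regions(g, split=180)
        rng = np.random.default_rng(4)
        res = regional_index(rng.uniform(0, 3, g.shape), rs)
        res2 = regional_index(res.aev, rs)
        assert np.allclose(res.aev, res2.aev, equal_nan=True)

    def test_scale_invariance_of_single_layer(self):
        # multiplying one input layer by a constant changes nothing
        g = toy_grid()
        rs = toy_regions(g, split=180)
        zone = g.ocean_mask
        rng = np.random.default_rng(5)
        base = {k: rng.uniform(0, 2, g.shape) for k in ("npp", "kgp", "dfp", "epp", "app")}
        res1 = regional_index(stack_from(g, **base), rs, zone_mask=zone)
        base["kgp"] = base["kgp"] * 137.0
        res2 = regional_index(stack_from(g, **base), rs, zone_mask=zone)
        assert np.allclose(res1.aev, res2.aev, equal_nan=True)
        bin_percentiles(res1)
        bin_percentiles(res2)
        assert np.array_equal(res1.bins, res2.bins)


class TestBins:
    def binned_sizes(self, values, cutoffs=(5, 10, 25)):
        n = len(values)
        g = toy_grid(1, n)
        rs = toy_regions(g)
        res = regional_index(np.asarray(values, dtype=float)[None, :], rs)
        bins = bin_percentiles(res, cutoffs)
        return [(bins == code).sum() for code in (3, 2, 1, 0)]

    def test_hundred_distinct_values(self):
        assert self.binned_sizes(np.arange(1, 101)) == [5, 5, 15, 75]

    def test_twenty_distinct_values(self):
        assert self.binned_sizes(np.arange(1, 21)) == [1, 1, 3, 15]

    def test_all_equal_goes_to_other(self):
        assert self.binned_sizes(np.full(40, 2.0)) == [0, 0, 0, 40]

    def test_bins_nest_under_cutoff_widening(self):
        rng = np.random.default_rng(9)
        vals = rng.uniform(0, 1, 200)
        g = toy_grid(1, 200)
        rs = toy_regions(g)
        res = regional_index(vals[None, :], rs)
        narrow = bin_percentiles(res, (5, 10, 25)).copy()
        wide = bin_percentiles(res, (10, 20, 50)).copy()
        assert np.all(wide[narrow == 3] >= 1)  # exceptional stays valuable

    def test_bad_cutoffs_raise(self):
        g = toy_grid()
        res = regional_index(np.ones(g.shape), toy_regions(g))
        with pytest.raises(ParameterError):
            bin_percentiles(res, (25, 10, 5))


class TestPercentDifference:
    @pytest.mark.parametrize("mean_in,mean_out,expected", [
        (0.52, 0.38, 31),  # Weddell Sea
        (0.61, 0.43, 35),  # East Antarctic
        (0.52, 0.36, 36),  # Amundsen Sea
        (0.43, 0.28, 42),  # hemispheric
    ])
    def test_reported_regional_values(self, mean_in, mean_out, expected):
        assert round(percent_difference(mean_in, mean_out)) == expected

    def test_equal_means_zero(self):
        assert percent_difference(0.4, 0.4) == 0.0

    def test_zero_denominator_raises(self):
        with pytest.raises(ParameterError):
            percent_difference(0.0, 0.0)


def _hand_stats_oracle(aev, bins, poly, area):
    """Independent re-computation of the polynya table with plain loops."""
    out = {}
    for tag, mask in (("inside", poly), ("outside", ~poly)):
        num = den = 0.0
        for i in range(aev.shape[0]):
            for j in range(aev.shape[1]):
                if mask[i, j] and np.isfinite(aev[i, j]):
                    num += area[i, j] * aev[i, j]
                    den += area[i, j]
        mean = num / den if den else np.nan
        sq = 0.0
        for i in range(aev.shape[0]):
            for j in range(aev.shape[1]):
                if mask[i, j] and np.isfinite(aev[i, j]):
                    sq += area[i, j] * (aev[i, j] - mean) ** 2
        out[f"avg_{tag}"] = mean
        out[f"std_{tag}"] = np.sqrt(sq / den) if den else np.nan
    out["pct_diff"] = 100 * (out["avg_inside"] - out["avg_outside"]) / (
        0.5 * (out["avg_inside"] + out["avg_outside"]))
    dom_area = sum(area[i, j] for i in range(aev.shape[0]) for j in range(aev.shape[1])
                   if np.isfinite(aev[i, j]))
    in_area = sum(area[i, j] for i in range(aev.shape[0]) for j in range(aev.shape[1])
                  if np.isfinite(aev[i, j]) and poly[i, j])
    out["pct_area"] = 100 * in_area / dom_area
    for code, label in enumerate(BIN_LABELS):
        tot = hit = 0.0
        for i in range(aev.shape[0]):
            for j in range(aev.shape[1]):
                if np.isfinite(aev[i, j]) and bins[i, j] == code:
                    tot += area[i, j]
                    if poly[i, j]:
                        hit += area[i, j]
        out[f"pct_{label}"] = 100 * hit / tot if tot else np.nan
    return out


class TestTables:
    @pytest.fixture
    def setup(self):
        g = toy_grid(6, 6)
        rng = np.random.default_rng(11)
        g.cell_area[:] = rng.uniform(0.5, 2.0, g.shape)  # non-trivial weights
        rs = toy_regions(g)
        aevsum = rng.uniform(0.05, 3.0, g.shape)
        res = regional_index(aevsum, rs)
        bin_percentiles(res)
        poly = rng.uniform(size=g.shape) < 0.3
        return g, res, poly

    def test_matches_hand_coded_oracle(self, setup):
        g, res, poly = setup
        table = polynya_region_stats(res, poly, include_hemi=False)["R1"]
        oracle = _hand_stats_oracle(res.aev, res.bins, poly, g.cell_area)
        assert table["avg_inside_poly"] == pytest.approx(oracle["avg_inside"])
        assert table["avg_outside_poly"] == pytest.approx(oracle["avg_outside"])
        assert table["std_inside_poly"] == pytest.approx(oracle["std_inside"])
        assert table["std_outside_poly"] == pytest.approx(oracle["std_outside"])
        assert table["pct_difference"] == pytest.approx(oracle["pct_diff"])
        assert table["pct_area_inside_poly"] == pytest.approx(oracle["pct_area"])
        for label in BIN_LABELS:
            assert table[f"pct_{label}_inside_poly"] == pytest.approx(
                oracle[f"pct_{label}"], nan_ok=True)

    def test_empty_polynya_mask(self, setup):
        g, res, _ = setup
        with pytest.warns(UserWarning):
            table = polynya_region_stats(res, np.zeros(g.shape, bool), include_hemi=False)
        assert np.isnan(table["R1"]["avg_inside_poly"])
        whole_mean = polynya_region_stats(res, np.zeros(g.shape, bool),
                                          include_hemi=False)["R1"]["avg_outside_poly"]
        assert table["R1"]["avg_outside_poly"] == pytest.approx(whole_mean)

    def test_bin_areas_partition(self, setup):
        g, res, poly = setup
        dom = np.isfinite(res.aev)
        areas = [g.cell_area[dom & (res.bins == c)].sum() for c in range(4)]
        assert sum(areas) == pytest.approx(g.cell_area[dom].sum())

    def test_mpa_full_and_empty(self, setup):
        g, res, _ = setup
        full = mpa_overlap(res, np.ones(g.shape, bool), include_hemi=False)
        empty = mpa_overlap(res, np.zeros(g.shape, bool), include_hemi=False)
        assert np.allclose(full["R1"].dropna(), 100.0)
        assert np.allclose(empty["R1"].dropna(), 0.0)

    def test_mpa_half_exceptional_by_area(self):
        g = toy_grid(1, 40)
        rs = toy_regions(g)
        res = regional_index(np.arange(1.0, 41.0)[None, :], rs)
        bin_percentiles(res)
        exc = res.bin_mask("exceptional")
        idx = np.argwhere(exc)
        mpa = np.zeros(g.shape, bool)
        mpa[idx[0][0], idx[0][1]] = True  # one of the two exceptional cells
        table = mpa_overlap(res, mpa, include_hemi=False)
        assert table["R1"]["pct_exceptional_inside_mpa"] == pytest.approx(50.0)


class TestLayerContributions:
    def test_sum_to_hundred(self):
        g = toy_grid()
        rs = toy_regions(g)
        rng = np.random.default_rng(13)
        base = {k: rng.uniform(0.1, 2.0, g.shape) for k in ("npp", "kgp", "dfp", "epp", "app")}
        res = regional_index(stack_from(g, **base), rs, zone_mask=g.ocean_mask)
        _, dominant, ambiguous = layer_contributions(res)
        stack = np.stack([res.scaled_layers[k] for k in ("NPP", "KGP", "DFP", "EPP", "APP")])
        total = 100 * stack / res.aevsum
        assert np.allclose(np.nansum(total, axis=0)[np.isfinite(res.aevsum)], 100.0)

    def test_single_layer_dominates_unambiguously(self):
        g = toy_grid()
        rs = toy_regions(g)
        only = stack_from(g, npp=np.ones(g.shape), kgp=np.zeros(g.shape),
                          dfp=np.zeros(g.shape), epp=np.zeros(g.shape),
                          app=np.zeros(g.shape))
        with pytest.warns(UserWarning):
            res = regional_index(only, rs, zone_mask=g.ocean_mask)
        table, dominant, ambiguous = layer_contributions(res)
        assert table["domain"]["NPP"] == pytest.approx(100.0)
        assert np.all(dominant[g.ocean_mask] == 0)
        assert not ambiguous.any()

    @pytest.mark.parametrize("top,second,expect_ambiguous", [
        (30.0, 28.0, True),   # 30 < 1.1 * 28 = 30.8
        (50.0, 20.0, False),  # 50 >= 22
    ])
    def test_ambiguity_rule(self, top, second, expect_ambiguous):
        assert (top < 1.1 * second) is expect_ambiguous
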