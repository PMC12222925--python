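import numpy as np
import pandas as pd
import pytest

from shiftorder import niche
from shiftorder.niche import (assign_whittaker_biome, biome_chisq,
                              categorize_elevation, grid_subsample, pore_area,
                              summarize_species)


def occ(rows):
    return pd.DataFrame(rows, columns=niche.OCC_COLUMNS)


class TestGridSubsample:
    def test_same_cell_collapses(self):
        df = occ([("sp1", 10.001, 5.001, 100, 20, 1000),
                  ("sp1", 10.002, 5.002, 110, 20, 1000)])
        assert len(grid_subsample(df)) == 1

    def test_per_species_rule(self):
        df = occ([("sp1", 10.001, 5.001, 100, 20, 1000),
                  ("sp2", 10.001, 5.001, 100, 20, 1000)])
        assert len(grid_subsample(df)) == 2

    def test_matches_brute_force_cell_count(self):
        rng = np.random.default_rng(0)
        cell = 1.0 / 120.0
        # 100 points scattered over 10 chosen distinct cells
        cells = [(int(c), int(c) + 300) for c in range(10)]
        lon = np.array([cells[i % 10][0] * cell + rng.uniform(0, cell)
                        for i in range(100)])
        lat = np.array([cells[i % 10][1] * cell + rng.uniform(0, cell)
                        for i in range(100)])
        df = occ([("sp", lo, la, 0.0, 20, 1000) for lo, la in zip(lon, lat)])
        out = grid_subsample(df, cell)
        brute = {(int(np.floor(lo / cell)), int(np.floor(la / cell)))
                 for lo, la in zip(lon, lat)}
        assert len(out) == len(brute) == 10

    def test_invariant_to_row_order(self):
        rng = np.random.default_rng(1)
        df = occ([("sp", rng.uniform(0, 0.1), rng.uniform(0, 0.1),
                   rng.uniform(0, 100), 20, 1000) for _ in range(50)])
        a = grid_subsample(df)
        b = grid_subsample(df.sample(frac=1, random_state=2))
        pd.testing.assert_frame_equal(a, b)

    def test_empty_input(self):
        assert grid_subsample(occ([])).empty


class TestSummaries:
    def test_single_record(self):
        s = summarize_species(occ([("sp", 0, 0, 800, 18, 1500)]))
        assert s.loc[0, "median_elevation_m"] == 800
        assert s.loc[0, "elevation_bin"] == "E2"

    def test_odd_count_median(self):
        s = summarize_species(occ([("sp", 0, 0, e, 20, 1500)
                                   for e in (100, 400, 1600)]))
        assert s.loc[0, "median_elevation_m"] == 400
        assert s.loc[0, "elevation_bin"] == "E1"

    def test_even_count_median_boundary(self):
        s = summarize_species(occ([("sp", 0, 0, 400, 20, 1500),
                                   ("sp", 0, 1, 600, 20, 1500)]))
        assert s.loc[0, "median_elevation_m"] == 500
        assert s.loc[0, "elevation_bin"] == "E2"  # left-closed boundary

    def test_latitude_is_median_absolute(self):
        s = summarize_species(occ([("sp", 0, -10, 0, 20, 1500),
                                   ("sp", 0, 12, 0, 20, 1500),
                                   ("sp", 0, -11, 0, 20, 1500)]))
        assert s.loc[0, "median_abs_latitude"] == 11

    def test_montane_flags_consistent_with_bins(self):
        rng = np.random.default_rng(4)
        elevs = np.concatenate([rng.uniform(0, 2500, 40),
                                [500.0, 1000.0, 1500.0]])
        s = summarize_species(occ([(f"sp{i}", 0, 0, e, 20, 1500)
                                   for i, e in enumerate(elevs)]))
        montane = s["montane_1000"].to_numpy()
        in_high_bin = s["elevation_bin"].isin(["E3", "E4"]).to_numpy()
        assert np.array_equal(montane, in_high_bin)


class TestCategorize:
    @pytest.mark.parametrize("e,expected", [
        (499, "E1"), (500, "E2"), (999.9, "E2"), (1000, "E3"),
        (1499, "E3"), (1500, "E4"), (1600, "E4"),
    ])
    def test_boundaries_left_closed(self, e, expected):
        assert categorize_elevation(e) == expected

    def test_negative_elevation_warns_to_lowest_bin(self):
        with pytest.warns(UserWarning, match="negative"):
            assert categorize_elevation(-5.0) == "E1"


class TestBiomes:
    def test_tropical_rain_forest_point(self):
        bid, extrap = assign_whittaker_biome(26.0, 3500.0)
        assert bid == 5 and not extrap

    def test_tundra_point(self):
        bid, extrap = assign_whittaker_biome(-12.0, 200.0)
        assert bid == 1 and not extrap

    def test_negative_precipitation_rejected(self):
        with pytest.raises(ValueError, match="negative precipitation"):
            assign_whittaker_biome(26.0, -1.0)

    def test_outside_every_polygon_flagged(self):
        bid, extrap = assign_whittaker_biome(-14.0, 4000.0)
        assert bid in range(1, 10) and extrap

    def test_missing_climate_missing_biome(self):
        ids, _ = assign_whittaker_biome(np.array([np.nan]), np.array([100.0]))
        assert ids[0] == 0


class TestChisq:
    def _summaries(self, counts):
        # counts: dict group -> dict biome -> n; encode via synthetic species
        rows, groups = [], {}
        i = 0
        for g, per in counts.items():
            for b, n in per.items():
                for _ in range(n):
                    rows.append({"species": f"s{i}", "biome": b})
                    groups[f"s{i}"] = g
                    i += 1
        return pd.DataFrame(rows), pd.Series(groups)

    def test_uniform_table_is_null(self):
        summ, grp = self._summaries({"a": {5: 10, 6: 10}, "b": {5: 10, 6: 10}})
        res = biome_chisq(grp, summ)
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(res.residuals.to_numpy(), 0.0)

    def test_hand_computed_2x2(self):
        # [[20, 5], [5, 20]]: E = 12.5 everywhere, chi2 = 4 * 7.5^2/12.5 = 18
        # with 1 df; every standardized residual is
        # (O-E)/sqrt(E (1-row/n)(1-col/n)) = 7.5/sqrt(12.5*0.5*0.5) = sqrt(18)
        summ, grp = self._summaries({"a": {5: 20, 6: 5}, "b": {5: 5, 6: 20}})
        res = biome_chisq(grp, summ)
        assert res.chi2 == pytest.approx(18.0, abs=1e-9)
        assert res.df == 1
        expected = 7.5 / np.sqrt(12.5 * 0.5 * 0.5)
        assert np.allclose(np.abs(res.residuals.to_numpy()), expected,
                           atol=1e-9)
        assert len(res.strong_cells) == 4

    def test_single_group_rejected(self):
        summ, grp = self._summaries({"a": {5: 10, 6: 10}})
        with pytest.raises(ValueError):
            biome_chisq(grp, summ)


class TestPoreArea:
    @pytest.mark.parametrize("h,w,expected", [
        (2.0, 2.0, np.pi),
        (0.0, 5.0, 0.0),
        (1.0, 3.0, 3 * np.pi / 4),
    ])
    def test_formula(self, h, w, expected):
        assert pore_area(h, w) == pytest.approx(expected, abs=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            pore_area(-1.0, 2.0)


# -- property-based invariants ---------------------------------------------

from hypothesis import given, settings, strategies as st


@settings(max_examples=100, derandomize=True, deadline=None)
@given(st.floats(min_value=0.0, max_value=5000.0, allow_nan=False))
def test_bin_and_montane_flag_always_agree(elevation):
    """The left-closed bin and the montane flags encode the same boundary."""
    b = categorize_elevation(elevation)
    assert (b in ("E3", "E4")) == (elevation >= 1000.0)
    assert (b == "E4") == (elevation >= 1500.0)
    assert (b != "E1") == (elevation >= 500.0)


@settings(max_examples=60, derandomize=True, deadline=None)
@given(st.floats(min_value=0, max_value=10, allow_nan=False),
       st.floats(min_value=0, max_value=10, allow_nan=False),
       st.floats(min_value=0.1, max_value=5, allow_nan=False))
def test_pore_area_bilinear_scaling(h, w, c):
    """A = pi a b is bilinear: scaling one axis scales the area."""
    assert pore_area(c * h, w) == pytest.approx(c * pore_area(h, w), rel=1e-12)
    assert pore_area(h, w) == pytest.approx(pore_area(w, h), rel=1e-12)
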