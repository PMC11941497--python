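"""Distance grouping, density maps, spatial profiles, timecourse."""

import numpy as np
import pandas as pd
import pytest

import epidermap as em
from epidermap.datatypes import ParameterError
from epidermap.pipeline import analyze_section
from epidermap.spatial import DEFAULT_HF_EDGES, bin_by_hf_distance, kde_integral


class TestHFGrouping:
    def test_half_open_bins(self):
        tab = pd.DataFrame(
            {"dist_hf": [99.0, 100.0, 750.0], "brdu_mean": [1.0, 2.0, 3.0], "ki67_mean": 1.0}
        )
        grouping = bin_by_hf_distance(tab)
        got = grouping.assignments.tolist()
        assert got[0] == "[0,100)"
        assert got[1] == "[100,250)"
        assert got[2] == "[750,inf)"

    def test_counts_conserve_finite_rows(self, analyzed):
        g = analyzed.gated
        grouping = bin_by_hf_distance(g)
        assert grouping.summary["n"].sum() == int(np.isfinite(g["dist_hf"]).sum())

    def test_composition_fractions_sum_to_one(self, analyzed):
        grouping = bin_by_hf_distance(analyzed.gated)
        comp = grouping.composition.set_index("group")
        sums = comp.sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)

    def test_follicle_free_sections_rejected(self):
        tab = pd.DataFrame({"dist_hf": [np.nan, np.nan], "brdu_mean": [1.0, 2.0]})
        with pytest.raises(ParameterError, match="follicle"):
            bin_by_hf_distance(tab)

    def test_near_follicle_group_has_minimal_brdu(self, analyzed):
        """The planted proliferation gradient puts the lowest mean BrdU
        in the [0,100) µm group."""
        grouping = bin_by_hf_distance(analyzed.gated)
        s = grouping.summary.set_index("group")["mean_brdu"]
        assert s.idxmin() == "[0,100)"


class TestKDE:
    def test_integral_close_to_one(self, rng):
        x = rng.normal(500, 200, 400)
        y = rng.lognormal(4, 0.4, 400)
        xg, yg, d = em.kde_density(x, y)
        assert kde_integral(xg, yg, d) == pytest.approx(1.0, abs=0.02)

    def test_two_planted_modes_recovered(self, rng):
        x = np.concatenate([rng.normal(0, 0.5, 200), rng.normal(50, 0.5, 200)])
        y = np.concatenate([rng.normal(0, 0.5, 200), rng.normal(30, 0.5, 200)])
        xg, yg, d = em.kde_density(x, y, grid_size=100)
        iy, ix = np.unravel_index(np.argmax(d), d.shape)
        peak1 = (xg[ix], yg[iy])
        # mask out the first peak's neighbourhood and find the second
        d2 = d.copy()
        d2[max(iy - 10, 0):iy + 10, max(ix - 10, 0):ix + 10] = 0
        iy2, ix2 = np.unravel_index(np.argmax(d2), d2.shape)
        peak2 = (xg[ix2], yg[iy2])
        peaks = sorted([peak1, peak2])
        cell = xg[1] - xg[0]
        assert peaks[0][0] == pytest.approx(0, abs=2 * cell)
        assert peaks[1][0] == pytest.approx(50, abs=2 * cell)

    def test_tight_cluster_peaks_at_its_location(self, rng):
        x = 10 + rng.normal(0, 1e-3, 12)
        y = -5 + rng.normal(0, 1e-3, 12)
        xg, yg, d = em.kde_density(x, y, grid_size=64)
        iy, ix = np.unravel_index(np.argmax(d), d.shape)
        assert xg[ix] == pytest.approx(10, abs=0.5)
        assert yg[iy] == pytest.approx(-5, abs=0.5)

    def test_too_few_points_rejected(self):
        with pytest.raises(ParameterError):
            em.kde_density([1.0] * 5, [2.0] * 5)


class TestClusterSpaceProfile:
    def test_planted_thickness_ordering(self, analyzed):
        profile = em.cluster_space_profile(analyzed.gated)
        s = profile.summary.set_index("cluster")["median_thickness"]
        assert s[4] > s[3]
        assert profile.summary["fraction"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_no_association_without_pattern(self):
        """With pattern_strength=0 the cluster-thickness omnibus should not
        reject (checked over several seeds)."""
        nonsig = 0
        seeds = range(30, 35)
        for seed in seeds:
            ds = em.generate_dataset(n=1200, pattern_strength=0.0, seed=seed)
            res = analyze_section(ds.nuclei, ds.annotations, seed=seed, forced_k=4)
            profile = em.cluster_space_profile(res.gated)
            if profile.thickness_test.p_value > 0.05:
                nonsig += 1
        assert nonsig >= len(seeds) - 1


class TestReliefContrast:
    def _with_marker(self, analyzed, effect):
        tab = analyzed.table.copy()
        rng = np.random.default_rng(9)
        base = rng.lognormal(4, 0.3, len(tab))
        if effect:
            # KRT15-like: stronger staining in locally thick epidermis
            z = (tab["epi_thickness"] - tab["epi_thickness"].mean()) / tab["epi_thickness"].std()
            base *= np.exp(0.4 * z)
        tab["krt15_mean"] = base
        return tab

    def test_planted_gradient_detected(self, analyzed):
        tab = self._with_marker(analyzed, effect=True)
        summary, result = em.relief_marker_contrast(tab, "krt15")
        s = summary.set_index("category")["mean_intensity"]
        assert s["invagination"] > s["evagination"]
        assert result.p_value < 0.05

    def test_null_marker_small_standardized_difference(self, analyzed):
        hits = 0
        for seed in range(5):
            tab = analyzed.table.copy()
            tab["null_mean"] = np.random.default_rng(seed).lognormal(4, 0.3, len(tab))
            summary, _ = em.relief_marker_contrast(tab, "null")
            pooled = tab["null_mean"].std()
            d = abs(np.diff(summary["mean_intensity"])[0]) / pooled
            if d < 0.2:
                hits += 1
        assert hits >= 4

    def test_constant_marker_zero_difference(self, analyzed):
        tab = analyzed.table.copy()
        tab["flat_mean"] = 5.0
        summary, result = em.relief_marker_contrast(tab, "flat")
        assert np.diff(summary["mean_intensity"])[0] == 0.0
        assert result.p_value == 1.0


@pytest.fixture(scope="module")
def processed():
    tc = em.generate_timecourse(seed=5, n=1200)
    return {
        tp: analyze_section(ds.nuclei, ds.annotations, seed=5).table
        for tp, ds in tc.items()
    }


class TestTimecourse:

    def test_ki67_fraction_declines_through_regeneration(self, processed):
        s = em.timecourse_summary(processed).per_timepoint.set_index("timepoint")
        assert s.loc["PG40", "ki67_fraction"] > s.loc["PG110", "ki67_fraction"]

    def test_unpatterned_pg40_thickness_indistinct(self, processed):
        from epidermap.stats import compare_groups

        tab = processed["PG40"]
        g3 = tab.loc[tab["cluster"] == 3, "epi_thickness"].to_numpy()
        g4 = tab.loc[tab["cluster"] == 4, "epi_thickness"].to_numpy()
        res = compare_groups([g3, g4])
        assert res.p_value > 0.05

    def test_summaries_reproducible(self):
        def run():
            tc = em.generate_timecourse(seed=6, n=400)
            tables = {
                tp: analyze_section(ds.nuclei, ds.annotations, seed=6).table
                for tp, ds in tc.items()
            }
            return em.timecourse_summary(tables)

        a, b = run(), run()
        pd.testing.assert_frame_equal(a.per_timepoint, b.per_timepoint)
        pd.testing.assert_frame_equal(a.cluster_profiles, b.cluster_profiles)
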