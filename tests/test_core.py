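"""Unit and property tests for the sgFC transform machinery."""

import numpy as np
import pytest
from scipy import stats

from sgfc.core import (
    SgfcConfig,
    bin_stats,
    euclidean_distances,
    fd_bin_count,
    smooth_sgfc,
    smoothing_spectrum,
    standardize_by_connected_global,
    zscore_unconnected,
)
from sgfc.matrices import FunctionalConnectome
from sgfc.synth import SynthParams, generate_fc, generate_regions, generate_sc

from conftest import fc_from_upper, hand_regions, sc_from_edges, tiny_instance


class TestEuclideanDistances:
    def test_3_4_5_triangle(self):
        regions = hand_regions([[0, 0, 0], [3, 4, 0]])
        d = euclidean_distances(regions)
        assert d[0, 1] == pytest.approx(5.0)
        assert d[0, 0] == 0.0

    def test_duplicate_centroids_rejected_upstream(self):
        with pytest.raises(ValueError, match="identical centroids"):
            hand_regions([[1, 2, 3], [1, 2, 3]])

    def test_matches_bruteforce_on_random_set(self):
        rng = np.random.default_rng(0)
        regions = hand_regions(rng.normal(size=(50, 3)) * 40)
        d = euclidean_distances(regions)
        for i in range(50):
            for j in range(50):
                expect = np.sqrt(((regions.centroids[i] - regions.centroids[j]) ** 2).sum())
                assert d[i, j] == pytest.approx(expect, abs=1e-12)


class TestFreedmanDiaconis:
    def test_uniform_grid_gives_ten_bins(self):
        # IQR = 499.5, h = 2*499.5*1000^(-1/3) = 99.9, ceil(999/99.9) = 10
        assert fd_bin_count(np.arange(1000.0)) == 10

    def test_four_point_sample(self):
        # IQR = 1.5, h = 3 * 4^(-1/3) ~ 1.8899, ceil(3/h) = 2
        assert fd_bin_count(np.array([0.0, 1.0, 2.0, 3.0])) == 2

    def test_zero_iqr_falls_back_to_sturges(self, caplog):
        x = np.array([5.0] * 30 + [0.0, 10.0])
        with caplog.at_level("WARNING"):
            count = fd_bin_count(x)
        # Sturges: ceil(log2(32)) + 1 = 6
        assert count == 6
        assert "Sturges" in caplog.text

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            fd_bin_count(np.array([1.0, 2.0, 3.0]))


class TestBinStats:
    def test_single_bin_equals_global_moments(self, small_instance):
        regions, sc, fc, d = small_instance
        scheme = bin_stats(fc, sc, d, 1)
        iu = np.triu_indices(regions.n, k=1)
        vals = fc.weights[iu][sc.binary_mask[iu]]
        assert scheme.mu[0] == pytest.approx(vals.mean())
        assert scheme.sigma[0] == pytest.approx(vals.std(ddof=1))

    def test_hand_built_five_nodes(self):
        # three connected pairs with FC {0.5, 0.7, 0.9} in one bin
        regions = hand_regions([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0], [4, 0, 0]])
        sc = sc_from_edges(5, [(0, 1), (1, 2), (2, 3)])
        fc = fc_from_upper(5, {(0, 1): 0.5, (1, 2): 0.7, (2, 3): 0.9})
        scheme = bin_stats(fc, sc, euclidean_distances(regions), 1)
        assert scheme.mu[0] == pytest.approx(0.7)
        assert scheme.sigma[0] == pytest.approx(0.2)

    def test_no_connected_edges_errors(self):
        regions = hand_regions([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0]])
        sc = sc_from_edges(4, [])
        fc = fc_from_upper(4, {(0, 1): 0.5})
        with pytest.raises(ValueError, match="reference distribution empty"):
            bin_stats(fc, sc, euclidean_distances(regions), 2)

    def test_reference_mean_decays_with_distance(self):
        # per-bin mu should trend downward with bin midpoint
        rhos = []
        for seed in range(10):
            params = SynthParams(seed=seed)
            regions = generate_regions(200, seed)
            sc = generate_sc(regions, params)
            fc, _ = generate_fc(regions, sc, params)
            d = euclidean_distances(regions)
            scheme = bin_stats(fc, sc, d, 50)
            mids = (scheme.edges[:-1] + scheme.edges[1:]) / 2
            ok = scheme.valid
            rhos.append(stats.spearmanr(mids[ok], scheme.mu[ok])[0])
        assert np.median(rhos) < 0


class TestZscoreUnconnected:
    def _two_bin_case(self):
        regions = hand_regions(
            [[0, 0, 0], [5, 0, 0], [10, 0, 0], [0, 40, 0], [5, 40, 0], [10, 40, 3]]
        )
        sc = sc_from_edges(6, [(0, 1), (1, 2), (3, 4), (0, 3), (1, 4)])
        rng = np.random.default_rng(3)
        entries = {}
        for i in range(6):
            for j in range(i + 1, 6):
                entries[(i, j)] = float(rng.uniform(-0.5, 0.9))
        fc = fc_from_upper(6, entries)
        return regions, sc, fc, euclidean_distances(regions)

    def test_value_at_reference_mean_is_zero(self, small_instance):
        regions, sc, fc, d = small_instance
        scheme = bin_stats(fc, sc, d, 2)
        # implant an unconnected weight exactly at its bin's mean
        iu = np.triu_indices(regions.n, k=1)
        unconn = np.where(~sc.binary_mask[iu])[0]
        i, j = iu[0][unconn[0]], iu[1][unconn[0]]
        b = scheme.bin_index(np.array([d[i, j]]))[0]
        if not scheme.valid[b]:
            pytest.skip("first unconnected pair fell in an invalid bin")
        w = fc.weights.copy()
        w[i, j] = w[j, i] = scheme.mu[b]
        z = zscore_unconnected(FunctionalConnectome(weights=w), sc, d, scheme)
        assert z.z[i, j] == pytest.approx(0.0, abs=1e-12)
        w[i, j] = w[j, i] = scheme.mu[b] + scheme.sigma[b]
        z = zscore_unconnected(FunctionalConnectome(weights=w), sc, d, scheme)
        assert z.z[i, j] == pytest.approx(1.0, abs=1e-12)

    def test_matches_bruteforce_on_two_bin_instance(self):
        regions, sc, fc, d = self._two_bin_case()
        scheme = bin_stats(fc, sc, d, 2)
        out = zscore_unconnected(fc, sc, d, scheme)
        # independent per-pair recomputation
        iu = np.triu_indices(6, k=1)
        lo, hi = d[iu].min(), d[iu].max()
        width = (hi - lo) / 2
        for i in range(6):
            for j in range(i + 1, 6):
                if sc.binary_mask[i, j]:
                    assert np.isnan(out.z[i, j])
                    continue
                b = 0 if d[i, j] < lo + width else 1
                ref = [
                    fc.weights[a, c]
                    for a in range(6)
                    for c in range(a + 1, 6)
                    if sc.binary_mask[a, c]
                    and (0 if d[a, c] < lo + width else 1) == b
                ]
                if len(ref) < 2 or np.std(ref, ddof=1) == 0:
                    assert np.isnan(out.z[i, j])
                else:
                    expect = (fc.weights[i, j] - np.mean(ref)) / np.std(ref, ddof=1)
                    assert out.z[i, j] == pytest.approx(expect, abs=1e-12)

    def test_undefined_markers_on_connected_and_diagonal(self, small_instance):
        regions, sc, fc, d = small_instance
        scheme = bin_stats(fc, sc, d, 3)
        out = zscore_unconnected(fc, sc, d, scheme)
        assert np.all(np.isnan(np.diag(out.z)))
        assert np.all(np.isnan(out.z[sc.binary_mask]))

    def test_merge_nearest_fills_invalid_bins(self, small_instance):
        regions, sc, fc, d = small_instance
        scheme = bin_stats(fc, sc, d, 40)  # many bins -> some invalid
        undef = zscore_unconnected(fc, sc, d, scheme, "undefined")
        merged = zscore_unconnected(fc, sc, d, scheme, "merge_nearest")
        n_undef = np.isfinite(undef.z).sum()
        n_merged = np.isfinite(merged.z).sum()
        assert n_merged >= n_undef
        if scheme.valid.any() and not scheme.valid.all():
            iu = np.triu_indices(regions.n, k=1)
            assert n_merged == 2 * (~sc.binary_mask[iu]).sum()


class TestSmoothing:
    def test_spectrum_of_eight_bins(self):
        assert smoothing_spectrum(8, 0.25) == [6, 7, 8, 9, 10]

    def test_zero_halfwidth_matches_single_bin_count(self, small_instance):
        regions, sc, fc, d = small_instance
        cfg = SgfcConfig(n_bins=4, smoothing_spectrum_halfwidth=0.0)
        smoothed = smooth_sgfc(fc, sc, d, cfg)
        scheme = bin_stats(fc, sc, d, 4, cfg)
        single = zscore_unconnected(fc, sc, d, scheme)
        np.testing.assert_allclose(smoothed.z, single.z, equal_nan=True)
        assert smoothed.provenance["spectrum"] == [4]

    def test_smoothed_equals_mean_of_members(self, small_instance):
        regions, sc, fc, d = small_instance
        cfg = SgfcConfig(n_bins=5)
        smoothed = smooth_sgfc(fc, sc, d, cfg)
        members = []
        for b in smoothed.provenance["spectrum"]:
            scheme = bin_stats(fc, sc, d, b, cfg)
            members.append(zscore_unconnected(fc, sc, d, scheme).z)
        stack = np.stack(members)
        counts = np.isfinite(stack).sum(axis=0)
        expect = np.where(counts > 0, np.nansum(np.nan_to_num(stack), axis=0), np.nan)
        expect = np.where(counts > 0, expect / np.maximum(counts, 1), np.nan)
        np.testing.assert_allclose(smoothed.z, expect, equal_nan=True, atol=1e-12)

    def test_monotone_response_of_single_edge(self, small_instance):
        # raising one unconnected weight raises its z and no other
        regions, sc, fc, d = small_instance
        cfg = SgfcConfig(n_bins=3, smoothing_spectrum_halfwidth=0.0)
        base = smooth_sgfc(fc, sc, d, cfg)
        iu = np.triu_indices(regions.n, k=1)
        unconn = np.where(~sc.binary_mask[iu] & np.isfinite(base.z[iu]))[0]
        i, j = int(iu[0][unconn[0]]), int(iu[1][unconn[0]])
        w = fc.weights.copy()
        w[i, j] = w[j, i] = w[i, j] + 0.05
        bumped = smooth_sgfc(FunctionalConnectome(weights=w), sc, d, cfg)
        assert bumped.z[i, j] > base.z[i, j]
        mask = np.isfinite(base.z)
        mask[i, j] = mask[j, i] = False
        np.testing.assert_allclose(bumped.z[mask], base.z[mask])


class TestGlobalStandardization:
    def test_equals_single_bin_composition(self, small_instance):
        regions, sc, fc, d = small_instance
        baseline = standardize_by_connected_global(fc, sc)
        scheme = bin_stats(fc, sc, d, 1)
        composed = zscore_unconnected(fc, sc, d, scheme)
        np.testing.assert_allclose(baseline, composed.z, equal_nan=True, atol=1e-12)

    def test_hand_built_values(self):
        regions = hand_regions([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0], [4, 1, 0]])
        sc = sc_from_edges(5, [(0, 1), (1, 2), (2, 3)])
        fc = fc_from_upper(5, {(0, 1): 0.5, (1, 2): 0.7, (2, 3): 0.9, (0, 4): 0.8})
        out = standardize_by_connected_global(fc, sc)
        # connected mean 0.7, sd 0.2 -> z(0.8) = 0.5; z(0) = -3.5
        assert out[0, 4] == pytest.approx(0.5)
        assert out[0, 2] == pytest.approx((0.0 - 0.7) / 0.2)
        assert np.isnan(out[0, 1])

    def test_zero_variance_errors(self):
        regions = hand_regions([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        sc = sc_from_edges(4, [(0, 1), (1, 2)])
        fc = fc_from_upper(4, {(0, 1): 0.5, (1, 2): 0.5})
        with pytest.raises(ValueError, match="variance"):
            standardize_by_connected_global(fc, sc)


def test_connected_edges_selfstandardize_to_unit_moments():
    """Applying the per-bin transform to the reference edges themselves
    must give mean 0 and sd 1 inside every valid bin."""
    for seed in range(3):
        regions, sc, fc, d = tiny_instance(seed, n=20, density=0.4)
        iu = np.triu_indices(regions.n, k=1)
        conn = sc.binary_mask[iu]
        scheme = bin_stats(fc, sc, d, 3)
        idx = scheme.bin_index(d[iu][conn])
        w = fc.weights[iu][conn]
        for b in np.where(scheme.valid)[0]:
            z = (w[idx == b] - scheme.mu[b]) / scheme.sigma[b]
            assert abs(z.mean()) < 1e-10
            assert abs(z.std(ddof=1) - 1.0) < 1e-10
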