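"""Hi-C metrics against brute-force oracles and constructed fixtures."""

import numpy as np
import pytest

from meiorec.binning import BinnedTrack
from meiorec.hic import (
    PsCurve,
    cis_total_ratio,
    fine_grain_compartment,
    fire_score,
    insulation_score,
    loop_length_estimate,
    ps_curve,
    ps_curves_by_compartment,
)
from meiorec.simulate import SimConfig, simulate_contacts, simulate_genome

from conftest import dense_contact_matrix


# ---------------------------------------------------------------------------
# cis/total


class TestCisTotal:
    def test_all_cis_gives_one(self):
        rng = np.random.default_rng(0)
        m = rng.poisson(5, (20, 20)).astype(float)
        m = np.triu(m) + np.triu(m, 1).T
        cm = dense_contact_matrix(m)
        np.testing.assert_allclose(cis_total_ratio(cm).values, 1.0)

    def test_simple_arithmetic(self):
        m = np.full((4, 4), 2.5)
        cm = dense_contact_matrix(m)
        cm.cis_raw = np.array([30.0, 10, 10, 10])
        cm.trans_raw = np.array([70.0, 0, 0, 0])
        assert cis_total_ratio(cm).values[0] == pytest.approx(0.30)

    def test_matches_brute_force_row_sums(self, mini_contacts):
        cm = mini_contacts
        track = cis_total_ratio(cm)
        dense = cm.matrices["chr1"].toarray()
        for b in (0, 100, 1777, 3999):
            if not cm.valid[b]:
                continue
            cis = dense[b].sum()
            expected = cis / (cis + cm.trans_raw[b])
            assert track.values[b] == pytest.approx(expected, abs=1e-12)

    def test_window_aggregation_preserves_uniform_ratio(self):
        n = 50
        m = np.full((n, n), 2.0)
        cm = dense_contact_matrix(m)
        cm.trans_raw = cm.cis_raw / 3.0  # uniform cis/total = 0.75 everywhere
        plain = cis_total_ratio(cm).values
        pooled = cis_total_ratio(cm, aggregation_bp=50_000).values
        np.testing.assert_allclose(plain, 0.75, atol=1e-12)
        np.testing.assert_allclose(pooled, 0.75, atol=1e-12)

    def test_in_unit_interval(self, mini_contacts):
        v = cis_total_ratio(mini_contacts).values
        ok = np.isfinite(v)
        assert ((v[ok] >= 0) & (v[ok] <= 1)).all()


# ---------------------------------------------------------------------------
# compartments


def _checkerboard(n=40, block=10, hi=4.0, lo=1.0):
    lab = (np.arange(n) // block) % 2
    same = lab[:, None] == lab[None, :]
    return np.where(same, hi, lo), lab


class TestCompartment:
    def test_rank_one_correlation_eigenvector_block_constant(self):
        # idealized checkerboard correlation (rank-1 two-group structure):
        # the leading eigenvector is exactly constant within blocks
        from meiorec.hic import _leading_eigenvector

        sign = np.where(np.arange(40) < 20, 1.0, -1.0)
        corr = np.outer(sign, sign)
        _, ev = _leading_eigenvector(corr)
        assert np.ptp(ev[:20]) < 1e-9 and np.ptp(ev[20:]) < 1e-9
        lab = (sign > 0).astype(float)
        assert abs(np.corrcoef(ev, lab)[0, 1]) == pytest.approx(1.0, abs=1e-9)

    def test_two_block_checkerboard(self):
        # full operation (including O/E, which bends exact block constancy):
        # signs separate the blocks and correlation with labels is ~1
        m, lab = _checkerboard(n=40, block=20)
        cm = dense_contact_matrix(m)
        ref = BinnedTrack("ref", lab.astype(float))
        out = fine_grain_compartment(
            cm, ref, chunk_bp=40 * 5000, min_valid_bins=2, eig_bin_bp=None
        )
        v = out.values
        assert len(set(np.sign(v[:20]))) == 1
        assert len(set(np.sign(v[20:]))) == 1
        assert np.sign(v[0]) != np.sign(v[-1])
        assert abs(np.corrcoef(v, lab)[0, 1]) >= 0.99

    def test_reference_negation_flips_sign(self):
        m, lab = _checkerboard()
        cm = dense_contact_matrix(m)
        a = fine_grain_compartment(
            cm, BinnedTrack("r", lab.astype(float)),
            chunk_bp=200_000, min_valid_bins=2, eig_bin_bp=None)
        b = fine_grain_compartment(
            cm, BinnedTrack("r", -lab.astype(float)),
            chunk_bp=200_000, min_valid_bins=2, eig_bin_bp=None)
        np.testing.assert_allclose(a.values, -b.values, atol=1e-12)

    def test_invariant_to_positive_scaling(self):
        m, lab = _checkerboard()
        ref = BinnedTrack("r", lab.astype(float))
        kw = dict(chunk_bp=200_000, min_valid_bins=2, eig_bin_bp=None)
        a = fine_grain_compartment(dense_contact_matrix(m), ref, **kw)
        b = fine_grain_compartment(dense_contact_matrix(3.7 * m), ref, **kw)
        np.testing.assert_allclose(a.values, b.values, atol=1e-9)

    def test_recovers_injected_labels(self, mini_contacts, mini_genome, mini_activity_ref):
        _, truth, _, _ = mini_genome
        out = fine_grain_compartment(mini_contacts, mini_activity_ref)
        ok = np.isfinite(out.values)
        r = np.corrcoef(out.values[ok], truth.comp_label[ok])[0, 1]
        assert r >= 0.9


# ---------------------------------------------------------------------------
# insulation


class TestInsulation:
    def test_toeplitz_interior_equal(self):
        n = 60
        idx = np.arange(n)
        m = 10.0 / (1.0 + np.abs(idx[:, None] - idx[None, :]))
        cm = dense_contact_matrix(m)
        v = insulation_score(cm, window_bp=25_000).values  # w = 5 bins
        interior = v[5 : n - 5]
        assert np.nanmax(interior) - np.nanmin(interior) < 1e-9

    def test_boundary_is_global_minimum(self):
        n = 60
        m = np.full((n, n), 0.05)
        m[:30, :30] = 5.0
        m[30:, 30:] = 5.0
        cm = dense_contact_matrix(m)
        v = insulation_score(cm, window_bp=25_000).values
        assert np.nanargmin(v) == 30

    def test_all_equal_matrix_scores_zero(self):
        cm = dense_contact_matrix(np.full((40, 40), 2.0))
        v = insulation_score(cm, window_bp=25_000).values
        np.testing.assert_allclose(v[5:35], 0.0, atol=1e-12)

    def test_scaling_invariance(self):
        rng = np.random.default_rng(5)
        m = rng.poisson(4, (50, 50)).astype(float)
        m = np.triu(m) + np.triu(m, 1).T
        a = insulation_score(dense_contact_matrix(m), 25_000).values
        b = insulation_score(dense_contact_matrix(5 * m), 25_000).values
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_matches_brute_force_diamond(self):
        rng = np.random.default_rng(6)
        n, w = 40, 4
        m = rng.poisson(4, (n, n)).astype(float)
        m = np.triu(m) + np.triu(m, 1).T
        cm = dense_contact_matrix(m)
        v = insulation_score(cm, window_bp=w * 5000).values
        means = np.full(n, np.nan)
        for b in range(w, n - w):
            means[b] = m[b - w : b, b : b + w].mean()
        expected = np.log2(means / np.nanmean(means))
        np.testing.assert_allclose(v, expected, atol=1e-12)

    def test_window_larger_than_chromosome(self):
        cm = dense_contact_matrix(np.ones((10, 10)))
        with pytest.warns(UserWarning, match="too large"):
            v = insulation_score(cm, window_bp=30_000).values
        assert np.isnan(v).all()


# ---------------------------------------------------------------------------
# FIRE


class TestFire:
    def test_homogeneous_matrix_all_zero(self):
        cm = dense_contact_matrix(np.full((80, 80), 3.0))
        v = fire_score(cm).values
        np.testing.assert_allclose(v, 0.0, atol=1e-9)

    def test_locally_enriched_bin_attains_max(self):
        n = 100
        rng = np.random.default_rng(7)
        m = np.ones((n, n)) + 0.01 * rng.random((n, n))
        m = (m + m.T) / 2
        hot = 50
        m[hot, hot - 40 : hot + 41] *= 2
        m[hot - 40 : hot + 41, hot] *= 2
        cm = dense_contact_matrix(m)
        assert np.nanargmax(fire_score(cm).values) == hot

    def test_constant_addition_preserves_ranking(self):
        rng = np.random.default_rng(8)
        n = 80
        m = rng.poisson(4, (n, n)).astype(float)
        m = np.triu(m) + np.triu(m, 1).T
        a = fire_score(dense_contact_matrix(m)).values
        b = fire_score(dense_contact_matrix(m + 7.0)).values
        assert (np.argsort(a) == np.argsort(b)).all()


# ---------------------------------------------------------------------------
# P(s) and loop length


class TestPsCurve:
    def test_delta_input_single_distance_bin(self):
        n = 400
        d0 = 37
        m = np.zeros((n, n))
        idx = np.arange(n - d0)
        m[idx, idx + d0] = 1.0
        m += m.T.copy()
        cm = dense_contact_matrix(m)
        curve = ps_curve(cm, min_pairs=1)
        nz = np.flatnonzero(np.nan_to_num(curve.p) > 0)
        assert len(nz) == 1
        lo, hi = curve.edges[nz[0]], curve.edges[nz[0] + 1]
        assert lo <= d0 * 5000 < hi

    def test_power_law_slope_recovered(self):
        cfg = SimConfig(chrom_lengths=(40_000_000,), shoulder_amp=0.0,
                        compartment_strength={"zygonema": 0.0},
                        n_prdm9_peaks=500, read_depth=4e6, seed=21)
        bins, truth, _, _ = simulate_genome(cfg)
        cm = simulate_contacts(bins, truth, cfg, "zygonema")
        curve = ps_curve(cm)
        sel = (curve.s_mid >= 1e5) & (curve.s_mid <= 5e6) & np.isfinite(curve.p)
        slope = np.polyfit(np.log10(curve.s_mid[sel]), np.log10(curve.p[sel]), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.05)

    def test_homogeneous_labels_leave_other_mask_empty(self):
        m = np.ones((50, 50))
        cm = dense_contact_matrix(m)
        curves = ps_curves_by_compartment(cm, np.ones(50), min_pairs=1)  # all A
        assert np.isnan(curves["B"].p).all()
        assert np.isfinite(curves["A"].p).any()

    def test_masked_pair_counts_are_disjoint(self, mini_contacts, mini_genome):
        _, truth, _, _ = mini_genome
        comp = truth.comp_label.astype(float) - 0.5
        a = ps_curve(mini_contacts, mask=comp > 0, min_pairs=1)
        b = ps_curve(mini_contacts, mask=comp < 0, min_pairs=1)
        both = ps_curve(mini_contacts, min_pairs=1)
        mixed = both.n_pairs - a.n_pairs - b.n_pairs
        assert (mixed >= 0).all()
        np.testing.assert_array_equal(a.n_pairs + b.n_pairs + mixed, both.n_pairs)


class TestLoopLength:
    def test_pure_power_law_returns_none(self):
        s = np.geomspace(5e3, 2e7, 80)
        edges = np.concatenate([s, [s[-1] * 1.12]])
        p = (s / s[0]) ** -1.0
        deriv = np.full_like(p, -1.0)
        curve = PsCurve(edges=edges, s_mid=s, p=p, deriv=deriv,
                        n_pairs=np.full(len(s), 1000))
        assert loop_length_estimate(curve) is None

    def test_too_few_populated_bins_returns_none(self):
        s = np.geomspace(5e3, 1e5, 5)
        curve = PsCurve(edges=np.concatenate([s, [2e5]]), s_mid=s,
                        p=np.ones(5), deriv=np.zeros(5), n_pairs=np.full(5, 10))
        with pytest.warns(UserWarning, match="populated"):
            assert loop_length_estimate(curve) is None

    def test_recovers_injected_one_mb_shoulder(self):
        cfg = SimConfig(chrom_lengths=(40_000_000,), loop_size_A=1e6, loop_size_B=1e6,
                        n_prdm9_peaks=500, read_depth=4e6, seed=23)
        bins, truth, _, _ = simulate_genome(cfg)
        cm = simulate_contacts(bins, truth, cfg, "zygonema")
        est = loop_length_estimate(ps_curve(cm))
        assert est is not None
        assert 0.8e6 <= est <= 1.25e6

    def test_a_b_ratio_near_threefold(self, mini_contacts, mini_genome):
        _, truth, _, _ = mini_genome
        curves = ps_curves_by_compartment(
            mini_contacts, truth.comp_label.astype(float) - 0.5
        )
        a = loop_length_estimate(curves["A"])
        b = loop_length_estimate(curves["B"])
        assert a is not None and b is not None
        assert 3.0 * 0.75 <= b / a <= 3.0 * 1.25
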