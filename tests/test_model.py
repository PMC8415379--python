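"""Feature matrix, PCA and forward-selection OLS."""

import numpy as np
import pandas as pd
import pytest

from meiorec.binning import BinnedTrack, make_bins
from meiorec.model import (
    FeatureMatrix,
    build_feature_matrix,
    forward_select_ols,
    run_pca,
    standardize,
)
from meiorec.recombination import SiteSet


def _sites(bin_ids, bins):
    ids = np.asarray(bin_ids)
    return SiteSet(
        "joint",
        pd.DataFrame(
            {"bin_id": ids, "chrom": bins.chrom_of(ids), "start": bins.bin_start(ids)}
        ),
    )


class TestFeatureMatrix:
    def test_standardize_idempotent(self):
        rng = np.random.default_rng(0)
        X = rng.random((50, 4)) * 7 + 3
        once = standardize(X)
        twice = standardize(once)
        np.testing.assert_allclose(once, twice, atol=1e-12)
        np.testing.assert_allclose(once.mean(0), 0.0, atol=1e-9)
        np.testing.assert_allclose(once.std(0), 1.0, atol=1e-9)

    def test_delta_track_window_mean(self):
        bins = make_bins({"chr1": 2_000_000}, 5000)  # 400 bins
        v = np.zeros(bins.n_bins)
        v[200] = 1.0
        track = BinnedTrack("d", v)
        rng = np.random.default_rng(1)
        noise = BinnedTrack("n", rng.random(bins.n_bins))
        sites = _sites([100, 200, 300], bins)
        fm = build_feature_matrix(sites, {"d": track, "n": noise}, bins, window_bins=50)
        # pre-scaling values: local = (0,1,0); window = (0, 1/101, 0)
        d_local = fm.X[:, fm.columns.index("d_local")]
        d_win = fm.X[:, fm.columns.index("d_win")]
        # standardization preserves the pattern: site 1 is the unique max of both
        assert np.argmax(d_local) == 1 and np.argmax(d_win) == 1
        assert d_local[0] == pytest.approx(d_local[2])
        # verify the raw window mean via the definition
        assert v[150:251].mean() == pytest.approx(1 / 101)

    def test_zero_variance_column_dropped(self):
        bins = make_bins({"chr1": 500_000}, 5000)
        const = BinnedTrack("c", np.full(bins.n_bins, 2.0))
        rng = np.random.default_rng(2)
        noise = BinnedTrack("n", rng.random(bins.n_bins))
        with pytest.warns(UserWarning, match="zero-variance"):
            fm = build_feature_matrix(_sites([10, 40, 70], bins),
                                      {"c": const, "n": noise}, bins)
        assert "c_local" in fm.dropped_columns and "c_win" in fm.dropped_columns
        assert all(not c.startswith("c_") for c in fm.columns)

    def test_rows_with_missing_features_dropped(self):
        bins = make_bins({"chr1": 500_000}, 5000)
        v = np.random.default_rng(3).random(bins.n_bins)
        v[40] = np.nan
        fm = build_feature_matrix(
            _sites([10, 40, 70], bins), {"v": BinnedTrack("v", v)}, bins
        )
        assert fm.n_dropped_rows == 1 and fm.X.shape[0] == 2


class TestPca:
    def _fm(self, X, names=None):
        names = names or [f"c{i}" for i in range(X.shape[1])]
        return FeatureMatrix(
            X=standardize(X), columns=names,
            rows=pd.DataFrame({"bin_id": np.arange(X.shape[0])}),
            n_dropped_rows=0, dropped_columns=[],
        )

    def test_perfectly_correlated_pair_rank_one(self):
        rng = np.random.default_rng(4)
        x = rng.random(200)
        pca = run_pca(self._fm(np.column_stack([x, 2 * x + 5])), n_components=2)
        assert pca.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("r", [0.2, 0.5, 0.8])
    def test_two_column_closed_form(self, r):
        rng = np.random.default_rng(5)
        n = 200_000  # large n so the sample correlation is close to r
        x = rng.normal(size=n)
        y = r * x + np.sqrt(1 - r**2) * rng.normal(size=n)
        pca = run_pca(self._fm(np.column_stack([x, y])), n_components=2)
        assert pca.explained_variance_ratio[0] == pytest.approx((1 + abs(r)) / 2, abs=0.01)

    def test_loadings_orthonormal(self):
        rng = np.random.default_rng(6)
        pca = run_pca(self._fm(rng.random((100, 6))), n_components=6)
        np.testing.assert_allclose(
            pca.loadings @ pca.loadings.T, np.eye(6), atol=1e-9
        )

    def test_full_reconstruction(self):
        rng = np.random.default_rng(7)
        fm = self._fm(rng.random((80, 5)))
        pca = run_pca(fm, n_components=5)
        np.testing.assert_allclose(pca.scores @ pca.loadings, fm.X, atol=1e-8)

    def test_sign_convention_largest_loading_positive(self):
        rng = np.random.default_rng(8)
        pca = run_pca(self._fm(rng.random((100, 5))), n_components=4)
        for row in pca.loadings:
            assert row[np.argmax(np.abs(row))] > 0

    def test_explained_variance_non_increasing(self):
        rng = np.random.default_rng(9)
        pca = run_pca(self._fm(rng.random((100, 8))), n_components=6)
        assert (np.diff(pca.explained_variance_ratio) <= 1e-12).all()
        assert pca.explained_variance_ratio.sum() <= 1 + 1e-9


class TestForwardSelection:
    def _candidates(self, rng, n=2000, k=10):
        return {f"x{i}": rng.normal(size=n) for i in range(1, k + 1)}

    def test_planted_predictor_recovered(self):
        hits, coefs = 0, []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            cand = self._candidates(rng)
            y = 2.0 * cand["x1"] + rng.normal(size=2000)
            fit = forward_select_ols(y, cand)
            if fit.selected == ["x1"]:
                hits += 1
            coefs.append(fit.coef.get("x1", np.nan))
        assert hits >= 19
        assert 1.9 <= np.nanmean(coefs) <= 2.1

    def test_pure_noise_selects_nothing(self):
        empty = 0
        for seed in range(20):
            rng = np.random.default_rng(200 + seed)
            cand = self._candidates(rng)
            y = rng.normal(size=2000)
            if forward_select_ols(y, cand).selected == []:
                empty += 1
        assert empty == 20

    def test_exact_candidate_selected_first_r2_one(self):
        rng = np.random.default_rng(10)
        cand = self._candidates(rng, n=500, k=5)
        y = cand["x3"].copy()
        fit = forward_select_ols(y, cand)
        assert fit.selected[0] == "x3"
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_r2_never_below_naive_when_naive_selected(self):
        rng = np.random.default_rng(11)
        cand = self._candidates(rng, n=1000, k=5)
        y = 1.5 * cand["x2"] + 0.5 * cand["x4"] + rng.normal(size=1000)
        fit = forward_select_ols(y, cand, naive_predictors=["x2"])
        assert set(["x2"]) <= set(fit.selected)
        assert fit.r2 >= fit.naive_r2

    def test_selection_independent_of_candidate_order(self):
        rng = np.random.default_rng(12)
        cand = self._candidates(rng, n=1000, k=6)
        y = 1.0 * cand["x5"] + 0.8 * cand["x2"] + rng.normal(size=1000)
        fit_a = forward_select_ols(y, cand)
        fit_b = forward_select_ols(y, dict(reversed(list(cand.items()))))
        assert fit_a.selected == fit_b.selected

    def test_collinear_candidate_skipped(self):
        rng = np.random.default_rng(13)
        cand = {"a": rng.normal(size=500)}
        cand["b"] = cand["a"] * 1.0  # exact duplicate
        y = cand["a"] + 0.1 * rng.normal(size=500)
        with pytest.warns(UserWarning, match="collinear"):
            fit = forward_select_ols(y, cand)
        assert fit.selected == ["a"]  # lexicographic tie then duplicate skipped


class TestRecombinationModels:
    @pytest.mark.parametrize("seed", [31, 32, 33])
    def test_sign_recovery_on_reduced_genome(self, seed):
        """DSB model: PRDM9 score positive and the activity axis positive;
        crossover model: position positive and an activity/gene-body-aligned
        component negative — matching the generative biases."""
        import warnings as _w

        from meiorec import binning, hic, model
        from meiorec.recombination import crossover_score_map, define_sites
        from meiorec.simulate import (
            SimConfig,
            simulate_contacts,
            simulate_crossovers,
            simulate_genome,
            simulate_peaks_and_tracks,
        )

        cfg = SimConfig(chrom_lengths=(30_000_000,), n_prdm9_peaks=1500,
                        n_crossovers=1000, read_depth=2.5e6, seed=seed)
        bins, truth, chromhmm, _ = simulate_genome(cfg)
        prdm9, dmc1, tracks_bg = simulate_peaks_and_tracks(bins, truth, cfg)
        xo = simulate_crossovers(bins, truth, dmc1, cfg)
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            cm = simulate_contacts(bins, truth, cfg, "zygonema")
            states = binning.chromhmm_overlap_tracks(chromhmm, bins)
            ref = binning.BinnedTrack(
                "ref", np.sum([states[s].values for s in binning.ACTIVE_STATES], axis=0)
            )
            variables = {
                "cis_total": hic.cis_total_ratio(cm),
                "compartment": hic.fine_grain_compartment(cm, ref),
                **states,
            }
            score_tracks = dict(variables)
            for name, peaks in [("prdm9", prdm9), ("dmc1", dmc1)]:
                v = np.full(bins.n_bins, np.nan)
                v[peaks["bin_id"].to_numpy()] = peaks["score"].to_numpy()
                score_tracks[name] = binning.BinnedTrack(name, v)
            score_tracks["crossover"] = crossover_score_map(xo, bins)
            joint = define_sites(prdm9, bins, score_tracks, label="joint")
            fm = model.build_feature_matrix(joint, variables, bins)
            pca = model.run_pca(fm, n_components=4)
            mask = np.isfinite(fm.rows["prdm9"].to_numpy(dtype=float))
            fits = model.fit_recombination_models(fm, pca, mask, mask)

        comp_col = fm.columns.index("compartment_local")

        def activity_sign(pc_name):
            i = int(pc_name[2:]) - 1
            return np.sign(np.corrcoef(pca.scores[:, i], fm.X[:, comp_col])[0, 1])

        dsb = fits["dsb"]
        assert "prdm9" in dsb.selected and dsb.coef["prdm9"] > 0
        pc_sel = [p for p in dsb.selected if p.startswith("PC")]
        assert pc_sel, "DSB model selected no chromatin component"
        assert any(dsb.coef[p] * activity_sign(p) > 0 for p in pc_sel)

        xo_fit = fits["crossover"]
        assert "position" in xo_fit.selected and xo_fit.coef["position"] > 0
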