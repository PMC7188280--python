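"""RRBLUP: ridge/GBLUP equivalence, prediction, cross-validation."""

import warnings

import numpy as np
import pandas as pd
import pytest

from wheatsel.mixedmodel import gls_blup
from wheatsel.predict import (cross_validate, fit_rrblup, predict_gebv,
                              predictive_ability)
from wheatsel.relatedness import compute_kinship
from wheatsel.simulate import (GeneticArchitecture, GenotypeMatrix, SimConfig,
                               derive_biparental, simulate_founders,
                               simulate_trial)

from conftest import make_geno, random_inbred_geno


def _training_instance(rng, n=50, m=200, h2=0.5, n_qtl=20):
    geno = random_inbred_geno(rng, n, m)
    qtl = rng.choice(m, size=n_qtl, replace=False)
    beta = rng.normal(0, 1, n_qtl)
    g = (geno.dosages()[:, qtl] - geno.dosages()[:, qtl].mean(0)) @ beta
    g = g / g.std()
    y = g + rng.normal(0, np.sqrt((1 - h2) / h2), n)
    return geno, pd.Series(y + 5.0, index=geno.line_ids), pd.Series(g, index=geno.line_ids)


class TestFit:
    def test_fixed_lambda_matches_closed_form_ridge(self, rng):
        geno, y, _ = _training_instance(rng)
        lam = 2.5
        model = fit_rrblup(geno, y, lambda_=lam)
        order = model.train_ids
        X = geno.data.loc[order].to_numpy(dtype=float)
        p = X.mean(axis=0) / 2
        W = X - 2 * p
        ridge = np.linalg.solve(W.T @ W + lam * np.eye(W.shape[1]),
                                W.T @ (y.loc[order] - model.beta.iloc[0]))
        assert np.allclose(model.marker_effects.to_numpy(), ridge, atol=1e-8)

    def test_marker_model_equals_K_model(self, rng):
        geno, y, _ = _training_instance(rng)
        model = fit_rrblup(geno, y)
        order = model.train_ids
        kin = compute_kinship(geno.subset_lines(order))
        _, _, u = gls_blup(y.loc[order].to_numpy(), np.ones((len(order), 1)),
                           kin.to_numpy(), model.sigma_u2, model.sigma_e2)
        assert np.allclose(model.train_gebv.to_numpy(), u, atol=1e-6)

    def test_null_phenotype_gives_near_zero_heritability(self):
        hits = 0
        n_seeds = 50
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            geno = random_inbred_geno(rng, 500, 120)
            y = pd.Series(rng.normal(5, 1, 500), index=geno.line_ids)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # boundary-variance warnings expected
                model = fit_rrblup(geno, y)
            ratio = model.sigma_u2 / (model.sigma_u2 + model.sigma_e2)
            hits += ratio < 0.05
        assert hits >= 0.9 * n_seeds

    def test_constant_phenotype_rejected(self, rng):
        geno = random_inbred_geno(rng, 40, 30)
        y = pd.Series(3.0, index=geno.line_ids)
        with pytest.raises(ValueError, match="constant"):
            fit_rrblup(geno, y)

    def test_monomorphic_fixed_marker_named_in_error(self, rng):
        geno = random_inbred_geno(rng, 40, 30)
        geno.data.iloc[:, 0] = 2
        y = pd.Series(rng.normal(5, 1, 40), index=geno.line_ids)
        bad = geno.marker_ids[0]
        with pytest.raises(ValueError, match=bad):
            fit_rrblup(geno, y, fixed_markers=[bad])

    def test_heavy_shrinkage_sends_gebv_to_zero(self, rng):
        geno, y, _ = _training_instance(rng)
        model = fit_rrblup(geno, y, lambda_=1e9)
        assert np.abs(model.train_gebv).max() < 1e-4
        assert model.beta.iloc[0] == pytest.approx(y.mean(), abs=1e-3)

    def test_translation_moves_intercept_only(self, rng):
        geno, y, _ = _training_instance(rng)
        m1 = fit_rrblup(geno, y, lambda_=3.0)
        m2 = fit_rrblup(geno, y + 10.0, lambda_=3.0)
        assert m2.beta.iloc[0] - m1.beta.iloc[0] == pytest.approx(10.0, abs=1e-8)
        assert np.allclose(m1.train_gebv, m2.train_gebv, atol=1e-8)

    def test_gs2_with_null_markers_close_to_gs1(self):
        # fixed markers with zero true effect: estimated coefficients are
        # near (not exactly) zero, so GEBVs agree statistically
        rng = np.random.default_rng(77)
        geno, y, _ = _training_instance(rng, n=300, m=200)
        null_markers = [geno.marker_ids[5], geno.marker_ids[105]]
        gs1 = fit_rrblup(geno, y)
        gs2 = fit_rrblup(geno, y, fixed_markers=null_markers)
        overlap = sorted(set(gs1.train_gebv.index))
        r = np.corrcoef(gs1.train_gebv[overlap], gs2.train_gebv[overlap])[0, 1]
        assert r > 0.98


class TestPredict:
    def test_training_lines_reproduce_training_gebv(self, rng):
        geno, y, _ = _training_instance(rng)
        model = fit_rrblup(geno, y)
        res = predict_gebv(model, geno)
        assert np.allclose(res.gebv[model.train_ids],
                           model.train_gebv[model.train_ids], atol=1e-10)

    def test_mean_dosage_line_has_zero_gebv(self, rng):
        geno, y, _ = _training_instance(rng)
        model = fit_rrblup(geno, y)
        mean_row = geno.data.mean(axis=0).to_frame().T
        mean_row.index = ["MEAN"]
        from wheatsel.simulate import GenotypeMatrix
        res = predict_gebv(model, GenotypeMatrix(mean_row))
        assert res.gebv["MEAN"] == pytest.approx(0.0, abs=1e-10)

    def test_progeny_prediction_recovers_genetic_values(self):
        # AMP-like training panel predicting related biparental progeny
        rs = []
        for seed in range(10):
            cfg = SimConfig(n_lines=400, n_markers=600, n_qtl=40, h2_target=0.8,
                            seed=seed)
            geno = simulate_founders(cfg)
            fb, truth = simulate_trial(geno, cfg)
            parents = geno.subset_lines(geno.line_ids[:2])
            prog = derive_biparental(parents, 200, "DH", seed=seed + 500)
            arch = GeneticArchitecture(truth.qtl_ids, truth.qtl_effects)
            _, prog_truth = simulate_trial(prog, cfg, seed=seed + 900,
                                           architecture=arch)
            y = truth.true_genetic_values["E1"]
            noisy = y + np.random.default_rng(seed).normal(0, 0.5, len(y))
            model = fit_rrblup(geno, noisy + 5.0)
            res = predict_gebv(model, prog)
            r = np.corrcoef(res.gebv[prog.line_ids],
                            prog_truth.true_genetic_values.loc[prog.line_ids, "E1"])[0, 1]
            rs.append(r)
        assert np.mean(rs) >= 0.5

    def test_empty_marker_overlap_rejected(self, rng):
        geno, y, _ = _training_instance(rng)
        model = fit_rrblup(geno, y)
        stranger = random_inbred_geno(rng, 5, 4)
        stranger.data.columns = [f"S1D_{i + 1}" for i in range(4)]
        with pytest.raises(ValueError, match="overlap"):
            predict_gebv(model, stranger)


class TestPredictiveAbility:
    def test_perfect_and_inverted_correlation(self, rng):
        g = pd.Series(rng.normal(0, 1, 20), index=[f"L{i}" for i in range(20)])
        assert predictive_ability(g, g * 2 + 1)[0] == pytest.approx(1.0)
        assert predictive_ability(g, -g)[0] == pytest.approx(-1.0)

    def test_null_pairs_rarely_exceed_point_two(self, rng):
        n, hits, runs = 450, 0, 100
        for _ in range(runs):
            a = pd.Series(rng.normal(0, 1, n), index=[f"L{i}" for i in range(n)])
            b = pd.Series(rng.normal(0, 1, n), index=a.index)
            r, used = predictive_ability(a, b)
            assert used == n
            hits += abs(r) < 0.2
        assert hits >= 0.95 * runs

    def test_zero_variance_rejected(self):
        a = pd.Series([1.0, 1.0, 1.0], index=list("abc"))
        b = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        with pytest.raises(ValueError, match="variance"):
            predictive_ability(a, b)


class TestCrossValidation:
    def test_leave_one_out_partition(self, rng):
        geno, y, _ = _training_instance(rng, n=10, m=30)
        with pytest.warns(UserWarning):
            oof, _, _ = cross_validate(geno, y, folds=10, seed=1)
        assert oof.notna().all() and len(oof) == 10

    def test_same_seed_is_deterministic(self, rng):
        geno, y, _ = _training_instance(rng, n=40, m=60)
        oof1, acc1, m1 = cross_validate(geno, y, folds=4, seed=9)
        oof2, acc2, m2 = cross_validate(geno, y, folds=4, seed=9)
        pd.testing.assert_series_equal(oof1, oof2)
        assert acc1 == acc2 and m1 == m2

    @staticmethod
    def _structured_panel(seed, n_families=20, fam_size=23, n_markers=2000):
        # a breeding panel is families of related lines, not unrelated
        # singletons; relatedness is what carries within-panel CV accuracy
        cfg = SimConfig(n_lines=40, n_markers=n_markers, seed=seed)
        founders = simulate_founders(cfg)
        frng = np.random.default_rng(seed + 1)
        frames = []
        for f in range(n_families):
            pid = frng.choice(40, 2, replace=False)
            parents = founders.subset_lines([founders.line_ids[i] for i in pid])
            prog = derive_biparental(parents, fam_size, "DH",
                                     seed=seed * 100 + f, id_prefix=f"FAM{f:02d}")
            frames.append(prog.data)
        from wheatsel.simulate import GenotypeMatrix
        return GenotypeMatrix(pd.concat(frames), founders.marker_map)

    def test_five_fold_ability_in_plausible_band(self):
        # h2 = 0.5, 460-line related panel, 2000 markers: mean CV
        # predictive ability between 0.3 and the sqrt(h2) ~ 0.8 ceiling
        accs = []
        for seed in range(6):
            panel = self._structured_panel(seed)
            rng = np.random.default_rng(seed + 9)
            qtl = rng.choice(panel.n_markers, 20, replace=False)
            W = panel.dosages()[:, qtl]
            W = W - W.mean(axis=0)
            g = W @ rng.normal(0, 1, 20)
            g = g / g.std()
            y = pd.Series(5 + g + rng.normal(0, 1, panel.n_lines),
                          index=panel.line_ids)
            _, _, mean_acc = cross_validate(panel, y, folds=5, seed=seed)
            accs.append(mean_acc)
        assert 0.3 <= np.mean(accs) <= 0.8

    def test_invalid_fold_counts_rejected(self, rng):
        geno, y, _ = _training_instance(rng, n=10, m=20)
        with pytest.raises(ValueError):
            cross_validate(geno, y, folds=1)
        with pytest.raises(ValueError):
            cross_validate(geno, y, folds=11)
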