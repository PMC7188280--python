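"""Association scan, BH-FDR step-up, top-SNP selection, drop-one R^2."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from wheatsel.assoc import (bh_fdr, run_mlm_gwas, select_top_snps,
                            snp_variance_explained, GWASResult)
from wheatsel.relatedness import KinshipMatrix, compute_kinship
from wheatsel.simulate import SimConfig, simulate_founders

from conftest import make_geno, random_inbred_geno


class TestBHFDR:
    def test_single_pvalue_unchanged(self):
        assert bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_hand_step_up(self):
        # p = (0.01 .. 0.05), m = 5: q(i) = min_{j>=i} 5 p(j)/j = 0.05 for all
        q = bh_fdr([0.01, 0.02, 0.03, 0.04, 0.05])
        assert np.allclose(q, 0.05)

    def test_matches_statsmodels(self, rng):
        p = rng.random(200)
        q = bh_fdr(p)
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(q, q_sm, atol=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=60))
    def test_permutation_equivariance_and_dominance(self, pvals):
        p = np.asarray(pvals)
        q = bh_fdr(p)
        assert (q >= p - 1e-15).all() and (q <= 1.0).all()
        perm = np.argsort(p, kind="mergesort")[::-1]
        assert np.allclose(bh_fdr(p[perm]), q[perm])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


@pytest.fixture(scope="module")
def amp_panel():
    cfg = SimConfig(n_lines=200, n_markers=400, seed=17)
    return simulate_founders(cfg)


class TestMLMScan:
    def test_duplicate_marker_content_gets_identical_pvalues(self, amp_panel):
        geno = make_geno(np.column_stack([amp_panel.dosages()[:, :50],
                                          amp_panel.dosages()[:, 0]]),
                         line_ids=amp_panel.line_ids)
        rng = np.random.default_rng(3)
        y = pd.Series(rng.normal(5, 1, geno.n_lines), index=geno.line_ids)
        res = run_mlm_gwas(geno, y)
        t = res.table.set_index("marker")
        dup_id = geno.marker_ids[-1]
        assert t.loc[dup_id, "pvalue"] == pytest.approx(
            t.loc[geno.marker_ids[0], "pvalue"], rel=1e-10)

    def test_identity_kinship_reduces_to_ols(self, amp_panel):
        rng = np.random.default_rng(4)
        y = pd.Series(rng.normal(5, 1, amp_panel.n_lines), index=amp_panel.line_ids)
        I = pd.DataFrame(np.eye(amp_panel.n_lines),
                         index=amp_panel.line_ids, columns=amp_panel.line_ids)
        kin = KinshipMatrix(I, 1.0, amp_panel.allele_freq())
        res = run_mlm_gwas(amp_panel, y, kinship=kin)
        t = res.table.set_index("marker")
        for m in amp_panel.marker_ids[:10]:
            if m not in t.index:
                continue
            lr = stats.linregress(amp_panel.data[m].loc[y.index], y)
            assert t.loc[m, "pvalue"] == pytest.approx(lr.pvalue, rel=1e-6)
            assert t.loc[m, "effect"] == pytest.approx(lr.slope, rel=1e-6)

    def test_planted_qtl_favorable_allele_sign(self):
        # the selected favourable allele matches the planted effect direction
        agree = total = 0
        for seed in range(20):
            cfg = SimConfig(n_lines=300, n_markers=300, seed=seed)
            geno = simulate_founders(cfg)
            rng = np.random.default_rng(seed + 10_000)
            j = int(rng.integers(geno.n_markers))
            sign = 1 if rng.random() < 0.5 else -1
            x = geno.data.iloc[:, j].astype(float)
            g = sign * (x - x.mean()) / x.std() * np.sqrt(0.15)
            y = pd.Series(5 + g + rng.normal(0, np.sqrt(0.85), geno.n_lines),
                          index=geno.line_ids)
            res = run_mlm_gwas(geno, y)
            sel = select_top_snps(res, k=5)
            row = sel.table[sel.table["marker"] == geno.marker_ids[j]]
            if not row.empty:
                total += 1
                expected = 2 if sign > 0 else 0
                agree += int(row["required_dosage"].iloc[0]) == expected
        assert total >= 10
        assert agree / total >= 0.95

    def test_small_overlap_rejected(self, rng):
        geno = random_inbred_geno(rng, 20, 50)
        y = pd.Series(rng.normal(5, 1, 20), index=geno.line_ids)
        with pytest.raises(ValueError, match="30"):
            run_mlm_gwas(geno, y)

    def test_substitution_is_logged(self, amp_panel):
        rng = np.random.default_rng(6)
        y = pd.Series(rng.normal(5, 1, amp_panel.n_lines), index=amp_panel.line_ids)
        res = run_mlm_gwas(amp_panel, y)
        assert "P3D" in res.method_note


class TestTopSNPs:
    def _result(self, pvals, effects, dataset="D1"):
        m = len(pvals)
        table = pd.DataFrame({
            "marker": [f"S1A_{i + 1}" for i in range(m)],
            "effect": effects, "se": 0.1, "pvalue": pvals,
            "qvalue": bh_fdr(pvals), "maf": 0.3,
        })
        table["significant"] = table["qvalue"] <= 0.05
        return GWASResult(table, dataset, 0.05, 100)

    def test_no_significant_markers_empty_set(self):
        res = self._result([0.4, 0.6, 0.9], [0.1, -0.1, 0.2])
        with pytest.warns(UserWarning):
            sel = select_top_snps(res, k=5)
        assert len(sel) == 0

    def test_k_larger_than_significant_count(self):
        res = self._result([1e-6, 1e-5, 0.9], [0.2, -0.3, 0.1])
        sel = select_top_snps(res, k=5)
        assert len(sel) == 2
        assert (sel.table["required_dosage"] == [2, 0]).all()

    def test_best_q_across_datasets(self):
        r1 = self._result([1e-4, 0.5], [0.2, 0.1], "D1")
        r2 = self._result([0.5, 1e-6], [-0.2, -0.3], "D2")
        sel = select_top_snps([r1, r2], k=2)
        assert list(sel.table["dataset"]) == ["D2", "D1"]
        # favourable direction taken from the dataset with the best q
        assert list(sel.table["required_dosage"]) == [0, 2]


class TestVarianceExplained:
    def test_single_marker_explaining_everything(self, rng):
        geno = random_inbred_geno(rng, 60, 5)
        y = pd.Series(geno.data.iloc[:, 0] * 0.5 + 2.0, index=geno.line_ids)
        r2 = snp_variance_explained(geno, y, [geno.marker_ids[0]])
        assert r2.iloc[0] == pytest.approx(1.0, abs=1e-10)

    def test_orthogonal_marker_contributes_zero(self, rng):
        geno = make_geno(np.array([[0, 0], [0, 2], [2, 0], [2, 2]] * 10))
        y = pd.Series(geno.data.iloc[:, 0].astype(float), index=geno.line_ids)
        r2 = snp_variance_explained(geno, y, geno.marker_ids)
        assert r2[geno.marker_ids[1]] == pytest.approx(0.0, abs=1e-10)

    def test_correlated_qtl_subadditive_vs_ols_oracle(self, rng):
        # two overlapping causal markers: drop-one R^2 sums below full R^2
        x1 = 2 * (rng.random(200) < 0.5)
        flip = rng.random(200) < 0.15
        x2 = np.where(flip, 2 - x1, x1)
        geno = make_geno(np.column_stack([x1, x2]))
        y = pd.Series(0.4 * x1 + 0.3 * x2 + rng.normal(0, 0.5, 200),
                      index=geno.line_ids)
        r2 = snp_variance_explained(geno, y, geno.marker_ids)
        X = np.column_stack([np.ones(200), x1, x2])
        yc = y.to_numpy() - y.mean()
        full = 1 - np.sum((yc - X @ np.linalg.lstsq(X, yc, rcond=None)[0]) ** 2) / np.sum(yc ** 2)
        assert r2.sum() <= full + 1e-10
        assert (r2 > 0).all()

    def test_collinear_marker_pruned_with_warning(self, rng):
        x = 2 * (rng.random(50) < 0.5)
        geno = make_geno(np.column_stack([x, x]))
        y = pd.Series(x + rng.normal(0, 0.3, 50), index=geno.line_ids)
        with pytest.warns(UserWarning, match="pruned"):
            r2 = snp_variance_explained(geno, y, geno.marker_ids)
        assert len(r2) == 1
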