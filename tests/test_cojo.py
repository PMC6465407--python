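"""Approximate joint/conditional analysis against exact least-squares."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sp

from eqtlink import cojo
from eqtlink.cojo import CollinearityError, cojo_select, conditional_stats, joint_fit
from eqtlink.simulate import (exact_hwe_genotypes, marginal_ols_stats,
                              panel_from_genotypes)
from eqtlink.sumstats import from_frame
from conftest import make_panel, gwas_frame


@pytest.fixture(scope="module")
def hwe_world():
    """n=2000 individuals, 6 exact-HWE variants in AR-1 LD, linear trait.

    With the panel equal to the analysis sample and exact HWE columns, the
    summary-statistics reconstruction of X'X is exact, so joint and
    conditional estimates must match multiple regression.
    """
    n = 2000
    fs = np.array([0.2, 0.3, 0.4, 0.3, 0.2, 0.5])
    G = exact_hwe_genotypes(n, fs, rho=0.8, seed=5)
    rng = np.random.default_rng(99)
    beta_true = np.array([0.3, 0.0, -0.2, 0.1, 0.0, 0.15])
    y = G @ beta_true + rng.standard_normal(n)
    stats = marginal_ols_stats(G, y)
    panel = panel_from_genotypes(G)
    return G, y, stats, panel


def _ols(G, y, cols):
    Gc = G - G.mean(axis=0)
    yc = y - y.mean()
    X = Gc[:, cols]
    b = np.linalg.solve(X.T @ X, X.T @ yc)
    sigma2 = (yc @ yc - b @ (X.T @ yc)) / (len(y) - len(cols) - 1)
    se = np.sqrt(sigma2 * np.diag(np.linalg.inv(X.T @ X)))
    return b, se


class TestJointFit:
    def test_single_variant_identity(self, hwe_world):
        _G, _y, stats, panel = hwe_world
        fit = joint_fit(stats, panel, ["s0"])
        rec = stats.record("s0")
        assert fit.b_joint[0] == pytest.approx(rec.beta, rel=1e-6)
        assert fit.se_joint[0] == pytest.approx(rec.se, rel=0.02)

    def test_orthogonal_variants_keep_marginals(self):
        # two uncorrelated variants on different chromosomes
        rng = np.random.default_rng(2)
        G = rng.integers(0, 3, (4000, 2)).astype(float)
        y = 0.2 * G[:, 0] - 0.1 * G[:, 1] + rng.standard_normal(4000)
        stats = marginal_ols_stats(G, y)
        panel = panel_from_genotypes(G)
        fit = joint_fit(stats, panel, ["s0", "s1"])
        r = panel.compute_r("s0", "s1")
        for j, vid in enumerate(["s0", "s1"]):
            # joint beta deviates from marginal only through the small
            # empirical correlation
            assert fit.b_joint[j] == pytest.approx(
                stats.record(vid).beta, rel=0.05 + 10 * abs(r))

    def test_matches_exact_ols(self, hwe_world):
        G, y, stats, panel = hwe_world
        cols = [0, 1, 2, 3]
        fit = joint_fit(stats, panel, [f"s{j}" for j in cols])
        ols_b, ols_se = _ols(G, y, cols)
        np.testing.assert_allclose(fit.b_joint, ols_b, rtol=1e-6)
        np.testing.assert_allclose(fit.se_joint, ols_se, rtol=1e-2)

    def test_collinear_pair_named(self, hwe_world):
        _G, _y, stats, panel = hwe_world
        dup = panel.dosages[:, [0]]
        G2 = np.hstack([panel.dosages, dup])
        meta = pd.concat([panel.variants[["variant_id", "chrom", "pos",
                                          "effect_allele", "other_allele"]],
                          pd.DataFrame([{"variant_id": "s0b", "chrom": "1",
                                         "pos": 1_007_000,
                                         "effect_allele": "A",
                                         "other_allele": "G"}])],
                         ignore_index=True)
        from eqtlink.ld import ReferencePanel
        panel2 = ReferencePanel(meta, G2)
        df = stats.df.copy()
        extra = df.iloc[[0]].assign(variant_id="s0b", pos=1_007_000)
        stats2 = from_frame(pd.concat([df, extra], ignore_index=True))
        with pytest.raises(CollinearityError, match="s0"):
            joint_fit(stats2, panel2, ["s0", "s0b"])


class TestConditionalStats:
    def test_empty_set_is_identity(self, hwe_world):
        _G, _y, stats, panel = hwe_world
        cond = conditional_stats(stats, panel, S=[])
        np.testing.assert_allclose(cond["b_cond"], stats.df["beta"])
        np.testing.assert_allclose(cond["p_cond"], stats.df["p"])

    def test_hand_arithmetic(self):
        """d_t=d_s=100, r=0.5, b_t=0.2, b_s=0.3 -> b_cond=(20-15)/100=0.05."""
        # build a world with w=0.5 (f=0.5), n=200 so d=100
        n = 200
        f = 0.5
        G = exact_hwe_genotypes(n, [f, f], rho=0.0, seed=1)
        # impose exact r=0.5 via constructed columns is fiddly; instead
        # verify the formula directly through the workspace
        from eqtlink.cojo import CojoWorkspace
        df = gwas_frame([
            ("s", "1", 1_000_000, "A", "G", 0.5, 0.3, 0.1, None, 200.0),
            ("t", "1", 1_001_000, "A", "G", 0.5, 0.2, 0.1, None, 200.0),
        ])
        df["p"] = 2 * sp.norm.sf(np.abs(df["beta"] / df["se"]))
        stats = from_frame(df)

        class FixedRPanel:
            def compute_r(self, a, b):
                return 0.5 if a != b else 1.0

            def ld_matrix(self, ids):
                from eqtlink.ld import LdMatrix
                m = len(ids)
                r = np.full((m, m), 0.5)
                np.fill_diagonal(r, 1.0)
                return LdMatrix(list(ids), r)

        ws = CojoWorkspace.build(stats, FixedRPanel())
        cond = conditional_stats(ws, S=["s"])
        got = cond.loc[cond["variant_id"] == "t", "b_cond"].iloc[0]
        # 1e-6 rather than exact: the PSD ridge on the LD diagonal shifts
        # b_J by ~1e-8 relative
        assert got == pytest.approx(0.05, rel=1e-6)

    def test_matches_exact_ols_residual_regression(self, hwe_world):
        G, y, stats, panel = hwe_world
        S = ["s0", "s1", "s2", "s3"]
        cond = conditional_stats(stats, panel, S=S)
        ols_b, _ = _ols(G, y, [0, 1, 2, 3])
        Gc = G - G.mean(axis=0)
        yc = y - y.mean()
        resid = yc - Gc[:, :4] @ ols_b
        for t in (4, 5):
            xt = Gc[:, t]
            expected = (xt @ resid) / (xt @ xt)
            got = cond.loc[cond["variant_id"] == f"s{t}", "b_cond"].iloc[0]
            assert got == pytest.approx(expected, rel=1e-6)

    def test_distant_variants_unchanged(self):
        """Variants beyond the LD horizon keep their marginal statistics."""
        rng = np.random.default_rng(4)
        G = rng.integers(0, 3, (2000, 3)).astype(float)
        y = 0.3 * G[:, 0] + rng.standard_normal(2000)
        stats = marginal_ols_stats(G, y, spacing=20_000_000)
        panel = panel_from_genotypes(G, spacing=20_000_000)
        cond = conditional_stats(stats, panel, S=["s0"])
        far = cond[cond["variant_id"] != "s0"]
        np.testing.assert_allclose(
            far["b_cond"], stats.df.set_index("variant_id").loc[
                far["variant_id"], "beta"], rtol=1e-9)


class TestCojoSelect:
    def test_single_signal_block_collapses(self, hwe_world):
        """Correlated proxies of one causal variant yield one selection."""
        n = 2000
        fs = [0.3] * 5
        G = exact_hwe_genotypes(n, fs, rho=0.95, seed=11)
        rng = np.random.default_rng(12)
        y = 0.35 * G[:, 2] + rng.standard_normal(n)
        stats = marginal_ols_stats(G, y)
        panel = panel_from_genotypes(G)
        sel = cojo_select(stats, panel, p_cutoff=5e-8)
        assert len(sel.selected) == 1
        best = stats.df.sort_values(["p", "pos"]).iloc[0]["variant_id"]
        assert sel.selected == [best]

    def test_independent_signals_both_selected(self):
        rng = np.random.default_rng(13)
        G = rng.integers(0, 3, (4000, 2)).astype(float)
        y = 0.25 * G[:, 0] - 0.25 * G[:, 1] + rng.standard_normal(4000)
        stats = marginal_ols_stats(G, y)
        panel = panel_from_genotypes(G, spacing=20_000_000)
        # keep positions consistent between stats and panel
        stats.df["pos"] = panel.variants["pos"].values
        sel = cojo_select(stats, panel, p_cutoff=5e-8)
        assert sorted(sel.selected) == ["s0", "s1"]
        for j, vid in enumerate(sel.fit.ids):
            assert sel.fit.b_joint[j] == pytest.approx(
                stats.record(vid).beta, rel=0.05)

    def test_masked_secondary_found_and_matches_best_subset(self):
        """A secondary signal invisible marginally is selected jointly, and
        the selected pair is the best 2-variant model by exhaustive OLS."""
        n = 2000
        m = 8
        fs = [0.3] * m
        G = exact_hwe_genotypes(n, fs, rho=0.93, seed=21)
        rng = np.random.default_rng(22)
        Gc = G - G.mean(axis=0)
        r = np.corrcoef(Gc.T)[2, 5]
        # opposing effects sized so the secondary's marginal signal vanishes
        b1 = 0.5
        b2 = -r * b1
        y = b1 * G[:, 2] + b2 * G[:, 5] + rng.standard_normal(n)
        stats = marginal_ols_stats(G, y)
        panel = panel_from_genotypes(G)
        sel = cojo_select(stats, panel, p_cutoff=5e-8, collinearity_r2=0.98)
        assert sorted(sel.selected) == ["s2", "s5"]
        assert stats.record("s5").p > 5e-8  # masked marginally
        # exhaustive best 2-subset by residual sum of squares
        yc = y - y.mean()
        best_rss, best_pair = np.inf, None
        for a in range(m):
            for b in range(a + 1, m):
                X = Gc[:, [a, b]]
                bb = np.linalg.solve(X.T @ X, X.T @ yc)
                rss = yc @ yc - bb @ (X.T @ yc)
                if rss < best_rss:
                    best_rss, best_pair = rss, (f"s{a}", f"s{b}")
        assert tuple(sorted(sel.selected)) == best_pair

    def test_row_order_invariance(self, hwe_world):
        _G, _y, stats, panel = hwe_world
        shuffled = from_frame(
            stats.df.sample(frac=1.0, random_state=0).reset_index(drop=True))
        a = cojo_select(stats, panel, p_cutoff=1e-3)
        b = cojo_select(shuffled, panel, p_cutoff=1e-3)
        assert a.selected == b.selected

    def test_no_residual_signal_after_selection(self, hwe_world):
        _G, _y, stats, panel = hwe_world
        cutoff = 1e-4
        sel = cojo_select(stats, panel, p_cutoff=cutoff)
        cond = conditional_stats(stats, panel, S=sel.selected)
        rest = cond[~cond["selected"] & ~cond["collinear"]]
        assert (rest["p_cond"] > cutoff).all()
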