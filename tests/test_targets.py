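"""Target prediction, direction calls and functional-interval support."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sp

from eqtlink import sumstats as ss
from eqtlink.sentinels import SentinelEqtl, SentinelEqtlSet
from eqtlink.targets import (AMBIGUOUS, DECREASED, INCREASED, UNKNOWN,
                             call_direction, functional_support,
                             predict_targets, read_gene_link_bed)
from conftest import make_panel, gwas_frame


def _sset(entries):
    out = SentinelEqtlSet()
    for (ds, gene), sents in entries.items():
        out.sentinels[(ds, gene)] = [
            SentinelEqtl(v, p, datasets=((ds, t),)) for v, p, t in sents]
    return out


def _gwas(rows):
    df = gwas_frame(rows)
    df["p"] = 2 * sp.norm.sf(np.abs(df["beta"] / df["se"]))
    return ss.from_frame(df)


def _catalog(rows):
    """rows: (ds, tissue, gene, vid, pos, a1, a2, beta)."""
    out = []
    for ds, tissue, gene, vid, pos, a1, a2, beta in rows:
        out.append({
            "dataset_id": ds, "tissue_class": tissue, "gene_id": gene,
            "gene_start": 1_000_000, "gene_end": 1_050_000, "chr": "1",
            "pos": pos, "variant_id": vid, "effect_allele": a1,
            "other_allele": a2, "beta": beta,
            "se": None if beta is None else 0.05, "p": 1e-12, "n": 500,
        })
    return ss.catalog_from_frame(pd.DataFrame(out))


@pytest.fixture
def ld_panel():
    """v0~v1 in high LD; v2 independent."""
    rng = np.random.default_rng(1)
    a = rng.integers(0, 3, 500)
    b = a.copy()
    b[rng.choice(500, 10, replace=False)] = rng.integers(0, 3, 10)
    c = rng.integers(0, 3, 500)
    return make_panel([a.tolist(), b.tolist(), c.tolist()],
                      positions=[1_000_000, 1_020_000, 1_400_000])


class TestPredictTargets:
    def test_identity_ld(self, ld_panel):
        sset = _sset({("d1", "G"): [("v0", 1e-12, "breast")]})
        preds = predict_targets(["v0"], sset, ld_panel, r2_min=0.8)
        assert len(preds) == 1
        assert (preds[0].risk_variant, preds[0].gene_id) == ("v0", "G")
        assert preds[0].best_r2 == pytest.approx(1.0)

    def test_below_threshold_no_prediction(self, ld_panel):
        r2 = ld_panel.compute_r("v0", "v2") ** 2
        assert r2 < 0.8
        sset = _sset({("d1", "G"): [("v2", 1e-12, "breast")]})
        assert predict_targets(["v0"], sset, ld_panel, r2_min=0.8) == []

    def test_proxy_ld_prediction_and_decoy_exclusion(self, ld_panel):
        sset = _sset({("d1", "G_true"): [("v1", 1e-12, "breast")],
                      ("d1", "G_decoy"): [("v2", 1e-12, "breast")]})
        preds = predict_targets(["v0"], sset, ld_panel, r2_min=0.8)
        assert [p.gene_id for p in preds] == ["G_true"]


class TestCallDirection:
    def test_sign_logic_decreased(self, ld_panel):
        """Risk allele A raises both risk and expression, so the protective
        allele (G) lowers expression: decreased expression, decreased risk."""
        gwas = _gwas([("v0", "1", 1_000_000, "A", "G", 0.4, 0.05, 0.008,
                       None, 50_000)])
        cat = _catalog([("d1", "breast", "G", "v0", 1_000_000, "A", "G", 0.3)])
        sset = _sset({("d1", "G"): [("v0", 1e-12, "breast")]})
        pred = predict_targets(["v0"], sset, ld_panel, r2_min=0.8)[0]
        call = call_direction(pred, gwas, cat, ld_panel)
        assert call.consolidated == DECREASED

    def test_sign_logic_increased(self, ld_panel):
        gwas = _gwas([("v0", "1", 1_000_000, "A", "G", 0.4, 0.05, 0.008,
                       None, 50_000)])
        cat = _catalog([("d1", "breast", "G", "v0", 1_000_000, "A", "G", -0.3)])
        sset = _sset({("d1", "G"): [("v0", 1e-12, "breast")]})
        pred = predict_targets(["v0"], sset, ld_panel, r2_min=0.8)[0]
        assert call_direction(pred, gwas, cat, ld_panel).consolidated == INCREASED

    def test_conflicting_datasets_ambiguous(self, ld_panel):
        gwas = _gwas([("v0", "1", 1_000_000, "A", "G", 0.4, 0.05, 0.008,
                       None, 50_000)])
        cat = _catalog([
            ("d1", "breast", "G", "v0", 1_000_000, "A", "G", 0.3),
            ("d2", "whole-blood", "G", "v0", 1_000_000, "A", "G", -0.3),
        ])
        sset = SentinelEqtlSet()
        sset.sentinels[("d1", "G")] = [
            SentinelEqtl("v0", 1e-12, datasets=(("d1", "breast"),))]
        sset.sentinels[("d2", "G")] = [
            SentinelEqtl("v0", 1e-12, datasets=(("d2", "whole-blood"),))]
        pred = predict_targets(["v0"], sset, ld_panel, r2_min=0.8)[0]
        assert call_direction(pred, gwas, cat, ld_panel).consolidated == AMBIGUOUS

    def test_unsigned_evidence_unknown(self, ld_panel):
        gwas = _gwas([("v0", "1", 1_000_000, "A", "G", 0.4, 0.05, 0.008,
                       None, 50_000)])
        cat = _catalog([("d1", "breast", "G", "v0", 1_000_000, "A", "G", None)])
        sset = _sset({("d1", "G"): [("v0", 1e-12, "breast")]})
        pred = predict_targets(["v0"], sset, ld_panel, r2_min=0.8)[0]
        assert call_direction(pred, gwas, cat, ld_panel).consolidated == UNKNOWN

    def test_strand_flip_resolved_by_harmonization(self, ld_panel):
        """Catalog reports the eQTL on the opposite strand with swapped
        alleles; naive sign comparison would be wrong.

        Panel codes v0 as A(effect)/G(other).  GWAS: effect allele A,
        beta +0.05 -> protective allele is G.  Catalog entry codes the same
        variant as C(effect)/T(other) (complement of G/A: the opposite
        strand, swapped): its effect allele C corresponds to panel G.
        Reported beta +0.3 for C therefore means protective-G raises
        expression -> increased expression with decreased risk.  Reading the
        sign naively off the reported beta relative to the GWAS effect
        allele A would call 'decreased'.
        """
        gwas = _gwas([("v0", "1", 1_000_000, "A", "G", 0.4, 0.05, 0.008,
                       None, 50_000)])
        cat = _catalog([("d1", "breast", "G", "v0", 1_000_000, "C", "T", 0.3)])
        sset = _sset({("d1", "G"): [("v0", 1e-12, "breast")]})
        pred = predict_targets(["v0"], sset, ld_panel, r2_min=0.8)[0]
        assert call_direction(pred, gwas, cat, ld_panel).consolidated == INCREASED

    @pytest.mark.parametrize("g_code", [("A", "G"), ("G", "A"),
                                        ("T", "C"), ("C", "T")])
    @pytest.mark.parametrize("e_code", [("A", "G"), ("G", "A"),
                                        ("T", "C"), ("C", "T")])
    def test_recoding_invariance(self, ld_panel, g_code, e_code):
        """The call is invariant to all allele re-codings of the GWAS and
        catalog records (signs transformed consistently)."""
        ga, go = g_code
        gwas_beta = 0.05 if ga in ("A", "T") else -0.05
        eaf = 0.4 if ga in ("A", "T") else 0.6
        gwas = _gwas([("v0", "1", 1_000_000, ga, go, eaf, gwas_beta, 0.008,
                       None, 50_000)])
        ea, eo = e_code
        eqtl_beta = 0.3 if ea in ("A", "T") else -0.3
        cat = _catalog([("d1", "breast", "G", "v0", 1_000_000, ea, eo,
                         eqtl_beta)])
        sset = _sset({("d1", "G"): [("v0", 1e-12, "breast")]})
        pred = predict_targets(["v0"], sset, ld_panel, r2_min=0.8)[0]
        assert call_direction(pred, gwas, cat, ld_panel).consolidated == DECREASED


class TestFunctionalSupport:
    def _bed(self, tmp_path, lines):
        f = tmp_path / "ann.bed"
        f.write_text("".join(lines))
        return read_gene_link_bed(f)

    def test_direct_overlap(self, tmp_path, ld_panel):
        ann = self._bed(tmp_path, ["1\t999900\t1000100\tG\tenhancer\n"])
        sset = _sset({("d1", "G"): [("v0", 1e-12, "breast")]})
        preds = predict_targets(["v0"], sset, ld_panel, r2_min=0.8)
        out = functional_support(preds, ld_panel, ann)
        assert out[0].supported
        assert out[0].hits[0].variant_id == "v0"

    def test_wrong_gene_not_supported(self, tmp_path, ld_panel):
        ann = self._bed(tmp_path, ["1\t999900\t1000100\tOTHER\tenhancer\n"])
        sset = _sset({("d1", "G"): [("v0", 1e-12, "breast")]})
        preds = predict_targets(["v0"], sset, ld_panel, r2_min=0.8)
        assert not functional_support(preds, ld_panel, ann)[0].supported

    def test_support_via_proxy_only(self, tmp_path, ld_panel):
        """Interval covers only the proxy v1 (r2>0.8 with v0)."""
        ann = self._bed(tmp_path, ["1\t1019990\t1020010\tG\tchia-pet\n"])
        sset = _sset({("d1", "G"): [("v0", 1e-12, "breast")]})
        preds = predict_targets(["v0"], sset, ld_panel, r2_min=0.8)
        out = functional_support(preds, ld_panel, ann, r2_min=0.8,
                                 maf_min=0.01)
        assert out[0].supported
        hit = out[0].hits[0]
        assert hit.variant_id == "v1"
        assert hit.r2_to_sentinel == pytest.approx(
            ld_panel.compute_r("v0", "v1") ** 2)
        # brute-force proxy enumeration agrees
        proxies = [v for v in ld_panel.variant_ids if v != "v0"
                   and ld_panel.compute_r("v0", v) ** 2 >= 0.8]
        assert hit.variant_id in proxies

    def test_half_open_bed_semantics(self, tmp_path, ld_panel):
        # BED [999999, 1000000) covers 1-based position 1_000_000 exactly
        ann = self._bed(tmp_path, ["1\t999999\t1000000\tG\tx\n"])
        sset = _sset({("d1", "G"): [("v0", 1e-12, "breast")]})
        preds = predict_targets(["v0"], sset, ld_panel, r2_min=0.8)
        assert functional_support(preds, ld_panel, ann)[0].supported
        # and [1000000, 1000001) does not
        ann2 = self._bed(tmp_path, ["1\t1000000\t1000001\tG\tx\n"])
        assert not functional_support(preds, ld_panel, ann2)[0].supported

    def test_malformed_bed_reports_line(self, tmp_path):
        f = tmp_path / "bad.bed"
        f.write_text("1\t100\t200\tG\n1\tnope\t300\tG\n")
        with pytest.raises(ValueError, match="line 2"):
            read_gene_link_bed(f)
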