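"""Synthetic worlds with planted, machine-readable truth.

Generates LD-blocked reference panels, case-control GWAS summary statistics
and multi-tissue cis-eQTL catalogs so that every pipeline stage can be
exercised against known ground truth without any external data.

Haplotypes use a latent-Gaussian threshold model: within a block, each
haplotype's latent values follow an AR-1 process with parameter rho
(independent across blocks and haplotypes); an allele is 1 when the latent
exceeds the (1 - MAF) normal quantile, and the genotype is the sum of two
independent haplotypes.  The model is deterministic given the seed, has
analytically controllable structure, and needs no external simulator.  The
latent rho is *not* the genotype correlation — thresholding attenuates it —
so realized dosage r is what every test measures and every analysis uses.

Per-variant MAFs are a deterministic low-discrepancy sequence over the
block's MAF range (golden-ratio stride), so the same block spec always
yields the same allele frequencies regardless of which generator consumes
it.

GWAS effects are planted on the log-odds scale and summary statistics are
*estimated* from simulated individuals (score test), so standard errors and
p-values behave like real data.  An ``analytic`` mode draws z-scores
directly from the asymptotic distribution for huge-n experiments; it is
clearly labeled an approximation and is never the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _st

from .ld import ReferencePanel
from .sumstats import EqtlCatalog, GwasSummaryStats, catalog_from_frame, from_frame

_GOLDEN = 0.6180339887498949

# Effect/other alleles assigned to every simulated variant: a fixed
# non-palindromic pair keeps harmonization exact and strand-unambiguous.
EFFECT_ALLELE = "A"
OTHER_ALLELE = "G"


@dataclass(frozen=True)
class BlockSpec:
    """One LD block: ``n_variants`` variants with AR-1 latent correlation
    ``rho``, MAFs in ``maf_range``, laid out from ``start`` every
    ``spacing`` bp on ``chrom``."""

    n_variants: int
    rho: float = 0.9
    maf_range: tuple = (0.2, 0.45)
    chrom: str = "1"
    start: int = 1_000_000
    spacing: int = 5_000

    def __post_init__(self):
        if not (0.0 <= self.rho < 1.0):
            raise ValueError("rho must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie in (0, 0.5]")

    @property
    def positions(self) -> np.ndarray:
        return self.start + self.spacing * np.arange(self.n_variants)

    @property
    def variant_ids(self) -> list[str]:
        return [f"v{self.chrom}_{p}" for p in self.positions]

    @property
    def mafs(self) -> np.ndarray:
        lo, hi = self.maf_range
        frac = np.mod(_GOLDEN * (1 + np.arange(self.n_variants)), 1.0)
        return lo + (hi - lo) * frac


@dataclass(frozen=True)
class GeneDef:
    gene_id: str
    chrom: str
    start: int
    end: int


@dataclass(frozen=True)
class EgeneSpec:
    """A true eGene in one tissue: causal eQTL variant -> effect (SD units,
    signed, per standardized-dosage copy)."""

    gene_id: str
    tissue_class: str
    causal: dict  # variant_id -> beta


@dataclass(frozen=True)
class DatasetSpec:
    dataset_id: str
    tissue_class: str
    n: int
    report_p_max: float = 1e-4
    report_signed: bool = True


@dataclass
class ScenarioTruth:
    """Planted ground truth attached to a scenario."""

    causal_gwas: dict = field(default_factory=dict)   # variant_id -> log-OR
    egenes: list = field(default_factory=list)        # EgeneSpec
    genes: dict = field(default_factory=dict)         # gene_id -> GeneDef
    shared_causal: list = field(default_factory=list)  # (variant, gene, direction)
    decoy_genes: list = field(default_factory=list)
    datasets: list = field(default_factory=list)      # DatasetSpec defaults


def _variant_table(blocks) -> pd.DataFrame:
    rows = []
    for b in blocks:
        for vid, pos, maf in zip(b.variant_ids, b.positions, b.mafs):
            rows.append({"variant_id": vid, "chrom": b.chrom, "pos": int(pos),
                         "effect_allele": EFFECT_ALLELE,
                         "other_allele": OTHER_ALLELE, "maf": float(maf)})
    return pd.DataFrame(rows)


def _block_genotypes(n: int, block: BlockSpec, rng: np.random.Generator) -> np.ndarray:
    """n x m int8 dosages for one block (two latent AR-1 haplotypes)."""
    m = block.n_variants
    thr = _st.norm.isf(block.mafs)  # allele present above this latent value
    g = np.zeros((n, m), dtype=np.int8)
    for _hap in range(2):
        z = np.empty((n, m))
        z[:, 0] = rng.standard_normal(n)
        scale = np.sqrt(1.0 - block.rho ** 2)
        for j in range(1, m):
            z[:, j] = block.rho * z[:, j - 1] + scale * rng.standard_normal(n)
        g += (z > thr[None, :]).astype(np.int8)
    return g


def _genotypes(n: int, blocks, rng: np.random.Generator) -> np.ndarray:
    return np.concatenate([_block_genotypes(n, b, rng) for b in blocks], axis=1)


def simulate_panel(n_individuals: int, blocks, seed: int) -> ReferencePanel:
    """Reference panel of ``n_individuals`` diploid genotypes over the block
    layout.  Bit-identical given (spec, seed)."""
    rng = np.random.default_rng(seed)
    meta = _variant_table(blocks)
    dosages = _genotypes(n_individuals, blocks, rng).astype(float)
    return ReferencePanel(
        meta[["variant_id", "chrom", "pos", "effect_allele", "other_allele"]],
        dosages)


# ---------------------------------------------------------------------------
# Case-control GWAS
# ---------------------------------------------------------------------------

def simulate_gwas(blocks, truth: ScenarioTruth, n_cases: int, n_controls: int,
                  seed: int, prevalence: float = 0.1,
                  mode: str = "sampled") -> GwasSummaryStats:
    """Case-control GWAS summary statistics with planted log-odds effects.

    ``sampled`` (default): disease status follows a logistic liability with
    the planted per-allele log-ORs (intercept set by ``prevalence``,
    genotypes centred so the intercept is the population prevalence at mean
    genotype); individuals are drawn until both arms fill, and per-variant
    score tests yield b, se, p, n.  ``analytic`` draws z-scores from the
    asymptotic joint distribution (LD from an internal 2,000-individual
    panel) — an approximation for huge-n experiments only.
    """
    meta = _variant_table(blocks)
    if mode == "analytic":
        return _analytic_gwas(blocks, meta, truth, n_cases, n_controls, seed)
    if mode != "sampled":
        raise ValueError(f"unknown GWAS simulation mode: {mode!r}")
    rng = np.random.default_rng(seed)
    n_total = n_cases + n_controls
    vid_index = {v: i for i, v in enumerate(meta["variant_id"])}
    causal_idx = np.array([vid_index[v] for v in truth.causal_gwas], dtype=int)
    causal_beta = np.array(list(truth.causal_gwas.values()), dtype=float)

    y = np.zeros(n_total, dtype=np.int8)
    y[:n_cases] = 1
    phi = n_cases / n_total

    if causal_idx.size == 0:
        # No genotype-phenotype link: labels are exchangeable, so score
        # statistics can be streamed block by block without materializing
        # the full genotype matrix.
        b_parts, se_parts, eaf_parts = [], [], []
        yc = y - phi
        for blk in blocks:
            Gf = _block_genotypes(n_total, blk, rng).astype(float)
            gbar = Gf.mean(axis=0)
            U = yc @ Gf
            ss = ((Gf - gbar) ** 2).sum(axis=0)
            V = phi * (1.0 - phi) * ss
            with np.errstate(divide="ignore", invalid="ignore"):
                b_parts.append(np.where(V > 0, U / V, 0.0))
                se_parts.append(np.where(V > 0, 1.0 / np.sqrt(V), np.inf))
            eaf_parts.append(gbar / 2.0)
        b = np.concatenate(b_parts)
        se = np.concatenate(se_parts)
        eaf = np.concatenate(eaf_parts)
        return _gwas_frame(meta, eaf, b, se, n_total)

    alpha = float(np.log(prevalence / (1.0 - prevalence)))
    mafs = meta["maf"].to_numpy()
    case_rows, ctrl_rows = [], []
    need_pool = int(1.3 * max(n_cases / prevalence,
                              n_controls / (1.0 - prevalence)))
    n_case_have = n_ctrl_have = 0
    while n_case_have < n_cases or n_ctrl_have < n_controls:
        G = _genotypes(need_pool, blocks, rng)
        eta = alpha + (G[:, causal_idx] - 2.0 * mafs[causal_idx]) @ causal_beta
        case = rng.random(need_pool) < 1.0 / (1.0 + np.exp(-eta))
        case_rows.append(G[case][: n_cases - n_case_have])
        ctrl_rows.append(G[~case][: n_controls - n_ctrl_have])
        n_case_have += case_rows[-1].shape[0]
        n_ctrl_have += ctrl_rows[-1].shape[0]
        need_pool = max(need_pool // 4, 10_000)
    Gf = np.concatenate(case_rows + ctrl_rows, axis=0).astype(float)

    gbar = Gf.mean(axis=0)
    U = (y - phi) @ Gf
    ss = ((Gf - gbar) ** 2).sum(axis=0)
    V = phi * (1.0 - phi) * ss
    with np.errstate(divide="ignore", invalid="ignore"):
        b = np.where(V > 0, U / V, 0.0)
        se = np.where(V > 0, 1.0 / np.sqrt(V), np.inf)
    return _gwas_frame(meta, gbar / 2.0, b, se, n_total)


def _gwas_frame(meta, eaf, b, se, n_total) -> GwasSummaryStats:
    p = _st.chi2.sf(np.where(np.isfinite(se), (b / se) ** 2, 0.0), df=1)
    frame = pd.DataFrame({
        "variant_id": meta["variant_id"], "chrom": meta["chrom"],
        "pos": meta["pos"], "effect_allele": EFFECT_ALLELE,
        "other_allele": OTHER_ALLELE, "eaf": eaf,
        "beta": b, "se": se, "p": p, "n": float(n_total),
    })
    ok = np.isfinite(frame["se"]) & (frame["eaf"] > 0) & (frame["eaf"] < 1)
    return from_frame(frame.loc[ok])


def _analytic_gwas(blocks, meta, truth, n_cases, n_controls, seed):
    rng = np.random.default_rng(seed)
    panel = simulate_panel(2000, blocks, seed=int(rng.integers(2**31 - 1)))
    R = np.eye(len(meta))
    offset = 0
    cols = {v: i for i, v in enumerate(meta["variant_id"])}
    for b in blocks:
        ids = b.variant_ids
        sub = panel.ld_matrix(ids).r
        idx = [cols[v] for v in ids]
        R[np.ix_(idx, idx)] = sub
        offset += len(ids)
    n = n_cases + n_controls
    phi = n_cases / n
    mafs = meta["maf"].to_numpy()
    d = 2.0 * mafs * (1.0 - mafs) * n * phi * (1.0 - phi)
    mu = np.zeros(len(meta))
    for v, beta in truth.causal_gwas.items():
        mu += R[:, cols[v]] * beta * np.sqrt(d[cols[v]])
    L = np.linalg.cholesky(R + 1e-8 * np.eye(len(meta)))
    z = mu + L @ rng.standard_normal(len(meta))
    se = 1.0 / np.sqrt(d)
    frame = pd.DataFrame({
        "variant_id": meta["variant_id"], "chrom": meta["chrom"],
        "pos": meta["pos"], "effect_allele": EFFECT_ALLELE,
        "other_allele": OTHER_ALLELE, "eaf": mafs,
        "beta": z * se, "se": se, "p": _st.chi2.sf(z ** 2, df=1),
        "n": float(n),
    })
    return from_frame(frame)


# ---------------------------------------------------------------------------
# Multi-tissue eQTL catalogs
# ---------------------------------------------------------------------------

def simulate_eqtl_catalog(blocks, truth: ScenarioTruth, datasets, seed: int,
                          cis_bp: int = 1_000_000) -> EqtlCatalog:
    """Per-dataset cis-eQTL catalogs with planted effect signs.

    For each dataset, expression of each gene is a linear function of the
    standardized dosages of its planted causal variants (for the dataset's
    tissue class) plus unit-variance noise; every variant within ``cis_bp``
    of the gene is regressed against it, and rows with p <= the dataset's
    ``report_p_max`` enter the catalog.  Datasets with ``report_signed``
    False omit beta/se, exercising the "unknown" direction paths.
    """
    meta = _variant_table(blocks)
    vid_index = {v: i for i, v in enumerate(meta["variant_id"])}
    pos_arr = meta["pos"].to_numpy()
    chrom_arr = meta["chrom"].to_numpy(dtype=str)
    rows = []
    master = np.random.default_rng(seed)
    for ds in datasets:
        rng = np.random.default_rng(master.integers(2**31 - 1))
        G = _genotypes(ds.n, blocks, rng).astype(float)
        Gs = G - G.mean(axis=0)
        sd = Gs.std(axis=0)
        sd[sd == 0] = 1.0
        Gstd = Gs / sd
        for gene_id, gd in sorted(truth.genes.items()):
            cis_cols = np.nonzero((chrom_arr == gd.chrom)
                                  & (pos_arr >= gd.start - cis_bp)
                                  & (pos_arr <= gd.end + cis_bp))[0]
            if cis_cols.size == 0:
                continue
            expr = rng.standard_normal(ds.n)
            for eg in truth.egenes:
                if eg.gene_id != gene_id or eg.tissue_class != ds.tissue_class:
                    continue
                for v, beta in eg.causal.items():
                    expr = expr + beta * Gstd[:, vid_index[v]]
            X = Gs[:, cis_cols]
            ssx = (X ** 2).sum(axis=0)
            ssx[ssx == 0] = np.nan
            yc = expr - expr.mean()
            bhat = (X.T @ yc) / ssx
            resid_ss = (yc @ yc) - bhat ** 2 * ssx
            dof = ds.n - 2
            se = np.sqrt(np.maximum(resid_ss, 0.0) / dof / ssx)
            with np.errstate(divide="ignore", invalid="ignore"):
                t = bhat / se
            p = 2.0 * _st.t.sf(np.abs(t), df=dof)
            for k, col in enumerate(cis_cols):
                if not np.isfinite(p[k]) or p[k] > ds.report_p_max:
                    continue
                rows.append({
                    "dataset_id": ds.dataset_id, "tissue_class": ds.tissue_class,
                    "gene_id": gene_id, "gene_start": gd.start,
                    "gene_end": gd.end, "chr": meta["chrom"].iloc[col],
                    "pos": int(meta["pos"].iloc[col]),
                    "variant_id": meta["variant_id"].iloc[col],
                    "effect_allele": EFFECT_ALLELE, "other_allele": OTHER_ALLELE,
                    "beta": float(bhat[k]) if ds.report_signed else np.nan,
                    "se": float(se[k]) if ds.report_signed else np.nan,
                    "p": float(p[k]), "n": ds.n,
                })
    from .sumstats import EQTL_COLUMNS
    frame = pd.DataFrame(rows, columns=EQTL_COLUMNS)
    if frame.empty:
        frame["beta_present"] = pd.Series(dtype=bool)
        return EqtlCatalog(frame)
    return catalog_from_frame(frame)


# ---------------------------------------------------------------------------
# Named scenarios
# ---------------------------------------------------------------------------

DIRECTION_DECREASED = "decreased_expr_decreased_risk"
DIRECTION_INCREASED = "increased_expr_decreased_risk"
DIRECTION_AMBIGUOUS = "ambiguous"

_DEFAULT_DATASETS = [
    DatasetSpec("ds_blood", "whole-blood", n=1000),
    DatasetSpec("ds_breast", "breast", n=1000),
]


def make_scenario(name: str):
    """Documented scenario worlds: ``(blocks, truth)``.

    shared_causal_basic : one variant drives both disease risk (log-OR 0.12)
        and a gene's expression (+0.5 SD) in two tissues; a decoy eGene sits
        in an independent block with no disease link.
    masked_secondary : two causal risk variants in moderate LD with opposing
        effects; the secondary is near-invisible marginally but joint-
        significant.
    multi_eqtl_gene : one gene with three independent causal eQTL, each with
        a sub-threshold disease effect (log-OR 0.05) — only their sum is
        detectable.
    direction_conflict : opposite-sign eQTL effects for the same gene in two
        tissues at a shared risk variant.
    null : planted eGenes but no disease effects at all.
    """
    if name == "shared_causal_basic":
        b_risk = BlockSpec(20, rho=0.9, chrom="1", start=1_000_000)
        b_decoy = BlockSpec(20, rho=0.9, chrom="1", start=6_000_000)
        b_null = BlockSpec(20, rho=0.9, chrom="2", start=1_000_000)
        blocks = [b_risk, b_decoy, b_null]
        causal = b_risk.variant_ids[10]
        decoy_causal = b_decoy.variant_ids[10]
        genes = {
            "G_target": GeneDef("G_target", "1", 1_150_000, 1_200_000),
            "G_decoy": GeneDef("G_decoy", "1", 6_150_000, 6_200_000),
        }
        truth = ScenarioTruth(
            causal_gwas={causal: 0.12},
            egenes=[EgeneSpec("G_target", "whole-blood", {causal: 0.5}),
                    EgeneSpec("G_target", "breast", {causal: 0.5}),
                    EgeneSpec("G_decoy", "whole-blood", {decoy_causal: 0.5})],
            genes=genes,
            shared_causal=[(causal, "G_target", DIRECTION_DECREASED)],
            decoy_genes=["G_decoy"],
            datasets=list(_DEFAULT_DATASETS),
        )
        return blocks, truth

    if name == "masked_secondary":
        b = BlockSpec(20, rho=0.95, chrom="1", start=1_000_000)
        primary, secondary = b.variant_ids[5], b.variant_ids[10]
        truth = ScenarioTruth(
            causal_gwas={primary: 0.28, secondary: -0.18},
            genes={}, datasets=[],
        )
        return [b], truth

    if name == "multi_eqtl_gene":
        blocks = [BlockSpec(12, rho=0.9, chrom="1", start=s)
                  for s in (1_500_000, 3_000_000, 4_500_000)]
        causals = [blk.variant_ids[6] for blk in blocks]
        genes = {"G_poly": GeneDef("G_poly", "1", 2_000_000, 4_000_000)}
        truth = ScenarioTruth(
            causal_gwas={v: 0.05 for v in causals},
            egenes=[EgeneSpec("G_poly", "whole-blood",
                              {v: 0.5 for v in causals})],
            genes=genes,
            shared_causal=[(v, "G_poly", DIRECTION_DECREASED) for v in causals],
            datasets=[DatasetSpec("ds_blood", "whole-blood", n=1000)],
        )
        return blocks, truth

    if name == "direction_conflict":
        b = BlockSpec(20, rho=0.9, chrom="1", start=1_000_000)
        causal = b.variant_ids[10]
        genes = {"G_conflict": GeneDef("G_conflict", "1", 1_150_000, 1_200_000)}
        truth = ScenarioTruth(
            causal_gwas={causal: 0.12},
            egenes=[EgeneSpec("G_conflict", "whole-blood", {causal: 0.5}),
                    EgeneSpec("G_conflict", "breast", {causal: -0.5})],
            genes=genes,
            shared_causal=[(causal, "G_conflict", DIRECTION_AMBIGUOUS)],
            datasets=list(_DEFAULT_DATASETS),
        )
        return [b], truth

    if name == "null":
        blocks = [BlockSpec(8, rho=0.8, chrom="1", start=1_000_000 + i * 3_000_000)
                  for i in range(10)]
        genes = {}
        egenes = []
        for i, blk in enumerate(blocks):
            gid = f"G_null{i}"
            genes[gid] = GeneDef(gid, "1", blk.start + 50_000, blk.start + 80_000)
            egenes.append(EgeneSpec(gid, "whole-blood",
                                    {blk.variant_ids[3]: 0.6}))
        truth = ScenarioTruth(causal_gwas={}, egenes=egenes, genes=genes,
                              decoy_genes=sorted(genes),
                              datasets=[DatasetSpec("ds_blood", "whole-blood",
                                                    n=1000)])
        return blocks, truth

    raise ValueError(f"unknown scenario: {name!r}")


def null_calibration_world(n_genes: int, seed: int, m_low: int = 2,
                           m_high: int = 8):
    """A large null world for type-I-error calibration: one independent
    block per gene (2-8 variants, random AR-1 rho in [0, 0.95]), every gene
    a true eGene, no disease effects."""
    rng = np.random.default_rng(seed)
    blocks, genes, egenes = [], {}, []
    for i in range(n_genes):
        m = int(rng.integers(m_low, m_high + 1))
        rho = float(rng.uniform(0.0, 0.95))
        blk = BlockSpec(m, rho=rho, chrom="1",
                        start=1_000_000 + i * 2_000_000, spacing=2_000)
        blocks.append(blk)
        gid = f"G{i:05d}"
        genes[gid] = GeneDef(gid, "1", blk.start + 1_000, blk.start + 10_000)
        causal = {blk.variant_ids[int(rng.integers(m))]: 0.6}
        egenes.append(EgeneSpec(gid, "whole-blood", causal))
    truth = ScenarioTruth(causal_gwas={}, egenes=egenes, genes=genes,
                          datasets=[DatasetSpec("ds_blood", "whole-blood",
                                                n=1000)])
    return blocks, truth


def exact_hwe_genotypes(n: int, mafs, rho: float, seed: int) -> np.ndarray:
    """Genotype matrix whose columns carry *exact* Hardy-Weinberg counts.

    For each column with frequency f the counts are round(n f^2) homozygous,
    round(2 n f (1-f)) heterozygous, rest reference — assigned by rank on
    correlated AR-1 latents so adjacent columns are in LD.  With exact HWE
    the centred sum of squares equals n * 2f(1-f) exactly, which makes the
    summary-statistics X'X reconstruction of the joint/conditional analysis
    equal to the individual-level X'X; used to validate that equivalence.
    Frequencies should be multiples of 0.1 with n a multiple of 100 so the
    counts are integral.
    """
    mafs = np.asarray(mafs, dtype=float)
    m = mafs.size
    rng = np.random.default_rng(seed)
    lat = np.empty((n, m))
    lat[:, 0] = rng.standard_normal(n)
    scale = np.sqrt(1.0 - rho ** 2)
    for j in range(1, m):
        lat[:, j] = rho * lat[:, j - 1] + scale * rng.standard_normal(n)
    G = np.zeros((n, m))
    for j, f in enumerate(mafs):
        n2 = round(n * f * f)
        n1 = round(2 * n * f * (1.0 - f))
        order = np.argsort(-lat[:, j])
        G[order[:n2], j] = 2.0
        G[order[n2:n2 + n1], j] = 1.0
    return G


def marginal_ols_stats(G: np.ndarray, y: np.ndarray, chrom: str = "1",
                       start: int = 1_000_000,
                       spacing: int = 1_000) -> GwasSummaryStats:
    """Per-variant simple-regression summary statistics from individual-level
    data (quantitative trait), in the canonical layout."""
    n, m = G.shape
    Gc = G - G.mean(axis=0)
    yc = y - y.mean()
    sxx = (Gc ** 2).sum(axis=0)
    b = (Gc.T @ yc) / sxx
    resid_ss = (yc @ yc) - b ** 2 * sxx
    se = np.sqrt(resid_ss / (n - 2) / sxx)
    p = 2.0 * _st.t.sf(np.abs(b / se), df=n - 2)
    frame = pd.DataFrame({
        "variant_id": [f"s{j}" for j in range(m)],
        "chrom": chrom, "pos": start + spacing * np.arange(m),
        "effect_allele": EFFECT_ALLELE, "other_allele": OTHER_ALLELE,
        "eaf": G.mean(axis=0) / 2.0, "beta": b, "se": se, "p": p,
        "n": float(n),
    })
    return from_frame(frame)


def panel_from_genotypes(G: np.ndarray, chrom: str = "1",
                         start: int = 1_000_000,
                         spacing: int = 1_000) -> ReferencePanel:
    """Wrap a raw dosage matrix as a reference panel (ids ``s0..s{m-1}``,
    matching :func:`marginal_ols_stats`)."""
    m = G.shape[1]
    meta = pd.DataFrame({
        "variant_id": [f"s{j}" for j in range(m)],
        "chrom": chrom, "pos": start + spacing * np.arange(m),
        "effect_allele": EFFECT_ALLELE, "other_allele": OTHER_ALLELE,
    })
    return ReferencePanel(meta, G.astype(float))


def truth_table(truth: ScenarioTruth) -> pd.DataFrame:
    """TSV-ready flat view of the planted truth."""
    rows = [{"kind": "causal_gwas", "variant_id": v, "gene_id": "",
             "value": b, "direction": ""} for v, b in truth.causal_gwas.items()]
    for eg in truth.egenes:
        for v, b in eg.causal.items():
            rows.append({"kind": f"eqtl:{eg.tissue_class}", "variant_id": v,
                         "gene_id": eg.gene_id, "value": b, "direction": ""})
    for v, g, d in truth.shared_causal:
        rows.append({"kind": "shared_causal", "variant_id": v, "gene_id": g,
                     "value": np.nan, "direction": d})
    for g in truth.decoy_genes:
        rows.append({"kind": "decoy", "variant_id": "", "gene_id": g,
                     "value": np.nan, "direction": ""})
    return pd.DataFrame(rows, columns=["kind", "variant_id", "gene_id",
                                       "value", "direction"])
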