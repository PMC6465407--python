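"""Sentinel-eQTL construction.

Two structures are built from the per-dataset cis-eQTL catalogs:

* a per-(dataset, gene) sentinel set for target-gene prediction — cis filter,
  significance filter, then greedy clumping at r^2 < 0.05 within +/- 2 Mb;
* a cross-dataset per-gene eQTL list for the gene-based test — the union of
  reported eQTL across datasets, each assigned its minimum p over datasets,
  clumped at r^2 < 0.1 within +/- 1 Mb.

cis distance is measured from gene boundaries (0 inside [gene_start,
gene_end], else base pairs to the nearer boundary).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .ld import ReferencePanel, clump
from .sumstats import EqtlCatalog

#: Bonferroni eQTL significance threshold: 0.05 over ~55,764 transcripts
#: each tested against ~1000 variants.
DEFAULT_EQTL_P_MAX = 0.05 / (55_764 * 1000)


@dataclass(frozen=True)
class SentinelEqtl:
    variant_id: str
    p: float
    datasets: tuple = ()  # contributing (dataset_id, tissue_class) pairs


@dataclass
class SentinelEqtlSet:
    """Mapping (dataset_id, gene_id) -> ordered sentinel list."""

    sentinels: dict = field(default_factory=dict)
    n_dropped_unclumpable: int = 0

    def get(self, dataset_id: str, gene_id: str) -> list[SentinelEqtl]:
        return self.sentinels.get((dataset_id, gene_id), [])

    def items(self):
        return self.sentinels.items()


@dataclass
class GeneEqtlList:
    """Mapping gene_id -> cross-dataset sentinel eQTL list."""

    genes: dict = field(default_factory=dict)
    n_dropped_unclumpable: int = 0

    def get(self, gene_id: str) -> list[SentinelEqtl]:
        return self.genes.get(gene_id, [])

    def gene_ids(self) -> list[str]:
        return sorted(self.genes)

    def items(self):
        return self.genes.items()


def cis_distance(pos: int, gene_start: int, gene_end: int) -> int:
    """0 inside the gene body, else distance to the nearer boundary."""
    if gene_start <= pos <= gene_end:
        return 0
    return gene_start - pos if pos < gene_start else pos - gene_end


def _cis_and_significant(df: pd.DataFrame, cis_bp: int, p_max: float) -> pd.DataFrame:
    dist = [cis_distance(int(r.pos), int(r.gene_start), int(r.gene_end))
            for r in df.itertuples()]
    out = df.loc[[d <= cis_bp for d in dist]]
    return out.loc[out["p"] <= p_max]


def build_prediction_sentinels(catalog: EqtlCatalog, panel: ReferencePanel,
                               p_max: float = DEFAULT_EQTL_P_MAX,
                               r2_max: float = 0.05,
                               window_bp: int = 2_000_000,
                               cis_bp: int = 1_000_000) -> SentinelEqtlSet:
    """Per-(dataset, gene) sentinel eQTL: cis filter, significance filter,
    greedy clump.  Variants absent from the LD panel cannot be clumped and
    are dropped (counted)."""
    out = SentinelEqtlSet()
    for (ds, gene), sub in catalog.df.groupby(["dataset_id", "gene_id"], sort=True):
        sub = _cis_and_significant(sub, cis_bp, p_max)
        if sub.empty:
            continue
        in_panel = pd.Series([v in panel for v in sub["variant_id"]],
                             index=sub.index)
        out.n_dropped_unclumpable += int((~in_panel).sum())
        sub = sub.loc[in_panel]
        if sub.empty:
            continue
        assoc = list(zip(sub["variant_id"], sub["p"]))
        tissue = sub["tissue_class"].iloc[0]
        sents = [SentinelEqtl(v, p, datasets=((ds, tissue),))
                 for v, p in clump(assoc, panel, p_max, r2_max, window_bp)]
        if sents:
            out.sentinels[(ds, gene)] = sents
    return out


def build_gene_test_list(catalog: EqtlCatalog, panel: ReferencePanel,
                         p_max: float = DEFAULT_EQTL_P_MAX,
                         r2_max: float = 0.1,
                         window_bp: int = 1_000_000,
                         cis_bp: int = 1_000_000,
                         apply_p_filter: bool = True) -> GeneEqtlList:
    """Cross-dataset per-gene sentinel eQTL list for the gene-based test.

    The union of eQTL over all datasets enters clumping once per gene, each
    variant carrying its minimum p over contributing datasets.  Clumping is
    applied to the union, not per tissue/study.  ``apply_p_filter=False``
    relaxes the significance filter (the cis filter always applies).
    """
    out = GeneEqtlList()
    eff_p_max = p_max if apply_p_filter else 1.0
    for gene, sub in catalog.df.groupby("gene_id", sort=True):
        sub = _cis_and_significant(sub, cis_bp, eff_p_max)
        if sub.empty:
            continue
        in_panel = pd.Series([v in panel for v in sub["variant_id"]],
                             index=sub.index)
        out.n_dropped_unclumpable += int((~in_panel).sum())
        sub = sub.loc[in_panel]
        if sub.empty:
            continue
        min_p = sub.groupby("variant_id")["p"].min()
        contrib = {
            v: tuple(sorted(set(zip(g["dataset_id"], g["tissue_class"]))))
            for v, g in sub.groupby("variant_id")
        }
        assoc = list(min_p.items())
        sents = [SentinelEqtl(v, p, datasets=contrib[v])
                 for v, p in clump(assoc, panel, eff_p_max, r2_max, window_bp)]
        if sents:
            out.genes[gene] = sents
    return out


def mean_sentinels_per_gene(sset: SentinelEqtlSet) -> pd.Series:
    """Arithmetic mean sentinel count over genes with >=1 sentinel, per
    dataset."""
    counts: dict[str, list[int]] = {}
    for (ds, _gene), sents in sset.items():
        counts.setdefault(ds, []).append(len(sents))
    return pd.Series({ds: sum(c) / len(c) for ds, c in sorted(counts.items())},
                     dtype=float)


def gene_list_table(glist: GeneEqtlList, panel: ReferencePanel) -> pd.DataFrame:
    """TSV-ready view: gene_id, variant_id, chr, pos, min_p, datasets."""
    rows = []
    for gene, sents in sorted(glist.items()):
        for s in sents:
            meta = panel.variant(s.variant_id)
            rows.append({
                "gene_id": gene, "variant_id": s.variant_id,
                "chr": meta.chrom if meta else "", "pos": meta.pos if meta else -1,
                "min_p": s.p,
                "datasets": ",".join(d for d, _t in s.datasets),
            })
    return pd.DataFrame(rows, columns=["gene_id", "variant_id", "chr", "pos",
                                       "min_p", "datasets"])
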