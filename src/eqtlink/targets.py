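"""Target-gene prediction, directional-effect calls and functional support.

A gene is predicted as a target of a sentinel risk variant when one of its
sentinel eQTL (in any dataset) is in high LD (r^2 > 0.8 by default) with the
risk variant.  Direction is then called at the eQTL variant's own GWAS
record: the disease-protective allele is the GWAS allele with negative
log-odds, and the call records whether that allele associates with higher or
lower expression of the predicted gene.  All allele codings are harmonized
to the reference panel before signs are compared.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .ld import ReferencePanel
from .sentinels import GeneEqtlList, SentinelEqtlSet
from .sumstats import (EqtlCatalog, GwasSummaryStats, SummaryRecord,
                       harmonize_alleles)

# per-evidence directions
LOWER = "lower_expression_with_protective_allele"
HIGHER = "higher_expression_with_protective_allele"
UNKNOWN = "unknown"

# consolidated directions
DECREASED = "decreased_expr_decreased_risk"
INCREASED = "increased_expr_decreased_risk"
AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class Evidence:
    dataset_id: str
    tissue_class: str
    eqtl_variant: str
    r2: float
    eqtl_p: float


@dataclass
class TargetPrediction:
    risk_variant: str
    gene_id: str
    evidence: list = field(default_factory=list)

    @property
    def best_r2(self) -> float:
        return max(e.r2 for e in self.evidence)


@dataclass
class DirectionCall:
    per_evidence: list  # (Evidence-like key, direction) pairs
    consolidated: str

    @property
    def directions(self) -> list[str]:
        return [d for _k, d in self.per_evidence]


@dataclass(frozen=True)
class SupportHit:
    variant_id: str      # sentinel or proxy whose position intersects
    r2_to_sentinel: float
    interval: tuple      # (chrom, start_1based, end_1based_inclusive)
    source: str
    linked_gene: str


@dataclass
class FunctionalSupport:
    prediction: TargetPrediction
    hits: list = field(default_factory=list)

    @property
    def supported(self) -> bool:
        return len(self.hits) > 0


def predict_targets(risk_sentinels, eqtl_sentinels: SentinelEqtlSet,
                    panel: ReferencePanel, r2_min: float = 0.8) -> list[TargetPrediction]:
    """One prediction per (risk variant, gene) with at least one sentinel
    eQTL at r^2 > ``r2_min`` with the risk variant.  ``risk_sentinels`` may
    be a CojoSelection or a plain list of variant ids.  Variant pairs not
    resolvable in the panel are skipped."""
    risk_ids = getattr(risk_sentinels, "variant_ids", risk_sentinels)
    preds: dict[tuple, TargetPrediction] = {}
    for rv in risk_ids:
        if rv not in panel:
            continue
        for (ds, gene), sents in eqtl_sentinels.items():
            for s in sents:
                if s.variant_id not in panel:
                    continue
                r2 = panel.compute_r(rv, s.variant_id) ** 2
                if r2 > r2_min:
                    key = (rv, gene)
                    pred = preds.setdefault(key, TargetPrediction(rv, gene))
                    tissue = s.datasets[0][1] if s.datasets else ""
                    pred.evidence.append(
                        Evidence(ds, tissue, s.variant_id, r2, s.p))
    return [preds[k] for k in sorted(preds)]


def genes_per_risk_variant(preds: list[TargetPrediction]) -> pd.Series:
    counts: dict[str, int] = {}
    for p in preds:
        counts[p.risk_variant] = counts.get(p.risk_variant, 0) + 1
    return pd.Series(counts, dtype=int).sort_index()


# ---------------------------------------------------------------------------
# Direction of the protective allele's effect on expression
# ---------------------------------------------------------------------------

def _protective_allele(gwas_rec: SummaryRecord, panel: ReferencePanel) -> str | None:
    """The panel-coded allele associated with reduced disease risk, or None
    if the record cannot be harmonized to the panel."""
    meta = panel.variant(gwas_rec.variant_id)
    if meta is None:
        return None
    out = harmonize_alleles(gwas_rec, meta.effect_allele, meta.other_allele)
    if not out.usable:
        return None
    rec = out.record
    return rec.other_allele if rec.beta > 0 else rec.effect_allele


def _evidence_direction(ev: Evidence, gene_id: str, gwas: GwasSummaryStats,
                        catalog: EqtlCatalog, panel: ReferencePanel) -> str:
    if ev.eqtl_variant not in gwas:
        return UNKNOWN
    gwas_rec = gwas.record(ev.eqtl_variant)
    protective = _protective_allele(gwas_rec, panel)
    if protective is None:
        return UNKNOWN
    row = catalog.lookup(ev.dataset_id, gene_id, ev.eqtl_variant)
    if row is None or not row["beta_present"]:
        return UNKNOWN
    meta = panel.variant(ev.eqtl_variant)
    erec = SummaryRecord(ev.eqtl_variant, row["effect_allele"], row["other_allele"],
                         eaf=0.5, beta=float(row["beta"]), se=1.0, p=float(row["p"]),
                         n=1.0)
    out = harmonize_alleles(erec, meta.effect_allele, meta.other_allele)
    if not out.usable:
        return UNKNOWN
    beta_for_protective = out.record.beta if protective == meta.effect_allele \
        else -out.record.beta
    return HIGHER if beta_for_protective > 0 else LOWER


def _consolidate(directions: list[str]) -> str:
    signed = [d for d in directions if d in (HIGHER, LOWER)]
    if not signed:
        return UNKNOWN
    if LOWER in signed and HIGHER in signed:
        return AMBIGUOUS
    return DECREASED if signed[0] == LOWER else INCREASED


def call_direction(pred: TargetPrediction, gwas: GwasSummaryStats,
                   catalog: EqtlCatalog, panel: ReferencePanel) -> DirectionCall:
    """Directional effect of the protective allele on the predicted gene.

    Evaluated at each supporting eQTL variant's own GWAS record (not
    transported through the risk variant).  Evidence without a signed eQTL
    effect, or unresolvable in GWAS/panel, is ``unknown``; conflicting signed
    evidence consolidates to ``ambiguous``.
    """
    per = [(ev, _evidence_direction(ev, pred.gene_id, gwas, catalog, panel))
           for ev in pred.evidence]
    return DirectionCall(per, _consolidate([d for _e, d in per]))


def direction_consistency_across_eqtl(gene_id: str, glist: GeneEqtlList,
                                      adjusted_gwas: GwasSummaryStats,
                                      catalog: EqtlCatalog, panel: ReferencePanel,
                                      p_nominal: float = 0.05) -> DirectionCall:
    """Direction consolidation across a gene's sentinel eQTL, restricted to
    those nominally associated (adjusted-GWAS p <= ``p_nominal``)."""
    per = []
    for s in glist.get(gene_id):
        if s.variant_id not in adjusted_gwas:
            continue
        grec = adjusted_gwas.record(s.variant_id)
        if grec.p > p_nominal:
            continue
        for ds, tissue in s.datasets:
            ev = Evidence(ds, tissue, s.variant_id, 1.0, s.p)
            per.append((ev, _evidence_direction(ev, gene_id, adjusted_gwas,
                                                catalog, panel)))
    return DirectionCall(per, _consolidate([d for _e, d in per]))


# ---------------------------------------------------------------------------
# Functional support via interval annotations
# ---------------------------------------------------------------------------

def read_gene_link_bed(path) -> pd.DataFrame:
    """BED with a gene-link column: chrom, start (0-based), end (half-open),
    gene, optional source label.  Converted at the boundary to 1-based
    inclusive coordinates."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"malformed BED line {lineno}: expected >=4 "
                                 f"tab-separated fields, got {len(parts)}")
            try:
                start0, end0 = int(parts[1]), int(parts[2])
            except ValueError:
                raise ValueError(f"malformed BED line {lineno}: non-integer "
                                 f"coordinates") from None
            rows.append({
                "chrom": parts[0], "start": start0 + 1, "end": end0,
                "gene": parts[3],
                "source": parts[4] if len(parts) > 4 else "bed",
            })
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene", "source"])


def functional_support(preds: list[TargetPrediction], panel: ReferencePanel,
                       annotations: pd.DataFrame, r2_min: float = 0.8,
                       maf_min: float = 0.01,
                       window_bp: int = 1_000_000) -> list[FunctionalSupport]:
    """Annotate predictions with enhancer/interaction interval support.

    Each risk sentinel is expanded with its proxies (r^2 > ``r2_min``, panel
    MAF > ``maf_min``); a prediction is supported iff any expanded variant's
    position lies in an interval linked to the predicted gene.
    """
    out = []
    for pred in preds:
        hits = []
        meta = panel.variant(pred.risk_variant)
        expanded = [(pred.risk_variant, 1.0)]
        if meta is not None:
            expanded += [(vid, r2) for vid, r2, _d in
                         panel.find_proxies(pred.risk_variant, r2_min=r2_min,
                                            window_bp=window_bp, maf_min=maf_min)]
        for vid, r2 in expanded:
            vmeta = panel.variant(vid)
            if vmeta is None:
                continue
            sel = annotations[(annotations["chrom"].astype(str) == vmeta.chrom)
                              & (annotations["start"] <= vmeta.pos)
                              & (annotations["end"] >= vmeta.pos)
                              & (annotations["gene"] == pred.gene_id)]
            for _, a in sel.iterrows():
                hits.append(SupportHit(vid, r2, (a["chrom"], int(a["start"]),
                                                 int(a["end"])),
                                       a["source"], a["gene"]))
        out.append(FunctionalSupport(pred, hits))
    return out
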