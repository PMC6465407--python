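"""Reference-panel LD service: allelic correlations, proxy search, clumping.

The panel is a dosage matrix (individuals x variants, values 0/1/2 counting
copies of the effect allele; NaN = missing).  All LD used downstream —
clumping thresholds, proxy search, the COJO X'X reconstruction and the
gene-test null — is the Pearson correlation of dosages over pairwise-complete
individuals.  LD across chromosomes or beyond ``LD_MAX_DIST_BP`` is defined
as exactly 0, mirroring the long-range independence assumption of
summary-statistics conditional analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: LD beyond this distance (or across chromosomes) is defined as exactly 0.
LD_MAX_DIST_BP = 10_000_000
#: Ridge added to correlation-matrix diagonals before any inversion.
LD_RIDGE = 1e-8
#: Variants with more than this missingness fraction are excluded from LD.
MAX_MISSING_FRAC = 0.10


class UndefinedLdError(ValueError):
    """LD requested for a monomorphic or unusable variant."""


class VariantLookupError(KeyError):
    """Variant absent from the reference panel."""


@dataclass(frozen=True)
class PanelVariant:
    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float


@dataclass
class LdMatrix:
    """Symmetric matrix of signed allelic correlations with unit diagonal."""

    ids: list
    r: np.ndarray

    def r2(self) -> np.ndarray:
        return self.r ** 2

    def with_ridge(self, ridge: float = LD_RIDGE) -> np.ndarray:
        out = self.r.copy()
        out[np.diag_indices_from(out)] += ridge
        return out


class ReferencePanel:
    """Genotype reference panel backing every LD computation.

    Parameters
    ----------
    variants : DataFrame with columns variant_id, chrom, pos, effect_allele,
        other_allele (one row per dosage column, same order).
    dosages : float array, individuals x variants, entries in {0,1,2} or NaN.
    """

    def __init__(self, variants: pd.DataFrame, dosages: np.ndarray):
        if variants["variant_id"].duplicated().any():
            dup = variants.loc[variants["variant_id"].duplicated(), "variant_id"].iloc[0]
            raise ValueError(f"duplicate variant_id in panel: {dup!r}")
        if dosages.shape[1] != len(variants):
            raise ValueError("dosage matrix width does not match variant table")
        self.dosages = np.asarray(dosages, dtype=float)
        variants = variants.reset_index(drop=True).copy()
        with np.errstate(invalid="ignore"):
            variants["eaf"] = np.nanmean(self.dosages, axis=0) / 2.0
        missing_frac = np.mean(np.isnan(self.dosages), axis=0)
        variants["ld_usable"] = missing_frac <= MAX_MISSING_FRAC
        self.variants = variants
        self._index = {v: i for i, v in enumerate(variants["variant_id"])}
        self._centered = None

    # -- lookups ------------------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def variant_ids(self) -> list:
        return list(self.variants["variant_id"])

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def column(self, variant_id: str) -> np.ndarray:
        try:
            return self.dosages[:, self._index[variant_id]]
        except KeyError:
            raise VariantLookupError(variant_id) from None

    def variant(self, variant_id: str) -> PanelVariant | None:
        i = self._index.get(variant_id)
        if i is None:
            return None
        row = self.variants.iloc[i]
        return PanelVariant(row["variant_id"], str(row["chrom"]), int(row["pos"]),
                            row["effect_allele"], row["other_allele"], float(row["eaf"]))

    def is_polymorphic(self, variant_id: str) -> bool:
        col = self.column(variant_id)
        vals = col[~np.isnan(col)]
        return vals.size > 0 and np.nanmin(vals) != np.nanmax(vals)

    # -- LD -----------------------------------------------------------------

    def _pair_r(self, i: int, j: int) -> float:
        x, y = self.dosages[:, i], self.dosages[:, j]
        ok = ~(np.isnan(x) | np.isnan(y))
        x, y = x[ok], y[ok]
        if x.size < 2:
            raise UndefinedLdError("fewer than 2 pairwise-complete individuals")
        xc, yc = x - x.mean(), y - y.mean()
        sx, sy = np.sqrt(xc @ xc), np.sqrt(yc @ yc)
        if sx == 0.0 or sy == 0.0:
            raise UndefinedLdError("monomorphic variant over complete pairs")
        return float(np.clip((xc @ yc) / (sx * sy), -1.0, 1.0))

    def compute_r(self, v1: str, v2: str) -> float:
        """Signed dosage correlation; exactly 0 across chromosomes or beyond
        :data:`LD_MAX_DIST_BP`."""
        i, j = self._index.get(v1), self._index.get(v2)
        if i is None:
            raise VariantLookupError(v1)
        if j is None:
            raise VariantLookupError(v2)
        if i == j:
            if not self.is_polymorphic(v1):
                raise UndefinedLdError(f"monomorphic variant: {v1}")
            return 1.0
        mi, mj = self.variants.iloc[i], self.variants.iloc[j]
        if str(mi["chrom"]) != str(mj["chrom"]) or abs(int(mi["pos"]) - int(mj["pos"])) > LD_MAX_DIST_BP:
            return 0.0
        return self._pair_r(i, j)

    def ld_matrix(self, ids: Sequence[str]) -> LdMatrix:
        ids = list(ids)
        m = len(ids)
        r = np.eye(m)
        for a in range(m):
            for b in range(a + 1, m):
                r[a, b] = r[b, a] = self.compute_r(ids[a], ids[b])
        return LdMatrix(ids, r)

    # -- proxy search -------------------------------------------------------

    def find_proxies(self, v: str, r2_min: float = 0.8,
                     window_bp: int = 1_000_000, maf_min: float = 0.0) -> list[tuple]:
        """Variants in LD r^2 >= ``r2_min`` with ``v`` within ``window_bp``,
        with panel MAF >= ``maf_min``; sorted by descending r^2, then
        ascending distance, then id.  Returns ``(variant_id, r2, distance)``
        tuples; ``v`` itself is excluded."""
        meta = self.variant(v)
        if meta is None:
            raise VariantLookupError(v)
        out = []
        sub = self.variants
        near = sub[(sub["chrom"].astype(str) == meta.chrom)
                   & ((sub["pos"] - meta.pos).abs() <= window_bp)
                   & (sub["variant_id"] != v)
                   & sub["ld_usable"]]
        for _, row in near.iterrows():
            maf = min(row["eaf"], 1.0 - row["eaf"])
            if maf < maf_min:
                continue
            try:
                r = self.compute_r(v, row["variant_id"])
            except UndefinedLdError:
                continue
            if r * r >= r2_min:
                out.append((row["variant_id"], r * r, abs(int(row["pos"]) - meta.pos)))
        out.sort(key=lambda t: (-t[1], t[2], t[0]))
        return out


# ---------------------------------------------------------------------------
# Greedy LD clumping
# ---------------------------------------------------------------------------

def clump(assoc: Iterable[tuple], panel: ReferencePanel, p_max: float,
          r2_max: float, window_bp: int) -> list[tuple]:
    """Greedy LD clumping of an association list down to sentinels.

    ``assoc`` is an iterable of ``(variant_id, p)``.  Only variants with
    ``p <= p_max`` and present in the panel enter (absent ones are dropped).
    Candidates are ranked by ascending p (ties: ascending position, then id);
    the top unclaimed variant becomes a sentinel and claims every unclaimed
    variant within ``window_bp`` (each direction) whose r^2 with it is
    ``>= r2_max``.  Returns ``(variant_id, p)`` sentinels in selection order.
    """
    entries = []
    for vid, p in assoc:
        if p > p_max:
            continue
        meta = panel.variant(vid)
        if meta is None:
            continue
        entries.append((p, meta.pos, vid, meta.chrom))
    entries.sort(key=lambda t: (t[0], t[1], t[2]))
    claimed: set[str] = set()
    sentinels = []
    for p, pos, vid, chrom in entries:
        if vid in claimed:
            continue
        sentinels.append((vid, p))
        claimed.add(vid)
        for p2, pos2, vid2, chrom2 in entries:
            if vid2 in claimed or chrom2 != chrom or abs(pos2 - pos) > window_bp:
                continue
            if panel.compute_r(vid, vid2) ** 2 >= r2_max:
                claimed.add(vid2)
    return sentinels


# ---------------------------------------------------------------------------
# Panel I/O
# ---------------------------------------------------------------------------

def read_panel_vcf(path) -> ReferencePanel:
    """Load a diploid-GT VCF as a reference panel (REF = other allele,
    ALT = effect allele, dosage = ALT count)."""
    from cyvcf2 import VCF

    rows, cols = [], []
    vcf = VCF(str(path))
    for rec in vcf:
        if len(rec.ALT) != 1:
            continue
        vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        rows.append({"variant_id": vid, "chrom": str(rec.CHROM), "pos": int(rec.POS),
                     "effect_allele": rec.ALT[0], "other_allele": rec.REF})
        gt = np.asarray(rec.genotype.array(), dtype=float)[:, :2]
        gt[gt < 0] = np.nan
        cols.append(gt.sum(axis=1))
    if not rows:
        raise ValueError("no biallelic records in VCF")
    return ReferencePanel(pd.DataFrame(rows), np.column_stack(cols))


def read_panel_tsv(path) -> ReferencePanel:
    """Plain genotype-matrix TSV: columns variant_id, chrom, pos,
    effect_allele, other_allele, then one column per individual (0/1/2,
    empty = missing); one row per variant."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    meta_cols = ["variant_id", "chrom", "pos", "effect_allele", "other_allele"]
    for col in meta_cols:
        if col not in df.columns:
            raise ValueError(f"missing panel column: {col!r}")
    geno = df.drop(columns=meta_cols).to_numpy(dtype=float).T
    return ReferencePanel(df[meta_cols], geno)


def write_panel_vcf(panel: ReferencePanel, path) -> None:
    """Write the panel as an uncompressed VCF (hard-calls; NaN -> ./.)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        chroms = panel.variants["chrom"].astype(str).unique()
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        samples = [f"ind{i}" for i in range(panel.n_individuals)]
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        order = panel.variants.sort_values(["chrom", "pos"]).index
        gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        for i in order:
            row = panel.variants.iloc[i]
            col = panel.dosages[:, i]
            gts = "\t".join(gt_map.get(g, "./.") if not np.isnan(g) else "./."
                            for g in col)
            fh.write(f"{row['chrom']}\t{int(row['pos'])}\t{row['variant_id']}\t"
                     f"{row['other_allele']}\t{row['effect_allele']}\t.\t.\t.\tGT\t{gts}\n")
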