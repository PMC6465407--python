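"""Reading, validation, harmonization and QC of GWAS and eQTL summary statistics.

GWAS summary statistics follow the GCTA ``.ma`` layout (``SNP A1 A2 freq b se
p N``, whitespace-delimited, optional ``CHR BP`` columns).  eQTL catalogs use a
single canonical TSV that stands in for the heterogeneous source-publication
tables: one row per (dataset, gene, variant) association, with an optional
signed effect.

All positions are 1-based inclusive.  Alleles are uppercase ACGT strings; the
effect allele is the allele whose dosage the effect size refers to.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats as _st

TISSUE_CLASSES = frozenset({"adipose", "breast", "immune", "spleen", "whole-blood"})

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID_BASES = frozenset("ACGT")

GWAS_COLUMNS = ["SNP", "A1", "A2", "freq", "b", "se", "p", "N"]
EQTL_COLUMNS = [
    "dataset_id", "tissue_class", "gene_id", "gene_start", "gene_end",
    "chr", "pos", "variant_id", "effect_allele", "other_allele",
    "beta", "se", "p", "n",
]


class FormatError(ValueError):
    """A mandatory column is missing or the table layout is unusable."""


class EmptyInputError(ValueError):
    """No valid record survived parsing."""


def complement(allele: str) -> str:
    """Reverse-strand complement of an allele string (e.g. ``AC`` -> ``TG``)."""
    return allele.translate(_COMPLEMENT)


def is_palindromic(a1: str, a2: str) -> bool:
    """True for strand-ambiguous pairs (A/T or C/G), where the complement of
    the pair equals the swapped pair and strand cannot be inferred from
    alleles alone."""
    return complement(a1) == a2


def _valid_allele(a) -> bool:
    return isinstance(a, str) and len(a) > 0 and set(a) <= _VALID_BASES


@dataclass(frozen=True)
class SummaryRecord:
    """One variant's marginal association statistics."""

    variant_id: str
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    p: float
    n: float
    chrom: str | None = None
    pos: int | None = None


@dataclass(frozen=True)
class HarmonizationOutcome:
    """Result of reconciling a record's allele coding with a reference pair."""

    status: str  # match | swapped | strand_flipped | strand_flipped_swapped |
    #              palindromic_ambiguous | mismatch
    record: SummaryRecord

    @property
    def usable(self) -> bool:
        return self.status in {
            "match", "swapped", "strand_flipped", "strand_flipped_swapped"
        }


@dataclass
class GwasSummaryStats:
    """A validated GWAS summary-statistics table.

    ``df`` columns: variant_id, chrom, pos, effect_allele, other_allele,
    eaf, beta, se, p, n.  ``chrom``/``pos`` may be missing (NaN) and are
    filled from the reference panel during QC.
    """

    df: pd.DataFrame
    n_rejected: int = 0
    rejection_reasons: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.df)

    def record(self, variant_id: str) -> SummaryRecord:
        row = self.df.loc[self.df["variant_id"] == variant_id]
        if row.empty:
            raise KeyError(variant_id)
        return _row_to_record(row.iloc[0])

    def __contains__(self, variant_id: str) -> bool:
        return bool((self.df["variant_id"] == variant_id).any())


def _row_to_record(row: pd.Series) -> SummaryRecord:
    pos = row.get("pos")
    chrom = row.get("chrom")
    return SummaryRecord(
        variant_id=str(row["variant_id"]),
        effect_allele=str(row["effect_allele"]),
        other_allele=str(row["other_allele"]),
        eaf=float(row["eaf"]),
        beta=float(row["beta"]),
        se=float(row["se"]),
        p=float(row["p"]),
        n=float(row["n"]),
        chrom=None if pd.isna(chrom) else str(chrom),
        pos=None if pd.isna(pos) else int(pos),
    )


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path)


def _validate_gwas_row(row: pd.Series) -> str | None:
    """Return a rejection reason, or None if the row is valid.

    Mutates ``row['p']`` in the caller's frame is avoided: p recomputation is
    handled by the caller using the returned sentinel ``"recompute_p"``.
    """
    a1, a2 = row["effect_allele"], row["other_allele"]
    if not (_valid_allele(a1) and _valid_allele(a2)) or a1 == a2:
        return "alleles"
    for col in ("eaf", "beta", "se", "n"):
        if pd.isna(row[col]):
            return "numeric"
    if not (0.0 < row["eaf"] < 1.0):
        return "eaf"
    if not (row["se"] > 0.0):
        return "se"
    if not (row["n"] > 0.0):
        return "n"
    p = row["p"]
    if pd.isna(p):
        return "recompute_p"
    if not (0.0 < p <= 1.0):
        return "p_range"
    # p and (b/se)^2 must agree on the chi-square scale within 10%.
    chi2 = (row["beta"] / row["se"]) ** 2
    chi2_from_p = _st.chi2.isf(min(float(p), 1.0), 1)
    if chi2 > 1e-12 or chi2_from_p > 1e-12:
        denom = max(chi2, chi2_from_p)
        if denom > 0 and abs(chi2 - chi2_from_p) / denom > 0.10:
            return "p_inconsistent"
    return None


def two_sided_p(beta: float, se: float) -> float:
    """Two-sided normal tail probability of z = beta/se."""
    return float(2.0 * _st.norm.sf(abs(beta / se)))


def read_gwas_sumstats(path, dialect: str = "ma") -> GwasSummaryStats:
    """Read a GCTA ``.ma``-style GWAS summary-statistics file.

    Rows violating the record invariants are counted per reason and dropped
    (never silently).  A missing p is recomputed from b/se.  Raises
    :class:`FormatError` for a missing mandatory column and
    :class:`EmptyInputError` if no valid row remains.
    """
    if dialect != "ma":
        raise FormatError(f"unknown summary-statistics dialect: {dialect!r}")
    with _open_text(path) as fh:
        df = pd.read_csv(fh, sep=r"\s+", comment="#", dtype={"SNP": str})
    for col in GWAS_COLUMNS:
        if col == "p":  # p may be absent entirely: recomputed below
            continue
        if col not in df.columns:
            raise FormatError(f"missing mandatory column: {col!r}")
    if "p" not in df.columns:
        df["p"] = np.nan
    out = pd.DataFrame({
        "variant_id": df["SNP"].astype(str),
        "chrom": df["CHR"].astype(str) if "CHR" in df.columns else pd.NA,
        "pos": pd.to_numeric(df["BP"], errors="coerce") if "BP" in df.columns else np.nan,
        "effect_allele": df["A1"].astype(str).str.upper(),
        "other_allele": df["A2"].astype(str).str.upper(),
        "eaf": pd.to_numeric(df["freq"], errors="coerce"),
        "beta": pd.to_numeric(df["b"], errors="coerce"),
        "se": pd.to_numeric(df["se"], errors="coerce"),
        "p": pd.to_numeric(df["p"], errors="coerce"),
        "n": pd.to_numeric(df["N"], errors="coerce"),
    })
    return _finalize_gwas_frame(out)


def from_frame(df: pd.DataFrame) -> GwasSummaryStats:
    """Build validated :class:`GwasSummaryStats` from an in-memory frame with
    canonical column names (used by the simulators)."""
    return _finalize_gwas_frame(df.copy())


def _finalize_gwas_frame(out: pd.DataFrame) -> GwasSummaryStats:
    reasons: dict[str, int] = {}
    keep = np.ones(len(out), dtype=bool)
    for i, (_, row) in enumerate(out.iterrows()):
        verdict = _validate_gwas_row(row)
        if verdict == "recompute_p":
            out.iat[i, out.columns.get_loc("p")] = two_sided_p(row["beta"], row["se"])
        elif verdict is not None:
            keep[i] = False
            reasons[verdict] = reasons.get(verdict, 0) + 1
    out = out.loc[keep].reset_index(drop=True)
    if len(out) == 0:
        raise EmptyInputError("no valid summary-statistics rows")
    return GwasSummaryStats(out, n_rejected=int((~keep).sum()), rejection_reasons=reasons)


def write_gwas_sumstats(stats: GwasSummaryStats, path, *, config_hash: str | None = None,
                        seed: int | None = None) -> None:
    """Write ``.ma`` layout (plus CHR/BP when present) with a ``#`` provenance
    block."""
    df = stats.df
    out = pd.DataFrame({
        "SNP": df["variant_id"], "A1": df["effect_allele"], "A2": df["other_allele"],
        "freq": df["eaf"], "b": df["beta"], "se": df["se"], "p": df["p"], "N": df["n"],
    })
    if df["pos"].notna().any():
        out.insert(1, "CHR", df["chrom"])
        out.insert(2, "BP", df["pos"].astype("Int64"))
    with open(path, "w") as fh:
        if config_hash is not None:
            fh.write(f"# config_hash={config_hash}\n")
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        out.to_csv(fh, sep="\t", index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# Allele harmonization
# ---------------------------------------------------------------------------

def harmonize_alleles(rec: SummaryRecord, panel_effect: str,
                      panel_other: str) -> HarmonizationOutcome:
    """Reconcile ``rec``'s allele coding with a reference (panel) allele pair.

    Decision table (non-palindromic pairs):

    ==========================  =======================  ====================
    record (A1, A2) vs panel    status                   transformation
    ==========================  =======================  ====================
    (E, O)                      match                    none
    (O, E)                      swapped                  beta -> -beta,
                                                         eaf -> 1 - eaf
    (comp E, comp O)            strand_flipped           alleles complemented
    (comp O, comp E)            strand_flipped_swapped   both of the above
    anything else               mismatch                 none (exclude)
    ==========================  =======================  ====================

    Palindromic pairs (A/T, C/G): ``match`` and ``strand_flipped_swapped``
    (and ``swapped`` / ``strand_flipped``) are indistinguishable without
    strand information, so any palindromic record whose allele set matches the
    panel's is flagged ``palindromic_ambiguous``; otherwise ``mismatch``.
    """
    a1, a2 = rec.effect_allele, rec.other_allele
    pe, po = panel_effect.upper(), panel_other.upper()
    if is_palindromic(a1, a2):
        status = "palindromic_ambiguous" if {a1, a2} == {pe, po} else "mismatch"
        return HarmonizationOutcome(status, rec)
    if (a1, a2) == (pe, po):
        return HarmonizationOutcome("match", rec)
    if (a1, a2) == (po, pe):
        return HarmonizationOutcome("swapped", _swap(rec))
    ca1, ca2 = complement(a1), complement(a2)
    if (ca1, ca2) == (pe, po):
        return HarmonizationOutcome("strand_flipped", _flip(rec))
    if (ca1, ca2) == (po, pe):
        return HarmonizationOutcome("strand_flipped_swapped", _swap(_flip(rec)))
    return HarmonizationOutcome("mismatch", rec)


def _swap(rec: SummaryRecord) -> SummaryRecord:
    return replace(rec, effect_allele=rec.other_allele, other_allele=rec.effect_allele,
                   beta=-rec.beta, eaf=1.0 - rec.eaf)


def _flip(rec: SummaryRecord) -> SummaryRecord:
    return replace(rec, effect_allele=complement(rec.effect_allele),
                   other_allele=complement(rec.other_allele))


# ---------------------------------------------------------------------------
# QC filtering against a reference panel
# ---------------------------------------------------------------------------

QC_REASONS = ["sample_size", "maf", "panel", "allele_match", "freq_diff"]


def qc_filter_gwas(stats: GwasSummaryStats, panel, min_n: float = 150_000,
                   min_maf: float = 0.01, max_freq_diff: float = 0.2):
    """Apply the GWAS exclusion rules against a reference panel.

    Rules, in order (a record is tallied under the first rule it fails):
    (i) n < min_n; (ii) MAF < min_maf; (iii) absent from, or monomorphic in,
    the panel; (iv) alleles that do not harmonize (mismatch or palindromic);
    (v) |GWAS EAF - panel EAF| > max_freq_diff after harmonization.

    Survivors are returned harmonized to the panel's allele coding, with
    chrom/pos filled from the panel.  Returns ``(filtered_stats, tally)``
    where ``tally`` maps each reason to its exclusion count.
    """
    tally = {r: 0 for r in QC_REASONS}
    kept_rows = []
    for _, row in stats.df.iterrows():
        rec = _row_to_record(row)
        if rec.n < min_n:
            tally["sample_size"] += 1
            continue
        if min(rec.eaf, 1.0 - rec.eaf) < min_maf:
            tally["maf"] += 1
            continue
        meta = panel.variant(rec.variant_id)
        if meta is None or not panel.is_polymorphic(rec.variant_id):
            tally["panel"] += 1
            continue
        out = harmonize_alleles(rec, meta.effect_allele, meta.other_allele)
        if not out.usable:
            tally["allele_match"] += 1
            continue
        h = out.record
        if abs(h.eaf - meta.eaf) > max_freq_diff:
            tally["freq_diff"] += 1
            continue
        kept_rows.append({
            "variant_id": h.variant_id, "chrom": meta.chrom, "pos": meta.pos,
            "effect_allele": h.effect_allele, "other_allele": h.other_allele,
            "eaf": h.eaf, "beta": h.beta, "se": h.se, "p": h.p, "n": h.n,
        })
    df = pd.DataFrame(kept_rows, columns=list(stats.df.columns))
    return GwasSummaryStats(df), tally


# ---------------------------------------------------------------------------
# eQTL catalogs
# ---------------------------------------------------------------------------

@dataclass
class EqtlCatalog:
    """Per-dataset cis-eQTL association records (one canonical TSV layout).

    ``df`` columns are :data:`EQTL_COLUMNS` plus ``beta_present``; records
    from source tables that do not publish signed effects keep NaN beta and
    ``beta_present=False`` (direction analysis reports them as unknown).
    """

    df: pd.DataFrame
    n_rejected: int = 0
    rejection_reasons: dict = field(default_factory=dict)

    @property
    def dataset_ids(self) -> list[str]:
        return sorted(self.df["dataset_id"].unique())

    def dataset(self, dataset_id: str) -> pd.DataFrame:
        return self.df.loc[self.df["dataset_id"] == dataset_id]

    def lookup(self, dataset_id: str, gene_id: str, variant_id: str) -> pd.Series | None:
        m = self.df[(self.df["dataset_id"] == dataset_id)
                    & (self.df["gene_id"] == gene_id)
                    & (self.df["variant_id"] == variant_id)]
        return None if m.empty else m.iloc[0]

    def __len__(self) -> int:
        return len(self.df)


def read_eqtl_catalog(path) -> EqtlCatalog:
    """Read the canonical eQTL-catalog TSV.

    Layout: ``dataset_id tissue_class gene_id gene_start gene_end chr pos
    variant_id effect_allele other_allele beta se p n`` (``beta``/``se`` may
    be empty).  Rows failing the invariants (tissue class outside the closed
    set, invalid alleles, gene_start > gene_end, p outside (0,1]) are counted
    per reason and dropped.
    """
    with _open_text(path) as fh:
        df = pd.read_csv(fh, sep="\t", comment="#", dtype={"chr": str})
    for col in EQTL_COLUMNS:
        if col in ("beta", "se"):
            if col not in df.columns:
                df[col] = np.nan
            continue
        if col not in df.columns:
            raise FormatError(f"missing mandatory column: {col!r}")
    return catalog_from_frame(df)


def catalog_from_frame(df: pd.DataFrame) -> EqtlCatalog:
    df = df.copy()
    df["effect_allele"] = df["effect_allele"].astype(str).str.upper()
    df["other_allele"] = df["other_allele"].astype(str).str.upper()
    reasons: dict[str, int] = {}
    keep = np.ones(len(df), dtype=bool)
    for i, (_, row) in enumerate(df.iterrows()):
        if row["tissue_class"] not in TISSUE_CLASSES:
            keep[i] = False
            reasons["tissue_class"] = reasons.get("tissue_class", 0) + 1
        elif not (_valid_allele(row["effect_allele"])
                  and _valid_allele(row["other_allele"])
                  and row["effect_allele"] != row["other_allele"]):
            keep[i] = False
            reasons["alleles"] = reasons.get("alleles", 0) + 1
        elif row["gene_start"] > row["gene_end"]:
            keep[i] = False
            reasons["gene_bounds"] = reasons.get("gene_bounds", 0) + 1
        elif not (0.0 < row["p"] <= 1.0):
            keep[i] = False
            reasons["p_range"] = reasons.get("p_range", 0) + 1
    out = df.loc[keep].reset_index(drop=True)
    if len(out) == 0:
        raise EmptyInputError("no valid eQTL rows")
    out["beta_present"] = out["beta"].notna()
    out["gene_start"] = out["gene_start"].astype(int)
    out["gene_end"] = out["gene_end"].astype(int)
    out["pos"] = out["pos"].astype(int)
    return EqtlCatalog(out, n_rejected=int((~keep).sum()), rejection_reasons=reasons)


def write_eqtl_catalog(catalog: EqtlCatalog, path, *, config_hash: str | None = None,
                       seed: int | None = None) -> None:
    with open(path, "w") as fh:
        if config_hash is not None:
            fh.write(f"# config_hash={config_hash}\n")
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        catalog.df[EQTL_COLUMNS].to_csv(fh, sep="\t", index=False, float_format="%.12g")
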