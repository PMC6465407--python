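"""Approximate joint and conditional analysis of GWAS summary statistics.

Reconstructs multiple-regression estimates from per-variant marginal
statistics plus reference-panel LD, enabling (i) stepwise selection of
independently associated variants and (ii) genome-wide conditional
adjustment on the selected set — the summary-data analogue of fitting all
selected variants jointly in the original sample.

Reconstruction, for variant j with effect-allele frequency f_j, marginal
effect b_j, standard error se_j and sample size n_j:

    w_j  = 2 f_j (1 - f_j)                 (HWE dosage variance)
    d_j  = w_j n_j                         (diagonal of X'X)
    h_j  = d_j b_j                         (X'y)
    B_jk = r_jk sqrt(w_j w_k) min(n_j,n_k) (off-diagonal X'X), B_jj = d_j
    yty  = median_j [ d_j b_j^2 + d_j se_j^2 (n_j - 1) ]

Joint estimates on a set S: b_J = B_SS^{-1} h_S with residual variance
sigma2_J = (yty - b_J'h_S) / (n_min - |S|), floored at a small positive
constant.  The cross-term sample size min(n_j, n_k) and the min-n residual
df are deliberately conservative under per-variant n heterogeneity
(meta-analysis input).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _st

from .ld import LD_RIDGE, ReferencePanel
from .sumstats import GwasSummaryStats

SIGMA2_FLOOR = 1e-12
DEFAULT_COLLINEARITY_R2 = 0.9


class CollinearityError(np.linalg.LinAlgError):
    """The selected set's LD matrix is singular beyond the ridge tolerance."""


def _chi2_sf(chi2: np.ndarray | float) -> np.ndarray | float:
    return _st.chi2.sf(chi2, df=1)


@dataclass
class CojoWorkspace:
    """Cached per-variant reconstruction terms for one (stats, panel) pair."""

    ids: list
    b: np.ndarray
    se: np.ndarray
    p: np.ndarray
    n: np.ndarray
    f: np.ndarray
    pos: np.ndarray
    chrom: np.ndarray
    w: np.ndarray
    d: np.ndarray
    h: np.ndarray
    yty: float
    panel: ReferencePanel
    _idx: dict = field(default_factory=dict)

    @classmethod
    def build(cls, stats: GwasSummaryStats, panel: ReferencePanel) -> "CojoWorkspace":
        df = stats.df
        ids = list(df["variant_id"])
        b = df["beta"].to_numpy(float)
        se = df["se"].to_numpy(float)
        n = df["n"].to_numpy(float)
        f = df["eaf"].to_numpy(float)
        w = 2.0 * f * (1.0 - f)
        d = w * n
        yty = float(np.median(d * b**2 + d * se**2 * (n - 1.0)))
        ws = cls(ids=ids, b=b, se=se, p=df["p"].to_numpy(float), n=n, f=f,
                 pos=df["pos"].to_numpy(float), chrom=df["chrom"].to_numpy(object),
                 w=w, d=d, h=d * b, yty=yty, panel=panel)
        ws._idx = {v: i for i, v in enumerate(ids)}
        return ws

    def _r_matrix(self, S: list[str]) -> np.ndarray:
        return self.panel.ld_matrix(S).r

    def _B(self, S: list[str]) -> np.ndarray:
        """Reconstructed X'X over S (ridge applied on the correlation scale)."""
        j = np.array([self._idx[v] for v in S])
        r = self._r_matrix(S)
        r[np.diag_indices_from(r)] += LD_RIDGE
        sw = np.sqrt(self.w[j])
        nmin = np.minimum.outer(self.n[j], self.n[j])
        B = r * np.outer(sw, sw) * nmin
        # diagonal: d_j (ridge retained via r diagonal)
        return B

    def _r_to_set(self, t_ids: list[str], S: list[str]) -> np.ndarray:
        """len(t_ids) x len(S) matrix of panel correlations."""
        out = np.empty((len(t_ids), len(S)))
        for a, t in enumerate(t_ids):
            for c, s in enumerate(S):
                out[a, c] = self.panel.compute_r(t, s) if t != s else 1.0
        return out


@dataclass
class JointFit:
    ids: list
    b_joint: np.ndarray
    se_joint: np.ndarray
    p_joint: np.ndarray
    sigma2: float


@dataclass
class CojoSelection:
    """Outcome of stepwise joint selection."""

    selected: list
    fit: JointFit | None
    log: pd.DataFrame  # columns: step, action, variant_id, p

    @property
    def variant_ids(self) -> list:
        return list(self.selected)


def joint_fit(stats_or_ws, panel: ReferencePanel | None = None,
              S: list[str] | None = None) -> JointFit:
    """Joint effect estimates for the variant set ``S`` from marginal
    statistics plus panel LD.  Raises :class:`CollinearityError` (naming the
    worst pair) if B_SS is singular beyond the ridge."""
    ws = stats_or_ws if isinstance(stats_or_ws, CojoWorkspace) \
        else CojoWorkspace.build(stats_or_ws, panel)
    if not S:
        raise ValueError("joint_fit requires a non-empty variant set")
    S = list(S)
    j = np.array([ws._idx[v] for v in S])
    r = ws._r_matrix(S)
    off = r - np.eye(len(S))
    if np.abs(off).max(initial=0.0) > 1.0 - 1e-6:
        raise _collinearity_error(ws, S)
    B = ws._B(S)
    h = ws.h[j]
    try:
        np.linalg.cholesky(B)
    except np.linalg.LinAlgError:
        raise _collinearity_error(ws, S) from None
    b_joint = np.linalg.solve(B, h)
    Binv = np.linalg.inv(B)
    n_min = float(np.min(ws.n[j]))
    dof = max(n_min - len(S), 1.0)
    sigma2 = max((ws.yty - float(b_joint @ h)) / dof, SIGMA2_FLOOR)
    se_joint = np.sqrt(sigma2 * np.diag(Binv))
    chi2 = (b_joint / se_joint) ** 2
    return JointFit(S, b_joint, se_joint, _chi2_sf(chi2), sigma2)


def _collinearity_error(ws: CojoWorkspace, S: list[str]) -> CollinearityError:
    worst, wr = None, -1.0
    r = ws._r_matrix(S)
    for a in range(len(S)):
        for b in range(a + 1, len(S)):
            if abs(r[a, b]) > wr:
                wr, worst = abs(r[a, b]), (S[a], S[b])
    return CollinearityError(
        f"collinear selected set; worst pair {worst} with |r|={wr:.6f}")


def conditional_stats(stats_or_ws, panel: ReferencePanel | None = None,
                      S: list[str] = (),
                      collinearity_r2: float = DEFAULT_COLLINEARITY_R2) -> pd.DataFrame:
    """Per-variant statistics conditional on the selected set ``S``.

    For t not in S:  b_cond = (d_t b_t - B_tS b_J) / d_t,
    se_cond = sqrt(sigma2_J / d_t), p from the 1-df chi-square tail.
    Variants with r^2 above ``collinearity_r2`` to any member of S are
    flagged ``collinear`` and inherit p = 1.  With empty S the marginal
    statistics are returned unchanged.
    """
    ws = stats_or_ws if isinstance(stats_or_ws, CojoWorkspace) \
        else CojoWorkspace.build(stats_or_ws, panel)
    S = list(S)
    m = len(ws.ids)
    out = pd.DataFrame({
        "variant_id": ws.ids,
        "b_cond": ws.b.copy(), "se_cond": ws.se.copy(), "p_cond": ws.p.copy(),
        "selected": [v in set(S) for v in ws.ids],
        "collinear": False,
    })
    if not S:
        out["chi2_cond"] = (out["b_cond"] / out["se_cond"]) ** 2
        return out
    fit = joint_fit(ws, S=S)
    others = [v for v in ws.ids if v not in set(S)]
    if others:
        R = ws._r_to_set(others, S)
        jo = np.array([ws._idx[v] for v in others])
        js = np.array([ws._idx[v] for v in S])
        nmin = np.minimum.outer(ws.n[jo], ws.n[js])
        BtS = R * np.outer(np.sqrt(ws.w[jo]), np.sqrt(ws.w[js])) * nmin
        b_cond = (ws.d[jo] * ws.b[jo] - BtS @ fit.b_joint) / ws.d[jo]
        se_cond = np.sqrt(fit.sigma2 / ws.d[jo])
        collinear = (R ** 2).max(axis=1) > collinearity_r2
        rows = out["variant_id"].isin(others)
        order = np.array([others.index(v) for v in out.loc[rows, "variant_id"]])
        out.loc[rows, "b_cond"] = b_cond[order]
        out.loc[rows, "se_cond"] = se_cond[order]
        p = _chi2_sf((b_cond / se_cond) ** 2)
        p = np.where(collinear, 1.0, p)
        out.loc[rows, "p_cond"] = p[order]
        out.loc[rows, "collinear"] = collinear[order]
    sel_rows = out["variant_id"].isin(S)
    sidx = np.array([S.index(v) for v in out.loc[sel_rows, "variant_id"]])
    out.loc[sel_rows, "b_cond"] = fit.b_joint[sidx]
    out.loc[sel_rows, "se_cond"] = fit.se_joint[sidx]
    out.loc[sel_rows, "p_cond"] = fit.p_joint[sidx]
    out["chi2_cond"] = np.where(out["collinear"], 0.0,
                                (out["b_cond"] / out["se_cond"]) ** 2)
    return out


def cojo_select(stats: GwasSummaryStats, panel: ReferencePanel,
                p_cutoff: float = 5e-8,
                collinearity_r2: float = DEFAULT_COLLINEARITY_R2) -> CojoSelection:
    """Stepwise selection of independently associated variants.

    Seed with the smallest-p variant (ties: position, then id) if its p is at
    or below ``p_cutoff``; then iterate: compute conditional p for every
    unselected candidate given the current set (candidates with r^2 above the
    collinearity cap to any selected variant are excluded), add the smallest
    conditional-p candidate if it qualifies, refit jointly, and drop any
    selected variant whose joint p has risen above the cutoff (most
    non-significant first).  Deterministic given inputs.
    """
    ws = CojoWorkspace.build(stats, panel)
    order_key = {v: (ws.p[i], ws.pos[i] if np.isfinite(ws.pos[i]) else 0, v)
                 for i, v in enumerate(ws.ids)}
    log_rows = []
    S: list[str] = []
    candidates = sorted(ws.ids, key=lambda v: order_key[v])
    if not candidates or ws.p[ws._idx[candidates[0]]] > p_cutoff:
        return CojoSelection([], None, pd.DataFrame(
            columns=["step", "action", "variant_id", "p"]))
    S.append(candidates[0])
    log_rows.append({"step": 0, "action": "add", "variant_id": S[0],
                     "p": float(ws.p[ws._idx[S[0]]])})
    step = 0
    while True:
        step += 1
        cond = conditional_stats(ws, S=S, collinearity_r2=collinearity_r2)
        cand = cond[(~cond["selected"]) & (~cond["collinear"])]
        if len(cand) == 0:
            break
        # smallest conditional p; ties by position then id
        cand = cand.assign(
            _pos=[ws.pos[ws._idx[v]] for v in cand["variant_id"]]
        ).sort_values(["p_cond", "_pos", "variant_id"])
        best = cand.iloc[0]
        if best["p_cond"] > p_cutoff:
            break
        S.append(best["variant_id"])
        log_rows.append({"step": step, "action": "add",
                         "variant_id": best["variant_id"],
                         "p": float(best["p_cond"])})
        # backward pass: remove joint-non-significant members
        while len(S) > 1:
            fit = joint_fit(ws, S=S)
            worst = int(np.argmax(fit.p_joint))
            if fit.p_joint[worst] <= p_cutoff:
                break
            removed = S.pop(worst)
            log_rows.append({"step": step, "action": "remove",
                             "variant_id": removed,
                             "p": float(fit.p_joint[worst])})
    fit = joint_fit(ws, S=S) if S else None
    # report in positional order for stability of outputs
    return CojoSelection(S, fit, pd.DataFrame(log_rows))


def selection_table(sel: CojoSelection) -> pd.DataFrame:
    """Joint estimates of the selected set as a tidy frame."""
    if sel.fit is None:
        return pd.DataFrame(columns=["variant_id", "b_joint", "se_joint", "p_joint"])
    return pd.DataFrame({
        "variant_id": sel.fit.ids,
        "b_joint": sel.fit.b_joint,
        "se_joint": sel.fit.se_joint,
        "p_joint": sel.fit.p_joint,
    })
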