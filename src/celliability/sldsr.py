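"""Stratified LD-score regression (heritability partitioning).

Per-SNP, per-annotation LD scores are sums of bias-corrected squared
correlations with annotation SNPs within a genetic-map window (1 cM by
default). GWAS chi-squares are then regressed on N x LD score per
annotation (joint fit with an intercept); per-annotation coefficients
(tau) get standard errors from a delete-one block jackknife over
contiguous SNP blocks, and one-tailed p-values test tau > 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse, stats

from .synthetic import ReferencePanel

BASE_ANNOTATION = "base"


def genes_to_annotation(
    gene_set: set[str],
    genes: pd.DataFrame,
    window: int = 100_000,
    snps: pd.DataFrame | None = None,
) -> np.ndarray:
    """Binary SNP annotation: 1 if within ``window`` bp of any set gene.

    Gene bodies are extended by ``window`` on both sides regardless of
    strand (the convention for heritability annotations). ``snps`` must
    carry CHR and BP columns.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    if snps is None:
        raise ValueError("snps table is required")
    out = np.zeros(len(snps), dtype=float)
    sub = genes[genes["gene_id"].isin(gene_set)]
    if sub.empty:
        import warnings

        warnings.warn("empty gene set produced an all-zero annotation")
        return out
    chrom_arr = snps["CHR"].astype(str).to_numpy()
    bp = snps["BP"].to_numpy()
    for chrom, grp in sub.groupby("chrom"):
        sel = chrom_arr == str(chrom)
        if not sel.any():
            continue
        pos = bp[sel]
        hit = np.zeros(pos.size, dtype=bool)
        for s, e in zip(grp["start"].to_numpy(), grp["end"].to_numpy()):
            hit |= (pos >= max(1, s - window)) & (pos <= e + window)
        out[np.flatnonzero(sel)[hit]] = 1.0
    return out


def ld_score_weights(panel: ReferencePanel, window_cm: float = 1.0) -> sparse.csr_matrix:
    """Banded matrix W of bias-corrected r-hat^2 within the cM window.

    W[j, k] = r^2_jk - (1 - r^2_jk) / (n - 2) for SNP pairs on the same
    chromosome within ``window_cm`` centimorgans (including the
    diagonal, where it is exactly 1); LD scores for any annotation a are
    then W @ a. Built once per panel and reused.
    """
    n = panel.n_individuals
    if n <= 2:
        raise ValueError("need more than 2 panel individuals")
    if window_cm <= 0:
        raise ValueError("window_cm must be positive")
    snps = panel.snps.reset_index(drop=True)
    x = panel.dosages.astype(float)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    z = (x - x.mean(axis=0)) / sd
    rows, cols, vals = [], [], []
    for chrom in snps["CHR"].unique():
        idx = np.flatnonzero(snps["CHR"].to_numpy() == chrom)
        cm = snps["CM"].to_numpy()[idx]
        order = np.argsort(cm, kind="stable")
        idx = idx[order]
        cm = cm[order]
        lo = np.searchsorted(cm, cm - window_cm, side="left")
        hi = np.searchsorted(cm, cm + window_cm, side="right")
        # chunked correlation against the union of neighbor windows
        chunk = 512
        for c0 in range(0, idx.size, chunk):
            c1 = min(c0 + chunk, idx.size)
            j0 = int(lo[c0:c1].min())
            j1 = int(hi[c0:c1].max())
            r = z[:, idx[c0:c1]].T @ z[:, idx[j0:j1]] / n
            r2 = r * r
            w = r2 - (1.0 - r2) / (n - 2)
            for jj in range(c0, c1):
                a, b = lo[jj] - j0, hi[jj] - j0
                rows.extend([idx[jj]] * (b - a))
                cols.extend(idx[j0 + a : j0 + b])
                vals.extend(w[jj - c0, a:b])
    m = len(snps)
    W = sparse.csr_matrix((vals, (rows, cols)), shape=(m, m))
    return W


def compute_ld_scores(
    panel: ReferencePanel,
    annot: pd.DataFrame,
    window_cm: float = 1.0,
    weights: sparse.csr_matrix | None = None,
) -> pd.DataFrame:
    """Per-SNP LD scores for each annotation column.

    ``annot`` has one column per annotation aligned to the panel SNP
    order (a base column of all ones is conventional). Returns SNP, CHR,
    BP plus one LD-score column per annotation.
    """
    if weights is None:
        weights = ld_score_weights(panel, window_cm)
    out = panel.snps[["SNP", "CHR", "BP"]].reset_index(drop=True).copy()
    for name in annot.columns:
        out[name] = weights @ annot[name].to_numpy(dtype=float)
    return out


@dataclass
class SldsrResult:
    """Joint-fit coefficients with block-jackknife inference."""

    annotations: list[str]
    tau: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray  # one-tailed, tau > 0
    intercept: float
    n_blocks: int

    def for_annotation(self, name: str) -> dict[str, float]:
        i = self.annotations.index(name)
        return {
            "tau": float(self.tau[i]),
            "se": float(self.se[i]),
            "z": float(self.z[i]),
            "p": float(self.p[i]),
        }


def sldsr_fit(
    sumstats: pd.DataFrame,
    ldscores: pd.DataFrame,
    n_blocks: int = 200,
    annotations: list[str] | None = None,
) -> SldsrResult:
    """Weighted regression of GWAS chi-square on N x LD scores.

    A first, unweighted pass on the base annotation estimates tau_base;
    second-pass weights are 1 / (l_base * 2 (1 + N tau_base l_base)^2),
    down-weighting high-LD SNPs (heteroskedasticity + double counting).
    Standard errors come from a delete-one jackknife over ``n_blocks``
    contiguous SNP blocks; p-values are one-tailed normal on tau / se.
    """
    merged = sumstats.merge(ldscores, on="SNP", suffixes=("", "_ld"))
    if annotations is None:
        annotations = [
            c for c in ldscores.columns if c not in ("SNP", "CHR", "BP")
        ]
    if BASE_ANNOTATION not in annotations:
        raise ValueError("LD scores must include the base annotation")
    m = len(merged)
    if n_blocks < 2:
        raise ValueError("n_blocks must be >= 2")
    if m < n_blocks:
        raise ValueError("fewer SNPs than jackknife blocks")

    chi2 = stats.chi2.isf(np.clip(merged["P"].to_numpy(dtype=float), 1e-300, 1.0), df=1)
    N = merged["N"].to_numpy(dtype=float)
    L = merged[annotations].to_numpy(dtype=float)
    X = np.column_stack([np.ones(m), N[:, None] * L])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("annotation design is rank deficient (duplicated annotation?)")

    l_base = merged[BASE_ANNOTATION].to_numpy(dtype=float)
    base_col = 1 + annotations.index(BASE_ANNOTATION)
    # pass 1: unweighted base-only fit for the weight model
    Xb = X[:, [0, base_col]]
    coef_b, *_ = np.linalg.lstsq(Xb, chi2, rcond=None)
    tau_base = max(float(coef_b[1]), 0.0)
    lb = np.maximum(l_base, 1.0)
    w = 1.0 / (lb * 2.0 * (1.0 + N * tau_base * lb) ** 2)

    sw = np.sqrt(w)
    Xw = X * sw[:, None]
    yw = chi2 * sw
    xtx = Xw.T @ Xw
    xty = Xw.T @ yw
    coef = np.linalg.solve(xtx, xty)

    # delete-one block jackknife on the weighted normal equations
    bounds = np.linspace(0, m, n_blocks + 1).astype(int)
    coefs = np.empty((n_blocks, X.shape[1]))
    for b in range(n_blocks):
        s, e = bounds[b], bounds[b + 1]
        xtx_b = Xw[s:e].T @ Xw[s:e]
        xty_b = Xw[s:e].T @ yw[s:e]
        coefs[b] = np.linalg.solve(xtx - xtx_b, xty - xty_b)
    mean_del = coefs.mean(axis=0)
    var = (n_blocks - 1) / n_blocks * ((coefs - mean_del) ** 2).sum(axis=0)
    se = np.sqrt(var)

    tau = coef[1:]
    tau_se = np.maximum(se[1:], 1e-300)
    z = tau / tau_se
    p = stats.norm.sf(z)
    return SldsrResult(
        annotations=list(annotations),
        tau=tau,
        se=tau_se,
        z=z,
        p=np.clip(p, 1e-300, 1.0),
        intercept=float(coef[0]),
        n_blocks=n_blocks,
    )
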