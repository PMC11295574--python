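"""Gene-level association scores from GWAS summary statistics.

Implements the SNP-wise mean model: a gene's statistic is the mean of
the chi-square statistics of the SNPs in its (extended) window, and its
p-value comes from the null distribution of that mean under the LD
(correlation) structure of those SNPs — a weighted sum of independent
1-df chi-squares with weights equal to the eigenvalues of the SNP
correlation matrix. The tail probability is computed by Imhof-type
numeric inversion of the characteristic function, with a two-moment
(Satterthwaite) approximation available as a fast fallback.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import ReferencePanel

log = logging.getLogger(__name__)

_P_FLOOR = 1e-300


def extend_gene_windows(
    genes: pd.DataFrame, upstream: int = 35_000, downstream: int = 10_000,
    strand_aware: bool = True,
) -> pd.DataFrame:
    """Extend gene bodies upstream/downstream (default 35 kb / 10 kb).

    Upstream is relative to the transcription start site, so on the minus
    strand the roles of the two flanks swap. Starts are floored at 1.
    """
    if upstream < 0 or downstream < 0:
        raise ValueError("window extensions must be >= 0")
    out = genes[["gene_id", "chrom", "start", "end"]].copy()
    if strand_aware and "strand" in genes.columns:
        minus = (genes["strand"] == "-").to_numpy()
    else:
        minus = np.zeros(len(genes), dtype=bool)
    up = np.where(minus, downstream, upstream)
    down = np.where(minus, upstream, downstream)
    out["start"] = np.maximum(1, genes["start"].to_numpy() - up)
    out["end"] = genes["end"].to_numpy() + down
    return out


def assign_snps(sumstats: pd.DataFrame, windows: pd.DataFrame) -> dict[str, np.ndarray]:
    """Map each gene window to the indices of the SNPs it contains.

    Windows are closed intervals; a SNP can belong to several genes.
    Genes containing no SNPs are dropped (their count is logged).
    """
    result: dict[str, np.ndarray] = {}
    empty = 0
    for chrom, grp in windows.groupby("chrom"):
        sel = np.flatnonzero(sumstats["CHR"].to_numpy() == chrom)
        if sel.size == 0:
            empty += len(grp)
            continue
        bp = sumstats["BP"].to_numpy()[sel]
        order = np.argsort(bp)
        bp_sorted = bp[order]
        for gid, s, e in zip(grp["gene_id"], grp["start"], grp["end"]):
            lo = np.searchsorted(bp_sorted, s, side="left")
            hi = np.searchsorted(bp_sorted, e, side="right")
            if hi > lo:
                result[gid] = sel[order[lo:hi]]
            else:
                empty += 1
    if empty:
        log.info("assign_snps: %d gene windows contained no SNPs", empty)
    return result


def ld_correlation(panel: ReferencePanel, snp_indices: np.ndarray) -> np.ndarray:
    """Pearson correlation of panel dosages for the given SNP columns.

    Monomorphic SNPs get an identity row/column (with a warning); the
    matrix is symmetrized.
    """
    snp_indices = np.asarray(snp_indices)
    if snp_indices.size == 0:
        raise ValueError("need at least one SNP")
    x = panel.dosages[:, snp_indices].astype(float)
    sd = x.std(axis=0)
    mono = sd == 0
    if mono.any():
        warnings.warn(f"{int(mono.sum())} monomorphic SNPs set to identity rows")
        sd = np.where(mono, 1.0, sd)
    z = (x - x.mean(axis=0)) / sd
    r = z.T @ z / x.shape[0]
    r[mono, :] = 0.0
    r[:, mono] = 0.0
    np.fill_diagonal(r, 1.0)
    return (r + r.T) / 2.0


_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(24)


def quadform_sf(x: float, eigenvalues: np.ndarray, tol: float = 1e-12) -> float:
    """Upper tail P(sum_j lam_j * chi2_1 > x) for non-negative weights.

    Equal weights reduce to a scaled chi-square (closed form). Otherwise
    Imhof's characteristic-function inversion is integrated lobe by
    lobe: the zeros of sin(theta(u)) are bracketed analytically, each
    lobe is integrated by Gauss–Legendre quadrature, and the resulting
    alternating series is accelerated by repeated Euler averaging to
    absolute tolerance ``tol``.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    lam = lam[lam > 1e-10]
    if lam.size == 0:
        return 1.0
    if x <= 0:
        return 1.0
    if np.allclose(lam, lam[0], rtol=1e-12, atol=0.0):
        return float(stats.chi2.sf(x / lam[0], df=lam.size))

    from scipy.optimize import brentq

    m = lam.size

    def theta(u: float) -> float:
        return 0.5 * float(np.sum(np.arctan(lam * u))) - 0.5 * x * u

    def integrand(u):
        u = np.atleast_1d(u)
        th = 0.5 * np.sum(np.arctan(np.outer(u, lam)), axis=1) - 0.5 * x * u
        rho = np.exp(0.25 * np.sum(np.log1p(np.outer(u, lam) ** 2), axis=1))
        return np.sin(th) / (u * rho)

    def lobe(a: float, b: float) -> float:
        mid, half = 0.5 * (a + b), 0.5 * (b - a)
        return float(half * (_GL_WEIGHTS @ integrand(mid + half * _GL_NODES)))

    # theta(0) = 0; theta is unimodal (theta' decreases monotonically)
    # and eventually falls at rate x/2, bounded by m*pi/4 - x*u/2. Lobe
    # boundaries are the roots of theta = k*pi: ascending levels on the
    # rising branch (when sum(lam) > x pushes theta positive), then
    # every level down on the decreasing branch.
    boundaries = [1e-300]
    start_k = -1
    if lam.sum() > x:  # rising phase exists; find the peak of theta
        hi = 1.0 / lam.min()
        while 0.5 * float(np.sum(lam / (1.0 + (lam * hi) ** 2))) > 0.5 * x:
            hi *= 2.0
        u_star = brentq(
            lambda u: float(np.sum(lam / (1.0 + (lam * u) ** 2))) - x, 1e-300, hi,
            xtol=1e-15,
        )
        k_top = int(np.floor(theta(u_star) / np.pi))
        prev = 1e-300
        for k in range(1, k_top + 1):  # ascending roots of theta = k*pi
            r = brentq(lambda u, kk=k: theta(u) - kk * np.pi, prev, u_star, xtol=1e-15)
            boundaries.append(r)
            prev = r
        start_k = k_top

    def theta_prime(u: float) -> float:
        return 0.5 * float(np.sum(lam / (1.0 + (lam * u) ** 2))) - 0.5 * x

    def descending_root(level: float, guess: float, lo: float) -> float:
        # Newton from the previous root (+ one period), bisection fallback
        u = guess
        for _ in range(60):
            f = theta(u) - level
            if abs(f) < 1e-13 * (1.0 + abs(level)):
                return u
            d = theta_prime(u)
            step = f / d
            nxt = u - step
            if nxt <= lo:  # safeguard: keep to the right of the last root
                nxt = 0.5 * (u + lo)
            u = nxt
        hi = (m * np.pi / 4 - level + np.pi) * 2.0 / x
        while theta(hi) > level:
            hi *= 2.0
        return brentq(lambda v: theta(v) - level, lo + 1e-300, hi, xtol=1e-14)

    head: list[float] = [lobe(a, b) for a, b in zip(boundaries[:-1], boundaries[1:])]
    tail: list[float] = []
    prev = boundaries[-1]
    period = 2.0 * np.pi / x
    # the alternating tail is Euler-accelerated, so a few hundred lobes
    # suffice even when the envelope decays slowly (small m)
    max_lobes = 300
    for k in range(start_k, start_k - max_lobes, -1):
        r = descending_root(k * np.pi, prev + period, prev)
        term = lobe(prev, r)
        if k == start_k:
            head.append(term)  # peak lobe; alternation starts after it
        else:
            tail.append(term)
            if abs(term) < tol:
                break
        prev = r
    total = sum(head) + _euler_sum(tail)
    p = 0.5 + total / np.pi
    return float(min(max(p, _P_FLOOR), 1.0))


def _euler_sum(terms: list[float]) -> float:
    """Sum an alternating series by repeated averaging of partial sums."""
    if not terms:
        return 0.0
    s = np.cumsum(terms)
    while s.size > 1:
        s = 0.5 * (s[1:] + s[:-1])
    return float(s[0])


def quadform_sf_satterthwaite(x: float, eigenvalues: np.ndarray) -> float:
    """Two-moment scaled-chi-square approximation of the quadratic-form tail."""
    lam = np.asarray(eigenvalues, dtype=float)
    lam = lam[lam > 1e-10]
    if lam.size == 0 or x <= 0:
        return 1.0
    s1, s2 = lam.sum(), (lam**2).sum()
    scale = s2 / s1
    df = s1 * s1 / s2
    return float(stats.chi2.sf(x / scale, df=df))


def gene_score(
    snp_p: np.ndarray, R: np.ndarray, N: int | None = None, method: str = "imhof"
) -> tuple[float, float, float]:
    """SNP-wise mean statistic for one gene: (statistic, p, z).

    Each SNP p is converted to a 1-df chi-square; the statistic is their
    mean. The null of m * statistic is sum_j lam_j chi2_1 with lam_j the
    eigenvalues of the SNP correlation matrix (floored at 0 after
    symmetrization). z is the upper-tail probit of the gene p.
    """
    p = np.asarray(snp_p, dtype=float)
    m = p.size
    if R.shape != (m, m):
        raise ValueError("R must be m x m for m SNPs")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("SNP p-values must lie in (0, 1]")
    q = stats.chi2.isf(p, df=1)
    t_stat = float(q.mean())
    if m == 1:
        gene_p = float(p[0])
    else:
        lam = np.linalg.eigvalsh((R + R.T) / 2.0)
        if lam.min() < -1e-6:
            raise ValueError("correlation matrix not positive semidefinite")
        lam = np.clip(lam, 0.0, None)
        if method == "imhof":
            gene_p = quadform_sf(m * t_stat, lam)
        elif method == "satterthwaite":
            gene_p = quadform_sf_satterthwaite(m * t_stat, lam)
        else:
            raise ValueError(f"unknown method {method!r}")
    gene_p = float(min(max(gene_p, _P_FLOOR), 1.0))
    z = float(stats.norm.isf(gene_p))
    return t_stat, gene_p, z


def gene_score_table(
    sumstats: pd.DataFrame,
    panel: ReferencePanel,
    genes: pd.DataFrame,
    upstream: int = 35_000,
    downstream: int = 10_000,
    method: str = "imhof",
) -> pd.DataFrame:
    """Per-gene association table under the SNP-wise mean model.

    SNPs absent from the panel are dropped (logged). Columns include the
    mean chi-square statistic, gene p and z, SNP count and the log window
    length / log SNP count covariates used by competitive enrichment.
    """
    shared = sumstats["SNP"].isin(panel.snps["SNP"])
    if not shared.all():
        log.info("gene_score_table: dropping %d SNPs absent from panel", int((~shared).sum()))
    ss = sumstats.loc[shared].reset_index(drop=True)
    pos_in_panel = panel.snps.reset_index(drop=True).set_index("SNP").index
    panel_idx = pd.Series(np.arange(len(pos_in_panel)), index=pos_in_panel)

    windows = extend_gene_windows(genes, upstream, downstream)
    mapping = assign_snps(ss, windows)
    win = windows.set_index("gene_id")

    rows = []
    for gid, idx in mapping.items():
        sub = ss.iloc[idx]
        p_idx = panel_idx[sub["SNP"]].to_numpy()
        R = ld_correlation(panel, p_idx)
        n_val = int(sub["N"].iloc[0]) if "N" in sub else None
        t_stat, gene_p, z = gene_score(sub["P"].to_numpy(), R, n_val, method=method)
        length = int(win.loc[gid, "end"] - win.loc[gid, "start"] + 1)
        rows.append((gid, len(idx), t_stat, gene_p, z, length))
    out = pd.DataFrame(
        rows, columns=["gene_id", "n_snps", "stat", "p", "z", "window_length"]
    )
    out["log_length"] = np.log(out["window_length"])
    out["log_nsnps"] = np.log(out["n_snps"])
    return out
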