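"""Rare protein-truncating-variant burden testing.

Pipeline: sample QC (kinship, ancestry, coverage) -> genotype QC
(depth, quality, allele balance) -> variant QC (VQSR, call rate,
Hardy–Weinberg, low complexity) -> singleton PTV definition -> Firth
penalized-likelihood logistic burden test of cases vs controls with
technical covariates. The stage flags on the variant bundle enforce
this order.

Thresholds follow the printed QC rules: genotype DP >= 10, GQ >= 30,
hom allele balance <= 0.1 / >= 0.9, het allele balance in [0.25, 0.75]
(closed); variants dropped for call rate < 0.9, HWE exact p < 1e-8
(both strict), VQSR failure or low-complexity regions; samples dropped
for kinship > 0.177 (one member per pair), flagged ancestry, or mean
depth < 20.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .synthetic import PTV_CLASSES, VariantTable

MISSING = -1


def sample_qc(
    samples: pd.DataFrame,
    kinship: pd.DataFrame,
    min_depth: float = 20.0,
    kinship_threshold: float = 0.177,
) -> pd.DataFrame:
    """Remove related, ancestry-flagged and low-coverage samples.

    For each pair with kinship strictly above the threshold one member
    is removed, greedily dropping the member involved in more pairs
    first (ties broken by removing the larger sample id), so an A-B,
    B-C chain loses only B. Kinship exactly at the threshold keeps both.
    """
    pairs = kinship[kinship["kinship"] > kinship_threshold]
    degree: dict[str, int] = {}
    edges = []
    for a, b in zip(pairs["id1"], pairs["id2"]):
        edges.append((a, b))
        degree[a] = degree.get(a, 0) + 1
        degree[b] = degree.get(b, 0) + 1
    removed: set[str] = set()
    live = [e for e in edges]
    while live:
        worst = max(degree, key=lambda s: (degree[s], s))
        if degree[worst] == 0:
            break
        removed.add(worst)
        nxt = []
        for a, b in live:
            if worst in (a, b):
                degree[a] -= 1
                degree[b] -= 1
            else:
                nxt.append((a, b))
        live = nxt
    out = samples[~samples["sample_id"].isin(removed)]
    out = out[out["ancestry_ok"].astype(bool)]
    out = out[out["mean_depth"] >= min_depth]
    return out.reset_index(drop=True)


def genotype_qc(
    vt: VariantTable,
    min_dp: int = 10,
    min_gq: int = 30,
    hom_ref_ab: float = 0.1,
    hom_alt_ab: float = 0.9,
    het_ab: tuple[float, float] = (0.25, 0.75),
) -> VariantTable:
    """Set genotypes failing depth/quality/allele-balance rules to missing.

    All boundaries are inclusive as printed (a het with allele balance
    exactly 0.25 passes). Idempotent.
    """
    out = vt.copy()
    gt = out.GT
    ok = (out.DP >= min_dp) & (out.GQ >= min_gq)
    ok &= ~((gt == 0) & (out.AB > hom_ref_ab))
    ok &= ~((gt == 2) & (out.AB < hom_alt_ab))
    ok &= ~((gt == 1) & ((out.AB < het_ab[0]) | (out.AB > het_ab[1])))
    out.GT = np.where((gt != MISSING) & ~ok, MISSING, gt).astype(np.int8)
    out.genotype_qc_done = True
    return out


def hwe_exact(n_homref: int, n_het: int, n_homalt: int) -> float:
    """Exact Hardy–Weinberg test p-value for one biallelic variant.

    Conditional on the allele counts, heterozygote counts of the same
    parity are enumerated by the standard recurrence on the conditional
    distribution; the p-value sums the probabilities of all
    configurations no more probable than the observed one.
    """
    n_homref, n_het, n_homalt = int(n_homref), int(n_het), int(n_homalt)
    if min(n_homref, n_het, n_homalt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_homref + n_het + n_homalt
    if n == 0:
        raise ValueError("need at least one genotype")
    rare = min(2 * n_homref + n_het, 2 * n_homalt + n_het)
    if rare == 0:
        return 1.0
    het_max = min(rare, 2 * n - rare)
    het_min = rare % 2
    hets = np.arange(het_min, het_max + 1, 2)
    probs = np.empty(hets.size)
    # start from the largest het count and recurse downwards
    probs[-1] = 1.0
    for i in range(hets.size - 1, 0, -1):
        het = hets[i]
        hom_r = (rare - het) // 2
        hom_c = n - het - hom_r
        # P(het-2) / P(het) = het (het-1) / (4 (hom_r+1)(hom_c+1))
        probs[i - 1] = probs[i] * het * (het - 1) / (4.0 * (hom_r + 1) * (hom_c + 1))
    probs /= probs.sum()
    obs = int(np.searchsorted(hets, n_het))
    if obs >= hets.size or hets[obs] != n_het:
        raise ValueError("heterozygote count inconsistent with allele counts")
    p = probs[probs <= probs[obs] * (1.0 + 1e-12)].sum()
    return float(min(p, 1.0))


def variant_qc(
    vt: VariantTable,
    min_call_rate: float = 0.9,
    hwe_alpha: float = 1e-8,
) -> VariantTable:
    """Drop VQSR-fail, low-call-rate, HWE-violating and low-complexity variants.

    Call rate is the fraction of non-missing genotypes after genotype
    QC (which must have been applied). Variants at exactly the call-rate
    or HWE boundary are kept (the exclusions are strict inequalities).
    """
    if not vt.genotype_qc_done:
        raise ValueError("genotype_qc must be applied before variant_qc")
    gt = vt.GT
    call_rate = (gt != MISSING).mean(axis=1)
    keep = vt.variants["vqsr_pass"].to_numpy(dtype=bool)
    keep &= ~vt.variants["low_complexity"].to_numpy(dtype=bool)
    keep &= call_rate >= min_call_rate
    hwe_p = np.ones(gt.shape[0])
    for i in np.flatnonzero(keep):
        hwe_p[i] = hwe_exact(
            int((gt[i] == 0).sum()), int((gt[i] == 1).sum()), int((gt[i] == 2).sum())
        )
    keep &= hwe_p >= hwe_alpha
    idx = np.flatnonzero(keep)
    out = VariantTable(
        variants=vt.variants.iloc[idx].reset_index(drop=True),
        GT=vt.GT[idx],
        DP=vt.DP[idx],
        GQ=vt.GQ[idx],
        AB=vt.AB[idx],
        samples=vt.samples.copy(),
        kinship=vt.kinship.copy(),
        genotype_qc_done=True,
        variant_qc_done=True,
    )
    return out


def define_ptv_singletons(vt: VariantTable) -> set[str]:
    """Qualifying variants: singleton PTVs absent from the external reference.

    A PTV is stop-gain, frameshift or splice donor/acceptor; a singleton
    has exactly one heterozygous carrier and no homozygous-alternative
    carrier among all retained samples.
    """
    if not vt.variant_qc_done:
        raise ValueError("variant_qc must be applied before PTV definition")
    is_ptv = vt.variants["consequence"].isin(PTV_CLASSES).to_numpy()
    het = (vt.GT == 1).sum(axis=1)
    hom = (vt.GT == 2).sum(axis=1)
    ext = vt.variants["in_external_ref"].to_numpy(dtype=bool)
    qual = is_ptv & (het == 1) & (hom == 0) & ~ext
    return set(vt.variants.loc[qual, "variant_id"])


@dataclass
class FirthResult:
    beta: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray  # two-sided Wald
    converged: bool
    n_iter: int
    loglik: float


def firth_logistic(
    y: np.ndarray,
    X: np.ndarray,
    penalty: float = 0.5,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> FirthResult:
    """Penalized-likelihood logistic regression (Jeffreys-prior penalty).

    Maximizes loglik + penalty * log det I(beta) by modified-score
    Newton iterations with step halving; penalty 0.5 is Firth's
    correction (finite estimates under separation), penalty 0 the
    ordinary MLE. Convergence when every modified-score component is
    below ``tol`` in absolute value.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    if y.size != n:
        raise ValueError("y and X have incompatible shapes")
    if not ((y == 0) | (y == 1)).all():
        raise ValueError("y must be binary")
    if y.sum() == 0 or y.sum() == n:
        raise ValueError("need at least one case and one control")
    if np.linalg.matrix_rank(X) < k:
        raise ValueError("design matrix is rank deficient")

    def penalized_loglik(beta: np.ndarray) -> float:
        eta = X @ beta
        ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
        if penalty > 0:
            p = expit(eta)
            w = p * (1 - p)
            sign, logdet = np.linalg.slogdet(X.T @ (X * w[:, None]))
            ll += penalty * logdet
        return ll

    beta = np.zeros(k)
    trace = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        p = expit(X @ beta)
        w = p * (1 - p)
        info = X.T @ (X * w[:, None])
        try:
            info_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError as exc:
            raise ValueError("Fisher information singular during iteration") from exc
        if penalty > 0:
            h = w * np.einsum("ij,jk,ik->i", X, info_inv, X)
            score = X.T @ (y - p + 2.0 * penalty * h * (0.5 - p))
        else:
            score = X.T @ (y - p)
        trace.append(float(np.abs(score).max()))
        if trace[-1] < tol:
            converged = True
            break
        step = info_inv @ score
        ll0 = penalized_loglik(beta)
        scale = 1.0
        for _ in range(12):
            cand = beta + scale * step
            if penalized_loglik(cand) >= ll0 - 1e-10:
                break
            scale /= 2.0
        beta = beta + scale * step
    if not converged:
        raise RuntimeError(
            f"Firth iterations did not converge in {max_iter} steps; "
            f"max-score trace tail: {trace[-5:]}"
        )
    p = expit(X @ beta)
    w = p * (1 - p)
    cov = np.linalg.inv(X.T @ (X * w[:, None]))
    se = np.sqrt(np.diag(cov))
    z = beta / se
    return FirthResult(
        beta=beta, se=se, z=z, p=2.0 * stats.norm.sf(np.abs(z)),
        converged=True, n_iter=it, loglik=penalized_loglik(beta),
    )


@dataclass
class BurdenResult:
    set_name: str
    odds_ratio: float
    p: float  # one-tailed, excess burden in cases
    coefficient: float
    se: float
    n_cases: int
    n_controls: int


COVARIATE_COLUMNS = [f"PC{i}" for i in range(1, 11)] + ["synonymous_count", "platform", "sex"]


def qualifying_counts(
    vt: VariantTable, qualifying: set[str], gene_set: set[str] | None = None
) -> np.ndarray:
    """Per-sample count of qualifying variants (optionally within a gene set)."""
    sel = vt.variants["variant_id"].isin(qualifying).to_numpy()
    if gene_set is not None:
        sel &= vt.variants["gene_id"].isin(gene_set).to_numpy()
    return (vt.GT[sel] == 1).sum(axis=0).astype(float)


def burden_test(
    samples: pd.DataFrame,
    vt: VariantTable,
    qualifying: set[str],
    gene_set: set[str],
    background_covariate: str = "none",
    expressed_genes: set[str] | None = None,
    set_name: str = "set",
) -> BurdenResult:
    """Firth burden test of case status on per-sample PTV counts.

    Counts qualifying singleton PTVs per sample within ``gene_set`` and
    regresses case status on that count plus the first 10 PCs,
    exome-wide synonymous burden, platform and sex. With
    ``background_covariate='all_expressed'`` the count over
    ``expressed_genes`` is added, so set tests are relative to the
    tissue-wide background burden. The p-value is the one-tailed
    (upper) Wald tail of the count coefficient.
    """
    if not qualifying:
        raise ValueError("no qualifying variants")
    keep = vt.samples["sample_id"].isin(samples["sample_id"]).to_numpy()
    sub = VariantTable(
        variants=vt.variants, GT=vt.GT[:, keep], DP=vt.DP[:, keep],
        GQ=vt.GQ[:, keep], AB=vt.AB[:, keep],
        samples=vt.samples.loc[keep].reset_index(drop=True),
        kinship=vt.kinship, genotype_qc_done=vt.genotype_qc_done,
        variant_qc_done=vt.variant_qc_done,
    )
    smp = samples.set_index("sample_id").loc[sub.samples["sample_id"]].reset_index()
    count = qualifying_counts(sub, qualifying, gene_set)
    if count.sum() == 0:
        raise ValueError("zero total burden in the tested gene set")
    y = smp["status"].to_numpy(dtype=float)
    cols = [np.ones(len(y)), count]
    names = ["intercept", "burden"]
    if background_covariate == "all_expressed":
        if expressed_genes is None:
            raise ValueError("background_covariate='all_expressed' needs expressed_genes")
        cols.append(qualifying_counts(sub, qualifying, expressed_genes))
        names.append("background_burden")
    elif background_covariate != "none":
        raise ValueError(f"unknown background_covariate {background_covariate!r}")
    for c in COVARIATE_COLUMNS:
        cols.append(smp[c].to_numpy(dtype=float))
        names.append(c)
    X = np.column_stack(cols)
    fit = firth_logistic(y, X)
    b, se = float(fit.beta[1]), float(fit.se[1])
    p_one = float(stats.norm.sf(b / se))
    return BurdenResult(
        set_name=set_name,
        odds_ratio=float(np.exp(b)),
        p=p_one,
        coefficient=b,
        se=se,
        n_cases=int(y.sum()),
        n_controls=int(len(y) - y.sum()),
    )
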