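"""Competitive gene-set enrichment and GO over-representation.

Competitive enrichment regresses per-gene association z-scores on set
membership plus technical covariates (log window length and log SNP
count by default); a positive membership coefficient means the set
carries more association signal than the rest of the genome. All
enrichment p-values are one-tailed in the "set mean greater" direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DEFAULT_COVARIATES = ("log_length", "log_nsnps")


@dataclass
class EnrichmentResult:
    set_name: str
    beta: float
    se: float
    p: float  # one-tailed, beta > 0
    n_set: int
    n_background: int
    degenerate: bool = False
    untestable: bool = False


def competitive_enrichment(
    scores: pd.DataFrame,
    gene_set: set[str],
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    set_name: str = "set",
) -> EnrichmentResult:
    """One-tailed competitive enrichment of a gene set.

    OLS of gene z on a membership indicator plus covariates and an
    intercept; p is the upper t tail of the membership coefficient. A
    degenerate fit (constant z) returns beta 0, p 0.5 with a flag.
    """
    member = scores["gene_id"].isin(gene_set).to_numpy(dtype=float)
    n_set = int(member.sum())
    n_bg = len(member) - n_set
    if n_set < 2 or n_bg < 2:
        raise ValueError("need >= 2 set genes and >= 2 background genes in the score table")
    y = scores["z"].to_numpy(dtype=float)
    X = np.column_stack(
        [np.ones(len(y)), member] + [scores[c].to_numpy(dtype=float) for c in covariates]
    )
    if np.ptp(y) == 0:
        return EnrichmentResult(set_name, 0.0, 0.0, 0.5, n_set, n_bg, degenerate=True)
    beta, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    dof = len(y) - rank
    resid = y - X @ beta
    sigma2 = float(resid @ resid) / dof
    if sigma2 <= 0:
        return EnrichmentResult(set_name, float(beta[1]), 0.0, 0.5, n_set, n_bg, degenerate=True)
    xtx_inv = np.linalg.pinv(X.T @ X)
    se = float(np.sqrt(sigma2 * xtx_inv[1, 1]))
    t = beta[1] / se
    p = float(stats.t.sf(t, dof))
    return EnrichmentResult(set_name, float(beta[1]), se, p, n_set, n_bg)


@dataclass
class OraResult:
    term: str
    overlap: int
    expected: float
    fold: float
    p: float
    p_adj: float = np.nan


def go_overrepresentation(
    gene_set: set[str],
    annotation: dict[str, set[str]],
    background: set[str],
) -> list[OraResult]:
    """One-sided hypergeometric over-representation of each term.

    ``annotation`` maps term id -> gene ids; terms and the query set are
    intersected with the background before testing; BH adjustment is
    applied across the tested terms.
    """
    gene_set = set(gene_set)
    background = set(background)
    if not gene_set <= background:
        raise ValueError("gene set must be a subset of the background")
    M = len(background)
    n_set = len(gene_set)
    results = []
    for term, term_genes in annotation.items():
        tg = set(term_genes) & background
        if not tg:
            continue
        k = len(gene_set & tg)
        expected = n_set * len(tg) / M
        fold = (k / expected) if expected > 0 else 0.0
        p = 1.0 if k == 0 else float(stats.hypergeom.sf(k - 1, M, len(tg), n_set))
        results.append(OraResult(term, k, expected, fold, p))
    if results:
        _, adj, _, _ = multipletests([r.p for r in results], method="fdr_bh")
        for r, a in zip(results, adj):
            r.p_adj = float(max(a, r.p))
    return results


def intersect_and_test(
    decile_set: set[str],
    annotation: dict[str, set[str]],
    top_k: int,
    scores: pd.DataFrame,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
) -> tuple[list[EnrichmentResult], float]:
    """Enrichment of decile ∩ term for the top_k most over-represented terms.

    Terms are ranked by over-representation of the decile set against
    all scored genes; each intersection is then tested competitively.
    Intersections with < 2 genes are flagged untestable. Returns the
    results and the Bonferroni threshold 0.05 / top_k.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    background = set(scores["gene_id"])
    ora = go_overrepresentation(decile_set & background, annotation, background)
    ora.sort(key=lambda r: (r.p, r.term))
    top_terms = [r.term for r in ora[:top_k]]
    results = []
    for term in top_terms:
        inter = decile_set & set(annotation[term]) & background
        if len(inter) < 2 or len(background - inter) < 2:
            results.append(
                EnrichmentResult(term, np.nan, np.nan, np.nan, len(inter),
                                 len(background) - len(inter), untestable=True)
            )
            continue
        res = competitive_enrichment(scores, inter, covariates, set_name=term)
        results.append(res)
    return results, 0.05 / top_k


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Per-test threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests
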