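"""Expression-specificity scoring of single-nucleus count data.

A gene's specificity for a cell type is its mean expression in that type
divided by the sum of its mean expression over all types, so each
retained gene's scores form a probability vector over cell types. Before
scoring, tiny clusters, non-autosomal genes, genes overlapping the
extended MHC region (chr6:25–35 Mb, hg19 — excluded for its extensive
LD) and uninformative genes are removed.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

AUTOSOMES = {str(i) for i in range(1, 23)}
NON_AUTOSOMES = {"X", "Y", "MT", "M"}
MHC_INTERVAL = ("6", 25_000_000, 35_000_000)


def _norm_chrom(label: str) -> str:
    s = str(label)
    return s[3:] if s.lower().startswith("chr") else s


def filter_clusters(ann: pd.DataFrame, min_cells: int = 10) -> pd.DataFrame:
    """Drop clusters with fewer than ``min_cells`` cells.

    Clusters that small cannot give representative mean-expression
    estimates. A cluster of exactly ``min_cells`` is kept.
    """
    if min_cells < 1:
        raise ValueError("min_cells must be >= 1")
    sizes = ann["cluster"].value_counts()
    keep = sizes.index[sizes >= min_cells]
    out = ann[ann["cluster"].isin(keep)].reset_index(drop=True)
    if out.empty:
        raise ValueError("no clusters survive the size filter")
    return out


def filter_genes(
    counts: pd.DataFrame,
    genes: pd.DataFrame,
    ann: pd.DataFrame,
    mhc: tuple[str, int, int] = MHC_INTERVAL,
    min_cells_expressing: int = 10,
    alpha_uninformative: float = 0.05,
) -> pd.DataFrame:
    """Remove non-autosomal, MHC-overlapping and uninformative genes.

    A gene overlapping the closed MHC interval by any base is removed.
    "Uninformative" means expressed in fewer than ``min_cells_expressing``
    cells, or no significant expression variation across cell types
    (one-way ANOVA on log-CP10K values, Benjamini–Hochberg adjusted
    p > ``alpha_uninformative``).
    """
    counts = counts.loc[:, ann["cell_id"]]
    gmap = genes.set_index("gene_id")
    missing = counts.index.difference(gmap.index)
    if len(missing):
        raise ValueError(f"gene models missing for: {missing[0]}")
    info = gmap.loc[counts.index]

    chroms = info["chrom"].map(_norm_chrom)
    unknown = ~chroms.isin(AUTOSOMES | NON_AUTOSOMES)
    if unknown.any():
        bad = counts.index[unknown][0]
        raise ValueError(f"unknown chromosome label for gene {bad}")
    keep = chroms.isin(AUTOSOMES).to_numpy()

    mhc_chrom, mhc_s, mhc_e = _norm_chrom(mhc[0]), mhc[1], mhc[2]
    overlap = (
        (chroms == mhc_chrom)
        & (info["start"].to_numpy() <= mhc_e)
        & (info["end"].to_numpy() >= mhc_s)
    )
    keep &= ~overlap.to_numpy()

    expressed_cells = (counts.to_numpy() > 0).sum(axis=1)
    keep &= expressed_cells >= min_cells_expressing

    sub = counts.loc[counts.index[keep]]
    if sub.empty:
        raise ValueError("no genes survive filtering")

    # cross-type variance screen on normalized values
    norm = normalize(sub, method="log_cp10k")
    labels = ann.set_index("cell_id").loc[norm.columns, "cluster"].to_numpy()
    pvals = _anova_pvalues(norm.to_numpy(), labels)
    reject, _, _, _ = multipletests(pvals, alpha=alpha_uninformative, method="fdr_bh")
    return sub.loc[sub.index[reject]]


def _anova_pvalues(x: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Vectorized one-way ANOVA p-value per row of ``x`` across label groups.

    Rows with zero between-group variance (including constant rows) get
    p = 1 so they are dropped as uninformative.
    """
    groups = pd.unique(labels)
    k = len(groups)
    n = x.shape[1]
    grand = x.mean(axis=1)
    ssb = np.zeros(x.shape[0])
    ssw = np.zeros(x.shape[0])
    for g in groups:
        sel = labels == g
        m = x[:, sel].mean(axis=1)
        ssb += sel.sum() * (m - grand) ** 2
        ssw += ((x[:, sel] - m[:, None]) ** 2).sum(axis=1)
    dfb, dfw = k - 1, n - k
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / dfb) / (ssw / dfw)
    p = stats.f.sf(f, dfb, dfw)
    # rows that are constant up to float jitter carry no information
    scale = n * (x * x).mean(axis=1)
    negligible = ssb <= 1e-12 * np.maximum(scale, 1e-300)
    p[~np.isfinite(f)] = np.where(negligible[~np.isfinite(f)], 1.0, 0.0)
    p[negligible] = 1.0
    return p


def normalize(counts: pd.DataFrame, method: str = "log_cp10k", theta: float = 100.0) -> pd.DataFrame:
    """Normalize a genes x cells count matrix.

    ``log_cp10k``: ln(1 + 1e4 * count / cell_total) — invariant to
    scaling all counts of a cell. ``pearson_residual``: (count - mu) /
    sqrt(mu + mu^2/theta) with mu = gene proportion x cell total and a
    fixed inverse-dispersion ``theta``, clipped at +/- sqrt(n_cells); a
    deterministic, dependency-light stand-in for a regularized NB fit
    that preserves the mean-ratio structure specificity needs.
    """
    x = counts.to_numpy(dtype=float)
    totals = x.sum(axis=0)
    if (totals == 0).any():
        bad = counts.columns[np.flatnonzero(totals == 0)[0]]
        raise ValueError(f"cell {bad} has zero total count")
    if method == "log_cp10k":
        out = np.log1p(1e4 * x / totals)
    elif method == "pearson_residual":
        gene_prop = x.sum(axis=1) / x.sum()
        mu = np.outer(gene_prop, totals)
        with np.errstate(invalid="ignore", divide="ignore"):
            res = (x - mu) / np.sqrt(mu + mu * mu / theta)
        res[~np.isfinite(res)] = 0.0
        clip = math.sqrt(x.shape[1])
        out = np.clip(res, -clip, clip)
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    return pd.DataFrame(out, index=counts.index, columns=counts.columns)


def specificity_matrix(normalized: pd.DataFrame, ann: pd.DataFrame) -> pd.DataFrame:
    """Per-gene, per-cell-type specificity: mean in type / sum of means.

    Rows sum to 1; genes with zero mean in every type are dropped.
    """
    labels = ann.set_index("cell_id").loc[normalized.columns, "cluster"]
    types = pd.unique(labels)
    if len(types) < 2:
        raise ValueError("specificity requires at least 2 cell types")
    means = pd.DataFrame(
        {t: normalized.loc[:, labels.index[labels == t]].mean(axis=1) for t in types}
    )
    total = means.sum(axis=1)
    keep = total > 0
    spec = means.loc[keep].div(total[keep], axis=0)
    return spec


def top_fraction_set(
    spec: pd.DataFrame,
    cell_type: str,
    fraction_or_n: float | int = 0.1,
    biotype_filter: str = "all",
    genes: pd.DataFrame | None = None,
    allow_short: bool = False,
) -> set[str]:
    """Genes in the top specificity decile (or top N) for one cell type.

    Ranks descending by specificity with ties broken by ascending gene
    id; a fraction f returns ceil(f * n_retained) genes. ``biotype_filter``
    ("protein_coding" / "noncoding") subsets before ranking and needs the
    gene-model table.
    """
    if cell_type not in spec.columns:
        raise KeyError(f"unknown cell type {cell_type!r}")
    col = spec[cell_type]
    if biotype_filter != "all":
        if genes is None:
            raise ValueError("biotype_filter requires the gene-model table")
        biot = genes.set_index("gene_id")["biotype"]
        if biotype_filter == "protein_coding":
            wanted = biot[biot == "protein_coding"].index
        elif biotype_filter == "noncoding":
            wanted = biot[biot != "protein_coding"].index
        else:
            raise ValueError(f"unknown biotype_filter {biotype_filter!r}")
        col = col[col.index.intersection(wanted)]
    n = len(col)
    if isinstance(fraction_or_n, float):
        f = fraction_or_n
        if not 0 < f <= 1:
            raise ValueError("fraction must lie in (0, 1]")
        k = math.ceil(f * n)
    else:
        k = int(fraction_or_n)
        if k <= 0:
            raise ValueError("top-N must be positive")
        if k > n:
            if not allow_short:
                raise ValueError(f"requested top {k} of only {n} genes")
            k = n
    order = sorted(col.items(), key=lambda kv: (-kv[1], kv[0]))
    return {g for g, _ in order[:k]}


def jaccard(a: set[str], b: set[str]) -> float:
    """Jaccard index |a ∩ b| / |a ∪ b|; 0 when both sets are empty."""
    union = set(a) | set(b)
    if not union:
        return 0.0
    return len(set(a) & set(b)) / len(union)
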