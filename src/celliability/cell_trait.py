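"""Per-cell trait-association scores along a developmental trajectory.

Each cell gets a trait-association score: the t-statistic of its own
expression in a regression of per-gene GWAS z-scores on that cell's
normalized expression, adjusting for each gene's dataset-average
expression. Scores are then regressed on pseudotime to ask whether
genetic liability rises along the trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .specificity import normalize


@dataclass
class TrajectoryResult:
    beta: float  # standardized
    p: float
    n_cells: int
    flagged: bool = False


def cell_score(
    cell_expr: np.ndarray,
    gene_stat: np.ndarray,
    avg_expr: np.ndarray,
) -> tuple[float, bool]:
    """Trait-association score of one cell: (t-statistic, degenerate flag).

    OLS of gene_stat on [1, cell_expr, avg_expr] across genes; the score
    is the t-statistic of the cell_expr coefficient. Constant or
    collinear cell expression yields score 0 with the flag set.
    """
    y = np.asarray(gene_stat, dtype=float)
    x1 = np.asarray(cell_expr, dtype=float)
    x2 = np.asarray(avg_expr, dtype=float)
    if y.size < 30:
        raise ValueError("need at least 30 genes for a cell score")
    X = np.column_stack([np.ones_like(y), x1, x2])
    rank = np.linalg.matrix_rank(X)
    if rank < 3 or np.ptp(x1) == 0:
        return 0.0, True
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = y.size - 3
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.pinv(X.T @ X)
    se = np.sqrt(cov[1, 1])
    if se == 0:
        return 0.0, True
    return float(beta[1] / se), False


def score_cells(
    expr: pd.DataFrame,
    gene_scores: pd.DataFrame,
    ann: pd.DataFrame | None = None,
    stat_column: str = "z",
) -> pd.DataFrame:
    """Trait-association score for every cell of a normalized matrix.

    ``expr`` is genes x cells (normalized); gene statistics are matched
    on gene_id (``stat_column`` selects z or another transform).
    Returns cell_id, score, flag, plus pseudotime/donor columns from
    ``ann`` when provided.
    """
    gs = gene_scores.set_index("gene_id")[stat_column]
    shared = expr.index.intersection(gs.index)
    if len(shared) < 30:
        raise ValueError("fewer than 30 genes shared between expression and gene scores")
    sub = expr.loc[shared]
    y = gs[shared].to_numpy(dtype=float)
    avg = sub.mean(axis=1).to_numpy()
    rows = []
    for cell in sub.columns:
        score, flag = cell_score(sub[cell].to_numpy(), y, avg)
        rows.append((cell, score, flag))
    out = pd.DataFrame(rows, columns=["cell_id", "score", "flagged"])
    if ann is not None:
        out = out.merge(ann, on="cell_id", how="left")
    return out


def filter_trajectory_genes(
    counts: pd.DataFrame, min_cells: int = 10
) -> pd.DataFrame:
    """Drop genes expressed in fewer than ``min_cells`` cells, then log-normalize.

    A gene with nonzero counts in exactly ``min_cells`` cells is kept.
    Returns the log-CP10K-normalized matrix.
    """
    if min_cells < 1:
        raise ValueError("min_cells must be >= 1")
    n_expressing = (counts.to_numpy() > 0).sum(axis=1)
    kept = counts.loc[counts.index[n_expressing >= min_cells]]
    return normalize(kept, method="log_cp10k")


def trajectory_test(scores: pd.DataFrame) -> TrajectoryResult:
    """Regress z-scored cell score on z-scored pseudotime.

    With both variables standardized and a single predictor the
    coefficient is the Pearson correlation (|beta| <= 1); p is the
    two-sided t-test of that slope.
    """
    df = scores.dropna(subset=["score", "pseudotime"])
    n = len(df)
    if n < 10:
        raise ValueError("need at least 10 cells with pseudotime")
    t = df["pseudotime"].to_numpy(dtype=float)
    s = df["score"].to_numpy(dtype=float)
    if np.ptp(t) == 0:
        raise ValueError("pseudotime is constant")
    if np.ptp(s) == 0:
        return TrajectoryResult(0.0, 1.0, n, flagged=True)
    tz = (t - t.mean()) / t.std()
    sz = (s - s.mean()) / s.std()
    res = stats.linregress(tz, sz)
    return TrajectoryResult(float(res.slope), float(res.pvalue), n)


def leave_one_donor_out(scores: pd.DataFrame) -> pd.DataFrame:
    """Trajectory test excluding each donor's cells in turn.

    A donor owning all cells gets a flagged row; a donor owning none
    reproduces the full-data result.
    """
    donors = pd.unique(scores["donor"].dropna())
    if len(donors) < 2:
        raise ValueError("need at least 2 donors")
    rows = []
    for d in donors:
        sub = scores[scores["donor"] != d]
        if len(sub) < 10 or sub["pseudotime"].nunique() <= 1:
            rows.append((d, np.nan, np.nan, len(sub), True))
            continue
        res = trajectory_test(sub)
        rows.append((d, res.beta, res.p, res.n_cells, res.flagged))
    return pd.DataFrame(
        rows, columns=["excluded_donor", "beta", "p", "n_cells", "flagged"]
    )


def simple_pseudotime(expr: pd.DataFrame, root_cells: list[str]) -> pd.Series:
    """Stand-in pseudotime: first principal component of the cells.

    The PC is oriented so the root cells sit at the low end, then
    min-max scaled to [0, 1]. ``expr`` should be a normalized genes x
    cells matrix. Duplicate cells map to equal pseudotime.
    """
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 cells")
    x = expr.to_numpy(dtype=float).T  # cells x genes
    x = x - x.mean(axis=0)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    if s.size == 0 or s[0] <= 1e-12:
        raise ValueError("expression matrix has rank 0")
    pc1 = u[:, 0] * s[0]
    pt = pd.Series(pc1, index=expr.columns)
    roots = [c for c in root_cells if c in pt.index]
    if roots and pt[roots].mean() > pt.mean():
        pt = -pt
    lo, hi = pt.min(), pt.max()
    if hi > lo:
        pt = (pt - lo) / (hi - lo)
    else:
        pt[:] = 0.0
    pt.name = "pseudotime"
    return pt
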