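"""End-to-end orchestration: cell-type scan and report.

``run_celltype_scan`` chains the stages — cluster/gene filtering,
normalization, specificity scoring, gene-level GWAS scores, competitive
enrichment and stratified LD-score regression per cell type — and flags
cell types whose top-specificity-decile gene set passes the Bonferroni
threshold in BOTH tests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import enrichment, gene_assoc, sldsr, specificity
from .synthetic import ReferencePanel

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Thresholds and stage parameters of a pipeline run.

    Defaults are the study's printed settings: min cluster size 10, top
    specificity decile, top-2000 robustness size, 35 kb/10 kb gene-score
    windows, 100 kb heritability windows, 1 cM LD scores, 200 jackknife
    blocks, HWE alpha 1e-8 and call-rate threshold 0.9.
    """

    seed: int = 0
    min_cells: int = 10
    fraction: float = 0.1
    top_n: int = 2000
    magma_up: int = 35_000
    magma_down: int = 10_000
    sldsr_window: int = 100_000
    window_cm: float = 1.0
    n_blocks: int = 200
    hwe_alpha: float = 1e-8
    call_rate: float = 0.9
    biotype_filter: str = "all"
    n_baseline: int = 3
    inputs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("min_cells", "top_n", "magma_up", "magma_down",
                     "sldsr_window", "n_blocks"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("fraction", "window_cm", "hwe_alpha", "call_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**d)

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def baseline_annotations(n_snps: int, n_baseline: int, seed: int) -> pd.DataFrame:
    """Base (all-ones) column plus random binary baseline annotations.

    A small generated stand-in for the 53-annotation baseline model,
    preserving the joint-fit structure without bundled reference data.
    """
    rng = np.random.default_rng(seed)
    annot = {"base": np.ones(n_snps)}
    for i in range(n_baseline):
        annot[f"baseline{i}"] = (rng.random(n_snps) < 0.3).astype(float)
    return pd.DataFrame(annot)


def run_celltype_scan(
    counts: pd.DataFrame,
    ann: pd.DataFrame,
    genes: pd.DataFrame,
    sumstats: pd.DataFrame,
    panel: ReferencePanel,
    config: RunConfig | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Per-cell-type enrichment scan with dual-Bonferroni significance flags.

    Returns a table (cell_type, n_set, magma_p, sldsr_p, significance
    flags) and a bundle of intermediate results for reporting.
    """
    cfg = config or RunConfig()
    ann_f = specificity.filter_clusters(ann, cfg.min_cells)
    log.info("scan: %d of %d clusters retained", ann_f["cluster"].nunique(), ann["cluster"].nunique())
    counts_f = specificity.filter_genes(counts, genes, ann_f)
    log.info("scan: %d of %d genes retained", counts_f.shape[0], counts.shape[0])
    norm = specificity.normalize(counts_f, method="log_cp10k")
    spec = specificity.specificity_matrix(norm, ann_f)

    scores = gene_assoc.gene_score_table(
        sumstats, panel, genes[genes["gene_id"].isin(spec.index)],
        upstream=cfg.magma_up, downstream=cfg.magma_down,
    )
    weights = sldsr.ld_score_weights(panel, cfg.window_cm)
    annot = baseline_annotations(len(panel.snps), cfg.n_baseline, cfg.seed)
    base_ld = sldsr.compute_ld_scores(panel, annot, cfg.window_cm, weights=weights)

    n_types = spec.shape[1]
    threshold = enrichment.bonferroni_threshold(n_types)
    n_blocks = min(cfg.n_blocks, max(2, len(panel.snps) // 20))
    rows = []
    for ct in spec.columns:
        gene_set = specificity.top_fraction_set(
            spec, ct, cfg.fraction, cfg.biotype_filter, genes
        )
        magma = enrichment.competitive_enrichment(scores, gene_set, set_name=ct)
        col = sldsr.genes_to_annotation(gene_set, genes, cfg.sldsr_window, panel.snps)
        ld = base_ld.copy()
        ld["set"] = weights @ col
        try:
            fit = sldsr.sldsr_fit(sumstats, ld, n_blocks=n_blocks)
            sldsr_p = fit.for_annotation("set")["p"]
        except ValueError as exc:
            log.warning("scan: SLDSR failed for %s: %s", ct, exc)
            sldsr_p = np.nan
        rows.append((ct, len(gene_set), magma.p, sldsr_p))
    table = pd.DataFrame(rows, columns=["cell_type", "n_set", "magma_p", "sldsr_p"])
    table["magma_significant"] = table["magma_p"] < threshold
    table["sldsr_significant"] = table["sldsr_p"] < threshold
    table["dual_significant"] = table["magma_significant"] & table["sldsr_significant"]
    bundle = {
        "config": cfg,
        "threshold": threshold,
        "n_celltypes": n_types,
        "scan": table,
        "specificity": spec,
        "gene_scores": scores,
    }
    return table, bundle


def report(bundle: dict) -> str:
    """Deterministic text report of a results bundle (no timestamps)."""
    if not bundle:
        raise ValueError("empty results bundle")
    cfg: RunConfig | None = bundle.get("config")
    lines = ["# celliability run report", ""]
    if cfg is not None:
        lines += [f"seed: {cfg.seed}", f"config-hash: {cfg.hash()}", ""]
    if "threshold" in bundle:
        lines += [
            f"cell types tested: {bundle.get('n_celltypes', 'NA')}",
            f"Bonferroni threshold: {bundle['threshold']:.4g}",
            "",
        ]
    emitted = False
    for key in ("scan", "gene_scores", "trajectory", "finemap", "burden", "go"):
        if key not in bundle:
            continue
        emitted = True
        lines.append(f"## {key}")
        obj = bundle[key]
        if isinstance(obj, pd.DataFrame):
            lines.append(obj.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
        else:
            lines.append(str(obj))
        lines.append("")
    if not emitted and "specificity" not in bundle:
        raise ValueError("results bundle contains no stage results")
    return "\n".join(lines)


def dot_plot(table: pd.DataFrame, value: str, path: str) -> None:
    """-log10 p dot plot per cell type (analogue of the scan figures)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, max(2, 0.25 * len(table))))
    y = np.arange(len(table))
    ax.scatter(-np.log10(table[value].clip(lower=1e-300)), y)
    ax.set_yticks(y)
    ax.set_yticklabels(table["cell_type"])
    ax.axvline(-np.log10(0.05), linestyle=":", color="gray")
    ax.set_xlabel(f"-log10 {value}")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
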