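"""Synthetic data generators with planted ground truth.

Every input the pipeline consumes — gene models, single-nucleus counts,
an LD reference panel with GWAS summary statistics, a developmental
trajectory, and case–control rare-variant genotypes — can be generated
here with known truth, so each downstream stage is testable end to end
without external downloads.

All draws flow from one ``numpy.random.Generator`` seeded per call; there
is no global random state.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

MHC_CHROM = "6"
MHC_START = 25_000_000
MHC_END = 35_000_000

PTV_CLASSES = ("stop_gained", "frameshift", "splice_donor", "splice_acceptor")
CONSEQUENCE_CLASSES = PTV_CLASSES + ("synonymous", "missense")


class ConfigurationError(ValueError):
    """Raised when a SimConfig field violates its constraints."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    Defaults define a scaled-down cortex-like study: ~1000 genes on two
    main autosomes (plus a few X/MHC genes to exercise filters), 10 cell
    populations of 200 nuclei from 6 donors, 20,000 SNPs in 200 AR(1) LD
    blocks, and a 2000-vs-2000 case–control exome arm.
    """

    seed: int = 0
    # single-nucleus counts
    n_genes: int = 1000
    n_cell_types: int = 10
    cells_per_type: int = 200
    n_donors: int = 6
    marker_fraction: float = 0.05
    marker_fold: float = 8.0
    nb_dispersion: float = 0.5  # alpha in var = mu + alpha * mu^2
    # panel / GWAS
    n_snps: int = 20_000
    n_ld_blocks: int = 200
    ld_rho: float = 0.5
    panel_n: int = 500
    gwas_n: int = 100_000
    planted_set_effect: float = 0.5  # per-SNP E[chi2] inflation in the planted set
    # rare variants
    n_cases: int = 2000
    n_controls: int = 2000
    planted_burden_or: float = 1.0

    def __post_init__(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "n_cell_types": self.n_cell_types,
            "cells_per_type": self.cells_per_type,
            "n_donors": self.n_donors,
            "n_snps": self.n_snps,
            "n_ld_blocks": self.n_ld_blocks,
            "panel_n": self.panel_n,
            "gwas_n": self.gwas_n,
            "n_cases": self.n_cases,
            "n_controls": self.n_controls,
        }
        for name, value in counts.items():
            if value <= 0 or int(value) != value:
                raise ConfigurationError(f"{name} must be a positive integer, got {value!r}")
        if not 0.0 < self.marker_fraction < 1.0:
            raise ConfigurationError("marker_fraction must lie in (0, 1)")
        if self.marker_fold < 1.0:
            raise ConfigurationError("marker_fold must be >= 1")
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be positive")
        if not 0.0 <= self.ld_rho < 1.0:
            raise ConfigurationError("ld_rho must lie in [0, 1)")
        if self.planted_set_effect < 0:
            raise ConfigurationError("planted_set_effect must be >= 0")
        if self.planted_burden_or < 1.0:
            raise ConfigurationError("planted_burden_or must be >= 1")

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class SyntheticTruth:
    """Ground truth planted by the generators."""

    marker_genes: dict[str, set[str]] = field(default_factory=dict)
    enriched_gene_set: set[str] = field(default_factory=set)
    true_tau: dict[str, float] = field(default_factory=dict)
    true_pseudotime: np.ndarray | None = None
    burden_genes: set[str] = field(default_factory=set)

    def to_jsonable(self) -> dict:
        return {
            "marker_genes": {k: sorted(v) for k, v in self.marker_genes.items()},
            "enriched_gene_set": sorted(self.enriched_gene_set),
            "true_tau": dict(self.true_tau),
            "true_pseudotime": None
            if self.true_pseudotime is None
            else [float(x) for x in self.true_pseudotime],
            "burden_genes": sorted(self.burden_genes),
        }


@dataclass
class ReferencePanel:
    """LD reference panel: dosage matrix plus aligned SNP metadata.

    ``dosages`` is individuals x SNPs with values in {0, 1, 2}; ``snps``
    carries SNP, CHR, BP, A1, A2 and a genetic-map position CM (synthetic
    map: 1 cM per Mb).
    """

    dosages: np.ndarray
    snps: pd.DataFrame
    block_index: np.ndarray  # per-SNP LD-block id

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    def snp_positions(self) -> pd.Index:
        return pd.Index(self.snps["SNP"])


def gen_gene_models(config: SimConfig) -> pd.DataFrame:
    """Generate a gene-model table with 1-based inclusive coordinates.

    Genes are laid out without overlap on chromosomes 1 and 2; a few are
    placed on chrX and inside the extended MHC window on chromosome 6 so
    the autosome and MHC filters are exercised. Each gene is tagged
    ``protein_coding`` or ``noncoding``.
    """
    if config.n_genes < 10:
        raise ConfigurationError("n_genes must be >= 10")
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    n_x = max(2, n // 50)
    n_mhc = max(2, n // 50)
    n_auto = n - n_x - n_mhc
    n_chr1 = n_auto - n_auto // 2

    rows = []
    gid = 0

    def lay(chrom: str, count: int, start_at: int) -> None:
        nonlocal gid
        pos = start_at
        for _ in range(count):
            gap = int(rng.integers(5_000, 50_000))
            length = int(rng.integers(2_000, 80_000))
            start = pos + gap
            end = start + length - 1
            strand = "+" if rng.random() < 0.5 else "-"
            biotype = "protein_coding" if rng.random() < 0.75 else "noncoding"
            rows.append((f"G{gid:05d}", chrom, start, end, strand, biotype))
            gid += 1
            pos = end

    lay("1", n_chr1, 1_000_000)
    lay("2", n_auto - n_chr1, 1_000_000)
    # MHC genes: short, guaranteed inside the closed window
    pos = MHC_START + 10_000
    for _ in range(n_mhc):
        length = int(rng.integers(2_000, 20_000))
        start = pos
        end = start + length - 1
        rows.append(
            (f"G{gid:05d}", MHC_CHROM, start, end, "+" if rng.random() < 0.5 else "-",
             "protein_coding" if rng.random() < 0.75 else "noncoding")
        )
        gid += 1
        pos = end + int(rng.integers(5_000, 50_000))
        if pos > MHC_END - 30_000:
            pos = MHC_START + int(rng.integers(10_000, 20_000)) + 100_000
    lay("X", n_x, 1_000_000)

    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand", "biotype"])
    return genes.reset_index(drop=True)


def _stage_for_donor(donor_idx: int, n_donors: int) -> str:
    third = max(1, n_donors // 3)
    if donor_idx < third:
        return "fetal"
    if donor_idx < 2 * third:
        return "infancy"
    return "adult"


def gen_counts(
    config: SimConfig, genes: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate clustered negative-binomial counts with planted markers.

    Returns a genes x cells count matrix, a cell annotation table
    (cell_id, cluster, donor, stage) and the planted truth. Each cell
    type gets ``marker_fraction`` of the genes with baseline mean
    multiplied by ``marker_fold``; two deliberately tiny clusters of 7
    and 3 cells are appended so cluster-size filtering is exercised. The
    planted marker set of the first cell type doubles as the GWAS-
    enriched gene set.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    gene_ids = genes["gene_id"].to_numpy()
    n_genes = len(gene_ids)
    base_mean = np.exp(rng.normal(0.0, 1.0, size=n_genes))  # log-normal baseline

    k = config.n_cell_types
    n_mark = max(1, int(round(config.marker_fraction * n_genes)))
    perm = rng.permutation(n_genes)
    marker_idx = {}
    truth = SyntheticTruth()
    for t in range(k):
        chunk = perm[t * n_mark : (t + 1) * n_mark]
        marker_idx[t] = chunk
        truth.marker_genes[f"type{t}"] = set(gene_ids[chunk])
    truth.enriched_gene_set = set(truth.marker_genes["type0"])

    cluster_sizes = [config.cells_per_type] * k + [7, 3]
    cluster_names = [f"type{t}" for t in range(k)] + ["tiny-1", "tiny-2"]

    theta = 1.0 / config.nb_dispersion  # NB shape so var = mu + alpha mu^2
    cols, cells, clusters = [], [], []
    for name, size in zip(cluster_names, cluster_sizes):
        mu = base_mean.copy()
        if name.startswith("type"):
            t = int(name[4:])
            mu[marker_idx[t]] *= config.marker_fold
        p = theta / (theta + mu)
        block = rng.negative_binomial(theta, p[:, None], size=(n_genes, size))
        cols.append(block)
        cells.extend(f"{name}_c{i}" for i in range(size))
        clusters.extend([name] * size)

    counts = pd.DataFrame(np.concatenate(cols, axis=1), index=gene_ids, columns=cells)
    n_cells = counts.shape[1]
    donors = np.array([f"D{i % config.n_donors}" for i in range(n_cells)])
    stages = np.array([_stage_for_donor(i % config.n_donors, config.n_donors) for i in range(n_cells)])
    ann = pd.DataFrame(
        {"cell_id": cells, "cluster": clusters, "donor": donors, "stage": stages}
    )
    return counts, ann, truth


def gen_panel_and_sumstats(
    config: SimConfig, genes: pd.DataFrame, truth: SyntheticTruth
) -> tuple[ReferencePanel, pd.DataFrame]:
    """Generate an LD reference panel and matching GWAS summary statistics.

    SNPs live on chromosomes 1 and 2, partitioned into contiguous blocks.
    Within a block, haplotype alleles follow a first-order Markov copy
    chain with copy probability ``ld_rho``, giving lag-d allele (and
    dosage) correlation rho^d — the AR(1) structure with closed-form
    correlations. GWAS z-scores are drawn multivariate normal with the
    same block correlation; SNPs inside genes of the planted enriched set
    receive a mean of +/- sqrt(planted_set_effect), inflating their
    expected chi-square by exactly ``planted_set_effect``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    auto = genes[genes["chrom"].isin(["1", "2"])]
    spans = {
        c: (1, int(auto.loc[auto["chrom"] == c, "end"].max()) + 100_000) for c in ["1", "2"]
    }
    total_span = sum(hi - lo for lo, hi in spans.values())
    n1 = int(round(config.n_snps * (spans["1"][1] - spans["1"][0]) / total_span))
    n_by_chrom = {"1": n1, "2": config.n_snps - n1}

    snp_rows = []
    positions = {}
    for chrom, m in n_by_chrom.items():
        lo, hi = spans[chrom]
        pos = np.sort(rng.choice(np.arange(lo, hi), size=m, replace=False))
        positions[chrom] = pos
    idx = 0
    for chrom in ["1", "2"]:
        for bp in positions[chrom]:
            snp_rows.append((f"rs{idx}", chrom, int(bp)))
            idx += 1
    snps = pd.DataFrame(snp_rows, columns=["SNP", "CHR", "BP"])
    snps["A1"] = np.where(rng.random(len(snps)) < 0.5, "A", "G")
    snps["A2"] = np.where(snps["A1"] == "A", "G", "A")
    snps["CM"] = snps["BP"] * 1e-6  # synthetic genetic map: 1 cM/Mb

    # contiguous LD blocks, never straddling a chromosome boundary
    block_index = np.zeros(len(snps), dtype=int)
    n_blocks = min(config.n_ld_blocks, len(snps))
    b1 = max(1, int(round(n_blocks * n_by_chrom["1"] / config.n_snps)))
    bid = 0
    offset = 0
    for chrom, nb in (("1", b1), ("2", n_blocks - b1)):
        m = n_by_chrom[chrom]
        bounds = np.linspace(0, m, max(nb, 1) + 1).astype(int)
        for k in range(len(bounds) - 1):
            block_index[offset + bounds[k] : offset + bounds[k + 1]] = bid
            bid += 1
        offset += m

    # haplotypes: per-block Markov copy chain with common per-block MAF
    n_hap = 2 * config.panel_n
    m = len(snps)
    dosages = np.zeros((config.panel_n, m), dtype=np.int8)
    maf = np.empty(m)
    rho = config.ld_rho
    for b in np.unique(block_index):
        cols = np.flatnonzero(block_index == b)
        f = float(rng.uniform(0.1, 0.5))
        maf[cols] = f
        hap = np.empty((n_hap, len(cols)), dtype=np.int8)
        hap[:, 0] = rng.random(n_hap) < f
        for j in range(1, len(cols)):
            copy = rng.random(n_hap) < rho
            fresh = (rng.random(n_hap) < f).astype(np.int8)
            hap[:, j] = np.where(copy, hap[:, j - 1], fresh)
        dos = hap[0::2] + hap[1::2]
        dosages[:, cols] = dos

    # planted mean shift on SNPs inside enriched-set gene bodies
    mu = np.zeros(m)
    if truth.enriched_gene_set and config.planted_set_effect > 0:
        sub = genes[genes["gene_id"].isin(truth.enriched_gene_set)]
        amp = np.sqrt(config.planted_set_effect)
        in_set = np.zeros(m, dtype=bool)
        for chrom, grp in sub.groupby("chrom"):
            sel = snps["CHR"].to_numpy() == chrom
            bp = snps.loc[sel, "BP"].to_numpy()
            hit = np.zeros(len(bp), dtype=bool)
            for s, e in zip(grp["start"].to_numpy(), grp["end"].to_numpy()):
                hit |= (bp >= s) & (bp <= e)
            in_set[np.flatnonzero(sel)[hit]] = True
        mu[in_set] = amp * np.where(rng.random(in_set.sum()) < 0.5, 1.0, -1.0)

    # z-scores: MVN with the block AR(1) correlation (rho^d), plus mean mu
    z = np.empty(m)
    for b in np.unique(block_index):
        cols = np.flatnonzero(block_index == b)
        eps = rng.standard_normal(len(cols))
        out = np.empty(len(cols))
        out[0] = eps[0]
        a = np.sqrt(1.0 - rho * rho)
        for j in range(1, len(cols)):
            out[j] = rho * out[j - 1] + a * eps[j]
        z[cols] = out
    z = z + mu

    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.clip(p, 1e-300, 1.0)
    sumstats = snps[["SNP", "CHR", "BP", "A1", "A2"]].copy()
    sumstats["P"] = p
    sumstats["N"] = config.gwas_n
    sumstats["Z"] = z

    truth.true_tau = {"enriched_set": config.planted_set_effect}
    panel = ReferencePanel(dosages=dosages, snps=snps.copy(), block_index=block_index)
    return panel, sumstats


def gen_trajectory(
    config: SimConfig,
    gene_z: pd.DataFrame,
    slope: float = 1.0,
    n_cells: int = 400,
) -> tuple[pd.DataFrame, np.ndarray, pd.DataFrame]:
    """Generate a developmental trajectory with drifting expression.

    Cells are ordered by a true pseudotime in [0, 1]; genes with high
    gene-level association z have log-mean expression increasing linearly
    with pseudotime at rate ``slope`` (slope 0 gives no relation). Counts
    are negative binomial. Returns (counts genes x cells, pseudotime,
    cell annotation with donor ids).
    """
    if len(gene_z) < 50:
        raise ValueError("gene_z must cover at least 50 genes")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    genes = gene_z["gene_id"].to_numpy()
    z = gene_z["z"].to_numpy(dtype=float)
    zs = (z - z.mean()) / (z.std() if z.std() > 0 else 1.0)

    t = np.linspace(0.0, 1.0, n_cells)
    base = rng.normal(0.5, 0.5, size=len(genes))
    log_mu = base[:, None] + slope * np.outer(zs, t - 0.5)
    mu = np.exp(log_mu)
    theta = 1.0 / config.nb_dispersion
    counts = rng.negative_binomial(theta, theta / (theta + mu))
    cell_ids = [f"traj_c{i}" for i in range(n_cells)]
    expr = pd.DataFrame(counts, index=genes, columns=cell_ids)
    ann = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "donor": [f"D{i % config.n_donors}" for i in range(n_cells)],
            "pseudotime": t,
        }
    )
    return expr, t, ann


@dataclass
class VariantTable:
    """Rare-variant call set bundle.

    Carries per-variant metadata, per-genotype matrices (variants x
    samples), the sample/covariate table and pairwise kinship — i.e.
    everything the burden pipeline consumes. QC stage flags enforce the
    pipeline order genotype QC -> variant QC -> PTV definition.
    """

    variants: pd.DataFrame  # variant_id chrom pos ref alt gene_id consequence in_external_ref vqsr_pass low_complexity
    GT: np.ndarray  # int8, {0,1,2}, -1 = missing
    DP: np.ndarray
    GQ: np.ndarray
    AB: np.ndarray
    samples: pd.DataFrame
    kinship: pd.DataFrame
    genotype_qc_done: bool = False
    variant_qc_done: bool = False

    @property
    def sample_ids(self) -> np.ndarray:
        return self.samples["sample_id"].to_numpy()

    def copy(self) -> "VariantTable":
        return VariantTable(
            variants=self.variants.copy(),
            GT=self.GT.copy(),
            DP=self.DP.copy(),
            GQ=self.GQ.copy(),
            AB=self.AB.copy(),
            samples=self.samples.copy(),
            kinship=self.kinship.copy(),
            genotype_qc_done=self.genotype_qc_done,
            variant_qc_done=self.variant_qc_done,
        )


def gen_rare_variants(
    config: SimConfig,
    genes: pd.DataFrame,
    truth: SyntheticTruth,
    n_variants_per_gene: float = 3.0,
    burden_gene_fraction: float = 0.1,
    n_burden_singletons: int = 200,
) -> VariantTable:
    """Generate case–control rare-variant genotypes with planted burden.

    Singleton PTVs are planted in a random set of protein-coding burden
    genes; case status is then assigned by a logistic model on each
    sample's carrier count with odds ratio ``planted_burden_or`` (so the
    Firth estimate has a well-defined target). The table deliberately
    contains one variant violating each QC rule (HWE, call rate, low
    DP/GQ/AB genotypes, VQSR fail, low-complexity) plus external-
    reference-flagged singletons, so every filter is exercised.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 4]))
    n_samples = config.n_cases + config.n_controls
    coding = genes[(genes["biotype"] == "protein_coding") & genes["chrom"].isin(["1", "2"])]
    gene_ids = coding["gene_id"].to_numpy()
    n_burden = max(2, int(round(burden_gene_fraction * len(gene_ids))))
    burden_genes = set(rng.choice(gene_ids, size=n_burden, replace=False))
    truth.burden_genes = burden_genes

    pos_by_gene = {
        g: (int(s), int(e), str(c))
        for g, s, e, c in zip(coding["gene_id"], coding["start"], coding["end"], coding["chrom"])
    }

    var_rows: list[tuple] = []
    gt_rows: list[np.ndarray] = []

    def add_variant(gene: str, consequence: str, carriers: np.ndarray, ext: bool = False,
                    vqsr: bool = True, lowc: bool = False, hom_alt: np.ndarray | None = None):
        s, e, c = pos_by_gene[gene]
        pos = int(rng.integers(s, e + 1))
        gt = np.zeros(n_samples, dtype=np.int8)
        gt[carriers] = 1
        if hom_alt is not None:
            gt[hom_alt] = 2
        var_rows.append(
            (f"v{len(var_rows)}", c, pos, "C", "T", gene, consequence, ext, vqsr, lowc)
        )
        gt_rows.append(gt)

    # planted singleton PTVs in burden genes, one random carrier each
    burden_list = sorted(burden_genes)
    for i in range(n_burden_singletons):
        gene = burden_list[i % len(burden_list)]
        cls = PTV_CLASSES[int(rng.integers(len(PTV_CLASSES)))]
        carrier = np.array([rng.integers(n_samples)])
        add_variant(gene, cls, carrier)

    # background variants across all coding genes
    non_burden = [g for g in gene_ids if g not in burden_genes]
    n_bg = int(n_variants_per_gene * len(gene_ids))
    for _ in range(n_bg):
        gene = non_burden[int(rng.integers(len(non_burden)))]
        cls = CONSEQUENCE_CLASSES[int(rng.integers(len(CONSEQUENCE_CLASSES)))]
        k = 1 if rng.random() < 0.6 else int(rng.integers(2, 8))
        carriers = rng.choice(n_samples, size=k, replace=False)
        add_variant(gene, cls, carriers)

    # QC violators
    some = non_burden[0]
    # HWE violation: many hom-alts, no hets
    add_variant(some, "synonymous", np.array([], dtype=int),
                hom_alt=rng.choice(n_samples, size=max(8, n_samples // 50), replace=False))
    # call-rate violation handled below via DP; VQSR fail; low complexity
    add_variant(some, "missense", rng.choice(n_samples, size=3, replace=False), vqsr=False)
    add_variant(some, "missense", rng.choice(n_samples, size=3, replace=False), lowc=True)
    # external-reference-present singleton PTV
    add_variant(burden_list[0], "stop_gained", np.array([rng.integers(n_samples)]), ext=True)
    # low-call-rate variant: genotypes mostly at DP<10 (set after DP matrix built)
    add_variant(some, "synonymous", rng.choice(n_samples, size=2, replace=False))

    variants = pd.DataFrame(
        var_rows,
        columns=["variant_id", "chrom", "pos", "ref", "alt", "gene_id",
                 "consequence", "in_external_ref", "vqsr_pass", "low_complexity"],
    )
    GT = np.vstack(gt_rows)
    n_var = GT.shape[0]

    DP = rng.integers(15, 80, size=(n_var, n_samples)).astype(np.int16)
    GQ = rng.integers(40, 99, size=(n_var, n_samples)).astype(np.int16)
    AB = np.where(GT == 1, rng.uniform(0.35, 0.65, size=(n_var, n_samples)),
                  np.where(GT == 2, rng.uniform(0.95, 1.0, size=(n_var, n_samples)),
                           rng.uniform(0.0, 0.05, size=(n_var, n_samples))))
    # plant genotype-level violations on an ordinary variant
    DP[0, 0] = 5  # depth below 10
    GQ[1 % n_var, 1] = 20  # genotype quality below 30
    bad_het = np.flatnonzero(GT[2] == 1)
    if bad_het.size:
        AB[2, bad_het[0]] = 0.9  # het allele balance outside [0.25, 0.75]
    # low-call-rate variant: push >10% of its genotypes below the DP threshold
    lowcall = n_var - 1
    drop = rng.choice(n_samples, size=int(0.2 * n_samples) + 1, replace=False)
    DP[lowcall, drop] = 5

    # sample covariates and case status from carrier counts in burden genes
    is_ptv = variants["consequence"].isin(PTV_CLASSES).to_numpy()
    in_burden = variants["gene_id"].isin(burden_genes).to_numpy()
    het_count = (GT == 1).sum(axis=1)
    hom_count = (GT == 2).sum(axis=1)
    singleton = (het_count == 1) & (hom_count == 0)
    qual = is_ptv & in_burden & singleton & ~variants["in_external_ref"].to_numpy()
    carrier_count = (GT[qual] == 1).sum(axis=0)

    beta0 = np.log(config.n_cases / config.n_controls)
    logit = beta0 + np.log(config.planted_burden_or) * carrier_count
    status = (rng.random(n_samples) < 1.0 / (1.0 + np.exp(-logit))).astype(int)

    pcs = rng.normal(size=(n_samples, 10))
    samples = pd.DataFrame({"sample_id": [f"S{i:05d}" for i in range(n_samples)]})
    samples["status"] = status
    samples["sex"] = rng.integers(0, 2, size=n_samples)
    samples["platform"] = rng.integers(0, 2, size=n_samples)
    samples["mean_depth"] = rng.uniform(25, 60, size=n_samples)
    samples["ancestry_ok"] = True
    for j in range(10):
        samples[f"PC{j + 1}"] = pcs[:, j]
    samples["synonymous_count"] = rng.poisson(20, size=n_samples)
    # plant sample-QC violations: a low-depth sample, an ancestry outlier,
    # a duplicate pair and a first-degree chain A-B, B-C
    samples.loc[0, "mean_depth"] = 12.0
    samples.loc[1, "ancestry_ok"] = False
    ids = samples["sample_id"]
    kinship = pd.DataFrame(
        {
            "id1": [ids[2], ids[4], ids[5]],
            "id2": [ids[3], ids[5], ids[6]],
            "kinship": [0.40, 0.20, 0.19],
        }
    )

    return VariantTable(
        variants=variants, GT=GT, DP=DP, GQ=GQ.astype(np.int16), AB=AB,
        samples=samples, kinship=kinship,
    )
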