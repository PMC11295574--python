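"""Readers and writers for the pipeline's on-disk formats.

Conventions: gene models are BED-like TSVs with 1-based inclusive
coordinates; summary statistics are whitespace-delimited text with
header ``SNP CHR BP A1 A2 P N``; counts are MatrixMarket plus gene/cell
TSVs; gene sets are GMT; panels and variants are VCF (uncompressed,
written directly, read back through pysam).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as scipy_io
from scipy import sparse

from .synthetic import ReferencePanel, SyntheticTruth, VariantTable

GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand", "biotype"]


# ---------------------------------------------------------------- gene models

def write_gene_models(genes: pd.DataFrame, path: str | Path) -> None:
    genes[GENE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_gene_models(path: str | Path) -> pd.DataFrame:
    genes = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(GENE_COLUMNS) - set(genes.columns)
    if missing:
        raise ValueError(f"gene-model table missing columns: {sorted(missing)}")
    return genes


# --------------------------------------------------------------------- counts

def write_counts(counts: pd.DataFrame, ann: pd.DataFrame, prefix: str | Path) -> None:
    """Write counts as MTX plus gene, cell and annotation TSVs."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    scipy_io.mmwrite(str(prefix) + ".mtx", sparse.csr_matrix(counts.to_numpy()))
    pd.Series(counts.index, name="gene_id").to_csv(
        str(prefix) + ".genes.tsv", sep="\t", index=False
    )
    ann.to_csv(str(prefix) + ".cells.tsv", sep="\t", index=False)


def read_counts(prefix: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    prefix = str(prefix)
    mat = scipy_io.mmread(prefix + ".mtx").toarray().astype(np.int64)
    genes = pd.read_csv(prefix + ".genes.tsv", sep="\t")["gene_id"]
    ann = pd.read_csv(prefix + ".cells.tsv", sep="\t")
    counts = pd.DataFrame(mat, index=genes.to_numpy(), columns=ann["cell_id"].to_numpy())
    return counts, ann


# ------------------------------------------------------------------- sumstats

def write_sumstats(sumstats: pd.DataFrame, path: str | Path) -> None:
    cols = ["SNP", "CHR", "BP", "A1", "A2", "P", "N"]
    sumstats[cols].to_csv(path, sep=" ", index=False)


def read_sumstats(path: str | Path) -> pd.DataFrame:
    ss = pd.read_csv(path, sep=r"\s+", dtype={"CHR": str})
    required = {"SNP", "CHR", "BP", "A1", "A2", "P", "N"}
    missing = required - set(ss.columns)
    if missing:
        raise ValueError(f"sumstats missing columns: {sorted(missing)}")
    if ss["SNP"].duplicated().any():
        raise ValueError("duplicate SNP ids in summary statistics")
    bad = (ss["P"] <= 0) | (ss["P"] > 1)
    if bad.any():
        raise ValueError(f"{int(bad.sum())} SNPs with p outside (0, 1]")
    return ss


# ------------------------------------------------------------------ gene sets

def write_gmt(sets: dict[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sets:
            genes = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\tna\t{genes}\n")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            out[parts[0]] = set(parts[2:])
    return out


# ------------------------------------------------------------------------ VCF

_VCF_HEADER = """##fileformat=VCFv4.2
##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence class">
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene id">
##INFO=<ID=EXT,Number=0,Type=Flag,Description="Present in external reference">
##INFO=<ID=LOWC,Number=0,Type=Flag,Description="Low-complexity region">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
"""

_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def write_panel_vcf(panel: ReferencePanel, path: str | Path) -> None:
    """Write reference-panel dosages as an uncompressed VCF (GT only)."""
    n = panel.n_individuals
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(panel.snps["CHR"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        names = "\t".join(f"I{i}" for i in range(n))
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{names}\n")
        for j, row in enumerate(panel.snps.itertuples(index=False)):
            gts = "\t".join(_GT_CODE[int(g)] for g in panel.dosages[:, j])
            fh.write(
                f"{row.CHR}\t{row.BP}\t{row.SNP}\t{row.A2}\t{row.A1}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_panel_vcf(path: str | Path, cm_per_mb: float = 1.0) -> ReferencePanel:
    import pysam

    with pysam.VariantFile(str(path)) as vf:
        sample_names = list(vf.header.samples)
        rows = []
        dosage_rows = []
        for rec in vf:
            rows.append((rec.id, str(rec.chrom), rec.pos, rec.alts[0], rec.ref))
            dosage_rows.append(
                [sum(a or 0 for a in rec.samples[s]["GT"]) for s in sample_names]
            )
    snps = pd.DataFrame(rows, columns=["SNP", "CHR", "BP", "A1", "A2"])
    snps["CM"] = snps["BP"] * 1e-6 * cm_per_mb
    dosages = np.array(dosage_rows, dtype=np.int8).T
    return ReferencePanel(dosages=dosages, snps=snps, block_index=np.zeros(len(snps), int))


def write_variants_vcf(vt: VariantTable, path: str | Path) -> None:
    """Write the rare-variant call set with DP/GQ/AD FORMAT fields."""
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        fh.write("##FILTER=<ID=VQSR,Description=\"Failed VQSR\">\n")
        for chrom in pd.unique(vt.variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        names = "\t".join(vt.sample_ids)
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{names}\n")
        for i, row in enumerate(vt.variants.itertuples(index=False)):
            info = f"CSQ={row.consequence};GENE={row.gene_id}"
            if row.in_external_ref:
                info += ";EXT"
            if row.low_complexity:
                info += ";LOWC"
            filt = "PASS" if row.vqsr_pass else "VQSR"
            fields = []
            for j in range(vt.GT.shape[1]):
                dp = int(vt.DP[i, j])
                ad_alt = int(round(vt.AB[i, j] * dp))
                fields.append(
                    f"{_GT_CODE[int(vt.GT[i, j])]}:{dp}:{int(vt.GQ[i, j])}:{dp - ad_alt},{ad_alt}"
                )
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.variant_id}\t{row.ref}\t{row.alt}\t.\t{filt}\t"
                f"{info}\tGT:DP:GQ:AD\t" + "\t".join(fields) + "\n"
            )


def read_variants_vcf(
    path: str | Path, samples: pd.DataFrame, kinship: pd.DataFrame | None = None
) -> VariantTable:
    import pysam

    with pysam.VariantFile(str(path)) as vf:
        sample_names = list(vf.header.samples)
        rows, gts, dps, gqs, abs_ = [], [], [], [], []
        for rec in vf:
            rows.append(
                (
                    rec.id, str(rec.chrom), rec.pos, rec.ref, rec.alts[0],
                    rec.info.get("GENE", ""), rec.info.get("CSQ", ""),
                    bool(rec.info.get("EXT", False)), "VQSR" not in rec.filter.keys(),
                    bool(rec.info.get("LOWC", False)),
                )
            )
            gt_row, dp_row, gq_row, ab_row = [], [], [], []
            for s in sample_names:
                smp = rec.samples[s]
                alleles = smp["GT"]
                if alleles is None or any(a is None for a in alleles):
                    gt_row.append(-1)
                else:
                    gt_row.append(sum(alleles))
                dp = smp.get("DP", 0) or 0
                dp_row.append(dp)
                gq_row.append(smp.get("GQ", 0) or 0)
                ad = smp.get("AD", (0, 0))
                ab_row.append((ad[1] / dp) if dp else 0.0)
            gts.append(gt_row)
            dps.append(dp_row)
            gqs.append(gq_row)
            abs_.append(ab_row)
    variants = pd.DataFrame(
        rows,
        columns=["variant_id", "chrom", "pos", "ref", "alt", "gene_id",
                 "consequence", "in_external_ref", "vqsr_pass", "low_complexity"],
    )
    if kinship is None:
        kinship = pd.DataFrame(columns=["id1", "id2", "kinship"])
    return VariantTable(
        variants=variants,
        GT=np.array(gts, dtype=np.int8),
        DP=np.array(dps, dtype=np.int16),
        GQ=np.array(gqs, dtype=np.int16),
        AB=np.array(abs_, dtype=float),
        samples=samples,
        kinship=kinship,
    )


# ----------------------------------------------------------------------- misc

def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_jsonable(), fh, indent=1)


def read_truth(path: str | Path) -> SyntheticTruth:
    with open(path) as fh:
        d = json.load(fh)
    return SyntheticTruth(
        marker_genes={k: set(v) for k, v in d["marker_genes"].items()},
        enriched_gene_set=set(d["enriched_gene_set"]),
        true_tau=d["true_tau"],
        true_pseudotime=None
        if d["true_pseudotime"] is None
        else np.asarray(d["true_pseudotime"]),
        burden_genes=set(d["burden_genes"]),
    )


def write_table(df: pd.DataFrame, path: str | Path, metadata: dict | None = None) -> None:
    """TSV with '#'-prefixed metadata header lines."""
    with open(path, "w") as fh:
        for k, v in (metadata or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
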