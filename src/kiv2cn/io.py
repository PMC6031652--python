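"""File I/O: VCF (via pysam), phenotype/result TSVs, depth summaries, YAML.

External coordinates are 1-based inclusive.  Dosages are written to the DS
FORMAT field (float); on read the DS field takes precedence and GT calls are
summed to 0/1/2 otherwise.  Imputation quality rides in the IQ INFO field
(1.0 for directly genotyped variants).
"""

from __future__ import annotations

import logging
import os

import numpy as np
import pandas as pd
import pysam
import yaml

from .core import VARIANT_COLUMNS, CohortBundle, allele_stats

log = logging.getLogger("kiv2cn")

DEPTH_COLUMNS = ["sample", "chrom", "start", "end", "mean_depth"]


def configure_logging(verbose: bool = False) -> None:
    logging.basicConfig(
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(levelname)s %(name)s: %(message)s",
    )


def write_vcf(path: str, samples, dosages: np.ndarray, variants: pd.DataFrame) -> None:
    """Write a VCF v4.2 with GT and DS per sample and IQ in INFO.

    DS is a VCF Float (stored as float32); dosages representable in float32
    round-trip exactly, anything else to ~7 significant digits.
    """
    header = pysam.VariantHeader()
    header.add_line("##fileformat=VCFv4.2")
    for chrom in pd.unique(variants["chrom"].astype(str)):
        header.contigs.add(chrom, length=536_870_911)
    header.add_line('##INFO=<ID=IQ,Number=1,Type=Float,Description="Imputation quality">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage of the ALT allele">')
    for s in samples:
        header.add_sample(str(s))
    order = np.lexsort((variants["pos"].to_numpy(), variants["chrom"].astype(str).to_numpy()))
    with pysam.VariantFile(path, "w", header=header) as vcf:
        for j in order:
            row = variants.iloc[j]
            rec = vcf.new_record(
                contig=str(row["chrom"]),
                start=int(row["pos"]) - 1,
                stop=int(row["pos"]) - 1 + len(str(row["ref"])),
                alleles=(str(row["ref"]), str(row["alt"])),
                id=str(row["variant_id"]),
            )
            rec.info["IQ"] = float(row.get("info_score", 1.0))
            for i, s in enumerate(samples):
                d = dosages[i, j]
                if np.isnan(d):
                    rec.samples[str(s)]["GT"] = (None, None)
                else:
                    g = int(round(d))
                    rec.samples[str(s)]["GT"] = (0, 1) if g == 1 else ((1, 1) if g == 2 else (0, 0))
                    rec.samples[str(s)]["DS"] = float(d)
            vcf.write(rec)


def read_vcf(path: str):
    """Read a VCF into (samples, dosage matrix, variant table).

    DS takes precedence over GT.  MAF/MAC are recomputed from the dosages.
    Malformed records raise ``ValueError`` naming the offending line.
    """
    try:
        vcf = pysam.VariantFile(path)
    except (OSError, ValueError) as exc:
        raise ValueError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vcf.header.samples)
    rows, cols = [], []
    for k, rec in enumerate(vcf):
        if rec.alts is None or len(rec.alts) != 1:
            raise ValueError(f"{path}: record {k + 1} at {rec.chrom}:{rec.pos} is not biallelic")
        col = np.full(len(samples), np.nan)
        for i, s in enumerate(samples):
            fmt = rec.samples[s]
            ds = fmt.get("DS")
            if ds is not None:
                col[i] = float(ds)
            else:
                gt = fmt.get("GT")
                if gt is not None and None not in gt:
                    col[i] = float(sum(gt))
        cols.append(col)
        rows.append(
            {
                "variant_id": rec.id or f"{rec.chrom}:{rec.pos}",
                "chrom": rec.chrom,
                "pos": rec.pos,
                "ref": rec.ref,
                "alt": rec.alts[0],
                "info_score": float(rec.info["IQ"]) if "IQ" in rec.info else 1.0,
            }
        )
    vcf.close()
    if not rows:
        raise ValueError(f"{path}: no variant records")
    dosages = np.column_stack(cols)
    variants = pd.DataFrame(rows)
    st = allele_stats(dosages)
    variants["maf"] = st["maf"].to_numpy()
    variants["mac"] = st["mac"].to_numpy()
    return samples, dosages, variants[VARIANT_COLUMNS]


def write_phenotypes(path: str, phenotypes: pd.DataFrame) -> None:
    phenotypes.to_csv(path, sep="\t", index_label="sample_id", float_format="%.10g")


def read_phenotypes(path: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    except Exception as exc:  # pandas raises several parser error types
        raise ValueError(f"cannot parse phenotype table {path}: {exc}") from exc
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: missing sample_id column")
    return df.set_index("sample_id")


def write_depth(path: str, depth: pd.DataFrame) -> None:
    depth[DEPTH_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_depth(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "chrom": str})
    missing = set(DEPTH_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: depth table missing columns {sorted(missing)}")
    return df


def write_result_table(path: str, results: pd.DataFrame) -> None:
    lead = [c for c in ["variant_id", "chrom", "pos", "maf", "beta", "se", "p", "n", "analysis"] if c in results.columns]
    rest = [c for c in results.columns if c not in lead]
    results[lead + rest].to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_yaml(path: str) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_yaml(path: str, obj) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)


def write_cohort(out_dir: str, bundle: CohortBundle) -> dict:
    """Write a bundle as VCF + phenotype TSV (+ depth TSV); returns the paths."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "vcf": os.path.join(out_dir, f"{bundle.name}.vcf"),
        "pheno": os.path.join(out_dir, f"{bundle.name}.pheno.tsv"),
    }
    write_vcf(paths["vcf"], bundle.samples, bundle.dosages, bundle.variants)
    write_phenotypes(paths["pheno"], bundle.phenotypes)
    if bundle.depth is not None:
        paths["depth"] = os.path.join(out_dir, f"{bundle.name}.depth.tsv")
        write_depth(paths["depth"], bundle.depth)
    return paths


def read_cohort(vcf_path: str, pheno_path: str, depth_path: str | None = None, name: str = "cohort") -> CohortBundle:
    """Assemble a :class:`CohortBundle` restricted to the sample intersection.

    Samples present in only one of the two files are dropped (counts logged);
    an empty intersection is an error.
    """
    samples, dosages, variants = read_vcf(vcf_path)
    pheno = read_phenotypes(pheno_path)
    common = [s for s in samples if s in pheno.index]
    n_drop_vcf = len(samples) - len(common)
    n_drop_pheno = len(pheno) - len(common)
    if n_drop_vcf or n_drop_pheno:
        log.info("read_cohort: dropped %d VCF-only and %d phenotype-only samples", n_drop_vcf, n_drop_pheno)
    if not common:
        raise ValueError("no samples shared between VCF and phenotype table")
    idx = [samples.index(s) for s in common]
    depth = None
    if depth_path is not None:
        depth = read_depth(depth_path)
        depth = depth[depth["sample"].isin(common)].reset_index(drop=True)
    return CohortBundle(
        samples=common,
        dosages=dosages[idx],
        variants=variants,
        phenotypes=pheno.loc[common],
        depth=depth,
        name=name,
    )
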