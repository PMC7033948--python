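"""Readers and writers for the pipeline's file formats.

Genotypes come in either as VCF (dosages from the DS FORMAT field when
present, otherwise summed GT alleles) or as a plain dosage TSV.  Expression,
covariates and survival are TSVs.  All coordinates are 1-based inclusive
(VCF convention); BED input is converted on read.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import (
    CAUSES,
    FormatError,
    GenotypeMatrix,
    ExpressionMatrix,
)

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def read_genotypes(path, format: str = "vcf", stratum: str | None = None) -> GenotypeMatrix:
    """Load a genotype panel from ``vcf`` or ``dosage-tsv``.

    Missing dosages are mean-imputed per variant at read time (the imputed
    fraction is logged); downstream linear algebra assumes complete matrices.
    """
    if format == "vcf":
        return _read_vcf(path, stratum)
    if format == "dosage-tsv":
        return _read_dosage_tsv(path, stratum)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path, stratum):
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows = []
    meta = []
    n_missing = 0
    n_total = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise FormatError(
                f"multi-allelic record at {rec.CHROM}:{rec.POS}; split upstream"
            )
        try:
            ds = rec.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            d = np.asarray(ds, dtype=float).reshape(-1)
        else:
            gt = rec.genotype.array()
            if gt is None:
                raise FormatError(f"record {rec.CHROM}:{rec.POS} has neither DS nor GT")
            alleles = np.asarray(gt)[:, :2].astype(float)
            alleles[alleles < 0] = np.nan  # missing calls
            d = alleles.sum(axis=1)
        bad = ~np.isfinite(d)
        n_total += d.size
        if bad.any():
            n_missing += int(bad.sum())
            fill = np.nanmean(d) if np.isfinite(d).any() else 0.0
            d = np.where(bad, fill, d)
        rows.append(d)
        vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}:{rec.REF}:{rec.ALT[0]}"
        meta.append((vid, rec.CHROM, rec.POS, rec.REF, rec.ALT[0]))
    if not rows:
        raise FormatError(f"no records in {path}")
    if n_missing:
        log.info("mean-imputed %d/%d missing dosages from %s", n_missing, n_total, path)
    variants = pd.DataFrame(meta, columns=["id", "chrom", "pos", "ref", "alt"])
    return GenotypeMatrix(np.column_stack(rows), variants, samples, stratum)


def _read_dosage_tsv(path, stratum):
    df = pd.read_csv(path, sep="\t")
    required = ["id", "chrom", "pos", "ref", "alt"]
    if df.columns[: len(required)].tolist() != required:
        raise FormatError(f"dosage TSV must start with columns {required}")
    samples = df.columns[len(required):].tolist()
    d = df[samples].to_numpy(dtype=float).T  # samples x variants
    if np.isnan(d).any():
        frac = np.isnan(d).mean()
        log.info("mean-imputing %.3f%% missing dosages from %s", 100 * frac, path)
        col_mean = np.nanmean(d, axis=0)
        col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
        idx = np.where(np.isnan(d))
        d[idx] = col_mean[idx[1]]
    return GenotypeMatrix(d, df[required].copy(), samples, stratum)


def write_dosage_tsv(g: GenotypeMatrix, path) -> None:
    body = pd.DataFrame(g.dosages.T, columns=g.samples)
    df = pd.concat([g.variants.reset_index(drop=True), body], axis=1)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_vcf(g: GenotypeMatrix, path) -> None:
    """Write dosages as a minimal VCF with a DS FORMAT field."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage of ALT allele">\n')
        chroms = g.variants["chrom"].unique()
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(g.samples) + "\n")
        for j, v in g.variants.iterrows():
            ds = "\t".join(f"{x:.4g}" for x in g.dosages[:, j])
            fh.write(f"{v['chrom']}\t{v['pos']}\t{v['id']}\t{v['ref']}\t{v['alt']}\t.\t.\t.\tDS\t{ds}\n")


# ---------------------------------------------------------------------------
# expression / covariates / survival
# ---------------------------------------------------------------------------

def read_expression(path) -> ExpressionMatrix:
    """Expression TSV: columns id, chrom, start, end then one column per sample."""
    df = pd.read_csv(path, sep="\t")
    required = ["id", "chrom", "start", "end"]
    if df.columns[: len(required)].tolist() != required:
        raise FormatError(f"expression TSV must start with columns {required}")
    samples = df.columns[len(required):].tolist()
    return ExpressionMatrix(df[samples].to_numpy(float).T, df[required].copy(), samples)


def write_expression(e: ExpressionMatrix, path) -> None:
    body = pd.DataFrame(e.values.T, columns=e.samples)
    df = pd.concat([e.genes.reset_index(drop=True), body], axis=1)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_covariates(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return df.set_index(df.columns[0])


def write_covariates(c: pd.DataFrame, path) -> None:
    c.to_csv(path, sep="\t", index_label="sample", float_format="%.10g")


def read_survival(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t").set_index("sample")
    if (df["time"] <= 0).any():
        raise FormatError("non-positive follow-up time in survival table")
    bad = set(df["cause"]) - set(CAUSES)
    if bad:
        raise FormatError(f"unknown cause labels {sorted(bad)}")
    return df


def write_survival(s: pd.DataFrame, path) -> None:
    s.to_csv(path, sep="\t", index_label="sample", float_format="%.10g")


def read_bed(path) -> pd.DataFrame:
    """BED intervals -> DataFrame(chrom, start, end) in 1-based inclusive coords."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=["chrom", "start", "end"])
    df["start"] = df["start"] + 1  # BED is 0-based half-open
    return df


def write_truth_json(truth_dict: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth_dict, fh, indent=1, sort_keys=True)


def write_config_yaml(config_dict: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_dict, fh, sort_keys=True)
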