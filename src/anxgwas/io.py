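"""Readers and writers for the formats the pipeline touches.

VCF v4.2 (GT genotypes, FILTER column) for genotypes, TSV for phenotype
tables and association summary statistics, YAML for run configuration.
All genomic coordinates are 1-based throughout, as in VCF.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from cyvcf2 import VCF

from .containers import GenotypeMatrix, validate_cohort

#: Canonical column order of a summary-statistics table.
SUMMARY_COLUMNS = [
    "id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "model",
    "beta_g",
    "se",
    "p",
    "n",
    "beta_age",
    "beta_sex",
    "intercept",
    "fit_ok",
]


def read_vcf(path) -> GenotypeMatrix:
    """Load a VCF into a dosage matrix.

    Dosage is the count of alternate alleles in the diploid GT call
    (phase is ignored); any call containing a missing allele becomes
    ``nan``.  Multiallelic records are retained and flagged through the
    ``n_alt`` metadata column — removing them is the QC stage's job.
    """
    path = str(path)
    try:
        vcf = VCF(path, gts012=False)
    except Exception as exc:
        raise OSError(f"cannot open VCF {path!r}: {exc}") from exc
    samples = list(vcf.samples)
    rows, dosage_cols = [], []
    for lineno, v in enumerate(vcf, start=1):
        try:
            gts = v.genotypes
            dos = np.empty(len(samples))
            for i, call in enumerate(gts):
                alleles = call[:-1]  # last entry is the phased flag
                if any(a is None or a < 0 for a in alleles):
                    dos[i] = np.nan
                else:
                    dos[i] = sum(1 for a in alleles if a > 0)
        except Exception as exc:
            raise ValueError(
                f"malformed VCF record {lineno} at {v.CHROM}:{v.POS}: {exc}"
            ) from exc
        rows.append(
            {
                "chrom": v.CHROM,
                "pos": int(v.POS),
                "id": v.ID if v.ID is not None else f"{v.CHROM}:{v.POS}",
                "ref": v.REF,
                "alt": ",".join(v.ALT) if v.ALT else ".",
                # cyvcf2 reports PASS as None
                "filter": v.FILTER if v.FILTER is not None else "PASS",
                "n_alt": max(len(v.ALT), 1),
            }
        )
        dosage_cols.append(dos)
    vcf.close()
    if rows:
        dosages = np.column_stack(dosage_cols)
        variants = pd.DataFrame(rows)
    else:
        dosages = np.empty((len(samples), 0))
        variants = pd.DataFrame(
            columns=["chrom", "pos", "id", "ref", "alt", "filter", "n_alt"]
        )
    return GenotypeMatrix(dosages=dosages, variants=variants, samples=samples)


_GT_BY_DOSAGE = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(G: GenotypeMatrix, path) -> None:
    """Write a GenotypeMatrix as an uncompressed VCF v4.2 with GT calls.

    Dosage 1 is emitted as 0/1 and dosage 2 as 1/1; a ``nan`` dosage becomes
    ``./.``.  The per-variant ``filter`` and ``alt`` metadata are written
    verbatim, so injected non-PASS or multiallelic records round-trip.
    """
    path = Path(path)
    chroms = list(dict.fromkeys(G.variants["chrom"])) if len(G.variants) else []
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=anxgwas\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FILTER=<ID=lowq,Description="Failed caller filters">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        header = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"
        if G.samples:
            header += "\tFORMAT\t" + "\t".join(G.samples)
        fh.write(header + "\n")
        for j, meta in enumerate(G.variants.itertuples(index=False)):
            calls = []
            for d in G.dosages[:, j]:
                calls.append("./." if np.isnan(d) else _GT_BY_DOSAGE[int(d)])
            fh.write(
                f"{meta.chrom}\t{meta.pos}\t{meta.id}\t{meta.ref}\t{meta.alt}"
                f"\t.\t{meta.filter}\t.\tGT\t" + "\t".join(calls) + "\n"
            )


def write_phenotypes(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> pd.DataFrame:
    """Load and validate a phenotype TSV (see containers.validate_cohort)."""
    table = pd.read_csv(path, sep="\t")
    return validate_cohort(table)


def write_summary_stats(rows: pd.DataFrame, path) -> None:
    """Write an association summary table as TSV.

    Floats are serialized with 10 significant digits so that genome-wide
    thresholding (5e-8) is stable across a write/read round trip.
    """
    out = rows.reindex(columns=SUMMARY_COLUMNS)
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_summary_stats(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"summary-statistics file lacks columns: {missing}")
    if len(df):
        df["fit_ok"] = df["fit_ok"].astype(bool)
        df["chrom"] = df["chrom"].astype(str)
        df["id"] = df["id"].astype(str)
    return df[SUMMARY_COLUMNS]


def load_config(path) -> dict:
    """Load a YAML run configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}
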