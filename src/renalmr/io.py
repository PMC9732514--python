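"""Reading and writing the delimited-text interchange formats.

Summary statistics: tab-separated with header ``snp chr pos ea oa eaf beta
se p n``.  Cohorts: phenotype/covariate TSV plus either a dosage matrix TSV
or a VCF with a DS FORMAT field.  Biomarker tables: TSV with a second
``#units`` header row declaring the unit of each concentration column.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .simulate import SUMMARY_COLUMNS

__all__ = [
    "read_summary_stats", "write_summary_stats",
    "write_cohort", "write_vcf_dosages", "read_vcf_dosages",
    "read_biomarker_table", "load_config",
]

_EXPECTED_UNITS = {"serum_creatinine": ("umol/l", "mg/dl"),
                   "serum_cystatin_c": ("mg/l",),
                   "bun": ("mmol/l",),
                   "uacr": ("mg/mmol",)}


def write_summary_stats(stats: pd.DataFrame, path) -> None:
    stats[SUMMARY_COLUMNS].to_csv(path, sep="\t", index=False, na_rep="NA")


def read_summary_stats(path) -> pd.DataFrame:
    stats = pd.read_csv(path, sep="\t", na_values=["NA"])
    missing = set(SUMMARY_COLUMNS) - set(stats.columns)
    if missing:
        raise ValueError(f"summary statistics at {path} missing columns {sorted(missing)}")
    return stats


def write_cohort(cohort, outdir, genotype_format: str = "tsv") -> None:
    """Write phenotypes/covariates and genotypes as text.

    ``genotype_format`` is ``tsv`` (individuals x SNPs dosage matrix) or
    ``vcf`` (dosages in a DS FORMAT field).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pheno = cohort.covariates.copy()
    pheno.insert(0, "exposure", cohort.exposure)
    pheno.insert(1, "outcome", cohort.outcome)
    for c in cohort.mediators.columns:
        pheno[c] = cohort.mediators[c]
    pheno.to_csv(outdir / "phenotypes.tsv", sep="\t", index=False)
    if cohort.biomarkers is not None:
        units = {"serum_creatinine": "umol/L", "serum_cystatin_c": "mg/L",
                 "bun": "mmol/L", "uacr": "mg/mmol", "age": "years", "sex": "code"}
        with open(outdir / "biomarkers.tsv", "w") as fh:
            fh.write("\t".join(cohort.biomarkers.columns) + "\n")
            fh.write("#units:" + "\t".join(
                units.get(c, "-") for c in cohort.biomarkers.columns) + "\n")
            cohort.biomarkers.to_csv(fh, sep="\t", index=False, header=False)
    if cohort.icd_codes is not None:
        with open(outdir / "icd_codes.txt", "w") as fh:
            for codes in cohort.icd_codes:
                fh.write(",".join(codes) + "\n")
    if genotype_format == "tsv":
        pd.DataFrame(cohort.dosages, columns=cohort.truth.snp_ids).to_csv(
            outdir / "dosages.tsv", sep="\t", index=False)
    elif genotype_format == "vcf":
        write_vcf_dosages(cohort, outdir / "genotypes.vcf")
    else:
        raise ValueError(f"unknown genotype format {genotype_format!r}")


def write_vcf_dosages(cohort, path) -> None:
    """Minimal VCF 4.2 with per-sample DS (dosage) values."""
    t = cohort.truth
    n = cohort.n
    samples = [f"S{i}" for i in range(n)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in sorted(set(int(c) for c in t.chrom)):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,'
                 'Description="Estimated alternate allele dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        order = np.lexsort((t.pos, t.chrom))
        for j in order:
            row = "\t".join(f"{d:g}" for d in cohort.dosages[:, j])
            fh.write(f"{t.chrom[j]}\t{t.pos[j]}\t{t.snp_ids[j]}\t{t.oa[j]}\t"
                     f"{t.ea[j]}\t.\tPASS\t.\tDS\t{row}\n")


def read_vcf_dosages(path):
    """Dosage matrix (individuals x SNPs) and SNP ids from a DS-field VCF."""
    try:
        from cyvcf2 import VCF
    except ImportError:  # pragma: no cover - cyvcf2 is an optional reader
        return _read_vcf_dosages_text(path)
    ids, rows = [], []
    for var in VCF(str(path)):
        ids.append(var.ID)
        ds = var.format("DS")
        rows.append(np.asarray(ds, dtype=float).ravel())
    return np.column_stack(rows), ids


def _read_vcf_dosages_text(path):
    ids, rows = [], []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            ids.append(parts[2])
            rows.append(np.array(parts[9:], dtype=float))
    return np.column_stack(rows), ids


def read_biomarker_table(path) -> pd.DataFrame:
    """Biomarker TSV with a mandatory ``#units:`` second row.

    Creatinine given in mg/dL is converted to umol/L on read; all other
    columns must already carry the expected unit.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        units_row = fh.readline().rstrip("\n")
        if not units_row.startswith("#units:"):
            raise ValueError("biomarker table must declare units in a '#units:' row")
        units = units_row[len("#units:"):].split("\t")
        df = pd.read_csv(fh, sep="\t", names=header)
    unit_of = dict(zip(header, units))
    for col, allowed in _EXPECTED_UNITS.items():
        if col in df.columns:
            u = unit_of.get(col, "").strip().lower().replace("µ", "u")
            if u not in allowed:
                raise ValueError(f"column {col!r} has unit {u!r}; expected one of {allowed}")
            if col == "serum_creatinine" and u == "mg/dl":
                df[col] = df[col] * 88.4
    return df


def load_config(path) -> dict:
    """Study or simulation configuration from a YAML (or JSON) file."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)
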