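"""Reading and writing the cohort tables, genotypes and run manifests.

All tabular outputs are UTF-8 CSV with a header row and ISO-8601 dates.
Genotypes can additionally round-trip through a minimal single-record
VCF v4.2 (GRCh37 chr19:54759361 T>C, GT field only), so CSV and VCF inputs
yield identical analysis tables for equivalent content.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__
from .association import GENOTYPES, VARIANT_RSID
from .config import STATINS, ValidationError
from .simulate import RECORDS_END, CohortBundle

logger = logging.getLogger(__name__)

VCF_CHROM = "19"
VCF_POS = 54759361  # GRCh37, 1-based
VCF_REF = "T"
VCF_ALT = "C"

_GT_FROM_GENOTYPE = {"T/T": "0/0", "T/C": "0/1", "C/T": "0/1", "C/C": "1/1"}
_GENOTYPE_FROM_GT = {"0/0": "T/T", "0/1": "T/C", "1/0": "T/C", "1/1": "C/C"}


def write_bundle(bundle: CohortBundle, out_dir, genotype_format: str = "csv") -> dict[str, str]:
    """Write the five bundle tables; returns a name -> path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name in ("patients", "prescriptions", "labs", "genotypes", "truth"):
        df = getattr(bundle, name).copy()
        for col in df.columns:
            if pd.api.types.is_datetime64_any_dtype(df[col]):
                df[col] = df[col].dt.strftime("%Y-%m-%d")
        path = out / f"{name}.csv"
        df.to_csv(path, index=False)
        paths[name] = str(path)
    if genotype_format == "vcf":
        path = out / "genotypes.vcf"
        write_vcf(bundle.genotypes, path)
        paths["genotypes_vcf"] = str(path)
    return paths


def _read_csv(path, required: set[str]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_prescriptions(path) -> pd.DataFrame:
    df = _read_csv(path, {"patient_id", "drug", "daily_dose_mg", "start_date", "days_supply"})
    bad = df[~df["drug"].isin(STATINS)]
    if len(bad):
        lines = (bad.index + 2).tolist()[:10]
        raise ValidationError(
            f"{path}: unknown drug codes {sorted(bad['drug'].unique())} at lines {lines}"
        )
    df["start_date"] = pd.to_datetime(df["start_date"], format="%Y-%m-%d")
    return df


def read_labs(path) -> pd.DataFrame:
    df = _read_csv(path, {"patient_id", "date", "analyte", "value"})
    df["date"] = pd.to_datetime(df["date"], format="%Y-%m-%d")
    if (df["value"] < 0).any():
        raise ValidationError(f"{path}: negative laboratory values")
    return df


def read_patients(path) -> pd.DataFrame:
    return _read_csv(path, {"patient_id", "sex"})


def read_genotypes_csv(path) -> pd.DataFrame:
    df = _read_csv(path, {"patient_id", "genotype"})
    bad = df[~df["genotype"].isin(GENOTYPES + ("C/T",))]
    if len(bad):
        lines = (bad.index + 2).tolist()[:10]
        raise ValidationError(
            f"{path}: unknown genotype codes {sorted(bad['genotype'].unique())} at lines {lines}"
        )
    if "rsid" not in df.columns:
        df["rsid"] = VARIANT_RSID
    return df


def write_vcf(genotypes: pd.DataFrame, path) -> None:
    """Write genotype calls as a minimal single-record VCF v4.2 (GT only)."""
    samples = genotypes["patient_id"].tolist()
    gts = [_GT_FROM_GENOTYPE[g] for g in genotypes["genotype"]]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##reference=GRCh37\n")
        fh.write(f"##contig=<ID={VCF_CHROM}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        fh.write(
            f"{VCF_CHROM}\t{VCF_POS}\t{VARIANT_RSID}\t{VCF_REF}\t{VCF_ALT}\t.\tPASS\t.\tGT\t"
        )
        fh.write("\t".join(gts) + "\n")


def read_genotypes_vcf(path) -> pd.DataFrame:
    """Read the single-variant VCF back into the genotypes table (via cyvcf2)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    records = list(vcf)
    if len(records) != 1:
        raise ValidationError(f"{path}: expected a single-record VCF, got {len(records)} records")
    rec = records[0]
    if rec.REF != VCF_REF or rec.ALT != [VCF_ALT]:
        raise ValidationError(
            f"{path}: expected biallelic {VCF_REF}>{VCF_ALT} record, got {rec.REF}>{rec.ALT}"
        )
    genos = []
    for sample, gt in zip(samples, rec.genotypes):
        a, b = sorted(gt[:2])
        if a < 0 or b < 0:
            raise ValidationError(f"{path}: missing GT for sample {sample}")
        genos.append({(0, 0): "T/T", (0, 1): "T/C", (1, 1): "C/C"}[(a, b)])
    return pd.DataFrame({"patient_id": samples, "rsid": rec.ID, "genotype": genos})


def read_bundle(in_dir) -> CohortBundle:
    """Load a bundle directory written by :func:`write_bundle`."""
    d = Path(in_dir)
    vcf = d / "genotypes.vcf"
    genotypes = (
        read_genotypes_vcf(vcf) if vcf.exists() else read_genotypes_csv(d / "genotypes.csv")
    )
    truth_path = d / "truth.csv"
    truth = pd.read_csv(truth_path) if truth_path.exists() else pd.DataFrame(
        columns=["patient_id"]
    )
    bundle = CohortBundle(
        patients=read_patients(d / "patients.csv"),
        prescriptions=read_prescriptions(d / "prescriptions.csv"),
        labs=read_labs(d / "labs.csv"),
        genotypes=genotypes,
        truth=truth,
        records_end=RECORDS_END,
    )
    bundle.validate()
    return bundle


def config_hash(config_yaml: str) -> str:
    return hashlib.sha256(config_yaml.encode()).hexdigest()


def write_manifest(
    out_dir,
    command: str,
    cfg_hash: str,
    seed: int,
    inputs: list[str],
    outputs: list[str],
) -> str:
    """Write the run manifest (command, config hash, seed, paths, version)."""
    manifest = {
        "command": command,
        "config_hash": cfg_hash,
        "seed": seed,
        "inputs": sorted(map(str, inputs)),
        "outputs": sorted(map(str, outputs)),
        "tool_version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    path = Path(out_dir) / f"manifest_{command}.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return str(path)
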