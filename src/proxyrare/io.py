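"""File readers/writers and pipeline configuration.

All tables are TSV with a header row and a participant-id column; genotypes
travel as VCF 4.2 with GT fields (read through cyvcf2).  Configuration is a
flat YAML document in which unknown keys are errors, not warnings.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from cyvcf2 import VCF


def read_vcf(path: str | Path) -> tuple[pd.DataFrame, np.ndarray]:
    """Read a VCF into (variant table, dosage matrix).

    Dosages count ALT alleles (0/1/2), positions are 1-based, missing
    genotypes become NaN and are excluded from allele-frequency
    denominators downstream.  Multi-allelic records are refused with an
    instruction to split them first.
    """
    path = str(path)
    vcf = VCF(path)
    samples = list(vcf.samples)
    rows, dosage_rows = [], []
    for rec in vcf:
        if len(rec.ALT) > 1:
            raise ValueError(
                f"multi-allelic record at {rec.CHROM}:{rec.POS}; split into "
                "biallelic records (e.g. bcftools norm -m -any) before reading"
            )
        alt = rec.ALT[0] if rec.ALT else "."
        rows.append(
            {
                "variant_id": rec.ID or f"{rec.CHROM}:{rec.POS}:{rec.REF}:{alt}",
                "chrom": rec.CHROM,
                "pos": rec.POS,
                "ref": rec.REF,
                "alt": alt,
            }
        )
        gt = rec.genotype.array()
        dos = gt[:, 0:2].astype(float)
        dos[dos < 0] = np.nan
        dosage_rows.append(dos.sum(axis=1))
    variants = pd.DataFrame(rows, columns=["variant_id", "chrom", "pos", "ref", "alt"])
    G = (
        np.column_stack(dosage_rows)
        if dosage_rows
        else np.empty((len(samples), 0))
    )
    variants.attrs["samples"] = samples
    return variants, G


def read_table(path: str | Path, index_col: str = "participant_id") -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_table(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings; defaults are the study conditions."""

    out_dir: str = "proxyrare_out"
    seed: int = 0
    n_participants: int = 20000
    # variant panel
    n_common: int = 200
    n_rare: int = 300
    n_ultra_rare: int = 400
    n_genes: int = 40
    # prediction
    k_outer: int = 10
    k_inner: int = 10
    min_features_present: int = 10
    # phenotype thresholds (% PDFF)
    steatosis_threshold: float = 5.5
    predicted_control_max: float = 4.0
    predicted_case_min: float = 6.0
    # association
    gene_min_cmac: float = 10.0
    run_loco: bool = True
    loco_block_size: int = 2000
    # effects
    n_causal_common: int = 2
    beta_common: float = 0.05
    n_causal_rare: int = 3
    beta_rare: float = 0.15
    n_causal_genes: int = 2
    beta_gene: float = 0.6
    diagnosis_sensitivity: float = 0.565
    imaging_fraction: float = 0.09
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)
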