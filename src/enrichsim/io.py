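"""File formats, run configuration and seed policy.

PLINK bed/bim/fam is the real-data entry point: the bed parser speaks the
v1.00 SNP-major binary dialect (magic bytes 0x6c 0x1b 0x01, two bits per
genotype packed four per byte).  Dosages count copies of the bim A1
allele; the PLINK missing code (binary 01) maps to the panel's missing
value.  Phenotypes, covariates and LD weights are written as
whitespace-delimited text with the conventional FID/IID leading columns.

Seed policy: a single master seed spawns per-stage child seeds through
``numpy.random.SeedSequence`` with fixed stage keys, so every stage and
replicate is independently re-runnable.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import yaml

from .panel import MISSING, GenotypePanel, MAFSpectrum, _observed_freq

__all__ = [
    "read_plink",
    "write_plink",
    "write_phenotypes",
    "write_covariates",
    "write_weights",
    "write_subset",
    "read_subset",
    "RunConfig",
    "stage_seed",
]

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])

# two-bit genotype code -> A1-allele dosage (01 is the missing code)
_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_DOSAGE_TO_CODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}


def write_plink(panel: GenotypePanel, prefix: Union[str, Path]) -> None:
    """Write a panel as PLINK bed/bim/fam (SNP-major v1.00)."""
    prefix = str(prefix)
    n, m = panel.n, panel.m
    with open(f"{prefix}.fam", "w") as fh:
        for i in range(n):
            fh.write(f"ind{i} ind{i} 0 0 0 -9\n")
    with open(f"{prefix}.bim", "w") as fh:
        for j in range(m):
            fh.write(
                f"{panel.chrom[j]}\t{panel.variant_ids[j]}\t0\t{panel.pos[j]}\tA\tG\n"
            )
    n_bytes = (n + 3) // 4
    with open(f"{prefix}.bed", "wb") as fh:
        fh.write(_BED_MAGIC)
        buf = np.zeros(n_bytes, dtype=np.uint8)
        for j in range(m):
            buf[:] = 0
            col = panel.dosages[:, j]
            for i in range(n):
                code = _DOSAGE_TO_CODE[int(col[i])]
                buf[i >> 2] |= code << ((i & 3) * 2)
            fh.write(buf.tobytes())


def read_plink(prefix: Union[str, Path]) -> GenotypePanel:
    """Read a PLINK bed/bim/fam triple into a panel.

    Raises a format error on a bad magic byte sequence or when the bed
    payload does not match the fam/bim dimensions.
    """
    prefix = str(prefix)
    fam = [line.split() for line in open(f"{prefix}.fam") if line.strip()]
    bim = [line.split() for line in open(f"{prefix}.bim") if line.strip()]
    n, m = len(fam), len(bim)
    raw = open(f"{prefix}.bed", "rb").read()
    if raw[:3] != _BED_MAGIC:
        raise ValueError("not a SNP-major PLINK v1.00 bed file (bad magic bytes)")
    n_bytes = (n + 3) // 4
    if len(raw) - 3 != n_bytes * m:
        raise ValueError(
            f"bed payload {len(raw) - 3} bytes does not match n={n}, m={m}"
        )
    data = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(m, n_bytes)
    codes = np.zeros((m, n_bytes * 4), dtype=np.uint8)
    for shift in range(4):
        codes[:, shift::4] = (data >> (2 * shift)) & 0b11
    dosages = _CODE_TO_DOSAGE[codes[:, :n]].T
    chrom = np.array([int(row[0]) for row in bim], dtype=np.int32)
    pos = np.array([int(row[3]) for row in bim], dtype=np.int64)
    ids = np.array([row[1] for row in bim], dtype=object)
    freq, call_rate = _observed_freq(dosages)
    return GenotypePanel(
        dosages=dosages, chrom=chrom, pos=pos, freq=freq, call_rate=call_rate,
        variant_ids=ids,
    )


def write_phenotypes(phenotypes: np.ndarray, path: Union[str, Path]) -> None:
    """PLINK-style phenotype file: FID IID then one column per replicate."""
    phenotypes = np.atleast_2d(np.asarray(phenotypes, dtype=float))
    if phenotypes.shape[0] == 1:
        phenotypes = phenotypes.T
    with open(path, "w") as fh:
        for i, row in enumerate(phenotypes):
            vals = " ".join(f"{v:.6g}" for v in row)
            fh.write(f"ind{i} ind{i} {vals}\n")


def write_covariates(matrix: np.ndarray, path: Union[str, Path]) -> None:
    """Whitespace-delimited FID IID PC1..PCk."""
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    with open(path, "w") as fh:
        for i, row in enumerate(matrix):
            vals = " ".join(f"{v:.6g}" for v in row)
            fh.write(f"ind{i} ind{i} {vals}\n")


def write_weights(variant_ids, weights: np.ndarray, path: Union[str, Path]) -> None:
    """Two-column LD-weight file (variant id, weight)."""
    with open(path, "w") as fh:
        for vid, w in zip(variant_ids, weights):
            fh.write(f"{vid} {w:.6g}\n")


def write_subset(variant_ids, path: Union[str, Path]) -> None:
    """PLINK-style extract list: one variant id per line."""
    with open(path, "w") as fh:
        for vid in variant_ids:
            fh.write(f"{vid}\n")


def read_subset(path: Union[str, Path]) -> list[str]:
    return [line.strip() for line in open(path) if line.strip()]


# ---------------------------------------------------------------------------
# configuration and seed policy

_STAGE_KEYS = {"panel": 1, "subset": 2, "cv": 3, "effects": 4, "phenotype": 5, "analysis": 6}


def stage_seed(master_seed: int, stage: str, replicate: int = 0) -> np.random.SeedSequence:
    """Child seed for a named pipeline stage and replicate index.

    Deterministic in (master_seed, stage, replicate), so any stage can be
    re-run in isolation without replaying the whole pipeline.
    """
    if stage not in _STAGE_KEYS:
        raise KeyError(f"unknown stage {stage!r}; one of {sorted(_STAGE_KEYS)}")
    return np.random.SeedSequence(entropy=master_seed, spawn_key=(_STAGE_KEYS[stage], replicate))


@dataclass
class RunConfig:
    """Serializable study settings (defaults mirror the full-scale design).

    At full scale the trait has h2 = 0.8 from 2000 CVs, 500 of them in
    the functional category, with 100 phenotype replicates; desk-scale
    runs shrink the panel and replicate counts but keep these ratios.
    """

    # panel
    n_individuals: int = 2000
    n_variants: int = 50_000
    chrom_length_bp: int = 100_000_000
    n_chromosomes: int = 5
    ld_decay_bp: float = 40_000.0
    spectrum_kind: str = "beta"
    spectrum_a: float = 0.5
    spectrum_b: float = 1.0
    maf_lo: float = 0.005
    maf_hi: float = 0.5
    # QC
    maf_min: float = 0.005
    callrate_min: float = 0.90
    hwe_alpha: float = 1e-6
    # trait
    h2: float = 0.8
    n_cv: int = 2000
    n_functional_cv: int = 500
    maf_range: str = "genome_wide"
    n_replicates: int = 100
    # model
    model: str = "gcta"
    alpha: Optional[float] = None
    window_kb: float = 100.0
    n_pcs: int = 10
    # run
    master_seed: int = 0
    output_dir: str = "results"

    def spectrum(self) -> MAFSpectrum:
        return MAFSpectrum(
            kind=self.spectrum_kind,
            a=self.spectrum_a,
            b=self.spectrum_b,
            lo=self.maf_lo,
            hi=self.maf_hi,
        )

    def to_yaml(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)
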