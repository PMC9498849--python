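"""Genomic relationship matrices for the VanRaden / GCTA / alpha / LDAK models.

All four models are special cases of a single frequency-scaled family.
With centered dosages x_ki - 2 p_i, per-SNP heterozygosity
h_i = 2 p_i (1 - p_i), exponent alpha and optional LD weights w*_i:

    z_ki = (x_ki - 2 p_i) * h_i^(alpha/2) * sqrt(w*_i)
    G    = Z Z^T / sum_i w*_i h_i^(1+alpha)

* alpha = 0,  w* = 1   -> VanRaden:  G = M M^T / (2 sum p_i q_i)
* alpha = -1, w* = 1   -> classic GCTA: standardized-genotype kinship / m
* alpha free, w* = 1   -> the alpha-model family
* alpha = -0.25 with LD weights -> the LDAK kinship (exponent 0.75 = 1 + alpha)

Under Hardy-Weinberg sampling E[(x - 2p)^2] = h, so the denominator makes
E[diag(G)] = 1 for every member of the family.  A literal "as-printed"
variant (shared centered M, scalar denominator per model) is available
via ``scaling="as_printed"`` for sensitivity checks; it does not reduce
to the standardized kinship at alpha = -1.
"""

from __future__ import annotations


from dataclasses import dataclass
from typing import Optional

import numpy as np

from .ldweights import LDWeights
from .panel import GenotypePanel, SubsetDefinition

__all__ = ["GRMSpec", "GRM", "Covariates", "build_grm", "grm_pca", "write_grm", "read_grm"]

#: alpha values explored by the alpha-model sweep.
ALPHA_GRID = (-1.25, -1.0, -0.75, -0.5, -0.25, 0.0, 0.25)

_FIXED_ALPHA = {"vanraden": 0.0, "gcta": -1.0}


@dataclass(frozen=True)
class GRMSpec:
    """Model family member: which scaling, which variants, which weights."""

    model: str = "vanraden"
    alpha: Optional[float] = None
    weights: Optional[LDWeights] = None
    subset: Optional[SubsetDefinition] = None
    scaling: str = "per_snp"

    def __post_init__(self) -> None:
        if self.model not in ("vanraden", "gcta", "alpha", "ldak"):
            raise ValueError(f"unknown GRM model {self.model!r}")
        if self.scaling not in ("per_snp", "as_printed"):
            raise ValueError("scaling must be 'per_snp' or 'as_printed'")
        if self.model in _FIXED_ALPHA:
            fixed = _FIXED_ALPHA[self.model]
            if self.alpha is not None and self.alpha != fixed:
                raise ValueError(f"{self.model} model fixes alpha = {fixed}")
            object.__setattr__(self, "alpha", fixed)
        elif self.alpha is None:
            object.__setattr__(self, "alpha", -0.25)
        if self.model == "ldak" and self.weights is None:
            raise ValueError("ldak model requires LD weights")
        if self.model != "ldak" and self.weights is not None:
            raise ValueError("LD weights are only used by the ldak model")


@dataclass
class GRM:
    matrix: np.ndarray
    spec: GRMSpec
    n_variants_used: int
    ids: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = self.matrix.shape[0]
        if self.matrix.shape != (n, n):
            raise ValueError("GRM must be square")
        if self.ids is None:
            self.ids = [f"ind{i}" for i in range(n)]

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


@dataclass
class Covariates:
    """Principal-component covariates for population-structure correction."""

    matrix: np.ndarray
    eigenvalues: np.ndarray
    source: str = "grm"


def build_grm(
    panel: GenotypePanel,
    spec: GRMSpec,
    normalize_diag: bool = False,
) -> GRM:
    """Construct the kinship for a model spec, optionally on a variant subset.

    Allele frequencies always come from the analysis panel, so subset and
    rest-of-genome GRMs share one frequency reference.  With
    ``normalize_diag=True`` the matrix is rescaled to mean diagonal exactly 1
    (used before variance-component fitting so heritability shares are on a
    common scale).
    """
    if not panel.is_complete:
        raise ValueError("panel has missing dosages; run QC first")
    idx = spec.subset.indices if spec.subset is not None else np.arange(panel.m)
    if len(idx) == 0:
        raise ValueError("empty variant subset")
    p = panel.freq[idx]
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("monomorphic variant in GRM subset (QC should remove these)")
    het = 2.0 * p * (1.0 - p)
    alpha = float(spec.alpha)

    if spec.model == "ldak":
        if spec.weights.m != panel.m:
            raise ValueError("LD weights were computed on a different panel")
        wstar = spec.weights.normalized[idx]
    else:
        wstar = np.ones(len(idx))

    M = panel.dosages[:, idx].astype(float) - 2.0 * p
    if spec.scaling == "per_snp":
        Z = M * het ** (alpha / 2.0) * np.sqrt(wstar)
        denom = float(np.sum(wstar * het ** (1.0 + alpha)))
    else:  # literal printed formulas: shared centered M, scalar denominator
        Z = M * np.sqrt(wstar)
        denom = float(len(idx)) if spec.model == "gcta" else float(
            np.sum(het ** (1.0 + alpha))
        )
    G = (Z @ Z.T) / denom
    if normalize_diag:
        G = G / np.mean(np.diag(G))
    used = int(np.sum(wstar > 0)) if spec.model == "ldak" else len(idx)
    return GRM(matrix=G, spec=spec, n_variants_used=used)


def grm_pca(grm: GRM, k: int = 10) -> Covariates:
    """Top-k eigenvectors of the GRM, for use as fixed-effect covariates.

    Eigenvalue-sorted descending; each vector's sign is fixed so its
    largest-magnitude element is positive.
    """
    if not np.all(np.isfinite(grm.matrix)):
        raise ValueError("non-finite GRM entries")
    if not 0 < k < grm.n:
        raise ValueError("need 0 < k < n")
    evals, evecs = np.linalg.eigh(grm.matrix)
    order = np.argsort(evals)[::-1][:k]
    V = evecs[:, order]
    lam = evals[order]
    for c in range(k):
        jmax = np.argmax(np.abs(V[:, c]))
        if V[jmax, c] < 0:
            V[:, c] = -V[:, c]
    return Covariates(matrix=V, eigenvalues=lam, source=grm.spec.model)


# ---------------------------------------------------------------------------
# GRM binary container (GCTA grm.bin dialect)


def write_grm(grm: GRM, prefix: str) -> None:
    """Write <prefix>.grm.bin / .grm.N.bin / .grm.id.

    grm.bin holds the float32 lower triangle including the diagonal,
    row-major (pair order (0,0), (1,0), (1,1), ...); grm.N.bin the
    float32 per-pair variant count; grm.id one "FID IID" line per
    individual.
    """
    n = grm.n
    tri = grm.matrix[np.tril_indices(n)]
    tri.astype("<f4").tofile(f"{prefix}.grm.bin")
    np.full(tri.shape, grm.n_variants_used, dtype="<f4").tofile(f"{prefix}.grm.N.bin")
    with open(f"{prefix}.grm.id", "w") as fh:
        for ident in grm.ids:
            fh.write(f"{ident}\t{ident}\n")


def read_grm(prefix: str) -> GRM:
    """Read a GRM written by :func:`write_grm` (float32 granularity)."""
    with open(f"{prefix}.grm.id") as fh:
        ids = [line.split()[1] for line in fh if line.strip()]
    n = len(ids)
    expect = n * (n + 1) // 2
    tri = np.fromfile(f"{prefix}.grm.bin", dtype="<f4")
    if len(tri) != expect:
        raise ValueError(
            f"truncated GRM: {len(tri)} values for n={n} (expected {expect})"
        )
    counts = np.fromfile(f"{prefix}.grm.N.bin", dtype="<f4")
    G = np.zeros((n, n))
    iu = np.tril_indices(n)
    G[iu] = tri
    G = G + G.T - np.diag(np.diag(G))
    n_used = int(counts[0]) if len(counts) else 0
    return GRM(matrix=G, spec=GRMSpec(model="vanraden"), n_variants_used=n_used, ids=ids)
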