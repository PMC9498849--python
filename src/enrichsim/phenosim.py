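"""Additive quantitative-trait simulation with known heritability truth.

A trait is controlled by ``n_cv`` causal variants (CVs) drawn from a given
MAF range, a fixed number of which lie inside a designated "functional"
variant subset.  Allelic effects follow the frequency-dependent family

    var(u_i) ∝ [2 p_i (1 - p_i)]^{alpha_sim},

normalised so the expected total genetic variance equals the target
heritability h^2 (phenotypic variance ~1).  With alpha_sim = -1 every CV
contributes the same expected variance h^2 / n_cv -- the equal-variance
architecture corresponding to negative selection.  Phenotypes are

    y = g + e,   g_k = sum_i (x_ki - 2 p_i) u_i,
    e ~ N(0, var(g) (1/h^2 - 1)),

with the residual variance tied to the realised sample variance of g so
that each replicate hits the target heritability in-sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .panel import GenotypePanel, SubsetDefinition

__all__ = [
    "MAF_RANGES",
    "CVSet",
    "EffectSet",
    "TraitReplicates",
    "select_cvs",
    "draw_effects",
    "simulate_phenotypes",
    "true_subset_h2",
]

#: Named CV MAF ranges: genome-wide, common, and uncommon architectures.
#: Intervals are closed except the uncommon upper bound, which is open.
MAF_RANGES: dict[str, tuple[float, float, bool]] = {
    "genome_wide": (0.005, 0.5, True),
    "common": (0.05, 0.5, True),
    "uncommon": (0.01, 0.05, False),
}


def _range_mask(maf: np.ndarray, maf_range) -> np.ndarray:
    if isinstance(maf_range, str):
        lo, hi, closed_hi = MAF_RANGES[maf_range]
    else:
        lo, hi = maf_range
        closed_hi = True
    upper = maf <= hi if closed_hi else maf < hi
    return (maf >= lo) & upper


@dataclass(frozen=True)
class CVSet:
    """Causal-variant indices, with the functional-subset stratification."""

    indices: np.ndarray
    n_functional: int
    maf_range: object

    def __post_init__(self) -> None:
        object.__setattr__(self, "indices", np.asarray(self.indices, dtype=np.int64))

    @property
    def n_cv(self) -> int:
        return len(self.indices)


@dataclass(frozen=True)
class EffectSet:
    """Per-CV allelic effect sizes for one trait realisation."""

    u: np.ndarray
    alpha_sim: float
    h2: float


@dataclass
class TraitReplicates:
    """Simulated phenotype replicates with full truth bookkeeping."""

    phenotypes: np.ndarray  # n_individuals x n_replicates
    genetic_values: np.ndarray  # n_individuals x n_replicates
    effects: np.ndarray  # n_cv x n_replicates (fresh draw per replicate)
    h2_target: float
    alpha_sim: float
    seed: int

    @property
    def n_replicates(self) -> int:
        return self.phenotypes.shape[1]

    def effect_set(self, replicate: int) -> EffectSet:
        return EffectSet(self.effects[:, replicate], self.alpha_sim, self.h2_target)

    def realized_h2(self) -> np.ndarray:
        """Per-replicate realised heritability var(g)/var(y)."""
        vg = self.genetic_values.var(axis=0, ddof=1)
        vy = self.phenotypes.var(axis=0, ddof=1)
        return vg / vy


def select_cvs(
    panel: GenotypePanel,
    functional: SubsetDefinition,
    maf_range="genome_wide",
    n_cv: int = 2000,
    n_functional: int = 500,
    seed: int = 0,
) -> CVSet:
    """Sample CVs stratified by functional-subset membership.

    ``n_functional`` CVs are drawn uniformly from the intersection of the
    functional subset with the MAF range, the remaining ``n_cv - n_functional``
    from its complement within the range.
    """
    if not 0 <= n_functional <= n_cv:
        raise ValueError("need 0 <= n_functional <= n_cv")
    in_range = _range_mask(panel.maf, maf_range)
    func_mask = functional.membership_mask(panel.m)
    pool_f = np.flatnonzero(in_range & func_mask)
    pool_r = np.flatnonzero(in_range & ~func_mask)
    if len(pool_f) < n_functional:
        raise ValueError(
            f"only {len(pool_f)} eligible variants in the functional stratum "
            f"for MAF range {maf_range!r}; need {n_functional}"
        )
    if len(pool_r) < n_cv - n_functional:
        raise ValueError(
            f"only {len(pool_r)} eligible variants outside the functional stratum "
            f"for MAF range {maf_range!r}; need {n_cv - n_functional}"
        )
    rng = np.random.default_rng(seed)
    chosen_f = rng.choice(pool_f, size=n_functional, replace=False)
    chosen_r = rng.choice(pool_r, size=n_cv - n_functional, replace=False)
    idx = np.sort(np.concatenate([chosen_f, chosen_r]))
    return CVSet(indices=idx, n_functional=n_functional, maf_range=maf_range)


def _effect_scale(p: np.ndarray, h2: float, alpha_sim: float) -> np.ndarray:
    """Per-CV effect-size SDs: var(u_i) ∝ (2pq)^alpha, sum of 2pq*var(u) = h2."""
    het = 2.0 * p * (1.0 - p)
    if np.any(het <= 0):
        raise ValueError("CV allele frequencies must lie strictly inside (0, 1)")
    raw = het**alpha_sim
    total = np.sum(raw * het)
    return np.sqrt(h2 * raw / total)


def draw_effects(
    cvset: CVSet,
    panel: GenotypePanel,
    h2: float = 0.8,
    alpha_sim: float = -1.0,
    seed: int = 0,
) -> EffectSet:
    """Draw allelic effects u_i ~ N(0, var) under the alpha architecture.

    At alpha_sim = -1 each CV's expected variance contribution
    E[u_i^2 * 2 p_i (1-p_i)] equals h2 / n_cv exactly.
    """
    if not 0.0 <= h2 <= 1.0:
        raise ValueError("h2 must be in [0, 1]")
    rng = np.random.default_rng(seed)
    if h2 == 0.0:
        u = np.zeros(cvset.n_cv)
    else:
        sd = _effect_scale(panel.freq[cvset.indices], h2, alpha_sim)
        u = rng.standard_normal(cvset.n_cv) * sd
    return EffectSet(u=u, alpha_sim=alpha_sim, h2=h2)


def simulate_phenotypes(
    panel: GenotypePanel,
    cvset: CVSet,
    h2: float = 0.8,
    n_replicates: int = 100,
    seed: int = 0,
    alpha_sim: float = -1.0,
    redraw_effects: bool = True,
) -> TraitReplicates:
    """Simulate y = g + e replicates with in-sample heritability h2.

    Effects are redrawn for each replicate by default (set
    ``redraw_effects=False`` to hold one effect draw fixed and vary only
    the residuals).  The residual SD uses the realised sample variance of
    g, so var(g)/var(y) ≈ h2 per replicate up to residual sampling noise.
    """
    if not panel.is_complete:
        raise ValueError("panel has missing dosages; run QC first")
    if not 0.0 <= h2 <= 1.0:
        raise ValueError("h2 must be in [0, 1]")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    effect_seeds = ss.spawn(n_replicates)
    resid_rng = np.random.default_rng(ss.spawn(1)[0])

    X = panel.dosages[:, cvset.indices].astype(float)
    W = X - 2.0 * panel.freq[cvset.indices]  # centered dosages
    n = panel.n
    phenos = np.empty((n, n_replicates))
    gvals = np.empty((n, n_replicates))
    effects = np.empty((cvset.n_cv, n_replicates))
    u_fixed = None
    for r in range(n_replicates):
        if redraw_effects or u_fixed is None:
            u = draw_effects(cvset, panel, h2, alpha_sim, seed=effect_seeds[r]).u
            u_fixed = u
        else:
            u = u_fixed
        g = W @ u
        var_g = g.var(ddof=1)
        if h2 == 0.0 or var_g == 0.0:
            e = resid_rng.standard_normal(n)  # pure-noise trait
        elif h2 == 1.0:
            e = np.zeros(n)
        else:
            e = resid_rng.standard_normal(n) * np.sqrt(var_g * (1.0 / h2 - 1.0))
        effects[:, r] = u
        gvals[:, r] = g
        phenos[:, r] = g + e
    return TraitReplicates(
        phenotypes=phenos,
        genetic_values=gvals,
        effects=effects,
        h2_target=h2,
        alpha_sim=alpha_sim,
        seed=seed,
    )


def true_subset_h2(
    cvset: CVSet,
    effects: EffectSet,
    subset: Optional[SubsetDefinition],
    panel: GenotypePanel,
    phenotype_var: float,
) -> float:
    """Analytic subset heritability from the known effect sizes.

    Sum over CVs inside the subset of u_i^2 * 2 p_i (1 - p_i), divided by
    the phenotypic variance; the HWE-expected variance convention keeps
    the truth additive over any partition of the genome.  ``subset=None``
    means the whole genome.
    """
    if phenotype_var <= 0:
        raise ValueError("phenotype_var must be positive")
    p = panel.freq[cvset.indices]
    contrib = effects.u**2 * 2.0 * p * (1.0 - p)
    if subset is not None:
        in_subset = subset.membership_mask(panel.m)[cvset.indices]
        contrib = contrib[in_subset]
    return float(contrib.sum() / phenotype_var)
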