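"""Synthetic genotype panels with controlled MAF spectrum and LD decay.

The generator emulates a dense livestock SNP panel: diploid dosages in
{0, 1, 2} on one (or several) synthetic chromosomes, a configurable minor
allele frequency spectrum covering 0.005-0.5, and linkage disequilibrium
that decays with physical distance.  Haplotypes are produced by a
first-order Markov "copy chain": the allele at each site is, with a
distance-dependent probability, maximally coupled to the allele at the
previous site (comonotone coupling given the two site frequencies) and
otherwise drawn independently.  Site frequencies are blockwise constant
(one spectrum draw per haplotype block), so neighbouring SNPs share a
frequency -- the prerequisite for high r^2 between binary variants --
while genome-wide the frequency distribution matches the requested
spectrum.  A fraction of sites are "young": they carry an independent,
predominantly rare frequency and couple only weakly to their block,
reproducing the empirical pattern that low-MAF variants sit in lower LD.

Quality control mirrors standard chip-data practice: variants are removed
for low minor allele frequency, low call rate, or departure from
Hardy-Weinberg equilibrium (1-df chi-square), in that order of precedence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats
from scipy.special import gammaln

MISSING = -1  # dosage code for a missing genotype

__all__ = [
    "MAFSpectrum",
    "GenotypePanel",
    "QCReport",
    "SubsetDefinition",
    "simulate_panel",
    "hwe_test",
    "apply_qc",
    "define_functional_subset",
    "define_random_subset",
]


class ParameterError(ValueError):
    """Invalid simulation or distribution parameters."""


@dataclass(frozen=True)
class MAFSpectrum:
    """Target distribution of allele frequencies on [lo, hi].

    ``kind="beta"`` maps a Beta(a, b) variate linearly onto [lo, hi];
    a < 1 with b >= 1 gives the familiar L/U-shaped spectrum with most
    mass at rare frequencies.  ``kind="uniform"`` is Beta(1, 1).
    """

    kind: str = "beta"
    a: float = 0.5
    b: float = 1.0
    lo: float = 0.005
    hi: float = 0.5

    def __post_init__(self) -> None:
        if self.kind not in ("beta", "uniform"):
            raise ParameterError(f"unknown spectrum kind {self.kind!r}")
        if not (0.0 < self.lo < self.hi <= 0.5):
            raise ParameterError(
                f"spectrum support [{self.lo}, {self.hi}] must satisfy 0 < lo < hi <= 0.5"
            )
        if self.kind == "beta" and (self.a <= 0 or self.b <= 0):
            raise ParameterError("beta spectrum needs a > 0 and b > 0")

    def ppf(self, u: np.ndarray) -> np.ndarray:
        """Quantile function: maps U(0,1) to a frequency in [lo, hi]."""
        u = np.asarray(u, dtype=float)
        if self.kind == "uniform":
            core = u
        else:
            core = stats.beta.ppf(u, self.a, self.b)
        return self.lo + (self.hi - self.lo) * core

    def cdf(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        core = np.clip((x - self.lo) / (self.hi - self.lo), 0.0, 1.0)
        if self.kind == "uniform":
            return core
        return stats.beta.cdf(core, self.a, self.b)


@dataclass
class GenotypePanel:
    """Individuals x variants dosage panel.

    dosages: int8 matrix, values in {0, 1, 2} or MISSING (-1) pre-QC.
    chrom: per-variant chromosome id (1-based).
    pos: per-variant bp coordinate, 1-based, strictly increasing within
        a chromosome.
    freq: per-variant frequency of the counted (A1) allele, computed
        from non-missing dosages.
    """

    dosages: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    freq: np.ndarray
    call_rate: np.ndarray
    variant_ids: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        self.chrom = np.asarray(self.chrom, dtype=np.int32)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.freq = np.asarray(self.freq, dtype=float)
        self.call_rate = np.asarray(self.call_rate, dtype=float)
        if self.variant_ids is None:
            self.variant_ids = np.array(
                [f"snp{c}_{p}" for c, p in zip(self.chrom, self.pos)], dtype=object
            )
        n, m = self.dosages.shape
        if not (len(self.chrom) == len(self.pos) == len(self.freq) == m):
            raise ValueError("per-variant metadata length mismatch")
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on chromosome {c}")

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def m(self) -> int:
        return self.dosages.shape[1]

    @property
    def maf(self) -> np.ndarray:
        """Minor allele frequency, the folded version of ``freq``."""
        return np.minimum(self.freq, 1.0 - self.freq)

    @property
    def is_complete(self) -> bool:
        return not np.any(self.dosages == MISSING)

    def take_variants(self, idx: np.ndarray) -> "GenotypePanel":
        idx = np.asarray(idx)
        return GenotypePanel(
            dosages=self.dosages[:, idx],
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            freq=self.freq[idx],
            call_rate=self.call_rate[idx],
            variant_ids=self.variant_ids[idx],
        )


@dataclass(frozen=True)
class QCReport:
    n_input: int
    n_removed_maf: int
    n_removed_callrate: int
    n_removed_hwe: int
    n_retained: int

    def __post_init__(self) -> None:
        total = (
            self.n_removed_maf
            + self.n_removed_callrate
            + self.n_removed_hwe
            + self.n_retained
        )
        if total != self.n_input:
            raise ValueError("QC accounting does not add up")


@dataclass(frozen=True)
class SubsetDefinition:
    """A named index set of variants (e.g. the 'functional' category)."""

    name: str
    indices: np.ndarray

    def __post_init__(self) -> None:
        idx = np.unique(np.asarray(self.indices, dtype=np.int64))
        if len(idx) != len(self.indices):
            raise ValueError("subset indices must be unique")
        object.__setattr__(self, "indices", idx)

    @property
    def size(self) -> int:
        return len(self.indices)

    def complement(self, m: int, name: Optional[str] = None) -> "SubsetDefinition":
        mask = np.ones(m, dtype=bool)
        mask[self.indices] = False
        return SubsetDefinition(name or f"not_{self.name}", np.flatnonzero(mask))

    def membership_mask(self, m: int) -> np.ndarray:
        mask = np.zeros(m, dtype=bool)
        mask[self.indices] = True
        return mask


# ---------------------------------------------------------------------------
# simulation


def _observed_freq(dosages: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(A1 allele frequency, call rate) from an int8 dosage matrix."""
    obs = dosages != MISSING
    n_obs = obs.sum(axis=0)
    allele_sum = np.where(obs, dosages, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_obs > 0, allele_sum / (2.0 * n_obs), np.nan)
    return freq, n_obs / dosages.shape[0]


def _jittered_positions(m: int, length_bp: int, rng: np.random.Generator) -> np.ndarray:
    """Strictly increasing 1-based positions: a jittered regular grid."""
    u = rng.uniform(0.05, 0.95, size=m)
    pos = np.floor((np.arange(m) + u) * (length_bp / m)).astype(np.int64) + 1
    # enforce strict monotonicity in pathological dense cases
    pos = np.maximum.accumulate(pos + np.arange(m) * 0)
    bad = np.flatnonzero(np.diff(pos) <= 0)
    while bad.size:
        pos[bad + 1] = pos[bad] + 1
        bad = np.flatnonzero(np.diff(pos) <= 0)
    return pos

def _block_field(
    pos: np.ndarray,
    split: "_YoungSplit",
    block_length_bp: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Blockwise-constant backbone frequencies from the block pool."""
    block = (pos // int(block_length_bp)).astype(np.int64)
    _, inverse = np.unique(block, return_inverse=True)
    n_blocks = inverse.max() + 1
    return split.draw_block(n_blocks, rng)[inverse]


class _YoungSplit:
    """Frequency pools for 'young' (low-LD) vs backbone sites.

    Young sites stand in for recent mutations, which are predominantly
    rare, so the young pool takes mass from the spectrum's tail below
    ``threshold`` first (fraction ``p_hi`` of it, capped at 1), spilling
    over above the threshold only if needed.  The backbone/block pool is
    the complementary reweighting, so the site-level mixture of the two
    pools reproduces the requested spectrum exactly.
    """

    def __init__(self, spectrum: MAFSpectrum, frac_young: float, threshold: float = 0.05):
        self.spectrum = spectrum
        self.frac = frac_young
        F_t = float(spectrum.cdf(threshold)) if frac_young > 0 else 0.0
        self.F_t = F_t
        if frac_young <= 0:
            self.p_hi = self.p_lo = 0.0
        else:
            self.p_hi = min(1.0, frac_young / F_t) if F_t > 0 else 0.0
            self.p_lo = (frac_young - self.p_hi * F_t) / (1.0 - F_t) if F_t < 1 else 0.0

    def _two_segment(self, k: int, mass_low: float, rng: np.random.Generator) -> np.ndarray:
        u = rng.uniform(size=k)
        v = rng.uniform(1e-12, 1 - 1e-12, size=k)
        below = u < mass_low
        quant = np.where(below, self.F_t * v, self.F_t + (1.0 - self.F_t) * v)
        return self.spectrum.ppf(quant)

    def draw_young(self, k: int, rng: np.random.Generator) -> np.ndarray:
        if self.frac <= 0:
            raise ValueError("no young pool configured")
        mass_low = self.p_hi * self.F_t / self.frac
        return self._two_segment(k, mass_low, rng)

    def draw_block(self, k: int, rng: np.random.Generator) -> np.ndarray:
        if self.frac <= 0:
            return self.spectrum.ppf(rng.uniform(1e-12, 1 - 1e-12, size=k))
        mass_low = (1.0 - self.p_hi) * self.F_t / (1.0 - self.frac)
        return self._two_segment(k, mass_low, rng)


def _attach_young_sites(
    H: np.ndarray,
    young_idx: np.ndarray,
    bg_idx: np.ndarray,
    freqs: np.ndarray,
    pos: np.ndarray,
    copy_scale_bp: float,
    rng: np.random.Generator,
) -> None:
    """Fill in 'young' sites, each coupled to its preceding backbone site.

    A young site carries a frequency unrelated to its haplotype block, so
    its correlation with neighbours is bounded by the frequency-mismatch
    cap of binary variants -- the low-LD behaviour of recent mutations.
    Coupling to a single anchor keeps the backbone chain intact.
    """
    n_hap = H.shape[0]
    anchor_of = np.searchsorted(bg_idx, young_idx) - 1
    for j, a in zip(young_idx, anchor_of):
        f_j = freqs[j]
        if a < 0:
            H[:, j] = rng.random(n_hap) < f_j
            continue
        b = bg_idx[a]
        f_b = freqs[b]
        q = np.exp(-(pos[j] - pos[b]) / copy_scale_bp)
        p_both = min(f_b, f_j)
        p1 = p_both / f_b
        p0 = (f_j - p_both) / (1.0 - f_b)
        u = rng.random(n_hap)
        coupled = np.where(H[:, b] == 1, u < p1, u < p0)
        independent = rng.random(n_hap) < f_j
        copy = rng.random(n_hap) < q
        H[:, j] = np.where(copy, coupled, independent)


def _copy_chain_haplotypes(
    n_hap: int,
    freqs: np.ndarray,
    pos: np.ndarray,
    copy_scale_bp: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Markov copy-chain haplotypes with exact per-site margins.

    At each step the allele is, with probability exp(-d/copy_scale_bp),
    drawn from the comonotone coupling with the previous site (maximal
    correlation compatible with the two margins), else independently.
    """
    m = len(freqs)
    H = np.empty((n_hap, m), dtype=np.int8)
    H[:, 0] = rng.random(n_hap) < freqs[0]
    if m == 1:
        return H
    q = np.exp(-np.diff(pos) / copy_scale_bp)
    for i in range(1, m):
        f_prev, f_cur = freqs[i - 1], freqs[i]
        p_both = min(f_prev, f_cur)
        p1 = p_both / f_prev  # P(cur=1 | prev=1) under comonotone coupling
        p0 = (f_cur - p_both) / (1.0 - f_prev)
        prev = H[:, i - 1] == 1
        u = rng.random(n_hap)
        coupled = np.where(prev, u < p1, u < p0)
        independent = rng.random(n_hap) < f_cur
        copy = rng.random(n_hap) < q[i - 1]
        H[:, i] = np.where(copy, coupled, independent)
    return H


def simulate_panel(
    n_individuals: int,
    n_variants: int,
    chrom_length_bp: int = 50_000_000,
    maf_spectrum: Optional[MAFSpectrum] = None,
    ld_decay_bp: float = 40_000.0,
    seed: int = 0,
    n_chromosomes: int = 1,
    missing_rate: float = 0.0,
    freq_block_bp: float = 250_000.0,
    frac_young: float = 0.15,
) -> GenotypePanel:
    """Simulate a diploid genotype panel with LD decaying over distance.

    Parameters
    ----------
    ld_decay_bp
        Distance at which the r^2 between a typical variant pair has
        decayed to ~0.5 (the conventional "LD decay distance").
    chrom_length_bp
        Length of each synthetic chromosome; variants are spread evenly
        (jittered grid) over ``n_chromosomes`` chromosomes.
    missing_rate
        Per-genotype probability of a missing call (pre-QC panels).
    freq_block_bp
        Length of the blocks over which the target allele frequency is
        constant (one independent spectrum draw per block).
    frac_young
        Fraction of sites drawing a fresh frequency unrelated to their
        block.  These behave like recent mutations: their LD with
        neighbours is capped by the frequency mismatch, which reproduces
        the empirical pattern that low-MAF variants sit in lower LD and
        hence receive larger LD weights.
    """
    if n_individuals < 1 or n_variants < 1:
        raise ParameterError("need at least one individual and one variant")
    if ld_decay_bp <= 0 or chrom_length_bp <= 0:
        raise ParameterError("length scales must be positive")
    if not 0.0 <= missing_rate < 1.0:
        raise ParameterError("missing_rate must be in [0, 1)")
    if not 0.0 <= frac_young < 1.0:
        raise ParameterError("frac_young must be in [0, 1)")
    spectrum = maf_spectrum if maf_spectrum is not None else MAFSpectrum()
    if not isinstance(spectrum, MAFSpectrum):
        raise ParameterError("maf_spectrum must be a MAFSpectrum")

    if freq_block_bp <= 0:
        raise ParameterError("freq_block_bp must be positive")
    # median r^2 at d: exp(-2d/L) = 0.5  ->  copy scale L = 2 d / ln 2
    copy_scale = 2.0 * ld_decay_bp / np.log(2.0)
    split = _YoungSplit(spectrum, frac_young)

    rng = np.random.default_rng(seed)
    per_chrom = np.full(n_chromosomes, n_variants // n_chromosomes, dtype=int)
    per_chrom[: n_variants % n_chromosomes] += 1

    blocks, chroms, positions, freqs_all = [], [], [], []
    for c, m_c in enumerate(per_chrom, start=1):
        if m_c == 0:
            continue
        pos = _jittered_positions(m_c, chrom_length_bp, rng)
        freqs = _block_field(pos, split, freq_block_bp, rng)
        young = rng.random(m_c) < frac_young
        if np.all(young):
            young[0] = False  # keep at least one backbone site
        bg_idx = np.flatnonzero(~young)
        young_idx = np.flatnonzero(young)
        H = np.empty((2 * n_individuals, m_c), dtype=np.int8)
        if len(young_idx):
            freqs[young_idx] = split.draw_young(len(young_idx), rng)
        H[:, bg_idx] = _copy_chain_haplotypes(
            2 * n_individuals, freqs[bg_idx], pos[bg_idx], copy_scale, rng
        )
        _attach_young_sites(H, young_idx, bg_idx, freqs, pos, copy_scale, rng)
        blocks.append(H[::2] + H[1::2])
        chroms.append(np.full(m_c, c, dtype=np.int32))
        positions.append(pos)
        freqs_all.append(freqs)
    dosages = np.concatenate(blocks, axis=1).astype(np.int8)
    if missing_rate > 0.0:
        miss = rng.random(dosages.shape) < missing_rate
        dosages[miss] = MISSING
    freq, call_rate = _observed_freq(dosages)
    return GenotypePanel(
        dosages=dosages,
        chrom=np.concatenate(chroms),
        pos=np.concatenate(positions),
        freq=freq,
        call_rate=call_rate,
    )


# ---------------------------------------------------------------------------
# quality control


def hwe_test(n_AA: int, n_Aa: int, n_aa: int, method: str = "chisq") -> float:
    """Hardy-Weinberg p-value: 1-df chi-square (default) or exact test.

    The chi-square flavour matches the PLINK-style thresholding workflow
    the QC defaults come from: expected genotype counts N*(p^2, 2pq, q^2)
    at the observed allele frequency.  ``method="exact"`` computes the
    conditional exact test (sum of heterozygote-count probabilities no
    more likely than the observed one, given the allele counts).
    Monomorphic variants return p = 1 by convention, so they are caught
    by the MAF filter rather than this test.
    """
    counts = np.array([n_AA, n_Aa, n_aa], dtype=float)
    if np.any(counts < 0):
        raise ValueError("genotype counts must be non-negative")
    total = counts.sum()
    if total == 0:
        raise ValueError("no observed genotypes")
    p = (2 * counts[0] + counts[1]) / (2 * total)
    if p in (0.0, 1.0):
        return 1.0
    if method == "chisq":
        expected = total * np.array([p**2, 2 * p * (1 - p), (1 - p) ** 2])
        statistic = np.sum((counts - expected) ** 2 / expected)
        return float(stats.chi2.sf(statistic, df=1))
    if method == "exact":
        return _hwe_exact(int(n_AA), int(n_Aa), int(n_aa))
    raise ValueError("method must be 'chisq' or 'exact'")


def _hwe_exact(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Conditional exact HWE p-value by direct enumeration.

    P(n_Aa | allele counts) ∝ n! / (n_AA! n_Aa! n_aa!) * 2^n_Aa; the
    p-value sums the probabilities of all heterozygote counts at most as
    likely as the observed one.
    """
    n = n_AA + n_Aa + n_aa
    n_a = 2 * n_AA + n_Aa  # minor-or-major allele count; symmetry below
    n_a = min(n_a, 2 * n - n_a)
    hets = np.arange(n_a % 2, n_a + 1, 2)
    homs_a = (n_a - hets) // 2
    homs_b = n - hets - homs_a
    logs = (
        hets * np.log(2.0)
        - gammaln(hets + 1)
        - gammaln(homs_a + 1)
        - gammaln(homs_b + 1)
    )
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    p_obs = probs[hets == n_Aa][0] if n_Aa in hets else 0.0
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def _hwe_pvalues(dosages: np.ndarray) -> np.ndarray:
    """Vectorised HWE chi-square p per variant, ignoring missing calls."""
    obs = dosages != MISSING
    n2 = ((dosages == 2) & obs).sum(axis=0).astype(float)
    n1 = ((dosages == 1) & obs).sum(axis=0).astype(float)
    n0 = ((dosages == 0) & obs).sum(axis=0).astype(float)
    total = n0 + n1 + n2
    with np.errstate(invalid="ignore", divide="ignore"):
        p = (2 * n2 + n1) / (2 * total)
        e2, e1, e0 = total * p**2, total * 2 * p * (1 - p), total * (1 - p) ** 2
        statistic = (n2 - e2) ** 2 / e2 + (n1 - e1) ** 2 / e1 + (n0 - e0) ** 2 / e0
    pval = stats.chi2.sf(statistic, df=1)
    mono = (p <= 0.0) | (p >= 1.0) | ~np.isfinite(statistic)
    return np.where(mono, 1.0, pval)


def apply_qc(
    panel: GenotypePanel,
    maf_min: float = 0.005,
    callrate_min: float = 0.90,
    hwe_alpha: float = 1e-6,
) -> tuple[GenotypePanel, QCReport]:
    """Standard chip QC: drop variants failing MAF, call-rate or HWE filters.

    A variant failing several filters is attributed to the first failed
    filter in the order MAF, call rate, HWE.  Missing dosages of surviving
    variants are imputed to the rounded mean dosage, so the returned panel
    is complete.
    """
    if panel.m == 0:
        raise ValueError("empty panel")
    freq, call_rate = _observed_freq(panel.dosages)
    maf = np.minimum(freq, 1.0 - freq)
    hwe_p = _hwe_pvalues(panel.dosages)

    fail_maf = ~(maf >= maf_min)  # NaN-frequency variants fail here too
    fail_cr = call_rate < callrate_min
    fail_hwe = hwe_p < hwe_alpha
    removed_maf = fail_maf
    removed_cr = fail_cr & ~removed_maf
    removed_hwe = fail_hwe & ~removed_maf & ~removed_cr
    keep = ~(removed_maf | removed_cr | removed_hwe)
    if not np.any(keep):
        raise ValueError("QC removed every variant: empty panel")

    dosages = panel.dosages[:, keep].copy()
    miss = dosages == MISSING
    if np.any(miss):
        kept_freq = freq[keep]
        fill = np.clip(np.rint(2.0 * kept_freq), 0, 2).astype(np.int8)
        dosages = np.where(miss, fill[np.newaxis, :], dosages)
    new_freq, new_cr = _observed_freq(dosages)
    clean = GenotypePanel(
        dosages=dosages,
        chrom=panel.chrom[keep],
        pos=panel.pos[keep],
        freq=new_freq,
        call_rate=new_cr,
        variant_ids=panel.variant_ids[keep],
    )
    report = QCReport(
        n_input=panel.m,
        n_removed_maf=int(removed_maf.sum()),
        n_removed_callrate=int(removed_cr.sum()),
        n_removed_hwe=int(removed_hwe.sum()),
        n_retained=int(keep.sum()),
    )
    return clean, report


# ---------------------------------------------------------------------------
# subsets


def define_functional_subset(
    panel: GenotypePanel,
    target_size: int,
    n_genes: Optional[int] = None,
    gene_length_bp: int = 250_000,
    seed: int = 0,
) -> SubsetDefinition:
    """SNPs falling in randomly placed gene-like intervals.

    Gene intervals of ``gene_length_bp`` are dropped uniformly on the
    genome until the union of contained SNPs reaches ``target_size``
    (within one gene's worth).  Emulates a category of SNPs mapped to
    genic regions, which is position-clustered rather than uniform.  The
    default interval length matches the haplotype-block scale of the
    synthetic genome: in livestock, genic regions span whole LD blocks,
    and a category that sliced through blocks would create artificial
    cross-category LD that real annotations do not have.
    """
    if not 0 < target_size <= panel.m:
        raise ValueError("target_size must be in (0, m]")
    if target_size == panel.m:
        return SubsetDefinition("functional", np.arange(panel.m))
    rng = np.random.default_rng(seed)
    density = panel.m / float(panel.pos.max() - panel.pos.min() + 1)
    per_gene = max(1.0, density * gene_length_bp)
    max_genes = n_genes if n_genes is not None else int(np.ceil(4 * target_size / per_gene)) + 8

    chrom_ids = np.unique(panel.chrom)
    selected = np.zeros(panel.m, dtype=bool)
    placed = 0
    while selected.sum() < target_size and placed < max_genes:
        c = chrom_ids[rng.integers(len(chrom_ids))]
        on_c = panel.chrom == c
        lo, hi = panel.pos[on_c].min(), panel.pos[on_c].max()
        start = rng.integers(lo, max(lo + 1, hi - gene_length_bp))
        in_gene = on_c & (panel.pos >= start) & (panel.pos < start + gene_length_bp)
        selected |= in_gene
        placed += 1
    size = int(selected.sum())
    if size < target_size - per_gene:
        raise ValueError(
            f"could not reach target_size={target_size} with {max_genes} genes "
            f"of {gene_length_bp} bp (got {size})"
        )
    return SubsetDefinition("functional", np.flatnonzero(selected))


def define_random_subset(
    panel: GenotypePanel, size: int, seed: int = 0, name: str = "nonfunctional"
) -> SubsetDefinition:
    """Uniform random variant subset without replacement."""
    if size > panel.m:
        raise ValueError(f"size {size} exceeds panel variant count {panel.m}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(panel.m, size=size, replace=False)
    return SubsetDefinition(name, idx)
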