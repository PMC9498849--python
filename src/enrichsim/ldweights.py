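"""LDAK-style per-SNP linkage-disequilibrium weights and LD diagnostics.

The genome is tiled into consecutive windows of a fixed kb length
(anchored at bp 1, half-open).  Within each window every SNP i receives

    w_i = 1 / sum_{i'} c(i, i')^2

where c(i, i')^2 is the squared Pearson correlation between dosage
vectors and the sum runs over the window's SNPs including i' = i, so
0 < w_i <= 1 with w_i = 1 for a SNP alone in its window.  SNPs in
high-LD regions are down-weighted.  Weights are normalised to mean one,
w*_i = w_i * m' / sum w, per window by default (m' = window SNP count).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import GenotypePanel

__all__ = ["LDWeights", "pairwise_r2", "compute_weights", "ld_decay_profile"]

#: LD-window lengths (kb) spanning sub-gene to multi-megabase scales.
DEFAULT_WINDOWS_KB = (1, 5, 50, 100, 500, 5000)


@dataclass(frozen=True)
class LDWeights:
    raw: np.ndarray
    normalized: np.ndarray
    window_kb: float
    window_assignment: np.ndarray
    m: int

    def __post_init__(self) -> None:
        if np.any(~np.isfinite(self.raw)) or np.any(~np.isfinite(self.normalized)):
            raise ValueError("non-finite LD weights")

    def thresholded(self, min_weight: float) -> "LDWeights":
        """Zero out normalised weights below ``min_weight``.

        Mimics pipelines that exclude near-zero-weight SNPs from the
        kinship; with the self-term convention raw weights are never
        exactly zero, so exclusion is by threshold.
        """
        norm = np.where(self.normalized < min_weight, 0.0, self.normalized)
        return LDWeights(self.raw, norm, self.window_kb, self.window_assignment, self.m)


def pairwise_r2(panel: GenotypePanel, i: int, j: int) -> float:
    """Squared Pearson correlation between two variants' dosage vectors."""
    x = panel.dosages[:, i].astype(float)
    y = panel.dosages[:, j].astype(float)
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        raise ValueError("zero-variance variant (monomorphic after QC?)")
    r = np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy)
    return float(r * r)


def _window_index(panel: GenotypePanel, window_kb: float) -> np.ndarray:
    """Half-open windows [k*W, (k+1)*W) anchored at bp 1, per chromosome."""
    w_bp = int(round(window_kb * 1000))
    local = (panel.pos - 1) // w_bp
    # offset so windows never straddle chromosomes
    key = panel.chrom.astype(np.int64) * (panel.pos.max() // w_bp + 2) + local
    _, idx = np.unique(key, return_inverse=True)
    return idx


def compute_weights(
    panel: GenotypePanel,
    window_kb: float,
    normalize: str = "window",
) -> LDWeights:
    """Inverse-sum-of-r^2 LD weights over fixed kb windows.

    normalize: "window" rescales weights to mean 1 within each window;
    "global" rescales once over the genome.
    """
    if window_kb <= 0:
        raise ValueError("window_kb must be positive")
    if normalize not in ("window", "global"):
        raise ValueError("normalize must be 'window' or 'global'")
    if not panel.is_complete:
        raise ValueError("panel has missing dosages; run QC first")
    assignment = _window_index(panel, window_kb)
    raw = np.empty(panel.m)
    norm = np.empty(panel.m)
    for w in np.unique(assignment):
        cols = np.flatnonzero(assignment == w)
        X = panel.dosages[:, cols].astype(float)
        sd = X.std(axis=0)
        if np.any(sd == 0):
            raise ValueError("zero-variance variant inside an LD window")
        R = np.corrcoef(X, rowvar=False)
        R = np.atleast_2d(R)
        w_i = 1.0 / (R**2).sum(axis=1)
        raw[cols] = w_i
        if normalize == "window":
            norm[cols] = w_i * len(cols) / w_i.sum()
    if normalize == "global":
        norm = raw * panel.m / raw.sum()
    return LDWeights(raw, norm, window_kb, assignment, panel.m)


def ld_decay_profile(
    panel: GenotypePanel,
    bin_edges_kb,
    max_pairs: int = 50_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean r^2 per physical-distance bin over randomly sampled SNP pairs.

    Returns one row per bin with the pair count and mean r^2 (NaN for
    empty bins).
    """
    if panel.m < 2:
        raise ValueError("need at least two variants")
    edges = np.asarray(bin_edges_kb, dtype=float) * 1000.0
    rng = np.random.default_rng(seed)
    X = panel.dosages.astype(float)
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0)

    i = rng.integers(0, panel.m, size=max_pairs)
    j = rng.integers(0, panel.m, size=max_pairs)
    ok = (i != j) & (panel.chrom[i] == panel.chrom[j]) & (sd[i] > 0) & (sd[j] > 0)
    i, j = i[ok], j[ok]
    dist = np.abs(panel.pos[i] - panel.pos[j]).astype(float)
    inside = (dist >= edges[0]) & (dist < edges[-1])
    i, j, dist = i[inside], j[inside], dist[inside]
    r = np.einsum("ni,ni->i", Xc[:, i], Xc[:, j]) / (panel.n * sd[i] * sd[j])
    r2 = r * r

    which = np.digitize(dist, edges) - 1
    rows = []
    for b in range(len(edges) - 1):
        sel = which == b
        rows.append(
            {
                "bin_lo_kb": edges[b] / 1000.0,
                "bin_hi_kb": edges[b + 1] / 1000.0,
                "n_pairs": int(sel.sum()),
                "mean_r2": float(r2[sel].mean()) if sel.any() else np.nan,
            }
        )
    return pd.DataFrame(rows)
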