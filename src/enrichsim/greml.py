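"""Restricted maximum likelihood for multi-kinship variance components.

Fits the linear mixed model

    y = X beta + sum_c g_c + e,   g_c ~ N(0, sigma2_c G_c),  e ~ N(0, sigma2_e I)

by average-information (AI) REML with EM fallback steps.  The restricted
log-likelihood is reported in the constant-free convention

    l_R = -1/2 [ log|V| + log|X' V^-1 X| + y' P y ],

with V = sum_c sigma2_c G_c + sigma2_e I and
P = V^-1 - V^-1 X (X' V^-1 X)^-1 X' V^-1.  Proposed AI steps are
accepted only if they do not decrease l_R (after step-halving); otherwise
an EM-type fixed-point step is tried.  Variances are clamped at a small
positive floor relative to var(y), with boundary hits flagged, so the
downstream heritability shares and enrichment folds are non-negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np
from scipy import linalg

from .grm import GRM

__all__ = ["MixedModelFit", "restricted_loglik", "reml_fit", "heritabilities"]

_FLOOR_FRAC = 1e-8  # variance floor as a fraction of var(y)


@dataclass
class MixedModelFit:
    sigma2_F: float
    sigma2_R: float
    sigma2_e: float
    beta_hat: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    se: np.ndarray
    at_boundary: np.ndarray
    loglik_path: list = field(default_factory=list)

    @property
    def variances(self) -> np.ndarray:
        return np.array([self.sigma2_F, self.sigma2_R, self.sigma2_e])

    def report(self) -> dict:
        """Machine-readable fit report."""
        return {
            "sigma2_F": self.sigma2_F,
            "sigma2_R": self.sigma2_R,
            "sigma2_e": self.sigma2_e,
            "se": list(map(float, self.se)),
            "loglik": self.loglik,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "at_boundary": list(map(bool, self.at_boundary)),
        }

    def __str__(self) -> str:
        lines = ["two-component REML fit"]
        for name, val, se in zip(
            ("sigma2_F", "sigma2_R", "sigma2_e"), self.variances, self.se
        ):
            lines.append(f"  {name:9s} {val:10.6g}  (SE {se:.4g})")
        lines.append(
            f"  loglik {self.loglik:.6f}  converged={self.converged}  iters={self.n_iter}"
        )
        return "\n".join(lines)


def _as_matrices(grms: Sequence[Union[GRM, np.ndarray]]) -> list[np.ndarray]:
    return [g.matrix if isinstance(g, GRM) else np.asarray(g, dtype=float) for g in grms]


def _vinv_pieces(y, X, Gs, variances):
    """Cholesky-based pieces: V^-1, P y, log|V|, log|X'V^-1X|, beta_hat."""
    n = len(y)
    V = variances[-1] * np.eye(n)
    for s2, G in zip(variances[:-1], Gs):
        V += s2 * G
    try:
        c, low = linalg.cho_factor(V, lower=True)
    except linalg.LinAlgError as err:
        raise ValueError(
            f"V not positive definite at variances {variances}; "
            f"condition estimate {np.linalg.cond(V):.3g}"
        ) from err
    logdet_V = 2.0 * np.sum(np.log(np.diag(c)))
    Vi = linalg.cho_solve((c, low), np.eye(n))
    ViX = Vi @ X
    XtViX = X.T @ ViX
    sign, logdet_X = np.linalg.slogdet(XtViX)
    if sign <= 0:
        raise ValueError("X' V^-1 X singular or indefinite (collinear covariates?)")
    XtViX_inv = np.linalg.inv(XtViX)
    beta = XtViX_inv @ (ViX.T @ y)
    P = Vi - ViX @ XtViX_inv @ ViX.T
    Py = P @ y
    return Vi, P, Py, beta, logdet_V, logdet_X


def restricted_loglik(
    y: np.ndarray,
    X: np.ndarray,
    grms: Sequence[Union[GRM, np.ndarray]],
    variances: Sequence[float],
) -> float:
    """Constant-free restricted log-likelihood at the given variances.

    ``variances`` lists one variance per kinship in ``grms`` followed by
    the residual variance.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Gs = _as_matrices(grms)
    variances = np.asarray(variances, dtype=float)
    if len(variances) != len(Gs) + 1:
        raise ValueError("need one variance per kinship plus a residual variance")
    _, _, Py, _, logdet_V, logdet_X = _vinv_pieces(y, X, Gs, variances)
    return float(-0.5 * (logdet_V + logdet_X + y @ Py))


def _em_step(variances, Gs_with_I, P, Py, n):
    """EM-type fixed-point update, positive by construction."""
    new = variances.copy()
    for c, G in enumerate(Gs_with_I):
        GPy = G @ Py
        quad = Py @ GPy
        tr = np.einsum("ij,ji->", P, G)
        if tr > 0 and quad > 0:
            new[c] = variances[c] * np.sqrt(quad / tr)
    return new


def reml_fit(
    y: np.ndarray,
    X: np.ndarray,
    grm_subset: Union[GRM, np.ndarray],
    grm_rest: Union[GRM, np.ndarray],
    init: Union[str, Sequence[float]] = "default",
    max_iter: int = 100,
    tol: float = 1e-6,
) -> MixedModelFit:
    """Two-kinship AI-REML fit (subset component, rest-of-genome, residual).

    Default initialisation puts half of var(y) in the residual and splits
    the remainder across the genetic components in proportion to their
    variant counts (equal split if counts are unavailable).
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(y):
        X = X.T
    n, p = X.shape
    if n <= p + 2:
        raise ValueError("need n > rank(X) + 2 observations")
    Gs = _as_matrices([grm_subset, grm_rest])
    Gs_with_I = Gs + [np.eye(n)]
    vary = float(np.var(y, ddof=1))
    floor = _FLOOR_FRAC * vary

    if isinstance(init, str):
        counts = []
        for g in (grm_subset, grm_rest):
            counts.append(g.n_variants_used if isinstance(g, GRM) else 1)
        share = np.asarray(counts, dtype=float) / sum(counts)
        variances = np.array([0.5 * vary * share[0], 0.5 * vary * share[1], 0.5 * vary])
    else:
        variances = np.asarray(init, dtype=float).copy()
        if len(variances) != 3:
            raise ValueError("init must provide three variances")
    variances = np.maximum(variances, floor)

    ll_path = []
    converged = False
    Vi = P = Py = beta = None
    AI = np.eye(3)
    for it in range(1, max_iter + 1):
        Vi, P, Py, beta, ldV, ldX = _vinv_pieces(y, X, Gs_with_I[:2], variances)
        ll = float(-0.5 * (ldV + ldX + y @ Py))
        ll_path.append(ll)

        # score and average-information matrix
        GPy = [G @ Py for G in Gs_with_I]
        score = np.array(
            [
                -0.5 * (np.einsum("ij,ji->", P, G) - Py @ gpy)
                for G, gpy in zip(Gs_with_I, GPy)
            ]
        )
        U = np.column_stack(GPy)
        AI = 0.5 * (U.T @ P @ U)

        # active set: components held at the floor while the score pushes down
        pinned = (variances <= floor * (1 + 1e-9)) & (score < 0)
        free = ~pinned
        if not np.any(free) or np.max(np.abs(score[free])) < 1e-10 * max(1.0, vary):
            converged = True
            break

        accepted = None
        try:
            delta = np.zeros(3)
            delta[free] = np.linalg.solve(AI[np.ix_(free, free)], score[free])
            hit = free & (variances + delta < floor)
            if np.any(hit) and np.any(free & ~hit):
                # re-solve with floor-bound components fixed (active-set step)
                sub = free & ~hit
                delta = np.zeros(3)
                delta[hit] = floor - variances[hit]
                delta[sub] = np.linalg.solve(AI[np.ix_(sub, sub)], score[sub])
        except np.linalg.LinAlgError:
            delta = None
        if delta is not None:
            step = 1.0
            for _ in range(6):  # step-halving safeguard
                prop = np.maximum(variances + step * delta, floor)
                try:
                    ll_new = restricted_loglik(y, X, Gs, prop)
                except ValueError:
                    ll_new = -np.inf
                if ll_new >= ll - 1e-10:
                    accepted = (prop, ll_new)
                    break
                step *= 0.5
        if accepted is None:  # EM fallback, monotone in practice
            prop = np.maximum(_em_step(variances, Gs_with_I, P, Py, n), floor)
            prop[pinned] = floor
            try:
                ll_new = restricted_loglik(y, X, Gs, prop)
            except ValueError:
                ll_new = -np.inf
            if ll_new >= ll - 1e-10:
                accepted = (prop, ll_new)
        if accepted is None:
            converged = True  # no improving direction left
            break

        new_variances, ll_new = accepted
        rel_ll = abs(ll_new - ll) / max(1.0, abs(ll))
        rel_par = np.max(np.abs(new_variances - variances)) / max(vary, 1e-12)
        variances = new_variances
        if rel_ll < tol and rel_par < 1e-6:
            converged = True
            ll_path.append(ll_new)
            break

    Vi, P, Py, beta, ldV, ldX = _vinv_pieces(y, X, Gs_with_I[:2], variances)
    ll = float(-0.5 * (ldV + ldX + y @ Py))
    if not ll_path or ll >= ll_path[-1] - 1e-9:
        ll_path.append(ll)
    GPy = [G @ Py for G in Gs_with_I]
    U = np.column_stack(GPy)
    AI = 0.5 * (U.T @ P @ U)
    try:
        se = np.sqrt(np.maximum(np.diag(np.linalg.inv(AI)), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(3, np.nan)
    return MixedModelFit(
        sigma2_F=float(variances[0]),
        sigma2_R=float(variances[1]),
        sigma2_e=float(variances[2]),
        beta_hat=beta,
        loglik=ll,
        converged=converged,
        n_iter=it if "it" in locals() else 0,
        se=se,
        at_boundary=variances <= floor * (1 + 1e-12),
        loglik_path=ll_path,
    )


def heritabilities(fit: MixedModelFit) -> tuple[float, float, float]:
    """(h2_subset, h2_rest, h2_total) as shares of total phenotypic variance.

    Valid on the heritability scale because the kinships are normalised
    to mean diagonal 1 before fitting.
    """
    total = fit.sigma2_F + fit.sigma2_R + fit.sigma2_e
    if total <= 0:
        raise ValueError("all variance components are zero")
    h2_f = fit.sigma2_F / total
    h2_r = fit.sigma2_R / total
    return h2_f, h2_r, h2_f + h2_r
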