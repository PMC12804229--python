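"""Restricted maximum likelihood for GRM-based variance components.

Fits ``y = X b + g + e`` with ``Var(g) = sum_i sigma_i^2 A_i`` and
``Var(e) = sigma_e^2 I`` by average-information REML with an EM-REML fallback
whenever an AI step fails to increase the restricted likelihood or leaves the
parameter space. Components are constrained to a small non-negative floor;
hitting the floor is flagged rather than hidden, since on small cohorts
constrained components are themselves a finding.

A multi-GRM call with MAF-bin GRMs gives a stratified (GREML-style)
partition of genetic variance; ``maf_bin_grms`` builds the bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import GenotypeMatrix
from .grm import GRM, compute_grm

__all__ = [
    "VarianceComponents",
    "RemlNonConvergence",
    "estimate_variance_components",
    "maf_bin_grms",
]


class RemlNonConvergence(RuntimeError):
    """Raised when REML fails to converge; carries the last iterate."""

    def __init__(self, message: str, components: np.ndarray, loglik: float):
        super().__init__(message)
        self.components = components
        self.loglik = loglik


@dataclass
class VarianceComponents:
    """REML estimates of genetic and residual variance.

    ``sigma_g2`` holds one entry per genetic component (one unless MAF-bin
    GRMs were supplied); ``h2`` is total genetic variance over total variance.
    """

    sigma_g2: np.ndarray
    sigma_e2: float
    se: np.ndarray  # SEs of (sigma_g2..., sigma_e2)
    h2: float
    h2_se: float
    loglik: float
    n_iter: int
    converged: bool
    constrained: np.ndarray  # flag per component, genetic then residual

    @property
    def total_genetic(self) -> float:
        return float(np.sum(self.sigma_g2))


def _reml_quantities(y, X, Vs, theta):
    """P y, log restricted likelihood and the projection pieces for theta."""
    n = y.size
    V = sum(t * Vi for t, Vi in zip(theta, Vs))
    L = np.linalg.cholesky(V)
    Vinv_y = np.linalg.solve(V, y)
    Vinv_X = np.linalg.solve(V, X)
    XtVinvX = X.T @ Vinv_X
    Lx = np.linalg.cholesky(XtVinvX)
    beta = np.linalg.solve(XtVinvX, X.T @ Vinv_y)
    Py = Vinv_y - Vinv_X @ beta
    logdet_V = 2.0 * np.sum(np.log(np.diag(L)))
    logdet_XVX = 2.0 * np.sum(np.log(np.diag(Lx)))
    ll = -0.5 * (logdet_V + logdet_XVX + float(y @ Py))
    return Py, V, Vinv_X, XtVinvX, ll


def _trace_P_A(V, Vinv_X, XtVinvX, A):
    """tr(P A) without forming P: tr(V^-1 A) - tr((X'V^-1X)^-1 X'V^-1 A V^-1 X)."""
    VinvA = np.linalg.solve(V, A)
    t1 = np.trace(VinvA)
    M = Vinv_X.T @ A @ Vinv_X
    t2 = np.trace(np.linalg.solve(XtVinvX, M))
    return t1 - t2


def estimate_variance_components(
    trait: np.ndarray,
    covariates: np.ndarray | None,
    grm: GRM | list[GRM],
    max_iter: int = 100,
    tol: float = 1e-6,
    raise_on_nonconvergence: bool = True,
) -> VarianceComponents:
    """AI-REML estimates of genetic and residual variance components.

    ``covariates`` (age, sex, PCs, ...) enter as fixed effects; an intercept
    is always included. Convergence is declared when the change in restricted
    log-likelihood falls below ``tol``.
    """
    y = np.asarray(trait, dtype=float)
    n = y.size
    grms = [grm] if isinstance(grm, GRM) else list(grm)
    for g in grms:
        if g.n != n:
            raise ValueError("GRM dimension does not match trait length")
    X = np.ones((n, 1))
    if covariates is not None and np.size(covariates):
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
        X = np.hstack([X, C])

    Vs = [g.matrix for g in grms] + [np.eye(n)]
    c = len(Vs)
    vary = float(np.var(y))
    floor = 1e-8 * vary
    theta = np.full(c, vary / c)
    # jitter the genetic covariances' diagonal for Cholesky robustness
    Vs = [Vi + 1e-9 * np.eye(n) if i < c - 1 else Vi for i, Vi in enumerate(Vs)]

    Py, V, Vinv_X, XtVinvX, ll = _reml_quantities(y, X, Vs, theta)
    converged = False
    n_iter = 0
    AI = np.eye(c)
    for n_iter in range(1, max_iter + 1):
        APy = [Vi @ Py for Vi in Vs]
        grad = np.array(
            [
                -0.5 * (_trace_P_A(V, Vinv_X, XtVinvX, Vi) - float(Py @ APy[i]))
                for i, Vi in enumerate(Vs)
            ]
        )
        # P A_i P y, reusing the projection
        PAPy = []
        for a in APy:
            Vinv_a = np.linalg.solve(V, a)
            PAPy.append(Vinv_a - Vinv_X @ np.linalg.solve(XtVinvX, Vinv_X.T @ a))
        AI = 0.5 * np.array([[float(APy[i] @ PAPy[j]) for j in range(c)] for i in range(c)])

        stepped = False
        try:
            delta = np.linalg.solve(AI, grad)
            # step-halving: back off the AI step until the likelihood ascends
            for shrink in (1.0, 0.5, 0.25, 0.1):
                cand = np.maximum(theta + shrink * delta, floor)
                out = _reml_quantities(y, X, Vs, cand)
                if np.isfinite(out[-1]) and out[-1] >= ll - 1e-10:
                    stepped = True
                    break
        except np.linalg.LinAlgError:
            pass
        if not stepped:  # EM-REML fallback: guaranteed ascent, slow
            cand = np.array(
                [
                    max(t + (t * t / n) * (float(Py @ APy[i]) - _trace_P_A(V, Vinv_X, XtVinvX, Vs[i])), floor)
                    for i, t in enumerate(theta)
                ]
            )
            out = _reml_quantities(y, X, Vs, cand)

        new_ll = out[-1]
        theta = cand
        Py, V, Vinv_X, XtVinvX = out[:4]
        if abs(new_ll - ll) < tol:
            ll = new_ll
            converged = True
            break
        ll = new_ll

    if not converged and raise_on_nonconvergence:
        raise RemlNonConvergence(
            f"REML did not converge in {max_iter} iterations", theta, ll
        )

    try:
        se = np.sqrt(np.maximum(np.diag(np.linalg.inv(AI)), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(c, np.nan)
    constrained = theta <= floor * (1.0 + 1e-6)
    sigma_g2 = theta[:-1]
    sigma_e2 = float(theta[-1])
    total = float(np.sum(theta))
    h2 = float(np.sum(sigma_g2) / total) if total > 0 else 0.0
    # delta-method SE of h2 = sg/(sg+se): gradient (se_tot, ..., -sg)/total^2
    try:
        cov = np.linalg.inv(AI)
        gvec = np.empty(c)
        sg = float(np.sum(sigma_g2))
        gvec[:-1] = sigma_e2 / total**2  # d h2 / d sigma_i
        gvec[-1] = -sg / total**2
        h2_se = float(np.sqrt(max(gvec @ cov @ gvec, 0.0)))
    except np.linalg.LinAlgError:
        h2_se = float("nan")
    return VarianceComponents(
        sigma_g2=sigma_g2,
        sigma_e2=sigma_e2,
        se=se,
        h2=min(max(h2, 0.0), 1.0),
        h2_se=h2_se,
        loglik=ll,
        n_iter=n_iter,
        converged=converged,
        constrained=constrained,
    )


def maf_bin_grms(genotypes: GenotypeMatrix, n_bins: int = 4) -> list[GRM]:
    """GRMs from MAF-quantile SNP bins, for stratified variance estimation."""
    p = genotypes.allele_frequencies()
    maf = np.minimum(p, 1.0 - p)
    edges = np.quantile(maf, np.linspace(0, 1, n_bins + 1))
    grms = []
    for b in range(n_bins):
        lo, hi = edges[b], edges[b + 1]
        mask = (maf >= lo) & (maf <= hi if b == n_bins - 1 else maf < hi)
        if mask.sum() == 0:
            continue
        grms.append(compute_grm(genotypes.subset(snps=mask)))
    return grms
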