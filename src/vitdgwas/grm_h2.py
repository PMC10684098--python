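"""Genomic relationship matrices and two-component REML heritability.

The heritability model fits two variance components simultaneously: a full
GRM (tagging SNP-based heritability from all genotyped relationships) and a
thresholded "bK" GRM in which entries below a relatedness cutoff (default
0.05) are zeroed, so that close relatives carry the extra pedigree-like
variance.  h2_SNP = sigma2_g / sigma2_P and h2_ped = (sigma2_g +
sigma2_bK) / sigma2_P.  The optimizer is average-information REML with EM
warm-up iterations and non-negativity clamping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.stats import norm

from .simdata import GenotypeMatrix


@dataclass
class GRM:
    values: np.ndarray          # n x n symmetric
    n_snps: int                 # SNPs used (uniform when no missingness)
    ids: np.ndarray

    def validate(self) -> None:
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("GRM not symmetric")


@dataclass
class VarCompFit:
    sigma2: np.ndarray          # one per GRM, residual last
    se: np.ndarray
    h2_snp: float
    h2_snp_se: float
    h2_ped: float
    h2_ped_se: float
    loglik: float
    converged: bool
    iterations: int


def compute_grm(genotypes: GenotypeMatrix, maf_min: float = 0.01) -> GRM:
    """GCTA-style GRM: A_jk = (1/m) sum_i (x_ij - 2p_i)(x_ik - 2p_i) / (2 p_i q_i).

    Frequencies are estimated in-sample; missing genotypes contribute their
    expectation (2p), i.e. zero on the standardized scale, and the per-pair
    SNP count is adjusted accordingly.
    """
    d = genotypes.dosages()
    p = np.nanmean(d, axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    keep = maf > maf_min
    if not keep.any():
        raise ValueError("no variant passes the MAF filter")
    d = d[:, keep]
    p = p[keep]
    z = (d - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    obs = ~np.isnan(z)
    z = np.where(obs, z, 0.0)
    a = z @ z.T
    if obs.all():
        counts = float(z.shape[1])
        a /= counts
    else:
        counts = obs.astype(float) @ obs.T.astype(float)
        a /= np.maximum(counts, 1.0)
    return GRM(values=a, n_snps=z.shape[1],
               ids=genotypes.samples["iid"].to_numpy())


def threshold_grm(grm: GRM, cutoff: float = 0.05) -> GRM:
    """Zero off-diagonal entries below the cutoff; keep the diagonal."""
    a = grm.values.copy()
    off = ~np.eye(a.shape[0], dtype=bool)
    a[off & (a < cutoff)] = 0.0
    return GRM(values=a, n_snps=grm.n_snps, ids=grm.ids)


def _reml_eval(theta, mats, y, x):
    """Return (P y, loglik, Vinv, P-related pieces) for current components."""
    n = y.size
    v = sum(t * m for t, m in zip(theta, mats))
    c, low = cho_factor(v, lower=True)
    logdet_v = 2.0 * np.log(np.diag(c)).sum()
    vinv_x = cho_solve((c, low), x)
    vinv_y = cho_solve((c, low), y)
    xtvx = x.T @ vinv_x
    cx = np.linalg.cholesky(xtvx)
    logdet_x = 2.0 * np.log(np.diag(cx)).sum()
    beta = np.linalg.solve(xtvx, x.T @ vinv_y)
    py = vinv_y - vinv_x @ beta
    ll = -0.5 * (logdet_v + logdet_x + float(y @ py))
    return py, ll, (c, low), vinv_x, xtvx


def _trace_pa(mats, cfac, vinv_x, xtvx):
    """tr(P A_i) for every component without forming P explicitly."""
    c, low = cfac
    n = vinv_x.shape[0]
    vinv = cho_solve((c, low), np.eye(n))
    w = np.linalg.solve(xtvx, vinv_x.T)        # (p, n)
    traces = []
    for m in mats:
        t = np.sum(vinv * m) - np.sum(vinv_x * (m @ w.T))
        traces.append(t)
    return np.array(traces)


def reml_two_component(y: np.ndarray, covariates: np.ndarray | None,
                       grms: list, max_iter: int = 100, tol: float = 1e-6,
                       em_steps: int = 3) -> VarCompFit:
    """AI-REML for V = sum_i sigma2_i A_i + sigma2_e I.

    ``grms`` may hold one GRM (plain GREML / the sparse-GRM null model) or
    two (full + bK-thresholded).  Components are clamped to
    [1e-6 * var(y), var(y)]; convergence is declared when the restricted
    log-likelihood changes by less than ``tol``.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if covariates is None:
        x = np.ones((n, 1))
    else:
        x = np.column_stack([np.ones(n), np.asarray(covariates, dtype=float)])
    mats = [g.values if isinstance(g, GRM) else np.asarray(g) for g in grms]
    mats.append(np.eye(n))
    k = len(mats)
    vary = y.var(ddof=1)
    floor, ceil = 1e-6 * vary, vary
    theta = np.full(k, vary / k)

    py, ll, cfac, vinv_x, xtvx = _reml_eval(theta, mats, y, x)
    converged = False
    it = 0
    ai = np.eye(k)
    for it in range(1, max_iter + 1):
        apy = [m @ py for m in mats]
        traces = _trace_pa(mats, cfac, vinv_x, xtvx)
        # P A_i P y, via a second projection of each A_i P y
        papy = [_project(cfac, vinv_x, xtvx, v) for v in apy]
        grad = np.array([-0.5 * (traces[i] - float(py @ apy[i]))
                         for i in range(k)])
        if it <= em_steps:
            ypapy = np.array([float(py @ apy[i]) for i in range(k)])
            theta_new = theta + theta ** 2 * (ypapy - traces) / n
        else:
            ai = np.empty((k, k))
            for i in range(k):
                for j in range(i, k):
                    ai[i, j] = ai[j, i] = 0.5 * float(apy[i] @ papy[j])
            try:
                step = np.linalg.solve(ai, grad)
            except np.linalg.LinAlgError:
                step = grad / np.maximum(np.diag(ai), 1e-12)
            theta_new = theta + step
        theta_new = np.clip(theta_new, floor, ceil)
        py_new, ll_new, cfac_new, vinv_x_new, xtvx_new = _reml_eval(
            theta_new, mats, y, x)
        # fall back to a damped step if the AI update lowered the likelihood
        shrink = 0
        while ll_new < ll - 1e-10 and shrink < 5 and it > em_steps:
            theta_new = 0.5 * (theta + theta_new)
            py_new, ll_new, cfac_new, vinv_x_new, xtvx_new = _reml_eval(
                theta_new, mats, y, x)
            shrink += 1
        delta = abs(ll_new - ll)
        theta, py, ll, cfac, vinv_x, xtvx = (theta_new, py_new, ll_new,
                                             cfac_new, vinv_x_new, xtvx_new)
        if it > em_steps and delta < tol:
            converged = True
            break

    # final AI matrix at the solution for standard errors
    apy = [m @ py for m in mats]
    papy = [_project(cfac, vinv_x, xtvx, v) for v in apy]
    ai = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            ai[i, j] = ai[j, i] = 0.5 * float(apy[i] @ papy[j])
    try:
        aiinv = np.linalg.inv(ai)
    except np.linalg.LinAlgError:
        aiinv = np.full((k, k), np.nan)
    se = np.sqrt(np.maximum(np.diag(aiinv), 0.0))

    total = theta.sum()
    h2_snp = theta[0] / total
    grad_snp = np.full(k, -theta[0] / total ** 2)
    grad_snp[0] += 1.0 / total
    h2_snp_se = float(np.sqrt(max(grad_snp @ aiinv @ grad_snp, 0.0)))
    if k >= 3:
        num = theta[0] + theta[1]
        h2_ped = num / total
        grad_ped = np.full(k, -num / total ** 2)
        grad_ped[0] += 1.0 / total
        grad_ped[1] += 1.0 / total
        h2_ped_se = float(np.sqrt(max(grad_ped @ aiinv @ grad_ped, 0.0)))
    else:
        h2_ped, h2_ped_se = h2_snp, h2_snp_se
    return VarCompFit(sigma2=theta, se=se, h2_snp=float(h2_snp),
                      h2_snp_se=h2_snp_se, h2_ped=float(h2_ped),
                      h2_ped_se=h2_ped_se, loglik=float(ll),
                      converged=converged, iterations=it)


def _project(cfac, vinv_x, xtvx, v):
    """Apply P = Vinv - Vinv X (X'Vinv X)^-1 X'Vinv to a vector v."""
    c, low = cfac
    vinv_v = cho_solve((c, low), v)
    beta = np.linalg.solve(xtvx, vinv_x.T @ v)
    return vinv_v - vinv_x @ beta


def estimate_difference_test(est1: float, se1: float, est2: float,
                             se2: float) -> tuple[float, float]:
    """Z-test of H0: est1 - est2 = 0, z = (est1-est2)/sqrt(se1^2+se2^2)."""
    if se1 <= 0 or se2 <= 0:
        raise ValueError("standard errors must be positive")
    z = (est1 - est2) / np.hypot(se1, se2)
    p = 2.0 * norm.sf(abs(z))
    return float(z), float(p)


def write_grm_tsv(grm: GRM, path) -> None:
    """Lower-triangle TSV: id1 id2 n_snps value."""
    n = len(grm.ids)
    rows = []
    for j in range(n):
        for i in range(j + 1):
            rows.append((grm.ids[j], grm.ids[i], grm.n_snps,
                         grm.values[j, i]))
    import pandas as pd
    pd.DataFrame(rows, columns=["id1", "id2", "n_snps", "value"]).to_csv(
        path, sep="\t", index=False)
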