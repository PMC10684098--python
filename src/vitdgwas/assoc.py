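"""Phenotype transformation, variant QC, and association testing.

Additive GWAS runs either ordinary least squares (per-variant multiple
regression on genotype plus covariates, computed through Frisch-Waugh
residualization so it is exactly the brute-force fit) or generalized least
squares with a sparse-GRM variance structure estimated once on the null
model — the fastGWA-style approximation to a per-variant mixed model.

Dominance GWAS fits genotype codings (0,1,2) and (0,1,0) jointly; this
design saturates the three genotype classes, so coefficients come in closed
form from class means.  The dominance term is tested with a 1-df Wald
chi-square.  Additive estimates from the joint fit are biased by the
non-orthogonal coding and are flagged non-reportable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import norm

from .grm_h2 import reml_two_component
from .simdata import GenotypeMatrix

ASSOC_COLUMNS = ["chrom", "pos", "id", "a1", "a2", "freq", "n",
                 "beta", "se", "p", "test"]


def rint(values) -> np.ndarray:
    """Rank-based inverse normal transform with the Blom (3/8) offset.

    Phi^-1((rank - 3/8) / (n + 1/4)); ties receive their average rank and
    missing values are preserved.
    """
    v = np.asarray(values, dtype=float)
    out = np.full(v.shape, np.nan)
    ok = ~np.isnan(v)
    x = v[ok]
    if x.size < 2:
        raise ValueError("need at least two non-missing values")
    if np.all(x == x[0]):
        raise ValueError("all values identical; ranks are degenerate")
    ranks = stats.rankdata(x, method="average")
    out[ok] = norm.ppf((ranks - 0.375) / (x.size + 0.25))
    return out


def hwe_chisq_p(n0: np.ndarray, n1: np.ndarray, n2: np.ndarray) -> np.ndarray:
    """1-df goodness-of-fit of genotype counts to p^2, 2pq, q^2."""
    n = n0 + n1 + n2
    with np.errstate(divide="ignore", invalid="ignore"):
        p = (2.0 * n0 + n1) / (2.0 * n)
        q = 1.0 - p
        e0, e1, e2 = n * p ** 2, 2.0 * n * p * q, n * q ** 2
        chi = ((n0 - e0) ** 2 / e0 + (n1 - e1) ** 2 / e1
               + (n2 - e2) ** 2 / e2)
    chi = np.where((e0 > 0) & (e1 > 0) & (e2 > 0), chi, 0.0)
    return stats.chi2.sf(chi, df=1)


def variant_qc(genotypes: GenotypeMatrix, maf_min: float = 0.01,
               hwe_p_min: float = 1e-6, miss_max: float = 0.05,
               n_smallest: int | None = None) -> tuple[np.ndarray, pd.DataFrame]:
    """Keep mask plus a per-variant report (freq, MAF, MAC, HWE p, missing).

    MAC is reported as MAF x 2N, with N the smallest analysis group when
    ``n_smallest`` is given (else the in-sample N).
    """
    d = genotypes.dosages()
    n_obs = np.sum(~np.isnan(d), axis=0)
    miss = 1.0 - n_obs / genotypes.n
    freq = np.where(n_obs > 0, np.nansum(d, axis=0) / (2.0 * np.maximum(n_obs, 1)), np.nan)
    maf = np.minimum(freq, 1.0 - freq)
    n_eff = n_smallest if n_smallest is not None else n_obs
    mac = maf * 2.0 * n_eff
    n0 = np.sum(d == 0, axis=0)
    n1 = np.sum(d == 1, axis=0)
    n2 = np.sum(d == 2, axis=0)
    hwe_p = hwe_chisq_p(n0.astype(float), n1.astype(float), n2.astype(float))
    keep = (maf > maf_min) & (hwe_p > hwe_p_min) & (miss < miss_max)
    report = pd.DataFrame({
        "id": genotypes.variants["id"].to_numpy(),
        "freq": freq, "maf": maf, "mac": mac,
        "hwe_p": hwe_p, "missing": miss, "keep": keep,
    })
    return keep, report


def _check_collinear(c: np.ndarray, names=None) -> None:
    q = np.linalg.matrix_rank(c)
    if q < c.shape[1]:
        # name the offending columns by leave-one-out rank probing
        names = names or [f"col{j}" for j in range(c.shape[1])]
        bad = [names[j] for j in range(c.shape[1])
               if np.linalg.matrix_rank(np.delete(c, j, axis=1)) == q]
        raise ValueError(f"collinear covariates: {bad}")


def _residualize(y: np.ndarray, g: np.ndarray, covariates) -> tuple:
    """Frisch-Waugh: residualize y and every genotype column on [1, C]."""
    n = y.size
    if covariates is None:
        c = np.ones((n, 1))
    else:
        c = np.column_stack([np.ones(n), np.asarray(covariates, dtype=float)])
        _check_collinear(c)
    q, _ = np.linalg.qr(c)
    y_r = y - q @ (q.T @ y)
    g_r = g - q @ (q.T @ g)
    return y_r, g_r, c.shape[1]


def additive_gwas(y: np.ndarray, genotypes: GenotypeMatrix,
                  covariates=None, mode: str = "ols",
                  grm=None) -> pd.DataFrame:
    """Per-variant additive association of a (typically RINT) phenotype.

    ``mode='ols'`` is an exact per-variant multiple regression.
    ``mode='gls'`` estimates (sigma2_g, sigma2_e) once on the null model
    with the supplied sparse GRM, then runs per-variant GLS with that V
    fixed; with a zero genetic component it coincides with OLS.
    """
    y = np.asarray(y, dtype=float)
    d = genotypes.dosages()
    col_means = np.nanmean(d, axis=0)
    freq = col_means / 2.0
    n_used = np.sum(~np.isnan(d), axis=0)
    d = np.where(np.isnan(d), col_means, d)

    if mode == "gls":
        if grm is None:
            raise ValueError("gls mode requires a GRM")
        fit = reml_two_component(y, covariates, [grm])
        v = fit.sigma2[0] * (grm.values if hasattr(grm, "values") else grm) \
            + fit.sigma2[1] * np.eye(y.size)
        from scipy.linalg import solve_triangular
        l = np.linalg.cholesky(v)
        y_w = solve_triangular(l, y, lower=True)
        d_w = solve_triangular(l, d, lower=True)
        ones = solve_triangular(l, np.ones(y.size), lower=True)
        if covariates is None:
            c_w = ones[:, None]
        else:
            c_w = solve_triangular(
                l, np.column_stack([np.ones(y.size),
                                    np.asarray(covariates, dtype=float)]),
                lower=True)
        q, _ = np.linalg.qr(c_w)
        y_r = y_w - q @ (q.T @ y_w)
        g_r = d_w - q @ (q.T @ d_w)
        k = c_w.shape[1]
    elif mode == "ols":
        y_r, g_r, k = _residualize(y, d, covariates)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    n = y.size
    sxx = np.einsum("ij,ij->j", g_r, g_r)
    sxy = g_r.T @ y_r
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = sxy / sxx
        rss = y_r @ y_r - beta * sxy
        df = n - k - 1
        se = np.sqrt(rss / df / sxx)
        z = beta / se
    p = 2.0 * norm.sf(np.abs(z))
    out = genotypes.variants[["chrom", "pos", "id", "a1", "a2"]].copy()
    out["freq"] = freq
    out["n"] = n_used
    out["beta"] = beta
    out["se"] = se
    out["p"] = np.clip(p, np.finfo(float).tiny, 1.0)
    out["test"] = "additive"
    return out


def dominance_gwas(y_resid: np.ndarray, genotypes: GenotypeMatrix) -> pd.DataFrame:
    """Joint additive (0,1,2) + dominance (0,1,0) fit per variant.

    The phenotype must already be residualized on confounders and
    RINT-transformed.  Because the design saturates the genotype classes,
    the fit equals the class-means model: b_add = (m2 - m0)/2 and
    b_dom = m1 - (m0 + m2)/2, with Var(b_dom) = s^2 (1/n1 + 1/(4 n0)
    + 1/(4 n2)) and s^2 the pooled within-class variance on n - 3 df.
    Variants lacking any of the three classes are flagged inestimable.
    """
    y = np.asarray(y_resid, dtype=float)
    d = genotypes.dosages()
    m = genotypes.m
    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    p = np.full(m, np.nan)
    chi2 = np.full(m, np.nan)
    flagged = np.zeros(m, dtype=bool)
    freq = np.nanmean(d, axis=0) / 2.0
    n_used = np.sum(~np.isnan(d), axis=0)
    for j in range(m):
        x = d[:, j]
        ok = ~np.isnan(x)
        xj, yj = np.rint(x[ok]).astype(int), y[ok]
        n0, n1, n2 = np.sum(xj == 0), np.sum(xj == 1), np.sum(xj == 2)
        if min(n0, n1, n2) == 0 or xj.size <= 3:
            flagged[j] = True
            continue
        m0, m1, m2 = yj[xj == 0].mean(), yj[xj == 1].mean(), yj[xj == 2].mean()
        sse = (np.sum((yj[xj == 0] - m0) ** 2) + np.sum((yj[xj == 1] - m1) ** 2)
               + np.sum((yj[xj == 2] - m2) ** 2))
        s2 = sse / (xj.size - 3)
        bd = m1 - 0.5 * (m0 + m2)
        var_bd = s2 * (1.0 / n1 + 0.25 / n0 + 0.25 / n2)
        if var_bd <= 0:
            flagged[j] = True
            continue
        beta[j] = bd
        se[j] = np.sqrt(var_bd)
        chi2[j] = bd ** 2 / var_bd
        p[j] = stats.chi2.sf(chi2[j], df=1)
    out = genotypes.variants[["chrom", "pos", "id", "a1", "a2"]].copy()
    out["freq"] = freq
    out["n"] = n_used
    out["beta"] = beta
    out["se"] = se
    out["p"] = np.clip(p, np.finfo(float).tiny, 1.0)
    out["chi2"] = chi2
    out["test"] = "dominance"
    out["inestimable"] = flagged
    return out


def _harmonize(records: pd.DataFrame, ref: pd.DataFrame) -> pd.DataFrame | None:
    """Align a stratum's records to the reference allele orientation."""
    merged = records.merge(ref[["id", "a1", "a2"]], on="id",
                           suffixes=("", "_ref"))
    same = (merged["a1"] == merged["a1_ref"]) & (merged["a2"] == merged["a2_ref"])
    flip = (merged["a1"] == merged["a2_ref"]) & (merged["a2"] == merged["a1_ref"])
    bad = ~(same | flip)
    if bad.any():
        import warnings
        warnings.warn(f"{int(bad.sum())} variants with unresolvable alleles "
                      "skipped in meta-analysis")
        merged = merged[~bad]
        same, flip = same[~bad], flip[~bad]
    merged.loc[flip, "beta"] = -merged.loc[flip, "beta"]
    merged.loc[flip, "freq"] = 1.0 - merged.loc[flip, "freq"]
    merged.loc[flip, ["a1", "a2"]] = merged.loc[flip, ["a2", "a1"]].to_numpy()
    return merged.drop(columns=["a1_ref", "a2_ref"])


def meta_ivw(records_by_stratum: list) -> pd.DataFrame:
    """Fixed-effect inverse-variance-weighted meta-analysis.

    beta_meta = sum(w_i b_i)/sum(w_i) with w_i = 1/se_i^2;
    se_meta = 1/sqrt(sum w_i).  Alleles are harmonized to the first
    stratum's orientation (flips negate beta); sample sizes add.
    """
    ref = records_by_stratum[0]
    if len(records_by_stratum) == 1:
        out = ref.copy()
        out["test"] = "meta"
        return out
    aligned = [ref] + [_harmonize(r, ref) for r in records_by_stratum[1:]]
    common = set(aligned[0]["id"])
    for a in aligned[1:]:
        common &= set(a["id"])
    aligned = [a[a["id"].isin(common)].sort_values("id").reset_index(drop=True)
               for a in aligned]
    w = np.array([1.0 / a["se"].to_numpy() ** 2 for a in aligned])
    b = np.array([a["beta"].to_numpy() for a in aligned])
    wsum = w.sum(axis=0)
    beta = (w * b).sum(axis=0) / wsum
    se = 1.0 / np.sqrt(wsum)
    z = beta / se
    out = aligned[0][["chrom", "pos", "id", "a1", "a2"]].copy()
    n_tot = np.sum([a["n"].to_numpy() for a in aligned], axis=0)
    f = np.array([a["freq"].to_numpy() for a in aligned])
    ns = np.array([a["n"].to_numpy() for a in aligned], dtype=float)
    out["freq"] = (f * ns).sum(axis=0) / ns.sum(axis=0)
    out["n"] = n_tot
    out["beta"] = beta
    out["se"] = se
    out["p"] = np.clip(2.0 * norm.sf(np.abs(z)), np.finfo(float).tiny, 1.0)
    out["test"] = "meta"
    return out.sort_values(["chrom", "pos"]).reset_index(drop=True)


def polygenic_score(genotypes: GenotypeMatrix, weights: pd.DataFrame) -> np.ndarray:
    """Weighted sum of effect-allele dosages.

    ``weights`` needs columns id, effect_allele, weight.  Missing genotypes
    contribute 2p times the weight (mean imputation); an effect allele equal
    to A2 flips the dosage.
    """
    vmap = {row["id"]: (j, row["a1"], row["a2"])
            for j, row in genotypes.variants.iterrows()}
    d = genotypes.dosages()
    col_means = np.nanmean(d, axis=0)
    d = np.where(np.isnan(d), col_means, d)
    score = np.zeros(genotypes.n)
    hits = 0
    for _, row in weights.iterrows():
        hit = vmap.get(row["id"])
        if hit is None:
            continue
        j, a1, a2 = hit
        if row["effect_allele"] == a1:
            dose = d[:, j]
        elif row["effect_allele"] == a2:
            dose = 2.0 - d[:, j]
        else:
            continue
        score += row["weight"] * dose
        hits += 1
    if hits == 0:
        raise ValueError("no overlap between weights and genotypes")
    return score
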