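"""Gene-by-skin-colour interaction testing via the vQTL framework.

Gene-environment interactions inflate the phenotypic variance within
genotype groups, so variants associated with trait *variance* (vQTLs) are
natural interaction candidates.  The pipeline: (1) pre-process the
phenotype within sex x supplement-intake strata (adjust for covariates,
drop outliers, standardize to mean 0 / variance 1, and record each
stratum's pre-standardization residual s.d. in nmol/L for unit
conversions); (2) screen variants for variance heterogeneity across the
three genotype groups with the median-centred Levene (Brown-Forsythe)
test; (3) fit y ~ g + e + g x e with mean-centred genotype and skin-colour
indicators against the very-fair reference, Bonferroni-corrected over the
vQTLs tested; (4) optionally scan the genome for interactions with one
two-level skin contrast at MAF > 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import norm

from .simdata import SKIN_LEVELS, GenotypeMatrix


@dataclass
class GeiFit:
    genotype_beta: float
    skin_betas: dict            # level -> main-effect coefficient (ref: very fair)
    gxe_betas: dict             # level -> interaction coefficient per A1 allele
    gxe_se: dict
    gxe_p: dict
    n: int
    residual_sd_nmol: float | None = None
    omitted_levels: list = field(default_factory=list)


def gei_preprocess(cohort: pd.DataFrame, covariates: list | None = None,
                   outlier_sd: float = 5.0
                   ) -> tuple[pd.Series, pd.DataFrame]:
    """Adjust and standardize the phenotype within sex x supplement strata.

    Within each stratum the phenotype is regressed on the covariates,
    residuals beyond ``outlier_sd`` standard deviations are dropped, and
    the survivors are re-standardized to mean 0, variance 1.  Returns the
    adjusted phenotype (NaN for dropped samples) and a stratum report with
    each stratum's pre-standardization residual s.d. in nmol/L.
    """
    covariates = covariates or ["age", "month", "centre"]
    adjusted = pd.Series(np.nan, index=cohort.index, name="vitd_adj")
    rows = []
    for (sex, supp), grp in cohort.groupby(["sex", "supplement"], observed=True):
        x_cols = []
        for c in covariates:
            col = grp[c]
            if col.dtype.kind in "OU" or str(col.dtype) == "category":
                x_cols.append(pd.get_dummies(col, drop_first=True, dtype=float))
            else:
                x_cols.append(col.astype(float))
        x = pd.concat(x_cols, axis=1).to_numpy(dtype=float)
        x = np.column_stack([np.ones(len(grp)), x])
        if len(grp) <= x.shape[1]:
            rows.append({"sex": sex, "supplement": supp, "n": len(grp),
                         "resid_sd_nmol": np.nan, "dropped": True,
                         "n_outliers": 0})
            continue
        y = grp["vitd"].to_numpy(dtype=float)
        coef, *_ = np.linalg.lstsq(x, y, rcond=None)
        resid = y - x @ coef
        sd = resid.std(ddof=1)
        keep = np.abs(resid - resid.mean()) <= outlier_sd * sd
        r = resid[keep]
        z = (r - r.mean()) / r.std(ddof=0)
        adjusted.loc[grp.index[keep]] = z
        rows.append({"sex": sex, "supplement": supp, "n": len(grp),
                     "resid_sd_nmol": sd, "dropped": False,
                     "n_outliers": int((~keep).sum())})
    report = pd.DataFrame(rows)
    report.attrs["mean_resid_sd_nmol"] = float(
        report.loc[~report["dropped"], "resid_sd_nmol"].mean())
    return adjusted, report


def vqtl_screen(y_adjusted: np.ndarray, genotypes: GenotypeMatrix
                ) -> pd.DataFrame:
    """Brown-Forsythe (median-centred Levene) variance-heterogeneity scan.

    Tests equality of phenotype variance across the genotype groups of each
    variant; single-group variants are skipped.
    """
    y = np.asarray(y_adjusted, dtype=float)
    d = genotypes.dosages()
    rows = []
    for j in range(genotypes.m):
        x = d[:, j]
        ok = ~(np.isnan(x) | np.isnan(y))
        xj = np.rint(x[ok]).astype(int)
        groups = [y[ok][xj == g] for g in (0, 1, 2)]
        groups = [g for g in groups if g.size >= 2]
        if len(groups) < 2:
            rows.append((genotypes.variants["id"].iloc[j], np.nan, np.nan, True))
            continue
        stat, p = stats.levene(*groups, center="median")
        rows.append((genotypes.variants["id"].iloc[j], stat, p, False))
    return pd.DataFrame(rows, columns=["id", "statistic", "p", "skipped"])


def gei_test(y_adjusted: np.ndarray, genotype: np.ndarray, skin: pd.Series,
             alpha_family: float = 0.05, n_tests: int = 25) -> tuple[GeiFit, bool]:
    """Fit y ~ g + e + g x e for one variant against ordinal skin colour.

    The genotype is mean-centred; skin enters as indicators with very fair
    as the reference.  The fit is judged family-wise significant when any
    interaction Wald p falls below ``alpha_family / n_tests``.
    """
    y = np.asarray(y_adjusted, dtype=float)
    g = np.asarray(genotype, dtype=float)
    skin = pd.Series(np.asarray(skin, dtype=object))
    ok = ~(np.isnan(y) | np.isnan(g))
    y, g, skin = y[ok], g[ok], skin[ok].reset_index(drop=True)
    g = g - g.mean()
    levels = [lv for lv in SKIN_LEVELS[1:]]
    present = [lv for lv in levels if (skin == lv).any()]
    omitted = [lv for lv in levels if lv not in present]
    cols = [np.ones(y.size), g]
    names = ["intercept", "g"]
    for lv in present:
        cols.append((skin == lv).to_numpy(dtype=float))
        names.append(f"e_{lv}")
    for lv in present:
        cols.append(g * (skin == lv).to_numpy(dtype=float))
        names.append(f"gxe_{lv}")
    x = np.column_stack(cols)
    xtx = x.T @ x
    coef = np.linalg.solve(xtx, x.T @ y)
    resid = y - x @ coef
    s2 = resid @ resid / (y.size - x.shape[1])
    cov = s2 * np.linalg.inv(xtx)
    se = np.sqrt(np.diag(cov))
    pvals = 2.0 * norm.sf(np.abs(coef / se))
    idx = {n: i for i, n in enumerate(names)}
    fit = GeiFit(
        genotype_beta=float(coef[idx["g"]]),
        skin_betas={lv: float(coef[idx[f"e_{lv}"]]) for lv in present},
        gxe_betas={lv: float(coef[idx[f"gxe_{lv}"]]) for lv in present},
        gxe_se={lv: float(se[idx[f"gxe_{lv}"]]) for lv in present},
        gxe_p={lv: float(pvals[idx[f"gxe_{lv}"]]) for lv in present},
        n=int(y.size),
        omitted_levels=omitted,
    )
    threshold = alpha_family / n_tests
    significant = any(p < threshold for p in fit.gxe_p.values())
    return fit, significant


def predicted_group_difference(skin_main: float, gxe_per_allele: float,
                               n_alleles: int) -> float:
    """Fitted between-skin-group difference at a given allele count.

    With main skin difference ``skin_main`` (s.d.) and per-allele
    interaction ``gxe_per_allele``, carrying ``n_alleles`` copies gives a
    difference of skin_main + n_alleles * gxe_per_allele.
    """
    return skin_main + n_alleles * gxe_per_allele


def gei_gwas(y_adjusted: np.ndarray, genotypes: GenotypeMatrix,
             skin: pd.Series, skin_pair: tuple, maf_min: float = 0.05,
             gws: float = 5e-8, suggestive: float = 1e-6) -> pd.DataFrame:
    """Genome-wide interaction scan for one two-level skin contrast.

    Restricted to samples in the two given skin levels and variants with
    MAF > ``maf_min``; per variant fits y ~ g + e + g x e and reports the
    interaction term.
    """
    if len(skin_pair) != 2:
        raise ValueError("skin_pair must name exactly two skin levels")
    ref, alt = skin_pair
    y = np.asarray(y_adjusted, dtype=float)
    skin = pd.Series(np.asarray(skin, dtype=object))
    in_pair = skin.isin([ref, alt]).to_numpy()
    keep = in_pair & ~np.isnan(y)
    y = y[keep]
    e = (skin[keep] == alt).to_numpy(dtype=float)
    d = genotypes.dosages()[keep]
    freq = np.nanmean(d, axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    rows = []
    v = genotypes.variants
    for j in range(genotypes.m):
        if not maf[j] > maf_min:
            continue
        g = d[:, j]
        ok = ~np.isnan(g)
        gj = g[ok] - g[ok].mean()
        yj, ej = y[ok], e[ok]
        x = np.column_stack([np.ones(gj.size), gj, ej, gj * ej])
        xtx = x.T @ x
        try:
            coef = np.linalg.solve(xtx, x.T @ yj)
        except np.linalg.LinAlgError:
            continue
        resid = yj - x @ coef
        s2 = resid @ resid / (gj.size - 4)
        cov = s2 * np.linalg.inv(xtx)
        se = np.sqrt(cov[3, 3])
        p = 2.0 * norm.sf(abs(coef[3] / se))
        rows.append((v["id"].iloc[j], v["a1"].iloc[j], freq[j],
                     coef[1], coef[2], coef[3], se, p, gj.size,
                     f"{ref} vs {alt}", p < gws, p < suggestive))
    return pd.DataFrame(rows, columns=[
        "SNP", "A1", "freq", "b_g", "b_e", "b_gxe", "se_gxe", "p_gxe", "n",
        "contrast", "gws", "suggestive"])


def sd_to_nmol(delta_sd: float, residual_sd_nmol: float) -> float:
    """Convert an effect in phenotype s.d. units to nmol/L (1-decimal)."""
    if residual_sd_nmol <= 0:
        raise ValueError("residual sd must be positive")
    return round(delta_sd * residual_sd_nmol, 1)
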