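"""Conditional-and-joint selection from GWAS summary statistics.

Given per-variant marginal statistics (the ``.ma`` layout: SNP A1 A2 freq b
se p N) and an LD reference panel, stepwise selection seeds with the most
significant genome-wide variant and iteratively adds the variant with the
smallest conditional p-value, provided it stays below the significance
threshold and is not collinear (multiple-regression R^2 with the selected
set below the cutoff).  Pairs farther apart than the window are treated as
uncorrelated.  The summary-based algebra reconstructs the multiple
regression of the phenotype on the selected set: with LD taken from the
GWAS sample itself, joint estimates coincide with an individual-level
multiple regression.

Also here: a conditional scan of all variants given a fixed set, and the
residual-based two-step conditional procedure used for dominance loci.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .assoc import dominance_gwas
from .simdata import GenotypeMatrix

MA_COLUMNS = ["SNP", "A1", "A2", "freq", "b", "se", "p", "N"]


@dataclass
class LDRef:
    """LD reference: genotype panel plus the windowed-correlation rule."""

    genotypes: GenotypeMatrix
    window_bp: float = 10e6
    _cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")
        v = self.genotypes.variants
        self.index = {s: j for j, s in enumerate(v["id"])}
        d = self.genotypes.dosages()
        mu = np.nanmean(d, axis=0)
        self._x = np.where(np.isnan(d), mu, d) - mu
        self._ss = np.einsum("ij,ij->j", self._x, self._x)
        self.pos = v["pos"].to_numpy()
        self.chrom = v["chrom"].to_numpy()
        self.nref = self.genotypes.n

    def has(self, snp: str) -> bool:
        return snp in self.index

    def variance(self, snp: str) -> float:
        """Sample variance (ddof=1) of the genotype in the reference."""
        j = self.index[snp]
        return self._ss[j] / (self.nref - 1)

    def cov(self, snps_a: list, snps_b: list) -> np.ndarray:
        """Reference genotype covariances with the window rule applied."""
        ja = [self.index[s] for s in snps_a]
        jb = [self.index[s] for s in snps_b]
        c = (self._x[:, ja].T @ self._x[:, jb]) / (self.nref - 1)
        pa, pb = self.pos[ja], self.pos[jb]
        ca, cb = self.chrom[ja], self.chrom[jb]
        far = (np.abs(pa[:, None] - pb[None, :]) > self.window_bp) | \
            (ca[:, None] != cb[None, :])
        c[far] = 0.0
        return c


@dataclass
class CojoResult:
    selected: pd.DataFrame      # SNP, b, se, p, bJ, seJ, pJ, var_explained
    log: pd.DataFrame           # iter, action, SNP, pJ
    var_y: float


def _reconstruct_var_y(sumstats: pd.DataFrame, ld: LDRef) -> float:
    """Median per-SNP reconstruction of the phenotypic variance.

    From a marginal regression with intercept, var(y) = D (b^2 +
    se^2 (N-2)) with D the genotype sample variance; the median over SNPs
    is robust to rows with atypical standard errors.
    """
    vals = []
    for _, r in sumstats.iterrows():
        if not ld.has(r["SNP"]):
            continue
        dvar = ld.variance(r["SNP"])
        n = r["N"]
        vals.append(dvar * (r["b"] ** 2 + r["se"] ** 2 * (n - 2)))
    if not vals:
        raise ValueError("no summary-statistic variant found in the LD reference")
    return float(np.median(vals))


def _joint_fit(snps: list, sumstats: pd.DataFrame, ld: LDRef,
               var_y: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Joint (bJ, seJ, pJ) of a set from summary stats + reference LD."""
    rows = sumstats.set_index("SNP").loc[snps]
    c = ld.cov(snps, snps)
    dvar = np.array([ld.variance(s) for s in snps])
    np.fill_diagonal(c, dvar)
    xty = rows["b"].to_numpy() * dvar
    bj = np.linalg.solve(c, xty)
    n_eff = float(rows["N"].min())
    k = len(snps)
    sigma2 = (var_y - bj @ xty) * (n_eff - 1) / (n_eff - k - 1)
    sigma2 = max(sigma2, 1e-12)
    cinv = np.linalg.inv(c)
    sej = np.sqrt(sigma2 * np.diag(cinv) / (n_eff - 1))
    pj = 2.0 * norm.sf(np.abs(bj / sej))
    return bj, sej, np.clip(pj, np.finfo(float).tiny, 1.0)


def _collinearity_r2(snp: str, selected: list, ld: LDRef) -> float:
    """Multiple-regression R^2 of the candidate on the selected set."""
    if not selected:
        return 0.0
    css = ld.cov(selected, selected)
    np.fill_diagonal(css, [ld.variance(s) for s in selected])
    cjs = ld.cov([snp], selected)[0]
    dj = ld.variance(snp)
    if dj <= 0:
        return 1.0
    try:
        r2 = float(cjs @ np.linalg.solve(css, cjs)) / dj
    except np.linalg.LinAlgError:
        return 1.0
    return r2


def cojo_select(sumstats: pd.DataFrame, ld_ref: LDRef,
                p_threshold: float = 5e-8, collinear_r2: float = 0.9
                ) -> CojoResult:
    """Stepwise conditional-and-joint model selection.

    Deterministic: ties in the minimum conditional p are broken by smaller
    genomic position, then lexicographic id.  Variants absent from the LD
    reference are skipped with a warning; no variant below the threshold
    yields an empty (non-error) result.
    """
    ss = sumstats.copy()
    missing = [s for s in ss["SNP"] if not ld_ref.has(s)]
    if missing:
        warnings.warn(f"{len(missing)} variants absent from the LD reference "
                      "were skipped")
        ss = ss[~ss["SNP"].isin(missing)]
    ss = ss.reset_index(drop=True)
    var_y = _reconstruct_var_y(ss, ld_ref)

    posmap = {s: ld_ref.pos[ld_ref.index[s]] for s in ss["SNP"]}

    def order_key(snp):
        return (posmap[snp], snp)

    log_rows = []
    selected: list[str] = []
    # seed: smallest marginal p below threshold
    cand = ss[ss["p"] < p_threshold]
    if cand.empty:
        return CojoResult(selected=pd.DataFrame(
            columns=["SNP", "b", "se", "p", "bJ", "seJ", "pJ",
                     "var_explained"]), log=pd.DataFrame(
            columns=["iter", "action", "SNP", "pJ"]), var_y=var_y)
    seed = min(cand.itertuples(), key=lambda r: (r.p, order_key(r.SNP)))
    selected.append(seed.SNP)
    log_rows.append((0, "seed", seed.SNP, seed.p))

    it = 0
    while True:
        it += 1
        remaining = [s for s in ss["SNP"] if s not in selected]
        best = None
        for snp in sorted(remaining, key=order_key):
            if _collinearity_r2(snp, selected, ld_ref) >= collinear_r2:
                continue
            trial = selected + [snp]
            bj, sej, pj = _joint_fit(trial, ss, ld_ref, var_y)
            p_cond = pj[-1]
            if p_cond < p_threshold and (best is None or p_cond < best[1]):
                best = (snp, p_cond)
        if best is None:
            break
        selected.append(best[0])
        log_rows.append((it, "add", best[0], best[1]))

    bj, sej, pj = _joint_fit(selected, ss, ld_ref, var_y)
    rows = ss.set_index("SNP").loc[selected]
    dvar = np.array([ld_ref.variance(s) for s in selected])
    out = pd.DataFrame({
        "SNP": selected,
        "b": rows["b"].to_numpy(), "se": rows["se"].to_numpy(),
        "p": rows["p"].to_numpy(),
        "bJ": bj, "seJ": sej, "pJ": pj,
        "var_explained": dvar * bj ** 2 / var_y,
    })
    out = out.sort_values("SNP", key=lambda s: s.map(posmap)).reset_index(drop=True)
    return CojoResult(selected=out,
                      log=pd.DataFrame(log_rows,
                                       columns=["iter", "action", "SNP", "pJ"]),
                      var_y=var_y)


def conditional_scan(sumstats: pd.DataFrame, ld_ref: LDRef,
                     condition_set: list, collinear_r2: float = 0.9
                     ) -> pd.DataFrame:
    """Per-variant effects conditioned on a fixed set of variants.

    Variants collinear with the conditioning set (R^2 >= cutoff, including
    any variant conditioned on itself) are flagged with no estimate.
    """
    if not condition_set:
        raise ValueError("condition_set must be non-empty")
    for s in condition_set:
        if not ld_ref.has(s):
            raise ValueError(f"conditioning variant {s} absent from LD reference")
    ss = sumstats[sumstats["SNP"].map(ld_ref.has)].reset_index(drop=True)
    var_y = _reconstruct_var_y(ss, ld_ref)
    rows = []
    for r in ss.itertuples():
        snp = r.SNP
        if snp in condition_set or \
                _collinearity_r2(snp, condition_set, ld_ref) >= collinear_r2:
            rows.append((snp, np.nan, np.nan, np.nan, True))
            continue
        bj, sej, pj = _joint_fit(condition_set + [snp], ss, ld_ref, var_y)
        rows.append((snp, bj[-1], sej[-1], pj[-1], False))
    out = pd.DataFrame(rows, columns=["SNP", "b_cond", "se_cond", "p_cond",
                                      "collinear"])
    out["test"] = "conditional"
    return out


def dominance_conditional(y_adjusted: np.ndarray, genotypes: GenotypeMatrix,
                          condition_snp: str, test_snps: list) -> pd.DataFrame:
    """Two-step conditional test for dominance signals.

    Step 1 residualizes the adjusted phenotype on both the additive (0,1,2)
    and dominance (0,1,0) codings of the conditioning SNP; step 2 re-runs
    the dominance test of the residuals on each test SNP.  A test SNP in
    near-perfect LD with the conditioning SNP is attenuated to the null.
    """
    v = genotypes.variants
    jc = v.index[v["id"] == condition_snp]
    if len(jc) == 0:
        raise ValueError(f"condition SNP {condition_snp} not found")
    jc = int(jc[0])
    d = genotypes.dosages()
    xc = d[:, jc]
    xc = np.where(np.isnan(xc), np.nanmean(xc), xc)
    if np.nanstd(xc) == 0:
        raise ValueError("condition SNP is monomorphic")
    za = xc - xc.mean()
    zd = (np.rint(xc) == 1).astype(float)
    zd -= zd.mean()
    x = np.column_stack([np.ones_like(za), za, zd])
    coef, *_ = np.linalg.lstsq(x, np.asarray(y_adjusted, float), rcond=None)
    resid = y_adjusted - x @ coef

    jt = [int(v.index[v["id"] == s][0]) for s in test_snps]
    sub = GenotypeMatrix(values=genotypes.values[:, jt],
                         variants=v.iloc[jt].reset_index(drop=True),
                         samples=genotypes.samples)
    out = dominance_gwas(resid, sub)
    out["condition_snp"] = condition_snp
    out["test"] = "conditional"
    return out
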