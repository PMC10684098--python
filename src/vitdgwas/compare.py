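"""Cross-population and cross-analysis effect comparison.

``rb`` estimates the correlation of *true* effect sizes between two sets of
estimates, de-attenuated for estimation error by subtracting the mean
squared standard error from each variance term:

    rb = cov(bx, by) / sqrt((var(bx) - mean(se_x^2)) (var(by) - mean(se_y^2)))

Its standard error comes from a leave-one-variant-out jackknife.  The
per-variant difference test is t = (b1 - b2)/sqrt(se1^2 + se2^2) against
the standard normal.  ``classify_loci`` labels independent loci of one GWAS
as shared / new / lost relative to another, with distance and LD
annotations against the other analysis's genome-wide-significant variants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm


@dataclass
class RbResult:
    rb: float
    se: float
    n_pairs: int
    flagged: bool  # |rb| beyond 1.05 — estimator noise warning


def _rb_point(bx, by, sex, sey):
    vx = np.var(bx, ddof=1) - np.mean(sex ** 2)
    vy = np.var(by, ddof=1) - np.mean(sey ** 2)
    if vx <= 0 or vy <= 0:
        side = "x" if vx <= 0 else "y"
        raise ValueError(
            f"no detectable effect-size variance on side {side}: "
            "var(b) - mean(se^2) <= 0")
    return np.cov(bx, by, ddof=1)[0, 1] / np.sqrt(vx * vy)


def rb(panel: pd.DataFrame) -> RbResult:
    """De-attenuated effect-size correlation with a jackknife se.

    ``panel`` needs columns b_x, se_x, b_y, se_y, aligned to the same
    effect allele per variant.
    """
    bx = panel["b_x"].to_numpy(float)
    by = panel["b_y"].to_numpy(float)
    sex = panel["se_x"].to_numpy(float)
    sey = panel["se_y"].to_numpy(float)
    if np.isnan(np.concatenate([bx, by, sex, sey])).any():
        raise ValueError("panel contains missing values")
    m = bx.size
    est = _rb_point(bx, by, sex, sey)
    jack = np.empty(m)
    keep = np.ones(m, dtype=bool)
    for i in range(m):
        keep[i] = False
        jack[i] = _rb_point(bx[keep], by[keep], sex[keep], sey[keep])
        keep[i] = True
    se = float(np.sqrt((m - 1) / m * np.sum((jack - jack.mean()) ** 2)))
    return RbResult(rb=float(est), se=se, n_pairs=m, flagged=abs(est) > 1.05)


def effect_difference_test(b1: float, se1: float, b2: float,
                           se2: float) -> tuple[float, float]:
    """t = (b1 - b2)/sqrt(se1^2 + se2^2); two-sided p from N(0,1)."""
    if se1 <= 0 or se2 <= 0:
        raise ValueError("standard errors must be positive")
    t = (b1 - b2) / np.hypot(se1, se2)
    return float(t), float(2.0 * norm.sf(abs(t)))


def _ld_r2(ld_ref, snp_a: str, snp_b: str) -> float:
    if ld_ref is None or not (ld_ref.has(snp_a) and ld_ref.has(snp_b)):
        return np.nan
    c = ld_ref.cov([snp_a], [snp_b])[0, 0]
    va, vb = ld_ref.variance(snp_a), ld_ref.variance(snp_b)
    if va <= 0 or vb <= 0:
        return np.nan
    return float(c ** 2 / (va * vb))


def _annotate(row, other_gws: pd.DataFrame, ld_ref, window_bp: float):
    """Distance and max LD r^2 to the nearest GWS variant of the other GWAS."""
    near = other_gws[(other_gws["chrom"] == row["chrom"]) &
                     (np.abs(other_gws["pos"] - row["pos"]) <= window_bp)]
    if near.empty:
        return np.nan, np.nan
    dist = (near["pos"] - row["pos"]).abs().min()
    r2s = [_ld_r2(ld_ref, row["id"], s) for s in near["id"]]
    r2s = [r for r in r2s if not np.isnan(r)]
    return float(dist), (max(r2s) if r2s else np.nan)


def classify_loci(loci_a: pd.DataFrame, loci_b: pd.DataFrame,
                  sumstats_a: pd.DataFrame, sumstats_b: pd.DataFrame,
                  ld_ref=None, gws: float = 5e-8, suggestive: float = 1e-6,
                  window_bp: float = 1e6) -> pd.DataFrame:
    """Label independent loci: shared, new (GWS in A only), lost (B only).

    ``loci_a``/``loci_b`` are the independent loci (e.g. COJO output) of
    each analysis with columns chrom, pos, id; ``sumstats_*`` carry the
    marginal p-values keyed by id for the cross-lookup.  New and lost loci
    are annotated with the distance and the maximum LD r^2 to the nearest
    GWS variant of the other analysis within the window; loci untested in
    the other analysis are labelled "untested".
    """
    pa = sumstats_a.set_index("id")["p"] if "id" in sumstats_a else \
        sumstats_a.set_index("SNP")["p"]
    pb = sumstats_b.set_index("id")["p"] if "id" in sumstats_b else \
        sumstats_b.set_index("SNP")["p"]
    gws_a = sumstats_a.rename(columns={"SNP": "id"})
    gws_a = gws_a[gws_a["p"] < gws]
    gws_b = sumstats_b.rename(columns={"SNP": "id"})
    gws_b = gws_b[gws_b["p"] < gws]

    rows = []
    for _, row in loci_a.iterrows():
        snp = row["id"]
        p_self = pa.get(snp, np.nan)
        p_other = pb.get(snp, np.nan)
        if np.isnan(p_other):
            label, sub = "new", "untested"
            dist, r2 = _annotate(row, gws_b, ld_ref, window_bp)
        elif p_other < gws:
            label, sub, dist, r2 = "shared", "", np.nan, np.nan
        else:
            label = "new"
            sub = ("no suggestive evidence" if p_other > suggestive
                   else "suggestive in other")
            dist, r2 = _annotate(row, gws_b, ld_ref, window_bp)
        rows.append((snp, row["chrom"], row["pos"], label, sub,
                     p_self, p_other, dist, r2))
    for _, row in loci_b.iterrows():
        snp = row["id"]
        p_other = pa.get(snp, np.nan)
        if not np.isnan(p_other) and p_other < gws:
            continue  # already covered as shared from A's side
        if np.isnan(p_other):
            sub = "untested"
        else:
            sub = ("no suggestive evidence" if p_other > suggestive
                   else "suggestive in other")
        dist, r2 = _annotate(row, gws_a, ld_ref, window_bp)
        rows.append((snp, row["chrom"], row["pos"], "lost", sub,
                     pb.get(snp, np.nan), p_other, dist, r2))
    return pd.DataFrame(rows, columns=[
        "id", "chrom", "pos", "label", "sublabel", "p_self", "p_other",
        "nearest_gws_bp", "max_ld_r2"])
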