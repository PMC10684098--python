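"""Permutation enrichment of SNP sets and analytic association power.

Enrichment: the observed count of test-set SNPs associated with at least
one queried trait is compared with the counts in random same-size sets
drawn without replacement from a candidate pool; the one-tailed empirical
p is the fraction of null sets with a count at least as large, with no
pseudo-count (so the smallest reportable value is 1/n_perm, reported
alongside).

Power: a quantitative-trait-locus association test is chi-square with 1 df
and non-centrality lambda = N h2_QTL / (1 - h2_QTL), where under
Hardy-Weinberg equilibrium h2_QTL = 2 p (1-p) beta^2 for allele frequency
p and per-allele effect beta in phenotype s.d. units.  Power at level
alpha is P(chi2_1(lambda) > q_alpha).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import ncx2, chi2


@dataclass
class EnrichSpec:
    test_set: list
    pool: list
    assoc_table: pd.DataFrame   # column "SNP" plus one p column per trait
    n_perm: int = 10_000
    threshold: float = 5e-8
    seed: int = 0

    def validate(self) -> None:
        universe = set(self.assoc_table["SNP"])
        if not set(self.test_set) <= universe:
            raise ValueError("test_set not contained in the association table")
        if len(self.test_set) > len(self.pool):
            raise ValueError("test_set larger than the sampling pool")


@dataclass
class EnrichResult:
    observed: int
    null_counts: np.ndarray
    p_empirical: float
    p_floor: float
    at_floor: bool


def enrichment_test(spec: EnrichSpec) -> EnrichResult:
    """One-tailed permutation enrichment for trait associations.

    A SNP "counts" when its minimum p across traits is below the
    threshold.  Null sets are drawn without replacement from the pool.
    """
    spec.validate()
    p_cols = [c for c in spec.assoc_table.columns if c != "SNP"]
    min_p = spec.assoc_table.set_index("SNP")[p_cols].min(axis=1)
    hit = (min_p < spec.threshold)
    observed = int(hit.loc[list(spec.test_set)].sum())
    rng = np.random.default_rng(spec.seed)
    pool = np.asarray(spec.pool)
    pool_hits = hit.reindex(pool).fillna(False).to_numpy()
    k = len(spec.test_set)
    counts = np.empty(spec.n_perm, dtype=int)
    for i in range(spec.n_perm):
        idx = rng.choice(pool.size, size=k, replace=False)
        counts[i] = int(pool_hits[idx].sum())
    p = float(np.sum(counts >= observed)) / spec.n_perm
    floor = 1.0 / spec.n_perm
    return EnrichResult(observed=observed, null_counts=counts,
                        p_empirical=p, p_floor=floor, at_floor=p == 0.0)


def qtl_h2(p: float, beta: float) -> float:
    """Variance explained by one QTL under HWE: 2 p (1-p) beta^2."""
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("allele frequency must be in (0, 1)")
    return 2.0 * p * (1.0 - p) * np.asarray(beta, dtype=float) ** 2


def ncp(n: float, h2_qtl: float) -> float:
    """Non-centrality parameter lambda = N h2 / (1 - h2)."""
    h2 = np.asarray(h2_qtl, dtype=float)
    if np.any(h2 >= 1.0) or np.any(h2 < 0.0):
        raise ValueError("h2_qtl must be in [0, 1)")
    return np.asarray(n, dtype=float) * h2 / (1.0 - h2)


def power(lam: float, alpha: float = 5e-8) -> float:
    """P(chi2_1(lambda) exceeds the central chi2_1 upper-alpha quantile)."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    lam = np.asarray(lam, dtype=float)
    if np.any(lam < 0.0):
        raise ValueError("lambda must be non-negative")
    q = chi2.isf(alpha, df=1)
    with np.errstate(all="ignore"):
        out = np.where(lam > 0, ncx2.sf(q, df=1, nc=np.maximum(lam, 1e-300)),
                       alpha)  # lambda = 0 gives the central test exactly
    return float(out) if out.ndim == 0 else out


def power_curve(variants: list, n_grid, alpha: float = 5e-8) -> pd.DataFrame:
    """Long-format (variant, N, power) over a sample-size grid.

    ``variants`` holds (p, beta) pairs or (id, p, beta) triples.
    """
    n_grid = list(n_grid)
    if not n_grid:
        raise ValueError("empty sample-size grid")
    rows = []
    for i, var in enumerate(variants):
        if len(var) == 3:
            vid, p, beta = var
        else:
            p, beta = var
            vid = f"variant{i}"
        h2 = qtl_h2(p, beta)
        for n in n_grid:
            rows.append((vid, n, float(power(ncp(n, h2), alpha))))
    return pd.DataFrame(rows, columns=["variant", "N", "power"])
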