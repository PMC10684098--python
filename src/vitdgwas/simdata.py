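"""Synthetic multi-ancestry cohorts with a known genetic architecture.

Every downstream stage of the pipeline (ancestry assignment, heritability,
additive/dominance association, conditional selection, interaction testing)
is exercised against cohorts generated here, where the true per-variant
effects are planted and recorded.

The generative model, in outline:

* allele frequencies follow the Balding-Nichols model: each ancestry draws
  its frequency from Beta(p(1-F)/F, (1-p)(1-F)/F) around a shared ancestral
  frequency p, so across-ancestry variance is F * p * (1-p);
* haplotypes carry block LD from an equicorrelated latent Gaussian (within a
  block every latent pair has correlation ``ld_rho``), thresholded at the
  frequency quantile; two haplotypes sum to a genotype, so Hardy-Weinberg
  holds within each ancestry;
* skin colour is an ordinal trait obtained by thresholding a latent
  liability combining designated pigmentation variants, principal
  components, and noise;
* the phenotype is a 25-hydroxyvitamin-D-like measurement in nmol/L:
  additive, dominance and genotype-by-skin-colour terms in phenotype-s.d.
  units, an ordinal skin-colour shift, a sinusoidal assessment-month
  component, small sex/age covariate effects, and Gaussian noise, mapped
  onto a plausible nmol/L location and scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

SKIN_LEVELS = ["very fair", "fair", "light olive", "dark olive", "brown", "black"]

# Default liability thresholds give roughly 11/68/15/4.5/1.4/0.1 percent per
# category, i.e. a light(very fair+fair) : darker split of about 79:21.
DEFAULT_SKIN_CUMPROBS = (0.11, 0.79, 0.94, 0.985, 0.999)

SUPPLEMENT_LEVELS = ["none", "other", "vitaminD", "missing"]

ASSAY_RANGE = (10.0, 375.0)


@dataclass
class SimConfig:
    """Knobs of the cohort generator.

    Effect sizes are in phenotype standard-deviation units; ``noise_sd`` is
    the residual standard deviation in nmol/L and also anchors the overall
    nmol/L scale of the trait.
    """

    n_per_ancestry: dict = field(default_factory=lambda: {"EUR": 1000})
    m_variants: int = 1000
    fst: dict = field(default_factory=dict)  # label -> F, default 0.1
    ld_block_size: int = 10
    ld_rho: float = 0.0
    causal_additive: list = field(default_factory=list)   # (index, beta_sd)
    causal_dominance: list = field(default_factory=list)  # (index, delta_sd)
    causal_gxe: list = field(default_factory=list)        # (index, beta_sd per skin level)
    skin_effect_sd: float = 0.0        # mean shift per ordinal skin level
    month_variance_frac: float = 0.0
    noise_sd: float = 18.8             # nmol/L
    baseline_nmol: float = 50.0
    related_pairs: int = 0
    missing_rate: float = 0.0
    # skin-colour liability composition
    skin_loci: list = field(default_factory=list)  # (index, liability weight)
    skin_pc_frac: float = 0.0          # liability variance from PCs
    skin_cumprobs: tuple = DEFAULT_SKIN_CUMPROBS
    seed: int = 0

    def validate(self) -> None:
        fracs = [self.month_variance_frac, self.skin_pc_frac]
        for f in fracs:
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"variance fraction {f} outside [0, 1]")
        if self.month_variance_frac > 1.0:
            raise ValueError("variance fractions exceed 1")
        for idx, _ in [*self.causal_additive, *self.causal_dominance,
                       *self.causal_gxe, *self.skin_loci]:
            if not 0 <= idx < self.m_variants:
                raise ValueError(f"causal index {idx} >= m_variants")
        if self.m_variants % self.ld_block_size:
            raise ValueError("ld_block_size must divide m_variants")
        for label, f in self.fst.items():
            if not 0.0 <= f < 1.0:
                raise ValueError(f"fst for {label} must be in [0, 1); 1 is degenerate")
        if not 0.0 <= self.ld_rho <= 1.0:
            raise ValueError("ld_rho outside [0, 1]")


@dataclass
class GenotypeMatrix:
    """Samples x variants counts of the A1 allele (-1 encodes missing)."""

    values: np.ndarray          # (n, m) int8
    variants: pd.DataFrame      # chrom, id, pos, a1, a2
    samples: pd.DataFrame       # iid, ancestry

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]

    def dosages(self) -> np.ndarray:
        """Float copy with missing as NaN."""
        d = self.values.astype(float)
        d[d < 0] = np.nan
        return d

    def freqs(self) -> np.ndarray:
        """In-sample frequency of A1 per variant (missing ignored)."""
        d = self.dosages()
        return np.nanmean(d, axis=0) / 2.0

    def validate(self) -> None:
        ok = np.isin(self.values, [-1, 0, 1, 2])
        if not ok.all():
            raise ValueError("genotype entries must be in {0,1,2} or missing")
        v = self.variants
        for _, grp in v.groupby("chrom"):
            if not grp["pos"].is_monotonic_increasing:
                raise ValueError("positions must increase within chromosome")
        if (v["a1"] == v["a2"]).any():
            raise ValueError("A1 must differ from A2")


@dataclass
class TruthRecord:
    """Planted generative parameters, one entry per variant (zeros if null)."""

    beta_a: np.ndarray
    beta_d: np.ndarray
    beta_gxe: np.ndarray
    h2_snp: float
    skin_effect_sd: float
    month_amplitude: float
    seed: int

    def frame(self, variant_ids) -> pd.DataFrame:
        return pd.DataFrame({
            "id": variant_ids,
            "beta_a": self.beta_a,
            "beta_d": self.beta_d,
            "beta_gxe": self.beta_gxe,
        })


def simulate_frequencies(config: SimConfig, ancestral: np.ndarray | None = None,
                         rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Per-ancestry allele frequencies under the Balding-Nichols model.

    Returns a DataFrame indexed by ancestry label with one column per
    variant.  ``fst -> 0`` collapses every row onto the ancestral frequency.
    """
    config.validate()
    rng = rng or np.random.default_rng(config.seed)
    m = config.m_variants
    if ancestral is None:
        ancestral = rng.uniform(0.05, 0.95, size=m)
    rows = {}
    for label in config.n_per_ancestry:
        f = config.fst.get(label, 0.1)
        if f >= 1.0:
            raise ValueError("fst = 1 gives a degenerate Beta distribution")
        if f <= 0.0:
            rows[label] = ancestral.copy()
        else:
            a = ancestral * (1.0 - f) / f
            b = (1.0 - ancestral) * (1.0 - f) / f
            p = rng.beta(a, b)
            rows[label] = np.clip(p, 1e-4, 1.0 - 1e-4)
    return pd.DataFrame(rows).T


def _haplotypes(freq: np.ndarray, n_hap: int, block: int, rho: float,
                rng: np.random.Generator) -> np.ndarray:
    """Haplotype alleles from an equicorrelated latent Gaussian per block."""
    m = freq.size
    if rho <= 0.0:
        z = rng.standard_normal((n_hap, m))
    else:
        n_blocks = m // block
        shared = np.repeat(rng.standard_normal((n_hap, n_blocks)), block, axis=1)
        eps = rng.standard_normal((n_hap, m))
        z = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * eps
    return (z < norm.ppf(freq)).astype(np.int8)


def simulate_genotypes(freqs: pd.DataFrame, config: SimConfig,
                       rng: np.random.Generator | None = None) -> GenotypeMatrix:
    """Genotypes per ancestry with block LD; two haplotypes per sample.

    Related pairs (``config.related_pairs``) are appended inside the first
    ancestry group: the second member of each pair reuses the first member's
    maternal haplotype, which gives an expected genomic relationship of 0.5
    (a parent-offspring-like pair).
    """
    config.validate()
    rng = rng or np.random.default_rng(config.seed + 1)
    m = config.m_variants
    if m == 0 or sum(config.n_per_ancestry.values()) == 0:
        raise ValueError("need at least one sample and one variant")

    blocks = []
    sample_rows = []
    for label, n in config.n_per_ancestry.items():
        p = freqs.loc[label].to_numpy()
        h1 = _haplotypes(p, n, config.ld_block_size, config.ld_rho, rng)
        h2 = _haplotypes(p, n, config.ld_block_size, config.ld_rho, rng)
        blocks.append(h1 + h2)
        sample_rows += [(f"{label}_{i:05d}", label) for i in range(n)]

    if config.related_pairs:
        label = next(iter(config.n_per_ancestry))
        p = freqs.loc[label].to_numpy()
        k = config.related_pairs
        shared = _haplotypes(p, k, config.ld_block_size, config.ld_rho, rng)
        own = _haplotypes(p, 2 * k, config.ld_block_size, config.ld_rho, rng)
        sibs = np.vstack([shared + own[:k], shared + own[k:]])
        blocks.append(sibs.astype(np.int8))
        sample_rows += [(f"{label}_relA_{i:04d}", label) for i in range(k)]
        sample_rows += [(f"{label}_relB_{i:04d}", label) for i in range(k)]

    values = np.vstack(blocks).astype(np.int8)
    if config.missing_rate > 0.0:
        mask = rng.random(values.shape) < config.missing_rate
        values[mask] = -1

    variants = pd.DataFrame({
        "chrom": np.ones(m, dtype=int),
        "id": [f"snp{i:06d}" for i in range(m)],
        "pos": np.arange(1, m + 1) * 10_000,  # 10-kb spacing, 1-based
        "a1": ["A"] * m,
        "a2": ["G"] * m,
    })
    samples = pd.DataFrame(sample_rows, columns=["iid", "ancestry"])
    return GenotypeMatrix(values=values, variants=variants, samples=samples)


def simulate_skin_colour(genotypes: GenotypeMatrix, pcs: np.ndarray | None,
                         config: SimConfig,
                         rng: np.random.Generator | None = None,
                         return_liability: bool = False):
    """Ordinal skin colour from a thresholded latent liability.

    Liability = weighted pigmentation genotypes + PC component + noise,
    standardized, then cut at the configured cumulative-probability
    thresholds.  ``skin_pc_frac`` sets the liability variance fraction
    carried by the supplied PCs.
    """
    rng = rng or np.random.default_rng(config.seed + 2)
    n = genotypes.n
    liab = np.zeros(n)
    if config.skin_loci:
        d = genotypes.dosages()
        for idx, w in config.skin_loci:
            x = d[:, idx]
            x = np.where(np.isnan(x), np.nanmean(x), x)
            sd = x.std()
            if sd > 0:
                liab += w * (x - x.mean()) / sd
    g_var = liab.var()
    if pcs is not None and config.skin_pc_frac > 0:
        pc = pcs[:, 0] - pcs[:, 0].mean()
        sd = pc.std()
        if sd == 0:
            raise ValueError("PC1 has zero variance")
        liab += np.sqrt(config.skin_pc_frac) * pc / sd
    resid_frac = max(1.0 - g_var - config.skin_pc_frac, 0.0)
    liab += np.sqrt(resid_frac) * rng.standard_normal(n)
    sd = liab.std()
    if sd > 0:
        liab = (liab - liab.mean()) / sd
    cuts = norm.ppf(np.asarray(config.skin_cumprobs))
    if not np.all(np.diff(cuts) > 0):
        raise ValueError("skin thresholds must be strictly increasing")
    idx = np.searchsorted(cuts, liab)
    skin = pd.Series(pd.Categorical.from_codes(idx, categories=SKIN_LEVELS,
                                               ordered=True), name="skin")
    return (skin, liab) if return_liability else skin


def simulate_phenotype(genotypes: GenotypeMatrix, skin: pd.Series,
                       config: SimConfig,
                       rng: np.random.Generator | None = None
                       ) -> tuple[pd.DataFrame, TruthRecord]:
    """Assemble the 25OHD-like phenotype and its covariates.

    On the standardized scale the systematic part is
    ``sum beta_a (x - 2p) + sum beta_d (z - 2pq) + skin shift
    + sum beta_gxe x_c e + month sinusoid + covariates``; noise brings the
    total variance to ~1, and the trait is mapped to nmol/L with the
    configured baseline and residual scale.
    """
    config.validate()
    rng = rng or np.random.default_rng(config.seed + 3)
    n, m = genotypes.n, genotypes.m
    d = genotypes.dosages()
    col_means = np.nanmean(d, axis=0)
    d = np.where(np.isnan(d), col_means, d)

    beta_a = np.zeros(m)
    beta_d = np.zeros(m)
    beta_g = np.zeros(m)
    y = np.zeros(n)
    explained = 0.0

    for idx, b in config.causal_additive:
        beta_a[idx] = b
        x = d[:, idx]
        y += b * (x - x.mean())
        explained += b ** 2 * x.var()
    for idx, delta in config.causal_dominance:
        beta_d[idx] = delta
        z = (np.rint(d[:, idx]) == 1).astype(float)
        y += delta * (z - z.mean())
        explained += delta ** 2 * z.var()

    skin_codes = skin.cat.codes.to_numpy().astype(float)
    e = skin_codes - skin_codes.mean()
    if config.skin_effect_sd:
        y += config.skin_effect_sd * e
        explained += config.skin_effect_sd ** 2 * e.var()
    for idx, b in config.causal_gxe:
        beta_g[idx] = b
        x = d[:, idx] - d[:, idx].mean()
        term = b * x * e
        y += term - term.mean()
        explained += term.var()

    month = rng.integers(1, 13, size=n)
    amp = np.sqrt(2.0 * config.month_variance_frac)
    month_term = amp * np.cos(2 * np.pi * (month - 7) / 12.0)
    y += month_term - month_term.mean()
    explained += config.month_variance_frac

    sex = rng.integers(0, 2, size=n)              # 0 female, 1 male
    age = rng.integers(40, 70, size=n).astype(float)
    y += 0.05 * (sex - sex.mean())                # small fixed covariate effects
    y -= 0.005 * (age - age.mean())
    explained += 0.05 ** 2 * 0.25 + (0.005 * age.std()) ** 2

    resid_frac = max(1.0 - explained, 0.05)
    y += np.sqrt(resid_frac) * rng.standard_normal(n)

    scale = config.noise_sd / np.sqrt(resid_frac)
    vitd = config.baseline_nmol + scale * y

    geno_value = d @ beta_a
    gv = geno_value - geno_value.mean()
    vary = y.var()
    h2_snp = gv.var() / vary if vary > 0 else 0.0

    centre = rng.integers(0, 5, size=n)
    supplement = np.asarray(SUPPLEMENT_LEVELS)[
        rng.choice(4, size=n, p=[0.55, 0.25, 0.15, 0.05])]

    cohort = pd.DataFrame({
        "iid": genotypes.samples["iid"].to_numpy(),
        "vitd": vitd,
        "skin": skin.to_numpy(),
        "sex": np.where(sex == 1, "male", "female"),
        "age": age,
        "month": month,
        "supplement": supplement,
        "centre": centre,
        "ancestry": genotypes.samples["ancestry"].to_numpy(),
    })
    lo, hi = ASSAY_RANGE
    cohort["assay_excluded"] = (cohort["vitd"] < lo) | (cohort["vitd"] > hi)

    truth = TruthRecord(beta_a=beta_a, beta_d=beta_d, beta_gxe=beta_g,
                        h2_snp=h2_snp, skin_effect_sd=config.skin_effect_sd,
                        month_amplitude=amp, seed=config.seed)
    return cohort, truth


def simulate_cohort(config: SimConfig,
                    ancestral: np.ndarray | None = None
                    ) -> tuple[GenotypeMatrix, pd.DataFrame, TruthRecord, pd.DataFrame]:
    """One-call convenience: frequencies -> genotypes -> skin -> phenotype."""
    rng = np.random.default_rng(config.seed)
    freqs = simulate_frequencies(config, ancestral=ancestral, rng=rng)
    geno = simulate_genotypes(freqs, config, rng=rng)
    skin = simulate_skin_colour(geno, None, config, rng=rng)
    cohort, truth = simulate_phenotype(geno, skin, config, rng=rng)
    return geno, cohort, truth, freqs


def summarize_cohort(cohort: pd.DataFrame,
                     deficiency_threshold: float = 25.0) -> pd.DataFrame:
    """Per-ancestry mean/median 25OHD and deficiency prevalence (< threshold)."""
    rows = []
    for label, grp in cohort.groupby("ancestry", observed=True):
        v = grp["vitd"]
        if len(v) == 0:
            rows.append({"ancestry": label, "n": 0, "mean": np.nan,
                         "median": np.nan, "prevalence": np.nan,
                         "undefined": True})
            continue
        rows.append({
            "ancestry": label,
            "n": len(v),
            "mean": v.mean(),
            "median": v.median(),
            "prevalence": float((v < deficiency_threshold).mean()),
            "undefined": False,
        })
    return pd.DataFrame(rows)


COHORT_COLUMNS = ["iid", "vitd", "skin", "sex", "age", "month",
                  "supplement", "centre", "ancestry"]


def write_cohort_tsv(cohort: pd.DataFrame, path) -> None:
    cohort[COHORT_COLUMNS].rename(columns={"iid": "IID"}).to_csv(
        path, sep="\t", index=False)


def write_truth_tsv(truth: TruthRecord, variant_ids, path) -> None:
    truth.frame(variant_ids).to_csv(path, sep="\t", index=False)
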