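"""Skin-colour-stratified GWAS with inverse-variance meta-analysis.

Samples are split into a light stratum (very fair + fair) and a dark
stratum (light olive, dark olive, brown); samples reporting black skin or
giving inconsistent skin-colour answers across visits are excluded.  Each
stratum gets its own GWAS — phenotype RINT-transformed within the stratum
and principal components recomputed on the stratum's samples, so both mean
and variance differences between the groups are absorbed — and results are
combined with a fixed-effect inverse-variance meta-analysis over variants
passing the MAF floor in both strata.  The meta-analysed loci can then be
classified against an unstratified ("skin-colour-agnostic") GWAS as
shared / new / lost.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ancestry import reference_pca
from .assoc import additive_gwas, meta_ivw, rint
from .compare import classify_loci
from .simdata import GenotypeMatrix


@dataclass
class StratumSpec:
    strata: dict = field(default_factory=lambda: {
        "light": ["very fair", "fair"],
        "dark": ["light olive", "dark olive", "brown"],
    })
    excluded: list = field(default_factory=lambda: ["black"])
    on_unknown: str = "exclude"   # or "error"

    def validate(self) -> None:
        seen = set()
        for label, cats in self.strata.items():
            overlap = seen & set(cats)
            if overlap:
                raise ValueError(f"skin categories in two strata: {overlap}")
            seen |= set(cats)


def build_strata(cohort: pd.DataFrame, spec: StratumSpec | None = None
                 ) -> tuple[pd.Series, pd.DataFrame]:
    """Assign each sample to a stratum; report exclusions by reason.

    If the cohort carries a ``skin_repeat`` column (a second self-report),
    samples whose two answers disagree are excluded as inconsistent.
    """
    spec = spec or StratumSpec()
    spec.validate()
    cat_to_stratum = {c: label for label, cats in spec.strata.items()
                      for c in cats}
    known = set(cat_to_stratum) | set(spec.excluded)
    assignment = pd.Series(pd.NA, index=cohort.index, dtype="object",
                           name="stratum")
    reasons = {"inconsistent": 0, "excluded category": 0, "unknown category": 0}
    skin = cohort["skin"].astype(object)
    repeat = cohort["skin_repeat"].astype(object) if "skin_repeat" in cohort \
        else None
    for i in cohort.index:
        s = skin.loc[i]
        if repeat is not None and not pd.isna(repeat.loc[i]) \
                and repeat.loc[i] != s:
            reasons["inconsistent"] += 1
            continue
        if s in spec.excluded:
            reasons["excluded category"] += 1
            continue
        if s not in known:
            if spec.on_unknown == "error":
                raise ValueError(f"unknown skin category {s!r}")
            reasons["unknown category"] += 1
            continue
        assignment.loc[i] = cat_to_stratum[s]
    report = pd.DataFrame({"reason": list(reasons), "n": list(reasons.values())})
    return assignment, report


def stratified_gwas_meta(y: np.ndarray, genotypes: GenotypeMatrix,
                         strata: pd.Series, covariates: np.ndarray | None = None,
                         n_pcs: int = 10, maf_min: float = 0.01
                         ) -> tuple[pd.DataFrame, dict]:
    """Per-stratum GWAS (within-stratum RINT + PCs) and its IVW meta.

    The meta-analysis is restricted to variants with MAF above the floor in
    *both* strata.  Returns the meta records and the per-stratum records.
    """
    y = np.asarray(y, dtype=float)
    per_stratum = {}
    masks = []
    for label in strata.dropna().unique():
        mask = (strata == label).to_numpy()
        sub = GenotypeMatrix(values=genotypes.values[mask],
                             variants=genotypes.variants,
                             samples=genotypes.samples[mask].reset_index(drop=True))
        if covariates is not None:
            cov = np.asarray(covariates, dtype=float)[mask]
        else:
            cov = None
        n_sub = int(mask.sum())
        k = min(n_pcs, max(n_sub - 2, 1))
        if cov is not None and n_sub <= cov.shape[1] + k + 2:
            raise ValueError(f"stratum {label} too small for the covariate model")
        _, pcs = reference_pca(sub, k=k)
        cov_full = pcs if cov is None else np.column_stack([cov, pcs])
        y_stratum = rint(y[mask])
        rec = additive_gwas(y_stratum, sub, covariates=cov_full, mode="ols")
        freq = rec["freq"].to_numpy()
        maf_ok = np.minimum(freq, 1.0 - freq) >= maf_min
        per_stratum[label] = rec
        masks.append(maf_ok)
    both = np.logical_and.reduce(masks)
    records = [rec[both].reset_index(drop=True) for rec in per_stratum.values()]
    meta = meta_ivw(records)
    return meta, per_stratum


def compare_to_agnostic(meta_loci: pd.DataFrame, agnostic_loci: pd.DataFrame,
                        meta_records: pd.DataFrame,
                        agnostic_records: pd.DataFrame, ld_ref=None,
                        gws: float = 5e-8, suggestive: float = 1e-6,
                        window_bp: float = 1e6) -> pd.DataFrame:
    """Classify stratified-meta loci against the unstratified GWAS."""
    return classify_loci(meta_loci, agnostic_loci, meta_records,
                         agnostic_records, ld_ref=ld_ref, gws=gws,
                         suggestive=suggestive, window_bp=window_bp)
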