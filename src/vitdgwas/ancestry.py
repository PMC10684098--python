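"""Ancestry assignment by PC projection and a Gaussian posterior.

Reference samples of known ancestry are decomposed by PCA on standardized
genotypes; study samples are projected onto those loadings (standardizing
with the *reference* means and scales), and each sample is assigned to the
population maximizing the posterior of a multivariate normal fitted to the
reference PC scores.  With equal spherical covariances and equal priors
this reduces to nearest-centroid (k-means-style) assignment; the full
covariance takes the orientation of each reference cluster into account.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import svd
from scipy.stats import multivariate_normal

from .simdata import GenotypeMatrix

AMBIGUOUS_PAIRS = {frozenset(("A", "T")), frozenset(("C", "G"))}


@dataclass
class AncestryModel:
    variants: pd.DataFrame          # chrom, id, pos, a1, a2 of the loading variants
    means: np.ndarray               # 2 * reference freq per variant
    scales: np.ndarray              # sqrt(2 p (1-p)) per variant
    loadings: np.ndarray            # variants x k, orthonormal columns
    k: int = 3
    populations: dict = field(default_factory=dict)  # label -> (mu, Sigma, prior)

    def validate(self) -> None:
        if self.populations:
            priors = [p for _, _, p in self.populations.values()]
            if abs(sum(priors) - 1.0) > 1e-8:
                raise ValueError("population priors must sum to 1")


def _standardize(dosages: np.ndarray, means: np.ndarray,
                 scales: np.ndarray) -> np.ndarray:
    z = (dosages - means) / scales
    return np.where(np.isnan(z), 0.0, z)  # missing -> reference mean


def reference_pca(ref: GenotypeMatrix, k: int = 3
                  ) -> tuple[AncestryModel, np.ndarray]:
    """Top-k PCA of the reference panel on standardized genotypes.

    Returns the model (loadings plus standardization constants) and the
    reference scores.  Monomorphic variants are dropped before
    standardization; scores equal standardized genotypes times loadings.
    """
    d = ref.dosages()
    p = np.nanmean(d, axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    d = d[:, poly]
    p = p[poly]
    means = 2.0 * p
    scales = np.sqrt(2.0 * p * (1.0 - p))
    z = _standardize(d, means, scales)
    if k > min(z.shape):
        raise ValueError(f"k={k} exceeds the rank bound {min(z.shape)}")
    u, s, vt = svd(z, full_matrices=False)
    loadings = vt[:k].T
    scores = z @ loadings
    model = AncestryModel(variants=ref.variants.loc[poly].reset_index(drop=True),
                          means=means, scales=scales, loadings=loadings, k=k)
    return model, scores


def project_samples(model: AncestryModel, genotypes: GenotypeMatrix,
                    min_variants: int = 10,
                    drop_ambiguous: bool = True) -> np.ndarray:
    """Project study samples onto the reference PCs.

    Variants are matched by (chrom, pos, unordered allele pair); an A1/A2
    swap relative to the reference flips the dosage (x -> 2 - x).  Strand-
    ambiguous A/T and C/G variants are dropped by default.
    """
    ref_key = {}
    for i, row in model.variants.iterrows():
        ref_key[(row["chrom"], row["pos"], frozenset((row["a1"], row["a2"])))] = (
            i, row["a1"])
    cols, ref_idx, flip = [], [], []
    for j, row in genotypes.variants.iterrows():
        pair = frozenset((row["a1"], row["a2"]))
        if drop_ambiguous and pair in AMBIGUOUS_PAIRS:
            continue
        hit = ref_key.get((row["chrom"], row["pos"], pair))
        if hit is None:
            continue
        i, ref_a1 = hit
        cols.append(j)
        ref_idx.append(i)
        flip.append(row["a1"] != ref_a1)
    if len(cols) < min_variants:
        raise ValueError(
            f"only {len(cols)} variants intersect the reference "
            f"(minimum {min_variants})")
    d = genotypes.dosages()[:, cols]
    flip = np.asarray(flip)
    d[:, flip] = 2.0 - d[:, flip]
    z = _standardize(d, model.means[ref_idx], model.scales[ref_idx])
    return z @ model.loadings[ref_idx]


def fit_population_model(model: AncestryModel, ref_scores: np.ndarray,
                         labels, priors: dict | None = None,
                         reg: float = 1e-6) -> AncestryModel:
    """Fit the per-population Gaussians on reference scores.

    Covariances are regularized by adding ``reg * mean(diag)`` times the
    identity; priors default to equal across populations.
    """
    labels = np.asarray(labels)
    pops = sorted(set(labels))
    if priors is None:
        priors = {p: 1.0 / len(pops) for p in pops}
    for pop in pops:
        sc = ref_scores[labels == pop]
        mu = sc.mean(axis=0)
        cov = np.cov(sc, rowvar=False)
        cov = np.atleast_2d(cov)
        eps = reg * np.mean(np.diag(cov))
        cov = cov + eps * np.eye(cov.shape[0])
        try:
            np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as exc:
            raise ValueError(f"covariance for {pop} singular after "
                             "regularization") from exc
        model.populations[pop] = (mu, cov, priors[pop])
    model.validate()
    return model


def assign_ancestry(model: AncestryModel, scores: np.ndarray) -> pd.DataFrame:
    """Posterior probabilities and hard labels for projected samples.

    posterior_k is proportional to prior_k times the multivariate-normal
    density at the sample's score; the label is the argmax, with ties broken
    by population order and flagged.
    """
    if not model.populations:
        raise ValueError("population Gaussians not fitted")
    pops = list(model.populations)
    logd = np.empty((scores.shape[0], len(pops)))
    for j, pop in enumerate(pops):
        mu, cov, prior = model.populations[pop]
        logd[:, j] = multivariate_normal.logpdf(scores, mean=mu, cov=cov) + \
            np.log(prior)
    logd -= logd.max(axis=1, keepdims=True)
    post = np.exp(logd)
    post /= post.sum(axis=1, keepdims=True)
    best = post.argmax(axis=1)
    tie = (post == post[np.arange(len(best)), best][:, None]).sum(axis=1) > 1
    out = pd.DataFrame(post, columns=[f"post_{p}" for p in pops])
    out["label"] = [pops[i] for i in best]
    out["tied"] = tie
    return out


def write_assignments_tsv(scores: np.ndarray, assignments: pd.DataFrame,
                          iids, path) -> None:
    k = scores.shape[1]
    out = pd.DataFrame(scores, columns=[f"PC{i+1}" for i in range(k)])
    out.insert(0, "IID", np.asarray(iids))
    out = pd.concat([out, assignments.reset_index(drop=True)], axis=1)
    out.to_csv(path, sep="\t", index=False)
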