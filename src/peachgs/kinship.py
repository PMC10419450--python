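"""Genomic relationship matrices and principal-component covariates.

Both are the standard confounding controls of mixed-model GWAS: the kinship
matrix absorbs polygenic resemblance between accessions as a random effect,
and the leading PCs of the genotype matrix enter as fixed covariates for
population structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genio import GenotypeMatrix

KINSHIP_METHODS = ("vanraden", "zhang")


@dataclass
class KinshipMatrix:
    """Symmetric PSD genomic relationship matrix with sample labels."""

    values: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("kinship matrix shape does not match sample ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("kinship matrix not symmetric")
        # PSD up to numerical noise
        w = np.linalg.eigvalsh(self.values)
        if w.min() < -1e-8 * max(1.0, abs(w.max())):
            raise ValueError("kinship matrix not PSD")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def subset(self, index: np.ndarray) -> "KinshipMatrix":
        idx = np.asarray(index)
        return KinshipMatrix(values=self.values[np.ix_(idx, idx)],
                             sample_ids=[self.sample_ids[i] for i in idx])

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=self.sample_ids,
                     columns=self.sample_ids).to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "KinshipMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(values=df.to_numpy(), sample_ids=[str(s) for s in df.index])


def genomic_kinship(g: GenotypeMatrix, method: str = "zhang") -> KinshipMatrix:
    """Genomic relationship matrix from imputed dosages.

    ``vanraden``: K = W W' / (2 * sum p_j (1 - p_j)) with W the dosage matrix
    centered by twice the allele frequency.  ``zhang``: the same matrix
    rescaled so its mean diagonal equals 1 — an approximation of the
    GAPIT-style rescaled relationship matrix (the original algorithm is not
    published in closed form).
    """
    if method not in KINSHIP_METHODS:
        raise ValueError(f"method must be one of {KINSHIP_METHODS}")
    dosage = g.dosage
    if np.isnan(dosage).any():
        raise ValueError("kinship requires imputed dosages (no missing values)")
    p = dosage.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if poly.sum() < 2:
        raise ValueError("need at least 2 polymorphic markers")
    w = dosage[:, poly] - 2.0 * p[poly]
    denom = 2.0 * np.sum(p[poly] * (1.0 - p[poly]))
    k = (w @ w.T) / denom
    if method == "zhang":
        k = k / np.mean(np.diag(k))
    k = (k + k.T) / 2.0  # exact symmetry against rounding
    return KinshipMatrix(values=k, sample_ids=list(g.sample_ids))


def pca_covariates(g: GenotypeMatrix, k: int = 3) -> np.ndarray:
    """Top-``k`` principal components of the column-standardized dosage matrix.

    Returns an ``n x k`` matrix of sample scores ordered by decreasing
    explained variance; columns are mutually orthogonal.  Computed from the
    eigendecomposition of the n x n sample covariance, which is cheap when
    markers far outnumber samples.
    """
    if k <= 0:
        raise ValueError("number of PCs must be positive")
    n, m = g.dosage.shape
    if k >= min(n, m):
        raise ValueError(f"k={k} must be < min(n_samples, n_markers)={min(n, m)}")
    if np.isnan(g.dosage).any():
        raise ValueError("PCA requires imputed dosages")
    x = g.dosage - g.dosage.mean(axis=0)
    sd = x.std(axis=0)
    keep = sd > 0
    x = x[:, keep] / sd[keep]
    cov = (x @ x.T) / x.shape[1]
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1][:k]
    scores = v[:, order] * np.sqrt(np.maximum(w[order], 0.0))
    return scores
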