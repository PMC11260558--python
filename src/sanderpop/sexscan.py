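"""Sex-linked locus detection by discriminant analysis of principal components.

GBS panels of percids can carry blocks of sex-differentiated loci that
masquerade as population structure.  The screen runs a PCA of the
mean-imputed, centred genotype matrix, fits a linear discriminant of sex on
the retained PC scores, and back-projects the discriminant axis into locus
space.  Squared, normalised back-projected coefficients are the per-locus
loadings; loci at or above a high quantile of the loading distribution
(default 0.99) are flagged as sex-linked.  A label-randomization procedure
provides a complementary significance threshold: the 95th percentile of the
maximum locus loading across permuted-label replicates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .vcfio import GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class DapcResult:
    scores: np.ndarray          # per-sample discriminant score
    loadings: np.ndarray        # per-locus loading, >= 0, sums to 1
    n_pcs: int
    labels: np.ndarray

    def __post_init__(self) -> None:
        s = self.loadings.sum()
        if not np.isclose(s, 1.0, atol=1e-8):
            raise ValueError(f"loadings must sum to 1 (got {s})")


def _default_n_pcs(explained_ratio: np.ndarray, n_samples: int) -> int:
    """Smallest PC count explaining >= 90% of variance, capped at n/3."""
    cum = np.cumsum(explained_ratio)
    k = int(np.searchsorted(cum, 0.90) + 1)
    return max(1, min(k, max(1, n_samples // 3)))


def dapc(
    gm: GenotypeMatrix | np.ndarray,
    labels: np.ndarray | list,
    n_pcs: int | None = None,
) -> DapcResult:
    """Two-group DAPC of a genotype matrix with per-locus loadings.

    Missing genotypes are mean-imputed per locus and the matrix centred
    before PCA.  ``labels`` must contain exactly two groups with at least
    two members each.
    """
    X = gm.imputed() if isinstance(gm, GenotypeMatrix) else np.asarray(gm, float)
    labels = np.asarray(labels)
    groups, counts = np.unique(labels, return_counts=True)
    if len(groups) != 2:
        raise ValueError(f"dapc requires exactly 2 groups, got {len(groups)}")
    if counts.min() < 2:
        raise ValueError("each group needs at least 2 individuals")
    Xc = X - X.mean(axis=0)
    max_rank = min(Xc.shape[0] - 1, Xc.shape[1])
    if n_pcs is None:
        probe = PCA(n_components=max_rank, svd_solver="full").fit(Xc)
        n_pcs = _default_n_pcs(probe.explained_variance_ratio_, Xc.shape[0])
    elif n_pcs > max_rank:
        logger.warning("dapc: n_pcs=%d exceeds rank %d; clipped", n_pcs, max_rank)
        n_pcs = max_rank
    pca = PCA(n_components=n_pcs, svd_solver="full").fit(Xc)
    pcs = pca.transform(Xc)
    lda = LinearDiscriminantAnalysis(n_components=1).fit(pcs, labels)
    scores = lda.transform(pcs)[:, 0]
    # back-project the discriminant axis into locus space
    axis = pca.components_.T @ lda.coef_[0]
    load = axis**2
    total = load.sum()
    if total <= 0:
        load = np.full(len(load), 1.0 / len(load))
    else:
        load = load / total
    return DapcResult(scores=scores, loadings=load, n_pcs=n_pcs, labels=labels)


def flag_sex_loci(result: DapcResult, quantile: float = 0.99) -> np.ndarray:
    """Indices of loci with loading >= the given quantile of all loadings.

    Ties at the threshold are all included.
    """
    if not 0 < quantile <= 1:
        raise ValueError("quantile must be in (0, 1]")
    thr = np.quantile(result.loadings, quantile)
    return np.flatnonzero(result.loadings >= thr)


def randomization_threshold(
    gm: GenotypeMatrix | np.ndarray,
    labels: np.ndarray | list,
    B: int = 100,
    n_pcs: int | None = None,
    percentile: float = 95.0,
    seed: int | None = None,
) -> float:
    """Label-randomization significance threshold for DAPC loadings.

    Labels are permuted ``B`` times (B >= 20); the threshold is the given
    percentile (default 95) of the per-replicate maximum locus loading.
    """
    if B < 20:
        raise ValueError("randomization requires B >= 20")
    X = gm.imputed() if isinstance(gm, GenotypeMatrix) else np.asarray(gm, float)
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    maxima = np.empty(B)
    for b in range(B):
        perm = rng.permutation(labels)
        res = dapc(X, perm, n_pcs=n_pcs)
        maxima[b] = res.loadings.max()
    return float(np.percentile(maxima, percentile))


def sex_scan_table(
    gm: GenotypeMatrix, result: DapcResult, flagged: np.ndarray
) -> pd.DataFrame:
    """BED-like table (chromosome, position, loading) of flagged loci."""
    return pd.DataFrame(
        dict(
            chrom=gm.chrom[flagged],
            pos=gm.pos[flagged],
            loading=result.loadings[flagged],
        )
    )
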