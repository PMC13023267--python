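"""Population-structure summaries: dosage matrix, PCA, hierarchical
clustering.

The genotype matrix holds alternate-allele dosages (0/1/2) for
individuals only — pools carry no genotypes.  Missing dosages are
mean-imputed per variant, the standard default for genotype PCA.  PCA
standardizes each variant (center, unit variance; zero-variance
variants dropped) and decomposes by SVD; clustering uses average
linkage on one minus the pairwise allele-sharing proportion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from skbio import TreeNode

from .model import VariantKey, VariantRecord

logger = logging.getLogger(__name__)


@dataclass
class DosageMatrix:
    samples: list[str]
    keys: list[VariantKey]
    values: np.ndarray  # samples x keys, mean-imputed float dosages

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class PcaResult:
    samples: list[str]
    coordinates: np.ndarray  # samples x components
    variance_explained: np.ndarray  # fraction per component, non-increasing


def build_dosage_matrix(
    records: list[VariantRecord],
    samples: list[str],
) -> DosageMatrix:
    """Assemble the samples × variants dosage matrix, mean-imputing
    missing genotypes per variant; variants with no called sample are
    dropped.
    """
    raw = np.full((len(samples), len(records)), np.nan)
    for j, record in enumerate(records):
        for i, s in enumerate(samples):
            gt = record.entry(s).gt
            if gt is not None:
                raw[i, j] = gt
    called = ~np.isnan(raw)
    keep = called.any(axis=0)
    if not keep.any():
        raise ValueError("dosage matrix is entirely missing")
    raw = raw[:, keep]
    keys = [r.key for r, k in zip(records, keep) if k]
    col_means = np.nanmean(raw, axis=0)
    idx = np.where(np.isnan(raw))
    raw[idx] = np.take(col_means, idx[1])
    return DosageMatrix(list(samples), keys, raw)


def pca(matrix: DosageMatrix, n_components: int = 10, scale: bool = True) -> PcaResult:
    """Centered (and by default variance-standardized) SVD decomposition.

    Zero-variance variants are dropped before scaling.  The fraction of
    variance explained is each squared singular value over the total.
    Component signs follow the convention that the largest-magnitude
    variant loading is positive.
    """
    x = matrix.values.astype(float)
    x = x - x.mean(axis=0)
    sd = x.std(axis=0)
    keep = sd > 0
    x = x[:, keep]
    if x.shape[1] < 2 or x.shape[0] < 2:
        raise ValueError("pca needs at least 2 samples and 2 variable variants")
    if scale:
        x = x / sd[keep]
    k = min(n_components, min(x.shape))
    if k < n_components:
        logger.info("pca: truncating to %d components", k)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    # sign convention: per component, largest-|loading| positive
    for c in range(vt.shape[0]):
        j = np.argmax(np.abs(vt[c]))
        if vt[c, j] < 0:
            vt[c] *= -1
            u[:, c] *= -1
    var = s**2
    return PcaResult(
        samples=list(matrix.samples),
        coordinates=u[:, :k] * s[:k],
        variance_explained=var[:k] / var.sum(),
    )


def allele_sharing_distance(matrix: DosageMatrix) -> np.ndarray:
    """Condensed distance: 1 − mean allele-sharing proportion.

    For dosages ``a`` and ``b`` the per-variant sharing is
    ``1 − |a − b| / 2``, so the distance averages ``|a − b| / 2``.
    """
    x = matrix.values
    n = x.shape[0]
    dist = np.zeros((n, n))
    for i in range(n):
        dist[i] = np.mean(np.abs(x - x[i]) / 2.0, axis=1)
    np.fill_diagonal(dist, 0.0)
    return squareform(dist, checks=False)


def hierarchical_clusters(
    matrix: DosageMatrix, method: str = "average"
) -> np.ndarray:
    """Linkage matrix from the allele-sharing distance (deterministic)."""
    if len(matrix.samples) < 2:
        raise ValueError("clustering needs at least 2 samples")
    return hierarchy.linkage(allele_sharing_distance(matrix), method=method)


def cut_clusters(linkage_matrix: np.ndarray, n_clusters: int) -> np.ndarray:
    """Flat cluster labels from cutting the dendrogram at n_clusters."""
    return hierarchy.fcluster(linkage_matrix, n_clusters, criterion="maxclust")


def dendrogram_newick(linkage_matrix: np.ndarray, samples: list[str]) -> str:
    """Render the dendrogram as a Newick string (leaf names = samples)."""
    tree = TreeNode.from_linkage_matrix(linkage_matrix, samples)
    return str(tree).strip()
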