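"""Sample-level ordination and clustering of metabolome profiles.

PCA runs on per-feature unit-normalized (z-scaled) log-free peak areas via
SVD, returning scores, loadings and percent variance explained.  Hierarchical
clustering of replicates uses Spearman rank correlation distance
(1 − ρ) with average linkage, so any strictly monotone per-sample transform
of the areas leaves the tree unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr

from .design import StudyDesign
from .errors import ValidationError
from .io import FeatureTable


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # features x components
    variance_explained: pd.Series  # percent per component, sums to 100
    dropped_features: List[str]  # zero-variance features removed before scaling

    def top_loadings(self, component: str, n: int = 10) -> pd.Series:
        """Features most discriminating on a component, by |loading|."""
        col = self.loadings[component]
        return col.reindex(col.abs().sort_values(ascending=False).index).head(n)


def pca_profiles(
    features: FeatureTable,
    design: Optional[StudyDesign] = None,
    scaling: str = "zscore",
) -> PCAResult:
    """Principal component analysis of sample metabolome profiles.

    Features are centered and (for ``scaling="zscore"``) scaled to unit
    variance; zero-variance features are dropped first and reported.  With all
    components retained, ``scores @ loadings.T`` reconstructs the normalized
    matrix exactly.
    """
    areas = features.areas
    if design is not None:
        areas = areas[[s for s in design.sample_ids if s in areas.columns]]
    if areas.shape[1] < 2:
        raise ValidationError("PCA needs at least two samples")
    X = areas.to_numpy(dtype=float).T  # samples x features
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    dropped = list(areas.index[~keep])
    X = X[:, keep]
    if X.shape[1] == 0:
        raise ValidationError("all features have zero variance")
    X = X - X.mean(axis=0)
    if scaling == "zscore":
        X = X / sd[keep]
    elif scaling != "none":
        raise ValidationError(f"unknown scaling {scaling!r}")
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    comps = [f"PC{i + 1}" for i in range(len(s))]
    scores = pd.DataFrame(u * s, index=areas.columns, columns=comps)
    loadings = pd.DataFrame(vt.T, index=areas.index[keep], columns=comps)
    total = (s**2).sum()
    var = pd.Series(100.0 * s**2 / total, index=comps, name="variance_explained")
    return PCAResult(scores, loadings, var, dropped)


@dataclass
class LinkageResult:
    Z: np.ndarray  # scipy linkage matrix
    distance: pd.DataFrame  # samples x samples, 1 - Spearman rho
    sample_ids: List[str]

    def cut(self, n_clusters: int) -> pd.Series:
        labels = fcluster(self.Z, t=n_clusters, criterion="maxclust")
        return pd.Series(labels, index=self.sample_ids, name="cluster")

    def merge_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.Z, columns=["left", "right", "height", "n_members"]
        )


def spearman_linkage(
    features: FeatureTable, method: str = "average"
) -> LinkageResult:
    """Hierarchical clustering of samples on Spearman correlation distance."""
    areas = features.areas
    if areas.shape[1] < 2:
        raise ValidationError("clustering needs at least two samples")
    X = areas.to_numpy(dtype=float)
    constant = X.std(axis=0) == 0
    if constant.any():
        bad = list(areas.columns[constant])
        raise ValidationError(
            f"constant profile (Spearman correlation undefined) for sample(s) {bad}"
        )
    rho = spearmanr(X, axis=0).statistic
    if np.ndim(rho) == 0:  # scipy returns a scalar for exactly two samples
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    dist = 1.0 - rho
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)  # symmetrise round-off
    Z = linkage(squareform(dist, checks=False), method=method)
    ddf = pd.DataFrame(dist, index=areas.columns, columns=areas.columns)
    return LinkageResult(Z, ddf, list(areas.columns))
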