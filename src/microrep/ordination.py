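"""Ordination and clustering of distance matrices.

Global structure: classical principal coordinate analysis (PCoA) with
per-feature loadings (Pearson correlation of each binary feature with the
first two coordinates, ranked by the L2 norm of the two correlations).
Local structure: t-SNE on the precomputed distance matrix.  Grouping:
complete-linkage hierarchical clustering, plus presence-fraction contrasts
between clusters to extract sub-type-specific features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.cluster.hierarchy import cut_tree, linkage
from sklearn.manifold import TSNE

from .distances import DistanceMatrix
from .model_io import BinaryProfileMatrix, ValidationError

__all__ = [
    "OrdinationResult",
    "EmbeddingResult",
    "ClusterAssignment",
    "pcoa",
    "feature_loadings",
    "tsne_embed",
    "hcluster",
    "subtype_contrast",
]


@dataclass
class OrdinationResult:
    organisms: list[str]
    coordinates: np.ndarray          # organisms x retained axes
    eigenvalues: np.ndarray          # positive eigenvalues of retained axes
    explained_fraction: np.ndarray   # eigenvalue / sum of positive eigenvalues
    negative_eigenvalue_mass: float  # summed magnitudes of negative eigenvalues

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PCo{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.organisms, columns=cols)


@dataclass
class EmbeddingResult:
    organisms: list[str]
    coordinates: np.ndarray  # organisms x 2
    perplexity: float
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.coordinates, index=self.organisms, columns=["tsne1", "tsne2"])


@dataclass
class ClusterAssignment:
    labels: dict[str, int]  # organism -> cluster id (1..k)
    k: int
    linkage: str = "complete"
    within_scope: str | None = None

    def members(self, cluster_id: int) -> list[str]:
        return sorted(o for o, c in self.labels.items() if c == cluster_id)


def pcoa(dist: DistanceMatrix, n_axes: int = 2) -> OrdinationResult:
    """Classical scaling (Torgerson PCoA) of a distance matrix.

    Double-centers -D^2/2, eigendecomposes, and keeps the ``n_axes`` leading
    axes with positive eigenvalues; coordinates are eigenvectors scaled by the
    square root of their eigenvalue.  Axes with nonpositive eigenvalues are
    dropped and their total magnitude is reported instead of applying a
    Cailliez/Lingoes correction.
    """
    if n_axes < 1:
        raise ValueError("n_axes must be >= 1")
    n = dist.n
    if n < n_axes + 1:
        raise ValueError(f"need at least {n_axes + 1} organisms for {n_axes} axes, got {n}")
    D2 = dist.values ** 2
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * (J @ D2 @ J)
    eigval, eigvec = scipy.linalg.eigh(B)  # ascending
    eigval, eigvec = eigval[::-1], eigvec[:, ::-1]
    pos = eigval > 1e-12
    neg_mass = float(np.abs(eigval[eigval < 0]).sum())
    pos_val, pos_vec = eigval[pos], eigvec[:, pos]
    k = min(n_axes, pos_val.size)
    coords = pos_vec[:, :k] * np.sqrt(pos_val[:k])
    coords = coords - coords.mean(axis=0)  # numerically re-center
    total = pos_val.sum()
    return OrdinationResult(
        organisms=list(dist.organisms),
        coordinates=coords,
        eigenvalues=pos_val[:k],
        explained_fraction=pos_val[:k] / total if total > 0 else np.zeros(k),
        negative_eigenvalue_mass=neg_mass,
    )


def _safe_pearson(x: np.ndarray, y: np.ndarray) -> float:
    # constant columns have no defined correlation; score them 0
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def feature_loadings(
    profiles: BinaryProfileMatrix,
    ordination: OrdinationResult,
    top_n: int = 200,
) -> pd.DataFrame:
    """Correlate each feature with the first two coordinates; rank by L2 norm.

    Returns a DataFrame (index = feature id, sorted by rank) with columns
    ``corr_axis1``, ``corr_axis2``, ``relevance``, ``rank`` and a boolean
    ``selected`` marking the ``top_n`` highest-relevance features.  Ties in
    relevance are broken by feature id for determinism.
    """
    if list(profiles.organisms) != list(ordination.organisms):
        raise ValidationError(["profiles and ordination organisms differ or are ordered differently"])
    if top_n > len(profiles.features):
        raise ValueError(f"top_n={top_n} exceeds feature count {len(profiles.features)}")
    X = profiles.values().astype(float)
    ax1 = ordination.coordinates[:, 0]
    ax2 = ordination.coordinates[:, 1] if ordination.coordinates.shape[1] > 1 else np.zeros_like(ax1)
    rows = []
    for j, feat in enumerate(profiles.features):
        c1 = _safe_pearson(X[:, j], ax1)
        c2 = _safe_pearson(X[:, j], ax2)
        rows.append((feat, c1, c2, float(np.hypot(c1, c2))))
    df = pd.DataFrame(rows, columns=["feature", "corr_axis1", "corr_axis2", "relevance"])
    df = df.sort_values(["relevance", "feature"], ascending=[False, True], kind="mergesort")
    df["rank"] = np.arange(1, len(df) + 1)
    df["selected"] = df["rank"] <= top_n
    return df.set_index("feature")


def tsne_embed(dist: DistanceMatrix, perplexity: float | None = None, seed: int = 42) -> EmbeddingResult:
    """2-D t-SNE embedding of a precomputed distance matrix (seed-deterministic)."""
    n = dist.n
    if perplexity is None:
        # largest conventional value strictly below the (n-1)/3 validity bound
        perplexity = min(30.0, max(1.0, (n - 2) // 3))
    if perplexity >= (n - 1) / 3:
        raise ValueError(
            f"perplexity {perplexity} too large for {n} organisms (must be < (n-1)/3)"
        )
    tsne = TSNE(
        n_components=2,
        metric="precomputed",
        init="random",
        perplexity=perplexity,
        random_state=seed,
    )
    coords = tsne.fit_transform(dist.values)
    return EmbeddingResult(
        organisms=list(dist.organisms),
        coordinates=np.asarray(coords, dtype=float),
        perplexity=float(perplexity),
        seed=seed,
    )


def hcluster(dist: DistanceMatrix, k: int, within_scope: str | None = None) -> ClusterAssignment:
    """Complete-linkage agglomeration cut to exactly k clusters.

    Cluster ids 1..k are assigned by decreasing cluster size, ties broken by
    the lexicographically smallest member id.
    """
    n = dist.n
    if not 2 <= k <= n:
        raise ValueError(f"k must be in [2, {n}], got {k}")
    Z = linkage(dist.condensed(), method="complete")
    raw = cut_tree(Z, n_clusters=k).ravel()
    groups: dict[int, list[str]] = {}
    for org, g in zip(dist.organisms, raw):
        groups.setdefault(int(g), []).append(org)
    ordered = sorted(groups.values(), key=lambda ms: (-len(ms), min(ms)))
    labels = {org: i + 1 for i, members in enumerate(ordered) for org in members}
    return ClusterAssignment(labels=labels, k=k, linkage="complete", within_scope=within_scope)


def subtype_contrast(
    profiles: BinaryProfileMatrix,
    clusters: ClusterAssignment,
    a: int,
    b: int,
    hi: float = 0.9,
    lo: float = 0.1,
) -> pd.DataFrame:
    """Features discriminating cluster ``a`` from cluster ``b``.

    A feature is A-specific when its presence fraction is >= ``hi`` in A and
    <= ``lo`` in B (and symmetrically B-specific).  Returns a DataFrame
    (columns ``fraction_a``, ``fraction_b``, ``direction``, ``gap``) sorted by
    decreasing fraction gap.
    """
    if a == b:
        raise ValueError("contrast requires two distinct clusters")
    mem_a, mem_b = clusters.members(a), clusters.members(b)
    if not mem_a or not mem_b:
        missing = a if not mem_a else b
        raise KeyError(f"cluster {missing} is empty or unknown")
    have = set(profiles.organisms)
    lost = [o for o in mem_a + mem_b if o not in have]
    if lost:
        raise ValidationError([f"cluster members missing from profiles: {lost}"])
    df = profiles.data
    frac_a = df.loc[mem_a].mean(axis=0)
    frac_b = df.loc[mem_b].mean(axis=0)
    a_spec = (frac_a >= hi) & (frac_b <= lo)
    b_spec = (frac_b >= hi) & (frac_a <= lo)
    out = pd.DataFrame(
        {
            "fraction_a": frac_a[a_spec | b_spec],
            "fraction_b": frac_b[a_spec | b_spec],
        }
    )
    out["direction"] = np.where(a_spec[a_spec | b_spec], "A-specific", "B-specific")
    out["gap"] = (out["fraction_a"] - out["fraction_b"]).abs()
    out.index.name = "feature"
    return out.sort_values(["gap", "feature"], ascending=[False, True], kind="mergesort")
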