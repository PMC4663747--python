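"""Pairwise dissimilarities: Jaccard distance on binary profiles and
cophenetic (patristic) distance on a rooted phylogeny.

The metabolic / phenotypic / annotation distance between two organisms is
1 - |b_i & b_j| / |b_i | b_j| over their binary feature vectors; two all-zero
profiles are treated as identical (distance 0).  The phylogenetic distance
between two leaves is the sum of branch lengths along the tree path through
their most recent common ancestor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .model_io import BinaryProfileMatrix, ValidationError

__all__ = [
    "DistanceMatrix",
    "jaccard_distance",
    "read_newick",
    "cophenetic_distance",
    "align_organisms",
    "read_distance_tsv",
    "write_distance_tsv",
]

logger = logging.getLogger(__name__)

KINDS = ("metabolic", "phenotypic", "annotation", "phylogenetic")

_KIND_FOR_FEATURES = {
    "reaction": "metabolic",
    "essential_nutrient": "phenotypic",
    "annotation": "annotation",
}


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarity matrix over named organisms."""

    organisms: list[str]
    values: np.ndarray
    kind: str = "metabolic"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.organisms)
        v: list[str] = []
        if len(set(self.organisms)) != n:
            v.append("duplicate organism ids")
        if self.values.shape != (n, n):
            v.append(f"matrix shape {self.values.shape} does not match {n} organisms")
        else:
            if not np.allclose(self.values, self.values.T, atol=1e-12):
                v.append("matrix not symmetric")
            if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
                v.append("nonzero diagonal")
            if np.any(self.values < -1e-12):
                v.append("negative distances")
        if self.kind not in KINDS:
            v.append(f"unknown distance kind {self.kind!r}")
        if v:
            raise ValidationError(v)
        np.fill_diagonal(self.values, 0.0)

    @property
    def n(self) -> int:
        return len(self.organisms)

    def loc(self, a: str, b: str) -> float:
        i, j = self.organisms.index(a), self.organisms.index(b)
        return float(self.values[i, j])

    def reorder(self, organisms: list[str]) -> "DistanceMatrix":
        idx = [self.organisms.index(o) for o in organisms]
        return DistanceMatrix(list(organisms), self.values[np.ix_(idx, idx)], self.kind)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.organisms, columns=self.organisms)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


def jaccard_distance(profiles: BinaryProfileMatrix) -> DistanceMatrix:
    """Jaccard distance between rows of a presence/absence matrix."""
    if len(profiles.organisms) < 2:
        raise ValidationError(["jaccard_distance requires >= 2 organisms"])
    mat = profiles.values().astype(bool)
    d = squareform(pdist(mat, metric="jaccard"))  # scipy defines 0/0 as 0
    kind = _KIND_FOR_FEATURES.get(profiles.feature_kind, "annotation")
    return DistanceMatrix(profiles.organisms, d, kind=kind)


def read_newick(path: str | Path) -> dendropy.Tree:
    """Read a rooted Newick tree with branch lengths.

    Explicitly unrooted input (``[&U]``) is rejected; trees without a rooting
    statement are taken as rooted at the top-level node, which is the common
    convention for outgroup-rooted phylogenies.
    """
    from dendropy.dataio.newickreader import NewickReader
    from dendropy.utility.error import DataParseError

    try:
        tree = dendropy.Tree.get(
            path=str(path),
            schema="newick",
            preserve_underscores=True,
        )
    except NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise ValidationError([f"{path}: duplicate leaf names ({exc})"]) from exc
    except DataParseError as exc:
        raise ValidationError([f"{path}: newick parse error: {exc}"]) from exc
    if tree.is_rooted is False:
        raise ValidationError([f"{path}: tree is explicitly unrooted"])
    tree.is_rooted = True
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    violations = []
    if len(labels) != len(set(labels)):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        violations.append(f"duplicate leaf names: {dupes}")
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        if node.edge.length is None:
            who = node.taxon.label if node.taxon else "<internal>"
            violations.append(f"edge above {who} has no branch length")
        elif node.edge.length < 0:
            who = node.taxon.label if node.taxon else "<internal>"
            violations.append(f"edge above {who} has negative length")
    if violations:
        raise ValidationError([f"{path}: {v}" for v in violations])
    return tree


def cophenetic_distance(tree: dendropy.Tree) -> DistanceMatrix:
    """Patristic distance between every leaf pair (path sum through the MRCA)."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(
        (leaf.taxon for leaf in tree.leaf_node_iter()), key=lambda t: t.label
    )
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return DistanceMatrix([t.label for t in taxa], d, kind="phylogenetic")


def align_organisms(
    dmats: list[DistanceMatrix],
    profiles: list[BinaryProfileMatrix] | None = None,
) -> tuple[list[DistanceMatrix], list[BinaryProfileMatrix]]:
    """Restrict all inputs to the common organism set, in one canonical order.

    Organisms missing from any input are dropped (logged); an empty
    intersection is an error.
    """
    profiles = profiles or []
    sets = [set(d.organisms) for d in dmats] + [set(p.organisms) for p in profiles]
    if not sets:
        return [], []
    common = set.intersection(*sets)
    if not common:
        raise ValidationError(["no organisms common to all inputs"])
    order = sorted(common)
    dropped = sorted(set.union(*sets) - common)
    if dropped:
        logger.warning("align_organisms: dropping %d organisms: %s", len(dropped), dropped)
    return (
        [d.reorder(order) for d in dmats],
        [p.restrict(order) for p in profiles],
    )


def write_distance_tsv(dmat: DistanceMatrix, path: str | Path) -> None:
    df = dmat.to_frame().map(lambda x: float(f"{x:.12g}"))
    df.index.name = "organism_id"
    df.to_csv(path, sep="\t", float_format="%.12g")


def read_distance_tsv(path: str | Path, kind: str = "metabolic") -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if list(df.index) != list(df.columns):
        raise ValidationError([f"{path}: row and column organism ids differ"])
    return DistanceMatrix(list(df.index), df.to_numpy(), kind=kind)
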