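"""Dated phylogeny handling: patristic distances and PGLS covariances.

The tree is rooted with branch lengths in million years (My).  Pairwise
divergence is the patristic distance (path length between tips); on an
ultrametric tree this is twice the divergence time, and divergence time is
the default reported predictor.  The phylogenetic covariance C has
C[i, j] = shared root-to-MRCA path length and C[i, i] = tip depth; Pagel's
lambda rescales the off-diagonal entries only.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np

ULTRAMETRIC_RTOL = 1e-6


class PhyloError(ValueError):
    pass


@dataclass
class Phylogeny:
    """A rooted, dated tree with uniquely labelled tips."""

    tree: dendropy.Tree
    is_ultrametric: bool

    @property
    def tip_labels(self) -> list[str]:
        return sorted(leaf.taxon.label for leaf in self.tree.leaf_node_iter())

    @property
    def n_tips(self) -> int:
        return len(self.tree.leaf_nodes())

    @property
    def depth(self) -> float:
        return max(self._tip_depths().values())

    def _tip_depths(self) -> dict[str, float]:
        self.tree.calc_node_root_distances(return_leaf_distances_only=False)
        return {
            leaf.taxon.label: leaf.root_distance for leaf in self.tree.leaf_node_iter()
        }

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


def _wrap_tree(tree: dendropy.Tree) -> Phylogeny:
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is None or not leaf.taxon.label:
            raise PhyloError("tree has unlabelled tips")
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise PhyloError("tip labels are not unique")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is not tree.seed_node:
            if edge.length is None:
                raise PhyloError("tree has edges without branch lengths")
            if edge.length < 0:
                raise PhyloError("negative branch length")
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    depths = [leaf.root_distance for leaf in tree.leaf_node_iter()]
    depth = max(depths)
    ultrametric = depth > 0 and (depth - min(depths)) <= ULTRAMETRIC_RTOL * depth
    return Phylogeny(tree, ultrametric)


def read_newick(source: str | Path) -> Phylogeny:
    """Parse a Newick tree (path or literal string) with branch lengths."""
    text = str(source)
    if isinstance(source, Path) or (len(text) < 4096 and "(" not in text):
        text = Path(source).read_text()
    try:
        tree = dendropy.Tree.get(
            file=io.StringIO(text), schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises assorted parse errors
        raise PhyloError(f"could not parse Newick input: {exc}") from exc
    if len(tree.leaf_nodes()) < 2:
        raise PhyloError("tree must have at least two tips")
    return _wrap_tree(tree)


@dataclass
class PhyloDistanceMatrix:
    """Symmetric matrix of pairwise tip distances (My)."""

    species: list[str]
    values: np.ndarray
    kind: str = "divergence_time"  # or "patristic"

    def pair(self, a: str, b: str) -> float:
        return float(self.values[self.species.index(a), self.species.index(b)])


def pairwise_divergence(
    phylogeny: Phylogeny, as_divergence_time: bool | None = None
) -> PhyloDistanceMatrix:
    """Patristic distances between all tip pairs.

    When ``as_divergence_time`` (default: on for ultrametric trees) the
    matrix holds patristic/2, i.e. the time since the common ancestor.
    """
    if as_divergence_time is None:
        as_divergence_time = phylogeny.is_ultrametric
    species = phylogeny.tip_labels
    pdm = phylogeny.tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in phylogeny.tree.taxon_namespace}
    n = len(species)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[species[i]], taxa[species[j]])
            values[i, j] = values[j, i] = d
    if as_divergence_time:
        values = values / 2.0
    kind = "divergence_time" if as_divergence_time else "patristic"
    return PhyloDistanceMatrix(species, values, kind)


@dataclass
class PhyloCovariance:
    """Phylogenetic covariance C (shared root-to-MRCA path lengths)."""

    species: list[str]
    C: np.ndarray
    lam: float = 1.0

    def __post_init__(self) -> None:
        C = np.asarray(self.C, dtype=float)
        if not np.allclose(C, C.T):
            raise PhyloError("covariance must be symmetric")
        self.C = C


def vcv_from_tree(phylogeny: Phylogeny) -> PhyloCovariance:
    """Build C from tip depths and patristic distances.

    Uses the tree identity d(i, j) = depth_i + depth_j - 2 C[i, j], which
    holds for additive (tree) distances, so C[i, j] is the root distance of
    the most recent common ancestor and C[i, i] the tip depth.
    """
    species = phylogeny.tip_labels
    depths = phylogeny._tip_depths()
    dvec = np.array([depths[s] for s in species])
    patristic = pairwise_divergence(phylogeny, as_divergence_time=False).values
    C = (dvec[:, None] + dvec[None, :] - patristic) / 2.0
    return PhyloCovariance(species, C, lam=1.0)


def lambda_transform(cov: PhyloCovariance, lam: float) -> PhyloCovariance:
    """Pagel's lambda: multiply off-diagonal covariances by lam in [0, 1]."""
    if not 0.0 <= lam <= 1.0:
        raise PhyloError(f"lambda must be in [0, 1], got {lam}")
    C = cov.C * lam
    np.fill_diagonal(C, np.diag(cov.C))
    return PhyloCovariance(cov.species, C, lam=lam)


def write_distance_csv(matrix: PhyloDistanceMatrix, path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame(matrix.values, index=matrix.species, columns=matrix.species).to_csv(path)
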