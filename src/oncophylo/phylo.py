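"""Phylogeny handling: Newick I/O, pruning, and the Brownian covariance matrix.

Trees are :class:`dendropy.Tree` objects throughout. What this module adds is
the comparative-methods layer: the species-by-species covariance matrix C
implied by Brownian motion on the tree (C_ij = shared root-to-MRCA path
length, C_ii = root-to-tip distance) and Pagel's λ transform, which scales
the off-diagonal of C by λ ∈ [0, 1] while leaving the diagonal unchanged.
λ = 1 recovers Brownian motion; λ = 0 erases phylogenetic signal (a star
phylogeny).

Branch lengths are used as-is (dated trees are typically in millions of
years); λ and the rate σ² absorb any overall scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np


def normalize_label(name: str) -> str:
    """Canonical tip-label form: underscores become spaces, whitespace collapsed."""
    return " ".join(str(name).replace("_", " ").split())


def read_newick(text: str) -> dendropy.Tree:
    """Parse a Newick string into a rooted tree.

    Polytomies are accepted. Duplicate tip labels are rejected because the
    species-to-row mapping of the covariance matrix must be unambiguous.
    """
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        if "Duplicate taxon labels" in str(exc):
            offender = str(exc).rsplit(":", 1)[-1].strip()
            raise ValueError(f"duplicate tip label: {offender!r}") from exc
        raise ValueError(f"malformed Newick: {exc}") from exc
    labels = [normalize_label(leaf.taxon.label) for leaf in tree.leaf_node_iter()]
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise ValueError(f"duplicate tip label: {lab!r}")
        seen.add(lab)
    return tree


def read_newick_file(path) -> dendropy.Tree:
    with open(path) as fh:
        return read_newick(fh.read())


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [normalize_label(leaf.taxon.label) for leaf in tree.leaf_node_iter()]


def prune_to_taxa(tree: dendropy.Tree, taxa) -> dendropy.Tree:
    """Prune a copy of ``tree`` down to ``taxa`` (normalized-label match).

    Path lengths between retained tips are preserved: unbranched internal
    nodes left behind by pruning are suppressed with their edge lengths
    summed. Requested taxa missing from the tree are ignored here (callers
    report them); if nothing overlaps a ``ValueError`` lists the missing set.
    """
    wanted = {normalize_label(t) for t in taxa}
    present = set(tip_labels(tree))
    keep = wanted & present
    if not keep:
        raise ValueError(
            f"no requested taxa found in tree; missing: {sorted(wanted - present)}"
        )
    pruned = tree.clone(depth=1)
    drop = [
        leaf.taxon
        for leaf in pruned.leaf_node_iter()
        if normalize_label(leaf.taxon.label) not in keep
    ]
    if drop:
        pruned.prune_taxa(drop, suppress_unifurcations=True)
    return pruned


@dataclass(frozen=True)
class PhyloCovariance:
    """Phylogenetic covariance matrix with its λ multiplier.

    ``matrix`` rows/columns follow ``taxa``. ``lam`` records the λ already
    applied (1.0 for the raw Brownian matrix).
    """

    taxa: tuple[str, ...]
    matrix: np.ndarray
    lam: float = 1.0

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("covariance shape does not match taxa")
        if not np.allclose(m, m.T, rtol=0, atol=1e-10):
            raise ValueError("covariance matrix must be symmetric")
        object.__setattr__(self, "matrix", m)

    @property
    def n(self) -> int:
        return len(self.taxa)

    def aligned_to(self, order) -> "PhyloCovariance":
        """Reindex rows/columns to the given species order."""
        order = [normalize_label(o) for o in order]
        pos = {t: i for i, t in enumerate(self.taxa)}
        missing = [o for o in order if o not in pos]
        if missing:
            raise KeyError(f"taxa not in covariance: {missing}")
        idx = np.array([pos[o] for o in order])
        return PhyloCovariance(tuple(order), self.matrix[np.ix_(idx, idx)], self.lam)


def _root_distances(tree: dendropy.Tree) -> dict:
    """Root-to-node distances; missing internal/tip branch lengths are errors."""
    dist: dict = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            dist[node] = node.edge.length or 0.0
            continue
        length = node.edge.length
        if length is None:
            raise ValueError("tree has a branch without a length")
        if length < 0:
            raise ValueError("negative branch length")
        dist[node] = dist[node.parent_node] + length
    return dist


def vcv(tree: dendropy.Tree) -> PhyloCovariance:
    """Brownian-motion covariance of the tip states, C.

    C_ij is the path length from the root to the most recent common ancestor
    of tips i and j; C_ii is the root-to-tip distance. For an ultrametric
    tree every C_ii equals the tree height. Computed in one postorder sweep:
    every tip pair split by an internal node at depth d gets C_ij = d.
    """
    depth = _root_distances(tree)
    leaves = [leaf for leaf in tree.leaf_node_iter()]
    taxa = tuple(normalize_label(leaf.taxon.label) for leaf in leaves)
    index = {leaf: i for i, leaf in enumerate(leaves)}
    n = len(leaves)
    C = np.zeros((n, n))
    tipsets: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = index[node]
            C[i, i] = depth[node]
            tipsets[node] = [i]
            continue
        children = node.child_nodes()
        sets = [tipsets.pop(ch) for ch in children]
        d = depth[node]
        for a in range(len(sets)):
            for b in range(a + 1, len(sets)):
                ia = np.asarray(sets[a])
                ib = np.asarray(sets[b])
                C[np.ix_(ia, ib)] = d
                C[np.ix_(ib, ia)] = d
        tipsets[node] = [i for s in sets for i in s]
    return PhyloCovariance(taxa, C, lam=1.0)


def lambda_transform(cov: PhyloCovariance, lam: float) -> PhyloCovariance:
    """Pagel's λ transform: off-diagonal entries scaled by λ, diagonal kept."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    C = cov.matrix
    out = lam * C + (1.0 - lam) * np.diag(np.diag(C))
    return PhyloCovariance(cov.taxa, out, lam=lam * cov.lam)


def tree_height(tree: dendropy.Tree) -> float:
    """Maximum root-to-tip distance."""
    depth = _root_distances(tree)
    return max(depth[leaf] for leaf in tree.leaf_node_iter())


def is_ultrametric(tree: dendropy.Tree, rel_tol: float = 1e-6) -> bool:
    depth = _root_distances(tree)
    tips = np.array([depth[leaf] for leaf in tree.leaf_node_iter()])
    h = tips.max()
    return bool(h == 0 or np.all(np.abs(tips - h) <= rel_tol * h))
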