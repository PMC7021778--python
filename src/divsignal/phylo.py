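"""Ultrametric family phylogenies and their matrix representations.

The comparative analyses in this package operate on a time-calibrated
(ultrametric) phylogeny whose tips are taxonomic families and whose branch
lengths are in million years (Ma).  Three interchangeable representations
are handled here:

* a rooted :class:`dendropy.Tree`;
* the *patristic* distance matrix (sum of branch lengths along the tip-to-tip
  path; on an ultrametric tree this equals twice the divergence-node age);
* the Brownian-motion covariance matrix ``C`` with ``C[i, j]`` equal to the
  shared root-to-MRCA path length, the residual covariance structure assumed
  by all BM-based statistics downstream.
"""

from __future__ import annotations

import io

import dendropy
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

__all__ = [
    "read_newick",
    "write_newick",
    "tip_labels",
    "tree_depth",
    "is_ultrametric",
    "patristic_matrix",
    "patristic_from_node_ages",
    "upgma",
    "bm_covariance",
]


def read_newick(source: str) -> dendropy.Tree:
    """Read a rooted tree from a Newick file path or literal string."""
    if "(" in source:
        return dendropy.Tree.get(data=source, schema="newick", rooting="force-rooted")
    return dendropy.Tree.get(path=source, schema="newick", rooting="force-rooted")


def write_newick(tree: dendropy.Tree, path: str | None = None) -> str:
    s = tree.as_string(schema="newick", suppress_rooting=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(s)
    return s


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def _root_distances(tree: dendropy.Tree) -> dict:
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    return {leaf.taxon.label: leaf.root_distance for leaf in tree.leaf_node_iter()}


def tree_depth(tree: dendropy.Tree) -> float:
    """Maximum root-to-tip path length (Ma)."""
    return max(_root_distances(tree).values())


def is_ultrametric(tree: dendropy.Tree, rtol: float = 1e-6) -> bool:
    """All root-to-tip path lengths equal within ``rtol`` times the depth."""
    d = np.array(list(_root_distances(tree).values()))
    depth = d.max()
    if depth == 0:
        return True
    return bool(np.ptp(d) <= rtol * depth)


def patristic_matrix(tree: dendropy.Tree) -> pd.DataFrame:
    """Tip-to-tip path-length matrix as a labeled square DataFrame."""
    pdm = tree.phylogenetic_distance_matrix()
    labels = tip_labels(tree)
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
    return pd.DataFrame(out, index=labels, columns=labels)


def patristic_from_node_ages(ages: pd.DataFrame) -> pd.DataFrame:
    """Patristic distances from a matrix of pairwise divergence-node ages.

    On an ultrametric tree the path between two tips goes up to their most
    recent common ancestor and back down, so the patristic distance is twice
    the node age.
    """
    a = np.asarray(ages, dtype=float)
    if a.shape[0] != a.shape[1]:
        raise ValueError("node-age matrix must be square")
    if not np.allclose(a, a.T, rtol=1e-8, atol=1e-10):
        raise ValueError("node-age matrix must be symmetric")
    if np.any(a < 0):
        raise ValueError("node ages must be nonnegative")
    d = 2.0 * a
    np.fill_diagonal(d, 0.0)
    labels = list(ages.index) if isinstance(ages, pd.DataFrame) else list(range(len(d)))
    return pd.DataFrame(d, index=labels, columns=labels)


def upgma(dist: pd.DataFrame) -> dendropy.Tree:
    """Average-linkage (UPGMA) tree from a patristic distance matrix.

    Node heights are half the average-linkage merge distance, so feeding an
    ultrametric patristic matrix reproduces it exactly (``patristic(upgma(d))
    == d``).  Output branch lengths inherit the input units (Ma).
    """
    d = np.asarray(dist, dtype=float)
    if d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, rtol=1e-8, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    labels = [str(x) for x in dist.index]
    n = len(labels)
    if n == 1:
        return read_newick(f"({labels[0]}:0.0);")
    Z = linkage(squareform(d, checks=False), method="average")
    # build newick bottom-up; cluster k>=n is row k-n of Z
    heights = np.zeros(2 * n - 1)
    nodes = {i: labels[i] for i in range(n)}
    for k, (a, b, h, _cnt) in enumerate(Z):
        a, b = int(a), int(b)
        ha, hb = h / 2.0 - heights[a], h / 2.0 - heights[b]
        heights[n + k] = h / 2.0
        nodes[n + k] = f"({nodes[a]}:{ha:.10g},{nodes[b]}:{hb:.10g})"
    return read_newick(nodes[2 * n - 2] + ";")


def bm_covariance(tree: dendropy.Tree, labels: list[str] | None = None) -> pd.DataFrame:
    """Brownian-motion covariance matrix of a (typically ultrametric) tree.

    ``C[i, j]`` is the shared path length from the root to the MRCA of tips
    *i* and *j*; the diagonal holds root-to-tip depths.  Computed for any
    rooted tree as ``(d_root(i) + d_root(j) - patristic(i, j)) / 2``.
    """
    rd = _root_distances(tree)
    if labels is None:
        labels = tip_labels(tree)
    pat = patristic_matrix(tree).loc[labels, labels].to_numpy()
    r = np.array([rd[l] for l in labels])
    C = (r[:, None] + r[None, :] - pat) / 2.0
    return pd.DataFrame(C, index=labels, columns=labels)
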