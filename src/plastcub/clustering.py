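"""RSCU-based clustering of taxa: codons x taxa matrix, dendrogram, Newick.

Codon usage vectors are a classical proxy for plastome relatedness: taxa
sharing a maternal lineage have near-identical pooled RSCU profiles, so
hierarchical agglomeration on the 59-dimensional RSCU columns recovers the
maternal topology.  Average linkage (UPGMA) on Euclidean distance is the
default; complete/ward linkage and correlation distance are options.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from skbio import TreeNode

from .genetic_code import DEFAULT_CODE, CodonCountTable, GeneticCode
from .indices import rscu

__all__ = ["rscu_matrix", "cluster_taxa", "distance_matrix", "to_newick"]


def rscu_matrix(taxon_counts: Mapping[str, CodonCountTable],
                code: GeneticCode = DEFAULT_CODE) -> pd.DataFrame:
    """59-codon x taxa matrix of RSCU values from pooled per-taxon counts.

    Rows follow a fixed order (amino acids alphabetically, codons
    alphabetically within each family); columns are taxon names in input
    order.
    """
    if len(taxon_counts) < 2:
        raise ValueError("rscu_matrix needs at least 2 taxa")
    row_order = list(code.analyzable_codons)
    cols = {}
    for taxon, counts in taxon_counts.items():
        if counts.total_codons == 0:
            raise ValueError(f"taxon {taxon!r} has an empty CDS set")
        vec = rscu(counts, code)
        cols[taxon] = [vec.values[c] for c in row_order]
    return pd.DataFrame(cols, index=row_order)


def distance_matrix(matrix: pd.DataFrame,
                    metric: str = "euclidean") -> pd.DataFrame:
    """Pairwise distances between taxon columns (symmetric, zero diagonal)."""
    taxa = list(matrix.columns)
    d = squareform(pdist(matrix.to_numpy(float).T, metric=metric))
    if not np.all(np.isfinite(d)):
        i, j = np.argwhere(~np.isfinite(d))[0]
        raise ValueError(f"non-finite distance between {taxa[i]} and {taxa[j]}")
    return pd.DataFrame(d, index=taxa, columns=taxa)


def cluster_taxa(matrix: pd.DataFrame, metric: str = "euclidean",
                 method: str = "average") -> TreeNode:
    """Hierarchical clustering of the RSCU columns into a taxon tree.

    Columns are ordered by taxon name before linkage so ties resolve
    deterministically; merge heights become branch lengths.  Returns a
    scikit-bio tree (Newick-serializable via :func:`to_newick`).
    """
    if matrix.shape[1] < 2:
        raise ValueError("clustering needs at least 2 taxa")
    ordered = matrix[sorted(matrix.columns)]
    x = ordered.to_numpy(float).T
    dist = pdist(x, metric=metric)
    if not np.all(np.isfinite(dist)):
        raise ValueError("non-finite distances; check the RSCU matrix")
    linkage = hierarchy.linkage(dist, method=method)
    tree = TreeNode.from_linkage_matrix(linkage, list(ordered.columns))
    # from_linkage_matrix can leave tiny negative lengths from float error
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return tree


def to_newick(tree: TreeNode) -> str:
    return str(tree).strip()
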