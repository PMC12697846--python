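"""Distance matrices from trees or sequences."""

from __future__ import annotations

import dendropy
import numpy as np
import pandas as pd


def patristic_distance_matrix(tree: dendropy.Tree) -> pd.DataFrame:
    """Leaf-to-leaf patristic (branch-length sum) distances as a DataFrame.

    Requires branch lengths on every edge on a leaf-to-leaf path.
    """
    for edge in tree.preorder_edge_iter():
        if edge.head_node is not tree.seed_node and edge.length is None:
            raise ValueError("tree has missing branch lengths")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    n = len(labels)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[i], taxa[j])
            mat[i, j] = mat[j, i] = d
    return pd.DataFrame(mat, index=labels, columns=labels)


def identity_distance_matrix(seqs: dict[str, str]) -> pd.DataFrame:
    """1 - pairwise alignment identity over a sequence set."""
    from habniche.microdiv import pairwise_identity

    ids = sorted(seqs)
    n = len(ids)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = 1.0 - pairwise_identity(seqs[ids[i]], seqs[ids[j]])
            mat[i, j] = mat[j, i] = d
    return pd.DataFrame(mat, index=ids, columns=ids)
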