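"""Phylogenetic distances: newick parsing, unit-height rescaling, patristic
matrix.

The regression predictor is the patristic distance (sum of branch lengths on
the tip-to-tip path) computed on a tree rescaled so that its height — the
maximum root-to-tip path length — equals 1. Rescaling divides every branch
by the same constant, so it changes only the scale of the distance matrix,
never its structure.
"""

from __future__ import annotations

from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "parse_newick",
    "rescale_to_unit_height",
    "tree_height",
    "patristic_matrix",
    "normalize_taxon",
    "read_distance_matrix",
    "write_distance_matrix",
]


def normalize_taxon(name: str) -> str:
    """Canonical taxon label: trimmed, spaces collapsed to underscores."""
    return "_".join(str(name).split())


def parse_newick(path_or_string: str | Path) -> dendropy.Tree:
    """Parse a newick tree, requiring branch lengths and unique tip labels."""
    from dendropy.dataio.newickreader import NewickReader

    src = str(path_or_string)
    try:
        if "(" in src and ";" in src:
            tree = dendropy.Tree.get(data=src, schema="newick", preserve_underscores=True)
        else:
            tree = dendropy.Tree.get(path=src, schema="newick", preserve_underscores=True)
    except NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise ValueError(f"duplicate tip labels in tree: {exc.message}") from exc
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate tip labels in tree")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise ValueError("tree has branches without lengths")
        if edge.length < 0:
            raise ValueError("negative branch length in tree")
    return tree


def tree_height(tree: dendropy.Tree) -> float:
    """Maximum root-to-tip path length."""
    tree.calc_node_root_distances(return_leaf_distances_only=True)
    return max(lf.root_distance for lf in tree.leaf_node_iter())


def rescale_to_unit_height(tree: dendropy.Tree) -> dendropy.Tree:
    """Divide every branch length by the tree height so the new maximum
    root-to-tip distance is exactly 1. Idempotent on unit-height trees."""
    h = tree_height(tree)
    if h <= 0:
        raise ValueError("tree height is zero; cannot rescale")
    out = tree.clone(depth=1)
    for edge in out.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length / h
    return out


def patristic_matrix(tree: dendropy.Tree) -> pd.DataFrame:
    """Symmetric tip-to-tip path-length matrix, rows/columns in tree tip
    order, labels normalized (spaces -> underscores)."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = [lf.taxon for lf in tree.leaf_node_iter()]
    labels = [normalize_taxon(t.label) for t in taxa]
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return pd.DataFrame(d, index=labels, columns=labels)


def read_distance_matrix(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Square labeled distance matrix (TSV, or CSV for .csv paths); labels
    normalized and symmetry checked."""
    if sep is None:
        sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = [normalize_taxon(x) for x in df.index]
    df.columns = [normalize_taxon(x) for x in df.columns]
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: matrix rows and columns differ")
    if not np.allclose(df.values, df.values.T, atol=1e-8):
        raise ValueError(f"{path}: matrix is not symmetric")
    return df


def write_distance_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", float_format="%.10g")
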