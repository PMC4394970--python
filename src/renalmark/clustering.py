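"""Median-centered two-way hierarchical clustering with CDT/GTR/ATR output.

Expression profiles are compared by shape: each gene row is centered
on its across-sample median, then genes and samples are clustered
agglomeratively with centered-Pearson similarity and average linkage
(the conventions of the classic Cluster 3.0 / Java TreeView pair).
Output files follow that trio: a CDT with rows and columns reordered
to tree leaf order, and GTR/ATR files listing merges as NODEnX lines.

Determinism: when two candidate merges tie on distance, the pair
containing the lowest original item index wins (then the lowest index
on the other side). The left child of a merge is the cluster with the
smaller minimum original index.

Exact field layout written (tab-separated):

    prefix.cdt   GID  UNIQID  NAME  GWEIGHT  <sample id...>
                 AID  (3 blanks) ARRY<i>X... (columns in leaf order)
                 EWEIGHT (3 blanks) 1...
                 GENE<i>X  <gene>  <gene>  1  <values...>   per gene,
                 rows in leaf order; <i> is the original row/column
                 index, values at full precision
    prefix.gtr   NODE<j+1>X  <child>  <child>  <similarity>  per
                 merge j in merge order; children are GENE<i>X or
                 NODE<k>X; similarity = 1 - merge distance
    prefix.atr   same with ARRY<i>X children
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dataio import ExpressionMatrix

__all__ = [
    "ClusterTree",
    "median_center",
    "hcluster",
    "write_cdt_gtr",
    "read_cdt_gtr",
]


def median_center(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each feature row's median so every row's median is zero.

    Idempotent; leaves annotations and units untouched (the values
    are no longer raw RPKM/RPM but median-centered versions thereof).
    """
    vals = matrix.values
    centered = vals.sub(vals.median(axis=1), axis=0)
    return ExpressionMatrix(values=centered, groups=matrix.groups,
                            unit=matrix.unit, ordinal_rank=dict(matrix.ordinal_rank))


@dataclass
class ClusterTree:
    """Result of agglomerative clustering on one axis.

    leaf_ids: item ids in input order. merges: (left, right,
    similarity) in merge order, where children are integers — 0..L-1
    for leaves (input order), L+j for the cluster made by merge j.
    leaf_order: original indices in dendrogram (left-subtree-first)
    order.
    """

    leaf_ids: list
    merges: list = field(default_factory=list)
    leaf_order: list = field(default_factory=list)

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    @property
    def ordered_ids(self) -> list:
        return [self.leaf_ids[i] for i in self.leaf_order]

    def validate(self) -> None:
        L = self.n_leaves
        if len(self.merges) != L - 1:
            raise ValueError(f"expected {L - 1} merges for {L} leaves, got {len(self.merges)}")
        seen = set()
        for left, right, _score in self.merges:
            for child in (left, right):
                if child in seen:
                    raise ValueError(f"child {child} referenced twice")
                seen.add(child)
        if sorted(self.leaf_order) != list(range(L)):
            raise ValueError("leaf_order is not a permutation of the leaves")


def _distance_matrix(X: np.ndarray, ids, metric: str) -> np.ndarray:
    if metric == "correlation":
        centered = X - X.mean(axis=1, keepdims=True)
        norms = np.sqrt((centered**2).sum(axis=1))
        flat = np.where(norms == 0)[0]
        if flat.size:
            raise ValueError(
                f"item {ids[flat[0]]!r} is constant; centered correlation is undefined"
            )
        corr = (centered @ centered.T) / np.outer(norms, norms)
        corr = np.clip(corr, -1.0, 1.0)
        return 1.0 - corr
    if metric == "euclidean":
        sq = (X**2).sum(axis=1)
        d2 = np.maximum(sq[:, None] + sq[None, :] - 2 * (X @ X.T), 0.0)
        return np.sqrt(d2)
    raise ValueError(f"unknown distance metric {metric!r}")


def hcluster(
    matrix: ExpressionMatrix | pd.DataFrame,
    axis: str = "genes",
    distance: str = "correlation",
    linkage: str = "average",
) -> ClusterTree:
    """Agglomerative clustering of genes (rows) or samples (columns).

    Average linkage uses the unweighted mean of original pairwise
    distances (UPGMA), maintained by the Lance-Williams size-weighted
    update; single/complete take min/max. Merge similarity is
    recorded as 1 - distance. Fully deterministic including ties (see
    module docstring).
    """
    vals = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    if axis == "genes":
        ids = list(vals.index)
        X = vals.to_numpy(dtype=float)
    elif axis == "samples":
        ids = list(vals.columns)
        X = vals.to_numpy(dtype=float).T
    else:
        raise ValueError("axis must be 'genes' or 'samples'")
    L = len(ids)
    if L < 2:
        raise ValueError("need at least 2 items to cluster")
    if linkage not in ("average", "single", "complete"):
        raise ValueError(f"unknown linkage {linkage!r}")

    D = _distance_matrix(X, ids, distance)
    # active clusters: key -> (node index, min original index, size)
    active: dict[int, tuple[int, int, int]] = {i: (i, i, 1) for i in range(L)}
    dist: dict[tuple[int, int], float] = {
        (i, j): float(D[i, j]) for i in range(L) for j in range(i + 1, L)
    }
    merges: list[tuple[int, int, float]] = []
    children: dict[int, tuple[int, int]] = {}
    next_node = L
    keys = list(range(L))
    while len(keys) > 1:
        best = None
        for a_i in range(len(keys)):
            for b_i in range(a_i + 1, len(keys)):
                a, b = keys[a_i], keys[b_i]
                d = dist[(min(a, b), max(a, b))]
                ma, mb = active[a][1], active[b][1]
                key = (d, min(ma, mb), max(ma, mb))
                if best is None or key < best[0]:
                    best = (key, a, b)
        (_d, _mi, _mj), a, b = best
        d_ab = dist[(min(a, b), max(a, b))]
        # left child = smaller min original index
        if active[a][1] <= active[b][1]:
            left_key, right_key = a, b
        else:
            left_key, right_key = b, a
        node_left = active[left_key][0]
        node_right = active[right_key][0]
        merges.append((node_left, node_right, 1.0 - d_ab))
        new_key = next_node
        children[new_key] = (node_left, node_right)
        na, nb = active[a][2], active[b][2]
        for k in keys:
            if k in (a, b):
                continue
            dak = dist[(min(a, k), max(a, k))]
            dbk = dist[(min(b, k), max(b, k))]
            if linkage == "average":
                dnew = (na * dak + nb * dbk) / (na + nb)
            elif linkage == "single":
                dnew = min(dak, dbk)
            else:
                dnew = max(dak, dbk)
            dist[(min(new_key, k), max(new_key, k))] = dnew
        active[new_key] = (new_key, min(active[a][1], active[b][1]), na + nb)
        keys = [k for k in keys if k not in (a, b)] + [new_key]
        next_node += 1

    # leaf order: left-subtree-first traversal from the root
    def _leaves(node: int) -> list[int]:
        if node < L:
            return [node]
        left, right = children[node]
        return _leaves(left) + _leaves(right)

    leaf_order = _leaves(next_node - 1)
    tree = ClusterTree(leaf_ids=ids, merges=merges, leaf_order=leaf_order)
    tree.validate()
    return tree


def _child_name(child: int, L: int, leaf_prefix: str) -> str:
    if child < L:
        return f"{leaf_prefix}{child}X"
    return f"NODE{child - L + 1}X"


def _write_tree(tree: ClusterTree, path, leaf_prefix: str) -> None:
    L = tree.n_leaves
    with open(path, "w") as fh:
        for j, (left, right, score) in enumerate(tree.merges):
            fh.write(
                f"NODE{j + 1}X\t{_child_name(left, L, leaf_prefix)}"
                f"\t{_child_name(right, L, leaf_prefix)}\t{score!r}\n"
            )


def write_cdt_gtr(
    matrix: ExpressionMatrix | pd.DataFrame,
    gene_tree: ClusterTree,
    sample_tree: ClusterTree,
    prefix,
) -> dict:
    """Write prefix.cdt / prefix.gtr / prefix.atr for TreeView-style display.

    Rows and columns are reordered to the trees' leaf orders; GID/AID
    labels encode the original indices so a reread recovers the trees
    exactly.
    """
    vals = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    if list(vals.index) != list(gene_tree.leaf_ids):
        raise ValueError("gene tree leaves do not match matrix rows")
    if list(vals.columns) != list(sample_tree.leaf_ids):
        raise ValueError("sample tree leaves do not match matrix columns")
    prefix = Path(prefix)
    cdt, gtr, atr = (prefix.with_suffix(s) for s in (".cdt", ".gtr", ".atr"))
    row_order = gene_tree.leaf_order
    col_order = sample_tree.leaf_order
    X = vals.to_numpy(dtype=float)
    with open(cdt, "w") as fh:
        sample_names = [str(vals.columns[j]) for j in col_order]
        fh.write("GID\tUNIQID\tNAME\tGWEIGHT\t" + "\t".join(sample_names) + "\n")
        fh.write("AID\t\t\t\t" + "\t".join(f"ARRY{j}X" for j in col_order) + "\n")
        fh.write("EWEIGHT\t\t\t\t" + "\t".join("1" for _ in col_order) + "\n")
        for i in row_order:
            gid = str(vals.index[i])
            row = "\t".join(repr(float(X[i, j])) for j in col_order)
            fh.write(f"GENE{i}X\t{gid}\t{gid}\t1\t{row}\n")
    _write_tree(gene_tree, gtr, "GENE")
    _write_tree(sample_tree, atr, "ARRY")
    return {"cdt": cdt, "gtr": gtr, "atr": atr}


def _parse_child(token: str, L: int, leaf_prefix: str) -> int:
    if token.startswith(leaf_prefix):
        return int(token[len(leaf_prefix):-1])
    if token.startswith("NODE"):
        return L + int(token[4:-1]) - 1
    raise ValueError(f"unparseable tree child token {token!r}")


def _read_tree(path, L: int, leaf_ids: list, leaf_order: list, leaf_prefix: str) -> ClusterTree:
    merges = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}: malformed tree line {line!r}")
            merges.append(
                (
                    _parse_child(parts[1], L, leaf_prefix),
                    _parse_child(parts[2], L, leaf_prefix),
                    float(parts[3]),
                )
            )
    tree = ClusterTree(leaf_ids=leaf_ids, merges=merges, leaf_order=leaf_order)
    tree.validate()
    return tree


def read_cdt_gtr(prefix) -> tuple[pd.DataFrame, ClusterTree, ClusterTree]:
    """Re-read a CDT/GTR/ATR trio written by :func:`write_cdt_gtr`.

    Returns the data frame in original (input) row/column order plus
    the two trees with their leaf orders.
    """
    prefix = Path(prefix)
    with open(prefix.with_suffix(".cdt")) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        aid = fh.readline().rstrip("\n").split("\t")
        fh.readline()  # EWEIGHT
        sample_names = header[4:]
        col_order = [int(t[4:-1]) for t in aid[4:]]
        row_order, gene_ids, rows = [], {}, {}
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            i = int(parts[0][4:-1])
            row_order.append(i)
            gene_ids[i] = parts[1]
            rows[i] = [float(v) for v in parts[4:]]
    L_rows, L_cols = len(row_order), len(col_order)
    # undo the column reordering to restore original column positions
    col_ids = [None] * L_cols
    for pos, j in enumerate(col_order):
        col_ids[j] = sample_names[pos]
    data = np.empty((L_rows, L_cols))
    index = [None] * L_rows
    for i in sorted(rows):
        index[i] = gene_ids[i]
        for pos, j in enumerate(col_order):
            data[i, j] = rows[i][pos]
    df = pd.DataFrame(data, index=index, columns=col_ids)
    gene_tree = _read_tree(prefix.with_suffix(".gtr"), L_rows, list(df.index), row_order, "GENE")
    sample_tree = _read_tree(prefix.with_suffix(".atr"), L_cols, list(df.columns), col_order, "ARRY")
    return df, gene_tree, sample_tree
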