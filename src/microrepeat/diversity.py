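"""Alpha and beta diversity metrics for rarefied count tables.

Univariate (alpha) metrics: taxon richness, Pielou-normalised Shannon
evenness (log base 2), and Faith's phylogenetic diversity on a rooted tree.
Pairwise (beta) metrics: Bray-Curtis dissimilarity and unweighted / weighted
UniFrac. `distance_matrix` applies any of these across all library pairs.

Phylogenetic metrics operate on a rooted tree with branch lengths whose
leaves cover the analysed taxa. Faith's PD here is root-inclusive: the branch
path from the observed subtree's MRCA up to the root is counted, matching the
convention of the classic QIIME pipeline (switchable).
"""

from __future__ import annotations

import warnings

import numpy as np
from skbio import TreeNode

from .counts import CountTable

__all__ = [
    "Phylogeny",
    "DistanceMatrix",
    "richness",
    "evenness",
    "faith_pd",
    "bray_curtis",
    "unweighted_unifrac",
    "weighted_unifrac",
    "distance_matrix",
    "METRICS",
]


class Phylogeny:
    """Rooted phylogeny over the taxa, backed by an skbio TreeNode.

    Precomputes, for every branch (edge above a non-root node), its length and
    the set of leaves below it — the representation UniFrac and Faith's PD
    operate on.
    """

    def __init__(self, tree: TreeNode):
        self.tree = tree
        self.leaf_names = [t.name for t in tree.tips()]
        if len(set(self.leaf_names)) != len(self.leaf_names):
            raise ValueError("duplicate leaf labels")
        self._leaf_index = {n: i for i, n in enumerate(self.leaf_names)}
        n = len(self.leaf_names)
        lengths = []
        masks = []
        for node in tree.postorder(include_self=False):
            bl = node.length if node.length is not None else 0.0
            if bl < 0:
                raise ValueError("negative branch length")
            mask = np.zeros(n, dtype=bool)
            if node.is_tip():
                mask[self._leaf_index[node.name]] = True
            else:
                for tip in node.tips():
                    mask[self._leaf_index[tip.name]] = True
            lengths.append(bl)
            masks.append(mask)
        self.branch_lengths = np.asarray(lengths)          # (n_branches,)
        self.branch_leaf_masks = np.asarray(masks)         # (n_branches, n_leaves)

    # ------------------------------------------------------------------ IO
    @classmethod
    def from_newick(cls, source) -> "Phylogeny":
        return cls(TreeNode.read(source, format="newick"))

    def to_newick(self, path) -> None:
        self.tree.write(path, format="newick")

    @property
    def total_branch_length(self) -> float:
        return float(self.branch_lengths.sum())

    def leaf_abundance_vector(self, column, taxon_ids) -> np.ndarray:
        """Map a count column (indexed by taxon_ids) onto the tree's leaves.

        Taxa absent from the tree raise: silently dropping them corrupts the
        UniFrac denominator.
        """
        missing = [t for t, c in zip(taxon_ids, column)
                   if c > 0 and t not in self._leaf_index]
        if missing:
            raise KeyError(f"taxa not found in the tree: {missing[:5]}"
                           + ("..." if len(missing) > 5 else ""))
        vec = np.zeros(len(self.leaf_names))
        for t, c in zip(taxon_ids, column):
            if t in self._leaf_index:
                vec[self._leaf_index[t]] = c
        return vec


class DistanceMatrix:
    """Symmetric library x library dissimilarity matrix with zero diagonal."""

    def __init__(self, ids, data):
        self.ids = list(ids)
        data = np.asarray(data, dtype=float)
        if data.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape mismatch")
        if np.any(data < 0):
            raise ValueError("negative dissimilarities")
        if not np.allclose(data, data.T, atol=1e-12):
            raise ValueError("matrix not symmetric")
        if not np.allclose(np.diag(data), 0):
            raise ValueError("nonzero diagonal")
        self.data = (data + data.T) / 2.0
        np.fill_diagonal(self.data, 0.0)

    def __getitem__(self, pair):
        i, j = pair
        return self.data[self.ids.index(i), self.ids.index(j)]

    def subset(self, ids) -> "DistanceMatrix":
        idx = [self.ids.index(i) for i in ids]
        return DistanceMatrix(list(ids), self.data[np.ix_(idx, idx)])

    def to_tsv(self, path) -> None:
        import pandas as pd
        pd.DataFrame(self.data, index=self.ids, columns=self.ids).to_csv(
            path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "DistanceMatrix":
        import pandas as pd
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index), df.to_numpy())


# --------------------------------------------------------------------------
# alpha metrics
# --------------------------------------------------------------------------

def richness(column) -> int:
    """Number of taxa with count > 0."""
    return int(np.count_nonzero(np.asarray(column)))


def evenness(column) -> float:
    """Pielou evenness: Shannon H (log2) divided by log2(richness).

    1 iff all present taxa are equiabundant; undefined (NaN, with a warning)
    when fewer than two taxa are present.
    """
    col = np.asarray(column, dtype=float)
    s = richness(col)
    if s < 2:
        warnings.warn("evenness undefined for richness < 2", RuntimeWarning,
                      stacklevel=2)
        return float("nan")
    p = col[col > 0] / col.sum()
    h = -(p * np.log2(p)).sum()
    return float(h / np.log2(s))


def faith_pd(column, tree: Phylogeny, taxon_ids=None,
             root_inclusive: bool = True) -> float:
    """Faith's phylogenetic diversity of one library.

    Sum of branch lengths spanned by the observed taxa. Root-inclusive by
    default: branches from the observed subtree's MRCA up to the root count.
    When all leaves are observed this equals the total tree length.
    """
    if taxon_ids is None:
        taxon_ids = tree.leaf_names
    vec = tree.leaf_abundance_vector(np.asarray(column), taxon_ids)
    present = vec > 0
    if not present.any():
        return 0.0
    on_path = tree.branch_leaf_masks[:, present].any(axis=1)
    if not root_inclusive:
        # exclude branches ancestral to ALL observed leaves (root-to-MRCA path)
        covers_all = tree.branch_leaf_masks[:, present].all(axis=1)
        on_path = on_path & ~covers_all
    return float(tree.branch_lengths[on_path].sum())


# --------------------------------------------------------------------------
# beta metrics
# --------------------------------------------------------------------------

def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity: sum|x-y| / sum(x+y), in [0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    denom = (x + y).sum()
    if denom == 0:
        raise ValueError("Bray-Curtis undefined for two empty libraries")
    return float(np.abs(x - y).sum() / denom)


def unweighted_unifrac(x, y, tree: Phylogeny, taxon_ids=None) -> float:
    """Unweighted UniFrac: unique branch length / total covered branch length.

    Presence/absence only, hence invariant to abundance rescaling.
    """
    if taxon_ids is None:
        taxon_ids = tree.leaf_names
    px = tree.leaf_abundance_vector(np.asarray(x), taxon_ids) > 0
    py = tree.leaf_abundance_vector(np.asarray(y), taxon_ids) > 0
    in_x = tree.branch_leaf_masks[:, px].any(axis=1) if px.any() else \
        np.zeros(len(tree.branch_lengths), dtype=bool)
    in_y = tree.branch_leaf_masks[:, py].any(axis=1) if py.any() else \
        np.zeros(len(tree.branch_lengths), dtype=bool)
    union = in_x | in_y
    unique = in_x ^ in_y
    denom = tree.branch_lengths[union].sum()
    if denom == 0:
        raise ValueError("UniFrac undefined: no observed branches")
    return float(tree.branch_lengths[unique].sum() / denom)


def weighted_unifrac(x, y, tree: Phylogeny, taxon_ids=None,
                     normalized: bool = False) -> float:
    """Weighted UniFrac: sum over branches of length * |p_x - p_y|.

    p(b) is the fraction of a library's reads on leaves below branch b. The
    raw (non-normalised) value is the default; `normalized=True` divides by
    the abundance-weighted maximum (sum over leaves of root-to-leaf depth
    times the two relative abundances), bounding the value in [0, 1].
    """
    if taxon_ids is None:
        taxon_ids = tree.leaf_names
    vx = tree.leaf_abundance_vector(np.asarray(x, dtype=float), taxon_ids)
    vy = tree.leaf_abundance_vector(np.asarray(y, dtype=float), taxon_ids)
    if vx.sum() == 0 or vy.sum() == 0:
        raise ValueError("weighted UniFrac undefined for an empty library")
    px = vx / vx.sum()
    py = vy / vy.sum()
    bx = tree.branch_leaf_masks @ px
    by = tree.branch_leaf_masks @ py
    raw = float(tree.branch_lengths @ np.abs(bx - by))
    if not normalized:
        return raw
    depths = tree.branch_lengths @ tree.branch_leaf_masks  # root-to-leaf depth
    dmax = float(depths @ (px + py))
    return raw / dmax if dmax > 0 else 0.0


# --------------------------------------------------------------------------
# distance-matrix construction
# --------------------------------------------------------------------------

METRICS = ("richness", "evenness", "faith_pd", "bray_curtis",
           "unweighted_unifrac", "weighted_unifrac")


def distance_matrix(table: CountTable, metric: str,
                    tree: Phylogeny | None = None,
                    **metric_kwargs) -> DistanceMatrix:
    """Pairwise dissimilarity matrix over all libraries of a count table.

    `metric` is one of "bray_curtis", "unweighted_unifrac",
    "weighted_unifrac". The framework's four standard dissimilarities are
    class-level Bray-Curtis, species-level Bray-Curtis (aggregate the table
    first), and the two UniFracs.
    """
    pairwise = {
        "bray_curtis": lambda a, b: bray_curtis(a, b),
        "unweighted_unifrac": lambda a, b: unweighted_unifrac(
            a, b, tree, table.taxon_ids),
        "weighted_unifrac": lambda a, b: weighted_unifrac(
            a, b, tree, table.taxon_ids, **metric_kwargs),
    }
    if metric not in pairwise:
        raise ValueError(f"unknown pairwise metric {metric!r}")
    if metric.endswith("unifrac") and tree is None:
        raise ValueError("UniFrac requires a phylogeny")
    f = pairwise[metric]
    n = table.n_libraries
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = f(table.counts[:, i], table.counts[:, j])
    return DistanceMatrix(table.library_ids, D)


def alpha_table(table: CountTable, metrics=("richness", "evenness"),
                tree: Phylogeny | None = None):
    """Per-library alpha metric table (libraries x metrics) as a DataFrame."""
    import pandas as pd
    funcs = {
        "richness": lambda c: richness(c),
        "evenness": lambda c: evenness(c),
        "faith_pd": lambda c: faith_pd(c, tree, table.taxon_ids),
    }
    out = {}
    for m in metrics:
        if m not in funcs:
            raise ValueError(f"unknown alpha metric {m!r}")
        if m == "faith_pd" and tree is None:
            raise ValueError("faith_pd requires a phylogeny")
        out[m] = [funcs[m](table.counts[:, j]) for j in range(table.n_libraries)]
    return pd.DataFrame(out, index=table.library_ids)
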