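"""Distance-based trees for the duplication-before-speciation test.

Poisson-corrected protein distances feed canonical neighbor joining
(Saitou-Nei). If each paralog's cross-species ortholog pair is
monophyletic when the tree is rooted on an outgroup, the duplications
that created the paralogs predate the species split.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import dendropy
import numpy as np

__all__ = [
    "DistanceMatrix",
    "Tree",
    "poisson_distance",
    "distance_matrix_from_peptides",
    "nj_tree",
    "is_monophyletic",
    "robinson_foulds",
    "filter_gappy_columns",
]


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValueError("duplicate labels")
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("matrix is not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(self.d < 0):
            raise ValueError("distances must be non-negative")

    def to_phylip(self) -> str:
        lines = [f" {len(self.labels)}"]
        for lab, row in zip(self.labels, self.d):
            lines.append(lab.ljust(12) + " ".join(f"{x:.6f}" for x in row))
        return "\n".join(lines) + "\n"


@dataclass
class Tree:
    """A phylogenetic tree, stored as newick plus a dendropy handle."""

    newick: str

    def dendropy_tree(self, taxon_namespace=None) -> dendropy.Tree:
        return dendropy.Tree.get(
            data=self.newick,
            schema="newick",
            taxon_namespace=taxon_namespace,
            preserve_underscores=True,
        )

    @property
    def leaf_labels(self) -> list[str]:
        t = self.dendropy_tree()
        return sorted(l.taxon.label for l in t.leaf_node_iter())


def poisson_distance(aa_a: str, aa_b: str) -> float:
    """Poisson-corrected distance -ln(1 - p) over shared ungapped columns.

    Returns inf when p >= 1 cannot be corrected (never happens for p < 1).
    """
    if len(aa_a) != len(aa_b):
        raise ValueError("aligned sequences must be equal length")
    shared = [(x, y) for x, y in zip(aa_a, aa_b) if x != "-" and y != "-"]
    if not shared:
        raise ValueError("no shared ungapped columns")
    p = sum(1 for x, y in shared if x != y) / len(shared)
    if p >= 1:
        return math.inf
    return -math.log1p(-p)


def filter_gappy_columns(seqs: dict[str, str], max_gap_fraction: float = 0.5) -> dict[str, str]:
    """Drop alignment columns whose gap fraction exceeds the threshold."""
    if not seqs:
        return {}
    ncol = len(next(iter(seqs.values())))
    keep = []
    for c in range(ncol):
        gaps = sum(1 for s in seqs.values() if s[c] == "-")
        if gaps / len(seqs) <= max_gap_fraction:
            keep.append(c)
    return {k: "".join(s[c] for c in keep) for k, s in seqs.items()}


def distance_matrix_from_peptides(seqs: dict[str, str]) -> DistanceMatrix:
    """Pairwise Poisson distances of pre-aligned peptides (sorted labels)."""
    labels = sorted(seqs)
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = poisson_distance(seqs[labels[i]], seqs[labels[j]])
    return DistanceMatrix(labels, d)


def _quote(label: str) -> str:
    return label.replace(" ", "_").replace("(", "_").replace(")", "_").replace(",", "_").replace(":", "_").replace(";", "_")


def nj_tree(dm: DistanceMatrix) -> Tree:
    """Canonical Saitou-Nei neighbor joining with deterministic tie-breaks.

    Ties in the Q matrix are broken by (label, label) order. Negative
    branch lengths are clamped to zero and the deficit moved to the
    sibling branch, keeping path lengths between the joined pair intact.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    # active nodes: newick fragment and label key for tie-breaking
    nodes = [(_quote(lab), _quote(lab)) for lab in dm.labels]
    d = dm.d.astype(float).copy()
    active = list(range(n))
    while len(active) > 2:
        m = len(active)
        # Q matrix over active nodes
        sums = {i: sum(d[i, j] for j in active if j != i) for i in active}
        best = None
        for ai in range(m):
            for bi in range(ai + 1, m):
                i, j = active[ai], active[bi]
                q = (m - 2) * d[i, j] - sums[i] - sums[j]
                key = (q, min(nodes[i][1], nodes[j][1]), max(nodes[i][1], nodes[j][1]))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        dij = d[i, j]
        li = 0.5 * dij + (sums[i] - sums[j]) / (2 * (len(active) - 2))
        lj = dij - li
        # clamp negatives, moving the deficit to the sibling branch
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        new_frag = f"({nodes[i][0]}:{li:.10f},{nodes[j][0]}:{lj:.10f})"
        new_key = min(nodes[i][1], nodes[j][1])
        # distances from the new node u to every other active node
        new_idx = len(nodes)
        d = np.pad(d, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            d[new_idx, k] = d[k, new_idx] = 0.5 * (d[i, k] + d[j, k] - dij)
        nodes.append((new_frag, new_key))
        active = [k for k in active if k not in (i, j)] + [new_idx]
    i, j = active
    # order the final join deterministically by key
    if nodes[j][1] < nodes[i][1]:
        i, j = j, i
    newick = f"({nodes[i][0]}:{max(d[i, j], 0.0) / 2:.10f},{nodes[j][0]}:{max(d[i, j], 0.0) / 2:.10f});"
    return Tree(newick=newick)


def is_monophyletic(tree: Tree, taxa: set[str], outgroup: str) -> bool:
    """True iff `taxa` form a clade once the tree is rooted on `outgroup`."""
    taxa = {_quote(t) for t in taxa}
    outgroup = _quote(outgroup)
    t = tree.dendropy_tree()
    labels = {l.taxon.label for l in t.leaf_node_iter()}
    unknown = (taxa | {outgroup}) - labels
    if unknown:
        raise ValueError(f"unknown leaf labels: {sorted(unknown)}")
    if outgroup in taxa:
        raise ValueError("outgroup cannot be in the tested taxa")
    og = t.find_node_with_taxon_label(outgroup)
    t.reroot_at_edge(og.edge, update_bipartitions=True)
    if len(taxa) == 1:
        return True
    mrca = t.mrca(taxon_labels=list(taxa))
    clade = {l.taxon.label for l in mrca.leaf_iter()}
    return clade == taxa


def robinson_foulds(tree_a: Tree, tree_b: Tree) -> int:
    """Unweighted RF distance between two trees over the same leaf set."""
    tns = dendropy.TaxonNamespace()
    ta = tree_a.dendropy_tree(taxon_namespace=tns)
    tb = tree_b.dendropy_tree(taxon_namespace=tns)
    ta.encode_bipartitions()
    tb.encode_bipartitions()
    return int(dendropy.calculate.treecompare.symmetric_difference(ta, tb))
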