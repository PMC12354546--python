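"""Phylogenetic trees with branch-class labels and time calibration.

Branch-model analyses (dN/dS ladders, local clocks) assign every branch of a
tree to an integer rate class.  Two labeling routes are supported:

* codeml-style ``#k`` suffixes on node labels in the Newick string, e.g.
  ``((A#1:0.1,B#1:0.1)#1:0.05,C:0.2);`` — a suffix labels the branch leading
  to that node;
* clade maps: a ``{class_name: [taxon, ...]}`` mapping; every branch inside
  the minimal subtree spanning a clade's taxa (optionally including the stem)
  receives that clade's class.

Unlabeled branches belong to the background class 0.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import dendropy
import numpy as np

__all__ = ["LabeledTree", "Chronogram", "TreeArrays"]

_CLASS_SUFFIX = re.compile(r"\s*#(\d+)\s*$")


@dataclass
class TreeArrays:
    """Array view of a (possibly multifurcating) tree for pruning.

    Nodes are numbered in postorder; the root is the last index.  For every
    non-root node ``i``, ``parent[i]`` is its parent's index, ``lengths[i]``
    the branch length of the edge above it and ``classes[i]`` that edge's
    integer class.  ``leaf_index[i]`` maps a leaf node to its row in the
    taxon list (−1 for internal nodes).
    """

    n_nodes: int
    parent: np.ndarray
    lengths: np.ndarray
    classes: np.ndarray
    leaf_index: np.ndarray
    postorder: np.ndarray
    children: list[list[int]]
    taxa: list[str]

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    @property
    def edges(self) -> np.ndarray:
        """Indices of non-root nodes, i.e. edges (node, parent[node])."""
        return np.array([i for i in self.postorder if i != self.root], dtype=int)

    def leafsets(self) -> list[frozenset]:
        """Per node: the set of taxa below it (topology-stable edge key)."""
        out: list[frozenset] = [frozenset()] * self.n_nodes
        for i in self.postorder:
            if self.leaf_index[i] >= 0:
                out[i] = frozenset([self.taxa[self.leaf_index[i]]])
            else:
                acc: set = set()
                for k in self.children[i]:
                    acc |= out[k]
                out[i] = frozenset(acc)
        return out


class LabeledTree:
    """A phylogeny whose branches carry integer rate-class labels.

    Parameters
    ----------
    tree:
        A ``dendropy.Tree``.  Branch lengths are expected substitutions per
        site (codon or nucleotide, depending on the analysis).
    rooted:
        Whether the tree is to be treated as rooted.  One-ratio dN/dS fits
        conventionally use the unrooted (basal multifurcation) form; branch
        models with ≥2 classes use the rooted form.
    """

    def __init__(self, tree: dendropy.Tree, rooted: bool = True):
        self.tree = tree
        self.rooted = rooted
        # dendropy's MRCA machinery needs an explicit rootedness state.
        tree.is_rooted = bool(rooted)
        for edge in tree.preorder_edge_iter():
            if not hasattr(edge, "class_id"):
                edge.class_id = 0
        self._validate()

    # ------------------------------------------------------------------ io

    @classmethod
    def from_newick(cls, newick: str, rooted: bool = True) -> "LabeledTree":
        """Parse Newick, honouring codeml-style ``#k`` branch-class suffixes."""
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
        for node in tree.preorder_node_iter():
            label = node.taxon.label if node.taxon is not None else node.label
            if label is None:
                node.edge.class_id = 0
                continue
            m = _CLASS_SUFFIX.search(label)
            if m:
                node.edge.class_id = int(m.group(1))
                stripped = label[: m.start()]
                if node.taxon is not None:
                    node.taxon.label = stripped
                else:
                    node.label = stripped or None
            else:
                node.edge.class_id = 0
        return cls(tree, rooted=rooted)

    def to_newick(self) -> str:
        """Serialize with ``#k`` suffixes on branches of class > 0."""
        import copy

        # full deep copy: a shallow clone shares Taxon objects, and the
        # label rewriting below must not mutate the original tree
        clone = copy.deepcopy(self.tree)
        for e_orig, e_new in zip(
            self.tree.preorder_edge_iter(), clone.preorder_edge_iter()
        ):
            e_new.class_id = e_orig.class_id
        for node in clone.preorder_node_iter():
            cid = getattr(node.edge, "class_id", 0)
            if cid:
                if node.taxon is not None:
                    node.taxon.label = f"{node.taxon.label}#{cid}"
                else:
                    node.label = f"{node.label or ''}#{cid}"
        return clone.as_string(schema="newick", unquoted_underscores=True).strip()

    # ------------------------------------------------------- labeling

    def label_clades(
        self,
        clades: dict[str, list[str]],
        include_stem: bool = True,
        class_ids: dict[str, int] | None = None,
    ) -> dict[str, int]:
        """Assign branch classes from named taxon groups.

        Every branch inside the minimal spanning subtree of a clade's taxa
        gets that clade's class id (1, 2, ... in iteration order unless
        ``class_ids`` is given).  Returns the name → class-id mapping.
        """
        assigned: dict[str, int] = {}
        next_id = 1
        for name, taxa in clades.items():
            cid = class_ids[name] if class_ids else next_id
            next_id = max(next_id, cid) + 1 if not class_ids else next_id + 1
            assigned[name] = cid
            mrca = self.tree.mrca(taxon_labels=taxa)
            if mrca is None:
                raise ValueError(f"clade {name!r}: taxa not found in tree")
            for node in mrca.preorder_iter():
                if node is mrca and not include_stem:
                    continue
                node.edge.class_id = cid
        self._validate()
        return assigned

    def is_monophyletic(self, taxa: set[str]) -> bool:
        mrca = self.tree.mrca(taxon_labels=sorted(taxa))
        if mrca is None:
            return False
        leaves = {lf.taxon.label for lf in mrca.leaf_iter()}
        return leaves == set(taxa)

    # ------------------------------------------------------- properties

    @property
    def taxa(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    @property
    def n_classes(self) -> int:
        return max(e.class_id for e in self.tree.preorder_edge_iter()) + 1

    def _validate(self) -> None:
        ids = sorted({e.class_id for e in self.tree.preorder_edge_iter()})
        if ids != list(range(len(ids))):
            raise ValueError(f"branch class labels must be contiguous 0..k-1, got {ids}")
        for e in self.tree.preorder_edge_iter():
            if e.length is not None and e.length < 0:
                raise ValueError("negative branch length")

    # ------------------------------------------------------- conversions

    def unrooted(self) -> "LabeledTree":
        """Collapse the root bifurcation into a basal multifurcation."""
        clone = self.tree.clone(depth=1)
        cls_by_edge = {}
        for e_orig, e_new in zip(
            self.tree.preorder_edge_iter(), clone.preorder_edge_iter()
        ):
            e_new.class_id = e_orig.class_id
        clone.deroot()
        out = LabeledTree.__new__(LabeledTree)
        out.tree = clone
        out.rooted = False
        for edge in clone.preorder_edge_iter():
            if not hasattr(edge, "class_id"):
                edge.class_id = 0
        out._validate()
        return out

    def subtree(self, taxa: set[str]) -> "LabeledTree":
        """Extract the subtree induced by ``taxa`` (suppressing unifurcations).

        Branch-class labels are reset to 0: a subtree of a labeled tree is
        used for within-cluster computations where the labels of the full
        design no longer apply.
        """
        clone = self.tree.clone(depth=1)
        clone.retain_taxa_with_labels(sorted(taxa))
        for edge in clone.preorder_edge_iter():
            edge.class_id = 0
        return LabeledTree(clone, rooted=self.rooted)

    def to_arrays(self, taxa_order: list[str] | None = None) -> TreeArrays:
        """Postorder array form.  Branch lengths None → 0."""
        nodes = list(self.tree.postorder_node_iter())
        index = {id(n): i for i, n in enumerate(nodes)}
        n = len(nodes)
        parent = np.full(n, -1, dtype=int)
        lengths = np.zeros(n)
        classes = np.zeros(n, dtype=int)
        leaf_index = np.full(n, -1, dtype=int)
        children: list[list[int]] = [[] for _ in range(n)]
        taxa = taxa_order if taxa_order is not None else self.taxa
        taxon_pos = {t: i for i, t in enumerate(taxa)}
        for i, node in enumerate(nodes):
            if node.parent_node is not None:
                p = index[id(node.parent_node)]
                parent[i] = p
                children[p].append(i)
                lengths[i] = node.edge.length or 0.0
                classes[i] = node.edge.class_id
            if node.is_leaf():
                if node.taxon.label not in taxon_pos:
                    raise ValueError(f"taxon {node.taxon.label!r} not in alignment")
                leaf_index[i] = taxon_pos[node.taxon.label]
        return TreeArrays(
            n_nodes=n,
            parent=parent,
            lengths=lengths,
            classes=classes,
            leaf_index=leaf_index,
            postorder=np.arange(n),
            children=children,
            taxa=taxa,
        )


class Chronogram(LabeledTree):
    """A rooted, time-calibrated tree: node ages plus branch rate classes.

    Branch lengths of the input Newick are interpreted as time spans (e.g.
    million years); ages are computed as depth below the maximum root-to-tip
    path, so an ultrametric input yields tip ages of 0.
    """

    def __init__(self, tree: dendropy.Tree):
        super().__init__(tree, rooted=True)
        self._compute_ages()

    @classmethod
    def from_newick(cls, newick: str, rooted: bool = True) -> "Chronogram":
        lt = LabeledTree.from_newick(newick, rooted=True)
        return cls(lt.tree)

    def _compute_ages(self) -> None:
        tree = self.tree
        depth = {id(tree.seed_node): 0.0}
        maxd = 0.0
        for node in tree.preorder_node_iter():
            if node.parent_node is not None:
                d = depth[id(node.parent_node)] + (node.edge.length or 0.0)
                depth[id(node)] = d
                maxd = max(maxd, d)
        for node in tree.preorder_node_iter():
            node.age_my = maxd - depth[id(node)]
        if maxd <= 0:
            raise ValueError("chronogram must have positive depth")

    @property
    def root_age(self) -> float:
        return self.tree.seed_node.age_my

    def durations(self, arrays: TreeArrays | None = None) -> np.ndarray:
        """Per-node time span of the branch above each node (postorder ids)."""
        nodes = list(self.tree.postorder_node_iter())
        out = np.zeros(len(nodes))
        for i, node in enumerate(nodes):
            if node.parent_node is not None:
                out[i] = node.parent_node.age_my - node.age_my
                if out[i] < -1e-9:
                    raise ValueError("child older than parent in chronogram")
        return np.maximum(out, 0.0)
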