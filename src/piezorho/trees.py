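"""Tagged phylogenies: Newick trees whose branches carry fg/bg labels.

Foreground (fg) branches are those tested for an elevated radical-substitution
rate (in the motivating analysis, the stems and members of the deep-diving
clades); everything else is background (bg). Two tagging dialects are
supported and must agree when both are present:

* inline ``#1`` suffixes on Newick labels (the branch above the labelled node
  is foreground), and
* a clade list: for each named clade (internal-node label, or a list of tip
  labels resolved to their MRCA) all branches inside the clade plus its stem
  are foreground.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

FG, BG = "fg", "bg"
_TAG_SUFFIX = "#1"


@dataclass
class TaggedTree:
    """A rooted working copy of the phylogeny with per-branch fg/bg tags.

    Node arrays are in postorder; ``parent[i]`` is the postorder index of node
    i's parent (-1 at the root). Edge lengths are expected substitutions per
    codon on the edge above each node.
    """

    tree: dendropy.Tree
    nodes: list = field(repr=False)
    parent: np.ndarray = field(repr=False)
    edge_length: np.ndarray = field(repr=False)
    edge_tag: list = field(repr=False)
    taxa: list = field(default_factory=list)

    # -- construction ------------------------------------------------------
    @classmethod
    def from_newick(cls, source: str, fg_clades=None, path: bool | None = None) -> "TaggedTree":
        """Parse a Newick tree; ``source`` is a path if it names an existing
        file (or path=True), otherwise a Newick string."""
        import os

        is_path = path if path is not None else os.path.exists(source)
        tree = dendropy.Tree.get(
            **({"path": source} if is_path else {"data": source}),
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
        return cls.from_dendropy(tree, fg_clades=fg_clades)

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree, fg_clades=None) -> "TaggedTree":
        inline_fg = set()
        for nd in tree:
            label = nd.taxon.label if nd.taxon else nd.label
            if label and label.endswith(_TAG_SUFFIX):
                clean = label[: -len(_TAG_SUFFIX)]
                if nd.taxon:
                    nd.taxon.label = clean
                else:
                    nd.label = clean
                inline_fg.add(id(nd))

        clade_fg = set()
        if fg_clades:
            for clade in fg_clades:
                members = cls._resolve_clade(tree, clade)
                clade_fg.update(id(nd) for nd in members)

        if inline_fg and clade_fg and inline_fg != clade_fg:
            raise ValueError(
                "conflicting foreground specifications: inline #1 tags and the "
                "clade list select different branch sets"
            )
        fg_ids = inline_fg | clade_fg

        nodes = list(tree.postorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        parent = np.full(len(nodes), -1, dtype=np.int64)
        lengths = np.zeros(len(nodes))
        tags = []
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                if nd.edge.length is not None and nd.edge.length < 0:
                    raise ValueError("negative branch length in input tree")
                lengths[i] = nd.edge.length or 0.0
            tags.append(FG if id(nd) in fg_ids else BG)
        taxa = [nd.taxon.label for nd in nodes if nd.is_leaf()]
        if len(set(taxa)) != len(taxa):
            raise ValueError("duplicate taxon labels in tree")
        return cls(tree=tree, nodes=nodes, parent=parent, edge_length=lengths,
                   edge_tag=tags, taxa=taxa)

    @staticmethod
    def _resolve_clade(tree: dendropy.Tree, clade):
        """A clade given as an internal-node label or a list of tip labels;
        returns the MRCA node plus all of its descendants (stem included via
        the MRCA's own edge)."""
        if isinstance(clade, str):
            mrca = next(
                (nd for nd in tree.preorder_node_iter() if nd.label == clade), None
            )
            if mrca is None:
                raise ValueError(f"clade label {clade!r} not found in tree")
        else:
            taxa = [t for t in tree.taxon_namespace if t.label in set(clade)]
            if len(taxa) != len(set(clade)):
                found = {t.label for t in taxa}
                raise ValueError(f"clade tips not in tree: {sorted(set(clade) - found)}")
            tree.is_rooted = True
            mrca = tree.mrca(taxa=taxa)
        return list(mrca.preorder_iter())

    # -- queries -----------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def is_leaf(self, i: int) -> bool:
        return self.nodes[i].is_leaf()

    def node_label(self, i: int) -> str | None:
        nd = self.nodes[i]
        return nd.taxon.label if nd.taxon else nd.label

    def leaf_indices(self) -> dict[str, int]:
        return {self.node_label(i): i for i in range(self.n_nodes) if self.is_leaf(i)}

    def find_node(self, label: str) -> int:
        for i in range(self.n_nodes):
            if self.node_label(i) == label:
                return i
        raise KeyError(f"node label {label!r} not found")

    def mrca_index(self, tip_labels) -> int:
        """Postorder index of the MRCA of the given tips."""
        leaf = self.leaf_indices()
        try:
            want = {leaf[t] for t in tip_labels}
        except KeyError as e:
            raise KeyError(f"tip {e.args[0]!r} not in tree") from None
        # climb from one tip, collecting ancestors; first common one wins
        below = {i: {i} for i in range(self.n_nodes) if self.is_leaf(i)}
        for i in range(self.n_nodes):  # postorder: children first
            if not self.is_leaf(i):
                below[i] = set().union(
                    *[below[j] for j in range(self.n_nodes) if self.parent[j] == i]
                ) | {i}
        for i in range(self.n_nodes):
            leaves_below = {j for j in below[i] if self.is_leaf(j)}
            if want <= leaves_below:
                return i
        raise RuntimeError("MRCA not found (disconnected tree?)")

    def children(self, i: int) -> list[int]:
        return [j for j in range(self.n_nodes) if self.parent[j] == i]

    @property
    def root_index(self) -> int:
        return self.n_nodes - 1  # postorder puts the root last

    @property
    def fg_edges(self) -> list[int]:
        return [i for i, t in enumerate(self.edge_tag) if t == FG and self.parent[i] >= 0]

    def with_edge_lengths(self, lengths: np.ndarray) -> "TaggedTree":
        out = TaggedTree(tree=self.tree, nodes=self.nodes, parent=self.parent,
                         edge_length=np.asarray(lengths, dtype=float).copy(),
                         edge_tag=list(self.edge_tag), taxa=list(self.taxa))
        return out

    def free_edge_indices(self) -> list[int]:
        """Edges with an optimizable length (every non-root edge)."""
        return [i for i in range(self.n_nodes) if self.parent[i] >= 0]


def read_tagged_tree(path: str, fg_clades=None) -> TaggedTree:
    """Read a Newick file and tag branches (spec op)."""
    return TaggedTree.from_newick(path, fg_clades=fg_clades, path=True)
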