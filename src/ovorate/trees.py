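"""Phylogeny container: a thin, branch-addressable wrapper around dendropy.

Branches are addressed by the label of their *child* node: tip branches by
the taxon name, internal branches by a deterministic post-order label
("N1", "N2", ...) assigned at construction when the newick carries none.
The same labels key per-branch rates (omega), branch lengths, and the
free-ratio output tables.
"""

from __future__ import annotations

import io

import dendropy


class TreeError(ValueError):
    pass


class PhyloTree:
    """Tree topology with nonnegative branch lengths and unique tip labels."""

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._label_nodes()
        self._validate()

    # -- construction ----------------------------------------------------
    @classmethod
    def from_newick(cls, source: str) -> "PhyloTree":
        """Parse a newick string (or the contents of a file-like path)."""
        tree = dendropy.Tree.get(
            data=source, schema="newick", preserve_underscores=True
        )
        return cls(tree)

    @classmethod
    def read(cls, path) -> "PhyloTree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def to_newick(self) -> str:
        out = io.StringIO()
        self._tree.write(
            file=out,
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
        )
        return out.getvalue().strip()

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    # -- internals -------------------------------------------------------
    def _label_nodes(self) -> None:
        counter = 1
        for node in self._tree.postorder_node_iter():
            if node.taxon is not None:
                node._ov_label = node.taxon.label
            elif node.label:
                node._ov_label = node.label
            else:
                node._ov_label = f"N{counter}"
                counter += 1

    def _validate(self) -> None:
        tips = self.tip_labels
        if len(set(tips)) != len(tips):
            raise TreeError("tip labels are not unique")
        for node in self._tree.postorder_node_iter():
            if node.parent_node is None:
                continue
            if node.edge.length is not None and node.edge.length < 0:
                raise TreeError(f"negative branch length on {node._ov_label!r}")

    # -- queries ---------------------------------------------------------
    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self._tree.leaf_node_iter()]

    @property
    def branch_labels(self) -> list[str]:
        """Labels of all branches (child-node labels), post-order."""
        return [
            n._ov_label
            for n in self._tree.postorder_node_iter()
            if n.parent_node is not None
        ]

    @property
    def branch_lengths(self) -> dict[str, float]:
        return {
            n._ov_label: (n.edge.length if n.edge.length is not None else 0.0)
            for n in self._tree.postorder_node_iter()
            if n.parent_node is not None
        }

    def with_branch_lengths(self, lengths: dict[str, float]) -> "PhyloTree":
        clone = PhyloTree(self._tree.clone(depth=1))
        for node in clone._tree.postorder_node_iter():
            if node.parent_node is not None:
                node.edge.length = float(lengths[node._ov_label])
        return clone

    def is_rooted_binary(self) -> bool:
        root = self._tree.seed_node
        return len(root.child_nodes()) == 2

    # -- structure for pruning/covariance --------------------------------
    def postorder_structure(self):
        """Post-order node table for likelihood computation.

        Returns a list of dicts with keys ``label``, ``parent`` (index or
        None), ``length``, ``is_tip``; the root is last.
        """
        nodes = list(self._tree.postorder_node_iter())
        index = {id(n): i for i, n in enumerate(nodes)}
        table = []
        for n in nodes:
            table.append(
                {
                    "label": n._ov_label,
                    "parent": index[id(n.parent_node)] if n.parent_node else None,
                    "length": n.edge.length if n.edge.length is not None else 0.0,
                    "is_tip": n.is_leaf(),
                }
            )
        return table

    def mrca_depths(self) -> tuple[list[str], "dict[tuple[str, str], float]"]:
        """Root-to-MRCA path lengths for every tip pair (incl. self pairs).

        The tree is treated as rooted at its seed node.
        """
        self._tree.is_rooted = True
        depths: dict[int, float] = {}
        for node in self._tree.preorder_node_iter():
            if node.parent_node is None:
                depths[id(node)] = 0.0
            else:
                edge = node.edge.length if node.edge.length is not None else 0.0
                depths[id(node)] = depths[id(node.parent_node)] + edge
        tips = self.tip_labels
        leaf = {l.taxon.label: l for l in self._tree.leaf_node_iter()}
        out: dict[tuple[str, str], float] = {}
        for a in tips:
            for b in tips:
                if a == b:
                    out[(a, b)] = depths[id(leaf[a])]
                else:
                    mrca = self._tree.mrca(taxa=[leaf[a].taxon, leaf[b].taxon])
                    out[(a, b)] = depths[id(mrca)]
        return tips, out


def star_tree(tips: list[str], lengths: "list[float] | float") -> PhyloTree:
    """Star phylogeny with the given tip branch lengths."""
    if isinstance(lengths, (int, float)):
        lengths = [float(lengths)] * len(tips)
    inner = ",".join(f"{t}:{l}" for t, l in zip(tips, lengths))
    return PhyloTree.from_newick(f"({inner});")
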