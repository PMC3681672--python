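"""Rooted, dated genealogies of serially sampled biopsies.

Time convention: node times are calendar years relative to baseline
endoscopy (baseline = 0, later sampling positive, ancestral history
negative).  A parent is strictly older (smaller time) than its children.
The tree root is the LUCA node — the last ancestor carrying the unaltered
(all-zero) genomic state, placed at the segment initiation time — whose
single child is the MRCA of the sampled biopsies; the LUCA->MRCA edge is
the stem branch.

Newick/NEXUS serialization goes through dendropy; node times are encoded
as branch lengths in years plus a root comment recording the LUCA time so
absolute times survive a round-trip.
"""

from __future__ import annotations

import io
from typing import Iterator

import dendropy


class TreeNode:
    """One node of a :class:`SampledTree` (lightweight, mutable)."""

    __slots__ = ("name", "time", "children", "parent")

    def __init__(self, name: str | None = None, time: float = 0.0):
        self.name = name
        self.time = float(time)
        self.children: list[TreeNode] = []
        self.parent: TreeNode | None = None

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "tip" if self.is_leaf else "node"
        return f"<{kind} {self.name or ''} t={self.time:.3f}>"


class SampledTree:
    """Binary rooted genealogy with dated tips and a LUCA stem branch.

    Parameters
    ----------
    luca : TreeNode
        Root node (the LUCA); must have exactly one child, the MRCA.
    """

    def __init__(self, luca: TreeNode):
        if len(luca.children) != 1:
            raise ValueError("LUCA must have exactly one child (the MRCA)")
        self.luca = luca
        self.validate()

    # ------------------------------------------------------------------ basic
    @property
    def mrca(self) -> TreeNode:
        return self.luca.children[0]

    def postorder(self) -> Iterator[TreeNode]:
        """Children before parents, LUCA last."""
        stack = [(self.luca, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded or node.is_leaf:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.luca]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def tips(self) -> list[TreeNode]:
        return [n for n in self.postorder() if n.is_leaf]

    def tip_names(self) -> list[str]:
        return [n.name for n in self.tips()]

    def internal_nodes(self) -> list[TreeNode]:
        return [n for n in self.postorder() if not n.is_leaf and n is not self.luca]

    def branches(self) -> list[tuple[TreeNode, float, float]]:
        """All (child_node, start_time, end_time) edges, including the stem."""
        out = []
        for node in self.postorder():
            if node.parent is not None:
                out.append((node, node.parent.time, node.time))
        return out

    def total_branch_time(self) -> float:
        return sum(end - start for _, start, end in self.branches())

    def validate(self) -> None:
        seen_names = set()
        for node in self.postorder():
            if node.parent is not None and node.parent.time >= node.time:
                raise ValueError(
                    f"parent time {node.parent.time} not older than child {node.time}"
                )
            if node.is_leaf:
                if not node.name:
                    raise ValueError("every tip must be named")
                if node.name in seen_names:
                    raise ValueError(f"duplicate tip name {node.name!r}")
                seen_names.add(node.name)
            elif node is not self.luca and len(node.children) != 2:
                raise ValueError("internal nodes must be binary")

    def copy(self) -> "SampledTree":
        mapping: dict[int, TreeNode] = {}
        for node in self.preorder():
            clone = TreeNode(node.name, node.time)
            mapping[id(node)] = clone
            if node.parent is not None:
                mapping[id(node.parent)].add_child(clone)
        return SampledTree(mapping[id(self.luca)])

    # ------------------------------------------------------------------- I/O
    def to_dendropy(self) -> dendropy.Tree:
        taxa = dendropy.TaxonNamespace()
        dtree = dendropy.Tree(taxon_namespace=taxa)
        dmap = {id(self.luca): dtree.seed_node}
        dtree.seed_node.label = "LUCA"
        dtree.seed_node.comments.append(f"&luca_time={self.luca.time!r}")
        for node in self.preorder():
            if node is self.luca:
                continue
            dnode = dmap[id(node.parent)].new_child()
            dnode.edge.length = node.time - node.parent.time
            if node.is_leaf:
                dnode.taxon = taxa.new_taxon(node.name)
            dmap[id(node)] = dnode
        return dtree

    def to_newick(self) -> str:
        return self.to_dendropy().as_string(
            schema="newick",
            suppress_rooting=True,
            suppress_internal_node_labels=False,
            suppress_item_comments=False,
        ).strip() + "\n"

    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree, luca_time: float | None = None) -> "SampledTree":
        seed = dtree.seed_node
        if luca_time is None:
            for comment in seed.comments:
                text = comment.lstrip("&")
                if text.startswith("luca_time="):
                    luca_time = float(text.split("=", 1)[1])
                    break
        if luca_time is None:
            luca_time = 0.0
        luca = TreeNode("LUCA" if seed.taxon is None else seed.taxon.label, luca_time)
        stack = [(seed, luca)]
        while stack:
            dnode, node = stack.pop()
            for dchild in dnode.child_nodes():
                length = dchild.edge.length or 0.0
                child = TreeNode(time=node.time + length)
                if dchild.is_leaf():
                    child.name = dchild.taxon.label if dchild.taxon else dchild.label
                node.add_child(child)
                stack.append((dchild, child))
        return cls(luca)

    @classmethod
    def from_newick(cls, text: str, luca_time: float | None = None) -> "SampledTree":
        dtree = dendropy.Tree.get(
            file=io.StringIO(text),
            schema="newick",
            extract_comment_metadata=False,
            suppress_internal_node_taxa=True,
        )
        return cls.from_dendropy(dtree, luca_time=luca_time)


def caterpillar(names: list[str], tip_time: float = 0.0, step: float = 1.0) -> SampledTree:
    """Fully unbalanced (ladder) tree fixture with contemporaneous tips."""
    if len(names) < 2:
        raise ValueError("need at least two tips")
    node = TreeNode(time=tip_time - step)
    node.add_child(TreeNode(names[0], tip_time))
    node.add_child(TreeNode(names[1], tip_time))
    for i, name in enumerate(names[2:], start=2):
        parent = TreeNode(time=tip_time - i * step)
        parent.add_child(node)
        parent.add_child(TreeNode(name, tip_time))
        node = parent
    luca = TreeNode("LUCA", node.time - step)
    luca.add_child(node)
    return SampledTree(luca)


def balanced(names: list[str], tip_time: float = 0.0, step: float = 1.0) -> SampledTree:
    """Balanced tree fixture for a power-of-two number of contemporaneous tips."""
    n = len(names)
    if n & (n - 1) or n < 2:
        raise ValueError("balanced fixture needs a power-of-two tip count >= 2")
    level: list[TreeNode] = [TreeNode(nm, tip_time) for nm in names]
    depth = 1
    while len(level) > 1:
        nxt = []
        for i in range(0, len(level), 2):
            parent = TreeNode(time=tip_time - depth * step)
            parent.add_child(level[i])
            parent.add_child(level[i + 1])
            nxt.append(parent)
        level = nxt
        depth += 1
    luca = TreeNode("LUCA", level[0].time - step)
    luca.add_child(level[0])
    return SampledTree(luca)
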