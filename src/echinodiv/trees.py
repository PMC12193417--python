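"""Phylogenetic tree container and Newick serialization.

A :class:`Tree` is a rooted representation of a (possibly unrooted) topology:
NJ trees are stored with a trifurcating root node, so no information about
rootedness is invented.  Branch lengths are non-negative; internal nodes may
carry integer bootstrap supports (0-100) which are written as plain internal
node labels in Newick output.

Newick dialect: leaf names containing any of ``()[]:;,'`` or whitespace are
single-quoted, with embedded single quotes doubled; branch lengths are written
to six decimal places.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

from .errors import ValidationError

_NEEDS_QUOTE = set("()[]:;,' \t\n")


@dataclass
class Node:
    name: Optional[str] = None
    length: float = 0.0
    support: Optional[int] = None
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self) -> Iterator["Node"]:
        """Pre-order traversal."""
        yield self
        for child in self.children:
            yield from child.walk()


@dataclass
class Tree:
    root: Node

    def leaves(self) -> list[Node]:
        return [n for n in self.root.walk() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def validate(self) -> None:
        names = self.leaf_names()
        if any(n is None or n == "" for n in names):
            raise ValidationError("tree contains an unnamed leaf")
        if len(set(names)) != len(names):
            raise ValidationError("duplicate leaf names in tree")
        for n in self.root.walk():
            if n.length < 0:
                raise ValidationError(f"negative branch length at node {n.name!r}")
            if n.support is not None and n.is_leaf:
                raise ValidationError("bootstrap support on a leaf")

    # -- topology -----------------------------------------------------------

    def bipartitions(self) -> dict[frozenset, Node]:
        """Non-trivial bipartitions induced by internal edges.

        Each internal edge splits the leaf set in two; the split is keyed by
        the canonical side *not* containing the lexicographically smallest
        leaf, so the key is invariant to where the tree happens to be rooted.
        Trivial splits (single leaf / all leaves) are omitted.
        """
        all_leaves = frozenset(self.leaf_names())
        anchor = min(all_leaves)
        out: dict[frozenset, Node] = {}
        for node in self.root.walk():
            if node is self.root or node.is_leaf:
                continue
            side = frozenset(n.name for n in node.walk() if n.is_leaf)
            if anchor in side:
                side = all_leaves - side
            if len(side) >= 2 and len(all_leaves - side) >= 2:
                out[side] = node
        return out

    def path_lengths(self) -> dict[tuple[str, str], float]:
        """Sum of branch lengths between every pair of leaves."""
        dists: dict[tuple[str, str], float] = {}

        def collect(node: Node) -> dict[str, float]:
            if node.is_leaf:
                return {node.name: node.length}
            sub = [collect(c) for c in node.children]
            for i in range(len(sub)):
                for j in range(i + 1, len(sub)):
                    for a, da in sub[i].items():
                        for b, db in sub[j].items():
                            key = (a, b) if a < b else (b, a)
                            dists[key] = da + db
            merged = {k: v + node.length for d in sub for k, v in d.items()}
            return merged

        collect(self.root)
        return dists

    # -- serialization ------------------------------------------------------

    def to_newick(self) -> str:
        return _node_to_newick(self.root, is_root=True) + ";"


def _quote(name: str) -> str:
    if any(c in _NEEDS_QUOTE for c in name):
        return "'" + name.replace("'", "''") + "'"
    return name


def _node_to_newick(node: Node, is_root: bool = False) -> str:
    if node.is_leaf:
        if not node.name:
            raise ValidationError("cannot serialize an unnamed leaf")
        body = _quote(node.name)
    else:
        inner = ",".join(_node_to_newick(c) for c in node.children)
        label = "" if node.support is None else str(int(node.support))
        body = f"({inner}){label}"
    if is_root:
        return body
    return f"{body}:{node.length:.6f}"
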