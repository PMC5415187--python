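"""Phylogenetic tree structure, Newick/NEXUS I/O, splits, distances and consensus.

The in-memory tree is a plain rooted node structure.  An unrooted tree is
represented with a basal multifurcation (``rooted=False``); every method that
is meaningful only up to root placement (splits, Robinson-Foulds distance,
consensus) works on the induced bipartitions and is therefore independent of
where the structure happens to be anchored.

Parsing goes through :mod:`dendropy`; serialization is a small emitter that
writes branch lengths to 10 significant digits and node annotations as
``[&key=value,...]`` comments, which dendropy reads back.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Mapping, Sequence

import dendropy


class TreeError(ValueError):
    pass


class Node:
    __slots__ = ("children", "parent", "length", "label", "annotations")

    def __init__(self, label: str | None = None, length: float | None = None):
        self.children: list[Node] = []
        self.parent: Node | None = None
        self.length = length
        self.label = label
        self.annotations: dict = {}

    def add_child(self, node: "Node") -> "Node":
        node.parent = self
        self.children.append(node)
        return node

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"<Node {self.label or '*'}>"


class PhyloTree:
    """A (possibly multifurcating) tree with leaves labelled by taxa."""

    def __init__(self, root: Node, rooted: bool = False):
        self.root = root
        self.rooted = rooted

    # -- construction ---------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str, rooted: bool | None = None) -> "PhyloTree":
        dt = dendropy.Tree.get(
            data=newick, schema="newick", extract_comment_metadata=True,
            suppress_internal_node_taxa=True,
        )
        tree = _from_dendropy(dt)
        if rooted is not None:
            tree.rooted = rooted
        return tree

    def copy(self) -> "PhyloTree":
        def rec(nd: Node) -> Node:
            new = Node(nd.label, nd.length)
            new.annotations = dict(nd.annotations)
            for c in nd.children:
                new.add_child(rec(c))
            return new

        return PhyloTree(rec(self.root), self.rooted)

    # -- traversal ------------------------------------------------------

    def postorder(self) -> Iterator[Node]:
        stack = [(self.root, False)]
        while stack:
            nd, seen = stack.pop()
            if seen:
                yield nd
            else:
                stack.append((nd, True))
                for c in reversed(nd.children):
                    stack.append((c, False))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            nd = stack.pop()
            yield nd
            stack.extend(reversed(nd.children))

    def leaves(self) -> list[Node]:
        return [nd for nd in self.postorder() if nd.is_leaf]

    @property
    def leaf_labels(self) -> list[str]:
        return [nd.label for nd in self.leaves()]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def edges(self) -> list[Node]:
        """Every non-root node owns the edge to its parent."""
        return [nd for nd in self.postorder() if nd is not self.root]

    # -- topology -------------------------------------------------------

    def is_binary(self) -> bool:
        """Fully resolved as an unrooted tree (root degree 3, others 2)."""
        for nd in self.postorder():
            if nd.is_leaf:
                continue
            want = 3 if (nd is self.root and not self.rooted) else 2
            if nd is self.root and self.rooted:
                want = 2
            if len(nd.children) != want:
                return False
        return True

    def suppress_unifurcations(self) -> None:
        changed = True
        while changed:
            changed = False
            for nd in list(self.postorder()):
                if not nd.is_leaf and len(nd.children) == 1:
                    child = nd.children[0]
                    if nd.length is not None or child.length is not None:
                        child.length = (nd.length or 0.0) + (child.length or 0.0)
                    if nd.parent is None:
                        child.parent = None
                        self.root = child
                    else:
                        i = nd.parent.children.index(nd)
                        nd.parent.children[i] = child
                        child.parent = nd.parent
                    changed = True
                    break

    def deroot(self) -> None:
        """Collapse a degree-2 root into a basal multifurcation (unrooted form)."""
        self.rooted = False
        while len(self.root.children) == 2 and not all(
            c.is_leaf for c in self.root.children
        ):
            keep, merge = self.root.children
            if merge.is_leaf:
                keep, merge = merge, keep
            self.root.children = [keep] + merge.children
            for c in merge.children:
                c.parent = self.root
                if c.length is not None or merge.length is not None:
                    c.length = (c.length or 0.0) + (merge.length or 0.0)
            keep.parent = self.root

    def splits(self, trivial: bool = False) -> dict[frozenset, Node]:
        """Canonical bipartitions, as the side *not* containing the reference leaf.

        The reference is the lexicographically smallest taxon, so split sets
        from trees anchored at different points are directly comparable.
        """
        labels = self.leaf_labels
        if len(set(labels)) != len(labels):
            raise TreeError("duplicate leaf labels")
        all_set = frozenset(labels)
        ref = min(labels)
        out: dict[frozenset, Node] = {}
        below: dict[int, frozenset] = {}
        for nd in self.postorder():
            if nd.is_leaf:
                below[id(nd)] = frozenset([nd.label])
            else:
                below[id(nd)] = frozenset().union(*(below[id(c)] for c in nd.children))
            if nd is self.root:
                continue
            side = below[id(nd)]
            if ref in side:
                side = all_set - side
            if not trivial and (len(side) < 2 or len(side) > len(all_set) - 2):
                continue
            out[side] = nd
        return out

    def topology_key(self) -> frozenset:
        """Hashable identity of the unrooted topology."""
        return frozenset(self.splits().keys())

    def rf_distance(self, other: "PhyloTree") -> int:
        if set(self.leaf_labels) != set(other.leaf_labels):
            raise TreeError("trees are on different leaf sets")
        return len(set(self.splits()) ^ set(other.splits()))

    def mrca(self, labels: Iterable[str]) -> Node:
        want = set(labels)
        missing = want - set(self.leaf_labels)
        if missing:
            raise TreeError(f"labels not on tree: {sorted(missing)}")
        below: dict[int, set] = {}
        best = self.root
        for nd in self.postorder():
            if nd.is_leaf:
                below[id(nd)] = {nd.label} & want
            else:
                below[id(nd)] = set().union(*(below[id(c)] for c in nd.children))
            if below[id(nd)] == want:
                return nd
        return best

    # -- serialization --------------------------------------------------

    def to_newick(self, annotations: bool = True, lengths: bool = True) -> str:
        def fmt(nd: Node) -> str:
            if nd.is_leaf:
                s = _escape_label(nd.label or "")
            else:
                s = "(" + ",".join(fmt(c) for c in nd.children) + ")"
                if nd.label:
                    s += _escape_label(nd.label)
            if annotations and nd.annotations:
                items = ",".join(f"{k}={_fmt_val(v)}" for k, v in nd.annotations.items())
                s += f"[&{items}]"
            if lengths and nd.length is not None:
                s += f":{nd.length:.10g}"
            return s

        return fmt(self.root) + ";"

    def __repr__(self):  # pragma: no cover
        return f"<PhyloTree {self.n_leaves} leaves>"


def _escape_label(label: str) -> str:
    return label.replace(" ", "_")


def _fmt_val(v) -> str:
    if isinstance(v, float):
        return f"{v:.10g}"
    return str(v)


def _from_dendropy(dt: dendropy.Tree) -> PhyloTree:
    nodes: dict = {}
    for dnd in dt.preorder_node_iter():
        label = None
        if dnd.taxon is not None:
            label = dnd.taxon.label.replace(" ", "_")
        elif dnd.is_leaf() and dnd.label:
            label = dnd.label.replace(" ", "_")
        nd = Node(label, dnd.edge.length)
        for ann in dnd.annotations:
            nd.annotations[ann.name] = _maybe_number(ann.value)
        if dnd.label and not dnd.is_leaf():
            # internal labels are treated as support annotations
            nd.annotations.setdefault("label", _maybe_number(dnd.label))
        nodes[dnd] = nd
        if dnd.parent_node is not None:
            nodes[dnd.parent_node].add_child(nd)
    tree = PhyloTree(nodes[dt.seed_node], rooted=bool(dt.is_rooted))
    tree.suppress_unifurcations()
    return tree


def _maybe_number(v):
    if isinstance(v, str):
        try:
            f = float(v)
        except ValueError:
            return v
        return int(f) if f.is_integer() and "." not in v and "e" not in v.lower() else f
    return v


# -- file I/O -----------------------------------------------------------


def read_trees(path) -> list[PhyloTree]:
    """Read trees from a Newick or NEXUS file (auto-detected)."""
    with open(path) as fh:
        text = fh.read()
    schema = "nexus" if text.lstrip().upper().startswith("#NEXUS") else "newick"
    try:
        tl = dendropy.TreeList.get(
            data=text, schema=schema, extract_comment_metadata=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises assorted error types
        raise TreeError(f"could not parse tree file {path}: {exc}") from exc
    return [_from_dendropy(t) for t in tl]


def write_trees(trees: Sequence[PhyloTree], path, schema: str = "nexus") -> None:
    with open(path, "w") as fh:
        if schema == "newick":
            for t in trees:
                fh.write(t.to_newick() + "\n")
            return
        fh.write("#NEXUS\nBEGIN TREES;\n")
        for i, t in enumerate(trees, 1):
            flag = "[&R] " if t.rooted else "[&U] "
            fh.write(f"    TREE tree_{i} = {flag}{t.to_newick()}\n")
        fh.write("END;\n")


# -- consensus ----------------------------------------------------------


def tree_from_clades(
    leaf_labels: Iterable[str],
    clades: Mapping[frozenset, float],
) -> PhyloTree:
    """Build the unrooted tree displaying a pairwise-compatible clade set.

    ``clades`` maps each canonical split side (not containing the reference
    leaf) to a frequency, stored on the node as the ``support`` annotation.
    """
    labels = sorted(set(leaf_labels))
    root = Node()
    span: dict[int, frozenset] = {}
    for lab in labels:
        leaf = root.add_child(Node(lab))
        span[id(leaf)] = frozenset([lab])
    span[id(root)] = frozenset(labels)
    for clade in sorted(clades, key=len, reverse=True):
        # descend to the smallest node whose span contains the clade
        nd = root
        while True:
            nxt = next(
                (c for c in nd.children if not c.is_leaf and span[id(c)] >= clade),
                None,
            )
            if nxt is None:
                break
            nd = nxt
        inside = [c for c in nd.children if span[id(c)] <= clade]
        if frozenset().union(*(span[id(c)] for c in inside)) != clade:
            raise TreeError("incompatible clade set")
        new = Node()
        new.annotations["support"] = clades[clade]
        for c in inside:
            nd.children.remove(c)
            new.add_child(c)
        nd.add_child(new)
        span[id(new)] = clade
    return PhyloTree(root, rooted=False)


def _split_counts(trees: Sequence[PhyloTree]) -> tuple[dict[frozenset, int], list[str]]:
    labels = trees[0].leaf_labels
    lset = set(labels)
    counts: dict[frozenset, int] = {}
    for t in trees:
        if set(t.leaf_labels) != lset:
            raise TreeError("consensus requires identical leaf sets")
        for s in t.splits():
            counts[s] = counts.get(s, 0) + 1
    return counts, labels


def strict_consensus(trees: Sequence[PhyloTree]) -> PhyloTree:
    counts, labels = _split_counts(trees)
    n = len(trees)
    keep = {s: 1.0 for s, c in counts.items() if c == n}
    return tree_from_clades(labels, keep)


def majority_consensus(trees: Sequence[PhyloTree], threshold: float = 0.5) -> PhyloTree:
    """Clades with frequency strictly above ``threshold`` (>= 0.5)."""
    if threshold < 0.5:
        raise TreeError("majority threshold below 0.5 can yield incompatible clades")
    counts, labels = _split_counts(trees)
    n = len(trees)
    keep = {s: c / n for s, c in counts.items() if c / n > threshold}
    return tree_from_clades(labels, keep)
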