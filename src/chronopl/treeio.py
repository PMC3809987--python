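"""Rooted trees with branch lengths: data model, Newick I/O, topology ops.

Everything downstream (simulation, likelihood, dating, experiments) works on
the :class:`Tree` and :class:`Chronogram` containers defined here.  The
coordinate convention for chronograms is that node ages increase toward the
root and extant leaves sit at age 0 (extant-only sampling).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

__all__ = [
    "Tree",
    "Node",
    "Chronogram",
    "CladeSpec",
    "NewickError",
    "parse_newick",
    "write_newick",
    "mrca",
    "prune_taxa",
    "crown_age",
    "is_ultrametric",
]


class NewickError(ValueError):
    """Malformed Newick input; carries the offending character position."""

    def __init__(self, message: str, pos: int | None = None):
        if pos is not None:
            message = f"{message} (at position {pos})"
        super().__init__(message)
        self.pos = pos


@dataclass
class Node:
    """A single tree node; ``length`` is the branch to its parent."""

    id: int
    parent: int | None = None
    children: list[int] = field(default_factory=list)
    label: str | None = None
    length: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children


class Tree:
    """Rooted tree; nodes addressed by integer id, root has ``parent=None``.

    Branch lengths are interpreted by context: expected substitutions/site
    for phylograms, millions of years (durations) when a chronogram is
    exported to Newick.
    """

    def __init__(self) -> None:
        self.nodes: dict[int, Node] = {}
        self.root: int | None = None
        self._next_id = 0

    # -- construction -------------------------------------------------

    def add_node(
        self,
        parent: int | None = None,
        label: str | None = None,
        length: float | None = None,
    ) -> int:
        nid = self._next_id
        self._next_id += 1
        self.nodes[nid] = Node(nid, parent, [], label, length)
        if parent is None:
            if self.root is not None:
                raise ValueError("tree already has a root")
            self.root = nid
        else:
            self.nodes[parent].children.append(nid)
        return nid

    # -- traversal ----------------------------------------------------

    def postorder(self) -> list[int]:
        order: list[int] = []
        stack = [self.root]
        while stack:
            nid = stack.pop()
            order.append(nid)
            stack.extend(self.nodes[nid].children)
        order.reverse()
        return order

    def preorder(self) -> list[int]:
        order: list[int] = []
        stack = [self.root]
        while stack:
            nid = stack.pop()
            order.append(nid)
            stack.extend(reversed(self.nodes[nid].children))
        return order

    def leaves(self) -> list[int]:
        return [nid for nid in self.postorder() if self.nodes[nid].is_leaf]

    @property
    def leaf_names(self) -> list[str]:
        return [self.nodes[n].label for n in self.leaves()]

    def leaf_by_name(self) -> dict[str, int]:
        return {self.nodes[n].label: n for n in self.leaves()}

    def branches(self) -> list[int]:
        """Non-root node ids; each identifies the branch to its parent."""
        return [nid for nid in self.postorder() if nid != self.root]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def is_binary(self) -> bool:
        return all(
            len(n.children) in (0, 2) for n in self.nodes.values()
        )

    def clade_leaves(self, nid: int) -> set[str]:
        """Leaf names under (and including) node ``nid``."""
        out: set[str] = set()
        stack = [nid]
        while stack:
            cur = self.nodes[stack.pop()]
            if cur.is_leaf:
                out.add(cur.label)
            else:
                stack.extend(cur.children)
        return out

    def copy(self) -> "Tree":
        t = Tree()
        t._next_id = self._next_id
        t.root = self.root
        t.nodes = {
            nid: Node(n.id, n.parent, list(n.children), n.label, n.length)
            for nid, n in self.nodes.items()
        }
        return t

    def validate(self) -> None:
        if self.root is None:
            raise ValueError("tree has no root")
        seen = self.postorder()
        if len(seen) != len(self.nodes):
            raise ValueError("tree is disconnected or cyclic")
        names = [self.nodes[n].label for n in self.leaves()]
        if any(not n for n in names):
            raise ValueError("leaf with empty label")
        if len(set(names)) != len(names):
            raise ValueError("duplicate leaf labels")
        for nid, n in self.nodes.items():
            if nid != self.root and n.length is not None and n.length < 0:
                raise ValueError(f"negative branch length on node {nid}")


# ----------------------------------------------------------------------
# Newick parsing / writing
# ----------------------------------------------------------------------

_UNQUOTED_STOP = set("(),:;[]' \t\n\r")


def _strip_comments(text: str) -> str:
    """Remove [...] comments (incl. NHX annotations), warning once."""
    if "[" not in text:
        return text
    warnings.warn("Newick comments/NHX annotations are stripped", stacklevel=3)
    out = []
    depth = 0
    for ch in text:
        if ch == "[":
            depth += 1
        elif ch == "]":
            if depth == 0:
                raise NewickError("unbalanced ']' in comment")
            depth -= 1
        elif depth == 0:
            out.append(ch)
    if depth:
        raise NewickError("unterminated '[' comment")
    return "".join(out)


def parse_newick(text: str, require_lengths: bool = True) -> Tree:
    """Parse one Newick tree.

    Accepts unquoted and single-quoted labels, decimal/scientific branch
    lengths and polytomies.  Square-bracket comments (NHX) are stripped with
    a warning.  By default every non-root branch must carry a length;
    pass ``require_lengths=False`` for bare topologies.

    Raises :class:`NewickError` (with character position) on malformed
    input: unbalanced parentheses, duplicate leaf labels, missing ';'.
    """
    if not text or not text.strip():
        raise NewickError("empty Newick string")
    s = _strip_comments(text).strip()
    if not s.endswith(";"):
        raise NewickError("missing terminating ';'", len(s))

    tree = Tree()
    pos = 0
    n = len(s)

    def skip_ws() -> None:
        nonlocal pos
        while pos < n and s[pos] in " \t\n\r":
            pos += 1

    def read_label() -> str | None:
        nonlocal pos
        skip_ws()
        if pos >= n:
            return None
        if s[pos] == "'":
            start = pos
            pos += 1
            buf = []
            while pos < n:
                if s[pos] == "'":
                    if pos + 1 < n and s[pos + 1] == "'":  # escaped quote
                        buf.append("'")
                        pos += 2
                        continue
                    pos += 1
                    return "".join(buf)
                buf.append(s[pos])
                pos += 1
            raise NewickError("unterminated quoted label", start)
        start = pos
        while pos < n and s[pos] not in _UNQUOTED_STOP:
            pos += 1
        return s[start:pos].replace("_", " ") if pos > start else None

    def read_length() -> float | None:
        nonlocal pos
        skip_ws()
        if pos < n and s[pos] == ":":
            pos += 1
            skip_ws()
            start = pos
            while pos < n and (s[pos] in "+-.eE0123456789"):
                pos += 1
            if pos == start:
                raise NewickError("expected branch length after ':'", start)
            try:
                return float(s[start:pos])
            except ValueError:
                raise NewickError(
                    f"bad branch length {s[start:pos]!r}", start
                ) from None
        return None

    def parse_clade(parent: int | None) -> int:
        nonlocal pos
        skip_ws()
        if pos < n and s[pos] == "(":
            open_pos = pos
            pos += 1
            nid = tree.add_node(parent)
            while True:
                parse_clade(nid)
                skip_ws()
                if pos >= n:
                    raise NewickError("unbalanced '('", open_pos)
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
                raise NewickError(f"unexpected character {s[pos]!r}", pos)
            tree.nodes[nid].label = read_label()
            tree.nodes[nid].length = read_length()
            return nid
        label_pos = pos
        label = read_label()
        if label is None:
            raise NewickError("expected leaf label", label_pos)
        nid = tree.add_node(parent, label=label)
        tree.nodes[nid].length = read_length()
        return nid

    root = parse_clade(None)
    skip_ws()
    if pos >= n or s[pos] != ";":
        raise NewickError("trailing content before ';'", pos)
    if tree.nodes[root].is_leaf:
        raise NewickError("tree has a single leaf")
    if require_lengths:
        for nid in tree.branches():
            if tree.nodes[nid].length is None:
                raise NewickError(f"missing branch length on node {nid}")
    try:
        tree.validate()
    except ValueError as exc:
        raise NewickError(str(exc)) from None
    return tree


def _fmt_len(x: float, digits: int | None) -> str:
    if digits is None:
        return format(x, ".17g")
    return format(x, f".{digits}g")


def write_newick(tree: Tree, digits: int | None = None) -> str:
    """Serialize to Newick.  ``digits=None`` writes full-precision lengths
    (parse/write round-trips exactly); pass e.g. ``digits=10`` for the
    10-significant-digit file convention."""

    def quote(label: str) -> str:
        if any(c in _UNQUOTED_STOP for c in label):
            return "'" + label.replace("'", "''") + "'"
        return label.replace(" ", "_")

    def rec(nid: int) -> str:
        node = tree.nodes[nid]
        if node.is_leaf:
            body = quote(node.label)
        else:
            body = "(" + ",".join(rec(c) for c in node.children) + ")"
            if node.label:
                body += quote(node.label)
        if nid != tree.root and node.length is not None:
            body += ":" + _fmt_len(node.length, digits)
        return body

    return rec(tree.root) + ";"


# ----------------------------------------------------------------------
# Topology operations
# ----------------------------------------------------------------------

def mrca(tree: Tree, taxa: set[str]) -> int:
    """Most recent common ancestor of the named leaves.

    Raises ``KeyError`` listing any taxa absent from the tree.
    """
    by_name = tree.leaf_by_name()
    missing = sorted(t for t in taxa if t not in by_name)
    if missing:
        raise KeyError(f"taxa not in tree: {missing}")
    if not taxa:
        raise ValueError("empty taxon set")
    # ancestor paths root->leaf; MRCA is the deepest shared prefix element
    paths = []
    for t in taxa:
        path = []
        nid = by_name[t]
        while nid is not None:
            path.append(nid)
            nid = tree.nodes[nid].parent
        paths.append(list(reversed(path)))
    anc = paths[0]
    for p in paths[1:]:
        k = 0
        while k < min(len(anc), len(p)) and anc[k] == p[k]:
            k += 1
        anc = anc[:k]
    return anc[-1]


def prune_taxa(tree: Tree, remove: set[str], min_leaves: int = 3) -> Tree:
    """Remove the named leaves; suppress resulting degree-2 nodes (their two
    branch lengths are summed) so pairwise path lengths between surviving
    leaves are conserved exactly.  A root left with a single child is
    collapsed onto that child.

    Raises ``ValueError`` if fewer than ``min_leaves`` leaves would remain
    (dating needs 3: a root plus an internal node).
    """
    names = set(tree.leaf_names)
    unknown = sorted(set(remove) - names)
    if unknown:
        raise KeyError(f"taxa not in tree: {unknown}")
    if len(names) - len(set(remove) & names) < max(min_leaves, 2):
        raise ValueError(f"pruning would leave fewer than {min_leaves} leaves")

    t = tree.copy()
    # drop leaves, then cascade childless internals
    doomed = [nid for nid in t.leaves() if t.nodes[nid].label in remove]
    while doomed:
        nid = doomed.pop()
        parent = t.nodes[nid].parent
        del t.nodes[nid]
        if parent is not None:
            t.nodes[parent].children.remove(nid)
            if not t.nodes[parent].children:
                doomed.append(parent)
    # suppress degree-2 internals (single-child nodes)
    for nid in list(t.nodes):
        node = t.nodes.get(nid)
        if node is None or node.is_leaf or len(node.children) != 1:
            continue
        child = t.nodes[node.children[0]]
        if node.parent is None:
            # collapse root onto its only child
            child.parent = None
            child.length = None
            t.root = child.id
            del t.nodes[nid]
        else:
            parent = t.nodes[node.parent]
            child.parent = parent.id
            if child.length is not None and node.length is not None:
                child.length = child.length + node.length
            parent.children[parent.children.index(nid)] = child.id
            del t.nodes[nid]
    # the collapse above may expose a new single-child root (chained case)
    while len(t.nodes[t.root].children) == 1:
        old = t.root
        t.root = t.nodes[old].children[0]
        t.nodes[t.root].parent = None
        t.nodes[t.root].length = None
        del t.nodes[old]
    t.validate()
    return t


def is_ultrametric(tree: Tree, tol: float = 1e-6) -> bool:
    """True iff all root-to-leaf path lengths agree within ``tol``."""
    if tol <= 0:
        raise ValueError("tol must be positive")
    depth = {tree.root: 0.0}
    for nid in tree.preorder():
        if nid == tree.root:
            continue
        node = tree.nodes[nid]
        depth[nid] = depth[node.parent] + (node.length or 0.0)
    leaf_depths = [depth[n] for n in tree.leaves()]
    return max(leaf_depths) - min(leaf_depths) < tol


# ----------------------------------------------------------------------
# Chronograms and clades
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class CladeSpec:
    """A named clade: the MRCA of whichever ``taxa`` survive in a tree."""

    name: str
    taxa: frozenset

    def __init__(self, name: str, taxa) -> None:
        taxa = frozenset(taxa)
        if len(taxa) < 2:
            raise ValueError("a clade spec needs at least 2 taxa")
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "taxa", taxa)


class Chronogram:
    """A tree whose nodes carry absolute ages in MYA (leaves at age 0).

    Branch duration ``t_k = age(parent) - age(child)`` must be positive up
    to a small tolerance; the tree is ultrametric by construction.
    """

    AGE_TOL = 1e-9

    def __init__(self, tree: Tree, ages: dict[int, float], validate: bool = True):
        self.tree = tree
        self.ages = dict(ages)
        if validate:
            self.validate()

    def validate(self) -> None:
        for nid in self.tree.postorder():
            node = self.tree.nodes[nid]
            age = self.ages[nid]
            if node.is_leaf and abs(age) > self.AGE_TOL:
                raise ValueError(f"extant leaf {node.label!r} has age {age}")
            if nid != self.tree.root:
                if self.ages[node.parent] <= age - self.AGE_TOL:
                    raise ValueError(
                        f"parent of node {nid} is not older ({self.ages[node.parent]} <= {age})"
                    )

    @property
    def root_age(self) -> float:
        return self.ages[self.tree.root]

    def duration(self, nid: int) -> float:
        """Duration of the branch subtending node ``nid`` (MY)."""
        return self.ages[self.tree.nodes[nid].parent] - self.ages[nid]

    def to_tree(self) -> Tree:
        """Export as a Tree with branch lengths equal to durations (MY)."""
        t = self.tree.copy()
        for nid in t.branches():
            t.nodes[nid].length = self.duration(nid)
        t.nodes[t.root].length = None
        return t

    def pruned(self, remove: set[str]) -> "Chronogram":
        """Prune leaves (a 2-leaf cherry is allowed), keeping the ages of
        surviving nodes."""
        sub = prune_taxa(self.to_tree(), remove, min_leaves=2)
        # recover ages from durations: leaves at 0, parents accumulate
        ages: dict[int, float] = {}
        for nid in sub.postorder():
            node = sub.nodes[nid]
            if node.is_leaf:
                ages[nid] = 0.0
            else:
                ages[nid] = max(
                    ages[c] + (sub.nodes[c].length or 0.0) for c in node.children
                )
        for nid in sub.branches():
            sub.nodes[nid].length = None
        return Chronogram(sub, ages, validate=False)

    def copy(self) -> "Chronogram":
        return Chronogram(self.tree.copy(), dict(self.ages), validate=False)


def crown_age(chron: Chronogram, clade: CladeSpec) -> float | None:
    """Age of the MRCA of the clade members present in the tree.

    Returns ``None`` (the "N/A" of report tables) when fewer than two
    members survive; non-monophyletic survivors yield the age of their MRCA,
    which may subtend non-members.
    """
    present = clade.taxa & set(chron.tree.leaf_names)
    if len(present) < 2:
        return None
    return chron.ages[mrca(chron.tree, present)]
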