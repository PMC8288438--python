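"""Rooted phylogenies: reading, validation, collapsing, and clade extraction.

The container here is deliberately minimal — a rooted tree of :class:`Node`
objects with optional branch lengths in millions of years (Myr) and unique tip
labels (plant family names in the intended use).  Newick parsing and writing
are delegated to :mod:`dendropy`; everything downstream (binarization, clade
extraction, lineage counting) operates on this container directly.
"""

from __future__ import annotations

import logging
import math
import os
import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

import dendropy

logger = logging.getLogger(__name__)

__all__ = [
    "Node",
    "Phylogeny",
    "CladeDefinition",
    "read_newick",
    "write_newick",
    "collapse_to_families",
    "binarize",
    "extract_clade",
    "lineages_at_time",
    "read_family_mapping",
    "read_clade_definitions",
]


class Node:
    """A single tree node. Tips carry a label; edges carry an optional length."""

    __slots__ = ("parent", "children", "length", "label")

    def __init__(self, label: str | None = None, length: float | None = None):
        self.parent: Node | None = None
        self.children: list[Node] = []
        self.length = length
        self.label = label

    @property
    def is_tip(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "tip" if self.is_tip else f"internal({len(self.children)})"
        return f"<Node {self.label!r} {kind} len={self.length}>"


class Phylogeny:
    """A rooted phylogeny with unique, non-empty tip labels.

    Invariants enforced at construction: a single root, parent/child link
    consistency, no duplicate or empty tip labels, and non-negative branch
    lengths where lengths are present.
    """

    def __init__(self, root: Node, validate: bool = True):
        self.root = root
        if validate:
            self._validate()

    # -- traversal ---------------------------------------------------------

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            # reversed keeps left-to-right (Newick encounter) order
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def tips(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_tip]

    @property
    def tip_labels(self) -> list[str]:
        return [t.label for t in self.tips()]

    @property
    def n_tips(self) -> int:
        return sum(1 for n in self.preorder() if n.is_tip)

    def is_binary(self) -> bool:
        return all(len(n.children) == 2 for n in self.preorder() if not n.is_tip)

    # -- validation --------------------------------------------------------

    def _validate(self) -> None:
        if self.root.parent is not None:
            raise ValueError("root must not have a parent")
        labels: list[str] = []
        seen: set[int] = set()
        for node in self.preorder():
            if id(node) in seen:
                raise ValueError("cycle detected in tree")
            seen.add(id(node))
            for child in node.children:
                if child.parent is not node:
                    raise ValueError("inconsistent parent link")
            if node.is_tip:
                if not node.label:
                    raise ValueError("empty tip label")
                labels.append(node.label)
            if node.length is not None and node.length < 0:
                raise ValueError(f"negative branch length {node.length}")
        dups = sorted(l for l, c in Counter(labels).items() if c > 1)
        if dups:
            raise ValueError(f"duplicate tip labels: {dups}")

    # -- utilities ---------------------------------------------------------

    def copy(self) -> "Phylogeny":
        mapping: dict[int, Node] = {}
        for node in self.postorder():
            new = Node(node.label, node.length)
            for child in node.children:
                new.add_child(mapping[id(child)])
            mapping[id(node)] = new
        return Phylogeny(mapping[id(self.root)], validate=False)

    def find_tip(self, label: str) -> Node:
        for tip in self.tips():
            if tip.label == label:
                return tip
        raise KeyError(f"tip {label!r} not found")

    def mrca(self, labels: Iterable[str]) -> Node:
        """Most recent common ancestor of the named tips."""
        labels = list(labels)
        want = set(labels)
        missing = want - set(self.tip_labels)
        if missing:
            raise KeyError(f"tips not in tree: {sorted(missing)}")
        # count of wanted tips below each node, in postorder
        below: dict[int, int] = {}
        target = len(want)
        for node in self.postorder():
            if node.is_tip:
                below[id(node)] = 1 if node.label in want else 0
            else:
                below[id(node)] = sum(below[id(c)] for c in node.children)
            if below[id(node)] == target:
                # first postorder node covering all targets is the MRCA
                candidate = node
                return candidate
        raise AssertionError("unreachable: root covers all tips")

    def depths(self) -> dict[int, float]:
        """Distance from the root to each node (missing lengths are an error)."""
        depth: dict[int, float] = {id(self.root): 0.0}
        for node in self.preorder():
            if node is self.root:
                continue
            if node.length is None:
                raise ValueError("tree has missing branch lengths; ages undefined")
            depth[id(node)] = depth[id(node.parent)] + node.length
        return depth

    def ages(self, rtol: float = 1e-6) -> dict[int, float]:
        """Node ages measured backward from the tips (tips at age 0).

        Requires the tree to be ultrametric within ``rtol`` of its depth.
        """
        depth = self.depths()
        tip_depths = [depth[id(t)] for t in self.tips()]
        T = max(tip_depths)
        tol = rtol * T if T > 0 else rtol
        dev = T - min(tip_depths)
        if dev > tol:
            raise ValueError(
                f"tree is not ultrametric: max tip-depth deviation {dev:.6g} "
                f"exceeds tolerance {tol:.6g}"
            )
        ages = {nid: T - d for nid, d in depth.items()}
        for tip in self.tips():
            ages[id(tip)] = 0.0
        return ages

    def to_newick(self) -> str:
        return write_newick(self)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Phylogeny {self.n_tips} tips>"


@dataclass(frozen=True)
class CladeDefinition:
    """A named clade: either an explicit member set or a pair of MRCA anchors."""

    name: str
    members: frozenset[str] | None = None
    mrca_anchors: tuple[str, str] | None = None

    def __post_init__(self):
        if not self.name:
            raise ValueError("clade name must be non-empty")
        if (self.members is None) == (self.mrca_anchors is None):
            raise ValueError("exactly one of members / mrca_anchors must be given")
        if self.members is not None and not self.members:
            raise ValueError(f"clade {self.name!r}: empty member set")


# ---------------------------------------------------------------------------
# Newick I/O (dendropy-backed)
# ---------------------------------------------------------------------------


def _looks_like_newick(text: str) -> bool:
    s = text.lstrip()
    return s.startswith("(") or (";" in s and "\n" not in s.split(";")[0] and "(" in s)


def read_newick(source: str | os.PathLike) -> Phylogeny:
    """Read a single rooted tree from a Newick string or file path.

    Quoted labels and square-bracket comments are accepted and stripped.
    Polytomies are preserved as read.
    """
    if isinstance(source, os.PathLike):
        with open(source) as fh:
            text = fh.read()
    elif isinstance(source, str) and not _looks_like_newick(source):
        if not os.path.exists(source):
            raise FileNotFoundError(source)
        with open(source) as fh:
            text = fh.read()
    else:
        text = str(source)

    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises a family of DataError subclasses
        message = str(exc)
        if "Duplicate taxon labels" in message:
            dups = message.rsplit(":", 1)[-1].strip()
            raise ValueError(f"duplicate tip labels: {dups}") from exc
        offset = ""
        col = getattr(exc, "col_num", None)
        line = getattr(exc, "line_num", None)
        if col is not None:
            offset = f" (line {line}, column {col})"
        raise ValueError(f"malformed Newick{offset}: {exc}") from exc

    def convert(dnode: dendropy.Node) -> Node:
        label = None
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.label is not None:
            label = dnode.label
        node = Node(label=label, length=dnode.edge.length)
        for dchild in dnode.child_nodes():
            node.add_child(convert(dchild))
        return node

    root = convert(dtree.seed_node)
    return Phylogeny(root)


def _format_length(x: float) -> str:
    if x == int(x) and abs(x) < 1e15:
        return str(int(x))
    return repr(float(x))


def _needs_quoting(label: str) -> bool:
    return any(c in label for c in " \t(),;:[]'")


def _newick_label(label: str | None) -> str:
    if label is None:
        return ""
    if _needs_quoting(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree: Phylogeny, path: str | os.PathLike | None = None) -> str:
    """Serialize to Newick; branch lengths round-trip at full precision."""
    parts: list[str] = []

    def render(node: Node) -> str:
        if node.is_tip:
            s = _newick_label(node.label)
        else:
            s = "(" + ",".join(render(c) for c in node.children) + ")"
            s += _newick_label(node.label)
        if node.length is not None:
            s += ":" + _format_length(node.length)
        return s

    text = render(tree.root) + ";"
    parts.append(text)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text


# ---------------------------------------------------------------------------
# Pruning machinery
# ---------------------------------------------------------------------------


def _add_lengths(a: float | None, b: float | None) -> float | None:
    if a is None and b is None:
        return None
    return (a or 0.0) + (b or 0.0)


def _pruned_to_tips(tree: Phylogeny, keep: set[int]) -> Node:
    """Subtree induced by the tip nodes whose ids are in ``keep``.

    Unbranched internal nodes are suppressed with lengths summed; the
    returned root is the MRCA of the kept tips (chains above it collapse
    into it).
    """
    cover: set[int] = set(keep)
    for node in tree.postorder():
        if not node.is_tip and any(id(c) in cover for c in node.children):
            cover.add(id(node))

    new_of: dict[int, Node] = {}
    for node in tree.postorder():
        if id(node) not in cover:
            continue
        if node.is_tip:
            new_of[id(node)] = Node(node.label, node.length)
            continue
        built = [new_of[id(c)] for c in node.children if id(c) in cover]
        if len(built) == 1:
            child = built[0]
            child.length = _add_lengths(child.length, node.length)
            new_of[id(node)] = child
        else:
            merged = Node(node.label, node.length)
            for b in built:
                merged.add_child(b)
            new_of[id(node)] = merged
    return new_of[id(tree.root)]


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def collapse_to_families(
    tree: Phylogeny, mapping: Mapping[str, str]
) -> Phylogeny:
    """Collapse a species-level tree to one exemplar tip per family.

    ``mapping`` sends species tip labels to family names.  Unmapped species
    are pruned (count logged).  The exemplar kept for each family is the
    first of its tips encountered in a postorder traversal; families whose
    tips are not monophyletic trigger a warning but are still collapsed to
    their exemplar.
    """
    tips = tree.tips()
    mapped = [t for t in tips if t.label in mapping]
    if not mapped:
        raise ValueError("no mappable tips: tree tips and mapping are disjoint")
    n_unmapped = len(tips) - len(mapped)
    if n_unmapped:
        logger.info("pruning %d species tips absent from the family mapping", n_unmapped)

    family_tips: dict[str, list[Node]] = {}
    exemplar: dict[str, Node] = {}
    for node in tree.postorder():
        if node.is_tip and node.label in mapping:
            fam = mapping[node.label]
            family_tips.setdefault(fam, []).append(node)
            exemplar.setdefault(fam, node)

    # monophyly check (on the mapped tips only)
    non_mono = []
    mapped_ids = {id(t) for t in mapped}
    for fam, fam_nodes in family_tips.items():
        if len(fam_nodes) == 1:
            continue
        anc = tree.mrca([t.label for t in fam_nodes])
        under = [
            n for n in _subtree_tips(anc) if id(n) in mapped_ids
        ]
        if len(under) != len(fam_nodes):
            non_mono.append(fam)
    if non_mono:
        warnings.warn(
            f"families not monophyletic in the species tree (exemplar rule "
            f"applied): {sorted(non_mono)}",
            stacklevel=2,
        )

    keep_ids = {id(t) for t in exemplar.values()}
    root = _pruned_to_tips(tree, keep_ids)
    label_to_family = {t.label: fam for fam, t in exemplar.items()}
    result = Phylogeny(root, validate=False)
    for tip in result.tips():
        tip.label = label_to_family[tip.label]
    result._validate()
    return result


def _subtree_tips(node: Node) -> list[Node]:
    out = []
    stack = [node]
    while stack:
        n = stack.pop()
        if n.is_tip:
            out.append(n)
        else:
            stack.extend(reversed(n.children))
    return out


def binarize(tree: Phylogeny, seed: int | None = None) -> Phylogeny:
    """Resolve every polytomy into nested dichotomies with zero-length edges.

    A polytomy of k children becomes k-1 nested dichotomies by left-to-right
    nesting in child order: ``(c1,c2,c3)`` -> ``((c1,c2):0,c3)``.  The tip
    set and all root-to-tip path lengths are unchanged, and the result is
    deterministic in the stored child order (the ``seed`` argument is part
    of the signature for forward compatibility; the resolution itself never
    consults it).
    """
    result = tree.copy()
    for node in list(result.postorder()):
        while len(node.children) > 2:
            first, second = node.children[0], node.children[1]
            inner = Node(length=0.0)
            inner.add_child(first)
            inner.add_child(second)
            inner.parent = node
            node.children = [inner] + node.children[2:]
    result._validate()
    return result


def extract_clade(tree: Phylogeny, clade: CladeDefinition) -> Phylogeny:
    """Extract a named clade as its own rooted tree.

    With explicit members, the induced subtree on those tips (rooted at
    their MRCA, stem removed).  With MRCA anchors, the complete subtree
    rooted at the anchors' MRCA.
    """
    tip_set = set(tree.tip_labels)
    if clade.members is not None:
        missing = sorted(set(clade.members) - tip_set)
        if missing:
            raise KeyError(
                f"clade {clade.name!r} not found: missing families {missing}"
            )
        keep = {id(t) for t in tree.tips() if t.label in clade.members}
        root = _pruned_to_tips(tree, keep)
        root.length = None
        root.parent = None
        return Phylogeny(root, validate=False)

    a, b = clade.mrca_anchors
    missing = sorted({a, b} - tip_set)
    if missing:
        raise KeyError(f"clade {clade.name!r} not found: missing families {missing}")
    anc = tree.mrca([a, b])
    sub = Phylogeny(anc, validate=False).copy()
    sub.root.length = None
    sub.root.parent = None
    return Phylogeny(sub.root)


def lineages_at_time(tree: Phylogeny, t: float, rtol: float = 1e-6) -> int:
    """Number of lineages (edges) crossing age ``t`` on an ultrametric tree.

    Ages run backward from the tips (tips at age 0).  An edge whose parent
    is older than ``t`` and whose child is at age <= ``t`` crosses; the root
    lineage counts for any ``t`` at or beyond the root age, so the count is
    1 there and equals the tip count at ``t = 0``.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    ages = tree.ages(rtol=rtol)
    root_age = ages[id(tree.root)]
    count = 1 if t >= root_age else 0
    for node in tree.preorder():
        if node is tree.root:
            continue
        if ages[id(node.parent)] > t >= ages[id(node)]:
            count += 1
    return count


# ---------------------------------------------------------------------------
# Tabular inputs
# ---------------------------------------------------------------------------


def read_family_mapping(path: str | os.PathLike) -> dict[str, str]:
    """Read a species->family mapping from a 2-column TSV (header required)."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise ValueError("empty mapping file")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise ValueError(f"mapping line {lineno}: expected 2 columns")
            species, family = parts[0].strip(), parts[1].strip()
            mapping[species] = family
    return mapping


def default_clade_names() -> list[str]:
    """The 18 major seed-plant clade names the family-level screen targets.

    Only the names ship with the package; family memberships depend on the
    tree in hand and are supplied as a clade-definition TSV.
    """
    path = os.path.join(os.path.dirname(__file__), "data", "default_clades.tsv")
    with open(path) as fh:
        fh.readline()
        return [line.strip() for line in fh if line.strip()]


def read_clade_definitions(path: str | os.PathLike) -> list[CladeDefinition]:
    """Read clade definitions from TSV.

    Two layouts are accepted, keyed on the header: long format
    ``clade_name<TAB>member_family`` (one row per member) or anchor format
    ``clade_name<TAB>anchor1<TAB>anchor2`` (one row per clade).
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        rows = [
            line.rstrip("\n").split("\t")
            for line in fh
            if line.strip()
        ]
    if len(header) >= 3:
        out = []
        for row in rows:
            if len(row) < 3:
                raise ValueError("anchor-format clade file needs 3 columns per row")
            out.append(
                CladeDefinition(
                    name=row[0].strip(),
                    mrca_anchors=(row[1].strip(), row[2].strip()),
                )
            )
        return out
    grouped: dict[str, set[str]] = {}
    order: list[str] = []
    for row in rows:
        if len(row) < 2:
            raise ValueError("member-format clade file needs 2 columns per row")
        name, member = row[0].strip(), row[1].strip()
        if name not in grouped:
            grouped[name] = set()
            order.append(name)
        grouped[name].add(member)
    return [
        CladeDefinition(name=name, members=frozenset(grouped[name])) for name in order
    ]
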