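"""Independent brute-force oracles used by the unit and acceptance tests.

These are written directly against the Node/Phylogeny containers with exact
rational arithmetic, entirely separate from the vectorized array kernels in
``psmphylo.dstat``.
"""

from fractions import Fraction
from itertools import product

from psmphylo.treekit import Node, Phylogeny


def brute_force_d(tree: Phylogeny, tip_values: dict[str, int]) -> Fraction:
    """d by direct recursion: internal value = mean of children, d = sum of
    |parent - child| over all edges.  Exact rational arithmetic."""

    value: dict[int, Fraction] = {}

    def fill(node: Node) -> Fraction:
        if node.is_tip:
            v = Fraction(tip_values[node.label])
        else:
            kids = [fill(c) for c in node.children]
            v = sum(kids, Fraction(0)) / len(kids)
        value[id(node)] = v
        return v

    fill(tree.root)
    total = Fraction(0)
    for node in tree.preorder():
        if node.parent is not None:
            total += abs(value[id(node)] - value[id(node.parent)])
    return total


def all_binary_shapes(n: int) -> list[str]:
    """Newick skeletons ('*' placeholders) of all rooted binary tree shapes
    with n tips (unordered children, so shapes are counted once)."""
    memo: dict[int, list[str]] = {1: ["*"]}

    def shapes(m: int) -> list[str]:
        if m in memo:
            return memo[m]
        out = []
        for i in range(1, m // 2 + 1):
            left, right = shapes(i), shapes(m - i)
            if i == m - i:
                for a_idx, a in enumerate(left):
                    for b in right[a_idx:]:
                        out.append(f"({a},{b})")
            else:
                for a in left:
                    for b in right:
                        out.append(f"({a},{b})")
        memo[m] = out
        return out

    return shapes(n)


def shape_to_tree(skeleton: str) -> Phylogeny:
    """Instantiate a shape with tips T1..Tn in reading order."""
    from psmphylo.treekit import read_newick

    parts = skeleton.split("*")
    labeled = "".join(
        part + (f"T{i+1}" if i < len(parts) - 1 else "")
        for i, part in enumerate(parts)
    )
    return read_newick(labeled + ";")


def all_labelings(n: int):
    """Every 0/1 assignment to tips T1..Tn."""
    for bits in product((0, 1), repeat=n):
        yield {f"T{i+1}": b for i, b in enumerate(bits)}
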