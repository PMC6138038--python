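"""Tree congruence: node heights, MRCA normalization, bipartitions.

Trees inferred separately from the maternal (F) and paternal (M)
mitogenome data sets live on different absolute time scales; dividing all
node heights by the height of the most recent common ancestor of a named
reference clade puts them on one relative scale so topologies and node
heights can be compared clade by clade. Newick/NEXUS parsing is delegated
to dendropy; heights and comparisons are computed here.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field

import dendropy
import pandas as pd


class TreeError(ValueError):
    pass


@dataclass
class Node:
    label: str | None = None  # leaf label (None for internal)
    length: float = 0.0  # branch length to parent
    children: list["Node"] = field(default_factory=list)
    height: float = 0.0  # derived
    height_interval: tuple[float, float] | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self):
        if self.is_leaf:
            yield self
        else:
            for c in self.children:
                yield from c.leaves()

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()


@dataclass
class HeightTree:
    """Rooted tree with derived node heights.

    Heights are computed as (max root-to-leaf path length) - (depth of the
    node); on an ultrametric tree every leaf has height 0. Non-ultrametric
    inputs are allowed unless ``require_ultrametric``.
    """

    root: Node
    normalized_to: frozenset[str] | None = None

    @property
    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.root.leaves()]

    def node_heights(self) -> dict[frozenset[str], float]:
        """Leaf-set -> height for every internal node (including root)."""
        out = {}
        for n in self.root.walk():
            if not n.is_leaf:
                out[frozenset(leaf.label for leaf in n.leaves())] = n.height
        return out

    def mrca(self, taxa) -> Node:
        taxa = set(taxa)
        missing = taxa - set(self.leaf_labels)
        if missing:
            raise TreeError(f"taxa not in tree: {sorted(missing)}")
        if len(taxa) < 2:
            raise TreeError("MRCA needs at least two taxa")
        node = self.root
        while True:
            carriers = [c for c in node.children
                        if taxa & {l.label for l in c.leaves()}]
            if len(carriers) == 1 and not carriers[0].is_leaf:
                cover = {l.label for l in carriers[0].leaves()}
                if taxa <= cover:
                    node = carriers[0]
                    continue
            return node

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial unrooted bipartitions, each encoded as the side not
        containing the reference (alphabetically first) leaf."""
        labels = set(self.leaf_labels)
        ref = min(labels)
        out = set()
        for n in self.root.walk():
            if n is self.root or n.is_leaf:
                continue
            side = frozenset(l.label for l in n.leaves())
            if ref in side:
                side = frozenset(labels - side)
            if 2 <= len(side) <= len(labels) - 2:
                out.add(side)
        return out


def _compute_heights(root: Node) -> None:
    depths = {}

    def down(n: Node, d: float):
        depths[id(n)] = d
        for c in n.children:
            down(c, d + c.length)

    down(root, 0.0)
    maxd = max(depths[id(l)] for l in root.leaves())
    for n in root.walk():
        n.height = maxd - depths[id(n)]


_HPD_RE = re.compile(
    r"height_95%?_?HPD=\{([0-9.eE+-]+),\s*([0-9.eE+-]+)\}")


def _from_dendropy(dtree: dendropy.Tree) -> Node:
    def conv(dn) -> Node:
        label = None
        if dn.is_leaf():
            label = (dn.taxon.label if dn.taxon is not None else dn.label)
            if label is None:
                raise TreeError("unlabeled leaf in tree")
            label = label.replace(" ", "_")
        node = Node(label=label,
                    length=dn.edge.length or 0.0,
                    children=[conv(c) for c in dn.child_nodes()])
        for comment in dn.comments or []:
            m = _HPD_RE.search(comment)
            if m:
                node.height_interval = (float(m.group(1)),
                                        float(m.group(2)))
        return node

    return conv(dtree.seed_node)


def parse_tree(text: str, fmt: str = "newick") -> HeightTree:
    """Parse a Newick or NEXUS tree into a :class:`HeightTree`."""
    if fmt not in ("newick", "nexus"):
        raise TreeError(f"unsupported tree format {fmt!r}")
    try:
        dtree = dendropy.Tree.get(data=text, schema=fmt,
                                  suppress_internal_node_taxa=True,
                                  extract_comment_metadata=False)
    except Exception as exc:  # noqa: BLE001
        raise TreeError(f"malformed {fmt} tree: {exc}") from exc
    root = _from_dendropy(dtree)
    labels = [n.label for n in root.leaves()]
    dupes = {l for l in labels if labels.count(l) > 1}
    if dupes:
        raise TreeError(f"duplicate leaf labels: {sorted(dupes)}")
    _compute_heights(root)
    return HeightTree(root=root)


def is_ultrametric(tree: HeightTree, rel_tol: float = 1e-6) -> bool:
    heights = [l.height for l in tree.root.leaves()]
    scale = max(tree.root.height, 1e-300)
    return max(heights) - min(heights) <= rel_tol * scale


def normalize_to_mrca(tree: HeightTree, taxa,
                      require_ultrametric: bool = False) -> HeightTree:
    """Rescale so the MRCA of ``taxa`` sits at height exactly 1.

    Scale-invariant and idempotent; topology unchanged.
    """
    if require_ultrametric and not is_ultrametric(tree):
        raise TreeError("tree is not ultrametric (strict mode)")
    node = tree.mrca(taxa)
    h = node.height
    if h <= 0:
        raise TreeError("MRCA height is zero; cannot normalize")

    def scale(n: Node) -> Node:
        return Node(label=n.label, length=n.length / h,
                    children=[scale(c) for c in n.children],
                    height=n.height / h,
                    height_interval=(
                        (n.height_interval[0] / h, n.height_interval[1] / h)
                        if n.height_interval else None))

    return HeightTree(root=scale(tree.root),
                      normalized_to=frozenset(taxa))


def rf_distance(t1: HeightTree, t2: HeightTree
                ) -> tuple[int, set[frozenset[str]], set[frozenset[str]],
                           set[frozenset[str]]]:
    """Robinson-Foulds distance plus shared/unique bipartition sets.

    Rooted inputs are compared as unrooted trees (standard RF); returns
    (distance, shared, unique_to_t1, unique_to_t2).
    """
    l1, l2 = set(t1.leaf_labels), set(t2.leaf_labels)
    if l1 != l2:
        raise TreeError(
            f"leaf sets differ: only in first {sorted(l1 - l2)}, only in "
            f"second {sorted(l2 - l1)}")
    b1, b2 = t1.bipartitions(), t2.bipartitions()
    return len(b1 ^ b2), b1 & b2, b1 - b2, b2 - b1


def matched_clade_heights(tm: HeightTree, tf: HeightTree) -> tuple[
        pd.DataFrame, list[frozenset[str]], list[frozenset[str]]]:
    """Compare node heights clade-by-clade between two normalized trees.

    Clades are matched by identical leaf sets; returns a table with
    height_M, height_F and their ratio, plus the clades unique to each
    tree (e.g. conspecific haplogroup cherries present in only one data
    set).
    """
    if tm.normalized_to is None or tf.normalized_to is None:
        raise TreeError(
            "both trees must be normalized (normalize_to_mrca) before "
            "height comparison")
    hm, hf = tm.node_heights(), tf.node_heights()
    shared = sorted(set(hm) & set(hf), key=lambda c: (len(c), sorted(c)))
    rows = []
    for clade in shared:
        m, f = hm[clade], hf[clade]
        rows.append({
            "clade": ",".join(sorted(clade)),
            "height_M": m, "height_F": f,
            "ratio": m / f if f > 0 else float("nan"),
        })
    table = pd.DataFrame(rows,
                         columns=["clade", "height_M", "height_F", "ratio"])
    only_m = sorted(set(hm) - set(hf), key=lambda c: (len(c), sorted(c)))
    only_f = sorted(set(hf) - set(hm), key=lambda c: (len(c), sorted(c)))
    return table, only_m, only_f
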