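"""Tree parsing, MRCA normalization and M-vs-F congruence."""

import numpy as np
import pytest

from mitopair.trees import (HeightTree, Node, TreeError, _compute_heights,
                            matched_clade_heights, normalize_to_mrca,
                            parse_tree, rf_distance)


def scale_tree(tree: HeightTree, factor: float) -> HeightTree:
    def conv(n: Node) -> Node:
        return Node(label=n.label, length=n.length * factor,
                    children=[conv(c) for c in n.children])
    root = conv(tree.root)
    _compute_heights(root)
    return HeightTree(root=root)


def random_newick(rng: np.random.Generator, labels) -> str:
    nodes = [f"{l}:{rng.uniform(0.1, 2.0):.4f}" for l in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b}):{rng.uniform(0.1, 2.0):.4f}")
    return nodes[0] + ";"


class TestParse:
    def test_heights_from_newick(self):
        t = parse_tree("((A:1,B:1):1,C:2);")
        assert sorted(t.leaf_labels) == ["A", "B", "C"]
        assert t.root.height == pytest.approx(2.0)
        assert t.node_heights()[frozenset({"A", "B"})] == pytest.approx(1.0)

    def test_nexus_translate_table(self):
        text = """#NEXUS
begin taxa; dimensions ntax=3; taxlabels A B C; end;
begin trees;
  translate 1 A, 2 B, 3 C;
  tree one = ((1:1,2:1):1,3:2);
end;
"""
        t = parse_tree(text, "nexus")
        assert sorted(t.leaf_labels) == ["A", "B", "C"]

    def test_duplicate_leaves_rejected(self):
        with pytest.raises(TreeError, match="duplicate"):
            parse_tree("((A:1,B:1):1,(A:1,C:1):1);")

    def test_malformed_rejected(self):
        with pytest.raises(TreeError):
            parse_tree("((A:1,B:1):1,C:2;")


class TestNormalize:
    def test_mrca_to_one(self):
        t = parse_tree("(((A:1,B:1):1,C:2):2,D:4);")
        n = normalize_to_mrca(t, ["A", "B"])
        h = n.node_heights()
        assert h[frozenset({"A", "B"})] == pytest.approx(1.0)
        assert h[frozenset({"A", "B", "C", "D"})] == pytest.approx(4.0)

    def test_all_leaves_normalizes_root(self):
        t = parse_tree("((A:1,B:1):1,C:2);")
        n = normalize_to_mrca(t, ["A", "B", "C"])
        assert n.root.height == pytest.approx(1.0)

    def test_scale_invariance_and_idempotence(self):
        rng = np.random.default_rng(13)
        labels = list("ABCDEF")
        for _ in range(100):
            t = parse_tree(random_newick(rng, labels))
            taxa = rng.choice(labels, size=3, replace=False).tolist()
            n1 = normalize_to_mrca(t, taxa)
            n7 = normalize_to_mrca(scale_tree(t, 7.0), taxa)
            h1, h7 = n1.node_heights(), n7.node_heights()
            assert set(h1) == set(h7)
            for clade in h1:
                assert h1[clade] == pytest.approx(h7[clade])
            n11 = normalize_to_mrca(n1, taxa)
            for clade in h1:
                assert n11.node_heights()[clade] == pytest.approx(h1[clade])

    def test_zero_height_mrca_rejected(self):
        t = parse_tree("((A:0,B:0):1,C:1);")
        with pytest.raises(TreeError):
            normalize_to_mrca(t, ["A", "B"])


class TestRF:
    def test_identical_trees_zero(self):
        t1 = parse_tree("((A:1,B:1):1,(C:1,D:1):1);")
        t2 = parse_tree("((B:2,A:2):1,(D:1,C:1):1);")
        rf, shared, u1, u2 = rf_distance(t1, t2)
        assert rf == 0
        assert not u1 and not u2

    def test_caterpillar_nni_neighbor_is_two(self):
        t1 = parse_tree("((((A:1,B:1):1,C:2):1,D:3):1,E:4);")
        t2 = parse_tree("((((A:1,C:1):1,B:2):1,D:3):1,E:4);")
        rf, _, u1, u2 = rf_distance(t1, t2)
        assert rf == 2
        # sides are canonicalized to exclude the reference leaf A:
        # {A,B}|{C,D,E} is unique to t1, {A,C}|{B,D,E} unique to t2
        assert u1 == {frozenset({"C", "D", "E"})}
        assert u2 == {frozenset({"B", "D", "E"})}

    def test_moved_taxon_names_the_clade(self):
        # one taxon moved across one edge: the unique bipartitions
        # pinpoint the displaced clade
        t1 = parse_tree("(((A:1,B:1):1,(C:1,X:1):1):1,(D:1,E:1):2);")
        t2 = parse_tree("(((A:1,(B:1,X:1):1):1,C:2):1,(D:1,E:1):2);")
        rf, _, u1, u2 = rf_distance(t1, t2)
        assert rf > 0
        moved = {s for s in (u1 | u2) if "X" in s}
        assert moved  # the displaced taxon appears in unique bipartitions

    def test_leaf_set_mismatch_lists_difference(self):
        t1 = parse_tree("((A:1,B:1):1,C:2);")
        t2 = parse_tree("((A:1,B:1):1,D:2);")
        with pytest.raises(TreeError, match="C.*D"):
            rf_distance(t1, t2)

    def test_agrees_with_dendropy(self):
        import dendropy
        from dendropy.calculate import treecompare
        rng = np.random.default_rng(14)
        labels = list("ABCDEFG")
        for _ in range(20):
            n1, n2 = (random_newick(rng, labels) for _ in range(2))
            rf, _, _, _ = rf_distance(parse_tree(n1), parse_tree(n2))
            tns = dendropy.TaxonNamespace()
            d1 = dendropy.Tree.get(data=n1, schema="newick",
                                   taxon_namespace=tns)
            d2 = dendropy.Tree.get(data=n2, schema="newick",
                                   taxon_namespace=tns)
            d1.encode_bipartitions()
            d2.encode_bipartitions()
            assert rf == treecompare.symmetric_difference(d1, d2)


class TestMatchedHeights:
    def test_identical_trees_all_ratio_one(self):
        t = parse_tree("(((A:1,B:1):1,C:2):1,D:3);")
        tm = normalize_to_mrca(t, ["A", "B", "C"])
        tf = normalize_to_mrca(t, ["A", "B", "C"])
        table, only_m, only_f = matched_clade_heights(tm, tf)
        assert np.allclose(table["ratio"], 1.0)
        assert not only_m and not only_f

    def test_prescaling_invisible_after_normalization(self):
        t = parse_tree("(((A:1,B:1):1,C:2):1,D:3);")
        tm = normalize_to_mrca(t, ["A", "B"])
        tf = normalize_to_mrca(scale_tree(t, 2.0), ["A", "B"])
        table, _, _ = matched_clade_heights(tm, tf)
        assert np.allclose(table["ratio"], 1.0)

    def test_extra_cherry_reported_unmatched(self):
        tm = parse_tree("(((Sw1:1,Sw2:1):1,Up:2):1,Out:3);")
        tf = parse_tree("((Sw1:1.5,Up:1.5):1,Out:2.5);")
        tm = normalize_to_mrca(tm, ["Sw1", "Up"])
        tf = normalize_to_mrca(tf, ["Sw1", "Up"])
        _, only_m, _ = matched_clade_heights(tm, tf)
        assert frozenset({"Sw1", "Sw2"}) in only_m

    def test_unnormalized_inputs_rejected(self):
        t = parse_tree("((A:1,B:1):1,C:2);")
        with pytest.raises(TreeError, match="normaliz"):
            matched_clade_heights(t, t)
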