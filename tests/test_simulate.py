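"""Simulator determinism, event bookkeeping and statistical calibration."""

import numpy as np
import pytest

from mitopair.composition import global_composition
from mitopair.curation import dual_space_consistency
from mitopair.divergence import count_substitutions, p_distance
from mitopair.genome import extract_feature_seq, translate_mito
from mitopair.simulate import (SimulationError, SimulationParams,
                               build_root, inject_duplication,
                               inject_frameshift, simulate)


class TestSimulate:
    def test_deterministic_in_seed(self):
        p = SimulationParams()
        a = simulate(p, seed=21)
        b = simulate(p, seed=21)
        assert set(a) == set(b)
        for k in a:
            assert a[k].seq == b[k].seq
        c = simulate(p, seed=22)
        assert any(a[k].seq != c[k].seq for k in a)

    def test_zero_branches_identical_to_root(self):
        p = SimulationParams(tree="(A:0.0,B:0.0);")
        gens = simulate(p, seed=2)
        assert gens[("A", "M")].seq == gens[("B", "M")].seq
        assert gens[("A", "M")].seq == build_root(p, "M", 2).seq

    def test_m_template_carries_morf_f_does_not(self, default_simulation):
        gm = default_simulation[("SwPL", "M")]
        gf = default_simulation[("SwPL", "F")]
        assert gm.get_features("m-ORF")
        assert not gf.get_features("m-ORF")

    def test_root_composition_matches_target(self):
        p = SimulationParams()
        a, c, g, t = p.base_freqs
        target_skew = (a - t) / (a + t)
        for seed in (31, 32, 33):
            comp = global_composition(build_root(p, "M", seed).seq)
            assert abs(comp.at_skew - target_skew) < 0.02
            assert abs(comp.gc_content - (g + c)) < 0.02

    def test_rate_m_below_one_rejected(self):
        with pytest.raises(SimulationError):
            SimulationParams(rate_m=0.5)

    def test_substitutions_scale_with_branch_length(self):
        p = SimulationParams(tree="(A:0.002,B:0.05);", rate_m=1.0)
        gens = simulate(p, seed=5)
        root = build_root(p, "F", 5)
        near = count_substitutions(root.seq, gens[("A", "F")].seq)
        far = count_substitutions(root.seq, gens[("B", "F")].seq)
        assert near < far


class TestInjectFrameshift:
    def test_deletion_bookkeeping(self, default_simulation):
        g = default_simulation[("SwPL", "M")]
        fs = inject_frameshift(g, "cox2", 30, "delete")
        assert len(fs.seq) == len(g.seq) - 1
        assert fs.get_feature("cox2").length == \
            g.get_feature("cox2").length - 1
        # downstream feature shifts by -1, upstream is untouched
        assert fs.get_feature("trnD").start == \
            g.get_feature("trnD").start - 1
        assert fs.get_feature("cox1").segments == \
            g.get_feature("cox1").segments

    def test_insertion_bookkeeping(self, default_simulation):
        g = default_simulation[("SwPL", "M")]
        fs = inject_frameshift(g, "cox2", 0, "insert", seed=3)
        assert len(fs.seq) == len(g.seq) + 1
        assert fs.get_feature("cox2").length == \
            g.get_feature("cox2").length + 1
        assert fs.get_feature("trnD").start == \
            g.get_feature("trnD").start + 1

    def test_untouched_features_extract_identically(self,
                                                    default_simulation):
        g = default_simulation[("SwPL", "M")]
        fs = inject_frameshift(g, "nad2", 100, "delete")
        for name in ("cox1", "nad5", "rrnS", "trnM"):
            assert extract_feature_seq(fs, fs.get_feature(name)) == \
                extract_feature_seq(g, g.get_feature(name))

    def test_offset_out_of_range(self, default_simulation):
        g = default_simulation[("SwPL", "M")]
        with pytest.raises(SimulationError):
            inject_frameshift(g, "cox2", 10 ** 6, "delete")

    def test_curation_roundtrip_flags_only_mutated_taxon(self):
        # full pipeline: simulate, frameshift one taxon's gene, screen
        p = SimulationParams(
            tree="((a:0.0005,b:0.0005):0.0005,(c:0.0005,d:0.0005):0.0005);")
        gens = simulate(p, seed=8)
        genomes = {leaf: gens[(leaf, "F")] for leaf in "abcd"}
        genomes["b"] = inject_frameshift(genomes["b"], "cox3", 200,
                                         "delete")
        nt, aa = {}, {}
        for leaf, g in genomes.items():
            cds = extract_feature_seq(g, g.get_feature("cox3"))
            nt[leaf] = cds
            aa[leaf] = translate_mito(cds).aa
        width = max(len(r) for r in aa.values())
        aa = {t: r.ljust(width, "-") for t, r in aa.items()}
        rep = dual_space_consistency(nt, aa)
        assert rep.suspicious == ["b"]


class TestInjectDuplication:
    def test_block_copy_gains_two_features(self, default_simulation):
        g = default_simulation[("SwPL", "M")]
        dup = inject_duplication(g, ["trnD", "m-ORF"])
        assert len(dup.features) == len(g.features) + 2
        assert len(dup.seq) == len(g.seq) + \
            g.get_feature("m-ORF").segments[0][1] - \
            g.get_feature("trnD").segments[0][0]

    def test_copies_extract_identically(self, default_simulation):
        g = default_simulation[("SwPL", "M")]
        dup = inject_duplication(g, ["trnD", "m-ORF"])
        for name in ("trnD", "m-ORF"):
            assert extract_feature_seq(dup, dup.get_feature(name + "-2")) \
                == extract_feature_seq(g, g.get_feature(name))

    def test_non_contiguous_rejected(self, default_simulation):
        g = default_simulation[("SwPL", "M")]
        with pytest.raises(SimulationError, match="contiguous"):
            inject_duplication(g, ["cox1", "m-ORF"])

    def test_duplicate_then_delete_restores_multiset(self,
                                                     default_simulation):
        from collections import Counter
        g = default_simulation[("SwPL", "M")]
        dup = inject_duplication(g, ["trnD", "m-ORF"])
        names = Counter(f.name for f in dup.features)
        names.subtract({"trnD-2": 1, "m-ORF-2": 1})
        assert +names == Counter(f.name for f in g.features)


class TestCalibration:
    def test_pair_distance_tracks_branch_sum(self):
        # two leaves at b each: p ~ 1 - exp(-2 b r) at small divergence
        b, r = 0.01, 1.0
        p = SimulationParams(tree=f"(A:{b},B:{b});", rate_m=1.0)
        obs = []
        for seed in range(40, 50):
            gens = simulate(p, seed=seed)
            obs.append(p_distance(gens[("A", "F")].seq,
                                  gens[("B", "F")].seq))
        expect_sub = 1.0 - np.exp(-2 * b * r)
        expect_p = expect_sub * (1 - expect_sub * 0.75)  # small back-hit
        assert abs(np.mean(obs) - expect_sub) < 0.003 or \
            abs(np.mean(obs) - expect_p) < 0.003
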