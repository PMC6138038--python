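"""Dual-space screening, profile building and frameshift-aware alignment."""

import math

import numpy as np
import pytest

from conftest import backtranslate, gene_family
from mitopair.curation import (CurationError, build_profile,
                               dual_space_consistency,
                               frameshift_aware_align, strip_gap_columns)

NEG_INF = float("-inf")


# ---------------------------------------------------------------------------
# exhaustive oracle: enumerate every move sequence of the alignment DP
# ---------------------------------------------------------------------------

def oracle_best_score(dna, profile, fs_penalty, code_table=5):
    """Brute-force maximum over all global move sequences.

    Mirrors the move definitions (match 3nt/1col with column log-odds of
    the translated codon, affine delete/insert, frameshift 2 or 4 nt per
    column at fs_penalty) by direct enumeration, no dynamic programming.
    """
    from mitopair.genome import translate_mito
    n, m = len(dna), len(profile)

    def rec(i, j, last):
        if i == n and j == m:
            return 0.0
        best = NEG_INF
        if i + 3 <= n and j + 1 <= m:  # match
            codon = dna[i:i + 3]
            aa = translate_mito(codon + "AAA", code_table).aa[0]
            s = rec(i + 3, j + 1, "M")
            if s > NEG_INF:
                best = max(best, profile.score_of(j, aa) + s)
        if j + 1 <= m:  # delete column
            cost = profile.gap_extend if last == "D" else profile.gap_open
            s = rec(i, j + 1, "D")
            if s > NEG_INF:
                best = max(best, cost + s)
        if i + 3 <= n:  # insert codon
            cost = profile.gap_extend if last == "I" else profile.gap_open
            s = rec(i + 3, j, "I")
            if s > NEG_INF:
                best = max(best, cost + s)
        if fs_penalty > NEG_INF and j + 1 <= m:
            for k in (2, 4):
                if i + k <= n:
                    s = rec(i + k, j + 1, "M")
                    if s > NEG_INF:
                        best = max(best, fs_penalty + s)
        return best

    return rec(0, 0, None)


def random_profile(rng, n_cols, alphabet="ACDE"):
    """A profile over a reduced amino-acid alphabet with random scores."""
    rows = ["".join(rng.choice(list(alphabet), size=n_cols))
            for _ in range(3)]
    return build_profile(rows)


class TestFrameshiftDP:
    def test_exact_backtranslation_recovers_consensus(self):
        prof = build_profile(["MKVLDE"] * 4)
        dna = backtranslate("MKVLDE")
        rec = frameshift_aware_align(dna, prof)
        assert rec.aa_row == "MKVLDE"
        assert rec.frameshift_events == []

    def test_single_insertion_detected_near_site(self):
        aa = "MKVLDEGH"
        prof = build_profile([aa] * 5)
        dna = backtranslate(aa)
        dna = dna[:9] + "A" + dna[9:]  # 1 nt inserted after codon 3 of 8
        rec = frameshift_aware_align(dna, prof)
        assert len(rec.frameshift_events) == 1
        pos, sign = rec.frameshift_events[0]
        assert sign == +1
        assert 6 <= pos <= 12
        # consensus recovered away from the event
        assert sum(a == b for a, b in zip(rec.aa_row, aa)) >= len(aa) - 2
        # score agrees with exhaustive enumeration
        assert rec.score == pytest.approx(
            oracle_best_score(dna, prof, -12.0))

    def test_matches_exhaustive_oracle_on_small_instances(self):
        rng = np.random.default_rng(8)
        for _ in range(40):
            m = int(rng.integers(1, 6))
            prof = random_profile(rng, m)
            n = int(rng.integers(3, 19))
            dna = "".join(rng.choice(list("ACGT"), size=n))
            fs = float(rng.choice([-3.0, -8.0, -15.0]))
            want = oracle_best_score(dna, prof, fs)
            if want == NEG_INF:
                with pytest.raises(CurationError):
                    frameshift_aware_align(dna, prof, fs_penalty=fs)
            else:
                got = frameshift_aware_align(dna, prof, fs_penalty=fs)
                assert got.score == pytest.approx(want)

    def test_infinite_penalty_reduces_to_codon_alignment(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            prof = random_profile(rng, int(rng.integers(2, 6)))
            dna = "".join(rng.choice(list("ACGT"), size=3 * int(
                rng.integers(1, 7))))
            rec = frameshift_aware_align(dna, prof, fs_penalty=NEG_INF)
            assert rec.frameshift_events == []
            assert rec.score == pytest.approx(
                oracle_best_score(dna, prof, NEG_INF))

    def test_score_monotone_in_penalties(self):
        prof = build_profile(["MKVLD"] * 3)
        dna = backtranslate("MKVD") + "A"
        scores = [frameshift_aware_align(dna, prof, fs_penalty=fs).score
                  for fs in (-3.0, -9.0, -20.0)]
        assert scores == sorted(scores, reverse=True)

    def test_irreconcilable_length_raises_with_no_frameshifts(self):
        prof = build_profile(["MKV"] * 2)
        with pytest.raises(CurationError):
            frameshift_aware_align("ATGAAAGTTA", prof, fs_penalty=NEG_INF)


class TestBuildProfile:
    def test_single_row(self):
        prof = build_profile(["MKV"])
        assert len(prof) == 3
        assert prof.consensus == "MKV"

    def test_conserved_column_argmax(self):
        prof = build_profile(["MAAAA", "MCCCC", "MDDDD", "MEEEE", "MFFFF"])
        assert prof.consensus[0] == "M"
        assert max(prof.scores[0], key=prof.scores[0].get) == "M"

    def test_gap_fraction_rule(self):
        # 10 columns, 6 rows; columns 3 and 7 gapped in 4/6 rows
        rows = []
        for i in range(6):
            row = list("MKVLDERGHT")
            if i < 4:
                row[3] = "-"
                row[7] = "-"
            rows.append("".join(row))
        prof = build_profile(rows)
        assert len(prof) == 8

    def test_scores_match_closed_form(self):
        prof = build_profile(["M", "M", "K"])
        bg = 1 / 20
        expect_m = math.log2((2 + 1 * bg) / (3 + 1) / bg)
        assert prof.scores[0]["M"] == pytest.approx(expect_m)

    def test_empty_alignment_rejected(self):
        with pytest.raises(CurationError):
            build_profile([])


class TestDualSpace:
    def test_clean_backtranslation_all_clean(self):
        aa = "MKVLDERG"
        nt_rows = {f"t{i}": backtranslate(aa) for i in range(4)}
        aa_rows = {f"t{i}": aa for i in range(4)}
        rep = dual_space_consistency(nt_rows, aa_rows)
        assert rep.suspicious == []
        assert all(v == 0 for v in rep.evidence.values())

    def test_frameshift_taxon_flagged(self):
        rng = np.random.default_rng(10)
        nt, aa = gene_family(rng, event="frameshift", offset=120)
        rep = dual_space_consistency(nt, aa)
        assert rep.suspicious == ["t0"]
        assert rep.evidence["t0"] >= 5

    def test_inframe_deletion_stays_clean(self):
        rng = np.random.default_rng(11)
        nt, aa = gene_family(rng, event="inframe")
        rep = dual_space_consistency(nt, aa)
        assert rep.suspicious == []

    def test_taxon_set_mismatch(self):
        with pytest.raises(CurationError):
            dual_space_consistency({"a": "ATG"}, {"b": "M"})

    def test_length_irreconcilable_flagged(self):
        aa = "MKVLDERG"
        nt_rows = {"a": backtranslate(aa), "b": backtranslate(aa)[:-6]}
        aa_rows = {"a": aa, "b": aa}
        rep = dual_space_consistency(nt_rows, aa_rows)
        assert "b" in rep.suspicious
        assert rep.length_ok["b"] is False


class TestStripGaps:
    def test_gap_free_unchanged(self):
        aln = {"a": "MKV", "b": "MKL"}
        stripped, eff, keep = strip_gap_columns(aln)
        assert stripped == aln
        assert eff == 3
        assert keep == [True] * 3

    def test_single_gap_column_removed(self):
        aln = {"a": "MKVLDERGHT", "b": "MKV-DERGHT"}
        _, eff, _ = strip_gap_columns(aln)
        assert eff == 9

    def test_all_gap_row_warns_and_zero(self):
        with pytest.warns(UserWarning):
            _, eff, _ = strip_gap_columns({"a": "---", "b": "MKV"})
        assert eff == 0

    def test_idempotent(self):
        rng = np.random.default_rng(12)
        rows = {f"t{i}": "".join(rng.choice(list("MKVLDE-"), size=30))
                for i in range(4)}
        once, eff1, _ = strip_gap_columns(rows)
        twice, eff2, _ = strip_gap_columns(once)
        assert once == twice
        assert eff1 == eff2
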