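"""Alignment curation for protein-coding mitochondrial genes.

Database mitogenomes sometimes carry single-nucleotide frameshifts
(sequencing or annotation errors) that garble the downstream translation
and poison amino-acid alignments. The curation procedure implemented here:

1. ``dual_space_consistency`` screens each taxon of a per-gene alignment by
   back-mapping its amino-acid row to codons of its raw CDS, re-translating,
   and counting columns where the implied residue disagrees with the
   majority residue of the remaining taxa. Frameshifted tails disagree in
   long runs; clean taxa and in-frame indels do not. Taxa failing the
   screen (or whose CDS length cannot be reconciled with the protein
   length) are flagged suspicious and dropped.
2. ``build_profile`` turns the curated amino-acid alignment into a
   position-specific scoring profile (log-odds against a background
   distribution, with per-column gap penalties).
3. ``frameshift_aware_align`` realigns a raw CDS nucleotide sequence
   against the profile with a dynamic program whose moves may consume 2 or
   4 nt against one profile column, recovering the protein alignment of a
   frameshifted record and reporting where the frame breaks.
4. ``strip_gap_columns`` removes every column containing a gap, reporting
   the effective alignment length actually informative for tree building.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .genome import translate_mito

AA20 = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AA20)}

#: fixed score for a stop codon consumed by a match move
STOP_SCORE = -8.0


class CurationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# dual-space consistency screening
# ---------------------------------------------------------------------------

@dataclass
class ConsistencyReport:
    """Per-taxon clean/suspicious verdicts with disagreement evidence."""

    verdicts: dict[str, str]  # taxon -> clean | suspicious
    evidence: dict[str, int]  # disagreeing-column count
    length_ok: dict[str, bool]
    threshold: int

    @property
    def suspicious(self) -> list[str]:
        return [t for t, v in self.verdicts.items() if v == "suspicious"]

    @property
    def clean(self) -> list[str]:
        return [t for t, v in self.verdicts.items() if v == "clean"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "taxon": list(self.verdicts),
            "verdict": list(self.verdicts.values()),
            "evidence": [self.evidence[t] for t in self.verdicts],
            "length_ok": [self.length_ok[t] for t in self.verdicts],
        })


def _implied_residues(nt: str, aa_row: str, code_table: int) -> list[str]:
    """Translate successive codons of ``nt`` under the gap pattern of
    ``aa_row``; returns one entry per alignment column ('-' at gaps)."""
    out = []
    pos = 0
    for col_aa in aa_row:
        if col_aa == "-":
            out.append("-")
            continue
        codon = nt[pos:pos + 3]
        if len(codon) < 3:
            out.append("?")  # ran out of nucleotides
        else:
            out.append(str(translate_mito(codon + "AA", code_table).aa[0])
                       if len(codon) == 3 else "?")
        pos += 3
    return out


def dual_space_consistency(gene_nt_rows: dict[str, str],
                           gene_aa_alignment: dict[str, str],
                           threshold: int = 5,
                           code_table: int = 5) -> ConsistencyReport:
    """Screen taxa whose nucleotide CDS is inconsistent with the protein
    alignment.

    For each taxon the amino-acid row is back-mapped to codons of the raw
    CDS and re-translated; evidence is the number of columns where the
    implied residue differs from the majority residue of the other taxa
    (columns without a majority among the others are not counted). A taxon
    is suspicious when evidence >= ``threshold`` or when its CDS length is
    not 3 * (ungapped protein length) + 0..3 (allowing a complete or
    incomplete terminal stop).
    """
    if set(gene_nt_rows) != set(gene_aa_alignment):
        missing = set(gene_nt_rows) ^ set(gene_aa_alignment)
        raise CurationError(
            f"taxon sets of nt rows and aa alignment differ: {sorted(missing)}")
    taxa = list(gene_aa_alignment)
    ncol = {len(r) for r in gene_aa_alignment.values()}
    if len(ncol) != 1:
        raise CurationError("aa alignment rows have unequal lengths")
    ncol = ncol.pop()

    implied = {t: _implied_residues(gene_nt_rows[t].upper().replace("U", "T"),
                                    gene_aa_alignment[t].upper(), code_table)
               for t in taxa}
    evidence: dict[str, int] = {t: 0 for t in taxa}
    for c in range(ncol):
        column = {t: implied[t][c] for t in taxa}
        for t in taxa:
            mine = column[t]
            if mine in ("-", "?"):
                continue
            others = [column[u] for u in taxa
                      if u != t and column[u] not in ("-", "?", "X")]
            if not others:
                continue
            res, cnt = Counter(others).most_common(1)[0]
            if cnt * 2 > len(others) and mine != res and mine != "X":
                evidence[t] += 1

    length_ok = {}
    for t in taxa:
        nt_len = len(gene_nt_rows[t])
        aa_len = len(gene_aa_alignment[t].replace("-", "").rstrip("*"))
        length_ok[t] = (nt_len - 3 * aa_len) in (0, 1, 2, 3)
    verdicts = {
        t: ("suspicious" if (evidence[t] >= threshold or not length_ok[t])
            else "clean")
        for t in taxa
    }
    return ConsistencyReport(verdicts=verdicts, evidence=evidence,
                             length_ok=length_ok, threshold=threshold)


# ---------------------------------------------------------------------------
# protein profile
# ---------------------------------------------------------------------------

@dataclass
class ProteinProfile:
    """Position-specific log-odds scoring columns over the 20 amino acids."""

    scores: list[dict[str, float]]  # one dict per kept column
    consensus: str
    gap_open: float = -10.0
    gap_extend: float = -1.0
    source: str = ""
    kept_columns: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.scores)

    def score_of(self, col: int, aa: str) -> float:
        """Column score of a residue; 'X' is neutral, '*' fixed penalty."""
        if aa == "X":
            return 0.0
        if aa == "*":
            return STOP_SCORE
        return self.scores[col][aa]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, col in enumerate(self.scores):
            row = {"column": i + 1, "consensus": self.consensus[i]}
            row.update({a: col[a] for a in AA20})
            rows.append(row)
        return pd.DataFrame(rows)


def build_profile(curated_aa_alignment: dict[str, str] | list[str],
                  background: dict[str, float] | None = None,
                  pseudocount: float = 1.0,
                  gap_drop: float = 0.5,
                  gap_open: float = -10.0, gap_extend: float = -1.0,
                  source: str = "") -> ProteinProfile:
    """Build a log-odds profile from a curated amino-acid alignment.

    Columns with a gap fraction >= ``gap_drop`` are dropped (insert
    regions). Per column: score(a) = log2((count_a + pc * bg_a) /
    (n_rows + pc) / bg_a); consensus is the most frequent residue, ties
    broken alphabetically.
    """
    rows = (list(curated_aa_alignment.values())
            if isinstance(curated_aa_alignment, dict)
            else list(curated_aa_alignment))
    if not rows:
        raise CurationError("empty alignment")
    if len({len(r) for r in rows}) != 1:
        raise CurationError("alignment rows have unequal lengths")
    if background is None:
        background = {a: 1.0 / 20 for a in AA20}
    n = len(rows)
    scores, consensus, kept = [], [], []
    for c in range(len(rows[0])):
        col = [r[c].upper() for r in rows]
        gaps = col.count("-")
        if gaps / n >= gap_drop:
            continue
        counts = Counter(a for a in col if a in _AA_INDEX)
        colscores = {}
        for a in AA20:
            bg = background[a]
            colscores[a] = math.log2(
                (counts.get(a, 0) + pseudocount * bg) / (n + pseudocount) / bg)
        best = min(AA20, key=lambda a: (-counts.get(a, 0), a))
        scores.append(colscores)
        consensus.append(best)
        kept.append(c)
    if not scores:
        raise CurationError("no columns survive the gap-fraction rule")
    return ProteinProfile(scores=scores, consensus="".join(consensus),
                          gap_open=gap_open, gap_extend=gap_extend,
                          source=source, kept_columns=kept)


# ---------------------------------------------------------------------------
# frameshift-aware DNA-to-profile alignment
# ---------------------------------------------------------------------------

@dataclass
class RecoveredAlignment:
    """Protein alignment of a raw CDS recovered against a profile."""

    aa_row: str  # over profile columns; lowercase = insertion, x = frameshift
    score: float
    frameshift_events: list[tuple[int, int]]  # (dna position, +1 | -1)


# DP states
_M, _D, _I = 0, 1, 2
NEG_INF = float("-inf")


def frameshift_aware_align(dna: str, profile: ProteinProfile,
                           fs_penalty: float = -12.0,
                           gap_open: float | None = None,
                           gap_extend: float | None = None,
                           code_table: int = 5) -> RecoveredAlignment:
    """Globally align a raw CDS against a protein profile, allowing
    frame-breaking moves.

    Moves (from dna position i, profile column j):

    - match: consume 3 nt and 1 column; score = column log-odds of the
      translated codon ('X' neutral, stop codons a fixed penalty)
    - delete: skip 1 column; affine gap (profile gap_open/gap_extend)
    - insert: consume 3 nt, no column; affine gap, residue reported
      lowercase
    - frameshift: consume 2 nt (net -1 in the dna) or 4 nt (net +1)
      against 1 column; score = ``fs_penalty``; reported as 'x'

    Co-optimal paths are broken by move priority
    match > delete > insert > frameshift(2) > frameshift(4).
    With ``fs_penalty = -inf`` this reduces to codon-level profile
    alignment. Returns the optimal global alignment (all nt and all
    columns consumed).
    """
    dna = dna.upper().replace("U", "T")
    n, m = len(dna), len(profile)
    if m == 0:
        raise CurationError("empty profile")
    if n < 3:
        raise CurationError("dna shorter than one codon")
    go = profile.gap_open if gap_open is None else gap_open
    ge = profile.gap_extend if gap_extend is None else gap_extend

    def codon_aa(i: int, k: int) -> str:
        """Residue emitted consuming k nt ending the move at i+k."""
        if k < 3:
            return "X"
        codon = dna[i:i + 3]
        return str(translate_mito(codon + ("A" * 3), code_table).aa[0])

    # score[j][state] per dna row i; states: M (last move consumed a
    # column+nt), D (last move deleted a column), I (last move inserted nt)
    # moves enumerated as (di, dj, kind)
    size = (n + 1) * (m + 1) * 3
    score = [NEG_INF] * size
    back: list[tuple[int, int, int, str] | None] = [None] * size

    def idx(i: int, j: int, s: int) -> int:
        return (i * (m + 1) + j) * 3 + s

    score[idx(0, 0, _M)] = 0.0
    # move kinds in priority order (first wins ties)
    for i in range(n + 1):
        for j in range(m + 1):
            for s in (_M, _D, _I):
                cur = score[idx(i, j, s)]
                if cur == NEG_INF:
                    continue
                # match
                if i + 3 <= n and j + 1 <= m:
                    aa = codon_aa(i, 3)
                    val = cur + profile.score_of(j, aa)
                    t = idx(i + 3, j + 1, _M)
                    if val > score[t]:
                        score[t] = val
                        back[t] = (i, j, s, "M")
                # delete column
                if j + 1 <= m:
                    val = cur + (ge if s == _D else go)
                    t = idx(i, j + 1, _D)
                    if val > score[t]:
                        score[t] = val
                        back[t] = (i, j, s, "D")
                # insert codon
                if i + 3 <= n:
                    val = cur + (ge if s == _I else go)
                    t = idx(i + 3, j, _I)
                    if val > score[t]:
                        score[t] = val
                        back[t] = (i, j, s, "I")
                # frameshifts
                if fs_penalty != NEG_INF:
                    if i + 2 <= n and j + 1 <= m:
                        val = cur + fs_penalty
                        t = idx(i + 2, j + 1, _M)
                        if val > score[t]:
                            score[t] = val
                            back[t] = (i, j, s, "F2")
                    if i + 4 <= n and j + 1 <= m:
                        val = cur + fs_penalty
                        t = idx(i + 4, j + 1, _M)
                        if val > score[t]:
                            score[t] = val
                            back[t] = (i, j, s, "F4")

    ends = [(score[idx(n, m, s)], s) for s in (_M, _D, _I)]
    best_score, best_state = max(ends, key=lambda x: x[0])
    if best_score == NEG_INF:
        raise CurationError(
            "no valid alignment path (dna length irreconcilable with the "
            "profile under the given penalties)")

    # traceback
    out: list[str] = []
    events: list[tuple[int, int]] = []
    i, j, s = n, m, best_state
    while (i, j) != (0, 0) or back[idx(i, j, s)] is not None:
        bt = back[idx(i, j, s)]
        if bt is None:
            break
        pi, pj, ps, kind = bt
        if kind == "M":
            out.append(codon_aa(pi, 3))
        elif kind == "D":
            out.append("-")
        elif kind == "I":
            out.append(codon_aa(pi, 3).lower())
        elif kind == "F2":
            out.append("x")
            events.append((pi, -1))
        else:  # F4
            out.append("x")
            events.append((pi, +1))
        i, j, s = pi, pj, ps
    out.reverse()
    events.reverse()
    return RecoveredAlignment(aa_row="".join(out), score=best_score,
                              frameshift_events=events)


# ---------------------------------------------------------------------------
# gap-column stripping
# ---------------------------------------------------------------------------

def strip_gap_columns(alignment: dict[str, str]
                      ) -> tuple[dict[str, str], int, list[bool]]:
    """Remove every column containing at least one gap.

    Returns (stripped alignment, effective length, per-column keep mask).
    """
    rows = list(alignment.values())
    if not rows:
        raise CurationError("empty alignment")
    if len({len(r) for r in rows}) != 1:
        raise CurationError("alignment rows have unequal lengths")
    ncol = len(rows[0])
    keep = [all(r[c] != "-" for r in rows) for c in range(ncol)]
    stripped = {t: "".join(r[c] for c in range(ncol) if keep[c])
                for t, r in alignment.items()}
    eff = sum(keep)
    if eff == 0 and ncol > 0:
        warnings.warn("all columns contain gaps; effective length 0",
                      stacklevel=2)
    return stripped, eff, keep
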