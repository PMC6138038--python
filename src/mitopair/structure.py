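"""Structural comparison of annotated mitogenomes.

Gene order extraction with a canonical rotation/orientation, detection of
gained/lost (duplicated) features between a query and a reference genome,
and classification of tRNA genes by anticodon and nearest-reference
identity — the toolkit behind spotting events like a tandem m-ORF + tRNA
duplication in a paternal mitogenome.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from Bio import Align
from Bio.Data import CodonTable

from .genome import (AnnotatedGenome, base_name, extract_feature_seq,
                     reverse_complement)


class StructureError(ValueError):
    pass


def gene_order(genome: AnnotatedGenome, anchor: str = "cox1"
               ) -> list[tuple[str, int]]:
    """Canonical signed gene order: (name, strand) tokens.

    The circular order is rotated to start at ``anchor``; if the anchor
    lies on the minus strand the whole order is reverse-complemented first,
    so the canonical form is invariant under genome rotation and under
    reverse-complementing the entire genome.
    """
    feats = sorted(genome.features, key=lambda f: f.start)
    tokens = [(f.name, f.strand) for f in feats]
    anchor_hits = [i for i, (n, _) in enumerate(tokens)
                   if base_name(n) == anchor]
    if not anchor_hits:
        raise StructureError(f"anchor gene {anchor!r} not annotated in "
                             f"{genome.id}")
    i = anchor_hits[0]
    if tokens[i][1] == -1:
        tokens = [(n, -s) for n, s in reversed(tokens)]
        anchor_hits = [k for k, (n, _) in enumerate(tokens)
                       if base_name(n) == anchor]
        i = anchor_hits[0]
    return tokens[i:] + tokens[:i]


@dataclass
class DuplicationReport:
    """Feature-repertoire differences between query and reference."""

    gained: list[tuple[str, int, int]]  # (name, query copies, ref copies)
    lost: list[tuple[str, int, int]]
    rearranged: bool

    @property
    def is_empty(self) -> bool:
        return not self.gained and not self.lost and not self.rearranged


def detect_extra_features(query: AnnotatedGenome,
                          reference: AnnotatedGenome,
                          anchor: str = "cox1") -> DuplicationReport:
    """Multiset comparison of (base) feature names plus gene-order check.

    Duplicated copies (``m-ORF-2``) are collapsed onto their base name for
    counting. ``rearranged`` is True when the canonical gene orders still
    differ after removing the gained/lost names.
    """
    qc = Counter(base_name(f.name) for f in query.features)
    rc = Counter(base_name(f.name) for f in reference.features)
    gained = sorted((n, qc[n], rc.get(n, 0)) for n in qc
                    if qc[n] > rc.get(n, 0))
    lost = sorted((n, qc.get(n, 0), rc[n]) for n in rc
                  if rc[n] > qc.get(n, 0))
    changed = {n for n, _, _ in gained} | {n for n, _, _ in lost}

    def reduced_order(g: AnnotatedGenome) -> list[tuple[str, int]]:
        try:
            order = gene_order(g, anchor=anchor)
        except StructureError:
            return [(base_name(f.name), f.strand) for f in g.features
                    if base_name(f.name) not in changed]
        return [(base_name(n), s) for n, s in order
                if base_name(n) not in changed]

    rearranged = reduced_order(query) != reduced_order(reference)
    return DuplicationReport(gained=gained, lost=lost, rearranged=rearranged)


_protein_aligner = Align.PairwiseAligner()
_protein_aligner.mode = "global"
_protein_aligner.match_score = 1
_protein_aligner.mismatch_score = -1
_protein_aligner.open_gap_score = -5
_protein_aligner.extend_gap_score = -1


def _percent_identity(a: str, b: str) -> float:
    aln = _protein_aligner.align(a, b)[0]
    s1, s2 = str(aln[0]), str(aln[1])
    matches = sum(1 for x, y in zip(s1, s2) if x == y and x != "-")
    return 100.0 * matches / max(len(a), len(b))


@dataclass
class TrnClassification:
    anticodon: str
    amino_acid: str  # one-letter assignment via the code table
    nearest: str
    ranking: list[tuple[str, float]]  # (reference name, percent identity)
    tie: bool
    anticodon_source: str  # annotation | heuristic


def anticodon_to_aa(anticodon: str, code_table: int = 5) -> str:
    """Amino acid read by a tRNA with this (DNA-sense) anticodon."""
    anticodon = anticodon.upper().replace("U", "T")
    codon = reverse_complement(anticodon)
    table = CodonTable.unambiguous_dna_by_id[code_table]
    if codon in table.stop_codons:
        return "*"
    return table.forward_table[codon]


def classify_trn(trn_seq: str, anticodon: str | None,
                 reference_trns: dict[str, str],
                 reference_anticodon_pos: dict[str, int] | None = None,
                 code_table: int = 5) -> TrnClassification:
    """Classify a tRNA gene by anticodon identity and nearest reference.

    When ``anticodon`` is None it is located heuristically: the query is
    aligned to the nearest reference and the 3-mer opposite the reference's
    known anticodon position (``reference_anticodon_pos``, 0-based) is
    read off. The heuristic is a clearly-labeled fallback for records
    lacking an anticodon annotation.
    """
    if not reference_trns:
        raise StructureError("empty tRNA reference set")
    ranking = sorted(((name, _percent_identity(trn_seq, seq))
                      for name, seq in reference_trns.items()),
                     key=lambda kv: (-kv[1], kv[0]))
    best_name, best_id = ranking[0]
    tie = len(ranking) > 1 and abs(ranking[1][1] - best_id) < 1e-9

    source = "annotation"
    if anticodon is None:
        if not reference_anticodon_pos or best_name not in \
                reference_anticodon_pos:
            raise StructureError(
                "anticodon not annotated and no reference anticodon "
                "position available for the heuristic fallback")
        aln = _protein_aligner.align(trn_seq,
                                     reference_trns[best_name])[0]
        s_q, s_r = str(aln[0]), str(aln[1])
        rpos = reference_anticodon_pos[best_name]
        qpos, rseen = None, 0
        qseen = 0
        for x, y in zip(s_q, s_r):
            if y != "-":
                if rseen == rpos:
                    qpos = qseen
                    break
                rseen += 1
            if x != "-":
                qseen += 1
        if qpos is None or qpos + 3 > len(trn_seq):
            raise StructureError("could not map anticodon position onto "
                                 "the query")
        anticodon = trn_seq[qpos:qpos + 3]
        source = "heuristic"
    anticodon = anticodon.upper().replace("U", "T")
    return TrnClassification(
        anticodon=anticodon,
        amino_acid=anticodon_to_aa(anticodon, code_table),
        nearest=best_name, ranking=ranking, tie=tie,
        anticodon_source=source)


def classify_genome_trn(genome: AnnotatedGenome, trn_name: str,
                        reference_names: list[str],
                        code_table: int = 5) -> TrnClassification:
    """Convenience wrapper: classify one annotated tRNA of a genome against
    other annotated tRNAs of the same (or another) genome."""
    feat = genome.get_feature(trn_name)
    refs = {}
    for name in reference_names:
        refs[name] = extract_feature_seq(genome, genome.get_feature(name))
    return classify_trn(extract_feature_seq(genome, feat), feat.anticodon,
                        refs, code_table=code_table)
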