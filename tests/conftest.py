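"""Shared fixtures: tiny GenBank records and seeded gene-family fixtures."""

from __future__ import annotations

import numpy as np
import pytest

from mitopair.genome import translate_mito

TINY_GENBANK = """\
LOCUS       TOY0001                   60 bp    DNA     circular INV 01-JAN-2018
DEFINITION  toy mitogenome fragment.
ACCESSION   TOY0001
VERSION     TOY0001.1
KEYWORDS    .
SOURCE      synthetic construct
  ORGANISM  synthetic construct
            .
FEATURES             Location/Qualifiers
     source          1..60
                     /organism="synthetic construct"
     CDS             1..30
                     /gene="COI"
     tRNA            complement(31..60)
                     /gene="trnM"
                     /note="anticodon:CAT"
ORIGIN
        1 atgaaacccg ggtttacgta cgtaacgtag ctagctagct agctaacgtt aacgttaacg
//
"""

#: codon chosen per amino acid for deterministic back-translation (table 5)
_BACKTABLE = {}


def backtranslate(aa: str) -> str:
    """Deterministic inverse of translate_mito (first codon per residue)."""
    if not _BACKTABLE:
        from Bio.Data import CodonTable
        fwd = CodonTable.unambiguous_dna_by_id[5].forward_table
        for codon in sorted(fwd):
            _BACKTABLE.setdefault(fwd[codon], codon)
    return "".join(_BACKTABLE[a] for a in aa)


def random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """Random stop-free CDS (coding strand, table 5)."""
    bases = "ACGT"
    out = []
    while len(out) < n_codons:
        codon = "".join(rng.choice(list(bases)) for _ in range(3))
        if codon not in ("TAA", "TAG"):
            out.append(codon)
    return "".join(out)


def mutate(rng: np.random.Generator, nt: str, p: float) -> str:
    """Per-site substitution with probability p (uniform replacement)."""
    bases = "ACGT"
    out = list(nt)
    for i in np.nonzero(rng.random(len(nt)) < p)[0]:
        out[i] = rng.choice([b for b in bases if b != out[i]])
    return "".join(out)


def gene_family(rng: np.random.Generator, n_taxa: int = 6,
                n_codons: int = 150, div: float = 0.001,
                event: str | None = None, event_taxon: str = "t0",
                offset: int | None = None):
    """A per-gene fixture: raw nt rows plus the protein alignment a correct
    aligner would produce.

    ``event``: None (clean), 'frameshift' (single-nt deletion at ``offset``
    nt from the 5' end of one taxon) or 'inframe' (3-nt codon deletion).
    The aa alignment places gaps where the true events are, mimicking a
    correct protein MSA; frameshifted tails keep their (garbled)
    translation in place.
    """
    anc = random_cds(rng, n_codons)
    nt_rows, aa_rows = {}, {}
    for k in range(n_taxa):
        taxon = f"t{k}"
        nt = mutate(rng, anc, div)
        aa = translate_mito(nt).aa
        nt_rows[taxon] = nt
        aa_rows[taxon] = aa
    ncol = n_codons
    if event == "frameshift":
        nt = nt_rows[event_taxon]
        if offset is None:
            offset = int(rng.integers(0, len(nt) - 60))
        nt = nt[:offset] + nt[offset + 1:]
        aa = translate_mito(nt).aa
        nt_rows[event_taxon] = nt
        aa_rows[event_taxon] = aa + "-" * (ncol - len(aa))
    elif event == "inframe":
        nt = nt_rows[event_taxon]
        if offset is None:
            offset = 3 * int(rng.integers(1, n_codons - 2))
        codon_idx = offset // 3
        nt = nt[:3 * codon_idx] + nt[3 * codon_idx + 3:]
        nt_rows[event_taxon] = nt
        aa = translate_mito(nt).aa
        aa_rows[event_taxon] = (aa[:codon_idx] + "-" + aa[codon_idx:])
    return nt_rows, aa_rows


@pytest.fixture
def tiny_genbank_text() -> str:
    return TINY_GENBANK


@pytest.fixture(scope="session")
def default_simulation():
    """One simulation under the default study conditions, shared."""
    from mitopair.simulate import SimulationParams, simulate
    return simulate(SimulationParams(), seed=11)
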