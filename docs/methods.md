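# Methods

## Scope and data model

`mitopair` analyses pairs of annotated mitochondrial genomes from the two
uniparental lineages (maternal F, paternal M) found in bivalves with
doubly uniparental inheritance. A genome is a circular (or linear)
sequence over `{A,C,G,T,N}` plus typed, stranded features. Coordinates
are 0-based half-open internally; GenBank interchange converts to and
from 1-based inclusive, joins become multi-segment features, and an
origin-spanning segment on a circular genome is stored with
`end > length` and resolved modulo the length. Gene labels are normalized
on read (`COI`/`CO1` → `cox1`, `16S` → `rrnL`, `MT-ORF` → `m-ORF`, ...)
because database annotations of these genomes use heterogeneous
vocabularies; the map is a declared approximation of the label
harmonization that published comparative work applies by hand. Ambiguity
codes other than `N` are rejected: finished mitogenome sequences are
unambiguous, and silently accepting IUPAC codes would corrupt the count
statistics. Translation follows the invertebrate mitochondrial code
(NCBI table 5; `AGA/AGG` → Ser, `ATA` → Met, `TGA` → Trp), configurable
by table number. A trailing 1–2 nt remainder is dropped with a flag
(incomplete stop codons are common in these annotations); internal stops
are kept as `*` and flagged rather than raised, since downstream
screening wants to see them.

## Composition profiling

AT skew is `(#A − #T)/(#A + #T)` and GC content `(#G + #C)/total` on the
deposited strand, with `N` excluded from every count; `#A + #T = 0`
yields an undefined (not erroneous) skew. Windowed profiles default to
300 bp windows in 25 bp steps — the presentation convention for circular
mitogenome maps — anchored at position 0 of the record as deposited
(anchor configurable; the choice only rotates the profile). On circular
genomes windows wrap and there are exactly `ceil(L/step)` of them, so
every position is covered by `window/step` windows; this coverage
identity is tested. Raw per-window values are stored; subtracting the
genome-wide mean is left to presentation.

## Divergence

Uncorrected p-distance uses pairwise deletion: columns with `-` or `N`
in either row are excluded entirely. With only two sequences pairwise
and complete deletion coincide except for `N` handling, which is why
pairwise deletion is the default and the only mode. Sliding windows move
over alignment columns and report per-window p with the number of
compared sites, so the site-weighted mean of a non-overlapping tiling
reconstructs the global p exactly (a partition identity used as a test
oracle).

Whole-genome pairs are aligned with a banded global aligner (Gotoh
three-state affine recursion; match +1, mismatch −1, gap open −8, gap
extend −1, band half-width 400 diagonals). Mitogenome pairs compared
here differ by a few percent with rare short indels, so the optimal path
stays near the main diagonal and the band turns a 17 kb × 17 kb problem
into seconds of work; the band width is generous by two orders of
magnitude relative to observed indel drift. Gap-to-gap transitions are
disallowed (a gap of length g costs `open + (g−1)·extend`), matching the
reference implementation the aligner is cross-checked against on random
edit instances. Before alignment both circular genomes are rotated to
start at `cox1`, removing the arbitrary deposit origin. Per-locus
distances extract both annotated sequences and align them the same way.

## Alignment curation

Public mitogenome CDSs occasionally contain single-nucleotide
frameshifts (sequencing or annotation errors). A frameshift garbles the
downstream translation, so a protein alignment built naively from
translations poisons tree inference. The curation stage:

1. **Dual-space consistency screen.** For each taxon of a per-gene data
   set (raw CDS nucleotides + protein alignment), the protein row is
   back-mapped to codons of the raw CDS, re-translated, and compared
   column by column against the majority residue of the *other* rows
   (columns where the others have no strict majority are skipped).
   A taxon is `suspicious` when ≥ `threshold` columns disagree, or when
   its CDS length is not `3·(ungapped protein length) + 0..3` (allowing
   complete or truncated terminal stops). The majority comparison is the
   operative definition of "nucleotide alignment inconsistent with the
   amino-acid alignment": a frameshifted tail is effectively random with
   respect to a conserved protein column and disagrees in a long run,
   while a clean taxon disagrees only where it carries a genuine
   non-synonymous substitution. The default threshold of 5 columns
   therefore separates the two regimes sharply at the divergence levels
   these screens operate on (conspecific to congeneric): injected
   frameshifts ≥ 60 nt from the 3′ end garble ≥ 20 codons (expected ~19
   disagreements), whereas single substitutions contribute ~1. The
   threshold deliberately tolerates a few ambiguous residues rather than
   discarding a taxon over one odd column. At deeper divergence the
   false-positive pressure rises and the threshold should be raised; the
   screen reports raw evidence counts so the cut is auditable.
2. **Profile construction.** The curated protein rows become a
   position-specific scoring profile: per column,
   `score(a) = log2((count_a + pc·bg_a) / (n_rows + pc) / bg_a)` with
   pseudocount 1.0 and a uniform 1/20 background by default; columns
   with ≥ 50 % gaps are treated as insert regions and dropped; consensus
   is the most frequent residue, ties broken alphabetically. This is a
   PSSM with per-column gap penalties (defaults: open −10, extend −1),
   a deliberately simpler object than a full Plan7 profile HMM — the
   transition structure a profile HMM would add is not needed to recover
   frame breaks, and the simpler object is exhaustively testable.
3. **Frameshift-aware recovery.** Raw DNA is aligned globally against
   the profile by dynamic programming over (dna position × column ×
   last-move state) with moves: match (3 nt against one column, scored
   by the column log-odds of the translated codon; `X` neutral, stop
   codons a fixed −8), column deletion and codon insertion (affine),
   and frameshift moves consuming 2 or 4 nt against one column for a
   flat `fs_penalty` (default −12, emitted as `x`). Ties are broken by
   move priority match > delete > insert > frameshift. With
   `fs_penalty = −inf` the program reduces exactly to codon-level
   profile alignment. The DP is verified against an independent
   exhaustive enumeration of all move sequences on small instances, and
   the reported frameshift events localize injected single-nucleotide
   indels.
4. **Gap stripping.** Columns containing any gap are removed before
   matrix export, and the resulting effective length is reported, since
   gapped columns carry no signal in the downstream partitioned
   analyses.

## Supermatrix

Per-gene alignments concatenate in input order into one matrix with a
1-based inclusive charset table; taxon labels can be routed through a
species-key map so M and F records of one species occupy consistent rows
across separate analyses. `strict` raises on a missing taxon; `pad`
fills with gaps. Exports: NEXUS (mixed nt+aa via a
`datatype=mixed(...)` header), relaxed PHYLIP (single datatype only —
the format cannot express mixed matrices, so the export refuses), and a
RAxML-style partition file. The NEXUS writer/reader pair round-trips
byte-identically.

## Tree congruence

Trees arrive as Newick or NEXUS (dendropy parses; FigTree-style
`height_95%_HPD` comments are retained as node intervals when present).
Node heights are `max root-to-leaf path − depth`, so leaves of an
ultrametric tree sit at 0; non-ultrametric inputs are allowed unless
strict mode is requested (relative leaf-depth spread > 1e-6 errors).
Normalization divides all heights by the height of the MRCA of a named
clade, which is scale-invariant and idempotent — the device that makes
node heights comparable between M and F trees inferred on different
time scales. Robinson–Foulds distance is computed on non-trivial
bipartitions of the unrooted topology (rooted inputs are compared
unrooted, the standard definition; MRCA operations still respect the
root), with shared and unique bipartition sets reported so a conflicting
clade can be named. Height comparison matches clades by identical leaf
sets and reports M/F height ratios plus clades present in only one tree
(e.g. conspecific haplogroup cherries that exist only in the M data
set).

## Simulator

The generator emulates the study conditions the analysis assumes: a
~16 kb circular genome with 13 protein-coding genes, 2 rRNAs, 22 tRNAs
and short spacers; the M template additionally carries an m-ORF next to
trnD. Defaults: base frequencies (A,C,G,T) = (0.235, 0.18, 0.15, 0.435),
i.e. AT skew ≈ −0.30 and GC ≈ 0.33, matching real unionid paternal
genomes; transition:transversion weight κ = 4, typical for mtDNA;
M-lineage rate multiplier r = 3, within the range reported for the
faster-evolving paternal lineage; a four-taxon guide tree with two
conspecific M haplogroups at ~0.1 total path length (whole-genome
p ≈ 0.095) and a congener pair at cox1-barcoding distance (~0.04).
Branch lengths are substitutions/site for the F lineage. Along each
branch every site substitutes with probability `1 − exp(−b·rate)`; the
replacement base is drawn with weight `π_target · κ^[transition]`
(HKY-like). Minus-strand CDSs are drawn in complement space so the
deposited strand keeps the target composition genome-wide; CDSs are
generated stop-free with an ATG start. Root genomes of the two lineages
are independent draws — the F/M split predates the family radiation, so
between-lineage homology at the nucleotide level is not simulated.

There is **no background indel process**: the only length changes are
explicit `inject_frameshift` (±1 nt inside a gene, all downstream
coordinates shifted) and `inject_duplication` (a contiguous feature
block copied, tandem by default, copies suffixed `-2`). This keeps
coordinate bookkeeping exact and lets round-trip tests assert feature
sequences byte-for-byte. Determinism: every branch and the root draw
from independent streams derived from `(seed, lineage, preorder branch
index)` via `numpy` seed sequences, so identical parameters and seed
give byte-identical output regardless of traversal internals.

What the simulator does *not* emulate — and what passing tests on it
therefore do not show about real data: among-site rate heterogeneity and
codon-position effects, strand-asymmetric mutational pressure changes
after rearrangements, background indels/microsatellites, selection on
amino-acid sites, and real tRNA secondary structure (template tRNAs are
random sequence with declared anticodons). The published-record
regression checks in `mitopair.validation` exist precisely to cover the
gap between simulated and real inputs; they require a one-time download
of the six GenBank records.

## Numerical and design choices

- Banded aligner scores are exact integers; the band raises an error if
  it cannot bridge the length difference.
- Windows with zero comparable sites report NaN rather than raising.
- Profile scores are finite by construction (pseudocount > 0).
- The acceptance pipeline (`scripts/acceptance.py`) uses the default
  four-taxon, ~16 kb conditions throughout, 30 screening trials and
  quick neighbor-joining trees from whole-genome p-distances for the
  M-vs-F congruence numbers; NJ is a distance summary used to exercise
  the congruence machinery end-to-end, not a stand-in for model-based
  inference, and its trees are not ultrametric — clade height ratios
  around 1.1 rather than exactly 1 reflect that, not a pipeline defect.
- Gene-order canonicalization anchors at `cox1` on the plus strand
  (reverse-complementing the token list when needed), making the order
  invariant under genome rotation and full reverse complement.
- tRNA anticodons are taken from annotation when present; the
  alignment-based localization against a reference with a known
  anticodon position is a clearly labeled heuristic fallback.

## Known limitations

- The dual-space screen's majority comparison needs ≥ 3 taxa per gene
  and low-to-moderate divergence; with 2 taxa there is no majority and
  only the length check operates.
- The frameshift DP is quadratic in (sequence × profile) and written
  for gene-scale inputs (≲ 2 kb), not whole genomes.
- `read_genbank` keeps only CDS/rRNA/tRNA features; D-loop and other
  miscellaneous annotations are dropped.
- Whole-genome alignment assumes collinear genomes (no rearrangement
  handling); rearranged pairs should be compared via `gene_order`
  first.
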