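"""Synthetic annotated F/M mitogenome pairs.

Generates the statistical structure the comparative analysis assumes: two
deeply divergent uniparental lineages evolving on a shared species tree,
the paternal (M) lineage faster by a rate multiplier r >= 1, negative AT
skew typical of the coding strand of these mitogenomes, an optional
m-ORF + tRNA block duplication, and optional single-nucleotide frameshifts
inside CDSs. Substitutions are per-site independent, HKY-like (target base
frequencies with a transition:transversion weight kappa); there is no
background indel process, so feature coordinates stay exact along the tree
and every injected event is fully bookkept.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .genome import AnnotatedGenome, Feature
from .trees import HeightTree, Node, parse_tree

_BASES = "ACGT"
_B2I = {b: i for i, b in enumerate(_BASES)}
# transition partner of each base (A<->G, C<->T)
_TRANSITION = np.array([2, 3, 0, 1])

_STOPS_TABLE5 = ("TAA", "TAG")


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class TemplateGene:
    name: str
    kind: str  # CDS | rRNA | tRNA | spacer
    length: int
    strand: int = 1
    anticodon: str | None = None


def default_template(include_morf: bool = True,
                     spacer: int = 20) -> list[TemplateGene]:
    """A realistic ~16 kb unionid-like mitogenome template.

    13 protein-coding genes, 2 rRNAs and 22 tRNAs with typical lengths;
    the paternal lineage additionally carries the supranumerary m-ORF next
    to trnD (the block whose duplication the analysis must detect). Short
    neutral spacers separate the genes so injected duplications never cut
    a neighbouring feature.
    """
    g = [
        TemplateGene("cox1", "CDS", 1539),
        TemplateGene("trnV", "tRNA", 66, 1, "TAC"),
        TemplateGene("cox2", "CDS", 690),
        TemplateGene("trnD", "tRNA", 66, 1, "GTC"),
    ]
    if include_morf:
        g.append(TemplateGene("m-ORF", "CDS", 300))
    g += [
        TemplateGene("atp8", "CDS", 165),
        TemplateGene("atp6", "CDS", 711),
        TemplateGene("trnM", "tRNA", 66, 1, "CAT"),
        TemplateGene("trnS1", "tRNA", 66, 1, "TCT"),
        TemplateGene("nad1", "CDS", 927, -1),
        TemplateGene("trnL1", "tRNA", 66, -1, "TAG"),
        TemplateGene("rrnL", "rRNA", 1250, -1),
        TemplateGene("trnY", "tRNA", 66, -1, "GTA"),
        TemplateGene("nad2", "CDS", 978),
        TemplateGene("trnC", "tRNA", 66, 1, "GCA"),
        TemplateGene("trnF", "tRNA", 66, -1, "GAA"),
        TemplateGene("nad5", "CDS", 1719, -1),
        TemplateGene("trnH", "tRNA", 66, -1, "GTG"),
        TemplateGene("nad4", "CDS", 1341, -1),
        TemplateGene("nad4l", "CDS", 291, -1),
        TemplateGene("trnT", "tRNA", 66, 1, "TGT"),
        TemplateGene("trnS2", "tRNA", 66, 1, "TGA"),
        TemplateGene("cob", "CDS", 1140),
        TemplateGene("nad6", "CDS", 492),
        TemplateGene("trnP", "tRNA", 66, -1, "TGG"),
        TemplateGene("nad3", "CDS", 354),
        TemplateGene("trnA", "tRNA", 66, 1, "TGC"),
        TemplateGene("trnR", "tRNA", 66, 1, "TCG"),
        TemplateGene("trnN", "tRNA", 66, 1, "GTT"),
        TemplateGene("trnE", "tRNA", 66, 1, "TTC"),
        TemplateGene("trnG", "tRNA", 66, 1, "TCC"),
        TemplateGene("trnQ", "tRNA", 66, -1, "TTG"),
        TemplateGene("trnI", "tRNA", 66, 1, "GAT"),
        TemplateGene("trnK", "tRNA", 66, 1, "TTT"),
        TemplateGene("trnW", "tRNA", 66, 1, "TCA"),
        TemplateGene("trnL2", "tRNA", 66, 1, "TAA"),
        TemplateGene("cox3", "CDS", 786),
        TemplateGene("rrnS", "rRNA", 850),
    ]
    out = []
    for tg in g:
        out.append(tg)
        out.append(TemplateGene("spacer", "spacer", spacer))
    return out


@dataclass
class SimulationParams:
    """Conditions of a two-lineage mitogenome simulation.

    Branch lengths of the guide tree are in substitutions/site for the
    maternal lineage; the paternal lineage evolves ``rate_m`` times
    faster. ``base_freqs`` (A, C, G, T) default to the negative-AT-skew
    composition typical of these genomes (AT skew about -0.30, GC about
    0.33).
    """

    tree: str = "((SwPL:0.017,SwCH:0.017):0.09,(Upic:0.007,Udel:0.007):0.1);"
    rate_f: float = 1.0
    rate_m: float = 3.0
    kappa: float = 4.0
    base_freqs: tuple[float, float, float, float] = (0.235, 0.18, 0.15, 0.435)
    template_f: list[TemplateGene] = field(
        default_factory=lambda: default_template(include_morf=False))
    template_m: list[TemplateGene] = field(
        default_factory=lambda: default_template(include_morf=True))

    def __post_init__(self):
        if self.rate_m < 1.0:
            raise SimulationError("rate_m must be >= 1 (M evolves faster)")
        if not np.isclose(sum(self.base_freqs), 1.0):
            raise SimulationError("base frequencies must sum to 1")
        if self.kappa <= 0 or not np.isfinite(self.kappa):
            raise SimulationError("kappa must be positive and finite")


def _rng(seed: int, *stream) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=tuple(stream)))


def _random_cds(length: int, freqs: np.ndarray,
                rng: np.random.Generator) -> np.ndarray:
    """Codon sequence without internal stops (coding strand), ATG start."""
    ncod = length // 3
    stops = np.array([[_B2I[c] for c in s] for s in _STOPS_TABLE5])
    codons = rng.choice(4, size=(ncod, 3), p=freqs)
    while True:  # redraw stop codons until none remain
        is_stop = np.zeros(ncod, dtype=bool)
        for s in stops:
            is_stop |= (codons == s).all(axis=1)
        k = int(is_stop.sum())
        if k == 0:
            break
        codons[is_stop] = rng.choice(4, size=(k, 3), p=freqs)
    out = np.empty(length, dtype=np.int64)
    out[:3 * ncod] = codons.reshape(-1)
    out[:3] = [_B2I["A"], _B2I["T"], _B2I["G"]]
    rem = length - 3 * ncod
    if rem:
        out[3 * ncod:] = rng.choice(4, size=rem, p=freqs)
    return out


def _build_root(template: list[TemplateGene], freqs: np.ndarray,
                rng: np.random.Generator, genome_id: str) -> AnnotatedGenome:
    chunks, feats = [], []
    pos = 0
    for tg in template:
        if tg.kind == "CDS":
            # minus-strand genes are drawn in complement space so the
            # deposited strand keeps the target composition everywhere
            cfreqs = freqs[::-1] if tg.strand == -1 else freqs
            arr = _random_cds(tg.length, cfreqs, rng)
            if tg.strand == -1:
                arr = (3 - arr)[::-1]  # revcomp in integer space
        else:
            arr = rng.choice(4, size=tg.length, p=freqs)
        chunks.append(arr)
        if tg.kind != "spacer":
            feats.append(Feature(kind=tg.kind, name=tg.name,
                                 strand=tg.strand,
                                 segments=((pos, pos + tg.length),),
                                 anticodon=tg.anticodon))
        pos += tg.length
    seq = "".join(_BASES[i] for i in np.concatenate(chunks))
    return AnnotatedGenome(id=genome_id, seq=seq, topology="circular",
                           features=feats)


def _evolve(arr: np.ndarray, branch_length: float, rate: float,
            kappa: float, freqs: np.ndarray,
            rng: np.random.Generator) -> np.ndarray:
    """One branch of per-site substitution; returns a new base-index array.

    Each site substitutes (changes to a different base) with probability
    1 - exp(-b * rate); the replacement is drawn with weight
    pi_target[b'] * (kappa for the transition partner, 1 otherwise).
    """
    p = -np.expm1(-branch_length * rate)
    if p <= 0:
        return arr.copy()
    hit = rng.random(arr.shape[0]) < p
    idx = np.nonzero(hit)[0]
    if idx.size == 0:
        return arr.copy()
    out = arr.copy()
    cur = arr[idx]
    # replacement weights: freqs, transition partner boosted, self zeroed
    w = np.tile(freqs, (idx.size, 1))
    w[np.arange(idx.size), _TRANSITION[cur]] *= kappa
    w[np.arange(idx.size), cur] = 0.0
    w /= w.sum(axis=1, keepdims=True)
    u = rng.random(idx.size)
    out[idx] = (np.cumsum(w, axis=1) < u[:, None]).sum(axis=1)
    return out


def build_root(params: SimulationParams, lineage: str,
               seed: int) -> AnnotatedGenome:
    """The ancestral genome of one lineage, before any branch evolution."""
    lin_idx = {"F": 0, "M": 1}[lineage]
    template = params.template_f if lineage == "F" else params.template_m
    freqs = np.asarray(params.base_freqs, dtype=float)
    return _build_root(template, freqs, _rng(seed, lin_idx, 0),
                       f"root_{lineage}")


def simulate(params: SimulationParams, seed: int
             ) -> dict[tuple[str, str], AnnotatedGenome]:
    """Simulate annotated genomes for every (leaf, lineage) combination.

    Deterministic in (params, seed): every branch consumes an independent
    stream derived by hashing (lineage, preorder branch index) into the
    seed. Annotations are carried through unchanged (substitutions only).
    """
    guide: HeightTree = parse_tree(params.tree, "newick")
    out: dict[tuple[str, str], AnnotatedGenome] = {}
    for lin_idx, (lineage, rate, template) in enumerate(
            (("F", params.rate_f, params.template_f),
             ("M", params.rate_m, params.template_m))):
        freqs = np.asarray(params.base_freqs, dtype=float)
        root_genome = _build_root(template, freqs,
                                  _rng(seed, lin_idx, 0), f"root_{lineage}")
        root_arr = np.array([_B2I[b] for b in root_genome.seq],
                            dtype=np.int64)
        counter = [0]

        def walk(node: Node, arr: np.ndarray):
            for child in node.children:
                counter[0] += 1
                child_arr = _evolve(arr, child.length, rate, params.kappa,
                                    freqs, _rng(seed, lin_idx, counter[0]))
                if child.is_leaf:
                    seq = "".join(_BASES[i] for i in child_arr)
                    out[(child.label, lineage)] = AnnotatedGenome(
                        id=f"{child.label}_{lineage}", seq=seq,
                        topology="circular",
                        features=list(root_genome.features))
                else:
                    walk(child, child_arr)

        walk(guide.root, root_arr)
    return out


# ---------------------------------------------------------------------------
# explicit structural events
# ---------------------------------------------------------------------------

def _single_segment(genome: AnnotatedGenome, gene: str) -> Feature:
    feat = genome.get_feature(gene)
    if len(feat.segments) != 1 or feat.segments[0][1] > len(genome.seq):
        raise SimulationError(
            f"injection supports only single-segment, non-wrapping "
            f"features; {gene!r} is not")
    return feat


def _shift_features(features: list[Feature], pos: int, delta: int,
                    point: bool) -> list[Feature]:
    """Shift coordinates after an edit at ``pos`` by ``delta``.

    ``point=True``: a 1-nt edit at index ``pos`` inside some feature
    (starts move only when strictly after pos, so the edited base stays in
    its feature); ``point=False``: a block insertion starting at ``pos``
    between features (a feature starting exactly at pos moves).
    Ends move when e > pos in both cases, so segments containing the edit
    stretch or shrink."""
    out = []
    for f in features:
        segs = []
        for s, e in f.segments:
            ns = s + delta if (s > pos if point else s >= pos) else s
            ne = e + delta if e > pos else e
            segs.append((ns, ne))
        out.append(replace(f, segments=tuple(segs)))
    return out


def inject_frameshift(genome: AnnotatedGenome, gene: str, offset: int,
                      kind: str = "delete", seed: int = 0
                      ) -> AnnotatedGenome:
    """Insert or delete one nucleotide inside a gene.

    ``offset`` is 0-based within the gene's transcript (5' end); the genome
    length changes by +-1 and all downstream feature coordinates shift
    accordingly.
    """
    if kind not in ("insert", "delete"):
        raise SimulationError(f"kind must be insert|delete, got {kind!r}")
    feat = _single_segment(genome, gene)
    s, e = feat.segments[0]
    if not 0 <= offset < feat.length:
        raise SimulationError(
            f"offset {offset} outside gene {gene!r} of length {feat.length}")
    pos = s + offset if feat.strand == 1 else e - 1 - offset
    if kind == "delete":
        seq = genome.seq[:pos] + genome.seq[pos + 1:]
        delta = -1
    else:
        base = _BASES[int(_rng(seed, 99).integers(4))]
        seq = genome.seq[:pos] + base + genome.seq[pos:]
        delta = +1
    feats = _shift_features(genome.features, pos, delta, point=True)
    return AnnotatedGenome(id=genome.id, seq=seq, topology=genome.topology,
                           features=feats)


def inject_duplication(genome: AnnotatedGenome, feature_names: list[str],
                       insert_after: str | None = None) -> AnnotatedGenome:
    """Copy a contiguous block of features and insert the copy.

    The named features must be adjacent in genome order (only unannotated
    spacer between them). The copy is inserted directly after the feature
    named ``insert_after`` (default: after the block itself, i.e. a tandem
    duplication); copies get a ``-2`` name suffix.
    """
    feats = [_single_segment(genome, n) for n in feature_names]
    order = sorted(genome.features, key=lambda f: f.start)
    idxs = sorted(order.index(f) for f in feats)
    if idxs != list(range(idxs[0], idxs[-1] + 1)):
        raise SimulationError(
            f"features {feature_names} are not contiguous in genome order")
    block_start = min(f.segments[0][0] for f in feats)
    block_end = max(f.segments[0][1] for f in feats)
    block_len = block_end - block_start
    if insert_after is None:
        pos = block_end
    else:
        pos = _single_segment(genome, insert_after).segments[0][1]
        if block_start < pos < block_end:
            raise SimulationError("insertion point lies inside the block")
    for f in genome.features:
        for s, e in f.segments:
            if s < pos < e:
                raise SimulationError(
                    f"insertion point {pos} falls inside feature {f.name!r}")
    seq = genome.seq[:pos] + genome.seq[block_start:block_end] + \
        genome.seq[pos:]
    shifted = _shift_features(genome.features, pos, block_len, point=False)
    new_feats = []
    for f in feats:
        s, e = f.segments[0]
        new_s = pos + (s - block_start)
        new_feats.append(replace(
            f, name=f.name + "-2",
            segments=((new_s, new_s + (e - s)),)))
    return AnnotatedGenome(id=genome.id, seq=seq, topology=genome.topology,
                           features=shifted + new_feats)
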