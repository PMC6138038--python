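"""Annotated mitogenome container and GenBank/FASTA I/O.

A mitogenome is held as an :class:`AnnotatedGenome`: a nucleotide sequence
(circular or linear) plus an ordered list of typed, stranded
:class:`Feature` records. Internally all coordinates are 0-based half-open;
GenBank interchange uses the conventional 1-based inclusive coordinates.
Feature extraction resolves origin-spanning segments on circular genomes,
and CDS translation follows the invertebrate mitochondrial code (NCBI
table 5) by default.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field, replace

import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

VALID_BASES = set("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Heterogeneous database gene labels mapped onto one canonical vocabulary.
#: Keys are lower-cased, stripped of separators.
NAME_NORMALIZATION = {
    # cytochrome oxidase subunits
    "cox1": "cox1", "coi": "cox1", "co1": "cox1", "coxi": "cox1",
    "cox2": "cox2", "coii": "cox2", "co2": "cox2", "coxii": "cox2",
    "cox3": "cox3", "coiii": "cox3", "co3": "cox3", "coxiii": "cox3",
    # cytochrome b
    "cob": "cob", "cytb": "cob", "cytochromeb": "cob",
    # NADH dehydrogenase
    "nad1": "nad1", "nd1": "nad1", "nad2": "nad2", "nd2": "nad2",
    "nad3": "nad3", "nd3": "nad3", "nad4": "nad4", "nd4": "nad4",
    "nad4l": "nad4l", "nd4l": "nad4l", "nad5": "nad5", "nd5": "nad5",
    "nad6": "nad6", "nd6": "nad6",
    # ATP synthase
    "atp6": "atp6", "atpase6": "atp6", "atp8": "atp8", "atpase8": "atp8",
    # rRNAs
    "rrnl": "rrnL", "16s": "rrnL", "16srrna": "rrnL", "lrrna": "rrnL",
    "rrns": "rrnS", "12s": "rrnS", "12srrna": "rrnS", "srrna": "rrnS",
    # male-lineage supranumerary ORF
    "morf": "m-ORF", "mtorf": "m-ORF", "orf": "m-ORF",
}


def normalize_name(raw: str) -> str:
    """Map a database gene label to the canonical vocabulary.

    tRNA labels keep their ``trnX`` form (``trnM``, ``trnASP`` ...);
    duplicated-copy suffixes (``m-ORF-2``) are preserved.
    """
    name = raw.strip()
    copy_suffix = ""
    m = re.match(r"^(.*?)[-_ ]?(\d+)$", name)
    key = re.sub(r"[-_ ]", "", name).lower()
    if key in NAME_NORMALIZATION:
        return NAME_NORMALIZATION[key]
    if m:
        base_key = re.sub(r"[-_ ]", "", m.group(1)).lower()
        if base_key in NAME_NORMALIZATION and base_key not in ("nad", "cox", "atp"):
            base = NAME_NORMALIZATION[base_key]
            copy_suffix = "-" + m.group(2)
            return base + copy_suffix
    tm = re.match(r"^trn[-_ ]?(\w+)$", name, flags=re.IGNORECASE)
    if tm:
        return "trn" + tm.group(1)
    tm = re.match(r"^tRNA[-_ ]?(\w+)$", name, flags=re.IGNORECASE)
    if tm:
        return "trn" + tm.group(1)
    return name


def base_name(name: str) -> str:
    """Collapse a duplicated-copy label (``m-ORF-2``) to its base (``m-ORF``)."""
    m = re.match(r"^(.*?)-(\d+)$", name)
    if m and m.group(1):
        return m.group(1)
    return name


class GenomeError(ValueError):
    """Malformed genome records or invalid coordinates."""


class TopologyError(GenomeError):
    """Operation requires a circular genome (coordinate wrap on linear)."""


@dataclass(frozen=True)
class Feature:
    """A typed, stranded genome feature.

    ``segments`` are [start, end) intervals, 0-based half-open, in
    transcription order before strand resolution: the extracted sequence is
    the concatenation of the segments, reverse-complemented as a whole when
    ``strand`` is -1. An origin-spanning feature on a circular genome may use
    a single segment with end > genome length (resolved modulo length).
    """

    kind: str  # CDS | rRNA | tRNA | other
    name: str
    strand: int  # +1 | -1
    segments: tuple[tuple[int, int], ...]
    anticodon: str | None = None

    def __post_init__(self):
        if self.kind not in ("CDS", "rRNA", "tRNA", "other"):
            raise GenomeError(f"unknown feature kind {self.kind!r}")
        if self.strand not in (1, -1):
            raise GenomeError(f"strand must be +1/-1, got {self.strand!r}")
        if not self.segments:
            raise GenomeError(f"feature {self.name!r} has no segments")
        for s, e in self.segments:
            if e <= s:
                raise GenomeError(
                    f"feature {self.name!r}: empty segment [{s},{e})")

    @property
    def start(self) -> int:
        return self.segments[0][0]

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.segments)


@dataclass
class AnnotatedGenome:
    """A circular or linear nucleotide sequence with ordered features."""

    id: str
    seq: str
    topology: str = "circular"  # circular | linear
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self):
        self.seq = self.seq.upper()
        if not self.seq:
            raise GenomeError("empty sequence")
        bad = set(self.seq) - VALID_BASES
        if bad:
            raise GenomeError(
                f"sequence contains non-ACGTN characters: {sorted(bad)}")
        if self.topology not in ("circular", "linear"):
            raise GenomeError(f"topology must be circular|linear, got "
                              f"{self.topology!r}")
        L = len(self.seq)
        for f in self.features:
            for s, e in f.segments:
                if s < 0 or s >= L:
                    raise GenomeError(
                        f"feature {f.name!r}: segment start {s} outside "
                        f"[0,{L})")
                if e > L and self.topology == "linear":
                    raise GenomeError(
                        f"feature {f.name!r}: end {e} exceeds linear genome "
                        f"length {L}")
                if e > 2 * L:
                    raise GenomeError(
                        f"feature {f.name!r}: segment [{s},{e}) wraps more "
                        f"than once around length {L}")
        self.features = sorted(self.features, key=lambda f: f.start)

    def __len__(self) -> int:
        return len(self.seq)

    def get_features(self, name: str) -> list[Feature]:
        """All features whose (exact) name matches."""
        return [f for f in self.features if f.name == name]

    def get_feature(self, name: str) -> Feature:
        """The unique/first feature with this name; KeyError if absent."""
        hits = self.get_features(name)
        if not hits:
            raise KeyError(f"genome {self.id}: no feature named {name!r}")
        return hits[0]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def extract_feature_seq(genome: AnnotatedGenome, feature: Feature) -> str:
    """Nucleotide sequence of a feature, strand- and topology-aware."""
    L = len(genome.seq)
    parts = []
    for s, e in feature.segments:
        if e <= L:
            parts.append(genome.seq[s:e])
        else:
            if genome.topology != "circular":
                raise TopologyError(
                    f"feature {feature.name!r} wraps the origin on a linear "
                    f"genome")
            parts.append(genome.seq[s:] + genome.seq[:e - L])
    cat = "".join(parts)
    return reverse_complement(cat) if feature.strand == -1 else cat


@dataclass(frozen=True)
class Translation:
    """Amino-acid translation plus quality flags."""

    aa: str
    has_remainder: bool = False  # trailing 1-2 nt dropped
    has_internal_stop: bool = False

    def __str__(self) -> str:
        return self.aa


def translate_mito(nt: str, code_table: int = 5) -> Translation:
    """Translate a CDS under a mitochondrial code (default NCBI table 5).

    The trailing 1-2 nt remainder of an incomplete final codon is dropped
    (flagged); internal stop codons are preserved as ``*`` and flagged;
    codons containing N translate to ``X``.
    """
    nt = nt.upper()
    if len(nt) < 3:
        raise GenomeError(f"CDS shorter than one codon: {len(nt)} nt")
    bad = set(nt) - VALID_BASES
    if bad:
        raise GenomeError(f"non-ACGTN characters in CDS: {sorted(bad)}")
    table = CodonTable.unambiguous_dna_by_id[code_table]
    stops = set(table.stop_codons)
    aa = []
    for i in range(0, len(nt) - 2, 3):
        codon = nt[i:i + 3]
        if "N" in codon:
            aa.append("X")
        elif codon in stops:
            aa.append("*")
        else:
            aa.append(table.forward_table[codon])
    aa = "".join(aa)
    return Translation(
        aa=aa,
        has_remainder=len(nt) % 3 != 0,
        has_internal_stop="*" in aa[:-1],
    )


def rotate(genome: AnnotatedGenome, new_origin: int) -> AnnotatedGenome:
    """Rotate a circular genome so that ``new_origin`` becomes position 0.

    Feature coordinates are shifted accordingly; a feature that comes to span
    the new origin is represented with end > L (single wrapped segment form).
    """
    if genome.topology != "circular":
        raise TopologyError("cannot rotate a linear genome")
    L = len(genome.seq)
    k = new_origin % L
    seq = genome.seq[k:] + genome.seq[:k]
    feats = []
    for f in genome.features:
        segs = []
        for s, e in f.segments:
            ns = (s - k) % L
            segs.append((ns, ns + (e - s)))
        feats.append(replace(f, segments=tuple(segs)))
    return AnnotatedGenome(id=genome.id, seq=seq, topology="circular",
                           features=feats)


# ---------------------------------------------------------------------------
# GenBank / FASTA I/O (delegated to Biopython, normalized on read)
# ---------------------------------------------------------------------------

_KIND_MAP = {"CDS": "CDS", "rRNA": "rRNA", "tRNA": "tRNA"}
_SKIP_TYPES = {"source", "gene", "misc_feature"}


def _feature_label(bio_feat: SeqFeature) -> str:
    q = bio_feat.qualifiers
    for key in ("gene", "product", "label", "note"):
        if key in q and q[key]:
            return str(q[key][0])
    return bio_feat.type


def _anticodon_of(bio_feat: SeqFeature) -> str | None:
    q = bio_feat.qualifiers
    for key in ("anticodon", "note"):
        for val in q.get(key, []):
            m = re.search(r"(?:anticodon[:= ]*|seq:)([ACGTUacgtu]{3})\b",
                          str(val))
            if m:
                return m.group(1).upper().replace("U", "T")
    return None


def read_genbank(text: str) -> AnnotatedGenome:
    """Parse a GenBank flat file into an :class:`AnnotatedGenome`.

    Gene labels are normalized to the canonical vocabulary (cox1, nad1,
    rrnL, m-ORF, trnM, ...); GenBank 1-based inclusive coordinates become
    0-based half-open; joins become multi-segment features.
    """
    try:
        record = SeqIO.read(io.StringIO(text), "genbank")
    except Exception as exc:  # noqa: BLE001 - re-raise with context
        raise GenomeError(f"malformed GenBank record: {exc}") from exc
    topology = record.annotations.get("topology", "linear")
    if topology not in ("circular", "linear"):
        topology = "linear"
    L = len(record.seq)
    features: list[Feature] = []
    for bf in record.features:
        if bf.type not in _KIND_MAP:
            continue
        kind = _KIND_MAP[bf.type]
        strand = -1 if bf.location.strand == -1 else 1
        parts = list(bf.location.parts)
        segs = [(int(p.start), int(p.end)) for p in parts]
        # GenBank complement(join(a,b)) lists parts in genome order; the
        # transcript is revcomp of the genome-order concatenation, which is
        # exactly our minus-strand convention.
        if strand == -1:
            segs = sorted(segs)
        # collapse an origin-spanning join (x..L, 0..y) to wrapped form
        if (topology == "circular" and len(segs) == 2
                and segs[0][1] == L and segs[1][0] == 0 and strand == 1):
            segs = [(segs[0][0], L + segs[1][1])]
        name = normalize_name(_feature_label(bf))
        features.append(Feature(
            kind=kind, name=name, strand=strand, segments=tuple(segs),
            anticodon=_anticodon_of(bf) if bf.type == "tRNA" else None,
        ))
    return AnnotatedGenome(id=record.id or record.name, seq=str(record.seq),
                           topology=topology, features=features)


def write_genbank(genome: AnnotatedGenome) -> str:
    """Serialize to a GenBank flat file (round-trips through read_genbank)."""
    record = SeqRecord(
        Seq(genome.seq), id=genome.id, name=genome.id.split(".")[0][:16],
        description=f"{genome.id} mitogenome",
        annotations={"molecule_type": "DNA", "topology": genome.topology},
    )
    L = len(genome.seq)
    for f in genome.features:
        locs = []
        for s, e in f.segments:
            if e <= L:
                locs.append(SimpleLocation(s, e, strand=f.strand))
            else:
                locs.append(SimpleLocation(s, L, strand=f.strand))
                locs.append(SimpleLocation(0, e - L, strand=f.strand))
        loc = locs[0] if len(locs) == 1 else CompoundLocation(locs)
        quals = {"gene": [f.name]}
        if f.anticodon:
            quals["note"] = [f"anticodon:{f.anticodon}"]
        record.features.append(SeqFeature(loc, type=f.kind, qualifiers=quals))
    out = io.StringIO()
    SeqIO.write(record, out, "genbank")
    return out.getvalue()


def read_fasta(text: str) -> dict[str, str]:
    """FASTA text -> ordered {id: sequence} mapping."""
    recs = list(SeqIO.parse(io.StringIO(text), "fasta"))
    if not recs:
        raise GenomeError("no FASTA records found")
    return {r.id: str(r.seq).upper() for r in recs}


def write_fasta(seqs: dict[str, str], width: int = 70) -> str:
    out = []
    for name, seq in seqs.items():
        out.append(f">{name}")
        for i in range(0, len(seq), width):
            out.append(seq[i:i + width])
    return "\n".join(out) + "\n"


def feature_table(genome: AnnotatedGenome) -> pd.DataFrame:
    """Tabular feature export (segments as 1-based inclusive strings)."""
    rows = []
    for f in genome.features:
        segs = ";".join(f"{s + 1}-{e}" for s, e in f.segments)
        rows.append({
            "id": genome.id, "kind": f.kind, "name": f.name,
            "strand": "+" if f.strand == 1 else "-",
            "segments": segs, "anticodon": f.anticodon or "",
        })
    return pd.DataFrame(
        rows, columns=["id", "kind", "name", "strand", "segments",
                       "anticodon"])
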