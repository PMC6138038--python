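"""Partitioned supermatrix construction and interchange formats.

Per-gene (or per-locus) alignments are concatenated into a single matrix
with a 1-based inclusive charset table, the form consumed by partitioned
phylogenetic inference. Exports: NEXUS (with charsets; mixed nt+aa
supported via a MrBayes-style datatype=mixed header), relaxed PHYLIP
(single datatype only) and a RAxML-style partition file.
"""

from __future__ import annotations

import re
from dataclasses import dataclass


class SupermatrixError(ValueError):
    pass


@dataclass(frozen=True)
class Partition:
    name: str
    datatype: str  # nt | aa
    start: int  # 1-based inclusive
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class Supermatrix:
    taxa: list[str]
    matrix: dict[str, str]
    partitions: list[Partition]

    @property
    def total_length(self) -> int:
        return self.partitions[-1].end if self.partitions else 0

    def __post_init__(self):
        total = self.total_length
        pos = 1
        for p in self.partitions:
            if p.start != pos:
                raise SupermatrixError(
                    f"partition {p.name} starts at {p.start}, expected {pos}")
            pos = p.end + 1
        for t in self.taxa:
            if len(self.matrix[t]) != total:
                raise SupermatrixError(
                    f"row {t} has length {len(self.matrix[t])}, expected "
                    f"{total}")

    def __eq__(self, other) -> bool:
        return (isinstance(other, Supermatrix)
                and self.taxa == other.taxa
                and self.matrix == other.matrix
                and self.partitions == other.partitions)


def concatenate(named_alignments: list[tuple[str, str, dict[str, str]]],
                taxon_policy: str = "strict",
                name_map: dict[str, str] | None = None) -> Supermatrix:
    """Concatenate (name, datatype, rows) alignments into a supermatrix.

    ``name_map`` translates record-level taxon labels (e.g. accession or
    lineage-tagged names) to shared species keys so that M and F records of
    one species can occupy the same row set across analyses. Under
    ``taxon_policy='strict'`` a taxon missing from any partition is an
    error; under ``'pad'`` the missing stretch is gap-filled.
    """
    if taxon_policy not in ("strict", "pad"):
        raise SupermatrixError(f"unknown taxon_policy {taxon_policy!r}")
    seen_names = set()
    mapped: list[tuple[str, str, dict[str, str]]] = []
    for name, datatype, rows in named_alignments:
        if name in seen_names:
            raise SupermatrixError(f"duplicate partition name {name!r}")
        seen_names.add(name)
        if datatype not in ("nt", "aa"):
            raise SupermatrixError(
                f"partition {name}: datatype must be nt|aa, got {datatype!r}")
        if name_map:
            newrows = {}
            for taxon, row in rows.items():
                key = name_map.get(taxon, taxon)
                if key in newrows:
                    raise SupermatrixError(
                        f"partition {name}: two rows map to taxon {key!r}")
                newrows[key] = row
            rows = newrows
        if len({len(r) for r in rows.values()}) > 1:
            raise SupermatrixError(f"partition {name} is not rectangular")
        mapped.append((name, datatype, rows))

    all_taxa = sorted({t for _, _, rows in mapped for t in rows})
    parts: list[Partition] = []
    chunks: dict[str, list[str]] = {t: [] for t in all_taxa}
    pos = 1
    for name, datatype, rows in mapped:
        length = len(next(iter(rows.values())))
        for t in all_taxa:
            if t in rows:
                chunks[t].append(rows[t])
            elif taxon_policy == "pad":
                chunks[t].append("-" * length)
            else:
                raise SupermatrixError(
                    f"taxon {t!r} missing from partition {name!r} "
                    f"(taxon_policy=strict)")
        parts.append(Partition(name=name, datatype=datatype, start=pos,
                               end=pos + length - 1))
        pos += length
    return Supermatrix(taxa=all_taxa,
                       matrix={t: "".join(chunks[t]) for t in all_taxa},
                       partitions=parts)


_NEX_DTYPE = {"nt": "dna", "aa": "protein"}
_NEX_DTYPE_BACK = {"dna": "nt", "protein": "aa"}


def export(sm: Supermatrix, fmt: str) -> str:
    """Serialize a supermatrix: 'nexus', 'phylip' or 'raxml'."""
    if fmt == "nexus":
        return _to_nexus(sm)
    if fmt == "phylip":
        return _to_phylip(sm)
    if fmt == "raxml":
        return _to_raxml(sm)
    raise SupermatrixError(f"unsupported format {fmt!r}")


def _to_nexus(sm: Supermatrix) -> str:
    dtypes = {p.datatype for p in sm.partitions}
    if len(dtypes) == 1:
        dt = _NEX_DTYPE[dtypes.pop()]
    else:
        spans = ",".join(f"{_NEX_DTYPE[p.datatype]}:{p.start}-{p.end}"
                         for p in sm.partitions)
        dt = f"mixed({spans})"
    width = max(len(t) for t in sm.taxa) + 2
    lines = [
        "#NEXUS", "",
        "begin data;",
        f"  dimensions ntax={len(sm.taxa)} nchar={sm.total_length};",
        f"  format datatype={dt} missing=? gap=-;",
        "  matrix",
    ]
    for t in sm.taxa:
        lines.append(f"  {t.ljust(width)}{sm.matrix[t]}")
    lines += ["  ;", "end;", "", "begin sets;"]
    for p in sm.partitions:
        lines.append(f"  charset {p.name} = {p.start}-{p.end};")
    lines += ["end;", ""]
    return "\n".join(lines)


def _to_phylip(sm: Supermatrix) -> str:
    if len({p.datatype for p in sm.partitions}) > 1:
        raise SupermatrixError(
            "relaxed PHYLIP cannot express a mixed nt+aa matrix; export the "
            "datatypes separately or use NEXUS")
    lines = [f"{len(sm.taxa)} {sm.total_length}"]
    for t in sm.taxa:
        lines.append(f"{t}  {sm.matrix[t]}")
    return "\n".join(lines) + "\n"


def _to_raxml(sm: Supermatrix) -> str:
    lines = []
    for p in sm.partitions:
        model = "DNA" if p.datatype == "nt" else "MTREV"
        lines.append(f"{model}, {p.name} = {p.start}-{p.end}")
    return "\n".join(lines) + "\n"


def read_nexus(text: str) -> Supermatrix:
    """Parse a NEXUS data+sets file as written by :func:`export`."""
    mdt = re.search(r"format\s+datatype=(\S+)", text)
    if not mdt:
        raise SupermatrixError("no NEXUS format/datatype line")
    dtspec = mdt.group(1)
    mixed = {}
    if dtspec.startswith("mixed("):
        for span in dtspec[6:].rstrip(")").split(","):
            kind, rng = span.split(":")
            s, e = rng.split("-")
            mixed[(int(s), int(e))] = _NEX_DTYPE_BACK[kind]
        default_dt = None
    else:
        default_dt = _NEX_DTYPE_BACK[dtspec]
    mmat = re.search(r"matrix\s*\n(.*?)\n\s*;", text, flags=re.S)
    if not mmat:
        raise SupermatrixError("no matrix block found")
    matrix: dict[str, str] = {}
    taxa: list[str] = []
    for line in mmat.group(1).splitlines():
        line = line.strip()
        if not line:
            continue
        taxon, seq = line.split(None, 1)
        matrix[taxon] = seq.strip()
        taxa.append(taxon)
    partitions = []
    for m in re.finditer(r"charset\s+(\S+)\s*=\s*(\d+)-(\d+)\s*;", text):
        name, s, e = m.group(1), int(m.group(2)), int(m.group(3))
        dt = default_dt
        if dt is None:
            dt = mixed.get((s, e))
            if dt is None:  # charset inside one mixed span
                dt = next((v for (a, b), v in mixed.items()
                           if a <= s and e <= b), "nt")
        partitions.append(Partition(name=name, datatype=dt, start=s, end=e))
    return Supermatrix(taxa=taxa, matrix=matrix, partitions=partitions)
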