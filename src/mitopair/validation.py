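"""Regression checks against deposited mitogenome records.

These checks reproduce published comparative statistics from six GenBank
records (two Unio pictorum and two Sinanodonta woodiana paternal
mitogenomes, the Chinese S. woodiana paternal record, and the Unio
delphinus paternal record). They need the records on disk — fetch once
with ``scripts/fetch_accessions.py`` — and then run offline in seconds.

Expected values (printed precision of the original report):

- substitutions MH349357 vs MH349358: 6 over 16,632 bp
- substitutions MH349356 vs MH349359: 22 over 17,616 bp
- whole-genome p-distance KM434235 vs MH349359: 0.097
- cox1 p-distance MH349358 vs KT326918: 0.04
- MH349359 composition: AT skew -0.3166, GC 0.3284
- MH349358 composition: AT skew -0.2828, GC 0.3396
- MH349359 vs MH349358: two m-ORF copies and one extra tRNA; the novel
  tRNA uses a TAT (Met-type) anticodon but is nearest to trnD (trnASP)
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .composition import global_composition
from .divergence import count_substitutions, genome_p_distance, \
    locus_p_distance
from .genome import AnnotatedGenome, base_name, extract_feature_seq, \
    read_genbank
from .structure import classify_trn, detect_extra_features

ACCESSIONS = ("MH349356", "MH349357", "MH349358", "MH349359",
              "KM434235", "KT326918")


def load_accessions(directory: str | Path) -> dict[str, AnnotatedGenome]:
    directory = Path(directory)
    genomes = {}
    for acc in ACCESSIONS:
        hits = sorted(directory.glob(f"{acc}*.gb")) + \
            sorted(directory.glob(f"{acc}*.gbk"))
        if not hits:
            raise FileNotFoundError(
                f"record {acc} not found in {directory}; run "
                f"scripts/fetch_accessions.py first (needs network once)")
        genomes[acc] = read_genbank(hits[0].read_text())
    return genomes


def novel_trn_check(genome: AnnotatedGenome) -> dict:
    """Classify the supranumerary Met-type tRNA of a paternal genome.

    Looks for a duplicated trnM-like feature (or any tRNA with a TAT
    anticodon) and ranks it against the canonical trnM and trnD of the
    same genome.
    """
    trns = [f for f in genome.features if f.kind == "tRNA"]
    tat = [f for f in trns if (f.anticodon or "").upper() == "TAT"]
    met = [f for f in trns if base_name(f.name).lower().startswith("trnm")]
    if tat:
        novel = tat[0]
    elif len(met) > 1:
        novel = met[-1]
    else:
        raise ValueError(f"no candidate novel tRNA found in {genome.id}")
    refs = {}
    for f in trns:
        nm = base_name(f.name).lower()
        if f is novel:
            continue
        if nm.startswith("trnm") and "trnM" not in refs:
            refs["trnM"] = extract_feature_seq(genome, f)
        if nm in ("trnd", "trnasp") and "trnD" not in refs:
            refs["trnD"] = extract_feature_seq(genome, f)
    if not refs:
        raise ValueError("reference tRNAs (trnM, trnD) not annotated")
    cls = classify_trn(extract_feature_seq(genome, novel), novel.anticodon,
                       refs)
    return {"anticodon": cls.anticodon, "amino_acid": cls.amino_acid,
            "nearest": cls.nearest, "ranking": cls.ranking}


def run_accession_checks(directory: str | Path) -> pd.DataFrame:
    """Compute every regression statistic; returns an observed-vs-expected
    table (comparison against the published precision is the caller's
    job)."""
    g = load_accessions(directory)
    rows = []

    def add(check, observed, expected):
        rows.append({"check": check, "observed": observed,
                     "expected": expected})

    add("subs_MH349357_MH349358",
        count_substitutions(g["MH349357"].seq, g["MH349358"].seq), 6)
    add("subs_MH349356_MH349359",
        count_substitutions(g["MH349356"].seq, g["MH349359"].seq), 22)
    add("p_KM434235_MH349359",
        round(genome_p_distance(g["KM434235"], g["MH349359"]), 3), 0.097)
    add("cox1_p_MH349358_KT326918",
        round(locus_p_distance(g["MH349358"], g["KT326918"], "cox1"), 2),
        0.04)
    c59 = global_composition(g["MH349359"].seq)
    c58 = global_composition(g["MH349358"].seq)
    add("at_skew_MH349359", round(c59.at_skew, 4), -0.3166)
    add("gc_MH349359", round(c59.gc_content, 4), 0.3284)
    add("at_skew_MH349358", round(c58.at_skew, 4), -0.2828)
    add("gc_MH349358", round(c58.gc_content, 4), 0.3396)
    rep = detect_extra_features(g["MH349359"], g["MH349358"])
    morf = next(((n, q, r) for n, q, r in rep.gained if n == "m-ORF"),
                None)
    add("morf_copies_MH349359", morf[1] if morf else 0, 2)
    extra_trn = sum(q - r for n, q, r in rep.gained
                    if n.lower().startswith("trn"))
    add("extra_trn_MH349359", extra_trn, 1)
    novel = novel_trn_check(g["MH349359"])
    add("novel_trn_anticodon", novel["anticodon"], "TAT")
    add("novel_trn_nearest", novel["nearest"], "trnD")
    return pd.DataFrame(rows)
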