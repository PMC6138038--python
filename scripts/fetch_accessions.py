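#!/usr/bin/env python
"""One-time download of the GenBank records used by the regression checks.

Usage:  python scripts/fetch_accessions.py [--outdir data/accessions]

Requires network access to NCBI eutils; afterwards the checks in
mitopair.validation (and the corresponding acceptance test) run offline.
"""

import argparse
import time
import urllib.request
from pathlib import Path

from mitopair.validation import ACCESSIONS

EFETCH = ("https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
          "?db=nuccore&id={acc}&rettype=gbwithparts&retmode=text")


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--outdir", default="data/accessions")
    args = ap.parse_args()
    outdir = Path(args.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for acc in ACCESSIONS:
        dest = outdir / f"{acc}.gb"
        if dest.exists():
            print(f"{acc}: already present")
            continue
        url = EFETCH.format(acc=acc)
        print(f"fetching {acc} ...")
        with urllib.request.urlopen(url, timeout=60) as resp:
            text = resp.read().decode()
        if "ORIGIN" not in text:
            raise RuntimeError(f"unexpected efetch response for {acc}")
        dest.write_text(text)
        time.sleep(0.4)  # NCBI rate courtesy
    print(f"done; records in {outdir}/")


if __name__ == "__main__":
    main()
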