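#!/usr/bin/env python
"""Optional: download the GenBank sequences behind the accession-gated test
tier into tests/data/accessions/ (requires network; the package never needs
these files to run).

    python scripts/fetch_accessions.py [--email you@example.org]
"""

from __future__ import annotations

import argparse
import sys
import urllib.parse
import urllib.request
from pathlib import Path

OUT = Path(__file__).resolve().parent.parent / "tests" / "data" / "accessions"

# ITS genotype references (small; fetched individually)
ITS_REFS = ["AB067721", "AB067744", "AB067740", "KJ720572",
            "KT232017", "KT232019", "KT232010"]

EFETCH = ("https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
          "?db=nuccore&rettype=fasta&retmode=text&id={}")


def fetch(accession: str) -> str:
    url = EFETCH.format(urllib.parse.quote(accession))
    with urllib.request.urlopen(url, timeout=60) as resp:
        return resp.read().decode()


def main() -> None:
    argparse.ArgumentParser(description=__doc__).parse_args()
    OUT.mkdir(parents=True, exist_ok=True)
    for acc in ITS_REFS:
        dest = OUT / f"{acc}.fasta"
        if dest.exists():
            print(f"{acc}: cached")
            continue
        try:
            dest.write_text(fetch(acc))
            print(f"{acc}: fetched")
        except OSError as exc:
            print(f"{acc}: FAILED ({exc})", file=sys.stderr)
    print(f"wrote to {OUT}")
    print("note: whole-genome assemblies (e.g. JAAVMX000000000) must be "
          "downloaded manually from NCBI Assembly and saved as "
          "<accession>.fasta in the same directory.")


if __name__ == "__main__":
    main()
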