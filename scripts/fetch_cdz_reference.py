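#!/usr/bin/env python
"""Fetch the CdzC/CdzD reference proteins from NCBI (network required).

Downloads the translated products of the Caulobacter crescentus NA1000
loci CCNA_03932 (CdzC) and CCNA_03933 (CdzD) via NCBI E-utilities and
writes them to data/reference/cdz_proteins.faa.  The test suite's
reference-composition check and any accession-based analysis read that
file; everything else in the package runs fully offline.

Usage:  python scripts/fetch_cdz_reference.py
"""
from __future__ import annotations

import sys
import time
import urllib.parse
import urllib.request
from pathlib import Path

EUTILS = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils"
LOCI = {"CdzC": "CCNA_03932", "CdzD": "CCNA_03933"}
OUT = Path(__file__).resolve().parents[1] / "data" / "reference" / "cdz_proteins.faa"


def _get(url: str) -> str:
    with urllib.request.urlopen(url, timeout=30) as resp:
        return resp.read().decode()


def fetch_protein(locus_tag: str) -> str:
    term = urllib.parse.quote(f"{locus_tag}[Gene Name] AND Caulobacter[Organism]")
    ids = _get(f"{EUTILS}/esearch.fcgi?db=protein&term={term}&retmode=json")
    import json

    idlist = json.loads(ids)["esearchresult"]["idlist"]
    if not idlist:
        raise RuntimeError(f"no protein record found for {locus_tag}")
    time.sleep(0.4)  # E-utilities rate limit
    fasta = _get(f"{EUTILS}/efetch.fcgi?db=protein&id={idlist[0]}&rettype=fasta&retmode=text")
    lines = fasta.strip().splitlines()
    return "".join(lines[1:])


def main() -> int:
    OUT.parent.mkdir(parents=True, exist_ok=True)
    records = []
    for name, locus in LOCI.items():
        seq = fetch_protein(locus)
        print(f"{name} ({locus}): {len(seq)} aa")
        records.append(f">{name}|{locus}\n{seq}\n")
        time.sleep(0.4)
    OUT.write_text("".join(records))
    print(f"wrote {OUT}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
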