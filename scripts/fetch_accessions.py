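#!/usr/bin/env python
"""Download the five published BAC insert sequences from NCBI (one-time;
network required). Usage:

    python scripts/fetch_accessions.py --out data/accessions
"""

import argparse
import os
import urllib.request

from tetrascan.reproduce import ACCESSIONS

EUTILS = (
    "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
    "?db=nuccore&id={acc}&rettype=fasta&retmode=text"
)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", default="data/accessions")
    args = ap.parse_args()
    os.makedirs(args.out, exist_ok=True)
    for acc, clone in ACCESSIONS.items():
        dest = os.path.join(args.out, acc + ".fasta")
        if os.path.exists(dest):
            print(f"{dest} exists, skipping")
            continue
        print(f"fetching {acc} ({clone}) ...")
        with urllib.request.urlopen(EUTILS.format(acc=acc), timeout=60) as resp:
            data = resp.read()
        if not data.startswith(b">"):
            raise RuntimeError(f"unexpected response for {acc}")
        with open(dest, "wb") as fh:
            fh.write(data)
        print(f"wrote {dest}")


if __name__ == "__main__":
    main()
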