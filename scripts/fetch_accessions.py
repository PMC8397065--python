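"""Fetch the five deposited Coeliadinae mitogenome records from NCBI.

Optional helper: the replication checks in the test suite run against local
copies of the deposited GenBank flat files when present under
``data/accessions/``. Requires network access to eutils.ncbi.nlm.nih.gov.

Usage: python scripts/fetch_accessions.py [--out data/accessions]
"""

import argparse
import sys
import time
import urllib.request
from pathlib import Path

ACCESSIONS = ("MZ502489", "MZ502490", "MZ502491", "MZ502492", "MZ502493")
EFETCH = (
    "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
    "?db=nuccore&id={acc}&rettype=gb&retmode=text"
)


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", default="data/accessions", type=Path)
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)
    for acc in ACCESSIONS:
        dest = args.out / f"{acc}.gb"
        if dest.exists():
            print(f"{dest} already present", file=sys.stderr)
            continue
        with urllib.request.urlopen(EFETCH.format(acc=acc), timeout=60) as resp:
            text = resp.read().decode()
        if not text.startswith("LOCUS"):
            print(f"{acc}: unexpected response, skipped", file=sys.stderr)
            return 1
        dest.write_text(text)
        print(f"wrote {dest}", file=sys.stderr)
        time.sleep(0.5)  # NCBI rate-limit etiquette
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
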