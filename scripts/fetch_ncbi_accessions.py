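#!/usr/bin/env python
"""One-time fetch of the real nsLTP accession set from NCBI.

Downloads the five legume query LTPs, the five allergenic reference LTPs and
the fifteen-allergen LTP panel into ``tests/fixtures/ncbi_ltp_accessions.fasta``
so the accession-bound acceptance checks can run.  Requires network access to
eutils.ncbi.nlm.nih.gov; the pipeline itself never fetches anything.

Usage:  python scripts/fetch_ncbi_accessions.py [--out PATH]
"""

from __future__ import annotations

import argparse
import sys
import time
import urllib.parse
import urllib.request
from pathlib import Path

ACCESSIONS = [
    # legume query LTPs
    "CAA05771",        # chickpea
    "CCF23017",        # mung bean
    "CAA56113",        # cowpea
    "XP_020207090",    # pigeon pea
    "XP_003549896",    # soybean
    # allergenic reference LTPs
    "AGW21358",        # peach (Pru p 3)
    "AJG44053",        # garden pea
    "AAX35806",        # lentil
    "ADC80502",        # green bean
    "ABX56711",        # peanut
    # fifteen-allergen LTP panel
    "P24296.2", "AAA32995.1", "E6Y8S8.1", "P19656.1", "NP_001316314.1",
    "P80273.2", "Q9ATH2.1", "ACI47547.1", "CAA63340.1", "P81651.2",
    "P82534.1", "Q9M5X8.1", "Q43017.1", "Q9M5X6.1", "Q9M5X7.1",
]

EUTILS = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"


def fetch(accession: str) -> str:
    query = urllib.parse.urlencode(
        {"db": "protein", "id": accession, "rettype": "fasta", "retmode": "text"}
    )
    with urllib.request.urlopen(f"{EUTILS}?{query}", timeout=60) as response:
        return response.read().decode()


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument(
        "--out",
        type=Path,
        default=Path(__file__).resolve().parent.parent
        / "tests"
        / "fixtures"
        / "ncbi_ltp_accessions.fasta",
    )
    args = parser.parse_args()
    args.out.parent.mkdir(parents=True, exist_ok=True)

    chunks = []
    for accession in ACCESSIONS:
        sys.stderr.write(f"fetching {accession}...\n")
        text = fetch(accession).strip()
        if not text.startswith(">"):
            sys.stderr.write(f"unexpected response for {accession}\n")
            return 1
        # rewrite the header so the record id is exactly the accession
        header, _, body = text.partition("\n")
        chunks.append(f">{accession} {header.lstrip('>')}\n{body}\n")
        time.sleep(0.4)  # NCBI rate limit
    args.out.write_text("".join(chunks))
    sys.stderr.write(f"wrote {len(ACCESSIONS)} records to {args.out}\n")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
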