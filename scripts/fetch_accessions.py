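#!/usr/bin/env python
"""Download the deposited crystal structures used by the accession-based
acceptance tests into tests/data/accessions/ (network required).

Usage::

    python scripts/fetch_accessions.py
"""

from __future__ import annotations

import urllib.request
from pathlib import Path

CODES = ["5b7s", "5b87", "5b89", "5b7u", "1jf9", "1kmk", "1kmj", "1t3i"]
DEST = Path(__file__).resolve().parent.parent / "tests" / "data" / "accessions"


def main() -> None:
    DEST.mkdir(parents=True, exist_ok=True)
    for code in CODES:
        out = DEST / f"{code}.pdb"
        if out.exists():
            print(f"{out} already present")
            continue
        url = f"https://files.rcsb.org/download/{code.upper()}.pdb"
        print(f"fetching {url}")
        with urllib.request.urlopen(url, timeout=60) as resp:
            out.write_bytes(resp.read())
        print(f"wrote {out}")


if __name__ == "__main__":
    main()
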