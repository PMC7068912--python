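#!/usr/bin/env python
"""Download the reference plastome EMBL records used by the acceptance tests.

The records are fetched from the ENA browser API into data/accessions/ and
are not redistributed with the package.  Requires network access.

Usage:  python scripts/fetch_accessions.py [ACCESSION ...]
"""

import sys
import urllib.request
from pathlib import Path

ACCESSIONS = [
    "AM777385",  # Lolium perenne
    "AP005672",  # Physcomitrella patens
    "KP119739",  # Orthotrichum rogeri
    "FJ546412",  # Syntrichia ruralis
    "AB197035",  # Selaginella uncinata
    "HM173080",  # Selaginella moellendorffii
    "KP688069",  # Hibiscus syriacus
    "AP009368",  # Olimarabidopsis pumila
    "KC117178",  # Ophioglossum californicum
    "GU191334",  # Equisetum arvense
]

URL = "https://www.ebi.ac.uk/ena/browser/api/embl/{acc}"


def main(argv: list[str]) -> int:
    accessions = argv or ACCESSIONS
    target_dir = Path(__file__).resolve().parents[1] / "data" / "accessions"
    target_dir.mkdir(parents=True, exist_ok=True)
    failures = 0
    for acc in accessions:
        target = target_dir / f"{acc}.embl"
        if target.exists():
            print(f"{acc}: already present")
            continue
        try:
            with urllib.request.urlopen(URL.format(acc=acc), timeout=60) as resp:
                data = resp.read()
            if not data.strip():
                raise RuntimeError("empty response")
            target.write_bytes(data)
            print(f"{acc}: {len(data)} bytes -> {target}")
        except Exception as exc:
            failures += 1
            print(f"{acc}: FAILED ({exc})", file=sys.stderr)
    return 1 if failures else 0


if __name__ == "__main__":
    raise SystemExit(main(sys.argv[1:]))
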