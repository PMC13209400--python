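#!/usr/bin/env python
"""Download the CP176011 chromosome FASTA from NCBI into scratch/.

Optional helper: enables the accession-backed descriptive-statistics
check in the test suite.  Requires network access; the test suite never
downloads anything itself and the rest of the suite does not depend on
this file.
"""

from __future__ import annotations

import sys
import urllib.parse
import urllib.request
from pathlib import Path

EUTILS = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
ACCESSION = "CP176011"
DEST = Path(__file__).resolve().parent.parent / "scratch" / f"{ACCESSION}.fasta"


def main() -> int:
    params = urllib.parse.urlencode(
        {"db": "nuccore", "id": ACCESSION, "rettype": "fasta", "retmode": "text"}
    )
    url = f"{EUTILS}?{params}"
    print(f"fetching {ACCESSION} from NCBI ...")
    with urllib.request.urlopen(url, timeout=120) as response:
        payload = response.read().decode()
    if not payload.startswith(">"):
        print("unexpected response (not FASTA)", file=sys.stderr)
        return 1
    DEST.parent.mkdir(parents=True, exist_ok=True)
    DEST.write_text(payload)
    n_bases = sum(len(line.strip()) for line in payload.splitlines()[1:])
    print(f"wrote {DEST} ({n_bases:,} bases)")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
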