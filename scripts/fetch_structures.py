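#!/usr/bin/env python
"""Download the wwPDB depositions used by the real-data analyses.

Fetches the Fab-HLA complex (6ID4), the unbound HLA-A*11:01 reference
(2HN7) and the receptor complexes (5WKH TCR, 4N8V KIR2DS2, 1AKJ CD8) into
data/structures/. Requires network access; the test suite and acceptance
script run fully on synthetic data when these files are absent, while the
real-data assertions fail with a pointer to this script.

Usage: python scripts/fetch_structures.py [--dest data/structures]
"""

from __future__ import annotations

import argparse
import sys
import urllib.request
from pathlib import Path

ENTRIES = ("6id4", "2hn7", "5wkh", "4n8v", "1akj")
URL = "https://files.rcsb.org/download/{code}.cif"


def main() -> int:
    ap = argparse.ArgumentParser()
    ap.add_argument("--dest", default="data/structures")
    args = ap.parse_args()
    dest = Path(args.dest)
    dest.mkdir(parents=True, exist_ok=True)
    failures = 0
    for code in ENTRIES:
        target = dest / f"{code}.cif"
        if target.exists():
            print(f"{target} already present")
            continue
        url = URL.format(code=code)
        try:
            print(f"fetching {url} ...")
            with urllib.request.urlopen(url, timeout=60) as resp:
                target.write_bytes(resp.read())
        except Exception as exc:  # noqa: BLE001 - report and continue
            print(f"  FAILED: {exc}", file=sys.stderr)
            failures += 1
    return 1 if failures else 0


if __name__ == "__main__":
    raise SystemExit(main())
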