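#!/usr/bin/env python
"""Download and unpack the four GEO GDS SOFT files used in the benchmarks.

Writes ``data/gds/<accession>.soft`` (uncompressed text).  Requires
network access to ftp.ncbi.nlm.nih.gov; run once, then both the
acceptance report (scripts/acceptance.py) and the dataset-statistic
acceptance test work offline.
"""

from __future__ import annotations

import gzip
import shutil
import sys
import urllib.request
from pathlib import Path

ACCESSIONS = ["GDS1761", "GDS5232", "GDS2735", "GDS1210"]
URL = ("https://ftp.ncbi.nlm.nih.gov/geo/datasets/"
       "{prefix}nnn/{acc}/soft/{acc}.soft.gz")


def main() -> int:
    out_dir = Path(__file__).resolve().parent.parent / "data" / "gds"
    out_dir.mkdir(parents=True, exist_ok=True)
    for acc in ACCESSIONS:
        dest = out_dir / f"{acc}.soft"
        if dest.exists():
            print(f"{acc}: already present", file=sys.stderr)
            continue
        url = URL.format(prefix=acc[:4], acc=acc)
        gz = out_dir / f"{acc}.soft.gz"
        print(f"{acc}: fetching {url}", file=sys.stderr)
        urllib.request.urlretrieve(url, gz)
        with gzip.open(gz, "rb") as src, open(dest, "wb") as out:
            shutil.copyfileobj(src, out)
        gz.unlink()
        print(f"{acc}: wrote {dest}", file=sys.stderr)
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
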