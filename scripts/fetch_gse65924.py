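#!/usr/bin/env python
"""Download the GSE65924 supplementary expression matrix into data/.

The mid-gastrula mouse embryo FPKM matrix (23,361 genes x 41 samples)
enables the optional real-data benchmark in the test suite.  The test
suite never downloads anything itself; run this helper once, then rerun
pytest.
"""

import sys
import urllib.request
from pathlib import Path

URL = (
    "https://ftp.ncbi.nlm.nih.gov/geo/series/GSE65nnn/GSE65924/suppl/"
    "GSE65924_E1.gene.expression.txt.gz"
)


def main() -> int:
    dest = Path(__file__).resolve().parent.parent / "data"
    dest.mkdir(exist_ok=True)
    target = dest / "GSE65924_E1.gene.expression.txt.gz"
    if target.exists():
        print(f"already present: {target}")
        return 0
    print(f"fetching {URL}")
    try:
        urllib.request.urlretrieve(URL, target)
    except OSError as exc:
        print(f"download failed: {exc}", file=sys.stderr)
        return 1
    print(f"wrote {target} ({target.stat().st_size} bytes)")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
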