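#!/usr/bin/env python
"""Download the three reference protein-peptide complexes into data/pdb/.

Needs network access to the RCSB PDB.  The structure-based checks in the
test suite and scripts/acceptance.py pick the files up automatically once
they are present.

Usage:
    python scripts/fetch_pdb.py [--dest data/pdb]
"""

import argparse
import urllib.request
from pathlib import Path

PDB_IDS = ("2LLO", "1DDV", "1JD5")
URL = "https://files.rcsb.org/download/{pdb_id}.pdb"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument(
        "--dest",
        type=Path,
        default=Path(__file__).resolve().parent.parent / "data" / "pdb",
    )
    args = parser.parse_args()
    args.dest.mkdir(parents=True, exist_ok=True)
    for pdb_id in PDB_IDS:
        target = args.dest / f"{pdb_id.lower()}.pdb"
        if target.exists():
            print(f"{target} already present")
            continue
        url = URL.format(pdb_id=pdb_id)
        print(f"fetching {url} -> {target}")
        with urllib.request.urlopen(url, timeout=60) as response:
            target.write_bytes(response.read())
    print("done")


if __name__ == "__main__":
    main()
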