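"""Optional: download genome FASTA files for a list of NCBI accessions.

Network-dependent and deliberately outside the test surface.  Feed it a
text file with one accession per line (e.g. NC_001659) and an email for
NCBI Entrez, and it writes one FASTA per accession, ready for
``dlphylo.RunConfig(inputs=(out_dir,), ...)``.

Usage:
    python scripts/fetch_accessions.py accessions.txt out_dir --email you@site.org
"""

from __future__ import annotations

import argparse
import time
from pathlib import Path

from Bio import Entrez, SeqIO


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("accessions", type=Path, help="text file, one accession per line")
    ap.add_argument("out_dir", type=Path)
    ap.add_argument("--email", required=True, help="contact email for NCBI Entrez")
    ap.add_argument("--db", default="nuccore")
    args = ap.parse_args()

    Entrez.email = args.email
    args.out_dir.mkdir(parents=True, exist_ok=True)
    accs = [a.strip() for a in args.accessions.read_text().splitlines() if a.strip()]
    for acc in accs:
        dest = args.out_dir / f"{acc}.fasta"
        if dest.exists():
            print(f"{acc}: already present")
            continue
        with Entrez.efetch(db=args.db, id=acc, rettype="fasta", retmode="text") as h:
            record = SeqIO.read(h, "fasta")
        SeqIO.write(record, str(dest), "fasta")
        print(f"{acc}: {len(record.seq)} bp -> {dest}")
        time.sleep(0.4)  # stay under NCBI rate limits


if __name__ == "__main__":
    main()
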