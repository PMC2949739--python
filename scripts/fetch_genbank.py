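#!/usr/bin/env python
"""Optional helper: download the study's deposited haplotype sequences.

Fetches GenBank accessions GU990095-GU990222 (128 cloned, phased haplotype
sequences: 4 immunity genes x 16 An. gambiae M-form individuals x 2
haplotypes) via NCBI Entrez and groups them into one FASTA per gene by
parsing the record definition lines.  Requires network access and an
e-mail address for Entrez; the downloaded sequences must then be aligned
(e.g. with mafft) before running the pipeline on them.

Usage:
    python scripts/fetch_genbank.py --email you@example.org --out data/genbank/
"""

from __future__ import annotations

import argparse
import os
import re
from collections import defaultdict

from Bio import Entrez, SeqIO

GENES = ("Gambicin", "NOS", "REL2", "FBN9")
ACCESSIONS = [f"GU{i:06d}" for i in range(990095, 990223)]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--email", required=True, help="Entrez contact e-mail")
    parser.add_argument("--out", required=True, help="output directory")
    args = parser.parse_args()

    Entrez.email = args.email
    os.makedirs(args.out, exist_ok=True)
    handle = Entrez.efetch(
        db="nucleotide", id=",".join(ACCESSIONS), rettype="gb", retmode="text"
    )
    by_gene = defaultdict(list)
    for rec in SeqIO.parse(handle, "genbank"):
        desc = rec.description
        gene = next(
            (g for g in GENES if re.search(g, desc, flags=re.IGNORECASE)), "unknown"
        )
        by_gene[gene].append(rec)
    handle.close()
    for gene, records in sorted(by_gene.items()):
        path = os.path.join(args.out, f"{gene}_gambiae_M.unaligned.fasta")
        SeqIO.write(records, path, "fasta")
        print(f"{gene}: {len(records)} records -> {path}")
    print("Align each file (e.g. `mafft --auto ...`) before analysis.")


if __name__ == "__main__":
    main()
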