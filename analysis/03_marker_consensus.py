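#!/usr/bin/env python
"""Merge candidate contigs across the six assemblies into non-redundant
markers, rank them by cumulative support, and export the top 11 for primer
design.

Reads the per-assembly candidate lists from 02 and the assembly FASTA from
01; writes the ranked marker table and the top-11 FASTA under results/.
"""

from pathlib import Path

import pandas as pd
from Bio import SeqIO

import radsexing as rs

ROOT = Path(__file__).resolve().parents[1] / "results"
SIM = Path(__file__).resolve().parents[1] / "scratch" / "simulated"


def main() -> None:
    cands = pd.read_csv(ROOT / "candidates_by_assembly.csv")
    male = cands[cands["sex"] == "M"]

    sequences = {}
    for fasta in sorted(SIM.glob("asm*.fasta")):
        if "_counts" in fasta.name:
            continue
        for rec in SeqIO.parse(str(fasta), "fasta"):
            sequences[rec.id] = str(rec.seq)

    cseqs = [
        rs.CandidateSeq(
            contig_id=row.contig_id,
            assembly_id=row.assembly,
            sequence=sequences[row.contig_id],
            passed_levels=tuple(int(x) for x in str(row.passed_levels).split(";") if x),
        )
        for row in male.itertuples()
    ]
    groups = rs.collapse_identical(cseqs)
    ranked = rs.cumulative_support_rank(groups)

    table = pd.DataFrame({
        "rank": [m.rank for m in ranked],
        "marker_id": [m.marker_id for m in ranked],
        "cumulative_support": [m.cumulative_support for m in ranked],
        "n_assemblies": [len(m.assemblies) for m in ranked],
        "length_bp": [len(m.sequence) for m in ranked],
    })
    table.to_csv(ROOT / "ranked_markers.csv", index=False)
    rs.select_top(ranked, k=11, path=ROOT / "top11_markers.fasta")

    print(f"{len(cseqs)} male candidates across assemblies -> "
          f"{len(groups)} non-redundant markers")
    print(table.head(11).to_string(index=False))
    print(f"top 11 written to {ROOT / 'top11_markers.fasta'}")


if __name__ == "__main__":
    main()
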