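#!/usr/bin/env python
"""Simulate the ddRAD study design: a 20-male + 20-female cohort with 10
planted Y-hemizygous loci among 2000 contigs, 10 % per-cell locus dropout,
and six partially-overlapping pseudo-assemblies.

Writes the file bundle every downstream step consumes (read-count TSVs, sex
registry, per-assembly FASTA) plus the ground-truth tables, under
scratch/simulated/ (bulky, regenerable output).
"""

from pathlib import Path

import pandas as pd

import radsexing as rs

SEED = 20
OUT = Path(__file__).resolve().parents[1] / "scratch" / "simulated"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    truth, counts = rs.simulate_cohort(
        n_males=20, n_females=20, n_contigs=2000, n_y_loci=10,
        dropout_prob=0.1, seed=SEED,
    )
    rs.synthetic.write_counts_tsv(counts, OUT / "read_counts.tsv")
    rs.synthetic.write_sex_registry(truth, OUT / "sex_registry.csv")
    pd.Series(sorted(truth.y_loci)).to_csv(OUT / "truth_y_loci.csv",
                                           index=False, header=["contig_id"])

    assemblies = rs.simulate_assemblies(truth, n_assemblies=6,
                                        split_prob=0.05, seed=SEED + 1)
    for asm in assemblies:
        rs.synthetic.write_assembly_fasta(asm, OUT / f"{asm.assembly_id}.fasta")
        rs.synthetic.write_counts_tsv(rs.assembly_read_counts(counts, asm),
                                      OUT / f"{asm.assembly_id}_counts.tsv")

    n_present = int((counts > 0).sum().sum())
    print(f"cohort: {len(truth.males)} males + {len(truth.females)} females, "
          f"{len(truth.contig_ids)} loci ({len(truth.y_loci)} planted Y)")
    print(f"read-count table: {n_present}/{counts.size} cells positive "
          f"({100 * n_present / counts.size:.1f} %)")
    print(f"assemblies: {len(assemblies)} -> {OUT}")


if __name__ == "__main__":
    main()
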