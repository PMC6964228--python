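#!/usr/bin/env python
"""Parental relatedness and pollen availability versus offspring sex.

Simulates an adult reference population with microsatellite genotypes,
computes the pairwise kinship F of each offspring's assigned parent pair
against that reference, median-splits offspring on parent kinship, and
tests per-mother female proportions against pollen-availability covariates
with Pearson correlations.  Writes the annotated offspring table and test
results under results/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

import radsexing as rs

SEED = 100
ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    rng = np.random.default_rng(SEED)
    n_adults = 200
    adults = [f"adult{k:03d}" for k in range(n_adults)]
    ped = pd.DataFrame({"individual_id": adults,
                        "mother_id": [None] * n_adults,
                        "father_id": [None] * n_adults})
    genotypes = rs.simulate_genotypes(ped, n_loci=12, n_alleles=6, seed=SEED)
    freqs = rs.allele_freqs(genotypes)  # whole adult dataset as reference

    off = rs.simulate_offspring_table(n=139, seed=SEED + 1)
    off["mother_id"] = rng.choice(adults[:58], size=len(off))
    off["father_id"] = rng.choice(adults[58:], size=len(off))
    annotated = rs.parent_pair_table(off, genotypes, freqs)
    annotated.to_csv(ROOT / "offspring_parent_kinship.csv", index=False)
    f = annotated["parent_f"]
    print(f"parent-pair kinship: n = {f.notna().sum()}, "
          f"range {f.min():.3f} .. {f.max():.3f}, mean {f.mean():.3f}")

    split = rs.median_split(annotated, "parent_f", label_col="grp")
    report = rs.group_sexratio_report(split, "grp")
    report.to_csv(ROOT / "kinship_split_tests.csv", index=False)
    print(f"median split at F = {split.attrs['median']:.3f}:")
    print(report.to_string(index=False))

    # pollen availability vs per-mother proportion of female offspring
    per_mother = (off.assign(is_f=(off["sex"] == "F").astype(float))
                  .groupby("mother_id")
                  .agg(prop_female=("is_f", "mean"), n=("is_f", "size")))
    per_mother["dist_nearest_male_m"] = rng.uniform(0.9, 18.6, size=len(per_mother))
    per_mother["males_within_10m"] = rng.integers(0, 9, size=len(per_mother))
    rows = []
    for covariate in ("dist_nearest_male_m", "males_within_10m"):
        r, df, p = rs.pearson_test(per_mother[covariate], per_mother["prop_female"])
        rows.append({"covariate": covariate, "r": r, "df": df, "p": p})
        print(f"{covariate}: r_{df} = {r:.3f}, p = {p:.2f}")
    pd.DataFrame(rows).to_csv(ROOT / "pollen_availability_tests.csv", index=False)


if __name__ == "__main__":
    main()
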