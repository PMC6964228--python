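"""Pairwise kinship from codominant multi-allelic genotypes.

Implements the multilocus kinship coefficient F of the Loiselle et al.
(1995) family: for a pair (i, j) at locus l with reference allele
frequencies p̄_la estimated from a reference sample of n_l gene-copy
diplotypes,

    num_l = Σ_a (p_ia − p̄_la)(p_ja − p̄_la) + Σ_a p̄_la(1 − p̄_la)/(n_l − 1)
    den_l = Σ_a p̄_la(1 − p̄_la)

where p_ia ∈ {0, 0.5, 1} is individual i's dosage of allele a divided by 2,
and n_l counts reference individuals genotyped at locus l.  The multilocus
estimate is the ratio of sums F = Σ_l num_l / Σ_l den_l, the standard
weighting that keeps uninformative loci harmless.  The small-sample term
makes the estimator unbiased around 0 for pairs unrelated relative to the
reference; expectation is ≈0.25 for parent-offspring and full sibs, ≈0.125
for half sibs.

Genotypes arrive as a long table (individual_id, locus, allele1, allele2);
missing data are handled per locus (pairwise-complete).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AlleleFrequencies",
    "KinshipEstimate",
    "allele_freqs",
    "loiselle_kinship",
    "pairwise_kinship",
    "parent_pair_table",
]


@dataclass(frozen=True)
class AlleleFrequencies:
    """Per-locus reference allele frequencies with gene-copy counts."""

    freqs: Mapping[str, Mapping[str, float]]   # locus -> allele -> frequency
    n_individuals: Mapping[str, int]           # locus -> reference individuals genotyped

    def loci(self) -> list[str]:
        return list(self.freqs)


@dataclass(frozen=True)
class KinshipEstimate:
    pair: tuple[str, str]
    f: float
    per_locus: Mapping[str, tuple[float, float]]  # locus -> (numerator, denominator)
    n_loci_used: int


def _genotype_map(genotypes: pd.DataFrame) -> dict[str, dict[str, tuple[str, str]]]:
    out: dict[str, dict[str, tuple[str, str]]] = {}
    for row in genotypes.itertuples():
        out.setdefault(row.individual_id, {})[row.locus] = (str(row.allele1), str(row.allele2))
    return out


def allele_freqs(
    genotypes: pd.DataFrame,
    reference_ids: Iterable[str] | None = None,
) -> AlleleFrequencies:
    """Estimate per-locus allele frequencies from a reference sample.

    Missing entries (NaN alleles or absent rows) are excluded per locus;
    gene-copy counts are 2 × the non-missing reference individuals.  A locus
    with zero observations in the reference is dropped with a warning; if no
    locus survives the whole table is rejected.
    """
    g = genotypes.dropna(subset=["allele1", "allele2"])
    if reference_ids is not None:
        ref = set(reference_ids)
        g = g[g["individual_id"].isin(ref)]
    freqs: dict[str, dict[str, float]] = {}
    n_ind: dict[str, int] = {}
    for locus in genotypes["locus"].drop_duplicates():
        sub = g[g["locus"] == locus]
        if len(sub) == 0:
            warnings.warn(f"locus {locus!r} has zero observations in the reference; dropped",
                          stacklevel=2)
            continue
        copies = pd.concat([sub["allele1"], sub["allele2"]]).astype(str)
        counts = copies.value_counts()
        freqs[str(locus)] = (counts / counts.sum()).to_dict()
        n_ind[str(locus)] = len(sub)
    if not freqs:
        raise ValueError("no locus with observations in the reference sample")
    return AlleleFrequencies(freqs=freqs, n_individuals=n_ind)


def _dosage(genotype: tuple[str, str], alleles: Sequence[str]) -> np.ndarray:
    d = np.zeros(len(alleles))
    index = {a: k for k, a in enumerate(alleles)}
    for a in genotype:
        d[index[a]] += 0.5
    return d


def loiselle_kinship(
    ind_i: str,
    ind_j: str,
    genotypes: pd.DataFrame,
    freqs: AlleleFrequencies,
) -> KinshipEstimate:
    """Multilocus kinship F between two individuals (ratio of sums over the
    loci at which both are genotyped and the reference is informative)."""
    gmap = _genotype_map(genotypes.dropna(subset=["allele1", "allele2"]))
    for ind in (ind_i, ind_j):
        if ind not in gmap:
            raise ValueError(f"individual {ind!r} has no genotypes")

    per_locus: dict[str, tuple[float, float]] = {}
    num_sum = den_sum = 0.0
    shared = [l for l in freqs.loci() if l in gmap[ind_i] and l in gmap[ind_j]]
    if not shared:
        raise ValueError(f"{ind_i!r} and {ind_j!r} share no genotyped locus")
    for locus in shared:
        f = freqs.freqs[locus]
        n = freqs.n_individuals[locus]
        if n < 2:
            raise ValueError(f"locus {locus!r}: reference of n >= 2 individuals required")
        alleles = list(f)
        p_bar = np.array([f[a] for a in alleles])
        pi = _dosage(gmap[ind_i][locus], alleles)
        pj = _dosage(gmap[ind_j][locus], alleles)
        num = float(((pi - p_bar) * (pj - p_bar)).sum()
                    + (p_bar * (1 - p_bar)).sum() / (n - 1))
        den = float((p_bar * (1 - p_bar)).sum())
        per_locus[locus] = (num, den)
        num_sum += num
        den_sum += den
    if den_sum == 0:
        raise ValueError("all shared loci are uninformative (zero denominator)")
    pair = tuple(sorted((ind_i, ind_j)))
    return KinshipEstimate(pair=pair, f=num_sum / den_sum,
                           per_locus=per_locus, n_loci_used=len(shared))


def pairwise_kinship(
    pairs: Sequence[tuple[str, str]],
    genotypes: pd.DataFrame,
    freqs: AlleleFrequencies,
) -> pd.DataFrame:
    """Vectorised multilocus F for many pairs at once.

    Same estimator as `loiselle_kinship`; returns a DataFrame with columns
    id_i, id_j, f, n_loci_used.
    """
    loci = freqs.loci()
    blocks = []       # per-locus (allele index, p_bar, bias, den)
    for locus in loci:
        f = freqs.freqs[locus]
        n = freqs.n_individuals[locus]
        if n < 2:
            raise ValueError(f"locus {locus!r}: reference of n >= 2 individuals required")
        alleles = list(f)
        p_bar = np.array([f[a] for a in alleles])
        het = float((p_bar * (1 - p_bar)).sum())
        blocks.append((alleles, p_bar, het / (n - 1), het))

    gmap = _genotype_map(genotypes.dropna(subset=["allele1", "allele2"]))
    ids = sorted({i for p in pairs for i in p})
    missing = [i for i in ids if i not in gmap]
    if missing:
        raise ValueError(f"individuals with no genotypes: {missing[:5]}")

    # centered dosage matrix per locus: n_ids x n_alleles, NaN when untyped
    row = {ind: k for k, ind in enumerate(ids)}
    centered = []
    typed = np.zeros((len(ids), len(loci)), dtype=bool)
    for li, (locus, (alleles, p_bar, _bias, _den)) in enumerate(zip(loci, blocks)):
        mat = np.full((len(ids), len(alleles)), np.nan)
        for ind in ids:
            g = gmap[ind].get(locus)
            if g is not None:
                mat[row[ind]] = _dosage(g, alleles) - p_bar
                typed[row[ind], li] = True
        centered.append(mat)

    bias = np.array([b for (_a, _p, b, _d) in blocks])
    den = np.array([d for (_a, _p, _b, d) in blocks])
    out = []
    for a, b in pairs:
        ia, ib = row[a], row[b]
        use = typed[ia] & typed[ib] & (den > 0)
        if not use.any():
            raise ValueError(f"{a!r} and {b!r} share no informative genotyped locus")
        cross = np.array([
            float(np.dot(centered[li][ia], centered[li][ib]))
            for li in np.flatnonzero(use)
        ])
        f_hat = (cross.sum() + bias[use].sum()) / den[use].sum()
        out.append({"id_i": a, "id_j": b, "f": f_hat, "n_loci_used": int(use.sum())})
    return pd.DataFrame(out)


def parent_pair_table(
    offspring: pd.DataFrame,
    genotypes: pd.DataFrame,
    freqs: AlleleFrequencies | None = None,
) -> pd.DataFrame:
    """Annotate each offspring with the kinship F of its assigned parents.

    Offspring whose mother or father lacks genotypes are flagged
    (``excluded`` = True, F = NaN) rather than failing the whole table.
    Reference allele frequencies default to the full genotype table (the
    whole-adult-sample convention).
    """
    if freqs is None:
        freqs = allele_freqs(genotypes)
    typed = set(genotypes.dropna(subset=["allele1", "allele2"])["individual_id"])
    out = offspring.copy()
    ok = out["mother_id"].isin(typed) & out["father_id"].isin(typed)
    out["excluded"] = ~ok
    out["parent_f"] = np.nan
    if ok.any():
        pairs_df = out.loc[ok, ["mother_id", "father_id"]].drop_duplicates()
        pairs = list(pairs_df.itertuples(index=False, name=None))
        kin = pairwise_kinship(pairs, genotypes, freqs)
        lookup = {(r.id_i, r.id_j): r.f for r in kin.itertuples()}
        out.loc[ok, "parent_f"] = [
            lookup[(m, f)] for m, f in
            zip(out.loc[ok, "mother_id"], out.loc[ok, "father_id"])
        ]
    return out
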