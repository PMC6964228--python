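"""Privacy rarefaction: separating sex-exclusive loci from missing-data noise.

In reduced-representation sequencing of a dioecious species, a contig that is
hemizygous on the Y chromosome is present in males and absent in females.
Stochastic locus dropout produces the same presence/absence pattern by
chance, especially when few individuals are compared.  Privacy rarefaction
resolves the two: at "stringency" level *s*, random subsamples of *s* males
and *s* females are drawn repeatedly, and a contig is scored *male-private*
in one draw iff it is present in all *s* drawn males and absent in all *s*
drawn females (female-private symmetric).  Artefactual candidates vanish as
*s* grows, while genuinely sex-linked loci keep near-complete bootstrap
support; a persistent excess of male-private over female-private candidates
at high stringency indicates an XY (male-heterogametic) system, the mirror
image a ZW system.

The scan operates on a boolean presence matrix derived from a read-count
table by a minimum-read threshold.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PresenceMatrix",
    "PrivacyRarefactionResult",
    "build_presence_matrix",
    "scan",
    "candidate_contigs",
    "classify_heterogamety",
    "incidence_report",
    "format_incidence",
]


@dataclass(frozen=True)
class PresenceMatrix:
    """Boolean presence of each contig (row) in each individual (column)."""

    contig_ids: tuple[str, ...]
    individual_ids: tuple[str, ...]
    matrix: np.ndarray  # bool, shape (n_contigs, n_individuals)
    min_reads: int

    def __post_init__(self) -> None:
        if self.matrix.shape != (len(self.contig_ids), len(self.individual_ids)):
            raise ValueError("matrix shape inconsistent with ids")
        if self.matrix.dtype != np.bool_:
            raise ValueError("matrix must be boolean")


def build_presence_matrix(counts: pd.DataFrame, min_reads: int = 1) -> PresenceMatrix:
    """Threshold a contig × individual read-count table into presence calls.

    presence(c, i) ⇔ count(c, i) >= ``min_reads``.
    """
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    if counts.index.has_duplicates:
        raise ValueError("duplicate contig ids")
    if counts.columns.has_duplicates:
        raise ValueError("duplicate individual ids")
    values = counts.to_numpy()
    if not np.issubdtype(values.dtype, np.number) or (values < 0).any():
        raise ValueError("read counts must be non-negative numbers")
    return PresenceMatrix(
        contig_ids=tuple(str(c) for c in counts.index),
        individual_ids=tuple(str(i) for i in counts.columns),
        matrix=values >= min_reads,
        min_reads=min_reads,
    )


@dataclass(frozen=True)
class PrivacyRarefactionResult:
    """Per-stringency candidate-count distributions and per-contig supports.

    ``male_counts[s-1]`` / ``female_counts[s-1]`` hold the number of
    male-/female-private contigs in each permutation at stringency ``s``
    (length ``n_boot``, or the number of exhaustive subset pairs).
    ``male_support`` / ``female_support`` are (n_contigs, S) arrays giving,
    per contig and level, the fraction of permutations in which the contig
    was private to that sex.
    """

    contig_ids: tuple[str, ...]
    stringencies: tuple[int, ...]
    male_counts: tuple[np.ndarray, ...]
    female_counts: tuple[np.ndarray, ...]
    male_support: np.ndarray
    female_support: np.ndarray
    n_boot: int
    seed: int | None
    exhaustive: bool = False

    def summary(self) -> pd.DataFrame:
        """Mean / median / quartiles of candidate counts per level and sex."""
        rows = []
        for s, mc, fc in zip(self.stringencies, self.male_counts, self.female_counts):
            for sex, c in (("male", mc), ("female", fc)):
                rows.append({
                    "stringency": s,
                    "sex": sex,
                    "n_perm": len(c),
                    "mean": float(np.mean(c)),
                    "median": float(np.median(c)),
                    "q25": float(np.quantile(c, 0.25)),
                    "q75": float(np.quantile(c, 0.75)),
                })
        return pd.DataFrame(rows)

    def mean_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """Mean male-private and female-private counts per stringency level."""
        return (
            np.array([float(np.mean(c)) for c in self.male_counts]),
            np.array([float(np.mean(c)) for c in self.female_counts]),
        )


def _check_sexes(
    matrix: PresenceMatrix, sexes: Mapping[str, str]
) -> tuple[np.ndarray, np.ndarray]:
    missing = [i for i in matrix.individual_ids if i not in sexes]
    if missing:
        raise ValueError(f"individuals missing from sex registry: {missing[:5]}")
    # pools ordered by individual id, so the subsampling stream is invariant
    # to column order and attached to group membership, not to the M/F label
    by_id = sorted(range(len(matrix.individual_ids)),
                   key=lambda i: matrix.individual_ids[i])
    males = np.array([i for i in by_id if sexes[matrix.individual_ids[i]] == "M"],
                     dtype=np.intp)
    females = np.array([i for i in by_id if sexes[matrix.individual_ids[i]] == "F"],
                       dtype=np.intp)
    if len(males) == 0 or len(females) == 0:
        raise ValueError("need at least one male and one female")
    return males, females


def _group_rng(seed: int | None, matrix: PresenceMatrix,
               pool: np.ndarray) -> np.random.Generator:
    """RNG stream keyed by the seed and the pooled individuals' ids, so the
    same group of individuals always sees the same subsample draws."""
    import hashlib

    ids = ",".join(matrix.individual_ids[i] for i in pool)
    digest = int.from_bytes(hashlib.sha256(ids.encode()).digest()[:8], "little")
    entropy = [digest] if seed is None else [seed, digest]
    if seed is None:
        return np.random.default_rng()
    return np.random.default_rng(np.random.SeedSequence(entropy))


def scan(
    matrix: PresenceMatrix,
    sexes: Mapping[str, str],
    n_boot: int = 200,
    max_stringency: int | None = None,
    seed: int | None = None,
    exhaustive: bool = False,
) -> PrivacyRarefactionResult:
    """Run the privacy-rarefaction scan over stringency levels 1..S.

    At each level ``s``, ``n_boot`` independent permutations each draw ``s``
    males and ``s`` females uniformly without replacement; privacy is scored
    strictly (present in *all* drawn carriers, absent in *all* drawn
    non-carriers).  With ``exhaustive=True`` every (male-subset,
    female-subset) pair is enumerated instead — exact supports for small
    cohorts, and the oracle the Monte-Carlo mode is validated against.
    """
    males, females = _check_sexes(matrix, sexes)
    S = min(len(males), len(females))
    if max_stringency is not None:
        if max_stringency > S:
            raise ValueError(f"max_stringency {max_stringency} exceeds min sex size {S}")
        S = max_stringency
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")

    present = matrix.matrix
    C = present.shape[0]
    rng_m = _group_rng(seed, matrix, males)
    rng_f = _group_rng(seed, matrix, females)

    male_counts: list[np.ndarray] = []
    female_counts: list[np.ndarray] = []
    msup = np.zeros((C, S))
    fsup = np.zeros((C, S))

    for s in range(1, S + 1):
        if exhaustive:
            m_subsets = [np.array(c) for c in itertools.combinations(males, s)]
            f_subsets = [np.array(c) for c in itertools.combinations(females, s)]
            draws = [(m, f) for m in m_subsets for f in f_subsets]
            midx = np.stack([d[0] for d in draws])
            fidx = np.stack([d[1] for d in draws])
        else:
            midx = np.stack([males[rng_m.choice(len(males), size=s, replace=False)]
                             for _ in range(n_boot)])
            fidx = np.stack([females[rng_f.choice(len(females), size=s, replace=False)]
                             for _ in range(n_boot)])
        B = midx.shape[0]
        # (C, B): contig private per permutation
        in_all_males = present[:, midx].all(axis=2)
        in_any_female = present[:, fidx].any(axis=2)
        in_all_females = present[:, fidx].all(axis=2)
        in_any_male = present[:, midx].any(axis=2)
        male_private = in_all_males & ~in_any_female
        female_private = in_all_females & ~in_any_male
        male_counts.append(male_private.sum(axis=0).astype(np.int64))
        female_counts.append(female_private.sum(axis=0).astype(np.int64))
        msup[:, s - 1] = male_private.mean(axis=1)
        fsup[:, s - 1] = female_private.mean(axis=1)

    return PrivacyRarefactionResult(
        contig_ids=matrix.contig_ids,
        stringencies=tuple(range(1, S + 1)),
        male_counts=tuple(male_counts),
        female_counts=tuple(female_counts),
        male_support=msup,
        female_support=fsup,
        n_boot=n_boot,
        seed=seed,
        exhaustive=exhaustive,
    )


def candidate_contigs(
    result: PrivacyRarefactionResult,
    min_support: float = 0.5,
    min_stringency: int = 3,
) -> pd.DataFrame:
    """Retain contigs with bootstrap support >= ``min_support`` for privacy
    to one sex at any stringency level >= ``min_stringency``.

    Returns a DataFrame with one row per retained (contig, sex): contig_id,
    sex ('M'/'F'), passed_levels (tuple of levels >= min_stringency where
    support >= min_support), max_support, and support_by_level (dict).
    """
    if not 0.0 < min_support <= 1.0:
        raise ValueError("min_support must lie in (0, 1]")
    levels = np.array(result.stringencies)
    if min_stringency < levels.min() or min_stringency > levels.max():
        raise ValueError("min_stringency outside evaluated levels")
    eligible = levels >= min_stringency

    rows = []
    for sex, sup in (("M", result.male_support), ("F", result.female_support)):
        hit = (sup[:, eligible] >= min_support).any(axis=1)
        for c in np.flatnonzero(hit):
            passed = tuple(int(l) for l in levels[eligible & (sup[c] >= min_support)])
            rows.append({
                "contig_id": result.contig_ids[c],
                "sex": sex,
                "passed_levels": passed,
                "max_support": float(sup[c, eligible].max()),
                "support_by_level": {int(l): float(v) for l, v in zip(levels, sup[c])},
            })
    df = pd.DataFrame(rows, columns=["contig_id", "sex", "passed_levels",
                                     "max_support", "support_by_level"])
    return df.sort_values(["sex", "contig_id"], ignore_index=True)


def classify_heterogamety(
    result: PrivacyRarefactionResult,
) -> tuple[str, dict]:
    """Classify the sex-determination system from the stringency curves.

    At the maximal evaluated stringency, 'XY-like' iff the mean male-private
    count exceeds 0 while the mean female-private count rounds to 0
    (mean < 0.5); 'ZW-like' symmetric; 'none' otherwise.  Requires at least
    three evaluated levels so that artefacts have had room to decay.
    """
    if len(result.stringencies) < 3:
        raise ValueError("classification needs >= 3 stringency levels")
    m_curve, f_curve = result.mean_counts()
    m, f = m_curve[-1], f_curve[-1]
    if m > 0 and f < 0.5:
        label = "XY-like"
    elif f > 0 and m < 0.5:
        label = "ZW-like"
    else:
        label = "none"
    diagnostics = {
        "stringencies": list(result.stringencies),
        "mean_male_private": m_curve.tolist(),
        "mean_female_private": f_curve.tolist(),
        "final_male_mean": float(m),
        "final_female_mean": float(f),
    }
    return label, diagnostics


def incidence_report(
    result: PrivacyRarefactionResult,
    assembly_total: int,
    stringency: int | None = None,
    sex: str = "M",
) -> float:
    """Mean sex-specific candidate count at a stringency level, as a
    percentage of the assembly's total contig count.

    Defaults to the highest evaluated stringency and male-private counts.
    """
    if assembly_total <= 0:
        raise ValueError("assembly_total must be positive")
    if stringency is None:
        stringency = result.stringencies[-1]
    if stringency not in result.stringencies:
        raise ValueError(f"stringency {stringency} was not evaluated")
    idx = result.stringencies.index(stringency)
    counts = result.male_counts[idx] if sex == "M" else result.female_counts[idx]
    return 100.0 * float(np.mean(counts)) / assembly_total


def format_incidence(pct: float, sig_figs: int = 2) -> str:
    """Render an incidence percentage at 2 significant figures, e.g. '0.0056 %'."""
    if pct == 0:
        return "0 %"
    from decimal import Decimal

    q = float(f"{pct:.{sig_figs}g}")
    return f"{Decimal(repr(q)):f} %"
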