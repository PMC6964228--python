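"""Synthetic ddRAD cohorts with planted sex-linked loci.

Generates every input the marker-discovery pipeline consumes — per-contig
read-count tables with a known set of Y- (or W-) hemizygous loci, alternative
pseudo-assemblies with contig sequences, PCR sexing-assay call tables,
microsatellite genotypes under Mendelian inheritance, and offspring tables
with pollen-dispersal and parental-kinship covariates.  Ground truth is
carried alongside so that recovery can be scored exactly.

The generative model is deliberately minimal: a cohort of ``n_males`` +
``n_females`` diploid individuals; ``n_contigs`` loci of which ``n_y_loci``
are Y-hemizygous (present only in males) and ``n_w_loci`` W-hemizygous
(present only in females); all remaining loci autosomal (present in
everyone).  Present (contig, individual) cells receive a positive Poisson
read count; independent per-cell dropout with probability ``dropout_prob``
then zeroes cells, emulating the stochastic locus absence that restriction-
site polymorphism, low coverage and library variation cause in real ddRAD
matrices.  All draws flow from one explicit seed; no global RNG state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CohortTruth",
    "Assembly",
    "simulate_cohort",
    "simulate_assemblies",
    "assembly_read_counts",
    "simulate_assay_calls",
    "simulate_offspring_table",
    "simulate_genotypes",
    "write_counts_tsv",
    "write_sex_registry",
    "write_assembly_fasta",
]

DEFAULT_MARKERS = ("Lm123977", "Lm435135")

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class CohortTruth:
    """Ground truth of a simulated cohort.

    individuals are ordered males first then females; ``sexes`` maps each
    individual id to 'M' or 'F'.  ``y_loci`` / ``w_loci`` are the planted
    hemizygous contig ids (disjoint).  ``params`` records the simulation
    parameters, seed included.
    """

    individuals: tuple[str, ...]
    sexes: Mapping[str, str]
    contig_ids: tuple[str, ...]
    y_loci: frozenset[str]
    w_loci: frozenset[str]
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.y_loci & self.w_loci:
            raise ValueError("planted Y and W locus sets must be disjoint")
        known = set(self.contig_ids)
        if not (self.y_loci <= known and self.w_loci <= known):
            raise ValueError("planted locus ids must exist among contig ids")
        p = self.params.get("dropout_prob", 0.0)
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout_prob must lie in [0, 1)")

    @property
    def males(self) -> tuple[str, ...]:
        return tuple(i for i in self.individuals if self.sexes[i] == "M")

    @property
    def females(self) -> tuple[str, ...]:
        return tuple(i for i in self.individuals if self.sexes[i] == "F")


@dataclass(frozen=True)
class Assembly:
    """One pseudo-assembly: contig sequences plus the contig→locus map."""

    assembly_id: str
    sequences: dict[str, str]  # contig id -> DNA sequence
    locus_of: dict[str, str]  # contig id -> underlying true locus id

    def __post_init__(self) -> None:
        for cid, seq in self.sequences.items():
            if not seq or set(seq) - {"A", "C", "G", "T"}:
                raise ValueError(f"contig {cid}: sequences must be non-empty A/C/G/T")
        if set(self.sequences) != set(self.locus_of):
            raise ValueError("sequences and locus map must cover the same contigs")


def _positive_poisson(rng: np.random.Generator, lam: float, size) -> np.ndarray:
    # zero-truncated Poisson via inverse-CDF conditioning on X >= 1
    from scipy import stats

    u = rng.uniform(size=size)
    p0 = np.exp(-lam)
    return stats.poisson.ppf(p0 + u * (1.0 - p0), lam).astype(np.int64)


def simulate_cohort(
    n_males: int,
    n_females: int,
    n_contigs: int,
    n_y_loci: int = 0,
    n_w_loci: int = 0,
    dropout_prob: float = 0.0,
    mean_coverage: float = 20.0,
    seed: int | None = None,
) -> tuple[CohortTruth, pd.DataFrame]:
    """Simulate a sexed cohort and its contig × individual read-count table.

    Before dropout, planted Y contigs have positive counts in every male and
    zero in every female (W symmetric); autosomal contigs are positive in
    everyone.  Dropout then independently zeroes each (contig, individual)
    cell with probability ``dropout_prob``.

    Returns ``(truth, counts)`` where ``counts`` is a DataFrame indexed by
    contig id with one integer column per individual.
    """
    if n_males < 1 or n_females < 1:
        raise ValueError("need at least one male and one female")
    if n_contigs < 1:
        raise ValueError("n_contigs must be positive")
    if n_y_loci < 0 or n_w_loci < 0 or n_y_loci + n_w_loci > n_contigs:
        raise ValueError("planted locus counts must be >= 0 and fit in n_contigs")
    if not 0.0 <= dropout_prob < 1.0:
        raise ValueError("dropout_prob must lie in [0, 1)")
    if mean_coverage <= 0:
        raise ValueError("mean_coverage must be positive")

    rng = np.random.default_rng(seed)
    males = tuple(f"M{i + 1:03d}" for i in range(n_males))
    females = tuple(f"F{i + 1:03d}" for i in range(n_females))
    individuals = males + females
    width = max(5, len(str(n_contigs)))
    contigs = tuple(f"locus{i + 1:0{width}d}" for i in range(n_contigs))

    y_ids = frozenset(contigs[:n_y_loci])
    w_ids = frozenset(contigs[n_y_loci : n_y_loci + n_w_loci])

    is_male = np.array([s in males for s in individuals])
    carrier = np.ones((n_contigs, len(individuals)), dtype=bool)
    carrier[:n_y_loci, :] = is_male[None, :]
    carrier[n_y_loci : n_y_loci + n_w_loci, :] = ~is_male[None, :]

    counts = np.zeros(carrier.shape, dtype=np.int64)
    counts[carrier] = _positive_poisson(rng, mean_coverage, int(carrier.sum()))
    if dropout_prob > 0:
        counts[rng.uniform(size=carrier.shape) < dropout_prob] = 0

    params = dict(
        n_males=n_males,
        n_females=n_females,
        n_contigs=n_contigs,
        n_y_loci=n_y_loci,
        n_w_loci=n_w_loci,
        dropout_prob=dropout_prob,
        mean_coverage=mean_coverage,
        seed=seed,
    )
    truth = CohortTruth(
        individuals=individuals,
        sexes={i: ("M" if m else "F") for i, m in zip(individuals, is_male)},
        contig_ids=contigs,
        y_loci=y_ids,
        w_loci=w_ids,
        params=params,
    )
    table = pd.DataFrame(counts, index=pd.Index(contigs, name="contig_id"),
                         columns=list(individuals))
    return truth, table


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def simulate_assemblies(
    truth: CohortTruth,
    n_assemblies: int = 6,
    split_prob: float = 0.0,
    contig_length: int = 131,
    seed: int | None = None,
) -> list[Assembly]:
    """Emulate alternative de novo assemblies of the same underlying loci.

    Each true locus receives one random DNA sequence, identical wherever the
    locus is assembled in one piece.  Within each assembly a locus is instead
    split into two overlapping fragments with probability ``split_prob``
    (both fragments keep the underlying locus id in ``locus_of``), emulating
    over-splitting at stricter clustering identity cutoffs.
    """
    if n_assemblies < 1:
        raise ValueError("n_assemblies must be >= 1")
    if not 0.0 <= split_prob <= 1.0:
        raise ValueError("split_prob must lie in [0, 1]")
    if contig_length < 20:
        raise ValueError("contig_length must be >= 20")

    rng = np.random.default_rng(seed)
    locus_seq = {lid: _random_seq(rng, contig_length) for lid in truth.contig_ids}

    assemblies = []
    for a in range(n_assemblies):
        aid = f"asm{a + 1}"
        seqs: dict[str, str] = {}
        locus_of: dict[str, str] = {}
        for lid in truth.contig_ids:
            full = locus_seq[lid]
            if rng.uniform() < split_prob:
                cut = contig_length // 2
                overlap = min(10, cut)
                for part, frag in (("a", full[: cut + overlap]), ("b", full[cut - overlap :])):
                    cid = f"{aid}_{lid}_{part}"
                    seqs[cid] = frag
                    locus_of[cid] = lid
            else:
                cid = f"{aid}_{lid}"
                seqs[cid] = full
                locus_of[cid] = lid
        assemblies.append(Assembly(assembly_id=aid, sequences=seqs, locus_of=locus_of))
    return assemblies


def assembly_read_counts(counts: pd.DataFrame, assembly: Assembly) -> pd.DataFrame:
    """Project a locus-level read-count table onto one assembly's contigs.

    Every contig inherits the counts of its underlying locus (split fragments
    both receive the locus's reads, as both halves recruit the same reads
    when mapped).
    """
    contig_ids = sorted(assembly.sequences)
    loci = [assembly.locus_of[c] for c in contig_ids]
    out = counts.loc[loci].copy()
    out.index = pd.Index(contig_ids, name="contig_id")
    return out


def simulate_assay_calls(
    truth: CohortTruth,
    marker_failure_prob: float = 0.0,
    control_failure_prob: float = 0.0,
    marker_ids: Sequence[str] = DEFAULT_MARKERS,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate the PCR sexing screen for a cohort of known sex.

    Females never amplify the male-linked markers.  Males amplify every
    marker unless a per-individual DNA-quality failure event occurs, which
    knocks out *both* markers jointly (the mode observed in real screens,
    where a single degraded sample fails all sex-linked primer pairs).  The
    positive control fails independently with ``control_failure_prob``.

    Returns a long table: individual_id, marker_id, amplified (0/1),
    control ('pass'/'fail').
    """
    for p in (marker_failure_prob, control_failure_prob):
        if not 0.0 <= p <= 1.0:
            raise ValueError("failure probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    for ind in truth.individuals:
        male = truth.sexes[ind] == "M"
        joint_failure = male and rng.uniform() < marker_failure_prob
        control = "fail" if rng.uniform() < control_failure_prob else "pass"
        for m in marker_ids:
            amplified = int(male and not joint_failure)
            rows.append((ind, m, amplified, control))
    return pd.DataFrame(rows, columns=["individual_id", "marker_id", "amplified", "control"])


def simulate_offspring_table(
    n: int = 589,
    prop_female: float = 0.5,
    n_mothers: int = 58,
    n_female_forced: int | None = None,
    pollen_median_m: float = 21.9,
    pollen_sdlog: float = 0.8,
    kinship_mean: float = 0.068,
    kinship_sd: float = 0.10,
    cohort_weights: Mapping[str, float] | None = None,
    subpop_weights: Mapping[str, float] | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate an offspring table with sexes, parents and covariates.

    Sexes are i.i.d. Bernoulli(``prop_female``) unless ``n_female_forced``
    pins the exact female count (a random permutation of a fixed margin,
    used to reproduce printed contingency tables).  Pollen dispersal
    distances are log-normal with the given median; parent-pair kinship is
    normal, clipped to a realistic envelope.  Mothers are assigned with
    unequal propensities so per-mother brood sizes vary (real broods range
    from singletons to tens of offspring).
    """
    if not 0.0 <= prop_female <= 1.0:
        raise ValueError("prop_female must lie in [0, 1]")
    if n < 1 or n_mothers < 1:
        raise ValueError("n and n_mothers must be positive")
    if n_female_forced is not None and not 0 <= n_female_forced <= n:
        raise ValueError("n_female_forced out of range")

    cohort_weights = cohort_weights or {
        "young seedling": 49, "seedling": 54, "juvenile": 460, "adolescent": 26,
    }
    subpop_weights = subpop_weights or {
        "VdM": 222, "FP": 143, "FF": 123, "CU": 93,
    }
    rng = np.random.default_rng(seed)

    if n_female_forced is None:
        sex = np.where(rng.uniform(size=n) < prop_female, "F", "M")
    else:
        sex = np.array(["F"] * n_female_forced + ["M"] * (n - n_female_forced))
        rng.shuffle(sex)

    mother_ids = [f"mother{i + 1:03d}" for i in range(n_mothers)]
    w = rng.dirichlet(np.full(n_mothers, 0.8))
    mothers = rng.choice(mother_ids, size=n, p=w)
    fathers = np.array([f"father{i:03d}" for i in rng.integers(1, 200, size=n)])

    pollen = np.exp(rng.normal(np.log(pollen_median_m), pollen_sdlog, size=n))
    kin = np.clip(rng.normal(kinship_mean, kinship_sd, size=n), -0.2, 0.45)

    def _draw(weights: Mapping[str, float]) -> np.ndarray:
        keys = list(weights)
        p = np.array([weights[k] for k in keys], dtype=float)
        return rng.choice(keys, size=n, p=p / p.sum())

    cohort = _draw(cohort_weights)
    subpop = _draw(subpop_weights)

    # seed mass/length only known for the youngest cohort (measured as seeds)
    mass = np.where(cohort == "young seedling",
                    np.clip(rng.normal(8.6, 2.0, size=n), 3.0, 13.0), np.nan)
    length = np.where(cohort == "young seedling",
                      np.clip(rng.normal(30.5, 2.5, size=n), 20.0, 40.0), np.nan)

    return pd.DataFrame({
        "offspring_id": [f"off{i + 1:04d}" for i in range(n)],
        "sex": sex,
        "mother_id": mothers,
        "father_id": fathers,
        "pollen_distance_m": np.round(pollen, 2),
        "parent_kinship": np.round(kin, 4),
        "cohort": cohort,
        "subpopulation": subpop,
        "seed_mass_kg": np.round(mass, 2),
        "seed_length_cm": np.round(length, 1),
    })


def simulate_genotypes(
    pedigree: pd.DataFrame,
    n_loci: int = 12,
    n_alleles: int = 5,
    allele_freqs: Mapping[str, Mapping[str, float]] | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate codominant multi-allelic genotypes down a pedigree.

    ``pedigree`` needs columns individual_id, mother_id, father_id (empty /
    NaN parents mark founders).  Founders draw two alleles from the locus
    allele frequencies (Hardy-Weinberg); non-founders receive one allele
    from each parent by fair Mendelian sampling.  Both parents must be
    present for a non-founder.  Pedigree cycles are rejected.

    Returns a long table: individual_id, locus, allele1, allele2.
    """
    if allele_freqs is None:
        if n_alleles < 2:
            raise ValueError("need >= 2 alleles per locus (monomorphic loci rejected)")
        freqs = {
            f"loc{l + 1:02d}": {f"a{a + 1}": 1.0 / n_alleles for a in range(n_alleles)}
            for l in range(n_loci)
        }
    else:
        freqs = {loc: dict(f) for loc, f in allele_freqs.items()}
        for loc, f in freqs.items():
            if len(f) < 2:
                raise ValueError(f"locus {loc} is monomorphic: >= 2 alleles required")
            tot = sum(f.values())
            if not np.isclose(tot, 1.0):
                raise ValueError(f"locus {loc}: allele frequencies must sum to 1")

    ped = pedigree.copy()
    for col in ("mother_id", "father_id"):
        ped[col] = ped[col].where(ped[col].notna() & (ped[col] != ""), None)
    ids = list(ped["individual_id"])
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate individual ids in pedigree")

    # topological order; a cycle leaves individuals unresolvable
    parents = {r.individual_id: (r.mother_id, r.father_id) for r in ped.itertuples()}
    order: list[str] = []
    resolved: set[str] = set()
    pending = list(ids)
    while pending:
        progressed = False
        rest = []
        for i in pending:
            m, f = parents[i]
            if all(p is None or p in resolved for p in (m, f)):
                order.append(i)
                resolved.add(i)
                progressed = True
            else:
                rest.append(i)
        if not progressed:
            unknown = [i for i in rest
                       if any(p is not None and p not in parents for p in parents[i])]
            if unknown:
                raise ValueError(f"non-founder with parent missing from pedigree: {unknown[:3]}")
            raise ValueError("pedigree contains a cycle")
        pending = rest

    rng = np.random.default_rng(seed)
    geno: dict[str, dict[str, tuple[str, str]]] = {}
    rows = []
    for ind in order:
        m, f = parents[ind]
        geno[ind] = {}
        for loc, fr in freqs.items():
            alleles = list(fr)
            p = np.array([fr[a] for a in alleles])
            if m is None and f is None:
                a1, a2 = rng.choice(alleles, size=2, p=p / p.sum())
            elif m is not None and f is not None:
                a1 = geno[m][loc][rng.integers(0, 2)]
                a2 = geno[f][loc][rng.integers(0, 2)]
            else:
                raise ValueError(f"individual {ind}: exactly one parent given")
            geno[ind][loc] = (a1, a2)
            rows.append((ind, loc, a1, a2))
    return pd.DataFrame(rows, columns=["individual_id", "locus", "allele1", "allele2"])


# --- writers -----------------------------------------------------------------

def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index=True)


def write_sex_registry(truth: CohortTruth, path) -> None:
    pd.DataFrame(
        {"individual_id": truth.individuals,
         "sex": [truth.sexes[i] for i in truth.individuals]}
    ).to_csv(path, index=False)


def write_assembly_fasta(assembly: Assembly, path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(assembly.sequences[cid]), id=cid,
                  description=f"locus={assembly.locus_of[cid]}")
        for cid in sorted(assembly.sequences)
    ]
    seqio_write(records, path, "fasta")
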