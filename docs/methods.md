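# Methods

## The problem and the model

In a dioecious species with male heterogamety (XY), loci in the
non-recombining region of the Y chromosome are hemizygous: every male
carries them, no female does. In reduced-representation sequencing
(ddRAD) of a cohort of known-sex individuals they surface as reference
contigs whose mapped reads come only from males. The difficulty is that
RAD data are riddled with stochastic locus absence — restriction-site
polymorphism, uneven library depth, allelic dropout — so "present in the
males I sequenced, absent in the females" is also the signature of noise.
Everything in this package is organised around separating those two
explanations and then using the resulting markers.

## Privacy rarefaction

At stringency level *s* the scan draws *s* males and *s* females uniformly
without replacement and scores a contig **male-private** for that draw iff
it is present in all *s* drawn males and absent in all *s* drawn females
(female-private symmetric; strict privacy, no tolerance fraction). Each
level is replicated `n_boot` times (default 200); the **bootstrap
support** of a contig at a level is the fraction of its draws in which the
contig was private, and the per-level candidate count is summarised by its
mean (plus median and quartiles) across draws. Supports are strict
Monte-Carlo proportions; for cohorts small enough, an exhaustive mode
enumerates every (male-subset, female-subset) pair and returns exact
supports — the oracle the Monte-Carlo mode is tested against.

A contig whose privacy is genuine keeps support near 1 as *s* grows; a
contig private by chance loses support roughly geometrically, because each
added individual is another opportunity to observe the disconfirming
pattern. Hence the two diagnostic curves (mean male-private and mean
female-private count per level): in an XY system the male curve flattens
to the true Y-locus count while the female curve collapses to zero.

Decision rules, all parameters of the API:

* **retention** — support ≥ `min_support` (0.5) at any stringency ≥
  `min_stringency` (3); retained contigs carry the full set of passed
  levels (levels ≥ `min_stringency` with support ≥ `min_support`).
* **heterogamety label** — at the maximal evaluated stringency: XY-like
  iff the mean male-private count is > 0 while the mean female-private
  count "rounds to zero" (mean < 0.5); ZW-like symmetric; otherwise none.
  At least three levels are required so artefacts have had room to decay.
* **incidence** — mean sex-specific candidate count at a chosen level as a
  percentage of the assembly's contig total, printed at 2 significant
  figures.

Presence itself is thresholded from a read-count table (`count ≥
min_reads`, default 1).

Numerical/design notes. Subsampling streams are keyed by the seed together
with the sorted ids of each sex group, not by the group's label or column
order; as a consequence permuting individuals (with the registry permuted
identically) leaves every output unchanged, and swapping all M/F labels
swaps the male/female outputs exactly — both properties are tested. At the
very top stringency of a balanced cohort only one distinct subset pair
exists, so the "bootstrap" degenerates to a single deterministic
comparison; analyses that classify heterogamety therefore scan to half the
per-sex sample size (for a 20+20 cohort, s = 10, which is also the
comparison depth at which marker incidence is quoted), where subset
diversity is maximal.

## Cross-assembly consensus

Alternative de novo assemblies of the same reads (different clustering
identities, single- vs paired-end) guard against assembler-specific false
positives, but re-discover the same loci under different contig ids.
Candidates are therefore collapsed at **100 % identity**: two sequences
group when one equals, or is an exact substring of, the other on either
strand; grouping is the transitive closure (two fragments both contained
in a longer contig group together), and the representative is the longest
member. This is deliberately an exact string operation — no alignment
heuristics, no mismatches — so the collapse is exactly reproducible.

Groups are ranked by **cumulative support**: the sum over all member
candidates of their passed stringency levels. Ties break on the highest
single-assembly support, then lexicographically on the representative id —
an arbitrary but fixed total order, so reruns are byte-identical. The top
k (default 11) are exported as FASTA with provenance-carrying headers.

Contig extension emulates recruiting perfectly matching unassembled reads:
a read (either strand) whose prefix is 100 % identical to the contig's 3'
end over ≥ `min_overlap` bases contributes its overhang; the sequence
grows one base at a time and stops at the first position where two
candidate reads disagree (a conservative alternative to majority voting,
chosen for reproducibility). The 5' end is handled via the reverse
complement. The output always contains the input, and re-extension is a
fixed point for non-degenerate inputs; a cap on total added bases (the
summed read length per end) guards against unbounded growth on periodic
sequences, where the fixed-point property necessarily fails.

## Molecular sexing assay

Per sample: amplification calls for the Y-linked markers plus a positive
control. Control failure ⇒ the sample is void. Otherwise ≥ 1 marker
amplifying calls the sample male — an OR rule, because hemizygous markers
drop out individually — with a discordance flag when markers disagree; no
amplification calls female. The rule's asymmetric blind spot is inherent:
a male whose DNA fails all marker PCRs while passing the control is
miscalled female, and is only detectable against a known-sex registry.
`validate_assay` computes exactly that screen (per-marker amplification
counts in known males, amplification among known females, miscall counts).

## Sex-ratio statistics

The central test is the exact two-sided binomial test under the
**point-probability convention**: with X ~ Binomial(n, p₀), the p-value
sums P(X = i) over all i whose point probability is ≤ P(X = k)·(1 + 1e-7).
The relative tolerance matters at ties (it is what makes the dead-centre
outcome, e.g. 34 or 35 of 69, give p = 1 exactly) and the sum is done in
log space so n of 10⁴ and beyond stays accurate. 95 % Clopper-Pearson
intervals are attached as an extension. Grouped reports apply the test per
group in input order; covariates are dichotomised at their median with
ties assigned to the "≤" group; Pearson tests use the t transform
r·√(n−2)/√(1−r²), also exposed as `p_from_r` for summary-level checks;
per-sex trait summaries report mean ± SE (sd/√N) with a point-biserial
test of trait against sex.

## Kinship

The pairwise kinship coefficient *F* of the Loiselle (1995) family, per
locus

    num_l = Σ_a (p_ia − p̄_la)(p_ja − p̄_la) + Σ_a p̄_la(1 − p̄_la)/(n_l − 1)
    den_l = Σ_a p̄_la(1 − p̄_la)

with p_ia ∈ {0, ½, 1} the half-dosage of allele a in individual i and p̄
the reference-sample frequencies (n_l reference individuals typed at locus
l). Loci combine as a **ratio of sums** (Σ num / Σ den), the standard
weighting that makes uninformative (monomorphic) loci contribute exactly
nothing; missing data are handled pairwise-complete per locus, and the
reference convention is the whole adult sample, including the tested pair.
The small-sample bias term centres unrelated pairs on zero; pedigree
expectations (≈ 0.25 parent-offspring and full sibs, ≈ 0.125 half sibs)
are recovered by the calibration experiments.

## Synthetic data

The generator emulates the study design rather than the sequencing
process. A cohort of `n_males` + `n_females` (defaults mirror the 20 + 20
discovery panel) carries `n_contigs` loci of which `n_y_loci` are planted
Y-hemizygous (and optionally `n_w_loci` W-hemizygous); carrier cells
receive a zero-truncated Poisson read count (mean 20, so presence survives
any sane `min_reads`), then independent per-cell dropout with probability
`dropout_prob` zeroes observations — the simplest mechanism that produces
the sex-private false positives the scan must defeat. Pseudo-assemblies
share one sequence per underlying locus (131 bp, the typical single-end
contig length) and over-split a locus into two overlapping fragments with
probability `split_prob`. Assay calls implement a per-individual
DNA-quality failure that knocks out both markers jointly — the observed
real-world failure mode — plus independent control failure. Offspring
tables default to the surveyed 589-offspring design (58 mothers with
strongly unequal brood propensities, log-normal pollen distances with
median 21.9 m, near-normal parent kinship centred at 0.068, cohort and
sub-population margins from the survey); a forced female count reproduces
printed contingency tables exactly. Genotypes follow Hardy-Weinberg
founders and fair Mendelian transmission down an explicit (acyclic)
pedigree.

What the generator does **not** model: read-level errors and quality
scores, restriction-site mutation as a mechanism (dropout is
phenomenological and per-cell; real missingness is structured by
individual library depth, which ranged over an order of magnitude in
comparable datasets — an optional per-individual tier exists but is off by
default), linkage between loci, selection or mortality. Passing tests
therefore demonstrate that the algorithms are correct under a clean,
known-truth missingness model, not that any particular real dataset meets
that model's assumptions.

## Validation experiments and problem sizes

`radsexing.experiments` packages three repeatable studies, shared verbatim
by the test suite and the reporting script; per-replicate seeds derive
from one master seed via `SeedSequence`.

* **Planted-marker recovery** — 50 replicates of the 20M + 20F / 2000
  contig / 10 planted loci / dropout 0.1 design, `n_boot` 200. Reported:
  planted loci retained by the 50 %-at-stringency-≥3 rule, false-positive
  male candidates, female candidates at maximal stringency. Note a hard
  combinatorial ceiling: retention at stringency 3 requires C(K,3)/C(20,3)
  ≥ ½, i.e. K ≥ 17 of 20 males still carrying the locus; with 10 % dropout
  K ~ Binomial(20, 0.9), so per-locus retention is ≈ 0.905 and the
  probability that ≥ 9 of 10 planted loci are retained in one replicate is
  ≈ 0.76 — the recovery experiment's per-seed success rate sits at that
  level by construction, while mean recovery is ≈ 9/10 and female false
  positives are essentially absent.
* **Heterogamety classification** — 100 replicates × three scenarios
  (planted-Y, the same matrix under a label swap, and a heavier-dropout
  null), 20 + 20 cohorts of 500 contigs scanned to stringency 10.
* **Kinship calibration** — 100 replicates of a 500-founder reference
  panel, 30 loci × 8 alleles, 25 parent-offspring and 25 unrelated pairs.

These sizes are scaled-down stand-ins for sequencing-scale discovery
(tens of thousands of contigs): they keep every replicate exact while the
whole suite runs in minutes on one CPU.

## Known limitations

* Strict privacy (no tolerance fraction) makes retention sensitive to
  per-carrier dropout at small cohort sizes, as quantified above; a
  tolerance variant would trade false negatives for false positives and is
  deliberately not implemented.
* The exact-identity collapse will not merge assembly variants that differ
  by even one base; near-identical redundancy is out of scope.
* The heterogamety classifier is a threshold rule on the final-level
  means; it reports "none" rather than attempting inference when both
  curves are non-zero.
* Kinship assumes autosomal, codominant, independent loci and a reference
  sample large enough that its frequencies are meaningful per locus.
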