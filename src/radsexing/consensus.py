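"""Cross-assembly candidate-marker consensus, ranking, and sequence export.

Candidate sex-linked contigs discovered independently in alternative de novo
assemblies are merged here: exact-identity redundancy collapse (a contig, its
reverse complement, or an exact substring of either counts as the same
marker), ranking by cumulative support summed over assemblies, greedy
contig extension from perfectly overlapping reads, and deterministic FASTA
export of the top candidates for primer design.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "CandidateSeq",
    "MarkerGroup",
    "CandidateMarker",
    "revcomp",
    "collapse_identical",
    "cumulative_support_rank",
    "extend_contig",
    "select_top",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID = frozenset("ACGT")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _validate_seq(seq: str, label: str = "sequence") -> None:
    if not seq:
        raise ValueError(f"{label} is empty")
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(f"{label} contains invalid characters: {sorted(bad)}")


@dataclass(frozen=True)
class CandidateSeq:
    """One candidate contig from one assembly, with its passed stringency levels."""

    contig_id: str
    assembly_id: str
    sequence: str
    passed_levels: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        _validate_seq(self.sequence, f"contig {self.contig_id}")

    @property
    def support(self) -> int:
        """Sum of passed stringency levels within this assembly."""
        return sum(self.passed_levels)


@dataclass(frozen=True)
class MarkerGroup:
    """A set of candidates collapsed at 100 % identity; representative is the
    longest member (ties: lexicographically smallest contig id)."""

    members: tuple[CandidateSeq, ...]

    @property
    def representative(self) -> CandidateSeq:
        return min(self.members, key=lambda c: (-len(c.sequence), c.contig_id))


@dataclass(frozen=True)
class CandidateMarker:
    """A ranked non-redundant marker with cross-assembly provenance."""

    marker_id: str
    sequence: str
    cumulative_support: int
    rank: int
    assemblies: tuple[str, ...]
    members: tuple[CandidateSeq, ...] = field(repr=False, default=())


def _same_marker(a: str, b: str) -> bool:
    """100 % identity on either strand, allowing exact containment."""
    if len(a) > len(b):
        a, b = b, a
    return a in b or revcomp(a) in b


def collapse_identical(candidates: Sequence[CandidateSeq]) -> list[MarkerGroup]:
    """Collapse candidates that are identical (or exact sub-sequences of one
    another, on either strand) into non-redundant groups.

    Grouping is the transitive closure of pairwise identity, so two short
    fragments both contained in a longer contig group together even if they
    do not overlap each other.
    """
    n = len(candidates)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    for i in range(n):
        for j in range(i + 1, n):
            if _same_marker(candidates[i].sequence, candidates[j].sequence):
                union(i, j)

    groups: dict[int, list[CandidateSeq]] = {}
    for i, c in enumerate(candidates):
        groups.setdefault(find(i), []).append(c)
    out = [MarkerGroup(members=tuple(sorted(g, key=lambda c: (c.assembly_id, c.contig_id))))
           for g in groups.values()]
    return sorted(out, key=lambda g: g.representative.contig_id)


def cumulative_support_rank(groups: Iterable[MarkerGroup]) -> list[CandidateMarker]:
    """Rank marker groups by cumulative support: the sum, over all member
    candidates from all assemblies, of their passed stringency levels.

    Ties break on the highest single-assembly support, then on the
    representative contig id — a fixed total order so reruns are identical.
    """
    scored = []
    for g in groups:
        rep = g.representative
        score = sum(c.support for c in g.members)
        best_single = max(c.support for c in g.members)
        scored.append((score, best_single, rep, g))
    scored.sort(key=lambda t: (-t[0], -t[1], t[2].contig_id))
    return [
        CandidateMarker(
            marker_id=rep.contig_id,
            sequence=rep.sequence,
            cumulative_support=score,
            rank=i + 1,
            assemblies=tuple(sorted({c.assembly_id for c in g.members})),
            members=g.members,
        )
        for i, (score, _best, rep, g) in enumerate(scored)
    ]


def _right_tails(seq: str, reads: Sequence[str], min_overlap: int) -> list[str]:
    """Tails of reads whose prefix matches the 3' end of ``seq`` perfectly
    over >= min_overlap bases (either strand), and which extend past it."""
    tails = []
    for read in reads:
        for r in (read, revcomp(read)):
            top = min(len(seq), len(r) - 1)
            for ov in range(top, min_overlap - 1, -1):
                if seq.endswith(r[:ov]):
                    tails.append(r[ov:])
                    break
    return [t for t in tails if t]


def _extend_right(seq: str, reads: Sequence[str], min_overlap: int,
                  max_extension: int) -> str:
    added = 0
    while added < max_extension:
        tails = _right_tails(seq, reads, min_overlap)
        if not tails:
            break
        nxt = {t[0] for t in tails}
        if len(nxt) > 1:  # two candidate reads disagree: stop at the conflict
            break
        seq += nxt.pop()
        added += 1
    return seq


def extend_contig(
    sequence: str,
    reads: Sequence[str],
    min_overlap: int = 20,
    max_extension: int | None = None,
) -> str:
    """Greedily extend a contig at both ends using perfectly matching reads.

    A read (on either strand) whose prefix is 100 % identical to the
    contig's 3' end over at least ``min_overlap`` bases contributes its
    overhang; extension proceeds one base at a time and stops at the first
    position where two candidate reads disagree, or when no read reaches
    past the end.  The 5' end is extended symmetrically (via the reverse
    complement).  The output always contains the input as a substring.

    ``max_extension`` caps the total bases added per end (default: the
    summed read length), guarding against unbounded growth on periodic
    sequences.
    """
    _validate_seq(sequence, "contig")
    for r in reads:
        _validate_seq(r, "read")
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    if not reads:
        return sequence
    if max_extension is None:
        max_extension = sum(len(r) for r in reads)

    out = _extend_right(sequence, reads, min_overlap, max_extension)
    out = revcomp(_extend_right(revcomp(out), reads, min_overlap, max_extension))
    return out


def select_top(ranked: Sequence[CandidateMarker], k: int = 11, path=None) -> list[str]:
    """Export the top-k ranked markers as FASTA (all, if fewer exist).

    Headers carry rank, cumulative support and assembly provenance, and are
    byte-stable across reruns.  Returns the FASTA lines; writes them to
    ``path`` when given.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    top = list(ranked[:k])
    records = [
        SeqRecord(
            Seq(m.sequence),
            id=m.marker_id,
            description=f"rank={m.rank} support={m.cumulative_support} "
                        f"assemblies={','.join(m.assemblies)}",
        )
        for m in top
    ]
    from io import StringIO

    buf = StringIO()
    seqio_write(records, buf, "fasta")
    text = buf.getvalue()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text.splitlines()
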