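"""Block clustering of translated ORFs and consensus building.

Overlapping translated ORF fragments that plausibly come from one
protein are grouped into blocks: two ORFs are linked when an ends-free
(overlap) alignment shows identity of at least 95% over an overlap of at
least 10 residues, and blocks are the single-linkage (transitive)
closure of those links. Each block then yields a consensus sequence by
laying members out against each other and taking the per-column
majority residue, so that a substitution error carried by one fragment
is outvoted wherever coverage is >= 2.

Identity is computed over the overlap span of the alignment: the
columns between the first and the last column in which both sequences
have a residue. By default internal gap columns inside that span count
in the denominator (``count_gap_columns=False`` restricts the
denominator to doubly-occupied columns).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Optional, Sequence

from Bio import Align

from .peptide import Peptide


@dataclass(frozen=True)
class OrfRecord:
    id: str
    seq: Peptide
    source_contig: str = ""

    def __post_init__(self) -> None:
        if len(self.seq) == 0:
            raise ValueError(f"ORF {self.id!r} has an empty sequence")


@dataclass(frozen=True)
class OverlapParams:
    """Scoring for the ends-free overlap alignment."""

    match: float = 2.0
    mismatch: float = -2.0
    gap_open: float = 5.0
    gap_extend: float = 1.0
    count_gap_columns: bool = True

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be >= 0")


DEFAULT_OVERLAP_PARAMS = OverlapParams()


@dataclass(frozen=True)
class PairEvidence:
    id_a: str
    id_b: str
    identity: float
    overlap: int


@dataclass
class OrfCluster:
    cluster_id: str
    members: list[OrfRecord]
    evidence: list[PairEvidence]
    consensus: Optional[Peptide] = None
    diagnostics: list[str] = field(default_factory=list)

    @property
    def member_ids(self) -> list[str]:
        return [m.id for m in self.members]


def _overlap_aligner(params: OverlapParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    aligner.end_gap_score = 0.0
    return aligner


def _alignment_stats(a_seq: str, b_seq: str, params: OverlapParams):
    """(identity, overlap, offset) from the best ends-free alignment.

    overlap counts doubly-occupied columns; identity's denominator
    additionally counts internal gap columns inside the overlap span
    when ``count_gap_columns`` is set. offset is the position of b's
    start relative to a's start in the layout (may be negative).
    """
    aln = _overlap_aligner(params).align(a_seq, b_seq)[0]
    ga, gb = str(aln[0]), str(aln[1])
    both = [i for i in range(len(ga)) if ga[i] != "-" and gb[i] != "-"]
    if not both:
        return 0.0, 0, None
    lo, hi = both[0], both[-1]
    overlap = len(both)
    matches = sum(1 for i in both if ga[i] == gb[i])
    denom = (hi - lo + 1) if params.count_gap_columns else overlap
    # layout offset: residues of a and b consumed before the first
    # doubly-occupied column
    a_before = sum(1 for i in range(lo) if ga[i] != "-")
    b_before = sum(1 for i in range(lo) if gb[i] != "-")
    offset = a_before - b_before
    return matches / denom, overlap, offset


def overlap_identity(a: OrfRecord | Peptide, b: OrfRecord | Peptide,
                     params: OverlapParams = DEFAULT_OVERLAP_PARAMS,
                     ) -> tuple[float, int]:
    """Identity fraction and overlap length between two ORFs.

    Symmetric in its arguments; returns ``(0.0, 0)`` when the best
    ends-free alignment has no column with residues from both.
    """
    sa = a.seq.seq if isinstance(a, OrfRecord) else a.seq
    sb = b.seq.seq if isinstance(b, OrfRecord) else b.seq
    identity, overlap, _ = _alignment_stats(sa, sb, params)
    return identity, overlap


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def cluster_orfs(orfs: Sequence[OrfRecord],
                 id_threshold: float = 0.95,
                 min_overlap: int = 10,
                 params: OverlapParams = DEFAULT_OVERLAP_PARAMS,
                 build_consensus: bool = True) -> list[OrfCluster]:
    """Single-linkage clusters over the >= identity / >= overlap graph.

    Clusters are ordered by their lexicographically smallest member id;
    members keep input order. Raising either threshold can only split
    clusters, never merge them.
    """
    if not 0 < id_threshold <= 1:
        raise ValueError("id_threshold must be in (0, 1]")
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    ids = [o.id for o in orfs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate ORF ids")

    uf = _UnionFind(ids)
    edges: dict[str, list[PairEvidence]] = defaultdict(list)
    for i in range(len(orfs)):
        for j in range(i + 1, len(orfs)):
            identity, overlap = overlap_identity(orfs[i], orfs[j], params)
            if identity >= id_threshold and overlap >= min_overlap:
                uf.union(orfs[i].id, orfs[j].id)
                edges[orfs[i].id].append(
                    PairEvidence(orfs[i].id, orfs[j].id, identity, overlap))

    groups: dict[str, list[OrfRecord]] = defaultdict(list)
    for o in orfs:
        groups[uf.find(o.id)].append(o)

    clusters = []
    ordered = sorted(groups.values(), key=lambda ms: min(m.id for m in ms))
    for k, members in enumerate(ordered, start=1):
        member_ids = {m.id for m in members}
        evidence = [e for mid in member_ids for e in edges.get(mid, [])
                    if e.id_b in member_ids]
        cluster = OrfCluster(f"cluster{k}", members, evidence)
        if build_consensus:
            cluster.consensus = consensus(cluster, params)
        clusters.append(cluster)
    return clusters


def consensus(cluster: OrfCluster,
              params: OverlapParams = DEFAULT_OVERLAP_PARAMS) -> Peptide:
    """Majority consensus over a progressive overlap layout.

    Members are placed in order of decreasing length (ties by id): each
    next member is positioned by its ends-free alignment against the
    current draft. Per column the majority residue wins; ties go to the
    residue from the longest (earliest-placed) member. A member whose
    best alignment shares no overlap with the draft is skipped with a
    diagnostic, so the consensus covers the largest consistent subset.
    """
    if not cluster.members:
        raise ValueError("cannot build a consensus of an empty cluster")
    members = sorted(cluster.members, key=lambda m: (-len(m.seq), m.id))
    if len(members) == 1:
        return Peptide(f"{cluster.cluster_id}_consensus", members[0].seq.seq)

    # votes[column] -> list of (rank, residue); columns may go negative
    votes: dict[int, list[tuple[int, str]]] = defaultdict(list)
    draft: dict[int, str] = {}  # column -> residue of earliest-placed member

    def place(member: OrfRecord, rank: int, offset: int) -> None:
        for i, ch in enumerate(member.seq.seq):
            col = offset + i
            votes[col].append((rank, ch))
            draft.setdefault(col, ch)

    place(members[0], 0, 0)
    for rank, member in enumerate(members[1:], start=1):
        cols = sorted(draft)
        draft_seq = "".join(draft[c] for c in cols)
        _, overlap, rel = _alignment_stats(draft_seq, member.seq.seq, params)
        if overlap == 0 or rel is None:
            cluster.diagnostics.append(
                f"{member.id}: no consistent overlap with layout; skipped")
            continue
        place(member, rank, cols[0] + rel)

    out = []
    for col in sorted(votes):
        tally: dict[str, int] = defaultdict(int)
        best_rank: dict[str, int] = {}
        for rank, ch in votes[col]:
            tally[ch] += 1
            best_rank[ch] = min(best_rank.get(ch, rank), rank)
        out.append(max(tally, key=lambda ch: (tally[ch], -best_rank[ch])))
    return Peptide(f"{cluster.cluster_id}_consensus", "".join(out))


def min_orf_length_filter(orfs: Sequence[OrfRecord], mrna_len: int,
                          min_fraction: float = 0.2) -> list[OrfRecord]:
    """Keep ORFs covering at least ``min_fraction`` of the mRNA length.

    Optional pre-filter mirroring the coding-sequence length rule used
    when ORFs are called from contigs; lengths are compared in residues
    against ``mrna_len`` in codons.
    """
    cutoff = min_fraction * mrna_len
    return [o for o in orfs if len(o.seq) >= cutoff]
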