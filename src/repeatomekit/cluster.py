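"""Desk-scale greedy identity clustering of repeat consensus sequences.

Mirrors the CD-HIT(-est) procedure used to group unclassified repeat
families: sequences are sorted longest-first, and each joins the first
existing cluster whose representative it matches at or above the identity
threshold (first-fit), otherwise it founds a new cluster. Identity is the
number of matched bases in an optimal global alignment divided by the
length of the shorter sequence — CD-HIT's convention for low thresholds —
and, because repeat consensi are strandless, the reverse complement is
tried as well and the better identity kept.

Alignment is exact dynamic programming (match +1, mismatch -1, gap -2, end
gaps penalized), maximizing score and, among optimal-score alignments, the
match count. No k-mer prefilter is used, so inputs are capped at 500
sequences of at most 5 kb each; genome-scale clustering is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Cluster",
    "pairwise_identity",
    "greedy_cluster",
    "write_clstr",
    "cluster_table",
]

MAX_SEQUENCES = 500
MAX_SEQ_LEN = 5000

_MATCH, _MISMATCH, _GAP = 1, -1, -2

_COMPLEMENT = str.maketrans("ACGTRYKMBVDHacgtrykmbvdh", "TGCAYRMKVBHDtgcayrmkvbhd")


@dataclass
class Cluster:
    """One identity cluster: the representative (longest member) and all
    members with their identity to it."""

    representative: str
    members: list[tuple[str, float]]

    @property
    def size(self) -> int:
        return len(self.members)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _align_matches(a: str, b: str) -> int:
    """Match count of the best global alignment of ``a`` and ``b``.

    Needleman-Wunsch over (score, matches) tuples: both components are
    additive along an alignment path, so the lexicographic maximum is a
    valid DP objective and returns the maximal match count among
    optimal-score alignments.
    """
    n, m = len(a), len(b)
    prev = [(j * _GAP, 0) for j in range(m + 1)]
    for i in range(1, n + 1):
        ai = a[i - 1]
        cur = [(i * _GAP, 0)]
        for j in range(1, m + 1):
            is_match = 1 if ai == b[j - 1] else 0
            ds, dm = prev[j - 1]
            diag = (ds + (_MATCH if is_match else _MISMATCH), dm + is_match)
            us, um = prev[j]
            up = (us + _GAP, um)
            ls, lm = cur[j - 1]
            left = (ls + _GAP, lm)
            cur.append(max(diag, up, left))
        prev = cur
    return prev[m][1]


def pairwise_identity(a: str, b: str, both_strands: bool = True) -> float:
    """Global-alignment identity between two sequences, in [0, 1].

    Identity = matched bases / length of the shorter sequence (capped at 1).
    With ``both_strands`` the reverse complement of ``b`` is also aligned
    and the larger identity returned.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    if len(a) > MAX_SEQ_LEN or len(b) > MAX_SEQ_LEN:
        raise ValueError(f"sequences longer than {MAX_SEQ_LEN} bp are not supported")
    au, bu = a.upper(), b.upper()
    matches = _align_matches(au, bu)
    if both_strands:
        matches = max(matches, _align_matches(au, reverse_complement(bu)))
    return min(1.0, matches / min(len(a), len(b)))


def greedy_cluster(
    sequences: Mapping[str, str] | Iterable[tuple[str, str]],
    threshold: float = 0.5,
    both_strands: bool = True,
) -> list[Cluster]:
    """First-fit greedy clustering at an identity threshold (default 50%).

    Sequences are processed longest-first (ties broken by name) and each is
    compared against existing cluster representatives in creation order,
    joining the first with identity >= threshold. The result is a partition
    whose representatives are the longest members of their clusters, and it
    is invariant to the input order.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    items = list(sequences.items()) if isinstance(sequences, Mapping) else list(sequences)
    names = [name for name, _ in items]
    if len(set(names)) != len(names):
        raise ValueError("sequence names must be unique")
    if len(items) > MAX_SEQUENCES:
        raise ValueError(f"more than {MAX_SEQUENCES} sequences; genome-scale clustering is out of scope")
    for name, seq in items:
        if not seq:
            raise ValueError(f"sequence {name!r} is empty")
        if len(seq) > MAX_SEQ_LEN:
            raise ValueError(f"sequence {name!r} exceeds {MAX_SEQ_LEN} bp")

    items.sort(key=lambda kv: (-len(kv[1]), kv[0]))
    clusters: list[Cluster] = []
    reps: list[str] = []  # representative sequences, creation order
    for name, seq in items:
        placed = False
        for cluster, rep_seq in zip(clusters, reps):
            ident = pairwise_identity(rep_seq, seq, both_strands=both_strands)
            if ident >= threshold:
                cluster.members.append((name, ident))
                placed = True
                break
        if not placed:
            clusters.append(Cluster(representative=name, members=[(name, 1.0)]))
            reps.append(seq)
    return clusters


def write_clstr(clusters: Sequence[Cluster], lengths: Mapping[str, int]) -> str:
    """CD-HIT ``.clstr``-style listing of the clusters."""
    lines = []
    for idx, cluster in enumerate(clusters):
        lines.append(f">Cluster {idx}")
        for member_idx, (name, ident) in enumerate(cluster.members):
            entry = f"{member_idx}\t{lengths[name]}nt, >{name}..."
            if name == cluster.representative:
                lines.append(f"{entry} *")
            else:
                lines.append(f"{entry} at {100 * ident:.2f}%")
    return "\n".join(lines) + "\n"


def cluster_table(clusters: Sequence[Cluster]) -> str:
    """TSV: cluster_id, member, identity to representative, is_representative."""
    lines = ["cluster_id\tmember\tidentity\tis_representative"]
    for idx, cluster in enumerate(clusters):
        for name, ident in cluster.members:
            is_rep = int(name == cluster.representative)
            lines.append(f"{idx}\t{name}\t{ident:.4f}\t{is_rep}")
    return "\n".join(lines) + "\n"
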