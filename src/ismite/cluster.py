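"""Greedy centroid clustering of candidate sequences.

Identity between two sequences is computed from one optimal global
alignment under a simple scheme (match +1, mismatch -1, gap -1, no affine
gaps) as matches / alignment columns. Clustering processes sequences
longest-first (ties broken by id) and assigns each sequence to the first
centroid it matches at or above the identity threshold, else it founds a new
cluster. The 0.9 default threshold is the historical default of greedy
centroid clusterers used for this task.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .seqio import SequenceRecord, reverse_complement


@dataclass(frozen=True)
class ClusterParams:
    identity_threshold: float = 0.9
    alphabet: str = "nt"

    def __post_init__(self):
        if not (0.0 < self.identity_threshold <= 1.0):
            raise ValueError("identity_threshold must be in (0, 1]")


@dataclass
class Cluster:
    centroid: SequenceRecord
    members: list  # list of (SequenceRecord, identity)


@njit(cache=True)
def _nw_identity(a, b):  # pragma: no cover
    """Global alignment (+1/-1/-1); returns (matches, alignment_columns).

    Ties between equal-score alignments are resolved deterministically by
    maximising (score, matches, -columns) lexicographically, all three
    being additive along an alignment path.
    """
    n, m = a.shape[0], b.shape[0]
    S = np.empty((n + 1, m + 1), dtype=np.int32)
    M = np.zeros((n + 1, m + 1), dtype=np.int32)
    C = np.zeros((n + 1, m + 1), dtype=np.int32)
    S[0, 0] = 0
    for i in range(1, n + 1):
        S[i, 0] = -i
        C[i, 0] = i
    for j in range(1, m + 1):
        S[0, j] = -j
        C[0, j] = j
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            eq = 1 if ai == b[j - 1] else 0
            ds = S[i - 1, j - 1] + (1 if eq == 1 else -1)
            dm = M[i - 1, j - 1] + eq
            us = S[i - 1, j] - 1
            um = M[i - 1, j]
            ls = S[i, j - 1] - 1
            lm = M[i, j - 1]
            bs, bm, bc = ds, dm, C[i - 1, j - 1] + 1
            if us > bs or (us == bs and (um > bm or (um == bm and C[i - 1, j] + 1 < bc))):
                bs, bm, bc = us, um, C[i - 1, j] + 1
            if ls > bs or (ls == bs and (lm > bm or (lm == bm and C[i, j - 1] + 1 < bc))):
                bs, bm, bc = ls, lm, C[i, j - 1] + 1
            S[i, j] = bs
            M[i, j] = bm
            C[i, j] = bc
    return M[n, m], C[n, m]


def _codes(s: str) -> np.ndarray:
    return np.frombuffer(s.encode("ascii"), dtype=np.uint8).astype(np.int16)


def pairwise_identity(a: SequenceRecord, b: SequenceRecord) -> float:
    """Fraction of matching columns in one optimal global alignment of a, b."""
    if a.alphabet != b.alphabet:
        raise ValueError("mixed alphabets")
    if not a.seq or not b.seq:
        raise ValueError("empty sequence")
    if a.seq == b.seq:
        return 1.0
    matches, cols = _nw_identity(_codes(a.seq), _codes(b.seq))
    return matches / cols


def strand_identity(a: SequenceRecord, b: SequenceRecord) -> float:
    """Identity ignoring strand: the better of forward and reverse complement."""
    ident = pairwise_identity(a, b)
    if a.alphabet == "nt" and ident < 1.0:
        rc = SequenceRecord(a.id, reverse_complement(a.seq), "nt")
        ident = max(ident, pairwise_identity(rc, b))
    return ident


def greedy_cluster(
    seqs: list[SequenceRecord], params: ClusterParams = ClusterParams()
) -> list[Cluster]:
    """Greedy centroid clustering, longest-first, deterministic.

    Nucleotide sequences join a cluster on either strand (element copies
    come in both orientations). Input order is canonicalised internally, so
    permuting the input does not change the result.
    """
    if not seqs:
        return []
    if len({s.alphabet for s in seqs}) > 1:
        raise ValueError("mixed alphabets in clustering input")
    ordered = sorted(seqs, key=lambda s: (-len(s.seq), s.id))
    clusters: list[Cluster] = []
    for s in ordered:
        placed = False
        for cl in clusters:
            ident = strand_identity(s, cl.centroid)
            if ident >= params.identity_threshold:
                cl.members.append((s, ident))
                placed = True
                break
        if not placed:
            clusters.append(Cluster(centroid=s, members=[(s, 1.0)]))
    return clusters
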