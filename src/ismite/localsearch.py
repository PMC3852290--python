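"""Seeded local-alignment search with Karlin-Altschul E-values.

Two modes are provided: nucleotide query vs nucleotide genome (``nt``,
match +1 / mismatch -2, affine gaps -5 open / -2 extend, word size 11) and
six-frame-translated nucleotide query vs a protein library (``tx``,
BLOSUM62, gaps -11 open / -1 extend, word size 4). Candidate regions are
located by exact word seeds and scored by a full affine-gap Smith-Waterman
on the candidate window, so every reported hit score equals the local-DP
optimum of its region.

E-values follow E = K * m * n * exp(-lambda * S). lambda is the positive
root of the Karlin sum  sum_ij p_i p_j exp(lambda * s_ij) = 1 at uniform
residue frequencies; for gapped alignment we apply the documented empirical
correction lambda_gapped = 0.9 * lambda_ungapped with K unchanged. K is a
fixed per-mode constant (nt 0.62, tx 0.04) of the usual order of magnitude
for these schemes; the E-value threshold semantics, not tool-exact
statistics, are what the pipelines rely on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from numba import njit
from scipy.optimize import brentq

from .seqio import SequenceRecord, reverse_complement, six_frame_translate

AA_ORDER = "ARNDCQEGHILKMFPSTWYVBZX*"


def karlin_lambda(scores: np.ndarray, probs: np.ndarray) -> float:
    """Positive root of sum_ij p_i p_j exp(lambda*s_ij) = 1.

    ``scores`` is a square matrix, ``probs`` the residue frequencies. The
    expected pair score must be negative and at least one score positive.
    """
    p = np.asarray(probs, dtype=float)
    s = np.asarray(scores, dtype=float)
    w = np.outer(p, p)
    if float((w * s).sum()) >= 0:
        raise ValueError("expected score per aligned pair must be negative")
    if s.max() <= 0:
        raise ValueError("no positive score")

    def f(lam):
        return float((w * np.exp(lam * s)).sum()) - 1.0

    hi = 0.5
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e4:
            raise RuntimeError("lambda bracket failed")
    return float(brentq(f, 1e-9, hi, xtol=1e-12))


@lru_cache(maxsize=None)
def _blosum62():
    from Bio.Align import substitution_matrices

    m = substitution_matrices.load("BLOSUM62")
    mat = np.full((25, 25), -4.0)
    idx = {a: i for i, a in enumerate(AA_ORDER)}
    for a in AA_ORDER:
        for b in AA_ORDER:
            if (a, b) in m:
                mat[idx[a], idx[b]] = m[a, b]
    return mat


def _nt_matrix(match: int, mismatch: int) -> np.ndarray:
    mat = np.full((5, 5), float(mismatch))
    for i in range(4):
        mat[i, i] = float(match)
    mat[4, :] = mat[:, 4] = float(mismatch)  # N never matches
    return mat


@dataclass(frozen=True, eq=False)
class ScoringScheme:
    mode: str  # "nt" or "tx"
    matrix: np.ndarray = field(repr=False)
    gap_open: int
    gap_extend: int
    K: float
    lam: float  # gapped lambda actually used in E-values
    word: int

    @staticmethod
    def nt(match: int = 1, mismatch: int = -2, gap_open: int = -5, gap_extend: int = -2,
           K: float = 0.62) -> "ScoringScheme":
        mat = _nt_matrix(match, mismatch)
        lam_u = karlin_lambda(mat[:4, :4], np.full(4, 0.25))
        return ScoringScheme("nt", mat, gap_open, gap_extend, K, 0.9 * lam_u, word=11)

    @staticmethod
    def tx(gap_open: int = -11, gap_extend: int = -1, K: float = 0.04) -> "ScoringScheme":
        mat = _blosum62()
        lam_u = karlin_lambda(mat[:20, :20], np.full(20, 0.05))
        return ScoringScheme("tx", mat, gap_open, gap_extend, K, 0.9 * lam_u, word=4)

    def bitscore(self, score: float) -> float:
        return (self.lam * score - math.log(self.K)) / math.log(2.0)


def karlin_evalue(score: float, m: int, n: int, scheme: ScoringScheme) -> float:
    """E = K * m * n * exp(-lambda * S)."""
    if m <= 0 or n <= 0:
        raise ValueError("search-space sizes must be positive")
    return scheme.K * m * n * math.exp(-scheme.lam * score)


@dataclass(frozen=True)
class AlignmentHit:
    query_id: str
    target_id: str
    query_span: tuple[int, int]
    target_span: tuple[int, int]
    frame: int  # nt mode: +1 / -1 strand; tx mode: +-1..3
    score: int
    bitscore: float
    evalue: float
    identity: float
    aln_len: int


@njit(cache=True)
def _sw_kernel(a, b, subst, gap_open, gap_extend):  # pragma: no cover
    """Affine-gap Smith-Waterman with traceback.

    Returns (score, a_start, a_end, b_start, b_end, matches, columns) of one
    optimal local alignment (ties resolved toward the smallest end cell,
    diagonal moves preferred in traceback).
    """
    n, m = a.shape[0], b.shape[0]
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    E = np.full((n + 1, m + 1), -10**7, dtype=np.int32)
    F = np.full((n + 1, m + 1), -10**7, dtype=np.int32)
    ptr = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 0 stop, 1 diag, 2 left(E), 3 up(F)
    pe = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 1 = E extends
    pf = np.zeros((n + 1, m + 1), dtype=np.uint8)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            eo = H[i, j - 1] + gap_open
            ee = E[i, j - 1] + gap_extend
            if ee > eo:
                E[i, j] = ee
                pe[i, j] = 1
            else:
                E[i, j] = eo
            fo = H[i - 1, j] + gap_open
            fe = F[i - 1, j] + gap_extend
            if fe > fo:
                F[i, j] = fe
                pf[i, j] = 1
            else:
                F[i, j] = fo
            d = H[i - 1, j - 1] + np.int32(subst[ai, b[j - 1]])
            h = 0
            p = 0
            if d > h:
                h = d
                p = 1
            if E[i, j] > h:
                h = E[i, j]
                p = 2
            if F[i, j] > h:
                h = F[i, j]
                p = 3
            H[i, j] = h
            ptr[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
    # traceback
    i, j = bi, bj
    matches = 0
    cols = 0
    state = 0  # 0 = H, 2 = E, 3 = F
    while i > 0 and j > 0:
        if state == 0:
            p = ptr[i, j]
            if p == 0:
                break
            if p == 1:
                cols += 1
                if a[i - 1] == b[j - 1]:
                    matches += 1
                i -= 1
                j -= 1
            elif p == 2:
                state = 2
            else:
                state = 3
        elif state == 2:
            cols += 1
            ext = pe[i, j]
            j -= 1
            if ext == 0:
                state = 0
        else:
            cols += 1
            ext = pf[i, j]
            i -= 1
            if ext == 0:
                state = 0
    return best, i, bi, j, bj, matches, cols


def _seed_regions(qcode, tcode, word, merge_dist=2000, band=64):
    """Exact-word seeds -> merged (t_lo, t_hi) candidate windows."""
    nq, nt_ = qcode.shape[0], tcode.shape[0]
    if nq < word or nt_ < word:
        return []
    index: dict[bytes, list[int]] = {}
    qb = qcode.tobytes()
    for q in range(nq - word + 1):
        w = qb[q : q + word]
        index.setdefault(w, []).append(q)
    tb = tcode.tobytes()
    spans = []
    for t in range(nt_ - word + 1):
        hits = index.get(tb[t : t + word])
        if hits:
            for q in hits:
                lo = max(0, t - q - band)
                hi = min(nt_, t + (nq - q) + band)
                spans.append((lo, hi))
    if not spans:
        return []
    spans.sort()
    merged = [list(spans[0])]
    for lo, hi in spans[1:]:
        if lo <= merged[-1][1] + merge_dist // 4:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return [(lo, hi) for lo, hi in merged]


_NT_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _NT_CODE[ord(_b)] = _i
_AA_CODE = np.full(256, AA_ORDER.index("X"), dtype=np.int8)
for _i, _a in enumerate(AA_ORDER):
    _AA_CODE[ord(_a)] = _i


def _enc(seq: str, mode: str) -> np.ndarray:
    raw = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    return (_NT_CODE if mode == "nt" else _AA_CODE)[raw]


def _prune_redundant(hits: list[AlignmentHit]) -> list[AlignmentHit]:
    """Drop hits whose query and target spans lie inside a better hit."""
    hits = sorted(hits, key=lambda h: (h.evalue, -h.score, h.target_span, h.query_span))
    kept: list[AlignmentHit] = []
    for h in hits:
        contained = False
        for k in kept:
            if (
                k.frame == h.frame
                and k.target_id == h.target_id
                and k.query_span[0] <= h.query_span[0]
                and h.query_span[1] <= k.query_span[1]
                and k.target_span[0] <= h.target_span[0]
                and h.target_span[1] <= k.target_span[1]
            ):
                contained = True
                break
        if not contained:
            kept.append(h)
    return kept


def search_nt(
    query: SequenceRecord,
    genome: SequenceRecord,
    evalue_max: float = 1e-5,
    scheme: ScoringScheme | None = None,
) -> list[AlignmentHit]:
    """Find local alignments of ``query`` in ``genome`` on both strands."""
    if scheme is None:
        scheme = ScoringScheme.nt()
    if query.alphabet != "nt" or genome.alphabet != "nt":
        raise ValueError("search_nt requires nucleotide sequences")
    tcode = _enc(genome.seq, "nt")
    m, n = len(query.seq), len(genome.seq)
    hits: list[AlignmentHit] = []
    for strand, qseq in ((1, query.seq), (-1, reverse_complement(query.seq))):
        qcode = _enc(qseq, "nt")
        # a merged window can hold several element copies; after aligning,
        # recurse into the target flanks outside the alignment
        stack = list(_seed_regions(qcode, tcode, scheme.word))
        while stack:
            lo, hi = stack.pop()
            if hi - lo < scheme.word:
                continue
            score, qs, qe, ts, te, matches, cols = _sw_kernel(
                qcode, tcode[lo:hi], scheme.matrix, scheme.gap_open, scheme.gap_extend
            )
            if score <= 0 or cols == 0:
                continue
            ev = karlin_evalue(score, m, n, scheme)
            if ev > evalue_max:
                continue
            if strand == 1:
                qspan = (qs, qe)
            else:
                qspan = (m - qe, m - qs)
            hits.append(
                AlignmentHit(
                    query.id, genome.id, qspan, (lo + ts, lo + te), strand,
                    int(score), scheme.bitscore(score), ev,
                    matches / cols, cols,
                )
            )
            if ts > 0:
                stack.append((lo, lo + ts))
            if lo + te < hi:
                stack.append((lo + te, hi))
    return _prune_redundant(hits)


def search_translated(
    query: SequenceRecord,
    proteins: list[SequenceRecord],
    evalue_max: float = 1e-5,
    scheme: ScoringScheme | None = None,
    table: int = 11,
) -> list[AlignmentHit]:
    """Search all six frame translations of ``query`` against a protein library.

    Query spans are reported in nucleotide coordinates on the input query;
    ``frame`` records the translation frame of the hit.
    """
    if scheme is None:
        scheme = ScoringScheme.tx()
    if query.alphabet != "nt":
        raise ValueError("query must be nucleotide")
    if not proteins:
        return []
    frames = six_frame_translate(query.seq, table=table, segment_ref=query.id)
    db_len = sum(len(p.seq) for p in proteins)
    qlen = len(query.seq)
    hits: list[AlignmentHit] = []
    for fr in frames:
        if len(fr.peptide) < scheme.word:
            continue
        pcode = _enc(fr.peptide, "aa")
        for prot in proteins:
            dcode = _enc(prot.seq, "aa")
            if not _seed_regions(pcode, dcode, scheme.word, band=10**9):
                continue
            score, qs, qe, ts, te, matches, cols = _sw_kernel(
                pcode, dcode, scheme.matrix, scheme.gap_open, scheme.gap_extend
            )
            if score <= 0 or cols == 0:
                continue
            ev = karlin_evalue(score, len(fr.peptide), db_len, scheme)
            if ev > evalue_max:
                continue
            # peptide -> nucleotide coordinates on the original query
            off = fr.nt_offset
            if fr.frame > 0:
                nt_s = off + 3 * qs
                nt_e = off + 3 * qe
            else:
                nt_s = qlen - (off + 3 * qe)
                nt_e = qlen - (off + 3 * qs)
            hits.append(
                AlignmentHit(
                    query.id, prot.id, (nt_s, nt_e), (ts, te), fr.frame,
                    int(score), scheme.bitscore(score), ev,
                    matches / cols, cols,
                )
            )
    return _prune_redundant(hits)


def hits_to_rows(hits: list[AlignmentHit]) -> list[dict]:
    """Fixed-order tabular form of a hit list."""
    return [
        {
            "query_id": h.query_id,
            "target_id": h.target_id,
            "pct_identity": round(100.0 * h.identity, 2),
            "aln_len": h.aln_len,
            "q_start": h.query_span[0],
            "q_end": h.query_span[1],
            "t_start": h.target_span[0],
            "t_end": h.target_span[1],
            "frame": h.frame,
            "bitscore": round(h.bitscore, 2),
            "evalue": h.evalue,
        }
        for h in hits
    ]
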