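"""Inverted-repeat (IR) detection and IR-delimited candidate extraction.

An IR pair is two arms of equal length on the same sequence such that the
right arm is the reverse complement of the left arm at all but a bounded
number of positions. Pairing is naturally indexed by the anti-diagonal
``c = x + y`` of the base-pair matrix: left-arm position ``x`` pairs with
right-arm position ``y = c - x``. An arm window must

* start and end on matching base pairs (no terminal mismatches),
* contain at most ``max_mismatch`` mismatching pairs (an N counts as a
  mismatch, so an arm can never be anchored on an N),
* have arm length within ``[min_arm, max_arm]``,
* have a non-negative spacer (gap) no longer than ``max_gap``.

A valid window is reported iff it is *maximal*: not properly contained in
another valid window on the same diagonal. This is the testable contract the
brute-force oracle in the test-suite enumerates directly.

Default parameters follow the common IS search settings: arms of 10-50 nt,
spacer up to 2 kb, at most 2 mismatches.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .seqio import SequenceRecord, reverse_complement

_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def encode(seq: str) -> np.ndarray:
    """Encode A,C,G,T -> 0..3; anything else (incl. N) -> 4."""
    return _CODE[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class IRParams:
    min_arm: int = 10
    max_arm: int = 50
    max_gap: int = 2000
    max_mismatch: int = 2

    def __post_init__(self):
        if not (0 < self.min_arm <= self.max_arm):
            raise ValueError("require 0 < min_arm <= max_arm")
        if self.max_gap < 0 or self.max_mismatch < 0:
            raise ValueError("max_gap and max_mismatch must be >= 0")


@dataclass(frozen=True)
class IRPair:
    """One inverted-repeat pair; intervals are 0-based half-open."""

    seq_id: str
    left: tuple[int, int]
    right: tuple[int, int]
    arm_len: int
    mismatches: int

    @property
    def span(self) -> tuple[int, int]:
        return (self.left[0], self.right[1])


@dataclass(frozen=True)
class IRCandidate:
    """The sequence delimited by (and including) an IR pair."""

    seq_id: str
    span: tuple[int, int]
    seq: str


@njit(cache=True)
def _find_pairs_kernel(code, min_arm, max_arm, max_gap, max_mismatch):  # pragma: no cover
    n = code.shape[0]
    cap = 1024
    out = np.empty((cap, 4), dtype=np.int64)  # a, b, c, mismatches
    m = 0
    pos = np.empty(max_arm + max_gap // 2 + 2, dtype=np.int64)
    for c in range(1, 2 * n - 2):
        b_hi = (c - 1) // 2
        if b_hi < 0:
            continue
        # smallest b with gap = c-1-2b <= max_gap, i.e. ceil((c-1-max_gap)/2)
        b_min = (c - max_gap) // 2
        a_lo = b_min - (max_arm - 1)
        if a_lo < 0:
            a_lo = 0
        if a_lo < c - (n - 1):
            a_lo = c - (n - 1)
        if b_hi - a_lo + 1 < min_arm:
            continue
        # collect matching pair positions on this diagonal
        k = 0
        for x in range(a_lo, b_hi + 1):
            cx = code[x]
            cy = code[c - x]
            if cx < 4 and cy < 4 and cx + cy == 3:
                pos[k] = x
                k += 1
        if k == 0:
            continue
        jmax = 0
        for i in range(k):
            if jmax < i:
                jmax = i
            # advance frontier: largest j with mm <= max_mismatch, len <= max_arm
            while jmax + 1 < k:
                length = pos[jmax + 1] - pos[i] + 1
                mm = (pos[jmax + 1] - pos[i]) - (jmax + 1 - i)
                if length > max_arm or mm > max_mismatch:
                    break
                jmax += 1
            b = pos[jmax]
            length = b - pos[i] + 1
            if length < min_arm or b < b_min:
                continue
            # maximal iff one-step left extension is impossible
            if i > 0:
                a2 = pos[i - 1]
                if a2 >= a_lo:
                    len2 = b - a2 + 1
                    mm2 = (b - a2) - (jmax - (i - 1))
                    if len2 <= max_arm and mm2 <= max_mismatch:
                        continue
            if m == cap:
                cap *= 2
                out2 = np.empty((cap, 4), dtype=np.int64)
                out2[:m] = out
                out = out2
            mm = (b - pos[i]) - (jmax - i)
            out[m, 0] = pos[i]
            out[m, 1] = b
            out[m, 2] = c
            out[m, 3] = mm
            m += 1
    return out[:m]


def find_inverted_repeats(rec: SequenceRecord, params: IRParams = IRParams()) -> list[IRPair]:
    """All maximal IR pairs of ``rec`` under ``params``.

    Deterministic; sorted by left-arm start, then total span length, then
    right-arm start.
    """
    if rec.alphabet != "nt":
        raise ValueError("IR detection requires a nucleotide sequence")
    code = encode(rec.seq)
    if code.shape[0] < 2 * params.min_arm:
        return []
    raw = _find_pairs_kernel(
        code, params.min_arm, params.max_arm, params.max_gap, params.max_mismatch
    )
    pairs = []
    for a, b, c, mm in raw:
        left = (int(a), int(b) + 1)
        right = (int(c - b), int(c - a) + 1)
        pairs.append(
            IRPair(rec.id, left, right, arm_len=int(b - a + 1), mismatches=int(mm))
        )
    pairs.sort(key=lambda p: (p.left[0], p.right[1] - p.left[0], p.right[0]))
    return pairs


def extract_ir_candidates(rec: SequenceRecord, pairs: list[IRPair]) -> list[IRCandidate]:
    """Extract the sequence delimited by each IR pair, arms included.

    Candidates with identical spans are deduplicated.
    """
    seen = set()
    out = []
    for p in pairs:
        if p.seq_id != rec.id:
            raise ValueError(f"IR pair from {p.seq_id!r} applied to {rec.id!r}")
        s, e = p.left[0], p.right[1]
        if not (0 <= s < e <= len(rec.seq)):
            raise ValueError("IR pair coordinates outside sequence")
        if (s, e) in seen:
            continue
        seen.add((s, e))
        out.append(IRCandidate(rec.id, (s, e), rec.seq[s:e]))
    return out


def _exact_count(hay: str, needle: str) -> int:
    n = 0
    i = hay.find(needle)
    while i != -1:
        n += 1
        i = hay.find(needle, i + 1)
    return n


def genome_kmer_positions(genome: str, k: int = 13) -> dict:
    """Forward-strand k-mer -> list of start positions."""
    index: dict[str, list[int]] = {}
    for i in range(len(genome) - k + 1):
        index.setdefault(genome[i : i + k], []).append(i)
    return index


def count_occurrences(
    candidate: str,
    genome: SequenceRecord,
    identity: float = 0.9,
    index: dict | None = None,
    min_needed: int = 2,
    return_loci: bool = False,
    terminal_window: int = 0,
    self_span: tuple[int, int] | None = None,
):
    """Number of genomic occurrences of ``candidate`` at >= ``identity``.

    An occurrence is a genome locus where the candidate (or its reverse
    complement) aligns end-to-end with edit distance at most
    ``(1 - identity) * len(candidate)``. Putative loci are anchored by the
    candidate's 13-mers through a forward-strand position index (a copy at
    >= 90% identity necessarily shares anchors), then each locus is verified
    by a banded infix edit-distance alignment on a short window. Counting
    stops once ``min_needed`` is reached.

    ``terminal_window`` > 0 additionally requires both terminal windows of
    that length to match at >= 80% identity: copies of an IR-delimited
    element share their terminal arms, whereas a chance arm pair offset
    into the flank of a repeated element does not.
    """
    import edlib

    k = 13
    L = len(candidate)
    if L < k:
        n = _exact_count(genome.seq, candidate)
        return (n, []) if return_loci else n
    if index is None:
        index = genome_kmer_positions(genome.seq, k)
    rc = reverse_complement(candidate)
    max_dist = int((1.0 - identity) * L)
    pad = max_dist + 20
    counted: list[tuple[int, int]] = []
    loci_out: list = []
    count = 0
    if self_span is not None:
        # the candidate is itself a genome substring: count its locus for free
        count = 1
        counted.append(self_span)
        loci_out.append((self_span[0], self_span[1], "+", 0))
        if count >= min_needed:
            return (count, loci_out) if return_loci else count
    step = 5
    for query in ([candidate] if rc == candidate else [candidate, rc]):
        # anchor = implied copy start for each shared k-mer
        anchors: dict[int, int] = {}
        for i in range(0, L - k + 1, step):
            for p in index.get(query[i : i + k], ()):
                anchors[p - i] = anchors.get(p - i, 0) + 1
        if not anchors:
            continue
        # cluster anchors into loci (indels shift anchors slightly)
        gap = max(16, max_dist)
        clusters: list[list[int]] = []
        weight: list[int] = []
        for a in sorted(anchors):
            if clusters and a - clusters[-1][-1] <= gap:
                clusters[-1].append(a)
                weight[-1] += anchors[a]
            else:
                clusters.append([a])
                weight.append(anchors[a])
        order = sorted(range(len(clusters)), key=lambda i: -weight[i])
        for ci in order[: max(6, 3 * min_needed)]:
            cl = clusters[ci]
            lo = max(0, cl[0] - pad)
            hi = min(len(genome.seq), cl[-1] + L + pad)
            if any(min(hi, e) - max(lo, s) > 0.5 * L for s, e in counted):
                continue  # locus already counted (e.g. palindromic overlap)
            res = edlib.align(
                query, genome.seq[lo:hi], mode="HW", task="locations", k=max_dist
            )
            if res["editDistance"] >= 0 and terminal_window > 0:
                w = min(terminal_window, L // 2)
                thr = max(1, int(0.2 * w))
                t = genome.seq[lo:hi]
                s, e = res["locations"][0]
                head = edlib.align(query[:w], t[s : s + w], mode="NW")
                tail = edlib.align(query[-w:], t[max(0, e + 1 - w) : e + 1], mode="NW")
                if head["editDistance"] > thr or tail["editDistance"] > thr:
                    counted.append((lo, hi))  # locus seen but not a copy
                    continue
            if res["editDistance"] >= 0:
                count += 1
                counted.append((lo, hi))
                s, e = res["locations"][0]
                loci_out.append(
                    (lo + s, lo + e + 1, "+" if query is candidate else "-",
                     int(res["editDistance"]))
                )
                if count >= min_needed:
                    return (count, loci_out) if return_loci else count
    return (count, loci_out) if return_loci else count


def filter_fragments(
    candidates: list[IRCandidate],
    genome: SequenceRecord,
    index: dict | None = None,
    min_copies: int = 2,
    pad: int = 30,
    flank_identity: float = 0.7,
) -> list[IRCandidate]:
    """Drop candidates that are internal fragments of a larger repeated unit.

    A true IR-delimited element ends where the repeat ends: the sequences
    flanking its genomic copies are unrelated (the target-site duplication
    varies per copy). When >= ``min_copies`` copies share near-identical
    ``pad``-base flanks on either side, that boundary lies strictly inside
    a longer repeated sequence — the candidate is a chance arm pair within
    a repeated element, not the element itself — and it is discarded.
    """
    import edlib

    if index is None:
        index = genome_kmer_positions(genome.seq) if candidates else {}
    g = genome.seq

    def close(a: str, b: str) -> bool:
        if len(a) < pad or len(b) < pad:
            return False  # genome edge: treat as unconserved
        r = edlib.align(a, b, mode="NW")
        return r["editDistance"] <= (1 - flank_identity) * max(len(a), len(b))

    out = []
    for c in candidates:
        _, loci = count_occurrences(
            c.seq, genome, 0.9, index, min_needed=max(min_copies, 4),
            return_loci=True, terminal_window=20, self_span=c.span,
        )
        s0, e0 = c.span
        lf0, rf0 = g[max(0, s0 - pad) : s0], g[e0 : e0 + pad]
        cons_left = cons_right = 1  # the candidate's own locus
        both_extend = 0
        for s, e, st, _d in loci:
            if min(e, e0) - max(s, s0) > 0.5 * (e0 - s0):
                continue  # self locus
            if st == "+":
                lf, rf = g[max(0, s - pad) : s], g[e : e + pad]
            else:
                lf = reverse_complement(g[e : e + pad])
                rf = reverse_complement(g[max(0, s - pad) : s])
            if close(lf0, lf):
                cons_left += 1
            if close(rf0, rf):
                cons_right += 1
            # exact agreement immediately beyond both ends: the copies still
            # agree past the candidate, so its boundary is not the repeat's
            ext_l = 0
            while ext_l < len(lf0) and ext_l < len(lf) and lf0[-1 - ext_l] == lf[-1 - ext_l]:
                ext_l += 1
            ext_r = 0
            while ext_r < len(rf0) and ext_r < len(rf) and rf0[ext_r] == rf[ext_r]:
                ext_r += 1
            if min(ext_l, ext_r) >= 2:
                both_extend += 1
        if max(cons_left, cons_right) >= min_copies:
            continue
        if both_extend >= min_copies - 1:
            continue
        out.append(c)
    return out


def filter_singletons(
    candidates: list[IRCandidate],
    genome: SequenceRecord,
    min_copies: int = 2,
    identity: float = 0.9,
) -> list[IRCandidate]:
    """Keep candidates whose sequence occurs >= ``min_copies`` times.

    Implements the copy-number filter that removes IR-delimited sequences
    present fewer than twice in the genome.
    """
    if min_copies <= 1:
        return list(candidates)
    if not candidates:
        return []
    k = 13
    g = genome.seq
    index = genome_kmer_positions(g, k)
    # positions whose k-mer recurs somewhere (either strand); candidates in
    # single-copy background carry almost none and are rejected in O(1)
    nk = max(len(g) - k + 1, 0)
    rep = np.zeros(nk, dtype=np.uint8)
    for i in range(nk):
        w = g[i : i + k]
        if len(index[w]) > 1:
            rep[i] = 1
        else:
            rc = reverse_complement(w)
            if rc != w and rc in index:
                rep[i] = 1
    rep_prefix = np.concatenate([[0], np.cumsum(rep, dtype=np.int64)])

    def repeated_fraction(s: int, e: int) -> float:
        lo, hi = s, max(s, min(e - k + 1, nk))
        if hi <= lo:
            return 0.0
        return float(rep_prefix[hi] - rep_prefix[lo]) / (hi - lo)

    cache: dict[str, int] = {}
    out = []
    for c in candidates:
        if c.seq not in cache:
            if repeated_fraction(*c.span) < 0.15:
                cache[c.seq] = 1
            else:
                cache[c.seq] = count_occurrences(
                    c.seq, genome, identity, index, min_copies,
                    terminal_window=20, self_span=c.span,
                )
        if cache[c.seq] >= min_copies:
            out.append(c)
    return out
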