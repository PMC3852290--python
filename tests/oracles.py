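"""Independent brute-force oracles used by the test-suite.

Everything here is deliberately naive (direct enumeration / tiny DPs coded
separately from the package) so it can serve as ground truth for the fast
implementations.
"""

from __future__ import annotations

import math

# standard genetic code (codon assignments of the bacterial/archaeal table)
_CODONS = {}
_BASES = "TCAG"
_AAS = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
for _i, _b1 in enumerate(_BASES):
    for _j, _b2 in enumerate(_BASES):
        for _k, _b3 in enumerate(_BASES):
            _CODONS[_b1 + _b2 + _b3] = _AAS[16 * _i + 4 * _j + _k]

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def translate_brute(seq: str) -> str:
    out = []
    for i in range(0, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        out.append(_CODONS.get(codon, "X"))
    return "".join(out)


# ---------------------------------------------------------------------------
# inverted repeats


def brute_ir_pairs(seq: str, min_arm: int, max_arm: int, max_gap: int, max_mismatch: int):
    """All maximal IR windows by direct enumeration.

    A window on anti-diagonal c pairs x with c - x; validity requires
    matching terminal pairs, bounded internal mismatches, arm length in
    range and gap in [0, max_gap]; maximal = not properly contained in
    another valid window of the same diagonal. Returns a set of
    (left_start, left_end, right_start, right_end, arm_len, mismatches).
    """
    n = len(seq)

    def match(x, y):
        a, b = seq[x], seq[y]
        return a in "ACGT" and b in "ACGT" and _COMP[a] == b

    out = set()
    for c in range(1, 2 * n - 2):
        valid = []
        a_min = max(0, c - (n - 1))
        b_max = (c - 1) // 2
        for a in range(a_min, b_max + 1):
            if not match(a, c - a):
                continue
            for b in range(a + min_arm - 1, min(a + max_arm, b_max + 1)):
                if not match(b, c - b):
                    continue
                gap = c - 1 - 2 * b
                if gap > max_gap:
                    continue
                mm = sum(0 if match(x, c - x) else 1 for x in range(a, b + 1))
                if mm <= max_mismatch:
                    valid.append((a, b, mm))
        for a, b, mm in valid:
            contained = any(
                (a2, b2) != (a, b) and a2 <= a and b <= b2 for a2, b2, _ in valid
            )
            if not contained:
                out.add((a, b + 1, c - b, c - a + 1, b - a + 1, mm))
    return out


def ir_pairs_as_tuples(pairs):
    return {
        (p.left[0], p.left[1], p.right[0], p.right[1], p.arm_len, p.mismatches)
        for p in pairs
    }


# ---------------------------------------------------------------------------
# alignment


def nw_identity_brute(a: str, b: str):
    """Global +1/-1/-1 alignment maximising (score, matches, -cols)."""
    n, m = len(a), len(b)
    NEG = (-(10**9), 0, 0)
    prev = [(-j, 0, -j) for j in range(m + 1)]
    for i in range(1, n + 1):
        cur = [(-i, 0, -i)] + [NEG] * m
        for j in range(1, m + 1):
            eq = a[i - 1] == b[j - 1]
            ds, dm, dc = prev[j - 1]
            cand = [(ds + (1 if eq else -1), dm + (1 if eq else 0), dc - 1)]
            us, um, uc = prev[j]
            cand.append((us - 1, um, uc - 1))
            ls, lm, lc = cur[j - 1]
            cand.append((ls - 1, lm, lc - 1))
            cur[j] = max(cand)
        prev = cur
    s, matches, negcols = prev[m]
    return matches, -negcols


def sw_score_brute(a: str, b: str, subst, gap_open: int, gap_extend: int) -> int:
    """Affine-gap local alignment optimum (score only), Gotoh recurrences."""
    n, m = len(a), len(b)
    NEG = -(10**9)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + gap_open, E[i][j - 1] + gap_extend)
            F[i][j] = max(H[i - 1][j] + gap_open, F[i - 1][j] + gap_extend)
            H[i][j] = max(
                0,
                H[i - 1][j - 1] + subst(a[i - 1], b[j - 1]),
                E[i][j],
                F[i][j],
            )
            best = max(best, H[i][j])
    return best


# ---------------------------------------------------------------------------
# profile HMM: exhaustive path enumeration

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def enumerate_profile_scores(hmm, peptide: str):
    """(viterbi_bits, forward_bits) without double counting.

    Paths are enumerated from every entry point; a path contributes one
    exit term each time it sits in a match state, which is exactly one
    alignment (envelope ends right there). Flanking residues contribute
    odds 1. So enumerate from each start only, and count exits at match
    states as terminal path probabilities.
    """
    K = hmm.K
    idx = {a: i for i, a in enumerate(AA20)}
    bg = hmm.background

    def m_odds(k, ch):
        if ch not in idx:
            return 1.0
        return hmm.match_emissions[k - 1][idx[ch]] / bg[idx[ch]]

    def i_odds(k, ch):
        if ch not in idx:
            return 1.0
        return hmm.insert_emissions[k][idx[ch]] / bg[idx[ch]]

    n = len(peptide)
    terms: list[float] = []

    def walk(state, node, pos, prob):
        if state == "M":
            terms.append(prob / K)  # exit here: envelope ends at pos
            tm = hmm.t_match[node]
            if pos < n:
                if node < K:
                    walk("M", node + 1, pos + 1, prob * tm[0] * m_odds(node + 1, peptide[pos]))
                walk("I", node, pos + 1, prob * tm[1] * i_odds(node, peptide[pos]))
            if node < K:
                walk("D", node + 1, pos, prob * tm[2])
        elif state == "I":
            ti = hmm.t_insert[node]
            if pos < n:
                if node < K:
                    walk("M", node + 1, pos + 1, prob * ti[0] * m_odds(node + 1, peptide[pos]))
                walk("I", node, pos + 1, prob * ti[1] * i_odds(node, peptide[pos]))
        else:
            td = hmm.t_delete[node]
            if pos < n:
                if node < K:
                    walk("M", node + 1, pos + 1, prob * td[0] * m_odds(node + 1, peptide[pos]))
            if node < K:
                walk("D", node + 1, pos, prob * td[1])

    for start in range(n):
        for k in range(1, K + 1):
            walk("M", k, start + 1, (1.0 / K) * m_odds(k, peptide[start]))

    best = max(terms)
    total = math.fsum(terms)
    return math.log2(best), math.log2(total)
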