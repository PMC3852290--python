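"""De novo discovery of repeated-sequence families and their consensus.

The search seeds on frequent l-mers (default l = 9, canonicalised with
their reverse complement so plus- and minus-strand copies of one family
share a seed) and grows a consensus outward from the aligned seed
occurrences by symmetric, gapless greedy extension:

* at each flank step the majority base over the live copies is appended to
  the consensus (ties broken lexicographically);
* each copy scores +1 when it agrees with the appended base and -2 when it
  does not; a copy drops out of the extension when its cumulative flank
  score falls ``max_score_drop`` below that copy's running maximum;
* the flank stops extending when fewer than ``min_copies`` copies are live.

A family is accepted when the final consensus is at least ``min_len`` long.
Accepted families mask their copy positions so each genome position
supports at most one family; seeds are visited by descending occurrence
count (then lexicographically), making the whole procedure deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .seqio import SequenceRecord, reverse_complement


@dataclass(frozen=True)
class RepeatParams:
    lmer: int = 9
    min_copies: int = 3
    min_len: int = 50
    max_len: int = 10000
    extension_penalty: int = -2  # score for a copy disagreeing with the consensus
    match_bonus: int = 1
    max_score_drop: int = 10

    def __post_init__(self):
        if self.lmer < 4:
            raise ValueError("lmer must be >= 4")
        if self.min_copies < 2:
            raise ValueError("min_copies must be >= 2")
        if self.min_len <= self.lmer:
            raise ValueError("min_len must exceed lmer")


@dataclass
class RepeatFamily:
    family_id: str
    consensus: str
    # (seq_id, (start, end), strand '+'|'-', identity to consensus)
    copies: list


def _canonical(w: str) -> str:
    rc = reverse_complement(w)
    return w if w <= rc else rc


def seed_lmers(genome: SequenceRecord, lmer: int = 9, min_count: int = 3):
    """Canonical l-mers occurring >= min_count times, with their positions.

    Positions are (offset, strand) pairs: strand '+' when the genome word
    equals the canonical form, '-' when its reverse complement does.
    Sorted by descending count, ties broken lexicographically.
    """
    if lmer > len(genome.seq):
        raise ValueError("lmer longer than genome")
    occ: dict[str, list] = {}
    s = genome.seq
    for i in range(len(s) - lmer + 1):
        w = s[i : i + lmer]
        if "N" in w:
            continue
        canon = _canonical(w)
        occ.setdefault(canon, []).append((i, "+" if w == canon else "-"))
    items = [(w, ps) for w, ps in occ.items() if len(ps) >= min_count]
    items.sort(key=lambda t: (-len(t[1]), t[0]))
    return items


def _entropy_per_base(word: str) -> float:
    n = len(word)
    h = 0.0
    for b in "ACGT":
        p = word.count(b) / n
        if p > 0:
            h -= p * math.log2(p)
    return h


def build_consensus(
    genome: SequenceRecord,
    seed_positions: list,
    params: RepeatParams = RepeatParams(),
    lmer: int | None = None,
) -> RepeatFamily | None:
    """Grow a repeat consensus from aligned seed occurrences.

    ``seed_positions`` is a list of (offset, strand) pairs locating one
    shared l-mer; all occurrences start aligned at that seed. Returns None
    when fewer than ``min_copies`` copies survive or the consensus stays
    shorter than ``min_len``.
    """
    L = lmer if lmer is not None else params.lmer
    if len(seed_positions) < params.min_copies:
        return None
    s = genome.seq
    n = len(s)

    def base_at(pos: int, strand: str, offset: int) -> str | None:
        # offset counted from seed start in the copy's own orientation
        if strand == "+":
            p = pos + offset
            if 0 <= p < n:
                return s[p]
        else:
            # minus copy: its forward direction runs leftward on the genome,
            # reading complemented bases; seed occupies [pos, pos+L)
            p = pos + L - 1 - offset
            if 0 <= p < n:
                return _COMP[s[p]]
        return None

    copies = [
        {"pos": p, "strand": st, "score": 0, "best": 0, "right": L, "left": 0,
         "right_best": L, "left_best": 0, "alive": True}
        for p, st in seed_positions
    ]

    cons_right: list[str] = []
    cons_left: list[str] = []

    best_ext = {"right": 0, "left": 0}
    for side in ("right", "left"):
        for c in copies:
            c["alive"] = True
            c["score"] = 0
            c["best"] = 0
        ext = 0
        side_total = 0
        side_best = 0
        while True:
            live = [c for c in copies if c["alive"]]
            if len(live) < params.min_copies:
                break
            if side == "right":
                off = L + ext
            else:
                off = -1 - ext
            votes: dict[str, int] = {}
            props = []
            for c in live:
                b = base_at(c["pos"], c["strand"], off)
                props.append((c, b))
                if b is not None and b != "N":
                    votes[b] = votes.get(b, 0) + 1
            if not votes:
                break
            maj = sorted(votes.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
            for c, b in props:
                if b is None:
                    c["alive"] = False
                    continue
                inc = params.match_bonus if b == maj else params.extension_penalty
                c["score"] += inc
                side_total += inc
                if c["score"] > c["best"]:
                    c["best"] = c["score"]
                    c[f"{side}_best"] = (L + ext + 1) if side == "right" else (ext + 1)
                if c["score"] < c["best"] - params.max_score_drop:
                    c["alive"] = False
            if side_total > side_best:
                side_best = side_total
                best_ext[side] = ext + 1
            if side == "right":
                cons_right.append(maj)
            else:
                cons_left.append(maj)
            ext += 1
            total = L + len(cons_right) + len(cons_left)
            if total >= params.max_len:
                break
        # record final best extents for copies that stayed alive to the end
        for c in copies:
            if side == "right":
                c["right"] = c["right_best"]
            else:
                c["left"] = c["left_best"]

    # trim each flank to the extension with the best summed agreement score:
    # past the true repeat boundary every copy turns random and the total
    # score declines, so the argmax sits at the boundary
    cons_right = cons_right[: best_ext["right"]]
    cons_left = cons_left[: best_ext["left"]]
    seed_word = "".join(base_at(copies[0]["pos"], copies[0]["strand"], k) for k in range(L))
    consensus = "".join(reversed(cons_left)) + seed_word + "".join(cons_right)
    lext = len(cons_left)
    if len(consensus) < params.min_len:
        return None

    out_copies = []
    rext = len(consensus) - lext
    for c in copies:
        # extents in copy orientation, clamped to the trimmed consensus
        left = min(c["left"], lext)
        right = min(c["right"], rext)
        clen = left + right
        # a real copy spans (nearly) the whole consensus; fragments betray
        # mixed-orientation chimeras seeded on palindromic words
        if clen < 0.8 * len(consensus):
            continue
        if c["strand"] == "+":
            start = c["pos"] - left
            end = c["pos"] + right
        else:
            start = c["pos"] + L - right
            end = c["pos"] + L + left
        start = max(0, start)
        end = min(n, end)
        cons_lo = lext - left
        matches = 0
        total = 0
        for k in range(-left, right):
            b = base_at(c["pos"], c["strand"], k)
            cb = consensus[lext + k]
            if b is not None:
                total += 1
                if b == cb:
                    matches += 1
        ident = matches / total if total else 0.0
        if ident < 0.7:
            continue
        out_copies.append((genome.id, (start, end), c["strand"], ident))
    # drop copies largely overlapping a better one (a nearly self-reverse-
    # complementary element can seed the same locus on both strands)
    out_copies.sort(key=lambda t: (-t[3], t[1]))
    kept = []
    for cand in out_copies:
        s, e = cand[1]
        if any(min(e, ke) - max(s, ks) > 0.5 * (e - s) for _, (ks, ke), _, _ in kept):
            continue
        kept.append(cand)
    kept.sort(key=lambda t: t[1])
    if len(kept) < params.min_copies:
        return None
    return RepeatFamily("fam", consensus, kept)


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def find_repeat_families(
    genome: SequenceRecord, params: RepeatParams = RepeatParams()
) -> list[RepeatFamily]:
    """Discover repeat families genome-wide.

    Seeds are visited by descending frequency; positions consumed by an
    accepted family are masked so later seeds cannot reuse them.
    """
    masked = bytearray(len(genome.seq))
    seeds = seed_lmers(genome, params.lmer, params.min_copies)
    families: list[RepeatFamily] = []
    for word, positions in seeds:
        if _entropy_per_base(word) < 1.0:
            continue
        free = []
        for p, st in positions:
            if any(masked[p : p + params.lmer]):
                continue
            # collapse occurrences overlapping the previous one (both
            # orientations of a near-palindromic word hit the same locus)
            if free and p - free[-1][0] < params.lmer:
                continue
            free.append((p, st))
        if len(free) < params.min_copies:
            continue
        fam = build_consensus(genome, free, params)
        if fam is None:
            continue
        fam = RepeatFamily(f"RF{len(families) + 1:03d}", fam.consensus, fam.copies)
        for _, (a, b), _, _ in fam.copies:
            masked[a:b] = b"\x01" * (b - a)
        families.append(fam)
    return families
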