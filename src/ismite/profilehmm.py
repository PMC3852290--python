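"""Protein profile HMMs: building from an MSA, local scoring, calibration.

Architecture is the classic match/insert/delete profile: alignment columns
with fewer than 50% gap characters become match states (a column with
exactly half gaps is an insert column); insert states sit between match
states. Emissions are observed counts plus ``pseudocount * background``
(background uniform 1/20), transitions come from the observed state paths
with Laplace (+1) smoothing.

Scoring is *local* log2-odds against the background: alignment may start at
any match state k (uniform entry probability 1/K) and end at any match
state (uniform exit weight 1/K); residues outside the aligned envelope are
emitted by the background and score zero. Entry/exit weights are scoring
conventions, not part of the per-node transition distributions.

E-values come from a Gumbel (extreme-value) fit to Viterbi scores of
i.i.d. background-sampled random peptides:
``E(s) = N_targets * (1 - exp(-exp(-lambda * (s - mu))))``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from numba import njit
from scipy.optimize import brentq

from .seqio import FrameTranslation, MSARow

AA20 = "ACDEFGHIKLMNPQRSTVWY"
_AA_IDX = {a: i for i, a in enumerate(AA20)}

# transition column order within the stored arrays
#   match-out:  M->M, M->I, M->D
#   insert-out: I->M, I->I
#   delete-out: D->M, D->D


@dataclass(frozen=True)
class GumbelCalib:
    mu: float
    lambda_gumbel: float
    n_calib: int
    seed: int


@dataclass(frozen=True, eq=False)
class ProfileHMM:
    name: str
    K: int
    match_emissions: np.ndarray  # (K, 20), rows sum to 1
    insert_emissions: np.ndarray  # (K+1, 20); insert k sits after match k (0 = before M1)
    t_match: np.ndarray  # (K+1, 3): from node k (0 = begin) -> M/I/D of node k(+1)
    t_insert: np.ndarray  # (K+1, 2)
    t_delete: np.ndarray  # (K+1, 2)
    background: np.ndarray  # (20,)
    calib: GumbelCalib | None = None

    def __post_init__(self):
        if self.K < 1:
            raise ValueError("profile needs at least one match state")
        for arr in (self.match_emissions, self.insert_emissions, self.t_match,
                    self.t_insert, self.t_delete):
            if not np.allclose(arr.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError("emission/transition rows must sum to 1")
        if self.calib is not None and self.calib.lambda_gumbel <= 0:
            raise ValueError("calibration lambda must be positive")

    def evalue(self, score: float, n_targets: int) -> float:
        if self.calib is None:
            raise ValueError(f"profile {self.name!r} is not calibrated")
        lam, mu = self.calib.lambda_gumbel, self.calib.mu
        return n_targets * -math.expm1(-math.exp(-lam * (score - mu)))


@dataclass(frozen=True)
class ProfileHit:
    profile: str
    target_id: str
    frame: int
    env: tuple[int, int]  # half-open on the peptide
    bits: float
    evalue: float


class FormatError(ValueError):
    pass


def build_profile(msa: list[MSARow], pseudocount: float = 1.0, name: str = "profile") -> ProfileHMM:
    """Build a profile HMM from an aligned peptide MSA.

    At least 2 rows are required; training from >= 50 sequences is
    recommended for usable sensitivity but not enforced.
    """
    if len(msa) < 2:
        raise ValueError("profile construction needs >= 2 aligned sequences")
    ncol = len(msa[0].seq)
    if any(len(r.seq) != ncol for r in msa):
        raise FormatError("ragged alignment")
    nseq = len(msa)
    gap_frac = [sum(1 for r in msa if r.seq[c] == "-") / nseq for c in range(ncol)]
    is_match = [g < 0.5 for g in gap_frac]
    K = sum(is_match)
    if K < 1:
        raise ValueError("no match columns (alignment too gappy)")
    bg = np.full(20, 1 / 20)

    m_counts = np.zeros((K, 20))
    i_counts = np.zeros((K + 1, 20))
    tm = np.zeros((K + 1, 3))
    ti = np.zeros((K + 1, 2))
    td = np.zeros((K + 1, 2))

    col2match = []
    k = 0
    for c in range(ncol):
        if is_match[c]:
            k += 1
        col2match.append(k)  # match node reached after column c

    for r in msa:
        # state path: begin(node 0) -> ... -> end
        prev = ("M", 0)  # begin behaves as M0
        for c in range(ncol):
            ch = r.seq[c]
            node = col2match[c]
            if is_match[c]:
                state = ("D", node) if ch == "-" else ("M", node)
                if state[0] == "M" and ch in _AA_IDX:
                    m_counts[node - 1, _AA_IDX[ch]] += 1
            else:
                if ch == "-":
                    continue
                state = ("I", node)
                if ch in _AA_IDX:
                    i_counts[node, _AA_IDX[ch]] += 1
            ps, pn = prev
            ss, _ = state
            if ps == "M":
                tm[pn, {"M": 0, "I": 1, "D": 2}[ss]] += 1
            elif ps == "I":
                ti[pn, {"M": 0, "I": 1}.get(ss, 0)] += 1
            else:
                td[pn, {"M": 0, "D": 1}.get(ss, 0)] += 1
            prev = state
        # exit transition to the virtual end node (counts toward M/D -> M)
        ps, pn = prev
        if ps == "M":
            tm[pn, 0] += 1
        elif ps == "I":
            ti[pn, 0] += 1
        else:
            td[pn, 0] += 1

    m_em = (m_counts + pseudocount * bg) / (m_counts + pseudocount * bg).sum(axis=1, keepdims=True)
    i_em = (i_counts + pseudocount * bg) / (i_counts + pseudocount * bg).sum(axis=1, keepdims=True)
    tm = (tm + 1.0) / (tm + 1.0).sum(axis=1, keepdims=True)
    ti = (ti + 1.0) / (ti + 1.0).sum(axis=1, keepdims=True)
    td = (td + 1.0) / (td + 1.0).sum(axis=1, keepdims=True)
    return ProfileHMM(name, K, m_em, i_em, tm, ti, td, bg)


# ---------------------------------------------------------------------------
# scoring


def _encode_peptide(pep: str) -> np.ndarray:
    return np.array([_AA_IDX.get(a, 20) for a in pep.upper()], dtype=np.int64)


def _log_tables(hmm: ProfileHMM):
    """Log2 tables; unknown residues (index 20) score 0 (background)."""
    with np.errstate(divide="ignore"):
        mlo = np.log2(hmm.match_emissions / hmm.background)
        ilo = np.log2(hmm.insert_emissions / hmm.background)
        tm = np.log2(hmm.t_match)
        ti = np.log2(hmm.t_insert)
        td = np.log2(hmm.t_delete)
    mlo = np.hstack([mlo, np.zeros((hmm.K, 1))])
    ilo = np.hstack([ilo, np.zeros((hmm.K + 1, 1))])
    return mlo, ilo, tm, ti, td


NEG = -1e30


@njit(cache=True)
def _viterbi_kernel(x, mlo, ilo, tm, ti, td, entry, exit_):  # pragma: no cover
    n = x.shape[0]
    K = mlo.shape[0]
    VM = np.full((K + 1, n + 1), NEG)
    VI = np.full((K + 1, n + 1), NEG)
    VD = np.full((K + 1, n + 1), NEG)
    SM = np.zeros((K + 1, n + 1), dtype=np.int64)
    SI = np.zeros((K + 1, n + 1), dtype=np.int64)
    SD = np.zeros((K + 1, n + 1), dtype=np.int64)
    best = NEG
    bi = 0
    bk = 0
    for i in range(1, n + 1):
        c = x[i - 1]
        for k in range(1, K + 1):
            # match
            v = entry
            src = i - 1
            t = VM[k - 1, i - 1] + tm[k - 1, 0]
            if t > v:
                v = t
                src = SM[k - 1, i - 1]
            t = VI[k - 1, i - 1] + ti[k - 1, 0]
            if t > v:
                v = t
                src = SI[k - 1, i - 1]
            t = VD[k - 1, i - 1] + td[k - 1, 0]
            if t > v:
                v = t
                src = SD[k - 1, i - 1]
            VM[k, i] = v + mlo[k - 1, c]
            SM[k, i] = src
            # insert (after match k)
            v = VM[k, i - 1] + tm[k, 1]
            src = SM[k, i - 1]
            t = VI[k, i - 1] + ti[k, 1]
            if t > v:
                v = t
                src = SI[k, i - 1]
            VI[k, i] = v + ilo[k, c]
            SI[k, i] = src
            # delete
            v = VM[k - 1, i] + tm[k - 1, 2]
            src = SM[k - 1, i]
            t = VD[k - 1, i] + td[k - 1, 1]
            if t > v:
                v = t
                src = SD[k - 1, i]
            VD[k, i] = v
            SD[k, i] = src
            s = VM[k, i] + exit_
            if s > best:
                best = s
                bi = i
                bk = SM[k, i]
    return best, bk, bi


@njit(cache=True)
def _lse2(a, b):  # pragma: no cover
    if a < b:
        a, b = b, a
    if b <= NEG / 2:
        return a
    return a + math.log2(1.0 + 2.0 ** (b - a))


@njit(cache=True)
def _forward_kernel(x, mlo, ilo, tm, ti, td, entry, exit_):  # pragma: no cover
    n = x.shape[0]
    K = mlo.shape[0]
    FM = np.full((K + 1, n + 1), NEG)
    FI = np.full((K + 1, n + 1), NEG)
    FD = np.full((K + 1, n + 1), NEG)
    total = NEG
    for i in range(1, n + 1):
        c = x[i - 1]
        for k in range(1, K + 1):
            v = entry
            v = _lse2(v, FM[k - 1, i - 1] + tm[k - 1, 0])
            v = _lse2(v, FI[k - 1, i - 1] + ti[k - 1, 0])
            v = _lse2(v, FD[k - 1, i - 1] + td[k - 1, 0])
            FM[k, i] = v + mlo[k - 1, c]
            v = _lse2(FM[k, i - 1] + tm[k, 1], FI[k, i - 1] + ti[k, 1])
            FI[k, i] = v + ilo[k, c]
            FD[k, i] = _lse2(FM[k - 1, i] + tm[k - 1, 2], FD[k - 1, i] + td[k - 1, 1])
            total = _lse2(total, FM[k, i] + exit_)
    return total


def viterbi_score(hmm: ProfileHMM, peptide: str) -> tuple[float, tuple[int, int]]:
    """Best local log2-odds score and its envelope on the peptide."""
    if not peptide:
        raise ValueError("empty peptide")
    x = _encode_peptide(peptide)
    mlo, ilo, tm, ti, td = _log_tables(hmm)
    entry = -math.log2(hmm.K)
    bits, s, e = _viterbi_kernel(x, mlo, ilo, tm, ti, td, entry, entry)
    return float(bits), (int(s), int(e))


def forward_score(hmm: ProfileHMM, peptide: str) -> float:
    """Local log2-odds forward (summed over all alignments) score."""
    if not peptide:
        raise ValueError("empty peptide")
    x = _encode_peptide(peptide)
    mlo, ilo, tm, ti, td = _log_tables(hmm)
    entry = -math.log2(hmm.K)
    return float(_forward_kernel(x, mlo, ilo, tm, ti, td, entry, entry))


# ---------------------------------------------------------------------------
# calibration


def fit_gumbel(scores: np.ndarray) -> tuple[float, float]:
    """Maximum-likelihood Gumbel fit; returns (mu, lambda)."""
    x = np.asarray(scores, dtype=float)
    if x.std() < 1e-12:
        raise ValueError("degenerate score variance; cannot calibrate")
    xbar = x.mean()

    def g(beta):
        w = np.exp(-(x - x.max()) / beta)
        return beta - xbar + (x * w).sum() / w.sum()

    b0 = x.std() * math.sqrt(6.0) / math.pi
    lo, hi = b0 / 10, b0 * 10
    while g(lo) > 0 and lo > 1e-9:
        lo /= 10
    while g(hi) < 0 and hi < 1e9:
        hi *= 10
    beta = brentq(g, lo, hi, xtol=1e-12)
    # mu from the ML profile: mu = -beta * log(mean(exp(-x/beta))), computed stably
    shift = x.max()
    mu = shift - beta * math.log(np.mean(np.exp(-(x - shift) / beta)))
    return float(mu), float(1.0 / beta)


def calibrate(
    hmm: ProfileHMM,
    n_random: int = 5000,
    len_mean: float = 350.0,
    len_sd: float = 120.0,
    seed: int = 0,
) -> ProfileHMM:
    """Fit the Gumbel null from Viterbi scores of random background peptides."""
    if n_random < 100:
        raise ValueError("n_random must be >= 100")
    rng = np.random.default_rng(seed)
    lengths = np.clip(rng.normal(len_mean, len_sd, n_random).round().astype(int), 30, None)
    mlo, ilo, tm, ti, td = _log_tables(hmm)
    entry = -math.log2(hmm.K)
    scores = np.empty(n_random)
    for i, L in enumerate(lengths):
        x = rng.choice(20, size=int(L), p=hmm.background).astype(np.int64)
        scores[i], _, _ = _viterbi_kernel(x, mlo, ilo, tm, ti, td, entry, entry)
    mu, lam = fit_gumbel(scores)
    return replace(hmm, calib=GumbelCalib(mu, lam, n_random, seed))


# ---------------------------------------------------------------------------
# search


def _hit_genome_interval(hit: ProfileHit) -> tuple[str, int, int] | None:
    """Genome-coordinate interval of a hit whose target id encodes a segment."""
    ref = hit.target_id
    if "|" not in ref:
        return None
    parent, _, span = ref.rpartition("|")
    try:
        a, b = span.split("-")
        seg_start, seg_end = int(a), int(b)
    except ValueError:
        return None
    seg_len = seg_end - seg_start
    off = abs(hit.frame) - 1
    s, e = hit.env
    if hit.frame > 0:
        nt_s = seg_start + off + 3 * s
        nt_e = seg_start + off + 3 * e
    else:
        nt_s = seg_start + seg_len - (off + 3 * e)
        nt_e = seg_start + seg_len - (off + 3 * s)
    return parent, nt_s, nt_e


def search_profiles(
    profiles: list[ProfileHMM],
    translations: list[FrameTranslation],
    evalue_max: float = 1e-5,
) -> list[ProfileHit]:
    """Score every (profile, frame-peptide) pair; keep hits with E <= max.

    ``N_targets`` for the E-value is the number of frame-peptides scored per
    profile. Hits duplicated by overlapping genome segments are collapsed to
    the best-scoring one; hits of *different* profiles on one locus are all
    kept (overlapping transposase families are informative).
    """
    for p in profiles:
        if p.calib is None:
            raise ValueError(f"profile {p.name!r} must be calibrated before search")
    n_targets = len(translations)
    hits: list[ProfileHit] = []
    for p in sorted(profiles, key=lambda h: h.name):
        mlo, ilo, tm, ti, td = _log_tables(p)
        entry = -math.log2(p.K)
        for tr in translations:
            if not tr.peptide:
                continue
            x = _encode_peptide(tr.peptide)
            bits, s, e = _viterbi_kernel(x, mlo, ilo, tm, ti, td, entry, entry)
            ev = p.evalue(float(bits), n_targets)
            if ev <= evalue_max:
                hits.append(
                    ProfileHit(p.name, tr.segment_ref, tr.frame, (int(s), int(e)),
                               float(bits), ev)
                )
    # collapse duplicates caused by segment overlap: same profile, same
    # genome locus (>=50% reciprocal overlap), same strand sign
    hits.sort(key=lambda h: (h.evalue, -h.bits, h.target_id, h.frame, h.env))
    kept: list[ProfileHit] = []
    kept_iv: list[tuple] = []
    for h in hits:
        iv = _hit_genome_interval(h)
        dup = False
        if iv is not None:
            parent, a, b = iv
            for (kp, kparent, ka, kb, ksign) in kept_iv:
                if kp == h.profile and kparent == parent and ksign == (h.frame > 0):
                    ov = min(b, kb) - max(a, ka)
                    if ov > 0 and ov >= 0.5 * min(b - a, kb - ka):
                        dup = True
                        break
        if not dup:
            kept.append(h)
            if iv is not None:
                kept_iv.append((h.profile, iv[0], iv[1], iv[2], h.frame > 0))
    return kept


# ---------------------------------------------------------------------------
# plain-text serialization (lossless to 12 significant digits)

_FMT_VERSION = "ismite-profile/1"


def write_profile(hmm: ProfileHMM, path) -> None:
    def row(a):
        return " ".join(f"{v:.12g}" for v in a)

    with open(path, "w") as fh:
        fh.write(f"# {_FMT_VERSION}\n")
        fh.write(f"NAME {hmm.name}\n")
        fh.write(f"K {hmm.K}\n")
        fh.write(f"BACKGROUND {row(hmm.background)}\n")
        for k in range(hmm.K):
            fh.write(f"MATCH {k + 1} {row(hmm.match_emissions[k])}\n")
        for k in range(hmm.K + 1):
            fh.write(f"INSERT {k} {row(hmm.insert_emissions[k])}\n")
        for k in range(hmm.K + 1):
            fh.write(f"TM {k} {row(hmm.t_match[k])}\n")
            fh.write(f"TI {k} {row(hmm.t_insert[k])}\n")
            fh.write(f"TD {k} {row(hmm.t_delete[k])}\n")
        if hmm.calib is not None:
            c = hmm.calib
            fh.write(f"CALIB {c.mu:.12g} {c.lambda_gumbel:.12g} {c.n_calib} {c.seed}\n")


def read_profile(path) -> ProfileHMM:
    name = "profile"
    K = 0
    bg = None
    calib = None
    rows: dict[str, dict[int, np.ndarray]] = {"MATCH": {}, "INSERT": {}, "TM": {}, "TI": {}, "TD": {}}
    with open(path) as fh:
        header = fh.readline().strip()
        if header != f"# {_FMT_VERSION}":
            raise FormatError(f"unrecognised profile format: {header!r}")
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            tag = parts[0]
            if tag == "NAME":
                name = parts[1]
            elif tag == "K":
                K = int(parts[1])
            elif tag == "BACKGROUND":
                bg = np.array([float(v) for v in parts[1:]])
            elif tag == "CALIB":
                calib = GumbelCalib(float(parts[1]), float(parts[2]), int(parts[3]), int(parts[4]))
            elif tag in rows:
                rows[tag][int(parts[1])] = np.array([float(v) for v in parts[2:]])
            else:
                raise FormatError(f"unknown record {tag!r}")
    if bg is None or K < 1:
        raise FormatError("incomplete profile file")
    m = np.vstack([rows["MATCH"][k + 1] for k in range(K)])
    ins = np.vstack([rows["INSERT"][k] for k in range(K + 1)])
    tm = np.vstack([rows["TM"][k] for k in range(K + 1)])
    ti = np.vstack([rows["TI"][k] for k in range(K + 1)])
    td = np.vstack([rows["TD"][k] for k in range(K + 1)])
    # renormalise away the 12-digit rounding before the sum-to-1 validation
    for arr in (m, ins, tm, ti, td):
        arr /= arr.sum(axis=1, keepdims=True)
    return ProfileHMM(name, K, m, ins, tm, ti, td, bg, calib)
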