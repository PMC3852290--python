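"""The three detection workflows and their connecting procedures.

* ``run_repeats_search``: repeat-family mining -> clustering -> 500 bp size
  split -> exhaustive IS copy expansion / MITE partner linking -> optional
  false-positive screen against a decoy library.
* ``run_ir_search``: inverted-repeat pairs -> IR-delimited candidates ->
  singleton removal -> the same downstream stages.
* ``run_hmm_pipeline``: 5 kb segmentation -> six-frame translation ->
  calibrated profile-HMM search -> clustering of hit peptides.

Paper-specific procedures implemented here: candidates above 500 bp go to
the IS branch and the rest (boundary included) to the MITE branch; MITE
partner search takes the terminal 23 bp of each end, locates all genomic
co-occurrences in proper orientation spanning < 3 kb, removes candidates
occurring fewer than twice, separates nested ("Russian doll") elements,
and validates partners by translated search against the transposase
library; calls whose best decoy hit beats their best transposase hit are
screened out.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from .cluster import Cluster, ClusterParams, greedy_cluster
from .irfinder import (
    IRParams,
    extract_ir_candidates,
    find_inverted_repeats,
    filter_fragments,
    filter_singletons,
)
from .localsearch import AlignmentHit, ScoringScheme, search_nt, search_translated
from .profilehmm import ProfileHMM, ProfileHit, search_profiles
from .repeatfinder import RepeatParams, find_repeat_families
from .seqio import (
    FrameTranslation,
    SequenceRecord,
    reverse_complement,
    segment_genome,
    six_frame_translate,
)

log = logging.getLogger("ismite.pipelines")


@dataclass(frozen=True)
class PipelineConfig:
    size_threshold: int = 500  # IS/MITE split on candidate length
    term_len: int = 23  # MITE terminal word used for partner search
    term_max_mismatch: int = 3  # ungapped surrogate for the permissive E<=0.1 terminal search
    mite_max_len: int = 3000  # partner intervals must stay below this
    evalue_is_expand: float = 1e-5
    evalue_term: float = 1e-1
    evalue_validate: float = 1e-5
    evalue_hmm: float = 1e-5
    min_copies_repeat: int = 3
    min_copies_ir: int = 2
    cluster_identity: float = 0.9
    segment_window: int = 5000
    segment_overlap: int = 300
    max_dr: int = 15
    ir: IRParams = field(default_factory=IRParams)
    repeat: RepeatParams = field(default_factory=RepeatParams)

    def __post_init__(self):
        if self.term_len >= self.mite_max_len:
            raise ValueError("term_len must be smaller than mite_max_len")
        for name in ("size_threshold", "term_len", "mite_max_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ElementCall:
    call_id: str
    kind: str  # IS | MITE | MITE_like_orphan | IS_like
    consensus: str
    copies: list  # (start, end, strand, truncated)
    family_annotation: str | None = None
    family_evalue: float | None = None
    ir: dict | None = None  # {"arm_len":, "mismatches":}
    dr: dict | None = None  # {"length":, "sequences": [..]}
    partner: str | None = None
    evidence: set = field(default_factory=set)


# ---------------------------------------------------------------------------
# stage operations


def split_by_size(clusters: list[Cluster], threshold: int = 500):
    """Centroids longer than ``threshold`` go to the IS branch, the rest
    (threshold length included) to the MITE branch."""
    is_c = [c for c in clusters if len(c.centroid.seq) > threshold]
    mite_c = [c for c in clusters if len(c.centroid.seq) <= threshold]
    return is_c, mite_c


def _merge_intervals(ivs: list[tuple[int, int, str]]) -> list[tuple[int, int, str]]:
    """Merge overlapping same-strand intervals."""
    out: list[list] = []
    for s, e, st in sorted(ivs):
        merged = False
        for o in out:
            if o[2] == st and s < o[1] and e > o[0]:
                o[0], o[1] = min(o[0], s), max(o[1], e)
                merged = True
                break
        if not merged:
            out.append([s, e, st])
    return [(a, b, st) for a, b, st in sorted(out)]


def expand_is_copies(
    consensus: SequenceRecord,
    genome: SequenceRecord,
    evalue: float = 1e-5,
    scheme: ScoringScheme | None = None,
) -> ElementCall:
    """Compile all genomic copies of an IS consensus, truncated ones included.

    Every local hit at E <= ``evalue`` becomes a copy; overlapping
    same-strand hits are merged; copies shorter than 90% of the consensus
    are flagged truncated.
    """
    hits = search_nt(consensus, genome, evalue_max=evalue, scheme=scheme)
    if not hits:
        raise RuntimeError(
            f"consensus {consensus.id!r} has no genomic hits; it should derive from the genome"
        )
    ivs = [(h.target_span[0], h.target_span[1], "+" if h.frame > 0 else "-") for h in hits]
    merged = _merge_intervals(ivs)
    copies = [
        (s, e, st, (e - s) < 0.9 * len(consensus.seq)) for s, e, st in merged
    ]
    return ElementCall(
        call_id=consensus.id, kind="IS", consensus=consensus.seq, copies=copies
    )


def annotate_dr(call: ElementCall, genome: SequenceRecord, max_dr: int = 15) -> None:
    """Report the longest flank word duplicated on both sides of >=2 copies."""
    g = genome.seq
    best_k = 0
    seqs: list[str] = []
    for k in range(max_dr, 1, -1):
        words = []
        for s, e, _st, trunc in call.copies:
            if trunc or s - k < 0 or e + k > len(g):
                continue
            left, right = g[s - k : s], g[e : e + k]
            if left == right and "N" not in left:
                words.append(left)
        if len(words) >= 2:
            best_k = k
            seqs = words
            break
    if best_k:
        call.dr = {"length": best_k, "sequences": seqs}


def annotate_terminal_ir(call: ElementCall, params: IRParams, slack: int = 5) -> None:
    """Record the longest IR pair whose arms sit at the consensus termini."""
    try:
        rec = SequenceRecord(call.call_id, call.consensus, "nt")
    except ValueError:
        return
    pairs = find_inverted_repeats(rec, params)
    terminal = [
        p
        for p in pairs
        if p.left[0] <= slack and p.right[1] >= len(call.consensus) - slack
    ]
    if terminal:
        best = max(terminal, key=lambda p: (p.arm_len, -p.mismatches))
        call.ir = {"arm_len": best.arm_len, "mismatches": best.mismatches}


def annotate_family(
    call: ElementCall,
    transposase_lib: list[SequenceRecord],
    evalue: float = 1e-5,
    scheme: ScoringScheme | None = None,
) -> AlignmentHit | None:
    """Best transposase-library hit -> family label (from the FASTA header).

    Library ids carry the family after the last '|', e.g. ``tnpA|IS3``.
    """
    if not transposase_lib:
        return None
    try:
        rec = SequenceRecord(call.call_id, call.consensus, "nt")
    except ValueError:
        return None
    hits = search_translated(rec, transposase_lib, evalue_max=evalue, scheme=scheme)
    if not hits:
        return None
    best = hits[0]
    fam = best.target_id.rpartition("|")[2] if "|" in best.target_id else best.target_id
    call.family_annotation = fam
    call.family_evalue = best.evalue
    return best


def match_word(genome: str, word: str, max_mismatch: int) -> list[int]:
    """Start positions where ``word`` matches the genome with <= max_mismatch
    substitutions (ungapped). N never matches."""
    n, k = len(genome), len(word)
    if n < k:
        return []
    g = np.frombuffer(genome.encode(), dtype=np.uint8)
    w = np.frombuffer(word.encode(), dtype=np.uint8)
    mism = np.zeros(n - k + 1, dtype=np.int32)
    nmask = g == ord("N")
    for j in range(k):
        mism += (g[j : n - k + 1 + j] != w[j]) | nmask[j : n - k + 1 + j]
    return [int(i) for i in np.nonzero(mism <= max_mismatch)[0]]


def separate_nested(
    intervals: list[tuple[int, int]], genome: SequenceRecord
) -> list[tuple[tuple[int, int], str]]:
    """Separate and reconstruct nested ("Russian doll") elements.

    For each interval, the spans of candidate intervals strictly contained
    in it are excised and its flanks joined; inner elements are emitted
    separately (their own reconstruction handles deeper nesting). Partially
    overlapping intervals are passed through with a warning.
    """
    out = []
    ivs = sorted(set(intervals))
    for s, e in ivs:
        inner = [
            (a, b) for a, b in ivs if (a, b) != (s, e) and s < a and b < e
        ]
        for a, b in ivs:
            if (a, b) != (s, e) and a < e and b > s and not (s <= a and b <= e) and not (a <= s and e <= b):
                log.warning("partially overlapping candidate intervals %s and %s", (s, e), (a, b))
        # keep only maximal inner intervals, then excise them
        maximal = [
            (a, b)
            for a, b in inner
            if not any((c, d) != (a, b) and c <= a and b <= d for c, d in inner)
        ]
        seq = genome.seq[s:e]
        for a, b in sorted(maximal, reverse=True):
            seq = seq[: a - s] + seq[b - s :]
        out.append(((s, e), seq))
    return out


def link_mite_partners(
    mite: Cluster,
    genome: SequenceRecord,
    transposase_lib: list[SequenceRecord],
    cfg: PipelineConfig = PipelineConfig(),
    scheme_nt: ScoringScheme | None = None,
    scheme_tx: ScoringScheme | None = None,
) -> tuple[ElementCall | None, ElementCall | None]:
    """MITE call plus (when found and validated) its autonomous IS partner.

    Returns (mite_call, partner_call); the partner is None for an orphan.
    A centroid too short to carry two terminal words is rejected (None, None).
    """
    centroid = mite.centroid
    if len(centroid.seq) < 2 * cfg.term_len:
        log.info("MITE candidate %s rejected: shorter than two terminal words", centroid.id)
        return None, None

    # the MITE's own genomic copies
    mhits = search_nt(centroid, genome, evalue_max=cfg.evalue_is_expand, scheme=scheme_nt)
    mivs = [
        (h.target_span[0], h.target_span[1], "+" if h.frame > 0 else "-")
        for h in mhits
        if h.identity >= cfg.cluster_identity
        and (h.query_span[1] - h.query_span[0]) >= 0.9 * len(centroid.seq)
    ]
    mite_call = ElementCall(
        call_id=centroid.id,
        kind="MITE",
        consensus=centroid.seq,
        copies=[(s, e, st, False) for s, e, st in _merge_intervals(mivs)],
    )

    t5 = centroid.seq[: cfg.term_len]
    t3 = centroid.seq[-cfg.term_len :]
    mm = cfg.term_max_mismatch
    # proper orientation: a 5' word must precede a 3' word on the same strand
    plus_pairs = [(p, q) for p in match_word(genome.seq, t5, mm)
                  for q in match_word(genome.seq, t3, mm)
                  if q >= p + cfg.term_len and (q + cfg.term_len - p) < cfg.mite_max_len]
    minus_pairs = [(p, q) for p in match_word(genome.seq, reverse_complement(t3), mm)
                   for q in match_word(genome.seq, reverse_complement(t5), mm)
                   if q >= p + cfg.term_len and (q + cfg.term_len - p) < cfg.mite_max_len]
    intervals = sorted(
        {(p, q + cfg.term_len) for p, q in plus_pairs}
        | {(p, q + cfg.term_len) for p, q in minus_pairs}
    )
    if not intervals:
        mite_call.kind = "MITE_like_orphan"
        return mite_call, None

    recon = separate_nested(intervals, genome)
    # copy-number filter: candidate sequences present < 2 times are dropped
    recs = [
        SequenceRecord(f"cand{i}|{iv[0]}-{iv[1]}", seq, "nt")
        for i, (iv, seq) in enumerate(recon)
        if len(seq) >= 2 * cfg.term_len
    ]
    groups = greedy_cluster(recs, ClusterParams(cfg.cluster_identity, "nt"))
    groups = [g for g in groups if len(g.members) >= 2]

    best: tuple[float, Cluster, AlignmentHit] | None = None
    for g in groups:
        if len(g.centroid.seq) <= len(centroid.seq):
            continue  # a partner must be longer than the MITE it mobilises
        hits = search_translated(
            g.centroid, transposase_lib, evalue_max=cfg.evalue_validate, scheme=scheme_tx
        )
        if hits and (best is None or hits[0].evalue < best[0]):
            best = (hits[0].evalue, g, hits[0])
    if best is None:
        mite_call.kind = "MITE_like_orphan"
        return mite_call, None

    _, g, hit = best
    ivs = []
    for m, _ident in g.members:
        a, b = m.id.rpartition("|")[2].split("-")
        ivs.append((int(a), int(b), "+"))
    partner = ElementCall(
        call_id=f"{centroid.id}_partner",
        kind="IS",
        consensus=g.centroid.seq,
        copies=[(s, e, st, False) for s, e, st in _merge_intervals(ivs)],
        family_annotation=hit.target_id.rpartition("|")[2] if "|" in hit.target_id else hit.target_id,
        family_evalue=hit.evalue,
    )
    mite_call.partner = partner.call_id
    return mite_call, partner


def filter_known_non_te(
    calls: list[ElementCall],
    decoy_lib: list[SequenceRecord],
    evalue: float = 1e-5,
    scheme_tx: ScoringScheme | None = None,
    scheme_nt: ScoringScheme | None = None,
) -> tuple[list[ElementCall], list[ElementCall]]:
    """Screen calls whose consensus looks like a known non-TE gene.

    A call is removed when its best decoy hit is stronger (lower E-value)
    than its best transposase-library hit (recorded on the call during
    family annotation). An empty decoy library passes everything through.
    """
    if not decoy_lib:
        return list(calls), []
    aa_decoys = [d for d in decoy_lib if d.alphabet == "aa"]
    nt_decoys = [d for d in decoy_lib if d.alphabet == "nt"]
    kept, removed = [], []
    for call in calls:
        try:
            rec = SequenceRecord(call.call_id, call.consensus, "nt")
        except ValueError:
            kept.append(call)
            continue
        decoy_e = None
        decoy_id = None
        if aa_decoys:
            hits = search_translated(rec, aa_decoys, evalue_max=evalue, scheme=scheme_tx)
            if hits:
                decoy_e, decoy_id = hits[0].evalue, hits[0].target_id
        for d in nt_decoys:
            hits = search_nt(rec, d, evalue_max=evalue, scheme=scheme_nt)
            if hits and (decoy_e is None or hits[0].evalue < decoy_e):
                decoy_e, decoy_id = hits[0].evalue, hits[0].target_id
        te_e = call.family_evalue if call.family_evalue is not None else float("inf")
        if decoy_e is not None and decoy_e < te_e:
            log.info("call %s removed: decoy %s at E=%.3g", call.call_id, decoy_id, decoy_e)
            removed.append(call)
        else:
            kept.append(call)
    return kept, removed


# ---------------------------------------------------------------------------
# full workflows


def _downstream(
    clusters: list[Cluster],
    genome: SequenceRecord,
    transposase_lib: list[SequenceRecord],
    cfg: PipelineConfig,
    evidence: str,
    decoy_lib: list[SequenceRecord] | None,
) -> list[ElementCall]:
    """Shared back end of both de novo paths: size split, expansion/linking,
    annotation and the decoy screen."""
    is_clusters, mite_clusters = split_by_size(clusters, cfg.size_threshold)
    calls: list[ElementCall] = []
    for c in is_clusters:
        call = expand_is_copies(c.centroid, genome, cfg.evalue_is_expand)
        annotate_family(call, transposase_lib, cfg.evalue_validate)
        annotate_terminal_ir(call, cfg.ir)
        annotate_dr(call, genome, cfg.max_dr)
        call.evidence.add(evidence)
        calls.append(call)
    for c in mite_clusters:
        mite_call, partner = link_mite_partners(c, genome, transposase_lib, cfg)
        if mite_call is None:
            continue
        # a MITE whose own body encodes a transposase over most of its length
        # is really a (short) IS
        annotate_family(mite_call, transposase_lib, cfg.evalue_validate)
        hits = (
            search_translated(
                SequenceRecord(mite_call.call_id, mite_call.consensus, "nt"),
                transposase_lib,
                evalue_max=cfg.evalue_validate,
            )
            if transposase_lib
            else []
        )
        covered = max(
            (h.query_span[1] - h.query_span[0] for h in hits), default=0
        )
        if covered > 0.5 * len(mite_call.consensus):
            mite_call.kind = "IS_like"
        annotate_terminal_ir(mite_call, cfg.ir)
        annotate_dr(mite_call, genome, cfg.max_dr)
        mite_call.evidence.add(evidence)
        calls.append(mite_call)
        if partner is not None:
            annotate_terminal_ir(partner, cfg.ir)
            annotate_dr(partner, genome, cfg.max_dr)
            partner.evidence.add(evidence)
            calls.append(partner)
    kept, _removed = filter_known_non_te(
        calls, decoy_lib or [], cfg.evalue_validate
    )
    return kept


def run_repeats_search(
    genome: SequenceRecord,
    transposase_lib: list[SequenceRecord],
    cfg: PipelineConfig = PipelineConfig(),
    decoy_lib: list[SequenceRecord] | None = None,
) -> list[ElementCall]:
    """Repeat-family mining front end ('Repeats search' workflow)."""
    rp = RepeatParams(
        lmer=cfg.repeat.lmer,
        min_copies=cfg.min_copies_repeat,
        min_len=cfg.repeat.min_len,
        max_len=cfg.repeat.max_len,
        extension_penalty=cfg.repeat.extension_penalty,
        match_bonus=cfg.repeat.match_bonus,
        max_score_drop=cfg.repeat.max_score_drop,
    )
    families = find_repeat_families(genome, rp)
    if not families:
        return []
    cons = [SequenceRecord(f.family_id, f.consensus, "nt") for f in families]
    clusters = greedy_cluster(cons, ClusterParams(cfg.cluster_identity, "nt"))
    return _downstream(clusters, genome, transposase_lib, cfg, "repeats", decoy_lib)


def _maximal_candidates(cands, genome: SequenceRecord):
    """Collapse redundant IR candidates at one locus.

    Chance arm pairs slightly offset from (or extending beyond) a repeated
    element also pass the copy-number filter; per overlap group we keep the
    candidate with the most genomic occurrences, ties resolved toward the
    least-diverged and then longest one, so the (near-)exact element span
    wins over junk-flanked extensions and jittered variants.
    """
    from .irfinder import count_occurrences, genome_kmer_positions

    index = genome_kmer_positions(genome.seq) if cands else {}
    cache: dict[str, tuple[int, list]] = {}
    scored = []
    for c in cands:
        if c.seq not in cache:
            cache[c.seq] = count_occurrences(
                c.seq, genome, 0.9, index, min_needed=6, return_loci=True,
                terminal_window=20, self_span=c.span,
            )
        n, loci = cache[c.seq]
        L = c.span[1] - c.span[0]
        others = [
            d
            for s, e, _st, d in loci
            if not (min(e, c.span[1]) - max(s, c.span[0]) > 0.5 * L)
        ]
        ratio = min(others) / L if others else 1.0
        scored.append((n, ratio, L, c))
    scored.sort(key=lambda t: (-t[0], t[1], -t[2], t[3].span))
    kept = []
    for _n, _r, _L, c in scored:
        s, e = c.span
        if any(
            min(e, k.span[1]) - max(s, k.span[0]) > 0.5 * (e - s) for k in kept
        ):
            continue
        kept.append(c)
    kept.sort(key=lambda c: c.span)
    return kept


def run_ir_search(
    genome: SequenceRecord,
    transposase_lib: list[SequenceRecord],
    cfg: PipelineConfig = PipelineConfig(),
    decoy_lib: list[SequenceRecord] | None = None,
) -> list[ElementCall]:
    """Inverted-repeat front end ('IRs search' workflow)."""
    pairs = find_inverted_repeats(genome, cfg.ir)
    cands = extract_ir_candidates(genome, pairs)
    cands = [c for c in cands if c.span[1] - c.span[0] >= 2 * cfg.ir.min_arm + 10]
    cands = filter_singletons(cands, genome, cfg.min_copies_ir, cfg.cluster_identity)
    cands = filter_fragments(cands, genome, min_copies=cfg.min_copies_ir)
    cands = _maximal_candidates(cands, genome)
    if not cands:
        return []
    recs = [
        SequenceRecord(f"irc{i}|{c.span[0]}-{c.span[1]}", c.seq, "nt")
        for i, c in enumerate(cands)
    ]
    clusters = greedy_cluster(recs, ClusterParams(cfg.cluster_identity, "nt"))
    return _downstream(clusters, genome, transposase_lib, cfg, "ir", decoy_lib)


def run_hmm_pipeline(
    records: list[SequenceRecord],
    profiles: list[ProfileHMM],
    cfg: PipelineConfig = PipelineConfig(),
) -> tuple[list[Cluster], list[ProfileHit]]:
    """Profile-HMM transposase search on genomes, reads or peptides.

    Nucleotide input is cut into overlapping windows and translated in six
    frames; peptide input is scored directly. Returns the clusters of hit
    peptides and the raw hit list.
    """
    alphabets = {r.alphabet for r in records}
    if len(alphabets) > 1:
        raise ValueError("mixed nucleotide/peptide input")
    translations: list[FrameTranslation] = []
    if alphabets == {"nt"}:
        for rec in records:
            if len(rec.seq) < 3:
                continue
            for seg in segment_genome(rec, cfg.segment_window, min(cfg.segment_overlap, cfg.segment_window - 1)):
                if seg.end - seg.start < 3:
                    continue
                translations.extend(six_frame_translate(seg.seq, segment_ref=seg.id))
    else:
        translations = [
            FrameTranslation(segment_ref=r.id, frame=1, peptide=r.seq, nt_offset=0)
            for r in records
        ]
    hits = search_profiles(profiles, translations, cfg.evalue_hmm)
    pep_by_ref = {(t.segment_ref, t.frame): t.peptide for t in translations}
    hit_seqs = []
    for i, h in enumerate(hits):
        pep = pep_by_ref[(h.target_id, h.frame)][h.env[0] : h.env[1]]
        if pep:
            hit_seqs.append(SequenceRecord(f"hit{i}|{h.profile}|{h.target_id}", pep, "aa"))
    clusters = (
        greedy_cluster(hit_seqs, ClusterParams(cfg.cluster_identity, "aa"))
        if hit_seqs
        else []
    )
    return clusters, hits


# ---------------------------------------------------------------------------
# GFF3 output


def calls_to_gff3(calls: list[ElementCall], genome_id: str) -> str:
    """One GFF3 feature per element copy (1-based inclusive coordinates)."""
    lines = ["##gff-version 3"]
    for call in calls:
        for i, (s, e, st, trunc) in enumerate(call.copies):
            attrs = [
                f"ID={call.call_id}.{i + 1}",
                f"call_id={call.call_id}",
                f"kind={call.kind}",
                f"evidence={','.join(sorted(call.evidence)) or '.'}",
            ]
            if call.family_annotation:
                attrs.append(f"family={call.family_annotation}")
            if call.partner:
                attrs.append(f"partner={call.partner}")
            if call.ir:
                attrs.append(f"ir_len={call.ir['arm_len']}")
            if call.dr:
                attrs.append(f"dr_len={call.dr['length']}")
            if trunc:
                attrs.append("truncated=true")
            lines.append(
                "\t".join(
                    [
                        genome_id,
                        "ismite",
                        "mobile_genetic_element",
                        str(s + 1),
                        str(e),
                        ".",
                        st,
                        ".",
                        ";".join(attrs),
                    ]
                )
            )
    return "\n".join(lines) + "\n"
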