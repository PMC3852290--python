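"""Synthetic genomes with implanted mobile elements, plus read fragmentation.

The simulator emulates the structure of prokaryotic ISs and MITEs: an
element is [IR arm] - internal sequence (optionally containing a
transposase ORF back-translated from a supplied peptide) - [reverse
complement of the IR arm]; on insertion the target-site word of ``dr_len``
bases is duplicated so the copy is flanked by direct repeats. MITE
families are built as internal deletions of their autonomous partner IS,
retaining both termini (and hence the partner's IRs), which is exactly the
structural signal the MITE-partner linking step exploits. Nested copies
("Russian dolls") are inserted inside a host family copy.

The generator emits a ground-truth record per copy; tests and the
acceptance analyses compute recall against this truth, never against an
external library. What the simulator does *not* model: sequencing error
profiles, chimeric reads, compositional skew, and real IS family diversity.

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Data import CodonTable

from .seqio import SequenceRecord, reverse_complement


@dataclass(frozen=True)
class ImplantSpec:
    family_id: str
    n_copies: int
    element_len: int
    ir_len: int = 17  # 0 for IR-less families
    dr_len: int = 5  # 0 for no target-site duplication
    transposase_source: str | None = None  # peptide; None for MITEs / orphan ISs
    mutation_rate: float = 0.0
    partner_of: str | None = None  # MITE: family id of the autonomous IS
    nested_in: str | None = None  # insert copies inside a copy of this family
    minus_fraction: float = 0.3

    def __post_init__(self):
        if self.ir_len * 2 + 50 > self.element_len:
            raise ValueError("element too short for its IRs")
        if self.dr_len > 15:
            raise ValueError("dr_len must be <= 15")
        if not (0.0 <= self.mutation_rate <= 0.2):
            raise ValueError("mutation rate must be in [0, 0.2]")


@dataclass
class TruthRecord:
    family_id: str
    kind: str  # "IS" or "MITE"
    interval: tuple[int, int]
    strand: str
    ir_len: int
    dr_len: int
    partner: str | None = None
    nested_in: str | None = None


_BASES = np.array(list("ACGT"))


def _random_nt(rng, n: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=n, p=p)])


def _codon_choices(table: int = 11) -> dict:
    tbl = CodonTable.unambiguous_dna_by_id[table]
    rev: dict[str, list[str]] = {}
    for codon, aa in tbl.forward_table.items():
        rev.setdefault(aa, []).append(codon)
    rev["*"] = sorted(tbl.stop_codons)
    for aa in rev:
        rev[aa].sort()
    return rev


def back_translate(peptide: str, rng, table: int = 11) -> str:
    """Uniform-codon back-translation (unknown residues get a random codon)."""
    rev = _codon_choices(table)
    out = []
    for aa in peptide.upper():
        codons = rev.get(aa)
        if codons is None:
            codons = rev["A"]
        out.append(codons[rng.integers(len(codons))])
    return "".join(out)


def mutate(seq: str, sub_rate: float, indel_rate: float = 0.0, seed: int = 0) -> str:
    """Apply i.i.d. per-position substitutions and indels."""
    if not (0 <= sub_rate <= 0.5 and 0 <= indel_rate <= 0.5):
        raise ValueError("rates must be in [0, 0.5]")
    rng = np.random.default_rng(seed)
    out = []
    for ch in seq:
        r = rng.random()
        if r < indel_rate / 2:
            continue  # deletion
        if r < indel_rate:
            out.append(str(_BASES[rng.integers(4)]))  # insertion before base
        if rng.random() < sub_rate and ch in "ACGT":
            alts = [b for b in "ACGT" if b != ch]
            out.append(alts[rng.integers(3)])
        else:
            out.append(ch)
    return "".join(out)


def _has_terminal_ir(element: str, window: int = 50) -> bool:
    """True when some arm pair near both termini would look like an IR
    under the default search parameters (arms >= 10, <= 2 mismatches)."""
    from .irfinder import IRParams, find_inverted_repeats
    from .seqio import SequenceRecord

    rec = SequenceRecord("m", element, "nt")
    params = IRParams(min_arm=10, max_arm=50, max_gap=len(element), max_mismatch=2)
    return any(
        p.left[0] < window and p.right[1] > len(element) - window
        for p in find_inverted_repeats(rec, params)
    )


def _make_master(spec: ImplantSpec, masters: dict, rng) -> str:
    if spec.partner_of is not None:
        partner = masters[spec.partner_of]
        keep = spec.element_len // 2
        if keep < max(spec.ir_len, 25):
            raise ValueError(f"MITE {spec.family_id}: termini too short")
        if spec.element_len >= len(partner):
            raise ValueError(f"MITE {spec.family_id}: not shorter than its partner")
        return partner[:keep] + partner[len(partner) - (spec.element_len - keep):]
    for _attempt in range(100):
        ir = _random_nt(rng, spec.ir_len) if spec.ir_len else ""
        core_len = spec.element_len - 2 * spec.ir_len
        if spec.transposase_source:
            orf = "ATG" + back_translate(spec.transposase_source, rng) + "TAA"
            if len(orf) + 20 > core_len:
                raise ValueError(f"{spec.family_id}: element too short for its ORF")
            pad = core_len - len(orf)
            left = pad // 2
            core = _random_nt(rng, left) + orf + _random_nt(rng, pad - left)
        else:
            core = _random_nt(rng, core_len)
        element = ir + core + (reverse_complement(ir) if ir else "")
        # an element declared IR-less must actually be IR-less: random
        # termini form a chance quasi-palindrome surprisingly often
        if spec.ir_len == 0 and _has_terminal_ir(element):
            continue
        return element
    raise RuntimeError(f"{spec.family_id}: could not build an IR-free element")


def simulate_genome(
    specs: list[ImplantSpec],
    background_len: int,
    gc: float = 0.5,
    seed: int = 0,
    spacing: int = 100,
) -> tuple[SequenceRecord, list[TruthRecord]]:
    """Background genome with implanted element copies and per-copy truth."""
    rng = np.random.default_rng(seed)
    bg = _random_nt(rng, background_len, gc)

    masters: dict[str, str] = {}
    for spec in specs:
        masters[spec.family_id] = _make_master(spec, masters, rng)

    top = [s for s in specs if s.nested_in is None]
    nested = [s for s in specs if s.nested_in is not None]

    n_sites = sum(s.n_copies for s in top)
    if (n_sites + 1) * spacing >= background_len:
        raise ValueError("implants do not fit in the background")
    sites: list[int] = []
    margin = spacing
    for _ in range(20000):
        if len(sites) == n_sites:
            break
        p = int(rng.integers(margin, background_len - margin))
        if all(abs(p - q) >= spacing for q in sites):
            sites.append(p)
    if len(sites) < n_sites:
        raise ValueError("could not place implants with the required spacing")

    placements = []  # (site, spec, copy_seq, strand)
    i = 0
    for spec in top:
        for c in range(spec.n_copies):
            elem = masters[spec.family_id]
            if spec.mutation_rate > 0:
                elem = mutate(elem, spec.mutation_rate, 0.0,
                              seed=int(rng.integers(2**31 - 1)))
            strand = "-" if rng.random() < spec.minus_fraction else "+"
            if strand == "-":
                elem = reverse_complement(elem)
            placements.append((sites[i], spec, elem, strand))
            i += 1
    placements.sort(key=lambda t: t[0])

    pieces = []
    truth: list[TruthRecord] = []
    prev = 0
    out_len = 0
    for site, spec, elem, strand in placements:
        dr = spec.dr_len
        pieces.append(bg[prev : site + dr])
        out_len += site + dr - prev
        start = out_len
        pieces.append(elem)
        out_len += len(elem)
        kind = "MITE" if spec.partner_of is not None else "IS"
        truth.append(
            TruthRecord(spec.family_id, kind, (start, out_len), strand,
                        spec.ir_len, dr, partner=spec.partner_of)
        )
        prev = site  # re-emit the DR word after the element
    pieces.append(bg[prev:])
    genome = "".join(pieces)

    # nested copies go inside a host family copy
    for spec in nested:
        hosts = [t for t in truth if t.family_id == spec.nested_in]
        if not hosts:
            raise ValueError(f"no host copies for nested family {spec.family_id}")
        for c in range(spec.n_copies):
            host = hosts[int(rng.integers(len(hosts)))]
            hs, he = host.interval
            inner_margin = spec.dr_len + 10 + host.ir_len
            if he - hs <= 2 * inner_margin:
                raise ValueError("host copy too short for nesting")
            p = int(rng.integers(hs + inner_margin, he - inner_margin))
            elem = masters[spec.family_id]
            if spec.mutation_rate > 0:
                elem = mutate(elem, spec.mutation_rate, 0.0,
                              seed=int(rng.integers(2**31 - 1)))
            strand = "-" if rng.random() < spec.minus_fraction else "+"
            if strand == "-":
                elem = reverse_complement(elem)
            dr = spec.dr_len
            ins = elem + genome[p : p + dr]
            genome = genome[: p + dr] + ins + genome[p + dr :]
            ins_len = len(ins)
            for t in truth:
                s, e = t.interval
                if s >= p + dr:
                    t.interval = (s + ins_len, e + ins_len)
                elif e > p:
                    t.interval = (s, e + ins_len)
            kind = "MITE" if spec.partner_of is not None else "IS"
            truth.append(
                TruthRecord(spec.family_id, kind, (p + dr, p + dr + len(elem)), strand,
                            spec.ir_len, dr, partner=spec.partner_of,
                            nested_in=spec.nested_in)
            )

    truth.sort(key=lambda t: t.interval)
    return SequenceRecord("simgenome", genome, "nt"), truth


def fragment_genome(
    rec: SequenceRecord,
    read_len: int,
    seed: int = 0,
    mode: str = "tiling",
    n_reads: int | None = None,
) -> list[SequenceRecord]:
    """Fragment a genome into reads; ids encode the source coordinates.

    ``tiling`` emits consecutive non-overlapping windows (last truncated);
    ``uniform`` draws ``n_reads`` windows at uniform random starts.
    """
    if read_len <= 0:
        raise ValueError("read_len must be positive")
    n = len(rec.seq)
    if read_len > n:
        raise ValueError("read_len exceeds genome length")
    reads = []
    if mode == "tiling":
        for s in range(0, n, read_len):
            e = min(s + read_len, n)
            if e - s >= 20:  # skip unusably short tail
                reads.append(SequenceRecord(f"{rec.id}|{s}-{e}", rec.seq[s:e], "nt"))
    elif mode == "uniform":
        rng = np.random.default_rng(seed)
        if n_reads is None:
            n_reads = n // read_len
        for _ in range(n_reads):
            s = int(rng.integers(0, n - read_len + 1))
            reads.append(SequenceRecord(f"{rec.id}|{s}-{s + read_len}", rec.seq[s : s + read_len], "nt"))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return reads
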