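"""Reference benchmark scenarios built on the synthetic-data generator.

These fix the study conditions used by the acceptance analyses and the
heavier integration tests: a 300 kb genome carrying four IS families
(with and without terminal IRs, exact and 5%-diverged copies) plus two
MITE families with autonomous partners, and an IS-rich genome for the
read-length (metagenome) recall experiment. Everything is deterministic
given the seed.
"""

from __future__ import annotations

import numpy as np

from .pipelines import ElementCall
from .profilehmm import ProfileHMM, build_profile, calibrate
from .seqio import MSARow, SequenceRecord
from .simdata import ImplantSpec, simulate_genome

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def random_peptide(rng, n: int) -> str:
    return "M" + "".join(np.array(list(AA20))[rng.integers(0, 20, n - 1)])


def synthetic_family_msa(rng, master: str, n_rows: int = 60, divergence: float = 0.10):
    """Gap-free MSA of diverged variants of a master peptide."""
    rows = []
    aa = np.array(list(AA20))
    for i in range(n_rows):
        s = list(master)
        for j in range(len(s)):
            if rng.random() < divergence:
                s[j] = str(aa[rng.integers(20)])
        rows.append(MSARow(f"s{i}", "".join(s)))
    return rows


def denovo_scenario(seed: int):
    """300 kb genome, 4 IS families + 2 partnered MITE families.

    Families: is1 (IRs, transposase, exact), is2 (no IRs, transposase,
    exact), is3 (IRs, transposase, 5% per-copy divergence), is4 (IRs, no
    recognisable transposase, 5% divergence); mite1 partners is1, mite2
    partners is3. Returns (genome, truth, transposase_library, specs).
    """
    rng = np.random.default_rng(seed)
    tnp1 = random_peptide(rng, 150)
    tnp2 = random_peptide(rng, 160)
    tnp3 = random_peptide(rng, 140)
    specs = [
        ImplantSpec("is1", n_copies=5, element_len=1200, ir_len=17, dr_len=5,
                    transposase_source=tnp1),
        ImplantSpec("is2", n_copies=3, element_len=900, ir_len=0, dr_len=0,
                    transposase_source=tnp2),
        ImplantSpec("is3", n_copies=8, element_len=700, ir_len=24, dr_len=8,
                    transposase_source=tnp3, mutation_rate=0.05),
        ImplantSpec("is4", n_copies=4, element_len=1500, ir_len=12, dr_len=0,
                    mutation_rate=0.05),
        ImplantSpec("mite1", n_copies=7, element_len=250, ir_len=17, dr_len=5,
                    partner_of="is1"),
        ImplantSpec("mite2", n_copies=5, element_len=300, ir_len=24, dr_len=8,
                    partner_of="is3"),
    ]
    genome, truth = simulate_genome(
        specs, background_len=300_000, seed=int(rng.integers(2**31 - 1))
    )
    lib = [
        SequenceRecord("tnp1|IS3", tnp1, "aa"),
        SequenceRecord("tnp2|IS200", tnp2, "aa"),
        SequenceRecord("tnp3|IS5", tnp3, "aa"),
    ]
    return genome, truth, lib, specs


MUTATED_FAMILIES = {"is3", "is4"}
EXACT_FAMILIES = {"is1", "is2", "mite1", "mite2"}
IRLESS_FAMILIES = {"is2"}


def family_recovery(calls: list[ElementCall], truth) -> dict[str, bool]:
    """Which implanted families have >= 1 call covering >= 1 copy well."""
    recovered = {t.family_id: False for t in truth}
    for t in truth:
        ts, te = t.interval
        for c in calls:
            for s, e, _st, _tr in c.copies:
                ov = min(te, e) - max(ts, s)
                if ov > 0.8 * (te - ts) and ov > 0.5 * (e - s):
                    recovered[t.family_id] = True
    return recovered


def partner_links_correct(calls: list[ElementCall], truth) -> int:
    """Count MITE families whose call links to an IS call overlapping the
    true partner family's copies."""
    by_id = {c.call_id: c for c in calls}
    mite_truth = {}
    for t in truth:
        if t.kind == "MITE":
            mite_truth.setdefault(t.family_id, t)
    partner_loci = {}
    for t in truth:
        partner_loci.setdefault(t.family_id, []).append(t.interval)
    correct = set()
    for fam, t in mite_truth.items():
        want = partner_loci.get(t.partner, [])
        for c in calls:
            if not c.kind == "MITE" or c.partner is None:
                continue
            # this MITE call must cover the family's copies
            covers = any(
                min(te, e) - max(ts, s) > 0.8 * (te - ts)
                for tr in truth
                if tr.family_id == fam
                for ts, te in [tr.interval]
                for s, e, _st, _x in c.copies
            )
            if not covers:
                continue
            p = by_id.get(c.partner)
            if p is None:
                continue
            hit = any(
                min(we, e) - max(ws, s) > 0.5 * (we - ws)
                for ws, we in want
                for s, e, _st, _x in p.copies
            )
            if hit:
                correct.add(fam)
    return len(correct)


def hmm_scenario(seed: int, n_copies: int = 12, background_len: int = 60_000):
    """IS-rich genome plus a calibrated profile for its transposase family.

    The profile is trained on a 10%-diverged synthetic MSA, not on the
    implanted master itself, so detection is non-trivial.
    """
    rng = np.random.default_rng(seed)
    master = random_peptide(rng, 150)
    rows = synthetic_family_msa(rng, master, n_rows=60, divergence=0.10)
    hmm = calibrate(
        build_profile(rows, name="tnp"),
        n_random=1500,
        seed=int(rng.integers(2**31 - 1)),
    )
    # the implanted transposases are distant relatives (~50% identity) of
    # the profile's training family, the regime where read length governs
    # detection: short windows carry too little signal, long ones enough
    aa = np.array(list(AA20))
    implanted = "".join(
        str(aa[rng.integers(20)]) if rng.random() < 0.5 else ch for ch in master
    )
    specs = [
        ImplantSpec("isH", n_copies=n_copies, element_len=700, ir_len=14, dr_len=4,
                    transposase_source=implanted, minus_fraction=0.4),
    ]
    genome, truth = simulate_genome(
        specs, background_len=background_len, seed=int(rng.integers(2**31 - 1))
    )
    return genome, truth, hmm


def hmm_recall(genome, truth, hmm: ProfileHMM, read_len: int | None,
               min_overlap: int = 60) -> float:
    """Fraction of implanted copies overlapped by a profile hit.

    ``read_len`` None scores the whole genome through the segmentation
    path; otherwise the genome is tiled into reads of that length first.
    """
    from .pipelines import run_hmm_pipeline
    from .simdata import fragment_genome

    records = [genome] if read_len is None else fragment_genome(genome, read_len)
    _clusters, hits = run_hmm_pipeline(records, [hmm])
    ivs = []
    for h in hits:
        iv = hit_genome_interval(h)
        if iv is not None:
            ivs.append(iv)
    found = 0
    for t in truth:
        s, e = t.interval
        if any(min(e, b) - max(s, a) > min_overlap for a, b in ivs):
            found += 1
    return found / len(truth) if truth else 0.0


def hit_genome_interval(hit) -> tuple[int, int] | None:
    """Absolute genome interval of a profile hit, resolving nested
    coordinate-bearing ids (read ids and segment ids both encode spans)."""
    from .profilehmm import _hit_genome_interval

    iv = _hit_genome_interval(hit)
    if iv is None:
        return None
    parent, a, b = iv
    while "|" in parent:
        head, _, span = parent.rpartition("|")
        try:
            s, _e = (int(x) for x in span.split("-"))
        except ValueError:
            break
        a += s
        b += s
        parent = head
    return a, b


def shuffled_control(genome: SequenceRecord, seed: int, length: int = 60_000) -> SequenceRecord:
    """Element-free control: a column shuffle of a slice of the genome."""
    rng = np.random.default_rng(seed)
    arr = np.frombuffer(genome.seq[:length].encode(), dtype=np.uint8).copy()
    rng.shuffle(arr)
    return SequenceRecord(f"shuffled{seed}", arr.tobytes().decode(), "nt")
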