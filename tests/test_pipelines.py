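import numpy as np
import pytest

from ismite.cluster import Cluster, pairwise_identity
from ismite.pipelines import (
    ElementCall,
    PipelineConfig,
    calls_to_gff3,
    expand_is_copies,
    filter_known_non_te,
    link_mite_partners,
    match_word,
    run_hmm_pipeline,
    run_ir_search,
    run_repeats_search,
    separate_nested,
    split_by_size,
)
from ismite.seqio import SequenceRecord, reverse_complement
from ismite.simdata import ImplantSpec, fragment_genome, simulate_genome
from .conftest import AA20, random_peptide

BASES = np.array(list("ACGT"))


def rand_nt(rng, n):
    return "".join(BASES[rng.integers(0, 4, n)])


def mk_cluster(seq, ident="c"):
    rec = SequenceRecord(ident, seq, "nt")
    return Cluster(centroid=rec, members=[(rec, 1.0)])


class TestSplitBySize:
    @pytest.mark.parametrize(
        "length,branch", [(501, "is"), (499, "mite"), (500, "mite")]
    )
    def test_boundary_assignment(self, length, branch):
        rng = np.random.default_rng(0)
        cl = mk_cluster(rand_nt(rng, length))
        is_c, mite_c = split_by_size([cl])
        assert (len(is_c), len(mite_c)) == ((1, 0) if branch == "is" else (0, 1))


class TestExpandISCopies:
    def test_truncated_copy_flagged(self):
        rng = np.random.default_rng(1)
        elem = rand_nt(rng, 900)
        parts = [rand_nt(rng, 2000)]
        for _ in range(4):
            parts += [elem, rand_nt(rng, 2000)]
        parts += [elem[: 900 // 2], rand_nt(rng, 2000)]  # 5' half copy
        genome = SequenceRecord("g", "".join(parts), "nt")
        call = expand_is_copies(SequenceRecord("cons", elem, "nt"), genome)
        assert len(call.copies) == 5
        truncated = [c for c in call.copies if c[3]]
        assert len(truncated) == 1
        s, e, _, _ = truncated[0]
        assert e - s < 0.9 * 900

    def test_overlapping_hits_merge(self):
        intervals = [(100, 300, "+"), (290, 500, "+"), (600, 700, "-")]
        from ismite.pipelines import _merge_intervals

        merged = _merge_intervals(intervals)
        assert merged == [(100, 500, "+"), (600, 700, "-")]

    def test_single_copy_retained(self):
        rng = np.random.default_rng(2)
        elem = rand_nt(rng, 800)
        genome = SequenceRecord(
            "g", rand_nt(rng, 3000) + elem + rand_nt(rng, 3000), "nt"
        )
        call = expand_is_copies(SequenceRecord("cons", elem, "nt"), genome)
        assert len(call.copies) == 1


class TestSeparateNested:
    def test_two_level_reconstruction_identical_to_intact(self):
        rng = np.random.default_rng(3)
        A = rand_nt(rng, 900)
        B = rand_nt(rng, 400)
        cut = 450
        interrupted = A[:cut] + B + A[cut:]
        genome = SequenceRecord(
            "g",
            rand_nt(rng, 500) + interrupted + rand_nt(rng, 500) + A + rand_nt(rng, 500),
            "nt",
        )
        outer = (500, 500 + len(interrupted))
        inner = (500 + cut, 500 + cut + 400)
        out = dict(separate_nested([outer, inner], genome))
        assert out[outer] == A  # 100% identical reconstruction
        assert out[inner] == B

    def test_non_overlapping_pass_through(self):
        rng = np.random.default_rng(4)
        g = SequenceRecord("g", rand_nt(rng, 2000), "nt")
        ivs = [(100, 400), (900, 1400)]
        out = separate_nested(ivs, g)
        assert [seq for _iv, seq in out] == [g.seq[100:400], g.seq[900:1400]]

    def test_three_level_russian_dolls(self):
        rng = np.random.default_rng(5)
        C = rand_nt(rng, 200)
        B0 = rand_nt(rng, 500)
        A0 = rand_nt(rng, 1000)
        B = B0[:250] + C + B0[250:]
        A = A0[:400] + B + A0[400:]
        genome = SequenceRecord("g", rand_nt(rng, 300) + A + rand_nt(rng, 300), "nt")
        a = (300, 300 + len(A))
        b = (700, 700 + len(B))
        c = (700 + 250, 700 + 250 + 200)
        out = dict(separate_nested([a, b, c], genome))
        assert out[a] == A0  # B (and C inside it) excised
        assert out[b] == B0
        assert out[c] == C


class TestMatchWord:
    def test_exact_and_mismatch_tolerance(self):
        genome = "AAAA" + "ACGTACGTACGTACGTACGTACG" + "TTTT"
        word = "ACGTACGTACGTACGTACGTACG"
        assert match_word(genome, word, 0) == [4]
        one_off = "ACGTACGTACGTACGTACGTACC"
        assert match_word(genome, one_off, 0) == []
        assert match_word(genome, one_off, 1) == [4]


class TestMitePartnerLinking:
    def test_partner_found_on_simulated_genome(self, sim_denovo):
        genome, truth, lib, _specs = sim_denovo
        mite_truth = next(t for t in truth if t.kind == "MITE")
        s, e = mite_truth.interval
        mite = mk_cluster(genome.seq[s:e], "mite")
        mcall, partner = link_mite_partners(mite, genome, lib)
        assert mcall is not None and mcall.kind == "MITE"
        assert partner is not None and partner.kind == "IS"
        assert mcall.partner == partner.call_id
        assert partner.family_annotation == "IS3"
        assert len(partner.consensus) > len(mcall.consensus)

    def test_orphan_when_termini_match_nowhere(self):
        rng = np.random.default_rng(6)
        genome = SequenceRecord("g", rand_nt(rng, 20_000), "nt")
        mite_seq = rand_nt(rng, 200)
        # implant two exact copies so the MITE itself is multi-copy
        g = genome.seq[:5000] + mite_seq + genome.seq[5000:10_000] + mite_seq + genome.seq[10_000:]
        genome = SequenceRecord("g", g, "nt")
        mcall, partner = link_mite_partners(mk_cluster(mite_seq, "m"), genome, [])
        assert partner is None
        assert mcall.kind == "MITE_like_orphan"

    def test_short_centroid_rejected(self):
        rng = np.random.default_rng(7)
        genome = SequenceRecord("g", rand_nt(rng, 1000), "nt")
        mcall, partner = link_mite_partners(mk_cluster("ACGTACGT" * 5, "m"), genome, [])
        assert mcall is None and partner is None

    def test_partner_interval_above_3kb_excluded(self):
        rng = np.random.default_rng(8)
        term5 = rand_nt(rng, 23)
        term3 = rand_nt(rng, 23)
        mite_seq = term5 + rand_nt(rng, 100) + term3
        # termini re-occur spanning 3.2 kb; no partner should be formed
        g = (
            rand_nt(rng, 2000) + mite_seq + rand_nt(rng, 1000) + mite_seq
            + rand_nt(rng, 1000) + term5 + rand_nt(rng, 3200) + term3 + rand_nt(rng, 2000)
        )
        genome = SequenceRecord("g", g, "nt")
        mcall, partner = link_mite_partners(mk_cluster(mite_seq, "m"), genome, [])
        assert partner is None


class TestFilterKnownNonTE:
    def _call(self, seq, fam_e=None):
        return ElementCall("c1", "IS", seq, [(0, len(seq), "+", False)], family_evalue=fam_e)

    def test_decoy_integrase_removed(self):
        rng = np.random.default_rng(9)
        decoy_pep = random_peptide(rng, 220)
        from ismite.simdata import back_translate

        orf = back_translate(decoy_pep, rng)
        call = self._call(rand_nt(rng, 60) + orf + rand_nt(rng, 60))
        decoys = [SequenceRecord("intA|integrase", decoy_pep, "aa")]
        kept, removed = filter_known_non_te([call], decoys)
        assert kept == [] and removed == [call]

    def test_stronger_transposase_hit_wins(self):
        rng = np.random.default_rng(10)
        decoy_pep = random_peptide(rng, 80)
        from ismite.simdata import back_translate

        orf = back_translate(decoy_pep, rng)
        call = self._call(rand_nt(rng, 60) + orf + rand_nt(rng, 60), fam_e=1e-60)
        decoys = [SequenceRecord("d", decoy_pep, "aa")]
        kept, removed = filter_known_non_te([call], decoys)
        assert kept == [call] and removed == []

    def test_empty_decoy_passthrough(self):
        rng = np.random.default_rng(11)
        call = self._call(rand_nt(rng, 300))
        kept, removed = filter_known_non_te([call], [])
        assert kept == [call] and removed == []


def _match_truth(calls, truth, genome):
    """Map implanted families to calls by copy-interval overlap."""
    recovered = {}
    for t in truth:
        ts, te = t.interval
        for c in calls:
            for s, e, _st, _tr in c.copies:
                ov = min(te, e) - max(ts, s)
                if ov > 0.8 * (te - ts) and ov > 0.5 * (e - s):
                    recovered.setdefault(t.family_id, set()).add(c.call_id)
    return recovered


class TestDeNovoWorkflows:
    def test_repeats_search_recovers_all_multicopy_families(self, sim_denovo):
        genome, truth, lib, _ = sim_denovo
        calls = run_repeats_search(genome, lib)
        rec = _match_truth(calls, truth, genome)
        assert {"isA", "isB", "miteA"} <= set(rec)
        assert all(c.evidence == {"repeats"} for c in calls)
        kinds = {c.call_id: c.kind for c in calls}
        mite_calls = [cid for cid in rec["miteA"] if kinds[cid].startswith("MITE")]
        assert mite_calls

    def test_ir_search_skips_irless_family_links_mite(self, sim_denovo):
        genome, truth, lib, _ = sim_denovo
        calls = run_ir_search(genome, lib)
        rec = _match_truth(calls, truth, genome)
        assert "isA" in rec
        assert "isB" not in rec  # no terminal IRs -> invisible to this path
        mite_call = next(c for c in calls if c.kind == "MITE")
        assert mite_call.partner is not None
        assert mite_call.ir is not None and mite_call.ir["arm_len"] >= 17
        partner = next(c for c in calls if c.call_id == mite_call.partner)
        assert partner.kind == "IS" and partner.family_annotation == "IS3"

    def test_element_free_genome_no_calls(self):
        rng = np.random.default_rng(77)
        genome = SequenceRecord("g", rand_nt(rng, 50_000), "nt")
        assert run_repeats_search(genome, []) == []
        assert run_ir_search(genome, []) == []

    def test_determinism(self, sim_denovo):
        genome, _, lib, _ = sim_denovo
        r1 = run_repeats_search(genome, lib)
        r2 = run_repeats_search(genome, lib)
        key = lambda calls: [(c.call_id, c.kind, c.consensus, c.copies) for c in calls]
        assert key(r1) == key(r2)

    def test_gff3_output_shape(self, sim_denovo):
        genome, _, lib, _ = sim_denovo
        calls = run_repeats_search(genome, lib)
        gff = calls_to_gff3(calls, genome.id)
        lines = [l for l in gff.splitlines() if l and not l.startswith("#")]
        assert len(lines) == sum(len(c.copies) for c in calls)
        for l in lines:
            cols = l.split("\t")
            assert len(cols) == 9
            assert int(cols[3]) >= 1 and int(cols[4]) <= len(genome.seq)


@pytest.fixture(scope="module")
def hmm_genome(tx_family):
    master, _rows = tx_family
    specs = [
        ImplantSpec("isH", n_copies=6, element_len=700, ir_len=14, dr_len=4,
                    transposase_source=master, minus_fraction=0.4),
    ]
    return simulate_genome(specs, background_len=40_000, seed=21)


class TestHMMPipeline:
    def test_genome_hits_cover_implanted_transposases(self, hmm_genome, tx_profile):
        genome, truth = hmm_genome
        clusters, hits = run_hmm_pipeline([genome], [tx_profile])
        from ismite.profilehmm import _hit_genome_interval

        hit_ivs = [_hit_genome_interval(h) for h in hits]
        found = 0
        for t in truth:
            s, e = t.interval
            if any(iv and min(e, iv[2]) - max(s, iv[1]) > 100 for iv in hit_ivs):
                found += 1
        assert found >= 5  # at least 5 of 6 copies
        assert clusters and sum(len(c.members) for c in clusters) == len(hits)

    def test_peptide_input_path(self, tx_profile, tx_family):
        master, _ = tx_family
        rng = np.random.default_rng(1)
        peps = [SequenceRecord("p1", master, "aa"),
                SequenceRecord("p2", random_peptide(rng, 300), "aa")]
        clusters, hits = run_hmm_pipeline(peps, [tx_profile])
        assert {h.target_id for h in hits} == {"p1"}

    def test_read_length_recall_ordering(self, hmm_genome, tx_profile):
        genome, truth = hmm_genome
        from ismite.profilehmm import _hit_genome_interval

        def recall(read_len):
            reads = fragment_genome(genome, read_len)
            _cl, hits = run_hmm_pipeline(reads, [tx_profile])
            ivs = []
            for h in hits:
                parent, _, span = h.target_id.partition("|")
                iv = _hit_genome_interval(h)
                if iv:
                    ivs.append((iv[1], iv[2]))
            found = 0
            for t in truth:
                s, e = t.interval
                if any(min(e, b) - max(s, a) > 60 for a, b in ivs):
                    found += 1
            return found / len(truth)

        r1000, r250, r100 = recall(1000), recall(250), recall(100)
        assert r1000 >= r250 >= r100

    def test_mixed_alphabet_rejected(self, tx_profile):
        with pytest.raises(ValueError):
            run_hmm_pipeline(
                [SequenceRecord("a", "ACGT", "nt"), SequenceRecord("b", "MKLV", "aa")],
                [tx_profile],
            )
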