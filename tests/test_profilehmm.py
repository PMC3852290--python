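import math

import numpy as np
import pytest
from scipy.stats import gumbel_r

from ismite.profilehmm import (
    ProfileHMM,
    build_profile,
    calibrate,
    fit_gumbel,
    forward_score,
    read_profile,
    search_profiles,
    viterbi_score,
    write_profile,
)
from ismite.seqio import FrameTranslation, MSARow
from .oracles import AA20, enumerate_profile_scores


def toy_hmm(rng, K=3):
    """A small random (but normalised) profile for oracle comparison."""

    def dirich(shape):
        x = rng.gamma(1.0, size=shape)
        return x / x.sum(axis=-1, keepdims=True)

    return ProfileHMM(
        "toy",
        K,
        match_emissions=dirich((K, 20)),
        insert_emissions=dirich((K + 1, 20)),
        t_match=dirich((K + 1, 3)),
        t_insert=dirich((K + 1, 2)),
        t_delete=dirich((K + 1, 2)),
        background=np.full(20, 1 / 20),
    )


class TestBuildProfile:
    def test_gapfree_identical_rows(self):
        rows = [MSARow(f"s{i}", "MKLVN") for i in range(10)]
        hmm = build_profile(rows)
        assert hmm.K == 5
        for k, aa in enumerate("MKLVN"):
            assert np.argmax(hmm.match_emissions[k]) == AA20.index(aa)

    def test_half_gap_column_is_insert(self):
        rows = [MSARow(f"s{i}", "MK-V") for i in range(5)] + [
            MSARow(f"t{i}", "MKAV") for i in range(5)
        ]
        hmm = build_profile(rows)
        assert hmm.K == 3  # the 50%-gap column does not become a match state

    def test_rows_normalised(self, tx_profile):
        for arr in (
            tx_profile.match_emissions,
            tx_profile.insert_emissions,
            tx_profile.t_match,
            tx_profile.t_insert,
            tx_profile.t_delete,
        ):
            assert np.allclose(arr.sum(axis=1), 1.0, atol=1e-9)

    def test_ragged_and_single_sequence_rejected(self):
        with pytest.raises(ValueError):
            build_profile([MSARow("a", "MK"), MSARow("b", "MKL")])
        with pytest.raises(ValueError):
            build_profile([MSARow("a", "MKL")])


class TestScoringAgainstEnumeration:
    @pytest.mark.parametrize("K,n,seed", [(1, 3, 0), (2, 4, 1), (3, 5, 2), (4, 5, 3), (4, 6, 4)])
    def test_viterbi_and_forward_equal_exhaustive_enumeration(self, K, n, seed):
        rng = np.random.default_rng(seed)
        hmm = toy_hmm(rng, K)
        pep = "".join(np.array(list(AA20))[rng.integers(0, 20, n)])
        v_oracle, f_oracle = enumerate_profile_scores(hmm, pep)
        v, _env = viterbi_score(hmm, pep)
        f = forward_score(hmm, pep)
        assert v == pytest.approx(v_oracle, abs=1e-9)
        assert f == pytest.approx(f_oracle, abs=1e-9)

    def test_forward_at_least_viterbi(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            hmm = toy_hmm(rng, int(rng.integers(1, 5)))
            pep = "".join(np.array(list(AA20))[rng.integers(0, 20, int(rng.integers(1, 8)))])
            assert forward_score(hmm, pep) >= viterbi_score(hmm, pep)[0] - 1e-12

    def test_modal_peptide_scores_near_closed_form(self, tx_profile):
        # near-deterministic columns: modal-residue peptide ~ sum of per-state
        # modal log-odds plus M->M transitions and entry/exit terms
        hmm = tx_profile
        modal = "".join(AA20[int(np.argmax(row))] for row in hmm.match_emissions)
        closed = (
            sum(math.log2(row.max() / (1 / 20)) for row in hmm.match_emissions)
            + sum(math.log2(hmm.t_match[k][0]) for k in range(1, hmm.K))
            - 2 * math.log2(hmm.K)
        )
        v, env = viterbi_score(hmm, modal)
        assert env == (0, hmm.K)
        assert v >= closed - 1e-6  # the DP may do better via another path

    def test_envelope_locates_embedded_motif(self, tx_profile, tx_family):
        master, _ = tx_family
        rng = np.random.default_rng(33)
        flank1 = "".join(np.array(list(AA20))[rng.integers(0, 20, 40)])
        flank2 = "".join(np.array(list(AA20))[rng.integers(0, 20, 55)])
        pep = flank1 + master + flank2
        _, (s, e) = viterbi_score(tx_profile, pep)
        assert abs(s - 40) <= 3 and abs(e - (40 + len(master))) <= 3


class TestCalibration:
    def test_gumbel_ml_recovers_parameters(self):
        mu, lam = 3.0, 0.7
        errs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            x = gumbel_r.rvs(loc=mu, scale=1 / lam, size=10_000, random_state=rng)
            mu_hat, lam_hat = fit_gumbel(x)
            errs.append(max(abs(mu_hat - mu) / mu, abs(lam_hat - lam) / lam))
            # cross-check against scipy's independent ML fit
            loc_s, scale_s = gumbel_r.fit(x)
            assert mu_hat == pytest.approx(loc_s, rel=1e-3)
            assert 1 / lam_hat == pytest.approx(scale_s, rel=1e-3)
        assert max(errs) < 0.05

    def test_calibration_deterministic(self, tx_family):
        _, rows = tx_family
        hmm = build_profile(rows, name="t")
        c1 = calibrate(hmm, n_random=150, seed=5).calib
        c2 = calibrate(hmm, n_random=150, seed=5).calib
        assert c1 == c2

    def test_evalue_monotone_decreasing(self, tx_profile):
        evs = [tx_profile.evalue(s, 600) for s in np.linspace(-5, 60, 40)]
        assert all(a > b for a, b in zip(evs, evs[1:]))

    def test_degenerate_scores_rejected(self):
        with pytest.raises(ValueError):
            fit_gumbel(np.full(500, 1.0))


class TestSearchProfiles:
    def test_training_consensus_found_in_frame(self, tx_profile, tx_family):
        master, _ = tx_family
        rng = np.random.default_rng(12)
        from ismite.simdata import back_translate
        from ismite.seqio import six_frame_translate

        bases = np.array(list("ACGT"))
        nt = (
            "".join(bases[rng.integers(0, 4, 100)])
            + back_translate(master, rng)
            + "".join(bases[rng.integers(0, 4, 101)])
        )
        frames = six_frame_translate(nt, segment_ref="seg|0-651")
        hits = search_profiles([tx_profile], frames, evalue_max=1e-5)
        assert hits
        assert hits[0].frame == 1 + (100 % 3)
        assert hits[0].evalue <= 1e-5

    def test_reversed_peptides_score_nothing(self, tx_profile):
        rng = np.random.default_rng(13)
        null = 0
        trials = 30
        for i in range(trials):
            pep = "".join(np.array(list(AA20))[rng.integers(0, 20, 300)])[::-1]
            tr = FrameTranslation(f"r{i}", 1, pep, 0)
            if not search_profiles([tx_profile], [tr], evalue_max=1e-5):
                null += 1
        assert null >= trials - 1

    def test_profile_order_invariance(self, tx_profile, tx_family):
        master, rows = tx_family
        other = calibrate(build_profile(rows[:30], name="other"), n_random=150, seed=3)
        tr = FrameTranslation("t", 1, master, 0)
        h1 = search_profiles([tx_profile, other], [tr], evalue_max=1.0)
        h2 = search_profiles([other, tx_profile], [tr], evalue_max=1.0)
        assert [(h.profile, h.bits) for h in h1] == [(h.profile, h.bits) for h in h2]

    def test_uncalibrated_profile_rejected(self, tx_family):
        _, rows = tx_family
        hmm = build_profile(rows, name="raw")
        with pytest.raises(ValueError):
            search_profiles([hmm], [FrameTranslation("t", 1, "MKLV", 0)])


class TestSerialization:
    def test_roundtrip_lossless(self, tx_profile, tmp_path):
        p = tmp_path / "x.profile"
        write_profile(tx_profile, p)
        back = read_profile(p)
        assert back.name == tx_profile.name and back.K == tx_profile.K
        for a, b in (
            (back.match_emissions, tx_profile.match_emissions),
            (back.insert_emissions, tx_profile.insert_emissions),
            (back.t_match, tx_profile.t_match),
            (back.t_insert, tx_profile.t_insert),
            (back.t_delete, tx_profile.t_delete),
        ):
            assert np.allclose(a, b, rtol=1e-11, atol=1e-13)
        assert back.calib.mu == pytest.approx(tx_profile.calib.mu, rel=1e-11)
        assert back.calib.lambda_gumbel == pytest.approx(
            tx_profile.calib.lambda_gumbel, rel=1e-11
        )
        # scoring is unchanged after a round trip
        pep = "MKLVNQERTA"
        assert viterbi_score(back, pep)[0] == pytest.approx(
            viterbi_score(tx_profile, pep)[0], abs=1e-9
        )
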