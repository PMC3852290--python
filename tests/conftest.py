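from __future__ import annotations

import numpy as np
import pytest

from ismite.profilehmm import build_profile, calibrate
from ismite.seqio import MSARow, SequenceRecord
from ismite.simdata import ImplantSpec, simulate_genome

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def random_peptide(rng, n: int) -> str:
    return "".join(np.array(list(AA20))[rng.integers(0, 20, n)])


def mutate_peptide(rng, pep: str, rate: float) -> str:
    out = []
    for ch in pep:
        if rng.random() < rate:
            out.append(AA20[rng.integers(20)])
        else:
            out.append(ch)
    return "".join(out)


@pytest.fixture(scope="session")
def tx_family():
    """A synthetic transposase family: master peptide + 60-row MSA.

    Rows are gap-free 10%-diverged variants of the master, so the MSA is
    trivially aligned and the profile's match states track the master.
    """
    rng = np.random.default_rng(4242)
    master = "M" + random_peptide(rng, 149)
    rows = [MSARow(f"s{i}", mutate_peptide(rng, master, 0.10)) for i in range(60)]
    return master, rows


@pytest.fixture(scope="session")
def tx_profile(tx_family):
    master, rows = tx_family
    hmm = build_profile(rows, name="tnpA")
    return calibrate(hmm, n_random=600, len_mean=200.0, len_sd=60.0, seed=7)


@pytest.fixture(scope="session")
def tx_library(tx_family):
    master, _ = tx_family
    return [SequenceRecord("tnpA|IS3", master, "aa")]


@pytest.fixture(scope="session")
def sim_denovo():
    """A small genome with one multi-copy IS (with IRs + transposase), one
    IR-less IS, and one MITE family partnered to the first IS."""
    rng = np.random.default_rng(99)
    master = "M" + "".join(np.array(list(AA20))[rng.integers(0, 20, 149)])
    specs = [
        ImplantSpec("isA", n_copies=4, element_len=800, ir_len=17, dr_len=5,
                    transposase_source=master, minus_fraction=0.25),
        ImplantSpec("isB", n_copies=3, element_len=700, ir_len=0, dr_len=0,
                    minus_fraction=0.0),
        ImplantSpec("miteA", n_copies=6, element_len=220, ir_len=17, dr_len=5,
                    partner_of="isA", minus_fraction=0.0),
    ]
    genome, truth = simulate_genome(specs, background_len=60_000, seed=11)
    lib = [SequenceRecord("tnpSim|IS3", master, "aa")]
    return genome, truth, lib, specs
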