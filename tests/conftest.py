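import numpy as np
import pytest

from structsieve.msa_engine import MultipleAlignment
from structsieve.structure_io import CaTrace
from structsieve.synthetic_fixtures import (
    default_core_mask,
    make_core_loop_ensemble,
    make_template,
    random_rigid_motion,
)

# Handcrafted two-chain PDB: chain A has 3 residues (residue 2 with altLocs),
# chain B has 2; plus a water, a hydrogen and a CA-less ligand to be skipped.
TWO_CHAIN_PDB = """\
ATOM      1  N   LEU A   1      11.104   6.134  -6.504  1.00 20.00           N
ATOM      2  CA  LEU A   1      11.639   6.071  -5.147  1.00 20.00           C
ATOM      3  C   LEU A   1      12.489   7.292  -4.846  1.00 20.00           C
ATOM      4  O   LEU A   1      13.030   7.915  -5.759  1.00 20.00           O
ATOM      5  CB  LEU A   1      12.448   4.789  -4.966  1.00 20.00           C
ATOM      6  CG  LEU A   1      11.672   3.485  -5.121  1.00 20.00           C
ATOM      7  N   GLY A   2      12.611   7.638  -3.566  1.00 20.00           N
ATOM      8  CA AGLY A   2      13.403   8.783  -3.163  0.40 20.00           C
ATOM      9  CA BGLY A   2      13.503   8.883  -3.263  0.60 20.00           C
ATOM     10  C   GLY A   2      14.868   8.420  -2.963  1.00 20.00           C
ATOM     11  O   GLY A   2      15.246   7.271  -3.184  1.00 20.00           O
ATOM     12  N   LYS A   3      15.686   9.394  -2.563  1.00 20.00           N
ATOM     13  CA  LYS A   3      17.103   9.167  -2.302  1.00 20.00           C
ATOM     14  C   LYS A   3      17.874  10.473  -2.162  1.00 20.00           C
ATOM     15  O   LYS A   3      17.318  11.548  -2.399  1.00 20.00           O
ATOM     16  CB  LYS A   3      17.283   8.341  -1.025  1.00 20.00           C
ATOM     17  H   LYS A   3      15.350  10.320  -2.400  1.00 20.00           H
TER
ATOM     18  CA  ALA B  10       1.000   2.000   3.000  1.00 20.00           C
ATOM     19  CA  SER B  11       4.500   2.500   3.500  1.00 20.00           C
TER
HETATM   20  O   HOH A 101      20.000  20.000  20.000  1.00 20.00           O
HETATM   21 CA    CA A 102      25.000  25.000  25.000  1.00 20.00          CA
END
"""


@pytest.fixture
def two_chain_pdb(tmp_path):
    p = tmp_path / "two_chain.pdb"
    p.write_text(TWO_CHAIN_PDB)
    return p


@pytest.fixture
def helix():
    return make_template(30, "helix")


@pytest.fixture
def core_loop_ensemble():
    """The master study conditions: K=6, 60-residue core at 0.2 Å noise,
    two 10-residue loops at 3.0 Å noise."""

    def _make(seed, K=6, outliers=0, outlier_noise_sd=5.0):
        mask = default_core_mask(60, (10, 10))
        template = make_template(len(mask), "random-walk", seed=seed)
        return make_core_loop_ensemble(
            K,
            template,
            mask,
            core_noise_sd=0.2,
            loop_noise_sd=3.0,
            outliers=outliers,
            outlier_noise_sd=outlier_noise_sd,
            seed=seed,
        )

    return _make


def identity_ensemble(K, template):
    """K exact rigid copies of a template, with the identity alignment."""
    return make_core_loop_ensemble(K, template, np.ones(len(template), bool), 0.0, 0.0, seed=11)


def random_columns_instance(seed, n=8, K=3, noise_hi=1.2):
    """Small identity-aligned ensemble of random points for sieve oracles."""
    rng = np.random.default_rng(seed)
    base = rng.uniform(-8, 8, size=(n, 3))
    sd = rng.uniform(0.05, noise_hi, size=n)
    traces = []
    for k in range(K):
        x = base + rng.normal(size=(n, 3)) * sd[:, None]
        R, t = random_rigid_motion(rng)
        traces.append(
            CaTrace(f"s{k}", x @ R.T + t, [("ALA", i + 1, "") for i in range(n)])
        )
    msa = MultipleAlignment(
        tuple(t.structure_id for t in traces), np.tile(np.arange(n), (K, 1))
    )
    return msa, traces
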