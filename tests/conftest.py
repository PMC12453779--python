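"""Shared fixtures: a tiny hand-written PDB, small synthetic corpora and a
desk-scale model config."""

from __future__ import annotations

import numpy as np
import pytest

from dtafusion import SynthSpec, build_pair_dataset, gen_dataset
from dtafusion.presets import desk_config

# four heavy atoms at known coordinates with two interleaved HETATMs
TINY_PDB = "\n".join([
    "ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C",
    "HETATM    2  O   HOH A 101       9.000   9.000   9.000  1.00  0.00           O",
    "ATOM      3  CA  GLY A   2       1.000   0.000   0.000  1.00  0.00           C",
    "ATOM      4  CB  GLY A   3       0.000   1.000   0.000  1.00  0.00           C",
    "HETATM    5  O   HOH A 102       8.000   8.000   8.000  1.00  0.00           O",
    "ATOM      6  N   GLY A   4       0.000   0.000   1.000  1.00  0.00           N",
    "END",
]) + "\n"


@pytest.fixture
def tiny_pdb() -> str:
    return TINY_PDB


@pytest.fixture(scope="session")
def small_corpus():
    """A fully dense 6x5 synthetic corpus (30 pairs), deterministic."""
    return gen_dataset(SynthSpec(n_drugs=6, n_proteins=5, pair_density=1.0,
                                 noise_sd=0.1, seed=7))


@pytest.fixture(scope="session")
def small_cfg():
    return desk_config(seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_corpus, small_cfg):
    return build_pair_dataset(small_corpus, small_cfg)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
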