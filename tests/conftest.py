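"""Shared fixtures: synthetic study alignments reused across test modules."""

import numpy as np
import pytest

import phylonull as pn


@pytest.fixture(scope="session")
def phylo_family():
    """The reference phylogenetic family: Yule tree, M=150, L=50, q=21."""
    return pn.generate_phylo_msa(pn.BenchmarkSpec(M=150, L=50, seed=42))


@pytest.fixture(scope="session")
def small_phylo_family():
    """A smaller tree-evolved family for cheap unit tests."""
    return pn.generate_phylo_msa(pn.BenchmarkSpec(M=60, L=30, seed=7))


@pytest.fixture(scope="session")
def planted_family():
    """Planted-contact Potts family at full depth: L=30, 20 pairs, M=2000."""
    pairs = pn.random_contact_pairs(30, 20, seed=7)
    spec = pn.BenchmarkSpec(M=2000, L=30, q=21, planted_pairs=pairs,
                            strength=2.0, seed=7)
    aln, cmap = pn.generate_potts_msa(spec)
    return aln, cmap, spec


@pytest.fixture
def rng():
    return np.random.default_rng(0)
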