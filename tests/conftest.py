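import numpy as np
import pytest

import piezorho as pz


@pytest.fixture(scope="session")
def k0_scale():
    return pz.AminoAcidPropertyScale.packaged_k0()


@pytest.fixture(scope="session")
def toy_scale():
    """An injected scale with easily hand-checked values (alphabetical ranks)."""
    from piezorho.property_partition import AMINO_ACIDS

    return pz.AminoAcidPropertyScale(
        values={aa: float(i + 1) for i, aa in enumerate(sorted(AMINO_ACIDS))},
        name="toy-rank",
    )


@pytest.fixture(scope="session")
def partition60(k0_scale):
    return pz.build_partition(k0_scale, 60)


@pytest.fixture(scope="session")
def tagged_tree():
    return pz.default_tagged_tree()


@pytest.fixture(scope="session")
def uniform_pi():
    return np.full(61, 1.0 / 61)


@pytest.fixture(scope="session")
def small_sim(tagged_tree, partition60):
    """One 300-codon branch-process alignment, reused across tests."""
    spec = pz.CodonSimSpec(tree=tagged_tree, partition=partition60,
                           n_codons=300, seed=7, kappa=6.0, omega=0.77,
                           gamma={"fg": 0.4, "bg": 0.2})
    return pz.simulate_codon_alignment(spec)
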