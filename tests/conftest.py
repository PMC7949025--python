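import numpy as np
import pytest

from pntkit import datasets, synth
from pntkit.structures import Structure


@pytest.fixture(scope="session")
def helix_bundle() -> Structure:
    """Ideal-geometry backbone of the 86-residue construct with its four helices."""
    return synth.gen_helix_bundle(datasets.ETV6_HELICES)


@pytest.fixture(scope="session")
def extended_chain() -> Structure:
    """Fully extended backbone of the same construct (no helical segments)."""
    from pntkit.structures import HelixAnnotation

    return synth.gen_helix_bundle(HelixAnnotation(segments=[]))


@pytest.fixture(scope="session")
def heterodimer(helix_bundle) -> Structure:
    """Two-chain model: identical bundles, chain B displaced to avoid overlap."""
    a = synth.gen_helix_bundle(datasets.ETV6_HELICES, chain_id="A")
    b = synth.gen_helix_bundle(datasets.ETV6_HELICES, chain_id="B")
    shifted = b.coordinates() + np.array([60.0, 0.0, 0.0])
    b.set_coordinates(shifted)
    return Structure(chains={"A": a.chains["A"], "B": b.chains["B"]})


@pytest.fixture(scope="session")
def non_proline_residues() -> list[int]:
    return [
        datasets.CONSTRUCT_START + i
        for i, aa in enumerate(datasets.CONSTRUCT_SEQUENCE)
        if i > 0 and aa != "P"
    ]
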