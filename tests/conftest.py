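import numpy as np
import pytest

from idrfunc import classify, features, synthetic

ALPHABET = features.ALPHABET


def random_sequence(rng: np.random.Generator, length: int, idr_id: str = "idr", protein_id: str = "prot") -> features.IDRSequence:
    residues = "".join(rng.choice(list(ALPHABET), size=length))
    return features.IDRSequence(idr_id=idr_id, protein_id=protein_id, residues=residues)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240)


@pytest.fixture(scope="session")
def signal_dataset() -> synthetic.SyntheticDataset:
    """Default acidic-signal dataset (~500 IDRs), shared across test modules."""
    return synthetic.generate_dataset(synthetic.SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def signal_expanded(signal_dataset) -> dict[str, frozenset[str]]:
    return {
        r: classify.expand_annotations(ts, signal_dataset.parent_map)
        for r, ts in signal_dataset.annotations.items()
    }
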