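import numpy as np
import pytest

from druggability.models import ModelConfig
from druggability.seq_io import LabeledDataset, ProteinRecord
from druggability.synthetic import SyntheticConfig, generate


@pytest.fixture
def tiny_dataset() -> LabeledDataset:
    """Five hand-written records, labels [1, 1, 1, 0, 0]."""
    records = [
        ProteinRecord("pos1", "MKVLWQRACDEFGHIKLMNPQRSTVWY"),
        ProteinRecord("pos2", "WYFWYFWYFHKRHKRAIMGLVAIMGLV"),
        ProteinRecord("pos3", "ACDEFGHIKLMNPQRSTVWYACDEFGH"),
        ProteinRecord("neg1", "PPPPGGGGSSSSTTTTNNNNQQQQCCC"),
        ProteinRecord("neg2", "DEDEDEDEDEKRKRKRKRKRILILILI"),
    ]
    return LabeledDataset(records=records, labels=np.array([1, 1, 1, 0, 0]))


@pytest.fixture(scope="session")
def separable_dataset() -> LabeledDataset:
    """Aromatic-enriched positives vs uniform negatives; clearly learnable."""
    return generate(
        SyntheticConfig(n_pos=60, n_neg=60, len_min=50, len_max=120, delta=5.0, seed=11)
    )


@pytest.fixture(scope="session")
def fast_model() -> ModelConfig:
    """Small boosted-tree config for quick unit tests (not the study defaults)."""
    return ModelConfig(n_estimators=40, max_depth=4)


def random_sequences(n: int, rng: np.random.Generator, min_len=2, max_len=60):
    from druggability.alphabets import CANONICAL_RESIDUES

    residues = np.array(list(CANONICAL_RESIDUES))
    for _ in range(n):
        L = int(rng.integers(min_len, max_len + 1))
        yield "".join(rng.choice(residues, size=L))
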