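import numpy as np
import pytest

from dtiscreen.fingerprints import parse_molecule, path_fingerprint
from dtiscreen.pairs import build_pair_dataset, label_pairs
from dtiscreen.protein import protein_features

# The canonical 20-residue worked example: a sequence whose hydrophobicity
# group-encoding, C/T/D descriptors are known by hand.
EXAMPLE_SEQUENCE = "MTEITAAMVKELRESTGAGA"
EXAMPLE_ENCODING = "32132223311311222222"


@pytest.fixture(scope="session")
def example_sequence() -> str:
    return EXAMPLE_SEQUENCE


def featurize_benchmark(bench):
    """Featurize a synthetic benchmark into (X, y, labeled pair table)."""
    fps = {r.drug_id: path_fingerprint(parse_molecule(r.smiles, r.drug_id))
           for r in bench.drugs.itertuples()}
    pvs = {r.target_id: protein_features(r.sequence).values
           for r in bench.proteins.itertuples()}
    labeled = label_pairs(bench.ki_table)
    return build_pair_dataset(labeled, fps, pvs)


def planted_feature_data(n=500, n_features=20, seed=0):
    """Noise features plus one feature that determines the label exactly."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, n_features))
    y = (X[:, 3] > 0).astype(int)
    return X, y
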