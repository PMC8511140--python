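import numpy as np
import pytest

from ccgnet.graphdata import FeaturizerCache, pair_from_smiles


@pytest.fixture(scope="session")
def cache():
    return FeaturizerCache()


@pytest.fixture(scope="session")
def sample_pair(cache):
    return pair_from_smiles("CCO", "c1ccncc1", label=1, sample_id="ethanol-pyridine",
                            cache=cache)


@pytest.fixture(scope="session")
def sample_pairs(cache):
    smiles = [
        ("CCO", "c1ccncc1", 1),
        ("CCCC", "Oc1ccccc1", 0),
        ("Nc1ccco1", "N#Cc1ccoc1C(=O)O", 1),
        ("Cc1ccc(O)cc1", "COc1ccccc1", 0),
    ]
    return [
        pair_from_smiles(a, b, label=y, sample_id=f"p{i}", cache=cache)
        for i, (a, b, y) in enumerate(smiles)
    ]


@pytest.fixture(scope="session")
def tiny_model(sample_pairs):
    """A small trained-free model and padded batch for layer-level checks."""
    from ccgnet.graphdata import pad_batch
    from ccgnet.network import CCGNet, CCGNetConfig

    batch = pad_batch(sample_pairs, n_max=40)
    model = CCGNet(CCGNetConfig(conv_widths=(4, 5), global_widths=(3, 4),
                                attention_heads=2, attention_hidden=3,
                                dense_head=(6, 2), seed=1))
    model.fit_scalers(batch)
    return model, batch
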