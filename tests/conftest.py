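import numpy as np
import pytest

from ervpredict import synthetic_fixtures as sf
from ervpredict.features import encode_table
from ervpredict.ensemble import plan_from_labels, train_ensemble
from ervpredict.mlp_core import TrainConfig


@pytest.fixture(scope="session")
def training_records():
    """Default synthetic training table: 33 positives + 117 negatives, seed 0."""
    return sf.generate_training_like(sf.SynthConfig(seed=0))


@pytest.fixture(scope="session")
def encoded(training_records):
    return encode_table(training_records)


@pytest.fixture(scope="session")
def small_ensemble(encoded):
    """A quick-to-train ensemble (2 permutations x 3 folds x 5 reinits)."""
    X, t = encoded
    plan = plan_from_labels(t, permutations=2, seed=7)
    cfg = TrainConfig(seed=7, max_epochs=1500)
    return train_ensemble(plan, (X, t), n_reinits=5, cfg=cfg), plan


@pytest.fixture()
def toy_locus():
    """3-exon gene on + strand with one mid-intron insertion."""
    spec = sf.ToyLocusSpec(
        exons=[(100, 200), (1000, 1100), (2000, 2100)],
        strand="+",
        insertions=[("ins1|IAP", 400, 500, "+")],
    )
    return spec, sf.generate_toy_locus(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240101)
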