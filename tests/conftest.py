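import numpy as np
import pandas as pd
import pytest

from rsslearn import simulate as sim
from rsslearn.dataset import minmax_normalize, stratified_rotations
from rsslearn.explain import PermutationExplainer
from rsslearn.model import EfficiencyRegressor
from rsslearn.sequences import H4S2_POSITIONS, enumerate_library, one_hot_encode


class LinearModel:
    """Plain linear predictor used as an analytic oracle for attribution."""

    def __init__(self, weights, intercept=0.0):
        self.w = np.asarray(weights, dtype=float)
        self.b = float(intercept)

    def predict(self, X):
        return np.asarray(X, dtype=float) @ self.w + self.b


@pytest.fixture(scope="session")
def h4s2_library():
    return enumerate_library(H4S2_POSITIONS)


@pytest.fixture(scope="session")
def h4s2_encoding(h4s2_library):
    return one_hot_encode(h4s2_library)


@pytest.fixture(scope="session")
def tms_4096(h4s2_encoding):
    from rsslearn.thermo import library_tms

    return library_tms(h4s2_encoding.index)


@pytest.fixture(scope="session")
def trained_setup():
    """A model trained on one default synthetic dataset, with its split."""
    truth = sim.make_truth(seed=7)
    table = sim.simulate_counts(truth, seed=8).drop(columns="replicate")
    norm = minmax_normalize(table)
    targets = norm.set_index("sequence")["target"]
    encoding = one_hot_encode(norm["sequence"].tolist())
    rot = stratified_rotations(norm, k=20, seed=9)[0]
    masks = rot.role_masks()
    seqs = rot.folds.index
    model = EfficiencyRegressor(random_state=7).fit(
        encoding.loc[seqs[masks["train"]]], targets.loc[seqs[masks["train"]]],
        validation_data=(encoding.loc[seqs[masks["validation"]]],
                         targets.loc[seqs[masks["validation"]]]),
    )
    return {"truth": truth, "norm": norm, "targets": targets,
            "encoding": encoding, "rotation": rot, "model": model}


@pytest.fixture(scope="session")
def trained_attributions(trained_setup):
    """Attributions of the trained model on a 512-variant subsample."""
    rng = np.random.default_rng(3)
    enc = trained_setup["encoding"]
    samples = enc.iloc[rng.choice(len(enc), 512, replace=False)]
    background = enc.iloc[rng.choice(len(enc), 64, replace=False)]
    attr = PermutationExplainer(
        trained_setup["model"], background, n_permutations=1, random_state=3
    ).attributions(samples)
    return attr
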