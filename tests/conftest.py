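import numpy as np
import pytest

from synergyflow import factorization as fz
from synergyflow import synthetic


@pytest.fixture(scope="session")
def truth():
    """Structured 16-muscle, 5-module planted ground truth, 5% noise."""
    return synthetic.cutting_preset_truth(seed=11)


@pytest.fixture(scope="session")
def upt_trials(truth):
    return synthetic.synthesize_trials(truth, 10, "UPT", seed=101)


@pytest.fixture(scope="session")
def ptb_trials(truth):
    return synthetic.synthesize_trials(truth, 1, "PTB", seed=102)


@pytest.fixture(scope="session")
def upt_concat(upt_trials):
    return fz.concatenate_trials(list(upt_trials.trials))


@pytest.fixture(scope="session")
def noiseless_truth():
    return synthetic.cutting_preset_truth(seed=7, noise_level=0.0)


@pytest.fixture(scope="session")
def noiseless_X(noiseless_truth):
    return noiseless_truth.weightings @ noiseless_truth.activations


#: fast-but-adequate fit settings used throughout the suite so the whole
#: run stays interactive; defaults of the public API are stricter
FAST_FIT = dict(n_restarts=2, max_iter=300, tol=1e-5)


@pytest.fixture(scope="session")
def fast_fit():
    return dict(FAST_FIT)


def matched_mean_similarity(truth, mset, n_trials=1):
    """Mean matched cosine similarity between planted and recovered weightings."""
    from synergyflow import analysis

    true_set = fz.MotorModuleSet(
        weightings=truth.weightings,
        activations=np.tile(truth.activations, (1, n_trials)),
        n_modules=truth.n_modules,
    )
    rep = analysis.match_modules(true_set, mset, on="weightings")
    return float(rep.pair_similarities.mean())
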