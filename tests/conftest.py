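import numpy as np
import pytest

import giftedsim as gs


@pytest.fixture(scope="session")
def inventory():
    return gs.build_phoneme_inventory()


@pytest.fixture(scope="session")
def corpus():
    return gs.generate_corpus(seed=1)


@pytest.fixture(scope="session")
def patterns(corpus):
    return corpus.pattern_arrays()


def make_params(**overrides) -> gs.ParameterSet:
    """A well-conditioned parameter set for learnability-style tests."""
    base = dict(
        hidden_units=60, temperature=1.0, noise=0.0, learning_rate=0.1,
        phonological_lr=1.0, semantic_lr=1.0, momentum=0.2, weight_variance=0.5,
        architecture="hidden_only", learning_algorithm="cross_entropy",
        response_threshold=0.4, pruning_onset=1000, pruning_probability=0.0,
        pruning_threshold=0.1, weight_decay=0.0, sparseness=0.0)
    base.update(overrides)
    return gs.ParameterSet(**base)


SCALED_SEED = 20260901
SCALED_CHECKPOINTS = (tuple(range(1, 61)) + tuple(range(65, 151, 5))
                      + tuple(range(160, 451, 10)))


@pytest.fixture(scope="session")
def scaled_run():
    """The desk-scale population experiment: 200 children, 450 epochs.

    Checkpoints are dense early (every epoch through 60, every fifth to
    150, every tenth after), keeping the gifted-classification window
    dense while the run stays tractable on one CPU.  Shared by the
    population-level acceptance checks.
    """
    return gs.run_population(n=200, epochs=450, checkpoints=SCALED_CHECKPOINTS,
                             master_seed=SCALED_SEED)
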