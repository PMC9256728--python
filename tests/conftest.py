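import numpy as np
import pytest

from activelab import Factor, LabeledDataset, SearchSpace


@pytest.fixture
def tiny_space():
    """3 x 4 all-numeric space (12 combinations)."""
    return SearchSpace([
        Factor("a", "numeric", (1.0, 2.0, 3.0), "mM"),
        Factor("b", "numeric", (0.0, 0.5, 1.0, 2.0), "mM"),
    ])


@pytest.fixture
def mixed_space():
    """One numeric factor and one 3-level categorical factor."""
    return SearchSpace([
        Factor("conc", "numeric", (1.0, 5.0, 10.0), "mM"),
        Factor("promoter", "categorical", ("p1", "p2", "p3")),
    ])


@pytest.fixture
def five_factor_space():
    """5 numeric factors x 4 levels = 1024 combinations."""
    return SearchSpace([
        Factor(name, "numeric", (0.25, 0.5, 0.75, 1.0), "mM")
        for name in ("f1", "f2", "f3", "f4", "f5")])


def make_signal_dataset(space, n, seed, signal=None, noise_sd=0.0, rounds=1):
    """Dataset whose objective is `signal(combination)` plus Gaussian noise."""
    rng = np.random.default_rng(seed)
    if signal is None:
        signal = lambda c: 2.0 * float(c[space.names[0]])  # noqa: E731
    per_round = n // rounds
    ds = LabeledDataset(space)
    for _ in range(rounds):
        combos = space.sample(per_round, seed=rng, exclude=ds.combinations())
        y = [signal(c) + rng.normal(0, noise_sd) for c in combos]
        ds = ds.with_round(combos, y)
    return ds


@pytest.fixture
def signal_dataset(five_factor_space):
    """100 points where the objective depends on f1, f2 and their product."""
    def signal(c):
        return 2.0 * c["f1"] + c["f2"] + 1.5 * c["f1"] * c["f2"]
    return make_signal_dataset(five_factor_space, 100, seed=0, signal=signal,
                               noise_sd=0.02)
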