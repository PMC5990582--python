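"""Shared fixtures and the independent trial-by-trial oracle.

The oracle deliberately avoids the package's kernels: it recomputes the
utility, delta-rule and softmax chain with plain Python floats and
``math``, so likelihood tests compare two independent code paths.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from igtbayes import (
    PVLDeltaParams,
    build_traditional_scheme,
    simulate_agent,
)


@pytest.fixture(scope="session")
def scheme():
    return build_traditional_scheme()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def example_agent(scheme):
    params = PVLDeltaParams(A=0.6, w=1.5, a=0.25, c=1.2)
    return simulate_agent(params, scheme, n_trials=40, seed=77), params


def oracle_trial_probs(choices, nets, A, w, a, c):
    """Choice probabilities per trial by direct sequential recomputation.

    choices: 1-based decks; nets: (scaled) net outcomes.  Returns a list of
    4-tuples, entry t conditioning on trials < t.
    """
    theta = 3.0**c - 1.0
    ev = [0.0, 0.0, 0.0, 0.0]
    rows = []
    for deck, x in zip(choices, nets):
        exps = [math.exp(theta * e - max(theta * v for v in ev)) for e in ev]
        total = sum(exps)
        rows.append(tuple(e / total for e in exps))
        if x >= 0:
            u = x**A if x > 0 else 0.0
        else:
            u = -w * (-x) ** A
        k = deck - 1
        ev[k] = ev[k] + a * (u - ev[k])
    return rows


def oracle_loglik(choices, nets, A, w, a, c):
    """Log-likelihood by direct sequential recomputation (log space, so it
    stays finite at extreme sensitivity values)."""
    theta = 3.0**c - 1.0
    ev = [0.0, 0.0, 0.0, 0.0]
    ll = 0.0
    for deck, x in zip(choices, nets):
        m = max(theta * v for v in ev)
        lse = m + math.log(sum(math.exp(theta * v - m) for v in ev))
        ll += theta * ev[deck - 1] - lse
        if x >= 0:
            u = x**A if x > 0 else 0.0
        else:
            u = -w * (-x) ** A
        k = deck - 1
        ev[k] = ev[k] + a * (u - ev[k])
    return ll


def random_instance(rng, n_trials=20):
    """A random in-range parameter vector plus a random choice/outcome
    sequence on the payoff scale used by the package (net / 100)."""
    params = PVLDeltaParams(
        A=rng.uniform(0.02, 0.98),
        w=rng.uniform(0.1, 4.9),
        a=rng.uniform(0.02, 0.98),
        c=rng.uniform(0.0, 5.0),
    )
    choices = rng.integers(1, 5, size=n_trials)
    nets = rng.choice([1.0, 0.5, -0.5, -1.0, -11.5, 2.5], size=n_trials)
    return params, choices, nets
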