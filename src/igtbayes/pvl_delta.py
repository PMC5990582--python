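"""PVL-Delta model: prospect utility, delta-rule updating, softmax choice.

The model evaluates each trial's net outcome with a prospect-theory utility
(curvature A, loss aversion w), updates the chosen deck's expectancy with a
delta rule (rate a), and chooses via softmax with sensitivity
theta = 3**c - 1.  Net outcomes are divided by ``outcome_scale`` (default
100) before the utility step so that theta * Ev stays in a numerically safe
range at c = 5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .igt_task import (
    GroupDataset,
    ParticipantData,
    PayoffScheme,
    TrialRecord,
    _BlockShuffler,
)

PARAM_NAMES = ("A", "w", "a", "c")
PARAM_BOUNDS = {"A": (0.0, 1.0), "w": (0.0, 5.0), "a": (0.0, 1.0), "c": (0.0, 5.0)}
DEFAULT_OUTCOME_SCALE = 100.0


@dataclass(frozen=True)
class PVLDeltaParams:
    """Natural-scale model parameters (A, w, a, c)."""

    A: float
    w: float
    a: float
    c: float

    def __post_init__(self):
        for name in PARAM_NAMES:
            lo, hi = PARAM_BOUNDS[name]
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"parameter {name}={v} outside [{lo}, {hi}]")

    @property
    def theta(self) -> float:
        return sensitivity(self.c)

    def as_array(self) -> np.ndarray:
        return np.array([self.A, self.w, self.a, self.c])

    def to_dict(self) -> dict:
        return {"A": self.A, "w": self.w, "a": self.a, "c": self.c}

    @classmethod
    def from_dict(cls, d: dict) -> "PVLDeltaParams":
        return cls(d["A"], d["w"], d["a"], d["c"])


@dataclass
class ExpectancyState:
    """Running expected utilities per deck plus per-deck draw counters."""

    Ev: np.ndarray = field(default_factory=lambda: np.zeros(4))
    draw_counts: np.ndarray = field(default_factory=lambda: np.zeros(4, dtype=np.int64))

    def copy(self) -> "ExpectancyState":
        return ExpectancyState(self.Ev.copy(), self.draw_counts.copy())


def utility(x: float, A: float, w: float) -> float:
    """Prospect utility of net outcome x: x**A for gains, -w*|x|**A for losses."""
    if not 0.0 <= A <= 1.0:
        raise ValueError(f"A={A} outside [0, 1]")
    if not 0.0 <= w <= 5.0:
        raise ValueError(f"w={w} outside [0, 5]")
    if x == 0.0:
        return 0.0  # both branches vanish; avoids 0**0 at A=0
    if x > 0.0:
        return x**A
    return -w * (-x) ** A


def update_expectancies(
    state: ExpectancyState, chosen_deck: int, u: float, a: float
) -> ExpectancyState:
    """Delta-rule update of the chosen deck only; returns a new state."""
    if not 0.0 <= a <= 1.0:
        raise ValueError(f"a={a} outside [0, 1]")
    if chosen_deck not in (1, 2, 3, 4):
        raise ValueError(f"deck must be 1-4, got {chosen_deck}")
    new = state.copy()
    k = chosen_deck - 1
    new.Ev[k] += a * (u - new.Ev[k])
    new.draw_counts[k] += 1
    return new


def sensitivity(c: float) -> float:
    """Softmax sensitivity theta = 3**c - 1."""
    if not 0.0 <= c <= 5.0:
        raise ValueError(f"c={c} outside [0, 5]")
    return 3.0**c - 1.0


def choice_probabilities(Ev: np.ndarray, c: float) -> np.ndarray:
    """Softmax choice probabilities over the four decks (stable at theta=242)."""
    Ev = np.asarray(Ev, dtype=float)
    if not np.all(np.isfinite(Ev)):
        raise ValueError("non-finite expectancies")
    theta = sensitivity(c)
    z = theta * Ev
    z -= z.max()
    p = np.exp(z)
    return p / p.sum()


def log_likelihood(
    p: ParticipantData,
    params: PVLDeltaParams,
    outcome_scale: float = DEFAULT_OUTCOME_SCALE,
) -> float:
    """Sequence log-likelihood of observed choices under the model.

    Trial 1 uses zero initial expectancies (uniform probabilities); losses
    enter through the trial records' net outcome so the stored sign
    convention cannot change the result.
    """
    if not p.trials:
        raise ValueError("empty trial sequence")
    choices = p.choices - 1
    net = p.net_outcomes / outcome_scale
    return float(
        _kernels.loglik_one(
            choices, net, len(p.trials), params.A, params.w, params.a, params.c
        )
    )


def simulate_agent(
    params: PVLDeltaParams,
    scheme: PayoffScheme,
    n_trials: int | None = None,
    seed=None,
    participant_id: str = "sim",
    outcome_scale: float = DEFAULT_OUTCOME_SCALE,
    forced_choices=None,
) -> ParticipantData:
    """Forward-simulate one agent playing the task.

    Choices are sampled from the softmax probabilities; payoffs are dealt by
    per-deck draw counters against the scheme.  ``forced_choices`` (sequence
    of deck ids 1-4) bypasses the choice rule, e.g. to audit the payoff
    schedule.
    """
    if n_trials is None:
        n_trials = scheme.n_trials_default
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    dealer = _BlockShuffler(scheme, rng)
    state = ExpectancyState()
    records = []
    for t in range(1, n_trials + 1):
        if forced_choices is not None:
            deck = int(forced_choices[t - 1])
        else:
            probs = choice_probabilities(state.Ev, params.c)
            deck = int(rng.choice(4, p=probs)) + 1
        reward, loss = dealer.deal(deck)
        records.append(TrialRecord(t, deck, reward, loss))
        u = utility((reward + loss) / outcome_scale, params.A, params.w)
        state = update_expectancies(state, deck, u, params.a)
    return ParticipantData(participant_id, records)


def group_log_likelihood(
    dataset: GroupDataset,
    params_per_participant: list[PVLDeltaParams],
    outcome_scale: float = DEFAULT_OUTCOME_SCALE,
) -> float:
    if len(params_per_participant) != len(dataset):
        raise ValueError("one parameter set required per participant")
    return sum(
        log_likelihood(p, th, outcome_scale)
        for p, th in zip(dataset, params_per_participant)
    )
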