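"""Iowa Gambling Task environment: payoff scheme, trial records, datasets.

The traditional four-deck scheme pays a fixed reward on every draw from a
deck and applies deck-specific losses on a fixed within-block schedule, so
that every complete 10-card block reproduces the canonical per-block totals
(decks A and B lose 250 net per block, decks C and D gain 250).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

DECK_LETTERS = ("A", "B", "C", "D")
_LETTER_TO_INT = {letter: i + 1 for i, letter in enumerate(DECK_LETTERS)}

# Canonical within-block loss placement (1-based position -> loss) for the
# traditional scheme.  Only per-block counts and totals are contractual;
# the placement follows the classic administration and is overridable.
_TRADITIONAL_LOSSES = {
    1: {3: -150.0, 5: -300.0, 7: -200.0, 9: -250.0, 10: -350.0},
    2: {9: -1250.0},
    3: {3: -50.0, 5: -50.0, 7: -50.0, 9: -50.0, 10: -50.0},
    4: {10: -250.0},
}
_TRADITIONAL_REWARDS = {1: 100.0, 2: 100.0, 3: 50.0, 4: 50.0}


def _coerce_deck(deck) -> int:
    if isinstance(deck, str):
        try:
            return _LETTER_TO_INT[deck.upper()]
        except KeyError:
            raise ValueError(f"unknown deck id {deck!r}") from None
    deck = int(deck)
    if deck not in (1, 2, 3, 4):
        raise ValueError(f"unknown deck id {deck!r}; expected 1-4 or A-D")
    return deck


@dataclass(frozen=True)
class PayoffScheme:
    """Per-deck reward/loss schedule with block structure.

    ``loss_schedule[k]`` maps 1-based within-block positions to non-positive
    loss magnitudes for deck ``k`` (1-4); positions absent from the mapping
    incur no loss.
    """

    reward_per_trial: dict[int, float]
    loss_schedule: dict[int, dict[int, float]]
    block_length: int = 10
    shuffle_within_block: bool = False
    endowment: float = 2000.0
    n_trials_default: int = 100

    def __post_init__(self):
        for k in (1, 2, 3, 4):
            if k not in self.reward_per_trial or k not in self.loss_schedule:
                raise ValueError(f"scheme must define deck {k}")
            for pos, loss in self.loss_schedule[k].items():
                if not 1 <= pos <= self.block_length:
                    raise ValueError(f"loss position {pos} outside block")
                if loss > 0:
                    raise ValueError("losses must be non-positive")

    def block_loss_total(self, deck) -> float:
        return float(sum(self.loss_schedule[_coerce_deck(deck)].values()))

    def block_loss_count(self, deck) -> int:
        return sum(v != 0 for v in self.loss_schedule[_coerce_deck(deck)].values())

    def block_net_outcome(self, deck) -> float:
        k = _coerce_deck(deck)
        return self.block_length * self.reward_per_trial[k] + self.block_loss_total(k)

    def with_shuffle(self, shuffle: bool = True) -> "PayoffScheme":
        return replace(self, shuffle_within_block=shuffle)


def build_traditional_scheme() -> PayoffScheme:
    """Traditional IGT payoff scheme (rewards 100/100/50/50, block losses
    -1250/-1250/-250/-250 with 5/1/5/1 loss cards per 10-card block)."""
    return PayoffScheme(
        reward_per_trial=dict(_TRADITIONAL_REWARDS),
        loss_schedule={k: dict(v) for k, v in _TRADITIONAL_LOSSES.items()},
    )


def draw_payoff(
    scheme: PayoffScheme,
    deck,
    draw_count_from_deck: int,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Payoff for the ``draw_count_from_deck``-th draw from ``deck``.

    Returns ``(reward, loss)`` with loss <= 0.  With
    ``scheme.shuffle_within_block`` the loss positions are permuted within
    the block using a fresh draw from ``rng`` (stateful dealing across many
    draws should go through the internal block-caching dealer, as
    :func:`igtbayes.pvl_delta.simulate_agent` does); without shuffling the
    schedule is deterministic in ``draw_count_from_deck``.
    """
    k = _coerce_deck(deck)
    n = int(draw_count_from_deck)
    if n < 1:
        raise ValueError("draw_count_from_deck must be >= 1")
    reward = scheme.reward_per_trial[k]
    pos = (n - 1) % scheme.block_length + 1
    if scheme.shuffle_within_block:
        if rng is None:
            raise ValueError("shuffle_within_block requires an rng")
        block_index = (n - 1) // scheme.block_length
        losses = _shuffled_block_losses(scheme, k, block_index, rng)
        loss = losses[pos - 1]
    else:
        loss = scheme.loss_schedule[k].get(pos, 0.0)
    return reward, float(loss)


def _shuffled_block_losses(scheme, deck, block_index, rng):
    """Loss vector for one block with positions permuted by ``rng``."""
    base = np.zeros(scheme.block_length)
    for pos, loss in scheme.loss_schedule[deck].items():
        base[pos - 1] = loss
    perm = rng.permutation(scheme.block_length)
    return base[perm]


class _BlockShuffler:
    """Stateful per-deck payoff dealer honoring optional block shuffling."""

    def __init__(self, scheme: PayoffScheme, rng: np.random.Generator | None):
        self.scheme = scheme
        self.rng = rng
        self.counts = {1: 0, 2: 0, 3: 0, 4: 0}
        self._block_cache: dict[tuple[int, int], np.ndarray] = {}

    def deal(self, deck: int) -> tuple[float, float]:
        self.counts[deck] += 1
        n = self.counts[deck]
        scheme = self.scheme
        reward = scheme.reward_per_trial[deck]
        pos = (n - 1) % scheme.block_length + 1
        if scheme.shuffle_within_block:
            block = (n - 1) // scheme.block_length
            key = (deck, block)
            if key not in self._block_cache:
                self._block_cache[key] = _shuffled_block_losses(
                    scheme, deck, block, self.rng
                )
            loss = self._block_cache[key][pos - 1]
        else:
            loss = scheme.loss_schedule[deck].get(pos, 0.0)
        return reward, float(loss)


@dataclass(frozen=True)
class TrialRecord:
    """One IGT trial: chosen deck, reward W(t) >= 0, loss L(t) <= 0."""

    trial_index: int
    deck: int
    reward: float
    loss: float

    def __post_init__(self):
        if self.trial_index < 1:
            raise ValueError("trial_index is 1-based")
        if self.deck not in (1, 2, 3, 4):
            raise ValueError(f"deck must be 1-4, got {self.deck}")
        if self.reward < 0:
            raise ValueError("reward must be >= 0")
        if self.loss > 0:
            raise ValueError("loss must be stored as a non-positive number")

    @property
    def net_outcome(self) -> float:
        return self.reward + self.loss


@dataclass
class ParticipantData:
    """Ordered trial sequence for one participant."""

    participant_id: str
    trials: list[TrialRecord]
    group_label: str | None = None

    def __post_init__(self):
        for i, tr in enumerate(self.trials, start=1):
            if tr.trial_index != i:
                raise ValueError(
                    f"participant {self.participant_id}: trial indices must be "
                    f"contiguous from 1 (index {tr.trial_index} at position {i})"
                )

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def choices(self) -> np.ndarray:
        return np.array([t.deck for t in self.trials], dtype=np.int64)

    @property
    def net_outcomes(self) -> np.ndarray:
        return np.array([t.net_outcome for t in self.trials])


@dataclass
class GroupDataset:
    """Collection of participants forming one group."""

    participants: list[ParticipantData]
    name: str = "group"

    def __len__(self) -> int:
        return len(self.participants)

    def __iter__(self):
        return iter(self.participants)

    def require_nonempty(self):
        if not self.participants:
            raise ValueError(f"group {self.name!r} has no participants")


def block_proportions(
    p: ParticipantData, block_size: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """Per-block deck-choice proportions.

    Returns ``(props, good)`` where ``props`` is a (blocks, 4) matrix whose
    rows sum to 1 and ``good`` holds the good-deck (C+D) proportion per
    block.  A trailing partial block is included; callers can detect it from
    the trial count.
    """
    if not p.trials:
        raise ValueError("empty trial sequence")
    choices = p.choices
    n_blocks = int(np.ceil(len(choices) / block_size))
    props = np.zeros((n_blocks, 4))
    for b in range(n_blocks):
        chunk = choices[b * block_size : (b + 1) * block_size]
        counts = np.bincount(chunk, minlength=5)[1:5]
        props[b] = counts / len(chunk)
    good = props[:, 2] + props[:, 3]
    return props, good


def scheme_to_config(scheme: PayoffScheme) -> dict:
    """Serializable dict form of a payoff scheme (deck letters as keys)."""
    return {
        "reward_per_trial": {DECK_LETTERS[k - 1]: v
                             for k, v in scheme.reward_per_trial.items()},
        "loss_schedule": {
            DECK_LETTERS[k - 1]: {str(pos): loss for pos, loss in sched.items()}
            for k, sched in scheme.loss_schedule.items()
        },
        "block_length": scheme.block_length,
        "shuffle_within_block": scheme.shuffle_within_block,
        "endowment": scheme.endowment,
        "n_trials_default": scheme.n_trials_default,
    }


def scheme_from_config(source) -> PayoffScheme:
    """Build a scheme from a dict or a JSON/YAML file path."""
    if not isinstance(source, dict):
        import json
        from pathlib import Path

        text = Path(source).read_text()
        if str(source).endswith((".yaml", ".yml")):
            import yaml

            cfg = yaml.safe_load(text)
        else:
            cfg = json.loads(text)
    else:
        cfg = source
    return PayoffScheme(
        reward_per_trial={_coerce_deck(k): float(v)
                          for k, v in cfg["reward_per_trial"].items()},
        loss_schedule={
            _coerce_deck(k): {int(pos): float(loss)
                              for pos, loss in sched.items()}
            for k, sched in cfg["loss_schedule"].items()
        },
        block_length=int(cfg.get("block_length", 10)),
        shuffle_within_block=bool(cfg.get("shuffle_within_block", False)),
        endowment=float(cfg.get("endowment", 2000.0)),
        n_trials_default=int(cfg.get("n_trials_default", 100)),
    )


_REQUIRED_COLUMNS = ["subject", "trial", "deck", "reward", "loss"]


def write_dataset(dataset: GroupDataset, path) -> None:
    """Write a group dataset as tidy CSV (subject, trial, deck, reward, loss)."""
    rows = []
    for p in dataset:
        for t in p.trials:
            rows.append((p.participant_id, t.trial_index, t.deck, t.reward, t.loss))
    pd.DataFrame(rows, columns=_REQUIRED_COLUMNS).to_csv(path, index=False)


def read_dataset(path, name: str = "group") -> GroupDataset:
    """Read a CSV dataset, validating schema, deck codes and trial contiguity."""
    df = pd.read_csv(path, dtype={"subject": str})
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"dataset {path} is missing column(s): {', '.join(missing)}")
    bad = ~df["deck"].isin([1, 2, 3, 4])
    if bad.any():
        row = int(df.index[bad][0]) + 2  # +1 header, +1 one-based
        raise ValueError(
            f"dataset {path}: deck value {df.loc[df.index[bad][0], 'deck']} "
            f"outside 1-4 at row {row}"
        )
    participants = []
    for sid, sub in df.groupby("subject", sort=False):
        sub = sub.sort_values("trial")
        trials_expected = np.arange(1, len(sub) + 1)
        if not np.array_equal(sub["trial"].to_numpy(), trials_expected):
            first_bad = int(
                sub.index[sub["trial"].to_numpy() != trials_expected][0]
            ) + 2
            raise ValueError(
                f"dataset {path}: non-contiguous trial indices for subject "
                f"{sid!r} (row {first_bad})"
            )
        trials = [
            TrialRecord(int(r.trial), int(r.deck), float(r.reward), float(r.loss))
            for r in sub.itertuples()
        ]
        participants.append(ParticipantData(str(sid), trials))
    return GroupDataset(participants, name=name)


def dataset_to_arrays(dataset: GroupDataset, scale: float = 100.0):
    """Pack a dataset into padded arrays for the vectorized likelihood.

    Returns ``(choices, net, n_trials)`` with ``choices`` (N, Tmax) int64
    (0-based deck index, padded with 0), ``net`` (N, Tmax) float64 net
    outcomes divided by ``scale``, and ``n_trials`` (N,) int64.
    """
    dataset.require_nonempty()
    n = len(dataset)
    tmax = max(len(p) for p in dataset)
    choices = np.zeros((n, tmax), dtype=np.int64)
    net = np.zeros((n, tmax))
    n_trials = np.zeros(n, dtype=np.int64)
    for i, p in enumerate(dataset):
        t = len(p)
        n_trials[i] = t
        choices[i, :t] = p.choices - 1
        net[i, :t] = p.net_outcomes / scale
    return choices, net, n_trials
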