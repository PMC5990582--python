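"""Post hoc absolute fit: one-step-ahead choice postdictions.

For each participant and trial, the fitted parameters and the *observed*
choice/payoff history through the previous trial yield the model's
probability of each deck on the current trial.  Averaging these
probabilities within 10-trial blocks across a group gives predicted block
curves that can be compared with the observed choice proportions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._kernels import predict_probs_one
from .igt_task import GroupDataset, ParticipantData, block_proportions
from .pvl_delta import DEFAULT_OUTCOME_SCALE, PVLDeltaParams


def one_step_ahead_probs(
    p: ParticipantData,
    params: PVLDeltaParams,
    outcome_scale: float = DEFAULT_OUTCOME_SCALE,
) -> np.ndarray:
    """(n_trials, 4) matrix of one-step-ahead deck probabilities.

    Row t conditions on the observed history through trial t-1; row 1 is
    uniform (zero initial expectancies).
    """
    if not p.trials:
        raise ValueError("empty trial sequence")
    choices = p.choices - 1
    net = p.net_outcomes / outcome_scale
    return predict_probs_one(
        choices, net, len(p.trials), params.A, params.w, params.a, params.c
    )


@dataclass
class PosthocCurves:
    """Block-wise predicted and observed choice proportions for one group."""

    group: str
    predicted: np.ndarray   # (blocks, 4), rows sum to 1
    observed: np.ndarray    # (blocks, 4), rows sum to 1
    block_size: int

    @property
    def predicted_good(self) -> np.ndarray:
        return self.predicted[:, 2] + self.predicted[:, 3]

    @property
    def observed_good(self) -> np.ndarray:
        return self.observed[:, 2] + self.observed[:, 3]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for b in range(self.predicted.shape[0]):
            for k, deck in enumerate("ABCD"):
                rows.append({
                    "group": self.group, "block": b + 1, "deck": deck,
                    "observed": self.observed[b, k],
                    "predicted": self.predicted[b, k],
                })
        return pd.DataFrame(rows)

    def plot(self, path) -> None:
        """Two-panel figure: per-deck curves and the good-deck aggregate."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        blocks = np.arange(1, self.predicted.shape[0] + 1)
        fig, axes = plt.subplots(1, 2, figsize=(9, 3.4), sharey=True)
        for k, deck in enumerate("ABCD"):
            axes[0].plot(blocks, self.observed[:, k], "o-", label=f"{deck} obs")
            axes[0].plot(blocks, self.predicted[:, k], "s--",
                         label=f"{deck} pred")
        axes[0].set_title(f"{self.group}: per deck")
        axes[0].legend(fontsize=6, ncol=2)
        axes[1].plot(blocks, self.observed_good, "o-", label="good obs")
        axes[1].plot(blocks, self.predicted_good, "s--", label="good pred")
        axes[1].set_title("good decks (C+D)")
        axes[1].legend(fontsize=8)
        for ax in axes:
            ax.set_xlabel("block")
            ax.set_ylim(0, 1)
        axes[0].set_ylabel("choice proportion")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def posthoc_block_curves(
    g: GroupDataset,
    fitted_params: list[PVLDeltaParams],
    block_size: int = 10,
    outcome_scale: float = DEFAULT_OUTCOME_SCALE,
) -> PosthocCurves:
    """Aggregate one-step-ahead predictions into block curves for a group."""
    g.require_nonempty()
    if len(fitted_params) != len(g):
        raise ValueError(
            f"got {len(fitted_params)} parameter sets for {len(g)} participants"
        )
    pred_acc, obs_acc = [], []
    for p, params in zip(g, fitted_params):
        probs = one_step_ahead_probs(p, params, outcome_scale)
        n_blocks = int(np.ceil(len(p) / block_size))
        pb = np.zeros((n_blocks, 4))
        for b in range(n_blocks):
            pb[b] = probs[b * block_size : (b + 1) * block_size].mean(axis=0)
        pred_acc.append(pb)
        obs_acc.append(block_proportions(p, block_size)[0])
    shapes = {a.shape for a in pred_acc}
    if len(shapes) != 1:
        raise ValueError("participants must share the same block structure")
    return PosthocCurves(
        group=g.name,
        predicted=np.mean(pred_acc, axis=0),
        observed=np.mean(obs_acc, axis=0),
        block_size=block_size,
    )
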