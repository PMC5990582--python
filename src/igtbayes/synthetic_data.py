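"""Synthetic two-group IGT studies with known ground truth.

Individual probit-scale parameters are drawn from group-level normals,
transformed to the natural scale, and used to forward-simulate agents on a
payoff scheme.  A master seed spawns one stream per participant, so the
first k participants of a study are identical across designs that differ
only in group size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hierarchical_inference import (
    PosteriorSamples,
    natural_from_probit_array,
)
from .igt_task import GroupDataset, PayoffScheme, build_traditional_scheme
from .pvl_delta import PARAM_NAMES, PVLDeltaParams, simulate_agent


@dataclass
class SyntheticTruth:
    """Ground truth of a generated group: hyperparameters, drawn individual
    parameters and the design needed for bit-identical regeneration."""

    group_name: str
    mu: np.ndarray            # probit-scale group means (4,)
    sigma: np.ndarray         # probit-scale group SDs (4,)
    individual_params: list[PVLDeltaParams]
    n_trials: int
    seed: int
    scheme_label: str = "traditional"

    def to_dict(self) -> dict:
        return {
            "group_name": self.group_name,
            "mu": list(map(float, self.mu)),
            "sigma": list(map(float, self.sigma)),
            "individuals": [p.to_dict() for p in self.individual_params],
            "n_trials": self.n_trials,
            "seed": self.seed,
            "scheme": self.scheme_label,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def generate_group_dataset(
    mu,
    sigma,
    n_participants: int,
    n_trials: int = 100,
    scheme: PayoffScheme | None = None,
    seed: int = 0,
    group_name: str = "group",
    id_prefix: str | None = None,
) -> tuple[GroupDataset, SyntheticTruth]:
    """Simulate one group of PVL-Delta agents.

    ``mu`` and ``sigma`` are length-4 probit-scale group-level means and SDs
    (order A, w, a, c); sigma = 0 collapses the group onto identical
    parameters.
    """
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if mu.shape != (4,) or sigma.shape != (4,):
        raise ValueError("mu and sigma must be length-4 (A, w, a, c)")
    if np.any(sigma < 0):
        raise ValueError("sigma must be >= 0")
    if n_participants < 1 or n_trials < 1:
        raise ValueError("n_participants and n_trials must be >= 1")
    if scheme is None:
        scheme = build_traditional_scheme()
    if id_prefix is None:
        id_prefix = group_name

    master = np.random.SeedSequence(seed)
    param_seq, *agent_seqs = master.spawn(n_participants + 1)
    param_rng = np.random.default_rng(param_seq)

    zp = mu + sigma * param_rng.standard_normal((n_participants, 4))
    natural = natural_from_probit_array(zp)

    participants, truths = [], []
    for i in range(n_participants):
        params = PVLDeltaParams(*natural[i])
        p = simulate_agent(
            params, scheme, n_trials, seed=agent_seqs[i],
            participant_id=f"{id_prefix}-{i + 1:03d}",
        )
        p.group_label = group_name
        participants.append(p)
        truths.append(params)

    dataset = GroupDataset(participants, name=group_name)
    truth = SyntheticTruth(group_name, mu, sigma, truths, n_trials, seed)
    return dataset, truth


@dataclass
class StudyDesign:
    n_per_group: tuple[int, int] = (19, 19)
    n_trials: int = 100
    scheme: PayoffScheme | None = None


def generate_two_group_study(
    truth1: dict,
    truth2: dict,
    design: StudyDesign | None = None,
    seed: int = 0,
) -> tuple[GroupDataset, dict]:
    """Generate a pooled two-group study with labels withheld.

    ``truth1``/``truth2`` are dicts with keys ``mu`` and ``sigma`` (probit
    scale, length 4).  Returns the pooled dataset (participants carry no
    group labels) and a truth record holding the hidden labels and both
    group truths; the default design is 19 + 19 participants, 100 trials.
    """
    if design is None:
        design = StudyDesign()
    g1, t1 = generate_group_dataset(
        truth1["mu"], truth1["sigma"], design.n_per_group[0], design.n_trials,
        design.scheme, seed=seed,
        group_name="group1", id_prefix="p1",
    )
    g2, t2 = generate_group_dataset(
        truth2["mu"], truth2["sigma"], design.n_per_group[1], design.n_trials,
        design.scheme, seed=seed + 1_000_003,
        group_name="group2", id_prefix="p2",
    )
    pooled_participants = []
    hidden_labels = []
    for p in list(g1) + list(g2):
        hidden_labels.append(1 if p.group_label == "group1" else 2)
        p.group_label = None
        pooled_participants.append(p)
    pooled = GroupDataset(pooled_participants, name="pooled")
    truth_record = {
        "labels": hidden_labels,
        "group1": t1.to_dict(),
        "group2": t2.to_dict(),
        "seed": seed,
        "design": {"n_per_group": list(design.n_per_group),
                   "n_trials": design.n_trials},
    }
    return pooled, truth_record


def recovery_report(truth: SyntheticTruth, fit: PosteriorSamples) -> pd.DataFrame:
    """Compare group-level truth with a hierarchical fit.

    One row per group-level parameter with the truth, posterior mean, bias,
    posterior SD, RMSE-contribution (squared bias + posterior variance) and
    a 95% central-interval coverage indicator.
    """
    n_fit = fit.metadata.get("n_participants")
    if n_fit is not None and n_fit != len(truth.individual_params):
        raise ValueError(
            f"design mismatch: truth has {len(truth.individual_params)} "
            f"participants, fit has {n_fit}"
        )
    rows = []
    for kind, values in (("mu", truth.mu), ("sigma", truth.sigma)):
        for j, p in enumerate(PARAM_NAMES):
            name = f"{kind}_{p}"
            draws = fit.stacked(name)
            mean = float(draws.mean())
            lo, hi = np.quantile(draws, [0.025, 0.975])
            true_val = float(values[j])
            rows.append({
                "parameter": name,
                "truth": true_val,
                "posterior_mean": mean,
                "bias": mean - true_val,
                "posterior_sd": float(draws.std(ddof=1)),
                "rmse": float(np.sqrt(np.mean((draws - true_val) ** 2))),
                "q2.5": float(lo),
                "q97.5": float(hi),
                "covered": int(lo <= true_val <= hi),
            })
    return pd.DataFrame(rows).set_index("parameter")
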