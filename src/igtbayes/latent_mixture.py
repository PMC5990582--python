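"""Two-group latent-mixture model with informed priors.

All participants are pooled and each receives a latent Bernoulli group
indicator z_i with unknown base rate psi ~ Uniform(0, 1), so that a priori
every participant is equally likely to belong to either group.  Group-level
means get normal priors and group-level SDs zero-truncated normal priors,
both moment-matched to the posteriors of a first-stage hierarchical fit of
each labeled group ("informed" mode); a flag switches back to the
first-stage priors instead (N(0,1) means, Uniform(0,1.5) SDs).

Because the priors are group-specific the mixture components are not
exchangeable, but component identity is still verified after sampling: each
component's fitted means must stay closer to its own prior centers than to
the other component's.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from ._kernels import loglik_many
from .hierarchical_inference import (
    MCMCConfig,
    PosteriorSamples,
    SIGMA_UPPER,
    _RobbinsMonro,
    _norm_logpdf_scaled,
    natural_from_probit_array,
)
from .igt_task import GroupDataset, dataset_to_arrays
from .pvl_delta import PARAM_NAMES


@dataclass(frozen=True)
class InformedPriorSpec:
    """Per-group, per-parameter prior moments.

    ``mu_moments[g][p]`` and ``sigma_moments[g][p]`` hold (mean, sd) of the
    normal prior on the group-level mean and of the zero-truncated normal
    prior on the group-level SD, for group g in {1, 2} and parameter p in
    (A, w, a, c).
    """

    mu_moments: tuple[dict, dict]
    sigma_moments: tuple[dict, dict]
    informed: bool = True
    provenance: dict = field(default_factory=dict, hash=False, compare=False)

    def __post_init__(self):
        for group in (0, 1):
            for p in PARAM_NAMES:
                for moms, what in ((self.mu_moments, "mu"),
                                   (self.sigma_moments, "sigma")):
                    m, s = moms[group][p]
                    if s <= 0:
                        raise ValueError(
                            f"{what}_{p} prior SD for group {group + 1} "
                            f"must be > 0, got {s}"
                        )

    def to_json(self, path) -> None:
        payload = {
            "informed": self.informed,
            "provenance": self.provenance,
            "groups": [
                {
                    "mu": {p: list(self.mu_moments[g][p]) for p in PARAM_NAMES},
                    "sigma": {p: list(self.sigma_moments[g][p])
                              for p in PARAM_NAMES},
                }
                for g in (0, 1)
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "InformedPriorSpec":
        with open(path) as fh:
            payload = json.load(fh)
        mu = tuple({p: tuple(g["mu"][p]) for p in PARAM_NAMES}
                   for g in payload["groups"])
        sigma = tuple({p: tuple(g["sigma"][p]) for p in PARAM_NAMES}
                      for g in payload["groups"])
        return cls(mu, sigma, informed=payload.get("informed", True),
                   provenance=payload.get("provenance", {}))


def uninformed_priors() -> InformedPriorSpec:
    """Stage-1 priors for both components: N(0,1) means; the Uniform(0,1.5)
    SD prior is approximated by a wide zero-truncated normal."""
    mu = tuple({p: (0.0, 1.0) for p in PARAM_NAMES} for _ in (0, 1))
    sigma = tuple({p: (0.75, 10.0) for p in PARAM_NAMES} for _ in (0, 1))
    return InformedPriorSpec(mu, sigma, informed=False)


def build_informed_priors(
    stage1_group1: PosteriorSamples, stage1_group2: PosteriorSamples
) -> InformedPriorSpec:
    """Moment-match normal / zero-truncated-normal priors to the stage-1
    posteriors of the two labeled groups."""
    mu_moms, sigma_moms = [], []
    unconverged = []
    for fit in (stage1_group1, stage1_group2):
        if fit.draws.size == 0:
            raise ValueError("empty posterior sample")
        moments = fit.group_level_moments()
        mu_g, sig_g = {}, {}
        for p in PARAM_NAMES:
            m, s = moments[f"mu_{p}"]
            if s <= 0:
                raise ValueError(f"degenerate posterior for mu_{p} (zero SD)")
            mu_g[p] = (m, s)
            m, s = moments[f"sigma_{p}"]
            if s <= 0:
                raise ValueError(f"degenerate posterior for sigma_{p} (zero SD)")
            sig_g[p] = (m, s)
        mu_moms.append(mu_g)
        sigma_moms.append(sig_g)
        if not fit.converged:
            unconverged.append(fit.metadata.get("group", "?"))
    if unconverged:
        warnings.warn(
            f"stage-1 posterior(s) {unconverged} not converged; informed "
            "priors may be unreliable"
        )
    return InformedPriorSpec(
        tuple(mu_moms), tuple(sigma_moms), informed=True,
        provenance={
            "stage1_groups": [stage1_group1.metadata.get("group"),
                              stage1_group2.metadata.get("group")],
            "stage1_unconverged": unconverged,
        },
    )


@dataclass
class MixtureResult:
    """Posterior group memberships and base rate.

    ``membership`` holds the posterior mean of z_i (probability of belonging
    to group 2).  The object is for membership inference only; parameter
    draws are withheld because the informed-prior construction uses the data
    twice.
    """

    participant_ids: list[str]
    membership: np.ndarray
    psi_draws: np.ndarray
    switch_rate: float
    component_identity_ok: bool
    metadata: dict = field(default_factory=dict)
    not_for_parameter_inference: bool = True

    @property
    def psi_mean(self) -> float:
        return float(self.psi_draws.mean())

    def to_csv(self, path) -> None:
        pd.DataFrame({
            "participant": self.participant_ids,
            "membership_group2": self.membership,
        }).to_csv(path, index=False)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "metadata": self.metadata,
                "psi": {"mean": self.psi_mean,
                        "sd": float(self.psi_draws.std(ddof=1)),
                        "q2.5": float(np.quantile(self.psi_draws, 0.025)),
                        "q97.5": float(np.quantile(self.psi_draws, 0.975))},
                "component_identity_ok": self.component_identity_ok,
                "not_for_parameter_inference": True,
            }, fh, indent=1)

    def plot_membership(self, path, truth=None) -> None:
        """Bar plot of membership probabilities with a 0.5 reference line."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        n = len(self.membership)
        colors = ["0.4" if truth is not None and t == 2 else "white"
                  for t in (truth if truth is not None else [1] * n)]
        fig, ax = plt.subplots(figsize=(max(6, n * 0.25), 3.2))
        ax.bar(np.arange(1, n + 1), self.membership, color=colors,
               edgecolor="black")
        ax.axhline(0.5, color="black", lw=1)
        ax.set_xlabel("participant")
        ax.set_ylabel("P(group 2)")
        ax.set_ylim(0, 1)
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def _trunc_norm_logpdf(x, mom):
    """Log-density kernel of a normal truncated to x > 0 (normalization
    constant omitted; it cancels in MH ratios)."""
    m, s = mom
    return -0.5 * ((x - m) / s) ** 2


def _run_mixture_chain(choices, net, n_trials, priors: InformedPriorSpec,
                       cfg: MCMCConfig, rng: np.random.Generator):
    n = choices.shape[0]
    pm_mu = np.array([[priors.mu_moments[g][p] for p in PARAM_NAMES]
                      for g in (0, 1)])            # (2, 4, 2)
    pm_sig = np.array([[priors.sigma_moments[g][p] for p in PARAM_NAMES]
                       for g in (0, 1)])

    psi = rng.uniform()
    g_i = (rng.uniform(size=n) < psi).astype(np.int64)
    mu = rng.normal(pm_mu[:, :, 0], pm_mu[:, :, 1])           # (2, 4)
    sigma = np.abs(rng.normal(pm_sig[:, :, 0], pm_sig[:, :, 1]))
    np.clip(sigma, 1e-3, SIGMA_UPPER if not priors.informed else None,
            out=sigma)
    zp = mu[g_i] + sigma[g_i] * rng.standard_normal((n, 4))

    use_lik = not cfg.prior_only
    ll = (loglik_many(choices, net, n_trials, natural_from_probit_array(zp))
          if use_lik else np.zeros(n))

    zp_adapt = _RobbinsMonro((n, 4))
    sig_adapt = _RobbinsMonro((2, 4), initial=0.2)

    iters = cfg.n_burnin + cfg.n_retained
    z_sum = np.zeros(n)
    z_rb_sum = np.zeros(n)
    psi_draws = np.empty(cfg.n_retained)
    g_trace = np.empty((cfg.n_retained, n), dtype=np.int8)
    mu_sum = np.zeros((2, 4))

    for it in range(iters):
        adapting = it < cfg.n_burnin

        # individual probit parameters
        mu_i = mu[g_i]
        sig_i = sigma[g_i]
        if not use_lik:
            zp = mu_i + sig_i * rng.standard_normal((n, 4))
        else:
            acc_mat = np.empty((n, 4)) if adapting else None
            for j in range(4):
                prop = zp[:, j] + zp_adapt.scale[:, j] * rng.standard_normal(n)
                zp_prop = zp.copy()
                zp_prop[:, j] = prop
                ll_prop = loglik_many(
                    choices, net, n_trials, natural_from_probit_array(zp_prop)
                )
                logr = (ll_prop - ll
                        + _norm_logpdf_scaled(prop, mu_i[:, j], sig_i[:, j])
                        - _norm_logpdf_scaled(zp[:, j], mu_i[:, j], sig_i[:, j]))
                accept = np.log(rng.uniform(size=n)) < logr
                zp[accept, j] = prop[accept]
                ll = np.where(accept, ll_prop, ll)
                if adapting:
                    acc_mat[:, j] = accept
            if adapting:
                zp_adapt.update(acc_mat)

        # memberships: exact full conditional
        lp = np.zeros((n, 2))
        for g in (0, 1):
            lp[:, g] = _norm_logpdf_scaled(
                zp, mu[g][None, :], sigma[g][None, :]
            ).sum(axis=1)
        lp[:, 0] += np.log1p(-psi)
        lp[:, 1] += np.log(psi)
        p2 = expit(lp[:, 1] - lp[:, 0])
        g_i = (rng.uniform(size=n) < p2).astype(np.int64)

        # joint flip move: switch component and redraw zp from the new
        # component's conditional prior (prior and proposal cancel, so the
        # acceptance ratio is the likelihood times the base-rate odds);
        # breaks the stickiness of the conditional membership update
        g_prop = 1 - g_i
        zp_prop = (mu[g_prop]
                   + sigma[g_prop] * rng.standard_normal((n, 4)))
        if use_lik:
            ll_prop = loglik_many(
                choices, net, n_trials, natural_from_probit_array(zp_prop)
            )
        else:
            ll_prop = ll
        log_odds = np.where(g_prop == 1, np.log(psi) - np.log1p(-psi),
                            np.log1p(-psi) - np.log(psi))
        accept = np.log(rng.uniform(size=n)) < (ll_prop - ll) + log_odds
        g_i = np.where(accept, g_prop, g_i)
        zp = np.where(accept[:, None], zp_prop, zp)
        ll = np.where(accept, ll_prop, ll)

        # base rate
        n2 = int(g_i.sum())
        psi = rng.beta(1 + n2, 1 + n - n2)

        # group-level means: conjugate Gibbs with (informed) normal priors
        for g in (0, 1):
            sel = g_i == g
            cnt = int(sel.sum())
            for j in range(4):
                pr_m, pr_s = pm_mu[g, j]
                prec = 1.0 / pr_s**2 + cnt / sigma[g, j] ** 2
                mean = (pr_m / pr_s**2
                        + zp[sel, j].sum() / sigma[g, j] ** 2) / prec
                mu[g, j] = mean + rng.standard_normal() / np.sqrt(prec)

        # group-level SDs: random walk under zero-truncated normal prior
        for g in (0, 1):
            sel = g_i == g
            cnt = int(sel.sum())
            ssq = ((zp[sel] - mu[g]) ** 2).sum(axis=0)
            prop_sig = sigma[g] + sig_adapt.scale[g] * rng.standard_normal(4)
            inside = prop_sig > 0
            if not priors.informed:
                inside &= prop_sig < SIGMA_UPPER
            with np.errstate(divide="ignore", invalid="ignore"):
                logr = np.where(
                    inside,
                    (-cnt * np.log(prop_sig) - ssq / (2 * prop_sig**2)
                     + _trunc_norm_logpdf(prop_sig, pm_sig[g].T))
                    - (-cnt * np.log(sigma[g]) - ssq / (2 * sigma[g] ** 2)
                       + _trunc_norm_logpdf(sigma[g], pm_sig[g].T)),
                    -np.inf,
                )
            accept = np.log(rng.uniform(size=4)) < logr
            sigma[g] = np.where(accept, prop_sig, sigma[g])
            if adapting:
                gamma = 1.0 / (it + 1) ** 0.6
                sig_adapt.log_scale[g] += gamma * (accept.astype(float) - 0.44)
                np.clip(sig_adapt.log_scale, -8.0, 3.0,
                        out=sig_adapt.log_scale)

        if it >= cfg.n_burnin:
            keep = it - cfg.n_burnin
            z_sum += g_i
            z_rb_sum += p2
            psi_draws[keep] = psi
            g_trace[keep] = g_i
            mu_sum += mu

    return {
        "z_mean": z_sum / cfg.n_retained,
        "z_rb": z_rb_sum / cfg.n_retained,
        "psi": psi_draws,
        "g_trace": g_trace,
        "mu_mean": mu_sum / cfg.n_retained,
    }


def fit_latent_mixture(
    all_participants: GroupDataset,
    priors: InformedPriorSpec,
    cfg: MCMCConfig | None = None,
) -> MixtureResult:
    """Infer group membership for pooled, unlabeled participants.

    Defaults follow the mixture stage: 5 chains, 1000 burn-in, 9000
    retained draws per chain.  Any group labels present on the input are
    ignored.
    """
    all_participants.require_nonempty()
    if len(all_participants) < 2:
        raise ValueError("latent-mixture analysis requires >= 2 participants")
    if cfg is None:
        cfg = MCMCConfig(n_chains=5, n_burnin=1000, n_retained=9000, seed=0)
    choices, net, n_trials = dataset_to_arrays(
        all_participants, scale=cfg.outcome_scale
    )

    seeds = np.random.SeedSequence([cfg.seed, 0x317A]).spawn(cfg.n_chains)
    chains = [
        _run_mixture_chain(choices, net, n_trials, priors, cfg,
                           np.random.default_rng(ss))
        for ss in seeds
    ]

    membership = np.mean([c["z_mean"] for c in chains], axis=0)
    psi_draws = np.concatenate([c["psi"] for c in chains])
    g_all = np.concatenate([c["g_trace"] for c in chains], axis=0)
    switch_rate = float((np.diff(g_all.astype(np.int8), axis=0) != 0).mean())

    # component-identity guard: fitted means must sit nearer their own prior
    # centers than the other component's
    mu_mean = np.mean([c["mu_mean"] for c in chains], axis=0)
    centers = np.array([[priors.mu_moments[g][p][0] for p in PARAM_NAMES]
                        for g in (0, 1)])
    own = np.linalg.norm(mu_mean - centers, axis=1)
    other = np.linalg.norm(mu_mean - centers[::-1], axis=1)
    identity_ok = bool(np.all(own <= other)) or not priors.informed
    if priors.informed and not identity_ok:
        warnings.warn("mixture components drifted toward the opposite "
                      "group's prior centers; labels may have switched")

    return MixtureResult(
        participant_ids=[p.participant_id for p in all_participants],
        membership=membership,
        psi_draws=psi_draws,
        switch_rate=switch_rate,
        component_identity_ok=identity_ok,
        metadata={"seed": cfg.seed, "n_chains": cfg.n_chains,
                  "n_retained": cfg.n_retained, "n_burnin": cfg.n_burnin,
                  "informed_priors": priors.informed,
                  "prior_only": cfg.prior_only},
    )


def classify_members(
    r: MixtureResult, threshold: float = 0.5, truth=None
) -> dict:
    """Threshold memberships into labels; report accuracy if truth given.

    Labels: 2 when membership > threshold, 1 when below, "unclassified" on
    an exact tie.
    """
    labels = []
    for m in r.membership:
        if m > threshold:
            labels.append(2)
        elif m < threshold:
            labels.append(1)
        else:
            labels.append("unclassified")
    out = {"labels": labels, "threshold": threshold}
    if truth is not None:
        truth = list(truth)
        if len(truth) != len(labels):
            raise ValueError("truth length mismatch")
        correct = sum(1 for l, t in zip(labels, truth) if l == t)
        confusion = {(t, l): 0 for t in (1, 2) for l in (1, 2, "unclassified")}
        for l, t in zip(labels, truth):
            confusion[(t, l)] += 1
        out["accuracy"] = correct / len(labels)
        out["confusion"] = confusion
    return out
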