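"""Product-space Bayes factor comparison of two groups of IGT players.

The 16 candidate models differ in which of the four group-level mean
parameters are allowed to differ between groups (group-level SDs are always
shared).  A supermodel carries, for every parameter, a common mean, two
group-specific means, and a binary difference indicator; indicators are
updated by exact full-conditional Gibbs steps while parameters inactive
under the currently visited model follow moment-matched pseudo-priors built
from pilot fits of the null and the full model (Carlin-Chib).  Under equal
prior model probabilities (1/16 each) the Bayes factor between two models
is the ratio of their posterior model probabilities, estimated as the
proportion of iterations in which each model is visited.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from ._kernels import loglik_many, loglik_rows_probit, zp_joint_update
from .hierarchical_inference import (
    MCMCConfig,
    SIGMA_UPPER,
    _RobbinsMonro,
    _norm_logpdf_scaled,
    natural_from_probit_array,
)
from .igt_task import GroupDataset, dataset_to_arrays
from .pvl_delta import PARAM_NAMES

JEFFREYS_CUTS = ((1.0, "anecdotal"), (3.0, "moderate"), (10.0, "strong"),
                 (30.0, "very strong"), (100.0, "extreme"))


# ---------------------------------------------------------------------------
# model space
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """One group-difference specification: which group-level means differ."""

    diff_A: bool = False
    diff_w: bool = False
    diff_a: bool = False
    diff_c: bool = False

    @property
    def indicators(self) -> tuple[bool, bool, bool, bool]:
        return (self.diff_A, self.diff_w, self.diff_a, self.diff_c)

    @property
    def is_null(self) -> bool:
        return not any(self.indicators)

    @property
    def name(self) -> str:
        if self.is_null:
            return "null"
        return "+".join(
            f"mu_{p}" for p, on in zip(PARAM_NAMES, self.indicators) if on
        )

    @property
    def n_differences(self) -> int:
        return sum(self.indicators)


def enumerate_model_space() -> list[ModelSpec]:
    """All 16 specifications, null first, then by number of differing means
    (ties broken in A, w, a, c order)."""
    specs = [ModelSpec(*bits) for bits in itertools.product([False, True], repeat=4)]
    specs.sort(key=lambda s: (s.n_differences,
                              tuple(not b for b in s.indicators)))
    assert specs[0].is_null and len(specs) == 16
    return specs


def bayes_factor_from_evidence(e0: float, e1: float) -> float:
    """BF_01 from two evidence values on a common scale (posterior model
    probabilities, or BF_10 values versus a shared null)."""
    if e0 <= 0 or e1 <= 0:
        raise ValueError("evidence values must be strictly positive")
    return e0 / e1


def jeffreys_category(bf: float) -> tuple[str, int]:
    """Jeffreys evidence label for a Bayes factor.

    Returns ``(label, direction)`` with direction +1 when the numerator
    model is favored (bf >= 1) and -1 otherwise; values below 1 are
    inverted before classification.
    """
    if bf <= 0 or not np.isfinite(bf):
        raise ValueError("Bayes factor must be positive and finite")
    direction = 1
    if bf < 1.0:
        bf, direction = 1.0 / bf, -1
    label = "extreme"
    for upper, lab in zip([c for c, _ in JEFFREYS_CUTS[1:]] + [np.inf],
                          [lab for _, lab in JEFFREYS_CUTS]):
        if bf < upper:
            label = lab
            break
    return label, direction


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

@dataclass
class ComparisonResult:
    """Posterior model probabilities over the 16 specifications."""

    specs: list[ModelSpec]
    probabilities: np.ndarray            # visit proportions, sum to 1
    probabilities_rb: np.ndarray         # Rao-Blackwellized companion
    indicator_trace: np.ndarray          # (chains, iterations, 4) bool
    switch_rate: float                   # fraction of iterations changing model
    pseudo_priors: dict
    metadata: dict = field(default_factory=dict)

    def probability(self, spec_or_name) -> float:
        return float(self.probabilities[self._index(spec_or_name)])

    def _index(self, spec_or_name) -> int:
        if isinstance(spec_or_name, ModelSpec):
            return self.specs.index(spec_or_name)
        names = [s.name for s in self.specs]
        return names.index(spec_or_name)

    def bayes_factor(self, m0, m1) -> float:
        """BF_m0,m1 as the ratio of posterior model probabilities."""
        return bayes_factor_from_evidence(
            self.probability(m0), self.probability(m1)
        )

    def table(self) -> pd.DataFrame:
        rows = []
        for spec, p, prb in zip(self.specs, self.probabilities,
                                self.probabilities_rb):
            rows.append({"model": spec.name,
                         "n_differences": spec.n_differences,
                         "posterior_probability": p,
                         "posterior_probability_rb": prb})
        return pd.DataFrame(rows)

    def bf_matrix(self) -> pd.DataFrame:
        names = [s.name for s in self.specs]
        p = np.where(self.probabilities > 0, self.probabilities, np.nan)
        return pd.DataFrame(p[:, None] / p[None, :], index=names, columns=names)

    def jeffreys_labels(self) -> dict[str, str]:
        """Evidence label of the null against every alternative."""
        out = {}
        p_null = self.probabilities[0]
        for spec, p in zip(self.specs[1:], self.probabilities[1:]):
            if p_null <= 0 or p <= 0:
                out[spec.name] = "undefined"
                continue
            label, _ = jeffreys_category(p_null / p)
            out[spec.name] = label
        return out

    def to_json(self, path) -> None:
        payload = {
            "metadata": self.metadata,
            "probabilities": {s.name: float(p)
                              for s, p in zip(self.specs, self.probabilities)},
            "probabilities_rb": {s.name: float(p)
                                 for s, p in zip(self.specs,
                                                 self.probabilities_rb)},
            "switch_rate": self.switch_rate,
            "jeffreys_vs_null": self.jeffreys_labels(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


# ---------------------------------------------------------------------------
# pilot fits (pseudo-prior construction)
# ---------------------------------------------------------------------------

def _fit_two_group_fixed(choices, net, n_trials, group_idx, diff: np.ndarray,
                         cfg: MCMCConfig, rng_seq) -> dict:
    """Metropolis-within-Gibbs fit of one fixed two-group specification.

    ``diff`` is a length-4 boolean vector; where True the two groups get
    separate means, elsewhere a common mean.  Group-level SDs are shared.
    Returns posterior moments for every mean parameter (for pseudo-priors).
    """
    n = choices.shape[0]
    in_g2 = group_idx == 1
    counts = np.array([int((~in_g2).sum()), int(in_g2.sum())])

    draws = {f"mu_common_{p}": [] for p in PARAM_NAMES}
    draws.update({f"mu1_{p}": [] for p in PARAM_NAMES})
    draws.update({f"mu2_{p}": [] for p in PARAM_NAMES})
    draws.update({f"sigma_{p}": [] for p in PARAM_NAMES})

    for ss in rng_seq:
        rng = np.random.default_rng(ss)
        mu_c = rng.normal(0, 1, 4)
        mu12 = rng.normal(0, 1, (2, 4))
        sigma = rng.uniform(0.2, 1.3, 4)
        means_i = np.where(diff, np.where(in_g2[:, None], mu12[1], mu12[0]),
                           mu_c)
        zp = means_i + sigma * rng.standard_normal((n, 4))
        use_lik = not cfg.prior_only
        ll = (loglik_many(choices, net, n_trials, natural_from_probit_array(zp))
              if use_lik else np.zeros(n))
        zp_adapt = _RobbinsMonro((n, 4))
        sig_adapt = _RobbinsMonro(4, initial=0.2)

        for it in range(cfg.n_burnin + cfg.n_retained):
            adapting = it < cfg.n_burnin
            means_i = np.where(
                diff, np.where(in_g2[:, None], mu12[1], mu12[0]), mu_c
            )
            if not use_lik:
                zp = means_i + sigma * rng.standard_normal((n, 4))
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
                            + _norm_logpdf_scaled(prop, means_i[:, j], sigma[j])
                            - _norm_logpdf_scaled(zp[:, j], means_i[:, j],
                                                  sigma[j]))
                    accept = np.log(rng.uniform(size=n)) < logr
                    zp[accept, j] = prop[accept]
                    ll = np.where(accept, ll_prop, ll)
                    if adapting:
                        acc_mat[:, j] = accept
                if adapting:
                    zp_adapt.update(acc_mat)

            # means
            for j in range(4):
                if diff[j]:
                    for g in (0, 1):
                        sel = in_g2 if g == 1 else ~in_g2
                        prec = 1.0 + counts[g] / sigma[j] ** 2
                        mean = (zp[sel, j].sum() / sigma[j] ** 2) / prec
                        mu12[g, j] = mean + rng.standard_normal() / np.sqrt(prec)
                else:
                    prec = 1.0 + n / sigma[j] ** 2
                    mean = (zp[:, j].sum() / sigma[j] ** 2) / prec
                    mu_c[j] = mean + rng.standard_normal() / np.sqrt(prec)

            # shared sigmas
            means_i = np.where(
                diff, np.where(in_g2[:, None], mu12[1], mu12[0]), mu_c
            )
            prop_sig = sigma + sig_adapt.scale * rng.standard_normal(4)
            inside = (prop_sig > 0) & (prop_sig < SIGMA_UPPER)
            ss2 = ((zp - means_i) ** 2).sum(axis=0)
            with np.errstate(divide="ignore", invalid="ignore"):
                logr = np.where(
                    inside,
                    -n * np.log(prop_sig) - ss2 / (2 * prop_sig**2)
                    + n * np.log(sigma) + ss2 / (2 * sigma**2),
                    -np.inf,
                )
            accept = np.log(rng.uniform(size=4)) < logr
            sigma = np.where(accept, prop_sig, sigma)
            if adapting:
                sig_adapt.update(accept)

            if it >= cfg.n_burnin:
                for j, p in enumerate(PARAM_NAMES):
                    draws[f"mu_common_{p}"].append(mu_c[j])
                    draws[f"mu1_{p}"].append(mu12[0, j])
                    draws[f"mu2_{p}"].append(mu12[1, j])
                    draws[f"sigma_{p}"].append(sigma[j])

    return {k: (float(np.mean(v)), float(np.std(v, ddof=1)))
            for k, v in draws.items()}


def build_pseudo_priors(g1: GroupDataset, g2: GroupDataset, cfg: MCMCConfig,
                        pilot_retained: int = 1000,
                        pilot_burnin: int = 500) -> dict:
    """Moment-matched normal pseudo-priors from pilot fits.

    The common means come from a pilot fit of the null model and the
    group-specific means from a pilot fit of the full (all-different) model,
    the two most extreme specifications in the space.
    """
    choices, net, n_trials, group_idx = _pool(g1, g2, cfg.outcome_scale)
    pilot_cfg = cfg.with_(n_burnin=pilot_burnin, n_retained=pilot_retained)
    root = np.random.SeedSequence(cfg.seed).spawn(2)
    null_moms = _fit_two_group_fixed(
        choices, net, n_trials, group_idx, np.zeros(4, dtype=bool),
        pilot_cfg, root[0].spawn(2),
    )
    full_moms = _fit_two_group_fixed(
        choices, net, n_trials, group_idx, np.ones(4, dtype=bool),
        pilot_cfg, root[1].spawn(2),
    )
    pseudo = {}
    for p in PARAM_NAMES:
        pseudo[f"mu_common_{p}"] = null_moms[f"mu_common_{p}"]
        pseudo[f"mu1_{p}"] = full_moms[f"mu1_{p}"]
        pseudo[f"mu2_{p}"] = full_moms[f"mu2_{p}"]
    # guard against degenerate pilot SDs
    for k, (m, s) in pseudo.items():
        pseudo[k] = (m, max(s, 1e-3))
    return pseudo


def _pool(g1: GroupDataset, g2: GroupDataset, scale: float):
    g1.require_nonempty()
    g2.require_nonempty()
    merged = GroupDataset(list(g1.participants) + list(g2.participants),
                          name="pooled")
    choices, net, n_trials = dataset_to_arrays(merged, scale=scale)
    group_idx = np.array([0] * len(g1) + [1] * len(g2))
    return choices, net, n_trials, group_idx


# ---------------------------------------------------------------------------
# product-space sampler
# ---------------------------------------------------------------------------

def _log_normal_evidence(zsum, zsq, n, sigma, prior_mean=0.0, prior_sd=1.0):
    """log integral of prod_i N(z_i | m, sigma) N(m | prior_mean, prior_sd) dm."""
    lam = 1.0 / prior_sd**2 + n / sigma**2
    b = zsum / sigma**2 + prior_mean / prior_sd**2
    return (
        -0.5 * n * np.log(2.0 * np.pi) - n * np.log(sigma)
        - np.log(prior_sd) - 0.5 * np.log(lam)
        - 0.5 * (zsq / sigma**2 + prior_mean**2 / prior_sd**2 - b**2 / lam)
    )


def _run_product_space_chain(choices, net, n_trials, group_idx, pseudo,
                             cfg: MCMCConfig, rng: np.random.Generator,
                             indicator_update: str = "collapsed"):
    n = choices.shape[0]
    in_g2 = group_idx == 1
    counts = np.array([int((~in_g2).sum()), int(in_g2.sum())])

    pm_c = np.array([pseudo[f"mu_common_{p}"] for p in PARAM_NAMES])  # (4,2)
    pm_1 = np.array([pseudo[f"mu1_{p}"] for p in PARAM_NAMES])
    pm_2 = np.array([pseudo[f"mu2_{p}"] for p in PARAM_NAMES])

    d = rng.integers(0, 2, size=4).astype(bool)
    mu_c = rng.normal(pm_c[:, 0], pm_c[:, 1])
    mu1 = rng.normal(pm_1[:, 0], pm_1[:, 1])
    mu2 = rng.normal(pm_2[:, 0], pm_2[:, 1])
    sigma = rng.uniform(0.2, 1.3, 4)

    def active_means():
        return np.where(d, np.where(in_g2[:, None], mu2, mu1), mu_c)

    zp = active_means() + sigma * rng.standard_normal((n, 4))
    use_lik = not cfg.prior_only
    ll = (loglik_rows_probit(choices, net, n_trials, zp)
          if use_lik else np.zeros(n))
    sign_i = np.where(in_g2, -1.0, 1.0)    # differential-move direction

    zp_adapt = _RobbinsMonro((n, 4), target=0.25)
    sig_adapt = _RobbinsMonro(4, initial=0.2)
    tr_adapt = _RobbinsMonro(4, initial=0.2)
    df_adapt = _RobbinsMonro(4, initial=0.2)
    sc_adapt = _RobbinsMonro(4, initial=0.2)

    iters = cfg.n_burnin + cfg.n_retained
    d_trace = np.empty((cfg.n_retained, 4), dtype=bool)
    p1_trace = np.empty((cfg.n_retained, 4))

    for it in range(iters):
        adapting = it < cfg.n_burnin

        # individual parameters: joint 4-coordinate Metropolis refreshes
        means_i = active_means()
        if not use_lik:
            zp = means_i + sigma * rng.standard_normal((n, 4))
        else:
            for _sweep in range(max(1, cfg.zp_sweeps)):
                acc = zp_joint_update(
                    choices, net, n_trials, zp, means_i, sigma,
                    zp_adapt.scale, ll,
                    rng.standard_normal((n, 4)), rng.uniform(size=n),
                )
                if adapting:
                    zp_adapt.update(acc[:, None] * np.ones((1, 4)))

        # shared sigmas
        prop_sig = sigma + sig_adapt.scale * rng.standard_normal(4)
        inside = (prop_sig > 0) & (prop_sig < SIGMA_UPPER)
        ss2 = ((zp - means_i) ** 2).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            logr = np.where(
                inside,
                -n * np.log(prop_sig) - ss2 / (2 * prop_sig**2)
                + n * np.log(sigma) + ss2 / (2 * sigma**2),
                -np.inf,
            )
        accept = np.log(rng.uniform(size=4)) < logr
        sigma = np.where(accept, prop_sig, sigma)
        if adapting:
            sig_adapt.update(accept)

        if use_lik:
            # group moves: joint translation (funnel), differential
            # translation (between-group difference), joint scale (funnel)
            tr_acc = np.zeros(4)
            df_acc = np.zeros(4)
            sc_acc = np.zeros(4)
            for j in range(4):
                delta = tr_adapt.scale[j] * rng.standard_normal()
                zp_prop = zp.copy()
                zp_prop[:, j] += delta
                ll_prop = loglik_rows_probit(choices, net, n_trials, zp_prop)
                if d[j]:
                    logpr = (0.5 * mu1[j] ** 2 - 0.5 * (mu1[j] + delta) ** 2
                             + 0.5 * mu2[j] ** 2 - 0.5 * (mu2[j] + delta) ** 2)
                else:
                    logpr = 0.5 * mu_c[j] ** 2 - 0.5 * (mu_c[j] + delta) ** 2
                if np.log(rng.uniform()) < (ll_prop - ll).sum() + logpr:
                    zp = zp_prop
                    ll = ll_prop
                    if d[j]:
                        mu1[j] += delta
                        mu2[j] += delta
                    else:
                        mu_c[j] += delta
                    tr_acc[j] = 1.0
            for j in range(4):
                delta = df_adapt.scale[j] * rng.standard_normal()
                zp_prop = zp.copy()
                zp_prop[:, j] += sign_i * delta
                ll_prop = loglik_rows_probit(choices, net, n_trials, zp_prop)
                if d[j]:
                    # group means move apart; individual deviations unchanged
                    logpr = (0.5 * mu1[j] ** 2 - 0.5 * (mu1[j] + delta) ** 2
                             + 0.5 * mu2[j] ** 2 - 0.5 * (mu2[j] - delta) ** 2)
                else:
                    # common mean fixed: the zp prior terms change
                    logpr = (
                        _norm_logpdf_scaled(zp_prop[:, j], mu_c[j], sigma[j])
                        - _norm_logpdf_scaled(zp[:, j], mu_c[j], sigma[j])
                    ).sum()
                if np.log(rng.uniform()) < (ll_prop - ll).sum() + logpr:
                    zp = zp_prop
                    ll = ll_prop
                    if d[j]:
                        mu1[j] += delta
                        mu2[j] -= delta
                    df_acc[j] = 1.0
            means_i = active_means()
            for j in range(4):
                eps = sc_adapt.scale[j] * rng.standard_normal()
                s_new = sigma[j] * np.exp(eps)
                if not 0.0 < s_new < SIGMA_UPPER:
                    continue
                zp_prop = zp.copy()
                zp_prop[:, j] = (means_i[:, j]
                                 + (zp[:, j] - means_i[:, j]) * np.exp(eps))
                ll_prop = loglik_rows_probit(choices, net, n_trials, zp_prop)
                if np.log(rng.uniform()) < (ll_prop - ll).sum() + eps:
                    sigma[j] = s_new
                    zp = zp_prop
                    ll = ll_prop
                    sc_acc[j] = 1.0
            if adapting:
                tr_adapt.update(tr_acc)
                df_adapt.update(df_acc)
                sc_adapt.update(sc_acc)

        # indicators then means
        zg1 = zp[~in_g2]
        zg2 = zp[in_g2]
        if indicator_update == "collapsed":
            # blocked update: d_j from its conditional with all three mean
            # variants integrated out analytically, then means given d_j
            for j in range(4):
                lp0 = _log_normal_evidence(
                    zp[:, j].sum(), (zp[:, j] ** 2).sum(), n, sigma[j]
                )
                lp1 = (
                    _log_normal_evidence(
                        zg1[:, j].sum(), (zg1[:, j] ** 2).sum(),
                        counts[0], sigma[j])
                    + _log_normal_evidence(
                        zg2[:, j].sum(), (zg2[:, j] ** 2).sum(),
                        counts[1], sigma[j])
                )
                p1 = float(expit(lp1 - lp0))
                d[j] = rng.uniform() < p1
                if it >= cfg.n_burnin:
                    p1_trace[it - cfg.n_burnin, j] = p1
            _draw_means(zp, in_g2, counts, d, sigma, mu_c, mu1, mu2,
                        pm_c, pm_1, pm_2, n, rng)
        else:  # carlin-chib: exact full conditionals given sampled means
            for j in range(4):
                lp0 = (
                    _norm_logpdf_scaled(zp[:, j], mu_c[j], sigma[j]).sum()
                    - 0.5 * mu_c[j] ** 2                    # real prior N(0,1)
                    + _pseudo_logpdf(mu1[j], pm_1[j])
                    + _pseudo_logpdf(mu2[j], pm_2[j])
                )
                lp1 = (
                    _norm_logpdf_scaled(zg1[:, j], mu1[j], sigma[j]).sum()
                    + _norm_logpdf_scaled(zg2[:, j], mu2[j], sigma[j]).sum()
                    - 0.5 * mu1[j] ** 2 - 0.5 * mu2[j] ** 2
                    + _pseudo_logpdf(mu_c[j], pm_c[j])
                )
                p1 = float(expit(lp1 - lp0))
                d[j] = rng.uniform() < p1
                if it >= cfg.n_burnin:
                    p1_trace[it - cfg.n_burnin, j] = p1
            _draw_means(zp, in_g2, counts, d, sigma, mu_c, mu1, mu2,
                        pm_c, pm_1, pm_2, n, rng)

        if it >= cfg.n_burnin:
            d_trace[it - cfg.n_burnin] = d

    return d_trace, p1_trace


def _draw_means(zp, in_g2, counts, d, sigma, mu_c, mu1, mu2,
                pm_c, pm_1, pm_2, n, rng):
    """Conjugate draws for active means; pseudo-prior draws for inactive."""
    for j in range(4):
        if d[j]:
            mu_c[j] = rng.normal(pm_c[j, 0], pm_c[j, 1])
            for g, mu_g in ((0, mu1), (1, mu2)):
                sel = in_g2 if g == 1 else ~in_g2
                prec = 1.0 + counts[g] / sigma[j] ** 2
                mean = (zp[sel, j].sum() / sigma[j] ** 2) / prec
                mu_g[j] = mean + rng.standard_normal() / np.sqrt(prec)
        else:
            prec = 1.0 + n / sigma[j] ** 2
            mean = (zp[:, j].sum() / sigma[j] ** 2) / prec
            mu_c[j] = mean + rng.standard_normal() / np.sqrt(prec)
            mu1[j] = rng.normal(pm_1[j, 0], pm_1[j, 1])
            mu2[j] = rng.normal(pm_2[j, 0], pm_2[j, 1])


def _pseudo_logpdf(x, mom):
    m, s = mom
    return -np.log(s) - 0.5 * ((x - m) / s) ** 2


def fit_product_space(
    g1: GroupDataset,
    g2: GroupDataset,
    cfg: MCMCConfig | None = None,
    pseudo_priors: dict | None = None,
    indicator_update: str = "collapsed",
) -> ComparisonResult:
    """Estimate posterior probabilities of all 16 group-difference models.

    Defaults follow the comparison stage: 3 chains, 1000 burn-in, 7000
    retained draws per chain.  ``indicator_update`` selects the backend:
    "collapsed" (default) integrates the three mean variants out of the
    indicator conditionals analytically, "carlin-chib" conditions on the
    sampled means and relies on the moment-matched pseudo-priors.  Both
    target the same posterior model probabilities.  ``pseudo_priors`` (from
    :func:`build_pseudo_priors`) may be passed to reuse pilot fits across
    runs; otherwise pilots are run internally when needed.
    """
    if indicator_update not in ("collapsed", "carlin-chib"):
        raise ValueError(f"unknown indicator_update {indicator_update!r}")
    if cfg is None:
        cfg = MCMCConfig(n_chains=3, n_burnin=1000, n_retained=7000, seed=0)
    if pseudo_priors is None:
        if cfg.prior_only or indicator_update == "collapsed":
            # pseudo-prior draws never enter the collapsed indicator
            # conditionals, so prior moments suffice
            pseudo_priors = {}
            for p in PARAM_NAMES:
                for key in (f"mu_common_{p}", f"mu1_{p}", f"mu2_{p}"):
                    pseudo_priors[key] = (0.0, 1.0)
        else:
            pseudo_priors = build_pseudo_priors(g1, g2, cfg)

    choices, net, n_trials, group_idx = _pool(g1, g2, cfg.outcome_scale)
    seeds = np.random.SeedSequence([cfg.seed, 0x9E37]).spawn(cfg.n_chains)
    d_traces, p1_traces = [], []
    for ss in seeds:
        rng = np.random.default_rng(ss)
        d_tr, p1_tr = _run_product_space_chain(
            choices, net, n_trials, group_idx, pseudo_priors, cfg, rng,
            indicator_update=indicator_update,
        )
        d_traces.append(d_tr)
        p1_traces.append(p1_tr)
    d_all = np.stack(d_traces)          # (chains, iters, 4)
    p1_all = np.stack(p1_traces)

    specs = enumerate_model_space()
    spec_bits = np.array([s.indicators for s in specs])   # (16, 4)

    flat_d = d_all.reshape(-1, 4)
    codes = flat_d @ (1 << np.arange(4))
    spec_codes = spec_bits @ (1 << np.arange(4))
    visit_counts = np.array([(codes == c).sum() for c in spec_codes])
    probs = visit_counts / len(codes)

    # Rao-Blackwellized: indicators are conditionally independent given the
    # continuous state, so the joint config probability factorizes
    flat_p1 = p1_all.reshape(-1, 4)
    per_cfg = np.where(spec_bits[None, :, :], flat_p1[:, None, :],
                       1.0 - flat_p1[:, None, :]).prod(axis=2)
    probs_rb = per_cfg.mean(axis=0)

    switches = (np.diff(d_all.reshape(cfg.n_chains, -1, 4), axis=1) != 0)
    switch_rate = float(switches.any(axis=2).mean())
    if switch_rate < 0.01:
        warnings.warn(
            "model indicator rarely switches; pseudo-priors may be "
            "mismatched and posterior model probabilities unreliable"
        )

    return ComparisonResult(
        specs=specs,
        probabilities=probs,
        probabilities_rb=probs_rb,
        indicator_trace=d_all,
        switch_rate=switch_rate,
        pseudo_priors=pseudo_priors,
        metadata={"seed": cfg.seed, "n_chains": cfg.n_chains,
                  "n_retained": cfg.n_retained, "n_burnin": cfg.n_burnin,
                  "prior_only": cfg.prior_only,
                  "n_group1": len(g1), "n_group2": len(g2)},
    )


def stability_check(
    g1: GroupDataset,
    g2: GroupDataset,
    cfg: MCMCConfig,
    reduced_retained: int = 5000,
    indicator_update: str = "collapsed",
) -> tuple[ComparisonResult, ComparisonResult, float]:
    """Re-run the product space with fewer retained draws and report the
    maximum absolute difference in posterior model probabilities."""
    pseudo = (build_pseudo_priors(g1, g2, cfg)
              if indicator_update == "carlin-chib" else None)
    full = fit_product_space(g1, g2, cfg, pseudo_priors=pseudo,
                             indicator_update=indicator_update)
    reduced = fit_product_space(
        g1, g2, cfg.with_(n_retained=reduced_retained, seed=cfg.seed + 1),
        pseudo_priors=full.pseudo_priors, indicator_update=indicator_update,
    )
    max_diff = float(np.abs(full.probabilities - reduced.probabilities).max())
    return full, reduced, max_diff
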