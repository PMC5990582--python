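"""Hierarchical Bayesian estimation of PVL-Delta parameters for one group.

Individual parameters are probit-transformed to the real line (w and c are
first rescaled by 1/5 to the unit interval) and modeled as draws from
group-level normals.  Priors: mu ~ N(0, 1) on each group-level mean and
sigma ~ Uniform(0, 1.5) on each group-level standard deviation.

The sampler is an adaptive Metropolis-within-Gibbs scheme: random-walk
updates of the individual probit parameters (vectorized across
participants), conjugate Gibbs updates of the group means, and bounded
random-walk updates of the group standard deviations.  Proposal scales are
tuned during burn-in only, so the retained draws come from a fixed-kernel
chain.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from ._kernels import loglik_many
from .igt_task import GroupDataset, dataset_to_arrays
from .pvl_delta import DEFAULT_OUTCOME_SCALE, PARAM_NAMES, PVLDeltaParams

PROBIT_EPS = 1e-6
_SCALES = np.array([1.0, 5.0, 1.0, 5.0])  # A, w, a, c natural-range widths

SIGMA_UPPER = 1.5
TARGET_ACCEPT = 0.44


# ---------------------------------------------------------------------------
# probit transforms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProbitParams:
    """Probit-scale counterpart of :class:`PVLDeltaParams`."""

    A: float
    w: float
    a: float
    c: float

    def as_array(self) -> np.ndarray:
        return np.array([self.A, self.w, self.a, self.c])


def to_probit(params: PVLDeltaParams, eps: float = PROBIT_EPS) -> ProbitParams:
    """Map natural parameters to the probit scale (clipping at the bounds)."""
    unit = params.as_array() / _SCALES
    clipped = np.clip(unit, eps, 1.0 - eps)
    if np.any(clipped != unit):
        warnings.warn("boundary parameter value clipped before probit transform")
    z = ndtri(clipped)
    return ProbitParams(*z)


def to_natural(pp: ProbitParams) -> PVLDeltaParams:
    """Inverse of :func:`to_probit`."""
    return PVLDeltaParams(*(ndtr(pp.as_array()) * _SCALES))


def natural_from_probit_array(zp: np.ndarray) -> np.ndarray:
    """Vectorized probit -> natural transform; last axis is (A, w, a, c)."""
    return ndtr(zp) * _SCALES


# ---------------------------------------------------------------------------
# config and results
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MCMCConfig:
    """Sampler settings; defaults follow the estimation stage (3 chains,
    2000 burn-in, 4000 retained per chain)."""

    n_chains: int = 3
    n_burnin: int = 2000
    n_retained: int = 4000
    seed: int = 0
    rhat_threshold: float = 1.05
    prior_only: bool = False
    outcome_scale: float = DEFAULT_OUTCOME_SCALE
    thin: int = 1
    zp_sweeps: int = 1  # inner refreshes of individual parameters per iteration

    def __post_init__(self):
        if self.n_chains < 2:
            raise ValueError("need >= 2 chains for convergence diagnostics")
        if self.n_burnin < 0 or self.n_retained < 1:
            raise ValueError("iteration counts must be positive")
        if self.seed is None:
            raise ValueError("a seed is mandatory")

    def with_(self, **kw) -> "MCMCConfig":
        return replace(self, **kw)


def gelman_rubin(chains: np.ndarray) -> float:
    """Split-chain Gelman-Rubin statistic for one parameter.

    ``chains`` has shape (n_chains, n_draws).  Each chain is split in half
    before comparing between- to within-chain variance.  Returns NaN when
    the within-chain variance is zero (diagnostic undefined).
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("need a (n_chains >= 2, n_draws) array")
    n = chains.shape[1] // 2
    if n < 2:
        raise ValueError("need >= 4 draws per chain")
    split = np.concatenate([chains[:, :n], chains[:, n : 2 * n]], axis=0)
    m = split.shape[0]
    within = split.var(axis=1, ddof=1)
    w = within.mean()
    if w == 0.0:
        return float("nan")
    b = n * split.mean(axis=1).var(ddof=1)
    var_hat = (n - 1) / n * w + b / n
    return float(np.sqrt(var_hat / w))


class PosteriorSamples:
    """Posterior draws (chains x iterations x named parameters) plus
    diagnostics and provenance metadata."""

    def __init__(self, draws: np.ndarray, names: list[str], config: MCMCConfig,
                 metadata: dict | None = None):
        if draws.ndim != 3 or draws.shape[2] != len(names):
            raise ValueError("draws must be (chains, iterations, parameters)")
        self.draws = draws
        self.names = list(names)
        self.config = config
        self.metadata = metadata or {}
        self._rhat: dict[str, float] | None = None

    def __getitem__(self, name: str) -> np.ndarray:
        return self.draws[:, :, self.names.index(name)]

    def stacked(self, name: str) -> np.ndarray:
        return self[name].reshape(-1)

    @property
    def rhat(self) -> dict[str, float]:
        if self._rhat is None:
            self._rhat = {
                name: gelman_rubin(self.draws[:, :, i])
                for i, name in enumerate(self.names)
            }
        return self._rhat

    @property
    def max_rhat(self) -> float:
        vals = [v for v in self.rhat.values() if np.isfinite(v)]
        return max(vals) if vals else float("nan")

    @property
    def converged(self) -> bool:
        r = self.rhat
        return all(np.isfinite(v) and v < self.config.rhat_threshold
                   for v in r.values())

    def summary(self) -> pd.DataFrame:
        rows = []
        for i, name in enumerate(self.names):
            x = self.draws[:, :, i].reshape(-1)
            rows.append({
                "parameter": name,
                "mean": x.mean(),
                "sd": x.std(ddof=1),
                "q2.5": np.quantile(x, 0.025),
                "q97.5": np.quantile(x, 0.975),
                "rhat": self.rhat[name],
            })
        return pd.DataFrame(rows).set_index("parameter")

    def to_csv(self, path) -> None:
        """Tidy export: chain, iteration, parameter, value."""
        c, it, p = self.draws.shape
        chain_idx = np.repeat(np.arange(c), it * p)
        iter_idx = np.tile(np.repeat(np.arange(it), p), c)
        par_idx = np.tile(np.arange(p), c * it)
        pd.DataFrame({
            "chain": chain_idx,
            "iteration": iter_idx,
            "parameter": np.asarray(self.names)[par_idx],
            "value": self.draws.reshape(-1),
        }).to_csv(path, index=False)

    def to_json_summary(self, path) -> None:
        payload = {
            "metadata": {**self.metadata, "seed": self.config.seed,
                         "n_chains": self.config.n_chains,
                         "n_retained": self.config.n_retained,
                         "n_burnin": self.config.n_burnin},
            "parameters": {
                name: {k: float(v) for k, v in row.items()}
                for name, row in self.summary().iterrows()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    # -- convenience accessors used downstream --------------------------------

    def group_level_moments(self) -> dict[str, tuple[float, float]]:
        """Posterior mean and SD for every mu_*/sigma_* parameter."""
        out = {}
        for name in self.names:
            if name.startswith(("mu_", "sigma_")):
                x = self.stacked(name)
                out[name] = (float(x.mean()), float(x.std(ddof=1)))
        return out

    def individual_posterior_means(self) -> list[PVLDeltaParams]:
        """Per-participant natural-scale point estimates.

        The posterior mean is taken on the probit scale and then transformed
        to the natural scale.
        """
        ids = self.metadata.get("participant_ids")
        if ids is None:
            raise ValueError("no individual-level parameters in this posterior")
        out = []
        for pid in ids:
            zbar = np.array([
                self.stacked(f"zp_{p}[{pid}]").mean() for p in PARAM_NAMES
            ])
            out.append(PVLDeltaParams(*natural_from_probit_array(zbar)))
        return out


# ---------------------------------------------------------------------------
# sampler
# ---------------------------------------------------------------------------

def _norm_logpdf_scaled(x, mu, sigma):
    return -np.log(sigma) - 0.5 * ((x - mu) / sigma) ** 2


class _RobbinsMonro:
    """Per-scalar proposal-scale adaptation toward a target acceptance rate."""

    def __init__(self, shape, initial=0.5, target=TARGET_ACCEPT):
        self.log_scale = np.full(shape, np.log(initial))
        self.target = target
        self.k = 0

    @property
    def scale(self):
        return np.exp(self.log_scale)

    def update(self, accepted):
        self.k += 1
        gamma = 1.0 / self.k**0.6
        self.log_scale += gamma * (np.asarray(accepted, dtype=float) - self.target)
        np.clip(self.log_scale, -8.0, 3.0, out=self.log_scale)


def _run_one_group_chain(choices, net, n_trials, cfg: MCMCConfig,
                         rng: np.random.Generator):
    """One chain of the single-group hierarchical sampler.

    Returns (mu_draws, sigma_draws, zp_draws) with shapes
    (iters, 4), (iters, 4), (iters, N, 4).
    """
    n = choices.shape[0]
    mu = rng.normal(0.0, 1.0, size=4)
    sigma = rng.uniform(0.2, 1.3, size=4)
    zp = mu + sigma * rng.standard_normal((n, 4))

    use_lik = not cfg.prior_only
    if use_lik:
        ll = loglik_many(choices, net, n_trials, natural_from_probit_array(zp))
    else:
        ll = np.zeros(n)

    zp_adapt = _RobbinsMonro((n, 4))
    sig_adapt = _RobbinsMonro(4, initial=0.2)
    tr_adapt = _RobbinsMonro(4, initial=0.2)
    sc_adapt = _RobbinsMonro(4, initial=0.2)

    iters = cfg.n_burnin + cfg.n_retained
    mu_draws = np.empty((cfg.n_retained, 4))
    sigma_draws = np.empty((cfg.n_retained, 4))
    zp_draws = np.empty((cfg.n_retained, n, 4))

    for it in range(iters):
        adapting = it < cfg.n_burnin
        for _sweep in range(max(1, cfg.zp_sweeps)):
            if not use_lik:
                # conditional of zp given (mu, sigma) is exactly the group
                # normal, so draw it directly (exact Gibbs)
                zp = mu + sigma * rng.standard_normal((n, 4))
            else:
                # individual probit parameters, one coordinate at a time, all
                # participants in parallel
                acc_mat = np.empty((n, 4)) if adapting else None
                for j in range(4):
                    prop_col = zp[:, j] + zp_adapt.scale[:, j] * rng.standard_normal(n)
                    zp_prop = zp.copy()
                    zp_prop[:, j] = prop_col
                    ll_prop = loglik_many(
                        choices, net, n_trials, natural_from_probit_array(zp_prop)
                    )
                    logr = (
                        ll_prop - ll
                        + _norm_logpdf_scaled(prop_col, mu[j], sigma[j])
                        - _norm_logpdf_scaled(zp[:, j], mu[j], sigma[j])
                    )
                    accept = np.log(rng.uniform(size=n)) < logr
                    zp[accept, j] = prop_col[accept]
                    ll = np.where(accept, ll_prop, ll)
                    if adapting:
                        acc_mat[:, j] = accept
                if adapting:
                    zp_adapt.update(acc_mat)

            # group means: conjugate normal update, prior N(0, 1)
            prec = 1.0 + n / sigma**2
            mean = (zp.sum(axis=0) / sigma**2) / prec
            mu = mean + rng.standard_normal(4) / np.sqrt(prec)

            # group SDs: bounded random walk under Uniform(0, 1.5)
            prop_sig = sigma + sig_adapt.scale * rng.standard_normal(4)
            inside = (prop_sig > 0.0) & (prop_sig < SIGMA_UPPER)
            ss = ((zp - mu) ** 2).sum(axis=0)
            with np.errstate(divide="ignore", invalid="ignore"):
                logr = np.where(
                    inside,
                    -n * np.log(prop_sig) - ss / (2 * prop_sig**2)
                    + n * np.log(sigma) + ss / (2 * sigma**2),
                    -np.inf,
                )
            accept = np.log(rng.uniform(size=4)) < logr
            sigma = np.where(accept, prop_sig, sigma)
            if adapting:
                sig_adapt.update(accept)

            if use_lik:
                # funnel-breaking group moves: translate (mu_j, zp[:, j])
                # jointly, then rescale (sigma_j, deviations) jointly
                tr_acc = np.zeros(4)
                sc_acc = np.zeros(4)
                for j in range(4):
                    delta = tr_adapt.scale[j] * rng.standard_normal()
                    zp_prop = zp.copy()
                    zp_prop[:, j] += delta
                    ll_prop = loglik_many(
                        choices, net, n_trials, natural_from_probit_array(zp_prop)
                    )
                    logr = ((ll_prop - ll).sum()
                            + 0.5 * mu[j] ** 2 - 0.5 * (mu[j] + delta) ** 2)
                    if np.log(rng.uniform()) < logr:
                        mu[j] += delta
                        zp = zp_prop
                        ll = ll_prop
                        tr_acc[j] = 1.0
                for j in range(4):
                    eps = sc_adapt.scale[j] * rng.standard_normal()
                    s_new = sigma[j] * np.exp(eps)
                    if not 0.0 < s_new < SIGMA_UPPER:
                        continue
                    zp_prop = zp.copy()
                    zp_prop[:, j] = mu[j] + (zp[:, j] - mu[j]) * np.exp(eps)
                    ll_prop = loglik_many(
                        choices, net, n_trials, natural_from_probit_array(zp_prop)
                    )
                    # prior and Jacobian terms collapse to +eps
                    if np.log(rng.uniform()) < (ll_prop - ll).sum() + eps:
                        sigma[j] = s_new
                        zp = zp_prop
                        ll = ll_prop
                        sc_acc[j] = 1.0
                if adapting:
                    tr_adapt.update(tr_acc)
                    sc_adapt.update(sc_acc)

        if it >= cfg.n_burnin:
            keep = it - cfg.n_burnin
            mu_draws[keep] = mu
            sigma_draws[keep] = sigma
            zp_draws[keep] = zp

    return mu_draws, sigma_draws, zp_draws


def fit_hierarchical_group(
    group: GroupDataset, cfg: MCMCConfig, store_individuals: bool = True
) -> PosteriorSamples:
    """Fit the hierarchical PVL-Delta model to one group.

    Returns posterior draws over the group-level means/SDs (probit scale,
    named ``mu_A`` ... ``sigma_c``) and, if ``store_individuals``, the
    individual probit parameters ``zp_A[<id>]`` etc.  A warning is raised
    (not an error) when any split-chain R-hat exceeds the configured
    threshold, and the result is flagged via ``converged``.
    """
    group.require_nonempty()
    if len(group) < 2:
        raise ValueError("hierarchical estimation requires >= 2 participants")
    choices, net, n_trials = dataset_to_arrays(group, scale=cfg.outcome_scale)

    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_chains)
    per_chain = []
    for ss in seeds:
        rng = np.random.default_rng(ss)
        per_chain.append(_run_one_group_chain(choices, net, n_trials, cfg, rng))

    ids = [p.participant_id for p in group]
    names = [f"mu_{p}" for p in PARAM_NAMES] + [f"sigma_{p}" for p in PARAM_NAMES]
    blocks = []
    for mu_d, sigma_d, zp_d in per_chain:
        cols = [mu_d, sigma_d]
        if store_individuals:
            # parameter-major flattening matches the name order below
            cols.append(zp_d.transpose(0, 2, 1).reshape(cfg.n_retained, -1))
        blocks.append(np.concatenate(cols, axis=1))
    if store_individuals:
        names += [f"zp_{p}[{pid}]" for p in PARAM_NAMES for pid in ids]
    draws = np.stack(blocks, axis=0)

    result = PosteriorSamples(
        draws, names, cfg,
        metadata={"group": group.name, "participant_ids": ids,
                  "n_participants": len(group),
                  "outcome_scale": cfg.outcome_scale,
                  "prior_only": cfg.prior_only,
                  "model": "pvl_delta_hierarchical_one_group"},
    )
    if not result.converged:
        warnings.warn(
            f"fit of group {group.name!r} has max R-hat "
            f"{result.max_rhat:.3f} >= {cfg.rhat_threshold}; inspect chains",
            stacklevel=2,
        )
    return result
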