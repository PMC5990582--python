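"""Numba-compiled inner loops for the PVL-Delta likelihood.

Kept separate so the public modules stay importable even while numba is
compiling; all kernels operate on padded (participant, trial) arrays as
produced by :func:`igtbayes.igt_task.dataset_to_arrays`.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_SQRT1_2 = 1.0 / math.sqrt(2.0)


@njit(cache=True, fastmath=True)
def _phi(x):
    """Standard normal CDF."""
    return 0.5 * math.erfc(-x * _SQRT1_2)


@njit(cache=True, fastmath=True)
def loglik_one(choices, net, n_trials, A, w, a, c):
    """Sequence log-likelihood for one participant.

    choices: 0-based deck indices; net: (scaled) net outcomes; n_trials:
    number of valid leading entries.  Trial 1 uses zero expectancies, i.e. a
    uniform softmax.
    """
    theta = 3.0**c - 1.0
    ev = np.zeros(4)
    ll = 0.0
    for t in range(n_trials):
        k = choices[t]
        # log softmax, max-subtracted for stability at large theta
        m = theta * ev[0]
        for j in range(1, 4):
            v = theta * ev[j]
            if v > m:
                m = v
        s = 0.0
        for j in range(4):
            s += np.exp(theta * ev[j] - m)
        ll += theta * ev[k] - m - np.log(s)
        x = net[t]
        if x >= 0.0:
            u = x**A
        else:
            u = -w * (-x) ** A
        ev[k] += a * (u - ev[k])
    return ll


@njit(cache=True, fastmath=True)
def loglik_many(choices, net, n_trials, params):
    """Vector of log-likelihoods for N participants.

    params: (N, 4) natural-scale (A, w, a, c) rows.
    """
    n = choices.shape[0]
    out = np.empty(n)
    for i in range(n):
        out[i] = loglik_one(
            choices[i], net[i], n_trials[i],
            params[i, 0], params[i, 1], params[i, 2], params[i, 3],
        )
    return out


@njit(cache=True, fastmath=True)
def loglik_rows_probit(choices, net, n_trials, zp):
    """Per-participant log-likelihoods from probit-scale parameters.

    zp: (N, 4) probit-scale rows; the natural transform (Phi, with w and c
    scaled by 5) happens inside the kernel.
    """
    n = choices.shape[0]
    out = np.empty(n)
    for i in range(n):
        out[i] = loglik_one(
            choices[i], net[i], n_trials[i],
            _phi(zp[i, 0]), 5.0 * _phi(zp[i, 1]),
            _phi(zp[i, 2]), 5.0 * _phi(zp[i, 3]),
        )
    return out


@njit(cache=True, fastmath=True)
def zp_joint_update(choices, net, n_trials, zp, means, sigma, scales, ll,
                    zn, un):
    """One joint Metropolis update of all four probit parameters per
    participant.

    zp, ll are modified in place; zn (N, 4) standard normals and un (N,)
    uniforms supply the randomness.  Returns the per-participant acceptance
    indicator.
    """
    n = zp.shape[0]
    acc = np.zeros(n)
    prop = np.empty(4)
    for i in range(n):
        lpr = 0.0
        for j in range(4):
            prop[j] = zp[i, j] + scales[i, j] * zn[i, j]
            d_cur = (zp[i, j] - means[i, j]) / sigma[j]
            d_new = (prop[j] - means[i, j]) / sigma[j]
            lpr += 0.5 * (d_cur * d_cur - d_new * d_new)
        llp = loglik_one(
            choices[i], net[i], n_trials[i],
            _phi(prop[0]), 5.0 * _phi(prop[1]),
            _phi(prop[2]), 5.0 * _phi(prop[3]),
        )
        if math.log(un[i]) < llp - ll[i] + lpr:
            for j in range(4):
                zp[i, j] = prop[j]
            ll[i] = llp
            acc[i] = 1.0
    return acc


@njit(cache=True, fastmath=True)
def predict_probs_one(choices, net, n_trials, A, w, a, c):
    """One-step-ahead choice probabilities (n_trials, 4).

    Row t conditions on the observed history through trial t-1; row 0 is
    uniform.
    """
    theta = 3.0**c - 1.0
    ev = np.zeros(4)
    out = np.empty((n_trials, 4))
    for t in range(n_trials):
        m = theta * ev[0]
        for j in range(1, 4):
            v = theta * ev[j]
            if v > m:
                m = v
        s = 0.0
        for j in range(4):
            s += np.exp(theta * ev[j] - m)
        for j in range(4):
            out[t, j] = np.exp(theta * ev[j] - m) / s
        k = choices[t]
        x = net[t]
        if x >= 0.0:
            u = x**A
        else:
            u = -w * (-x) ** A
        ev[k] += a * (u - ev[k])
    return out
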