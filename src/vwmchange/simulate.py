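"""Synthetic change-detection experiments and simulated observers.

The generator mirrors the statistical design of a two-display orientation
change-detection session: set size drawn uniformly from {2, 4, 6, 8} on each
trial, item orientations i.i.d. uniform on the circular stimulus space, a
50% chance that exactly one item changes, with the change magnitude uniform
on the circle (so its physical magnitude is uniform on [0, 90] degrees), and
1800 trials per simulated observer (three sessions of 600).

A trial set is a pandas DataFrame with one row per trial:

====================  =====================================================
column                meaning
====================  =====================================================
``trial_id``          0-based index
``set_size``          number of items N
``change``            1 if one item changed between displays, else 0
``change_loc``        index of the changed item, -1 on no-change trials
``delta``             signed change magnitude, internal radians (0 if none)
``theta``             ndarray of first-display stimuli, internal radians
``phi``               ndarray of second-display stimuli, internal radians
====================  =====================================================

``phi`` equals ``theta`` except at ``change_loc`` where the internal angle is
shifted by ``delta``.  CSV round-tripping stores stimuli in physical degrees
(semicolon-joined) per the documented dialect.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .circular import (
    internal_to_physical_deg,
    kappa_from_j_interp,
    log_i0,
    physical_deg_to_internal,
    wrap,
)
from .models import MODELS, validate_params

__all__ = [
    "DEFAULT_SET_SIZES",
    "DEFAULT_N_TRIALS",
    "generate_experiment",
    "simulate_observer",
    "trials_to_csv",
    "trials_from_csv",
]

DEFAULT_SET_SIZES = (2, 4, 6, 8)
DEFAULT_N_TRIALS = 1800  # three sessions of 600 trials


def generate_experiment(
    n_trials=DEFAULT_N_TRIALS,
    set_sizes=DEFAULT_SET_SIZES,
    p_change_true=0.5,
    seed=None,
    rng=None,
):
    """Generate a synthetic trial set with the task's statistical structure.

    Deterministic given ``seed``: the same seed yields an identical table.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    set_sizes = [int(s) for s in set_sizes]
    if not set_sizes or any(s < 1 for s in set_sizes):
        raise ValueError("set_sizes must be a non-empty list of positive integers")
    if not 0.0 <= p_change_true <= 1.0:
        raise ValueError("p_change_true must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)

    n = rng.choice(set_sizes, size=n_trials)
    change = (rng.random(n_trials) < p_change_true).astype(int)
    loc = np.where(change == 1, np.floor(rng.random(n_trials) * n).astype(int), -1)
    delta = np.where(change == 1, rng.uniform(-np.pi, np.pi, size=n_trials), 0.0)

    flat_theta = rng.uniform(-np.pi, np.pi, size=int(n.sum()))
    offsets = np.concatenate([[0], np.cumsum(n)])
    theta_rows, phi_rows = [], []
    for t in range(n_trials):
        th = flat_theta[offsets[t] : offsets[t + 1]]
        ph = th.copy()
        if change[t]:
            ph[loc[t]] = wrap(ph[loc[t]] + delta[t])
        theta_rows.append(th)
        phi_rows.append(ph)

    return pd.DataFrame(
        {
            "trial_id": np.arange(n_trials),
            "set_size": n,
            "change": change,
            "change_loc": loc,
            "delta": delta,
            "theta": theta_rows,
            "phi": phi_rows,
        }
    )


def _simulate_ip(trials, p, rng):
    n_trials = len(trials)
    n = trials["set_size"].to_numpy()
    change = trials["change"].to_numpy()
    loc = trials["change_loc"].to_numpy()
    k_eff = np.minimum(n, p["K"])
    del loc  # by symmetry only membership of the changed item matters
    # The changed item is among the min(N, K) uniformly chosen memorized
    # items with probability K_eff / N; simulate that event directly.
    noticed = (change == 1) & (rng.random(n_trials) * n < k_eff)
    prob = np.where(noticed, 1.0 - p["epsilon"], p["g"])
    return (rng.random(n_trials) < prob).astype(int)


def _allocate_batch(model, p, n, n_trials, rng, share_vp=False):
    """Vectorized per-trial precision allocation, shape (n_trials, n)."""
    if model == "EP":
        J = np.full((n_trials, n), p["J_1"] * n ** p["alpha"])
        return J, J
    if model == "SA":
        ranks = np.argsort(rng.random((n_trials, n)), axis=1).argsort(axis=1)
        K = p["K"]
        if n > K:
            counts = (ranks < K).astype(float)
        else:
            counts = (K // n) + (ranks < (K % n)).astype(float)
        J = counts * p["J_s"]
        return J, J
    if model == "SR":
        K = p["K"]
        if n <= K:
            J = np.full((n_trials, n), p["J_1"] / n)
        else:
            ranks = np.argsort(rng.random((n_trials, n)), axis=1).argsort(axis=1)
            J = (ranks < K).astype(float) * (p["J_1"] / K)
        return J, J
    # VP
    mean_j = p["J1_bar"] * n ** p["alpha"]
    shape = mean_j / p["tau"]
    J_x = rng.gamma(shape, p["tau"], size=(n_trials, n))
    J_y = J_x if share_vp else rng.gamma(shape, p["tau"], size=(n_trials, n))
    return J_x, J_y


def simulate_observer(model, params, trials, seed=None, rng=None, share_vp=False):
    """Simulate one observer's binary responses to a trial set.

    Noisy models draw per-item measurements from the Von Mises noise model
    and apply the MAP decision rule; IP applies its epsilon/guessing rule.
    Deterministic given ``seed``.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    p = validate_params(model, params)
    if rng is None:
        rng = np.random.default_rng(seed)

    if model == "IP":
        return _simulate_ip(trials, p, rng)

    responses = np.zeros(len(trials), dtype=int)
    prior_term = np.log(p["p_change"]) - np.log1p(-p["p_change"])
    # Group by set size so each batch is a rectangular array.
    for n, idx in trials.groupby("set_size").groups.items():
        idx = np.asarray(idx)
        n = int(n)
        theta = np.stack(trials.loc[idx, "theta"].to_numpy())
        phi = np.stack(trials.loc[idx, "phi"].to_numpy())
        J_x, J_y = _allocate_batch(model, p, n, len(idx), rng, share_vp)
        kx = kappa_from_j_interp(J_x)
        ky = kappa_from_j_interp(J_y)
        x = rng.vonmises(theta, kx)
        y = rng.vonmises(phi, ky)
        kc = np.sqrt(kx**2 + ky**2 + 2 * kx * ky * np.cos(y - x))
        log_r = log_i0(kx) + log_i0(ky) - log_i0(kc)
        m = log_r.max(axis=1, keepdims=True)
        log_sum = m[:, 0] + np.log(np.exp(log_r - m).sum(axis=1))
        log_d = prior_term - np.log(n) + log_sum
        responses[idx] = (log_d > 0).astype(int)
    return responses


def trials_to_csv(trials, path, responses=None):
    """Write a trial set (and optionally responses) in the CSV dialect.

    Stimuli and change magnitudes are stored in physical degrees in
    [-90, 90); internal angles are recovered on load by doubling.
    """
    out = pd.DataFrame(
        {
            "trial_id": trials["trial_id"],
            "set_size": trials["set_size"],
            "change": trials["change"],
            "change_loc": trials["change_loc"],
            "delta_deg_physical": np.degrees(trials["delta"].to_numpy()) / 2.0,
            "theta_deg_physical": [
                ";".join(f"{v:.8f}" for v in internal_to_physical_deg(row))
                for row in trials["theta"]
            ],
            "phi_deg_physical": [
                ";".join(f"{v:.8f}" for v in internal_to_physical_deg(row))
                for row in trials["phi"]
            ],
        }
    )
    out["response"] = "" if responses is None else np.asarray(responses, dtype=int)
    out.to_csv(path, index=False)


def trials_from_csv(path):
    """Read a trial-set CSV; returns ``(trials, responses_or_None)``."""
    raw = pd.read_csv(path)
    theta = [
        physical_deg_to_internal(np.array(s.split(";"), dtype=float))
        for s in raw["theta_deg_physical"]
    ]
    phi = [
        physical_deg_to_internal(np.array(s.split(";"), dtype=float))
        for s in raw["phi_deg_physical"]
    ]
    trials = pd.DataFrame(
        {
            "trial_id": raw["trial_id"].astype(int),
            "set_size": raw["set_size"].astype(int),
            "change": raw["change"].astype(int),
            "change_loc": raw["change_loc"].astype(int),
            "delta": np.radians(raw["delta_deg_physical"].to_numpy()) * 2.0,
            "theta": theta,
            "phi": phi,
        }
    )
    responses = None
    if "response" in raw and not raw["response"].isna().all():
        responses = raw["response"].astype(int).to_numpy()
    return trials, responses
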