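"""The five observer models of change detection and their decision stage.

Encoding models (how memory resource is allocated over the N displayed
items):

* ``IP`` — infinite-precision item limit: min(N, K) randomly chosen items are
  stored perfectly, the rest not at all.  Responses come from an
  epsilon/guessing rule rather than from noisy measurements.
* ``SA`` — slots plus averaging: K indivisible resource chunks, each worth
  Fisher information ``J_s``, spread as evenly as possible over the items
  (when N > K, K random items get one chunk each and the rest are dropped).
* ``SR`` — slots plus resources: like SA but resource is continuous; encoded
  items get ``J_1 / min(N, K)``.
* ``EP`` — equal precision: every item gets ``J_1 * N**alpha``.
* ``VP`` — variable precision: each item's precision is drawn from a gamma
  distribution with mean ``J1_bar * N**alpha`` and scale ``tau``,
  independently across items, displays and trials.

Decision stage (all noisy models): the observer computes the posterior ratio
``d = p(change | x, y) / p(no change | x, y)`` under the true generative
model of the task — change occurs with prior probability ``p_change``, at a
uniformly random item, with magnitude uniform on the circle.  Marginalizing
analytically gives

    d = p_change/(1-p_change) * (1/N) * sum_i I0(kx_i) I0(ky_i) / I0(kc_i),
    kc_i = sqrt(kx_i^2 + ky_i^2 + 2 kx_i ky_i cos(y_i - x_i)),

evaluated in the log domain.  The MAP observer reports "change" iff d > 1
(the measure-zero tie d = 1 is resolved to "no change"); a probability-
matching observer reports "change" with probability logistic(k log d).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

from .circular import kappa_from_j_interp, log_i0, vonmises_sample, wrap

__all__ = [
    "MODELS",
    "PARAM_NAMES",
    "PARAM_RANGES",
    "REFERENCE_PARAMS",
    "validate_params",
    "EncodingState",
    "sa_chunk_allocation",
    "allocate_precision",
    "log_decision_variable",
    "decision_variable",
    "map_response",
    "prob_matching_response",
    "ip_response",
]

MODELS = ("IP", "SA", "SR", "EP", "VP")

#: Free parameters of each model, keyed by their conventional names.
PARAM_NAMES = {
    "IP": ("K", "epsilon", "g"),
    "SA": ("J_s", "K", "p_change"),
    "SR": ("J_1", "K", "p_change"),
    "EP": ("J_1", "alpha", "p_change"),
    "VP": ("J1_bar", "tau", "alpha", "p_change"),
}

#: Tested parameter ranges used for fitting grids and for the uniform prior
#: in marginal-likelihood model comparison.
PARAM_RANGES = {
    "IP": {"K": (1, 8), "epsilon": (0.0, 1.0), "g": (0.0, 0.5)},
    "SA": {"J_s": (1.0, 40.0), "K": (1, 8), "p_change": (0.2, 0.8)},
    "SR": {"J_1": (1.0, 60.0), "K": (1, 8), "p_change": (0.2, 0.8)},
    "EP": {"J_1": (1.0, 60.0), "alpha": (-2.0, 0.0), "p_change": (0.2, 0.8)},
    "VP": {
        "J1_bar": (5.0, 300.0),
        "tau": (5.0, 300.0),
        "alpha": (-2.0, 0.0),
        "p_change": (0.2, 0.8),
    },
}

#: Parameter values representative of human observers in orientation change
#: detection (group means of maximum-likelihood fits; capacities rounded to
#: integers for simulation).  Used as generator settings in recovery studies.
REFERENCE_PARAMS = {
    "IP": {"K": 3, "epsilon": 0.220, "g": 0.247},
    "SA": {"J_s": 3.94, "K": 4, "p_change": 0.584},
    "SR": {"J_1": 14.2, "K": 4, "p_change": 0.574},
    "EP": {"J_1": 20.3, "alpha": -1.28, "p_change": 0.492},
    "VP": {"J1_bar": 53.1, "tau": 31.2, "alpha": -0.88, "p_change": 0.532},
}


def validate_params(model, params):
    """Check a parameter dict against the model's names and constraints.

    Returns the validated dict; raises ``ValueError`` on an unknown model,
    missing/extra keys or out-of-domain values.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    names = PARAM_NAMES[model]
    if set(params) != set(names):
        raise ValueError(
            f"{model} expects parameters {names}, got {tuple(sorted(params))}"
        )
    p = dict(params)
    if "K" in p:
        if p["K"] != int(p["K"]) or p["K"] < 1:
            raise ValueError(f"K must be a positive integer, got {p['K']!r}")
        p["K"] = int(p["K"])
    if "p_change" in p and not 0.0 < p["p_change"] < 1.0:
        raise ValueError("p_change must lie in (0, 1)")
    if "epsilon" in p and not 0.0 <= p["epsilon"] <= 1.0:
        raise ValueError("epsilon must lie in [0, 1]")
    if "g" in p and not 0.0 <= p["g"] <= 1.0:
        raise ValueError("g must lie in [0, 1]")
    for key in ("J_s", "J_1"):
        if key in p and p[key] < 0:
            raise ValueError(f"{key} must be non-negative")
    if "J1_bar" in p and p["J1_bar"] <= 0:
        raise ValueError("J1_bar must be positive")
    if "tau" in p and p["tau"] <= 0:
        raise ValueError("tau must be positive")
    if "alpha" in p and p["alpha"] > 0:
        raise ValueError("alpha must be <= 0 (precision cannot grow with set size)")
    return p


@dataclass
class EncodingState:
    """Per-item encoding on one trial.

    For noisy models, ``J_x``/``J_y`` hold the per-item Fisher information
    used for the first and second display (identical objects for SA/SR/EP,
    independent gamma draws for VP) and ``kappa_x``/``kappa_y`` the derived
    Von Mises concentrations.  For IP, ``memorized`` holds the indices of the
    perfectly stored items and the precision fields are ``None``.
    """

    model: str
    J_x: np.ndarray | None = None
    J_y: np.ndarray | None = None
    kappa_x: np.ndarray | None = None
    kappa_y: np.ndarray | None = None
    memorized: np.ndarray | None = None


def sa_chunk_allocation(K, N, rng):
    """Distribute K indivisible chunks as evenly as possible over N items.

    If N > K, K randomly chosen items receive one chunk each and the rest
    receive none.  If N <= K, every item gets ``K // N`` chunks and ``K % N``
    randomly chosen items get one extra, so counts are ``floor(K/N)`` or
    ``ceil(K/N)`` and sum to K.  E.g. K=4, N=3 gives counts {2, 1, 1}.
    """
    if K != int(K) or N != int(N) or K < 1 or N < 1:
        raise ValueError(f"K and N must be positive integers, got K={K!r}, N={N!r}")
    K, N = int(K), int(N)
    counts = np.zeros(N, dtype=int)
    if N > K:
        counts[rng.choice(N, size=K, replace=False)] = 1
    else:
        counts += K // N
        extra = K % N
        if extra:
            counts[rng.choice(N, size=extra, replace=False)] += 1
    return counts


def allocate_precision(model, params, N, rng, share_vp_across_displays=False):
    """Draw one trial's resource allocation -> :class:`EncodingState`.

    The same allocation applies to both displays, except in the VP model
    where each display receives independent gamma precision draws (set
    ``share_vp_across_displays=True`` to test the shared-draw alternative).
    Unencoded items have J = 0 and enter the decision rule with kappa = 0,
    i.e. their measurements are pure noise.
    """
    p = validate_params(model, params)
    if N < 1 or N != int(N):
        raise ValueError(f"set size must be a positive integer, got {N!r}")
    N = int(N)

    if model == "IP":
        memorized = rng.choice(N, size=min(N, p["K"]), replace=False)
        return EncodingState(model=model, memorized=np.sort(memorized))

    if model == "SA":
        J = sa_chunk_allocation(p["K"], N, rng).astype(float) * p["J_s"]
        J_x = J_y = J
    elif model == "SR":
        K = p["K"]
        if N <= K:
            J = np.full(N, p["J_1"] / N)
        else:
            J = np.zeros(N)
            J[rng.choice(N, size=K, replace=False)] = p["J_1"] / K
        J_x = J_y = J
    elif model == "EP":
        J = np.full(N, p["J_1"] * N ** p["alpha"])
        J_x = J_y = J
    else:  # VP
        mean_j = p["J1_bar"] * N ** p["alpha"]
        shape = mean_j / p["tau"]
        J_x = rng.gamma(shape, p["tau"], size=N)
        J_y = J_x if share_vp_across_displays else rng.gamma(shape, p["tau"], size=N)

    return EncodingState(
        model=model,
        J_x=J_x,
        J_y=J_y,
        kappa_x=kappa_from_j_interp(J_x),
        kappa_y=kappa_from_j_interp(J_y),
    )


def _log_item_ratios(x, y, kx, ky):
    """Per-item log likelihood ratio log[p(x_i,y_i|changed)/p(x_i,y_i|same)]."""
    kc = np.sqrt(kx**2 + ky**2 + 2.0 * kx * ky * np.cos(y - x))
    return log_i0(kx) + log_i0(ky) - log_i0(kc)


def log_decision_variable(x, y, kx, ky, p_change):
    """Log posterior ratio log d for one trial's measurement vectors."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    kx, ky = np.asarray(kx, dtype=float), np.asarray(ky, dtype=float)
    if not (x.shape == y.shape == kx.shape == ky.shape):
        raise ValueError("x, y, kx, ky must have equal shapes")
    if x.ndim != 1 or x.size < 1:
        raise ValueError("measurement vectors must be 1-D and non-empty")
    if np.any(kx < 0) or np.any(ky < 0):
        raise ValueError("concentrations must be non-negative")
    if not 0.0 < p_change < 1.0:
        raise ValueError("p_change must lie in (0, 1)")
    log_r = _log_item_ratios(x, y, kx, ky)
    n = x.size
    return (
        np.log(p_change)
        - np.log1p(-p_change)
        - np.log(n)
        + special.logsumexp(log_r)
    )


def decision_variable(x, y, kx, ky, p_change):
    """Posterior ratio d = p(C=1 | x, y) / p(C=0 | x, y).

    May overflow to ``inf`` for extreme concentrations; use
    :func:`log_decision_variable` when only comparisons are needed.
    """
    return float(np.exp(log_decision_variable(x, y, kx, ky, p_change)))


def map_response(d):
    """MAP decision: report "change" (1) iff d > 1; ties go to "no change"."""
    if d < 0 or np.isnan(d):
        raise ValueError(f"decision variable must be >= 0, got {d!r}")
    return int(d > 1.0)


def prob_matching_response(d, k, rng):
    """Probability-matching response: report "change" w.p. logistic(k log d).

    ``k = 0`` is a fair coin regardless of the posterior; ``k -> inf``
    recovers the MAP rule.
    """
    if k < 0:
        raise ValueError(f"gain k must be non-negative, got {k!r}")
    if d < 0 or np.isnan(d):
        raise ValueError(f"decision variable must be >= 0, got {d!r}")
    if k == 0:
        p = 0.5
    else:
        with np.errstate(divide="ignore"):
            p = special.expit(k * np.log(d))
    return int(rng.random() < p)


def ip_response(trial, params, rng):
    """Response of the infinite-precision item-limit observer on one trial.

    Memorizes min(N, K) random items perfectly.  If a change occurred at a
    memorized item the observer reports "change" with probability 1 - epsilon;
    in every other case it reports "change" with guessing probability g.
    """
    p = validate_params("IP", params)
    n = int(trial.set_size)
    memorized = rng.choice(n, size=min(n, p["K"]), replace=False)
    noticed = bool(trial.change) and int(trial.change_loc) in memorized
    prob = 1.0 - p["epsilon"] if noticed else p["g"]
    return int(rng.random() < prob)


def simulate_measurements(theta, phi, state, rng):
    """Noisy measurements of both displays given an encoding state."""
    x = vonmises_sample(np.asarray(theta, dtype=float), state.kappa_x, rng)
    y = vonmises_sample(np.asarray(phi, dtype=float), state.kappa_y, rng)
    return wrap(x), wrap(y)
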