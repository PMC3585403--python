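"""Per-trial response probabilities and maximum-likelihood fitting.

For the noisy models (SA, SR, EP, VP) the probability of reporting "change"
has no closed form and is estimated by Monte Carlo: simulate the encoding
and measurement noise many times and average the MAP-decision indicator.
Two estimators are provided:

* :func:`response_probability` — the direct estimator for a single trial.
* a table estimator used by :func:`fit_model` — by symmetry of the task the
  report probability depends on a trial only through its set size N and the
  absolute change magnitude |delta| (no-change trials are the delta = 0
  case), so the fitter simulates a (set size x delta-grid) table per
  candidate parameter vector and interpolates per trial.  This is orders of
  magnitude cheaper than per-trial simulation and makes grid fitting of
  1800-trial datasets tractable.

Common random numbers: the measurement noise is produced by inverse-CDF
transform of uniform draws that are fixed once per fit (a cached Von Mises
quantile table, bilinear in (u, log kappa)), and VP precision draws apply
the gamma quantile function to fixed uniforms.  All grid points therefore
see comonotone noise, which smooths the Monte-Carlo likelihood surface and
makes fits exactly reproducible given the seed.

Estimated probabilities are clipped to [1/(2 n_mc), 1 - 1/(2 n_mc)] so the
Bernoulli log likelihood stays finite.  The IP model's response probability
is exact: p("change") = g on no-change trials and
min(K,N)/N (1-eps) + (1 - min(K,N)/N) g on change trials.

Optimization is grid-then-refine: evaluate the log likelihood on a grid
spanning the tested parameter ranges (the same table later feeds the
marginal likelihood), then zoom once around the grid optimum with a local
5-point-per-dimension grid.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import special

from .circular import kappa_from_j_interp, log_i0
from .models import MODELS, PARAM_NAMES, PARAM_RANGES, validate_params

__all__ = [
    "ParameterGrid",
    "FitResult",
    "default_grid",
    "response_probability",
    "ip_response_probability",
    "predict_trial_probs",
    "bernoulli_loglik",
    "fit_model",
]


# ---------------------------------------------------------------------------
# Von Mises quantile table (inverse-CDF sampling with common random numbers)
# ---------------------------------------------------------------------------

class _VMQuantileTable:
    """Quantile function of the centered Von Mises, tabulated over kappa."""

    KAPPA_MIN = 1e-3  # below this the density is uniform to ~0.1%
    KAPPA_MAX = 1e4

    def __init__(self, n_kappa=151, n_u=2049, n_angle=4096):
        self.log_k = np.linspace(
            np.log(self.KAPPA_MIN), np.log(self.KAPPA_MAX), n_kappa
        )
        self.u_grid = np.linspace(0.0, 1.0, n_u)
        table = np.empty((n_kappa, n_u))
        uniform = np.linspace(-np.pi, np.pi, n_angle)
        for i, lk in enumerate(self.log_k):
            k = np.exp(lk)
            # pass 1: uniform angle grid (adequate resolution for small kappa)
            x = self._invert(uniform, k)
            # pass 2: add the pass-1 quantiles to the grid, which
            # concentrates nodes in the density bulk -- at large kappa the
            # bulk is a few hundredths of a radian wide and a uniform grid
            # alone misses it.  The uniform nodes are kept so no trapezoid
            # interval is ever wide where the density still has mass.
            grid = np.unique(np.concatenate([uniform, x]))
            table[i] = self._invert(grid, k)
        self.table = table

    def _invert(self, ang, k):
        pdf = np.exp(k * np.cos(ang) - np.log(2 * np.pi) - log_i0(k))
        cdf = np.concatenate(
            [[0.0], np.cumsum((pdf[1:] + pdf[:-1]) * 0.5 * np.diff(ang))]
        )
        cdf /= cdf[-1]
        # guard repeated cdf values (flat tails) for a well-defined inverse
        cdf = np.maximum.accumulate(cdf)
        return np.interp(self.u_grid, cdf, ang)

    def ppf(self, u, kappa):
        """Bilinear lookup; kappa below KAPPA_MIN is treated as uniform.

        Queries are clipped to the innermost tabulated quantiles: the
        stored endpoints are the +-pi support bounds, which the true
        quantile function only approaches at astronomically extreme u, so
        interpolating into the endpoint cells would fabricate tail mass.
        """
        u = np.clip(np.asarray(u, dtype=float), self.u_grid[1], self.u_grid[-2])
        k = np.clip(np.asarray(kappa, dtype=float), 0.0, self.KAPPA_MAX)
        out = np.empty(np.broadcast(u, k).shape)
        uniform = k < self.KAPPA_MIN
        u_b, k_b = np.broadcast_arrays(u, k)
        if np.any(uniform):
            out[uniform] = 2 * np.pi * (u_b[uniform] - 0.5)
        sel = ~uniform
        if np.any(sel):
            lk = np.log(k_b[sel])
            step = self.log_k[1] - self.log_k[0]
            fi = np.clip((lk - self.log_k[0]) / step, 0.0, len(self.log_k) - 1 - 1e-9)
            i0_ = fi.astype(int)
            wi = fi - i0_
            fu = np.clip(u_b[sel] * (len(self.u_grid) - 1), 0.0,
                         len(self.u_grid) - 1 - 1e-9)
            j0 = fu.astype(int)
            wj = fu - j0
            t = self.table
            row0 = t[i0_, j0] * (1 - wj) + t[i0_, j0 + 1] * wj
            row1 = t[i0_ + 1, j0] * (1 - wj) + t[i0_ + 1, j0 + 1] * wj
            out[sel] = row0 * (1 - wi) + row1 * wi
        return out


_vm_table_cache: _VMQuantileTable | None = None


def _vm_table():
    global _vm_table_cache
    if _vm_table_cache is None:
        _vm_table_cache = _VMQuantileTable()
    return _vm_table_cache


# ---------------------------------------------------------------------------
# Parameter grids
# ---------------------------------------------------------------------------

@dataclass
class ParameterGrid:
    """Sorted per-parameter value lists spanning the tested ranges."""

    model: str
    axes: dict[str, np.ndarray]

    def __post_init__(self):
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        names = PARAM_NAMES[self.model]
        if tuple(self.axes) != names:
            raise ValueError(f"{self.model} grid must have axes {names} in order")
        if any(len(v) == 0 for v in self.axes.values()):
            raise ValueError("empty grid axis")
        for name, values in self.axes.items():
            values = np.asarray(values, dtype=float)
            lo, hi = PARAM_RANGES[self.model][name]
            if np.any(values < lo) or np.any(values > hi):
                raise ValueError(
                    f"{self.model}.{name} grid values must lie in [{lo}, {hi}]"
                )
            if np.any(np.diff(values) <= 0):
                raise ValueError(f"{self.model}.{name} grid must be strictly sorted")
            if name == "K" and np.any(values != values.astype(int)):
                raise ValueError("K grid must contain integers")
            self.axes[name] = values

    @property
    def shape(self):
        return tuple(len(v) for v in self.axes.values())

    @property
    def size(self):
        return int(np.prod(self.shape))

    def points(self):
        """Iterate parameter dicts in C order of the axes."""
        names = list(self.axes)
        for values in itertools.product(*self.axes.values()):
            yield dict(zip(names, values))

    def to_dict(self):
        return {
            "model": self.model,
            "axes": {k: np.asarray(v).tolist() for k, v in self.axes.items()},
        }


#: Parameters that live on a scale (refined multiplicatively).
_SCALE_PARAMS = {"J_s", "J_1", "J1_bar", "tau"}

#: Default grid points per continuous dimension.  The decision prior
#: ``p_change`` (and the IP response parameters) only shift the decision
#: threshold, not the simulated noise, so their axes are swept at almost no
#: cost and get much finer grids than the encoding dimensions.
_DEFAULT_GRID_POINTS = {
    "IP": {"epsilon": 21, "g": 21},
    "SA": {"J_s": 11, "p_change": 25},
    "SR": {"J_1": 11, "p_change": 25},
    "EP": {"J_1": 11, "alpha": 9, "p_change": 25},
    "VP": {"J1_bar": 11, "tau": 9, "alpha": 9, "p_change": 25},
}

#: Scaled-down grids for recovery studies (coarse grid + local refinement).
_COARSE_GRID_POINTS = {
    "IP": {"epsilon": 11, "g": 11},
    "SA": {"J_s": 9, "p_change": 13},
    "SR": {"J_1": 9, "p_change": 13},
    "EP": {"J_1": 9, "alpha": 7, "p_change": 13},
    "VP": {"J1_bar": 7, "tau": 5, "alpha": 7, "p_change": 13},
}


def default_grid(model, coarse=False):
    """Linearly spaced grid over the tested range of each parameter.

    Linear spacing makes the plain grid average used for the marginal
    likelihood an exact discretization of the uniform prior over the range.
    ``coarse=True`` selects the scaled-down grids used in recovery studies.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    axes = {}
    points = _COARSE_GRID_POINTS[model] if coarse else _DEFAULT_GRID_POINTS[model]
    for name in PARAM_NAMES[model]:
        lo, hi = PARAM_RANGES[model][name]
        if name == "K":
            axes[name] = np.arange(int(lo), int(hi) + 1, dtype=float)
        else:
            axes[name] = np.linspace(lo, hi, points[name])
    return ParameterGrid(model=model, axes=axes)


# ---------------------------------------------------------------------------
# Response probabilities
# ---------------------------------------------------------------------------

def ip_response_probability(params, set_size, change):
    """Exact "change"-report probability of the IP observer."""
    p = validate_params("IP", params)
    n = np.asarray(set_size, dtype=float)
    change = np.asarray(change)
    frac = np.minimum(p["K"], n) / n
    prob = np.where(
        change == 1, frac * (1.0 - p["epsilon"]) + (1.0 - frac) * p["g"], p["g"]
    )
    return prob if prob.ndim else float(prob)


class _NoiseBank:
    """Fixed uniform draws shared by every grid point of one fit."""

    def __init__(self, set_sizes, n_mc, seed):
        rng = np.random.default_rng(seed)
        self.n_mc = int(n_mc)
        self.u = {}
        for n in sorted(int(s) for s in set_sizes):
            self.u[n] = {
                "x": rng.random((self.n_mc, n)),
                "y": rng.random((self.n_mc, n)),
                "gx": rng.random((self.n_mc, n)),
                "gy": rng.random((self.n_mc, n)),
                "rank": np.argsort(rng.random((self.n_mc, n)), axis=1).argsort(axis=1),
            }


def _precision_draws(model, p, n, bank_n):
    """Per-sample precision arrays (n_mc, n) for both displays."""
    n_mc = bank_n["x"].shape[0]
    if model == "EP":
        J = np.full((n_mc, n), p["J_1"] * n ** p["alpha"])
        return J, J
    if model == "SA":
        K = p["K"]
        ranks = bank_n["rank"]
        if n > K:
            counts = (ranks < K).astype(float)
        else:
            counts = (K // n) + (ranks < (K % n)).astype(float)
        J = counts * p["J_s"]
        return J, J
    if model == "SR":
        K = p["K"]
        if n <= K:
            J = np.full((n_mc, n), p["J_1"] / n)
        else:
            J = (bank_n["rank"] < K).astype(float) * (p["J_1"] / K)
        return J, J
    # VP: gamma quantile transform of the fixed uniforms (shape varies with
    # the candidate parameters, the underlying uniforms do not).
    shape = p["J1_bar"] * n ** p["alpha"] / p["tau"]
    u_gx = np.clip(bank_n["gx"], 1e-12, 1 - 1e-12)
    u_gy = np.clip(bank_n["gy"], 1e-12, 1 - 1e-12)
    J_x = special.gammaincinv(shape, u_gx) * p["tau"]
    J_y = special.gammaincinv(shape, u_gy) * p["tau"]
    return J_x, J_y


def _log_sum_tables(model, p, bank, delta_grid):
    """Prior-independent part of the decision variable, per MC sample.

    Returns ``{N: array (n_delta, n_mc)}`` holding
    ``logsumexp_i log r_i`` so that ``log d = log[p_c/(1-p_c)] - log N +
    log_sum``.  The change is placed at item 0 without loss of generality
    (allocation and noise are exchangeable over items); only that item's
    likelihood-ratio term depends on delta, so the delta dimension costs a
    single Bessel evaluation per sample.  ``p`` needs only the encoding
    parameters; the decision prior enters later, which lets a whole
    ``p_change`` grid axis reuse one set of these tables.
    """
    vm = _vm_table()
    out = {}
    for n, u in bank.u.items():
        J_x, J_y = _precision_draws(model, p, n, u)
        kx = kappa_from_j_interp(J_x)
        ky = kappa_from_j_interp(J_y)
        ex = vm.ppf(u["x"], kx)
        ey = vm.ppf(u["y"], ky)
        w = ey - ex  # measurement difference of unchanged items
        a = log_i0(kx) + log_i0(ky)
        if n > 1:
            kc = np.sqrt(
                kx[:, 1:] ** 2
                + ky[:, 1:] ** 2
                + 2 * kx[:, 1:] * ky[:, 1:] * np.cos(w[:, 1:])
            )
            log_r = a[:, 1:] - log_i0(kc)
            m = log_r.max(axis=1)
            l_rest = m + np.log(np.exp(log_r - m[:, None]).sum(axis=1))
        else:
            l_rest = np.full(bank.n_mc, -np.inf)
        cos0 = np.cos(delta_grid[:, None] + w[None, :, 0])
        kc0 = np.sqrt(
            kx[None, :, 0] ** 2
            + ky[None, :, 0] ** 2
            + 2 * kx[None, :, 0] * ky[None, :, 0] * cos0
        )
        log_r0 = a[None, :, 0] - log_i0(kc0)
        out[n] = np.logaddexp(l_rest[None, :], log_r0)
    return out


def _prob_tables(log_sums, p_change):
    """Threshold the decision variable -> ``{N: p(report | delta bin)}``."""
    prior = np.log(p_change) - np.log1p(-p_change)
    return {
        n: (prior - np.log(n) + ls > 0).mean(axis=1) for n, ls in log_sums.items()
    }


def _clip_probs(p, n_mc):
    floor = 1.0 / (2.0 * n_mc)
    return np.clip(p, floor, 1.0 - floor)


def predict_trial_probs(model, params, trials, n_mc=1000, seed=0, n_delta=21,
                        bank=None):
    """Per-trial "change"-report probabilities for a whole trial set.

    Noisy models use the Monte-Carlo table estimator with ``n_mc`` samples
    per (set size, delta) cell; IP is exact.  Probabilities are clipped away
    from 0 and 1 so downstream log likelihoods are finite.
    """
    p = validate_params(model, params)
    if model == "IP":
        prob = ip_response_probability(
            p, trials["set_size"].to_numpy(), trials["change"].to_numpy()
        )
        return _clip_probs(prob, max(n_mc, 1))
    if n_mc < 1:
        raise ValueError("n_mc must be >= 1 for noisy models")
    if bank is None:
        bank = _NoiseBank(trials["set_size"].unique(), n_mc, seed)
    delta_grid = np.linspace(0.0, np.pi, n_delta)
    log_sums = _log_sum_tables(model, p, bank, delta_grid)
    table = _prob_tables(log_sums, p["p_change"])
    out = np.empty(len(trials))
    set_size = trials["set_size"].to_numpy()
    absdelta = np.abs(trials["delta"].to_numpy())
    for n in np.unique(set_size):
        sel = set_size == n
        out[sel] = np.interp(absdelta[sel], delta_grid, table[int(n)])
    return _clip_probs(out, bank.n_mc)


def response_probability(model, params, trial, n_mc=1000, rng=None, seed=None):
    """Direct Monte-Carlo estimate of P(report "change") on one trial.

    Simulates ``n_mc`` independent encodings and measurement pairs of the
    trial's actual stimuli and averages the MAP indicator (exact closed form
    for IP).  ``trial`` is a row of a trial-set DataFrame (any object with
    ``set_size``, ``change``, ``change_loc``, ``theta``, ``phi``).
    """
    p = validate_params(model, params)
    if model == "IP":
        return ip_response_probability(p, trial.set_size, trial.change)
    if n_mc < 1:
        raise ValueError("n_mc must be >= 1 for noisy models")
    if rng is None:
        rng = np.random.default_rng(seed)
    from .simulate import _allocate_batch  # shared vectorized allocation

    n = int(trial.set_size)
    theta = np.broadcast_to(np.asarray(trial.theta, dtype=float), (n_mc, n))
    phi = np.broadcast_to(np.asarray(trial.phi, dtype=float), (n_mc, n))
    J_x, J_y = _allocate_batch(model, p, n, n_mc, rng)
    kx = kappa_from_j_interp(J_x)
    ky = kappa_from_j_interp(J_y)
    x = rng.vonmises(theta, kx)
    y = rng.vonmises(phi, ky)
    kc = np.sqrt(kx**2 + ky**2 + 2 * kx * ky * np.cos(y - x))
    log_r = log_i0(kx) + log_i0(ky) - log_i0(kc)
    m = log_r.max(axis=1)
    log_sum = m + np.log(np.exp(log_r - m[:, None]).sum(axis=1))
    log_d = (
        np.log(p["p_change"]) - np.log1p(-p["p_change"]) - np.log(n) + log_sum
    )
    return float(_clip_probs((log_d > 0).mean(), n_mc))


def bernoulli_loglik(responses, probs):
    """Sum of log Bernoulli probabilities of the observed responses."""
    r = np.asarray(responses, dtype=float)
    p = np.asarray(probs, dtype=float)
    return float(np.sum(r * np.log(p) + (1.0 - r) * np.log1p(-p)))


# ---------------------------------------------------------------------------
# Maximum-likelihood fitting
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Maximum-likelihood fit of one model to one dataset."""

    model: str
    params: dict
    log_likelihood: float
    grid_max_log_likelihood: float
    log_likelihood_table: np.ndarray = field(repr=False)
    grid: ParameterGrid = field(repr=False)
    n_mc: int = 0
    seed: int = 0

    def to_dict(self):
        return {
            "model": self.model,
            "mle": self.params,
            "logL": self.log_likelihood,
            "grid_max_logL": self.grid_max_log_likelihood,
            "logL_table": self.log_likelihood_table.tolist(),
            "grid": self.grid.to_dict(),
            "n_mc": self.n_mc,
            "seed": self.seed,
        }


class _TrialIndex:
    """Precomputed per-set-size views of a dataset for fast interpolation."""

    def __init__(self, trials, responses):
        set_size = trials["set_size"].to_numpy()
        absdelta = np.abs(trials["delta"].to_numpy())
        r = np.asarray(responses, dtype=float)
        self.groups = {}
        for n in np.unique(set_size):
            sel = set_size == n
            self.groups[int(n)] = (absdelta[sel], r[sel])

    def loglik(self, prob_tables, delta_grid, n_mc):
        total = 0.0
        for n, (absdelta, r) in self.groups.items():
            p = _clip_probs(np.interp(absdelta, delta_grid, prob_tables[n]), n_mc)
            total += float(np.sum(r * np.log(p) + (1.0 - r) * np.log1p(-p)))
        return total


def _eval_axes(model, axes, trials, responses, n_mc, seed, n_delta, bank=None,
               index=None):
    """Log likelihood on the outer product of ``axes`` (ordered dict).

    For noisy models the last axis is ``p_change``; the expensive encoding
    simulation runs once per combination of the other axes and the whole
    ``p_change`` axis is swept by re-thresholding the decision variable.
    IP is evaluated exactly (vectorized closed form).
    """
    names = list(axes)
    shape = tuple(len(axes[k]) for k in names)
    responses = np.asarray(responses, dtype=float)
    table = np.empty(shape)

    if model == "IP":
        set_size = trials["set_size"].to_numpy()
        change = trials["change"].to_numpy()
        for i, vals in enumerate(itertools.product(*(axes[k] for k in names))):
            params = dict(zip(names, vals))
            params["K"] = int(params["K"])
            probs = _clip_probs(
                ip_response_probability(params, set_size, change), max(n_mc, 1)
            )
            table.flat[i] = bernoulli_loglik(responses, probs)
        return table, None

    if names[-1] != "p_change":
        raise ValueError("noisy-model axes must end with p_change")
    if bank is None:
        bank = _NoiseBank(trials["set_size"].unique(), n_mc, seed)
    if index is None:
        index = _TrialIndex(trials, responses)
    delta_grid = np.linspace(0.0, np.pi, n_delta)
    pc_axis = axes["p_change"]
    enc_names = names[:-1]
    enc_table = table.reshape(-1, len(pc_axis))
    for i, vals in enumerate(itertools.product(*(axes[k] for k in enc_names))):
        enc = dict(zip(enc_names, vals))
        if "K" in enc:
            enc["K"] = int(enc["K"])
        enc["p_change"] = 0.5  # placeholder; not used by the encoding stage
        log_sums = _log_sum_tables(model, enc, bank, delta_grid)
        for j, pc in enumerate(pc_axis):
            tables = _prob_tables(log_sums, float(pc))
            enc_table[i, j] = index.loglik(tables, delta_grid, bank.n_mc)
    return table, bank


def _zoom_refine(model, grid, best, trials, responses, n_mc, seed,
                 n_delta, index, max_iter=10):
    """Iterative local grid search around the coarse-grid optimum.

    Each iteration evaluates a 3-point-per-continuous-dimension window of
    half-width ``step`` centered on the incumbent; the window shrinks only
    when the optimum is interior, so the search can walk out of a shallow
    coarse-grid basin before converging.  K stays at its (exhaustively
    gridded) coarse value.  Runs at a higher MC precision than the coarse
    grid pass because nearby points on the likelihood ridge differ by only
    a few log units — less than the small-sample bias of a low-``n_mc``
    estimator, which would otherwise tilt the ridge.
    """
    names = list(grid.axes)
    cont = [n for n in names if n != "K" and len(grid.axes[n]) > 1]
    # Scale parameters move multiplicatively: the likelihood ridge of e.g.
    # the VP model is curved in (J1_bar, tau) but near-linear in their logs,
    # and additive axis-aligned windows stall on the ridge wall.
    log_scale = {n for n in cont if n in _SCALE_PARAMS}
    steps, factors = {}, {}
    for n in cont:
        ax = grid.axes[n]
        if n in log_scale:
            factors[n] = float(np.exp(np.mean(np.diff(np.log(np.maximum(ax, 1e-12))))))
        else:
            steps[n] = float(np.diff(ax).mean())
    bank = (
        None
        if model == "IP"
        else _NoiseBank(trials["set_size"].unique(), n_mc, seed)
    )

    def evaluate(point):
        axes = {name: np.array([float(point[name])]) for name in names}
        t, _ = _eval_axes(model, axes, trials, responses, n_mc, seed,
                          n_delta, bank=bank, index=index)
        return float(t.flat[0])

    def walk(best, best_ll, factors, steps, n_iter):
        factors, steps = dict(factors), dict(steps)
        for _ in range(n_iter):
            axes = {}
            for name in names:
                if name not in cont:
                    axes[name] = np.array([float(best[name])])
                    continue
                lo, hi = PARAM_RANGES[model][name]
                center = best[name]
                if name in log_scale:
                    f = factors[name]
                    window = np.array([center / f, center, center * f])
                else:
                    s = steps[name]
                    window = np.linspace(center - s, center + s, 3)
                axes[name] = np.unique(np.clip(window, lo, hi))
            table, _ = _eval_axes(model, axes, trials, responses, n_mc, seed,
                                  n_delta, bank=bank, index=index)
            idx = np.unravel_index(int(np.argmax(table)), table.shape)
            cand = {name: float(axes[name][i]) for name, i in zip(names, idx)}
            if "K" in cand:
                cand["K"] = int(cand["K"])
            cand_ll = float(table.max())
            on_edge = any(
                idx[k] in (0, len(axes[name]) - 1)
                and not np.isclose(
                    axes[name][idx[k]], PARAM_RANGES[model][name]
                ).any()
                for k, name in enumerate(names)
                if name in cont and len(axes[name]) > 1
            )
            if cand_ll > best_ll:
                best, best_ll = cand, cand_ll
            if not on_edge:
                for name in log_scale:
                    factors[name] = float(np.sqrt(factors[name]))
                for name in steps:
                    steps[name] /= 2.0
        return best, best_ll

    # re-evaluate the incumbent at refinement precision for fair comparison
    best_ll = evaluate(best)
    best, best_ll = walk(best, best_ll, factors, steps, max_iter)

    if log_scale:
        # The scale parameters are nearly degenerate along a common ray
        # (e.g. raising mean precision and its variability scale together
        # barely changes the response statistics), and the local walk can
        # settle anywhere on that shallow ridge.  Scan the ray over a wide
        # multiplicative range, jump to its optimum, and repolish.
        ray = []
        for s in np.geomspace(1 / 2.5, 2.5, 11):
            cand = dict(best)
            for name in log_scale:
                lo, hi = PARAM_RANGES[model][name]
                cand[name] = float(np.clip(best[name] * s, lo, hi))
            ray.append(cand)
        lls = np.array([evaluate(c) for c in ray])
        j = int(np.argmax(lls))
        if lls[j] > best_ll:
            best, best_ll = ray[j], float(lls[j])
        best, best_ll = walk(
            best, best_ll,
            {n: 1.35 for n in log_scale},
            {n: s / 2 for n, s in steps.items()},
            4,
        )
    return best, best_ll


def fit_model(model, trials, responses, grid=None, n_mc=1000, seed=0,
              refine=True, n_delta=21, n_mc_refine=None):
    """Maximum-likelihood fit by grid evaluation with common random numbers.

    Evaluates the Bernoulli log likelihood of the responses at every grid
    point (IP exactly; noisy models via the Monte-Carlo table estimator with
    shared noise draws), then optionally refines around the grid optimum
    with an iterative local search at higher MC precision (``n_mc_refine``,
    default ``4 * n_mc``).  Fully deterministic given ``seed``.
    """
    if len(trials) != len(np.asarray(responses)):
        raise ValueError("trials and responses must be aligned")
    if grid is None:
        grid = default_grid(model)
    if grid.model != model:
        raise ValueError("grid was built for a different model")

    index = _TrialIndex(trials, responses)
    bank = (
        None
        if model == "IP"
        else _NoiseBank(trials["set_size"].unique(), n_mc, seed)
    )
    table, bank = _eval_axes(model, grid.axes, trials, responses, n_mc, seed,
                             n_delta, bank=bank, index=index)
    flat_idx = int(np.argmax(table))
    idx = np.unravel_index(flat_idx, grid.shape)
    names = list(grid.axes)
    best = {name: float(grid.axes[name][i]) for name, i in zip(names, idx)}
    if "K" in best:
        best["K"] = int(best["K"])
    best_ll = float(table.flat[flat_idx])
    grid_max = best_ll

    if refine:
        if n_mc_refine is None:
            n_mc_refine = 4 * n_mc
        best, best_ll = _zoom_refine(model, grid, best, trials, responses,
                                     n_mc_refine, seed, n_delta, index)

    return FitResult(
        model=model,
        params=best,
        log_likelihood=best_ll,
        grid_max_log_likelihood=grid_max,
        log_likelihood_table=table,
        grid=grid,
        n_mc=int(n_mc),
        seed=int(seed),
    )
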