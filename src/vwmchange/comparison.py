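"""Bayesian model comparison via grid-marginalized likelihoods.

Each model's evidence is the likelihood of the data averaged over a uniform
prior on its parameters' tested ranges.  With linearly spaced grids this is
the plain average of the per-grid-point likelihoods,

    log p(data | model) = logsumexp(logL table) - log(#grid points),

computed overflow-safely.  Differences are reported relative to the VP
model, so a value of -x for some model means the data are e**x times more
probable under VP.  Grid marginalization (rather than MCMC) keeps the
integral deterministic given the fitting seed; resolution is a config knob
and halving the step is the standard convergence check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special

from .fitting import FitResult, default_grid, fit_model
from .models import MODELS

__all__ = [
    "ComparisonResult",
    "marginal_log_likelihood",
    "marginal_from_table",
    "compare_models",
    "aggregate_comparisons",
]


def marginal_from_table(log_likelihood_table):
    """Log of the uniform-prior average of gridded likelihoods."""
    table = np.asarray(log_likelihood_table, dtype=float)
    if table.size == 0:
        raise ValueError("empty log-likelihood table")
    return float(special.logsumexp(table) - np.log(table.size))


def marginal_log_likelihood(model, trials, responses, grid=None, n_mc=1000,
                            seed=0, fit=None):
    """Marginal log likelihood of one model for one dataset.

    Reuses a :class:`~vwmchange.fitting.FitResult`'s grid table when given
    (``fit=``); otherwise evaluates the grid.  The grid must span the tested
    parameter ranges for the uniform prior to be meaningful.
    """
    if fit is not None:
        if fit.model != model:
            raise ValueError("fit/model mismatch")
        if grid is not None and fit.grid.to_dict() != grid.to_dict():
            raise ValueError("fit was computed on a different grid")
        return marginal_from_table(fit.log_likelihood_table)
    result = fit_model(model, trials, responses, grid=grid, n_mc=n_mc,
                       seed=seed, refine=False)
    return marginal_from_table(result.log_likelihood_table)


@dataclass
class ComparisonResult:
    """Marginal log likelihoods of all five models on one dataset."""

    marginal: dict[str, float]
    delta_vs_vp: dict[str, float]
    fits: dict[str, FitResult] = field(default_factory=dict, repr=False)

    @property
    def best_model(self):
        return max(self.marginal, key=self.marginal.get)

    def to_dict(self):
        return {"marginal_logL": self.marginal, "delta_logL_vs_VP": self.delta_vs_vp}


def compare_models(trials, responses, grids=None, n_mc=1000, seed=0,
                   models=MODELS, coarse=False):
    """Fit all models on identical data and compare marginal likelihoods.

    ``grids`` maps model id to a :class:`ParameterGrid`; missing entries use
    :func:`default_grid` (``coarse=True`` selects the scaled-down grids).
    Deterministic given ``seed``.
    """
    if "VP" not in models:
        raise ValueError("comparison is reported relative to VP; include it")
    grids = dict(grids or {})
    marginal, fits = {}, {}
    for model in models:
        grid = grids.get(model) or default_grid(model, coarse=coarse)
        fit = fit_model(model, trials, responses, grid=grid, n_mc=n_mc,
                        seed=seed, refine=False)
        fits[model] = fit
        marginal[model] = marginal_from_table(fit.log_likelihood_table)
    delta = {m: marginal[m] - marginal["VP"] for m in marginal}
    return ComparisonResult(marginal=marginal, delta_vs_vp=delta, fits=fits)


def aggregate_comparisons(results):
    """Mean and s.e.m. of the per-dataset delta log likelihoods vs VP."""
    if not results:
        raise ValueError("no comparison results to aggregate")
    models = list(results[0].delta_vs_vp)
    out = {}
    for m in models:
        vals = np.array([r.delta_vs_vp[m] for r in results], dtype=float)
        sem = vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else 0.0
        out[m] = {"mean": float(vals.mean()), "sem": float(sem), "n": len(vals)}
    return out
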