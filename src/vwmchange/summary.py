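"""Descriptive statistics and the apparent-guessing-rate analysis.

Summaries follow the conventions of the change-detection literature: hit
rate H = P(report "change" | change) and false-alarm rate F = P(report
"change" | no change) per set size; psychometric curves bin the physical
change magnitude on change trials into ten 9-degree bins ((0, 9], ...,
(81, 90]) with all no-change trials in a separate magnitude-0 bin; Cowan's
K = N (H - F) / (1 - F) is the classic item-limit capacity estimator.

The apparent-guessing-rate (AGR) analysis fits, separately at each set
size, a two-parameter mixture: with probability AGR the observer guesses
("change" with probability 1/2), otherwise it responds like an equal-
precision Bayesian observer with precision J_EP (decision prior fixed at
the true p_change = 0.5).  On data generated by the variable-precision
model the fitted AGR rises with set size even though the generator contains
no guessing — variability in precision masquerades as guessing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .fitting import _NoiseBank, bernoulli_loglik, predict_trial_probs

__all__ = [
    "SummaryStats",
    "AGRFit",
    "summarize",
    "cowan_k",
    "fit_agr",
    "rmse_summary",
]

_BIN_WIDTH_DEG = 9.0


@dataclass
class SummaryStats:
    """Per-set-size rates and binned psychometric curves."""

    set_sizes: tuple
    hit_rate: dict[int, float]
    fa_rate: dict[int, float]
    n_change: dict[int, int]
    n_nochange: dict[int, int]
    bin_edges_deg: np.ndarray = field(repr=False)
    #: per set size: proportion "change" per magnitude bin; index 0 is the
    #: no-change bin, indices 1..n_bins cover (0, w], ..., ((n-1)w, nw] deg.
    psychometric: dict[int, np.ndarray] = field(repr=False, default_factory=dict)
    psychometric_counts: dict[int, np.ndarray] = field(repr=False,
                                                       default_factory=dict)

    def to_frame(self):
        import pandas as pd

        rows = []
        for n in self.set_sizes:
            rows.append(
                {
                    "set_size": n,
                    "hit_rate": self.hit_rate[n],
                    "fa_rate": self.fa_rate[n],
                    "n_change": self.n_change[n],
                    "n_nochange": self.n_nochange[n],
                }
            )
        return pd.DataFrame(rows)


def summarize(trials, responses, bin_width_deg=_BIN_WIDTH_DEG):
    """Hit/false-alarm rates and psychometric curves per set size."""
    responses = np.asarray(responses)
    if len(trials) != len(responses):
        raise ValueError("trials and responses must be aligned")
    set_size = trials["set_size"].to_numpy()
    change = trials["change"].to_numpy()
    mag_deg = np.degrees(np.abs(trials["delta"].to_numpy())) / 2.0
    if np.any(mag_deg > 90.0 + 1e-9):
        raise ValueError("physical change magnitudes must lie in [0, 90] degrees")
    n_bins = int(round(90.0 / bin_width_deg))
    edges = np.linspace(0.0, 90.0, n_bins + 1)

    set_sizes = tuple(int(n) for n in np.unique(set_size))
    hit, fa, nc, nn, psych, counts = {}, {}, {}, {}, {}, {}
    for n in set_sizes:
        sel = set_size == n
        ch = sel & (change == 1)
        no = sel & (change == 0)
        nc[n] = int(ch.sum())
        nn[n] = int(no.sum())
        hit[n] = float(responses[ch].mean()) if nc[n] else np.nan
        fa[n] = float(responses[no].mean()) if nn[n] else np.nan
        # bin 0: all no-change trials; bins 1..n_bins: half-open (lo, hi]
        prop = np.full(n_bins + 1, np.nan)
        cnt = np.zeros(n_bins + 1, dtype=int)
        prop[0], cnt[0] = fa[n], nn[n]
        which = np.searchsorted(edges, mag_deg[ch], side="left")
        which = np.clip(which, 1, n_bins)
        for b in range(1, n_bins + 1):
            in_bin = which == b
            cnt[b] = int(in_bin.sum())
            if cnt[b]:
                prop[b] = float(responses[ch][in_bin].mean())
        psych[n], counts[n] = prop, cnt
    return SummaryStats(
        set_sizes=set_sizes,
        hit_rate=hit,
        fa_rate=fa,
        n_change=nc,
        n_nochange=nn,
        bin_edges_deg=edges,
        psychometric=psych,
        psychometric_counts=counts,
    )


def cowan_k(H, F, N):
    """Item-limit capacity estimate K = N (H - F) / (1 - F).

    May be negative; no clipping is applied.  Undefined at F = 1.
    """
    if not 0.0 <= H <= 1.0 or not 0.0 <= F <= 1.0:
        raise ValueError("H and F must be rates in [0, 1]")
    if F >= 1.0:
        raise ValueError("Cowan's K is undefined at a false-alarm rate of 1")
    return N * (H - F) / (1.0 - F)


@dataclass
class AGRFit:
    """Apparent guessing rate and EP precision fitted at one set size."""

    set_size: int
    agr: float
    j_ep: float
    log_likelihood: float
    n_trials: int


def fit_agr(trials, responses, set_size, agr_grid=None, j_grid=None,
            n_mc=2000, seed=0, guess_rate=0.5):
    """Fit the guessing + equal-precision mixture at one set size.

    With probability AGR the response is a guess ("change" with probability
    ``guess_rate``); otherwise it follows the EP Bayesian observer with
    precision ``J_EP`` and decision prior 0.5.  Maximum likelihood over an
    (AGR, J) grid; the EP response probabilities are Monte-Carlo estimates
    with common random numbers across the J grid.
    """
    responses = np.asarray(responses)
    sel = trials["set_size"].to_numpy() == set_size
    sub = trials.loc[sel].reset_index(drop=True)
    r = np.asarray(responses[sel], dtype=float)
    if len(sub) < 50:
        warnings.warn(
            f"only {len(sub)} trials at set size {set_size}; AGR fit unstable",
            stacklevel=2,
        )
    if agr_grid is None:
        agr_grid = np.linspace(0.0, 1.0, 41)
    if j_grid is None:
        # J_EP >= 1 keeps the EP component out of the guessing regime: a
        # near-zero-precision EP observer responds at chance and is
        # indistinguishable from the guessing component (flat ridge).
        j_grid = np.geomspace(1.0, 500.0, 29)

    bank = _NoiseBank([set_size], n_mc, seed)
    best = (-np.inf, None, None)
    for j in j_grid:
        p_ep = predict_trial_probs(
            "EP", {"J_1": float(j), "alpha": 0.0, "p_change": 0.5},
            sub, n_mc=n_mc, seed=seed, bank=bank,
        )
        for agr in agr_grid:
            p_mix = agr * guess_rate + (1.0 - agr) * p_ep
            ll = bernoulli_loglik(r, np.clip(p_mix, 1e-9, 1 - 1e-9))
            if ll > best[0]:
                best = (ll, float(agr), float(j))
    return AGRFit(
        set_size=int(set_size),
        agr=best[1],
        j_ep=best[2],
        log_likelihood=best[0],
        n_trials=len(sub),
    )


def rmse_summary(data_stats, model_stats, which="rates"):
    """Root-mean-square difference between two summaries.

    ``which`` selects the cells: ``"rates"`` uses the hit and false-alarm
    rates per set size, ``"psychometric"`` all magnitude-bin proportions per
    set size, ``"all"`` both.  Requires identical set sizes and binning.
    """
    if data_stats.set_sizes != model_stats.set_sizes:
        raise ValueError("summaries cover different set sizes")
    if not np.array_equal(data_stats.bin_edges_deg, model_stats.bin_edges_deg):
        raise ValueError("summaries use different magnitude binning")
    cells_a, cells_b = [], []
    if which in ("rates", "all"):
        for n in data_stats.set_sizes:
            cells_a += [data_stats.hit_rate[n], data_stats.fa_rate[n]]
            cells_b += [model_stats.hit_rate[n], model_stats.fa_rate[n]]
    if which in ("psychometric", "all"):
        for n in data_stats.set_sizes:
            cells_a += list(data_stats.psychometric[n])
            cells_b += list(model_stats.psychometric[n])
    if which not in ("rates", "psychometric", "all"):
        raise ValueError("which must be 'rates', 'psychometric' or 'all'")
    a = np.asarray(cells_a, dtype=float)
    b = np.asarray(cells_b, dtype=float)
    ok = ~(np.isnan(a) | np.isnan(b))
    if not np.any(ok):
        raise ValueError("no comparable cells")
    return float(np.sqrt(np.mean((a[ok] - b[ok]) ** 2)))
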