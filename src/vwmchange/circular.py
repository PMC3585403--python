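"""Circular-variable math shared by all noisy observer models.

Orientation is a circular variable with period pi (a bar rotated by 180
degrees looks the same).  All model math runs on the *internal* doubled
circle: a physical orientation in [-pi/2, pi/2) maps bijectively to an
internal angle in (-pi, pi] by doubling, so that orientation and genuinely
periodic features (hue treated as a circular variable) share one code path.

Measurement noise is Von Mises, ``p(x | theta) = exp(kappa cos(x - theta)) /
(2 pi I0(kappa))``, and memory *precision* is identified with the Fisher
information of that distribution, ``J = kappa I1(kappa) / I0(kappa)``.
``j_from_kappa`` / ``kappa_from_j`` convert between the two; both are
computed with exponentially scaled Bessel functions so they stay finite for
concentrations far beyond the overflow point of the unscaled I0 (~kappa=700).
"""

from __future__ import annotations

import numpy as np
from scipy import optimize, special

__all__ = [
    "wrap",
    "to_internal",
    "from_internal",
    "internal_to_physical_deg",
    "physical_deg_to_internal",
    "log_i0",
    "vonmises_logpdf",
    "vonmises_sample",
    "j_from_kappa",
    "kappa_from_j",
    "kappa_from_j_interp",
]

TWO_PI = 2.0 * np.pi

# Upper bracket for the kappa <-> J inversion; fitted precisions implied by
# realistic parameter ranges (J up to a few hundred) sit far below this.
_KAPPA_MAX = 1.0e4


def wrap(angle):
    """Map angles to the internal principal interval (-pi, pi]."""
    a = np.asarray(angle, dtype=float)
    w = np.mod(a, TWO_PI)
    w = np.where(w > np.pi, w - TWO_PI, w)
    out = np.where(w <= -np.pi, w + TWO_PI, w)  # guard -pi from fp fuzz
    return out if out.ndim else float(out)


def to_internal(theta_phys):
    """Physical orientation (radians, period pi) -> internal angle (period 2 pi)."""
    return wrap(2.0 * np.asarray(theta_phys, dtype=float))


def from_internal(angle):
    """Internal angle -> physical orientation in (-pi/2, pi/2] radians."""
    return wrap(angle) / 2.0


def internal_to_physical_deg(angle):
    """Internal angle -> physical orientation in degrees, (-90, 90]."""
    return np.degrees(from_internal(angle))


def physical_deg_to_internal(deg):
    """Physical orientation in degrees -> internal angle."""
    return to_internal(np.radians(np.asarray(deg, dtype=float)))


def _check_nonneg(value, name):
    arr = np.asarray(value, dtype=float)
    if np.any(arr < 0) or np.any(np.isnan(arr)):
        raise ValueError(f"{name} must be non-negative, got {value!r}")
    return arr


def log_i0(kappa):
    """log I0(kappa), overflow-safe via the exponentially scaled Bessel i0e."""
    k = np.asarray(kappa, dtype=float)
    return np.log(special.i0e(k)) + k


def vonmises_logpdf(x, mu, kappa):
    """Log density of the Von Mises measurement distribution.

    ``kappa = 0`` gives the uniform density ``1/(2 pi)``.  Finite for kappa
    well above 1e4 because the normalizer is evaluated in the log domain.
    """
    k = _check_nonneg(kappa, "kappa")
    x = np.asarray(x, dtype=float)
    mu = np.asarray(mu, dtype=float)
    out = k * np.cos(x - mu) - np.log(TWO_PI) - log_i0(k)
    return out if out.ndim else float(out)


def vonmises_sample(mu, kappa, rng, size=None):
    """Draw Von Mises samples on the internal circle.

    Parameters
    ----------
    mu : array_like
        Circular mean (internal radians).
    kappa : array_like
        Concentration, >= 0 (0 yields uniform samples).
    rng : numpy.random.Generator
        Seeded generator; all randomness flows through it.
    size : optional
        Output shape, as for ``Generator.vonmises``.
    """
    _check_nonneg(kappa, "kappa")
    return wrap(rng.vonmises(mu, kappa, size=size))


def j_from_kappa(kappa):
    """Fisher information of the Von Mises distribution: J = kappa I1/I0.

    Uses scaled Bessel ratios, so it is accurate and monotone for kappa up to
    (and beyond) 1e4 where the unscaled Bessel functions overflow.
    """
    k = _check_nonneg(kappa, "kappa")
    with np.errstate(invalid="ignore"):
        ratio = np.where(k > 0, special.i1e(k) / special.i0e(k), 0.0)
    out = k * ratio
    return out if out.ndim else float(out)


def _kappa_from_j_scalar(j):
    if j == 0.0:
        return 0.0
    hi = max(_KAPPA_MAX, 2.0 * j + 2.0)
    return optimize.brentq(
        lambda k: j_from_kappa(k) - j, 0.0, hi, xtol=1e-12, rtol=1e-12
    )


def kappa_from_j(J):
    """Invert the J(kappa) map by bracketed root finding.

    Exact at ``J = 0``; round trips with :func:`j_from_kappa` to relative
    tolerance well below 1e-6.  Accepts scalars or arrays (elementwise).
    """
    arr = _check_nonneg(J, "J")
    if arr.ndim == 0:
        return _kappa_from_j_scalar(float(arr))
    flat = np.array([_kappa_from_j_scalar(v) for v in arr.ravel()])
    return flat.reshape(arr.shape)


class _KappaInterp:
    """Cached monotone log-log interpolation of kappa(J) for hot paths."""

    def __init__(self, n=800):
        kgrid = np.concatenate([[0.0], np.logspace(-6, np.log10(_KAPPA_MAX), n)])
        jgrid = j_from_kappa(kgrid)
        self._logj = np.log(jgrid[1:])
        self._logk = np.log(kgrid[1:])
        self._jmin = jgrid[1]
        self._jmax = jgrid[-1]

    def __call__(self, J):
        arr = _check_nonneg(J, "J")
        flat = np.clip(np.asarray(arr, dtype=float), 0.0, self._jmax)
        pos = flat > 0
        out = np.zeros_like(flat)
        if np.any(pos):
            lj = np.log(np.maximum(flat[pos], self._jmin))
            out[pos] = np.exp(np.interp(lj, self._logj, self._logk))
        return out if out.ndim else float(out)


_kappa_interp_cache: _KappaInterp | None = None


def kappa_from_j_interp(J):
    """Fast vectorized kappa(J) via a cached interpolation table.

    Relative accuracy ~1e-5; used in simulation and fitting loops where the
    root-finding inverse would dominate runtime.
    """
    global _kappa_interp_cache
    if _kappa_interp_cache is None:
        _kappa_interp_cache = _KappaInterp()
    return _kappa_interp_cache(J)
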