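"""Shared test utilities, including the brute-force decision-rule oracle."""

import numpy as np
from scipy.special import i0


def oracle_decision_variable(x, y, kx, ky, p_change, n_theta=2001, n_delta=401):
    """Posterior ratio by numerical marginalization of the generative model.

    Integrates the measurement likelihood over the uniform stimulus prior
    (and, under change, over the uniform change magnitude and the uniform
    change location) by trapezoidal quadrature.  Independent of the closed
    form used by the package.
    """
    x, y, kx, ky = (np.asarray(a, dtype=float) for a in (x, y, kx, ky))
    n = len(x)
    th = np.linspace(-np.pi, np.pi, n_theta)
    dl = np.linspace(-np.pi, np.pi, n_delta)

    def vm(z, mu, k):
        return np.exp(k * np.cos(z - mu)) / (2 * np.pi * i0(k))

    p_same = np.empty(n)
    p_changed = np.empty(n)
    for i in range(n):
        f = vm(x[i], th, kx[i]) * vm(y[i], th, ky[i]) / (2 * np.pi)
        p_same[i] = np.trapezoid(f, th)
        g = vm(x[i], th[None, :], kx[i]) * vm(y[i], th[None, :] + dl[:, None], ky[i])
        inner = np.trapezoid(g, th, axis=1)
        p_changed[i] = np.trapezoid(inner, dl) / (2 * np.pi) ** 2
    likelihood_ratio = np.mean(p_changed / p_same)
    return p_change / (1 - p_change) * likelihood_ratio


def random_decision_configs(n_configs, rng, max_n=3, kappas=(1.0, 5.0, 20.0)):
    """Random measurement/concentration configurations for oracle checks."""
    configs = []
    for _ in range(n_configs):
        n = int(rng.integers(1, max_n + 1))
        configs.append(
            dict(
                x=rng.uniform(-np.pi, np.pi, n),
                y=rng.uniform(-np.pi, np.pi, n),
                kx=rng.choice(kappas, n).astype(float),
                ky=rng.choice(kappas, n).astype(float),
                p_change=float(rng.uniform(0.3, 0.7)),
            )
        )
    return configs
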