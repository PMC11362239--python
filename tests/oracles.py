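"""Independent numerical oracles used by the test suite only."""

import numpy as np
from scipy.stats import norm


def probit_loglik(beta, X, y):
    eta = X @ beta
    p = np.clip(norm.cdf(eta), 1e-12, 1 - 1e-12)
    return float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


def grid_search_ml(X, y, span=6.0, points=9, refinements=14):
    """Brute-force probit ML by nested grid refinement over 4 coefficients."""
    center = np.zeros(4)
    width = span
    for _ in range(refinements):
        axes = [np.linspace(c - width, c + width, points) for c in center]
        grids = np.meshgrid(*axes, indexing="ij")
        cand = np.stack([g.ravel() for g in grids], axis=1)
        eta = cand @ X.T
        p = np.clip(norm.cdf(eta), 1e-12, 1 - 1e-12)
        ll = (np.log(p) @ y) + (np.log1p(-p) @ (1 - y))
        center = cand[int(np.argmax(ll))]
        width *= 2.0 / (points - 1)
    return center
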