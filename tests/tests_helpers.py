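"""Shared deterministic oracles for the genetic-algorithm tests."""

import numpy as np

from herbscreen.ga import evaluate_population


def fixed_toy_scorer(X):
    """Deterministic logistic scorer with per-herb effects and interactions."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    w = np.array([0.8, -0.3, 0.5, 0.1, -0.7, 0.9, 0.2, -0.5, 0.4, -0.1, 0.6, -0.9])
    z = X @ w + 0.6 * X[:, 0] * X[:, 5] - 0.4 * X[:, 2] * X[:, 7] - 0.5
    return 1.0 / (1.0 + np.exp(-z))


def enumerate_minimum(scorer, d, target):
    """Exhaustive enumeration of all 2^d subsets (the independent oracle)."""
    bits = ((np.arange(2**d)[:, None] >> np.arange(d)) & 1).astype(np.uint8)
    return float(evaluate_population(bits, scorer, target).min())
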