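"""Minimal Gaussian-process Bayesian optimization (expected improvement).

Used for SVM hyperparameter search.  Kept deliberately small: continuous box
bounds, latin-ish random initialization, Matern-5/2 GP surrogate, expected
improvement maximized over a random candidate pool.  Deterministic given the
generator.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
from scipy.stats import norm
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern

import warnings


def maximize(
    objective: Callable[[np.ndarray], float],
    bounds: Sequence[tuple[float, float]],
    n_calls: int,
    rng: np.random.Generator,
    n_initial: int | None = None,
    n_candidates: int = 256,
) -> tuple[np.ndarray, float, list[tuple[np.ndarray, float]]]:
    """Maximize ``objective`` over a box with ``n_calls`` total evaluations.

    Returns ``(best_x, best_y, history)``.
    """
    bounds = np.asarray(bounds, dtype=float)
    dim = len(bounds)
    if n_calls < 1:
        raise ValueError("n_calls must be >= 1")
    if n_initial is None:
        n_initial = max(2, min(n_calls // 3, 10))
    n_initial = min(n_initial, n_calls)

    def sample(n: int) -> np.ndarray:
        return rng.uniform(bounds[:, 0], bounds[:, 1], size=(n, dim))

    X = list(sample(n_initial))
    y = [float(objective(x)) for x in X]

    kernel = Matern(length_scale=np.ones(dim), nu=2.5)
    while len(y) < n_calls:
        gp = GaussianProcessRegressor(
            kernel=kernel,
            alpha=1e-6,
            normalize_y=True,
            n_restarts_optimizer=1,
            random_state=int(rng.integers(2**31)),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=ConvergenceWarning)
            gp.fit(np.asarray(X), np.asarray(y))
        cand = sample(n_candidates)
        mu, sigma = gp.predict(cand, return_std=True)
        best = max(y)
        sigma = np.maximum(sigma, 1e-12)
        z = (mu - best) / sigma
        ei = (mu - best) * norm.cdf(z) + sigma * norm.pdf(z)
        x_next = cand[int(np.argmax(ei))]
        X.append(x_next)
        y.append(float(objective(x_next)))

    i_best = int(np.argmax(y))
    return X[i_best], y[i_best], list(zip(X, y))
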