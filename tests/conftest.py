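"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pytest
from scipy.special import ndtr

from selfmotion.psychometric import negative_log_likelihood
from selfmotion.staircase import Response, StaircaseConfig, init_staircase, update


def simulate_staircase_trials(mu, sigma, rng, starts=(+10.0, -10.0), n_steps=25,
                              duration=1.0):
    """Collect (velocity, response) trials by running staircases against a
    cumulative-Gaussian responder with PSE ``mu`` and width ``sigma``
    (velocity units).  One 25-step staircase per entry in ``starts``
    (displacement units)."""
    xs, ys = [], []
    for start in starts:
        state = init_staircase(StaircaseConfig(initial_magnitude=start, n_steps=n_steps))
        while not state.completed:
            v = 2.0 * state.current_magnitude / duration
            right = rng.random() < ndtr((v - mu) / sigma)
            xs.append(v)
            ys.append(1.0 if right else 0.0)
            state = update(state, Response.RIGHT if right else Response.LEFT)
    return np.asarray(xs), np.asarray(ys)


def grid_search_mle(x, y, n_grid=200, sigma_min=0.02):
    """Exhaustive lattice search for the (mu, sigma) MLE — oracle for the
    optimizer.  Returns (mu, sigma, cell_mu, cell_sigma)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    span = x.max() - x.min()
    mus = np.linspace(x.min() - 1.0, x.max() + 1.0, n_grid)
    sigmas = np.linspace(sigma_min, 2.0 * span, n_grid)
    z = (x[None, None, :] - mus[:, None, None]) / sigmas[None, :, None]
    p = np.clip(ndtr(z), 1e-12, 1 - 1e-12)
    nll = -(y * np.log(p) + (1 - y) * np.log(1 - p)).sum(axis=2)
    i, j = np.unravel_index(np.argmin(nll), nll.shape)
    return mus[i], sigmas[j], mus[1] - mus[0], sigmas[1] - sigmas[0]


@pytest.fixture
def rng():
    return np.random.default_rng(20250921)
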