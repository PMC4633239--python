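"""Cumulative-Gaussian psychometric fitting, bootstrap resampling, comparison.

The psychometric model for a 2AFC direction task is

    P(RIGHT | v) = lapse/2 + (1 - lapse) * Phi((v - mu) / sigma)

with ``mu`` the point of subjective equality (PSE) and ``sigma`` the
psychometric width (threshold).  ``mu`` and ``sigma`` are estimated by
maximum likelihood with a bounded multi-start quasi-Newton optimizer; the
lapse rate is fixed, not fitted (default 0, the conventional choice for this design).

Sampling variability of the PSE is quantified by a nonparametric bootstrap:
trials are resampled with replacement, refitted, and the resampled means
yield percentile confidence intervals.  Two conditions measured in the same
block are compared by the Monte Carlo difference of their resampled PSEs:
``p = 2 * min(f, 1 - f)`` where ``f`` is the fraction of paired resampled
differences at or below zero, floored at ``1/(N+1)`` so p is never exactly 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import log_ndtr, ndtr
from sklearn.base import BaseEstimator

__all__ = [
    "CumulativeGaussianPsychometric",
    "PsychometricFit",
    "ResampleDistribution",
    "ConditionComparison",
    "negative_log_likelihood",
    "fit_cdf",
    "resample",
    "compare",
]

_P_CLIP = 1e-12


def _as_xy(stimuli, responses):
    """Coerce stimuli and responses to float / {0,1} arrays (1 = RIGHT)."""
    x = np.asarray(stimuli, dtype=float).ravel()
    r = np.asarray(responses)
    if r.dtype.kind in "UOS":
        mapping = {"L": 0.0, "LEFT": 0.0, "R": 1.0, "RIGHT": 1.0, "0": 0.0, "1": 1.0}
        try:
            y = np.array([mapping[str(v).strip().upper()] for v in r.ravel()])
        except KeyError as exc:
            raise ValueError(f"unrecognised response label {exc.args[0]!r}") from None
    else:
        y = r.astype(float).ravel()
        if not np.isin(y, (0.0, 1.0)).all():
            raise ValueError("numeric responses must be 0 (LEFT) or 1 (RIGHT)")
    if x.shape != y.shape:
        raise ValueError(f"stimuli and responses differ in length: {x.shape} vs {y.shape}")
    if x.size == 0:
        raise ValueError("empty trial set")
    return x, y


def negative_log_likelihood(mu, sigma, lapse, stimuli, responses) -> float:
    """Negative log-likelihood of (mu, sigma) for binary direction responses.

    ``responses`` may be 0/1 (1 = RIGHT) or 'L'/'R' labels.
    """
    x, y = _as_xy(stimuli, responses)
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    p = lapse / 2.0 + (1.0 - lapse) * ndtr((x - mu) / sigma)
    p = np.clip(p, _P_CLIP, 1.0 - _P_CLIP)
    return float(-(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)).sum())


def _nll_and_grad(params, x, y, lapse):
    mu, sigma = params
    z = (x - mu) / sigma
    phi = np.exp(-0.5 * z * z) / np.sqrt(2.0 * np.pi)
    p = lapse / 2.0 + (1.0 - lapse) * ndtr(z)
    p = np.clip(p, _P_CLIP, 1.0 - _P_CLIP)
    nll = -(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)).sum()
    w = (p - y) / (p * (1.0 - p)) * (1.0 - lapse) * phi
    g_mu = (w * (-1.0 / sigma)).sum()
    g_sigma = (w * (-z / sigma)).sum()
    return nll, np.array([g_mu, g_sigma])


def _separating_gap(x, y):
    """(lo, hi) of the gap separating LEFT from RIGHT responses, or None.

    Perfect separation means every LEFT response sits at a stimulus strictly
    below every RIGHT response (boundaries +/- inf when a class is absent).
    """
    x_left = x[y == 0]
    x_right = x[y == 1]
    lo = x_left.max() if x_left.size else -np.inf
    hi = x_right.min() if x_right.size else np.inf
    return (lo, hi) if lo < hi else None


class CumulativeGaussianPsychometric(BaseEstimator):
    """Maximum-likelihood cumulative-Gaussian psychometric function.

    A scikit-learn style estimator: ``fit(X, y)`` takes signed stimulus
    magnitudes (1d or column vector) and binary responses (1 = RIGHT, or
    'L'/'R' labels) and estimates the PSE ``mu_`` and width ``sigma_``.

    Parameters
    ----------
    lapse : float
        Fixed lapse rate in [0, 0.5); not estimated.
    sigma_floor : float
        Lower bound on sigma (stimulus units).  Perfectly separable data
        (which would drive sigma to 0 when ``lapse == 0``) are flagged
        ``degenerate_`` and assigned the midpoint of the separating gap as
        ``mu_`` with ``sigma_ = sigma_floor``.
    n_starts : int
        Number of deterministic optimizer starts (a moment-based start plus
        perturbations); ties broken by likelihood, then smaller sigma.

    Attributes
    ----------
    mu_, sigma_ : float
        Fitted PSE and width.
    loglik_ : float
        Maximised log-likelihood.
    converged_, degenerate_ : bool
    n_trials_ : int
    """

    def __init__(self, lapse: float = 0.0, sigma_floor: float = 0.01, n_starts: int = 5):
        self.lapse = lapse
        self.sigma_floor = sigma_floor
        self.n_starts = n_starts

    def _starts(self, x, y):
        x_left = x[y == 0]
        x_right = x[y == 1]
        if x_left.size and x_right.size:
            mu0 = 0.5 * (x_left.mean() + x_right.mean())
        else:
            mu0 = x.mean()
        spread = x.std()
        sigma0 = max(spread if spread > 0 else 1.0, 10 * self.sigma_floor)
        starts = [
            (mu0, sigma0),
            (mu0 + sigma0, sigma0),
            (mu0 - sigma0, sigma0),
            (mu0, sigma0 / 4.0),
            (mu0, sigma0 * 4.0),
        ]
        return starts[: max(1, self.n_starts)]

    def fit(self, X, y, starts: Optional[Sequence] = None):
        """Fit (mu, sigma) by bounded multi-start maximum likelihood.

        ``starts`` overrides the deterministic default start list (used by
        the bootstrap fast path, which starts each refit from the base fit).
        """
        x, yy = _as_xy(X, y)
        if not 0 <= self.lapse < 0.5:
            raise ValueError(f"lapse must lie in [0, 0.5), got {self.lapse}")
        self.n_trials_ = x.size
        self.classes_ = np.array([0, 1])

        if self.lapse == 0.0:
            gap = _separating_gap(x, yy)
            if gap is not None:
                lo, hi = gap
                if np.isinf(lo) and np.isinf(hi):  # cannot happen for nonempty data
                    mu = 0.0
                elif np.isinf(lo):
                    mu = float(hi)
                elif np.isinf(hi):
                    mu = float(lo)
                else:
                    mu = float((lo + hi) / 2.0)
                self.mu_ = mu
                self.sigma_ = float(self.sigma_floor)
                self.degenerate_ = True
                self.converged_ = True
                self.loglik_ = -negative_log_likelihood(
                    self.mu_, self.sigma_, self.lapse, x, yy
                )
                return self

        span = x.max() - x.min()
        scale = span if span > 0 else max(abs(x).max(), 1.0)
        bounds = [
            (x.min() - 2.0 * scale - 1.0, x.max() + 2.0 * scale + 1.0),
            (self.sigma_floor, 20.0 * scale + 1.0),
        ]
        best = None
        for mu0, sigma0 in starts if starts is not None else self._starts(x, yy):
            sigma0 = min(max(sigma0, bounds[1][0]), bounds[1][1])
            mu0 = min(max(mu0, bounds[0][0]), bounds[0][1])
            res = minimize(
                _nll_and_grad,
                np.array([mu0, sigma0]),
                args=(x, yy, self.lapse),
                jac=True,
                method="L-BFGS-B",
                bounds=bounds,
            )
            key = (round(res.fun, 10), res.x[1])
            if best is None or key < (round(best.fun, 10), best.x[1]):
                best = res
        self.mu_ = float(best.x[0])
        self.sigma_ = float(best.x[1])
        self.loglik_ = -float(best.fun)
        self.converged_ = bool(best.success)
        self.degenerate_ = False
        return self

    def predict_proba(self, X):
        """P(LEFT), P(RIGHT) columns for signed stimulus magnitudes."""
        x = np.asarray(X, dtype=float).ravel()
        p_right = self.lapse / 2.0 + (1.0 - self.lapse) * ndtr((x - self.mu_) / self.sigma_)
        return np.column_stack([1.0 - p_right, p_right])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def result(self) -> "PsychometricFit":
        """Snapshot the fitted attributes into a :class:`PsychometricFit`."""
        return PsychometricFit(
            mu=self.mu_,
            sigma=self.sigma_,
            lapse=self.lapse,
            n_trials=self.n_trials_,
            log_likelihood=self.loglik_,
            converged=self.converged_,
            degenerate=self.degenerate_,
        )


@dataclass(frozen=True)
class PsychometricFit:
    """Fitted cumulative-Gaussian parameters and fit metadata."""

    mu: float
    sigma: float
    lapse: float
    n_trials: int
    log_likelihood: float
    converged: bool
    degenerate: bool


def fit_cdf(stimuli, responses, lapse: float = 0.0, sigma_floor: float = 0.01,
            n_starts: int = 5) -> PsychometricFit:
    """Fit a cumulative Gaussian to direction responses (thin wrapper)."""
    est = CumulativeGaussianPsychometric(lapse=lapse, sigma_floor=sigma_floor, n_starts=n_starts)
    return est.fit(stimuli, responses).result()


@dataclass(frozen=True)
class ResampleDistribution:
    """Bootstrap distribution of the PSE from resampled refits."""

    estimates: np.ndarray
    n_resamples: int
    confidence: float
    n_failed: int = 0
    n_degenerate: int = 0
    mean: float = field(init=False)
    sd: float = field(init=False)
    ci_low: float = field(init=False)
    ci_high: float = field(init=False)

    def __post_init__(self):
        est = np.asarray(self.estimates, dtype=float)
        object.__setattr__(self, "estimates", est)
        object.__setattr__(self, "mean", float(est.mean()))
        object.__setattr__(self, "sd", float(est.std(ddof=1)) if est.size > 1 else 0.0)
        alpha = (1.0 - self.confidence) / 2.0
        lo, hi = np.quantile(est, [alpha, 1.0 - alpha])
        object.__setattr__(self, "ci_low", float(lo))
        object.__setattr__(self, "ci_high", float(hi))


class ResampleError(RuntimeError):
    """Too few successful bootstrap refits."""


_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


def _batched_probit_mle(xb, yb, a0, b0, sigma_floor, max_iter=80, gtol=1e-8):
    """Probit MLE batched over bootstrap replicates by Newton's method.

    Solves the same likelihood as :class:`CumulativeGaussianPsychometric`
    with ``lapse = 0``, reparametrised as ``P(RIGHT) = Phi(a + b v)`` (so
    ``mu = -a/b``, ``sigma = 1/b``); the log-likelihood is concave in
    ``(a, b)``, making the batched Newton iteration reliable.  Rows are
    ``(B, n)`` resampled stimuli/responses.  Returns ``(mu, sigma,
    converged)`` arrays; replicates that do not converge, or whose MLE
    leaves ``sigma`` outside ``[sigma_floor, 1e6]``, are flagged for the
    caller's scalar fallback path.  Perfectly separable replicates must be
    removed by the caller beforehand.
    """
    B, n = xb.shape
    q = 2.0 * yb - 1.0  # +1 RIGHT, -1 LEFT
    a = np.full(B, a0, dtype=float)
    b = np.full(B, b0, dtype=float)
    active = np.ones(B, dtype=bool)

    def nll(a_, b_, x_, q_):
        s = q_ * (a_[:, None] + b_[:, None] * x_)
        return -log_ndtr(s).sum(axis=1)

    cur = nll(a, b, xb, q)
    for _ in range(max_iter):
        if not active.any():
            break
        ia = np.where(active)[0]
        x_, q_ = xb[ia], q[ia]
        z = a[ia][:, None] + b[ia][:, None] * x_
        s = q_ * z
        # r = phi(s) / Phi(s), computed in log space for tail stability
        r = np.exp(-0.5 * s * s - _LOG_SQRT_2PI - log_ndtr(s))
        u = q_ * r                 # dL/dz
        h = r * (s + r)            # -d2L/dz2, positive
        g0 = u.sum(axis=1)
        g1 = (u * x_).sum(axis=1)
        s0 = h.sum(axis=1)
        s1 = (h * x_).sum(axis=1)
        s2 = (h * x_ * x_).sum(axis=1)
        det = s0 * s2 - s1 * s1
        det = np.where(det <= 0, np.nan, det)
        da = (s2 * g0 - s1 * g1) / det
        db = (s0 * g1 - s1 * g0) / det
        bad = ~np.isfinite(da) | ~np.isfinite(db)
        da[bad] = 0.0
        db[bad] = 0.0

        # damped step: halve until the NLL does not increase
        step = np.ones(len(ia))
        for _ in range(25):
            a_try = a[ia] + step * da
            b_try = b[ia] + step * db
            new = nll(a_try, b_try, x_, q_)
            worse = new > cur[ia] + 1e-12
            if not worse.any():
                break
            step[worse] *= 0.5
        a[ia] = a[ia] + step * da
        b[ia] = b[ia] + step * db
        cur[ia] = nll(a[ia], b[ia], x_, q_)
        gnorm = np.maximum(np.abs(g0), np.abs(g1))
        done = (gnorm < gtol * n) | bad
        active[ia] = ~done

    with np.errstate(divide="ignore", invalid="ignore"):
        mu = -a / b
        sigma = 1.0 / b
    converged = ~active & (b > 1e-6) & (sigma >= sigma_floor) & (sigma <= 1e6)
    return mu, sigma, converged


def _separable_mu_batch(xb, yb):
    """Gap-midpoint PSE for each replicate, plus the separability mask."""
    xl = np.where(yb == 0, xb, -np.inf).max(axis=1)
    xr = np.where(yb == 1, xb, np.inf).min(axis=1)
    sep = xl < xr
    mu = np.where(
        np.isinf(xl), np.where(np.isinf(xr), 0.0, xr),
        np.where(np.isinf(xr), xl, 0.5 * (xl + xr)),
    )
    return mu, sep


def resample(stimuli, responses, n_resamples: int = 2000,
             rng: Optional[np.random.Generator] = None, *,
             lapse: float = 0.0, sigma_floor: float = 0.01,
             confidence: float = 0.95, min_success_fraction: float = 0.5) -> ResampleDistribution:
    """Nonparametric bootstrap of the PSE: resample trials, refit, collect mu.

    Each replicate draws ``n`` trials with replacement and refits; refits
    start from the base fit (plus fallback starts on failure).  Degenerate
    (perfectly separable) replicates contribute their gap-midpoint estimate
    and are counted in ``n_degenerate``; non-converged refits are dropped and
    counted in ``n_failed``.
    """
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    rng = np.random.default_rng(rng)
    x, y = _as_xy(stimuli, responses)
    n = x.size

    base = CumulativeGaussianPsychometric(lapse=lapse, sigma_floor=sigma_floor)
    base.fit(x, y)
    warm = [(base.mu_, max(base.sigma_, 2 * sigma_floor))]
    est = CumulativeGaussianPsychometric(lapse=lapse, sigma_floor=sigma_floor)

    idx = rng.integers(0, n, size=(n_resamples, n))
    estimates = []
    n_failed = 0
    n_degenerate = 0
    if lapse == 0.0:
        # batched Newton on the probit parametrisation; scalar fallback for
        # replicates the batch solver cannot certify
        xb, yb = x[idx], y[idx]
        mu_sep, sep = _separable_mu_batch(xb, yb)
        mus = np.where(sep, mu_sep, np.nan)
        n_degenerate = int(sep.sum())
        todo = ~sep
        if todo.any():
            sigma0 = max(base.sigma_, 2 * sigma_floor)
            mu_b, _, ok = _batched_probit_mle(
                xb[todo], yb[todo], a0=-base.mu_ / sigma0, b0=1.0 / sigma0,
                sigma_floor=sigma_floor,
            )
            out = np.where(ok, mu_b, np.nan)
            mus[np.where(todo)[0]] = out
        for i in np.where(np.isnan(mus))[0]:
            est.fit(x[idx[i]], y[idx[i]], starts=warm)
            if not est.converged_:
                est.fit(x[idx[i]], y[idx[i]])
            if est.converged_:
                mus[i] = est.mu_
                n_degenerate += int(est.degenerate_)
            else:
                n_failed += 1
        estimates = [m for m in mus if np.isfinite(m)]
    else:
        for row in idx:
            xb, yb = x[row], y[row]
            est.fit(xb, yb, starts=warm)
            if not est.converged_:
                est.fit(xb, yb)  # full multi-start fallback
            if not est.converged_:
                n_failed += 1
                continue
            if est.degenerate_:
                n_degenerate += 1
            estimates.append(est.mu_)

    if len(estimates) < max(1, int(min_success_fraction * n_resamples)):
        raise ResampleError(
            f"only {len(estimates)} of {n_resamples} bootstrap refits converged "
            f"({n_failed} failures)"
        )
    return ResampleDistribution(
        estimates=np.array(estimates),
        n_resamples=n_resamples,
        confidence=confidence,
        n_failed=n_failed,
        n_degenerate=n_degenerate,
    )


@dataclass(frozen=True)
class ConditionComparison:
    """Left-visual minus right-visual PSE difference with Monte Carlo p-value."""

    mu_left: float
    mu_right: float
    difference: float
    p_two_sided: float
    ci_low: float
    ci_high: float
    n_pairs: int


def compare(dist_left: ResampleDistribution, dist_right: ResampleDistribution,
            confidence: float = 0.95) -> ConditionComparison:
    """Monte Carlo comparison of two resampled PSE distributions.

    The difference is ``mean_left - mean_right``; the two-sided p-value is
    ``2 * min(f, 1-f)`` with ``f`` the fraction of index-paired resampled
    differences <= 0, floored at ``1/(N+1)``.
    """
    left = dist_left.estimates
    right = dist_right.estimates
    if left.size != right.size:
        warnings.warn(
            f"resample counts differ ({left.size} vs {right.size}); "
            "pairing by index after truncation",
            stacklevel=2,
        )
        m = min(left.size, right.size)
        left, right = left[:m], right[:m]
    diffs = left - right
    n = diffs.size
    # ties split evenly so that identical distributions give p ~ 1
    f = float((diffs < 0).mean() + 0.5 * (diffs == 0).mean())
    p = 2.0 * min(f, 1.0 - f)
    p = min(1.0, max(p, 1.0 / (n + 1)))
    alpha = (1.0 - confidence) / 2.0
    lo, hi = np.quantile(diffs, [alpha, 1.0 - alpha])
    return ConditionComparison(
        mu_left=dist_left.mean,
        mu_right=dist_right.mean,
        difference=dist_left.mean - dist_right.mean,
        p_two_sided=p,
        ci_low=float(lo),
        ci_high=float(hi),
        n_pairs=n,
    )
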