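"""Psychometric estimation of the critical switching height.

For one participant in one threat condition, the probability of selecting a
heel landing decreases with step height ``h``; the logistic model

    P(heel | h) = 1 / (1 + exp(b * (h - h_crit)))

has its 50% point at the critical switching height ``h_crit`` and steepness
``b > 0`` (units 1/m).  The fit is a Bernoulli maximum-likelihood fit with a
deterministic multi-start optimizer; the protocol's bracketing guarantees
informative data in typical runs, and the degenerate cases are handled by
the published clamping rule:

* every trial at every visited height was a toe landing -> ``h_crit`` is set
  to 0.015 m (``clamped_low``);
* every trial was a heel landing -> 0.165 m (``clamped_high``);
* an interior maximum-likelihood estimate falling outside [0.015, 0.165] m
  is clamped to the nearest bound, keeping the published codomain;
* complete separation (perfect heel below, perfect toe above, no mixed
  height) makes the likelihood improper in ``b``; the slope is capped at
  ``B_MAX`` and ``h_crit`` set to the midpoint of the bracketing heights
  (``separated``), which is the definitional 50% point.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize
from scipy.special import expit, log_expit

__all__ = ["PsychometricFit", "fit_psychometric", "heel_probability",
           "H_CLAMP_LOW", "H_CLAMP_HIGH", "B_MAX"]

H_CLAMP_LOW = 0.015  # m
H_CLAMP_HIGH = 0.165  # m
B_MAX = 2000.0  # 1/m, slope cap under complete separation
_B_MIN = 1e-2

_STATUS = ("interior", "clamped_low", "clamped_high", "separated")


@dataclass(frozen=True)
class PsychometricFit:
    """Fitted heel-probability curve for one participant x condition."""

    h_crit: float  # m
    slope: float  # 1/m
    status: str
    log_likelihood: float
    n_trials: int

    def __post_init__(self):
        if self.status not in _STATUS:
            raise ValueError(f"unknown status {self.status!r}")


def _encode(strategies: Sequence) -> np.ndarray:
    out = np.empty(len(strategies), dtype=float)
    for i, s in enumerate(strategies):
        if s in ("heel", 1, 1.0, True):
            out[i] = 1.0
        elif s in ("toe", 0, 0.0, False):
            out[i] = 0.0
        else:
            raise ValueError(f"strategy must be 'heel' or 'toe', got {s!r}")
    return out


def _nll(params: np.ndarray, uniq: np.ndarray, k_heel: np.ndarray,
         m_tot: np.ndarray, ridge: float) -> float:
    """Binomial negative log likelihood aggregated per unique height
    (aggregation makes the value independent of trial order)."""
    h_crit, b = params
    z = b * (h_crit - uniq)  # logit of P(heel)
    ll = k_heel * log_expit(z) + (m_tot - k_heel) * log_expit(-z)
    return -float(np.sum(ll)) + ridge * b * b


def fit_psychometric(
    heights: Sequence[float],
    strategies: Sequence,
    ridge: float = 1e-6,
) -> PsychometricFit:
    """Maximum-likelihood logistic fit of heel probability versus height.

    Parameters
    ----------
    heights : step height of each trial, metres.
    strategies : per-trial landing strategy, ``'heel'``/``'toe'`` (or 1/0).
    ridge : weak L2 penalty on the slope for numerical stability; set to
        0.0 for the unpenalized MLE (used by the brute-force oracle tests).
    """
    h = np.asarray(heights, dtype=float)
    if h.size == 0:
        raise ValueError("empty trial set")
    y = _encode(strategies)
    if h.size != y.size:
        raise ValueError("heights and strategies differ in length")
    n = int(h.size)

    if np.all(y == 0.0):  # toe everywhere -> switching below the grid
        return PsychometricFit(H_CLAMP_LOW, B_MAX, "clamped_low", 0.0, n)
    if np.all(y == 1.0):  # heel everywhere -> switching above the grid
        return PsychometricFit(H_CLAMP_HIGH, B_MAX, "clamped_high", 0.0, n)

    uniq = np.unique(h)
    frac = np.array([y[h == u].mean() for u in uniq])
    pure_heel = uniq[frac == 1.0]
    pure_toe = uniq[frac == 0.0]
    mixed = uniq[(frac > 0.0) & (frac < 1.0)]
    if mixed.size == 0 and pure_heel.size and pure_toe.size:
        if pure_heel.max() < pure_toe.min():
            # complete separation: likelihood increases without bound in b
            mid = 0.5 * (pure_heel.max() + pure_toe.min())
            return PsychometricFit(float(mid), B_MAX, "separated", 0.0, n)

    # deterministic multi-start: a vectorized coarse lattice over
    # (h_crit, b) seeds a single local polish from its best cell
    k_heel = np.array([y[h == u].sum() for u in uniq])
    m_tot = np.array([(h == u).sum() for u in uniq])
    h_grid = np.arange(-0.05, 0.2501, 0.0025)
    b_grid = np.geomspace(5.0, B_MAX, 41)
    z = b_grid[None, :, None] * (h_grid[:, None, None] - uniq[None, None, :])
    ll = (k_heel * log_expit(z) + (m_tot - k_heel) * log_expit(-z)).sum(axis=2)
    nll_grid = -ll + ridge * b_grid[None, :] ** 2
    i, j = np.unravel_index(np.argmin(nll_grid), nll_grid.shape)
    # polish from the best cell and from the per-slope profile optima:
    # quasi-separated data push the slope to the boundary, where the
    # optimum in h_crit is sharper than the lattice resolution
    seeds = {(int(i), int(j))}
    for jj in list(range(0, b_grid.size, 8)) + [b_grid.size - 1]:
        ii = int(np.argmin(nll_grid[:, jj]))
        # only polish profile seeds that are near-competitive
        if nll_grid[ii, jj] <= nll_grid[i, j] + 3.0:
            seeds.add((ii, jj))
    best_val = nll_grid[i, j]
    h_hat, b_hat = h_grid[i], b_grid[j]
    for ii, jj in sorted(seeds):
        res = optimize.minimize(
            _nll,
            x0=np.array([h_grid[ii], b_grid[jj]]),
            args=(uniq, k_heel, m_tot, ridge),
            method="L-BFGS-B",
            bounds=[(-0.2, 0.4), (_B_MIN, B_MAX)],
        )
        if res.fun < best_val:
            best_val = res.fun
            h_hat, b_hat = res.x
    loglik = -_nll(np.array([h_hat, b_hat]), uniq, k_heel, m_tot, 0.0)
    if h_hat < H_CLAMP_LOW:
        return PsychometricFit(H_CLAMP_LOW, float(b_hat), "clamped_low", loglik, n)
    if h_hat > H_CLAMP_HIGH:
        return PsychometricFit(H_CLAMP_HIGH, float(b_hat), "clamped_high", loglik, n)
    return PsychometricFit(float(h_hat), float(b_hat), "interior", loglik, n)


def heel_probability(fit: PsychometricFit, h: float | np.ndarray):
    """Evaluate the fitted heel-landing probability at height ``h``.

    Defined for interior and separated fits; clamped fits place the
    switching point outside the sampled grid, where the curve is not
    identified, so evaluation raises with the fit status.
    """
    if fit.status in ("clamped_low", "clamped_high"):
        raise ValueError(
            f"heel probability undefined for a {fit.status} fit: the curve "
            "is not identified beyond the sampled height range"
        )
    z = fit.slope * (fit.h_crit - np.asarray(h, dtype=float))
    out = expit(z)
    return float(out) if out.ndim == 0 else out
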