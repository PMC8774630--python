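"""Error metrics between coefficient vectors and mixture densities.

``l1_error`` is the coefficient error ``sum_j |beta_hat_j - beta*_j|``.
``tv_error`` is the total-variation error between the two mixture densities,
computed here as the *full* integral ``int |h_bhat - h_bstar|`` — without
the conventional 1/2 factor — so it ranges in [0, 2] for a pair of densities
and can exceed 1.  Continuous dictionaries use a composite trapezoid rule on
a wide grid; discrete ones sum over the integers up to a tail-mass cutoff.
``support_metrics`` scores recovery of the set of active components.

Estimated coefficient vectors are deliberately *not* renormalized to sum to
one before scoring: the metrics evaluate the raw penalized estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .solver import SUPPORT_EPS

__all__ = ["GridSpec", "l1_error", "tv_error", "support_metrics",
           "renormalize_simplex"]


def renormalize_simplex(beta) -> np.ndarray:
    """Rescale a non-negative coefficient vector to sum to one.

    Optional post-processing for reporting; the error metrics in this module
    always score the raw penalized estimator unless handed a renormalized
    vector explicitly.  An all-zero vector is returned unchanged.
    """
    beta = np.asarray(beta, dtype=float)
    s = beta.sum()
    return beta / s if s > 0 else beta.copy()


@dataclass(frozen=True)
class GridSpec:
    """Integration grid for the TV error.

    For continuous dictionaries: ``n_points`` equally spaced points on
    ``[lower, upper]``.  For discrete ones only ``tail_mass`` matters: the
    integer range is truncated where every component's upper tail mass drops
    below it.  ``lower``/``upper`` default to a data-free envelope of the
    dictionary (means +- 8 max sigma).
    """

    lower: float | None = None
    upper: float | None = None
    n_points: int = 20_001
    tail_mass: float = 1e-10

    def __post_init__(self) -> None:
        if self.lower is not None and self.upper is not None \
                and not self.lower < self.upper:
            raise ValueError("need lower < upper")
        if self.n_points < 1001:
            raise ValueError("n_points must be at least 1001")
        if self.tail_mass > 1e-10:
            raise ValueError("tail_mass must be <= 1e-10")


def l1_error(beta_hat, beta_star) -> float:
    """Coefficient error ``sum_j |beta_hat_j - beta*_j|``."""
    beta_hat = np.asarray(beta_hat, dtype=float)
    beta_star = np.asarray(beta_star, dtype=float)
    if beta_hat.shape != beta_star.shape:
        raise ValueError("coefficient vectors must have equal length")
    return float(np.abs(beta_hat - beta_star).sum())


def _continuous_bounds(dictionary, grid: GridSpec) -> tuple[float, float]:
    means = np.array([c.params["a"] for c in dictionary.components])
    sig = np.array([c.params["sigma"] for c in dictionary.components])
    lo = grid.lower if grid.lower is not None else float(means.min() - 8.0 * sig.max())
    hi = grid.upper if grid.upper is not None else float(means.max() + 8.0 * sig.max())
    # widen until the grid covers essentially all of every component's mass
    span = hi - lo
    while (stats.norm.cdf(lo, means, sig).max()
           + stats.norm.sf(hi, means, sig).max()) > 1e-8:
        lo -= 0.25 * span
        hi += 0.25 * span
    return lo, hi


def tv_error(dictionary, beta_hat, beta_star,
             grid: GridSpec | None = None) -> float:
    """Total-variation error ``int |h_bhat - h_bstar|`` (no 1/2 factor)."""
    grid = grid or GridSpec()
    beta_hat = np.asarray(beta_hat, dtype=float)
    beta_star = np.asarray(beta_star, dtype=float)
    dbeta = beta_hat - beta_star
    if dictionary.discrete:
        kmax = max(c._tail_cutoff(grid.tail_mass)
                   for c in dictionary.components) + 10
        H = dictionary.evaluate(np.arange(kmax + 1))
        return float(np.abs(H @ dbeta).sum())
    lo, hi = _continuous_bounds(dictionary, grid)
    xs = np.linspace(lo, hi, grid.n_points)
    H = dictionary.evaluate(xs)
    return float(np.trapezoid(np.abs(H @ dbeta), xs))


def tv_error_precomputed(H: np.ndarray, xs: np.ndarray | None,
                         beta_hat, beta_star) -> float:
    """TV error from a precomputed evaluation matrix ``H[i, j] = h_j(x_i)``.

    ``xs=None`` means a discrete grid (plain sum instead of trapezoid);
    used by the replication harness to amortize dictionary evaluation.
    """
    diff = np.abs(H @ (np.asarray(beta_hat, float) - np.asarray(beta_star, float)))
    if xs is None:
        return float(diff.sum())
    return float(np.trapezoid(diff, xs))


def support_metrics(beta_hat, beta_star) -> dict:
    """Support-recovery scores of ``I_hat = {j : beta_hat_j > eps}``.

    Precision/recall use the convention that an empty estimated (or true)
    support scores 1 only against an equally empty counterpart, else 0.
    """
    beta_hat = np.asarray(beta_hat, dtype=float)
    beta_star = np.asarray(beta_star, dtype=float)
    if beta_hat.shape != beta_star.shape:
        raise ValueError("coefficient vectors must have equal length")
    I_hat = set(np.flatnonzero(beta_hat > SUPPORT_EPS).tolist())
    I_star = set(np.flatnonzero(np.abs(beta_star) > SUPPORT_EPS).tolist())
    inter = len(I_hat & I_star)
    if I_hat:
        precision = inter / len(I_hat)
    else:
        precision = 1.0 if not I_star else 0.0
    if I_star:
        recall = inter / len(I_star)
    else:
        recall = 1.0 if not I_hat else 0.0
    return {"exact_recovery": I_hat == I_star,
            "precision": precision, "recall": recall}
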