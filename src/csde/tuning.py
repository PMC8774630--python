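"""Tuning-parameter selection by random-dichotomy cross-validation.

The sample is split once (seeded) into two random halves and the estimator
is fitted on each half.  Two discrepancy criteria are available:

``distance``
    squared L2 distance between the two fitted densities,
    ``(b1 - b2)' Psi (b1 - b2)`` — stability of the fit across the split.
``heldout``
    symmetrized held-out empirical L2 risk,
    ``loss(b1; X2) + loss(b2; X1)`` with
    ``loss(b; X) = -2/n sum_i h_b(x_i) + ||h_b||^2`` — the unpenalized loss
    the estimator itself minimizes, evaluated out of sample (default).

The pair ``(lam1, c)`` is then chosen by nested coordinate search over the
two grids: alternately minimize the criterion over ``lam1`` with ``c`` held
fixed and vice versa, until the criterion improves by less than the search
precision ``xi`` between outer rounds.  Ties break toward larger ``lam1``
(sparser fits).  Penalty levels at which the full-sample fit is identically
zero are excluded: an estimator that keeps no component estimates nothing,
yet the distance criterion would score it perfectly stable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .solver import EmpiricalMoments, effective_ridge, fit, fit_density
from .weights import PenaltySpec, compute_weights

__all__ = ["TuningConfig", "cv_criterion", "nested_search"]


@dataclass(frozen=True)
class TuningConfig:
    """Grids and controls for the nested (lam1, c) search."""

    lam1_grid: tuple = (0.0,)
    c_grid: tuple = (0.0,)
    xi: float = 0.001
    n_splits: int = 1
    seed: int = 0
    max_rounds: int = 20
    criterion: str = "heldout"  # or "distance"
    exclude_empty: bool = True

    def __post_init__(self) -> None:
        for name, grid in (("lam1_grid", self.lam1_grid), ("c_grid", self.c_grid)):
            g = np.asarray(grid, dtype=float)
            if g.size == 0 or np.any(g < 0) or np.any(np.diff(g) < 0):
                raise ValueError(f"{name} must be non-empty, non-negative, sorted")
        if self.xi <= 0:
            raise ValueError("search precision xi must be positive")
        if self.n_splits < 1:
            raise ValueError("need at least one dichotomy")
        if self.criterion not in ("distance", "heldout"):
            raise ValueError("criterion must be 'distance' or 'heldout'")


def _heldout_loss(beta: np.ndarray, moments: EmpiricalMoments,
                  gram: np.ndarray) -> float:
    """Unpenalized empirical L2 risk of ``h_beta`` on held-out moments."""
    return float(-2.0 * moments.b @ beta + beta @ gram @ beta)


def cv_criterion(samples, dictionary, spec: PenaltySpec, seed: int = 0,
                 n_splits: int = 1, criterion: str = "distance",
                 tol: float = 1e-5, max_iter: int = 2000) -> float:
    """Random-dichotomy cross-validation criterion for one penalty spec.

    Splits the sample into two seeded halves, fits on each and scores the
    discrepancy (see module docstring); with ``n_splits > 1`` the mean over
    independent dichotomies is returned.
    """
    samples = np.asarray(samples, dtype=float)
    n = samples.size
    if n < 4:
        raise ValueError("need at least 4 samples for a dichotomy")
    gram = dictionary.gram
    L = dictionary.sup_norms
    rng = np.random.default_rng(seed)
    vals = []
    for _ in range(n_splits):
        perm = rng.permutation(n)
        half = n // 2
        parts = [samples[perm[:half]], samples[perm[half:]]]
        moments = [EmpiricalMoments.from_samples(dictionary, p) for p in parts]
        betas = []
        for m in moments:
            wv = compute_weights(spec, L, dictionary.W, m.n)
            betas.append(fit(m, gram, wv, effective_ridge(spec), tol=tol,
                             max_iter=max_iter).beta_hat)
        if criterion == "distance":
            d = betas[0] - betas[1]
            vals.append(float(d @ gram @ d))
        else:
            vals.append(_heldout_loss(betas[0], moments[1], gram)
                        + _heldout_loss(betas[1], moments[0], gram))
    return float(np.mean(vals))


def _evaluate(samples, dictionary, spec, config, cache):
    key = (spec.lam1, spec.c)
    if key in cache:
        return cache[key]
    val = cv_criterion(samples, dictionary, spec, seed=config.seed,
                       n_splits=config.n_splits, criterion=config.criterion)
    if config.exclude_empty:
        full = fit_density(samples, dictionary, spec, tol=1e-5, max_iter=2000)
        if full.support.size == 0:
            val = np.inf
    cache[key] = val
    return val


def nested_search(samples, dictionary, config: TuningConfig,
                  spec: PenaltySpec | None = None):
    """Select ``(lam1, c)`` by alternating 1-d grid minimization.

    ``spec`` provides the weight mode (defaults to the corrected estimator
    with printed-scale weights); its ``lam1``/``c`` fields are overwritten
    by the search.  Returns ``(best_spec, trace)`` where ``trace`` is a
    DataFrame of every (round, lam1, c, criterion) evaluation.
    """
    base = spec or PenaltySpec(mode="csde", weight_scale_mode="fixed_lam1")
    cache: dict = {}
    rows = []

    lam1 = float(config.lam1_grid[len(config.lam1_grid) // 2])
    c = float(config.c_grid[0])
    best = _evaluate(samples, dictionary, replace(base, lam1=lam1, c=c),
                     config, cache)
    rows.append((0, lam1, c, best))

    converged = False
    for rnd in range(1, config.max_rounds + 1):
        prev_best = best
        # minimize over lam1 at fixed c; ties -> larger lam1
        for cand in config.lam1_grid:
            val = _evaluate(samples, dictionary,
                            replace(base, lam1=float(cand), c=c), config, cache)
            rows.append((rnd, float(cand), c, val))
            if val < best or (val == best and cand > lam1):
                best, lam1 = val, float(cand)
        # minimize over c at fixed lam1
        for cand in config.c_grid:
            val = _evaluate(samples, dictionary,
                            replace(base, lam1=lam1, c=float(cand)), config, cache)
            rows.append((rnd, lam1, float(cand), val))
            if val < best:
                best, c = val, float(cand)
        if prev_best - best < config.xi:
            converged = True
            break

    trace = pd.DataFrame(rows, columns=["round", "lam1", "c", "criterion"])
    trace.attrs["converged"] = converged
    if not np.isfinite(best):
        # every candidate collapsed to the empty fit; fall back to the
        # smallest penalty on the grid
        lam1, c = float(config.lam1_grid[0]), float(config.c_grid[0])
    return replace(base, lam1=lam1, c=c), trace
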