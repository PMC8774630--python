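"""EM baseline for mixture weights with fixed, known components.

Only the mixing proportions are estimated; component densities stay fixed.
E-step responsibilities and M-step:

    w_ij = p_j h_j(x_i) / sum_s p_s h_s(x_i),
    p_j <- (1/n) sum_i w_ij,

iterated until the largest weight change falls below the cessation level.
The observed-data log-likelihood is non-decreasing along the iterations and
the weight vector stays on the probability simplex.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

__all__ = ["EMConfig", "EMResult", "em_fit"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EMConfig:
    """EM settings: cessation level ``xi``, iteration cap, initial weights."""

    xi: float = 1e-4
    max_iter: int = 10_000
    init: np.ndarray | None = None  # default: equal weights 1/W

    def __post_init__(self) -> None:
        if self.xi <= 0:
            raise ValueError("cessation level xi must be positive")
        if self.init is not None:
            init = np.asarray(self.init, dtype=float)
            if np.any(init < 0) or abs(init.sum() - 1.0) > 1e-10:
                raise ValueError("init must lie on the probability simplex")


@dataclass
class EMResult:
    weights: np.ndarray
    loglik_trace: np.ndarray
    n_iter: int
    converged: bool
    warnings: list = field(default_factory=list)


def em_fit(samples, dictionary, config: EMConfig | None = None) -> EMResult:
    """Estimate mixture weights by EM with fixed component densities."""
    config = config or EMConfig()
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 1 or samples.size == 0:
        raise ValueError("samples must be a non-empty 1-d array")
    H = dictionary.evaluate(samples)          # (n, W)
    n, W = H.shape
    p = (np.full(W, 1.0 / W) if config.init is None
         else np.asarray(config.init, dtype=float).copy())

    warns: list[str] = []
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        mix = H @ p                            # (n,)
        dead = mix <= 0.0
        if np.any(dead):
            msg = (f"{int(dead.sum())} sample(s) have zero density under "
                   "every weighted component; uniform responsibilities used")
            if not warns:
                logger.warning(msg)
            warns.append(msg)
        resp = np.where(dead[:, None], 1.0 / W,
                        H * p[None, :] / np.where(mix, mix, 1.0)[:, None])
        trace.append(float(np.log(np.where(dead, 1.0, mix)).sum()))
        p_new = resp.sum(axis=0) / n
        p_new /= p_new.sum()                   # guard round-off off-simplex
        delta = float(np.max(np.abs(p_new - p)))
        p = p_new
        if delta < config.xi:
            converged = True
            break
    if not converged:
        logger.warning("EM hit max_iter=%d without reaching xi=%g",
                       config.max_iter, config.xi)
    return EMResult(weights=p, loglik_trace=np.asarray(trace), n_iter=it,
                    converged=converged, warnings=warns)
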