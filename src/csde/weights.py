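"""Data-dependent penalty weights.

The weighted l1 penalty uses per-component levels ``omega_k`` calibrated so
that the first-order (KKT) conditions of the penalized fit hold with high
probability.  McDiarmid's bounded-differences inequality applied to the
empirical moment ``(1/n) sum_i h_k(X_i)`` gives, for confidence ``delta``,

    omega_k = 2 sqrt(2) L_k v(delta/2) + c B,
    v(delta) = sqrt(log(W / delta) / n),

where ``L_k = ||h_k||_inf``, ``c`` is the ridge (measurement-error) tuning
parameter and ``B`` bounds ``max_j |beta*_j|`` (1 for mixture weights).  The
shifted weights ``omega~_k = omega_k - cB`` are the pure concentration part:
the event ``|b_k - E b_k| <= omega~_k`` holds with probability at least
``1 - 2 exp(-n omega~_k^2 / (8 L_k^2))``.

Besides the confidence-driven scaling, a ``fixed_lam1`` mode substitutes a
user-supplied scale ``lam1`` for ``v(delta/2)`` so that a printed pair
``(lam1, c)`` fully determines the weights; ``spades`` reproduces the
un-shifted weighted-l1-only scheme ``4 L_k lam1``; ``uniform`` is a plain
(Lasso/Elastic-net) constant penalty.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["PenaltySpec", "WeightVector", "v_of", "compute_weights"]

_MODES = ("uniform", "spades", "csde")
_SCALE_MODES = ("delta", "fixed_lam1")


@dataclass(frozen=True)
class PenaltySpec:
    """Penalty configuration for one fit.

    Parameters
    ----------
    lam1
        Global l1 scale.  Ignored in ``csde`` mode with
        ``weight_scale_mode="delta"``, where ``v(delta/2)`` takes its place.
    c
        Ridge parameter (the measurement-error correction); 0 disables it.
    delta
        Confidence level for the concentration weights.
    B
        Bound on ``max_j |beta*_j]``; 1 for simplex mixture weights.
    mode
        ``"uniform"`` | ``"spades"`` | ``"csde"``.
    weight_scale_mode
        ``"delta"`` (theory-faithful) or ``"fixed_lam1"``.
    """

    lam1: float = 0.0
    c: float = 0.0
    delta: float = 0.1
    B: float = 1.0
    mode: str = "csde"
    weight_scale_mode: str = "delta"

    def __post_init__(self) -> None:
        if self.lam1 < 0 or self.c < 0 or self.B <= 0:
            raise ValueError("need lam1 >= 0, c >= 0, B > 0")
        if not (0.0 < self.delta < 1.0):
            raise ValueError(f"delta must lie in (0, 1), got {self.delta}")
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}")
        if self.weight_scale_mode not in _SCALE_MODES:
            raise ValueError(f"weight_scale_mode must be one of {_SCALE_MODES}")

    def to_config(self) -> dict:
        return {"lam1": self.lam1, "c": self.c, "delta": self.delta,
                "B": self.B, "mode": self.mode,
                "weight_scale_mode": self.weight_scale_mode}

    @classmethod
    def from_config(cls, cfg: dict) -> "PenaltySpec":
        return cls(**cfg)


@dataclass(frozen=True)
class WeightVector:
    """Penalty weights ``omega`` and their shifted version ``omega - cB``."""

    omega: np.ndarray
    omega_tilde: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.omega_tilde < -1e-15):
            raise ValueError("shifted weights must be non-negative")


def v_of(delta: float, W: int, n: int) -> float:
    """Concentration scale ``v(delta) = sqrt(log(W / delta) / n)``."""
    if n < 1 or W < 1:
        raise ValueError("need n >= 1 and W >= 1")
    if not 0.0 < delta < 1.0:
        raise ValueError(f"delta must lie in (0, 1), got {delta}")
    ratio = W / delta
    if ratio <= 1.0:
        raise ValueError(f"W/delta must exceed 1, got {ratio}")
    return math.sqrt(math.log(ratio) / n)


def compute_weights(spec: PenaltySpec, L: np.ndarray, W: int | None = None,
                    n: int | None = None) -> WeightVector:
    """Penalty weights for a dictionary with sup-norms ``L``.

    csde / delta mode:       omega_k = 2 sqrt(2) L_k v(delta/2) + c B
    csde / fixed_lam1 mode:  omega_k = 2 sqrt(2) L_k lam1 + c B
    spades:                  omega_k = 4 L_k lam1 (no shift; c not in weights)
    uniform:                 omega_k = lam1
    """
    L = np.asarray(L, dtype=float)
    if np.any(L <= 0) or not np.all(np.isfinite(L)):
        raise ValueError("sup-norms must be strictly positive and finite")
    W = L.size if W is None else int(W)

    if spec.mode == "uniform":
        omega = np.full(W, spec.lam1, dtype=float)
        return WeightVector(omega=omega, omega_tilde=omega.copy())
    if spec.mode == "spades":
        omega = 4.0 * L * spec.lam1
        return WeightVector(omega=omega, omega_tilde=omega.copy())

    shift = spec.c * spec.B
    if spec.weight_scale_mode == "delta":
        if n is None:
            raise ValueError("delta-mode weights require the sample size n")
        scale = v_of(spec.delta / 2.0, W, n)
    else:
        scale = spec.lam1
    omega_tilde = 2.0 * math.sqrt(2.0) * L * scale
    return WeightVector(omega=omega_tilde + shift, omega_tilde=omega_tilde)
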