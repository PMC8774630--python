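"""Dictionaries of base densities.

The estimation target is an unknown density written as a finite mixture

    h(z) = sum_j beta*_j h_j(z),    sum_j beta*_j = 1,  beta*_j >= 0,

where the ``h_j`` are *known* probability densities (the dictionary).  This
module represents such a family: evaluation of every component at a point,
analytic sup-norms ``L_j = ||h_j||_inf``, L2 norms, and the Gram matrix
``Psi[i, j] = <h_i, h_j>`` of pairwise L2 inner products (an integral for
continuous families, a sum over the integers for discrete ones).

Gaussian and Poisson families get closed-form / series Gram entries; any
other univariate density can be wrapped as a ``custom`` component, whose
inner products fall back to adaptive quadrature.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import integrate, stats

__all__ = ["BaseDensity", "Dictionary"]

_SQRT_2PI = math.sqrt(2.0 * math.pi)

#: families whose support is the non-negative integers
_DISCRETE_FAMILIES = frozenset({"poisson", "negbin"})


@dataclass(frozen=True)
class BaseDensity:
    """A single dictionary component.

    Parameters
    ----------
    family
        ``"gaussian"`` (params: mean ``a``, scale ``sigma > 0``),
        ``"poisson"`` (params: rate ``lam > 0``) or ``"custom"``
        (params: a pdf callable plus optional support bounds).
    params
        Family-specific parameter mapping.
    """

    family: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family == "gaussian":
            sigma = float(self.params["sigma"])
            if not (sigma > 0 and math.isfinite(sigma)):
                raise ValueError(f"gaussian scale must be positive, got {sigma}")
        elif self.family == "poisson":
            lam = float(self.params["lam"])
            if not (lam > 0 and math.isfinite(lam)):
                raise ValueError(f"poisson rate must be positive, got {lam}")
        elif self.family == "negbin":
            lam, r = float(self.params["lam"]), float(self.params["r"])
            if not (lam > 0 and r > 0 and math.isfinite(lam) and math.isfinite(r)):
                raise ValueError("negbin needs mean lam > 0 and dispersion r > 0")
        elif self.family == "custom":
            if not callable(self.params.get("pdf")):
                raise ValueError("custom component requires a 'pdf' callable")
        else:
            raise ValueError(f"unknown family {self.family!r}")

    @property
    def discrete(self) -> bool:
        return self.family in _DISCRETE_FAMILIES

    def pdf(self, x) -> np.ndarray:
        """Density (or pmf) at ``x``; vectorized."""
        x = np.asarray(x, dtype=float)
        if self.family == "gaussian":
            a, s = float(self.params["a"]), float(self.params["sigma"])
            z = (x - a) / s
            return np.exp(-0.5 * z * z) / (s * _SQRT_2PI)
        if self.family in ("poisson", "negbin"):
            if np.any(x != np.floor(x)) or np.any(x < 0):
                raise ValueError("discrete component evaluated at a "
                                 "non-integer or negative point")
            k = x.astype(np.int64)
            if self.family == "poisson":
                return stats.poisson.pmf(k, float(self.params["lam"]))
            lam, r = float(self.params["lam"]), float(self.params["r"])
            return stats.nbinom.pmf(k, r, r / (r + lam))
        out = np.asarray(self.params["pdf"](x), dtype=float)
        return out

    def sup_norm(self) -> float:
        """Analytic sup-norm ``L = ||h||_inf``.

        Gaussian: ``1 / (sigma sqrt(2 pi))``.  Poisson: the pmf maximized
        over its (unimodal) support, i.e. at ``floor(lam)`` and ``lam - 1``
        when ``lam`` is an integer.  Custom: numeric maximum over a dense
        grid of the declared support.
        """
        if self.family == "gaussian":
            return 1.0 / (float(self.params["sigma"]) * _SQRT_2PI)
        if self.family == "poisson":
            lam = float(self.params["lam"])
            k_mode = int(math.floor(lam))
            cands = [k_mode]
            if lam == k_mode and k_mode >= 1:
                cands.append(k_mode - 1)
            return float(max(stats.poisson.pmf(k, lam) for k in cands))
        if self.family == "negbin":
            ks = np.arange(int(self._tail_cutoff(1e-14)) + 1)
            return float(self.pdf(ks).max())
        lo, hi = self._support()
        grid = np.linspace(lo, hi, 20001)
        return float(np.max(self.pdf(grid)))

    def _tail_cutoff(self, tail: float) -> int:
        """Smallest k with upper tail mass below ``tail`` (discrete only)."""
        if self.family == "poisson":
            return int(stats.poisson.ppf(1.0 - tail, float(self.params["lam"])))
        if self.family == "negbin":
            lam, r = float(self.params["lam"]), float(self.params["r"])
            return int(stats.nbinom.ppf(1.0 - tail, r, r / (r + lam)))
        raise ValueError("tail cutoff applies to discrete families only")

    def _support(self) -> tuple[float, float]:
        """Effective support bounds (continuous families)."""
        if self.family == "gaussian":
            a, s = float(self.params["a"]), float(self.params["sigma"])
            return a - 10.0 * s, a + 10.0 * s
        if self.family == "custom":
            return (float(self.params.get("lower", -50.0)),
                    float(self.params.get("upper", 50.0)))
        raise ValueError("discrete component has integer support")

    def total_mass(self) -> float:
        """Integral / sum of the density over its support (should be 1)."""
        if self.discrete:
            kmax = self._tail_cutoff(1e-14) + 5
            return float(self.pdf(np.arange(kmax + 1)).sum())
        lo, hi = self._support()
        val, _ = integrate.quad(lambda t: float(self.pdf(t)), lo, hi, limit=200)
        return float(val)

    # -- serialization ----------------------------------------------------
    def to_config(self) -> dict:
        if self.family == "custom":
            raise ValueError("custom components are not serializable")
        return {"family": self.family,
                "params": {k: float(v) for k, v in self.params.items()}}


def _gaussian_gram(means: np.ndarray, sigmas: np.ndarray) -> np.ndarray:
    """Closed-form Gram of Gaussian densities.

    ``<phi(.|a_i, s_i), phi(.|a_j, s_j)>`` is the value at 0 of the density
    of the difference of the two independent Gaussians:
    ``exp(-(a_i - a_j)^2 / (2 (s_i^2 + s_j^2))) / sqrt(2 pi (s_i^2 + s_j^2))``.
    """
    da = means[:, None] - means[None, :]
    v = sigmas[:, None] ** 2 + sigmas[None, :] ** 2
    return np.exp(-(da * da) / (2.0 * v)) / np.sqrt(2.0 * math.pi * v)


def _discrete_gram(components, tail: float = 1e-12) -> np.ndarray:
    """Series Gram of discrete pmfs, truncated where every tail mass < tail."""
    kmax = max(c._tail_cutoff(tail) for c in components) + 10
    ks = np.arange(kmax + 1)
    P = np.vstack([c.pdf(ks) for c in components])   # (W, K)
    return P @ P.T


class Dictionary:
    """Ordered family ``{h_j}_{j=1..W}`` of same-family base densities.

    Carries lazily computed sup-norms ``L_j``, L2 norms and the Gram matrix
    ``Psi`` of pairwise inner products.  Optional per-component positive
    ``scales`` support normalized views (``h_j / ||h_j||``) without touching
    the underlying components.
    """

    def __init__(self, components: Sequence[BaseDensity],
                 scales: np.ndarray | None = None) -> None:
        components = list(components)
        if not components:
            raise ValueError("dictionary needs at least one component")
        fam0 = components[0].family
        if any(c.family != fam0 for c in components):
            raise ValueError("all components must share one family")
        self.components: list[BaseDensity] = components
        self._scales = (np.ones(len(components)) if scales is None
                        else np.asarray(scales, dtype=float))
        if np.any(self._scales <= 0):
            raise ValueError("component scales must be strictly positive")
        self._gram: np.ndarray | None = None
        self._sup: np.ndarray | None = None

    # -- constructors -----------------------------------------------------
    @classmethod
    def gaussian(cls, means: Sequence[float], sigmas: Sequence[float]) -> "Dictionary":
        means = np.asarray(means, dtype=float)
        sigmas = np.asarray(sigmas, dtype=float)
        if means.shape != sigmas.shape:
            raise ValueError("means and sigmas must have equal length")
        return cls([BaseDensity("gaussian", {"a": a, "sigma": s})
                    for a, s in zip(means, sigmas)])

    @classmethod
    def poisson(cls, rates: Sequence[float]) -> "Dictionary":
        return cls([BaseDensity("poisson", {"lam": float(l)}) for l in rates])

    @classmethod
    def negbin(cls, means: Sequence[float], r: float) -> "Dictionary":
        """Negative binomials with means ``lam_j`` and common dispersion
        ``r`` (variance ``lam + lam^2 / r``)."""
        return cls([BaseDensity("negbin", {"lam": float(l), "r": float(r)})
                    for l in means])

    @classmethod
    def custom(cls, pdfs: Sequence[Callable], lower: float = -50.0,
               upper: float = 50.0) -> "Dictionary":
        return cls([BaseDensity("custom", {"pdf": f, "lower": lower, "upper": upper})
                    for f in pdfs])

    # -- basic properties -------------------------------------------------
    def __len__(self) -> int:
        return len(self.components)

    @property
    def W(self) -> int:
        return len(self.components)

    @property
    def family(self) -> str:
        return self.components[0].family

    @property
    def discrete(self) -> bool:
        return self.components[0].discrete

    @property
    def sup_norms(self) -> np.ndarray:
        """Vector of ``L_j = ||h_j||_inf`` (scaled view included)."""
        if self._sup is None:
            self._sup = np.array([c.sup_norm() for c in self.components])
        return self._sup * self._scales

    @property
    def gram(self) -> np.ndarray:
        """Gram matrix ``Psi[i, j] = <h_i, h_j>``."""
        if self._gram is None:
            self._gram = self._compute_gram()
        S = self._scales
        return self._gram * np.outer(S, S)

    @property
    def norms(self) -> np.ndarray:
        """L2 norms ``||h_j|| = sqrt(Psi_jj)``."""
        return np.sqrt(np.diag(self.gram))

    def _compute_gram(self) -> np.ndarray:
        if self.family == "gaussian":
            means = np.array([c.params["a"] for c in self.components], dtype=float)
            sigmas = np.array([c.params["sigma"] for c in self.components], dtype=float)
            return _gaussian_gram(means, sigmas)
        if self.discrete:
            return _discrete_gram(self.components)
        return self._quadrature_gram()

    def _quadrature_gram(self) -> np.ndarray:
        W = self.W
        G = np.empty((W, W))
        for i in range(W):
            for j in range(i, W):
                ci, cj = self.components[i], self.components[j]
                lo = min(ci._support()[0], cj._support()[0])
                hi = max(ci._support()[1], cj._support()[1])
                val, err = integrate.quad(
                    lambda t: float(ci.pdf(t)) * float(cj.pdf(t)), lo, hi,
                    limit=400)
                if not math.isfinite(val) or err > 1e-6:
                    raise ArithmeticError(
                        f"quadrature for Gram entry ({i},{j}) did not "
                        f"converge (value={val}, abserr={err})")
                G[i, j] = G[j, i] = val
        return G

    # -- evaluation -------------------------------------------------------
    def evaluate(self, x) -> np.ndarray:
        """Evaluate every component at ``x``.

        Returns shape ``(W,)`` for scalar ``x`` and ``(len(x), W)`` for a
        vector.  Discrete families reject non-integer points.
        """
        x = np.asarray(x, dtype=float)
        scalar = x.ndim == 0
        xv = np.atleast_1d(x)
        if self.discrete and (np.any(xv != np.floor(xv)) or np.any(xv < 0)):
            raise ValueError("discrete dictionary evaluated at non-integer "
                             "or negative points")
        if self.family == "gaussian":
            a = np.array([c.params["a"] for c in self.components])
            s = np.array([c.params["sigma"] for c in self.components])
            z = (xv[:, None] - a[None, :]) / s[None, :]
            H = np.exp(-0.5 * z * z) / (s[None, :] * _SQRT_2PI)
        elif self.family == "poisson":
            lams = np.array([c.params["lam"] for c in self.components])
            H = stats.poisson.pmf(xv.astype(np.int64)[:, None], lams[None, :])
        elif self.family == "negbin":
            lams = np.array([c.params["lam"] for c in self.components])
            rs = np.array([c.params["r"] for c in self.components])
            H = stats.nbinom.pmf(xv.astype(np.int64)[:, None], rs[None, :],
                                 (rs / (rs + lams))[None, :])
        else:
            H = np.column_stack([c.pdf(xv) for c in self.components])
        H = H * self._scales[None, :]
        return H[0] if scalar else H

    def mixture_pdf(self, x, beta) -> np.ndarray:
        """Mixture density ``h_beta(x) = sum_j beta_j h_j(x)``."""
        beta = np.asarray(beta, dtype=float)
        H = self.evaluate(np.atleast_1d(x))
        out = H @ beta
        return float(out[0]) if np.ndim(x) == 0 else out

    # -- normalization ----------------------------------------------------
    def normalize(self) -> "Dictionary":
        """View with every component divided by its L2 norm.

        The Gram of the result has unit diagonal; idempotent.
        """
        norms = self.norms
        if np.any(norms <= 0):
            raise ValueError("cannot normalize a zero-norm component")
        d = Dictionary(self.components, scales=self._scales / norms)
        d._gram = self._gram
        d._sup = self._sup
        return d

    # -- serialization ----------------------------------------------------
    def to_config(self) -> dict:
        return {"family": self.family,
                "components": [c.to_config()["params"] for c in self.components],
                "scales": self._scales.tolist()}

    @classmethod
    def from_config(cls, cfg: dict) -> "Dictionary":
        fam = cfg["family"]
        comps = [BaseDensity(fam, dict(p)) for p in cfg["components"]]
        scales = np.asarray(cfg.get("scales", np.ones(len(comps))), dtype=float)
        return cls(comps, scales=scales)

    def to_json(self) -> str:
        return json.dumps(self.to_config())

    @classmethod
    def from_json(cls, s: str) -> "Dictionary":
        return cls.from_config(json.loads(s))
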