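"""Model/results interface over the penalized density fit.

:class:`SparseDensityModel` bundles a univariate sample with a dictionary
of base densities; ``fit`` runs the penalized minimal-L2-distance estimator
(weighted l1 + ridge, non-negative by default), ``fit_em`` runs the EM
baseline for the mixture weights and ``fit_cv`` tunes ``(lam1, c)`` by
random-dichotomy cross-validation first.  All return a
:class:`SparseDensityResults` carrying the coefficients, active support,
first-order (KKT) residuals, coherence/eigenvalue diagnostics of the
dictionary and a printable ``summary()``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dictionary import Dictionary
from .em import EMConfig, em_fit
from .solver import (EmpiricalMoments, FitResult, diagnostics, effective_ridge,
                     fit, fit_density)
from .tuning import TuningConfig, nested_search
from .weights import PenaltySpec, compute_weights

__all__ = ["SparseDensityModel", "SparseDensityResults"]


class SparseDensityModel:
    """Sparse mixture-weight estimation for a univariate sample.

    Parameters
    ----------
    samples
        Observed (possibly error-contaminated) univariate data.
    dictionary
        Known base densities whose mixture models the clean density.
    """

    def __init__(self, samples, dictionary: Dictionary) -> None:
        samples = np.asarray(samples, dtype=float)
        if samples.ndim != 1 or samples.size == 0:
            raise ValueError("samples must be a non-empty 1-d array")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples contain NaN or infinity")
        if dictionary.discrete and np.any(samples != np.floor(samples)):
            raise ValueError("discrete dictionary with non-integer samples")
        self.samples = samples
        self.dictionary = dictionary
        self.nobs = samples.size

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, column: str,
                       dictionary: Dictionary) -> "SparseDensityModel":
        return cls(df[column].to_numpy(dtype=float), dictionary)

    def fit(self, penalty: PenaltySpec | None = None, *, lam1: float = 0.0,
            c: float = 0.0, mode: str = "csde",
            weight_scale_mode: str = "fixed_lam1", delta: float = 0.1,
            nonneg: bool = True, tol: float = 1e-6,
            max_iter: int = 10_000) -> "SparseDensityResults":
        """Penalized fit; pass a full :class:`PenaltySpec` or keywords."""
        spec = penalty or PenaltySpec(lam1=lam1, c=c, delta=delta, mode=mode,
                                      weight_scale_mode=weight_scale_mode)
        res = fit_density(self.samples, self.dictionary, spec, nonneg=nonneg,
                          tol=tol, max_iter=max_iter)
        return SparseDensityResults(self, res.beta_hat, spec, method=spec.mode,
                                    fit_result=res)

    def fit_em(self, config: EMConfig | None = None) -> "SparseDensityResults":
        """EM estimate of the mixture weights (fixed components)."""
        res = em_fit(self.samples, self.dictionary, config or EMConfig())
        out = SparseDensityResults(self, res.weights, None, method="em")
        out.em_result = res
        return out

    def fit_cv(self, config: TuningConfig,
               spec: PenaltySpec | None = None) -> "SparseDensityResults":
        """Tune ``(lam1, c)`` by cross-validation, then fit."""
        best, trace = nested_search(self.samples, self.dictionary, config,
                                    spec=spec)
        out = self.fit(penalty=best)
        out.cv_trace = trace
        return out


class SparseDensityResults:
    """Fitted mixture weights plus diagnostics."""

    def __init__(self, model: SparseDensityModel, params: np.ndarray,
                 penalty: PenaltySpec | None, method: str,
                 fit_result: FitResult | None = None) -> None:
        self.model = model
        self.params = np.asarray(params, dtype=float)
        self.penalty = penalty
        self.method = method
        self.fit_result = fit_result
        self.em_result = None
        self.cv_trace = None

    @property
    def support(self) -> np.ndarray:
        from .solver import SUPPORT_EPS
        return np.flatnonzero(np.abs(self.params) > SUPPORT_EPS)

    @property
    def nnz(self) -> int:
        return int(self.support.size)

    @property
    def kkt_max_violation(self) -> float:
        return self.fit_result.kkt_max_violation if self.fit_result else np.nan

    @property
    def objective(self) -> float:
        return self.fit_result.objective if self.fit_result else np.nan

    def density(self, x) -> np.ndarray:
        """Fitted mixture density evaluated at ``x``."""
        return self.model.dictionary.mixture_pdf(x, self.params)

    def diagnostics(self) -> dict:
        """Coherence and minimal-eigenvalue diagnostics on the support."""
        return diagnostics(self.model.dictionary.gram, self.support)

    def params_frame(self) -> pd.DataFrame:
        d = self.model.dictionary
        frame = pd.DataFrame({"component": np.arange(1, d.W + 1),
                              "beta_hat": self.params})
        if self.penalty is not None:
            wv = compute_weights(self.penalty, d.sup_norms, d.W,
                                 self.model.nobs)
            frame["omega"] = wv.omega
        return frame

    def summary(self) -> str:
        d = self.model.dictionary
        lines = [
            "Sparse mixture density fit",
            "=" * 44,
            f"method:            {self.method}",
            f"observations:      {self.model.nobs}",
            f"dictionary:        {d.family}, W = {d.W}",
            f"active components: {self.nnz}",
            f"sum of weights:    {self.params.sum():.6f}",
        ]
        if self.penalty is not None:
            lines.append(f"penalty:           lam1 = {self.penalty.lam1:g}, "
                         f"c = {effective_ridge(self.penalty):g}")
        if self.fit_result is not None:
            lines.append(f"objective:         {self.objective:.6f}")
            lines.append(f"max KKT residual:  {self.kkt_max_violation:.3e}")
            lines.append(f"sweeps:            {self.fit_result.n_iter} "
                         f"(converged: {self.fit_result.converged})")
        if self.em_result is not None:
            lines.append(f"EM iterations:     {self.em_result.n_iter} "
                         f"(converged: {self.em_result.converged})")
        lines.append("-" * 44)
        lines.append("active components (component, parameter, weight):")
        for j in self.support:
            comp = d.components[j]
            par = (f"a={comp.params['a']:g}, sigma={comp.params['sigma']:g}"
                   if d.family == "gaussian"
                   else f"lam={comp.params['lam']:g}")
            lines.append(f"  {j + 1:>4}  {par:<28} {self.params[j]:.4f}")
        return "\n".join(lines)

    def plot(self, ax=None, x=None, label="fitted density"):
        """Plot the fitted density (matplotlib optional)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        d = self.model.dictionary
        if x is None:
            if d.discrete:
                x = np.arange(0, int(self.model.samples.max()) + 10)
            else:
                lo, hi = self.model.samples.min(), self.model.samples.max()
                x = np.linspace(lo - 1, hi + 1, 1000)
        y = self.density(x)
        if d.discrete:
            ax.stem(x, y, label=label)
        else:
            ax.plot(x, y, label=label)
        ax.set_xlabel("x")
        ax.set_ylabel("density")
        return ax
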