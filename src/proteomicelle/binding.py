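"""Quadratic (ligand-depletion) single-site binding model.

In a biolayer-interferometry steady-state series the immobilized ligand is
present at a concentration ``lt`` comparable to Kd, so the free-receptor
approximation fails and the exact mass-balance root must be used.  The
fraction of ligand bound at total receptor ``rt`` is

    f(rt) = [(rt + lt + Kd) - sqrt((rt + lt + Kd)^2 - 4 rt lt)] / (2 lt)

(the limit rt/(rt + Kd) as lt -> 0), and the measured response is

    y(rt) = Rmax * f(rt) + ns * rt

with a nonspecific linear term ``ns``.  Model/results classes follow the
statsmodels convention; :func:`fit_quadratic_binding` is the one-call form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares

from .io import CurveTable
from .melt import FitError

__all__ = [
    "bound_fraction",
    "QuadraticBindingModel",
    "QuadraticBindingResults",
    "fit_quadratic_binding",
]


def bound_fraction(rt, lt, kd):
    """Fraction of immobilized ligand bound at total receptor ``rt`` (nM).

    Exact single-site mass-balance root, evaluated in the numerically
    stable form ``2 rt / (b + sqrt(b^2 - 4 rt lt))`` with
    ``b = rt + lt + kd``; this reduces smoothly to the depletion-free
    ``rt / (rt + kd)`` as ``lt -> 0``.  Result is in [0, 1].
    """
    rt = np.asarray(rt, dtype=float)
    if np.any(rt < 0):
        raise ValueError("receptor concentrations must be >= 0")
    if lt < 0:
        raise ValueError("ligand concentration must be >= 0")
    if kd <= 0:
        raise ValueError("kd must be > 0")
    b = rt + lt + kd
    disc = np.maximum(b * b - 4.0 * rt * lt, 0.0)
    return 2.0 * rt / (b + np.sqrt(disc))


class QuadraticBindingModel:
    """Least-squares fit of ``Rmax * bound_fraction + ns * rt``.

    ``lt`` (the immobilized ligand concentration, nM) is a fixed design
    constant, not a fitted parameter.  Set ``fit_ns=False`` to pin the
    nonspecific slope to zero.
    """

    def __init__(self, rt, response, lt: float, fit_ns: bool = True):
        self.rt = np.asarray(rt, dtype=float)
        self.y = np.asarray(response, dtype=float)
        if self.rt.shape != self.y.shape or self.rt.ndim != 1:
            raise ValueError("rt and response must be equal-length vectors")
        if lt is None:
            raise ValueError("the immobilized ligand concentration lt is required")
        if np.unique(self.rt).size < 2:
            raise ValueError("degenerate series: all receptor concentrations equal")
        n_free = 3 if fit_ns else 2
        if self.rt.size < n_free + 2:
            raise ValueError(
                f"need at least {n_free + 2} receptor concentrations"
            )
        self.lt = float(lt)
        self.fit_ns = fit_ns

    @classmethod
    def from_curve(cls, curve: CurveTable, lt: float, fit_ns: bool = True):
        return cls(curve.x, curve.y, lt, fit_ns=fit_ns)

    def _initial_guess(self) -> np.ndarray:
        rmax0 = float(np.max(self.y))
        if rmax0 <= 0:
            rmax0 = max(float(np.ptp(self.y)), 1e-6)
        half = rmax0 / 2.0
        j = int(np.argmin(np.abs(self.y - half)))
        kd0 = float(max(self.rt[j], 1e-3))
        if self.fit_ns:
            return np.array([kd0, rmax0, 0.0])
        return np.array([kd0, rmax0])

    def fit(self) -> "QuadraticBindingResults":
        x0 = self._initial_guess()
        lo = [1e-9, 0.0] + ([-np.inf] if self.fit_ns else [])
        hi = [np.inf, np.inf] + ([np.inf] if self.fit_ns else [])

        def predict(x):
            kd, rmax = x[0], x[1]
            ns = x[2] if self.fit_ns else 0.0
            return rmax * bound_fraction(self.rt, self.lt, kd) + ns * self.rt

        def resid(x):
            return predict(x) - self.y

        sol = least_squares(
            resid, x0, bounds=(lo, hi), method="trf",
            xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=10_000,
        )
        if not sol.success:
            raise FitError(
                f"binding fit did not converge: {sol.message}",
                last_params=sol.x,
                residual_norm=float(np.linalg.norm(sol.fun)),
            )
        names = ["kd", "rmax"] + (["ns"] if self.fit_ns else [])
        dof = max(self.rt.size - len(names), 1)
        s2 = float(sol.fun @ sol.fun) / dof
        try:
            cov = np.linalg.inv(sol.jac.T @ sol.jac) * s2
        except np.linalg.LinAlgError:
            cov = np.full((len(names),) * 2, np.nan)
        params = pd.Series(dict(zip(names, sol.x)))
        if not self.fit_ns:
            params["ns"] = 0.0
        bse = pd.Series({n: float(np.sqrt(max(cov[i, i], 0.0)))
                         for i, n in enumerate(names)})
        if not self.fit_ns:
            bse["ns"] = 0.0
        return QuadraticBindingResults(
            model=self, params=params, bse=bse, cov=cov, dof=dof,
            resid=sol.fun, nfev=sol.nfev,
        )


@dataclass
class QuadraticBindingResults:
    """Fitted Kd / Rmax / ns with asymptotic (t-based) confidence intervals."""

    model: QuadraticBindingModel
    params: pd.Series
    bse: pd.Series
    cov: np.ndarray
    dof: int
    resid: np.ndarray
    nfev: int

    ci_method: str = "asymptotic (Student t on Jacobian SE)"

    def __getattr__(self, name):
        if name in ("kd", "rmax", "ns"):
            return float(self.params[name])
        raise AttributeError(name)

    @property
    def lt(self) -> float:
        return self.model.lt

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        tcrit = stats.t.ppf(1.0 - alpha / 2.0, self.dof)
        lo = self.params - tcrit * self.bse
        hi = self.params + tcrit * self.bse
        return pd.DataFrame({"lower": lo, "upper": hi})

    def predict(self, rt) -> np.ndarray:
        return self.rmax * bound_fraction(
            np.asarray(rt, dtype=float), self.lt, self.kd
        ) + self.ns * np.asarray(rt, dtype=float)

    def plot(self, ax=None):
        """Dose series and fitted curve on one axis (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        rt = self.model.rt
        ax.plot(rt, self.model.y, "o", ms=4, alpha=0.6, label="data")
        rr = np.linspace(0.0, rt.max(), 400)
        ax.plot(rr, self.predict(rr), "-",
                label=f"fit (Kd={self.kd:.1f} nM)")
        ax.set_xlabel("receptor (nM)")
        ax.set_ylabel("response")
        ax.legend()
        return ax

    def summary(self) -> str:
        ci = self.conf_int()
        lines = [
            "Quadratic (ligand-depletion) binding fit",
            f"  n points: {self.model.rt.size}   lt: {self.lt} nM   "
            f"CI: {self.ci_method}",
            f"  {'param':<6s}{'value':>12s}{'SE':>12s}{'95% CI':>26s}",
        ]
        for p in self.params.index:
            lines.append(
                f"  {p:<6s}{self.params[p]:>12.4f}{self.bse[p]:>12.4f}"
                f"      [{ci.loc[p, 'lower']:>9.4f}, {ci.loc[p, 'upper']:>9.4f}]"
            )
        return "\n".join(lines)


def fit_quadratic_binding(
    series: CurveTable, lt: float, fit_ns: bool = True
) -> QuadraticBindingResults:
    """Fit a steady-state binding series; see :class:`QuadraticBindingModel`."""
    return QuadraticBindingModel.from_curve(series, lt, fit_ns=fit_ns).fit()
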