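"""Six-parameter Boltzmann model for thermal melting curves.

A thermostability melt (CD ellipticity at 222 nm, or retention of a
fluorescent ligand) is modelled as a logistic transition between two
sloped baselines:

    y(T) = b_low(T) + [b_high(T) - b_low(T)] / (1 + exp((Tm - T)/s))

with b_low(T) = a_low + m_low*T and b_high(T) = a_high + m_high*T.  The six
parameters are the two asymptotes, the two baseline slopes, the apparent
melting temperature Tm (deg C) and the transition slope s (deg C).  This is
the standard sigmoid whose named parameters match protein melt reporting
("Tm" and "slope"); any subset may be constrained to fixed values, e.g.
``{"a_high": 0.07}`` or zero baseline slopes.

:class:`BoltzmannMeltModel` / :class:`BoltzmannMeltResults` follow the
model/results convention of statsmodels; :func:`fit_boltzmann6` is the
one-call functional form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .io import CurveTable

__all__ = [
    "PARAM_NAMES",
    "FitError",
    "boltzmann6",
    "normalize_melt",
    "BoltzmannMeltModel",
    "BoltzmannMeltResults",
    "fit_boltzmann6",
    "DeltaTm",
    "delta_tm",
]

PARAM_NAMES = ("a_low", "a_high", "m_low", "m_high", "tm", "s")


class FitError(RuntimeError):
    """Nonlinear fit failed to converge; carries the last iterate."""

    def __init__(self, message: str, last_params=None, residual_norm=None):
        super().__init__(message)
        self.last_params = last_params
        self.residual_norm = residual_norm


def boltzmann6(t, a_low, a_high, m_low, m_high, tm, s):
    """Evaluate the six-parameter Boltzmann melt at temperature(s) ``t``.

    Requires transition slope ``s > 0``.  With zero baseline slopes the
    curve runs monotonically from ``a_low`` (low T) to ``a_high`` (high T)
    and passes through their midpoint at ``t = tm``.
    """
    if s <= 0:
        raise ValueError(f"transition slope must be > 0, got {s}")
    t = np.asarray(t, dtype=float)
    base_low = a_low + m_low * t
    base_high = a_high + m_high * t
    z = np.clip((tm - t) / s, -500.0, 500.0)
    return base_low + (base_high - base_low) / (1.0 + np.exp(z))


def normalize_melt(curve: CurveTable) -> CurveTable:
    """Affinely rescale a melt so the lowest-T point maps to 1, highest to 0.

    This is the folded-fraction convention for a decreasing melt: full
    signal (folded) at the start of the ramp, zero at the end.  Idempotent;
    raises on a degenerate curve whose endpoint signals coincide.
    """
    if len(curve) < 2 or curve.x[0] == curve.x[-1]:
        raise ValueError("melt needs at least two distinct temperatures")
    y_lo, y_hi = curve.y[0], curve.y[-1]
    if y_lo == y_hi:
        raise ValueError(
            f"degenerate melt {curve.label}: identical endpoint signals"
        )
    y = (curve.y - y_hi) / (y_lo - y_hi)
    return CurveTable(
        curve.x.copy(), y, detergent=curve.detergent, state=curve.state,
        replicate=curve.replicate, kind=curve.kind,
    )


class BoltzmannMeltModel:
    """Least-squares fit of the six-parameter Boltzmann melt.

    Parameters
    ----------
    temperature, signal
        The melt series (deg C, signal units).
    constraints
        Mapping of parameter name to fixed value, e.g. ``{"a_high": 0.07}``
        or ``{"m_low": 0.0, "m_high": 0.0}``.

    The fit is a deterministic trust-region least-squares run (tolerances
    1e-10, at most 1e4 evaluations, no random restarts).  Standard errors
    come from the Jacobian at the optimum with residual-variance scaling.
    """

    def __init__(self, temperature, signal, constraints: dict | None = None):
        self.t = np.asarray(temperature, dtype=float)
        self.y = np.asarray(signal, dtype=float)
        if self.t.shape != self.y.shape or self.t.ndim != 1:
            raise ValueError("temperature and signal must be equal-length vectors")
        if self.t.size < 8:
            raise ValueError("need at least 8 points spanning the transition")
        constraints = dict(constraints or {})
        unknown = set(constraints) - set(PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown constrained parameters {sorted(unknown)}")
        if "s" in constraints and constraints["s"] <= 0:
            raise ValueError("constrained s must be > 0")
        self.constraints = constraints
        self.free_names = [p for p in PARAM_NAMES if p not in constraints]

    @classmethod
    def from_curve(cls, curve: CurveTable, constraints=None) -> "BoltzmannMeltModel":
        return cls(curve.x, curve.y, constraints=constraints)

    # -- initialisation ------------------------------------------------------

    def _initial_guess(self) -> dict:
        t, y = self.t, self.y
        n = t.size
        k = max(2, n // 10)  # outer 10% of points on each side
        m_low, a_low = np.polyfit(t[:k], y[:k], 1)
        m_high, a_high = np.polyfit(t[-k:], y[-k:], 1)
        # smoothed derivative locates the transition; edge windows are
        # excluded because the running mean is biased there
        win = max(3, n // 20) | 1
        from scipy.ndimage import uniform_filter1d

        ys = uniform_filter1d(y, win, mode="nearest")
        dy = np.gradient(ys, t)
        interior = slice(win, n - win) if n > 3 * win else slice(None)
        j = int(np.argmax(np.abs(dy[interior]))) + (
            win if n > 3 * win else 0
        )
        tm0 = float(t[j])
        dy_max = float(np.abs(dy[j]))
        span = abs((a_high + m_high * tm0) - (a_low + m_low * tm0))
        s0 = span / (4.0 * dy_max) if dy_max > 0 else 2.0
        s0 = float(np.clip(s0, 0.2, (t[-1] - t[0]) / 4.0))
        init = {
            "a_low": float(a_low), "a_high": float(a_high),
            "m_low": float(m_low), "m_high": float(m_high),
            "tm": tm0, "s": s0,
        }
        init.update(self.constraints)
        return init

    # -- fitting -------------------------------------------------------------

    def fit(self, init: dict | None = None) -> "BoltzmannMeltResults":
        guess = self._initial_guess()
        if init:
            guess.update({k: float(v) for k, v in init.items()})
            guess.update(self.constraints)

        lo = np.full(len(self.free_names), -np.inf)
        hi = np.full(len(self.free_names), np.inf)
        for i, p in enumerate(self.free_names):
            if p == "s":
                lo[i] = 1e-8
            elif p == "tm":
                lo[i], hi[i] = self.t[0], self.t[-1]

        def assemble(x):
            params = dict(zip(self.free_names, x))
            params.update(self.constraints)
            return params

        def resid(x):
            p = assemble(x)
            return boltzmann6(self.t, **p) - self.y

        # deterministic multi-start: the derivative-based guess plus fixed
        # transition-midpoint candidates; best residual norm wins
        starts = [dict(guess)]
        if init is None and "tm" not in self.constraints:
            span = self.t[-1] - self.t[0]
            for q in (0.25, 0.5, 0.75):
                alt = dict(guess)
                alt["tm"] = float(self.t[0] + q * span)
                alt["s"] = float(span / 20.0)
                starts.append(alt)

        sol = None
        for start in starts:
            x0 = np.clip(
                np.array([start[p] for p in self.free_names]), lo, hi
            )
            cand = least_squares(
                resid, x0, bounds=(lo, hi), method="trf",
                xtol=1e-10, ftol=1e-10, gtol=1e-10, max_nfev=10_000,
            )
            if cand.success and (sol is None or cand.cost < sol.cost):
                sol = cand
        if sol is None:
            raise FitError(
                "Boltzmann fit did not converge from any start",
                last_params=assemble(np.array([guess[p] for p in self.free_names])),
                residual_norm=float("nan"),
            )
        params = assemble(sol.x)

        # asymptotic SEs from the Jacobian; constrained parameters get SE 0
        dof = max(self.t.size - len(self.free_names), 1)
        s2 = float(sol.fun @ sol.fun) / dof
        jtj = sol.jac.T @ sol.jac
        try:
            cov_free = np.linalg.inv(jtj) * s2
        except np.linalg.LinAlgError:
            cov_free = np.full((len(self.free_names),) * 2, np.nan)
        se = {p: 0.0 for p in self.constraints}
        for i, p in enumerate(self.free_names):
            se[p] = float(np.sqrt(max(cov_free[i, i], 0.0)))
        return BoltzmannMeltResults(
            model=self,
            params=pd.Series({p: params[p] for p in PARAM_NAMES}),
            bse=pd.Series({p: se[p] for p in PARAM_NAMES}),
            cov_free=cov_free,
            nfev=sol.nfev,
            resid=sol.fun,
        )


@dataclass
class BoltzmannMeltResults:
    """Fitted melt parameters, their standard errors, and diagnostics."""

    model: BoltzmannMeltModel
    params: pd.Series
    bse: pd.Series
    cov_free: np.ndarray
    nfev: int
    resid: np.ndarray

    def __getattr__(self, name):
        if name in PARAM_NAMES:
            return float(self.params[name])
        raise AttributeError(name)

    @property
    def constrained(self) -> dict:
        return dict(self.model.constraints)

    @property
    def rss(self) -> float:
        return float(self.resid @ self.resid)

    def predict(self, t) -> np.ndarray:
        return boltzmann6(np.asarray(t, dtype=float), **self.params.to_dict())

    def plot(self, ax=None):
        """Data and fitted melt on one axis (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.model.t
        ax.plot(t, self.model.y, ".", ms=3, alpha=0.5, label="data")
        tt = np.linspace(t[0], t[-1], 400)
        ax.plot(tt, self.predict(tt), "-", label=f"fit (Tm={self.tm:.1f} C)")
        ax.set_xlabel("temperature (C)")
        ax.set_ylabel("signal")
        ax.legend()
        return ax

    def summary(self) -> str:
        lines = [
            "Six-parameter Boltzmann melt fit",
            f"  n points: {self.model.t.size}   RSS: {self.rss:.6g}   nfev: {self.nfev}",
            f"  constrained: {self.constrained or 'none'}",
            f"  {'param':<8s}{'value':>12s}{'SE':>12s}",
        ]
        for p in PARAM_NAMES:
            lines.append(f"  {p:<8s}{self.params[p]:>12.4f}{self.bse[p]:>12.4f}")
        return "\n".join(lines)


def fit_boltzmann6(
    curve: CurveTable,
    constraints: dict | None = None,
    init: dict | None = None,
) -> BoltzmannMeltResults:
    """Fit a melt curve; see :class:`BoltzmannMeltModel`."""
    return BoltzmannMeltModel.from_curve(curve, constraints=constraints).fit(init=init)


@dataclass
class DeltaTm:
    """Ligand-induced melting-temperature shift for one detergent/level."""

    detergent: str
    level: str  # "secondary" (CD) or "tertiary" (ligand retention)
    tm_apo: float
    tm_holo: float

    @property
    def delta(self) -> float:
        return self.tm_holo - self.tm_apo

    @property
    def delta_rounded(self) -> float:
        """Presentation value, one decimal."""
        return round(self.delta, 1)


def delta_tm(
    tm_holo: float, tm_apo: float, detergent: str = "", level: str = ""
) -> DeltaTm:
    """Ligand-induced Tm shift, ``tm_holo - tm_apo`` (deg C)."""
    return DeltaTm(detergent=detergent, level=level, tm_apo=tm_apo, tm_holo=tm_holo)
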