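"""Relative partitioning of stabilization into detergent- and ligand-driven
components, plus the linear correlations tying stability scales together.

The apo tertiary melting temperature serves as a proxy for the
detergent-driven component (conformational rigidity) and the
ligand-induced tertiary Tm shift as a proxy for the ligand-driven
component; both are normalised to a reference detergent so the ratios are
dimensionless.  These are relative trend indicators on the Celsius scale
as reported — deliberately *not* absolute free energies, and no van't
Hoff conversion of Tm shifts into kJ/mol is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .melt import DeltaTm, delta_tm

__all__ = [
    "StabilityTable",
    "PartitionResult",
    "relative_partition",
    "CorrelationResult",
    "linear_corr",
    "energy_stability_corr",
]

LEVELS = ("secondary", "tertiary")
STATES = ("apo", "holo")


class StabilityTable:
    """Per-detergent, per-state, per-level melting temperatures.

    Backed by a DataFrame with columns ``detergent, state, level, tm,
    tm_se`` (``level`` is "secondary" for CD melts, "tertiary" for
    ligand-retention melts).
    """

    def __init__(self, frame: pd.DataFrame):
        required = {"detergent", "state", "level", "tm"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"stability table missing columns {sorted(missing)}")
        frame = frame.copy()
        if "tm_se" not in frame.columns:
            frame["tm_se"] = np.nan
        bad_levels = set(frame["level"]) - set(LEVELS)
        if bad_levels:
            raise ValueError(f"unknown levels {sorted(bad_levels)}")
        bad_states = set(frame["state"]) - set(STATES)
        if bad_states:
            raise ValueError(f"unknown states {sorted(bad_states)}")
        key = frame[["detergent", "state", "level"]]
        if key.duplicated().any():
            raise ValueError("duplicate (detergent, state, level) entries")
        self.frame = frame.reset_index(drop=True)

    @classmethod
    def from_entries(
        cls, entries: Mapping[tuple[str, str, str], float | tuple[float, float]]
    ) -> "StabilityTable":
        """Build from ``{(detergent, state, level): tm or (tm, se)}``."""
        rows = []
        for (det, state, level), v in entries.items():
            tm, se = (v if isinstance(v, (tuple, list)) else (v, np.nan))
            rows.append(
                {"detergent": det, "state": state, "level": level,
                 "tm": float(tm), "tm_se": float(se)}
            )
        return cls(pd.DataFrame(rows))

    def detergents(self) -> list[str]:
        return sorted(self.frame["detergent"].unique())

    def tm(self, detergent: str, state: str, level: str) -> float:
        f = self.frame
        hit = f[
            (f.detergent == detergent) & (f.state == state) & (f.level == level)
        ]
        if not len(hit):
            raise KeyError((detergent, state, level))
        return float(hit["tm"].iloc[0])

    def delta(self, level: str, detergent: str | None = None):
        """Ligand-induced Tm shift(s) at the given level."""
        dets = [detergent] if detergent else self.detergents()
        out = [
            delta_tm(
                self.tm(d, "holo", level), self.tm(d, "apo", level),
                detergent=d, level=level,
            )
            for d in dets
        ]
        return out[0] if detergent else out


@dataclass
class PartitionResult:
    """Relative detergent-driven and ligand-driven stability components.

    ``conf_rel[d]`` = apo tertiary Tm of d over that of the reference;
    ``ligand_rel[d]`` = ligand-induced tertiary Tm shift of d over that of
    the reference.  Both equal exactly 1.0 at the reference.
    """

    reference: str
    conf_rel: dict[str, float] = field(default_factory=dict)
    ligand_rel: dict[str, float] = field(default_factory=dict)

    def rounded(self, ndigits: int = 1) -> "PartitionResult":
        """Presentation copy rounded to ``ndigits`` decimals."""
        return PartitionResult(
            self.reference,
            {d: round(v, ndigits) for d, v in self.conf_rel.items()},
            {d: round(v, ndigits) for d, v in self.ligand_rel.items()},
        )

    def to_frame(self) -> pd.DataFrame:
        dets = list(self.conf_rel)
        return pd.DataFrame(
            {"detergent": dets,
             "conf_rel": [self.conf_rel[d] for d in dets],
             "ligand_rel": [self.ligand_rel[d] for d in dets]}
        )


def relative_partition(table: StabilityTable, reference: str = "DM") -> PartitionResult:
    """Partition stabilization into relative detergent/ligand components.

    Requires tertiary apo and holo Tm for every detergent in the table.
    Ratios are taken on the Celsius scale as printed (Kelvin ratios would
    not reproduce the reported values); full precision is retained here
    and rounding happens only at presentation.
    """
    dets = table.detergents()
    if reference not in dets:
        raise KeyError(f"reference detergent {reference!r} not in table")
    ref_apo = table.tm(reference, "apo", "tertiary")
    ref_delta = table.delta("tertiary", reference).delta
    if ref_delta == 0:
        raise ZeroDivisionError(
            f"reference {reference!r} has zero ligand-induced tertiary shift; "
            "ligand_rel is undefined"
        )
    conf = {d: table.tm(d, "apo", "tertiary") / ref_apo for d in dets}
    lig = {d: table.delta("tertiary", d).delta / ref_delta for d in dets}
    return PartitionResult(reference=reference, conf_rel=conf, ligand_rel=lig)


@dataclass
class CorrelationResult:
    """Ordinary least-squares line with its coefficient of determination."""

    slope: float
    intercept: float
    r_squared: float
    n: int
    stderr: float = float("nan")

    def predict(self, x):
        return self.slope * np.asarray(x, dtype=float) + self.intercept


def linear_corr(x, y) -> CorrelationResult:
    """OLS fit of y on x with r^2 = 1 - SS_res/SS_tot."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("x and y must be equal-length vectors with n >= 2")
    if np.all(x == x[0]):
        raise ValueError("x is constant; the slope is undefined")
    res = stats.linregress(x, y)
    yhat = res.slope * x + res.intercept
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return CorrelationResult(
        slope=float(res.slope), intercept=float(res.intercept),
        r_squared=float(r2), n=x.size, stderr=float(res.stderr),
    )


def energy_stability_corr(
    energies: Mapping[tuple[str, str], float],
    table: StabilityTable,
    level: str = "secondary",
) -> CorrelationResult:
    """Correlate per-condition interaction energies with melting temperatures.

    ``energies`` maps ``(detergent, state)`` to a total interaction energy
    (kJ/mol); each key must have a matching Tm at the requested level.
    """
    keys = sorted(energies)
    missing = []
    pairs = []
    for det, state in keys:
        try:
            tm = table.tm(det, state, level)
        except KeyError:
            missing.append((det, state))
            continue
        pairs.append((energies[(det, state)], tm))
    if missing:
        raise KeyError(f"no {level} Tm for conditions {missing}")
    if len(pairs) < 3:
        raise ValueError("need at least 3 matched (energy, Tm) pairs")
    e, tm = zip(*pairs)
    return linear_corr(np.array(e), np.array(tm))
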