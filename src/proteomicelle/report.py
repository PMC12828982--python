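"""Assemble fit, partitioning, correlation and trajectory results into a
reproducible report (CSV bundle plus a markdown summary).

The report body is a pure function of its inputs — no timestamps — so
regenerating from the same inputs is byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from .fixtures import load_fixtures
from .partition import CorrelationResult, PartitionResult

__all__ = ["Report", "build_report"]


@dataclass
class Report:
    """A bundle of labelled tables plus a rendered markdown summary."""

    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    body: str = ""

    def write(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables.items():
            df.to_csv(outdir / f"{name}.csv", index=False)
        (outdir / "summary.md").write_text(self.body)
        return outdir


def _fixture_delta_table() -> pd.DataFrame:
    fx = load_fixtures()
    table = fx.stability_table()
    rows = []
    for level in ("secondary", "tertiary"):
        for d in table.detergents():
            dt = table.delta(level, d)
            rows.append(
                {"detergent": d, "level": level, "tm_apo": dt.tm_apo,
                 "tm_holo": dt.tm_holo, "delta_tm": dt.delta_rounded}
            )
    return pd.DataFrame(rows)


def build_report(
    fits: Mapping[str, object] | None = None,
    partition: PartitionResult | None = None,
    correlations: Mapping[str, CorrelationResult] | None = None,
    metrics: Mapping[str, pd.DataFrame] | None = None,
) -> Report:
    """Build a structured report from any non-empty subset of results.

    ``fits`` maps labels to melt/binding results objects (anything with a
    ``params``/``bse`` pair); ``metrics`` maps metric names to tidy
    DataFrames.  The reference-table comparison (ligand-induced Tm shifts
    recomputed from the published melting temperatures) is always
    included.
    """
    tables: dict[str, pd.DataFrame] = {}
    lines: list[str] = ["# Detergent/ligand stabilization report", ""]

    deltas = _fixture_delta_table()
    tables["fixture_delta_tm"] = deltas
    lines += [
        "## Ligand-induced Tm shifts from the published melting temperatures",
        "",
        deltas.to_markdown(index=False),
        "",
    ]

    if fits:
        rows = []
        for label, res in fits.items():
            for p, v in res.params.items():
                rows.append(
                    {"fit": label, "param": p, "value": v,
                     "se": float(res.bse[p])}
                )
        tables["fits"] = pd.DataFrame(rows)
        lines += ["## Curve fits", "", tables["fits"].to_markdown(index=False), ""]

    if partition is not None:
        part = partition.rounded().to_frame()
        tables["partition"] = part
        lines += [
            f"## Relative partitioning (reference: {partition.reference})",
            "",
            part.to_markdown(index=False),
            "",
            "conf_rel: detergent-driven component (apo tertiary Tm ratio); "
            "ligand_rel: ligand-driven component (tertiary Tm-shift ratio). "
            "Dimensionless trend indicators, not absolute free energies.",
            "",
        ]

    if correlations:
        rows = [
            {"correlation": name, "slope": round(c.slope, 2),
             "intercept": round(c.intercept, 2),
             "r_squared": round(c.r_squared, 2), "n": c.n}
            for name, c in correlations.items()
        ]
        tables["correlations"] = pd.DataFrame(rows)
        lines += [
            "## Linear correlations", "",
            tables["correlations"].to_markdown(index=False), "",
        ]

    if metrics:
        for name, df in metrics.items():
            tables[f"metric_{name}"] = df
        lines += [
            "## Trajectory metrics", "",
            "Included tables: " + ", ".join(f"`metric_{n}.csv`" for n in metrics),
            "",
        ]

    return Report(tables=tables, body="\n".join(lines))
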