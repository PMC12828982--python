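"""Published reference tables for the enNTS1 detergent series.

The reported experimental anchors for a thermostabilized neurotensin
receptor 1 variant (enNTS1) solubilized in DM, DDM, or LMNG micelles:
NT(8-13) equilibrium dissociation constants from biolayer interferometry,
apparent secondary- (CD 222 nm) and tertiary-structure (ligand retention)
melting temperatures with transition slopes, and the transmembrane helix
residue ranges used for trajectory analysis.  Values are stored exactly
as printed, with their reported uncertainties.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .ensemble import SelectionSpec
from .partition import StabilityTable

__all__ = ["PrintedTable", "Fixtures", "load_fixtures", "A_HIGH_CONSTRAINT"]

#: High-temperature asymptote used to constrain the LMNG holo CD melt fit.
A_HIGH_CONSTRAINT = 0.07

DETERGENTS = ("DM", "DDM", "LMNG")


class PrintedTable(dict):
    """Mapping of key -> printed value that also tracks uncertainties.

    Indexing returns the value; :meth:`uncertainty` the reported +/-.
    """

    def __init__(self, entries: dict):
        vals = {k: v[0] for k, v in entries.items()}
        super().__init__(vals)
        self._unc = {k: v[1] for k, v in entries.items()}

    def uncertainty(self, key) -> float:
        return self._unc[key]


# NT(8-13) Kd (nM) by detergent, steady-state BLI with ligand depletion
_KD = PrintedTable({"DM": (13.7, 3.3), "DDM": (35.9, 5.1), "LMNG": (94.9, 26.0)})

# secondary-structure (CD 222 nm) melting temperatures, deg C
_TM2 = PrintedTable({
    ("DM", "apo"): (50.4, 0.07), ("DM", "holo"): (76.4, 0.06),
    ("DDM", "apo"): (71.6, 0.2), ("DDM", "holo"): (91.2, 0.2),
    ("LMNG", "apo"): (82.4, 0.1), ("LMNG", "holo"): (97.6, 0.2),
})

# tertiary-structure (fluorescent ligand retention) melting temperatures
_TM3 = PrintedTable({
    ("DM", "apo"): (35.9, 0.2), ("DM", "holo"): (50.8, 0.2),
    ("DDM", "apo"): (57.7, 0.4), ("DDM", "holo"): (64.9, 0.2),
    ("LMNG", "apo"): (74.4, 0.4), ("LMNG", "holo"): (76.5, 0.3),
})

# transition slopes s (deg C) of the same melts
_SLOPE2 = {
    ("DM", "apo"): 3.9, ("DM", "holo"): 2.0,
    ("DDM", "apo"): 4.4, ("DDM", "holo"): 2.7,
    ("LMNG", "apo"): 2.1, ("LMNG", "holo"): 1.6,
}
_SLOPE3 = {
    ("DM", "apo"): 3.4, ("DM", "holo"): 1.5,
    ("DDM", "apo"): 3.3, ("DDM", "holo"): 1.6,
    ("LMNG", "apo"): 2.6, ("LMNG", "holo"): 2.5,
}

# transmembrane helix ranges (construct numbering, 1-based inclusive)
_TM_RANGES = {
    "apo": [(61, 91), (100, 130), (139, 172), (183, 206), (231, 271),
            (299, 333), (341, 370)],
    "holo": [(61, 91), (97, 130), (139, 172), (183, 207), (231, 271),
             (301, 333), (341, 373)],
}


@dataclass
class Fixtures:
    """Bundle of the printed reference tables."""

    kd: PrintedTable = field(default_factory=lambda: PrintedTable({}))
    tm2: PrintedTable = field(default_factory=lambda: PrintedTable({}))
    tm3: PrintedTable = field(default_factory=lambda: PrintedTable({}))
    slope2: dict = field(default_factory=dict)
    slope3: dict = field(default_factory=dict)
    tm_selections: dict[str, SelectionSpec] = field(default_factory=dict)
    a_high_constraint: float = A_HIGH_CONSTRAINT

    def stability_table(self) -> StabilityTable:
        """All twelve (detergent, state, level) Tm entries as a table."""
        entries = {}
        for (det, state), tm in self.tm2.items():
            entries[(det, state, "secondary")] = (tm, self.tm2.uncertainty((det, state)))
        for (det, state), tm in self.tm3.items():
            entries[(det, state, "tertiary")] = (tm, self.tm3.uncertainty((det, state)))
        return StabilityTable.from_entries(entries)

    def stability_frame(self) -> pd.DataFrame:
        """The stability table with slopes, one labelled row per melt."""
        df = self.stability_table().frame
        slope = {
            ("secondary", det, state): v
            for (det, state), v in self.slope2.items()
        } | {
            ("tertiary", det, state): v
            for (det, state), v in self.slope3.items()
        }
        df["slope"] = [
            slope[(lvl, det, st)]
            for lvl, det, st in zip(df["level"], df["detergent"], df["state"])
        ]
        return df

    def kd_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"detergent": list(self.kd),
             "kd_nM": list(self.kd.values()),
             "kd_se_nM": [self.kd.uncertainty(d) for d in self.kd]}
        )


def load_fixtures() -> Fixtures:
    """The printed Kd / Tm / slope tables and TM helix selections."""
    selections = {
        state: SelectionSpec(
            name=f"TM_{state}",
            residue_ranges=list(ranges),
            atom_name_filter=["N", "CA", "C", "O"],
        )
        for state, ranges in _TM_RANGES.items()
    }
    return Fixtures(
        kd=PrintedTable({k: (v, _KD.uncertainty(k)) for k, v in _KD.items()}),
        tm2=PrintedTable({k: (v, _TM2.uncertainty(k)) for k, v in _TM2.items()}),
        tm3=PrintedTable({k: (v, _TM3.uncertainty(k)) for k, v in _TM3.items()}),
        slope2=dict(_SLOPE2),
        slope3=dict(_SLOPE3),
        tm_selections=selections,
    )
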