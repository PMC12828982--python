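"""Annotated coordinate ensembles and atom selections.

The central container is :class:`AnnotatedEnsemble`: an ordered atom table
(roles, optional charges and Lennard-Jones parameters) plus a stack of
coordinate frames in nanometres.  Every trajectory metric in
:mod:`proteomicelle.metrics` consumes this object, whether the frames came
from a multi-model PDB, an XYZ file, or the synthetic proteomicelle
generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ROLES",
    "ATOM_COLUMNS",
    "AtomRecord",
    "AnnotatedEnsemble",
    "SelectionSpec",
    "resolve_selection",
    "element_mass",
]

#: Recognised atom roles.  Every atom touched by a metric must carry one.
ROLES = frozenset(
    {"protein", "detergent_head", "detergent_tail", "ligand", "solvent", "ion"}
)

ATOM_COLUMNS = [
    "atom_id",
    "atom_name",
    "element",
    "residue_name",
    "residue_id",
    "chain",
    "role",
    "charge",
    "lj_epsilon",
    "lj_sigma",
]

# Standard atomic masses (u) for the elements a proteomicelle model contains.
_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "NA": 22.990,
    "CL": 35.45,
}


def element_mass(element: str) -> float:
    """Atomic mass in u for ``element``; unknown elements default to carbon."""
    return _MASSES.get(element.upper(), 12.011)


@dataclass
class AtomRecord:
    """One atom: identity, role, and optional nonbonded parameters.

    ``charge`` is in elementary charges, ``lj_epsilon`` in kJ/mol and
    ``lj_sigma`` in nm.  Parameters left as NaN mean "not supplied"; energy
    operations refuse to run on such atoms rather than defaulting to zero.
    """

    atom_id: int
    atom_name: str
    element: str
    residue_name: str
    residue_id: int
    chain: str = "A"
    role: str = "protein"
    charge: float = float("nan")
    lj_epsilon: float = float("nan")
    lj_sigma: float = float("nan")

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {sorted(ROLES)}")
        if np.isfinite(self.lj_sigma) and self.lj_sigma <= 0:
            raise ValueError(f"lj_sigma must be > 0, got {self.lj_sigma}")


class AnnotatedEnsemble:
    """Atom annotations plus an ordered stack of coordinate frames.

    Parameters
    ----------
    atoms
        DataFrame with :data:`ATOM_COLUMNS` (or an iterable of
        :class:`AtomRecord`).
    coords
        Array of shape ``(n_frames, n_atoms, 3)`` in nm.
    times
        Frame times in ns, strictly increasing.  Defaults to ``0, 1, 2, ...``.
    box
        Optional orthorhombic box lengths (nm).
    """

    def __init__(
        self,
        atoms: pd.DataFrame | Iterable[AtomRecord],
        coords: np.ndarray,
        times: Sequence[float] | None = None,
        box: Sequence[float] | None = None,
    ) -> None:
        if not isinstance(atoms, pd.DataFrame):
            atoms = pd.DataFrame([vars(a) for a in atoms]).rename(
                columns={"chain": "chain"}
            )
        atoms = atoms.reset_index(drop=True)
        missing = [c for c in ATOM_COLUMNS if c not in atoms.columns]
        for c in missing:
            if c in ("charge", "lj_epsilon", "lj_sigma"):
                atoms[c] = np.nan
            elif c == "chain":
                atoms[c] = "A"
            else:
                raise ValueError(f"atom table missing required column {c!r}")
        self.atoms = atoms[ATOM_COLUMNS].copy()
        if self.atoms["atom_id"].duplicated().any():
            raise ValueError("atom_id values must be unique within a structure")
        bad_roles = set(self.atoms["role"]) - ROLES
        if bad_roles:
            raise ValueError(f"unknown roles {sorted(bad_roles)}")

        coords = np.asarray(coords, dtype=float)
        if coords.ndim == 2:
            coords = coords[None]
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if coords.shape[0] < 1:
            raise ValueError("ensemble needs at least one frame")
        if coords.shape[1] != len(self.atoms):
            raise ValueError(
                f"coordinate frames carry {coords.shape[1]} atoms but the atom "
                f"table has {len(self.atoms)}"
            )
        if np.isnan(coords).any():
            raise ValueError("coordinates contain NaN")
        self.coords = coords

        if times is None:
            times = np.arange(coords.shape[0], dtype=float)
        times = np.asarray(times, dtype=float)
        if times.shape != (coords.shape[0],):
            raise ValueError("times must have one entry per frame")
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("frame times must be strictly increasing")
        self.times = times
        self.box = None if box is None else np.asarray(box, dtype=float)

    # -- basic introspection -------------------------------------------------

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def masses(self) -> np.ndarray:
        """Per-atom masses (u) looked up by element."""
        return np.array([element_mass(e) for e in self.atoms["element"]])

    def indices_by_role(self, *roles: str) -> np.ndarray:
        bad = set(roles) - ROLES
        if bad:
            raise ValueError(f"unknown roles {sorted(bad)}")
        mask = self.atoms["role"].isin(roles).to_numpy()
        return np.flatnonzero(mask)

    def subset(self, indices: np.ndarray) -> "AnnotatedEnsemble":
        """New ensemble restricted to ``indices`` (all frames kept)."""
        indices = np.asarray(indices, dtype=int)
        return AnnotatedEnsemble(
            self.atoms.iloc[indices].reset_index(drop=True),
            self.coords[:, indices],
            times=self.times,
            box=self.box,
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<AnnotatedEnsemble {self.n_atoms} atoms x {self.n_frames} frames, "
            f"roles={sorted(set(self.atoms['role']))}>"
        )


@dataclass
class SelectionSpec:
    """A named atom selection: residue ranges plus optional filters.

    ``residue_ranges`` are inclusive 1-based ``(first, last)`` pairs, the
    convention used for transmembrane helix definitions (e.g. TM1 61-91).
    ``atom_name_filter`` restricts to named atoms (e.g. backbone
    ``["N", "CA", "C", "O"]``); ``role_filter`` restricts to atom roles.
    """

    name: str
    residue_ranges: list[tuple[int, int]] = field(default_factory=list)
    atom_name_filter: list[str] | None = None
    role_filter: set[str] | None = None

    def __post_init__(self) -> None:
        if not self.residue_ranges and self.role_filter is None:
            raise ValueError(f"selection {self.name!r} selects nothing")
        for lo, hi in self.residue_ranges:
            if lo > hi:
                raise ValueError(
                    f"selection {self.name!r}: range ({lo}, {hi}) has first > last"
                )

    def helix_of(self, residue_id: int) -> int | None:
        """Index of the range (helix) containing ``residue_id``, or None."""
        for k, (lo, hi) in enumerate(self.residue_ranges):
            if lo <= residue_id <= hi:
                return k
        return None


def resolve_selection(ensemble: AnnotatedEnsemble, spec: SelectionSpec) -> np.ndarray:
    """Atom indices matching ``spec``, in ascending order.

    Pure function of its inputs; raises if the resolved selection is empty.
    """
    atoms = ensemble.atoms
    if spec.residue_ranges:
        mask = np.zeros(len(atoms), dtype=bool)
        rid = atoms["residue_id"].to_numpy()
        for lo, hi in spec.residue_ranges:
            mask |= (rid >= lo) & (rid <= hi)
    else:
        mask = np.ones(len(atoms), dtype=bool)
    if spec.atom_name_filter is not None:
        mask &= atoms["atom_name"].isin(spec.atom_name_filter).to_numpy()
    if spec.role_filter is not None:
        bad = set(spec.role_filter) - ROLES
        if bad:
            raise ValueError(f"unknown roles in filter: {sorted(bad)}")
        mask &= atoms["role"].isin(spec.role_filter).to_numpy()
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise ValueError(f"selection {spec.name!r} resolves to no atoms")
    return idx
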