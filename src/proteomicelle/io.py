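"""Readers and writers for structures, trajectories, and curve tables.

Structures arrive as multi-model PDB (parsed with biotite) or plain XYZ
frame files; curves as delimited tables with ``x, y, detergent, state,
replicate`` columns.  Coordinates are stored internally in nm; PDB/XYZ
files are read and written in Angstrom and converted on the way through.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .ensemble import ATOM_COLUMNS, ROLES, AnnotatedEnsemble

logger = logging.getLogger("proteomicelle")

__all__ = [
    "FormatError",
    "CurveTable",
    "read_structure",
    "write_structure",
    "read_role_map",
    "write_role_table",
    "read_curves",
    "write_curves",
]

NM_PER_ANGSTROM = 0.1


class FormatError(ValueError):
    """Malformed input file (inconsistent models, unmapped residues, ...)."""


# ---------------------------------------------------------------------------
# curve tables
# ---------------------------------------------------------------------------


@dataclass
class CurveTable:
    """One experimental curve: x/y series plus its condition labels.

    ``x`` is temperature in deg C for melts or receptor concentration in nM
    for binding series; ``y`` the measured signal (arbitrary units or nm of
    BLI response).
    """

    x: np.ndarray
    y: np.ndarray
    detergent: str = ""
    state: str = ""
    replicate: str | int = 0
    kind: str | None = None  # "melt" | "binding" | None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1-D vectors of equal length")
        if np.isnan(self.x).any() or np.isnan(self.y).any():
            raise ValueError("curve contains missing values")
        if self.kind == "melt":
            order = np.argsort(self.x, kind="stable")
            self.x = self.x[order]
            self.y = self.y[order]
            if np.any(np.diff(self.x) == 0):
                dups = np.unique(self.x[np.flatnonzero(np.diff(self.x) == 0)])
                logger.warning(
                    "melt curve %s/%s/%s has duplicated temperatures %s (kept)",
                    self.detergent, self.state, self.replicate, dups,
                )

    @property
    def label(self) -> tuple:
        return (self.detergent, self.state, self.replicate)

    def __len__(self) -> int:
        return self.x.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x": self.x,
                "y": self.y,
                "detergent": self.detergent,
                "state": self.state,
                "replicate": self.replicate,
            }
        )


def read_curves(path: str | Path, kind: str | None = None) -> list[CurveTable]:
    """Read a delimited curve file into one :class:`CurveTable` per condition.

    The file must have columns ``x, y, detergent, state, replicate``; one
    table is produced per unique ``(detergent, state, replicate)``.  Melt
    curves (``kind="melt"``) are sorted by temperature; duplicated
    temperatures are kept and flagged in the log.
    """
    df = pd.read_csv(path)
    required = {"x", "y", "detergent", "state", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    for col in ("x", "y"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(coerced.isna() & df[col].notna())
        if bad.size:
            # +2: one for the header line, one for 1-based numbering
            raise FormatError(
                f"{path}: non-numeric {col!r} at data row {bad[0] + 2}: "
                f"{df[col].iloc[bad[0]]!r}"
            )
        if coerced.isna().any():
            raise FormatError(f"{path}: missing {col!r} values")
        df[col] = coerced
    out = []
    for (det, state, rep), grp in df.groupby(
        ["detergent", "state", "replicate"], sort=True
    ):
        out.append(
            CurveTable(
                grp["x"].to_numpy(), grp["y"].to_numpy(),
                detergent=str(det), state=str(state), replicate=rep, kind=kind,
            )
        )
    return out


def write_curves(tables: Iterable[CurveTable], path: str | Path) -> None:
    pd.concat([t.to_frame() for t in tables], ignore_index=True).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# role maps / annotation tables
# ---------------------------------------------------------------------------


def read_role_map(source: str | Path | pd.DataFrame | Mapping[str, str]) -> pd.DataFrame:
    """Normalise a role map into a DataFrame.

    Accepted inputs: a ``{residue_name: role}`` mapping, a CSV path, or a
    DataFrame with columns ``residue_name, role`` and optionally
    ``atom_name, charge, lj_epsilon, lj_sigma``.  Rows without ``atom_name``
    assign the role (and any parameters) to every atom of the residue;
    rows with ``atom_name`` override per atom.
    """
    if isinstance(source, Mapping):
        df = pd.DataFrame(
            {"residue_name": list(source), "role": list(source.values())}
        )
    elif isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source)
    if "residue_name" not in df.columns or "role" not in df.columns:
        raise FormatError("role map needs residue_name and role columns")
    bad = set(df["role"]) - ROLES
    if bad:
        raise FormatError(f"role map contains unknown roles {sorted(bad)}")
    for col in ("atom_name", "charge", "lj_epsilon", "lj_sigma"):
        if col not in df.columns:
            df[col] = np.nan
    return df


def _apply_role_map(atoms: pd.DataFrame, role_map: pd.DataFrame) -> pd.DataFrame:
    atoms = atoms.copy()
    unmapped = sorted(set(atoms["residue_name"]) - set(role_map["residue_name"]))
    if unmapped:
        raise FormatError(
            f"role map does not cover residue names: {unmapped}"
        )
    per_res = role_map[role_map["atom_name"].isna()].set_index("residue_name")
    per_atom = role_map[role_map["atom_name"].notna()].set_index(
        ["residue_name", "atom_name"]
    )
    roles, charge, eps, sig = [], [], [], []
    for rn, an in zip(atoms["residue_name"], atoms["atom_name"]):
        row = None
        if (rn, an) in per_atom.index:
            row = per_atom.loc[(rn, an)]
        elif rn in per_res.index:
            row = per_res.loc[rn]
        else:
            raise FormatError(
                f"role map has only atom-level rows for {rn!r} and none matches "
                f"atom {an!r}"
            )
        roles.append(row["role"])
        charge.append(row.get("charge", np.nan))
        eps.append(row.get("lj_epsilon", np.nan))
        sig.append(row.get("lj_sigma", np.nan))
    atoms["role"] = roles
    atoms["charge"] = np.asarray(charge, dtype=float)
    atoms["lj_epsilon"] = np.asarray(eps, dtype=float)
    atoms["lj_sigma"] = np.asarray(sig, dtype=float)
    return atoms


def write_role_table(ensemble: AnnotatedEnsemble, path: str | Path) -> None:
    """Write the full per-atom annotation table (roles and parameters)."""
    ensemble.atoms.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# structures
# ---------------------------------------------------------------------------


def read_structure(
    path: str | Path,
    role_map: str | Path | pd.DataFrame | Mapping[str, str] | None = None,
    atoms: str | Path | pd.DataFrame | None = None,
    time_step_ns: float = 1.0,
) -> AnnotatedEnsemble:
    """Read a multi-model PDB or XYZ frame file into an ensemble.

    PDB MODEL blocks (or XYZ frames) become frames; atom identity must be
    constant across frames.  For PDB, ``role_map`` assigns roles (and
    optional charges / LJ parameters) by residue name.  For XYZ, which
    carries no residue information, a full per-atom annotation table
    (``atoms``, CSV path or DataFrame) is required instead.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".xyz":
        return _read_xyz(path, atoms, time_step_ns)
    if suffix != ".pdb":
        raise FormatError(f"unsupported structure format {suffix!r}")

    import biotite.structure.io.pdb as pdb

    try:
        pfile = pdb.PDBFile.read(str(path))
        stack = pfile.get_structure(model=None)
    except Exception as exc:  # biotite raises on inconsistent models
        raise FormatError(f"{path}: {exc}") from exc
    coords = np.asarray(stack.coord, dtype=float) * NM_PER_ANGSTROM
    if coords.ndim == 2:
        coords = coords[None]
    table = pd.DataFrame(
        {
            "atom_id": np.arange(1, stack.array_length() + 1),
            "atom_name": stack.atom_name,
            "element": stack.element,
            "residue_name": stack.res_name,
            "residue_id": stack.res_id,
            "chain": stack.chain_id,
            "role": "protein",
            "charge": np.nan,
            "lj_epsilon": np.nan,
            "lj_sigma": np.nan,
        }
    )
    if role_map is not None:
        table = _apply_role_map(table, read_role_map(role_map))
    times = np.arange(coords.shape[0], dtype=float) * time_step_ns
    return AnnotatedEnsemble(table, coords, times=times)


def _read_xyz(
    path: Path,
    atoms: str | Path | pd.DataFrame | None,
    time_step_ns: float,
) -> AnnotatedEnsemble:
    if atoms is None:
        raise FormatError(
            f"{path}: XYZ files carry no residue or role information; pass a "
            "per-atom annotation table"
        )
    if not isinstance(atoms, pd.DataFrame):
        atoms = pd.read_csv(atoms)
    lines = Path(path).read_text().splitlines()
    frames: list[np.ndarray] = []
    i = 0
    n_expected = None
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].split()[0])
        except ValueError as exc:
            raise FormatError(f"{path}: bad atom-count line {i + 1}") from exc
        if n_expected is None:
            n_expected = n
        elif n != n_expected:
            raise FormatError(
                f"{path}: frame {len(frames) + 1} has {n} atoms, expected {n_expected}"
            )
        block = lines[i + 2 : i + 2 + n]
        if len(block) < n:
            raise FormatError(f"{path}: truncated frame {len(frames) + 1}")
        xyz = np.array(
            [[float(v) for v in ln.split()[1:4]] for ln in block], dtype=float
        )
        frames.append(xyz * NM_PER_ANGSTROM)
        i += 2 + n
    if not frames:
        raise FormatError(f"{path}: no frames found")
    coords = np.stack(frames)
    times = np.arange(coords.shape[0], dtype=float) * time_step_ns
    return AnnotatedEnsemble(atoms, coords, times=times)


def write_structure(ensemble: AnnotatedEnsemble, path: str | Path) -> None:
    """Write all frames as a multi-model PDB (or XYZ) file.

    Roles and nonbonded parameters do not fit in PDB records; use
    :func:`write_role_table` alongside to preserve them.
    """
    path = Path(path)
    if path.suffix.lower() == ".xyz":
        _write_xyz(ensemble, path)
        return

    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    n = ensemble.n_atoms
    stack = struc.AtomArrayStack(ensemble.n_frames, n)
    stack.coord = ensemble.coords / NM_PER_ANGSTROM
    at = ensemble.atoms
    stack.atom_name = at["atom_name"].to_numpy(dtype="U6")
    stack.element = at["element"].to_numpy(dtype="U2")
    stack.res_name = at["residue_name"].to_numpy(dtype="U5")
    stack.res_id = at["residue_id"].to_numpy(dtype=int)
    stack.chain_id = at["chain"].astype(str).str[:1].to_numpy(dtype="U4")
    stack.hetero = ~(at["role"] == "protein").to_numpy()
    pfile = pdb.PDBFile()
    pfile.set_structure(stack)
    pfile.write(str(path))


def _write_xyz(ensemble: AnnotatedEnsemble, path: Path) -> None:
    elements = ensemble.atoms["element"].tolist()
    with open(path, "w") as fh:
        for f in range(ensemble.n_frames):
            fh.write(f"{ensemble.n_atoms}\n")
            fh.write(f"frame {f} t={ensemble.times[f]:.6g} ns\n")
            for el, (x, y, z) in zip(
                elements, ensemble.coords[f] / NM_PER_ANGSTROM
            ):
                fh.write(f"{el:<3s} {x:14.6f} {y:14.6f} {z:14.6f}\n")
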