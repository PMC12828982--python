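"""Shrake-Rupley solvent-accessible surface area and hydrophobic mismatch.

SASA uses a deterministic golden-spiral point set on each atom's expanded
sphere (radius + probe); a point is accessible when it lies outside every
neighbour's expanded sphere.  Residual hydrophobic mismatch sums the SASA
of hydrophobic transmembrane residues whose detergent-contact persistence
falls strictly below a threshold (default 20%) — the solvent-exposed
hydrophobic surface the micelle fails to cover.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from ..ensemble import AnnotatedEnsemble, SelectionSpec, resolve_selection
from .contacts import contact_frequency

__all__ = ["VDW_RADII_NM", "HYDROPHOBIC_RESIDUES", "sasa", "residual_mismatch",
           "MismatchResult"]

#: van der Waals radii by element, nm
VDW_RADII_NM = {
    "C": 0.170,
    "N": 0.155,
    "O": 0.152,
    "S": 0.180,
    "H": 0.120,
    "P": 0.180,
}

HYDROPHOBIC_RESIDUES = frozenset(
    {"GLY", "ALA", "PRO", "VAL", "MET", "CYS", "ILE", "TRP", "PHE", "TYR",
     "LEU"}
)


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * k
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def sasa(
    coords,
    sel=None,
    probe_nm: float = 0.14,
    n_sphere_points: int = 960,
    frame: int = 0,
    radii: dict[str, float] | None = None,
    per_atom: bool = False,
):
    """Per-residue solvent-accessible surface area in A^2.

    ``coords`` may be an :class:`AnnotatedEnsemble` (with ``sel`` and
    ``frame``) or a plain ``(n, 3)`` nm array, in which case ``radii`` per
    atom must be supplied as an array.  The atoms in the selection act
    both as surface atoms and as occluders.  Returns a Series indexed by
    residue_id (or a per-atom array when ``per_atom`` is set).
    """
    radii_map = VDW_RADII_NM if radii is None else radii
    if isinstance(coords, AnnotatedEnsemble):
        ens = coords
        idx = np.arange(ens.n_atoms) if sel is None else np.asarray(sel, dtype=int)
        xyz = ens.coords[frame, idx]
        elements = ens.atoms["element"].to_numpy()[idx]
        unknown = sorted(
            {str(e).upper() for e in elements} - set(radii_map)
        )
        if unknown:
            raise ValueError(f"no van der Waals radius for element(s) {unknown}")
        r_atom = np.array([radii_map[str(e).upper()] for e in elements])
        res_ids = ens.atoms["residue_id"].to_numpy()[idx]
    else:
        xyz = np.asarray(coords, dtype=float)
        if not isinstance(radii_map, np.ndarray) and radii is not None:
            r_atom = np.asarray(radii, dtype=float)
        elif isinstance(radii_map, np.ndarray):
            r_atom = radii_map
        else:
            raise ValueError("plain coordinates need an explicit radii array")
        res_ids = np.zeros(xyz.shape[0], dtype=int)

    n = xyz.shape[0]
    r_exp = r_atom + probe_nm
    points = _sphere_points(n_sphere_points)
    tree = cKDTree(xyz)
    max_reach = 2.0 * (r_exp.max())
    areas = np.zeros(n)
    for i in range(n):
        surf = xyz[i] + r_exp[i] * points
        nbrs = [j for j in tree.query_ball_point(xyz[i], max_reach) if j != i]
        if nbrs:
            nb_xyz = xyz[nbrs]
            nb_r = r_exp[nbrs]
            d2 = np.sum((surf[:, None, :] - nb_xyz[None, :, :]) ** 2, axis=2)
            buried = np.any(d2 < (nb_r**2)[None, :], axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = frac * 4.0 * np.pi * r_exp[i] ** 2
    areas_A2 = areas * 100.0  # nm^2 -> A^2
    if per_atom:
        return areas_A2
    return pd.Series(areas_A2).groupby(res_ids).sum()


@dataclass
class MismatchResult:
    """Hydrophobic TM residues left uncovered by the detergent shell."""

    residues: list[int]
    per_residue_sasa: pd.Series  # A^2, frame-averaged
    total_area: float            # A^2
    persistence: pd.Series       # detergent-contact frequency per TM residue


def residual_mismatch(
    ensemble: AnnotatedEnsemble,
    tm_spec: SelectionSpec,
    detergent_sel=None,
    persistence_threshold: float = 0.20,
    contact_cutoff_nm: float = 0.45,
    probe_nm: float = 0.14,
    n_sphere_points: int = 960,
    frame_stride: int = 1,
) -> MismatchResult:
    """Residual hydrophobic mismatch area of the transmembrane region.

    Hydrophobic TM residues (Gly, Ala, Pro, Val, Met, Cys, Ile, Trp, Phe,
    Tyr, Leu) whose contact frequency with any detergent atom (head or
    tail) is strictly below ``persistence_threshold`` are collected, and
    their solvent-accessible surface area — protein atoms as occluders —
    is averaged over frames and summed.
    """
    atoms = ensemble.atoms
    prot = ensemble.indices_by_role("protein")
    tm_sel_all = resolve_selection(
        ensemble,
        SelectionSpec(name=tm_spec.name, residue_ranges=tm_spec.residue_ranges),
    )
    tm_prot = np.intersect1d(tm_sel_all, prot)
    tm_rids = np.unique(atoms["residue_id"].to_numpy()[tm_prot])

    if detergent_sel is None:
        detergent_sel = ensemble.indices_by_role(
            "detergent_head", "detergent_tail"
        )
    detergent_sel = np.asarray(detergent_sel, dtype=int)

    if detergent_sel.size:
        contacts = contact_frequency(
            ensemble, tm_prot, detergent_sel, cutoff_nm=contact_cutoff_nm,
            granularity="residue",
        )
        freq_by_res = (
            contacts.table.groupby("entity_a")["frequency"].max()
            if len(contacts.table) else pd.Series(dtype=float)
        )
    else:
        freq_by_res = pd.Series(dtype=float)
    persistence = pd.Series(
        {int(r): float(freq_by_res.get(r, 0.0)) for r in tm_rids}
    )

    res_name_of = dict(
        zip(atoms["residue_id"].to_numpy()[tm_prot],
            atoms["residue_name"].to_numpy()[tm_prot])
    )
    qualifying = [
        int(r) for r in tm_rids
        if res_name_of[r] in HYDROPHOBIC_RESIDUES
        and persistence[int(r)] < persistence_threshold
    ]

    frames = range(0, ensemble.n_frames, max(frame_stride, 1))
    acc: pd.Series | None = None
    n_used = 0
    for f in frames:
        s = sasa(
            ensemble, sel=prot, probe_nm=probe_nm,
            n_sphere_points=n_sphere_points, frame=f,
        )
        acc = s if acc is None else acc.add(s, fill_value=0.0)
        n_used += 1
    mean_sasa = acc / n_used
    per_res = mean_sasa.reindex(qualifying).fillna(0.0)
    return MismatchResult(
        residues=qualifying,
        per_residue_sasa=per_res,
        total_area=float(per_res.sum()),
        persistence=persistence,
    )
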