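"""Geometric trajectory metrics: RMSD, RMSF, shape, RDF, occupancy, helicity."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from ..ensemble import AnnotatedEnsemble, SelectionSpec, resolve_selection

__all__ = [
    "kabsch",
    "superpose",
    "rmsd",
    "rmsf",
    "ShapeResult",
    "micelle_shape",
    "RDFCurve",
    "rdf_from_core",
    "RDFResult",
    "detergent_rdf",
    "OccupancyGrid",
    "spatial_occupancy",
    "helicity_fraction",
    "helicity_vs_rmsd",
]


# ---------------------------------------------------------------------------
# superposition / RMSD / RMSF
# ---------------------------------------------------------------------------


def kabsch(mobile: np.ndarray, ref: np.ndarray):
    """Optimal rigid-body alignment of ``mobile`` onto ``ref``.

    Returns ``(R, t)`` such that ``mobile @ R.T + t`` is the least-squares
    superposition (Kabsch, via scipy's quaternion solver).
    """
    mc = mobile.mean(axis=0)
    rc = ref.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref - rc, mobile - mc)
    R = rot.as_matrix()
    t = rc - mc @ R.T
    return R, t


def superpose(coords: np.ndarray, ref: np.ndarray, fit_idx=None) -> np.ndarray:
    """Superpose frames onto ``ref`` using atoms ``fit_idx`` for the fit.

    ``coords`` has shape ``(n_frames, n_atoms, 3)`` (a single frame is
    allowed); the transform fitted on ``fit_idx`` is applied to all atoms.
    """
    single = coords.ndim == 2
    frames = coords[None] if single else coords
    if fit_idx is None:
        fit_idx = np.arange(frames.shape[1])
    out = np.empty_like(frames)
    for f in range(frames.shape[0]):
        R, t = kabsch(frames[f, fit_idx], ref[fit_idx])
        out[f] = frames[f] @ R.T + t
    return out[0] if single else out


def rmsd(frame: np.ndarray, ref: np.ndarray, sel=None, superpose_first: bool = True) -> float:
    """RMS deviation (nm) of ``frame`` from ``ref`` over selection ``sel``.

    With ``superpose_first`` the optimal rigid-body fit on the selection
    precedes the RMS; otherwise the raw displacement RMS is returned.
    """
    frame = np.asarray(frame, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if frame.shape != ref.shape:
        raise ValueError(
            f"frame and reference differ in size: {frame.shape} vs {ref.shape}"
        )
    if sel is None:
        sel = np.arange(frame.shape[0])
    a, b = frame[sel], ref[sel]
    if a.shape != b.shape:
        raise ValueError(
            f"selection sizes differ: {a.shape[0]} vs {b.shape[0]} atoms"
        )
    if superpose_first:
        R, t = kabsch(a, b)
        a = a @ R.T + t
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def rmsf(
    ensemble: AnnotatedEnsemble,
    sel=None,
    superpose_sel=None,
    superpose_first: bool = True,
) -> np.ndarray:
    """Per-atom RMS fluctuation (nm) about the mean structure.

    Frames are first superposed (on ``superpose_sel``, defaulting to the
    protein atoms, else to ``sel``) onto frame 0 and then onto the
    resulting mean structure, after which the fluctuation of each selected
    atom about its mean position is evaluated.  ``superpose_first=False``
    skips alignment, giving the raw closed-form fluctuation.
    """
    if ensemble.n_frames < 2:
        raise ValueError("RMSF needs at least two frames")
    if sel is None:
        sel = np.arange(ensemble.n_atoms)
    sel = np.asarray(sel, dtype=int)
    coords = ensemble.coords
    if superpose_first:
        if superpose_sel is None:
            prot = ensemble.indices_by_role("protein")
            superpose_sel = prot if prot.size >= 3 else sel
        aligned = superpose(coords, coords[0], fit_idx=superpose_sel)
        aligned = superpose(aligned, aligned.mean(axis=0), fit_idx=superpose_sel)
    else:
        aligned = coords
    x = aligned[:, sel]
    mean = x.mean(axis=0)
    return np.sqrt(np.mean(np.sum((x - mean) ** 2, axis=2), axis=0))


# ---------------------------------------------------------------------------
# micelle shape
# ---------------------------------------------------------------------------


@dataclass
class ShapeResult:
    """Gyration-tensor shape: eigenvalues (nm^2, descending), principal
    axes lengths (2*sqrt(eigenvalue), nm) and eccentricity = shortest axis
    over longest axis (1 = sphere)."""

    eigenvalues: np.ndarray
    axes: np.ndarray
    eccentricity: float
    degenerate: bool = False


def micelle_shape(coords, sel=None, frame: int = 0, masses=None) -> ShapeResult:
    """Shape of a selection from the mass-weighted gyration tensor.

    ``coords`` may be an :class:`AnnotatedEnsemble` (with ``sel`` and
    ``frame``) or a plain ``(n, 3)`` array in nm.  A collinear point set
    is reported as ``eccentricity = 0`` with the ``degenerate`` flag set.
    """
    if isinstance(coords, AnnotatedEnsemble):
        ens = coords
        if sel is None:
            sel = ens.indices_by_role("detergent_head", "detergent_tail")
        xyz = ens.coords[frame, sel]
        if masses is None:
            masses = ens.masses()[np.asarray(sel, dtype=int)]
    else:
        xyz = np.asarray(coords, dtype=float)
        if sel is not None:
            xyz = xyz[sel]
    if xyz.shape[0] < 4:
        raise ValueError("shape analysis needs at least 4 points")
    w = np.ones(xyz.shape[0]) if masses is None else np.asarray(masses, dtype=float)
    com = (w[:, None] * xyz).sum(axis=0) / w.sum()
    d = xyz - com
    gyr = (w[:, None, None] * d[:, :, None] * d[:, None, :]).sum(axis=0) / w.sum()
    evals = np.linalg.eigvalsh(gyr)[::-1]  # descending
    evals = np.clip(evals, 0.0, None)
    axes = 2.0 * np.sqrt(evals)
    if evals[0] <= 0:
        return ShapeResult(evals, axes, 0.0, degenerate=True)
    if evals[1] / evals[0] < 1e-10:  # collinear
        return ShapeResult(evals, axes, 0.0, degenerate=True)
    ecc = float(np.sqrt(evals[2] / evals[0]))
    return ShapeResult(evals, axes, ecc)


# ---------------------------------------------------------------------------
# radial distribution function
# ---------------------------------------------------------------------------


@dataclass
class RDFCurve:
    """g(r) for one shell selection around a core center of mass."""

    r: np.ndarray          # bin centers, nm
    g: np.ndarray          # dimensionless
    counts: np.ndarray     # mean raw counts per bin (diagnostic)
    auc_2nm: float         # trapezoid integral of g over r <= 2 nm


def rdf_from_core(
    ensemble: AnnotatedEnsemble,
    core_sel,
    shell_sel,
    bin_nm: float = 0.02,
    r_max: float = 3.5,
) -> RDFCurve:
    """Radial distribution of shell atoms around the core center of mass.

    Per frame, shell-atom distances from the (mass-weighted) core COM are
    histogrammed and normalised per bin by the spherical shell volume
    ``4 pi r^2 dr`` and by the mean number density of the shell selection
    inside the analysis sphere of radius ``r_max``; frames are averaged
    with equal weight.  With this ideal-gas convention a uniformly filling
    selection gives g(r) = 1 and a uniform rescaling of the shell atom
    count leaves g unchanged.
    """
    if bin_nm <= 0:
        raise ValueError("bin_nm must be > 0")
    core_sel = np.asarray(core_sel, dtype=int)
    shell_sel = np.asarray(shell_sel, dtype=int)
    if core_sel.size == 0 or shell_sel.size == 0:
        raise ValueError("core and shell selections must be non-empty")
    n_bins = int(np.ceil(r_max / bin_nm))
    edges = np.arange(n_bins + 1) * bin_nm
    centers = 0.5 * (edges[:-1] + edges[1:])
    shell_vol = 4.0 * np.pi * centers**2 * bin_nm
    sphere_vol = 4.0 / 3.0 * np.pi * r_max**3
    masses = ensemble.masses()[core_sel]

    g_acc = np.zeros(n_bins)
    c_acc = np.zeros(n_bins)
    used = 0
    for f in range(ensemble.n_frames):
        core = ensemble.coords[f, core_sel]
        com = (masses[:, None] * core).sum(axis=0) / masses.sum()
        d = np.linalg.norm(ensemble.coords[f, shell_sel] - com, axis=1)
        inside = d[d <= r_max]
        counts, _ = np.histogram(inside, bins=edges)
        if inside.size == 0:
            continue
        rho = inside.size / sphere_vol
        g_acc += counts / shell_vol / rho
        c_acc += counts
        used += 1
    if used == 0:
        raise ValueError("no shell atoms inside the analysis sphere in any frame")
    g = g_acc / used
    counts_mean = c_acc / used
    mask = centers <= 2.0
    auc = float(np.trapezoid(g[mask], centers[mask]))
    return RDFCurve(centers, g, counts_mean, auc)


@dataclass
class RDFResult:
    """Head and tail detergent RDFs around the receptor core."""

    r: np.ndarray
    g_head: np.ndarray
    g_tail: np.ndarray
    auc_head_2nm: float
    auc_tail_2nm: float


def detergent_rdf(
    ensemble: AnnotatedEnsemble,
    core_sel=None,
    bin_nm: float = 0.02,
    r_max: float = 3.5,
) -> RDFResult:
    """Head/tail RDFs of the detergent around the protein center of mass."""
    if core_sel is None:
        core_sel = ensemble.indices_by_role("protein")
    head = ensemble.indices_by_role("detergent_head")
    tail = ensemble.indices_by_role("detergent_tail")
    gh = rdf_from_core(ensemble, core_sel, head, bin_nm, r_max)
    gt = rdf_from_core(ensemble, core_sel, tail, bin_nm, r_max)
    return RDFResult(gh.r, gh.g, gt.g, gh.auc_2nm, gt.auc_2nm)


# ---------------------------------------------------------------------------
# spatial occupancy
# ---------------------------------------------------------------------------


@dataclass
class OccupancyGrid:
    """Voxelised frame-occupancy counts in the receptor frame of reference."""

    origin: np.ndarray     # nm, corner of voxel (0,0,0)
    voxel_nm: float
    counts: np.ndarray     # 3-D integer array; frames in which any atom hit

    @property
    def occupied_voxels(self) -> int:
        return int(np.count_nonzero(self.counts))

    @property
    def total_occupancy(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        idx = np.argwhere(self.counts > 0)
        xyz = self.origin + (idx + 0.5) * self.voxel_nm
        return pd.DataFrame(
            {"x": xyz[:, 0], "y": xyz[:, 1], "z": xyz[:, 2],
             "count": self.counts[tuple(idx.T)]}
        )


def spatial_occupancy(
    ensemble: AnnotatedEnsemble,
    molecule_sel,
    voxel_nm: float,
    superpose_sel=None,
) -> OccupancyGrid:
    """Count, per voxel, the frames in which any selected atom falls in it.

    Frames are first superposed on ``superpose_sel`` (default: protein
    atoms, if any) so the grid lives in the receptor frame of reference.
    """
    if voxel_nm <= 0:
        raise ValueError("voxel_nm must be > 0")
    molecule_sel = np.asarray(molecule_sel, dtype=int)
    coords = ensemble.coords
    if superpose_sel is None:
        prot = ensemble.indices_by_role("protein")
        superpose_sel = prot if prot.size >= 3 else None
    if superpose_sel is not None:
        coords = superpose(coords, coords[0], fit_idx=superpose_sel)
    x = coords[:, molecule_sel]
    lo = x.reshape(-1, 3).min(axis=0)
    idx_all = np.floor((x - lo) / voxel_nm).astype(int)
    shape = idx_all.reshape(-1, 3).max(axis=0) + 1
    counts = np.zeros(shape, dtype=int)
    for f in range(ensemble.n_frames):
        vox = np.unique(idx_all[f], axis=0)
        counts[tuple(vox.T)] += 1
    return OccupancyGrid(origin=lo, voxel_nm=voxel_nm, counts=counts)


# ---------------------------------------------------------------------------
# helicity
# ---------------------------------------------------------------------------


def _dihedrals(p0, p1, p2, p3):
    """Signed dihedral angles (deg) for stacked coordinate quadruples."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    v = b0 - np.sum(b0 * b1n, axis=-1, keepdims=True) * b1n
    w = b2 - np.sum(b2 * b1n, axis=-1, keepdims=True) * b1n
    x = np.sum(v * w, axis=-1)
    y = np.sum(np.cross(b1n, v) * w, axis=-1)
    return np.degrees(np.arctan2(y, x))


#: Ramachandran window used as the helicity surrogate criterion.
PHI_WINDOW = (-100.0, -30.0)
PSI_WINDOW = (-80.0, -5.0)
MIN_HELIX_RUN = 4


def helicity_fraction(
    ensemble: AnnotatedEnsemble, tm_spec: SelectionSpec
) -> np.ndarray:
    """Fraction of TM residues in helical conformation, per frame.

    A residue counts as helical when its backbone dihedrals fall in the
    alpha window (phi in (-100, -30), psi in (-80, -5) deg) within a run
    of at least four consecutive such residues of the same helix range.
    Residues whose phi or psi is undefined (helix termini) never count.
    """
    atoms = ensemble.atoms
    # index backbone atoms per residue
    bb: dict[int, dict[str, int]] = {}
    for i, (rid, name) in enumerate(zip(atoms["residue_id"], atoms["atom_name"])):
        if name in ("N", "CA", "C"):
            bb.setdefault(int(rid), {})[name] = i

    ranges = tm_spec.residue_ranges
    tm_residues = [
        rid for lo, hi in ranges for rid in range(lo, hi + 1)
    ]
    missing = [
        rid for rid in tm_residues
        if set(bb.get(rid, {})) != {"N", "CA", "C"}
    ]
    if missing:
        raise ValueError(
            f"missing backbone N/CA/C atoms for residues {missing[:10]}"
            + ("..." if len(missing) > 10 else "")
        )

    n_total = len(tm_residues)
    fractions = np.zeros(ensemble.n_frames)
    for f in range(ensemble.n_frames):
        xyz = ensemble.coords[f]
        n_helical = 0
        for lo, hi in ranges:
            rids = list(range(lo, hi + 1))
            flags = np.zeros(len(rids), dtype=bool)
            for k, rid in enumerate(rids):
                prev_ok = rid - 1 in bb and rid - 1 >= lo
                next_ok = rid + 1 in bb and rid + 1 <= hi
                if not (prev_ok and next_ok):
                    continue
                phi = _dihedrals(
                    xyz[bb[rid - 1]["C"]], xyz[bb[rid]["N"]],
                    xyz[bb[rid]["CA"]], xyz[bb[rid]["C"]],
                )
                psi = _dihedrals(
                    xyz[bb[rid]["N"]], xyz[bb[rid]["CA"]],
                    xyz[bb[rid]["C"]], xyz[bb[rid + 1]["N"]],
                )
                flags[k] = (
                    PHI_WINDOW[0] < phi < PHI_WINDOW[1]
                    and PSI_WINDOW[0] < psi < PSI_WINDOW[1]
                )
            # keep only runs of >= MIN_HELIX_RUN consecutive helical residues
            run = 0
            for k in range(len(flags) + 1):
                if k < len(flags) and flags[k]:
                    run += 1
                else:
                    if 0 < run < MIN_HELIX_RUN:
                        flags[k - run : k] = False
                    run = 0
            n_helical += int(flags.sum())
        fractions[f] = n_helical / n_total if n_total else 0.0
    return fractions


def helicity_vs_rmsd(
    ensemble: AnnotatedEnsemble,
    tm_spec: SelectionSpec,
    ref: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-frame (helicity, TM-backbone RMSD) pairs for 2-D summaries."""
    sel = resolve_selection(ensemble, tm_spec)
    if ref is None:
        ref = ensemble.coords[0]
    hel = helicity_fraction(ensemble, tm_spec)
    rms = np.array(
        [rmsd(ensemble.coords[f], ref, sel=sel) for f in range(ensemble.n_frames)]
    )
    return pd.DataFrame(
        {"frame": np.arange(ensemble.n_frames), "time_ns": ensemble.times,
         "helicity": hel, "rmsd_nm": rms}
    )
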