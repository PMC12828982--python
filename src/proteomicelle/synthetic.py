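"""Synthetic inputs with the statistical structure the analysis expects.

Three generators cover the pipeline end to end without any external data:

* :func:`gen_melt` — noisy six-parameter Boltzmann melts on a dense
  temperature ramp (default 5-100 deg C at 0.2 deg C, Gaussian noise);
* :func:`gen_binding` — quadratic-depletion dose series;
* :func:`gen_bundle` / :func:`gen_proteomicelle` — a seven-helix ideal
  bundle wrapped in a coarse-bead detergent shell with tunable packing
  radius, per-frame mobility, and per-detergent contact persistence.

Detergents are coarse bead chains (four tail beads inner, two head beads
outer) rather than all-atom maltosides: every downstream metric — RDF,
RMSF, contacts, interaction energy with the supplied parameters,
hydrophobic mismatch — is exercised identically at desk scale.  All
generators are deterministic functions of (spec, seed); per-detergent
randomness uses spawned substreams so reproducibility does not depend on
iteration order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .ensemble import AnnotatedEnsemble, SelectionSpec
from .io import CurveTable
from .melt import boltzmann6
from .binding import bound_fraction

__all__ = [
    "MeltSimSpec",
    "MicelleSimSpec",
    "gen_melt",
    "gen_binding",
    "gen_bundle",
    "gen_proteomicelle",
    "BundleResult",
    "micelle_series",
]

BACKBONE = ("N", "CA", "C", "O")

# mostly-hydrophobic repeat, as in a transmembrane segment
_SEQ_PATTERN = ("LEU", "ALA", "VAL", "PHE", "ILE", "LEU", "SER", "ALA",
                "GLY", "MET")

# CHARMM-like backbone partial charges (e) and LJ parameters (kJ/mol, nm)
_BB_PARAMS = {
    "N": (-0.47, 0.83680, 0.329633),
    "CA": (0.07, 0.23012, 0.356359),
    "C": (0.51, 0.46024, 0.356359),
    "O": (-0.51, 0.50208, 0.302906),
}


# ---------------------------------------------------------------------------
# curve generators
# ---------------------------------------------------------------------------


@dataclass
class MeltSimSpec:
    """Specification of one synthetic melt curve.

    ``params`` holds the six Boltzmann parameters (see
    :mod:`proteomicelle.melt`); the default grid mimics a CD temperature
    ramp from 5 to 100 deg C at 0.2 deg C intervals.
    """

    params: Mapping[str, float]
    temperature_grid: np.ndarray = field(
        default_factory=lambda: np.arange(5.0, 100.0 + 1e-9, 0.2)
    )
    noise_sd: float = 0.02
    seed: int = 0
    detergent: str = ""
    state: str = ""
    replicate: str | int = 0

    def __post_init__(self) -> None:
        self.temperature_grid = np.asarray(self.temperature_grid, dtype=float)
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if np.any(np.diff(self.temperature_grid) <= 0):
            raise ValueError("temperature grid must be strictly increasing")


def gen_melt(spec: MeltSimSpec) -> CurveTable:
    """Noisy Boltzmann melt: model evaluation plus seeded Gaussian noise."""
    rng = np.random.default_rng(spec.seed)
    y = boltzmann6(spec.temperature_grid, **dict(spec.params))
    if spec.noise_sd > 0:
        y = y + rng.normal(0.0, spec.noise_sd, size=y.shape)
    return CurveTable(
        spec.temperature_grid.copy(), y, detergent=spec.detergent,
        state=spec.state, replicate=spec.replicate, kind="melt",
    )


def gen_binding(
    kd: float,
    rmax: float,
    ns: float,
    lt: float,
    rt_grid: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
    detergent: str = "",
    state: str = "",
    replicate: str | int = 0,
) -> CurveTable:
    """Quadratic-depletion dose series: ``rmax*f(rt) + ns*rt`` plus noise."""
    if kd <= 0:
        raise ValueError("kd must be > 0")
    if lt < 0:
        raise ValueError("lt must be >= 0")
    rng = np.random.default_rng(seed)
    rt = np.asarray(rt_grid, dtype=float)
    y = rmax * bound_fraction(rt, lt, kd) + ns * rt
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=y.shape)
    return CurveTable(
        rt, y, detergent=detergent, state=state, replicate=replicate,
        kind="binding",
    )


# ---------------------------------------------------------------------------
# helical bundle
# ---------------------------------------------------------------------------


def _extend(a, b, c, bond, angle_deg, dihedral_deg):
    """Place atom d given three predecessors and internal coordinates."""
    angle = np.deg2rad(angle_deg)
    dihedral = np.deg2rad(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(angle),
            bond * np.sin(angle) * np.cos(dihedral),
            bond * np.sin(angle) * np.sin(dihedral),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _ideal_helix(n_res: int, phi: float = -63.0, psi: float = -42.0):
    """Backbone N/CA/C/O of an ideal alpha-helix, axis along z, in nm.

    Built by natural-extension from standard bond geometry with the given
    backbone dihedrals (omega fixed at 180 deg); the alpha-helical values
    produce a rise close to 0.15 nm/residue and ~100 deg twist.
    """
    n_ca, ca_c, c_n, c_o = 0.1458, 0.1525, 0.1329, 0.1231
    ang_nca_c, ang_cac_n, ang_cn_ca = 111.2, 116.2, 121.7

    N = np.zeros((n_res, 3))
    CA = np.zeros((n_res, 3))
    C = np.zeros((n_res, 3))
    N[0] = [0.0, 0.0, 0.0]
    CA[0] = [n_ca, 0.0, 0.0]
    ang = np.deg2rad(ang_nca_c)
    C[0] = CA[0] + ca_c * np.array([-np.cos(ang), np.sin(ang), 0.0])
    for i in range(1, n_res):
        N[i] = _extend(N[i - 1], CA[i - 1], C[i - 1], c_n, ang_cac_n, psi)
        CA[i] = _extend(CA[i - 1], C[i - 1], N[i], n_ca, ang_cn_ca, 180.0)
        C[i] = _extend(C[i - 1], N[i], CA[i], ca_c, ang_nca_c, phi)
    O = np.zeros((n_res, 3))
    for i in range(n_res):
        nxt = N[i + 1] if i + 1 < n_res else _extend(
            N[i], CA[i], C[i], c_n, ang_cac_n, psi
        )
        # carbonyl O opposite the next amide N in the peptide plane
        O[i] = _extend(nxt, CA[i], C[i], c_o, 122.5, 180.0)

    # rotate the principal axis of the CA trace onto z
    ca_c0 = CA - CA.mean(axis=0)
    _, _, vt = np.linalg.svd(ca_c0, full_matrices=False)
    axis = vt[0]
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis, z)
    s, c = np.linalg.norm(v), float(axis @ z)
    if s > 1e-12:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        R = np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)
    else:
        R = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    center = CA.mean(axis=0)
    out = {}
    for name, arr in (("N", N), ("CA", CA), ("C", C), ("O", O)):
        out[name] = (arr - center) @ R.T
    return out


# ---------------------------------------------------------------------------
# proteomicelle
# ---------------------------------------------------------------------------


@dataclass
class MicelleSimSpec:
    """Toy proteomicelle: bundle geometry, shell packing, and dynamics.

    ``packing_radius`` (nm) is the radius of the detergent shell measured
    from the bundle's center of mass; ``mobility_sd`` the per-frame
    Gaussian step of each detergent (nm); ``persistence_profile`` an
    optional per-detergent target protein-contact fraction in [0, 1]
    (scalar broadcast allowed).  With a profile, each frame places each
    detergent either against the protein surface or out at the shell by a
    seeded Bernoulli draw, so empirical contact persistence tracks the
    target within sampling error.  Without a profile detergents only
    jitter about their shell anchor, so ``mobility_sd = 0`` gives exactly
    zero detergent RMSF.
    """

    n_helices: int = 7
    helix_length: int = 24
    n_detergent: int = 48
    head_fraction: float = 1.0 / 3.0
    packing_radius: float = 2.5
    mobility_sd: float = 0.02
    n_frames: int = 25
    persistence_profile: float | Sequence[float] | None = None
    seed: int = 0
    # geometry knobs
    ring_radius: float = 1.1
    beads_per_detergent: int = 6
    bead_spacing: float = 0.18
    shell_width: float = 0.6
    contact_gap: float = 0.30

    def __post_init__(self) -> None:
        if self.n_detergent < 0:
            raise ValueError("n_detergent must be >= 0")
        if not 0.0 <= self.head_fraction <= 1.0:
            raise ValueError("head_fraction must be in [0, 1]")
        if self.mobility_sd < 0:
            raise ValueError("mobility_sd must be >= 0")
        if self.persistence_profile is not None:
            prof = np.broadcast_to(
                np.asarray(self.persistence_profile, dtype=float),
                (self.n_detergent,),
            ).copy()
            if np.any((prof < 0) | (prof > 1)):
                raise ValueError("persistence_profile values must be in [0, 1]")
            self.persistence_profile = prof

    @property
    def n_head_beads(self) -> int:
        return int(round(self.beads_per_detergent * self.head_fraction))

    @property
    def n_tail_beads(self) -> int:
        return self.beads_per_detergent - self.n_head_beads


class BundleResult(NamedTuple):
    ensemble: AnnotatedEnsemble
    tm_spec: SelectionSpec


def gen_bundle(spec: MicelleSimSpec) -> BundleResult:
    """Ideal alpha-helical bundle on a ring (single frame).

    Each helix contributes ``helix_length`` residues with backbone
    N/CA/C/O atoms; residue ids run consecutively helix after helix and
    the emitted TM selection lists one inclusive range per helix.
    """
    helix = _ideal_helix(spec.helix_length)
    rows = []
    coords = []
    ranges = []
    rid = 0
    atom_id = 1
    for h in range(spec.n_helices):
        theta = 2.0 * np.pi * h / max(spec.n_helices, 1)
        shift = np.array(
            [spec.ring_radius * np.cos(theta), spec.ring_radius * np.sin(theta), 0.0]
        )
        first_rid = rid + 1
        for i in range(spec.helix_length):
            rid += 1
            res_name = _SEQ_PATTERN[i % len(_SEQ_PATTERN)]
            for name in BACKBONE:
                q, eps, sig = _BB_PARAMS[name]
                rows.append(
                    {
                        "atom_id": atom_id,
                        "atom_name": name,
                        "element": name[0],
                        "residue_name": res_name,
                        "residue_id": rid,
                        "chain": chr(ord("A") + h % 26),
                        "role": "protein",
                        "charge": q,
                        "lj_epsilon": eps,
                        "lj_sigma": sig,
                    }
                )
                coords.append(helix[name][i] + shift)
                atom_id += 1
        ranges.append((first_rid, rid))
    atoms = pd.DataFrame(rows)
    xyz = np.asarray(coords)[None]  # one frame
    xyz = xyz - xyz[0].mean(axis=0)  # bundle COM at the origin
    ens = AnnotatedEnsemble(atoms, xyz)
    tm_spec = SelectionSpec(
        name="TM", residue_ranges=ranges, atom_name_filter=list(BACKBONE)
    )
    return BundleResult(ens, tm_spec)


def _sphere_directions(
    rng: np.random.Generator, n: int, belt_bias: float = 0.5
) -> np.ndarray:
    """Quasi-uniform directions compressed toward the equator.

    ``belt_bias`` scales the z-component before renormalisation; values
    below 1 concentrate detergents into a belt around the transmembrane
    region, the way a micelle wraps the hydrophobic span rather than the
    helix ends.
    """
    v = rng.normal(size=(n, 3))
    v[:, 2] *= belt_bias
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _reflect(r: float, lo: float, hi: float) -> float:
    """Reflect a radial coordinate into [lo, hi]."""
    if hi <= lo:
        return lo
    span = hi - lo
    t = (r - lo) % (2.0 * span)
    return lo + (t if t <= span else 2.0 * span - t)


def gen_proteomicelle(spec: MicelleSimSpec) -> BundleResult:
    """Helical bundle plus a dynamic coarse-bead detergent shell.

    Each detergent is a radial chain of tail beads (inner) and head beads
    (outer) anchored on a direction drawn uniformly on the sphere.  Frames
    perturb each detergent anchor by Gaussian steps of ``mobility_sd``
    (radially reflected at the shell boundaries); an optional
    ``persistence_profile`` toggles each detergent between a
    protein-contact position and the shell with the target frequency.
    """
    bundle, tm_spec = gen_bundle(spec)
    prot_xyz = bundle.coords[0]
    n_frames = spec.n_frames

    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(spec.n_detergent + 1)
    rng_dir = np.random.default_rng(children[0])
    dirs = _sphere_directions(rng_dir, max(spec.n_detergent, 1))

    rows = []
    det_coords = np.zeros((n_frames, spec.n_detergent * spec.beads_per_detergent, 3))
    atom_id = int(bundle.atoms["atom_id"].max()) if len(bundle.atoms) else 0
    rid = int(bundle.atoms["residue_id"].max()) if len(bundle.atoms) else 0
    shell_lo = spec.packing_radius - spec.shell_width / 2.0
    shell_hi = spec.packing_radius + spec.shell_width / 2.0

    for d in range(spec.n_detergent):
        rng = np.random.default_rng(children[d + 1])
        u = dirs[d]
        # contact point: just past the outermost protein atom lying near the
        # ray from the bundle COM along u, so the anchor stays on the ray
        proj = prot_xyz @ u
        perp = np.sqrt(np.maximum(np.sum(prot_xyz**2, axis=1) - proj**2, 0.0))
        near_ray = (perp <= 0.25) & (proj > 0)
        if near_ray.any():
            j_sup = int(np.argmax(np.where(near_ray, proj, -np.inf)))
            gap = float(
                np.sqrt(max(spec.contact_gap**2 - perp[j_sup] ** 2, 0.01))
            )
            contact_anchor = (float(proj[j_sup]) + gap) * u
        else:
            # ray misses the bundle (e.g. grazes an inter-helix groove):
            # anchor directly off the least-distant atom instead
            cand = np.flatnonzero(proj > 0)
            j_sup = int(cand[np.argmin(perp[cand])])
            contact_anchor = prot_xyz[j_sup] + spec.contact_gap * u
        r_contact = float(np.linalg.norm(contact_anchor))
        u_ray = contact_anchor / max(r_contact, 1e-12)
        # detached position: radially outward along the same ray, so a
        # persistence toggle moves the detergent along one direction only;
        # extend until genuinely clear of the whole bundle (grooves can keep
        # an outward-shifted anchor near a neighbouring helix)
        detach = max(spec.packing_radius - r_contact, 0.35)
        far_anchor = contact_anchor + detach * u_ray
        for _ in range(20):
            if np.min(np.linalg.norm(prot_xyz - far_anchor, axis=1)) > 0.60:
                break
            detach += 0.2
            far_anchor = contact_anchor + detach * u_ray
        r_far = max(spec.packing_radius, float(np.max(proj)) + 0.6)

        rid += 1
        for b in range(spec.beads_per_detergent):
            is_head = b >= spec.n_tail_beads
            atom_id += 1
            rows.append(
                {
                    "atom_id": atom_id,
                    "atom_name": (f"H{b - spec.n_tail_beads + 1}" if is_head
                                  else f"T{b + 1}"),
                    "element": "O" if is_head else "C",
                    "residue_name": "DTG",
                    "residue_id": rid,
                    "chain": "X",
                    "role": "detergent_head" if is_head else "detergent_tail",
                    "charge": (0.25 if (is_head and (b - spec.n_tail_beads) % 2 == 0)
                               else (-0.25 if is_head else 0.0)),
                    "lj_epsilon": 0.65 if is_head else 0.45,
                    "lj_sigma": 0.31 if is_head else 0.35,
                }
            )

        anchor = r_far * u
        drift = np.zeros(3)
        prof = spec.persistence_profile
        for f in range(n_frames):
            if prof is not None:
                # Bernoulli placement realises the target contact fraction;
                # jitter is per-frame (not a walk) so it cannot drift a
                # detergent out of its contact position.
                in_contact = rng.random() < prof[d]
                base = contact_anchor if in_contact else far_anchor
                jitter = (rng.normal(0.0, spec.mobility_sd, size=3)
                          if spec.mobility_sd > 0 else 0.0)
                pos = base + jitter
            else:
                if spec.mobility_sd > 0:
                    drift = drift + rng.normal(0.0, spec.mobility_sd, size=3)
                pos = anchor + drift
                # keep the micelle intact: reflect the radius into the shell
                r = float(np.linalg.norm(pos))
                if r > 1e-12:
                    pos = pos * (_reflect(r, shell_lo, shell_hi) / r)
            ru = pos / max(float(np.linalg.norm(pos)), 1e-12)
            for b in range(spec.beads_per_detergent):
                det_coords[f, d * spec.beads_per_detergent + b] = (
                    pos + b * spec.bead_spacing * ru
                )

    atoms = pd.concat(
        [bundle.atoms, pd.DataFrame(rows)], ignore_index=True
    ) if rows else bundle.atoms
    prot_stack = np.repeat(prot_xyz[None], n_frames, axis=0)
    coords = (
        np.concatenate([prot_stack, det_coords], axis=1) if rows else prot_stack
    )
    times = np.arange(n_frames, dtype=float)
    ens = AnnotatedEnsemble(atoms, coords, times=times)
    return BundleResult(ens, tm_spec)


def micelle_series(seed: int = 0, n_frames: int = 25) -> dict[str, MicelleSimSpec]:
    """Toy stand-ins for the DM / DDM / LMNG proteomicelles.

    The series encodes the qualitative detergent chemistry: DM forms the
    loosest, most mobile shell with almost no persistent protein contacts;
    DDM is intermediate, with a mixed population of transient and
    persistent molecules; LMNG forms the tightest, least mobile and most
    persistent shell.  Contact-persistence targets straddle the 20%
    mismatch threshold, so residual hydrophobic mismatch decreases along
    the series while near-protein RDF density increases.
    """
    base = dict(n_helices=7, helix_length=24, n_detergent=48, n_frames=n_frames)
    ddm_profile = np.tile([0.1, 0.9], 24)  # mixed transient/persistent pool
    return {
        "DM": MicelleSimSpec(
            packing_radius=2.8, mobility_sd=0.05,
            persistence_profile=0.12, seed=seed, **base,
        ),
        "DDM": MicelleSimSpec(
            packing_radius=2.5, mobility_sd=0.03,
            persistence_profile=ddm_profile, seed=seed + 1, **base,
        ),
        "LMNG": MicelleSimSpec(
            packing_radius=2.1, mobility_sd=0.015,
            persistence_profile=0.95, seed=seed + 2, **base,
        ),
    }
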