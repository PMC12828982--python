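"""Pairwise nonbonded interaction energies (Lennard-Jones + Coulomb).

Short-range energies between two atom groups with a plain distance cutoff
(default 1.2 nm), Lorentz-Berthelot combination rules, and no switching
function or long-range corrections: the decomposition contract of an MD
"short-range" energy report, not a reimplementation of an MD engine.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from ..ensemble import AnnotatedEnsemble

__all__ = ["COULOMB_CONSTANT", "EnergyBreakdown", "interaction_energy"]

#: f = 1/(4 pi eps0) in kJ mol^-1 nm e^-2
COULOMB_CONSTANT = 138.935458


@dataclass
class EnergyBreakdown:
    """LJ + Coulomb energies (kJ/mol) between two groups at one frame."""

    e_lj: float
    e_coul: float
    timepoint: float = 0.0

    @property
    def e_total(self) -> float:
        return self.e_lj + self.e_coul


def _require_params(ensemble: AnnotatedEnsemble, idx: np.ndarray, label: str):
    at = ensemble.atoms.iloc[idx]
    bad = at[
        at["charge"].isna() | at["lj_epsilon"].isna() | at["lj_sigma"].isna()
    ]
    if len(bad):
        ids = bad["atom_id"].tolist()[:10]
        raise ValueError(
            f"group {label}: atoms lacking charge/LJ parameters "
            f"(atom_id {ids}{'...' if len(bad) > 10 else ''}); energies are "
            "not computed with silently zeroed parameters"
        )


def interaction_energy(
    ensemble: AnnotatedEnsemble,
    group_a,
    group_b,
    cutoff_nm: float = 1.2,
    frame: int = 0,
) -> EnergyBreakdown:
    """Short-range LJ + Coulomb energy between two disjoint atom groups.

    e_coul = sum f q_i q_j / r over pairs with r <= cutoff;
    e_lj = sum 4 eps_ij [(sig_ij/r)^12 - (sig_ij/r)^6], with sigma
    combined arithmetically and epsilon geometrically (Lorentz-Berthelot).
    Pairs beyond the cutoff contribute exactly zero.
    """
    a = np.asarray(group_a, dtype=int)
    b = np.asarray(group_b, dtype=int)
    if np.intersect1d(a, b).size:
        raise ValueError("groups must be disjoint")
    _require_params(ensemble, a, "a")
    _require_params(ensemble, b, "b")

    xa = ensemble.coords[frame, a]
    xb = ensemble.coords[frame, b]
    r = cdist(xa, xb)
    mask = r <= cutoff_nm
    if not mask.any():
        return EnergyBreakdown(0.0, 0.0, timepoint=float(ensemble.times[frame]))

    at = ensemble.atoms
    qa = at["charge"].to_numpy()[a]
    qb = at["charge"].to_numpy()[b]
    ea = at["lj_epsilon"].to_numpy()[a]
    eb = at["lj_epsilon"].to_numpy()[b]
    sa = at["lj_sigma"].to_numpy()[a]
    sb = at["lj_sigma"].to_numpy()[b]

    rij = r[mask]
    ii, jj = np.nonzero(mask)
    qq = qa[ii] * qb[jj]
    eps = np.sqrt(ea[ii] * eb[jj])
    sig = 0.5 * (sa[ii] + sb[jj])

    e_coul = float(np.sum(COULOMB_CONSTANT * qq / rij))
    sr6 = (sig / rij) ** 6
    e_lj = float(np.sum(4.0 * eps * (sr6**2 - sr6)))
    return EnergyBreakdown(e_lj, e_coul, timepoint=float(ensemble.times[frame]))
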