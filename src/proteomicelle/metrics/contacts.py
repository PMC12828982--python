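"""Contact frequencies, persistence counts, and contact-map deltas.

A pair of entities (atoms or residues) is "in contact" in a frame when any
qualifying inter-atom distance is at or below the cutoff (closed
boundary); its frequency is the fraction of frames in contact, pooled
with equal weight per frame when several runs are aggregated.  Persistent
interhelical hydrogen bonds and van der Waals contacts apply a strict
``> threshold`` rule (the printed convention ">40%"), at atom-pair
granularity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from ..ensemble import AnnotatedEnsemble, SelectionSpec

__all__ = [
    "ContactTable",
    "contact_frequency",
    "ligand_contact_delta",
    "persistent_interhelical_contacts",
]

HBOND_DIST_NM = 0.35
HBOND_ANGLE_DEG = 30.0
VDW_DIST_NM = 0.45


@dataclass
class ContactTable:
    """Pairwise contact frequencies over frames.

    ``table`` has columns ``entity_a, entity_b, frequency``; entities are
    atom_ids or residue_ids depending on ``granularity``.
    """

    table: pd.DataFrame
    cutoff_nm: float
    granularity: str  # "atom" | "residue"
    n_frames: int = 0
    meta: dict = field(default_factory=dict)

    def filter(self, threshold: float, strict: bool = True) -> "ContactTable":
        """Pairs above the frequency threshold (strictly, by default)."""
        f = self.table["frequency"]
        kept = self.table[f > threshold if strict else f >= threshold]
        return ContactTable(
            kept.reset_index(drop=True), self.cutoff_nm, self.granularity,
            self.n_frames, dict(self.meta),
        )

    def frequency_of(self, a, b) -> float:
        t = self.table
        hit = t[((t.entity_a == a) & (t.entity_b == b))
                | ((t.entity_a == b) & (t.entity_b == a))]
        return float(hit["frequency"].iloc[0]) if len(hit) else 0.0

    def __len__(self) -> int:
        return len(self.table)


def _frame_pairs(xa, xb, ids_a, ids_b, cutoff):
    """Unique entity pairs with any atom distance <= cutoff in one frame."""
    tree = cKDTree(xb)
    pairs = set()
    neighbours = tree.query_ball_point(xa, cutoff)
    for i, hits in enumerate(neighbours):
        for j in hits:
            pairs.add((ids_a[i], ids_b[j]))
    return pairs


def contact_frequency(
    ensemble: AnnotatedEnsemble,
    group_a,
    group_b,
    cutoff_nm: float = 0.45,
    granularity: str = "residue",
) -> ContactTable:
    """Contact frequency of entity pairs between two atom groups."""
    if cutoff_nm <= 0:
        raise ValueError("cutoff_nm must be > 0")
    if granularity not in ("atom", "residue"):
        raise ValueError("granularity must be 'atom' or 'residue'")
    a = np.asarray(group_a, dtype=int)
    b = np.asarray(group_b, dtype=int)
    key = "atom_id" if granularity == "atom" else "residue_id"
    ids_a = ensemble.atoms[key].to_numpy()[a]
    ids_b = ensemble.atoms[key].to_numpy()[b]

    counts: dict[tuple, int] = {}
    for f in range(ensemble.n_frames):
        for pair in _frame_pairs(
            ensemble.coords[f, a], ensemble.coords[f, b], ids_a, ids_b, cutoff_nm
        ):
            counts[pair] = counts.get(pair, 0) + 1
    rows = [
        {"entity_a": pa, "entity_b": pb, "frequency": c / ensemble.n_frames}
        for (pa, pb), c in sorted(counts.items())
    ]
    table = pd.DataFrame(rows, columns=["entity_a", "entity_b", "frequency"])
    return ContactTable(table, cutoff_nm, granularity, ensemble.n_frames)


def ligand_contact_delta(table_a: ContactTable, table_b: ContactTable) -> pd.DataFrame:
    """Per-pair frequency differences ``a - b`` over the union of pairs.

    Pairs absent from one table count as frequency 0 there, so a contact
    present only in ``a`` appears with a positive delta of its frequency.
    """
    if table_a.granularity != table_b.granularity:
        raise ValueError(
            f"granularity mismatch: {table_a.granularity} vs {table_b.granularity}"
        )
    fa = {(r.entity_a, r.entity_b): r.frequency for r in table_a.table.itertuples()}
    fb = {(r.entity_a, r.entity_b): r.frequency for r in table_b.table.itertuples()}
    rows = []
    for pair in sorted(set(fa) | set(fb)):
        va, vb = fa.get(pair, 0.0), fb.get(pair, 0.0)
        rows.append(
            {"entity_a": pair[0], "entity_b": pair[1],
             "freq_a": va, "freq_b": vb, "delta": va - vb}
        )
    return pd.DataFrame(
        rows, columns=["entity_a", "entity_b", "freq_a", "freq_b", "delta"]
    )


# ---------------------------------------------------------------------------
# interhelical hydrogen bonds and vdW contacts
# ---------------------------------------------------------------------------


def _angle_deg(origin, p, q):
    """Angle at ``origin`` between directions to p and q (deg)."""
    u = p - origin
    v = q - origin
    c = float(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def persistent_interhelical_contacts(
    ensemble: AnnotatedEnsemble,
    tm_spec: SelectionSpec,
    kind: str = "hbond",
    threshold: float = 0.4,
    hbond_dist_nm: float = HBOND_DIST_NM,
    hbond_angle_deg: float = HBOND_ANGLE_DEG,
    vdw_dist_nm: float = VDW_DIST_NM,
):
    """Persistent contacts between residues of *different* TM helices.

    Hydrogen bond: donor-acceptor heavy-atom distance <= 0.35 nm and
    hydrogen-donor-acceptor angle <= 30 deg (donor = N/O with a covalently
    attached hydrogen, acceptor = N/O).  Van der Waals: heavy-atom
    distance <= 0.45 nm, excluding pairs that qualify as hydrogen bonds in
    the same frame.  A pair is persistent when its frequency is strictly
    above ``threshold``.  Returns ``(count, ContactTable)`` at atom-pair
    granularity.
    """
    if kind not in ("hbond", "vdw"):
        raise ValueError("kind must be 'hbond' or 'vdw'")
    atoms = ensemble.atoms
    rid = atoms["residue_id"].to_numpy()
    helix = np.array([
        -1 if tm_spec.helix_of(int(r)) is None else tm_spec.helix_of(int(r))
        for r in rid
    ])
    in_tm = helix >= 0
    elements = atoms["element"].to_numpy()
    is_h = np.char.upper(elements.astype(str)) == "H"
    heavy_tm = np.flatnonzero(in_tm & ~is_h)
    if heavy_tm.size == 0:
        raise ValueError("no TM heavy atoms found")

    # covalent hydrogens: nearest heavy atom of the same residue in frame 0
    h_of: dict[int, list[int]] = {}
    h_idx = np.flatnonzero(is_h & in_tm)
    if h_idx.size:
        x0 = ensemble.coords[0]
        for h in h_idx:
            same_res = np.flatnonzero((rid == rid[h]) & ~is_h)
            if same_res.size == 0:
                continue
            d = np.linalg.norm(x0[same_res] - x0[h], axis=1)
            j = same_res[int(np.argmin(d))]
            if d.min() <= 0.13:
                h_of.setdefault(int(j), []).append(int(h))
    if kind == "hbond" and not h_of:
        raise ValueError(
            "hydrogen bond analysis requested but no hydrogens are present; "
            "use kind='vdw' for heavy-atom contacts only"
        )

    polar = np.isin(np.char.upper(elements.astype(str)), ("N", "O"))
    donors = [i for i in np.flatnonzero(polar & in_tm) if int(i) in h_of]
    acceptors = np.flatnonzero(polar & in_tm)

    atom_ids = atoms["atom_id"].to_numpy()
    hb_counts: dict[tuple, int] = {}
    vdw_counts: dict[tuple, int] = {}
    for f in range(ensemble.n_frames):
        xyz = ensemble.coords[f]
        hb_pairs_frame = set()
        for dnr in donors:
            for acc in acceptors:
                if acc == dnr or helix[acc] == helix[dnr]:
                    continue
                dda = float(np.linalg.norm(xyz[acc] - xyz[dnr]))
                if dda > hbond_dist_nm:
                    continue
                ang = min(
                    _angle_deg(xyz[dnr], xyz[h], xyz[acc]) for h in h_of[int(dnr)]
                )
                if ang <= hbond_angle_deg:
                    pair = tuple(sorted((int(atom_ids[dnr]), int(atom_ids[acc]))))
                    hb_pairs_frame.add(pair)
        for pair in hb_pairs_frame:
            hb_counts[pair] = hb_counts.get(pair, 0) + 1
        if kind == "vdw":
            tree = cKDTree(xyz[heavy_tm])
            for i, j in tree.query_pairs(vdw_dist_nm):
                gi, gj = heavy_tm[i], heavy_tm[j]
                if helix[gi] == helix[gj]:
                    continue
                pair = tuple(sorted((int(atom_ids[gi]), int(atom_ids[gj]))))
                if pair in hb_pairs_frame:
                    continue
                vdw_counts[pair] = vdw_counts.get(pair, 0) + 1

    counts = hb_counts if kind == "hbond" else vdw_counts
    rows = [
        {"entity_a": a, "entity_b": b, "frequency": c / ensemble.n_frames}
        for (a, b), c in sorted(counts.items())
    ]
    table = ContactTable(
        pd.DataFrame(rows, columns=["entity_a", "entity_b", "frequency"]),
        cutoff_nm=hbond_dist_nm if kind == "hbond" else vdw_dist_nm,
        granularity="atom",
        n_frames=ensemble.n_frames,
        meta={"kind": kind, "threshold": threshold},
    )
    persistent = table.filter(threshold, strict=True)
    return len(persistent), persistent
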