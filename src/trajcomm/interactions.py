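"""Per-frame protein–ligand interaction detection and torsion profiling.

Geometric interaction criteria (per frame):

- hydrogen bond: H···acceptor ≤ 2.5 Å, donor angle D–H···A ≥ 120°, and
  acceptor angle X–A···H ≥ 90° for some heavy atom X bonded to A;
- hydrophobic: apolar carbon–carbon contact ≤ 3.6 Å, where an apolar
  carbon has no O/N/S within 1.7 Å (distance-inferred bonding);
- ionic: charged-group centroids ≤ 3.7 Å (carboxylates, Lys/Arg amine
  and guanidinium groups; ligand groups perceived from geometry);
- water bridge: a water simultaneously hydrogen-bonded to protein and
  ligand under relaxed criteria (H···A ≤ 2.8 Å, donor angle ≥ 110°).

Aromatic stacking is subsumed by the hydrophobic ring-carbon contacts;
no separate π–π category is assigned.  Bonds are perceived by distance
on the first frame (X–H ≤ 1.2 Å, heavy–heavy ≤ 1.7 Å).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .io import STANDARD_AA, WATER_NAMES, FrameSeries, Topology

logger = logging.getLogger(__name__)

CATEGORIES = ("hbond", "hydrophobic", "ionic", "water_bridge")

HBOND_HA_MAX = 2.5  # Å
HBOND_DONOR_ANGLE_MIN = 120.0  # degrees, D-H...A
HBOND_ACCEPTOR_ANGLE_MIN = 90.0  # degrees, X-A...H
HYDROPHOBIC_CC_MAX = 3.6  # Å
IONIC_CENTROID_MAX = 3.7  # Å
WATER_HA_MAX = 2.8  # relaxed H-bond distance for water bridges
WATER_DONOR_ANGLE_MIN = 110.0
BOND_XH_MAX = 1.2  # Å, covalent X-H
BOND_HEAVY_MAX = 1.7  # Å, covalent heavy-heavy
DEFAULT_REPORT_THRESHOLD = 0.30

#: Protein charged groups by residue name → atom-name tuples.
_CHARGED_GROUPS = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2"),
}


class TopologyError(ValueError):
    pass


@dataclass(frozen=True)
class InteractionEvent:
    frame: int
    residue: str  # protein residue label, e.g. TYR_334
    ligand_atom: str  # ligand atom name
    category: str

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown interaction category {self.category!r}")


def _bond_lists(topology: Topology, coords0: np.ndarray):
    """Distance-inferred bonded neighbors from the first frame."""
    n = topology.n_atoms
    heavy = np.array([a.is_heavy for a in topology.atoms])
    tree = cKDTree(coords0)
    neighbors: list[list[int]] = [[] for _ in range(n)]
    for i, j in tree.query_pairs(BOND_HEAVY_MAX):
        hi, hj = heavy[i], heavy[j]
        d = np.linalg.norm(coords0[i] - coords0[j])
        if hi and hj:
            neighbors[i].append(j)
            neighbors[j].append(i)
        elif hi != hj and d <= BOND_XH_MAX:
            neighbors[i].append(j)
            neighbors[j].append(i)
    return neighbors


def _angle(a: np.ndarray, vertex: np.ndarray, b: np.ndarray) -> float:
    v1, v2 = a - vertex, b - vertex
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        return 0.0
    cosang = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


class _System:
    """Precomputed atom roles for interaction detection."""

    def __init__(self, topology: Topology, coords0: np.ndarray):
        atoms = topology.atoms
        if any(not a.element for a in atoms):
            raise TopologyError("atoms with missing element information")
        self.topology = topology
        self.neighbors = _bond_lists(topology, coords0)
        self.is_protein = np.array([a.residue_name in STANDARD_AA for a in atoms])
        self.is_water = np.array([a.residue_name in WATER_NAMES for a in atoms])
        self.is_ligand = np.array([a.is_ligand for a in atoms])
        self.res_label = [f"{a.residue_name}_{a.residue_number}" for a in atoms]
        elem = [a.element.upper() for a in atoms]
        self.is_h = np.array([e == "H" for e in elem])
        self.polar_heavy = np.array([e in {"N", "O", "S"} for e in elem])
        self.is_carbon = np.array([e == "C" for e in elem])
        # apolar carbon: no O/N/S bonded within 1.7 Å
        self.apolar_c = np.array(
            [
                self.is_carbon[i]
                and not any(self.polar_heavy[j] for j in self.neighbors[i])
                for i in range(len(atoms))
            ]
        )
        # donors: polar heavy atoms with a bonded H; (donor, H) pairs
        self.donor_pairs = [
            (i, j)
            for i in np.nonzero(self.polar_heavy)[0]
            for j in self.neighbors[i]
            if self.is_h[j]
        ]
        self.acceptors = [
            i for i in np.nonzero(self.polar_heavy)[0] if elem[i] in {"N", "O"}
        ]
        self.has_hydrogens = bool(self.is_h.any())
        self.charged_groups = self._find_charged_groups()

    def _find_charged_groups(self):
        """(label, member atom ids, kind) for protein and ligand charged groups."""
        atoms = self.topology.atoms
        groups = []
        by_res = self.topology.atoms_by_residue()
        for key, ids in by_res.items():
            chain, num, name = key
            if name in _CHARGED_GROUPS:
                wanted = _CHARGED_GROUPS[name]
                members = [i for i in ids if atoms[i].name.upper() in wanted]
                if members:
                    groups.append((f"{name}_{num}", members, "protein"))
            elif atoms[ids[0]].is_ligand:
                # carboxylate: C bonded to two O's that carry no H
                for i in ids:
                    if not self.is_carbon[i]:
                        continue
                    oxy = [
                        j
                        for j in self.neighbors[i]
                        if atoms[j].element.upper() == "O"
                        and not any(self.is_h[k] for k in self.neighbors[j])
                    ]
                    if len(oxy) >= 2:
                        groups.append((f"{name}_{num}", oxy, "ligand"))
                # protonated amine: N with ≥ 2 bonded H
                for i in ids:
                    if atoms[i].element.upper() == "N":
                        nh = sum(self.is_h[j] for j in self.neighbors[i])
                        if nh >= 2:
                            groups.append((f"{name}_{num}", [i], "ligand"))
        return groups


def _hbond_geometry(
    coords: np.ndarray,
    donor: int,
    h: int,
    acceptor: int,
    neighbors: list[list[int]],
    is_h: np.ndarray,
    ha_max: float,
    donor_angle_min: float,
    acceptor_angle_min: float | None,
) -> bool:
    if np.linalg.norm(coords[h] - coords[acceptor]) > ha_max:
        return False
    if _angle(coords[donor], coords[h], coords[acceptor]) < donor_angle_min:
        return False
    if acceptor_angle_min is not None:
        heavies = [x for x in neighbors[acceptor] if not is_h[x]]
        if heavies and not any(
            _angle(coords[x], coords[acceptor], coords[h]) >= acceptor_angle_min
            for x in heavies
        ):
            return False
    return True


def detect_interactions(topology: Topology, series: FrameSeries) -> list[InteractionEvent]:
    """Scan every frame for protein–ligand interaction events.

    Hydrogen-bond (and water-bridge) detection requires explicit
    hydrogens; without any H in the topology those categories are
    disabled with a warning.
    """
    sys_ = _System(topology, series.coords[0])
    if not sys_.has_hydrogens:
        logger.warning("no hydrogens present: hbond/water_bridge detection disabled")
    events: list[InteractionEvent] = []
    atoms = topology.atoms

    lig_mask = sys_.is_ligand
    prot_mask = sys_.is_protein
    wat_mask = sys_.is_water
    lig_ids = np.nonzero(lig_mask)[0]
    if len(lig_ids) == 0:
        raise TopologyError("no ligand atoms flagged in topology")

    donor_pairs = sys_.donor_pairs
    acceptors = sys_.acceptors

    for f in range(series.n_frames):
        c = series.coords[f]
        seen: set[tuple[str, str, str]] = set()

        if sys_.has_hydrogens:
            # protein donor → ligand acceptor and ligand donor → protein acceptor
            for d, h in donor_pairs:
                for a in acceptors:
                    if prot_mask[d] and lig_mask[a]:
                        res, lat = sys_.res_label[d], atoms[a].name
                    elif lig_mask[d] and prot_mask[a]:
                        res, lat = sys_.res_label[a], atoms[d].name
                    else:
                        continue
                    if _hbond_geometry(
                        c, d, h, a, sys_.neighbors, sys_.is_h,
                        HBOND_HA_MAX, HBOND_DONOR_ANGLE_MIN, HBOND_ACCEPTOR_ANGLE_MIN,
                    ):
                        seen.add((res, lat, "hbond"))

            # water bridges: water H-bonded to both protein and ligand
            for w_key, w_ids in topology.atoms_by_residue().items():
                if w_key[2] not in WATER_NAMES:
                    continue
                linked_prot: list[int] = []
                linked_lig: list[int] = []
                for d, h in donor_pairs:
                    for a in acceptors:
                        w_donor = d in w_ids
                        w_accept = a in w_ids
                        if not (w_donor ^ w_accept):
                            continue
                        other = a if w_donor else d
                        if not (prot_mask[other] or lig_mask[other]):
                            continue
                        if _hbond_geometry(
                            c, d, h, a, sys_.neighbors, sys_.is_h,
                            WATER_HA_MAX, WATER_DONOR_ANGLE_MIN, None,
                        ):
                            (linked_prot if prot_mask[other] else linked_lig).append(other)
                for p in linked_prot:
                    for l in linked_lig:
                        seen.add((sys_.res_label[p], atoms[l].name, "water_bridge"))

        # hydrophobic: apolar C (protein) vs apolar C (ligand)
        pc = np.nonzero(sys_.apolar_c & prot_mask)[0]
        lc = np.nonzero(sys_.apolar_c & lig_mask)[0]
        if len(pc) and len(lc):
            dists = np.linalg.norm(c[pc][:, None, :] - c[lc][None, :, :], axis=2)
            for ii, jj in zip(*np.nonzero(dists <= HYDROPHOBIC_CC_MAX)):
                seen.add((sys_.res_label[pc[ii]], atoms[lc[jj]].name, "hydrophobic"))

        # ionic: charged-group centroid distances
        pgroups = [g for g in sys_.charged_groups if g[2] == "protein"]
        lgroups = [g for g in sys_.charged_groups if g[2] == "ligand"]
        for pres, pids, _ in pgroups:
            pcen = c[pids].mean(axis=0)
            for _, lids, _ in lgroups:
                lcen = c[lids].mean(axis=0)
                if np.linalg.norm(pcen - lcen) <= IONIC_CENTROID_MAX:
                    seen.add((pres, atoms[lids[0]].name, "ionic"))

        events.extend(
            InteractionEvent(f, res, lat, cat) for res, lat, cat in sorted(seen)
        )
    return events


def interaction_fractions(
    events: list[InteractionEvent],
    n_frames: int,
    report_threshold: float = DEFAULT_REPORT_THRESHOLD,
    union_categories: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Interaction fractions per (residue, category) plus a filtered report.

    The fraction is the number of distinct frames with at least one
    event for the pair divided by ``n_frames``.  The report keeps rows
    with fraction ≥ ``report_threshold`` (inclusive).  With
    ``union_categories`` the fraction is computed per residue over the
    union of all categories.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be ≥ 1")
    frames: dict[tuple[str, str], set[int]] = {}
    for e in events:
        key = (e.residue, "any" if union_categories else e.category)
        frames.setdefault(key, set()).add(e.frame)
    rows = [
        {"residue": res, "category": cat, "fraction": len(fs) / n_frames}
        for (res, cat), fs in sorted(frames.items())
    ]
    table = pd.DataFrame(rows, columns=["residue", "category", "fraction"])
    report = table[table["fraction"] >= report_threshold].reset_index(drop=True)
    report = report.sort_values("fraction", ascending=False, kind="stable").reset_index(drop=True)
    return table, report


def dihedral_angles(coords: np.ndarray, quad: tuple[int, int, int, int]) -> np.ndarray:
    """Signed dihedral (degrees, (−180, 180]) per frame; NaN where collinear."""
    p = coords[:, list(quad), :]
    b1 = p[:, 1] - p[:, 0]
    b2 = p[:, 2] - p[:, 1]
    b3 = p[:, 3] - p[:, 2]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    norm1 = np.linalg.norm(n1, axis=1)
    norm2 = np.linalg.norm(n2, axis=1)
    b2n = np.linalg.norm(b2, axis=1)
    bad = (norm1 < 1e-10) | (norm2 < 1e-10) | (b2n < 1e-10)
    x = np.sum(n1 * n2, axis=1)
    y = np.sum(np.cross(n1, n2) * b2 / np.where(b2n, b2n, 1.0)[:, None], axis=1)
    ang = np.degrees(np.arctan2(y, x))
    ang = np.where(ang <= -180.0, ang + 360.0, ang)  # map −180 → +180
    ang[bad] = np.nan
    return ang


def torsion_profile(
    topology: Topology,
    series: FrameSeries,
    bond_list: list[tuple[int, int, int, int]],
    bin_width: float = 10.0,
) -> dict[str, dict]:
    """Torsion angle series and normalized histograms per rotatable bond.

    Each bond is a dihedral quadruple of atom indices.  Histograms use
    10° bins over (−180, 180]; frames with collinear geometry are
    skipped and counted.
    """
    edges = np.arange(-180.0, 180.0 + bin_width / 2, bin_width)
    out: dict[str, dict] = {}
    for quad in bond_list:
        if len(quad) != 4 or len(set(quad)) != 4:
            raise ValueError(f"dihedral quadruple must be 4 distinct atom indices, got {quad}")
        angles = dihedral_angles(series.coords, tuple(quad))
        valid = angles[~np.isnan(angles)]
        counts, _ = np.histogram(valid, bins=edges)
        hist = counts / max(len(valid), 1)
        name = "-".join(topology.atoms[i].name for i in quad)
        out[name] = {
            "atoms": tuple(int(i) for i in quad),
            "angles": angles,
            "histogram": hist,
            "bin_edges": edges,
            "n_skipped": int(np.isnan(angles).sum()),
        }
    return out
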