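"""Seeded synthetic-trajectory and energy-table generators.

Every pipeline input can be produced here with known ground truth:
Gaussian conformational ensembles with planted inter-residue correlation
blocks and per-residue variances, multi-state conformational mixtures
with exact state fractions, deterministic interaction schedules, and
per-frame MM-GBSA term tables with stated means and SDs.  All
randomness flows through a single :func:`numpy.random.default_rng` seed;
outputs are byte-identical across runs.

The generators emulate the statistical structure the analyses assume —
stationary fluctuations about a fixed mean, block-correlated
displacements, discrete conformational basins — not force-field
physics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import Atom, FrameSeries, Topology
from .interactions import InteractionEvent

CA_SPACING = 3.8  # Å, ideal Cα–Cα distance in an extended chain
HELIX_RISE = 1.5  # Å per residue
HELIX_TWIST = 100.0  # degrees per residue
HELIX_RADIUS = 2.3  # Å


class ParameterError(ValueError):
    pass


def make_reference(
    n_residues: int,
    geometry: str = "extended",
    with_ligand: bool = False,
    ligand_atoms: int = 5,
) -> tuple[Topology, FrameSeries]:
    """Ideal poly-alanine-like chain: Cα plus one sidechain dummy per residue.

    ``geometry`` is ``extended`` (Cα every 3.8 Å along x) or ``helix``
    (1.5 Å rise, 100° twist, 2.3 Å radius).  With ``with_ligand`` a
    ``LIG`` residue of heavy atoms is appended near the chain midpoint.
    """
    if n_residues < 3:
        raise ParameterError("need at least 3 residues")
    if geometry not in {"extended", "helix"}:
        raise ParameterError(f"unknown geometry {geometry!r}")
    atoms: list[Atom] = []
    coords: list[np.ndarray] = []
    serial = 1
    for i in range(n_residues):
        if geometry == "extended":
            # zigzag keeps consecutive Cα at exactly CA_SPACING while
            # avoiding the collinear degeneracy of a straight line
            dx = np.sqrt(CA_SPACING**2 - 1.0)
            ca = np.array([dx * i, float(i % 2), 0.0])
            cb = ca + np.array([0.0, 0.0, 1.5])
        else:
            theta = np.radians(HELIX_TWIST * i)
            ca = np.array(
                [HELIX_RADIUS * np.cos(theta), HELIX_RADIUS * np.sin(theta), HELIX_RISE * i]
            )
            out = np.array([np.cos(theta), np.sin(theta), 0.0])
            cb = ca + 1.5 * out
        for name, xyz in (("CA", ca), ("CB", cb)):
            atoms.append(
                Atom(serial, name, "C", i + 1, "ALA", "A", is_ligand=False, is_heavy=True)
            )
            coords.append(xyz)
            serial += 1
    if with_ligand:
        center = np.mean([c for c, a in zip(coords, atoms) if a.name == "CA"], axis=0)
        for k in range(ligand_atoms):
            ang = 2 * np.pi * k / max(ligand_atoms, 1)
            xyz = center + np.array([1.4 * np.cos(ang), 1.4 * np.sin(ang), 4.0])
            atoms.append(
                Atom(serial, f"C{k + 1}", "C", n_residues + 1, "LIG", "B",
                     is_ligand=True, is_heavy=True)
            )
            coords.append(xyz)
            serial += 1
    topology = Topology(atoms)
    series = FrameSeries(np.asarray(coords)[None, :, :])
    return topology, series


@dataclass
class EnsembleSpec:
    """Gaussian ensemble with planted correlation blocks.

    ``sigma`` is the per-coordinate fluctuation SD in Å (scalar or one
    value per residue); ``blocks`` lists (residue indices, ρ) with
    disjoint members and ρ ∈ [0, 1).  Within a block every displacement
    component is √ρ·s_b(t) + √(1−ρ)·ε_i(t) with iid normal factors, so
    the planted intra-block correlation is exactly ρ.
    """

    n_residues: int
    sigma: float | np.ndarray = 0.5
    blocks: list[tuple[list[int], float]] = field(default_factory=list)
    n_frames: int = 1000
    seed: int = 0
    geometry: str = "extended"
    rigid_motion: bool = False

    def __post_init__(self):
        seen: set[int] = set()
        for members, rho in self.blocks:
            if not 0 <= rho < 1:
                raise ParameterError("block ρ must be in [0, 1)")
            if seen & set(members):
                raise ParameterError("correlation blocks must be disjoint")
            seen |= set(members)
        if np.any(np.asarray(self.sigma) <= 0):
            raise ParameterError("sigma must be positive")


def sample_correlated_ensemble(spec: EnsembleSpec) -> tuple[Topology, FrameSeries]:
    """Draw a frame series with the planted block-correlation structure.

    Every atom of a residue is displaced rigidly by that residue's
    displacement vector, so Cα and sidechain dummies move together.
    With ``rigid_motion`` a random rotation+translation is additionally
    applied per frame (for superposition tests).
    """
    topology, ref = make_reference(spec.n_residues, spec.geometry)
    rng = np.random.default_rng(spec.seed)
    sigma = np.broadcast_to(np.asarray(spec.sigma, dtype=float), (spec.n_residues,))
    t, n = spec.n_frames, spec.n_residues

    eps = rng.standard_normal((t, n, 3))
    disp = eps.copy()
    for members, rho in spec.blocks:
        shared = rng.standard_normal((t, 1, 3))
        disp[:, members, :] = np.sqrt(rho) * shared + np.sqrt(1 - rho) * eps[:, members, :]
    disp = disp * sigma[None, :, None]

    coords = np.repeat(ref.coords, t, axis=0)
    res_of_atom = np.array([a.residue_number - 1 for a in topology.atoms])
    coords += disp[:, res_of_atom, :]
    if spec.rigid_motion:
        coords = _apply_random_rigid(coords, rng)
    return topology, FrameSeries(coords)


def _apply_random_rigid(coords: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    out = np.empty_like(coords)
    for f in range(coords.shape[0]):
        rot = Rotation.random(random_state=rng).as_matrix()
        shift = rng.uniform(-10, 10, size=3)
        out[f] = coords[f] @ rot.T + shift
    return out


@dataclass
class TwoStateSpec:
    """Discrete conformational mixture with exact state fractions.

    ``states`` lists (fraction, displacement Å) per basin; fractions sum
    to 1 and frame counts are assigned deterministically (largest
    remainder), then shuffled by seed.  The displacement is applied to
    ``displaced_residues`` (default: all) along z with a period-4 sign
    pattern (+, +, −, −) when ``alternating``; the pattern is
    mean-free and uncorrelated with every rigid-body mode of the
    reference chain, so a least-squares fit cannot absorb it and the
    fitted inter-state RMSD on the displaced atoms equals the
    displacement magnitude.
    """

    n_residues: int
    states: list[tuple[float, float]] = field(default_factory=lambda: [(0.7, 0.0), (0.3, 4.0)])
    displaced_residues: list[int] | None = None
    alternating: bool = True
    noise_sigma: float = 0.3
    n_frames: int = 1000
    seed: int = 0
    geometry: str = "extended"

    def __post_init__(self):
        fracs = [f for f, _ in self.states]
        if any(not 0 < f <= 1 for f in fracs) or abs(sum(fracs) - 1) > 1e-9:
            raise ParameterError("state fractions must lie in (0, 1] and sum to 1")
        if self.noise_sigma < 0:
            raise ParameterError("noise_sigma must be non-negative")


def _exact_counts(fractions: list[float], n: int) -> list[int]:
    raw = [f * n for f in fractions]
    counts = [int(np.floor(r)) for r in raw]
    rem = n - sum(counts)
    order = np.argsort([c - r for c, r in zip(counts, raw)])  # largest remainder first
    for i in range(rem):
        counts[order[i]] += 1
    return counts


def sample_two_state(spec: TwoStateSpec) -> tuple[Topology, FrameSeries, np.ndarray]:
    """Draw the mixture; returns (topology, series, true state labels)."""
    topology, ref = make_reference(spec.n_residues, spec.geometry)
    rng = np.random.default_rng(spec.seed)
    counts = _exact_counts([f for f, _ in spec.states], spec.n_frames)
    labels = np.repeat(np.arange(len(spec.states)), counts)
    rng.shuffle(labels)

    moved = (
        np.arange(spec.n_residues)
        if spec.displaced_residues is None
        else np.asarray(spec.displaced_residues, dtype=int)
    )
    pattern = np.zeros(spec.n_residues)
    if spec.alternating:
        signs = np.array([1.0, 1.0, -1.0, -1.0])
        pattern[moved] = signs[np.arange(len(moved)) % 4]
    else:
        pattern[moved] = 1.0

    res_of_atom = np.array([a.residue_number - 1 for a in topology.atoms])
    coords = np.repeat(ref.coords, spec.n_frames, axis=0)
    for s, (_, disp) in enumerate(spec.states):
        idx = np.nonzero(labels == s)[0]
        if disp != 0.0 and len(idx):
            shift = np.zeros((spec.n_residues, 3))
            shift[:, 2] = disp * pattern
            coords[idx] += shift[res_of_atom][None, :, :]
    if spec.noise_sigma > 0:
        noise = rng.standard_normal((spec.n_frames, spec.n_residues, 3)) * spec.noise_sigma
        coords += noise[:, res_of_atom, :]
    return topology, FrameSeries(coords), labels


def make_interaction_schedule(
    n_frames: int, targets: dict[tuple[str, str], float], ligand_atom: str = "C1"
) -> list[InteractionEvent]:
    """Deterministic on/off schedule hitting each target fraction exactly.

    Each (residue, category) pair is on for ``floor(fraction ×
    n_frames)`` leading frames.
    """
    events: list[InteractionEvent] = []
    for (residue, category), frac in sorted(targets.items()):
        if not 0 <= frac <= 1:
            raise ParameterError(f"fraction for {residue}/{category} outside [0, 1]")
        k = int(np.floor(frac * n_frames + 1e-9))
        events.extend(
            InteractionEvent(f, residue, ligand_atom, category) for f in range(k)
        )
    return events


@dataclass
class EnergySpec:
    """Gaussian per-(entity, term) energy draws with known ΔG statistics.

    ``params`` maps (entity, term) → (mean, sd) in kcal/mol.  ΔG(f) is
    the complex − ligand − receptor total, so its true mean is the
    signed sum of means and its true SD the root sum of variances.
    """

    params: dict[tuple[str, str], tuple[float, float]]
    n_frames: int = 1000
    seed: int = 0

    def __post_init__(self):
        from .energy import ENTITIES, TERMS

        for (entity, term), (_, sd) in self.params.items():
            if entity not in ENTITIES or term not in TERMS:
                raise ParameterError(f"unknown (entity, term): {(entity, term)}")
            if sd < 0:
                raise ParameterError("SDs must be non-negative")

    @property
    def true_dg_mean(self) -> float:
        sign = {"complex": 1.0, "ligand": -1.0, "receptor": -1.0}
        return sum(sign[e] * m for (e, _), (m, _) in self.params.items())

    @property
    def true_dg_sd(self) -> float:
        return float(np.sqrt(sum(sd**2 for _, (_, sd) in self.params.items())))

    @classmethod
    def from_target(
        cls,
        dg_mean: float,
        dg_sd: float,
        group_fractions: dict[str, float] | None = None,
        n_frames: int = 1000,
        seed: int = 0,
    ) -> "EnergySpec":
        """Spec whose ΔG distribution matches a target mean and SD.

        The mean is split across the three component groups (default:
        the approximate share seen in MM-GBSA tables for a buried
        lipophilic binder — vdW 60%, lipophilic 50%, electrostatic
        −10%); variance is split evenly over the three complex-side
        terms carrying the groups.
        """
        if group_fractions is None:
            group_fractions = {"vdw": 0.6, "lipophilic": 0.5, "electrostatic": -0.1}
        carriers = {"vdw": "vdw", "lipophilic": "lipophilic", "electrostatic": "coulomb"}
        sd_each = dg_sd / np.sqrt(3)
        params: dict[tuple[str, str], tuple[float, float]] = {}
        # receptor/ligand baselines (cancel in ΔG)
        for entity, base in (("receptor", -900.0), ("ligand", -60.0)):
            params[(entity, "vdw")] = (base, 0.0)
        for group, frac in group_fractions.items():
            term = carriers[group]
            # complex value = receptor + ligand baselines + the ΔG share,
            # so the per-term complex − ligand − receptor difference is the share
            base = sum(
                params.get((e, term), (0.0, 0.0))[0] for e in ("receptor", "ligand")
            )
            params[("complex", term)] = (base + dg_mean * frac, sd_each)
        return cls(params=params, n_frames=n_frames, seed=seed)


def make_energy_tables(spec: EnergySpec) -> tuple[pd.DataFrame, float, float]:
    """Draw the long-format energy table; returns (table, true ΔG mean, SD)."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    for (entity, term), (mean, sd) in sorted(spec.params.items()):
        values = mean + sd * rng.standard_normal(spec.n_frames)
        rows.append(
            pd.DataFrame(
                {"frame": np.arange(spec.n_frames), "entity": entity, "term": term,
                 "value": values}
            )
        )
    table = pd.concat(rows, ignore_index=True)
    return table, spec.true_dg_mean, spec.true_dg_sd
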