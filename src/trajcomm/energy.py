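"""MM-GBSA binding-energy bookkeeping.

This layer consumes per-frame energy term tables (long format: frame,
entity, term, value) produced by an end-point free-energy workflow and
performs the downstream arithmetic: per-frame binding energy

    ΔG(f) = E_complex(f) − (E_ligand(f) + E_receptor(f)),

component grouping (electrostatic = Coulomb + H-bond + GB solvation;
van der Waals = vdW + π–π packing + self-contact; lipophilic), trailing-
window means ± sample SD, relative binding energies across systems, and
per-residue decomposition aggregation.  It never computes force-field
or solvation energies itself.  Sign convention: favorable is negative.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

ENTITIES = ("complex", "receptor", "ligand")
TERMS = ("coulomb", "hbond", "gb_solvation", "vdw", "pi_pi", "self_contact", "lipophilic")
#: Component grouping of the ΔG difference per term.
GROUPS = {
    "electrostatic": ("coulomb", "hbond", "gb_solvation"),
    "vdw": ("vdw", "pi_pi", "self_contact"),
    "lipophilic": ("lipophilic",),
}


class EnergyDataError(ValueError):
    pass


@dataclass
class BindingEnergySummary:
    de_mean: float
    de_sd: float
    grouped_mean: dict[str, float]
    grouped_sd: dict[str, float]
    window: tuple[int, int]  # first and last frame id of the window


def load_energy_table(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    """Read a long-format energy term table (frame, entity, term, value)."""
    df = pd.read_csv(path, sep=sep)
    validate_energy_table(df)
    return df


def validate_energy_table(df: pd.DataFrame) -> None:
    required = {"frame", "entity", "term", "value"}
    if not required.issubset(df.columns):
        raise EnergyDataError(f"energy table must have columns {sorted(required)}")
    bad_entities = set(df["entity"]) - set(ENTITIES)
    if bad_entities:
        raise EnergyDataError(f"unknown entities: {sorted(bad_entities)}")
    bad_terms = set(df["term"]) - set(TERMS)
    if bad_terms:
        raise EnergyDataError(f"unknown terms: {sorted(bad_terms)}")
    if df.duplicated(["frame", "entity", "term"]).any():
        raise EnergyDataError("duplicate (frame, entity, term) rows")


def _entity_totals(df: pd.DataFrame) -> pd.DataFrame:
    """Per-frame, per-entity summed terms; errors on incomplete frames."""
    totals = df.pivot_table(index="frame", columns="entity", values="value", aggfunc="sum")
    missing = totals.isna()
    if missing.any().any() or set(ENTITIES) - set(totals.columns):
        frames = sorted(
            set(totals.index[missing.any(axis=1)])
            | (set(totals.index) if set(ENTITIES) - set(totals.columns) else set())
        )
        raise EnergyDataError(f"frames missing an entity: {frames[:10]}")
    return totals


def binding_energy_per_frame(df: pd.DataFrame) -> pd.Series:
    """ΔG(f) = Σ_terms complex − (Σ_terms ligand + Σ_terms receptor)."""
    validate_energy_table(df)
    totals = _entity_totals(df)
    dg = totals["complex"] - totals["ligand"] - totals["receptor"]
    dg.name = "dG"
    return dg.sort_index()


def group_components(df: pd.DataFrame) -> pd.DataFrame:
    """Grouped per-frame ΔG components (electrostatic, vdw, lipophilic).

    Each term's complex − ligand − receptor difference is computed per
    frame, then summed within its group; the three group columns sum to
    ΔG(f) exactly.
    """
    validate_energy_table(df)
    per_term = df.pivot_table(index="frame", columns=["entity", "term"], values="value")
    out = {}
    for group, terms in GROUPS.items():
        vals = np.zeros(len(per_term))
        for term in terms:
            for entity, sign in (("complex", 1.0), ("ligand", -1.0), ("receptor", -1.0)):
                col = (entity, term)
                if col in per_term.columns:
                    vals = vals + sign * per_term[col].fillna(0.0).to_numpy()
        out[group] = vals
    return pd.DataFrame(out, index=per_term.index).sort_index()


def summarize_window(
    dg: pd.Series,
    grouped: pd.DataFrame | None = None,
    last_fraction: float = 0.2,
) -> BindingEnergySummary:
    """Mean ± sample SD of ΔG (and grouped components) over a trailing window.

    ``last_fraction`` is the trailing fraction of frames used (the
    convention of summarizing the final stretch of a long trajectory);
    it must select at least one frame.
    """
    if not 0 < last_fraction <= 1:
        raise ValueError("last_fraction must be in (0, 1]")
    n = len(dg)
    k = max(int(round(n * last_fraction)), 1)
    if k > n:
        raise ValueError("window exceeds series length")
    tail = dg.sort_index().iloc[n - k :]
    gm: dict[str, float] = {}
    gs: dict[str, float] = {}
    if grouped is not None:
        gtail = grouped.sort_index().iloc[len(grouped) - k :]
        gm = {c: float(gtail[c].mean()) for c in grouped.columns}
        gs = {c: float(gtail[c].std(ddof=1)) if k > 1 else 0.0 for c in grouped.columns}
    return BindingEnergySummary(
        de_mean=float(tail.mean()),
        de_sd=float(tail.std(ddof=1)) if k > 1 else 0.0,
        grouped_mean=gm,
        grouped_sd=gs,
        window=(int(tail.index[0]), int(tail.index[-1])),
    )


def relative_energies(de_means: dict[str, float]) -> dict[str, float]:
    """ΔΔE per system relative to the most favorable (lowest) ΔE."""
    if not de_means:
        raise ValueError("need at least one system")
    ref = min(de_means.values())
    return {k: round(v - ref, 10) for k, v in de_means.items()}


# ---------------------------------------------------------------------------
# Per-residue decomposition
# ---------------------------------------------------------------------------

def load_residue_decomposition(path: str | Path, sep: str = "\t") -> dict[str, float]:
    """Two-column (residue, kcal/mol) decomposition file → dict.

    Residue ids look like ``VAL_332``; comment lines start with '#'.
    """
    decomp: dict[str, float] = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(sep) if sep in line else line.split()
            if parts[0].lower() in {"residue", "res"}:
                continue
            if len(parts) < 2:
                raise EnergyDataError(f"bad decomposition line: {raw!r}")
            if parts[0] in decomp:
                raise EnergyDataError(f"duplicate residue {parts[0]}")
            decomp[parts[0]] = float(parts[1])
    return decomp


def residue_set_total(decomposition: dict[str, float], residue_ids: list[str]) -> float:
    """Summed contribution of a residue set (error on unknown ids)."""
    missing = [r for r in residue_ids if r not in decomposition]
    if missing:
        raise KeyError(f"unknown residue id(s): {missing}")
    return float(sum(decomposition[r] for r in residue_ids))


def _residue_number(residue_id: str) -> int:
    try:
        return int(residue_id.rsplit("_", 1)[1])
    except (IndexError, ValueError):
        return 0


def top_contributors(decomposition: dict[str, float], k: int = 1) -> list[tuple[str, float]]:
    """Residues ranked by |contribution| descending; ties by residue number."""
    if not decomposition:
        raise ValueError("empty decomposition")
    ranked = sorted(
        decomposition.items(), key=lambda kv: (-abs(kv[1]), _residue_number(kv[0]))
    )
    return ranked[:k]


def threshold_report(
    decomposition: dict[str, float], min_magnitude: float = 1.0
) -> list[tuple[str, float]]:
    """Residues with |contribution| strictly above ``min_magnitude``, by magnitude."""
    passing = [(r, v) for r, v in decomposition.items() if abs(v) > min_magnitude]
    passing.sort(key=lambda kv: (-abs(kv[1]), _residue_number(kv[0])))
    return passing
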