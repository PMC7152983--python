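"""Bundled reference tables.

Published MM-GBSA summaries and per-residue decompositions for
chiglitazar bound to the three PPAR ligand-binding domains; used as
worked-example inputs for the energy bookkeeping layer.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from ..energy import load_residue_decomposition

SYSTEMS = ("alpha", "beta", "gamma")


def _path(name: str):
    return resources.files(__package__).joinpath(name)


def load_reference_energies() -> pd.DataFrame:
    """Per-system MM-GBSA summary table (ΔE, ΔVDW, ΔLIPO, ΔGBELE means ± SD)."""
    with resources.as_file(_path("chiglitazar_ppar_binding_energies.tsv")) as p:
        return pd.read_csv(p, sep="\t", comment="#")


def load_reference_decomposition(system: str) -> dict[str, float]:
    """Per-residue decomposition (kcal/mol) for 'alpha', 'beta' or 'gamma'."""
    if system not in SYSTEMS:
        raise ValueError(f"system must be one of {SYSTEMS}")
    with resources.as_file(_path(f"chiglitazar_ppar_{system}_decomposition.tsv")) as p:
        return load_residue_decomposition(p)
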