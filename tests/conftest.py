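import numpy as np
import pytest

from trajcomm.io import Atom, FrameSeries, Topology


@pytest.fixture
def tripeptide() -> tuple[Topology, FrameSeries]:
    """Three-residue Cα/Cβ chain, one frame."""
    from trajcomm.synth import make_reference

    return make_reference(3, "extended")


@pytest.fixture
def liganded_chain() -> tuple[Topology, FrameSeries]:
    """Ten-residue chain with a 5-heavy-atom LIG residue appended."""
    from trajcomm.synth import make_reference

    return make_reference(10, "extended", with_ligand=True)


def make_topology(spec: list[tuple]) -> Topology:
    """Build a Topology from (name, element, resnum, resname, chain, het) rows."""
    from trajcomm.io import STANDARD_AA, WATER_NAMES

    atoms = []
    for serial, (name, element, resnum, resname, chain, het) in enumerate(spec, 1):
        atoms.append(
            Atom(
                serial=serial,
                name=name,
                element=element,
                residue_number=resnum,
                residue_name=resname,
                chain_id=chain,
                is_ligand=het and resname not in STANDARD_AA and resname not in WATER_NAMES,
                is_heavy=element.upper() != "H",
            )
        )
    return Topology(atoms)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
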