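from __future__ import annotations

import numpy as np
import pytest

from calpain_ppi.structure import AtomRecord, Structure
from calpain_ppi.synth import ToyComplexSpec, make_toy_complex


@pytest.fixture
def contact_complex() -> Structure:
    """Two 4-residue chains in van der Waals contact (gap 0)."""
    return make_toy_complex(
        ToyComplexSpec(residues_per_chain=4, atoms_per_residue=3, inter_chain_gap=0.0)
    )


@pytest.fixture
def separated_complex() -> Structure:
    """Two chains 50 A apart: no mutual occlusion possible."""
    return make_toy_complex(
        ToyComplexSpec(residues_per_chain=4, atoms_per_residue=3, inter_chain_gap=50.0)
    )


def random_cluster(n_atoms: int, seed: int) -> Structure:
    """A compact random atom cluster with mixed radii, one residue per atom."""
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0.0, 8.0, size=(n_atoms, 3))
    radii = rng.choice([1.52, 1.55, 1.70, 1.80], size=n_atoms)
    elements = {1.52: "O", 1.55: "N", 1.70: "C", 1.80: "S"}
    atoms = [
        AtomRecord(
            serial=i + 1,
            atom_name=f"{elements[r]}1",
            element=elements[r],
            alt_loc="",
            chain_id="A",
            res_seq=i + 1,
            insertion_code="",
            res_name="UNK",
            x=float(x),
            y=float(y),
            z=float(z),
            radius=float(r),
        )
        for i, ((x, y, z), r) in enumerate(zip(coords, radii))
    ]
    return Structure(atoms, source_id=f"cluster{seed}")
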