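import numpy as np
import pytest

from protongate.structure_io import Atom, ChargedStructure


def make_structure(records, charges=None):
    """Build a ChargedStructure from (serial, name, element, resname, resnum,
    chain, x, y, z) tuples, optionally attaching charges positionally."""
    atoms = []
    for i, rec in enumerate(records):
        serial, name, element, resname, resnum, chain, x, y, z = rec
        q = None if charges is None else float(charges[i])
        atoms.append(
            Atom(
                atom_id=serial,
                name=name,
                element=element,
                residue_name=resname,
                residue_number=resnum,
                chain_id=chain,
                position=(float(x), float(y), float(z)),
                partial_charge=q,
            )
        )
    return ChargedStructure(atoms=tuple(atoms))


def random_charged_structure(rng, n=100, z_range=(0.0, 30.0), signed=True):
    """Random point-charge cloud for slab/center property tests."""
    z = rng.uniform(*z_range, size=n)
    q = rng.normal(0, 0.5, size=n) if signed else rng.uniform(0.05, 1.0, size=n)
    if signed and abs(q.sum()) < 0.5:
        q[0] += 1.0  # keep the net charge well away from zero
    records = [
        (i + 1, "CB", "C", "ALA", i + 1, "A", 0.0, 0.0, zi) for i, zi in enumerate(z)
    ]
    return make_structure(records, charges=q)


@pytest.fixture
def three_atom_structure():
    return make_structure(
        [
            (1, "N", "N", "GLY", 1, "A", 1.0, 2.0, 3.0),
            (2, "CA", "C", "GLY", 1, "A", 2.5, 2.0, 4.0),
            (3, "O", "O", "HOH", 2, "A", 8.0, 1.0, 10.5),
        ]
    )


@pytest.fixture(scope="session")
def default_cluster():
    """One 976-atom synthetic cluster shared across tests (read-only)."""
    from protongate.synthetic_data import gen_structure

    return gen_structure(seed=1)
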