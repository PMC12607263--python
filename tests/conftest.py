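import numpy as np
import pytest

from prokit import fixtures


@pytest.fixture
def collinear5():
    """Five single-CA residues 3.8 A apart on the x-axis."""
    return fixtures.make_collinear_chain(5)


@pytest.fixture
def ethanol():
    return fixtures.make_toy_molecule("ethanol")


@pytest.fixture
def tripeptide():
    """A small multi-residue peptide-like fixture for SASA convergence.

    Three cys-pair copies shifted apart: enough atoms for mutual occlusion
    without being slow at high point counts.
    """
    from prokit.structure import Atom, Residue, Structure

    base = fixtures.make_cys_pair(2.05)
    residues = []
    serial = 1
    for shift in range(3):
        for res in base.residues:
            atoms = [
                Atom(serial + i, a.name, a.element,
                     a.coords + np.array([shift * 4.0, 0.0, 0.0]),
                     a.occupancy, a.bfactor)
                for i, a in enumerate(res.atoms)
            ]
            serial += len(atoms)
            residues.append(
                Residue("A", res.seq_number + 2 * shift, res.res_name, atoms)
            )
    return Structure("peptide6", residues)
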