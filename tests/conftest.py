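"""Shared fixtures: everything is generated programmatically at test time."""

import numpy as np
import pytest

from pldock.energetics import precalculate_table
from pldock.fixtures import FixtureSpec, make_funnel_complex
from pldock.search import Scorer

#: granularity used by grid-backed tests; coarser than the production
#: default to keep lattice construction fast on the toy complexes
TEST_GRANULARITY = 0.25


@pytest.fixture(scope="session")
def table():
    """Default pair-potential table (120 pairs x 16,384 samples)."""
    return precalculate_table()


@pytest.fixture(scope="session")
def funnel(table):
    """Certified planted-optimum surface-pocket complex (rigid ligand)."""
    return make_funnel_complex(FixtureSpec(seed=0), table=table,
                               granularity=TEST_GRANULARITY)


@pytest.fixture(scope="session")
def funnel_scorer(funnel, table):
    """Grid-backed scorer for the funnel complex (maps built once)."""
    return Scorer(funnel.template, funnel.receptor, funnel.box, table)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


# ---------------------------------------------------------------------------
# Hand-written PDBQT snippets
# ---------------------------------------------------------------------------

def _atom(serial, name, x, y, z, ad, record="ATOM"):
    name_f = name if len(name) == 4 else f" {name:<3s}"
    return (f"{record:<6s}{serial:>5d} {name_f:<4s} LIG A   1    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00     0.000 {ad:<2s}")


@pytest.fixture(scope="session")
def tiny_receptor_text():
    """Three heavy atoms (C, N, O) plus a polar hydrogen on the nitrogen."""
    return "\n".join([
        _atom(1, "C1", 0.0, 0.0, 0.0, "C"),
        _atom(2, "N1", 3.0, 0.0, 0.0, "N"),
        _atom(3, "H1", 3.6, 0.8, 0.0, "HD"),
        _atom(4, "O1", 0.0, 3.0, 0.0, "OA"),
    ]) + "\n"


@pytest.fixture(scope="session")
def metal_receptor_text():
    return "\n".join([
        _atom(1, "C1", 0.0, 0.0, 0.0, "C"),
        _atom(2, "ZN", 2.5, 0.0, 0.0, "Zn", record="HETATM"),
    ]) + "\n"


@pytest.fixture(scope="session")
def rigid_ligand_text():
    """No BRANCH records: a rigid three-heavy-atom ligand."""
    return "\n".join([
        "ROOT",
        _atom(1, "C1", 0.0, 0.0, 0.0, "C"),
        _atom(2, "C2", 1.5, 0.0, 0.0, "C"),
        _atom(3, "O1", 2.2, 1.2, 0.0, "OA"),
        "ENDROOT",
        "TORSDOF 0",
    ]) + "\n"


@pytest.fixture(scope="session")
def hydroxyl_ligand_text():
    """Ethanol-like: the single BRANCH rotates only the hydroxyl hydrogen."""
    return "\n".join([
        "ROOT",
        _atom(1, "C1", 0.0, 0.0, 0.0, "C"),
        _atom(2, "C2", 1.5, 0.0, 0.0, "C"),
        "ENDROOT",
        "BRANCH 2 3",
        _atom(3, "O1", 2.2, 1.2, 0.0, "OA"),
        _atom(4, "HO", 3.1, 1.1, 0.3, "HD"),
        "ENDBRANCH 2 3",
        "TORSDOF 1",
    ]) + "\n"


@pytest.fixture(scope="session")
def methyl_ligand_text():
    """A BRANCH moving three hydrogens only (methyl rotor)."""
    return "\n".join([
        "ROOT",
        _atom(1, "C1", 0.0, 0.0, 0.0, "C"),
        _atom(2, "O1", 1.4, 0.0, 0.0, "OA"),
        "ENDROOT",
        "BRANCH 2 3",
        _atom(3, "C2", 2.1, 1.2, 0.0, "C"),
        _atom(4, "H1", 3.0, 1.1, 0.6, "H"),
        _atom(5, "H2", 1.5, 1.9, 0.5, "H"),
        _atom(6, "H3", 2.4, 1.6, -0.9, "H"),
        "ENDBRANCH 2 3",
        "TORSDOF 1",
    ]) + "\n"


@pytest.fixture(scope="session")
def biphenyl_ligand_text():
    """A BRANCH moving six heavy atoms: the torsion must stay active."""
    ring1 = [(0.0, 0.0), (1.4, 0.0), (2.1, 1.2), (1.4, 2.4), (0.0, 2.4),
             (-0.7, 1.2)]
    ring2 = [(3.5, 1.2), (4.2, 0.0), (5.6, 0.0), (6.3, 1.2), (5.6, 2.4),
             (4.2, 2.4)]
    lines = ["ROOT"]
    for i, (x, y) in enumerate(ring1, start=1):
        lines.append(_atom(i, f"C{i}", x, y, 0.0, "A"))
    lines.append("ENDROOT")
    lines.append("BRANCH 3 7")
    for i, (x, y) in enumerate(ring2, start=7):
        lines.append(_atom(i, f"C{i}", x, y, 0.0, "A"))
    lines.append("ENDBRANCH 3 7")
    lines.append("TORSDOF 1")
    return "\n".join(lines) + "\n"


@pytest.fixture(scope="session")
def flexible_ligand_text():
    """Two active torsions moving heavy atoms; used by kinematics tests."""
    return "\n".join([
        "ROOT",
        _atom(1, "C1", 0.0, 0.0, 0.0, "C"),
        _atom(2, "C2", 1.5, 0.0, 0.0, "C"),
        "ENDROOT",
        "BRANCH 2 3",
        _atom(3, "C3", 2.2, 1.3, 0.0, "C"),
        _atom(4, "C4", 3.7, 1.3, 0.0, "C"),
        "BRANCH 4 5",
        _atom(5, "N1", 4.4, 2.6, 0.0, "N"),
        _atom(6, "O1", 5.8, 2.6, 0.3, "OA"),
        "ENDBRANCH 4 5",
        "ENDBRANCH 2 3",
        "TORSDOF 2",
    ]) + "\n"
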