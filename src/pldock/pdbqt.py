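"""PDBQT receptors and ligands.

The PDBQT dialect of the AutoDock family extends PDB ATOM/HETATM records
with a partial charge and an AutoDock atom-type tag, and describes ligand
flexibility with a torsion tree (ROOT/ENDROOT, nested BRANCH/ENDBRANCH,
TORSDOF).  This module parses both kinds of file, assigns each heavy atom
one of the engine's 15 functional atom types, builds the torsion tree, and
re-classifies as *inactive* any torsion that moves no heavy atom (hydroxyl,
amine, methyl rotors): such torsions cannot change the score and are removed
from the optimisation variables.

Covalent connectivity, which PDBQT does not carry inside rigid frames, is
perceived geometrically: two atoms are bonded when their distance is below
1.15 x the sum of their covalent radii.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "AtomTypeInfo",
    "Atom",
    "Receptor",
    "TorsionNode",
    "LigandTemplate",
    "PdbqtError",
    "ATOM_TYPES",
    "TYPE_CODES",
    "parse_receptor",
    "parse_ligand",
    "detect_inactive_torsions",
    "write_docked_pdbqt",
    "parse_docked_models",
]


class PdbqtError(ValueError):
    """Malformed PDBQT content (bad record, unknown type, broken tree)."""


# ---------------------------------------------------------------------------
# Atom typing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AtomTypeInfo:
    """One of the 15 heavy-atom functional types used by the scoring terms.

    ``vdw_radius`` is the Van der Waals radius (Angstrom) entering the
    surface distance; the three flags drive the hydrophobic and hydrogen
    bond term masks.  Metal ions are treated as hydrogen-bond donors.
    """

    code: str
    vdw_radius: float
    is_hydrophobic: bool = False
    is_hbond_donor: bool = False
    is_hbond_acceptor: bool = False


def _t(code, r, h=False, d=False, a=False):
    return AtomTypeInfo(code, r, h, d, a)


#: The 15 heavy-atom types.  Carbons split by polarity (bonded to N/O or
#: not); nitrogens and oxygens by donor/acceptor character; halogens are
#: hydrophobic; metal ions are donors.
ATOM_TYPES: dict[str, AtomTypeInfo] = {
    t.code: t
    for t in (
        _t("C_H", 1.9, h=True),
        _t("C_P", 1.9),
        _t("N", 1.8),
        _t("N_D", 1.8, d=True),
        _t("N_A", 1.8, a=True),
        _t("N_DA", 1.8, d=True, a=True),
        _t("O_A", 1.7, a=True),
        _t("O_DA", 1.7, d=True, a=True),
        _t("S", 2.0),
        _t("P", 2.1),
        _t("F", 1.5, h=True),
        _t("Cl", 1.8, h=True),
        _t("Br", 2.0, h=True),
        _t("I", 2.2, h=True),
        _t("Met", 1.2, d=True),
    )
}

TYPE_CODES: tuple[str, ...] = tuple(ATOM_TYPES)

_METAL_AD_TYPES = {
    "Zn", "Fe", "Mg", "Mn", "Ca", "Cu", "Ni", "Cd", "Co", "Sr", "Hg",
    "K", "Li", "Na", "Cs", "ZN", "FE", "MG", "MN", "CA", "CU", "NI",
    "CD", "CO", "SR", "HG",
}

# AutoDock type -> (element, base kind); kind refined by connectivity.
_AD_ELEMENT = {
    "H": "H", "HD": "H", "HS": "H",
    "C": "C", "A": "C",
    "N": "N", "NS": "N", "NA": "N",
    "O": "O", "OA": "O", "OS": "O",
    "S": "S", "SA": "S",
    "P": "P", "F": "F", "Cl": "Cl", "Br": "Br", "I": "I",
}

#: covalent radii (Angstrom) for geometric bond perception
_COVALENT_RADIUS = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05, "P": 1.07,
    "F": 0.57, "Cl": 1.02, "Br": 1.20, "I": 1.39,
}
_COVALENT_DEFAULT = 1.40  # metals and anything exotic
_BOND_TOLERANCE = 1.15


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    ad_type: str
    coords: np.ndarray
    partial_charge: float = 0.0
    type: str | None = None  # one of TYPE_CODES; None for hydrogens

    @property
    def is_hydrogen(self) -> bool:
        return self.element == "H"

    @property
    def type_info(self) -> AtomTypeInfo:
        if self.type is None:
            raise PdbqtError(f"atom {self.serial} ({self.name}) is a hydrogen")
        return ATOM_TYPES[self.type]


@dataclass
class Receptor:
    """Rigid receptor: a typed atom list; only heavy atoms are scored."""

    atoms: list[Atom]

    def __post_init__(self):
        if not self.atoms:
            raise PdbqtError("receptor contains no atoms")

    @property
    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def heavy_coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.heavy_atoms], dtype=float)

    def heavy_types(self) -> list[str]:
        return [a.type for a in self.heavy_atoms]

    def heavy_elements(self) -> list[str]:
        return [a.element for a in self.heavy_atoms]


@dataclass
class TorsionNode:
    """One rigid frame of the torsion tree.

    ``rotor_axis`` is the (parent-side, child-side) pair of atom serials of
    the rotatable bond connecting this frame to its parent; the root frame
    has none.  ``active`` is False when rotating the bond moves no heavy
    atom anywhere in the subtree.
    """

    atoms: list[Atom] = field(default_factory=list)
    rotor_axis: tuple[int, int] | None = None
    active: bool = True
    children: list["TorsionNode"] = field(default_factory=list)

    def walk(self):
        yield self
        for child in self.children:
            yield from child.walk()


@dataclass
class LigandTemplate:
    """A parsed flexible ligand: torsion tree + connectivity byproducts.

    ``one_four_exclusions`` holds unordered heavy-atom serial pairs separated
    by at most three consecutive covalent bonds; such pairs are excluded
    from the intra-molecular score.
    """

    root: TorsionNode
    atoms: list[Atom]
    torsdof: int
    one_four_exclusions: set[tuple[int, int]]
    layout: list[tuple] = field(default_factory=list, repr=False)
    source_name: str = ""

    # derived, filled by _finalize
    n_active: int = 0
    n_inactive: int = 0
    n_heavy: int = 0
    frames: list[TorsionNode] = field(default_factory=list, repr=False)
    frame_parent: list[int] = field(default_factory=list, repr=False)
    frame_of_atom: dict[int, int] = field(default_factory=dict, repr=False)
    serial_to_index: dict[int, int] = field(default_factory=dict, repr=False)
    frame_atom_idx: list = field(default_factory=list, repr=False)
    _input_coords: "np.ndarray | None" = field(default=None, repr=False)

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def heavy_coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.heavy_atoms()], dtype=float)

    def input_coords(self) -> np.ndarray:
        if self._input_coords is None:
            self._input_coords = np.array(
                [a.coords for a in self.atoms], dtype=float)
        return self._input_coords

    def heavy_indices(self) -> np.ndarray:
        return np.array(
            [i for i, a in enumerate(self.atoms) if not a.is_hydrogen], dtype=int
        )

    def atom_by_serial(self, serial: int) -> Atom:
        for a in self.atoms:
            if a.serial == serial:
                return a
        raise PdbqtError(f"no atom with serial {serial}")


# ---------------------------------------------------------------------------
# Parsing helpers
# ---------------------------------------------------------------------------

def _parse_atom_line(line: str, lineno: int) -> Atom:
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except ValueError as exc:
        raise PdbqtError(f"line {lineno}: malformed ATOM record: {exc}") from exc
    charge_field = line[66:76].strip()
    try:
        charge = float(charge_field) if charge_field else 0.0
    except ValueError:
        charge = 0.0  # output files reuse these columns for energies
    ad_type = line[77:79].strip() or line[76:].strip()
    if not ad_type:
        raise PdbqtError(f"line {lineno}: missing AutoDock atom type")
    if ad_type in _METAL_AD_TYPES:
        element = ad_type.capitalize()
    elif ad_type in _AD_ELEMENT:
        element = _AD_ELEMENT[ad_type]
    else:
        raise PdbqtError(f"line {lineno}: unknown AutoDock atom type {ad_type!r}")
    return Atom(serial, name, element, ad_type,
                np.array([x, y, z], dtype=float), charge)


def perceive_bonds(atoms: list[Atom]) -> dict[int, set[int]]:
    """Geometric bond perception: serial -> set of bonded serials."""
    adjacency: dict[int, set[int]] = {a.serial: set() for a in atoms}
    if len(atoms) < 2:
        return adjacency
    coords = np.array([a.coords for a in atoms])
    radii = np.array([
        _COVALENT_RADIUS.get(a.element, _COVALENT_DEFAULT) for a in atoms
    ])
    tree = cKDTree(coords)
    max_bond = _BOND_TOLERANCE * 2.0 * radii.max()
    for i, j in tree.query_pairs(r=max_bond):
        cut = _BOND_TOLERANCE * (radii[i] + radii[j])
        if np.linalg.norm(coords[i] - coords[j]) < cut:
            adjacency[atoms[i].serial].add(atoms[j].serial)
            adjacency[atoms[j].serial].add(atoms[i].serial)
    return adjacency


def _assign_types(atoms: list[Atom], adjacency: dict[int, set[int]]) -> None:
    """Resolve each heavy atom's functional type from its AD type + bonds."""
    by_serial = {a.serial: a for a in atoms}
    for atom in atoms:
        if atom.is_hydrogen:
            atom.type = None
            continue
        neighbours = [by_serial[s] for s in adjacency[atom.serial]]
        has_polar_h = any(n.ad_type == "HD" for n in neighbours)
        ad = atom.ad_type
        if ad in _METAL_AD_TYPES:
            atom.type = "Met"
        elif atom.element == "C":
            bonded_hetero = any(n.element in ("N", "O") for n in neighbours)
            atom.type = "C_P" if bonded_hetero else "C_H"
        elif atom.element == "N":
            acceptor = ad == "NA"
            if acceptor and has_polar_h:
                atom.type = "N_DA"
            elif acceptor:
                atom.type = "N_A"
            elif has_polar_h:
                atom.type = "N_D"
            else:
                atom.type = "N"
        elif atom.element == "O":
            atom.type = "O_DA" if has_polar_h else "O_A"
        elif atom.element in ("S", "P", "F", "Cl", "Br", "I"):
            atom.type = atom.element
        else:  # pragma: no cover - guarded by _parse_atom_line
            raise PdbqtError(f"cannot type atom {atom.serial} ({atom.ad_type})")


def parse_receptor(pdbqt_text: str) -> Receptor:
    """Parse a rigid receptor, assigning the 15 functional heavy-atom types.

    Hydrogens are kept (polar hydrogens determine donor character) but are
    excluded from all scoring.
    """
    atoms: list[Atom] = []
    for lineno, line in enumerate(pdbqt_text.splitlines(), start=1):
        record = line[:6].strip()
        if record in ("ATOM", "HETATM"):
            atoms.append(_parse_atom_line(line, lineno))
    if not atoms:
        raise PdbqtError("no ATOM/HETATM records found")
    _assign_types(atoms, perceive_bonds(atoms))
    return Receptor(atoms)


# ---------------------------------------------------------------------------
# Ligand parsing and torsion tree
# ---------------------------------------------------------------------------

def parse_ligand(pdbqt_text: str) -> LigandTemplate:
    """Parse a flexible ligand into its torsion tree.

    The BRANCH nesting defines the rigid frames; after parsing, torsions
    whose subtree moves no heavy atom are re-classified inactive and the
    1-4 exclusion set is built from perceived connectivity.
    """
    root: TorsionNode | None = None
    stack: list[TorsionNode] = []
    atoms: list[Atom] = []
    layout: list[tuple] = []
    torsdof = 0
    seen_root = False

    for lineno, raw in enumerate(pdbqt_text.splitlines(), start=1):
        line = raw.rstrip("\n")
        record = line[:6].strip() if len(line) >= 4 else line.strip()
        tokens = line.split()
        if not tokens:
            continue
        key = tokens[0]
        if key == "ROOT":
            if seen_root:
                raise PdbqtError(f"line {lineno}: duplicate ROOT")
            root = TorsionNode()
            stack = [root]
            seen_root = True
            layout.append(("root",))
        elif key == "ENDROOT":
            if not stack or stack[-1] is not root:
                raise PdbqtError(f"line {lineno}: ENDROOT outside ROOT")
            layout.append(("endroot",))
        elif key == "BRANCH":
            if root is None:
                raise PdbqtError(f"line {lineno}: BRANCH before ROOT")
            try:
                a, b = int(tokens[1]), int(tokens[2])
            except (IndexError, ValueError) as exc:
                raise PdbqtError(f"line {lineno}: malformed BRANCH") from exc
            node = TorsionNode(rotor_axis=(a, b))
            stack[-1].children.append(node)
            stack.append(node)
            layout.append(("branch", a, b))
        elif key == "ENDBRANCH":
            if len(stack) < 2:
                raise PdbqtError(f"line {lineno}: unmatched ENDBRANCH")
            stack.pop()
            layout.append(("endbranch", int(tokens[1]), int(tokens[2])))
        elif key == "TORSDOF":
            torsdof = int(tokens[1])
            layout.append(("torsdof", torsdof))
        elif record in ("ATOM", "HETATM"):
            if root is None:
                raise PdbqtError(f"line {lineno}: ATOM before ROOT")
            atom = _parse_atom_line(line, lineno)
            stack[-1].atoms.append(atom)
            atoms.append(atom)
            layout.append(("atom", atom.serial, record))
    if root is None:
        raise PdbqtError("ligand has no ROOT record")
    if len(stack) != 1:
        raise PdbqtError("unmatched BRANCH: tree not closed")
    if not atoms:
        raise PdbqtError("ligand has no atoms")

    adjacency = perceive_bonds(atoms)
    _assign_types(atoms, adjacency)
    template = LigandTemplate(
        root=root,
        atoms=atoms,
        torsdof=torsdof,
        one_four_exclusions=_one_four_pairs(atoms, adjacency),
        layout=layout,
    )
    return detect_inactive_torsions(template)


def _one_four_pairs(atoms: list[Atom],
                    adjacency: dict[int, set[int]]) -> set[tuple[int, int]]:
    """Unordered heavy-atom pairs within three consecutive covalent bonds."""
    heavy = {a.serial for a in atoms if not a.is_hydrogen}
    pairs: set[tuple[int, int]] = set()
    for start in heavy:
        frontier = {start}
        visited = {start}
        for _ in range(3):
            frontier = {
                n for s in frontier for n in adjacency[s] if n not in visited
            }
            visited |= frontier
            for other in frontier & heavy:
                pairs.add((min(start, other), max(start, other)))
    return pairs


def detect_inactive_torsions(template: LigandTemplate) -> LigandTemplate:
    """Deactivate torsions that move hydrogens only; refresh derived counts.

    A torsion is inactive iff its subtree contains no heavy atom other than
    the child-side axis atom itself (which lies on the rotation axis and
    therefore does not move).  Idempotent: the classification depends only
    on the tree geometry.
    """
    for node in template.root.walk():
        if node.rotor_axis is None:
            continue
        axis_child = node.rotor_axis[1]
        subtree_heavy = {
            a.serial
            for sub in node.walk()
            for a in sub.atoms
            if not a.is_hydrogen
        }
        node.active = bool(subtree_heavy - {axis_child})
    _finalize(template)
    return template


def _finalize(template: LigandTemplate) -> None:
    frames = list(template.root.walk())
    parent = [-1] * len(frames)
    index = {id(f): i for i, f in enumerate(frames)}
    for i, f in enumerate(frames):
        for child in f.children:
            parent[index[id(child)]] = i
    template.frames = frames
    template.frame_parent = parent
    template.frame_of_atom = {
        a.serial: i for i, f in enumerate(frames) for a in f.atoms
    }
    template.serial_to_index = {
        a.serial: i for i, a in enumerate(template.atoms)
    }
    template.frame_atom_idx = [
        np.array([template.serial_to_index[a.serial] for a in f.atoms],
                 dtype=int)
        for f in frames
    ]
    template._input_coords = None
    branches = [f for f in frames if f.rotor_axis is not None]
    template.n_active = sum(f.active for f in branches)
    template.n_inactive = len(branches) - template.n_active
    template.n_heavy = sum(not a.is_hydrogen for a in template.atoms)


def mobile_heavy_pairs(template: LigandTemplate) -> list[tuple[int, int]]:
    """Atom-index pairs contributing to the intra-molecular score.

    A pair contributes when the tree path between the two frames crosses at
    least one *active* torsion (the atoms can move relative to each other)
    and the pair is not a 1-4 exclusion.
    """
    frames = template.frames
    parent = template.frame_parent
    # set of active-edge frame ids on the root path of each frame
    active_path: list[frozenset[int]] = []
    for i, f in enumerate(frames):
        path = set()
        j = i
        while j > 0:
            if frames[j].rotor_axis is not None and frames[j].active:
                path.add(j)
            j = parent[j]
        active_path.append(frozenset(path))

    atoms = template.atoms
    heavy = [(i, a) for i, a in enumerate(atoms) if not a.is_hydrogen]
    pairs = []
    for (i, ai), (j, aj) in itertools.combinations(heavy, 2):
        fi = template.frame_of_atom[ai.serial]
        fj = template.frame_of_atom[aj.serial]
        if active_path[fi] == active_path[fj]:
            continue  # rigidly coupled
        key = (min(ai.serial, aj.serial), max(ai.serial, aj.serial))
        if key in template.one_four_exclusions:
            continue
        pairs.append((i, j))
    return pairs


# ---------------------------------------------------------------------------
# Writing docked output
# ---------------------------------------------------------------------------

def _format_atom_line(atom: Atom, coords: np.ndarray, energy: float,
                      record: str = "ATOM") -> str:
    e = min(max(energy, -99.99), 999.99)
    name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
    return (
        f"{record:<6s}{atom.serial:>5d} {name:<4s}{'LIG':>4s} {'A':1s}{1:>4d}    "
        f"{coords[0]:8.3f}{coords[1]:8.3f}{coords[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"    {e:6.2f} {atom.ad_type:<2s}"
    )


def write_docked_pdbqt(template: LigandTemplate, poses, metadata=None) -> str:
    """Serialize docked poses as a multi-MODEL PDBQT document.

    Header REMARKs carry the ligand's property record, SMILES and supplier
    list when provided in ``metadata``.  Each MODEL carries the predicted
    free energy, ligand efficiency, putative hydrogen bonds, random-forest
    affinity and consensus score as REMARKs, and prints each atom's
    inter-molecular energy right-aligned in text columns 71-76.
    """
    lines: list[str] = []
    meta = metadata or {}
    if "properties" in meta:
        props = meta["properties"]
        lines.append("REMARK PROPERTIES " + " ".join(str(v) for v in props))
    if "smiles" in meta:
        lines.append(f"REMARK SMILES {meta['smiles']}")
    if "suppliers" in meta:
        sup = meta["suppliers"]
        lines.append(f"REMARK {len(sup)} SUPPLIERS " + " ".join(sup))

    n_atoms = len(template.atoms)
    heavy_idx = list(template.heavy_indices())
    for m, pose in enumerate(poses, start=1):
        if len(pose.coords) != n_atoms:
            raise PdbqtError(
                f"pose {m}: {len(pose.coords)} coordinates for {n_atoms} atoms"
            )
        per_atom = np.zeros(n_atoms)
        if pose.breakdown is not None:
            per_atom[heavy_idx] = pose.breakdown.per_atom_inter
        lines.append(f"MODEL {m:>8d}")
        lines.append(
            f"REMARK PREDICTED FREE ENERGY {pose.energy_kcal:12.3f} KCAL/MOL"
        )
        lines.append(
            "REMARK LIGAND EFFICIENCY "
            f"{pose.energy_kcal / max(template.n_heavy, 1):12.4f} KCAL/MOL/HA"
        )
        for rec_serial, lig_serial, dist in pose.hbonds or []:
            lines.append(
                f"REMARK HBOND RECEPTOR {rec_serial} LIGAND {lig_serial}"
                f" {dist:6.2f} A"
            )
        if pose.rf_pkd is not None:
            lines.append(f"REMARK RF AFFINITY {pose.rf_pkd:9.3f} PKD")
        if pose.consensus_pkd is not None:
            lines.append(f"REMARK CONSENSUS {pose.consensus_pkd:9.3f} PKD")
        serial_to_index = {a.serial: i for i, a in enumerate(template.atoms)}
        for item in template.layout:
            kind = item[0]
            if kind == "atom":
                idx = serial_to_index[item[1]]
                atom = template.atoms[idx]
                lines.append(
                    _format_atom_line(atom, pose.coords[idx], per_atom[idx],
                                      record=item[2])
                )
            elif kind == "root":
                lines.append("ROOT")
            elif kind == "endroot":
                lines.append("ENDROOT")
            elif kind == "branch":
                lines.append(f"BRANCH {item[1]:>3d} {item[2]:>3d}")
            elif kind == "endbranch":
                lines.append(f"ENDBRANCH {item[1]:>3d} {item[2]:>3d}")
            elif kind == "torsdof":
                lines.append(f"TORSDOF {item[1]}")
        lines.append("ENDMDL")
    return "\n".join(lines) + "\n"


def parse_docked_models(text: str):
    """Parse a multi-MODEL docked PDBQT back into a template plus poses.

    The first MODEL defines the template (torsion tree and typing); each
    MODEL contributes one pose holding its coordinates and the predicted
    free energy read back from the REMARK line.  Inverse of
    :func:`write_docked_pdbqt` up to printed precision.
    """
    from .conformation import ScoredPose  # local: avoids an import cycle

    blocks: list[list[str]] = []
    current: list[str] | None = None
    for line in text.splitlines():
        key = line.split()[0] if line.split() else ""
        if key == "MODEL":
            current = []
        elif key == "ENDMDL":
            if current is not None:
                blocks.append(current)
            current = None
        elif current is not None:
            current.append(line)
    if not blocks:
        raise PdbqtError("no MODEL blocks found")

    def _strip_remarks(block: list[str]) -> str:
        return "\n".join(l for l in block if not l.startswith("REMARK")) + "\n"

    template = parse_ligand(_strip_remarks(blocks[0]))
    poses: list[ScoredPose] = []
    for block in blocks:
        model = parse_ligand(_strip_remarks(block))
        energy = 0.0
        for line in block:
            if line.startswith("REMARK PREDICTED FREE ENERGY"):
                energy = float(line.split()[4])
        poses.append(ScoredPose(conformation=None, coords=model.input_coords(),
                                energy_kcal=energy))
    return template, poses
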