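"""Molecular and tabular I/O: PDB receptors, SYBYL MOL2 ligands, van der Waals
parameter tables, and ligand-receptor distance-profile restraints.

Conventions
-----------
* Coordinates are Cartesian ångströms throughout.
* Atom indices are 1-based, matching PDB/MOL2 serial numbers.
* Partial charges are in elementary-charge units; receptors read from plain
  PDB carry charge 0 (the Coulomb term then has no receptor contribution),
  ligands must carry charges in their MOL2 file.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException

from .parameters import DEFAULT_PARAMETERS

__all__ = [
    "AtomRecord",
    "Receptor",
    "Ligand",
    "ParameterTable",
    "DistanceProfile",
    "FormatError",
    "ParameterLookupError",
    "read_pdb",
    "write_pdb",
    "read_mol2",
    "write_mol2",
    "assign_parameters",
    "read_parameter_table",
    "read_distance_profile",
    "detect_rotatable_bonds",
]


class FormatError(ValueError):
    """A molecular/tabular input file violates its format contract."""


class ParameterLookupError(KeyError):
    """One or more atom types cannot be resolved in the parameter table."""


@dataclass
class AtomRecord:
    """One atom with force-field annotations.

    ``vdw_radius`` (r_i, Å) and ``well_depth`` (ε_i, kcal/mol) are ``None``
    until :func:`assign_parameters` resolves them from a table.
    """

    index: int                     # 1-based serial
    element: str
    atom_name: str
    atom_type: str
    coords: np.ndarray             # shape (3,), Å
    charge: float = 0.0
    vdw_radius: float | None = None
    well_depth: float | None = None
    residue_id: tuple[str, int, str] | None = None  # (chain, resseq, resname)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.index}: coords must be a finite 3-vector")
        if self.vdw_radius is not None and self.vdw_radius <= 0:
            raise ValueError(f"atom {self.index}: vdw_radius must be > 0")
        if self.well_depth is not None and self.well_depth < 0:
            raise ValueError(f"atom {self.index}: well_depth must be >= 0")

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"


class _Molecule:
    """Shared coordinate/parameter accessors for Receptor and Ligand."""

    atoms: list[AtomRecord]

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    @property
    def heavy_mask(self) -> np.ndarray:
        return np.array([a.is_heavy for a in self.atoms], dtype=bool)

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms], dtype=float)

    @property
    def is_parameterized(self) -> bool:
        return all(a.vdw_radius is not None and a.well_depth is not None
                   for a in self.atoms)

    @property
    def vdw_radii(self) -> np.ndarray:
        if not self.is_parameterized:
            raise ValueError("molecule has unparameterized atoms; "
                             "call assign_parameters first")
        return np.array([a.vdw_radius for a in self.atoms], dtype=float)

    @property
    def well_depths(self) -> np.ndarray:
        if not self.is_parameterized:
            raise ValueError("molecule has unparameterized atoms; "
                             "call assign_parameters first")
        return np.array([a.well_depth for a in self.atoms], dtype=float)

    def _check_indices(self) -> None:
        indices = [a.index for a in self.atoms]
        if indices != list(range(1, len(indices) + 1)):
            raise ValueError("atom indices must be unique and contiguous from 1")


@dataclass
class Receptor(_Molecule):
    """A protein structure: ordered atoms with residue annotations."""

    atoms: list[AtomRecord]

    def __post_init__(self) -> None:
        self._check_indices()

    @property
    def residues(self) -> dict[tuple, list[int]]:
        """Map residue_id -> 1-based atom indices, in file order."""
        out: dict[tuple, list[int]] = {}
        for a in self.atoms:
            out.setdefault(a.residue_id, []).append(a.index)
        return out


@dataclass
class Ligand(_Molecule):
    """A small molecule: atoms, a bond table, and rotatable-bond indices.

    ``bonds`` holds (i, j, bond_type) with 1-based atom indices;
    ``rotatable_bonds`` holds 0-based indices into ``bonds``.
    """

    atoms: list[AtomRecord]
    bonds: list[tuple[int, int, str]]
    rotatable_bonds: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._check_indices()
        n = self.n_atoms
        for i, j, _ in self.bonds:
            if not (1 <= i <= n and 1 <= j <= n) or i == j:
                raise ValueError(f"bond ({i},{j}) references invalid atom indices")
        for b in self.rotatable_bonds:
            if not (0 <= b < len(self.bonds)):
                raise ValueError(f"rotatable bond index {b} out of range")
        if n > 1 and not nx.is_connected(self.graph()):
            raise ValueError("ligand bond graph is not connected")

    def graph(self) -> nx.Graph:
        """Bond graph over all atoms (1-based node labels)."""
        g = nx.Graph()
        g.add_nodes_from(range(1, self.n_atoms + 1))
        g.add_edges_from((i, j) for i, j, _ in self.bonds)
        return g

    def heavy_graph(self) -> nx.Graph:
        """Bond graph restricted to heavy atoms, with element node labels."""
        g = nx.Graph()
        for a in self.atoms:
            if a.is_heavy:
                g.add_node(a.index, element=a.element.upper())
        for i, j, _ in self.bonds:
            if i in g and j in g:
                g.add_edge(i, j)
        return g


@dataclass
class ParameterTable:
    """Map atom_type -> (vdw_radius, well_depth); element-symbol fallback."""

    table: dict[str, tuple[float, float]]

    def lookup(self, atom_type: str, element: str) -> tuple[float, float]:
        """Exact atom_type match, then element-symbol fallback, else KeyError."""
        if atom_type in self.table:
            return self.table[atom_type]
        elem = element.upper()
        if elem in self.table:
            return self.table[elem]
        raise KeyError(atom_type)

    @classmethod
    def default(cls) -> "ParameterTable":
        return cls(dict(DEFAULT_PARAMETERS))


@dataclass
class DistanceProfile:
    """Ligand-receptor distance restraints: rows (i, j, μ_ij, σ_ij).

    ``i`` is a 1-based receptor atom index, ``j`` a 1-based ligand atom
    index, μ the mean reference distance (Å) and σ its standard deviation
    (Å).  An empty profile contributes zero restraint energy.
    """

    entries: list[tuple[int, int, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for i, j, mu, sigma in self.entries:
            if mu <= 0:
                raise ValueError(f"profile entry ({i},{j}): mu must be > 0")
            if sigma <= 0:
                raise ValueError(f"profile entry ({i},{j}): sigma must be > 0 "
                                 "(its square divides the restraint)")

    def __len__(self) -> int:
        return len(self.entries)


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def _guess_element(atom_name: str) -> str:
    stripped = atom_name.strip().lstrip("0123456789")
    if not stripped:
        return "X"
    if len(stripped) >= 2 and stripped[:2].upper() in ("CL", "BR", "ZN", "MG",
                                                       "FE", "NA", "MN", "CU"):
        return stripped[:2].capitalize()
    return stripped[0].upper()


def read_pdb(path: str | Path) -> Receptor:
    """Read a PDB file into a :class:`Receptor`.

    All atoms present are retained (hydrogens included if the file has them).
    For disordered atoms the alphabetically first altloc (normally ``A``) is
    kept.  Charges are 0; van der Waals parameters are unset until
    :func:`assign_parameters`.
    """
    parser = PDBParser(PERMISSIVE=False, QUIET=True)
    try:
        structure = parser.get_structure("receptor", str(path))
    except (PDBConstructionException, ValueError) as exc:
        raise FormatError(f"{path}: unparseable PDB record: {exc}") from exc

    records: list[AtomRecord] = []
    serial = 0
    for model in structure:
        for chain in model:
            for residue in chain:
                resname = residue.get_resname().strip()
                resseq = residue.get_id()[1]
                for atom in residue.get_atoms():
                    if atom.is_disordered():
                        children = sorted(atom.disordered_get_list(),
                                          key=lambda a: a.get_altloc())
                        atom = children[0]
                    serial += 1
                    element = (atom.element or "").strip() or \
                        _guess_element(atom.get_name())
                    records.append(AtomRecord(
                        index=serial,
                        element=element.capitalize(),
                        atom_name=atom.get_name(),
                        atom_type=element.upper(),
                        coords=np.asarray(atom.get_coord(), dtype=float),
                        residue_id=(chain.get_id(), resseq, resname),
                    ))
        break  # first model only
    if not records:
        raise FormatError(f"{path}: no ATOM/HETATM records found")
    return Receptor(atoms=records)


def write_pdb(receptor: Receptor, path: str | Path) -> None:
    """Write a receptor as ATOM records (fixed-column PDB)."""
    with open(path, "w") as fh:
        for a in receptor.atoms:
            chain, resseq, resname = a.residue_id or ("A", 1, "UNK")
            x, y, z = a.coords
            fh.write(
                f"ATOM  {a.index:5d} {a.atom_name:<4.4s}{resname:>4.3s} "
                f"{chain:1.1s}{resseq:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {a.element.upper():>2.2s}\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# MOL2
# ---------------------------------------------------------------------------

def read_mol2(path: str | Path) -> Ligand:
    """Read a SYBYL MOL2 file into a :class:`Ligand`.

    Requires ``@<TRIPOS>ATOM`` and ``@<TRIPOS>BOND`` sections and a charge
    column on every atom line.  Rotatable bonds are detected as single-order
    bonds that are neither terminal (both endpoints need at least two heavy
    neighbours) nor part of a ring; see :func:`detect_rotatable_bonds`.
    """
    text = Path(path).read_text()
    sections: dict[str, list[str]] = {}
    current: list[str] | None = None
    for raw in text.splitlines():
        line = raw.rstrip()
        if line.startswith("@<TRIPOS>"):
            name = line[len("@<TRIPOS>"):].strip().upper()
            current = sections.setdefault(name, [])
            continue
        if current is not None and line.strip() and not line.startswith("#"):
            current.append(line)

    if "ATOM" not in sections or not sections["ATOM"]:
        raise FormatError(f"{path}: missing @<TRIPOS>ATOM section")
    if "BOND" not in sections:
        raise FormatError(f"{path}: missing @<TRIPOS>BOND section")

    atoms: list[AtomRecord] = []
    for line in sections["ATOM"]:
        fields = line.split()
        if len(fields) < 9:
            raise FormatError(
                f"{path}: atom line '{line.strip()}' has no charge column; "
                "pre-assign partial charges (e.g. with an external "
                "preparation tool) before docking")
        idx = int(fields[0])
        name = fields[1]
        xyz = [float(v) for v in fields[2:5]]
        atype = fields[5]
        charge = float(fields[8])
        element = atype.split(".")[0].capitalize()
        atoms.append(AtomRecord(index=idx, element=element, atom_name=name,
                                atom_type=atype, coords=np.array(xyz),
                                charge=charge))
    atoms.sort(key=lambda a: a.index)

    bonds: list[tuple[int, int, str]] = []
    for line in sections["BOND"]:
        fields = line.split()
        if len(fields) < 4:
            raise FormatError(f"{path}: malformed bond line '{line.strip()}'")
        bonds.append((int(fields[1]), int(fields[2]), fields[3]))

    lig = Ligand(atoms=atoms, bonds=bonds)
    lig.rotatable_bonds = detect_rotatable_bonds(lig)
    return lig


def detect_rotatable_bonds(ligand: Ligand) -> list[int]:
    """0-based indices of bonds that are single, non-terminal and non-ring.

    A bond is rotatable when its type is ``"1"``, both endpoints have at
    least two heavy neighbours, and the bond lies on no ring of the bond
    graph.  This is stricter than taking every single bond: rotating a
    terminal or ring bond is either a null move or breaks ring geometry.
    """
    g = ligand.graph()
    ring_edges = set()
    for cycle in nx.cycle_basis(g):
        for k in range(len(cycle)):
            i, j = cycle[k], cycle[(k + 1) % len(cycle)]
            ring_edges.add(frozenset((i, j)))
    heavy = {a.index for a in ligand.atoms if a.is_heavy}
    heavy_deg = {n: sum(1 for m in g.neighbors(n) if m in heavy) for n in g}
    out = []
    for b, (i, j, btype) in enumerate(ligand.bonds):
        if btype != "1":
            continue
        if frozenset((i, j)) in ring_edges:
            continue
        if heavy_deg.get(i, 0) < 2 or heavy_deg.get(j, 0) < 2:
            continue
        out.append(b)
    return out


def write_mol2(ligand: Ligand, path: str | Path,
               poses: list[np.ndarray] | None = None,
               mol_name: str = "LIG") -> None:
    """Write a ligand as SYBYL MOL2.

    With ``poses`` (each an (n_atoms, 3) coordinate array) a multi-molecule
    file is written, one ``@<TRIPOS>MOLECULE`` block per pose; otherwise the
    ligand's own coordinates are written once.
    """
    coord_sets = poses if poses is not None else [ligand.coords]
    with open(path, "w") as fh:
        for m, xyz in enumerate(coord_sets):
            xyz = np.asarray(xyz, dtype=float)
            if xyz.shape != (ligand.n_atoms, 3):
                raise ValueError("pose coordinate shape mismatch")
            name = mol_name if len(coord_sets) == 1 else f"{mol_name}_{m + 1}"
            fh.write("@<TRIPOS>MOLECULE\n")
            fh.write(f"{name}\n")
            fh.write(f"{ligand.n_atoms:d} {len(ligand.bonds):d} 0 0 0\n")
            fh.write("SMALL\nUSER_CHARGES\n")
            fh.write("@<TRIPOS>ATOM\n")
            for a, (x, y, z) in zip(ligand.atoms, xyz):
                fh.write(f"{a.index:>7d} {a.atom_name:<8s} "
                         f"{x:>9.4f} {y:>9.4f} {z:>9.4f} "
                         f"{a.atom_type:<8s} 1 {mol_name:<8s} "
                         f"{a.charge:>9.4f}\n")
            fh.write("@<TRIPOS>BOND\n")
            for b, (i, j, btype) in enumerate(ligand.bonds, start=1):
                fh.write(f"{b:>6d} {i:>5d} {j:>5d} {btype:>4s}\n")


# ---------------------------------------------------------------------------
# parameter assignment
# ---------------------------------------------------------------------------

def assign_parameters(mol, table: ParameterTable | None = None):
    """Set ``vdw_radius``/``well_depth`` on every atom of a molecule in place.

    Lookup order: exact atom_type, then element symbol; any atom type still
    unresolved raises :class:`ParameterLookupError` listing the offenders.
    Returns the molecule for chaining.
    """
    if table is None:
        table = ParameterTable.default()
    missing: list[str] = []
    for a in mol.atoms:
        try:
            r, eps = table.lookup(a.atom_type, a.element)
        except KeyError:
            missing.append(a.atom_type)
            continue
        a.vdw_radius = r
        a.well_depth = eps
    if missing:
        raise ParameterLookupError(
            "unresolvable atom types (no exact or element-level entry): "
            + ", ".join(sorted(set(missing))))
    return mol


def read_parameter_table(path: str | Path) -> ParameterTable:
    """Read a TSV with columns atom_type, vdw_radius, well_depth."""
    df = pd.read_csv(path, sep="\t", comment="#",
                     names=["atom_type", "vdw_radius", "well_depth"],
                     dtype={"atom_type": str})
    table = {}
    for _, row in df.iterrows():
        r, eps = float(row.vdw_radius), float(row.well_depth)
        if r <= 0 or eps < 0:
            raise FormatError(f"parameter table row {row.atom_type}: "
                              "need radius > 0 and well depth >= 0")
        table[str(row.atom_type)] = (r, eps)
    return ParameterTable(table)


def read_distance_profile(path: str | Path) -> DistanceProfile:
    """Read restraints as TSV rows (receptor_atom, ligand_atom, mu, sigma).

    An empty file yields an empty profile (the restraint term is then 0).
    """
    text = Path(path).read_text().strip()
    if not text:
        return DistanceProfile(entries=[])
    df = pd.read_csv(io.StringIO(text), sep=r"\s+", comment="#", header=None,
                     names=["i", "j", "mu", "sigma"])
    entries = [(int(r.i), int(r.j), float(r.mu), float(r.sigma))
               for r in df.itertuples()]
    return DistanceProfile(entries=entries)
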