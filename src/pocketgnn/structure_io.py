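"""Reading and writing protein structures.

Parses PDB files into an :class:`AtomSet` of protein atoms plus a list of
:class:`LigandSite` ground-truth binding sites, classifying every atom
into the six-letter chemical alphabet [C, H, O, N, S, Se] used by the
surface featurization (anything else maps to "other").

Ligand auto-detection keeps any HETATM residue with at least
``MIN_LIGAND_ATOMS`` heavy atoms whose residue name is not in
:data:`EXCLUDED_RESNAMES` (waters, common ions, buffer and cryo
components).  Each ligand copy becomes its own site; all protein chains
are merged into one atom set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning

#: chemical alphabet; index in this list is the chem_index
CHEM_ALPHABET = ("C", "H", "O", "N", "S", "SE")

#: chem_index value for elements outside the alphabet
OTHER = -1

#: residue names never treated as ligands
EXCLUDED_RESNAMES = frozenset({
    "HOH", "WAT", "DOD",                       # waters
    "NA", "CL", "K", "ZN", "MG", "CA", "MN",   # ions
    "FE", "CU", "NI", "CO", "CD", "HG", "BR", "IOD", "CS", "LI",
    "SO4", "PO4", "NO3", "CO3", "ACT", "FMT",  # buffer anions
    "GOL", "EDO", "PEG", "PG4", "MPD", "DMS", "BME", "TRS", "EPE",
})

MIN_LIGAND_ATOMS = 4


class StructureParseError(ValueError):
    """Raised when a PDB file cannot be parsed."""


class EmptyStructureError(ValueError):
    """Raised when a file contains no protein atoms."""


def element_to_chem_index(symbol: str):
    """Map an element symbol to its index in ``[C, H, O, N, S, Se]``.

    Returns the string ``"other"`` for any valid element outside the
    alphabet.  Case-insensitive.  Raises ``ValueError`` on empty input.
    """
    if not symbol or not symbol.strip():
        raise ValueError("empty element symbol")
    sym = symbol.strip().upper()
    try:
        return CHEM_ALPHABET.index(sym)
    except ValueError:
        return "other"


def _chem_index_int(symbol: str) -> int:
    idx = element_to_chem_index(symbol)
    return OTHER if idx == "other" else idx


@dataclass
class AtomSet:
    """Protein atoms: coordinates (Å), element symbols, chemical indices.

    ``chem_index`` stores the alphabet position 0..5, or -1 (:data:`OTHER`)
    for elements outside the alphabet.
    """

    coords: np.ndarray
    elements: list
    chem_index: np.ndarray
    is_protein: np.ndarray = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64).reshape(-1, 3)
        self.chem_index = np.asarray(self.chem_index, dtype=np.int64)
        if self.is_protein is None:
            self.is_protein = np.ones(len(self.coords), dtype=bool)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite atom coordinates")
        if len(self.coords) != len(self.elements) or len(self.coords) != len(self.chem_index):
            raise ValueError("inconsistent AtomSet field lengths")

    def __len__(self):
        return len(self.coords)

    @classmethod
    def from_elements(cls, coords, elements):
        return cls(coords, list(elements),
                   np.array([_chem_index_int(e) for e in elements]))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "x": self.coords[:, 0], "y": self.coords[:, 1],
            "z": self.coords[:, 2], "element": self.elements,
            "chem_index": self.chem_index, "is_protein": self.is_protein,
        })


@dataclass
class LigandSite:
    """A bound ligand kept as ground truth; ``center`` is the unweighted
    mean of its heavy-atom coordinates."""

    ligand_id: str
    atom_coords: np.ndarray
    center: np.ndarray = field(init=False)

    def __post_init__(self):
        self.atom_coords = np.asarray(self.atom_coords,
                                      dtype=np.float64).reshape(-1, 3)
        if len(self.atom_coords) == 0:
            raise ValueError(f"ligand {self.ligand_id} has no heavy atoms")
        self.center = self.atom_coords.mean(axis=0)


def _element_of(atom) -> str:
    el = (atom.element or "").strip()
    if not el:  # fall back to the first letter of the atom name
        el = "".join(c for c in atom.get_name() if c.isalpha())[:1]
    return el.upper()


def read_structure(path, ligand_selector="auto"):
    """Parse a PDB file into ``(AtomSet, [LigandSite, ...])``.

    ``ligand_selector`` is either ``"auto"`` (heavy-atom-count rule with
    the exclusion list) or an explicit list of HETATM residue names to
    keep as ligands.  For disordered atoms the highest-occupancy
    conformer (Biopython's selected child) is used.
    """
    path = Path(path)
    if not path.exists():
        raise StructureParseError(f"no such file: {path}")
    parser = PDBParser(QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", PDBConstructionWarning)
            structure = parser.get_structure(path.stem, str(path))
    except Exception as exc:  # noqa: BLE001 - surface the parser's message
        raise StructureParseError(f"cannot parse {path}: {exc}") from exc

    coords, elements = [], []
    ligands = []
    model = next(structure.get_models())
    for chain in model:
        for residue in chain:
            hetflag = residue.id[0]
            atoms = residue.get_unpacked_list()
            # highest-occupancy conformer only
            best = {}
            for atom in atoms:
                name = atom.get_name()
                occ = atom.get_occupancy() or 0.0
                if name not in best or occ > (best[name].get_occupancy() or 0.0):
                    best[name] = atom
            atoms = list(best.values())
            if hetflag == " ":
                for atom in atoms:
                    coords.append(atom.coord)
                    elements.append(_element_of(atom))
            elif hetflag.startswith("H_") or hetflag == "W":
                resname = residue.get_resname().strip()
                heavy = [a for a in atoms if _element_of(a) != "H"]
                if ligand_selector == "auto":
                    keep = (resname not in EXCLUDED_RESNAMES
                            and len(heavy) >= MIN_LIGAND_ATOMS)
                else:
                    keep = resname in set(ligand_selector)
                if keep and heavy:
                    lig_id = f"{resname}_{chain.id}_{residue.id[1]}"
                    ligands.append(LigandSite(
                        lig_id, np.array([a.coord for a in heavy])))

    if not coords:
        raise EmptyStructureError(f"{path} contains no protein atoms")
    return AtomSet.from_elements(np.array(coords), elements), ligands


def write_structure(atoms: AtomSet, path, ligands=None):
    """Write an AtomSet (and optional ligand sites) as a PDB file."""
    lines = []
    serial = 1
    for i in range(len(atoms)):
        x, y, z = atoms.coords[i]
        el = atoms.elements[i]
        name = el[:1] if len(el) == 1 else el.capitalize()
        lines.append(
            f"ATOM  {serial:5d} {name:>3s}  GLY A{(i % 9999) + 1:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {el:>2s}")
        serial += 1
    for j, lig in enumerate(ligands or []):
        for k, (x, y, z) in enumerate(lig.atom_coords):
            lines.append(
                f"HETATM{serial:5d}  C{k + 1:<2d} LIG B{j + 1:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C")
            serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
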