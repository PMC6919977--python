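"""Read, write and query protein(-DNA) structures in PDB format.

Residue numbering is kept exactly as deposited (1-based PDB numbering), so
residue labels used throughout the literature on forkhead DBDs (Arg211,
His212, ...) address residues directly.  Parsing is delegated to biotite;
a light pre-validation pass reports the line number of malformed
coordinate fields, which biotite does not.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from biotite.structure import AtomArray
from biotite.structure.io.pdb import PDBFile

from dbdscreen.errors import (
    ChainNotFoundError,
    DomainError,
    EmptyStructureError,
    StructureParseError,
)

#: Residue names recognized as nucleic acid (DNA + RNA one-letter deposits).
NUCLEIC_NAMES = frozenset({"DA", "DT", "DG", "DC", "A", "U", "G", "C"})

ResidueKey = tuple[str, int, str]  # (chain id, residue number, residue name)


@dataclass(frozen=True)
class Atom:
    """A single atom with deposited serial, name, element and position (Å)."""

    serial: int
    name: str
    element: str
    coords: np.ndarray
    residue_key: ResidueKey

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (3,) or not np.all(np.isfinite(coords)):
            raise DomainError(f"atom {self.serial}: coordinates must be a finite 3-vector")
        if not self.element:
            raise DomainError(f"atom {self.serial}: element must be non-empty")
        object.__setattr__(self, "coords", coords)


@dataclass
class Residue:
    """A residue with PDB numbering and a deterministic polymer classification."""

    chain: str
    number: int
    name: str
    atoms: list[Atom]
    polymer_class: str = field(init=False)

    def __post_init__(self) -> None:
        if not self.atoms:
            raise DomainError(f"residue {self.key}: atom list must be non-empty")
        self.polymer_class = classify_residue(self.name, [a.name for a in self.atoms])

    @property
    def key(self) -> ResidueKey:
        return (self.chain, self.number, self.name)

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"residue {self.key} has no atom {name!r}")

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.element != "H"]


def classify_residue(name: str, atom_names: list[str]) -> str:
    """Classify a residue as protein / nucleic / other.

    Nucleic residues are recognized by name; anything else carrying a CA
    atom counts as protein; the remainder is "other".
    """
    if name in NUCLEIC_NAMES:
        return "nucleic"
    if "CA" in atom_names:
        return "protein"
    return "other"


@dataclass
class ComplexStructure:
    """An ordered residue list plus named residue-span annotations.

    Annotations map a label (e.g. ``"H3"`` for the DNA-recognition helix)
    to a ``(chain, start, end)`` inclusive span; every annotated span must
    refer to residues that exist.
    """

    residues: list[Residue] = field(default_factory=list)
    annotations: dict[str, tuple[str, int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        keys = [r.key for r in self.residues]
        if len(keys) != len(set(keys)):
            raise DomainError("residue keys must be unique")
        for label, (chain, start, end) in self.annotations.items():
            if not any(r.chain == chain and start <= r.number <= end for r in self.residues):
                raise DomainError(f"annotation {label!r} refers to no existing residue")

    @property
    def chains(self) -> set[str]:
        return {r.chain for r in self.residues}

    def chain_residues(self, chain: str) -> list[Residue]:
        if chain not in self.chains:
            raise ChainNotFoundError(f"chain {chain!r} not in structure (has {sorted(self.chains)})")
        return [r for r in self.residues if r.chain == chain]

    def residue(self, chain: str, number: int) -> Residue:
        for r in self.residues:
            if r.chain == chain and r.number == number:
                return r
        raise KeyError(f"no residue {chain}:{number}")

    def atoms(self) -> list[Atom]:
        return [a for r in self.residues for a in r.atoms]

    def coords(self, heavy_only: bool = False) -> np.ndarray:
        atoms = [a for r in self.residues for a in (r.heavy_atoms() if heavy_only else r.atoms)]
        if not atoms:
            return np.zeros((0, 3))
        return np.stack([a.coords for a in atoms])

    def __len__(self) -> int:
        return len(self.residues)


def span_length(start: int, end: int) -> int:
    """Inclusive residue count of a numbering span: end - start + 1."""
    if start > end:
        raise DomainError(f"span start {start} exceeds end {end}")
    return end - start + 1


def select_residues(s: ComplexStructure, chain: str, span: tuple[int, int]) -> ComplexStructure:
    """Residues of ``chain`` with numbers in the inclusive ``span``, order preserved."""
    lo, hi = span
    picked = [r for r in s.chain_residues(chain) if lo <= r.number <= hi]
    return ComplexStructure(residues=picked)


def _prevalidate_pdb(text: str) -> None:
    """Raise StructureParseError naming the line of any malformed coordinate field."""
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        for lo, hi in ((30, 38), (38, 46), (46, 54)):
            raw = line[lo:hi].strip()
            try:
                float(raw)
            except ValueError:
                raise StructureParseError(
                    f"line {lineno}: malformed coordinate field {raw!r}"
                ) from None


def _from_atom_array(arr: AtomArray) -> ComplexStructure:
    residues: list[Residue] = []
    current: tuple[str, int, str] | None = None
    atoms: list[Atom] = []
    serials = (
        arr.get_annotation("atom_id")
        if "atom_id" in arr.get_annotation_categories()
        else np.arange(1, arr.array_length() + 1)
    )
    for i in range(arr.array_length()):
        key = (str(arr.chain_id[i]), int(arr.res_id[i]), str(arr.res_name[i]))
        if key != current:
            if current is not None:
                residues.append(Residue(current[0], current[1], current[2], atoms))
            current, atoms = key, []
        element = str(arr.element[i]).strip() or str(arr.atom_name[i])[:1]
        atoms.append(
            Atom(
                serial=int(serials[i]),
                name=str(arr.atom_name[i]),
                element=element.capitalize(),
                coords=np.array(arr.coord[i], dtype=float),
                residue_key=key,
            )
        )
    if current is not None:
        residues.append(Residue(current[0], current[1], current[2], atoms))
    return ComplexStructure(residues=residues)


def read_structure(path_or_text) -> ComplexStructure:
    """Parse a PDB file (path, file object, or raw text) into a ComplexStructure.

    ATOM and HETATM records are read; the highest-occupancy altloc is kept;
    unknown residues are classified "other".  An entirely empty file raises
    :class:`EmptyStructureError`; a file with header records but no atoms
    yields a structure with zero residues.
    """
    if hasattr(path_or_text, "read"):
        text = path_or_text.read()
    else:
        text = str(path_or_text)
        if "\n" not in text and not text.startswith(("ATOM", "HETATM", "HEADER")):
            with open(text) as fh:
                text = fh.read()
    if not text.strip():
        raise EmptyStructureError("structure file is empty")
    _prevalidate_pdb(text)
    pdb = PDBFile.read(io.StringIO(text))
    if not any(line.startswith(("ATOM", "HETATM")) for line in text.splitlines()):
        return ComplexStructure()
    try:
        arr = pdb.get_structure(model=1, altloc="occupancy")
    except Exception as exc:  # biotite raises several types on bad records
        raise StructureParseError(f"could not parse PDB records: {exc}") from exc
    return _from_atom_array(arr)


def to_atom_array(s: ComplexStructure) -> AtomArray:
    atoms = s.atoms()
    arr = AtomArray(len(atoms))
    for i, a in enumerate(atoms):
        arr.chain_id[i] = a.residue_key[0]
        arr.res_id[i] = a.residue_key[1]
        arr.res_name[i] = a.residue_key[2]
        arr.atom_name[i] = a.name
        arr.element[i] = a.element.upper()
        arr.coord[i] = a.coords
        arr.hetero[i] = False
    arr.set_annotation("atom_id", np.array([a.serial for a in atoms], dtype=int))
    return arr


def write_structure(s: ComplexStructure, path_or_buf) -> None:
    """Write the structure as PDB text (coordinates at standard 3-decimal precision)."""
    pdb = PDBFile()
    pdb.set_structure(to_atom_array(s))
    if hasattr(path_or_buf, "write"):
        pdb.write(path_or_buf)
    else:
        with open(path_or_buf, "w") as fh:
            pdb.write(fh)


def structure_info(s: ComplexStructure) -> dict:
    """Summary used by the CLI: chain ids, residue/atom counts, polymer classes."""
    per_chain = {}
    for chain in sorted(s.chains):
        rs = s.chain_residues(chain)
        per_chain[chain] = {
            "n_residues": len(rs),
            "n_atoms": sum(len(r.atoms) for r in rs),
            "polymer_classes": sorted({r.polymer_class for r in rs}),
            "span": [min(r.number for r in rs), max(r.number for r in rs)],
        }
    return {"n_residues": len(s), "chains": per_chain}
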