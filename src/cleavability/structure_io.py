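"""Reading and writing protein structures and DSSP output.

Structures are read from fixed-column PDB files into a lightweight
:class:`StructureModel`. The original ``ATOM`` lines are retained verbatim so
that :func:`write_score_structure` can emit a file identical to its input
except for the temperature-factor column, which then carries per-residue
susceptibility scores for visualization (scores in [0, 1] are written as
score x 100, the conventional 0-100 coloring range).

For experimentally determined structures the temperature-factor column is the
crystallographic B-factor (A^2); for predicted models the same column carries a
per-residue confidence score in [0, 100] (e.g. AlphaFold's pLDDT), which is why
``source_kind`` travels with the structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio.Data.IUPACData import protein_letters_3to1

__all__ = [
    "AtomRecord",
    "ResidueRecord",
    "StructureModel",
    "DsspRecord",
    "read_structure",
    "extract_sequence",
    "parse_dssp",
    "write_score_structure",
    "write_structure",
    "three_to_one",
]

#: 3-letter -> 1-letter code for the 20 standard amino acids.
_THREE_TO_ONE = {k.upper(): v for k, v in protein_letters_3to1.items()}

#: Residue names treated as water and always dropped.
_WATERS = {"HOH", "DOD", "WAT"}


def three_to_one(res_name: str) -> str:
    """One-letter code for a 3-letter residue name; 'X' for anything nonstandard.

    Nonstandard residues (including chemically modified ones such as MSE) map
    to 'X' and are excluded from example generation downstream, because the
    features and PSSM columns are defined for the 20 standard residues.
    """
    return _THREE_TO_ONE.get(res_name.upper().strip(), "X")


@dataclass
class AtomRecord:
    """A single atom parsed from an ATOM/HETATM record."""

    name: str
    element: str
    coords: np.ndarray  # shape (3,), Angstrom
    occupancy: float
    tempfactor: float
    raw_line: str = ""  # original PDB line, kept for bit-faithful rewriting

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.name!r}")
        if self.tempfactor < 0:
            raise ValueError(f"negative temperature factor for atom {self.name!r}")


@dataclass
class ResidueRecord:
    chain_id: str
    seq_num: int
    icode: str
    res_name: str
    atoms: list[AtomRecord] = field(default_factory=list)

    @property
    def one_letter(self) -> str:
        return three_to_one(self.res_name)

    @property
    def tempfactor(self) -> float:
        """Unweighted mean temperature factor over the residue's atoms."""
        return float(np.mean([a.tempfactor for a in self.atoms]))

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class StructureModel:
    """One structure: ordered chains of ordered residues.

    ``source_kind`` is ``"experimental"`` (temperature factors are B-factors)
    or ``"predicted"`` (the same column is a confidence score in [0, 100]).
    """

    structure_id: str
    source_kind: str
    chains: dict[str, list[ResidueRecord]]

    def __post_init__(self) -> None:
        if self.source_kind not in ("experimental", "predicted"):
            raise ValueError(f"unknown source_kind {self.source_kind!r}")

    def chain(self, chain_id: str) -> list[ResidueRecord]:
        if chain_id not in self.chains:
            raise KeyError(
                f"chain {chain_id!r} not in structure {self.structure_id!r} "
                f"(available: {sorted(self.chains)})"
            )
        return self.chains[chain_id]

    def residue_tempfactors(self, chain_id: str) -> np.ndarray:
        return np.array([r.tempfactor for r in self.chain(chain_id)])


@dataclass
class DsspRecord:
    chain_id: str
    seq_num: int
    icode: str
    one_letter: str
    ss8: str  # one of H,G,I,E,B,T,S,'-'
    acc: float  # absolute accessible surface, A^2

    def __post_init__(self) -> None:
        if self.acc < 0:
            raise ValueError("negative accessibility in DSSP record")


def _parse_atom_line(line: str) -> tuple[str, str, int, str, str, AtomRecord]:
    name = line[12:16].strip()
    altloc = line[16].strip()
    res_name = line[17:20].strip()
    chain_id = line[21].strip() or " "
    seq_num = int(line[22:26])
    icode = line[26].strip()
    x = float(line[30:38])
    y = float(line[38:46])
    z = float(line[46:54])
    occ_str = line[54:60].strip()
    occupancy = float(occ_str) if occ_str else 1.0
    bf_str = line[60:66].strip()
    tempfactor = float(bf_str) if bf_str else 0.0
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        # fall back on the first letter of the atom name (columns 13-14 carry
        # the element for standard backbone/sidechain atoms)
        element = name[:1]
    atom = AtomRecord(
        name=name,
        element=element,
        coords=np.array([x, y, z]),
        occupancy=occupancy,
        tempfactor=tempfactor,
        raw_line=line.rstrip("\n"),
    )
    return altloc, chain_id, seq_num, icode, res_name, atom


def read_structure(path: str | Path, source_kind: str = "experimental") -> StructureModel:
    """Read a fixed-column PDB file into a :class:`StructureModel`.

    Only ``ATOM`` records of the first ``MODEL`` are kept; ``HETATM`` records,
    waters, and alternate locations other than '' or 'A' are dropped, so every
    residue carries a single deterministic conformer.

    Raises ``FileNotFoundError`` for a missing file and ``ValueError`` when the
    file contains no usable ATOM records.
    """
    path = Path(path)
    chains: dict[str, list[ResidueRecord]] = {}
    index: dict[tuple[str, int, str], ResidueRecord] = {}
    with open(path) as fh:
        for line in fh:
            rec = line[:6]
            if rec == "ENDMDL":
                break  # first model only
            if rec != "ATOM  ":
                continue
            altloc, chain_id, seq_num, icode, res_name, atom = _parse_atom_line(line)
            if altloc not in ("", "A"):
                continue
            if res_name in _WATERS:
                continue
            key = (chain_id, seq_num, icode)
            residue = index.get(key)
            if residue is None:
                residue = ResidueRecord(chain_id, seq_num, icode, res_name)
                index[key] = residue
                chains.setdefault(chain_id, []).append(residue)
            residue.atoms.append(atom)
    if not index:
        raise ValueError(f"no ATOM records in {path}")
    for chain_id, residues in chains.items():
        ordered = sorted(residues, key=lambda r: (r.seq_num, r.icode))
        if [id(r) for r in ordered] != [id(r) for r in residues]:
            chains[chain_id] = ordered
    return StructureModel(structure_id=path.stem, source_kind=source_kind, chains=chains)


def extract_sequence(structure: StructureModel, chain_id: str) -> str:
    """Amino-acid sequence of a chain, one letter per resolved residue.

    Nonstandard residues appear as 'X'. An empty chain yields "".
    """
    return "".join(r.one_letter for r in structure.chain(chain_id))


_SS8_CODES = set("HGIEBTS-")


def parse_dssp(path: str | Path) -> list[DsspRecord]:
    """Parse classic-format DSSP output into per-residue records.

    Chain-break lines ('!') are skipped; a blank secondary-structure column
    becomes '-'. Raises ``ValueError`` if the ``#  RESIDUE`` header that opens
    the residue table is missing.
    """
    records: list[DsspRecord] = []
    in_body = False
    with open(path) as fh:
        for line in fh:
            if not in_body:
                if line.lstrip().startswith("#  RESIDUE"):
                    in_body = True
                continue
            if len(line) < 38:
                continue
            if line[13] == "!":
                continue  # chain break
            seq_field = line[5:10].strip()
            if not seq_field:
                continue
            ss8 = line[16]
            if ss8 == " ":
                ss8 = "-"
            if ss8 not in _SS8_CODES:
                raise ValueError(f"unknown DSSP secondary-structure code {ss8!r}")
            records.append(
                DsspRecord(
                    chain_id=line[11].strip() or " ",
                    seq_num=int(seq_field),
                    icode=line[10].strip(),
                    one_letter=line[13],
                    ss8=ss8,
                    acc=float(line[34:38]),
                )
            )
    if not in_body:
        raise ValueError(f"not a classic-format DSSP file (missing '#  RESIDUE' header): {path}")
    return records


def write_structure(structure: StructureModel, path: str | Path) -> None:
    """Write the structure's ATOM records verbatim (plus END)."""
    with open(path, "w") as fh:
        for residues in structure.chains.values():
            for residue in residues:
                for atom in residue.atoms:
                    fh.write(atom.raw_line + "\n")
        fh.write("END\n")


def write_score_structure(
    structure: StructureModel,
    scores: Iterable[float],
    path: str | Path,
    chain_id: str | None = None,
) -> None:
    """Write the structure with per-residue scores in the temperature-factor column.

    Each atom line of the output is identical to the corresponding input line
    except for columns 61-66, which carry ``score * 100`` formatted ``%6.2f``.
    A round-trip read recovers the scores to two decimals. Scores are given in
    residue order over the selected chain (or over all chains when
    ``chain_id`` is None), one per residue.
    """
    if chain_id is not None:
        residues = structure.chain(chain_id)
    else:
        residues = [r for ch in structure.chains.values() for r in ch]
    scores = list(scores)
    if len(scores) != len(residues):
        raise ValueError(
            f"score count {len(scores)} does not match residue count {len(residues)}"
        )
    with open(path, "w") as fh:
        for residue, score in zip(residues, scores):
            for atom in residue.atoms:
                line = atom.raw_line
                if len(line) < 66:
                    line = line.ljust(66)
                fh.write(f"{line[:60]}{100.0 * float(score):6.2f}{line[66:]}\n")
        fh.write("END\n")
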