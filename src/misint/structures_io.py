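"""Coordinate containers and PDB input/output.

The in-memory model is a minimal hierarchy (Structure > Chain > Residue >
Atom) carrying only what the distance-based criteria of the pipeline need:
atom names, element symbols and Cartesian coordinates in Angstrom.  Parsing
and writing of the PDB format is delegated to :mod:`gemmi`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

#: the 20 standard three-letter amino-acid codes
STANDARD_AA = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

#: one-letter equivalents, used by residue-class groupings
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

_WATER_NAMES = {"HOH", "WAT", "DOD"}


class PDBParseError(ValueError):
    """Raised when a coordinate file cannot be interpreted."""


class PDBWriteError(ValueError):
    """Raised when a structure cannot be expressed in PDB format."""


@dataclass
class Atom:
    """A named atom with Cartesian coordinates in Angstrom."""

    name: str
    element: str
    coord: np.ndarray

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name}: coordinates must be 3 finite reals")


@dataclass
class Residue:
    """One amino-acid residue; ``index`` is 1-based and sequential per chain."""

    index: int
    name: str
    atoms: list[Atom]
    author_number: int | None = None

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError(f"residue {self.name}{self.index} has no atoms")

    @property
    def is_standard(self) -> bool:
        return self.name in STANDARD_AA

    @property
    def one_letter(self) -> str | None:
        return THREE_TO_ONE.get(self.name)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms])


@dataclass
class Chain:
    """An ordered run of residues with a single-character identifier."""

    id: str
    residues: list[Residue]

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"chain {self.id} is empty")
        idx = [r.index for r in self.residues]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError(f"chain {self.id}: residue indices must strictly increase")

    def __len__(self) -> int:
        return len(self.residues)

    def ca_coords(self) -> np.ndarray:
        """CA coordinates, one row per residue that has a CA atom."""
        rows = [r.atom("CA").coord for r in self.residues if r.atom("CA") is not None]
        return np.array(rows).reshape(-1, 3)

    def all_coords(self) -> np.ndarray:
        return np.vstack([r.coords for r in self.residues])

    def atom_residue_index(self) -> np.ndarray:
        """For each atom row of :meth:`all_coords`, the residue position (0-based)."""
        return np.repeat(np.arange(len(self.residues)), [len(r.atoms) for r in self.residues])


@dataclass
class Structure:
    """A set of chains under one identifier."""

    id: str
    chains: list[Chain]

    def __post_init__(self) -> None:
        ids = [c.id for c in self.chains]
        if len(set(ids)) != len(ids):
            raise ValueError(f"structure {self.id}: duplicate chain ids {ids}")

    def __iter__(self) -> Iterator[Chain]:
        return iter(self.chains)

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r} in structure {self.id}")

    def n_atoms(self) -> int:
        return sum(len(r.atoms) for c in self.chains for r in c.residues)


@dataclass
class HomologyModel:
    """A monomer model together with its target coverage.

    ``coverage`` is the fraction of the full-length target sequence that is
    present in the model (modelled residues / target length).
    """

    structure: Structure
    target_length: int
    coverage: float

    def __post_init__(self) -> None:
        if not (0.0 < self.coverage <= 1.0):
            raise ValueError(f"coverage must be in (0, 1], got {self.coverage}")


def _guess_element(atom_name: str) -> str:
    name = atom_name.strip()
    if not name:
        return "C"
    if name[0].isdigit():
        name = name.lstrip("0123456789")
    # two-letter elements relevant to amino acids
    if name[:2].upper() in ("SE",):
        return "Se"
    return name[0].upper()


def read_pdb(path: str | Path) -> Structure:
    """Read a PDB file into a :class:`Structure`.

    HETATM records (including waters) are skipped; for alternate locations
    only the first conformer (blank or 'A') is kept, with a logged warning.
    Residues are renumbered sequentially per chain; the author numbering is
    kept on each residue.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:  # gemmi reports the offending line
        raise PDBParseError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise PDBParseError(f"{path}: no model in file")
    model = st[0]
    chains: list[Chain] = []
    dropped_alt = 0
    for gchain in model:
        residues: list[Residue] = []
        for i, gres in enumerate(gchain):
            if gres.het_flag == "H" or gres.name in _WATER_NAMES:
                continue
            atoms: list[Atom] = []
            for gatom in gres:
                if gatom.altloc not in ("", "\x00", "A"):
                    dropped_alt += 1
                    continue
                pos = gatom.pos
                atoms.append(
                    Atom(
                        name=gatom.name,
                        element=gatom.element.name or _guess_element(gatom.name),
                        coord=np.array([pos.x, pos.y, pos.z]),
                    )
                )
            if atoms:
                residues.append(
                    Residue(
                        index=len(residues) + 1,
                        name=gres.name,
                        atoms=atoms,
                        author_number=gres.seqid.num,
                    )
                )
        if residues:
            chains.append(Chain(id=gchain.name, residues=residues))
    if dropped_alt:
        logger.warning("%s: dropped %d alternate-location atoms", path, dropped_alt)
    if not chains:
        raise PDBParseError(f"{path}: no ATOM records")
    return Structure(id=path.stem, chains=chains)


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write a :class:`Structure` as PDB ATOM records with TER between chains."""
    if structure.n_atoms() > 99999:
        raise PDBWriteError("PDB format is limited to 99999 atoms")
    st = gemmi.Structure()
    st.name = structure.id
    model = gemmi.Model("1")
    for chain in structure.chains:
        gchain = gemmi.Chain(chain.id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.index, " ")
            gres.het_flag = "A"
            for atom in res.atoms:
                gatom = gemmi.Atom()
                gatom.name = atom.name
                gatom.element = gemmi.Element(atom.element)
                gatom.pos = gemmi.Position(*atom.coord)
                gres.add_atom(gatom)
            gchain.add_residue(gres)
        model.add_chain(gchain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def filter_models_by_coverage(
    models: Iterable[HomologyModel], min_coverage: float = 0.4
) -> list[HomologyModel]:
    """Keep models covering at least ``min_coverage`` of their target length.

    Models below the threshold are excluded; order is preserved.
    """
    out: list[HomologyModel] = []
    for m in models:
        if not (0.0 < m.coverage <= 1.0):
            raise ValueError(f"coverage outside (0, 1]: {m.coverage}")
        if m.coverage >= min_coverage:
            out.append(m)
    return out


def read_pairs_tsv(path: str | Path):
    """Read a pair list (columns id_a, id_b and optionally label, source)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"id_a", "id_b"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_annotations_tsv(path: str | Path):
    """Read a long-format annotation table (columns id, key, value)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"id", "key", "value"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df
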