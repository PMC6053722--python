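"""PDB-format structure I/O and the pipeline's structure data model.

Parsing is delegated to :mod:`gemmi`; this module resolves the format's
ambiguities deterministically so the rest of the pipeline sees a single,
reproducible view of a structure:

* only the first MODEL of a multi-model file is kept;
* water and other HETATM records are dropped by default;
* for alternate-conformer groups, the highest-occupancy conformer is kept
  (ties broken by the alphabetically first alt-loc identifier);
* author (PDB) residue numbering is preserved everywhere, because the
  lysozyme literature refers to residues by author numbers (21, 62, ...).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Optional, Union

import gemmi
import numpy as np

__all__ = [
    "AtomSite",
    "ResidueSite",
    "StructureModel",
    "ResidueKey",
    "PDBParseError",
    "read_pdb",
    "write_pdb",
]

#: Residue identity used throughout the pipeline: (chain_id, author seq number,
#: insertion code).  Insertion codes are "" for almost all inputs here.
ResidueKey = tuple


class PDBParseError(ValueError):
    """Raised when a PDB stream cannot be turned into a StructureModel."""


WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


@dataclass
class AtomSite:
    """One atom: name, element, coordinates (Å), occupancy and B-factor (Å²)."""

    serial: int
    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0
    alt_loc: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name!r}: coords must be a finite 3-vector")
        if self.b_factor < 0:
            raise ValueError(f"atom {self.name!r}: negative B-factor")
        if not self.name:
            raise ValueError("atom name must be non-empty")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


@dataclass
class ResidueSite:
    """One residue: chain, author number, insertion code, name, atoms."""

    chain_id: str
    seq_number: int
    insertion_code: str
    res_name: str
    atoms: list = field(default_factory=list)

    @property
    def key(self) -> ResidueKey:
        return (self.chain_id, self.seq_number, self.insertion_code)

    def atom(self, name: str) -> Optional[AtomSite]:
        """First atom with this name, or None."""
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_atoms(self) -> list:
        return [a for a in self.atoms if not a.is_hydrogen]

    @property
    def ca(self) -> Optional[AtomSite]:
        return self.atom("CA")

    def mean_b_factor(self) -> float:
        """Per-residue B-factor: unweighted mean over this residue's atoms."""
        return float(np.mean([a.b_factor for a in self.atoms]))


@dataclass
class StructureModel:
    """A parsed structure: ordered chains of residues, plus resolution if known."""

    id: str
    chains: dict = field(default_factory=dict)  # chain_id -> list[ResidueSite]
    resolution: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.chains:
            raise ValueError("StructureModel needs at least one chain")
        seen = set()
        for cid, residues in self.chains.items():
            for r in residues:
                if not r.atoms:
                    raise ValueError(f"residue {r.key} has no atoms")
                if r.key in seen:
                    raise ValueError(f"duplicate residue key {r.key}")
                seen.add(r.key)

    def residues(self) -> Iterable[ResidueSite]:
        for residues in self.chains.values():
            yield from residues

    def residue(self, key: ResidueKey) -> ResidueSite:
        chain_id, seq, icode = key
        for r in self.chains[chain_id]:
            if r.seq_number == seq and r.insertion_code == icode:
                return r
        raise KeyError(key)

    @property
    def n_residues(self) -> int:
        return sum(len(v) for v in self.chains.values())

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues())


def _pick_alt_conformers(residue: gemmi.Residue) -> list:
    """Resolve alt-loc groups: per atom name keep the highest-occupancy
    conformer, ties broken by the alphabetically first alt-loc."""
    by_name: dict = {}
    for atom in residue:
        by_name.setdefault(atom.name, []).append(atom)
    kept = []
    for name, group in by_name.items():
        best = min(group, key=lambda a: (-a.occ, a.altloc or "~"))
        kept.append(best)
    # preserve original file order
    order = {id(a): i for i, a in enumerate(residue)}
    kept.sort(key=lambda a: order[id(a)])
    return kept


def read_pdb(
    source: Union[str, io.TextIOBase],
    *,
    model_id: Optional[str] = None,
    keep_hetatm: bool = False,
) -> StructureModel:
    """Parse PDB-format text into a :class:`StructureModel`.

    Parameters
    ----------
    source
        PDB text, a text stream, or a filesystem path ending in ``.pdb``/``.ent``.
    model_id
        Identifier for the returned model; defaults to the file's ID code or
        the path stem.
    keep_hetatm
        Retain non-water HETATM residues (waters are always dropped).
    """
    path_stem = None
    if hasattr(source, "read"):
        text = source.read()
    elif isinstance(source, str) and not source.lstrip().startswith(
        ("ATOM", "HETATM", "HEADER", "REMARK", "MODEL", "CRYST", "TITLE", "EXPDTA", "SEQRES")
    ) and "\n" not in source:
        import pathlib

        p = pathlib.Path(source)
        path_stem = p.stem
        text = p.read_text()
    else:
        text = source

    n_atom_records = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith(("ATOM", "HETATM")):
            n_atom_records += line.startswith("ATOM")
            try:
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    float(line[lo:hi])
            except (ValueError, IndexError) as exc:
                raise PDBParseError(
                    f"malformed coordinate field on line {lineno}: {line.rstrip()!r}"
                ) from exc
    if n_atom_records == 0:
        raise PDBParseError("no ATOM records found")

    try:
        st = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:  # gemmi reports the offending line
        raise PDBParseError(f"malformed PDB record: {exc}") from exc

    if len(st) == 0:
        raise PDBParseError("no coordinate model found")
    model = st[0]  # first MODEL only

    chains: dict = {}
    for chain in model:
        residues: list = []
        for res in chain:
            het = res.het_flag == "H"
            if res.name in WATER_NAMES:
                continue
            if het and not keep_hetatm:
                continue
            atoms = [
                AtomSite(
                    serial=a.serial,
                    name=a.name,
                    element=a.element.name,
                    coords=np.array([a.pos.x, a.pos.y, a.pos.z]),
                    occupancy=a.occ,
                    b_factor=a.b_iso,
                    alt_loc=(a.altloc or "").replace("\x00", ""),
                )
                for a in _pick_alt_conformers(res)
            ]
            if not atoms:
                continue
            residues.append(
                ResidueSite(
                    chain_id=chain.name,
                    seq_number=res.seqid.num,
                    insertion_code=(res.seqid.icode or "").strip(),
                    res_name=res.name,
                    atoms=atoms,
                )
            )
        if residues:
            chains[chain.name] = residues

    if not chains:
        raise PDBParseError("no protein residues retained")

    resolution = st.resolution if st.resolution and st.resolution > 0 else None
    header_id = (
        st.info["_entry.id"].strip().lower() if "_entry.id" in st.info else None
    ) or None
    name = model_id or header_id or path_stem or "model"
    return StructureModel(id=name, chains=chains, resolution=resolution)


def write_pdb(model: StructureModel) -> str:
    """Serialize a :class:`StructureModel` back to PDB-format text.

    Chains are emitted in model order, each terminated by a TER record;
    coordinates keep 3 decimals and B-factors 2, as the format prescribes,
    so ``read_pdb(write_pdb(m))`` reproduces the retained fields.
    """
    st = gemmi.Structure()
    st.name = model.id
    if model.resolution is not None:
        st.resolution = model.resolution
    gmodel = gemmi.Model("1")
    for chain_id, residues in model.chains.items():
        if len(chain_id) != 1:
            raise ValueError(
                f"chain id {chain_id!r} does not fit the single-column PDB chain field"
            )
        gchain = gemmi.Chain(chain_id)
        for r in residues:
            gres = gemmi.Residue()
            gres.name = r.res_name
            gres.seqid = gemmi.SeqId(r.seq_number, r.insertion_code or " ")
            gres.het_flag = "A"
            for a in r.atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(*a.coords)
                ga.occ = a.occupancy
                ga.b_iso = a.b_factor
                ga.altloc = a.alt_loc or "\0"
                gres.add_atom(ga)
            gchain.add_residue(gres)
        gmodel.add_chain(gchain)
    st.add_model(gmodel)
    st.setup_entities()
    return st.make_pdb_string(gemmi.PdbWriteOptions(minimal=True, numbered_ter=True))
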