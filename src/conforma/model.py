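"""In-memory structure model and coordinate-file I/O.

The model keeps *author* numbering (auth chain id / auth seq id / insertion
code) as the canonical addressing scheme, because that is how residues are
referred to in the structural literature (e.g. "F153", "residues 292-304").

Parsing is delegated to :mod:`gemmi`; the normalisation applied on top is:

* alternate locations are collapsed to the highest-occupancy conformer
  (ties broken by alphabetically first altloc letter),
* hydrogens are dropped,
* waters and other hetero residues are kept as ligands, outside the polymer.

Selenomethionine (MSE) is treated as methionine for sequence and C-alpha
purposes and stays in the polymer.
"""

from __future__ import annotations

import copy
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "ResidueKey",
    "Residue",
    "StructureModel",
    "DomainDefinition",
    "CalphaSelection",
    "StructureParseError",
    "SelectionError",
    "read_structure",
    "write_pdb",
    "select_calpha",
    "extract_sequence",
    "three_to_one",
]


class StructureParseError(ValueError):
    """Raised when a coordinate file cannot be turned into a valid model."""


class SelectionError(KeyError):
    """Raised when a chain/domain selection resolves to nothing."""


#: standard 3-letter -> 1-letter amino-acid mapping (MSE folded into MET)
_AA3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M",
}

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}

#: atomic masses for the elements that occur in protein models (Da)
ATOMIC_MASS = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "SE": 78.971, "FE": 55.845, "ZN": 65.38, "MG": 24.305,
}


def three_to_one(res_name: str) -> str:
    """One-letter code for a residue name; unknown names map to ``X``."""
    return _AA3TO1.get(res_name.upper(), "X")


@dataclass
class AtomRecord:
    """A single heavy atom with author-file metadata."""

    name: str
    element: str
    coords: np.ndarray  # shape (3,), angstrom
    occupancy: float = 1.0
    b_factor: float = 0.0
    altloc: str = ""
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coords must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")


class ResidueKey(NamedTuple):
    """Author-numbered residue identity: (chain, number, insertion code, name)."""

    chain_id: str
    seq_num: int
    icode: str
    res_name: str

    def __str__(self) -> str:  # e.g. "A/PHE153"
        return f"{self.chain_id}/{self.res_name}{self.seq_num}{self.icode.strip()}"


@dataclass
class Residue:
    key: ResidueKey
    atoms: dict[str, AtomRecord] = field(default_factory=dict)

    @property
    def ca(self) -> AtomRecord | None:
        return self.atoms.get("CA")

    def heavy_atoms(self) -> Iterable[AtomRecord]:
        return self.atoms.values()


@dataclass
class DomainDefinition:
    """A named set of inclusive author-numbered residue intervals."""

    name: str
    ranges: list[tuple[str, int, int]]  # (chain_id, start_seq, end_seq)

    def __post_init__(self) -> None:
        if not self.ranges:
            raise ValueError(f"domain {self.name}: ranges must be non-empty")
        per_chain: dict[str, list[tuple[int, int]]] = {}
        for chain_id, start, end in self.ranges:
            if start > end:
                raise ValueError(f"domain {self.name}: range {start}-{end} has start > end")
            per_chain.setdefault(chain_id, []).append((start, end))
        for chain_id, spans in per_chain.items():
            spans.sort()
            for (s0, e0), (s1, _e1) in zip(spans, spans[1:]):
                if s1 <= e0:
                    raise ValueError(
                        f"domain {self.name}: overlapping ranges on chain {chain_id}"
                    )

    def contains(self, key: ResidueKey) -> bool:
        return any(
            key.chain_id == chain_id and start <= key.seq_num <= end
            for chain_id, start, end in self.ranges
        )

    def on_chain(self, chain_id: str) -> "DomainDefinition":
        """Restriction of the definition to a single chain (renamed intervals kept)."""
        ranges = [r for r in self.ranges if r[0] == chain_id]
        if not ranges:
            raise SelectionError(f"domain {self.name} has no ranges on chain {chain_id}")
        return DomainDefinition(self.name, ranges)


@dataclass
class StructureModel:
    """Parsed coordinate set: ordered polymer chains plus hetero ligands."""

    id: str
    chains: dict[str, list[Residue]]
    ligands: list[Residue] = field(default_factory=list)
    source_format: str = "pdb"

    def residues(self) -> Iterable[Residue]:
        for chain in self.chains.values():
            yield from chain

    def all_atoms(self, include_ligands: bool = False) -> list[tuple[ResidueKey, AtomRecord]]:
        out = [(res.key, atom) for res in self.residues() for atom in res.heavy_atoms()]
        if include_ligands:
            out.extend((res.key, atom) for res in self.ligands for atom in res.heavy_atoms())
        return out

    def chain(self, chain_id: str) -> list[Residue]:
        try:
            return self.chains[chain_id]
        except KeyError:
            raise SelectionError(
                f"chain {chain_id!r} not in model {self.id} (have {sorted(self.chains)})"
            ) from None

    def find_residue(self, chain_id: str, seq_num: int, icode: str = "") -> Residue:
        for res in self.chain(chain_id):
            if res.key.seq_num == seq_num and res.key.icode == icode:
                return res
        raise SelectionError(f"residue {chain_id}/{seq_num}{icode} not in model {self.id}")

    def ligand_residues(self, res_name: str | None = None) -> list[Residue]:
        if res_name is None:
            return list(self.ligands)
        return [r for r in self.ligands if r.key.res_name == res_name.upper()]

    def copy(self) -> "StructureModel":
        return copy.deepcopy(self)

    def transform(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Return a rigidly transformed copy (x -> R x + t), ligands included."""
        out = self.copy()
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        for res in list(out.residues()) + out.ligands:
            for atom in res.heavy_atoms():
                atom.coords = R @ atom.coords + t
        return out


class CalphaSelection(NamedTuple):
    """C-alpha pick with a skip report for residues lacking a CA atom."""

    entries: list[tuple[ResidueKey, np.ndarray]]
    skipped: list[tuple[ResidueKey, str]]

    def coords(self) -> np.ndarray:
        return np.array([c for _, c in self.entries], dtype=float).reshape(-1, 3)

    def keys(self) -> list[ResidueKey]:
        return [k for k, _ in self.entries]

    def skip_report_tsv(self) -> str:
        lines = ["chain\tseq_num\treason"]
        lines += [f"{k.chain_id}\t{k.seq_num}\t{reason}" for k, reason in self.skipped]
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# reading


def _collapse_altlocs(records: list[AtomRecord]) -> list[AtomRecord]:
    """One atom per name: highest occupancy wins, ties -> first altloc letter."""
    by_name: dict[str, list[AtomRecord]] = {}
    for rec in records:
        by_name.setdefault(rec.name, []).append(rec)
    kept = []
    for recs in by_name.values():
        recs.sort(key=lambda a: (-a.occupancy, a.altloc))
        winner = recs[0]
        winner.altloc = ""
        kept.append(winner)
    return kept


def _is_polymer_residue(res_name: str) -> bool:
    return res_name.upper() in _AA3TO1


def read_structure(path: str | Path, format: str = "auto") -> StructureModel:
    """Read a PDB or mmCIF file into a normalised :class:`StructureModel`.

    ``format`` may be ``pdb``, ``mmcif`` or ``auto`` (extension/content based).
    The first model of multi-model files is used.
    """
    path = Path(path)
    if not path.exists():
        raise StructureParseError(f"file not found: {path}")
    try:
        if format == "pdb":
            st = gemmi.read_pdb(str(path))
        elif format == "mmcif":
            doc = gemmi.cif.read(str(path))
            st = gemmi.make_structure_from_block(doc.sole_block())
        elif format == "auto":
            st = gemmi.read_structure(str(path))
        else:
            raise ValueError(f"unknown format {format!r}")
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"cannot parse {path.name}: {exc}") from exc

    if len(st) == 0:
        raise StructureParseError(f"{path.name}: file contains no models")
    gmodel = st[0]

    chains: dict[str, list[Residue]] = {}
    ligands: list[Residue] = []
    for gchain in gmodel:
        for gres in gchain:
            icode = gres.seqid.icode.strip()
            res_name = gres.name.upper()
            key = ResidueKey(gchain.name, gres.seqid.num, icode, res_name)
            records = []
            for gatom in gres:
                if gatom.element.is_hydrogen:
                    continue
                records.append(
                    AtomRecord(
                        name=gatom.name,
                        element=gatom.element.name.upper(),
                        coords=np.array([gatom.pos.x, gatom.pos.y, gatom.pos.z]),
                        occupancy=min(max(gatom.occ, 0.0), 1.0),
                        b_factor=gatom.b_iso,
                        altloc=(gatom.altloc or "").strip(),
                        is_hetero=gres.het_flag == "H",
                    )
                )
            if not records:
                continue
            residue = Residue(key, {a.name: a for a in _collapse_altlocs(records)})
            if _is_polymer_residue(res_name):
                chains.setdefault(gchain.name, []).append(residue)
            else:
                ligands.append(residue)

    for chain in chains.values():
        chain.sort(key=lambda r: (r.key.seq_num, r.key.icode))

    if not chains:
        raise StructureParseError(f"{path.name}: no polymer residues")

    fmt = format
    if fmt == "auto":
        fmt = "mmcif" if path.suffix.lower() in {".cif", ".mmcif"} else "pdb"
    return StructureModel(id=path.stem, chains=chains, ligands=ligands, source_format=fmt)


# ---------------------------------------------------------------------------
# writing (fixed-column PDB; enough for synthetic structures and round-trips)

_PDB_ATOM_FMT = (
    "{record:<6}{serial:>5} {name:<4}{altloc:1}{res_name:<3} {chain:1}"
    "{seq_num:>4}{icode:1}   {x:>8.3f}{y:>8.3f}{z:>8.3f}{occ:>6.2f}{b:>6.2f}"
    "          {element:>2}"
)


def _pdb_atom_name(name: str, element: str) -> str:
    # columns 13-16: element right-justified in 13-14 for 1/2-letter elements
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1:
        return f" {name:<3}"
    return f"{name:<4}"


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write the model as fixed-column PDB text (polymer then ligands)."""
    lines: list[str] = []
    serial = 0

    def emit(res: Residue, record: str) -> None:
        nonlocal serial
        for atom in res.heavy_atoms():
            serial += 1
            lines.append(
                _PDB_ATOM_FMT.format(
                    record=record,
                    serial=serial,
                    name=_pdb_atom_name(atom.name, atom.element),
                    altloc=atom.altloc or " ",
                    res_name=res.key.res_name,
                    chain=res.key.chain_id[:1] or "A",
                    seq_num=res.key.seq_num,
                    icode=res.key.icode or " ",
                    x=atom.coords[0],
                    y=atom.coords[1],
                    z=atom.coords[2],
                    occ=atom.occupancy,
                    b=atom.b_factor,
                    element=atom.element[:2],
                )
            )

    for chain_id in model.chains:
        for res in model.chains[chain_id]:
            emit(res, "ATOM")
        lines.append("TER")
    for res in model.ligands:
        emit(res, "HETATM")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# selections


def select_calpha(
    model: StructureModel, selection: DomainDefinition | str
) -> CalphaSelection:
    """C-alpha coordinates for a chain or domain, in chain order.

    Residues without a CA atom are skipped and listed in the skip report.
    """
    if isinstance(selection, str):
        residues = model.chain(selection)
    else:
        residues = [r for r in model.residues() if selection.contains(r.key)]
        if not residues:
            raise SelectionError(f"selection {selection.name!r} matches nothing")
    if not residues:
        raise SelectionError("selection matches nothing")

    entries: list[tuple[ResidueKey, np.ndarray]] = []
    skipped: list[tuple[ResidueKey, str]] = []
    for res in residues:
        ca = res.ca
        if ca is None:
            skipped.append((res.key, "no CA atom"))
        else:
            entries.append((res.key, ca.coords.copy()))
    if not entries:
        raise SelectionError("selection matches nothing (no residue has a CA atom)")
    return CalphaSelection(entries, skipped)


def extract_sequence(model: StructureModel, chain_id: str, gap_char: str = "-") -> str:
    """One-letter sequence over the chain's author-number span.

    Missing residue numbers (disordered stretches) appear as ``gap_char``;
    unknown residue names appear as ``X``. Length is max - min seq_num + 1.
    """
    residues = model.chain(chain_id)
    by_num: dict[int, str] = {}
    for res in residues:
        by_num[res.key.seq_num] = three_to_one(res.key.res_name)
    lo, hi = min(by_num), max(by_num)
    return "".join(by_num.get(i, gap_char) for i in range(lo, hi + 1))
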