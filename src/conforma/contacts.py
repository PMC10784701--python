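"""Distance-based active-site contact analysis.

All criteria are heavy-atom distances: crystal structures at typical
resolutions carry no reliable hydrogens, so hydrogen bonds are reported as
donor/acceptor heavy-atom pairs within a distance cutoff, with chemical
typing from a residue/atom table (an optional coarse angle filter on the
donor antecedent is available but off by default). Salt bridges pair the
charged-group nitrogens of Arg/Lys/His (and the N-terminal amine) with the
carboxylate oxygens of Asp/Glu (and the C-terminal carboxylate).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .model import AtomRecord, Residue, ResidueKey, StructureModel

__all__ = [
    "ContactRecord",
    "AtomSelection",
    "select_atoms",
    "ligand_environment",
    "hydrogen_bonds",
    "salt_bridges",
    "min_distance",
    "contacts_tsv",
]


@dataclass
class ContactRecord:
    key_1: ResidueKey
    atom_1: str
    key_2: ResidueKey
    atom_2: str
    distance: float
    kind: str  # contact | hbond | salt_bridge

    def canonical(self) -> "ContactRecord":
        """Order-independent orientation (smaller residue key first)."""
        if (self.key_2, self.atom_2) < (self.key_1, self.atom_1):
            return ContactRecord(
                self.key_2, self.atom_2, self.key_1, self.atom_1, self.distance, self.kind
            )
        return self


AtomSelection = Sequence[tuple[ResidueKey, AtomRecord]]


def select_atoms(
    model: StructureModel,
    chain: str | None = None,
    seq_num: int | None = None,
    res_name: str | None = None,
    atom_names: Iterable[str] | None = None,
    include_ligands: bool = False,
) -> list[tuple[ResidueKey, AtomRecord]]:
    """Flat atom list filtered by chain / residue number / name / atom names."""
    atom_names = {a.upper() for a in atom_names} if atom_names else None
    out = []
    for key, atom in model.all_atoms(include_ligands=include_ligands):
        if chain is not None and key.chain_id != chain:
            continue
        if seq_num is not None and key.seq_num != seq_num:
            continue
        if res_name is not None and key.res_name != res_name.upper():
            continue
        if atom_names is not None and atom.name.upper() not in atom_names:
            continue
        out.append((key, atom))
    return out


# ---------------------------------------------------------------------------
# donor / acceptor typing (heavy atoms, standard residues; waters are both)

_SIDECHAIN_DONORS = {
    "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"}, "CYS": {"SG"},
    "ASN": {"ND2"}, "GLN": {"NE2"}, "LYS": {"NZ"}, "TRP": {"NE1"},
    "ARG": {"NE", "NH1", "NH2"}, "HIS": {"ND1", "NE2"},
}
_SIDECHAIN_ACCEPTORS = {
    "ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}, "ASN": {"OD1"},
    "GLN": {"OE1"}, "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"},
    "HIS": {"ND1", "NE2"}, "MET": {"SD"},
}
_WATERS = {"HOH", "WAT", "DOD", "H2O"}

_BASIC_ATOMS = {"ARG": {"NE", "NH1", "NH2"}, "LYS": {"NZ"}, "HIS": {"ND1", "NE2"}}
_ACIDIC_ATOMS = {"ASP": {"OD1", "OD2"}, "GLU": {"OE1", "OE2"}}


def _is_donor(key: ResidueKey, atom: AtomRecord) -> bool:
    if key.res_name in _WATERS:
        return atom.element == "O"
    if atom.name == "N" and key.res_name != "PRO":
        return True  # backbone amide
    if atom.is_hetero:  # non-water ligand (cofactor): type by element
        return atom.element in {"N", "O"}
    return atom.name in _SIDECHAIN_DONORS.get(key.res_name, ())


def _is_acceptor(key: ResidueKey, atom: AtomRecord) -> bool:
    if key.res_name in _WATERS:
        return atom.element == "O"
    if atom.name in {"O", "OXT"}:
        return True  # backbone carbonyl / terminal carboxylate
    if atom.is_hetero:
        return atom.element in {"N", "O", "S"}
    return atom.name in _SIDECHAIN_ACCEPTORS.get(key.res_name, ())


# ---------------------------------------------------------------------------


def _pairwise_contacts(
    set_a: AtomSelection,
    set_b: AtomSelection,
    cutoff: float,
    kind: str,
    accept: Callable[[ResidueKey, AtomRecord, ResidueKey, AtomRecord], bool] | None = None,
) -> list[ContactRecord]:
    if not set_a or not set_b:
        return []
    coords_b = np.array([a.coords for _, a in set_b])
    tree = cKDTree(coords_b)
    records = []
    for key_a, atom_a in set_a:
        for j in tree.query_ball_point(atom_a.coords, cutoff):
            key_b, atom_b = set_b[j]
            if key_a == key_b:
                continue  # no intra-residue contacts
            if accept is not None and not accept(key_a, atom_a, key_b, atom_b):
                continue
            d = float(np.linalg.norm(atom_a.coords - atom_b.coords))
            if 0.0 < d <= cutoff:
                records.append(ContactRecord(key_a, atom_a.name, key_b, atom_b.name, d, kind))
    unique = {}
    for rec in records:
        rec = rec.canonical()
        unique[(rec.key_1, rec.atom_1, rec.key_2, rec.atom_2)] = rec
    return sorted(unique.values(), key=lambda r: r.distance)


def ligand_environment(
    model: StructureModel,
    ligand: str | ResidueKey,
    cutoff: float = 4.0,
) -> tuple[list[ContactRecord], dict[ResidueKey, float]]:
    """Polymer atoms within ``cutoff`` of any atom of the named ligand.

    ``ligand`` is a hetero residue name (e.g. ``"SAM"``) or an exact residue
    key. Returns distance-sorted contacts plus a per-residue minimum-distance
    summary.
    """
    if isinstance(ligand, ResidueKey):
        lig_residues = [r for r in model.ligands if r.key == ligand]
    else:
        lig_residues = model.ligand_residues(ligand)
    if not lig_residues:
        names = sorted({r.key.res_name for r in model.ligands})
        raise ValueError(f"ligand {ligand!r} not found; hetero residues present: {names}")
    lig_atoms = [(r.key, a) for r in lig_residues for a in r.heavy_atoms()]
    poly_atoms = model.all_atoms(include_ligands=False)
    records = _pairwise_contacts(lig_atoms, poly_atoms, cutoff, "contact")
    per_residue: dict[ResidueKey, float] = {}
    for rec in records:
        poly_key = rec.key_1 if not _is_ligand_key(rec.key_1, lig_residues) else rec.key_2
        per_residue[poly_key] = min(per_residue.get(poly_key, np.inf), rec.distance)
    return records, per_residue


def _is_ligand_key(key: ResidueKey, lig_residues: list[Residue]) -> bool:
    return any(key == r.key for r in lig_residues)


def hydrogen_bonds(
    model: StructureModel,
    selection_a: AtomSelection | None = None,
    selection_b: AtomSelection | None = None,
    d_max: float = 3.5,
    angle_filter: bool = False,
) -> list[ContactRecord]:
    """Donor-acceptor heavy-atom pairs within ``d_max``.

    Without hydrogens the rule is distance plus chemical typing only.
    With ``angle_filter`` a coarse geometry check requires the
    antecedent-donor-acceptor angle to be >= 90 degrees.
    """
    everything = model.all_atoms(include_ligands=True)
    set_a = list(selection_a) if selection_a is not None else everything
    set_b = list(selection_b) if selection_b is not None else everything

    antecedents = _antecedent_map(model) if angle_filter else {}

    def accept(k1: ResidueKey, a1: AtomRecord, k2: ResidueKey, a2: AtomRecord) -> bool:
        forward = _is_donor(k1, a1) and _is_acceptor(k2, a2)
        backward = _is_donor(k2, a2) and _is_acceptor(k1, a1)
        if not (forward or backward):
            return False
        if angle_filter:
            ok = False
            if forward and _angle_ok(antecedents, k1, a1, a2):
                ok = True
            if backward and _angle_ok(antecedents, k2, a2, a1):
                ok = True
            return ok
        return True

    return _pairwise_contacts(set_a, set_b, d_max, "hbond", accept)


def _antecedent_map(model: StructureModel) -> dict[tuple[ResidueKey, str], np.ndarray]:
    """Covalent antecedent (bonded heavy atom) per potential donor atom."""
    out = {}
    for res in list(model.residues()) + model.ligands:
        atoms = list(res.heavy_atoms())
        for atom in atoms:
            others = [a for a in atoms if a.name != atom.name]
            if not others:
                continue
            nearest = min(others, key=lambda a: np.linalg.norm(a.coords - atom.coords))
            out[(res.key, atom.name)] = nearest.coords
    return out


def _angle_ok(
    antecedents: dict, key: ResidueKey, donor: AtomRecord, acceptor: AtomRecord
) -> bool:
    ante = antecedents.get((key, donor.name))
    if ante is None:
        return True
    v1 = ante - donor.coords
    v2 = acceptor.coords - donor.coords
    cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2) + 1e-12)
    return np.degrees(np.arccos(np.clip(cosang, -1, 1))) >= 90.0


def salt_bridges(model: StructureModel, d_max: float = 4.0) -> list[ContactRecord]:
    """Charged-group nitrogen/oxygen pairs within ``d_max`` (plus termini)."""
    basic, acidic = [], []
    for chain_id, chain in model.chains.items():
        for i, res in enumerate(chain):
            for atom in res.heavy_atoms():
                if atom.name in _BASIC_ATOMS.get(res.key.res_name, ()):
                    basic.append((res.key, atom))
                if atom.name in _ACIDIC_ATOMS.get(res.key.res_name, ()):
                    acidic.append((res.key, atom))
                # chain termini carry charges too
                if i == 0 and atom.name == "N":
                    basic.append((res.key, atom))
                if i == len(chain) - 1 and atom.name in {"OXT", "O"}:
                    acidic.append((res.key, atom))
    records = _pairwise_contacts(basic, acidic, d_max, "salt_bridge")
    return records


def min_distance(
    selection_a: AtomSelection, selection_b: AtomSelection
) -> tuple[float, ContactRecord]:
    """Minimum heavy-atom distance between two selections (self-pairs excluded)."""
    if not selection_a or not selection_b:
        raise ValueError("min_distance: both selections must be non-empty")
    best = None
    for key_a, atom_a in selection_a:
        for key_b, atom_b in selection_b:
            if key_a == key_b and atom_a.name == atom_b.name:
                continue
            d = float(np.linalg.norm(atom_a.coords - atom_b.coords))
            if best is None or d < best[0]:
                best = (d, ContactRecord(key_a, atom_a.name, key_b, atom_b.name, d, "contact"))
    if best is None:
        raise ValueError("min_distance: selections contain only self-pairs")
    return best


def contacts_tsv(records: Iterable[ContactRecord]) -> str:
    lines = ["chain\tseq_num\tres_name\tatom\tchain_2\tseq_num_2\tres_name_2\tatom_2\tdistance\tkind"]
    for rec in records:
        lines.append(
            f"{rec.key_1.chain_id}\t{rec.key_1.seq_num}\t{rec.key_1.res_name}\t{rec.atom_1}\t"
            f"{rec.key_2.chain_id}\t{rec.key_2.seq_num}\t{rec.key_2.res_name}\t{rec.atom_2}\t"
            f"{rec.distance:.3f}\t{rec.kind}"
        )
    return "\n".join(lines) + "\n"
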