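"""Ground-truthed synthetic inputs for every analysis stage.

Three generators, all pure functions of (spec, seed):

* ``make_two_domain_pair`` — a poly-alanine backbone built from ideal
  peptide geometry with helical dihedrals, split into two domains; the
  "closed" copy has domain B rotated by a known hinge angle about a known
  axis, optionally with Gaussian coordinate noise. The truth record carries
  the exact per-residue displacements, so hinge-angle and displacement
  recovery can be scored without re-deriving geometry.
* ``make_cavity_solid`` — a watertight spherical shell of pseudo-atoms on a
  Fibonacci lattice enclosing a cavity of known analytic volume, with an
  optional aperture cone.
* ``make_motif_family`` — sequence families derived from a fixed scaffold
  by seeded point mutation, with motif-tier and catalytic-class residues
  planted at the reference positions at prescribed fractions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model import AtomRecord, Residue, ResidueKey, StructureModel
from .motifs import AMINO_ACIDS, TIER_ORDER, SequenceRecord

__all__ = [
    "ToyStructureSpec",
    "CavitySolidSpec",
    "make_two_domain_pair",
    "make_cavity_solid",
    "analytic_cavity_volume",
    "make_motif_family",
    "random_scaffold",
    "build_helix",
    "SCAFFOLD_SEQUENCE",
]

# ideal peptide geometry (angstrom / degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.5
OMEGA = 180.0

HELIX_PHI = -57.0
HELIX_PSI = -47.0


def _place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray, bond: float, angle_deg: float, torsion_deg: float
) -> np.ndarray:
    """Natural-extension-reference-frame placement of the next atom.

    Returns the point at distance ``bond`` from ``c``, with angle
    ``angle_deg`` at ``c`` (b-c-new) and torsion ``torsion_deg`` about b-c
    (a-b-c-new).
    """
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array(
        [
            -bond * math.cos(angle),
            bond * math.sin(angle) * math.cos(torsion),
            bond * math.sin(angle) * math.sin(torsion),
        ]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


def build_helix(
    n_res: int,
    phi: float = HELIX_PHI,
    psi: float = HELIX_PSI,
    chain_id: str = "A",
    start_num: int = 1,
    res_name: str = "ALA",
) -> StructureModel:
    """Ideal-geometry poly-alanine backbone (N, CA, C, O) with fixed phi/psi."""
    if n_res < 1:
        raise ValueError("build_helix: need at least one residue")
    # seed the first residue with an arbitrary non-collinear frame
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = n0 + np.array([BOND_N_CA, 0.0, 0.0])
    angle = math.radians(ANGLE_N_CA_C)
    c0 = ca0 + BOND_CA_C * np.array([-math.cos(angle), math.sin(angle), 0.0])

    backbone: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = [(n0, ca0, c0)]
    for _ in range(1, n_res):
        n_prev, ca_prev, c_prev = backbone[-1]
        n_next = _place_atom(n_prev, ca_prev, c_prev, BOND_C_N, ANGLE_CA_C_N, psi)
        ca_next = _place_atom(ca_prev, c_prev, n_next, BOND_N_CA, ANGLE_C_N_CA, OMEGA)
        c_next = _place_atom(c_prev, n_next, ca_next, BOND_CA_C, ANGLE_N_CA_C, phi)
        backbone.append((n_next, ca_next, c_next))

    residues = []
    for i, (n, ca, c) in enumerate(backbone):
        key = ResidueKey(chain_id, start_num + i, "", res_name)
        atoms = {
            "N": AtomRecord("N", "N", n),
            "CA": AtomRecord("CA", "C", ca),
            "C": AtomRecord("C", "C", c),
        }
        # carbonyl O: in the peptide plane, opposite the next N (psi + 180)
        o = _place_atom(n, ca, c, BOND_C_O, ANGLE_CA_C_O, psi + 180.0)
        atoms["O"] = AtomRecord("O", "O", o)
        residues.append(Residue(key, atoms))
    return StructureModel(id=f"helix{n_res}", chains={chain_id: residues}, source_format="pdb")


def _rotation_about(axis: np.ndarray, point: np.ndarray, theta_deg: float) -> tuple[np.ndarray, np.ndarray]:
    """(R, t) of the rotation by theta about the line (point, axis)."""
    u = np.asarray(axis, float)
    u = u / np.linalg.norm(u)
    th = math.radians(theta_deg)
    K = np.array([[0, -u[2], u[1]], [u[2], 0, -u[0]], [-u[1], u[0], 0]])
    R = np.eye(3) + math.sin(th) * K + (1 - math.cos(th)) * (K @ K)
    t = point - R @ point
    return R, t


@dataclass
class ToyStructureSpec:
    """Two-domain conformer-pair specification; seed fixes all randomness."""

    n_res_domain_a: int = 40
    n_res_domain_b: int = 40
    hinge_axis: Sequence[float] = (0.0, 0.0, 1.0)
    hinge_point: Sequence[float] | None = None  # default: CA of the junction residue
    theta_deg: float = 12.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta_deg < 180.0:
            raise ValueError("theta_deg must lie in [0, 180)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if min(self.n_res_domain_a, self.n_res_domain_b) < 3:
            raise ValueError("each domain needs at least 3 residues")


def make_two_domain_pair(
    spec: ToyStructureSpec,
) -> tuple[StructureModel, StructureModel, dict]:
    """Open/closed conformer pair with exact hinge ground truth.

    Domain A spans residues 1..n_a, domain B spans n_a+1..n_a+n_b of one
    continuous helical chain. The closed copy applies the hinge rotation to
    every atom of domain B; independent Gaussian noise (sigma per
    coordinate) is then added to each copy. The truth record stores the
    rotation, the noise-free per-residue CA displacements and each B-residue
    CA's perpendicular distance from the hinge axis.
    """
    n_a, n_b = spec.n_res_domain_a, spec.n_res_domain_b
    open_model = build_helix(n_a + n_b)
    open_model.id = f"toy_open_t{spec.theta_deg:g}_s{spec.noise_sigma:g}_{spec.seed}"

    axis = np.asarray(spec.hinge_axis, float)
    axis = axis / np.linalg.norm(axis)
    if spec.hinge_point is None:
        point = open_model.chain("A")[n_a - 1].ca.coords.copy()
    else:
        point = np.asarray(spec.hinge_point, float)
    R, t = _rotation_about(axis, point, spec.theta_deg)

    closed_model = open_model.copy()
    closed_model.id = open_model.id.replace("open", "closed")
    for res in closed_model.chain("A")[n_a:]:
        for atom in res.heavy_atoms():
            atom.coords = R @ atom.coords + t

    displacements = {}
    radii = {}
    for res_o, res_c in zip(open_model.chain("A"), closed_model.chain("A")):
        num = res_o.key.seq_num
        displacements[num] = float(np.linalg.norm(res_c.ca.coords - res_o.ca.coords))
        rel = res_o.ca.coords - point
        radii[num] = float(np.linalg.norm(rel - (rel @ axis) * axis))
    truth = {
        "theta_deg": spec.theta_deg,
        "axis": axis.tolist(),
        "point": point.tolist(),
        "domain_a": (1, n_a),
        "domain_b": (n_a + 1, n_a + n_b),
        "displacements": displacements,
        "axis_radii": radii,
        "noise_sigma": spec.noise_sigma,
        "seed": spec.seed,
    }

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        for model in (open_model, closed_model):
            for res in model.chain("A"):
                for atom in res.heavy_atoms():
                    atom.coords = atom.coords + rng.normal(0.0, spec.noise_sigma, 3)
    return open_model, closed_model, truth


@dataclass
class CavitySolidSpec:
    """Spherical-shell pseudo-structure enclosing a cavity of known volume."""

    shell_radius: float = 7.7
    atom_spacing: float = 1.0
    atom_vdw: float = 1.7
    aperture_deg: float | None = None  # full cone apex angle of the opening about +z
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shell_radius <= self.atom_vdw:
            raise ValueError("shell_radius must exceed atom_vdw")
        if self.atom_spacing <= 0:
            raise ValueError("atom_spacing must be positive")


def _fibonacci_unit(n: int) -> np.ndarray:
    i = np.arange(n)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(1.0 - z * z)
    return np.column_stack([r * np.cos(golden * i), r * np.sin(golden * i), z])


def analytic_cavity_volume(spec: CavitySolidSpec, probe_radius: float = 3.0) -> float:
    """Closed-form enclosed-cavity volume: (4/3) pi (R - r_vdw)^3.

    Reported as 0 when the aperture hole admits a probe of the given radius
    (the cavity is then open to solvent and no enclosed volume exists).
    """
    if spec.aperture_deg:
        half = min(spec.aperture_deg / 2.0, 90.0)
        hole_radius = spec.shell_radius * math.sin(math.radians(half))
        if spec.aperture_deg >= 180.0 or hole_radius - spec.atom_vdw >= probe_radius:
            return 0.0
    cavity_radius = spec.shell_radius - spec.atom_vdw
    return 4.0 / 3.0 * math.pi * cavity_radius**3


def make_cavity_solid(spec: CavitySolidSpec) -> tuple[StructureModel, float]:
    """Shell of carbon pseudo-atoms on a Fibonacci lattice + analytic volume.

    The lattice density is chosen so nearest-neighbour spacing does not
    exceed ``atom_spacing``; a leak check warns when the spacing cannot make
    the shell watertight (spacing >= 2 * atom_vdw).
    """
    import warnings

    if spec.atom_spacing >= 2.0 * spec.atom_vdw:
        warnings.warn(
            "atom_spacing >= 2*atom_vdw: shell is not watertight and the "
            "enclosed cavity may leak to solvent",
            stacklevel=2,
        )
    n = max(8, math.ceil(4.0 * math.pi * spec.shell_radius**2 / (0.6 * spec.atom_spacing**2)))
    points = spec.shell_radius * _fibonacci_unit(n)
    if spec.aperture_deg:
        cos_cut = math.cos(math.radians(spec.aperture_deg / 2.0))
        points = points[points[:, 2] / spec.shell_radius < cos_cut]
    residues = []
    for i, xyz in enumerate(points, start=1):
        key = ResidueKey("A", i, "", "UNK")
        residues.append(Residue(key, {"C1": AtomRecord("C1", "C", xyz)}))
    # UNK is not a polymer name, but the cavity detector takes atoms as given;
    # register the shell as a single-chain model of UNK "residues"
    model = StructureModel(
        id=f"shell_r{spec.shell_radius:g}", chains={"A": residues}, source_format="pdb"
    )
    return model, analytic_cavity_volume(spec)


# ---------------------------------------------------------------------------
# motif families

# Fixed 340-residue scaffold (the mapping reference for planted families).
# Deterministic arbitrary protein-like sequence; the planted positions
# (140/153/157/250/253/297/301) are set per class by the generator.
_scaffold_rng = np.random.default_rng(20230817)
SCAFFOLD_SEQUENCE = "".join(
    AMINO_ACIDS[i] for i in _scaffold_rng.integers(0, len(AMINO_ACIDS), 340)
)
del _scaffold_rng

#: residues planted at (153, 157, 297, 301) to realise exactly one tier
_TIER_PLANTS = {
    "yellow": ("F", "M", "M", "M"),
    "orange": ("F", "M", "Y", "M"),   # 297 in [FYML] but not M
    "maroon": ("L", "M", "L", "F"),   # slot1 relaxed, 301 not M
    "purple": ("L", "M", "A", "F"),   # 297 outside [FYML]
    "none": ("A", "A", "A", "A"),
}
_MOTIF_POSITIONS = (153, 157, 297, 301)
_PLANTED_POSITIONS = (140, 153, 157, 250, 253, 297, 301)


def random_scaffold(seed: int, length: int = 340) -> str:
    """An unrelated protein-like sequence (scaffolds, decoys, SSN tests).

    To serve as a family scaffold the length must span the planted
    positions; :func:`make_motif_family` enforces that.
    """
    rng = np.random.default_rng(seed)
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, len(AMINO_ACIDS), length))


def make_motif_family(
    n: int,
    tier_fractions: dict[str, float] | None = None,
    catalytic_fractions: dict[str, float] | None = None,
    mutation_rate: float = 0.05,
    seed: int = 0,
    scaffold: str | None = None,
    id_prefix: str | None = None,
) -> tuple[list[SequenceRecord], list[dict]]:
    """Sequence family with planted motif tiers and catalytic classes.

    ``tier_fractions`` are cumulative and must respect nesting
    (yellow <= orange <= maroon <= purple <= 1): a fraction f_yellow of the
    family matches the yellow patterns, f_orange - f_yellow are exactly
    orange, and so on; the remainder matches no tier.
    ``catalytic_fractions`` gives independent fractions for ``his_253`` and
    ``tyr_140``. Point mutations at ``mutation_rate`` per site are applied
    everywhere except the planted positions, which are overwritten last.
    ``scaffold`` replaces the default 340-residue scaffold (use
    :func:`random_scaffold` to build unrelated families for SSN tests).
    """
    tier_fractions = dict(tier_fractions or {"yellow": 0.1, "orange": 0.3, "maroon": 0.5, "purple": 0.7})
    catalytic_fractions = dict(catalytic_fractions or {"his_253": 0.5, "tyr_140": 0.3})
    cum = [tier_fractions.get(t, 0.0) for t in TIER_ORDER]
    if any(not 0.0 <= f <= 1.0 for f in cum) or any(a > b for a, b in zip(cum, cum[1:])):
        raise ValueError(
            "tier fractions must lie in [0,1] and be nested: yellow <= orange <= maroon <= purple"
        )
    if not 0.0 <= mutation_rate <= 1.0:
        raise ValueError("mutation_rate must lie in [0, 1]")

    counts = [round(f * n) for f in cum]
    tier_of: list[str] = []
    for i in range(n):
        for tier, cutoff in zip(TIER_ORDER, counts):
            if i < cutoff:
                tier_of.append(tier)
                break
        else:
            tier_of.append("none")

    n_his = round(catalytic_fractions.get("his_253", 0.0) * n)
    n_tyr = round(catalytic_fractions.get("tyr_140", 0.0) * n)

    base = SCAFFOLD_SEQUENCE if scaffold is None else scaffold.upper()
    if len(base) < max(_PLANTED_POSITIONS):
        raise ValueError("scaffold too short for the planted positions")
    prefix = id_prefix if id_prefix is not None else f"fam{seed}"
    rng = np.random.default_rng(seed)
    records, truth = [], []
    for i in range(n):
        seq = list(base)
        if mutation_rate > 0:
            for j in range(len(seq)):
                if (j + 1) not in _PLANTED_POSITIONS and rng.random() < mutation_rate:
                    choices = AMINO_ACIDS.replace(seq[j], "")
                    seq[j] = choices[rng.integers(0, len(choices))]
        tier = tier_of[i]
        for pos, residue in zip(_MOTIF_POSITIONS, _TIER_PLANTS[tier]):
            seq[pos - 1] = residue
        has_his = i < n_his
        has_tyr = i < n_tyr
        seq[253 - 1] = "H" if has_his else "S"
        seq[140 - 1] = "Y" if has_tyr else "F"
        seq[250 - 1] = "H"  # conserved cofactor-binding histidine
        rec = SequenceRecord(f"{prefix}_{i:04d}", "".join(seq))
        records.append(rec)
        truth.append(
            {
                "id": rec.id,
                "tier": tier,
                "his_253_equivalent": has_his,
                "tyr_140_equivalent": has_tyr,
            }
        )
    return records, truth


def truth_table_tsv(truth: list[dict]) -> str:
    lines = ["id\ttier\this_253\ttyr_140"]
    for rec in truth:
        lines.append(
            f"{rec['id']}\t{rec['tier']}\t{rec['his_253_equivalent']}\t{rec['tyr_140_equivalent']}"
        )
    return "\n".join(lines) + "\n"
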