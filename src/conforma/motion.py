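"""Inter-domain motion analysis.

The workflow mirrors how open/closed conformer pairs are compared in the
structural literature: superpose the two models on an *anchor* domain (the
rigid part, e.g. a dimerization domain), then characterise what the other
domain does in that frame —

* ``domain_rotation`` fits the moving domain and decomposes the residual
  rigid transform into a rotation angle, a screw axis (Chasles
  decomposition), an anchor point on the axis and a translation along it;
* ``displacement_field`` records per-residue C-alpha displacement vectors
  (for a pure hinge of angle theta, a residue at perpendicular distance r
  from the axis moves by the chord 2 r sin(theta/2));
* ``backbone_dihedrals`` / ``kink_delta`` quantify backbone phi/psi changes
  at hinge or kink residues, with circular wrapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from .model import (
    ATOMIC_MASS,
    DomainDefinition,
    Residue,
    ResidueKey,
    SelectionError,
    StructureModel,
    select_calpha,
)
from .superpose import SuperpositionResult, align_reject, kabsch_fit

__all__ = [
    "RigidMotion",
    "DisplacementField",
    "DihedralSeries",
    "domain_anchored_fit",
    "domain_rotation",
    "displacement_field",
    "difference_field",
    "center_of_mass",
    "backbone_dihedrals",
    "kink_delta",
    "dihedral_angle",
]

#: CA-CA distance (angstrom) above which consecutive residues are treated
#: as a chain break even when numbering is contiguous
CHAIN_BREAK_CA_CA = 4.5


@dataclass
class RigidMotion:
    """Screw (Chasles) decomposition of a rigid transform."""

    angle_deg: float
    axis: np.ndarray | None  # unit vector; None when angle ~ 0
    anchor: np.ndarray | None  # point on the axis, angstrom
    screw_shift: float  # translation along the axis, angstrom
    note: str = ""

    @property
    def axis_defined(self) -> bool:
        return self.axis is not None

    def apply(self, coords: np.ndarray) -> np.ndarray:
        """Apply the recomposed transform to an (n, 3) coordinate array."""
        if self.axis is None:
            return np.asarray(coords, float).copy()
        R = _axis_angle_matrix(self.axis, np.deg2rad(self.angle_deg))
        p = self.anchor
        return (coords - p) @ R.T + p + self.screw_shift * self.axis

    def to_dict(self) -> dict:
        return {
            "angle_deg": self.angle_deg,
            "axis": None if self.axis is None else self.axis.tolist(),
            "anchor": None if self.anchor is None else self.anchor.tolist(),
            "screw_shift": self.screw_shift,
            "note": self.note,
        }


@dataclass
class DisplacementField:
    """Per-residue C-alpha displacement vectors with summary statistics."""

    entries: list[tuple[ResidueKey, np.ndarray, float]]  # (key, vector, magnitude)

    @property
    def magnitudes(self) -> np.ndarray:
        return np.array([m for _, _, m in self.entries])

    @property
    def stats(self) -> dict:
        mags = self.magnitudes
        i = int(np.argmax(mags))
        return {
            "mean": float(mags.mean()),
            "rmsd": float(np.sqrt(np.mean(mags**2))),
            "max": float(mags.max()),
            "argmax": self.entries[i][0],
            "n": len(self.entries),
        }

    def to_tsv(self) -> str:
        lines = ["chain\tseq_num\tres_name\tdx\tdy\tdz\tmagnitude"]
        for key, vec, mag in self.entries:
            lines.append(
                f"{key.chain_id}\t{key.seq_num}\t{key.res_name}\t"
                f"{vec[0]:.4f}\t{vec[1]:.4f}\t{vec[2]:.4f}\t{mag:.4f}"
            )
        return "\n".join(lines) + "\n"


@dataclass
class DihedralSeries:
    """Backbone phi/psi per residue; None where undefined (termini, breaks)."""

    chain_id: str
    values: dict[int, tuple[float | None, float | None]] = field(default_factory=dict)

    def phi(self, seq_num: int) -> float | None:
        return self.values.get(seq_num, (None, None))[0]

    def psi(self, seq_num: int) -> float | None:
        return self.values.get(seq_num, (None, None))[1]

    def to_tsv(self) -> str:
        lines = ["seq_num\tphi\tpsi"]
        for num in sorted(self.values):
            phi, psi = self.values[num]
            fmt = lambda v: "NA" if v is None else f"{v:.2f}"
            lines.append(f"{num}\t{fmt(phi)}\t{fmt(psi)}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# rigid-motion decomposition


def _axis_angle_matrix(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation matrix for a unit axis."""
    u = np.asarray(axis, float)
    u = u / np.linalg.norm(u)
    K = np.array([[0, -u[2], u[1]], [u[2], 0, -u[0]], [-u[1], u[0], 0]])
    return np.eye(3) + np.sin(angle_rad) * K + (1 - np.cos(angle_rad)) * (K @ K)


def decompose_transform(rotation: np.ndarray, translation: np.ndarray) -> RigidMotion:
    """Screw decomposition of ``x -> R x + t``.

    Angle from the trace; axis from the antisymmetric part (eigenvector of R
    for eigenvalue 1, signed right-handed); the translation splits into a
    component along the axis (screw shift) and an in-plane part absorbed by
    placing the axis through an anchor point solving (I - R) p = t_perp.
    """
    R = np.asarray(rotation, float)
    t = np.asarray(translation, float)
    cos_theta = np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)
    angle = float(np.degrees(np.arccos(cos_theta)))
    if angle < 0.1:
        return RigidMotion(
            angle_deg=angle,
            axis=None,
            anchor=None,
            screw_shift=float(np.linalg.norm(t)),
            note="undefined (near identity)",
        )
    # right-handed axis from the antisymmetric part; fall back to the
    # eigen-decomposition near 180 degrees where R - R.T vanishes
    w = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
    if np.linalg.norm(w) > 1e-8:
        axis = w / np.linalg.norm(w)
    else:
        evals, evecs = np.linalg.eig(R)
        axis = np.real(evecs[:, np.argmin(np.abs(evals - 1.0))])
        axis = axis / np.linalg.norm(axis)
    screw_shift = float(t @ axis)
    t_perp = t - screw_shift * axis
    # (I - R) is singular along the axis; least squares picks the anchor in
    # the plane through the origin perpendicular to the axis
    anchor, *_ = np.linalg.lstsq(np.eye(3) - R, t_perp, rcond=None)
    return RigidMotion(angle_deg=angle, axis=axis, anchor=anchor, screw_shift=screw_shift)


# ---------------------------------------------------------------------------
# domain-anchored comparison


def _matched_domain_calpha(
    ref_model: StructureModel,
    mob_model: StructureModel,
    domain: DomainDefinition,
) -> tuple[list[ResidueKey], np.ndarray, np.ndarray]:
    """Cα pairs (matched by chain + author number) within a domain."""
    ref_sel = select_calpha(ref_model, domain)
    mob_sel = select_calpha(mob_model, domain)
    mob_by_key = {(k.chain_id, k.seq_num, k.icode): c for k, c in mob_sel.entries}
    keys, ref_xyz, mob_xyz = [], [], []
    for key, coords in ref_sel.entries:
        mob_c = mob_by_key.get((key.chain_id, key.seq_num, key.icode))
        if mob_c is not None:
            keys.append(key)
            ref_xyz.append(coords)
            mob_xyz.append(mob_c)
    if len(keys) < 3:
        raise SelectionError(
            f"domain {domain.name!r}: fewer than 3 common C-alpha pairs"
        )
    return keys, np.array(ref_xyz), np.array(mob_xyz)


def domain_anchored_fit(
    ref_model: StructureModel,
    mob_model: StructureModel,
    anchor_domain: DomainDefinition,
    max_cycles: int = 5,
    reject_factor: float = 2.0,
) -> tuple[StructureModel, SuperpositionResult]:
    """Superpose the mobile model onto the reference by the anchor domain.

    Returns the rigidly transformed mobile model and the fit; every
    downstream rotation/displacement measure is taken in this frame.
    """
    _keys, ref_xyz, mob_xyz = _matched_domain_calpha(ref_model, mob_model, anchor_domain)
    fit = align_reject(ref_xyz, mob_xyz, max_cycles=max_cycles, reject_factor=reject_factor)
    return mob_model.transform(fit.rotation, fit.translation), fit


def domain_rotation(
    ref_model: StructureModel,
    mob_model_in_anchor_frame: StructureModel,
    moving_domain: DomainDefinition,
) -> RigidMotion:
    """Rotation/screw decomposition of the moving domain's residual transform.

    Expects the mobile model already superposed on the anchor domain.
    """
    _keys, ref_xyz, mob_xyz = _matched_domain_calpha(
        ref_model, mob_model_in_anchor_frame, moving_domain
    )
    fit = kabsch_fit(ref_xyz, mob_xyz)
    # fit maps ref <- mob; the domain motion ref -> mob is the inverse
    R = fit.rotation.T
    t = -R @ fit.translation
    return decompose_transform(R, t)


def displacement_field(
    ref_model: StructureModel,
    mob_model_in_anchor_frame: StructureModel,
    region: DomainDefinition,
) -> DisplacementField:
    """Per-residue Cα displacement (mobile minus reference) within a region."""
    keys, ref_xyz, mob_xyz = _matched_domain_calpha(
        ref_model, mob_model_in_anchor_frame, region
    )
    vectors = mob_xyz - ref_xyz
    entries = [
        (key, vec, float(np.linalg.norm(vec))) for key, vec in zip(keys, vectors)
    ]
    return DisplacementField(entries)


def difference_field(field_1: DisplacementField, field_2: DisplacementField) -> DisplacementField:
    """Residue-wise vector difference of two displacement fields.

    Used to ask whether two conformational transitions are the *same* motion:
    if so, the difference magnitudes are small and noise-like. Computed over
    the intersection of the residue sets.
    """
    lookup = {(k.chain_id, k.seq_num, k.icode): v for k, v, _ in field_2.entries}
    entries = []
    for key, vec, _mag in field_1.entries:
        other = lookup.get((key.chain_id, key.seq_num, key.icode))
        if other is not None:
            diff = vec - other
            entries.append((key, diff, float(np.linalg.norm(diff))))
    if not entries:
        raise ValueError("difference_field: residue sets do not intersect")
    return DisplacementField(entries)


def center_of_mass(
    model: StructureModel,
    domain: DomainDefinition,
    weighting: Literal["geometric", "mass"] = "geometric",
) -> np.ndarray:
    """Geometric or mass-weighted centroid of all heavy atoms in a domain."""
    coords, weights = [], []
    for res in model.residues():
        if domain.contains(res.key):
            for atom in res.heavy_atoms():
                coords.append(atom.coords)
                weights.append(ATOMIC_MASS.get(atom.element, 12.011))
    if not coords:
        raise SelectionError(f"domain {domain.name!r} selects no atoms")
    coords = np.array(coords)
    if weighting == "mass":
        w = np.array(weights)
        return (coords * w[:, None]).sum(axis=0) / w.sum()
    return coords.mean(axis=0)


# ---------------------------------------------------------------------------
# backbone dihedrals


def dihedral_angle(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral of four points, degrees in (-180, 180]."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - (b0 @ b1n) * b1n
    w = b2 - (b2 @ b1n) * b1n
    angle = np.degrees(np.arctan2(np.cross(b1n, v) @ w, v @ w))
    # arctan2 returns [-180, 180]; fold -180 onto +180
    return float(angle if angle > -180.0 else 180.0)


def _contiguous_segments(residues: Sequence[Residue]) -> Iterable[list[Residue]]:
    """Split a chain at numbering gaps or CA-CA distances above the break cutoff."""
    segment: list[Residue] = []
    for res in residues:
        if segment:
            prev = segment[-1]
            gap = res.key.seq_num != prev.key.seq_num + 1
            broken = True
            if prev.ca is not None and res.ca is not None:
                broken = np.linalg.norm(res.ca.coords - prev.ca.coords) > CHAIN_BREAK_CA_CA
            if gap or broken:
                yield segment
                segment = []
        segment.append(res)
    if segment:
        yield segment


def backbone_dihedrals(model: StructureModel, chain_id: str) -> DihedralSeries:
    """Phi/psi series for a chain; undefined at termini and chain breaks."""
    residues = model.chain(chain_id)
    series = DihedralSeries(chain_id=chain_id)
    computed = 0
    for segment in _contiguous_segments(residues):
        for i, res in enumerate(segment):
            atoms = res.atoms
            phi = psi = None
            if i > 0 and all(n in atoms for n in ("N", "CA", "C")):
                prev = segment[i - 1]
                if "C" in prev.atoms:
                    phi = dihedral_angle(
                        prev.atoms["C"].coords,
                        atoms["N"].coords,
                        atoms["CA"].coords,
                        atoms["C"].coords,
                    )
            if i < len(segment) - 1 and all(n in atoms for n in ("N", "CA", "C")):
                nxt = segment[i + 1]
                if "N" in nxt.atoms:
                    psi = dihedral_angle(
                        atoms["N"].coords,
                        atoms["CA"].coords,
                        atoms["C"].coords,
                        nxt.atoms["N"].coords,
                    )
            series.values[res.key.seq_num] = (phi, psi)
            if phi is not None or psi is not None:
                computed += 1
    if computed == 0:
        raise ValueError(f"chain {chain_id}: no computable backbone dihedral")
    return series


def circular_delta(a: float, b: float) -> float:
    """Absolute angular difference on the circle, degrees in [0, 180]."""
    d = abs(a - b) % 360.0
    return d if d <= 180.0 else 360.0 - d


def kink_delta(
    series_open: DihedralSeries,
    series_closed: DihedralSeries,
    residues: Sequence[int],
) -> list[dict]:
    """Per-residue |delta phi| / |delta psi| between two conformers.

    Differences are taken on the circle (178 vs -178 degrees -> 4). Residues
    whose phi or psi is undefined in either series are flagged, not dropped.
    """
    out = []
    for num in residues:
        phi_o, psi_o = series_open.values.get(num, (None, None))
        phi_c, psi_c = series_closed.values.get(num, (None, None))
        rec: dict = {"seq_num": num, "flags": []}
        if phi_o is None or phi_c is None:
            rec["delta_phi"] = None
            rec["flags"].append("phi undefined")
        else:
            rec["delta_phi"] = circular_delta(phi_o, phi_c)
        if psi_o is None or psi_c is None:
            rec["delta_psi"] = None
            rec["flags"].append("psi undefined")
        else:
            rec["delta_psi"] = circular_delta(psi_o, psi_c)
        deltas = [d for d in (rec["delta_phi"], rec["delta_psi"]) if d is not None]
        rec["max_delta"] = max(deltas) if deltas else None
        out.append(rec)
    return out
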