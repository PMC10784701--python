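"""Solvent-accessible surface area, interface area and cavity volumes.

``sasa`` is a Shrake-Rupley implementation: each atom's van der Waals sphere
is inflated by the probe radius and sampled with a near-uniform point set;
the accessible area is the exposed fraction of the inflated sphere times its
full area. ``interface_area`` is the standard buried-surface half-difference
(SASA_A + SASA_B - SASA_AB) / 2.

``pocket_volumes`` is a grid-probe cavity detector in the POCASA style:
grid points inside atoms are protein, points reachable by a large spherical
probe rolling outside the protein are solvent, and what remains — space too
narrow for the probe but outside the atoms — forms pocket candidates, which
are grouped by 6-connectivity and trimmed by a minimum point count and a
minimum burial depth. Absolute volumes from grid methods depend on the
trimming semantics of the particular tool, so open/closed *ratios*
(``cavity_reduction``) are the robust statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .model import AtomRecord, Residue, ResidueKey, StructureModel

__all__ = [
    "VDW_RADII",
    "SasaResult",
    "InterfaceResult",
    "PocketResult",
    "sasa",
    "interface_area",
    "pocket_volumes",
    "cavity_reduction",
]

#: van der Waals radii by element (angstrom); unmatched elements fall back to C
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80, "SE": 1.90}
DEFAULT_VDW = 1.70


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n near-uniform unit vectors (golden-spiral lattice)."""
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(1.0 - z * z)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _gather_atoms(
    source: StructureModel | Sequence[tuple[ResidueKey, AtomRecord]],
    chains: Iterable[str] | None = None,
    include_ligands: bool = False,
) -> list[tuple[ResidueKey, AtomRecord]]:
    if isinstance(source, StructureModel):
        if chains is None:
            return source.all_atoms(include_ligands=include_ligands)
        out = []
        for cid in chains:
            out.extend((r.key, a) for r in source.chain(cid) for a in r.heavy_atoms())
        return out
    return list(source)


@dataclass
class SasaResult:
    per_atom: list[tuple[ResidueKey, str, float]]  # (residue, atom name, area)
    probe_radius: float
    n_sphere_points: int

    @property
    def total(self) -> float:
        return float(sum(a for _, _, a in self.per_atom))

    @property
    def per_residue(self) -> dict[ResidueKey, float]:
        out: dict[ResidueKey, float] = {}
        for key, _name, area in self.per_atom:
            out[key] = out.get(key, 0.0) + area
        return out

    def per_residue_tsv(self) -> str:
        lines = ["chain\tseq_num\tres_name\tsasa"]
        for key, area in self.per_residue.items():
            lines.append(f"{key.chain_id}\t{key.seq_num}\t{key.res_name}\t{area:.2f}")
        return "\n".join(lines) + "\n"


def sasa(
    source: StructureModel | Sequence[tuple[ResidueKey, AtomRecord]],
    probe_radius: float = 1.4,
    n_points: int = 960,
    chains: Iterable[str] | None = None,
    radii: dict[str, float] | None = None,
) -> SasaResult:
    """Shrake-Rupley solvent-accessible surface area.

    ``source`` is a model (optionally restricted to ``chains``) or an
    explicit (residue key, atom) list. Areas are per heavy atom in square
    angstrom; the probe-inflated sphere of each atom is sampled with
    ``n_points`` near-uniform points and a point is buried when it falls
    inside any neighbouring atom's inflated sphere.
    """
    atoms = _gather_atoms(source, chains)
    if not atoms:
        raise ValueError("sasa: no atoms in selection")
    table = dict(VDW_RADII)
    if radii:
        table.update({k.upper(): v for k, v in radii.items()})
    coords = np.array([a.coords for _, a in atoms])
    r_vdw = np.array([table.get(a.element, DEFAULT_VDW) for _, a in atoms])
    r_ext = r_vdw + probe_radius
    sphere = _fibonacci_sphere(n_points)

    tree = cKDTree(coords)
    max_reach = 2.0 * r_ext.max()
    per_atom: list[tuple[ResidueKey, str, float]] = []
    for i, (key, atom) in enumerate(atoms):
        points = coords[i] + r_ext[i] * sphere
        exposed = np.ones(n_points, dtype=bool)
        for j in tree.query_ball_point(coords[i], max_reach):
            if j == i:
                continue
            d2 = np.sum((points - coords[j]) ** 2, axis=1)
            exposed &= d2 > r_ext[j] ** 2
        area = 4.0 * np.pi * r_ext[i] ** 2 * exposed.mean()
        per_atom.append((key, atom.name, float(area)))
    return SasaResult(per_atom=per_atom, probe_radius=probe_radius, n_sphere_points=n_points)


@dataclass
class InterfaceResult:
    area: float  # buried interface, square angstrom
    sasa_a: float
    sasa_b: float
    sasa_ab: float


def interface_area(
    model: StructureModel,
    group_a: Iterable[str],
    group_b: Iterable[str],
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> InterfaceResult:
    """Buried interface between two chain groups: (SASA_A + SASA_B - SASA_AB)/2."""
    group_a, group_b = set(group_a), set(group_b)
    if not group_a or not group_b:
        raise ValueError("interface_area: both chain groups must be non-empty")
    if group_a & group_b:
        raise ValueError(f"interface_area: groups overlap on {sorted(group_a & group_b)}")
    sasa_a = sasa(model, probe_radius, n_points, chains=sorted(group_a)).total
    sasa_b = sasa(model, probe_radius, n_points, chains=sorted(group_b)).total
    sasa_ab = sasa(model, probe_radius, n_points, chains=sorted(group_a | group_b)).total
    area = max(0.0, (sasa_a + sasa_b - sasa_ab) / 2.0)
    return InterfaceResult(area=area, sasa_a=sasa_a, sasa_b=sasa_b, sasa_ab=sasa_ab)


# ---------------------------------------------------------------------------
# grid-probe cavity detection


@dataclass
class Pocket:
    point_count: int
    volume: float  # cubic angstrom
    centroid: np.ndarray
    max_depth: int  # burial depth in grid steps
    points: np.ndarray | None = None  # (n, 3) grid-point coordinates


@dataclass
class PocketResult:
    grid_spacing: float
    probe_radius: float
    pockets: list[Pocket]  # sorted by volume, descending
    trim_params: tuple[int, int] = (11, 10)

    @property
    def total_volume(self) -> float:
        return float(sum(p.volume for p in self.pockets))

    def pocket_containing(self, point: np.ndarray, max_dist: float = 3.0) -> Pocket | None:
        """The pocket whose grid points come nearest ``point`` (within max_dist)."""
        best, best_d = None, max_dist
        for pocket in self.pockets:
            if pocket.points is None or len(pocket.points) == 0:
                continue
            d = np.min(np.linalg.norm(pocket.points - point, axis=1))
            if d < best_d:
                best, best_d = pocket, d
        return best

    def points_as_pdb(self) -> str:
        """Pocket grid points as pseudo-atom HETATM records for visualization."""
        lines = []
        serial = 0
        for rank, pocket in enumerate(self.pockets, start=1):
            for xyz in pocket.points if pocket.points is not None else []:
                serial += 1
                lines.append(
                    f"HETATM{serial:>5}  O   PKT A{rank:>4}    "
                    f"{xyz[0]:>8.3f}{xyz[1]:>8.3f}{xyz[2]:>8.3f}  1.00  0.00           O"
                )
        lines.append("END")
        return "\n".join(lines) + "\n"


def _rasterize_spheres(
    shape: tuple[int, int, int],
    origin: np.ndarray,
    spacing: float,
    centers: np.ndarray,
    radii: np.ndarray,
) -> np.ndarray:
    """Boolean grid marking points within any sphere (center_i, radius_i)."""
    mask = np.zeros(shape, dtype=bool)
    for center, radius in zip(centers, radii):
        lo = np.maximum(np.floor((center - radius - origin) / spacing).astype(int), 0)
        hi = np.minimum(
            np.ceil((center + radius - origin) / spacing).astype(int) + 1, shape
        )
        if np.any(lo >= hi):
            continue
        axes = [origin[k] + spacing * np.arange(lo[k], hi[k]) for k in range(3)]
        dx, dy, dz = np.meshgrid(*(ax - c for ax, c in zip(axes, center)), indexing="ij")
        sub = dx * dx + dy * dy + dz * dz <= radius * radius
        mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] |= sub
    return mask


def pocket_volumes(
    source: StructureModel | Sequence[tuple[ResidueKey, AtomRecord]],
    grid_spacing: float = 0.5,
    probe_radius: float = 3.0,
    single_point_threshold: int = 11,
    depth_threshold: int = 10,
    radii: dict[str, float] | None = None,
    keep_points: bool = True,
    max_grid_points: int = 80_000_000,
) -> PocketResult:
    """Grid-probe pocket/cavity detection.

    Ligands and waters are excluded when ``source`` is a model, so cavity
    volumes of liganded and unliganded conformers are comparable. Pockets
    smaller than ``single_point_threshold`` grid points, or with maximum
    burial depth (grid steps to the nearest solvent point) below
    ``depth_threshold``, are discarded.
    """
    atoms = _gather_atoms(source, None, include_ligands=False)
    if not atoms:
        raise ValueError("pocket_volumes: no atoms")
    if grid_spacing <= 0 or probe_radius <= grid_spacing:
        raise ValueError("pocket_volumes: need grid_spacing > 0 and probe > grid")
    table = dict(VDW_RADII)
    if radii:
        table.update({k.upper(): v for k, v in radii.items()})
    coords = np.array([a.coords for _, a in atoms])
    r_vdw = np.array([table.get(a.element, DEFAULT_VDW) for _, a in atoms])

    pad = probe_radius + r_vdw.max() + 2 * grid_spacing
    origin = coords.min(axis=0) - pad
    upper = coords.max(axis=0) + pad
    shape = tuple(np.ceil((upper - origin) / grid_spacing).astype(int) + 1)
    if int(np.prod(shape)) > max_grid_points:
        raise MemoryError(
            f"grid of {np.prod(shape):,} points exceeds the ceiling; "
            "use a coarser grid_spacing or raise max_grid_points"
        )

    protein = _rasterize_spheres(shape, origin, grid_spacing, coords, r_vdw)
    # probe centers are excluded from the protein inflated by the probe radius
    inflated = _rasterize_spheres(shape, origin, grid_spacing, coords, r_vdw + probe_radius)
    probe_centers = ~inflated
    # the probe rolls in from bulk: keep only center positions connected to
    # the box boundary, so a probe-sized void sealed inside the protein is a
    # cavity, not solvent
    center_labels, _n = ndimage.label(probe_centers)
    boundary_labels = np.unique(
        np.concatenate(
            [
                center_labels[0].ravel(), center_labels[-1].ravel(),
                center_labels[:, 0].ravel(), center_labels[:, -1].ravel(),
                center_labels[:, :, 0].ravel(), center_labels[:, :, -1].ravel(),
            ]
        )
    )
    boundary_labels = boundary_labels[boundary_labels > 0]
    probe_centers &= np.isin(center_labels, boundary_labels)
    # solvent: any empty point within one probe radius of a reachable center
    dist_to_center = ndimage.distance_transform_edt(
        ~probe_centers, sampling=grid_spacing
    )
    solvent = ~protein & (dist_to_center <= probe_radius)
    candidates = ~protein & ~solvent

    labels, n_groups = ndimage.label(candidates)  # default structure = 6-connectivity
    # burial depth in grid steps: taxicab distance to the nearest solvent point
    depth = ndimage.distance_transform_cdt(~solvent, metric="taxicab")

    pockets: list[Pocket] = []
    if n_groups:
        sizes = ndimage.sum_labels(candidates, labels, index=np.arange(1, n_groups + 1))
        max_depths = ndimage.maximum(depth, labels, index=np.arange(1, n_groups + 1))
        for gid, (size, gdepth) in enumerate(zip(sizes, max_depths), start=1):
            size = int(size)
            if size < single_point_threshold or int(gdepth) < depth_threshold:
                continue
            idx = np.argwhere(labels == gid)
            pts = origin + idx * grid_spacing
            pockets.append(
                Pocket(
                    point_count=size,
                    volume=size * grid_spacing**3,
                    centroid=pts.mean(axis=0),
                    max_depth=int(gdepth),
                    points=pts if keep_points else None,
                )
            )
    pockets.sort(key=lambda p: -p.volume)
    return PocketResult(
        grid_spacing=grid_spacing,
        probe_radius=probe_radius,
        pockets=pockets,
        trim_params=(single_point_threshold, depth_threshold),
    )


def cavity_reduction(
    open_result: PocketResult,
    closed_result: PocketResult,
    selector: str | np.ndarray = "largest",
) -> float:
    """Percent volume reduction of a cavity between open and closed states.

    ``selector`` is ``"largest"`` or a 3-point (angstrom) — e.g. a cofactor
    atom position — choosing the pocket nearest that point in each state.
    Returns 100 * (V_open - V_closed) / V_open.
    """

    def pick(result: PocketResult) -> float:
        if isinstance(selector, str):
            if selector != "largest":
                raise ValueError(f"unknown selector {selector!r}")
            return result.pockets[0].volume if result.pockets else 0.0
        pocket = result.pocket_containing(np.asarray(selector, float))
        return pocket.volume if pocket is not None else 0.0

    v_open = pick(open_result)
    v_closed = pick(closed_result)
    if v_open <= 0:
        raise ValueError("cavity_reduction: open-state cavity volume is zero")
    return 100.0 * (v_open - v_closed) / v_open
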