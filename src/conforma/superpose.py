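"""Least-squares rigid superposition of matched C-alpha sets.

``kabsch_fit`` is the closed-form SVD solution of the orthogonal Procrustes
problem with the determinant correction that forbids reflections.
``align_reject`` is the iterative variant used by common structure-comparison
tools: refit after discarding pairs whose residual exceeds a multiple of the
current RMSD, so that a flexible minority (e.g. a rotated domain) does not
dominate the fit — this is what produces "N kept of M" C-alpha counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .model import Residue, ResidueKey, three_to_one

__all__ = [
    "ChainPairing",
    "SuperpositionResult",
    "pair_residues",
    "kabsch_fit",
    "align_reject",
    "apply_transform",
]


@dataclass
class ChainPairing:
    """Ordered residue correspondence between a reference and a mobile chain."""

    pairs: list[tuple[ResidueKey, ResidueKey]]
    method: Literal["by_number", "by_alignment"]

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class SuperpositionResult:
    rotation: np.ndarray  # 3x3, det = +1
    translation: np.ndarray  # 3-vector; mobile' = R @ mobile + t
    rmsd: float  # over kept pairs, angstrom
    n_kept: int
    kept_mask: np.ndarray  # bool per input pair
    cycles_run: int = 1

    def as_homogeneous(self) -> np.ndarray:
        H = np.eye(4)
        H[:3, :3] = self.rotation
        H[:3, 3] = self.translation
        return H

    def to_json(self) -> str:
        return json.dumps(
            {
                "matrix": self.as_homogeneous().tolist(),
                "rmsd": self.rmsd,
                "n_kept": self.n_kept,
                "cycles_run": self.cycles_run,
            },
            indent=2,
        )


def apply_transform(coords: np.ndarray, result: SuperpositionResult) -> np.ndarray:
    return coords @ result.rotation.T + result.translation


def _global_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def pair_residues(
    ref_chain: Sequence[Residue],
    mob_chain: Sequence[Residue],
    mode: Literal["by_number", "by_alignment"] = "by_number",
) -> ChainPairing:
    """Match residues between two chains; only pairs where both CAs exist.

    ``by_number`` pairs identical (seq_num, icode); ``by_alignment`` pairs
    aligned columns of a BLOSUM62 global alignment of the one-letter
    sequences (robust to insertions/deletions and renumbering).
    """
    if not ref_chain or not mob_chain:
        raise ValueError("pair_residues: both chains must be non-empty")

    pairs: list[tuple[ResidueKey, ResidueKey]] = []
    if mode == "by_number":
        mob_index = {(r.key.seq_num, r.key.icode): r for r in mob_chain}
        for ref in ref_chain:
            mob = mob_index.get((ref.key.seq_num, ref.key.icode))
            if mob is not None and ref.ca is not None and mob.ca is not None:
                pairs.append((ref.key, mob.key))
    elif mode == "by_alignment":
        ref_seq = "".join(three_to_one(r.key.res_name) for r in ref_chain)
        mob_seq = "".join(three_to_one(r.key.res_name) for r in mob_chain)
        alignment = _global_aligner().align(ref_seq, mob_seq)[0]
        for (r0, r1), (m0, _m1) in zip(*alignment.aligned):
            for offset in range(r1 - r0):
                ref = ref_chain[r0 + offset]
                mob = mob_chain[m0 + offset]
                if ref.ca is not None and mob.ca is not None:
                    pairs.append((ref.key, mob.key))
    else:
        raise ValueError(f"unknown pairing mode {mode!r}")

    if not pairs:
        raise ValueError("pair_residues: zero residue pairs")
    return ChainPairing(pairs=pairs, method=mode)


def _check_coords(ref: np.ndarray, mob: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.asarray(ref, dtype=float).reshape(-1, 3)
    mob = np.asarray(mob, dtype=float).reshape(-1, 3)
    if ref.shape != mob.shape:
        raise ValueError(f"coordinate sets differ in length: {ref.shape} vs {mob.shape}")
    if len(ref) < 3:
        raise ValueError("need at least 3 point pairs for a rigid fit")
    # collinear (rank < 2) reference geometry leaves the rotation underdetermined
    sv = np.linalg.svd(ref - ref.mean(axis=0), compute_uv=False)
    if sv[1] < 1e-8:
        raise ValueError("degenerate geometry: points are collinear")
    return ref, mob


def kabsch_fit(ref_coords: np.ndarray, mob_coords: np.ndarray) -> SuperpositionResult:
    """Optimal rigid transform (rotation + translation, no reflection).

    Returns the transform such that ``R @ mob + t`` minimises the RMSD to
    ``ref`` over all proper rigid motions.
    """
    ref, mob = _check_coords(ref_coords, mob_coords)
    ref_c = ref.mean(axis=0)
    mob_c = mob.mean(axis=0)
    H = (mob - mob_c).T @ (ref - ref_c)
    U, _S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ref_c - R @ mob_c
    residuals = ref - (mob @ R.T + t)
    rmsd = float(np.sqrt(np.mean(np.sum(residuals**2, axis=1))))
    n = len(ref)
    return SuperpositionResult(
        rotation=R,
        translation=t,
        rmsd=rmsd,
        n_kept=n,
        kept_mask=np.ones(n, dtype=bool),
        cycles_run=1,
    )


def align_reject(
    ref_coords: np.ndarray,
    mob_coords: np.ndarray,
    max_cycles: int = 5,
    reject_factor: float = 2.0,
) -> SuperpositionResult:
    """Iterative superposition with residual-based outlier rejection.

    Each cycle refits on the kept pairs and discards pairs whose residual
    distance exceeds ``reject_factor`` times the current RMSD. Stops when a
    cycle discards nothing or ``max_cycles`` is reached. The final RMSD is
    over kept pairs only; the mask records which pairs survived.
    """
    ref, mob = _check_coords(ref_coords, mob_coords)
    n = len(ref)
    kept = np.ones(n, dtype=bool)
    result = kabsch_fit(ref, mob)
    cycles = 1
    while cycles < max_cycles:
        residuals = np.linalg.norm(
            ref - (mob @ result.rotation.T + result.translation), axis=1
        )
        # floor keeps numerically perfect fits from rejecting on rounding dust
        cutoff = max(reject_factor * result.rmsd, 1e-3)
        new_kept = kept & (residuals <= cutoff)
        if new_kept.sum() < 3:
            raise ValueError("rejection collapsed: fewer than 3 pairs remain")
        if new_kept.sum() == kept.sum():
            break
        kept = new_kept
        result = kabsch_fit(ref[kept], mob[kept])
        cycles += 1
    return SuperpositionResult(
        rotation=result.rotation,
        translation=result.translation,
        rmsd=result.rmsd,
        n_kept=int(kept.sum()),
        kept_mask=kept,
        cycles_run=cycles,
    )
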