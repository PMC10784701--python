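"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: the superposition
oracle is the quaternion (Horn) eigenvalue method, not SVD; the alignment
oracle is a from-scratch Gotoh affine-gap dynamic program.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def quaternion_fit(ref: np.ndarray, mob: np.ndarray) -> tuple[float, np.ndarray]:
    """Optimal-superposition RMSD and rotation by Horn's quaternion method.

    Builds the 4x4 key matrix from the correlation of the centered clouds;
    the largest eigenvalue gives the minimal residual, its eigenvector the
    rotation quaternion.
    """
    ref = np.asarray(ref, float)
    mob = np.asarray(mob, float)
    n = len(ref)
    rc = ref - ref.mean(axis=0)
    mc = mob - mob.mean(axis=0)
    S = mc.T @ rc  # correlation matrix (mobile -> reference)
    Sxx, Sxy, Sxz = S[0]
    Syx, Syy, Syz = S[1]
    Szx, Szy, Szz = S[2]
    K = np.array(
        [
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ]
    )
    evals, evecs = np.linalg.eigh(K)
    lam = evals[-1]
    q = evecs[:, -1]  # (w, x, y, z)
    w, x, y, z = q
    R = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )
    e0 = float(np.sum(rc**2) + np.sum(mc**2))
    rmsd = float(np.sqrt(max(0.0, (e0 - 2.0 * lam) / n)))
    return rmsd, R


def gotoh_global(
    a: str,
    b: str,
    open_score: float = -10.0,
    extend_score: float = -0.5,
) -> tuple[float, dict[int, int | None]]:
    """Global affine-gap alignment: optimal score and a 1-based position map.

    Gap of length L costs open + (L-1)*extend, matching the convention of
    Biopython's PairwiseAligner. Returns the mapping from positions of ``a``
    to positions of ``b`` (None where ``a``'s residue aligns to a gap).
    """
    la, lb = len(a), len(b)
    NEG = -1e9
    M = np.full((la + 1, lb + 1), NEG)
    X = np.full((la + 1, lb + 1), NEG)  # gap in b (a consumed)
    Y = np.full((la + 1, lb + 1), NEG)  # gap in a (b consumed)
    M[0, 0] = 0.0
    for i in range(1, la + 1):
        X[i, 0] = open_score + (i - 1) * extend_score
    for j in range(1, lb + 1):
        Y[0, j] = open_score + (j - 1) * extend_score
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            s = _BLOSUM62[a[i - 1], b[j - 1]]
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + open_score, X[i - 1, j] + extend_score)
            Y[i, j] = max(M[i, j - 1] + open_score, Y[i, j - 1] + extend_score)
    score = max(M[la, lb], X[la, lb], Y[la, lb])

    # traceback (one optimal path; deterministic preference M > X > Y)
    mapping: dict[int, int | None] = {}
    i, j = la, lb
    state = max(("M", "X", "Y"), key=lambda st: {"M": M, "X": X, "Y": Y}[st][la, lb])
    while i > 0 or j > 0:
        if state == "M":
            mapping[i] = j
            prev = max(
                ("M", "X", "Y"),
                key=lambda st: {"M": M, "X": X, "Y": Y}[st][i - 1, j - 1],
            )
            i, j = i - 1, j - 1
            state = prev
        elif state == "X":
            mapping[i] = None
            if i > 1 and abs(X[i, j] - (X[i - 1, j] + extend_score)) < 1e-9:
                state = "X"
            else:
                state = "M"
            i -= 1
        else:  # Y
            if j > 1 and abs(Y[i, j] - (Y[i, j - 1] + extend_score)) < 1e-9:
                state = "Y"
            else:
                state = "M"
            j -= 1
        if i == 0 and j == 0:
            break
        if i == 0:
            state = "Y"
        elif j == 0:
            state = "X"
    return float(score), mapping


def random_point_cloud(rng: np.random.Generator, n: int, spread: float = 10.0) -> np.ndarray:
    return rng.uniform(-spread, spread, size=(n, 3))


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix via QR of a Gaussian matrix."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q
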