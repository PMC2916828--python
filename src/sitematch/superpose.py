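"""Optimal rigid-body superposition by the quaternion method.

Given two equal-length ordered point lists, find the proper rotation and
translation minimising the root-mean-square deviation of the second list
onto the first.  The optimum is obtained from the largest eigenvalue of the
4x4 quaternion key matrix built from the covariance of the centred point
sets; reflections are excluded by construction, which matters for chiral
arrangements of atoms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Superposition", "optimal_superposition", "rmsd_under_correspondence"]


@dataclass(frozen=True)
class Superposition:
    """A proper rigid transform ``x -> rotation @ x + translation`` plus its RMSD.

    ``rotation`` is a 3x3 proper orthogonal matrix (det = +1), ``translation``
    a 3-vector in Angstroms, and ``rmsd`` the root-mean-square deviation of the
    transformed second point list onto the first.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform an (n, 3) coordinate array."""
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation


def _quaternion_to_matrix(q: np.ndarray) -> np.ndarray:
    w, x, y, z = q
    return np.array(
        [
            [w * w + x * x - y * y - z * z, 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), w * w - x * x + y * y - z * z, 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), w * w - x * x - y * y + z * z],
        ]
    )


def optimal_superposition(points_a, points_b) -> Superposition:
    """Best proper rigid superposition of ``points_b`` onto ``points_a``.

    The correspondence is positional: ``points_b[i]`` is matched with
    ``points_a[i]``.  Returns the :class:`Superposition` whose rotation and
    translation minimise sqrt(sum_i |a_i - (R b_i + t)|^2 / n) over all proper
    rigid motions.  Degenerate inputs (single point, collinear or coincident
    sets, exactly symmetric sets with a tied top eigenvalue) return a finite
    RMSD and a valid proper rotation; only the RMSD is then uniquely defined.

    Raises ``ValueError`` on empty input or a length mismatch.
    """
    a = np.asarray(points_a, dtype=float).reshape(-1, 3)
    b = np.asarray(points_b, dtype=float).reshape(-1, 3)
    if a.shape != b.shape:
        raise ValueError(f"point lists differ in length: {len(a)} vs {len(b)}")
    n = len(a)
    if n == 0:
        raise ValueError("cannot superpose empty point lists")

    cen_a = a.mean(axis=0)
    cen_b = b.mean(axis=0)
    x = a - cen_a
    y = b - cen_b

    # M = sum_i y_i a_i^T drives the 4x4 key matrix; its top eigenvalue L gives
    # the minimal residual  E = G_a + G_b - 2 L  over proper rotations only.
    m = y.T @ x
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    key = np.array(
        [
            [sxx + syy + szz, szy - syz, sxz - szx, syx - sxy],
            [szy - syz, sxx - syy - szz, sxy + syx, szx + sxz],
            [sxz - szx, sxy + syx, -sxx + syy - szz, syz + szy],
            [syx - sxy, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    eigvals, eigvecs = np.linalg.eigh(key)
    lam = eigvals[-1]
    quat = eigvecs[:, -1]
    # the eigenvector quaternion describes the frame change b -> a; the
    # rotation applied to b's coordinates is its transpose
    rotation = _quaternion_to_matrix(quat / np.linalg.norm(quat)).T

    residual = float((x * x).sum() + (y * y).sum() - 2.0 * lam)
    rmsd = float(np.sqrt(max(residual, 0.0) / n))
    translation = cen_a - rotation @ cen_b
    return Superposition(rotation=rotation, translation=translation, rmsd=rmsd)


def rmsd_under_correspondence(units_a, units_b, correspondence) -> Superposition:
    """Superpose the pseudoatoms of paired match units.

    ``correspondence`` is a sequence of ``(index_a, index_b, recipe_pairs)``
    entries pairing ``units_a[index_a]`` with ``units_b[index_b]``;
    ``recipe_pairs`` lists ``(recipe_name_a, recipe_name_b)`` in pairing order.
    Recipe pairs for which either unit lacks the pseudoatom (missing atoms in
    the coordinates) are skipped.  Flattens the paired pseudoatom coordinates
    in pairing order and delegates to :func:`optimal_superposition`.
    """
    coords_a = []
    coords_b = []
    for ia, ib, recipe_pairs in correspondence:
        ua, ub = units_a[ia], units_b[ib]
        for ra, rb in recipe_pairs:
            pa = ua.get(ra)
            pb = ub.get(rb)
            if pa is None or pb is None:
                continue
            coords_a.append(pa.coords)
            coords_b.append(pb.coords)
    if not coords_a:
        raise ValueError("correspondence pairs no pseudoatoms")
    return optimal_superposition(np.array(coords_a), np.array(coords_b))
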