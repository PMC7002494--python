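"""Shared numerics: rigid-body superposition and numerical SASA.

The solvent-accessible surface area uses Shrake-Rupley sphere sampling with
a deterministic Fibonacci point distribution, so areas are reproducible to
the bit across runs and platforms.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

#: van der Waals radii (A) for the elements common in macromolecules.
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "SE": 1.90, "F": 1.47, "CL": 1.75, "BR": 1.85,
    "I": 1.98, "FE": 1.40, "ZN": 1.39, "MG": 1.73, "CA": 1.95,
    "MN": 1.40, "NA": 2.27, "K": 2.75, "CU": 1.40,
}
DEFAULT_VDW = 1.70


def vdw_radius(element: str) -> float:
    return VDW_RADII.get(element.upper(), DEFAULT_VDW)


def fibonacci_sphere(n: int) -> np.ndarray:
    """n deterministic, near-uniform unit vectors (golden-spiral lattice)."""
    i = np.arange(n, dtype=float)
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    theta = 2.0 * np.pi * i / phi
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def shrake_rupley_sasa(coords: np.ndarray,
                       radii: np.ndarray,
                       probe: float = 1.44,
                       n_points: int = 960) -> np.ndarray:
    """Per-atom solvent-accessible surface area.

    Each atom's solvent sphere (vdW radius + probe) is sampled with
    ``n_points`` Fibonacci points; a point is accessible if it lies outside
    every neighbouring atom's solvent sphere.  Area = accessible fraction
    times the sphere area.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    n = len(coords)
    if n == 0:
        return np.zeros(0)
    sphere = fibonacci_sphere(n_points)
    solv = radii + probe
    tree = cKDTree(coords)
    max_r = solv.max()
    areas = np.zeros(n)
    for i in range(n):
        pts = coords[i] + solv[i] * sphere
        nbrs = [j for j in tree.query_ball_point(coords[i],
                                                 solv[i] + max_r)
                if j != i]
        if nbrs:
            nb = np.asarray(nbrs)
            d2 = ((pts[:, None, :] - coords[nb][None, :, :]) ** 2).sum(-1)
            buried = (d2 <= (solv[nb] ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = frac * 4.0 * np.pi * solv[i] ** 2
    return areas


def kabsch(mobile: np.ndarray, target: np.ndarray,
           ) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``target``.

    Returns (rotation 3x3, translation 3, RMSD) such that
    ``mobile @ R.T + t`` best fits ``target``.  Proper rotations only
    (reflections are excluded by the determinant correction).
    """
    mobile = np.asarray(mobile, float)
    target = np.asarray(target, float)
    if mobile.shape != target.shape or mobile.ndim != 2:
        raise ValueError("point sets must have identical (n, 3) shapes")
    cm = mobile.mean(axis=0)
    ct = target.mean(axis=0)
    h = (mobile - cm).T @ (target - ct)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    tran = ct - rot @ cm
    moved = mobile @ rot.T + tran
    rmsd = float(np.sqrt(((moved - target) ** 2).sum(axis=1).mean()))
    return rot, tran, rmsd


def apply_rigid(coords: np.ndarray, rot: np.ndarray,
                tran: np.ndarray) -> np.ndarray:
    return np.asarray(coords, float) @ np.asarray(rot).T + tran


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    return float(np.sqrt(((a - b) ** 2).sum(axis=1).mean()))
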