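"""Generalized Procrustes analysis for 2D landmark configurations.

The geometric engine of the pipeline: configurations are translated to the
origin, scaled to unit centroid size, and rotated (reflections are never
introduced — mirrored copies enter the symmetry analysis as data, so an
alignment that could reflect would destroy the decomposition).  The consensus
is the arithmetic mean of the aligned configurations, iterated to a fixed
point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class DegenerateConfigurationError(ValueError):
    """All landmarks coincide; no shape is defined."""


def centroid_size(coords: np.ndarray) -> float:
    """Root summed squared distances of the landmarks to their centroid."""
    coords = np.asarray(coords, dtype=float)
    centered = coords - coords.mean(axis=0)
    return float(np.sqrt((centered**2).sum()))


def center_scale(coords: np.ndarray) -> tuple[np.ndarray, float]:
    """Translate centroid to the origin and scale to unit centroid size.

    Returns the normalized configuration and the original centroid size.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] < 3:
        raise ValueError("need k >= 3 landmarks")
    centered = coords - coords.mean(axis=0)
    size = float(np.sqrt((centered**2).sum()))
    if size < 1e-12:
        raise DegenerateConfigurationError("all landmarks coincide (centroid size 0)")
    return centered / size, size


def _rotation_angle(A: np.ndarray, B: np.ndarray) -> float:
    """Angle of the proper rotation minimizing ||R A - B||^2 (A, B centered)."""
    # 2D closed form: with H = A^T B, theta = atan2(H01 - H10, H00 + H11)
    H = A.T @ B
    return float(np.arctan2(H[0, 1] - H[1, 0], H[0, 0] + H[1, 1]))


def rotation_matrix(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


def optimal_rotation(
    A: np.ndarray, B: np.ndarray, allow_reflection: bool = False
) -> tuple[np.ndarray, float]:
    """Rotate centered, unit-size A onto B, minimizing summed squared distance.

    Returns ``(rotated_A, angle)``.  With ``allow_reflection=False`` (the
    default, and the only mode the pipeline uses) the transform has
    determinant +1 even when a reflection would fit better.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape:
        raise ValueError(f"landmark count mismatch: {A.shape} vs {B.shape}")
    if allow_reflection:
        H = A.T @ B
        U, _, Vt = np.linalg.svd(H)
        R = (U @ Vt).T
        rotated = A @ R.T
        theta = float(np.arctan2(R[1, 0], R[0, 0]))
        return rotated, theta
    theta = _rotation_angle(A, B)
    return A @ rotation_matrix(theta).T, theta


def _align_all(configs: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotate each (k,2) configuration in (n,k,2) onto `target` (vectorized)."""
    H = np.einsum("nki,kj->nij", configs, target)
    theta = np.arctan2(H[:, 0, 1] - H[:, 1, 0], H[:, 0, 0] + H[:, 1, 1])
    c, s = np.cos(theta), np.sin(theta)
    R = np.empty((configs.shape[0], 2, 2))
    R[:, 0, 0] = c
    R[:, 0, 1] = -s
    R[:, 1, 0] = s
    R[:, 1, 1] = c
    return np.einsum("nki,nji->nkj", configs, R)


@dataclass
class ProcrustesFit:
    """Result of a generalized Procrustes superimposition."""

    aligned: np.ndarray  # (n, k, 2), centered, unit centroid size, rotated
    consensus: np.ndarray  # (k, 2), unit centroid size
    centroid_sizes: np.ndarray  # (n,), original scales
    iterations: int
    converged: bool

    @property
    def n(self) -> int:
        return self.aligned.shape[0]

    @property
    def k(self) -> int:
        return self.aligned.shape[1]


def gpa(
    configs,
    tol: float = 1e-10,
    max_iter: int = 200,
    principal_align: bool = True,
) -> ProcrustesFit:
    """Generalized Procrustes analysis of >= 2 equally sized configurations.

    Iteratively rotates every (centered, unit-size) configuration onto the
    provisional consensus, recomputes the consensus, and rescales it to unit
    centroid size, until the mean squared residual changes by less than
    `tol`.  With `principal_align` the final consensus is rotated onto its
    principal axes (largest variance on x), which fixes the otherwise
    arbitrary global orientation of scores.
    """
    arr = [np.asarray(c, dtype=float) for c in configs]
    if len(arr) < 2:
        raise ValueError("GPA needs at least two configurations")
    ks = {a.shape for a in arr}
    if len(ks) != 1:
        raise ValueError("configurations differ in landmark count")
    scaled = []
    sizes = []
    for a in arr:
        s, size = center_scale(a)
        scaled.append(s)
        sizes.append(size)
    X = np.stack(scaled)  # (n, k, 2)

    consensus = X[0]
    prev_msr = np.inf
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        X = _align_all(X, consensus)
        consensus = X.mean(axis=0)
        csize = np.sqrt((consensus**2).sum())
        if csize < 1e-12:
            raise DegenerateConfigurationError("consensus collapsed to a point")
        consensus = consensus / csize
        msr = float(((X - consensus) ** 2).sum() / X.shape[0])
        if abs(prev_msr - msr) < tol:
            converged = True
            break
        prev_msr = msr

    if principal_align:
        # rotate so the consensus' principal axes line up with x/y
        cov = consensus.T @ consensus
        evals, evecs = np.linalg.eigh(cov)
        R = evecs[:, ::-1]  # descending variance
        if np.linalg.det(R) < 0:
            R[:, 1] = -R[:, 1]
        # sign convention: largest-|coordinate| entry of each axis positive
        proj = consensus @ R
        for j in range(2):
            col = proj[:, j]
            if col[np.argmax(np.abs(col))] < 0:
                R[:, j] = -R[:, j]
        consensus = consensus @ R
        X = np.einsum("nki,ij->nkj", X, R)
        X = _align_all(X, consensus)

    return ProcrustesFit(
        aligned=X,
        consensus=X.mean(axis=0),
        centroid_sizes=np.asarray(sizes),
        iterations=iterations,
        converged=converged,
    )


def procrustes_distance(A: np.ndarray, B: np.ndarray) -> float:
    """Partial Procrustes distance between two configurations.

    Root of the minimized summed squared difference after centering, scaling
    to unit centroid size, and optimal proper rotation.  Symmetric in its
    arguments.
    """
    A0, _ = center_scale(np.asarray(A, dtype=float))
    B0, _ = center_scale(np.asarray(B, dtype=float))
    if A0.shape != B0.shape:
        raise ValueError("landmark count mismatch")
    rotated, _ = optimal_rotation(A0, B0)
    return float(np.sqrt(((rotated - B0) ** 2).sum()))


def tangent_project(fit: ProcrustesFit) -> np.ndarray:
    """Project aligned configurations onto the tangent space at the consensus.

    Returns an (n, 2k) matrix of tangent coordinates — deviations from the
    consensus orthogonal to it.  For small shape variation, Euclidean
    distances in this space approximate Procrustes distances.
    """
    m = fit.consensus.reshape(-1)
    m = m / np.linalg.norm(m)
    X = fit.aligned.reshape(fit.n, -1)
    return X - np.outer(X @ m, m)
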