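"""PCA morphospaces of positional asymmetry.

Two ordinations are built from the species-average configurations:

* :func:`mirrored_pca` — PCA of the jointly superimposed species means and
  their mirrored copies.  Because the sample is closed under
  reflect-and-relabel, each principal component describes either purely
  symmetric or purely asymmetric variation; original/mirror pairs sit at
  opposite positions along asymmetric PCs, and the ideally symmetric
  configuration projects to the center of the ordination.
* :func:`asymmetric_pca` — PCA of the species asymmetric components alone
  (no mirrors), centered on the grand-mean asymmetric configuration; its
  scores are the shape space into which the phylogeny is mapped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .symmetry import (
    SpeciesAsymmetryMean,
    SymmetryMap,
    joint_symmetry_gpa,
    symmetric_projector_split,
)

PC_SYMMETRIC = "symmetric"
PC_ASYMMETRIC = "asymmetric"
PC_MIXED = "mixed"


@dataclass
class Morphospace:
    """A PCA basis with scores and per-PC symmetry classification."""

    center: np.ndarray  # flat (2k,) configuration at the origin of the space
    eigenvectors: np.ndarray  # (2k, n_pc), columns ordered by eigenvalue
    eigenvalues: np.ndarray  # (n_pc,), descending
    scores: np.ndarray  # (n_obs, n_pc)
    labels: list[str]
    pc_class: list[str]
    variance_fractions: np.ndarray

    @property
    def n_pc(self) -> int:
        return self.eigenvalues.size

    def scores_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.n_pc)]
        df = pd.DataFrame(self.scores, index=self.labels, columns=cols)
        df.index.name = "configuration"
        return df

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "eigenvalue": self.eigenvalues,
                "variance_fraction": self.variance_fractions,
                "class": self.pc_class,
            },
            index=[f"PC{i + 1}" for i in range(self.n_pc)],
        )


def _pca(deviations: np.ndarray, eig_floor: float = 1e-12) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Centered PCA by SVD; drops numerically null components.

    Eigenvectors are sign-fixed so the largest-magnitude loading is positive.
    """
    n = deviations.shape[0]
    U, s, Vt = np.linalg.svd(deviations, full_matrices=False)
    eigvals = s**2 / (n - 1)
    keep = eigvals > eig_floor * max(eigvals.max(), 1e-300)
    eigvals = eigvals[keep]
    V = Vt[keep].T
    scores = deviations @ V
    for j in range(V.shape[1]):
        i = np.argmax(np.abs(V[:, j]))
        if V[i, j] < 0:
            V[:, j] = -V[:, j]
            scores[:, j] = -scores[:, j]
    return V, eigvals, scores


def mirrored_pca(
    means: list[SpeciesAsymmetryMean],
    smap: SymmetryMap,
    class_tol: float = 1e-6,
) -> Morphospace:
    """PCA of species means together with their mirrored copies.

    The 2S configurations are superimposed in a joint symmetric GPA and their
    aligned coordinates decomposed by PCA.  Each PC is classified by the
    original/mirror score pattern: *asymmetric* when mirrors score opposite
    to originals, *symmetric* when they score equal, *mixed* otherwise
    (tolerance ``class_tol`` relative to the PC's score scale).
    """
    if len(means) < 3:
        raise ValueError("need at least 3 species")
    S = len(means)
    configs = np.stack([m.mean for m in means])
    joint = joint_symmetry_gpa(configs, smap)
    X = joint.fit.aligned.reshape(2 * S, -1)
    center = X.mean(axis=0)
    V, eigvals, scores = _pca(X - center)

    pc_class = []
    for j in range(eigvals.size):
        zo = scores[:S, j]
        zm = scores[S:, j]
        scale = max(float(np.abs(scores[:, j]).max()), 1e-300)
        if np.abs(zo + zm).max() <= class_tol * scale:
            pc_class.append(PC_ASYMMETRIC)
        elif np.abs(zo - zm).max() <= class_tol * scale:
            pc_class.append(PC_SYMMETRIC)
        else:
            pc_class.append(PC_MIXED)

    labels = [m.species_id for m in means] + [m.species_id + "_mirror" for m in means]
    total = float(((X - center) ** 2).sum() / (2 * S - 1))
    return Morphospace(
        center=center,
        eigenvectors=V,
        eigenvalues=eigvals,
        scores=scores,
        labels=labels,
        pc_class=pc_class,
        variance_fractions=eigvals / total if total > 0 else eigvals,
    )


def symmetric_asymmetric_variance(ms: Morphospace, smap: SymmetryMap) -> tuple[float, float]:
    """Total variance of a mirrored morphospace split by component.

    Decomposes each observation's deviation from the center into its
    symmetric and asymmetric parts; their variances add up to the total.
    """
    dev = ms.scores @ ms.eigenvectors.T
    sym, asym = symmetric_projector_split(dev, smap)
    n = dev.shape[0]
    return float((sym**2).sum() / (n - 1)), float((asym**2).sum() / (n - 1))


def asymmetric_pca(means: list[SpeciesAsymmetryMean]) -> Morphospace:
    """PCA of the species asymmetric components, without mirrored copies.

    Centered at the grand-mean asymmetric configuration; all PCs are
    asymmetric by construction.  Full-rank scores preserve the pairwise
    distances between species asymmetric components.
    """
    if len(means) < 3:
        raise ValueError("need at least 3 species")
    A = np.stack([m.asym_vector() for m in means])
    center = A.mean(axis=0)
    V, eigvals, scores = _pca(A - center)
    total = float(((A - center) ** 2).sum() / (len(means) - 1))
    return Morphospace(
        center=center,
        eigenvectors=V,
        eigenvalues=eigvals,
        scores=scores,
        labels=[m.species_id for m in means],
        pc_class=[PC_ASYMMETRIC] * eigvals.size,
        variance_fractions=eigvals / total if total > 0 else eigvals,
    )


def plot_scores(ms: Morphospace, path, pcx: int = 1, pcy: int = 2) -> None:
    """PC score scatter plot (SVG/PNG by file extension)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    if ms.n_pc < 2:
        raise ValueError("need at least two PCs to plot")
    x = ms.scores[:, pcx - 1]
    y = ms.scores[:, pcy - 1]
    mirror = [lbl.endswith("_mirror") for lbl in ms.labels]
    for xi, yi, lbl, m in zip(x, y, ms.labels, mirror):
        ax.scatter(xi, yi, c="0.6" if m else "tab:red", s=18)
        if not m:
            ax.annotate(lbl, (xi, yi), fontsize=6, alpha=0.8)
    ax.axhline(0.0, lw=0.5, c="0.8")
    ax.axvline(0.0, lw=0.5, c="0.8")
    ax.set_xlabel(f"PC{pcx} ({100 * ms.variance_fractions[pcx - 1]:.1f}%)")
    ax.set_ylabel(f"PC{pcy} ({100 * ms.variance_fractions[pcy - 1]:.1f}%)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
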