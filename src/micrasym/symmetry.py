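"""Object-symmetry analysis of configurations with an internal symmetry axis.

A *Micrasterias* lateral lobe carries two sublobes (LLS below, ULS above)
related by a symmetry axis running between them.  Object symmetry is analyzed
by merging every configuration with its reflected-and-relabelled copy in one
GPA: the average of an aligned original and its mirror is the symmetric
component, half their difference the asymmetric component.  A Procrustes
ANOVA then partitions shape variation into

* individuals — symmetric shape differences among cells,
* positional asymmetry — the average shape difference between the paired
  sublobes (the within-configuration analogue of directional asymmetry),
* fluctuating asymmetry (FA) — individual deviations from that average
  (the individual x side interaction), and
* measurement error — disagreement between digitization replicates,

with permutation tests for the first three effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .landmark_io import LandmarkDataset
from .procrustes import ProcrustesFit, _align_all, gpa, rotation_matrix

EFFECTS = ("individuals", "positional_asymmetry", "fluctuating_asymmetry", "measurement_error")


@dataclass(frozen=True)
class SymmetryMap:
    """Pairing of landmarks across the sublobe symmetry axis.

    ``pairs`` lists (lower-side, upper-side) landmark indices (1-based);
    ``axis_points`` lists the unpaired landmarks lying on the axis.  Together
    they must partition 1..k.  The reflection axis is the line x = 0 by
    convention (reflect-and-relabel negates x, then swaps paired labels).
    """

    pairs: tuple[tuple[int, int], ...]
    axis_points: tuple[int, ...]
    roles: tuple[str, str] = ("lower", "upper")

    def __post_init__(self) -> None:
        object.__setattr__(self, "pairs", tuple(tuple(p) for p in self.pairs))
        object.__setattr__(self, "axis_points", tuple(self.axis_points))
        if len(self.pairs) < 1:
            raise ValueError("need at least one landmark pair")
        used = [i for p in self.pairs for i in p] + list(self.axis_points)
        if len(used) != len(set(used)):
            raise ValueError("a landmark index appears twice in the symmetry map")
        if set(used) != set(range(1, len(used) + 1)):
            raise ValueError("pairs and axis points must partition 1..k")

    @property
    def k(self) -> int:
        return 2 * len(self.pairs) + len(self.axis_points)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def permutation(self) -> np.ndarray:
        """Index array `perm` with perm[i] = source landmark (0-based) of output i."""
        perm = np.empty(self.k, dtype=int)
        for a, b in self.pairs:
            perm[a - 1] = b - 1
            perm[b - 1] = a - 1
        for a in self.axis_points:
            perm[a - 1] = a - 1
        return perm

    def subspace_dims(self) -> tuple[int, int]:
        """(symmetric, asymmetric) shape-space dimensions for 2D object symmetry.

        With p pairs and u axis points (k = 2p + u), each subspace of the
        (2k - 4)-dimensional shape space has dimension 2p + u - 2.
        """
        d = 2 * self.n_pairs + len(self.axis_points) - 2
        return d, d


def standard_map(k: int) -> SymmetryMap:
    """The sublobe symmetry maps of the 7- and 15-landmark schemes.

    Landmarks run along the lobe margin, so mirror partners are (1,k),
    (2,k-1), ... with the middle landmark on the axis:
    7 landmarks — pairs (1,7),(2,6),(3,5), axis {4} (LLS vs ULS);
    15 landmarks — pairs (1,15)...(7,9), axis {8}.
    """
    if k % 2 == 0:
        raise ValueError("standard maps exist only for odd landmark counts")
    if k < 3:
        raise ValueError("need k >= 3")
    p = (k - 1) // 2
    pairs = tuple((i, k + 1 - i) for i in range(1, p + 1))
    return SymmetryMap(pairs=pairs, axis_points=(p + 1,), roles=("LLS", "ULS"))


def reflect_relabel(coords: np.ndarray, smap: SymmetryMap) -> np.ndarray:
    """Reflect across x = 0 and swap paired landmark labels.

    An involution: applying it twice returns the input exactly.  A
    configuration symmetric about the axis is a fixed point.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] != smap.k:
        raise ValueError(f"map is for k={smap.k}, configuration has k={coords.shape[0]}")
    reflected = coords.copy()
    reflected[:, 0] = -reflected[:, 0]
    return reflected[smap.permutation()]


def _reflect_relabel_batch(configs: np.ndarray, smap: SymmetryMap) -> np.ndarray:
    out = configs.copy()
    out[..., 0] = -out[..., 0]
    return out[:, smap.permutation(), :]


def symmetric_projector_split(vectors: np.ndarray, smap: SymmetryMap) -> tuple[np.ndarray, np.ndarray]:
    """Split flat (…, 2k) coordinate vectors into symmetric and asymmetric parts.

    sym = (v + T v)/2, asym = (v - T v)/2, where T is reflect-and-relabel
    acting linearly on coordinates; sym + asym = v exactly.
    """
    v = np.asarray(vectors, dtype=float)
    shape = v.shape
    confs = v.reshape(shape[:-1] + (smap.k, 2))
    refl = confs.copy()
    refl[..., 0] = -refl[..., 0]
    refl = np.take(refl, smap.permutation(), axis=-2)
    sym = (confs + refl) / 2.0
    asym = (confs - refl) / 2.0
    return sym.reshape(shape), asym.reshape(shape)


@dataclass
class JointSymmetryFit:
    """GPA over originals and their reflected/relabelled copies.

    ``fit.aligned`` stacks the N aligned originals first, then the N aligned
    mirrors in the same order.  The consensus is symmetric under
    reflect-and-relabel by construction.
    """

    fit: ProcrustesFit
    smap: SymmetryMap
    n_originals: int

    @property
    def aligned_originals(self) -> np.ndarray:
        return self.fit.aligned[: self.n_originals]

    @property
    def aligned_mirrors(self) -> np.ndarray:
        return self.fit.aligned[self.n_originals:]

    @property
    def consensus(self) -> np.ndarray:
        return self.fit.consensus


def joint_symmetry_gpa(
    configs, smap: SymmetryMap, tol: float = 1e-12, max_iter: int = 200
) -> JointSymmetryFit:
    """GPA of the doubled set {originals} ∪ {reflect_relabel(originals)}.

    After convergence the frame is rotated so the consensus is invariant
    under reflect-and-relabel (the symmetry axis sits on x = 0), the
    consensus is explicitly symmetrized, and every configuration is realigned
    to it once more.
    """
    if isinstance(configs, LandmarkDataset):
        configs = configs.coords_array()
    originals = np.asarray([np.asarray(c, dtype=float) for c in configs])
    n = originals.shape[0]
    mirrors = _reflect_relabel_batch(originals, smap)
    fit = gpa(np.concatenate([originals, mirrors]), tol=tol, max_iter=max_iter,
              principal_align=False)

    # The consensus shape is reflection-symmetric, but its representative may
    # sit in a rotated frame: T m = R(theta) m.  Rotating everything by
    # theta/2 makes the consensus a fixed point of T.
    m = fit.consensus
    Tm = reflect_relabel(m, smap)
    H = Tm.T @ m
    beta = float(np.arctan2(H[0, 1] - H[1, 0], H[0, 0] + H[1, 1]))  # R(beta) Tm ≈ m
    alpha = -beta / 2.0  # T m = R(-beta) m  =>  rotate frame by alpha
    R = rotation_matrix(alpha)
    m = m @ R.T
    X = np.einsum("nki,ji->nkj", fit.aligned, R)
    m = (m + reflect_relabel(m, smap)) / 2.0
    m = m / np.sqrt((m**2).sum())
    X = _align_all(X, m)
    fit.aligned = X
    # consensus: the (exactly symmetrized) arithmetic mean of the aligned set
    m = X.mean(axis=0)
    fit.consensus = (m + reflect_relabel(m, smap)) / 2.0
    return JointSymmetryFit(fit=fit, smap=smap, n_originals=n)


@dataclass
class SymmetryComponents:
    """Per-specimen symmetric/asymmetric decomposition in the joint frame.

    symmetric[i] + asymmetric[i] == aligned original i, exactly; the
    asymmetric part changes sign under reflect-and-relabel.
    Both are stored as (n, k, 2) arrays; symmetric as full configurations,
    asymmetric as signed deviations.
    """

    symmetric: np.ndarray
    asymmetric: np.ndarray
    consensus: np.ndarray
    smap: SymmetryMap

    def symmetric_deviations(self) -> np.ndarray:
        """Symmetric components as flat deviations from the consensus, (n, 2k)."""
        n = self.symmetric.shape[0]
        return (self.symmetric - self.consensus).reshape(n, -1)

    def asymmetric_vectors(self) -> np.ndarray:
        """Asymmetric components as flat vectors, (n, 2k)."""
        return self.asymmetric.reshape(self.asymmetric.shape[0], -1)


def symmetry_components(joint: JointSymmetryFit) -> SymmetryComponents:
    """Average/half-difference of each aligned original and its mirror twin."""
    O = joint.aligned_originals
    M = joint.aligned_mirrors
    return SymmetryComponents(
        symmetric=(O + M) / 2.0,
        asymmetric=(O - M) / 2.0,
        consensus=joint.consensus,
        smap=joint.smap,
    )


@dataclass
class SymmetryAnovaTable:
    """Procrustes ANOVA of object symmetry (SS/df/MS/R²/F/p per effect)."""

    effects: dict[str, dict[str, float]]
    n_specimens: int
    n_replicates: int
    n_perm: int
    seed: int | None
    denominator: str
    fa_testable: bool

    @property
    def ss_total(self) -> float:
        return sum(e["SS"] for e in self.effects.values())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame.from_dict(self.effects, orient="index")
        df.index.name = "effect"
        df.attrs["seed"] = self.seed
        df.attrs["n_perm"] = self.n_perm
        return df

    def __getitem__(self, effect: str) -> dict[str, float]:
        return self.effects[effect]


def _group_means(rows: np.ndarray, n: int, r: int) -> np.ndarray:
    return rows.reshape(n, r, -1).mean(axis=1)


def symmetry_anova(
    dataset: LandmarkDataset,
    smap: SymmetryMap,
    n_perm: int = 999,
    seed: int | None = None,
    denominator: str = "fa",
) -> SymmetryAnovaTable:
    """Procrustes ANOVA of object symmetry on a balanced n x r design.

    Sums of squares are computed over all 2·n·r aligned configurations
    (originals plus mirrors) in the joint tangent space, so the four effect
    SS add up to the total exactly.  Degrees of freedom use the symmetric and
    asymmetric subspace dimensions d_s = d_a = 2p + u - 2.

    F ratios: individuals and positional asymmetry over FA (or over a pooled
    FA+error MS with ``denominator="pooled"``), FA over measurement error.
    p-values come from permutations of the exchangeable units for each
    effect: side labels within specimens (positional), symmetric rows across
    specimens (individuals), asymmetric rows across specimens (FA), with
    p = (#{F_perm >= F_obs} + 1) / (n_perm + 1).

    With a single replicate (r = 1) the error row is omitted and FA is
    untestable (``fa_testable`` False).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if denominator not in ("fa", "pooled"):
        raise ValueError("denominator must be 'fa' or 'pooled'")
    counts = dataset.replicate_counts()
    if len(set(counts.values())) != 1:
        raise ValueError(f"unbalanced design; replicate counts per specimen: {counts}")
    r = next(iter(counts.values()))
    specs = dataset.specimen_ids
    n = len(specs)
    if n < 2:
        raise ValueError("need at least two specimens")
    order = {s: i for i, s in enumerate(specs)}
    # rows sorted by (specimen, replicate) so reshape(n, r, ...) groups correctly
    recs = sorted(dataset.records, key=lambda rec: (order[rec.specimen_id], rec.replicate))
    configs = np.stack([rec.coords for rec in recs])

    joint = joint_symmetry_gpa(configs, smap)
    comp = symmetry_components(joint)
    S = comp.symmetric_deviations()  # (nr, 2k)
    A = comp.asymmetric_vectors()  # (nr, 2k)

    s_gm = S.mean(axis=0)
    a_gm = A.mean(axis=0)
    s_i = _group_means(S, n, r)
    a_i = _group_means(A, n, r)

    ss_ind = 2.0 * r * float(((s_i - s_gm) ** 2).sum())
    ss_pos = 2.0 * n * r * float((a_gm**2).sum())
    ss_fa = 2.0 * r * float(((a_i - a_gm) ** 2).sum())
    ss_err_s = 2.0 * float(((S - np.repeat(s_i, r, axis=0)) ** 2).sum())
    ss_err_a = 2.0 * float(((A - np.repeat(a_i, r, axis=0)) ** 2).sum())
    ss_err = ss_err_s + ss_err_a

    d_s, d_a = smap.subspace_dims()
    df_ind = (n - 1) * d_s
    df_pos = d_a
    df_fa = (n - 1) * d_a
    df_err = n * (r - 1) * (d_s + d_a)

    ss_total = ss_ind + ss_pos + ss_fa + ss_err
    ms_ind = ss_ind / df_ind
    ms_pos = ss_pos / df_pos
    ms_fa = ss_fa / df_fa
    ms_err = ss_err / df_err if df_err > 0 else np.nan

    def _denom(ss_fa_val: float, ss_err_val: float) -> float:
        if denominator == "fa":
            return ss_fa_val / df_fa
        return (ss_fa_val + ss_err_val) / (df_fa + df_err)

    def _safe_div(num, den):
        num = np.asarray(num, dtype=float)
        den = np.asarray(den, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(den > 0, num / np.where(den > 0, den, 1.0),
                           np.where(num > 0, np.inf, np.nan))
        return out if out.ndim else float(out)

    f_ind = _safe_div(ms_ind, _denom(ss_fa, ss_err))
    f_pos = _safe_div(ms_pos, _denom(ss_fa, ss_err))
    f_fa = _safe_div(ms_fa, ms_err) if df_err > 0 else np.nan

    rng = np.random.default_rng(seed)

    # positional asymmetry: specimen-wise sign flips of the asymmetric
    # component (equivalently, permuting original/mirror side labels)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    a_norm2 = float((a_i**2).sum())
    m_eps = (signs @ a_i) / n  # (n_perm, 2k) permuted grand means
    ss_pos_p = 2.0 * n * r * (m_eps**2).sum(axis=1)
    ss_fa_p = 2.0 * r * (a_norm2 - n * (m_eps**2).sum(axis=1))
    if denominator == "fa":
        denom_p = ss_fa_p / df_fa
    else:
        denom_p = (ss_fa_p + ss_err) / (df_fa + df_err)
    f_pos_p = _safe_div(ss_pos_p / df_pos, denom_p)
    p_pos = (int((f_pos_p >= f_pos * (1 - 1e-12)).sum()) + 1) / (n_perm + 1)

    # individuals: shuffle symmetric rows across specimens
    nr = n * r
    perm_idx = np.stack([rng.permutation(nr) for _ in range(n_perm)])
    Sp = S[perm_idx]  # (n_perm, nr, 2k)
    si_p = Sp.reshape(n_perm, n, r, -1).mean(axis=2)
    ss_ind_p = 2.0 * r * ((si_p - s_gm) ** 2).sum(axis=(1, 2))
    f_ind_p = _safe_div(ss_ind_p / df_ind, _denom(ss_fa, ss_err))
    p_ind = (int((f_ind_p >= f_ind * (1 - 1e-12)).sum()) + 1) / (n_perm + 1)

    # FA: shuffle asymmetric rows across specimens, retest against error
    if df_err > 0:
        perm_idx = np.stack([rng.permutation(nr) for _ in range(n_perm)])
        Ap = A[perm_idx]
        ai_p = Ap.reshape(n_perm, n, r, -1).mean(axis=2)
        ss_fa_p2 = 2.0 * r * ((ai_p - a_gm) ** 2).sum(axis=(1, 2))
        ss_err_a_p = 2.0 * ((Ap.reshape(n_perm, n, r, -1)
                             - ai_p[:, :, None, :]) ** 2).sum(axis=(1, 2, 3))
        f_fa_p = _safe_div(ss_fa_p2 / df_fa, (ss_err_s + ss_err_a_p) / df_err)
        p_fa = (int((f_fa_p >= f_fa * (1 - 1e-12)).sum()) + 1) / (n_perm + 1)
    else:
        p_fa = np.nan

    effects = {
        "individuals": dict(SS=ss_ind, df=df_ind, MS=ms_ind, R2=ss_ind / ss_total,
                            F=f_ind, p=p_ind),
        "positional_asymmetry": dict(SS=ss_pos, df=df_pos, MS=ms_pos,
                                     R2=ss_pos / ss_total, F=f_pos, p=p_pos),
        "fluctuating_asymmetry": dict(SS=ss_fa, df=df_fa, MS=ms_fa,
                                      R2=ss_fa / ss_total, F=f_fa, p=p_fa),
    }
    if df_err > 0:
        effects["measurement_error"] = dict(SS=ss_err, df=df_err, MS=ms_err,
                                            R2=ss_err / ss_total, F=np.nan, p=np.nan)
    return SymmetryAnovaTable(
        effects=effects,
        n_specimens=n,
        n_replicates=r,
        n_perm=n_perm,
        seed=seed,
        denominator=denominator,
        fa_testable=df_err > 0,
    )


@dataclass
class SpeciesAsymmetryMean:
    """Species-average configuration with its mirror and asymmetric component."""

    species_id: str
    mean: np.ndarray  # (k, 2) mean of aligned originals
    mirrored: np.ndarray  # (k, 2) reflect_relabel of the mean
    asymmetry: np.ndarray  # (k, 2) signed asymmetric component of the mean
    n_specimens: int

    def asym_vector(self) -> np.ndarray:
        return self.asymmetry.reshape(-1)


def species_asymmetry_means(
    dataset: LandmarkDataset, smap: SymmetryMap
) -> list[SpeciesAsymmetryMean]:
    """Per-species mean aligned configuration, mirror, and asymmetric component.

    All species are superimposed in one joint symmetric GPA so the asymmetric
    components are comparable across species.  Replicates contribute equally
    to each species mean.
    """
    joint = joint_symmetry_gpa(dataset, smap)
    aligned = joint.aligned_originals
    out = []
    for sp in dataset.species:
        mask = np.array([rec.species_id == sp for rec in dataset.records])
        if not mask.any():
            raise ValueError(f"no specimens for species {sp}")
        mean = aligned[mask].mean(axis=0)
        mirror = reflect_relabel(mean, smap)
        n_specimens = len({rec.specimen_id for rec, m in zip(dataset.records, mask) if m})
        out.append(
            SpeciesAsymmetryMean(
                species_id=sp,
                mean=mean,
                mirrored=mirror,
                asymmetry=(mean - mirror) / 2.0,
                n_specimens=n_specimens,
            )
        )
    return out
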