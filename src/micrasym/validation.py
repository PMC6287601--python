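"""Independent cross-checks and Monte-Carlo calibration studies.

Each routine here computes a quantity twice — once through the package and
once through an independent route (brute-force grid search, generic
numerical optimization, or the known sampling distribution of a simulated
null) — and reports the discrepancy or the calibration statistic.  The
oracle computations are deliberately self-contained: they do not call the
implementation they check.
"""

from __future__ import annotations

import numpy as np
import scipy.optimize
import scipy.stats

from . import phylo, procrustes, simulate, symmetry
from .landmark_io import LandmarkDataset, SpecimenRecord


# ---------------------------------------------------------------------------
# oracle equivalence


def grid_procrustes_error(
    n_pairs: int = 50, seed: int | None = None, grid_step: float = 0.001
) -> float:
    """Worst |procrustes_distance - brute-force rotation-grid minimum|.

    The oracle centers and scales both configurations directly and minimizes
    the summed squared difference over an explicit rotation grid
    (`grid_step` radians), never calling the closed-form rotation.
    Random pairs use 4-6 landmarks.
    """
    rng = np.random.default_rng(seed)
    thetas = np.arange(0.0, 2 * np.pi, grid_step)
    cos, sin = np.cos(thetas), np.sin(thetas)
    worst = 0.0
    for _ in range(n_pairs):
        k = int(rng.integers(4, 7))
        A = rng.normal(size=(k, 2))
        B = rng.normal(size=(k, 2))
        # oracle: explicit normalization + grid search
        A0 = A - A.mean(axis=0)
        A0 = A0 / np.sqrt((A0**2).sum())
        B0 = B - B.mean(axis=0)
        B0 = B0 / np.sqrt((B0**2).sum())
        # ||R A - B||^2 over all grid angles at once
        xa, ya = A0[:, 0], A0[:, 1]
        rx = np.outer(cos, xa) - np.outer(sin, ya)
        ry = np.outer(sin, xa) + np.outer(cos, ya)
        ss = ((rx - B0[:, 0]) ** 2 + (ry - B0[:, 1]) ** 2).sum(axis=1)
        oracle = float(np.sqrt(ss.min()))
        worst = max(worst, abs(procrustes.procrustes_distance(A, B) - oracle))
    return worst


def scp_oracle_error(
    n_trees: int = 100, seed: int | None = None, max_tips: int = 8
) -> float:
    """Worst |Q - Q_opt| against generic numerical optimization.

    For random trees (4..`max_tips` tips, random branch lengths) and random
    2-dimensional tip data, the oracle minimizes the weighted squared-change
    objective over all internal-node states with BFGS started from zero.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    for t in range(n_trees):
        n_tips = int(rng.integers(4, max_tips + 1))
        tree = simulate.simulate_tree(n_tips, seed=int(rng.integers(2**31)))
        # randomize branch lengths away from ultrametric
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length = float(rng.uniform(0.05, 2.0))
        labels = phylo.tip_labels(tree)
        X = rng.normal(size=(n_tips, 2))
        res = phylo.squared_change_parsimony(tree, X, labels=labels)

        # oracle: explicit objective over internal states
        nodes = list(tree.preorder_node_iter())
        internal = [nd for nd in nodes if not nd.is_leaf()]
        idx = {nd: i for i, nd in enumerate(internal)}
        tip_state = {lbl: X[i] for i, lbl in enumerate(labels)}

        def q_of(flat: np.ndarray) -> float:
            states = flat.reshape(len(internal), 2)
            total = 0.0
            for nd in nodes:
                if nd.parent_node is None:
                    continue
                child = states[idx[nd]] if nd in idx else tip_state[nd.taxon.label]
                parent = states[idx[nd.parent_node]]
                total += ((child - parent) ** 2).sum() / nd.edge.length
            return total

        opt = scipy.optimize.minimize(
            q_of, np.zeros(2 * len(internal)), method="BFGS",
            options={"gtol": 1e-12, "maxiter": 10_000},
        )
        worst = max(worst, abs(res.q_total - float(opt.fun)))
    return worst


# ---------------------------------------------------------------------------
# null calibrations


def _single_species_dataset(
    n: int, r: int, params: simulate.SimulationParams, delta_scale: float,
    rng: np.random.Generator,
) -> LandmarkDataset:
    """One species, n specimens x r replicates, optional true asymmetry."""
    smap = symmetry.standard_map(params.k)
    base = simulate.default_base_shape(params.k)
    project = simulate._shape_projectors(base, smap)
    d = 2 * params.k
    delta = project(rng.normal(0.0, delta_scale, d), "asym") if delta_scale > 0 else 0.0
    records = []
    for i in range(n):
        ind = project(rng.normal(0.0, params.sigma_ind, d), "sym")
        fa = project(rng.normal(0.0, params.sigma_fa, d), "asym")
        latent = base.reshape(-1) + delta + ind + fa
        for rep in range(1, r + 1):
            noisy = latent + rng.normal(0.0, params.sigma_me, d)
            records.append(
                SpecimenRecord(f"sp1_i{i + 1:03d}", "sp1", rep, noisy.reshape(params.k, 2))
            )
    return LandmarkDataset(records)


def positional_type1_error(
    n_sims: int = 200,
    n: int = 20,
    r: int = 2,
    n_perm: int = 199,
    alpha: float = 0.05,
    seed: int | None = None,
) -> float:
    """Type-I error of the positional-asymmetry test under delta = 0.

    Simulates single-species datasets with individual variation, FA and
    digitization error but no positional asymmetry, and reports the fraction
    of permutation p-values at or below `alpha`.
    """
    rng = np.random.default_rng(seed)
    params = simulate.SimulationParams(k=7)
    smap = symmetry.standard_map(7)
    rejections = 0
    for _ in range(n_sims):
        dataset = _single_species_dataset(n, r, params, 0.0, rng)
        tab = symmetry.symmetry_anova(
            dataset, smap, n_perm=n_perm, seed=int(rng.integers(2**31))
        )
        if tab["positional_asymmetry"]["p"] <= alpha:
            rejections += 1
    return rejections / n_sims


def signal_null_pvalues(
    n_sims: int = 200,
    n_tips: int = 19,
    n_dims: int = 5,
    n_perm: int = 199,
    seed: int | None = None,
) -> np.ndarray:
    """Signal-test p-values for iid (phylogeny-free) tip data."""
    rng = np.random.default_rng(seed)
    tree = simulate.simulate_tree(n_tips, seed=int(rng.integers(2**31)))
    labels = phylo.tip_labels(tree)
    out = np.empty(n_sims)
    for s in range(n_sims):
        X = rng.normal(size=(n_tips, n_dims))
        out[s] = phylo.phylo_signal_test(
            tree, X, labels=labels, n_perm=n_perm, seed=int(rng.integers(2**31))
        ).p_value
    return out


def pls_null_pvalues(
    n_sims: int = 200,
    n_tips: int = 14,
    n_dims: int = 6,
    n_perm: int = 199,
    seed: int | None = None,
) -> np.ndarray:
    """phylo_pls p-values for independent Brownian blocks on one tree."""
    rng = np.random.default_rng(seed)
    tree = simulate.simulate_tree(n_tips, seed=int(rng.integers(2**31)))
    labels = phylo.tip_labels(tree)
    C = phylo.phylo_cov(tree, labels).to_numpy()
    chol = np.linalg.cholesky(C)
    out = np.empty(n_sims)
    for s in range(n_sims):
        X = chol @ rng.normal(size=(n_tips, n_dims))
        Y = chol @ rng.normal(size=(n_tips, n_dims))
        out[s] = phylo.phylo_pls(
            tree, X, Y, labels=labels, n_perm=n_perm, seed=int(rng.integers(2**31))
        ).p_value
    return out


def ks_uniformity_pvalue(pvalues: np.ndarray) -> float:
    """Kolmogorov-Smirnov p for uniformity of permutation p-values."""
    return float(scipy.stats.kstest(pvalues, "uniform").pvalue)


# ---------------------------------------------------------------------------
# parameter recovery at the study's sampling depth


def paper_scale_recovery(
    seed: int | None = None,
    n_perm: int = 999,
    params: simulate.SimulationParams | None = None,
) -> dict:
    """Recovery of species asymmetry vectors at the full sampling design.

    Simulates the default study (19 species x 75 specimens x 2 replicates,
    15 landmarks), then

    * compares each recovered species asymmetric component with the true
      one mapped into the fitted frame (the true species mean pushed
      through the same center/scale/rotate + reflect-relabel decomposition),
      counting species within 3 standard errors of the mean vector, and
    * runs the per-species Procrustes ANOVA for every strong-asymmetry
      species (|delta| >= 5 sigma_FA) and collects the positional p-values.
    """
    rng = np.random.default_rng(seed)
    if params is None:
        params = simulate.SimulationParams(seed=int(rng.integers(2**31)))
    smap = symmetry.standard_map(params.k)
    tree, dataset, truth = simulate.simulate_study(params)

    joint = symmetry.joint_symmetry_gpa(dataset, smap)
    comp = symmetry.symmetry_components(joint)
    A = comp.asymmetric_vectors()  # (n_records, 2k)
    consensus = joint.consensus

    species = dataset.species
    records = dataset.records
    rec_species = np.array([rec.species_id for rec in records])
    rec_specimen = np.array([rec.specimen_id for rec in records])
    within_3se = 0
    norms = {}
    for sp in species:
        mask = rec_species == sp
        # specimen-level asymmetric components (replicates averaged)
        spec_ids, spec_inv = np.unique(rec_specimen[mask], return_inverse=True)
        sums = np.zeros((spec_ids.size, A.shape[1]))
        np.add.at(sums, spec_inv, A[mask])
        counts = np.bincount(spec_inv)
        spec_means = sums / counts[:, None]
        est = spec_means.mean(axis=0)
        se = float(np.sqrt(spec_means.var(axis=0, ddof=1).sum() / len(spec_ids)))
        # truth mapped into the fitted frame
        true_mean = truth.species[sp].mean_symmetric + truth.species[sp].delta
        scaled, _ = procrustes.center_scale(true_mean)
        aligned, _ = procrustes.optimal_rotation(scaled, consensus / np.linalg.norm(consensus))
        a_true = (aligned - symmetry.reflect_relabel(aligned, smap)).reshape(-1) / 2.0
        err = float(np.linalg.norm(est - a_true))
        norms[sp] = float(np.linalg.norm(truth.species[sp].delta))
        if err <= 3.0 * se:
            within_3se += 1

    strong = [sp for sp in species if norms[sp] >= 5.0 * params.sigma_fa]
    strong_p = []
    for sp in strong:
        tab = symmetry.symmetry_anova(
            dataset.subset_species([sp]), smap, n_perm=n_perm,
            seed=int(rng.integers(2**31)),
        )
        strong_p.append(tab["positional_asymmetry"]["p"])
    return {
        "n_species": len(species),
        "n_within_3se": within_3se,
        "n_strong": len(strong),
        "strong_positional_p": strong_p,
        "delta_norms": norms,
    }


# ---------------------------------------------------------------------------
# star-tree reductions


def _plain_two_block_pls_r(X: np.ndarray, Y: np.ndarray) -> float:
    """Oracle: ordinary (non-phylogenetic) two-block PLS correlation."""
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    R = Xc.T @ Yc / (X.shape[0] - 1)
    U, _, Vt = np.linalg.svd(R, full_matrices=False)
    sx = Xc @ U[:, 0]
    sy = Yc @ Vt[0]
    return abs(float(np.corrcoef(sx, sy)[0, 1]))


def star_tree_reductions(seed: int | None = None, n_tips: int = 12) -> dict:
    """phylo_pls on a unit-branch star tree vs ordinary two-block PLS,
    and the signal test's behaviour when the tree carries no structure.

    On a star tree with equal branch lengths C = I, so the phylogenetic
    transformation is the identity and Q is permutation-invariant.
    """
    rng = np.random.default_rng(seed)
    newick = "(" + ",".join(f"t{i}:1" for i in range(1, n_tips + 1)) + ");"
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.is_rooted = True
    labels = [f"t{i}" for i in range(1, n_tips + 1)]
    X = rng.normal(size=(n_tips, 5))
    Y = rng.normal(size=(n_tips, 4))
    res = phylo.phylo_pls(tree, X, Y, labels=labels, n_perm=49, seed=1)
    r_diff = abs(res.r_pls - _plain_two_block_pls_r(X, Y))
    sig = phylo.phylo_signal_test(tree, X, labels=labels, n_perm=199, seed=2)
    return {"pls_star_abs_diff": r_diff, "star_signal_p": sig.p_value}
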