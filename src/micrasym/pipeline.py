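"""Orchestration of the full positional-asymmetry study workflow.

Stages: per-species object-symmetry Procrustes ANOVAs (the Table-1 analogue)
→ species asymmetry means → PCA morphospaces → phylogenetic-signal tests and
phylomorphospace projection → the three phylogenetic integration (PLS)
analyses.  Every stochastic step derives its seed from the pipeline seed, so
a rerun with the same configuration reproduces the report exactly.

Four parallel analyses are carved out of the 15-landmark configurations:

========================  =========================  =====================
analysis                  landmarks (of 15)          species
========================  =========================  =====================
sublobes_7lm              1,3,5,8,11,13,15           all
sublobes_15lm             1..15                      lobulate subset
lobules_lls               1..7                       lobulate subset
lobules_uls               9..15                      lobulate subset
========================  =========================  =====================

"Lobulate" species are those whose sublobes carry 3rd-order terminal
lobules; this is a dataset annotation (14 of the 19 in the original survey),
not something inferred from the shapes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import yaml

from . import landmark_io, morphospace, phylo, simulate, symmetry

logger = logging.getLogger("micrasym")

NOT_APPLICABLE = "X"


@dataclass(frozen=True)
class AnalysisSpec:
    name: str
    indices: tuple[int, ...]  # 1-based landmark subset of the parent scheme
    map_k: int
    lobulate_only: bool


ANALYSES_15 = (
    AnalysisSpec("sublobes_7lm", (1, 3, 5, 8, 11, 13, 15), 7, False),
    AnalysisSpec("sublobes_15lm", tuple(range(1, 16)), 15, True),
    AnalysisSpec("lobules_lls", tuple(range(1, 8)), 7, True),
    AnalysisSpec("lobules_uls", tuple(range(9, 16)), 7, True),
)
ANALYSES_7 = (AnalysisSpec("sublobes_7lm", tuple(range(1, 8)), 7, False),)

# the three integration comparisons: whole-lobe asymmetry vs each lobule
# block, and the two lobule blocks against each other
PLS_COMPARISONS = (
    ("sublobes_15lm", "lobules_lls"),
    ("sublobes_15lm", "lobules_uls"),
    ("lobules_lls", "lobules_uls"),
)


@dataclass
class PipelineConfig:
    """Inputs, permutation counts, and seed for one pipeline run."""

    tps_path: str | None = None
    tree_path: str | None = None
    simulate: simulate.SimulationParams | None = None
    lobulate_species: list[str] | None = None
    n_lobulate: int = 14  # used when lobulate_species not given (simulated data)
    n_perm_anova: int = 999
    n_perm_signal: int = 9999
    n_perm_pls: int = 999
    seed: int | None = None
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulate", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulate = simulate.SimulationParams(**sim)
        return cfg

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items()}
        if self.simulate is not None:
            d["simulate"] = dict(self.simulate.__dict__)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class PipelineReport:
    """All tables and results of one run, with provenance."""

    anova_tables: dict[str, dict[str, symmetry.SymmetryAnovaTable | None]]
    species_means: dict[str, list[symmetry.SpeciesAsymmetryMean]]
    morphospaces: dict[str, dict[str, morphospace.Morphospace]]
    signal_tests: dict[str, phylo.SignalTestResult]
    integrations: dict[str, phylo.IntegrationResult]
    phylomorphospaces: dict[str, pd.DataFrame]
    provenance: dict = field(default_factory=dict)

    def table1(self) -> pd.DataFrame:
        """MS / R² / p of positional asymmetry per species and analysis.

        Non-applicable cells (species without 3rd-order lobules) are marked
        'X', mirroring the layout of the published summary table.
        """
        analyses = list(self.anova_tables)
        species = sorted({s for d in self.anova_tables.values() for s in d})
        cols = pd.MultiIndex.from_product([analyses, ["MS", "R2", "p"]])
        table = pd.DataFrame(index=species, columns=cols, dtype=object)
        for an, per_species in self.anova_tables.items():
            for sp in species:
                tab = per_species.get(sp)
                if tab is None:
                    table.loc[sp, (an, "MS")] = NOT_APPLICABLE
                    table.loc[sp, (an, "R2")] = NOT_APPLICABLE
                    table.loc[sp, (an, "p")] = NOT_APPLICABLE
                else:
                    eff = tab["positional_asymmetry"]
                    table.loc[sp, (an, "MS")] = round(eff["MS"], 6)
                    table.loc[sp, (an, "R2")] = round(eff["R2"], 6)
                    table.loc[sp, (an, "p")] = eff["p"]
        table.index.name = "species"
        return table


def _child_seed(seed_seq: np.random.SeedSequence) -> int:
    return int(seed_seq.spawn(1)[0].generate_state(1)[0] % (2**31))


def _analysis_plan(dataset: landmark_io.LandmarkDataset) -> tuple[AnalysisSpec, ...]:
    if dataset.k == 15:
        return ANALYSES_15
    if dataset.k == 7:
        return ANALYSES_7
    raise ValueError(f"no analysis plan for k={dataset.k} landmarks")


def _lobulate(dataset: landmark_io.LandmarkDataset, config: PipelineConfig) -> list[str]:
    if config.lobulate_species is not None:
        unknown = set(config.lobulate_species) - set(dataset.species)
        if unknown:
            raise ValueError(f"lobulate species not in dataset: {sorted(unknown)}")
        return list(config.lobulate_species)
    return dataset.species[: config.n_lobulate]


def run_symmetry_stage(
    dataset: landmark_io.LandmarkDataset,
    config: PipelineConfig,
    seed_seq: np.random.SeedSequence | None = None,
) -> dict[str, dict[str, symmetry.SymmetryAnovaTable | None]]:
    """Per-species Procrustes ANOVA for every applicable analysis.

    Species outside an analysis' scope get ``None`` (the 'X' cells of the
    summary table); species with fewer than two specimens are skipped with a
    warning.
    """
    t0 = time.perf_counter()
    seed_seq = seed_seq or np.random.SeedSequence(config.seed)
    lobulate = _lobulate(dataset, config)
    results: dict[str, dict[str, symmetry.SymmetryAnovaTable | None]] = {}
    for spec in _analysis_plan(dataset):
        sub = landmark_io.extract_landmarks(dataset, spec.indices)
        smap = symmetry.standard_map(spec.map_k)
        per_species: dict[str, symmetry.SymmetryAnovaTable | None] = {}
        for sp in dataset.species:
            if spec.lobulate_only and sp not in lobulate:
                per_species[sp] = None
                continue
            sp_data = sub.subset_species([sp])
            if len(sp_data.specimen_ids) < 2:
                logger.warning("skipping %s in %s: <2 specimens", sp, spec.name)
                per_species[sp] = None
                continue
            per_species[sp] = symmetry.symmetry_anova(
                sp_data, smap, n_perm=config.n_perm_anova, seed=_child_seed(seed_seq)
            )
        results[spec.name] = per_species
    logger.info("symmetry stage done in %.1fs (seed=%s)", time.perf_counter() - t0, config.seed)
    return results


def run_morphospace_stage(
    dataset: landmark_io.LandmarkDataset, config: PipelineConfig
) -> tuple[dict[str, list[symmetry.SpeciesAsymmetryMean]], dict[str, dict[str, morphospace.Morphospace]]]:
    """Species asymmetry means and the two PCA morphospaces per analysis."""
    t0 = time.perf_counter()
    lobulate = _lobulate(dataset, config)
    means_by: dict[str, list[symmetry.SpeciesAsymmetryMean]] = {}
    spaces: dict[str, dict[str, morphospace.Morphospace]] = {}
    for spec in _analysis_plan(dataset):
        sub = landmark_io.extract_landmarks(dataset, spec.indices)
        if spec.lobulate_only:
            sub = sub.subset_species([s for s in sub.species if s in lobulate])
        smap = symmetry.standard_map(spec.map_k)
        means = symmetry.species_asymmetry_means(sub, smap)
        means_by[spec.name] = means
        spaces[spec.name] = {
            "mirrored": morphospace.mirrored_pca(means, smap),
            "asymmetric": morphospace.asymmetric_pca(means),
        }
    logger.info("morphospace stage done in %.1fs", time.perf_counter() - t0)
    return means_by, spaces


def run_phylo_stage(
    config: PipelineConfig,
    means_by_analysis: dict[str, list[symmetry.SpeciesAsymmetryMean]],
    spaces: dict[str, dict[str, morphospace.Morphospace]],
    tree: dendropy.Tree,
    seed_seq: np.random.SeedSequence | None = None,
) -> tuple[dict[str, phylo.SignalTestResult], dict[str, phylo.IntegrationResult], dict[str, pd.DataFrame]]:
    """Signal tests, phylomorphospace projections, and the PLS comparisons.

    Signal is tested on the full species asymmetry vectors of each analysis
    (tree pruned to the species present); the phylomorphospace export holds
    tip and squared-change-parsimony ancestor scores in the asymmetric PCA
    of each analysis.
    """
    t0 = time.perf_counter()
    seed_seq = seed_seq or np.random.SeedSequence(
        config.seed if config.seed is None else config.seed + 1
    )
    tree_tips = set(phylo.tip_labels(tree))
    signal: dict[str, phylo.SignalTestResult] = {}
    phylomaps: dict[str, pd.DataFrame] = {}
    asym_blocks: dict[str, pd.DataFrame] = {}
    for name, means in means_by_analysis.items():
        species = [m.species_id for m in means]
        missing = set(species) - tree_tips
        if missing:
            raise ValueError(f"{name}: species not on tree: {sorted(missing)}")
        sub_tree = phylo.prune_to(tree, species) if set(species) != tree_tips else tree
        block = pd.DataFrame(
            np.stack([m.asym_vector() for m in means]), index=species
        )
        asym_blocks[name] = block
        signal[name] = phylo.phylo_signal_test(
            sub_tree, block, n_perm=config.n_perm_signal, seed=_child_seed(seed_seq)
        )
        # phylomorphospace: SCP ancestor states in the asymmetric PCA scores
        space = spaces[name]["asymmetric"]
        scores = pd.DataFrame(space.scores, index=space.labels).reindex(species)
        scp = phylo.squared_change_parsimony(sub_tree, scores)
        rows = [(sp, "tip", *scores.loc[sp]) for sp in species]
        for i, (node, state) in enumerate(scp.node_states.items()):
            label = node.label or f"node{i}"
            rows.append((label, "ancestor", *state))
        phylomaps[name] = pd.DataFrame(
            rows, columns=["node", "kind", *[f"PC{j+1}" for j in range(scores.shape[1])]]
        )

    integrations: dict[str, phylo.IntegrationResult] = {}
    for bx, by in PLS_COMPARISONS:
        if bx not in asym_blocks or by not in asym_blocks:
            continue
        X, Y = asym_blocks[bx], asym_blocks[by]
        common = [s for s in X.index if s in set(Y.index)]
        sub_tree = phylo.prune_to(tree, common) if set(common) != tree_tips else tree
        integrations[f"{bx}__vs__{by}"] = phylo.phylo_pls(
            sub_tree,
            X.loc[common],
            Y.loc[common],
            n_perm=config.n_perm_pls,
            seed=_child_seed(seed_seq),
        )
    logger.info("phylo stage done in %.1fs", time.perf_counter() - t0)
    return signal, integrations, phylomaps


def run_all(config: PipelineConfig) -> PipelineReport:
    """Execute every stage and (optionally) write the report tree."""
    seed_seq = np.random.SeedSequence(config.seed)
    if config.simulate is not None:
        params = config.simulate
        tree, dataset, truth = simulate.simulate_study(params)
    elif config.tps_path:
        dataset = landmark_io.read_tps(config.tps_path)
        tree = landmark_io.read_newick(config.tree_path) if config.tree_path else None
        truth = None
    else:
        raise ValueError("config needs either a simulate block or a tps_path")

    anova_tables = run_symmetry_stage(dataset, config, seed_seq=seed_seq)
    means_by, spaces = run_morphospace_stage(dataset, config)
    if tree is not None:
        signal, integrations, phylomaps = run_phylo_stage(
            config, means_by, spaces, tree, seed_seq=seed_seq
        )
    else:
        signal, integrations, phylomaps = {}, {}, {}

    report = PipelineReport(
        anova_tables=anova_tables,
        species_means=means_by,
        morphospaces=spaces,
        signal_tests=signal,
        integrations=integrations,
        phylomorphospaces=phylomaps,
        provenance={
            "seed": config.seed,
            "n_perm_anova": config.n_perm_anova,
            "n_perm_signal": config.n_perm_signal,
            "n_perm_pls": config.n_perm_pls,
            "config_hash": config.config_hash(),
            "simulated": config.simulate is not None,
        },
    )
    if config.out_dir:
        write_report(report, config, dataset, tree)
    return report


def report_json(report: PipelineReport) -> dict:
    """JSON-serializable summary of a report."""
    return {
        "provenance": report.provenance,
        "signal_tests": {
            name: {"Q": res.q_observed, "p": res.p_value, "n_perm": res.n_perm,
                   "seed": res.seed}
            for name, res in report.signal_tests.items()
        },
        "integrations": {
            name: {"r_pls": res.r_pls, "p": res.p_value, "n_perm": res.n_perm,
                   "seed": res.seed}
            for name, res in report.integrations.items()
        },
    }


def write_report(
    report: PipelineReport,
    config: PipelineConfig,
    dataset: landmark_io.LandmarkDataset,
    tree: dendropy.Tree | None,
) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.table1().to_csv(out / "positional_asymmetry_table.csv")
    for name, per_species in report.anova_tables.items():
        frames = {sp: tab.to_frame() for sp, tab in per_species.items() if tab is not None}
        if frames:
            pd.concat(frames, names=["species", "effect"]).to_csv(
                out / f"anova_{name}.csv"
            )
    for name, spaces in report.morphospaces.items():
        for kind, ms in spaces.items():
            ms.scores_frame().to_csv(out / f"scores_{name}_{kind}.csv")
            ms.summary_frame().to_csv(out / f"pcs_{name}_{kind}.csv")
    for name, frame in report.phylomorphospaces.items():
        frame.to_csv(out / f"phylomorphospace_{name}.csv", index=False)
    (out / "report.json").write_text(json.dumps(report_json(report), indent=2))
    landmark_io.write_tps(dataset, out / "dataset.tps")
    if tree is not None:
        landmark_io.write_newick(tree, out / "tree.nwk")
    logger.info("report written to %s", out)
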