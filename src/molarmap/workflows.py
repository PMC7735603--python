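"""End-to-end workflows and run configuration.

Two pipelines chain the modules: the mutant-classification workflow
(maps -> features -> accuracy grid -> parsimonious model -> morphospace
-> phenetic vs pseudo-genetic distances) and the phylogenetic workflow
(species maps -> K grid -> combined mutant+species morphospace with
ancestral nodes -> PGLS on diet -> hull coverage).  Each run writes its
tabular outputs plus a JSON manifest with the configuration hash, all
seeds, and package versions, sufficient to reproduce it.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datamining import (
    LEARNERS,
    cv_accuracy_grid,
    phylo_signal_grid,
    select_parsimonious_model,
)
from .errors import InputError
from .geometry import load_annotated_mesh, orient_and_crop
from .maps import centroid_size_normalize, compute_parameter_maps, radial_sample
from .phylostats import (
    ancestral_states,
    as_tree,
    between_group_pca,
    hull_coverage,
    mantel_test,
    pgls_categorical,
    phenetic_distance_matrix,
    pseudo_genetic_distance,
    tip_labels,
    wt_disparity_correlation,
)
from .spectral import COMBOS, assemble_features

log = logging.getLogger("molarmap")

__all__ = ["RunConfig", "specimen_to_mapset", "run_classification_workflow",
           "run_phylo_workflow"]


@dataclass
class RunConfig:
    """Validated parameters of a pipeline run."""

    specimen_table: str = ""  # CSV: specimen_id, group, mesh, [sidecar]
    genotype_table: str = ""  # CSV: strain x gene dosage classes
    tree_file: str = ""  # Newick
    diet_table: str = ""  # CSV: taxon, diet
    out_dir: str = "molarmap_out"
    grid_K: int = 300
    grid_L: int = 300
    combos: tuple = tuple(COMBOS)
    f_min: int = 1
    f_max_ml: int = 50
    f_max_k: int = 100
    learners: tuple = LEARNERS
    folds: int = 10
    tolerance: float = 0.0
    axes: int = 2
    n_perm: int = 999
    seed: int = 0
    wt_label: str = "WT"

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        if self.grid_K < 2 or self.grid_L < 2:
            raise InputError("grid dimensions must be >= 2")
        if self.f_min < 0 or self.f_max_ml < self.f_min or self.f_max_k < self.f_min:
            raise InputError("invalid filter-size range")
        if self.folds < 2:
            raise InputError("folds must be >= 2")
        for c in self.combos:
            if c not in COMBOS:
                raise InputError(f"unknown combo {c!r}")

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def specimen_to_mapset(mesh, outline, anchor, grid_K, grid_L,
                       specimen_id="", group=""):
    """Mesh + annotation -> centroid-size-normalized MapSet."""
    crown = orient_and_crop(mesh, outline, anchor)
    grid = radial_sample(crown, grid_K, grid_L)
    ms = compute_parameter_maps(grid, crown)
    ms.specimen_id = specimen_id
    ms.group = group
    return centroid_size_normalize(ms)


def _load_specimens(config: RunConfig):
    table = pd.read_csv(config.specimen_table)
    required = {"specimen_id", "group", "mesh"}
    if not required <= set(table.columns):
        raise InputError(f"specimen table needs columns {sorted(required)}")
    mapsets = []
    base = Path(config.specimen_table).parent
    for _, row in table.iterrows():
        mesh_path = base / row["mesh"]
        sidecar = base / row["sidecar"] if "sidecar" in table.columns else None
        try:
            mesh, outline, anchor = load_annotated_mesh(mesh_path, sidecar)
            mapsets.append(
                specimen_to_mapset(
                    mesh, outline, anchor, config.grid_K, config.grid_L,
                    specimen_id=str(row["specimen_id"]), group=str(row["group"]),
                )
            )
        except Exception as exc:
            raise type(exc)(
                f"stage=mapping specimen={row['specimen_id']}: {exc}"
            ) from exc
    return mapsets


def _manifest(config: RunConfig, extra: dict) -> dict:
    return {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "config": asdict(config),
        "config_hash": config.digest(),
        "seed": config.seed,
        **extra,
    }


def _write(out_dir: Path, name: str, df: pd.DataFrame):
    out_dir.mkdir(parents=True, exist_ok=True)
    df.to_csv(out_dir / name)


def run_classification_workflow(config: RunConfig, mapsets=None) -> dict:
    """Mutant pipeline: accuracy grid, model choice, morphospace, distances.

    ``mapsets`` may be passed directly (e.g. from the synthetic
    generator); otherwise they are built from ``config.specimen_table``.
    Returns a result dict; all artifacts land in ``config.out_dir``.
    """
    config.validate()
    if config.f_max_ml > min(config.grid_K, config.grid_L) // 2:
        raise InputError("f_max_ml exceeds the grid Nyquist range")
    out_dir = Path(config.out_dir)
    if mapsets is None:
        mapsets = _load_specimens(config)

    genotypes = pd.read_csv(config.genotype_table, index_col=0)
    strains = sorted({ms.group for ms in mapsets})
    missing = [s for s in strains if s not in genotypes.index]
    if missing:
        raise InputError(f"stage=genotypes: no genotype row for strain {missing[0]}")

    log.info("accuracy grid over %d combos x f<=%d", len(config.combos), config.f_max_ml)
    grid = cv_accuracy_grid(
        mapsets,
        combos=config.combos,
        f_range=range(config.f_min, config.f_max_ml + 1),
        learners=config.learners,
        folds=config.folds,
        seed=config.seed,
    )
    combo, f, learner = select_parsimonious_model(grid, config.tolerance)
    log.info("selected model: combo=%s f=%d learner=%s", combo, f, learner)

    feats, shifts = assemble_features(mapsets, combo, f)
    X = np.stack([fv.values for fv in feats])
    groups = [fv.group for fv in feats]
    space = between_group_pca(X, groups, project={"individuals": X})

    axes = min(config.axes, space.scores.shape[1])
    pdist_df = phenetic_distance_matrix(space, axes=axes)
    gen_from_wt, gen_pair = pseudo_genetic_distance(genotypes.loc[strains])
    order = space.group_labels
    gen_pair = gen_pair.loc[order, order]
    # the matrix-level and from-WT correlations need >= 3 strains
    if len(order) >= 3:
        r_mantel, p_mantel = mantel_test(
            pdist_df.to_numpy(), gen_pair.to_numpy(),
            n_perm=config.n_perm, seed=config.seed,
        )
        if config.wt_label in order:
            wt_idx = order.index(config.wt_label)
            phen_from_wt = pdist_df.iloc[:, wt_idx]
        else:
            phen_from_wt = pdist_df.iloc[:, 0]
        r_wt, r2_wt, p_wt = wt_disparity_correlation(
            gen_from_wt.loc[order].to_numpy(), phen_from_wt.to_numpy()
        )
    else:
        r_mantel = p_mantel = r_wt = r2_wt = p_wt = float("nan")

    _write(out_dir, "accuracy_grid.csv", grid.table.set_index(["combo", "f", "learner"]))
    _write(out_dir, "pc_scores.csv",
           pd.DataFrame(space.scores, index=order,
                        columns=[f"PC{i+1}" for i in range(space.scores.shape[1])]))
    _write(out_dir, "phenetic_distances.csv", pdist_df)
    _write(out_dir, "pseudo_genetic_distances.csv", gen_pair)
    _write(out_dir, "alignment_shifts.csv",
           pd.DataFrame({"specimen": [fv.specimen_id for fv in feats],
                         "shift": shifts}).set_index("specimen"))
    manifest = _manifest(config, {
        "workflow": "classification",
        "selected_model": {"combo": combo, "f": f, "learner": learner},
        "mantel": {"r": r_mantel, "p": p_mantel},
        "wt_disparity": {"r": r_wt, "r2": r2_wt, "p": p_wt},
        "variance_fractions": space.variance_fractions.tolist(),
    })
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return {
        "grid": grid,
        "selected": (combo, f, learner),
        "morphospace": space,
        "phenetic_distances": pdist_df,
        "genetic_distances": gen_pair,
        "genetic_from_wt": gen_from_wt,
        "mantel": (r_mantel, p_mantel),
        "wt_disparity": (r_wt, r2_wt, p_wt),
        "manifest": manifest,
    }


def run_phylo_workflow(config: RunConfig, species_mapsets=None,
                       mutant_mapsets=None) -> dict:
    """Comparative pipeline: K grid, combined morphospace, PGLS, hulls."""
    config.validate()
    if config.f_max_k > min(config.grid_K, config.grid_L) // 2:
        raise InputError("f_max_k exceeds the grid Nyquist range")
    out_dir = Path(config.out_dir)
    tree = as_tree(config.tree_file)
    tips = tip_labels(tree)
    if species_mapsets is None:
        species_mapsets = _load_specimens(config)

    diet = pd.read_csv(config.diet_table, index_col=0).iloc[:, 0]
    missing = [t for t in tips if t not in diet.index]
    if missing:
        raise InputError(f"stage=diet: diet table missing taxon {missing[0]}")

    grid = phylo_signal_grid(
        species_mapsets, tree, combos=config.combos,
        f_range=range(config.f_min, config.f_max_k + 1),
    )
    best = grid.best()
    combo, f = str(best["combo"]), int(best["f"])
    log.info("highest phylogenetic signal: combo=%s f=%d K=%.3f", combo, f, best["k"])

    all_sets = list(species_mapsets) + list(mutant_mapsets or [])
    feats, shifts = assemble_features(all_sets, combo, f)
    X = np.stack([fv.values for fv in feats])
    groups = [fv.group for fv in feats]
    space = between_group_pca(X, groups, project={"individuals": X})
    order = space.group_labels

    # species-mean features in tree-tip order for K, PGLS, ancestors
    gidx = {g: i for i, g in enumerate(order)}
    species_means = np.stack(
        [X[np.array(groups) == t].mean(axis=0) for t in tips]
    )
    node_ids, anc = ancestral_states(tree, species_means, tip_order=tips)
    anc_scores = space.project(anc)
    space.projected["ancestors"] = anc_scores

    pgls = pgls_categorical(
        species_means, tree, [diet.loc[t] for t in tips],
        n_perm=config.n_perm, seed=config.seed,
    )

    mutant_groups = [g for g in order if g not in set(tips)]
    hulls = None
    if len(mutant_groups) >= 3:
        scores_df = pd.DataFrame(space.scores[:, :2], index=order)
        hulls = hull_coverage(scores_df, mutant_groups, tips)

    _write(out_dir, "k_grid.csv", grid.table.set_index(["combo", "f"]))
    _write(out_dir, "pc_scores.csv",
           pd.DataFrame(space.scores, index=order,
                        columns=[f"PC{i+1}" for i in range(space.scores.shape[1])]))
    _write(out_dir, "ancestor_scores.csv",
           pd.DataFrame(anc_scores, index=node_ids,
                        columns=[f"PC{i+1}" for i in range(anc_scores.shape[1])]))
    manifest = _manifest(config, {
        "workflow": "phylo",
        "selected_model": {"combo": combo, "f": f, "k": float(best["k"])},
        "pgls": {k: (list(v) if isinstance(v, tuple) else v)
                 for k, v in pgls.items()},
        "variance_fractions": space.variance_fractions.tolist(),
    })
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return {
        "grid": grid,
        "selected": (combo, f),
        "morphospace": space,
        "ancestors": (node_ids, anc, anc_scores),
        "pgls": pgls,
        "hulls": hulls,
        "manifest": manifest,
    }
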