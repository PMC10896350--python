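"""Dataset filters and end-to-end orchestration.

The run proceeds as the analysis design dictates: (optional) ANI
dereplication -> core/accessory gene split -> defense-system prevalence
filter with the species gate (at least two retained systems) -> gain-loss
ancestral reconstruction of accessory gene families and of defense systems ->
per-branch gene-gain rates and defense branch states -> permutation-tested
Spearman association per system -> optional spacer-turnover stage. Every run
emits TSV reports, a structured run log and a provenance JSON (config hash,
seeds, package version); reruns from the same config and master seed produce
byte-identical report TSVs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as dfio
from .association import GainDefenseAssociation
from .flux import branch_gains, defense_branch_states
from .gainloss import DegenerateDataError, GainLossModel
from .simulate import SimulationConfig, simulate_dataset, write_dataset
from .spacers import cluster_spacers, spacer_turnover
from .tree import PhyloTree, read_newick

__all__ = [
    "PipelineConfig",
    "InvalidInputError",
    "DegenerateGateError",
    "dereplicate_by_ani",
    "filter_defense_prevalence",
    "filter_core_genes",
    "run_all",
]

logger = logging.getLogger(__name__)


class InvalidInputError(ValueError):
    """Malformed or inconsistent inputs (CLI exit code 2)."""


class DegenerateGateError(RuntimeError):
    """Dataset fails a degeneracy gate, e.g. fewer than two retained defense
    systems or an empty accessory set (CLI exit code 3)."""


@dataclass
class PipelineConfig:
    """End-to-end run configuration (filters, thresholds, seeds)."""

    # either simulation ...
    simulation: SimulationConfig | None = None
    # ... or explicit input paths
    tree_path: str | None = None
    matrix_path: str | None = None
    defense_path: str | None = None
    ani_path: str | None = None
    spacer_path: str | None = None

    core_threshold: float = 0.95
    defense_window: tuple[float, float] = (0.20, 0.80)
    og_freq_window: tuple[float, float] = (0.10, 0.90)
    ani_threshold: float = 0.999
    min_defense_systems: int = 2
    n_perm: int = 10_000
    rho_threshold: float = 0.3
    p_threshold: float = 1e-4
    seed: int = 0
    run_spacer_stage: bool = True

    def __post_init__(self) -> None:
        for name in ("core_threshold", "ani_threshold"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise InvalidInputError(f"{name} must lie in (0, 1)")
        for name in ("defense_window", "og_freq_window"):
            lo, hi = getattr(self, name)
            if not (0 < lo < hi < 1):
                raise InvalidInputError(f"{name} must be a well-ordered window in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulation", None)
        if sim is not None:
            sim = SimulationConfig(**sim)
        for key in ("defense_window", "og_freq_window"):
            if key in raw:
                raw[key] = tuple(raw[key])
        try:
            return cls(simulation=sim, **raw)
        except TypeError as exc:
            raise InvalidInputError(f"bad config key: {exc}") from exc

    def digest(self) -> str:
        d = dataclasses.asdict(self)
        return hashlib.sha256(
            json.dumps(d, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


# ------------------------------------------------------------------ filters


def dereplicate_by_ani(
    ani: pd.DataFrame, threshold: float = 0.999
) -> tuple[list[str], dict[str, list[str]]]:
    """Single-linkage dereplication at an ANI cutoff.

    Genomes joined by any chain of pairs with ANI >= threshold collapse into
    one cluster; the representative is the lexicographically smallest ID.
    Conflicting asymmetric entries (A-B and B-A differing) are an error.
    """
    seen: dict[tuple[str, str], float] = {}
    for _, row in ani.iterrows():
        a, b = str(row["genome_a"]), str(row["genome_b"])
        if a == b:
            continue
        key = (min(a, b), max(a, b))
        v = float(row["ani"])
        if key in seen and abs(seen[key] - v) > 1e-9:
            raise InvalidInputError(
                f"conflicting ANI entries for pair {key}: {seen[key]} vs {v}"
            )
        seen[key] = v
    genomes = sorted({g for pair in seen for g in pair})
    parent = {g: g for g in genomes}

    def find(g: str) -> str:
        while parent[g] != g:
            parent[g] = parent[parent[g]]
            g = parent[g]
        return g

    for (a, b), v in seen.items():
        if v >= threshold:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)
    clusters: dict[str, list[str]] = {}
    for g in genomes:
        clusters.setdefault(find(g), []).append(g)
    reps = sorted(clusters)
    return reps, {r: sorted(ms) for r, ms in clusters.items()}


def filter_defense_prevalence(
    defense_table: pd.DataFrame, window: tuple[float, float] = (0.20, 0.80)
) -> list[str]:
    """Defense systems whose genome prevalence lies in the closed window."""
    lo, hi = window
    prev = defense_table.mean(axis=0)
    return [s for s in defense_table.columns if lo <= prev[s] <= hi]


def filter_core_genes(
    matrix: pd.DataFrame, threshold: float = 0.95
) -> tuple[list[str], list[str]]:
    """Partition gene families into (core, accessory) by prevalence >= threshold."""
    prev = matrix.mean(axis=0)
    core = [og for og in matrix.columns if prev[og] >= threshold]
    accessory = [og for og in matrix.columns if prev[og] < threshold]
    return core, accessory


# ------------------------------------------------------------------ run-all


def _load_inputs(config: PipelineConfig):
    if config.simulation is not None:
        ds = simulate_dataset(config.simulation)
        return ds.tree, ds.matrix, ds.defense_table, ds.spacers, ds
    if not (config.tree_path and config.matrix_path and config.defense_path):
        raise InvalidInputError("need either a simulation config or tree/matrix/defense paths")
    tree = read_newick(Path(config.tree_path).read_text())
    matrix = dfio.read_presence_absence(config.matrix_path)
    defense = dfio.read_presence_absence(config.defense_path)
    if config.ani_path:
        reps, _ = dereplicate_by_ani(
            dfio.read_ani_table(config.ani_path), config.ani_threshold
        )
        keep = [g for g in matrix.index if g in set(reps)]
        matrix = matrix.loc[keep]
        defense = defense.loc[[g for g in defense.index if g in set(reps)]]
    missing = [t for t in tree.tip_labels if t not in matrix.index]
    if missing:
        raise InvalidInputError(f"tree tips absent from matrix: {missing[:10]}")
    spacers = dfio.read_spacer_fasta(config.spacer_path) if config.spacer_path else None
    return tree, matrix, defense, spacers, None


def run_all(config: PipelineConfig, outdir: str | Path) -> dict[str, Path]:
    """Execute the full pipeline; returns the emitted report paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    run_id = config.digest()
    log_path = outdir / "run.log"
    stages: list[str] = []

    def stage(name: str, t0: float) -> None:
        line = f"run={run_id} stage={name} elapsed={time.perf_counter() - t0:.2f}s"
        logger.info(line)
        stages.append(line)

    t0 = time.perf_counter()
    tree, matrix, defense, spacer_arrays, dataset = _load_inputs(config)
    if dataset is not None:
        write_dataset(dataset, outdir / "inputs")
    stage("load", t0)

    t0 = time.perf_counter()
    core, accessory = filter_core_genes(matrix, config.core_threshold)
    if not accessory:
        raise DegenerateGateError("no accessory gene families: association stage halted")
    retained_systems = filter_defense_prevalence(defense, config.defense_window)
    if len(retained_systems) < config.min_defense_systems:
        raise DegenerateGateError(
            f"only {len(retained_systems)} defense system(s) in the "
            f"{config.defense_window} prevalence window; "
            f"need >= {config.min_defense_systems}"
        )
    stage("filter", t0)

    paths: dict[str, Path] = {}
    t0 = time.perf_counter()
    try:
        og_res = GainLossModel(tree, matrix[accessory]).fit()
        def_res = GainLossModel(tree, defense[retained_systems]).fit()
    except DegenerateDataError as exc:
        raise DegenerateGateError(str(exc)) from exc
    og_states = og_res.ancestral_probabilities()
    def_states = def_res.ancestral_probabilities()
    paths["og_states"] = outdir / "og_ancestral_states.tsv"
    paths["defense_states_nodes"] = outdir / "defense_ancestral_states.tsv"
    og_res.to_tsv(paths["og_states"])
    def_res.to_tsv(paths["defense_states_nodes"])
    stage("reconstruct", t0)

    t0 = time.perf_counter()
    flux = branch_gains(og_states, tree)
    dstates = defense_branch_states(def_states, tree)
    paths["flux"] = outdir / "branch_flux.tsv"
    paths["defense_states"] = outdir / "defense_branch_states.tsv"
    flux.to_csv(paths["flux"], sep="\t", float_format="%.6f")
    dstates.to_csv(paths["defense_states"], sep="\t", float_format="%.6f")
    stage("flux", t0)

    t0 = time.perf_counter()
    assoc = GainDefenseAssociation(flux, dstates).fit(
        n_perm=config.n_perm,
        seed=config.seed,
        rho_threshold=config.rho_threshold,
        p_threshold=config.p_threshold,
    )
    paths["association"] = outdir / "association.tsv"
    assoc.to_tsv(paths["association"])
    stage("associate", t0)

    if config.run_spacer_stage and spacer_arrays:
        t0 = time.perf_counter()
        clusters, _ = cluster_spacers(spacer_arrays)
        turnover = spacer_turnover(tree, clusters)
        paths["turnover"] = outdir / "spacer_turnover.tsv"
        turnover.to_csv(paths["turnover"], sep="\t", index=False, float_format="%.6f")
        stage("spacers", t0)

    provenance = {
        "run_id": run_id,
        "package": "defenseflux",
        "version": __version__,
        "seed": config.seed,
        "config": json.loads(json.dumps(dataclasses.asdict(config), default=str)),
        "n_genomes": int(matrix.shape[0]),
        "n_core": len(core),
        "n_accessory": len(accessory),
        "retained_systems": retained_systems,
        "gain_rate": og_res.gain_rate,
        "loss_rate": og_res.loss_rate,
    }
    paths["provenance"] = outdir / "provenance.json"
    paths["provenance"].write_text(json.dumps(provenance, indent=2, sort_keys=True) + "\n")
    log_path.write_text("\n".join(stages) + "\n")
    paths["log"] = log_path
    return paths
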