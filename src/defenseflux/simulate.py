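"""Synthetic datasets with known ground truth for the whole pipeline.

The generator emulates the study design end to end: a clocklike (Yule)
species tree scaled to root height 1; binary defense systems evolving by a
gain-loss chain; accessory gene content whose per-branch gain rate is
modulated multiplicatively by the defense state (``base * m**s_b`` with the
branch state ``s_b`` the endpoint average of the true node states, matching
the inference-side definition — ``m < 1`` means defense inhibits gene gain
and ``m = 1`` is exactly "no effect"); CRISPR spacer arrays with Poisson
acquisition and exponential loss of unique random 32-mers; and circular
genome layouts where defense genes sit inside mobile-element islands together
with cargo genes while background genes are placed uniformly.

Every generator is deterministic given ``(config, seed)``. True node states
and true per-branch gain-event counts are returned alongside the tip data, so
inference can be checked against ground truth.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as dfio
from .tree import PhyloTree

__all__ = [
    "IslandSpec",
    "SimulationConfig",
    "SyntheticDataset",
    "simulate_tree",
    "simulate_binary_trait",
    "simulate_gene_content",
    "simulate_spacer_arrays",
    "simulate_genome_layout",
    "simulate_dataset",
    "write_dataset",
]

ALPHABET = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class IslandSpec:
    """A mobile-element island: a window on the chromosome holding a defense
    system's genes plus cargo genes."""

    name: str
    center: int
    width: int = 20_000
    defense_system: str | None = None
    cargo_ogs: tuple[str, ...] = ()


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study.

    Defaults describe one species-scale dataset: 200 genomes, two defense
    systems at stationary prevalence 0.5 (inside the 20-80% analysis window),
    400 accessory gene families with stationary prevalence 1/3, and a strong
    inhibitory defense effect (``m = 0.2``) on the first system only.
    """

    n_tips: int = 200
    birth_rate: float = 1.0
    seed: int = 0
    # defense systems
    n_defense_systems: int = 2
    defense_gain: float = 1.0
    defense_loss: float = 1.0
    effect_multiplier: float = 0.2  # applies to system DS1; others neutral
    # accessory gene content
    n_accessory_ogs: int = 400
    base_gain_rate: float = 0.5
    og_loss_rate: float = 1.0
    # spacer arrays
    spacer_acquisition: float = 30.0
    spacer_loss: float = 1.0
    spacer_length: int = 32
    # genome layout
    chromosome_length: int = 2_000_000
    gene_length: int = 1_000
    islands: tuple[IslandSpec, ...] | None = None
    defense_genes_per_system: int = 2

    def __post_init__(self) -> None:
        for name in (
            "birth_rate",
            "defense_gain",
            "defense_loss",
            "base_gain_rate",
            "og_loss_rate",
            "spacer_acquisition",
            "spacer_loss",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.effect_multiplier <= 0:
            raise ValueError("effect_multiplier must be positive")
        if self.islands is None:
            cargo = tuple(f"OG{i:04d}" for i in range(1, 11))
            self.islands = (
                IslandSpec(
                    name="island1",
                    center=self.chromosome_length // 4,
                    width=20_000,
                    defense_system="DS1",
                    cargo_ogs=cargo,
                ),
            )

    @property
    def system_ids(self) -> list[str]:
        return [f"DS{i + 1}" for i in range(self.n_defense_systems)]

    def multiplier_for(self, system: str) -> float:
        return self.effect_multiplier if system == "DS1" else 1.0


@dataclass
class SyntheticDataset:
    """A complete simulated input bundle plus its ground truth."""

    tree: PhyloTree
    defense_node_states: pd.DataFrame  # nodes x systems, true 0/1 states
    defense_table: pd.DataFrame  # tips x systems
    og_node_states: np.ndarray  # (n_nodes, n_ogs) true 0/1 states
    matrix: pd.DataFrame  # tips x OGs
    true_branch_gains: pd.Series  # child node ID -> gain-event count
    spacers: dict[str, list[str]]
    layouts: dict[str, pd.DataFrame]
    config: SimulationConfig

    @property
    def og_ids(self) -> list[str]:
        return list(self.matrix.columns)


# ----------------------------------------------------------------- tree


def simulate_tree(n_tips: int, birth_rate: float = 1.0, seed=0) -> PhyloTree:
    """Yule tree with ``n_tips`` leaves, ultrametric, scaled to root height 1."""
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    rng = np.random.default_rng(seed)
    # pure-birth process started from the root split: 2 lineages at time 0
    children: dict[int, list[int]] = {0: [1, 2], 1: [], 2: []}
    birth_time = {0: 0.0, 1: 0.0, 2: 0.0}
    active = [1, 2]
    t = 0.0
    next_id = 3
    while len(active) < n_tips:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        j = int(rng.integers(len(active)))
        node = active[j]
        a, b = next_id, next_id + 1
        next_id += 2
        children[node] = [a, b]
        children[a] = []
        children[b] = []
        birth_time[a] = birth_time[b] = t
        active[j] = a
        active.append(b)
    t += rng.exponential(1.0 / (birth_rate * n_tips))
    height = t

    # preorder arrays; tips end at `height`, then scale root height to 1
    parent_l: list[int] = []
    length_l: list[float] = []
    order: list[int] = []
    stack = [(0, -1)]
    while stack:
        node, par = stack.pop()
        my_id = len(order)
        order.append(node)
        parent_l.append(par)
        end = height if not children[node] else birth_time[children[node][0]]
        start = birth_time[node]
        length_l.append((end - start) / height)
        for ch in reversed(children[node]):
            stack.append((ch, my_id))
    labels: list[str | None] = [None] * len(order)
    k = 1
    for i, node in enumerate(order):
        if not children[node]:
            labels[i] = f"G{k:04d}"
            k += 1
    return PhyloTree(parent_l, length_l, labels)


# ------------------------------------------------------- binary traits


def _branch_probs(gain: float, loss: float, t: np.ndarray):
    """(p01, p10) per branch, handling the all-rates-zero degenerate case."""
    r = gain + loss
    if r == 0:
        z = np.zeros_like(t)
        return z, z
    decay = np.exp(-r * t)
    return gain / r * (1 - decay), loss / r * (1 - decay)


def simulate_binary_trait(
    tree: PhyloTree, gain: float, loss: float, root_prob: float, rng
) -> np.ndarray:
    """Forward-simulate a gain-loss trait; returns true states at ALL nodes."""
    rng = np.random.default_rng(rng)
    p01, p10 = _branch_probs(gain, loss, tree.lengths)
    states = np.zeros(tree.n_nodes, dtype=np.int8)
    states[0] = rng.random() < root_prob
    u = rng.random(tree.n_nodes)
    for v in range(1, tree.n_nodes):
        s = states[tree.parent[v]]
        p_one = p01[v] if s == 0 else 1.0 - p10[v]
        states[v] = u[v] < p_one
    return states


def simulate_gene_content(
    tree: PhyloTree,
    defense_branch_state: np.ndarray,
    n_ogs: int,
    base_gain_rate: float,
    og_loss_rate: float,
    effect_multiplier: float | np.ndarray,
    rng,
    root_prob: float | None = None,
) -> tuple[pd.DataFrame, np.ndarray, pd.Series]:
    """Accessory gene families evolving with defense-modulated gain rates.

    Parameters
    ----------
    defense_branch_state
        Per-node array; entry ``v`` is the true defense branch state
        ``(s_parent + s_v)/2`` of the branch above node ``v`` (entry 0 unused).
        May already combine several systems.
    effect_multiplier
        Scalar ``m``: the gain rate on a branch is ``base * m**s_b``. An array
        of per-branch multipliers is also accepted.

    Returns ``(tip_matrix, node_states, true_branch_gains)`` where the gains
    count actual 0->1 events per branch summed over gene families.
    """
    rng = np.random.default_rng(rng)
    n = tree.n_nodes
    if root_prob is None:
        tot = base_gain_rate + og_loss_rate
        root_prob = base_gain_rate / tot if tot > 0 else 0.0
    gain_b = base_gain_rate * np.asarray(effect_multiplier, dtype=float) ** np.asarray(
        defense_branch_state, dtype=float
    )
    gain_b = np.broadcast_to(gain_b, (n,)).copy()

    states = np.zeros((n, n_ogs), dtype=np.int8)
    states[0] = rng.random(n_ogs) < root_prob
    gains = np.zeros(n, dtype=np.int64)
    for v in range(1, n):
        cur = states[tree.parent[v]].copy()
        t_total = tree.lengths[v]
        g, l = gain_b[v], og_loss_rate
        elapsed = np.zeros(n_ogs)
        alive = np.ones(n_ogs, dtype=bool)
        while alive.any():
            idx = np.flatnonzero(alive)
            rates = np.where(cur[idx] == 0, g, l)
            with np.errstate(divide="ignore"):
                dt = rng.exponential(np.where(rates > 0, 1.0 / np.maximum(rates, 1e-300), np.inf))
            dt[rates == 0] = np.inf
            elapsed[idx] += dt
            flip = idx[elapsed[idx] <= t_total]
            gains[v] += int(np.count_nonzero(cur[flip] == 0))
            cur[flip] ^= 1
            alive[:] = False
            alive[flip] = True
        states[v] = cur
    og_ids = [f"OG{i + 1:04d}" for i in range(n_ogs)]
    tip_rows = states[tree.tip_ids]
    matrix = pd.DataFrame(tip_rows, index=pd.Index(tree.tip_labels, name="genome"), columns=og_ids)
    true_gains = pd.Series(
        gains[1:], index=pd.Index(np.arange(1, n), name="child_node"), name="true_gain"
    )
    return matrix, states, true_gains


# ------------------------------------------------------------ spacers


def _random_spacer(rng, length: int) -> str:
    return bytes(ALPHABET[rng.integers(0, 4, size=length)]).decode()


def simulate_spacer_arrays(
    tree: PhyloTree,
    acquisition_rate: float,
    loss_rate: float,
    seed=0,
    spacer_length: int = 32,
    n_root: int | None = None,
) -> dict[str, list[str]]:
    """Spacer arrays per tip: unique 32-mers acquired (Poisson along branches)
    and lost (exponential survival); descendants inherit surviving spacers.

    ``n_root`` defaults to a Poisson draw at the acquisition/loss stationary
    mean (0 when loss is 0 or acquisition is 0).
    """
    rng = np.random.default_rng(seed)
    if n_root is None:
        if loss_rate > 0 and acquisition_rate > 0:
            n_root = int(rng.poisson(acquisition_rate / loss_rate))
        else:
            n_root = 0
    arrays: list[list[str]] = [[] for _ in range(tree.n_nodes)]
    arrays[0] = [_random_spacer(rng, spacer_length) for _ in range(n_root)]
    for v in range(1, tree.n_nodes):
        t = tree.lengths[v]
        inherited = [
            s
            for s in arrays[tree.parent[v]]
            if rng.random() < (np.exp(-loss_rate * t) if loss_rate > 0 else 1.0)
        ]
        n_new = rng.poisson(acquisition_rate * t)
        for _ in range(n_new):
            u = rng.uniform(0.0, t)  # acquisition time along the branch
            if loss_rate == 0 or rng.random() < np.exp(-loss_rate * (t - u)):
                inherited.append(_random_spacer(rng, spacer_length))
        arrays[v] = inherited
    return {tree.tip_labels[i]: arrays[tip] for i, tip in enumerate(tree.tip_ids)}


# ------------------------------------------------------------- layouts


def simulate_genome_layout(
    matrix: pd.DataFrame,
    defense_table: pd.DataFrame,
    islands: Sequence[IslandSpec],
    chromosome_length: int,
    seed=0,
    gene_length: int = 1_000,
    defense_genes_per_system: int = 2,
) -> dict[str, pd.DataFrame]:
    """Circular gene coordinates per genome.

    Island cargo genes and defense genes land inside their island window;
    every other gene family present in a genome is placed uniformly on the
    chromosome. Coordinates are starts of ``gene_length``-bp genes, 0-based
    half-open, wrapped circularly.
    """
    for isl in islands:
        if isl.width > chromosome_length:
            raise ValueError(f"island {isl.name} larger than the chromosome")
    rng = np.random.default_rng(seed)
    og_island: dict[str, IslandSpec] = {}
    for isl in islands:
        for og in isl.cargo_ogs:
            og_island[og] = isl
    layouts: dict[str, pd.DataFrame] = {}
    L = chromosome_length
    for genome in matrix.index:
        rows = []

        def place(og_id: str, isl: IslandSpec | None) -> None:
            if isl is None:
                start = int(rng.integers(0, L))
            else:
                lo = isl.center - isl.width // 2
                start = int(lo + rng.integers(0, max(isl.width - gene_length, 1))) % L
            rows.append(
                {
                    "genome": genome,
                    "replicon": "chromosome",
                    "start": start,
                    "end": start + gene_length,
                    "strand": "+" if rng.random() < 0.5 else "-",
                    "og_id": og_id,
                }
            )

        for system in defense_table.columns:
            if defense_table.at[genome, system]:
                isl = next(
                    (i for i in islands if i.defense_system == system), None
                )
                for k in range(defense_genes_per_system):
                    place(f"{system}__g{k + 1}", isl)
        present = matrix.columns[matrix.loc[genome].to_numpy(dtype=bool)]
        for og in present:
            place(og, og_island.get(og))
        layouts[genome] = pd.DataFrame(rows, columns=dfio.COORD_COLUMNS)
    return layouts


# ---------------------------------------------------------- full bundle


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate the full input bundle (tree, traits, spacers, layouts)."""
    root_seq = np.random.SeedSequence(config.seed)
    seeds = root_seq.spawn(5)
    tree = simulate_tree(config.n_tips, config.birth_rate, seeds[0])

    rng_def = np.random.default_rng(seeds[1])
    tot = config.defense_gain + config.defense_loss
    root_prob = config.defense_gain / tot if tot > 0 else 0.0
    def_states = {}
    for system in config.system_ids:
        def_states[system] = simulate_binary_trait(
            tree, config.defense_gain, config.defense_loss, root_prob, rng_def
        )
    defense_node_states = pd.DataFrame(def_states)
    defense_node_states.index.name = "node_id"
    defense_table = defense_node_states.iloc[tree.tip_ids].set_index(
        pd.Index(tree.tip_labels, name="genome")
    )

    # combined multiplicative defense effect per branch (entry v = branch above v)
    child = np.arange(1, tree.n_nodes)
    log_mult = np.zeros(tree.n_nodes)
    for system in config.system_ids:
        s = def_states[system].astype(float)
        s_b = np.zeros(tree.n_nodes)
        s_b[child] = 0.5 * (s[tree.parent[child]] + s[child])
        log_mult += s_b * np.log(config.multiplier_for(system))
    matrix, og_states, true_gains = simulate_gene_content(
        tree,
        defense_branch_state=np.ones(tree.n_nodes),  # exponent folded below
        n_ogs=config.n_accessory_ogs,
        base_gain_rate=config.base_gain_rate,
        og_loss_rate=config.og_loss_rate,
        effect_multiplier=np.exp(log_mult),
        rng=np.random.default_rng(seeds[2]),
    )

    spacers = simulate_spacer_arrays(
        tree,
        config.spacer_acquisition,
        config.spacer_loss,
        seed=seeds[3],
        spacer_length=config.spacer_length,
    )
    layouts = simulate_genome_layout(
        matrix,
        defense_table,
        config.islands,
        config.chromosome_length,
        seed=seeds[4],
        gene_length=config.gene_length,
        defense_genes_per_system=config.defense_genes_per_system,
    )
    return SyntheticDataset(
        tree=tree,
        defense_node_states=defense_node_states,
        defense_table=defense_table,
        og_node_states=og_states,
        matrix=matrix,
        true_branch_gains=true_gains,
        spacers=spacers,
        layouts=layouts,
        config=config,
    )


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the bundle in the pipeline's input formats, plus provenance JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "tree": outdir / "species_tree.nwk",
        "matrix": outdir / "gene_presence_absence.tsv",
        "defense": outdir / "defense_systems.tsv",
        "spacers": outdir / "spacers.fasta",
        "coords": outdir / "gene_coords.tsv",
        "provenance": outdir / "provenance.json",
    }
    paths["tree"].write_text(dataset.tree.to_newick() + "\n")
    dfio.write_presence_absence(dataset.matrix, paths["matrix"])
    dfio.write_presence_absence(dataset.defense_table, paths["defense"])
    dfio.write_spacer_fasta(dataset.spacers, paths["spacers"])
    coords = pd.concat(
        [dataset.layouts[g] for g in sorted(dataset.layouts)], ignore_index=True
    )
    dfio.write_gene_coords(coords, paths["coords"])
    cfg = dataclasses.asdict(dataset.config)
    cfg["islands"] = [dataclasses.asdict(i) for i in dataset.config.islands]
    paths["provenance"].write_text(
        json.dumps({"generator": "defenseflux.simulate", "config": cfg}, indent=2, sort_keys=True)
        + "\n"
    )
    return paths
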