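"""Genome-level comparisons and phylogenetic profiling.

Four pieces of machinery:

* Mann-Whitney U contrasts of per-genome gene counts between carrier and
  non-carrier groups (exact enumeration for small tie-free samples, normal
  approximation with continuity correction otherwise);
* the Fritz-Purvis D statistic for phylogenetic signal in a binary trait,
  with its two simulation nulls — tip-label shuffles (D ~ 1) and
  prevalence-matched thresholded Brownian motion (D ~ 0) — and the
  strict-inequality trait filters built on it;
* observed-vs-expected co-occurrence of trait pairs in genomes, tested with a
  one-sided binomial tail under independence and Bonferroni-corrected;
* genomic colocalization: the median (over genomes) minimum circular
  distance between a defense system's genes and an orthologous group's genes,
  against an empirical null of randomly sampled chromosomal gene families.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .tree import PhyloTree

__all__ = [
    "DStatResult",
    "ColocalizationResult",
    "DegenerateTraitError",
    "mann_whitney",
    "fritz_purvis_d",
    "fritz_purvis_d_many",
    "filter_traits_by_d",
    "cooccurrence_test",
    "ogs_associated_with_system",
    "circular_distance",
    "colocalization_test",
]

logger = logging.getLogger(__name__)

OG_D_THRESHOLD = -0.2
DEFENSE_D_THRESHOLD = 0.2
FREQ_WINDOW = (0.10, 0.90)


class DegenerateTraitError(ValueError):
    """Raised for monomorphic traits, for which D (or a contrast) is undefined."""


@dataclass(frozen=True)
class DStatResult:
    """Fritz-Purvis D for one binary trait. D ~ 1 for phylogenetically random
    traits, D ~ 0 for traits evolving like thresholded Brownian motion."""

    trait_id: str
    D: float
    n_perm: int
    s_obs: float


@dataclass(frozen=True)
class ColocalizationResult:
    """Median genomic distance of a (defense system, OG) pair vs a sampling null."""

    system_id: str
    og_id: str
    median_distance: float
    p_value: float
    n_null_samples: int
    n_genomes: int
    computable: bool = True


# ------------------------------------------------------------ Mann-Whitney


def mann_whitney(group_a, group_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U (U statistic of ``group_a``, p-value).

    Exact enumeration for small tie-free samples (both n <= 20), otherwise
    the tie-corrected normal approximation with continuity correction.
    """
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (a.size <= 20 and b.size <= 20 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


# --------------------------------------------------------- Fritz-Purvis D


def _change_sums(tree: PhyloTree, tip_values: np.ndarray) -> np.ndarray:
    """Sum over branches of |nodal estimate difference|, per trait column.

    Nodal values are estimated bottom-up as the unweighted mean of the
    daughters' values; ``tip_values`` has shape (n_tips, C).
    """
    n = tree.n_nodes
    vals = np.zeros((n, tip_values.shape[1]))
    tip_pos = {int(node): k for k, node in enumerate(tree.tip_ids)}
    for v in tree.postorder():
        if tree.is_tip(v):
            vals[v] = tip_values[tip_pos[v]]
        else:
            vals[v] = np.mean([vals[c] for c in tree.children[v]], axis=0)
    child = np.arange(1, n)
    return np.abs(vals[child] - vals[tree.parent[child]]).sum(axis=0)


def _brownian_tips(tree: PhyloTree, n_draws: int, rng) -> np.ndarray:
    """Tip values of standard Brownian motion on the tree, (n_tips, n_draws)."""
    n = tree.n_nodes
    x = np.zeros((n, n_draws))
    incr = rng.standard_normal((n, n_draws)) * np.sqrt(tree.lengths)[:, None]
    for v in range(1, n):
        x[v] = x[tree.parent[v]] + incr[v]
    return x[tree.tip_ids]


def fritz_purvis_d(
    tree: PhyloTree,
    trait,
    n_perm: int = 1000,
    seed=0,
    trait_id: str = "trait",
) -> DStatResult:
    """Fritz-Purvis D of a binary tip trait.

    ``D = (S_obs - mean S_brownian) / (mean S_random - mean S_brownian)``
    where S is the sum of changes in nodal trait estimates across branches,
    the random null shuffles tip labels and the Brownian null thresholds
    simulated Brownian tip values at the observed prevalence.
    """
    y = np.asarray(trait, dtype=np.float64)
    if y.size != tree.n_tips:
        raise ValueError("trait length must equal the number of tips")
    k = int(y.sum())
    if k == 0 or k == y.size:
        raise DegenerateTraitError(f"trait {trait_id!r} is monomorphic")
    rng = np.random.default_rng(seed)
    s_obs = float(_change_sums(tree, y[:, None])[0])

    keys = rng.random((y.size, n_perm))
    shuffled = y[np.argsort(keys, axis=0)]
    s_rand = _change_sums(tree, shuffled)

    bm = _brownian_tips(tree, n_perm, rng)
    # threshold at observed prevalence: the k largest tips carry the trait
    order = np.argsort(-bm, axis=0)
    thresh = np.zeros_like(bm)
    np.put_along_axis(thresh, order[:k], 1.0, axis=0)
    s_brown = _change_sums(tree, thresh)

    denom = s_rand.mean() - s_brown.mean()
    if abs(denom) < 1e-12:
        raise DegenerateTraitError(f"trait {trait_id!r}: degenerate null separation")
    d = (s_obs - s_brown.mean()) / denom
    return DStatResult(trait_id=trait_id, D=float(d), n_perm=n_perm, s_obs=s_obs)


def fritz_purvis_d_many(
    tree: PhyloTree,
    matrix: pd.DataFrame,
    n_perm: int = 1000,
    seed=0,
) -> dict[str, DStatResult]:
    """D for every non-monomorphic column of a genomes x traits matrix."""
    data = matrix.loc[tree.tip_labels]
    out: dict[str, DStatResult] = {}
    base = np.random.SeedSequence(entropy=seed if isinstance(seed, int) else 0)
    for idx, col in enumerate(data.columns):
        try:
            out[col] = fritz_purvis_d(
                tree,
                data[col].to_numpy(),
                n_perm=n_perm,
                seed=np.random.SeedSequence(entropy=base.entropy, spawn_key=(idx,)),
                trait_id=str(col),
            )
        except DegenerateTraitError:
            logger.warning("trait %s monomorphic: D not computed", col)
    return out


def filter_traits_by_d(
    og_results: Mapping[str, DStatResult],
    defense_results: Mapping[str, DStatResult],
    og_threshold: float = OG_D_THRESHOLD,
    defense_threshold: float = DEFENSE_D_THRESHOLD,
) -> tuple[set[str], set[str]]:
    """Retain OGs with D strictly above ``og_threshold`` and defense systems
    with D strictly above ``defense_threshold`` (boundaries excluded)."""
    ogs = {t for t, r in og_results.items() if r.D > og_threshold}
    systems = {t for t, r in defense_results.items() if r.D > defense_threshold}
    return ogs, systems


# ----------------------------------------------------------- co-occurrence


def cooccurrence_test(
    matrix: pd.DataFrame,
    pairs: Sequence[tuple[str, str]],
    alpha: float = 0.05,
    freq_window: tuple[float, float] = FREQ_WINDOW,
) -> pd.DataFrame:
    """Observed vs expected co-occurrence of trait pairs across genomes.

    For each pair the observed count O of genomes carrying both traits is
    compared with the independence expectation ``E = n * f_a * f_b`` via the
    one-sided binomial tail ``P(X >= O | n, f_a * f_b)``; Bonferroni
    correction is over the number of tested pairs. Pairs whose traits fall
    outside the frequency window are skipped with a warning.
    """
    n = matrix.shape[0]
    freq = matrix.mean(axis=0)
    lo, hi = freq_window
    kept: list[tuple[str, str]] = []
    for a, b in pairs:
        bad = [t for t in (a, b) if not (lo <= freq[t] <= hi)]
        if bad:
            logger.warning("pair (%s, %s): trait(s) %s outside frequency window, skipped", a, b, bad)
            continue
        kept.append((a, b))
    rows = []
    for a, b in kept:
        fa, fb = float(freq[a]), float(freq[b])
        obs = int(((matrix[a] == 1) & (matrix[b] == 1)).sum())
        p = float(stats.binom.sf(obs - 1, n, fa * fb))
        rows.append(
            {
                "trait_a": a,
                "trait_b": b,
                "observed": obs,
                "expected": n * fa * fb,
                "p_value": p,
            }
        )
    out = pd.DataFrame(
        rows, columns=["trait_a", "trait_b", "observed", "expected", "p_value"]
    )
    m = len(out)
    out["p_adjusted"] = np.minimum(out["p_value"] * max(m, 1), 1.0)
    out["significant"] = out["p_adjusted"] < alpha
    return out.sort_values("p_adjusted", kind="stable").reset_index(drop=True)


def ogs_associated_with_system(
    matrix: pd.DataFrame,
    system_genes: Sequence[str],
    og_ids: Sequence[str],
    alpha: float = 0.05,
    freq_window: tuple[float, float] = FREQ_WINDOW,
) -> list[str]:
    """OGs significantly co-occurring with EVERY gene of a multi-gene system."""
    pairs = [(og, gene) for og in og_ids for gene in system_genes]
    res = cooccurrence_test(matrix, pairs, alpha=alpha, freq_window=freq_window)
    hits = res[res["significant"]]
    out = []
    for og in og_ids:
        sig_genes = set(hits.loc[hits["trait_a"] == og, "trait_b"])
        if set(system_genes) <= sig_genes:
            out.append(og)
    return out


# --------------------------------------------------------- colocalization


def circular_distance(a: float, b: float, length: float) -> float:
    """Shortest distance between two positions on a circular replicon."""
    d = abs(a - b) % length
    return min(d, length - d)


def _min_circular_distance(pos_a: np.ndarray, pos_b: np.ndarray, length: float) -> float:
    d = np.abs(pos_a[:, None] - pos_b[None, :]) % length
    return float(np.minimum(d, length - d).min())


def colocalization_test(
    layouts: Mapping[str, pd.DataFrame],
    chromosome_length: float,
    system_ogs: Sequence[str],
    target_og: str,
    n_samples: int = 1000,
    seed=0,
    null_pool: Sequence[str] | None = None,
    system_id: str = "system",
) -> ColocalizationResult:
    """Median genomic distance between a defense system and an OG vs chance.

    The observed statistic is the median over genomes (carrying both) of the
    minimum circular start-to-start distance between any system gene and any
    OG member gene on the chromosome. The null repeats the statistic for
    ``n_samples`` gene families sampled uniformly from the chromosomal pool;
    the empirical p-value is ``(k+1)/(n_samples+1)`` with k the number of
    null medians at most the observed one.
    """
    rng = np.random.default_rng(seed)
    sys_set = set(system_ogs)
    # per-genome chromosomal gene-start positions by og
    sys_pos: dict[str, np.ndarray] = {}
    og_pos: dict[str, dict[str, np.ndarray]] = {}
    for genome, df in layouts.items():
        chrom = df[df["replicon"] == "chromosome"]
        sp = chrom.loc[chrom["og_id"].isin(sys_set), "start"].to_numpy(float)
        if sp.size:
            sys_pos[genome] = sp
        for og, grp in chrom.groupby("og_id"):
            og_pos.setdefault(og, {})[genome] = grp["start"].to_numpy(float)

    def median_stat(og: str) -> float | None:
        carriers = [g for g in sys_pos if g in og_pos.get(og, {})]
        if not carriers:
            return None
        dists = [
            _min_circular_distance(sys_pos[g], og_pos[og][g], chromosome_length)
            for g in carriers
        ]
        return float(np.median(dists))

    observed = median_stat(target_og)
    if observed is None:
        return ColocalizationResult(
            system_id, target_og, float("nan"), float("nan"), n_samples, 0, False
        )
    n_genomes = sum(1 for g in sys_pos if g in og_pos.get(target_og, {}))

    if null_pool is None:
        null_pool = sorted(
            og
            for og, carriers in og_pos.items()
            if og not in sys_set
            and og != target_og
            and any(g in sys_pos for g in carriers)
        )
    if not null_pool:
        raise ValueError("empty null pool: no chromosomal OGs co-occur with the system")
    draws = rng.choice(len(null_pool), size=n_samples, replace=True)
    k = 0
    cache: dict[int, float] = {}
    for j in draws:
        if j not in cache:
            stat = median_stat(null_pool[j])
            cache[j] = np.inf if stat is None else stat
        if cache[j] <= observed:
            k += 1
    p = (k + 1) / (n_samples + 1)
    return ColocalizationResult(
        system_id, target_og, observed, float(p), n_samples, n_genomes, True
    )
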