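"""Per-branch gene-gain rates and defense-system branch states.

Ancestral presence probabilities are converted into the branch statistics the
association test consumes. For a branch from parent node *u* to child node
*v*:

* raw gain  ``G_b = sum over traits of max(0, p_v - p_u)`` — only positive
  probability increments count; losses are ignored;
* normalized gain ``g_b = G_b / max(length, eps)`` — gains per unit branch
  length, with a small floor ``eps`` guarding the zero-length branches that
  occur in real core-genome trees;
* defense branch state ``s_b = (p_u + p_v) / 2`` — the average of the
  ancestral and descendant presence probabilities of a defense system.

The root has no incoming branch and contributes nothing; a rooted binary tree
with *n* tips yields ``2n - 2`` branch rows. Gains are probability mass, not
integer event counts — no rounding anywhere.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .tree import PhyloTree

__all__ = ["branch_gains", "defense_branch_states", "BRANCH_LENGTH_FLOOR"]

BRANCH_LENGTH_FLOOR = 1e-6


def _check_nodes(states: pd.DataFrame, tree: PhyloTree) -> None:
    needed = set(range(tree.n_nodes))
    have = set(int(i) for i in states.index)
    missing = sorted(needed - have)
    if missing:
        raise ValueError(f"states missing for node IDs: {missing[:10]}")


def branch_gains(
    states: pd.DataFrame,
    tree: PhyloTree,
    eps: float = BRANCH_LENGTH_FLOOR,
) -> pd.DataFrame:
    """Per-branch raw and length-normalized gene gain from ancestral states.

    Parameters
    ----------
    states
        Presence probabilities, rows indexed by preorder node ID, one column
        per trait (as produced by ``GainLossResults.ancestral_probabilities``).
    tree
        The tree the node IDs refer to.
    eps
        Branch-length floor applied before division.

    Returns
    -------
    DataFrame indexed by child node ID with columns ``raw_gain``,
    ``branch_length`` and ``normalized_gain``, in preorder branch order.
    """
    _check_nodes(states, tree)
    probs = states.loc[np.arange(tree.n_nodes)].to_numpy(dtype=np.float64)
    child = np.arange(1, tree.n_nodes)
    parent = tree.parent[child]
    inc = probs[child] - probs[parent]
    raw = np.maximum(inc, 0.0).sum(axis=1)
    lengths = tree.lengths[child]
    norm = raw / np.maximum(lengths, eps)
    out = pd.DataFrame(
        {"raw_gain": raw, "branch_length": lengths, "normalized_gain": norm},
        index=pd.Index(child, name="child_node"),
    )
    return out


def defense_branch_states(states: pd.DataFrame, tree: PhyloTree) -> pd.DataFrame:
    """Average of ancestral and descendant presence per branch and system.

    Returns a DataFrame indexed by child node ID with one column per defense
    system; every value lies in [0, 1].
    """
    _check_nodes(states, tree)
    probs = states.loc[np.arange(tree.n_nodes)].to_numpy(dtype=np.float64)
    child = np.arange(1, tree.n_nodes)
    parent = tree.parent[child]
    s = 0.5 * (probs[parent] + probs[child])
    return pd.DataFrame(
        s, index=pd.Index(child, name="child_node"), columns=states.columns
    )
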