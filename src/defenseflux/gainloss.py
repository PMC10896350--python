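"""Two-state gain-loss continuous-time Markov model on a species tree.

A binary trait (orthologous-group or defense-system presence) evolves along
the tree with gain rate ``g`` (0 -> 1) and loss rate ``l`` (1 -> 0), both in
events per unit branch length. The transition kernel over a branch of length
``t`` is available in closed form:

    P01(t) = g/(g+l) * (1 - exp(-(g+l) t))
    P10(t) = l/(g+l) * (1 - exp(-(g+l) t))

The likelihood of the tip pattern of one trait is computed by Felsenstein's
pruning algorithm; marginal posterior presence probabilities at every internal
node come from the up-down (inside-outside) pass. A single global ``(g, l)``
pair is shared by all trait columns of a presence/absence matrix and fitted by
bounded maximum likelihood; the root prior defaults to the stationary
distribution ``pi = g/(g+l)``.

The model/results split follows the statsmodels convention::

    res = GainLossModel(tree, matrix).fit()
    res.gain_rate, res.loss_rate
    probs = res.ancestral_probabilities()   # nodes x traits, tips observed
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .tree import PhyloTree

__all__ = [
    "GainLossParams",
    "GainLossModel",
    "GainLossResults",
    "DegenerateDataError",
    "transition_matrix",
    "fit_gain_loss",
    "reconstruct_marginals",
]

RATE_BOUNDS = (1e-6, 1e3)


class DegenerateDataError(ValueError):
    """Raised when every trait column is constant: rates are unidentifiable.

    Callers should skip fitting for such matrices (constant traits carry no
    information about gain or loss)."""


@dataclass(frozen=True)
class GainLossParams:
    """Gain/loss rates and root presence prior of the two-state model."""

    gain: float
    loss: float
    root_prior: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.gain) and self.gain > 0):
            raise ValueError("gain rate must be positive and finite")
        if not (np.isfinite(self.loss) and self.loss > 0):
            raise ValueError("loss rate must be positive and finite")
        if not 0.0 <= self.root_prior <= 1.0:
            raise ValueError("root prior must lie in [0, 1]")

    @property
    def stationary(self) -> float:
        return self.gain / (self.gain + self.loss)

    def transition_matrix(self, t: float) -> np.ndarray:
        return transition_matrix(self.gain, self.loss, t)


def transition_matrix(gain: float, loss: float, t: float) -> np.ndarray:
    """Closed-form 2x2 transition kernel of the gain-loss chain over time t."""
    if t < 0:
        raise ValueError("branch length t must be nonnegative")
    r = gain + loss
    decay = np.exp(-r * t)
    p01 = gain / r * (1.0 - decay)
    p10 = loss / r * (1.0 - decay)
    return np.array([[1.0 - p01, p01], [p10, 1.0 - p10]])


def _branch_kernels(tree: PhyloTree, gain: float, loss: float) -> np.ndarray:
    """Transition matrices for every node's incoming branch, shape (N, 2, 2)."""
    r = gain + loss
    decay = np.exp(-r * tree.lengths)
    p01 = gain / r * (1.0 - decay)
    p10 = loss / r * (1.0 - decay)
    out = np.empty((tree.n_nodes, 2, 2))
    out[:, 0, 0] = 1.0 - p01
    out[:, 0, 1] = p01
    out[:, 1, 0] = p10
    out[:, 1, 1] = 1.0 - p10
    return out


class GainLossModel:
    """Shared-rate gain-loss model for a genomes x traits binary matrix.

    Parameters
    ----------
    tree
        Rooted species tree whose tip labels cover the matrix rows.
    matrix
        Binary DataFrame, genomes as rows (matching tip labels), traits as
        columns. Every tree tip must appear as a row.
    root_prior
        ``"stationary"`` (default) ties the root prior to ``g/(g+l)`` during
        fitting; a float in [0, 1] fixes it.
    """

    def __init__(
        self,
        tree: PhyloTree,
        matrix: pd.DataFrame,
        root_prior: float | str = "stationary",
    ) -> None:
        self.tree = tree
        missing = [t for t in tree.tip_labels if t not in matrix.index]
        if missing:
            raise ValueError(f"matrix rows missing for tips: {missing[:10]}")
        self.trait_ids = list(matrix.columns)
        data = matrix.loc[tree.tip_labels].to_numpy()
        if not np.isin(data, (0, 1)).all():
            raise ValueError("presence/absence values must be binary 0/1")
        self.tipdata = data.astype(np.float64)  # (n_tips, C) in tip preorder
        self.root_prior = root_prior
        self._col_var = self.tipdata.std(axis=0) > 0

    # ------------------------------------------------------------- likelihood
    def _pruning(self, params: GainLossParams):
        """Post-order pass: per-node scaled partials and child->parent messages.

        Returns ``(partials, messages, logscale)`` with shapes (N, C, 2),
        (N, C, 2) and (C,). ``messages[v]`` is the likelihood message from the
        subtree rooted at v to its parent, indexed by the parent state.
        """
        tree = self.tree
        n, c = tree.n_nodes, self.tipdata.shape[1]
        kernels = _branch_kernels(tree, params.gain, params.loss)
        partial = np.empty((n, c, 2))
        message = np.empty((n, c, 2))
        logscale = np.zeros(c)
        tip_pos = {int(node): k for k, node in enumerate(tree.tip_ids)}
        for v in tree.postorder():
            if tree.is_tip(v):
                obs = self.tipdata[tip_pos[v]]
                partial[v, :, 0] = 1.0 - obs
                partial[v, :, 1] = obs
            else:
                p = np.ones((c, 2))
                for ch in tree.children[v]:
                    p *= message[ch]
                norm = p.sum(axis=1)
                norm[norm == 0.0] = 1.0  # impossible data guarded upstream
                partial[v] = p / norm[:, None]
                logscale += np.log(norm)
            if v != 0:
                # message to parent: sum over this node's state
                message[v] = partial[v] @ kernels[v].T
        return partial, message, logscale

    def _resolve_params(self, gain: float, loss: float) -> GainLossParams:
        if self.root_prior == "stationary":
            prior = gain / (gain + loss)
        else:
            prior = float(self.root_prior)
        return GainLossParams(gain, loss, prior)

    def loglike_per_column(self, params: GainLossParams) -> np.ndarray:
        partial, _, logscale = self._pruning(params)
        pi = np.array([1.0 - params.root_prior, params.root_prior])
        root = partial[0] @ pi
        with np.errstate(divide="ignore"):
            return logscale + np.log(root)

    def loglike(self, params: GainLossParams) -> float:
        """Summed log-likelihood of all trait columns."""
        return float(self.loglike_per_column(params).sum())

    # ------------------------------------------------------------------ fitting
    def fit(self, start: tuple[float, float] | None = None) -> "GainLossResults":
        """Maximise the summed log-likelihood over (gain, loss).

        Deterministic bounded optimisation in log-rate space from a
        method-of-moments start: the observed matrix mean sets the stationary
        frequency ``g/(g+l)`` and the total rate starts at 1.
        """
        if not self._col_var.any():
            raise DegenerateDataError(
                "all trait columns are constant; skip fitting for this matrix"
            )
        if start is None:
            f = float(np.clip(self.tipdata.mean(), 0.01, 0.99))
            start = (f, 1.0 - f)
        lo, hi = np.log(RATE_BOUNDS[0]), np.log(RATE_BOUNDS[1])

        def neg_ll(x: np.ndarray) -> float:
            params = self._resolve_params(float(np.exp(x[0])), float(np.exp(x[1])))
            return -self.loglike(params)

        x0 = np.clip(np.log(start), lo, hi)
        opt = minimize(
            neg_ll, x0, method="L-BFGS-B", bounds=[(lo, hi), (lo, hi)]
        )
        params = self._resolve_params(float(np.exp(opt.x[0])), float(np.exp(opt.x[1])))
        return GainLossResults(self, params, -float(opt.fun), bool(opt.success))

    # --------------------------------------------------------------- marginals
    def marginals(self, params: GainLossParams) -> np.ndarray:
        """Marginal posterior P(state=1 | tips) for every node, shape (N, C).

        Up-down algorithm: the downward message at the root is the prior; for
        each child it combines the parent's downward message with the sibling
        messages and passes through the branch kernel. Tips are pinned to
        their observed states.
        """
        tree = self.tree
        n, c = tree.n_nodes, self.tipdata.shape[1]
        kernels = _branch_kernels(tree, params.gain, params.loss)
        partial, message, _ = self._pruning(params)
        pi = np.array([1.0 - params.root_prior, params.root_prior])
        down = np.empty((n, c, 2))
        down[0] = pi
        for u in tree.preorder():
            kids = tree.children[u]
            for v in kids:
                out = down[u].copy()
                for w in kids:
                    if w != v:
                        out *= message[w]
                d = out @ kernels[v]
                norm = d.sum(axis=1)
                norm[norm == 0.0] = 1.0
                down[v] = d / norm[:, None]
        post = down * partial
        total = post.sum(axis=2)
        total[total == 0.0] = 1.0
        probs = post[:, :, 1] / total
        # pin tips to their exact observed states
        tip_pos = {int(node): k for k, node in enumerate(tree.tip_ids)}
        for v in tree.tip_ids:
            probs[v] = self.tipdata[tip_pos[int(v)]]
        return probs


class GainLossResults:
    """Fitted gain-loss model: rates, likelihood and ancestral reconstruction."""

    def __init__(
        self,
        model: GainLossModel,
        params: GainLossParams,
        loglike: float,
        converged: bool,
    ) -> None:
        self.model = model
        self.params = params
        self.llf = loglike
        self.converged = converged

    @property
    def gain_rate(self) -> float:
        return self.params.gain

    @property
    def loss_rate(self) -> float:
        return self.params.loss

    @property
    def root_prior(self) -> float:
        return self.params.root_prior

    def ancestral_probabilities(self) -> pd.DataFrame:
        """Posterior presence probability per node (rows) and trait (columns).

        Rows are indexed by preorder node ID; tip rows equal the observed 0/1
        states exactly.
        """
        probs = self.model.marginals(self.params)
        df = pd.DataFrame(probs, columns=self.model.trait_ids)
        df.index.name = "node_id"
        return df

    def to_tsv(self, path) -> None:
        """Serialize as tidy TSV: trait_id, node_id, probability (6 decimals)."""
        df = self.ancestral_probabilities()
        tidy = df.reset_index().melt(
            id_vars="node_id", var_name="trait_id", value_name="probability"
        )
        tidy["probability"] = tidy["probability"].map(lambda p: f"{p:.6f}")
        tidy[["trait_id", "node_id", "probability"]].to_csv(path, sep="\t", index=False)

    def summary(self) -> str:
        lines = [
            "Gain-loss model (two-state CTMC, shared rates)",
            "=" * 46,
            f"n tips:         {self.model.tree.n_tips}",
            f"n traits:       {len(self.model.trait_ids)}",
            f"gain rate g:    {self.gain_rate:.6g}",
            f"loss rate l:    {self.loss_rate:.6g}",
            f"root prior pi:  {self.root_prior:.6g}",
            f"stationary g/(g+l): {self.params.stationary:.6g}",
            f"log-likelihood: {self.llf:.6g}",
            f"converged:      {self.converged}",
        ]
        return "\n".join(lines)


def fit_gain_loss(
    tree: PhyloTree, matrix: pd.DataFrame, root_prior: float | str = "stationary"
) -> GainLossResults:
    """Fit shared gain/loss rates to a presence/absence matrix on a tree."""
    return GainLossModel(tree, matrix, root_prior=root_prior).fit()


def reconstruct_marginals(
    tree: PhyloTree, matrix: pd.DataFrame, params: GainLossParams
) -> pd.DataFrame:
    """Marginal ancestral presence probabilities under supplied parameters."""
    model = GainLossModel(tree, matrix, root_prior=params.root_prior)
    probs = model.marginals(params)
    df = pd.DataFrame(probs, columns=model.trait_ids)
    df.index.name = "node_id"
    return df
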