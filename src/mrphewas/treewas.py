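"""Bayesian association scan over a diagnosis-code tree.

A two-state latent process ("no effect" / "effect") runs along the edges of
the ICD10-like code hierarchy: the root state is Bernoulli(pi1) and each
child copies its parent's state with probability rho, otherwise redrawing
from the stationary law (1 - pi1, pi1). Each node contributes a Gaussian
summary likelihood for its estimated log-odds ratio b_hat with standard
error se: a point mass at zero effect under the null state, an average over
a discrete effect grid under the active state. Exact per-node posterior
probabilities of a non-zero effect are obtained by sum-product (upward /
downward) message passing, linear in the number of nodes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

DEFAULT_PP_THRESHOLD = 0.75
DEFAULT_EFFECT_GRID = (-0.4, -0.2, -0.1, -0.05, 0.05, 0.1, 0.2, 0.4)


@dataclass(frozen=True)
class TreePrior:
    """Markov-process prior on the latent effect states.

    pi1: stationary probability of the active state; rho: probability a child
    copies its parent's state (else it redraws from the stationary law);
    effect_grid: discrete support of non-zero log-odds effects, with uniform
    weights.
    """

    pi1: float = 0.001
    rho: float = 0.99
    effect_grid: tuple[float, ...] = DEFAULT_EFFECT_GRID

    def __post_init__(self) -> None:
        if not 0 < self.pi1 < 1:
            raise ValueError("pi1 must lie strictly in (0,1)")
        if not 0.5 <= self.rho < 1:
            raise ValueError("rho must lie in [0.5, 1)")
        if len(self.effect_grid) == 0 or any(e == 0 for e in self.effect_grid):
            raise ValueError("effect_grid must be non-empty and exclude 0")

    @property
    def stationary(self) -> np.ndarray:
        return np.array([1 - self.pi1, self.pi1])

    def transition(self) -> np.ndarray:
        """T[s_parent, s_child] = rho*1[equal] + (1-rho)*stationary[s_child]."""
        return self.rho * np.eye(2) + (1 - self.rho) * self.stationary[None, :]


@dataclass
class CodeTree:
    """Rooted diagnosis-code tree with per-node case sets.

    A node's cases are the union of individuals carrying any descendant-or-
    self code.
    """

    graph: nx.DiGraph              # edges parent -> child
    root: str
    case_sets: dict[str, set] = field(default_factory=dict)
    cohort_ids: pd.Index | None = None

    @property
    def nodes(self) -> list[str]:
        return list(nx.dfs_preorder_nodes(self.graph, self.root))

    def n_cases(self, node: str) -> int:
        return len(self.case_sets.get(node, ()))

    def children(self, node: str) -> list[str]:
        return list(self.graph.successors(node))


def build_code_tree(edges: pd.DataFrame, records: pd.DataFrame | None = None,
                    cohort_ids=None) -> CodeTree:
    """Validate an edge list (child, parent) and aggregate case sets bottom-up.

    Raises on cycles or multiple roots. Individuals carrying a code are
    counted at that code's node and every ancestor.
    """
    g = nx.DiGraph()
    for child, parent in zip(edges["child"].astype(str), edges["parent"].astype(str)):
        g.add_edge(parent, child)
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("edge list contains a cycle")
    roots = [n for n in g.nodes if g.in_degree(n) == 0]
    if len(roots) != 1:
        raise ValueError(f"tree must have exactly one root, found {roots}")
    if any(g.in_degree(n) > 1 for n in g.nodes):
        raise ValueError("a node has multiple parents")
    root = roots[0]

    case_sets: dict[str, set] = {n: set() for n in g.nodes}
    if records is not None and len(records):
        unknown = set(records["icd10_code"].astype(str)) - set(g.nodes)
        if unknown:
            warnings.warn(f"{len(unknown)} diagnosis codes not in tree; dropped")
        for code, grp in records.groupby(records["icd10_code"].astype(str)):
            if code in case_sets:
                case_sets[code] |= set(grp["individual_id"])
        for node in reversed(list(nx.topological_sort(g))):
            for child in g.successors(node):
                case_sets[node] |= case_sets[child]
    ids = pd.Index(cohort_ids) if cohort_ids is not None else None
    return CodeTree(g, root, case_sets, ids)


def node_summaries(score: pd.Series, tree: CodeTree,
                   covariates: pd.DataFrame | None = None,
                   categorical: tuple[str, ...] = ("centre",)) -> pd.DataFrame:
    """Per-node logistic fit of case status on the score.

    Returns node, n_cases, b_hat, se, estimable. Nodes with zero cases or
    zero controls (or non-converging fits) are flagged inestimable.
    """
    from .phewas import _design_matrix

    ids = tree.cohort_ids
    if ids is None:
        raise ValueError("tree carries no cohort ids; pass cohort_ids to build_code_tree")
    X = _design_matrix(score.loc[ids], covariates, categorical)
    rows = []
    for node in tree.nodes:
        members = tree.case_sets.get(node, set())
        y = ids.isin(members).astype(float)
        n_cases = int(y.sum())
        b = se = np.nan
        estimable = False
        if 0 < n_cases < len(ids):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fit = sm.Logit(y, X.to_numpy(float)).fit(disp=0, maxiter=50)
                if fit.mle_retvals["converged"] and np.isfinite(fit.bse[1]) \
                        and fit.bse[1] < 1e3:
                    b, se, estimable = float(fit.params[1]), float(fit.bse[1]), True
            except np.linalg.LinAlgError:
                pass
        rows.append((node, n_cases, b, se, estimable))
    return pd.DataFrame(rows, columns=["node", "n_cases", "b_hat", "se",
                                       "estimable"])


def _node_likelihoods(summaries: pd.DataFrame, prior: TreePrior
                      ) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Per-node likelihood of (null, active) states and per-effect weights.

    Inestimable nodes contribute likelihood 1 in both states. Likelihoods are
    rescaled per node (posteriors are scale-free).
    """
    grid = np.asarray(prior.effect_grid, dtype=float)
    lik: dict[str, np.ndarray] = {}
    effect_post: dict[str, np.ndarray] = {}
    for row in summaries.itertuples(index=False):
        if not row.estimable or not np.isfinite(row.se):
            lik[row.node] = np.ones(2)
            effect_post[row.node] = np.full(grid.size, 1 / grid.size)
            continue
        l0 = stats.norm.pdf(row.b_hat, 0.0, row.se)
        per_effect = stats.norm.pdf(row.b_hat, grid, row.se)
        l1 = per_effect.mean()
        scale = max(l0, l1)
        if scale == 0:  # far tails: fall back to log-space differences
            logs = stats.norm.logpdf(row.b_hat, np.concatenate(([0.0], grid)), row.se)
            m = logs.max()
            l0 = np.exp(logs[0] - m)
            per_effect = np.exp(logs[1:] - m)
            l1 = per_effect.mean()
            scale = max(l0, l1)
        lik[row.node] = np.array([l0, l1]) / scale
        effect_post[row.node] = (per_effect / per_effect.sum()
                                 if per_effect.sum() > 0
                                 else np.full(grid.size, 1 / grid.size))
    return lik, effect_post


def tree_posterior(tree: CodeTree, summaries: pd.DataFrame,
                   prior: TreePrior = TreePrior()) -> pd.DataFrame:
    """Exact marginal posterior probability of a non-zero effect per node.

    Upward-downward sum-product over the two-state latent Markov process;
    cost O(|nodes| x |effect grid|). Returns node, pp_nonzero and the
    posterior mean effect (0 under the null state, grid-averaged under the
    active state).
    """
    lik, effect_post = _node_likelihoods(summaries, prior)
    for node in tree.nodes:
        if node not in lik:  # nodes absent from summaries: flat likelihood
            lik[node] = np.ones(2)
            grid = np.asarray(prior.effect_grid)
            effect_post[node] = np.full(grid.size, 1 / grid.size)
    T = prior.transition()          # T[parent, child]
    order = list(nx.dfs_postorder_nodes(tree.graph, tree.root))

    # upward: phi[v][s] = L_v(s) * prod_c sum_{s_c} T[s, s_c] phi[c][s_c]
    phi: dict[str, np.ndarray] = {}
    up_msg: dict[str, np.ndarray] = {}   # message child -> parent, indexed by s_parent
    for node in order:
        val = lik[node].copy()
        for child in tree.children(node):
            val *= up_msg[child]
        phi[node] = val / val.sum()
        msg = T @ phi[node]
        up_msg[node] = msg / msg.sum()

    # downward: beta[v][s] = prior-side belief arriving at v
    beta: dict[str, np.ndarray] = {tree.root: prior.stationary}
    posts = {}
    for node in nx.dfs_preorder_nodes(tree.graph, tree.root):
        post = beta[node] * lik[node]
        for child in tree.children(node):
            post *= up_msg[child]
        post = post / post.sum()
        posts[node] = post
        for child in tree.children(node):
            # belief at node excluding child's subtree, propagated through T
            excl = beta[node] * lik[node]
            for other in tree.children(node):
                if other != child:
                    excl *= up_msg[other]
            msg = excl @ T
            beta[child] = msg / msg.sum()

    grid = np.asarray(prior.effect_grid, dtype=float)
    rows = []
    for node in tree.nodes:
        pp = float(posts[node][1])
        mean_effect = pp * float(grid @ effect_post[node])
        rows.append((node, pp, mean_effect))
    out = pd.DataFrame(rows, columns=["node", "pp_nonzero", "posterior_mean_effect"])
    return out.merge(summaries[["node", "n_cases", "b_hat", "se"]],
                     on="node", how="left")


def significant_nodes(posteriors: pd.DataFrame,
                      threshold: float = DEFAULT_PP_THRESHOLD) -> list[str]:
    """Nodes whose posterior probability of non-zero effect strictly exceeds
    the threshold."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0,1)")
    hits = posteriors.loc[posteriors["pp_nonzero"] > threshold, "node"]
    return list(hits)
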