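"""Score-based MCMC search over DAGs, consensus averaging and de-looping.

Each node's local model is a linear-Gaussian regression on its parents,
scored by BIC (reported as -BIC/2 so that higher is better) with an
additive log-score bonus ``kappa`` for every parent edge present in the
structural prior set.  The network score is the sum of local scores
(decomposable), so single-edge proposals need only one or two local
re-evaluations.  Many independent Metropolis-Hastings chains start from
distinct random DAGs; the endpoint of each chain contributes one
network, and the consensus keeps directed edges appearing in strictly
more than a threshold fraction of the sampled networks.  Because
consensus edges come from different DAGs, the result may contain
cycles; an iterative de-loop removes, at each step, the single most
weakly supported edge that lies on some cycle (an edge inside a
nontrivial strongly connected component), until the graph is acyclic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix


@dataclass(frozen=True)
class McmcConfig:
    """Structure-search settings.

    ``n_networks`` chains each contribute their endpoint DAG;
    ``consensus_threshold`` is strict (an edge needs occurrence
    frequency > threshold to survive).  Chain ``c`` derives its RNG from
    ``seed + c``.  ``burn_in`` is a lower bound on chain length kept for
    interface stability: since only the endpoint of each chain is
    consumed, no within-chain averaging window needs discarding.
    """

    n_networks: int = 1000
    consensus_threshold: float = 0.30
    max_parents: int = 5
    kappa: float = 12.0
    ebic_gamma: float = 1.5
    steps: int = 400_000
    burn_in: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_networks < 1:
            raise ValueError("need at least one network")
        if not 0.0 <= self.consensus_threshold < 1.0:
            raise ValueError("consensus threshold must be in [0, 1)")
        if self.max_parents < 0:
            raise ValueError("max parents must be nonnegative")
        if self.steps < self.burn_in:
            raise ValueError("steps must cover the burn-in")


class GaussianBicScore:
    """Decomposable BIC scorer with prior bonuses, cached per parent set.

    Works from the centered Gram matrix, so a local score is a small
    solve regardless of sample size.
    """

    def __init__(
        self,
        data: ExpressionMatrix | pd.DataFrame,
        priors: pd.DataFrame | None = None,
        kappa: float = 12.0,
        ebic_gamma: float = 1.5,
    ) -> None:
        values = data.values if isinstance(data, ExpressionMatrix) else data
        X = values.to_numpy(dtype=float).T  # samples x genes
        X = X - X.mean(axis=0)
        self.genes: list[str] = list(values.index)
        self.index = {g: i for i, g in enumerate(self.genes)}
        self.n = X.shape[0]
        self.S = X.T @ X
        self.kappa = kappa
        self.prior_parents: dict[int, set[int]] = {}
        if priors is not None and len(priors):
            for row in priors.itertuples(index=False):
                s, t = self.index.get(row.source), self.index.get(row.target)
                if s is None or t is None:
                    continue
                self.prior_parents.setdefault(t, set()).add(s)
        self.ebic_gamma = ebic_gamma
        self._cache: dict[tuple[int, tuple[int, ...]], float] = {}
        self._log_n = np.log(self.n)
        self._log_p = np.log(max(len(self.genes), 2))
        self._const = np.log(2.0 * np.pi)

    def local(self, j: int, parents: tuple[int, ...]) -> float:
        """-BIC/2 of gene j regressed on its parents, plus prior bonus."""
        key = (j, parents)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        if len(set(parents)) != len(parents):
            raise ValueError("duplicate parents form a singular design")
        n, S = self.n, self.S
        if parents:
            P = list(parents)
            spp = S[np.ix_(P, P)]
            spj = S[P, j]
            try:
                b = np.linalg.solve(spp, spj)
            except np.linalg.LinAlgError as err:
                raise ValueError(f"singular design for node {j}") from err
            rss = S[j, j] - float(spj @ b)
        else:
            rss = S[j, j]
        rss = max(rss, 1e-12)
        sigma2 = rss / n
        loglik = -0.5 * n * (self._const + np.log(sigma2) + 1.0)
        k = len(parents) + 2  # coefficients + intercept + variance
        # extended-BIC edge penalty controls the family-wise false-edge
        # rate over the ~p^2 candidate parents at moderate n
        score = (
            loglik
            - 0.5 * k * self._log_n
            - self.ebic_gamma * len(parents) * self._log_p
        )
        prior = self.prior_parents.get(j)
        if prior:
            score += self.kappa * len(prior.intersection(parents))
        self._cache[key] = score
        return score

    def local_by_name(self, gene: str, parent_genes) -> float:
        j = self.index[gene]
        parents = tuple(sorted(self.index[g] for g in parent_genes))
        return self.local(j, parents)

    def network_score(self, parent_sets: list[tuple[int, ...]]) -> float:
        return sum(self.local(j, ps) for j, ps in enumerate(parent_sets))


def local_score(
    gene: str,
    parent_set,
    data: ExpressionMatrix | pd.DataFrame,
    priors: pd.DataFrame | None = None,
    kappa: float = 12.0,
    ebic_gamma: float = 1.5,
) -> float:
    """Convenience wrapper: one local score without keeping the scorer."""
    scorer = GaussianBicScore(data, priors, kappa, ebic_gamma)
    if gene in set(parent_set):
        raise ValueError("a gene cannot be its own parent")
    return scorer.local_by_name(gene, parent_set)


# ---------------------------------------------------------------------------
# MCMC over DAG space
# ---------------------------------------------------------------------------

def _has_path(children: list[set[int]], start: int, goal: int) -> bool:
    """Depth-first reachability start -> goal over child sets."""
    if start == goal:
        return True
    stack = [start]
    seen = {start}
    while stack:
        node = stack.pop()
        for nxt in children[node]:
            if nxt == goal:
                return True
            if nxt not in seen:
                seen.add(nxt)
                stack.append(nxt)
    return False


def _random_start(
    p: int, max_parents: int, rng: np.random.Generator
) -> tuple[list[set[int]], list[set[int]]]:
    """Random sparse DAG: random order, forward edges, ~0.5 expected parents.

    Sparse starts matter under a parent-count cap: dense random starts
    fill parent slots with arbitrary edges that score-improving single
    moves cannot always displace.
    """
    order = rng.permutation(p)
    parents: list[set[int]] = [set() for _ in range(p)]
    children: list[set[int]] = [set() for _ in range(p)]
    prob = min(1.0, 0.5 / max(p - 1, 1))
    for pos_j in range(1, p):
        j = order[pos_j]
        for pos_i in range(pos_j):
            i = order[pos_i]
            if len(parents[j]) >= max_parents:
                break
            if rng.random() < prob:
                parents[j].add(i)
                children[i].add(j)
    return parents, children


def _run_chain(
    scorer: GaussianBicScore,
    config: McmcConfig,
    chain_seed: int,
) -> list[set[int]]:
    """One Metropolis-Hastings chain; returns the endpoint's parent sets.

    Proposals add, delete or reverse a uniformly chosen single edge;
    moves creating a cycle or exceeding the parent limit are rejected.
    Acceptance uses min(1, exp(score difference)); the proposal-count
    asymmetry is not corrected, which biases the stationary law slightly
    but leaves the score landscape untouched — endpoints concentrate on
    high-scoring structures, which is all consensus averaging consumes.
    """
    rng = np.random.default_rng(chain_seed)
    p = len(scorer.genes)
    parents, children = _random_start(p, config.max_parents, rng)
    local = scorer.local
    cur = [local(j, tuple(sorted(parents[j]))) for j in range(p)]

    move_codes = rng.integers(0, 3, size=config.steps)
    pair_i = rng.integers(0, p, size=config.steps)
    pair_j = rng.integers(0, p - 1, size=config.steps)
    accept_u = rng.random(size=config.steps)

    for step in range(config.steps):
        i = int(pair_i[step])
        j = int(pair_j[step])
        if j >= i:
            j += 1
        move = move_codes[step]
        if move == 0:  # add i -> j
            if i in parents[j] or j in parents[i]:
                continue
            if len(parents[j]) >= config.max_parents:
                continue
            if _has_path(children, j, i):
                continue
            new = local(j, tuple(sorted(parents[j] | {i})))
            delta = new - cur[j]
            if delta >= 0 or accept_u[step] < np.exp(delta):
                parents[j].add(i)
                children[i].add(j)
                cur[j] = new
        elif move == 1:  # delete i -> j
            if i not in parents[j]:
                continue
            new = local(j, tuple(sorted(parents[j] - {i})))
            delta = new - cur[j]
            if delta >= 0 or accept_u[step] < np.exp(delta):
                parents[j].discard(i)
                children[i].discard(j)
                cur[j] = new
        else:  # reverse i -> j into j -> i
            if i not in parents[j]:
                continue
            if len(parents[i]) >= config.max_parents:
                continue
            # temporarily drop the edge, then check for another i -> j path
            children[i].discard(j)
            parents[j].discard(i)
            if _has_path(children, i, j):
                children[i].add(j)
                parents[j].add(i)
                continue
            new_j = local(j, tuple(sorted(parents[j])))
            new_i = local(i, tuple(sorted(parents[i] | {j})))
            delta = (new_j + new_i) - (cur[j] + cur[i])
            if delta >= 0 or accept_u[step] < np.exp(delta):
                parents[i].add(j)
                children[j].add(i)
                cur[j] = new_j
                cur[i] = new_i
            else:
                children[i].add(j)
                parents[j].add(i)
    return parents


def mcmc_structure_search(
    data: ExpressionMatrix | pd.DataFrame,
    priors: pd.DataFrame | None = None,
    config: McmcConfig | None = None,
) -> list[nx.DiGraph]:
    """Sample DAGs from independent randomly started MH chains.

    Returns one DiGraph per chain (the chain endpoint).  All graphs
    share the gene node set of the input data.
    """
    config = config or McmcConfig()
    scorer = GaussianBicScore(data, priors, config.kappa, config.ebic_gamma)
    genes = scorer.genes
    dags = []
    for c in range(config.n_networks):
        parents = _run_chain(scorer, config, config.seed + c)
        g = nx.DiGraph()
        g.add_nodes_from(genes)
        for j, ps in enumerate(parents):
            for i in ps:
                g.add_edge(genes[i], genes[j])
        dags.append(g)
    return dags


# ---------------------------------------------------------------------------
# consensus, de-loop, neighborhood
# ---------------------------------------------------------------------------

def consensus_average(
    networks: list[nx.DiGraph], threshold: float = 0.30
) -> nx.DiGraph:
    """Directed edges shared by strictly more than ``threshold`` of networks.

    Edge weights are occurrence frequencies (count / N).  The result may
    contain cycles; run :func:`deloop` before any DAG-only analysis.
    """
    if not networks:
        raise ValueError("empty network list")
    nodes = set(networks[0].nodes)
    for g in networks[1:]:
        if set(g.nodes) != nodes:
            raise ValueError("networks must share an identical node set")
    n = len(networks)
    counts: dict[tuple, int] = {}
    for g in networks:
        for e in g.edges():
            counts[e] = counts.get(e, 0) + 1
    out = nx.DiGraph()
    out.add_nodes_from(sorted(nodes))
    for (u, v), c in counts.items():
        w = c / n
        if w > threshold:
            out.add_edge(u, v, weight=w)
    return out


class DeloopResult(NamedTuple):
    network: nx.DiGraph
    removed: list[tuple[str, str, float]]


def deloop(network: nx.DiGraph, weight: str = "weight") -> DeloopResult:
    """Iteratively remove the weakest cycle-participating edge.

    At each step the edges lying on at least one directed cycle are
    exactly those inside a nontrivial strongly connected component; the
    single minimum-weight such edge is removed (ties broken by
    lexicographic (source, target)), until the graph is acyclic.
    """
    g = network.copy()
    removed: list[tuple[str, str, float]] = []
    while True:
        cyclic_edges = []
        for comp in nx.strongly_connected_components(g):
            if len(comp) < 2:
                continue
            for u, v, d in g.edges(comp, data=True):
                if u in comp and v in comp:
                    cyclic_edges.append((d.get(weight, 1.0), u, v))
        if not cyclic_edges:
            break
        w, u, v = min(cyclic_edges, key=lambda t: (t[0], t[1], t[2]))
        g.remove_edge(u, v)
        removed.append((u, v, w))
    return DeloopResult(network=g, removed=removed)


def extract_neighborhood(
    network: nx.DiGraph,
    root: str,
    depth: int = 3,
    trim: bool = False,
) -> nx.DiGraph:
    """Induced subnetwork reachable from ``root`` within ``depth`` steps.

    With ``trim``, non-root nodes of total degree 1 inside the
    subnetwork ("single leaf nodes") are removed iteratively.
    """
    if root not in network:
        raise ValueError(f"root {root!r} not in network")
    lengths = nx.single_source_shortest_path_length(network, root, cutoff=depth)
    sub = network.subgraph(lengths).copy()
    if trim:
        while True:
            leaves = [
                n for n in sub.nodes if n != root and sub.degree(n) == 1
            ]
            if not leaves:
                break
            sub.remove_nodes_from(leaves)
    return sub
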