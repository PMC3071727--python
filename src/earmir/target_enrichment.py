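"""Degree-preserving permutation test for miRNA target-site enrichment.

Predictions are a weighted bipartite graph: miRNA families on one side,
genes on the other, one edge per (family, gene) pair whose weight is the
summed strength of that pair's predicted sites (``max(0, -context_score)``
per site — more negative context scores mean stronger predicted repression).
The observed statistic for a family and a gene set S is the total weight of
its edges into S. The null preserves both degree sequences: repeated random
double-edge swaps — take edges (m1,g1), (m2,g2) and rewire to (m1,g2),
(m2,g1) when both new edges are absent — with each weight traveling on its
family-side half-edge. This chain is symmetric and connected over the
(graph, within-family weight assignment) states, so its stationary
distribution is uniform; statistics for every family and set are updated
incrementally per accepted swap and sampled after a burn-in with thinning.
Empirical p-values carry the +1/(N+1) correction and count ties in the tail.

Enrichment is tested on the conserved-sites-only graph; depletion on the
graph of all (conserved + nonconserved) sites.

``exact_null_small`` enumerates the full null for toy graphs (<= 12 edges)
and is the independent oracle for the sampler.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from numba import njit

from .data_io import DataIOError, GeneSetCollection, TargetPredictionTable
from .integration_sets import set_layer
from .mrna_diffexp import benjamini_hochberg

logger = logging.getLogger(__name__)

_TIE_TOL = 1e-9


class GraphError(ValueError):
    """Raised on invalid graph construction or randomization inputs."""


@dataclass(frozen=True)
class WeightedTargetGraph:
    """Simple weighted bipartite family-gene graph (sites pre-collapsed)."""

    families: tuple[str, ...]
    genes: tuple[str, ...]
    edge_fam: np.ndarray  # int32 index into families, one per edge
    edge_gene: np.ndarray  # int32 index into genes
    edge_weight: np.ndarray  # float64, >= 0
    conserved_only: bool

    @property
    def n_edges(self) -> int:
        return int(self.edge_fam.shape[0])

    def family_degrees(self) -> np.ndarray:
        return np.bincount(self.edge_fam, minlength=len(self.families))

    def gene_degrees(self) -> np.ndarray:
        return np.bincount(self.edge_gene, minlength=len(self.genes))

    def family_weight_multisets(self) -> dict[str, tuple[float, ...]]:
        out: dict[str, list[float]] = {f: [] for f in self.families}
        for f_idx, w in zip(self.edge_fam, self.edge_weight):
            out[self.families[f_idx]].append(float(w))
        return {f: tuple(sorted(ws)) for f, ws in out.items()}

    def adjacency(self) -> np.ndarray:
        adj = np.zeros((len(self.families), len(self.genes)), dtype=np.bool_)
        adj[self.edge_fam, self.edge_gene] = True
        return adj


def build_graph(
    predictions: TargetPredictionTable,
    universe: Iterable[str],
    conserved_only: bool,
) -> WeightedTargetGraph:
    """Collapse per-site predictions into a universe-restricted weighted graph.

    Sites outside the universe are dropped; per (family, gene) pair the site
    weights ``max(0, -context_score)`` are summed into a single edge (a
    positive context score contributes weight 0 but the edge still exists);
    families left without edges are dropped and logged.
    """
    universe = {g.upper() for g in universe}
    if not universe:
        raise GraphError("empty universe")
    sites = predictions.sites
    if conserved_only:
        sites = sites.loc[sites["conserved"]]
    sites = sites.loc[sites["gene_id"].isin(universe)]
    if sites.empty:
        raise GraphError("no prediction sites left after filtering")
    weights = np.maximum(0.0, -sites["site_context_score"].to_numpy(dtype=float))
    edges = (
        pd.DataFrame(
            {
                "family_id": sites["family_id"].to_numpy(),
                "gene_id": sites["gene_id"].to_numpy(),
                "weight": weights,
            }
        )
        .groupby(["family_id", "gene_id"], as_index=False)["weight"]
        .sum()
    )
    families = tuple(sorted(edges["family_id"].unique()))
    genes = tuple(sorted(universe))
    fam_index = {f: i for i, f in enumerate(families)}
    gene_index = {g: i for i, g in enumerate(genes)}
    n_dropped = len(set(predictions.sites["family_id"])) - len(families)
    if n_dropped:
        logger.info("%d familie(s) dropped with no edges in the universe", n_dropped)
    return WeightedTargetGraph(
        families=families,
        genes=genes,
        edge_fam=edges["family_id"].map(fam_index).to_numpy(dtype=np.int32),
        edge_gene=edges["gene_id"].map(gene_index).to_numpy(dtype=np.int32),
        edge_weight=edges["weight"].to_numpy(dtype=np.float64),
        conserved_only=conserved_only,
    )


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------


@njit(cache=True)
def _swap_attempts(edge_fam, edge_gene, edge_weight, adj, n_swaps, seed):  # pragma: no cover
    np.random.seed(seed)
    n_edges = edge_fam.shape[0]
    failed = 0
    for _ in range(n_swaps):
        i = np.random.randint(n_edges)
        j = np.random.randint(n_edges)
        m1, g1 = edge_fam[i], edge_gene[i]
        m2, g2 = edge_fam[j], edge_gene[j]
        if m1 != m2 and g1 != g2 and not adj[m1, g2] and not adj[m2, g1]:
            adj[m1, g1] = False
            adj[m2, g2] = False
            adj[m1, g2] = True
            adj[m2, g1] = True
            edge_gene[i] = g2
            edge_gene[j] = g1
        else:
            failed += 1
    return failed


@njit(cache=True)
def _sampling_chain(
    edge_fam,
    edge_gene,
    edge_weight,
    adj,
    in_set,
    t_obs,
    n_burn,
    n_samples,
    thin,
    seed,
    ge_counts,
    le_counts,
):  # pragma: no cover
    np.random.seed(seed)
    n_edges = edge_fam.shape[0]
    n_fam, n_sets = t_obs.shape
    t_cur = t_obs.copy()
    total = n_burn + n_samples * thin
    attempt = 0
    while attempt < total:
        i = np.random.randint(n_edges)
        j = np.random.randint(n_edges)
        m1, g1 = edge_fam[i], edge_gene[i]
        m2, g2 = edge_fam[j], edge_gene[j]
        if m1 != m2 and g1 != g2 and not adj[m1, g2] and not adj[m2, g1]:
            adj[m1, g1] = False
            adj[m2, g2] = False
            adj[m1, g2] = True
            adj[m2, g1] = True
            edge_gene[i] = g2
            edge_gene[j] = g1
            w1 = edge_weight[i]
            w2 = edge_weight[j]
            for s in range(n_sets):
                d = in_set[g2, s] - in_set[g1, s]
                if d != 0.0:
                    t_cur[m1, s] += w1 * d
                    t_cur[m2, s] -= w2 * d
        attempt += 1
        if attempt > n_burn and (attempt - n_burn) % thin == 0:
            for f in range(n_fam):
                for s in range(n_sets):
                    tol = _TIE_TOL * (1.0 + abs(t_obs[f, s]))
                    if t_cur[f, s] >= t_obs[f, s] - tol:
                        ge_counts[f, s] += 1
                    if t_cur[f, s] <= t_obs[f, s] + tol:
                        le_counts[f, s] += 1


def _child_seed(seed: int, salt: int = 0) -> int:
    return int(np.random.SeedSequence([seed, salt]).generate_state(1)[0] % (2**31))


def randomize(
    graph: WeightedTargetGraph, n_swaps: int, seed: int = 0
) -> tuple[WeightedTargetGraph, int]:
    """Apply ``n_swaps`` attempted double-edge swaps; return (graph', failed).

    Both degree sequences and every family's weight multiset are preserved
    exactly; illegal attempts are skipped and counted.
    """
    if graph.n_edges < 2:
        raise GraphError("randomization needs at least 2 edges")
    edge_gene = graph.edge_gene.copy()
    failed = _swap_attempts(
        graph.edge_fam,
        edge_gene,
        graph.edge_weight,
        graph.adjacency(),
        n_swaps,
        _child_seed(seed),
    )
    return (
        WeightedTargetGraph(
            families=graph.families,
            genes=graph.genes,
            edge_fam=graph.edge_fam.copy(),
            edge_gene=edge_gene,
            edge_weight=graph.edge_weight.copy(),
            conserved_only=graph.conserved_only,
        ),
        int(failed),
    )


def _observed_statistics(graph: WeightedTargetGraph, in_set: np.ndarray) -> np.ndarray:
    t_obs = np.zeros((len(graph.families), in_set.shape[1]))
    contrib = graph.edge_weight[:, None] * in_set[graph.edge_gene, :]
    np.add.at(t_obs, graph.edge_fam, contrib)
    return t_obs


def _membership(graph: WeightedTargetGraph, gene_sets: Sequence[frozenset[str]]) -> np.ndarray:
    gene_index = {g: i for i, g in enumerate(graph.genes)}
    in_set = np.zeros((len(graph.genes), len(gene_sets)))
    for s, members in enumerate(gene_sets):
        extra = set(members) - set(graph.genes)
        if extra:
            raise GraphError(
                f"gene set contains genes outside the graph universe: {sorted(extra)[:5]}"
            )
        for g in members:
            in_set[gene_index[g], s] = 1.0
    return in_set


def sample_null_tails(
    graph: WeightedTargetGraph,
    gene_sets: Sequence[frozenset[str]],
    n_perm: int = 10_000,
    burn_in: int | None = None,
    thin: int | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One swap chain for all families and sets simultaneously.

    Returns (t_obs, p_enrich, p_deplete), each (n_families, n_sets), with
    p = (1 + tail count) / (n_perm + 1).
    """
    if burn_in is None:
        burn_in = 10 * graph.n_edges
    if thin is None:
        thin = graph.n_edges
    in_set = _membership(graph, gene_sets)
    t_obs = _observed_statistics(graph, in_set)
    ge = np.zeros(t_obs.shape, dtype=np.int64)
    le = np.zeros(t_obs.shape, dtype=np.int64)
    if graph.n_edges >= 2:
        _sampling_chain(
            graph.edge_fam.copy(),
            graph.edge_gene.copy(),
            graph.edge_weight,
            graph.adjacency(),
            in_set,
            t_obs,
            int(burn_in),
            int(n_perm),
            int(thin),
            _child_seed(seed, 1),
            ge,
            le,
        )
    else:  # a single edge admits no swap; the null is the observed graph
        ge[:] = n_perm
        le[:] = n_perm
    p_enrich = (1.0 + ge) / (n_perm + 1.0)
    p_deplete = (1.0 + le) / (n_perm + 1.0)
    return t_obs, p_enrich, p_deplete


def enrichment_test(
    graph: WeightedTargetGraph,
    gene_set: frozenset[str] | set[str],
    n_perm: int = 10_000,
    burn_in: int | None = None,
    thin: int | None = None,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Permutation test of one gene set against every family in the graph."""
    gene_set = frozenset(g.upper() for g in gene_set)
    degenerate = len(gene_set) == 0
    t_obs, p_enrich, p_deplete = sample_null_tails(
        graph, [gene_set], n_perm=n_perm, burn_in=burn_in, thin=thin, seed=seed
    )
    direction = np.where(
        p_enrich[:, 0] < alpha,
        "enriched",
        np.where(p_deplete[:, 0] < alpha, "depleted", "none"),
    )
    return pd.DataFrame(
        {
            "t_obs": t_obs[:, 0],
            "n_perm": n_perm,
            "p_enrich": p_enrich[:, 0],
            "p_deplete": p_deplete[:, 0],
            "direction": direction,
            "degenerate": degenerate,
        },
        index=pd.Index(graph.families, name="family_id"),
    )


# ---------------------------------------------------------------------------
# exact small-graph oracle
# ---------------------------------------------------------------------------


def exact_null_small(
    graph: WeightedTargetGraph, gene_set: frozenset[str] | set[str]
) -> pd.DataFrame:
    """Exact tail probabilities by full enumeration of the null (<= 12 edges).

    The swap chain is a symmetric random walk on weighted-graph states (an
    edge is a (family, gene, weight) triple; a swap exchanges the gene
    endpoints of two edges), so its stationary law is uniform on the
    component reachable from the observed graph. That component is
    enumerated here by breadth-first search over all legal double-edge
    swaps. Note this is *not* in general the uniform law over all
    degree-matched graphs with independent within-family weight orderings:
    a complete bipartite graph, for instance, admits no legal swap, its
    null is the single observed state, and both tails are exactly 1.
    """
    if graph.n_edges > 12:
        raise GraphError("exact enumeration is limited to graphs with <= 12 edges")
    gene_set = frozenset(g.upper() for g in gene_set)
    in_set = np.array([g in gene_set for g in graph.genes], dtype=float)
    t_obs = _observed_statistics(graph, in_set[:, None])[:, 0]

    n_edges = graph.n_edges
    start = tuple(
        sorted(
            (int(f), int(g), round(float(w), 12))
            for f, g, w in zip(graph.edge_fam, graph.edge_gene, graph.edge_weight)
        )
    )
    seen = {start}
    frontier = [start]
    while frontier:
        state = frontier.pop()
        pairs = {(f, g) for f, g, _w in state}
        for i in range(n_edges):
            for j in range(n_edges):
                m1, g1, w1 = state[i]
                m2, g2, w2 = state[j]
                if m1 == m2 or g1 == g2:
                    continue
                if (m1, g2) in pairs or (m2, g1) in pairs:
                    continue
                nxt = list(state)
                nxt[i] = (m1, g2, w1)
                nxt[j] = (m2, g1, w2)
                nxt = tuple(sorted(nxt))
                if nxt not in seen:
                    seen.add(nxt)
                    frontier.append(nxt)

    n_fam = len(graph.families)
    ge = np.zeros(n_fam)
    le = np.zeros(n_fam)
    for state in seen:
        t_state = np.zeros(n_fam)
        for f, g, w in state:
            t_state[f] += w * in_set[g]
        tol = _TIE_TOL * (1.0 + np.abs(t_obs))
        ge += t_state >= t_obs - tol
        le += t_state <= t_obs + tol
    n_states = len(seen)
    return pd.DataFrame(
        {
            "t_obs": t_obs,
            "p_enrich": ge / n_states,
            "p_deplete": le / n_states,
            "n_states": n_states,
        },
        index=pd.Index(graph.families, name="family_id"),
    )


# ---------------------------------------------------------------------------
# all sets x all families
# ---------------------------------------------------------------------------


def test_all(
    predictions: TargetPredictionTable,
    sets: GeneSetCollection,
    n_perm: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
    burn_in: int | None = None,
    thin: int | None = None,
) -> pd.DataFrame:
    """Enrichment/depletion of every family's targets in every gene set.

    Sets are grouped by universe; per universe the conserved-sites graph
    drives the enrichment tail and the all-sites graph the depletion tail
    (each with its own chain). Raw empirical p-values are reported alongside
    BH q-values computed across families within each set and tail.
    """
    by_universe: dict[frozenset[str], list[str]] = {}
    for name in sets.sets:
        by_universe.setdefault(sets.universes[name], []).append(name)

    frames = []
    for batch_idx, (universe, names) in enumerate(
        sorted(by_universe.items(), key=lambda kv: sorted(kv[1]))
    ):
        gene_sets = [sets.sets[n] & universe for n in names]
        for mode, conserved_only in (("enrich", True), ("deplete", False)):
            graph = build_graph(predictions, universe, conserved_only=conserved_only)
            restricted = [frozenset(s) & set(graph.genes) for s in gene_sets]
            t_obs, p_enrich, p_deplete = sample_null_tails(
                graph,
                restricted,
                n_perm=n_perm,
                burn_in=burn_in,
                thin=thin,
                seed=_child_seed(seed, 101 + 2 * batch_idx + (0 if conserved_only else 1)),
            )
            p = p_enrich if mode == "enrich" else p_deplete
            frames.append(
                pd.DataFrame(
                    {
                        "family_id": np.repeat(graph.families, len(names)),
                        "set_name": np.tile(names, len(graph.families)),
                        f"t_obs_{mode}": t_obs.ravel(),
                        f"p_{mode}": p.ravel(),
                    }
                )
            )
    enrich = [f for f in frames if "p_enrich" in f.columns]
    deplete = [f for f in frames if "p_deplete" in f.columns]
    merged = pd.merge(
        pd.concat(enrich, ignore_index=True),
        pd.concat(deplete, ignore_index=True),
        on=["family_id", "set_name"],
        how="outer",
    )
    merged["n_perm"] = n_perm
    for tail in ("enrich", "deplete"):
        merged[f"q_{tail}"] = np.nan
        for name, idx in merged.groupby("set_name").groups.items():
            pvals = merged.loc[idx, f"p_{tail}"]
            ok = pvals.notna().to_numpy()
            if ok.any():
                merged.loc[idx[ok], f"q_{tail}"] = benjamini_hochberg(
                    pvals.to_numpy()[ok]
                )
    merged["direction"] = np.where(
        merged["p_enrich"] < alpha,
        "enriched",
        np.where(merged["p_deplete"] < alpha, "depleted", "none"),
    )
    return merged.sort_values(["set_name", "family_id"]).reset_index(drop=True)
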