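"""Signed, thresholded Spearman co-expression graphs.

An edge joins two genes when their Spearman correlation across samples
satisfies |rho| >= rho_cut and the multiplicity-adjusted p-value clears
alpha_edge.  Positive-edge connected components (optionally refined by
greedy modularity) play the role of co-expression "cliques"; genes
outside a community with several negative edges into it are negative
bridges — candidate antagonists of the community's shared program.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix

__all__ = [
    "CoexGraph",
    "CommunitySet",
    "spearman_matrix",
    "build_graph",
    "find_communities",
    "negative_bridges",
    "export_graph",
    "read_graphml",
]


def spearman_matrix(matrix: ExpressionMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs Spearman rho and two-sided p (t approximation).

    Ranks use average ties; p comes from t = rho * sqrt((n-2)/(1-rho^2))
    on n-2 df.  Constant features get NaN rho/p (excluded from graphs).
    Warns below 30 samples; errors below 10.
    """
    n = matrix.n_samples
    if n < 10:
        raise ValueError("need at least 10 samples for a correlation network")
    if n < 30:
        warnings.warn(f"only {n} samples: correlation estimates will be noisy")
    vals = matrix.values.to_numpy()
    const = np.ptp(vals, axis=1) == 0
    ranks = np.apply_along_axis(stats.rankdata, 1, vals)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(ranks)
    rho[const, :] = np.nan
    rho[:, const] = np.nan
    np.fill_diagonal(rho, np.where(const, np.nan, 1.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = rho * np.sqrt((n - 2) / np.clip(1 - rho**2, 1e-300, None))
        p = 2 * stats.t.sf(np.abs(t), n - 2)
    p[np.abs(rho) >= 1 - 1e-12] = 0.0
    p[np.isnan(rho)] = np.nan
    np.fill_diagonal(p, 0.0)
    ids = matrix.values.index
    return (
        pd.DataFrame(rho, index=ids, columns=ids),
        pd.DataFrame(p, index=ids, columns=ids),
    )


@dataclass
class CoexGraph:
    """Thresholded signed correlation graph plus derived annotations."""

    graph: nx.Graph
    rho_cut: float
    alpha_edge: float
    adjust: str
    n_samples: int
    communities: dict[str, int] = field(default_factory=dict)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def positive_subgraph(self) -> nx.Graph:
        pos = [(u, v) for u, v, d in self.graph.edges(data=True) if d["sign"] > 0]
        g = nx.Graph()
        g.add_nodes_from(self.graph.nodes(data=True))
        g.add_edges_from(
            (u, v, self.graph.edges[u, v]) for u, v in pos
        )
        return g

    def attach_hr_class(self, screen_table: pd.DataFrame) -> None:
        """Annotate nodes with the screen's prognosis class where known."""
        for node in self.graph.nodes:
            if node in screen_table.index:
                self.graph.nodes[node]["hr_class"] = str(
                    screen_table.loc[node, "prognosis_class"]
                )


def build_graph(
    rho: pd.DataFrame,
    p: pd.DataFrame,
    rho_cut: float = 0.6,
    adjust: str = "bonferroni",
    alpha_edge: float = 0.05,
    n_samples: int | None = None,
) -> CoexGraph:
    """Threshold a correlation matrix into a signed graph.

    p-values are adjusted over the n*(n-1)/2 unordered pairs
    (``bonferroni`` or ``bh``); an edge is kept iff |rho| >= rho_cut
    AND adjusted p <= alpha_edge.  NaN correlations (constant genes)
    never produce edges.
    """
    if not 0 < alpha_edge <= 1:
        raise ValueError("alpha_edge must lie in (0, 1]")
    if rho_cut <= 0:
        raise ValueError("rho_cut must be positive")
    ids = list(rho.index)
    R = rho.to_numpy()
    P = p.to_numpy()
    if R.shape != P.shape or R.shape[0] != R.shape[1]:
        raise ValueError("rho and p must be square and congruent")
    n = len(ids)
    iu = np.triu_indices(n, k=1)
    pu = P[iu]
    valid = ~np.isnan(pu)
    padj = np.full_like(pu, np.nan)
    if adjust == "bonferroni":
        padj[valid] = np.minimum(pu[valid] * valid.sum(), 1.0)
    elif adjust == "bh":
        padj[valid] = multipletests(pu[valid], method="fdr_bh")[1]
    elif adjust == "none":
        padj[valid] = pu[valid]
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    ru = R[iu]
    keep = valid & (np.abs(ru) >= rho_cut) & (padj <= alpha_edge)
    g = nx.Graph()
    g.add_nodes_from(ids)
    for a, b, r_ab, q_ab in zip(
        iu[0][keep], iu[1][keep], ru[keep], padj[keep]
    ):
        g.add_edge(
            ids[a],
            ids[b],
            rho=float(r_ab),
            sign=int(np.sign(r_ab)),
            adjusted_p=float(q_ab),
        )
    return CoexGraph(
        graph=g,
        rho_cut=rho_cut,
        alpha_edge=alpha_edge,
        adjust=adjust,
        n_samples=n_samples or 0,
    )


@dataclass
class CommunitySet:
    """Communities over the positive-edge subgraph.

    ``assignment`` covers every node with at least one positive edge;
    ``main`` lists the communities of size >= min_size (largest first);
    smaller components are background but keep an assignment index.
    """

    assignment: dict[str, int]
    main: list[set]
    min_size: int

    @property
    def n_main(self) -> int:
        return len(self.main)


def find_communities(
    coex: CoexGraph, min_size: int = 5, refine: bool = False
) -> CommunitySet:
    """Positive-edge connected components, optionally modularity-refined.

    With ``refine`` the components are re-partitioned by greedy
    modularity (which never splits a clique smaller than min_size in
    practice); without it the components themselves are the
    communities.
    """
    pos = coex.positive_subgraph()
    pos.remove_nodes_from([n for n in list(pos.nodes) if pos.degree(n) == 0])
    if refine and pos.number_of_edges() > 0:
        parts = list(nx.algorithms.community.greedy_modularity_communities(pos))
    else:
        parts = list(nx.connected_components(pos))
    parts.sort(key=lambda s: (-len(s), sorted(s)[0] if s else ""))
    assignment = {node: i for i, comp in enumerate(parts) for node in comp}
    main = [set(c) for c in parts if len(c) >= min_size]
    coex.communities = assignment
    return CommunitySet(assignment=assignment, main=main, min_size=min_size)


def negative_bridges(
    coex: CoexGraph, community: set, bridge_min: int = 3
) -> pd.DataFrame:
    """Genes outside ``community`` with >= bridge_min negative edges into it.

    Ranked by negative-degree into the community, then by mean |rho| of
    those edges.  Returns a table indexed by gene with columns
    ``neg_degree`` and ``mean_abs_rho``.
    """
    community = set(community)
    if not community <= set(coex.graph.nodes):
        raise ValueError("community contains unknown genes")
    rows = []
    for node in coex.graph.nodes:
        if node in community:
            continue
        rhos = [
            d["rho"]
            for _, v, d in coex.graph.edges(node, data=True)
            if v in community and d["sign"] < 0
        ]
        if len(rhos) >= bridge_min:
            rows.append((node, len(rhos), float(np.mean(np.abs(rhos)))))
    out = pd.DataFrame(rows, columns=["gene", "neg_degree", "mean_abs_rho"]).set_index(
        "gene"
    )
    return out.sort_values(["neg_degree", "mean_abs_rho"], ascending=False)


def export_graph(coex: CoexGraph, path: str, fmt: str = "graphml") -> None:
    """Write the graph as GraphML or a 3-column edge-list TSV.

    GraphML keeps all node/edge attributes (rho, sign, adjusted_p,
    community, hr_class) and round-trips losslessly through
    :func:`read_graphml`.
    """
    g = coex.graph.copy()
    for node, comm in coex.communities.items():
        g.nodes[node]["community"] = int(comm)
    if fmt == "graphml":
        nx.write_graphml(g, path)
    elif fmt == "edgelist_tsv":
        with open(path, "w") as fh:
            fh.write("source\ttarget\trho\n")
            for u, v, d in g.edges(data=True):
                fh.write(f"{u}\t{v}\t{d['rho']:.6g}\n")
    else:
        raise ValueError(f"unknown export format {fmt!r}")


def read_graphml(path: str) -> nx.Graph:
    return nx.read_graphml(path)
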