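"""PPI subnetworks, MCODE clustering, metastructures and the random null.

The analysis induces a subnetwork of the query genes on a STRING-style edge
list (confidence scores 0-1000, default cutoff 400 = "medium"), gates on a
network-connectivity enrichment p-value (< 1e-16, strictly) and partitions
the surviving graph with MCODE (Bader & Hogue's molecular-complex detection):

1. *Vertex weighting* — each vertex's closed neighborhood is reduced to its
   highest k-core; the weight is k times the density of that core. Vertices
   with degree below ``degree_cutoff`` weigh 0.
2. *Complex prediction* — seed at the highest-weight unassigned vertex and
   grow breadth-first, admitting neighbors whose weight is at least
   (1 - node_score_cutoff) x seed weight, never reusing vertices consumed by
   an earlier complex.
3. *Post-processing* — complexes without a ``k_core``-core are dropped;
   the haircut removes singly-connected members (one pass).

Note that growth is thresholded against the *seed* weight, so two equally
dense modules joined by even a single edge between high-weight vertices merge
into one complex; separability of clusters comes from weight heterogeneity
at module boundaries, as in real protein networks.

The connectivity gate uses a degree-product (Chung-Lu) null: the expected
edge count among the query nodes is lambda = sum over pairs of
min(1, k_u k_v / 2m) with degrees and edge count from the background
network, and the p-value is the upper Poisson tail of the observed count.
This approximates STRING's (unpublished) internal null; the printed gate
threshold is kept verbatim.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import AnnotationLibrary, enrich_categories, top_enriched

__all__ = [
    "OVERALL_GROUPS",
    "PPI_GATE_P",
    "ClusterReport",
    "build_subnetwork",
    "ppi_enrichment_p",
    "mcode_vertex_weights",
    "mcode",
    "metastructure",
    "compare_to_random",
    "annotate_clusters",
    "category_fractions",
    "default_group_map",
]

PPI_GATE_P = 1e-16
OVERALL_GROUPS = ["immune", "tissue repair", "metabolic", "motility", "cell stress", "general"]


def build_subnetwork(genes: set[str], edge_table: pd.DataFrame, min_score: float = 400) -> nx.Graph:
    """Induced simple subgraph on ``genes`` keeping edges with score >= min_score.

    Duplicate and reciprocal rows collapse (highest score wins); self-loops drop.
    """
    G = nx.Graph()
    G.add_nodes_from(sorted(set(genes) & (set(edge_table["node1"]) | set(edge_table["node2"]))))
    for row in edge_table.itertuples(index=False):
        u, v, s = row.node1, row.node2, float(row.combined_score)
        if u == v or s < min_score:
            continue
        if u in G and v in G:
            if G.has_edge(u, v):
                G[u][v]["combined_score"] = max(G[u][v]["combined_score"], s)
            else:
                G.add_edge(u, v, combined_score=s)
    return G


def ppi_enrichment_p(sub: nx.Graph, background: nx.Graph) -> float:
    """Upper-tail Poisson p-value for the observed edge count among sub nodes.

    Contract: fewer than 2 nodes (or an edgeless background) gives p = 1.
    """
    extra = set(sub.nodes) - set(background.nodes)
    if extra:
        raise ValueError(f"subnetwork nodes missing from background: {sorted(extra)[:5]}")
    if sub.number_of_nodes() < 2:
        return 1.0
    m = background.number_of_edges()
    if m == 0:
        return 1.0
    nodes = sorted(sub.nodes)
    k = np.array([background.degree(v) for v in nodes], dtype=float)
    prod = np.outer(k, k) / (2.0 * m)
    iu = np.triu_indices(len(nodes), 1)
    lam = float(np.minimum(1.0, prod[iu]).sum())
    obs = sub.number_of_edges()
    return float(stats.poisson.sf(obs - 1, lam))


def mcode_vertex_weights(G: nx.Graph, degree_cutoff: int = 2) -> dict:
    """MCODE vertex weights: core number x density of the closed-neighborhood core."""
    w = {}
    for v in G.nodes:
        if G.degree(v) < degree_cutoff:
            w[v] = 0.0
            continue
        nbhd = G.subgraph(set(G[v]) | {v})
        core = nx.core_number(nbhd)
        k = max(core.values())
        if k == 0:
            w[v] = 0.0
            continue
        core_nodes = [u for u, c in core.items() if c >= k]
        H = nbhd.subgraph(core_nodes)
        n = H.number_of_nodes()
        dens = 2.0 * H.number_of_edges() / (n * (n - 1)) if n > 1 else 0.0
        w[v] = float(k * dens)
    return w


@dataclass
class ClusterReport:
    cluster_id: int
    members: tuple
    seed: str
    seed_weight: float
    score: float
    size: int
    intra_edges: int = 0
    inter_edges: dict = field(default_factory=dict)
    top_categories: list = field(default_factory=list)
    overall_group: str = "general"


def mcode(
    G: nx.Graph,
    degree_cutoff: int = 2,
    node_score_cutoff: float = 0.2,
    k_core: int = 2,
    max_depth: int = 100,
    haircut: bool = True,
    fluff: bool = False,
) -> list[ClusterReport]:
    """Partition a simple graph into MCODE complexes (see module docstring).

    Deterministic: seeds and BFS exploration order ties break lexicographically
    by node label. Returns disjoint clusters sorted by score = seed weight x
    size (descending), then seed label. ``fluff`` is accepted for parameter
    parity but not implemented (the analysis never enables it).
    """
    if fluff:
        raise NotImplementedError("fluff post-processing is not used by this analysis")
    weights = mcode_vertex_weights(G, degree_cutoff)
    assigned: set = set()
    complexes: list[tuple[str, float, set]] = []
    for seed in sorted(G.nodes, key=lambda v: (-weights[v], str(v))):
        if seed in assigned:
            continue
        thr = (1.0 - node_score_cutoff) * weights[seed]
        members = {seed}
        frontier = [seed]
        depth = 0
        while frontier and depth < max_depth:
            nxt = []
            for u in sorted(frontier, key=str):
                for v in sorted(G[u], key=str):
                    if v in assigned or v in members:
                        continue
                    if weights[v] >= thr:
                        members.add(v)
                        nxt.append(v)
            frontier = nxt
            depth += 1
        assigned |= members  # consumed even if the complex is filtered below
        sub = G.subgraph(members)
        if len(nx.k_core(sub, k=k_core)) == 0:
            continue
        if haircut:
            keep = {v for v in members if sub.degree(v) >= 2}
            if seed not in keep:  # haircut never orphans the seed's complex silently
                keep.add(seed)
            members = keep
        complexes.append((seed, weights[seed], members))
    reports = []
    ordered = sorted(complexes, key=lambda t: (-(t[1] * len(t[2])), str(t[0])))
    for i, (seed, w, members) in enumerate(ordered, start=1):
        reports.append(
            ClusterReport(
                cluster_id=i,
                members=tuple(sorted(members, key=str)),
                seed=seed,
                seed_weight=w,
                score=w * len(members),
                size=len(members),
            )
        )
    return reports


def metastructure(clusters: list[ClusterReport], net: nx.Graph) -> pd.DataFrame:
    """Fill per-cluster size/intra/inter counts and assert edge conservation.

    Every edge is either inside one cluster, between two clusters, or touches
    an unclustered node; the three tallies must sum to the edge count.
    """
    node2cluster = {}
    for c in clusters:
        for v in c.members:
            node2cluster[v] = c.cluster_id
    intra = {c.cluster_id: 0 for c in clusters}
    inter: dict[int, dict[int, int]] = {c.cluster_id: {} for c in clusters}
    unclustered_incident = 0
    for u, v in net.edges:
        cu, cv = node2cluster.get(u), node2cluster.get(v)
        if cu is None or cv is None:
            unclustered_incident += 1
        elif cu == cv:
            intra[cu] += 1
        else:
            inter[cu][cv] = inter[cu].get(cv, 0) + 1
            inter[cv][cu] = inter[cv].get(cu, 0) + 1
    total_inter_pairs = sum(sum(d.values()) for d in inter.values()) // 2
    assert sum(intra.values()) + total_inter_pairs + unclustered_incident == net.number_of_edges()
    rows = []
    for c in clusters:
        c.intra_edges = intra[c.cluster_id]
        c.inter_edges = dict(sorted(inter[c.cluster_id].items()))
        rows.append(
            {
                "cluster_id": c.cluster_id,
                "seed": c.seed,
                "size": c.size,
                "intra": c.intra_edges,
                "inter": sum(c.inter_edges.values()),
                "score": c.score,
            }
        )
    out = pd.DataFrame(rows, columns=["cluster_id", "seed", "size", "intra", "inter", "score"])
    out.attrs["unclustered_incident_edges"] = unclustered_incident
    return out


def _welch_row(a: np.ndarray, b: np.ndarray) -> dict:
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    diff = a.mean() - b.mean()
    se2 = va / na + vb / nb
    if se2 == 0.0:
        # degenerate zero-variance contract: exact equality test
        equal = diff == 0.0
        return {"t": 0.0 if equal else np.inf * np.sign(diff), "df": np.nan,
                "p": 1.0 if equal else 0.0, "ci_low": diff, "ci_high": diff}
    t = diff / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    half = stats.t.ppf(0.975, df) * np.sqrt(se2)
    return {"t": float(t), "df": float(df), "p": float(p),
            "ci_low": float(diff - half), "ci_high": float(diff + half)}


def compare_to_random(
    real_stats: pd.DataFrame,
    random_stats: pd.DataFrame,
    metrics: tuple[str, ...] = ("size", "intra", "inter"),
) -> pd.DataFrame:
    """Welch's t-test per metastructure metric, real clusters vs random-gene clusters."""
    rows = []
    for m in metrics:
        a = real_stats[m].to_numpy(dtype=float)
        b = random_stats[m].to_numpy(dtype=float)
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"metric {m!r}: need >= 2 clusters on both sides (got {len(a)} vs {len(b)})")
        row = {"metric": m, "mean_real": float(a.mean()), "mean_random": float(b.mean())}
        row.update(_welch_row(a, b))
        rows.append(row)
    return pd.DataFrame(rows)


def default_group_map(categories, groups: list[str] = OVERALL_GROUPS) -> dict[str, str]:
    """Round-robin category -> overall-group map for synthetic annotation schemes."""
    return {cat: groups[i % len(groups)] for i, cat in enumerate(sorted(categories))}


def annotate_clusters(
    clusters: list[ClusterReport],
    library: AnnotationLibrary,
    group_map: dict[str, str],
    top_k: int = 3,
) -> list[ClusterReport]:
    """Fill per-cluster top enriched categories and a curated-style overall group.

    The overall group is the majority overall-group of annotated members
    (falling back to 'general'), standing in for the curator judgment the
    published metastructures relied on.
    """
    for c in clusters:
        members = set(c.members) & library.universe
        if members:
            res = enrich_categories(members, library)
            c.top_categories = top_enriched(res, top_k)["category"].tolist()
        votes: dict[str, int] = {}
        for g in members:
            for cat in library.memberships.get(g, ()):
                if cat not in group_map:
                    raise ValueError(f"category {cat!r} missing from group map")
                grp = group_map[cat]
                votes[grp] = votes.get(grp, 0) + 1
        c.overall_group = min(votes, key=lambda g: (-votes[g], g)) if votes else "general"
    return clusters


def category_fractions(genes, library: AnnotationLibrary, group_map: dict[str, str]) -> pd.Series:
    """Percent of annotated genes per overall functional group (sums to 100)."""
    genes = list(genes)
    if not genes:
        raise ValueError("empty gene list")
    unmapped = sorted(set(library.categories) - set(group_map))
    if unmapped:
        raise ValueError(f"categories missing from group map: {unmapped[:10]}")
    counts = {g: 0 for g in sorted(set(group_map.values()))}
    annotated = 0
    for gene in genes:
        cats = library.memberships.get(gene)
        if not cats:
            continue
        annotated += 1
        # an exclusive scheme has exactly one category; otherwise split the vote
        for cat in cats:
            counts[group_map[cat]] += 1 / len(cats)
    if annotated == 0:
        raise ValueError("no input gene is annotated in the library")
    return pd.Series({g: 100.0 * c / annotated for g, c in counts.items()}, name="percent")
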