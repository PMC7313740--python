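"""Tissue-network connectivity between CNV genes and signaling pathways.

Probabilistic tissue networks (per-edge posterior probability of a
functional interaction) are thresholded at a strict posterior cutoff,
traversed with Dijkstra's algorithm using inverse-posterior edge weights,
and summarized as connectivity = 1 / (weighted shortest-path length) for
every (CNV gene, pathway gene) pair.  Interior nodes of the canonical
shortest path are the pair's connector genes; connector sets are tested for
annotation-term over-representation with one-tailed Fisher exact tests.

The canonical path among ties is the lexicographically smallest node
sequence, which makes connector extraction deterministic across runs and
platforms.  ``connectors="union"`` instead collects the interior nodes of
every tied shortest path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd

from .stats import FisherResult, bh_adjust, fisher_2x2, welch_t

#: Relative tolerance when comparing float path lengths for tie detection.
_REL_TOL = 1e-9


def threshold_network(
    edges: pd.DataFrame,
    p_min: float = 0.2,
    tissue: str = "",
) -> nx.Graph:
    """Build a tissue network keeping only edges with posterior > ``p_min``.

    ``edges`` columns: gene_a, gene_b, posterior.  Retained edges carry
    ``posterior`` and traversal ``weight`` = 1/posterior attributes; nodes
    with no retained edge are dropped.
    """
    need = {"gene_a", "gene_b", "posterior"}
    missing = need - set(edges.columns)
    if missing:
        raise ValueError(f"edge list missing columns: {sorted(missing)}")
    post = edges["posterior"].to_numpy(dtype=float)
    if ((post < 0) | (post > 1)).any():
        raise ValueError("posterior probabilities must lie in [0, 1]")
    kept = edges[post > p_min]
    if kept.empty:
        raise ValueError(
            f"no edges with posterior > {p_min}; lower the threshold"
        )
    g = nx.Graph(tissue=tissue)
    for a, b, p in kept[["gene_a", "gene_b", "posterior"]].itertuples(index=False):
        if a == b:
            continue
        p = float(p)
        if g.has_edge(a, b):
            p = max(p, g[a][b]["posterior"])
        g.add_edge(a, b, posterior=p, weight=1.0 / p)
    return g


@dataclass
class PathResult:
    source: str
    target: str
    length: float           # sum of inverse-posterior weights; inf if unreachable
    connectivity: float     # 1/length; 0 if unreachable
    connectors: list[str] = field(default_factory=list)
    reachable: bool = True
    path: list[str] = field(default_factory=list)


def _close(a: float, b: float) -> bool:
    return abs(a - b) <= _REL_TOL * max(1.0, abs(a), abs(b))


def _lexicographic_path(g: nx.Graph, source: str, target: str, dist_t: dict) -> list[str]:
    """Walk the lexicographically smallest shortest path from source to target.

    ``dist_t`` holds Dijkstra distances from the target.  At each step, among
    neighbors that remain on some shortest path (w(u,v) + d_t(v) == d_t(u)),
    the smallest node name is taken; greedy smallest-next-node yields the
    lexicographically smallest full sequence.
    """
    path = [source]
    current = source
    while current != target:
        best = None
        for nbr in g.neighbors(current):
            if nbr not in dist_t:
                continue
            if _close(g[current][nbr]["weight"] + dist_t[nbr], dist_t[current]):
                if best is None or str(nbr) < str(best):
                    best = nbr
        if best is None:  # numeric safety net; cannot happen on consistent input
            raise RuntimeError("shortest-path walk lost track of the route")
        path.append(best)
        current = best
    return path


def shortest_path(
    g: nx.Graph,
    source: str,
    target: str,
    connectors: str = "canonical",
) -> PathResult:
    """Weighted shortest path between two genes with deterministic tie-break.

    Connectivity is 1/length, so a direct edge that is itself the shortest
    path has connectivity equal to its posterior.  Missing or disconnected
    endpoints give an unreachable result (length inf, connectivity 0) with a
    warning rather than an error.
    """
    if source == target:
        raise ValueError("source and target must differ")
    if source not in g or target not in g:
        warnings.warn(
            f"node missing from network: "
            f"{[n for n in (source, target) if n not in g]}",
            stacklevel=2,
        )
        return PathResult(source, target, float("inf"), 0.0, [], reachable=False)
    dist_t = nx.single_source_dijkstra_path_length(g, target, weight="weight")
    if source not in dist_t:
        return PathResult(source, target, float("inf"), 0.0, [], reachable=False)
    length = float(dist_t[source])
    path = _lexicographic_path(g, source, target, dist_t)
    if connectors == "union":
        dist_s = nx.single_source_dijkstra_path_length(g, source, weight="weight")
        interior = sorted(
            n
            for n in g.nodes
            if n not in (source, target)
            and n in dist_s
            and n in dist_t
            and _close(dist_s[n] + dist_t[n], length)
        )
    elif connectors == "canonical":
        interior = path[1:-1]
    else:
        raise ValueError("connectors must be 'canonical' or 'union'")
    return PathResult(
        source,
        target,
        length,
        1.0 / length,
        list(interior),
        reachable=True,
        path=path,
    )


def pairwise_connectivity(
    g: nx.Graph,
    cnv_genes,
    pathway_genes,
    connectors: str = "canonical",
) -> pd.DataFrame:
    """Shortest-path connectivity for every (CNV gene, pathway gene) pair.

    Genes absent from the network are excluded (logged); genes belonging to
    both sets are skipped as degenerate source-target pairs.  Raises when
    either set has no gene left in the network.
    """
    cnv = sorted(set(cnv_genes))
    pathway = sorted(set(pathway_genes))
    overlap = set(cnv) & set(pathway)
    if overlap:
        warnings.warn(
            f"genes in both CNV and pathway sets skipped: {sorted(overlap)}",
            stacklevel=2,
        )
    cnv_in = [x for x in cnv if x in g and x not in overlap]
    path_in = [x for x in pathway if x in g and x not in overlap]
    missing = [x for x in cnv + pathway if x not in g]
    if missing:
        warnings.warn(
            f"{len(missing)} genes absent from network excluded: {missing[:5]}",
            stacklevel=2,
        )
    if not cnv_in or not path_in:
        raise ValueError(
            f"no pairs to test; genes missing from network: {missing}"
        )
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for s in cnv_in:
            for t in path_in:
                r = shortest_path(g, s, t, connectors=connectors)
                rows.append(
                    {
                        "source": s,
                        "target": t,
                        "length": r.length,
                        "connectivity": r.connectivity,
                        "reachable": r.reachable,
                        "connectors": ";".join(r.connectors),
                    }
                )
    return pd.DataFrame(rows)


def connector_union(results: pd.DataFrame) -> set[str]:
    """All connector genes appearing in a pairwise-connectivity table."""
    out: set[str] = set()
    for s in results.loc[results["reachable"], "connectors"]:
        if s:
            out.update(s.split(";"))
    return out


def compare_tissue_connectivity(
    connectivity: dict[str, dict[str, np.ndarray]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Welch t-tests of connectivity between tissues, per pathway.

    ``connectivity[tissue][pathway]`` holds the reachable pairs'
    connectivity values.  Every tissue pair is tested within each pathway;
    BH correction runs across all comparisons in the table.  Groups smaller
    than 2 are skipped with a warning.
    """
    rows = []
    tissues = sorted(connectivity)
    pathways = sorted({p for t in tissues for p in connectivity[t]})
    for pathway in pathways:
        for t1, t2 in combinations(tissues, 2):
            a = np.asarray(connectivity.get(t1, {}).get(pathway, []), dtype=float)
            b = np.asarray(connectivity.get(t2, {}).get(pathway, []), dtype=float)
            if a.size < 2 or b.size < 2:
                warnings.warn(
                    f"skipping {pathway}: {t1} vs {t2} (group too small)",
                    stacklevel=2,
                )
                continue
            res = welch_t(a, b)
            rows.append(
                {
                    "pathway": pathway,
                    "tissue_a": t1,
                    "tissue_b": t2,
                    "mean_a": float(a.mean()),
                    "mean_b": float(b.mean()),
                    "n_a": a.size,
                    "n_b": b.size,
                    "t": res.t,
                    "df": res.df,
                    "p": res.p,
                }
            )
    out = pd.DataFrame(rows)
    if not out.empty:
        out["q"] = bh_adjust(out["p"])
        out["significant"] = out["q"] < alpha
    return out


@dataclass
class EnrichmentResult:
    term: str
    n_connectors_with: int
    n_connectors: int
    n_background_with: int
    n_background: int
    fisher: FisherResult
    q: float = float("nan")


def enrich_connectors(
    connectors,
    annotations: dict[str, set],
    background,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """One-tailed Fisher over-representation of annotation terms in connectors.

    ``annotations`` maps gene to its terms; ``background`` is the annotation
    universe (all annotated network nodes) and must contain the connectors.
    BH correction runs across terms.  An empty connector set returns an
    empty list with a warning.
    """
    connectors = set(connectors)
    background = set(background)
    if not connectors:
        warnings.warn("empty connector set; no enrichment computed", stacklevel=2)
        return []
    if not connectors <= background:
        raise ValueError(
            f"connectors outside background: {sorted(connectors - background)[:5]}"
        )
    terms = sorted({t for g in background for t in annotations.get(g, ())})
    results = []
    non_connectors = background - connectors
    for term in terms:
        with_term = {g for g in background if term in annotations.get(g, ())}
        a = len(connectors & with_term)
        b = len(connectors - with_term)
        c = len(non_connectors & with_term)
        d = len(non_connectors - with_term)
        fr = fisher_2x2([[a, b], [c, d]], alternative="greater")
        results.append(
            EnrichmentResult(
                term=term,
                n_connectors_with=a,
                n_connectors=len(connectors),
                n_background_with=len(with_term),
                n_background=len(background),
                fisher=fr,
            )
        )
    qs = bh_adjust([r.fisher.p for r in results])
    for r, q in zip(results, qs):
        r.q = float(q)
    return results
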