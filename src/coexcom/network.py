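"""Significance-filtered, correlation-weighted gene co-expression graph.

Two genes are linked when the two-sided test of their Pearson correlation
rejects zero correlation at the configured level (default 0.01, i.e. the 99%
confidence interval excludes zero).  The clustering weight is ``|r|`` so the
community-detection quality function sees nonnegative weights; the signed
correlation is kept as the edge attribute ``r``.

Graphs are ``igraph.Graph`` objects with vertex attribute ``name`` (gene id)
and edge attributes ``r``, ``weight``, ``p``.
"""

from __future__ import annotations

import logging

import igraph as ig
import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

EDGE_COLUMNS = ("gene_a", "gene_b", "r", "weight", "p")


def correlation_pvalues(r: np.ndarray, n_samples: int) -> np.ndarray:
    """Two-sided p-values for H0: rho = 0 via t = r*sqrt((n-2)/(1-r^2))."""
    df = n_samples - 2
    rr = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rr * np.sqrt(df / (1.0 - rr * rr))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    # |r| = 1 gives t -> inf hence p -> 0
    p = np.where(np.isclose(np.abs(rr), 1.0), 0.0, p)
    return p


def build_network(matrix: pd.DataFrame, alpha: float = 0.01) -> ig.Graph:
    """Build the co-expression graph from a genes x samples matrix.

    Constant genes (zero variance) cannot carry a correlation and are
    dropped with a warning.  Requires at least 4 samples so the t-test has
    at least 2 degrees of freedom.
    """
    if matrix.shape[1] < 4:
        raise ValueError("network construction needs at least 4 samples")
    values = matrix.to_numpy(dtype=float)
    sds = values.std(axis=1)
    keep = sds > 0
    if not keep.any():
        raise ValueError("all genes are constant; cannot build a network")
    if (~keep).sum():
        dropped = list(matrix.index[~keep][:5])
        logger.warning("dropping %d constant gene(s), e.g. %s", (~keep).sum(), dropped)
    genes = list(matrix.index[keep])
    values = values[keep]

    r = np.corrcoef(values)
    np.fill_diagonal(r, 0.0)
    p = correlation_pvalues(r, matrix.shape[1])
    ia, ja = np.triu_indices(len(genes), k=1)
    mask = p[ia, ja] < alpha
    ia, ja = ia[mask], ja[mask]

    graph = ig.Graph(n=len(genes), edges=list(zip(ia.tolist(), ja.tolist())),
                     directed=False)
    graph.vs["name"] = genes
    graph.es["r"] = r[ia, ja].tolist()
    graph.es["weight"] = np.abs(r[ia, ja]).tolist()
    graph.es["p"] = p[ia, ja].tolist()
    logger.info("network: %d genes, %d edges (alpha=%g)",
                graph.vcount(), graph.ecount(), alpha)
    return graph


def induced_subgraph(graph: ig.Graph, genes) -> ig.Graph:
    """Subgraph on the listed genes; edge attributes are NOT recomputed."""
    names = set(graph.vs["name"])
    genes = list(genes)
    unknown = [g for g in genes if g not in names]
    if unknown:
        raise ValueError(f"unknown gene(s): {unknown[:5]}")
    return graph.induced_subgraph(graph.vs.select(name_in=set(genes)))


def graph_summary(graph: ig.Graph) -> dict:
    n, m = graph.vcount(), graph.ecount()
    density = 0.0 if n < 2 else 2.0 * m / (n * (n - 1))
    return {"n_nodes": n, "n_edges": m, "density": density}


def write_edge_list(graph: ig.Graph, path) -> None:
    """Edge-list TSV: gene_a, gene_b, r, weight, p (12 significant digits)."""
    with open(path, "w") as fh:
        fh.write("\t".join(EDGE_COLUMNS) + "\n")
        names = graph.vs["name"]
        for e in graph.es:
            a, b = names[e.source], names[e.target]
            fh.write(f"{a}\t{b}\t{e['r']:.12g}\t{e['weight']:.12g}\t{e['p']:.12g}\n")


def read_edge_list(path, nodes=None) -> ig.Graph:
    """Read an edge-list TSV written by :func:`write_edge_list`.

    ``nodes`` optionally supplies the full vertex set (isolated genes do not
    appear on any edge row).  Duplicate unordered pairs are a parse error.
    """
    edges, attrs, seen = [], {"r": [], "weight": [], "p": []}, set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != list(EDGE_COLUMNS):
            raise ValueError(f"bad edge-list header: {header}")
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 5:
                raise ValueError(f"malformed edge row at line {lineno}")
            a, b, r, w, p = parts
            key = (min(a, b), max(a, b))
            if key in seen:
                raise ValueError(f"duplicate gene pair {key} at line {lineno}")
            seen.add(key)
            edges.append((a, b))
            try:
                attrs["r"].append(float(r))
                attrs["weight"].append(float(w))
                attrs["p"].append(float(p))
            except ValueError as exc:
                raise ValueError(f"malformed numeric field at line {lineno}") from exc
    names = list(nodes) if nodes is not None else sorted({g for e in edges for g in e})
    index = {g: i for i, g in enumerate(names)}
    graph = ig.Graph(n=len(names),
                     edges=[(index[a], index[b]) for a, b in edges],
                     directed=False)
    graph.vs["name"] = names
    for key, vals in attrs.items():
        graph.es[key] = vals
    return graph
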