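"""Hypergeometric over-representation of communities against gene sets.

The sampling frame (universe) is the set of genes in the co-expression
network, since communities can only draw from those genes.  For a community
of n genes and an annotation set covering K universe genes, the upper-tail
p-value is P(X >= k) with X ~ Hypergeometric(N_u, K, n) and k the observed
overlap.  Multi-set collections are Bonferroni-corrected within community
(p_bonferroni = min(1, m * p) for m sets tested).
"""

from __future__ import annotations

import dataclasses

from scipy import stats


@dataclasses.dataclass
class EnrichmentResult:
    community_id: str
    set_name: str
    universe_size: int
    set_size: int
    community_size: int
    overlap: int
    overlap_genes: list
    p: float
    p_bonferroni: float
    significant_raw: bool
    significant_bonferroni: bool

    def to_row(self) -> dict:
        d = dataclasses.asdict(self)
        d["overlap_genes"] = ",".join(self.overlap_genes)
        return d


def read_gmt(path) -> dict:
    """Read a GMT file: name, description, tab-separated genes per line."""
    sets: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"GMT line {lineno} has fewer than 3 fields")
            name = parts[0]
            if name in sets:
                raise ValueError(f"duplicate gene-set name {name!r} at line {lineno}")
            genes = {g for g in parts[2:] if g}
            if not genes:
                raise ValueError(f"gene set {name!r} at line {lineno} is empty")
            sets[name] = genes
    return sets


def write_gmt(sets: dict, path, description: str = "") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *sorted(genes)]) + "\n")


def hypergeometric_overrep(community_genes, annotation_set, universe,
                           community_id: str = "", set_name: str = "",
                           alpha_raw: float = 0.01,
                           n_sets_tested: int = 1,
                           alpha_bonferroni: float = 0.05) -> EnrichmentResult:
    """Exact upper-tail hypergeometric test of one community against one set."""
    universe = set(universe)
    community = set(community_genes)
    outside = community - universe
    if outside:
        raise ValueError(f"community genes outside the universe: {sorted(outside)[:5]}")
    annotation = set(annotation_set) & universe
    overlap = sorted(community & annotation)
    n_u, big_k, n = len(universe), len(annotation), len(community)
    k = len(overlap)
    # P(X >= k); sf(k-1) is the exact tail sum
    p = float(stats.hypergeom.sf(k - 1, n_u, big_k, n))
    p = min(1.0, max(p, 0.0))
    p_bonf = min(1.0, p * n_sets_tested)
    return EnrichmentResult(
        community_id=community_id,
        set_name=set_name,
        universe_size=n_u,
        set_size=big_k,
        community_size=n,
        overlap=k,
        overlap_genes=overlap,
        p=p,
        p_bonferroni=p_bonf,
        significant_raw=p < alpha_raw,
        significant_bonferroni=p_bonf < alpha_bonferroni,
    )


def enrich_all(communities: dict, collection: dict, universe,
               alpha_raw: float = 0.01, alpha_bonferroni: float = 0.05):
    """Test every (community, gene set) pair.

    ``communities`` maps community id -> gene list; ``collection`` maps set
    name -> gene set.  With a single-set collection (the curated disease-gene
    list case) the Bonferroni-corrected p equals the raw p and significance
    is effectively judged at the raw level.
    """
    if not communities or not collection:
        raise ValueError("communities and collection must be nonempty")
    if not set(universe):
        raise ValueError("empty universe")
    m = len(collection)
    results = []
    for cid in sorted(communities):
        for name in sorted(collection):
            results.append(hypergeometric_overrep(
                communities[cid], collection[name], universe,
                community_id=cid, set_name=name,
                alpha_raw=alpha_raw, n_sets_tested=m,
                alpha_bonferroni=alpha_bonferroni,
            ))
    return results
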