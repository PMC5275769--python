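"""Union-target pathway enrichment with a random-miRNA-set negative control.

The target genes of a miRNA signature are pooled (union) and tested for
over-representation in each pathway with the one-sided hypergeometric test
(identical to Fisher's one-sided exact test).  Because curated miRNA-target
databases are over-weighted with cancer and cell-cycle pathways, many
pathways reach significance for *any* miRNA set; the negative-control filter
repeats the analysis for seeded random miRNA sets (default: 20 sets of 11)
and retains only query pathways that never reach the significance cutoff in
any random run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import PipelineError

logger = logging.getLogger(__name__)

#: negative-control defaults: 20 random sets matching the 11-miRNA signature,
#: significance cutoff P < 1e-6
DEFAULT_N_SETS = 20
DEFAULT_SET_SIZE = 11
DEFAULT_P_CUTOFF = 1e-6


@dataclass
class NullFilterReport:
    """Outcome of the random-set negative-control filter."""

    query_pathways: list[str]  # significant for the query at p_cutoff
    null_hit_counts: dict[str, int]  # pathway → #null runs reaching p_cutoff
    retained: list[str]  # query pathways with zero null hits
    enrichment: pd.DataFrame  # full query EnrichmentResult table
    parameters: dict = field(default_factory=dict)


def union_targets(mirnas, target_map: dict[str, set[str]]) -> set[str]:
    """Union of the target sets of the given miRNAs; unmapped ones are logged."""
    out: set[str] = set()
    for m in mirnas:
        if m in target_map:
            out |= target_map[m]
        else:
            logger.warning("miRNA %s has no entry in the target map", m)
    return out


def enrich(
    gene_set: set[str],
    pathways: dict[str, tuple[str, set[str]]],
    universe: set[str],
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of ``gene_set`` in each pathway.

    Pathways and the gene set are intersected with the universe first.
    Returns a DataFrame indexed by pathway with columns ``k`` (overlap),
    ``K`` (pathway size in universe), ``n`` (gene-set size in universe),
    ``N`` (universe size), and ``p`` = P(X ≥ k).
    """
    if not universe:
        raise PipelineError("gene universe is empty")
    gs = gene_set & universe
    N, n = len(universe), len(gs)
    rows = []
    for pw, (_, genes) in pathways.items():
        members = genes & universe
        K = len(members)
        k = len(gs & members)
        # upper tail P(X >= k); sf(k-1) so k = 0 gives exactly 1
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append((pw, k, K, n, N, min(max(p, 0.0), 1.0)))
    df = pd.DataFrame(rows, columns=["pathway", "k", "K", "n", "N", "p"])
    return df.set_index("pathway")


def default_gene_universe(
    target_map: dict[str, set[str]],
    pathways: dict[str, tuple[str, set[str]]],
) -> set[str]:
    """Union of all pathway genes and all mapped target genes."""
    universe: set[str] = set()
    for genes in target_map.values():
        universe |= genes
    for _, genes in pathways.values():
        universe |= genes
    return universe


def random_null_filter(
    query_mirnas,
    target_map: dict[str, set[str]],
    pathways: dict[str, tuple[str, set[str]]],
    mirna_universe,
    n_sets: int = DEFAULT_N_SETS,
    set_size: int = DEFAULT_SET_SIZE,
    p_cutoff: float = DEFAULT_P_CUTOFF,
    seed: int = 0,
    gene_universe: set[str] | None = None,
    exclude_query: bool = False,
    max_null_hits: int = 0,
) -> NullFilterReport:
    """Enrichment of the query signature filtered by random-set negative controls.

    Draws ``n_sets`` seeded random sets of ``set_size`` miRNAs (without
    replacement within a draw) from ``mirna_universe``, runs the same
    union-target enrichment on each, and retains the query's significant
    pathways that pass ``p_cutoff`` in at most ``max_null_hits`` (default 0)
    null runs.  ``exclude_query=True`` removes the query miRNAs from the
    draw universe.
    """
    mirna_universe = sorted(set(mirna_universe))
    query = list(query_mirnas)
    if exclude_query:
        mirna_universe = [m for m in mirna_universe if m not in set(query)]
    if set_size > len(mirna_universe):
        raise PipelineError(
            f"set_size {set_size} exceeds the miRNA universe ({len(mirna_universe)})"
        )
    if n_sets < 0:
        raise PipelineError("n_sets must be ≥ 0")
    universe = gene_universe or default_gene_universe(target_map, pathways)

    query_table = enrich(union_targets(query, target_map), pathways, universe)
    query_sig = list(query_table.index[query_table["p"] < p_cutoff])

    rng = np.random.default_rng(seed)
    null_hits = {pw: 0 for pw in pathways}
    for _ in range(n_sets):
        draw = rng.choice(mirna_universe, size=set_size, replace=False)
        table = enrich(union_targets(draw, target_map), pathways, universe)
        for pw in table.index[table["p"] < p_cutoff]:
            null_hits[pw] += 1

    retained = [pw for pw in query_sig if null_hits[pw] <= max_null_hits]
    return NullFilterReport(
        query_pathways=query_sig,
        null_hit_counts=null_hits,
        retained=retained,
        enrichment=query_table,
        parameters={
            "n_sets": n_sets, "set_size": set_size, "p_cutoff": p_cutoff,
            "seed": seed, "mirna_universe_size": len(mirna_universe),
            "gene_universe_size": len(universe), "exclude_query": exclude_query,
            "max_null_hits": max_null_hits,
        },
    )
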