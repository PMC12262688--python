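"""Local target aggregation, over-representation analysis and hub-gene ranking.

Downstream annotation runs entirely on user-supplied files — a two-column
miRNA→target table (e.g. exported from a validated-interaction database),
GMT gene-set collections, and an optional protein-protein interaction edge
list — so no web service is required and results are reproducible against
pinned annotation snapshots.

Over-representation uses the hypergeometric upper tail (identical to a
one-sided Fisher exact test), Benjamini-Hochberg FDR across the tested
sets, and ranks significant sets by log10(observed/expected).
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import ContractError, FormatError

log = logging.getLogger(__name__)


def read_target_map(path: str | os.PathLike) -> dict[str, set[str]]:
    """Read a two-column (mirna, gene) TSV into mirna -> target-set, genes uppercased."""
    frame = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if frame.shape[1] < 2:
        raise FormatError(f"{path}: expected two tab-separated columns (mirna, gene)")
    out: dict[str, set[str]] = {}
    for mirna, gene in zip(frame[0], frame[1]):
        gene = str(gene).strip().upper()
        if not gene:
            raise FormatError(f"{path}: empty gene symbol for {mirna}")
        out.setdefault(str(mirna).strip(), set()).add(gene)
    return out


def read_gmt(path: str | os.PathLike) -> dict[str, set[str]]:
    """Read a GMT file (set_id, description, genes...) into set_id -> gene set."""
    sets: dict[str, set[str]] = {}
    with open(path) as handle:
        for line in handle:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = {g.strip().upper() for g in parts[2:] if g.strip()}
    if not sets:
        raise FormatError(f"{path}: no gene sets parsed")
    return sets


def read_edge_list(path: str | os.PathLike) -> list[tuple[str, str]]:
    """Read a two-column TSV of undirected gene-gene edges."""
    frame = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    return [(str(a).strip().upper(), str(b).strip().upper()) for a, b in zip(frame[0], frame[1])]


def aggregate_targets(
    target_map: dict[str, set[str]], mirnas, min_mirnas: int = 2
) -> list[str]:
    """Genes targeted by at least ``min_mirnas`` of the queried miRNAs.

    Multi-miRNA queries keep genes hit by >= min_mirnas distinct miRNAs
    (default 2), which concentrates the list on convergent regulation; a
    single-miRNA query returns that miRNA's full target set. Queried miRNAs
    absent from the map are logged and skipped.
    """
    present = []
    for m in mirnas:
        if m in target_map:
            present.append(m)
        else:
            log.warning("miRNA %s absent from target map; skipped", m)
    if not present:
        log.warning("no queried miRNA found in the target map")
        return []
    if len(present) == 1:
        return sorted(target_map[present[0]])
    counts: dict[str, int] = {}
    for m in present:
        for g in target_map[m]:
            counts[g] = counts.get(g, 0) + 1
    genes = sorted(g for g, c in counts.items() if c >= min_mirnas)
    if not genes:
        log.warning("no gene targeted by >= %d of the queried miRNAs", min_mirnas)
    return genes


@dataclass
class EnrichmentResult:
    set_id: str
    observed: int
    expected: float
    p_fisher: float
    fdr: float
    ratio_log10: float
    genes: list[str]


def over_representation(
    genes,
    gene_sets: dict[str, set[str]],
    universe=None,
    fdr_max: float = 0.05,
    min_observed: int = 3,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a gene list against GMT sets.

    ``universe`` defaults to the union of all genes in the collection; query
    genes outside it are dropped with a warning. Per set, observed is the
    query/set overlap, expected is |query|·|set|/|universe|, p is the
    one-sided hypergeometric upper tail, and FDR is Benjamini-Hochberg over
    all tested sets. A set is flagged significant when fdr < ``fdr_max`` and
    observed >= ``min_observed`` (a gene count of at least three). Rows are
    ordered by log10(observed/expected) descending; zero-overlap sets carry
    an undefined ratio and sort last.
    """
    if universe is None:
        universe = set().union(*gene_sets.values()) if gene_sets else set()
    universe = {str(g).upper() for g in universe}
    if not universe:
        raise ContractError("empty gene universe")
    query = {str(g).upper() for g in genes}
    if not query:
        raise ContractError("empty query gene list")
    outside = query - universe
    if outside:
        log.warning("%d query gene(s) outside the universe dropped", len(outside))
        query &= universe
        if not query:
            raise ContractError("no query gene lies in the universe")

    m_univ, n_query = len(universe), len(query)
    rows = []
    for set_id in sorted(gene_sets):
        members = {str(g).upper() for g in gene_sets[set_id]} & universe
        overlap = sorted(query & members)
        observed = len(overlap)
        expected = n_query * len(members) / m_univ
        p = float(stats.hypergeom.sf(observed - 1, m_univ, len(members), n_query))
        ratio = np.log10(observed / expected) if observed > 0 and expected > 0 else np.nan
        rows.append(
            {
                "set_id": set_id,
                "set_size": len(members),
                "observed": observed,
                "expected": expected,
                "p_fisher": min(p, 1.0),
                "ratio_log10": ratio,
                "genes": ",".join(overlap),
            }
        )
    frame = pd.DataFrame(rows)
    frame["fdr"] = multipletests(frame["p_fisher"], method="fdr_bh")[1]
    frame["significant"] = (frame["fdr"] < fdr_max) & (frame["observed"] >= min_observed)
    frame = frame.sort_values(
        ["ratio_log10", "set_id"], ascending=[False, True], na_position="last",
        kind="mergesort",
    ).reset_index(drop=True)
    return frame[
        ["set_id", "set_size", "observed", "expected", "p_fisher", "fdr",
         "ratio_log10", "significant", "genes"]
    ]


def hub_degree(edges, k: int) -> list[tuple[str, int]]:
    """Top-k genes by node degree in an undirected interaction network.

    Self-loops are dropped and duplicate edges counted once; ties in degree
    break lexicographically so the ranking is deterministic.
    """
    if k <= 0:
        raise ContractError("k must be positive")
    graph = nx.Graph()
    for a, b in edges:
        if a != b:
            graph.add_edge(a, b)
    ranked = sorted(graph.degree, key=lambda it: (-it[1], it[0]))
    return [(g, int(d)) for g, d in ranked[:k]]
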