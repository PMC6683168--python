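"""Chromosome localization of DEP-encoding genes and gene-set
over-representation.

Localization counts unique genes per karyotype chromosome for each
regulation direction.  Over-representation is the hypergeometric upper
tail: for a list of n genes from a universe of N, a set covering K of the
universe and overlapping the list in k genes,

    p = sum_{k' >= k} C(K, k') C(N-K, n-k') / C(N, n),

with BH-FDR across sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

from .dep import bh_fdr
from .io import CHROMOSOME_ORDER


def localize(
    genes_by_direction: Mapping[str, Iterable[str]],
    annotation: Mapping[str, str],
) -> pd.DataFrame:
    """Count unique genes per chromosome for each regulation direction.

    Gene symbols are case-folded; duplicate proteins mapping to one gene
    count once.  Genes absent from the annotation land in the 'unlocated'
    row.  Rows are ordered by karyotype (1..22, X, Y, MT, unplaced,
    unlocated); columns are the directions.
    """
    if not annotation:
        raise ValueError("empty gene->chromosome annotation")
    ann = {g.upper(): c for g, c in annotation.items()}
    index = list(CHROMOSOME_ORDER) + ["unlocated"]
    table = pd.DataFrame(0, index=index, columns=list(genes_by_direction), dtype=int)
    for direction, genes in genes_by_direction.items():
        unique_genes = {g.upper() for g in genes}
        for gene in unique_genes:
            table.loc[ann.get(gene, "unlocated"), direction] += 1
    return table


@dataclass
class EnrichmentResult:
    set_name: str
    overlap: int
    set_size: int
    list_size: int
    universe_size: int
    p_value: float
    q_value: float
    members_hit: list[str]


def hypergeom_enrich(
    gene_list: Iterable[str],
    gene_sets: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of ``gene_list`` in each set.

    The list must be contained in the universe (offenders are named);
    sets are intersected with the universe before testing.  Results are
    BH-corrected across sets and sorted by ascending p-value.
    """
    uni = {g.upper() for g in universe}
    lst = {g.upper() for g in gene_list}
    offenders = sorted(lst - uni)
    if offenders:
        raise ValueError(
            f"gene list not contained in universe; offenders: {offenders[:10]}"
        )
    n = len(lst)
    big_n = len(uni)
    names, ps, rows = [], [], []
    for name, members in gene_sets.items():
        mset = {g.upper() for g in members} & uni
        big_k = len(mset)
        hit = sorted(lst & mset)
        k = len(hit)
        if big_k == 0:
            p = 1.0
        else:
            p = float(stats.hypergeom.sf(k - 1, big_n, big_k, n))
        names.append(name)
        ps.append(min(p, 1.0))
        rows.append((name, k, big_k, n, big_n, hit))
    qs = bh_fdr(ps) if ps else []
    results = [
        EnrichmentResult(name, k, big_k, nn, bn, p, float(q), hit)
        for (name, k, big_k, nn, bn, hit), p, q in zip(rows, ps, qs)
    ]
    results.sort(key=lambda r: (r.p_value, r.set_name))
    return results


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "set_name": [r.set_name for r in results],
            "overlap": [r.overlap for r in results],
            "set_size": [r.set_size for r in results],
            "list_size": [r.list_size for r in results],
            "universe_size": [r.universe_size for r in results],
            "p_value": [r.p_value for r in results],
            "q_value": [r.q_value for r in results],
            "members_hit": [";".join(r.members_hit) for r in results],
        }
    )
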