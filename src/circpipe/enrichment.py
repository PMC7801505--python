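"""Term over-representation analysis of circRNA host genes.

One-sided Fisher's exact test per term against an expressed-gene
background, Benjamini-Hochberg correction across the tested terms.  Term
gene sets are intersected with the background first; terms with fewer
than 5 or more than 400 background genes are excluded — small terms cost
power under multiple testing, huge terms carry little interpretative
value.  Term sets come from a GMT-style file, so runs are reproducible
offline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

from .diffexp import bh_adjust


@dataclass
class EnrichmentResult:
    term_id: str
    term_name: str
    term_size: int
    overlap: int
    query_size: int
    background_size: int
    p_value: float
    fdr: float
    significant: bool


def fisher_overrepresentation(
    overlap: int, query_size: int, term_size: int, background_size: int
) -> float:
    """One-sided Fisher exact p for over-representation.

    Table: [[overlap, query - overlap], [term - overlap,
    background - query - term + overlap]].  Equals the hypergeometric
    upper tail P[X >= overlap].
    """
    a = overlap
    b = query_size - overlap
    c = term_size - overlap
    d = background_size - query_size - term_size + overlap
    if min(a, b, c, d) < 0:
        raise ValueError("inconsistent contingency table")
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="greater")[1])


def enrich(
    query_genes: Iterable[str],
    term_gene_sets: Mapping[str, tuple[str, set[str]]] | Mapping[str, set[str]],
    background_genes: Iterable[str],
    min_term: int = 5,
    max_term: int = 400,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Test each term for over-representation of the query in the background.

    ``term_gene_sets`` maps term id -> gene set, or term id ->
    (term name, gene set).  The query must be a subset of the background.
    Term sets are intersected with the background before the 5..400 size
    filter, so "term size" always means background-expressed term genes.
    """
    background = set(background_genes)
    if not background:
        raise ValueError("empty background")
    query = set(query_genes)
    stray = query - background
    if stray:
        raise ValueError(f"query genes absent from background: {sorted(stray)[:5]}")

    tested: list[tuple[str, str, int, int]] = []
    for term_id in sorted(term_gene_sets):
        entry = term_gene_sets[term_id]
        if isinstance(entry, tuple):
            name, genes = entry
        else:
            name, genes = term_id, entry
        term_bg = set(genes) & background
        if not (min_term <= len(term_bg) <= max_term):
            continue
        tested.append((term_id, name, len(term_bg), len(term_bg & query)))

    pvals = [
        fisher_overrepresentation(ov, len(query), tsize, len(background))
        for _, _, tsize, ov in tested
    ]
    fdrs = bh_adjust(pvals)
    return [
        EnrichmentResult(tid, name, tsize, ov, len(query), len(background),
                         p, float(q), bool(q < alpha))
        for (tid, name, tsize, ov), p, q in zip(tested, pvals, fdrs)
    ]


def read_gmt(path) -> dict[str, tuple[str, set[str]]]:
    """GMT: one term per line — id, description, then member genes (tabs)."""
    out: dict[str, tuple[str, set[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}: line {lineno}: GMT row needs >= 3 fields")
            out[f[0]] = (f[1], {g for g in f[2:] if g})
    return out


def read_gene_list(path) -> list[str]:
    with open(path) as fh:
        return [ln.strip() for ln in fh if ln.strip()]


def enrichment_table(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    rows = [
        {"term_id": r.term_id, "term_name": r.term_name, "term_size": r.term_size,
         "overlap": r.overlap, "query_size": r.query_size,
         "background_size": r.background_size, "p_value": r.p_value,
         "fdr": r.fdr, "significant": r.significant}
        for r in sorted(results, key=lambda r: r.p_value)
    ]
    return pd.DataFrame(rows)
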