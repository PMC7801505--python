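"""SRPBM normalization and nonparametric differential expression.

Backsplice read counts are normalized to Spliced Reads Per Billion Mapped
reads (SRPBM = count / total mapped reads * 1e9), optionally adjusted for
batch, then tested per circRNA across treatment groups with a
Kruskal-Wallis test and Benjamini-Hochberg correction.  The rank-based
test suits circRNA counts, which are low and overdispersed relative to
mRNA, at the cost of power at small n.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import SampleDesign, ValidationError


@dataclass
class DeResult:
    circ_id: str
    group_medians: dict[str, float]
    kw_statistic: float
    p_value: float
    adjusted_p: float
    significant: bool


def srpbm(counts: pd.DataFrame, mapped_totals: pd.Series | dict) -> pd.DataFrame:
    """Spliced Reads Per Billion Mapped reads: ``count / total * 1e9``.

    ``counts`` is circRNAs x samples; ``mapped_totals`` gives each
    sample's total mapped reads (the library-size definition is the
    caller's choice — see docs).  Zero or missing totals are an error.
    """
    totals = pd.Series(mapped_totals)
    missing = [s for s in counts.columns if s not in totals.index]
    if missing:
        raise ValidationError(f"no mapped totals for samples: {missing}")
    totals = totals[counts.columns].astype(float)
    bad = totals[totals <= 0]
    if len(bad):
        raise ValidationError(f"non-positive mapped totals for samples: {list(bad.index)}")
    return counts.astype(float).div(totals, axis=1) * 1e9


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal-Wallis H with tie correction; p from the chi-square
    approximation with k-1 df.

    All values identical across all groups yields (0.0, 1.0) rather than
    an error — a constant circRNA carries no group signal.
    """
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("kruskal_wallis needs >= 2 non-empty groups")
    flat = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.all(flat == flat[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*[np.asarray(g, dtype=float) for g in groups])
    return float(h), float(p)


def kruskal_wallis_permutation(
    groups: Sequence[Sequence[float]], max_permutations: int = 50000
) -> tuple[float, float]:
    """Exact permutation p-value for the Kruskal-Wallis H statistic.

    Intended for tiny n where the chi-square approximation is coarse;
    enumerates all assignments of the pooled values to the group sizes
    (a uniform subsample when more than ``max_permutations``).
    """
    h_obs, _ = kruskal_wallis(groups)
    flat = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    sizes = [len(g) for g in groups]
    n = len(flat)

    def h_of(order: Sequence[int]) -> float:
        vals = flat[list(order)]
        parts = []
        at = 0
        for k in sizes:
            parts.append(vals[at : at + k])
            at += k
        return kruskal_wallis(parts)[0]

    perms = permutations(range(n))
    count = 0
    ge = 0
    for order in perms:
        count += 1
        if h_of(order) >= h_obs - 1e-12:
            ge += 1
        if count >= max_permutations:
            break
    return h_obs, ge / count


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def batch_center(norm: pd.DataFrame, design: Sequence[SampleDesign]) -> pd.DataFrame:
    """Per-batch median-centering of log1p SRPBM values.

    A simple location adjustment: within each batch, subtract the batch's
    per-circRNA median log1p value and add back the global median, then
    return to the SRPBM scale.  It removes additive batch shifts only.
    """
    batches = {d.sample_id: (d.batch or "") for d in design}
    logx = np.log1p(norm)
    global_med = logx.median(axis=1)
    out = logx.copy()
    for b in sorted(set(batches.values())):
        cols = [c for c in norm.columns if batches.get(c, "") == b]
        if not cols:
            continue
        med = logx[cols].median(axis=1)
        out[cols] = logx[cols].sub(med, axis=0).add(global_med, axis=0)
    return np.expm1(out).clip(lower=0.0)


def run_de(
    counts: pd.DataFrame,
    mapped_totals: pd.Series | dict,
    design: Sequence[SampleDesign],
    grouping: str = "group",
    alpha: float = 0.05,
    batch_adjust: bool = False,
    exact_permutation: bool = False,
) -> list[DeResult]:
    """SRPBM -> (optional batch centering) -> per-circRNA Kruskal-Wallis -> BH.

    ``grouping`` selects the design attribute defining the test groups
    (``group`` or ``timepoint``).  Significance is adjusted p < ``alpha``.
    """
    by_id = {d.sample_id: d for d in design}
    missing = [s for s in counts.columns if s not in by_id]
    if missing:
        raise ValidationError(f"samples missing from design: {missing}")
    norm = srpbm(counts, mapped_totals)
    if batch_adjust:
        norm = batch_center(norm, design)

    group_cols: dict[str, list[str]] = {}
    for s in counts.columns:
        group_cols.setdefault(getattr(by_id[s], grouping), []).append(s)
    if len(group_cols) < 2:
        raise ValueError(f"need >= 2 groups under grouping {grouping!r}")

    stats_p = []
    for circ_id, row in norm.iterrows():
        groups = [row[cols].to_numpy() for cols in group_cols.values()]
        if exact_permutation:
            h, p = kruskal_wallis_permutation(groups)
        else:
            h, p = kruskal_wallis(groups)
        stats_p.append((circ_id, h, p))

    adj = bh_adjust([p for _, _, p in stats_p])
    results = []
    for (circ_id, h, p), q in zip(stats_p, adj):
        medians = {g: float(np.median(norm.loc[circ_id, cols])) for g, cols in group_cols.items()}
        results.append(DeResult(str(circ_id), medians, h, p, float(q), bool(q < alpha)))
    return results


def de_table(results: Sequence[DeResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {"circ_id": r.circ_id, "kw_statistic": r.kw_statistic,
               "p_value": r.p_value, "adjusted_p": r.adjusted_p,
               "significant": r.significant}
        row.update({f"median_{g}": v for g, v in r.group_medians.items()})
        rows.append(row)
    return pd.DataFrame(rows)
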