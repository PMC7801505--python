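"""Cross-species backsplice conservation: chain liftover and classification.

Each circRNA's two backsplice splice sites are lifted to the target genome
through a UCSC chain file and compared with circRNAs annotated there.
Every circRNA receives exactly one of six categories:

``not_aligned``
    at least one splice site could not be lifted;
``no_homologous``
    neither lifted site is near an annotated circRNA splice site;
``five_prime_utilized`` / ``three_prime_utilized``
    only the 5'/3' site (strand-resolved) is used by some annotated circRNA;
``both_sites_utilized``
    both sites are used, but only by different annotated circRNAs;
``homologous``
    a single annotated circRNA uses both sites.

A lifted site is considered to match an annotated site when they fall on
the same target chromosome within ``tolerance_nt`` bases (inclusive on
both sides; the default +-2 spans 5 positions).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .types import Chain, ChainSet, CircDbRecord, GenomicInterval

logger = logging.getLogger(__name__)

CATEGORIES = (
    "not_aligned",
    "no_homologous",
    "five_prime_utilized",
    "three_prime_utilized",
    "both_sites_utilized",
    "homologous",
)


@dataclass(frozen=True)
class LiftResult:
    """Outcome of lifting one interval through a chain set."""

    status: str  # "mapped" | "unmapped"
    target: GenomicInterval | None = None
    remap_ratio: float = 0.0

    @property
    def mapped(self) -> bool:
        return self.status == "mapped"


@dataclass
class ConservationCall:
    circ_id: str
    lifted_5p: LiftResult
    lifted_3p: LiftResult
    category: str
    matched_db_ids: list[str] = field(default_factory=list)


def _covering_chains(chains: ChainSet, query: GenomicInterval) -> list[Chain]:
    return [
        c
        for c in chains
        if c.source_name == query.chrom
        and c.source_start < query.end
        and query.start < c.source_end
    ]


def _map_through_chain(chain: Chain, query: GenomicInterval) -> tuple[int, list[int]]:
    """Map query bases through one chain's aligned blocks.

    Returns (n_mapped, target_positions) where positions are actual
    (forward-strand) target coordinates of the mapped bases.
    """
    spos = chain.source_start
    tpos = chain.target_start  # in target-strand frame
    mapped: list[int] = []
    for b in chain.blocks:
        lo = max(query.start, spos)
        hi = min(query.end, spos + b.size)
        for q in range(lo, hi):
            t_frame = tpos + (q - spos)
            if chain.target_strand == "-":
                mapped.append(chain.target_size - 1 - t_frame)
            else:
                mapped.append(t_frame)
        spos += b.size + b.source_gap
        tpos += b.size + b.target_gap
        if spos >= query.end:
            break
    return len(mapped), mapped


def lift_interval(
    chains: ChainSet, query: GenomicInterval, min_ratio: float = 0.95
) -> LiftResult:
    """Lift an interval through the best-scoring covering chain.

    The interval maps iff the fraction of its bases falling inside aligned
    blocks is >= ``min_ratio``.  Ties between equal-score covering chains
    are broken deterministically toward the lowest chain id (logged).
    Under a minus-strand chain the result's strand is flipped.
    """
    cands = _covering_chains(chains, query)
    if not cands:
        return LiftResult("unmapped")
    best_score = max(c.score for c in cands)
    best = [c for c in cands if c.score == best_score]
    if len(best) > 1:
        logger.info(
            "query %s:%d-%d covered by %d equal-score chains; using chain id %d",
            query.chrom, query.start, query.end, len(best),
            min(c.chain_id for c in best),
        )
    chain = min(best, key=lambda c: c.chain_id)

    n_mapped, positions = _map_through_chain(chain, query)
    ratio = n_mapped / len(query)
    if ratio < min_ratio or n_mapped == 0:
        return LiftResult("unmapped", remap_ratio=ratio)
    if chain.target_strand == "-":
        strand = {"+": "-", "-": "+", ".": "."}[query.strand]
    else:
        strand = query.strand
    target = GenomicInterval(chain.target_name, min(positions), max(positions) + 1, strand)
    return LiftResult("mapped", target, ratio)


def splice_sites(interval: GenomicInterval) -> tuple[GenomicInterval, GenomicInterval]:
    """The two backsplice flank positions as 1-base intervals (left, right).

    The left site is the interval's first base, the right site its last
    base, in genomic orientation.
    """
    left = GenomicInterval(interval.chrom, interval.start, interval.start + 1, interval.strand)
    right = GenomicInterval(interval.chrom, interval.end - 1, interval.end, interval.strand)
    return left, right


def lift_circ_ends(
    chains: ChainSet,
    interval: GenomicInterval,
    min_ratio: float = 0.95,
    full_interval: bool = False,
) -> tuple[LiftResult, LiftResult]:
    """Lift the two splice-site flanks, returned strand-resolved as (5', 3').

    For plus (or unknown) strand the 5' site is the genomic left end; for
    minus strand it is the genomic right end.  By default each flank is
    lifted as a 1-base interval (all-or-none under ``min_ratio``); with
    ``full_interval`` the whole circRNA interval is lifted instead, the
    ratio applies to its full length, and the site positions are the ends
    of the lifted interval.
    """
    if full_interval:
        res = lift_interval(chains, interval, min_ratio)
        if not res.mapped:
            return LiftResult("unmapped", remap_ratio=res.remap_ratio), LiftResult(
                "unmapped", remap_ratio=res.remap_ratio
            )
        t = res.target
        lift_left = LiftResult("mapped", GenomicInterval(t.chrom, t.start, t.start + 1, t.strand), res.remap_ratio)
        lift_right = LiftResult("mapped", GenomicInterval(t.chrom, t.end - 1, t.end, t.strand), res.remap_ratio)
    else:
        left, right = splice_sites(interval)
        lift_left = lift_interval(chains, left, min_ratio)
        lift_right = lift_interval(chains, right, min_ratio)
    if interval.strand == "-":
        return lift_right, lift_left
    return lift_left, lift_right


def _site_matches(
    pos: GenomicInterval, db: Sequence[CircDbRecord], tolerance_nt: int
) -> set[tuple[int, str]]:
    """(record index, 'left'|'right') pairs whose splice site is within tolerance."""
    p = pos.start
    hits: set[tuple[int, str]] = set()
    for i, rec in enumerate(db):
        if rec.interval.chrom != pos.chrom:
            continue
        if abs(p - rec.interval.start) <= tolerance_nt:
            hits.add((i, "left"))
        if abs(p - (rec.interval.end - 1)) <= tolerance_nt:
            hits.add((i, "right"))
    return hits


def classify_conservation(
    circ_id: str,
    lifted_5p: LiftResult,
    lifted_3p: LiftResult,
    db: Sequence[CircDbRecord],
    tolerance_nt: int = 2,
) -> ConservationCall:
    """Assign one of the six conservation categories from lifted splice sites.

    ``homologous`` requires a single database record whose two splice sites
    are each matched by one of the circRNA's two lifted sites (at opposite
    sites of the record).
    """
    if not (lifted_5p.mapped and lifted_3p.mapped):
        return ConservationCall(circ_id, lifted_5p, lifted_3p, "not_aligned")

    hits5 = _site_matches(lifted_5p.target, db, tolerance_nt)
    hits3 = _site_matches(lifted_3p.target, db, tolerance_nt)

    shared = {
        i
        for (i, s5) in hits5
        for (j, s3) in hits3
        if i == j and s5 != s3
    }
    if shared:
        ids = sorted(db[i].circ_id for i in shared)
        return ConservationCall(circ_id, lifted_5p, lifted_3p, "homologous", ids)

    ids = sorted({db[i].circ_id for i, _ in hits5} | {db[i].circ_id for i, _ in hits3})
    if hits5 and hits3:
        cat = "both_sites_utilized"
    elif hits5:
        cat = "five_prime_utilized"
    elif hits3:
        cat = "three_prime_utilized"
    else:
        cat = "no_homologous"
    return ConservationCall(circ_id, lifted_5p, lifted_3p, cat, ids)


def conserve(
    circ_id: str,
    interval: GenomicInterval,
    chains: ChainSet,
    db: Sequence[CircDbRecord],
    tolerance_nt: int = 2,
    min_ratio: float = 0.95,
    full_interval: bool = False,
) -> ConservationCall:
    """Lift one circRNA's splice sites and classify its conservation."""
    l5, l3 = lift_circ_ends(chains, interval, min_ratio, full_interval)
    return classify_conservation(circ_id, l5, l3, db, tolerance_nt)


def conserve_all(
    circs: Iterable[tuple[str, GenomicInterval]],
    chains: ChainSet,
    db: Sequence[CircDbRecord],
    tolerance_nt: int = 2,
    min_ratio: float = 0.95,
    full_interval: bool = False,
) -> list[ConservationCall]:
    return [
        conserve(cid, iv, chains, db, tolerance_nt, min_ratio, full_interval)
        for cid, iv in circs
    ]


def summarize_categories(calls: Sequence[ConservationCall]) -> pd.DataFrame:
    """Per-category counts and percentages.

    Percentages use ALL detected circRNAs as denominator, including the
    ``not_aligned`` ones, so the homologous fraction is reported relative
    to everything detected, not only to what lifted.
    """
    if not calls:
        raise ValueError("no conservation calls to summarize")
    total = len(calls)
    counts = {c: 0 for c in CATEGORIES}
    for call in calls:
        counts[call.category] += 1
    return pd.DataFrame(
        {
            "category": list(CATEGORIES),
            "count": [counts[c] for c in CATEGORIES],
            "percent": [100.0 * counts[c] / total for c in CATEGORIES],
        }
    )
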