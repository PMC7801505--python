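"""Relating circRNA backsplice junctions to gene models.

Covers host-gene overlap, exon-intron boundary concordance of the two
backsplice ends, exon content, and the per-gene / per-chromosome summary
distributions typically reported for a circRNA catalogue.
"""

from __future__ import annotations

from collections import Counter
from typing import Sequence

import pandas as pd

from .consensus import CircCandidate
from .conservation import ConservationCall
from .types import GeneAnnotation, GenomicInterval

BOUNDARY_CLASSES = ("both_ends", "one_end", "neither", "intergenic")


def overlap_genes(circ: GenomicInterval, ann: GeneAnnotation) -> list[str]:
    """IDs of genes overlapping the circRNA by >= 1 base (empty = intergenic)."""
    return [g.gene_id for g in ann.overlapping(circ)]


def boundary_concordance(
    circ: GenomicInterval, ann: GeneAnnotation, tolerance: int = 0
) -> str:
    """Classify how the circRNA's ends relate to annotated exon boundaries.

    The circ start is concordant when it coincides (within ``tolerance``)
    with an exon start of ANY overlapping gene, and the circ end with an
    exon end.  Returns ``both_ends``, ``one_end``, ``neither`` or
    ``intergenic`` (no gene overlap at all).
    """
    hosts = ann.overlapping(circ)
    if not hosts:
        return "intergenic"
    start_ok = False
    end_ok = False
    for g in hosts:
        for e in ann.exons.get(g.gene_id, []):
            if abs(e.start - circ.start) <= tolerance:
                start_ok = True
            if abs(e.end - circ.end) <= tolerance:
                end_ok = True
    if start_ok and end_ok:
        return "both_ends"
    if start_ok or end_ok:
        return "one_end"
    return "neither"


def exon_count(circ: GenomicInterval, ann: GeneAnnotation) -> int:
    """Number of host-gene exons lying fully inside the circRNA interval.

    Exons shared by several overlapping genes at identical coordinates are
    counted once.
    """
    inside: set[tuple[int, int]] = set()
    for g in ann.overlapping(circ):
        for e in ann.exons.get(g.gene_id, []):
            if circ.start <= e.start and e.end <= circ.end:
                inside.add((e.start, e.end))
    return len(inside)


def circs_per_gene(
    candidates: Sequence[CircCandidate], ann: GeneAnnotation
) -> pd.DataFrame:
    """Histogram of circRNAs hosted per gene (genes with >= 1 circRNA)."""
    per_gene: Counter[str] = Counter()
    for c in candidates:
        for gid in overlap_genes(c.interval, ann):
            per_gene[gid] += 1
    hist = Counter(per_gene.values())
    return pd.DataFrame(
        sorted(hist.items()), columns=["circs_per_gene", "n_genes"]
    )


def per_chrom_counts(candidates: Sequence[CircCandidate]) -> pd.DataFrame:
    """circRNA tally per chromosome, largest first."""
    tally = Counter(c.interval.chrom for c in candidates)
    rows = sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(rows, columns=["chrom", "n_circs"])


def infer_human_host_gene(
    call: ConservationCall, target_annotation: GeneAnnotation
) -> list[str]:
    """Host gene(s) in the target species for a homologous but locally
    unannotated circRNA.

    The circRNA must have been classified ``homologous``; its lifted end
    coordinates define the target-genome interval screened for overlapping
    genes.  Returns an empty list when the lifted interval is intergenic
    in the target annotation too.
    """
    if call.category != "homologous":
        raise ValueError(
            f"{call.circ_id}: human host-gene screening requires a homologous "
            f"circRNA (got {call.category})"
        )
    t5, t3 = call.lifted_5p.target, call.lifted_3p.target
    if t5.chrom != t3.chrom:
        return []
    lo = min(t5.start, t3.start)
    hi = max(t5.end, t3.end)
    lifted = GenomicInterval(t5.chrom, lo, hi, t5.strand)
    return overlap_genes(lifted, target_annotation)


def annotate_candidates(
    candidates: Sequence[CircCandidate], ann: GeneAnnotation, tolerance: int = 0
) -> pd.DataFrame:
    """Per-circRNA annotation table: hosts, boundary class, exon count."""
    rows = []
    for c in candidates:
        hosts = overlap_genes(c.interval, ann)
        rows.append(
            {
                "circ_id": c.circ_id,
                "chrom": c.interval.chrom,
                "start": c.interval.start,
                "end": c.interval.end,
                "strand": c.interval.strand,
                "host_genes": ",".join(hosts),
                "boundary": boundary_concordance(c.interval, ann, tolerance),
                "n_exons": exon_count(c.interval, ann),
                "strand_assumed": c.interval.strand == ".",
            }
        )
    return pd.DataFrame(rows)
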