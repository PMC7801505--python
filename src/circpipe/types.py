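"""Shared domain types for the circRNA pipeline.

All genomic coordinates held by these types are 0-based half-open
(BED convention), regardless of the convention of the file they were
read from.  Readers in :mod:`circpipe.io` perform the conversion.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

Strand = str  # "+", "-" or "." (unknown)
STRANDS = {"+", "-", "."}


class ValidationError(ValueError):
    """Raised when an input object violates a structural invariant."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A genomic interval, 0-based half-open.

    Parameters
    ----------
    chrom : str
        Chromosome / contig name (non-empty).
    start, end : int
        0-based inclusive start, exclusive end; ``0 <= start < end``.
    strand : {"+", "-", "."}
        "." encodes unknown strand; it is never coerced to "+".
    """

    chrom: str
    start: int
    end: int
    strand: Strand = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("interval chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"interval requires 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def key(self) -> tuple[str, int, int]:
        """Strand-blind junction identity used for cross-caller matching."""
        return (self.chrom, self.start, self.end)

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def strands_compatible(a: Strand, b: Strand) -> bool:
    """True if strands are equal or at least one is unknown."""
    return a == b or a == "." or b == "."


@dataclass
class BsjCallSet:
    """One caller's backsplice-junction calls with per-sample read counts.

    ``circ_types`` optionally carries the caller's own annotation of each
    junction (exonic / intronic / intergenic), keyed by junction identity.
    """

    caller_id: str
    sample_order: list[str]
    calls: list[tuple[GenomicInterval, np.ndarray]] = field(default_factory=list)
    circ_types: dict[tuple[str, int, int], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.sample_order)
        seen: set[tuple] = set()
        for iv, counts in self.calls:
            if len(counts) != n:
                raise ValidationError(
                    f"caller {self.caller_id}: junction {iv} has "
                    f"{len(counts)} counts for {n} samples"
                )
            if np.any(np.asarray(counts) < 0):
                raise ValidationError(f"caller {self.caller_id}: negative count at {iv}")
            k = (iv.chrom, iv.start, iv.end, iv.strand)
            if k in seen:
                raise ValidationError(f"caller {self.caller_id}: duplicate junction {iv}")
            seen.add(k)

    def __len__(self) -> int:
        return len(self.calls)

    def __iter__(self) -> Iterator[tuple[GenomicInterval, np.ndarray]]:
        return iter(self.calls)


@dataclass(frozen=True)
class Gene:
    gene_id: str
    name: str
    interval: GenomicInterval


@dataclass
class GeneAnnotation:
    """Gene models with exon structure and an interval-query index.

    ``exons[gene_id]`` is sorted by start; every exon lies within its
    gene's interval.
    """

    genes: list[Gene]
    exons: dict[str, list[GenomicInterval]]

    def __post_init__(self) -> None:
        self._by_id = {g.gene_id: g for g in self.genes}
        for g in self.genes:
            exs = self.exons.get(g.gene_id, [])
            exs.sort(key=lambda e: (e.start, e.end))
            for e in exs:
                if not (g.interval.start <= e.start and e.end <= g.interval.end):
                    raise ValidationError(
                        f"exon {e} outside gene {g.gene_id} interval {g.interval}"
                    )
            self.exons[g.gene_id] = exs
        # per-chromosome gene lists sorted by start, for overlap queries
        self._per_chrom: dict[str, list[Gene]] = {}
        for g in sorted(self.genes, key=lambda g: (g.interval.chrom, g.interval.start)):
            self._per_chrom.setdefault(g.interval.chrom, []).append(g)
        self._chrom_starts = {
            c: [g.interval.start for g in gs] for c, gs in self._per_chrom.items()
        }

    def gene(self, gene_id: str) -> Gene:
        return self._by_id[gene_id]

    def __len__(self) -> int:
        return len(self.genes)

    def overlapping(self, query: GenomicInterval) -> list[Gene]:
        """Genes overlapping ``query`` by >= 1 base, in positional order."""
        genes = self._per_chrom.get(query.chrom, [])
        if not genes:
            return []
        # genes are non-overlapping in our fixtures but may not be in real
        # annotations, so scan left from the insertion point conservatively
        starts = self._chrom_starts[query.chrom]
        hi = bisect.bisect_left(starts, query.end)
        out = [g for g in genes[:hi] if g.interval.end > query.start]
        return out


@dataclass(frozen=True)
class ChainBlock:
    """A gapless aligned block followed by (source_gap, target_gap) bases."""

    size: int
    source_gap: int = 0
    target_gap: int = 0


@dataclass
class Chain:
    """One pairwise-alignment chain in UCSC chain-file semantics.

    The *source* genome is the one coordinates are lifted from (the first
    genome named on the ``chain`` header line); *target* is the genome
    lifted to.  For ``target_strand == "-"`` target start/end are in
    reversed-strand coordinates, as in the UCSC format.
    """

    score: float
    source_name: str
    source_size: int
    source_strand: Strand
    source_start: int
    source_end: int
    target_name: str
    target_size: int
    target_strand: Strand
    target_start: int
    target_end: int
    blocks: list[ChainBlock]
    chain_id: int = 0

    def validate(self) -> None:
        if not self.blocks:
            raise ValidationError(f"chain {self.chain_id}: no blocks")
        if any(b.size <= 0 for b in self.blocks):
            raise ValidationError(f"chain {self.chain_id}: block size must be > 0")
        src = sum(b.size + b.source_gap for b in self.blocks)
        tgt = sum(b.size + b.target_gap for b in self.blocks)
        if src != self.source_end - self.source_start:
            raise ValidationError(
                f"chain {self.chain_id}: source span {self.source_end - self.source_start}"
                f" != blocks+gaps {src}"
            )
        if tgt != self.target_end - self.target_start:
            raise ValidationError(
                f"chain {self.chain_id}: target span {self.target_end - self.target_start}"
                f" != blocks+gaps {tgt}"
            )
        if self.blocks[-1].source_gap or self.blocks[-1].target_gap:
            raise ValidationError(f"chain {self.chain_id}: trailing gap after last block")


@dataclass
class ChainSet:
    chains: list[Chain]

    def __post_init__(self) -> None:
        for c in self.chains:
            c.validate()

    def __len__(self) -> int:
        return len(self.chains)

    def __iter__(self) -> Iterator[Chain]:
        return iter(self.chains)


@dataclass(frozen=True)
class CircDbRecord:
    """A circRNA annotated in the target species (CIRCpedia-style)."""

    circ_id: str
    interval: GenomicInterval
    host_gene: str = ""


@dataclass(frozen=True)
class SampleDesign:
    sample_id: str
    group: str
    timepoint: str = ""
    batch: str = ""


def check_design(design: Sequence[SampleDesign]) -> None:
    ids = [d.sample_id for d in design]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate sample IDs in design")
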