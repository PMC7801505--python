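"""Two-caller backsplice-junction consensus and expression filtering.

A circRNA is retained when both callers report the identical junction
(exact chrom/start/end after coordinate normalization, compatible strand)
and it is expressed — at least ``min_count`` backsplice reads — in at
least ``min_samples`` *of the same samples in both callers*.  Depending
on the experimental design the sample requirement is evaluated over all
samples (``all_samples``) or within any single treatment group
(``within_group``).  Survivors carry the reference caller's counts and a
sequential identifier assigned in genomic order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Iterable, Sequence

import numpy as np
import pandas as pd

from .types import (
    BsjCallSet,
    GenomicInterval,
    SampleDesign,
    ValidationError,
    strands_compatible,
)


@dataclass
class CircCandidate:
    """A consensus-filtered circRNA with reference counts and sequential ID."""

    circ_id: str
    interval: GenomicInterval
    counts: np.ndarray  # per-sample, from the reference caller
    circ_type: str = "unknown"  # exonic | intronic | intergenic | unknown


@dataclass(frozen=True)
class MatchedJunction:
    interval: GenomicInterval
    counts_a: np.ndarray
    counts_b: np.ndarray


def match_junctions(a: BsjCallSet, b: BsjCallSet, strict_strand: bool = False) -> list[MatchedJunction]:
    """Pair junctions reported identically by both callers.

    A pair matches iff chrom, start and end are identical and strands are
    compatible (equal, or at least one unknown; ``strict_strand`` demands
    equality).  Each junction is matched at most once.  The returned
    interval keeps the more informative strand.
    """
    if a.sample_order != b.sample_order:
        raise ValidationError(
            f"sample_order mismatch between callers {a.caller_id!r} and {b.caller_id!r}"
        )
    by_key: dict[tuple, list[tuple[GenomicInterval, np.ndarray]]] = {}
    for iv, counts in b:
        by_key.setdefault(iv.key, []).append((iv, counts))
    out: list[MatchedJunction] = []
    for iv_a, counts_a in a:
        for entry in by_key.get(iv_a.key, []):
            iv_b, counts_b = entry
            ok = iv_a.strand == iv_b.strand if strict_strand else strands_compatible(iv_a.strand, iv_b.strand)
            if ok:
                strand = iv_a.strand if iv_a.strand != "." else iv_b.strand
                merged = GenomicInterval(iv_a.chrom, iv_a.start, iv_a.end, strand)
                out.append(MatchedJunction(merged, counts_a, counts_b))
                by_key[iv_a.key].remove(entry)  # each b-junction used once
                break
    return out


def is_expressed(count: int, min_count: int = 2) -> bool:
    """A circRNA needs at least ``min_count`` backsplice reads to count as expressed."""
    if count < 0:
        raise ValidationError("negative read count")
    return count >= min_count


def filter_candidates(
    matches: Sequence[MatchedJunction],
    design: Sequence[SampleDesign],
    sample_order: Sequence[str],
    mode: str = "all_samples",
    min_samples: int = 3,
    min_count: int = 2,
    reference: str = "a",
    samples_shared: bool = True,
    id_prefix: str = "circRNA",
    circ_types: dict[tuple[str, int, int], str] | None = None,
) -> list[CircCandidate]:
    """Apply the expression filter and assign sequential identifiers.

    ``all_samples`` keeps a junction iff >= ``min_samples`` samples are
    expressed (count >= ``min_count``) in BOTH callers — the same samples
    in both when ``samples_shared`` (the default reading of the rule; the
    looser reading counts samples per caller independently).
    ``within_group`` requires those samples to lie within one treatment
    group.  Survivors take the reference caller's counts ("a" or "b") and
    IDs ``circRNA1, circRNA2, ...`` in (chrom, start, end) order.
    """
    if mode not in ("all_samples", "within_group"):
        raise ValueError(f"unknown mode {mode!r}")
    if reference not in ("a", "b"):
        raise ValueError("reference must be 'a' or 'b'")
    by_id = {d.sample_id: d for d in design}
    missing = [s for s in sample_order if s not in by_id]
    if missing:
        raise ValidationError(f"samples missing from design: {missing}")
    groups: dict[str, list[int]] = {}
    for i, s in enumerate(sample_order):
        groups.setdefault(by_id[s].group, []).append(i)
    if mode == "within_group" and all(len(ix) < min_samples for ix in groups.values()):
        raise ValueError(
            f"min_samples={min_samples} exceeds every group size in within_group mode"
        )

    survivors: list[tuple[GenomicInterval, np.ndarray]] = []
    for m in matches:
        ok_a = np.asarray(m.counts_a) >= min_count
        ok_b = np.asarray(m.counts_b) >= min_count
        if samples_shared:
            ok = ok_a & ok_b
            if mode == "all_samples":
                keep = int(ok.sum()) >= min_samples
            else:
                keep = any(int(ok[ix].sum()) >= min_samples for ix in groups.values())
        else:
            if mode == "all_samples":
                keep = int(ok_a.sum()) >= min_samples and int(ok_b.sum()) >= min_samples
            else:
                keep = any(
                    int(ok_a[ix].sum()) >= min_samples and int(ok_b[ix].sum()) >= min_samples
                    for ix in groups.values()
                )
        if keep:
            survivors.append((m.interval, m.counts_a if reference == "a" else m.counts_b))

    survivors.sort(key=lambda t: (t[0].chrom, t[0].start, t[0].end))
    circ_types = circ_types or {}
    return [
        CircCandidate(f"{id_prefix}{i + 1}", iv, counts,
                      circ_types.get(iv.key, "unknown"))
        for i, (iv, counts) in enumerate(survivors)
    ]


def run_consensus(
    a: BsjCallSet,
    b: BsjCallSet,
    design: Sequence[SampleDesign],
    mode: str = "all_samples",
    min_samples: int = 3,
    min_count: int = 2,
    reference: str = "a",
    strict_strand: bool = False,
    samples_shared: bool = True,
) -> list[CircCandidate]:
    """Match junctions between two callers and filter to the consensus set.

    ``circ_type`` on the survivors comes from the reference caller's own
    annotation column when it carries one, else ``unknown``.
    """
    matches = match_junctions(a, b, strict_strand=strict_strand)
    ref_set = a if reference == "a" else b
    return filter_candidates(
        matches, design, a.sample_order, mode=mode, min_samples=min_samples,
        min_count=min_count, reference=reference, samples_shared=samples_shared,
        circ_types=ref_set.circ_types,
    )


def compare_sets(
    named_sets: Sequence[tuple[str, Iterable[Hashable]]],
    min_size: int = 0,
) -> pd.DataFrame:
    """Exact-membership intersection table over all subset patterns (UpSet-style).

    Each element of the union is assigned to exactly one membership
    pattern (the full subset of sets containing it); the table lists every
    non-empty pattern with its count, largest first.  ``min_size`` drops
    small patterns for display only.
    """
    names = [n for n, _ in named_sets]
    if len(set(names)) != len(names):
        raise ValueError("duplicate set names")
    sets = {n: set(s) for n, s in named_sets}
    union = set().union(*sets.values()) if sets else set()
    patterns: dict[frozenset, int] = {}
    for x in union:
        member = frozenset(n for n in names if x in sets[n])
        patterns[member] = patterns.get(member, 0) + 1
    rows = [
        {"sets": "&".join(n for n in names if n in p), "degree": len(p), "count": c}
        for p, c in patterns.items()
        if c >= min_size
    ]
    rows.sort(key=lambda r: (-r["count"], r["sets"]))
    return pd.DataFrame(rows, columns=["sets", "degree", "count"])
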