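"""Seeded synthetic-data generators with planted ground truth.

Every generator is a pure function of (seed, parameters), so fixtures are
reproducible byte-for-byte.  The defaults emulate the study design the
pipeline targets: a 12-sample, 3-group repeated-vaccination experiment
(four animals per treatment), two circRNA callers that agree on a core
set of junctions and each add private noise, backsplice read counts that
are low and overdispersed (negative binomial, mean 4, NB2 dispersion
0.5), a cross-species chain file with shifts, gaps and occasional
inversions, and a circRNA database in the target species arranged so that
lifting and classifying each planted circRNA reproduces its planted
conservation category — including sites placed exactly +-2 nt away
(matching, at the tolerance boundary) and +-3 nt away (just outside).

For every planted attribute there is a downstream operation whose output
can be compared to it exactly (ground-truth closure).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .conservation import CATEGORIES, conserve, lift_circ_ends
from .sponge import MirnaRecord, scan_binding_sites
from .types import (
    BsjCallSet,
    Chain,
    ChainBlock,
    ChainSet,
    CircDbRecord,
    Gene,
    GeneAnnotation,
    GenomicInterval,
    SampleDesign,
)

BOUNDARY_CLASSES = ("both_ends", "one_end", "neither", "intergenic")


class GenerationError(RuntimeError):
    """Raised when requested ground truth cannot be realized."""


@dataclass(frozen=True)
class TrueCirc:
    interval: GenomicInterval
    category: str  # planted conservation category
    host_gene: str | None
    boundary_class: str


@dataclass
class SyntheticTruth:
    """Planted ground truth for one simulated dataset."""

    true_circs: list[TrueCirc]
    planted_sponge_sites: dict[str, list[tuple[str, int, int]]] = field(default_factory=dict)
    de_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for c in self.true_circs:
            if c.category not in CATEGORIES:
                raise GenerationError(f"unknown planted category {c.category!r}")
        for effects in self.de_effects.values():
            if any(fc <= 0 for fc in effects.values()):
                raise GenerationError("fold-changes must be > 0")

    def expected_ids(self) -> dict[str, TrueCirc]:
        """Sequential IDs the consensus stage will assign, by genomic order."""
        ordered = sorted(
            self.true_circs, key=lambda c: (c.interval.chrom, c.interval.start, c.interval.end)
        )
        return {f"circRNA{i + 1}": c for i, c in enumerate(ordered)}


# ---------------------------------------------------------------------------
# study designs
# ---------------------------------------------------------------------------

def encephalon_design() -> list[SampleDesign]:
    """The 12-sample parietal-cortex design: 3 treatment groups of 4 animals."""
    groups = {
        "Adjuvant": ["114-E", "115-E", "116-E", "117-E"],
        "Vaccine": ["121-E", "122-E", "124-E", "126-E"],
        "Control": ["131-E", "135-E", "136-E", "137-E"],
    }
    return [
        SampleDesign(s, g, timepoint="Tf")
        for g, samples in groups.items()
        for s in samples
    ]


def pbmc_design() -> list[SampleDesign]:
    """The PBMC design: 2 treatment groups, 3 animals each, 2 timepoints."""
    rows = [
        ("121-A", "Adjuvant", "T0"), ("124-A", "Adjuvant", "T0"), ("125-A", "Adjuvant", "T0"),
        ("121-B", "Adjuvant", "Tf"), ("124-B", "Adjuvant", "Tf"), ("125-B", "Adjuvant", "Tf"),
        ("111-A", "Vaccine", "T0"), ("114-A", "Vaccine", "T0"), ("116-A", "Vaccine", "T0"),
        ("111-B", "Vaccine", "Tf"), ("114-B", "Vaccine", "Tf"), ("116-B", "Vaccine", "Tf"),
    ]
    return [SampleDesign(s, g, timepoint=t, batch=t) for s, g, t in rows]


# ---------------------------------------------------------------------------
# gene annotation
# ---------------------------------------------------------------------------

def gen_annotation(
    seed: int,
    n_genes: int = 60,
    exons_per_gene_range: tuple[int, int] = (2, 6),
    chrom_lengths: dict[str, int] | None = None,
    exon_len_range: tuple[int, int] = (100, 300),
    intron_len_range: tuple[int, int] = (100, 800),
    intergenic_range: tuple[int, int] = (500, 2000),
) -> GeneAnnotation:
    """Non-overlapping multi-exon genes, allocated to chromosomes in
    proportion to their length (longer chromosomes carry more genes, the
    pattern real circRNA catalogues show per chromosome)."""
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    chrom_lengths = chrom_lengths or {"chr1": 2_000_000, "chr2": 1_000_000}
    chroms = sorted(chrom_lengths)
    lengths = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    alloc = rng.multinomial(n_genes, lengths / lengths.sum())

    genes: list[Gene] = []
    exons: dict[str, list[GenomicInterval]] = {}
    gi = 0
    for chrom, k in zip(chroms, alloc):
        pos = int(rng.integers(*intergenic_range))
        for _ in range(k):
            n_ex = int(rng.integers(exons_per_gene_range[0], exons_per_gene_range[1] + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            ex_list: list[GenomicInterval] = []
            cursor = pos
            for j in range(n_ex):
                elen = int(rng.integers(*exon_len_range))
                ex_list.append(GenomicInterval(chrom, cursor, cursor + elen, strand))
                cursor += elen
                if j < n_ex - 1:
                    cursor += int(rng.integers(*intron_len_range))
            if cursor >= chrom_lengths[chrom]:
                raise GenerationError(
                    f"{chrom} (length {chrom_lengths[chrom]}) too short for {k} genes"
                )
            gi += 1
            gid = f"G{gi:04d}"
            genes.append(Gene(gid, f"gene{gi}", GenomicInterval(chrom, pos, cursor, strand)))
            exons[gid] = ex_list
            pos = cursor + int(rng.integers(*intergenic_range))
    return GeneAnnotation(genes, exons)


# ---------------------------------------------------------------------------
# planted circRNA truth
# ---------------------------------------------------------------------------

_DEFAULT_CATEGORY_WEIGHTS = {
    # roughly the mix reported for real catalogues: most circRNAs homologous,
    # a small not-aligned tail, the rest split among partial categories
    "homologous": 0.60,
    "no_homologous": 0.14,
    "five_prime_utilized": 0.08,
    "three_prime_utilized": 0.08,
    "both_sites_utilized": 0.05,
    "not_aligned": 0.05,
}

_DEFAULT_BOUNDARY_WEIGHTS = {
    "both_ends": 0.70,
    "one_end": 0.15,
    "neither": 0.10,
    "intergenic": 0.05,
}


def _weighted_cycle(rng: np.random.Generator, weights: dict[str, float], n: int) -> list[str]:
    """n labels matching the weights as closely as possible, each label
    appearing at least once when n allows, order shuffled deterministically."""
    labels = sorted(weights)
    counts = {lab: int(round(weights[lab] * n)) for lab in labels}
    if n >= len(labels):
        for lab in labels:
            counts[lab] = max(counts[lab], 1)
    seq: list[str] = []
    for lab in labels:
        seq.extend([lab] * counts[lab])
    seq = seq[:n]
    while len(seq) < n:
        seq.append(labels[int(rng.integers(len(labels)))])
    rng.shuffle(seq)
    return seq


def gen_truth(
    seed: int,
    ann: GeneAnnotation,
    n_circs: int = 40,
    category_weights: dict[str, float] | None = None,
    boundary_weights: dict[str, float] | None = None,
    min_circ_len: int = 100,
) -> SyntheticTruth:
    """Plant circRNAs on an annotation with known boundary classes, host
    genes and conservation categories (to be realized by
    :func:`gen_chain_for_truth` / :func:`gen_circ_db`)."""
    rng = np.random.default_rng(seed)
    cats = _weighted_cycle(rng, category_weights or _DEFAULT_CATEGORY_WEIGHTS, n_circs)
    bnds = _weighted_cycle(rng, boundary_weights or _DEFAULT_BOUNDARY_WEIGHTS, n_circs)

    gene_pool = [g for g in ann.genes if len(ann.exons.get(g.gene_id, [])) >= 1]
    rng.shuffle(gene_pool)
    if not gene_pool:
        raise GenerationError("annotation has no genes with exons")

    used: set[tuple[str, int, int]] = set()
    flanks: dict[str, list[int]] = {}
    circs: list[TrueCirc] = []
    gene_iter = iter(gene_pool * ((n_circs // max(1, len(gene_pool))) + 6))

    def take_gene(min_exons: int = 1) -> Gene:
        for g in gene_iter:
            if len(ann.exons[g.gene_id]) >= min_exons:
                return g
        raise GenerationError("ran out of genes for planting circRNAs")

    for cat, bclass in zip(cats, bnds):
        for _attempt in range(50):
            if bclass == "intergenic":
                # midpoint of the widest gap between genes on a chromosome
                by_chrom: dict[str, list[Gene]] = {}
                for g in ann.genes:
                    by_chrom.setdefault(g.interval.chrom, []).append(g)
                chrom = sorted(by_chrom)[int(rng.integers(len(by_chrom)))]
                gs = sorted(by_chrom[chrom], key=lambda g: g.interval.start)
                gaps = [
                    (gs[i].interval.end, gs[i + 1].interval.start)
                    for i in range(len(gs) - 1)
                    if gs[i + 1].interval.start - gs[i].interval.end > min_circ_len + 40
                ]
                if not gaps:
                    continue
                lo, hi = gaps[int(rng.integers(len(gaps)))]
                start = int(rng.integers(lo + 10, hi - min_circ_len - 10))
                iv = GenomicInterval(chrom, start, start + min_circ_len + int(rng.integers(0, 100)), ".")
                host = None
            else:
                g = take_gene(min_exons=2 if bclass == "neither" else 1)
                exs = ann.exons[g.gene_id]
                i = int(rng.integers(len(exs)))
                j = int(rng.integers(i, len(exs)))
                start, end = exs[i].start, exs[j].end
                if bclass == "one_end":
                    shift = int(rng.integers(5, 30))
                    start += shift
                    if any(abs(e.start - start) == 0 for e in exs):
                        continue
                elif bclass == "neither":
                    k = int(rng.integers(len(exs) - 1))
                    lo, hi = exs[k].end + 5, exs[k + 1].start - 5
                    if hi - lo < min_circ_len:
                        # fall back to shifting both ends into exon bodies
                        start, end = exs[i].start + 7, exs[j].end - 7
                        if any(e.start == start for e in exs) or any(e.end == end for e in exs):
                            continue
                    else:
                        start, end = lo, min(hi, lo + min_circ_len + int(rng.integers(0, 50)))
                if end - start < min_circ_len:
                    continue
                iv = GenomicInterval(g.interval.chrom, start, end, g.interval.strand)
                host = g.gene_id
            if iv.key in used:
                continue
            # keep splice-site flanks well separated so a planted DB record
            # cannot cross-match another circRNA's lifted splice sites, even
            # after chain gaps shrink distances in the target genome
            new_flanks = (iv.start, iv.end - 1)
            if any(
                abs(f - g) < 300 for f in new_flanks for g in flanks.get(iv.chrom, [])
            ):
                continue
            used.add(iv.key)
            flanks.setdefault(iv.chrom, []).extend(new_flanks)
            circs.append(TrueCirc(iv, cat, host, bclass))
            break
        else:
            raise GenerationError(f"could not place a {bclass}/{cat} circRNA")

    de_effects = {f"planted{i}": {} for i in range(0)}  # null by default
    return SyntheticTruth(circs, {}, de_effects, seed)


# ---------------------------------------------------------------------------
# caller tables
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float, size: int) -> np.ndarray:
    """NB2 draw: variance = mean + dispersion * mean^2."""
    if dispersion <= 0:
        return rng.poisson(mean, size)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size)


def gen_caller_tables(
    truth: SyntheticTruth,
    design: Sequence[SampleDesign],
    fp_rate_per_caller: float = 0.5,
    dropout_rate: float = 0.05,
    count_model: tuple[float, float] = (4.0, 0.5),
    seed: int | None = None,
    count_floor: int = 0,
    chrom_lengths: dict[str, int] | None = None,
) -> tuple[BsjCallSet, BsjCallSet]:
    """Two callers' junction tables: shared true positives, caller-private
    false positives, per-(caller, sample) negative-binomial counts.

    ``count_floor`` clamps true-circRNA counts from below; with
    ``fp_rate=0, dropout=0, count_floor >= min_count`` the downstream
    consensus recovers exactly the planted set (the noiseless limit).
    """
    if not (0 <= fp_rate_per_caller <= 1 and 0 <= dropout_rate <= 1):
        raise ValueError("rates must lie in [0, 1]")
    rng = np.random.default_rng(truth.seed + 1 if seed is None else seed)
    mean, disp = count_model
    samples = [d.sample_id for d in design]
    n = len(samples)
    ids = truth.expected_ids()
    fc_by_circ = {
        cid: truth.de_effects.get(cid, {}) for cid in ids
    }
    group_of = {d.sample_id: d.group for d in design}

    calls_a: list[tuple[GenomicInterval, np.ndarray]] = []
    calls_b: list[tuple[GenomicInterval, np.ndarray]] = []
    for cid, tc in ids.items():
        drop_a = rng.random() < dropout_rate
        drop_b = rng.random() < dropout_rate
        for drop, calls in ((drop_a, calls_a), (drop_b, calls_b)):
            if drop:
                continue
            counts = np.empty(n, dtype=np.int64)
            for si, s in enumerate(samples):
                fc = fc_by_circ[cid].get(group_of[s], 1.0)
                counts[si] = _nb_draw(rng, mean * fc, disp, 1)[0]
            if count_floor:
                counts = np.maximum(counts, count_floor)
            calls.append((tc.interval, counts))

    chrom_lengths = chrom_lengths or {}
    used = {tc.interval.key for tc in truth.true_circs}
    n_fp = int(round(fp_rate_per_caller * len(truth.true_circs)))
    chroms = sorted({tc.interval.chrom for tc in truth.true_circs})
    for calls in (calls_a, calls_b):
        made = 0
        while made < n_fp:
            chrom = chroms[int(rng.integers(len(chroms)))]
            limit = chrom_lengths.get(chrom, 1_000_000)
            start = int(rng.integers(0, max(1, limit - 500)))
            end = start + int(rng.integers(80, 400))
            key = (chrom, start, end)
            if key in used:
                continue
            used.add(key)  # FPs are caller-private junctions
            counts = np.maximum(_nb_draw(rng, mean, disp, n), count_floor)
            calls.append((GenomicInterval(chrom, start, end, "+" if rng.random() < 0.5 else "-"), counts))
            made += 1

    return (
        BsjCallSet("dcc_sim", samples, calls_a),
        BsjCallSet("segemehl_sim", samples, calls_b),
    )


# ---------------------------------------------------------------------------
# chains
# ---------------------------------------------------------------------------

def gen_chain(
    seed: int,
    source_length: int = 10_000,
    n_blocks: int = 10,
    gap_model: tuple[int, int] = (0, 30),
    inversion_prob: float = 0.0,
    source_name: str = "chr1",
    target_name: str = "hchr1",
) -> ChainSet:
    """One random chain: ``n_blocks`` gapless blocks separated by random
    source/target gaps, inverted with probability ``inversion_prob``."""
    rng = np.random.default_rng(seed)
    blocks: list[ChainBlock] = []
    for i in range(n_blocks):
        size = int(rng.integers(5, max(6, source_length // (2 * n_blocks))))
        if i == n_blocks - 1:
            blocks.append(ChainBlock(size))
        else:
            sg = int(rng.integers(gap_model[0], gap_model[1] + 1))
            tg = int(rng.integers(gap_model[0], gap_model[1] + 1))
            blocks.append(ChainBlock(size, sg, tg))
    src_span = sum(b.size + b.source_gap for b in blocks)
    tgt_span = sum(b.size + b.target_gap for b in blocks)
    source_start = int(rng.integers(0, max(1, source_length - src_span)))
    inverted = rng.random() < inversion_prob
    target_size = tgt_span + int(rng.integers(0, 1000))
    target_start = int(rng.integers(0, target_size - tgt_span + 1))
    chain = Chain(
        score=1000.0,
        source_name=source_name, source_size=max(source_length, source_start + src_span),
        source_strand="+", source_start=source_start, source_end=source_start + src_span,
        target_name=target_name, target_size=target_size,
        target_strand="-" if inverted else "+",
        target_start=target_start, target_end=target_start + tgt_span,
        blocks=blocks, chain_id=1,
    )
    return ChainSet([chain])


def gen_chain_for_truth(
    seed: int,
    truth: SyntheticTruth,
    chrom_lengths: dict[str, int],
    gap_model: tuple[int, int] = (5, 40),
    n_extra_gaps: int = 8,
    inversion_prob: float = 0.25,
    target_prefix: str = "h",
) -> ChainSet:
    """One chain per chromosome, arranged so every planted circRNA's
    splice sites lift — except the ``not_aligned`` ones, whose right
    flank is buried inside a source gap."""
    rng = np.random.default_rng(seed)
    chains: list[Chain] = []
    for ci, chrom in enumerate(sorted(chrom_lengths), start=1):
        L = chrom_lengths[chrom]
        must_map: set[int] = set()
        must_gap: set[int] = set()
        for tc in truth.true_circs:
            if tc.interval.chrom != chrom:
                continue
            flanks = (tc.interval.start, tc.interval.end - 1)
            if tc.category == "not_aligned":
                must_map.add(flanks[0])
                must_gap.add(flanks[1])
            else:
                must_map.update(flanks)

        gap_regions: list[tuple[int, int]] = [(u, u + 3) for u in sorted(must_gap)]
        tries = 0
        while len(gap_regions) < len(must_gap) + n_extra_gaps and tries < 200:
            tries += 1
            glen = int(rng.integers(*gap_model))
            gstart = int(rng.integers(0, max(1, L - glen)))
            region = (gstart, gstart + glen)
            if any(region[0] < p + 2 and p - 1 < region[1] for p in must_map):
                continue
            if any(region[0] < e + 2 and s - 2 < region[1] for s, e in gap_regions):
                continue
            gap_regions.append(region)
        gap_regions.sort()

        blocks: list[ChainBlock] = []
        cursor = 0
        for gs, ge in gap_regions:
            if gs <= cursor:
                continue
            size = gs - cursor
            tg = int(rng.integers(0, 25))
            blocks.append(ChainBlock(size, ge - gs, tg))
            cursor = ge
        last = max(cursor + 1, max(must_map) + 2 if must_map else cursor + 100)
        last = min(L, max(last, cursor + 50))
        blocks.append(ChainBlock(last - cursor))

        src_span = sum(b.size + b.source_gap for b in blocks)
        tgt_span = sum(b.size + b.target_gap for b in blocks)
        inverted = rng.random() < inversion_prob
        target_size = tgt_span + 500
        chains.append(
            Chain(
                score=1000.0 + ci,
                source_name=chrom, source_size=L, source_strand="+",
                source_start=0, source_end=src_span,
                target_name=f"{target_prefix}{chrom}", target_size=target_size,
                target_strand="-" if inverted else "+",
                target_start=100, target_end=100 + tgt_span,
                blocks=blocks, chain_id=ci,
            )
        )
    return ChainSet(chains)


# ---------------------------------------------------------------------------
# circRNA database with planted conservation outcomes
# ---------------------------------------------------------------------------

def gen_circ_db(
    truth: SyntheticTruth,
    chains: ChainSet,
    seed: int | None = None,
    tolerance_nt: int = 2,
    min_ratio: float = 0.95,
    host_genes: dict[str, str] | None = None,
    verify: bool = True,
) -> list[CircDbRecord]:
    """Place database records so that lifting and classifying each planted
    circRNA yields exactly its planted category.

    Matching records are planted at offsets cycling through
    ``-tolerance..+tolerance`` (so the +-2 boundary is exercised on the
    matching side); non-matching sites sit exactly ``tolerance + 1`` bases
    away (the -+3 negative boundary).  ``host_genes`` optionally maps a
    planted circ's source key to a target-species host gene recorded on
    its DB entry.  With ``verify`` the classifier is run on the result and
    a :class:`GenerationError` is raised on any mismatch — impossible
    placements (e.g. a homologous circ whose end falls in a chain gap)
    surface here.
    """
    rng = np.random.default_rng(truth.seed + 2 if seed is None else seed)
    offsets = list(range(-tolerance_nt, tolerance_nt + 1))
    far = tolerance_nt + 1
    records: list[CircDbRecord] = []
    ids = truth.expected_ids()
    k = 0

    def next_off() -> int:
        nonlocal k
        off = offsets[k % len(offsets)]
        k += 1
        return off

    def make_record(chrom: str, site_a: int, site_b: int, host: str = "") -> CircDbRecord:
        lo, hi = min(site_a, site_b), max(site_a, site_b)
        rid = f"HSA_CIRC_{len(records) + 1:06d}"
        return CircDbRecord(rid, GenomicInterval(chrom, lo, hi + 1, "."), host)

    for cid, tc in ids.items():
        l5, l3 = lift_circ_ends(chains, tc.interval, min_ratio)
        host = (host_genes or {}).get(cid, "")
        if tc.category == "not_aligned":
            if l5.mapped and l3.mapped:
                raise GenerationError(
                    f"{cid}: planted not_aligned but both splice sites lifted"
                )
            continue
        if not (l5.mapped and l3.mapped):
            raise GenerationError(
                f"{cid}: planted {tc.category} but a splice site failed to lift"
            )
        p5, p3 = l5.target.start, l3.target.start
        chrom = l5.target.chrom
        if tc.category == "homologous":
            records.append(make_record(chrom, p5 + next_off(), p3 + next_off(), host))
        elif tc.category == "no_homologous":
            # both sites exactly tolerance+1 away: the negative boundary
            away5 = p5 + far if abs(p5 + far - p3) > tolerance_nt else p5 - far
            away3 = p3 - far if abs(p3 - far - p5) > tolerance_nt else p3 + far
            records.append(make_record(chrom, away5, away3, host))
        elif tc.category in ("five_prime_utilized", "three_prime_utilized"):
            hit = p5 if tc.category == "five_prime_utilized" else p3
            other = p3 if tc.category == "five_prime_utilized" else p5
            partner = hit + 40 if abs(hit + 40 - other) > far else hit - 40
            records.append(make_record(chrom, hit + next_off(), partner, host))
        elif tc.category == "both_sites_utilized":
            part5 = p5 + 40 if abs(p5 + 40 - p3) > far else p5 - 40
            part3 = p3 - 40 if abs(p3 - 40 - p5) > far else p3 + 40
            records.append(make_record(chrom, p5 + next_off(), part5, host))
            records.append(make_record(chrom, p3 + next_off(), part3, host))

    if verify:
        for cid, tc in ids.items():
            call = conserve(cid, tc.interval, chains, records, tolerance_nt, min_ratio)
            if call.category != tc.category:
                raise GenerationError(
                    f"{cid}: planted {tc.category} but classified {call.category}"
                )
    return records


# ---------------------------------------------------------------------------
# sponge fixtures
# ---------------------------------------------------------------------------

_RNA_COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}


def _revcomp_rna(seq: str) -> str:
    return "".join(_RNA_COMP[b] for b in reversed(seq))


def _seed_window_ok(window: str, seed_seq: str, min_seed_pairs: int) -> bool:
    """True if this 8-base target window could satisfy the scanner's seed test."""
    pairs = 0
    for i, mb in enumerate(seed_seq):
        tb = window[len(seed_seq) - 1 - i]
        if (mb, tb) in (("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")):
            pairs += 1
    return pairs >= min_seed_pairs


def gen_sponge_fixture(
    seed: int,
    circ_length: int,
    mirna: MirnaRecord,
    n_planted_sites: int = 5,
    spacing: int = 30,
    min_seed_pairs: int = 6,
    max_site_len: int = 20,
    score_threshold: int = -10,
) -> tuple[str, list[tuple[str, int, int]]]:
    """A circRNA sequence (DNA alphabet) with exact full-length binding
    sites embedded in seed-free background.

    The background is rejection-sampled so no 8-base window passes the
    scanner's seed criterion (>= ``min_seed_pairs`` of 8 positions paired)
    — any reported site must pass that test, so off-site background can
    contribute exactly zero sites.  Planted sites are exact reverse
    complements of the full miRNA; the expected-site coordinates are
    those of the perfect ``max_site_len``-base duplex window the scanner
    reports.
    """
    m = mirna.sequence
    footprint = len(m)
    if n_planted_sites * (footprint + spacing) > circ_length:
        raise GenerationError(
            f"{n_planted_sites} sites of footprint {footprint} + spacing {spacing} "
            f"exceed circ length {circ_length}"
        )
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGU"))
    seed_seq = m[:8]

    seq = list(rng.choice(bases, size=circ_length))

    def clean_windows(positions_to_skip: list[tuple[int, int]]) -> None:
        """Resample until no background window passes the seed criterion."""
        for _ in range(2000):
            dirty = []
            s = "".join(seq)
            for x in range(0, circ_length - 7):
                if any(a <= x + 7 and x < b for a, b in positions_to_skip):
                    continue
                if _seed_window_ok(s[x : x + 8], seed_seq, min_seed_pairs):
                    dirty.append(x)
            if not dirty:
                return
            for x in dirty:
                for j in range(x, x + 8):
                    if not any(a <= j < b for a, b in positions_to_skip):
                        seq[j] = str(rng.choice(bases))
        raise GenerationError("could not generate seed-free background")

    clean_windows([])

    step = footprint + spacing
    start0 = (circ_length - n_planted_sites * step + spacing) // 2
    embeds: list[tuple[int, int]] = []
    site_rna = _revcomp_rna(m)
    for i in range(n_planted_sites):
        p = start0 + i * step
        seq[p : p + footprint] = list(site_rna)
        embeds.append((p, p + footprint))
    clean_windows(embeds)

    L = min(footprint, max_site_len)
    expected_windows = [(p + footprint - L, p + footprint) for p, _ in embeds]

    # repair loop: windows straddling an embed boundary can still pass the
    # seed test using embedded bases; resample their background bases until
    # the raw scan reports exactly the planted windows
    for _ in range(200):
        raw = scan_binding_sites(
            "fixture", "".join(seq), mirna, (1, 8), min_seed_pairs,
            max_site_len, score_threshold,
        )
        spurious = [s for s in raw if (s.start, s.end) not in expected_windows]
        if not spurious:
            break
        touched = False
        for s in spurious:
            for j in range(s.start, s.end):
                if not any(a <= j < b for a, b in embeds):
                    seq[j] = str(rng.choice(bases))
                    touched = True
        if not touched:
            raise GenerationError("spurious site lies entirely within planted bases")
    else:
        raise GenerationError("could not purge spurious sites from sponge fixture")

    dna = "".join(seq).replace("U", "T")
    expected = [(mirna.name, s, e) for s, e in expected_windows]
    return dna, expected


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------

def gen_counts(
    design: Sequence[SampleDesign],
    truth: SyntheticTruth,
    library_sizes: dict[str, int] | None = None,
    seed: int | None = None,
    count_model: tuple[float, float] = (4.0, 0.5),
) -> tuple[pd.DataFrame, pd.Series]:
    """CircRNA x sample count matrix plus per-sample mapped-read totals.

    Counts are NB2 draws with mean scaled by the sample's group
    fold-change (from ``truth.de_effects``; 1.0 = null) and by the
    sample's library size relative to the mean library.
    """
    rng = np.random.default_rng(truth.seed + 3 if seed is None else seed)
    samples = [d.sample_id for d in design]
    library_sizes = library_sizes or {
        s: int(30e6 + rng.integers(0, 10e6)) for s in samples
    }
    libs = pd.Series({s: library_sizes[s] for s in samples}, dtype=float)
    rel = libs / libs.mean()
    mean, disp = count_model
    group_of = {d.sample_id: d.group for d in design}
    ids = list(truth.expected_ids())
    mat = np.zeros((len(ids), len(samples)), dtype=np.int64)
    for i, cid in enumerate(ids):
        effects = truth.de_effects.get(cid, {})
        for j, s in enumerate(samples):
            fc = effects.get(group_of[s], 1.0)
            mat[i, j] = _nb_draw(rng, mean * fc * rel[s], disp, 1)[0]
    counts = pd.DataFrame(mat, index=ids, columns=samples)
    return counts, libs.astype(int)


def gen_null_counts(
    seed: int,
    n_circs: int = 1000,
    design: Sequence[SampleDesign] | None = None,
    count_model: tuple[float, float] = (4.0, 0.5),
) -> tuple[pd.DataFrame, pd.Series, list[SampleDesign]]:
    """A pure null dataset: identical NB distributions in every group."""
    design = list(design) if design is not None else encephalon_design()
    rng = np.random.default_rng(seed)
    samples = [d.sample_id for d in design]
    mean, disp = count_model
    mat = _nb_draw(rng, mean, disp, n_circs * len(samples)).reshape(n_circs, len(samples))
    counts = pd.DataFrame(mat, index=[f"circRNA{i+1}" for i in range(n_circs)], columns=samples)
    totals = pd.Series({s: int(30e6 + rng.integers(0, 10e6)) for s in samples})
    return counts, totals, design


# ---------------------------------------------------------------------------
# full fixture bundle
# ---------------------------------------------------------------------------

def truth_to_json(truth: SyntheticTruth) -> str:
    payload = {
        "seed": truth.seed,
        "true_circs": [
            {
                "chrom": c.interval.chrom, "start": c.interval.start,
                "end": c.interval.end, "strand": c.interval.strand,
                "category": c.category, "host_gene": c.host_gene,
                "boundary_class": c.boundary_class,
            }
            for c in truth.true_circs
        ],
        "planted_sponge_sites": truth.planted_sponge_sites,
        "de_effects": truth.de_effects,
    }
    return json.dumps(payload, indent=1, sort_keys=True)


def simulate_bundle(seed: int, out_dir, n_genes: int = 60, n_circs: int = 40) -> SyntheticTruth:
    """Emit the complete fixture bundle to ``out_dir``: GTF, two caller
    tables, chain file, circRNA DB, sponge FASTA + miRNA table, sample
    sheet, count matrix and the planted truth as JSON."""
    import os

    from . import io as cio

    os.makedirs(out_dir, exist_ok=True)
    chrom_lengths = {"chr1": 2_000_000, "chr2": 1_000_000}
    ann = gen_annotation(seed, n_genes=n_genes, chrom_lengths=chrom_lengths)
    truth = gen_truth(seed + 1, ann, n_circs=n_circs)
    design = encephalon_design()
    a, b = gen_caller_tables(truth, design, seed=seed + 2, chrom_lengths=chrom_lengths)
    chains = gen_chain_for_truth(seed + 3, truth, chrom_lengths)
    db = gen_circ_db(truth, chains, seed=seed + 4)
    mir = MirnaRecord("miR-7_sim", "UGGAAGACUAGUGAUUUUGUUGU", orthology_confident=True)
    circ_seq, sites = gen_sponge_fixture(seed + 5, 2000, mir)
    truth.planted_sponge_sites = {"circRNA_sponge": sites}
    counts, totals = gen_counts(design, truth, seed=seed + 6)

    cio.write_gtf(ann, os.path.join(out_dir, "annotation.gtf"))
    cio.write_caller_table(a, os.path.join(out_dir, "caller_dcc.tsv"), dialect="dcc")
    cio.write_caller_table(b, os.path.join(out_dir, "caller_segemehl.tsv"), dialect="segemehl")
    cio.write_chain(chains, os.path.join(out_dir, "lift.chain"))
    cio.write_circ_db(db, os.path.join(out_dir, "circ_db.tsv"))
    cio.write_fasta({"circRNA_sponge": circ_seq}, os.path.join(out_dir, "circ_seqs.fasta"))
    cio.write_fasta({mir.name: mir.sequence.replace("U", "T")}, os.path.join(out_dir, "mirnas.fasta"))
    pd.DataFrame(
        [{"name": mir.name, "orthology_confident": True,
          "hairpin_identity": "", "hairpin_coverage": ""}]
    ).to_csv(os.path.join(out_dir, "mirna_orthology.tsv"), sep="\t", index=False)
    cio.write_sample_sheet(design, os.path.join(out_dir, "samples.tsv"))
    counts.rename_axis("circ_id").to_csv(os.path.join(out_dir, "counts.tsv"), sep="\t")
    totals.rename_axis("sample_id").rename("mapped_total").to_csv(
        os.path.join(out_dir, "mapped_totals.tsv"), sep="\t"
    )
    with open(os.path.join(out_dir, "truth.json"), "w") as fh:
        fh.write(truth_to_json(truth))
    return truth
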