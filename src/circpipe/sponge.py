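"""miRNA-sponge screening of circRNAs.

Stages mirror the usual sponge workflow: (1) intersect lifted circRNA
coordinates with reported clusters of miRNA binding sites (>= 75% of the
cluster covered); (2) drop pairs whose miRNA has no confident orthologue
in the study species; (3) scan circRNA sequences for binding sites with a
seed-complementarity duplex model; (4) remove overlapping sites greedily
by score; (5) report the per-base site ratio and, for individual sites,
an end-to-end duplex profile.

The duplex model is a deliberately simple integer score — Watson-Crick
pair -2, G:U wobble -1, mismatch +1, gap +3 (the scan itself is ungapped)
— not a thermodynamic free-energy model.  Parameters mirror the common
seed-scanner conventions: seed span 1-8 of the miRNA, at least 6 of those
8 positions paired, duplex limited to 20 target bases, score threshold
-10.  What downstream analysis consumes is the presence and density of
sites, which this model captures.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .types import GenomicInterval

WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
WOBBLE = {("G", "U"), ("U", "G")}
RNA_ALPHABET = set("ACGU")

SCORE_WC = -2
SCORE_WOBBLE = -1
SCORE_MISMATCH = 1
SCORE_GAP = 3  # the default scan is ungapped; exposed for completeness


@dataclass(frozen=True)
class SpongeCluster:
    """A reported cluster of binding sites for one miRNA (target-genome coords)."""

    interval: GenomicInterval
    mirna: str
    reported_site_count: int = 1

    def __post_init__(self) -> None:
        if self.reported_site_count < 1:
            raise ValueError("reported_site_count must be >= 1")


@dataclass
class MirnaRecord:
    """A mature miRNA with orthology evidence for the study species."""

    name: str
    sequence: str  # mature sequence, RNA alphabet, 5'->3'
    orthology_confident: bool = False
    hairpin_identity: float | None = None
    hairpin_coverage: float | None = None

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("T", "U")
        if not seq or set(seq) - RNA_ALPHABET:
            raise ValueError(f"miRNA {self.name}: invalid sequence {self.sequence!r}")
        self.sequence = seq


@dataclass(frozen=True)
class BindingSite:
    """A scored duplex location on a circRNA sequence (0-based half-open)."""

    circ_id: str
    start: int
    end: int
    mirna: str
    score: int  # more negative = stronger
    seed_pairs: int
    mismatches: int

    def overlaps(self, other: "BindingSite") -> bool:
        return self.start < other.end and other.start < self.end


def _paired(m_base: str, t_base: str) -> int:
    """0 = mismatch, 1 = wobble, 2 = Watson-Crick."""
    if (m_base, t_base) in WC:
        return 2
    if (m_base, t_base) in WOBBLE:
        return 1
    return 0


def to_rna(seq: str) -> str:
    seq = seq.upper().replace("T", "U")
    bad = set(seq) - RNA_ALPHABET
    if bad:
        raise ValueError(f"non-nucleotide characters in sequence: {sorted(bad)}")
    return seq


def intersect_clusters(
    lifted_circs: Sequence[tuple[str, GenomicInterval]],
    clusters: Sequence[SpongeCluster],
    min_frac: float = 0.75,
) -> list[tuple[str, SpongeCluster]]:
    """(circ_id, cluster) pairs where the circRNA covers >= ``min_frac`` of
    the cluster (fraction relative to the cluster; inclusive threshold)."""
    out = []
    for circ_id, iv in lifted_circs:
        for cl in clusters:
            frac = iv.overlap_length(cl.interval) / len(cl.interval)
            if frac >= min_frac:
                out.append((circ_id, cl))
    return out


def filter_orthology(
    pairs: Sequence[tuple[str, SpongeCluster]],
    mirnas: Sequence[MirnaRecord],
    min_identity: float = 0.90,
    min_coverage: float = 0.95,
) -> list[tuple[str, SpongeCluster]]:
    """Keep pairs whose miRNA has a confident orthologue in the study species.

    A miRNA passes when flagged ``orthology_confident``, or when its
    hairpin aligns with identity >= ``min_identity`` over >= ``min_coverage``
    of its length (both inclusive).  Every pair's miRNA must be present in
    ``mirnas``.
    """
    by_name = {m.name: m for m in mirnas}
    missing = {cl.mirna for _, cl in pairs} - set(by_name)
    if missing:
        raise KeyError(f"miRNAs absent from records: {sorted(missing)}")

    def ok(m: MirnaRecord) -> bool:
        if m.orthology_confident:
            return True
        if m.hairpin_identity is None or m.hairpin_coverage is None:
            return False
        return m.hairpin_identity >= min_identity and m.hairpin_coverage >= min_coverage

    return [(cid, cl) for cid, cl in pairs if ok(by_name[cl.mirna])]


def scan_binding_sites(
    circ_id: str,
    circ_seq: str,
    mirna: MirnaRecord,
    seed_span: tuple[int, int] = (1, 8),
    min_seed_pairs: int = 6,
    max_site_len: int = 20,
    score_threshold: int = -10,
    orientation: str = "forward",
) -> list[BindingSite]:
    """Scan a circRNA sequence for miRNA binding sites.

    The miRNA is slid antiparallel along the target: miRNA position ``i``
    (0-based, from the 5' end) pairs with target position ``end - 1 - i``.
    A window is a site when >= ``min_seed_pairs`` of the seed positions
    (miRNA bases ``seed_span``, 1-based inclusive) pair (Watson-Crick or
    G:U) AND the ungapped duplex over min(miRNA length, ``max_site_len``)
    target bases scores <= ``score_threshold``.

    ``orientation="reverse"`` scans the reverse complement of the target
    and mirrors the coordinates back onto the input sequence.
    """
    t = to_rna(circ_seq)
    if orientation == "reverse":
        comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
        rc = "".join(comp[b] for b in reversed(t))
        n = len(t)
        sites = scan_binding_sites(
            circ_id, rc, mirna, seed_span, min_seed_pairs, max_site_len,
            score_threshold, orientation="forward",
        )
        mirrored = [
            BindingSite(s.circ_id, n - s.end, n - s.start, s.mirna, s.score,
                        s.seed_pairs, s.mismatches)
            for s in sites
        ]
        return sorted(mirrored, key=lambda s: s.start)
    if orientation != "forward":
        raise ValueError(f"unknown orientation {orientation!r}")

    m = mirna.sequence
    lo, hi = seed_span
    if not (1 <= lo <= hi <= len(m)):
        raise ValueError(f"seed span {seed_span} outside miRNA of length {len(m)}")
    seed_idx = range(lo - 1, hi)
    L = min(len(m), max_site_len)
    if L < hi:
        raise ValueError("site length cannot be shorter than the seed span")

    sites: list[BindingSite] = []
    for e in range(L, len(t) + 1):
        s = e - L
        seed_pairs = sum(1 for i in seed_idx if _paired(m[i], t[e - 1 - i]) > 0)
        if seed_pairs < min_seed_pairs:
            continue
        score = 0
        mismatches = 0
        for i in range(L):
            p = _paired(m[i], t[e - 1 - i])
            if p == 2:
                score += SCORE_WC
            elif p == 1:
                score += SCORE_WOBBLE
            else:
                score += SCORE_MISMATCH
                mismatches += 1
        if score <= score_threshold:
            sites.append(
                BindingSite(circ_id, s, e, mirna.name, score, seed_pairs, mismatches)
            )
    return sites


def remove_overlaps(sites: Sequence[BindingSite]) -> list[BindingSite]:
    """Greedy non-overlapping selection, strongest (most negative score)
    first; ties broken by leftmost start, then shortest site.  Output is
    sorted by start position."""
    kept: list[BindingSite] = []
    for site in sorted(sites, key=lambda s: (s.score, s.start, s.end - s.start)):
        if all(not site.overlaps(k) for k in kept):
            kept.append(site)
    return sorted(kept, key=lambda s: s.start)


def per_base_ratio(sites: Sequence[BindingSite], circ_length: int) -> float:
    """Non-overlapping binding sites per base of the harbouring sequence."""
    if circ_length <= 0:
        raise ValueError("circ_length must be positive")
    return len(sites) / circ_length


def duplex_profile(
    mirna: MirnaRecord, site_seq: str, seed_span: tuple[int, int] = (1, 8)
) -> tuple[int, int, str]:
    """End-to-end ungapped duplex of the miRNA against one site sequence.

    Returns (canonical seed pairs, total mismatches, pairing string).
    The pairing string runs 5'->3' along the miRNA: ``|`` Watson-Crick,
    ``:`` G:U wobble, ``.`` mismatch (overhangs count as mismatches).
    G:U pairs count toward complementarity but not toward "canonical".
    """
    m = mirna.sequence
    t = to_rna(site_seq)
    lo, hi = seed_span
    marks = []
    canonical_seed = 0
    mismatches = 0
    span = max(len(m), len(t))
    for i in range(span):
        j = len(t) - 1 - i
        if i >= len(m) or j < 0:
            marks.append(".")
            mismatches += 1
            continue
        p = _paired(m[i], t[j])
        if p == 2:
            marks.append("|")
            if lo - 1 <= i <= hi - 1:
                canonical_seed += 1
        elif p == 1:
            marks.append(":")
        else:
            marks.append(".")
            mismatches += 1
    return canonical_seed, mismatches, "".join(marks)


def read_clusters_bed(path) -> list[SpongeCluster]:
    """Read sponge clusters from BED-plus: chrom start end miRNA site_count [strand]."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split("\t")
            try:
                chrom, start, end, mir = f[0], int(f[1]), int(f[2]), f[3]
                count = int(f[4]) if len(f) > 4 else 1
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}: line {lineno}: malformed cluster row") from exc
            strand = f[5] if len(f) > 5 and f[5] in ("+", "-") else "."
            out.append(SpongeCluster(GenomicInterval(chrom, start, end, strand), mir, count))
    return out


def load_mirnas(fasta: dict[str, str], ortho_table) -> list[MirnaRecord]:
    """Combine a mature-miRNA FASTA with an orthology-confidence table.

    ``ortho_table`` is a DataFrame with columns ``name``,
    ``orthology_confident`` and optional ``hairpin_identity`` /
    ``hairpin_coverage``.
    """
    import pandas as pd

    meta = {str(r["name"]): r for _, r in ortho_table.iterrows()}
    out = []
    for name, seq in fasta.items():
        row = meta.get(name)
        conf = False
        ident = cov = None
        if row is not None:
            conf = str(row["orthology_confident"]).strip().lower() in ("1", "true", "yes")
            ident = None if pd.isna(row.get("hairpin_identity")) else float(row["hairpin_identity"])
            cov = None if pd.isna(row.get("hairpin_coverage")) else float(row["hairpin_coverage"])
        out.append(MirnaRecord(name, seq, conf, ident, cov))
    return out
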