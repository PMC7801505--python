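"""Readers and writers for every external format the pipeline touches.

Internally every coordinate is 0-based half-open.  Each reader declares the
convention of its source format (``one_closed`` for GTF/GFF and DCC-style
tables, ``zero_half_open`` for BED-like files) and converts on ingestion,
so downstream code never sees mixed conventions.

Caller-table dialects
---------------------
``dcc``
    Tab-separated with a header line; columns ``Chr``, ``Start``, ``End``,
    ``Strand`` followed by one count column per sample (named by sample).
    Coordinates default to 1-based closed, as DCC emits.
``segemehl``
    BED6-like, no header: ``chrom start end name score strand`` followed by
    one count column per sample.  Coordinates default to 0-based half-open.
    Sample names must be supplied (or are auto-named ``s1..sN``).
``generic``
    Like ``dcc`` but with lower-case ``chrom start end strand`` headers.
"""

from __future__ import annotations

import logging
import os
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

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
    ValidationError,
    check_design,
)

logger = logging.getLogger(__name__)

ZERO_HALF_OPEN = "zero_half_open"
ONE_CLOSED = "one_closed"


class ParseError(ValueError):
    """Raised on a malformed input row; names the offending line."""


def to_internal(start: int, end: int, convention: str) -> tuple[int, int]:
    """Convert (start, end) in ``convention`` to 0-based half-open."""
    if convention == ZERO_HALF_OPEN:
        return start, end
    if convention == ONE_CLOSED:
        return start - 1, end
    raise ValueError(f"unknown coordinate convention {convention!r}")


def from_internal(start: int, end: int, convention: str) -> tuple[int, int]:
    """Inverse of :func:`to_internal`."""
    if convention == ZERO_HALF_OPEN:
        return start, end
    if convention == ONE_CLOSED:
        return start + 1, end
    raise ValueError(f"unknown coordinate convention {convention!r}")


_DIALECTS = {
    "dcc": dict(header=True, default_convention=ONE_CLOSED, bedlike=False),
    "segemehl": dict(header=False, default_convention=ZERO_HALF_OPEN, bedlike=True),
    "generic": dict(header=True, default_convention=ZERO_HALF_OPEN, bedlike=False),
}


def read_caller_table(
    path: str | os.PathLike,
    dialect: str = "generic",
    convention: str | None = None,
    sample_names: Sequence[str] | None = None,
    caller_id: str | None = None,
) -> BsjCallSet:
    """Read one caller's backsplice-junction table into a :class:`BsjCallSet`.

    Duplicate junction rows (same chrom/start/end/strand) within the file
    are summed, with a logged warning — real caller output occasionally
    repeats a junction across annotation contexts.

    Raises
    ------
    ParseError
        On a malformed row, naming the 1-based line number.
    ValidationError
        On a negative count.
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    cfg = _DIALECTS[dialect]
    convention = convention or cfg["default_convention"]
    caller_id = caller_id or dialect

    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    lines = [(i + 1, ln) for i, ln in enumerate(lines) if ln.strip()]
    if not lines:
        return BsjCallSet(caller_id, list(sample_names or []), [])

    if cfg["bedlike"]:
        meta_cols = 6  # chrom start end name score strand
        first_fields = lines[0][1].split("\t")
        n_samples = len(first_fields) - meta_cols
        if n_samples < 1:
            raise ParseError(f"{path}: line 1: expected >= {meta_cols + 1} columns")
        if sample_names is None:
            sample_names = [f"s{i + 1}" for i in range(n_samples)]
        data_lines = lines
        strand_idx, start_idx, end_idx = 5, 1, 2
        type_idx = None
    else:
        header = lines[0][1].split("\t")
        lowered = [h.lower() for h in header]
        try:
            c_i = lowered.index("chr") if "chr" in lowered else lowered.index("chrom")
            start_idx = lowered.index("start")
            end_idx = lowered.index("end")
        except ValueError as exc:
            raise ParseError(f"{path}: line 1: missing coordinate column ({exc})")
        strand_idx = lowered.index("strand") if "strand" in lowered else None
        type_idx = None
        for cand in ("type", "region", "circ_type"):
            if cand in lowered:
                type_idx = lowered.index(cand)
                break
        meta = {c_i, start_idx, end_idx}
        meta |= {i for i in (strand_idx, type_idx) if i is not None}
        sample_cols = [i for i in range(len(header)) if i not in meta]
        file_samples = [header[i] for i in sample_cols]
        if sample_names is not None:
            missing = set(sample_names) - set(file_samples)
            if missing:
                raise ParseError(f"{path}: declared sample columns absent: {sorted(missing)}")
            sample_cols = [header.index(s) for s in sample_names]
        else:
            sample_names = file_samples
        data_lines = lines[1:]

    n_samples = len(sample_names)
    acc: dict[tuple, np.ndarray] = {}
    circ_types: dict[tuple[str, int, int], str] = {}
    dup = 0
    for lineno, ln in data_lines:
        f = ln.split("\t")
        try:
            if cfg["bedlike"]:
                chrom = f[0]
                start, end = int(f[start_idx]), int(f[end_idx])
                strand = f[strand_idx] if f[strand_idx] in ("+", "-") else "."
                raw_counts = f[6 : 6 + n_samples]
            else:
                chrom = f[c_i]
                start, end = int(f[start_idx]), int(f[end_idx])
                strand = "."
                if strand_idx is not None and f[strand_idx] in ("+", "-"):
                    strand = f[strand_idx]
                raw_counts = [f[i] for i in sample_cols]
            counts = np.array([int(x) for x in raw_counts], dtype=np.int64)
        except (IndexError, ValueError) as exc:
            raise ParseError(f"{path}: line {lineno}: malformed row ({exc})") from exc
        if np.any(counts < 0):
            raise ValidationError(f"{path}: line {lineno}: negative count")
        start, end = to_internal(start, end, convention)
        try:
            iv = GenomicInterval(chrom, start, end, strand)
        except ValidationError as exc:
            raise ParseError(f"{path}: line {lineno}: {exc}") from exc
        k = (iv.chrom, iv.start, iv.end, iv.strand)
        if k in acc:
            acc[k] = acc[k] + counts
            dup += 1
        else:
            acc[k] = counts
        if type_idx is not None and len(f) > type_idx:
            ctype = f[type_idx].strip().lower()
            if ctype in ("exonic", "intronic", "intergenic"):
                circ_types[iv.key] = ctype
    if dup:
        logger.warning("%s: summed %d duplicate junction row(s)", path, dup)
    calls = [(GenomicInterval(*k), v) for k, v in acc.items()]
    return BsjCallSet(caller_id, list(sample_names), calls, circ_types)


# ---------------------------------------------------------------------------
# gene annotation (GTF / GFF3)
# ---------------------------------------------------------------------------

def read_gene_annotation(path: str | os.PathLike) -> GeneAnnotation:
    """Read a GTF or GFF3 file into a :class:`GeneAnnotation`.

    Exon features are grouped under their gene IDs (``gene_id`` attribute
    for GTF, ``Parent`` chain for GFF3); exons whose gene cannot be
    resolved are skipped with a warning.  1-based closed coordinates are
    converted to the internal 0-based half-open convention.  A gene
    referenced only by exons gets an interval spanning its exon envelope.
    """
    import gffutils

    with open(path) as fh:
        text = fh.read()
    if not text.strip():
        return GeneAnnotation([], {})

    db = gffutils.create_db(
        text,
        dbfn=":memory:",
        from_string=True,
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )

    genes: dict[str, Gene] = {}
    for g in db.features_of_type("gene"):
        gid = g.attributes.get("gene_id", [g.id])[0]
        name = (g.attributes.get("gene_name") or g.attributes.get("Name") or [gid])[0]
        strand = g.strand if g.strand in ("+", "-") else "."
        genes[gid] = Gene(gid, name, GenomicInterval(g.seqid, g.start - 1, g.end, strand))

    exons: dict[str, list[GenomicInterval]] = {}
    for e in db.features_of_type("exon"):
        gid = None
        if "gene_id" in e.attributes:
            gid = e.attributes["gene_id"][0]
        else:  # GFF3: walk Parent chain to a gene feature
            for anc in db.parents(e):
                if anc.featuretype == "gene":
                    gid = anc.attributes.get("gene_id", [anc.id])[0]
                    break
        if gid is None:
            logger.warning("exon at %s:%d-%d has no resolvable gene; skipped", e.seqid, e.start, e.end)
            continue
        strand = e.strand if e.strand in ("+", "-") else "."
        exons.setdefault(gid, []).append(GenomicInterval(e.seqid, e.start - 1, e.end, strand))

    for gid, exs in exons.items():
        if gid not in genes:  # synthesize the gene as its exon envelope
            chrom = exs[0].chrom
            strand = exs[0].strand
            genes[gid] = Gene(
                gid, gid,
                GenomicInterval(chrom, min(e.start for e in exs), max(e.end for e in exs), strand),
            )
    return GeneAnnotation(list(genes.values()), exons)


def write_gtf(ann: GeneAnnotation, path: str | os.PathLike) -> None:
    """Write a GeneAnnotation as GTF (1-based closed coordinates)."""
    with open(path, "w") as fh:
        for g in sorted(ann.genes, key=lambda g: (g.interval.chrom, g.interval.start)):
            iv = g.interval
            attrs = f'gene_id "{g.gene_id}"; gene_name "{g.name}";'
            fh.write(
                f"{iv.chrom}\tcircpipe_sim\tgene\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t{attrs}\n"
            )
            for e in ann.exons.get(g.gene_id, []):
                eattrs = (
                    f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1"; '
                    f'gene_name "{g.name}";'
                )
                fh.write(
                    f"{e.chrom}\tcircpipe_sim\texon\t{e.start + 1}\t{e.end}\t.\t{e.strand}\t.\t{eattrs}\n"
                )


def write_caller_table(
    callset: BsjCallSet,
    path: str | os.PathLike,
    dialect: str = "generic",
    convention: str | None = None,
) -> None:
    """Write a BsjCallSet in one of the caller-table dialects."""
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    cfg = _DIALECTS[dialect]
    convention = convention or cfg["default_convention"]
    rows = sorted(callset.calls, key=lambda t: (t[0].chrom, t[0].start, t[0].end))
    with open(path, "w") as fh:
        if cfg["bedlike"]:
            for i, (iv, counts) in enumerate(rows, start=1):
                start, end = from_internal(iv.start, iv.end, convention)
                cols = [iv.chrom, str(start), str(end), f"bsj{i}", "0", iv.strand]
                cols += [str(int(c)) for c in counts]
                fh.write("\t".join(cols) + "\n")
        else:
            head = ["Chr", "Start", "End", "Strand"] if dialect == "dcc" else [
                "chrom", "start", "end", "strand"
            ]
            fh.write("\t".join(head + list(callset.sample_order)) + "\n")
            for iv, counts in rows:
                start, end = from_internal(iv.start, iv.end, convention)
                cols = [iv.chrom, str(start), str(end), iv.strand]
                cols += [str(int(c)) for c in counts]
                fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# UCSC chain files
# ---------------------------------------------------------------------------

def read_chain(path: str | os.PathLike) -> ChainSet:
    """Parse a UCSC chain file.

    The first-named genome on each ``chain`` header line is the *source*
    (lifted from), the second the *target* (lifted to), matching how
    liftOver consumes old-to-new chain files.  Block arithmetic is
    validated against the declared spans.
    """
    chains: list[Chain] = []
    cur: Chain | None = None
    auto_id = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("chain"):
                f = line.split()
                if len(f) not in (12, 13):
                    raise ParseError(f"{path}: line {lineno}: bad chain header")
                auto_id += 1
                cur = Chain(
                    score=float(f[1]),
                    source_name=f[2], source_size=int(f[3]), source_strand=f[4],
                    source_start=int(f[5]), source_end=int(f[6]),
                    target_name=f[7], target_size=int(f[8]), target_strand=f[9],
                    target_start=int(f[10]), target_end=int(f[11]),
                    blocks=[],
                    chain_id=int(f[12]) if len(f) == 13 else auto_id,
                )
                chains.append(cur)
            else:
                if cur is None:
                    raise ParseError(f"{path}: line {lineno}: block outside a chain")
                f = line.split()
                if len(f) == 3:
                    cur.blocks.append(ChainBlock(int(f[0]), int(f[1]), int(f[2])))
                elif len(f) == 1:
                    cur.blocks.append(ChainBlock(int(f[0])))
                else:
                    raise ParseError(f"{path}: line {lineno}: bad block line")
    return ChainSet(chains)


def write_chain(chains: ChainSet, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for c in chains:
            fh.write(
                f"chain {c.score:g} {c.source_name} {c.source_size} {c.source_strand} "
                f"{c.source_start} {c.source_end} {c.target_name} {c.target_size} "
                f"{c.target_strand} {c.target_start} {c.target_end} {c.chain_id}\n"
            )
            for b in c.blocks[:-1]:
                fh.write(f"{b.size} {b.source_gap} {b.target_gap}\n")
            fh.write(f"{c.blocks[-1].size}\n\n")


# ---------------------------------------------------------------------------
# circRNA database, FASTA, sample sheet, BED, tables
# ---------------------------------------------------------------------------

def read_circ_db(path: str | os.PathLike, convention: str = ZERO_HALF_OPEN) -> list[CircDbRecord]:
    """Read a tab-separated circRNA database.

    Expected header: ``circ_id chrom start end strand gene`` (gene may be
    empty).
    """
    df = pd.read_csv(path, sep="\t", dtype={"circ_id": str, "chrom": str})
    out = []
    for row in df.itertuples(index=False):
        start, end = to_internal(int(row.start), int(row.end), convention)
        strand = row.strand if row.strand in ("+", "-") else "."
        gene = "" if pd.isna(getattr(row, "gene", "")) else str(getattr(row, "gene", ""))
        out.append(CircDbRecord(str(row.circ_id), GenomicInterval(row.chrom, start, end, strand), gene))
    return out


def write_circ_db(records: Iterable[CircDbRecord], path: str | os.PathLike) -> None:
    rows = [
        dict(circ_id=r.circ_id, chrom=r.interval.chrom, start=r.interval.start,
             end=r.interval.end, strand=r.interval.strand, gene=r.host_gene)
        for r in records
    ]
    pd.DataFrame(rows, columns=["circ_id", "chrom", "start", "end", "strand", "gene"]).to_csv(
        path, sep="\t", index=False
    )


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """FASTA records keyed by the first header token, sequences upper-cased."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | os.PathLike) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_sample_sheet(path: str | os.PathLike) -> list[SampleDesign]:
    """Tab-separated sample sheet with header ``sample_id group [timepoint] [batch]``."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if "sample_id" not in df.columns or "group" not in df.columns:
        raise ParseError(f"{path}: sample sheet needs 'sample_id' and 'group' columns")
    design = [
        SampleDesign(r["sample_id"], r["group"],
                     r.get("timepoint", ""), r.get("batch", ""))
        for _, r in df.iterrows()
    ]
    check_design(design)
    return design


def write_sample_sheet(design: Iterable[SampleDesign], path: str | os.PathLike) -> None:
    rows = [dict(sample_id=d.sample_id, group=d.group, timepoint=d.timepoint, batch=d.batch)
            for d in design]
    pd.DataFrame(rows, columns=["sample_id", "group", "timepoint", "batch"]).to_csv(
        path, sep="\t", index=False
    )


def write_bed(records: Iterable[tuple[str, GenomicInterval]], path: str | os.PathLike) -> None:
    """Write (name, interval) pairs as BED6 (0-based half-open)."""
    with open(path, "w") as fh:
        for name, iv in records:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def read_bed(path: str | os.PathLike) -> list[tuple[str, GenomicInterval]]:
    """Read BED (>= 3 columns) back into (name, interval) pairs."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            try:
                chrom, start, end = f[0], int(f[1]), int(f[2])
            except (IndexError, ValueError) as exc:
                raise ParseError(f"{path}: line {lineno}: malformed BED row") from exc
            name = f[3] if len(f) > 3 else f"region{lineno}"
            strand = f[5] if len(f) > 5 and f[5] in ("+", "-") else "."
            out.append((name, GenomicInterval(chrom, start, end, strand)))
    return out


def write_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
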