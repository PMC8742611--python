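"""From deconvolved parts to a deduplicated RNA-DNA contact table.

A contact is emitted only when both parts of a read map uniquely; multi-
mapping parts are excluded outright (contact specificity beats sensitivity
for downstream enrichment testing). PCR duplicates are collapsed on the 5'
coordinates of both parts — the standard proximity-ligation duplicate
definition.

The bundled aligner is an exact-match fixture aligner for synthetic
genomes; real libraries enter through :func:`ingest_alignments` (SAM/BAM or
a 6-column TSV) produced by a production aligner upstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam
from intervaltree import IntervalTree

from .core_io import (
    CONTACT_COLUMNS,
    FormatError,
    GeneRecord,
    GenomeRef,
    contacts_to_frame,
    empty_contact_frame,
)
from .deconvolve import DeconvolvedRead, revcomp

logger = logging.getLogger("redchip")

UNASSIGNED = "unassigned"

#: dedup key: 5' coordinates of both parts within one library
DEDUP_KEY = ["rna_chrom", "rna_start", "dna_chrom", "dna_start", "fraction", "replicate"]


@dataclass(frozen=True)
class PartAlignment:
    """Genomic placement of one RNA or DNA part of a read."""

    read_id: str
    part: str  # {"rna", "dna"}
    chrom: str
    start: int
    end: int
    strand: str
    unique: bool


@dataclass
class ContactTable:
    """A contact set plus library metadata.

    ``frame`` holds the canonical 11 columns (see core_io.CONTACT_COLUMNS);
    ``meta`` carries per-stage counts for conservation reporting.
    """

    frame: pd.DataFrame
    fraction: str
    replicate: int
    meta: dict = field(default_factory=dict)

    @property
    def total_contacts(self) -> int:
        return len(self.frame)

    def contacts(self):
        from .core_io import frame_to_contacts

        return frame_to_contacts(self.frame)


# ---------------------------------------------------------------------------
# Alignment


def _occurrences(seq: str, sub: str, limit: int = 2) -> list[int]:
    """Start offsets of exact occurrences of sub in seq (up to limit)."""
    hits: list[int] = []
    pos = seq.find(sub)
    while pos != -1 and len(hits) < limit:
        hits.append(pos)
        pos = seq.find(sub, pos + 1)
    return hits


def align_exact(
    parts: Mapping[str, str], genome: GenomeRef, part_kind: str
) -> list[PartAlignment]:
    """Exact-match alignment of part sequences on both genome strands.

    ``unique`` is true iff the sequence occurs exactly once genome-wide
    (both strands pooled). RNA parts are given in transcript sense, so a
    forward-strand hit means strand "+". Empty sequences yield nothing.
    """
    alns: list[PartAlignment] = []
    for read_id, seq in parts.items():
        if not seq:
            continue
        rc = revcomp(seq)
        hits: list[tuple[str, int, str]] = []
        for chrom in genome.chrom_names:
            chrom_seq = genome.sequences[chrom]
            for pos in _occurrences(chrom_seq, seq):
                hits.append((chrom, pos, "+"))
                if len(hits) > 1:
                    break
            if len(hits) > 1:
                break
            for pos in _occurrences(chrom_seq, rc):
                hits.append((chrom, pos, "-"))
                if len(hits) > 1:
                    break
            if len(hits) > 1:
                break
        if not hits:
            continue
        chrom, pos, strand = hits[0]
        alns.append(
            PartAlignment(read_id, part_kind, chrom, pos, pos + len(seq), strand,
                          unique=len(hits) == 1)
        )
    return alns


def align_parts(
    reads: Iterable[DeconvolvedRead], genome: GenomeRef
) -> tuple[list[PartAlignment], list[PartAlignment]]:
    """Align RNA and DNA parts of OK reads; returns (rna_alns, dna_alns)."""
    ok = [r for r in reads if r.status == "OK"]
    rna = align_exact({r.read_id: r.rna_seq for r in ok}, genome, "rna")
    dna = align_exact({r.read_id: r.dna_seq for r in ok}, genome, "dna")
    logger.info("align_parts: %d OK reads, %d RNA / %d DNA alignments", len(ok), len(rna), len(dna))
    return rna, dna


def ingest_alignments(
    path: str | Path, part_kind: str, known_chroms: Sequence[str] | None = None
) -> list[PartAlignment]:
    """Ingest externally produced alignments (SAM/BAM or 6-column TSV).

    SAM/BAM: unmapped records are skipped; secondary/supplementary records
    and records with mapping quality 0 are flagged unique=False. TSV columns:
    read_id, chrom, start, end, strand, unique(0/1). No CIGAR-aware
    processing — only coordinates, strand and read id are taken.
    """
    path = Path(path)
    alns: list[PartAlignment] = []
    if path.suffix.lower() in (".sam", ".bam", ".cram"):
        with pysam.AlignmentFile(str(path), check_sq=False) as fh:
            for rec in fh:
                if rec.is_unmapped:
                    continue
                chrom = rec.reference_name
                if known_chroms is not None and chrom not in known_chroms:
                    raise FormatError(f"{path}: unknown reference {chrom!r}")
                unique = not (rec.is_secondary or rec.is_supplementary or rec.mapping_quality == 0)
                alns.append(
                    PartAlignment(
                        rec.query_name, part_kind, chrom,
                        rec.reference_start, rec.reference_end,
                        "-" if rec.is_reverse else "+", unique,
                    )
                )
    else:
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip() or line.startswith("#"):
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 6:
                    raise FormatError(f"{path}:{lineno}: expected 6 columns")
                read_id, chrom, start, end, strand, uniq = fields[:6]
                if known_chroms is not None and chrom not in known_chroms:
                    raise FormatError(f"{path}:{lineno}: unknown reference {chrom!r}")
                alns.append(
                    PartAlignment(read_id, part_kind, chrom, int(start), int(end),
                                  strand, uniq in ("1", "true", "True"))
                )
    logger.info("ingest_alignments: %d records from %s", len(alns), path)
    return alns


# ---------------------------------------------------------------------------
# Gene assignment


class GeneIndex:
    """Interval index over genes for strand-aware overlap assignment."""

    def __init__(self, genes: Iterable[GeneRecord]):
        self.genes = {g.gene_id: g for g in genes}
        self._trees: dict[str, IntervalTree] = {}
        for g in self.genes.values():
            self._trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g)

    def overlapping(self, chrom: str, start: int, end: int) -> list[GeneRecord]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [iv.data for iv in tree.overlap(start, end)]


def assign_gene(aln: PartAlignment, index: GeneIndex) -> str:
    """Assign an RNA-part alignment to its source gene.

    Candidates are genes overlapping the alignment on the SAME strand (an
    antisense transcript must itself be annotated to be counted). Largest
    overlap wins; ties break to the shorter gene, then lexicographic id.
    Returns the sentinel ``"unassigned"`` when no candidate exists.
    """
    best: tuple[int, int, str] | None = None
    best_gene = UNASSIGNED
    for g in index.overlapping(aln.chrom, aln.start, aln.end):
        if g.strand != aln.strand:
            continue
        overlap = min(aln.end, g.end) - max(aln.start, g.start)
        key = (-overlap, g.length, g.gene_id)
        if best is None or key < best:
            best = key
            best_gene = g.gene_id
    return best_gene


# ---------------------------------------------------------------------------
# Contact building


def build_contacts(
    rna_alns: Iterable[PartAlignment],
    dna_alns: Iterable[PartAlignment],
    genes: Iterable[GeneRecord] | GeneIndex,
    fraction: str,
    replicate: int,
) -> ContactTable:
    """Pair unique RNA/DNA alignments by read id into a deduplicated table.

    meta records the conservation ledger: reads_in = contacts +
    rejected_not_unique + duplicates_removed.
    """
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    rna_by_id = {a.read_id: a for a in rna_alns}
    dna_by_id = {a.read_id: a for a in dna_alns}
    read_ids = set(rna_by_id) | set(dna_by_id)

    rows = []
    rejected = 0
    for read_id in sorted(read_ids):
        r, d = rna_by_id.get(read_id), dna_by_id.get(read_id)
        if r is None or d is None or not (r.unique and d.unique):
            rejected += 1
            continue
        rows.append(
            (read_id, r.chrom, r.start, r.end, r.strand, assign_gene(r, index),
             d.chrom, d.start, d.end, fraction, replicate)
        )
    frame = (
        pd.DataFrame(rows, columns=CONTACT_COLUMNS) if rows else empty_contact_frame()
    )
    before = len(frame)
    frame = frame.drop_duplicates(subset=DEDUP_KEY, keep="first").reset_index(drop=True)
    dups = before - len(frame)
    meta = {
        "reads_in": len(read_ids),
        "contacts": len(frame),
        "rejected_not_unique": rejected,
        "duplicates_removed": dups,
    }
    logger.info(
        "build_contacts(%s rep%d): %d reads -> %d contacts (%d rejected, %d duplicates)",
        fraction, replicate, len(read_ids), len(frame), rejected, dups,
    )
    return ContactTable(frame, fraction, replicate, meta)


def gene_contact_counts(table: ContactTable | pd.DataFrame) -> dict[str, int]:
    """Total contacts per assigned gene (the unassigned sentinel is dropped)."""
    frame = table.frame if isinstance(table, ContactTable) else table
    if not len(frame):
        return {}
    counts = frame.loc[frame["gene_id"] != UNASSIGNED, "gene_id"].value_counts()
    return {str(k): int(v) for k, v in counts.items()}


__all__ = [
    "PartAlignment",
    "ContactTable",
    "GeneIndex",
    "align_exact",
    "align_parts",
    "ingest_alignments",
    "assign_gene",
    "build_contacts",
    "gene_contact_counts",
    "contacts_to_frame",
    "UNASSIGNED",
]
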