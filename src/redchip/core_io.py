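"""Domain types and on-disk formats for the RNA-DNA contact pipeline.

All internal coordinates are 0-based half-open. Conversion to 1-based
conventions happens only at format boundaries (GTF in, bedGraph out).

The contact TSV dialect is fixed: tab-separated, one header line, columns
``read_id, rna_chrom, rna_start, rna_end, rna_strand, gene_id, dna_chrom,
dna_start, dna_end, fraction, replicate``. Round-tripping a table through
:func:`write_contacts` / :func:`read_contacts` is the identity.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

logger = logging.getLogger("redchip")

BIOTYPES = ("protein_coding", "lincRNA", "antisense", "snRNA", "snoRNA", "other")
FRACTIONS = ("IP", "input")

#: column order of the contact TSV; also the column order of contact frames.
CONTACT_COLUMNS = [
    "read_id",
    "rna_chrom",
    "rna_start",
    "rna_end",
    "rna_strand",
    "gene_id",
    "dna_chrom",
    "dna_start",
    "dna_end",
    "fraction",
    "replicate",
]

_CONTACT_DTYPES = {
    "read_id": str,
    "rna_chrom": str,
    "rna_start": np.int64,
    "rna_end": np.int64,
    "rna_strand": str,
    "gene_id": str,
    "dna_chrom": str,
    "dna_start": np.int64,
    "dna_end": np.int64,
    "fraction": str,
    "replicate": np.int64,
}


class FormatError(ValueError):
    """Malformed input file (message names the offending line/record)."""


@dataclass
class GenomeRef:
    """A loaded reference genome: ordered chromosomes with sequences."""

    chrom_names: list[str]
    chrom_lengths: list[int]
    sequences: dict[str, str]

    def __post_init__(self) -> None:
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise FormatError("duplicate chromosome names in genome")
        for name, length in zip(self.chrom_names, self.chrom_lengths):
            if len(self.sequences[name]) != length:
                raise FormatError(
                    f"sequence length of {name} != declared length {length}"
                )

    @property
    def lengths(self) -> dict[str, int]:
        return dict(zip(self.chrom_names, self.chrom_lengths))

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene: 0-based half-open interval plus strand and biotype."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str = "other"

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"{self.gene_id}: invalid interval [{self.start},{self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        if self.biotype not in BIOTYPES:
            raise ValueError(f"{self.gene_id}: unknown biotype {self.biotype!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class IntervalTrack:
    """A labelled set of genomic intervals (chromatin states, peaks)."""

    records: list[tuple[str, int, int, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[tuple[str, int, int, str]]:
        return iter(self.records)

    def labels(self) -> list[str]:
        return sorted({r[3] for r in self.records if r[3]})

    def by_chrom(self) -> dict[str, list[tuple[int, int, str]]]:
        out: dict[str, list[tuple[int, int, str]]] = {}
        for chrom, start, end, label in self.records:
            out.setdefault(chrom, []).append((start, end, label))
        for ivs in out.values():
            ivs.sort()
        return out


@dataclass(frozen=True)
class Contact:
    """One RNA-part/DNA-part coordinate pair with library labels.

    ``rna_strand`` is the sense orientation of the transcript; ``gene_id``
    is the assigned source gene or the sentinel ``"unassigned"``.
    """

    read_id: str
    rna_chrom: str
    rna_start: int
    rna_end: int
    rna_strand: str
    gene_id: str
    dna_chrom: str
    dna_start: int
    dna_end: int
    fraction: str
    replicate: int

    def __post_init__(self) -> None:
        if not (self.rna_start < self.rna_end and self.dna_start < self.dna_end):
            raise ValueError(f"{self.read_id}: degenerate part interval")
        if self.fraction not in FRACTIONS:
            raise ValueError(f"{self.read_id}: fraction must be one of {FRACTIONS}")
        if self.replicate < 1:
            raise ValueError(f"{self.read_id}: replicate must be >= 1")


def contacts_to_frame(contacts: Iterable[Contact]) -> pd.DataFrame:
    """Convert Contact records to the canonical 11-column frame."""
    rows = [[getattr(c, col) for col in CONTACT_COLUMNS] for c in contacts]
    frame = pd.DataFrame(rows, columns=CONTACT_COLUMNS)
    return frame.astype(_CONTACT_DTYPES) if len(frame) else empty_contact_frame()


def frame_to_contacts(frame: pd.DataFrame) -> list[Contact]:
    return [Contact(**rec) for rec in frame[CONTACT_COLUMNS].to_dict("records")]


def empty_contact_frame() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=t) for c, t in _CONTACT_DTYPES.items()})


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def read_fasta(path: str | Path) -> GenomeRef:
    """Load a FASTA file into a :class:`GenomeRef` (sequences uppercased)."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if not first:
            raise FormatError(f"{path}: empty file (line 1)")
        if not first.startswith(">"):
            raise FormatError(f"{path}: line 1 is not a FASTA header")
    names: list[str] = []
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise FormatError(f"{path}: duplicate record name {rec.id!r}")
        names.append(rec.id)
        seqs[rec.id] = str(rec.seq).upper()
    genome = GenomeRef(names, [len(seqs[n]) for n in names], seqs)
    logger.info("read_fasta: %d chromosomes, %d bp", len(names), sum(genome.chrom_lengths))
    return genome


def write_fasta(genome: GenomeRef, path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in genome.chrom_names:
            fh.write(f">{name}\n")
            seq = genome.sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


_MATE_SUFFIX = re.compile(r"/[12]$")


def _core_id(read_id: str) -> str:
    """Strip /1, /2 mate suffixes and anything after the first whitespace."""
    return _MATE_SUFFIX.sub("", read_id.split()[0])


def read_fastq_pairs(
    path_r1: str | Path, path_r2: str | Path
) -> Iterator[tuple[str, str, str, str, str]]:
    """Yield ``(id, seq1, qual1, seq2, qual2)`` from a matched FASTQ pair.

    Ids must match record-by-record up to /1 and /2 suffixes; a mismatch or
    unequal record counts raise :class:`FormatError` naming the record.
    """
    with open(path_r1) as fh1, open(path_r2) as fh2:
        it1 = FastqGeneralIterator(fh1)
        it2 = FastqGeneralIterator(fh2)
        k = 0
        while True:
            rec1 = next(it1, None)
            rec2 = next(it2, None)
            if rec1 is None and rec2 is None:
                return
            k += 1
            if rec1 is None or rec2 is None:
                raise FormatError(f"unequal pair counts: one file ends before record {k}")
            id1, id2 = _core_id(rec1[0]), _core_id(rec2[0])
            if id1 != id2:
                raise FormatError(f"read id mismatch at record {k}: {id1!r} vs {id2!r}")
            yield id1, rec1[1].upper(), rec1[2], rec2[1].upper(), rec2[2]


def write_fastq_pairs(
    records: Iterable[tuple[str, str, str, str, str]],
    path_r1: str | Path,
    path_r2: str | Path,
) -> int:
    n = 0
    with open(path_r1, "w") as f1, open(path_r2, "w") as f2:
        for read_id, seq1, qual1, seq2, qual2 in records:
            f1.write(f"@{read_id}/1\n{seq1}\n+\n{qual1}\n")
            f2.write(f"@{read_id}/2\n{seq2}\n+\n{qual2}\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# BED / GTF


def read_bed(path: str | Path) -> IntervalTrack:
    """Parse a BED3/BED4 file (0-based half-open; column 4 is the label)."""
    records: list[tuple[str, int, int, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            label = fields[3] if len(fields) > 3 else ""
            records.append((chrom, start, end, label))
    logger.info("read_bed: %d intervals from %s", len(records), path)
    return IntervalTrack(records)


def write_bed(track: IntervalTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, label in track:
            cols = [chrom, str(start), str(end)] + ([label] if label else [])
            fh.write("\t".join(cols) + "\n")


_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def read_gtf_genes(path: str | Path) -> list[GeneRecord]:
    """Parse ``gene`` features from a GTF file into :class:`GeneRecord` list.

    GTF is 1-based closed; records are converted to 0-based half-open on the
    way in. Biotypes outside the closed vocabulary map to ``"other"``.
    """
    genes: list[GeneRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GTF columns")
            if fields[2] != "gene":
                continue
            attrs = dict(_GTF_ATTR.findall(fields[8]))
            gene_id = attrs.get("gene_id")
            if not gene_id:
                raise FormatError(f"{path}:{lineno}: missing gene_id attribute")
            if gene_id in seen:
                raise FormatError(f"{path}:{lineno}: duplicate gene_id {gene_id!r}")
            seen.add(gene_id)
            biotype = attrs.get("gene_biotype", attrs.get("gene_type", "other"))
            if biotype not in BIOTYPES:
                biotype = "other"
            genes.append(
                GeneRecord(
                    gene_id=gene_id,
                    chrom=fields[0],
                    start=int(fields[3]) - 1,  # 1-based closed -> 0-based half-open
                    end=int(fields[4]),
                    strand=fields[6],
                    biotype=biotype,
                )
            )
    logger.info("read_gtf_genes: %d genes from %s", len(genes), path)
    return genes


def write_gtf_genes(genes: Iterable[GeneRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; gene_biotype "{g.biotype}";'
            fh.write(
                "\t".join(
                    [g.chrom, "redchip", "gene", str(g.start + 1), str(g.end),
                     ".", g.strand, ".", attrs]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Contact TSV


def write_contacts(contacts, path: str | Path) -> None:
    """Write a contact table (frame, ContactTable, or Contact iterable) as TSV."""
    frame = _as_contact_frame(contacts)
    frame[CONTACT_COLUMNS].to_csv(path, sep="\t", index=False)
    logger.info("write_contacts: %d contacts -> %s", len(frame), path)


def read_contacts(path: str | Path) -> pd.DataFrame:
    """Read a contact TSV back into the canonical frame (round-trip identity)."""
    frame = pd.read_csv(path, sep="\t", dtype={c: str for c in CONTACT_COLUMNS})
    missing = [c for c in CONTACT_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing contact columns {missing}")
    if len(frame):
        bad = set(frame["fraction"]) - set(FRACTIONS)
        if bad:
            raise FormatError(f"{path}: unknown fraction value(s) {sorted(bad)}")
    else:
        return empty_contact_frame()
    return frame[CONTACT_COLUMNS].astype(_CONTACT_DTYPES)


def _as_contact_frame(contacts) -> pd.DataFrame:
    if isinstance(contacts, pd.DataFrame):
        return contacts
    if hasattr(contacts, "frame"):  # ContactTable
        return contacts.frame
    return contacts_to_frame(contacts)


# ---------------------------------------------------------------------------
# bedGraph coverage export


def export_coverage_bedgraph(
    contacts,
    genome: GenomeRef,
    which: str,
    path: str | Path,
    bin_size: int = 1000,
) -> None:
    """Write binned coverage of the RNA or DNA parts as a sparse bedGraph.

    Each part contributes 1 to the bin containing its midpoint; zero bins
    are omitted (bedGraph sparse convention); the last bin of a chromosome
    is truncated at the chromosome end.
    """
    if which not in ("rna", "dna"):
        raise ValueError("which must be 'rna' or 'dna'")
    frame = _as_contact_frame(contacts)
    chrom_col, s_col, e_col = f"{which}_chrom", f"{which}_start", f"{which}_end"
    with open(path, "w") as fh:
        for chrom in genome.chrom_names:
            length = genome.lengths[chrom]
            sub = frame[frame[chrom_col] == chrom]
            if not len(sub):
                continue
            mid = ((sub[s_col].to_numpy() + sub[e_col].to_numpy()) // 2).astype(np.int64)
            n_bins = -(-length // bin_size)
            counts = np.bincount(np.minimum(mid // bin_size, n_bins - 1), minlength=n_bins)
            for b in np.nonzero(counts)[0]:
                start = int(b) * bin_size
                end = min(start + bin_size, length)
                fh.write(f"{chrom}\t{start}\t{end}\t{int(counts[b])}\n")


# ---------------------------------------------------------------------------
# YAML configuration


def load_config(path: str | Path) -> dict:
    """Load a YAML config file into a plain dict (round-trips with save_config)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a YAML mapping")
    return cfg


def save_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
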