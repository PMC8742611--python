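"""Split chimeric read pairs into DNA tags and RNA parts at the bridge adapter.

The library chemistry puts each sequenced chimera into a fixed read-1
layout::

    [DNA tag][bridge adapter][RNA part, cDNA orientation]

The DNA tag is the short (~18-22 bp) fragment released by MmeI cutting at a
distance from its site in the bridge; the RNA part is the reverse
transcript primed from the bridge, so the transcript-sense RNA sequence is
the reverse complement of the read segment after the bridge. Template
switching at the RNA 5' end can append a few non-templated bases that show
up as extra G's at the transcript 5' end; these are optionally trimmed.

Bridge matching is substitution-only (Hamming distance, no indels): the
bridge is short, and an indel-tolerant search buys little yield for its
complexity. Pairs with zero or multiple bridge hits are classified rather
than rescued — an ambiguous chimera would create spurious contacts.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

from .core_io import read_fastq_pairs

logger = logging.getLogger("redchip")

STATUSES = ("OK", "NO_BRIDGE", "MULTI_BRIDGE", "DNA_SHORT", "DNA_LONG", "RNA_SHORT")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class BridgeConfig:
    """Chemistry model of the bridge-adapter junction.

    Parameters
    ----------
    bridge_seq_forward
        Bridge adapter sequence as it appears in read 1 (DNA-tag side first).
    max_mismatches
        Hamming-distance budget for bridge matching; N counts as mismatch.
    dna_tag_min, dna_tag_max
        Accepted DNA-tag length window (bp); defaults bracket the MmeI-type
        cut length.
    rna_min_len
        Minimum RNA-part length (bp) for a pair to be usable.
    gggg_trim
        Trim up to 4 G's at the transcript 5' end (template-switch artifact).
    use_read2
        Extend the RNA part with the mate when its bridge-free prefix
        overlaps read 1's RNA segment; off by default (single-side
        deconvolution).
    """

    bridge_seq_forward: str
    max_mismatches: int = 1
    dna_tag_min: int = 18
    dna_tag_max: int = 22
    rna_min_len: int = 14
    gggg_trim: bool = True
    use_read2: bool = False
    mate_min_overlap: int = 10

    def __post_init__(self) -> None:
        self.bridge_seq_forward = self.bridge_seq_forward.upper()
        if not self.bridge_seq_forward or set(self.bridge_seq_forward) - set("ACGT"):
            raise ValueError("bridge_seq_forward must be nonempty over {A,C,G,T}")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")
        if not 0 <= self.dna_tag_min <= self.dna_tag_max:
            raise ValueError("need 0 <= dna_tag_min <= dna_tag_max")
        if self.rna_min_len < 0:
            raise ValueError("rna_min_len must be >= 0")

    def to_dict(self) -> dict:
        return {
            "bridge_seq_forward": self.bridge_seq_forward,
            "max_mismatches": self.max_mismatches,
            "dna_tag_min": self.dna_tag_min,
            "dna_tag_max": self.dna_tag_max,
            "rna_min_len": self.rna_min_len,
            "gggg_trim": self.gggg_trim,
            "use_read2": self.use_read2,
            "mate_min_overlap": self.mate_min_overlap,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BridgeConfig":
        return cls(**d)


@dataclass(frozen=True)
class DeconvolvedRead:
    """One read pair split into DNA tag and transcript-sense RNA part."""

    read_id: str
    dna_seq: str
    rna_seq: str
    status: str


def find_bridge(seq: str, bridge: str, max_mismatches: int) -> list[int]:
    """All 0-based offsets where the bridge matches within the mismatch budget.

    Substitution-only: offset p matches iff the Hamming distance between
    ``seq[p:p+len(bridge)]`` and ``bridge`` is <= ``max_mismatches``. An N in
    the read counts as a mismatch. A bridge longer than the read yields no
    matches.
    """
    n, m = len(seq), len(bridge)
    hits: list[int] = []
    for p in range(n - m + 1):
        window = seq[p : p + m]
        if max_mismatches == 0:
            if window == bridge:
                hits.append(p)
            continue
        mm = 0
        for a, b in zip(window, bridge):
            if a != b:
                mm += 1
                if mm > max_mismatches:
                    break
        if mm <= max_mismatches:
            hits.append(p)
    return hits


def _trim_template_switch(rna_sense: str, max_g: int = 4) -> str:
    """Drop up to ``max_g`` leading G's (template-switch artifact)."""
    k = 0
    while k < min(max_g, len(rna_sense)) and rna_sense[k] == "G":
        k += 1
    return rna_sense[k:]


def split_read_pair(
    read_id: str, seq1: str, seq2: str, cfg: BridgeConfig
) -> DeconvolvedRead:
    """Deconvolve one pair; failure modes are encoded in ``status``.

    Statuses are assigned by the first failing rule in fixed order:
    NO_BRIDGE -> MULTI_BRIDGE -> DNA_SHORT/DNA_LONG -> RNA_SHORT -> OK.
    """
    seq1 = seq1.upper()
    hits = find_bridge(seq1, cfg.bridge_seq_forward, cfg.max_mismatches)
    if not hits:
        return DeconvolvedRead(read_id, "", "", "NO_BRIDGE")
    if len(hits) > 1:
        return DeconvolvedRead(read_id, "", "", "MULTI_BRIDGE")
    p = hits[0]
    dna_seq = seq1[:p]
    rna_read = seq1[p + len(cfg.bridge_seq_forward) :]
    if cfg.use_read2 and seq2:
        rna_read = _extend_with_mate(rna_read, seq2.upper(), cfg.mate_min_overlap)
    rna_seq = revcomp(rna_read)
    if cfg.gggg_trim:
        rna_seq = _trim_template_switch(rna_seq)
    if len(dna_seq) < cfg.dna_tag_min:
        status = "DNA_SHORT"
    elif len(dna_seq) > cfg.dna_tag_max:
        status = "DNA_LONG"
    elif len(rna_seq) < cfg.rna_min_len:
        status = "RNA_SHORT"
    else:
        status = "OK"
    return DeconvolvedRead(read_id, dna_seq, rna_seq, status)


def _extend_with_mate(rna_read: str, seq2: str, min_overlap: int) -> str:
    """Merge read 2 into the RNA segment via the longest suffix/prefix overlap.

    Read 2 reads the chimera from the opposite end, so its reverse
    complement continues read 1. Without an overlap of at least
    ``min_overlap`` exact bases the mate is ignored.
    """
    mate = revcomp(seq2)
    best = 0
    max_k = min(len(rna_read), len(mate))
    for k in range(max_k, min_overlap - 1, -1):
        if rna_read[-k:] == mate[:k]:
            best = k
            break
    if best:
        return rna_read + mate[best:]
    return rna_read


def deconvolve_pairs(
    pairs: Iterable[tuple[str, str, str, str, str]], cfg: BridgeConfig
) -> tuple[list[DeconvolvedRead], Counter]:
    """Deconvolve an in-memory stream of (id, seq1, qual1, seq2, qual2)."""
    reads: list[DeconvolvedRead] = []
    counts: Counter = Counter({s: 0 for s in STATUSES})
    for read_id, seq1, _q1, seq2, _q2 in pairs:
        rec = split_read_pair(read_id, seq1, seq2, cfg)
        reads.append(rec)
        counts[rec.status] += 1
    return reads, counts


def deconvolve_library(
    fastq_r1: str | Path, fastq_r2: str | Path, cfg: BridgeConfig
) -> tuple[list[DeconvolvedRead], Counter]:
    """Deconvolve a paired FASTQ library; statuses partition the input."""
    reads, counts = deconvolve_pairs(read_fastq_pairs(fastq_r1, fastq_r2), cfg)
    logger.info(
        "deconvolve_library: %d pairs in, %d OK (%s)",
        len(reads),
        counts["OK"],
        ", ".join(f"{s}={counts[s]}" for s in STATUSES if s != "OK"),
    )
    return reads, counts


# ---------------------------------------------------------------------------
# TSV surface (parts + per-stage stats)


def write_parts(reads: Iterable[DeconvolvedRead], path: str | Path) -> None:
    frame = pd.DataFrame(
        [(r.read_id, r.status, r.dna_seq, r.rna_seq) for r in reads],
        columns=["read_id", "status", "dna_seq", "rna_seq"],
    )
    frame.to_csv(path, sep="\t", index=False)


def read_parts(path: str | Path) -> list[DeconvolvedRead]:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return [
        DeconvolvedRead(row.read_id, row.dna_seq, row.rna_seq, row.status)
        for row in frame.itertuples()
    ]


def write_status_stats(counts: Counter, path: str | Path) -> None:
    total = sum(counts.values())
    with open(path, "w") as fh:
        fh.write("status\tcount\tfraction\n")
        for status in STATUSES:
            frac = counts[status] / total if total else 0.0
            fh.write(f"{status}\t{counts[status]}\t{frac:.6f}\n")
        fh.write(f"TOTAL\t{total}\t1.000000\n")
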