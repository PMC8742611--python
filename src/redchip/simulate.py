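"""Fully synthetic RNA-DNA proximity-ligation + ChIP experiments.

The simulator emulates the statistical structure the enrichment analysis
targets, with complete ground truth at every stage:

* a random multi-chromosome genome with near-unique k-mer content, so an
  exact-match aligner recovers part positions;
* non-overlapping strand-annotated genes of several biotypes with
  log-normal expression weights;
* a chromatin-state segmentation in which one designated state (default
  "Polycomb") covers the neighborhoods of the enriched genes, plus ChIP
  peaks placed inside that state;
* contact sets per fraction and replicate: the input fraction samples
  (gene, DNA position) pairs from a base distribution (cis placement by a
  symmetric-exponential distance decay around the gene, trans placement
  uniform on a nonparental chromosome); the IP fraction reweights the same
  distribution by the enrichment factor ``e`` whenever the source gene is
  enriched AND the DNA position falls in the designated state, then
  renormalizes (importance reweighting rather than mechanistic ChIP
  modeling — it creates exactly the proportion-ratio signal the fold-change
  estimator measures, which makes parameter recovery well-posed);
* paired FASTQ reads with the bridge adapter embedded in the read-1 layout
  [DNA tag][bridge][reverse-complemented RNA fragment], with optional
  bridge-deletion noise, substitution noise and template-switch G's.

Everything is deterministic under a fixed seed (byte-identical outputs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .contacts import ContactTable
from .core_io import (
    CONTACT_COLUMNS,
    GeneRecord,
    GenomeRef,
    IntervalTrack,
    write_bed,
    write_fasta,
    write_fastq_pairs,
    write_gtf_genes,
)
from .deconvolve import BridgeConfig, revcomp

logger = logging.getLogger("redchip")

#: bridge adapter used in synthetic libraries (a fixture oligo; the parser
#: is agnostic to the actual oligo identity)
FIXTURE_BRIDGE = "GCTGAGGAATTCTGGATCCT"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    """Parameters of one synthetic experiment.

    Defaults describe the reference study design used throughout the test
    suite: 2 chromosomes x 2 Mb, 200 genes, 5% of genes enriched with
    factor e = 2 at Polycomb-state positions, 50,000 contacts per fraction,
    2 replicates.
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 2_000_000
    n_genes: int = 200
    biotype_weights: dict = field(
        default_factory=lambda: {
            "protein_coding": 0.55,
            "lincRNA": 0.20,
            "antisense": 0.10,
            "snRNA": 0.08,
            "snoRNA": 0.07,
        }
    )
    gene_len_min: int = 2_000
    gene_len_max: int = 10_000
    state_labels: tuple = ("Polycomb", "Promoter", "Enhancer", "Insulator", "Quiescent")
    enriched_state: str = "Polycomb"
    state_segment_bp: int = 25_000
    enriched_flank_bp: int = 500_000
    n_peaks: int = 50
    peak_width: int = 400
    n_contacts_per_fraction: int = 50_000
    n_replicates: int = 2
    enriched_gene_fraction: float = 0.05
    enrichment_factor: float = 2.0
    p_cis: float = 0.75
    cis_decay_scale: float = 100_000.0
    rna_len_min: int = 20
    rna_len_max: int = 60
    dna_tag_min: int = 18
    dna_tag_max: int = 22
    noise: float = 0.0  # probability a pair loses its bridge
    sub_rate: float = 0.0  # per-base substitution probability
    simulate_template_switch_g: bool = False

    def __post_init__(self) -> None:
        if self.enrichment_factor <= 0:
            raise ValueError("enrichment_factor must be > 0")
        if not (0 <= self.p_cis <= 1 and 0 <= self.noise <= 1 and 0 <= self.sub_rate <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if not 0 <= self.enriched_gene_fraction <= 1:
            raise ValueError("enriched_gene_fraction must lie in [0, 1]")
        if min(self.n_chroms, self.chrom_length, self.n_genes) <= 0:
            raise ValueError("counts must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["state_labels"] = list(self.state_labels)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "state_labels" in d:
            d["state_labels"] = tuple(d["state_labels"])
        return cls(**d)


def default_bridge_config(cfg: SimConfig) -> BridgeConfig:
    """Bridge config matched to the simulated chemistry.

    Template-switch trimming is enabled only when the library actually
    carries the artifact, so that clean libraries round-trip bit-exactly.
    """
    return BridgeConfig(
        bridge_seq_forward=FIXTURE_BRIDGE,
        dna_tag_min=cfg.dna_tag_min,
        dna_tag_max=cfg.dna_tag_max,
        gggg_trim=cfg.simulate_template_switch_g,
    )


@dataclass
class SimReference:
    """Synthetic genome, annotation and regulatory tracks plus gene truth."""

    genome: GenomeRef
    genes: list[GeneRecord]
    states: IntervalTrack
    peaks: IntervalTrack
    gene_truth: pd.DataFrame  # gene_id, ..., expression_weight, enriched, e
    designated: dict  # chrom -> (starts, ends) arrays of the enriched state


@dataclass
class TruthTable:
    """Ground truth of a simulated read library."""

    frame: pd.DataFrame  # read_id, gene_id, part intervals, fraction, replicate,
    #                      dna_seq, rna_seq (expected recovery), corrupted


# ---------------------------------------------------------------------------
# Reference


def _random_chromosome(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def _duplicate_kmer_fraction(seq_arrays: list[np.ndarray], k: int = 20) -> float:
    """Fraction of k-mer positions whose k-mer occurs more than once."""
    codes = []
    for arr in seq_arrays:
        if len(arr) < k:
            continue
        val = np.zeros(len(arr) - k + 1, dtype=np.uint64)
        for j in range(k):
            val = (val << np.uint64(2)) | arr[j : len(arr) - k + 1 + j].astype(np.uint64)
        codes.append(val)
    if not codes:
        return 0.0
    allc = np.concatenate(codes)
    _, counts = np.unique(allc, return_counts=True)
    return float((counts[counts > 1]).sum() / len(allc))


def simulate_reference(cfg: SimConfig) -> SimReference:
    """Generate genome, genes, chromatin states and peaks for one experiment."""
    rng = np.random.default_rng([101, cfg.seed])
    chrom_names = [f"chr{i+1}" for i in range(cfg.n_chroms)]

    # genome: redraw a chromosome if duplicated 20-mers ever exceed 1%
    # (vanishingly rare for random sequence at these sizes)
    seqs: dict[str, str] = {}
    for name in chrom_names:
        for _attempt in range(5):
            ints = rng.integers(0, 4, size=cfg.chrom_length)
            if _duplicate_kmer_fraction([ints]) < 0.01:
                break
        seqs[name] = _BASES[ints].tobytes().decode()
    genome = GenomeRef(chrom_names, [cfg.chrom_length] * cfg.n_chroms, seqs)

    # genes: slot-based packing -> non-overlapping by construction
    per_chrom = [cfg.n_genes // cfg.n_chroms] * cfg.n_chroms
    for i in range(cfg.n_genes % cfg.n_chroms):
        per_chrom[i] += 1
    biotypes = list(cfg.biotype_weights)
    bt_p = np.array([cfg.biotype_weights[b] for b in biotypes], dtype=float)
    bt_p = bt_p / bt_p.sum()
    genes: list[GeneRecord] = []
    gid = 0
    for chrom, n_here in zip(chrom_names, per_chrom):
        if n_here == 0:
            continue
        slot = cfg.chrom_length // n_here
        if slot < cfg.gene_len_max + 2:
            raise ValueError(
                f"infeasible packing: {n_here} genes of up to {cfg.gene_len_max} bp "
                f"do not fit on a {cfg.chrom_length} bp chromosome"
            )
        for j in range(n_here):
            length = int(rng.integers(cfg.gene_len_min, cfg.gene_len_max + 1))
            start = j * slot + int(rng.integers(0, slot - length))
            genes.append(
                GeneRecord(
                    gene_id=f"gene{gid:04d}",
                    chrom=chrom,
                    start=start,
                    end=start + length,
                    strand="+" if rng.random() < 0.5 else "-",
                    biotype=str(rng.choice(biotypes, p=bt_p)),
                )
            )
            gid += 1

    # enriched genes and the designated-state layout around them
    n_enriched = int(round(cfg.n_genes * cfg.enriched_gene_fraction))
    enriched_idx = set(rng.choice(cfg.n_genes, size=n_enriched, replace=False).tolist())
    enriched_ids = {genes[i].gene_id for i in enriched_idx}

    designated_raw: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}
    for i in sorted(enriched_idx):
        g = genes[i]
        designated_raw[g.chrom].append(
            (max(0, g.start - cfg.enriched_flank_bp),
             min(cfg.chrom_length, g.end + cfg.enriched_flank_bp))
        )
    designated: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    merged: dict[str, list[tuple[int, int]]] = {}
    for chrom, ivs in designated_raw.items():
        merged[chrom] = _merge_intervals(ivs)
        starts = np.array([s for s, _ in merged[chrom]], dtype=np.int64)
        ends = np.array([e for _, e in merged[chrom]], dtype=np.int64)
        designated[chrom] = (starts, ends)

    # segmentation: designated state over the merged windows, other labels
    # tiling the gaps in fixed-size segments
    other_labels = [s for s in cfg.state_labels if s != cfg.enriched_state]
    records: list[tuple[str, int, int, str]] = []
    for chrom in chrom_names:
        cursor = 0
        blocks = merged[chrom] + [(cfg.chrom_length, cfg.chrom_length)]
        for ds, de in blocks:
            pos = cursor
            while pos < ds:
                seg_end = min(pos + cfg.state_segment_bp, ds)
                label = other_labels[int(rng.integers(0, len(other_labels)))]
                records.append((chrom, pos, seg_end, label))
                pos = seg_end
            if de > ds:
                records.append((chrom, ds, de, cfg.enriched_state))
            cursor = max(cursor, de)
    states = IntervalTrack(records)

    # peaks inside the designated state (length-weighted placement); if no
    # gene is enriched, peaks fall uniformly on the genome
    peak_records: list[tuple[str, int, int, str]] = []
    pool = [(chrom, s, e) for chrom, ivs in merged.items() for s, e in ivs]
    if not pool:
        pool = [(c, 0, cfg.chrom_length) for c in chrom_names]
    lens = np.array([e - s for _, s, e in pool], dtype=float)
    for k in range(cfg.n_peaks):
        i = int(rng.choice(len(pool), p=lens / lens.sum()))
        chrom, s, e = pool[i]
        width = min(cfg.peak_width, e - s)
        start = int(rng.integers(s, max(s + 1, e - width)))
        peak_records.append((chrom, start, start + width, f"peak{k:03d}"))
    peaks = IntervalTrack(peak_records)

    gene_truth = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "chrom": [g.chrom for g in genes],
            "start": [g.start for g in genes],
            "end": [g.end for g in genes],
            "strand": [g.strand for g in genes],
            "biotype": [g.biotype for g in genes],
            "enriched": [g.gene_id in enriched_ids for g in genes],
            "e": [cfg.enrichment_factor if g.gene_id in enriched_ids else 1.0 for g in genes],
        }
    )
    logger.info(
        "simulate_reference: %d chroms x %d bp, %d genes (%d enriched), %d states, %d peaks",
        cfg.n_chroms, cfg.chrom_length, len(genes), n_enriched, len(states), len(peaks),
    )
    return SimReference(genome, genes, states, peaks, gene_truth, designated)


def _merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


# ---------------------------------------------------------------------------
# Contacts


def _in_designated(ref: SimReference, chroms: np.ndarray, positions: np.ndarray) -> np.ndarray:
    out = np.zeros(len(positions), dtype=bool)
    for chrom, (starts, ends) in ref.designated.items():
        if len(starts) == 0:
            continue
        mask = chroms == chrom
        if not mask.any():
            continue
        pos = positions[mask]
        idx = np.searchsorted(starts, pos, side="right") - 1
        out[mask] = (idx >= 0) & (pos < ends[np.maximum(idx, 0)])
    return out


def _draw_base_contacts(
    cfg: SimConfig, ref: SimReference, rng: np.random.Generator,
    expr_p: np.ndarray, n: int,
) -> pd.DataFrame:
    """Draw n contacts from the base (input-fraction) distribution."""
    genes = ref.genes
    g_start = np.array([g.start for g in genes])
    g_len = np.array([g.length for g in genes])
    g_mid = g_start + g_len // 2
    g_chrom_idx = np.array([ref.genome.chrom_names.index(g.chrom) for g in genes])

    gi = rng.choice(len(genes), size=n, p=expr_p)
    rna_len = np.minimum(
        rng.integers(cfg.rna_len_min, cfg.rna_len_max + 1, size=n), g_len[gi]
    )
    rna_start = g_start[gi] + (rng.random(n) * (g_len[gi] - rna_len + 1)).astype(np.int64)
    dna_len = rng.integers(cfg.dna_tag_min, cfg.dna_tag_max + 1, size=n)

    is_cis = rng.random(n) < cfg.p_cis
    dist = rng.laplace(0.0, cfg.cis_decay_scale, size=n).astype(np.int64)
    cis_start = np.clip(g_mid[gi] + dist, 0, cfg.chrom_length - dna_len)

    shift = rng.integers(0, max(cfg.n_chroms - 1, 1), size=n)
    trans_chrom_idx = shift + (shift >= g_chrom_idx[gi])
    if cfg.n_chroms == 1:
        is_cis = np.ones(n, dtype=bool)  # no nonparental chromosome exists
    trans_start = (rng.random(n) * (cfg.chrom_length - dna_len + 1)).astype(np.int64)

    dna_chrom_idx = np.where(is_cis, g_chrom_idx[gi], trans_chrom_idx)
    dna_start = np.where(is_cis, cis_start, trans_start)
    chrom_arr = np.array(ref.genome.chrom_names, dtype=object)
    return pd.DataFrame(
        {
            "gene_idx": gi,
            "rna_start": rna_start,
            "rna_end": rna_start + rna_len,
            "dna_chrom": chrom_arr[dna_chrom_idx],
            "dna_start": dna_start,
            "dna_end": dna_start + dna_len,
        }
    )


def simulate_contacts(
    cfg: SimConfig, ref: SimReference
) -> dict[tuple[str, int], ContactTable]:
    """Contact tables per (fraction, replicate), with IP importance-reweighting.

    The IP fraction is drawn by rejection from the base distribution with
    acceptance proportional to e for (enriched gene, designated-state DNA
    position) pairs and 1 otherwise, which renormalizes the distribution
    exactly as the fold-change model assumes. Replicates are independent.
    """
    rng = np.random.default_rng([202, cfg.seed])
    expr_w = rng.lognormal(0.0, 1.0, size=len(ref.genes))
    expr_p = expr_w / expr_w.sum()
    ref.gene_truth["expression_weight"] = expr_w

    enriched = ref.gene_truth["enriched"].to_numpy()
    e = cfg.enrichment_factor
    e_max = max(e, 1.0)
    gene_ids = np.array([g.gene_id for g in ref.genes], dtype=object)
    gene_chroms = np.array([g.chrom for g in ref.genes], dtype=object)
    gene_strands = np.array([g.strand for g in ref.genes], dtype=object)

    tables: dict[tuple[str, int], ContactTable] = {}
    n = cfg.n_contacts_per_fraction
    for fraction in ("input", "IP"):
        for rep in range(1, cfg.n_replicates + 1):
            if fraction == "input":
                draw = _draw_base_contacts(cfg, ref, rng, expr_p, n)
            else:
                kept: list[pd.DataFrame] = []
                got = 0
                while got < n:
                    batch = _draw_base_contacts(cfg, ref, rng, expr_p, int(n * 1.3) + 100)
                    mid = ((batch["dna_start"].to_numpy() + batch["dna_end"].to_numpy()) // 2)
                    boost = enriched[batch["gene_idx"].to_numpy()] & _in_designated(
                        ref, batch["dna_chrom"].to_numpy(dtype=object), mid
                    )
                    w = np.where(boost, e, 1.0) / e_max
                    accept = rng.random(len(batch)) < w
                    sel = batch[accept]
                    kept.append(sel)
                    got += len(sel)
                draw = pd.concat(kept, ignore_index=True).iloc[:n].reset_index(drop=True)
            gi = draw["gene_idx"].to_numpy()
            prefix = f"{fraction}_r{rep}"
            frame = pd.DataFrame(
                {
                    "read_id": [f"{prefix}_{i:07d}" for i in range(len(draw))],
                    "rna_chrom": gene_chroms[gi],
                    "rna_start": draw["rna_start"].to_numpy(),
                    "rna_end": draw["rna_end"].to_numpy(),
                    "rna_strand": gene_strands[gi],
                    "gene_id": gene_ids[gi],
                    "dna_chrom": draw["dna_chrom"].to_numpy(),
                    "dna_start": draw["dna_start"].to_numpy(),
                    "dna_end": draw["dna_end"].to_numpy(),
                    "fraction": fraction,
                    "replicate": rep,
                }
            )[CONTACT_COLUMNS]
            tables[(fraction, rep)] = ContactTable(frame, fraction, rep, {"simulated": True})
    logger.info(
        "simulate_contacts: %d tables x %d contacts", len(tables), n
    )
    return tables


# ---------------------------------------------------------------------------
# Reads


def contacts_to_reads(
    table: ContactTable,
    ref: SimReference,
    bridge_cfg: BridgeConfig,
    cfg: SimConfig,
) -> tuple[list[tuple[str, str, str, str, str]], TruthTable]:
    """Render a contact table into paired reads with the bridge embedded.

    Read 1 = [genomic DNA tag][bridge][revcomp(transcript-sense RNA
    fragment)] (+ template-switch C's at the 3' end when simulated); read 2
    is the reverse complement of read 1 (minimal mate model). With
    probability ``cfg.noise`` the bridge is deleted from a pair; ``cfg.
    sub_rate`` applies uniform substitutions. The truth table records, per
    read, the DNA/RNA fragments a perfect parser recovers.
    """
    rng = np.random.default_rng(
        [303, cfg.seed, 0 if table.fraction == "IP" else 1, table.replicate]
    )
    bridge = bridge_cfg.bridge_seq_forward
    records: list[tuple[str, str, str, str, str]] = []
    truth_rows = []
    for row in table.frame.itertuples(index=False):
        dna_seq = ref.genome.sequences[row.dna_chrom][row.dna_start : row.dna_end]
        rna_genomic = ref.genome.sequences[row.rna_chrom][row.rna_start : row.rna_end]
        rna_sense = rna_genomic if row.rna_strand == "+" else revcomp(rna_genomic)
        expected_rna = rna_sense
        tail = ""
        if cfg.simulate_template_switch_g:
            k = int(rng.integers(0, 4))
            tail = "C" * k  # read-1 3' end = transcript 5' end, complemented
            if bridge_cfg.gggg_trim:
                # trimming removes the artifact together with any genuine
                # leading G run (up to 4 total): recoverable truth
                g_run = 0
                padded = "G" * k + rna_sense
                while g_run < min(4, len(padded)) and padded[g_run] == "G":
                    g_run += 1
                expected_rna = padded[g_run:]
        corrupted = bool(rng.random() < cfg.noise)
        mid = "" if corrupted else bridge
        seq1 = dna_seq + mid + revcomp(rna_sense) + tail
        if cfg.sub_rate > 0:
            seq1 = _substitute(seq1, cfg.sub_rate, rng)
        seq2 = revcomp(seq1)
        qual = "I" * len(seq1)
        records.append((row.read_id, seq1, qual, seq2, qual))
        truth_rows.append(
            (row.read_id, row.gene_id, row.rna_chrom, row.rna_start, row.rna_end,
             row.rna_strand, row.dna_chrom, row.dna_start, row.dna_end,
             row.fraction, row.replicate, dna_seq, expected_rna, corrupted)
        )
    truth = TruthTable(
        pd.DataFrame(
            truth_rows,
            columns=["read_id", "gene_id", "rna_chrom", "rna_start", "rna_end",
                     "rna_strand", "dna_chrom", "dna_start", "dna_end",
                     "fraction", "replicate", "dna_seq", "rna_seq", "corrupted"],
        )
    )
    return records, truth


def _substitute(seq: str, rate: float, rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    if len(hits) == 0:
        return seq
    arr[hits] = _BASES[(np.searchsorted(_BASES, arr[hits]) + rng.integers(1, 4, len(hits))) % 4]
    return arr.tobytes().decode()


# ---------------------------------------------------------------------------
# On-disk experiment


def write_simulation(
    cfg: SimConfig, outdir: str | Path, with_reads: bool = True
) -> dict:
    """Run the full simulator and write every artifact under ``outdir``.

    Writes ref.fa, genes.gtf, states.bed, peaks.bed, gene_truth.tsv,
    contacts_<fraction>_rep<k>.tsv and (optionally) reads_*_R1/R2.fastq
    plus truth_*.tsv per library. Returns a manifest of the paths.
    """
    from .core_io import write_contacts

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ref = simulate_reference(cfg)
    tables = simulate_contacts(cfg, ref)
    bridge_cfg = default_bridge_config(cfg)

    manifest: dict = {"outdir": str(outdir)}
    write_fasta(ref.genome, outdir / "ref.fa")
    write_gtf_genes(ref.genes, outdir / "genes.gtf")
    write_bed(ref.states, outdir / "states.bed")
    write_bed(ref.peaks, outdir / "peaks.bed")
    manifest.update(
        genome=str(outdir / "ref.fa"), genes=str(outdir / "genes.gtf"),
        states=str(outdir / "states.bed"), peaks=str(outdir / "peaks.bed"),
    )
    manifest["libraries"] = {}
    for (fraction, rep), table in tables.items():
        stem = f"{fraction.lower()}_rep{rep}"
        write_contacts(table, outdir / f"contacts_{stem}.tsv")
        entry = {"contacts": str(outdir / f"contacts_{stem}.tsv")}
        if with_reads:
            reads, truth = contacts_to_reads(table, ref, bridge_cfg, cfg)
            r1 = outdir / f"reads_{stem}_R1.fastq"
            r2 = outdir / f"reads_{stem}_R2.fastq"
            write_fastq_pairs(reads, r1, r2)
            truth.frame.to_csv(outdir / f"truth_{stem}.tsv", sep="\t", index=False)
            entry.update(r1=str(r1), r2=str(r2), truth=str(outdir / f"truth_{stem}.tsv"))
        manifest["libraries"][stem] = entry
    ref.gene_truth.to_csv(outdir / "gene_truth.tsv", sep="\t", index=False)
    manifest["gene_truth"] = str(outdir / "gene_truth.tsv")
    manifest["bridge"] = bridge_cfg.to_dict()
    return manifest
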