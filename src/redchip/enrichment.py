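"""IP/input enrichment analyses over RNA-DNA contact tables.

The central statistic is a depth-normalized fold change per RNA:

    FC = (count_IP / total_IP) / (count_input / total_input)

where ``count`` is the gene's cis (or trans) contact count and ``total`` is
the library's total contact count. Cis contacts are those whose DNA part
overlaps a window of +/- 1 Mb around the gene body (gene included) on the
parent chromosome; trans contacts lie on nonparental chromosomes. An RNA is
called enriched when its fold change exceeds the threshold (default 1.3,
strict inequality) in EVERY replicate, after a minimum-count filter
(default 10 contacts per fraction) that keeps low-coverage ratios from
blowing up.

Chromatin-state and peak assignment use the DNA-part midpoint: tags are
~20 bp, so the midpoint is an orientation-free point estimate of the
contact position.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .contacts import ContactTable, UNASSIGNED
from .core_io import GeneRecord, IntervalTrack

logger = logging.getLogger("redchip")

DEFAULT_WINDOW_BP = 1_000_000
DEFAULT_FC_THRESHOLD = 1.3
DEFAULT_MIN_COUNT = 10


@dataclass
class RNAProfile:
    """Per-gene aggregated contact counts for one library."""

    gene_id: str
    biotype: str
    cis_window: tuple[str, int, int]
    cis_count: int
    trans_count: int
    state_counts: dict[str, int]
    fraction: str
    replicate: int


@dataclass
class EnrichmentResult:
    """Per-gene IP/input fold changes and the enriched call."""

    gene_id: str
    biotype: str
    fc_per_replicate: list[float]  # NaN where undefined (min-count filter)
    enriched: bool
    mode: str  # {"cis", "trans"}


# ---------------------------------------------------------------------------
# Windows and cis/trans counting


def cis_window(gene: GeneRecord, window_bp: int, chrom_length: int) -> tuple[int, int]:
    """Gene body extended by ``window_bp`` on each side, clamped to the chromosome."""
    if window_bp < 0:
        raise ValueError("window_bp must be >= 0")
    return max(0, gene.start - window_bp), min(chrom_length, gene.end + window_bp)


def count_cis_trans(
    gene: GeneRecord,
    contacts: pd.DataFrame | ContactTable,
    window_bp: int = DEFAULT_WINDOW_BP,
    chrom_length: int | None = None,
) -> tuple[int, int]:
    """(cis, trans) contact counts for one gene.

    Cis: DNA part overlaps the cis window on the parent chromosome. Trans:
    DNA part on any other chromosome. Parental-chromosome contacts outside
    the window belong to neither.
    """
    frame = contacts.frame if isinstance(contacts, ContactTable) else contacts
    sub = frame[frame["gene_id"] == gene.gene_id]
    if not len(sub):
        return 0, 0
    if chrom_length is None:
        chrom_length = int(sub["dna_end"].max()) + window_bp + 1
    lo, hi = cis_window(gene, window_bp, chrom_length)
    on_parent = sub["dna_chrom"] == gene.chrom
    cis = int((on_parent & (sub["dna_start"] < hi) & (sub["dna_end"] > lo)).sum())
    trans = int((~on_parent).sum())
    return cis, trans


def cis_trans_counts_all(
    frame: pd.DataFrame,
    genes: Sequence[GeneRecord],
    chrom_lengths: Mapping[str, int],
    window_bp: int = DEFAULT_WINDOW_BP,
) -> pd.DataFrame:
    """Vectorized per-gene (cis, trans) counts for a whole library.

    Returns a frame indexed by gene_id with columns cis, trans, total.
    """
    info = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "chrom": [g.chrom for g in genes],
            "win_lo": [cis_window(g, window_bp, chrom_lengths[g.chrom])[0] for g in genes],
            "win_hi": [cis_window(g, window_bp, chrom_lengths[g.chrom])[1] for g in genes],
        }
    ).set_index("gene_id")
    assigned = frame[frame["gene_id"] != UNASSIGNED]
    merged = assigned.merge(info, left_on="gene_id", right_index=True, how="inner")
    on_parent = merged["dna_chrom"] == merged["chrom"]
    is_cis = on_parent & (merged["dna_start"] < merged["win_hi"]) & (merged["dna_end"] > merged["win_lo"])
    out = pd.DataFrame(index=info.index)
    out["cis"] = is_cis.groupby(merged["gene_id"]).sum().reindex(info.index, fill_value=0).astype(int)
    out["trans"] = (~on_parent).groupby(merged["gene_id"]).sum().reindex(info.index, fill_value=0).astype(int)
    out["total"] = merged.groupby("gene_id").size().reindex(info.index, fill_value=0).astype(int)
    return out


# ---------------------------------------------------------------------------
# Fold change and calling


def fold_change(
    count_ip: int,
    total_ip: int,
    count_in: int,
    total_in: int,
    min_count: int = DEFAULT_MIN_COUNT,
) -> float:
    """Depth-normalized IP/input ratio; NaN when either count fails the filter.

    Scale-invariant: multiplying one library's count and total by any c > 0
    leaves the value unchanged.
    """
    if total_ip <= 0 or total_in <= 0:
        raise ValueError("library totals must be positive")
    if count_ip < min_count or count_in < min_count:
        return float("nan")
    return (count_ip / total_ip) / (count_in / total_in)


def call_enriched(fc_per_replicate: Sequence[float], threshold: float = DEFAULT_FC_THRESHOLD) -> bool:
    """True iff every replicate fold change is defined and strictly above threshold."""
    fcs = list(fc_per_replicate)
    if not fcs:
        raise ValueError("need at least one replicate")
    return all(not math.isnan(fc) and fc > threshold for fc in fcs)


def enrichment_table(
    ip_tables: Sequence[ContactTable | pd.DataFrame],
    input_tables: Sequence[ContactTable | pd.DataFrame],
    genes: Sequence[GeneRecord],
    chrom_lengths: Mapping[str, int],
    mode: str = "cis",
    window_bp: int = DEFAULT_WINDOW_BP,
    threshold: float = DEFAULT_FC_THRESHOLD,
    min_count: int = DEFAULT_MIN_COUNT,
) -> pd.DataFrame:
    """Per-gene fold changes across replicate-matched IP/input pairs.

    Replicate k of IP is always compared with replicate k of input;
    replicates are never merged for calling (the published rule requires
    enrichment in every replicate). A merged-replicate fold change is
    reported as a descriptive extra (``fc_merged``).
    """
    if mode not in ("cis", "trans"):
        raise ValueError("mode must be 'cis' or 'trans'")
    if len(ip_tables) != len(input_tables) or not ip_tables:
        raise ValueError("need equal, nonzero numbers of IP and input tables")

    def _frame(t):
        return t.frame if isinstance(t, ContactTable) else t

    gene_ids = [g.gene_id for g in genes]
    out = pd.DataFrame(
        {"gene_id": gene_ids, "biotype": [g.biotype for g in genes]}
    ).set_index("gene_id")

    sum_counts_ip = pd.Series(0, index=out.index, dtype=float)
    sum_counts_in = pd.Series(0, index=out.index, dtype=float)
    tot_ip_all = tot_in_all = 0
    for k, (t_ip, t_in) in enumerate(zip(ip_tables, input_tables), start=1):
        f_ip, f_in = _frame(t_ip), _frame(t_in)
        c_ip = cis_trans_counts_all(f_ip, genes, chrom_lengths, window_bp)
        c_in = cis_trans_counts_all(f_in, genes, chrom_lengths, window_bp)
        total_ip, total_in = len(f_ip), len(f_in)
        out[f"count_ip_rep{k}"] = c_ip[mode]
        out[f"count_input_rep{k}"] = c_in[mode]
        fc = np.where(
            (c_ip[mode] >= min_count) & (c_in[mode] >= min_count),
            (c_ip[mode] / max(total_ip, 1)) / (c_in[mode] / max(total_in, 1)).replace(0, np.nan),
            np.nan,
        )
        out[f"fc_rep{k}"] = fc
        sum_counts_ip += c_ip[mode]
        sum_counts_in += c_in[mode]
        tot_ip_all += total_ip
        tot_in_all += total_in

    fc_cols = [c for c in out.columns if c.startswith("fc_rep")]
    out["enriched"] = (out[fc_cols] > threshold).all(axis=1) & out[fc_cols].notna().all(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out["fc_merged"] = np.where(
            (sum_counts_ip >= min_count) & (sum_counts_in >= min_count),
            (sum_counts_ip / max(tot_ip_all, 1)) / (sum_counts_in / max(tot_in_all, 1)),
            np.nan,
        )
    out["mode"] = mode
    logger.info(
        "enrichment_table(%s): %d genes, %d enriched at FC>%g in %d replicates",
        mode, len(out), int(out["enriched"].sum()), threshold, len(ip_tables),
    )
    return out.reset_index()


# ---------------------------------------------------------------------------
# Chromatin-state annotation


class StateIndex:
    """Point lookup of a non-overlapping chromatin-state segmentation."""

    def __init__(self, segmentation: IntervalTrack):
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._labels: dict[str, list[str]] = {}
        by_chrom = segmentation.by_chrom()
        for chrom, ivs in by_chrom.items():
            for (s1, e1, _), (s2, _, _) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise ValueError(f"overlapping state segments on {chrom}")
            self._starts[chrom] = np.array([iv[0] for iv in ivs], dtype=np.int64)
            self._ends[chrom] = np.array([iv[1] for iv in ivs], dtype=np.int64)
            self._labels[chrom] = [iv[2] for iv in ivs]

    def lookup(self, chroms: Sequence[str], positions: np.ndarray) -> list[str | None]:
        """State label at each (chrom, position), None when unsegmented."""
        out: list[str | None] = [None] * len(positions)
        chrom_arr = np.asarray(chroms, dtype=object)
        for chrom in np.unique(chrom_arr):
            if chrom not in self._starts:
                continue
            mask = chrom_arr == chrom
            pos = positions[mask]
            idx = np.searchsorted(self._starts[chrom], pos, side="right") - 1
            valid = (idx >= 0) & (pos < self._ends[chrom][np.maximum(idx, 0)])
            labels = self._labels[chrom]
            for where, i, ok in zip(np.nonzero(mask)[0], idx, valid):
                out[where] = labels[i] if ok else None
        return out


def _dna_midpoints(frame: pd.DataFrame) -> np.ndarray:
    return ((frame["dna_start"].to_numpy() + frame["dna_end"].to_numpy()) // 2).astype(np.int64)


def contact_states(frame: pd.DataFrame, segmentation: IntervalTrack | StateIndex) -> pd.Series:
    """Chromatin state of each contact's DNA-part midpoint (None if unsegmented)."""
    index = segmentation if isinstance(segmentation, StateIndex) else StateIndex(segmentation)
    labels = index.lookup(frame["dna_chrom"].tolist(), _dna_midpoints(frame))
    return pd.Series(labels, index=frame.index, dtype=object)


def state_percentages(
    gene: GeneRecord | str,
    contacts: pd.DataFrame | ContactTable,
    segmentation: IntervalTrack | StateIndex,
    scope: str = "cis_window",
    window_bp: int = DEFAULT_WINDOW_BP,
    chrom_length: int | None = None,
) -> dict[str, float]:
    """Percentage of a gene's contacts per chromatin state (sums to 100).

    The DNA-part midpoint determines the state; contacts whose midpoint
    falls outside every segment are excluded from the denominator. Scope
    ``cis_window`` restricts to cis contacts, ``genome`` uses all contacts
    of the gene.
    """
    if scope not in ("cis_window", "genome"):
        raise ValueError("scope must be 'cis_window' or 'genome'")
    frame = contacts.frame if isinstance(contacts, ContactTable) else contacts
    if isinstance(gene, GeneRecord):
        gene_id = gene.gene_id
    else:
        gene_id = gene
    sub = frame[frame["gene_id"] == gene_id]
    if scope == "cis_window":
        if not isinstance(gene, GeneRecord):
            raise ValueError("cis_window scope needs a GeneRecord")
        if chrom_length is None:
            chrom_length = int(frame["dna_end"].max() or 0) + window_bp + 1
        lo, hi = cis_window(gene, window_bp, chrom_length)
        sub = sub[(sub["dna_chrom"] == gene.chrom) & (sub["dna_start"] < hi) & (sub["dna_end"] > lo)]
    if not len(sub):
        return {}
    labels = contact_states(sub, segmentation)
    counts = labels.dropna().value_counts()
    total = counts.sum()
    if total == 0:
        return {}
    return {str(k): 100.0 * v / total for k, v in counts.items()}


def state_ratio_ip_input(
    contacts_ip: pd.DataFrame | ContactTable,
    contacts_input: pd.DataFrame | ContactTable,
    segmentation: IntervalTrack | StateIndex,
) -> dict[str, float]:
    """Depth-normalized IP/input contact ratio per chromatin state.

    Per state: (count_IP/total_IP) / (count_input/total_input). States with
    zero input contacts are reported NaN.
    """
    f_ip = contacts_ip.frame if isinstance(contacts_ip, ContactTable) else contacts_ip
    f_in = contacts_input.frame if isinstance(contacts_input, ContactTable) else contacts_input
    if not len(f_ip) or not len(f_in):
        raise ValueError("both contact tables must be nonempty")
    index = segmentation if isinstance(segmentation, StateIndex) else StateIndex(segmentation)
    ip_counts = contact_states(f_ip, index).dropna().value_counts()
    in_counts = contact_states(f_in, index).dropna().value_counts()
    states = sorted(set(ip_counts.index) | set(in_counts.index))
    out: dict[str, float] = {}
    for s in states:
        n_ip, n_in = int(ip_counts.get(s, 0)), int(in_counts.get(s, 0))
        if n_in == 0:
            out[s] = float("nan")
        else:
            out[s] = (n_ip / len(f_ip)) / (n_in / len(f_in))
    return out


# ---------------------------------------------------------------------------
# Peak metaprofile


def peak_metaprofile(
    contacts: pd.DataFrame | ContactTable,
    peaks: IntervalTrack,
    flank_bp: int = 10_000,
    n_bins: int = 41,
) -> pd.DataFrame:
    """Binned distribution of DNA-part midpoints around the nearest peak center.

    For each contact the signed distance from its DNA-part midpoint to the
    NEAREST peak center is computed; distances within +/- flank_bp are
    binned into ``n_bins`` (odd, so a center bin exists). Values are
    contacts per million total contacts per bin. Contacts farther than the
    flank from every peak are excluded.
    """
    if n_bins % 2 == 0 or n_bins < 1:
        raise ValueError("n_bins must be odd and positive")
    if len(peaks) == 0:
        raise ValueError("empty peak set")
    frame = contacts.frame if isinstance(contacts, ContactTable) else contacts
    centers: dict[str, np.ndarray] = {}
    for chrom, ivs in peaks.by_chrom().items():
        centers[chrom] = np.sort(np.array([(s + e) // 2 for s, e, _ in ivs], dtype=np.int64))
    mids = _dna_midpoints(frame)
    chroms = frame["dna_chrom"].to_numpy(dtype=object)
    dists = np.full(len(frame), np.iinfo(np.int64).max, dtype=np.int64)
    for chrom, cc in centers.items():
        mask = chroms == chrom
        if not mask.any():
            continue
        pos = mids[mask]
        idx = np.searchsorted(cc, pos)
        left = cc[np.clip(idx - 1, 0, len(cc) - 1)]
        right = cc[np.clip(idx, 0, len(cc) - 1)]
        d_left = pos - left
        d_right = pos - right
        pick_right = np.abs(d_right) < np.abs(d_left)
        dists[mask] = np.where(pick_right, d_right, d_left)
    in_range = np.abs(dists) <= flank_bp
    edges = np.linspace(-flank_bp, flank_bp, n_bins + 1)
    counts, _ = np.histogram(dists[in_range], bins=edges)
    total = len(frame)
    cpm = counts * 1e6 / total if total else counts.astype(float)
    bin_centers = (edges[:-1] + edges[1:]) / 2
    return pd.DataFrame({"bin_center": bin_centers, "count": counts, "cpm": cpm})


# ---------------------------------------------------------------------------
# Statistical tests


def biotype_fc_test(
    results: pd.DataFrame, biotype_a: str, biotype_b: str, fc_col: str = "fc_merged"
) -> tuple[float, float]:
    """Two-sided rank-sum comparison of fold-change distributions of two biotypes.

    Mann-Whitney U with an exact null for groups of <= 8 untied values and
    the tie-corrected normal approximation otherwise. Returns (U, p).
    """
    a = results.loc[results["biotype"] == biotype_a, fc_col].dropna().to_numpy(dtype=float)
    b = results.loc[results["biotype"] == biotype_b, fc_col].dropna().to_numpy(dtype=float)
    return rank_sum_test(a, b)


def rank_sum_test(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U on raw samples (see biotype_fc_test)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs >= 3 defined values")
    if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
        return float(len(a) * len(b) / 2), 1.0
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (len(a) <= 8 and len(b) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), min(float(res.pvalue), 1.0)


def overlap_test(
    set_a: Iterable[str], set_b: Iterable[str], universe_size: int
) -> tuple[int, float]:
    """One-sided Fisher's exact (hypergeometric upper tail) on a list overlap.

    Tests whether |A intersect B| is larger than expected for random draws
    of |A| and |B| from a universe of ``universe_size`` items. Returns
    (overlap_count, p).
    """
    sa, sb = set(set_a), set(set_b)
    if universe_size < len(sa | sb):
        raise ValueError("universe smaller than the union of the two sets")
    k = len(sa & sb)
    p = float(stats.hypergeom.sf(k - 1, universe_size, len(sa), len(sb)))
    return k, min(p, 1.0)


def rank_rnas(counts: Mapping[str, int]) -> list[tuple[str, int, float]]:
    """Genes by descending contact count with their share of the total.

    Ties break lexicographically by gene id. Returns (gene_id, count, share).
    """
    total = sum(counts.values())
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [(g, c, c / total if total else 0.0) for g, c in ordered]


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (reported alongside raw p)."""
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out
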