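import pandas as pd
import pytest

from redchip.core_io import CONTACT_COLUMNS
from redchip.simulate import (
    SimConfig,
    default_bridge_config,
    simulate_contacts,
    simulate_reference,
)

#: compact study design reused across read-level tests: small genome so the
#: exact-match fixture aligner stays fast, short decay so cis structure is
#: visible on 300 kb chromosomes
SMALL_DESIGN = dict(
    seed=7,
    n_chroms=2,
    chrom_length=300_000,
    n_genes=40,
    gene_len_min=1_000,
    gene_len_max=3_000,
    enriched_flank_bp=50_000,
    cis_decay_scale=20_000.0,
    state_segment_bp=10_000,
    n_peaks=20,
    n_contacts_per_fraction=800,
    enriched_gene_fraction=0.1,
)


@pytest.fixture(scope="session")
def small_cfg():
    return SimConfig(**SMALL_DESIGN)


@pytest.fixture(scope="session")
def small_ref(small_cfg):
    return simulate_reference(small_cfg)


@pytest.fixture(scope="session")
def small_tables(small_cfg, small_ref):
    return simulate_contacts(small_cfg, small_ref)


@pytest.fixture(scope="session")
def small_bridge(small_cfg):
    return default_bridge_config(small_cfg)


def make_contacts(rows, fraction="IP", replicate=1):
    """Build a canonical contact frame from terse row dicts."""
    defaults = {
        "read_id": None,
        "rna_chrom": "chr1",
        "rna_start": 100,
        "rna_end": 140,
        "rna_strand": "+",
        "gene_id": "geneA",
        "dna_chrom": "chr1",
        "dna_start": 500,
        "dna_end": 520,
        "fraction": fraction,
        "replicate": replicate,
    }
    full = []
    for i, row in enumerate(rows):
        rec = dict(defaults, **row)
        if rec["read_id"] is None:
            rec["read_id"] = f"r{i:04d}"
        full.append(rec)
    if not full:
        from redchip.core_io import empty_contact_frame

        return empty_contact_frame()
    return pd.DataFrame(full, columns=CONTACT_COLUMNS)
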