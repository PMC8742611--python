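# redchip

Analysis toolkit for protein-centric RNA–DNA interactome experiments that
combine RNA–DNA proximity ligation with chromatin immunoprecipitation.
In such an experiment, RNA 3′ ends are ligated to a bridge adapter that is
in turn ligated to nearby DNA ends; after IP against a protein of interest
(e.g. EZH2 of Polycomb repressive complex 2, or CTCF), the purified
chimeras are paired-end sequenced. Each read pair therefore encodes one
RNA–DNA contact that may be mediated by the chosen protein, and a parallel
*input* (non-IP) library records the unselected contact background.

`redchip` is for computational biologists processing such libraries. It
covers the full path from raw reads to called RNAs:

1. **Deconvolution** — locate the bridge adapter in read 1 (substitution-
   tolerant Hamming search) and split the read into the short MmeI DNA tag
   (default 18–22 bp) and the transcript-sense RNA part, trimming
   template-switch G artifacts; every pair receives exactly one status
   (`OK`, `NO_BRIDGE`, `MULTI_BRIDGE`, `DNA_SHORT`, `DNA_LONG`,
   `RNA_SHORT`), so statuses partition the library.
2. **Contacts** — map both parts (bundled exact-match aligner for
   synthetic genomes, or ingest SAM/BAM/TSV from a production aligner),
   assign RNA parts to annotated genes strand-specifically, collapse PCR
   duplicates on the 5′ coordinates of both parts, and write a tab-separated
   contact table.
3. **Enrichment** — for each RNA, the depth-normalized IP/input fold change

   $$FC_g = \frac{n^{IP}_g / N^{IP}}{n^{in}_g / N^{in}}$$

   over its *cis* contacts (DNA part within ±1 Mb of the gene, gene body
   included) or *trans* contacts (nonparental chromosomes). An RNA is
   called enriched when FC > 1.3 in **every** replicate and both fractions
   supply at least 10 contacts. Supporting analyses: chromatin-state
   percentages and IP/input state ratios (DNA-part midpoint vs a labeled
   segmentation), ChIP-peak metaprofiles, Mann–Whitney comparisons of fold
   changes between RNA biotypes, and one-sided Fisher tests for overlap
   with orthogonal RNA lists (e.g. fRIP-seq positives).
4. **Simulation** — a fully synthetic experiment generator (genome, genes
   with biotypes, chromatin states, peaks, contact tables with a known
   injected enrichment factor, and FASTQ reads with the embedded bridge)
   with complete ground truth, so the entire pipeline is testable without
   any external data.

## Worked example

```python
from redchip import SimConfig, simulate_reference, simulate_contacts, enrichment_table
from redchip.enrichment import state_ratio_ip_input

cfg = SimConfig(seed=1, chrom_length=8_000_000, n_genes=120,
                enriched_flank_bp=150_000, cis_decay_scale=50_000.0,
                enriched_gene_fraction=0.08)
ref = simulate_reference(cfg)          # genome + genes + states + peaks + truth
tables = simulate_contacts(cfg, ref)   # (fraction, replicate) -> ContactTable

res = enrichment_table(
    [tables[("IP", 1)], tables[("IP", 2)]],
    [tables[("input", 1)], tables[("input", 2)]],
    ref.genes, ref.genome.lengths, mode="cis",
)
print(res[res["enriched"]][["gene_id", "biotype", "fc_rep1", "fc_rep2"]])
```

prints the 10 called RNAs — on this seed exactly the 10 genes simulated
with enrichment factor e = 2:

```
10 RNAs called cis-enriched (FC > 1.3 in both replicates), 10 truly enriched:
 gene_id        biotype  fc_rep1  fc_rep2
gene0003      antisense     1.87     1.92
gene0004      antisense     1.58     2.15
gene0027 protein_coding     2.02     1.96
...
gene0115 protein_coding     1.90     2.11
```

The per-replicate fold changes cluster around the injected factor 2. The
chromatin-state ratio singles out the designated (Polycomb-like) state
where the enrichment was injected, mirroring the figure-style readout of a
real IP:

```
IP/input contact ratio per chromatin state (rep 1):
  Enhancer   0.95
  Insulator  0.93
  Polycomb   1.28
  Promoter   0.94
  Quiescent  0.96
```

and the peak metaprofile shows DNA parts piling up at peak centers
(6720 vs 3680 contacts per million at the profile edges).

## Command line

```bash
redchip simulate   --config sim.yaml --outdir sim/
redchip deconvolve --r1 R1.fastq --r2 R2.fastq --config cfg.yaml \
                   --out parts.tsv --stats stats.tsv
redchip contacts   --parts parts.tsv --genome ref.fa --genes genes.gtf \
                   --fraction IP --replicate 1 --out contacts.tsv
redchip enrich     --ip ip_rep1.tsv --ip ip_rep2.tsv \
                   --input in_rep1.tsv --input in_rep2.tsv \
                   --genes genes.gtf --genome ref.fa \
                   --states states.bed --peaks peaks.bed --out results.tsv
redchip run        --config pipeline.yaml      # the whole thing, end to end
```

Every stage logs record counts in and out, and `redchip run` writes a
report in which the conservation identities hold exactly: reads in equals
the sum over statuses, and OK reads equal contacts plus rejected plus
deduplicated reads.

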