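# Methods

## Read model and deconvolution

The library chemistry determines a fixed read-1 layout:

```
[DNA tag][bridge adapter][RNA part, cDNA orientation]
```

DNA is fragmented with NlaIII, ends are ligated to one side of a bridge
adapter whose other side ligates the 3′ end of a nearby RNA; after IP and
purification, MmeI cuts at a fixed distance from its recognition site in
the bridge, releasing a short genomic DNA tag. Reverse transcription primes
from the bridge and runs to the RNA 5′ end, where template switching can
append a few non-templated bases.

Consequences for parsing, and the choices made here:

* **Bridge search** is substitution-only (Hamming distance, default budget
  1 mismatch; `N` counts as mismatch). The bridge is short (the bundled
  synthetic oligo is 20 nt) and indel-tolerant matching would add
  complexity for negligible yield; this is a documented limitation. The
  actual oligo sequence is a required configuration value — the algorithm
  is agnostic to its identity.
* **Statuses partition the library** in a fixed decision order:
  `NO_BRIDGE` (0 hits) → `MULTI_BRIDGE` (≥ 2 hits) → `DNA_SHORT`/`DNA_LONG`
  (tag outside the accepted window, default 18–22 bp for an MmeI-type cut;
  configurable because accepted tag lengths vary with the enzyme) →
  `RNA_SHORT` (< 14 nt after trimming) → `OK`. Pairs with multiple bridge
  hits are discarded rather than resolved to the leftmost hit: an ambiguous
  chimera would create spurious contacts.
* **RNA orientation**: the RNA part is reported in transcript sense
  (reverse complement of the read segment after the bridge), which makes
  gene assignment a strand equality downstream.
* **Template-switch trimming** removes up to 4 G's at the transcript 5′
  end. When the artifact run merges with genuine genomic G's the two are
  indistinguishable, so up to 4 genuine leading G's can be lost; this is
  inherent information loss, not a parser defect.
* **Read 2 is ignored by default** (single-side deconvolution). An
  optional merge extends the RNA part with the mate when an exact
  suffix/prefix overlap of ≥ 10 nt exists. The NlaIII residue at the DNA
  end is retained, not trimmed.

## Contacts

A contact is emitted only when both parts of an OK read align uniquely;
multi-mapped parts are excluded outright rather than rescued, trading
sensitivity for the contact specificity that enrichment testing needs.
PCR duplicates are collapsed on the 5′ coordinates of both parts within a
(fraction, replicate) library — the standard proximity-ligation duplicate
definition. Gene assignment considers genes overlapping the RNA alignment
on the same strand only (an antisense transcript must itself be annotated
to be counted); among candidates the largest overlap wins, ties break to
the shorter gene and then to the lexicographically smaller id, which makes
the rule deterministic. Any gene-body overlap counts (exon structure is
not modeled). The bundled aligner does exact matching on both strands and
is intended for synthetic genomes; real libraries should enter through
`ingest_alignments` (coordinates, strand and read id only; records that
are secondary, supplementary or have mapping quality 0 are treated as
non-unique).

## Enrichment model

For gene *g* with contact count *n_g* in a library of *N* total contacts,
the fold change is the ratio of proportions

FC_g = (n_g^IP / N^IP) / (n_g^in / N^in).

Normalizing by total library contacts is the minimal depth correction and
makes FC invariant under rescaling any one library. Counts are taken over
the gene's **cis** contacts — DNA part overlapping the gene body extended
by ±1 Mb (window configurable) on the parent chromosome — or its **trans**
contacts (any nonparental chromosome). Parental-chromosome contacts beyond
the window belong to neither class.

Calling: an RNA is enriched iff FC > 1.3 (strict) in **every** replicate;
replicate *k* of IP is always compared with replicate *k* of input, and
replicates are never merged for calling (a pooled `fc_merged` is reported
as a descriptive extra). FC is undefined (NA, gene excluded) when either
fraction supplies fewer than `min_count = 10` contacts; without an
abundance filter low-coverage ratios blow up. Both threshold and filter
are configurable.

Chromatin-state assignment uses the DNA-part midpoint against a
non-overlapping labeled segmentation: tags are ~20 bp, so the midpoint is
an orientation-free point estimate. State percentages are computed over
classified contacts (midpoints outside every segment are excluded and
reported), so they sum to 100. The IP/input state ratio is depth-normalized
the same way as FC. Peak metaprofiles bin the signed distance from each
DNA-part midpoint to the nearest peak center (default ±10 kb, 41 bins, an
odd count so a center bin exists), normalized to contacts per million.

Statistical tests: biotype fold-change distributions are compared with a
two-sided Mann–Whitney U (exact null for untied groups of ≤ 8, normal
approximation with tie correction otherwise); list overlaps use a
one-sided Fisher's exact test (hypergeometric upper tail). Both are
conventional nonparametric choices for these readouts and both are checked
in the test suite against brute-force oracles (full label enumeration /
direct tail summation) that are independent of the implementation (which
delegates to SciPy). When many tests are run, Benjamini–Hochberg adjusted
p-values are available alongside raw ones.

## Simulator

The generator emulates the statistical structure the estimator targets,
not sequencing physics:

* **Genome**: i.i.d. random bases; a chromosome is redrawn if more than 1%
  of its 20-mers are duplicated (for the default 2 × 2 Mb design the
  duplicate fraction is ~10⁻⁵, so exact-match alignment is effectively
  lossless and end-to-end truth recovery is a meaningful test).
* **Genes**: slot-based placement, hence non-overlapping; biotypes drawn
  from a configurable mix (55% protein_coding, 20% lincRNA, 10% antisense,
  8% snRNA, 7% snoRNA); expression weights log-normal(0, 1) — arbitrary
  but configurable, giving the heavy-tailed per-gene coverage real
  libraries show.
* **Input contacts**: source gene ∝ expression weight; RNA interval
  uniform within the gene; with probability `p_cis = 0.75` the DNA
  position falls on the parent chromosome at a signed distance from the
  gene drawn from a symmetric exponential (Laplace) with scale 100 kb —
  real contact frequency decays with distance, and a decay is required for
  the ±1 Mb window to capture a meaningful cis fraction — otherwise
  uniform on a random nonparental chromosome. Tag lengths are uniform in
  the MmeI window.
* **IP contacts** are drawn from the same base distribution reweighted by
  the enrichment factor *e* whenever the source gene is enriched **and**
  the DNA position lies in the designated chromatin state, then
  renormalized (rejection sampling). This importance-reweighting design
  creates exactly the proportion-ratio signal FC estimates, so parameter
  recovery is well-posed: the expected measured FC of an enriched gene is
  e/Z with Z = 1 + (e − 1)·q, where q is the base probability mass of
  boosted pairs (~5% at the defaults, predicting FC ≈ 1.93 for e = 2 —
  which is what the acceptance run measures).
* **Layout**: the designated state (default "Polycomb") covers each
  enriched gene ± 500 kb; remaining sequence is tiled with the other
  labels in 25-kb segments; ChIP peaks are placed inside the designated
  state. At the default 2-Mb chromosome scale the designated state
  therefore covers most of the genome — adequate for fold-change recovery,
  but state-ratio readouts are more legible on sparser layouts (larger
  chromosomes or smaller flanks), as in the README example.
* **Reads**: read 1 = tag + bridge + revcomp(RNA fragment); read 2 is the
  reverse complement of read 1 (minimal mate model — mates carry no
  independent information, consistent with single-side deconvolution).
  Noise knobs: `noise` deletes the bridge in that fraction of pairs,
  `sub_rate` applies uniform substitutions, and
  `simulate_template_switch_g` appends 0–3 artifact bases. Template-switch
  simulation is off by default and the matching bridge config enables
  trimming only when the artifact is simulated, so clean libraries
  round-trip bit-exactly; the ground-truth table always records the
  fragments a perfect parser recovers (post-trim when trimming applies).

Everything is deterministic under a fixed seed: each stage derives its
generator from (stage tag, seed, library labels), so outputs are
byte-identical across runs and independent of stage order.

### What the simulator does not emulate

No quality-score model, GC or mappability bias, splicing (RNA fragments
are contiguous gene-body slices), chromatin-state maps with realistic
length distributions, or inter-replicate batch effects (replicates are
i.i.d. draws). Passing tests therefore demonstrate correctness of the
algorithms and calibration of the caller under the stated generative
model, not performance on real human libraries, where alignment ambiguity,
annotation overlap and replicate heterogeneity will dominate.

## Problem sizes and numerical choices

The parameter-recovery and null-calibration checks use the reference
design: 2 chromosomes × 2 Mb, 200 genes, 5% enriched at e = 2.0 (or 1.0
for the null), 50,000 contacts per fraction, 2 replicates, aggregated over
20 simulation seeds. Read-level checks use 1,000-pair libraries on a
2 × 300 kb genome — compact sizes chosen so the exact-match aligner and
brute-force test oracles remain the binding cost, while per-gene counts
(median ≈ 100 contacts) are large enough for stable fold changes.

Tie-breaks and degenerate inputs are handled deterministically throughout:
gene-assignment ties resolve by gene length then id; RNA ranking ties by
id; empty contact tables produce header-only files; an empty peak set or
an overlapping state segmentation raises immediately. The uniform-profile
flatness check in the acceptance suite bounds all 41 bins at the
Šidák-adjusted per-bin quantile whose familywise error equals the 3σ level
(≈ 3.99σ per bin), since a per-bin 3σ bound over 41 simultaneous bins
rejects ~10% of uniform profiles.

## Known limitations

* Substitution-only bridge matching; an indel in the bridge loses the pair.
* Up to 4 genuine leading G's can be trimmed along with template-switch
  artifacts.
* Multi-mapped parts are dropped, biasing against repeat-derived RNAs.
* Intron-containing genes are treated as a single body for assignment.
* The bundled aligner is exact-match only and scales linearly with genome
  size; it is a fixture for synthetic data, not a production aligner.
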