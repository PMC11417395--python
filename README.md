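# tramseq

Quantifying tRNA expression and mapping tRNA modifications from small-RNA
sequencing data.

tRNA genes exist in dozens-to-thousands of identical or near-identical
copies, and mature tRNAs are densely modified. Both properties defeat
standard RNA-seq pipelines: multimapping reads are discarded, and
modification-induced reverse-transcription (RT) errors either break the
alignment or are mistaken for variants. `tramseq` implements an analysis
pipeline built for this regime, aimed at researchers profiling tRNA
abundance and modification dynamics (for example across developmental
stages) from libraries prepared with a processive RT such as TGIRT:

* **mock** libraries (untreated) carry the RT-error signatures of
  modifications;
* **DM** libraries (demethylated with AlkB before library prep) erase the
  signatures of m¹A/m¹G/m³C/m²₂G and are used for unbiased quantification;
* **BS** libraries (demethylated, then bisulfite-converted) read
  unmethylated C as T, so C retention reports m⁵C.

## Method

1. **Reference construction.** Mature tRNA references are built from
   tRNAscan-SE/GtRNAdb-style nuclear predictions plus mitochondrial tRNAs:
   introns removed, 3′ CCA appended when not genomically encoded, the His
   G₋₁ prepended. Identical mature sequences collapse into one reference.
   Canonical (Sprinzl) position labels — 1…76 with 20a/20b and variable-arm
   e-positions — are transferred from a packaged numbered structural
   alignment by profile alignment, so positions are comparable across tRNAs
   of different lengths. References below 500 RPM (reads per million) in
   every DM sample are removed, and high-frequency SNPs seen in the DM
   pileups (allele fraction ≥ 0.8, coverage ≥ 50) are corrected.
2. **Preprocessing.** Reads follow the layout `[3N][insert][6N][adapter]`;
   the two randomer blocks form a 9-nt UMI. Inserts are extracted, size- and
   quality-filtered, and PCR duplicates collapsed by (insert, UMI).
3. **Alignment.** Every co-optimal end-free placement of an insert within
   any reference at edit distance ≤ 3 is reported (multi-best-hit). BS
   libraries are aligned with an asymmetric C→T tolerance. Untemplated 5′
   additions by the RT are trimmed post-alignment. SAM import/export (NH,
   NM, MD tags) allows swapping in an external mapper.
4. **Clustering.** References differing at ≤ 3 positions merge
   (single-linkage); then any cluster whose reads are > 50 % co-optimal in a
   larger cluster is absorbed into it, iterated to a fixpoint.
5. **Quantification.** Multimappers are assigned uniformly at random among
   co-optimal hits with a seeded per-read hash (reproducible and
   order-independent). Cluster abundance = assigned reads per cluster /
   total mapped reads; per-reference deconvolution and anticodon-family
   tables (nuclear-only denominators) are also produced.
6. **Modification calling**, per cluster × canonical position:
   * misincorporation rate = Σ mismatching reads / Σ coverage over
     equivalent member positions (deletions count as mismatch; reads are
     compared to their own member reference, so intra-cluster variants are
     not mismatches);
   * RT-stop fraction at N = reads starting at N+1 / coverage at N+1
     (cDNA is synthesised 3′→5′);
   * C-retention = read Cs at reference Cs / (those Cs + read Ts at
     reference C or T); at a site with methylation fraction *m* and
     conversion efficiency *e* the expected retention is *m* + (1−*m*)(1−*e*);
   * mock-vs-DM classification: sites with mock rate ≥ 0.15 are
     `demethylation_sensitive` when the DM rate falls below half the mock
     rate, else `demethylation_resistant` (A34 sites with dominant G
     misincorporation are flagged inosine-consistent).
7. **Downstream analyses.** Genome context: mean number of predicted tRNA
   genes within ±5 kb of each expressed isodecoder's gene copies, compared
   between early- and late-expressed groups (≥ 4-fold increase defines
   "late") with a two-sided Mann–Whitney U test. Codon usage:
   expression-weighted codon frequencies over representative CDS, mapped to
   anticodon families through a wobble decoding table and correlated
   (Pearson, Holm–Bonferroni across families) with tRNA abundance.

A first-class synthetic-data generator (`tramseq.simulate`) produces
reference families, genomic layouts, and mock/DM/BS FASTQ libraries with
per-read ground truth; it is the test harness for every stage.

## Worked example

Simulate a three-family experiment — an m¹A58-like site (misincorporation
0.9, demethylation-sensitive) on the Phe-GAA family, a hard-stop site at
position 37 (stop probability 0.5) on Gly-GCC, and a 50 %-methylated m⁵C at
position 49 on Gln-CTG — then run the full pipeline:

```yaml
# example_spec.yaml
n_families: 3
copies_per_family: [2, 3]
n_reads: 6000
seed: 42
pcr_dup_rate: 0.2
mod_sites:
  - {target: fam0, label: "58", misincorporation_prob: 0.9, demethylation_sensitive: true}
  - {target: fam1, label: "37", stop_prob: 0.5, demethylation_sensitive: false}
m5c_sites:
  - {target: fam2, label: "49", methylation_fraction: 0.5}
```

```yaml
# run.yaml
output_dir: outdir
seed: 7
reference:
  nuclear_fasta: simdir/reference.fa
samples:
  - {name: mock1, library: mock, fastq: simdir/mock.fastq}
  - {name: dm1, library: dm, fastq: simdir/dm.fastq}
  - {name: bs1, library: bs, fastq: simdir/bs.fastq}
```

```bash
tramseq simulate example_spec.yaml -o simdir   # writes reference.fa + mock/dm/bs.fastq
tramseq run run.yaml
```

With 6 000 reads per library (seed 42) this prints `simulated 7 references
into simdir`, and the output directory contains:

* `clusters.tsv` — the 7 references collapse into 3 clusters (`Gln-CTG`,
  `Gly-GCC`, `Phe-GAA`), exactly the simulated families;
* `abundance.clusters.tsv` — DM fractions 0.440 / 0.276 / 0.283 (uniform
  per-reference truth: 3/7, 2/7, 2/7 ≈ 0.429 / 0.286 / 0.286);
* `modified_sites.tsv` — one site: `Phe-GAA  58  mock 0.888  dm 0.000
  demethylation_sensitive` (truth 0.9, erased by demethylation);
* `modification_profiles.tsv` — RT-stop fraction 0.522 at Gly-GCC position
  37 (truth 0.5, reads restarting at 38), and C-retention 0.481 at Gln-CTG
  position 49 (expected 0.5 + 0.5·0.01 = 0.505 at conversion efficiency
  0.99);
* `preprocess_stats.json` — 6 000 reads per library, 1 202 PCR duplicates
  removed in the DM sample (simulated duplication rate 0.2).

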