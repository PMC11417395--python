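# Methods

This note documents the models, conventions and numerical choices behind
`tramseq`, what the synthetic-data generator does and does not emulate, and
the design decisions taken where more than one reasonable convention
exists.

## Mature-reference convention

References are mature tRNA sequences. Genomic predictions are converted by
removing header-annotated introns (1-based inclusive spans), appending the
3′ CCA whenever the sequence does not already end in CCA (mitochondrial
sequences included), and prepending the His G₋₁ when the sequence does not
already start with G. The convention is declared rather than inferred from
any upstream database: modification positions are conventionally quoted in
mature Sprinzl coordinates (58, e2, …), so the reference must be the mature
form for position labels to mean what the literature means. The two
ambiguous cases — a genomically encoded CCA, and a His gene whose first
base is already G — resolve toward "do not duplicate", which can in
principle under-append; both are rare and harmless for position-level
statistics.

Identical mature sequences collapse into a single reference that records
all source gene ids. Reference ids are `AA-anticodon-k` (prefix `mt-` for
mitochondrial), numbering distinct sequences within an (origin, amino acid,
anticodon) family.

## Canonical (Sprinzl) numbering

Position labels are strings: `"1"…"76"` core positions, `"-1"` for His G₋₁,
letter-suffixed D-loop insertions (`"20a"`, `"20b"`), and `"e1"`, `"e2"`, …
for the variable arm between 45 and 46. A total order over labels
(`sprinzl_key`) places suffixed labels after their parent and e-labels
between 45 and 46.

Labels are transferred from a numbered multiple alignment shipped with the
package (`data/synthetic_numbering.sto` — a constructed, synthetic
miniature alignment of 21 backbone variants standing in for a curated
structural tRNA alignment; its Stockholm dialect stores labels in
`#=GF CANONICAL_LABELS` plus a `#=GC CANON` column mask). Each reference is
aligned not against a consensus string but against the alignment *profile*:
per column, the majority base over occupying rows and the column's
occupancy. Matching scores +2/−1; reference insertions are affine
(−6 open, −1 extend); skipping a column costs 0.5 + 4·occupancy. The
occupancy-weighted deletion cost is the load-bearing choice: sparse columns
(His −1, 20a/20b, the variable arm) are nearly free to skip, so ordinary
tRNAs pass over them, while long-armed tRNAs gain matches by occupying
them. A plain consensus-string alignment was tried first and mislabels long
variable arms whenever an arm base coincides with the consensus base at
position 46 — the wrong placement then scores strictly higher, so no
tie-break can repair it; the profile costs remove the ambiguity. Reference
positions matched to labelled columns inherit the label; positions matched
to unlabelled columns or inserted after 45 become e-labels; a single
unmatched leading base becomes −1; other insertions get letter suffixes of
the preceding label. The resulting map must be strictly increasing in
Sprinzl order and must place the annotated anticodon at 34–36, otherwise
the reference is rejected as unnumberable (as is any alignment scoring
below `min_score_frac` (default 0.5) of the perfect-match score).

## Reference filtering and SNP polishing

Only references reaching `min_rpm` (default 500 reads per million mapped)
in at least `required_samples` (default 1) demethylated samples are kept;
the threshold is inclusive. Filtering uses the DM libraries because
demethylation removes the coverage bias against heavily modified tRNAs.

In place of manual reference curation, a conservative automated polish
rewrites a reference base only when a single alternative base reaches
allele fraction ≥ 0.8 at coverage ≥ 50 in the pooled DM pileups.
Modification signatures rarely exceed 0.8 even unmapped-demethylated, and
the demethylation-sensitive ones are largely absent from DM data, so the
default threshold separates genuine SNPs from modification artefacts.
Substitutions only — canonical maps are preserved.

## Read layout and preprocessing

The sequenced read is `[3-nt randomer][insert][6-nt randomer][3′ adapter]`:
circularization places the RT primer's 5′ randomers in front of the insert.
The adapter is located by leftmost prefix match allowing 1 mismatch per 10
compared bases (minimum overlap 10). The concatenated 9-nt randomer pair is
the UMI. Defaults: insert length 20–300, mean insert Phred ≥ 20 (the
quality rule is a declared choice; only "quality filtering" is specified by
the protocol).

Deduplication keys on (full insert sequence, UMI) — alignment-free, chosen
over positional dedup because tRNA inserts are short and fully sequenced,
making the key robust to multimapping ambiguity. The representative is the
highest-quality read, ties broken by smallest read id, which makes dedup
deterministic and order-independent. UMI collisions (two molecules with
identical insert and identical 9-mer) are possible at high depth and are
the method's intrinsic undercount.

Untemplated 5′ additions (terminal transferase activity of the RT on
run-off cDNAs) are trimmed after alignment: up to `max_untemplated5`
(default 2) leading soft-clipped or mismatched bases are removed and the
read realigned; matching bases are never trimmed. A sequencing error in a
read's first base is indistinguishable from an untemplated addition and is
trimmed too — at error rate 1e-3 this contributes a ≈0.03 % false stop
signal at a reference's 5′-most positions, negligible against the 0.15
reporting threshold.

## Alignment

Reference sets here are at most a few hundred short sequences, so the
aligner is exhaustive over references with no index: per reference, the
best end-free placement (read fully aligned, reference overhangs free) is
found with edlib's bit-parallel banded DP at cutoff `max_edits` (default
3, mirroring the ≤ 3-difference clustering granularity so reads cross-map
within but rarely across clusters). All references achieving the global
minimum are reported, each with `n_best_hits` set. Within one reference,
ties keep the 5′-most start and, at equal start, the longest window — so
terminal bases map as mismatches rather than indels and read-start counts
are deterministic. Read bases inserted immediately 5′ of the mapped region
are recorded as soft-clips and feed untemplated trimming.

Bisulfite mode scores read T against reference C as a match while read C
against reference T stays a mismatch; implemented by lowercasing reference
Cs and declaring the equalities C≡c, T≡c (asymmetry verified in tests).
Observed read bases are preserved, so retention is counted from the pileup.

SAM export writes `=`/`X`/`I`/`D`/`S` CIGARs with NH, NM and MD tags plus a
`ZB` bisulfite flag; import resolves `M` runs against the reference, so any
external mapper's SAM can be substituted.

## Clustering

Stage 1: single-linkage transitive closure over pairs at edit distance ≤ 3
(edit rather than Hamming distance, so length variants are covered;
"any pair merges" implies transitivity). Stage 2: for cluster c,
shared(c→d) is the fraction of read instances with a co-optimal hit in c
that also hit d; if the maximum over larger clusters (by read count)
strictly exceeds 0.5, c merges into the argmax (ties → larger read count,
then lexicographic id), smallest clusters first, iterated to a fixpoint.
The ordering, tie-breaks, instance-counting and fixpoint iteration are
declared choices; termination is guaranteed because every merge reduces the
cluster count. Cluster ids join member identities (`Gln-CTG/TTG`,
`Lys-TTT_Sup-TTA`).

## Quantification

Each multimapping read is assigned to one co-optimal hit uniformly at
random, keyed on (seed, read id) through a cryptographic hash rather than a
shared RNG stream — the assignment is reproducible, independent of input
order, and stable under parallelism. Cluster fractions (reads per cluster /
total mapped) are the primary output; per-reference deconvolution drives
isodecoder-level views. Because co-optimal hits cannot span clusters more
than `max_edits` apart, within-cluster randomness cancels exactly in
cluster totals. Anticodon-family fractions exclude mitochondrial references
from numerator and denominator; a parallel view normalizes individual
mitochondrial tRNAs to the mitochondrial pool.

## Modification signatures

All profiles are per cluster × canonical label × sample, with cells under
`min_cov` (default 20) reported missing (never zero).

*Misincorporation*: mismatch counts and coverage are summed over equivalent
member positions first, then divided. A read is compared to its assigned
member reference, so intra-cluster sequence variants contribute no
mismatch. Deletions count toward mismatch (they are part of the RT error
signature); the choice is configurable.

*RT stops*: reverse transcription halting at position N yields a cDNA — and
read — whose 5′-most base maps to N+1, so stop(N) = read starts at N+1 /
coverage at N+1, aggregated per label over members. Trimming untemplated
additions precedes stop counting.

*C retention*: per single reference, retention at reference Cs is
C/(C+T) over read bases. The cluster rule additionally counts read Ts
mapped to member-reference Ts in the denominator; at labels where members
disagree (C in one member, T in another) this deflates retention — a known
caveat of the clustered view, reproduced exactly by a hand-computed
fixture in the tests. Read bases other than C/T enter neither count.

*Classification*: sites with mock misincorporation ≥ `min_rate` (0.15) in
at least one sample are reported; mean DM rate < `drop_frac` (0.5) × mean
mock rate → demethylation-sensitive (m¹A/m¹G/m³C/m²₂G candidates),
otherwise resistant (editing/acp³U/bulky candidates); resistant A34 sites
with dominant G misincorporation are flagged inosine-consistent. Multi-
sample summaries average per-replicate rates unweighted.

## Downstream analyses

*Genome context*: per gene, the number of predicted tRNA genes whose
interval midpoint lies within [start − 5 kb, end + 5 kb) — midpoint
membership and self-inclusion are declared (and configurable) conventions;
per isodecoder, the mean over identical gene copies. Isodecoders need a
mean mapped-read fraction ≥ 0.002 at either stage; a ≥ 4-fold increase
(late/early) defines the late group. Groups are compared with a two-sided
Mann–Whitney U (normal approximation with continuity and tie correction,
via scipy).

*Codon usage*: freq(c) = Σ_g count_g(c)·w_g / Σ_g codons(g)·w_g over one
representative CDS per gene (primary-isoform table when provided, longest
CDS otherwise); non-multiple-of-3 or internal-stop CDS are logged and
skipped. Frequencies sum to 1 and are invariant to rescaling the expression
weights. The decoding table implements Crick wobble with inosine at A34
(G34→{C,T}, T34→{A,G}, C34→{G}, A34→{T,C,A} codon third positions) and can
be replaced by an edited TSV. Pearson correlations are computed per stage
across anticodon families and per family across stages; time-course
p-values are Holm–Bonferroni-adjusted across families (statsmodels).
Correlations over fewer than 3 points are reported missing.

## Synthetic data

The generator defines the study conditions for all tests. Families are
built from a canonical 76-nt cloverleaf backbone (anticodon at 34–36,
T54/U55/C56, A58, discriminator + CCA): family centres receive
`cross_family_min_diff + 2·max(intra_family_diffs)` substitutions at
mutable positions and are rejection-sampled (bounded retries) until centre
distances guarantee that every cross-family copy pair differs by at least
`cross_family_min_diff` (default 6) edits while intra-family pairs stay
within `max(intra_family_diffs)` (default 3). Positions named by declared
modification sites are excluded from mutation so the sites exist in every
copy. Structural variety (D-loop insertions, an 11-nt variable arm) cycles
deterministically across families. Gene copies of repetitive families are
laid out as tandem arrays (300 bp spacing, within a 10 kb window); all
other copies are ≥ 50 kb apart.

Reads are simulated per molecule: reference drawn by abundance; for BS
libraries, per-molecule methylation then conversion (unmethylated C→T with
probability *e* = 0.99 by default); then an RT walk 3′→5′ over the
molecule's sites — stop with `stop_prob` (read then begins one base 3′ of
the site) else misincorporate with `misincorporation_prob` (random
non-reference base, or a forced base for inosine-like sites). Events
compose multiplicatively along the walk: a 5′ site is only observed by
molecules not already truncated, which is what makes downstream
stop-fraction denominators correct. DM (and BS, which is
demethylated before conversion) zeroes both probabilities at
demethylation-sensitive sites. Uniform sequencing errors (default 1e-3 per
base) follow; run-off (non-truncated) cDNAs then gain one untemplated 5′
base with probability 0.7, modelling terminal transferase activity at the
template end — truncated cDNAs, where the RT dissociates at the
modification rather than running off, do not. Reads are wrapped in the
library layout with random UMIs; PCR duplication emits
`round(n_reads·pcr_dup_rate)` exact copies of uniformly drawn molecules, so
the pre-PCR molecule count is exact by construction. The same seed yields
byte-identical FASTQ.

Not emulated: quality-score error models (qualities are constant),
polymerase-specific indel spectra, ligation sequence bias, tRNA fragments,
and position-dependent error rates. Passing tests therefore demonstrate
correctness of the estimators under the stated generative model, not
robustness to every artefact of real libraries.

## Pipeline, determinism and problem sizes

The `run` pipeline executes build-ref → preprocess → DM-based filtering and
polishing → final alignment (per library type) → clustering →
quantification → modification calling, with optional genome-context and
codon stages; any stage failure is reported with its stage name. Given
identical configuration, inputs and seed, all TSV outputs are
byte-identical; a rerun whose manifest hash (configuration + input digests
+ package version) is unchanged is skipped outright. The run manifest
echoes every parameter and the seed. Unknown configuration keys are
rejected before any compute. Processing is single-threaded; the `threads`
field is recorded in the manifest for forward compatibility.

Test and acceptance runs use simulations of 3–50 thousand reads over 1–10
families (≥ 5 000× coverage where estimator error bounds are asserted),
sizes at which every asserted tolerance is several standard errors wide
while the whole suite stays fast.

## Known limitations

* Untemplated-addition trimming cannot distinguish an addition that
  happens to match the reference from genuine read-through; stop fractions
  are unaffected only because additions occur on run-off products.
* The cluster C-retention rule deflates retention at member-variant
  positions (see above); the per-reference rule does not.
* Abundance uses one seeded assignment draw; an averaging mode over
  multiple draws is available in the quantifier but not the default.
* The SNP polish is an automated approximation of manual curation; sites
  with allele fractions between modification-level and fixed (0.5–0.8) are
  deliberately left unpolished.
* RT-error magnitudes are lower bounds on modification stoichiometry in
  real data; the simulator treats site probabilities as exact, so recovery
  tests validate the estimators, not the chemistry.
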