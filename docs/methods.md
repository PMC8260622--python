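# Methods

`utrkit` implements the computational loop of a 5′ UTR engineering platform:
quantify translation efficiency (TE) of natural transcripts, standardize
their 5′ UTRs into a fixed-length screening library, learn a sequence →
expression surrogate, evolve synthetic UTRs against that surrogate with a
genetic algorithm, and analyze the FACS-bin sort-seq screen that measures
the library. This note records the models, the parameters that matter, and
the design choices made where the design was genuinely open.

## Translation efficiency

TE is the ratio of ribosome-footprint abundance to mRNA abundance,

    TE = RPF RPKM / RNA RPKM,    RPKM = count / (length/10^3) / (total/10^6),

computed per transcript from pre-tabulated Ribo-seq and RNA-seq counts (read
alignment and P-site handling are out of scope). TE is invariant to joint
library-size changes and is left undefined (NaN) when the RNA RPKM is zero;
no pseudocount enters the ratio. Instead, transcripts with fewer than 10 raw
reads in either assay (configurable) are flagged by the coverage filter —
raw-count thresholds are depth-dependent but conservative, and pair naturally
with RPKM reporting. RPKM uses the full transcript length, matching the
per-transcript TE definition.

## Library standardization

The library fixes the diversity region at 100 bp (the practical ceiling of
array-based oligo synthesis). Longer UTRs contribute two variants — the
5′-most and 3′-most 100 bp; shorter ones are padded at the 5′ end with
repeats of the structure-free CAA motif, in two versions whose pads are
phase-shifted by one nucleotide. Padding sits at the 5′ end so the native
sequence stays adjacent to the Kozak/CDS junction; both padded versions are
emitted and the caller may filter. Inputs shorter than 3 nt are rejected.

Every ATG is removed by mutating one of its three nucleotides, chosen
uniformly among the nine single-nucleotide substitutions, rejecting and
redrawing any draw that does not strictly reduce the total ATG count.
Substituting C at the T position always reduces the count (C occurs in no
position of ATG, so no new ATG can include the changed site), which makes
the rejection loop provably terminating even for overlapping or adjacent
start codons. Repair is deterministic given the generator state.

Natural panels are chosen per context — top/bottom by TE for the two cell
lines, top by TE for muscle, top by mRNA level for the muscle expression
panel — with defaults (1505, 937), (1692, 756), 1831 and 1693, summing to
8414 natural members; the two designed sets (2388 high-TE designs, 1198
lightly evolved test variants) bring the library to 12,000. Ties are broken
by lexicographic transcript id so panel selection is reproducible; top and
bottom panels are disjoint within a context. Synthesis oligos are
`20-nt flank + 100-nt UTR + 20-nt flank` (140-mers); combinatorial members
join two standardized UTRs with a CAACAA linker (206 nt).

## Sequence features

A UTR is featurized together with the first 15 bp of the downstream CDS (the
start-codon neighborhood): k-mer frequencies for k ∈ {1,2,3} by default (84
features, configurable up to k=6), a folding-energy proxy, the UTR length,
and upstream-ORF counts. Frequencies are window-normalized so feature scale
is length-invariant. k-mers and folding energy are computed on the
UTR+context concatenation; length and uORF counts on the UTR alone (the CDS
context deliberately contains the main start codon, which is not an uAUG).
An uAUG is any ATG occurrence (overlaps counted); a uORF additionally
requires an in-frame TAA/TAG/TGA entirely within the UTR.

The default folding engine is a Nussinov-style maximum base-pairing dynamic
program (Watson–Crick plus GU wobble, minimum hairpin loop of 3 nt) scored
at −1 kcal/mol per pair. It is a structure-propensity proxy, not a
thermodynamic minimum free energy: more negative means more pairable
structure, which is the monotone signal the surrogate consumes. Any callable
mapping an RNA string to a non-positive float can be plugged in as an
alternative engine. The DP is O(n³) and numba-accelerated with an identical
pure-Python fallback; it is verified against exhaustive structure
enumeration for sequences up to 14 nt.

The feature schema (names, order, engine) is hashed and stored with every
trained model; prediction refuses mismatched schemas.

## Surrogate models

For each (context, target) pair a regressor maps features to TE or mRNA
level. Targets are log-transformed, `log2(y + 1e-3)`, before fitting
(toggleable) because TE and RPKM are right-skewed; predictions are
back-transformed. Evaluation is 5-fold cross-validation on a seeded shuffle
of row indices (the assignment is stored with the model); the metric is the
Spearman correlation with average ranks, and a fold in which the model
predicts a constant is scored 0 (no ranking information). The final model is
refit on all rows.

Four families are provided: a random forest (500 trees — the classic R
default — fixed for determinism), an elastic-net linear model (internal
regularization path, the glmnet-style default), a single regression tree,
and an RBF support-vector machine; the linear and SVM models are fit on
standardized features. `compare_models` ranks families under shared fold
assignments. Predicted protein expression is the product
`predict_mrna × predict_te`.

## Genetic algorithm

Each run draws 100 standardized natural UTRs as the initial population and
evolves them for up to 50 generations: fitness-ranked tournament selection,
single-point crossover (rate 0.5), per-nucleotide substitution mutation
(rate 0.02) followed by AUG repair, with the best 2 sequences carried over
unchanged (so the best-fitness trajectory is non-decreasing). Fitness is
memoized per sequence; it is the surrogate's predicted TE or predicted
expression, on the scale used for that run. From all sequences evaluated in
a run, the top 5 with pairwise Hamming distance ≥ 5 are kept, restricted to
those at least 0.05 fitness units above the best initial seed — a constant
fitness therefore keeps nothing.

The variation operators are not uniquely determined by the problem; the
package uses standard choices, all configurable. Tournament size defaults
to 3: with size 2 the selection differential only balances the mutation
load (2 expected substitutions per offspring) at roughly 0.86–0.92 of the
achievable optimum on a GC-content toy objective, whereas size 3 reliably
reaches ≥ 0.95 of the optimum within the 50-generation budget. A
"two-generation" mode (max_generations=2, relaxed improvement threshold,
no crossover) produces lightly mutated variants that stay within a few
substitutions of their seeds, for building model-validation sets.

## Screen analysis

Reads are assigned by locating the exact 20-nt left flank, extracting the
100-nt insert, requiring the exact right flank, and looking the insert up in
the library — exact by default, or within `max_mismatch` substitutions when
the match is unique. For a designed fixed-length library this dictionary
matching is exact and self-contained; no external aligner is involved.
Every read is either assigned to one member or counted unassigned.

Counts are normalized with median-of-ratios size factors: the reference is
the per-member geometric mean across samples (members with any zero
excluded), and each sample's factor is the median of count/reference. The
median is taken over the raw ratios, per the definition; this differs from a
log-space median only in tie-averaging when the member count is even. Note
that jointly rescaling all samples leaves the factors unchanged (the
geometric reference scales with the data); normalized counts are relative,
not absolute.

Per-bin enrichment over the unsorted background is summarized two ways:

* a descriptive log2 ratio, `log2((n_bin + 0.5)/(n_unsorted + 0.5))`
  averaged over replicate pairs (pseudocount configurable);
* a negative-binomial Wald test. Counts are modeled as
  NB(μ = size factor × q_condition, α_condition) with
  Var = μ + αμ². The log2 fold change is `log2(q_bin/q_unsorted)`; its
  standard error comes from the delta method,
  Var(log q̂) = (1/n²) Σ_s (1/(q f_s) + α).

Dispersion is estimated per member and **per condition** by method of
moments, then shrunk in log space toward an abundance-binned trend with
weight df/(df+4) (df = replicates − 1); members without a valid moment
estimate take the trend. The trend is the ratio of summed moment numerators
to summed denominators within base-mean quantile bins (≥ 25 members per
bin), interpolated in log-log space — averaging raw moments avoids the
selection bias of discarding negative estimates. Dispersion is deliberately
not pooled across conditions: a narrow sorting gate holds only a handful of
cells per ordinary member, so its cell-sampling dispersion is an order of
magnitude above the unsorted background (α ≈ 0.8 vs ≈ 0.02 in simulation),
and a shared estimate is miscalibrated in both directions. Reported
standard errors were checked against the empirical sampling SD of the log2
fold change over repeated simulated screens (ratio 1.0–1.15). Members with
zero counts everywhere, or a zero condition mean, yield NA rows excluded
from testing; the Wald p-values are Benjamini–Hochberg adjusted per bin.

A hit must show fold change ≥ 1.5 **and** adjusted p < 0.05 in all three
top bins; the log2-ratio-above-0.52 line is reported alongside as a
diagnostic, not as part of the call. Replicate agreement is the Pearson
correlation of log2 normalized counts (+0.5) between the two replicate
lines per bin. Category enrichment among hits is
`100 × (hit rate in category)/(hit rate outside)`, undefined (NaN) when a
denominator is zero.

## Synthetic data

The simulators generate every input with known truth, serialized alongside.

* **Transcriptomes** — UTRs of uniform random composition, lengths uniform
  on [30, 300] nt, plus an ATG-led CDS (≥ 15 nt).
* **Ribo/RNA counts** — true log2 TE is a planted linear function of 3-mer
  frequencies plus Gaussian noise; the default weight scale gives the
  planted signal an SD of ~1 log2 unit across a cohort (natural TEs span a
  few fold) and the noise SD is set to half the signal SD (2:1
  signal-to-noise). mRNA levels are lognormal (1 log2-unit SD). Counts are
  gamma-Poisson (NB) with dispersion 0.1 at a configurable depth, means
  proportional to mRNA×length (RNA) and mRNA×TE×length (RPF).
* **Screens** — each cell carries one uniformly assigned member
  (single-copy, as recombinase integration guarantees); log fluorescence is
  Normal(log strength, 0.5) — a ~50% expression CV, typical for a
  single-copy reporter; cells are ranked and the top 2.5%/2.5–5%/5–10%
  fractions define the bins with floor rounding, the unsorted bin being all
  cells; reads are multinomial from bin compositions at a fixed per-sample
  depth. The default sorted population is 500 cells per library member:
  sorting happens after a week of expansion from the ≥ 25-fold founder
  coverage, and at this scale the simulated between-replicate correlations
  (r ≈ 0.89–0.94 per bin for a library with 1 log2-unit strength spread)
  match the reproducibility reported for recombinase-mediated screens;
  founder-scale populations (< 25× library) trigger a warning. FASTQ output
  reconstructs flanked 140-nt reads.

What the simulators do **not** model: PCR amplification bias and duplicate
reads, sequencing errors (off by default; an error rate can be exercised
through mismatch-tolerant matching), sequence-dependent expression in the
screen (strengths are assigned, not computed from sequence), multi-copy
integration or position effects (the noise sources recombinase integration
removes), and UTR-length biology beyond the planted k-mer signal. Passing
tests therefore demonstrate that the pipeline recovers what it is pointed
at under a faithful noise model — not that the biological effect sizes of
any particular screen will reproduce.

## Problem sizes and numerical choices

The test and acceptance runs use: TE recovery at n=500 transcripts and 10⁶
reads per assay; surrogate cross-validation at n=2000 transcripts and
2×10⁶ reads (so measurement noise does not dominate the planted signal);
GA runs at the default population 100 × 50 generations; screens at a
1000-member library, 2 replicates, 2×10⁵ reads per sample, with 50 members
planted at 2-fold strength. Dispersions are floored at 1e-8; p-values are
clipped into (0, 1]; all stochastic steps consume a single seeded
`numpy.random.Generator`, and identical configs (seed included) reproduce
outputs byte-for-byte, CLI included.

## Known limitations

The folding proxy ignores thermodynamic stacking and pseudoknots; the
dispersion shrinkage is a moment/trend approximation, not the full
empirical-Bayes machinery of DESeq2; the surrogate feature set is
configurable but makes no claim to match any particular published feature
ranking; and hit calling assumes exactly the four-bin sort layout
(top 2.5 / 2.5–5 / 5–10 / unsorted).
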