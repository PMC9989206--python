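# Methods

`discomics` reimplements, as a tested library + CLI, the computational
pipeline used to compare engineered cartilage discs made from articular
chondrocytes (AC) and bone-marrow mesenchymal stromal cells (MSC), three
donors per cell type: isomiR-aware small-RNA quantification, two-group
negative-binomial differential expression, label-free proteome statistics,
and miRNA-target / differential-protein integration.

## Reference build (`mirbase_reference`)

Hairpin and mature FASTA files in the miRBase dialect are species-filtered
by id prefix and normalized to an uppercase DNA alphabet (U→T) so that
sequencing reads compare directly against the reference. "Overlapping"
hairpin entries are removed by exact containment: entries are processed in
order of decreasing length (ties by id), and an entry is dropped iff its
sequence is identical to or a contiguous substring of an already retained
one, forward strand only. This is the minimal deterministic reading of
"sharing identical or overlapping sequences"; partial prefix/suffix overlaps
are *not* removed, and the predicate is isolated in `dedup_hairpins` so an
alternative reading can be swapped in. The procedure is idempotent, the
retained set contains no mutually contained pair, and it matches an O(n²)
all-pairs oracle in the tests.

Mature miRNAs are located on retained hairpins by exact substring search
(every occurrence yields a locus; repeated occurrences within one hairpin
keep the leftmost). Genomic GFF3 coordinates are deliberately not used —
substring location avoids genome-coordinate lifting and keeps the reference
self-contained. The seed of a sequence is nucleotides 2–8 (1-based), the
primary determinant of target recognition. Coordinates are 0-based
half-open internally; SAM output is 1-based.

## Read preprocessing (`smallrna_reads`)

Reads are kept iff their mean Phred quality is ≥ 20 (inclusive). The 3'
adapter (required parameter — kit adapters differ; the synthetic generator
uses the Illumina small-RNA adapter TGGAATTCTCGGGTGCCAAGG) is located at the
leftmost read position where an adapter prefix of ≥ 8 nt matches with
mismatch rate ≤ 0.125; untrimmed reads are dropped by default. Inserts
outside 16–30 nt are discarded, and identical inserts are collapsed to
unique sequences with counts, ordered by count descending then sequence.
UMI-carrying kits place the UMI 3' of the adapter, so adapter trimming
already discards it; no UMI deduplication is performed. All parameters are
config-exposed; the defaults are conventional for miRNA-seq.

## Mapping (`hairpin_mapper`)

Ungapped, forward-strand alignment with at most `v` mismatches over the full
read (default v = 2), no indels and no quality weighting — `-v`-mode
semantics of the classic short-read mappers. Among all hits the
minimum-mismatch stratum is taken; ties are broken deterministically by
(hairpin id, then offset) instead of the original tools' pseudo-random
choice, so reruns are reproducible. Candidates come from an exact k-mer
index (k = 10); because the pigeonhole guarantee needs reads of ≥ (v+1)·k
nt, shorter reads — i.e. miRNA-length reads — are scanned exhaustively with
a vectorized Hamming computation, so the result always equals the
brute-force minimum-Hamming search (property-tested). Each collapsed read
is assigned to at most one hairpin, so counts are conserved.

## isomiR quantification (`isomir_quant`)

A mapped read is attributed to a mature locus iff it starts *and* ends
within ±2 nt (the "bleed" window) of the annotated start/stop; among
multiple qualifying loci the one minimizing |Δstart|+|Δend| wins (ties: 5p
arm). The counted feature is the pair (mature id, seed of the **read**):
5'-shifted or seed-mutated isomiRs therefore form distinct features with
their own seeds, while 3'-only variants share the canonical seed and are
counted together with the canonical form — variants sharing a seed are
expected to repress the same targets. A feature is "canonical" iff its seed
equals the locus seed; differential features whose seed differs are reported
as isomiRs.

Detection filtering keeps features whose mean RPM across all samples is
strictly greater than 10 (per-sample "min" and "any" rules are options; the
original study does not state which rule was used). Library size defaults
to the total reads assigned to features, which is recomputable from the
matrix itself.

## Count differential expression (`count_de`)

The classic single-factor exact-test workflow for two groups of NB counts,
variance μ + φμ²:

1. **TMM normalization** — reference sample = the one whose upper-quartile
   count rate is closest to the mean; per-sample factor = precision-weighted
   mean of M-values after trimming 30% of M and 5% of A on each side,
   rescaled to geometric mean 1.
2. **Common dispersion** — counts are quantile-adjusted to pseudo-counts at
   the geometric-mean library size (normal/gamma-averaged quantile mapping,
   group-wise NB rates fitted by Newton iteration), and the conditional NB
   log-likelihood (given per-group totals) summed over features is maximized
   on the δ = φ/(1+φ) scale, with two equalize/estimate rounds. Features
   with total count ≤ 5 contribute almost no curvature and are excluded from
   the likelihood. Tagwise dispersion is deliberately omitted: n = 3 per
   group carries little per-feature information.
3. **Exact test** — per feature, conditional on the total of the equalized
   group sums; the two-sided p is the sum of conditional probabilities of
   all splits at most as probable as the observed one (the "small-p" rule,
   which differs from tail-doubling in asymmetric cases). φ = 0 reduces to
   the conditional binomial: a (0, 10) split at equal library sizes gives
   p = 2·2⁻¹⁰ = 0.001953125.
4. **BH FDR** and calling: DE iff linear |FC| ≥ 2 and FDR ≤ 0.05 (both
   inclusive). log2FC (group 2 vs group 1) uses prior-count-moderated
   (0.125) group-mean pseudo-counts so on/off features get finite values;
   these moderated values feed the top-N ranking downstream.

The implementation reproduces the classic Bioconductor path closely (TMM
factors to ~1e-6, dispersion to ~0.1%, small-p exact-test p-values at
median relative difference ~1e-4 on a 300-feature matrix; cross-checked
against edgeR via Rscript in the test suite). Exact scale invariance under
multiplying one sample by a constant does **not** hold to machine precision:
the common library size (geometric mean) moves, and the quantile adjustment
is nonlinear, so individual p-values wobble at the discretization level
while DE calls and the ordering of evidence are stable — asserted as such.

## Proteome statistics (`proteome_de`)

MaxQuant-style protein-group tables: flagged contaminants are removed,
intensities log10-transformed, and proteins kept iff they have ≥ 2 valid
values out of 3 in at least one group. Proteins valid in only one group
(after the filter, so with ≥ 2 values there) are **on/off** qualitative
differences. For the quantitative comparison, missing values are imputed
column-wise from Normal(mean − 1.8·SD, (0.3·SD)²) of the observed values —
the standard down-shifted-normal convention for intensity-dependent (MNAR)
dropout; width/down-shift are the common defaults and are config-exposed.

The two-sample test uses a pooled-variance t statistic (optional s0 offset,
default 0) whose null distribution pools all distinct balanced label
reassignments other than the observed one — 9 of the C(6,3)/2 = 10 distinct
splits for 3 vs 3. Estimated FDR at cutoff c = (mean permuted exceedances) /
(observed exceedances), capped at 1 and made monotone; significant proteins
additionally need ≥ 2-fold difference (|Δlog10| ≥ log10 2). Per-protein
permutation p-values use the add-one convention, so the attainable floor is
1/10 — the granularity limit of a 3 vs 3 design. Two consequences worth
knowing: (i) moderate real effects (e.g. 4-fold at realistic noise) can sit
just above the q = 0.05 boundary because the q-value lattice is coarse;
(ii) effects surviving MCAR dropout are weakened by imputation, since
imputed values are drawn from the down-shifted global column distribution.
Both are faithful to the Perseus-style procedure, not artifacts of this
implementation.

Targeted (PRM) tables are summarized as: per peptide and sample, the mean
of the 3 most intense fragment-ion areas; per protein, the mean across
peptides; then a plain two-sided equal-variance t-test, significance at
p ≤ 0.05, with p = 1 for degenerate all-equal rows.

## Target integration (`target_integration`)

One 3'UTR per gene: genes with a single annotated UTR keep it; genes with
several are restricted to transcript support level 1–2 and the longest UTR
wins (ties to the smallest transcript id). Prediction tables (miRAW-like:
per-pair probability and duplex MFE) are filtered to probability ≥ 0.99995
and MFE ≤ −15 kcal/mol. The MFE rule as printed in the source protocol
("MFE < −15 … removed") would discard *strong* duplexes; conventionally MFE
thresholds discard weak ones, so the default retains MFE ≤ −15 and the
literal behavior is available via `literal_mfe=True`.

Per direction, the top 10 DE miRNAs ranked by |moderated log2FC| (ties:
smaller FDR, then label; isomiRs and canonical forms compete in one ranking)
are paired with the DE proteins moving the *opposite* way: a protein counts
as targeted iff its gene is hit by ≥ 1 filtered prediction from the panel.
Coverage = targeted / all DE proteins in that direction, with unmapped
proteins kept in the denominator; percentages are rounded half-up.

## Synthetic data (`synthetic_data`)

All generators are pure functions of their seed. Defaults encode the study
conditions: 3 vs 3 libraries; library sizes ~ Uniform(0.8, 1.2)·10⁶ (typical
miRNA-seq depth); NB counts with common dispersion 0.1 and log-uniform
abundances spanning ~5–500 reads per million per feature; planted effects
|log2FC| = 2 on a 10% feature subset; reads drawn from planted mature loci
with a mixture of (Δstart, Δend) offsets, constant Q30 qualities and the
Illumina small-RNA adapter; protein tables with log10 intensities
~ N(6.5, 0.6) across proteins, replicate noise SD 0.15, 8% MCAR dropout and
a planted on/off (MNAR) subset; prediction tables whose planted edges pass
both filters while decoys straddle them.

What the generators do *not* emulate: hairpin secondary structure,
non-templated tailing, sequence-composition bias, UMI structure,
retention-time/spectral detail, and correlated protein complexes. Passing
tests therefore demonstrate the correctness of the algorithms under the
stated statistical model, not end-to-end fidelity to any particular
instrument or library kit; the accession-scale counts of the original study
additionally depend on unpublished preprocessing parameters and an external
neural-network predictor's outputs, and are out of scope.

## Problem sizes and numerical choices

The test suite and `scripts/acceptance.py` use desk-scale instances chosen
to estimate each property tightly while staying fast: 1,000 reads × 50
hairpins for the mapper oracle; 200-sequence pools for the dedup oracle;
5,000 features × 20 seeds (tests) or 5 seeds (script) for null type-I
behavior; 2,000 features for dispersion recovery; 1,000-protein tables (20
null seeds) and 2·10⁵-draw imputation-moment checks; planted 46-of-72 and
64-of-84 coverage instances. Dispersion optimization is bounded on
δ ∈ [10⁻⁴, 100/101] (xatol 10⁻⁴); exact-test enumeration is segmented at
~2·10⁶ flat states to bound memory; probability comparisons use a 1+10⁻¹²
relative guard against floating-point ties; degenerate inputs (empty FASTA,
all-zero samples, <2 observed values per column, empty protein lists) raise
or return documented values rather than propagating NaN.
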