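# Methods

## 1. Conversion calling

A sequenced molecule transcribed during the 4sU window carries 4sU in place
of some uridines; reverse transcription reads these as transcript-sense
T-to-C substitutions. For a gene on the genomic minus strand the same event
appears as A-to-G in genome coordinates, so calling is strand-aware: reads
are tallied in transcript sense throughout.

Per read, every aligned position whose reference base is a transcript-sense T
and whose base quality is at least `min_qual` (default Phred 20) counts as a
covered T site; a site where the read base is the transcript-sense C counts
as a conversion. Mismatches come from the alignment's MD tag (or directly
from a reference sequence when no MD tag is present). A molecule is called
**labeled** when it shows at least `k_min` conversions (default 1; `k_min=2`
is supported as a robustness setting and detection is monotonically
non-increasing in `k_min`). For UMI data, conversions are unioned across all
reads of a UMI before classification.

**SNV blacklist.** A genomic variant at a T position mimics labeling in every
read. Positions are blacklisted when coverage ≥ `snv_min_cov` (default 10)
and apparent conversion fraction ≥ `snv_min_frac` (default 0.25) — real
labeling at ~1% per-thymine conversion cannot reach such fractions.
Positions with coverage below the threshold cannot be classified; they are
reported separately and masked only in `strict_low_coverage` mode.

**Conversion rate** for any grouping (global, per gene, per cell) is pooled:
Σ conversions / Σ covered T sites. Groups with zero covered sites are
reported missing (NaN), never as 0.

## 2. Detection model

With per-thymine conversion probability `p_c` and `n_t` thymines per read,
a labeled molecule is detected (`k_min=1`) with probability
`p_detect = 1 − (1 − p_c)^{n_t}`; for higher `k_min` it is the binomial
survival function. At the study regime `p_c = 0.037`, `n_t = 50`, the
false-negative rate is 1 − p_detect = 15.18%, i.e. roughly one in seven
labeled molecules shows no conversion at all. When `n_t` varies, the model
accepts a (values, weights) distribution and takes the expectation; a
truncated-Poisson helper covers the case where reads are required to contain
at least one T. `p_c` itself is estimated from observed conversion counts of
labeled reads by zero-truncated binomial maximum likelihood (the zero class
is unobservable because zero-conversion reads are classified unlabeled).

## 3. Half-life kinetics

For a gene at steady state, the labeled fraction after labeling time *t*
follows the saturation curve

    f(t) = α (1 − e^(−λt)),    τ½ = ln 2 / λ.

The plateau α < 1 absorbs detection losses (the ~15% FNR above) and
incomplete 4sU uptake, which keeps λ — and therefore τ½ — unbiased. Fits use
`scipy.optimize.least_squares` with:

- parameterization in log λ (with α free on [0, 1] or fixed at 1), bounds
  from `tau_bounds_h` (default 0.5–48 h);
- weights √n per point (n = molecules behind each ratio), so deep timepoints
  dominate appropriately; the reported r² is weighted;
- 5 deterministic multi-starts on a log-spaced λ grid, tight tolerances
  (`xtol=ftol=gtol=1e-14`), best solution by cost;
- fits at a τ bound are flagged `converged=False`; genes with fewer than 4
  points or fewer than 3 distinct times are flagged unfittable rather than
  fitted badly;
- a delta-method 95% CI on τ from the least-squares Jacobian.

Only the 0.5–12 h timepoints enter the fit by default (`max_time_h=12`): a
single 4sU injection is exhausted by ~24 h, so later timepoints violate the
constant-labeling assumption. The summary reports genes with r² > `r2_min`
(default 0.7) and τ strictly inside the bounds.

## 4. Injury response

The response statistic for each gene compares newly made RNA between an
injured and a sham condition within one cell type:

1. **Pseudo-bulk**: sum labeled counts over the cell type's cells, per
   condition.
2. **Background correction**: sequencing errors falsely label some unlabeled
   molecules. The per-thymine error floor ε̂ is the median rate of the 11
   non-T>C substitution types (transcript sense); the expected false-labeled
   count is U · (1 − (1 − ε̂)^n̄ₜ) with U the unlabeled pseudo-bulk, and is
   subtracted with a floor at zero.
3. **Normalization + pseudocount**: l̂ = 10⁴ · c / L + π, where L is the cell
   type's total corrected labeled counts and π = 1 by default. Adding the
   pseudocount *after* depth normalization makes the ratio exactly invariant:
   scaling all labeled counts by a constant scales numerator and denominator
   of c/L by the same power of two (IEEE multiplication by a common factor
   cancels bit-exactly in the division), so R is bit-identical under labeled
   depth changes, and unlabeled-pool inflation never reaches l̂ at ε̂ = 0.
4. **Ratio**: R = l̂_injured / l̂_sham, reported with log₂ R.

Because only labeled counts enter, R is independent of pre-existing unlabeled
RNA by construction — the property the experimental design is built around.

**Inference.** Condition labels are permuted across the cell type's cells;
the p-value uses the add-one estimator
p = (1 + #{|log₂ R_null| ≥ |log₂ R_obs|}) / (1 + n_perm), with a 1e-12
tolerance on the comparison so exact ties are never dropped by floating-point
noise. When the number of distinct assignments is small the test enumerates
them exhaustively; otherwise Monte Carlo permutations are evaluated in
vectorized batches (indicator-matrix products), which keeps 1000 genes ×
1000 permutations under a second. Genes whose summed corrected labeled
counts fall below `min_count` (default 5) are reported with `tested=False`
rather than silently dropped. P-values are BH-corrected across tested genes;
`responsive` requires q < 0.05 and log₂ R > 1.

**Pathway layers.** A gene-set "layer" is scored per cell as the percent of
the cell's total counts falling in the set, summarized as mean ± SEM per
group, with warnings (not errors) for genes absent from the matrix.

## 5. Simulators: fidelity and limits

All generators take a single integer seed, use one `numpy` Generator, and are
byte-reproducible. Defaults are the study conditions the pipeline targets;
they are not tuning knobs.

**Read-level bulk time course** (`simulate_bulk_timecourse`): 50 genes with
log-uniform half-lives on 0.5–48 h, timepoints 0.5/1/3/6/12 h × 3
replicates, Poisson molecule counts (mean 100), 100-nt reads, per-thymine
conversion probability 0.037, uniform per-type sequencing error 2×10⁻⁴,
optional planted SNV positions (which convert in every read) and optional
4sU exhaustion (effective labeling time (1 − e^(−μt))/μ). Each gene's
reference contains an *exact* transcript-sense T count of
round(gene_len · n̄ₜ / read_len) at random positions, so the nominal n̄ₜ = 50
thymines per read holds without sampling drift and the analytic FNR applies
exactly. Limits: reads are gapless and uniquely assigned to genes; base
qualities are constant; no positional error profile.

**Count-level time course** (`simulate_timecourse_counts`): binomial
labeled/unlabeled counts straight from the saturation curve — the minimal
generator for testing the fitter in isolation.

**Paired single-cell injury** (`simulate_sc_injury`): 3 cell types ×
100–200 cells per condition, ~7 h labeling window, labeled molecule counts
Poisson around abundance · (1 − 2^(−t/τ)), thinned by the truncated-Poisson
detection probability; injured-condition transcription of 25 induced genes
is multiplied by 4 in macrophage-like cells only. Baseline abundance follows
the steady-state identity *abundance ∝ k · τ* (gamma-distributed
transcription rates k, renormalized to the configured mean), so long-lived
transcripts dominate the pre-existing pool and the emergent labeled fraction
at 7 h lands near 20–25% — the regime real tissue shows, driven by abundant
long-lived transcripts. The per-condition unlabeled pools can be scaled
independently (default analysis uses 1.5× in injured) precisely so that the
claimed independence of R from old RNA is exercised, not assumed. Limits:
no ambient RNA, no doublets, no UMI collisions; detection is modeled as a
single thinning factor rather than per-read sequencing.

## 6. Numerical and I/O conventions

- One `np.random.default_rng(seed)` per simulation; derived seeds are drawn
  below 2³¹.
- TSV outputs carry a `# slamkit v<version> config_hash=<12-hex>` comment
  line; the hash is sha256 of the canonicalized YAML config.
- SAM writing is restricted to gapless alignments and sets MD tags so files
  round-trip without the reference; matrices are written as Matrix Market
  pairs (labeled/unlabeled) with shared features/barcodes files; blacklists
  are BED with low-coverage positions marked in the name field.
- YAML configs are schema-validated; unknown keys are rejected rather than
  ignored.
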