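# slamkit — SLAM-seq / scSLAM-seq analysis of RNA turnover and injury response

`slamkit` quantifies nascent-RNA labeling from metabolic-labeling sequencing
experiments. In SLAM-seq, cells (or a whole animal) receive 4-thiouridine
(4sU); transcripts made during the labeling window incorporate 4sU, which
reverse transcription reads out as transcript-sense T-to-C substitutions.
Counting those substitutions per read, per molecule, and per cell lets you

- estimate **per-gene RNA half-lives** from a labeling time course, by fitting
  the saturation model *f(t) = α(1 − e^(−λt))* with τ½ = ln 2 / λ;
- compute an **injury-response statistic**: the ratio of newly made (labeled)
  RNA between an injured and a sham condition, which is independent of the
  pre-existing unlabeled RNA pool by construction;
- reason about **detection limits**: with a per-thymine conversion probability
  around 1% and ~50 thymines per read, roughly 15% of genuinely labeled
  molecules show zero conversions and are missed.

The package includes read-level and count-level simulators whose defaults
mirror the study conditions the pipeline is designed for (adult-heart
labeling, ~1% conversion rates, half-lives on 0.5–48 h, a ~7 h single-cell
labeling window, induced genes in macrophage-like cells after injury), so
every statistical claim can be checked against planted ground truth.

## Layout

- `src/slamkit/` — the library; all computation lives here.
  - `conversions.py` — per-read T>C calling (Phred ≥ 20 filter, strand-aware),
    SNV blacklisting (≥ 25% apparent conversion at ≥ 10× coverage),
    conversion-rate tables, 12-type substitution spectra.
  - `quantify.py` — molecule/UMI classification (labeled = ≥ k conversions,
    default k = 1), labeled/unlabeled count matrices, detection model and
    zero-truncated estimator of the conversion probability.
  - `kinetics.py` — bounded weighted nonlinear least squares for the
    saturation model, multi-start, with delta-method confidence intervals.
  - `injury.py` — background-corrected, depth-normalized labeled-RNA response
    ratio with vectorized permutation p-values and BH correction; pathway
    gene-set layer scoring.
  - `simulate.py` — read-level bulk time-course generator (writes SAM),
    count-level time-course generator, paired sham/injured single-cell
    generator.
  - `io.py`, `config.py`, `pipeline.py`, `cli.py` — SAM/BED/MTX/TSV/GMT I/O,
    YAML config with validation and hashing, stage drivers, and the `slamkit`
    command-line interface.
- `analysis/` — numbered scripts that run the study end to end on simulated
  data and write small tables under `results/`. Large intermediates (SAM
  files, matrices) go under `scratch/`, which is disposable.
- `scripts/acceptance.py` — one-shot end-to-end run that reports headline
  quantities as JSON.
- `docs/methods.md` — model equations, parameter defaults, and numerical
  choices.

## Worked example

Run the analysis scripts in order (each is a thin driver over the library):

```sh
python analysis/01_simulate_bulk.py
python analysis/02_conversion_calling.py
python analysis/03_halflives.py
python analysis/04_simulate_injury.py
python analysis/05_injury_response.py
```

Actual output:

```
simulated 75425 reads over 50 genes, 5 timepoints x 3 replicates (seed 17)
10 SNV positions planted
true labeled fraction by labeling time:
    0.5 h: 0.129
    1.0 h: 0.227
    3.0 h: 0.448
    6.0 h: 0.612
   12.0 h: 0.752

loaded 75425 aligned reads
global conversion rate: 1.706% raw, 1.625% after SNV masking
blacklisted 10 positions (112 under-covered, left unmasked)

fitted 50 genes; 49 pass (r2 > 0.7, tau in (0.5, 48.0) h)
mean half-life 6.27 h, median 3.94 h
recovery vs truth: median |relative error| 10.4%, median signed error -5.9%

simulated 1000 genes x 3 cell types x 200 cells/condition (seed 23)
labeled fraction: sham 24.2%, injured 18.4% (7 h window; detection losses included)
25 genes induced 4.0x in macrophage-like cells; unlabeled pools differ 1.5x
between conditions by design

macrophage: 24 responsive genes called (q < 0.05, log2 R > 1); 24/25 planted
induced genes recovered, 0 false calls
endothelial: 0 responsive genes (no induction simulated)
cardiomyocyte: 0 responsive genes (no induction simulated)
induced-layer percent of transcriptome (macrophage):
  macrophage_injured: 2.85% +/- 0.01%
  macrophage_sham: 1.54% +/- 0.01%
```

Two things worth noting in those numbers. The blacklist recovers exactly the
10 planted variant positions despite variants and labeling both appearing as
T>C mismatches — coverage-conditioned conversion fractions separate them
cleanly. And the injury call is unaffected by the deliberate 1.5× difference
in pre-existing unlabeled RNA between conditions, because the statistic only
ever touches labeled counts.

The same stages are available as a CLI (`slamkit sim-bulk`, `slamkit
convcall`, `slamkit snv`, `slamkit quant`, `slamkit decay`, `slamkit
response`, `slamkit score`), each writing a manifest with the config hash.

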