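# Methods

## Model and assumptions

The copy-number signal model is dosage-based: a chromosome present at copy
ratio *r* multiplies the expected expression of every gene on it by *r*
relative to a euploid baseline defined by a reference cell population. On the
log-normalized scale a whole-chromosome gain of r = 1.5 shifts each gene on
that chromosome by roughly ln 1.5 ≈ 0.4, while per-gene technical noise is
zero-mean; averaging over a 101-gene window therefore suppresses noise by
~10× while leaving the chromosome-wide shift intact. The method assumes
(i) the reference population is euploid at every gene, (ii) CNAs in the
observation population affect whole chromosomes (sub-chromosomal events are
diluted by the chromosome-wide summation), and (iii) expression dosage tracks
DNA dosage on average — no dosage compensation.

## Pipeline stages and parameters

| stage | parameter | default | units | why |
|---|---|---|---|---|
| QC | `min_genes` | 1400 | genes | detected-gene floor; `>=` semantics |
| QC | `max_mito_frac` | 0.15 | fraction | strict `<`; computed on raw counts |
| normalize | `scale` | 10,000 | counts | LogNormalize target sum, ln(1+x) |
| ordering | `min_cells_expressing` | 3 | cells | drops near-silent genes before smoothing |
| profile | `clip` | ±3 | centered log units | bounds single-gene outliers before smoothing |
| profile | `window` | 101 | genes | boxcar width, truncated at chromosome ends |
| denoise | `sd_multiplier` | 1.5 | reference SDs | zeroing band around baseline (observation cells only) |
| scoring | `multiplier` | 2.5 | SDs of D | outlier threshold, strict inequality |
| scoring | `mean_over` | `all` | — | cells defining the per-segment mean (`observation` optional) |
| scoring | `sd` | `sample` | — | spread estimate for the rule (`mad` optional) |
| growth | `threshold` | 125 | mm² | terminal burden, inclusive |
| growth | `ref_median` + `margin` | 13 + 7 | days | partial-responder definition |

The distribution peak is a Gaussian-KDE mode (Silverman bandwidth, argmax on a
512-point grid over [min, max]) with a median fallback for n < 10 or constant
samples — a deterministic, standard smooth-mode estimator; "peak" denotes a
mode and the estimator is otherwise a free choice. The chromosome sum of
deviations is signed, not absolute: whole-chromosome events shift all segments
with one sign, so signed summation preserves gain/loss direction, and the
absolute value enters only in the final |D − peak| comparison. Values are kept
on the centered log scale throughout; the statistic is translation-based, so
any monotone affine convention would give identical calls.

Degenerate inputs: a zero SD on a chromosome flags nothing; ties at exactly
2.5 SD are not outliers; a constant growth series fits k = 0; zero-area
(fully regressed) time points are excluded from growth fits because the log
initialization and the exponential model are undefined at 0, and such
subjects are handled by the responder classification instead. Exponential
fits are initialized from OLS on log areas and refined by nonlinear least
squares on the raw areas; non-convergence is reported via a flag, not raised.

## Synthetic data: what it does and does not emulate

The generator emulates a two-group droplet scRNA-seq design: log-normal
per-gene baseline means (log-SD 1.0 around an expected 5 counts/gene),
log-normal library-size factors (CV 0.3), gamma-Poisson counts (dispersion
0.1), and whole-chromosome copy-ratio events planted in a configurable
fraction of observation cells (1–3 chromosomes each, ratios {0.5, 1.5} by
default). Defaults give ~10⁴ counts and ~1,700 detected genes per typical
cell over the default 8 × 250-gene genome, so ordinary cells clear the
1,400-gene QC floor — chosen once for realism against typical 10x runs. Ten
mitochondrial genes with ~10× baseline expression sit on a pseudo-contig "MT"
(≈5% of counts), exist only to exercise the QC filter, and drop out of CNV
scoring because they carry no genomic position.

Not emulated: doublets, batch effects, UMI saturation, sub-chromosomal CNAs,
dosage compensation, and cell-cycle or cell-type expression programs. Passing
tests therefore demonstrate correctness of the computation and its behavior
under dosage + overdispersed noise, not robustness to the confounders of real
tumor data (where, e.g., cell-type differences can mimic CNAs).

## Behavior of the 2.5-SD rule worth knowing

Two properties are intrinsic to thresholding |D − peak| against the *sample*
SD of the mixed distribution and are reproduced, not bugs:

- **Null floor.** With no true CNAs, each chromosome flags ~1–3% of cells
  (two-tail mass beyond 2.5 SD); unioned over 8 chromosomes via the
  ≥1-chromosome rule this calls ~9–12% of a fully euploid population
  aneuploid. Real reference populations scored by this class of rule show the
  same order (~10%).
- **Signal-dependent false positives.** True carriers inflate the
  per-chromosome SD, which *suppresses* false positives among euploid cells;
  as the copy ratio grows past the point where carrier detection saturates,
  the total called fraction can therefore plateau or dip slightly even though
  carrier detection itself is monotone in effect size. Called fractions track
  planted fractions of 10% and 34% within ~±0.03 at the default study size
  (200 reference + 400 observation cells, 8 chromosomes × 250 genes).

## Design choices where the design was open

- Per-segment "overall mean" is taken over all cells (reference +
  observation) by default, with `mean_over="observation"` exposed, since
  either reading is defensible.
- Segments are genes (post-smoothing); no HMM segmentation.
- Denoising leaves reference cells untouched; the band uses the reference
  sample SD per segment.
- Chromosome order follows the position table's order of appearance
  (numeric-name tables come out in natural order); gene coordinates are
  1-based inclusive.
- Problem sizes in the test suite (down to 3 × 40-gene genomes for unit
  tests, 8 × 250 for end-to-end recovery) were chosen so that the smoothing
  window, QC floor, and statistics remain meaningful at each scale.

## Known limitations

Copy ratios are whole-chromosome and multiplicative; calls are binary per
chromosome (direction available from the sign of D, magnitude not
estimated). The KDE mode can sit slightly off-center for small or skewed
samples. The growth models assume exponential kinetics throughout the
observation window; regressing tumors are flagged through the response
classification rather than fit with richer models.
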