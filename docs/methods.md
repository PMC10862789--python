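# Methods

## The problem and the data model

CRISPRi Perturb-seq screens knock down one gene per cell population and
read out the transcriptome. After pseudobulk aggregation, each
perturbation is summarised as one vector of z-scores: per gene, the
pseudobulk expression in standard deviations relative to the mean and
SD of control (non-targeting) sgRNAs from the same 10X gemgroup (the
library-preparation batch that defines the normalization stratum).
Under the null — a knockdown that does not move a gene — that gene's z
is approximately standard normal.

`perturbstress` asks, per perturbation, which stress-responsive
signaling pathways the knockdown activates: the integrated stress
response (ISR, ATF4-driven), the ER unfolded protein response (UPR,
with its ATF6 and IRE1/XBP1s arms), the heat shock response (HSR,
HSF1-driven) and the oxidative stress response (OSR, NRF2-driven).

## Activation score and significance

Each pathway is represented by a small panel (10–20) of its
transcriptional target genes, plus one designated control panel of
stably expressed genes. The **activation score** of pathway *P* in
perturbation *i* is the arithmetic mean of the panel's z-scores:

    score(i, P) = mean_{g ∈ P} z[i, g]

Significance compares the panel's z-values against the control panel's
z-values *within the same perturbation*:

* **Welch's t-test** (unequal variances) on the means is the volcano
  p-value. For bar-panel style multi-pathway comparisons, the k-group
  **Welch ANOVA** is used with **Games–Howell** pairwise post hoc
  contrasts (the standard unequal-variance companion; Dunnett T3 would
  be an equally defensible choice and the post hoc step is isolated so
  it can be swapped).
* The **Brown-Forsythe** test (median-centered Levene) on the same two
  groups reports whether the panel's dispersion differs from control.

Treating the panel's genes as a sample assumes their z-scores are
roughly exchangeable and independent; the generator's correlated-module
mode (below) exists to stress that assumption.

Conventions for degenerate inputs, chosen so batch runs over thousands
of perturbations never abort: two constant groups give p = 1 when equal
and p = 0 when not; per-row scoring failures are logged and the batch
continues. Multiple-testing adjustment across perturbations is off by
default (each volcano point is a raw per-test p-value); Benjamini–
Hochberg within pathway is available via `adjust="fdr_bh"`. α defaults
to 0.05; the 0.05/0.01/0.005 asterisk tiers are exposed via
`ActivationResults.stars()`.

The packaged panels (`resources/stress_panels_synthetic.gmt`) are
synthetic stand-ins assembled from field-typical target genes — e.g.
DDIT3/ATF3/TRIB3 for the ISR, HSPA5/HERPUD1/DNAJB9 for the UPR — with
13 ISR genes, a 19-gene control set, and 10–20 genes per other panel.
They are suitable for method validation and synthetic studies; analyses
of real data should load a curated GMT via `parse_gmt`. Gene symbols
are matched by exact string equality after uppercasing (no aliasing);
genes absent from the measured panel are dropped with a logged coverage
fraction (warning below 0.5 coverage by default), and a panel losing
all its genes is a hard error.

## Transcriptome-wide comparison

Two perturbations activating the same program produce correlated
z-profiles. The pair comparison first restricts to responsive genes —
|z| strictly greater than 0.5 in **either** profile (the union rule) —
then fits ordinary least squares of one profile on the other and
reports slope, intercept and R². R² equals the squared Pearson r, so
the headline statistic is orientation-free. Grouped comparisons (e.g.
a trio of EIF2B-subunit knockdowns) average member profiles gene-wise
before filtering and regression. Gene classes (mtDNA-encoded genes,
flagged by the standard "MT-" prefix or by explicit annotation) are
contrasted as within-class vs outside-class mean z per perturbation,
plus the between-perturbation within-class difference.

PCA treats perturbations as observations and genes as variables,
centering genes and not scaling by default (mirroring R's `prcomp`),
with variance fractions from the singular values. Components are
deterministic up to sign; a constant matrix yields a flagged result.

## The synthetic generator

`simulate_study` emulates the pipeline's assumed data-generating
process end to end:

1. **Raw expression.** Per gene, baseline location ~ N(5, 2) and scale
   ~ logNormal(0, 0.4) (arbitrary units); each sgRNA row adds
   scale-multiplied standard-normal noise. Planted effects enter as
   δ·scale so they land as a δ mean shift on the z scale.
2. **Strata.** Perturbations are assigned round-robin to 4 gemgroups;
   each gemgroup carries 250 control sgRNAs with no planted effects.
3. **Normalization.** `z_normalize` standardizes every row against its
   gemgroup's control mean and sample SD (ddof = 1 throughout — the
   convention is stated because published resources rarely print
   theirs). Applied to the controls themselves this is exactly
   standardizing (mean 0, SD 1 per gene per gemgroup). For
   perturbations, normalizing against *estimated* control statistics
   leaves null z as a scaled t-variate with SD
   √((1 + 1/n)(n − 1)/(n − 3)) (`expected_null_z_sd`); 250 controls per
   gemgroup keep this inflation at ~0.6%, so null z is standard to
   within Monte-Carlo resolution of the tests. Few controls per
   stratum both inflate this factor and correlate false-positive calls
   across the perturbations of a gemgroup (they share the SD estimate).
4. **Classes.** The default study plants: mito-like (ISR δ = 1.5, with
   a −0.8 shift on the 13 mtDNA-encoded genes), ER-like (UPR δ = 1.5,
   ISR δ = 0.5 for the PERK arm), KEAP1-like (OSR δ = 1.5), UBA1-like
   (HSR δ = 1.5), EIF2B-like (ISR δ = 1.5 by a non-mitochondrial
   mechanism), and null — 40 members each plus 100 null members,
   enough for call-rate estimates at a few-percent resolution while
   keeping a full study under ~5 s. δ = 1.5 on a 13–20-gene panel vs
   the 19-gene control gives the Welch test ≥95% power, so selectivity
   patterns are crisp; δ = 0.5 is deliberately in the partial-power
   regime (~25%).
5. **Knockdown fractions** are Beta(6, 2) draws independent of effect
   size, giving the score-vs-knockdown correlation a true null.
6. **Correlated-module mode** (`module_loading > 0`) adds a shared
   latent factor per pathway panel per perturbation, violating the
   independence assumption of the panel-vs-control test; it is off by
   default.

All randomness flows from one `numpy.random.Generator` drawn in a fixed
order, so a fixed seed reproduces the study bit-for-bit.

What the generator does **not** emulate: UMI/count-level noise, guide
assignment errors, gene-gene correlation outside the optional module
mode, heavy-tailed per-gene z distributions seen in real screens, and
knockdowns that fail. Passing tests therefore demonstrate correctness
of the computations and calibration under the assumed model, not
robustness to every property of real Perturb-seq data.

`simulate_null_matrix` is a fast path emitting exactly iid standard
normal z (no raw/normalization stage), used for calibration studies
where the null must be exact.

## Numerical and design choices

* Welch/Brown-Forsythe via scipy, k-group Welch ANOVA and Games–Howell
  via pingouin, OLS via scipy's linregress, PCA via scikit-learn's full
  SVD; the test suite checks each against independently coded textbook
  formulas (Welch–Satterthwaite df, Welch's 1951 F, ANOVA on median
  deviations, normal equations) to 1e-10.
* The z filter uses strict inequality (|z| > 0.5), so boundary genes
  are excluded; the filter is antitone in the threshold.
* TSV round-trips write floats with %.17g and read with round-trip
  parsing, so write→read is bit-identical.
* The TSV reader sniffs orientation by comparing the metadata sidecar
  length to the matrix dimensions and logs a transpose.
* Missing z values are refused by default; explicit `missing="zero"` or
  `"drop"` policies are logged. A zero control SD in normalization is
  likewise refused unless a drop/zero policy is chosen.

## Problem sizes used by the reproduction script

`scripts/acceptance.py` uses 1,000 null perturbations for calibration,
500 perturbations per planted shift for recovery, three replicate
default studies (300 perturbations × 2,000 genes each) for
selectivity/regression/PCA summaries, and 40 independent null pairs for
the R² baseline — sizes at which Monte-Carlo error is well below the
effects being measured.

## Known limitations

* Gene-symbol matching is exact; no alias resolution or ID conversion.
* The packaged factor lists are illustrative stand-ins, far smaller
  than real curated proteostasis annotations.
* The omnibus path materialises a long DataFrame per perturbation and
  is not optimised for genome-wide sweeps (the two-group path is).
* p-values are not adjusted across the pathway dimension (only, and
  optionally, across perturbations).
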