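# Methods

## Model

Each enhancer is modeled independently: its openness `O` (an
enhancers × samples matrix row; openness = the maximum DNase-hypersensitivity
signal over the enhancer's genome bins, `openness_model.compute_openness`)
is regressed on the expression of its binding TFs (`E_T`) and associated
target genes (`E_G`),

```
min_{α,β} ‖O − α₀ − γ_T Σ_p α_p TF_p − γ_G Σ_q β_q TG_q‖²₂
          + λ(‖α‖²₂ + ‖α‖₁ + ‖β‖²₂ + ‖β‖₁).
```

Notes on the implementation of this objective:

* The two intercepts that would attach to the TF and gene sums are not
  separately identifiable; a single intercept is fitted.
* Both penalty norms carry the same weight λ. In scikit-learn's
  parameterization — `(1/2n)‖y−Xw‖² + αρ‖w‖₁ + (α(1−ρ)/2)‖w‖²` — equal L1/L2
  weights require `ρ = 1/3` and `α = 3λ/(2n)`; the popular "0.5 mixing"
  would weight the L1 term twice as strongly as the L2 term. We use the
  exact mapping. At λ = 0 the solver switches to plain least squares.
* λ defaults to per-enhancer selection by internal 5-fold cross-validation
  (`ElasticNetCV`); a fixed λ can be supplied and is what the examples use
  (λ = 0.1) for speed and determinism.
* γ_T = γ_G = 1 by default; they act as fixed column multipliers applied
  after standardization, so unequal values change the relative penalization
  of the two feature groups. `feature_mode="TGonly"` drops TF columns — the
  target-genes-only baseline that the TF-aware model is compared against.
* Alternative backends fit the same feature → openness mapping: a random
  forest (100 trees, √p features per split, mandatory seed) and an RBF SVR
  (library defaults). They carry their own implicit regularization; λ does
  not apply.

**Preprocessing.** Expression is log2(x+1)-transformed only when the matrix
looks raw (any value > 50), then per-feature z-scored with training-cohort
statistics; prediction reuses the training centers/scales. Constant training
columns get unit scale instead of dividing by zero. Modes `none`, `log`, and
`log_zscore` (default) are available. Negative linear predictions are
clipped to 0, since openness is a nonnegative DH-derived quantity; clipping
happens before everything downstream, including evaluation.

**Degenerate inputs.** A constant training target produces an intercept-only
model flagged `degenerate`. Missing values are never imputed: matrices keep
NaN on read and model fitting rejects them with an explicit error. Enhancers
with fewer than two usable features are skipped and reported, not fitted.

## Prior networks

Enhancer→gene links come from an association table; TF→enhancer links from
binding-site intervals, attached when a site overlaps the enhancer by at
least one base (full containment available as `mode="containment"`; ChIP-seq
peak boundaries are too fuzzy for containment to be the default). The
modeled universe keeps enhancers with ≥ 2 target genes **and** ≥ 2 binding
TFs ("at least two" was preferred over a stricter "more than two" reading;
both are reachable through the `--min-genes/--min-tfs` flags). A TF that is
also a target gene of the same enhancer contributes two features, one per
role. Coordinates are stored 0-based half-open; printed coordinates and
variant positions are 1-based inclusive and converted at the boundary.

## Evaluation

`τ_C` (per-enhancer cross-cell Pearson r), `τ_E` (per-sample cross-enhancer
Pearson r) and the normalized squared error
`τ = ΣΣ(O−Ô)² / ΣΣ(O−Ō)²` (Ō the grand mean). Correlations of constant
vectors are reported as undefined (NaN) and excluded from summaries with
their count recorded — zero-filling would bias medians. Cross-validation
drivers: leave-one-out (faithful to small cohorts) and k-fold (default for
the 120-cell study, where LOO would cost 120 refits per enhancer for no
extra insight).

Per-enhancer DH properties characterize predictability: spread (samples
with DH > 0), variation (sd across samples, ddof = 1), specificity (cell
types with at least one sample with DH > 2). The predictability filter
retains enhancers with spread > 100, variation strictly above the cohort
lower quartile (computed on the unfiltered cohort, before the other two
conditions), and specificity > 10; all three inequalities strict by default.
When no cell-type labels exist, each sample is its own type, with a warning.

## Differential calling

The primary test is an empirical-Bayes moderated t: per-feature pooled
variances `s²` (df `d = n_t + n_c − 2`) are shrunk toward a prior `s0²`
with prior df `d0`, both estimated by matching the mean and variance of
`log s²` across features through the digamma/trigamma relations of the
scaled-F sampling distribution (trigamma inverted by Newton iteration). The
statistic `logFC / (s̃ √(1/n_t + 1/n_c))` with `s̃² = (d0·s0² + d·s²)/(d0+d)`
is referred to a t distribution on `d + d0` df. Edge cases: fewer than 10
features → shrinkage disabled with a warning (`d0 = 0`, exact ordinary
pooled t); observed dispersion of `log s²` below its sampling floor →
`d0 = ∞` (full shrinkage, normal reference); exactly identical variances →
`d0 = 0`, so the moderated test reduces exactly to the ordinary t — with no
dispersion there is no prior to estimate.

The Wilcoxon rank-sum cross-check uses midranks, exact enumeration of all
`C(n, n_t)` labelings when both groups are ≤ 8, and a tie-corrected normal
approximation with continuity correction otherwise. All-tied features get
p = 1.

**Calling thresholds.** diffEnhancers: |ΔO| > 0.5 and p < 0.001, both
strict. Perturbed genes: |logFC| > 0.8 and p < 0.05 on expression. No
multiple-testing adjustment by default (the thresholds are raw-p
conventions); Benjamini–Hochberg is available (`--adjust bh`). The
differential test runs on predicted openness **directly** (`fc_scale="raw"`):
the moderated-t "logFC" is then simply the difference of group means on the
openness scale, which is the scale the 0.5 threshold is commensurate with.
A log2(x+1) pre-transform is available (`fc_scale="log2p1"`) but is not the
default: on a DH-like scale (baseline values ≈ 5–10) the transform
compresses a biologically large shift of several noise sd to ≈ 0.1–0.3,
far below the 0.5 gate, making the threshold effectively unsatisfiable.
Conditions with fewer than two samples on either side are skipped with a
recorded reason rather than tested.

## Annotation

A diffEnhancer's evidence chain: (i) motif hits — user-supplied motif-site
intervals overlapping the enhancer (motif discovery/PWM scanning is
deliberately upstream of this package); (ii) concordant genes — target genes
that are also drug-perturbed; (iii) variants with q < 0.05 (strict) located
inside the enhancer under the 1-based inclusive convention; (iv) consistent
variants — those whose associated gene is concordant. Significant variants
outside every enhancer whose gene matches a concordant gene are reported in
a separate gene-linked tier (gene-body pharmacogenomic variants). Raising
the q threshold can only add variants (monotonicity is property-tested).

## Synthetic data generator

The generator emulates the *structure* of the real inputs, not their
empirical distributions:

* **Expression**: cell-type block model — per-(feature, type) means drawn
  Uniform(2, 10) on a log2-like scale, within-type Gaussian noise sd 1.
  Because values stay below 50, the default preprocessing's log detection is
  a deliberate no-op on generated data.
* **Openness**: the planted linear map of the enhancer's standardized TF/TG
  expression with coefficients ±Uniform(0.5, 1.5) (random sign, so both
  activating and repressive regulators occur), intercept Uniform(4, 8)
  raised when needed so the noise-free signal stays above 0.5 — keeping the
  noiseless model exactly linear (no truncation) while the *noisy* values
  are truncated at 0 like real DH signal. Noise sd defaults to 0.1 × the
  planted signal sd per enhancer (`relative_noise`), the study's baseline
  condition.
* **Network**: 100 enhancers of 2–20 kb, non-overlapping on one toy
  chromosome; 3 target genes and 3 TFs each. Target-gene sets are disjoint
  across enhancers so a planted drug effect reaches exactly the designated
  responsive enhancers — real enhancer-gene networks share genes, and with
  sharing the "responsive set" would not be well-defined. TFs are shared
  across enhancers, as in real networks. One binding site per (enhancer, TF)
  is placed inside the enhancer, so rebuilding the TF network from sites
  reproduces it.
* **Perturbation**: one cell line (fresh type means), 20 control + 20
  treated samples, 30% of enhancers responsive. `effect_size` is expressed
  in units of the enhancer's within-cell-line openness noise sd (the sd
  induced by expression noise propagating through the planted map), making
  "an effect of k noise sd" a well-posed instruction; each responsive
  enhancer's target genes are shifted in the direction of their planted
  coefficient by the derived per-gene amount, and recorded as the drug's
  perturbed genes. Defaults use effect_size = 2.
* **Variants**: one consistent variant planted inside each responsive
  enhancer (gene = a perturbed target gene, q < 0.05) plus decoys of three
  kinds — outside all enhancers, inside with a non-perturbed gene, and
  non-significant.

What passing tests on this generator do **not** show: robustness to the
heavy zero-inflation and skew of real DH signal, to measurement batch
effects, to mis-specified priors (wrong TF-enhancer links), or to the
nonlinear regulation real enhancers exhibit. They do show that the
estimation, calling and annotation machinery is correct when its modeling
assumptions hold.

## Problem sizes and numerical choices

The bundled study uses 100 enhancers × 120 cells (12 types) for training,
5-fold cross-validated prediction at fixed λ = 0.1, and a 20 vs 20
perturbation — sizes at which every stage is deterministic given a seed and
the full pipeline runs in seconds. Elastic-net coordinate descent runs with
`max_iter = 50 000`; the λ = 0 path uses the closed-form least-squares
solution; OLS-vs-elastic-net agreement is asserted at 1e-6. All generators
are bit-reproducible given (parameters, seed); stochastic backends (random
forest, CV fold assignment) take explicit seeds.

## Known limitations

* Per-enhancer independent models ignore shared chromatin programs across
  enhancers; no parameter sharing or multi-task regularization.
* The SVM backend is untuned (library defaults) and mainly serves as an
  alternative-regularizer comparison point.
* The moderated t assumes approximate normality of (predicted) openness
  within groups; the Wilcoxon cross-check is provided for skewed cases.
* Variant annotation is positional set logic; no linkage-disequilibrium
  expansion and no causal claims.
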