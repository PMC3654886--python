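# Methods

## Data model

The pipeline operates on a gene-by-sample matrix of expression **ratios**
(treatment/control).  Two-colour array data is commonly deposited as log10
ratios; because correlations of log ratios and of ratios differ, all
statistics here are computed on the ratio scale, and log10 input is
back-transformed with 10^x at load time (`input_scale="log10_ratio"`, the
default).  Genes with missing values are dropped rather than imputed — every
downstream statistic (Pearson correlation, SD, t-test) assumes complete
per-gene vectors — and the dropped count is logged.  Time points are ordered
by an explicit integer in the sample map, never by parsing labels ("10d"
vs "4w" do not sort lexically).

## Null model for the correlation threshold

Each time point contributes a different number of samples n, and the
sampling spread of a Pearson correlation depends strongly on n.  To hold all
time points to the same standard, each sample size gets a randomization
summary: 100,000 pairs of independent standard-normal vectors of length n,
|r| recorded for each, sorted descending; the value at the 1-based position
⌈0.05·draws⌉ is the **high-correlation threshold**, and the mean |r| is the
**baseline** used to normalize trajectory curves.  Both use the *absolute*
correlation: the signed null mean is ~0, which would make the baseline
normalization degenerate, and a module's coherence is indifferent to sign.

Under the null the density of r is f(r) ∝ (1−r²)^((n−4)/2) for any i.i.d.
continuous draws, so the standard-normal choice is not a restriction.  The
CDF of |r| is the regularized incomplete beta I_{r²}(1/2, (n−2)/2);
`analytic_null_abs_quantile` inverts it and serves as the simulation's
oracle (at n = 4, |r| is exactly uniform: the 95% threshold is 0.95).

## Module formation

At one time point, genes are agglomerated on absolute Pearson correlation:
starting from singletons, the pair of modules whose union has the highest
average internal |PCC| is merged, **provided that average exceeds the null
threshold**; clustering ends when no qualifying merge remains.  Ties are
broken by the lexicographically smallest combined gene-id tuple, making
results independent of input order.  Internal pair-sums and a cross-sum
matrix are maintained incrementally so a merge evaluation is O(1) after the
O(g²) setup; tests verify the bookkeeping equals naive recomputation.
Zero-variance genes (undefined correlations) are excluded with a warning,
never silently.

Candidate scoring considers **every module formed during the agglomeration**
(every dendrogram node with ≥ `min_size` members), not only the final
partition.  The reason is structural: once a strong module has assembled,
its internal average is so far above the threshold that the union with *any*
remaining gene still clears it, so the final partition inevitably dilutes a
strong module with background genes until its average sinks to the
threshold.  The intermediate nodes retain the undiluted module.  The final
partition remains available (`cluster_modules`, CLI `cluster`) and satisfies
the usual guarantees: every returned module's internal average exceeds the
threshold, and no two returned modules could still merge.

## Composite index and critical-point flagging

For a module M on a time-point slice: SD_in is the mean over members of the
per-gene sample standard deviation (n−1 denominator — samples run as low as
4); PCC_in the mean |PCC| over member pairs; PCC_out the mean |PCC| over all
member × non-member pairs (all non-members, not a neighbourhood); and
s = SD_in·PCC_in/PCC_out.  A module fully decoupled from the background
(PCC_out = 0) reports s = +∞ with a warning.  Per time point the argmax-s
module is the candidate (ties: larger module, then lexicographic members).

Scores are compared across time points on the raw scale: the per-time-point
baseline normalization cancels between PCC_in and PCC_out, so normalized and
raw composite indices are identical; normalized components exist only for
trajectory reporting.  A time point is **flagged critical** when its
candidate score is at least `fold` (default 3) times the median of all
candidate scores — a deterministic reading of "clearly higher than the other
time points" that lets two dominant points in a six-point profile both pass.
If all scores are zero nothing is flagged.

## Downstream analyses

Disease onset is expected at the time point following the critical one
(overridable per time point in the pipeline config).  A non-member gene is
**regulated** by the module iff (a) at the onset point its correlation with
at least `min_links` members is individually significant — two-sided p from
t = r√((n−2)/(1−r²)) with n−2 df, p < α = 0.05 — and (b) a two-sided
two-sample Student t-test (pooled variance; Welch behind a flag) between
critical and onset samples gives p < α.  The default `min_links = 10`
presumes modules of roughly a hundred genes; at the simulation's scale
(candidates of ~5–8 genes) the analysis scripts use `min_links = 3`, chosen
for link-count separation: planted regulated genes link to ~40–50% of
members, background genes to ~6%.

**Pathway pair counts**: ordered pairs (d, p), d a module gene, p a pathway
gene, d ≠ p, with |PCC| above the high-correlation threshold at a given time
point; genes in both sets may appear on both sides but never pair with
themselves (so a module's "involved" count can reach its full size without
set subtraction).  **Bridge genes** re-apply the regulated-gene criteria to
a second module at that module's critical point, with the DE filter between
the second module's critical and onset points; the overlap between the first
module's regulated genes and the second module's members is reported
separately.  **Enrichment** is the exact upper tail P(X ≥ k) of the
hypergeometric(N, K, n), summed in log space; one test is performed per
module, so no multiple-testing correction is applied.

## Synthetic data

The generator plants exactly the structure the detector assumes, as
equicorrelated Gaussian blocks on the log10 scale, exponentiated to the
ratio scale.  Defaults (chosen once, as study-shaped, realistic values):

| parameter | default | meaning |
|---|---|---|
| timepoints | 6 ages, 7/6/4/7/6/5 samples | the study design |
| n_genes / module_size | 200 / 20 | transcriptome and planted module |
| critical_index | 1 | transition at the first age (largest n) |
| rho_in_high / rho_in_base | 0.9 / 0.2 | module correlation at/off the transition |
| rho_out / rho_bg | 0.05 / 0.2 | module–background correlation at/off it |
| sigma_high / sigma_base | 0.6 / 0.2 log10 units | member SD at/off it (3×) |
| n_regulated / rho_reg / de_shift | 0 (opt-in: 30) / 0.8 / −1.0 | onset association block |

The background is a single equicorrelated block, i.e. one shared factor —
the simplest structure consistent with a global correlation level.  The
critical time point is placed at the first age because that age has the most
samples (n = 7): at the n = 4 age the null threshold is ≈ 0.95 while a
ρ = 0.9 module's expected sample |PCC| is only ≈ 0.87, so no clustering
procedure could assemble the module whole there.  `sigma_base` = 0.2 log10
units matches typical two-colour log-ratio spreads.

The optional **regulated extension** (`n_regulated > 0`) adds, at the onset
time point, a joint equicorrelated block (ρ = 0.8) over module + regulated
genes plus a −1.0 log10 mean shift on the regulated genes.  Two points are
deliberate: a correlation of ~0.8 between regulated and module genes
mathematically forces a joint high-correlation block (factor constraints),
and the shift is *negative* because a positive log-mean shift multiplies the
ratio-scale SD (by 10 for +1.0), which would hand the onset point a spurious
variance signal.  The extension is off by default so that the default
dataset carries exactly the three planted signatures and nothing else; the
pipeline tests and analysis scripts enable it explicitly.

Gene sets and a disease annotation are generated alongside: one set
over-samples the module by `enriched_fraction`, and the annotation marks
genes disease-related at a 15% baseline rate, raised by 0.5 for planted
signal genes, giving the enrichment test a planted positive.

## What the simulations do and do not show

Passing recovery tests show the pipeline finds a planted transition under
the model's assumptions: one coherent module, one critical point, Gaussian
log-ratios, no batch or probe effects, no replicate probes.  They do not
show that real microarray data satisfies those assumptions.

Two quantitative limits at the study's sample sizes are worth stating
because they are properties of the *statistics*, not of the implementation:

1. **Membership recovery is bounded.** With n = 7 samples, the sample |PCC|
   of two independent genes scatters with sd ≈ 0.38, so among ~180
   background genes dozens are, in sample, as correlated with the module as
   its own members.  Correlation clustering therefore cannot return the
   exact planted membership; measured over the whole merge tree, the best
   node anywhere (the ceiling for *any* selection rule) has median Jaccard
   ≈ 0.5 against truth.  Detected candidates are tight sub-modules —
   sufficient to time the transition, insufficient as a complete gene list.
2. **Flagging power is factor-limited.** The module is a single-factor
   block, and its ratio-scale SD depends exponentially on the 7-sample
   spread of that factor; in roughly 1 seed in 5 the draw compresses enough
   that the critical point's score no longer clears 3× the median.  Without
   planted signal, flagging is clean (no false flags in 10/10 seeds).

## Numerical choices

Correlations are clipped to [−1, 1] before p-values; |r| = 1 maps to p = 0.
The hypergeometric tail is summed in log space (gammaln + logsumexp) and
capped at 1.  Covariance matrices are verified PSD (eigenvalues ≥ −1e−10;
small negative round-off clipped at sampling).  All randomness derives from
explicit seeds; per-stage seeds are spawned from the master seed so stages
are reproducible in isolation.  Clustering tie-breaks (lexicographic
combined gene tuple) make module formation invariant to gene order, and
per-pair float symmetry is enforced so the merge argmax cannot depend on
matrix orientation.
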