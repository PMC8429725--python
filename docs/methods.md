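# Methods

This note documents the statistical models behind each stage of the
pipeline, the defaults and why they were chosen, what the synthetic
generators do and do not emulate, and the numerical choices that matter for
reproducing results.

## Setting

The package analyses allele-specific measurements in clonal cell lines
derived from an F1 hybrid background (129/Sv x Castaneus), where strain
SNPs make the two parental alleles distinguishable in sequencing and
pyrosequencing read-outs. The central quantity is the **allelic ratio**:
the fraction of allele-specific signal from the Cast allele over the total,
stored as a fraction in [0, 1]. Because each clonal line descends from a
single cell, a gene's allelic choice is shared by all cells of a clone, and
the distribution of ratios *across* clones reveals the gene's stable
allelic states — information that single-cell snapshots cannot give,
since transcriptional bursting makes transient monoallelism ubiquitous.

## Ratios and categories

A ratio is reported only when the total informative (allele-specific) read
count reaches a threshold: 20 reads for RNA-seq gene ratios, 10 for
ATAC-seq peaks, both configurable. Below the threshold the entry is marked
`excluded_low_reads` rather than reported as a noisy value. Pyrosequencing
percentages arrive without read counts and bypass the filter.

Categories partition [0, 1]: monoallelic (r < 0.15 or r > 0.85), biased
(0.15 <= r <= 0.35 or 0.65 <= r <= 0.85), biallelic (0.35 < r < 0.65).
The placement of the boundary points themselves (closed on the biased
intervals, open elsewhere) is a declared convention: interval notation in
percent ("15–35%") is ambiguous at the endpoints, so we fixed a rule that
keeps the strict inequalities where they are written as such and make the
printed ranges inclusive. Exactly one category holds at every r, and the
category is monotone in r.

## Mixture decomposition of clonal ratio distributions

A gene's ratios across n clones are modelled as a univariate Gaussian
mixture with K components, each component one stable allelic state with its
own mean and variance. Fitting is by EM; model selection maximises

    BIC = 2 logL − k_free log n,

with k_free = 3K−1 for component-specific variances ("unequal" family) and
2K for a shared variance ("equal" family). Both families are searched for
K = 1..K_max (default 5, capped at n/2 so every component can hold at least
two observations); ties go to the smaller K, then the equal family. This
is the convention of the standard R mixture-model machinery in which BIC
is maximised, so selected models are comparable with that ecosystem.

Numerical choices:

* **Initialisation** — the sorted sample is cut into K contiguous
  quantile blocks; block moments seed the first EM run, and 10 seeded
  random perturbations of that start guard against local maxima.
  Results are deterministic given the seed.
* **Variance floor** 1e-6 (ratio² units) prevents singular components when
  ratios are replicated (e.g. many clones at exactly 0 or 1).
* **Convergence** — relative log-likelihood change < 1e-8 or 1000
  iterations. The log-likelihood trace is retained and is non-decreasing
  up to the floor tolerance.
* **No truncation** — plain Gaussians are fitted although ratios are
  bounded; densities are not renormalised. This mirrors standard practice
  and keeps BIC values comparable; it is a mild misspecification for
  boundary components that the recovery tolerances absorb.

One consequence of fitting plain Gaussians to count-derived ratios is
worth knowing: each allelic state's observed ratios are a
Gaussian–binomial convolution (state spread plus counting noise), and at
panel sizes around 150 clones the BIC resolves that slight
non-Gaussianity as an extra component in roughly 5–10% of draws, most
often splitting the central biallelic state in two. Recovery of the true
state count therefore sits close to, not far above, a 90% bar under
realistic read depths; the spurious components are narrow and central, so
state means and the monoallelic shares remain accurate even when K is
overcalled.

Uncertainty is quantified two ways. A **parametric bootstrap LRT** of K vs
K+1 simulates B datasets (default 1000) from the fitted null, refits both
hypotheses with the same EM settings as the observed fits (so the statistic
is exchangeable between observed and bootstrap worlds), and reports
p = (1 + #{boot >= obs})/(B + 1). Sequential testing starts at K = 1 and
stops at the first p > 0.05. Bootstrap refits use 2 restarts, 200
iterations and tolerance 1e-6 — lighter than the headline fits, chosen so
a 1000-replicate test completes in seconds while leaving the null
calibration intact (the type-I rate at nominal 0.05 stays within
[0.02, 0.10] in the acceptance checks). **Nonparametric bootstrap
percentile intervals** (default 95%, B = 1000) cover the component
parameters, with components matched across replicates by sorting on means;
replicates with tied means set a label-switching flag and widen the
interval to the across-component union.

## RNA-FISH burst test

In tissue, a cell showing one nascent-RNA pinpoint may be stably
monoallelic or merely caught with one allele in the OFF phase of bursting
(or below detection). For a homogeneous cell population with genetically
identical alleles, an active allele is seen with probability
P_detect = P_ON × P_sense, estimated from the data as
p = n_tot / (2 N_cells) where n_tot = n1 + 2 n2 is the total pinpoint
count. If every cell were biallelic with independent alleles, the number
of pinpoints per cell would be Binomial(2, p); the test compares the
observed (n0, n1, n2) tallies to N·((1−p)², 2p(1−p), p²) with a
chi-squared statistic on 1 degree of freedom (three classes, one estimated
parameter). Rejection indicates an excess of one-signal cells that
bursting and detection losses cannot produce — a stably silent allele in
part of the population.

Conventions: no continuity correction; expected classes below 5 raise a
warning rather than an error; the default analysis pools animals within a
region (pooling across regions requires an explicit override because the
test assumes a homogeneous cell type), and per-animal results are emitted
alongside. Cells with zero signals are part of N_cells: excluding them
while keeping the plug-in estimator p = n_tot/(2 N_detected) inflates the
statistic under the null (the estimator is then inconsistent for the
conditional class probabilities), so a zero-truncated variant is not
offered.

**Power is limited at moderate detection probabilities.** A population
with stable-monoallelic fraction f has class probabilities
(f(1−p) + (1−f)(1−p)², f p + (1−f)·2p(1−p), (1−f)p²), which a pure
binomial with a slightly smaller p̂ mimics closely. The noncentrality at
f = 0.33, p = 0.6 is only ≈ 0.0015·N, so at N = 300 cells the test
rejects ≈ 11% of the time; ≥ 90% power at those rates would need roughly
6,800 cells. Power climbs steeply with p: at p = 0.95 and N = 300 it is
already ≈ 0.8. Detecting stable monoallelism by this test therefore
requires either high detection efficiency or large cell counts; the
acceptance checks report the honestly simulated rate in the moderate-p
regime rather than asserting power the test does not have.

## Regulatory scan

For a gene with allelic imbalance, the scan asks which accessible-
chromatin peak within ±3 Mb of the TSS has allele-specific accessibility
that predicts the gene's allele-specific expression across clones. Peak
membership in the window is decided by the peak midpoint (deterministic
for straddling peaks); peaks without a strain SNP carry no allelic signal
and are dropped up front. Per peak, clone values with fewer than 10
allele-specific ATAC reads are removed; the peak is tested only if at
least 4 values remain and at least 2 of those clones have a biased RNA
ratio (< 1/3 or > 2/3) — without expression variation across clones the
regression is uninformative. The regression is ordinary least squares of
RNA ratio on ATAC ratio; F = (n−2)R²/(1−R²) with (1, n−2) df equals the
squared slope t statistic, so the direction of the regression affects only
the reported slope. p-values are Bonferroni-adjusted over the peaks
actually tested for that gene (the per-gene family, matching how such
scans report "m of M peaks tested"), and the best peak minimises the
adjusted p with ties broken toward the TSS.

## Downstream statistics

* **State comparisons** use the two-sample Kolmogorov–Smirnov test
  (asymptotic p), e.g. stem-cell vs progenitor ratio distributions.
* **Stability** between timepoints is the per-clone Pearson correlation of
  gene ratios, with the 20-read filter applied at both timepoints and at
  least 3 shared genes required.
* **Dosage**: clones are split into high/low expressors at a caller-chosen
  threshold (the split is a per-gene judgement; a 2-component mixture on
  log10 levels can propose the antimode). Among high expressors,
  monoallelic and biallelic clones are compared with a two-tailed
  equal-variance Student t-test (df = n1+n2−2); biased clones are
  excluded. Under cis-acting silencing each active allele contributes
  independently, so the monoallelic/biallelic mean ratio concentrates near
  one half — the synthetic per-allele model reproduces this and the
  pipeline recovers it.
* **Protein ~ mRNA** uses the same simple-OLS machinery as the scan.
* **Screen hit calling**: each reporter clone's vehicle controls give a
  mean and sample SD (n−1); a compound's effect is its ratio shift toward
  the silent allele relative to that clone's control mean (the two clones
  silence opposite alleles, so the sign convention is per clone, fixed by
  a silent-allele annotation). A hit must exceed mean + 3 SD in **both**
  clones; missing data in either clone marks the compound ND. The
  two-clone requirement is what controls false positives: with thresholds
  estimated from 11 control wells the per-clone exceedance is t-like
  (≈ 0.8% rather than the known-parameter 0.13%), but requiring both
  clones drives the null call rate below 1 in 10,000.
* **Dose-response** fits a 4-parameter logistic on log10 dose by
  multi-start least squares (20 seeded starts), with zero-dose wells
  placed two decades below the lowest nonzero dose so they anchor the
  bottom asymptote. After fitting, orientation is normalised so
  bottom <= top (Hill sign flipped accordingly); EC50 is reported in µM.
  Non-converging fits return a no-fit status rather than garbage
  parameters.

## Synthetic data: what it emulates and what it does not

The generators produce the statistical structure each stage assumes, with
truth labels, so recovery can be measured exactly:

* **Clone panels** — per clone: a differentiation experiment is assigned;
  the experiment's state proportions are a Dirichlet perturbation of the
  gene's state weights (concentration 50 by default — visible
  experiment-to-experiment variability without degenerate experiments;
  infinity freezes the proportions); the clone's true ratio is drawn from
  its state's truncated-to-[0,1] Gaussian plus technical noise
  (sd 0.01); reads are Binomial(Poisson(1000), ratio), a depth at which
  counting noise adds ≈ 0.016 sd at balanced ratios — the scale of a
  deep pyrosequencing or RNA-seq assay. Presets cover the three regimes a
  gene can occupy: one tight biallelic state (mean 0.41, the slight 129
  bias typical of a biallelic control), two reciprocally biased states,
  and full random monoallelic expression (25/50/25 at means
  0.05/0.5/0.95, sd 0.03).
* **FISH populations** — a stable fraction f of cells with one
  permanently silent allele (detected as 0 or 1 signals) mixed with
  bursty biallelic cells (Binomial(2, p) signals).
* **Peak landscapes** — 150 peaks uniform in the ±3 Mb window, 13 clones
  whose RNA ratios span [0.05, 0.95]; the coupled peak sits at the TSS
  and tracks the RNA ratio with sd 0.05; uncoupled peaks fluctuate around
  0.5 with sd 0.10; reads are Binomial(Poisson(100), ratio).
* **Screen plates** — 11 controls per clone, null compounds from the
  control distribution, true hits shifted toward the silent allele in both
  clones.

Not emulated: read alignment and allele assignment (the pipeline consumes
allele-resolved counts), linked genes or shared cis-elements (each gene is
generated independently), spatial structure or cell-type mixtures in the
FISH populations, plate effects or compound toxicity in the screen, and
any sequence-level realism. Passing recovery tests therefore demonstrates
that the statistical machinery is correct under its stated model, not that
the model captures every failure mode of real data (batch effects,
alignment bias toward the reference allele, heterogeneous cell
populations).

## Problem sizes used in tests and the acceptance script

Calibration and recovery are measured at: 1000 null FISH populations and
200 powered ones (N = 300 cells each); 200 clone panels of 150 clones for
mixture recovery; 200 null datasets (n = 100, B = 199) for the bootstrap
LRT; 100 coupled and 200 null landscapes for the scan; 100 screen plates
plus one 10,000-compound null plate; 100 noisy dose-response fits. These
sizes keep a full run in the minutes range on one CPU; at 200 simulations
a rate has Monte-Carlo standard error around 0.02, which matters for
quantities that sit near their asserted bound (the mixture state-count
recovery discussed above is the one such case).

## Known limitations

* The mixture model treats ratios as unbounded Gaussians; genes with heavy
  pile-up at exactly 0 or 1 are handled by the variance floor but a
  truncated or beta mixture would model them more faithfully.
* The burst test's power analysis above assumes the pooled population is
  homogeneous; cell-type mixtures inflate or mask the one-signal excess in
  ways the test cannot distinguish.
* The screen's effect definition (ratio shift toward the silent allele
  relative to the control mean) is one of several defensible readings of a
  mean + 3 SD rule; alternatives (fold change, raw ratio thresholds)
  would change borderline calls.
* Bonferroni across tested peaks is conservative when peaks are correlated
  (adjacent peaks often are); the scan may therefore under-call secondary
  regulatory regions.
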