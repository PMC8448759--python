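# Methods

## The model

annonet builds neural networks for genotype-to-phenotype prediction in which
every connection is prescribed by a biological annotation. A network is a
stack of sparse layers; layer inputs and outputs are named biological
entities (variants, genes, exons, pathways, tissues), and a connection from
node *i* to node *j* exists only if an annotation links the two (a variant
lies in a gene, a gene belongs to a pathway, a gene is among a tissue's most
differentially expressed). Each layer computes

    y_j = activation( sum_{i in links(j)} x_i * w_ij + B_j )

with one learnable weight per link and one bias per output node; non-links
are structurally absent from the parameter vector, not zeroed after the
fact. Every layer is preceded by batch normalisation *without* learnable
scale or shift, so each layer sees inputs with approximately zero mean and
unit variance. This matters for interpretation: a weight then plays the role
of a standardised regression coefficient, and the simplest network (variants
to genes to output) reads as thousands of parallel gene-level regressions
feeding one logistic regression.

Classification networks use tanh hidden activations and a sigmoid output
trained with class-weighted binary cross-entropy; regression networks use
ReLU hidden activations, a linear output and mean squared error. An L1
penalty on all link weights (biases excluded) controls how many variants the
network ends up using.

## Importance and interpretation

Because batch normalisation carries no learnable affine terms, the only
learnable parameters along any output-to-input path are link weights. The
contribution of an input variant is the sum over all paths of the product of
the weights along the path; the importance of an intermediate node is the
total path mass routed through it. Relative importance normalises by the sum
of absolute importances within a layer, so shares sum to one even when signs
mix; the sign of the raw importance is kept as the direction of effect. This
is deliberately a first-order quantity: activation nonlinearities are
ignored, and the number reads like an effect size, not a significance test.
For a purely linear network the contributions are exactly the coefficients
of the output in the inputs (verified in tests against exhaustive path
enumeration).

Weight normalisation for cross-sections (Manhattan-style exports) multiplies
each weight by the empirical standard deviation of its source activation on
a user-supplied batch, correcting for the fact that batch normalisation is
only a batch-wise approximation of unit variance.

An open choice: whether intermediate sunburst rings should aggregate signed
or absolute path mass. We use absolute values throughout the ring
normalisation, because signed sums can cancel and leave shares undefined;
the per-node signed importance remains available in the table.

## Training

Mini-batch gradient descent with a batch size of 64, by Adam (learning
rates 0.01, 0.001, 0.0001) or Adadelta (learning rate 1), with early
stopping once the validation loss has not improved for 10 consecutive
epochs; weights are restored from the best-validation epoch. The monitored
validation loss is the full objective (data term plus L1 penalty), matching
common framework semantics. Model selection walks the cartesian grid of the
four optimizer settings and L1 penalties {0.1, 0.001, 1e-5, 0} — 16
configurations — picking the configuration with the highest validation AUC
(exact ties break toward the smaller penalty); the held-out test set is
touched only once, after selection. The published penalty list this grid
reconstructs contains a repeated value that is almost certainly a typo for
0.01; we de-duplicate and note that reading 0.01 instead of the second
0.001 would leave the grid size at 16.

Forward and backward passes are written out explicitly over
numpy/scipy.sparse, including the batch-normalisation backward pass and
hand-derived Adam/Adadelta updates, which keeps the package dependency-light
and single-threaded deterministic: a single seeded generator drives weight
initialisation and batch shuffling, and two runs with the same seed produce
identical histories. Correctness is established in the test suite against a
masked-dense analytic oracle and finite differences.

Numerical choices: batch normalisation uses population variance with
epsilon 1e-3 and running-moment momentum 0.99 (constant features map to
zero, never NaN); predictions are clipped at 1e-7 before logarithms; class
weights default to inverse class frequency normalised to mean one,
w1 = n/(2 n_cases), w0 = n/(2 n_controls); weights initialise uniformly in
±sqrt(6/(fan_in+1)) per output node with zero biases; batches with fewer
than two samples are skipped (a batch moment is undefined); training aborts
with diagnostics on non-finite loss. Default cap of 500 epochs for
desk-scale runs.

## Data pipeline

Genotypes arrive as VCF (GT or DS fields) or as an additive text table and
convert losslessly to a chunked HDF5 store (default 4,096-variant chunks;
conversion streams variants so peak memory does not scale with variant
count) or an in-memory matrix. Missing genotypes are imputed to the
per-variant mean and counted; non-diploid records are an error with locus
context. Monomorphic variants are removed before training. Positions are
1-based as in VCF.

Splitting is 60/20/20 train/validation/test, stratified so the case/control
ratio is preserved per set within one sample per stratum. Relatedness is
handled conservatively: the kinship graph is thresholded at 0.0625
(approximately second degree) and every connected component above the
threshold is placed wholly in the training set — the per-pair rule closed
transitively, which is the only self-consistent reading — so validation and
test sets contain only mutually unrelated samples. If relatedness leaves too
few unrelated samples to fill the requested validation/test sizes, the split
fails with the achievable ratios rather than silently rebalancing.

## The simulator

The generator is the standard liability-threshold construction — the model
under which a "theoretical maximum AUC versus heritability" curve is well
defined — with every knob exposed. Per-variant minor allele
frequencies are uniform on a range, dosages Binomial(2, MAF), independent
across variants and samples (no linkage disequilibrium, no population
structure, no imputation noise — so passing tests speak to statistical
behaviour, not to robustness against cohort artefacts). The liability is

    L = sqrt(h2) * g + sqrt(1 - h2) * e,   e ~ N(0,1),

with g the standardised genetic score, so the realised liability-scale
heritability equals the configured h2 by construction; cases are samples
with L above the standard-normal quantile of 1 − prevalence.

Two causal architectures:

* **additive** — round(polygenicity · m) variants receive N(0,1) effects.
  Defaults: 5,000 samples, 20 genes × 10 variants, MAF ~ U(0.05, 0.5),
  h² = 0.5, polygenicity 0.1, prevalence 0.5 (balanced case-control).
* **pairwise_and** — each causal gene carries two causal variants and
  contributes 1 to the genetic score only when a sample carries at least one
  minor allele at *both*; a non-linearity that a single-variant linear model
  cannot fully capture and that rewards grouping interacting variants within
  one gene node. Defaults: 2 causal genes of 20, h² = 0.9 (the construction
  emulates a near-deterministic two-hit disease mechanism), MAF ~ U(0.1,
  0.5) so joint carriers are common enough to learn from.

Alternative prevalences are supported, with an ascertainment helper that
downsamples to a chosen case fraction after thresholding.

The **theoretical maximum AUC** at heritability h² and prevalence K is the
AUC of the Bayes-optimal genotype score — the genetic liability g itself —
computed by numerical integration of the conditional densities of g given
case/control status on a 200,001-point grid over ±8 genetic standard
deviations (exact limits 0.5 at h² = 0 and 1.0 at h² = 1 are returned
directly). The value is invariant to the case/control mix of the sample.
Tests confirm agreement with a 10⁶-draw Monte-Carlo oracle to ±0.002.

## Baselines and bounds

The LASSO baseline is a single sigmoid neuron over all variants with L1
weights, trained by the same loop (batch normalisation disabled so
coefficients stay on the dosage scale); with zero penalty and unit class
weights it reproduces reference unpenalised logistic regression coefficients
to well below 1e-3 on fixtures. Random-comparator networks keep the shape
and exact link count of a template but place links uniformly at random
(rejecting draws until every output keeps a link, at most 100 retries), so
annotated-versus-random comparisons are capacity-matched by construction.
The genetics-only performance ceiling takes the monozygotic-twin concordance
c and prevalence K as explicit inputs — no literature value is embedded —
and returns sensitivity ≤ c, specificity ≤ 1 − K, accuracy ≤
(c·n_cases + (1−K)·n_controls)/n.

## Problem sizes and study conditions

The simulation studies shipped with the package use desk-scale sizes chosen
once: the interaction demonstration at n = 5,000 with 10 seeds; the
heritability grid h² ∈ {0.1, 0.5, 0.9} × n ∈ {1,000, 5,000, 20,000} with 5
seeds per cell and 200 variants; null-label calibration at n = 2,000 with 5
seeds. Training for these studies uses one of the grid's own configurations
(Adam, learning rate 0.01, penalty 1e-5, at most 50 epochs with patience
10). The architecture decision to append a final all-to-one layer only when
the last connectivity matrix has more than one output keeps the output node
distinct from pathway nodes in every realistic hierarchy.

## Known limitations

* Importance is first-order: strongly interacting paths through saturating
  activations are summarised by weight products only.
* The simulator's independence assumptions mean recovery results do not
  speak to linkage disequilibrium leakage between neighbouring genes.
* Training is plain CPU numpy; it is meant for annotation-scale sparse
  networks (up to a few hundred thousand links), not for millions of
  variants on GPU.
* Variants annotated to several genes are linked to every annotated gene;
  no weight sharing or precedence is applied.
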