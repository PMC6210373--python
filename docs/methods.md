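# Methods

`nirselect` implements a wrapper feature-selection workflow for
classifying samples from near-infrared (NIR) absorbance spectra:
Savitzky–Golay de-noising, Mahalanobis-distance outlier removal,
principal-component extraction, genetic-algorithm (GA) selection of a
fixed-size subset of the candidate principal components (PCs), a
binary-decision-tree multiclass soft-margin SVM with Gaussian RBF kernel,
and per-class evaluation criteria.  Because no suitable public spectral
dataset accompanies this problem setting, a synthetic-spectra generator
with a planted, fully known class structure is a first-class part of the
package; every stage is validated against it.

## Pipeline model and assumptions

**Input.** A wide table of N spectra × P absorbance points on a strictly
monotonic wavenumber grid (the emulated instrument records P = 2084
points from 12,000 down to 3499 cm⁻¹), plus a categorical label per
sample.

**Savitzky–Golay smoothing** (`preprocessing.SavitzkyGolay`): each point
is replaced by the value of a least-squares polynomial of order
`poly_order` (default 2) fitted over a centred sliding window of
`window` points (default 121).  At the spectrum edges the window
polynomial is fitted asymmetrically (scipy's `mode="interp"`), so output
length equals input length and the rest of the pipeline keeps a fixed
grid.  The filter is linear and reproduces polynomials up to its order
exactly; on unit white noise the interior output variance equals the sum
of squared filter coefficients (both properties are tested).

**Outlier removal** (`preprocessing.MahalanobisOutlierDetector`): the
Mahalanobis distance of each spectrum to the mean spectrum, computed by
default in a top-25 PC-score representation because the raw P×P
covariance is singular when N ≪ P.  The covariance is regularised as
S + λI with λ = `shrinkage` · trace(S)/dim (default shrinkage 1e−6).
Samples beyond sqrt(χ²₀.₉₉₉(dim)) are dropped (quantile configurable);
survivors keep their order.  Both the representation and the threshold
are package choices — the workflow this reproduces does not specify
them — and are exposed in the configuration.

**PCA** (`decomposition.SpectralPCA`): classical mean-centred PCA with
1/(N−1) covariance normalisation, computed through an SVD of the centred
data for numerical stability.  Components are ordered by descending
eigenvalue; the "information" of a component set is the sum of its
explained-variance ratios against the *total* variance over all P
points.  The largest-magnitude entry of each loading is made positive so
fits are reproducible across BLAS builds.  The top K = 25 components
(configurable) form the candidate pool for subset selection.

**Binary SVM** (`svm.BinaryRBFSVM`): the standard soft-margin dual —
minimise ½αᵀQα − 1ᵀα with Q_ij = y_i y_j K(x_i, x_j), subject to
0 ≤ α_i ≤ C and Σα_i y_i = 0 — with the Gaussian kernel
K(x, y) = exp(−‖x−y‖²/(2σ²)).  The dual is solved by libsvm's SMO
(called at the low level for speed; a unit test pins the resulting
decision function to sklearn's `SVC` bit-for-bit, and an active-set
brute-force oracle verifies dual optimality and the KKT constraints on
small problems).  The fitted machine is stored explicitly (support
vectors, dual coefficients α_i y_i, bias), so the decision function is
evaluated in-package and models serialise to JSON.  Defaults C = 2,
σ = 2, chosen in the reproduced workflow by grid search with 5-fold CV;
`evaluation.grid_search_params` reproduces that procedure over a
half-power-of-two grid 2^(i/2), i = −4..4, with ties broken toward
smaller C then smaller σ.

**Multiclass scheme** (`svm.TreeSVM`): an inverted binary tree over the
class set; each internal node splits its classes into two groups and
trains one binary SVM to route samples, so Q classes need exactly Q − 1
machines.  The grouping rule is not specified by the reproduced
workflow; the default policy (`centroid`) runs a deterministic 2-means
on the class-mean score vectors, seeded with the two most distant means;
an `ordered` policy (first half of the sorted labels goes left) is
provided for fully forced topologies in tests.  PC scores enter the SVM
as-is (centred by PCA, no further standardisation).

**Genetic subset selection** (`ga`): an individual is a 0/1 mask over
the 25 candidate PCs with fixed cardinality k.  Fitness is the
stratified 5-fold cross-validated accuracy of the tree SVM on the masked
training-score columns (pooled over folds; fold assignment seeded, so a
run's fitness landscape is deterministic and cacheable by mask).
Selection is fitness-proportionate roulette; reproduction is one-point
crossover (probability 0.6) and uniform per-bit mutation (probability
0.01); after every variation a repair operator restores cardinality k by
randomly clearing surplus or setting missing bits.  The best individuals
are copied into the next generation unchanged (elitism), which makes the
best-fitness trace non-decreasing.  Termination: `max_generations`
(default 100) or no best-fitness improvement greater than 1e−6 for
`stagnation_generations` (default 20).  Defaults mirror the reproduced
study (population 200, 100 generations, crossover 0.6, mutation 0.01).

**Evaluation** (`evaluation`): stratified random 80/20 split with the
training count rounded *up* (332 samples → 266/66, matching the
reproduced study's printed counts; sklearn's float `train_size` floors
and would give 265/67).  Per class, one-vs-rest confusion counts feed
sensitivity nTP/(nTP+nFN), specificity nTN/(nTN+nFP), precision
nTP/(nTP+nFP) and F1 = 2nTP/(2nTP+nFP+nFN); overall prediction accuracy
is n_correct/n_total.  F1 equals the harmonic mean of precision and
sensitivity wherever both are defined; zero-denominator ratios are
reported as NaN with a warning.

## The synthetic-spectra generator

`synthetic.generate` emulates the four-region study conditions: class
counts 38/144/70/80 (total 332), 2084-point descending grid, absorption
peaks near 4004, 4313, 4727 and 5163 cm⁻¹ on a smooth envelope, plus a
per-sample quadratic baseline drift (sd 0.002) and white noise
(sd 0.002).  Latent structure:

* Twelve smooth orthonormal latent directions (random Gaussian-bump
  mixtures, Gram–Schmidt orthogonalised) with a geometric total-variance
  schedule 2.0 · 0.65^(j−1).  The realised per-component total variance
  is rescaled to this schedule exactly, so the population PCA rank order
  equals the configured order, and the 0.65 decay keeps adjacent
  eigengaps large enough that sample eigenvectors at N = 332 align with
  the latent directions.
* Class signal only on the configured `informative_ranks` (default
  {1, 6, 7, 8, 10, 11}, deliberately including low-variance ranks so
  "less informative" PCs are the class-discriminative ones).  Each
  informative component carries a mean contrast between one pair of
  classes (pairs in lexicographic order), separating that pair by
  0.5 · `effect_size` within-class standard deviations on that
  component.
* With unequal class counts, such pairwise contrasts couple the
  informative components through the rank-(Q−1) between-class
  covariance, which would rotate the population principal axes away
  from the latent directions and smear the signal into the top PCs.
  The generator cancels the off-diagonal part of that between-class
  covariance with a shared (class-independent) correlation of the
  within-class noise: Cov_within = I − offdiag(B).  The population
  covariance is then exactly diagonal in the latent basis.  Positive
  definiteness bounds the achievable contrast; if needed the offsets are
  shrunk to keep the smallest within-covariance eigenvalue at 0.15
  (at the default class counts this caps the per-pair separation near
  2.1 within-sd units, i.e. effect sizes up to ≈ 4.2 take full effect).

`effect_size = 0` plants no signal (any classifier sits at chance);
accuracy is monotone in `effect_size` (tested over {0, 1, 2, 4}).

What the generator does **not** emulate: real NIR physics (radiative
transfer, water bands, scatter effects needing MSC/SNV correction),
instrument drift between batches, nonlinear detector response, or
label noise.  Passing tests therefore demonstrate that the pipeline
recovers a planted linear-latent class structure under realistic
dimensions and imbalance — not that it would reach any particular
accuracy on real leaf spectra.

## Study conditions used by the acceptance script

The published headline accuracies of the workflow this package
reproduces depend on a proprietary 332-spectrum dataset and are not
reproducible; the acceptance script instead recomputes the data-free
worked examples (split arithmetic, class accounting, F1 identities),
verifies the SVM dual and the GA against brute-force oracles, and runs
the full pipeline on the synthetic preset.  The planted-signal runs use:
tobacco-like preset with `effect_size = 4.0` (strong signal), C = 2,
σ = 2, GA at k = 6 with population 64, at most 100 generations,
stagnation window 40 and `elitism_count = 6`, for 20 independent seeded
runs (10 of them also evaluated on the held-out split).  Population 64
rather than 200 keeps twenty full runs within a single-CPU session; the
enlarged elitism compensates for the weak selection pressure of
fitness-proportionate roulette when all fitness values cluster near 0.8
— with a single elite the incumbent reproduces too rarely for the GA to
finish refining the last one or two bits of the mask.  The library
defaults remain the reproduced study's values (population 200, elitism
1).

## Numerical choices

* SVM solver tolerance: 1e−6 in `BinaryRBFSVM` (KKT contract); the GA's
  fitness evaluator uses libsvm's default 1e−3, since CV accuracy is
  insensitive to it and a GA run evaluates thousands of masks.
* Grid-search ties: smaller C, then smaller σ.
* GA fitness cache: keyed by mask bits; revisited individuals are not
  re-evaluated.  All-zero-fitness populations fall back to uniform
  parent selection (logged).
* Roulette selection requires non-negative fitness (accuracies always
  are).
* One global seed fans out to per-stage seeds via
  `numpy.random.SeedSequence.spawn`, so stages can be re-run in
  isolation; two runs with the same configuration and seed produce
  byte-identical artifacts.
* Degenerate inputs raise early: even/oversized SG windows, N < 3 for
  covariance estimation, single-class SVM fits, empty masks, classes
  smaller than the CV fold count, infeasible subset sizes.

## Known limitations

* The decision-tree multiclass scheme is order-dependent under the
  `centroid` policy when class means are nearly coincident; with no
  mean structure at all the split becomes arbitrary (though still
  deterministic).
* Mahalanobis outlier detection in PC space inherits the PCA's
  sensitivity to the very outliers it screens; for heavily contaminated
  data an iterative or robust-covariance variant would be preferable.
* The GA with fitness-proportionate selection has weak late-stage
  selection pressure; for small fitness gaps expect to rely on elitism
  and longer stagnation windows, as the acceptance conditions do.
* `BinaryRBFSVM` relies on scikit-learn's low-level libsvm binding; an
  equivalence test against the public `SVC` interface guards against
  API drift.
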