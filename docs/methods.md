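# Methods

## Problem and data model

Mammalian methylation arrays measure DNA methylation at a common set of
conserved CpG probes across many species. A compendium of such data has
individual samples (rows) over probes (columns), each sample carrying a
species label and a tissue label, with beta values in [0, 1]. Because
samples are collected opportunistically, only a small fraction of the
species × tissue grid is observed. The quantity of interest is the
*species-tissue combination mean sample*: the per-probe average over all
individuals of one (species, tissue) pair. The package imputes
combination mean samples for pairs that were never profiled, provided
the species was profiled in some other tissue and the tissue in some
other species.

Label vocabularies are sorted lexicographically so the one-hot encoding
(species block of width S, then tissue block of width T) is
deterministic across runs. Beta matrices are stored samples × probes;
missing values are rejected at load time (an opt-in flag fills them
with per-probe means, default off).

## The conditional variational autoencoder

The imputation model is a CVAE. The encoder (recognition network) maps
the concatenation of a sample x ∈ [0,1]^M and its one-hot label
y ∈ {0,1}^(S+T) through fully connected hidden layers to two parallel
linear heads: the posterior mean μ ∈ R^Z and σ ∈ R^Z, the elementwise
log of the diagonal posterior covariance. Storing the log-variance
makes the losses numerically stable. A latent draw uses the
reparameterization trick,

    z = μ + exp(σ/2) ⊙ ε,   ε ~ N(0, I_Z),

keeping the Monte-Carlo estimate of the evidence lower bound
differentiable. The decoder (generation network) maps (z, y) through
the mirrored hidden stack to M raw logits; the logistic of the logits
is the beta-scale reconstruction.

Training minimizes

    L_TRAIN = L_RECON + L_REG,

where L_RECON is binary cross entropy with the beta values as soft
targets, computed in logits form and summed over probes, and

    L_REG = ½ Σ_k (exp σ_k + μ_k² − 1 − σ_k)

is the closed-form KL divergence of the posterior from N(0, I). The
evidence lower bound is a log-likelihood to be maximized; the
implementation minimizes its negation (standard BCE plus KL), the only
reading consistent with gradient-descent training. Within a sample both
terms are sums; across a batch the objective is the mean, keeping the
loss on a per-sample scale regardless of batch size. One Monte-Carlo
draw per sample per step is used (configurable).

The forward pass, backpropagation and the Adam optimizer are
implemented directly in numpy. A single seed drives weight
initialization (Glorot uniform), batch shuffling and the ε draws, so
training is bit-reproducible. A NaN/inf step loss aborts training with
the offending epoch index.

### Hyperparameters

Defaults are the winning grid-search combination on the real
compendium: two hidden layers (1024, 512), tanh, latent dimension
Z = 8, learning rate 1e-3, Adam epsilon 1e-4. Epochs (100) and batch
size (32) are training-budget settings; there is no early stopping —
model selection happens only through the validation grid search, which
trains each candidate, imputes every validation combination, and picks
the candidate with the highest mean sample-wise Pearson correlation
(ties go to the first candidate in grid order). The shipped default
grid leads with the winning combination plus small perturbations of
latent dimension and learning rate, and is fully overridable.

### Imputation

Imputation is individual-agnostic by construction: instead of encoding
an existing sample, a latent vector is drawn from the standard normal
prior — the distribution the posterior is regularized toward — and
decoded with the target one-hot label; the logistic of the decoder
output is the imputed combination mean sample. On a trained model the
specific latent draw has minimal impact (imputations from different
draws correlate > 0.99); the label drives the output. Grid imputation
derives a deterministic per-target sub-seed from the request seed and
the target's position in the sorted full grid, so results are
reproducible and independent of target ordering. Multiple draws per
target, averaged on the beta scale, are supported (default 1).

## Baselines

Three mean baselines impute a target (s, t) as the per-probe average of
all training samples of species s (any tissue), of tissue t (any
species), or of the entire training set. The logistic baseline fits one
L2-penalized logistic regression per probe on the one-hot labels with
soft targets: every training row enters twice, once with class 1 and
sample weight β (the probe's beta value) and once with class 0 and
weight 1 − β, so the fitted positive-class probability is the predicted
methylation value. The penalty is written λ‖W‖² with the intercept
unpenalized; scikit-learn's inverse-regularization convention is
converted as C = 1/(2λ), a mapping unit-tested against a brute-force
optimizer on the explicit loss. λ is tuned over {1, 2, 4, 8, 16} by
validation sample-wise Pearson (ties to the smallest λ).

## Evaluation statistics

Sample-wise metrics compare an imputed and an observed combination mean
across probes (Pearson, MSE), one value per combination; probe-wise
metrics are the transpose. Correlations undefined because one vector is
constant are reported as missing and excluded from aggregate means
rather than set to zero.

Three per-probe variances stratify probe-level results, all computed
from combination means (so unequal individual counts cannot skew them)
with population (1/n) normalization: inter-combination variance (across
all combination means), mean inter-tissue variance (across-tissue
variance within each species having > 1 tissue, averaged over those
species) and mean inter-species variance (the symmetric quantity over
tissues). On a fully crossed grid with additive combo means the
inter-combination variance decomposes exactly into the sum of the other
two — a property test. Quartile summaries rank probes by a chosen
variance (stable sort, ties by probe index) and cut them into four
near-equal groups.

Species/tissue signal is quantified as an AUC: all unordered pairs of
distinct combination means are scored by their Pearson correlation, a
pair is positive if it shares the species (or tissue), and the AUC uses
the Mann-Whitney rank formulation with ties credited 0.5 — hence
invariance to monotone transforms of the scores. Pairs with undefined
correlations are dropped; a fully degenerate grid (e.g. the species
baseline after species-signal removal, which is identically zero)
scores 0.5. Species-signal removal subtracts each row's same-species
training average, leaving tissue-specific residuals in [−1, 1].

Method pairs are compared per combination by the two-sided Wilcoxon
signed-rank test (zero differences dropped; exact distribution for
n ≤ 25, normal approximation above) together with the fraction of
combinations where one method strictly beats the other.

Individual-to-individual variability — the mean pairwise correlation of
same-combination individuals, averaged unweighted over combinations
with ≥ 2 individuals — provides the ceiling any imputation can aim for.

## Cross-validation

Only combinations whose species has ≥ 2 observed tissues and whose
tissue has ≥ 2 observed species are eligible test targets; these are
partitioned uniformly at random into k = 5 folds. Within a fold, the
remaining combinations are split into training and validation: 20% are
drawn as candidate validation, any candidate lacking a same-species or
same-tissue combination in candidate training migrates to training, and
if fewer than 10% survive the draw is repeated with a fresh sub-seed
(cap 1000 attempts; exhaustion is an error, never a silent relaxation).
Test combinations without both same-species and same-tissue training
data are dropped from evaluation, mirroring the availability rule of
the source protocol. Per-combination metrics are concatenated across
folds before summarizing. λ tuning uses the same training/validation
split as the CVAE grid search within each fold.

## Lifespan regression

Log (natural) maximum lifespan is regressed on combination mean
methylation in a leave-one-species-out scheme. Tissue-agnostic mode
uses one species-average row per species (unweighted over its
tissues); tissue-specific mode keeps combination rows, with every row
of a species sharing its log-lifespan and all held out together. The
per-tissue summary restricts to tissues predicted in ≥ 3 species
(Pearson over one or two points is not meaningful) and averages
unweighted over included tissues. With far more probes than species the
least-squares problem is underdetermined; the minimum-norm solution
(scikit-learn's `LinearRegression`, which calls lstsq) is used, the
only canonical choice in that regime.

## Synthetic data generator

The generator emulates the compendium's structure: probe baseline
logits g_m ~ N(0, 1.5²), species effects a_{s,m} ~ N(0, 1.5²), tissue
effects b_{t,m} ~ N(0, 0.5²) and an optional phylogenetic-group effect
(default off). The true combination mean is the inverse logit of the
summed effects, which keeps means in (0, 1) and makes effects additive
on the logit scale. Species effects are three times larger than tissue
effects, reproducing the empirical dominance of species identity over
tissue identity in pairwise correlations of real combination means
(species AUC near 1 versus a modest tissue AUC). Individuals are drawn
from Beta(μκ, (1−μ)κ) with concentration κ = 100 — about ±0.05 noise at
mid-range methylation, giving individual-to-individual correlations
near 0.98, comparable to real arrays — rather than Gaussian noise,
which would leave the unit interval. Default size is 20 species × 6
tissues × 300 probes with 3 individuals per observed combination and
70% of the grid observed; the observed subset is redrawn until every
held-out combination keeps ≥ 1 same-species and ≥ 1 same-tissue
observed combination.

The synthetic lifespan table makes log-lifespan a linear function of
the species-average methylation at a few chosen probes, plus optional
Gaussian noise; the chosen probes and coefficients are returned so
recovery can be checked against the known rule.

What the generator does not emulate: phylogenetic correlation between
species effects (real species resemble their relatives; synthetic
species are independent), probe-level mappability biology, age/sex
covariates, and batch structure. Two consequences matter for
interpreting results. First, passing recovery tests shows the machinery
learns additive species/tissue structure from labels, not that it
handles every pathology of real arrays. Second, with independent
species effects and many more probes than species, a held-out species'
features are nearly orthogonal to the training row space, so the
minimum-norm lifespan regression cannot extrapolate — unlike on real,
phylogenetically correlated data. The noiseless lifespan recovery
fixture therefore uses more species than probes (30 species × 4 tissues
× 20 probes), the identifiable regime where ordinary least squares
recovers the generating rule exactly.

## Numerical choices

- BCE is evaluated in logits form, `max(l,0) − l·x + log1p(exp(−|l|))`,
  stable for large |l|.
- Beta draws are clipped to [1e-6, 1 − 1e-6] to guarantee the open
  interval.
- Logistic fits: lbfgs, gradient tolerance 1e-8, iteration cap 10,000;
  exceeding the cap raises with the probe index.
- Quartile boundaries use a stable argsort (ties broken by probe
  index) and `array_split` sizing (earlier groups take the remainder).
- Grid-search and λ-tuning ties resolve to the first candidate /
  smallest λ.
- All seeds are plain integers or tuples fed to
  `numpy.random.default_rng`; derived sub-seeds are generated by
  `SeedSequence` and kept below 2³¹.

## Problem sizes used in tests and the acceptance script

Desk-scale runs use the default synthetic fixture (20 × 6 × 300, 3
individuals per combination) for the recovery experiment, an 8 × 4 × 80
fixture with a (128, 64) network for unit tests, and the 30 × 4 × 20
fixture for lifespan recovery. These sizes were chosen so the full
suite exercises every stage — training, grid search, cross-validation,
imputation, evaluation, regression — in minutes on one CPU while
leaving each statistical property comfortably detectable.

## Known limitations

- The CVAE runs on CPU numpy; it is intended for method-level work and
  desk-scale data, not for training on tens of thousands of samples
  with 37k probes (that regime wants a GPU framework).
- The latent prior is the unweighted standard normal; no β-VAE
  weighting or alternative priors.
- Lifespan regression performs no phylogenetic correction (no PGLS);
  predictions on real data inherit phylogenetic pseudo-replication.
- The generator's independence assumptions understate the difficulty
  of separating species from order-level signal in real compendia.
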