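# Methods

## Feature model

The ICO vector treats each metagenomic sample as one integrated pool of
reads. Counting uses overlapping windows with stride 1 that never span read
boundaries; windows containing any non-A/C/G/T letter (N or other IUPAC
codes) are skipped. For a k-mer split into prefix *i* (length *m*) and
suffix *j* (length *n = k − m*):

* *p_ij* = count of the k-mer *i·j* divided by the total k-mer count;
* *p_i*, *p_j* come from **independent sliding-window counts at lengths m
  and n**, not from marginals of the k-mer table — the two definitions
  differ at read boundaries, and the independent counts match the
  probabilistic definition of an occurrence frequency at each length;
* *p_{j|i}* is row-normalized over k-mer counts sharing prefix *i*, so the
  conditional rows sum to exactly 1 despite boundary effects.

Zero conventions: a zero junction count gives *f_ij* = 0 and contributes 0
to *I(i)* (0·log 0 ≡ 0); a zero *p_i* or *p_j* zeroes every term involving
it. These cases carry no correlation signal, and the convention avoids
division by zero. An optional pseudocount (default 0, added to every cell
of every count table) is exposed for sensitivity analysis. K-mers are
counted as read, with no reverse-complement canonicalization.

Component order is fixed: splits *m* = 1 … *k* − 1, within each split the
f-block lexicographic in *i* then *j* (A < C < G < T) followed by the
I-block lexicographic in *i*; names are `F:<m>:<i>:<j>` and `I:<m>:<i>`
(`C:<kmer>` for the composition baseline). This makes feature selection and
serialization bit-reproducible.

Normalization is min-max **within each sample's vector** — the components
of one vector span very different magnitudes (f-ratios near 1, I-values
near 0) — mapping it to [0, 1]; a constant vector maps to zeros. Per-column
scaling across samples is deliberately not used. The same normalization is
applied to composition vectors by default.

Labels: the positive (diseased) class maps to +1; when the caller does not
designate it, the lexicographically later label is used and a notice
logged.

## Kernel PLS and feature weights

Kernel PLS is kernel NIPALS on the double-centered kernel with response
deflation (see the `kpls` module docstring for the recursion). With a
linear kernel the component scores equal classical NIPALS PLS1 scores on
centered data to machine precision, which the tests verify against an
independent textbook oracle. The default kernel is gaussian with the
median heuristic (γ = 1 / median nonzero pairwise squared distance), which
removes a free parameter; a linear kernel is available by flag. The
default number of components is min(5, N − 1).

Per-feature importance is the response-loading-weighted squared covariance
between each centered, unit-norm feature column and the score components,
`w_j = Σ_a q_a² (x̃_j · t_a)²` — a VIP-style score. This is the single most
consequential design choice in the module; it is isolated behind
`feature_weights` so an alternative formula can be substituted without
touching the selection recursion. Ranking ties break by canonical feature
name, making selection deterministic.

## Selection and evaluation protocol

Feature selection runs on the **full training set**; LOOCV evaluates only
classifier training at each rung. The recorded accuracies therefore carry
selection optimism and are model-selection scores, not unbiased error
estimates — on null data the selected features correlate with the labels by
construction. The optimal round maximizes accuracy with ties going to the
smaller set, the only reading of "maximal accuracy with minimal components"
that is always unique. The full-dimension rung (round 0) is evaluated and
eligible too, so a single-rung ladder degenerates cleanly to a plain SVM.

SVM defaults are rbf kernel, C = 1, γ = 1/(n_features · Var(X)),
configurable. LOOCV folds that contain a single class (only possible for
tiny inputs, e.g. one sample per class) fall back to majority-class
prediction with a logged warning rather than erroring.

The stability test draws stratified training subsets without replacement
(per-repeat sub-seeds derived from a master seed by counter) and reports
the spread of optimal LOOCV accuracies; the generality test trains once and
reports the spread of F1-measures over held-out subsets, F1 because test
subsets may be class-imbalanced. The paired t-test is two-sided with the
sample (n − 1) standard-deviation convention; zero-spread differences make
the statistic undefined and are reported as NaN rather than raised.

## Synthetic data generator

Each taxon is a stationary order-2 Markov chain (Dirichlet(1.0) transition
rows; initial contexts drawn from the chain's stationary distribution, so
no burn-in is needed). Order 2 is rich enough that ICO at k ≥ 3 carries
signal beyond mononucleotide composition yet cheap to simulate. The
between-class signal is purely compositional: both classes share one taxon
pool and one Dirichlet(2.0) mixing draw π, and class *c* mixes with
(1 − δ)·π + δ·restrict_c(π), where restrict_c renormalizes π on class *c*'s
half of the taxon pool. δ = 0 gives identical classes, δ = 1 disjoint
taxon support. This emulates beta-diversity differences between cohorts; it
does **not** emulate sequencing errors, quality variation, real genome
structure (repeats, genes, strand asymmetry), uneven sample depths, or
host-derived reads — so passing tests demonstrate the machinery recovers
compositional signal under clean conditions, not clinical performance.

Default study conditions used by the end-to-end checks: 5 taxa, 20 samples
per class, 5000 reads × 100 bp per sample (0.5 Mb — enough for stable 4-mer
ICO estimates), k = 4, ladder 852 → 100 → 20, divergence 0.5 with a
divergence-0 null control. The planted-feature benchmark uses 40 samples
with 10 informative columns (between-class mean shift 2.0) among 990
standard-normal noise columns, ladder 1000 → 100 → 10, 20 seeds. The
acceptance script runs the stability/generality protocols at 10 repeats
with 12 training samples per class on the divergence-0.5 dataset.

## Numerical notes and known limitations

* LOOCV on balanced null data is anti-conservative in the *downward*
  direction: with no usable signal the SVM's near-constant kernel makes it
  predict the training fold's majority class, which is always the held-out
  sample's opposite, driving accuracy toward 0 rather than 0.5. This is a
  well-known LOOCV artifact, visible in the divergence-0 control; the null
  tests therefore assert "no better than chance", the scientifically
  meaningful direction.
* KPLS component extraction stops early when the deflated kernel no longer
  covaries with the residual response (norm < 1e-12); a response orthogonal
  to every centered kernel column yields a zero component with zero
  loading.
* Feature-matrix TSV round-trips are exact: writing uses shortest
  round-trip float repr and reading uses round-trip float parsing.
* Dataset generation is byte-deterministic under the master seed, with
  per-sample seeds derived by counter so samples regenerate independently.
* Only binary classification is supported; there is no probability
  calibration, hyperparameter search, multi-class support, or
  quality-based read filtering (pre-processing is the caller's job).
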