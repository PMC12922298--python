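# Methods

## The statistic

Inter-subject functional connectivity (ISFC) is the Pearson correlation
between region *i*'s time series in one subject and region *j*'s series
in a different subject, both watching the same naturalistic stimulus.
Signals not locked to the stimulus — intrinsic connectivity, scanner
noise, head motion (as long as motion is not synchronized across
subjects) — are uncorrelated across brains, so ISFC isolates
stimulus-driven coupling.

We compute the *pairwise* variant: one R×R matrix per unordered subject
pair within a group, rather than the leave-one-out average form. Because
connection directionality is not analyzed, each pair matrix `C` is
symmetrized as `(C + Cᵀ)/2` before anything else; symmetrization is a
projection, so the order "symmetrize each pair, then take the median" is
the one implemented (medians of symmetrized matrices are not the same as
symmetrized medians, and the per-pair order is the one that matches the
symmetrized-matrix interpretation). The group summary is the entrywise
**median** across pair matrices, chosen over the mean because pairwise
correlation values are non-normal and pairs sharing a subject are
dependent. No Fisher z-transform is applied before the median: the
median is equivariant under monotone transforms, so the median of r
equals the back-transformed median of z and the step would be a no-op.

The diagonal of each pair matrix is the (symmetrized) inter-subject
correlation (ISC) of a region with itself across brains. It is computed
and stored but excluded from the R(R−1)/2 unique-pair accounting and
from every difference, significance and replication statistic.

## Cleaning chain

Input series are atlas ROI tables (T rows × R regions). The design
matrix is `[intercept, linear trend, 6 motion parameters, white matter,
CSF, discrete-cosine basis]`, fitted jointly in a single least-squares
pass per region — sequential residualization is order-dependent and is
deliberately avoided. All-zero regressor columns are dropped as inert;
any remaining rank deficiency is an error naming the collinear columns
(QR with column pivoting). Residuals are shifted to zero mean and scaled
by the sample (T−1) standard deviation. Cleaning is idempotent to 1e−8.

* **DCT basis**: the K = ⌊2·T·TR/cutoff⌋ lowest non-constant cosine
  terms, cutoff 128 s (the fMRIPrep default; periods longer than the
  cutoff are removed). Columns are mutually orthogonal; K = 0 returns an
  empty basis with a warning.
* **Framewise displacement**: Power-style sum of absolute backward
  differences of the three translations (mm) plus 50 mm × the rotation
  differences (radians), FD[0] = 0 — the fMRIPrep convention.
* **Exclusion**: subjects with mean FD strictly above 0.5 mm are
  dropped before analysis; a subject at exactly 0.5 is retained. The
  rule is applied per run (single-run semantics).

## Permutation inference

The observed statistic per region pair is the within-group-1 median
ISFC minus the within-group-2 median. Because every pooled subject
pair's matrix is precomputed once (`PooledPairTensor`), a label shuffle
only changes which pairs count as within-group, making 5000 permutations
cheap. Shuffles reassign whole subjects (never time points), preserve
the observed group sizes, and are drawn uniformly; when the number of
distinct label assignments is at most the requested count the null is
enumerated exhaustively instead (with a warning).

Significance is called per pair from that pair's own null percentiles
(not a pooled null across pairs): two-sided, beyond the 97.5th/2.5th
percentile for α = .05 and 99.5th/0.5th for α = .01, uncorrected for
multiple comparisons. P-values use the add-one convention
`p = (1 + #{|null| ≥ |obs|}) / (1 + B)`, so p is never zero and the test
is valid (conservative) at any B. Masks are signed: +1 where group 1 >
group 2 significantly, −1 for the reverse.

The per-ROI count map tallies each region's significant positive and
negative connections (diagonal excluded); each significant pair
contributes to exactly two regions.

The motion-synchronization check applies the same machinery to a scalar
statistic: pairwise Pearson correlations of FD traces (frame 0 dropped —
FD is undefined there) and a permutation test of the within-group median
coupling difference.

## Replication statistics

With a discovery and a replication mask on the same region order, the
overlap matrix is their entrywise sum; ±2 marks same-sign
co-significance. Replication **requires matching sign** — same indices
with opposite signs count as non-replicated. The rate divides the number
of ±2 upper-triangle cells by the discovery mask's significant-pair
count. Its null shuffles the **replication** mask's region order (rows
and columns by the same permutation; discovery fixed — either choice is
distribution-equivalent, one is fixed for reproducibility), recomputing
the rate each time; `p = (1 + #{null ≥ obs}) / (1 + B)`.

The cross-dataset Pearson r correlates the two difference matrices over
their unique upper-triangle values; its permutation p reuses the same
ROI-shuffle null, two-sided on |r|. The rate statistic is discrete, so
the add-one p is conservative under ties; calibration tests therefore
assess uniformity after the standard randomized tie-break, and the
reported p is checked to stay on the conservative side.

## Synthetic data generator

The generator emulates the one feature that makes ISFC meaningful: a
latent stimulus shared by every subject. It is a latent Gaussian model —
the simplest family with a controllable region correlation Σᵤ and an
exact closed-form ISFC:

* `u` is a T×R Gaussian matrix, columns zero-mean unit-variance with
  correlation Σᵤ (symmetric, unit diagonal, positive semidefinite —
  validated via the smallest eigenvalue). Temporal smoothness is AR(1)
  coloring with coefficient `exp(−1/smoothness)` (smoothness in TRs),
  applied identically to every column so Σᵤ is preserved exactly.
* Subject *s* in group *g* observes `x = w_g ⊙ u + σ·ε` with white
  idiosyncratic noise ε. Latent signals have unit variance, so σ is
  directly a noise-to-signal ratio. Gains live in [0, 1].
* The population pairwise ISFC follows in closed form,
  `ρ_ij = w_i w_j Σᵤ[i,j] / √((w_i²+σ²)(w_j²+σ²))`, including the
  diagonal (the ISC). Every downstream computation is validated against
  this oracle.
* Group differences are planted via the gain vectors, not via
  group-specific Σᵤ, keeping the stimulus genuinely shared. The default
  planted effect (gains 0.9 vs 0.3 on five coupled regions, Σᵤ = 0.5
  among them, σ = 1) gives expected ISFC gaps around 0.18 — bracketing,
  not matching, the 0.08–0.16 range of maximal median differences
  plausible in real two-site movie data, since no empirical effect-size
  estimate is available to calibrate against.
* Confounds: motion parameters are independent per-subject Gaussian
  random walks. Mean FD is exactly linear in a global step scale, so one
  rescale from the realized to the target mean FD calibrates it to
  machine precision (an iterative search would converge to the same
  point). A configurable fraction of "high movers" is calibrated to mean
  FD 0.8 mm, above the 0.5 mm exclusion threshold. WM/CSF channels are
  AR(1) noise independent of the stimulus; standardized DVARS is a
  positive noise series. On disk, the first-row FD and DVARS cells are
  written as `n/a`, as fMRIPrep does.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: no hemodynamic-response convolution or
voxel-level structure; noise is white and homoscedastic (no physiological
rhythms, scanner drift beyond the removable trend, or motion-induced
signal artifacts coupled to the FD traces); gains are time-invariant (no
attention drift); and the latent stimulus is Gaussian, unlike real movie
feature time courses. Results on this model validate the *statistical
machinery*, not the neuroscience of any particular dataset.

## Default problem sizes

Simulation studies in the test suite and acceptance script use 15
regions, 200–1000 timepoints and 10–15 subjects per group — sizes at
which the permutation distributions are well resolved and the whole
suite runs in minutes while exercising every code path; the
implementation handles the 273-region case (37,128 unique pairs) through
the same vectorized routines, with the pooled pair tensor as the only
memory-relevant object (pairs × R² doubles, logged at construction).
Type-I calibration uses 200 null datasets × 500 permutations; power
checks use 1000 permutations.

## Numerical conventions and edge cases

* Correlations on standardized columns are computed as cross-products
  divided by T−1; this matches naive per-entry Pearson to 1e−10 and is
  tested against that oracle.
* Even pair counts take the midpoint of the two central order statistics
  (the standard sample median).
* Zero-variance region columns are an error at every stage that
  correlates (they should be impossible after cleaning, which already
  errors on zero residual variance naming the region).
* Percentile thresholds use linear interpolation (`numpy.percentile`
  defaults); mask and quantile outputs are derived from the same call so
  they can never disagree.
* All randomness flows through `numpy.random.Generator` seeded
  explicitly; identical seeds give byte-identical artifacts, verified
  via SHA-256 in the run manifest.

## Known limitations

* Pair matrices for all pooled subject pairs are held in memory; for
  very large cohorts × 273 regions this is a few GB and would need a
  chunked median.
* No multiple-comparison correction is offered (by design, matching the
  uncorrected two-sided percentile rule); downstream users wanting FDR
  control must apply it to the p-value matrix themselves.
* Covariate adjustment of ISFC group differences (age, sex, education)
  is out of scope: mapping subject-level covariates onto pair-level
  statistics has no single standard form, and no variant is implemented.
* The ROI-shuffle null ignores spatial autocorrelation of brain maps;
  anatomically informed nulls (spin tests) are deliberately not
  implemented.
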