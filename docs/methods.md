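# Methods

## Measurement model and quality control

The unit of measurement is the per-spot signal-to-noise ratio,
SNR = (signal mean − background mean) / background SD — the conventional
scanner definition; the quantification software's own LOWESS step is
treated as upstream of this package, which consumes post-quantification
values.  QC proceeds in a fixed order:

1. cells flagged `bad`/`empty` by manual inspection are masked;
   negative-control features are masked everywhere; positive and
   printing controls stay in the matrix but never enter marker
   statistics (excluded by category);
2. the detection filter keeps a subtracted feature when, in at least one
   (bulk, biological replicate) group, **strictly more than half** of its
   unmasked technical replicates have SNR **strictly above** the
   threshold (default 7).  With six technical replicates, 4 passes
   suffice and 3 do not; SNR exactly 7.0 does not pass.  Aggregation
   across groups is *any-group-passes*: a feature detected in one bulk
   but absent in another is precisely a candidate marker, so joint
   filtering would discard the signal of interest;
3. spike-in normalization rescales every hybridization by
   reference / (its mean spike-in SNR), the reference being the grand
   mean of the per-hybridization spike-in means.  The operation is
   idempotent and exactly removes multiplicative slide effects when the
   spike-in is measured noise-free;
4. fingerprints average unmasked technical replicates within each
   biological replicate, then biological replicates with equal weight:
   one value per feature per bulk.

Subtraction efficiency for the tester/driver validation is
100 × (n_total − n_detected)/n_total over the printed subtracted
features, reported exactly and rounded half-up (3 detected of 290 →
98.97% → 99%; removal leaves 287 analysis features).

## Univariate statistics

Group summaries use sample variance (denominator n − 1).  Fisher's ratio
(M₁ − M₂)²/(V₁ + V₂) scores univariate two-class separability; for equal
group sizes it is a monotone function of the squared pooled t, so its
ranking and the |t| ranking coincide up to the pooled/Welch distinction.
The independent-samples t-test is oriented DN − SD, two-sided, with the
pooled-variance form (df = n₁ + n₂ − 2) when a mean-centered Levene test
does not reject variance equality at α = 0.05 and the Welch form with
Welch–Satterthwaite df otherwise; df is reported exact and as printed
(integer for pooled, one decimal for Welch).  The 12 values per bulk
(2 biological × 6 technical replicates) are treated as independent
observations — the convention of the reference analysis, visible in its
df = 22 — although technical replicates are pseudo-replicates; the
resulting p-values rank features rather than control error rates, which
is why the pipeline's final call requires agreement of three criteria.
No multiple-testing correction is applied, matching the reference
procedure; a configuration hook exists but defaults off.

The Levene statistic depends on the shape of the sample, not only on
(mean, SD, n).  Exact-moment fixtures therefore reproduce printed t and
df values exactly, but cannot pin which variant an `auto` run resolves;
fixture-based checks pass the variant implied by the printed df.

## Stepwise discriminant analysis

Wilks' lambda on a feature subset is det(W)/det(T) (pooled within-group
scatter over total scatter).  Entry and removal use the partial-F
statistic F = (n − g − q)(Λ_small/Λ_large − 1)/(g − 1) with g = 2 groups
and q already-entered features, referred to F(g − 1, n − g − q); for a
single feature this equals the squared pooled t exactly.  The stepwise
loop enters the candidate with the smallest entry p while p < 0.05,
then removes entered features whose removal p exceeds 0.10; ties break
by smaller p then lexicographic feature name; candidates whose
within-group variance is ≥ (1 − 10⁻⁸) explained by the entered set are
excluded (tolerance), which bars exact duplicates.  The step bound
defaults to twice the candidate count and a repeated-subset guard stops
cycles.  Only the two-group case is implemented (the bulk comparisons
are pairwise); priors are equal by default with a proportional option.

Classification uses Fisher's linear classification functions
c_k(x) = μ_kᵀS⁻¹x − ½μ_kᵀS⁻¹μ_k + ln(prior_k) with S the pooled
within-group covariance; exact score ties go to the lexicographically
first group label.  Reciprocal validation trains on the technical
replicates of one biological replicate and tests on the other, both
directions; by default (`select_on="all"`) selection runs once on all
cases — matching a reported single feature set per comparison — with
`select_on="training"` available for fully out-of-sample selection.
When the selection is larger than a training split can support, the
pooled covariance is singular; the fit raises, and the validation
wrapper records NaN accuracies with a note instead of aborting.

## Marker selection

Set A = features stepwise-selected in any comparison, B = union of the
per-comparison Fisher-ratio top-10 (ties at the cut rank break
lexicographically), C = features with t-test p < α in any comparison
(default α = 0.05; with the reference study's printed statistics only
0.05 makes the published Venn regions internally consistent, and both
0.05 and 0.01 are exposed).  The seven-region Venn partition uses set
semantics — a feature selected in several comparisons counts once — and
the triple intersection A∩B∩C is the putative marker set.  Each marker
carries its supporting comparisons and a direction of effect (DN when
the DN-bulk mean exceeds the SD-bulk mean in its strongest comparison).

## Genome context

Genetic windows convert to physical distance under a 100 cM-per-
chromosome assumption: window_bp = round(cM/100 × chromosome length).
Distances are nearest-boundary to nearest-boundary, signed (positive =
downstream in increasing coordinates), zero on overlap, with 1-based
inclusive GFF3 coordinates; genes sort by |distance| then id.
Sequence-similarity search is out of scope — the locus is supplied as
coordinates and annotation comes from a user GFF3 plus a chromosome-
length table.

## Synthetic data

*Exact-moment fixtures.*  `exact_moment_sample` affinely transforms a
seeded normal draw so the sample mean and SD (ddof = 1) hit their
targets to ~1e−12; any statistic depending on data only through
(mean, SD, n) is then exact, which is how the reference study's t
statistics are reconstructed from its printed group statistics.

*Dosage model.*  The octoploid population simulator draws each gamete as
Binomial(ploidy/2, parent dosage/ploidy) and sums two gametes per
offspring; dosage maps to the 1–4 flowering score by thresholds
(≥6 → 1, 4–5 → 2, 2–3 → 3, ≤1 → 4 by default).  This quantifies the
hypothesis that flowering strength tracks the copy number of a
marker-linked allele; the true dosage-to-phenotype mapping in octoploid
strawberry is unknown, so thresholds and parent dosages are parameters,
not claims.  The study-emulation defaults use three 200-plant crosses
(one DN × SD with parent dosages (3, 0), two DN × DN with (3, 3)),
which reproduces the reported segregation pattern: about half the
DN × SD progeny short-day, and strong day-neutrals only as rare
transgressive segregants of the DN × DN crosses.  Bulks are sampled to
the reference sizes (2, 19, 18, 10).

*Signal model.*  SNR(f, h) = μ_f · (1 + β·D_b·1{f planted}) ·
exp(ε_fh) · g_h, with per-feature log-normal baselines
(log-mean 5, log-SD 1), bulk mean dosage D_b, independent cell noise
ε ~ N(0, σ²) on the log scale (σ = 0.35, a plausible coefficient of
variation for scanner intensities, which are positive and
heteroskedastic), and a per-slide distortion g_h (log-SD 0.2) that
spike-in normalization must undo.  β is solved from
(1 + β·D_DN1)/(1 + β·D_SD) = target ratio (default 3, the reference
marker's reported DN1/SD signal ratio); with σ = 0 the normalized
fingerprint ratio is exactly 3 and normalization removes g_h to
floating-point accuracy.

*What the generator does not emulate.*  Real slides induce strong
correlation across features (shared hybridization, background and
print-tip effects); here features are mutually independent apart from
the residual slide factor left by noisy spike-in estimation.  This has a
visible consequence: with 287 independent candidates and only 24 cases,
the stepwise entry rule (enter while the minimum p over ~280 candidates
is below 0.05) almost always finds an admissible candidate until the
residual degrees of freedom are exhausted, so selections run to ~20
features per comparison and several chance features co-populate the
Fisher top-10 and the t-significant set (all three criteria are computed
from the same 24 values).  Under these study conditions the planted
marker is recovered essentially always, but the triple intersection also
contains a few chance features per run — a property of stepwise
selection at this candidate-to-case ratio, not an implementation defect.
The reference experiment's much smaller selections (6 per comparison)
are consistent with heavy inter-feature correlation in real data, which
this generator deliberately does not model.

## Numerical and design choices

* Feature order is the printed layout order everywhere; all outputs are
  deterministic given configuration and seed, and repeated runs write
  byte-identical artifacts.
* Fingerprint tables round-trip at 12 significant digits; scan tables
  re-exported from simulated SNR use a flat synthetic background
  (mean 100, SD 10) and 6 significant digits.
* Efficiency percentages round half-up; printed df rounds to the integer
  (pooled) or one decimal (Welch).
* Degenerate inputs raise typed errors: zero background SD, zero total
  variance with distinct means, singular scatter, flowering scores
  outside 1–4, parent dosages outside [0, ploidy].
* Problem sizes in the test suite are chosen for desk-scale runs: the
  planted-marker property uses 50 seeded end-to-end runs at the full
  287-feature design; oracle comparisons use ≤6-feature instances where
  exhaustive search is exact; null calibrations use 10,000 two-sample
  draws and 1,000 permutation-style replicates.

## Known limitations

* Technical-replicate pseudo-replication is reproduced, not corrected
  (see above); absolute p-values are optimistic.
* The reciprocal-validation accuracies of the reference study are not
  reproducible without its raw hybridization values; the machinery is
  instead validated by properties (100% training accuracy on separable
  data, chance-level test accuracy on label-independent data).
* Only two-group DFA is provided; multi-group discriminant analysis and
  alternative cross-validation schemes are out of scope, as are image
  quantification, LOWESS/print-tip normalization and sequence-similarity
  search.
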