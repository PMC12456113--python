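# Methods

`betulabc` implements a complete simulation-based inference pipeline for the
Quaternary demographic history of Arctic dwarf birch (*Betula nana*,
*B. glandulosa* and their subspecific lineages) from unlinked biallelic SNP
data: a structured-coalescent SNP simulator, approximate Bayesian
computation with random forests (ABC-RF) for scenario choice and parameter
estimation, classical population-structure diagnostics, and conversion of
inferred event times to calendar years for comparison with ice-sheet
chronologies.  This note records the model, the numerical choices, and what
the synthetic-data tests do and do not establish.

## Demographic model

A scenario is a set of populations (some unsampled "ghosts") with diploid
effective sizes `Ne`, plus timed events in backward coalescent time
(generations before present):

* **divergence** — at time `t` all lineages of the derived population move
  to the ancestor (forward: the derived population splits off).
* **admixture** — two sources found a new population with proportion `ra`
  from the first; backward, each lineage of the admixed population jumps to
  source 1 with probability `ra`, else source 2.
* **introgression** — a unidirectional pulse: each recipient lineage jumps
  to the donor with probability `ri`.  Secondary contact is coded as a
  discrete pulse rather than a continuous migration interval; the pulse is
  the standard DIYABC-style discretisation and keeps the event time and
  intensity identifiable from SNP frequency data.
* **bottleneck** — `Ne` reduced to a drawn value on `[t, t + duration]`,
  encoded internally as two step changes; **ne_change** is the single-step
  variant.

Priors are uniform or log-uniform per parameter; order relations between
event times (e.g. the ancestral split predates the derived split) are
declared explicitly and enforced by rejection sampling.  Ties in event time
are broken by event-list position.

### The packaged global catalogue

Four competing scenarios over six sampled populations — Nana, Svalbard,
Exilis, an admixed Glandulosa-west × Exilis population, Glandulosa west and
Glandulosa east — plus the unsampled Tundrarum ghost:

1. **global_1** (full secondary-contact model): Nana diverges from an
   ancestral Exilis; the two Glandulosa lineages diverge from Exilis;
   Exilis × Nana admixture founds the Tundrarum ghost; Glandulosa-east →
   Glandulosa-west introgression; Exilis × Glandulosa-west admixture founds
   the Admixed population; Tundrarum → Nana gene flow; Svalbard diverges
   from Nana.
2. **global_2**: the same deep topology with divergences only.
3. **global_3**: gene flow in North America only (the Glandulosa
   introgression and the Admixed-founding admixture), no Tundrarum.
4. **global_4**: secondary contact without the Exilis–Glandulosa admixture
   (the Admixed population arises by plain divergence).

Sampled population sizes default to 20 diploids each.  The exact prior
bounds used in the original study are not published in the main text, so
the catalogue declares its own: `Ne ~ U(100, 100000)` for every population,
mixing/pulse proportions `U(0.01, 0.99)`, and per-event log-uniform time
priors bracketing the magnitudes implied by the reported dates at a 10–14
year generation time (e.g. deep divergences `LU(2e4–2e5)` generations, the
Tundrarum admixture `LU(5e3–5e4)`, the post-glacial Tundrarum → Nana pulse
`LU(300–5000)`, the Svalbard split `LU(50–2000)`).  All priors live in the
YAML scenario configs and are user-editable; these defaults are the
conditions under which every packaged self-test runs.

## Coalescent SNP simulation

Within a population holding `k` lineages, coalescence occurs at rate
`k(k−1)/(4Ne)` per generation (continuous-time approximation, exact event
cut points).  Loci are unlinked: every locus draws an independent
genealogy, matching datasets thinned to one SNP per RAD locus; there is no
recombination machinery.  Each genealogy receives exactly **one** mutation
on a branch chosen with probability proportional to branch length — the
fixed-S scheme conditioning every locus on polymorphism, so no mutation
rate is ever parameterised and event times are estimated in raw
generations.  A consequence checked by the oracle tests: the simulated
site-pattern distribution is `E[L_pattern / L_total]` over genealogies
(per-tree normalisation), not the ratio of expectations.

Ascertainment mimics RAD SNP filtering: optional per-genotype missingness
is applied first, then the pooled-sample minor allele frequency is computed
over non-missing genotypes and loci below the threshold (default 0.025) are
discarded and redrawn, keeping the locus count fixed.  More than 10,000
consecutive rejections abort the run.  The MAF filter is applied to
simulated and observed data alike.  Ghost populations contribute lineages
only through events.

The per-locus kernel is numba-compiled; a 120-diploid, 200-locus dataset
simulates in ~35 ms, which makes reference tables of 10^4 datasets a
desk-scale computation.

## Summary statistics

The fixed-order feature vector per dataset: per-population mean and
variance of unbiased gene diversity `He = n/(n−1)·(1 − p² − q²)` and the
proportion of monomorphic loci; pairwise Hudson FST (ratio of locus-summed
numerators/denominators — unbiased under unequal sample sizes, the standard
choice in the f-statistics literature) and Nei's standard distance; `f3`
for every (target; A, B) triad and `f4` for all three pairings of every
population quartet (frequency-product forms, uncorrected — the small
sampling bias is identical across simulated and observed data and therefore
harmless to the forest).  Entries undefined for a dataset (an absent
population, a degenerate ratio) are imputed with the training-column mean
and flagged with indicator columns that the forest may itself use.

Stand-alone admixture tests use Patterson's D in ABBA/BABA form and the
f4-ratio `α = f4(A0, O; X, B) / f4(A0, O; A, B)`, with uncertainty from a
weighted delete-one block jackknife over contiguous locus blocks (default
20 blocks; weights are block sizes, reducing to the textbook unweighted
formula for equal blocks).  A site is "informative" when its denominator
contribution is positive.  Because RAD loci are unlinked, contiguous blocks
in locus order approximate independent resampling units.  For unpolarised
input the frequency-difference f4 forms are polarisation-free; single-site
D examples are not.

## ABC random forests

The reference table holds one row per simulated dataset: scenario label,
parameter draw, summary statistics (equal allocation across scenarios;
defaults 2,000 rows/scenario for model choice and 5,000 for estimation,
with the study-scale 10,000/~25,000 available by configuration).  Before
classification the table is augmented with linear-discriminant projections
fitted on the scenario labels (at most `n_scenarios − 1` axes, within-class
covariance ridge-regularised with a fixed 1e-8 shrinkage); the axes also
serve as the overlap diagnostic between simulated and observed data.

**Model choice** trains a 500-tree random-forest classifier; the prior
error rate is the out-of-bag misclassification proportion, and the observed
dataset is classified by per-tree votes (argmax; ties resolved to the
lowest scenario index and flagged).  The posterior probability follows the
ABC-RF error-regression construction: a second 500-tree regression forest
is trained on the out-of-bag misclassification indicator, and the posterior
of the selected scenario is one minus its prediction at the observed point
(clipped to [0, 1]).  This error forest uses `min_samples_leaf = 10`:
without it the prediction at a single point inherits the variance of the
handful of nearest training rows shared across trees.  A selection is
accepted when the posterior reaches 0.65 and the local error stays at or
below 0.20; the staged (hierarchical) runner applies these thresholds per
stage and halts with diagnostics otherwise.

**Parameter estimation** fits one regression forest per raw parameter
(times in generations, sizes in diploids — raw rather than composite
`t/Ne` ratios).  Posterior weights for the observed dataset are leaf
co-occurrence frequencies: each training row gains `1/leaf size` for every
tree in which it shares the observed point's leaf, counted once per row
(bootstrap multiplicity is ignored — a deliberate simplification that
avoids reliance on forest internals; the calibration test shows 95% CI
coverage of 93% under the two-population benchmark).  Point estimate:
weighted median.  Credible interval: weighted 2.5/97.5% quantiles.  Global
accuracy: out-of-bag `mean |ŷ − y| / mean |y|` (NMAE).  Local accuracy:
weighted RMS deviation from the weighted median.

## Population-structure diagnostics

Pairwise Hamming distances sum allele-count differences over loci with
calls in both individuals, rescaled by `L_total / L_compared` so uneven
missingness does not shrink distances (a strict mode disables the
rescaling).  Geographic distances are great circles on a sphere of radius
6371.0088 km.  Mantel and partial Mantel tests correlate lower triangles,
permute rows/columns of the second matrix jointly, and report
`p = (1 + #{r_perm ≥ r_obs}) / (1 + n_perm)` (one-sided greater by default,
matching isolation-by-distance hypotheses; 999 permutations).  The partial
variant correlates residuals from linear fits on the covariate matrix; a
covariate that explains the second matrix exactly yields r = 0 by
convention, while one collinear with the first matrix is an error.  NMDS
minimises Kruskal stress-1 by alternating isotonic regression on
dissimilarity ranks with Guttman configuration updates, starting from the
classical-scaling solution plus random restarts (default 20).  Rarefied
allelic richness uses the closed-form hypergeometric expectation
`Σ_a [1 − C(N−N_a, n)/C(N, n)]` per locus.

## Chronology

Event-time posteriors in generations convert to calendar years under the
bracketing generation times of 10 and 14 years (so the g = 14 value is
exactly 1.4 × the g = 10 value before rounding).  Formatted output uses
three significant figures with automatic ka/mya units, rounding after unit
conversion; raw values are always carried alongside.  Converted median
spans intersect a user-editable CSV of named paleo intervals (Marine
Isotope Stages, ice-free-corridor windows, Bering Land Bridge emergence);
the packaged default table cites its sources per row.  Only temporal
overlap is computed — no spatial intersection with ice-sheet polygons.

## What the synthetic tests show — and do not

The simulator is validated against closed forms (pairwise TMRCA = 2N),
against msprime as an independent coalescent oracle (joint site-frequency
spectra by chi-square GOF; Hudson FST under a deep split), and against
degenerate-event equivalences.  The statistics are validated against
brute-force recomputation and algebraic identities; the jackknife against
the textbook formula; Mantel against scikit-bio; the f4-ratio and the RF
credible intervals by parameter-recovery calibration.  Desk-scale
self-consistency uses the packaged catalogue at 2,000 simulations per
scenario with 200 loci: pseudo-observed data simulated under scenario 1 at
mid-prior parameters is re-identified with median posterior ≈ 0.78, and the
gene-flow vs no-gene-flow binary choice has out-of-bag error ≈ 1.5%.
These sizes are the package's default desk-scale protocol; study-scale
tables simply take proportionally longer.

The generator emulates unlinked, polymorphism-ascertained biallelic SNPs
with uniform missingness.  It does not model linked sites, allele dropout
from restriction-site mutations, sequencing error, uneven coverage, or
reference bias — so passing tests demonstrate the statistical machinery is
correct and calibrated under the stated model, not that real RAD data meet
that model.  Inference on real data inherits the usual ABC caveats: results
are conditional on the scenario set and priors, ghost-population histories
are only weakly identified, and calendar dates scale linearly with the
assumed generation time.
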