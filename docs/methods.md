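# Methods

This note documents the models, estimators and numerical choices behind
`msatdem`, and what its synthetic experiments do and do not show.

## Data model

Genotypes are integer allele states (fragment sizes or repeat counts) in
an individuals × loci × 2 array; `0` marks an empty slot.  Most
statistics treat states as categorical labels; allele-size variance and
(δμ)² use the integer value.  Birds are ZW/ZZ: a female carries one Z
copy, so her call at a Z-linked locus is hemizygous (`xxx000` in the
GenePop dialect) rather than half-missing.  A fixed policy keeps
hemizygotes from biasing the statistics: allele frequencies, expected
heterozygosity and rarefaction richness use all typed gene copies
(females contribute one at Z loci); observed heterozygosity,
F<sub>IS</sub>, Hardy–Weinberg tests and the θ variance components use
male diploid genotypes only.

Locus filters: the amplification-failure rule removes a locus only when
it is 100% missing in at least one population (or population group) —
partial missingness never triggers removal.  Map-distance thinning is a
greedy per-linkage-group scan in map order keeping a locus only when at
least the threshold (default 10 cM) from the last kept locus; loci on
unique linkage groups are always kept.  Both filters are deterministic
in input order.

## Diversity and differentiation estimators

* H<sub>E</sub>: Nei's unbiased estimator (C/(C−1))(1−Σp²) on the C
  typed gene copies of a population × locus cell (C may be odd with
  hemizygous females).
* F<sub>IS</sub>: Weir & Cockerham's within-population components,
  f = Σb/Σ(b+c) over loci and alleles.
* Allelic richness: hurlbert rarefaction
  Σ<sub>i</sub>[1 − C(2N−N<sub>i</sub>, g)/C(2N, g)]; `g = auto` uses
  the minimum typed copy count over nonempty cells so every cell can be
  rarefied.
* θ (F<sub>ST</sub>): Weir & Cockerham (1984) components a (among
  populations), b (among individuals), c (within individuals), summed
  over alleles and loci; pairwise multi-locus θ = Σa/Σ(a+b+c).  Loci
  monomorphic across a pair contribute nothing.  The permutation test
  permutes whole multilocus genotypes between the two populations (no
  HWE assumption), p = (1+k)/(N+1) so p is never zero.  The HWE test, in
  contrast, permutes alleles among individuals within a cell with |F_IS|
  as the statistic — the two permutation units are deliberately
  different.
* Jost's D<sub>est</sub>: per locus from Nei–Chesser bias-corrected
  H<sub>S</sub> and H<sub>T</sub> with the harmonic mean sample size
  (s = 2 populations), combined across loci by the harmonic mean.
  Per-locus values ≤ 0 enter the harmonic mean as ε = 10⁻⁴ (the harmonic
  mean is undefined at 0); ε is configurable.  Bootstrap CIs resample
  individuals with replacement within populations (percentile, 95%).

## Coalescent simulator

Continuous-time approximation: k lineages in a population of N diploids
coalesce at rate k(k−1)/2 per 2N generations; Z-linked loci carry 1.5N
copies, giving the 0.75 scaling (this is on by default and switchable by
treating a locus as autosomal).  Demographic events are instantaneous,
in backward time (0 = present): merges move lineage sets into the
ancestor (if the named ancestor has itself already merged, lineages
follow it to its current representative), admixture reassigns each
lineage to one of two sources by a Bernoulli draw, size changes swap the
rate constant.  Populations are independent between events, so each
epoch draws the successive Kingman coalescence times per population in
one vectorised pass; exponential memorylessness makes truncation at
epoch boundaries exact.  Lineages left in two or more never-merging
populations raise a connectivity error.

Mutations are Poisson on branch lengths with a single mean rate for all
loci (the per-locus gamma scatter option is off by default).  SMM steps
are ±1 repeat unit; GSM steps are geometric, P(k) = (1−p)p^(k−1).  An
optional contiguous allele range (width 40 by default where used, the
DIYABC-style convention) applies reflecting boundaries — for unit steps
the reflected walk equals the folded free walk, which is how it is
implemented; geometric steps are folded then clamped (overshoot past a
boundary is rare at realistic rates).  Without a range bound a final
guard shifts states up if the walk ever reaches zero, keeping allele
states positive.

Calibration checks (also in the test suite): E[T₂] = 2N autosomal and
1.5N Z-linked; equilibrium SMM gene diversity 1 − 1/√(1+8Nμ);
distributional agreement with msprime (an independent coalescent
implementation) on a two-population split model.

## Demographic scenarios

A scenario is a set of populations with size symbols, a time-ordered
event list, and uniform or log-uniform priors with optional ordering
constraints (enforced by rejection; an acceptance rate below 10⁻⁴ is an
error).  The bundled library covers the Canary Islands analyses: a
three-scenario topology test over {Europe, Canaries, North Africa}
(priors N<sub>e</sub> ∈ [10², 10⁶], t ∈ [10², 10⁵] generations), western
/ central / eastern island-group sets (N<sub>e</sub> ∈ [10², 10⁴],
t ∈ [10², 10⁶]) including admixture variants, and a final six-scenario,
nine-population set.  Only the members fixed by the published text (the
Europe-outgroup topology; the simultaneous-split group scenarios; the
final-set members 2 and 6) are treated as faithful; the remaining
members are plausible reconstructions and carry
`note="topology partially inferred"`.  Simultaneous splits share one
time symbol.  Generations convert to years at a 2-year generation time.

## ABC

Summary statistics per dataset: for each population, mean alleles per
locus, mean Nei H<sub>E</sub> and mean allele-size variance; for each
pair, multi-locus θ and mean (δμ)² (squared difference of mean allele
size).  The population order of the vector is fixed per reference table
(the sample-configuration order), so records from scenarios that list
populations differently remain comparable.  Undefined θ (pair with no
usable locus) is recorded as 0.

Statistics are standardised by their MAD across the table (sd fallback
when the MAD is 0; floor 1) and compared by Euclidean distance.  The
direct estimate is the scenario composition of the `n_closest = 500`
nearest records (ties at the cutoff broken by record index).  The
logistic estimate retains the `n_regression` nearest records, fits a
multinomial logistic regression of scenario identity on the
standardised differences with Epanechnikov weights
w = 1 − (d/d<sub>max</sub>)² and a small ridge (10⁻⁶), and reads the
fitted probabilities at zero difference.  Parameter posteriors use the
scenario's `n_accept = 500` closest records, log-transform strictly
positive parameters, apply a weighted local-linear regression adjustment
θ* = θ − βᵀ(S − s<sub>obs</sub>), and summarise by weighted Gaussian-KDE
(Silverman bandwidth) mode and 95% HPD on a 512-point grid, clamped to
the prior support.  Reference tables are reproducible and chunkable:
each record's RNG stream derives from (seed, scenario index, record
index), so chunked and single-shot generation are identical.

### Problem sizes

The published analyses ran millions of simulations per scenario; this
package's experiments are desk-scale by design and labelled as such.
The scenario-choice experiment uses a 20,000-records-per-scenario table
(60,000 records), 14 unlinked loci (10 autosomal, 4 Z-linked), 10
diploids per population, μ = 10⁻⁴ (the low end of the commonly used
microsatellite range) with a 40-state allele range, and 20 replicate
observed datasets scored against one shared table — regenerating the
table per replicate would add nothing but runtime, since replicate
variation is dominated by the observed dataset.  The "well-separated"
truth places the outgroup split near the prior maximum (95,000
generations), the island/African split very recent (500 generations),
and sizes in the well-populated upper prior region.  Split-time recovery
uses a two-population model, a 6,000-record table and 50 truths drawn
from the prior, which makes rejection-ABC coverage exactly calibrated up
to table noise; the regression adjustment can trade a little coverage
for sharpness, hence the ≥85% acceptance threshold rather than 95%.

## Synthetic fixtures

The study-shaped fixture has 10 populations with the study's sample
sizes (206 individuals; sexes alternate, males rounded up so Z loci
always have diploid carriers), 21 loci (4 Z-linked, three multi-locus
linkage groups with map positions such that 10 cM thinning of the 19
working loci keeps 14), and a documented invented demography: a large
European/North African background (N<sub>e</sub> = 8,000–10,000) with
island populations of N<sub>e</sub> = 500–2,500 splitting 700–3,000
generations ago, an archipelago ancestor joining North Africa at 3,000
and the Afrocanarian clade joining Europe at 19,000 generations;
μ = 10⁻⁴, SMM, 40-state range.  Drift intensities t/2N span ~0.04–1,
which reproduces the qualitative empirical pattern — mainland diversity
high, island fixation strong, pairwise F<sub>ST</sub> spanning roughly
0.02–0.65 — without claiming any printed value.  Loci `Tgu9` (all eight
Afrocanarian populations) and `Pca8` (La Palma) are masked to mimic
primer-site amplification failure.

What passing these tests shows: the estimators, simulator and ABC
machinery are internally consistent, calibrated against closed forms and
an independent simulator, and able to recover known truths at desk
scale.  What they do not show: anything about the real genotypes (never
deposited), real mutation-rate heterogeneity, null alleles, scoring
error, or linkage disequilibrium within the simulated loci (loci are
simulated independently; the map positions only drive the thinning
filter).

## Other numerical choices

* ΔK uses means and the n−1 standard deviation across runs per K;
  endpoint Ks are undefined, zero-sd Ks are flagged rather than
  dropped silently.  No outlier-rejection rule is applied to aberrant
  runs.
* Label alignment maximises the summed per-individual dot product with
  the first run, exhaustively over K! permutations for K ≤ 8, with an
  opt-in greedy mode above that.
* HWE p-values are reported per cell uncorrected; a Bonferroni-adjusted
  column is provided but never applied, and the table-level summary
  reports the per-population minimum p.
* The "number of unique alleles" column counts alleles private to a
  population across all loci (not per-locus averages).
* Permutation and bootstrap conventions: p = (1+k)/(N+1); percentile
  bootstrap CIs; every routine takes an integer seed and is reproducible.

## Known limitations

No continuous migration (splits and pulse admixture only, matching the
modelled histories); no recombination within loci; no null-allele or
genotyping-error model; the logistic estimate can saturate at 1.0 for
cleanly separable scenarios (the ridge keeps it finite, not humble); GSM
with a range bound clamps boundary overshoot rather than re-reflecting
per mutation.
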