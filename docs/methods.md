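# Methods

## Data model

A cohort is a donors × taxa matrix of non-negative integer read counts;
a donor's **depth** is its row sum. Counts must be integers — the
binomial detection model and every multinomial bootstrap step are
defined on reads, not on pre-normalized proportions — so fractional
inputs are rejected rather than rounded. Donors with zero depth carry no
information and are dropped at ingest with a warning (treated as
non-response) instead of failing the run. Normalizing each row by its
depth yields the compositional profile; closure (rows summing to 1) is
validated to 1e-9 on construction and holds exactly for count-derived
profiles. Taxon labels are opaque strings; collapsing OTUs into genera
is done by a caller-supplied label extractor because lineage formats
vary across classifiers.

## Ubiquity and core election

`Ubiq(t, a)` is the fraction of donors whose abundance of taxon *t*
strictly exceeds *a* — the empirical survival function of the per-donor
abundance distribution. Strict `>` is used both for the abundance
indicator and for the ubiquity cutoff in core election, so a taxon whose
ubiquity equals the cutoff exactly is excluded. The curve object stores
the sorted per-donor abundances, which makes evaluation exact at every
point (right-continuous step interpolation between the distinct observed
values) rather than an approximation on a grid.

Minor-core election uses two conventions deliberately: presence at the
detection floor is *inclusive* (`abundance >= floor` — the curve
"originates" at the floor), while the low-abundance ceiling is *strict*
(`abundance > ceiling` disqualifies). The ceiling criterion is "no donor
above the ceiling"; an optional `ceiling_tolerance` (default 0, as a
fraction of donors) relaxes it for noisy cohorts since the graphical
criterion it formalizes has no unique numeric reading. The default floor
1e-4 and ceiling 1e-2 mean a cohort must be sequenced to depth of order
1e4–1e5 reads per donor before minor-core calls are reliable; the
synthetic generator warns when the requested depth cannot resolve the
smallest planted minor abundance.

Body-region summaries combine habitat-level ubiquities two ways, each
answering a different question: the **mean** estimates the chance that a
habitat drawn from the region carries the taxon; the **product**
("and"-ing) estimates the chance the taxon is present in *every*
habitat. A taxon absent from a habitat's table has ubiquity 0 there, so
it annihilates the product — by construction the region core via
"and"-ing requires detection everywhere.

The binomial presence qualification (`(1-p)^n <= 0.05`, inclusive) is
exposed as a standalone predicate rather than silently gating the
ubiquity curves: curves are plotted from the 1e-4 floor regardless, and
callers who want detection-qualified presence apply the predicate
themselves.

## Bootstrap confidence intervals on core counts

Each of B = 160 replicates resamples donors with replacement and then
redraws every drawn donor's reads as a multinomial of its depth over its
observed proportions, propagating both cohort-composition and
read-sampling uncertainty. The observed count is computed on the
unperturbed table. Lower/upper bounds are nearest-rank percentiles at
(1−ci)/2 and 1−(1−ci)/2 (no interpolation; B is small). The median is
the standard sample median — the mean of the two middle order statistics
when B is even — which is why half-integer medians can appear in
reports.

## The AWKS statistic

Per taxon, `KS_t` is the supremum of |Ubiq_X − Ubiq_Y| over abundance
cutoffs. Both curves are step functions changing only at observed
values, so the supremum is attained on {0} ∪ {observed abundances} and
is computed exactly (this equals the classical two-sample KS statistic
on the per-donor abundance samples; the test suite cross-checks against
both `scipy.stats.ks_2samp` and a dense-grid brute-force scan). AWKS
weights each `KS_t` by the average of the two cohort-mean abundances
(zeros included), which sums to 1 over the union taxa set by closure;
hence AWKS ∈ [0, 1] and AWKS ≤ max_t KS_t. The statistic is symmetric
and equals 0 iff every taxon's curves coincide on the union breakpoints.

**Null distribution.** Under H0 (same taxonomic profile) donors of the
two cohorts are exchangeable, so the default null pools all donors,
draws n_X + n_Y pseudo-donors with replacement, splits them into
pseudo-cohorts of the original sizes, redraws each pseudo-donor's reads
as a multinomial of its depth, and recomputes AWKS. B = 1000 by default.
The empirical null is used directly — its distribution is visibly
non-Gaussian, so no parametric approximation is attempted. The
one-tailed p-value is `#{null >= observed}/B`, displayed as `< 1/B` when
the count is 0; an add-one `(count+1)/(B+1)` convention is available via
a flag. A `within-first` mode bootstraps both pseudo-cohorts from cohort
X alone, quantifying the statistic's variability within a single cohort;
it is provided because either reading of a pooled-vs-within resampling
design is defensible, and neither is asserted as canonical.

**Multiple testing.** `bh_adjust` implements Benjamini–Hochberg step-up:
sort the m p-values ascending, find the largest i with
p_(i) ≤ i·α/m, reject ranks 1…i. Thresholds are reported rounded to 3
decimals (the printing convention of the tables it mirrors) but
decisions always use unrounded values. Interval p-values like "<0.001"
are accepted and resolved to the midpoint of (0, bound), which cannot
alter a step-up decision when the bound is below the smallest threshold.

## Synthetic cohorts

The generator plants the three-class structure the analyses assume:

| parameter | default | rationale |
|---|---|---|
| donors | 100 | order of a per-habitat survey cohort |
| depth | 5 000 reads/donor | typical pyrosequencing per-sample depth |
| major core | 5 taxa at base 0.30/0.20/0.10/0.05/0.02, presence 1.0 | spans both sides of the 10% cutoff; all clear 1% |
| minor core | 5 taxa log-spaced in [2e-4, 2e-3], presence 0.8 | inside the (1e-4, 1e-2) minor window, majority presence |
| sporadic | 50 taxa, rank-r base ∝ r^−1.5, presence 0.3 | power-law long tail carrying interpersonal variability |
| σ (log10 noise) | 0.1 | ±26% typical donor-to-donor fold variation per taxon |

Per donor: Bernoulli presence per taxon, lognormal multiplicative
perturbation (Normal(0, σ) on log10), renormalization to closure, then a
single multinomial draw of the donor's depth. Read sampling is therefore
simple random sampling — exactly the assumption behind the binomial
detection model and the p(1−p)/(n−1) proportion variance. The generator
deliberately omits PCR amplification bias (no accepted generative model
to emulate), sequencing error/chimeras, and phylogenetic correlation
among taxa; a green recovery test therefore establishes that the
election machinery is correct under the stated sampling model, not that
it is robust to platform artifacts. `generate_pair` spawns two
independent seeded streams from one master seed; fold-change effects
multiply cohort Y's base abundances before renormalization, so an
"effect" on one taxon also compositionally depresses the others, as it
would in real relative-abundance data.

## Numerical choices

- Survival/KS evaluation via `searchsorted` on sorted values: exact, no
  grid, no tolerance.
- Bootstrap multinomials are drawn with numpy's broadcast
  `Generator.multinomial`; all randomness flows from
  `numpy.random.default_rng(seed)` or spawned `SeedSequence` children,
  so every stochastic routine is bit-reproducible under a seed.
- Var-Ab uses sample (n−1) standard deviation of log10 abundances;
  single-responder taxa are emitted with sd undefined (`None`/NaN)
  rather than dropped so plots can still show the glyph; all-zero taxa
  are omitted.
- In `varab` summaries zeros are non-responses, never imputed with a
  pseudocount.
- SVG/PDF output strips timestamps and fixes the matplotlib hashsalt, so
  rendering is byte-deterministic given identical inputs.

## Known limitations

- Core counts and AWKS magnitudes from real survey data depend on the
  classifier, depth distribution and cohort composition; the package
  reproduces procedures and conventions, not published habitat-specific
  numbers, which require the original profiles.
- The pooled bootstrap null assumes donor exchangeability under H0 and
  ignores donor metadata (no stratification).
- No paired (same-donor, two-visit) test: cohorts are compared as
  exchangeable groups, so individual-level shifts that preserve cohort
  composition are invisible by design.
- BIOM support covers the 1.0 JSON format only (dense and sparse);
  HDF5-based BIOM 2.x files must be exported to JSON or TSV first.
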