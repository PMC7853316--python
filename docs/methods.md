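# Methods

This note documents the statistical model behind `gradient-niche`, the
choices made where the procedure was genuinely open, and what the synthetic
data generator does and does not emulate.

## Data model

The analysis unit is the *plot*: a standardized survey area with one region,
one habitat (forest or grassland) and one value per environmental gradient.
Counts are individuals per plot and must be integers; if a survey pools
replicate samples per plot, that aggregation happens before loading.  Forest
and grassland are analyzed independently throughout, each with its own
gradient roster (forest: FORMI, Inonat, Idwcut, Iharv, pH, moisture;
grassland: LUI, mowing, grazing, fertilization, pH, moisture).  Species
present in the abundance matrix but missing from the trait table are
excluded from the CWM stage only — the niche statistics need no traits — and
species without a Red-List code block only the vulnerability stage.

## Community-weighted means and their models

`CWM_p = Σ_i T_i a_ip / A_p` is computed over the species with a known trait
value, with `A_p` recomputed over those species, so it is always a proper
weighted mean and always lies inside the present species' trait range.
Ordinal traits are coded as consecutive integers 1..k in the order the
categories escalate (e.g. light preference: deep shade = 1 … indifferent
= 4).  The native scores of the source trait database would be an equally
defensible coding; since the choice is not derivable from the data, the 1..k
default is used and any pre-coded table can be supplied instead.

Each gradient is fitted in its own model `CWM ~ gradient + region +
gradient:region` rather than jointly, matching how such results are usually
tabulated and avoiding the interpretation problems of mutually confounded
gradients.  The ANOVA is sequential (type I) with the gradient entered
first; the table is assembled from nested OLS fits rather than the formula
ANOVA interface, which would reorder categorical main effects ahead of the
gradient.  Grazing and fertilization are square-root transformed before
fitting (both are zero-inflated, strongly right-skewed intensities);
transforms are overridable per gradient.  Plots with zero individuals have
no defined CWM; they are flagged in the validation report and excluded from
the models.

## Niche statistics and the null model

AWM and AWSD are the abundance-weighted mean and *population-form* standard
deviation of the gradient over occupied plots (divisor `A_i`, not
`A_i − 1`): the niche breadth of a single-site species is exactly zero,
which the hypervolume definition relies on.  CV = AWSD/AWM standardizes
breadth against the mean and is undefined (flagged, never a mid-specialist)
when AWM = 0, which can only occur when every occupied plot has gradient
value 0.

The null model draws, per iteration, `N_i` distinct plots uniformly from
the pool of analyzed plots of the habitat *within the regions where the
species was recorded*, so a species bounded by its biogeographic range is
not mistaken for a land-use specialist.  The observed nonzero-abundance
multiset is assigned to the drawn plots in random order.  Carrying the
observed abundances (rather than equal weights) preserves `A_i` and the
abundance weighting of the observed statistic; equal-weight permutation is
available as `weighting="presence"`.  Tail probabilities count ties as
extreme (`≥`/`≤`), the conservative permutation convention, and quantiles
are nearest-rank order statistics, which makes classifications
bit-reproducible for a given seed.

Classification: winner (strictly above the null 95th percentile of AWMs),
loser (strictly below the 5th), otherwise mid-specialist when the observed
CV lies below the null 5th percentile of CVs and is nonzero, else neutral.
The mid-specialist rule needs an operational threshold because "narrower
than expected" alone assigns no significance level; the 5% quantile mirrors
the winner/loser rule, and a comparison against the null mean CV is
available (`cv_rule="mean"`).  Abiotic gradients (pH, moisture) use the
same machinery with "high"/"low" labels.

Randomness is organized as per-species × gradient substreams derived from a
master seed and CRC32 hashes of the species and gradient names.  Adding or
removing a species, or permuting plot rows, therefore never changes any
other species' draws (the abundance multiset and the candidate pool are
sorted by plot id before drawing).

## Hypervolume

The five-dimensional niche hypervolume is the plain product of the five
habitat-appropriate AWSDs — the three *single* land-use components plus pH
and moisture; compound indices (LUI, FORMI) are excluded because they are
sums of the single components and would double-count those dimensions.  It
is a scalar breadth proxy, not a geometric volume estimate: permutation
invariant in its components, linear in each, and zero whenever any
dimension has zero breadth (in particular for single-site species).

## Vulnerability models

Red-List codes are encoded as ordinal ranks with least concern = 0.  The
default mapping is `* = 0, V = R = 1, G = 3(code) = 2, 2 = 3, 1 = 4`:
near-threatened and very-rare below the named threat categories,
"endangered to unknown extent" pooled with vulnerable.  The exact coding is
not derivable from the category list alone and results can be sensitive to
it, so the mapping is fully overridable in config.

The rarity/response model is a Poisson GLM (log link) of the rank on the
species-level AWM of the focal gradient plus log occurrence and log total
abundance (both ≥ 1 by construction, so no pseudo-count is needed).  The
species-level summary of "the respective land-use parameter" is taken to be
the AWM — the only species-level gradient summary the niche stage defines.
Grazing and fertilization AWMs are square-root transformed first.  Habitats
with fewer than seven coded species are skipped with a notice rather than
fitted (four parameters on fewer species is numerically meaningless).

The hypervolume–vulnerability association is a Spearman rank correlation
computed from the S statistic with average ranks for ties; rho uses the
no-tie identity `1 − 6S/(n(n²−1))` (the convention that accompanies
S-reporting), and p the two-sided large-sample t approximation with n − 2
degrees of freedom.

## Synthetic communities

The generator emulates the study design the analysis assumes: 3 regions × 2
habitats × 50 plots (optionally 34 grassland plots in one region, matching
the reduced sampling of the original survey), gradients drawn uniformly
over the observed ranges (LUI 0.53–4.52, FORMI 0–2.82, single forest
components 0–1, mowing 0–3, grazing 0–851, fertilization 0–433, pH
3.0–6.72, moisture 8.55–55.22).  Expected abundance follows Gaussian
response curves, multiplied across gradients for multi-gradient species
(independent environmental filters), times a habitat factor parameterized
by the forest share of expected abundance; counts are Poisson (default) or
negative-binomial for overdispersion checks, and `noise="none"` rounds the
expectation for deterministic limit tests.  Default species are built to a
declared status on their habitat's compound index: losers/winners sit at
the gradient minimum/maximum with breadth 0.15× the range, mid-specialists
at the centre with 0.08×, neutral species have breadth 4× the range
(effectively flat).  A peak expected abundance of 8 makes declared
losers/winners occupy ≥30 plots with ≥100 individuals across 150
habitat plots — abundant enough for the permutation test to have near-full
power, which is the regime the power checks target.

What the generator does *not* emulate: spatial autocorrelation and
dispersal limitation, region × gradient confounding (available only as an
optional uniform offset), trait–niche correlations, and observation error
such as undetected or misidentified individuals.  Passing tests therefore
show that the estimators recover the truth *under the model's own
assumptions*; they cannot certify behavior under spatial structure or
detection bias.

## Numerical choices and problem sizes

Monte-Carlo classification uses 10,000 iterations by default (the test
suite and the reproduction script use 300–2,000 where only calibration, not
final inference, is at stake).  The calibration study runs 1,000 replicate
single-region datasets of 50 plots; power and recovery use 100–200
replicates of 150-plot habitats.  The exhaustive null enumeration used as
an oracle is feasible for pools of ≤ 8 sites.  All simulations derive their
streams from a single seed and are exactly reproducible.

## Known limitations

* The permutation null conditions on the observed abundance multiset; it
  does not model sampling error in the abundances themselves.
* The hypervolume is a product of marginal breadths and ignores
  correlations between niche dimensions.
* Poisson is an approximation for an ordinal bounded rank response; with
  ranks 0–4 it is serviceable but not exact, and the ordinal encoding
  itself is an assumption (see above).
* CWMs treat ordinal trait ranks as numeric, standard practice for
  community-weighted means but still an approximation.
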