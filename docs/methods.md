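# Methods

This note documents the models implemented in `perturbmap`, the synthetic
screen its validation rests on, the numerical choices that matter, and
what the passing tests do and do not establish.

## The generative model

The synthetic-data generator is first-class code: it defines the study
conditions under which every downstream method is validated, and all of
its draws are retained as ground truth.

**Genotypes.** A panel of haploid segregants from a two-parent cross is
simulated as 16 chromosomes of ~40 evenly spaced biallelic markers
(18.75 kb spacing, ~12 Mb genome, 1-based coordinates, chrI..chrXVI).
Along each chromosome the allele follows a two-state Markov chain with a
per-interval switch probability (default 0.12), giving geometric LD decay.
No crossover interference or map units are modelled; linkage mapping only
requires realistic LD structure.

**Fitness architecture.** Baseline fitness (per generation, natural log)
is b_s = sum_l a_l x_sl + N(0, 0.03) over three additive QTL of effect
0.04 each - appreciable heritable growth variation, and QTL that are
individually mappable at n = 169. An induced, active gRNA g shifts
segregant s to

    w_sg = b_s + m_g + kappa b_s + sum_l beta_gl x_sl + eps_sg

* m_g <= 0: mean effect, Uniform(-0.35, -0.05) for an efficacious 35% of
  non-control gRNAs (the library targets essential genes; the remainder,
  and all controls, are exactly neutral). The fractions and magnitudes
  follow the regime reported for genome-scale inducible CRISPRi screens
  in yeast.
* kappa = -0.15: baseline coupling - the same knockdown hits fitter
  segregants harder.
* eps_sg ~ N(0, tau |m_g| + sigma_lin), tau = 0.2, sigma_lin = 0.015,
  drawn once per (segregant, gRNA) and stored. It is reproducible
  segregant-specific signal (higher-order epistasis by construction),
  not measurement noise; it produces the characteristic growth of
  deviation-value dispersion with effect size.
* Hubs: an amplifying hub (no baseline effect; beta = 0.5 |m_g|, the 3S
  allele increasingly beneficial with stronger knockdowns) and a masking
  hub (a major baseline QTL, effect 0.1, whose realised induced allele
  effect is a max(0, 1 - 3|m_g|); beta compensates the kappa coupling so
  this holds exactly). Each hub interacts with a disjoint set of 12
  efficacious gRNAs.

**Competition and sequencing.** All assays share one lineage table: each
(segregant barcode, gRNA) combination receives 1-3 lineages tagged by
distinct gRNA barcodes (mean ~1.15, matching reported integrants per
strain), with log-normal T0 abundances (CV 0.3, a "roughly uniform"
starting pool). Frequencies evolve deterministically in expectation,
f_i(t+dt) proportional to f_i(t) exp(s_i dt), renormalised per transfer;
observed counts at generations {0, 2, 4, 6, 10} are multinomial draws of
the configured depth (default 10^6). An optional bottleneck adds drift;
it is off by default, so multinomial sampling is the only measurement
noise. PCR chimeras are injected at the count level: every (segregant
barcode, gRNA barcode) pair - valid or not - gains Poisson counts with
mean depth (c0 + a_seg F_seg + a_guide F_guide); defaults put the
chimeric read fraction near 5%, within the <10% regime such libraries
show. Read-level emission (anchored barcodes, Q37, configurable
substitution rate) exists for validating extraction and matching;
count-level injection suffices for testing the correction because the
correction model is frequency-linear.

What the generator does **not** emulate: de novo mutation within
lineages, diploid genetics, time-varying per-lineage fitness, leaky gRNA
expression (off by default, configurable), chromatin-accessibility
variation, index hopping, or quality-score heterogeneity. Passing tests
therefore establish that the estimators recover the stated generative
structure at desk scale - not that real libraries are free of these
additional effects.

## Barcode processing

Reads are rejected when the mean quality of the first 35 bases of either
mate falls below 30, or when the fixed anchor (CCCGAGTCGCGATAA for gRNA
barcodes, TACCGTTCGTATAGG for segregant barcodes) is not found
immediately downstream of the 20-nt barcode window (exact match by
default; one mismatch configurable). Observed barcodes match a reference
when 100 (1 - edit/max(len)) >= 90 - about a 1-2 nt difference on a
20-mer - with ties broken to the lexicographically smallest reference id.
Edit distances come from edlib. Matched pairs whose combination is absent
from the lineage table are tallied separately as chimera candidates.

The chimera model is ordinary least squares of candidate-pair frequency
on the two marginal barcode frequencies, fit separately in the first four
time points and averaged. The design includes every invalid pair over the
observed barcodes with zero counts for unobserved ones - restricting to
observed rows would bias the intercept upward because most rare chimeras
are unobserved at any one time point. Correction subtracts each double
barcode's predicted chimeric frequency, floors at zero, and rescales to
counts; depth normalisation then puts every time point on a common total
(default 450,000,000).

## Fitness inference

Counts are modelled as Poisson around depth(t) f_i(t) with
f_i(t) = phi_i exp(s_i t) / L(t), L(t) = sum_j phi_j exp(s_j t). Fitting
alternates (phi_i, s_i) Newton updates (vectorised over lineages, 2x2
systems in closed form) with recomputation of L, damping steps so the
total deviance never increases; convergence at max |delta s| < 1e-6 or
200 iterations. The additive gauge freedom (s -> s + c) is fixed by
centring to the T0-frequency-weighted mean. The per-lineage fit score is
the total Poisson log-likelihood of the fitted trajectory.

Numerical choices: initialisation from least-squares slopes of
log-frequency (pseudo-count 0.5); fitness bounded to [-1, 1] per
generation, because a lineage below -1 declines more than e^2 per
transfer and its trajectory carries no further information - unbounded
estimates for such lineages diverge and would dominate recovery
statistics; all-zero lineages are flagged with undefined fitness, never
silently dropped.

QC removes lineages with scores below Q1 - 1.0 IQR (the literal
one-interquartile-range rule; not 1.5) or with fewer than 5 T0 reads,
then iterates the structural filters (segregants with <100 distinct
gRNAs, gRNAs with <2 distinct segregants) to a fixed point. Assay
alignment uses control gRNAs: per-gRNA mean fitnesses, dropping controls
that are negative and inconsistent between induced and control assays
(difference beyond 2 SD of control differences - the inconsistency rule
is not further specified by the protocol this follows, so the 2-SD
operationalisation is exposed as configuration), shifting each induced
assay by the difference of retained-control medians, and finally
shifting everything so the mean CON lineage fitness is exactly zero.

## Guide effects

Per gRNA, base and random-slope mixed models (statsmodels MixedLM, ML)
compare CON and one induced assay; the LRT between them (chi-square, 2
df) detects background effects at alpha 0.05, and the fixed-coefficient
p value from the selected model feeds Benjamini-Hochberg correction over
all tested gRNAs. The interaction family is corrected over gRNAs with
mean effects only. Optimiser note: lbfgs occasionally reports a spurious
infinite likelihood (collapsed variance component) or under-converges
the base model, inflating the LRT; fits fall back through bfgs/cg, and
any significant LRT is re-verified with bfgs, keeping the
higher-likelihood solution per model.

Efficacy uses a conservative data-derived null: with all targets
essential, true effects are non-positive, so the upper half of the
mean-effect distribution is null-dominated. The null SD is estimated by
reflecting values at or above the centre (median by default; the mean is
available by configuration since both conventions are in circulation)
and the cutoff is centre - 3 SD. gRNAs whose 20-nt binding window
overlaps a segregating variant are excluded before modelling.

Deviation values are random-slope BLUPs re-centred per gRNA (mean zero
over segregants with estimates); gRNAs with fewer than 35 segregant
deviations are dropped. A no-shrinkage mode (per-segregant
induced-minus-control means) exists for hand-checkable arithmetic and
for unattenuated slope estimation: BLUP shrinkage deflates regression
slopes computed *from* deviations, so the structure-recovery study uses
the fixed mode for the baseline-coupling slope and reads the dispersion
slope from the mixed model's random-slope SD (the square root of the
slope variance component), which estimates the true segregant-effect
dispersion free of measurement-noise inflation.

## Heritability

H2 is the between-segregant share of the sum of squares of per-lineage
guide effects (induced lineage fitness minus the segregant's control
baseline; baseline from control-gRNA CON lineages by default, all CON
lineages optionally). h2 comes from a one-random-effect REML: markers
centred by allele frequency and scaled by sqrt(p(1-p)), A = ZZ'/m,
intercept projected out with error contrasts, eigendecomposition of the
rotated A, and a bounded 1-D search over the log variance ratio; h2 is
clipped to [0, 1]. The relationship matrix is built from genotypes (the
only coherent reading; deviations have no role in relatedness).

A calibration fact worth knowing: at n = 169 the REML null (purely
environmental trait) has median near zero but a long right tail - about
17% of null estimates exceed 0.1 and ~3% exceed 0.2. This is the
sampling behaviour of GREML at this panel size, not an estimator defect;
the unit tests check the distribution rather than a sharp per-replicate
bound, and planted-value recovery (h2 = 0.5 within 0.1 on average) holds
as stated.

## Linkage mapping and hubs

Scans are per-marker simple regressions with two-sided t tests
(monomorphic markers get p = 1; p floored at 1e-300 before -log10;
missing trait values dropped pairwise). The permutation threshold
shuffles a randomly chosen trait's values across segregants - genotype
rows intact, preserving LD - 1000 times and takes the 5th percentile of
minimum p values. With the default marker density this lands near
-log10 p = 4, the same order as thresholds reported for comparable
designs. Peaks are local maxima above threshold, accepted greedily by
significance; the confidence interval extends while -log10 p stays
within 2 units of the peak, and a candidate is rejected if its interval
comes within 100 kb of an accepted interval (interval-to-interval, the
stricter reading). Peaks within 10 kb of the trait gRNA's binding site
are flagged cis and excluded from trans analyses. Baseline fitness is
mapped with the identical machinery.

Hub calling follows the Poisson-overlap recipe: lambda = total drop
interval length / genome length, per-bin level 0.05 / ceil(genome /
20 kb), k = smallest count with upper-tail probability strictly below
that level. Overlap is counted at marker positions (per-bp reduces to
marker resolution at this density). Tied maximal counts resolve to the
position closest to the tied positions' mean. Classification thresholds:
regression slope of |allele contrast| on |m_g| with p < 0.05; positive =
amplifying, negative at a baseline-fitness locus = masking, negative
elsewhere = attenuating. Sign epistasis requires both the baseline and
the flipped induced contrast to clear two standard errors. At the
default depth the masking classification is power-limited when run
through the full count-level pipeline (fewer weak-|m| members map); the
dedicated hub-recovery study therefore feeds the mapping machinery
architecture-level deviations, isolating detection and classification
from fitness-estimation noise, which the fitness-recovery and
calibration studies cover separately.

## Validation studies and problem sizes

The seeded studies in `perturbmap.experiments` (run by the test suite
and `scripts/acceptance.py`) use: 169 segregants x 200 gRNAs at depth
10^6 for fitness recovery, chimera recovery and null calibration; 100
replicates for hub recovery and for heritability recovery; 500 null
traits for FWER calibration; and depth 4 x 10^6 for the
deviation-structure study, where the baseline-coupling slope is
otherwise attenuated ~25% by a per-lineage small-count MLE bias that is
second-order at the higher depth (the structure study also omits hubs,
since a masking hub's interaction term covaries with baseline fitness
and would confound the pooled regression - the coupling and dispersion
relationships are properties of the hub-free part of the model). These
sizes are desk-scale stand-ins for a real screen's ~2.8M lineages, and
the information available per lineage, not the estimators, is what
bounds recovery at this scale: a Cramer-Rao calculation at these
conditions caps the truth-estimate fitness correlation near 0.965, and
the estimator reaches ~0.955.

## Known limitations

* Fitness estimation assumes constant per-lineage fitness and Poisson
  counts; overdispersion from PCR duplication beyond the chimera model
  is not modelled (UMI collapsing exists but is off by default, since
  UMIs added in late PCR cycles cannot fully identify duplicates).
* The mixed-model LRT uses a 2-df chi-square reference, which is
  conservative for variance components on the boundary.
* Hub classification needs >= 3 members with both allele classes and
  spread in |m_g|; hubs below that are reported unclassified.
* One gRNA per gene selection implements the stated ordering
  (interaction significance, mapped loci, id) but gene-level aggregation
  beyond that is out of scope.
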