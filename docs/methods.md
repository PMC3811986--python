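# Methods

## Data model and coding

Genotypes are biallelic SNP dosages: per marker, the count of a designated
reference allele a1 in {0, 1, 2}, with missing calls kept missing (no
imputation anywhere in the discovery pipeline). The reference allele is
pinned by an explicit allele-reference file rather than by observed
frequency: frequency-based coding can flip between the maternal and
offspring sample sets, which would corrupt every mother-child comparison.
Positions are 1-based (MAP convention); no strand flipping is attempted.
Input formats are text PED/MAP (PLINK 6-column dialect), a 3-column
mother/child/status pair file, and family-structured PED for trios.

## Quality control

Per-sample call rate must exceed 0.97 (strict inequality); per-marker call
rate must be at least 0.97, evaluated separately in the maternal and
offspring sets, and a marker failing in either set is dropped from the
combined analysis. Mother-child Mendelian errors — for a biallelic marker
the only duo-detectable inconsistency is the opposite-homozygote pair
(0, 2) or (2, 0) — are tabulated across all complete duos and a marker with
more than 10 errors is dropped. Hardy-Weinberg equilibrium is tested in
control mothers with the exact conditional test (probability of k
heterozygotes ∝ 2^k n!/(n_AA! n_AB! n_BB!) given the allele counts;
two-sided tail = sum of outcomes no more probable than the observed one,
standard rather than mid-p definition, computed in log space); markers with
P < 10⁻¹⁰ are dropped. The F inbreeding coefficient
(O_hom − E_hom)/(L − E_hom) with E_hom from control-mother allele
frequencies, and duo relatedness (IBS0 rate and method-of-moments pi-hat
given allele frequencies) are computed for flagging only: samples with
F < −0.15 are marked possibly contaminated and duos with IBS0 rate > 0.01
marked misidentified, but exclusion is left to the analyst, because
contamination/misidentification calls on real data involve outlier
judgment that a hard threshold misstates.

## Stratification

Population structure is handled empirically: samples are clustered by
complete-linkage agglomerative clustering on the 1 − IBS distance
(IBS(i, j) = mean over jointly non-missing markers of shared-allele-count/2),
mothers and children separately. Main-effect tests stratify individuals by
their own solution; paired (interaction) tests stratify duos by the
maternal solution. The cluster count K is tuned by scanning K = 1..k_max,
computing the genomic inflation factor λ = median(X²)/0.4549364 of the
proband and maternal genome-wide scans at each K, and scoring each K by
max(|λ_proband − 1|, |λ_maternal − 1|) so that deflation is penalized like
inflation. The smallest K whose score is within a flatness tolerance
(default 0.05) of the minimum is selected: a median-based λ has sampling
noise of roughly 2.3/√M at M markers (≈0.05 for a few thousand markers), so
score differences below that scale do not justify extra strata, and exact
ties never occur in floating point. The λ-vs-K scans may be thinned to
every n-th marker (`marker_step`) to bound cost on large panels; the final
cluster solution is recomputed on the full panel.

## Discovery tests

All five models use the Cochran-Mantel-Haenszel 1-df chi-square without
continuity correction (the correction would shift boundary P-values;
omitting it matches the conventional test), with the Mantel-Haenszel common
odds ratio. Strata with fewer than two observations or a zero margin carry
no information and are dropped from both sums; a marker where all strata
drop is reported untestable (NA) rather than raising. Main-effect tests
count two allele observations per non-missing individual. Interaction tests
count duos, classified by three binary models: offspring-heterozygous
(child het, mother homozygous — the child carries an allele the mother
lacks), maternal-heterozygous (the mirror image), and difference (genotypes
not identical). Opposite-homozygote duos are genotyping errors by the QC
logic and are excluded from classification, never counted as exposed.

Two classifier modes exist because the discovery-side definition of the
conditioned models is ambiguous: `literal` (default) classifies every
Mendelian-consistent complete pair as exposed or unexposed exactly as the
two-class definitions read; `conditioned` additionally drops
homozygous-child pairs from the offspring-het model (and homozygous-mother
pairs from the maternal-het model) as uninformative, mirroring the trio
replication analogs which condition on offspring genotype. Both are config
switches; no claim is made about which matches the original analysis.

Reporting tiers are P < 10⁻⁴ (suggestive, carried to LRT follow-up and
replication), P < 10⁻⁵ (top) and P < 5×10⁻⁸ (genome-wide).

## Multinomial likelihood and LRT

For one marker, the seven Mendelian-possible (mother m, child c) dosage
cells get population probabilities μ(m, c) = HWE(m; q) Σ_f HWE(f; q)
T(c | m, f) under HWE and random mating, and a multiplicative risk
ρ(m, c) = r1^c s1^m j^I(m,c), where I is the active interaction model's
indicator (diff: m ≠ c; offhet: c = 1 ∧ m ≠ 1; mathet: m = 1 ∧ c ≠ 1) and
two copies act as the square of one (r2 = r1², s2 = s1²). Case duos follow
μρ renormalized — ascertainment conditions on affection, so the baseline
risk α cancels and only relative risks are identifiable from case-control
duo counts; α is therefore not a free parameter of the fit. Controls are
modeled as population duos (rare-disease approximation; the phenotype's
prevalence is far below 1, and the synthetic generator's default baseline
risk of 0.01 keeps the approximation accurate in-simulation).

Fitting maximizes the multinomial log-likelihood over a chosen free subset
of {q, r1, s1, j}; fixed risks are pinned at 1, a fixed q at its moment
estimate from control duos. Risk parameters are optimized on the log scale
with |ln θ| ≤ ln 50, q through a logit; L-BFGS-B from a small multi-start
grid (each free risk started at 0.5, 1, 2), keeping the best, with ftol
1e-12; non-convergence of every start flags the result instead of raising.
The maternal-effect LRT compares {q, r1, s1} to {q, r1}; the interaction
LRT compares {q, r1, s1, j} to {q, r1, s1}; both are 1-df chi-square tests
on 2Δln L, with tiny negative differences clamped to zero. The exact
parameterization beyond the published description (the original software's
supplementary tables are not available) is reconstructed from the model
narrative; this is the package's largest inference and the reason the fit
exposes its free-parameter sets explicitly.

## Trio replication

Proband effects replicate by the TDT: b transmissions of a1 and c of a2
from heterozygous parents, X² = (b − c)²/(b + c), OR = b/c. Maternal
effects replicate by an allelic chi-square with mothers as "cases" and
fathers as "controls" — valid because the parents' genotypes are
unconditionally independent, and resting on the working assumption that
maternal effects are distinct from paternal effects. The three interaction
analogs condition on offspring genotype (offhet: het children, parent
indicator = homozygous; mathet: homozygous children, indicator =
heterozygous; diff: all trios, indicator = genotype different from the
proband's, reading "opposite genotype" as non-identical for consistency
with the discovery difference model).

Conditioning on the child's genotype makes the two parents' genotypes
dependent, so a naive unmatched 2×2 Pearson chi-square of all mothers
against all fathers is miscalibrated: empirically ~0.068 type-I error at
nominal 0.05 for the offspring-het analog and ~0.038 for the maternal-het
analog. Only trios whose parents are discordant for the indicator carry
information, so the default test is the matched discordant-pair form:
b = mother-indicator-only trios, c = father-only, X² = (b − c)²/(b + c) —
exactly calibrated under the null by parental exchangeability. The
unmatched Pearson form is retained (`matched=False`) for comparison and for
its closed-form oracle checks.

Per-dataset log odds ratios (Woolf SE, Haldane-Anscombe 0.5 only when a
cell is zero and the merged path is not taken) are pooled by
DerSimonian-Laird: τ² = max(0, (Q − (k−1))/(Σw − Σw²/Σw)) with fixed
weights w = 1/se², re-weighting w* = 1/(se² + τ²), two-sided normal P. When
any dataset has a zero count at a marker, the per-dataset counts are summed
and tested jointly instead ("merged" fallback). A hit replicates if its
meta (or merged) P beats 0.05 divided by the number of marker-model results
carried into replication *and* its effect direction matches discovery;
same-direction P < 0.05 is reported as nominal only.

## Synthetic data

The generator emulates the statistical structure the analysis assumes and
is the package's test bed: unlinked biallelic markers with ancestral a1
frequencies uniform on (0.05, 0.5); optional strata with Balding-Nichols
divergence (per-stratum frequency ~ Beta(q(1−F)/F, (1−q)(1−F)/F) at Fst F,
the standard minimal model of structure — real ancestry mixtures are richer
than any single-F model); parents drawn under HWE, children by Mendelian
transmission; affection ~ Bernoulli(min(1, α·ρ(m, c))) with the duo risk
model at a single causal marker (α default 0.01, small enough that controls
approximate the population), optionally multiplied by a per-stratum
enrichment to confound status with ancestry; case/control or
affected-trio quotas filled by rejection sampling; remaining markers drawn
null conditional on stratum. Default duo quotas are 366 cases and 369
controls (735 pairs), the discovery cohort's size. Everything is
bit-reproducible from one integer seed, and truth records (strata, causal
marker, generating parameters) are emitted for recovery tests. What the
generator does **not** emulate: linkage disequilibrium, genotyping error
(beyond an optional uniform per-call missingness), X-chromosome
inheritance, and realistic ancestry admixture — so passing tests certify
the statistical machinery under the stated model, not robustness to those
real-data features.

## Problem sizes used in the test suite

The statistical acceptance tests run at sizes chosen to make their
assertions sharp at desk scale: 2,000 Monte-Carlo replicates for the power
check at 385/379; 10,000 null markers at 735 duos for type-I calibration of
the five scans (binomial 99% bounds) and 5,000 markers for the
structure/λ check; 200 replicates of 2,000 duos for maternal-risk recovery
and 1,000 datasets of 1,000 duos for null LRT calibration; 10,000 markers
at 300 trios for replication-test calibration; and a 5,000-marker,
735-pair end-to-end determinism run compared byte for byte.

## Known limitations

- The multinomial parameterization is a reconstruction (see above); other
  parameterizations (parent-of-origin, X-specific likelihoods, control-free
  case-only likelihoods) are out of scope.
- Mother and father in the unmatched trio tests are treated as independent;
  the matched default sidesteps the resulting miscalibration but reduces
  the informative count to discordant pairs.
- The K-selection criterion ("overall" inflation as the max deviation of
  the two λs, with a flatness tolerance) is one reasonable operationalization
  among several; the λ-vs-K table is always written out so the choice is
  auditable.
- The CMH allelic test assumes within-stratum HWE for its allele-counting;
  gross departures would be caught upstream by the HWE filter.
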