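# Methods

This note records the models implemented in `paleokin`, the defaults and
why they were chosen, what the synthetic data do and do not emulate, and
the numerical choices a maintainer would want written down.

## Population-history simulation and the f-statistic oracle

Allele frequencies drift along a user-specified admixture graph under
the Balding–Nichols model: given a parent frequency `p` and a drift
amount `F ∈ [0, 1)`, the child frequency is drawn from
`Beta(p(1−F)/F, (1−p)(1−F)/F)` — mean `p`, variance `F·p(1−p)`. An
admixture event mixes two source frequencies linearly
(`α·p_A + (1−α)·p_B`) before the child's own drift. Root frequencies
are uniform on [0.05, 0.95]; all frequencies are clamped to
[10⁻⁶, 1−10⁻⁶] so genotype likelihoods stay finite (degenerate sites
carry no information).

This model was chosen because it makes every f-statistic expectation
available in closed form. The process is a martingale, so
`E[p_X] = E[p_root]` for every node, and the second moments
`E[p_X p_Y]` propagate in topological order: drift leaves cross-moments
untouched and shrinks own-moments toward the mean
(`E[p²] ← F·μ + (1−F)·E[p²_parent]`), admixture mixes moments linearly.
`expected_f2/f3/f4` evaluate any statistic exactly from that table —
the "path overlap" oracle that the estimators are validated against.
Because sites are exchangeable and independent, the block jackknife's
SE captures both sampling and drift-realization noise, which is what
makes "estimate within 3 SE of expectation" a well-calibrated check.

**Not emulated:** linkage (no recombination map — positions exist only
for thinning and block bookkeeping), background selection,
ascertainment bias of real SNP arrays, and reference bias in mapping.
Passing tests therefore demonstrate correctness of the estimators under
the stated sampling model, not robustness to those real-data artefacts.

## Pedigree gene-drop and sequencing noise

Pedigree simulation transmits one allele per parent per site
(autosomes), the maternal X to sons and one maternal plus the paternal
X to daughters, the Y label father→son, and the mitochondrial label
mother→offspring. Every founder allele carries a unique identifier that
is copied on transmission, so realized IBD coefficients (k0, k1, k2)
and realized θ_X are known exactly — they serve as the oracle for the
kinship estimators instead of their Mendelian expectations, removing
sibling-variance slop from the checks.

Sequencing draws per-site read counts from Poisson(λ), copies one of
the two true alleles per read (or, with probability ε, a contaminant
allele Bernoulli-drawn from the contaminant population's frequency),
applies base error (flip to a uniformly random other base), then
terminal deamination: each read is terminal (distance tag 1) with
probability 0.3, otherwise interior (distance 2–15, uniform), and
terminal C→T / G→A flips occur at the spec's deamination rate. Defaults
(λ around 1–4, base error 0.002, deamination 0.15, ε = 0) reflect
typical shotgun ancient-DNA libraries from temperate-climate remains.
Contaminant reads come from population frequencies, not a fixed
haplotype — sufficient for exercising the QC gates, which is all they
are used for here.

## Damage-aware genotype calling

Per read with base quality `Q` (error `e = 10^(−Q/10)`) and distance
tag `d`, the probability of an observed base given a true allele chains
deamination (C→T with the 5′ profile at `d`, G→A with the 3′ profile;
flat fallback for untagged reads) with sequencing error. Site
likelihoods are per-read products under the three diploid genotypes
(two for hemizygous male X/Y calls); GQ is the phred difference between
the best and second-best genotype under a flat prior — no population
prior is defensible for a single ancient individual. This implies GQ
grows by `10·log10 2 ≈ 3` per concordant read, so GQ 50 needs ~17 clean
reads at a site.

Pseudo-haploid calls draw one read uniformly; the RNG stream is keyed
by (seed, crc32(individual)) so results are independent of processing
order. Genetic sex uses `Ry = nY/(nX+nY)` with a 95% Wilson CI;
thresholds Ry < 0.016 (XX) and Ry > 0.075 (XY) are config defaults.
The QC gate fails an individual only when contamination exceeds 0.2 or
terminal damage falls below 25%; missing fields are logged, not failed.

## Kinship

The mismatch classifier computes P0 (pairwise pseudo-haploid mismatch)
on sites with reference-population MAF ≥ 0.1, in 1 Mb windows (the
per-window values give a spread estimate), normalizes by the cohort
median — which assumes a mostly-unrelated cohort, hence the explicit
override for small ones and the hard refusal below 10 pairs — and cuts
at 0.625 / 0.8125 / 0.90625, the midpoints of the `1−φ` expectations
for φ = 0.5, 0.25, 0.125, 0.

The ML estimator maximizes
`Σ_sites log Σ_m k_m Σ_{g1,g2} L1(g1) L2(g2) P(g1,g2 | IBD=m, f)` over
the k-simplex by EM (start (⅓,⅓,⅓), tolerance 10⁻⁶ in log-likelihood,
cap 2000 iterations — EM approaches simplex-boundary optima like the
parent-offspring `k2 = 0` slowly, and each iteration is a cheap (n,3)
product, so the generous cap costs nothing). Sites are pre-thinned
per pair with a greedy 2,500 bp scan of the intersected panel,
mirroring per-pair LD thinning practice. θ classification cutoffs are
the standard powers-of-two midpoints (0.3536 / 0.1768 / 0.0884).

IBS summaries freeze the operative formulas in one place:
`KING θ = (N_both-het − 2·N_opp-hom) / (N_het1 + N_het2)`,
`R0 = N_opp-hom / N_both-het`, `R1 = N_both-het / (IBS0 + IBS1)`. The
field sometimes reports an "R2"; here it is an alias for KING θ, noted
as a documentation decision rather than a claim about other tools.

θ_X is a moment estimator: posterior mean allele dosages (HWE prior at
the reference frequency; Bernoulli prior for male X) give
`θ̂_X = Σ(x1−q)(x2−q) / Σ q(1−q)` on a haploid-sharing scale where
father-son ≈ 0, mother-son ≈ 0.5, brothers ≈ 0.5. It is comparable
across pair types, which is what the pedigree rules need; it is not a
full joint-likelihood X model, and at very low depth the prior
shrinkage attenuates it slightly (visible in tests as mother-son
estimates near 0.4 at 4× — still far from the father-son 0).

Evidence gates: 10,000 overlapping autosomal sites (1,000 on the X)
before any degree call enters downstream rules. When the two methods
disagree, the likelihood-based call is kept and the conflict flagged.

## f3 / f4 / D and the cohort contrasts

Population frequencies are plain allele-count means; the
sample-size/heterozygosity correction is off by default because it is
not meaningful for pseudo-haploid calls (the switch exists for diploid
data). D's denominator uses the total-heterozygosity normalization
shown in the README. The jackknife follows the weighted delete-one
formula (weights = per-block SNP counts); with equal weights it reduces
exactly to the classical delete-one formula, which is tested.

Cohort filters: individuals genotyped at < 85% of panel sites are
dropped; one highest-coverage representative is kept per close-kin
group (connected components of degree ≤ 2 calls); variants whose
non-reference allele occurs in exactly one remaining individual are
removed.

Within-group diversity reports the distribution of `1 − f3(O; i, j)`
over non-relative pairs (degree ≤ 2 excluded). The autosome-vs-X
contrast regresses `f3_auto` on `f3_X` across partner populations and
standardizes the residuals: male-biased gene flow from a source
depresses that source's X affinity relative to autosomes, yielding a
positive residual. The per-individual site-affinity D excludes the
focal individual — and its 1st/2nd-degree relatives — from the
site-population term; leaving relatives in would inflate apparent site
affinity for members of large kin groups, which is exactly the signal
being tested. The per-sex comparison adds a Mann-Whitney rank test as
summary plumbing; the substantive output is the two D distributions.
The D sign is oriented so that positive means "clades with own site".

## qpAdm-style fitting

For target `t`, sources `s₁..s_S` and rights `r₀..r_J`, the fitted
system is `a_j = Σ_{i≥2} w_i b_{ij}` with
`a_j = f4(t, s₁; r₀, r_j)` and `b_{ij} = f4(s_i, s₁; r₀, r_j)`, and
`w₁ = 1 − Σ w_i` absorbing the affine constraint (weights sum to 1 by
construction; the result is invariant to which source or right is the
base, which is tested). "allsnps" behaviour computes each f4 on its own
four-population overlap; intersection mode is available. The residual
covariance is the block-jackknife covariance of the residual vector at
a first-stage OLS solution; the GLS residual chi-square with
`df = (J) − (S−1) = |rights| − |sources|` gives the model p-value, and
weight SEs come from refitting with each block deleted. A singular
covariance is ridge-regularized with `ε = 10⁻⁸·trace/dim` (logged; an
absolute floor handles the exactly-degenerate case of a target
identical to a source). Numerical equivalence with ADMIXTOOLS is not
claimed; the validation surface is parameter recovery and p-value
calibration on simulated graphs. The "maxrank"/"details"/"summary"
flags of the original tool are config echoes only.

The nested rule, rotation screen (every k-subset of a pool as sources,
complement as rights, with a combinatorial guard and single-individual
source flags) and the per-individual three-way decomposition with
two-way fallback (focal source absent ⇒ ancestry 0, provenance
recorded) follow the decision logic described in the README.

## Y-haplogroup assignment

The ISOGG-style table is TSV (name, haplogroup, position, ancestral,
derived); multi-position markers are split, markers off the panel are
dropped with a count, and parent links are taken from label nesting
when not explicit. Recoding: transition calls with GQ < 50 are kept
only when they show C or G; at transversion sites whose two alleles
exclude T (resp. A), an observed T (A) is relabelled C (G). Assignment
scores every root-to-leaf path by cumulative derived calls and reports
the deepest node with derived support on the best path ("lowest level
supported"); the alternative maximal-count reading is exposed as
`mode="max_count"`. Ties prefer the lineage with fewer conflicting
ancestral calls; a surviving tie reports the deepest common ancestor
with a flag. Damage-repaired (UDG) transition calls, when provided,
override non-UDG ones.

## Pedigree rules

Rule order is fixed: (1) both juveniles → siblings; (2) male-male with
shared mito → siblings; (3) adult female + juvenile with shared mito →
mother-child (k2 evidence can override to siblings); (4)
k-coefficients: k1 ≥ 0.75 with R0 ≤ 0.05 → parent-offspring,
k2 ≥ 0.15 → siblings; (5) male-male θ_X ≤ 0.10 → father-son
tiebreaker. Parent-offspring direction comes from age class, from a
shared mitochondrial haplogroup in a mixed-sex adult pair (a
father-daughter pair would not share mito, so the female is the
mother), or from first-degree kinship to both members of a typed
sibling pair (a child of one sibling would be second-degree to the
other — only their parent is first-degree to both). Unresolvable
directions carry ambiguity flags; contradictory hard evidence flags the
edge without dropping it; parent edges that would create an ancestry
cycle are rejected and flagged.

Second-degree triangulation applies the two sibling rules to fixpoint
(first-degree to one sibling + second to the other ⇒ child/nephew;
second-degree to exactly one of a genotyped sibling pair ⇒ grandchild),
then labels remaining second-degree edges that the reconstructed graph
already implies (grandparental chain, sibling-of-parent, single shared
parent ⇒ half-sibling — retained as a candidate even though narrative
accounts often mention only grandparental/avuncular). Untyped edges
keep the full candidate set; male-male pairs with gated X evidence get
θ_X pruning notes (θ_X ≈ 0 excludes maternal-line grandfather/uncle).
The engine is deterministic: sorted processing order, pure rules,
byte-identical serialization.

The social-structure summary reports kin-fraction by sex and haplotype
diversity `h = n/(n−1)·(1−Σp²)` for mito vs Y — numbers only, no
verdict; the statistical patrilocality contrast lives in the
D-statistic machinery. Haplogroup-only "possible" links (e.g. a mito
match for an individual without nuclear data) are emitted as
annotations, never as edges.

## Validation problem sizes

The test suite and the reproduction script use: 50k sites for graph /
qpAdm checks (20 replicates), 135k sites at 1.2× for the kinship
classification cohort (giving ≥ 50k overlapping MAF-filtered sites per
pair; 20 replicates), 30k sites at 4× for the EM k1 check, a 50-node
tree with 20% missingness for Y recovery (100 replicates), and 20k
autosomal + 6k X sites for the sex-bias and patrilocality scenarios
(20 replicates). These sizes put each check's Monte-Carlo error well
below its decision margin while keeping the full run around a minute.

## Known limitations

- No linkage: LD thinning is exercised only as position bookkeeping.
- The qpAdm machinery assumes the f4 covariance is well estimated by
  the block jackknife; with very few blocks the chi-square is
  approximate.
- θ_X is a moment estimator with prior shrinkage at low depth (see
  above).
- The simulator's damage model is two-state (terminal/interior) per
  read; real damage decays smoothly with distance, which the caller's
  per-distance profiles support but the generator does not exercise.
- Mitochondrial haplogroup assignment is out of scope; mito labels are
  metadata inputs throughout.
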