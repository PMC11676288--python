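# Methods

This note records the models implemented, the conventions chosen where the
field admits more than one, what the synthetic-data generator does and does
not emulate, and the numerical decisions a maintainer would need to know.

## Data model

All statistics operate on samples × taxa integer count matrices
(`CommunityTable`), one per domain (bacteria, fungi, protist). Counts stay
integers end-to-end; relative abundances are derived on demand and never
stored, which prevents double-normalisation. Files are tab-separated with
taxa as rows (the dominant amplicon dialect); an explicit flag flips
orientation — no sniffing. No rarefaction or other count normalisation is
applied anywhere; diversity is computed on raw counts and the choice is
deliberate and visible here rather than buried in a default.

The downstream taxon universe is set by a prevalence/abundance filter
(defaults: present in ≥ 25% of samples, then the top 50 taxa per domain by
total abundance, ties broken lexically so results are deterministic). These
defaults are package choices; they are logged on every run so network and
niche accounting is reproducible.

## Diversity and ordination

* Shannon entropy is in nats so that Pielou's identity J = H / ln S holds
  exactly. Samples with a single taxon have J undefined and are flagged,
  not reported as 0/0.
* Simpson is the Gini–Simpson index 1 − Σ p², the convention of mainstream
  amplicon toolchains.
* Chao1 uses the bias-corrected form S + F₁(F₁−1)/(2(F₂+1)), well defined
  when doubletons are absent.
* PCoA: Gower double-centering of −½D², eigendecomposition, negative
  eigenvalues dropped from both the coordinates and the
  proportion-explained denominator. Axis signs follow a fixed convention
  (first nonzero loading positive) so output does not depend on the BLAS.
* PERMANOVA: one-way pseudo-F from within-group sums of squared distances,
  seeded label permutations, p by the add-one rule. Default 999
  permutations. With planted group separation the attainable minimum p is
  bounded below by permutations that reproduce the planted split (2/924 of
  them at 6 + 6), which the tests account for.
* Two-group comparisons use the Wilcoxon rank-sum test via
  `scipy.stats.mannwhitneyu(method="auto")`: exact when both groups are
  ≤ 8 and tie-free, normal approximation with tie correction otherwise. At
  the design size (6 vs 6) complete separation gives the exact two-sided
  p = 2·6!·6!/12! ≈ 0.00216. No multiple-testing correction is applied at
  the phylum level; the raw 0.05 threshold is reported as such.

## Co-occurrence networks

Spearman correlations are computed on within-domain relative abundances
over the merged three-domain taxon set, per group. Edges require
|ρ| > 0.8 AND p < 0.05, both strict. Both signs form edges (magnitude
thresholding) and the sign is stored; a signed-only mode is a switch.
Constant taxa have undefined ρ and are excluded with a log record. Because
the per-group sample size is 6, the t-approximation for p is crude; the
default for n ≤ 8 is an exact permutation p from full enumeration of the
n! sample orderings, vectorised as one matrix product per permutation.
Node/edge accounting counts a node only when incident to a retained edge,
and an empty network is a valid result. No topology metrics beyond counts
are computed — the analysis this package supports reports only counts.

## Niche breadth and the neutral model

Levins breadth B_j = 1/Σᵢ P²ᵢⱼ with P the within-taxon share per sample;
community breadth is the abundance-weighted mean of member B_j. B_j is
invariant to relabeling samples and to scaling one taxon's counts, but not
to scaling one sample — the within-taxon proportions change, and that
asymmetry is intended.

Generalists/specialists are called against a totals-preserving multinomial
resampling null: each sample's total is redrawn over the pooled
metacommunity frequencies, B recomputed, and taxa falling above/below the
central 95% band are generalists/specialists. This null was chosen over
fixed-fixed swap algorithms because it is simple, exactly seedable, and
adequate at 12 samples; users comparing against swap-based results should
expect the resampling null to be somewhat more liberal for abundant taxa.

Dispersal is quantified as the migration parameter m of Sloan's neutral
community model: predicted occupancy 1 − BetaCDF(d | Nmp, Nm(1−p)) with
detection limit d = 1/N, N the median sample total, fitted by bounded
least squares on the occupancy scale (m ∈ (10⁻⁶, 1], scipy bounded
scalar minimisation, xatol 10⁻⁸). R² is computed against mean observed
occupancy and may be negative. A saturated table (every taxon everywhere)
leaves m unidentified at the upper bound and emits a warning. One property
sometimes assumed in the literature — that strong selection lowers the
Sloan R² — did not hold for our generators (selection sharpens the
occupancy step, which the beta curve fits well); the discriminating
quantity is m̂ itself, which orders dispersal regimes correctly.

## Assembly partitioning

βMNTD is abundance-weighted: ½[Σ_{i∈A} f_i min_{j∈B} d(i,j) + symmetric],
minima taken over taxa present in the other sample, so shared taxa
contribute zero. βNTI is the z-score of observed βMNTD against the
taxa-shuffle null (taxon labels permuted across tips; richness and
abundances untouched), 999 replicates by default (tests use 199). Pairs
with null SD = 0 (e.g. identical communities) are flagged degenerate,
excluded from all fractions, and logged. RC_bray preserves each sample's
richness and total: identities drawn without replacement weighted by
occupancy frequency (Gumbel top-k), one individual seeded per chosen
taxon, the remainder multinomial over metacommunity frequencies; RC is the
rank of observed Bray–Curtis in the null ensemble rescaled to [−1, 1].

Classification uses the framework's conventional thresholds, ±2 for βNTI
and ±0.95 for RC, exposed as parameters because they are conventions, not
measurements. Deterministic fraction = both selection labels; the rest is
stochastic. Under the null, RC for a pair drawn from the null procedure
itself is rank-uniform on [−1, 1] — its absolute value averages 0.5 by
construction — so calibration is asserted on the signed mean (≈ 0) and on
the mass beyond ±0.95 (≈ 5%), and βNTI calibration is asserted on the
fraction |z| > 2 aggregated over independent datasets, because the 66
pairwise z-scores within one dataset share a single tree/abundance
configuration and are strongly correlated.

## Synthetic data

The generator emulates a two-group benthic mesocosm: 2 × 6 samples,
richness 300/100/150 for bacteria/fungi/protists, lognormal metacommunity
(σ = 1.5 by default), local community size 10⁴ reads, Yule (pure-birth)
ultrametric phylogenies built by direct forward simulation, random phylum
assignments from per-domain pools of realistic names, and nitrogen
chemistry in µg/g around freshwater-pond baselines (TN ≈ 1000, FA ≈ 120,
ammonia ≈ 30, nitrate ≈ 12, nitrite ≈ 1.5) with treatment offsets on FA
(+40) and ammonia (+15); EN and ON are filled by the same derivation code
the analysis uses, so their identities hold exactly and the treatment
group shows higher FA/EN/ammonia and lower ON by construction.

Neutral communities are Dirichlet-multinomial draws with concentration
N·m·meta, so the generator's m is the very parameter the Sloan fit
estimates — the recovery loop is closed (m = 0.1 fixtures are recovered
with median m̂ ∈ [0.05, 0.2] over 20 seeds). Small m produces dispersal
limitation; m near 1 near-panmixia.

Selection regimes need more care. A scalar Brownian trait on a Yule tree
is a weak proxy for clade membership (distant clades revisit the same
value), Gaussian filter tails leak out-of-clade taxa whose large nearest-
taxon distances cancel the signal, and Dirichlet turnover cannot produce
membership turnover and within-sample evenness at once. The regime
generator therefore uses: (1) multivariate Brownian optima (8 independent
traits — squared trait distance concentrates around patristic distance);
(2) the environment placed at the optimum of the taxon whose trait
neighbourhood is most clade-compact; (3) a plateau kernel
exp(−(d²/s)³) with a hard tolerance limit (zero weight beyond the 20%
trait-distance radius) so nothing outside the tolerated clade occurs; and
(4) a within-clade lottery — each sample hosts a weighted random 60%
subset of the tolerated pool with evenly allocated reads — supplying
turnover of close relatives. This produces ≥ 60% homogeneous-selection
calls at the 12 × 150 test scale robustly across trees. The simpler
Gaussian-filter operation (weights ∝ meta·exp(−strength·(env−opt)²)) is
kept as `simulate_selected_communities` for its limit properties
(strength 0 reduces to mass action; shared strong filtering lowers mean
Bray–Curtis).

What the generator does **not** emulate: sequencing depth variation,
compositional bias, PCR/chimera artefacts, taxonomically structured
abundances, temporal dynamics, or realistic ASV-level tree shapes (real
amplicon trees have far shorter terminal branches than Yule trees, which
makes phylogenetic-turnover signals stronger in real data than here).
Passing tests therefore demonstrate correctness and calibration of the
statistics, not performance claims about any particular real dataset.

## Problem sizes used in tests

The suite runs the calibration and recovery checks at reduced but
statistically meaningful scale chosen as part of the test design:
PERMANOVA type-I error over 500 neutral datasets at 199 permutations;
βNTI/RC calibration at 199 null replicates (8 datasets / 100 seed pairs);
regime recovery on 12 × 150 fixtures at 199 replicates and 3 seeds with a
majority criterion; Sloan recovery over 20 seeds at 60 samples. Defaults
in the package remain 999 replicates/permutations.

## Orchestration

`run_pipeline` executes stages in dependency order from one `RunConfig`
(YAML-round-trippable), writes tidy TSVs plus a JSON manifest (version,
config hash, per-stage wall time, warnings, every file written), and
preserves partial results on failure with the failing stage recorded. A
single global seed expands into per-stage seeds via
`SeedSequence(seed).spawn` in a fixed order, so stages rerun in isolation
reproduce bit-exactly. The assembly stage requires a tree per domain and
fails with an instruction to supply a newick or disable the stage.

## Known limitations

* Raup–Crick is O(pairs × replicates) with Python-level pair loops;
  hundreds of samples would need batching.
* The exact network p-values enumerate n! orderings — intended for n ≤ 8.
* db-RDA with the full chemistry set (TN, FA, ammonia, nitrate, nitrite,
  EN, ON) is rank-deficient by construction (the derived pools are linear
  combinations); the fit warns and uses the pseudo-inverse, and biplot
  scores for collinear variables should be read with care.
* Group-wise analyses assume exactly two groups, mirroring the supported
  design.
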