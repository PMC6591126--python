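# Methods

This note documents the statistical machinery, the synthetic-data model,
and the numerical conventions the package commits to, in the order the
pipeline applies them.

## OTU table preprocessing

Counts are samples × OTUs, non-negative integers. The low-abundance
filter removes an OTU only if its global read fraction is below
`global_frac` (default 0.1%) **and** its within-sample fraction is below
`sample_frac` (default 0.5%) in every sample; an OR mode is available by
flag. The filter is idempotent. Rarefaction draws a multivariate
hypergeometric subsample (uniform without replacement) to a common depth,
so every rarefied row sums exactly to the depth; the pipeline rarefies to
the deepest common depth ≤ the nominal 1000 reads, since the abundance
filter can leave rows a few reads short. Prevalence filtering (present in
≥ 2 samples, counted after rarefaction) is applied per analysis level, so
each group network is built on OTUs observed at least twice within that
group's samples.

## MIC association inference

For a pair of vectors of length n the grid budget is
B(n) = max(⌊n^0.6⌋, 4); the clamp guarantees a 2×2 grid exists at the
minimum supported n of 8. For every resolution (k_x, k_y) with
k_x·k_y ≤ B and both ≥ 2, one axis is equipartitioned by rank into k
bins with the standard greedy tie-preserving rule, and the other axis is
partitioned by a dynamic program over atomic "clumps" (groups of tied
values, which may never be split). The column contribution to mutual
information is additive, so the DP is exact; the test suite verifies
equality with exhaustive enumeration of every cut-point partition on all
instances with n ≤ 12. The characteristic value is I*/log₂ min(k_x, k_y),
maximized over both axis orientations; MIC is the matrix maximum. Because
only rank order enters, MIC is exactly invariant under strictly
increasing transforms of either variable.

Two conventions worth noting. First, MIC equals exactly 1 on a noiseless
monotone relation only when the rank equipartition is even; at odd n the
best achievable 2×2 value is the entropy of a ⌊n/2⌋/⌈n/2⌉ split, e.g.
0.99885 at n = 25. Second, when the number of clumps exceeds
`max_clumps_factor` × the column budget, adjacent clumps are merged into
superclumps; at the sample sizes this package targets (n ≤ 100) the cap
never binds and the DP remains exact.

### Significance and FDR

Under exchangeability the null distribution of MIC depends only on n and
the table's typical tie structure, so one shared null serves every pair:
each draw picks two random columns of the analyzed table and
independently permutes both. p = (1 + #{null ≥ observed}) / (1 + draws).
Benjamini–Hochberg q-values are computed by the step-up rule and edges
are pairs with q < 0.05. Significant pairs are classed *nonlinear* when
MIC − r² > 0.2 (or r is undefined), else *positive*/*negative* by the
sign of Pearson r.

The depth of the shared null matters: with ~5,000 pairs tested at the
group level, the BH threshold sits at p ≈ 10⁻³–10⁻⁴, far out in the null
tail. Group-level analyses therefore default to 9,999 null draws
(pipeline default); the global-null FDR check uses the conventional 999
draws, where BH is simply conservative. Pairs in which either vector has
fewer than 4 nonzero entries are flagged `low_support` and the flag
propagates to the network export.

## Networks and keystone taxa

Networks are undirected, simple, unweighted; nodes are OTUs incident to
at least one FDR-significant edge. Centralities are computed within each
connected component: closeness is the reciprocal of the mean geodesic
length to reachable nodes, betweenness is the geodesic-fraction sum
normalized by (N−1)(N−2)/2 with N the component size, and the network
clustering coefficient averages local clustering over all nodes with
degree-<2 nodes contributing 0 (the alternative connected-nodes-only
convention is one flag away). Diameter and mean path length are taken
over connected pairs, so fragmented graphs stay finite.

Keystone taxa are selected by joint strict thresholds — degree > 50,
closeness > 0.44, betweenness < 0.12 for a pooled 60-sample network;
degree > 10, closeness > 0.28, betweenness < 0.18 for 20-sample group
networks — or alternatively as the intersection of the top-k nodes on
each attribute (ties broken by OTU id). Proportional influence of a
taxonomic order is reported as incident edges per member node (E/N); the
literal N/E orientation is available by flag. Keystone-removal reports
recompute the full topology on the induced subgraph.

The random-graph baseline generates Barabási–Albert graphs from a
complete seed graph on m+1 nodes with degree-proportional attachment and
no multi-edges (m = round(E/N) when matching a reference network), plus
Erdős–Rényi graphs with matched node and edge counts, and locates the
observed clustering coefficient and mean path length within both null
ensembles. `powerlaw_fit` is the legacy least-squares fit of log P(k) on
log k; on finite scale-free graphs this estimator is biased low (≈1.8 on
BA(500, 4) whose tail exponent is ≈3), so tests of the BA asymptotics use
a maximum-likelihood tail estimator instead, and the R² of the
least-squares fit should be read as a linearity diagnostic, not the
exponent's pedigree.

## Community statistics

Shannon diversity uses natural logs; Sheldon evenness is e^H/S (Pielou's
H/ln S is also reported). PERMANOVA partitions squared Bray–Curtis
distances with unrestricted permutation of raw observations; the pseudo-F
is cross-checked in tests against both a from-scratch sum-of-squares
oracle and scikit-bio. PERMDISP embeds samples by principal coordinates
with the imaginary-part correction (squared distances along
negative-eigenvalue axes subtract, clamped at zero), measures distances
to group centroids, and permutes the least-squares residuals; the
statistic is cross-checked against R's `vegan::betadisper`, which
implements the same correction (scikit-bio's permdisp discards negative
eigenvalues and differs by design). Indicator species analysis uses the
group-equalized IndVal.g (specificity from group mean abundances) with a
per-OTU label-permutation test of the max-over-groups statistic; the raw
group-total variant is a flag.

The two-sample KS test reports D = sup|F_a − F_b| with the asymptotic
Kolmogorov p-value at effective n = n_a·n_b/(n_a+n_b). The asymptotic
p is conservative at small n (measured type-I ≈ 0.027 at 40 per side
versus 0.041 at 200 per side), so calibration tests run at 200 per side;
comparisons of bootstrap distributions instead of raw attribute vectors
reproduce the legacy procedure behind a flag, with the caveat that
bootstrapping inflates the effective n and deflates p-values.

## Random-forest driver attribution

The regression forest is bagged explicitly over fully grown scikit-learn
trees with mtry = ⌈p/3⌉, so out-of-bag permutation importance (%IncMSE)
is computed exactly per tree; impurity importance is the mean normalized
variance-reduction total. Significance is rfPermute-style: the forest is
refit on response-permuted data to build a null importance distribution
per predictor, p = (1 + #{null ≥ observed})/(1 + n_perm), and drivers are
predictors with p ≤ α (α = 0.01). Selection uses ≤ rather than < because
with the scaled-down 99 permutations the smallest attainable p is exactly
0.01; the test's level is unchanged. The keystone-abundance response is
the summed relative abundance of the keystone OTUs per sample (a
presence-count response is available).

## The synthetic study generator

The generator emulates a 3-system field survey: 20 farms per system,
1000 reads per farm, 100–200 OTUs, planted hub counts 0 (conventional),
2 (no-till), 10 (organic). All dependence is planted on latent
log-abundances and realized through exponentiation to compositions and a
multinomial draw per farm, so the data carry genuine count noise and
compositional closure.

Each system with hubs has a **hub module** driven by a fixed-spread
environmental gradient (permuted normal scores, so the planted signal
does not swing with the luck of an i.i.d. draw). Hubs respond to the
gradient as a steep **staircase** whose jumps sit exactly at the
occupancy thresholds of their partner taxa; half the hubs climb and half
descend, which leaves hub–hub |dependence| at ≈1 (mixed pairs are
negative associations) while keeping the module's total read share flat.
That mass balance matters: a coherently swinging abundant block imprints
a monotone compositional ramp on every other taxon's counts and wires
unrelated OTUs together. **Presence/absence partners** occupy samples
deterministically above (or below) staggered gradient quantiles
(θ ∈ [0.3, 0.7]); against any hub they form a clean 2×2 block pattern
whose MIC is the occupancy entropy, while any two partners share only the
bounded information of overlapping binary indicators — this breaks the
correlation transitivity that otherwise forces high-degree nodes into
cliques. **Background guilds** are near-duplicate blocks (pairwise latent
correlation 0.9995, damped dispersion, a 3:1 positive:negative load
split) that supply a reliable mass of true edges in every system; they
ignite the BH step-up into its high-power regime and anchor the detection
threshold, while their size (8) keeps every guild member's degree below
the keystone cut-off. Abundance offsets place hubs (~30–45 reads),
partners (~20–35 when present), and guild members (~20–30) above the
multinomial noise floor; remaining OTUs follow a lognormal rank-abundance
at a few reads.

Soil covariates are linear in the realized summed hub relative abundance
(standardized) plus Gaussian noise, scaled so each planted covariate's
marginal R² is ≈0.5; signs follow the intensification narrative (P
fractions and bulk density negative, pH and AMF colonization positive),
and AMF PLFA is left unlinked as a built-in negative control. The
intensity index is drawn around per-system means 2.5/1.5/0.5 (arbitrary
units, conventional highest). Ground truth records hub identities, guild
membership, covariate effects, and the strongly planted pairs (latent
|dependence| ≥ 0.95: hub–hub, hub–presence-partner, and guild pairs).

**What passing tests do and do not show.** The generator produces the
statistical *structure* the analysis assumes — rank dependence, count
noise, compositional closure, group-specific blocks — but not the messy
features of real amplicon data: no sequencing or chimera artifacts, no
taxonomy misassignment, no spatial autocorrelation among farms, no
overdispersion beyond the lognormal-multinomial compound, and effect
sizes chosen (per the design) to be strong enough to detect at n = 20.
Recovery results therefore certify the pipeline's correctness and
calibration, not field-data effect sizes.

**A known, instructive limitation.** With 20 samples and ~5,000 tested
pairs, FDR-controlled MIC only resolves near-deterministic dependence, so
a node's recoverable degree is bounded by its number of
near-deterministic partners. The two no-till hubs have 1 hub neighbor and
4 presence partners — structurally below the degree > 10 cut-off — so
no-till keystones are rarely recovered (the recovered counts still order
organic > no-till ≥ conventional, and pooled recall stays above 0.8 on
the strength of the organic module). This mirrors the general point that
keystone counts from small-n networks are power-limited, not just
biology-limited.

## Problem sizes and seeds

Acceptance-level simulations use the emulated design at 100 OTUs with two
background guilds per system (the full-scale default is 200 OTUs, three
guilds), ten replicate seeds, 9,999 shared-null draws for group networks,
999 for the global-null FDR check, 199 permutations inside the 1,000-
replicate calibration studies, and 150-tree forests with 99 response
permutations. Every random stage draws its seed deterministically from
one global seed (via `numpy.random.SeedSequence`), so stages and whole
runs are bit-reproducible.
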