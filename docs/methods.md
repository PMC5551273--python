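# Methods

This note records the models, conventions and numerical choices behind
`phylocomm`, and what the synthetic-data generator does and does not
emulate.

## Branch-length scenarios

Composite supertrees summarize topologies from many source studies, so
their branch lengths are not estimable in any common unit. All metrics
therefore run over *scenarios* on a fixed topology:

* **equal** — every non-root branch is one node step (length 1). The root
  carries no branch of its own.
* **ultrametric** — starting from equal lengths, every tip's root-to-tip
  path is brought up to the maximum depth by adding the deficit to the
  branch *nearest the root* that is private to the deficient subtree
  (top-down: each child's stem is stretched until its subtree height
  matches its parent's). No branch is ever shortened, and an
  already-ultrametric tree passes through unchanged (depth tolerance
  1e-9).
* **perturbed** — either base scheme plus an independent
  Uniform(−a, +a) draw per branch, a = 0.99 by default; by default ten
  perturbed replicates per base scheme, giving 22 realizations. Perturbed
  ultrametric trees are deliberately *not* re-ultrametricized — the point
  of the sensitivity analysis is to break the scheme's exact assumptions.
  A perturbation that would drive any branch non-positive is an error, not
  a clamp.

Polytomies are kept as-is (distances pass through the shared node); the
supertree's partial resolution is a datum, not a nuisance. Resolution is
reported as internal nodes (root excluded) out of `tips − 1` "possible"
relationships, the convention under which a 199-tip tree with 80 internal
nodes scores 79/198; the root-inclusive count is available via a flag.

Patristic distances are computed in one postorder sweep
(d(i,j) = depth_i + depth_j − 2·depth of the MRCA) and checked in the test
suite against an independent per-pair path-walking oracle.

## Alpha metrics

**Faith's PD** is the total branch length of the minimal subtree spanning
the community's taxa, including the path to the tree's root by default (so
single-taxon PD is defined); a flag excludes the stem above the
community's MRCA. PD is monotone non-decreasing under taxon addition.

**MPD** over distinct-taxon pairs: unweighted, the mean of d_ij over
unordered pairs of present taxa; abundance-weighted,
Σ_{i≠j} f_i f_j d_ij / Σ_{i≠j} f_i f_j. Conspecific pairs (same taxon,
d = 0) are excluded from the weighted denominator by default, matching the
distinct-taxa convention of the standard community-phylogenetics software;
the individual-pairs convention (denominator (Σf)² − Σf) is available via
`include_conspecific=True`.

**SES / NRI.** The null model is a taxa-label shuffle on the distance
matrix: each replicate relabels the community as a uniformly random
same-size subset of the full taxon pool, carrying the observed abundance
multiset along — richness and abundances are preserved exactly, which is
the only constraint the design requires. With 999 replicates (default),
SES = (MPD_obs − mean)/sd and NRI = −SES. Rank p-values use
(r + 1)/(n + 1) and are one-sided for clustering by default (two-sided by
flag). Ties between a null replicate and the observed value are counted as
exceedances using a 1e-9 relative tolerance; without it, floating-point
jitter would split exact ties (e.g. a replicate that redraws the observed
community) at random. A null with zero spread — e.g. an unweighted
community containing the whole pool — is flagged degenerate with NRI = 0
rather than dividing by zero.

**Fisher's method**: X² = −2 Σ ln pᵢ referred to χ² with 2k df; requires
every p in (0, 1].

## Phylobetadiversity

D_pw between communities A and B is the mean patristic distance over all
cross-community taxon pairs: weighted, (fᵀ D g)/(Σf · Σg); unweighted, the
same with presence vectors. Cross pairs of the *same* taxon contribute
d = 0 — this is what makes abundance weighting informative when
communities share dominant taxa, and it is the mechanism behind the
weighted/unweighted contrast in the ordinations. Matrix diagonals are
stored as 0 (ordination input needs zero self-distance); the
self-inclusive mean D_pw(A, A) is available separately as a diagnostic.
Weighted D_pw is invariant to rescaling any one community's abundances.

## Ordination and PERMANOVA

NMDS minimizes Kruskal stress-1 by SMACOF with isotonic regression
(scikit-learn backend), initialized from classical metric scaling plus 20
seeded random restarts; the best-stress solution is kept and centered.
On exactly Euclidean planar inputs the metric-scaling start is already
optimal and stress is ~0.

PERMANOVA Gower-centers the squared distance matrix
(G = −½ J D² J) and partitions trace(G) by sequential (order-of-entry)
sums of squares over the factors — tree type then year by default, both
treated as factors. Pseudo-F uses the full-model residual mean square;
p-values come from 999 free row permutations with the same tie tolerance
as above (symmetric relabelings produce exact F ties that float jitter
would otherwise split). r² = SS_term/SS_total, and the r² partition sums
to 1 by construction. The single-factor case is cross-checked against an
independent one-way implementation and against exhaustive enumeration of
all row orders at n = 6 in the test suite.

Confidence ellipses per host type use the group mean and covariance scaled
by the χ²(2) quantile at the 95% level; groups with fewer than three
points are skipped with a warning.

## Mixed models

Tree-type effects on PD, MPD and NRI are estimated by linear mixed models
with hybrid as the reference level (intercept = hybrid mean; Fremont and
narrowleaf enter as contrasts), a species-richness covariate for PD
models, and crossed random intercepts — branch-length realization, year,
and (for individual-tree analyses) tree id — fitted by REML via variance
components. Random factors with fewer than two observed levels carry no
information and are dropped; with none left the model collapses to OLS,
its exact degenerate limit. Confidence intervals use the t distribution
with *containment* degrees of freedom: a fixed effect that is constant
within every level of a random factor (tree-type contrasts are constant
within trees) is referenced to that factor's level count minus the number
of fixed effects constant within it, taking the smallest qualifying value;
effects varying within all groupings use residual df. With crossed random
effects the intercept's containment df can be very small, making intercept
CIs conservative; the contrasts — the quantities of scientific interest —
are unaffected. Significance is CI-excludes-zero, and likelihood
invariance to contrast coding (refitting with a different reference
reproduces fitted values and contrast differences) is asserted in the
tests. Non-convergence raises with the optimizer's diagnostics; there is
no silent fallback.

## Synthetic-data generator

The generator emulates the study design: 3 host tree types × 4 years ×
13 replicate trees (~156 samples, the scale of the original survey) on a
199-taxon Yule tree whose internal nodes are collapsed to exactly 79 of
198 resolved (the composite supertree's resolution).

Assembly processes per host type:

* **filtering** (both parental types): inclusion weight
  exp(−λ·d(focal, taxon)) around a *focal* taxon drawn once per host type
  and shared by all its replicates and years — the host environment, not
  the individual tree, does the filtering. Abundances are geometric
  (mean 2.6 per present species, the individual-tree scale of the study)
  and assigned largest-first to the taxa nearest the focal, so replicate
  communities of one type share their dominant species.
* **repulsion** (hybrids): taxa join sequentially with weight
  exp(+λ·min distance to the already-included set); abundances geometric,
  unranked.
* **neutral**: uniform; λ = 0 reduces every process to it.

Defaults λ_filter = 1.5 and λ_repulsion = 1.0 were set by a calibration
run so that mean pooled type-year occupancy sits near the study's ~32% of
the taxon pool (individual samples near 7.5%) while preserving clear
clustering/overdispersion signals. Per-sample richness is Poisson around
7.5% of the pool, truncated to ≥ 2.

**What the generator does not emulate.** Species-abundance totals at the
pooled scale (tens of individuals per pooled species in the field data)
are not reproduced — pooling 13 geometric samples yields pooled means
around 7–9 — because the field numbers are not mutually consistent with
the per-sample scale at this sample count; the individual-tree scale is
the calibrated one. Richness is more asymmetric between hybrid and
parental pools than in the field data (repulsion unions are large).
Year-to-year community turnover, detection error and taxonomic
misassignment are absent. Passing end-to-end tests therefore demonstrates
that the *pipeline* recovers a known assembly contrast at realistic sample
sizes, not that the field system behaves like the generator.

A further genuine property worth knowing: the repulsion process acts in
node-step (equal-scheme) distances, and the basal stretching that makes
the tree ultrametric equalizes deep pairwise distances, so the pooled
hybrid overdispersion signal attenuates (and can cross zero) when NRI is
measured on ultrametric distances. End-to-end pattern-recovery checks
therefore evaluate NRI in the equal-scheme metric — the space the
generative process operates in — while the acceptance script reports
pooled NRI under both schemes.

## Reproducibility and problem sizes

Every stochastic stage is seeded; pipeline runs derive all stage seeds
from one master seed (`numpy.random.SeedSequence`), and a run writes a
manifest with seeds, input digests and output inventory — rerunning a
config reproduces every table bit-for-bit. The test suite uses fixed
seeds and scaled problem sizes chosen for sharp signals at desk scale:
oracle checks on 200 random trees of ≤ 12 tips, exhaustive null
enumeration on 6–8-tip trees, 500-community null calibration,
200-dataset PERMANOVA type-I calibration, 50-replicate end-to-end
pattern recovery, and 100-replicate mixed-model coverage/power
simulations.
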