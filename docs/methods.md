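# Methods

This note documents the statistical models, the synthetic-data generative
process, and the numerical conventions used throughout `lianascape`, in
enough detail to reimplement any stage.

## Study design emulated by the generator

The default `SimulationConfig` describes a lowland moist-forest monitoring
design: four 9-ha (300 × 300 m) permanent plots in which all trees ≥ 10 cm
DBH are mapped and measured in two censuses; 144 20 × 20 m liana quadrats
(4 per hectare, on a 50-m lattice, one quadrat per lattice cell with a 10-m
margin so the buffered 40 × 40 m window stays inside the plot); all lianas
≥ 1 cm diameter recorded per quadrat with their host tree(s); a giant-herb
cover index (1 = < 20%, 2 = 20–70%, 3 = > 70% projected cover) on a 10-m
point lattice (100 points/ha, 9 points per quadrat with closed bounds); and
1-m DEM/DSM rasters per plot. Default densities are 450 tree stems/ha and
1077 liana stems/ha; the liana diameter mixture (62% of stems in 1–2 cm,
32% in 2–5 cm, 6% in an exponential tail truncated at 27 cm) reproduces the
size structure typical of such censuses. Liana rank abundances come from a
sorted Dirichlet draw with low concentration (0.15), which yields a handful
of hyperdominant taxa; trees use concentration 0.4 over 60 species.

Generative stages, all drawn from a single `numpy` Generator seeded by
`config.seed` (bit-for-bit reproducibility is a tested invariant):

1. **Terrain.** Gaussian-filtered white noise rescaled to a low relief
   (default 6 m, far below the ~25 m total relief of a plateau site), plus
   Gaussian-bump termite mounds at Poisson locations (default 2.25/ha,
   radius ~N(9.9, 3.3²) m, height ~N(4.1, 1.5²) m, bump sd = radius/2).
2. **Canopy.** An independent autocorrelated field rescaled to
   [0, 45] m, with low-canopy gap discs (default 8% of area, radius 12 m);
   DSM = DEM + canopy. The real spatial covariance of tropical canopies is
   not modelled — only its autocorrelation length and gap patchiness.
3. **Trees.** Uniform positions, Dirichlet-multinomial species identities,
   DBH = 10 + Exp(12) cm, per-species wood density ~N(0.6, 0.15²) clipped
   to (0.2, 1.2) g/cm³. Census 2 applies nonnegative growth increments
   (N(0.5, 0.4²) cm, floored at 0), 2% mortality, and ~2% recruitment just
   above the 10-cm threshold, so ΔBA_T varies among windows.
4. **Giant herbs.** Ordered-logit index with cutpoints set from the base
   marginal (0.5/0.3/0.2) and a latent shift of −0.12 per metre of local
   canopy height, so herbs concentrate in gaps; the coefficient at 0
   recovers the base marginal exactly.
5. **Lianas.** Per-quadrat counts are Poisson with
   log λ = log(density × 0.04 ha) + z'β, where z is the standardized
   environment vector and β (`beta_structure`) carries the canopy/stand
   structure signs (negative QMD_T, meanTCH, WD_T, ΔBA_T, GHFC; ~−0.15 per
   SD for the three main drivers, about half that for the two secondary
   ones, i.e. ~15% fewer stems per SD around the mean). Taxon identity is
   multinomial with probability ∝ base abundance × exp(env_response · z);
   `env_niche_sd = 0` (default) disables environmental niches. Each liana
   draws its host among the tree stems of its buffered window with
   probability ∝ `theta_host[taxon, species]` (all-ones = neutral); 15%
   receive a distinct second host. Liana positions exist only at quadrat
   resolution, as in quadrat-based inventories.
6. **Traits.** Seven leaf/stem economics traits drawn within observed
   ranges (leaf thickness 0.04–0.2 mm, SLA 13.0–64.7 mm²/mg, C 38.9–48.2%,
   N 2.1–5.8%, PO₄ 0.07–0.27%, K 0.3–2.2%, stem tissue density
   0.16–0.59 g/cm³) through a normal-CDF map of a latent score
   ρ·z(niche) + √(1−ρ²)·noise, so `trait_niche_correlation` ρ tunes the
   trait–environment signal from absent (0) to deterministic (1). Trait m
   is tied to environmental axis m mod 8.

What passing tests on these data do **not** show: robustness to real-world
features the generator omits — clonal liana recruitment, spatially
aggregated tree distributions, dispersal limitation, measurement error in
diameters and identifications, and canopy–terrain covariance. Calibration
results transfer to field data only insofar as the permutation null
(exchangeability of quadrats / species) holds there too.

## Environmental variables

Tree variables (N_T, BA_T, QMD_T, WD_T, ΔBA_T) are computed over the
buffered 40 × 40 m window; N_T/BA_T are per hectare, ΔBA_T is the absolute
basal-area difference in m² between censuses. WD_T is the unweighted mean
over stems (basal-area weighting is a configurable alternative; the
unweighted mean is the default "tree mean wood density"). meanTCH is the
mean of DSM − DEM over window cells, negatives clipped to 0, nodata
excluded. GHFC averages the 9 lattice points per quadrat (closed bounds;
fewer points are flagged). All predictors are standardized (mean 0, sd 1)
before modelling; pairwise |r| ≥ 0.7 among predictors is flagged by
`correlation_screen`.

**Relative slope position.** RSP = AACL/(AACL + ABRL) is re-derived from
first principles rather than reproducing any particular GIS toolbox: D8
steepest-descent routing (slope = drop/distance, ties to the first
neighbour in a fixed scan order), flow accumulation by processing cells in
descending elevation order, channels = {accumulation ≥ threshold, default
1% of cells} ∪ {terminal cells}, and AACL = elevation drop along the D8
path to the first channel cell. Ridges and ABRL apply the identical
construction to the negated DEM. Counting terminal cells (local minima and
boundary sinks) as network members makes a mound summit a ridge cell with
ABRL ≡ 0, hence RSP exactly 1 at summits and exactly 0 on channels, and
makes the inversion symmetry RSP(−DEM) = 1 − RSP(DEM) exact. Closed
depressions in noisy DEMs should be removed beforehand with the
priority-flood `fill_pits`; filling is deliberately not fused into RSP
because epsilon-filling the negated surface would demote summits from the
ridge network. Only relative topography is meaningful at a low-relief site,
so no multi-scale terrain analysis is attempted.

## Structure models

Ordinary least squares with intercept; Wald 95% CIs from the t
distribution; AIC in the profile-Gaussian form n·log(RSS/n) + 2(k+1) with k
mean parameters and one variance parameter (additive constants dropped
consistently — only differences matter). Stepwise selection starts from the
full model and greedily applies the single add/drop with the lowest AIC
until no move improves, breaking exact ties toward fewer predictors; tests
verify it attains the exhaustive best subset in ≥ 90% of small-p
replicates.

The pseudo-replication check fits y = Xβ + Zu + e with a random intercept
per group by profiling the restricted likelihood over the variance ratio
λ = σ²_group/σ²_resid (per-group Woodbury identities; coarse log-grid then
bounded scalar minimisation; λ = 0 always evaluated so the REML LR
statistic 2·(llᵣ(λ̂) − llᵣ(0)) is nonnegative by construction). The LR
p-value uses χ²₁ without the boundary half-mixture correction, which is
conservative for detecting a variance component; grouping defaults to the
1-ha subplot level, with the 9-ha plot level added when several plots
exist. Estimates agree with `statsmodels` MixedLM (REML) to numerical
tolerance in the cross-check tests.

## Ordination

With P = A/total, row masses r, column masses c, NSCA decomposes
q_ij = p_ij/r_i − c_j under the row metric diag(r) and identity column
metric (weighted SVD of diag(√r)·Q); total inertia Σᵢ rᵢ Σⱼ q²_ij equals
the eigenvalue sum (checked against an independent elementwise oracle at
1e-8). Sites are rows ("profiles of taxa within sites"), which is what
gives abundant taxa their extra weight; the transpose orientation found in
parts of the literature is intentionally not used. Axis orientation is
fixed by making the largest-|loading| taxon positive.

NSCAIV projects the columns of Q onto span(1, E) by row-weighted least
squares and decomposes the projection; the explained fraction is the
inertia ratio, and its permutation test permutes rows of E
(p = (1 + exceedances)/(1 + n_perm), the convention used by every
permutation test in the package, with 999 permutations by default). CCA
uses the chi-square scaling q_ij/√c_j; partial CCA first residualizes both
Q and E on the conditioning table Z = centered (x, y, x², xy, y²) of
quadrat coordinates, then permutes the residualized predictor rows. With Z
empty, PCCA reduces to CCA exactly; the CCA constrained fraction matches
vegan's `cca` to 1e-8 in the oracle test.

Variograms of axis scores use equal-width distance classes up to the
maximum inter-site distance (11 by default; bin edges are a package choice
since only the class count is conventional), γ = half the mean squared
score difference per class, a 2.5/97.5% envelope from permuting scores over
locations (9999 permutations by default), and per-class exceedance flags.
Classes with fewer than two pairs are merged leftward and logged.

## Trait–environment

CWM_k = Σⱼ a_kj tⱼ / Σⱼ a_kj and SNCⱼ = Σₖ a_kj eₖ / Σₖ a_kj, computed on
the trait-covered taxon subset (site totals renormalize implicitly; sites
with zero covered abundance are flagged missing). Both regressions are
weighted by Hill numbers of order 2, N2 = (Σw)²/Σw², of the site's
abundance vector (CWM side) or the species' occurrence vector (SNC side).
The max-test takes p = max(p_site, p_species), where p_site permutes
environment values over sites and p_species permutes trait values over
species; the max bounds the size at the nominal level whichever of the two
null dimensions actually generated the data, at the price of conservatism
under the complete null — the calibration suite therefore checks p_max's
rejection rate from above, and the two component tests' rates two-sidedly.

The reported fourth-corner correlation is the N2-site-weighted Pearson
correlation between the CWM of the abundance-standardized trait and the
abundance-standardized environment (trait standardized with species
abundance weights, environment with site abundance weights). The exact
weighting scheme varies across the fourth-corner literature; this choice is
documented as an assumption, is affine-invariant at 1e-10 (tested), and its
validity is asserted through the calibration property rather than by
matching any published correlation table numerically.

The trait-shuffle null for CWM–axis correlations recomputes Pearson
r(CWM(t), axis score) after shuffling the trait among taxa (999 shuffles;
two-sided p).

## Host specificity

The RV coefficient between column-centered tables,
RV = trace(X'YY'X)/√(trace((X'X)²)·trace((Y'Y)²)), is tested by permuting
rows of Y; the environment-residualized variant applies the same test to
the residual deviation matrices of the constrained ordinations of the two
communities (uniform row weighting for the co-inertia step, since no common
weighting of the two tables is canonical).

The randomization test takes one unit per liana–host link (a liana with a
second host contributes two independent draws; links whose host falls
outside the buffered window are rejected with a warning, host-less lianas
are excluded and tallied). Each replicate redraws every link uniformly —
with replacement, so a link may redraw its observed host — among the tree
stems of its quadrat's buffered window, which preserves the number of links
per liana taxon per quadrat and hence all spatial and abundance structure
except host identity. Stems are drawn unweighted by size. Envelopes use the
order statistics at ranks ⌈0.025(n+1)⌉ and ⌊0.975(n+1)⌋ of the n replicate
counts (ranks 25 and 975 at n = 999), guaranteeing integer bounds; bounds
are inclusive, so a count on the bound is "ns". Because the statistic is an
integer count, ties at the bounds make the exact attainable size smaller
than 5%; the test reports each pair's attained α alongside the
classification, and the calibration suite compares observed rejection rates
against that attainable size. Abundance filters default to > 60 linked
individuals per liana taxon and > 100 stems per tree species.

## Desk-scale problem sizes

The default pipeline run (144 quadrats, 999 permutations, 9999 for
variograms) completes in well under a minute on one CPU. The test suite
uses scaled-down designs chosen once as the package's own desk-scale
conditions: a single 9-ha plot (36 quadrats, 3-m raster cells, 8 liana
taxa, 10 tree species) for the 1000-replicate null-calibration suite with
99–199 permutations per test; 20 replicates for host-preference power
(10× preference of the most abundant liana for the most abundant tree);
10 replicates of the full 144-quadrat design for trait–environment power
(ρ = 0.9, niche sd 0.5) and 5 for stepwise recovery. Binomial precision at
these sizes is ~1 percentage point for the calibration rates.

## Known limitations

* D8 routing quantizes flow to eight directions; RSP on near-flat tied
  terrain degenerates to terminal cells (synthetic smooth fields have no
  exact ties). The channel threshold (1% of cells) is a scale choice, not
  estimated.
* The REML optimiser handles a single random intercept (one grouping
  factor at a time); no crossed or nested simultaneous fits, no spatial
  error models.
* NSCA/CCA site scores are reported unscaled by axis inertia beyond the
  principal-coordinate convention; no detrending, no Moran eigenvector
  maps.
* The fourth-corner standardization is one defensible choice among
  several; comparisons across packages should use the permutation p-values
  rather than the raw r magnitudes.
* The generator draws tree positions uniformly; clustered or
  habitat-tracking tree distributions would weaken the exchangeability the
  RV and host-randomization nulls assume, and are out of scope.
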