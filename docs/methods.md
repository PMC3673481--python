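# Methods

This note documents the models behind `seapop`, the parameters that
matter, the choices made where the design was genuinely open, and what
the synthetic data can and cannot tell you about real systems.

## The synthetic seascape

`build_seascape` generates an elongated irregular basin on an
`nx x ny` grid (default 60 x 40 at 15 km cells, i.e. a basin of roughly
900 x 600 km — the extent of a large semi-enclosed sea at a resolution
coarse enough for desk-scale runs). The coastline is a super-ellipse
perturbed by low-frequency angular harmonics; depth grows ~10 m per
cell of distance from shore, so the "shallow" band (depth <= 12 m, the
spawning/release habitat) is the one-to-two-cell coastal ring. The
12 m cutoff resolves an ambiguity in how coastal release habitat is
usually described (release cells characterised both as "mean depth
above 12 m" and as "depth <= 12 m"); we adopt <= 12 m — shallow coastal
cells — as the physically coherent reading.

Currents come from a streamfunction: a time-oscillating double gyre
plus an exponentially coast-trapped boundary current, tapered to zero
on land and on the one-cell coastal halo. Velocities are central
differences of psi (u = dpsi/dy, v = -dpsi/dx), which makes the
*discrete* divergence identically zero and guarantees exactly zero
velocity on land. Snapshots are stored every 6 h; the field is rescaled
to a 0.12 m/s maximum speed. That scale matters: with 21-day
trajectories it lets a particle cross an order one-tenth of the basin
per dispersal event, which is what produces site-to-site connectivities
spanning tens of orders of magnitude after 30 dispersal events. Faster
currents homogenise the basin and compress the connectivity range to a
few orders.

Site environments follow the basin's two clines: salinity decreases
linearly (hence monotonically) with the shortest water-path distance
from the entrance cell (default 30 at the entrance to 2 at the far
end), April temperature follows a south-to-north linear trend, and
spawning-time values add N(0, 0.5) jitter to the April values.
Water-path distances are 8-connected shortest paths through water
(diagonal steps cost sqrt(2) x cell size), computed with Dijkstra on a
sparse graph.

## Dispersal and connectivity

Advection is fixed-step RK4 (default dt = 1 h; 2 h in scaled-down
runs — both CFL-safe at these speeds and cell sizes) on bilinear-in-
space, linear-in-time interpolated velocities. A step that lands on a
land cell is reflected specularly across the boundary of the cell it
came from, once; if the reflected position is still on land the
particle stays put for that step. A particle crossing the open domain
boundary is flagged LOST and frozen. There is no explicit diffusion
term: the time-dependent gyre provides chaotic stirring, and the
subgrid turbulence of a full circulation model is out of scope.

The release design is 140 particles per cell per event, 25 events
evenly spaced in a spring window (days 90-165), for 25 years — 87,500
trajectories per cell, kept as the default bookkeeping even though
desk-scale runs use far fewer (typically 2,000 per cell: 100 particles
x 20 events, a size chosen so the complete chain runs in minutes on
one CPU).

The dispersal matrix P is destination-row/source-column: P[i, j] is
the fraction of trajectories from cell j ending in cell i. Trajectories
ending offshore (deep cells) or LOST contribute to the column deficit;
no renormalisation is ever applied, so P^30 entries are absolute
probabilities that legitimately underflow toward zero. Site
connectivity D[a, b] averages the 5 x 5 block of P between the sites'
release cells (the mean keeps values on the probability scale; the
alternative, summing, only shifts the log scale by a constant).
The Mantel input is d = -log10(max(S, floor)) with floor 1e-60 — the
transform is monotone, so rank-based conclusions do not depend on its
exact form, and the floor only affects pairs whose connectivity
underflowed entirely.

## Genotype simulation

`simulate_genotypes` is a discrete-generation Wright-Fisher model with
deme structure. Each generation every deme is refilled with Ne
offspring; an offspring draws its source deme from the migration row of
its destination deme (rows sum to 1; diagonal = 1 - immigration), then
two parents uniformly from the source deme, one random allele per
parent per locus (free recombination). Mutation is per transmitted
copy (default 5e-4/locus/generation, a standard microsatellite rate):
SMM steps +-1 repeat with reflection at the code bounds [50, 500]; IAM
draws a fresh code uniformly from the bounds (a bounded-range stand-in
for "every mutation is new"; collisions with segregating alleles are
rare and only make the IAM slightly conservative).

Viability selection at the optional selected locus uses rejection
sampling: an offspring carrying k copies of the target allele in deme d
is accepted with probability proportional to max(1 + s z_d, eps)^k,
where z_d is the deme's standardized salinity; rejected offspring are
redrawn. The rejection scheme is deliberate: selecting by *resampling*
a fixed offspring pool adds offspring-number variance that halves the
effective population size and (measured) doubles neutral FST, whereas
rejection keeps the Wright-Fisher baseline.

Calibration: with 15 demes, Ne = 200 and island-model immigration
m = 0.135, the equilibrium expectation F = 1/(1 + 4 Ne m (d/(d-1))^2)
gives 0.008 — the weak-structure regime the package targets — and the
simulator reproduces it (the suite checks recovery within 3 Monte-Carlo
SEs and band membership across seeds). The selection coefficient
s = 0.1 was chosen by a coarse design-time scan so the selected locus
equilibrates near theta = 0.075 (band [0.04, 0.12]). Simulations start
from a panmictic founder pool and run 400 generations, several times
the 1/(2m) relaxation time of the between-deme component.

Connectivity-derived migration (`migration_from_connectivity`)
distributes each deme's immigrants in proportion to its directed
inward connectivities. Two row scalings are provided. With
`site_scaling="uniform"` every deme receives the same total
immigration; only relative source shares carry information — and,
empirically, this erases the relationship between differentiation and
connectivity (the Mantel correlation collapses to noise), because a
site's *absolute* isolation no longer affects its gene flow. With
`site_scaling="log"` (used by the pipeline) row immigration scales
log-linearly with total inward connectivity between 15% and 100% of
`m_total`, so oceanographically isolated sites also receive fewer
migrants in total. This restores the mechanism the analysis is about
and yields Mantel r ~ 0.3-0.4 between pairwise theta and -log10
connectivity. Under this scaling global theta rises to ~0.02-0.03 —
isolated demes genuinely differentiate more — which is a property of
the scenario, not a calibration error.

## Estimators and tests

*Weir-Cockerham theta.* Variance components are computed per allele
from per-population sample sizes, allele frequencies and observed
heterozygote frequencies; per-locus and multilocus estimates are ratios
of summed components. Monomorphic loci, loci typed in fewer than two
populations, and mean sample sizes <= 1 are skipped and excluded from
the sums. Negative estimates are retained (standard for moments
estimators). The implementation is vectorised over loci and alleles;
the test suite pins it to an independent loop-wise transcription of the
published formulas at 1e-12.

*Diversity.* Unbiased He; allelic richness by exact hypergeometric
rarefaction (log-gamma evaluation), with the rarefaction size
defaulting to the smallest number of typed gene copies over site x
locus cells; both verified against brute-force enumeration.

*Permutation analogues of the exact tests.* Genic differentiation uses
G = 2 sum O ln(O/E) on the site x allele table with individuals
permuted among sites; heterozygote-deficiency tests shuffle the 2n
allele copies of a site x locus cell into new diploids; genotypic LD
permutes one locus's genotypes among individuals within a site. These
target the same nulls as the classical Markov-chain exact tests but
are fully specifiable and seed-reproducible; their p-values are
approximations to, not replicas of, MCMC exact-test p-values. All
permutation p-values use the (1 + exceedances)/(1 + permutations)
form, so the attainable minimum is 1/(n_perm + 1).

*Mantel machinery.* r is the Pearson correlation of lower-triangle
vectors; the null permutes rows and columns of the second matrix
simultaneously. P-values are one-sided toward *positive* correlation
(the convention of the common R implementations): a sign-adaptive
one-sided test would double the nominal type-I rate, which the
calibration tests would catch. The partial test residualises both
matrices on the control by OLS and permutes the residualised matrix.
No multiple-testing correction is applied across a Mantel battery.

*Outlier scan.* The neutral cloud is Balding-Nichols rather than a
coalescent island simulation: ancestral frequencies (symmetric
Dirichlet over a geometric number of alleles for IAM; a discretized
Gaussian ladder over repeat classes for SMM), deme frequencies
Dirichlet(p(1-F)/F), HWE sampling at the study's sample sizes, theta
re-estimated with the same Weir-Cockerham code. This matches
island-model equilibrium moments and is orders of magnitude faster
than coalescent simulation; it is a documented approximation, not a
claim about Fdist internals. The "neutral mean" applies one trimming
pass: loci outside the CI of a provisional null at the raw mean are
dropped and the mean recomputed. Classification uses equal-count He
bins (default 20) with linear interpolation of quantiles between bin
centres; the working p-value for the FDR step is the one-sided
empirical p on the locus's own side of the envelope — a two-sided
doubling could never clear the Benjamini-Hochberg rank-1 threshold at
any feasible cloud size, because empirical p-values are floored at
1/(bin size + 1). Power experiments use the conventional 100,000
simulations.

*Allele-environment associations.* For every locus x allele x
variable, logistic regression of individual allele presence/absence on
the individual's site value, fit by a vectorised 2-parameter IRLS
(50 iterations max, tolerance 1e-8; verified against the closed-form
2 x 2 solution and statsmodels). Wald = (beta/se)^2 against
chi-square(1); the Bonferroni divisor is the total number of tests
(alleles x variables). Complete separation (|beta| diverging) is
flagged and its p set conservatively to 1 rather than dropped.

## Problem sizes

Default test and reproduction runs use the 60 x 40 basin, ~126 shallow
cells, 2,000 trajectories per cell (2 h steps), 30 matrix powers,
Ne = 200 demes for 400 generations, 100,000-locus null clouds for
power experiments and 50-seed repetition counts — sizes chosen so the
complete suite and the reproduction script each run in minutes on a
single CPU while keeping every statistical check at its stated
repetition count.

## What the synthetic data does not show

The generator emulates the *statistical regime* of a brackish-basin
study — sample sizes, marker counts, background and outlier FST,
clines, asymmetric connectivity — not any real bathymetry, circulation
hindcast, or species biology. Passing tests demonstrate that the
estimators are correct, calibrated and powered under the stated
conditions; they do not validate a circulation model, and absolute
connectivity values have no physical meaning beyond their orders of
magnitude and asymmetry. Larval behaviour (vertical migration,
mortality, growth), 3-D flow, sea ice and riverine forcing are all
out of scope. Genotype data carry no null alleles or scoring errors,
so the QC filters are exercised on engineered fixtures rather than on
realistic failure modes.
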