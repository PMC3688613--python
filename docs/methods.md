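# Methods

`matenet` delimits two hybridizing species in a mixed stand from who
actually mates with whom.  The interfertility criterion of the
biological species concept is operationalized as community structure in
the *mating network*: an undirected, unweighted graph whose nodes are
adult trees and whose links mark at least one observed mating event
between two adults.  Under complete reproductive isolation species are
the connected components of that network; under a relaxed reading that
tolerates occasional hybridization they are its communities.  A
parallel criterion builds a *relatedness network* by thresholding
pairwise relatedness estimates.  Both networks are summarized with the
same mixed-membership block model, and the resulting assignments are
compared with genotype- and morphology-based references.

## The model

Each node i carries a membership vector u_i on the simplex over Q
extremal hypothetical nodes (EHNs).  Edges are independent Bernoulli
draws with

    pi_ij = u_i' B u_j,

where B is a symmetric Q x Q connectivity matrix with entries in
[0, 1] whose row and column 0 are identically zero: EHN 0 is a virtual
node connected to nothing.  It is always present and absorbs degree
heterogeneity — weakly connected adults (few sampled offspring) load
on EHN 0 rather than distorting the species EHNs.  Because pi_ij is a
convex combination of B entries it is automatically a probability.
The log-likelihood sums over unordered node pairs with probabilities
clipped to [1e-9, 1 - 1e-9].

With Q = 3 (EHN 0 plus one EHN per species) the membership simplex is
a triangle.  An individual is assigned to a pure species when its node
lies on the edge between EHN 0 and that species' EHN — concretely,
when its weight on the *other* species EHN is at most epsilon
(default 0.05; the absolute rule is used because simplex edges are
absolute loci).  Nodes inside the triangle mix both species EHNs and
are classified intermediate; nodes with almost all mass on EHN 0 are
also intermediate but flagged low-information, since the network
simply says little about them.

### Inference

Maximum likelihood by alternating projected-gradient ascent with
backtracking line search: B steps are projected onto the box with the
zero row/column re-imposed, U steps onto the simplex (per-row Euclidean
projection), and each accepted step strictly increases the
log-likelihood, so the iterate sequence is monotone.  The U update
moves all rows jointly under a single global backtracking search; the
objective is concave in B and in each row of U separately, and the
joint step vectorizes the sweep.  Convergence is a relative
log-likelihood change below `tol` (default 1e-6); `max_iter` defaults
to 2000.  Ten restarts are used by default: one softened spectral
initialization (leading eigenvectors, k-means on Q-1 clusters, EHN-0
loading proportional to degree deficit) plus random Dirichlet draws.
Model choice across Q uses AIC with k = n(Q-1) + (Q-1)Q/2 free
parameters (free simplex coordinates plus the free symmetric block of
B), with an explicit manual override, because the AIC-best model can
reflect the sampling design rather than biology (see below).

### Identifiability

Two conventions pin the EHN labelling: EHN 0 is the structural zero
row, and the remaining EHNs are sorted by descending within-EHN
connectivity.  A third is needed because the likelihood is *exactly
flat* under rescaling any species EHN's membership column by c > 0
with the corresponding B entries divided accordingly — EHN 0 absorbs
the slack and no pi_ij changes.  The package pins this ridge
archetype-style: each connected EHN is scaled so its best-represented
node attains membership 1 (the extremal node is the tightest hull
vertex).  B entries are therefore comparable across fits, but the
absolute scale of a *generating* B is unrecoverable in principle; only
the combination B_qq * max_i(u_iq)^2 is identified.

A related, genuinely statistical limit: when between-group connectivity
is very small but nonzero, maximum likelihood prefers to explain each
rare cross-group edge through a small opposite-membership of one
endpoint (of order 1 / (B_qq * sum_j u_jq), typically 0.04-0.1) rather
than through a nonzero between-EHN entry.  Nodes with a cross edge
therefore sit slightly inside the triangle, and a handful of truly pure
individuals are classified intermediate at epsilon = 0.05.  This is a
property of the likelihood itself — an optimizer started at the
generating parameters migrates to the same solution — and it bounds how
sharply planted mixed-membership structure can be recovered.

## Paternity and the mating network

Fathers are assigned by multilocus exclusion.  At each locus the
feasible paternal allele set is what remains of the offspring genotype
after removing one maternal contribution (if mother and offspring share
both alleles, either may be paternal); a candidate fails a locus when
he carries no feasible allele, and is excluded after more than
`max_mismatch` failures (default 0, strict exclusion; set 1 to tolerate
one genotyping error).  Offspring with exactly one surviving candidate
define mating events; ambiguous (multiple) and fatherless (none)
offspring contribute nothing, and mother-offspring incompatibilities
are flagged and dropped.  Each unique unordered mother-father couple
becomes one link; selfings are counted and dropped (the network is over
couples of distinct trees).  Exclusion is conservative: with complete
adult sampling and error-free genotypes a single-category assignment is
necessarily the true father, at the cost of a non-assignment rate.

## Relatedness

The estimator is the Queller-Goodnight moment estimator: per ordered
pair, locus numerators and denominators are summed before division, and
the two directions are averaged so r(i,j) = r(j,i) exactly.  Pairs with
fewer than `min_loci` (default 6 of 12, guarding high-variance
estimates) jointly genotyped loci, or a zero summed denominator, are
undefined.  With true frequencies the estimator is unbiased: about 0,
0.25 and 0.5 for unrelated, half-sib and full-sib dyads; frequencies
default to the adult sample.  The relatedness threshold is calibrated
as the maximum estimate among known-unrelated offspring pairs (pairs
from the progeny test sharing neither parent); adults strictly above it
are linked.  A fallback threshold of 0.22 is available when no
calibration pairs exist.  Ties at the threshold are non-edges.

## Congruence and the neighborhood effect

Pure-group names are arbitrary per criterion, so labels are first
harmonized against a reference criterion by the optimal 2x2 pairing on
the pure-by-pure overlap.  The summary counts individuals fully
consistent across criteria, species inversions (conflicting pure
labels), individuals intermediate by at least one criterion, and the
fraction of discrepancies involving only intermediates.  The
neighborhood test restricts to individuals whose genotype and
morphology assignments agree on a pure label, asks whether the
mating-based label matches that consensus, and regresses this
congruence indicator on the proportion of allospecific neighbors within
a radius (default 69 m, the mean in-stand pollen dispersal distance;
boundary inclusive, Euclidean distance, intermediates excluded as
neighbors).  The reported test is the likelihood-ratio chi-square with
1 df (a Wald statistic is also returned); complete separation yields a
flagged, unreliable result instead of an exception.

## The synthetic stand

The generator emulates a ~5 ha mixed stand of two wind-pollinated,
partially interfertile tree species:

- **Stand.** 298 adults by default (178 species A, 120 species B) with
  uniform positions on 200 x 250 m.  Species labels are spatially
  autocorrelated (`species_clustering`, default 0.75, mixing a
  long-axis gradient with uniform noise): mixed stands of related trees
  are strongly segregated with a mixed contact zone, and a spatially
  uniform stand would make every individual's allospecific-neighbor
  fraction nearly identical, leaving no neighborhood contrast at all.
- **Genotypes.** 12 unlinked codominant loci with 10 alleles each.
  Per-species frequencies interpolate between a shared Dirichlet draw
  and its opposite rank orderings (`differentiation`, default 0.8, a
  panel enriched for species-discriminating markers); genotypes are
  Hardy-Weinberg draws.  Adults are unrelated within species — the
  generator has no family structure, so a calibrated relatedness
  network over synthetic adults is legitimately sparse (only
  structure-noise pairs exceed the threshold).  Conclusions about the
  relatedness criterion on real stands, where natural regeneration
  creates pervasive kinship, do not follow from synthetic runs.
- **Mating.** 51 of 298 mothers sampled, ~60 open-pollinated offspring
  each.  A father j for mother i is drawn with weight
  exp(-d_ij / `dispersal_scale`) times `compatibility` (default 0.2)
  when heterospecific; selfing is excluded.  With probability
  `immigration` (default 0.45, echoing roughly 45% external
  paternities in stands of this kind) the father is external and the
  paternal gamete is drawn from species-level frequencies, the species
  chosen by stand composition.  Offspring genotypes are Mendelian, with
  an optional per-allele error that resamples from pooled frequencies.
- **Reference assignments.** The genotype criterion thresholds a
  maximum-likelihood admixture proportion (concave per-individual
  likelihood, grid argmax) at (0.2, 0.8); the morphology criterion
  thresholds a 1-D trait (species means 0/1, Gaussian noise 0.1) at the
  same cutpoints.  These stand in for external admixture-clustering and
  leaf-morphometric pipelines, which are inputs, not reproduced
  methods.  At a 12-locus panel a few percent of purebreds fall in the
  intermediate band — that is estimator sampling noise, not a bug.

A single integer seed fans out to fixed per-stage substreams, so every
pipeline run is byte-for-byte reproducible.

## The sampling-design artifact

On the partial progeny design only mothers can acquire high degree, and
father-father pairs can never be linked.  This bipartite tendency is a
*likelihood-dominant* structure: on default-scale synthetic networks the
Q = 3 maximum-likelihood fit can place all connectivity between two
EHNs (mothers vs fathers) instead of within two species EHNs.  The
package flags such fits (`csbm.connectivity_structure`) rather than
hiding them; covariate-adjusted block models that could absorb the
design are out of scope.  Two features weaken the artifact: spatial
species clustering (which concentrates each mother's links in her
conspecific neighborhood) and, decisively, a complete progeny design in
which every adult is sampled as a mother — the design used by the
strict-isolation and neighborhood-effect validation scenarios
(`analysis/07_complete_design.py`, 20 offspring per mother to keep
runtimes modest).

## Validation scenarios and their sizes

The acceptance suite runs on one CPU in a few minutes: 1000 dyads per
kinship class for estimator calibration; 20 random 6-node graphs
against a 2000-draw Monte-Carlo oracle; planted-model recovery at
n = 200 over 10 seeds; strict isolation (compatibility 0, immigration
0, complete design) on one 298-adult stand; the neighborhood effect at
compatibility 0.2 over 10 seeds; 500-replicate chi-square calibration
of the LRT; paternity soundness over ~3000 offspring.  The planted
model uses pure-edge memberships drawn uniform on (0.3, 0.95) and 10
interior Dirichlet(2) nodes.

## Known limitations

- Mating events per couple (~1.2 on defaults) are lower than real
  stands show (~2.2): male reproductive success is unmodelled, so the
  synthetic mating network has more distinct couples than a real
  progeny test of the same size.
- No adult family structure, multi-year masting, seed dispersal,
  linkage, or realistic leaf-trait distributions.
- The triadic likelihood relatedness estimator is not implemented; a
  precomputed relatedness matrix can be imported to preserve fidelity
  on real data.
- The B matrix of a fit is interpretable only under the archetypal
  scale convention described above; comparing raw B entries to a
  generating model's values is meaningless without it, and residual
  membership leakage makes very small between-group entries collapse to
  zero with the cross edges absorbed into memberships.
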