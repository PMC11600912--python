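# Methods

## Model

All evaluations use a multi-parity animal model in which parities 1–5 of a
305-day yield trait are distinct, correlated traits: y = Xβ + u + e with
u ~ N(0, K ⊗ G₀) (animal-major ordering) and block-diagonal residuals — an
animal with observed parity set O contributes the submatrix R₀[O, O], so
missing later parities are handled by trait-wise residual submatrices, not
imputation. Fixed effects are herd × year × season (shared across
parities; one reference level dropped for estimability) and farm type
within parity, which doubles as the per-parity intercept. A tiny ridge
(1e−6) on the fixed-effect diagonal acts as a vague prior so that levels
disconnected from the rest of the design in small datasets stay estimable;
it perturbs well-posed solutions at the 1e−6 level and keeps the REML
identities consistent (it is simply part of the coefficient matrix).

### Relationship matrices

A⁻¹ is assembled sparsely from Henderson's rules with exact inbreeding by
the Meuwissen–Luo algorithm; `diag(A) = 1 + F` is verified property-wise.
Unknown-parent genetic groups use the phantom-parent device: group columns
(keyed by sex, birth-year bin, missing-parent slot; 5-year bins by
default, configurable because the grouping bin width is a convention)
are appended after all animals, unknown parents point at their group, and
the Mendelian-sampling variance treats the slot as unknown. Group
equations carry no data and are confounded with a fixed constant, so a
1e−8 ridge keeps them non-singular. Exact reliabilities are computed from
systems without groups.

The genomic matrix is VanRaden's first method with observed allele
frequencies computed on the genotyped subset (base-population founder
frequencies are unobservable in practice); missing
dosages are mean-imputed to 2p before centring. G is adjusted to A22 by
the two-statistic linear map α + βG matching diagonal and off-diagonal
means, then blended with polygenic weight w: G_w = (1−w)G_tuned + w·A22.
H⁻¹ adds (G_w⁻¹ − A22⁻¹) on the genotyped block; below w = 0.05 a 1e−8
ridge guards the inversion against marker-limited rank deficiency.

### ssSNPBLUP

The marker-effects flavour solves for breeding values u of all animals,
SNP effects g, and one genomic-mean effect per parity. Writing the
genotyped block as u₂ = 1c + Zg + a₂ with Var(c) = (1−w)α·G₀,
Var(g_j) = (1−w)β/s·G₀ (s = 2Σp(1−p)) and Var(a₂) = w·A22 ⊗ G₀, and
attaching u₁ through the pedigree, yields a joint precision using only
A⁻¹, A22⁻¹ and Z. Eliminating (c, g) recovers exactly the H⁻¹ built from
G_w = (1−w)(α + βZZ′/s) + w·A22, so the two flavours agree to solver
precision; the suite asserts 1e-4 relative and observes ~1e-13. The
genomic-mean effect carries the tuning constant α; when the tuned α is
negative the corresponding precision entry is negative and the system is
solved by the direct factorization (the identity is algebraic and does
not require a PD joint prior). w = 1 drops the marker block (ABLUP);
w = 0 is rejected with a hint to add polygenic variance.

### Solvers

Direct sparse LU with the MMD-AT-PLUS-A ordering (an order of magnitude
less fill-in than the default on the dense genotyped block) is the
default; preconditioned conjugate gradients with a Jacobi preconditioner
(relative-residual tolerance 1e−10) serve large SPD systems. Prediction-
error covariance blocks come from a dense inverse for systems of ≤ 2,000
equations and from exact per-animal column solves against the cached
factorization above that — simpler than a Takahashi selected inverse and
exact for the animal subsets the experiments need.

### REML

`MultiParityREML` maximises the REML log-likelihood over the 30 free
elements of (G₀, R₀) — or fewer when some parities carry no records, in
which case the model reduces to the observed traits. Score and AI matrix
are computed exactly from the inverted coefficient matrix (problem sizes
are desk-scale, so a dense inverse per iteration is affordable); the
update is the undamped AI step when it climbs, otherwise the best of
Levenberg-damped AI steps and EM steps with over-relaxed extrapolation
(κ up to 8), which cures the geometric EM crawl near variance boundaries.
Non-PD proposals are repaired by eigenvalue bending (floor 1e−8, relative
1e−5); candidates are accepted only if the log-likelihood does not
decrease, so the accepted path is monotone by construction. Convergence:
relative parameter change < 1e−3 (default) or log-likelihood gain below
1e−6·|logL|. SEs come from the inverse AI matrix; h² SEs by the delta
method. Starting values are 40/60 splits of the per-parity phenotypic
variances.

### Reliabilities and index

r²ᵢ = 1 − (wPᵢw′)/((wG₀w′)·diag(H)ᵢ) with the lactation-index weight
vector w = (1, 0.73, 0.51, 0.34, 0.21)/2.79; the ratio is invariant to
the scaling of w (both quadratic forms scale identically), which a unit
test asserts, so the normalised vector is used. diag(H) for non-genotyped
animals is the pedigree diagonal plus the genomic projection
A₁₂A22⁻¹(G_w − A22)A22⁻¹A₂₁ — the joint-matrix diagonal; with no
genotypes it reduces to 1 + F. Reliabilities outside [0, 1] by less than
1e−6 are clamped with a warning, larger excursions raise.

## Synthetic herds

The generator emulates the data structure of a small national Holstein
herdbook: overlapping generations; a handful of widely used service
bulls per year (drawn from a small service pool, producing large paternal
half-sib families); cows calving first at age two with up to five
parities inside the simulated span, so late-born cohorts have genotypes
but no or few records — exactly the forward-prediction regime; herd ×
year × season and farm-type effects drawn as Gaussian conventions
(SD 0.5 and 0.25 on a unit-phenotypic-variance scale); and selective
genotyping concentrated in recent birth years (bulls ~0.9 throughout,
cows ramping from 0 to 0.8 over the last eight cohorts).

Genetics: founders are drawn in Hardy–Weinberg proportions at uniform
[0.05, 0.5] frequencies; descendants by gene dropping over independent
loci (no recombination map or LD decay — a stated non-goal). True
breeding values are the sum of a QTL part (a random marker subset with
Gaussian effects rescaled so the founder-generation marker variance
equals exactly `marker_share`·G₀, default 0.8 so the polygenic-weight
experiments have a known optimum away from the edges) and a residual
polygenic part recursed through the pedigree with Mendelian-sampling
variance from the exact inbreeding coefficients. The default G₀/R₀ give
per-parity heritabilities (0.47, 0.36, 0.29, 0.25, 0.21) on unit
phenotypic variance — the declining pattern typical of repeated
lactations — with genetic correlations 0.9^|lag| and mild residual
correlations 0.25·0.8^(lag−1). Truncation selection of parents on
first-parity TBV is available behind a flag but off by default, because
selection induces the very inflation the validation experiments measure
and the acceptance checks assume an unselected base.

What passing tests on these herds do not show: robustness to LD
structure, genotyping error, preferential treatment of genotyped cows,
multi-breed structure, or selection — the generator's defaults are the
unbiased, known-truth regime that makes parameter recovery and oracle
equivalence provable.

## Study conditions (scaled down)

The validation studies run at sizes a workstation solves in minutes; the
statistical structure, not the scale, is what the checks exercise.

- Flavour equivalence and degenerate limits: one herd of ~420 animals,
  200 markers, ~220 genotyped.
- Relationship oracles: 50 random pedigrees of 50–300 animals; ten
  30-animal single-step instances.
- REML recovery: 20 replicate herds of ~330 animals (~950 records over
  5 parities, pedigree restricted to four ancestor generations of the
  recorded cows, mirroring the variance-component protocol), AI-REML at
  tol 1e−3; each parity's h² is compared with its simulated truth at two
  reported SEs, pooled over replicates × parities.
- Truncation slope: 10 replicate herds of ~2,000 animals (~650
  genotyped), ssGBLUP at w = 0.5, cutoff four years before the last
  calving; candidate sires are genotyped bulls whose first daughters
  calved after the cutoff (the real-data reliability threshold of 0.75
  is a `CandidateRule` parameter, off by default because scaled-down
  herds sit below it).
- Genotyped-fraction study: one ~1,550-animal herd with few service
  bulls and large paternal half-sib families, fractions
  (0, 0.25, 0.5, 0.75, 1) of one sex's genotypes, 10 random subsets per
  interior fraction (edges are deterministic), the other sex fixed at
  fully genotyped. Both arms — complete and truncated records — are
  evaluated with the same genotype subset, so the zero fraction of both
  sexes reduces to the pedigree-only comparison; the sampled pool is
  restricted to genotyped animals with phenotypic data before the
  cutoff (own records for cows, daughter records for bulls), the
  training animals whose genotypes inform the truncated arm. The rising
  correlation-with-fraction pattern is a property of the
  daughter-dominated candidate regime: when candidate sires have few
  recorded daughters even in the complete data, added cow genotypes
  sharpen the complete arm as much as the truncated one and the
  correlation can fall instead — a regime the published herdbook is not
  in. The published-table arithmetic for cows-per-bull equivalence
  divides edge correlation gains by the genotyped counts and rounds to
  one decimal (trailing .0 dropped, so 4.96 reports as "5").
- Polygenic sweep: grid 0.1–0.9 in steps of 0.1, six replicate herds,
  reporting mean slope and correlation series and their trend
  correlation. The two directions the sweep exhibits — slope rising and
  correlation falling with the polygenic weight — rest on competing
  mechanisms in a known-truth world: the correlation falls only when the
  markers carry most of the genetic variance (true polygenic weight near
  the bottom of the grid), whereas a below-one slope rising toward one
  requires the predictions to be overdispersed at low weight (true
  polygenic weight high, or selection-induced inflation). With the
  default marker share of 0.8 the replicate-mean directions hold and
  strengthen as replicates are added, but they are properties of the
  replicate mean, not of every individual herd: single herds, or herds
  drawn under a different master seed, can show a flat or reversed slope
  series. Real populations sit in a regime (strong LD-based genomic
  information, intense selection, very large daughter counts) that this
  recombination-free generator reproduces only in aggregate.

## Known limitations

Dense per-iteration inverses cap REML at a few thousand equations; the
MME solvers handle tens of thousands but not national scale (no APY or
iteration-on-data). Genetic groups are attached to the pedigree part
only. The two-step national evaluation that the averaging operation
consumes is an external input, not reimplemented.
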