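# Methods

## Study design emulated

The package targets a two-group replicate design: ten thin (~50 µm, "Z50")
and ten thick (~400 µm, "Z400") biofilm communities characterized by a
sample × sequence-variant count table.  All inference runs on rarefied
counts; presence/absence analyses use a presence threshold of count ≥ 1
after rarefaction, with no relative-abundance filtering.  An optional
minimum-total-count taxon filter exists but defaults to off, since whether
rare variants should be removed before diversity estimation is a
study-specific choice.

## Rarefaction and Hill numbers

Rarefaction is one multivariate-hypergeometric draw per sample (subsampling
without replacement) to a common depth, by default the smallest sample
total.  A single draw, not an average over repeats, is used — the common
convention — and the seed is a required, logged parameter.  Hill numbers use
the natural logarithm; ¹D = exp(−Σ pᵢ ln pᵢ) restores units of effective
taxa, so 1 ≤ ¹D ≤ ⁰D and evenness ¹D/⁰D ∈ (0, 1].

## Beta partition and the β-ratio

The Baselga decomposition is computed per pair from the incidence components
(a, b, c); the identity β_sim + β_sne = β_sor holds to machine precision by
construction (β_sne is computed as the difference).  Pair-set summaries are
produced for within-group-1, within-group-2 and between-group pairs.  The
authoritative β_ratio is the ratio of pair-set *means* (mean β_sne / mean
β_sor) rather than the mean of pairwise ratios: pairwise ratios are unstable
when β_sor ≈ 0 (near-identical samples).  Both variants are reported; the
ratio is reported as undefined (NaN), not 0, when mean β_sor = 0.  A group
with fewer than two samples gets an absent (NaN) within-group summary, not
an error.

## Quasiswap null model and SES

Null incidence matrices preserve each sample's richness (row sums) and each
taxon's incidence (column sums) exactly.  One replicate is built by

1. random sequential allocation of an integer matrix with the observed
   marginals (a shuffled multiset of column labels dealt to rows),
2. quasiswap moves on random 2×2 submatrices until all entries are 0/1 —
   the submatrix is drawn with one corner on a super-binary cell, which is a
   rejection-free equivalent of uniform picks (a 2×2 without any entry > 1
   never yields an accepted move); moves that keep the super-binary count
   constant are also accepted, because dense matrices admit states with no
   single strictly-reducing move,
3. a burn-in of plain checkerboard swaps, 10 × matrix fill attempts: a
   symmetric Markov chain whose stationary distribution is uniform over the
   feasible matrix set.  On enumerable instances the sampled distribution is
   statistically uniform (chi-square test in the suite).

The burn-in length and the binarization iteration cap are implementation
constants logged in CLI output.  Per pair, SES = (observed β_sor − null
mean)/null s.d. (s.d. with one delta degree of freedom) over 999 replicates
by default; pairs with zero null s.d. are reported undefined and excluded
from set means with a logged count.  Within-group analyses restrict the
regional pool: the group's sub-table is randomized after dropping taxa
absent from the group.  Between-group pairs are always evaluated against
randomizations of the full 20-sample table; whether a joint per-group
randomization should be used instead is not decidable from the design, and
the full-table reading is the default.

## Raup–Crick with Bray–Curtis

Null communities for RC_bray preserve each sample's observed richness and
total read count: taxa are drawn without replacement with probability
proportional to their occurrence frequency across all samples (an
unweighted option exists), each drawn taxon receives one individual, and the
remaining individuals are distributed multinomially with probability
proportional to the drawn taxa's regional relative abundances.  Because
totals are preserved, observed and null Bray–Curtis values for a pair share
a denominator, so the below/equal/above comparisons are exact integer
comparisons; ties count at half weight:
RC = 2·((n_below + 0.5·n_equal)/n_reps) − 1 ∈ [−1, 1].

A caveat the validation quantifies: when a single shared taxon dominates
abundances on both sides, observed quantitative dissimilarity is genuinely
close to its null expectation even under complete turnover of the remaining
taxa, and mean RC can sit well below +0.95.  The quantitative recovery
condition is therefore defined on disjoint group pools; the incidence-based
SES recovers the shared-core scenarios regardless.

## PERMANOVA and PCoA

PERMANOVA uses the distance-based identity (no coordinate embedding):
SS_total = Σ_{i<j} d²ᵢⱼ/N, SS_within = Σ_g Σ_{i<j∈g} d²ᵢⱼ/n_g,
F = (SS_between/(a−1))/(SS_within/(N−a)).  The permutation p-value uses the
+1 convention so p is never 0; when the number of distinct label
arrangements is at most the requested permutation count, they are enumerated
exhaustively and p is the exact proportion (identity arrangement included).
Only the one-factor design is supported.  Note that β_sne is not a proper
dissimilarity; PERMANOVA on it can yield negative pseudo-F/R² for pathological
tables, which the report passes through rather than masking.  PCoA is
classical metric MDS: double-centering −½·J·D²·J, symmetric
eigendecomposition, coordinates scaled by √λ; negative eigenvalues are
reported and their axes dropped, and proportions explained are over the sum
of positive eigenvalues.

## Synthetic-community generator

Each group has a regional pool = shared core + group-exclusive taxa
(turnover control) + extra taxa in group 2 only (nestedness control; group
1's pool is then a strict subset).  Per replicate, each pool member occurs
independently with probability `occupancy` (drift), and read counts are one
multinomial draw at a depth uniform in `depth_range`, so depths are exact.
Taxon mean relative abundances are log-normal and fixed across replicates;
core taxa share one draw between groups while group-exclusive taxa get their
own, so between-group differences are purely deterministic (pool membership)
and a single-pool scenario is exactly neutral — drawing core abundances
separately per group would contaminate the neutral calibration with
deterministic abundance differences.

Defaults: 10 samples per group; occupancy 0.9 (0.8 in the neutral preset,
placing within-group variation safely inside the |SES| < 2 band, which no
published within-group variance estimate constrains more tightly);
log-normal σ = 1.0, a conventional species-abundance-distribution shape;
depths 5,000–10,000 reads.  Scenario presets: `neutral` (one pool of 100),
`turnover` (core 20, 40+40 exclusive), `nestedness` (core 50, 40 extra),
and `study_like` (~3,500 taxa, 30,000–60,000 reads, group-2 richness excess)
for scale-realistic smoke tests.  The generator emulates richness asymmetry,
shared cores, turnover/nested structure and uneven sampling; it does not
emulate phylogenetic structure, sequencing error/chimeras, or within-biofilm
spatial structure — so passing recovery tests demonstrate correctness of the
inference machinery under the stated assembly regimes, not robustness to
those unmodelled features of real amplicon data.

Validation conditions (fixed in the suite): neutral SES coverage pooled over
10 seeds × 190 pairs with 999 null replicates; regime recovery over 20 seeds
per scenario; every run seeded by stable string-hash derivation from one
master seed, so results are bit-reproducible and adding a stage never
perturbs another stage's stream.

## Biofilm oxygen model

Steady-state 1-D reaction–diffusion for DO, NH₄-N, NO₂-N and soluble
organics (COD): D_k·d²S/dz² = Σ ν·r(z, S) with zero flux at the substratum
and flux continuity through a diffusive boundary layer at the interface,
D_w(S_bulk − S(L))/L_BL = D_f·dS/dz|_L.  Guild rates are dual-Monod:
r_j = q_max,j · f · X(z) · fraction_j(z) · S_sub/(K_sub+S_sub) · S_O2/(K_O2+S_O2),
with f the active fraction of the measured dry solids (the 20–80% scenario
dial), X(z) the density profile and fraction_j(z) the guild's depth profile
(qFISH-style input data, interpolated from breakpoints).  Stoichiometry:
heterotrophs consume 1 − 1.42·Y_H g O₂ per g COD (Y_H = 0.45 gVSS/gCOD →
0.361); AOB 3.43 g O₂ and NOB 1.14 g O₂ per g N, with NO₂-N produced 1:1
from NH₄-N.  Kinetic defaults are literature-style activated-sludge /
nitrifier constants (q: 8 gCOD, 5 gN, 8 gN per g biomass per day; K_O2 0.2 /
0.5 / 0.68 mg/L; K_sub 5 / 1.0 / 0.5 mg/L), stored on the config and fully
user-overridable; bulk defaults are DO 5.5 mg/L, NH₄-N 19.6 mg/L, NO₂-N
0.5 mg/L, COD 30 mg/L.  Anammox is deliberately absent from the oxygen
model (strictly anaerobic; it does not consume O₂), and the model resolves
heterogeneity in the depth direction only — no lateral transport, channels
or voids, which in real biofilms can carry oxygen deeper locally.

Numerics: conservative vertex-centred finite volumes on a uniform grid
(200 nodes by default; a uniform grid is adequate at these thicknesses), damped Newton
with an analytic sparse Jacobian, concentrations clipped at zero between
iterates, convergence at a scaled residual of 1e-8 of each solute's
characteristic flux.  Because the scheme is conservative, the interface flux
equals depth-integrated net consumption to solver tolerance (the suite
checks 0.1%).  Near-zero-order kinetics (K → 0) are stiff; when the direct
solve stalls, a continuation floors the Monod constants at a decreasing
sequence, warm-starting each stage.  The anoxia threshold for the anoxic
fraction is DO < 0.1 mg/L (configurable; "anoxic" has no canonical numeric
definition).  Boundary-layer calibration is bisection of L_BL ∈ [1, 2000] µm
against a measured areal ammonium-oxidation rate to 0.5% relative tolerance,
with the monotone decrease of flux in L_BL checked at the bracket ends; the
intended anchor is an areal rate measured under the continuous operating
conditions rather than a potential batch rate.

Default thin/thick presets: Z50 — 50 µm, 100 kg/m³ dry solids, uniform
guild fractions (het 0.50 / AOB 0.35 / NOB 0.15), reflecting a denser, more
homogeneous thin film; Z400 — 400 µm, density grading 60 → 30 kg/m³ from
substratum to surface, AOB enriched in the upper third and NOB in the middle
depths, supplied as breakpoint data rather than hard-coded.  Boundary layer
50 µm by default.  With these inputs the model yields the qualitative
contrast the suite asserts: the 400 µm film keeps an anoxic region at every
active fraction in 0.2–0.8, while the 50 µm film is fully oxygenated at low
active fractions and partially anoxic at high ones.

## Known limitations

* The quasiswap chain's uniformity is verified on enumerable instances;
  for large matrices uniform mixing rests on the burn-in heuristic.
* RC_bray's null-assembly weighting (occurrence-weighted draws,
  abundance-weighted filling) is one member of a family; the unweighted
  variant is exposed, and conclusions near the ±0.95 boundary should be
  checked under both.
* PERMANOVA assumes exchangeability under the null; no dispersion
  (PERMDISP-style) test is included, so a significant result can reflect
  dispersion as well as location differences.
* The oxygen model is steady-state and 1-D: no growth/detachment dynamics,
  no 2-D/3-D structure, no anammox kinetics.
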