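# biofilm-assembly

Does biofilm thickness deterministically structure nitrifying microbial
communities?  In moving bed biofilm reactors (MBBRs), carriers with different
wall heights cap biofilm thickness at roughly 50 µm or 400 µm; comparing ten
replicate communities of each type asks whether the thin community is a
nested, aerobic subset of the thick one, a different community altogether
(turnover), or just a random draw from a common pool.  This package
implements the complete statistical machinery for that question, plus the
physical model that links thickness to oxygen availability, and a synthetic
community generator that provides ground truth for validating every stage.

## What it computes

**Alpha diversity** (`biofilm_assembly.alpha`) — counts are rarefied to even
depth (subsampling without replacement), then the first two Hill numbers are
reported per sample: richness ⁰D, diversity ¹D = exp(−Σ pᵢ ln pᵢ), and
evenness ¹D/⁰D.

**Beta-diversity partition** (`biofilm_assembly.beta`) — pairwise Sørensen
dissimilarity and its Baselga decomposition.  For a pair with *a* shared
taxa and *b*, *c* taxa unique to each sample:

    β_sor = (b + c) / (2a + b + c)
    β_sim = min(b, c) / (a + min(b, c))        (turnover)
    β_sne = β_sor − β_sim                      (nestedness-resultant)

and the dominance statistic β_ratio = β_sne/β_sor per pair set (within each
group, between groups): below 0.5 turnover dominates, above 0.5 nestedness.

**Null models** (`biofilm_assembly.nullmodels`) — quasiswap randomization of
the incidence matrix (exactly preserving sample richness and taxon
incidence; 999 replicates by default) yields the standardized effect size
SES = (observed β_sor − null mean)/null s.d. per pair, with |SES| > 2 as the
deterministic-assembly criterion; within-group runs restrict the regional
pool to taxa present in the group.  The abundance-based Raup–Crick metric
RC_bray compares observed Bray–Curtis dissimilarities with richness- and
abundance-constrained null assemblies; |RC| > 0.95 flags deviation from the
stochastic expectation.

**PERMANOVA and PCoA** (`biofilm_assembly.ordination`) — one-factor
permutational ANOVA on any of the dissimilarity matrices (pseudo-F, R²,
permutation p with the +1 convention, exhaustive enumeration when feasible)
and classical principal coordinate analysis, both from first principles.

**1-D biofilm oxygen model** (`biofilm_assembly.biofilm`) — steady-state
reaction–diffusion of O₂, NH₄-N, NO₂-N and soluble organics across the
biofilm depth, with heterotroph/AOB/NOB dual-Monod kinetics, a diffusive
boundary layer calibrated against a measured areal ammonium-oxidation rate,
and scenario sweeps over the active-biomass fraction (20–80% of dry solids).

**Synthetic communities** (`biofilm_assembly.synthetic`) — 10+10 replicate
count tables with a controllable shared core, group-exclusive pools
(turnover), nested extra taxa (nestedness), occupancy drift and multinomial
read sampling, plus the ground-truth regime label for recovery tests.

Analysis classes follow the scikit-learn estimator convention
(`Rarefier`, `HillDiversity`, `SorensenPartition`, `QuasiswapSES`,
`RaupCrick`, `PCoA`), with plain functions as thin wrappers.

## Worked example

Generate a turnover-dominated synthetic study and run the full chain:

```bash
biofilm-assembly synth --preset turnover --seed 42 \
    --out counts.tsv --meta meta.tsv --truth truth.json
biofilm-assembly run --counts counts.tsv --meta meta.tsv \
    --out out --reps 999 --perms 999 --seed 42
```

prints the verdict block

```json
{
  "between": "deterministic",
  "between_beta_ratio": 0.007441737270445685,
  "dominance": "turnover",
  "signals": {
    "mean_between_rc": 0.9998398398398399,
    "mean_between_ses": 6.182634831236055,
    "within_Z400_frac_abs_ses_lt_2": 0.9555555555555556,
    "within_Z50_frac_abs_ses_lt_2": 0.9111111111111111
  },
  "within": "stochastic"
}
```

Between-group pairs are far more dissimilar than the marginal-preserving
null expects (mean SES ≈ +6.2, far beyond +2; mean RC ≈ +1.0): assembly
between the two thickness classes is deterministic.  Within-group pairs sit
inside |SES| < 2 for ~91–96% of pairs: replicates of the same thickness are
consistent with stochastic assembly.  The between-group β_ratio ≈ 0.007 —
far below 0.5 — correctly identifies species replacement (turnover), not
nested species loss, as the dominant component, matching the generator's
ground truth (`truth.json` records `"regime": "turnover_dominated"`).
`out/beta_summary.tsv` carries the pair-set means behind these numbers
(e.g. mean between-group β_sor 0.690 vs β_sne 0.005).

The oxygen model reproduces the thin/thick contrast from bulk conditions
(DO 5.5 mg/L, NH₄-N 19.6 mg/L) and literature kinetics:

```bash
biofilm-assembly biofilm1d sweep --preset z400 --out-prefix z400_
# anoxic_fractions: {0.2: 0.43, 0.4: 0.65, 0.6: 0.74, 0.8: 0.78}
biofilm-assembly biofilm1d sweep --preset z50 --out-prefix z50_
# anoxic_fractions: {0.2: 0.0, 0.4: 0.0, 0.6: 0.0, 0.8: 0.14}
```

the 400 µm biofilm holds an anoxic region in every active-biomass scenario,
while the 50 µm biofilm is fully oxygenated unless most of its dry solids
are active.

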