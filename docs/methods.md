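# Methods

This note documents the models, defaults and numerical choices behind
`famseg`, and what the synthetic generators do and do not emulate.

## 1. Genetics stage

### Pedigree and genotype simulation

The built-in family (`famseg.examples.af_family`) is a three-generation
pedigree with atrial fibrillation as the affection status: unsequenced
founders, six siblings in generation II (one affected sibling deceased and
unsequenced, one unaffected sibling sequenced), a married-in spouse, and two
affected sons in generation III. Seven members carry exomes; six of them are
affected. The exact status of the unsampled members is a reconstruction —
they influence Mendelian transmission only.

Genotypes are produced by gene-dropping (`simulate_pedigree_genotypes`):

* *causal* variants are planted heterozygous in an explicit carrier list
  (the co-segregation pattern the screen must find) and hom-ref elsewhere;
* *background* variants draw founder genotypes from Hardy–Weinberg
  proportions at the variant's population MAF and transmit one allele per
  parent per child, so every trio is Mendelian-consistent by construction.

Background variants default to common (MAF uniform on 0.05–0.45) because
their role is to power kinship estimation, not to stress the rarity filter;
their ref/alt alleles are drawn with a transition bias giving an expected
exome-like TiTv of 2.72. All draws come from one `numpy` generator seeded
per call; per-cell/per-member streams are spawned from a `SeedSequence`, so
outputs are bit-reproducible and independent of cohort size.

What the generator does **not** emulate: linkage disequilibrium, genotyping
error, coverage-dependent missingness, sex chromosomes, and de novo
mutation. Passing tests therefore show the filters and estimators are
implemented correctly, not that they are robust to artifacts of real exome
data.

### Filters

Rarity (`rarity_filter`): pass iff (max GnomAD subpopulation MAF < 1e-4 OR
in-house MAF < 1/(2·1972)) AND dbSNP status ∈ {absent, non_common}. MAFs
are fractions everywhere; annotation tables that quote percentages must be
converted on construction (the built-in candidate fixtures store 0.3526% as
0.003526). Missing annotations fail closed by default (`unannotated`
reason), configurable to pass.

Co-segregation (`cosegregation_filter`): dominant model — every sequenced
affected member must be het or hom-alt; sequenced unaffected carriers
disqualify (both togglable). Members without exomes never vote. Missing
genotypes in an affected member fail conservatively by default,
configurable to `ignore-member`; either way the per-member evidence is
returned.

Ranking: CADD descending, then GERP descending, then variant id — a total
order, so the table is invariant to input permutation.

### Kinship

`king_robust_kinship` implements the robust between-family concordance
estimator (het–het and opposite-homozygote counts over shared non-missing
sites). It is exact for duplicates (φ = 0.5) and unbiased near 0.25/0.125
for first/second-degree pairs under the simulator. A floor of 100 shared
informative sites (configurable) guards against unstable estimates; the
pipeline default of 2000 background markers keeps the per-pair sampling
error near 0.02, comfortably inside the powers-of-two degree bins
(monozygotic > 2^−1.5; first (2^−2.5, 2^−1.5]; second (2^−3.5, 2^−2.5];
third (2^−4.5, 2^−3.5]; otherwise unrelated). `verify_pedigree` compares
inferred bins against bins of the pedigree-expected kinship computed by the
classic recursion.

## 2. Electrophysiology stage

### Channel model

Whole-cell current: I(t) = g_max·C_m·m(t)·h(t)·(V(t) − V_rev), one
activation gate m and one inactivation gate h, Boltzmann steady states,
first-order relaxation. Within each constant-voltage protocol segment the
gate ODEs are linear, so gates are advanced with the exact exponential
solution — the integrator has no step-size error; the sample interval only
sets measurement resolution (0.05 ms for millisecond-scale protocols, 1 ms
for multi-second ones). The driving force is ohmic, matching the analysis
assumption of local IV linearity between +10 and +30 mV; GHK rectification,
Ca-dependent inactivation, stochastic single-channel gating and ancillary
subunit effects are deliberately out of model.

m uses τ_act (default 1.5 ms) above −40 mV and τ_deact (1.0 ms) below it;
h uses a single τ_inact for entry and recovery. τ_act/τ_deact are model
choices — no published values exist for them — and are kept short enough
that activation equilibrates within the 20 ms IV step.

Presets (`channel_preset`): `wt` and `v1686m` set V50 of activation
(−1.0 / +2.4 mV), V50 of inactivation (−39.0 / −35.7 mV; the WT value is
printed unsigned in the source but is physiologically negative) and τ_inact
(386 / 316 ms) to the published group means. Slopes default to k_act = 3 mV
and k_inact = 5 mV (not published; k_act is chosen steep enough that the
+10..+30 mV reversal-potential window sits near full activation — see
Limitations). V_rev = 40 mV. g_max is not a frozen number: it is calibrated
at preset construction so the noiseless simulated peak current density
equals the published mean (−21.8 / −21.2 pA/pF).

### Protocols

* `iv`: 20 ms steps, −60..+70 mV in 5 mV increments, holding −80 mV.
* `ssi`: per-sweep conditioning at −100..+30 mV held 5 s (≥ 10·τ_inact, so
  h equilibrates; simulating a longer ladder would change nothing but run
  time), then a +20 mV test pulse.
* `tail`: +20 mV for 20 ms, then 30 ms test pulses −80..+10 mV.
* `slow_inact`: a single 3 s step from −80 to +20 mV.

### Cohort variability

`CohortSpec` draws per cell: g_max lognormal (CV 0.5), both V50s normal
(SD 3.0 mV), τ_inact lognormal (CV 0.3), capacitance lognormal (mean 15 pF,
CV 0.3); lognormals are arithmetic-mean-preserving so cohort means sit at
the preset values. Recording noise is white Gaussian, 5 pA per sample.
The dispersions were set once from the published SEM·√n scales (e.g.
τ_inact: 23·√26/386 ≈ 0.30; peak density: 1.9·√25/21.2 ≈ 0.45 and
2.6·√32/21.8 ≈ 0.67, split at 0.5; the V50 SDs implied by the four printed
SEMs range ~2.7–12 mV and 3.0 mV is taken near the activation-side values).
Real cells additionally show series-resistance error, leak, rundown and
capacitive transients; none are modeled, and the analysis accordingly does
no leak or Rs compensation.

### Analysis

Peak current is the signed largest-magnitude extremum in the test window,
after a 5-sample boxcar that stands in for the low-pass filtering applied
to real records before cursor placement (without it, the extremum of ~400
noisy samples is biased away from zero by ≈ σ·√(2 ln N)). V_rev is the
x-intercept of the OLS line through IV points in +10..+30 mV (≥3 points,
positive slope required). The conductance transform excludes points within
5 mV of V_rev (0/0 guard). Boltzmann fits are two-parameter (V50, k),
initialized at the interpolated half-max crossing with k = 5 mV, k bounded
in (0, 30], Levenberg–Marquardt-style least squares with 1e-10 tolerances —
deterministic by construction. Exponential fits use y = A·exp(−t/τ) + C
with endpoint-based initialization; tail fits skip the first 2 samples
after the transition (capacitive-transient guard, inert for simulated
data). Fits that fail, peg a parameter at its bound, or place V50 outside
the sampled voltage range return `converged=False` and are skipped by
cohort summaries — mirroring per-cell quality control, and the reason the
per-quantity n can differ within a group.

Group statistics: unpaired two-sided pooled-variance t-tests for scalars;
fixed-effects two-way ANOVA (group × voltage with interaction, cells as
replicates — no repeated-measures structure is claimed) for curves, with
per-voltage t-tests Šidák-adjusted as p_adj = 1 − (1−p)^m.

## 3. Pipeline

`run_all` executes: simulate family files → re-read → TiTv QC → kinship +
pedigree verification → rarity/co-segregation/ranking → per-group cohort
simulation under iv/ssi/slow_inact at the published per-group n (32/20/26
WT, 25/18/24 variant) → per-cell fits → group comparisons. The resolved
YAML config is written next to the outputs; the log records version, seed,
input digests and per-stage decision counts. Identical config + seed gives
byte-identical tables.

Problem sizes throughout (2000 background markers, published cohort n,
desk-scale protocols) keep a full run in seconds while leaving every
statistical check well-powered.

## 4. Known limitations

* **Reversal-potential regression bias.** Because activation is incomplete
  at +10 mV, the +10..+30 mV x-intercept overestimates V_rev by ~0.5 mV
  (WT) to ~1.5 mV (variant preset), and more for cells whose drawn V50 is
  high. Propagated through the conductance transform this attenuates fitted
  activation V50 by ~0.1–0.3 mV at the preset means (up to ~1 mV at cohort
  dispersion). This is a property of the regression-window procedure
  itself, reproduced deliberately; the noiseless identity tests therefore
  verify the conductance-transform + fit path against the true V_rev, and
  the estimator against its own 1 mV tolerance.
* Availability curves assume the conditioning pulse fully equilibrates h;
  channels with much slower inactivation than the presets would need a
  longer conditioning segment.
* The single-τ inactivation gate cannot represent biexponential decay or
  distinct recovery kinetics; the exponential fitter is deliberately
  single-component.
* Kinship degree bins assume outbred families; inbreeding or population
  substructure (not simulated) would shift expectations.
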