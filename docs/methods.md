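# Methods

This note documents the models and procedures implemented in `silycat`, the
parameter choices that matter, what the synthetic cohort generator does and
does not emulate, and the numerical conventions used throughout.

## Study design assumed by the analysis

All statistics assume a paired batch-fermentation design: each donor
contributes one treatment well (silymarin extract at 50 µg mL⁻¹ final
concentration) and one control well, sampled at 0, 2, 4, 8 and 24 h, with
donors split into two age groups (10 young, 10 elder by default). The dose
validator checks the well arithmetic: 25 µL of a 2 mg mL⁻¹ working solution
into an 835 + 40 + 100 + 25 = 1000 µL well gives 50 µg mL⁻¹.

## Mass arithmetic and reaction matching

Monoisotopic masses are sums of lightest-isotope exact masses
(C 12.000000, H 1.00782503, O 15.99491462 Da); average masses use standard
atomic weights (C 12.011, H 1.008, O 15.999). Protonation adds the proton
mass 1.007276 Da (not the hydrogen atomic weight — the ion is M+H⁺, and the
observed ions agree with this convention to ≤1 mDa, which we attribute to
instrument error).

Catabolite mass shifts are computed against the flavonolignan reference ion
at *m/z* 483.129 for every catabolite, including products of the minor
2,3-dehydro parent at 481.113 — a deliberate, documented simplification: the
reference is ambiguous for isomeric products anyway and a single reference
keeps the delta column interpretable.

The reaction library holds three primitives: demethylation (net −CH₂),
hydrogenation (+H₂), dehydroxylation (−O). Matching enumerates all
multisets up to `max_steps` (default 2; repeats allowed) and keeps
combinations within `tolerance_da` of the observed shift, sorted by
absolute error. The default tolerance is 5 mDa (≈10 ppm at *m/z* 480): wide
enough for the demethylation/hydrogenation series (errors ≤0.6 mDa), narrow
enough that genuinely unexplained shifts stay unexplained.

Two documented anomalies in the reference catabolite set are deliberately
*not* reproduced by default:

* the five ions at *m/z* 467.0975 have Δ = −16.0315, which matches loss of
  CH₄ (−16.0313) far better than loss of O (−15.9949, 37 mDa away), yet are
  conventionally labelled dehydroxylation products. At the default
  tolerance the engine reports them unmatched; a "legacy loose" preset
  (40 mDa) regenerates the conventional label.
* the ion at *m/z* 399.1052 is conventionally assigned C₂₅H₁₈O₅, whose
  [M+H]⁺ would be 399.1227 — inconsistent by 17 mDa. The engine leaves its
  formula blank.

A dihydroxylation primitive (+2 OH) exists in the library but is disabled
by default; occasional references to that reaction in flavonolignan
catabolism are most plausibly slips for dehydroxylation.

## Parent matching

The eight packaged silymarin constituents are matched by m/z (tolerance
5 mDa) and retention time (tolerance 0.15 min). Six constituents are exact
isomers at *m/z* 483.1287 separated only chromatographically, and the
isosilybin A/B pair elutes 0.02 min apart — inside the RT tolerance of
both. Policy: a unique nearest-by-RT candidate wins and a warning is
emitted; an exact tie raises an explicit ambiguity error rather than
choosing silently.

## Treatment filter

Per timepoint, each feature is tested with an exact two-sided Wilcoxon
signed-rank test of treatment vs control across donors (zero differences
dropped; exact null for n ≤ 25, normal approximation above or under ties). A
feature is retained globally if significant at ≥1 timepoint at α = 0.05.
No multiplicity correction is applied at this screening stage — FDR control
is reserved for the metabolite effect tables, where inference is reported.
Sidedness and α are package choices; both are configurable.

## Kinetics

AUC uses the trapezoidal rule on the (0, 2, 4, 8, 24) h grid. Relative AUC
is the percentage of the largest catabolite AUC. Classification runs on the
donor-mean curve: transient if the maximum falls at 4 or 8 h; otherwise
final, early if first detected at 2–4 h, late from ≥8 h. Ties in the
maximum resolve to the *later* timepoint (a plateau held to 24 h is not a
mid-course peak). "Detected" means intensity above `detection_threshold`,
default 0 — appropriate for the generator, whose control signal is exactly
zero; for real data the threshold must be set explicitly (e.g. the blank
wells' 95th percentile).

## Metabolome statistics

Missing concentrations are imputed as ⅓ of the global minimum recorded
value. Tests run on log₁₀(AUC + increment); the increment defaults to half
the smallest positive value when zeros are present (and is recorded in the
run provenance — results on data with true zeros are mildly sensitive to
this choice). The paired t-test covers the treatment effect; the mean
pairwise relative change (T−C)/C × 100 accompanies it and is an unbiased
estimate of a multiplicative effect under lognormal noise. BH q-values are
computed within each cohort family (overall n = 20, young n = 10, elder
n = 10) separately. A zero-variance difference vector (e.g. an exact
multiplicative duplicate) makes the t statistic diverge; the result is
flagged degenerate with an undefined p rather than a fabricated one.

## Ecology

Shannon uses natural log; Simpson is reported as the Gini–Simpson form
1 − Σpᵢ² (inverse Simpson is available behind a flag). Both are computed on
per-sample proportions, so library-size normalization is implicit; no
rarefaction is performed. Bray–Curtis is Σ|xᵢ−yᵢ|/Σ(xᵢ+yᵢ).

PERMANOVA partitions squared distances (Anderson): SS_total =
Σ_{i<j} d²ᵢⱼ/n, SS_within = Σ_groups Σ_{i<j∈g} d²ᵢⱼ/n_g, pseudo-F =
(SS_between/(a−1))/(SS_within/(n−a)), R² = SS_between/SS_total. The p-value
uses free label permutation, (hits+1)/(n_perm+1) with 9999 permutations by
default, seeded and bit-reproducible; an exhaustive mode enumerates all
distinct relabelings for small n. Free (unstratified) permutation is the
default; a donor-paired design would justify stratified permutation, which
is intentionally left out of scope of the default path.

## Integration

Genus counts are clr-transformed (log(x + pseudocount) minus the row mean
of logs; pseudocount 1 for counts). The multi-block model is deliberately
reduced: one latent component per block, whose loading vector is the
covariance of each standardized feature with the centred group indicator,
hard-thresholded to the keepX largest magnitudes (30 taxa / 3 parents /
5 catabolites) and renormalised to unit norm. This keeps the fixed, tuned
sparsity of a multiblock sPLS-DA while dropping design-matrix weighting,
multi-component fitting and cross-validated tuning — the selected feature
sets and their network, not the tuning machinery, carry the scientific
content. Cross-validated error rates of the full framework are therefore
not reproduced.

The relevance network scores a cross-block pair either by the rank-one
similarity approximation (product of each feature's correlation with the
averaged pair of block scores; default) or by direct pairwise Pearson
correlation (`method="direct"`). Edges need |r| > 0.6 and never connect
features within a block. Note the similarity score of a feature duplicated
across blocks is cor(x, t)² ≤ 1; only the direct method returns exactly 1
for duplicates.

## Synthetic cohort generator

The generator produces the statistical structure the analysis assumes, not
mechanistic community dynamics.

* **Parents** decay exponentially (k = 0.30 h⁻¹; 0.80 h⁻¹ for silychristin
  and 2,3-dehydrosilybin, which vanish by 8 h); all are effectively gone by
  24 h. Amplitudes are proportional to the packaged mixture percentages.
* **Catabolites** follow a Bateman formation–decay course (transients,
  k₁ = 0.50, k₂ = 0.15 h⁻¹, peak ≈ 3.4 h), a saturating formation course
  (early finals, k₁ = 0.35 h⁻¹), or the same with a 6 h onset lag (late
  finals, k₁ = 0.25 h⁻¹). Amplitudes are proportional to the packaged
  relative-AUC column. Control wells carry exactly zero signal before
  noise, and the multiplicative noise model keeps them zero.
* **Planted group structure** encodes the age effects the cohort is built
  to exhibit: the
  399.105@10.4 catabolite gets a 2.5-fold elder production multiplier and
  its formation is coupled to *Oscillibacter* abundance; isosilybin B gets
  a 1.3-fold elder AUC multiplier (slower degradation). The group
  multiplier scales the formation *amplitude*, hence exactly the AUC: at
  zero noise the elder/young AUC ratio equals the multiplier to 1e-6.
* **Noise.** Donor-level lognormal variation on amplitudes (sd 0.15) and
  rates (sd 0.10), and well-level multiplicative lognormal intensity noise
  (CV 20%). The amplitude sd was chosen so that a group-mean AUC ratio at
  n = 10/group has ≈9% coefficient of variation — modest but visible
  inter-donor variability consistent with a ±0.4 two-sigma recovery band on
  a 2.5-fold effect.
* **Couplings** act on the *within-group* standardized clr abundance of the
  coupled taxon: amplitude ×= exp(βz) with β = r/√(1−r²) · σ_rest, where
  σ_rest approximates the residual donor-level log-AUC spread. This yields
  the target within-group correlation (default r = 0.8) without
  confounding the explicit group multiplier.
* **NMR metabolome.** 35 metabolites (14 responsive with the packaged
  per-group effect sizes, 21 null) on smooth control time courses
  (consumed sugars decline, fermentation products rise), per-donor
  lognormal baselines (sd 0.3), multiplicative treatment effects with
  donor-level response heterogeneity (sd 4 percentage points on the
  relative-change scale) and multiplicative measurement noise (log-sd
  0.02). The heterogeneity value makes small planted effects borderline
  significant and large ones strong, matching the qualitative p-value
  spread such studies report.
* **Taxa.** 40 genera in 12 orders (consecutive abundance-ranked genera
  share an order, giving a skewed order profile; genus-level Shannon ≈2.7,
  order-level ≈1.6). Samples are Dirichlet-multinomial draws
  (concentration 200, depth 50 000) around group-specific means with a
  two-fold young-high *Faecalibacterium* and elder-high *Oscillibacter*;
  treatment flattens the 24 h mean composition slightly (exponent 0.95),
  a small evenness increase.
* **Decoys** are background features identical across the paired wells of
  each donor; the treatment filter must remove all of them.
* Randomness comes from per-table streams spawned from one seed, so
  adding a block never perturbs the others; a given seed is byte-stable.

A separate deterministic, noise-free **fixture** encodes the packaged
parent/catabolite tables on class-shaped grids scaled so the donor-mean
AUCs reproduce the relative-AUC column exactly and the classifier yields
exactly 6 transient / 9 early / 5 late catabolites. Donors carry small
deterministic scale offsets (1 + 0.002·d) purely to untie the signed-rank
differences; the common factor cancels from all relative quantities.

What passing tests on this generator do **not** show: robustness to
chromatographic misalignment, retention-time drift, matrix effects,
non-lognormal intensity error, compositional artefacts beyond the
Dirichlet-multinomial, or real donor-to-donor kinetic diversity (which is
only qualitatively known and is emulated by a single lognormal scale).

## Problem sizes and determinism

Default analyses run at the study's own scale (20 donors, 5 timepoints,
33 + 10 features, 35 metabolites, 40 genera); property checks use
Monte-Carlo sizes chosen for stable verdicts at desk scale (e.g. 10 000
null replicates for the paired-test level, 40 seeded cohorts for
effect-recovery bias, exhaustive permutation on 6-sample PERMANOVA
instances). All stochastic stages take explicit seeds; PERMANOVA p-values
and whole-pipeline manifests are bit-reproducible under a fixed
configuration.

## Known limitations

* The delta reference 483.129 is a simplification for catabolites of the
  2,3-dehydro parent (see above).
* The filtering α and test sidedness of the screening stage are package
  defaults; other choices are defensible and configurable.
* The simplified one-component integration model does not estimate
  classification error; it is a feature-selection and network device only.
* PERMANOVA's default free permutation ignores donor pairing; use the
  per-group analyses for paired questions.
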