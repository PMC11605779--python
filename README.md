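# silycat

Analysis toolkit for the microbial catabolism of silymarin — the milk-thistle
(*Silybum marianum*) flavonolignan complex — in paired in vitro fecal
fermentations, together with its effects on the fermentation metabolome and
the gut microbiota.

The package is aimed at food-science / gut-microbiome researchers running
batch fermentation studies: it turns an aligned LC-MS feature matrix, an NMR
metabolite concentration table and 16S count tables from a paired
treatment/control, multi-timepoint design into curated catabolite tables,
kinetic classifications, effect statistics, community-ecology summaries and
a cross-omics relevance network. A seeded synthetic-cohort generator
reproduces the statistical structure of such a study at desk scale, so every
stage is testable without access to donor data.

## What it computes

**Catabolite annotation by reaction mass deltas.** Catabolites of the
flavonolignan isomers (neutral C₂₅H₂₂O₁₀, [M+H]⁺ at *m/z* 483.129) are
recognised by the shift Δ*m/z* of their protonated ion against that
reference. The engine enumerates multisets of primitive biotransformations —
demethylation (−CH₂, −14.0157 Da), hydrogenation (+H₂, +2.0157 Da),
dehydroxylation (−O, −15.9949 Da) — up to a step limit and keeps combinations
whose net theoretical shift lies within tolerance (default 5 mDa) of the
observed Δ, e.g. Δ = −12.0005 ≈ −CH₂ + H₂ (demethylation + hydrogenation).
Catabolites are named `m/z@RT` (three and one decimals).

**Treatment filtering and kinetics.** Features responding to treatment are
kept by an exact paired Wilcoxon signed-rank test per timepoint (treatment
vs control across donors, α = 0.05). Per-feature exposure is the trapezoidal
AUC over 0–24 h; catabolites are ranked by AUC as % of the most abundant
one, and classified from the donor-mean curve: *transient* (peak at 4 or
8 h), *final early* (maximal at 24 h, detected from 2–4 h), *final late*
(detected from ≥8 h).

**Metabolome effect statistics.** Below-detection values are imputed as ⅓ of
the lowest recorded concentration; AUCs are log₁₀-transformed (with a
uniform increment when zeros occur) and compared by paired t-tests
(treatment effect) or independent t-tests (age effect), with
Benjamini–Hochberg q-values per cohort family and the mean pairwise relative
change ((T−C)/C × 100).

**Ecology.** Shannon (−Σpᵢ ln pᵢ) and Gini–Simpson (1−Σpᵢ²) alpha
diversity, Bray–Curtis dissimilarity, and a from-first-principles PERMANOVA
(Anderson's pseudo-F, free label permutation, 9999 permutations, seeded).

**Integration.** Genus counts are clr-transformed; one sparse discriminant
component per block (taxa / parent components / catabolites, keepX =
30/3/5) links the blocks to the age groups, and a relevance network keeps
cross-block correlations with |r| > 0.6.

## Worked example

```python
from silycat import RunConfig, run_all

res = run_all(RunConfig(outdir="demo_run", seed=1))
print(res["catabolites"].head(6))
```

writes the full report bundle (TSV tables plus a provenance manifest) for a
simulated 20-donor cohort and prints:

```
        name  delta_mz                    reactions  relative_auc_pct kinetic_class
469.113@11.5  -14.0162                demethylation        100.000000   final_early
469.113@11.9  -14.0161                demethylation         36.383988   final_early
399.105@10.4  -84.0238                                      31.985265   final_early
469.113@11.4  -14.0162                demethylation         28.962027   final_early
471.129@11.1  -12.0005 demethylation; hydrogenation         23.624259   final_early
469.113@12.0  -14.0161                demethylation         22.649416   final_early
```

The most abundant catabolite is the demethylation product at
*m/z* 469.113 / 11.5 min; 399.105@10.4 carries a shift no short reaction
combination explains (blank `reactions`), and its rank is boosted here
because the generator plants a 2.5-fold elder-group production multiplier on
it. Downstream summaries from the same run:

```
PERMANOVA (age, catabolite AUC profiles): R2=0.195, p=0.0004
Shannon (genus, 24 h): treatment 2.709 vs control 2.647 (paired t p=0.054)
isovalerate: p=3.49e-07, q=4.07e-06, relative change -8.61%
```

so age structures the catabolite profiles, treatment nudges diversity
upward, and isovalerate production drops under treatment — each the direct
consequence of a planted generator condition. With the direct
feature-correlation network (`network_method="direct"`) the run recovers
exactly the planted taxon–catabolite association:

```
block_a     feature_a     block_b feature_b        r
   taxa Oscillibacter catabolites       C08 0.858195
```

A command-line interface mirrors the library
(`silycat masses --formula C24H20O10`, `silycat simulate`, `silycat
annotate`, `silycat kinetics`, `silycat stats`, `silycat ecology`,
`silycat run`).

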