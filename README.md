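# cardiomet

Cardiometabolic phenotyping of matched severe-obesity cohorts.

Clinical studies of rare obesity syndromes — the motivating case is adults
with Prader-Willi syndrome (PWS) compared against age-, sex- and BMI-matched
adults with essential obesity (EOB) — run the same analysis chain over and
over: basal metabolic rate (BMR) from indirect calorimetry, body composition
from bioelectrical impedance (BIA), derived risk indices, metabolic-syndrome
(MetS) classification, and covariate-adjusted group comparisons. `cardiomet`
packages that chain as a tested, reusable pipeline for biostatisticians and
clinical researchers, together with a seeded synthetic-cohort generator
matched to published group summaries, so the whole workflow runs and is
verifiable without access to subject-level data.

## What it computes

* **Weir equation** (abbreviated): `EE = (3.941·V̇O₂ + 1.106·V̇CO₂)·1440`
  kcal/day, V̇O₂/V̇CO₂ in L/min.
* **BIA body composition**: sex-specific linear prediction
  `FFM = a + b·ht²/R + c·W + d·age` (configurable coefficients), FM = W − FFM,
  BMI, and BMR normalised per kg FFM and per kg body weight.
* **Indices**: HOMA-IR = insulin·glucose[mmol/L]/22.5; the sex-specific
  visceral adiposity index (VAI); the continuous MetS z-score
  Σ(component − anchor)/SD with sex-specific anchors (HDL term reversed).
* **MetS classification**: ≥ 3 of 5 altered components (WC, TG, HDL, BP,
  fasting glucose, with treatment/diagnosis clauses) plus prevalence tables.
* **Group statistics**: mean (95% CI) summaries, percent differences,
  Shapiro–Wilk routing to parametric or rank-transform ANCOVA
  (`y ~ group + age + sex`), and four-subgroup comparisons with Tukey or
  Bonferroni post-hoc letters.

See `docs/methods.md` for the model details, assumptions and numerical
choices.

## Worked example

```python
import cardiomet as cm

bundle = cm.run_pipeline(cm.RunConfig(seed=20250401, outdir="out"))
table = bundle.comparison.table.set_index("variable")
for v in ["weight", "bmr", "bmr_per_kg_ffm", "glucose", "hdl_c"]:
    r = table.loc[v]
    print(f"{v:16s} EOB {r['EOB_mean']:8.2f}  PWS {r['PWS_mean']:8.2f}  "
          f"diff {r['percent_diff']:+6.1f}%  p {r['p_adjusted']:.3g}  {r['method']}")
```

prints (seed 20250401):

```
weight           EOB   121.70  PWS    96.65  diff  -20.6%  p 1.76e-08  parametric
bmr              EOB  2037.08  PWS  1498.96  diff  -26.4%  p 2.25e-09  parametric
bmr_per_kg_ffm   EOB    34.82  PWS    34.13  diff   -2.0%  p 0.361  parametric
glucose          EOB    88.80  PWS    95.15  diff   +7.2%  p 0.0128  parametric
hdl_c            EOB    39.36  PWS    48.19  diff  +22.4%  p 0.000412  parametric
```

Read: the synthetic PWS cohort is ~21% lighter with ~26% lower absolute BMR
than its matched EOB cohort (both strongly significant after adjusting for
age and sex), but BMR *per kg of fat-free mass* is indistinguishable —
the lower energy expenditure is explained by the smaller lean mass, not by
a syndrome-specific metabolic defect. Glucose runs higher and HDL markedly
higher in the PWS-like cohort, mirroring the pattern the generator was
parameterised to. `bundle.prevalence` holds the component-prevalence table
and `bundle.subgroup_comparison` the four-subgroup (MetS±) letters.

The same pipeline is scriptable from a shell:

```bash
cardiomet generate --seed 7 --outdir out     # two cohort CSVs
cardiomet report   --seed 7 --outdir out     # full bundle + report.txt
cardiomet verify                             # arithmetic check of the bundled
                                             # published summaries
```

`cardiomet verify` recomputes every published headline percent difference
from the bundled group means and flags the handful that are not
arithmetically consistent with the printed tables (adjusted means were
likely used there); details in `docs/methods.md`.

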