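# depmarker

Mutation markers of CRISPR knockout sensitivity in cancer cell-line
dependency screens — plus co-dependency profiling and cutoff-optimized
survival analysis.

## The problem

Genome-scale CRISPR knockout screens (DepMap-style) assign every
(cell line, gene) pair a *gene-effect* dependency score: more negative
means the line depends more strongly on the gene, with score < −0.5
marking a *sensitive* line (most cells depleted) and −1 the median of
common-essential genes. For a drug target — say a chromatin-repressor
subunit such as EZH2, SUZ12 or EED — the clinically useful question is:
**which mutations predict that a tumor cell line will be sensitive to
knockout of the target?** Such mutations are candidate patient-selection
biomarkers for inhibitors of that target.

`depmarker` implements that screen end to end, for anyone analyzing
public dependency releases or their own score matrices:

1. **Sensitivity calling** — a line is sensitive to a target knockout
   iff its gene-effect score is strictly below a threshold τ (default
   −0.5).
2. **Marker screen** — silent (synonymous) mutations are removed via
   the `Variant_Classification` attribute; every remaining mutated gene
   *G* is tested for dependence between "mutated in *G*" and
   "sensitive to the target" with a one-sided Fisher exact test on the
   2×2 table (a = mutated ∧ sensitive, b = mutated ∧ not, c = wild-type
   ∧ sensitive, d = wild-type ∧ not):

   P = P(A ≥ a | margins) under the hypergeometric null.

   Results are ranked by p; markers with fewer than m_min = 10 mutated
   lines are flagged (never dropped); Benjamini–Hochberg q-values are
   always emitted; screens against several targets can be intersected
   to find markers shared by a whole complex.
3. **Co-dependency** — Pearson correlation of two genes' score profiles
   across lines (pairwise-complete); genes in one complex rank at the
   top of each other's correlation lists.
4. **Survival engine** — Kaplan–Meier curves, the two-group log-rank
   test, univariate Cox proportional-hazards regression (Efron ties,
   Newton iterations, Wald/LRT/score p-values, HR = exp(β) with 95% CI),
   and the *quartile-restricted cutoff scan*: every distinct expression
   value between Q1 and Q3 dichotomizes the cohort, each split is scored
   by Cox LRT, and the best-performing cutoff defines the final groups.
   The scanned minimum p is selection-optimistic; every scan result
   carries a `cutoff_optimized` caveat flag.
5. **Synthetic data** — generators that plant known structure (selective
   genes as a two-component score mixture, shared latent sensitivity
   states, marker odds ratios, proportional-hazards effects) and emit
   truth tables, so every stage is testable without downloads.

## Worked example

```python
import numpy as np
import depmarker as dm

# a 777-line screen: EZH2 knockout kills ~30% of lines; SMARCB1
# mutations are planted to be enriched among the sensitive ones
# (q1 = 0.5 in sensitive lines vs q0 = 0.05 elsewhere), among 200
# background genes mutating at 5% independently of sensitivity
matrix, truth = dm.simulate_gene_effect(dm.EffectSimSpec(
    n_lines=777, selective_genes={"EZH2": 0.3}, seed=11))
mutations = dm.simulate_mutations(dm.MarkerSimSpec(
    "SMARCB1", "EZH2", q1=0.5, q0=0.05, n_background_genes=200, seed=12), truth)

report = dm.run_screen(matrix, mutations, None, "EZH2")
print(f"{report.n_sensitive}/{report.n_evaluable} sensitive")
print(report.results.head(3).to_string(index=False))
```

```
248/777 sensitive
marker_gene   a  b   c   d  n_mutated      p_value      q_value  significant_at_alpha
    SMARCB1 125 36 123 493        161 4.061789e-42 8.164197e-40                  True
    MBG0067  19 16 229 513         35 4.204473e-03 4.225495e-01                  True
    MBG0119  19 19 229 510         38 1.332421e-02 8.805924e-01                  True
```

The planted marker ranks first by a huge margin: of its 161 mutated
lines, 125 are sensitive (a), against 123 sensitive among the 616
wild-type lines — one-sided Fisher p ≈ 4×10⁻⁴². The two runner-up
background genes clear raw p < 0.05 (as some always will among 200 null
tests) but their BH q-values stay far from significance.

```python
cohort, _ = dm.simulate_survival(dm.SurvivalSimSpec(
    n_subjects=400, log_hazard=np.log(2), censoring_rate=0.05, seed=3))
print(dm.survival_report(cohort, mode="scan").summary())
```

```
{'mode': 'scan', 'cutoff': 0.4846648782067015, 'n_low': 263, 'n_high': 137,
 'hazard_ratio': 3.0050971140810034, 'ci_95': [2.328557253477278, 3.878199108728119],
 'logrank_p': 9.013087322656622e-19, 'cox_lrt_p': 2.42274230986245e-16,
 'cutoff_optimized': True}
```

With a planted log-hazard of ln 2 per expression unit, the scan places
the cutoff at ≈0.48 and reports HR ≈ 3.0 for high vs low expressors —
note `cutoff_optimized: True`, reminding you the split was chosen to
minimize p.

## Command line

```bash
depmarker simulate --config sim.yaml --seed 5 --out data/
depmarker screen --gene-effect data/gene_effect.csv --mutations data/mutations.csv \
    --target EZH2 --out screen_ezh2/
depmarker intersect screen_*/screen_*.tsv --out shared_markers.tsv
depmarker codep --gene-effect data/gene_effect.csv --query EZH2 --top 5 --out codep.tsv
depmarker survival --cohort data/cohort.tsv --mode scan --out surv/
depmarker freq --records alterations.csv --group-sizes sizes.csv --out freq.tsv
```

Tables are TSV, logs go to stderr, and every output directory receives a
JSON run manifest (tool version, config, input SHA-256 digests, seed).

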