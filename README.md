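# abframe

Germline-guided antibody light-chain framework optimization, with the full
downstream assay analysis of the resulting variant panel.

Therapeutic antibody candidates often carry framework residues that drifted
from their germline origin during selection. Because germline V genes are
under evolutionary pressure for stable, well-expressed protein, reverting
rare framework residues to the closest germline gene is a simple, rational
route to better biophysical behaviour — without touching the CDRs that bind
antigen. This package implements that workflow end to end for an antibody VL
domain and the measurements used to judge the outcome:

* **Kabat numbering** of V domains (consensus-template alignment; canonical
  insertion sites; framework/CDR delineation), and **germline scanning**:
  framework identity over Kabat FR1–FR3 (70 positions for an insertion-free
  kappa chain), mismatch grouping into mutation regions, and enumeration of
  all 2^k parental/germline framework combinations with signature names
  (DIQMAQ … EIVLGE);
* **SPR kinetics**: global 1:1 Langmuir fits of sensorgram panels,
  KD = kd/ka;
* **Thermal stability**: DSF melt-curve midpoints by smoothed first
  derivative or sigmoid fit, ΔTm between variants;
* **Aggregation**: SE-HPLC species fractions by retention-window
  integration, 12-week stability time-courses;
* **Pharmacokinetics**: mono- vs bi-exponential plasma decay
  (C(t) = C0α e^(−αt) + C0β e^(−βt), α > β), extra sum-of-squares F-test
  model selection, LOQ censoring, and NCA — AUC(0–144 h) by trapezoid,
  CL = D/AUC, MRT, V_D,ss = CL × MRT, t½,β = ln2/β;
* **Statistics**: Spearman rank correlation of Tm vs expression titer with
  exact permutation p-values for small panels, one-way ANOVA with Tukey HSD,
  and fold-difference checks;
* **Synthetic data generators** that plant the study's effect sizes (two-fold
  KD envelope, +0.5/+2/+4 °C Tm classes, 3–10× titer gains for
  A66G-containing variants, 97% vs 89% monomer, two-compartment PK truths)
  and emit their truth tables for recovery testing.

For whom: antibody engineers who want a tested, scriptable reference
implementation of the germlining workflow, and anyone needing clean,
seed-reproducible implementations of the surrounding assay analyses.

## Worked example

The numbered drivers under `analysis/` run the whole campaign on synthetic
inputs (seed 1 shown; every number below is actual script output).

```bash
python analysis/01_design_variants.py --seed 1
```

```
closest germline: KV3-20L (92.86% framework identity, 94.74% total V region)
framework mismatches: L1:D->E, L3:Q->V, L4:M->L, L66:A->G, L79:Q->E
mutation regions: 1-4, 66, 79
panel: 9 variants -> 1-DIQMAQ, 2-DIQMAQ-K, 3-EIVLAQ, 4-DIQMGQ, 5-DIQMAE,
6-EIVLGQ, 7-EIVLAE, 8-DIQMGE, 9-EIVLGE
```

The parental VL differs from its closest germline at five framework
positions (65/70 = 92.86% identity), which group into three mutation
regions; the panel is all 2³ parental/germline combinations plus a
lysine-bearing duplicate of the parental. Each variant's name spells out the
residues at the six signature positions.

```bash
python analysis/04_pharmacokinetics.py --seed 1
```

```
  antibody  dose_mg_per_kg model  n_uncensored  c0_mg_per_l  t_half_beta_h  auc_mg_h_per_l  cl_ml_per_h_per_kg
2-DIQMAQ-K             5.0  mono             7         3.33          10.49           58.07               86.11
2-DIQMAQ-K            15.0    bi             9         9.11          51.95          208.80               71.84
...
  9-EIVLGE            30.0    bi            11       212.57          84.04         5815.32                5.16

exposure ratio (optimized / parental) at 30 mg/kg: 15.1x
dose-averaged terminal half-life, optimized variant: 4.2 days
```

The parental low-dose arm loses its tail to the detection limit (7 of 11
points remain) and falls back to a one-compartment fit; every other arm
justifies the two-compartment model by F-test. The fully germlined variant
clears an order of magnitude more slowly (≈3–5 vs ≈70–90 mL/h/kg) and its
terminal half-life is IgG-typical (days, not hours).

`02_binding_kinetics.py` (affinities within two-fold of parental, max fold
1.86), `03_stability.py` (ΔTm up to +4.6 °C; monomer 97% vs 89% at week 0),
and `05_statistics.py` (Spearman ρ = 0.87, one-sided exact p = 0.0023;
ANOVA F = 57.3 with only A66G-containing variants significant vs parental)
complete the picture. Equivalent functionality is exposed as a CLI
(`abframe number|germline-scan|design-variants|fit-spr|fit-dsf|
sec-timecourse|pk-fit|pk-nca|stats|simulate|run`).

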