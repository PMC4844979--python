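# micromet

Kinetic modelling of how melanoma micrometastases evade the immune system
and anticancer vaccination, and of what that predicts for patient gene
expression.

`micromet` is aimed at systems-biology and tumor-immunology groups who want
to connect a small mechanistic tumor–immune model to clinical
transcriptomics: it simulates cytotoxic-T-cell / melanoma kinetics under
therapeutic vaccination, screens thousands of virtual patients to extract
phenotypic signatures of immune sensitivity and resistance, analyses the
tumor-persistence condition mathematically, and compares the in-silico
signatures with (synthetic) patient expression cohorts aggregated into
immune metagenes.

## The model

Two populations in normalized units: cytotoxic T cells `T` and melanoma
cells `M` in a pre-angiogenic micrometastasis (carrying capacity `M_T`,
initial cluster `M(0) = 0.00081` ≙ 30 cells):

    dT/dt = (k_apc + k_gir·V_c(t)) · (k_atg·M)^g1 / (k_tapc^g1 + (k_atg·M)^g1)
          + k_atc·T · (k_atg·M)^g2 / (k_tatc^g2 + (k_atg·M)^g2)
          − k_dtc·( T³ + ρ_mem·T(t − t_dtc) )

    dM/dt = k_pmc·M·(1 − M/M_T)
          − k_iap·k_atg/(1 + k_iev) · T·M
          − k_ink·M · k_nkc^g_nk / (k_nkc^g_nk + k_atg^g_nk)

T cells are activated by antigen-presenting cells (inherent rate `k_apc`,
plus the pulsed vaccine input `V_c(t)` amplified by the patient's systemic
response `k_gir`), expand on contact with antigen-presenting tumor cells,
and undergo biphasic depletion (fast cubic decay plus a small delayed
memory-cell term). The tumor grows logistically, is killed by T cells in
proportion to antigen presentation `k_atg` (attenuated by immune evasion
`k_iev`) and by natural killer cells that preferentially attack cells with
*low* surface antigen presentation (decreasing Hill term; `k_ink =
0.02·k_iap`). The opposite `k_atg` dependence of the two killing arms is
the core of the analysis: a tumor with *intermediate* antigen presentation
minimizes the combined attack.

Near the tumor-free state the per-capita elimination pressure at a steady
T-cell level `T_s` is

    F_imef = k_iap·k_atg/(1+k_iev)·T_s + k_ink·k_nkc^g_nk/(k_nkc^g_nk + k_atg^g_nk)

and the micrometastasis persists exactly when `k_pmc > F_imef`.

Vaccination is a step input: six 180-day cycles, each opening with a 5-day
unit pulse. Co-adjuvants act during the first 30 days: IL-2 multiplies
`k_iap` and `k_atc` by 10, IFN-α multiplies `k_atg` by 15.

## Worked example

```python
from micromet import (ModelParameters, run_scenario, run_screen,
                      log_normalize, hcluster, extract_subpopulations)
from micromet.signatures import signature_table

# nominal patient: the inherent immune response controls the tumor
p = ModelParameters()
print(round(run_scenario(p, 2).M[-1], 3))   # 0.019  (M(1500) < 0.05)

# virtual cohort: sample 2000 parameter sets, classify phenotypes
screen = run_screen(n=2000, seed=2016)
print(screen.group_counts())
# {'non_tumor': 183, 'immune_sensitive': 676, 'vaccine_sensitive': 34,
#  'vaccine_resistant': 1107, 'unclassified': 0}

# signatures of the vaccine-resistant subpopulations
norm = log_normalize(screen.parameters("vaccine_resistant"))
clusters = extract_subpopulations(norm, hcluster(norm))
print(signature_table(clusters).round(2))
```

`run_scenario(p, 2).M[-1]` is the melanoma burden (n.u.) 1500 days after
tumor initiation under the inherent response alone; 0.019 < 0.05 means the
nominal tumor is immune-controlled. The screen's group counts say how many
sampled virtual patients grow a tumor that is controlled by inherent
immunity, rescued by vaccination, or resistant to both. Each row of the
signature table is one resistant subpopulation's mean parameter pattern on
the normalized [−1, 1] scale — negative `k_iap` (weak T-cell cytotoxicity)
with low-to-intermediate `k_atg` is the characteristic resistance
signature.

The same stages are available from the shell:

```bash
micromet screen --n 2000 --seed 2016 --out screen.tsv
micromet signatures --screen screen.tsv --out-prefix resistant
micromet synth --seed 1 --out-dir cohort/
micromet compare --screen screen.tsv --expression cohort/expression.tsv \
    --annotation cohort/annotation.tsv --labels cohort/labels.tsv --out compare.json
micromet therapy --screen screen.tsv --out therapy.json
```

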