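# Methods

## Model

The package simulates the interaction between a melanoma micrometastasis
(`M`, normalized units) and cytotoxic T cells (`T`, n.u.) with a pair of
nonlinear ODEs carrying one discrete delay (full equations in the README
and `micromet.model`). Modelling assumptions:

* **Pre-angiogenic growth.** The micrometastasis has not breached the
  vessel wall, so tumor growth is logistic with carrying capacity
  `M_T = 1`; `M(0) = 0.00081` represents a 30-cell initiating cluster, so
  one cell is `2.7e-5` n.u.
* **Antigen-gated T-cell activation and expansion.** Both APC-mediated
  activation and T-cell self-expansion are sigmoidal (`g1 = g2 = 2`) in the
  amount of presented antigen `k_atg·M`; the vaccine enters only through
  the activation term, as `k_apc + k_gir·V_c(t)`.
* **Biphasic T-cell depletion.** A fast cubic decay plus a small delayed
  linear term (`ρ_mem = 0.01`, `t_dtc = 30` d) that stands in
  phenomenologically for the long-lived memory fraction.
* **Two complementary killing arms.** T-cell killing is proportional to
  `k_atg` and divided by `1 + k_iev` (immune evasion blunts recognition);
  NK-cell killing follows a decreasing Hill function of `k_atg`
  (`k_nkc = 1`, `g_nk = 6`) with amplitude `k_ink = 0.02·k_iap`. Their
  opposite dependence on antigen presentation creates the intermediate-
  `k_atg` resistance niche that the persistence analysis (below)
  formalizes.

The algebraic forms are a term-by-term reconstruction from the qualitative
description of each rate process; every stated dependency is reproduced,
and the reconstruction is validated dynamically — the persistence
inequality derived from it agrees with direct simulation in 100% of
sampled parameter sets (see *Persistence analysis*).

## Parameters

All rates in 1/day, populations in n.u. The defaults live in one versioned
file, `src/micromet/data/nominal_params.yaml`.

| parameter | default | meaning / rationale |
|---|---|---|
| `k_pmc` | 1 | tumor proliferation; equals the screen's lower bound (slower tumors never establish) |
| `M_T` | 1 | carrying capacity (normalization) |
| `k_atg` | 1 | antigen presentation, normalized to 1 nominally |
| `k_iap` | 1 | T-cell cytotoxic efficiency |
| `k_ink` | 0.02·`k_iap` | NK killing amplitude, tied to `k_iap` |
| `k_iev` | 1 | immune evasion |
| `k_apc` | 0.04 | inherent APC activation |
| `k_gir` | 1 | vaccine amplification (systemic response) |
| `k_atc` | 0.02 | T-cell self-expansion |
| `k_tapc`, `k_tatc` | 0.02 | activation/expansion Hill half-constants |
| `g_1`, `g_2` | 2 | sigmoidal activation/expansion |
| `k_nkc`, `g_nk` | 1, 6 | NK Hill half-constant and steepness |
| `k_dtc` | 0.005 | T-cell depletion |
| `ρ_mem`, `t_dtc` | 0.01, 30 d | delayed (memory) depletion |

The auxiliary constants (`k_atc`, `k_tapc`, `k_tatc`, `k_dtc`) are not
identifiable from literature values at this level of abstraction; they were
calibrated once against the qualitative structure the model must
reproduce: (i) the nominal parameter set is immune-sensitive (the inherent
response holds `M(1500) = 0.019 < 0.05`); (ii) a non-immunogenic nominal
tumor reaches `M(30) > 0.9`; (iii) all four phenotype groups are populated
in a sampled cohort; and (iv) the combined IL-2 + IFN-α co-adjuvant
depletes the majority of vaccine-resistant virtual patients while either
cytokine alone does not. The calibration lives in the regime where
vaccine-driven T-cell pulses (ceiling `(k_gir/k_dtc)^(1/3)`) substantially
exceed the inherent T-cell equilibrium — otherwise vaccination can never
rescue a patient whom the inherent response fails, and the
vaccine-sensitive phenotype is structurally empty.

## Numerics

* **Method of steps, classical RK4, fixed step 0.05 d.** The delayed
  `T(t − t_dtc)` is read from the stored trajectory by linear
  interpolation, with constant pre-history `T(t < 0) = T0`. Fixed-step
  integration keeps results bit-reproducible across runs and platforms;
  pulse edges and the therapy-window boundary fall exactly on grid points.
* **`M` is propagated in log space** (`u = ln M`). Sampled extremes reach
  per-capita kill rates of ~10³–10⁴/day, which an explicit scheme cannot
  follow in linear state at this step; the `ln M` equation's only
  self-coupling is the logistic term (`|h·∂u̇/∂u| ≤ k_pmc·h ≈ 0.25`), so
  the scheme stays stable across the entire sampled cube. `T` remains
  linear (its stiffest term keeps `h·λ ≲ 1.6`). Negative round-off in `T`
  is clipped to 0.
* **Extinction threshold.** A deterministic ODE lets `M` regrow from
  arbitrarily small values, so after the last vaccine pulse (day 1085)
  every suppressed tumor would recover long before the day-1500 read-out
  and therapy could never cure. Populations are discrete: once `M` falls
  below one cell (2.7e-5 n.u.) it is treated as eradicated (absorbing
  zero). The threshold is an argument of `integrate` (0 disables it).
* **Divergence guard** at 10³ n.u.; an offending trajectory raises an
  error naming the time, and screen rows that fail are flagged and
  excluded from signature mining rather than dropped.
* Accuracy checks: with immunity off the integrator matches the logistic
  closed form to <1e-8 at step 0.05; with the delay disabled it matches an
  adaptive reference integration to <1e-8; halving the step changes
  `M(1500)` by <1e-14 at the nominal point.

## Virtual-patient screen

Five parameters are sampled by Latin hypercube in log10 space — `k_pmc` in
[1, 5], `k_atg`, `k_iap`, `k_iev`, `k_gir` in [0.02, 50] — one design
reused across the three scenarios (non-immunogenic growth, inherent
response, vaccination). Classification uses strict thresholds: tumor if
`M₁(30) > 0.9`; immune-sensitive if `M₂(1500) < 0.05`; vaccine-sensitive
if `M₃(1500) < 0.05`; else vaccine-resistant. Ties at a threshold go to the
less-sensitive label (the source convention is unstated). `k_ink` tracks
the sampled `k_iap`. The full-scale design is 10⁴ rows; the test suite and
the reproduction script use n = 2000, which reproduces the same group
structure at ~3% of the cost.

Under this reconstruction the vaccine-sensitive group is real but small
(~1.5–2% of rows): vaccination rescues only tumors in a narrow band where
the inherent response almost suffices and the pulse-driven T-cell spike
pushes the tumor below one cell. The non-tumor group (~9%) consists of
low-`k_atg`, high-`k_iap` rows where NK cells alone control the HLA-low
tumor — the NK arm of the model acting exactly as designed.

## Signature clustering

Group parameter blocks are log10-transformed and normalized per column to
[−1, 1] (constant columns map to 0), then clustered with Euclidean
distance and average (UPGMA) linkage, columns first, then rows. Leaf
orders are *exactly* optimal: an in-package dynamic program over subtree
endpoint pairs (min-plus products with traceback) finds the
minimum-total-adjacent-distance order among all 2^(n−1) orders consistent
with the dendrogram; it is validated against exhaustive search on small
instances. Subpopulations are maximal dendrogram subtrees in which every
parameter has ≥75% sign agreement (values exactly 0 count toward neither
sign) and which hold at least `min_fraction` of the group (default 0.05;
under uniform LHS sampling the largest sign-pure subtrees hold 5–9% of a
group, so a 0.10 floor finds nothing). Both knobs are exposed because the
original subpopulations were read off a heat map by inspection.

Reported resistant subpopulations share weak T-cell cytotoxicity (negative
normalized `k_iap`) with low-to-intermediate antigen presentation; on the
global sampled scale the resistant group's median `k_atg` sits in the
middle tercile, but its within-group normalized mean is negative rather
than centered — the NK amplitude `0.02·k_iap` is too weak in low-`k_iap`
rows to forbid low `k_atg` outright.

## Persistence analysis

Linearizing the melanoma equation at `M → 0` with `T` held at `T_s` gives
the immune-efficiency function `F_imef` (README); the tumor persists iff
`k_pmc > F_imef`. `persists()` is validated against
`frozen_T_growth_rate()`, a short RK4 simulation of the full right-hand
side with `T` clamped, at `M = 1e-4`: the sign agrees in 100% of 200
log-uniformly sampled parameter sets. The `F_imef` surface has an interior
minimum in `k_atg` for small `T_s`, and its low-efficiency `k_atg` region
widens as `T_s` decreases.

The total-killing-rate curve (T + NK arms per unit `M` at `T = M = 1`) is
documented at the calibration setting `k_iap = 1`, `k_ink = 0.02`,
`k_nkc = 1`, `g_nk = 6`, `k_iev = 100`: strong evasion makes the two arms
comparable, and the curve over `k_atg` ∈ [0.01, 100] attains its minimum
at `k_atg ≈ 1.4` — strictly interior. At mild evasion (`k_iev ≲ 80`) the
linear T-cell term dominates everywhere and the minimum sits at the left
boundary; the interior "tight balance" requires the strong-evasion regime.

## Metagenes and the synthetic cohort

Genes are annotated into five categories; categories 1–4 map onto
`k_atg`, `k_iap`, `k_iev`, `k_gir`, and a metagene is the arithmetic mean
of its member genes per sample (arithmetic vs geometric makes little
difference on this scale). Patients are clustered with complete linkage /
Euclidean distance; the two subtrees of the root are the margin clusters.
Benefit/non-benefit naming comes from sample metadata when available,
otherwise the cluster with the higher general-immune metagene is called
benefit. Per-sample metagenes are log10-normalized to [−1, 1] per category
across all samples before cluster means are taken, so patient profiles and
in-silico signature means live on the same scale; comparison is the
Euclidean distance on the four mapped dimensions (`k_pmc` has no metagene
counterpart).

The clinical input this emulates is a pretreatment 84-gene signature over
melanoma patients with and without benefit from immunotherapy; that
dataset is not redistributable, so `micromet.synthetic` generates
expression matrices with the same structure: 84 genes split 20/20/20/14/10
across the categories (the true split is unpublished; this one is a fixed
synthetic stand-in), group-level category means encoding the qualitative
clinical contrast (benefit: high antigen presentation 6.0 and general
immune response 6.0; non-benefit: intermediate antigen presentation 2.5,
low apoptosis 1.2, elevated evasion 3.0; unknown category 2.0 in both),
and i.i.d. Gaussian noise (default sd 1.0) on the relative-expression
scale. Defaults of 14 benefit / 22 non-benefit samples mirror the typical
responder minority in vaccine trials.

What the generator does *not* emulate: probe-level microarray noise and
normalization artifacts, gene–gene correlation within categories,
mis-annotation, and batch effects. Passing the recovery and comparison
tests therefore shows the pipeline is correct and well-conditioned under
category-structured signal, not that real cohorts will separate as
cleanly.

## Co-adjuvant therapy

Regimens start from the standard initiating tumor (`T0 = 0`,
`M0 = 0.00081`, `k_apc = 0.04`) with the first vaccine cycle of the
standard schedule; IL-2 (×10 on `k_iap`, `k_atc`) and IFN-α (×15 on
`k_atg`) act during the first 30 days and the simulation runs to day 100,
where depletion is scored against the 0.05-n.u. threshold. On the
vaccine-resistant rows of a seeded n = 2000 screen the vaccine alone
depletes none, each single cytokine ~33–41%, and the combination ~78% —
only the combination clears the majority, because IFN-α moves the tumor
out of the low-`k_atg` blind spot of T-cell killing while IL-2 amplifies
the effectors attacking it.

## Known limitations

* The equations are a reconstruction; Hill-argument placement (e.g.
  whether `k_atg` multiplies inside the activation Hill) could differ from
  the original without changing any of the qualitative dependencies that
  were used to build and validate it.
* No additional immune cell types, cytokine pharmacokinetics (the 30-day
  co-adjuvant window is a mean-value simplification), stiff-solver
  support, or bifurcation analysis of the coupled system.
* The vaccine-sensitive phenotype occupies a narrow parameter band here;
  its prevalence is sensitive to the unpublished auxiliary constants.
* The extinction threshold makes long-horizon outcomes discontinuous in
  parameters by construction (a trajectory either crosses one cell or does
  not); classification is nevertheless stable under step refinement.
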