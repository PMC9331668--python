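# Methods

This note documents the models, parameter choices, and numerical
conventions behind `pmrisk`, and what the shipped defaults do and do not
represent.

## Pipeline overview

1. **Sample tables** (`pmrisk.io`): long-format delimited text, one row
   per filter sample × metal; PM₂.₅ mass in µg·m⁻³, metal concentrations
   in ng·m⁻³.  Validation raises on negative concentrations and duplicate
   sample × metal rows; an extract concentration exceeding its total is
   flagged (`qc_extract_gt_total`) and logged, never clamped — it is
   evidence of analytical error and must stay visible.
2. **Bioaccessibility** (`pmrisk.bioaccessibility`): fraction (%) =
   100 × extract / total.  Group-level fractions divide the group *mean*
   extract by the group mean total, not the mean of per-sample ratios;
   this is the convention that reproduces the case study's summary table
   from its printed means, and it weights samples by concentration rather
   than equally.  Levels: [0, 15) low, [15, 30) intermediate, [30, 50]
   high, (50, ∞) very high.  The published scheme's intervals touch at
   15/30/50 %; boundary values are assigned upward at 15 and 30 and to
   `high` at exactly 50, a convention this package fixes because the
   source scheme never classifies an exact-boundary value.
3. **Deposition** (`pmrisk.deposition`): see below.
4. **Exposure and risk** (`pmrisk.exposure`, `pmrisk.risk`): the USEPA
   dose equations and HQ/HI/ILCR characterisation given in the README.
   ADD is algebraically independent of ED (the ED in the numerator
   cancels against AT_n = ED × 365) and LADD = ADD × ED/70 exactly; both
   identities are asserted in the tests.  The single ng→mg conversion in
   the package (× 10⁻⁶) is applied when concentration summaries are
   assembled in `pmrisk.exposure.concentration_summary`.
5. **Monte Carlo** (`pmrisk.montecarlo`): see below.

## Deposition fractions

The external multiple-path dosimetry software used for the original
deposition runs is proprietary and its internals are not reproducible
from public information, so `pmrisk` provides two DF sources:

**Closed-form engine.**  The fitted closed-form expressions of the
ICRP-66 regional deposition model (head/extrathoracic, tracheobronchial,
alveolar; nose breathing, reference adult) evaluated at the aerodynamic
diameter (d·√ρ; particles are treated as spheres of density 1.0 g·cm⁻³
by default).  A separately fitted total-deposition curve from the same
model family serves as an independent cross-check; the two agree to
within ~6 percentage points over 0.01–10 µm, and the characteristic
U-shaped total-deposition curve (minimum near 0.3 µm) is verified
numerically.  Cohort physiology enters through a penetration-probability
scaling rule, DF′ = 1 − (1 − DF)^s, with s = (VT/FRC)/(VT/FRC)_ref for
the alveolar region and s = minute-ventilation ratio for the
tracheobronchial region.  The exponent form keeps every component in
[0, 1] for any s > 0 and is monotone — smaller FRC (children) gives a
larger pulmonary fraction; if the scaled components ever exceed the
simplex they are renormalised with a warning.  This scaling rule is a
design choice of this package, chosen for its simplicity and guaranteed
validity, not a published lung model.

**Override table.**  A per-cohort CSV (age_group, sex, df_head, df_tb,
df_pulmonary) validated row-by-row against the simplex invariants.  The
shipped default table is *calibrated to the case study*: pulmonary
fractions 0.15–0.26 for children and 0.12–0.14 for adults, decreasing
with age within each life stage, male above female, total deposition
0.64–0.79 (children) and 0.72–0.80 (adults); the 2–5 male (0.255) and
23–30 male (0.139) pulmonary values are pinned by the published risk
ratios between the with- and without-deposition variants.  All
paper-facing numbers flow through this table; the closed-form engine is
the self-contained alternative for other particle sizes or populations.

Only the pulmonary fraction enters the dose equations: alveolar deposits
persist for a day or more, long enough for dissolution to matter, while
head/TB deposits clear within hours via the mucociliary escalator.

**FRC formulas** (`frc_estimate`): children (age < 23) use a power law in
height only, FRC = a·H^b with shipped defaults a = 1.29 × 10⁻⁵,
b = 3.73 (≈ 450 mL at 105 cm, ≈ 2.6 L at 168 cm); adults use sex-specific
linear forms in height and age (male: 0.0472·H + 0.0090·age − 5.92 L;
female: 0.0360·H + 0.0031·age − 3.182 L), the standard European
reference equations.  Coefficients must be passed explicitly (they ship
in the default config); there are no hidden fallbacks.

## Registry defaults and calibration

The case study cites exposure-handbook values for per-cohort body weight
and inhalation rate without printing them.  The shipped registry
therefore sets BW to handbook-convention age-group means (16.8–80 kg)
and back-computes InhR from the published dose table given BW and the
shipped DF (InhR = ADD·365·BW / (C_ALF·DF·350)), yielding 8.4–14.6
m³·day⁻¹ for children and 11.0–18.4 m³·day⁻¹ for adults — within the
plausible long-term range.  These are calibrated defaults, clearly
overridable: any `exposure:` block in the YAML config replaces them, and
with replaced values the dose table changes accordingly while every
structural invariant (LADD/ADD ratio, variant orderings, linearity)
still holds.

Toxicity registry: RfD 1.0 × 10⁻³ (Cd) and 3.5 × 10⁻³ (Pb)
mg·kg⁻¹·day⁻¹; CSF 6.3 (mg·kg⁻¹·day⁻¹)⁻¹ for Cd.  Pb carries no CSF, and
requesting an ILCR for it raises `NotACarcinogenError` rather than
returning a silent zero.  Category boundaries are read strictly: HI = 1
and ILCR = 10⁻⁶ or 10⁻⁴ fall in the lower category.

## Monte Carlo

Per the study design only the respiration rate is random: normal with
mean equal to the registry InhR, truncated at zero by resampling;
concentrations and body weights are held at their means.  The
coefficient of variation was not published; the shipped default is 0.3,
a typical inter-individual spread for long-term inhalation rates, and is
a required, prominently documented knob (`monte_carlo.inh_r_cv`).
Because the published simulation's CV is unknown, the published
cumulative-probability percentages are *not* numerical targets; the
package asserts the qualitative findings instead (no HI draw reaches 1;
adult ALF exceedance of ILCR = 10⁻⁶ above children's; fluid-only
variants dominate the combined ones).  Default 5000 iterations (runs in
well under a second; the full suite uses smaller draws where the test is
about structure, not convergence).  One InhR draw per cohort per
iteration is shared across metals and variants — one simulated person —
which preserves the perfect rank correlation between variants that
drawing independently would destroy.  A seed is mandatory everywhere;
identical seeds give bit-identical draws (numpy `default_rng`).

## Synthetic data

`generate_samples` emulates the sampling design (≈ 40 valid filter
samples per year across two urban sites).  Totals and PM mass are
log-normal with moments matched to the site profile (σ² = ln(1 + s²/m²),
μ = ln m − σ²/2); extractable fractions are beta with matched mean and
variance, so extract = fraction × total never exceeds the total.  PM
mass and metal concentrations are drawn independently by default (their
true correlation at the study sites is unknown).  What the generator
does **not** emulate: seasonal and meteorological structure, detection
limits and censoring, inter-metal correlation from shared sources, or
the fraction SDs (unpublished; default 0.05 absolute).  Tests passing on
generated data therefore demonstrate correctness of the computation
chain under the stated distributional assumptions, not robustness to
every feature of real monitoring data.

Exact-mean "pseudo-samples" (one degenerate sample per site carrying the
published annual means, `huludao.pseudo_samples`) drive the
reproduction workflow: because every pipeline statistic is a ratio or
linear functional of the means, feeding the means through the pipeline
reproduces the summary-level published results exactly.

## Numerical conventions and edge cases

- Doses are mg·kg⁻¹·day⁻¹ internally; display columns (`add_1e6`) use
  the case study's 10⁻⁶ mg·kg⁻¹·day⁻¹ convention.  Risk values keep full
  precision; rounding (HI to one significant figure, ILCR to three) is a
  display concern left to the caller.
- A bioaccessible fraction with zero total concentration is an error
  (`UndefinedFractionError`), not NaN.
- Sites whose fluid concentrations are entirely missing are omitted from
  the bioaccessibility table with a logged warning; missing fluids enter
  the dose stage as zero concentration, so the corresponding variants
  are zero rather than poisoning the others.
- Group summaries use sample SD (ddof = 1), 0.0 for singleton groups.
- Result CSV round-trips are lossless (pandas shortest-round-trip float
  formatting).

## Known limitations

- The closed-form deposition engine is a reference-adult fit plus a
  heuristic scaling rule; it is suitable for sensitivity analysis, not a
  substitute for a full airway-geometry dosimetry run.  Airway-generation
  resolution, clearance kinetics and hygroscopic growth are out of scope.
- The calibrated InhR/DF registry reproduces the case-study dose table
  by construction; transferring the package to another study area
  requires site-specific concentrations and, ideally, cohort DF values
  from a dosimetry model.
- Inhalation only: no dermal or ingestion pathways, and no metal
  interaction (synergy/antagonism) in the hazard index.
- Published summary cells that are internally inconsistent at printed
  precision (three bioaccessibility percentages, one LADD cell, one ILCR
  third digit) are documented in `pmrisk.huludao` and checked at
  correspondingly relaxed tolerances.
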