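# Methods

This note documents the model, its parameters and defaults, the synthetic
inputs, and the numerical and design choices behind `dairylca`. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Scope and system boundary

The package models a dairy system from cradle to farm gate. Upstream, the
feed chain (cultivation, processing, transport), purchased utilities and the
feed additive's manufacture enter through an emission-factor table; there is
no connector to any commercial LCA database, and the additive's plant-gate
footprint (e.g. 2.10 kg CO₂ eq, 54.78 Pt land, 9.35 m³ water deprivation per
kg of dried live yeast) is an *input parameter* of the farm stage, not a
modeled process. Downstream, on-farm enteric and manure emissions, energy,
water and bedding are computed per cow-year and normalized per kg of fat- and
protein-corrected milk (FPCM). Capital goods, post-farm stages and
lactation-curve modeling are out of scope.

## Annualization

A trial record holds group means over a 1-based inclusive days-in-milk
window. Annual figures combine:

* trial-window milk and intake (daily rate × duration);
* reference-system milk outside the window, shared by both groups, so group
  differences exist only inside the window;
* outside-window intake extrapolated proportionally to milk
  (FI_out = FI_trial × MY_out/MY_trial), always from the **control** group's
  window values — the treatment group inherits it;
* a fixed dry-period intake, default 600 kg DM over 60 days.

The intake decomposition `fi_annual = fi_trial + fi_outside + fi_dry` is
exact, not approximate, and is validated on construction. Annual FPCM applies
the trial composition to the annual milk mass. Gross annual energy intake is
either supplied directly or derived from the ration's energy density; the
default density is 18.45 MJ/kg DM, which is also the ratio implied by the
shipped trial records. Trial feed efficiency is daily FPCM over daily DMI.
Cumulative-window masses (not daily rates) drive the extrapolation; the
shipped French reference system pins the published outside-window intake
(2427 kg) where the pure formula gives 2430.4 — a ≤3 kg print-rounding
difference retained as an explicit override field rather than silently
recomputed.

The additive mass (dose [g/d] × days / 1000) contributes to the footprint
but not to the DMI, energy or feed-efficiency denominators: at 5–10 g/d it
is three orders of magnitude below intake reporting precision.

## On-farm emissions

`EmissionParams` defaults (all per-system configurable):

| parameter | default | meaning |
|---|---|---|
| ym | 6.5 % | share of gross energy emitted as enteric CH₄ (Tier-2 dairy) |
| ch4_energy_density | 55.65 MJ/kg | energy content of CH₄ |
| digestibility / ash / urinary | 0.70 / 0.08 / 0.04 | volatile-solids balance |
| b0 × 0.67 × mcf | 0.24 m³/kg VS, 0.17 | manure CH₄ pathway (liquid slurry) |
| cp_fraction | 0.165 | ration crude protein; N intake = FI·CP/6.25 |
| n_retention_fraction | 0.25 | N retained in milk and tissue |
| ef3 / ef4 / ef5 | 0.005 / 0.01 / 0.011 | direct and indirect N₂O factors |
| frac_gas / frac_leach | 0.30 / 0.10 | N volatilized / leached |
| nmvoc / pm10 / pm25 | 8.9 / 0.63 / 0.41 kg/head | inventory-guidebook-style flat factors |

Enteric CH₄ is GE·(Ym/100)/55.65. When a trial reports measured daily
enteric CH₄ (only the UK trial does), the measurement feeds the inventory
inside the trial window and the Tier-2 model covers the remaining year; the
provenance flag `ch4_measured` records this, and the override touches CH₄
flows only. NMVOC and particulate matter are computed as mass flows but feed
no reported impact category, matching how such inventories are usually
reported at midpoint level.

## Characterization and allocation

Climate-change factors default to AR6 GWP100 (biogenic CH₄ 27, fossil CH₄
29.8, N₂O 273). Ammonia maps to acidification (3.02 mol H⁺ eq/kg) and
terrestrial eutrophication; leached N maps to marine eutrophication; these
are stored in a configurable `CharacterizationFactors` object, not hard-coded
chemistry, because absolute results depend on the factor vintage. Freshwater
and marine eutrophication are carried in grams of P/N equivalents — the unit
of the additive's plant-gate characterization — and one scale constant in
the fixture builder bridges the kg-scale magnitudes that per-kg-milk tables
customarily print.

Farm impacts are allocated to milk by the dairy biophysical rule
AF = 1 − 6.04·M_meat/M_milk, with M_milk read as annual FPCM sold (falling
back to the system's own annual FPCM). AF is computed from the *annual*
profile in both annual and window-only accounting. A ratio ≥ 1/6.04 raises a
dedicated allocation-collapse error. Because M_meat is shared within a pair,
a treatment group with more FPCM receives a slightly *larger* share of farm
impacts — the conservative-allocation property, asserted in tests.

Category totals are AF × (Σ source rows)/FPCM with the nine-source breakdown
(feed compounds, roughages, on-farm CO₂/N₂O/CH₄, energy, water, additive,
land-use change) preserved; the breakdown-sum-equals-total identity is
enforced at 10⁻¹² relative precision inside the results object itself.

## Comparison and uncertainty

Relative differences use the control as denominator. Window-only accounting
restricts FPCM, intake, energy and (pro-rata) utilities and N intake to the
trial window. With outside-window inputs equalized, annualization dilutes
the window-scale difference — property-tested on randomized scenarios with
composition effects held at unity, since trial fat/protein also rescale the
FPCM of the *shared* outside-window milk and are therefore not purely
window-confined effects. Multi-trial aggregation is the unweighted mean of
per-trial control and treatment values, with the pooled difference recomputed
from unrounded means.

Monte Carlo propagation draws emission factors lognormally (per-cell
geometric standard deviation; gsd 1.0 means no spread) and zootechnical
inputs normally (per-group standard errors). The default is *paired*
sampling: one factor draw per iteration applied to both systems, so shared
background uncertainty cancels from the difference — the interpretation
problem that unpaired sampling has for small between-system differences. An
unpaired mode exists for comparison. Default 1000 iterations; all randomness
flows through one seeded `numpy` generator, making runs bit-reproducible.

One-at-a-time sensitivity scales a named parameter (emission parameters, or
trial fields suffixed `_control`/`_treatment`, with `my`/`dmi`/`fat`/
`protein`/`dose` shorthands) by 1 ± δ (default 10%) and reports central-
difference elasticities of the control climate total plus the sensitivity of
the difference in percentage points, ranked by magnitude. For a fully
modeled trial the climate total is linear in Ym, so its elasticity equals
the modeled enteric-CH₄ contribution share — used as an analytic cross-check
in the tests. δ = 0 returns zero elasticities after verifying the names
resolve.

## Synthetic inputs

`generate_scenario` draws complete control/treatment pairs from one seed.
Default effect multipliers emulate the spread seen across published
supplementation trials: milk yield 1.06 ± 0.055 (−1% to +13% across the
three shipped trials), DMI 1.01 ± 0.05, composition 1.005 ± ~0.012. Control
herds draw daily yield 30–48 kg, feed efficiency 1.4–1.9, 90–120-day
windows, doses of 5 or 10 g/d, biophysical allocation factors 0.85–0.92, and
factor-table gsd 1.05–1.3. Groups differ only through the effect
multipliers; reference systems, diets, utilities and the meat coproduct are
shared. What the generator does **not** emulate: lactation-curve shape,
seasonal manure-system variation, herd demography, and correlated effects
between yield and intake — so passing property tests demonstrate structural
correctness of the accounting, not predictive realism for any actual herd.

`load_trial_fixtures` ships the three published European trials. Absolute
per-category footprints depend on proprietary background databases, so the
factor table is *calibrated*: per trial, each contribution row of the
published control column yields one free factor (feed, roughage, energy,
water, fuel and LUC rows solve an emission factor; the on-farm CH₄ row
solves a per-trial Ym, 9.2–11.6%; the N₂O row solves a ration crude-protein
fraction, 0.17–0.22, through the N balance). The calibrated Ym values absorb
everything the background database layered onto the Tier-2 defaults and are
closure devices, not biological estimates. Control columns therefore
reproduce to printed precision by construction (a closure check); treatment
columns are genuine predictions from the trial effects and land within
~0.02 kg CO₂ eq/kg of the published totals — the published treatment columns
embed ration differences the trials did not print. Non-climate factors for
calibrated items echo typical per-kg-milk category-to-carbon ratios and are
plausibility scaffolding only. The assumed control allocation factor is 0.88
(unpublished in the source trials).

## Numerical choices and degenerate inputs

* Windows are 1-based inclusive; a trial spanning the whole lactation gets
  zero outside-window terms. One shipped trial prints a day range and a
  duration that disagree by three days; the duration (92 d), with which every
  mass in the record is consistent, defines the window.
* Zero denominators (trial milk yield, FPCM, category totals in contribution
  analysis) raise dedicated errors rather than propagating NaN.
* Emission-factor CSV round-trips exactly (`%.17g` on write, round-trip float
  parsing on read); duplicate (item, category) keys and negative factors are
  rejected by name.
* Monte Carlo draws of zootechnical inputs are clipped to their physical
  domains (positive rates, composition below 10%); with zero SE the trial
  values pass through untouched, so degenerate distributions collapse the
  simulation onto the deterministic point estimate exactly.
* Problem sizes: the shipped analyses are per-cow-year computations that run
  in milliseconds; the test suite uses 10–300 Monte Carlo iterations and
  150-trial generator runs, and the full suite completes in a few seconds.

## Known limitations

* The calibrated fixtures validate internal consistency against published
  control columns; they cannot independently validate absolute footprints,
  which require real background databases.
* Nitrogen fate uses a single retention fraction and one manure system; no
  grazing/housing split or seasonal MCF.
* The annualization assumes flat reference-system performance outside the
  trial window (no lactation curve), exactly as the underlying extrapolation
  method states.
* Trial-side uncertainty treats group means as independent normals; within-
  herd covariance between yield and intake is not modeled.
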