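# Methods

## Model structure

The simulator advances a herd of individually represented animals one day
at a time. Within a day the sub-steps run in a fixed, documented order:
(1) life events per animal in stable list order — age/DIM/pregnancy
counters, class transitions, calving (newborn heifer calves join the herd
the same day), pregnancy checks, dry-off, breeding; (2) culling and
herd-size maintenance; (3) on ration-interval days (default every 3 days),
pen reassignment → per-animal requirements → pen averaging → least-cost
formulation → assignment; (4) milk; (5) body weight; (6) excretion and
enteric methane; (7) aggregation into the daily record. The order is a
design choice: the members of the update are biologically prescribed, their
sequence is not, and fixing it is what makes runs reproducible.

### Random-number architecture

One master seed spawns five named, mutually independent PCG64 streams
(`lifecycle`, `bodyweight`, `rho`, `culling`, `sampling`) via
`SeedSequence.spawn`; initialization and scenario runs use distinct
`(seed, phase)` children. Because the feed-efficiency multiplier ρ has its
own stream, two runs sharing a seed and differing only in the ρ
distribution consume identical draw sequences everywhere else: births,
culls, class counts and daily milk are bit-identical, which is the paired
design the scenario comparison relies on. Bounded distributions enforce
their limits by resampling, never clipping, so draws are true truncated
normals.

## Life cycle

Five classes: calf (birth to weaning, default day 56), heifer I (weaning to
the breeding start age, default 400 d), heifer II (breeding period), heifer
III (within the pre-fresh period, default 30 d before expected calving),
cow (lactating/dry; absorbing). Growth follows linear average-daily-gain
targets toward milestones expressed as fractions of mature shrunk body
weight (shrunk = 0.96 × full): 55% at first conception, 82% at first
calving, 92% at the end of the first lactation, 100% by the end of the
second. Pregnant animals add conceptus growth; lactating cows add the
lactation tissue-change curve. Negative gain targets are floored at zero —
the model never forces weight loss to meet a milestone.

Reproduction supports estrus detection, synchronized estrus detection and
timed AI, separately configurable for heifers and cows. Estrous cycles are
drawn per cycle (mean 21 d, bounds [18, 25] — a reconstruction, as the
underlying protocol constants are farm inputs); detection is a per-estrus
draw; conception a per-service draw; gestation length is drawn at
conception (279 ± 5 d, bounds [266, 294]). Pregnancy loss is applied at the
three configured check days with per-check probability
q = 1 − (1 − L)^(1/3) so the compounded loss equals the configured total L
(default 0.12). Open heifers past 700 d of age and open cows past 400 DIM
are culled deterministically for reproductive failure; health culls are
daily per-reason hazards applied to cows, with annual probabilities summing
to ≈0.29 — chosen so a 1000-cow herd produces on the order of 330
health/production culls per year. The optional pre-drawn longevity day at
birth is off by default (daily hazards are the default exit process).

Herd size is steered by comparing the cow herd plus its in-herd pregnant
heifer pipeline with the target (target lactating count / (1 − expected dry
fraction), plus a 4% pre-fresh buffer): deficits are filled from the
replacement market, surplus pre-fresh heifers are sold (exit reason
"sold" — a single exit pathway shared with culls).

## Initialization herd

Founder female calves are simulated forward through the full life cycle
with no herd-size control; every entry into the pre-fresh stage is
snapshotted into the replacement market, and the surviving population forms
the sampling pool. The starting herd is drawn from the pool without
replacement with exact per-class counts, day-fields shifted so the pool's
last day becomes simulation day 0. Default starting counts approximate the
steady-state standing stock implied by the default parameters (per cow:
0.40 heifer I, 0.36 heifer II, 0.04 heifer III, 0.07 calves).

Problem sizes: the documented defaults of `build_initialization_herd` are
1000 founders × 5000 days. The packaged case-study configuration and the
acceptance script use 400 founders × 2800 days, which yields a pool of
~800 animals and a ~1000-entry market — comfortably larger than the 200-
lactating-cow starting herd draws — at a few seconds of runtime; the
scenario conclusions are ratio-based and insensitive to pool size beyond
sampling adequacy.

## Nutrition

Requirements are additive NRC (2001)-style terms in NEl, MP, Ca and P:
maintenance on metabolic body weight (0.080·BW^0.75 Mcal NEl/d;
3.8·BW^0.75 g MP/d), growth scaled by the target ADG, pregnancy beyond day
190 ((0.00318·d − 0.0352)·(CBW/45)/0.218 Mcal/d), and lactation per kg milk
at the herd's fat/protein tests (NEl/kg = 0.0929·fat% + 0.0547·protein% +
0.0395·lactose%). Expected DMI uses the NRC lactating-cow prediction
((0.372·FCM + 0.0968·BW^0.75)·(1 − e^(−0.192·(WOL+3.67)))), 1.85% of BW for
dry cows, and an allometric 0.0965·BW^0.75 for growing heifers. Weather is
accepted as an optional input but the default requirements are
thermoneutral; no temperature adjustment is applied.

Pens: lactating cows are split into DIM terciles (default 3 pens), dry cows
and each heifer class form one pen each, calves are fed individually (milk
at 10% of birth weight as-fed with a linear weaning ramp, plus the
broken-line starter-intake regression; an energy/protein-allowable gain
calculation is available as the mechanistic alternative to the ADG target).
Pen requirements are arithmetic means scaled by a lead factor (≥ 1,
default 1, applied to nutrients but not to intake).

The least-cost ration is solved with SLSQP (iteration cap 100, tolerance
1e-8) with analytic gradients; the total-DM constraint is an **equality**
at the predicted intake, which keeps diet percentages well defined. A
converged solution is re-verified against every constraint at 1e-6 relative
tolerance independently of the solver's own status. On failure, estimated
milk is reduced 0.5 kg (subtracting the marginal NEl/MP/Ca/P of a kg of
milk, so requirements are monotone non-increasing across retries) up to 20
times before a hard error naming the violated constraints. Ration
assignment gives every pen member the pen's diet composition and its own
predicted intake (whose pen mean equals the ration's DM total); the
efficiency multiplier then produces the simulated intake. The packaged
feed library (corn silage, soybean meal, wet brewers grain, dicalcium
phosphate, limestone, plus the calf feeds) is a documented NRC-style
reconstruction — prices and compositions are fixture values, so absolute
ration compositions and costs are illustrative, not predictions.

## Excretion and enteric methane

Coefficients live in a single constants table (`constants.py`) so they can
be corrected without touching model code; values are documented
reconstructions of the cited functional forms, magnitude-checked against
typical Holstein figures (≈25 kg DMI, ≈400 g/d enteric CH₄, ≈68 kg/d
manure for a lactating cow). Calves: manure/solids linear in BW; CH₄ =
(0.013·BW^0.75·4.184)/0.05565 g/d. Heifers: manure/TS/VS linear in BW; CH₄
linear in DMI in L/d, converted at 0.662 g/L (25 °C). Lactating cows:
manure, total solids, urine, fecal water, VS (split 56% degradable) and N
linear in the **simulated** (efficiency-adjusted) DMI. Dry cows: BW-based
manure; CH₄ always from the Mitscherlich model regardless of the global
switch, because the intake/milk regression carries milk terms that are
meaningless for dry cows. The Mitscherlich model saturates at 45.98 MJ/d
of CH₄ as a function of metabolisable-energy intake (NEl/0.64); the IPCC
Tier 2 route computes dietary gross energy from ration composition
(23.85/39.33/17.5 MJ/kg for CP/fat/carbohydrate, 8% ash) and applies
Ym = 6.5%. Negative linear predictions at extreme inputs are clamped to 0.

A structural consequence worth stating: heifer and dry-cow manure is
body-weight-driven and therefore insensitive to the efficiency multiplier,
while all lactating-cow excretion and every enteric model respond to
intake. Herd-level emission reductions under improved efficiency are
consequently smaller than the intake reduction — the case-study's central
nonlinearity — and the package reproduces it from whole-herd aggregation,
not from any tuned constant.

## GHG accounting

Annual volatile solids feed the anaerobic-lagoon methane estimate
CH₄ = VS·B₀·ρ_CH₄·MCF with B₀ = 0.24 m³/kg VS, density 0.662 kg/m³ and
MCF = 0.71 (North-American lagoon; the implied 0.113 kg CH₄/kg VS budget
matches published lagoon accounting). Direct N₂O = N·EF·44/28 with
EF = 0.002 kg N₂O-N/kg N. CO₂-equivalents use GWP₁₀₀ 30 and 298 and are
computed in **consistent mass units** throughout; reported reductions are
invariant to the unit choice.

## What the synthetic configuration does and does not show

The packaged configuration is a self-contained synthetic herd: its feed
prices, requirement constants and emission coefficients are documented
defaults, not calibrated farm data. Tests that pass against it demonstrate
the machinery — determinism, common-seed invariance, constraint
satisfaction, the ρ → intake → emissions chain and its dilution — not
predictive accuracy for any real farm. Absolute annual totals (tonnes of
milk, methane, manure) scale with these fixtures and with herd size;
within-run ratios are the scientifically meaningful outputs.

## Numerical choices and degenerate inputs

SD = 0 distributions return their mean (and must contain it within
bounds); empty pens, empty feed libraries, non-positive body weights,
probabilities outside [0, 1] and inverted bounds raise named errors;
gestation ≤ 50 d is rejected by the conceptus equations (growth is zero
through day 50); the conceptus total uses the multiplicative grouping
(0.0148·GL − 2.408)·CBW — the literal alternative yields negative mass for
all realistic inputs and is retained only behind a flag for inspection.
Ties in pen splitting and surplus-heifer sales are broken by (key, id) so
iteration order never depends on hashing.

## Known limitations

No disease-state dynamics (health culls are reduced-form hazards), no
twinning, no seasonality, no genetic transmission of the efficiency
multiplier from dam to calf, no manure storage/treatment process model
beyond the empirical lagoon estimate, no upstream feed-production
footprints, and no economics beyond feed price. Heifer intake for the
methane regression uses the optimizer-assigned intake rather than an
independent prediction. The efficiency multiplier applies to all classes'
intake; summaries are reported over lactating cows.
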