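# herdsim

Stochastic, individual-animal simulation of a dairy herd on a daily time
step: the full animal life cycle (calf → heifer I/II/III → cow, lactating or
dry), least-cost ration formulation against NRC-style nutrient requirements,
manure excretion and enteric methane by animal class, and a per-animal feed
efficiency layer for paired scenario analysis with greenhouse-gas
accounting.

It is written for animal and environmental scientists who want to ask
herd-level "what if" questions — here, specifically: *if a herd is bred for
lower residual feed intake, how much do feed use, methane and manure
emissions fall?*

## The model in brief

Every animal is simulated individually. Life events (calf sex, stillbirth,
conception, estrus detection, pregnancy loss, health culling) are Monte
Carlo draws — an event with probability *p* occurs when *p > u*,
*u ~ U[0, 1)* — and continuous traits (body weights, gestation length,
estrous cycle) come from bounded truncated-normal distributions. Key
equations:

* **Milk**: Wood lactation curve, milk = *a·t^b·e^(−ct)* per parity group.
* **Conceptus**: total mass (0.0148·GL − 2.408)·CBW for gestation length GL
  and calf birth weight CBW, deposited as 3W(t−50)²/(GL−50)³ kg/d from day 51.
* **Lactation tissue**: ±(s/m)·e^(1−t/m)·(t/m − 1) kg/d with (s, m) =
  (20, 65) primiparous, (40, 70) multiparous — early mobilisation, later
  repletion, net ≈ 0 over a lactation.
* **Rations**: minimise Σ cⱼxⱼ s.t. NEl/MP/Ca/P supplies ≥ pen requirement,
  total DM = predicted intake, NDF ∈ [25, 40]% DM, forage NDF ≥ 19% DM,
  fat ≤ 7% DM, 0 ≤ xⱼ ≤ max inclusion; solved by SLSQP with a 0.5-kg milk
  step-down fallback on non-convergence.
* **Feed efficiency**: each animal carries a lifetime multiplier ρ on its
  predicted dry matter intake (simulated DMI = ρ · expected DMI). ρ is drawn
  from its own random stream, so common-seed runs that differ only in the ρ
  distribution have bit-identical life cycles, milk and demographics — only
  intake and the intake-driven emissions move.
* **Emissions**: enteric CH₄ by class (metabolic-BW relation for calves,
  intake regression for heifers, a three-way switch for lactating cows —
  intake/milk regression, Mitscherlich saturating curve, or IPCC Tier 2 on
  dietary gross energy; dry cows always use the Mitscherlich form); manure,
  solids, volatile solids and N from class-specific empirical equations;
  lagoon CH₄ = VS·B₀·ρ_CH₄·MCF; direct N₂O = N·EF·44/28; CO₂-eq with
  GWP₁₀₀ = 30 (CH₄) and 298 (N₂O).

## Worked example

```python
from herdsim.config import default_config
from herdsim.engine import compare_scenarios

cfg = default_config()          # 200-lactating-cow Holstein herd, 365 days
results, table = compare_scenarios(cfg, ["Baseline", "High", "VeryHigh"], seed=3)
print(table[["simulated_intake_t", "total_co2eq_t",
             "intake_reduction_pct", "co2eq_reduction_pct"]].round(2))
```

prints (seed 3):

```
          simulated_intake_t  total_co2eq_t  intake_reduction_pct  co2eq_reduction_pct
scenario
Baseline             2438.72        3688.96                  0.00                 0.00
High                 2292.44        3501.82                  6.00                 5.07
VeryHigh             2146.15        3314.56                 12.00                10.15
```

The three scenarios share one seed and one initialization herd and differ
only in the mean of the ρ distribution (1.00, 0.94, 0.88; SD 0.06). Annual
simulated intake falls by almost exactly 6% and 12% — the configured mean
shift — while total CO₂-eq falls by only ~5% and ~10%: emission-model
intercepts and the body-weight-driven (efficiency-insensitive) manure of
heifers and dry cows dilute the intake reduction. Daily milk and every
demographic series are identical across the three runs, by construction.

The same workflow is available from the shell:

```bash
herdsim init --seed 3 --out init.sqlite           # build & persist the init herd
herdsim run --seed 3 --init-db init.sqlite --scenario High --out output/
herdsim compare --seed 3 --init-db init.sqlite --out output/
```

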