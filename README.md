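# roostnrg

Bioenergetics and overheating risk of artificial bat roosts.

Artificial roost boxes ("rocket boxes") are deployed for bats of
conservation concern, but their microclimates vary strongly with box
design, landscape placement, weather and the bats themselves — warm
enough to spare a maternity colony the cost of endothermy, or hot enough
to kill. `roostnrg` turns multi-position roost temperature records into
physiological and risk currencies and asks which factors drive them:

1. **Daily energy expenditure (DEE).** Piecewise metabolic-rate models
   for two thermoregulatory strategies. A continuously endothermic bat
   pays BMR inside the thermoneutral zone [T_lc, T_uc] and
   BMR + |ΔT|·C_eu outside it. A facultatively heterothermic bat behaves
   identically above the torpor onset (25 °C) but below it pays the
   torpid rate TMR_min·Q10^((T_roost−T_tor_min)/10), with
   Q10 = 1.6 + 0.26·T_roost − 0.006·T_roost², defending a 2 °C minimum
   body temperature below the set point. Each hour the modelled bat
   occupies the logger position minimizing its rate; hourly rates ×
   8.44 g × 20.083 J/mlO2, summed over 24 h, give DEE in kJ.
2. **Overheating events.** Counts of hourly readings strictly above
   40 °C per box-day (144 readings on a complete day), with per-position
   breakdowns.
3. **Multimodel inference.** Fourteen a priori candidate models (design,
   placement, bat abundance, daily maximum temperature and wind, with
   interactions) fit as Gaussian LMs (DEE; log scale for the
   heterothermic response) or Poisson GLMs (counts), ranked by AICc,
   model-averaged over the 90% confidence set, with 85% Wald intervals
   flagging informative parameters, VIF screening and balanced-grid
   predicted means.

A synthetic-study generator reproduces the structure of a balanced
two-site field deployment (40 boxes = 2 sites × 4 placements × 5
designs, 12 bi-hourly loggers each, April–September) with known injected
effects, so the full pipeline is testable end to end without field data.

## Worked example

```python
import datetime as dt
import roostnrg as r

cfg = r.SimulationConfig(seed=7, start_date=dt.date(2019, 6, 1),
                         end_date=dt.date(2019, 7, 31))
study = r.simulate_study(cfg)
dee = r.dee_table(study.grids)
heat = r.overheating_table(study.grids, metadata=study.metadata)
table = r.build_box_day_table(dee, heat, study.weather,
                              study.bat_counts, study.metadata)
print(len(table), table["dee_endothermic"].mean(),
      table["n_overheating_events"].sum())

res = r.select_models(r.filter_for_overheating_model(table),
                      "n_overheating_events")
print(res.ranking.head(3)[["name", "k", "aicc", "delta", "weight"]])
```

Output (abridged):

```
box-days: 2440
mean DEE endothermic: 18.8 kJ
mean DEE heterothermic: 4.3 kJ
total overheating events: 6623
name  k    aicc  delta  weight
 m14 21 4964.77   0.00    0.75
 m10 26 4966.93   2.17    0.25
 m12 18 5052.15  87.39    0.00
design[T.VR]:  +0.197 [0.131, 0.262]   informative=True
design[T.CH]:  -0.672 [-0.758, -0.586] informative=True
design[T.WTR]: -0.764 [-0.875, -0.653] informative=True
design[T.EJW]: -0.735 [-0.824, -0.645] informative=True
```

Over a simulated June–July, an endothermic bat picking the best position
each hour spends ~19 kJ/day while a heterothermic one spends ~4 kJ/day.
The overheating Poisson GLM ranks the placement-weather interaction
model (m14) on top with the design-bats model (m10) competing
(ΔAICc ≈ 2), and the averaged design coefficients recover the injected
truth: removing vents (VR) raises overheating risk relative to the
reference design (log-rate +0.20), while the chimney, reflective-roof
and water-jacket designs lower it — the same qualitative ordering the
generator encodes.

## Command line

```sh
roostnrg simulate --seed 1 --out data/
roostnrg dee      --temps data/temperatures.csv --boxes data/boxes.csv --out dee.csv
roostnrg overheat --temps data/temperatures.csv --out heat.csv
roostnrg select   --temps data/temperatures.csv --boxes data/boxes.csv \
                  --weather data/weather.csv --bats data/bat_counts.csv \
                  --response overheat --out results/overheat
```

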