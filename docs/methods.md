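# Methods

## The bioenergetic model

`roostnrg` estimates the daily energy expenditure (DEE) of a small
vespertilionid bat occupying an artificial roost box instrumented with
temperature loggers at 12 positions (top/middle/bottom × N/E/S/W faces).
Two thermoregulatory strategies are modelled with piecewise
metabolic-rate functions of roost temperature T_roost (mlO2 g⁻¹ hr⁻¹):

**Continuous endothermy.** Within the thermoneutral zone
[T_lc, T_uc] = [32, 36.26] °C the rate equals the basal metabolic rate
BMR = 2.6. Below T_lc it is BMR + (T_lc − T_roost)·C_eu and above T_uc
it is BMR + (T_roost − T_uc)·C_eu, with euthermic conductance
C_eu = 0.2638 mlO2 g⁻¹ hr⁻¹ °C⁻¹.

**Facultative heterothermy.** Identical above the torpor onset
T_onset = 25 °C. At or below it (the torpor branch owns the boundary,
so the rate drops discontinuously there — torpor entry) the torpid rate
is TMR_min · Q10^((T_roost − T_tor_min)/10) with TMR_min = 0.03,
T_tor_min = 2 °C and a temperature-dependent
Q10 = 1.6 + 0.26·T_roost − 0.006·T_roost². Below T_tor_min the bat
defends a minimum body temperature:
TMR_min + (T_tor_min − T_roost)·C_t with torpid conductance C_t = 0.055.
On (T_tor_min, T_onset] the torpid rate is strictly increasing, so the
coldest available position is always the cheapest for a torpid bat.
Entry and arousal costs of torpor bouts are not modelled (their cost,
duration and frequency are too variable to parameterize defensibly), and
the heterothermic rate never exceeds the endothermic rate at any
temperature, so heterothermic DEE is bounded above by endothermic DEE on
identical inputs.

Each hour the bat is assumed to occupy the position (among those with a
logger recording that hour) minimizing its metabolic rate; ties break to
the first position in the fixed top-N … bottom-W ordering, for
determinism. Hourly mass-specific rates are scaled by body mass
(8.44 g, a reproductive female little brown bat, the standard surrogate
for the Indiana bat) and the oxyjoule equivalent 20.083 J/mlO2, summed
over the local midnight-to-midnight 24-h day and reported in kJ. No cost
cap is applied above the 45 °C lethal threshold: the minimization rule
itself keeps bats off lethal positions whenever any cooler logger is
available. A box-day in which any hour lacks all readings is excluded
rather than imputed. One consequence of the hourly minimization is that
a bat between 25 and 32 °C pays normothermic cost only when no
torpor-eligible (cooler) position is available that hour; real torpid
bats move less freely than this, so heterothermic DEE is a lower bound.

## Logger schedule and grids

Loggers record bi-hourly on alternating (even/odd hour) schedules, two
of each parity per level, so every hour has six readings and a complete
box-day has 144. Readings are quantized to the 0.5 °C logger resolution.
Duplicate (box, position, timestamp) records are treated as corruption
(hard error), not silently deduplicated.

## Overheating events

An overheating event is one reading strictly above 40 °C (exactly 40.0
does not count). Counts run over available readings even on incomplete
days, with `n_readings` reported alongside so completeness is visible.
Fully shaded (forest) placements log almost no events; including them
makes Poisson count models inestimable, so they are removed from the
overheating modelling table only.

## Candidate models and multimodel inference

Fourteen a priori models combine box design (5 levels, reference REF),
landscape placement (reference open), daily bat count, daily maximum air
temperature and daily maximum wind speed, with design×placement,
design×bats, and design- or placement-×-weather interactions.
Responses: endothermic DEE (Gaussian LM), heterothermic DEE (Gaussian LM
on the natural-log scale, for normality of residuals), and daily
overheating counts (Poisson GLM). No box-level random effect is used:
identical boxes are assumed exchangeable given design, placement and
weather. Models are ranked by AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1), where
k counts the residual variance for Gaussian models (the R convention).
Models within ΔAICc ≤ 2 of the best are "competing". The 90% confidence
set is the smallest weight-ordered prefix with cumulative Akaike weight
≥ 0.90; coefficients are model-averaged over it.

Full averaging is the default (a model lacking a term contributes a
structural zero with zero variance); conditional averaging is available
because the two conventions differ and published analyses rarely say
which they used. Unconditional standard errors follow
Burnham–Anderson: se = Σᵢ wᵢ √(seᵢ² + (βᵢ − β̄)²). A parameter is
*informative* when its 85% Wald interval (estimate ± z₀.₉₂₅·se, link
scale) excludes zero — a deliberately liberal screen that avoids
discarding biologically relevant terms inside top models.
Multicollinearity is screened by VIF on the dummy-coded main effects
(each column regressed on the others; VIF = 1/(1−R²); a single predictor
is 1 by convention, perfect collinearity reported infinite).

Predicted marginal means average model predictions over a balanced
reference grid (all levels of the other factor crossed, numeric
covariates at their means); Poisson predictions are on the count scale,
and log-response predictions are back-transformed both naively and with
the lognormal half-variance correction exp(x̄ + σ̂²/2), labelled, since
the two differ and neither is universally preferred.

## The synthetic study generator

The generator emulates the structure of a balanced two-site deployment:
2 sites × 4 placements × 5 designs = 40 boxes, 1 April–15 September
(168 days). Box-hour temperature is built additively — daily mean air
temperature, a diel cosine (range 11 °C, warmest at 15:00), a solar gain
of up to 12 °C scaled per placement (open 1.0, east/west 0.78 with the
gain phase-shifted ∓2 h, forest 0.08) and reduced 2% per m/s of wind, a
vertical gradient of up to 10 °C top-to-bottom scaled by the solar
curve, saturating social-thermoregulation heating (0.1 °C per bat up to
70 bats ≈ 7 °C, applied to the night/morning hours when the colony is in
the roost), and Gaussian sensor noise (sd 0.5 °C) — then quantized to
0.5 °C. Design modifiers act on the forcing curve, not the noise:
ventilation and reflectance damp its amplitude (REF 6%, VR 0% — vent
removal makes it the warmest, CH 22%, WTR 6%+18%), and thermal mass
(EJW) is a 4-h moving average that both lags the daily maximum and
buffers extremes. Daily maximum air temperature follows a seasonal
sinusoid (base 19 °C, amplitude 9 °C, peak in late July, day-to-day sd
4 °C, clipped to 1.3–36.4 °C); maximum wind is gamma(2, 1.5) m/s.
Colonies occupy half the non-forest boxes and ramp up through the
season. Randomness flows through named substreams (weather,
temperatures, bats, parity) spawned from one mandatory seed so that
adding boxes never perturbs the weather draws; which two faces per level
record even hours is randomized per box, since the field protocol fixes
only the two-per-parity-per-level constraint.

These values were chosen once to produce a season whose outputs sit in
the realistic range for temperate-zone rocket boxes — mean endothermic
DEE ≈ 20 kJ, heterothermic ≈ 3–4 kJ, on the order of 10⁴ overheating
events in ~10⁶ readings concentrated at top positions and solar-exposed
placements. What the generator does *not* emulate: physically based heat
transfer in box materials, humidity and rainfall, cloud-cover days with
collapsed vertical gradients, within-day bat movement feedbacks on
logger readings, or site-level weather differences. Passing tests
therefore demonstrate that the pipeline is correct and that the
statistical machinery recovers effects of the kind and size injected —
not that field data would yield any particular ranking.

## Numerical choices and limitations

All rates are computed in double precision with no rounding before
presentation. Branch boundaries are owned as written in the criteria
(TNZ closed at both ends; torpor branch closed at T_onset; defence
branch closed at T_tor_min, where its extra term vanishes, keeping the
torpid transition continuous). Rank-deficient candidates (e.g. an empty
design×placement cell) are flagged and excluded from ranking with a
warning rather than aborting the candidate set. AICc raises when
n − k − 1 ≤ 0. The default test and recovery experiments use a 4-week
mid-summer window (40 boxes, 28 days), sized for stable power in the
Poisson design-effect recovery check while keeping the suite quick.
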