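"""Piecewise metabolic-rate models and daily energy expenditure (DEE).

Two thermoregulatory scenarios for a small vespertilionid bat roosting in
an artificial box:

* **Continuous endothermy** — the bat defends a normothermic body
  temperature at every roost temperature.  Metabolic rate equals the basal
  metabolic rate (BMR) inside the thermoneutral zone ``[t_lc, t_uc]`` and
  rises linearly with thermal conductance ``c_eu`` per degree of deviation
  outside it.

* **Facultative heterothermy** — identical to the endothermic scenario
  above the torpor onset temperature ``t_onset``; at or below it the bat
  enters torpor, where metabolic rate scales as
  ``TMR_min * Q10 ** ((T_roost - t_tor_min) / 10)`` with a
  temperature-dependent Q10, until the minimum torpid set point
  ``t_tor_min`` below which a minimum body temperature is defended with
  torpid conductance ``c_t``.

A behaviourally thermoregulating bat is assumed to occupy, each hour, the
logger position in the box whose temperature minimizes its metabolic rate.
Hourly mass-specific rates (mlO2 g^-1 hr^-1) are converted to whole-animal
energy (J) using body mass and the oxyjoule equivalent, summed over the
24-h day and reported in kJ.

Entry/arousal costs of torpor bouts are deliberately not modelled, and no
cap is applied above the lethal threshold: the position-minimization rule
makes hot positions unattractive whenever any cooler logger is available.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterable

import numpy as np
import yaml

__all__ = [
    "BioenergeticParams",
    "Scenario",
    "metabolic_rate_endothermic",
    "metabolic_rate_heterothermic",
    "q10_factor",
    "hourly_best_rate",
    "daily_energy_expenditure",
    "dee_table",
    "MissingDataError",
]


class MissingDataError(ValueError):
    """An hour (or day) has no usable temperature readings."""


class Scenario(str, enum.Enum):
    """Thermoregulatory strategy of the modelled bat."""

    ENDOTHERMIC = "endothermic"
    HETEROTHERMIC = "heterothermic"


@dataclass(frozen=True)
class BioenergeticParams:
    """Physiological constants for the metabolic-rate models.

    Defaults describe a reproductive female little brown bat
    (*Myotis lucifugus*), the standard physiological surrogate for the
    Indiana bat.

    Attributes
    ----------
    bmr : float
        Basal metabolic rate, mlO2 g^-1 hr^-1.
    t_lc, t_uc : float
        Lower / upper critical temperature bounding the thermoneutral
        zone, °C.
    c_eu : float
        Euthermic thermal conductance, mlO2 g^-1 hr^-1 °C^-1.
    t_onset : float
        Roost temperature at or below which a facultatively heterothermic
        bat enters torpor, °C.
    tmr_min : float
        Minimum torpid metabolic rate, mlO2 g^-1 hr^-1.
    t_tor_min : float
        Minimum torpid set point; below it a torpid bat defends body
        temperature, °C.
    c_t : float
        Torpid thermal conductance, mlO2 g^-1 hr^-1 °C^-1.
    mass : float
        Body mass, g.
    joules_per_ml_o2 : float
        Oxyjoule conversion, J per ml O2.
    lethal_temp : float
        Informational lethal threshold, °C (not used in the rate
        equations; see module docstring).
    """

    bmr: float = 2.6
    t_lc: float = 32.0
    t_uc: float = 36.26
    c_eu: float = 0.2638
    t_onset: float = 25.0
    tmr_min: float = 0.03
    t_tor_min: float = 2.0
    c_t: float = 0.055
    mass: float = 8.44
    joules_per_ml_o2: float = 20.083
    lethal_temp: float = 45.0

    def __post_init__(self) -> None:
        if not (self.t_tor_min < self.t_onset < self.t_lc < self.t_uc):
            raise ValueError(
                "temperature thresholds must satisfy "
                "t_tor_min < t_onset < t_lc < t_uc"
            )
        for name in ("bmr", "c_eu", "tmr_min", "c_t", "mass", "joules_per_ml_o2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @classmethod
    def from_file(cls, path: str | Path) -> "BioenergeticParams":
        """Load parameters from a YAML or JSON mapping; missing keys keep defaults."""
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError(f"{path}: expected a mapping of parameter names")
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"{path}: unknown parameters {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in data.items()})


def _validate_finite(t_roost: np.ndarray | float) -> np.ndarray:
    t = np.asarray(t_roost, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("t_roost must be finite")
    return t


def metabolic_rate_endothermic(
    t_roost: float | np.ndarray, params: BioenergeticParams | None = None
) -> float | np.ndarray:
    """Mass-specific metabolic rate (mlO2 g^-1 hr^-1) under continuous endothermy.

    Equals BMR on the thermoneutral zone ``[t_lc, t_uc]`` and increases
    linearly with slope ``c_eu`` per °C outside it.  Accepts scalars or
    arrays; returns the same shape.
    """
    p = params or BioenergeticParams()
    t = _validate_finite(t_roost)
    rate = np.where(
        t < p.t_lc,
        p.bmr + (p.t_lc - t) * p.c_eu,
        np.where(t > p.t_uc, p.bmr + (t - p.t_uc) * p.c_eu, p.bmr),
    )
    return rate if rate.ndim else float(rate)


def q10_factor(t_roost: float | np.ndarray) -> float | np.ndarray:
    """Temperature-dependent Q10 of torpid metabolism: 1.6 + 0.26 T - 0.006 T^2."""
    t = _validate_finite(t_roost)
    q = 1.6 + 0.26 * t - 0.006 * t * t
    return q if q.ndim else float(q)


def metabolic_rate_heterothermic(
    t_roost: float | np.ndarray, params: BioenergeticParams | None = None
) -> float | np.ndarray:
    """Mass-specific metabolic rate (mlO2 g^-1 hr^-1) under facultative heterothermy.

    Branches, from warm to cold (boundaries owned per the inequalities
    below):

    * ``t_roost > t_onset`` — normothermic; identical to
      :func:`metabolic_rate_endothermic`.
    * ``t_tor_min < t_roost <= t_onset`` — torpid:
      ``tmr_min * q10_factor(t) ** ((t - t_tor_min) / 10)``.
    * ``t_roost <= t_tor_min`` — torpid defence of minimum body
      temperature: ``tmr_min + (t_tor_min - t) * c_t``.

    The rate drops discontinuously at ``t_onset`` (torpor entry); every
    other boundary is continuous.
    """
    p = params or BioenergeticParams()
    t = _validate_finite(t_roost)
    endo = np.where(
        t < p.t_lc,
        p.bmr + (p.t_lc - t) * p.c_eu,
        np.where(t > p.t_uc, p.bmr + (t - p.t_uc) * p.c_eu, p.bmr),
    )
    # clip keeps the q10 exponent well-defined on branches where it is unused
    t_tor = np.clip(t, p.t_tor_min, p.t_onset)
    torpid = p.tmr_min * (1.6 + 0.26 * t_tor - 0.006 * t_tor * t_tor) ** (
        (t_tor - p.t_tor_min) / 10.0
    )
    defence = p.tmr_min + (p.t_tor_min - t) * p.c_t
    rate = np.where(t > p.t_onset, endo, np.where(t > p.t_tor_min, torpid, defence))
    return rate if rate.ndim else float(rate)


_RATE_FUNCS = {
    Scenario.ENDOTHERMIC: metabolic_rate_endothermic,
    Scenario.HETEROTHERMIC: metabolic_rate_heterothermic,
}


def hourly_best_rate(
    temps_available: Iterable[float],
    scenario: Scenario | str,
    params: BioenergeticParams | None = None,
) -> tuple[float, float]:
    """Temperature and rate of the energy-minimizing roost position this hour.

    ``temps_available`` must be ordered by the fixed position convention
    (top-N, top-E, ... bottom-W restricted to the loggers recording this
    hour); ties are broken toward the earliest position in that ordering.

    Returns ``(chosen_temperature, rate)``.

    Raises
    ------
    MissingDataError
        If no temperatures are available.
    """
    temps = np.asarray(list(temps_available), dtype=float)
    if temps.size == 0:
        raise MissingDataError("no temperature readings available this hour")
    rates = _RATE_FUNCS[Scenario(scenario)](temps, params)
    i = int(np.argmin(rates))  # argmin takes the first minimum: fixed-order tie-break
    return float(temps[i]), float(rates[i])


def daily_energy_expenditure(
    grid,
    scenario: Scenario | str,
    params: BioenergeticParams | None = None,
) -> float:
    """Daily energy expenditure (kJ) for one box-day temperature grid.

    For each of the 24 hours the bat occupies the available position with
    the lowest metabolic rate; hourly mass-specific rates are converted to
    whole-animal joules (``rate * mass * joules_per_ml_o2``) and summed.

    Parameters
    ----------
    grid
        A :class:`~roostnrg.microclimate.RoostTemperatureGrid` (anything
        with a ``(24, n_positions)`` float ``temps`` array, NaN where a
        logger was not recording).
    scenario : Scenario or str
        ``"endothermic"`` or ``"heterothermic"``.
    params : BioenergeticParams, optional

    Raises
    ------
    MissingDataError
        If any hour has no reading at all; such box-days are excluded
        from analysis rather than imputed.
    """
    p = params or BioenergeticParams()
    temps = np.asarray(grid.temps, dtype=float)
    if temps.ndim != 2 or temps.shape[0] != 24:
        raise ValueError("grid.temps must be a 24 x n_positions matrix")
    avail = np.isfinite(temps)
    if not avail.any(axis=1).all():
        missing = np.flatnonzero(~avail.any(axis=1))
        raise MissingDataError(
            f"hours with no readings: {missing.tolist()}; day excluded"
        )
    rates = _RATE_FUNCS[Scenario(scenario)](np.where(avail, temps, 0.0), p)
    rates = np.where(avail, rates, np.inf)
    hourly = rates.min(axis=1)
    return float(hourly.sum() * p.mass * p.joules_per_ml_o2 / 1000.0)


def dee_table(
    grids,
    params: BioenergeticParams | None = None,
    metadata=None,
):
    """Tidy DEE table: one row per box-day x scenario.

    Box-days with any fully-missing hour are excluded (the day cannot be
    evaluated without imputing temperatures).  If ``metadata`` (a DataFrame
    indexed or keyed by ``box_id`` with ``site``, ``design``, ``placement``)
    is given, those columns are joined on.

    Returns a pandas DataFrame with columns
    ``box_id, date, scenario, dee_kj, n_hours_used`` (+ metadata columns).
    """
    import pandas as pd

    rows = []
    for grid in grids:
        avail = np.isfinite(np.asarray(grid.temps, dtype=float))
        n_hours = int(avail.any(axis=1).sum())
        if n_hours < 24:
            continue
        for scenario in Scenario:
            rows.append(
                {
                    "box_id": grid.box_id,
                    "date": grid.date,
                    "scenario": scenario.value,
                    "dee_kj": daily_energy_expenditure(grid, scenario, params),
                    "n_hours_used": n_hours,
                }
            )
    table = pd.DataFrame(
        rows, columns=["box_id", "date", "scenario", "dee_kj", "n_hours_used"]
    )
    if metadata is not None and len(table):
        meta = metadata.reset_index() if metadata.index.name == "box_id" else metadata
        cols = [c for c in ("site", "design", "placement") if c in meta.columns]
        table = table.merge(meta[["box_id", *cols]], on="box_id", how="left")
    return table
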