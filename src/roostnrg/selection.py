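"""Information-theoretic model selection for the box-day responses.

Fourteen a priori candidate models — combinations of box design,
landscape placement, bat abundance, daily maximum air temperature and
wind speed, with biologically motivated interactions — are fit to each
response:

* ``dee_endothermic`` — linear model (Gaussian);
* ``dee_heterothermic`` — linear model on the natural-log scale;
* ``n_overheating_events`` — Poisson GLM (forest placements must be
  filtered out first; they log almost no events and break estimation).

Models are ranked by AICc; models within 2 AICc of the best are
"competing"; a 90% confidence set (smallest weight-ordered prefix with
cumulative Akaike weight >= 0.90) supports model averaging.  Averaged
coefficients use full averaging by default (a term absent from a model
contributes zero) with Burnham-Anderson unconditional standard errors;
a parameter is "informative" when its 85% Wald interval excludes zero.

The reference design is REF and the reference placement is open: every
design is a variant of REF, and solar-exposed placements are the baseline
of applied interest.  No box-level random effect is used — identical
boxes are assumed exchangeable given design, placement and weather.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

__all__ = [
    "DESIGN_LEVELS",
    "PLACEMENT_LEVELS",
    "RESPONSES",
    "CandidateModelSpec",
    "build_candidate_set",
    "build_box_day_table",
    "FittedCandidate",
    "fit_candidates",
    "aicc",
    "aicc_rank",
    "ModelSelectionResult",
    "confidence_set_average",
    "vif_screen",
    "predict_means",
    "select_models",
]

DESIGN_LEVELS = ("REF", "VR", "CH", "WTR", "EJW")
PLACEMENT_LEVELS = ("open", "east", "west", "forest")

#: response column -> (patsy left-hand side, family)
RESPONSES = {
    "dee_endothermic": ("dee_endothermic", "gaussian"),
    "dee_heterothermic": ("np.log(dee_heterothermic)", "gaussian"),
    "n_overheating_events": ("n_overheating_events", "poisson"),
}

_TERM_TO_COLUMN = {
    "Design": "design",
    "Placement": "placement",
    "Total_Bats": "total_bats",
    "Max_Temp": "max_temp",
    "Max_Wind": "max_wind",
}

_CANDIDATE_TERMS: dict[str, list[str]] = {
    "null": [],
    "m2": ["Design"],
    "m3": ["Placement"],
    "m4": ["Design", "Placement", "Design:Placement"],
    "m5": ["Design", "Placement", "Total_Bats", "Design:Total_Bats"],
    "m6": ["Design", "Placement", "Total_Bats", "Design:Placement",
           "Design:Total_Bats"],
    "m7": ["Design", "Placement", "Total_Bats", "Max_Temp", "Design:Placement",
           "Design:Total_Bats", "Design:Max_Temp"],
    "m8": ["Design", "Placement", "Total_Bats", "Max_Temp", "Design:Placement",
           "Design:Total_Bats", "Placement:Max_Temp"],
    "m9": ["Design", "Placement", "Total_Bats", "Max_Temp", "Max_Wind",
           "Design:Placement", "Design:Total_Bats", "Design:Max_Temp",
           "Design:Max_Wind"],
    "m10": ["Design", "Placement", "Total_Bats", "Max_Temp", "Max_Wind",
            "Design:Placement", "Design:Total_Bats", "Placement:Max_Temp",
            "Placement:Max_Wind"],
    "m11": ["Design", "Placement", "Max_Temp", "Design:Placement",
            "Design:Max_Temp"],
    "m12": ["Design", "Placement", "Max_Temp", "Design:Placement",
            "Placement:Max_Temp"],
    "m13": ["Design", "Placement", "Max_Temp", "Max_Wind", "Design:Placement",
            "Design:Max_Temp", "Design:Max_Wind"],
    "m14": ["Design", "Placement", "Max_Temp", "Max_Wind", "Design:Placement",
            "Placement:Max_Temp", "Placement:Max_Wind"],
}


@dataclass(frozen=True)
class CandidateModelSpec:
    """One a priori candidate: a name and its fixed-effect terms."""

    name: str
    terms: tuple[str, ...]

    def formula(self, response: str) -> str:
        lhs, _family = RESPONSES[response]
        if not self.terms:
            return f"{lhs} ~ 1"
        rhs = " + ".join(
            ":".join(_TERM_TO_COLUMN[part] for part in term.split(":"))
            for term in self.terms
        )
        return f"{lhs} ~ {rhs}"

    @property
    def variables(self) -> set[str]:
        return {
            _TERM_TO_COLUMN[part] for term in self.terms for part in term.split(":")
        }


def build_candidate_set() -> list[CandidateModelSpec]:
    """The 14 a priori candidate model specifications."""
    return [
        CandidateModelSpec(name=name, terms=tuple(terms))
        for name, terms in _CANDIDATE_TERMS.items()
    ]


def build_box_day_table(
    dee: pd.DataFrame,
    overheating: pd.DataFrame,
    weather: pd.DataFrame,
    bat_counts: pd.DataFrame,
    metadata: pd.DataFrame,
) -> pd.DataFrame:
    """Join per-box-day observations into the modelling table.

    Inputs are the tidy outputs of the upstream stages; the result has
    one row per box-day with both DEE scenarios, the overheating count,
    design, placement, site, total bats and daily weather maxima.
    """
    wide = dee.pivot_table(
        index=["box_id", "date"], columns="scenario", values="dee_kj"
    ).rename(
        columns={"endothermic": "dee_endothermic", "heterothermic": "dee_heterothermic"}
    ).reset_index()
    table = wide.merge(
        overheating[["box_id", "date", "n_events", "n_readings"]], on=["box_id", "date"]
    ).rename(columns={"n_events": "n_overheating_events"})
    table = table.merge(metadata[["box_id", "site", "design", "placement"]], on="box_id")
    table = table.merge(weather, on=["site", "placement", "date"], how="left")
    table = table.merge(bat_counts, on=["box_id", "date"], how="left")
    return prepare_factors(table)


def prepare_factors(table: pd.DataFrame) -> pd.DataFrame:
    """Set factor dtypes with REF / open as the leading (reference) levels."""
    table = table.copy()
    for column, levels in (("design", DESIGN_LEVELS), ("placement", PLACEMENT_LEVELS)):
        if column in table.columns:
            table[column] = pd.Categorical(
                table[column],
                categories=[lv for lv in levels if lv in set(map(str, table[column]))],
            )
    return table


@dataclass
class FittedCandidate:
    spec: CandidateModelSpec
    result: object | None
    family: str
    ok: bool
    message: str = ""

    @property
    def k(self) -> int:
        """Estimated parameters: mean parameters, + residual variance if Gaussian."""
        n_mean = len(self.result.params)
        return n_mean + (1 if self.family == "gaussian" else 0)

    @property
    def loglik(self) -> float:
        return float(self.result.llf)

    def r_squared(self) -> float:
        if self.family == "gaussian":
            return float(getattr(self.result, "rsquared", np.nan))
        null_dev = getattr(self.result, "null_deviance", None)
        if not null_dev:
            return np.nan
        return 1.0 - float(self.result.deviance) / float(null_dev)

    def overdispersion(self) -> float | None:
        """Pearson chi-square / residual df for count models, else None."""
        if self.family != "poisson" or not hasattr(self.result, "pearson_chi2"):
            return None
        return float(self.result.pearson_chi2 / self.result.df_resid)


def fit_candidates(
    table: pd.DataFrame,
    response: str,
    specs: list[CandidateModelSpec] | None = None,
) -> list[FittedCandidate]:
    """Fit every candidate to the identical complete-case row set.

    Complete cases are determined by the union of variables across all
    candidates so rankings compare like with like.  Rank-deficient
    candidates (a design absent from a placement, say) are flagged
    ``ok=False`` and excluded from ranking with a warning rather than
    aborting the set.
    """
    if response not in RESPONSES:
        raise ValueError(f"unknown response {response!r}; one of {sorted(RESPONSES)}")
    specs = specs if specs is not None else build_candidate_set()
    _lhs, family = RESPONSES[response]
    if family == "poisson" and "forest" in set(table["placement"].astype(str)):
        raise ValueError(
            "forest placements must be removed before fitting the "
            "overheating count model (see filter_for_overheating_model)"
        )
    variables = set().union(*(s.variables for s in specs)) | {response}
    data = prepare_factors(table.dropna(subset=sorted(variables)))

    fits: list[FittedCandidate] = []
    for spec in specs:
        formula = spec.formula(response)
        try:
            if family == "gaussian":
                model = smf.ols(formula, data=data)
            else:
                model = smf.glm(formula, data=data, family=sm.families.Poisson())
            exog = model.exog if family == "gaussian" else model.exog
            if np.linalg.matrix_rank(exog) < exog.shape[1]:
                raise np.linalg.LinAlgError("design matrix is rank deficient")
            result = model.fit()
            if not np.all(np.isfinite(result.bse)):
                raise np.linalg.LinAlgError("non-finite standard errors")
            fits.append(FittedCandidate(spec=spec, result=result, family=family, ok=True))
        except (np.linalg.LinAlgError, patsy.PatsyError, ValueError) as exc:
            warnings.warn(
                f"candidate {spec.name} not estimable and excluded from "
                f"ranking: {exc}",
                stacklevel=2,
            )
            fits.append(
                FittedCandidate(spec=spec, result=None, family=family, ok=False,
                                message=str(exc))
            )
    return fits


def aicc(loglik: float, k: int, n: int) -> float:
    """AICc = -2 loglik + 2k + 2k(k+1)/(n - k - 1)."""
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined: n={n} too small for k={k}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)


def aicc_rank(fits: list[FittedCandidate], n_obs: int | None = None) -> pd.DataFrame:
    """Rank estimable candidates by AICc.

    Returns a DataFrame (best first) with columns ``name, k, loglik,
    aicc, delta, weight, r_squared, overdispersion``; Akaike weights sum
    to one over the estimable set.
    """
    usable = [f for f in fits if f.ok]
    if not usable:
        raise ValueError("no estimable candidates to rank")
    if n_obs is None:
        n_obs = int(usable[0].result.nobs)
    if any(int(f.result.nobs) != n_obs for f in usable):
        raise ValueError("candidates were not fit to the same rows")
    rows = [
        {
            "name": f.spec.name,
            "k": f.k,
            "loglik": f.loglik,
            "aicc": aicc(f.loglik, f.k, n_obs),
            "r_squared": f.r_squared(),
            "overdispersion": f.overdispersion(),
        }
        for f in usable
    ]
    table = pd.DataFrame(rows).sort_values("aicc", kind="mergesort").reset_index(drop=True)
    table["delta"] = table["aicc"] - table["aicc"].iloc[0]
    rel = np.exp(-0.5 * table["delta"])
    table["weight"] = rel / rel.sum()
    return table[["name", "k", "loglik", "aicc", "delta", "weight",
                  "r_squared", "overdispersion"]]


@dataclass
class ModelSelectionResult:
    """Ranking plus confidence-set averaged inference for one response."""

    response: str
    ranking: pd.DataFrame
    competing: list[str]          # models with delta <= 2
    confidence_set: list[str]     # 90% cumulative-weight set
    averaged: pd.DataFrame        # term, estimate, se, ci_low, ci_high, informative
    ci_level: float
    fits: dict[str, FittedCandidate] = field(repr=False, default_factory=dict)


def confidence_set_average(
    ranking: pd.DataFrame,
    fits: list[FittedCandidate],
    level: float = 0.90,
    ci_level: float = 0.85,
    method: str = "full",
    response: str = "",
) -> ModelSelectionResult:
    """Average coefficients over the confidence set with Akaike weights.

    The confidence set is the smallest prefix of the weight-ordered
    ranking whose cumulative weight reaches ``level``.  Under ``full``
    averaging a model lacking a term contributes a structural zero with
    zero variance; ``conditional`` averaging renormalizes over the models
    containing the term.  Standard errors are unconditional
    (sqrt of within-model variance plus between-model spread), and the
    85% Wald interval on the link scale flags informative parameters.
    """
    if method not in ("full", "conditional"):
        raise ValueError("method must be 'full' or 'conditional'")
    by_weight = ranking.sort_values("weight", ascending=False, kind="mergesort")
    cum = by_weight["weight"].cumsum()
    n_keep = int(np.searchsorted(cum.to_numpy(), level) + 1)
    n_keep = min(n_keep, len(by_weight))
    conf_names = by_weight["name"].iloc[:n_keep].tolist()
    competing = ranking.loc[ranking["delta"] <= 2.0, "name"].tolist()

    fit_by_name = {f.spec.name: f for f in fits if f.ok}
    weights = by_weight.set_index("name")["weight"].iloc[:n_keep]
    weights = weights / weights.sum()

    terms: list[str] = []
    for name in conf_names:
        for term in fit_by_name[name].result.params.index:
            if term not in terms:
                terms.append(term)

    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    rows = []
    for term in terms:
        est_parts, se_parts, w_parts = [], [], []
        for name in conf_names:
            params = fit_by_name[name].result.params
            bse = fit_by_name[name].result.bse
            w = float(weights.loc[name])
            if term in params.index:
                est_parts.append(float(params[term]))
                se_parts.append(float(bse[term]))
                w_parts.append(w)
            elif method == "full":
                est_parts.append(0.0)
                se_parts.append(0.0)
                w_parts.append(w)
        w_arr = np.array(w_parts)
        if method == "conditional":
            w_arr = w_arr / w_arr.sum()
        est_arr, se_arr = np.array(est_parts), np.array(se_parts)
        estimate = float(w_arr @ est_arr)
        se = float(w_arr @ np.sqrt(se_arr**2 + (est_arr - estimate) ** 2))
        lo, hi = estimate - z * se, estimate + z * se
        rows.append(
            {
                "term": term,
                "estimate": estimate,
                "se": se,
                "ci_low": lo,
                "ci_high": hi,
                "informative": bool(lo > 0.0 or hi < 0.0),
            }
        )
    averaged = pd.DataFrame(rows)
    return ModelSelectionResult(
        response=response,
        ranking=ranking,
        competing=competing,
        confidence_set=conf_names,
        averaged=averaged,
        ci_level=ci_level,
        fits=fit_by_name,
    )


def vif_screen(table: pd.DataFrame, predictors: list[str]) -> pd.DataFrame:
    """Variance inflation factors for the main-effect predictors.

    Each predictor column of the dummy-coded main-effects design matrix
    is regressed on all the others; VIF_j = 1 / (1 - R^2_j).  Perfect
    collinearity is reported as infinite and flagged.  A single predictor
    has VIF 1 by convention.
    """
    if not predictors:
        raise ValueError("at least one predictor required")
    rhs = " + ".join(predictors)
    frame = patsy.dmatrix(rhs, prepare_factors(table), return_type="dataframe")
    X, names = np.asarray(frame), frame.columns
    rows = []
    for j, name in enumerate(names):
        if name == "Intercept":
            continue
        if X.shape[1] <= 2:  # intercept + single column
            rows.append({"predictor": name, "vif": 1.0, "collinear": False})
            continue
        others = np.delete(X, j, axis=1)
        y = X[:, j]
        beta, _res, rank, _sv = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ beta
        ss_tot = float(((y - y.mean()) ** 2).sum())
        ss_res = float((resid**2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        if r2 >= 1.0 - 1e-12:
            rows.append({"predictor": name, "vif": np.inf, "collinear": True})
        else:
            rows.append({"predictor": name, "vif": 1.0 / (1.0 - r2), "collinear": False})
    return pd.DataFrame(rows)


def predict_means(
    fit: FittedCandidate,
    data: pd.DataFrame,
    factor: str,
    backtransform_log: bool = False,
) -> pd.DataFrame:
    """Predicted marginal means per level of ``factor``.

    Predictions are averaged over a balanced reference grid: every level
    of the other factor crossed with every level of ``factor``, numeric
    covariates held at their means (the standard estimated-marginal-means
    construction).  Poisson predictions are returned on the response
    (count) scale.  For log-transformed Gaussian responses, set
    ``backtransform_log`` to also report the exponentiated mean, with and
    without the half-variance lognormal bias correction.
    """
    used = fit.spec.variables
    factors = [c for c in ("design", "placement") if c in used]
    numerics = [c for c in ("total_bats", "max_temp", "max_wind") if c in used]
    if factor not in factors:
        if factor not in ("design", "placement"):
            raise ValueError(f"unknown factor {factor!r}")
        factors = factors + [factor]  # intercept-only model: grand mean per level

    levels = {f: list(pd.Categorical(data[f]).categories) for f in factors}
    grid = pd.DataFrame(
        [
            dict(zip(levels.keys(), combo))
            for combo in _cartesian([levels[f] for f in factors])
        ]
    )
    for col in numerics:
        grid[col] = float(data[col].mean())
    for f in factors:
        observed = set(data[f].astype(str))
        missing = set(map(str, grid[f])) - observed
        if missing and f in used:
            raise ValueError(f"levels {sorted(missing)} absent from fitted data")
    grid = prepare_factors(grid) if {"design", "placement"} & set(grid) else grid
    pred = np.asarray(fit.result.predict(grid))  # GLM predict: response scale
    grid = grid.assign(_pred=pred)
    out = grid.groupby(factor, observed=True)["_pred"].mean().rename("mean").reset_index()
    if backtransform_log:
        if fit.family != "gaussian":
            raise ValueError("backtransform_log applies to log-Gaussian fits only")
        sigma2 = float(fit.result.mse_resid)
        out["mean_backtransformed"] = np.exp(out["mean"])
        out["mean_backtransformed_biascorr"] = np.exp(out["mean"] + sigma2 / 2.0)
    return out


def _cartesian(level_lists: list[list]) -> list[tuple]:
    import itertools

    return list(itertools.product(*level_lists))


def select_models(
    table: pd.DataFrame,
    response: str,
    level: float = 0.90,
    ci_level: float = 0.85,
    method: str = "full",
) -> ModelSelectionResult:
    """End-to-end selection: fit the 14 candidates, rank, average, flag."""
    fits = fit_candidates(table, response)
    ranking = aicc_rank(fits)
    return confidence_set_average(
        ranking, fits, level=level, ci_level=ci_level, method=method, response=response
    )
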