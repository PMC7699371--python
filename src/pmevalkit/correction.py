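"""Mixed-effects correction models and three-criterion variable selection.

The correction model predicts the (transformed) reference concentration from
the (transformed) monitor output. Every evaluation-variable effect enters as
a slope on the monitor predictor x:

    y = b0 + b1 x + sum_f  beta_f (x * code_f)          fixed slope terms
           + sum_r  u_{r, level} * x,  u ~ N(0, tau_r^2)  random slope terms

Fixed slope terms: session drift (hours), temperature (centred at 20 degC),
relative humidity (centred at 50%), exposure pattern (1 = transient) and
power supply (1 = battery). Random slope terms: per-unit and per-material
deviations of the base slope, with no random intercept. Units and materials
are modelled as random because the fielded population of devices and
workplace aerosols is sampled, not enumerated.

Estimation is maximum likelihood throughout (not REML) so that
likelihood-ratio ANOVA and AIC comparisons between nested fixed/random
structures are valid. Each candidate variable is judged by three criteria
against the model without it: LRT p < 0.05, a decrease in AIC, and a smaller
mean absolute error on the back-transformed (ug/m^3) scale. Only variables
passing all three enter the final model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
import statsmodels.formula.api as smf

from .screening import TransformChoice

__all__ = [
    "TERM_ROLES",
    "PRIORITY_ORDER",
    "ModelSpec",
    "VariableTestResult",
    "MixedEffectsCorrection",
    "fit_model",
    "test_variable",
    "build_final_model",
    "predict_concentration",
    "run_variable_selection",
    "prepare_model_frame",
]

#: Whether each evaluation variable enters as a fixed or a random slope.
TERM_ROLES: dict[str, str] = {
    "unit": "random",
    "material": "random",
    "drift": "fixed",
    "temperature": "fixed",
    "humidity": "fixed",
    "pattern": "fixed",
    "power": "fixed",
}

#: Testing order: structural terms (device, drift, material) first; once
#: passed they are carried as corrections in the remaining tests.
PRIORITY_ORDER = ("unit", "drift", "material", "temperature", "humidity", "pattern", "power")
_STRUCTURAL = frozenset({"unit", "drift", "material"})

#: How each fixed variable is coded in the model frame (column of codes that
#: multiplies the monitor predictor x).
_FIXED_CODES = {
    "drift": ("session_time", lambda df: df["session_time"].astype(float)),
    "temperature": ("temp_c", lambda df: df["temperature"].astype(float) - 20.0),
    "humidity": ("rh_c", lambda df: df["relative_humidity"].astype(float) - 50.0),
    "pattern": ("pattern_ind", lambda df: (df["pattern"] == "transient").astype(float)),
    "power": ("power_ind", lambda df: (df["power"] == "battery").astype(float)),
}
_RANDOM_GROUPS = {"unit": "unit_id", "material": "material"}


@dataclass(frozen=True)
class ModelSpec:
    """Structure of a correction model: which slope terms accompany x."""

    fixed_slope_terms: frozenset = frozenset()
    random_slope_terms: frozenset = frozenset()
    transform: TransformChoice = field(default_factory=lambda: TransformChoice("log10"))

    def __post_init__(self) -> None:
        object.__setattr__(self, "fixed_slope_terms", frozenset(self.fixed_slope_terms))
        object.__setattr__(self, "random_slope_terms", frozenset(self.random_slope_terms))
        bad = (self.fixed_slope_terms | self.random_slope_terms) - set(TERM_ROLES)
        if bad:
            raise ValueError(f"unknown terms {sorted(bad)}")
        wrong = {t for t in self.fixed_slope_terms if TERM_ROLES[t] != "fixed"} | {
            t for t in self.random_slope_terms if TERM_ROLES[t] != "random"
        }
        if wrong:
            raise ValueError(f"terms assigned to the wrong effect kind: {sorted(wrong)}")

    def with_variable(self, variable: str) -> "ModelSpec":
        if TERM_ROLES[variable] == "fixed":
            return ModelSpec(
                self.fixed_slope_terms | {variable}, self.random_slope_terms, self.transform
            )
        return ModelSpec(
            self.fixed_slope_terms, self.random_slope_terms | {variable}, self.transform
        )


@dataclass(frozen=True)
class VariableTestResult:
    """Outcome of the three-criterion test for one evaluation variable."""

    variable: str
    anova_p: float
    delta_aic: float  # AIC(with) - AIC(without); negative favours inclusion
    mae_without: float  # ug/m^3, back-transformed scale
    mae_with: float
    passed: bool
    note: str = ""

    @property
    def mae_fold(self) -> float:
        """Fold improvement in MAE from including the variable."""
        return self.mae_without / self.mae_with


def prepare_model_frame(data: pd.DataFrame, transform: TransformChoice) -> pd.DataFrame:
    """Add transformed response/predictor and coded covariates to a long table.

    Expects columns ``reference`` and ``monitor`` (ug/m^3) plus whatever
    condition columns the model terms need (unit_id, material, temperature,
    relative_humidity, power, pattern, session_time).
    """
    df = data.copy()
    df["__y"] = transform.transform(df["reference"].to_numpy())
    df["__x"] = transform.transform(df["monitor"].to_numpy())
    for term, (col, fn) in _FIXED_CODES.items():
        if _FIXED_CODES[term][0] not in df.columns:
            try:
                df[col] = fn(df)
            except KeyError:
                pass  # condition column absent; term cannot be used
    df = df[np.isfinite(df["__y"]) & np.isfinite(df["__x"])]
    return df


class MixedEffectsCorrection(RegressorMixin, BaseEstimator):
    """Correction model mapping monitor output to reference concentration.

    sklearn-style estimator. ``fit`` takes a long-format DataFrame of
    condition columns plus a ``monitor`` column, and the raw reference
    concentrations as ``y``; both sides are transformed internally with
    ``transform`` (a TransformChoice or one of its names). With no random
    terms the fit is ordinary least squares; otherwise a linear mixed model
    estimated by ML, with crossed random slopes expressed as variance
    components within a single enclosing group.

    Fitted attributes: ``coefficients_`` (fixed effects), ``random_slopes_``
    (term -> level -> slope deviation), ``variance_components_``,
    ``loglike_``, ``aic_``, ``n_params_``, ``fit_log_``.
    """

    def __init__(
        self,
        fixed_slope_terms: Sequence[str] = (),
        random_slope_terms: Sequence[str] = (),
        transform: TransformChoice | str = "log10",
    ):
        self.fixed_slope_terms = fixed_slope_terms
        self.random_slope_terms = random_slope_terms
        self.transform = transform

    # -- helpers ----------------------------------------------------------

    def _spec(self) -> ModelSpec:
        tr = self.transform
        if isinstance(tr, str):
            tr = TransformChoice(tr)
        return ModelSpec(frozenset(self.fixed_slope_terms),
                         frozenset(self.random_slope_terms), tr)

    def _formula(self, spec: ModelSpec) -> str:
        rhs = ["__x"]
        for term in sorted(spec.fixed_slope_terms):
            rhs.append(f"__x:{_FIXED_CODES[term][0]}")
        return "__y ~ " + " + ".join(rhs)

    # -- estimator API ----------------------------------------------------

    def fit(self, X: pd.DataFrame, y=None):
        spec = self._spec()
        data = X.copy()
        if y is not None:
            data["reference"] = np.asarray(y, float)
        if "reference" not in data.columns or "monitor" not in data.columns:
            raise ValueError("fit needs 'monitor' and 'reference' columns (or y)")
        df = prepare_model_frame(data, spec.transform)
        if df.empty:
            raise ValueError("no finite rows after transformation")
        log: list[str] = []
        # a slope term whose code is constant in this subset is inestimable
        # (all-zero or collinear with the base slope); drop it here
        estimable = set()
        for term in spec.fixed_slope_terms:
            col = _FIXED_CODES[term][0]
            if col in df.columns and df[col].nunique() > 1:
                estimable.add(term)
            else:
                log.append(f"fixed slope term '{term}' constant in data; dropped")
        spec = ModelSpec(frozenset(estimable), spec.random_slope_terms, spec.transform)
        for term in sorted(spec.random_slope_terms):
            gcol = _RANDOM_GROUPS[term]
            if gcol not in df.columns or df[gcol].nunique() < 2:
                spec = ModelSpec(
                    spec.fixed_slope_terms, spec.random_slope_terms - {term}, spec.transform
                )
                log.append(f"random slope term '{term}' has < 2 levels; dropped")
        formula = self._formula(spec)

        random_terms = sorted(spec.random_slope_terms)
        while True:
            if not random_terms:
                res = smf.ols(formula, df).fit()
                n_params = res.df_model + 2  # coefficients + residual scale
                break
            vc = {t: f"0 + C({_RANDOM_GROUPS[t]}):__x" for t in random_terms}
            df["_one"] = 1
            res = None
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = smf.mixedlm(formula, df, groups="_one", re_formula="0", vc_formula=vc)
                # bfgs occasionally stalls near a variance boundary; fall back
                # to derivative-free optimizers before declaring the term bad
                for method in ("bfgs", "powell", "cg", "nm"):
                    try:
                        cand = model.fit(reml=False, method=method)
                    except (np.linalg.LinAlgError, ValueError):
                        continue
                    if cand.converged:
                        res = cand
                        if method != "bfgs":
                            log.append(f"mixed fit used fallback optimizer '{method}'")
                        break
            if res is None:
                dropped = random_terms.pop()  # drop least-prioritized term
                log.append(f"singular/non-convergent random term '{dropped}' removed")
                continue
            n_params = len(res.fe_params) + len(random_terms) + 1
            break

        self.result_ = res
        self.spec_ = ModelSpec(spec.fixed_slope_terms, frozenset(random_terms), spec.transform)
        self.loglike_ = float(res.llf)
        self.n_params_ = int(n_params)
        # uniform AIC across the OLS / mixed boundary: -2 llf + 2 k with
        # k = fixed coefficients + variance components + residual scale
        self.aic_ = -2.0 * self.loglike_ + 2.0 * self.n_params_
        params = res.params if not random_terms else res.fe_params
        self.coefficients_ = {name: float(v) for name, v in params.items()}
        self.variance_components_ = {}
        self.random_slopes_: dict[str, dict[str, float]] = {}
        if random_terms:
            vcomp = res.vcomp if hasattr(res, "vcomp") else []
            for t, v in zip(random_terms, vcomp):
                self.variance_components_[t] = float(max(v, 0.0))
            re = res.random_effects
            blups = re[next(iter(re))]
            for t in random_terms:
                group_col = _RANDOM_GROUPS[t]
                levels: dict[str, float] = {}
                prefix = f"{t}[C({group_col})["
                for name, val in blups.items():
                    if name.startswith(prefix):
                        level = name[len(prefix):].split("]")[0]
                        levels[level] = float(val)
                self.random_slopes_[t] = levels
        self.fit_log_ = log
        self.n_obs_ = int(df.shape[0])
        return self

    def predict_transformed(self, X: pd.DataFrame) -> np.ndarray:
        """Point prediction on the transformed scale.

        Unseen random-effect levels get the population-level (zero) slope
        deviation; the affected rows are flagged in ``unseen_levels_`` and a
        warning is issued.
        """
        if not hasattr(self, "result_"):
            raise AttributeError("model is not fitted")
        spec = self.spec_
        df = prepare_model_frame(
            X.assign(reference=1.0) if "reference" not in X.columns else X, spec.transform
        )
        x = df["__x"].to_numpy()
        slope = np.full(x.size, self.coefficients_["__x"])
        for term in spec.fixed_slope_terms:
            col = _FIXED_CODES[term][0]
            slope += self.coefficients_[f"__x:{col}"] * df[col].to_numpy(float)
        flags = np.zeros(x.size, bool)
        for term in spec.random_slope_terms:
            levels = df[_RANDOM_GROUPS[term]].astype(str)
            dev = self.random_slopes_.get(term, {})
            slope += levels.map(dev).fillna(0.0).to_numpy(float)
            flags |= ~levels.isin(dev).to_numpy()
        self.unseen_levels_ = flags
        if flags.any():
            warnings.warn(
                f"{int(flags.sum())} predictions used population-level random effects "
                "(unseen group levels)",
                stacklevel=2,
            )
        return self.coefficients_.get("Intercept", 0.0) + slope * x

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Back-transformed point prediction in ug/m^3 (no smearing correction)."""
        spec = self.spec_
        return np.asarray(spec.transform.inverse(self.predict_transformed(X)), float)

    def mae(self, X: pd.DataFrame, y=None) -> float:
        """Mean absolute error on the back-transformed (ug/m^3) scale."""
        ref = np.asarray(X["reference"] if y is None else y, float)
        pred = self.predict(X)
        return float(np.mean(np.abs(pred - ref)))


def fit_model(data: pd.DataFrame, spec: ModelSpec) -> MixedEffectsCorrection:
    """Fit a correction model with the given structure on a long-format table."""
    est = MixedEffectsCorrection(
        fixed_slope_terms=sorted(spec.fixed_slope_terms),
        random_slope_terms=sorted(spec.random_slope_terms),
        transform=spec.transform,
    )
    return est.fit(data)


def test_variable(
    data: pd.DataFrame,
    variable: str,
    baseline: ModelSpec,
    alpha: float = 0.05,
) -> VariableTestResult:
    """Three-criterion comparison of nested models with and without a variable.

    The ANOVA p-value is a likelihood-ratio test between the two ML fits
    (chi-square, 1 df for a fixed slope; for a random slope the 50:50
    chi-square boundary mixture, i.e. half the 1-df tail probability).
    Delta AIC and the back-transformed MAE complete the three criteria.
    """
    if variable not in TERM_ROLES:
        raise ValueError(f"unknown evaluation variable {variable!r}")
    role = TERM_ROLES[variable]
    col = _RANDOM_GROUPS.get(variable) or {
        "drift": "session_time",
        "temperature": "temperature",
        "humidity": "relative_humidity",
        "pattern": "pattern",
        "power": "power",
    }[variable]
    if col in data.columns and data[col].nunique() < 2:
        raise ValueError(f"variable {variable!r} is constant in this subset")

    without = fit_model(data, baseline)
    with_ = fit_model(data, baseline.with_variable(variable))

    lr = max(2.0 * (with_.loglike_ - without.loglike_), 0.0)
    if role == "fixed":
        p = float(stats.chi2.sf(lr, df=1))
        note = ""
    else:
        p = float(0.5 * stats.chi2.sf(lr, df=1)) if lr > 0 else 1.0
        note = "boundary-corrected LRT (50:50 chi-square mixture) for random slope"

    delta_aic = with_.aic_ - without.aic_
    mae_without = without.mae(data)
    mae_with = with_.mae(data)
    passed = (p < alpha) and (delta_aic < 0) and (mae_with < mae_without)
    return VariableTestResult(variable, p, delta_aic, mae_without, mae_with, passed, note)


def run_variable_selection(
    data_by_variable: Mapping[str, pd.DataFrame],
    transform: TransformChoice,
    alpha: float = 0.05,
    order: Sequence[str] = PRIORITY_ORDER,
) -> tuple[list[VariableTestResult], ModelSpec]:
    """Test each evaluation variable in priority order with carry-forward.

    Structural terms (unit, drift, material) that pass are added to the
    baseline used for the remaining variables, so later tests are corrected
    for them. Returns the test table and the final ModelSpec of passed terms.
    """
    baseline = ModelSpec(transform=transform)
    results = []
    passed: list[str] = []
    for variable in order:
        if variable not in data_by_variable:
            continue
        try:
            res = test_variable(data_by_variable[variable], variable, baseline, alpha)
        except ValueError as exc:
            res = VariableTestResult(variable, np.nan, np.nan, np.nan, np.nan, False, str(exc))
        results.append(res)
        if res.passed:
            passed.append(variable)
            if variable in _STRUCTURAL:
                baseline = baseline.with_variable(variable)
    final_spec = ModelSpec(transform=transform)
    for v in passed:
        final_spec = final_spec.with_variable(v)
    return results, final_spec


def build_final_model(
    all_experiments: pd.DataFrame,
    passed_variables: Sequence[str],
    transform: TransformChoice,
) -> MixedEffectsCorrection:
    """Fit the final correction model (all passed terms) on pooled experiments."""
    spec = ModelSpec(transform=transform)
    for v in passed_variables:
        spec = spec.with_variable(v)
    return fit_model(all_experiments, spec)


def predict_concentration(
    model: MixedEffectsCorrection,
    monitor_reading,
    conditions: Mapping,
    cutoff: float | None = None,
) -> np.ndarray:
    """Predict the reference concentration for monitor reading(s) under conditions.

    ``conditions`` supplies the model's term columns (unit_id, material,
    temperature, relative_humidity, power, pattern, session_time as needed).
    Readings above ``cutoff`` are rejected: screening removed that regime, so
    the model is not valid there.
    """
    readings = np.atleast_1d(np.asarray(monitor_reading, float))
    if cutoff is not None and np.any(readings > cutoff):
        raise ValueError(
            "monitor reading above the screening cutoff; truncate the series first"
        )
    frame = pd.DataFrame({"monitor": readings})
    for key, val in conditions.items():
        frame[key] = val
    return model.predict(frame)
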