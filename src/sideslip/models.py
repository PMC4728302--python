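"""Regression models of sideslip and roll dynamics.

The core objects follow the statsmodels convention: a :class:`ManeuverModel`
is built from a stroke table (one row per halfstroke) and a
:class:`ModelSpec`; ``fit()`` returns a :class:`ManeuverResults` carrying
coefficients, standard errors, p-values, log-likelihood, AICc and r^2, with
a ``summary()`` table.

The a priori physics is a constant dorsally-directed force of one body
weight that the moth reorients by rolling:

    y_ddot = K_yb * g sin(beta) + K_yy * y_dot
             + K_yP * sgn(beta) * phi_p_bar_c + K_yT * sgn(beta) * theta_p_bar_c
    z_ddot = K_zb * g (1 - cos(beta)) + K_zz * z_dot
             + K_zP * phi_p_bar_c + K_zT * theta_p_bar_c
    beta_dot = K_ba * alpha_LR + K_bP * phi_p_LR + K_bT * theta_p_LR
               + K_by * y_dot            (no intercept)

with g = 980.665 cm s^-2 and +z down, so both roll coefficients are
expected near +1, the velocity coefficients negative (passive damping), and
the roll-velocity model forced through zero (a stably hovering moth has no
asymmetry and no damping input).  Model selection uses a cascade of AICc
comparisons ordered by full-model significance, followed by random-intercept
(REML) mixed-model variants.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .simulate import GRAVITY_CM_S2

__all__ = [
    "ModelSpec",
    "ManeuverModel",
    "ManeuverResults",
    "EQN_LATERAL",
    "EQN_VERTICAL",
    "EQN_ROLL",
    "CANDIDATE_EXTRAS",
    "design_matrix",
    "fit_linear",
    "fit_mixed_random_intercept",
    "aicc",
    "cascade_select",
    "contribution_table",
    "damping_time_constants",
    "updown_binned_ttests",
    "roll_acceleration_check",
]

RESPONSES = ("y_ddot", "z_ddot", "beta_dot", "beta_ddot")


def _col(table, name):
    if name not in table.columns:
        raise KeyError(f"stroke table lacks required column '{name}'")
    return table[name].to_numpy(dtype=float)


def _alpha_col(table, name):
    """Wing-pitch columns, masking halfstrokes whose alpha came from the
    lower-quality missing-hindwing-tip fallback (those rows are kept in the
    table but carry no usable chord orientation)."""
    x = _col(table, name)
    if "alpha_quality_L" in table.columns and "alpha_quality_R" in table.columns:
        bad = ((table["alpha_quality_L"] != "chord")
               | (table["alpha_quality_R"] != "chord")).to_numpy()
        x = np.where(bad, np.nan, x)
    return x


# term name -> builder(table, g) for each predictor the models may use
TERM_BUILDERS = {
    "g_sin_beta": lambda T, g: g * np.sin(np.deg2rad(_col(T, "beta"))),
    "g_one_minus_cos_beta": lambda T, g: g * (1.0 - np.cos(np.deg2rad(_col(T, "beta")))),
    "y_dot": lambda T, g: _col(T, "y_dot"),
    "z_dot": lambda T, g: _col(T, "z_dot"),
    "sgn_phi_p_bar_c": lambda T, g: _col(T, "sgn_beta") * _col(T, "phi_p_bar_c"),
    "sgn_theta_p_bar_c": lambda T, g: _col(T, "sgn_beta") * _col(T, "theta_p_bar_c"),
    "phi_p_bar_c": lambda T, g: _col(T, "phi_p_bar_c"),
    "theta_p_bar_c": lambda T, g: _col(T, "theta_p_bar_c"),
    "alpha_LR": lambda T, g: _alpha_col(T, "alpha_LR"),
    "phi_p_LR": lambda T, g: _col(T, "phi_p_LR"),
    "theta_p_LR": lambda T, g: _col(T, "theta_p_LR"),
    "phi_LR": lambda T, g: _col(T, "phi_LR"),
    "theta_LR": lambda T, g: _col(T, "theta_LR"),
    "drag_i": lambda T, g: _col(T, "drag_i"),
    "alpha_bar_c": lambda T, g: _alpha_col(T, "alpha_bar_c"),
    "psi_p_bar_c": lambda T, g: _col(T, "psi_p_bar_c"),
    "psi_p_LR": lambda T, g: _col(T, "psi_p_LR"),
}


@dataclass(frozen=True)
class ModelSpec:
    """Which response, predictors and structure a maneuver model uses.

    ``updown_split`` names terms whose coefficient is estimated separately
    for down- and upstrokes.  Roll-velocity (and roll-acceleration) models
    never carry an intercept.
    """

    response: str
    terms: tuple
    intercept: bool = False
    group: str | None = None            # None, 'moth_id' or 'trial_id'
    updown_split: frozenset = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "terms", tuple(self.terms))
        object.__setattr__(self, "updown_split", frozenset(self.updown_split))
        if self.response not in RESPONSES:
            raise ValueError(f"response must be one of {RESPONSES}")
        unknown = [t for t in self.terms if t not in TERM_BUILDERS]
        if unknown:
            raise ValueError(
                f"unknown terms {unknown}; valid terms: {sorted(TERM_BUILDERS)}")
        if self.response in ("beta_dot", "beta_ddot") and self.intercept:
            raise ValueError("roll models are fitted without an intercept")
        bad = self.updown_split - set(self.terms)
        if bad:
            raise ValueError(f"updown_split names absent terms: {sorted(bad)}")

    def describe(self) -> str:
        parts = list(self.terms)
        if self.intercept:
            parts = ["1"] + parts
        s = f"{self.response} ~ {' + '.join(parts) if parts else '0'}"
        if self.group:
            s += f" + (1|{self.group})"
        if self.updown_split:
            s += f" [up/down split: {', '.join(sorted(self.updown_split))}]"
        return s


EQN_LATERAL = ModelSpec(
    response="y_ddot",
    terms=("g_sin_beta", "y_dot", "sgn_phi_p_bar_c", "sgn_theta_p_bar_c"),
    intercept=False)

EQN_VERTICAL = ModelSpec(
    response="z_ddot",
    terms=("g_one_minus_cos_beta", "z_dot", "phi_p_bar_c", "theta_p_bar_c"),
    intercept=False)

EQN_ROLL = ModelSpec(
    response="beta_dot",
    terms=("alpha_LR", "phi_p_LR", "theta_p_LR", "y_dot"),
    intercept=False)

# additionally attempted predictors kept in the pool for full-model p-values
CANDIDATE_EXTRAS = ("drag_i", "alpha_bar_c", "phi_LR", "theta_LR")


def design_matrix(table: pd.DataFrame, spec: ModelSpec, g: float = GRAVITY_CM_S2
                  ) -> tuple[pd.Series, pd.DataFrame, int]:
    """Response vector and predictor matrix for a spec.

    Rows with any missing value in the response or predictors are dropped;
    the number dropped is returned.  Split terms produce ``term__down`` and
    ``term__up`` columns.
    """
    y = pd.Series(_col(table, spec.response), name=spec.response)
    cols = {}
    for t in spec.terms:
        x = TERM_BUILDERS[t](table, g)
        if t in spec.updown_split:
            is_down = (table["stroke"] == "down").to_numpy()
            cols[f"{t}__down"] = np.where(is_down, x, 0.0)
            cols[f"{t}__up"] = np.where(is_down, 0.0, x)
        else:
            cols[t] = x
    X = pd.DataFrame(cols, index=table.index)
    if spec.intercept:
        X.insert(0, "intercept", 1.0)
    mask = np.isfinite(y.to_numpy())
    if len(X.columns):
        mask &= np.isfinite(X.to_numpy()).all(axis=1)
    n_dropped = int((~mask).sum())
    return y[mask].reset_index(drop=True), X[mask].reset_index(drop=True), n_dropped


def aicc(llf: float, k: int, n: int) -> float:
    """Corrected Akaike information criterion.

    AICc = -2 llf + 2k + 2k(k+1)/(n-k-1), with k counting every estimated
    parameter including variance components.  Requires n - k - 1 > 0.
    """
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined for n={n}, k={k} (need n - k - 1 > 0)")
    return -2.0 * llf + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)


class ManeuverResults:
    """Fitted maneuver model: coefficients, uncertainty and fit quality.

    Attributes
    ----------
    params, bse, tvalues, pvalues : pd.Series indexed by predictor name
    llf : Gaussian log-likelihood (REML for mixed models)
    k_params : parameters counted in AICc (coefficients + variances)
    aicc : corrected AIC
    r_squared : adjusted r^2 (linear) or conditional r^2 (mixed)
    group_var : random-intercept variance (mixed models, else None)
    singular : True when the random-intercept variance collapsed to ~0
    """

    def __init__(self, model, params, bse, llf, nobs, k_params, resid,
                 fittedvalues, r_squared, r2_kind, group_var=None,
                 singular=False, converged=True, scale=None):
        self.model = model
        self.spec = model.spec
        self.params = params
        self.bse = bse
        with np.errstate(divide="ignore", invalid="ignore"):
            self.tvalues = params / bse
        df = max(nobs - len(params) - 1, 1)
        self.df_resid = df
        self.pvalues = pd.Series(
            2.0 * stats.t.sf(np.abs(self.tvalues), df), index=params.index)
        self.llf = float(llf)
        self.nobs = int(nobs)
        self.k_params = int(k_params)
        try:
            self.aicc = aicc(self.llf, self.k_params, self.nobs)
        except ValueError:
            # too few rows for the small-sample correction
            self.aicc = np.nan
        self.resid = resid
        self.fittedvalues = fittedvalues
        self.r_squared = float(r_squared) if r_squared is not None else np.nan
        self.r2_kind = r2_kind
        self.group_var = group_var
        self.singular = singular
        self.converged = converged
        self.scale = scale

    def summary(self) -> str:
        lines = [
            f"Maneuver model: {self.spec.describe()}",
            f"n = {self.nobs} halfstrokes, k = {self.k_params} parameters",
            f"logLik = {self.llf:.3f}   AICc = {self.aicc:.3f}   "
            f"{self.r2_kind} r^2 = {self.r_squared:.4f}",
        ]
        if self.group_var is not None:
            flag = "  [singular]" if self.singular else ""
            lines.append(f"random intercept ({self.spec.group}) variance = "
                         f"{self.group_var:.4g}{flag}")
        lines.append(f"{'term':<22}{'K':>12}{'SE':>11}{'t':>9}{'p':>11}")
        for name in self.params.index:
            lines.append(
                f"{name:<22}{self.params[name]:>12.5g}{self.bse[name]:>11.4g}"
                f"{self.tvalues[name]:>9.3f}{self.pvalues[name]:>11.3g}")
        return "\n".join(lines)

    def __repr__(self):
        return (f"<ManeuverResults {self.spec.describe()!r} "
                f"n={self.nobs} aicc={self.aicc:.2f}>")


class ManeuverModel:
    """Linear or random-intercept mixed model of one body-state derivative.

    Parameters
    ----------
    table : stroke table (one row per halfstroke)
    spec : ModelSpec
    g : gravitational acceleration used in the roll transforms (cm/s^2)

    ``fit()`` dispatches on ``spec.group``: ordinary least squares when no
    grouping is set, otherwise a Gaussian random-intercept model estimated
    by restricted maximum likelihood (REML).
    """

    def __init__(self, table: pd.DataFrame, spec: ModelSpec,
                 g: float = GRAVITY_CM_S2):
        self.table = table
        self.spec = spec
        self.g = g
        self.endog, self.exog, self.n_dropped = design_matrix(table, spec, g)
        if spec.group is not None:
            if spec.group not in table.columns:
                raise KeyError(f"grouping column '{spec.group}' absent")
            groups = table[spec.group]
            mask = np.isfinite(_col(table, spec.response))
            for t in spec.terms:
                mask &= np.isfinite(TERM_BUILDERS[t](table, g))
            self.groups = groups[mask].reset_index(drop=True)
        else:
            self.groups = None

    @classmethod
    def from_csv(cls, path, spec: ModelSpec, g: float = GRAVITY_CM_S2):
        from .kinematics import read_stroke_table
        return cls(read_stroke_table(path), spec, g=g)

    def fit(self) -> ManeuverResults:
        if len(self.exog.columns) == 0:
            return self._fit_null()
        if self.spec.group is None:
            return self._fit_ols()
        return self._fit_mixed()

    # -- ordinary least squares ------------------------------------------
    def _fit_ols(self) -> ManeuverResults:
        y = self.endog.to_numpy()
        X = self.exog
        n, p = X.shape
        if n <= p:
            raise ValueError(f"too few rows (n={n}) for {p} parameters")
        rank = np.linalg.matrix_rank(X.to_numpy())
        if rank < p:
            corr = np.corrcoef(X.to_numpy(), rowvar=False)
            np.fill_diagonal(corr, 0.0)
            i, j = np.unravel_index(np.nanargmax(np.abs(corr)), corr.shape)
            raise ValueError(
                "design matrix is rank deficient; most collinear columns: "
                f"{X.columns[i]} and {X.columns[j]}")
        res = sm.OLS(y, X).fit()
        return ManeuverResults(
            model=self, params=res.params, bse=res.bse, llf=res.llf, nobs=n,
            k_params=p + 1, resid=res.resid, fittedvalues=res.fittedvalues,
            r_squared=res.rsquared_adj, r2_kind="adjusted",
            scale=float(res.ssr / n))

    # -- empty (null) model ----------------------------------------------
    def _fit_null(self) -> ManeuverResults:
        y = self.endog.to_numpy()
        n = len(y)
        sigma2 = float(np.mean(y ** 2))
        llf = -0.5 * n * (math.log(2.0 * math.pi * sigma2) + 1.0)
        empty = pd.Series(dtype=float)
        return ManeuverResults(
            model=self, params=empty, bse=empty, llf=llf, nobs=n, k_params=1,
            resid=y.copy(), fittedvalues=np.zeros(n),
            r_squared=0.0, r2_kind="adjusted")

    # -- random-intercept mixed model (REML) ------------------------------
    def _fit_mixed(self) -> ManeuverResults:
        y = self.endog.to_numpy()
        X = self.exog
        groups = self.groups
        if groups.nunique() < 2:
            raise ValueError("mixed model needs at least 2 groups")
        if groups.value_counts().min() < 2:
            raise ValueError("every group needs at least 2 rows")
        n, p = X.shape
        singular = False
        converged = True
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            md = sm.MixedLM(y, X, groups=groups)
            try:
                res = md.fit(reml=True, method=["lbfgs", "bfgs"])
            except Exception:
                res = md.fit(reml=True, method="powell")
            for w in caught:
                msg = str(w.message).lower()
                if "singular" in msg or "boundary" in msg:
                    singular = True
                if "converge" in msg and "fail" in msg:
                    converged = False
        cov_re = np.atleast_2d(np.asarray(res.cov_re))
        group_var = float(cov_re[0, 0]) if cov_re.size else 0.0
        if group_var < 1e-8 * max(res.scale, 1e-12):
            singular = True
        params = res.fe_params
        bse = res.bse_fe
        try:
            fitted = np.asarray(res.fittedvalues)
        except (ValueError, np.linalg.LinAlgError):
            # singular random-effect covariance: fall back to fixed effects
            fitted = X.to_numpy() @ params.to_numpy()
        var_fixed = float(np.var(X.to_numpy() @ params.to_numpy()))
        var_resid = float(res.scale)
        denom = var_fixed + group_var + var_resid
        r2_cond = (var_fixed + group_var) / denom if denom > 0 else np.nan
        return ManeuverResults(
            model=self, params=params, bse=bse, llf=res.llf, nobs=n,
            k_params=p + 2, resid=y - fitted, fittedvalues=fitted,
            r_squared=r2_cond, r2_kind="conditional",
            group_var=group_var, singular=singular, converged=converged,
            scale=var_resid)


def fit_linear(table: pd.DataFrame, spec: ModelSpec,
               g: float = GRAVITY_CM_S2) -> ManeuverResults:
    """Ordinary least squares fit of a spec (group ignored)."""
    return ManeuverModel(table, replace(spec, group=None), g=g).fit()


def fit_mixed_random_intercept(table: pd.DataFrame, spec: ModelSpec,
                               group: str = "moth_id",
                               g: float = GRAVITY_CM_S2) -> ManeuverResults:
    """Random-intercept REML fit of a spec with the given grouping."""
    return ManeuverModel(table, replace(spec, group=group), g=g).fit()


# ---------------------------------------------------------------------------
# cascade AICc selection
# ---------------------------------------------------------------------------


def cascade_select(table: pd.DataFrame, response: str, candidate_terms,
                   intercept: bool = False, groups=("moth_id", "trial_id"),
                   try_updown: bool | None = None,
                   g: float = GRAVITY_CM_S2) -> tuple[ModelSpec, list[dict]]:
    """AICc cascade model selection.

    Terms are ordered by their p-value in the full linear model containing
    every candidate (ties broken by larger |t|).  Starting from the null
    model (intercept-only, or empty for zero-intercept responses), each term
    is added in order and kept only if it lowers AICc; after every
    acceptance the model with the lone exclusion of the previously confirmed
    term is re-tested (the cascade's one-step recursion).  Once the linear
    cascade finishes, random-intercept variants of the surviving terms are
    evaluated (and, for roll responses, single-term up/down coefficient
    splits).  Returns the minimum-AICc spec and the full decision trace.
    """
    candidate_terms = list(candidate_terms)
    if len(candidate_terms) < 2:
        raise ValueError("cascade selection needs at least 2 candidate terms")
    if response in ("beta_dot", "beta_ddot"):
        intercept = False
    if try_updown is None:
        try_updown = response in ("beta_dot", "beta_ddot")
    trace = []

    full = fit_linear(table, ModelSpec(response, tuple(candidate_terms),
                                       intercept=intercept), g=g)
    order = sorted(candidate_terms,
                   key=lambda t: (full.pvalues[t], -abs(full.tvalues[t])))
    trace.append({"step": "significance order", "order": order,
                  "pvalues": full.pvalues[order].to_dict()})

    def evaluate(spec):
        try:
            return ManeuverModel(table, spec, g=g).fit()
        except ValueError:
            return None

    current = ModelSpec(response, (), intercept=intercept)
    best = evaluate(current)
    best_aicc = best.aicc
    trace.append({"step": "null", "spec": current.describe(), "aicc": best_aicc})
    prev_confirmed = None
    for term in order:
        cand = replace(current, terms=current.terms + (term,))
        fit = evaluate(cand)
        accepted = fit is not None and fit.aicc < best_aicc
        trace.append({"step": f"add {term}", "spec": cand.describe(),
                      "aicc": fit.aicc if fit else np.nan, "accepted": accepted})
        if accepted:
            current, best, best_aicc = cand, fit, fit.aicc
            # recurse one step: retest with the lone exclusion of the
            # previously confirmed term
            if prev_confirmed is not None and prev_confirmed in current.terms:
                reduced = replace(current, terms=tuple(
                    t for t in current.terms if t != prev_confirmed))
                rfit = evaluate(reduced)
                drop = rfit is not None and rfit.aicc < best_aicc
                trace.append({"step": f"retest without {prev_confirmed}",
                              "spec": reduced.describe(),
                              "aicc": rfit.aicc if rfit else np.nan,
                              "accepted": drop})
                if drop:
                    current, best, best_aicc = reduced, rfit, rfit.aicc
            prev_confirmed = term

    if current.terms:
        for grp in groups or ():
            if grp not in table.columns or table[grp].nunique() < 2:
                continue
            if table[grp].value_counts().min() < 2:
                continue
            cand = replace(current, group=grp)
            fit = evaluate(cand)
            acc = fit is not None and fit.aicc < best_aicc
            trace.append({"step": f"random intercept {grp}",
                          "spec": cand.describe(),
                          "aicc": fit.aicc if fit else np.nan, "accepted": acc})
            if acc:
                current, best, best_aicc = cand, fit, fit.aicc
        if try_updown and "stroke" in table.columns:
            for term in current.terms:
                cand = replace(current, updown_split=frozenset({term}))
                fit = evaluate(cand)
                acc = fit is not None and fit.aicc < best_aicc
                trace.append({"step": f"up/down split {term}",
                              "spec": cand.describe(),
                              "aicc": fit.aicc if fit else np.nan,
                              "accepted": acc})
                if acc:
                    current, best, best_aicc = cand, fit, fit.aicc
    trace.append({"step": "selected", "spec": current.describe(),
                  "aicc": best_aicc})
    return current, trace


# ---------------------------------------------------------------------------
# derived reports
# ---------------------------------------------------------------------------


def contribution_table(results: ManeuverResults) -> pd.Series:
    """Percent contribution of each fitted term.

    contribution_i = 100 |K_i| mean|x_i| / sum_j |K_j| mean|x_j| over the
    model's own design matrix (the intercept column is excluded).
    """
    X = results.model.exog
    terms = [c for c in results.params.index if c != "intercept"]
    if not terms:
        raise ValueError("contribution table needs at least one non-intercept term")
    weights = {t: abs(results.params[t]) * float(np.mean(np.abs(X[t])))
               for t in terms}
    total = sum(weights.values())
    if total <= 0:
        raise ValueError("all contribution weights are zero")
    return pd.Series({t: 100.0 * w / total for t, w in weights.items()},
                     name="percent_contribution")


def damping_time_constants(results: ManeuverResults) -> dict:
    """Damping time constants implied by fitted velocity coefficients.

    Treating the fitted equation as v_dot = K v with the other terms at
    equilibrium, a negative K gives time constant -1/K and half-life
    ln(2)/|K|.  Non-negative coefficients are flagged with non-finite
    results rather than raising.
    """
    vel_term = {"y_ddot": "y_dot", "z_ddot": "z_dot", "beta_dot": "y_dot"}
    out = {}
    term = vel_term.get(results.spec.response)
    names = ([term] if term and term in results.params.index else [])
    names += [t for t in results.params.index
              if t.startswith(f"{term}__")] if term else []
    for name in names:
        K = float(results.params[name])
        if K < 0:
            tau = -1.0 / K
            out[name] = {"K": K, "time_constant_s": tau,
                         "half_life_s": math.log(2.0) * tau, "flagged": False}
        else:
            out[name] = {"K": K, "time_constant_s": np.nan,
                         "half_life_s": np.nan, "flagged": True}
    if not out:
        raise ValueError(
            f"model for {results.spec.response} contains no velocity-damping term")
    return out


def updown_binned_ttests(table: pd.DataFrame,
                         measures=("alpha", "phi_p", "theta_p"),
                         quantile: float = 0.25) -> dict:
    """Compare wing kinematics during high roll velocity with normal flapping.

    Halfstrokes in the bottom ``quantile`` of |roll velocity| are treated as
    normal flapping; the rest as high-roll.  For every measure the wing
    ipsilateral / contralateral to the roll direction is compared against
    the normal-bin baseline (one-sample t-test of the per-halfstroke
    deviation from the baseline mean) and ipsi vs contra directly
    (unpaired two-sample t-test).  Degenerate zero-variance comparisons get
    p = 1 with a warning.
    """
    bd = _col(table, "beta_dot")
    ok = np.isfinite(bd)
    if ok.sum() < 16:
        raise ValueError("need at least 16 halfstrokes with roll velocity")
    thresh = np.quantile(np.abs(bd[ok]), quantile)
    normal = table[ok & (np.abs(bd) <= thresh)]
    high = table[ok & (np.abs(bd) > thresh)]
    if len(normal) < 8 or len(high) < 8:
        raise ValueError("need at least 8 halfstrokes in each roll-velocity bin")

    def side_values(rows, measure, ipsi):
        sign = np.sign(_col(rows, "beta_dot"))
        getter = _alpha_col if measure == "alpha" else _col
        left = getter(rows, f"{measure}_L")
        right = getter(rows, f"{measure}_R")
        # positive roll velocity = rolling right -> right wing ipsilateral
        pick_right = (sign > 0) if ipsi else (sign <= 0)
        return np.where(pick_right, right, left)

    def safe_t1(x):
        x = x[np.isfinite(x)]
        if len(x) < 2 or np.std(x, ddof=1) < 1e-12:
            warnings.warn("degenerate (constant) comparison; p set to 1",
                          RuntimeWarning)
            return {"mean_diff": float(np.mean(x)) if len(x) else np.nan,
                    "t": 0.0, "p": 1.0, "n": len(x)}
        t, p = stats.ttest_1samp(x, 0.0)
        return {"mean_diff": float(np.mean(x)), "t": float(t), "p": float(p),
                "n": len(x)}

    def safe_t2(a, b):
        a, b = a[np.isfinite(a)], b[np.isfinite(b)]
        if len(a) < 2 or len(b) < 2 or (np.std(a, ddof=1) < 1e-12
                                        and np.std(b, ddof=1) < 1e-12):
            warnings.warn("degenerate (constant) comparison; p set to 1",
                          RuntimeWarning)
            return {"mean_diff": float(np.mean(a) - np.mean(b)) if len(a) and len(b)
                    else np.nan, "t": 0.0, "p": 1.0, "n": (len(a), len(b))}
        t, p = stats.ttest_ind(a, b)
        return {"mean_diff": float(np.mean(a) - np.mean(b)), "t": float(t),
                "p": float(p), "n": (len(a), len(b))}

    report = {"n_normal": len(normal), "n_high": len(high),
              "threshold_deg_s": float(thresh)}
    for m in measures:
        getter = _alpha_col if m == "alpha" else _col
        base = np.concatenate([getter(normal, f"{m}_L"), getter(normal, f"{m}_R")])
        base_mean = float(np.nanmean(base))
        ipsi = side_values(high, m, ipsi=True)
        contra = side_values(high, m, ipsi=False)
        report[m] = {
            "normal_mean": base_mean,
            "ipsi_vs_normal": safe_t1(ipsi - base_mean),
            "contra_vs_normal": safe_t1(contra - base_mean),
            "ipsi_vs_contra": safe_t2(ipsi, contra),
        }
    return report


def roll_acceleration_check(table: pd.DataFrame,
                            terms=EQN_ROLL.terms,
                            g: float = GRAVITY_CM_S2) -> dict:
    """Fit roll velocity and roll acceleration to the same asymmetry terms.

    In a heavily damped (first-order) roll system the asymmetries predict
    roll velocity well and roll acceleration poorly; the report puts the two
    fits side by side, plus single-predictor roll-acceleration regressions.
    """
    if "beta_ddot" not in table.columns:
        raise KeyError("stroke table lacks beta_ddot")
    vel = fit_linear(table, ModelSpec("beta_dot", tuple(terms)), g=g)
    acc = fit_linear(table, ModelSpec("beta_ddot", tuple(terms)), g=g)
    singles = {}
    for t in terms:
        f = fit_linear(table, ModelSpec("beta_ddot", (t,)), g=g)
        singles[t] = {"K": float(f.params[t]), "p": float(f.pvalues[t]),
                      "r_squared": f.r_squared}
    return {
        "beta_dot_fit": vel, "beta_ddot_fit": acc,
        "r2_beta_dot": vel.r_squared, "r2_beta_ddot": acc.r_squared,
        "first_order": vel.r_squared > acc.r_squared,
        "beta_ddot_single_fits": singles,
    }
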