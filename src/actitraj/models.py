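"""Developmental trajectory models for day-level movement behaviours.

Minutes outcomes (sedentary, LPA, energetic play, total PA and components)
are modelled with linear mixed models: fixed effects for sex, a restricted
cubic spline (RCS) in age with four knots, the age-spline-by-sex
interaction and adjustment covariates, plus a child-level random intercept
for repeated measures; estimation is REML. Guideline adherence (a
child-wave binary) is modelled with a logistic mixed model estimated by a
Laplace-type (MAP) approximation. Marginal means are model predictions on
an (age, sex) grid with the remaining covariates held at representative
values, with delta-method 95% confidence intervals.

The RCS basis is the Harrell truncated-power parameterisation: for knots
t1 < ... < tk the basis has the linear term plus k-2 nonlinear terms

    h_j(x) = [ (x-t_j)+^3 - (x-t_{k-1})+^3 (t_k-t_j)/(t_k-t_{k-1})
               + (x-t_k)+^3 (t_{k-1}-t_j)/(t_k-t_{k-1}) ] / (t_k-t_1)^2

each continuous through its second derivative and exactly linear outside
the boundary knots. Default knot placement follows the standard 4-knot
quantiles (0.05, 0.35, 0.65, 0.95) of the observed ages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from scipy.optimize import minimize
from statsmodels.tools.numdiff import approx_hess2

__all__ = [
    "SplineSpec",
    "TrajectoryFit",
    "MarginalMeans",
    "EffectSize",
    "WaldTest",
    "DEFAULT_COVARIATES",
    "rcs_basis",
    "place_knots",
    "build_design",
    "fit_lmm",
    "fit_glmm",
    "marginal_means",
    "wald_joint_test",
    "cohens_d",
    "sum_composites",
    "power_two_sample",
]

DEFAULT_KNOT_QUANTILES = (0.05, 0.35, 0.65, 0.95)

#: Adjustment covariates in the full day-level model: family
#: socio-demographics, device wear time, season, and the pandemic-period
#: flag. Categorical references are the first sorted level.
DEFAULT_COVARIATES = (
    "maternal_work",
    "dwelling",
    "yard_size",
    "season",
    "covid",
    "wear_minutes",
)

_CONTINUOUS_COVARIATES = {"wear_minutes"}


@dataclass(frozen=True)
class SplineSpec:
    """Knot locations of a restricted cubic spline (4 knots by default)."""

    knots: tuple[float, ...]
    placement_quantiles: tuple[float, ...] = DEFAULT_KNOT_QUANTILES

    def __post_init__(self) -> None:
        k = np.asarray(self.knots, dtype=float)
        if k.size < 3:
            raise ValueError("a restricted cubic spline needs at least 3 knots")
        if not np.all(np.diff(k) > 0):
            raise ValueError(f"knots must be strictly increasing, got {self.knots}")

    @property
    def n_knots(self) -> int:
        return len(self.knots)

    @property
    def n_basis(self) -> int:
        """Columns of the basis: one linear + (k-2) nonlinear terms."""
        return self.n_knots - 1


def place_knots(
    ages: np.ndarray, quantiles: tuple[float, ...] = DEFAULT_KNOT_QUANTILES
) -> SplineSpec:
    """Place knots at fixed quantiles of the observed ages.

    Uses linear-interpolation quantiles so repeated runs agree exactly.
    Requires at least 20 distinct ages for the outer quantiles to be
    meaningful.
    """
    ages = np.asarray(ages, dtype=float)
    if np.unique(ages).size < 20:
        raise ValueError("need >= 20 distinct ages to place spline knots")
    knots = tuple(float(q) for q in np.quantile(ages, quantiles, method="linear"))
    return SplineSpec(knots=knots, placement_quantiles=quantiles)


def rcs_basis(x: np.ndarray, spec: SplineSpec) -> np.ndarray:
    """Evaluate the restricted cubic spline basis at ``x``.

    Returns an (n, k-1) matrix: first column the linear term, then the k-2
    nonlinear truncated-power terms, normalised by the squared knot span so
    all columns live on comparable scales.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    t = np.asarray(spec.knots, dtype=float)
    k = t.size
    span2 = (t[-1] - t[0]) ** 2
    cols = [x]
    plus = lambda v: np.maximum(v, 0.0) ** 3
    for j in range(k - 2):
        term = (
            plus(x - t[j])
            - plus(x - t[k - 2]) * (t[k - 1] - t[j]) / (t[k - 1] - t[k - 2])
            + plus(x - t[k - 1]) * (t[k - 2] - t[j]) / (t[k - 1] - t[k - 2])
        ) / span2
        cols.append(term)
    return np.column_stack(cols)


@dataclass
class _CovariateInfo:
    """How each adjustment covariate entered the design, for prediction."""

    name: str
    kind: str  # "continuous" | "categorical"
    reference: object | None = None
    levels: tuple | None = None
    mean: float | None = None


@dataclass
class TrajectoryFit:
    """A fitted trajectory model with everything prediction needs."""

    outcome: str
    kind: str  # "linear" | "logistic"
    spec: SplineSpec
    term_names: list[str]
    fe_params: np.ndarray
    fe_cov: np.ndarray
    random_intercept_var: float
    residual_var: float | None
    covariates: list[_CovariateInfo]
    converged: bool
    method: str
    n_obs: int
    n_groups: int
    notes: str = ""
    covariate_rows: pd.DataFrame | None = field(default=None, repr=False)

    def coef_table(self) -> pd.DataFrame:
        se = np.sqrt(np.diag(self.fe_cov))
        z = np.where(se > 0, self.fe_params / se, np.nan)
        p = 2 * stats.norm.sf(np.abs(z))
        return pd.DataFrame(
            {"term": self.term_names, "estimate": self.fe_params, "se": se, "z": z, "p": p}
        )

    def term_index(self, name: str) -> int:
        return self.term_names.index(name)


class MarginalGrid(NamedTuple):
    age: float
    sex: str
    estimate: float
    lo95: float
    hi95: float


@dataclass
class MarginalMeans:
    """Marginal-mean predictions over an (age, sex) grid with 95% CIs."""

    outcome: str
    policy: str
    grid: pd.DataFrame  # columns: age, sex, estimate, lo95, hi95
    warnings: list[str] = field(default_factory=list)

    def at(self, age: float, sex: str) -> MarginalGrid:
        row = self.grid[(self.grid["age"] == age) & (self.grid["sex"] == sex)]
        if row.empty:
            raise KeyError(f"no grid point (age={age}, sex={sex})")
        r = row.iloc[0]
        return MarginalGrid(age, sex, float(r["estimate"]), float(r["lo95"]), float(r["hi95"]))


# ---------------------------------------------------------------------------
# Design construction
# ---------------------------------------------------------------------------

def _spline_term_names(spec: SplineSpec) -> list[str]:
    return ["age"] + [f"age_nl{j+1}" for j in range(spec.n_knots - 2)]


def build_design(
    data: pd.DataFrame,
    spec: SplineSpec,
    covariates: Sequence[str] = (),
    covariate_info: list[_CovariateInfo] | None = None,
) -> tuple[np.ndarray, list[str], list[_CovariateInfo]]:
    """Build the fixed-effects design matrix from a day-level table.

    Layout: intercept, sex_male, age-spline block, sex-by-age-spline block,
    then covariates (continuous as-is; categorical as treatment dummies
    against the first sorted level). When ``covariate_info`` is given
    (prediction path) levels and references are taken from it rather than
    re-derived, so train/predict encodings always agree.
    """
    n = len(data)
    sex_male = (data["sex"].astype(str) == "male").to_numpy(dtype=float)
    basis = rcs_basis(data["age_years"].to_numpy(dtype=float), spec)
    sp_names = _spline_term_names(spec)

    cols = [np.ones(n), sex_male, basis, basis * sex_male[:, None]]
    names = ["intercept", "sex_male"] + sp_names + [f"sex_male:{s}" for s in sp_names]

    infos: list[_CovariateInfo] = []
    lookup = {c.name: c for c in covariate_info} if covariate_info else {}
    for cov in covariates:
        if cov in _CONTINUOUS_COVARIATES:
            vals = data[cov].to_numpy(dtype=float)
            info = lookup.get(cov) or _CovariateInfo(
                cov, "continuous", mean=float(vals.mean())
            )
            cols.append(vals[:, None])
            names.append(cov)
        else:
            if cov in lookup:
                info = lookup[cov]
                levels = info.levels
            else:
                levels = tuple(sorted(data[cov].astype(str).unique()))
                info = _CovariateInfo(cov, "categorical", reference=levels[0], levels=levels)
            vals = data[cov].astype(str)
            for lev in info.levels[1:]:
                cols.append((vals == str(lev)).to_numpy(dtype=float)[:, None])
                names.append(f"{cov}[{lev}]")
        infos.append(info)

    X = np.column_stack([np.atleast_2d(c.T).T if c.ndim == 1 else c for c in cols])
    return X, names, infos


def _prediction_row(
    age: float,
    sex: str,
    fit: TrajectoryFit,
    policy: str,
) -> np.ndarray:
    """One design row for (age, sex) under the covariate policy.

    ``reference`` sets categorical covariates to their reference level and
    continuous ones to the training-sample mean. ``population`` averages
    the design over the observed covariate rows (categoricals at their
    empirical distribution).
    """
    spec = fit.spec
    basis = rcs_basis(np.array([age]), spec)[0]
    male = 1.0 if sex == "male" else 0.0
    head = np.concatenate([[1.0, male], basis, basis * male])

    tail = []
    if policy == "reference":
        for info in fit.covariates:
            if info.kind == "continuous":
                tail.append(info.mean)
            else:
                tail.extend([0.0] * (len(info.levels) - 1))
    elif policy == "population":
        if fit.covariate_rows is None or fit.covariate_rows.empty:
            raise ValueError("population policy needs the stored covariate rows")
        rows = fit.covariate_rows
        for info in fit.covariates:
            if info.kind == "continuous":
                tail.append(float(rows[info.name].astype(float).mean()))
            else:
                vals = rows[info.name].astype(str)
                for lev in info.levels[1:]:
                    tail.append(float((vals == str(lev)).mean()))
    else:
        raise ValueError(f"unknown covariate policy {policy!r}")
    return np.concatenate([head, np.asarray(tail, dtype=float)])


# ---------------------------------------------------------------------------
# Model fitting
# ---------------------------------------------------------------------------

def fit_lmm(
    cohort: pd.DataFrame,
    outcome: str,
    spec: SplineSpec | None = None,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    group_col: str = "child_id",
) -> TrajectoryFit:
    """Fit the linear mixed model for a minutes outcome by REML.

    Fixed effects: sex, age RCS, age-by-sex interaction and the requested
    covariates; random child intercept. Non-convergence is flagged on the
    returned fit, never silently ignored.
    """
    if outcome not in cohort.columns:
        raise ValueError(f"outcome column {outcome!r} not present")
    data = cohort.dropna(subset=[outcome]).reset_index(drop=True)
    if spec is None:
        spec = place_knots(data["age_years"].to_numpy())
    covariates = [c for c in covariates if c in data.columns]
    X, names, infos = build_design(data, spec, covariates)
    y = data[outcome].to_numpy(dtype=float)
    groups = data[group_col].to_numpy()

    model = sm.MixedLM(y, X, groups=groups)
    result = None
    failure = ""
    # some optimizers can step into a singular region on hard replicates;
    # fall back through a small chain before flagging non-convergence
    for method in ("lbfgs", "bfgs", "powell"):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                result = model.fit(reml=True, method=method, maxiter=500)
            break
        except (np.linalg.LinAlgError, ValueError) as e:
            failure = f"{method}: {e}"
            result = None
    if result is None:
        k = X.shape[1]
        return TrajectoryFit(
            outcome=outcome, kind="linear", spec=spec, term_names=names,
            fe_params=np.full(k, np.nan), fe_cov=np.full((k, k), np.nan),
            random_intercept_var=float("nan"), residual_var=float("nan"),
            covariates=infos, converged=False, method="REML",
            n_obs=len(data), n_groups=int(pd.Series(groups).nunique()),
            notes=f"optimizer failure ({failure})",
        )
    k = X.shape[1]
    fe = np.asarray(result.fe_params, dtype=float)
    cov = np.asarray(result.cov_params())[:k, :k]
    converged = bool(result.converged)
    notes = ""
    if not converged:
        # boundary case: noise-free data is fitted exactly but the variance
        # components sit at zero, which the optimizer flags as non-convergence
        resid = y - X @ fe
        if np.all(np.isfinite(fe)) and np.abs(resid).max() <= 1e-8 * max(1.0, np.abs(y).max()):
            converged = True
            notes = "degenerate: zero residual variance (exact fit)"
    return TrajectoryFit(
        outcome=outcome,
        kind="linear",
        spec=spec,
        term_names=names,
        fe_params=fe,
        fe_cov=cov,
        random_intercept_var=float(np.asarray(result.cov_re).ravel()[0]),
        residual_var=float(result.scale),
        covariates=infos,
        converged=converged,
        method="REML",
        n_obs=len(data),
        n_groups=int(pd.Series(groups).nunique()),
        notes=notes,
        covariate_rows=data[covariates].copy() if covariates else pd.DataFrame(index=data.index),
    )


def fit_glmm(
    cohort: pd.DataFrame,
    outcome: str,
    spec: SplineSpec | None = None,
    covariates: Sequence[str] = (),
    group_col: str = "child_id",
) -> TrajectoryFit:
    """Fit the logistic mixed model for a binary adherence outcome.

    The marginal likelihood integrates the child-level random intercept
    out by Gauss-Hermite quadrature (the scalar-random-effect counterpart
    of the Laplace family used by standard GLMM tooling); estimates are on
    the log-odds scale with full covariance from the numerical Hessian. A
    degenerate outcome (all children meet, or none do) is complete
    separation: the fit is returned flagged, with no finite estimates
    claimed.
    """
    data = cohort.dropna(subset=[outcome]).reset_index(drop=True)
    y = data[outcome].astype(float).to_numpy()
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError(f"outcome {outcome!r} must be binary 0/1")
    if spec is None:
        spec = place_knots(data["age_years"].to_numpy())
    covariates = [c for c in covariates if c in data.columns]
    X, names, infos = build_design(data, spec, covariates)

    if np.all(y == y[0]):  # degenerate: nothing to estimate
        k = X.shape[1]
        return TrajectoryFit(
            outcome=outcome, kind="logistic", spec=spec, term_names=names,
            fe_params=np.full(k, np.nan), fe_cov=np.full((k, k), np.nan),
            random_intercept_var=float("nan"), residual_var=None,
            covariates=infos, converged=False, method="MAP-Laplace",
            n_obs=len(data), n_groups=int(data[group_col].nunique()),
            notes="complete separation: outcome constant",
        )

    codes, _ = pd.factorize(data[group_col].astype(str))
    order = np.argsort(codes, kind="stable")
    y_s, X_s, codes_s = y[order], X[order], codes[order]
    # group boundaries for segmented sums (data sorted by group)
    starts = np.flatnonzero(np.r_[True, np.diff(codes_s) != 0])
    n_groups = starts.size

    nodes, weights = np.polynomial.hermite.hermgauss(25)
    log_w = np.log(weights) - 0.5 * np.log(np.pi)
    k = X.shape[1]

    def neg_loglik(theta: np.ndarray) -> float:
        beta, log_sigma = theta[:k], theta[k]
        sigma = np.exp(log_sigma)
        eta = X_s @ beta
        # obs x node linear predictor with the scaled quadrature offsets
        lin = eta[:, None] + np.sqrt(2.0) * sigma * nodes[None, :]
        sgn = 2.0 * y_s - 1.0
        ll_obs = -np.logaddexp(0.0, -sgn[:, None] * lin)
        ll_grp = np.add.reduceat(ll_obs, starts, axis=0)  # group x node
        m = ll_grp.max(axis=1, keepdims=True)
        log_int = m[:, 0] + np.log(np.exp(ll_grp - m + log_w[None, :]).sum(axis=1))
        return -float(log_int.sum())

    start = np.zeros(k + 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        opt = minimize(neg_loglik, start, method="BFGS",
                       options={"maxiter": 500, "gtol": 1e-5})
        hess = approx_hess2(opt.x, neg_loglik)
    # numeric-gradient BFGS often stops on "precision loss" with the score
    # already negligible relative to the likelihood's curvature; accept that
    converged = bool(opt.success) or float(np.max(np.abs(opt.jac))) < 1.0
    try:
        cov_all = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        cov_all = np.full((k + 1, k + 1), np.nan)
    fe = opt.x[:k]
    sigma = float(np.exp(opt.x[k]))
    return TrajectoryFit(
        outcome=outcome, kind="logistic", spec=spec, term_names=names,
        fe_params=fe, fe_cov=cov_all[:k, :k],
        random_intercept_var=sigma**2, residual_var=None,
        covariates=infos, converged=converged, method="ML-GaussHermite25",
        n_obs=len(data), n_groups=int(n_groups),
        notes="" if converged else f"optimizer: {opt.message}",
        covariate_rows=data[covariates].copy() if covariates else pd.DataFrame(index=data.index),
    )


# ---------------------------------------------------------------------------
# Inference and prediction
# ---------------------------------------------------------------------------

def marginal_means(
    fit: TrajectoryFit,
    ages: Sequence[float] = (2, 3, 4, 5, 6, 7),
    sexes: Sequence[str] = ("male", "female"),
    policy: str = "reference",
) -> MarginalMeans:
    """Predict marginal means with delta-method 95% CIs on an age grid.

    Covariates are held at representative values per ``policy``
    ("reference": categorical reference level, continuous at the sample
    mean; "population": averaged over the observed covariate rows).
    Logistic fits are back-transformed to proportions. Ages beyond the
    boundary knots attach an extrapolation warning.
    """
    if not fit.converged:
        raise ValueError(f"fit for {fit.outcome!r} did not converge ({fit.notes})")
    z = stats.norm.ppf(0.975)
    lo_k, hi_k = fit.spec.knots[0], fit.spec.knots[-1]
    warns = []
    rows = []
    for sex in sexes:
        for age in ages:
            x = _prediction_row(float(age), sex, fit, policy)
            eta = float(x @ fit.fe_params)
            var = float(x @ fit.fe_cov @ x)
            se = float(np.sqrt(max(var, 0.0)))  # clip: exact fits can give -0
            lo, hi = eta - z * se, eta + z * se
            if fit.kind == "logistic":
                expit = lambda v: 1.0 / (1.0 + np.exp(-v))
                eta, lo, hi = expit(eta), expit(lo), expit(hi)
            rows.append({"age": float(age), "sex": sex, "estimate": eta, "lo95": lo, "hi95": hi})
            if age < lo_k or age > hi_k:
                warns.append(
                    f"age {age} outside the knot-supported range [{lo_k:.2f}, {hi_k:.2f}]"
                )
    return MarginalMeans(outcome=fit.outcome, policy=policy, grid=pd.DataFrame(rows), warnings=warns)


@dataclass(frozen=True)
class WaldTest:
    statistic: float
    df: int
    p_value: float
    terms: tuple[str, ...]


def wald_joint_test(fit: TrajectoryFit, terms: Sequence[str]) -> WaldTest:
    """Joint Wald chi-square test that a block of coefficients is zero.

    With one term this reduces to the two-sided z-test. Raises on an empty
    block or a singular covariance sub-block.
    """
    if not terms:
        raise ValueError("term block must be non-empty")
    idx = [fit.term_index(t) for t in terms]
    beta = fit.fe_params[idx]
    V = fit.fe_cov[np.ix_(idx, idx)]
    if not np.all(np.isfinite(V)):
        raise ValueError("covariance unavailable for the requested block")
    try:
        sol = np.linalg.solve(V, beta)
    except np.linalg.LinAlgError as e:
        raise ValueError("singular covariance sub-block") from e
    stat = float(beta @ sol)
    df = len(idx)
    return WaldTest(statistic=stat, df=df, p_value=float(stats.chi2.sf(stat, df)), terms=tuple(terms))


def interaction_terms(fit: TrajectoryFit) -> list[str]:
    """Names of the age-spline-by-sex interaction block."""
    return [t for t in fit.term_names if t.startswith("sex_male:")]


class EffectSize(NamedTuple):
    """A standardized mean difference with its 2-dp presentation value."""

    value: float
    rounded: float


def cohens_d(delta: float, sd: float) -> EffectSize:
    """Standardized effect size delta/sd (Cohen's d for a mean difference).

    Returns full precision together with the conventional two-decimal
    presentation (e.g. a 5 min/day change against SD 42 min/day is d =
    0.119..., presented as 0.12).
    """
    if sd <= 0:
        raise ValueError("sd must be positive")
    d = delta / sd
    return EffectSize(value=d, rounded=round(d, 2))


def sum_composites(
    lpa: float,
    walk: float,
    run: float,
    mv_act_g: float,
) -> dict[str, float]:
    """Composite conventions: energetic play and total physical activity.

    Energetic play (MVPA) is walking + running + moderate-vigorous
    activities and games; total physical activity is energetic play + light
    activities and games. Inputs are mean min/day and must be non-negative.
    """
    comps = {"lpa": lpa, "walk": walk, "run": run, "mv_act_g": mv_act_g}
    for k, v in comps.items():
        if v < 0:
            raise ValueError(f"{k} must be non-negative, got {v}")
    energetic = walk + run + mv_act_g
    return {"energetic_play": energetic, "total_pa": lpa + energetic}


def power_two_sample(
    delta: float, sd: float, n_per_group: int, alpha: float = 0.05
) -> float:
    """Normal-approximation power for a two-sample mean comparison.

    A design-exploration convenience; assumes equal, independent groups
    with common SD.
    """
    if sd <= 0 or n_per_group <= 0:
        raise ValueError("sd and n_per_group must be positive")
    ncp = abs(delta) / (sd * np.sqrt(2.0 / n_per_group))
    z_a = stats.norm.ppf(1 - alpha / 2)
    return float(stats.norm.sf(z_a - ncp) + stats.norm.cdf(-z_a - ncp))
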