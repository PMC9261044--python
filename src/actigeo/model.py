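"""City-stratified multilevel negative-binomial regression, reported as IRRs.

The outcome is minutes of activity (PA or MVPA) per participant x date x DA
row.  The model is NB2 (variance mu + mu^2/theta) with a log link and no
offset, a per-participant random intercept and a random slope on the centred
within-person observation-day index, with correlated bivariate normal random
effects:

    y_ij | b_i ~ NB2(mu_ij, theta),  log mu_ij = x_ij' beta + b0_i + b1_i t_ij
    (b0_i, b1_i) ~ N(0, Sigma)

The marginal likelihood integrates the random effects per participant with
adaptive Gauss-Hermite quadrature (Laplace approximation when the number of
quadrature points is 1): each participant's integrand is re-centred at its
conditional mode and scaled by the Cholesky factor of the negative Hessian
there.  Dispersion is profiled on the log scale; the random-effect covariance
is parameterized by log standard deviations and an atanh-correlation.  Wald
inference on the log scale yields incidence rate ratios with 95% intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy import optimize
from scipy.special import gammaln, logsumexp
from statsmodels.tools import numdiff

from .exposures import PROXIMITY_AMENITIES, exposure_correlations
from .spatial_aggregation import filter_min_dwell

__all__ = [
    "ModelSpec",
    "FitControl",
    "NBGLMMFit",
    "build_design",
    "fit_nb_glmm",
    "nb_glmm_loglik",
    "irr_table",
    "run_study",
    "StudyReport",
]


#: categorical covariates with fixed, documented reference levels
CATEGORICAL_LEVELS: dict[str, list[str]] = {
    "gentrification_class": ["high_ses", "low_ses_not_gentrified", "gentrified"],
    "age_group": ["18-24", "25-44", "45-64", "65+"],
    "gender_group": ["woman", "man", "nonbinary"],
    "income_group": ["<50k", "50-100k", "100k+"],
    "race_group": ["white", "minority_indigenous"],
}

DEFAULT_FIXED: tuple[str, ...] = (
    "can_ale_q",
    "gentrification_class",
    "urban_compactness",
    *[f"{a}_q" for a in PROXIMITY_AMENITIES],
    "age_group",
    "gender_group",
    "income_group",
    "race_group",
    "is_home_da",
    "is_weekend",
    "precipitation_mm",
    "temperature_c",
)


@dataclass
class ModelSpec:
    """What to regress on what.

    ``fixed`` lists covariate columns; entries in :data:`CATEGORICAL_LEVELS`
    expand to dummies against their fixed reference (first level), all others
    enter numerically (quintiles as 1-5 scores).  ``re_structure`` is
    ``"intercept_slope"`` (default), ``"intercept"`` or ``"none"``.
    """

    outcome: str = "pa_minutes"
    fixed: tuple[str, ...] = DEFAULT_FIXED
    group_col: str = "participant_id"
    day_index_col: str = "day_index"
    re_structure: str = "intercept_slope"


@dataclass(frozen=True)
class FitControl:
    nagq: int = 7
    maxiter: int = 300
    gtol: float = 1e-6
    # mode error eps perturbs the marginal loglik only at O(eps^2), so 1e-8
    # keeps the likelihood accurate to ~1e-16
    inner_tol: float = 1e-8
    inner_maxiter: int = 50
    log_sd_bounds: tuple[float, float] = (-8.0, 3.0)
    log_theta_bounds: tuple[float, float] = (-4.0, 7.0)


@dataclass
class NBGLMMFit:
    """A fitted multilevel NB model."""

    beta: pd.Series  # fixed effects, log scale
    vcov: pd.DataFrame  # of the fixed effects
    re_cov: np.ndarray  # (d, d) random-effect covariance (d per structure)
    dispersion: float
    loglik: float
    converged: bool
    n_obs: int
    n_groups: int
    spec: ModelSpec
    n_dropped_missing: int = 0
    message: str = ""
    params_packed: np.ndarray | None = None  # full optimizer vector, for warm starts


def build_design(table: pd.DataFrame, spec: ModelSpec) -> tuple[pd.DataFrame, pd.Series, int]:
    """Design matrix (with intercept), outcome vector, and missing-row count.

    Rows with missing values in any used column are dropped (complete-case)
    and counted.  Raises on non-integer outcomes or a rank-deficient design,
    naming the offending columns.
    """
    cols = [spec.outcome, spec.group_col] + [c for c in spec.fixed]
    if spec.day_index_col in table.columns:
        cols.append(spec.day_index_col)
    missing_cols = [c for c in cols if c not in table.columns]
    if missing_cols:
        raise ValueError(f"table lacks columns: {missing_cols}")
    sub = table[cols].copy()
    n0 = len(sub)
    sub = sub.dropna()
    n_dropped = n0 - len(sub)

    y = sub[spec.outcome]
    y_arr = y.to_numpy()
    if not np.allclose(y_arr, np.round(y_arr)) or (y_arr < 0).any():
        raise ValueError("outcome must be non-negative integer minutes")

    X = pd.DataFrame(index=sub.index)
    X["intercept"] = 1.0
    for c in spec.fixed:
        if c in CATEGORICAL_LEVELS:
            levels = CATEGORICAL_LEVELS[c]
            obs = set(sub[c].unique())
            if unknown := obs - set(levels):
                raise ValueError(f"unknown levels in {c}: {sorted(unknown)}")
            for lev in levels[1:]:
                if lev in obs:
                    X[f"{c}[{lev}]"] = (sub[c] == lev).astype(float)
        else:
            X[c] = sub[c].astype(float)

    M = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(M)
    if rank < M.shape[1]:
        _, R = np.linalg.qr(M)
        bad = [X.columns[j] for j in range(M.shape[1]) if abs(R[j, j]) < 1e-8]
        raise ValueError(f"design matrix not full rank; collinear columns: {bad}")
    X.index = sub.index
    return X, sub, n_dropped


def _nb_logpmf_const(y: np.ndarray) -> np.ndarray:
    return -gammaln(y + 1.0)


def _segment_sum(values: np.ndarray, gidx: np.ndarray, n_groups: int) -> np.ndarray:
    """Sum `values` (n,) or (n, m) by group index."""
    if values.ndim == 1:
        return np.bincount(gidx, weights=values, minlength=n_groups)
    out = np.empty((n_groups, values.shape[1]))
    for j in range(values.shape[1]):
        out[:, j] = np.bincount(gidx, weights=values[:, j], minlength=n_groups)
    return out


def _conditional_modes(
    eta0: np.ndarray,
    y: np.ndarray,
    theta: float,
    Z: np.ndarray,
    gidx: np.ndarray,
    n_groups: int,
    Sigma_inv: np.ndarray,
    control: FitControl,
    b_start: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised per-group Newton ascent of the joint log-density.

    Returns the modes ``b`` (G, d) and the negative Hessians ``H`` (G, d, d)
    of the joint density at the modes.  The joint density is strictly concave
    in b (NB log-likelihood is concave in the linear predictor), so the mode
    is unique and a warm start only shortens the ascent.
    """
    d = Z.shape[1]
    b = np.zeros((n_groups, d)) if b_start is None else b_start.copy()

    def joint(bcur: np.ndarray) -> np.ndarray:
        eta = eta0 + (Z * bcur[gidx]).sum(axis=1)
        eta = np.clip(eta, -30, 30)
        mu = np.exp(eta)
        ll = theta * (np.log(theta) - np.log(theta + mu)) + y * (eta - np.log(theta + mu))
        per_g = _segment_sum(ll, gidx, n_groups)
        prior = -0.5 * np.einsum("gi,ij,gj->g", bcur, Sigma_inv, bcur)
        return per_g + prior

    f_old = joint(b)
    H = np.tile(Sigma_inv, (n_groups, 1, 1))
    for _ in range(control.inner_maxiter):
        eta = eta0 + (Z * b[gidx]).sum(axis=1)
        eta = np.clip(eta, -30, 30)
        mu = np.exp(eta)
        frac = mu / (mu + theta)
        d1 = y - (y + theta) * frac  # d loglik / d eta
        w = (y + theta) * theta * mu / (mu + theta) ** 2  # -d2 loglik / d eta2
        g = _segment_sum(Z * d1[:, None], gidx, n_groups) - b @ Sigma_inv
        # per-group d x d Hessian
        H = np.einsum("ni,nj,n->nij", Z, Z, w)
        H = np.stack(
            [_segment_sum(H[:, i, j], gidx, n_groups) for i in range(d) for j in range(d)], axis=1
        ).reshape(n_groups, d, d) + Sigma_inv
        step = np.linalg.solve(H, g[:, :, None])[:, :, 0]
        step_size = np.max(np.abs(step))
        if step_size < control.inner_tol:
            break
        # step-halving where the joint density would decrease
        scale = np.ones(n_groups)
        f_new = joint(b + step)
        for _half in range(8):
            worse = f_new < f_old - 1e-13
            if not worse.any():
                break
            scale[worse] *= 0.5
            f_new = joint(b + scale[:, None] * step)
        b = b + scale[:, None] * step
        f_old = f_new
    return b, H


def nb_glmm_loglik(
    params: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    Z: np.ndarray,
    gidx: np.ndarray,
    n_groups: int,
    structure: str,
    control: FitControl,
    mode_cache: dict | None = None,
) -> float:
    """Marginal log-likelihood at a packed parameter vector.

    Packing: beta (p), log theta, then per structure: [log_sd0, log_sd1,
    atanh_rho] (intercept_slope), [log_sd0] (intercept), [] (none).
    ``mode_cache`` (a dict with key "b") warm-starts the conditional-mode
    search across nearby evaluations; the result is unchanged because the
    per-group joint density is strictly concave.
    """
    p = X.shape[1]
    beta = params[:p]
    theta = float(np.exp(params[p]))
    eta0 = X @ beta
    lgy = gammaln(y + theta) - gammaln(theta) + _nb_logpmf_const(y)  # eta-independent

    if structure == "none":
        eta = np.clip(eta0, -30, 30)
        mu = np.exp(eta)
        ll = lgy + theta * (np.log(theta) - np.log(theta + mu)) + y * (eta - np.log(theta + mu))
        return float(ll.sum())

    d = Z.shape[1]
    if structure == "intercept_slope":
        sd0, sd1 = np.exp(params[p + 1]), np.exp(params[p + 2])
        rho = np.tanh(params[p + 3])
        Sigma = np.array([[sd0**2, rho * sd0 * sd1], [rho * sd0 * sd1, sd1**2]])
    elif structure == "intercept":
        sd0 = np.exp(params[p + 1])
        Sigma = np.array([[sd0**2]])
    else:
        raise ValueError(f"unknown random-effect structure {structure!r}")
    Sigma_inv = np.linalg.inv(Sigma)
    _, logdet_Sigma = np.linalg.slogdet(Sigma)

    b_start = mode_cache.get("b") if mode_cache is not None else None
    b, H = _conditional_modes(eta0, y, theta, Z, gidx, n_groups, Sigma_inv, control, b_start)
    if mode_cache is not None:
        mode_cache["b"] = b

    def joint_at(bnodes: np.ndarray) -> np.ndarray:
        """Joint log density f(b) per (group, node); bnodes is (G, m, d)."""
        m = bnodes.shape[1]
        brow = bnodes[gidx]  # (n, m, d)
        eta = eta0[:, None] + np.einsum("nmd,nd->nm", brow, Z)
        eta = np.clip(eta, -30, 30)
        mu = np.exp(eta)
        ll = theta * (np.log(theta) - np.log(theta + mu)) + y[:, None] * (eta - np.log(theta + mu))
        flat_idx = (gidx[:, None] * m + np.arange(m)[None, :]).ravel()
        per_g = np.bincount(flat_idx, weights=ll.ravel(), minlength=n_groups * m).reshape(
            n_groups, m
        )
        quad = np.einsum("gmi,ij,gmj->gm", bnodes, Sigma_inv, bnodes)
        prior = -0.5 * quad - 0.5 * d * np.log(2 * np.pi) - 0.5 * logdet_Sigma
        return per_g + prior

    if control.nagq <= 1:
        f_mode = joint_at(b[:, None, :])[:, 0]
        _, logdet_H = np.linalg.slogdet(H)
        marg = f_mode + 0.5 * d * np.log(2 * np.pi) - 0.5 * logdet_H
    else:
        x_nodes, w_nodes = hermgauss(control.nagq)
        if d == 2:
            U = np.array([[xi, xj] for xi in x_nodes for xj in x_nodes])
            logw = np.array(
                [np.log(wi) + np.log(wj) for wi in w_nodes for wj in w_nodes]
            ) + (U**2).sum(axis=1)
        else:
            U = x_nodes[:, None]
            logw = np.log(w_nodes) + x_nodes**2
        L = np.linalg.cholesky(H)  # H = L L^T, A = L^{-T}, A A^T = H^{-1}
        eye = np.eye(d)
        A = np.linalg.solve(np.transpose(L, (0, 2, 1)), np.tile(eye, (n_groups, 1, 1)))
        offsets = np.sqrt(2.0) * np.einsum("gij,mj->gmi", A, U)
        bnodes = b[:, None, :] + offsets
        f = joint_at(bnodes)
        _, logdet_H = np.linalg.slogdet(H)
        # |sqrt(2) A| = 2^{d/2} det(H)^{-1/2}
        marg = 0.5 * d * np.log(2.0) - 0.5 * logdet_H + logsumexp(f + logw[None, :], axis=1)

    return float(marg.sum() + lgy.sum())


def _poisson_start(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    import statsmodels.api as sm

    try:
        res = sm.GLM(y, X, family=sm.families.Poisson()).fit(maxiter=50)
        return np.asarray(res.params, dtype=float)
    except Exception:
        b, *_ = np.linalg.lstsq(X, np.log(y + 0.5), rcond=None)
        return b


def fit_nb_glmm(
    table: pd.DataFrame,
    spec: ModelSpec | None = None,
    control: FitControl | None = None,
    start_params: np.ndarray | None = None,
) -> NBGLMMFit:
    """Maximum (marginal) likelihood fit of the multilevel NB model.

    Deterministic for fixed data and control.  Non-convergence is flagged on
    the returned fit, never silent.  ``start_params`` optionally seeds the
    optimizer (packed as beta, log theta, RE parameters); the default start
    is a Poisson GLM for beta with a moment estimate of the dispersion.
    """
    spec = spec or ModelSpec()
    control = control or FitControl()
    Xdf, sub, n_dropped = build_design(table, spec)
    y = sub[spec.outcome].to_numpy(dtype=float)
    X = Xdf.to_numpy(dtype=float)
    groups, gidx = np.unique(sub[spec.group_col].to_numpy(), return_inverse=True)
    n_groups = len(groups)
    if n_groups < 2 and spec.re_structure != "none":
        raise ValueError("need at least 2 groups for random effects")

    if spec.re_structure == "intercept_slope":
        t = sub[spec.day_index_col].to_numpy(dtype=float)
        t = t - t.mean()
        Z = np.column_stack([np.ones_like(t), t])
        re_names = ["log_sd_intercept", "log_sd_slope", "atanh_corr"]
        re_start = [np.log(0.3), np.log(0.05), 0.0]
    elif spec.re_structure == "intercept":
        Z = np.ones((len(y), 1))
        re_names = ["log_sd_intercept"]
        re_start = [np.log(0.3)]
    elif spec.re_structure == "none":
        Z = np.zeros((len(y), 0))
        re_names, re_start = [], []
    else:
        raise ValueError(f"unknown re_structure {spec.re_structure!r}")

    p = X.shape[1]
    if start_params is not None and len(start_params) == p + 1 + len(re_start):
        x0 = np.asarray(start_params, dtype=float)
    else:
        beta0 = _poisson_start(X, y)
        mu0 = np.exp(np.clip(X @ beta0, -30, 30))
        resid = ((y - mu0) ** 2 - mu0).sum()
        theta0 = float(np.clip((mu0**2).sum() / max(resid, 1e-6), 0.1, 100.0))
        x0 = np.concatenate([beta0, [np.log(theta0)], re_start])

    lo = np.full(len(x0), -np.inf)
    hi = np.full(len(x0), np.inf)
    lo[p], hi[p] = control.log_theta_bounds
    for j in range(len(re_start)):
        if re_names[j].startswith("log_sd"):
            lo[p + 1 + j], hi[p + 1 + j] = control.log_sd_bounds
        else:
            lo[p + 1 + j], hi[p + 1 + j] = -5.0, 5.0

    mode_cache: dict = {}

    def nll(params: np.ndarray) -> float:
        return -nb_glmm_loglik(
            params, X, y, Z, gidx, n_groups, spec.re_structure, control, mode_cache
        )

    res = optimize.minimize(
        nll,
        x0,
        method="L-BFGS-B",
        bounds=list(zip(lo, hi)),
        options={"maxiter": control.maxiter, "ftol": 1e-10, "gtol": control.gtol},
    )

    # observed-information covariance of all parameters; fixed-effect block reported
    hess = numdiff.approx_hess1(res.x, nll)
    try:
        vcov_all = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        vcov_all = np.linalg.pinv(hess)
    names = list(Xdf.columns)
    vcov = pd.DataFrame(vcov_all[:p, :p], index=names, columns=names)

    theta_hat = float(np.exp(res.x[p]))
    if spec.re_structure == "intercept_slope":
        sd0, sd1 = np.exp(res.x[p + 1]), np.exp(res.x[p + 2])
        rho = np.tanh(res.x[p + 3])
        re_cov = np.array([[sd0**2, rho * sd0 * sd1], [rho * sd0 * sd1, sd1**2]])
    elif spec.re_structure == "intercept":
        sd0 = np.exp(res.x[p + 1])
        re_cov = np.array([[sd0**2]])
    else:
        re_cov = np.zeros((0, 0))

    return NBGLMMFit(
        beta=pd.Series(res.x[:p], index=names),
        vcov=vcov,
        re_cov=re_cov,
        dispersion=theta_hat,
        loglik=float(-res.fun),
        converged=bool(res.success),
        n_obs=len(y),
        n_groups=n_groups,
        spec=spec,
        n_dropped_missing=n_dropped,
        message=str(res.message),
        params_packed=np.asarray(res.x, dtype=float),
    )


def irr_table(fit: NBGLMMFit, level: float = 0.95) -> pd.DataFrame:
    """Incidence rate ratios with Wald confidence intervals and p-values."""
    from scipy.stats import norm

    z = norm.ppf(0.5 + level / 2)
    var = np.diag(fit.vcov.to_numpy())
    # non-PD observed information (e.g. variance parameters at a bound) gives
    # no usable SE for the affected terms
    se = np.sqrt(np.where(var >= 0, var, np.nan))
    beta = fit.beta.to_numpy()
    out = pd.DataFrame(
        {
            "term": fit.beta.index,
            "estimate": beta,
            "se": se,
            "irr": np.exp(beta),
            "ci_lo": np.exp(beta - z * se),
            "ci_hi": np.exp(beta + z * se),
            "p": 2 * norm.sf(np.abs(beta) / np.where(se > 0, se, np.inf)),
        }
    )
    return out


@dataclass
class StudyReport:
    """All model fits of a study run plus the exposure-correlation report."""

    fits: dict[tuple[str, str, str], NBGLMMFit] = field(default_factory=dict)
    irr: dict[tuple[str, str, str], pd.DataFrame] = field(default_factory=dict)
    errors: dict[tuple[str, str, str], str] = field(default_factory=dict)
    exposure_corr: dict[str, pd.DataFrame] = field(default_factory=dict)


def run_study(
    tables_by_city: dict[str, pd.DataFrame],
    outcomes: tuple[str, ...] = ("pa_minutes", "mvpa_minutes"),
    dwell_threshold: int = 5,
    spec: ModelSpec | None = None,
    control: FitControl | None = None,
) -> StudyReport:
    """Main fits for each city x outcome, plus >=``dwell_threshold``-minute
    sensitivity refits, plus a per-city exposure correlation matrix.

    A stratum failing its preconditions is recorded under ``errors``; the
    remaining strata are still fit.
    """
    base = spec or ModelSpec()
    report = StudyReport()
    for city_id, table in tables_by_city.items():
        exp_cols = [c for c in table.columns if c.endswith("_q") or c == "urban_compactness"]
        report.exposure_corr[city_id] = exposure_correlations(
            table.drop_duplicates("da_id")[["da_id"] + exp_cols]
        )
        for outcome in outcomes:
            s = ModelSpec(
                outcome=outcome,
                fixed=base.fixed,
                group_col=base.group_col,
                day_index_col=base.day_index_col,
                re_structure=base.re_structure,
            )
            for arm, tbl in (
                ("main", table),
                ("sensitivity", filter_min_dwell(table, dwell_threshold)),
            ):
                key = (city_id, outcome, arm)
                try:
                    fit = fit_nb_glmm(tbl, s, control)
                    report.fits[key] = fit
                    report.irr[key] = irr_table(fit)
                except (ValueError, np.linalg.LinAlgError) as exc:
                    report.errors[key] = f"{type(exc).__name__}: {exc}"
    return report
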