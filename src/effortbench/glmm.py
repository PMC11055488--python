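"""Generalized linear mixed models with crossed random effects.

Two families are supported, matching the study variables they model:

* binomial with logit link — correct/incorrect trial outcomes (sentence
  categorization, final-word repetition, end-of-list recall);
* Gamma with log link — shifted reaction times (strictly positive seconds).

Estimation maximizes the Laplace approximation to the integrated likelihood.
For fixed variance parameters, fixed effects and random-effect modes are
found jointly by penalized iteratively reweighted least squares (PIRLS);
the outer optimization runs over the log standard deviations of the random
effect blocks (plus the log Gamma shape).  Random effects are modelled as
independent blocks (no intercept-slope correlation): each grouping factor
contributes an intercept block and one block per slope column, every block
with its own variance.  Grouping factors are crossed, not nested.

Model specifications use a small formula dialect mirroring common
mixed-model notation::

    rt_shifted_s ~ snr_condition + session + answer + (1 + snr_condition | participant_id) + (1 | item_id)

Inference on coefficients is Wald-z; model comparison uses AIC (backward
elimination of one term at a time) and likelihood-ratio tests for added
interactions.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import patsy
from scipy import linalg, optimize, sparse, special, stats

__all__ = ["RandomTerm", "ModelSpec", "ModelFit", "fit_glmm",
           "backward_select_aic", "add_interactions_lrt",
           "standardized_coefficients", "r2_nakagawa", "overdispersion_check"]

_MIN_SD = 1e-4          # below this a variance component is reported singular
_LOGSD_BOUNDS = (-12.0, 4.0)


# ---------------------------------------------------------------------------
# model specification

@dataclass(frozen=True)
class RandomTerm:
    """Random effects for one grouping factor: intercept and/or slopes."""

    group: str
    intercept: bool = True
    slopes: tuple[str, ...] = ()

    def formula_part(self) -> str:
        terms = (["1"] if self.intercept else ["0"]) + list(self.slopes)
        return f"({' + '.join(terms)} | {self.group})"


@dataclass(frozen=True)
class ModelSpec:
    """Family, response, fixed terms and random terms of one GLMM."""

    response: str
    family: str  # 'binomial' or 'gamma'
    fixed: tuple[str, ...]
    random: tuple[RandomTerm, ...] = ()
    trials: str | None = None  # optional column of binomial trial counts

    def __post_init__(self) -> None:
        if self.family not in ("binomial", "gamma"):
            raise ValueError(f"family must be 'binomial' or 'gamma', got {self.family!r}")
        fixed_set = set(self.fixed)
        for rt in self.random:
            for s in rt.slopes:
                if s not in fixed_set:
                    raise ValueError(
                        f"random slope {s!r} for group {rt.group!r} has no "
                        "matching fixed term")

    @classmethod
    def from_formula(cls, formula: str, family: str,
                     trials: str | None = None) -> "ModelSpec":
        lhs, _, rhs = formula.partition("~")
        if not _:
            raise ValueError(f"formula needs a '~': {formula!r}")
        rand_parts = re.findall(r"\(([^|()]+)\|([^)]+)\)", rhs)
        fixed_part = re.sub(r"\(([^|()]+)\|([^)]+)\)", "", rhs)
        fixed = tuple(t.strip() for t in fixed_part.split("+")
                      if t.strip() not in ("", "1"))
        random = []
        for terms, group in rand_parts:
            names = [t.strip() for t in terms.split("+") if t.strip()]
            intercept = "0" not in names and "-1" not in names
            slopes = tuple(t for t in names if t not in ("0", "1", "-1"))
            random.append(RandomTerm(group.strip(), intercept, slopes))
        return cls(lhs.strip(), family, fixed, tuple(random), trials)

    @property
    def formula(self) -> str:
        parts = list(self.fixed) if self.fixed else ["1"]
        parts += [rt.formula_part() for rt in self.random]
        return f"{self.response} ~ {' + '.join(parts)}"

    def drop_fixed(self, term: str) -> "ModelSpec":
        return replace(self, fixed=tuple(t for t in self.fixed if t != term))

    def drop_slope(self, group: str, slope: str) -> "ModelSpec":
        new = tuple(replace(rt, slopes=tuple(s for s in rt.slopes if s != slope))
                    if rt.group == group else rt for rt in self.random)
        return replace(self, random=new)

    def drop_group(self, group: str) -> "ModelSpec":
        return replace(self, random=tuple(rt for rt in self.random
                                          if rt.group != group))

    def with_fixed(self, *terms: str) -> "ModelSpec":
        return replace(self, fixed=self.fixed + tuple(t for t in terms
                                                      if t not in self.fixed))


# ---------------------------------------------------------------------------
# families

class _Binomial:
    name = "binomial"
    link_variance = np.pi ** 2 / 3  # logit-scale residual variance (R2)

    @staticmethod
    def linkinv(eta):
        return special.expit(eta)

    @staticmethod
    def irls(eta, y, m, shape):
        mu = np.clip(special.expit(eta), 1e-10, 1 - 1e-10)
        var = mu * (1 - mu)
        w = m * var
        z = eta + (y - mu) / var
        return mu, w, z

    @staticmethod
    def loglik(eta, y, m, shape):
        mu = np.clip(special.expit(eta), 1e-12, 1 - 1e-12)
        x = y * m
        const = special.gammaln(m + 1) - special.gammaln(x + 1) \
            - special.gammaln(m - x + 1)
        return float(np.sum(const + x * np.log(mu) + (m - x) * np.log1p(-mu)))

    @staticmethod
    def pearson(eta, y, m, shape):
        mu = np.clip(special.expit(eta), 1e-10, 1 - 1e-10)
        return m * (y - mu) ** 2 / (mu * (1 - mu))


class _Gamma:
    name = "gamma"

    @staticmethod
    def linkinv(eta):
        return np.exp(eta)

    @staticmethod
    def irls(eta, y, m, shape):
        mu = np.exp(np.clip(eta, -30, 30))
        w = np.full_like(mu, shape)
        z = eta + (y - mu) / mu
        return mu, w, z

    @staticmethod
    def loglik(eta, y, m, shape):
        mu = np.exp(np.clip(eta, -30, 30))
        k = shape
        return float(np.sum(k * np.log(k) - special.gammaln(k)
                            + (k - 1) * np.log(y) - k * np.log(mu) - k * y / mu))

    @staticmethod
    def pearson(eta, y, m, shape):
        mu = np.exp(np.clip(eta, -30, 30))
        return shape * (y - mu) ** 2 / mu ** 2


_FAMILIES = {"binomial": _Binomial, "gamma": _Gamma}


# ---------------------------------------------------------------------------
# design construction

@dataclass
class _REBlock:
    label: str          # e.g. "participant_id:(Intercept)" or "item_id:snr"
    group: str
    level_idx: np.ndarray
    values: np.ndarray  # covariate multiplying the indicator (1 for intercepts)
    n_levels: int


@dataclass
class _Design:
    y: np.ndarray
    m: np.ndarray           # binomial trial counts (1 for gamma/Bernoulli)
    X: np.ndarray
    coef_names: list[str]
    Z: sparse.csr_matrix    # n x q, empty columns allowed when no REs
    blocks: list[_REBlock]
    block_slices: list[slice]


def _build_design(spec: ModelSpec, data: pd.DataFrame) -> _Design:
    df = data.copy()
    y_raw = df[spec.response]
    if y_raw.dtype == object or str(y_raw.dtype) == "boolean":
        y_raw = y_raw.astype("boolean")
    df["_y"] = pd.to_numeric(y_raw, errors="coerce")
    df = df.dropna(subset=["_y"])  # missing responses dropped listwise
    if df.empty:
        raise ValueError("no non-missing responses to fit")
    for col in df.columns:  # patsy cannot sniff pandas nullable dtypes
        dt = df[col].dtype
        if isinstance(dt, pd.BooleanDtype):
            df[col] = df[col].astype("float64")
        elif isinstance(dt, (pd.Float64Dtype, pd.Int64Dtype, pd.Int32Dtype)):
            df[col] = df[col].to_numpy(dtype="float64", na_value=np.nan)

    fixed_formula = "1 + " + " + ".join(spec.fixed) if spec.fixed else "1"
    X_dm = patsy.dmatrix(fixed_formula, df, return_type="dataframe",
                         NA_action=patsy.NAAction(NA_types=[]))
    X = np.asarray(X_dm, dtype=float)
    y = df["_y"].to_numpy(dtype=float)
    m = (df[spec.trials].to_numpy(dtype=float) if spec.trials
         else np.ones(len(df)))

    if spec.family == "binomial":
        if np.any((y < 0) | (y > 1)):
            raise ValueError("binomial response must lie in [0, 1]")
    elif np.any(y <= 0):
        raise ValueError("gamma response must be strictly positive")

    blocks: list[_REBlock] = []
    for rt in spec.random:
        codes, levels = pd.factorize(df[rt.group], sort=True)
        if (codes < 0).any():
            raise ValueError(f"missing values in grouping factor {rt.group!r}")
        n_levels = len(levels)
        if rt.intercept:
            blocks.append(_REBlock(f"{rt.group}:(Intercept)", rt.group,
                                   codes, np.ones(len(df)), n_levels))
        for slope in rt.slopes:
            sl_dm = patsy.dmatrix("1 + " + slope, df, return_type="dataframe",
                                  NA_action=patsy.NAAction(NA_types=[]))
            for col in sl_dm.columns[1:]:
                blocks.append(_REBlock(f"{rt.group}:{col}", rt.group, codes,
                                       sl_dm[col].to_numpy(dtype=float),
                                       n_levels))

    n = len(df)
    offset = 0
    rows, cols, vals = [], [], []
    block_slices = []
    for blk in blocks:
        rows.append(np.arange(n))
        cols.append(offset + blk.level_idx)
        vals.append(blk.values)
        block_slices.append(slice(offset, offset + blk.n_levels))
        offset += blk.n_levels
    if blocks:
        Z = sparse.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, offset))
    else:
        Z = sparse.csr_matrix((n, 0))
    return _Design(y, m, X, list(X_dm.columns), Z, blocks, block_slices)


# ---------------------------------------------------------------------------
# PIRLS + Laplace

def _expand_pvar(design: _Design, sigma2: np.ndarray) -> np.ndarray:
    pvar = np.empty(design.Z.shape[1])
    for s2, sl in zip(sigma2, design.block_slices):
        pvar[sl] = s2
    return pvar


def _pirls(design: _Design, family, shape: float, pvar: np.ndarray,
           start: np.ndarray | None = None,
           max_iter: int = 100, tol: float = 1e-9):
    """Joint penalized IRLS over (beta, u) for fixed variance parameters.

    Random effects are parametrized as ``b = sd * u`` with a unit-normal
    penalty on ``u`` (columns of Z scaled by the block standard deviation),
    which keeps the working system well-conditioned as variances shrink to
    zero.  Returns the joint solution, the linear predictor, the penalized
    log-likelihood, the final working Hessian and a convergence flag.
    """
    X, y, m = design.X, design.y, design.m
    n, p = X.shape
    q = design.Z.shape[1]
    s = np.sqrt(pvar)
    Zs = design.Z.multiply(s[None, :]).tocsr() if q else design.Z
    theta = np.zeros(p + q) if start is None else start.copy()
    if start is None:
        # crude initialization on the link scale
        if family.name == "binomial":
            mu0 = np.clip((y * m + 0.5) / (m + 1), 0.01, 0.99)
            eta = np.log(mu0 / (1 - mu0))
        else:
            eta = np.log(np.maximum(y, 1e-3))
        beta, *_ = np.linalg.lstsq(X, eta, rcond=None)
        theta[:p] = beta

    def eta_of(t):
        return X @ t[:p] + (Zs @ t[p:] if q else 0.0)

    def pll(t, eta):
        pen = 0.5 * float(np.sum(t[p:] ** 2)) if q else 0.0
        return family.loglik(eta, y, m, shape) - pen

    eta = eta_of(theta)
    cur = pll(theta, eta)
    M = None
    converged = False
    for _ in range(max_iter):
        mu, w, z = family.irls(eta, y, m, shape)
        w = np.maximum(w, 1e-12)
        Xw = X * w[:, None]
        A11 = X.T @ Xw
        if q:
            WZ = Zs.multiply(w[:, None])
            A12 = np.asarray((WZ.T @ X).T)
            A22 = (Zs.T @ WZ).toarray()
            A22[np.diag_indices(q)] += 1.0
            M = np.block([[A11, A12], [A12.T, A22]])
            rhs = np.concatenate([Xw.T @ z, np.asarray(WZ.T @ z).ravel()])
        else:
            M = A11
            rhs = Xw.T @ z
        try:
            c, low = linalg.cho_factor(M)
            new = linalg.cho_solve((c, low), rhs)
        except linalg.LinAlgError:
            new = np.linalg.lstsq(M, rhs, rcond=None)[0]
        # step halving on the penalized log-likelihood
        step = 1.0
        for _half in range(25):
            cand = theta + step * (new - theta)
            eta_c = eta_of(cand)
            val = pll(cand, eta_c)
            if np.isfinite(val) and val >= cur - 1e-12:
                break
            step *= 0.5
        delta = val - cur
        theta, eta, cur = cand, eta_c, val
        if abs(delta) < tol * (1.0 + abs(cur)):
            converged = True
            break
    return theta, eta, cur, M, converged


def _laplace_loglik(design: _Design, family, shape, pvar, theta, eta) -> float:
    """Laplace-approximate marginal log-likelihood at the PIRLS solution."""
    p = design.X.shape[1]
    q = design.Z.shape[1]
    ll = family.loglik(eta, design.y, design.m, shape)
    if q == 0:
        return ll
    u = theta[p:]
    ll -= 0.5 * float(np.sum(u ** 2))
    _, w, _ = family.irls(eta, design.y, design.m, shape)
    s = np.sqrt(pvar)
    Zs = design.Z.multiply(s[None, :]).tocsr()
    WZ = Zs.multiply(np.maximum(w, 1e-12)[:, None])
    S = (Zs.T @ WZ).toarray()
    S[np.diag_indices(q)] += 1.0
    sign, logdet = np.linalg.slogdet(S)
    if sign <= 0:
        return -np.inf
    return ll - 0.5 * logdet


# ---------------------------------------------------------------------------
# fitted model

@dataclass
class ModelFit:
    """A fitted GLMM: coefficients, variance components, likelihood, inference."""

    spec: ModelSpec
    coefficients: pd.DataFrame  # term, estimate, se, ci_low, ci_high, p_value
    variance_components: dict[str, float]  # block label -> variance
    shape: float | None
    loglik: float
    aic: float
    n_params: int
    n_obs: int
    converged: bool
    singular: bool
    dispersion_ratio: float = np.nan
    marginal_r2: float = np.nan
    conditional_r2: float = np.nan
    _design: _Design | None = field(default=None, repr=False)
    _eta: np.ndarray | None = field(default=None, repr=False)
    _theta: np.ndarray | None = field(default=None, repr=False)

    @property
    def params(self) -> pd.Series:
        return self.coefficients.set_index("term")["estimate"]


def fit_glmm(spec: ModelSpec, data: pd.DataFrame,
             maxiter: int = 300) -> ModelFit:
    """Fit a GLMM by maximizing the Laplace-approximate likelihood.

    Missing responses are dropped listwise.  Non-convergence and singular
    variance components are flagged on the returned fit, not raised.
    """
    design = _build_design(spec, data)
    family = _FAMILIES[spec.family]
    n_blocks = len(design.blocks)
    is_gamma = spec.family == "gamma"

    # starting shape from a moment estimate on the raw response
    shape0 = 1.0
    if is_gamma:
        cv2 = np.var(design.y) / np.mean(design.y) ** 2
        shape0 = float(np.clip(1.0 / max(cv2, 1e-3), 0.1, 1e3))

    state = {"start": None}

    def objective(params: np.ndarray) -> float:
        sigma2 = np.exp(2.0 * params[:n_blocks])
        shape = float(np.exp(params[n_blocks])) if is_gamma else 1.0
        pvar = _expand_pvar(design, sigma2)
        theta, eta, _, _, ok = _pirls(design, family, shape, pvar,
                                      start=state["start"])
        if ok:
            state["start"] = theta
        ll = _laplace_loglik(design, family, shape, pvar, theta, eta)
        return -ll if np.isfinite(ll) else 1e10

    n_outer = n_blocks + (1 if is_gamma else 0)
    if n_outer:
        x0 = np.concatenate([np.full(n_blocks, np.log(0.3)),
                             [np.log(shape0)] if is_gamma else []])
        res = optimize.minimize(
            objective, x0, method="Nelder-Mead",
            options={"xatol": 1e-4, "fatol": 1e-7, "maxiter": 400 * max(1, n_outer),
                     "maxfev": 400 * max(1, n_outer)})
        xopt = np.clip(res.x, _LOGSD_BOUNDS[0], None)
        outer_ok = bool(res.success) or res.fun < objective(x0)
    else:
        xopt = np.empty(0)
        outer_ok = True

    sigma2 = np.exp(2.0 * xopt[:n_blocks])
    shape = float(np.exp(xopt[n_blocks])) if is_gamma else None
    pvar = _expand_pvar(design, sigma2)
    theta, eta, _, M, inner_ok = _pirls(design, family, shape or 1.0, pvar,
                                        start=state["start"], max_iter=200)
    ll = _laplace_loglik(design, family, shape or 1.0, pvar, theta, eta)

    p = design.X.shape[1]
    try:
        Minv_top = linalg.inv(M)[:p, :p] if M is not None else np.full((p, p), np.nan)
        se = np.sqrt(np.maximum(np.diag(Minv_top), 0.0))
    except linalg.LinAlgError:
        se = np.full(p, np.nan)
    beta = theta[:p]
    zcrit = stats.norm.ppf(0.975)
    with np.errstate(divide="ignore", invalid="ignore"):
        zval = beta / se
    coef = pd.DataFrame({
        "term": design.coef_names,
        "estimate": beta,
        "se": se,
        "ci_low": beta - zcrit * se,
        "ci_high": beta + zcrit * se,
        "p_value": 2.0 * stats.norm.sf(np.abs(zval)),
    })

    k = p + n_blocks + (1 if is_gamma else 0)
    singular = bool(np.any(np.sqrt(sigma2) < _MIN_SD)) if n_blocks else False
    fit = ModelFit(
        spec=spec,
        coefficients=coef,
        variance_components={blk.label: float(s2)
                             for blk, s2 in zip(design.blocks, sigma2)},
        shape=shape,
        loglik=float(ll),
        aic=float(2 * k - 2 * ll),
        n_params=k,
        n_obs=len(design.y),
        converged=bool(outer_ok and inner_ok and np.isfinite(ll)),
        singular=singular,
        _design=design,
        _eta=eta,
        _theta=theta,
    )
    fit.dispersion_ratio = overdispersion_check(fit)[0]
    fit.marginal_r2, fit.conditional_r2 = r2_nakagawa(fit)
    return fit


# ---------------------------------------------------------------------------
# model selection and inference helpers

def _removal_candidates(spec: ModelSpec) -> list[tuple[str, ModelSpec]]:
    cands: list[tuple[str, ModelSpec]] = []
    slope_vars = {s for rt in spec.random for s in rt.slopes}
    for term in spec.fixed:
        if term in slope_vars:
            continue  # a random slope's variable must stay fixed
        # interactions must go before their main effects
        if any(term != other and _is_component(term, other)
               for other in spec.fixed):
            continue
        cands.append((f"fixed:{term}", spec.drop_fixed(term)))
    for rt in spec.random:
        for s in rt.slopes:
            cands.append((f"slope:{s}|{rt.group}", spec.drop_slope(rt.group, s)))
        if rt.intercept and not rt.slopes:
            cands.append((f"intercept:{rt.group}", spec.drop_group(rt.group)))
    return cands


def _is_component(term: str, other: str) -> bool:
    """True when `term` is a main effect contained in interaction `other`."""
    return ":" in other and term in other.split(":")


_SLOPE_REMOVAL_PRIORITY = ("list", "item")  # weakest-identified groups first


def backward_select_aic(full_spec: ModelSpec, data: pd.DataFrame,
                        ) -> tuple[ModelFit, list[dict]]:
    """Backward elimination: drop the single term whose removal lowers AIC most.

    If the full model fails to converge, random slopes are removed first
    (item/list groups before participant) until a converging model is found.
    Ties in AIC (within 1e-9) prefer the simpler model.  The trace records
    every candidate refit.
    """
    trace: list[dict] = []
    spec = full_spec
    fit = fit_glmm(spec, data)
    trace.append({"step": 0, "action": "full", "formula": spec.formula,
                  "aic": fit.aic, "converged": fit.converged})
    # convergence fallback: strip slopes, weakest groups first
    while not fit.converged:
        slopes = [(rt.group, s) for rt in spec.random for s in rt.slopes]
        if not slopes:
            break
        slopes.sort(key=lambda gs: (not any(k in gs[0].lower()
                                            for k in _SLOPE_REMOVAL_PRIORITY)))
        group, s = slopes[0]
        spec = spec.drop_slope(group, s)
        fit = fit_glmm(spec, data)
        trace.append({"step": 0, "action": f"drop-for-convergence:{s}|{group}",
                      "formula": spec.formula, "aic": fit.aic,
                      "converged": fit.converged})

    step = 1
    while True:
        best_label, best_fit = None, None
        for label, cand_spec in _removal_candidates(spec):
            cand = fit_glmm(cand_spec, data)
            trace.append({"step": step, "action": f"try-remove:{label}",
                          "formula": cand_spec.formula, "aic": cand.aic,
                          "converged": cand.converged})
            if not cand.converged:
                continue
            if best_fit is None or cand.aic < best_fit.aic - 1e-9 or (
                    abs(cand.aic - best_fit.aic) <= 1e-9
                    and cand.n_params < best_fit.n_params):
                best_label, best_fit = label, cand
        if best_fit is not None and (
                best_fit.aic < fit.aic - 1e-9
                or (abs(best_fit.aic - fit.aic) <= 1e-9
                    and best_fit.n_params < fit.n_params)):
            spec, fit = best_fit.spec, best_fit
            trace.append({"step": step, "action": f"remove:{best_label}",
                          "formula": spec.formula, "aic": fit.aic,
                          "converged": fit.converged})
            step += 1
        else:
            break
    return fit, trace


def add_interactions_lrt(base_fit: ModelFit, candidate_terms: list[str],
                         data: pd.DataFrame, alpha: float = 0.05,
                         ) -> tuple[ModelFit, dict]:
    """Likelihood-ratio test for interaction terms added to a fitted model.

    Returns the augmented fit together with the chi-square statistic, its
    degrees of freedom (parameter-count difference) and p-value; the
    interactions are "kept" when p < ``alpha``.
    """
    aug_spec = base_fit.spec.with_fixed(*candidate_terms)
    aug_fit = fit_glmm(aug_spec, data)
    df = aug_fit.n_params - base_fit.n_params
    if df < 0:
        raise ValueError("augmented model is not a superset of the base model")
    chi2 = max(0.0, 2.0 * (aug_fit.loglik - base_fit.loglik))
    if df == 0:
        result = {"chi2": 0.0, "df": 0, "p_value": 1.0, "kept": False}
    else:
        p = float(stats.chi2.sf(chi2, df))
        result = {"chi2": float(chi2), "df": int(df), "p_value": p,
                  "kept": p < alpha}
    return aug_fit, result


def _continuous_columns(spec: ModelSpec, data: pd.DataFrame) -> list[str]:
    cols = []
    for col in data.columns:
        if not any(re.search(rf"\b{re.escape(col)}\b", t) for t in spec.fixed):
            continue
        s = data[col]
        if pd.api.types.is_numeric_dtype(s) and not pd.api.types.is_bool_dtype(s) \
                and s.nunique(dropna=True) > 2:
            cols.append(col)
    return cols


def standardized_coefficients(fit: ModelFit, data: pd.DataFrame) -> ModelFit:
    """Refit on a dataset with z-scored continuous predictors.

    Binary dummies and categorical contrasts are left unscaled, and the
    response is untouched (logit/log responses cannot be z-scored), so a
    standardized coefficient is the effect of a one-SD predictor change on
    the link scale.  Zero-variance covariates are left unscaled with a
    warning.
    """
    if not fit.converged:
        warnings.warn("standardizing a non-converged fit")
    df = data.copy()
    for col in _continuous_columns(fit.spec, df):
        sd = df[col].std(ddof=0)
        if not np.isfinite(sd) or sd == 0:
            warnings.warn(f"covariate {col!r} has zero variance; left unscaled")
            continue
        df[col] = (df[col] - df[col].mean()) / sd
    return fit_glmm(fit.spec, df)


def r2_nakagawa(fit: ModelFit) -> tuple[float, float]:
    """Marginal and conditional R2 on the link scale.

    Marginal: variance of the fixed-effect linear predictor over the total
    (fixed + random + family residual) variance; conditional adds the
    random-effect variance to the numerator.  The family residual variance is
    pi^2/3 for the logit link and the trigamma of the shape for the
    Gamma-log family.
    """
    design = fit._design
    if design is None:
        raise ValueError("fit carries no design information")
    p = design.X.shape[1]
    beta = fit._theta[:p]
    var_fixed = float(np.var(design.X @ beta))
    if design.blocks:
        sigma2 = np.array([fit.variance_components[b.label]
                           for b in design.blocks])
        pvar = _expand_pvar(design, sigma2)
        zsq = design.Z.multiply(design.Z)
        var_random = float(np.mean(zsq @ pvar))
    else:
        var_random = 0.0
    if fit.spec.family == "binomial":
        var_resid = _Binomial.link_variance
    else:
        var_resid = float(special.polygamma(1, fit.shape))
    total = var_fixed + var_random + var_resid
    return var_fixed / total, (var_fixed + var_random) / total


def overdispersion_check(fit: ModelFit, threshold: float = 1.5,
                         ) -> tuple[float, bool]:
    """Pearson chi-square over residual degrees of freedom.

    The residual df is ``n - (fixed coefficients + variance parameters)``.
    A ratio above ``threshold`` flags overdispersion relative to the family
    variance function.
    """
    design = fit._design
    if design is None:
        raise ValueError("fit carries no design information")
    family = _FAMILIES[fit.spec.family]
    pearson = float(np.sum(family.pearson(fit._eta, design.y, design.m,
                                          fit.shape or 1.0)))
    df = fit.n_obs - fit.n_params
    ratio = pearson / df if df > 0 else np.nan
    return ratio, bool(ratio > threshold)
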