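"""Smooth additive vital-rate models on person-period data.

Annual reproduction and annual mortality are modelled as binary responses on
one-row-per-female-year data — the discrete-time survival formulation in
which the yearly death indicator regressed on covariates with a logit link
estimates the annual hazard.  Covariate effects of body size and age enter as
penalized regression splines (P-splines: cubic B-spline bases with
second-order difference penalties), grouping factors (colony, year, birth
year, individual) as ridge-penalized dummy blocks — the classical
random-effect-as-penalty equivalence — and reproductive-history covariates
(age at first reproduction, fecundity) as parametric terms.

Smoothing parameters are chosen by minimizing a UBRE-type criterion,
deviance + 2 * gamma * EDF, with the effective degrees of freedom inflated by
``gamma`` (default 1.4) to guard against overfitting; with penalties switched
off and linear terms only the fit reduces exactly to maximum-likelihood
logistic regression.  Model comparison uses AIC on the effective degrees of
freedom of the penalized fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import BSpline
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "SmoothTerm",
    "LinearTerm",
    "RandomTerm",
    "ModelSpec",
    "VitalRateModel",
    "fit_model",
    "select_model",
    "fit_mortality_with_reproduction_costs",
    "sensitivity_excluding_year",
    "predict_rates",
]


# ---------------------------------------------------------------------------
# Model specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SmoothTerm:
    """Penalized spline smooth of one covariate with basis dimension k."""

    name: str
    k: int = 6
    degree: int = 3

    @property
    def label(self) -> str:
        return f"s({self.name})"


@dataclass(frozen=True)
class LinearTerm:
    name: str

    @property
    def label(self) -> str:
        return self.name


@dataclass(frozen=True)
class RandomTerm:
    """Grouping factor fitted as a ridge-penalized dummy block."""

    name: str

    @property
    def label(self) -> str:
        return f"re({self.name})"


@dataclass(frozen=True)
class ModelSpec:
    """Response, terms and fitting settings for one vital-rate model."""

    response: str
    smooth: tuple = ()
    linear: tuple = ()
    random: tuple = ()
    family: str = "binomial"  # or "poisson"
    link: str = "logit"  # or "cloglog" (binomial only)
    gamma: float = 1.4
    select: bool = True  # optimize penalties by UBRE; else use `alpha`
    alpha: float = 1.0  # fixed penalty weight when select=False

    def __post_init__(self):
        object.__setattr__(self, "smooth", tuple(
            t if isinstance(t, SmoothTerm) else SmoothTerm(t) for t in self.smooth))
        object.__setattr__(self, "linear", tuple(
            t if isinstance(t, LinearTerm) else LinearTerm(t) for t in self.linear))
        object.__setattr__(self, "random", tuple(
            t if isinstance(t, RandomTerm) else RandomTerm(t) for t in self.random))
        for t in self.smooth:
            if t.k < 3:
                raise ValueError(f"smooth term {t.name}: k must be >= 3")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.family not in ("binomial", "poisson"):
            raise ValueError(f"unsupported family {self.family!r}")
        if self.family == "poisson" and self.link != "log":
            object.__setattr__(self, "link", "log")

    @property
    def terms(self) -> tuple:
        return self.smooth + self.linear + self.random

    @property
    def n_terms(self) -> int:
        return len(self.terms)


# ---------------------------------------------------------------------------
# Family / link machinery
# ---------------------------------------------------------------------------

class _Family:
    def __init__(self, family: str, link: str):
        self.family = family
        self.link = link

    def linkinv(self, eta):
        if self.link == "logit":
            return 1.0 / (1.0 + np.exp(-eta))
        if self.link == "cloglog":
            return 1.0 - np.exp(-np.exp(np.clip(eta, -30, 30)))
        return np.exp(np.clip(eta, -30, 30))  # log

    def mu_eta(self, eta):
        if self.link == "logit":
            mu = self.linkinv(eta)
            return mu * (1.0 - mu)
        if self.link == "cloglog":
            e = np.clip(eta, -30, 30)
            return np.exp(e - np.exp(e))
        return np.exp(np.clip(eta, -30, 30))

    def variance(self, mu):
        if self.family == "binomial":
            return mu * (1.0 - mu)
        return mu

    def deviance(self, y, mu) -> float:
        eps = 1e-12
        mu = np.clip(mu, eps, None if self.family == "poisson" else 1 - eps)
        if self.family == "binomial":
            with np.errstate(divide="ignore", invalid="ignore"):
                d = (np.where(y > 0, y * np.log(y / mu), 0.0)
                     + np.where(y < 1, (1 - y) * np.log((1 - y) / (1 - mu)), 0.0))
            return float(2.0 * np.sum(d))
        with np.errstate(divide="ignore", invalid="ignore"):
            d = np.where(y > 0, y * np.log(y / mu), 0.0) - (y - mu)
        return float(2.0 * np.sum(d))


# ---------------------------------------------------------------------------
# Design construction
# ---------------------------------------------------------------------------

class _BuiltTerm:
    """A term's realized design block, with its penalty and prediction rule."""

    def __init__(self, label: str, cols, penalized: bool):
        self.label = label
        self.cols = cols
        self.penalized = penalized


class _Design:
    """Assembled model matrix with per-term column slices and penalties."""

    def __init__(self, spec: ModelSpec, data: pd.DataFrame):
        self.spec = spec
        blocks = [np.ones((len(data), 1))]
        self.term_slices: dict[str, slice] = {"(intercept)": slice(0, 1)}
        self.penalties: list[tuple[str, np.ndarray, slice]] = []
        self._smooth_info: dict[str, dict] = {}
        self._random_levels: dict[str, list] = {}
        col = 1
        for t in spec.linear:
            x = data[t.name].to_numpy(dtype=float)[:, None]
            blocks.append(x)
            self.term_slices[t.label] = slice(col, col + 1)
            col += 1
        for t in spec.smooth:
            X, S, info = self._build_smooth(t, data[t.name].to_numpy(dtype=float))
            blocks.append(X)
            sl = slice(col, col + X.shape[1])
            self.term_slices[t.label] = sl
            self.penalties.append((t.label, S, sl))
            self._smooth_info[t.label] = info
            col += X.shape[1]
        self._random_weights: dict[str, np.ndarray] = {}
        for t in spec.random:
            levels = sorted(pd.unique(data[t.name]))
            Z = (data[t.name].to_numpy()[:, None] == np.array(levels)[None, :]).astype(float)
            blocks.append(Z)
            sl = slice(col, col + len(levels))
            self.term_slices[t.label] = sl
            self.penalties.append((t.label, np.eye(len(levels)), sl))
            self._random_levels[t.name] = levels
            self._random_weights[t.name] = Z.mean(axis=0)
            col += len(levels)
        self.X = np.hstack(blocks)
        self.n_coef = col

    @staticmethod
    def _build_smooth(t: SmoothTerm, x: np.ndarray):
        ux = np.unique(x)
        k = t.k
        if k > len(ux):
            warnings.warn(f"smooth {t.name}: k={k} exceeds {len(ux)} unique values; "
                          f"reduced to {len(ux)}")
            k = max(3, len(ux))
        degree = min(t.degree, k - 1)
        n_interior = k - degree - 1
        lo, hi = float(x.min()), float(x.max())
        if hi <= lo:
            raise ValueError(f"smooth {t.name}: covariate is constant")
        if n_interior > 0:
            qs = np.linspace(0, 1, n_interior + 2)[1:-1]
            interior = np.quantile(ux, qs)
        else:
            interior = np.array([])
        knots = np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])
        B = BSpline.design_matrix(np.clip(x, lo, hi), knots, degree).toarray()
        # second-order difference penalty (P-spline)
        D = np.diff(np.eye(k), n=2, axis=0)
        S = D.T @ D
        # absorb the sum-to-zero identifiability constraint
        c = B.mean(axis=0)[None, :]
        _, _, vt = np.linalg.svd(c, full_matrices=True)
        Z = vt[1:, :].T  # k x (k-1) null-space basis of the constraint
        info = {"knots": knots, "degree": degree, "Z": Z, "range": (lo, hi)}
        return B @ Z, Z.T @ S @ Z, info

    def predict_matrix(self, data: pd.DataFrame, include_random: bool = True,
                       flag_extrapolation: bool = False):
        n = len(data)
        X = np.zeros((n, self.n_coef))
        X[:, 0] = 1.0
        extrapolated = np.zeros(n, dtype=bool)
        for t in self.spec.linear:
            X[:, self.term_slices[t.label]] = data[t.name].to_numpy(dtype=float)[:, None]
        for t in self.spec.smooth:
            info = self._smooth_info[t.label]
            x = data[t.name].to_numpy(dtype=float)
            lo, hi = info["range"]
            extrapolated |= (x < lo) | (x > hi)
            B = BSpline.design_matrix(np.clip(x, lo, hi), info["knots"],
                                      info["degree"]).toarray()
            X[:, self.term_slices[t.label]] = B @ info["Z"]
        for t in self.spec.random:
            if include_random and t.name in data.columns:
                levels = self._random_levels[t.name]
                Z = (data[t.name].to_numpy()[:, None]
                     == np.array(levels)[None, :]).astype(float)
                X[:, self.term_slices[t.label]] = Z
            else:
                # population-level prediction: frequency-weighted average level,
                # so shrunken group effects do not bias the marginal rate
                X[:, self.term_slices[t.label]] = self._random_weights[t.name][None, :]
        if flag_extrapolation and extrapolated.any():
            warnings.warn(f"{int(extrapolated.sum())} prediction points lie outside "
                          "the observed covariate support")
        return X, extrapolated


# ---------------------------------------------------------------------------
# Penalized IRLS core
# ---------------------------------------------------------------------------

def _total_penalty(design: _Design, lambdas: np.ndarray) -> np.ndarray:
    S = np.zeros((design.n_coef, design.n_coef))
    for lam, (_, Sj, sl) in zip(lambdas, design.penalties):
        S[sl, sl] += lam * Sj
    return S


def _pirls(X: np.ndarray, y: np.ndarray, S: np.ndarray, fam: _Family,
           beta0: np.ndarray | None = None, max_iter: int = 100,
           tol: float = 1e-10):
    n, p = X.shape
    beta = np.zeros(p) if beta0 is None else beta0.copy()
    dev_old = np.inf
    XtWX = None
    for _ in range(max_iter):
        eta = X @ beta
        mu = fam.linkinv(eta)
        dmu = fam.mu_eta(eta)
        var = np.maximum(fam.variance(mu), 1e-10)
        w = np.maximum(dmu * dmu / var, 1e-10)
        z = eta + (y - mu) / np.maximum(dmu, 1e-10)
        WX = X * w[:, None]
        XtWX = X.T @ WX
        A = XtWX + S
        b = WX.T @ z
        try:
            cf = cho_factor(A + 1e-10 * np.eye(p))
            beta_new = cho_solve(cf, b)
        except np.linalg.LinAlgError:
            beta_new = np.linalg.lstsq(A, b, rcond=None)[0]
        beta = beta_new
        dev = fam.deviance(y, fam.linkinv(X @ beta)) + float(beta @ S @ beta)
        if abs(dev_old - dev) < tol * (abs(dev) + 0.1):
            break
        dev_old = dev
    eta = X @ beta
    mu = fam.linkinv(eta)
    dmu = fam.mu_eta(eta)
    var = np.maximum(fam.variance(mu), 1e-10)
    w = np.maximum(dmu * dmu / var, 1e-10)
    XtWX = (X * w[:, None]).T @ X
    A = XtWX + S
    Vb = np.linalg.inv(A + 1e-10 * np.eye(p))
    F = Vb @ XtWX  # influence of the unpenalized fit: edf = tr(F)
    return beta, Vb, F, fam.deviance(y, mu)


# ---------------------------------------------------------------------------
# Fitted model
# ---------------------------------------------------------------------------

@dataclass
class VitalRateModel:
    """A fitted penalized additive vital-rate model."""

    spec: ModelSpec
    design: _Design = field(repr=False)
    coef: np.ndarray = field(repr=False)
    cov: np.ndarray = field(repr=False)
    lambdas: np.ndarray
    edf_by_term: dict
    edf_total: float
    deviance: float
    null_deviance: float
    n_obs: int
    term_pvalues: dict
    term_stats: dict

    @property
    def deviance_explained(self) -> float:
        if self.null_deviance == 0:
            return 0.0
        return max(0.0, 1.0 - self.deviance / self.null_deviance)

    @property
    def aic(self) -> float:
        return self.deviance + 2.0 * self.edf_total

    def predict(self, newdata: pd.DataFrame, include_random: bool = False,
                response: bool = True, level: float = 0.95,
                flag_extrapolation: bool = True) -> pd.DataFrame:
        """Predicted rates with pointwise intervals (delta method, link scale)."""
        X, extrap = self.design.predict_matrix(newdata, include_random=include_random,
                                               flag_extrapolation=flag_extrapolation)
        eta = X @ self.coef
        se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", X, self.cov, X), 0.0))
        zq = stats.norm.ppf(0.5 + level / 2.0)
        fam = _Family(self.spec.family, self.spec.link)
        if response:
            fit = fam.linkinv(eta)
            lo = fam.linkinv(eta - zq * se)
            hi = fam.linkinv(eta + zq * se)
        else:
            fit, lo, hi = eta, eta - zq * se, eta + zq * se
        return pd.DataFrame({"fit": fit, "lo": lo, "hi": hi,
                             "extrapolated": extrap}, index=newdata.index)

    def summary(self) -> dict:
        """JSON-serializable fit summary."""
        return {
            "response": self.spec.response,
            "family": self.spec.family,
            "link": self.spec.link,
            "terms": [t.label for t in self.spec.terms],
            "lambdas": {lab: float(l) for (lab, _, _), l
                        in zip(self.design.penalties, self.lambdas)},
            "edf": {k: round(float(v), 3) for k, v in self.edf_by_term.items()},
            "edf_total": round(float(self.edf_total), 3),
            "pvalues": {k: (None if v is None else float(v))
                        for k, v in self.term_pvalues.items()},
            "deviance": float(self.deviance),
            "null_deviance": float(self.null_deviance),
            "deviance_explained": round(float(self.deviance_explained), 4),
            "aic": float(self.aic),
            "n_obs": int(self.n_obs),
        }


def _term_tests(spec: ModelSpec, design: _Design, beta, Vb, F):
    """Per-term EDFs and Wald tests on the penalized fit."""
    edf_by_term = {}
    pvalues = {}
    stats_out = {}
    diagF = np.diag(F)
    for t in spec.terms:
        sl = design.term_slices[t.label]
        edf = float(np.sum(diagF[sl]))
        edf_by_term[t.label] = edf
        bj = beta[sl]
        Vj = Vb[sl, sl]
        if isinstance(t, LinearTerm):
            se = float(np.sqrt(max(Vj[0, 0], 0.0)))
            z = float(bj[0] / se) if se > 0 else np.nan
            pvalues[t.label] = float(2 * stats.norm.sf(abs(z)))
            stats_out[t.label] = {"coef": float(bj[0]), "se": se, "z": z}
        elif isinstance(t, SmoothTerm):
            stat = float(bj @ np.linalg.pinv(Vj) @ bj)
            df = max(edf, 1e-3)
            pvalues[t.label] = float(stats.chi2.sf(stat, df))
            stats_out[t.label] = {"chi2": stat, "edf": edf}
        else:  # random term: variance-component style, no test reported
            pvalues[t.label] = None
            stats_out[t.label] = {"edf": edf, "n_levels": sl.stop - sl.start}
    return edf_by_term, pvalues, stats_out


def fit_model(person_period: pd.DataFrame, spec: ModelSpec,
              lambda_grid: np.ndarray | None = None) -> VitalRateModel:
    """Fit one penalized additive vital-rate model.

    When ``spec.select`` is true, smoothing parameters are chosen by
    cyclic-coordinate grid search minimizing deviance + 2 * gamma * EDF;
    otherwise every penalized term uses ``spec.alpha`` (0 disables
    penalization entirely, giving the exact unpenalized ML fit).
    """
    data = person_period
    used = [spec.response] + [t.name for t in spec.smooth + spec.linear]
    bad = [c for c in used if data[c].isna().any()]
    if bad:
        raise ValueError(f"columns contain missing values: {bad}")
    y = data[spec.response].to_numpy(dtype=float)
    if spec.family == "binomial" and (y.min() == y.max()):
        raise ValueError(f"response {spec.response!r} has a single class; "
                         "cannot fit a binomial model")
    fam = _Family(spec.family, spec.link)
    design = _Design(spec, data)
    X = design.X
    n_pen = len(design.penalties)

    # null deviance from the intercept-only fit
    mu0 = np.full_like(y, y.mean())
    null_dev = fam.deviance(y, mu0)

    if n_pen == 0 or not spec.select:
        lambdas = np.full(n_pen, float(spec.alpha))
        beta, Vb, F, dev = _pirls(X, y, _total_penalty(design, lambdas), fam)
    else:
        if lambda_grid is None:
            lambda_grid = 10.0 ** np.arange(-3.0, 7.1, 1.0)
        lambdas = np.ones(n_pen)
        beta = None
        best = None
        for _sweep in range(2):
            for j in range(n_pen):
                for lam in lambda_grid:
                    trial = lambdas.copy()
                    trial[j] = lam
                    b, Vb_t, F_t, dev_t = _pirls(
                        X, y, _total_penalty(design, trial), fam, beta0=beta)
                    score = dev_t + 2.0 * spec.gamma * float(np.trace(F_t))
                    if best is None or score < best[0] - 1e-9:
                        best = (score, trial.copy(), b, Vb_t, F_t, dev_t)
                lambdas = best[1].copy()
                beta = best[2]
        _, lambdas, beta, Vb, F, dev = best

    edf_total = float(np.trace(F))
    edf_by_term, pvalues, term_stats = _term_tests(spec, design, beta, Vb, F)
    return VitalRateModel(spec=spec, design=design, coef=beta, cov=Vb,
                          lambdas=lambdas, edf_by_term=edf_by_term,
                          edf_total=edf_total, deviance=dev,
                          null_deviance=null_dev, n_obs=len(y),
                          term_pvalues=pvalues, term_stats=term_stats)


# ---------------------------------------------------------------------------
# Higher-level operations
# ---------------------------------------------------------------------------

def select_model(person_period: pd.DataFrame,
                 candidate_specs: list[ModelSpec]) -> list[tuple[ModelSpec, VitalRateModel]]:
    """Fit all candidate specs and rank them by AIC (ties: fewer terms)."""
    if not candidate_specs:
        raise ValueError("need at least one candidate specification")
    fits = [(spec, fit_model(person_period, spec)) for spec in candidate_specs]
    return sorted(fits, key=lambda sm: (round(sm[1].aic, 6), sm[0].n_terms))


def fit_mortality_with_reproduction_costs(
        person_period: pd.DataFrame, k: int = 6,
        random: tuple = ("colony_id", "year"),
        include_size: bool = True, select: bool = True,
        gamma: float = 1.4, alpha: float = 1.0,
        fecundity_mode: str = "lifetime") -> VitalRateModel:
    """Cost-of-reproduction mortality model on the restricted cohort.

    Restricts to complete lives that reproduced at least once (fecundity is a
    realized lifetime rate and AFR is defined), then fits the annual death
    indicator on smooths of age and size plus parametric AFR and fecundity.
    The size smooth's p-value reports whether size retains a direct effect
    once the reproductive covariates are included.

    ``fecundity_mode="lifetime"`` attaches the completed-life fecundity (LRS
    per breeding season) as a fixed covariate; ``"to_date"`` uses the
    offspring-per-season rate realized up to each person-year, the causally
    ordered alternative.
    """
    sub = person_period.loc[person_period["complete_life"].astype(bool)
                            & (person_period["afr_covariate"] > 0)]
    if len(sub) == 0:
        raise ValueError("restricted cohort (complete lives that reproduced) is empty")
    if fecundity_mode == "lifetime":
        fec = "fecundity_covariate"
    elif fecundity_mode == "to_date":
        fec = "fecundity_to_date"
    else:
        raise ValueError(f"unknown fecundity_mode {fecundity_mode!r}")
    smooths = [SmoothTerm("age", k=k)]
    if include_size:
        smooths.append(SmoothTerm("size_centered", k=k))
    spec = ModelSpec(response="died", smooth=tuple(smooths),
                     linear=("afr_covariate", fec),
                     random=tuple(random), gamma=gamma, select=select,
                     alpha=alpha)
    return fit_model(sub, spec)


@dataclass
class SensitivityResult:
    """Refit comparison after excluding one calendar year."""

    excluded_year: int
    n_removed: int
    full: VitalRateModel
    reduced: VitalRateModel
    linear_coef_delta: dict
    pvalue_delta: dict


def sensitivity_excluding_year(person_period: pd.DataFrame, year: int,
                               spec: ModelSpec) -> SensitivityResult:
    """Refit ``spec`` with one calendar year removed and report the deltas."""
    if year not in set(person_period["year"]):
        raise ValueError(f"year {year} not present in the person-period table")
    mask = person_period["year"] != year
    full = fit_model(person_period, spec)
    reduced = fit_model(person_period.loc[mask], spec)
    coef_delta = {}
    for t in spec.linear:
        lab = t.label if isinstance(t, LinearTerm) else t
        coef_delta[lab] = (reduced.term_stats[lab]["coef"]
                           - full.term_stats[lab]["coef"])
    p_delta = {lab: ((reduced.term_pvalues[lab] - full.term_pvalues[lab])
                     if full.term_pvalues[lab] is not None else None)
               for lab in full.term_pvalues}
    return SensitivityResult(excluded_year=year,
                             n_removed=int((~mask).sum()),
                             full=full, reduced=reduced,
                             linear_coef_delta=coef_delta, pvalue_delta=p_delta)


def predict_rates(model: VitalRateModel, size_grid, age_grid,
                  fixed: dict | None = None,
                  size_col: str = "size_centered",
                  age_col: str = "age") -> pd.DataFrame:
    """Response-scale probability surface over a size x age grid.

    Other covariates are held at the supplied ``fixed`` values (grouping
    factors are excluded: predictions are population-level).  Points outside
    the observed covariate support are flagged.
    """
    size_grid = np.asarray(size_grid, dtype=float)
    age_grid = np.asarray(age_grid, dtype=float)
    ss, aa = np.meshgrid(size_grid, age_grid, indexing="ij")
    newdata = pd.DataFrame({size_col: ss.ravel(), age_col: aa.ravel()})
    for name, val in (fixed or {}).items():
        newdata[name] = val
    pred = model.predict(newdata, include_random=False, response=True)
    out = pd.DataFrame({
        size_col: newdata[size_col],
        age_col: newdata[age_col],
        "rate": pred["fit"],
        "lo": pred["lo"],
        "hi": pred["hi"],
        "extrapolated": pred["extrapolated"],
    })
    return out
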