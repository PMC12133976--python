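"""Gamma log-link mixed models with crossed random intercepts.

Home-range areas are positive and right-skewed, so they are modelled as
Gamma(shape alpha, mean mu) with log mu = X beta + Z b, where b collects
independent random intercepts for site and year (crossed factors).  The
marginal likelihood is approximated by the Laplace method: an inner penalized
Newton (IRLS) step jointly profiles the fixed effects and random-effect modes,
and an outer derivative-free optimization runs over (log sigma_site,
log sigma_year, log shape).  In the zero-variance limit the fit reduces to an
ordinary gamma GLM.

Categorical coding is treatment contrasts with female and forest as reference
levels, so positive sex and habitat coefficients read as "larger than a
female in forest".  Continuous predictors can be standardized internally for
conditioning of the three-way interaction; predictions accept original-scale
covariates either way.

The module also provides the 12-model candidate ladder, Akaike-weight model
comparison, a per-term Wald chi-square deviance table, Tukey-style habitat
contrasts with a compact letter display, and delta-method prediction curves.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
from scipy import optimize, stats
from scipy.special import gammaln

logger = logging.getLogger(__name__)

SEX_REFERENCE = "female"
HABITAT_REFERENCE = "forest"
HABITAT_LEVELS = ("forest", "grassland", "shrubland")

MAIN_TERMS = ("sex", "condition", "habitat", "latitude", "density")

#: Table rows of the full model, in reporting order.
FULL_MODEL_TERMS = MAIN_TERMS + (
    "sex:condition",
    "habitat:latitude",
    "latitude:density",
    "habitat:density",
    "habitat:latitude:density",
)


class ConvergenceError(RuntimeError):
    """Raised when the mixed-model fit fails to converge.

    Carries the best iterate and its gradient norm for inspection.
    """

    def __init__(self, msg, params=None, grad_norm=None):
        super().__init__(msg)
        self.params = params
        self.grad_norm = grad_norm


@dataclass(frozen=True)
class ModelSpec:
    """Fixed-effect structure of one candidate model (random intercepts for
    site and year are always included)."""
    name: str
    fixed_terms: tuple[str, ...]

    def __post_init__(self):
        for t in self.fixed_terms:
            for factor in t.split(":"):
                if factor not in MAIN_TERMS:
                    raise ValueError(f"unknown factor {factor!r} in term {t!r}")
            if ":" in t:
                self._check_marginality(t)

    def _check_marginality(self, term: str):
        factors = term.split(":")
        from itertools import combinations
        for r in range(1, len(factors)):
            for sub in combinations(factors, r):
                cand = ":".join(sub)
                if not any(set(cand.split(":")) == set(ft.split(":"))
                           for ft in self.fixed_terms):
                    raise ValueError(
                        f"term {term!r} requires lower-order term {cand!r}")


def build_model_set() -> list[ModelSpec]:
    """The 12-model candidate ladder.

    From intercept-only through main effects, the biologically motivated
    two-way interactions (sex x condition; habitat x latitude; latitude x
    density; habitat x density) singly and in combination, up to the full
    model adding the latitude x habitat x density three-way term.
    """
    mains = MAIN_TERMS
    specs = [
        ModelSpec("m01_intercept", ()),
        ModelSpec("m02_mains", mains),
        ModelSpec("m03_sex_cond", mains + ("sex:condition",)),
        ModelSpec("m04_hab_lat", mains + ("habitat:latitude",)),
        ModelSpec("m05_lat_den", mains + ("latitude:density",)),
        ModelSpec("m06_hab_den", mains + ("habitat:density",)),
        ModelSpec("m07_sexcond_hablat", mains + ("sex:condition", "habitat:latitude")),
        ModelSpec("m08_sexcond_latden", mains + ("sex:condition", "latitude:density")),
        ModelSpec("m09_sexcond_habden", mains + ("sex:condition", "habitat:density")),
        ModelSpec("m10_env2way", mains + ("habitat:latitude", "latitude:density",
                                          "habitat:density")),
        ModelSpec("m11_all2way", mains + ("sex:condition", "habitat:latitude",
                                          "latitude:density", "habitat:density")),
        ModelSpec("m12_full", FULL_MODEL_TERMS),
    ]
    assert len(specs) == 12
    return specs


# ---------------------------------------------------------------------------
# design matrices

def _base_columns(df: pd.DataFrame, scaler: dict) -> dict[str, np.ndarray]:
    cols = {}
    sex = df["sex"].astype(str).str.lower()
    cols["sex[male]"] = (sex == "male").to_numpy(float)
    hab = df["habitat"].astype(str).str.lower()
    for lev in HABITAT_LEVELS[1:]:
        cols[f"habitat[{lev}]"] = (hab == lev).to_numpy(float)
    for cont in ("condition", "latitude", "density"):
        c, s = scaler.get(cont, (0.0, 1.0))
        cols[cont] = (df[cont].to_numpy(float) - c) / s
    return cols


_TERM_COLUMNS = {
    "sex": ("sex[male]",),
    "condition": ("condition",),
    "habitat": ("habitat[grassland]", "habitat[shrubland]"),
    "latitude": ("latitude",),
    "density": ("density",),
}


def _term_column_names(term: str) -> list[str]:
    parts = [_TERM_COLUMNS[f] for f in term.split(":")]
    out = [[]]
    for group in parts:
        out = [prev + [g] for prev in out for g in group]
    return [":".join(combo) for combo in out]


def build_design(df: pd.DataFrame, spec: ModelSpec,
                 scaler: dict | None = None) -> tuple[np.ndarray, list[str], dict]:
    """Design matrix, column names, and term -> column-index mapping.

    ``scaler`` maps each continuous predictor to a (center, scale) pair
    applied before products are formed; identity when omitted.
    """
    scaler = scaler or {}
    base = _base_columns(df, scaler)
    names = ["(Intercept)"]
    cols = [np.ones(len(df))]
    term_slices: dict[str, list[int]] = {}
    for term in spec.fixed_terms:
        idxs = []
        for cname in _term_column_names(term):
            parts = cname.split(":")
            col = base[parts[0]].copy()
            for p in parts[1:]:
                col = col * base[p]
            idxs.append(len(names))
            names.append(cname)
            cols.append(col)
        term_slices[term] = idxs
    X = np.column_stack(cols)
    return X, names, term_slices


def make_scaler(df: pd.DataFrame) -> dict:
    """Center/scale parameters for the continuous predictors."""
    out = {}
    for cont in ("condition", "latitude", "density"):
        v = df[cont].to_numpy(float)
        s = v.std(ddof=1)
        out[cont] = (float(v.mean()), float(s if s > 0 else 1.0))
    return out


# ---------------------------------------------------------------------------
# fitting

@dataclass
class GlmmFit:
    """A converged gamma log-link mixed-model fit."""
    spec: ModelSpec
    coef: pd.Series                      # fixed effects, log scale
    cov: pd.DataFrame = field(repr=False)  # Wald covariance of fixed effects
    sigma_site: float
    sigma_year: float
    shape: float
    loglik: float
    aic: float
    n_obs: int
    term_slices: dict = field(repr=False)
    scaler: dict = field(repr=False)
    ranef: dict = field(repr=False)      # factor -> pd.Series of modes
    covariate_ranges: dict = field(repr=False)
    converged: bool = True
    grad_norm: float = np.nan

    @property
    def n_fixed(self) -> int:
        return len(self.coef)

    def wald_ci(self, level: float = 0.95) -> pd.DataFrame:
        z = stats.norm.ppf(0.5 + level / 2.0)
        se = np.sqrt(np.diag(self.cov.to_numpy()))
        return pd.DataFrame({
            "estimate": self.coef, "se": se,
            "lo": self.coef - z * se, "hi": self.coef + z * se,
        })


def _inner_newton(y, U, p, dinv, alpha, start, max_iter=200, tol=1e-9):
    """Penalized Newton over stacked (beta, b); returns modes and Hessian."""
    n = len(y)
    pen = np.concatenate([np.zeros(p), dinv])
    th = start.copy()
    logy = np.log(y)

    def pll(t):
        eta = U @ t
        return alpha * np.sum(-eta - y * np.exp(-eta)) - 0.5 * np.sum(pen * t * t)

    H = None
    grad_norm = np.inf
    for _ in range(max_iter):
        eta = U @ th
        r = y * np.exp(-eta)
        w = alpha * r
        g = alpha * (r - 1.0)
        grad = U.T @ g - pen * th
        grad_norm = np.max(np.abs(grad))
        if grad_norm < tol * max(1.0, alpha * np.sqrt(n)):
            break
        H = (U.T * w) @ U
        H[np.diag_indices_from(H)] += pen
        try:
            delta = sla.solve(H, grad, assume_a="pos")
        except sla.LinAlgError:
            H[np.diag_indices_from(H)] += 1e-8 * H.diagonal().mean()
            delta = sla.solve(H, grad, assume_a="pos")
        f0 = pll(th)
        step = 1.0
        while step > 1e-12:
            cand = th + step * delta
            if pll(cand) >= f0 - 1e-10 * abs(f0):
                break
            step *= 0.5
        th = th + step * delta
    eta = U @ th
    w = alpha * y * np.exp(-eta)
    H = (U.T * w) @ U
    H[np.diag_indices_from(H)] += pen
    _ = logy
    return th, H, grad_norm


def _laplace_loglik(y, U, p, ns, ny_, params, start):
    """Profile Laplace log-likelihood at (log sig_site, log sig_year, log shape)."""
    ls, ly, la = params
    alpha = np.exp(la)
    dinv = np.concatenate([np.full(ns, np.exp(-2.0 * ls)),
                           np.full(ny_, np.exp(-2.0 * ly))])
    th, H, gn = _inner_newton(y, U, p, dinv, alpha, start)
    eta = U @ th
    b = th[p:]
    ll_cond = np.sum(alpha * la - gammaln(alpha) + (alpha - 1.0) * np.log(y)
                     - alpha * eta - alpha * y * np.exp(-eta))
    Hbb = H[p:, p:]
    sign, logdetH = np.linalg.slogdet(Hbb)
    if sign <= 0:
        return -np.inf, th, H, gn
    logdetD = 2.0 * ns * ls + 2.0 * ny_ * ly
    ll = ll_cond - 0.5 * np.sum(dinv * b * b) - 0.5 * logdetD - 0.5 * logdetH
    return ll, th, H, gn


def fit_glmm(df: pd.DataFrame, spec: ModelSpec,
             response: str = "area50_m2",
             site_col: str = "site_id", year_col: str = "year",
             standardize: bool = True,
             fix_variances: tuple[float, float] | None = None,
             grad_tol: float = 1e-4) -> GlmmFit:
    """Fit one candidate model by Laplace-approximated maximum likelihood.

    ``df`` must be complete-case with a strictly positive response.  With
    ``standardize`` the continuous predictors are centered and scaled before
    interaction products are formed (the scaler is stored on the fit and
    applied transparently in prediction).  ``fix_variances`` pins
    (sigma_site, sigma_year), e.g. ``(0, 0)`` for the GLM limit.
    """
    y = df[response].to_numpy(float)
    if np.any(~np.isfinite(y)) or np.any(y <= 0):
        bad = np.where(~np.isfinite(y) | (y <= 0))[0]
        raise ValueError(f"non-positive/missing response in rows {bad[:10].tolist()}")
    need = {f for t in spec.fixed_terms for f in t.split(":")}
    for c in need:
        if df[c].isna().any():
            raise ValueError(f"missing values in predictor {c!r}: complete cases only")

    scaler = make_scaler(df) if standardize else {}
    X, names, term_slices = build_design(df, spec, scaler)
    site_codes, sites = pd.factorize(df[site_col], sort=True)
    year_codes, years = pd.factorize(df[year_col], sort=True)
    ns, nyr = len(sites), len(years)
    if ns < 2 or nyr < 2:
        raise ValueError("need >= 2 levels in each random factor")
    n, p = X.shape
    Z = np.zeros((n, ns + nyr))
    Z[np.arange(n), site_codes] = 1.0
    Z[np.arange(n), ns + year_codes] = 1.0
    U = np.hstack([X, Z])

    # moment start: log-scale OLS for beta, log dispersion for shape
    logy = np.log(y)
    beta0, *_ = np.linalg.lstsq(X, logy, rcond=None)
    resid = logy - X @ beta0
    alpha0 = max(0.5, 1.0 / max(resid.var(), 1e-3))
    start_th = [np.concatenate([beta0, np.zeros(ns + nyr)])]

    def obj(params):
        ll, th, H, gn = _laplace_loglik(y, U, p, ns, nyr, params, start_th[0])
        if np.isfinite(ll):
            start_th[0] = th
        return -ll

    if fix_variances is not None:
        ss, sy = fix_variances
        ls = np.log(max(ss, 1e-4))
        lyv = np.log(max(sy, 1e-4))

        def obj1(la):
            return obj([ls, lyv, la[0]])

        res = optimize.minimize(obj1, [np.log(alpha0)], method="Nelder-Mead",
                                options=dict(xatol=1e-6, fatol=1e-8, maxiter=200))
        params = np.array([ls, lyv, res.x[0]])
    else:
        x0 = np.array([np.log(0.3), np.log(0.3), np.log(alpha0)])
        res = optimize.minimize(
            obj, x0, method="Nelder-Mead",
            bounds=[(-7.0, 3.0), (-7.0, 3.0), (-4.0, 8.0)],
            options=dict(xatol=1e-4, fatol=1e-7, maxiter=600, adaptive=True))
        params = res.x
        if not res.success and res.fun == np.inf:
            raise ConvergenceError("outer optimization failed", params=res.x)

    ll, th, H, gn = _laplace_loglik(y, U, p, ns, nyr, params, start_th[0])
    if gn > grad_tol * max(1.0, np.exp(params[2]) * np.sqrt(n)):
        raise ConvergenceError(
            f"inner gradient norm {gn:.3g} above tolerance", params=th, grad_norm=gn)
    Hinv = np.linalg.inv(H)
    cov_beta = Hinv[:p, :p]
    sigma_site, sigma_year, shape = np.exp(params)
    if fix_variances is not None:
        sigma_site, sigma_year = fix_variances
    k = p + 2 + 1  # fixed effects + two variance components + gamma shape
    fit = GlmmFit(
        spec=spec,
        coef=pd.Series(th[:p], index=names),
        cov=pd.DataFrame(cov_beta, index=names, columns=names),
        sigma_site=float(sigma_site), sigma_year=float(sigma_year),
        shape=float(shape), loglik=float(ll), aic=float(-2.0 * ll + 2.0 * k),
        n_obs=n, term_slices=term_slices, scaler=scaler,
        ranef={"site": pd.Series(th[p:p + ns], index=sites),
               "year": pd.Series(th[p + ns:], index=years)},
        covariate_ranges={c: (float(df[c].min()), float(df[c].max()))
                          for c in ("condition", "latitude", "density")
                          if c in df and df[c].notna().any()},
        grad_norm=float(gn),
    )
    return fit


# ---------------------------------------------------------------------------
# model comparison and inference

def aic_weights(fits: list[GlmmFit] | pd.Series | np.ndarray) -> pd.DataFrame:
    """Akaike weights: w_i = exp(-dAIC_i/2) / sum_j exp(-dAIC_j/2)."""
    if len(fits) and isinstance(fits[0], GlmmFit):
        names = [f.spec.name for f in fits]
        aics = np.array([f.aic for f in fits], float)
    else:
        aics = np.asarray(fits, float)
        names = [f"model{i + 1}" for i in range(len(aics))]
    if len(aics) < 2:
        raise ValueError("need at least two fits to compare")
    d = aics - aics.min()
    w = np.exp(-d / 2.0)
    w /= w.sum()
    out = pd.DataFrame({"model": names, "aic": aics, "delta_aic": d, "weight": w})
    return out.sort_values("aic", kind="stable").reset_index(drop=True)


def wald_anova(fit: GlmmFit) -> pd.DataFrame:
    """Per-term Wald chi-square deviance table.

    For each fixed-effect term T, chi2 = b_T' V_T^-1 b_T over the term's
    coefficient block with df = block size; p from the upper chi-square tail.
    A singular block falls back to the pseudo-inverse with df reduced to the
    block's numerical rank (warned).
    """
    rows = []
    beta = fit.coef.to_numpy()
    V = fit.cov.to_numpy()
    for term, idxs in fit.term_slices.items():
        b = beta[idxs]
        Vt = V[np.ix_(idxs, idxs)]
        dfree = len(idxs)
        try:
            chi2 = float(b @ sla.solve(Vt, b, assume_a="pos"))
        except sla.LinAlgError:
            warnings.warn(f"singular covariance block for term {term!r}; "
                          "using rank-adjusted test")
            Vp = np.linalg.pinv(Vt)
            chi2 = float(b @ Vp @ b)
            dfree = int(np.linalg.matrix_rank(Vt))
        rows.append({"term": term, "chisq": chi2, "df": dfree,
                     "p_value": float(stats.chi2.sf(chi2, dfree))})
    return pd.DataFrame(rows)


def _reference_row(fit: GlmmFit, habitat: str, overrides: dict | None = None) -> np.ndarray:
    """Design row at covariate means (standardized: 0), sex balanced at 0.5."""
    base = {
        "sex[male]": 0.5,
        "habitat[grassland]": 1.0 if habitat == "grassland" else 0.0,
        "habitat[shrubland]": 1.0 if habitat == "shrubland" else 0.0,
        "condition": 0.0, "latitude": 0.0, "density": 0.0,
    }
    if overrides:
        base.update(overrides)
    row = np.zeros(fit.n_fixed)
    for i, name in enumerate(fit.coef.index):
        if name == "(Intercept)":
            row[i] = 1.0
        else:
            v = 1.0
            for part in name.split(":"):
                v *= base[part]
            row[i] = v
    return row


def _single_step_adjust(z: np.ndarray, R: np.ndarray) -> np.ndarray:
    """Single-step multivariate-normal (Tukey-style) adjusted p-values."""
    mvn = stats.multivariate_normal(mean=np.zeros(len(z)), cov=R,
                                    allow_singular=True)
    out = []
    for zi in np.abs(z):
        inside = mvn.cdf(np.full(len(z), zi), lower_limit=np.full(len(z), -zi))
        out.append(min(1.0, max(0.0, 1.0 - float(inside))))
    return np.asarray(out)


def _letter_display(levels, differ) -> dict[str, str]:
    """Compact letter display: levels sharing a letter are not distinguishable."""
    groups: list[set] = []
    for lev in levels:
        placed = False
        for g in groups:
            if all(not differ(lev, other) for other in g):
                g.add(lev)
                placed = True
        if not placed:
            groups.append({lev})
    letters = {lev: "" for lev in levels}
    for g, letter in zip(groups, "abcdefgh"):
        for lev in g:
            letters[lev] += letter
    return letters


def habitat_contrasts(fit: GlmmFit, alpha_level: float = 0.05) -> pd.DataFrame:
    """Pairwise habitat comparisons of adjusted means on the link scale.

    Covariates sit at their means (standardized zero), sex is balanced, and
    random effects at zero; z-tests are adjusted single-step over the three
    pairwise contrasts, and a compact letter display marks groups that do not
    differ at ``alpha_level``.
    """
    if "habitat" not in fit.term_slices:
        raise ValueError("habitat is not in the fitted model")
    rows = {h: _reference_row(fit, h) for h in HABITAT_LEVELS}
    pairs = [("grassland", "forest"), ("shrubland", "forest"),
             ("grassland", "shrubland")]
    L = np.vstack([rows[a] - rows[b] for a, b in pairs])
    V = fit.cov.to_numpy()
    est = L @ fit.coef.to_numpy()
    covL = L @ V @ L.T
    se = np.sqrt(np.diag(covL))
    z = est / se
    R = covL / np.outer(se, se)
    p_adj = _single_step_adjust(z, R)
    tab = pd.DataFrame({
        "contrast": [f"{a} - {b}" for a, b in pairs],
        "estimate": est, "se": se, "z": z, "p_adjusted": p_adj,
    })
    sig = {frozenset(pair): p < alpha_level for pair, p in zip(pairs, p_adj)}

    def differ(a, b):
        return sig.get(frozenset((a, b)), False)

    letters = _letter_display(HABITAT_LEVELS, differ)
    tab.attrs["letters"] = letters
    return tab


def predict_response(fit: GlmmFit, newdata: pd.DataFrame,
                     level: float = 0.95) -> pd.DataFrame:
    """Expected areas (m^2) with delta-method intervals at random effects 0.

    ``newdata`` carries original-scale covariates (sex, condition, habitat,
    latitude, density as needed by the model); the fit's internal scaler is
    applied.  Requests outside the fitted covariate ranges trigger an
    extrapolation warning.
    """
    for c, (lo, hi) in fit.covariate_ranges.items():
        if c in newdata:
            v = newdata[c].to_numpy(float)
            if np.nanmin(v) < lo - 1e-9 or np.nanmax(v) > hi + 1e-9:
                warnings.warn(f"prediction grid extrapolates beyond the fitted "
                              f"range of {c} [{lo:.3g}, {hi:.3g}]")
    spec = fit.spec
    nd = newdata.copy()
    for c in ("sex", "habitat", "condition", "latitude", "density"):
        if c not in nd:
            nd[c] = {"sex": SEX_REFERENCE, "habitat": HABITAT_REFERENCE}.get(c, 0.0)
    X, names, _ = build_design(nd, spec, fit.scaler)
    assert names == list(fit.coef.index)
    eta = X @ fit.coef.to_numpy()
    se = np.sqrt(np.einsum("ij,jk,ik->i", X, fit.cov.to_numpy(), X))
    zq = stats.norm.ppf(0.5 + level / 2.0)
    out = newdata.copy()
    out["mu"] = np.exp(eta)
    out["lo"] = np.exp(eta - zq * se)
    out["hi"] = np.exp(eta + zq * se)
    return out


def latitude_tertile_points(latitudes: np.ndarray) -> dict[str, float]:
    """Representative low/mid/high latitudes (tertile midpoints) for slicing
    prediction curves by latitude."""
    q = np.quantile(np.asarray(latitudes, float), [1 / 6, 0.5, 5 / 6])
    return {"low": float(q[0]), "mid": float(q[1]), "high": float(q[2])}
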