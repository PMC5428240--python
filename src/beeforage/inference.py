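"""Candidate-model comparison with AICc and colony random intercepts.

The analysis asks which covariate best predicts each per-bee response,
and whether adding learning performance (LPI) to that best model is
warranted.  Five responses are modelled, each with colony membership as
a random intercept:

* ``nectar_rate``, ``pollen_rate`` — Gaussian, identity scale;
* ``mean_bouts_per_day``, ``mean_bout_duration`` — Gaussian on the
  square-root scale (stabilises the right skew);
* ``days_foraged`` — Poisson with log link (count of foraging days,
  foragers only).

Model building is bottom-up: a basic model (intercept + colony random
intercept) is compared by AICc against single-covariate models; LPI is
then added to the best of these, and is judged predictive only if it
lowers AICc by more than 2.

All models are fitted by maximum likelihood (not REML), because AICc
comparisons across different fixed-effect structures are only valid on
the full likelihood.  The Gaussian mixed model uses the closed-form
marginal likelihood with GLS profiling of the fixed effects; the
Poisson mixed model integrates the random intercept by adaptive
Gauss-Hermite quadrature.  The parameter count ``k`` includes variance
components (fixed effects + random-intercept variance, plus the
residual variance for Gaussian families).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln, logsumexp
from statsmodels.tools.numdiff import approx_hess1

logger = logging.getLogger(__name__)

GAUSSIAN_IDENTITY = "gaussian_identity"
GAUSSIAN_SQRT = "gaussian_sqrt"
POISSON_LOG = "poisson_log"

FAMILY_BY_RESPONSE = {
    "nectar_rate": GAUSSIAN_IDENTITY,
    "pollen_rate": GAUSSIAN_IDENTITY,
    "mean_bouts_per_day": GAUSSIAN_SQRT,
    "mean_bout_duration": GAUSSIAN_SQRT,
    "days_foraged": POISSON_LOG,
}

#: candidate fixed effects per response (efficiency responses also get
#: experience; the activity responses do not)
CANDIDATES_BY_RESPONSE = {
    "nectar_rate": ("colony_age", "worker_age", "worker_mass", "experience"),
    "pollen_rate": ("colony_age", "worker_age", "worker_mass", "experience"),
    "days_foraged": ("colony_age", "worker_age", "worker_mass"),
    "mean_bouts_per_day": ("colony_age", "worker_age", "worker_mass"),
    "mean_bout_duration": ("colony_age", "worker_age", "worker_mass"),
}

DELTA_AICC_RULE = 2.0

_LOG2PI = math.log(2.0 * math.pi)


class EstimationError(Exception):
    """Raised when a model cannot be estimated on the given data."""


def aicc(log_likelihood: float, k: int, n: int) -> float:
    """Small-sample corrected Akaike information criterion.

    AICc = -2*ll + 2k + 2k(k+1)/(n - k - 1); requires n > k + 1.
    """
    if n <= k + 1:
        raise EstimationError(f"AICc undefined for n={n}, k={k} (need n > k + 1)")
    return -2.0 * log_likelihood + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


# ---------------------------------------------------------------------------
# model specification

@dataclass(frozen=True)
class ModelSpec:
    response: str
    fixed_effects: tuple[str, ...] = ()
    family: str = ""
    random_intercept: str = "colony_id"

    def __post_init__(self) -> None:
        if not self.family:
            object.__setattr__(self, "family", FAMILY_BY_RESPONSE[self.response])

    @property
    def name(self) -> str:
        return " + ".join(self.fixed_effects) if self.fixed_effects else "basic"


@dataclass
class FittedModel:
    spec: ModelSpec
    loglik: float
    params: pd.Series          # intercept + fixed-effect estimates
    bse: pd.Series
    k: int                     # fixed effects + variance components
    n: int
    re_var: float              # colony random-intercept variance
    resid_var: float | None    # Gaussian families only
    converged: bool = True
    singular: bool = False     # random-effect variance collapsed to 0

    @property
    def aicc(self) -> float:
        return aicc(self.loglik, self.k, self.n)


def _design(data: pd.DataFrame, spec: ModelSpec):
    y = data[spec.response].to_numpy(dtype=float)
    if spec.family == GAUSSIAN_SQRT:
        if np.any(y < 0):
            raise EstimationError(f"{spec.response}: negative values under sqrt transform")
        y = np.sqrt(y)
    cols = ["intercept", *spec.fixed_effects]
    X = np.column_stack([np.ones(len(data))] +
                        [data[c].to_numpy(dtype=float) for c in spec.fixed_effects])
    groups = data[spec.random_intercept].to_numpy()
    return y, X, cols, groups


# ---------------------------------------------------------------------------
# Gaussian linear mixed model, ML

def _gaussian_profile_ll(lam: float, y, X, group_idx, sizes):
    """Profile log-likelihood over beta and resid variance at ratio lam.

    lam = re_var / resid_var.  V_g = I + lam * J per group; its inverse
    is I - lam/(1 + lam*m) * J, so weighted cross-products reduce to
    group sums.
    """
    n, p = X.shape
    shrink = lam / (1.0 + lam * sizes)          # per group
    # V^-1 A = A - shrink * 1 (1'A) per group
    XtVX = X.T @ X
    XtVy = X.T @ y
    logdet = float(np.sum(np.log1p(lam * sizes)))
    for g, m in enumerate(sizes):
        mask = group_idx == g
        sx = X[mask].sum(axis=0)
        sy = y[mask].sum()
        XtVX -= shrink[g] * np.outer(sx, sx)
        XtVy -= shrink[g] * sx * sy
    beta = np.linalg.solve(XtVX, XtVy)
    r = y - X @ beta
    rss = float(r @ r)
    for g, m in enumerate(sizes):
        sr = r[group_idx == g].sum()
        rss -= shrink[g] * sr * sr
    sigma2 = rss / n
    ll = -0.5 * n * (_LOG2PI + math.log(sigma2) + 1.0) - 0.5 * logdet
    return ll, beta, sigma2, XtVX


def fit_gaussian_lmm(data: pd.DataFrame, spec: ModelSpec) -> FittedModel:
    """ML fit of y = X beta + u_colony + e, u ~ N(0, re_var), e ~ N(0, resid_var).

    The variance ratio is optimised on a log grid refined by bounded
    scalar minimisation; the boundary ratio 0 (no colony variance, exact
    OLS) is always considered, and a boundary estimate is flagged
    singular rather than treated as an error.
    """
    y, X, cols, groups = _design(data, spec)
    labels, group_idx = np.unique(groups, return_inverse=True)
    if len(labels) < 2:
        raise EstimationError("need >= 2 colonies for a colony random intercept")
    sizes = np.bincount(group_idx).astype(float)

    def nll_at(loglam):
        return -_gaussian_profile_ll(math.exp(loglam), y, X, group_idx, sizes)[0]

    grid = np.linspace(-10.0, 8.0, 19)
    best_loglam = min(grid, key=nll_at)
    res = optimize.minimize_scalar(
        nll_at, bounds=(best_loglam - 2.0, best_loglam + 2.0), method="bounded",
        options={"xatol": 1e-8})
    lam = math.exp(res.x)
    ll, beta, sigma2, XtVX = _gaussian_profile_ll(lam, y, X, group_idx, sizes)
    ll0, beta0, sigma20, XtVX0 = _gaussian_profile_ll(0.0, y, X, group_idx, sizes)
    singular = False
    if ll0 >= ll - 1e-10:   # boundary: no colony variance
        lam, ll, beta, sigma2, XtVX = 0.0, ll0, beta0, sigma20, XtVX0
        singular = True
        logger.warning("%s ~ %s: colony variance estimated at 0 (singular fit)",
                       spec.response, spec.name)
    cov = np.linalg.inv(XtVX) * sigma2
    p = X.shape[1]
    return FittedModel(
        spec=spec, loglik=float(ll),
        params=pd.Series(beta, index=cols), bse=pd.Series(np.sqrt(np.diag(cov)), index=cols),
        k=p + 2, n=len(y), re_var=lam * sigma2, resid_var=sigma2, singular=singular)


# ---------------------------------------------------------------------------
# Poisson GLMM with log link, ML by adaptive Gauss-Hermite quadrature

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(15)


def _poisson_group_ll(y, eta0, sigma):
    """log integral over u ~ N(0,1) of prod Poisson(y | exp(eta0 + sigma*u)).

    The integrand is re-centred at its mode (one-dimensional Newton) and
    rescaled by the curvature there, then integrated with 15-point
    Gauss-Hermite quadrature — the adaptive scheme lme4 uses.
    """
    base = float(np.sum(gammaln(y + 1)))
    if sigma < 1e-10:
        return float(np.sum(y * eta0 - np.exp(eta0))) - base
    u = 0.0
    for _ in range(100):
        mu = np.exp(eta0 + sigma * u)
        g = sigma * float(np.sum(y - mu)) - u
        h = -sigma * sigma * float(np.sum(mu)) - 1.0
        step = g / h
        u -= step
        if abs(step) < 1e-10:
            break
    mu = np.exp(eta0 + sigma * u)
    h = sigma * sigma * float(np.sum(mu)) + 1.0
    s = 1.0 / math.sqrt(h)
    pts = u + math.sqrt(2.0) * s * _GH_NODES
    fvals = np.array([float(np.sum(y * (eta0 + sigma * p) - np.exp(eta0 + sigma * p)))
                      - 0.5 * p * p for p in pts])
    log_terms = np.log(_GH_WEIGHTS) + _GH_NODES ** 2 + fvals
    return float(logsumexp(log_terms)) + math.log(math.sqrt(2.0) * s) \
        - 0.5 * math.log(2.0 * math.pi) - base


def _poisson_nll(theta, y, X, group_slices):
    beta, sigma = theta[:-1], abs(theta[-1])
    eta = X @ beta
    if np.any(eta > 50):
        return 1e10
    return -sum(_poisson_group_ll(y[sl], eta[sl], sigma) for sl in group_slices)


def fit_poisson_glmm(data: pd.DataFrame, spec: ModelSpec) -> FittedModel:
    """ML fit of y ~ Poisson(exp(X beta + u_colony)), u ~ N(0, re_var)."""
    y, X, cols, groups = _design(data, spec)
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise EstimationError(f"{spec.response}: Poisson family needs non-negative counts")
    labels, group_idx = np.unique(groups, return_inverse=True)
    if len(labels) < 2:
        raise EstimationError("need >= 2 colonies for a colony random intercept")
    order = np.argsort(group_idx, kind="stable")
    y, X, group_idx = y[order], X[order], group_idx[order]
    bounds = np.searchsorted(group_idx, np.arange(len(labels) + 1))
    slices = [slice(bounds[g], bounds[g + 1]) for g in range(len(labels))]

    # plain Poisson GLM start values via IRLS
    p = X.shape[1]
    beta = np.zeros(p)
    beta[0] = math.log(max(np.mean(y), 1e-3))
    for _ in range(50):
        mu = np.exp(np.clip(X @ beta, -30, 30))
        W = mu
        z = X @ beta + (y - mu) / np.maximum(mu, 1e-10)
        XtWX = X.T @ (X * W[:, None])
        try:
            new = np.linalg.solve(XtWX, X.T @ (W * z))
        except np.linalg.LinAlgError:
            break
        if np.max(np.abs(new - beta)) < 1e-10:
            beta = new
            break
        beta = new

    x0 = np.append(beta, 0.3)
    res = optimize.minimize(_poisson_nll, x0, args=(y, X, slices),
                            method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 5000})
    success = bool(res.success)
    res2 = optimize.minimize(_poisson_nll, res.x, args=(y, X, slices), method="BFGS",
                             options={"gtol": 1e-8})
    theta = res.x
    if res2.fun < res.fun - 1e-12:
        theta = res2.x
        success = success or bool(res2.success)
    sigma = abs(theta[-1])
    singular = sigma < 1e-4
    if singular:
        theta = np.append(theta[:-1], 0.0)
        logger.warning("%s ~ %s: colony variance estimated at 0 (singular fit)",
                       spec.response, spec.name)
    ll = -_poisson_nll(theta, y, X, slices)

    H = approx_hess1(theta, _poisson_nll, args=(y, X, slices))
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov)[:p], 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    return FittedModel(
        spec=spec, loglik=float(ll),
        params=pd.Series(theta[:p], index=cols), bse=pd.Series(se, index=cols),
        k=p + 1, n=len(y), re_var=float(sigma ** 2), resid_var=None,
        converged=success, singular=singular)


def fit_candidate(spec: ModelSpec, data: pd.DataFrame) -> FittedModel:
    """Dispatch a candidate model to the family-appropriate ML fitter."""
    used = [spec.response, spec.random_intercept, *spec.fixed_effects]
    if data[used].isna().any().any():
        raise EstimationError(f"missing values in columns used by {spec.name}")
    if spec.family == POISSON_LOG:
        return fit_poisson_glmm(data, spec)
    return fit_gaussian_lmm(data, spec)


# ---------------------------------------------------------------------------
# candidate-model comparison

def build_comparison_table(names: list[str], aicc_values: list[float]) -> pd.DataFrame:
    """Delta-AICc table from externally supplied AICc values.

    delta_aicc = AICc - min(AICc) over the finite rows; non-convergent
    rows may carry NaN and get no delta.
    """
    vals = np.asarray(aicc_values, dtype=float)
    best = np.nanmin(vals)
    return pd.DataFrame({"model": names, "AICc": vals, "delta_aicc": vals - best})


def compare_candidates(response: str, data: pd.DataFrame,
                       candidates: tuple[str, ...] | None = None,
                       lpi_col: str = "lpi") -> pd.DataFrame:
    """Bottom-up AICc comparison for one response.

    Fits the basic model and each single-covariate model, picks the
    lowest-AICc one (ties to fewer parameters), then refits it with LPI
    added.  Returns a table with one row per model (model, AICc,
    delta_aicc, k, loglik, estimate/se per fixed effect, best_flag,
    lpi_verdict).  LPI "predicts" the response only if adding it lowers
    AICc by more than 2.
    """
    if candidates is None:
        candidates = CANDIDATES_BY_RESPONSE[response]
    family = FAMILY_BY_RESPONSE[response]
    used = [response, "colony_id", lpi_col, *candidates]
    sub = data.dropna(subset=used).copy()
    if family == POISSON_LOG:
        sub = sub[sub[response] > 0]  # foragers only: zero-day bees excluded

    specs = [ModelSpec(response, ())] + [ModelSpec(response, (c,)) for c in candidates]
    fits: dict[str, FittedModel | None] = {}
    for spec in specs:
        try:
            fits[spec.name] = fit_candidate(spec, sub)
        except EstimationError as exc:
            logger.warning("%s ~ %s failed: %s", response, spec.name, exc)
            fits[spec.name] = None

    ok = [(name, f) for name, f in fits.items() if f is not None and f.converged]
    if not ok:
        raise EstimationError(f"no candidate model converged for {response}")
    best_name, best_fit = min(ok, key=lambda nf: (nf[1].aicc, nf[1].k))

    lpi_spec = ModelSpec(response, (*best_fit.spec.fixed_effects, lpi_col))
    lpi_name = f"{best_name} + {lpi_col}"
    try:
        fits[lpi_name] = fit_candidate(lpi_spec, sub)
    except EstimationError as exc:
        logger.warning("%s ~ %s failed: %s", response, lpi_name, exc)
        fits[lpi_name] = None

    rows = []
    for name, f in fits.items():
        row = {"model": name, "response": response,
               "AICc": f.aicc if f is not None and f.converged else np.nan,
               "k": f.k if f is not None else np.nan,
               "loglik": f.loglik if f is not None else np.nan,
               "n": f.n if f is not None else np.nan,
               "converged": bool(f is not None and f.converged)}
        if f is not None:
            for term in f.params.index:
                if term == "intercept":
                    continue
                row[f"estimate_{term}"] = f.params[term]
                row[f"se_{term}"] = f.bse[term]
        rows.append(row)
    table = pd.DataFrame(rows)
    table["delta_aicc"] = table["AICc"] - np.nanmin(table["AICc"])

    lpi_fit = fits[lpi_name]
    predicts = (lpi_fit is not None and lpi_fit.converged
                and lpi_fit.aicc <= best_fit.aicc - DELTA_AICC_RULE)
    winner = lpi_name if predicts else best_name
    table["best_flag"] = table["model"] == winner
    table["lpi_verdict"] = "predicts" if predicts else "does_not_predict"
    return table


# ---------------------------------------------------------------------------
# per-bee analysis table and end-to-end driver

RESPONSES = ("nectar_rate", "pollen_rate", "days_foraged",
             "mean_bouts_per_day", "mean_bout_duration")


def build_analysis_table(bees: pd.DataFrame, scores: pd.DataFrame,
                         activity: pd.DataFrame,
                         efficiency: pd.DataFrame) -> pd.DataFrame:
    """Join covariates, learning scores, activity and efficiency on bee_id."""
    merged = (bees.merge(scores[["bee_id", "lpi"]], on="bee_id", how="left")
                  .merge(activity, on="bee_id", how="left")
                  .merge(efficiency, on="bee_id", how="left"))
    merged["days_foraged"] = merged["days_foraged"].fillna(0).astype(int)
    return merged


def compare_all_responses(data: pd.DataFrame,
                          responses: tuple[str, ...] = RESPONSES) -> dict[str, pd.DataFrame]:
    """Candidate-model comparison tables for every response."""
    return {resp: compare_candidates(resp, data) for resp in responses}


# ---------------------------------------------------------------------------
# supporting descriptive statistics

def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average-rank ties; two-sided p."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("need >= 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rank correlation undefined for a constant vector")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def anova_oneway(groups) -> tuple[float, int, int, float]:
    """Classical one-way ANOVA; returns (F, df_between, df_within, p)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    df1 = len(groups) - 1
    df2 = sum(len(g) for g in groups) - len(groups)
    if np.ptp(np.concatenate(groups)) == 0:
        return 0.0, df1, df2, 1.0
    F, p = stats.f_oneway(*groups)
    if math.isnan(F):  # identical constant groups
        return 0.0, df1, df2, 1.0
    return float(F), df1, df2, float(p)


def mann_whitney_z(a, b) -> tuple[float, float, float]:
    """Rank-sum test with normal approximation; returns (U, z, p).

    U is the statistic for the first sample; z uses the tie-corrected
    variance without continuity correction; p is two-sided.
    """
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    r1 = float(ranks[:n1].sum())
    U = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    N = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts ** 3 - counts)) / (N * (N - 1)) if N > 1 else 0.0
    var = n1 * n2 / 12.0 * ((N + 1) - tie_term)
    if var <= 0:
        return float(U), 0.0, 1.0
    z = (U - mu) / math.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(U), float(z), float(p)
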