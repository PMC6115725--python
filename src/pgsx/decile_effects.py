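"""Effects of a score across the phenotype distribution.

Two routes estimate how the per-allele (or per-s.d.) effect of a polygenic
score varies over the BMI distribution:

* conditional-quantile regression at the decile midpoints
  tau = 0.05, 0.15, ..., 0.95, minimizing the check loss
  rho_tau(u) = u (tau - 1[u < 0]), with case-bootstrap standard errors;
* decile-stratified OLS: samples are cut into ten equal-count BMI bins and
  BMI is regressed on score + covariates within each bin.

Because raw BMI has a mean-variance relationship, a rising profile can
reflect pure scale inflation rather than genuinely amplified genetic
effects; the rank-based inverse normal transformation (Blom offset 3/8)
is provided as the control that removes global mean-variance scaling.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.optimize import linprog

from .association import DEFAULT_COVARIATES
from .pgs_builder import assign_deciles

logger = logging.getLogger(__name__)

DECILE_MIDPOINTS = tuple(np.round(np.arange(0.05, 1.0, 0.1), 2))
DECILE_BOUNDARIES = tuple(np.round(np.arange(0.1, 1.0, 0.1), 2))


@dataclasses.dataclass
class DecileEffectProfile:
    """Ten ordered effect estimates of a score across a distribution.

    ``table`` columns: decile (1..10), beta, se, lo, hi (95% CI).
    Undefined entries (degenerate bins) are NaN.  For quantile profiles,
    ``beta_cov`` holds the estimated joint covariance of the ten score
    coefficients: quantile estimates at different taus share the sample and
    are strongly correlated, so trend inference must not treat them as
    independent.  Stratified-OLS profiles use disjoint bins and leave it
    None (independence holds).
    """

    score_name: str
    table: pd.DataFrame
    method: str  # "quantile" | "strata-ols"
    transform: str  # "raw" | "int"
    beta_cov: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.table) != 10:
            raise ValueError("profile must have exactly 10 deciles")
        ok = self.table.dropna()
        if not ((ok["lo"] <= ok["beta"]) & (ok["beta"] <= ok["hi"])).all():
            raise ValueError("CI must contain the point estimate")

    @property
    def betas(self) -> np.ndarray:
        return self.table["beta"].to_numpy()

    @property
    def ses(self) -> np.ndarray:
        return self.table["se"].to_numpy()


def check_loss(u: np.ndarray, tau: float) -> float:
    """Pinball loss sum: rho_tau(u) = u * (tau - 1[u < 0])."""
    u = np.asarray(u, dtype=float)
    return float(np.sum(u * (tau - (u < 0))))


def _solve_check_loss(y: np.ndarray, X: np.ndarray, tau: float) -> np.ndarray:
    """Exact check-loss minimizer via the quantile-regression dual LP.

    The dual has n box-constrained variables and only p equality
    constraints, so it scales well; the primal vertex is recovered by
    interpolating the p observations whose dual variables are strictly
    interior.  Degenerate bases fall back to the (larger) primal LP.
    """
    n, p = X.shape
    res = linprog(-y, A_eq=X.T, b_eq=(1 - tau) * X.sum(axis=0),
                  bounds=[(0, 1)] * n, method="highs")
    if res.status == 0:
        a = res.x
        interior = np.flatnonzero((a > 1e-8) & (a < 1 - 1e-8))
        if len(interior) == p:
            Xi = X[interior]
            if np.linalg.matrix_rank(Xi) == p:
                return np.linalg.solve(Xi, y[interior])
    # degenerate or failed dual: primal LP with residual split u+ - u-
    c = np.concatenate([np.zeros(p), tau * np.ones(n), (1 - tau) * np.ones(n)])
    A = sparse.hstack(
        [sparse.csr_matrix(X), sparse.eye(n), -sparse.eye(n)], format="csr"
    )
    res = linprog(c, A_eq=A, b_eq=y,
                  bounds=[(None, None)] * p + [(0, None)] * (2 * n),
                  method="highs")
    if res.status != 0:
        raise RuntimeError(f"quantile LP failed to converge: {res.message}")
    return res.x[:p]


def quantile_fit(
    y: np.ndarray,
    X: np.ndarray,
    tau: float,
    bootstrap: int = 0,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Coefficients minimizing the tau-check loss of ``y`` on ``X``.

    Solved exactly as a linear program (HiGHS).  ``X`` must include the
    intercept and be full rank.  With ``bootstrap > 0``, case-bootstrap
    standard errors are returned (seeded).
    """
    if not 0 < tau < 1:
        raise ValueError("tau must be in (0, 1)")
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank-deficient")

    coef = _solve_check_loss(y, X, tau)

    ses = None
    if bootstrap > 0:
        rng = np.random.default_rng(seed)
        n = len(y)
        draws = np.empty((bootstrap, X.shape[1]))
        for b in range(bootstrap):
            idx = rng.integers(0, n, size=n)
            draws[b] = _solve_check_loss(y[idx], X[idx], tau)
        ses = draws.std(axis=0, ddof=1)
    return coef, ses


def _hall_sheather_bandwidth(tau: float, n: int, alpha: float = 0.05) -> float:
    z = stats.norm.ppf(1 - alpha / 2)
    q = stats.norm.ppf(tau)
    num = 1.5 * stats.norm.pdf(q) ** 2
    den = 2 * q**2 + 1
    return n ** (-1 / 3) * z ** (2 / 3) * (num / den) ** (1 / 3)


def _sparsity(resid: np.ndarray, tau: float) -> float:
    """Sparsity s(tau) = 1/f(F^-1(tau)) by the Hall-Sheather difference
    quotient of the empirical residual quantile function."""
    n = len(resid)
    h = _hall_sheather_bandwidth(tau, n)
    lo = max(tau - h, 1.0 / (n + 1))
    hi = min(tau + h, n / (n + 1.0))
    q_hi, q_lo = np.quantile(resid, [hi, lo])
    return float((q_hi - q_lo) / (hi - lo))


def quantile_beta_covariance(
    y: np.ndarray,
    X: np.ndarray,
    coefs: np.ndarray,
    taus: Sequence[float],
    coef_index: int = 1,
) -> np.ndarray:
    """Asymptotic joint covariance of one coefficient across quantile fits.

    Under iid errors, cov(b(s), b(t)) = (s^t - s t) x sparsity(s) x
    sparsity(t) x (X'X)^-1 at the coefficient of interest; sparsities come
    from each fit's own residuals.  ``coefs`` is the (n_taus x p) matrix of
    fitted coefficient vectors.
    """
    d_inv = np.linalg.inv(X.T @ X)[coef_index, coef_index]
    taus = np.asarray(taus, dtype=float)
    sparsities = np.array([
        _sparsity(y - X @ coefs[i], taus[i]) for i in range(len(taus))
    ])
    tmin = np.minimum.outer(taus, taus)
    bridge = tmin - np.outer(taus, taus)
    return bridge * np.outer(sparsities, sparsities) * d_inv


def inverse_normal_transform(y: np.ndarray) -> np.ndarray:
    """Blom rank-based inverse normal transform.

    y_i -> Phi^{-1}((rank_i - 3/8) / (n + 1/4)), ranks averaged over ties.
    Output is approximately standard normal whatever the input distribution
    and is invariant to strictly monotone transformations of y.
    """
    y = np.asarray(y, dtype=float)
    ranks = stats.rankdata(y, method="average")
    return stats.norm.ppf((ranks - 3.0 / 8.0) / (len(y) + 0.25))


def _prepare(pheno: pd.DataFrame, score: pd.DataFrame,
             covar_names: Sequence[str], transform: str):
    merged = pheno.merge(score[["sample_id", "score"]], on="sample_id")
    if len(merged) != len(score):
        logger.warning("%d score rows missing phenotypes", len(score) - len(merged))
    y = merged["bmi"].to_numpy(dtype=float)
    if transform == "int":
        y = inverse_normal_transform(y)
    elif transform != "raw":
        raise ValueError("transform must be 'raw' or 'int'")
    s = merged["score"].to_numpy(dtype=float)
    if np.ptp(s) == 0:
        raise ValueError("degenerate score: constant across samples")
    covars = np.column_stack(
        [merged[c].to_numpy(dtype=float) for c in covar_names]
    ) if covar_names else np.empty((len(merged), 0))
    return y, s, covars


def profile_by_quantile(
    pheno: pd.DataFrame,
    score: pd.DataFrame,
    covar_names: Sequence[str] = DEFAULT_COVARIATES,
    taus: Sequence[float] = DECILE_MIDPOINTS,
    transform: str = "raw",
    bootstrap: int = 200,
    seed: int = 0,
    score_name: str = "pgs",
) -> DecileEffectProfile:
    """Score effect at each decile of the conditional BMI distribution.

    One quantile regression of BMI on score + covariates per tau.  SEs come
    from the asymptotic (Hall-Sheather sparsity) covariance by default;
    ``bootstrap > 0`` replaces them with case-bootstrap SEs.  The full
    cross-tau covariance is attached for trend inference.
    """
    y, s, covars = _prepare(pheno, score, covar_names, transform)
    X = np.column_stack([np.ones(len(y)), s, covars])
    coefs = np.empty((len(taus), X.shape[1]))
    boot_ses = []
    for d, tau in enumerate(taus, start=1):
        coef, ses = quantile_fit(y, X, tau, bootstrap=bootstrap,
                                 seed=None if seed is None else seed + d)
        coefs[d - 1] = coef
        boot_ses.append(ses[1] if ses is not None else np.nan)
    cov = quantile_beta_covariance(y, X, coefs, taus)
    se = np.where(np.isfinite(boot_ses), boot_ses, np.sqrt(np.diag(cov)))
    beta = coefs[:, 1]
    z = stats.norm.ppf(0.975)
    table = pd.DataFrame({
        "decile": np.arange(1, len(taus) + 1), "beta": beta, "se": se,
        "lo": beta - z * se, "hi": beta + z * se,
    })
    return DecileEffectProfile(score_name, table, method="quantile",
                               transform=transform, beta_cov=cov)


def profile_by_stratified_ols(
    pheno: pd.DataFrame,
    score: pd.DataFrame,
    covar_names: Sequence[str] = DEFAULT_COVARIATES,
    transform: str = "raw",
    score_name: str = "pgs",
) -> DecileEffectProfile:
    """Score effect within each equal-count decile bin of BMI.

    OLS of BMI on score + covariates restricted to each bin; analytic
    standard errors.  A score constant within a bin yields a flagged NaN
    entry for that decile.
    """
    y, s, covars = _prepare(pheno, score, covar_names, transform)
    bins = assign_deciles(y)
    z = stats.norm.ppf(0.975)
    rows = []
    for d in range(1, 11):
        mask = bins == d
        sd_ = s[mask]
        if np.ptp(sd_) == 0 or mask.sum() < covars.shape[1] + 3:
            rows.append({"decile": d, "beta": np.nan, "se": np.nan,
                         "lo": np.nan, "hi": np.nan})
            continue
        X = np.column_stack([np.ones(mask.sum()), sd_, covars[mask]])
        coef, _, rank, _ = np.linalg.lstsq(X, y[mask], rcond=None)
        resid = y[mask] - X @ coef
        df = mask.sum() - rank
        sigma2 = resid @ resid / df
        se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
        rows.append({"decile": d, "beta": coef[1], "se": se,
                     "lo": coef[1] - z * se, "hi": coef[1] + z * se})
    return DecileEffectProfile(score_name, pd.DataFrame(rows),
                               method="strata-ols", transform=transform)


@dataclasses.dataclass
class TrendStatistics:
    slope: float
    slope_se: float
    slope_p: float
    ratio_top_bottom: float


def trend_statistics(profile: DecileEffectProfile) -> TrendStatistics:
    """Linear trend of the decile betas on decile index 1..10.

    Quantile profiles carry the joint covariance of the betas (estimates at
    different taus share the sample); the trend is then the GLS slope under
    that covariance.  Stratified-OLS profiles have independent bins, so
    inverse-variance weighted least squares applies (unweighted when SEs
    are unavailable).  The ratio is decile 10 over decile 1, NaN when the
    denominator is 0 or undefined.
    """
    tab = profile.table.dropna(subset=["beta"])
    d = tab["decile"].to_numpy(dtype=float)
    b = tab["beta"].to_numpy()
    se = tab["se"].to_numpy()
    if len(b) < 3:
        raise ValueError("too few defined deciles for a trend")

    Z = np.column_stack([np.ones(len(b)), d])
    if profile.beta_cov is not None:
        idx = tab.index.to_numpy()
        S = profile.beta_cov[np.ix_(idx, idx)]
        Si = np.linalg.inv(S)
        V = np.linalg.inv(Z.T @ Si @ Z)
        coef = V @ Z.T @ Si @ b
        slope = coef[1]
        slope_se = np.sqrt(V[1, 1])
    elif np.isfinite(se).all() and (se > 0).all():
        w = 1.0 / se**2
        W = np.diag(w)
        V = np.linalg.inv(Z.T @ W @ Z)
        coef = V @ Z.T @ W @ b
        slope = coef[1]
        slope_se = np.sqrt(V[1, 1])
    else:
        coef, _, _, _ = np.linalg.lstsq(Z, b, rcond=None)
        slope = coef[1]
        resid = b - Z @ coef
        sxx = np.sum((d - d.mean()) ** 2)
        slope_se = np.sqrt(np.sum(resid**2) / (len(b) - 2) / sxx)
    slope_p = 2 * stats.norm.sf(abs(slope / slope_se)) if slope_se > 0 else np.nan

    beta1 = profile.table.at[0, "beta"]
    beta10 = profile.table.at[9, "beta"]
    ratio = beta10 / beta1 if np.isfinite(beta1) and beta1 != 0 else np.nan
    return TrendStatistics(float(slope), float(slope_se), float(slope_p),
                           float(ratio))
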