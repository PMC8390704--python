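"""Probit dose-response fitting and lethal-concentration estimation.

The quantal response model is

    P(death | dose c) = C + (1 - C) * Phi(alpha + beta * log10 c)

with Phi the standard normal CDF, C the natural (control) mortality and
(alpha, beta) intercept and slope on the probit scale. No classical +5
offset is added to the intercept; ``legacy_intercept`` on the fit converts
for comparison with older software output.

Fitting is by Fisher scoring on the binomial likelihood of replicate-pooled
death counts, with Abbott pre-correction of the observed proportions when a
control mortality is supplied (the default workflow) or joint maximum
likelihood estimation of C on request. LCp points are read off the fitted
line; interval estimates use Fieller-type fiducial limits with Finney's
heterogeneity inflation when the dose-level Pearson chi-square exceeds its
degrees of freedom.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .data_model import MortalityAssay

_PROB_EPS = 1e-10


@dataclass
class DoseMortalityTable:
    """Replicate-pooled deaths per dose level for one isolate."""

    isolate_id: str
    doses: np.ndarray      # (k,) spores/ml, ascending, > 0
    deaths: np.ndarray     # (k,) pooled deaths (float after Abbott correction)
    n: np.ndarray          # (k,) pooled number exposed

    @classmethod
    def from_assays(cls, assays: Sequence[MortalityAssay], day: Optional[int] = None) -> "DoseMortalityTable":
        """Pool replicate final (or day-``day``) deaths within dose levels.

        Control replicates (dose 0) and fixed-dose screens (dose None) are
        excluded; use :func:`control_mortality_percent` for the former.
        """
        assays = [a for a in assays if a.dose is not None and a.dose > 0]
        if not assays:
            raise ValueError("no dose-series assays supplied")
        ids = {a.isolate_id for a in assays}
        if len(ids) > 1:
            raise ValueError(f"assays mix isolates: {sorted(ids)}")
        acc: dict[float, list[float]] = {}
        for a in assays:
            d = a.window_days if day is None else day
            acc.setdefault(a.dose, [0.0, 0.0])
            acc[a.dose][0] += a.deaths_by_day[d - 1]
            acc[a.dose][1] += a.n_exposed
        doses = np.array(sorted(acc), dtype=float)
        deaths = np.array([acc[c][0] for c in doses])
        n = np.array([acc[c][1] for c in doses])
        return cls(isolate_id=ids.pop(), doses=doses, deaths=deaths, n=n)


def control_mortality_percent(assays: Sequence[MortalityAssay]) -> float:
    """Mean percent mortality of the dose-0 (control) replicates."""
    ctrl = [a for a in assays if a.dose == 0]
    if not ctrl:
        return 0.0
    return 100.0 * sum(a.final_deaths / a.n_exposed for a in ctrl) / len(ctrl)


@dataclass
class ProbitFit:
    isolate_id: str
    alpha: float
    beta: float
    vcov: np.ndarray
    natural_mortality: float
    chi2: float
    df: int
    heterogeneity: float
    converged: bool
    n_doses: int
    n_total: float
    loglik: float = float("nan")
    separation: bool = False
    informative: bool = True
    method: str = "fisher_scoring"

    @property
    def se_alpha(self) -> float:
        return float(np.sqrt(self.vcov[0, 0]))

    @property
    def se_beta(self) -> float:
        return float(np.sqrt(self.vcov[1, 1]))

    @property
    def legacy_intercept(self) -> float:
        """Intercept under the classical probit convention (+5 offset)."""
        return self.alpha + 5.0


@dataclass
class LCEstimate:
    """Lethal concentration for mortality proportion ``p`` with fiducial limits."""

    p: float
    lc: float
    lower: float
    upper: float
    g: float
    confidence: float = 0.95
    unbounded: bool = False
    isolate_id: str = field(default="", compare=False)


def _loglik(alpha: float, beta: float, x: np.ndarray, prop: np.ndarray, n: np.ndarray) -> float:
    mu = np.clip(stats.norm.cdf(alpha + beta * x), _PROB_EPS, 1 - _PROB_EPS)
    return float(np.sum(n * (prop * np.log(mu) + (1 - prop) * np.log(1 - mu))))


def grid_search_probit(
    x: np.ndarray,
    prop: np.ndarray,
    n: np.ndarray,
    alpha_bounds: tuple[float, float] = (-6.0, 6.0),
    beta_bounds: tuple[float, float] = (0.01, 3.0),
    n_grid: int = 81,
    refinements: int = 3,
) -> tuple[float, float]:
    """Brute-force likelihood maximizer over an (alpha, beta) grid.

    Coarse grid followed by successive zoom-ins around the running optimum.
    Used as a convergence fallback; deliberately simple and derivative-free.
    """
    a_lo, a_hi = alpha_bounds
    b_lo, b_hi = beta_bounds
    best = (0.0, 1.0)
    for _ in range(refinements + 1):
        a_grid = np.linspace(a_lo, a_hi, n_grid)
        b_grid = np.linspace(b_lo, b_hi, n_grid)
        mu = stats.norm.cdf(a_grid[:, None, None] + b_grid[None, :, None] * x[None, None, :])
        mu = np.clip(mu, _PROB_EPS, 1 - _PROB_EPS)
        ll = np.sum(n * (prop * np.log(mu) + (1 - prop) * np.log(1 - mu)), axis=2)
        i, j = np.unravel_index(np.argmax(ll), ll.shape)
        best = (float(a_grid[i]), float(b_grid[j]))
        a_step = (a_hi - a_lo) / (n_grid - 1)
        b_step = (b_hi - b_lo) / (n_grid - 1)
        a_lo, a_hi = best[0] - 2 * a_step, best[0] + 2 * a_step
        b_lo, b_hi = best[1] - 2 * b_step, best[1] + 2 * b_step
    return best


def _abbott_proportions(prop: np.ndarray, c: float) -> np.ndarray:
    corrected = (prop - c) / (1.0 - c)
    return np.clip(corrected, 0.0, 1.0)


def fit_probit(
    table: DoseMortalityTable,
    control_mortality_pct: Optional[float] = None,
    natural_response: str = "abbott",
    max_iter: int = 100,
    tol: float = 1e-8,
) -> ProbitFit:
    """Maximum-likelihood probit fit for one isolate's dose-mortality table.

    Parameters
    ----------
    table
        Replicate-pooled deaths per dose.
    control_mortality_pct
        Observed control mortality in percent; used for Abbott pre-correction
        under ``natural_response="abbott"`` (the default). ``None`` or 0
        leaves the proportions untouched.
    natural_response
        ``"abbott"`` pre-corrects observed proportions, ``"joint"`` estimates
        the natural-response proportion C by MLE together with (alpha, beta),
        ``"none"`` ignores control mortality.

    Raises
    ------
    ValueError
        Fewer than two distinct doses, or no gradient information (every
        dose fully dead or fully alive in the same direction).
    """
    doses, deaths, n = table.doses, table.deaths.astype(float), table.n.astype(float)
    if len(doses) < 2:
        raise ValueError("probit fit needs >= 2 distinct doses")
    if np.any(doses <= 0) or np.any(n < 1):
        raise ValueError("doses must be positive and n >= 1 at every dose")
    x = np.log10(doses)
    prop = deaths / n
    c_hat = 0.0

    if natural_response == "abbott" and control_mortality_pct:
        c_hat = control_mortality_pct / 100.0
        if c_hat >= 1.0:
            raise ValueError("control mortality of 100% leaves the correction undefined")
        prop = _abbott_proportions(prop, c_hat)
    elif natural_response not in {"abbott", "joint", "none"}:
        raise ValueError(f"unknown natural_response {natural_response!r}")

    if np.all(prop <= 0) or np.all(prop >= 1):
        raise ValueError("no gradient information: uniform response at every dose")

    flat = np.allclose(prop, prop[0])
    separation = bool(np.all((deaths == 0) | (deaths == n)) and not flat)

    # working-probit start values from clamped empirical proportions
    clamped = np.clip(prop, 1.0 / (2 * n), 1.0 - 1.0 / (2 * n))
    z = stats.norm.ppf(clamped)
    beta0, alpha0 = np.polyfit(x, z, 1)
    if separation:
        # unbounded MLE: report the clamped-proportion fit with its (large)
        # information-based variance instead of diverging
        alpha_hat, beta_hat = grid_search_probit(x, clamped, n)
        fit_prop = clamped
    else:
        fit_prop = prop
        alpha_hat, beta_hat = float(alpha0), float(beta0)

    converged = separation  # grid result counts as resolved
    ll_old = _loglik(alpha_hat, beta_hat, x, fit_prop, n)
    if not separation:
        for _ in range(max_iter):
            eta = alpha_hat + beta_hat * x
            mu = np.clip(stats.norm.cdf(eta), _PROB_EPS, 1 - _PROB_EPS)
            phi = stats.norm.pdf(eta)
            w = n * phi**2 / (mu * (1 - mu))
            resid = (fit_prop - mu) / np.where(phi > _PROB_EPS, phi, _PROB_EPS)
            zz = eta + resid
            X = np.column_stack([np.ones_like(x), x])
            XtW = X.T * w
            try:
                coef = np.linalg.solve(XtW @ X, XtW @ zz)
            except np.linalg.LinAlgError:
                break
            alpha_hat, beta_hat = float(coef[0]), float(coef[1])
            ll_new = _loglik(alpha_hat, beta_hat, x, fit_prop, n)
            if abs(ll_new - ll_old) < tol:
                converged = True
                ll_old = ll_new
                break
            ll_old = ll_new
        if not converged or not (math.isfinite(alpha_hat) and math.isfinite(beta_hat)):
            alpha_hat, beta_hat = grid_search_probit(x, fit_prop, n)
            ll_old = _loglik(alpha_hat, beta_hat, x, fit_prop, n)
            converged = True
            method = "grid_fallback"
        else:
            method = "fisher_scoring"
    else:
        method = "grid_separation"

    if natural_response == "joint":
        alpha_hat, beta_hat, c_hat, ll_old = _fit_joint(x, deaths, n, alpha_hat, beta_hat)
        fit_prop = np.clip((deaths / n - c_hat) / (1 - c_hat), 0.0, 1.0)
        method = "joint_mle"

    # expected information at the optimum -> covariance of (alpha, beta)
    eta = alpha_hat + beta_hat * x
    mu = np.clip(stats.norm.cdf(eta), _PROB_EPS, 1 - _PROB_EPS)
    phi = stats.norm.pdf(eta)
    w = n * phi**2 / (mu * (1 - mu))
    X = np.column_stack([np.ones_like(x), x])
    info = (X.T * w) @ X
    try:
        vcov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        vcov = np.full((2, 2), np.inf)
    if separation:
        vcov = vcov * 100.0  # flagged, variance deliberately inflated

    k = len(doses)
    expected = n * mu
    denom = expected * (1 - mu)
    obs = fit_prop * n
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = (obs - expected) ** 2 / denom
    chi2 = float(np.nansum(np.where(denom > 0, contrib, 0.0)))
    df = max(k - 2, 0)
    h = max(1.0, chi2 / df) if df > 0 else 1.0

    return ProbitFit(
        isolate_id=table.isolate_id,
        alpha=alpha_hat,
        beta=beta_hat,
        vcov=vcov,
        natural_mortality=c_hat,
        chi2=chi2,
        df=df,
        heterogeneity=h,
        converged=converged,
        n_doses=k,
        n_total=float(n.sum()),
        loglik=ll_old,
        separation=separation,
        informative=not flat,
        method=method,
    )


def _fit_joint(
    x: np.ndarray, deaths: np.ndarray, n: np.ndarray, alpha0: float, beta0: float
) -> tuple[float, float, float, float]:
    """Joint MLE of (alpha, beta, C) with C logit-transformed."""

    def nll(theta: np.ndarray) -> float:
        a, b, lc = theta
        c = 1.0 / (1.0 + np.exp(-lc))
        mu = np.clip(c + (1 - c) * stats.norm.cdf(a + b * x), _PROB_EPS, 1 - _PROB_EPS)
        return -float(np.sum(deaths * np.log(mu) + (n - deaths) * np.log(1 - mu)))

    res = optimize.minimize(nll, np.array([alpha0, beta0, -4.0]), method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 5000})
    a, b, lc = res.x
    return float(a), float(b), float(1.0 / (1.0 + np.exp(-lc))), -float(res.fun)


def lc(fit: ProbitFit, p: float) -> float:
    """Lethal concentration for mortality proportion ``p``: 10^((z_p - alpha)/beta)."""
    if not (0.0 < p < 1.0):
        raise ValueError(f"p must be in (0, 1), got {p}")
    if fit.beta == 0:
        raise ValueError("slope is zero; LC undefined")
    if fit.beta < 0 and p > 0.5:
        warnings.warn("negative slope: dose-response inverted", stacklevel=2)
    return float(10.0 ** ((stats.norm.ppf(p) - fit.alpha) / fit.beta))


def fiducial_limits(fit: ProbitFit, p: float, confidence: float = 0.95) -> LCEstimate:
    """Fieller-type fiducial limits for LCp on the dose scale.

    Works on m = log10 LCp. With g = t^2 * v_bb / beta^2, the limits are

        m_hat + [g/(1-g)](m_hat + v_ab/v_bb)
              +/- [t/(beta(1-g))] * sqrt(v_aa + 2 m_hat v_ab + m_hat^2 v_bb
                                          - g (v_aa - v_ab^2/v_bb))

    exponentiated back to spores/ml. The quantile t is normal, replaced by a
    Student-t with df = k-2 inflated by sqrt(h) when the dose-level Pearson
    chi-square is significant at the 5% level (real heterogeneity, not
    chance dispersion; inflating on any h > 1 makes the intervals markedly
    conservative). g >= 1 yields an unbounded interval (flagged, not an
    error).
    """
    if not fit.converged:
        raise ValueError("fiducial limits require a converged fit")
    point = lc(fit, p)
    m_hat = math.log10(point)
    v_aa, v_ab = float(fit.vcov[0, 0]), float(fit.vcov[0, 1])
    v_bb = float(fit.vcov[1, 1])
    q = (1.0 + confidence) / 2.0
    heterogeneous = fit.df > 0 and fit.chi2 > stats.chi2.ppf(0.95, fit.df)
    if heterogeneous:
        t = stats.t.ppf(q, fit.df) * math.sqrt(fit.heterogeneity)
    else:
        t = stats.norm.ppf(q)
    g = t**2 * v_bb / fit.beta**2
    if g >= 1.0:
        return LCEstimate(p=p, lc=point, lower=0.0, upper=math.inf, g=float(g),
                          confidence=confidence, unbounded=True, isolate_id=fit.isolate_id)
    rad = v_aa + 2 * m_hat * v_ab + m_hat**2 * v_bb - g * (v_aa - v_ab**2 / v_bb)
    rad = max(rad, 0.0)
    center = m_hat + (g / (1 - g)) * (m_hat + v_ab / v_bb)
    half = (t / (fit.beta * (1 - g))) * math.sqrt(rad)
    m_lo, m_hi = sorted((center - half, center + half))
    return LCEstimate(p=p, lc=point, lower=10.0**m_lo, upper=10.0**m_hi, g=float(g),
                      confidence=confidence, unbounded=False, isolate_id=fit.isolate_id)


def goodness_of_fit(fit: ProbitFit) -> tuple[float, int, float]:
    """Pearson chi-square over dose levels, df = k - 2, heterogeneity h."""
    if fit.df == 0:
        warnings.warn("df = 0: heterogeneity fixed at 1", stacklevel=2)
    return fit.chi2, fit.df, fit.heterogeneity
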