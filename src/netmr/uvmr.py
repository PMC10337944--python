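"""Univariable two-sample Mendelian randomization estimators and diagnostics.

Models follow the fit-and-results idiom: construct a model from a
:class:`~netmr.sumstats.HarmonizedSet`, call ``fit()``, and read estimates off
the returned results object.

* :class:`IVW` — inverse-variance-weighted meta-analysis of Wald ratios
  (weighted regression of outcome betas on exposure betas through the
  origin), fixed-effect or multiplicative random-effects, with the
  heterogeneity-driven ``auto`` switch (random effects when Cochran's Q has
  p < 0.05).
* :class:`MREgger` — weighted regression with a free intercept; the slope is
  the pleiotropy-robust causal estimate under InSIDE, the intercept tests
  directional pleiotropy.
* :class:`MaximumLikelihood` — profile likelihood accounting for measurement
  error in the exposure betas.
* :class:`RAPS` — robust adjusted profile score with optional Huber loss and
  overdispersion parameter.

Stand-alone diagnostics: :func:`cochran_q`, :func:`steiger_test`,
:func:`leave_one_out`, :func:`power_binary`, :func:`wald_ratio`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .exceptions import (
    ConfigError,
    DegenerateInstrumentError,
    EstimationError,
    InsufficientInstrumentsError,
)
from .sumstats import HarmonizedSet

Z975 = stats.norm.ppf(0.975)

#: Huber tuning constant (95% Gaussian efficiency)
HUBER_K = 1.345


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran's Q heterogeneity statistic around an IVW or Egger fit."""

    q: float
    df: int
    pval: float
    method: str  # "ivw" | "egger"


@dataclass(frozen=True)
class PleiotropyResult:
    """MR-Egger intercept test for directional pleiotropy."""

    intercept: float
    intercept_se: float
    pval: float


@dataclass(frozen=True)
class SteigerResult:
    """Directionality check: variance explained in exposure vs outcome."""

    r2_exposure: float
    r2_outcome: float
    direction_correct: bool
    pval: float


@dataclass(frozen=True)
class PowerResult:
    """Analytic power of an MR test against a binary outcome."""

    power: float
    alpha: float
    assumed_or: float
    r2_sum: float
    n_outcome: int
    case_fraction: float


@dataclass(frozen=True)
class MRResults:
    """A causal-effect estimate on the log-odds (or SD) scale.

    ``or_`` and the 95% CI are exponentiated; ``pval`` is the two-sided
    normal tail of beta/se.
    """

    method: str  # wald | ivw_fe | ivw_re | egger | ml | raps
    beta: float
    se: float
    n_snp: int
    model: str = "fixed"  # fixed | multiplicative_random
    heterogeneity: HeterogeneityResult | None = None
    pleiotropy: PleiotropyResult | None = None
    extra: dict = field(default_factory=dict)

    @property
    def or_(self) -> float:
        return math.exp(self.beta)

    @property
    def ci_low(self) -> float:
        return math.exp(self.beta - Z975 * self.se)

    @property
    def ci_high(self) -> float:
        return math.exp(self.beta + Z975 * self.se)

    @property
    def pval(self) -> float:
        return 2.0 * stats.norm.sf(abs(self.beta / self.se))

    def conf_int(self) -> tuple[float, float]:
        """95% CI on the beta (log) scale."""
        return (self.beta - Z975 * self.se, self.beta + Z975 * self.se)

    def to_record(self) -> dict:
        rec = {
            "method": self.method,
            "model": self.model,
            "nsnp": self.n_snp,
            "beta": self.beta,
            "se": self.se,
            "or": self.or_,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "pval": self.pval,
        }
        if self.heterogeneity is not None:
            rec["q"] = self.heterogeneity.q
            rec["q_pval"] = self.heterogeneity.pval
        if self.pleiotropy is not None:
            rec["egger_intercept"] = self.pleiotropy.intercept
            rec["egger_intercept_pval"] = self.pleiotropy.pval
        return rec

    def summary(self) -> str:
        lines = [
            f"{self.method.upper()} ({self.model}), {self.n_snp} SNPs",
            f"  beta = {self.beta:+.4f} (SE {self.se:.4f}), p = {self.pval:.3g}",
            f"  OR = {self.or_:.3f} (95% CI {self.ci_low:.3f}-{self.ci_high:.3f})",
        ]
        if self.heterogeneity is not None:
            h = self.heterogeneity
            lines.append(f"  Cochran Q = {h.q:.2f} on {h.df} df, p = {h.pval:.3g}")
        if self.pleiotropy is not None:
            p = self.pleiotropy
            lines.append(
                f"  Egger intercept = {p.intercept:+.4f} (SE {p.intercept_se:.4f}),"
                f" p = {p.pval:.3g}"
            )
        return "\n".join(lines)


def wald_ratio(bx: float, sx: float, by: float, sy: float) -> MRResults:
    """Single-instrument ratio estimate by/bx with first-order delta SE sy/|bx|."""
    if bx == 0:
        raise DegenerateInstrumentError("Wald ratio undefined for zero exposure effect")
    return MRResults(method="wald", beta=by / bx, se=sy / abs(bx), n_snp=1)


def _require(hset: HarmonizedSet, minimum: int, what: str) -> None:
    if hset.n_snp < minimum:
        raise InsufficientInstrumentsError(
            f"{what} requires at least {minimum} SNPs, got {hset.n_snp}"
        )
    if hset.beta_exposure.ndim != 1:
        raise ConfigError(f"{what} expects a single-exposure harmonized set")


def _ivw_core(bx: np.ndarray, by: np.ndarray, sy: np.ndarray) -> tuple[float, float, float]:
    """Return (beta, fixed se, Q) for the origin-constrained weighted fit."""
    w = 1.0 / sy**2
    denom = float(np.sum(w * bx**2))
    beta = float(np.sum(w * bx * by)) / denom
    se_fe = denom**-0.5
    q = float(np.sum(w * (by - beta * bx) ** 2))
    return beta, se_fe, q


class IVW:
    """Inverse-variance-weighted estimator on a harmonized set.

    ``fit(model=...)`` with ``"fixed"``, ``"multiplicative_random"`` or
    ``"auto"`` (random effects iff Cochran's Q p < 0.05).  Random-effects SEs
    use the multiplicative inflation max(1, sqrt(Q/(J-1))) and never deflate.
    """

    def __init__(self, hset: HarmonizedSet):
        self.data = hset

    def fit(self, model: str = "auto") -> MRResults:
        hset = self.data
        if model not in ("fixed", "multiplicative_random", "auto"):
            raise ConfigError(f"unknown IVW model {model!r}")
        _require(hset, 1 if model == "fixed" else (1 if model == "auto" else 2), "IVW")
        bx, by, sy = hset.beta_exposure, hset.beta_outcome, hset.se_outcome
        beta, se_fe, q = _ivw_core(bx, by, sy)
        j = hset.n_snp
        het = None
        if j >= 2:
            df = j - 1
            het = HeterogeneityResult(q=q, df=df, pval=float(stats.chi2.sf(q, df)), method="ivw")
        if model == "auto":
            model = (
                "multiplicative_random" if het is not None and het.pval < 0.05 else "fixed"
            )
        if model == "multiplicative_random":
            if j < 2:
                raise InsufficientInstrumentsError(
                    "random-effects IVW requires at least 2 SNPs"
                )
            phi = max(1.0, math.sqrt(q / (j - 1)))
            se = se_fe * phi
            method = "ivw_re"
        else:
            se = se_fe
            method = "ivw_fe"
        return MRResults(
            method=method, beta=beta, se=se, n_snp=j, model=model, heterogeneity=het
        )


class MREgger:
    """MR-Egger regression: weighted fit of by on bx with a free intercept.

    Each SNP is first oriented so its exposure beta is non-negative (both
    betas sign-flipped together).  The slope estimates the causal effect under
    InSIDE; a non-zero intercept indicates directional pleiotropy.  Both SEs
    are inflated by max(1, sqrt(Q_egger/(J-2))).
    """

    def __init__(self, hset: HarmonizedSet):
        self.data = hset

    def fit(self, min_snp: int = 3) -> MRResults:
        hset = self.data
        _require(hset, min_snp, "MR-Egger")
        sgn = np.where(hset.beta_exposure < 0, -1.0, 1.0)
        bx = hset.beta_exposure * sgn
        by = hset.beta_outcome * sgn
        sy = hset.se_outcome
        w = 1.0 / sy**2
        x = np.column_stack([np.ones_like(bx), bx])
        xtwx = x.T @ (w[:, None] * x)
        coef = np.linalg.solve(xtwx, x.T @ (w * by))
        cov_unit = np.linalg.inv(xtwx)  # covariance at unit residual scale
        resid = by - x @ coef
        q = float(np.sum(w * resid**2))
        j = hset.n_snp
        phi = max(1.0, math.sqrt(q / (j - 2))) if j > 2 else 1.0
        se_slope = math.sqrt(cov_unit[1, 1]) * phi
        se_int = math.sqrt(cov_unit[0, 0]) * phi
        het = HeterogeneityResult(
            q=q, df=j - 2, pval=float(stats.chi2.sf(q, j - 2)) if j > 2 else 1.0,
            method="egger",
        )
        pleio = PleiotropyResult(
            intercept=float(coef[0]),
            intercept_se=se_int,
            pval=2.0 * float(stats.norm.sf(abs(coef[0] / se_int))),
        )
        return MRResults(
            method="egger",
            beta=float(coef[1]),
            se=se_slope,
            n_snp=j,
            model="multiplicative_random" if phi > 1.0 else "fixed",
            heterogeneity=het,
            pleiotropy=pleio,
        )


def _ml_profile_negll(theta: float, bx, sx, by, sy) -> float:
    # nuisance per-SNP true exposure effects profiled out in closed form
    return float(np.sum((by - theta * bx) ** 2 / (sy**2 + theta**2 * sx**2)))


class MaximumLikelihood:
    """Profile-likelihood estimator allowing error in the exposure betas.

    Observed (bx_j, by_j) are modelled as independent normals centred at
    (gamma_j, theta*gamma_j); the per-SNP gamma_j are profiled out in closed
    form, leaving a one-dimensional objective in theta.  The SE comes from the
    curvature of the profile log-likelihood at the optimum.
    """

    def __init__(self, hset: HarmonizedSet):
        self.data = hset

    def fit(
        self,
        bracket: tuple[float, float] = (-10.0, 10.0),
        tol: float = 1e-8,
        maxiter: int = 500,
    ) -> MRResults:
        hset = self.data
        _require(hset, 2, "maximum likelihood")
        bx, sx = hset.beta_exposure, hset.se_exposure
        by, sy = hset.beta_outcome, hset.se_outcome
        res = optimize.minimize_scalar(
            _ml_profile_negll,
            bounds=bracket,
            args=(bx, sx, by, sy),
            method="bounded",
            options={"xatol": tol, "maxiter": maxiter},
        )
        if not res.success:
            raise EstimationError(f"ML profile optimization failed: {res.message}")
        theta = float(res.x)
        # polish with a derivative root for full precision when interior
        def dprofile(t: float) -> float:
            v = sy**2 + t**2 * sx**2
            r = by - t * bx
            return float(np.sum(-2 * bx * r / v - r**2 * 2 * t * sx**2 / v**2))

        h = 1e-5 * (1.0 + abs(theta))
        lo, hi = theta - 10 * h, theta + 10 * h
        if dprofile(lo) * dprofile(hi) < 0:
            theta = float(optimize.brentq(dprofile, lo, hi, xtol=1e-12))
        # curvature of the -2 log-likelihood profile -> observed information
        f0 = _ml_profile_negll(theta, bx, sx, by, sy)
        fp = _ml_profile_negll(theta + h, bx, sx, by, sy)
        fm = _ml_profile_negll(theta - h, bx, sx, by, sy)
        d2 = (fp - 2 * f0 + fm) / h**2
        if d2 <= 0:
            raise EstimationError("non-positive profile curvature at the ML optimum")
        se = math.sqrt(2.0 / d2)
        return MRResults(method="ml", beta=theta, se=se, n_snp=hset.n_snp)


class RAPS:
    """Robust adjusted profile score estimator.

    Solves sum_j psi(t_j) * dt_j/dtheta = 0 with standardized residuals
    t_j = (by_j - theta bx_j) / sqrt(sy_j^2 + theta^2 sx_j^2 + tau^2).
    ``loss="huber"`` uses psi(t) = clip(t, -1.345, 1.345); with
    ``overdispersion=True`` tau^2 is chosen so the mean squared residual is 1.
    SE by the sandwich formula; p-values use the normal approximation.
    """

    def __init__(self, hset: HarmonizedSet):
        self.data = hset

    @staticmethod
    def _psi(t: np.ndarray, loss: str) -> np.ndarray:
        if loss == "l2":
            return t
        return np.clip(t, -HUBER_K, HUBER_K)

    @staticmethod
    def _psi_prime(t: np.ndarray, loss: str) -> np.ndarray:
        if loss == "l2":
            return np.ones_like(t)
        return (np.abs(t) <= HUBER_K).astype(float)

    def _score(self, theta: float, tau2: float, loss: str) -> float:
        h = self.data
        v = h.se_outcome**2 + theta**2 * h.se_exposure**2 + tau2
        s = np.sqrt(v)
        t = (h.beta_outcome - theta * h.beta_exposure) / s
        dt = -h.beta_exposure / s - t * theta * h.se_exposure**2 / v
        return float(np.sum(self._psi(t, loss) * dt))

    def _solve_theta(self, tau2: float, loss: str, bracket, maxiter) -> float:
        grid = np.linspace(bracket[0], bracket[1], 201)
        vals = np.array([self._score(g, tau2, loss) for g in grid])
        sign_change = np.flatnonzero(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0)
        if len(sign_change) == 0:
            raise EstimationError(
                f"RAPS score has no root in [{bracket[0]}, {bracket[1]}]"
            )
        # closest root to the IVW start, for stability under multiple roots
        i = sign_change[np.argmin(np.abs(grid[sign_change]))]
        return float(
            optimize.brentq(
                self._score, grid[i], grid[i + 1], args=(tau2, loss),
                xtol=1e-10, maxiter=maxiter,
            )
        )

    def _mean_t2(self, theta: float, tau2: float) -> float:
        h = self.data
        v = h.se_outcome**2 + theta**2 * h.se_exposure**2 + tau2
        t = (h.beta_outcome - theta * h.beta_exposure) ** 2 / v
        return float(np.mean(t))

    def fit(
        self,
        loss: str = "l2",
        overdispersion: bool = False,
        bracket: tuple[float, float] = (-10.0, 10.0),
        maxiter: int = 500,
    ) -> MRResults:
        hset = self.data
        _require(hset, 3, "RAPS")
        if loss not in ("l2", "huber"):
            raise ConfigError(f"unknown RAPS loss {loss!r}")
        tau2 = 0.0
        theta = self._solve_theta(tau2, loss, bracket, maxiter)
        if overdispersion:
            for _ in range(50):
                if self._mean_t2(theta, 0.0) <= 1.0:
                    new_tau2 = 0.0
                else:
                    hi = 1.0
                    while self._mean_t2(theta, hi) > 1.0 and hi < 1e6:
                        hi *= 10.0
                    new_tau2 = float(
                        optimize.brentq(
                            lambda t2: self._mean_t2(theta, t2) - 1.0, 0.0, hi, xtol=1e-12
                        )
                    )
                new_theta = self._solve_theta(new_tau2, loss, bracket, maxiter)
                if abs(new_theta - theta) < 1e-10 and abs(new_tau2 - tau2) < 1e-10:
                    theta, tau2 = new_theta, new_tau2
                    break
                theta, tau2 = new_theta, new_tau2
        # sandwich SE
        v = hset.se_outcome**2 + theta**2 * hset.se_exposure**2 + tau2
        s = np.sqrt(v)
        t = (hset.beta_outcome - theta * hset.beta_exposure) / s
        dt = -hset.beta_exposure / s - t * theta * hset.se_exposure**2 / v
        a = float(np.sum(self._psi_prime(t, loss) * dt**2))
        b = float(np.sum((self._psi(t, loss) * dt) ** 2))
        if a == 0:
            raise EstimationError("degenerate RAPS information")
        se = math.sqrt(b) / a
        return MRResults(
            method="raps",
            beta=theta,
            se=se,
            n_snp=hset.n_snp,
            extra={"tau2": tau2, "loss": loss},
        )


# ---------------------------------------------------------------------------
# diagnostics


def cochran_q(hset: HarmonizedSet, around: str = "ivw") -> HeterogeneityResult:
    """Cochran's Q around the IVW line (df = J-1) or the Egger fit (df = J-2)."""
    if around == "ivw":
        _require(hset, 2, "Cochran Q (IVW)")
        res = IVW(hset).fit(model="fixed")
        assert res.heterogeneity is not None
        return res.heterogeneity
    if around == "egger":
        _require(hset, 3, "Cochran Q (Egger)")
        res = MREgger(hset).fit()
        assert res.heterogeneity is not None
        return res.heterogeneity
    raise ConfigError(f"unknown Q reference fit {around!r}")


def steiger_test(
    hset: HarmonizedSet,
    n_exposure: int | None = None,
    n_outcome: int | None = None,
) -> SteigerResult:
    """Directionality: summed instrument r^2 on exposure vs outcome.

    Per-SNP r^2 = F/(F + n - 2) with F = (beta/se)^2 against the respective
    trait; the p-value is a two-sample z test on Fisher-transformed sqrt(r^2).
    """
    n_x = n_exposure if n_exposure is not None else hset.n_exposure
    n_y = n_outcome if n_outcome is not None else hset.n_outcome
    if n_x is None or n_y is None:
        raise ConfigError("Steiger test needs exposure and outcome sample sizes")
    if n_x <= 3 or n_y <= 3:
        raise ConfigError("Steiger test needs sample sizes > 3")
    fx = (hset.beta_exposure / hset.se_exposure) ** 2
    fy = (hset.beta_outcome / hset.se_outcome) ** 2
    r2_x = float(np.sum(fx / (fx + n_x - 2)))
    r2_y = float(np.sum(fy / (fy + n_y - 2)))
    r2_x_c = min(r2_x, 1.0)
    r2_y_c = min(r2_y, 1.0)
    z_x = np.arctanh(math.sqrt(r2_x_c)) if r2_x_c < 1 else np.inf
    z_y = np.arctanh(math.sqrt(r2_y_c)) if r2_y_c < 1 else np.inf
    z = (z_x - z_y) / math.sqrt(1.0 / (n_x - 3) + 1.0 / (n_y - 3))
    pval = 2.0 * float(stats.norm.sf(abs(z))) if np.isfinite(z) else 1.0
    return SteigerResult(
        r2_exposure=r2_x,
        r2_outcome=r2_y,
        direction_correct=r2_x > r2_y,
        pval=pval,
    )


def leave_one_out(hset: HarmonizedSet, model: str = "auto") -> pd.DataFrame:
    """IVW re-estimated J times, excluding one SNP each; flags influential SNPs.

    A row is flagged when dropping its SNP changes the sign of the estimate or
    makes a nominally significant full-set estimate lose significance.
    """
    if hset.n_snp < 3:
        raise InsufficientInstrumentsError("leave-one-out requires at least 3 SNPs")
    full = IVW(hset).fit(model=model)
    rows = []
    for i, vid in enumerate(hset.snp_ids):
        sub = hset.subset([j for j in range(hset.n_snp) if j != i])
        est = IVW(sub).fit(model=model)
        flagged = (np.sign(est.beta) != np.sign(full.beta)) or (
            full.pval < 0.05 <= est.pval
        )
        rows.append(
            {
                "left_out_variant": vid,
                "beta": est.beta,
                "se": est.se,
                "or": est.or_,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "pval": est.pval,
                "flagged": bool(flagged),
            }
        )
    return pd.DataFrame(rows)


def power_binary(
    r2_sum: float,
    n_outcome: int,
    case_fraction: float,
    assumed_or: float,
    alpha: float = 0.05,
) -> PowerResult:
    """Analytic two-sided power for MR against a binary outcome.

    Non-centrality approximation: the IVW z statistic is ~N(x, 1) with
    x = sqrt(n * r2 * cf * (1 - cf)) * ln(OR), so
    power = Phi(x - z_{1-a/2}) + Phi(-x - z_{1-a/2}); equals alpha at OR = 1.
    """
    if not 0.0 < case_fraction < 1.0:
        raise ConfigError("case_fraction must be in (0,1)")
    if not 0.0 < r2_sum < 1.0:
        raise ConfigError("r2_sum must be in (0,1)")
    if assumed_or <= 0:
        raise ConfigError("assumed_or must be positive")
    z_crit = stats.norm.ppf(1.0 - alpha / 2.0)
    x = math.sqrt(n_outcome * r2_sum * case_fraction * (1.0 - case_fraction)) * abs(
        math.log(assumed_or)
    )
    power = float(stats.norm.cdf(x - z_crit) + stats.norm.cdf(-x - z_crit))
    return PowerResult(
        power=power,
        alpha=alpha,
        assumed_or=assumed_or,
        r2_sum=r2_sum,
        n_outcome=n_outcome,
        case_fraction=case_fraction,
    )
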