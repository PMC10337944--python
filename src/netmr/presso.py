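"""MR-PRESSO: simulation-based global pleiotropy test, per-SNP outlier
detection, and the distortion test.

The global test compares the observed leave-one-out residual sum of squares
against a parametric-bootstrap null; per-SNP outlier p-values compare each
observed squared residual with its simulated counterparts (Bonferroni
adjusted); the distortion test asks whether removing the flagged outliers
changes the pooled IVW estimate more than removing random SNPs would.

All randomness flows from an explicit seed, so the outlier lists feeding the
"after removing outliers" re-analysis are reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigError, InsufficientInstrumentsError
from .sumstats import HarmonizedSet
from .uvmr import IVW, MRResults


@dataclass
class PressoResults:
    """Global, outlier, and distortion results of one MR-PRESSO run."""

    rss_obs: float
    global_pval: float
    n_sim: int
    seed: int
    outlier_ids: list[str] = field(default_factory=list)
    outlier_table: pd.DataFrame | None = None
    distortion_pval: float | None = None
    estimate_raw: MRResults | None = None
    estimate_corrected: MRResults | None = None

    @property
    def has_outliers(self) -> bool:
        return len(self.outlier_ids) > 0

    def summary(self) -> str:
        lines = [
            f"MR-PRESSO global: RSS_obs = {self.rss_obs:.4g}, "
            f"p = {self.global_pval:.4g} ({self.n_sim} simulations, seed {self.seed})",
            f"  outliers flagged: {len(self.outlier_ids)}"
            + (f" ({', '.join(self.outlier_ids)})" if self.outlier_ids else ""),
        ]
        if self.distortion_pval is not None:
            lines.append(f"  distortion test p = {self.distortion_pval:.4g}")
        if self.estimate_corrected is not None:
            lines.append("  corrected " + self.estimate_corrected.summary().splitlines()[0])
        return "\n".join(lines)


def _loo_slopes(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW slopes theta_hat(-j), vectorized over j.

    ``bx``/``by`` may be 1-D (one dataset) or 2-D (n_sim, J) for bootstrap
    replicates; weights ``w`` are always the observed 1/sy^2.
    """
    s1 = np.sum(w * bx * by, axis=-1, keepdims=True)
    s2 = np.sum(w * bx**2, axis=-1, keepdims=True)
    return (s1 - w * bx * by) / (s2 - w * bx**2)


def _residual_sim(
    hset: HarmonizedSet, n_sim: int, seed: int, weighted: bool
) -> tuple[np.ndarray, float, np.ndarray]:
    """Observed LOO residuals, RSS, and the (n_sim, J) simulated residuals."""
    bx, sx = hset.beta_exposure, hset.se_exposure
    by, sy = hset.beta_outcome, hset.se_outcome
    w = 1.0 / sy**2 if weighted else np.ones_like(sy)
    theta_loo = _loo_slopes(bx, by, w)
    resid = by - theta_loo * bx
    rss_obs = float(np.sum(w * resid**2))

    rng = np.random.default_rng(seed)
    by_star = theta_loo * bx + sy * rng.standard_normal((n_sim, bx.size))
    bx_star = bx + sx * rng.standard_normal((n_sim, bx.size))
    theta_star = _loo_slopes(bx_star, by_star, w)
    resid_star = by_star - theta_star * bx_star
    return resid, rss_obs, resid_star


class MRPresso:
    """MR-PRESSO on a harmonized set; ``fit()`` runs global test, outlier
    scan, and (when outliers are found) the distortion test.

    Parameters
    ----------
    hset : HarmonizedSet
        Single-exposure harmonized instruments (J >= 4).
    n_sim : int
        Parametric-bootstrap replicates (default 1000).
    seed : int
        Mandatory; all p-values and outlier lists are deterministic given it.
    weighted : bool
        Use 1/sy^2-weighted residual sums (default); False gives the
        unweighted variant.
    """

    def __init__(self, hset: HarmonizedSet, n_sim: int = 1000, *, seed: int,
                 weighted: bool = True):
        if hset.beta_exposure.ndim != 1:
            raise ConfigError("MR-PRESSO expects a single-exposure harmonized set")
        if hset.n_snp < 4:
            raise InsufficientInstrumentsError("MR-PRESSO requires at least 4 SNPs")
        if n_sim < 1:
            raise ConfigError("n_sim must be >= 1")
        self.data = hset
        self.n_sim = int(n_sim)
        self.seed = int(seed)
        self.weighted = weighted

    # -- stages -------------------------------------------------------------

    def global_test(self) -> PressoResults:
        """Observed vs simulated leave-one-out weighted RSS."""
        hset = self.data
        resid, rss_obs, resid_star = _residual_sim(
            hset, self.n_sim, self.seed, self.weighted
        )
        w = 1.0 / hset.se_outcome**2 if self.weighted else np.ones(hset.n_snp)
        rss_star = np.sum(w * resid_star**2, axis=1)
        global_pval = (1.0 + float(np.sum(rss_star >= rss_obs))) / (self.n_sim + 1.0)
        return PressoResults(
            rss_obs=rss_obs,
            global_pval=global_pval,
            n_sim=self.n_sim,
            seed=self.seed,
            estimate_raw=IVW(hset).fit(model="auto"),
        )

    def outlier_test(self, alpha: float = 0.05) -> PressoResults:
        """Per-SNP outlier p-values, Bonferroni-adjusted across the J SNPs."""
        hset = self.data
        resid, rss_obs, resid_star = _residual_sim(
            hset, self.n_sim, self.seed, self.weighted
        )
        j = hset.n_snp
        p_raw = (1.0 + np.sum(resid_star**2 >= resid**2, axis=0)) / (self.n_sim + 1.0)
        p_adj = np.minimum(1.0, p_raw * j)
        flagged = p_adj < alpha
        table = pd.DataFrame(
            {
                "variant_id": hset.snp_ids,
                "residual": resid,
                "pval": p_raw,
                "pval_adj": p_adj,
                "flagged": flagged,
            }
        )
        res = self.global_test()
        res.outlier_ids = [v for v, f in zip(hset.snp_ids, flagged) if f]
        res.outlier_table = table
        return res

    def distortion_test(self, outlier_ids: list[str]) -> tuple[float, MRResults]:
        """Distortion p and the outlier-corrected IVW estimate.

        D = (theta_raw - theta_corrected)/|theta_corrected| is compared with
        the same statistic after removing equally many random SNPs.
        """
        hset = self.data
        if not outlier_ids:
            raise ConfigError("distortion test needs a non-empty outlier list")
        if len(outlier_ids) >= hset.n_snp:
            raise ConfigError("cannot flag every SNP as an outlier")
        unknown = set(outlier_ids) - set(hset.snp_ids)
        if unknown:
            raise ConfigError(f"unknown outlier ids: {sorted(unknown)}")
        raw = IVW(hset).fit(model="auto")
        kept = hset.exclude(outlier_ids)
        corrected = IVW(kept).fit(model="auto")
        d_obs = (raw.beta - corrected.beta) / abs(corrected.beta)
        rng = np.random.default_rng(self.seed + 1)  # distinct stream from RSS sim
        j, k = hset.n_snp, len(outlier_ids)
        d_null = np.empty(self.n_sim)
        for i in range(self.n_sim):
            drop = rng.choice(j, size=k, replace=False)
            sub = hset.subset(np.setdiff1d(np.arange(j), drop))
            theta = IVW(sub).fit(model="fixed").beta
            d_null[i] = (raw.beta - theta) / abs(theta) if theta != 0 else np.inf
        pval = (1.0 + float(np.sum(np.abs(d_null) >= abs(d_obs)))) / (self.n_sim + 1.0)
        return pval, corrected

    def fit(self, alpha: float = 0.05, iterate: bool = False) -> PressoResults:
        """Full MR-PRESSO pass: global test, outlier scan, distortion test.

        With ``iterate=True`` the outlier scan is repeated on the reduced set
        until no new outlier is flagged (single pass by default).
        """
        res = self.outlier_test(alpha=alpha)
        if iterate and res.outlier_ids:
            current = self.data
            all_outliers = list(res.outlier_ids)
            round_seed = self.seed
            while all_outliers and current.n_snp - len(res.outlier_ids) >= 4:
                current = current.exclude(res.outlier_ids)
                round_seed += 1
                sub = MRPresso(
                    current, self.n_sim, seed=round_seed, weighted=self.weighted
                ).outlier_test(alpha=alpha)
                if not sub.outlier_ids:
                    break
                all_outliers.extend(sub.outlier_ids)
                res.outlier_ids = sub.outlier_ids
            res.outlier_ids = all_outliers
        if res.outlier_ids and len(res.outlier_ids) < self.data.n_snp:
            res.distortion_pval, res.estimate_corrected = self.distortion_test(
                res.outlier_ids
            )
        return res
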