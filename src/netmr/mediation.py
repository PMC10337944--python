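"""Multivariable MR and the network mediation decomposition.

The mediation logic follows the difference method on the log-odds scale: the
total effect of the exposure on the outcome comes from univariable IVW, the
direct effect (conditional on one or more mediators) from multivariable IVW,
and the indirect effect is their difference.  The proportion mediated is

    PM = beta_indirect / beta_total = 1 - beta_direct / beta_total.

:func:`run_network` orchestrates the full design: the three univariable
layers (exposure->outcome, exposure->mediators, mediators->outcome) with the
complete sensitivity battery per edge, MR-PRESSO outlier removal feeding the
headline estimates, per-mediator MVMR decompositions, and the joint
all-mediator MVMR.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import __version__
from .exceptions import (
    CollinearityError,
    ConfigError,
    HarmonizationError,
    InsufficientInstrumentsError,
    UndefinedMediationError,
)
from .presso import MRPresso, PressoResults
from .sumstats import (
    HarmonizedSet,
    InstrumentCriteria,
    SummaryRecord,
    align_to,
    clump_by_distance,
    f_statistic,
    harmonize_pair,
    read_sumstats,
    select_instruments,
)
from .uvmr import (
    IVW,
    MaximumLikelihood,
    MREgger,
    MRResults,
    RAPS,
    Z975,
    leave_one_out,
    power_binary,
    steiger_test,
)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class MVMRResults:
    """Direct (conditional) effects of several exposures on one outcome."""

    exposures: tuple[str, ...]
    betas: np.ndarray
    ses: np.ndarray
    n_snp: int
    model: str
    q: float
    q_pval: float

    @property
    def pvals(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.betas / self.ses))

    def beta(self, exposure: str) -> float:
        return float(self.betas[self.exposures.index(exposure)])

    def se(self, exposure: str) -> float:
        return float(self.ses[self.exposures.index(exposure)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "exposure": self.exposures,
                "beta": self.betas,
                "se": self.ses,
                "or": np.exp(self.betas),
                "ci_low": np.exp(self.betas - Z975 * self.ses),
                "ci_high": np.exp(self.betas + Z975 * self.ses),
                "pval": self.pvals,
                "nsnp": self.n_snp,
                "model": self.model,
            }
        )

    def summary(self) -> str:
        lines = [f"MVMR ({self.model}), {self.n_snp} SNPs, Q = {self.q:.2f} (p = {self.q_pval:.3g})"]
        for name, b, s, p in zip(self.exposures, self.betas, self.ses, self.pvals):
            lines.append(
                f"  {name}: beta = {b:+.4f} (SE {s:.4f}), OR = {math.exp(b):.3f}, p = {p:.3g}"
            )
        return "\n".join(lines)


def harmonize_multi(
    exposures: dict[str, list[SummaryRecord]],
    outcome: list[SummaryRecord],
    restrict_to: set[str] | None = None,
    palindrome_eaf_band: tuple[float, float] = (0.42, 0.58),
) -> HarmonizedSet:
    """Harmonize several exposures and one outcome to a shared orientation.

    The first exposure's effect allele defines the orientation.  Variants
    missing from any trait, or failing allele reconciliation against the
    reference, are dropped with a reason.
    """
    if len(exposures) < 1:
        raise ConfigError("harmonize_multi needs at least one exposure")
    names = list(exposures)
    ref_name = names[0]
    maps = {name: {r.variant_id: r for r in recs} for name, recs in exposures.items()}
    out_map = {r.variant_id: r for r in outcome}

    ref_records = exposures[ref_name]
    if restrict_to is not None:
        ref_records = [r for r in ref_records if r.variant_id in restrict_to]

    ids: list[str] = []
    bx_rows, sx_rows, by, sy, eas, oas = [], [], [], [], [], []
    dropped: list[tuple[str, str]] = []
    for ref in ref_records:
        vid = ref.variant_id
        present = all(vid in maps[n] for n in names) and vid in out_map
        if not present:
            dropped.append((vid, "missing-in-some-trait"))
            continue
        row_b, row_s = [ref.beta], [ref.se]
        ok = True
        for n in names[1:]:
            aligned, reason = align_to(ref, maps[n][vid], palindrome_eaf_band)
            if aligned is None:
                dropped.append((vid, f"{reason} ({n})"))
                ok = False
                break
            row_b.append(aligned.beta)
            row_s.append(aligned.se)
        if not ok:
            continue
        out_aligned, reason = align_to(ref, out_map[vid], palindrome_eaf_band)
        if out_aligned is None:
            dropped.append((vid, f"{reason} (outcome)"))
            continue
        ids.append(vid)
        bx_rows.append(row_b)
        sx_rows.append(row_s)
        by.append(out_aligned.beta)
        sy.append(out_aligned.se)
        eas.append(ref.effect_allele)
        oas.append(ref.other_allele)
    if not ids:
        raise HarmonizationError("no overlapping variants across all traits")
    n_each = [
        next((r.n for r in exposures[n] if r.n is not None), None) for n in names
    ]
    return HarmonizedSet(
        snp_ids=ids,
        beta_exposure=np.array(bx_rows),
        se_exposure=np.array(sx_rows),
        beta_outcome=np.array(by),
        se_outcome=np.array(sy),
        n_exposure=n_each[0],
        n_outcome=next((out_map[v].n for v in ids if out_map[v].n is not None), None),
        dropped=dropped,
        exposure_names=names,
        effect_alleles=eas,
        other_alleles=oas,
        n_exposures_each=n_each,
    )


def union_instruments(
    exposures: dict[str, list[SummaryRecord]],
    criteria: InstrumentCriteria = InstrumentCriteria(),
) -> set[str]:
    """Union of genome-wide-significant instruments, re-clumped jointly.

    Joint clumping is greedy on each variant's best (smallest) p across the
    contributing exposures.
    """
    best: dict[str, SummaryRecord] = {}
    for recs in exposures.values():
        try:
            selected = select_instruments(recs, criteria)
        except Exception:
            selected = []
        for r in selected:
            if r.variant_id not in best or r.pval < best[r.variant_id].pval:
                best[r.variant_id] = r
    if not best:
        raise InsufficientInstrumentsError(
            "no exposure contributed a genome-wide-significant instrument"
        )
    clumped = clump_by_distance(
        list(best.values()), window_kb=criteria.clump_window_kb,
        r2_threshold=criteria.clump_r2,
    )
    return {r.variant_id for r in clumped}


class MVMR:
    """Multivariable IVW: weighted regression of outcome betas on the
    exposure-beta matrix without intercept (weights 1/sy^2).

    Coefficient k is the direct effect of exposure k conditional on the
    others.  Construct from a multi-exposure :class:`HarmonizedSet`, or use
    :meth:`from_sumstats` to build the union-instrument set from raw records.
    """

    def __init__(self, hset: HarmonizedSet):
        if hset.beta_exposure.ndim != 2:
            raise ConfigError("MVMR needs a multi-exposure harmonized set (2-D betas)")
        self.data = hset

    @classmethod
    def from_sumstats(
        cls,
        exposures: dict[str, list[SummaryRecord]],
        outcome: list[SummaryRecord],
        criteria: InstrumentCriteria = InstrumentCriteria(),
        palindrome_eaf_band: tuple[float, float] = (0.42, 0.58),
    ) -> "MVMR":
        ids = union_instruments(exposures, criteria)
        hset = harmonize_multi(
            exposures, outcome, restrict_to=ids,
            palindrome_eaf_band=palindrome_eaf_band,
        )
        return cls(hset)

    def fit(self, model: str = "auto") -> MVMRResults:
        hset = self.data
        x = hset.beta_exposure
        j, k = x.shape
        if j <= k + 1:
            raise InsufficientInstrumentsError(
                f"MVMR with {k} exposures needs more than {k + 1} SNPs, got {j}"
            )
        corr = np.corrcoef(x, rowvar=False)
        for a in range(k):
            for b in range(a + 1, k):
                if abs(corr[a, b]) > 0.9999:
                    raise CollinearityError(
                        "collinear exposure effects: "
                        f"{hset.exposure_names[a]} vs {hset.exposure_names[b]}"
                    )
        if np.linalg.matrix_rank(x) < k:
            raise CollinearityError("exposure-beta matrix is rank deficient")
        w = 1.0 / hset.se_outcome**2
        xtwx = x.T @ (w[:, None] * x)
        betas = np.linalg.solve(xtwx, x.T @ (w * hset.beta_outcome))
        cov = np.linalg.inv(xtwx)
        resid = hset.beta_outcome - x @ betas
        q = float(np.sum(w * resid**2))
        df = j - k
        q_pval = float(stats.chi2.sf(q, df))
        if model == "auto":
            model = "multiplicative_random" if q_pval < 0.05 else "fixed"
        if model not in ("fixed", "multiplicative_random"):
            raise ConfigError(f"unknown MVMR model {model!r}")
        phi = max(1.0, math.sqrt(q / df)) if model == "multiplicative_random" else 1.0
        ses = np.sqrt(np.diag(cov)) * phi
        return MVMRResults(
            exposures=tuple(hset.exposure_names),
            betas=betas,
            ses=ses,
            n_snp=j,
            model=model,
            q=q,
            q_pval=q_pval,
        )


@dataclass(frozen=True)
class MediationResult:
    """Total/direct/indirect decomposition and proportion mediated."""

    exposure: str
    outcome: str
    mediators: tuple[str, ...]
    beta_total: float
    beta_direct: float
    total_se: float | None = None
    direct_se: float | None = None
    pm_ci: tuple[float, float] | None = None

    @property
    def beta_indirect(self) -> float:
        return self.beta_total - self.beta_direct

    @property
    def pm(self) -> float:
        return self.beta_indirect / self.beta_total

    @property
    def or_total(self) -> float:
        return math.exp(self.beta_total)

    @property
    def or_direct(self) -> float:
        return math.exp(self.beta_direct)

    def to_record(self) -> dict:
        rec = {
            "exposure": self.exposure,
            "outcome": self.outcome,
            "adjusted_for": "+".join(self.mediators),
            "beta_total": self.beta_total,
            "beta_direct": self.beta_direct,
            "beta_indirect": self.beta_indirect,
            "or_total": self.or_total,
            "or_direct": self.or_direct,
            "pm": self.pm,
            "pm_percent": 100.0 * self.pm,
        }
        if self.pm_ci is not None:
            rec["pm_ci_low"], rec["pm_ci_high"] = self.pm_ci
        return rec

    def summary(self) -> str:
        ci = (
            f" (95% CI {self.pm_ci[0]:.3f}-{self.pm_ci[1]:.3f})"
            if self.pm_ci is not None
            else ""
        )
        return (
            f"{self.exposure} -> {self.outcome} via {'+'.join(self.mediators)}: "
            f"total = {self.beta_total:+.4f} (OR {self.or_total:.3f}), "
            f"direct = {self.beta_direct:+.4f} (OR {self.or_direct:.3f}), "
            f"indirect = {self.beta_indirect:+.4f}, PM = {100 * self.pm:.2f}%{ci}"
        )


def mediation_decompose(
    total: MRResults | float,
    direct: float,
    direct_se: float | None = None,
    total_se: float | None = None,
    exposure: str = "exposure",
    outcome: str = "outcome",
    mediators: tuple[str, ...] = ("mediator",),
    bootstrap: int = 0,
    seed: int = 0,
) -> MediationResult:
    """Difference-method mediation on the log-odds scale.

    ``beta_indirect = beta_total - beta_direct`` and ``PM =
    beta_indirect/beta_total``.  The PM confidence interval uses the delta
    method treating the two estimates as independent,
    var(PM) ~ (direct^2/total^4) var(total) + var(direct)/total^2; a
    parametric bootstrap (``bootstrap`` > 0 draws) is available instead.
    """
    if isinstance(total, MRResults):
        beta_total, total_se = total.beta, total.se
    else:
        beta_total = float(total)
    if beta_total == 0.0:
        raise UndefinedMediationError("total effect is zero; PM undefined")
    result_ci = None
    pm = (beta_total - direct) / beta_total
    if total_se is not None and direct_se is not None:
        if bootstrap > 0:
            rng = np.random.default_rng(seed)
            tot = rng.normal(beta_total, total_se, size=bootstrap)
            dirs = rng.normal(direct, direct_se, size=bootstrap)
            draws = 1.0 - dirs / tot
            result_ci = (
                float(np.quantile(draws, 0.025)),
                float(np.quantile(draws, 0.975)),
            )
        else:
            var_pm = (direct**2 / beta_total**4) * total_se**2 + (
                direct_se**2 / beta_total**2
            )
            half = Z975 * math.sqrt(var_pm)
            result_ci = (pm - half, pm + half)
    if pm < 0.0 or pm > 1.0:
        warnings.warn(
            f"inconsistent mediation: PM = {pm:.3f} outside [0, 1] "
            f"({exposure} -> {outcome} via {'+'.join(mediators)})",
            stacklevel=2,
        )
    return MediationResult(
        exposure=exposure,
        outcome=outcome,
        mediators=tuple(mediators),
        beta_total=beta_total,
        beta_direct=float(direct),
        total_se=total_se,
        direct_se=direct_se,
        pm_ci=result_ci,
    )


# ---------------------------------------------------------------------------
# network orchestration


@dataclass
class NetworkConfig:
    """Configuration of a full network-MR run.

    ``sumstats`` maps trait names to TSV paths; ``exposure``/``outcome`` name
    the endpoints and ``mediators`` lists the intermediate traits, all of
    which must be keys of ``sumstats``.
    """

    sumstats: dict[str, str]
    exposure: str
    outcome: str
    mediators: list[str]
    seed: int
    criteria: InstrumentCriteria = field(default_factory=InstrumentCriteria)
    palindrome_eaf_band: tuple[float, float] = (0.42, 0.58)
    n_sim: int = 1000
    presso_alpha: float = 0.05
    model: str = "auto"
    outcome_case_fraction: float | None = None

    def __post_init__(self) -> None:
        missing = [
            t
            for t in (self.exposure, self.outcome, *self.mediators)
            if t not in self.sumstats
        ]
        if missing:
            raise ConfigError(f"config lists no sumstats path for: {missing}")

    @classmethod
    def from_yaml(cls, path) -> "NetworkConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: expected a mapping at top level")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        if "criteria" in raw and isinstance(raw["criteria"], dict):
            raw["criteria"] = InstrumentCriteria(**raw["criteria"])
        if "palindrome_eaf_band" in raw:
            raw["palindrome_eaf_band"] = tuple(raw["palindrome_eaf_band"])
        if "seed" not in raw:
            raise ConfigError(f"{path}: a seed is mandatory")
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "sumstats": dict(self.sumstats),
            "exposure": self.exposure,
            "outcome": self.outcome,
            "mediators": list(self.mediators),
            "seed": self.seed,
            "criteria": {
                "p_threshold": self.criteria.p_threshold,
                "clump_r2": self.criteria.clump_r2,
                "clump_window_kb": self.criteria.clump_window_kb,
                "min_f": self.criteria.min_f,
            },
            "palindrome_eaf_band": list(self.palindrome_eaf_band),
            "n_sim": self.n_sim,
            "presso_alpha": self.presso_alpha,
            "model": self.model,
            "outcome_case_fraction": self.outcome_case_fraction,
        }

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass
class EdgeReport:
    """Everything computed for one exposure->outcome edge."""

    exposure: str
    outcome: str
    hset: HarmonizedSet
    hset_corrected: HarmonizedSet
    estimates: dict[str, MRResults]
    presso: PressoResults | None
    loo: pd.DataFrame | None
    steiger: object
    mean_f: float
    power: float | None

    @property
    def headline(self) -> MRResults:
        """The post-outlier-removal IVW estimate (auto model)."""
        return self.estimates["ivw"]

    def to_rows(self) -> list[dict]:
        rows = []
        for name, est in self.estimates.items():
            row = {"exposure": self.exposure, "outcome": self.outcome}
            row.update(est.to_record())
            row["mean_f"] = self.mean_f
            row["steiger_pval"] = self.steiger.pval
            row["steiger_correct"] = self.steiger.direction_correct
            row["power"] = self.power if self.power is not None else float("nan")
            if self.presso is not None:
                row["presso_global_pval"] = self.presso.global_pval
                row["presso_n_outliers"] = len(self.presso.outlier_ids)
            rows.append(row)
        return rows


def analyze_edge(
    exposure_records: list[SummaryRecord],
    outcome_records: list[SummaryRecord],
    criteria: InstrumentCriteria = InstrumentCriteria(),
    palindrome_eaf_band: tuple[float, float] = (0.42, 0.58),
    n_sim: int = 1000,
    seed: int = 0,
    presso_alpha: float = 0.05,
    model: str = "auto",
    exposure_name: str = "exposure",
    outcome_name: str = "outcome",
    case_fraction: float | None = None,
) -> EdgeReport:
    """The paper-style univariable battery for one edge.

    Selects instruments, harmonizes, runs MR-PRESSO and removes flagged
    outliers, then fits IVW (auto fixed/random per Cochran's Q), MR-Egger,
    maximum likelihood and RAPS on the retained SNPs, plus Steiger,
    leave-one-out, instrument F statistics and (binary outcomes) power.
    """
    instruments = select_instruments(exposure_records, criteria)
    hset = harmonize_pair(instruments, outcome_records, palindrome_eaf_band)
    presso = None
    corrected = hset
    if hset.n_snp >= 4:
        presso = MRPresso(hset, n_sim=n_sim, seed=seed).fit(alpha=presso_alpha)
        if presso.outlier_ids and len(presso.outlier_ids) < hset.n_snp:
            corrected = hset.exclude(presso.outlier_ids)
            log.info(
                "%s->%s: removed %d MR-PRESSO outliers (%d SNPs remain)",
                exposure_name, outcome_name, len(presso.outlier_ids), corrected.n_snp,
            )
    estimates: dict[str, MRResults] = {}
    estimates["ivw"] = IVW(corrected).fit(model=model)
    if corrected.n_snp >= 3:
        estimates["egger"] = MREgger(corrected).fit()
    if corrected.n_snp >= 2:
        estimates["ml"] = MaximumLikelihood(corrected).fit()
    if corrected.n_snp >= 3:
        estimates["raps"] = RAPS(corrected).fit(loss="huber", overdispersion=True)
    if presso is not None and presso.estimate_corrected is not None:
        estimates["presso"] = presso.estimate_corrected
    per_f, mean_f = f_statistic(corrected)
    steiger = steiger_test(corrected)
    loo = leave_one_out(corrected, model=model) if corrected.n_snp >= 3 else None
    power = None
    if case_fraction is not None and corrected.n_outcome:
        n_x = corrected.n_exposure
        if n_x:
            r2 = float(np.sum(per_f / (per_f + n_x - 2)))
            power = power_binary(
                r2_sum=min(r2, 0.999),
                n_outcome=corrected.n_outcome,
                case_fraction=case_fraction,
                assumed_or=estimates["ivw"].or_,
            ).power
    return EdgeReport(
        exposure=exposure_name,
        outcome=outcome_name,
        hset=hset,
        hset_corrected=corrected,
        estimates=estimates,
        presso=presso,
        loo=loo,
        steiger=steiger,
        mean_f=mean_f,
        power=power,
    )


@dataclass
class NetworkReport:
    """Bundle of everything a network run produced."""

    config: NetworkConfig
    edges: dict[tuple[str, str], EdgeReport]
    mvmr: dict[str, MVMRResults]
    mediation: list[MediationResult]

    def univariable_table(self) -> pd.DataFrame:
        rows: list[dict] = []
        for report in self.edges.values():
            rows.extend(report.to_rows())
        return pd.DataFrame(rows)

    def mediation_table(self) -> pd.DataFrame:
        rows = []
        for m in self.mediation:
            rec = m.to_record()
            # forest-plot style columns
            direct_se = m.direct_se
            if direct_se is not None:
                rec["or_direct_ci_low"] = math.exp(m.beta_direct - Z975 * direct_se)
                rec["or_direct_ci_high"] = math.exp(m.beta_direct + Z975 * direct_se)
            rows.append(rec)
        return pd.DataFrame(rows)

    def write(self, out_dir) -> dict[str, str]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, str] = {}

        def _save(name: str, df: pd.DataFrame) -> None:
            p = out_dir / name
            df.to_csv(p, sep="\t", index=False)
            paths[name] = str(p)

        _save("univariable.tsv", self.univariable_table())
        _save("mediation.tsv", self.mediation_table())
        for (exp, out), report in self.edges.items():
            tag = f"{exp}__{out}"
            if report.loo is not None:
                _save(f"loo_{tag}.tsv", report.loo)
            if report.presso is not None and report.presso.outlier_table is not None:
                _save(f"presso_{tag}.tsv", report.presso.outlier_table)
            drops = pd.DataFrame(report.hset.dropped, columns=["variant_id", "reason"])
            _save(f"drops_{tag}.tsv", drops)
        manifest = {
            "package_version": __version__,
            "config_hash": self.config.config_hash(),
            "seed": self.config.seed,
            "outputs": paths,
        }
        mp = out_dir / "manifest.json"
        mp.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        paths["manifest.json"] = str(mp)
        return paths


class NetworkMR:
    """Full network-MR mediation analysis driven by a :class:`NetworkConfig`.

    ``run()`` executes the three univariable layers, per-mediator and joint
    MVMR decompositions, and returns a :class:`NetworkReport`.
    """

    def __init__(self, config: NetworkConfig,
                 tables: dict[str, list[SummaryRecord]] | None = None):
        self.config = config
        if tables is None:
            tables = {
                name: read_sumstats(path) for name, path in config.sumstats.items()
            }
        missing = [
            t
            for t in (config.exposure, config.outcome, *config.mediators)
            if t not in tables
        ]
        if missing:
            raise ConfigError(f"missing sumstats tables for: {missing}")
        self.tables = tables

    def _edge_seed(self, index: int) -> int:
        state = np.random.SeedSequence([self.config.seed, 7, index]).generate_state(1)
        return int(state[0] % 2**31)

    def run(self) -> NetworkReport:
        cfg = self.config
        tables = self.tables
        edges: dict[tuple[str, str], EdgeReport] = {}
        pairs = [(cfg.exposure, cfg.outcome)]
        pairs += [(cfg.exposure, m) for m in cfg.mediators]
        pairs += [(m, cfg.outcome) for m in cfg.mediators]
        for i, (a, b) in enumerate(pairs):
            cf = cfg.outcome_case_fraction if b == cfg.outcome else None
            try:
                edges[(a, b)] = analyze_edge(
                    tables[a],
                    tables[b],
                    criteria=cfg.criteria,
                    palindrome_eaf_band=cfg.palindrome_eaf_band,
                    n_sim=cfg.n_sim,
                    seed=self._edge_seed(i),
                    presso_alpha=cfg.presso_alpha,
                    model=cfg.model,
                    exposure_name=a,
                    outcome_name=b,
                    case_fraction=cf,
                )
            except Exception as exc:
                raise type(exc)(f"edge {a} -> {b}: {exc}") from exc

        total = edges[(cfg.exposure, cfg.outcome)].headline
        mvmr_results: dict[str, MVMRResults] = {}
        mediation: list[MediationResult] = []
        mediator_sets = [([m], m) for m in cfg.mediators]
        if len(cfg.mediators) > 1:
            mediator_sets.append((list(cfg.mediators), "joint"))
        for meds, label in mediator_sets:
            exposures = {cfg.exposure: tables[cfg.exposure]}
            for m in meds:
                exposures[m] = tables[m]
            try:
                fit = MVMR.from_sumstats(
                    exposures,
                    tables[cfg.outcome],
                    criteria=cfg.criteria,
                    palindrome_eaf_band=cfg.palindrome_eaf_band,
                ).fit(model=cfg.model)
            except Exception as exc:
                raise type(exc)(f"MVMR [{label}]: {exc}") from exc
            mvmr_results[label] = fit
            mediation.append(
                mediation_decompose(
                    total,
                    fit.beta(cfg.exposure),
                    direct_se=fit.se(cfg.exposure),
                    exposure=cfg.exposure,
                    outcome=cfg.outcome,
                    mediators=tuple(meds),
                )
            )
        return NetworkReport(
            config=cfg, edges=edges, mvmr=mvmr_results, mediation=mediation
        )


def run_network(config: NetworkConfig,
                tables: dict[str, list[SummaryRecord]] | None = None) -> NetworkReport:
    """Convenience wrapper: ``NetworkMR(config, tables).run()``."""
    return NetworkMR(config, tables).run()
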