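"""Synthetic two-sample GWAS summary statistics from a known causal graph.

The generator encodes a linear liability model

    exposure  X  <- gamma_j * G_j                     (per-SNP effects)
    mediator  M_k <- alpha_k * X  (+ own instruments)
    outcome   Y  <- delta * X + sum_k rho_k * M_k  (+ pleiotropy eta_j)

so SNP j with exposure effect gamma_j has true mediator-k effect
gamma_j*alpha_k and true outcome effect gamma_j*(delta + sum_k alpha_k*rho_k)
+ eta_j.  The total effect is delta_total = delta + sum_k alpha_k*rho_k and
the proportion mediated through mediator k is PM_k = alpha_k*rho_k /
delta_total.

Effects are on standardized scales, so the sampling SE of each per-allele
estimate is the closed form 1/sqrt(2 p (1-p) N) (divided additionally by
sqrt(cf (1-cf)) on the log-odds scale for a binary outcome); estimates for
different traits are drawn from independent streams, emulating two
non-overlapping samples.

The default scenario reproduces the conditions of a network MR study of
education and major depressive disorder: total effect ln(0.693) of one SD of
schooling on MDD log-odds, four mediators (neuroticism, BMI, smoking,
household income) with single-path mediated proportions
{52.92, 15.54, 31.86, 81.30}% , GWAS sample sizes 766,345 / 329,821 /
336,107 / 359,706 / 397,751 / 173,005 (34.6% cases), ~250 exposure
instruments and {65, 262, 67, 40} mediator-specific instruments.  Because
those proportions sum to more than 1, the implied direct effect delta has the
opposite sign to the total effect — a feature of the published profile, not a
bug.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigError, UndefinedMediationError
from .sumstats import SummaryRecord, write_sumstats

#: printed-profile constants for the default scenario
_DELTA_TOTAL = math.log(0.693)
_PM_PROFILE = (0.5292, 0.1554, 0.3186, 0.8130)
_ALPHA_PROFILE = (
    math.log(0.716),   # education -> neuroticism
    math.log(0.672),   # education -> BMI
    math.log(1.101),   # education -> smoking (printed orientation)
    math.log(1.927),   # education -> household income
)
_RHO_PROFILE = tuple(
    pm * _DELTA_TOTAL / a for pm, a in zip(_PM_PROFILE, _ALPHA_PROFILE)
)
_DELTA_DIRECT = _DELTA_TOTAL * (1.0 - sum(_PM_PROFILE))

_ALLELE_CYCLE = (
    ("A", "G"), ("G", "A"), ("A", "C"), ("C", "A"),
    ("T", "G"), ("G", "T"), ("T", "C"), ("C", "T"),
)

#: spacing (bp) between adjacent SNPs on a chromosome; larger than the
#: default 10,000 kb clump window so clumping is a no-op unless LD is added
_POS_SPACING = 25_000_000
_N_CHROM = 22


@dataclass(frozen=True)
class PleiotropySpec:
    """Direct SNP->outcome effects: none, balanced (mean 0), or directional."""

    mode: str = "none"  # none | balanced | directional
    sd: float = 0.0
    mean: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("none", "balanced", "directional"):
            raise ConfigError(f"unknown pleiotropy mode {self.mode!r}")
        if self.mode == "balanced" and self.mean != 0.0:
            raise ConfigError("balanced pleiotropy requires mean = 0")


@dataclass(frozen=True)
class NetworkScenario:
    """Ground-truth parameters of the simulated causal graph.

    Defaults encode the education -> {neuroticism, BMI, smoking, income} ->
    MDD study conditions described in the module docstring.
    """

    m_snps: int = 320
    maf_range: tuple[float, float] = (0.05, 0.5)
    prop_causal: float = 0.8
    sigma_gamma: float = 0.025
    alpha: tuple[float, ...] = _ALPHA_PROFILE
    rho: tuple[float, ...] = _RHO_PROFILE
    delta: float = _DELTA_DIRECT
    pleiotropy: PleiotropySpec = field(default_factory=PleiotropySpec)
    mediator_n_snps: tuple[int, ...] = (65, 262, 67, 40)
    mediator_effect_sd: float = 0.03
    #: causal effects are drawn conditional on |true z| >= this, emulating the
    #: fact that published instrument lists contain only detectable loci
    #: (0 disables the conditioning)
    min_instrument_z: float = 7.0
    n_exposure: int = 766_345
    n_mediators: tuple[int, ...] = (329_821, 336_107, 359_706, 397_751)
    n_outcome: int = 173_005
    outcome_binary: bool = True
    case_fraction: float = 0.34595
    seed: int = 0
    exposure_name: str = "education"
    mediator_names: tuple[str, ...] = ("neuroticism", "bmi", "smoking", "income")
    outcome_name: str = "mdd"

    def __post_init__(self) -> None:
        k = len(self.alpha)
        for name, tup in (
            ("rho", self.rho),
            ("mediator_n_snps", self.mediator_n_snps),
            ("n_mediators", self.n_mediators),
            ("mediator_names", self.mediator_names),
        ):
            if len(tup) != k:
                raise ConfigError(f"{name} must have one entry per mediator ({k})")
        if not 0.0 < self.prop_causal <= 1.0:
            raise ConfigError("prop_causal must be in (0,1]")
        if min((self.n_exposure, self.n_outcome, *self.n_mediators), default=1) <= 0:
            raise ConfigError("all sample sizes must be positive")
        lo, hi = self.maf_range
        if not 0.0 < lo <= hi < 1.0:
            raise ConfigError("maf_range must satisfy 0 < lo <= hi < 1")
        if self.outcome_binary and not 0.0 < self.case_fraction < 1.0:
            raise ConfigError("case_fraction must be in (0,1)")

    @property
    def n_mediator_traits(self) -> int:
        return len(self.alpha)

    @property
    def delta_total(self) -> float:
        return self.delta + float(np.dot(self.alpha, self.rho))

    @property
    def trait_names(self) -> tuple[str, ...]:
        return (self.exposure_name, *self.mediator_names, self.outcome_name)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["pleiotropy"] = asdict(self.pleiotropy)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkScenario":
        d = dict(d)
        if "pleiotropy" in d and isinstance(d["pleiotropy"], dict):
            d["pleiotropy"] = PleiotropySpec(**d["pleiotropy"])
        for key in (
            "alpha", "rho", "mediator_n_snps", "n_mediators", "mediator_names",
            "maf_range",
        ):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        unknown = set(d) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ConfigError(f"unknown scenario keys: {sorted(unknown)}")
        return cls(**d)


def null_edge_scenario(
    theta: float = 0.0,
    m_snps: int = 60,
    sigma_gamma: float = 0.05,
    n_exposure: int = 300_000,
    n_outcome: int = 200_000,
    seed: int = 0,
    pleiotropy: PleiotropySpec | None = None,
    outcome_binary: bool = True,
    case_fraction: float = 0.35,
    **extra,
) -> NetworkScenario:
    """A mediator-free exposure->outcome scenario (true effect ``theta``)."""
    return NetworkScenario(
        **extra,
        m_snps=m_snps,
        prop_causal=1.0,
        sigma_gamma=sigma_gamma,
        alpha=(),
        rho=(),
        delta=theta,
        pleiotropy=pleiotropy or PleiotropySpec(),
        mediator_n_snps=(),
        n_exposure=n_exposure,
        n_mediators=(),
        n_outcome=n_outcome,
        outcome_binary=outcome_binary,
        case_fraction=case_fraction,
        seed=seed,
        mediator_names=(),
    )


@dataclass(frozen=True)
class TrueEffects:
    """Per-SNP ground truth implied by a scenario's structural equations."""

    variant_ids: list[str]
    chrom: list[str]
    pos: list[int]
    maf: np.ndarray
    effect_alleles: list[str]
    other_alleles: list[str]
    gamma: np.ndarray                     # SNP -> exposure
    beta_mediators: np.ndarray            # (M, K) SNP -> mediator_k
    beta_outcome: np.ndarray              # SNP -> outcome (incl. pleiotropy)
    eta: np.ndarray                       # pleiotropic component
    mediator_block: np.ndarray            # -1 exposure block, else mediator index
    exposure_causal: np.ndarray           # bool: gamma != 0 by construction
    delta: float
    delta_total: float
    pm: tuple[float, ...]

    @property
    def n_snps(self) -> int:
        return len(self.variant_ids)


def _structure_rng(scenario: NetworkScenario) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([scenario.seed, 0]))


def _truncated_effects(
    rng: np.random.Generator, sd: float, min_abs: np.ndarray | float, size: int
) -> np.ndarray:
    """Draws from N(0, sd) conditioned on |effect| >= min_abs (vectorized).

    Inverse-CDF sampling of the half-normal magnitude above the threshold;
    min_abs = 0 recovers the unconditional normal.
    """
    sign = rng.choice([-1.0, 1.0], size=size)
    u = rng.uniform(size=size)
    c = np.broadcast_to(np.asarray(min_abs, dtype=float), (size,)) / sd
    # magnitude quantile within the upper tail [c, inf) of |N(0,1)|
    lower = 2.0 * stats.norm.cdf(c) - 1.0
    mag = stats.norm.ppf(0.5 + 0.5 * (lower + u * (1.0 - lower)))
    return sign * sd * mag


def implied_effects(scenario: NetworkScenario) -> TrueEffects:
    """Ground-truth effect vectors for every trait, plus delta_total and PM_k.

    The SNP panel is the exposure block (``m_snps`` SNPs, a ``prop_causal``
    fraction causal) followed by one block of mediator-specific instruments
    per mediator.
    """
    k = scenario.n_mediator_traits
    delta_total = scenario.delta_total
    if k > 0 and delta_total == 0.0:
        raise UndefinedMediationError(
            "total effect is zero: proportions mediated are undefined"
        )
    pm = tuple(
        a * r / delta_total for a, r in zip(scenario.alpha, scenario.rho)
    ) if k else ()

    rng = _structure_rng(scenario)
    m_total = scenario.m_snps + sum(scenario.mediator_n_snps)
    maf = rng.uniform(*scenario.maf_range, size=m_total)

    n_causal = int(round(scenario.prop_causal * scenario.m_snps))
    gamma = np.zeros(m_total)
    se_exp = _sampling_se(maf[:n_causal], scenario.n_exposure, None)
    gamma[:n_causal] = _truncated_effects(
        rng, scenario.sigma_gamma, scenario.min_instrument_z * se_exp, n_causal
    )
    exposure_causal = np.zeros(m_total, dtype=bool)
    exposure_causal[:n_causal] = True

    eta = np.zeros(m_total)
    spec = scenario.pleiotropy
    if spec.mode != "none":
        eta[:n_causal] = rng.normal(spec.mean, spec.sd, size=n_causal)

    mediator_block = np.full(m_total, -1, dtype=int)
    beta_mediators = np.zeros((m_total, k))
    alpha = np.asarray(scenario.alpha)
    rho = np.asarray(scenario.rho)
    beta_mediators[:, :] = gamma[:, None] * alpha[None, :] if k else 0.0
    offset = scenario.m_snps
    for ki, nk in enumerate(scenario.mediator_n_snps):
        block = slice(offset, offset + nk)
        mediator_block[block] = ki
        se_med = _sampling_se(maf[block], scenario.n_mediators[ki], None)
        own = _truncated_effects(
            rng, scenario.mediator_effect_sd,
            scenario.min_instrument_z * se_med, nk,
        )
        beta_mediators[block, :] = 0.0
        beta_mediators[block, ki] = own
        offset += nk

    beta_outcome = gamma * delta_total + eta
    if k:
        for ki in range(k):
            blk = mediator_block == ki
            beta_outcome[blk] = beta_mediators[blk, ki] * rho[ki]

    ids = [f"rs{j + 1}" for j in range(m_total)]
    chrom = [str(j % _N_CHROM + 1) for j in range(m_total)]
    pos = [(j // _N_CHROM + 1) * _POS_SPACING for j in range(m_total)]
    ea = [_ALLELE_CYCLE[j % len(_ALLELE_CYCLE)][0] for j in range(m_total)]
    oa = [_ALLELE_CYCLE[j % len(_ALLELE_CYCLE)][1] for j in range(m_total)]
    return TrueEffects(
        variant_ids=ids,
        chrom=chrom,
        pos=pos,
        maf=maf,
        effect_alleles=ea,
        other_alleles=oa,
        gamma=gamma,
        beta_mediators=beta_mediators,
        beta_outcome=beta_outcome,
        eta=eta,
        mediator_block=mediator_block,
        exposure_causal=exposure_causal,
        delta=scenario.delta,
        delta_total=delta_total,
        pm=pm,
    )


def _sampling_se(maf: np.ndarray, n: int, case_fraction: float | None) -> np.ndarray:
    se = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)
    if case_fraction is not None:
        se = se / math.sqrt(case_fraction * (1.0 - case_fraction))
    return se


def _draw_trait(
    truth: TrueEffects,
    true_beta: np.ndarray,
    n: int,
    case_fraction: float | None,
    rng: np.random.Generator,
) -> list[SummaryRecord]:
    se = _sampling_se(truth.maf, n, case_fraction)
    beta_hat = true_beta + se * rng.standard_normal(truth.n_snps)
    z = beta_hat / se
    pval = np.clip(2.0 * stats.norm.sf(np.abs(z)), 1e-320, 1.0)
    return [
        SummaryRecord(
            variant_id=truth.variant_ids[j],
            chrom=truth.chrom[j],
            pos=truth.pos[j],
            effect_allele=truth.effect_alleles[j],
            other_allele=truth.other_alleles[j],
            eaf=float(truth.maf[j]),
            beta=float(beta_hat[j]),
            se=float(se[j]),
            pval=float(pval[j]),
            n=n,
        )
        for j in range(truth.n_snps)
    ]


def simulate_network_sumstats(
    scenario: NetworkScenario,
) -> tuple[dict[str, list[SummaryRecord]], TrueEffects]:
    """Simulate per-trait summary statistics; returns ({trait: records}, truth).

    Each trait's estimates use an independent random stream derived from the
    scenario seed, emulating non-overlapping samples.
    """
    truth = implied_effects(scenario)
    tables: dict[str, list[SummaryRecord]] = {}
    for t, name in enumerate(scenario.trait_names):
        rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 1 + t]))
        if name == scenario.exposure_name:
            true_beta, n, cf = truth.gamma, scenario.n_exposure, None
        elif name == scenario.outcome_name:
            cf = scenario.case_fraction if scenario.outcome_binary else None
            true_beta, n = truth.beta_outcome, scenario.n_outcome
        else:
            ki = scenario.mediator_names.index(name)
            true_beta, n, cf = (
                truth.beta_mediators[:, ki],
                scenario.n_mediators[ki],
                None,
            )
        tables[name] = _draw_trait(truth, true_beta, n, cf, rng)
    return tables, truth


def write_scenario(
    scenario: NetworkScenario, out_dir
) -> dict[str, str]:
    """Write per-trait sumstats TSVs plus a ground-truth sidecar.

    Returns a mapping of logical names (trait names, ``truth``, ``scenario``)
    to file paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tables, truth = simulate_network_sumstats(scenario)
    paths: dict[str, str] = {}
    for name, records in tables.items():
        p = out_dir / f"{name}.sumstats.tsv"
        write_sumstats(records, p)
        paths[name] = str(p)

    truth_df = pd.DataFrame(
        {
            "variant_id": truth.variant_ids,
            "gamma": truth.gamma,
            "eta": truth.eta,
            "beta_outcome": truth.beta_outcome,
            "mediator_block": truth.mediator_block,
        }
    )
    for ki, name in enumerate(scenario.mediator_names):
        truth_df[f"beta_{name}"] = truth.beta_mediators[:, ki]
    truth_path = out_dir / "truth.tsv"
    truth_df.to_csv(truth_path, sep="\t", index=False)
    paths["truth"] = str(truth_path)

    summary = {
        "delta": truth.delta,
        "delta_total": truth.delta_total,
        "pm": list(truth.pm),
        "scenario": scenario.to_dict(),
    }
    scen_path = out_dir / "scenario.json"
    scen_path.write_text(json.dumps(summary, indent=2))
    paths["scenario"] = str(scen_path)
    return paths
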