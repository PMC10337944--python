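"""GWAS summary statistics: reading, validation, instrument selection, harmonization.

The in-memory unit is :class:`SummaryRecord`, one variant's association with
one trait.  Instrument selection applies the genome-wide significance
threshold (p < 5e-8) followed by greedy distance clumping (optionally
LD-informed when an r^2 matrix is supplied).  :func:`harmonize_pair` aligns
exposure and outcome records to a shared effect-allele orientation, resolving
allele swaps and strand flips and dropping unresolvable palindromic variants.
"""

from __future__ import annotations

import gzip
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    ConfigError,
    HarmonizationError,
    NoInstrumentsError,
    SumstatsError,
)

log = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
PALINDROMIC_PAIRS = {frozenset(("A", "T")), frozenset(("C", "G"))}

#: standard column names; a column_map may rename any of them
STANDARD_COLUMNS = (
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
)
MANDATORY_COLUMNS = ("variant_id", "effect_allele", "other_allele", "beta", "se", "pval")

#: |log10(p_reported / p_from_z)| above which a consistency warning is raised
PZ_CONSISTENCY_FACTOR = 10.0


@dataclass(frozen=True)
class SummaryRecord:
    """One variant's association with one trait.

    ``beta`` is the per-effect-allele estimate: log odds for binary traits,
    SD units for continuous traits.  ``eaf`` and ``n`` may be None when the
    source file does not carry them.
    """

    variant_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    chrom: str | None = None
    pos: int | None = None
    eaf: float | None = None
    n: int | None = None

    @property
    def is_palindromic(self) -> bool:
        return frozenset((self.effect_allele, self.other_allele)) in PALINDROMIC_PAIRS

    @property
    def z(self) -> float:
        return self.beta / self.se


@dataclass(frozen=True)
class InstrumentCriteria:
    """Instrument-selection thresholds.

    Defaults: genome-wide significance 5e-8, pairwise independence r^2 < 0.001
    within a 10,000 kb clump window, and mean F above 10 flagged otherwise.
    """

    p_threshold: float = 5e-8
    clump_r2: float = 0.001
    clump_window_kb: int = 10_000
    min_f: float = 10.0

    def __post_init__(self) -> None:
        if not 0.0 < self.p_threshold < 1.0:
            raise ConfigError(f"p_threshold must be in (0,1), got {self.p_threshold}")
        if self.clump_window_kb <= 0:
            raise ConfigError(f"clump_window_kb must be > 0, got {self.clump_window_kb}")


@dataclass(frozen=True)
class RowIssue:
    """A per-row problem found while reading or validating a file."""

    line: int  # 1-based line number in the source file (header = line 1)
    variant_id: str
    reason: str
    fatal: bool  # fatal rows are dropped; non-fatal are warnings


@dataclass
class HarmonizedSet:
    """Per-SNP effect/SE pairs for exposure(s) and outcome on one orientation.

    ``beta_exposure``/``se_exposure`` are (J,) arrays for a single exposure or
    (J, K) arrays for K exposures (multivariable use); orientation is to the
    (first) exposure's effect allele.
    """

    snp_ids: list[str]
    beta_exposure: np.ndarray
    se_exposure: np.ndarray
    beta_outcome: np.ndarray
    se_outcome: np.ndarray
    n_exposure: int | None = None
    n_outcome: int | None = None
    dropped: list[tuple[str, str]] = field(default_factory=list)
    exposure_names: list[str] = field(default_factory=lambda: ["exposure"])
    effect_alleles: list[str] = field(default_factory=list)
    other_alleles: list[str] = field(default_factory=list)
    n_exposures_each: list[int] | None = None  # per-exposure sample sizes (MVMR)

    def __post_init__(self) -> None:
        self.beta_exposure = np.asarray(self.beta_exposure, dtype=float)
        self.se_exposure = np.asarray(self.se_exposure, dtype=float)
        self.beta_outcome = np.asarray(self.beta_outcome, dtype=float)
        self.se_outcome = np.asarray(self.se_outcome, dtype=float)
        j = len(self.snp_ids)
        if j < 1:
            raise HarmonizationError("harmonized set must contain at least one variant")
        for arr, name in (
            (self.beta_exposure, "beta_exposure"),
            (self.se_exposure, "se_exposure"),
            (self.beta_outcome, "beta_outcome"),
            (self.se_outcome, "se_outcome"),
        ):
            if arr.shape[0] != j:
                raise HarmonizationError(f"{name} length {arr.shape[0]} != {j} snp_ids")
        kept = set(self.snp_ids)
        for vid, _ in self.dropped:
            if vid in kept:
                raise HarmonizationError(f"variant {vid} appears in both kept and dropped")

    @property
    def n_snp(self) -> int:
        return len(self.snp_ids)

    @property
    def n_exposure_traits(self) -> int:
        return 1 if self.beta_exposure.ndim == 1 else self.beta_exposure.shape[1]

    def __len__(self) -> int:
        return self.n_snp

    def subset(self, keep: Sequence[int] | np.ndarray) -> "HarmonizedSet":
        """Return a new set restricted to the given row indices (kept order)."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return HarmonizedSet(
            snp_ids=[self.snp_ids[i] for i in keep],
            beta_exposure=self.beta_exposure[keep],
            se_exposure=self.se_exposure[keep],
            beta_outcome=self.beta_outcome[keep],
            se_outcome=self.se_outcome[keep],
            n_exposure=self.n_exposure,
            n_outcome=self.n_outcome,
            dropped=list(self.dropped),
            exposure_names=list(self.exposure_names),
            effect_alleles=[self.effect_alleles[i] for i in keep] if self.effect_alleles else [],
            other_alleles=[self.other_alleles[i] for i in keep] if self.other_alleles else [],
            n_exposures_each=self.n_exposures_each,
        )

    def exclude(self, variant_ids: Iterable[str]) -> "HarmonizedSet":
        drop = set(variant_ids)
        keep = [i for i, v in enumerate(self.snp_ids) if v not in drop]
        return self.subset(keep)

    def to_frame(self) -> pd.DataFrame:
        d: dict[str, object] = {"variant_id": self.snp_ids}
        if self.beta_exposure.ndim == 1:
            d["beta_exp"] = self.beta_exposure
            d["se_exp"] = self.se_exposure
        else:
            for k, name in enumerate(self.exposure_names):
                d[f"beta_exp_{name}"] = self.beta_exposure[:, k]
                d[f"se_exp_{name}"] = self.se_exposure[:, k]
        d["beta_out"] = self.beta_outcome
        d["se_out"] = self.se_outcome
        return pd.DataFrame(d)

    def write_tsv(self, path, drops_path=None) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)
        if drops_path is not None:
            pd.DataFrame(self.dropped, columns=["variant_id", "reason"]).to_csv(
                drops_path, sep="\t", index=False
            )


# ---------------------------------------------------------------------------
# reading & validation


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def validate_record(rec: SummaryRecord) -> tuple[str | None, str | None]:
    """Return (fatal_reason, warning) for a record; (None, None) if clean."""
    if rec.effect_allele not in VALID_ALLELES or rec.other_allele not in VALID_ALLELES:
        return f"invalid alleles {rec.effect_allele}/{rec.other_allele}", None
    if rec.effect_allele == rec.other_allele:
        return "effect allele equals other allele", None
    if not math.isfinite(rec.beta):
        return "non-finite beta", None
    if not (math.isfinite(rec.se) and rec.se > 0):
        return "nonpositive SE", None
    if not (0.0 < rec.pval <= 1.0):
        return f"p-value {rec.pval} outside (0,1]", None
    if rec.eaf is not None and not (0.0 < rec.eaf < 1.0):
        return f"EAF {rec.eaf} outside (0,1)", None
    if rec.n is not None and rec.n <= 0:
        return f"nonpositive sample size {rec.n}", None
    # p vs |z| consistency, warning only: published p-values are often truncated
    p_z = 2.0 * stats.norm.sf(abs(rec.beta / rec.se))
    if p_z > 0 and rec.pval > 0:
        ratio = abs(math.log10(rec.pval) - math.log10(p_z))
        if ratio > math.log10(PZ_CONSISTENCY_FACTOR):
            return None, (
                f"p-value {rec.pval:.3g} inconsistent with |z|={abs(rec.beta / rec.se):.2f}"
                f" (implies p~{p_z:.3g})"
            )
    return None, None


def read_sumstats(
    path,
    column_map: Mapping[str, str] | None = None,
    max_bad_fraction: float = 0.10,
    return_issues: bool = False,
):
    """Read a (possibly gzipped) TSV of summary statistics.

    ``column_map`` maps standard names (``beta``, ``se``, ...) to the file's
    column headers.  Rows violating hard invariants are dropped and reported
    with their line numbers; the file is rejected if more than
    ``max_bad_fraction`` of data rows fail.
    """
    column_map = dict(column_map or {})
    unknown = set(column_map) - set(STANDARD_COLUMNS)
    if unknown:
        raise ConfigError(f"column_map has unknown standard names: {sorted(unknown)}")

    with _open_text(path) as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str)
    rename = {v: k for k, v in column_map.items()}
    df = df.rename(columns=rename)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigError(f"{path}: missing mandatory columns {missing}")

    records: list[SummaryRecord] = []
    issues: list[RowIssue] = []
    n_fatal = 0
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        row = row._asdict()
        vid = str(row["variant_id"])
        try:
            rec = SummaryRecord(
                variant_id=vid,
                effect_allele=str(row["effect_allele"]).upper(),
                other_allele=str(row["other_allele"]).upper(),
                beta=float(row["beta"]),
                se=float(row["se"]),
                pval=float(row["pval"]),
                chrom=str(row["chrom"]) if row.get("chrom") not in (None, "", "nan") else None,
                pos=int(float(row["pos"])) if row.get("pos") not in (None, "", "nan") else None,
                eaf=float(row["eaf"]) if row.get("eaf") not in (None, "", "nan", "NA") else None,
                n=int(float(row["n"])) if row.get("n") not in (None, "", "nan", "NA") else None,
            )
        except (TypeError, ValueError) as exc:
            issues.append(RowIssue(line, vid, f"unparseable numeric: {exc}", fatal=True))
            n_fatal += 1
            continue
        fatal, warning = validate_record(rec)
        if fatal:
            issues.append(RowIssue(line, vid, fatal, fatal=True))
            n_fatal += 1
            continue
        if warning:
            issues.append(RowIssue(line, vid, warning, fatal=False))
        records.append(rec)

    for issue in issues:
        level = logging.WARNING if issue.fatal else logging.INFO
        log.log(level, "%s line %d (%s): %s", path, issue.line, issue.variant_id, issue.reason)
    n_rows = len(df)
    if n_rows and n_fatal / n_rows > max_bad_fraction:
        raise SumstatsError(
            f"{path}: {n_fatal}/{n_rows} rows failed validation "
            f"(> {max_bad_fraction:.0%}); first: {issues[0].reason}"
        )
    if return_issues:
        return records, issues
    return records


def write_sumstats(records: Sequence[SummaryRecord], path) -> None:
    """Write records in the standard TSV dialect (inverse of read_sumstats)."""
    df = pd.DataFrame(
        {
            "variant_id": [r.variant_id for r in records],
            "chrom": [r.chrom for r in records],
            "pos": [r.pos for r in records],
            "effect_allele": [r.effect_allele for r in records],
            "other_allele": [r.other_allele for r in records],
            "eaf": [r.eaf for r in records],
            "beta": [r.beta for r in records],
            "se": [r.se for r in records],
            "pval": [r.pval for r in records],
            "n": [r.n for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# instrument selection


def _sort_key(rec: SummaryRecord):
    # chromosome sorted numerically when possible, then position
    chrom = rec.chrom or ""
    try:
        ckey = (0, int(chrom))
    except ValueError:
        ckey = (1, 0)
    return (ckey, chrom, rec.pos if rec.pos is not None else -1)


def clump_by_distance(
    records: Sequence[SummaryRecord],
    window_kb: int = 10_000,
    ld: pd.DataFrame | None = None,
    r2_threshold: float = 0.001,
) -> list[SummaryRecord]:
    """Greedy clumping: keep the lowest-p variant, discard its neighbours.

    A neighbour is any unassigned variant on the same chromosome within
    ``window_kb`` kilobases, or (when an ``ld`` r^2 matrix indexed by
    variant_id is supplied) any variant with r^2 >= ``r2_threshold``.
    Ties on p are broken by (chrom, pos) order.  Output is position-sorted.
    """
    if ld is not None:
        vals = ld.to_numpy()
        if ld.shape[0] != ld.shape[1] or not np.allclose(vals, vals.T):
            raise ConfigError("ld matrix must be square and symmetric")
        if not np.allclose(np.diag(vals), 1.0):
            raise ConfigError("ld matrix must have unit diagonal")
    pending = sorted(records, key=lambda r: (r.pval, _sort_key(r)))
    kept: list[SummaryRecord] = []
    assigned: set[str] = set()
    window_bp = window_kb * 1000
    for rec in pending:
        if rec.variant_id in assigned:
            continue
        kept.append(rec)
        assigned.add(rec.variant_id)
        for other in pending:
            if other.variant_id in assigned:
                continue
            near = (
                rec.chrom is not None
                and other.chrom == rec.chrom
                and rec.pos is not None
                and other.pos is not None
                and abs(other.pos - rec.pos) <= window_bp
            )
            linked = False
            if ld is not None and rec.variant_id in ld.index and other.variant_id in ld.index:
                linked = float(ld.loc[rec.variant_id, other.variant_id]) >= r2_threshold
            if near or linked:
                assigned.add(other.variant_id)
    return sorted(kept, key=_sort_key)


def select_instruments(
    records: Sequence[SummaryRecord],
    criteria: InstrumentCriteria = InstrumentCriteria(),
    ld: pd.DataFrame | None = None,
) -> list[SummaryRecord]:
    """Genome-wide-significant, clumped instruments, ordered by (chrom, pos)."""
    sig = [r for r in records if r.pval < criteria.p_threshold]
    if not sig:
        raise NoInstrumentsError(
            f"no variants reach p < {criteria.p_threshold:g}; cannot build instrument set"
        )
    return clump_by_distance(
        sig, window_kb=criteria.clump_window_kb, ld=ld, r2_threshold=criteria.clump_r2
    )


# ---------------------------------------------------------------------------
# harmonization


def _complemented(rec: SummaryRecord) -> SummaryRecord:
    return replace(
        rec,
        effect_allele=COMPLEMENT[rec.effect_allele],
        other_allele=COMPLEMENT[rec.other_allele],
    )


def _flipped(rec: SummaryRecord) -> SummaryRecord:
    return replace(
        rec,
        effect_allele=rec.other_allele,
        other_allele=rec.effect_allele,
        beta=-rec.beta,
        eaf=None if rec.eaf is None else 1.0 - rec.eaf,
    )


def align_to(reference: SummaryRecord, other: SummaryRecord,
             palindrome_eaf_band: tuple[float, float] = (0.42, 0.58)) -> tuple[SummaryRecord | None, str | None]:
    """Align ``other`` to the effect/other allele orientation of ``reference``.

    Returns (aligned_record, None) on success, (None, reason) when the
    variant must be dropped.  Handles allele swaps, strand flips, and
    palindromic ambiguity via effect-allele frequencies.
    """
    ref_ea, ref_oa = reference.effect_allele, reference.other_allele
    lo, hi = palindrome_eaf_band

    if reference.is_palindromic:
        if frozenset((other.effect_allele, other.other_allele)) != frozenset((ref_ea, ref_oa)):
            return None, "allele-mismatch"
        # strand is unresolvable from alleles; use EAF on both sides
        if reference.eaf is None or other.eaf is None:
            return None, "palindromic-ambiguous"
        if lo <= reference.eaf <= hi or lo <= other.eaf <= hi:
            return None, "palindromic-ambiguous"
        cand = other if other.effect_allele == ref_ea else _flipped(other)
        # minor allele must agree; if frequencies disagree in side, the other
        # strand was reported: negate beta and mirror the EAF
        if (reference.eaf < 0.5) != (cand.eaf < 0.5):
            cand = _flipped(cand)
        # on a palindrome the flipped labels name the same strand pair, so
        # restore the reference orientation
        return replace(cand, effect_allele=ref_ea, other_allele=ref_oa), None

    for candidate in (other, _complemented(other)):
        if candidate.effect_allele == ref_ea and candidate.other_allele == ref_oa:
            return candidate, None
        if candidate.effect_allele == ref_oa and candidate.other_allele == ref_ea:
            return _flipped(candidate), None
    return None, "allele-mismatch"


def harmonize_pair(
    exposure: Sequence[SummaryRecord],
    outcome: Sequence[SummaryRecord],
    palindrome_eaf_band: tuple[float, float] = (0.42, 0.58),
) -> HarmonizedSet:
    """Align outcome records to the exposure's effect-allele orientation.

    Shared variants with swapped alleles get their outcome beta sign flipped
    (and EAF mirrored); strand flips are complemented then aligned;
    palindromic variants are kept only when both EAFs fall outside
    ``palindrome_eaf_band`` and agree on the minor allele.
    """
    out_by_id = {r.variant_id: r for r in outcome}
    shared = [r for r in exposure if r.variant_id in out_by_id]
    if not shared:
        raise HarmonizationError("no overlapping variants between exposure and outcome")

    ids, bx, sx, by, sy, eas, oas = [], [], [], [], [], [], []
    dropped: list[tuple[str, str]] = []
    for exp_rec in shared:
        aligned, reason = align_to(exp_rec, out_by_id[exp_rec.variant_id], palindrome_eaf_band)
        if aligned is None:
            dropped.append((exp_rec.variant_id, reason))
            continue
        ids.append(exp_rec.variant_id)
        bx.append(exp_rec.beta)
        sx.append(exp_rec.se)
        by.append(aligned.beta)
        sy.append(aligned.se)
        eas.append(exp_rec.effect_allele)
        oas.append(exp_rec.other_allele)
    if not ids:
        raise HarmonizationError(
            f"all {len(shared)} shared variants dropped during harmonization"
        )
    n_exp = next((r.n for r in shared if r.n is not None), None)
    n_out = next((out_by_id[v].n for v in ids if out_by_id[v].n is not None), None)
    return HarmonizedSet(
        snp_ids=ids,
        beta_exposure=np.array(bx),
        se_exposure=np.array(sx),
        beta_outcome=np.array(by),
        se_outcome=np.array(sy),
        n_exposure=n_exp,
        n_outcome=n_out,
        dropped=dropped,
        effect_alleles=eas,
        other_alleles=oas,
    )


def f_statistic(hset: HarmonizedSet) -> tuple[np.ndarray, float]:
    """Per-SNP instrument-strength F = (beta/se)^2 and its arithmetic mean."""
    if hset.beta_exposure.ndim != 1:
        raise ConfigError("f_statistic expects a single-exposure harmonized set")
    per_snp = (hset.beta_exposure / hset.se_exposure) ** 2
    return per_snp, float(per_snp.mean())
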