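"""Shared fixtures: small harmonized sets and the default simulated network."""

from __future__ import annotations

import numpy as np
import pytest

from netmr import (
    HarmonizedSet,
    NetworkScenario,
    SummaryRecord,
    simulate_network_sumstats,
)
from netmr.sumstats import harmonize_pair, select_instruments
from netmr.simgwas import null_edge_scenario


def make_hset(bx, by, sy, sx=None, ids=None) -> HarmonizedSet:
    """Build a single-exposure harmonized set from plain effect arrays."""
    bx = np.asarray(bx, dtype=float)
    if sx is None:
        sx = np.full_like(bx, 1e-12)  # effectively error-free exposure betas
    return HarmonizedSet(
        snp_ids=list(ids) if ids is not None else [f"rs{i+1}" for i in range(len(bx))],
        beta_exposure=bx,
        se_exposure=np.asarray(sx, dtype=float),
        beta_outcome=np.asarray(by, dtype=float),
        se_outcome=np.asarray(sy, dtype=float),
        n_exposure=100_000,
        n_outcome=100_000,
    )


def rec(
    vid="rs1",
    ea="A",
    oa="G",
    beta=0.1,
    se=0.01,
    pval=1e-12,
    eaf=None,
    chrom="1",
    pos=1_000_000,
    n=100_000,
) -> SummaryRecord:
    return SummaryRecord(
        variant_id=vid, effect_allele=ea, other_allele=oa, beta=beta, se=se,
        pval=pval, eaf=eaf, chrom=chrom, pos=pos, n=n,
    )


def simulated_edge(seed=0, theta=0.1, m_snps=20, **kw):
    """Harmonized instrument set from a mediator-free simulated scenario."""
    sc = null_edge_scenario(theta=theta, m_snps=m_snps, seed=seed, **kw)
    tables, truth = simulate_network_sumstats(sc)
    instruments = select_instruments(tables[sc.exposure_name])
    return harmonize_pair(instruments, tables[sc.outcome_name]), truth


@pytest.fixture(scope="session")
def paper_scenario() -> NetworkScenario:
    return NetworkScenario(seed=1)


@pytest.fixture(scope="session")
def paper_tables(paper_scenario):
    return simulate_network_sumstats(paper_scenario)


@pytest.fixture(scope="session")
def clean_edge():
    """A homogeneous no-pleiotropy edge with a nonzero causal effect."""
    return simulated_edge(seed=7, theta=-0.37, m_snps=200, n_exposure=500_000,
                          n_outcome=300_000)
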