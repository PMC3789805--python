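"""Shared fixtures: one mid-sized synthetic cohort, processed once.

The cohort is 200 kbp over two chromosomes with two accessions per diploid
group at 40x — large enough for every caller to see hundreds to thousands
of events, small enough to keep the whole suite fast.  Session scope keeps
the expensive pileup/genotype steps to a single run.
"""
from __future__ import annotations

import numpy as np
import pytest

from homeoscan import categorize as cat
from homeoscan import homoeosnp as hs
from homeoscan import pileup as pu
from homeoscan.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def sim_cfg() -> SimConfig:
    return SimConfig(genome_length=200_000, n_chromosomes=2, n_genes=40,
                     seed=7)


@pytest.fixture(scope="session")
def cohort(sim_cfg):
    return simulate_cohort(sim_cfg)


@pytest.fixture(scope="session")
def ref_lengths(cohort):
    return cohort.reference.lengths


@pytest.fixture(scope="session")
def diploid_pileups(cohort, ref_lengths):
    return {name: pu.pileup_readset(rs, ref_lengths)
            for name, rs in cohort.readsets.items() if name != "Tetra"}


@pytest.fixture(scope="session")
def diploid_coverage(cohort, ref_lengths):
    return {name: pu.coverage_readset(rs, ref_lengths)
            for name, rs in cohort.readsets.items() if name != "Tetra"}


@pytest.fixture(scope="session")
def diploid_genotypes(diploid_pileups):
    return {name: {c: hs.call_genotypes(pt) for c, pt in tables.items()}
            for name, tables in diploid_pileups.items()}


@pytest.fixture(scope="session")
def snp_index(diploid_genotypes, cohort):
    return hs.call_homoeo_snps(diploid_genotypes, cohort.groups)


@pytest.fixture(scope="session")
def tetra_split(cohort, snp_index, ref_lengths):
    """Categorized tetraploid subgenomes: readsets, genotypes, coverage."""
    mx = cohort.readsets["Tetra"]
    codes, stats = cat.categorize_readset(mx, snp_index)
    out = {"codes": codes, "stats": stats}
    for label, code in (("AT", 0), ("DT", 1)):
        rs = mx.subset(codes == code, accession=f"Tetra.{label}")
        tables = pu.pileup_readset(rs, ref_lengths)
        out[label] = {
            "readset": rs,
            "genotypes": {c: hs.call_genotypes(t) for c, t in tables.items()},
            "coverage": pu.coverage_readset(rs, ref_lengths),
        }
    return out
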