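"""Shared fixtures: small simulated cohorts and hand-built site tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from wpoly.io import ABSENT, MISSING, SiteTable
from wpoly.simulate import SimulationConfig, simulate_cohort


def table_from_haplotypes(mat, chrom="chr1", start_pos=1, chrom_class="autosome",
                          positions=None, prefix="s"):
    """SiteTable of haploid samples from a (n_sites, n_seq) 0/1 matrix."""
    mat = np.asarray(mat, dtype=np.int8)
    n_sites, n_seq = mat.shape
    alleles = np.full((n_sites, n_seq, 2), ABSENT, dtype=np.int8)
    alleles[:, :, 0] = mat
    pos = (np.asarray(positions, dtype=np.int64) if positions is not None
           else np.arange(start_pos, start_pos + n_sites))
    return SiteTable(
        chrom=np.full(n_sites, chrom, dtype=object),
        pos=pos,
        ref=np.full(n_sites, "A", dtype=object),
        alt=np.full(n_sites, "T", dtype=object),
        alleles=alleles,
        samples=[f"{prefix}{i}" for i in range(n_seq)],
        chrom_class=chrom_class,
    )


def table_from_diploids(mat0, mat1, chrom="chr1", prefix="s"):
    """SiteTable of diploid samples from two (n_sites, n_ind) allele matrices."""
    mat0 = np.asarray(mat0, dtype=np.int8)
    mat1 = np.asarray(mat1, dtype=np.int8)
    n_sites, n_ind = mat0.shape
    alleles = np.stack([mat0, mat1], axis=2)
    return SiteTable(
        chrom=np.full(n_sites, chrom, dtype=object),
        pos=np.arange(1, n_sites + 1),
        ref=np.full(n_sites, "A", dtype=object),
        alt=np.full(n_sites, "T", dtype=object),
        alleles=alleles,
        samples=[f"{prefix}{i}" for i in range(n_ind)],
        chrom_class="autosome",
    )


@pytest.fixture(scope="session")
def base_cohort():
    """Structured two-species cohort with a deep W haplogroup split."""
    cfg = SimulationConfig(
        n_per_group=5, n_males_per_species=2,
        ne_auto=2.0e4, ne_w=1.0e4,
        t_species=2.0e4, t_plumage=2.0e5,
        n_windows=40, window_len_bp=20_000, seed=11,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    """Panmictic cohort: species and morph labels carry no signal."""
    cfg = SimulationConfig(
        n_per_group=10, n_males_per_species=2,
        ne_auto=2.0e4, ne_w=1.0e4,
        t_species=0.0, t_plumage=0.0,
        n_windows=100, window_len_bp=20_000, seed=23,
        chromosomes=("autosome",),
    )
    return simulate_cohort(cfg)


@pytest.fixture()
def female_groups(base_cohort):
    meta = base_cohort.metadata
    f = meta[meta["sex"] == "F"]
    return {
        f"{sp[:3]}_{morph}": list(sub["sample"])
        for (sp, morph), sub in f.groupby(["species", "morph"])
    }
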