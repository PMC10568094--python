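"""Shared fixtures: generated cohorts at several scales.

Everything is generated at test time from seeds; nothing is read from
disk.  The mid-size "study" (train + test cohorts of one synthetic
population) is session-scoped because several experiment tests reuse it.
"""

from __future__ import annotations

import numpy as np
import pytest

from ibdprofiler.cohort_io import GenotypeMatrix, PhenotypeTable, VariantRecord
from ibdprofiler.structure_qc import attach_pcs
from ibdprofiler.synthetic_cohort import (
    default_config,
    make_fixture,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def tiny_cohort():
    """50 samples x 100 variants with 10 PCs attached."""
    return make_fixture("tiny", seed=0)


def build_study(n_train=2500, n_test=2000, n_variants=1200, seed=0, **overrides):
    """Train/test cohorts drawn from one synthetic population."""
    out = []
    for i, n in enumerate((n_train, n_test)):
        cfg = default_config(n, n_variants, seed=seed * 7919 + i, **overrides)
        geno, pheno = simulate_cohort(cfg)
        pheno = attach_pcs(geno, pheno, k=10)
        out.append((geno, pheno, cfg))
    return tuple(out)


@pytest.fixture(scope="session")
def midsize_study():
    """2,500-sample train + 2,000-sample test, 1,200 variants."""
    return build_study(seed=17)


def toy_genotypes(n_samples=40, n_variants=12, seed=0, chromosome="1", spacing=10_000):
    """Small unstructured genotype matrix with A/G variants."""
    rng = np.random.default_rng(seed)
    maf = rng.uniform(0.1, 0.5, size=n_variants)
    dosages = rng.binomial(2, maf, size=(n_samples, n_variants)).astype(float)
    variants = [
        VariantRecord(f"rs{j}", chromosome, 1 + j * spacing, "A", "G")
        for j in range(n_variants)
    ]
    return GenotypeMatrix(dosages, [f"S{i}" for i in range(n_samples)], variants)
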