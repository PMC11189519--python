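"""Shared fixtures and cohort builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from relictpop.variant_store import CohortMatrix, GroupAssignment, SiteRecord

BASES = "ACGT"


def make_cohort(
    dosages,
    *,
    chrom: str = "A01",
    positions=None,
    groups: dict[str, str] | None = None,
    sample_names=None,
    mean_depth: float = 30.0,
    site_ids: bool = True,
) -> CohortMatrix:
    """Build a cohort matrix from a dosage array (samples x sites)."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n, L = dosages.shape
    if positions is None:
        positions = np.arange(1, L + 1) * 10
    if sample_names is None:
        sample_names = [f"s{i}" for i in range(n)]
    sites = []
    for j in range(L):
        alt_seen = bool((dosages[:, j] > 0).any())
        sites.append(
            SiteRecord(
                chrom=chrom if isinstance(chrom, str) else chrom[j],
                pos=int(positions[j]),
                ref_allele="A",
                alt_alleles=("T",),
                site_id=f"site{j}" if site_ids else None,
                mean_depth=mean_depth,
                site_class="snp" if alt_seen else "invariant",
            )
        )
    ga = GroupAssignment(groups) if groups else None
    return CohortMatrix(list(sample_names), sites, dosages, ga)


def random_cohort(
    rng: np.random.Generator,
    n_samples: int,
    n_sites: int,
    *,
    missing_rate: float = 0.0,
    groups: dict[str, str] | None = None,
    chrom: str = "A01",
) -> CohortMatrix:
    """Random dosage matrix with allele frequencies spread over (0, 1)."""
    p = rng.uniform(0.05, 0.95, n_sites)
    dosages = (rng.random((n_samples, n_sites)) < p).astype(np.int8) + (
        rng.random((n_samples, n_sites)) < p
    ).astype(np.int8)
    if missing_rate > 0:
        dosages[rng.random((n_samples, n_sites)) < missing_rate] = -1
    positions = np.sort(rng.choice(np.arange(1, n_sites * 50), n_sites, replace=False))
    return make_cohort(dosages, chrom=chrom, positions=positions, groups=groups)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260905)


@pytest.fixture(scope="session")
def neutral_sim_cohort():
    """A mid-size single-population equilibrium cohort reused by several
    statistical tests (session-scoped: one simulation for the whole run)."""
    from relictpop.simpop import (
        DemographyModel,
        PopulationSpec,
        draw_diploids,
        simulate_wf,
        single_chrom_layout,
    )

    model = DemographyModel(
        populations=[PopulationSpec("wild", [(None, 100)])],
        mu=5e-5,
        recomb_rate=5e-5,
        layout=single_chrom_layout(),
    )
    res = simulate_wf(model, 20_000, {"wild": 10}, seed=1234)
    m = draw_diploids(res, pairing_seed=5, depth_mean=30.0, fill_invariant=True)
    return res, m
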