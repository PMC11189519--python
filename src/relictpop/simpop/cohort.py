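"""Turn simulation output into an analysis-ready diploid cohort: pair
haplotypes, discretize positions onto the chromosome layout, materialize
invariant sites, and optionally inject missingness and per-site depth.
"""

from __future__ import annotations

import os
from typing import Mapping

import numpy as np

from relictpop.simpop.engine import SimResult
from relictpop.variant_store.model import (
    MISSING,
    CohortMatrix,
    GroupAssignment,
    SiteRecord,
)
from relictpop.variant_store.vcfio import write_groups, write_vcf

__all__ = ["draw_diploids", "emit_cohort_vcf", "contig_lengths"]

_BASES = np.array(list("ACGT"))


def contig_lengths(s: SimResult) -> dict[str, int]:
    return s.layout.chrom_lengths_bp(s.total_bp)


def _discretize(s: SimResult) -> tuple[list[str], np.ndarray]:
    """Map continuous site positions to unique integer positions per
    chromosome (1-based). Collisions take the next free integer."""
    bounds = s.layout.boundaries
    lengths = contig_lengths(s)
    names = s.layout.chrom_names
    lefts = np.concatenate([[0.0], bounds[:-1]])
    chrom_idx = s.layout.chrom_of(s.site_u)
    chroms: list[str] = []
    pos = np.empty(s.n_sites, dtype=np.int64)
    used: dict[int, set[int]] = {i: set() for i in range(len(names))}
    for j in range(s.n_sites):
        ci = int(chrom_idx[j])
        frac = s.layout.fractions[ci]
        length = lengths[names[ci]]
        rel = (s.site_u[j] - lefts[ci]) / frac
        p = min(int(rel * length) + 1, length)
        while p in used[ci]:
            p += 1
            if p > length:
                p = 1
        if len(used[ci]) >= length:
            raise ValueError(f"more sites than integer positions on {names[ci]}")
        used[ci].add(p)
        chroms.append(names[ci])
        pos[j] = p
    return chroms, pos


def draw_diploids(
    s: SimResult,
    pairing_seed: int,
    group_map: Mapping[str, str] | None = None,
    missing_rate: float = 0.0,
    depth_mean: float | None = 30.0,
    fill_invariant: bool = True,
) -> CohortMatrix:
    """Pair sampled haplotypes into diploids and build a cohort matrix.

    Haplotypes were sampled per individual, so consecutive pairs belong to
    the same simulated diploid and selfing-induced F_IS structure survives.
    ``group_map`` renames populations to group labels; invariant sites are
    materialized at every unoccupied integer position when
    ``fill_invariant`` is set.
    """
    rng = np.random.default_rng(pairing_seed)
    samples: list[str] = []
    assignment: dict[str, str] = {}
    dosage_rows: list[np.ndarray] = []
    for pop, haps in s.haplotypes.items():
        if haps.shape[0] % 2:
            raise ValueError(f"odd haplotype count for {pop}")
        n = haps.shape[0] // 2
        dosage = haps[0::2].astype(np.int8) + haps[1::2].astype(np.int8)
        label = group_map.get(pop, pop) if group_map else pop
        for i in range(n):
            name = f"{pop}_{i + 1:02d}"
            samples.append(name)
            assignment[name] = label
        dosage_rows.append(dosage)
    snp_dosages = (
        np.concatenate(dosage_rows, axis=0)
        if dosage_rows
        else np.zeros((0, s.n_sites), dtype=np.int8)
    )
    n_samples = len(samples)
    chroms, pos = _discretize(s)

    ref_idx = rng.integers(0, 4, s.n_sites)
    alt_idx = (ref_idx + rng.integers(1, 4, s.n_sites)) % 4
    sites: list[SiteRecord] = []
    for j in range(s.n_sites):
        alt_seen = bool((snp_dosages[:, j] > 0).any())
        sites.append(
            SiteRecord(
                chrom=chroms[j],
                pos=int(pos[j]),
                ref_allele=str(_BASES[ref_idx[j]]),
                alt_alleles=(str(_BASES[alt_idx[j]]),),
                site_id=f"{chroms[j]}_{pos[j]}",
                site_class="snp" if alt_seen else "invariant",
            )
        )
    dosages = snp_dosages
    if fill_invariant:
        lengths = contig_lengths(s)
        occupied: dict[str, set[int]] = {c: set() for c in s.layout.chrom_names}
        for rec in sites:
            occupied[rec.chrom].add(rec.pos)
        inv_sites: list[SiteRecord] = []
        for chrom in s.layout.chrom_names:
            free = sorted(set(range(1, lengths[chrom] + 1)) - occupied[chrom])
            inv_ref = rng.integers(0, 4, len(free))
            for p, ri in zip(free, inv_ref):
                inv_sites.append(
                    SiteRecord(
                        chrom=chrom,
                        pos=int(p),
                        ref_allele=str(_BASES[ri]),
                        alt_alleles=(),
                        site_id=f"{chrom}_{p}",
                        site_class="invariant",
                    )
                )
        sites = sites + inv_sites
        dosages = np.concatenate(
            [dosages, np.zeros((n_samples, len(inv_sites)), dtype=np.int8)], axis=1
        )
    if depth_mean is not None and sites:
        # Poisson total around the target so the depth filter has teeth
        depths = rng.poisson(depth_mean * max(n_samples, 1), len(sites)) / max(n_samples, 1)
        for rec, dp in zip(sites, depths):
            rec.mean_depth = float(dp)
    if missing_rate > 0:
        drop = rng.random(dosages.shape) < missing_rate
        dosages = np.where(drop, np.int8(MISSING), dosages)
    m = CohortMatrix(
        samples=samples,
        sites=sites,
        dosages=dosages,
        groups=GroupAssignment(assignment),
    )
    return m.sorted_by_position().reclassified()


def emit_cohort_vcf(
    m: CohortMatrix,
    path: str | os.PathLike,
    contigs: dict[str, int] | None = None,
    groups_path: str | os.PathLike | None = None,
) -> None:
    """Write the all-sites VCF (plus the sample->group table when asked)."""
    write_vcf(m, path, contig_lengths=contigs)
    if groups_path is not None:
        if m.groups is None:
            raise ValueError("cohort has no group assignment to write")
        write_groups(m.groups, groups_path)
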