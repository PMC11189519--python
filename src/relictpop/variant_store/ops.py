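"""Site-level set operations: splitting, filtering, concatenation, cohort
merging, and genic-interval intersection.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np

from relictpop.variant_store.model import (
    MISSING,
    CohortMatrix,
    FilterParams,
    GenomicIntervals,
    GroupAssignment,
    SiteRecord,
)

logger = logging.getLogger(__name__)


def split_sites(m: CohortMatrix) -> tuple[CohortMatrix, CohortMatrix]:
    """Partition into (invariant, variable) by observed alternate-allele
    frequency among called genotypes (``--max-maf 0`` semantics).

    Sites with no called genotype at all land on the invariant side.
    """
    alt, _ = m.alt_counts()
    invariant = alt == 0
    return m.take_sites(invariant), m.take_sites(~invariant)


def _observed_allele_count(m: CohortMatrix) -> np.ndarray:
    """Number of distinct observed alleles per site.

    The dosage model collapses alternate alleles, so sites flagged
    ``multiallelic`` at read time are treated as having 3 observed alleles;
    for all others the count is (ref observed) + (alt observed).
    """
    d = m.dosages
    called = d >= 0
    ref_seen = (called & (d < 2)).any(axis=0)
    alt_seen = (called & (d > 0)).any(axis=0)
    count = ref_seen.astype(np.int64) + alt_seen.astype(np.int64)
    multi = np.asarray([s.site_class == "multiallelic" for s in m.sites])
    count[multi] = np.maximum(count[multi], 3)
    return count


def filter_sites(m: CohortMatrix, p: FilterParams) -> CohortMatrix:
    """Apply every filter clause; a site survives only if all clauses pass.

    Minor-allele count/frequency use called genotypes only. Sites without a
    known mean depth pass the depth clauses (logged).
    """
    d = m.dosages
    missing_count = (d == MISSING).sum(axis=0)
    alt, n_alleles = m.alt_counts()
    mac = np.minimum(alt, n_alleles - alt)
    with np.errstate(divide="ignore", invalid="ignore"):
        maf = np.where(n_alleles > 0, mac / np.maximum(n_alleles, 1), 0.0)
    depth = m.mean_depths()
    depth_known = np.isfinite(depth)
    n_unknown = int((~depth_known).sum())
    if n_unknown and (p.min_mean_depth > 0 or np.isfinite(p.max_mean_depth)):
        logger.info("depth unknown for %d sites; treated as passing the depth filter", n_unknown)
    keep = missing_count <= p.max_missing_count
    keep &= _observed_allele_count(m) <= p.max_alleles
    keep &= mac >= p.min_mac
    keep &= maf >= p.min_maf
    keep &= ~depth_known | ((depth >= p.min_mean_depth) & (depth <= p.max_mean_depth))
    if p.drop_indels:
        keep &= np.asarray([s.site_class != "indel" for s in m.sites])
    return m.take_sites(keep)


def concat_sites(a: CohortMatrix, b: CohortMatrix) -> CohortMatrix:
    """Union of two site sets over identical sample lists (bcftools concat)."""
    if a.samples != b.samples:
        raise ValueError("concat_sites requires identical sample lists")
    keys_a = set(a.site_keys())
    dup = keys_a.intersection(b.site_keys())
    if dup:
        raise ValueError(f"duplicate (chrom, pos) in concat: {sorted(dup)[:5]}")
    merged = CohortMatrix(
        samples=a.samples,
        sites=list(a.sites) + list(b.sites),
        dosages=np.concatenate([a.dosages, b.dosages], axis=1),
        groups=a.groups or b.groups,
    )
    return merged.sorted_by_position()


def merge_cohorts(a: CohortMatrix, b: CohortMatrix) -> CohortMatrix:
    """Merge disjoint sample sets (bcftools merge).

    The site set is the union of positions; a sample's dosage at a position
    absent from its source cohort is missing. Where both cohorts define a
    site, REF (and ALT, when both sides carry one) must agree.
    """
    overlap = set(a.samples) & set(b.samples)
    if overlap:
        raise ValueError(f"sample sets not disjoint: {sorted(overlap)[:5]}")
    keys_a = {k: j for j, k in enumerate(a.site_keys())}
    keys_b = {k: j for j, k in enumerate(b.site_keys())}
    all_keys = sorted(set(keys_a) | set(keys_b))
    n_a, n_b = a.n_samples, b.n_samples
    samples = a.samples + b.samples
    dosages = np.full((n_a + n_b, len(all_keys)), MISSING, dtype=np.int8)
    sites: list[SiteRecord] = []
    for col, key in enumerate(all_keys):
        ja = keys_a.get(key)
        jb = keys_b.get(key)
        if ja is not None:
            dosages[:n_a, col] = a.dosages[:, ja]
        if jb is not None:
            dosages[n_a:, col] = b.dosages[:, jb]
        if ja is not None and jb is not None:
            ra, rb = a.sites[ja], b.sites[jb]
            if ra.ref_allele != rb.ref_allele:
                raise ValueError(f"conflicting REF at {key}: {ra.ref_allele} vs {rb.ref_allele}")
            if ra.alt_alleles and rb.alt_alleles and ra.alt_alleles != rb.alt_alleles:
                raise ValueError(
                    f"conflicting ALT at {key}: {ra.alt_alleles} vs {rb.alt_alleles}"
                )
            alts = ra.alt_alleles or rb.alt_alleles
            depth = _combine_depth(ra.mean_depth, n_a, rb.mean_depth, n_b)
            cls = "indel" if "indel" in (ra.site_class, rb.site_class) else (
                "multiallelic"
                if "multiallelic" in (ra.site_class, rb.site_class)
                else "snp"
            )
            sites.append(
                replace(ra, alt_alleles=alts, mean_depth=depth, site_class=cls,
                        site_id=ra.site_id or rb.site_id)
            )
        else:
            sites.append(a.sites[ja] if ja is not None else b.sites[jb])
    groups = None
    if a.groups is not None or b.groups is not None:
        assignment = {}
        if a.groups is not None:
            assignment.update(a.groups.assignment)
        if b.groups is not None:
            assignment.update(b.groups.assignment)
        groups = GroupAssignment(assignment)
    return CohortMatrix(samples, sites, dosages, groups).reclassified()


def _combine_depth(da: float, na: int, db: float, nb: int) -> float:
    known_a, known_b = np.isfinite(da), np.isfinite(db)
    if known_a and known_b:
        return (da * na + db * nb) / (na + nb)
    if known_a:
        return da
    if known_b:
        return db
    return float("nan")


def intersect_genic(m: CohortMatrix, g: GenomicIntervals) -> CohortMatrix:
    """Keep sites whose 0-based position falls inside an interval of the
    same chromosome (half-open convention)."""
    keep = np.zeros(m.n_sites, dtype=bool)
    chroms = m.chroms()
    pos0 = m.positions() - 1
    for chrom in np.unique(chroms.astype(str)):
        mask = chroms == chrom
        keep[mask] = g.contains(chrom, pos0[mask])
    return m.take_sites(keep)
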