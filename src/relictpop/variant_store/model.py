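"""Core data model: site records, the cohort dosage matrix, group labels,
genomic intervals, and filter parameters.

Coordinate conventions (used everywhere downstream):

* VCF/site positions are 1-based.
* Genomic intervals are 0-based half-open (BED convention); a site at
  position ``pos`` lies in interval ``(start, end)`` iff ``start <= pos-1 < end``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

#: dosage value for a missing (uncalled or half-called) genotype
MISSING: int = -1

#: recognised site classes
SITE_CLASSES = ("invariant", "snp", "indel", "multiallelic")

GROUP_LABELS = ("MK", "wild", "LR1", "LR2", "cultivar", "outgroup")


class VcfParseError(ValueError):
    """Raised when a VCF data line cannot be parsed; carries the line number."""


class UnsupportedPloidyError(ValueError):
    """Raised when a genotype is not diploid."""


@dataclass
class SiteRecord:
    """One VCF data line: a variant or invariant site.

    ``site_class`` follows the observed genotypes: ``invariant`` means no
    alternate allele was seen in any called genotype, ``indel`` means some
    allele has length != 1 (or is symbolic), ``multiallelic`` means more
    than two distinct alleles were observed.
    """

    chrom: str
    pos: int
    ref_allele: str = "A"
    alt_alleles: tuple[str, ...] = ()
    site_id: str | None = None
    mean_depth: float = float("nan")
    site_class: str = "snp"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.site_class not in SITE_CLASSES:
            raise ValueError(f"unknown site_class {self.site_class!r}")
        self.alt_alleles = tuple(self.alt_alleles)

    @property
    def is_indel(self) -> bool:
        return self.site_class == "indel"

    def key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)


def classify_alleles(ref: str, alts: Sequence[str]) -> str | None:
    """Return ``"indel"`` if any allele is non-SNP-like, else ``None``."""
    for allele in (ref, *alts):
        if len(allele) != 1 or allele.upper() not in "ACGTN":
            return "indel"
    return None


@dataclass
class GroupAssignment:
    """Mapping of each sample to exactly one group label."""

    assignment: dict[str, str]

    def __post_init__(self) -> None:
        self.assignment = dict(self.assignment)

    def label_of(self, sample: str) -> str:
        return self.assignment[sample]

    def members(self, label: str) -> list[str]:
        return [s for s, g in self.assignment.items() if g == label]

    def labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.assignment.values():
            seen.setdefault(g)
        return list(seen)

    def __contains__(self, sample: str) -> bool:
        return sample in self.assignment

    def __len__(self) -> int:
        return len(self.assignment)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "GroupAssignment":
        return cls(dict(pairs))


@dataclass
class FilterParams:
    """Site-filter thresholds (vcftools dialect).

    Defaults reproduce the standard SNP preset:
    ``--max-missing-count 0 --max-alleles 2 --mac 1 --maf 0.05
    --min-meanDP 10 --max-meanDP 100 --remove-indels``.
    """

    max_missing_count: int = 0
    max_alleles: int = 2
    min_mac: int = 1
    min_maf: float = 0.05
    min_mean_depth: float = 10.0
    max_mean_depth: float = 100.0
    drop_indels: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_maf <= 0.5):
            raise ValueError("min_maf must be in [0, 0.5]")
        if self.min_mean_depth > self.max_mean_depth:
            raise ValueError("min_mean_depth must be <= max_mean_depth")

    @classmethod
    def snp_preset(cls) -> "FilterParams":
        """The SNP-VCF preset (MAF 0.05, biallelic, no missing, depth 10-100)."""
        return cls()

    @classmethod
    def novel_preset(cls) -> "FilterParams":
        """Biallelic full-call preset used for the 67-sample novel-allele set
        (``--max-missing-count 0 --mac 1 --max-alleles 2``; no MAF or depth
        clause)."""
        return cls(
            max_missing_count=0,
            max_alleles=2,
            min_mac=1,
            min_maf=0.0,
            min_mean_depth=0.0,
            max_mean_depth=float("inf"),
            drop_indels=True,
        )

    @classmethod
    def disabled(cls, n_samples: int) -> "FilterParams":
        """A pass-everything parameter set (identity filter)."""
        return cls(
            max_missing_count=n_samples,
            max_alleles=2**31,
            min_mac=0,
            min_maf=0.0,
            min_mean_depth=0.0,
            max_mean_depth=float("inf"),
            drop_indels=False,
        )


@dataclass
class GenomicIntervals:
    """Normalized 0-based half-open intervals keyed by chromosome.

    Intervals are sorted and overlap-merged on construction.
    """

    by_chrom: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        norm: dict[str, np.ndarray] = {}
        for chrom, arr in self.by_chrom.items():
            a = np.asarray(arr, dtype=np.int64).reshape(-1, 2)
            if a.size == 0:
                continue
            if np.any(a[:, 0] >= a[:, 1]):
                bad = a[a[:, 0] >= a[:, 1]][0]
                raise ValueError(f"interval start >= end on {chrom}: {tuple(bad)}")
            a = a[np.argsort(a[:, 0], kind="stable")]
            merged = [a[0].tolist()]
            for s, e in a[1:]:
                if s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], int(e))
                else:
                    merged.append([int(s), int(e)])
            norm[chrom] = np.asarray(merged, dtype=np.int64)
        self.by_chrom = norm

    @classmethod
    def from_tuples(cls, tuples: Iterable[tuple[str, int, int]]) -> "GenomicIntervals":
        by: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in tuples:
            by.setdefault(chrom, []).append((start, end))
        return cls({c: np.asarray(v, dtype=np.int64) for c, v in by.items()})

    def contains(self, chrom: str, pos0: np.ndarray) -> np.ndarray:
        """Vectorized membership test for 0-based positions on one chromosome."""
        pos0 = np.asarray(pos0, dtype=np.int64)
        arr = self.by_chrom.get(chrom)
        if arr is None or arr.size == 0:
            return np.zeros(pos0.shape, dtype=bool)
        # which interval could contain each position: the last with start <= pos
        idx = np.searchsorted(arr[:, 0], pos0, side="right") - 1
        ok = idx >= 0
        hit = np.zeros(pos0.shape, dtype=bool)
        hit[ok] = pos0[ok] < arr[idx[ok], 1]
        return hit

    @property
    def n_intervals(self) -> int:
        return sum(len(a) for a in self.by_chrom.values())


@dataclass
class CohortMatrix:
    """Samples x sites dosage matrix plus site metadata.

    ``dosages`` is an int8 array of shape (n_samples, n_sites) holding the
    alternate-allele count per genotype (0/1/2) or :data:`MISSING` (-1).
    Sites are kept sorted by (chrom, pos) with no duplicate key.
    """

    samples: list[str]
    sites: list[SiteRecord]
    dosages: np.ndarray
    groups: GroupAssignment | None = None

    def __post_init__(self) -> None:
        self.samples = list(self.samples)
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.shape != (len(self.samples), len(self.sites)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.sites)} sites"
            )

    # ---- basic accessors -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def positions(self) -> np.ndarray:
        return np.asarray([s.pos for s in self.sites], dtype=np.int64)

    def chroms(self) -> np.ndarray:
        return np.asarray([s.chrom for s in self.sites], dtype=object)

    def mean_depths(self) -> np.ndarray:
        return np.asarray([s.mean_depth for s in self.sites], dtype=np.float64)

    def site_keys(self) -> list[tuple[str, int]]:
        return [s.key() for s in self.sites]

    def sample_indices(self, names: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.asarray([lookup[n] for n in names], dtype=np.intp)
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"sample {exc.args[0]!r} not in cohort") from None

    def group_rows(self, label: str) -> np.ndarray:
        """Row indices of the samples assigned to ``label``."""
        if self.groups is None:
            raise ValueError("cohort has no group assignment")
        members = [s for s in self.samples if s in self.groups and self.groups.label_of(s) == label]
        if not members:
            raise ValueError(f"group {label!r} has no samples in this cohort")
        return self.sample_indices(members)

    # ---- dosage summaries ------------------------------------------------
    def called_mask(self) -> np.ndarray:
        return self.dosages >= 0

    def alt_counts(self, rows: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Per-site (alt allele count, called allele count) over ``rows``."""
        d = self.dosages if rows is None else self.dosages[rows]
        called = d >= 0
        n_alleles = 2 * called.sum(axis=0, dtype=np.int64)
        alt = np.where(called, d, 0).sum(axis=0, dtype=np.int64)
        return alt, n_alleles

    # ---- structural edits ------------------------------------------------
    def take_sites(self, indices: np.ndarray) -> "CohortMatrix":
        indices = np.asarray(indices)
        if indices.dtype == bool:
            indices = np.flatnonzero(indices)
        return CohortMatrix(
            samples=self.samples,
            sites=[self.sites[i] for i in indices],
            dosages=self.dosages[:, indices],
            groups=self.groups,
        )

    def take_samples(self, names: Sequence[str]) -> "CohortMatrix":
        rows = self.sample_indices(names)
        groups = self.groups
        if groups is not None:
            groups = GroupAssignment({n: groups.assignment[n] for n in names if n in groups})
        return CohortMatrix(
            samples=list(names),
            sites=list(self.sites),
            dosages=self.dosages[rows],
            groups=groups,
        )

    def sorted_by_position(self) -> "CohortMatrix":
        order = sorted(range(self.n_sites), key=lambda i: self.sites[i].key())
        if order == list(range(self.n_sites)):
            return self
        return self.take_sites(np.asarray(order, dtype=np.intp))

    def validate(self) -> None:
        """Check the structural invariants; raise ValueError on violation."""
        keys = self.site_keys()
        if any(b <= a for a, b in zip(keys, keys[1:])):
            raise ValueError("sites not strictly sorted by (chrom, pos)")
        if np.any(self.dosages > 2) or np.any(self.dosages < MISSING):
            raise ValueError("dosages outside {-1, 0, 1, 2}")
        alt_present = np.asarray([len(s.alt_alleles) > 0 for s in self.sites])
        has_alt_dosage = (self.dosages > 0).any(axis=0)
        if np.any(has_alt_dosage & ~alt_present):
            raise ValueError("nonzero dosage at a site without an alternate allele")

    def reclassified(self) -> "CohortMatrix":
        """Recompute invariant/snp classes from the current dosages.

        Indel and multiallelic labels are sticky (they depend on allele
        strings, which structural edits never change).
        """
        alt, _ = self.alt_counts()
        new_sites = []
        for rec, a in zip(self.sites, alt):
            if rec.site_class in ("indel", "multiallelic"):
                new_sites.append(rec)
            else:
                cls = "invariant" if a == 0 else "snp"
                new_sites.append(replace(rec, site_class=cls) if cls != rec.site_class else rec)
        return CohortMatrix(self.samples, new_sites, self.dosages, self.groups)

    # ---- comparison helper (tests) --------------------------------------
    def equals(self, other: "CohortMatrix") -> bool:
        return (
            self.samples == other.samples
            and self.site_keys() == other.site_keys()
            and [s.site_id for s in self.sites] == [s.site_id for s in other.sites]
            and [s.site_class for s in self.sites] == [s.site_class for s in other.sites]
            and np.array_equal(self.dosages, other.dosages)
        )


def group_assignment_to_mapping(groups: GroupAssignment | Mapping[str, str]) -> GroupAssignment:
    if isinstance(groups, GroupAssignment):
        return groups
    return GroupAssignment(dict(groups))
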