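"""Novel-allele classification against a reference panel and the
exact-subset (UpSet-style) overlap decomposition.

A biallelic SNP site is *eligible* when every reference-panel individual is
homozygous reference (dosage 0); a focal group is *flagged* there when at
least one member carries the alternate (dosage 1 or 2).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np

from relictpop.variant_store.model import CohortMatrix

__all__ = ["NovelSiteFlags", "OverlapTable", "classify_novel", "overlap_decomposition"]


@dataclass
class NovelSiteFlags:
    focal_groups: list[str]
    site_ids: list[str]  # one per site of the input matrix
    eligible: np.ndarray  # (n_sites,) bool
    flags: np.ndarray  # (n_focal, n_sites) bool; False wherever not eligible
    n_sites_total: int

    @property
    def n_eligible(self) -> int:
        return int(self.eligible.sum())

    def flagged_any(self) -> np.ndarray:
        return self.eligible & self.flags.any(axis=0)

    def group_marginal(self, group: str) -> int:
        return int(self.flags[self.focal_groups.index(group)].sum())


@dataclass
class OverlapTable:
    """Counts per exact nonempty subset of focal groups, plus marginals."""

    focal_groups: list[str]
    exact_counts: dict[tuple[str, ...], int]  # keyed by sorted group tuple
    marginals: dict[str, int]
    total_flagged: int


def classify_novel(
    m: CohortMatrix,
    reference_groups: Sequence[str] = ("wild", "outgroup"),
    focal_groups: Sequence[str] = ("MK", "LR1", "LR2", "cultivar"),
) -> NovelSiteFlags:
    """Flag, per focal group, the sites carrying alleles absent from the
    reference panel. Requires a fully-called matrix."""
    if np.any(m.dosages < 0):
        raise ValueError("novel-allele classification requires a fully-called matrix")
    ref_rows = np.concatenate([m.group_rows(g) for g in reference_groups])
    eligible = (m.dosages[ref_rows] == 0).all(axis=0)
    flags = np.zeros((len(focal_groups), m.n_sites), dtype=bool)
    for gi, g in enumerate(focal_groups):
        rows = m.group_rows(g)
        flags[gi] = eligible & (m.dosages[rows] > 0).any(axis=0)
    site_ids = [
        s.site_id if s.site_id is not None else f"{s.chrom}_{s.pos}" for s in m.sites
    ]
    return NovelSiteFlags(
        focal_groups=list(focal_groups),
        site_ids=site_ids,
        eligible=eligible,
        flags=flags,
        n_sites_total=m.n_sites,
    )


def overlap_decomposition(f: NovelSiteFlags) -> OverlapTable:
    """Partition flagged sites by their exact flagged-group set."""
    groups = f.focal_groups
    flagged = f.flagged_any()
    exact: dict[tuple[str, ...], int] = {}
    for size in range(1, len(groups) + 1):
        for combo in combinations(range(len(groups)), size):
            member = np.ones(f.flags.shape[1], dtype=bool)
            for gi in range(len(groups)):
                if gi in combo:
                    member &= f.flags[gi]
                else:
                    member &= ~f.flags[gi]
            count = int((member & flagged).sum())
            if count:
                exact[tuple(groups[i] for i in combo)] = count
    marginals = {g: f.group_marginal(g) for g in groups}
    return OverlapTable(
        focal_groups=list(groups),
        exact_counts=exact,
        marginals=marginals,
        total_flagged=int(flagged.sum()),
    )
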