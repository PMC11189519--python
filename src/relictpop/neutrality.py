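"""Folded site frequency spectrum and windowed Tajima's D from called
genotypes.

Sites with any missing genotype in the focal group are excluded from the
SFS, S, and theta-pi (and counted), so the haplotype sample size n is
constant at twice the group size. theta-pi uses the phase-free allele-count
identity: a site with ``a`` alternate alleles among ``n`` haplotypes adds
``a (n - a) / C(n, 2)`` mean pairwise differences.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from relictpop.variant_store.model import CohortMatrix

__all__ = [
    "FoldedSFS",
    "NeutralityWindow",
    "TajimaConstants",
    "tajima_constants",
    "folded_sfs",
    "tajima_windows",
]


@dataclass
class FoldedSFS:
    group: str
    n_alleles: int  # 2 x group size
    bins: np.ndarray  # counts indexed by minor-allele count, 0..n//2
    n_skipped_missing: int

    @property
    def n_sites(self) -> int:
        return int(self.bins.sum())

    def singleton_share(self) -> float:
        """Share of segregating sites that are singletons (minor count 1)."""
        seg = self.bins[1:].sum()
        return float(self.bins[1] / seg) if seg > 0 else math.nan


@dataclass
class TajimaConstants:
    n: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float


def tajima_constants(n: int) -> TajimaConstants:
    """Constants of the D variance formula for n haplotypes (Tajima 1989)."""
    if n < 2:
        raise ValueError("need at least 2 haplotypes")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return TajimaConstants(n, a1, a2, b1, b2, c1, c2, e1, e2)


@dataclass
class NeutralityWindow:
    chrom: str
    start: int
    end: int
    n_sites: int  # fully-called sites in window
    s: int  # segregating sites
    theta_pi: float
    theta_w: float
    tajima_d: float  # NaN when S == 0
    n: int  # haplotype sample size


def _full_call_alt_counts(
    m: CohortMatrix, group: str | Sequence[str]
) -> tuple[np.ndarray, np.ndarray, int, int]:
    """(site mask of fully-called sites, alt counts there, n haplotypes,
    number of sites skipped for missingness)."""
    if isinstance(group, str):
        rows = m.group_rows(group)
    else:
        rows = m.sample_indices(list(group))
    if len(rows) == 0:
        raise ValueError("empty group")
    d = m.dosages[rows]
    full = (d >= 0).all(axis=0)
    alt = d.sum(axis=0, dtype=np.int64)
    n = 2 * len(rows)
    return full, alt, n, int((~full).sum())


def folded_sfs(m: CohortMatrix, group: str | Sequence[str]) -> FoldedSFS:
    """Histogram of minor-allele counts over fully-called sites."""
    full, alt, n, skipped = _full_call_alt_counts(m, group)
    minor = np.minimum(alt[full], n - alt[full])
    bins = np.bincount(minor, minlength=n // 2 + 1)
    label = group if isinstance(group, str) else ",".join(group)
    return FoldedSFS(group=label, n_alleles=n, bins=bins, n_skipped_missing=skipped)


def tajima_windows(
    m: CohortMatrix,
    group: str | Sequence[str],
    window_bp: int = 50_000,
    step_bp: int = 10_000,
) -> list[NeutralityWindow]:
    """Sliding-window Tajima's D (windows anchored at position 1; a site
    contributes to every window covering it)."""
    full, alt, n, _ = _full_call_alt_counts(m, group)
    if n < 4:
        warnings.warn("fewer than 4 haplotypes: D variance formula is unstable")
    const = tajima_constants(n)
    pair_comps = n * (n - 1) / 2.0
    chroms = m.chroms()
    pos = m.positions()
    out: list[NeutralityWindow] = []
    for chrom in sorted(set(chroms.astype(str))):
        cmask = (chroms == chrom) & full
        p = pos[cmask]
        a = alt[cmask]
        seg = (a > 0) & (a < n)
        pi_site = a * (n - a) / pair_comps
        order = np.argsort(p, kind="stable")
        p, a, seg, pi_site = p[order], a[order], seg[order], pi_site[order]
        # prefix sums for O(1) window aggregation
        cum_sites = np.concatenate([[0], np.cumsum(np.ones_like(p))])
        cum_s = np.concatenate([[0], np.cumsum(seg.astype(np.int64))])
        cum_pi = np.concatenate([[0.0], np.cumsum(pi_site)])
        extent = int(pos[chroms == chrom].max())
        start = 1
        while start <= extent:
            end = start + window_bp
            lo = np.searchsorted(p, start, side="left")
            hi = np.searchsorted(p, end, side="left")
            s = int(cum_s[hi] - cum_s[lo])
            theta_pi = float(cum_pi[hi] - cum_pi[lo])
            theta_w = s / const.a1
            var = const.e1 * s + const.e2 * s * (s - 1)
            if s > 0 and var > 0:
                d_stat = (theta_pi - theta_w) / math.sqrt(var)
            else:
                d_stat = math.nan
            out.append(
                NeutralityWindow(
                    chrom=chrom,
                    start=start,
                    end=end,
                    n_sites=int(cum_sites[hi] - cum_sites[lo]),
                    s=s,
                    theta_pi=theta_pi,
                    theta_w=theta_w,
                    tajima_d=d_stat,
                    n=n,
                )
            )
            start += step_bp
    return out
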