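"""Genotype-dosage linkage disequilibrium: pairwise r2 within a distance
cap, decay curves with replicate downsampling, and windowed r2 pruning.

r2 is the squared Pearson correlation of dosage vectors (composite LD, no
phase assumed) over pairwise-complete samples. Pairs where either vector is
monomorphic among the complete cases are skipped rather than emitted as NaN.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from relictpop.variant_store.model import CohortMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "LDPair",
    "DecayCurve",
    "pairwise_r2",
    "decay_curve",
    "downsampled_decay",
    "ld_prune",
    "prune_window_starts",
]

DEFAULT_MAX_DIST = 500_000


@dataclass
class LDPair:
    chrom: str
    site_i: int  # site index into the matrix
    site_j: int
    pos_i: int
    pos_j: int
    dist_bp: int
    r2: float


@dataclass
class DecayCurve:
    """Mean r2 and pair count per distance bin [k*b, (k+1)*b)."""

    bin_width: int
    bin_left: np.ndarray
    mean_r2: np.ndarray  # NaN for empty bins
    count: np.ndarray


def _masked_r2_block(x: np.ndarray, block: np.ndarray) -> np.ndarray:
    """r2 of one dosage vector against each column of ``block``,
    pairwise-complete over samples; NaN marks skipped (monomorphic) pairs."""
    xm = x >= 0
    bm = block >= 0
    both = xm[:, None] & bm
    n = both.sum(axis=0).astype(np.float64)
    xv = np.where(both, x[:, None], 0).astype(np.float64)
    bv = np.where(both, block, 0).astype(np.float64)
    sx = xv.sum(axis=0)
    sy = bv.sum(axis=0)
    sxx = (xv * xv).sum(axis=0)
    syy = (bv * bv).sum(axis=0)
    sxy = (xv * bv).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        cov = sxy - sx * sy / n
        vx = sxx - sx * sx / n
        vy = syy - sy * sy / n
        r2 = (cov * cov) / (vx * vy)
    bad = (n < 2) | (vx <= 0) | (vy <= 0)
    r2[bad] = np.nan
    return r2


def pairwise_r2(
    m: CohortMatrix,
    group: str | Sequence[str] | None = None,
    max_dist: int = DEFAULT_MAX_DIST,
) -> list[LDPair]:
    """All same-chromosome site pairs with |pos_i - pos_j| <= max_dist."""
    if group is None:
        rows = np.arange(m.n_samples)
    elif isinstance(group, str):
        rows = m.group_rows(group)
    else:
        rows = m.sample_indices(list(group))
    if len(rows) < 2:
        raise ValueError("need at least 2 samples for r2")
    d = m.dosages[rows]
    chroms = m.chroms()
    pos = m.positions()
    out: list[LDPair] = []
    n_skipped = 0
    for chrom in sorted(set(chroms.astype(str))):
        idx = np.flatnonzero(chroms == chrom)
        p = pos[idx]
        for a in range(len(idx)):
            hi = np.searchsorted(p, p[a] + max_dist, side="right")
            if hi <= a + 1:
                continue
            js = idx[a + 1 : hi]
            r2 = _masked_r2_block(d[:, idx[a]], d[:, js])
            for off, j in enumerate(js):
                if math.isnan(r2[off]):
                    n_skipped += 1
                    continue
                out.append(
                    LDPair(
                        chrom=chrom,
                        site_i=int(idx[a]),
                        site_j=int(j),
                        pos_i=int(p[a]),
                        pos_j=int(pos[j]),
                        dist_bp=int(pos[j] - p[a]),
                        r2=float(r2[off]),
                    )
                )
    if n_skipped:
        logger.info("skipped %d monomorphic/undersized pairs", n_skipped)
    return out


def decay_curve(pairs: Sequence[LDPair], bin_width: int = 1000) -> DecayCurve:
    """Bin pairs by distance; mean r2 per bin, NaN for empty bins."""
    if not pairs:
        raise ValueError("no LD pairs to bin")
    dist = np.asarray([p.dist_bp for p in pairs], dtype=np.int64)
    r2 = np.asarray([p.r2 for p in pairs], dtype=np.float64)
    n_bins = int(dist.max() // bin_width) + 1
    which = dist // bin_width
    count = np.bincount(which, minlength=n_bins)
    total = np.bincount(which, weights=r2, minlength=n_bins)
    with np.errstate(divide="ignore", invalid="ignore"):
        mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return DecayCurve(
        bin_width=bin_width,
        bin_left=np.arange(n_bins, dtype=np.int64) * bin_width,
        mean_r2=mean,
        count=count,
    )


def downsampled_decay(
    m: CohortMatrix,
    group: str | Sequence[str],
    n_sub: int = 10,
    reps: int = 10,
    seed: int = 0,
    max_dist: int = DEFAULT_MAX_DIST,
    bin_width: int = 1000,
) -> list[DecayCurve]:
    """Replicate LD-decay curves from random subsamples without replacement."""
    if isinstance(group, str):
        members = [m.samples[i] for i in m.group_rows(group)]
    else:
        members = list(group)
    if len(members) < n_sub:
        raise ValueError(f"group of {len(members)} smaller than n_sub={n_sub}")
    rng = np.random.default_rng(seed)
    curves = []
    for _ in range(reps):
        chosen = [members[i] for i in rng.choice(len(members), size=n_sub, replace=False)]
        pairs = pairwise_r2(m, chosen, max_dist=max_dist)
        curves.append(decay_curve(pairs, bin_width=bin_width))
    return curves


def mean_curve(curves: Sequence[DecayCurve]) -> DecayCurve:
    """Pair-count-weighted mean of replicate curves on a shared bin grid."""
    bw = curves[0].bin_width
    n_bins = max(len(c.bin_left) for c in curves)
    total = np.zeros(n_bins)
    count = np.zeros(n_bins, dtype=np.int64)
    for c in curves:
        k = len(c.bin_left)
        valid = c.count > 0
        total[:k][valid] += c.mean_r2[:k][valid] * c.count[:k][valid]
        count[:k] += c.count
    with np.errstate(divide="ignore", invalid="ignore"):
        mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return DecayCurve(bw, np.arange(n_bins, dtype=np.int64) * bw, mean, count)


def prune_window_starts(n_sites: int, window_snps: int, step_snps: int) -> list[int]:
    """Window start indices over the original (per-chromosome) SNP ordering."""
    if n_sites <= window_snps:
        return [0]
    starts = list(range(0, n_sites - window_snps + 1, step_snps))
    if starts[-1] + window_snps < n_sites:
        starts.append(n_sites - window_snps)
    return starts


def ld_prune(
    m: CohortMatrix,
    group: str | Sequence[str] | None = None,
    window_snps: int = 50,
    step_snps: int = 10,
    r2_max: float = 0.1,
) -> tuple[CohortMatrix, list[int], list[int]]:
    """Windowed greedy r2 pruning (``--indep-pairwise W S R`` dialect).

    Windows are W consecutive sites of the original per-chromosome ordering,
    advancing by S. Within a window, while any retained pair exceeds
    ``r2_max``, the member with the smaller cohort MAF is removed (tie: the
    later position). Returns (pruned matrix, kept indices, removed indices).
    """
    if group is None:
        rows = np.arange(m.n_samples)
    elif isinstance(group, str):
        rows = m.group_rows(group)
    else:
        rows = m.sample_indices(list(group))
    d = m.dosages[rows]
    alt, n_alleles = m.alt_counts(rows)
    with np.errstate(divide="ignore", invalid="ignore"):
        maf = np.where(
            n_alleles > 0,
            np.minimum(alt, n_alleles - alt) / np.maximum(n_alleles, 1),
            0.0,
        )
    chroms = m.chroms()
    pos = m.positions()
    keep = np.ones(m.n_sites, dtype=bool)
    for chrom in sorted(set(chroms.astype(str))):
        idx = np.flatnonzero(chroms == chrom)
        for s in prune_window_starts(len(idx), window_snps, step_snps):
            window = idx[s : s + window_snps]
            _prune_one_window(d, maf, pos, window, keep, r2_max)
    kept = np.flatnonzero(keep)
    removed = np.flatnonzero(~keep)
    return m.take_sites(kept), kept.tolist(), removed.tolist()


def _prune_one_window(
    d: np.ndarray,
    maf: np.ndarray,
    pos: np.ndarray,
    window: np.ndarray,
    keep: np.ndarray,
    r2_max: float,
) -> None:
    active = [int(i) for i in window if keep[i]]
    while len(active) > 1:
        worst = None
        for ai in range(len(active)):
            i = active[ai]
            block = d[:, active[ai + 1 :]]
            if block.shape[1] == 0:
                continue
            r2 = _masked_r2_block(d[:, i], block)
            over = np.flatnonzero(np.nan_to_num(r2, nan=0.0) > r2_max)
            if over.size:
                worst = (i, active[ai + 1 + int(over[0])])
                break
        if worst is None:
            return
        i, j = worst
        # remove the smaller-MAF member; tie -> the later position
        if maf[i] < maf[j]:
            victim = i
        elif maf[j] < maf[i]:
            victim = j
        else:
            victim = j if pos[j] > pos[i] else i
        keep[victim] = False
        active.remove(victim)
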