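"""Missing-data-aware windowed diversity and divergence statistics.

pi and dxy are ratio-of-sums estimators over ALL sites (variant and
invariant), computed per site from allele tallies: for ``n`` called
haplotypes of which ``a`` carry the alternate allele, the number of
mismatching unordered haplotype pairs is ``a * (n - a)`` and the number of
comparisons is ``n * (n - 1) / 2``. This allele-count algebra is exact for
unphased diploids because the estimators only depend on per-site allele
counts.

Fst uses the Weir & Cockerham (1984) two-level variance components
(a: among populations, b: among individuals within populations, c: within
individuals); a window's value is ``sum(a) / sum(a + b + c)``. A Hudson-type
estimator is available behind a flag.

Undefined windows (zero comparisons) carry NaN, never 0, and are excluded
from window-mean summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from relictpop.variant_store.model import CohortMatrix

__all__ = [
    "DiversityWindow",
    "HetReport",
    "RelatednessPair",
    "pi_windows",
    "dxy_windows",
    "fst_windows",
    "het_fis",
    "relatedness_ajk",
    "summarize",
    "windows_to_frame",
]

DEFAULT_WINDOW_BP = 10_000


@dataclass
class DiversityWindow:
    """One half-open window [start, start+window_bp) anchored at position 1.

    ``n_diffs``/``n_comps`` are summed pairwise-mismatch and comparison
    tallies for pi/dxy, or summed WC84 numerator/denominator components for
    Fst; ``value`` is their ratio (NaN when the denominator is zero).
    """

    chrom: str
    start: int
    end: int
    n_sites: int
    n_diffs: float
    n_comps: float
    value: float
    stat: str
    partial: bool = False


@dataclass
class HetReport:
    """Per-individual homozygosity accounting and inbreeding coefficient."""

    sample: str
    obs_hom: int
    exp_hom: float
    n_called: int
    he: float
    fis: float


@dataclass
class RelatednessPair:
    """Allele-frequency-standardized genotype covariance (Yang-style Ajk)."""

    sample_j: str
    sample_k: str
    ajk: float
    n_sites: int


def _group_rows(m: CohortMatrix, group: str | Sequence[str]) -> np.ndarray:
    if isinstance(group, str):
        return m.group_rows(group)
    return m.sample_indices(list(group))


def _aggregate_windows(
    m: CohortMatrix,
    diffs: np.ndarray,
    comps: np.ndarray,
    window_bp: int,
    stat: str,
) -> list[DiversityWindow]:
    """Tile each chromosome from position 1 and pool per-site tallies."""
    chroms = m.chroms()
    pos = m.positions()
    out: list[DiversityWindow] = []
    for chrom in sorted(set(chroms.astype(str))):
        mask = chroms == chrom
        p = pos[mask]
        d = diffs[mask]
        c = comps[mask]
        extent = int(p.max())
        n_windows = (extent - 1) // window_bp + 1
        widx = (p - 1) // window_bp
        sum_d = np.zeros(n_windows)
        sum_c = np.zeros(n_windows)
        n_scored = np.zeros(n_windows, dtype=np.int64)
        np.add.at(sum_d, widx, d)
        np.add.at(sum_c, widx, c)
        np.add.at(n_scored, widx, (c > 0).astype(np.int64))
        for w in range(n_windows):
            start = w * window_bp + 1
            end = start + window_bp
            partial = end - 1 > extent
            value = sum_d[w] / sum_c[w] if sum_c[w] > 0 else math.nan
            out.append(
                DiversityWindow(
                    chrom=chrom,
                    start=start,
                    end=end,
                    n_sites=int(n_scored[w]),
                    n_diffs=float(sum_d[w]),
                    n_comps=float(sum_c[w]),
                    value=value,
                    stat=stat,
                    partial=partial,
                )
            )
    return out


def _site_pi_tallies(m: CohortMatrix, rows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    alt, n = m.alt_counts(rows)
    diffs = alt * (n - alt)
    comps = n * (n - 1) // 2
    return diffs.astype(np.float64), comps.astype(np.float64)


def pi_windows(
    m: CohortMatrix,
    group: str | Sequence[str],
    window_bp: int = DEFAULT_WINDOW_BP,
) -> list[DiversityWindow]:
    """Windowed nucleotide diversity within ``group`` (pixy-style).

    Sites with fewer than two called haplotypes in the group contribute
    nothing to either tally.
    """
    rows = _group_rows(m, group)
    diffs, comps = _site_pi_tallies(m, rows)
    return _aggregate_windows(m, diffs, comps, window_bp, "pi")


def dxy_windows(
    m: CohortMatrix,
    group1: str | Sequence[str],
    group2: str | Sequence[str],
    window_bp: int = DEFAULT_WINDOW_BP,
) -> list[DiversityWindow]:
    """Windowed between-group divergence: only cross-group haplotype pairs."""
    r1 = _group_rows(m, group1)
    r2 = _group_rows(m, group2)
    if set(r1.tolist()) & set(r2.tolist()):
        raise ValueError("dxy groups must be disjoint")
    a1, n1 = m.alt_counts(r1)
    a2, n2 = m.alt_counts(r2)
    diffs = (a1 * (n2 - a2) + (n1 - a1) * a2).astype(np.float64)
    comps = (n1 * n2).astype(np.float64)
    return _aggregate_windows(m, diffs, comps, window_bp, "dxy")


def _wc84_components(
    m: CohortMatrix, groups_rows: list[np.ndarray]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-site WC84 variance components (a, b, c) and a contributing mask.

    A site contributes when every group has at least two called genotypes;
    monomorphic sites contribute exact zeros.
    """
    r = len(groups_rows)
    n_i = []
    p_i = []
    h_i = []
    for rows in groups_rows:
        d = m.dosages[rows]
        called = d >= 0
        n = called.sum(axis=0, dtype=np.float64)
        alt = np.where(called, d, 0).sum(axis=0, dtype=np.float64)
        het = np.where(called, d == 1, False).sum(axis=0, dtype=np.float64)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(n > 0, alt / np.maximum(2 * n, 1), 0.0)
            h = np.where(n > 0, het / np.maximum(n, 1), 0.0)
        n_i.append(n)
        p_i.append(p)
        h_i.append(h)
    n_i = np.stack(n_i)  # (r, L)
    p_i = np.stack(p_i)
    h_i = np.stack(h_i)
    ok = (n_i >= 2).all(axis=0)
    nbar = n_i.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        nc = (r * nbar - (n_i**2).sum(axis=0) / (r * nbar)) / (r - 1)
        pbar = (n_i * p_i).sum(axis=0) / (r * nbar)
        s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum(axis=0) / (r * nbar)
        inner = pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4
        a = nbar / nc * (s2 - inner / (nbar - 1))
        b = nbar / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
    a = np.where(ok, a, 0.0)
    b = np.where(ok, b, 0.0)
    c = np.where(ok, c, 0.0)
    return a, b, c, ok


def _hudson_components(
    m: CohortMatrix, groups_rows: list[np.ndarray]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if len(groups_rows) != 2:
        raise ValueError("Hudson Fst is defined for exactly two groups")
    a1, n1 = m.alt_counts(groups_rows[0])
    a2, n2 = m.alt_counts(groups_rows[1])
    ok = (n1 >= 2) & (n2 >= 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = np.where(n1 > 0, a1 / np.maximum(n1, 1), 0.0)
        p2 = np.where(n2 > 0, a2 / np.maximum(n2, 1), 0.0)
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / np.maximum(n1 - 1, 1) - p2 * (1 - p2) / np.maximum(n2 - 1, 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
    num = np.where(ok, num, 0.0)
    den = np.where(ok, den, 0.0)
    return num, den, ok


def fst_windows(
    m: CohortMatrix,
    group1: str | Sequence[str],
    group2: str | Sequence[str],
    window_bp: int = DEFAULT_WINDOW_BP,
    estimator: str = "wc84",
) -> list[DiversityWindow]:
    """Windowed Fst between two groups (WC84 by default).

    Window value = sum of among-population components over sum of all
    components; invariant sites contribute exact zeros to both sums.
    """
    rows = [_group_rows(m, group1), _group_rows(m, group2)]
    if estimator == "wc84":
        a, b, c, _ = _wc84_components(m, rows)
        num, den = a, a + b + c
    elif estimator == "hudson":
        num, den, _ = _hudson_components(m, rows)
    else:
        raise ValueError(f"unknown Fst estimator {estimator!r}")
    return _aggregate_windows(m, num, den, window_bp, f"fst_{estimator}")


def fst_sitewise_components(
    m: CohortMatrix, group1: str | Sequence[str], group2: str | Sequence[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Expose per-site WC84 (a, b, c) arrays; used by tests and summaries."""
    rows = [_group_rows(m, group1), _group_rows(m, group2)]
    a, b, c, _ = _wc84_components(m, rows)
    return a, b, c


def het_fis(m: CohortMatrix) -> list[HetReport]:
    """Per-individual observed/expected homozygosity and F_IS.

    Allele frequencies are taken over the whole cohort present in the
    matrix. Per site with frequency ``p`` over ``N`` called alleles the
    expected homozygosity carries the small-sample correction
    ``1 - 2 p (1-p) N / (N-1)``; sites with ``N < 2`` are skipped.
    """
    if m.n_samples < 2:
        raise ValueError("het_fis needs at least 2 samples")
    d = m.dosages
    called = d >= 0
    alt, n_alleles = m.alt_counts()
    usable = n_alleles >= 2
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(usable, alt / np.maximum(n_alleles, 1), 0.0)
        corr = np.where(usable, n_alleles / np.maximum(n_alleles - 1, 1), 0.0)
    exp_hom_site = np.where(usable, 1.0 - 2.0 * p * (1.0 - p) * corr, 0.0)
    use = called & usable[None, :]
    n_called = use.sum(axis=1)
    obs_hom = (use & ((d == 0) | (d == 2))).sum(axis=1)
    exp_hom = use.astype(np.float64) @ exp_hom_site
    out: list[HetReport] = []
    for i, sample in enumerate(m.samples):
        nc = int(n_called[i])
        he = (nc - int(obs_hom[i])) / nc if nc > 0 else math.nan
        denom = nc - exp_hom[i]
        fis = (obs_hom[i] - exp_hom[i]) / denom if denom != 0 else math.nan
        out.append(
            HetReport(
                sample=sample,
                obs_hom=int(obs_hom[i]),
                exp_hom=float(exp_hom[i]),
                n_called=nc,
                he=he,
                fis=fis,
            )
        )
    return out


def relatedness_ajk(m: CohortMatrix) -> list[RelatednessPair]:
    """Pairwise Ajk: mean over usable sites of
    ``(g_j - 2p)(g_k - 2p) / (2 p (1-p))`` with cohort-wide ``p``.

    Only polymorphic sites (0 < p < 1) contribute; a pair's mean runs over
    sites where both members are called.
    """
    if m.n_samples < 2:
        raise ValueError("relatedness needs at least 2 samples")
    d = m.dosages.astype(np.float64)
    called = m.dosages >= 0
    alt, n_alleles = m.alt_counts()
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), 0.0)
    usable = (p > 0) & (p < 1)
    if not usable.any():
        raise ValueError("no polymorphic sites usable for relatedness")
    scale = np.sqrt(2.0 * p * (1.0 - p), where=usable, out=np.zeros_like(p))
    x = np.where(called & usable[None, :], (d - 2.0 * p) / np.where(usable, scale, 1.0), 0.0)
    mask = (called & usable[None, :]).astype(np.float64)
    num = x @ x.T
    cnt = mask @ mask.T
    out: list[RelatednessPair] = []
    for j in range(m.n_samples):
        for k in range(j + 1, m.n_samples):
            c = cnt[j, k]
            ajk = num[j, k] / c if c > 0 else math.nan
            out.append(RelatednessPair(m.samples[j], m.samples[k], float(ajk), int(c)))
    return out


def windows_to_frame(windows: list[DiversityWindow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [w.chrom for w in windows],
            "start": [w.start for w in windows],
            "end": [w.end for w in windows],
            "n_sites": [w.n_sites for w in windows],
            "n_diffs": [w.n_diffs for w in windows],
            "n_comps": [w.n_comps for w in windows],
            "value": [w.value for w in windows],
            "stat": [w.stat for w in windows],
            "partial": [w.partial for w in windows],
        }
    )


def summarize(windows: list[DiversityWindow]) -> pd.DataFrame:
    """Per-chromosome and genome-wide summaries, both pooled
    (ratio of summed tallies) and window-mean (mean of defined ratios)."""
    df = windows_to_frame(windows)
    rows = []

    def _summary(sub: pd.DataFrame, label: str) -> dict:
        pooled = sub.n_diffs.sum() / sub.n_comps.sum() if sub.n_comps.sum() > 0 else math.nan
        defined = sub.value.dropna()
        return {
            "chrom": label,
            "pooled": pooled,
            "window_mean": defined.mean() if len(defined) else math.nan,
            "n_windows": len(sub),
            "n_defined": len(defined),
        }

    for chrom, sub in df.groupby("chrom", sort=True):
        rows.append(_summary(sub, str(chrom)))
    rows.append(_summary(df, "genome"))
    return pd.DataFrame(rows)
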