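"""Independent brute-force reference implementations.

Everything here is written as plain loops over haplotype pairs / direct
formula transcriptions, deliberately sharing no code path with the package
estimators it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def haplotypes_of(dosage: int) -> list[int]:
    """Expand a diploid dosage into two haplotype alleles (missing -> none)."""
    if dosage < 0:
        return []
    return {0: [0, 0], 1: [0, 1], 2: [1, 1]}[dosage]


def pi_site(dosages_column: np.ndarray) -> tuple[int, int]:
    """(mismatching pairs, total pairs) over all haplotype pairs at a site."""
    haps: list[int] = []
    for d in dosages_column:
        haps.extend(haplotypes_of(int(d)))
    diffs = comps = 0
    for a, b in itertools.combinations(haps, 2):
        comps += 1
        diffs += int(a != b)
    return diffs, comps


def dxy_site(col1: np.ndarray, col2: np.ndarray) -> tuple[int, int]:
    h1: list[int] = []
    h2: list[int] = []
    for d in col1:
        h1.extend(haplotypes_of(int(d)))
    for d in col2:
        h2.extend(haplotypes_of(int(d)))
    diffs = comps = 0
    for a in h1:
        for b in h2:
            comps += 1
            diffs += int(a != b)
    return diffs, comps


def pooled_pi(dosages: np.ndarray) -> float:
    """Ratio-of-sums pi over all sites of a (samples x sites) group block."""
    diffs = comps = 0
    for j in range(dosages.shape[1]):
        d, c = pi_site(dosages[:, j])
        diffs += d
        comps += c
    return diffs / comps if comps else math.nan


def pooled_dxy(d1: np.ndarray, d2: np.ndarray) -> float:
    diffs = comps = 0
    for j in range(d1.shape[1]):
        d, c = dxy_site(d1[:, j], d2[:, j])
        diffs += d
        comps += c
    return diffs / comps if comps else math.nan


def wc84_site(col1: np.ndarray, col2: np.ndarray) -> tuple[float, float, float] | None:
    """Weir & Cockerham (1984) variance components for one biallelic site,
    two populations; None when either group has < 2 called genotypes."""
    cols = [col1[col1 >= 0], col2[col2 >= 0]]
    if any(len(c) < 2 for c in cols):
        return None
    r = 2
    n = [float(len(c)) for c in cols]
    p = [float(np.sum(c)) / (2 * len(c)) for c in cols]
    h = [float(np.sum(c == 1)) / len(c) for c in cols]
    nbar = sum(n) / r
    nc = (r * nbar - sum(x * x for x in n) / (r * nbar)) / (r - 1)
    pbar = sum(ni * pi for ni, pi in zip(n, p)) / (r * nbar)
    s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
    hbar = sum(ni * hi for ni, hi in zip(n, h)) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (1.0 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2
    return a, b, c


def pooled_fst(d1: np.ndarray, d2: np.ndarray) -> float:
    num = den = 0.0
    for j in range(d1.shape[1]):
        comp = wc84_site(d1[:, j], d2[:, j])
        if comp is None:
            continue
        a, b, c = comp
        num += a
        den += a + b + c
    return num / den if den != 0 else math.nan


def r2_pair(x: np.ndarray, y: np.ndarray) -> float | None:
    """Squared Pearson correlation over pairwise-complete entries; None for
    undersized or monomorphic pairs."""
    ok = (x >= 0) & (y >= 0)
    xv, yv = x[ok].astype(float), y[ok].astype(float)
    if len(xv) < 2 or np.all(xv == xv[0]) or np.all(yv == yv[0]):
        return None
    r = np.corrcoef(xv, yv)[0, 1]
    return float(r * r)


def ibs_pair(x: np.ndarray, y: np.ndarray) -> float:
    num = cnt = 0
    for a, b in zip(x, y):
        if a >= 0 and b >= 0:
            num += abs(int(a) - int(b)) / 2.0
            cnt += 1
    return num / cnt


def fis_individual(dosages: np.ndarray, i: int) -> tuple[int, float, int]:
    """(obs_hom, exp_hom, n_called) for individual ``i`` with cohort-wide
    frequencies and the N/(N-1) small-sample correction."""
    obs = n_called = 0
    exp = 0.0
    for j in range(dosages.shape[1]):
        col = dosages[:, j]
        called = col[col >= 0]
        big_n = 2 * len(called)
        if big_n < 2 or col[i] < 0:
            continue
        p = float(np.sum(called)) / big_n
        exp += 1.0 - 2.0 * p * (1.0 - p) * big_n / (big_n - 1)
        obs += int(col[i] in (0, 2))
        n_called += 1
    return obs, exp, n_called


def ajk_pair(dosages: np.ndarray, j: int, k: int) -> float:
    terms = []
    for s in range(dosages.shape[1]):
        col = dosages[:, s]
        called = col[col >= 0]
        if len(called) == 0:
            continue
        p = float(np.sum(called)) / (2 * len(called))
        if p <= 0 or p >= 1 or col[j] < 0 or col[k] < 0:
            continue
        terms.append((col[j] - 2 * p) * (col[k] - 2 * p) / (2 * p * (1 - p)))
    return float(np.mean(terms)) if terms else math.nan


def folded_sfs_counts(dosages: np.ndarray) -> dict[int, int]:
    """Minor-allele-count histogram over fully-called sites."""
    n_hap = 2 * dosages.shape[0]
    out: dict[int, int] = {}
    for j in range(dosages.shape[1]):
        col = dosages[:, j]
        if np.any(col < 0):
            continue
        alt = int(np.sum(col))
        minor = min(alt, n_hap - alt)
        out[minor] = out.get(minor, 0) + 1
    return out


def tajima_d(s: int, theta_pi: float, n: int) -> float:
    """Direct transcription of the D statistic (Tajima 1989)."""
    if s == 0:
        return math.nan
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return (theta_pi - s / a1) / math.sqrt(e1 * s + e2 * s * (s - 1))


def theta_pi_from_haplotypes(haps: np.ndarray) -> float:
    """Mean pairwise differences summed over sites, by explicit pair loops
    over phased haplotype rows."""
    n = haps.shape[0]
    total = 0
    pairs = 0
    for a, b in itertools.combinations(range(n), 2):
        total += int(np.sum(haps[a] != haps[b]))
        pairs += 1
    return total / pairs if pairs else math.nan


def random_additive_tree(rng: np.random.Generator, n_taxa: int):
    """Random binary tree topology with positive branch lengths; returns
    (newick string, labels, exact leaf-to-leaf distance matrix)."""
    labels = [f"T{i}" for i in range(n_taxa)]
    index = {lab: i for i, lab in enumerate(labels)}
    dist = np.zeros((n_taxa, n_taxa))
    # sequential random joins; each subtree tracks root-to-leaf depths, and a
    # join fixes the pairwise distances between its two leaf sets
    nodes: list[tuple[str, dict[str, float]]] = [(lab, {lab: 0.0}) for lab in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        nwk_j, d_j = nodes.pop(j)
        nwk_i, d_i = nodes.pop(i)
        li = float(rng.uniform(0.1, 2.0))
        lj = float(rng.uniform(0.1, 2.0))
        for a, da in d_i.items():
            for b, db in d_j.items():
                d = da + li + db + lj
                dist[index[a], index[b]] = dist[index[b], index[a]] = d
        merged = {k: v + li for k, v in d_i.items()}
        merged.update({k: v + lj for k, v in d_j.items()})
        nodes.append((f"({nwk_i}:{li},{nwk_j}:{lj})", merged))
    newick = nodes[0][0] + ";"
    return newick, labels, dist
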