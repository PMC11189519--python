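"""Discrete-generation forward Wright-Fisher simulation.

State is a haplotype x segregating-site 0/1 matrix over all living
populations, with columns kept sorted by genome position. Each generation:
offspring pick parents (own deme, a migrant source deme, or the founding
source at a split), gametes are formed with an independent starting phase
per chromosome plus Poisson crossovers within chromosomes, and new
infinite-sites mutations land on a continuous unit position line. Columns
fixed or lost across all living haplotypes leave the segregating set (a
globally fixed column is a substitution and redefines the ancestral state
at that position).

The per-generation work runs through three numba kernels (gamete segment
copies, column sums, and the prune/insert column merge) so that large
burn-ins run near memory bandwidth. Everything is driven by one seeded
Generator: a fixed seed reproduces the run bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from relictpop.simpop.demography import DemographyModel, GenomeLayout

__all__ = ["SimResult", "simulate_wf"]

#: reject demographies whose per-site heterozygosity would strain the
#: infinite-sites bookkeeping
MAX_THETA_SITE = 0.25


@dataclass
class SimResult:
    """Sampled haplotypes plus the truth record needed by the tests."""

    layout: GenomeLayout
    total_bp: int
    site_u: np.ndarray  # sorted continuous positions in [0, 1)
    haplotypes: dict[str, np.ndarray]  # pop -> (2 * n_sampled, n_sites) uint8
    truth: dict = field(default_factory=dict)

    @property
    def n_sites(self) -> int:
        return int(self.site_u.size)

    def sampled_pops(self) -> list[str]:
        return list(self.haplotypes)


def _pad8(k: int) -> int:
    return (k + 7) & ~7


@njit(cache=True, inline="always")
def _seg_copy(h8, h64, src_row, out8, out64, g, lo, hi):
    """Copy bytes [lo, hi) of one parent row into one gamete row,
    word-wise in the aligned middle."""
    if hi - lo < 24:
        for j in range(lo, hi):
            out8[g, j] = h8[src_row, j]
        return
    a = lo
    while a & 7:
        out8[g, a] = h8[src_row, a]
        a += 1
    b = hi & ~7
    for w in range(a >> 3, b >> 3):
        out64[g, w] = h64[src_row, w]
    for j in range(b, hi):
        out8[g, j] = h8[src_row, j]


@njit(cache=True)
def _copy_gametes(h8, h64, out8, out64, rows_a, rows_b, coins, cross_cols,
                  cross_off, chrom_col_start):
    """Write each gamete as segment copies of its two parental haplotypes.

    Phase restarts per chromosome (free recombination between chromosomes);
    each crossover column flips the phase within its chromosome.
    """
    g_total = out8.shape[0]
    n_chrom = chrom_col_start.shape[0] - 1
    for g in range(g_total):
        si = cross_off[g]
        send = cross_off[g + 1]
        for c in range(n_chrom):
            lo = chrom_col_start[c]
            hi = chrom_col_start[c + 1]
            cur = coins[g, c]
            while si < send and cross_cols[si] < lo:
                si += 1
            pos = lo
            while si < send and cross_cols[si] < hi:
                b = cross_cols[si]
                if b > pos:
                    row = rows_b[g] if cur else rows_a[g]
                    _seg_copy(h8, h64, row, out8, out64, g, pos, b)
                cur ^= 1
                pos = b
                si += 1
            row = rows_b[g] if cur else rows_a[g]
            _seg_copy(h8, h64, row, out8, out64, g, pos, hi)


@njit(cache=True)
def _colsum(child, k, out):
    g_total = child.shape[0]
    for j in range(k):
        out[j] = 0
    for g in range(g_total):
        for j in range(k):
            out[j] += child[g, j]


@njit(cache=True)
def _scatter_runs(child, final, run_src, run_tgt, run_len):
    """Copy kept column runs of ``child`` into their merged positions."""
    g_total = child.shape[0]
    n_runs = run_src.shape[0]
    for g in range(g_total):
        for r in range(n_runs):
            s = run_src[r]
            t = run_tgt[r]
            for j in range(run_len[r]):
                final[g, t + j] = child[g, s + j]


class _Engine:
    #: generations between fixed/lost-column sweeps (1 = every generation;
    #: larger values trade dead-column ballast for fewer sweeps, which
    #: benchmarks slower here). A column fixed since the last sweep is
    #: simply an alt-fixed site until the sweep redefines ancestral state.
    PRUNE_EVERY = 1

    def __init__(self, model: DemographyModel, total_bp: int, rng: np.random.Generator):
        self.model = model
        self.total_bp = total_bp
        self.rng = rng
        self.layout = model.layout
        self.chrom_lefts = np.concatenate([[0.0], self.layout.boundaries[:-1]])
        self.mut_rate = model.mu * total_bp
        self.rec_rate = model.recomb_rate * total_bp
        self.haps = np.zeros((0, 0), dtype=np.uint8)  # padded width
        self.k = 0  # logical number of segregating columns
        self.site_u = np.zeros(0, dtype=np.float64)
        self.offsets: dict[str, tuple[int, int]] = {}  # pop -> (row offset, N diploids)

    # -- per generation ----------------------------------------------------
    def step(self, t_child: int) -> None:
        model = self.model
        rng = self.rng
        child_specs = [
            (p, p.ne_at(t_child)) for p in model.populations if p.exists_at(t_child)
        ]
        pop_names = [p.name for p, _ in child_specs]
        pop_off = np.asarray(
            [self.offsets.get(n, (0, 0))[0] for n in pop_names], dtype=np.int64
        )
        pop_n = np.asarray(
            [self.offsets.get(n, (0, 0))[1] for n in pop_names], dtype=np.int64
        )
        new_offsets: dict[str, tuple[int, int]] = {}
        row = 0
        rows_a_parts: list[np.ndarray] = []
        rows_b_parts: list[np.ndarray] = []
        for pi, (p, n_child) in enumerate(child_specs):
            new_offsets[p.name] = (row, n_child)
            row += 2 * n_child
            if p.split_time is not None and t_child == p.split_time:
                src = np.full(n_child, pop_names.index(p.source), dtype=np.int64)
            else:
                src = np.full(n_child, pi, dtype=np.int64)
                draws = rng.random(n_child)
                acc = 0.0
                for (dest, origin), rate in model.migration.items():
                    if dest != p.name or origin not in self.offsets:
                        continue
                    src[(draws >= acc) & (draws < acc + rate)] = pop_names.index(origin)
                    acc += rate
            src_off = pop_off[src]
            src_n = pop_n[src]
            p1 = rng.integers(0, src_n)
            selfed = rng.random(n_child) < p.selfing_rate
            p2 = np.where(selfed, p1, rng.integers(0, src_n))
            # interleave the two gametes of each offspring: rows 2i, 2i+1
            ra = np.empty(2 * n_child, dtype=np.int64)
            rb = np.empty(2 * n_child, dtype=np.int64)
            ra[0::2] = src_off + 2 * p1
            rb[0::2] = src_off + 2 * p1 + 1
            ra[1::2] = src_off + 2 * p2
            rb[1::2] = src_off + 2 * p2 + 1
            rows_a_parts.append(ra)
            rows_b_parts.append(rb)
        rows_a = np.concatenate(rows_a_parts)
        rows_b = np.concatenate(rows_b_parts)
        g_total = rows_a.size
        k = self.k

        # crossovers, per-chromosome starting phases, mutations
        n_cross = rng.poisson(self.rec_rate, g_total)
        total_cross = int(n_cross.sum())
        cross_u = rng.random(total_cross)
        coins = rng.integers(0, 2, (g_total, self.layout.n_chroms), dtype=np.uint8)
        n_mut = rng.poisson(self.mut_rate, g_total)
        total_mut = int(n_mut.sum())
        mut_u = rng.random(total_mut)
        mut_owner = np.repeat(np.arange(g_total), n_mut)
        mut_order = np.argsort(mut_u, kind="stable")
        new_u = mut_u[mut_order]
        new_owner = mut_owner[mut_order]

        if k > 0:
            cross_owner = np.repeat(np.arange(g_total), n_cross)
            order = np.lexsort((cross_u, cross_owner))
            cross_cols = np.searchsorted(self.site_u, cross_u[order]).astype(np.int64)
            cross_off = np.zeros(g_total + 1, dtype=np.int64)
            np.cumsum(n_cross, out=cross_off[1:])
            chrom_col_start = np.empty(self.layout.n_chroms + 1, dtype=np.int64)
            chrom_col_start[:-1] = np.searchsorted(self.site_u, self.chrom_lefts)
            chrom_col_start[-1] = k
            child = np.empty((g_total, _pad8(k)), dtype=np.uint8)
            _copy_gametes(
                self.haps, self.haps.view(np.uint64), child, child.view(np.uint64),
                rows_a, rows_b, coins, cross_cols, cross_off, chrom_col_start,
            )
            if t_child % self.PRUNE_EVERY == 0:
                colsum = np.empty(k, dtype=np.int64)
                _colsum(child, k, colsum)
                kept = np.flatnonzero((colsum > 0) & (colsum < g_total))
            else:
                kept = np.arange(k, dtype=np.int64)
        else:
            child = np.zeros((g_total, 0), dtype=np.uint8)
            kept = np.zeros(0, dtype=np.int64)

        # merge kept columns with the new (sorted) mutations
        k_keep = kept.size
        k_new = k_keep + total_mut
        kept_u = self.site_u[kept]
        shift = np.searchsorted(new_u, kept_u)  # new muts preceding each kept col
        tgt = np.arange(k_keep, dtype=np.int64) + shift
        tgt_new = np.arange(total_mut, dtype=np.int64) + np.searchsorted(
            kept_u, new_u, side="right"
        )
        final = np.zeros((g_total, _pad8(k_new)), dtype=np.uint8)
        if k_keep:
            # maximal runs where both source and target advance by one
            brk = np.flatnonzero((np.diff(kept) != 1) | (np.diff(tgt) != 1))
            starts = np.concatenate([[0], brk + 1])
            ends = np.concatenate([brk + 1, [k_keep]])
            _scatter_runs(
                child, final, kept[starts], tgt[starts], (ends - starts).astype(np.int64)
            )
        if total_mut:
            final[new_owner, tgt_new] = 1
        merged_u = np.empty(k_new, dtype=np.float64)
        merged_u[tgt] = kept_u
        merged_u[tgt_new] = new_u
        self.haps = final
        self.k = k_new
        self.site_u = merged_u
        self.offsets = new_offsets


def simulate_wf(
    model: DemographyModel,
    total_bp: int,
    n_sample: dict[str, int],
    seed: int,
    burnin_factor: int = 10,
) -> SimResult:
    """Run the forward simulation and sample diploid individuals at present.

    ``n_sample`` maps population name to the number of diploids drawn
    without replacement at generation 0. Burn-in lasts
    ``burnin_factor * max(Ne)`` generations before the oldest demographic
    event.
    """
    theta = 4.0 * model.max_ne() * model.mu
    if theta > MAX_THETA_SITE:
        raise ValueError(
            f"4*Ne*mu = {theta:.3g} per site is too large for infinite-sites "
            f"bookkeeping (max {MAX_THETA_SITE})"
        )
    for name, n in n_sample.items():
        if n > model.pop(name).ne_at(0):
            raise ValueError(
                f"cannot sample {n} diploids from {name} of size {model.pop(name).ne_at(0)}"
            )
    rng = np.random.default_rng(seed)
    eng = _Engine(model, total_bp, rng)
    t_start = int(math.ceil(model.oldest_event_time)) + burnin_factor * model.max_ne()
    row = 0
    for p in model.root_populations():
        n0 = p.ne_at(t_start)
        eng.offsets[p.name] = (row, n0)
        row += 2 * n0
    eng.haps = np.zeros((row, 0), dtype=np.uint8)
    for t_child in range(t_start - 1, -1, -1):
        eng.step(t_child)

    haplotypes: dict[str, np.ndarray] = {}
    for name, n in n_sample.items():
        off, pop_n = eng.offsets[name]
        chosen = np.sort(rng.choice(pop_n, size=n, replace=False))
        rows = np.empty(2 * n, dtype=np.int64)
        rows[0::2] = off + 2 * chosen
        rows[1::2] = off + 2 * chosen + 1
        haplotypes[name] = eng.haps[rows, : eng.k]
    # drop columns carrying no derived allele among any sampled haplotype
    if haplotypes:
        union_count = np.zeros(eng.k, dtype=np.int64)
        for h in haplotypes.values():
            union_count += h.sum(axis=0, dtype=np.int64)
        keep = union_count > 0
    else:
        keep = np.zeros(eng.k, dtype=bool)
    haplotypes = {n: np.ascontiguousarray(h[:, keep]) for n, h in haplotypes.items()}
    truth = {
        "seed": seed,
        "total_bp": total_bp,
        "mu": model.mu,
        "recomb_rate": model.recomb_rate,
        "burnin_generations": burnin_factor * model.max_ne(),
        "theta_site": {p.name: model.theta_site(p.name) for p in model.populations},
        "selfing_f": {p.name: model.selfing_f(p.name) for p in model.populations},
        "split_times": {
            p.name: p.split_time for p in model.populations if p.split_time is not None
        },
        "migration": {f"{d}<-{s}": r for (d, s), r in model.migration.items()},
    }
    return SimResult(
        layout=model.layout,
        total_bp=total_bp,
        site_u=eng.site_u[keep],
        haplotypes=haplotypes,
        truth=truth,
    )
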