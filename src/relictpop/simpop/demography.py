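"""Demography and genome-layout definitions for the forward simulator.

All times are in generations before present; epochs are piecewise-constant
diploid population sizes. Rates are per site per generation. Presets are
desk-scaled (small Ne with inflated mu and r, holding 4*Ne*mu and 4*Ne*r
fixed) so that statistical expectations are testable in seconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GenomeLayout",
    "PopulationSpec",
    "DemographyModel",
    "default_layout",
    "single_chrom_layout",
]


@dataclass(frozen=True)
class GenomeLayout:
    """Two-subgenome chromosome layout on a continuous unit line.

    The default layout carries two "At" chromosomes and one "Dt" chromosome
    with total At length ~1.6x the Dt length.
    """

    chrom_names: tuple[str, ...]
    fractions: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.chrom_names) != len(self.fractions):
            raise ValueError("chrom_names and fractions must align")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")

    @property
    def boundaries(self) -> np.ndarray:
        """Right boundaries of each chromosome on [0, 1)."""
        return np.cumsum(np.asarray(self.fractions, dtype=np.float64))

    @property
    def n_chroms(self) -> int:
        return len(self.chrom_names)

    def chrom_lengths_bp(self, total_bp: int) -> dict[str, int]:
        return {
            name: max(1, int(round(frac * total_bp)))
            for name, frac in zip(self.chrom_names, self.fractions)
        }

    def chrom_of(self, u: np.ndarray) -> np.ndarray:
        """Chromosome index for continuous positions u in [0, 1)."""
        return np.searchsorted(self.boundaries, u, side="right").astype(np.int8)

    def subgenome_ratio(self) -> float:
        at = sum(f for n, f in zip(self.chrom_names, self.fractions) if n.startswith("A"))
        dt = sum(f for n, f in zip(self.chrom_names, self.fractions) if n.startswith("D"))
        return at / dt if dt else math.inf


def default_layout() -> GenomeLayout:
    return GenomeLayout(("A01", "A02", "D01"), (0.32, 0.295, 0.385))


def single_chrom_layout(name: str = "A01") -> GenomeLayout:
    """Degenerate one-chromosome layout (handy for fast statistical checks)."""
    return GenomeLayout((name,), (1.0,))


@dataclass
class PopulationSpec:
    """One population: epochs of diploid size, optional founding split.

    ``epochs`` is a list of ``(time_ago, Ne)`` pairs with strictly
    decreasing times toward the present; an entry applies to all
    generations at or below its time until the next entry takes over. Use
    ``None`` as the first time for "since the beginning".
    """

    name: str
    epochs: list[tuple[float | None, int]]
    selfing_rate: float = 0.0
    source: str | None = None
    split_time: int | None = None

    def __post_init__(self) -> None:
        times = [math.inf if t is None else float(t) for t, _ in self.epochs]
        if any(b >= a for a, b in zip(times, times[1:])):
            raise ValueError(f"{self.name}: epoch times must strictly decrease")
        if any(ne < 2 for _, ne in self.epochs):
            raise ValueError(f"{self.name}: Ne must be >= 2")
        if not (0.0 <= self.selfing_rate <= 1.0):
            raise ValueError(f"{self.name}: selfing_rate must be in [0, 1]")
        if (self.source is None) != (self.split_time is None):
            raise ValueError(f"{self.name}: source and split_time go together")
        self._times = times

    def exists_at(self, t_ago: int) -> bool:
        return self.split_time is None or t_ago <= self.split_time

    def ne_at(self, t_ago: int) -> int:
        # epochs are ordered past -> present; the last entry whose start
        # time is still >= t_ago wins
        chosen = self.epochs[0][1]
        for t_from, (_, ne) in zip(self._times, self.epochs):
            if t_from >= t_ago:
                chosen = ne
        return chosen

    @property
    def oldest_time(self) -> float:
        times = [t for t in self._times if math.isfinite(t)]
        if self.split_time is not None:
            times.append(float(self.split_time))
        return max(times) if times else 0.0


@dataclass
class DemographyModel:
    """Multi-population piecewise-constant demography with splits,
    migration, and partial selfing."""

    populations: list[PopulationSpec]
    migration: dict[tuple[str, str], float] = field(default_factory=dict)  # (dest, source) -> rate
    mu: float = 2.5e-5
    recomb_rate: float = 2.5e-5
    generation_time: float = 1.0
    layout: GenomeLayout = field(default_factory=default_layout)

    def __post_init__(self) -> None:
        names = [p.name for p in self.populations]
        if len(set(names)) != len(names):
            raise ValueError("duplicate population names")
        known = set(names)
        for p in self.populations:
            if p.source is not None and p.source not in known:
                raise ValueError(f"{p.name}: unknown source {p.source!r}")
        for (dest, src), rate in self.migration.items():
            if dest not in known or src not in known:
                raise ValueError(f"migration references unknown population ({dest}, {src})")
            if not (0.0 <= rate <= 1.0):
                raise ValueError("migration rates must be in [0, 1]")
        if not (0.0 <= self.mu <= 1.0 and 0.0 <= self.recomb_rate <= 1.0):
            raise ValueError("mu and recomb_rate must be in [0, 1]")

    def pop(self, name: str) -> PopulationSpec:
        for p in self.populations:
            if p.name == name:
                return p
        raise KeyError(name)

    def root_populations(self) -> list[PopulationSpec]:
        return [p for p in self.populations if p.split_time is None]

    @property
    def oldest_event_time(self) -> float:
        return max((p.oldest_time for p in self.populations), default=0.0)

    def max_ne(self) -> int:
        return max(ne for p in self.populations for _, ne in p.epochs)

    def theta_site(self, name: str) -> float:
        """4 * Ne(present) * mu for one population."""
        return 4.0 * self.pop(name).ne_at(0) * self.mu

    def selfing_f(self, name: str) -> float:
        """Equilibrium inbreeding coefficient s / (2 - s)."""
        s = self.pop(name).selfing_rate
        return s / (2.0 - s)
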