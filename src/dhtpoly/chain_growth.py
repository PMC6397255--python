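"""Stochastic simulation of initiator-triggered living chain-growth
copolymerization of A/B hairpin tiles, plus an initiator-free thermal
step-growth control.

Model
-----
Living modes treat one A-B repeat unit as the propagation step: an active
terminus regenerates the same 6-nt invading segment after every A-B addition,
so alternation is exact by construction and each chain is I-[A-B]_k.  Because
the initiator's active segment is sequence-identical to the segment exposed by
an opened B hairpin, initiation and propagation share the same toehold
kinetics; in the fast-mixing (``ideal``) limit every repeat unit therefore
lands on a uniformly random initiator site and the per-site unit count is
multinomial — Poisson([M]0/[I]0) as the site count grows.  The ``kinetic``
mode runs the same chemistry as an exact Gillespie simulation with explicit
rate constants.

The ``thermal`` mode is the no-initiator control: step-growth condensation at
extent of reaction p, giving the Flory most-probable (geometric) tile-count
distribution with PDI -> 1 + p.

Concentrations enter only through the monomer-to-initiator ratio; volume is
implicit and counts are anchored by ``n_initiators`` (living) or
``n_monomer_units`` (thermal).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Optional

import numpy as np

__all__ = [
    "SimParams",
    "ChainState",
    "PopulationState",
    "simulate_living",
    "simulate_thermal",
    "extend_population",
    "chain_contour_lengths",
    "unit_counts",
    "tile_counts",
]

Mode = Literal["ideal", "kinetic", "thermal"]


@dataclass
class SimParams:
    """Simulation conditions.

    ratio_MI is [M]0/[I]0 with [A]0 = [B]0 = [M]0 (the paper's convention);
    if omitted it is derived from the concentrations.  Rate constants only
    matter in kinetic mode and default to equal initiation and propagation
    kinetics (the initiator's invading segment is sequence-identical to the
    propagating one).
    """

    monomer_conc_A: float = 1.0      # uM
    monomer_conc_B: float = 1.0      # uM
    initiator_conc: Optional[float] = None  # uM
    ratio_MI: Optional[float] = None
    n_initiators: int = 10_000
    mode: Mode = "ideal"
    k_init: float = 1.0
    k_prop: float = 1.0
    conversion_p: Optional[float] = None
    n_monomer_units: int = 100_000
    seed: Optional[int] = None

    def resolved_ratio(self) -> float:
        if self.ratio_MI is not None:
            r = float(self.ratio_MI)
        else:
            if self.initiator_conc is None or self.initiator_conc <= 0:
                raise ValueError("need ratio_MI or a positive initiator_conc")
            r = self.monomer_conc_A / self.initiator_conc
        if r < 0:
            raise ValueError("ratio_MI must be >= 0")
        return r

    def validate(self) -> None:
        if self.monomer_conc_A < 0 or self.monomer_conc_B < 0:
            raise ValueError("concentrations must be >= 0")
        if self.mode in ("ideal", "kinetic"):
            if self.n_initiators < 1:
                raise ValueError("no active sites: n_initiators must be >= 1")
            self.resolved_ratio()
        elif self.mode == "thermal":
            if self.conversion_p is None:
                raise ValueError("thermal mode requires conversion_p")
            if not (0.0 <= self.conversion_p < 1.0):
                raise ValueError("conversion_p must satisfy 0 <= p < 1")
        else:
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class ChainState:
    """One polymer chain.

    Living chains are I-[A-B]_k (n_tiles = 2k, even, active terminus expecting
    the next A).  Thermal chains alternate starting from A with any parity and
    have no active terminus.
    """

    n_tiles: int
    active_terminus: Literal["expects_A", "expects_B", "none"] = "expects_A"

    @property
    def n_A(self) -> int:
        return (self.n_tiles + 1) // 2

    @property
    def n_B(self) -> int:
        return self.n_tiles // 2

    @property
    def n_units(self) -> int:
        """Complete A-B repeat units."""
        return self.n_tiles // 2

    @property
    def sequence(self) -> list[str]:
        return ["A", "B"][: 2] * (self.n_tiles // 2) + (
            ["A"] if self.n_tiles % 2 else []
        )

    @classmethod
    def from_sequence(cls, tiles: list[str],
                      active_terminus: str = "none") -> "ChainState":
        for i, t in enumerate(tiles):
            expected = "A" if i % 2 == 0 else "B"
            if t != expected:
                raise ValueError("chain must strictly alternate starting with A")
        return cls(n_tiles=len(tiles), active_terminus=active_terminus)


@dataclass
class PopulationState:
    """Free species counts plus the chain population of one simulation run."""

    free_A: int
    free_B: int
    free_I: int
    chains: list[ChainState]
    rng_state: Optional[dict] = None
    mode: Mode = "ideal"
    meta: dict = field(default_factory=dict)

    def total_A(self) -> int:
        return self.free_A + sum(c.n_A for c in self.chains)

    def total_B(self) -> int:
        return self.free_B + sum(c.n_B for c in self.chains)

    def total_I(self) -> int:
        living = 0 if self.mode == "thermal" else len(self.chains)
        return self.free_I + living

    def assert_mass_conserved(self) -> None:
        m = self.meta
        for key, total in (("total_A", self.total_A()),
                           ("total_B", self.total_B()),
                           ("total_I", self.total_I())):
            if key in m and m[key] != total:
                raise AssertionError(
                    f"mass conservation violated for {key}: "
                    f"{total} != {m[key]}"
                )


def _finish(pop: PopulationState, rng: np.random.Generator) -> PopulationState:
    pop.rng_state = rng.bit_generator.state
    pop.assert_mass_conserved()
    return pop


def simulate_living(params: SimParams) -> PopulationState:
    """Run living copolymerization to monomer exhaustion.

    ideal: each A-B repeat unit is assigned to a uniformly random initiator
    site (exact multinomial form of the fast-mixing limit).  Sites left with
    zero units remain free initiators.

    kinetic: exact stochastic simulation over
    I + A(-B) -> I-[A-B]* (k_init) and chain* + A(-B) -> chain* (k_prop).
    """
    params.validate()
    if params.mode not in ("ideal", "kinetic"):
        raise ValueError("simulate_living requires mode 'ideal' or 'kinetic'")
    rng = np.random.default_rng(params.seed)
    n = params.n_initiators
    ratio = params.resolved_ratio()
    total_units = int(round(ratio * n))

    if params.mode == "ideal":
        if total_units == 0:
            pop = PopulationState(
                free_A=0, free_B=0, free_I=n, chains=[], mode="ideal",
                meta={"ratio_MI": ratio, "n_initiators": n,
                      "total_A": 0, "total_B": 0, "total_I": n,
                      "seed": params.seed},
            )
            return _finish(pop, rng)
        units = rng.multinomial(total_units, np.full(n, 1.0 / n))
        chains = [ChainState(2 * int(k), "expects_A") for k in units if k > 0]
        free_I = int(np.count_nonzero(units == 0))
    else:
        chains_units: list[int] = []
        free_I = n
        free_units = total_units
        t = 0.0
        while free_units > 0:
            a_init = params.k_init * free_I * free_units
            a_prop = params.k_prop * len(chains_units) * free_units
            a_tot = a_init + a_prop
            if a_tot <= 0:
                break  # no active sites left: leftover monomer stays free
            t += rng.exponential(1.0 / a_tot)
            if rng.random() * a_tot < a_init:
                free_I -= 1
                chains_units.append(1)
            else:
                chains_units[int(rng.integers(len(chains_units)))] += 1
            free_units -= 1
        chains = [ChainState(2 * k, "expects_A") for k in chains_units]

    used_units = sum(c.n_units for c in chains)
    leftover = total_units - used_units
    pop = PopulationState(
        free_A=leftover, free_B=leftover, free_I=free_I, chains=chains,
        mode=params.mode,
        meta={"ratio_MI": ratio, "n_initiators": n,
              "total_A": total_units, "total_B": total_units, "total_I": n,
              "seed": params.seed},
    )
    return _finish(pop, rng)


def simulate_thermal(params: SimParams) -> PopulationState:
    """Initiator-free step-growth condensation at extent of reaction p.

    Chain tile counts follow the Flory most-probable (geometric) distribution
    with mean 1/(1-p); chains are drawn until the monomer budget
    ``n_monomer_units`` is spent (the final chain may overshoot by its tail,
    which is the cost of exact mass bookkeeping on discrete draws).
    """
    params.validate()
    if params.mode != "thermal":
        raise ValueError("simulate_thermal requires mode 'thermal'")
    p = float(params.conversion_p)
    rng = np.random.default_rng(params.seed)
    sizes: list[int] = []
    remaining = params.n_monomer_units
    if p == 0.0:
        sizes = [1] * remaining
        remaining = 0
    else:
        while remaining > 0:
            batch = rng.geometric(1.0 - p, size=max(16, remaining // max(1, int(1 / (1 - p)))))
            for s in batch:
                sizes.append(int(s))
                remaining -= int(s)
                if remaining <= 0:
                    break
    n_A = sum((s + 1) // 2 for s in sizes)
    n_B = sum(s // 2 for s in sizes)
    pop = PopulationState(
        free_A=0, free_B=0, free_I=0,
        chains=[ChainState(s, "none") for s in sizes],
        mode="thermal",
        meta={"conversion_p": p, "n_monomer_units": params.n_monomer_units,
              "total_A": n_A, "total_B": n_B, "total_I": 0,
              "seed": params.seed},
    )
    return _finish(pop, rng)


def extend_population(
    pop: PopulationState,
    added_A: int,
    added_B: int,
    seed: Optional[int] = None,
) -> PopulationState:
    """Stepwise monomer re-feeding: growth resumes on existing chains only.

    Returns a new PopulationState; the input is not mutated.  Chain count is
    unchanged (the living-restart contract); added monomers beyond complete
    A-B pairs stay in the free pools.
    """
    if added_A < 0 or added_B < 0:
        raise ValueError("added monomer counts must be >= 0")
    if pop.mode == "thermal" or not all(
        c.active_terminus != "none" for c in pop.chains
    ):
        raise ValueError("no active termini: population is not living")
    if seed is not None:
        rng = np.random.default_rng(seed)
    elif pop.rng_state is not None:
        rng = np.random.default_rng(0)
        rng.bit_generator.state = pop.rng_state
    else:
        rng = np.random.default_rng()

    pool_A = pop.free_A + added_A
    pool_B = pop.free_B + added_B
    new_units = min(pool_A, pool_B)
    chains = [replace(c) for c in pop.chains]
    if new_units > 0 and chains:
        add = rng.multinomial(new_units, np.full(len(chains), 1.0 / len(chains)))
        for c, k in zip(chains, add):
            c.n_tiles += 2 * int(k)
    consumed = new_units if chains else 0
    meta = dict(pop.meta)
    meta["total_A"] = meta.get("total_A", 0) + added_A
    meta["total_B"] = meta.get("total_B", 0) + added_B
    meta["cumulative_ratio"] = meta["total_A"] / max(1, meta.get("n_initiators", 1))
    out = PopulationState(
        free_A=pool_A - consumed,
        free_B=pool_B - consumed,
        free_I=pop.free_I,
        chains=chains,
        mode=pop.mode,
        meta=meta,
    )
    return _finish(out, rng)


def chain_contour_lengths(
    pop: PopulationState,
    tile_length_nm: float = 16.0,
    initiator_length_nm: float = 0.0,
) -> np.ndarray:
    """Per-chain contour length in nm: n_tiles x tile length (+ optional
    initiator contribution, 0 by default)."""
    if tile_length_nm <= 0:
        raise ValueError("tile_length_nm must be > 0")
    return np.array(
        [c.n_tiles * tile_length_nm + initiator_length_nm for c in pop.chains],
        dtype=float,
    )


def unit_counts(pop: PopulationState, include_uninitiated: bool = False) -> np.ndarray:
    """A-B repeat units per chain; optionally append the zero counts of
    never-initiated initiator sites (for untruncated per-site statistics)."""
    counts = [c.n_units for c in pop.chains]
    if include_uninitiated:
        counts += [0] * pop.free_I
    return np.array(counts, dtype=int)


def tile_counts(pop: PopulationState, include_uninitiated: bool = False) -> np.ndarray:
    counts = [c.n_tiles for c in pop.chains]
    if include_uninitiated:
        counts += [0] * pop.free_I
    return np.array(counts, dtype=int)
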