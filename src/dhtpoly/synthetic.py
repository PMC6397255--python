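"""Synthetic fixtures for every pipeline stage: constraint-satisfying tile
strand sets, AFM-style noisy length samples, and photobleaching trace batches.

The tile generator builds an (A, B, I) reaction system around the four 6-nt
segments that define the activation chemistry — TGTCAC (A's toehold), TGAACC
(A's hairpin loop), GGTTCA (B's toehold) and GTGACA (B's exposed segment and
the initiator's 3' active segment) — filling the remaining bases randomly
under two constraints: none of the four segments (which are two
reverse-complement couples) may recur anywhere else, and repeated words are
greedily avoided (sequence-symmetry minimization).  Every generated system
passes validation and closes the activation cascade by construction.

AFM length emulation adds Gaussian measurement noise and an additive tip
broadening to the true contour lengths and drops objects below a detection
floor.  The noise defaults (8 nm sd, 10 nm floor) are plausible
instrument-scale package defaults, not measured values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import photobleach
from .chain_growth import PopulationState, chain_contour_lengths
from .dispersity import LengthSample
from .photobleach import Trace
from .tile_model import (
    DomainAnnotation,
    ReactionSystem,
    StickyPair,
    StrandSpec,
    TileSpec,
    reverse_complement,
    symmetry_score,
)

__all__ = [
    "NoiseModel",
    "generate_tile_set",
    "gen_afm_lengths",
    "gen_trace_batch",
    "PRINTED_SEGMENTS",
]

# the four printed activation segments and their roles
PRINTED_SEGMENTS = {
    "A_toehold": "TGTCAC",
    "A_loop": "TGAACC",
    "B_toehold": "GGTTCA",
    "B_loop": "GTGACA",
}

_BASES = "ACGT"


@dataclass(frozen=True)
class NoiseModel:
    """AFM-style measurement model for contour lengths (nm)."""

    length_noise_sd: float = 8.0
    min_detectable_nm: float = 10.0
    tip_broadening_nm: float = 0.0

    def __post_init__(self) -> None:
        if self.length_noise_sd < 0 or self.min_detectable_nm < 0:
            raise ValueError("noise sd and detection floor must be >= 0")


def _forbidden_words() -> list[str]:
    words = set(PRINTED_SEGMENTS.values())
    words |= {reverse_complement(w) for w in words}
    return sorted(words)


def _random_filler(
    rng: np.random.Generator,
    length: int,
    context: str,
    forbidden: Sequence[str],
    n_candidates: int = 8,
) -> str:
    """Random filler that never creates a forbidden 6-mer (checked with local
    context across junctions) and greedily minimizes repeated 6-mers."""
    if length == 0:
        return ""
    best, best_score = None, None
    for _ in range(200):
        cand = "".join(rng.choice(list(_BASES), size=length))
        probe = context[-5:] + cand if context else cand
        if any(w in probe or w in cand for w in forbidden):
            continue
        score = symmetry_score(context + cand, k=6) if len(context + cand) >= 6 else 0
        if best is None or score < best_score:
            best, best_score = cand, score
            n_candidates -= 1
            if n_candidates <= 0:
                break
    if best is None:
        raise RuntimeError("could not sample filler under segment constraints")
    return best


def _segment_counts_ok(system: ReactionSystem) -> bool:
    """Each reserved 6-mer must occur exactly in its designated role and
    nowhere else across the whole strand set (GTGACA twice: B's loop and the
    initiator's active segment)."""
    expected = {"TGTCAC": 1, "TGAACC": 1, "GGTTCA": 1, "GTGACA": 2}
    seqs = [s.sequence for t in system.tiles.values() for s in t.strands]
    if system.initiator is not None:
        seqs.append(system.initiator.sequence)
    for word, want in expected.items():
        got = sum(seq.count(word) for seq in seqs)
        if got != want:
            return False
    return True


def generate_tile_set(
    seed: Optional[int] = None,
    stem_len: int = 8,
    loop_len: int = 6,
    sticky_len: int = 8,
    core_len: int = 16,
    max_attempts: int = 50,
) -> ReactionSystem:
    """Build a validated (A, B, I) reaction system with the printed segments
    in their printed roles.

    Strand architecture per tile X (four strands x1..x4):

    - x1: duplex core (2 x core_len);
    - x2: 5' sticky end + complement of the core's first half;
    - x3: complement of the core's second half + 3' toehold
      (+ a 5' sticky end on b3, which pairs with a4's);
    - x4: 5' sticky end + hairpin (stem, loop, reverse-complement stem).

    Declared inter-tile pairs: a2~b2 and a4~b3.  Reserved segments are kept
    unique by rejection sampling (assembly junctions can recreate one, so
    whole attempts are redrawn until the global count check passes).  Raises
    on infeasible geometry (stem_len < 6 or loop_len < 6).
    """
    if stem_len < 6:
        raise ValueError("stem_len must be >= 6 (hairpin infeasible)")
    if loop_len < 6:
        raise ValueError("loop_len must be >= 6 (printed segment must fit)")
    rng = np.random.default_rng(seed)
    for _ in range(max_attempts):
        system = _generate_once(rng, stem_len, loop_len, sticky_len, core_len)
        if _segment_counts_ok(system):
            return system
    raise RuntimeError("could not satisfy segment-uniqueness constraints")


def _generate_once(
    rng: np.random.Generator,
    stem_len: int,
    loop_len: int,
    sticky_len: int,
    core_len: int,
) -> ReactionSystem:
    forbidden = _forbidden_words()

    built = ""  # running context for symmetry minimization

    def filler(n: int) -> str:
        nonlocal built
        s = _random_filler(rng, n, built, forbidden)
        built += s
        return s

    def checked(seq: str) -> str:
        nonlocal built
        built += seq
        return seq

    tiles: dict[str, TileSpec] = {}
    sticky_a2 = filler(sticky_len)
    sticky_a4 = filler(sticky_len)
    sticky_b2 = reverse_complement(sticky_a2)
    sticky_b3 = reverse_complement(sticky_a4)

    for tid, prefix in (("A", "a"), ("B", "b")):
        toehold = PRINTED_SEGMENTS[f"{tid}_toehold"]
        loop_seed = PRINTED_SEGMENTS[f"{tid}_loop"]
        core = filler(2 * core_len)
        stem = filler(stem_len)
        loop = checked(loop_seed) + filler(loop_len - 6)

        s1 = StrandSpec(f"{prefix}1", core,
                        labels={"5p": "biotin"} if tid == "A" else {})
        s2_seq = (sticky_a2 if tid == "A" else sticky_b2) + reverse_complement(
            core[:core_len]
        )
        s2 = StrandSpec(f"{prefix}2", s2_seq)
        s3_sticky = "" if tid == "A" else sticky_b3
        s3_seq = s3_sticky + reverse_complement(core[core_len:]) + checked(toehold)
        s3 = StrandSpec(f"{prefix}3", s3_seq)
        s4_sticky = sticky_a4 if tid == "A" else filler(sticky_len)
        s4_seq = s4_sticky + stem + loop + reverse_complement(stem)
        s4 = StrandSpec(f"{prefix}4", s4_seq)

        off3 = len(s3_sticky)
        domains = [
            DomainAnnotation(f"{prefix}1", 0, 2 * core_len, "core"),
            DomainAnnotation(f"{prefix}2", 0, sticky_len, "sticky_end"),
            DomainAnnotation(f"{prefix}2", sticky_len, sticky_len + core_len, "core"),
            DomainAnnotation(f"{prefix}3", off3, off3 + core_len, "core"),
            DomainAnnotation(f"{prefix}3", off3 + core_len,
                             off3 + core_len + 6, "toehold"),
            DomainAnnotation(f"{prefix}4", 0, sticky_len, "sticky_end"),
            DomainAnnotation(f"{prefix}4", sticky_len, sticky_len + stem_len, "stem"),
            DomainAnnotation(f"{prefix}4", sticky_len + stem_len,
                             sticky_len + stem_len + loop_len, "loop"),
            DomainAnnotation(f"{prefix}4", sticky_len + stem_len + loop_len,
                             sticky_len + 2 * stem_len + loop_len, "stem"),
        ]
        if s3_sticky:
            domains.insert(3, DomainAnnotation(f"{prefix}3", 0, sticky_len,
                                               "sticky_end"))
        sticky_pairs = (
            [StickyPair("a2", "B", "b2"), StickyPair("a4", "B", "b3")]
            if tid == "A"
            else [StickyPair("b2", "A", "a2"), StickyPair("b3", "A", "a4")]
        )
        tiles[tid] = TileSpec(
            tile_id=tid,
            strands=[s1, s2, s3, s4],
            domains=domains,
            sticky_pairs=sticky_pairs,
            crossover_separation_nt=26,
            tile_length_bp=47,
        )

    # initiator: random 5' tail + the active segment (identical to B's loop
    # segment, hence complementary to A's toehold) at the 3' end
    initiator_seq = filler(10) + checked(PRINTED_SEGMENTS["B_loop"])
    initiator = StrandSpec("I", initiator_seq, labels={})
    return ReactionSystem(tiles=tiles, initiator=initiator)


def gen_afm_lengths(
    pop: PopulationState,
    noise: NoiseModel = NoiseModel(),
    tile_length_nm: float = 16.0,
    seed: Optional[int] = None,
) -> tuple[LengthSample, int]:
    """AFM-style contour-length sample from a simulated population.

    Returns (sample, n_dropped): true lengths + Gaussian noise + tip
    broadening, with objects below the detection floor dropped and counted.
    """
    if not pop.chains:
        raise ValueError("population has no chains")
    rng = np.random.default_rng(seed)
    true = chain_contour_lengths(pop, tile_length_nm)
    measured = true + noise.tip_broadening_nm
    if noise.length_noise_sd > 0:
        measured = measured + rng.normal(0.0, noise.length_noise_sd, size=true.size)
    keep = measured >= max(noise.min_detectable_nm, np.nextafter(0, 1))
    n_dropped = int((~keep).sum())
    if not keep.any():
        raise ValueError("no objects above the detection floor")
    return LengthSample(measured[keep]), n_dropped


def gen_trace_batch(
    pop: PopulationState,
    step_height: float = 1.0,
    noise_sd: float = 0.2,
    mean_dwell_s: float = 3.0,
    duration_s: float = 80.0,
    frame_rate_hz: float = photobleach.DEFAULT_FRAME_RATE_HZ,
    seed: Optional[int] = None,
    max_traces: Optional[int] = None,
) -> list[Trace]:
    """One photobleaching trace per chain, with the true step count equal to
    the chain's number of Cy3-carrying (A) tiles."""
    if not pop.chains:
        raise ValueError("population has no chains")
    ss = np.random.SeedSequence(seed)
    chains = pop.chains if max_traces is None else pop.chains[:max_traces]
    child_seeds = ss.generate_state(len(chains)) % (2**31)
    return [
        photobleach.synthesize_trace(
            n_steps=c.n_A,
            step_height=step_height,
            noise_sd=noise_sd,
            mean_dwell_s=mean_dwell_s,
            duration_s=duration_s,
            frame_rate_hz=frame_rate_hz,
            seed=int(s),
        )
        for c, s in zip(chains, child_seeds)
    ]
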