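"""DNA hairpin-tile (DHT) monomers and the strand-displacement activation cascade.

A DHT is a double-crossover (DX) motif assembled from four single strands.  One
strand carries a closed hairpin (stem + loop) whose sticky end doubles as a
toehold; the tile is metastable until an invading segment opens the hairpin by
toehold-mediated strand displacement (SDR).  An initiator strand I opens the
first tile, each opened loop invades the next tile's toehold, and the cascade
closes when the last exposed segment is sequence-identical to the initiator's
active segment — this is the topological basis of initiator-triggered
chain growth.

Coordinates are 0-based half-open intervals on strands; sequences are stored
5'->3'.  Hairpin openability is a topological flag tracked by the cascade, not
a free-energy computation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional

__all__ = [
    "DNA_ALPHABET",
    "StrandSpec",
    "DomainAnnotation",
    "StickyPair",
    "TileSpec",
    "HelixGeometry",
    "ReactionSystem",
    "ActivationEvent",
    "Violation",
    "reverse_complement",
    "validate_tile",
    "validate_system",
    "sdr_cascade",
    "crossover_turns_and_side",
    "tile_dimensions",
    "symmetry_score",
]

DNA_ALPHABET = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

DomainRole = Literal["core", "sticky_end", "stem", "loop", "toehold"]
LabelKind = Literal["biotin", "Cy3", "Cy5"]


def reverse_complement(seq: str) -> str:
    """Watson–Crick reverse complement of a 5'->3' DNA string (returned 5'->3').

    Raises ValueError on any character outside {A, C, G, T}.
    """
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise ValueError(f"non-DNA characters in sequence: {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class StrandSpec:
    """A single DNA strand, 5'->3', with optional end labels.

    labels maps an end ("5p" or "3p") to one of biotin / Cy3 / Cy5; at most one
    label per end.
    """

    name: str
    sequence: str
    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"strand {self.name!r}: empty sequence")
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise ValueError(
                f"strand {self.name!r}: non-DNA characters {sorted(bad)}"
            )
        for end in self.labels:
            if end not in ("5p", "3p"):
                raise ValueError(f"strand {self.name!r}: bad label end {end!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DomainAnnotation:
    """A functional interval [start, end) on a named strand."""

    strand: str
    start: int
    end: int
    role: DomainRole

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"domain on {self.strand!r}: bad interval [{self.start}, {self.end})"
            )

    def slice_of(self, strand: StrandSpec) -> str:
        if self.end > len(strand):
            raise ValueError(
                f"domain [{self.start}, {self.end}) exceeds strand "
                f"{strand.name!r} of length {len(strand)}"
            )
        return strand.sequence[self.start : self.end]


@dataclass(frozen=True)
class StickyPair:
    """A declared inter-tile complementary sticky-end pair.

    Each side names the strand carrying the sticky end (located through that
    strand's sticky_end annotation).
    """

    strand: str
    partner_tile: str
    partner_strand: str


@dataclass
class TileSpec:
    """A DHT monomer: exactly four annotated strands plus design metadata."""

    tile_id: str
    strands: list[StrandSpec]
    domains: list[DomainAnnotation]
    sticky_pairs: list[StickyPair] = field(default_factory=list)
    crossover_separation_nt: int = 26
    tile_length_bp: int = 47

    def strand(self, name: str) -> StrandSpec:
        for s in self.strands:
            if s.name == name:
                return s
        raise KeyError(f"tile {self.tile_id}: no strand {name!r}")

    def domains_on(self, strand: str, role: Optional[str] = None) -> list[DomainAnnotation]:
        return [
            d
            for d in self.domains
            if d.strand == strand and (role is None or d.role == role)
        ]

    def domains_with_role(self, role: str) -> list[DomainAnnotation]:
        return [d for d in self.domains if d.role == role]

    @property
    def toehold_seq(self) -> str:
        doms = self.domains_with_role("toehold")
        if not doms:
            raise ValueError(f"tile {self.tile_id}: no toehold annotated")
        return doms[0].slice_of(self.strand(doms[0].strand))

    @property
    def loop_seq(self) -> str:
        doms = self.domains_with_role("loop")
        if not doms:
            raise ValueError(f"tile {self.tile_id}: no loop annotated")
        return doms[0].slice_of(self.strand(doms[0].strand))


@dataclass(frozen=True)
class HelixGeometry:
    """B-form helix geometry used throughout."""

    rise_nm_per_bp: float = 0.34
    diameter_nm: float = 2.25
    bp_per_turn: float = 10.5
    interhelix_gap_nm: float = 0.5

    def __post_init__(self) -> None:
        for name in ("rise_nm_per_bp", "diameter_nm", "bp_per_turn"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class ReactionSystem:
    """Tiles plus (optional) initiator; activation edges derive from sequences."""

    tiles: dict[str, TileSpec]
    initiator: Optional[StrandSpec] = None

    def initiator_active_segment(self, length: int = 6) -> str:
        if self.initiator is None:
            raise ValueError("system has no initiator")
        return self.initiator.sequence[-length:]

    def activation_edges(self) -> list[tuple[str, str]]:
        """Directed edges (source, target): source's exposed segment can invade
        target's toehold.  Sources are 'I' and every tile (via its loop)."""
        edges: list[tuple[str, str]] = []
        sources: list[tuple[str, str]] = []
        if self.initiator is not None:
            sources.append(("I", self.initiator.sequence))
        for tid, tile in self.tiles.items():
            sources.append((tid, tile.loop_seq))
        for src, seq in sources:
            for tid, tile in self.tiles.items():
                if src == tid:
                    continue
                if reverse_complement(tile.toehold_seq) in seq:
                    edges.append((src, tid))
        return edges


@dataclass(frozen=True)
class ActivationEvent:
    """One SDR step of the cascade."""

    step: int
    invader: str          # "I" or a tile id
    segment: str          # the invading segment (complement of the toehold)
    target: str           # tile whose hairpin is opened / re-targeted
    toehold: str          # the target's toehold sequence
    closes_cycle: bool = False


@dataclass(frozen=True)
class Violation:
    rule: str
    tile_id: str
    location: str
    message: str


def _check_domains(tile: TileSpec, out: list[Violation]) -> None:
    by_strand: dict[str, list[DomainAnnotation]] = {}
    strand_names = {s.name for s in tile.strands}
    for d in tile.domains:
        if d.strand not in strand_names:
            out.append(
                Violation("unknown_strand", tile.tile_id, d.strand,
                          f"domain references unknown strand {d.strand!r}")
            )
            continue
        strand = tile.strand(d.strand)
        if d.end > len(strand):
            out.append(
                Violation("domain_out_of_bounds", tile.tile_id,
                          f"{d.strand}[{d.start}:{d.end}]",
                          "interval exceeds strand length")
            )
            continue
        by_strand.setdefault(d.strand, []).append(d)
    for name, doms in by_strand.items():
        doms = sorted(doms, key=lambda d: d.start)
        for a, b in zip(doms, doms[1:]):
            if b.start < a.end:
                out.append(
                    Violation("domain_overlap", tile.tile_id,
                              f"{name}[{b.start}:{b.end}]",
                              f"overlaps [{a.start}:{a.end})")
                )


def _sticky_seq(tile: TileSpec, strand: str) -> Optional[str]:
    doms = tile.domains_on(strand, "sticky_end")
    if not doms:
        return None
    return doms[0].slice_of(tile.strand(strand))


def validate_tile(tile: TileSpec, system: Optional[ReactionSystem] = None) -> list[Violation]:
    """Check the structural design rules of one tile.

    Violations are data, not exceptions.  Rules:

    - ``strand_count``: exactly 4 strands.
    - domain bookkeeping (bounds, overlap).
    - ``stem_mismatch``: the two stem halves of the hairpin strand must be
      reverse-complementary.
    - ``sticky_pair_mismatch``: every declared inter-tile sticky pair must be
      reverse-complementary (checked when the partner tile is resolvable
      through *system*; otherwise reported as ``sticky_pair_unresolved``).
    - ``toehold_occluded``: the toehold must stay single-stranded — no other
      strand of the same tile may contain its reverse complement.
    """
    out: list[Violation] = []
    if len(tile.strands) != 4:
        out.append(
            Violation("strand_count", tile.tile_id, "strands",
                      f"expected 4 strands, got {len(tile.strands)}")
        )
    _check_domains(tile, out)

    present = {s.name for s in tile.strands}

    # hairpin stem self-consistency: stems come in complementary pairs per strand
    stems_by_strand: dict[str, list[DomainAnnotation]] = {}
    for d in tile.domains_with_role("stem"):
        if d.strand in present:
            stems_by_strand.setdefault(d.strand, []).append(d)
    for name, stems in stems_by_strand.items():
        stems = sorted(stems, key=lambda d: d.start)
        if len(stems) % 2 != 0:
            out.append(
                Violation("stem_unpaired", tile.tile_id, name,
                          f"odd number of stem domains ({len(stems)})")
            )
            continue
        strand = tile.strand(name)
        half = len(stems) // 2
        for i in range(half):
            a, b = stems[i], stems[-1 - i]
            try:
                sa, sb = a.slice_of(strand), b.slice_of(strand)
            except ValueError:
                continue
            if reverse_complement(sa) != sb:
                out.append(
                    Violation("stem_mismatch", tile.tile_id,
                              f"{name}[{a.start}:{a.end}]~[{b.start}:{b.end}]",
                              "stem halves are not reverse-complementary")
                )

    # sticky pairs
    for pair in tile.sticky_pairs:
        if pair.strand not in present:
            out.append(
                Violation("sticky_pair_unresolved", tile.tile_id, pair.strand,
                          "strand missing from tile")
            )
            continue
        mine = _sticky_seq(tile, pair.strand)
        if mine is None:
            out.append(
                Violation("sticky_pair_unresolved", tile.tile_id, pair.strand,
                          "no sticky_end annotation on strand")
            )
            continue
        if system is None or pair.partner_tile not in system.tiles:
            out.append(
                Violation("sticky_pair_unresolved", tile.tile_id,
                          f"{pair.strand}~{pair.partner_tile}.{pair.partner_strand}",
                          "partner tile not available")
            )
            continue
        partner = system.tiles[pair.partner_tile]
        theirs = _sticky_seq(partner, pair.partner_strand)
        if theirs is None:
            out.append(
                Violation("sticky_pair_unresolved", tile.tile_id,
                          f"{pair.partner_tile}.{pair.partner_strand}",
                          "no sticky_end annotation on partner strand")
            )
            continue
        if reverse_complement(mine) != theirs:
            out.append(
                Violation("sticky_pair_mismatch", tile.tile_id,
                          f"{pair.strand}~{pair.partner_tile}.{pair.partner_strand}",
                          "sticky ends are not reverse-complementary")
            )

    # toehold must remain single-stranded within the tile
    try:
        toe = tile.toehold_seq
    except (ValueError, KeyError):
        toe = None
        out.append(Violation("missing_toehold", tile.tile_id, "domains",
                             "no toehold annotated on a present strand"))
    if toe is not None:
        toe_strand = tile.domains_with_role("toehold")[0].strand
        rc = reverse_complement(toe)
        for s in tile.strands:
            if s.name != toe_strand and rc in s.sequence:
                out.append(
                    Violation("toehold_occluded", tile.tile_id, s.name,
                              "strand contains the toehold's complement")
                )

    if tile.crossover_separation_nt <= 0:
        out.append(
            Violation("crossover_separation", tile.tile_id,
                      "crossover_separation_nt", "must be > 0")
        )
    return out


def validate_system(system: ReactionSystem) -> list[Violation]:
    out: list[Violation] = []
    for tile in system.tiles.values():
        out.extend(validate_tile(tile, system))
    return out


def sdr_cascade(system: ReactionSystem, segment_length: int = 6) -> list[ActivationEvent]:
    """Replay the alternating activation cascade.

    Event 1: the initiator invades the first tile whose toehold it complements,
    opening that tile's hairpin.  Each opened loop then invades the next closed
    tile's toehold.  When an exposed segment targets an already-open tile the
    cascade has closed into a cycle; for the canonical (I, A, B) system the
    closing segment is sequence-identical to the initiator's 3' active
    segment.  A non-closing system returns the maximal prefix; a system
    without an initiator returns no events.
    """
    if not system.tiles:
        raise ValueError("empty reaction system")
    if system.initiator is None:
        return []

    opened: set[str] = set()
    events: list[ActivationEvent] = []
    source_name = "I"
    source_seq = system.initiator.sequence
    step = 0
    while True:
        target = None
        for tid, tile in system.tiles.items():
            if tid in opened:
                continue
            if reverse_complement(tile.toehold_seq) in source_seq:
                target = tile
                break
        if target is not None:
            step += 1
            events.append(
                ActivationEvent(
                    step=step,
                    invader=source_name,
                    segment=reverse_complement(target.toehold_seq),
                    target=target.tile_id,
                    toehold=target.toehold_seq,
                    closes_cycle=False,
                )
            )
            opened.add(target.tile_id)
            source_name = target.tile_id
            source_seq = target.loop_seq
            continue
        # no closed target: does the exposed segment re-target an open tile?
        for tid in opened:
            tile = system.tiles[tid]
            if reverse_complement(tile.toehold_seq) in source_seq:
                step += 1
                events.append(
                    ActivationEvent(
                        step=step,
                        invader=source_name,
                        segment=reverse_complement(tile.toehold_seq),
                        target=tid,
                        toehold=tile.toehold_seq,
                        closes_cycle=True,
                    )
                )
                return events
        return events


def crossover_turns_and_side(
    separation_nt: int, geom: HelixGeometry = HelixGeometry()
) -> tuple[float, str]:
    """Helical turns spanned by the inter-tile crossover separation, and the
    side on which the next monomer binds.

    The separation is rounded to the nearest half-turn: an integer number of
    turns places the partner on the opposite side of the growing chain (2D
    growth geometry), a half-integer on the same side (1D linear growth).
    """
    if separation_nt <= 0:
        raise ValueError("separation_nt must be > 0")
    turns = separation_nt / geom.bp_per_turn
    nearest_half = round(turns * 2.0) / 2.0
    side = "opposite" if float(nearest_half).is_integer() else "same"
    return turns, side


def tile_dimensions(
    tile: TileSpec, geom: HelixGeometry = HelixGeometry()
) -> tuple[float, float, float]:
    """(thickness, width, length) of a DX tile in nm.

    length = bp per helix x rise; width = two helix diameters plus the
    inter-helix gap; thickness = one helix diameter.
    """
    if tile.tile_length_bp <= 0:
        raise ValueError("tile_length_bp must be > 0")
    length = tile.tile_length_bp * geom.rise_nm_per_bp
    width = 2.0 * geom.diameter_nm + geom.interhelix_gap_nm
    thickness = geom.diameter_nm
    return thickness, width, length


def symmetry_score(seq: str, k: int) -> int:
    """Number of distinct k-mers occurring more than once in *seq*.

    A cheap sequence-symmetry-minimization heuristic used when generating
    strand sets: lower is better (fewer repeated words, fewer spurious
    hybridization registers).
    """
    if k < 1 or k > len(seq):
        raise ValueError(f"k={k} out of range for sequence of length {len(seq)}")
    counts: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        counts[kmer] = counts.get(kmer, 0) + 1
    return sum(1 for c in counts.values() if c > 1)
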