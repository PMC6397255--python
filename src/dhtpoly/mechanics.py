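"""Elastic-rod mechanics of duplex DNA, DX tiles and tile filaments.

A structure is discretized as a 1D rod of nodes along the helical axis
(one node per base pair, coarse-grained for long filaments).  Each element
carries a bending stiffness by kind:

- ``duplex``     — B-form worm-like chain, 230 pN nm^2,
- ``duplex_DX``  — double-crossover cross-section, 2 x duplex by default,
- ``nicked``     — backbone nick, duplex / 100,
- ``ss``         — single-stranded overhangs and loops, kBT x 1 nm
                   (a very soft entropic element).

Thermal fluctuations at 298 K are computed by normal-mode analysis of the
transverse Euler–Bernoulli bending energy: assemble the curvature stiffness
matrix, drop the two rigid-body modes (translation + rotation), give every
remaining mode kBT/2 per equipartition, and sum the two independent
transverse directions into a per-node RMSF.  Stretching (1100 pN) and torsion
(460 pN nm^2) are carried as parameters but excluded from the default RMSF:
bending is the dominant soft mode for slender rods.

Relative compliance follows the beam definition: the bending stiffness of a
24-bp duplex divided by that of the filament, with k_b proportional to
B_eff / L^3 (B_eff the length-weighted harmonic mean of element stiffness;
an exponent of 1 is available for the linear-in-length convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Union

import numpy as np

from .tile_model import HelixGeometry

__all__ = [
    "RodParams",
    "RodModel",
    "RMSFProfile",
    "build_rod",
    "dsdna_design",
    "monomer_design",
    "filament_design",
    "compute_rmsf",
    "relative_compliance",
    "effective_bend_stiffness",
]

ElementKind = Literal["duplex", "duplex_DX", "nicked", "ss"]


@dataclass(frozen=True)
class RodParams:
    """Mechanical parameters (pN, nm units).

    kBT = 4.114 pN nm at 298 K; bend_stiffness/kBT ~ 56 nm reproduces the
    canonical ~50 nm duplex persistence length.
    """

    bend_stiffness: float = 230.0      # pN nm^2
    stretch_modulus: float = 1100.0    # pN
    torsion_stiffness: float = 460.0   # pN nm^2
    nick_softening: float = 100.0
    kBT: float = 4.114                 # pN nm at 298 K
    ss_persistence_nm: float = 1.0
    dx_multiplier: float = 2.0
    max_nodes: int = 2000

    def __post_init__(self) -> None:
        for name in ("bend_stiffness", "stretch_modulus", "torsion_stiffness",
                     "kBT", "ss_persistence_nm", "dx_multiplier"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.nick_softening < 1:
            raise ValueError("nick_softening must be >= 1")

    def element_stiffness(self, kind: ElementKind) -> float:
        if kind == "duplex":
            return self.bend_stiffness
        if kind == "duplex_DX":
            return self.dx_multiplier * self.bend_stiffness
        if kind == "nicked":
            return self.bend_stiffness / self.nick_softening
        if kind == "ss":
            return self.kBT * self.ss_persistence_nm
        raise ValueError(f"unknown element kind {kind!r}")


@dataclass
class RodModel:
    """Discretized rod: N nodes, N-1 elements with per-element stiffness."""

    node_positions: np.ndarray          # arc length, nm
    element_bend: np.ndarray            # pN nm^2
    element_kind: list[str]
    crossover_nodes: list[int] = field(default_factory=list)
    label: str = ""

    def __post_init__(self) -> None:
        self.node_positions = np.asarray(self.node_positions, dtype=float)
        self.element_bend = np.asarray(self.element_bend, dtype=float)
        if self.node_positions.size < 2:
            raise ValueError("rod needs at least 2 nodes")
        if self.element_bend.size != self.node_positions.size - 1:
            raise ValueError("need one element per node gap")
        if np.any(self.element_bend <= 0):
            raise ValueError("element stiffness must be > 0")

    @property
    def n_nodes(self) -> int:
        return int(self.node_positions.size)

    @property
    def length_nm(self) -> float:
        return float(self.node_positions[-1] - self.node_positions[0])


@dataclass(frozen=True)
class RMSFProfile:
    rmsf_nm: np.ndarray
    positions_nm: np.ndarray
    temperature_K: float = 298.0

    @property
    def min_rmsf(self) -> float:
        return float(self.rmsf_nm.min())

    @property
    def max_rmsf(self) -> float:
        return float(self.rmsf_nm.max())


def dsdna_design(bp: int) -> dict:
    return {"kind": "dsDNA", "bp": bp}


def monomer_design(tile_length_bp: int = 47, ss_end_nt: int = 8) -> dict:
    return {"kind": "monomer", "tile_length_bp": tile_length_bp,
            "ss_end_nt": ss_end_nt}


def filament_design(n_AB: int, tile_length_bp: int = 47, ss_end_nt: int = 8) -> dict:
    return {"kind": "filament", "n_AB": n_AB, "tile_length_bp": tile_length_bp,
            "ss_end_nt": ss_end_nt}


def _elements_for(design: dict) -> list[str]:
    kind = design.get("kind")
    if kind == "dsDNA":
        bp = int(design["bp"])
        if bp <= 0:
            raise ValueError("bp must be > 0")
        return ["duplex"] * bp
    if kind == "monomer":
        n = int(design.get("tile_length_bp", 47))
        ss = int(design.get("ss_end_nt", 8))
        if n <= 0:
            raise ValueError("tile_length_bp must be > 0")
        return ["ss"] * ss + ["duplex_DX"] * n + ["ss"] * ss
    if kind == "filament":
        n_ab = int(design["n_AB"])
        n = int(design.get("tile_length_bp", 47))
        ss = int(design.get("ss_end_nt", 8))
        if n_ab <= 0 or n <= 0:
            raise ValueError("n_AB and tile_length_bp must be > 0")
        tiles = 2 * n_ab  # I-[A-B]_n
        elems = ["ss"] * ss
        for i in range(tiles):
            if i:
                elems.append("nicked")  # inter-tile junction
            elems.extend(["duplex_DX"] * n)
        elems.extend(["ss"] * ss)
        return elems
    raise ValueError(f"unknown design kind {kind!r}")


def build_rod(
    design: dict,
    geom: HelixGeometry = HelixGeometry(),
    params: RodParams = RodParams(),
) -> RodModel:
    """Discretize a design into a rod, one node per base step (coarse-grained
    by an integer factor so rods stay at or below params.max_nodes nodes)."""
    kinds = _elements_for(design)
    B = np.array([params.element_stiffness(k) for k in kinds])
    n_elem = len(kinds)
    factor = max(1, math.ceil(n_elem / (params.max_nodes - 1)))
    if factor > 1:
        # series coarse-graining: harmonic mean of grouped element stiffness
        pad = (-n_elem) % factor
        Bp = np.concatenate([B, np.full(pad, np.inf)]) if pad else B
        groups = Bp.reshape(-1, factor)
        weights = np.isfinite(groups).sum(axis=1)
        B = weights / np.where(np.isfinite(groups), 1.0 / groups, 0.0).sum(axis=1)
        kinds = ["coarse"] * B.size
    ell = geom.rise_nm_per_bp * factor
    positions = np.arange(B.size + 1) * ell
    return RodModel(
        node_positions=positions,
        element_bend=B,
        element_kind=list(kinds),
        label=str(design.get("kind", "")),
    )


def _bending_stiffness_matrix(rod: RodModel) -> np.ndarray:
    """K for transverse displacements w: E = 1/2 w^T K w with the discrete
    curvature energy sum_j b_j * ell * ((w_{j-1} - 2 w_j + w_{j+1})/ell^2)^2 / 1,
    b_j the series (harmonic-mean) stiffness of the two elements at node j."""
    n = rod.n_nodes
    ell = float(np.diff(rod.node_positions).mean())
    Bl, Br = rod.element_bend[:-1], rod.element_bend[1:]
    b = 2.0 * Bl * Br / (Bl + Br)  # interior nodes 1..n-2
    K = np.zeros((n, n))
    coef = b * ell / ell**4
    for j in range(1, n - 1):
        c = coef[j - 1]
        idx = (j - 1, j, j + 1)
        w = (1.0, -2.0, 1.0)
        for a, wa in zip(idx, w):
            for bcol, wb in zip(idx, w):
                K[a, bcol] += c * wa * wb
    return K


def compute_rmsf(rod: RodModel, params: RodParams = RodParams()) -> RMSFProfile:
    """Per-node thermal RMSF at 298 K from bending normal modes.

    Eigen-decompose the curvature stiffness matrix, drop the two rigid-body
    modes, equipartition each remaining mode at kBT, and combine the two
    independent transverse directions: RMSF_i = sqrt(2 kBT [K^+]_ii).
    """
    K = _bending_stiffness_matrix(rod)
    n = K.shape[0]
    # deflate the two exact rigid-body modes (translation, rotation) so the
    # softest bending modes of long rods are never confused with them
    rigid = np.stack(
        [np.ones(n), rod.node_positions - rod.node_positions.mean()], axis=1
    )
    Q, _ = np.linalg.qr(np.concatenate([rigid, np.eye(n)], axis=1))
    Q = Q[:, 2:n]  # orthonormal complement of the rigid subspace
    Kr = Q.T @ K @ Q
    evals, evecs = np.linalg.eigh(Kr)
    if evals.min() <= 0:
        raise np.linalg.LinAlgError(
            "non-rigid-body null space: stiffness matrix is singular beyond "
            "translation and rotation"
        )
    V = Q @ evecs
    var_1d = params.kBT * np.einsum("im,m->i", V**2, 1.0 / evals)
    rmsf = np.sqrt(2.0 * var_1d)
    return RMSFProfile(rmsf_nm=rmsf, positions_nm=rod.node_positions.copy())


def effective_bend_stiffness(rod: RodModel) -> float:
    """Length-weighted harmonic mean of element bending stiffness (series
    springs along the arc)."""
    ell = np.diff(rod.node_positions)
    return float(ell.sum() / (ell / rod.element_bend).sum())


def relative_compliance(
    reference: RodModel, rod: RodModel, exponent: int = 3
) -> float:
    """k_b(reference) / k_b(rod) with k_b = c * B_eff / L^exponent.

    exponent 3 is the cantilever-beam spring constant; exponent 1 encodes the
    inversely-proportional-to-length convention.  The constant c cancels.
    """
    if exponent not in (1, 3):
        raise ValueError("exponent must be 1 or 3")
    for r in (reference, rod):
        if r.length_nm <= 0:
            raise ValueError("rod has zero length")
    kb_ref = effective_bend_stiffness(reference) / reference.length_nm**exponent
    kb_rod = effective_bend_stiffness(rod) / rod.length_nm**exponent
    return kb_ref / kb_rod
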