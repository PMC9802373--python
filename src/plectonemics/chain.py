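"""Discretized twistable wormlike chain: conformations, energies, topology.

A conformation is a string of beads with fixed bond length ``a`` held at
fixed linking number ΔLk. Twist is implicit: the twist absorbed by the
molecule is ``Tw = ΔLk − Wr`` (uniform-twist convention), so the only
topological quantity tracked geometrically is the writhe Wr, computed with
the exact pairwise solid-angle (Klenin–Langowski) formula under the
open-chain convention with both termini directed along the stretching axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import _kernels
from .params import ElasticParams, MoleculeSpec

__all__ = [
    "ChainConformation",
    "BridgeConstraint",
    "bending_energy",
    "twist_energy",
    "writhe",
    "straight_conformation",
    "solenoid_conformation",
    "detect_plectoneme",
    "plectoneme_lengths",
    "select_bridge_sites",
    "loop_linking_number",
    "partition_linking_number",
]


@dataclass
class ChainConformation:
    """Bead positions of a fixed-ΔLk chain.

    Attributes
    ----------
    positions :
        (n_beads, 3) coordinates in nm.
    segment_length :
        Bond length ``a`` (nm); consecutive beads are exactly this far apart.
    delta_lk :
        Imposed linking difference (turns), fixed for an entire trajectory.
    excluded_diameter :
        Hard-core bead diameter (nm) enforced between beads of contour
        separation > 1.
    """

    positions: np.ndarray
    segment_length: float
    delta_lk: float
    excluded_diameter: float = 4.0

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be an (n, 3) array")
        if self.positions.shape[0] < 3:
            raise ValueError("need at least 3 beads")
        bonds = np.linalg.norm(np.diff(self.positions, axis=0), axis=1)
        if not np.allclose(bonds, self.segment_length, rtol=0, atol=1e-6):
            raise ValueError("consecutive beads must be segment_length apart")

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]

    @property
    def contour_length(self) -> float:
        return (self.n_beads - 1) * self.segment_length

    @property
    def extension(self) -> float:
        """End-to-end distance along the stretching (z) axis (nm)."""
        return float(self.positions[-1, 2] - self.positions[0, 2])

    def writhe(self) -> float:
        return writhe(self.positions)

    def twist(self) -> float:
        """Implicit twist Tw = ΔLk − Wr (turns)."""
        return self.delta_lk - self.writhe()

    def min_nonadjacent_distance(self) -> float:
        """Post-hoc self-avoidance scan: minimum distance between beads
        beyond the hard-core contour-exclusion window (must be ≥
        excluded_diameter)."""
        ex_sep = max(1, int(self.excluded_diameter / self.segment_length + 1e-9))
        return float(_kernels.min_nonadjacent_distance(self.positions, ex_sep))

    def mirror(self) -> "ChainConformation":
        """Mirror image (x → −x); negates chirality, hence the writhe."""
        p = self.positions.copy()
        p[:, 0] *= -1.0
        return ChainConformation(
            p, self.segment_length, -self.delta_lk, self.excluded_diameter
        )


@dataclass(frozen=True)
class BridgeConstraint:
    """A protein bridge pinning beads ``bead_i`` and ``bead_j`` together.

    During a constrained simulation the six beads i−1, i, i+1, j−1, j, j+1
    keep their relative positions (rigid relative pose of the two site
    frames), partitioning the chain into a looped domain of contour length
    ``loop_length`` and an unlooped remainder.
    """

    bead_i: int
    bead_j: int
    segment_length: float
    distance: float = float("nan")

    def __post_init__(self) -> None:
        if not 0 < self.bead_i < self.bead_j:
            raise ValueError("require 0 < bead_i < bead_j")

    @property
    def loop_length(self) -> float:
        """Contour length ΔL of the looped domain (nm)."""
        return (self.bead_j - self.bead_i) * self.segment_length


# ---------------------------------------------------------------------------
# energies and topology


def bending_energy(chain: ChainConformation, params: ElasticParams) -> float:
    """Bending energy (A/a)·Σ(1 − cos θᵢ) over interior joints, in k_BT.

    The Monte Carlo engine additionally applies the same form to the two
    terminal clamp joints (tangents restrained along ẑ); those boundary
    terms are not part of the chain's internal bending energy reported here.
    """
    t = np.diff(chain.positions, axis=0)
    t /= np.linalg.norm(t, axis=1)[:, None]
    cos = np.sum(t[:-1] * t[1:], axis=1)
    return float(
        params.bend_persistence / chain.segment_length * np.sum(1.0 - cos)
    )


def twist_energy(chain: ChainConformation, params: ElasticParams) -> float:
    """Twist energy (2π²C/L)·(ΔLk − Wr)² in k_BT (uniform-twist partition)."""
    tw = chain.delta_lk - chain.writhe()
    return float(
        2.0
        * math.pi**2
        * params.twist_persistence
        / chain.contour_length
        * tw**2
    )


def writhe(positions: np.ndarray) -> float:
    """Writhe (turns) of an open chain by the exact pairwise Gauss sum.

    Termini are assumed to be directed along the stretching axis, the
    open-chain convention under which the pairwise sum over real segments
    is the writhe of the closure through infinity.
    """
    pos = np.ascontiguousarray(positions, dtype=np.float64)
    seg = np.diff(pos, axis=0)
    if np.any(np.linalg.norm(seg, axis=1) < 1e-12):
        raise ValueError("coincident consecutive beads")
    return float(_kernels.total_writhe(pos))


# ---------------------------------------------------------------------------
# initial conformations


def straight_conformation(
    n_beads: int,
    segment_length: float,
    delta_lk: float,
    excluded_diameter: float = 4.0,
    amplitude: float = 0.2,
) -> ChainConformation:
    """Nearly straight chain along ẑ with a tiny helical perturbation.

    The perturbation breaks the collinearity of the segments (the Gauss
    pair terms are degenerate for an exactly straight chain) while keeping
    the writhe negligible. Bond lengths are restored exactly by rescaling
    the z-spacing of successive beads.
    """
    s = np.arange(n_beads)
    phase = 2.0 * math.pi * s / max(n_beads / 4.0, 8.0)
    x = amplitude * np.cos(phase)
    y = amplitude * np.sin(phase)
    pos = np.zeros((n_beads, 3))
    pos[:, 0] = x
    pos[:, 1] = y
    dz = np.sqrt(
        segment_length**2 - np.diff(x) ** 2 - np.diff(y) ** 2
    )
    pos[1:, 2] = np.cumsum(dz)
    return ChainConformation(pos, segment_length, delta_lk, excluded_diameter)


def solenoid_conformation(
    n_beads: int,
    segment_length: float,
    delta_lk: float,
    target_writhe: float,
    excluded_diameter: float = 4.0,
) -> ChainConformation:
    """Solenoidal helix carrying roughly ``target_writhe`` turns of writhe.

    Used to start postbuckling runs near the equilibrium writhe instead of
    waiting for a plectoneme to nucleate from a straight chain. For a
    solenoid with pitch angle α and n_t turns, Wr ≈ n_t(1 − sin α); the
    helix radius follows from the contour length. The construction is
    unknotted and self-avoiding for the geometries used here.
    """
    if target_writhe <= 0:
        return straight_conformation(
            n_beads, segment_length, delta_lk, excluded_diameter
        )
    ns = n_beads - 1
    length = ns * segment_length
    sin_a = 0.35
    n_turns = target_writhe / (1.0 - sin_a)
    arc_per_turn = length / n_turns
    radius = arc_per_turn * math.sqrt(1.0 - sin_a**2) / (2.0 * math.pi)
    pitch = arc_per_turn * sin_a
    # guard against consecutive superhelical turns clashing
    if pitch < excluded_diameter * 1.2:
        sin_a = min(0.8, excluded_diameter * 1.2 * n_turns / length)
        n_turns = target_writhe / (1.0 - sin_a)
        arc_per_turn = length / n_turns
        radius = arc_per_turn * math.sqrt(1.0 - sin_a**2) / (2.0 * math.pi)
        pitch = arc_per_turn * sin_a
    s = np.arange(n_beads) * segment_length
    theta = 2.0 * math.pi * s / arc_per_turn
    pos = np.empty((n_beads, 3))
    pos[:, 0] = radius * np.cos(theta) - radius
    pos[:, 1] = radius * np.sin(theta)
    pos[:, 2] = s * sin_a
    # restore exact bond lengths (the analytic helix has equal chords,
    # but rounding leaves ~1e-13 deviations; renormalize the chords)
    seg = np.diff(pos, axis=0)
    seg *= segment_length / np.linalg.norm(seg, axis=1)[:, None]
    pos[1:] = pos[0] + np.cumsum(seg, axis=0)
    return ChainConformation(pos, segment_length, delta_lk, excluded_diameter)


# ---------------------------------------------------------------------------
# plectoneme detection and bridge-site selection


def plectoneme_conformation(
    n_beads: int,
    segment_length: float,
    delta_lk: float,
    loop_contour: float,
    n_turns: float,
    radius: float = 3.2,
    excluded_diameter: float = 4.0,
) -> ChainConformation:
    """Chain seeded with a single developed interwound plectoneme.

    Two stems along ẑ flank an interwound double helix of contour
    ``loop_contour`` carrying ≈ ``n_turns`` of writhe (radius ``radius``,
    pitch from the per-turn strand contour). The construction places the
    superhelix column beside the stems with ≥ excluded-diameter clearance
    and enforces exact bond lengths by arc-length resampling. Used to
    start postbuckling runs in the developed-plectoneme basin instead of
    waiting for nucleation and growth from a straight chain.
    """
    L = (n_beads - 1) * segment_length
    lp = min(loop_contour, 0.8 * L)
    n_turns = max(n_turns, 1.0)
    r = radius
    # per-strand helix: ℓ_turn² = (2πr)² + pitch²
    ell = lp / (2.0 * n_turns)
    min_ell = 2.0 * math.pi * r * 1.05
    if ell < min_ell:  # open the helix rather than fail
        n_turns = lp / (2.0 * min_ell)
        ell = lp / (2.0 * n_turns)
    pitch = math.sqrt(max(ell**2 - (2.0 * math.pi * r) ** 2, 1.0))
    h_p = n_turns * pitch
    x0 = 2.0 * r + excluded_diameter + 1.0  # superhelix axis offset

    # dense polyline: stem1, entry chord, strand up, U-turn, strand down,
    # exit chord, stem2 (overlong; trimmed by resampling)
    stem1 = max(0.3 * (L - lp), 20.0)
    pts: list[np.ndarray] = [np.array([0.0, 0.0, 0.0])]

    def line_to(q, step=1.0):
        q = np.asarray(q, dtype=float)
        p0 = pts[-1]
        d = np.linalg.norm(q - p0)
        n = max(2, int(d / step))
        for t in np.linspace(0, 1, n + 1)[1:]:
            pts.append(p0 + t * (q - p0))

    line_to([0.0, 0.0, stem1])
    line_to([x0 - r, 0.0, stem1])  # entry chord to strand-1 bottom
    # strand 1 ascends at phase π
    n_fine = max(200, int(lp))
    for t in np.linspace(0, 1, n_fine)[1:]:
        phi = math.pi + 2.0 * math.pi * n_turns * t
        pts.append(
            np.array([x0 + r * math.cos(phi), r * math.sin(phi), stem1 + h_p * t])
        )
    # U-turn: arc over the top of the column (apex r+2 above the last turn)
    phi_top = math.pi + 2.0 * math.pi * n_turns
    top = stem1 + h_p
    A = np.array([x0 + r * math.cos(phi_top), r * math.sin(phi_top), top])
    M = np.array([x0, 0.0, top])
    for s in np.linspace(0, 1, 24)[1:]:
        ang = math.pi * s
        pts.append(
            M
            + math.cos(ang) * (A - M)
            + math.sin(ang) * np.array([0.0, 0.0, r + 2.0])
        )
    # strand 2 descends at phase φ+π
    for t in np.linspace(0, 1, n_fine)[1:]:
        phi = phi_top + math.pi - 2.0 * math.pi * n_turns * t
        pts.append(
            np.array(
                [x0 + r * math.cos(phi), r * math.sin(phi), stem1 + h_p * (1.0 - t)]
            )
        )
    # exit: detour around the column in −y, then rejoin the stem axis
    clear = 2.0 * r + excluded_diameter
    line_to([x0 + r, -clear, stem1])
    line_to([0.0, -clear, stem1 + 4.0])
    line_to([0.0, 0.0, stem1 + clear + 4.0])
    line_to([0.0, 0.0, stem1 + clear + 4.0 + 1.2 * L])

    poly = np.array(pts)
    seglen = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    s_cum = np.r_[0.0, np.cumsum(seglen)]
    targets = np.arange(n_beads) * segment_length
    if targets[-1] > s_cum[-1]:
        raise ValueError("constructed path too short for the chain")
    pos = np.empty((n_beads, 3))
    for k, sv in enumerate(targets):
        j = int(np.searchsorted(s_cum, sv, side="right") - 1)
        j = min(j, len(seglen) - 1)
        f = (sv - s_cum[j]) / max(seglen[j], 1e-12)
        pos[k] = poly[j] + f * (poly[j + 1] - poly[j])
    # exact bond lengths
    seg = np.diff(pos, axis=0)
    seg *= segment_length / np.linalg.norm(seg, axis=1)[:, None]
    pos[1:] = pos[0] + np.cumsum(seg, axis=0)
    conf = ChainConformation(pos, segment_length, delta_lk, excluded_diameter)
    # overwound DNA needs positive plectoneme writhe: mirror if needed
    if delta_lk > 0 and conf.writhe() < 0:
        p2 = conf.positions.copy()
        p2[:, 1] *= -1.0
        conf = ChainConformation(p2, segment_length, delta_lk, excluded_diameter)
    return conf


def detect_plectoneme(
    chain: ChainConformation,
    proximity_nm: float = 10.0,
    min_contour_factor: float = 4.0,
    smooth_beads: int = 5,
) -> np.ndarray:
    """Label each bead stretched (False) or plectonemic (True).

    A bead is plectonemic when some bead at contour separation larger than
    ``min_contour_factor`` bending persistence lengths (taken as 40 nm·4 by
    default via the separation threshold below) lies within ``proximity_nm``.
    Labels are smoothed by a centred ``smooth_beads`` majority vote.
    """
    pos = chain.positions
    n = chain.n_beads
    min_sep = max(2, int(round(min_contour_factor * 40.0 / chain.segment_length)))
    d2 = proximity_nm**2
    diff = pos[:, None, :] - pos[None, :, :]
    dist2 = np.einsum("ijk,ijk->ij", diff, diff)
    idx = np.arange(n)
    far = np.abs(idx[:, None] - idx[None, :]) > min_sep
    labels = np.any((dist2 < d2) & far, axis=1)
    if smooth_beads > 1:
        k = np.ones(smooth_beads)
        votes = np.convolve(labels.astype(float), k, mode="same")
        counts = np.convolve(np.ones(n), k, mode="same")
        labels = votes / counts > 0.5
    return labels


def plectoneme_lengths(
    chain: ChainConformation, labels: np.ndarray | None = None
) -> tuple[float, float]:
    """Contour length partition (L_s, L_p) with L_s + L_p = L exactly.

    Each bead carries contour weight L/n so the partition is exact.
    """
    if labels is None:
        labels = detect_plectoneme(chain)
    weight = chain.contour_length / chain.n_beads
    lp = float(np.sum(labels) * weight)
    return chain.contour_length - lp, lp


def select_bridge_sites(
    chain: ChainConformation,
    threshold: float = 8.0,
    antiparallel_max_dot: float = -0.5,
    labels: np.ndarray | None = None,
) -> list[BridgeConstraint]:
    """Candidate protein-bridging site pairs on a plectonemic snapshot.

    Returns pairs of beads (i, j) that are both in the plectonemic phase,
    closer than ``threshold`` nm, and sit on opposite superhelical strands
    (antiparallel local tangents, dot < ``antiparallel_max_dot``). Each
    candidate is annotated with the looped contour length ΔL. An empty list
    (e.g., for a stretched chain) is a valid result.
    """
    if labels is None:
        labels = detect_plectoneme(chain)
    pos = chain.positions
    n = chain.n_beads
    tangents = np.zeros_like(pos)
    tangents[1:-1] = pos[2:] - pos[:-2]
    tangents[0] = pos[1] - pos[0]
    tangents[-1] = pos[-1] - pos[-2]
    tangents /= np.linalg.norm(tangents, axis=1)[:, None]

    min_sep = max(4, int(round(4.0 * 40.0 / chain.segment_length)))
    out: list[BridgeConstraint] = []
    # constrained sites need interior neighbours on both sides
    plect = np.flatnonzero(labels)
    plect = plect[(plect >= 2) & (plect <= n - 3)]
    for a_idx, i in enumerate(plect):
        for j in plect[a_idx + 1 :]:
            if j - i <= min_sep:
                continue
            d = float(np.linalg.norm(pos[i] - pos[j]))
            if d >= threshold:
                continue
            if float(tangents[i] @ tangents[j]) >= antiparallel_max_dot:
                continue
            out.append(
                BridgeConstraint(
                    bead_i=int(i),
                    bead_j=int(j),
                    segment_length=chain.segment_length,
                    distance=d,
                )
            )
    return out


def loop_linking_number(
    chain: ChainConformation, bridge: BridgeConstraint
) -> float:
    """Linking difference trapped in the bridged loop (turns).

    The loop subchain i..j is closed by the straight bridge chord; its
    linking difference is the writhe of that closed loop plus the loop's
    share of the implicit twist under the uniform-twist convention,
    Tw·ΔL/L.
    """
    if not (0 < bridge.bead_i < bridge.bead_j < chain.n_beads):
        raise ValueError("bridge does not fit this chain")
    wr_loop = float(
        _kernels.loop_writhe(chain.positions, bridge.bead_i, bridge.bead_j)
    )
    tw = chain.delta_lk - chain.writhe()
    return wr_loop + tw * bridge.loop_length / chain.contour_length


def partition_linking_number(
    chain: ChainConformation, bridge: BridgeConstraint
) -> tuple[float, float]:
    """(loop ΔLk, complement ΔLk); sums to the total ΔLk by construction
    of the uniform twist-partition convention."""
    lk_loop = loop_linking_number(chain, bridge)
    return lk_loop, chain.delta_lk - lk_loop
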