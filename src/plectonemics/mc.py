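"""Metropolis Monte Carlo of the fixed-ΔLk twistable wormlike chain.

Moves are sub-chain crankshaft rotations and end pivots, Metropolis-accepted
on E_bend + E_twist − f·z. Self-intersections are rejected (bead hard core,
checked along the swept rotation in ≤10° increments) and any single move
changing the writhe by more than 0.5 turns is rejected as a strand-passage
sentinel, so the imposed linking number is conserved exactly.

Bridged simulations additionally hold the relative pose of two binding
sites fixed; see :func:`run_bridged_simulation`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import _kernels, theory
from .chain import (
    BridgeConstraint,
    ChainConformation,
    detect_plectoneme,
    plectoneme_conformation,
    plectoneme_lengths,
    solenoid_conformation,
    straight_conformation,
)
from .params import ElasticParams, MoleculeSpec

__all__ = [
    "McEnsemble",
    "mc_step",
    "run_simulation",
    "run_bridged_simulation",
    "run_rotation_series",
]


def _block_stats(x: np.ndarray, n_blocks: int = 16) -> tuple[float, float]:
    """Mean and block-averaged standard error of a correlated sample."""
    x = np.asarray(x, dtype=float)
    n_blocks = min(n_blocks, max(2, x.size // 4))
    blocks = np.array_split(x, n_blocks)
    means = np.array([b.mean() for b in blocks])
    return float(x.mean()), float(means.std(ddof=1) / math.sqrt(len(means)))


def _block_var(x: np.ndarray, n_blocks: int = 16) -> tuple[float, float]:
    """Variance and its block-averaged standard error."""
    x = np.asarray(x, dtype=float)
    n_blocks = min(n_blocks, max(2, x.size // 4))
    blocks = np.array_split(x, n_blocks)
    per_block = np.array([b.var(ddof=1) for b in blocks])
    return float(x.var(ddof=1)), float(
        per_block.std(ddof=1) / math.sqrt(len(per_block))
    )


@dataclass
class McEnsemble:
    """Sampled observables of one MC trajectory."""

    z: np.ndarray
    writhe: np.ndarray
    snapshots: np.ndarray
    delta_lk: float
    force: float
    seed: int
    n_steps: int
    stride: int
    segment_length: float
    excluded_diameter: float
    acceptance: dict[str, float]
    final_conformation: ChainConformation
    loop_delta_lk: np.ndarray | None = None
    bridge: BridgeConstraint | None = None
    equilibrated: bool = True
    final_writhe: float = float("nan")  # incrementally tracked Wr at the end

    def mean_extension(self, n_blocks: int = 16) -> tuple[float, float]:
        """⟨z⟩ (nm) with block-averaged SE."""
        return _block_stats(self.z, n_blocks)

    def extension_variance(self, n_blocks: int = 16) -> tuple[float, float]:
        """⟨Δz²⟩ (nm²) with block-averaged SE."""
        return _block_var(self.z, n_blocks)

    def plectoneme_length(self) -> tuple[float, float]:
        """⟨L_p⟩ (nm) over stored snapshots, with SE."""
        lps = []
        for snap in self.snapshots:
            c = ChainConformation(
                snap, self.segment_length, self.delta_lk, self.excluded_diameter
            )
            lps.append(plectoneme_lengths(c)[1])
        return _block_stats(np.array(lps), n_blocks=8)


def _spawn_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s % 2**31) for s in ss.generate_state(n)]


#: plectonemic supercoiling density used to size seeded start conformations
SEED_SIGMA_P = 0.085


def _plectoneme_seed(
    n_beads: int,
    a: float,
    delta_lk: float,
    d_ex: float,
    sigma: float,
    sigma_s: float,
) -> ChainConformation:
    L = (n_beads - 1) * a
    frac = (sigma - sigma_s) / (SEED_SIGMA_P - sigma_s)
    lp = float(np.clip(L * frac, 60.0, 0.78 * L))
    pitch_nm = 10.5 * 0.34
    n_turns = max(1.5, 0.8 * SEED_SIGMA_P * lp / pitch_nm)
    return plectoneme_conformation(
        n_beads, a, delta_lk, loop_contour=lp, n_turns=n_turns,
        excluded_diameter=d_ex,
    )


def _initial_conformation(
    n_beads: int,
    a: float,
    delta_lk: float,
    d_ex: float,
    force: float,
    params: ElasticParams,
    molecule: MoleculeSpec,
    start: str,
) -> ChainConformation:
    sigma = theory.supercoiling_density(delta_lk, molecule)
    if start == "straight":
        return straight_conformation(n_beads, a, delta_lk, d_ex)
    if start == "solenoid":
        return solenoid_conformation(
            n_beads, a, delta_lk, target_writhe=0.65 * delta_lk, excluded_diameter=d_ex
        )
    try:
        coex = theory.solve_coexistence(force, params)
        sigma_s = coex.sigma_s
    except theory.NoCoexistenceError:
        sigma_s = math.inf
    if start == "plectoneme":
        return _plectoneme_seed(
            n_beads, a, delta_lk, d_ex, sigma, min(sigma_s, 0.7 * sigma)
        )
    # auto: seed a developed plectoneme once clearly past buckling — the
    # nucleation-and-growth route from a straight chain is far slower than
    # desk-scale runs can afford
    if sigma > 1.4 * sigma_s:
        return _plectoneme_seed(n_beads, a, delta_lk, d_ex, sigma, sigma_s)
    return straight_conformation(n_beads, a, delta_lk, d_ex)


def _run_kernel(
    conf: ChainConformation,
    params: ElasticParams,
    force: float,
    n_steps: int,
    stride: int,
    snap_stride: int,
    seed: int,
    theta_crank: float,
    theta_pivot: float,
    max_block: int,
    max_pivot: int,
    p_crank: float,
    p_cluster: float,
    bridge: BridgeConstraint | None,
):
    bi = bridge.bead_i if bridge is not None else -1
    bj = bridge.bead_j if bridge is not None else -1
    pos = conf.positions  # modified in place
    return _kernels.run_mc(
        pos,
        float(conf.delta_lk),
        float(conf.segment_length),
        float(params.bend_persistence),
        float(params.twist_persistence),
        float(params.kT),
        float(force),
        float(conf.excluded_diameter),
        int(n_steps),
        int(stride),
        int(snap_stride),
        int(seed),
        float(theta_crank),
        float(theta_pivot),
        int(max_block),
        int(max_pivot),
        float(p_crank),
        float(p_cluster),
        int(bi),
        int(bj),
        0.5,
        math.radians(10.0),
    )


def _simulate(
    conf: ChainConformation,
    params: ElasticParams,
    force: float,
    n_steps: int,
    n_equil: int,
    stride: int,
    snap_stride: int,
    seed: int,
    bridge: BridgeConstraint | None,
    theta_crank: float,
    theta_pivot: float,
    max_block: int | None,
    max_pivot: int | None,
    p_crank: float,
    p_cluster: float,
) -> McEnsemble:
    nb = conf.n_beads
    # large blocks (with angles scaled down by block size) relax the slow
    # plectoneme modes far better than many small moves
    if max_block is None:
        max_block = max(4, min(2 * nb // 5, 80))
    if max_pivot is None:
        max_pivot = max(2, min(nb // 2, 100))
    s_eq, s_run = _spawn_seeds(seed, 2)
    if n_equil > 0:
        _run_kernel(
            conf,
            params,
            force,
            n_equil,
            max(n_equil, 1),
            max(n_equil, 1),
            s_eq,
            theta_crank,
            theta_pivot,
            max_block,
            max_pivot,
            p_crank,
            p_cluster,
            bridge,
        )
    z, wr, lwr, snaps, prop, acc, wr_final = _run_kernel(
        conf,
        params,
        force,
        n_steps,
        stride,
        snap_stride,
        s_run,
        theta_crank,
        theta_pivot,
        max_block,
        max_pivot,
        p_crank,
        p_cluster,
        bridge,
    )
    names = ["crankshaft", "pivot", "cluster"]
    acceptance = {
        n: (float(a) / p if p else float("nan"))
        for n, a, p in zip(names, acc, prop)
    }
    loop_dlk = None
    if bridge is not None:
        share = bridge.loop_length / conf.contour_length
        loop_dlk = lwr + (conf.delta_lk - wr) * share
    ens = McEnsemble(
        z=z,
        writhe=wr,
        snapshots=snaps,
        delta_lk=conf.delta_lk,
        force=force,
        seed=seed,
        n_steps=n_steps,
        stride=stride,
        segment_length=conf.segment_length,
        excluded_diameter=conf.excluded_diameter,
        acceptance=acceptance,
        final_conformation=conf,
        loop_delta_lk=loop_dlk,
        bridge=bridge,
        final_writhe=float(wr_final),
    )
    # non-equilibration diagnostic: drifting block means between the halves
    half = z.size // 2
    m1, e1 = _block_stats(z[:half], 8)
    m2, e2 = _block_stats(z[half:], 8)
    if abs(m1 - m2) > 3.0 * math.hypot(e1, e2):
        ens.equilibrated = False
        warnings.warn(
            f"possible non-equilibration: half-trace means {m1:.1f} vs "
            f"{m2:.1f} nm differ by more than 3 SE",
            stacklevel=2,
        )
    return ens


def mc_step(
    conf: ChainConformation,
    params: ElasticParams,
    force: float,
    seed: int,
    theta_crank: float = 1.2,
    theta_pivot: float = 0.7,
) -> tuple[ChainConformation, bool]:
    """Attempt a single Metropolis move; returns (chain, accepted).

    Proposes a crankshaft or end pivot, rejects self-intersections along
    the swept rotation and topology-violating writhe jumps, and accepts
    on the total energy change. Rejection is a normal outcome: the chain
    is returned unchanged. The imposed ΔLk is untouched either way.
    """
    nb = conf.n_beads
    z0, wr0, lw, snaps, prop, acc, wr = _run_kernel(
        conf,
        params,
        force,
        1,
        1,
        1,
        seed,
        theta_crank,
        theta_pivot,
        max(4, min(2 * nb // 5, 80)),
        max(2, min(nb // 2, 100)),
        0.7,
        0.0,
        None,
    )
    return conf, bool(acc.sum() > 0)


def run_simulation(
    molecule: MoleculeSpec,
    delta_lk: float,
    force: float,
    params: ElasticParams | None = None,
    *,
    seed: int,
    n_steps: int = 2_000_000,
    n_equil: int = 500_000,
    stride: int = 1000,
    snap_stride: int | None = None,
    segment_length: float = 2.5,
    excluded_diameter: float = 4.0,
    initial: ChainConformation | None = None,
    start: str = "auto",
    theta_crank: float = 1.2,
    theta_pivot: float = 0.7,
    max_block: int | None = None,
    max_pivot: int | None = None,
) -> McEnsemble:
    """Simulate a torsionally constrained chain under tension.

    The chain has ``round(L/a)`` segments of length ``a = segment_length``;
    the default run length is desk-scale (orders of magnitude below
    publication-scale runs) and is meant for tests and quick exploration.
    Reproducible: identical arguments and seed give identical trajectories.
    """
    params = params or ElasticParams()
    if initial is not None:
        conf = ChainConformation(
            initial.positions.copy(),
            initial.segment_length,
            delta_lk,
            initial.excluded_diameter,
        )
    else:
        n_beads = int(round(molecule.contour_length / segment_length)) + 1
        conf = _initial_conformation(
            n_beads,
            segment_length,
            delta_lk,
            excluded_diameter,
            force,
            params,
            molecule,
            start,
        )
    if snap_stride is None:
        snap_stride = 10 * stride
    return _simulate(
        conf,
        params,
        force,
        n_steps,
        n_equil,
        stride,
        snap_stride,
        seed,
        None,
        theta_crank,
        theta_pivot,
        max_block,
        max_pivot,
        p_crank=0.7,
        p_cluster=0.0,
    )


def run_bridged_simulation(
    initial: ChainConformation,
    bridge: BridgeConstraint,
    force: float,
    params: ElasticParams | None = None,
    *,
    seed: int,
    n_steps: int = 2_000_000,
    n_equil: int = 500_000,
    stride: int = 1000,
    snap_stride: int | None = None,
    theta_crank: float = 1.2,
    theta_pivot: float = 0.7,
    max_block: int | None = None,
    max_pivot: int | None = None,
) -> McEnsemble:
    """Simulate with a protein bridge holding sites i and j in fixed pose.

    ``initial`` must be a conformation (typically an equilibrated
    postbuckling snapshot) on which ``bridge`` was selected. Ordinary moves
    never touch the six-bead bridge cluster; dedicated large crankshaft
    moves translate/rotate the cluster rigidly so the bridged complex keeps
    its spatial fluctuations. Reports loop ΔLk samples alongside z and Wr.
    """
    params = params or ElasticParams()
    nb = initial.n_beads
    if not (1 <= bridge.bead_i - 1 and bridge.bead_j + 1 <= nb - 2):
        raise ValueError("bridge sites too close to the chain ends")
    conf = ChainConformation(
        initial.positions.copy(),
        initial.segment_length,
        initial.delta_lk,
        initial.excluded_diameter,
    )
    if snap_stride is None:
        snap_stride = 10 * stride
    return _simulate(
        conf,
        params,
        force,
        n_steps,
        n_equil,
        stride,
        snap_stride,
        seed,
        bridge,
        theta_crank,
        theta_pivot,
        max_block,
        max_pivot,
        p_crank=0.7,
        p_cluster=0.12,
    )


def run_rotation_series(
    molecule: MoleculeSpec,
    delta_lks: Sequence[float],
    force: float,
    params: ElasticParams | None = None,
    *,
    seed: int,
    n_steps: int = 1_500_000,
    n_equil_first: int = 1_000_000,
    n_equil: int = 300_000,
    stride: int = 1000,
    segment_length: float = 2.5,
    excluded_diameter: float = 4.0,
    **kwargs,
) -> list[McEnsemble]:
    """Anneal a chain through a ladder of ΔLk values, sampling at each.

    The final conformation at one ΔLk seeds the next (the imposed linking
    number is an external control; the conformation remains valid), which
    cuts the per-point equilibration dramatically compared to independent
    cold starts. Points are visited in the order given: descending ladders
    shrink a well-developed plectoneme and avoid nucleation hysteresis,
    ascending ones grow it.
    """
    params = params or ElasticParams()
    dlks = [float(d) for d in delta_lks]
    seeds = _spawn_seeds(seed, len(dlks))
    out: list[McEnsemble] = []
    conf: ChainConformation | None = None
    for k, dlk in enumerate(dlks):
        ens = run_simulation(
            molecule,
            dlk,
            force,
            params,
            seed=seeds[k],
            n_steps=n_steps,
            n_equil=n_equil_first if k == 0 else n_equil,
            stride=stride,
            segment_length=segment_length,
            excluded_diameter=excluded_diameter,
            initial=conf,
            **kwargs,
        )
        conf = ens.final_conformation
        out.append(ens)
    return out
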