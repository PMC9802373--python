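"""Tests of the Monte Carlo engine: detailed-balance ingredients, topology
conservation, self-avoidance, and thermodynamic consistency."""

import math

import numpy as np
import pytest

from plectonemics import _kernels, chain, mc, theory
from plectonemics.params import ElasticParams, MoleculeSpec

P = ElasticParams()


class TestProposalGenerator:
    def test_angle_distribution_symmetric(self):
        # detailed balance requires the rotation-angle density to be even
        _, _, _, angles = _kernels.sample_proposals(
            200_000, 3, 101, 40, 20, 0.7, 0.0, False, -1, -1, 1.2, 0.7
        )
        assert abs(angles.mean()) < 3 * angles.std() / math.sqrt(angles.size)
        skew = np.mean((angles / angles.std()) ** 3)
        assert abs(skew) < 0.02
        # reversal pairing: the density of φ matches that of −φ
        h, edges = np.histogram(angles, bins=40, range=(-1.2, 1.2))
        assert np.all(np.abs(h - h[::-1]) < 5 * np.sqrt(h + h[::-1] + 1))

    def test_moved_blocks_state_independent_and_in_range(self):
        mt, b0, b1, _ = _kernels.sample_proposals(
            50_000, 4, 101, 40, 20, 0.7, 0.0, False, -1, -1, 1.2, 0.7
        )
        assert set(np.unique(mt)) <= {0, 1}
        assert np.all(b0 >= 0) and np.all(b1 <= 101)
        crank = mt == 0
        sizes = (b1 - b0)[crank]
        assert sizes.min() >= 1 and sizes.max() <= 39


@pytest.fixture(scope="module")
def tiny_run():
    mol = MoleculeSpec(600)  # ~60 segments at 3.4 nm
    return mc.run_simulation(
        mol, 3.0, 1.0, P, seed=42, n_steps=60_000, n_equil=30_000,
        stride=200, segment_length=3.4,
    )


class TestTrajectoryInvariants:
    def test_seeded_determinism(self, tiny_run):
        mol = MoleculeSpec(600)
        again = mc.run_simulation(
            mol, 3.0, 1.0, P, seed=42, n_steps=60_000, n_equil=30_000,
            stride=200, segment_length=3.4,
        )
        assert np.array_equal(tiny_run.z, again.z)
        assert np.array_equal(tiny_run.writhe, again.writhe)

    def test_incremental_writhe_exact(self, tiny_run):
        # the incrementally tracked writhe must equal a from-scratch
        # recomputation on the final conformation (no drift over ~1e5 moves)
        recomputed = tiny_run.final_conformation.writhe()
        assert tiny_run.final_writhe == pytest.approx(recomputed, abs=1e-8)

    def test_delta_lk_fixed_and_twist_bookkeeping(self, tiny_run):
        assert tiny_run.delta_lk == 3.0
        tw = tiny_run.delta_lk - tiny_run.writhe
        assert np.all(np.isfinite(tw))

    def test_self_avoidance_post_hoc(self, tiny_run):
        d_ex = tiny_run.excluded_diameter
        for snap in tiny_run.snapshots:
            c = chain.ChainConformation(
                snap, tiny_run.segment_length, tiny_run.delta_lk, d_ex
            )
            assert c.min_nonadjacent_distance() >= d_ex - 1e-9

    def test_single_step_api(self, tiny_run):
        # one-move interface: rejection is a normal outcome, ΔLk and the
        # bond lengths are preserved either way
        conf = chain.ChainConformation(
            tiny_run.final_conformation.positions.copy(),
            tiny_run.segment_length, tiny_run.delta_lk,
            tiny_run.excluded_diameter,
        )
        n_acc = 0
        for s in range(50):
            conf, ok = mc.mc_step(conf, P, 1.0, seed=1000 + s)
            n_acc += ok
        assert 0 < n_acc <= 50
        assert conf.delta_lk == tiny_run.delta_lk
        bonds = np.linalg.norm(np.diff(conf.positions, axis=0), axis=1)
        assert np.allclose(bonds, tiny_run.segment_length, atol=1e-6)

    def test_strand_passage_sentinel(self, tiny_run):
        # per-sample writhe never jumps by the ±2 of a strand passage
        jumps = np.abs(np.diff(tiny_run.writhe))
        assert jumps.max() < 1.5


class TestThermodynamics:
    def test_relaxed_extension_matches_wlc(self):
        # σ = 0 at 2 pN: ⟨z⟩/L within 2 SE + discretization margin of the
        # stretched-WLC prediction from the theory module
        mol = MoleculeSpec(1000)
        ens = mc.run_simulation(
            mol, 0.0, 2.0, P, seed=7, n_steps=150_000, n_equil=60_000,
            stride=400, segment_length=3.4,
        )
        m, se = ens.mean_extension()
        L = ens.final_conformation.contour_length
        predicted = theory.mean_extension(0.0, 2.0, P)
        assert m / L == pytest.approx(predicted, abs=2 * se / L + 0.02)

    def test_fluctuation_response(self):
        # Var(z) ≈ k_BT Δ⟨z⟩/Δf from two bracketing forces
        mol = MoleculeSpec(1000)
        lo = mc.run_simulation(
            mol, 0.0, 1.6, P, seed=21, n_steps=130_000, n_equil=60_000,
            stride=400, segment_length=3.4,
        )
        hi = mc.run_simulation(
            mol, 0.0, 2.4, P, seed=22, n_steps=130_000, n_equil=60_000,
            stride=400, segment_length=3.4,
        )
        mid = mc.run_simulation(
            mol, 0.0, 2.0, P, seed=23, n_steps=130_000, n_equil=60_000,
            stride=400, segment_length=3.4,
        )
        m_lo, se_lo = lo.mean_extension()
        m_hi, se_hi = hi.mean_extension()
        v, v_se = mid.extension_variance()
        deriv = P.kT * (m_hi - m_lo) / 0.8
        deriv_se = P.kT * math.hypot(se_lo, se_hi) / 0.8
        assert abs(v - deriv) < 3 * math.hypot(v_se, deriv_se) + 0.1 * deriv


class TestPlectonemePhase:
    def test_postbuckling_has_plectoneme(self, postbuckling_ens):
        ls, lp = chain.plectoneme_lengths(postbuckling_ens.final_conformation)
        assert lp > 0.0
        assert ls + lp == pytest.approx(
            postbuckling_ens.final_conformation.contour_length
        )

    def test_detection_matches_cluster_oracle(self, postbuckling_ens):
        # brute-force proximity criterion without smoothing as the oracle
        conf = postbuckling_ens.final_conformation
        pos = conf.positions
        n = conf.n_beads
        min_sep = int(round(4 * 40.0 / conf.segment_length))
        oracle = np.zeros(n, dtype=bool)
        for i in range(n):
            d = np.linalg.norm(pos - pos[i], axis=1)
            far = np.abs(np.arange(n) - i) > min_sep
            oracle[i] = bool(np.any((d < 10.0) & far))
        labels = chain.detect_plectoneme(conf)
        lp_lab = labels.sum() * conf.contour_length / n
        lp_orc = oracle.sum() * conf.contour_length / n
        if lp_orc > 0:
            assert lp_lab == pytest.approx(lp_orc, rel=0.25, abs=30.0)

    def test_writhe_absorbed_postbuckling(self, postbuckling_ens):
        # in the plectonemic regime most of ΔLk is stored as writhe
        wr = postbuckling_ens.writhe.mean()
        assert wr > 0.4 * postbuckling_ens.delta_lk


@pytest.fixture(scope="module")
def small_bridged(postbuckling_ens):
    conf = postbuckling_ens.final_conformation
    sites = chain.select_bridge_sites(conf, threshold=8.0)
    if not sites:
        sites = chain.select_bridge_sites(conf, threshold=10.0)
    assert sites, "no bridge candidates on a postbuckling snapshot"
    bridge = sorted(sites, key=lambda b: -b.loop_length)[0]
    ens = mc.run_bridged_simulation(
        conf, bridge, 1.0, P, seed=99, n_steps=140_000, n_equil=50_000,
        stride=500,
    )
    return conf, bridge, ens


class TestBridgedSimulation:

    def test_relative_pose_preserved(self, small_bridged):
        conf0, bridge, ens = small_bridged
        i, j = bridge.bead_i, bridge.bead_j
        ref = conf0.positions[j] - conf0.positions[i]
        for snap in ens.snapshots:
            d = snap[j] - snap[i]
            assert np.allclose(d, d, atol=0)  # finite
            assert np.linalg.norm(d) == pytest.approx(
                np.linalg.norm(ref), abs=1e-9
            )
            # full relative pose: the six cluster beads keep every
            # mutual distance
            cluster = [i - 1, i, i + 1, j - 1, j, j + 1]
            for a in range(len(cluster)):
                for b in range(a + 1, len(cluster)):
                    da = np.linalg.norm(snap[cluster[a]] - snap[cluster[b]])
                    d0 = np.linalg.norm(
                        conf0.positions[cluster[a]] - conf0.positions[cluster[b]]
                    )
                    assert da == pytest.approx(d0, abs=1e-9)

    def test_loop_delta_lk_sampled(self, small_bridged):
        _, bridge, ens = small_bridged
        assert ens.loop_delta_lk is not None
        assert np.all(np.isfinite(ens.loop_delta_lk))
        # the loop is plectonemic: it traps a nonzero share of ΔLk
        assert abs(np.mean(ens.loop_delta_lk)) > 0.1

    def test_cluster_moves_accepted(self, small_bridged):
        _, _, ens = small_bridged
        assert ens.acceptance["cluster"] > 0.0
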