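"""Shared fixtures: Monte Carlo ensembles and synthetic traces.

The MC fixtures are the expensive part of the suite; they are session
scoped and sized to desk scale (chains of ~2 kbp, 10⁵–10⁶ Monte Carlo
steps) so the whole suite stays within a desktop run.
"""

import numpy as np
import pytest

from plectonemics import analysis, chain, mc, synth
from plectonemics.params import ElasticParams, MoleculeSpec

PARAMS = ElasticParams()

# desk-scale study conditions for the f = 0.5 pN rotation series: the
# ladder spans the variance-rise region (σ ≈ 0.026–0.045) and the
# asymptotic linear extension branch (σ ≈ 0.042–0.060)
ROTATION_NBP = 2000
ROTATION_DLKS = [5.0, 6.2, 7.4, 8.6, 9.8, 11.4]
ROTATION_FORCE = 0.5
ROTATION_SEG = 3.4
# σ above which the extension branch is fitted (past the finite-size
# rounded buckling shoulder) and up to which the variance still rises
SLOPE_SIGMA_MIN = 7.4 / (2000 / 10.5) - 1e-9
VAR_SIGMA_MAX = 8.6 / (2000 / 10.5) + 1e-9


@pytest.fixture(scope="session")
def postbuckling_ens():
    """Small equilibrated postbuckling ensemble (1.5 kbp, σ≈0.063, 1 pN).

    Deep enough in the plectonemic regime that the superhelix exceeds the
    4A contour-separation detection threshold on this short chain."""
    mol = MoleculeSpec(1500)
    return mc.run_simulation(
        mol,
        9.0,
        1.0,
        PARAMS,
        seed=101,
        n_steps=200_000,
        n_equil=200_000,
        stride=500,
        segment_length=3.4,
        start="plectoneme",
    )


@pytest.fixture(scope="session")
def rotation_series_f05():
    """Annealed ΔLk series of a 2 kbp chain at 0.5 pN (postbuckling)."""
    mol = MoleculeSpec(ROTATION_NBP)
    return mc.run_rotation_series(
        mol,
        ROTATION_DLKS,
        ROTATION_FORCE,
        PARAMS,
        seed=2718,
        n_steps=160_000,
        n_equil_first=280_000,
        n_equil=70_000,
        stride=400,
        segment_length=ROTATION_SEG,
        start="straight",
        max_block=80,
        max_pivot=100,
    )


@pytest.fixture(scope="session")
def rotation_curve_f05(rotation_series_f05):
    mol = MoleculeSpec(ROTATION_NBP)
    return analysis.rotation_curve_from_ensembles(rotation_series_f05, mol)


@pytest.fixture(scope="session")
def slope_sigma_min():
    """σ above which the extension branch is fitted (past the shoulder)."""
    return SLOPE_SIGMA_MIN


@pytest.fixture(scope="session")
def var_sigma_max():
    """σ up to which the variance still rises linearly for this chain."""
    return VAR_SIGMA_MAX


@pytest.fixture(scope="session")
def bridged_runs(rotation_series_f05):
    """Bridged ensembles at fixed σ for three loop sizes, plus baseline.

    Bridge sites are selected on the deepest postbuckling conformation of
    the rotation series that offers juxtaposed opposite strands; the
    unconstrained continuation of the same snapshot serves as the
    before-bridging baseline.
    """
    # search the deepest-σ conformations first: their plectonemes are the
    # largest and always carry juxtaposed opposite strands
    conf = None
    sites: list = []
    for ens in sorted(rotation_series_f05, key=lambda e: -e.delta_lk):
        cand_conf = ens.final_conformation
        for thr, factor in ((8.0, 4.0), (10.0, 4.0), (10.0, 3.0)):
            labels = chain.detect_plectoneme(
                cand_conf, min_contour_factor=factor
            )
            sites = chain.select_bridge_sites(
                cand_conf, threshold=thr, labels=labels
            )
            if sites:
                break
        if sites:
            conf = cand_conf
            base = ens
            break
    assert sites, "no bridge candidates on any postbuckling conformation"
    # spread loop sizes from small to near-full plectoneme
    sites = sorted(sites, key=lambda b: b.loop_length)
    want = np.linspace(0.15, 0.85, 3) * max(s.loop_length for s in sites)
    chosen = []
    for w in want:
        s = min(sites, key=lambda b: abs(b.loop_length - w))
        if s not in chosen:
            chosen.append(s)
    runs = []
    for k, s in enumerate(chosen):
        runs.append(
            mc.run_bridged_simulation(
                conf,
                s,
                ROTATION_FORCE,
                PARAMS,
                seed=515 + k,
                n_steps=160_000,
                n_equil=45_000,
                stride=400,
                max_block=80,
                max_pivot=100,
            )
        )
    baseline = mc.run_simulation(
        MoleculeSpec(ROTATION_NBP),
        base.delta_lk,
        ROTATION_FORCE,
        PARAMS,
        seed=414,
        n_steps=160_000,
        n_equil=45_000,
        stride=400,
        segment_length=ROTATION_SEG,
        initial=conf,
        max_block=80,
        max_pivot=100,
    )
    return {"baseline": baseline, "bridged": runs}


@pytest.fixture(scope="session")
def kinetics_trace():
    """Long synthetic switching trace mirroring the loop-kinetics study
    conditions (48 nm spacing, τ_p = 65 s, P = 20 nm, ΔL = 254 nm)."""
    base = synth.TraceModel(
        mean=800.0,
        variance=300.0,
        corr_time=0.01,
        acquisition_rate=1000.0,
        duration=16000.0,
    )
    sw = synth.SwitchingModel(
        loop_length=254.0,
        plectoneme_stiffness=20.0,
        level_spacing=48.0,
        rebinding_time=65.0,
        n_levels=5,
    )
    trace = synth.generate_switching_trace(sw, base, seed=808)
    return {"trace": trace, "switching": sw, "base": base}


@pytest.fixture(scope="session")
def kinetics_statemodel(kinetics_trace):
    tr = kinetics_trace["trace"]
    et = analysis.ExtensionTrace(
        tr.time, tr.z, tr.acquisition_rate, force=0.5, sigma=0.04
    )
    return analysis.segment_states(et, filter_window_s=10.0)
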