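"""Synthetic magnetic-tweezers data: extension traces and rotation curves.

Bead-tracking traces of a DNA tether in a harmonic well are emulated as an
Ornstein–Uhlenbeck (OU) process whose stationary variance ⟨Δz²⟩ and
correlation time τ_c are related to the friction coefficient γ through
τ_c = (γ/k_BT)·⟨Δz²⟩. Protein-bridging dynamics are emulated as a
continuous-time Markov chain over discrete linking-number states of the
looped domain: leave events occur at rate 1/τ_p and the destination state
is drawn from the equilibrium occupancies p_i (self-transitions allowed),
which produces observed per-state dwell times τ_i = τ_p/(1 − p_i).

All generators are seeded and return the ground truth alongside the
observations so that every stage of the analysis pipeline can be tested
without instrument data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .params import ElasticParams, MoleculeSpec
from . import theory

__all__ = [
    "TraceModel",
    "SwitchingModel",
    "SyntheticTrace",
    "RotationCurveData",
    "generate_ou_trace",
    "generate_switching_trace",
    "generate_rotation_dataset",
]


@dataclass(frozen=True)
class TraceModel:
    """Stationary harmonic-well model of a tracked bead.

    ``friction`` (pN·s/nm) is derived from τ_c = γ⟨Δz²⟩/k_BT and therefore
    always consistent with the variance/correlation-time pair.
    """

    mean: float
    variance: float
    corr_time: float
    acquisition_rate: float = 1000.0
    duration: float = 10.0
    temperature: float = 298.0

    def __post_init__(self) -> None:
        if self.variance <= 0 or self.corr_time <= 0:
            raise ValueError("variance and corr_time must be positive")
        if self.acquisition_rate <= 0 or self.duration <= 0:
            raise ValueError("acquisition_rate and duration must be positive")
        if self.acquisition_rate * self.duration < 1e3:
            raise ValueError("trace must contain at least 1000 samples")

    @property
    def kT(self) -> float:
        from .params import KB

        return KB * self.temperature

    @property
    def friction(self) -> float:
        """γ = k_BT·τ_c/⟨Δz²⟩ (pN·s/nm)."""
        return self.kT * self.corr_time / self.variance

    @property
    def n_samples(self) -> int:
        return int(round(self.acquisition_rate * self.duration))


@dataclass(frozen=True)
class SwitchingModel:
    """Markov switching among discrete loop linking-number states.

    ``levels`` are the ΔΔLk values of the states (integers, turns);
    occupancies follow a Gaussian in ΔΔLk of variance ΔL/(4π²P) and the
    extension of state k is ``base_mean − spacing·ΔΔLk_k`` (adding a turn
    to the loop frees a turn to the unlooped plectoneme, shortening the
    tether by one per-turn slope).
    """

    loop_length: float = 254.0
    plectoneme_stiffness: float = 20.0
    level_spacing: float = 48.0
    rebinding_time: float = 65.0
    n_levels: int = 5

    def __post_init__(self) -> None:
        if self.n_levels < 1 or self.n_levels % 2 == 0:
            raise ValueError("n_levels must be a positive odd integer")
        if min(
            self.loop_length,
            self.plectoneme_stiffness,
            self.level_spacing,
            self.rebinding_time,
        ) <= 0:
            raise ValueError("all switching parameters must be positive")

    @property
    def levels(self) -> np.ndarray:
        half = self.n_levels // 2
        return np.arange(-half, half + 1)

    @property
    def lk_variance(self) -> float:
        """⟨(ΔΔLk)²⟩ = ΔL/(4π²P) of the untruncated Gaussian."""
        return self.loop_length / (
            4.0 * math.pi**2 * self.plectoneme_stiffness
        )

    @property
    def occupancies(self) -> np.ndarray:
        p = np.exp(-self.levels.astype(float) ** 2 / (2.0 * self.lk_variance))
        return p / p.sum()

    def dwell_times(self) -> np.ndarray:
        """Observed mean dwell time per state, τ_i = τ_p/(1 − p_i)."""
        return self.rebinding_time / (1.0 - self.occupancies)


@dataclass
class SyntheticTrace:
    """A generated extension trace plus its ground truth."""

    time: np.ndarray
    z: np.ndarray
    acquisition_rate: float
    force: float = float("nan")
    sigma: float = float("nan")
    state_path: np.ndarray | None = None
    state_levels: np.ndarray | None = None
    label: str = "synthetic"


def _ou_exact(
    n: int, mean: float, variance: float, rho: float, rng: np.random.Generator
) -> np.ndarray:
    """Exact-discretization stationary OU samples (AR(1) recursion)."""
    innov = rng.standard_normal(n) * math.sqrt(variance * (1.0 - rho * rho))
    innov[0] = rng.standard_normal() * math.sqrt(variance)
    # x_t = rho x_{t-1} + innov_t  via an IIR filter (vectorized recursion)
    x = signal.lfilter([1.0], [1.0, -rho], innov)
    return mean + x


def generate_ou_trace(model: TraceModel, seed: int) -> SyntheticTrace:
    """Stationary OU trace at the model's acquisition rate.

    The first sample is already drawn from the stationary distribution, and
    the lag-1 autocorrelation is exactly exp(−Δt/τ_c).
    """
    rng = np.random.default_rng(seed)
    n = model.n_samples
    dt = 1.0 / model.acquisition_rate
    rho = math.exp(-dt / model.corr_time)
    z = _ou_exact(n, model.mean, model.variance, rho, rng)
    t = np.arange(n) * dt
    return SyntheticTrace(time=t, z=z, acquisition_rate=model.acquisition_rate)


def generate_switching_trace(
    switching: SwitchingModel, base: TraceModel, seed: int
) -> SyntheticTrace:
    """Markov-switching trace with OU noise superposed.

    Returns the observed trace together with the ground-truth state path
    (per-sample level index into ``switching.levels``).
    """
    rng = np.random.default_rng(seed)
    n = base.n_samples
    dt = 1.0 / base.acquisition_rate
    duration = n * dt
    p = switching.occupancies
    levels = switching.levels

    # continuous-time jump process: leave events at rate 1/τ_p, destination
    # drawn from the occupancies (self-transitions allowed)
    t_events = [0.0]
    s_events = [int(rng.choice(levels.size, p=p))]
    t_now = 0.0
    while t_now < duration:
        t_now += rng.exponential(switching.rebinding_time)
        t_events.append(t_now)
        s_events.append(int(rng.choice(levels.size, p=p)))
    t_events = np.array(t_events)
    s_events = np.array(s_events)

    t = np.arange(n) * dt
    state_idx = s_events[np.searchsorted(t_events, t, side="right") - 1]
    level_means = base.mean - switching.level_spacing * levels.astype(float)

    rho = math.exp(-dt / base.corr_time)
    noise = _ou_exact(n, 0.0, base.variance, rho, rng)
    z = level_means[state_idx] + noise
    return SyntheticTrace(
        time=t,
        z=z,
        acquisition_rate=base.acquisition_rate,
        state_path=state_idx,
        state_levels=levels,
    )


@dataclass
class RotationCurveData:
    """⟨z⟩ and ⟨Δz²⟩ versus σ at one force (theory truth plus noisy copy)."""

    sigma: np.ndarray
    z_mean: np.ndarray
    z_var: np.ndarray
    z_true: np.ndarray
    var_true: np.ndarray
    force: float
    contour_length: float
    sigma_s: float
    sigma_p: float
    kappa: float


def generate_rotation_dataset(
    forces,
    sigma_max_frac: float = 0.9,
    n_sigma: int = 30,
    molecule: MoleculeSpec | None = None,
    params: ElasticParams | None = None,
    rel_noise: float = 0.02,
    seed: int = 0,
) -> list[RotationCurveData]:
    """Theory rotation curves with additive Gaussian measurement noise.

    σ runs from 0 to ``sigma_max_frac``·σ_p at each force. ``rel_noise`` is
    the noise SD relative to the largest value of each observable; zero
    noise returns the theory curves exactly.
    """
    params = params or ElasticParams()
    molecule = molecule or MoleculeSpec(7900)
    rng = np.random.default_rng(seed)
    L = molecule.contour_length
    out = []
    for f in np.atleast_1d(forces):
        coex = theory.solve_coexistence(float(f), params)
        sig = np.linspace(0.0, sigma_max_frac * coex.sigma_p, n_sigma)
        z = np.array([theory.mean_extension(s, float(f), params) * L for s in sig])
        v = np.array(
            [theory.extension_variance(s, float(f), params) * L for s in sig]
        )
        z_obs = z + rng.standard_normal(z.size) * rel_noise * np.max(np.abs(z))
        v_obs = v + rng.standard_normal(v.size) * rel_noise * np.max(np.abs(v))
        out.append(
            RotationCurveData(
                sigma=sig,
                z_mean=z_obs,
                z_var=v_obs,
                z_true=z,
                var_true=v,
                force=float(f),
                contour_length=L,
                sigma_s=coex.sigma_s,
                sigma_p=coex.sigma_p,
                kappa=coex.kappa,
            )
        )
    return out
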