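"""Analytical theory of stretched, overwound DNA: prebuckling elasticity and
two-phase (stretched/plectonemic) coexistence.

The molecule is described by free energies per unit length (units of force,
pN): a stretched phase

    S(σ; f) = −g(f) + ½ k_BT c_s(f) ω0² σ²,

with ``g(f) = f − √(k_BT f / A)`` the high-force wormlike-chain free energy
gain and ``c_s(f) = C·[1 − (C/4A)·√(k_BT/(A f))]`` the force-renormalized
(Moroz–Nelson) twist persistence length, and a plectonemic phase

    P(σ) = ½ k_BT P ω0² σ²,

with constant torsional stiffness ``P``. Beyond the buckling density σ_s the
equilibrium free energy is the double tangent between the two branches,
linear in σ; mean extension and extension variance follow by force
differentiation,

    ⟨z⟩/L = −dF/df,      ⟨Δz²⟩/L = −k_BT d²F/df² = k_BT d(⟨z⟩/L)/df.

On the coexistence branch ⟨z⟩/L = Γ(f)·(σ_p − σ) and the variance grows
linearly in σ, reaching κ = k_BT Γ ∂σ_p/∂f at σ = σ_p.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import optimize

from .params import ElasticParams, MoleculeSpec

__all__ = [
    "NoCoexistenceError",
    "FullyPlectonemicError",
    "PhaseCoexistence",
    "supercoiling_density",
    "linking_difference",
    "stretched_free_energy",
    "plectoneme_free_energy",
    "free_energy",
    "solve_coexistence",
    "mean_extension",
    "extension_variance",
    "fit_scaling_exponent",
    "prebuckling_curvatures",
    "postbuckling_slopes",
]


class NoCoexistenceError(ValueError):
    """The double-tangent construction is degenerate at this force.

    Coexistence requires the stretched phase to be torsionally stiffer than
    the plectonemic one (c_s(f) > P) and a positive stretching free energy.
    """


class FullyPlectonemicError(ValueError):
    """σ exceeds σ_p: the molecule is fully plectonemic (not modelled)."""


# ---------------------------------------------------------------------------
# scalar building blocks


def _g(f: float, p: ElasticParams) -> float:
    """Stretched-WLC free energy gain per length (pN), high-force expansion."""
    return f - math.sqrt(p.kT * f / p.bend_persistence)


def _dg_df(f: float, p: ElasticParams) -> float:
    return 1.0 - 0.5 * math.sqrt(p.kT / (p.bend_persistence * f))


def _cs(f: float, p: ElasticParams) -> float:
    """Force-renormalized twist persistence length c_s(f) (nm)."""
    A, C = p.bend_persistence, p.twist_persistence
    return C * (1.0 - (C / (4.0 * A)) * math.sqrt(p.kT / (A * f)))


def _dcs_df(f: float, p: ElasticParams) -> float:
    A, C = p.bend_persistence, p.twist_persistence
    return C * (C / (8.0 * A)) * math.sqrt(p.kT / A) * f ** -1.5


def _check_force(f: float) -> None:
    if not f > 0.0:
        raise ValueError("force must be strictly positive (pN)")


# ---------------------------------------------------------------------------
# σ ↔ ΔLk bookkeeping


def supercoiling_density(delta_lk: float, molecule: MoleculeSpec) -> float:
    """Supercoiling density σ = ΔLk/Lk0 (dimensionless)."""
    lk0 = molecule.lk0
    if not lk0 > 0.0:
        raise ValueError("relaxed linking number Lk0 must be positive")
    return delta_lk / lk0


def linking_difference(sigma: float, molecule: MoleculeSpec) -> float:
    """Inverse of :func:`supercoiling_density`: ΔLk = σ·Lk0 (turns)."""
    lk0 = molecule.lk0
    if not lk0 > 0.0:
        raise ValueError("relaxed linking number Lk0 must be positive")
    return sigma * lk0


# ---------------------------------------------------------------------------
# phase free energies


def stretched_free_energy(sigma: float, f: float, params: ElasticParams) -> float:
    """Free energy per length S(σ; f) of the stretched phase (pN)."""
    _check_force(f)
    return (
        -_g(f, params)
        + 0.5 * params.kT * _cs(f, params) * params.omega0**2 * sigma**2
    )


def plectoneme_free_energy(sigma: float, params: ElasticParams) -> float:
    """Free energy per length P(σ) of the plectonemic phase (pN).

    Quadratic in σ with constant stiffness P; independent of force.
    """
    return (
        0.5
        * params.kT
        * params.plectoneme_stiffness
        * params.omega0**2
        * sigma**2
    )


# ---------------------------------------------------------------------------
# double tangent construction


@dataclass(frozen=True)
class PhaseCoexistence:
    """Result of the double-tangent construction at a given force.

    Attributes
    ----------
    sigma_s, sigma_p :
        Supercoiling densities of the coexisting stretched and plectonemic
        phases (buckling onset and full-plectoneme densities).
    gamma :
        Force-dependent prefactor Γ: slope of ⟨z⟩/L versus σ postbuckling.
    kappa :
        κ = k_BT Γ ∂σ_p/∂f (nm² of variance per nm of contour length),
        the variance-per-length limit at σ → σ_p.
    force :
        Applied force (pN).
    """

    sigma_s: float
    sigma_p: float
    gamma: float
    kappa: float
    force: float

    def stretched_fraction(self, sigma: float) -> float:
        """Fraction ν of the molecule in the stretched phase at density σ."""
        if sigma <= self.sigma_s:
            return 1.0
        if sigma > self.sigma_p:
            raise FullyPlectonemicError(
                f"sigma={sigma:.4f} exceeds sigma_p={self.sigma_p:.4f}"
            )
        return (self.sigma_p - sigma) / (self.sigma_p - self.sigma_s)


def _coexistence_closed_form(f: float, p: ElasticParams) -> tuple[float, float]:
    ct_s = p.kT * _cs(f, p) * p.omega0**2
    ct_p = p.kT * p.plectoneme_stiffness * p.omega0**2
    g = _g(f, p)
    if ct_s <= ct_p or g <= 0.0:
        raise NoCoexistenceError(
            "degenerate double tangent: requires c_s(f) > P and g(f) > 0 "
            f"(c_s={_cs(f, p):.3f} nm, P={p.plectoneme_stiffness:.3f} nm, "
            f"g={g:.4f} pN at f={f:.3f} pN)"
        )
    sigma_p = math.sqrt(2.0 * g / (ct_p * (1.0 - ct_p / ct_s)))
    sigma_s = (ct_p / ct_s) * sigma_p
    return sigma_s, sigma_p


def _tangency_residual(x: np.ndarray, f: float, p: ElasticParams) -> np.ndarray:
    """Defining equations of the common tangent between S and P."""
    ss, sp = x
    ct_s = p.kT * _cs(f, p) * p.omega0**2
    ct_p = p.kT * p.plectoneme_stiffness * p.omega0**2
    slope_s = ct_s * ss
    slope_p = ct_p * sp
    chord = (
        plectoneme_free_energy(sp, p) - stretched_free_energy(ss, f, p)
    ) / (sp - ss)
    return np.array([slope_s - slope_p, slope_s - chord])


def _coexistence_grid_search(
    f: float, p: ElasticParams, n: int = 400
) -> tuple[float, float]:
    """Brute-force fallback: minimize the mixed free energy at a probe σ."""
    hi = 0.5
    grid = np.linspace(1e-4, hi, n)
    best = (math.inf, 0.0, 0.0)
    for ss in grid:
        sp = grid[grid > ss + 1e-3]
        if sp.size == 0:
            continue
        probe = 0.5 * (ss + sp)  # midpoints keep ν well inside (0, 1)
        nu = (sp - probe) / (sp - ss)
        fmix = nu * stretched_free_energy(ss, f, p) + (1 - nu) * np.array(
            [plectoneme_free_energy(s, p) for s in sp]
        )
        k = int(np.argmin(fmix))
        if fmix[k] < best[0]:
            best = (fmix[k], ss, sp[k])
    if not math.isfinite(best[0]):
        raise NoCoexistenceError(f"no coexistence found at f={f} pN")
    return best[1], best[2]


def _gamma(f: float, sigma_s: float, sigma_p: float, p: ElasticParams) -> float:
    """Γ from the extension of the stretched phase at σ_s (envelope theorem)."""
    z_s = _dg_df(f, p) - 0.5 * p.omega0**2 * sigma_s**2 * p.kT * _dcs_df(f, p)
    return z_s / (sigma_p - sigma_s)


def solve_coexistence(f: float, params: ElasticParams) -> PhaseCoexistence:
    """Solve the stretched/plectonemic double tangent at force ``f``.

    Newton refinement of the two tangency conditions, initialized from the
    closed-form solution of the quadratic model; falls back to a grid search
    if Newton strays. Raises :class:`NoCoexistenceError` when the tangent is
    degenerate (no buckling at this force for these parameters).
    """
    _check_force(f)
    x0 = np.array(_coexistence_closed_form(f, params))
    sol = optimize.root(_tangency_residual, x0, args=(f, params), tol=1e-12)
    if sol.success and 0.0 < sol.x[0] < sol.x[1]:
        sigma_s, sigma_p = float(sol.x[0]), float(sol.x[1])
    else:  # pragma: no cover - quadratic model never reaches this branch
        sigma_s, sigma_p = _coexistence_grid_search(f, params)

    gamma = _gamma(f, sigma_s, sigma_p, params)

    # κ = k_BT Γ ∂σ_p/∂f by Richardson-refined central differences.
    def sp_of_f(force: float) -> float:
        ss, sp = _coexistence_closed_form(force, params)
        return sp

    dsp_df = _central_derivative(sp_of_f, f, 1e-3 * f)
    kappa = params.kT * gamma * dsp_df
    return PhaseCoexistence(
        sigma_s=sigma_s, sigma_p=sigma_p, gamma=gamma, kappa=kappa, force=f
    )


# ---------------------------------------------------------------------------
# observables


def free_energy(sigma: float, f: float, params: ElasticParams) -> float:
    """Equilibrium free energy per length F(σ; f) (pN), both branches.

    Prebuckling (σ ≤ σ_s) this is S(σ; f); on the coexistence branch it is
    the double-tangent mixture, linear in σ.
    """
    if sigma < 0.0:
        raise ValueError("underwound DNA (σ < 0) is out of scope")
    coex = solve_coexistence(f, params)
    if sigma <= coex.sigma_s:
        return stretched_free_energy(sigma, f, params)
    if sigma > coex.sigma_p:
        raise FullyPlectonemicError(
            f"sigma={sigma:.4f} beyond sigma_p={coex.sigma_p:.4f}"
        )
    nu = coex.stretched_fraction(sigma)
    return nu * stretched_free_energy(
        coex.sigma_s, f, params
    ) + (1.0 - nu) * plectoneme_free_energy(coex.sigma_p, params)


def mean_extension(sigma: float, f: float, params: ElasticParams) -> float:
    """Fractional mean extension ⟨z⟩/L at supercoiling density σ ≥ 0."""
    if sigma < 0.0:
        raise ValueError("underwound DNA (σ < 0) is out of scope")
    _check_force(f)
    coex = solve_coexistence(f, params)
    if sigma > coex.sigma_p:
        raise FullyPlectonemicError(
            f"sigma={sigma:.4f} beyond sigma_p={coex.sigma_p:.4f}: the fully "
            "plectonemic regime is not modelled"
        )
    if sigma <= coex.sigma_s:
        return (
            _dg_df(f, params)
            - 0.5 * params.omega0**2 * sigma**2 * params.kT * _dcs_df(f, params)
        )
    return coex.gamma * (coex.sigma_p - sigma)


def _central_derivative(fun: Callable[[float], float], x: float, h: float) -> float:
    """Central difference with one Richardson refinement step."""
    d1 = (fun(x + h) - fun(x - h)) / (2.0 * h)
    h2 = 0.5 * h
    d2 = (fun(x + h2) - fun(x - h2)) / (2.0 * h2)
    return (4.0 * d2 - d1) / 3.0


def extension_variance(sigma: float, f: float, params: ElasticParams) -> float:
    """Extension variance per length ⟨Δz²⟩/L (nm) at density σ ≥ 0.

    Computed as k_BT ∂(⟨z⟩/L)/∂f (the fluctuation–response route) by
    central differences with Richardson refinement, differentiating each
    branch's own extension expression: the prebuckling branch directly,
    and the coexistence branch through Γ(f) and σ_p(f) so that the
    evaluation remains valid up to σ = σ_p, where the variance per length
    reaches κ = k_BT Γ ∂σ_p/∂f.
    """
    coex = solve_coexistence(f, params)  # validates force; flags σ > σ_p below
    if sigma < 0.0:
        raise ValueError("underwound DNA (σ < 0) is out of scope")
    if sigma > coex.sigma_p:
        raise FullyPlectonemicError(
            f"sigma={sigma:.4f} beyond sigma_p={coex.sigma_p:.4f}"
        )
    h = 1e-3 * f
    if sigma <= coex.sigma_s:

        def z_pre(force: float) -> float:
            return (
                _dg_df(force, params)
                - 0.5
                * params.omega0**2
                * sigma**2
                * params.kT
                * _dcs_df(force, params)
            )

        return params.kT * _central_derivative(z_pre, f, h)

    def gamma_of_f(force: float) -> float:
        ss, sp = _coexistence_closed_form(force, params)
        return _gamma(force, ss, sp, params)

    def sp_of_f(force: float) -> float:
        return _coexistence_closed_form(force, params)[1]

    dgamma = _central_derivative(gamma_of_f, f, h)
    dsp = _central_derivative(sp_of_f, f, h)
    return params.kT * (
        dgamma * (coex.sigma_p - sigma) + coex.gamma * dsp
    )


# ---------------------------------------------------------------------------
# force scalings


def fit_scaling_exponent(
    forces: Sequence[float], values: Sequence[float]
) -> float:
    """Least-squares slope of log|value| versus log(force).

    Requires at least four strictly positive force/|value| pairs.
    """
    f = np.asarray(forces, dtype=float)
    v = np.abs(np.asarray(values, dtype=float))
    if f.size < 4:
        raise ValueError("need at least 4 force/value pairs")
    if np.any(f <= 0.0) or np.any(v <= 0.0):
        raise ValueError("forces and |values| must be strictly positive")
    slope, _ = np.polyfit(np.log(f), np.log(v), 1)
    return float(slope)


def prebuckling_curvatures(
    f: float, params: ElasticParams, sigma_probe: float = 5e-3
) -> tuple[float, float]:
    """Curvatures d²/dσ² of ⟨z⟩/L and ⟨Δz²⟩/L at σ = 0 (prebuckling).

    Evaluated by a central second difference at ±``sigma_probe``; both are
    exact for the quadratic prebuckling model. Expected to scale as f^(−3/2)
    and f^(−5/2) at large force.
    """
    coex = solve_coexistence(f, params)
    h = min(sigma_probe, 0.4 * coex.sigma_s)
    curv_z = (
        mean_extension(h, f, params)
        - 2.0 * mean_extension(0.0, f, params)
        + mean_extension(h, f, params)
    ) / h**2  # even in σ: use mirrored point
    curv_v = (
        extension_variance(h, f, params)
        - 2.0 * extension_variance(0.0, f, params)
        + extension_variance(h, f, params)
    ) / h**2
    return float(curv_z), float(curv_v)


def postbuckling_slopes(f: float, params: ElasticParams) -> tuple[float, float]:
    """Slopes d/dσ of ⟨z⟩/L and ⟨Δz²⟩/L on the coexistence branch.

    The extension slope is −Γ(f); the variance slope is −k_BT ∂Γ/∂f
    (evaluated by central differences). Expected force scalings: f^(−1/2)
    and f^(−3/2).
    """
    coex = solve_coexistence(f, params)

    def gamma_of_f(force: float) -> float:
        c = solve_coexistence(force, params)
        return c.gamma

    dgamma_df = _central_derivative(gamma_of_f, f, 1e-3 * f)
    return float(-coex.gamma), float(-params.kT * dgamma_df)
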