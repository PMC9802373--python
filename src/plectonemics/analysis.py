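"""Fluctuation-analysis pipeline for supercoiled-DNA extension data.

From extension time traces and rotation (⟨z⟩, ⟨Δz²⟩ versus σ) curves this
module extracts: the buckling characterization (prebuckling curvature,
postbuckling slope), the σ_p/κ calibration by linear extrapolation of the
postbuckling branches, topological-domain sizes from variance drops
(ΔL = Δ⟨Δz²⟩/κ), the plectoneme torsional stiffness from the width of the
loop linking-number distribution (P = ΔL/(4π²⟨(ΔΔLk)²⟩)), and loop kinetics
(per-state dwell times τ_i and the intrinsic rebinding time
τ_p = (1 − p_i)·τ_i).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize, signal
from statsmodels.stats.diagnostic import lilliefors

from . import _kernels
from .params import ElasticParams, MoleculeSpec

__all__ = [
    "ExtensionTrace",
    "RotationCurve",
    "WindowedStats",
    "RotationFit",
    "FluctuationCalibration",
    "DomainSize",
    "StateModel",
    "DwellTimeResult",
    "windowed_stats",
    "autocorrelation_time",
    "fit_rotation_curve",
    "calibrate",
    "infer_domain_size",
    "mean_extension_change",
    "segment_states",
    "plectoneme_stiffness",
    "plectoneme_stiffness_from_samples",
    "dwell_time_analysis",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class ExtensionTrace:
    """Uniformly sampled extension time series at known force and σ."""

    time: np.ndarray
    z: np.ndarray
    acquisition_rate: float
    force: float = float("nan")
    sigma: float = float("nan")
    label: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if self.time.shape != self.z.shape or self.time.ndim != 1:
            raise ValueError("time and z must be 1-D arrays of equal length")
        if not self.acquisition_rate > 0:
            raise ValueError("acquisition_rate must be positive")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("trace contains non-finite extension values")
        if self.time.size >= 2:
            dt = np.diff(self.time)
            dt0 = 1.0 / self.acquisition_rate
            if np.any(dt <= 0):
                raise ValueError("time must be strictly increasing")
            if np.max(np.abs(dt - dt0)) > 1e-6 * dt0 + 1e-12:
                raise ValueError("sampling must be uniform at the stated rate")

    @property
    def n_samples(self) -> int:
        return self.z.size

    @property
    def duration(self) -> float:
        return self.n_samples / self.acquisition_rate


@dataclass
class RotationCurve:
    """⟨z⟩ and ⟨Δz²⟩ versus supercoiling density at one force."""

    sigma: np.ndarray
    z_mean: np.ndarray
    z_var: np.ndarray
    force: float
    contour_length: float
    lk0: float = float("nan")
    z_se: np.ndarray | None = None
    var_se: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sigma = np.asarray(self.sigma, dtype=float)
        if np.any(np.diff(self.sigma) <= 0):
            raise ValueError("sigma values must be strictly increasing")
        for name in ("z_se", "var_se"):
            v = getattr(self, name)
            if v is not None and np.any(np.asarray(v) <= 0):
                raise ValueError(f"{name} must be positive")


# ---------------------------------------------------------------------------
# trace statistics


@dataclass
class WindowedStats:
    """Non-overlapping window means/variances of a trace."""

    window_s: float
    times: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    pooled_mean: float
    pooled_mean_se: float
    pooled_var: float
    pooled_var_se: float


def windowed_stats(trace: ExtensionTrace, window_s: float = 1.0) -> WindowedStats:
    """Mean and unbiased variance in non-overlapping windows.

    The pooled variance is the average of the per-window variances (each
    window's own mean is subtracted, which removes drift slower than the
    window), with a standard error from the scatter across windows.
    """
    w = int(round(window_s * trace.acquisition_rate))
    if w < 10:
        raise ValueError("window must contain at least 10 samples")
    n_win = trace.n_samples // w
    if n_win < 2:
        raise ValueError("trace must span at least 2 windows")
    z = trace.z[: n_win * w].reshape(n_win, w)
    means = z.mean(axis=1)
    variances = z.var(axis=1, ddof=1)
    times = trace.time[: n_win * w].reshape(n_win, w).mean(axis=1)
    sqn = math.sqrt(n_win)
    return WindowedStats(
        window_s=window_s,
        times=times,
        means=means,
        variances=variances,
        pooled_mean=float(means.mean()),
        pooled_mean_se=float(means.std(ddof=1) / sqn),
        pooled_var=float(variances.mean()),
        pooled_var_se=float(variances.std(ddof=1) / sqn),
    )


def autocorrelation_time(trace: ExtensionTrace, max_lag_frac: float = 0.25) -> float:
    """Integral correlation time τ_c (s) of the extension fluctuations.

    The normalized autocorrelation is integrated (trapezoid) up to its
    first non-positive value. A correlation that has not decayed below
    e⁻¹ within ``max_lag_frac`` of the trace is flagged as non-decaying.
    """
    z = trace.z - trace.z.mean()
    n = z.size
    nfft = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(z, nfft)
    acf = np.fft.irfft(f * np.conj(f), nfft)[:n].real
    acf /= acf[0]
    max_lag = max(2, int(n * max_lag_frac))
    nonpos = np.flatnonzero(acf[:max_lag] <= 0.0)
    if nonpos.size == 0:
        raise ValueError(
            "autocorrelation has not decayed to zero within a quarter of "
            "the trace: τ_c estimate unreliable (trace too short?)"
        )
    k = int(nonpos[0])
    dt = 1.0 / trace.acquisition_rate
    # trapezoid over [0, k): 0.5·ρ0 + ρ1 + ... + ρ_{k-1}
    return float(dt * (0.5 + acf[1:k].sum()))


# ---------------------------------------------------------------------------
# rotation-curve fitting and calibration


@dataclass
class RotationFit:
    """Two-regime fit of a rotation curve."""

    curvature: float  # nm per unit σ², prebuckling (even quadratic)
    intercept_pre: float  # nm at σ=0
    slope: float  # nm per unit σ, postbuckling (negative for ⟨z⟩)
    intercept_post: float  # nm
    sigma_buckling: float
    split_index: int
    sse: float
    buckling_detected: bool

    @property
    def slope_per_turn(self) -> float:
        """|slope| converted to nm per turn (requires lk0 via the curve)."""
        raise AttributeError(
            "use fit.slope / curve.lk0 via slope_per_turn(curve)"
        )


def _even_quad_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares y = a + c·x²; returns (a, c, sse)."""
    X = np.column_stack([np.ones_like(x), x**2])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    sse = float(np.sum((y - X @ coef) ** 2))
    return float(coef[0]), float(coef[1]), sse


def _lin_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    X = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    sse = float(np.sum((y - X @ coef) ** 2))
    return float(coef[0]), float(coef[1]), sse


def fit_rotation_curve(curve: RotationCurve, observable: str = "z") -> RotationFit:
    """Even-quadratic prebuckling plus linear postbuckling fit.

    The regime boundary is chosen by scanning all admissible split points
    and minimizing the total squared residual; the buckling density is the
    intersection of the two branches. When the best split sits at the edge
    of the scan (the curve is described by a single regime) the fit is
    flagged as not having detected buckling.
    """
    y = curve.z_mean if observable == "z" else curve.z_var
    x = curve.sigma
    n = x.size
    if n < 8:
        raise ValueError("need at least 8 points spanning both regimes")

    def split_scan(values):
        best = None
        for k in range(3, n - 3):
            _, _, sse1 = _even_quad_fit(x[:k], values[:k])
            _, _, sse2 = _lin_fit(x[k:], values[k:])
            sse = sse1 + sse2
            if best is None or sse < best[0]:
                best = (sse, k)
        return best

    _, k = split_scan(y)
    # The variance jumps discontinuously at buckling, which localizes the
    # transition far more sharply than the kink in ⟨z⟩; use it when
    # variance data accompany an extension fit.
    if observable == "z" and curve.z_var is not None and np.all(
        np.isfinite(curve.z_var)
    ):
        _, kv = split_scan(curve.z_var)
        sigma_b = 0.5 * (x[kv - 1] + x[kv])
    else:
        sigma_b = 0.5 * (x[k - 1] + x[k])

    pre = x < sigma_b
    post = x > sigma_b
    if pre.sum() < 3 or post.sum() < 3:
        raise ValueError("buckling point leaves too few points in a regime")
    a, c, sse1 = _even_quad_fit(x[pre], y[pre])
    b0, b1, sse2 = _lin_fit(x[post], y[post])
    sse = sse1 + sse2
    detected = 3 < k < n - 4 and x[0] < sigma_b < x[-1]
    return RotationFit(
        curvature=c,
        intercept_pre=a,
        slope=b1,
        intercept_post=b0,
        sigma_buckling=sigma_b,
        split_index=k,
        sse=sse,
        buckling_detected=detected,
    )


@dataclass
class FluctuationCalibration:
    """σ_p and κ from linear extrapolation of the postbuckling branches."""

    sigma_p: float
    sigma_p_se: float
    kappa: float  # nm² variance per nm looped length
    kappa_se: float
    slope_per_turn: float  # nm/turn; NaN when the curve has no lk0
    force: float
    contour_length: float
    sigma_fit_min: float
    sigma_fit_max: float
    extrapolation_reliable: bool


def _weighted_linfit(
    x: np.ndarray, y: np.ndarray, se: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted least squares y = b0 + b1·x; returns (coef, covariance)."""
    w = np.ones_like(x) if se is None else 1.0 / np.asarray(se) ** 2
    X = np.column_stack([np.ones_like(x), x])
    XtW = X.T * w
    cov = np.linalg.inv(XtW @ X)
    coef = cov @ (XtW @ y)
    if se is None:
        # scale covariance by residual variance
        resid = y - X @ coef
        dof = max(x.size - 2, 1)
        cov = cov * float(resid @ resid) / dof
    return coef, cov


def calibrate(
    curve: RotationCurve,
    sigma_min: float | None = None,
    buckling_margin: float = 0.005,
    var_sigma_min: float | None = None,
    var_sigma_max: float | None = None,
) -> FluctuationCalibration:
    """Extrapolate the postbuckling branches to obtain σ_p and κ.

    σ_p is the zero-extension intercept of the linear ⟨z⟩ branch; κ is the
    linear ⟨Δz²⟩ branch evaluated at σ_p, divided by the contour length
    (the variance-per-length limit as the molecule becomes fully
    plectonemic). The ⟨z⟩ window starts ``buckling_margin`` above the
    detected buckling density unless ``sigma_min`` is given explicitly;
    the ⟨Δz²⟩ fit may use its own window (``var_sigma_min``/``max``) —
    the regime where the variance still rises linearly with σ, which for
    short molecules ends before the extension branch does. Extrapolating
    σ_p beyond twice the fitted range is flagged as unreliable.
    """
    if sigma_min is None:
        fit = fit_rotation_curve(curve)
        sigma_min = fit.sigma_buckling + buckling_margin
    mask = curve.sigma >= sigma_min
    vlo = sigma_min if var_sigma_min is None else var_sigma_min
    vhi = var_sigma_max if var_sigma_max is not None else np.inf
    vmask = (curve.sigma >= vlo) & (curve.sigma <= vhi)
    if int(mask.sum()) < 4 or int(vmask.sum()) < 4:
        raise ValueError("need at least 4 postbuckling points in each curve")
    x = curve.sigma[mask]
    z = curve.z_mean[mask]
    xv = curve.sigma[vmask]
    v = curve.z_var[vmask]
    z_se = None if curve.z_se is None else curve.z_se[mask]
    v_se = None if curve.var_se is None else curve.var_se[vmask]

    (b0, b1), cov_z = _weighted_linfit(x, z, z_se)
    if b1 >= 0:
        raise ValueError("postbuckling extension branch must decrease with σ")
    sigma_p = -b0 / b1
    # var(σp) by first-order propagation of (b0, b1)
    grad = np.array([-1.0 / b1, b0 / b1**2])
    sigma_p_se = float(math.sqrt(grad @ cov_z @ grad))

    (c0, c1), cov_v = _weighted_linfit(xv, v, v_se)
    var_at_sp = c0 + c1 * sigma_p
    gv = np.array([1.0, sigma_p])
    var_at_sp_se = math.sqrt(gv @ cov_v @ gv + (c1 * sigma_p_se) ** 2)
    L = curve.contour_length
    kappa = var_at_sp / L
    kappa_se = var_at_sp_se / L

    reliable = sigma_p <= 2.0 * float(x.max())
    if not reliable:
        warnings.warn(
            f"sigma_p={sigma_p:.3f} extrapolates beyond twice the fitted σ "
            f"range (max {x.max():.3f}): calibration unreliable",
            stacklevel=2,
        )
    spt = float("nan")
    if math.isfinite(curve.lk0) and curve.lk0 > 0:
        spt = abs(b1) / curve.lk0
    return FluctuationCalibration(
        sigma_p=float(sigma_p),
        sigma_p_se=sigma_p_se,
        kappa=float(kappa),
        kappa_se=float(kappa_se),
        slope_per_turn=spt,
        force=curve.force,
        contour_length=L,
        sigma_fit_min=float(x.min()),
        sigma_fit_max=float(x.max()),
        extrapolation_reliable=reliable,
    )


# ---------------------------------------------------------------------------
# domain-size inference


@dataclass
class DomainSize:
    """Looped-domain length inferred from a variance drop (Eq.-6-style)."""

    delta_L: float
    delta_L_se: float
    variance_drop: float
    variance_drop_se: float
    bridging_detected: bool


def infer_domain_size(
    var_before: float,
    var_after: float,
    calib: FluctuationCalibration,
    var_before_se: float = 0.0,
    var_after_se: float = 0.0,
) -> DomainSize:
    """ΔL = (⟨Δz²⟩_before − ⟨Δz²⟩_after)/κ with propagated uncertainty.

    A non-positive variance drop yields ΔL = 0 with the no-bridging
    diagnostic rather than an error.
    """
    if var_before < 0 or var_after < 0:
        raise ValueError("variances must be non-negative")
    drop = var_before - var_after
    drop_se = math.hypot(var_before_se, var_after_se)
    if drop <= 0:
        return DomainSize(0.0, drop_se / calib.kappa, drop, drop_se, False)
    dl = drop / calib.kappa
    dl_se = dl * math.sqrt(
        (drop_se / drop) ** 2 + (calib.kappa_se / calib.kappa) ** 2
    )
    return DomainSize(float(dl), float(dl_se), float(drop), float(drop_se), True)


def mean_extension_change(
    before: ExtensionTrace, after: ExtensionTrace, window_s: float = 1.0
) -> tuple[float, float]:
    """Δ⟨z⟩ = ⟨z⟩_after − ⟨z⟩_before with combined standard error.

    Both traces must be recorded at the same force and supercoiling
    density; two-phase theory predicts no change upon bridging, so the
    no-change null is what this difference is tested against.
    """
    for attr in ("force", "sigma"):
        a, b = getattr(before, attr), getattr(after, attr)
        if math.isfinite(a) and math.isfinite(b) and not math.isclose(a, b, rel_tol=1e-6):
            raise ValueError(f"traces recorded at different {attr}: {a} vs {b}")
    sb = windowed_stats(before, window_s)
    sa = windowed_stats(after, window_s)
    diff = sa.pooled_mean - sb.pooled_mean
    se = math.hypot(sa.pooled_mean_se, sb.pooled_mean_se)
    return float(diff), float(se)


# ---------------------------------------------------------------------------
# state segmentation, plectoneme stiffness, kinetics


@dataclass
class StateModel:
    """Discrete extension levels of a filtered trace."""

    level_index: np.ndarray  # ΔΔLk relative to the most populated level
    level_z: np.ndarray  # mean extension per level (nm)
    occupancy: np.ndarray
    spacing: float  # nm per turn
    spacing_se: float
    assignments: np.ndarray  # per-sample level position (index into levels)
    filter_window_s: float
    acquisition_rate: float

    @property
    def n_levels(self) -> int:
        return self.level_index.size


def segment_states(
    trace: ExtensionTrace,
    filter_window_s: float = 10.0,
    min_prominence_frac: float = 0.05,
) -> StateModel:
    """Discover discrete extension levels in a sliding-average trace.

    The raw trace is filtered with a ``filter_window_s`` sliding average;
    levels are histogram peaks of the filtered signal constrained to a
    common spacing; samples are assigned to the nearest level with a
    hysteresis of 0.25× the spacing. Fewer than two resolvable peaks give
    a valid single-state model.
    """
    w = int(round(filter_window_s * trace.acquisition_rate))
    if trace.n_samples < 10 * w:
        raise ValueError("trace must span at least 10 filter windows")
    filt = ndimage.uniform_filter1d(trace.z, size=w, mode="nearest")

    nbins = 200
    hist, edges = np.histogram(filt, bins=nbins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    smooth = ndimage.uniform_filter1d(hist.astype(float), size=5)
    # zero-pad so that peaks in the outermost bins are detectable
    padded = np.r_[0.0, smooth, 0.0]
    peaks, _ = signal.find_peaks(
        padded, prominence=min_prominence_frac * smooth.max()
    )
    peaks = peaks - 1
    if peaks.size < 2:
        assignments = np.zeros(trace.n_samples, dtype=np.int64)
        return StateModel(
            level_index=np.array([0]),
            level_z=np.array([float(filt.mean())]),
            occupancy=np.array([1.0]),
            spacing=float("nan"),
            spacing_se=float("nan"),
            assignments=assignments,
            filter_window_s=filter_window_s,
            acquisition_rate=trace.acquisition_rate,
        )

    peak_z = centers[peaks]
    # common-spacing constraint: refine spacing by assigning integer ranks
    spacing = float(np.median(np.diff(np.sort(peak_z))))
    ref = peak_z[np.argmax(smooth[peaks])]
    for _ in range(3):
        k = np.round((peak_z - ref) / spacing)
        if np.unique(k).size < 2:
            break
        coef = np.polyfit(k, peak_z, 1)
        spacing, ref = float(coef[0]), float(coef[1])
    k = np.round((peak_z - ref) / spacing).astype(int)
    k_grid = np.arange(k.min(), k.max() + 1)
    levels = ref + spacing * k_grid

    assignments = _kernels.assign_states_hysteresis(
        filt, levels.astype(np.float64), 0.25 * abs(spacing)
    )
    occ = np.bincount(assignments, minlength=levels.size).astype(float)
    occ /= occ.sum()
    level_z = np.array(
        [
            trace.z[assignments == i].mean() if occ[i] > 0 else levels[i]
            for i in range(levels.size)
        ]
    )
    # spacing SE from the scatter of level means about the common grid
    pop = occ > 0.005
    if pop.sum() >= 3:
        coef, cov = np.polyfit(k_grid[pop], level_z[pop], 1, cov=True)
        spacing, spacing_se = float(coef[0]), float(math.sqrt(cov[0, 0]))
    else:
        spacing_se = float("nan")

    # index levels by ΔΔLk relative to the most populated one; an added
    # loop turn lowers the tether, so extension decreases with the index
    imax = int(np.argmax(occ))
    order = np.argsort(-level_z) if spacing < 0 else np.argsort(level_z)
    # enforce: higher index = lower extension (one extra turn in the loop)
    idx_rel = np.round((level_z[imax] - level_z) / abs(spacing)).astype(int)
    return StateModel(
        level_index=idx_rel,
        level_z=level_z,
        occupancy=occ,
        spacing=float(abs(spacing)),
        spacing_se=spacing_se,
        assignments=assignments,
        filter_window_s=filter_window_s,
        acquisition_rate=trace.acquisition_rate,
    )


def plectoneme_stiffness(
    model: StateModel, loop_length: float
) -> tuple[float, float]:
    """Plectoneme torsional stiffness P = ΔL/(4π²⟨(ΔΔLk)²⟩) (nm).

    ⟨(ΔΔLk)²⟩ is the squared width of a Gaussian fitted to the level
    occupancies versus ΔΔLk (free center and amplitude). The uncertainty
    comes from the fit covariance. Requires at least 3 occupied levels.
    """
    mask = model.occupancy > 0
    k = model.level_index[mask].astype(float)
    p = model.occupancy[mask]
    if k.size < 3:
        raise ValueError("need at least 3 occupied levels for the Gaussian fit")

    def gauss(x, amp, mu, width):
        return amp * np.exp(-((x - mu) ** 2) / (2.0 * width**2))

    try:
        popt, pcov = optimize.curve_fit(
            gauss,
            k,
            p,
            p0=[p.max(), float(k[np.argmax(p)]), max(k.std(), 0.5)],
            maxfev=10000,
        )
    except RuntimeError as err:  # pragma: no cover - pathological input
        raise ValueError(f"non-Gaussian occupancies: {err}") from err
    width = abs(float(popt[2]))
    width_se = float(math.sqrt(max(pcov[2, 2], 0.0)))
    lk_var = width**2
    P = loop_length / (4.0 * math.pi**2 * lk_var)
    P_se = P * 2.0 * width_se / width if width > 0 else float("nan")
    return float(P), float(P_se)


def plectoneme_stiffness_from_samples(
    lk_samples: np.ndarray, loop_length: float
) -> float:
    """Direct-variance estimator P = ΔL/(4π²·Var[ΔLk_loop]) (nm)."""
    v = float(np.var(np.asarray(lk_samples, dtype=float), ddof=1))
    if v <= 0:
        raise ValueError("loop linking-number samples have zero variance")
    return loop_length / (4.0 * math.pi**2 * v)


@dataclass
class DwellState:
    """Dwell-time statistics of one extension state."""

    level_index: int
    occupancy: float
    n_dwells: int
    tau: float  # ML exponential mean (s)
    tau_se: float
    tau_p: float  # (1 − p_i)·τ_i
    gof_pvalue: float  # Lilliefors test of exponentiality


@dataclass
class DwellTimeResult:
    states: list[DwellState]
    tau_p: float
    tau_p_sd: float
    n_short_excluded: int


def _dwells_from_assignments(
    assignments: np.ndarray, rate: float
) -> tuple[np.ndarray, np.ndarray]:
    """(state, duration_s) of each completed dwell, censored ends dropped."""
    change = np.flatnonzero(np.diff(assignments) != 0)
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change + 1, [assignments.size]])
    states = assignments[starts]
    durations = (ends - starts) / rate
    # first and last dwells are censored by the trace boundaries
    return states[1:-1], durations[1:-1]


def dwell_time_analysis(
    model: StateModel,
    min_events: int = 20,
    top_states: int = 3,
) -> DwellTimeResult:
    """Per-state exponential dwell times and the rebinding time τ_p.

    Dwells shorter than the filter window are excluded (the sliding
    average suppresses sub-window events); censored first/last dwells are
    dropped. Because an exponential is memoryless, the retained dwells
    minus the cutoff are again exponential with the original mean, so the
    cutoff is subtracted before the maximum-likelihood fit and the
    goodness-of-fit test (this removes the left-truncation bias). States
    with fewer than ``min_events`` usable dwells are skipped with a
    warning. τ_p is summarized as mean ± SD over the ``top_states``
    most-populated analyzable states; exponentiality is assessed per state
    with a Lilliefors test.
    """
    states, durations = _dwells_from_assignments(
        model.assignments, model.acquisition_rate
    )
    cutoff = model.filter_window_s
    keep = durations >= cutoff
    n_short = int(np.sum(~keep))
    states, durations = states[keep], durations[keep] - cutoff

    out: list[DwellState] = []
    for pos in range(model.n_levels):
        d = durations[states == pos]
        if d.size < min_events:
            if model.occupancy[pos] > 0.05:
                warnings.warn(
                    f"state {model.level_index[pos]} has only {d.size} dwell "
                    f"events (<{min_events}): skipped",
                    stacklevel=2,
                )
            continue
        tau = float(d.mean())  # exponential MLE of the de-truncated dwells
        p_i = float(model.occupancy[pos])
        try:
            _, pval = lilliefors(d, dist="exp")
        except Exception:  # pragma: no cover
            pval = float("nan")
        out.append(
            DwellState(
                level_index=int(model.level_index[pos]),
                occupancy=p_i,
                n_dwells=int(d.size),
                tau=tau,
                tau_se=tau / math.sqrt(d.size),
                tau_p=(1.0 - p_i) * tau,
                gof_pvalue=float(pval),
            )
        )
    if not out:
        raise ValueError("no state has enough dwell events for analysis")
    ranked = sorted(out, key=lambda s: -s.occupancy)[:top_states]
    taus = np.array([s.tau_p for s in ranked])
    return DwellTimeResult(
        states=out,
        tau_p=float(taus.mean()),
        tau_p_sd=float(taus.std(ddof=1)) if taus.size > 1 else float("nan"),
        n_short_excluded=n_short,
    )


# ---------------------------------------------------------------------------
# bridging MC ensembles → rotation curve


def rotation_curve_from_ensembles(
    ensembles, molecule: MoleculeSpec
) -> RotationCurve:
    """Assemble a RotationCurve from a ΔLk series of MC ensembles."""
    ens = sorted(ensembles, key=lambda e: e.delta_lk)
    lk0 = molecule.lk0
    sig, zm, zv, zse, vse = [], [], [], [], []
    for e in ens:
        m, se = e.mean_extension()
        v, ve = e.extension_variance()
        sig.append(e.delta_lk / lk0)
        zm.append(m)
        zv.append(v)
        zse.append(max(se, 1e-9))
        vse.append(max(ve, 1e-9))
    L = ens[0].final_conformation.contour_length
    return RotationCurve(
        sigma=np.array(sig),
        z_mean=np.array(zm),
        z_var=np.array(zv),
        force=ens[0].force,
        contour_length=L,
        lk0=lk0,
        z_se=np.array(zse),
        var_se=np.array(vse),
    )
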