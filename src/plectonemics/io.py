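"""Plain-text file formats: traces, rotation curves, calibrations, reports,
conformation snapshots, and run configuration.

Everything is tab-separated text with ``#``-prefixed header metadata so
that runs are diffable and reproducible from their sidecar config + seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from .analysis import ExtensionTrace, FluctuationCalibration, RotationCurve
from .chain import ChainConformation
from .params import ElasticParams, MoleculeSpec

__all__ = [
    "RunConfig",
    "read_trace",
    "write_trace",
    "read_rotation_curve",
    "write_rotation_curve",
    "write_theory_curve",
    "write_calibration",
    "read_calibration",
    "write_report",
    "read_report",
    "write_xyz",
    "read_xyz",
]


# ---------------------------------------------------------------------------
# traces


def _parse_headers(path: Path) -> tuple[dict[str, float], int]:
    meta: dict[str, float] = {}
    n_header = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
            parts = line[1:].split()
            if len(parts) >= 2:
                try:
                    meta[parts[0].lower()] = float(parts[1])
                except ValueError:
                    pass
    return meta, n_header


def write_trace(trace, path) -> None:
    """Write a trace as ``# key value`` headers plus time/z[/state] columns."""
    path = Path(path)
    state = getattr(trace, "state_path", None)
    with open(path, "w") as fh:
        fh.write(f"# rate_hz {trace.acquisition_rate:.10g}\n")
        if math.isfinite(getattr(trace, "force", float("nan"))):
            fh.write(f"# force_pn {trace.force:.10g}\n")
        if math.isfinite(getattr(trace, "sigma", float("nan"))):
            fh.write(f"# sigma {trace.sigma:.10g}\n")
        fh.write("# columns time_s z_nm" + (" state" if state is not None else "") + "\n")
        cols = {"time_s": trace.time, "z_nm": trace.z}
        if state is not None:
            cols["state"] = np.asarray(state, dtype=int)
        pd.DataFrame(cols).to_csv(
            fh, sep="\t", header=False, index=False, float_format="%.6f"
        )


def read_trace(path, acquisition_rate: float | None = None) -> ExtensionTrace:
    """Read a two/three-column trace; malformed rows are reported by line.

    The acquisition rate comes from the ``# rate_hz`` header unless
    overridden. Non-monotone time or non-finite extension values raise.
    """
    path = Path(path)
    meta, n_header = _parse_headers(path)
    rate = acquisition_rate if acquisition_rate is not None else meta.get("rate_hz")
    if rate is None:
        raise ValueError(f"{path}: no '# rate_hz' header and no rate given")
    try:
        data = np.loadtxt(path, comments="#", ndmin=2)
        bad = np.flatnonzero(~np.all(np.isfinite(data), axis=1))
        if bad.size:
            raise ValueError("non-finite row")
    except ValueError:
        # slow path: locate offending lines for the error message
        bad_lines = []
        with open(path) as fh:
            for ln, line in enumerate(fh, start=1):
                s = line.strip()
                if not s or s.startswith("#"):
                    continue
                try:
                    vals = [float(v) for v in s.split()]
                    if len(vals) < 2 or not all(math.isfinite(v) for v in vals):
                        bad_lines.append(ln)
                except ValueError:
                    bad_lines.append(ln)
        raise ValueError(
            f"{path}: malformed or non-finite rows at lines {bad_lines[:10]}"
        ) from None
    return ExtensionTrace(
        time=data[:, 0],
        z=data[:, 1],
        acquisition_rate=float(rate),
        force=float(meta.get("force_pn", float("nan"))),
        sigma=float(meta.get("sigma", float("nan"))),
        label=path.name,
    )


# ---------------------------------------------------------------------------
# rotation curves


def write_rotation_curve(curve: RotationCurve, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# force_pn {curve.force:.10g}\n")
        fh.write(f"# contour_length_nm {curve.contour_length:.10g}\n")
        if math.isfinite(curve.lk0):
            fh.write(f"# lk0 {curve.lk0:.10g}\n")
        fh.write("# columns sigma z_mean_nm z_var_nm2 z_se_nm var_se_nm2\n")
        zse = curve.z_se if curve.z_se is not None else np.full(curve.sigma.size, np.nan)
        vse = (
            curve.var_se if curve.var_se is not None else np.full(curve.sigma.size, np.nan)
        )
        for row in zip(curve.sigma, curve.z_mean, curve.z_var, zse, vse):
            fh.write("\t".join(f"{v:.8g}" for v in row) + "\n")


def read_rotation_curve(path) -> RotationCurve:
    path = Path(path)
    meta, _ = _parse_headers(path)
    data = np.loadtxt(path, comments="#", ndmin=2)
    z_se = data[:, 3] if data.shape[1] > 3 and np.all(np.isfinite(data[:, 3])) else None
    v_se = data[:, 4] if data.shape[1] > 4 and np.all(np.isfinite(data[:, 4])) else None
    return RotationCurve(
        sigma=data[:, 0],
        z_mean=data[:, 1],
        z_var=data[:, 2],
        force=float(meta.get("force_pn", float("nan"))),
        contour_length=float(meta.get("contour_length_nm", float("nan"))),
        lk0=float(meta.get("lk0", float("nan"))),
        z_se=z_se,
        var_se=v_se,
    )


def write_theory_curve(path, force: float, sigma, mean_ext_frac, var_per_len) -> None:
    """Theory export: fractional extension and variance per length vs σ."""
    with open(path, "w") as fh:
        fh.write(f"# force_pN {force:.10g}\n")
        fh.write("# columns sigma mean_ext_frac var_per_len_nm\n")
        for row in zip(sigma, mean_ext_frac, var_per_len):
            fh.write("\t".join(f"{v:.8g}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# flat key/value files (calibration, reports, config)


def _write_kv(path, mapping: dict) -> None:
    with open(path, "w") as fh:
        for k, v in mapping.items():
            fh.write(f"{k}\t{v}\n")


def _read_kv(path) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            k, _, v = s.partition("\t")
            if not v:
                k, _, v = s.partition(" ")
            out[k.strip()] = v.strip()
    return out


def write_calibration(calib: FluctuationCalibration, path) -> None:
    _write_kv(
        path,
        {
            "sigma_p": f"{calib.sigma_p:.8g}",
            "sigma_p_se": f"{calib.sigma_p_se:.8g}",
            "kappa_nm2_per_nm": f"{calib.kappa:.8g}",
            "kappa_se": f"{calib.kappa_se:.8g}",
            "slope_per_turn_nm": f"{calib.slope_per_turn:.8g}",
            "force_pn": f"{calib.force:.8g}",
            "contour_length_nm": f"{calib.contour_length:.8g}",
            "sigma_fit_min": f"{calib.sigma_fit_min:.8g}",
            "sigma_fit_max": f"{calib.sigma_fit_max:.8g}",
            "extrapolation_reliable": str(calib.extrapolation_reliable),
        },
    )


def read_calibration(path) -> FluctuationCalibration:
    kv = _read_kv(path)
    return FluctuationCalibration(
        sigma_p=float(kv["sigma_p"]),
        sigma_p_se=float(kv.get("sigma_p_se", "nan")),
        kappa=float(kv["kappa_nm2_per_nm"]),
        kappa_se=float(kv.get("kappa_se", "nan")),
        slope_per_turn=float(kv.get("slope_per_turn_nm", "nan")),
        force=float(kv.get("force_pn", "nan")),
        contour_length=float(kv.get("contour_length_nm", "nan")),
        sigma_fit_min=float(kv.get("sigma_fit_min", "nan")),
        sigma_fit_max=float(kv.get("sigma_fit_max", "nan")),
        extrapolation_reliable=kv.get("extrapolation_reliable", "True") == "True",
    )


def write_report(path, mapping: dict) -> None:
    """Flat key → value report, one entry per line."""
    _write_kv(path, mapping)


def read_report(path) -> dict[str, str]:
    return _read_kv(path)


# ---------------------------------------------------------------------------
# conformations


def write_xyz(conf: ChainConformation, path, labels=None, comment: str = "") -> None:
    """XYZ-format snapshot; the element column encodes the phase label
    (S = stretched, P = plectonemic) when labels are given."""
    path = Path(path)
    n = conf.n_beads
    with open(path, "w") as fh:
        fh.write(f"{n}\n")
        fh.write(
            f"delta_lk={conf.delta_lk:.6g} a={conf.segment_length:.6g} "
            f"d_ex={conf.excluded_diameter:.6g} {comment}\n"
        )
        for i in range(n):
            el = "C"
            if labels is not None:
                el = "P" if labels[i] else "S"
            x, y, z = conf.positions[i]
            fh.write(f"{el}\t{x:.6f}\t{y:.6f}\t{z:.6f}\n")


def read_xyz(path) -> ChainConformation:
    path = Path(path)
    with open(path) as fh:
        n = int(fh.readline())
        meta = {}
        for tok in fh.readline().split():
            if "=" in tok:
                k, _, v = tok.partition("=")
                try:
                    meta[k] = float(v)
                except ValueError:
                    pass
        pos = np.empty((n, 3))
        for i in range(n):
            parts = fh.readline().split()
            pos[i] = [float(parts[1]), float(parts[2]), float(parts[3])]
    return ChainConformation(
        pos,
        segment_length=meta.get("a", 2.5),
        delta_lk=meta.get("delta_lk", 0.0),
        excluded_diameter=meta.get("d_ex", 4.0),
    )


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Resolved configuration of a run; round-trips losslessly as text."""

    # elastic parameters
    bend_persistence: float = 40.0
    twist_persistence: float = 100.0
    plectoneme_stiffness: float = 20.0
    helical_repeat: float = 10.5
    helical_rise: float = 0.34
    temperature: float = 298.0
    # molecule
    n_bp: int = 2000
    # simulation schedule
    force_pn: float = 0.5
    sigma: float = 0.0
    segment_length: float = 2.5
    excluded_diameter: float = 4.0
    n_steps: int = 2_000_000
    n_equil: int = 500_000
    stride: int = 1000
    # analysis options
    variance_window_s: float = 1.0
    filter_window_s: float = 10.0
    # bookkeeping
    seed: int = 1
    output_dir: str = "."

    def elastic_params(self) -> ElasticParams:
        return ElasticParams(
            bend_persistence=self.bend_persistence,
            twist_persistence=self.twist_persistence,
            plectoneme_stiffness=self.plectoneme_stiffness,
            helical_repeat=self.helical_repeat,
            helical_rise=self.helical_rise,
            temperature=self.temperature,
        )

    def molecule(self) -> MoleculeSpec:
        return MoleculeSpec(
            n_bp=self.n_bp,
            helical_repeat=self.helical_repeat,
            helical_rise=self.helical_rise,
        )

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for f in fields(self):
                fh.write(f"{f.name}: {getattr(self, f.name)}\n")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        kv: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                s = line.strip()
                if not s or s.startswith("#"):
                    continue
                k, _, v = s.partition(":")
                kv[k.strip()] = v.strip()
        kwargs = {}
        for f in fields(cls):
            if f.name in kv:
                kwargs[f.name] = _cast(f.type, kv[f.name])
        return cls(**kwargs)


def _cast(type_name, value: str):
    if type_name in (int, "int"):
        return int(value)
    if type_name in (float, "float"):
        return float(value)
    return value
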