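"""End-to-end analysis of an incremental-exercise blood-gas series.

The pipeline mirrors how dynamic blood chemistry reshapes hemoglobin's
dissociation curves during an incremental test to exhaustion:

1. fit smooth trajectories (polynomials in %VO2max) to the measured femoral
   venous PO2, PCO2, plasma pH and O2Hb saturation;
2. build per-sample blood-gas states (Gibbs-Donnan pH conversion, linear
   femoral temperature ramp, fixed Hct/Hb/[2,3-DPG]);
3. compute per-sample *in vitro* dissociation curves and their inflection
   points, and composite *in vivo* ODC/CDC/HDC curves by sweeping the model
   along the fitted trajectories;
4. locate the in vivo inflection points and the CDC-HDC intersection;
5. calibrate [2,3-DPG] so the simulated O2Hb saturations are unbiased
   against the measured ones (Bland-Altman), and quantify temperature
   sensitivity by re-running with temperature fixed at 37 degC.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import ModelConstants
from .curves import (
    DEFAULT_GRID_STEP,
    DissociationCurve,
    InflectionPoint,
    find_inflection,
    find_intersection,
    in_vitro_curve,
)
from .model import BloodGasState, _saturation_arrays, _species_arrays, ph_rbc_from_plasma

__all__ = [
    "ExerciseSample",
    "PipelineConfig",
    "FittedTrajectory",
    "BlandAltmanResult",
    "AnalysisReport",
    "read_series",
    "write_series",
    "fit_trajectories",
    "per_sample_states",
    "in_vivo_curves",
    "calibrate_dpg",
    "bland_altman",
    "simulated_so2",
    "run_analysis",
    "sensitivity_analysis",
]

_DEFAULT = ModelConstants()

CSV_COLUMNS = ["pct_vo2max", "po2_mmHg", "pco2_mmHg", "ph_plasma", "so2_pct"]


@dataclass(frozen=True)
class ExerciseSample:
    """One pooled blood-gas sample at a given exercise intensity."""

    pct_vo2max: float
    PO2: float
    PCO2: float
    pH_plasma: float
    SO2_measured: float

    def __post_init__(self) -> None:
        vals = [self.pct_vo2max, self.PO2, self.PCO2, self.pH_plasma, self.SO2_measured]
        if not np.isfinite(vals).all():
            raise ValueError("exercise sample fields must be finite")
        if not (0 <= self.pct_vo2max <= 100):
            raise ValueError(f"pct_vo2max must be in [0, 100], got {self.pct_vo2max}")
        if not (0 <= self.SO2_measured <= 100):
            raise ValueError(f"SO2 must be a percentage in [0, 100], got {self.SO2_measured}")


def _validate_series(series: list[ExerciseSample]) -> None:
    v = [s.pct_vo2max for s in series]
    if any(b < a for a, b in zip(v, v[1:])):
        raise ValueError("pct_vo2max must be non-decreasing across the series")


def read_series(path: str | Path) -> list[ExerciseSample]:
    """Read a series from CSV with columns pct_vo2max,po2_mmHg,pco2_mmHg,ph_plasma,so2_pct."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"input CSV is missing column(s): {sorted(missing)}")
    series = [
        ExerciseSample(r.pct_vo2max, r.po2_mmHg, r.pco2_mmHg, r.ph_plasma, r.so2_pct)
        for r in df.itertuples()
    ]
    _validate_series(series)
    return series


def write_series(series: list[ExerciseSample], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "pct_vo2max": [s.pct_vo2max for s in series],
            "po2_mmHg": [s.PO2 for s in series],
            "pco2_mmHg": [s.PCO2 for s in series],
            "ph_plasma": [s.pH_plasma for s in series],
            "so2_pct": [s.SO2_measured for s in series],
        }
    )
    df.to_csv(path, index=False)


@dataclass
class PipelineConfig:
    """Knobs of the exercise analysis.

    ``dpg`` is used as-is when ``calibrate=False``; otherwise it is replaced
    by the value that zeroes the Bland-Altman mean bias.  ``temp_mode`` is
    ``"ramp"`` (37 -> 38 degC across the samples, emulating femoral-vein
    warming) or ``"fixed"`` (37 degC).  ``hdc`` selects the proton curve
    definition: total protonated amine (default) or the deoxy species alone.
    """

    dpg: float = 4.65e-3
    calibrate: bool = True
    temp_mode: str = "ramp"
    T_start: float = 37.0
    T_end: float = 38.0
    hdc: str = "total"  # or "deoxy_only"
    Hct: float = 0.45
    Hb_rbc: float = 0.00528
    grid_step: float = DEFAULT_GRID_STEP
    inflection_window: tuple[float, float] = (2.0, 80.0)
    dpg_bounds: tuple[float, float] = (0.0005, 0.00465)
    dpg_tol: float = 1e-5
    n_eval: int = 2001
    constants: ModelConstants = field(default_factory=ModelConstants)

    def __post_init__(self) -> None:
        if self.temp_mode not in ("ramp", "fixed"):
            raise ValueError("temp_mode must be 'ramp' or 'fixed'")
        if self.hdc not in ("total", "deoxy_only"):
            raise ValueError("hdc must be 'total' or 'deoxy_only'")

    def replace(self, **kw) -> "PipelineConfig":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["constants"] = self.constants.to_dict()
        return d


@dataclass
class FittedTrajectory:
    """Polynomial fits of the four measured channels in %VO2max.

    ``po2``/``so2`` are cubic by design (their S-shape needs two curvature
    changes); PCO2 and pH degrees are chosen among 1-3 by corrected AIC.
    Polynomials are stored as :class:`numpy.polynomial.Polynomial` in raw
    %VO2max units.  The temperature ramp is linear in %VO2max between the
    first and last sample.
    """

    po2: np.polynomial.Polynomial
    pco2: np.polynomial.Polynomial
    ph_plasma: np.polynomial.Polynomial
    so2: np.polynomial.Polynomial
    degrees: dict
    v_range: tuple[float, float]
    T_start: float = 37.0
    T_end: float = 38.0

    def temperature(self, v) -> np.ndarray:
        v0, v1 = self.v_range
        frac = (np.asarray(v, dtype=float) - v0) / (v1 - v0) if v1 > v0 else 0.0
        return self.T_start + (self.T_end - self.T_start) * np.clip(frac, 0.0, 1.0)

    def coefficients(self) -> dict:
        return {
            name: list(getattr(self, name).coef)
            for name in ("po2", "pco2", "ph_plasma", "so2")
        }


def _aicc(rss: float, n: int, k: int, scale: float) -> float:
    """Corrected AIC for a Gaussian least-squares fit with k parameters
    (polynomial coefficients + residual variance).

    ``rss`` is floored at the round-off level of the data so that exact
    (interpolating) fits of different degrees tie and the penalty term
    resolves the tie toward the lowest degree.
    """
    if n - k - 1 < 1:
        return math.inf
    rss = max(rss, n * (1e-9 * scale) ** 2)
    return n * math.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def _polyfit(x: np.ndarray, y: np.ndarray, deg: int) -> tuple[np.polynomial.Polynomial, float]:
    p, info = np.polynomial.Polynomial.fit(x, y, deg, full=True)
    resid = info[0]
    rss = float(resid[0]) if len(resid) else float(np.sum((p(x) - y) ** 2))
    return p.convert(), rss


def _select_degree(x: np.ndarray, y: np.ndarray, degrees=(1, 2, 3)):
    scale = max(1.0, float(np.sqrt(np.mean(np.square(y)))))
    best = None
    for deg in degrees:
        p, rss = _polyfit(x, y, deg)
        score = _aicc(rss, x.size, deg + 2, scale)
        if best is None or score < best[0] - 1e-12:
            best = (score, deg, p)
    if best is None or not math.isfinite(best[0]):
        # fall back to the lowest admissible degree when AICc degenerates
        p, _ = _polyfit(x, y, degrees[0])
        return degrees[0], p
    return best[1], best[2]


def fit_trajectories(
    series: list[ExerciseSample],
    config: PipelineConfig | None = None,
) -> FittedTrajectory:
    """Least-squares polynomial trajectories of PO2, PCO2, pH and SO2."""
    config = config or PipelineConfig()
    _validate_series(series)
    if len(series) < 6:
        raise ValueError(f"need >= 6 samples to fit trajectories, got {len(series)}")
    v = np.array([s.pct_vo2max for s in series], dtype=float)
    if np.unique(v).size < 4:
        raise ValueError("design is rank deficient: fewer than 4 distinct intensities")
    po2, _ = _polyfit(v, np.array([s.PO2 for s in series]), 3)
    so2, _ = _polyfit(v, np.array([s.SO2_measured for s in series]), 3)
    dC, pco2 = _select_degree(v, np.array([s.PCO2 for s in series]))
    dH, ph = _select_degree(v, np.array([s.pH_plasma for s in series]))
    return FittedTrajectory(
        po2=po2,
        pco2=pco2,
        ph_plasma=ph,
        so2=so2,
        degrees={"po2": 3, "so2": 3, "pco2": dC, "ph_plasma": dH},
        v_range=(float(v[0]), float(v[-1])),
        T_start=config.T_start,
        T_end=config.T_end if config.temp_mode == "ramp" else config.T_start,
    )


def per_sample_states(
    series: list[ExerciseSample],
    dpg: float,
    temp_mode: str = "ramp",
    config: PipelineConfig | None = None,
) -> list[BloodGasState]:
    """Blood-gas states for each sample: Gibbs-Donnan pH, linear T ramp."""
    config = config or PipelineConfig()
    n = len(series)
    if temp_mode == "ramp" and n > 1:
        temps = config.T_start + (config.T_end - config.T_start) * np.arange(n) / (n - 1)
    else:
        temps = np.full(n, config.T_start)
    return [
        BloodGasState(
            PO2=s.PO2,
            PCO2=s.PCO2,
            pH_rbc=float(ph_rbc_from_plasma(s.pH_plasma, config.constants)),
            DPG=dpg,
            T=float(t),
            Hct=config.Hct,
            Hb_rbc=config.Hb_rbc,
        )
        for s, t in zip(series, temps)
    ]


def simulated_so2(
    series: list[ExerciseSample],
    dpg: float,
    temp_mode: str = "ramp",
    config: PipelineConfig | None = None,
) -> np.ndarray:
    """Model O2Hb saturation (%) at each sample's measured blood chemistry."""
    config = config or PipelineConfig()
    states = per_sample_states(series, dpg, temp_mode, config)
    out = [
        float(
            _saturation_arrays(st.PO2, st.PCO2, st.pH_rbc, st.DPG, st.T, config.constants)[0]
        )
        for st in states
    ]
    return 100.0 * np.asarray(out)


@dataclass(frozen=True)
class BlandAltmanResult:
    """Mean bias and 1.96-SD limits of agreement, in percentage points."""

    mean_bias: float
    loa_low: float
    loa_high: float
    n: int


def bland_altman(measured, simulated) -> BlandAltmanResult:
    """Agreement of simulated vs measured saturations (simulated - measured)."""
    measured = np.asarray(measured, dtype=float)
    simulated = np.asarray(simulated, dtype=float)
    if measured.shape != simulated.shape:
        raise ValueError("measured and simulated series must have equal length")
    if measured.size < 2:
        raise ValueError("need at least 2 paired values")
    d = simulated - measured
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return BlandAltmanResult(bias, bias - 1.96 * sd, bias + 1.96 * sd, int(d.size))


def calibrate_dpg(
    series: list[ExerciseSample],
    temp_mode: str = "ramp",
    dpg_bounds: tuple[float, float] = (0.0005, 0.00465),
    config: PipelineConfig | None = None,
    bias_tol: float = 0.05,
) -> float:
    """[2,3-DPG] (M) that zeroes the mean simulated-minus-measured SO2 bias.

    The bias is monotone decreasing in [2,3-DPG] (more DPG -> higher P50 ->
    lower simulated saturation), so a plain bisection suffices.
    """
    config = config or PipelineConfig()
    meas = np.array([s.SO2_measured for s in series], dtype=float)

    def bias(dpg: float) -> float:
        return float(np.mean(simulated_so2(series, dpg, temp_mode, config) - meas))

    lo, hi = dpg_bounds
    f_lo, f_hi = bias(lo), bias(hi)
    if f_lo == 0:
        return lo
    if f_hi == 0:
        return hi
    if f_lo * f_hi > 0:
        raise ValueError(
            "mean bias is not bracketed by dpg_bounds: "
            f"bias({lo:g} M) = {f_lo:+.3f} pp, bias({hi:g} M) = {f_hi:+.3f} pp"
        )
    while hi - lo > config.dpg_tol:
        mid = 0.5 * (lo + hi)
        f_mid = bias(mid)
        if f_mid == 0:
            return mid
        if f_lo * f_mid < 0:
            hi, f_hi = mid, f_mid
        else:
            lo, f_lo = mid, f_mid
    dpg = 0.5 * (lo + hi)
    final = bias(dpg)
    if abs(final) > bias_tol:
        warnings.warn(
            f"calibration converged in DPG but residual bias is {final:+.3f} pp",
            stacklevel=2,
        )
    return dpg


def _monotone_prefix(po2: np.ndarray) -> int:
    """Length of the maximal prefix on which PO2 is strictly decreasing."""
    dec = np.diff(po2) < 0
    if not dec[0]:
        return 1
    stop = np.argmin(dec) if not dec.all() else dec.size
    return int(stop) + 1


def in_vivo_curves(
    traj: FittedTrajectory,
    dpg: float,
    temp_mode: str = "ramp",
    config: PipelineConfig | None = None,
) -> dict[str, DissociationCurve]:
    """Composite in vivo ODC/CDC/HDC along the fitted exercise trajectory.

    The model is swept over a fine %VO2max grid with the fitted PO2, PCO2 and
    pH and the temperature ramp; the parametric traces are trimmed to the
    maximal prefix on which PO2 strictly decreases (the near-plateau tail at
    the critical capillary PO2 is excluded from differentiation) and
    resampled onto a uniform PO2 grid by linear interpolation.
    """
    config = config or PipelineConfig()
    v0, v1 = traj.v_range
    v = np.linspace(v0, v1, config.n_eval)
    po2 = traj.po2(v)
    pco2 = traj.pco2(v)
    ph_pl = traj.ph_plasma(v)
    if temp_mode == "ramp":
        T = traj.temperature(v)
    else:
        T = np.full_like(v, traj.T_start)
    if np.any(po2 <= 0):
        raise ValueError("fitted PO2 trajectory is non-positive inside the range")

    n_keep = _monotone_prefix(po2)
    if n_keep < 10 or (po2[0] - po2[n_keep - 1]) < 2.0:
        raise ValueError(
            "fitted PO2 trajectory is not monotonically decreasing over a usable range"
        )
    sl = slice(0, n_keep)
    po2, pco2, ph_pl, T, v = po2[sl], pco2[sl], ph_pl[sl], T[sl], v[sl]
    ph_rbc = ph_rbc_from_plasma(ph_pl, config.constants)

    sp = _species_arrays(po2, pco2, ph_rbc, dpg, T, config.constants)
    odc_vals = sp[8]
    cdc_vals = sp[9]
    hdc_vals = sp[1] + sp[5] if config.hdc == "total" else sp[1]

    step = config.grid_step
    lo = math.ceil(po2[-1] / step) * step
    hi = math.floor(po2[0] / step) * step
    grid = lo + step * np.arange(int(round((hi - lo) / step)) + 1)
    # po2 decreases along v; reverse for interpolation
    xs = po2[::-1]
    out = {}
    for label, vals in (("ODC", odc_vals), ("CDC", cdc_vals), ("HDC", hdc_vals)):
        out[label] = DissociationCurve(
            grid,
            np.interp(grid, xs, vals[::-1]),
            label=label,
            provenance="in_vivo",
            meta={"v_range": [float(v[0]), float(v[-1])], "dpg": dpg, "temp_mode": temp_mode},
        )
    return out


@dataclass
class AnalysisReport:
    """Everything the exercise analysis computes, JSON-serializable."""

    dpg_used: float
    dpg_calibrated: bool
    temp_mode: str
    fit_degrees: dict
    fit_coefficients: dict
    per_sample: list
    in_vivo: dict
    bland_altman: BlandAltmanResult
    config: dict
    flags: list

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["bland_altman"] = dataclasses.asdict(self.bland_altman)
        return d


def run_analysis(
    series: list[ExerciseSample],
    config: PipelineConfig | None = None,
) -> AnalysisReport:
    """Full pipeline: fit, calibrate, curves, inflections, intersection."""
    config = config or PipelineConfig()
    _validate_series(series)
    flags: list[str] = []

    if config.calibrate:
        dpg = calibrate_dpg(series, config.temp_mode, config.dpg_bounds, config)
    else:
        dpg = config.dpg

    traj = fit_trajectories(series, config)
    states = per_sample_states(series, dpg, config.temp_mode, config)
    sim = simulated_so2(series, dpg, config.temp_mode, config)
    meas = np.array([s.SO2_measured for s in series])
    ba = bland_altman(meas, sim)

    per_sample = []
    for s, st, so2 in zip(series, states, sim):
        entry = {
            "pct_vo2max": s.pct_vo2max,
            "PO2": s.PO2,
            "PCO2": s.PCO2,
            "pH_rbc": st.pH_rbc,
            "T": st.T,
            "SO2_measured": s.SO2_measured,
            "SO2_simulated": float(so2),
        }
        curve = in_vitro_curve(st, "ODC", constants=config.constants)
        try:
            infl = find_inflection(curve, config.inflection_window)
            entry["invitro_odc_inflection_po2"] = infl.PO2
            entry["invitro_odc_inflection_saturation"] = infl.value
        except ValueError as e:  # pragma: no cover - smooth model curves inflect
            flags.append(f"in vitro inflection failed at {s.pct_vo2max}%: {e}")
        per_sample.append(entry)

    in_vivo: dict = {}
    try:
        curves = in_vivo_curves(traj, dpg, config.temp_mode, config)
        for label, curve in curves.items():
            try:
                band = (0.2, 0.6) if label == "ODC" else (0.0, 1.0)
                infl = find_inflection(curve, config.inflection_window, value_band=band)
                in_vivo[f"{label.lower()}_inflection_po2"] = infl.PO2
                in_vivo[f"{label.lower()}_inflection_value"] = infl.value
            except ValueError as e:
                flags.append(f"in vivo {label} inflection: {e}")
        try:
            in_vivo["cdc_hdc_intersection_po2"] = find_intersection(
                curves["CDC"], curves["HDC"]
            )
        except ValueError as e:
            flags.append(f"CDC-HDC intersection: {e}")
        in_vivo["po2_range"] = [float(curves["ODC"].grid[0]), float(curves["ODC"].grid[-1])]
    except ValueError as e:
        flags.append(f"in vivo curves: {e}")

    return AnalysisReport(
        dpg_used=float(dpg),
        dpg_calibrated=bool(config.calibrate),
        temp_mode=config.temp_mode,
        fit_degrees=traj.degrees,
        fit_coefficients=traj.coefficients(),
        per_sample=per_sample,
        in_vivo=in_vivo,
        bland_altman=ba,
        config=config.to_dict(),
        flags=flags,
    )


_DELTA_KEYS = (
    "odc_inflection_po2",
    "cdc_inflection_po2",
    "hdc_inflection_po2",
    "cdc_hdc_intersection_po2",
)


def sensitivity_analysis(
    series: list[ExerciseSample],
    config: PipelineConfig | None = None,
    scenarios: dict[str, PipelineConfig] | None = None,
) -> dict:
    """Re-run the analysis under alternative scenarios and report PO2 shifts.

    The default scenario fixes temperature at 37 degC and re-calibrates
    [2,3-DPG], mirroring the robustness check of the temperature-ramp
    assumption.
    """
    config = config or PipelineConfig()
    baseline = run_analysis(series, config)
    if scenarios is None:
        scenarios = {"fixed_T": config.replace(temp_mode="fixed", calibrate=True)}
    out = {"baseline": baseline, "scenarios": {}}
    for name, scen_cfg in scenarios.items():
        rep = run_analysis(series, scen_cfg)
        deltas = {}
        for key in _DELTA_KEYS:
            if key in baseline.in_vivo and key in rep.in_vivo:
                deltas[key] = rep.in_vivo[key] - baseline.in_vivo[key]
        deltas["bland_altman_bias"] = rep.bland_altman.mean_bias - baseline.bland_altman.mean_bias
        out["scenarios"][name] = {"report": rep, "deltas": deltas}
    return out
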