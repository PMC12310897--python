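"""Synthetic incremental-exercise blood-gas series with known ground truth.

The generator emulates the statistical structure of pooled femoral-venous
sampling during an incremental cycling test: an S-shaped monotone PO2
decline approaching a plateau near the critical capillary PO2, a monotone
PCO2 rise, a pH decline that accelerates past a threshold intensity, and a
measured O2Hb saturation produced by running the noise-free chemistry
through the equilibrium model at a generator-chosen true [2,3-DPG].
Additive, channel-independent Gaussian noise is applied on top, so every
pipeline stage has a recoverable truth (including the noise-free in vivo ODC
and its brute-force inflection point).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .constants import ModelConstants
from .model import _saturation_arrays, ph_rbc_from_plasma
from .pipeline import ExerciseSample, write_series

__all__ = ["GeneratorSpec", "SyntheticTruth", "generate", "write_truth", "write_synthetic_run"]

_DEFAULT = ModelConstants()


@dataclass(frozen=True)
class GeneratorSpec:
    """Shapes, noise levels and seed of a synthetic exercise test.

    Units: PO2/PCO2 in mmHg, pH dimensionless, saturation in percentage
    points, intensities in %VO2max, [2,3-DPG] in M, temperatures in degC.
    Defaults span physiologic femoral-venous ranges: PO2 falling from the
    low 40s towards a ~20 mmHg plateau, PCO2 rising into the 70s, pH
    drifting down from 7.38 with an accelerating drop past the threshold.
    """

    n_samples: int = 12
    pct_start: float = 0.0
    pct_end: float = 100.0
    # logistic PO2 decline: upper asymptote, plateau, midpoint (%), width (%).
    # The plateau sits at the lower end of reported end-exercise femoral
    # venous PO2 so the composite in vivo ODC retains a convex foot (and
    # hence an inflection point) below the Bohr-steepened mid-section.
    po2_start: float = 42.0
    po2_plateau: float = 15.0
    po2_midpoint: float = 35.0
    po2_steepness: float = 10.0
    # monotone PCO2 rise with mild curvature (power-law exponent)
    pco2_start: float = 46.0
    pco2_end: float = 72.0
    pco2_curvature: float = 1.3
    # pH: linear drift plus quadratic acceleration past the threshold
    ph_start: float = 7.38
    ph_slope: float = 5e-4
    ph_threshold: float = 60.0
    ph_quad: float = 1.6e-4
    # additive measurement noise SDs
    noise_po2: float = 0.5
    noise_pco2: float = 1.0
    noise_ph: float = 0.008
    noise_so2: float = 1.0
    # model-side truth
    true_dpg: float = 0.0029
    T_start: float = 37.0
    T_end: float = 38.0
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("need at least 2 samples")
        if not (self.po2_start > self.po2_plateau > 0):
            raise ValueError("require po2_start > po2_plateau > 0")
        if self.pco2_end <= self.pco2_start:
            raise ValueError("PCO2 must rise (pco2_end > pco2_start)")
        if min(self.noise_po2, self.noise_pco2, self.noise_ph, self.noise_so2) < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.ph_slope < 0 or self.ph_quad < 0:
            raise ValueError("pH profile must be non-increasing")

    def replace(self, **kw) -> "GeneratorSpec":
        return dataclasses.replace(self, **kw)

    # noise-free channel profiles -------------------------------------------
    def po2_of(self, v) -> np.ndarray:
        v = np.asarray(v, dtype=float)
        span = self.po2_start - self.po2_plateau
        return self.po2_plateau + span / (
            1.0 + np.exp((v - self.po2_midpoint) / self.po2_steepness)
        )

    def v_of_po2(self, po2) -> np.ndarray:
        """Analytic inverse of the logistic PO2 profile (strictly decreasing)."""
        po2 = np.asarray(po2, dtype=float)
        span = self.po2_start - self.po2_plateau
        return self.po2_midpoint + self.po2_steepness * np.log(
            span / (po2 - self.po2_plateau) - 1.0
        )

    def pco2_of(self, v) -> np.ndarray:
        v = np.asarray(v, dtype=float)
        frac = (v - self.pct_start) / (self.pct_end - self.pct_start)
        return self.pco2_start + (self.pco2_end - self.pco2_start) * frac**self.pco2_curvature

    def ph_of(self, v) -> np.ndarray:
        v = np.asarray(v, dtype=float)
        excess = np.clip(v - self.ph_threshold, 0.0, None)
        return self.ph_start - self.ph_slope * v - self.ph_quad * excess**2

    def temperature_of(self, v) -> np.ndarray:
        frac = (np.asarray(v, dtype=float) - self.pct_start) / (self.pct_end - self.pct_start)
        return self.T_start + (self.T_end - self.T_start) * frac


@dataclass
class SyntheticTruth:
    """Noise-free ground truth attached to a generated series."""

    samples: list  # noise-free ExerciseSamples
    true_dpg: float
    odc_grid: np.ndarray  # uniform PO2 grid of the noise-free in vivo ODC
    odc_values: np.ndarray
    inflection_po2: float  # brute-force scan of the noise-free in vivo ODC

    def to_dict(self) -> dict:
        return {
            "true_dpg": self.true_dpg,
            "inflection_po2": self.inflection_po2,
            "samples": [dataclasses.asdict(s) for s in self.samples],
        }


def _truth_so2(spec: GeneratorSpec, v: np.ndarray, constants: ModelConstants) -> np.ndarray:
    ph_rbc = ph_rbc_from_plasma(spec.ph_of(v), constants)
    s = _saturation_arrays(
        spec.po2_of(v), spec.pco2_of(v), ph_rbc, spec.true_dpg, spec.temperature_of(v), constants
    )[0]
    return 100.0 * s


def _truth_in_vivo_odc(
    samples: list, spec: GeneratorSpec, constants: ModelConstants, scan_step: float = 1e-3
) -> tuple[np.ndarray, np.ndarray, float]:
    """Noise-free in vivo ODC on a fine PO2 grid + brute-force inflection.

    The in vivo ODC is a property of the analysis construction (the model
    swept along cubic trajectory fits), so its ground truth is that same
    construction applied to the noise-free samples.  This routine is
    deliberately independent of the pipeline: plain ``np.polyfit`` cubics, a
    dense parametric sweep, and a 1e-3 mmHg grid scan of the
    central-difference second derivative.
    """
    v = np.array([s.pct_vo2max for s in samples], dtype=float)
    c_po2 = np.polyfit(v, [s.PO2 for s in samples], 3)
    c_pco2 = np.polyfit(v, [s.PCO2 for s in samples], 3)
    c_ph = np.polyfit(v, [s.pH_plasma for s in samples], 3)
    vv = np.linspace(v[0], v[-1], 200001)
    po2 = np.polyval(c_po2, vv)
    dec = np.diff(po2) < 0
    n_keep = (int(np.argmin(dec)) + 1) if not dec.all() else po2.size
    po2, vv = po2[:n_keep], vv[:n_keep]

    lo = float(np.ceil(po2[-1] / scan_step) * scan_step)
    hi = float(np.floor(po2[0] / scan_step) * scan_step)
    grid = lo + scan_step * np.arange(int(round((hi - lo) / scan_step)) + 1)
    # v(PO2) is monotone on the kept prefix; chemistry is then evaluated
    # exactly at the scan grid so the second derivative is interpolation-free
    v_grid = np.interp(grid, po2[::-1], vv[::-1])
    T = spec.T_start + (spec.T_end - spec.T_start) * (v_grid - v[0]) / (v[-1] - v[0])
    vals = _saturation_arrays(
        grid,
        np.polyval(c_pco2, v_grid),
        ph_rbc_from_plasma(np.polyval(c_ph, v_grid), constants),
        spec.true_dpg,
        T,
        constants,
    )[0]
    d2 = (vals[2:] - 2.0 * vals[1:-1] + vals[:-2]) / scan_step**2
    x = grid[1:-1]
    best = None
    for i in np.nonzero((d2[:-1] > 0) & (d2[1:] < 0))[0]:
        root = x[i] + scan_step * d2[i] / (d2[i] - d2[i + 1])
        value = np.interp(root, grid, vals)
        if 0.2 <= value <= 0.6:
            best = root
            break
        if best is None:
            best = root
    if best is None:
        raise RuntimeError("no inflection in the noise-free in vivo ODC")
    return grid, vals, float(best)


def generate(
    spec: GeneratorSpec | None = None, constants: ModelConstants = _DEFAULT
) -> tuple[list[ExerciseSample], SyntheticTruth]:
    """Generate a noisy series plus its noise-free truth bundle.

    Deterministic given ``spec.seed``; with all noise SDs zero the series
    lies exactly on the truth curves.
    """
    spec = spec or GeneratorSpec()
    rng = np.random.default_rng(spec.seed)
    v = np.linspace(spec.pct_start, spec.pct_end, spec.n_samples)

    po2 = spec.po2_of(v)
    pco2 = spec.pco2_of(v)
    ph = spec.ph_of(v)
    so2 = _truth_so2(spec, v, constants)

    clean = [
        ExerciseSample(float(a), float(b), float(c), float(d), float(e))
        for a, b, c, d, e in zip(v, po2, pco2, ph, so2)
    ]

    po2_n = np.maximum(po2 + rng.normal(0.0, spec.noise_po2, v.size), 1.0)
    pco2_n = np.maximum(pco2 + rng.normal(0.0, spec.noise_pco2, v.size), 1.0)
    ph_n = ph + rng.normal(0.0, spec.noise_ph, v.size)
    so2_n = np.clip(so2 + rng.normal(0.0, spec.noise_so2, v.size), 0.0, 100.0)
    noisy = [
        ExerciseSample(float(a), float(b), float(c), float(d), float(e))
        for a, b, c, d, e in zip(v, po2_n, pco2_n, ph_n, so2_n)
    ]

    grid, vals, infl = _truth_in_vivo_odc(clean, spec, constants)
    truth = SyntheticTruth(
        samples=clean,
        true_dpg=spec.true_dpg,
        odc_grid=grid,
        odc_values=vals,
        inflection_po2=infl,
    )
    return noisy, truth


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    """Write the truth sidecar JSON (scalars + noise-free samples)."""
    Path(path).write_text(json.dumps(truth.to_dict(), indent=1))


def write_synthetic_run(
    spec: GeneratorSpec, out_dir: str | Path, constants: ModelConstants = _DEFAULT
) -> tuple[Path, Path]:
    """Emit the pipeline input CSV and truth.json into ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    series, truth = generate(spec, constants)
    csv_path = out_dir / "series.csv"
    write_series(series, csv_path)
    truth_path = out_dir / "truth.json"
    write_truth(truth, truth_path)
    return csv_path, truth_path
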