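"""Sampled dissociation curves and their numerical analysis.

Curves are sampled on a fine uniform PO2 grid (default 0-100 mmHg, step
0.05 mmHg).  Inflection points are located where the central-difference
second derivative crosses zero from positive to negative (concave-up to
concave-down); curve intersections are roots of the difference of the two
linear interpolants.  Both are refined with a bracketed root solver to an
absolute tolerance of 1e-6 mmHg, so the results are deterministic and far
below the 0.01 mmHg scale at which they are reported.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from .constants import ModelConstants
from .model import BloodGasState, _saturation_arrays, _species_arrays

__all__ = [
    "DEFAULT_GRID_STEP",
    "DissociationCurve",
    "InflectionPoint",
    "NoInflectionError",
    "NoIntersectionError",
    "make_grid",
    "in_vitro_curve",
    "find_inflection",
    "find_intersection",
    "find_p50",
]

DEFAULT_GRID_STEP = 0.05  # mmHg
DEFAULT_WINDOW = (2.0, 80.0)  # mmHg search window for inflections

_DEFAULT = ModelConstants()


class NoInflectionError(ValueError):
    """The second derivative never crosses zero inside the search window."""


class NoIntersectionError(ValueError):
    """The two curves have no isolated crossing inside the window."""


@dataclass
class DissociationCurve:
    """A dissociation curve sampled over a strictly increasing PO2 grid.

    ``label`` is one of ODC (O2 saturation), CDC (carbamate fraction) or HDC
    (protonated-amine fraction); ``provenance`` records whether the curve was
    computed at one fixed blood chemistry (``in_vitro``) or along a changing
    exercise trajectory (``in_vivo``).
    """

    grid: np.ndarray
    values: np.ndarray
    label: str = "ODC"
    provenance: str = "in_vitro"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.grid.ndim != 1 or self.grid.shape != self.values.shape:
            raise ValueError("grid and values must be 1-D arrays of equal length")
        if self.grid.size < 50:
            raise ValueError(f"curve needs >= 50 samples, got {self.grid.size}")
        if not np.all(np.diff(self.grid) > 0):
            raise ValueError("PO2 grid must be strictly increasing")
        if np.any(self.values < -1e-9) or np.any(self.values > 1 + 1e-9):
            raise ValueError("curve values must be fractions in [0, 1]")

    def __call__(self, po2) -> np.ndarray:
        """Linear interpolation of the curve at arbitrary PO2."""
        return np.interp(po2, self.grid, self.values)

    @property
    def step(self) -> float:
        return float(self.grid[1] - self.grid[0])

    def to_csv(self, path: str | Path) -> None:
        """Write the curve as two-column CSV with a JSON sidecar for labels."""
        path = Path(path)
        header = "po2_mmHg,value"
        np.savetxt(
            path,
            np.column_stack([self.grid, self.values]),
            delimiter=",",
            header=header,
            comments="",
            fmt="%.17g",
        )
        sidecar = {"label": self.label, "provenance": self.provenance, "meta": self.meta}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_csv(cls, path: str | Path) -> "DissociationCurve":
        path = Path(path)
        arr = np.loadtxt(path, delimiter=",", skiprows=1)
        kw = {}
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            kw = {
                "label": meta.get("label", "ODC"),
                "provenance": meta.get("provenance", "in_vitro"),
                "meta": meta.get("meta", {}),
            }
        return cls(arr[:, 0], arr[:, 1], **kw)


@dataclass(frozen=True)
class InflectionPoint:
    """Location of a concave-up to concave-down curvature change."""

    PO2: float
    value: float
    second_derivative_bracket: tuple[float, float]


def make_grid(lo: float = 0.0, hi: float = 100.0, step: float = DEFAULT_GRID_STEP) -> np.ndarray:
    """Uniform PO2 grid including both endpoints."""
    n = int(round((hi - lo) / step))
    return lo + step * np.arange(n + 1)


def in_vitro_curve(
    state: BloodGasState,
    quantity: str = "ODC",
    grid: np.ndarray | None = None,
    constants: ModelConstants = _DEFAULT,
) -> DissociationCurve:
    """Dissociation curve at one fixed blood chemistry, varying only PO2.

    ODC: S_HbO2(PO2).  CDC: S_HbCO2(PO2), the carbamate-bound fraction, which
    falls with PO2 (Haldane effect).  HDC: the protonated-amine fraction
    f_HbNH3+ + f_O2HbNH3+ (``quantity='HDC_deoxy'`` restricts to the deoxy
    species f_HbNH3+ alone).
    """
    if grid is None:
        grid = make_grid()
    grid = np.asarray(grid, dtype=float)
    args = (grid, state.PCO2, state.pH_rbc, state.DPG, state.T, constants)
    if quantity == "ODC":
        vals = _saturation_arrays(*args)[0]
    elif quantity == "CDC":
        vals = _saturation_arrays(*args)[1]
    elif quantity in ("HDC", "HDC_total"):
        sp = _species_arrays(*args)
        vals = sp[1] + sp[5]
    elif quantity == "HDC_deoxy":
        vals = _species_arrays(*args)[1]
    else:
        raise ValueError(f"unknown quantity {quantity!r}")
    return DissociationCurve(
        grid,
        vals,
        label="HDC" if quantity.startswith("HDC") else quantity,
        provenance="in_vitro",
        meta={"state": {"PCO2": state.PCO2, "pH_rbc": state.pH_rbc, "DPG": state.DPG, "T": state.T}},
    )


def _second_derivative(curve: DissociationCurve) -> np.ndarray:
    """Central-difference second derivative at interior grid points."""
    y, h = curve.values, curve.step
    if not np.allclose(np.diff(curve.grid), h, rtol=0, atol=1e-9 * h):
        raise ValueError("second derivative requires a uniform grid")
    return (y[2:] - 2.0 * y[1:-1] + y[:-2]) / h**2


def find_inflection(
    curve: DissociationCurve,
    window: tuple[float, float] = DEFAULT_WINDOW,
    value_band: tuple[float, float] = (0.2, 0.6),
) -> InflectionPoint:
    """Locate the inflection point: the +- zero crossing of the curvature.

    The second derivative is computed by central differences on the uniform
    grid; the zero of its linear interpolant is refined by a bracketed root
    solver.  If several concave-up to concave-down crossings exist, the one
    whose curve value falls inside ``value_band`` is preferred (the
    physiological ODC inflection sits near 36% saturation); remaining ties go
    to the lowest PO2 with a warning.
    """
    d2 = _second_derivative(curve)
    x = curve.grid[1:-1]
    lo = max(window[0], x[0])
    hi = min(window[1], x[-1])
    if hi <= lo:
        raise NoInflectionError("search window does not overlap the curve interior")
    mask = (x >= lo) & (x <= hi)
    xs, d2s = x[mask], d2[mask]
    if xs.size < 3:
        raise NoInflectionError("too few interior grid points in the window")

    # curvature below the round-off floor of the finite-difference stencil is
    # indistinguishable from zero (a straight line is "no inflection", not
    # thousands of noise crossings)
    tol = 64.0 * np.finfo(float).eps * max(1.0, float(np.max(np.abs(curve.values)))) / curve.step**2
    crossings = []
    for i in range(xs.size - 1):
        a, b = d2s[i], d2s[i + 1]
        if a > tol and b < -tol:
            root = xs[i] + (xs[i + 1] - xs[i]) * a / (a - b)
            crossings.append((root, (float(xs[i]), float(xs[i + 1]))))
        elif abs(a) <= tol and i > 0 and d2s[i - 1] > tol and b < -tol:
            crossings.append((float(xs[i]), (float(xs[i - 1]), float(xs[i + 1]))))
    if not crossings:
        raise NoInflectionError(
            f"no concave-up to concave-down curvature change in [{lo:g}, {hi:g}] mmHg"
        )
    if len(crossings) > 1:
        in_band = [c for c in crossings if value_band[0] <= curve(c[0]) <= value_band[1]]
        if len(in_band) == 1:
            crossings = in_band
        else:
            if in_band:
                crossings = in_band
            warnings.warn(
                f"{len(crossings)} candidate inflections; choosing the lowest PO2",
                stacklevel=2,
            )
            crossings.sort(key=lambda c: c[0])
            crossings = crossings[:1]
    root, bracket = crossings[0]
    # refine on the linear interpolant of d2 (root is already exact for a
    # linear interpolant; brentq guards against ties at grid nodes)
    f = lambda z: np.interp(z, xs, d2s)
    if f(bracket[0]) * f(bracket[1]) < 0:
        root = brentq(f, bracket[0], bracket[1], xtol=1e-6)
    return InflectionPoint(float(root), float(curve(root)), bracket)


def find_intersection(
    curveA: DissociationCurve,
    curveB: DissociationCurve,
    window: tuple[float, float] | None = None,
) -> float:
    """PO2 at which two curves cross, via their linear interpolants.

    Evaluates the difference of the interpolants on the union of both grids
    restricted to the overlap (or ``window``), brackets sign changes, and
    refines the root to 1e-6 mmHg.  With several crossings the one at highest
    PO2 is returned with a warning (during exercise PO2 falls, so this is the
    crossing encountered first).
    """
    lo = max(curveA.grid[0], curveB.grid[0])
    hi = min(curveA.grid[-1], curveB.grid[-1])
    if window is not None:
        lo, hi = max(lo, window[0]), min(hi, window[1])
    if hi <= lo:
        raise NoIntersectionError("curves do not overlap on the requested window")
    xs = np.union1d(curveA.grid, curveB.grid)
    xs = xs[(xs >= lo) & (xs <= hi)]
    diff = curveA(xs) - curveB(xs)

    brackets = []
    for i in range(xs.size - 1):
        a, b = diff[i], diff[i + 1]
        if a * b < 0:
            brackets.append((xs[i], xs[i + 1]))
        elif a == 0 and (i == 0 or diff[i - 1] != 0) and b != 0:
            brackets.append((xs[i], xs[i]))
    if diff[-1] == 0 and xs.size > 1 and diff[-2] != 0:
        brackets.append((xs[-1], xs[-1]))
    if not brackets:
        if np.all(diff == 0):
            raise NoIntersectionError("curves are identical: no isolated crossing")
        raise NoIntersectionError(f"no crossing in [{lo:g}, {hi:g}] mmHg")
    if len(brackets) > 1:
        warnings.warn(
            f"{len(brackets)} crossings found; returning the one at highest PO2",
            stacklevel=2,
        )
    a, b = max(brackets, key=lambda br: br[1])
    if a == b:
        return float(a)
    f = lambda z: float(curveA(z) - curveB(z))
    return float(brentq(f, a, b, xtol=1e-6))


def find_p50(
    state: BloodGasState,
    constants: ModelConstants = _DEFAULT,
    bracket: tuple[float, float] = (1e-6, 100.0),
) -> float:
    """Half-saturation PO2 by root search on S_HbO2(PO2) - 1/2.

    Must agree with the closed-form shift-product P50 to well below 1e-6
    mmHg; kept as an independent cross-check of the Hill closure.
    """

    def f(po2: float) -> float:
        s = _saturation_arrays(po2, state.PCO2, state.pH_rbc, state.DPG, state.T, constants)[0]
        return float(s) - 0.5

    return float(brentq(f, bracket[0], bracket[1], xtol=1e-9))
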