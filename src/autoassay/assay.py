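"""Deterministic microplate-assay arithmetic.

Covers the bookkeeping around an NADH-coupled kinetic assay in a 96-well
plate:

* mixture-volume planning to a fixed end volume (225 ul by default, the
  standard recipe volume), with per-component stock concentrations and
  pipettable-volume limits;
* the two-buffer pH system: a monotone spline calibration between the
  basic-stock fraction of a TRIS/MES mixture and the resulting pH;
* slope extraction from A340 kinetic traces by windowed linear regression;
* the NADH molar-absorption calibration (epsilon) from a standard curve
  and conversion of trace slopes to activities, including the per-mg
  Bradford normalization  act_per_mg = act_total / (coeff * A_BF * V_lysate).

Activity unit: mU = nmol NADH consumed per minute in the well, so
act_total [mU] = |slope| [A340/min] / epsilon [A340 per mM] * V_well [ul].
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence
import warnings

import numpy as np
import pandas as pd
import yaml
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq
from scipy.stats import linregress

from .errors import (InfeasibleMixtureError, InsufficientDataError,
                     InvalidArgumentError, OutOfRangeError, PrecisionError,
                     WindowTooStrictError)

__all__ = [
    "StockComponent",
    "WellPlan",
    "BufferCalibration",
    "KineticTrace",
    "EpsilonCalibration",
    "ActivityResult",
    "plan_mixture_volumes",
    "buffer_fraction_for_pH",
    "extract_slope",
    "calibrate_epsilon",
    "compute_activity",
    "synthetic_buffer_calibration",
    "traces_to_csv",
    "traces_from_csv",
]

DEFAULT_END_VOLUME = 225.0   # ul
DEFAULT_MIN_VOLUME = 3.0     # ul, smallest reliably pipettable nonzero volume


@dataclass(frozen=True)
class StockComponent:
    """A pipettable stock: concentration [mM] and volume limits [ul]."""

    name: str
    stock_conc: float
    min_volume: float = DEFAULT_MIN_VOLUME
    max_volume: float = np.inf
    fixed_volume: float | None = None

    def __post_init__(self) -> None:
        if self.fixed_volume is None and self.stock_conc <= 0:
            raise InvalidArgumentError(f"{self.name}: stock_conc must be > 0")
        if self.min_volume < 0 or self.min_volume > self.max_volume:
            raise InvalidArgumentError(
                f"{self.name}: need 0 <= min_volume <= max_volume"
            )


@dataclass
class WellPlan:
    """Per-component volumes plus water, summing exactly to the end volume."""

    volumes: dict[str, float]
    water: float
    end_volume: float = DEFAULT_END_VOLUME

    def __post_init__(self) -> None:
        if self.water < 0:
            raise InfeasibleMixtureError("water volume is negative")
        total = sum(self.volumes.values()) + self.water
        if abs(total - self.end_volume) > 1e-9:
            raise InfeasibleMixtureError(
                f"volumes sum to {total} ul, not {self.end_volume} ul"
            )


def plan_mixture_volumes(components: Sequence[StockComponent],
                         targets: Mapping[str, float],
                         end_volume: float = DEFAULT_END_VOLUME) -> WellPlan:
    """Volumes achieving the target final concentrations [mM] in one well.

    volume_i = target_i * end_volume / stock_i, or the component's fixed
    volume; water fills to the end volume.  Raises
    :class:`InfeasibleMixtureError` when volumes cannot fit and
    :class:`PrecisionError` when a nonzero volume falls below the
    component's minimum pipettable volume.
    """
    known = {c.name for c in components}
    unknown = set(targets) - known
    if unknown:
        raise InvalidArgumentError(f"targets for unknown components: {unknown}")
    volumes: dict[str, float] = {}
    for c in components:
        if c.fixed_volume is not None:
            v = float(c.fixed_volume)
        else:
            tgt = float(targets.get(c.name, 0.0))
            if tgt < 0:
                raise InvalidArgumentError(f"{c.name}: negative target")
            v = tgt * end_volume / c.stock_conc
        if v > 0 and v < c.min_volume:
            raise PrecisionError(
                f"{c.name}: volume {v:.3g} ul below minimum pipettable "
                f"{c.min_volume} ul"
            )
        if v > c.max_volume:
            raise InfeasibleMixtureError(
                f"{c.name}: volume {v:.3g} ul exceeds maximum {c.max_volume} ul"
            )
        volumes[c.name] = v
    total = sum(volumes.values())
    if total > end_volume + 1e-9:
        raise InfeasibleMixtureError(
            f"component volumes sum to {total:.3g} ul > end volume "
            f"{end_volume} ul"
        )
    water = end_volume - total
    return WellPlan(volumes=volumes, water=water, end_volume=end_volume)


def stocks_from_yaml(path) -> list[StockComponent]:
    with open(path) as fh:
        entries = yaml.safe_load(fh)
    out = []
    for e in entries:
        out.append(StockComponent(
            name=e["name"], stock_conc=float(e.get("stock_conc", 1.0)),
            min_volume=float(e.get("min_volume", DEFAULT_MIN_VOLUME)),
            max_volume=float(e.get("max_volume", np.inf)),
            fixed_volume=(float(e["fixed_volume"])
                          if e.get("fixed_volume") is not None else None),
        ))
    return out


# ---------------------------------------------------------------------------
# two-buffer pH calibration
# ---------------------------------------------------------------------------

@dataclass
class BufferCalibration:
    """Monotone spline between basic-buffer fraction and measured pH."""

    points: list[tuple[float, float]]   # (basic_fraction in [0,1], pH)
    _forward: PchipInterpolator = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        pts = sorted(self.points)
        f = np.array([p[0] for p in pts])
        pH = np.array([p[1] for p in pts])
        if len(pts) < 4:
            raise InsufficientDataError("need >= 4 calibration points")
        if np.any(np.diff(f) <= 0) or not (np.all(np.diff(pH) > 0)
                                           or np.all(np.diff(pH) < 0)):
            raise InvalidArgumentError(
                "calibration must be strictly monotone in fraction"
            )
        self.points = pts
        self._forward = PchipInterpolator(f, pH)

    @property
    def pH_range(self) -> tuple[float, float]:
        vals = [p[1] for p in self.points]
        return min(vals), max(vals)

    def pH_of_fraction(self, fraction: float) -> float:
        if not 0.0 <= fraction <= 1.0:
            raise OutOfRangeError(f"fraction {fraction} outside [0, 1]")
        return float(self._forward(fraction))

    def fraction_of_pH(self, pH: float) -> float:
        lo, hi = self.pH_range
        if not lo - 1e-9 <= pH <= hi + 1e-9:
            raise OutOfRangeError(f"pH {pH} outside calibrated [{lo}, {hi}]")
        f0, f1 = self.points[0][0], self.points[-1][0]
        p0, p1 = float(self._forward(f0)), float(self._forward(f1))
        pH = min(max(pH, min(p0, p1)), max(p0, p1))  # clamp float fuzz
        if pH == p0:
            return float(f0)
        if pH == p1:
            return float(f1)
        return float(brentq(lambda f: self._forward(f) - pH, f0, f1,
                            xtol=1e-12))


def buffer_fraction_for_pH(cal: BufferCalibration, pH: float) -> float:
    """Basic-stock fraction producing the requested pH (inverse spline)."""
    return cal.fraction_of_pH(pH)


def synthetic_buffer_calibration(n_points: int = 16,
                                 pKa_acid: float = 6.15,
                                 pKa_base: float = 8.06,
                                 conc_M: float = 0.05,
                                 pH_low: float = 4.75,
                                 pH_high: float = 9.2) -> BufferCalibration:
    """Synthetic 16-point fraction->pH table for a TRIS/MES two-stock system.

    Synthetic stand-in for a measured calibration curve: both stocks hold
    the acid buffer (MES, pKa 6.15) and the base buffer (TRIS, pKa 8.06) at
    equal concentration, adjusted with strong acid/base to the two endpoint
    pH values; mixture pH follows from charge balance (Henderson-Hasselbalch
    for both buffers plus water).  Gives the nearly linear mid-range
    characteristic of this buffer system.
    """
    Ka_a, Ka_b = 10.0 ** -pKa_acid, 10.0 ** -pKa_base
    Kw = 1e-14

    def net_strong_ion(pH: float) -> float:
        H = 10.0 ** -pH
        mes_anion = conc_M * Ka_a / (Ka_a + H)
        trisH = conc_M * H / (H + Ka_b)
        return mes_anion - trisH + Kw / H - H

    n_a, n_b = net_strong_ion(pH_low), net_strong_ion(pH_high)
    pts = []
    for f in np.linspace(0.0, 1.0, n_points):
        target = (1.0 - f) * n_a + f * n_b
        pH = brentq(lambda p: net_strong_ion(p) - target, 1.0, 13.0,
                    xtol=1e-12)
        pts.append((float(f), float(pH)))
    return BufferCalibration(points=pts)


# ---------------------------------------------------------------------------
# kinetic traces and activities
# ---------------------------------------------------------------------------

@dataclass
class KineticTrace:
    """A340 absorbance time series for one well; times in seconds."""

    times: np.ndarray
    a340: np.ndarray
    well_id: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.a340 = np.asarray(self.a340, dtype=float)
        if self.times.size != self.a340.size or self.times.size < 2:
            raise InvalidArgumentError("need |times| = |a340| >= 2")
        if np.any(np.diff(self.times) <= 0):
            raise InvalidArgumentError("times must be strictly increasing")


@dataclass
class SlopeResult:
    slope: float                 # A340 per minute
    window: tuple[float, float]  # first/last time [s] used
    n_points: int


def extract_slope(trace: KineticTrace,
                  min_od: float = -np.inf, max_od: float = np.inf,
                  t_min: float = -np.inf, t_max: float = np.inf) -> SlopeResult:
    """OLS slope [A340/min] over the OD/time window of a kinetic trace.

    Points are kept when min_od <= A340 <= max_od and t_min <= t <= t_max —
    the rule that excludes the depleted-substrate floor and detector
    saturation from the regression.
    """
    keep = ((trace.a340 >= min_od) & (trace.a340 <= max_od)
            & (trace.times >= t_min) & (trace.times <= t_max))
    if keep.sum() < 2:
        raise WindowTooStrictError(
            f"only {int(keep.sum())} trace points survive the window"
        )
    t, a = trace.times[keep], trace.a340[keep]
    if np.ptp(t) == 0:
        raise WindowTooStrictError("surviving points share one time stamp")
    res = linregress(t, a)
    return SlopeResult(slope=float(res.slope) * 60.0,
                       window=(float(t[0]), float(t[-1])),
                       n_points=int(keep.sum()))


@dataclass
class EpsilonCalibration:
    """NADH absorbance-per-concentration coefficient under assay geometry."""

    epsilon: float   # A340 per mM NADH in the well
    r2: float
    intercept: float = 0.0

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise InvalidArgumentError("epsilon must be > 0")


def calibrate_epsilon(standards: Sequence[tuple[float, float]]
                      ) -> EpsilonCalibration:
    """epsilon from a standard curve of (conc [mM], A340) pairs.

    Least-squares line with free intercept (the plate blank); the slope is
    epsilon.  Requires >= 3 standards at >= 2 distinct concentrations.
    """
    if len(standards) < 3:
        raise InsufficientDataError("need >= 3 standards")
    c = np.array([s[0] for s in standards], dtype=float)
    a = np.array([s[1] for s in standards], dtype=float)
    if len(np.unique(c)) < 2:
        raise InsufficientDataError("standards at >= 2 distinct concentrations")
    res = linregress(c, a)
    return EpsilonCalibration(epsilon=float(res.slope),
                              r2=float(res.rvalue ** 2),
                              intercept=float(res.intercept))


@dataclass
class ActivityResult:
    act_total: float            # mU (nmol NADH/min in the well)
    act_per_mg: float | None    # mU per mg protein
    slope: float                # A340/min
    window: tuple[float, float] | None = None


def compute_activity(slope: float, eps: EpsilonCalibration,
                     bradford_a: float | None = None,
                     bradford_coeff: float | None = None,
                     lysate_volume: float | None = None,
                     well_volume: float = DEFAULT_END_VOLUME,
                     window: tuple[float, float] | None = None
                     ) -> ActivityResult:
    """Convert a trace slope to total and per-mg activity.

    act_total = |slope| / epsilon * well_volume  (mM/min * ul = nmol/min = mU;
    NADH consumption gives a negative slope, hence the absolute value).
    act_per_mg = act_total / (bradford_coeff * bradford_a * lysate_volume);
    reported as None, with a warning, when the protein amount is missing or
    non-positive.
    """
    act_total = abs(slope) / eps.epsilon * well_volume
    act_per_mg: float | None = None
    if None not in (bradford_a, bradford_coeff, lysate_volume):
        protein_mg = bradford_coeff * bradford_a * lysate_volume
        if protein_mg > 0:
            act_per_mg = act_total / protein_mg
        else:
            warnings.warn("non-positive protein amount; per-mg activity "
                          "not reported", stacklevel=2)
    return ActivityResult(act_total=float(act_total), act_per_mg=act_per_mg,
                          slope=float(slope), window=window)


# ---------------------------------------------------------------------------
# trace I/O (long-format CSV: well_id, t_s, a340)
# ---------------------------------------------------------------------------

def traces_to_csv(traces: Sequence[KineticTrace], path) -> None:
    frames = [pd.DataFrame({"well_id": tr.well_id, "t_s": tr.times,
                            "a340": tr.a340}) for tr in traces]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def traces_from_csv(path) -> list[KineticTrace]:
    df = pd.read_csv(path)
    out = []
    for wid, grp in df.groupby("well_id", sort=False):
        grp = grp.sort_values("t_s")
        out.append(KineticTrace(times=grp["t_s"].to_numpy(),
                                a340=grp["a340"].to_numpy(),
                                well_id=str(wid)))
    return out
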