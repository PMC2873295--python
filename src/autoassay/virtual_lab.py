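"""Virtual liquid-handling robot and plate reader.

A synthetic stand-in for the physical instrument stack: given a
ground-truth diprotic enzyme, it synthesizes A340 kinetic traces for
requested conditions — NADH consumption at the enzyme's rate plus a small
pH-dependent spontaneous-oxidation background, pipetting noise on the
dispensed concentrations and photometric noise on each reading — and runs
the full measurement pipeline (trace -> slope -> activity) so every other
module can be exercised in a closed loop without hardware.

The background model reflects the observed behaviour of blank wells: a
constant low oxidation rate with a small extra component growing linearly
below a knee pH (default 5.5), always far below the enzymatic signal.

Allosteric-effector axes (e.g. KCl, fructose 1,6-bisphosphate) for which
no mechanistic model exists are emulated as smooth multiplicative activity
factors: log-shaped bumps peaking at a configurable optimum with decline
at high concentration, matching the rise-and-fall profiles seen in
measured response surfaces.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .assay import (DEFAULT_END_VOLUME, EpsilonCalibration, KineticTrace,
                    compute_activity, extract_slope)
from .design import Condition, Design
from .errors import InvalidConditionError
from .kinetics import DiproticParams, diprotic_rate

__all__ = [
    "Background",
    "ModulatorEffect",
    "GroundTruth",
    "background_rate",
    "enzyme_rate",
    "simulate_trace",
    "measure_design",
    "make_evaluator",
]

#: Table-like reference constants of the yeast pyruvate-kinase diprotic fit,
#: with a per-well Vmax (2.5 mU ~ 0.2 ug lysate protein per well) so traces
#: stay measurable over a 30-cycle read.
DEFAULT_ENZYME = dict(Vmax=2.5, KM=0.53, K1E=1.9e-6, K2E=4.4e-9,
                      K1ES=2.2e-6, K2ES=9.6e-9, alpha=0.16, beta=0.0)


@dataclass(frozen=True)
class Background:
    """pH-dependent spontaneous NADH oxidation [A340/min]."""

    base_rate: float = 1e-5
    low_pH_extra: float = 4e-5   # extra per pH unit below the knee
    pH_knee: float = 5.5

    def __post_init__(self) -> None:
        if self.base_rate < 0 or self.low_pH_extra < 0:
            raise ValueError("background rates must be >= 0")


@dataclass(frozen=True)
class ModulatorEffect:
    """Smooth multiplicative activity factor for one effector axis.

    factor(c) = floor + (1 - floor) * exp(-(u - u_opt)^2 / (2 w^2)) with
    u = log(1 + c); peaks (factor = 1) exactly at c_opt, declines toward
    ``floor`` at 0 and at high concentration.
    """

    name: str
    c_opt: float
    width: float = 0.8
    floor: float = 0.05

    def factor(self, c) -> np.ndarray:
        u = np.log1p(np.asarray(c, dtype=float))
        u0 = np.log1p(self.c_opt)
        bump = np.exp(-((u - u0) ** 2) / (2.0 * self.width**2))
        return self.floor + (1.0 - self.floor) * bump


@dataclass
class GroundTruth:
    """Virtual enzyme plus instrument and noise model."""

    enzyme: DiproticParams = field(
        default_factory=lambda: DiproticParams(**DEFAULT_ENZYME))
    epsilon: float = 0.62          # A340 per mM NADH in the well
    blank: float = 0.04            # plate/lid blank absorbance
    nadh0: float = 0.625           # mM NADH in the well at t = 0
    background: Background = field(default_factory=Background)
    pipetting_cv: float = 0.02     # log-normal CV per dispensed component
    photometric_sd: float = 0.003  # A340 per reading
    well_volume: float = DEFAULT_END_VOLUME  # ul
    s_default: float = 1.0         # mM PEP when the design has no PEP axis
    modulators: list[ModulatorEffect] = field(default_factory=list)
    cycles: int = 30
    interval: float = 60.0         # s
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epsilon <= 0 or self.nadh0 <= 0 or self.well_volume <= 0:
            raise ValueError("epsilon, nadh0 and well_volume must be > 0")
        if self.pipetting_cv < 0 or self.photometric_sd < 0:
            raise ValueError("noise parameters must be >= 0")

    # -- serialisation ----------------------------------------------------
    def to_yaml(self, path) -> None:
        payload = {
            "enzyme": self.enzyme.as_dict(),
            "epsilon": self.epsilon, "blank": self.blank,
            "nadh0": self.nadh0,
            "background": {"base_rate": self.background.base_rate,
                           "low_pH_extra": self.background.low_pH_extra,
                           "pH_knee": self.background.pH_knee},
            "pipetting_cv": self.pipetting_cv,
            "photometric_sd": self.photometric_sd,
            "well_volume": self.well_volume, "s_default": self.s_default,
            "modulators": [{"name": m.name, "c_opt": m.c_opt,
                            "width": m.width, "floor": m.floor}
                           for m in self.modulators],
            "cycles": self.cycles, "interval": self.interval,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GroundTruth":
        with open(path) as fh:
            p = yaml.safe_load(fh)
        return cls(
            enzyme=DiproticParams(**p["enzyme"]),
            epsilon=p.get("epsilon", 0.62), blank=p.get("blank", 0.04),
            nadh0=p.get("nadh0", 0.625),
            background=Background(**p.get("background", {})),
            pipetting_cv=p.get("pipetting_cv", 0.02),
            photometric_sd=p.get("photometric_sd", 0.003),
            well_volume=p.get("well_volume", DEFAULT_END_VOLUME),
            s_default=p.get("s_default", 1.0),
            modulators=[ModulatorEffect(**m) for m in p.get("modulators", [])],
            cycles=p.get("cycles", 30), interval=p.get("interval", 60.0),
            seed=p.get("seed", 0),
        )


def background_rate(truth: GroundTruth, pH: float) -> float:
    """Spontaneous NADH oxidation rate [A340/min] at the given pH.

    Constant above the knee; grows linearly below it; continuous at the
    knee.  Always small against the enzymatic signal at default settings.
    """
    bg = truth.background
    if pH >= bg.pH_knee:
        return bg.base_rate
    return bg.base_rate + bg.low_pH_extra * (bg.pH_knee - pH)


def _condition_inputs(truth: GroundTruth, condition: Condition
                      ) -> tuple[float, float, dict[str, float]]:
    vals = condition.values
    if "pH" not in vals:
        raise InvalidConditionError(
            f"condition {condition.id!r} lacks the required 'pH' axis"
        )
    pH = float(vals["pH"])
    S = float(vals.get("PEP", truth.s_default))
    mods = {m.name: float(vals[m.name]) for m in truth.modulators
            if m.name in vals}
    return pH, S, mods


def enzyme_rate(truth: GroundTruth, condition: Condition) -> float:
    """Noise-free activity [mU] of the virtual enzyme at a condition."""
    pH, S, mods = _condition_inputs(truth, condition)
    v = float(diprotic_rate(truth.enzyme, S, pH))
    for m in truth.modulators:
        if m.name in mods:
            v *= float(m.factor(mods[m.name]))
    return v


def true_optimum_condition(truth: GroundTruth, pH_grid=None) -> Condition:
    """The condition maximizing the noise-free virtual activity.

    Modulator axes peak exactly at their c_opt; the pH maximum is located
    on a fine grid (the enzyme's alpha/beta may be nonzero, so the closed
    form is not assumed).
    """
    if pH_grid is None:
        pH_grid = np.arange(2.0, 12.0, 1e-4)
    rates = diprotic_rate(truth.enzyme, truth.s_default, pH_grid)
    vals = {"pH": float(pH_grid[int(np.argmax(rates))])}
    for m in truth.modulators:
        vals[m.name] = m.c_opt
    return Condition(vals, id="truth-optimum")


def simulate_trace(truth: GroundTruth, condition: Condition,
                   cycles: int | None = None, interval: float | None = None,
                   seed: int = 0) -> KineticTrace:
    """Synthesize the A340 kinetic trace of one well.

    A340(t) = blank + epsilon * max(0, nadh0 - r * t) + photometric noise,
    where r [mM/min] combines the enzymatic consumption v/well_volume (v
    evaluated at the pipetting-noise-perturbed condition) and the
    background bg/epsilon.  The trace floors at the blank once NADH is
    depleted.  Seed-reproducible.
    """
    cycles = cycles or truth.cycles
    interval = interval or truth.interval
    rng = np.random.default_rng(seed)
    pH, S, mods = _condition_inputs(truth, condition)
    if truth.pipetting_cv > 0:
        S = S * rng.lognormal(mean=0.0, sigma=truth.pipetting_cv)
        mods = {k: v * rng.lognormal(mean=0.0, sigma=truth.pipetting_cv)
                for k, v in mods.items()}
    v = float(diprotic_rate(truth.enzyme, S, pH))
    for m in truth.modulators:
        if m.name in mods:
            v *= float(m.factor(mods[m.name]))
    conc_rate = v / truth.well_volume + background_rate(truth, pH) / truth.epsilon
    times = np.arange(cycles, dtype=float) * interval
    nadh = np.clip(truth.nadh0 - conc_rate * times / 60.0, 0.0, None)
    a340 = truth.blank + truth.epsilon * nadh
    if truth.photometric_sd > 0:
        a340 = a340 + rng.normal(0.0, truth.photometric_sd, size=a340.shape)
    return KineticTrace(times=times, a340=a340,
                        well_id=condition.id or "well")


def measure_design(truth: GroundTruth, design: Design,
                   seed: int = 0) -> pd.DataFrame:
    """Measure every condition of a design on the virtual instrument.

    Runs simulate -> windowed slope -> background-corrected activity for
    each well (one spawned random stream per well, so results are
    deterministic for a fixed seed) and returns a table with one activity
    [mU] per condition, directly usable as a campaign evaluator source.
    """
    eps = EpsilonCalibration(epsilon=truth.epsilon, r2=1.0,
                             intercept=truth.blank)
    ss = np.random.SeedSequence([seed, truth.seed])
    child_seeds = ss.generate_state(max(1, len(design.conditions)))
    rows = []
    for cond, cseed in zip(design.conditions, child_seeds):
        trace = simulate_trace(truth, cond, seed=int(cseed))
        sl = extract_slope(trace, min_od=truth.blank + 0.05, max_od=2.5)
        pH = float(cond.values["pH"])
        net = max(0.0, abs(sl.slope) - background_rate(truth, pH))
        act = compute_activity(net, eps, well_volume=truth.well_volume)
        row = {"id": cond.id}
        row.update({k: cond.values[k] for k in design.space.names})
        row["activity_mU"] = act.act_total
        rows.append(row)
    cols = ["id"] + design.space.names + ["activity_mU"]
    return pd.DataFrame(rows, columns=cols)


def make_evaluator(truth: GroundTruth, seed: int = 0):
    """A ``Condition -> activity`` callable for :func:`run_campaign`.

    Each call uses the next stream of a deterministic seed sequence, so a
    campaign replayed with identical config and seed sees identical noise.
    """
    eps = EpsilonCalibration(epsilon=truth.epsilon, r2=1.0,
                             intercept=truth.blank)
    counter = {"i": 0}

    def evaluate(condition: Condition) -> float:
        i = counter["i"]
        counter["i"] += 1
        cseed = int(np.random.SeedSequence([seed, truth.seed, i]).generate_state(1)[0])
        trace = simulate_trace(truth, condition, seed=cseed)
        sl = extract_slope(trace, min_od=truth.blank + 0.05, max_od=2.5)
        pH = float(condition.values["pH"])
        net = max(0.0, abs(sl.slope) - background_rate(truth, pH))
        act = compute_activity(net, eps, well_volume=truth.well_volume)
        return act.act_total

    return evaluate
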