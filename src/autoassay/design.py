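"""Parameter spaces and experimental designs.

A :class:`ParameterSpace` is an ordered set of bounded axes, each with a
scaling (linear, ``log`` for decade-spanning concentrations, or a custom
monotone map) that is applied *before* normalization to the unit cube. All
design generation, distance bookkeeping and surrogate modelling happen in
the normalized cube; conditions are stored in natural units.

Design generators:

* :func:`space_filling_design` — maximin Latin-hypercube sampling: a fixed
  number of seeded LHS draws is scored by minimum pairwise distance and the
  best draw kept.  Seed-reproducible.
* :func:`factorial_design` — full cross product of per-axis levels with
  replicates, in a deterministic order (replicates outermost, later axes
  varying fastest).
* :func:`cross_design` — cross an existing design with levels of one new
  axis (e.g. several substrate concentrations per space-filling point).
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.spatial.distance import pdist
from scipy.stats import qmc

from .errors import InvalidArgumentError, OutOfRangeError

__all__ = [
    "Axis",
    "ParameterSpace",
    "Condition",
    "Design",
    "space_filling_design",
    "factorial_design",
    "cross_design",
    "normalize_points",
    "denormalize_points",
]

#: number of seeded Latin-hypercube draws scored when building a maximin design
DEFAULT_LHS_CANDIDATES = 50

_BOUND_RTOL = 1e-9


@dataclass(frozen=True)
class Axis:
    """One bounded assay parameter (concentration axis or pH)."""

    name: str
    low: float
    high: float
    scaling: str | Callable[[float], float] = "linear"

    def __post_init__(self) -> None:
        if not np.isfinite(self.low) or not np.isfinite(self.high):
            raise InvalidArgumentError(f"axis {self.name!r}: bounds must be finite")
        if not self.high > self.low:
            raise InvalidArgumentError(
                f"axis {self.name!r}: high ({self.high}) must exceed low ({self.low})"
            )
        if self.scaling == "log" and self.low <= 0:
            raise InvalidArgumentError(
                f"axis {self.name!r}: log scaling requires low > 0"
            )
        if callable(self.scaling):
            probe = np.linspace(self.low, self.high, 65)
            vals = np.asarray([self.scaling(p) for p in probe], dtype=float)
            d = np.diff(vals)
            if not (np.all(d > 0) or np.all(d < 0)):
                raise InvalidArgumentError(
                    f"axis {self.name!r}: custom scaling must be strictly monotone"
                )
        elif self.scaling not in ("linear", "log"):
            raise InvalidArgumentError(
                f"axis {self.name!r}: unknown scaling {self.scaling!r}"
            )

    # -- scaled coordinate ------------------------------------------------
    def _f(self, x):
        if self.scaling == "linear":
            return np.asarray(x, dtype=float)
        if self.scaling == "log":
            return np.log10(np.asarray(x, dtype=float))
        f = np.vectorize(self.scaling, otypes=[float])
        return f(x)

    def normalize(self, x):
        """Map natural units -> [0, 1] (scaling applied first)."""
        flo, fhi = self._f(self.low), self._f(self.high)
        return (self._f(x) - flo) / (fhi - flo)

    def denormalize(self, t):
        """Map [0, 1] -> natural units (inverse of :meth:`normalize`)."""
        t = np.asarray(t, dtype=float)
        if self.scaling == "linear":
            return self.low + t * (self.high - self.low)
        if self.scaling == "log":
            llo, lhi = np.log10(self.low), np.log10(self.high)
            return 10.0 ** (llo + t * (lhi - llo))

        def invert(ti: float) -> float:
            if ti <= 0.0:
                return self.low
            if ti >= 1.0:
                return self.high
            return brentq(lambda x: self.normalize(x) - ti, self.low, self.high,
                          xtol=1e-14, rtol=1e-14)

        return np.vectorize(invert, otypes=[float])(t)

    def contains(self, x: float) -> bool:
        slack = _BOUND_RTOL * (self.high - self.low)
        return (self.low - slack) <= x <= (self.high + slack)


@dataclass(frozen=True)
class ParameterSpace:
    """Ordered, bounded, optionally scaled axes of an assay-parameter space."""

    axes: tuple[Axis, ...]

    def __post_init__(self) -> None:
        axes = tuple(self.axes)
        object.__setattr__(self, "axes", axes)
        names = [a.name for a in axes]
        if len(set(names)) != len(names):
            raise InvalidArgumentError(f"duplicate axis names: {names}")
        if not axes:
            raise InvalidArgumentError("a ParameterSpace needs at least one axis")

    @property
    def names(self) -> list[str]:
        return [a.name for a in self.axes]

    @property
    def dim(self) -> int:
        return len(self.axes)

    def axis(self, name: str) -> Axis:
        for a in self.axes:
            if a.name == name:
                return a
        raise InvalidArgumentError(f"no axis named {name!r}")

    # -- serialisation ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "axes": [
                {"name": a.name, "low": a.low, "high": a.high,
                 "scaling": a.scaling if isinstance(a.scaling, str) else "custom"}
                for a in self.axes
            ]
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ParameterSpace":
        axes = tuple(
            Axis(e["name"], float(e["low"]), float(e["high"]),
                 e.get("scaling", "linear"))
            for e in d["axes"]
        )
        return cls(axes)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ParameterSpace":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class Condition:
    """A named point in assay-parameter space, in natural units."""

    values: dict[str, float]
    id: str = ""
    replicate: int = 1
    meta: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise InvalidArgumentError("replicate index must be >= 1")


def validate_condition(space: ParameterSpace, cond: Condition) -> None:
    for ax in space.axes:
        if ax.name not in cond.values:
            raise OutOfRangeError(
                f"condition {cond.id!r} lacks a value for axis {ax.name!r}"
            )
        v = cond.values[ax.name]
        if not ax.contains(v):
            raise OutOfRangeError(
                f"condition {cond.id!r}: {ax.name}={v} outside "
                f"[{ax.low}, {ax.high}]"
            )


@dataclass
class Design:
    """An ordered collection of conditions over one parameter space."""

    space: ParameterSpace
    conditions: list[Condition]
    kind: str = "space_filling"

    def __post_init__(self) -> None:
        for c in self.conditions:
            validate_condition(self.space, c)

    def __len__(self) -> int:
        return len(self.conditions)

    def __iter__(self):
        return iter(self.conditions)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.conditions:
            row = {"id": c.id, "replicate": c.replicate,
                   "round": c.meta.get("round", 1)}
            row.update({n: c.values[n] for n in self.space.names})
            rows.append(row)
        cols = ["id", "replicate", "round"] + self.space.names
        return pd.DataFrame(rows, columns=cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, space: ParameterSpace, df: pd.DataFrame,
                   kind: str = "space_filling") -> "Design":
        conds = []
        for _, row in df.iterrows():
            vals = {n: float(row[n]) for n in space.names}
            conds.append(Condition(vals, id=str(row.get("id", "")),
                                   replicate=int(row.get("replicate", 1)),
                                   meta={"round": int(row.get("round", 1))}))
        return cls(space, conds, kind=kind)

    @classmethod
    def from_csv(cls, space: ParameterSpace, path,
                 kind: str = "space_filling") -> "Design":
        return cls.from_frame(space, pd.read_csv(path), kind=kind)


# ---------------------------------------------------------------------------
# point transforms
# ---------------------------------------------------------------------------

def normalize_points(space: ParameterSpace,
                     conditions: Sequence[Condition]) -> np.ndarray:
    """Conditions -> (n, d) matrix in the scaled unit cube.

    Raises :class:`OutOfRangeError` (naming axis and condition id) for any
    out-of-bounds value.
    """
    for c in conditions:
        validate_condition(space, c)
    if not conditions:
        return np.empty((0, space.dim))
    cols = [np.clip(ax.normalize([c.values[ax.name] for c in conditions]), 0.0, 1.0)
            for ax in space.axes]
    return np.column_stack(cols)


def denormalize_points(space: ParameterSpace, X: np.ndarray,
                       kind: str = "space_filling",
                       id_prefix: str = "pt") -> list[Condition]:
    """(n, d) unit-cube matrix -> conditions in natural units."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    conds = []
    for i, row in enumerate(X):
        vals = {ax.name: float(ax.denormalize(t))
                for ax, t in zip(space.axes, row)}
        conds.append(Condition(vals, id=f"{id_prefix}:{i}"))
    return conds


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def space_filling_design(space: ParameterSpace, n: int, seed: int = 0,
                         n_candidates: int = DEFAULT_LHS_CANDIDATES) -> Design:
    """Maximin Latin-hypercube design of ``n`` points in the scaled cube.

    ``n_candidates`` seeded LHS draws are scored by minimum pairwise
    Euclidean distance and the best is kept, so the design covers the full
    allowed range more evenly than uniform-random sampling. Deterministic
    for a fixed seed.
    """
    if n < 1:
        raise InvalidArgumentError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    best, best_score = None, -np.inf
    for _ in range(max(1, n_candidates)):
        sampler = qmc.LatinHypercube(d=space.dim, seed=rng)
        cand = sampler.random(n)
        score = pdist(cand).min() if n > 1 else 1.0
        if score > best_score:
            best, best_score = cand, score
    conds = denormalize_points(space, best, id_prefix="sf")
    return Design(space, conds, kind="space_filling")


def factorial_design(space: ParameterSpace,
                     levels: Mapping[str, Sequence[float]],
                     replicates: int = 1) -> Design:
    """Full factorial: every combination of per-axis levels x replicates.

    Ordering is deterministic: replicates outermost, axes in declaration
    order with the last-declared axis varying fastest.
    """
    if replicates < 1:
        raise InvalidArgumentError("replicates must be >= 1")
    for ax in space.axes:
        if ax.name not in levels:
            raise InvalidArgumentError(f"no levels given for axis {ax.name!r}")
        for v in levels[ax.name]:
            if not ax.contains(v):
                raise InvalidArgumentError(
                    f"level {v} outside bounds of axis {ax.name!r}"
                )
    grids = [list(levels[ax.name]) for ax in space.axes]
    conds = []
    serial = 0
    for rep in range(1, replicates + 1):
        for combo in itertools.product(*grids):
            vals = dict(zip(space.names, (float(v) for v in combo)))
            conds.append(Condition(vals, id=f"fact:{serial}", replicate=rep))
            serial += 1
    return Design(space, conds, kind="factorial")


def cross_design(design: Design, axis: Axis,
                 levels: Sequence[float]) -> Design:
    """Cross an existing design with levels of one additional axis.

    Used e.g. to measure several substrate concentrations at each point of
    a space-filling design over pH and effector axes. Levels vary fastest.
    """
    for v in levels:
        if not axis.contains(v):
            raise InvalidArgumentError(f"level {v} outside bounds of {axis.name!r}")
    new_space = ParameterSpace(design.space.axes + (axis,))
    conds = []
    serial = 0
    for c in design.conditions:
        for v in levels:
            vals = dict(c.values)
            vals[axis.name] = float(v)
            conds.append(Condition(vals, id=f"cross:{serial}",
                                   replicate=c.replicate))
            serial += 1
    return Design(new_space, conds, kind="factorial")
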